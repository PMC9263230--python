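"""Construction of the cis-eQTL genetic instrument.

Stages, in the order a practitioner runs them: restrict to the cis window
around the gene with a nominal P-value filter, intersect with the outcome
panel's available variants, prune-and-threshold LD clump, then compute
strength diagnostics (variance explained and the F statistic, with the
conventional F > 10 adequacy rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SummaryStatRecord, LDMatrix, logger


@dataclass
class GeneRegion:
    """A gene's span; the cis window is measured from these boundaries."""

    gene_id: str
    chrom: str
    start: int  # 1-based
    end: int    # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


@dataclass
class Instrument:
    """The selected, weighted variant set plus strength diagnostics.

    Weights are the exposure-study per-allele effects on (normalized)
    expression; a positive weight means the counted allele increases
    expression.
    """

    variants: list[SummaryStatRecord]
    weights: list[float]
    r2_explained: float
    f_statistic: float
    weak: bool

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.weights):
            raise ValueError("variants and weights length mismatch")

    @property
    def k(self) -> int:
        return len(self.variants)

    @classmethod
    def from_records(cls, records: list[SummaryStatRecord], n: int) -> "Instrument":
        r2 = estimate_r2_from_summary(records)
        f, weak = instrument_strength(r2, n, len(records))
        return cls(records, [r.beta for r in records], r2, f, weak)


def select_cis_variants(
    records: list[SummaryStatRecord],
    region: GeneRegion,
    window_bp: int = 500_000,
    p_threshold: float = 0.05,
) -> list[SummaryStatRecord]:
    """Keep variants inside the cis window with P strictly below threshold.

    The window is [start − window_bp, end + window_bp], inclusive at both
    boundaries.  Off-chromosome records are dropped up front (count logged).
    An empty result is fatal, with diagnostic counts of how many records
    failed each filter.
    """
    on_chrom = [r for r in records if r.chrom == region.chrom]
    n_off = len(records) - len(on_chrom)
    if n_off:
        logger.info("select_cis_variants: dropped %d off-chromosome record(s)", n_off)
    lo, hi = region.start - window_bp, region.end + window_bp
    in_window = [r for r in on_chrom if lo <= r.pos <= hi]
    kept = [r for r in in_window
            if r.pvalue is not None and r.pvalue < p_threshold]
    if not kept:
        raise ValueError(
            "no variants pass the cis filters: "
            f"{n_off} off-chromosome, {len(on_chrom) - len(in_window)} outside "
            f"[{lo}, {hi}], {len(in_window) - len(kept)} with P >= {p_threshold}"
        )
    logger.info("select_cis_variants: %d/%d variants retained", len(kept), len(records))
    return kept


def _clump_sort_key(r: SummaryStatRecord):
    # ties on P broken by larger |beta|, then lexicographic ID, so the result
    # is invariant to input row order
    return (r.pvalue, -abs(r.beta) if r.beta is not None else 0.0, r.variant_id)


def greedy_clump(
    records: list[SummaryStatRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.01,
) -> list[SummaryStatRecord]:
    """Prune-and-threshold clumping of a candidate variant list.

    Repeatedly select the remaining record with the smallest P value (ties:
    larger |beta|, then variant ID), then discard every remaining record in
    LD with it at r² > threshold.  Output preserves selection order and is
    maximal: no discarded variant could be re-added without violating the
    threshold against a selected one.
    """
    missing = [r.variant_id for r in records if r.variant_id not in ld.variant_ids]
    if missing:
        raise ValueError(f"variant IDs absent from the LD matrix: {missing}")
    pos = {v: i for i, v in enumerate(ld.variant_ids)}
    remaining = sorted(records, key=_clump_sort_key)
    selected: list[SummaryStatRecord] = []
    while remaining:
        index_variant = remaining.pop(0)
        selected.append(index_variant)
        i = pos[index_variant.variant_id]
        remaining = [r for r in remaining
                     if ld.r2[i, pos[r.variant_id]] <= r2_threshold]
    dropped = len(records) - len(selected)
    if dropped:
        logger.info("greedy_clump: pruned %d variant(s) at r² > %g",
                    dropped, r2_threshold)
    return selected


def intersect_with_panel(
    records: list[SummaryStatRecord],
    panel_ids: set[str],
) -> list[SummaryStatRecord]:
    """Drop variants missing from the outcome study's genotyping panel."""
    kept = [r for r in records if r.variant_id in panel_ids]
    removed = [r.variant_id for r in records if r.variant_id not in panel_ids]
    if removed:
        logger.info("intersect_with_panel: removed %d variant(s): %s",
                    len(removed), ", ".join(removed))
    if not kept:
        raise ValueError("no instrument variants remain after panel intersection")
    return kept


def instrument_strength(r2_explained: float, n: int, k: int) -> tuple[float, bool]:
    """Standard instrument F statistic and the weak-instrument flag.

    F = (r² / k) / ((1 − r²) / (n − k − 1)).  Returns (F, weak) where weak is
    True when F ≤ 10, the conventional adequacy cutoff for MR instruments.
    """
    if not 0 <= r2_explained < 1:
        raise ValueError(f"r2_explained {r2_explained} outside [0, 1)")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (got n={n}, k={k})")
    f = (r2_explained / k) / ((1.0 - r2_explained) / (n - k - 1))
    return f, f <= 10.0


def estimate_r2_from_summary(records: list[SummaryStatRecord]) -> float:
    """Variance explained from summary statistics: Σ 2·EAF·(1−EAF)·β².

    Assumes a variance-standardized exposure and independent (post-clumping)
    variants.  When individual-level genotypes are available the joint
    regression R² is the better estimate; both are reported by the CLI when
    possible.
    """
    missing = [r.variant_id for r in records if r.eaf is None or r.beta is None]
    if missing:
        raise ValueError(
            f"EAF/beta missing for {missing}; supply individual-level "
            "genotypes and use the joint-regression R² instead"
        )
    r2 = sum(2.0 * r.eaf * (1.0 - r.eaf) * r.beta ** 2 for r in records)
    return float(np.clip(r2, 0.0, np.nextafter(1.0, 0.0)))


def individual_level_r2(genotypes: np.ndarray, exposure: np.ndarray) -> float:
    """Joint-regression R² of the measured exposure on all instrument dosages."""
    g = np.asarray(genotypes, float)
    y = np.asarray(exposure, float)
    X = np.column_stack([np.ones(len(y)), g])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid @ resid) / tss) if tss > 0 else 0.0
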