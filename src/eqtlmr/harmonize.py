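"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs both studies' effects expressed for the same effect
allele at every variant.  Four situations arise: the studies agree; the
allele labels are swapped (flip the outcome effect's sign); the outcome study
reported the opposite strand (map through the A↔T / C↔G complement first);
or the variant is palindromic (A/T or C/G), where strand cannot be inferred
from alleles and the effect-allele frequency must arbitrate.  Every record's
fate is kept in an audit trail.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SummaryStatRecord, logger

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: palindromic variants with EAF this close to 0.5 on either side are dropped
DEFAULT_EAF_TOLERANCE = 0.08


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    action: str  # kept | sign_flipped | strand_complemented | dropped_*


@dataclass
class HarmonizedSet:
    """The kept pairs (analysis set) plus the audit of dropped variants."""

    pairs: list[HarmonizedPair]
    dropped: list[HarmonizedPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.variant_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant_ids in harmonized set")

    @property
    def k(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        bx = np.array([p.beta_exposure for p in self.pairs])
        sx = np.array([p.se_exposure for p in self.pairs])
        by = np.array([p.beta_outcome for p in self.pairs])
        sy = np.array([p.se_outcome for p in self.pairs])
        return bx, sx, by, sy

    def to_frame(self, include_dropped: bool = False) -> pd.DataFrame:
        rows = self.pairs + (self.dropped if include_dropped else [])
        return pd.DataFrame([vars(p) for p in rows])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizedSet":
        pairs, dropped = [], []
        for row in df.itertuples(index=False):
            pair = HarmonizedPair(
                variant_id=str(row.variant_id),
                beta_exposure=float(row.beta_exposure),
                se_exposure=float(row.se_exposure),
                beta_outcome=float(row.beta_outcome),
                se_outcome=float(row.se_outcome),
                eaf_exposure=None if pd.isna(row.eaf_exposure) else float(row.eaf_exposure),
                eaf_outcome=None if pd.isna(row.eaf_outcome) else float(row.eaf_outcome),
                action=str(row.action),
            )
            (dropped if pair.action.startswith("dropped") else pairs).append(pair)
        return cls(pairs, dropped)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC


def _ambiguous_eaf(eaf: float | None, tol: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= tol


def align_alleles(
    exposure: list[SummaryStatRecord],
    outcome: list[SummaryStatRecord],
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE,
) -> HarmonizedSet:
    """Join the two studies on variant ID and harmonize allele orientation.

    Non-palindromic variants: matching alleles are kept; swapped labels flip
    the outcome beta (and EAF); a strand complement is applied first when the
    alleles only match through A↔T/C↔G.  Palindromic variants are kept only
    when both EAFs are informative (outside 0.5 ± eaf_tolerance) and agree on
    which allele is minor; otherwise they are dropped.  Irreconcilable
    alleles are dropped as mismatches.  Harmonizing an already-harmonized
    set is a no-op.
    """
    for study, recs in (("exposure", exposure), ("outcome", outcome)):
        ids = [r.variant_id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate variant_id in {study} study")
    out_by_id = {r.variant_id: r for r in outcome}

    pairs: list[HarmonizedPair] = []
    dropped: list[HarmonizedPair] = []
    for ex in exposure:
        oc = out_by_id.get(ex.variant_id)
        if oc is None:
            continue  # not joined; count conservation is over joined variants

        def make(action: str, beta_oc: float, eaf_oc: float | None) -> HarmonizedPair:
            return HarmonizedPair(ex.variant_id, ex.beta, ex.se, beta_oc, oc.se,
                                  ex.eaf, eaf_oc, action)

        ea, oa = oc.effect_allele, oc.other_allele
        if _is_palindromic(ex.effect_allele, ex.other_allele):
            if {ea, oa} != {ex.effect_allele, ex.other_allele}:
                dropped.append(make("dropped_mismatch", oc.beta, oc.eaf))
                continue
            # label orientation first, then frequency arbitration for strand
            if ea == ex.effect_allele:
                beta_oc, eaf_oc = oc.beta, oc.eaf
            else:
                beta_oc = -oc.beta
                eaf_oc = None if oc.eaf is None else 1.0 - oc.eaf
            if (_ambiguous_eaf(ex.eaf, eaf_tolerance)
                    or _ambiguous_eaf(eaf_oc, eaf_tolerance)
                    or (ex.eaf - 0.5) * (eaf_oc - 0.5) < 0):
                dropped.append(make("dropped_palindromic", beta_oc, eaf_oc))
                continue
            pairs.append(make("kept", beta_oc, eaf_oc))
            continue

        if (ea, oa) == (ex.effect_allele, ex.other_allele):
            pairs.append(make("kept", oc.beta, oc.eaf))
        elif (oa, ea) == (ex.effect_allele, ex.other_allele):
            pairs.append(make("sign_flipped", -oc.beta,
                              None if oc.eaf is None else 1.0 - oc.eaf))
        else:
            cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
            if (cea, coa) == (ex.effect_allele, ex.other_allele):
                pairs.append(make("strand_complemented", oc.beta, oc.eaf))
            elif (coa, cea) == (ex.effect_allele, ex.other_allele):
                pairs.append(make("strand_complemented", -oc.beta,
                                  None if oc.eaf is None else 1.0 - oc.eaf))
            else:
                dropped.append(make("dropped_mismatch", oc.beta, oc.eaf))

    if dropped:
        logger.info("align_alleles: dropped %d variant(s): %s", len(dropped),
                    ", ".join(f"{p.variant_id} ({p.action})" for p in dropped))
    return HarmonizedSet(pairs, dropped)


def orient_to_positive_exposure(hset: HarmonizedSet) -> HarmonizedSet:
    """Flip pairs so every exposure beta is positive (Egger's sign convention).

    Jointly negating (beta_exposure, beta_outcome) leaves every ratio-based
    estimator unchanged; only Egger's intercept depends on this orientation.
    """
    out = copy.deepcopy(hset)
    for p in out.pairs:
        if p.beta_exposure < 0:
            p.beta_exposure = -p.beta_exposure
            p.beta_outcome = -p.beta_outcome
            if p.eaf_exposure is not None:
                p.eaf_exposure = 1.0 - p.eaf_exposure
            if p.eaf_outcome is not None:
                p.eaf_outcome = 1.0 - p.eaf_outcome
    return out
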