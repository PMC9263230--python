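"""Readers, writers, configuration and provenance for the MR pipeline.

All on-disk formats are plain delimited text (TSV/CSV, delimiter
auto-detected) or VCF.  Coordinates are 1-based and inclusive throughout,
matching VCF convention.  Every pipeline stage writes a JSON result (machine
twin) and a TSV (human twin) plus a provenance block recording the
configuration, the seed and checksums of the inputs.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("eqtlmr")
if not logger.handlers:  # stderr at INFO unless the caller configured logging
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

VALID_ALLELES = frozenset("ACGT")

#: default summary-statistics column names; consortium files differ, so the
#: mapping is user-configurable (see ``read_summary_stats``).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


class ValidationError(ValueError):
    """Raised when an input file fails structural or per-row validation."""


@dataclass
class SummaryStatRecord:
    """One variant's marginal association with one trait.

    ``beta`` is the per-effect-allele effect in trait units (linear) or
    log-odds (logistic).  ``eaf`` is the effect-allele frequency and may be
    missing (``None``), which disables frequency-based palindromic resolution
    downstream.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float | None
    se: float | None
    pvalue: float | None
    n: int | None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the record is valid)."""
        problems: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            problems.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele == other_allele")
        if self.pos < 1:
            problems.append(f"pos {self.pos} < 1")
        if self.beta is not None:
            if self.se is None or not (self.se > 0):
                problems.append(f"se must be > 0 when beta present (got {self.se})")
        if self.pvalue is not None and not (0 < self.pvalue <= 1):
            problems.append(f"pvalue {self.pvalue} outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            problems.append(f"eaf {self.eaf} outside [0, 1]")
        return problems


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered variant list."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValidationError(
                f"LD matrix shape {self.r2.shape} does not match {k} variant IDs"
            )

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in ids]
        return LDMatrix(list(ids), self.r2[np.ix_(idx, idx)])


@dataclass
class RunConfig:
    """Pipeline thresholds and simulation sizes.

    Defaults reproduce the instrument-construction settings used for
    eQTL-based MR of a cis gene region: a 500 kb window around the gene,
    nominal P < 0.05 association with expression, and r² > 0.01 pruning.
    ``relative_reduction`` is the reporting unit for rescaled effects
    (0.34 = effects per 34% relative reduction in the expression score).
    """

    cis_window_bp: int = 500_000
    p_threshold: float = 0.05
    r2_threshold: float = 0.01
    relative_reduction: float = 0.34
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    ivw_model: str = "fixed"

    def __post_init__(self) -> None:
        if self.cis_window_bp < 0:
            raise ValidationError("cis_window_bp must be >= 0")
        for name in ("p_threshold", "r2_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.relative_reduction < 1:
            raise ValidationError("relative_reduction must be in (0, 1)")
        if self.n_boot < 1 or self.n_sim < 1:
            raise ValidationError("n_boot and n_sim must be >= 1")
        if self.ivw_model not in ("fixed", "multiplicative_random"):
            raise ValidationError(f"unknown ivw_model {self.ivw_model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "."):
        return None
    return float(value)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a delimited summary-statistics table into validated records.

    ``column_map`` maps record field names to the file's column headers;
    unspecified fields fall back to :data:`DEFAULT_COLUMN_MAP`.  Alleles are
    uppercased.  Rows violating record invariants are collected and reported
    together with their line numbers, then a :class:`ValidationError` is
    raised if any were found.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    missing = [cmap[f] for f in required if cmap[f] not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")

    records: list[SummaryStatRecord] = []
    errors: list[str] = []
    n_missing_eaf = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        get = lambda f: getattr(row, cmap[f]) if cmap[f] in df.columns else None
        try:
            rec = SummaryStatRecord(
                variant_id=str(get("variant_id")),
                chrom=str(get("chrom")),
                pos=int(get("pos")),
                effect_allele=str(get("effect_allele")).upper(),
                other_allele=str(get("other_allele")).upper(),
                eaf=_opt_float(get("eaf")),
                beta=_opt_float(get("beta")),
                se=_opt_float(get("se")),
                pvalue=_opt_float(get("pvalue")),
                n=None if get("n") is None or pd.isna(get("n")) else int(get("n")),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        problems = rec.validate()
        if problems:
            errors.extend(f"line {line}: {p}" for p in problems)
        else:
            if rec.eaf is None:
                n_missing_eaf += 1
            records.append(rec)
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    if n_missing_eaf:
        logger.warning(
            "%s: %d record(s) with missing EAF; palindromic variants will be "
            "dropped during harmonization", path, n_missing_eaf,
        )
    return records


def summary_stats_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_summary_stats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as TSV using the default column names (round-trip safe)."""
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    cols = list(DEFAULT_COLUMN_MAP.values())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for r in records:
            row = []
            for c in cols:
                v = getattr(r, inv[c])
                row.append("" if v is None else (repr(v) if isinstance(v, float) else v))
            w.writerow(row)


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square r² matrix with variant-ID header row and column.

    Asymmetries up to 1e-6 are averaged away; the diagonal is forced to 1.
    Values outside [-1e-9, 1 + 1e-9] or a non-square layout are fatal.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: LD matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column variant IDs differ")
    m = df.to_numpy(dtype=float)
    if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
        bad = m[(m < -1e-9) | (m > 1 + 1e-9)]
        raise ValidationError(f"{path}: r² values outside [0, 1]: {bad[:5]}")
    asym = np.abs(m - m.T).max()
    if asym > 1e-6:
        raise ValidationError(f"{path}: matrix asymmetric by {asym:.3g} (> 1e-6)")
    m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return LDMatrix([str(v) for v in df.index], m)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    columns = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:  # dosage field preferred over hard genotype calls
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = var.gt_types.astype(float)
            dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        miss = np.isnan(dose)
        if miss.any():
            frac = miss.mean()
            fill = np.nanmean(dose) if not miss.all() else 0.0
            dose = np.where(miss, fill, dose)
            level = logger.warning if frac > 0.10 else logger.info
            level("%s: %.1f%% missing genotypes imputed to mean %.3f",
                  vid, 100 * frac, fill)
        ids.append(vid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        columns.append(dose)
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate variant IDs")
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: duplicate sample IDs")
    dosages = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=samples, columns=ids,
    )
    meta = pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "pos": poss,
         "counted_allele": [a.upper() for a in alts],
         "other_allele": [r.upper() for r in refs]}
    )
    return dosages, meta


def read_genotypes(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes as a samples × variants dosage matrix plus metadata.

    VCF input (``.vcf``/``.vcf.gz``): the counted (dosage) allele is ALT; the
    DS FORMAT field is preferred over GT when present; missing calls are
    imputed to the variant's mean dosage with the missingness logged (warning
    above 10%).  Otherwise the file is read as a delimited dosage matrix with
    sample IDs in the first column and variant IDs in the header (metadata
    columns then carry only the variant ID).
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        dosages, meta = _read_vcf_dosages(path)
    else:
        df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
        if df.columns.duplicated().any() or df.index.duplicated().any():
            raise ValidationError(f"{path}: duplicate sample or variant IDs")
        dosages = df.astype(float)
        for vid in dosages.columns:
            col = dosages[vid]
            if col.isna().any():
                frac = col.isna().mean()
                dosages[vid] = col.fillna(col.mean())
                level = logger.warning if frac > 0.10 else logger.info
                level("%s: %.1f%% missing dosages imputed to mean", vid, 100 * frac)
        meta = pd.DataFrame(
            {"variant_id": dosages.columns, "chrom": pd.NA, "pos": pd.NA,
             "counted_allele": pd.NA, "other_allele": pd.NA}
        )
    vals = dosages.to_numpy()
    if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 2 + 1e-9):
        raise ValidationError(f"{path}: dosages outside [0, 2]")
    return dosages, meta


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_prefix: str | Path,
    config: RunConfig,
    seed: int,
    inputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Write a JSON provenance block (config, seed, input checksums)."""
    block = {
        "config": config.to_dict(),
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
        },
    }
    path = Path(f"{out_prefix}.provenance.json")
    path.write_text(json.dumps(block, indent=2) + "\n")
    return path


def write_result(out_prefix: str | Path, stage: str, payload: dict,
                 table: pd.DataFrame | None = None) -> None:
    """Write the JSON/TSV result twins for one pipeline stage."""
    Path(f"{out_prefix}.{stage}.json").write_text(json.dumps(payload, indent=2,
                                                             default=float) + "\n")
    if table is not None:
        table.to_csv(f"{out_prefix}.{stage}.tsv", sep="\t", index=False)
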