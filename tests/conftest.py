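import logging

import numpy as np
import pytest

from eqtlmr import HarmonizedPair, HarmonizedSet, SimScenario, SummaryStatRecord

logging.getLogger("eqtlmr").setLevel(logging.WARNING)


def make_record(vid="rs1", chrom="17", pos=100, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pvalue=1e-4, n=10_000) -> SummaryStatRecord:
    return SummaryStatRecord(vid, chrom, pos, ea, oa, eaf, beta, se, pvalue, n)


def make_pair(vid, bx, sx, by, sy, eaf_x=0.3, eaf_y=0.3,
              action="kept") -> HarmonizedPair:
    return HarmonizedPair(vid, bx, sx, by, sy, eaf_x, eaf_y, action)


def make_set(bx, by, sy, sx=None) -> HarmonizedSet:
    sx = sx if sx is not None else [0.01] * len(bx)
    return HarmonizedSet([
        make_pair(f"rs{i}", bx[i], sx[i], by[i], sy[i]) for i in range(len(bx))
    ])


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    """A fast two-cohort scenario used across simulation tests."""
    return SimScenario(n_exposure_cohort=4000, n_outcome_cohort=4000, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """One full default-condition study (13 variants, r² 0.015)."""
    from eqtlmr import align_alleles, simulate_summary_pair

    scn = SimScenario(n_exposure_cohort=20_000, n_outcome_cohort=20_000, seed=42)
    ex, oc = simulate_summary_pair(scn)
    return scn, align_alleles(ex, oc)
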