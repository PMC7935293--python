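import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pearlmap.matrix import GenotypeMatrix, PhenotypeTable

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def make_gm(variants, calls, samples=None, dp=None, gq=None):
    """Toy GenotypeMatrix from (chrom, pos, ref, alt, qual) tuples and a
    samples x variants call list."""
    calls = np.asarray(calls, dtype=np.int8)
    if samples is None:
        samples = [f"S{i + 1}" for i in range(calls.shape[0])]
    return GenotypeMatrix(
        variants=pd.DataFrame(variants,
                              columns=["chrom", "pos", "ref", "alt", "qual"]),
        samples=samples,
        calls=calls,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One small noise-free cohort reused across tests (6 cases, 6 controls)."""
    from pearlmap.simulate import CohortSimParams, simulate_cohort

    params = CohortSimParams(
        n_cases=6, n_controls=6, n_scaffolds=1, scaffold_length=60_000,
        sweep_length=10_000, theta=0.004, missing_rate=0.0, err_max=0.0,
        recomb_erosion=0.0, seed=7,
    )
    return simulate_cohort(params)


@pytest.fixture()
def two_group_phen():
    def _make(cases, controls):
        return PhenotypeTable(
            {**{s: "pearl-eye" for s in cases},
             **{s: "wild-type" for s in controls}}
        )
    return _make
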