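import numpy as np
import pandas as pd
import pytest

from glrisk.cohort import Cohort


def make_cohort(
    n=60,
    n_snps=4,
    seed=0,
    mafs=None,
    event_rate=0.4,
    covariates=None,
):
    """Small random cohort with valid invariants for unit tests."""
    rng = np.random.default_rng(seed)
    mafs = mafs if mafs is not None else np.full(n_snps, 0.3)
    geno = pd.DataFrame(
        rng.binomial(2, mafs, size=(n, len(mafs))),
        columns=[f"rs{i + 1:03d}" for i in range(len(mafs))],
    )
    if covariates is None:
        covariates = pd.DataFrame(
            {
                "bmi": rng.normal(27, 5, n),
                "alcohol": rng.gamma(1.0, 6.0, n),
            }
        )
    time = rng.exponential(10, n) + 0.01
    event = (rng.random(n) < event_rate).astype(int)
    if event.sum() < 2:  # unit tests need a couple of events
        event[:2] = 1
    return Cohort(
        subject_ids=np.array([f"S{i:04d}" for i in range(n)]),
        genotypes=geno,
        covariates=covariates,
        time_years=time,
        event=event,
    )


@pytest.fixture
def small_cohort():
    return make_cohort()


@pytest.fixture
def cohort_files(tmp_path, small_cohort):
    from glrisk.cohort import write_tables

    return write_tables(small_cohort, tmp_path)
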