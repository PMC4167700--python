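import io

import numpy as np
import pandas as pd
import pytest

from qtcohort import IntervalTable
from qtcohort.simulate import CohortParams, StratumSpec


def make_table(qt, rr, sex=None, age=None, manufacturer=None) -> IntervalTable:
    """Build an IntervalTable from second-scale arrays with simple defaults."""
    qt = np.asarray(qt, dtype=float)
    n = qt.size
    df = pd.DataFrame({
        "qt": qt,
        "rr": np.asarray(rr, dtype=float),
        "sex": sex if sex is not None else ["male"] * n,
        "age": age if age is not None else np.full(n, 50.0),
        "manufacturer": manufacturer if manufacturer is not None else ["FD"] * n,
    })
    return IntervalTable(df)


@pytest.fixture
def two_row_csv() -> io.StringIO:
    return io.StringIO(
        "qt,rr,sex,age,manufacturer\n400,950,male,50,NK\n388,876,female,45,FD\n"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140917)


def single_stratum_params(
    mode="log", slope=0.347, residual_sd=None, target_r2=None, **kw
) -> CohortParams:
    """One male stratum with published-scale RR/age moments, no covariates."""
    stratum = StratumSpec(
        manufacturer="FD", sex="male", n=kw.pop("n", 500),
        rr_mean=900.0, rr_sd=140.0, age_mean=50.0, age_sd=10.0,
        qt_mean=400.0, qt_sd=27.0,
    )
    if residual_sd is None and target_r2 is None:
        residual_sd = 0.0
    return CohortParams(
        mode=mode, strata=(stratum,), slope=slope,
        residual_sd=residual_sd, target_r2=target_r2, **kw,
    )
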