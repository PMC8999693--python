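import numpy as np
import pandas as pd
import pytest

import arvcrisk as av


@pytest.fixture(scope="session")
def published():
    return av.published_model()


@pytest.fixture(scope="session")
def recalibrated():
    return av.recalibrated_model()


@pytest.fixture
def fixture_patient():
    """Male, 40 y, no recent syncope, NSVT history, PVC 1399, 3 TWI leads, RVEF 27.6%."""
    return av.PatientCovariates(
        sex_male=1, age_years=40, recent_syncope=0, nsvt_history=1,
        pvc_24h=1399, twi_leads=3, rvef_pct=27.6,
    )


@pytest.fixture(scope="session")
def zero_model():
    """All-zero coefficients: every patient sits on the baseline (LP = 0)."""
    return av.RiskModelSpec(0, 0, 0, 0, 0, 0, 0, s0_table={5.0: 0.5}, label="zero")


def toy_cohort(times, events, prior=None, **covariates) -> pd.DataFrame:
    """Minimal schema-complete cohort table around given follow-up data."""
    n = len(times)
    base = {
        "sex_male": 1, "age_years": 40.0, "recent_syncope": 0, "nsvt_history": 0,
        "pvc_24h": 1000.0, "twi_leads": 3, "rvef_pct": 30.0,
    }
    base.update(covariates)
    df = pd.DataFrame({"patient_id": [f"P{i:03d}" for i in range(n)]})
    for k, v in base.items():
        df[k] = v if np.ndim(v) else [v] * n
    df["prior_sustained_va"] = prior if prior is not None else 1
    df["time_years"] = np.asarray(times, dtype=float)
    df["event"] = np.asarray(events, dtype=int)
    df["endpoint"] = "icd_therapy"
    return df


@pytest.fixture
def make_cohort():
    return toy_cohort


def harrell_c_bruteforce(risks, times, events) -> float:
    """Pure-python pair enumeration: usable = strictly shorter time has the
    event; concordant pairs count 1, score ties 1/2."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


@pytest.fixture(scope="session")
def c_oracle():
    return harrell_c_bruteforce
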