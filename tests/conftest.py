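import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small raw synthetic cohort shared by pipeline-level tests."""
    from dyadinform.synthetic import get_preset, generate_cohort
    return generate_cohort(get_preset("paper_like", n_dyads=80, seed=42))


def make_scored_visits(rows: list[dict]) -> pd.DataFrame:
    """Build a scored visit table from terse row dicts (test fixture aid)."""
    defaults = dict(
        months_from_baseline=None, is_discontinuation_visit=False,
        dyad_type="spousal", cdr_global_baseline=0.0, cdr_sb=0.0,
        age=79.0, education=15.0, sex="female", race_caucasian=1,
        cvd_history=0, p_cfi=1.0, s_cfi=1.0, composite=0.0)
    full = []
    for r in rows:
        d = {**defaults, **r}
        if d["months_from_baseline"] is None:
            d["months_from_baseline"] = 12.0 * (d.get("visit_year") or 0)
        full.append(d)
    df = pd.DataFrame(full)
    df["visit_year"] = df["visit_year"].astype(float)
    return df
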