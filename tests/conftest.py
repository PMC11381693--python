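import numpy as np
import pandas as pd
import pytest

import ltcmine as lm


@pytest.fixture(scope="session")
def registry():
    return lm.load_registry()


def make_cohort(rows, registry):
    """Build a cohort frame from compact row dicts; unspecified conditions are 0."""
    records = []
    for i, row in enumerate(rows):
        rec = {cid: 0 for cid in registry.condition_ids}
        rec.update(
            participant_id=row.get("participant_id", f"P{i:04d}"),
            sex=row.get("sex", "F"),
            age_years=row.get("age_years", 60),
            grip_max_kg=row.get("grip_max_kg", np.nan),
            unable_health=row.get("unable_health", False),
        )
        for cid in row.get("conditions", ()):
            rec[cid] = 1
        records.append(rec)
    df = pd.DataFrame(records)
    df["grip_max_kg"] = df["grip_max_kg"].astype("Float64")
    return lm.add_ltc_count(df, registry)


@pytest.fixture(scope="session")
def small_cohort(registry):
    """Realistic-calibration cohort, small n, for pipeline-level tests."""
    cfg = lm.biobank_like_config(seed=20260927, n_per_sex=2000)
    cohort, _ = lm.generate_cohort(cfg, registry)
    return cohort


@pytest.fixture(scope="session")
def analytic_cohort(small_cohort):
    """Classified and MLTC-restricted version of the small cohort."""
    return lm.restrict_to_mltc(lm.classify_sarcopenia_risk(small_cohort))
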