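import numpy as np
import pandas as pd
import pytest

import cvdscore as cs

DEFAULTS = {
    "sex": "male", "age": 50.0, "smoking": False, "sbp": 130.0,
    "glucose": 5.4, "cholesterol": 6.0, "diabetes": False,
    "fasting_hours": 8.0,
}


def make_table(rows, provenance="test") -> cs.CohortTable:
    """Build a CohortTable from partial row dicts, filling sensible defaults."""
    filled = []
    for r in rows:
        row = dict(DEFAULTS)
        row.update(r)
        row.setdefault("entry_age", row["age"])
        row.setdefault("exit_age", row["entry_age"] + 20.0)
        row.setdefault("event", False)
        filled.append(row)
    return cs.CohortTable(df=pd.DataFrame(filled), provenance=provenance)


@pytest.fixture
def six_subject_table():
    """Hand-built censored table for the IPCW weight oracle (horizon 10).

    Follow-up times 2, 4, 6, 8, 12, 15 with events at 2, 6, 15; the censoring
    Kaplan-Meier drops at 4, 8 and 12.
    """
    specs = [(2, True), (4, False), (6, True), (8, False), (12, False), (15, True)]
    return make_table([
        {"entry_age": 40.0, "exit_age": 40.0 + t, "event": ev} for t, ev in specs
    ])


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized synthetic cohort under the published glucose-model truth."""
    return cs.simulate_cohort(cs.default_config(seed=42), 8000, seed=42)


@pytest.fixture(scope="session")
def glucose_fit(sim_cohort):
    return cs.fit_weibull_ph(sim_cohort, ["smoking", "sbp", "glucose"])
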