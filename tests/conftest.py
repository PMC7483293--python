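import numpy as np
import pandas as pd
import pytest

import ppiscale as pps


def make_noiseless_summaries(
    curve: pps.StartleCurveParams,
    scalings: dict,
    startle_levels=(0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    sem: float = 0.02,
) -> pd.DataFrame:
    """Exact model-mean summaries for one animal (zero trial noise)."""
    rows = []
    for s in startle_levels:
        rows.append(
            {
                "prepulse_db": 0.0,
                "delay_ms": 0.0,
                "startle_db": s,
                "mean_log_movement": float(
                    pps.predicted_movement(s, None, curve)
                ),
                "sem": sem,
                "n_trials": 60,
            }
        )
    for (p, d), (alpha, beta) in scalings.items():
        sc = pps.ConditionScaling(p, d, alpha, beta)
        for s in startle_levels:
            if s == 0:
                continue
            rows.append(
                {
                    "prepulse_db": p,
                    "delay_ms": d,
                    "startle_db": s,
                    "mean_log_movement": float(
                        pps.predicted_movement(s, sc, curve)
                    ),
                    "sem": sem,
                    "n_trials": 60,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def example_curve():
    return pps.StartleCurveParams(m_max=2.0, r=0.2, s0=25.0, m0=0.1)


@pytest.fixture(scope="session")
def small_cohort():
    """3 animals, 2 conditions, 60 trials/stimulus — shared across tests."""
    spec = pps.CohortSpec(
        groups=(("wt", 3),),
        conditions=((6.0, 100.0), (14.0, 100.0)),
        seed=42,
    )
    animals, scalings, trials = pps.simulate_cohort(spec)
    return spec, animals, scalings, trials


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    spec, animals, scalings, trials = small_cohort
    tm = pps.trials_from_table(trials)
    results = pps.fit_cohort(tm)
    summaries = {
        a: pps.summarize_movement(sub).reset_index(drop=True)
        for a, sub in tm.groupby("animal_id")
    }
    return animals, scalings, results, summaries
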