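import numpy as np
import pandas as pd
import pytest

import midkit as mk


@pytest.fixture(scope="session")
def calibrated_config():
    return mk.paper_calibrated_config()


@pytest.fixture(scope="session")
def calibrated_cohort(calibrated_config):
    """One registry-calibrated cohort with its planted truth (seed 0)."""
    return mk.generate_cohort(calibrated_config, seed=0)


def replicate_change_differences(config, n_reps, seed):
    """Run the full pipeline on seeded replicate cohorts; collect the
    change-difference estimates per (metric, anchor, direction).

    Screening is disabled (threshold 0) so every planted cell is estimated
    in every replicate: the point is the estimator, not the screen.
    ``value_unfloored`` carries the raw group contrast even where the
    published pipeline would floor it at the SEM.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for rep_seed in seeds:
        cohort, _ = mk.generate_cohort(config, seed=int(rep_seed))
        results = mk.MIDModel(
            cohort,
            metrics=config.metric_definitions,
            anchors=config.anchor_definitions,
            screen_threshold=0.0,
            scales=("absolute",),
        ).fit()
        ok = results.estimates.query("status == 'ok' and method == 'change_difference'")
        rows.append(
            ok[["metric", "anchor", "direction", "value", "value_unfloored",
                "floored", "sem"]]
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def calibrated_replicates(calibrated_config):
    """200 seeded replicate cohorts of the calibrated configuration."""
    return replicate_change_differences(calibrated_config, n_reps=200, seed=0)


def toy_cohort(
    baseline,
    followup,
    e10=None,
    iswt=None,
    survived=None,
    metric_name="rvef",
) -> mk.PairedCohort:
    """Small hand-built cohort with a single metric (helper, not a fixture)."""
    n = len(baseline)
    data = {
        "patient_id": [f"T{i:03d}" for i in range(n)],
        f"{metric_name}_baseline": baseline,
        f"{metric_name}_followup": followup,
    }
    if e10 is not None:
        data["e10_baseline"], data["e10_followup"] = e10
    if iswt is not None:
        data["iswt_baseline"], data["iswt_followup"] = iswt
    data["survived_1yr"] = survived if survived is not None else np.ones(n, dtype=int)
    return mk.PairedCohort(pd.DataFrame(data))
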