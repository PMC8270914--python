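import pandas as pd
import pytest

import reefrange as rr
from reefrange import synthetic_data


@pytest.fixture(scope="session")
def paper_system():
    """Study-scale fixture (147 sharks) with simulated detections, run once."""
    cfg, reefs, receivers, tagging, truth = synthetic_data.paper_cohort()
    detections = rr.simulate_detections(truth, receivers, cfg, seed=123)
    filtered, n_removed = rr.filter_false_detections(detections)
    windowed = rr.apply_post_capture_window(filtered, tagging)
    cohort = rr.build_cohort(windowed, tagging, receivers)
    return {
        "config": cfg, "reefs": reefs, "receivers": receivers,
        "tagging": tagging, "truth": truth, "detections": detections,
        "filtered": filtered, "n_removed": n_removed,
        "windowed": windowed, "cohort": cohort,
    }


@pytest.fixture(scope="session")
def paper_ud(paper_system):
    matrix = rr.daily_occurrences(paper_system["windowed"],
                                  paper_system["cohort"].retained_ids)
    ud = rr.ud_table(matrix, paper_system["tagging"], paper_system["receivers"],
                     paper_system["reefs"])
    return {"matrix": matrix, "ud": ud, "ud_all": ud[ud["season"] == "all"]}


@pytest.fixture()
def toy_receivers():
    """Three receivers on one reef at 1, 4 and 7 km."""
    return pd.DataFrame({
        "receiver_id": ["R1", "R2", "R3"],
        "reef_id": ["reef_1"] * 3,
        "position_km": [1.0, 4.0, 7.0],
        "lat": [-21.0] * 3,
        "lon": [163.0, 163.03, 163.06],
        "status": ["active"] * 3,
    })


@pytest.fixture()
def linear_reef():
    """One reef with A(s) = 2 s (2 km² of slope per km of reef)."""
    return {"reef_1": rr.ReefGeometry.from_density(
        "reef_1", 10.0, 2.0, anchors=((-21.0, 163.0), (-21.0, 163.1)))}
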