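"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pandas as pd
import pytest

from fluopop import preset, process_traces, simulate_population
from fluopop.population import ActivityClass


@pytest.fixture(scope="session")
def control_sim():
    """160-cell control-condition population (default preset)."""
    return simulate_population(preset("control", n_cells=160, seed=11))


@pytest.fixture(scope="session")
def control_processed(control_sim):
    return process_traces(control_sim.traces)


@pytest.fixture(scope="session")
def separated_sim():
    """160-cell population whose classes occupy disjoint feature regions."""
    return simulate_population(preset("separated", n_cells=160, seed=11))


@pytest.fixture(scope="session")
def separated_processed(separated_sim):
    return process_traces(separated_sim.traces)


def make_blob_features(n_per_class=40, seed=0) -> tuple[pd.DataFrame, list[ActivityClass]]:
    """Four well-separated (spike_count, ca_max) blobs, one per class."""
    rng = np.random.default_rng(seed)
    centers = {
        ActivityClass.HYPERACTIVE: (10.0, 1.2),
        ActivityClass.MODERATE: (3.0, 0.9),
        ActivityClass.LOW: (3.0, 0.25),
        ActivityClass.SILENT: (0.0, 0.05),
    }
    rows, labels = [], []
    cid = 0
    for cls, (cx, cy) in centers.items():
        for _ in range(n_per_class):
            cid += 1
            count = max(0, int(round(cx + rng.normal(0, 0.5))))
            if cls is ActivityClass.SILENT:
                count = 0
            elif cls in (ActivityClass.MODERATE, ActivityClass.LOW):
                count = int(np.clip(count, 1, 6))
            else:
                count = max(count, 7)
            amp = max(0.0, cy + rng.normal(0, 0.04))
            rows.append({"cell_id": cid, "spike_count": count, "ca_max": amp,
                         "condition": "control"})
            labels.append(cls)
    return pd.DataFrame(rows), labels


@pytest.fixture()
def blob_features():
    return make_blob_features(seed=3)
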