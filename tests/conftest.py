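import numpy as np
import pytest

from chiptile import chisq, consensus, io
from chiptile.pipeline import call_peaks
from chiptile.simulate import SimConfig, simulate_annotation, simulate_tracks


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """Default-conditions synthetic dataset: features, raw replicate tracks, truth."""
    features = simulate_annotation(sim_config)
    replicates, truth = simulate_tracks(features, sim_config)
    return features, replicates, truth


@pytest.fixture(scope="session")
def normalized_replicates(sim_dataset):
    _, replicates, _ = sim_dataset
    return [io.normalize_replicate(tracks) for tracks in replicates]


@pytest.fixture(scope="session")
def called_peaks(normalized_replicates):
    """Consensus peaks from the full detection chain at default parameters."""
    peaks, per_rep, models = call_peaks(
        normalized_replicates, chisq.ScanParams(), {}, consensus.MergeParams())
    return peaks, per_rep, models


def midpoint_distance(midpoint, start, end):
    if midpoint < start:
        return start - midpoint
    if midpoint > end:
        return midpoint - end
    return 0
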