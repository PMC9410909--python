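import numpy as np
import pytest

from chromswitch.core_io import Fragment, GenomicInterval, Peak, SignalTrack
from chromswitch.synthetic_data import (
    SimulationConfig,
    simulate_accessibility,
    simulate_fragments,
    simulate_mode_dataset,
    simulate_state_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=3,
        n_state_regions=50,
        n_bins_diff=2000,
        n_increased=40,
        n_decreased=40,
        n_confounded=30,
        n_per_cluster=25,
        n_direct_foci=4,
        n_nucleosomal_foci=4,
        fragments_per_focus=300,
    )


@pytest.fixture(scope="session")
def state_paths(small_config, tmp_path_factory):
    return simulate_state_dataset(small_config, tmp_path_factory.mktemp("states"))


@pytest.fixture(scope="session")
def acc_paths(small_config, tmp_path_factory):
    return simulate_accessibility(small_config, tmp_path_factory.mktemp("acc"))


@pytest.fixture(scope="session")
def mode_paths(small_config, tmp_path_factory):
    return simulate_mode_dataset(small_config, tmp_path_factory.mktemp("modes"))


@pytest.fixture(scope="session")
def fragment_paths(small_config, tmp_path_factory):
    return simulate_fragments(small_config, tmp_path_factory.mktemp("frags"))


def random_track(rng, chrom="chr1", span=10_000, n_runs=30, gap_prob=0.3):
    """Random piecewise-constant track with gaps, for per-base oracles."""
    edges = np.sort(rng.choice(np.arange(1, span), size=n_runs, replace=False))
    edges = np.concatenate([[0], edges, [span]])
    records = []
    for s, e in zip(edges[:-1], edges[1:]):
        if rng.random() > gap_prob:
            records.append((chrom, int(s), int(e), float(rng.uniform(0, 10))))
    return SignalTrack.from_records(records)


def per_base_values(track, chrom, span):
    """Brute-force per-base expansion of a track (uncovered = 0)."""
    arr = np.zeros(span)
    for c, s, e, v in track.iter_runs():
        if c == chrom:
            arr[s:e] = v
    return arr


def make_peak(chrom, start, end, summit=None, name=".", score=10.0):
    summit = (start + end) // 2 if summit is None else summit
    return Peak(GenomicInterval(chrom, start, end), summit, score, name)


def make_fragment(chrom, start, end):
    return Fragment(GenomicInterval(chrom, start, end))
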