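import numpy as np
import pandas as pd
import pytest

from chromswitch.chromatin_states import (
    ChromatinState,
    GeneAnnotator,
    build_region_universe,
    call_states,
    classify_state,
    compute_transitions,
    count_changed,
    fraction_covered,
    promoter_window,
    summit_window,
)
from chromswitch.core_io import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    ValidationError,
    read_peaks,
)
from conftest import make_peak


def index_of(*intervals):
    return IntervalIndex(intervals)


REGION = GenomicInterval("chr1", 1000, 2000)
HIT = GenomicInterval("chr1", 1500, 1600)  # overlaps REGION
MISS = GenomicInterval("chr1", 5000, 5100)


class TestClassifyState:
    @pytest.mark.parametrize(
        "k4,ac,me3,expected,flag",
        [
            (HIT, HIT, MISS, ChromatinState.ACTIVE, False),
            (HIT, MISS, MISS, ChromatinState.PRIMED, False),
            (MISS, MISS, HIT, ChromatinState.REPRESSED, False),
            (MISS, MISS, MISS, ChromatinState.QUIESCENT, False),
            (HIT, MISS, HIT, ChromatinState.PRIMED, True),  # bivalent-like
            (HIT, HIT, HIT, ChromatinState.ACTIVE, True),
            (MISS, HIT, MISS, ChromatinState.OTHER, False),  # K27ac alone
            (MISS, HIT, HIT, ChromatinState.REPRESSED, False),  # me3 before ac-alone
        ],
    )
    def test_mark_combinations(self, k4, ac, me3, expected, flag):
        state, multi = classify_state(REGION, index_of(k4), index_of(ac), index_of(me3))
        assert state is expected and multi is flag

    def test_k27ac_alone_can_fold_into_active(self):
        state, _ = classify_state(
            REGION, index_of(MISS), index_of(HIT), index_of(MISS),
            fold_other_into_active=True,
        )
        assert state is ChromatinState.ACTIVE

    def test_order_independent_of_peak_input(self):
        peaks = [HIT, MISS, GenomicInterval("chr1", 1900, 2100)]
        a, _ = classify_state(REGION, IntervalIndex(peaks), index_of(MISS), index_of(MISS))
        b, _ = classify_state(REGION, IntervalIndex(peaks[::-1]), index_of(MISS), index_of(MISS))
        assert a is b is ChromatinState.PRIMED


class TestRegionUniverse:
    def test_single_summit_gives_1kb_window(self):
        peaks = [[make_peak("chr1", 9800, 10200, summit=10_000)]]
        assert build_region_universe(peaks) == [GenomicInterval("chr1", 9500, 10500)]

    def test_overlapping_windows_merge(self):
        peaks = [
            [make_peak("chr1", 9900, 10100, summit=10_000)],
            [make_peak("chr1", 10_300, 10_500, summit=10_400)],
        ]
        assert build_region_universe(peaks) == [GenomicInterval("chr1", 9500, 10900)]

    def test_window_clipped_at_chromosome_start(self):
        peaks = [[make_peak("chr1", 100, 300, summit=200)]]
        assert build_region_universe(peaks) == [GenomicInterval("chr1", 0, 700)]

    def test_empty_input_gives_empty_universe(self):
        assert build_region_universe([]) == []


class TestCompartments:
    GENES = [
        GeneModel("plus", GenomicInterval("chr1", 50_000, 80_000, "+")),
        GeneModel("minus", GenomicInterval("chr2", 100_000, 130_000, "-")),
    ]

    def test_promoter_within_5kb_upstream_plus_strand(self):
        annot = GeneAnnotator(self.GENES)
        assert annot.compartment(GenomicInterval("chr1", 46_000, 47_000)) == "promoter"

    def test_gene_body_beyond_promoter_window(self):
        annot = GeneAnnotator(self.GENES)
        region = GenomicInterval("chr1", 69_500, 70_500)  # TSS+20 kb, inside gene
        assert annot.compartment(region) == "distal"
        assert annot.location(region) == "gene_body"

    def test_far_region_is_distal(self):
        annot = GeneAnnotator(self.GENES)
        region = GenomicInterval("chr1", 1_050_000, 1_051_000)
        assert annot.compartment(region) == "distal"
        assert annot.location(region) == "distal"

    def test_minus_strand_promoter_mirrors_upstream(self):
        annot = GeneAnnotator(self.GENES)
        # minus-strand TSS at 129,999; upstream extends rightwards
        assert annot.location(GenomicInterval("chr2", 133_000, 134_000)) == "promoter"
        assert annot.location(GenomicInterval("chr2", 124_000, 125_000)) == "gene_body"

    def test_promoter_window_bounds(self):
        w = promoter_window(self.GENES[0])
        assert (w.start, w.end) == (45_000, 50_500)


class TestTransitions:
    def test_identical_conditions_are_all_diagonal(self, state_paths):
        peaks = {
            key: read_peaks(state_paths[key])
            for key in state_paths
            if key != "truth"
        }
        universe = build_region_universe(list(peaks.values()))
        marks_a = {m: peaks[f"{m}_condA"] for m in ("k4me1", "k27ac", "k27me3")}
        calls = call_states(universe, marks_a, "condA")
        table = compute_transitions(calls, calls)
        assert count_changed(table) == 0
        assert table["count"].sum() == len(universe)

    def test_three_region_plan_counts_off_diagonal(self, tmp_path):
        from chromswitch.synthetic_data import SimulationConfig, simulate_state_dataset

        plan = [("quiescent", "active"), ("active", "primed"), ("active", "active")]
        paths = simulate_state_dataset(SimulationConfig(seed=0), tmp_path, plan)
        peaks = {k: read_peaks(v) for k, v in paths.items() if k != "truth"}
        universe = build_region_universe(list(peaks.values()))
        calls = {
            cond: call_states(
                universe, {m: peaks[f"{m}_{cond}"] for m in ("k4me1", "k27ac", "k27me3")}, cond
            )
            for cond in ("condA", "condB")
        }
        table = compute_transitions(calls["condA"], calls["condB"])
        assert count_changed(table) == 2
        assert table["count"].sum() == len(universe)

    def test_planted_truth_recovered_exactly(self, state_paths):
        """Noise-free planted states are reproduced region for region."""
        truth = pd.read_csv(state_paths["truth"], sep="\t")
        peaks = {k: read_peaks(v) for k, v in state_paths.items() if k != "truth"}
        universe = build_region_universe(list(peaks.values()))
        calls = {
            cond: call_states(
                universe, {m: peaks[f"{m}_{cond}"] for m in ("k4me1", "k27ac", "k27me3")}, cond
            )
            for cond in ("condA", "condB")
        }
        # regions whose planted states imply no marks in either condition do not
        # enter the universe; all others must match the truth table
        by_pos = {
            (r.chrom, r.start): (a, b)
            for r, a, b in zip(
                truth.apply(lambda x: GenomicInterval(x.chrom, x.start, x.end), axis=1),
                truth.state_a,
                truth.state_b,
            )
        }
        n_checked = 0
        for ca, cb in zip(calls["condA"], calls["condB"]):
            key = (ca.region.chrom, ca.region.start)
            assert key in by_pos
            assert (ca.state.value, cb.state.value) == by_pos[key]
            n_checked += 1
        n_visible = sum(
            1 for a, b in zip(truth.state_a, truth.state_b)
            if (a, b) != ("quiescent", "quiescent")
        )
        assert n_checked == n_visible

    def test_marginals_conserved(self, state_paths):
        peaks = {k: read_peaks(v) for k, v in state_paths.items() if k != "truth"}
        universe = build_region_universe(list(peaks.values()))
        calls = {
            cond: call_states(
                universe, {m: peaks[f"{m}_{cond}"] for m in ("k4me1", "k27ac", "k27me3")}, cond
            )
            for cond in ("condA", "condB")
        }
        table = compute_transitions(calls["condA"], calls["condB"])
        row_sums = table.groupby("state_a")["count"].sum().to_dict()
        from collections import Counter

        assert row_sums == Counter(c.state.value for c in calls["condA"])
        col_sums = table.groupby("state_b")["count"].sum().to_dict()
        assert col_sums == Counter(c.state.value for c in calls["condB"])

    def test_mismatched_universes_rejected(self):
        from chromswitch.chromatin_states import StateCall

        a = [StateCall(REGION, ChromatinState.ACTIVE, "a", "distal")]
        b = [StateCall(GenomicInterval("chr1", 0, 1000), ChromatinState.ACTIVE, "b", "distal")]
        with pytest.raises(ValidationError):
            compute_transitions(a, b)


class TestFractionCovered:
    def test_full_and_empty_coverage(self):
        targets = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(5)]
        covering = [[make_peak("chr1", 0, 10_000)]]
        assert fraction_covered(targets, covering) == 1.0
        assert fraction_covered(targets, []) == 0.0
        assert fraction_covered([], covering) == 0.0

    def test_random_targets_match_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        targets = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 100_000, 100)
        ]
        peaks = [
            make_peak("chr1", int(s), int(s) + int(ln))
            for s, ln in zip(rng.integers(0, 100_000, 50), rng.integers(50, 400, 50))
        ]
        expected = (
            sum(any(t.overlaps(p.interval) for p in peaks) for t in targets) / 100
        )
        assert fraction_covered(targets, [peaks]) == expected
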