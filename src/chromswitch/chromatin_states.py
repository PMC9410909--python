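"""Rule-based chromatin-state classification and cross-condition transitions.

Each histone-mark peak summit defines a 1-kb window; windows from all marks
and both conditions are merged into one shared region universe.  A region's
state per condition follows mark co-occurrence: active (H3K4me1 + H3K27ac),
primed (H3K4me1 only), repressed (H3K27me3), quiescent (no marks).  H3K27ac
without H3K4me1 is an unenumerated combination and is labelled OTHER (a
config switch folds it into ACTIVE).  Cross-tabulating the two conditions'
calls gives the transition table behind an alluvial plot; off-diagonal
cells are state-switching regions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_io import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    Peak,
    ValidationError,
    merge_intervals,
)

PROMOTER_UPSTREAM = 5000
PROMOTER_DOWNSTREAM = 500
WINDOW_HALF = 500


class ChromatinState(enum.Enum):
    ACTIVE = "active"
    PRIMED = "primed"
    QUIESCENT = "quiescent"
    REPRESSED = "repressed"
    OTHER = "other"


@dataclass(frozen=True)
class StateCall:
    region: GenomicInterval
    state: ChromatinState
    condition: str
    compartment: str  # promoter | distal
    multi_match: bool = False


def summit_window(peak: Peak, half: int = WINDOW_HALF) -> GenomicInterval:
    """1-kb window spanning the peak summit, clipped at the chromosome start."""
    start = max(0, peak.summit - half)
    return GenomicInterval(peak.interval.chrom, start, peak.summit + half)


def build_region_universe(
    peaksets: Sequence[Sequence[Peak]], half: int = WINDOW_HALF
) -> list[GenomicInterval]:
    """Merged universe of summit windows across all marks and conditions.

    Windows overlapping by >=1 bp are merged into a single universe region,
    so both conditions are classified over identical regions and transitions
    are well defined.  Merged regions longer than 1 kb are kept as merged.
    """
    windows = [summit_window(p, half) for peaks in peaksets for p in peaks]
    return merge_intervals(windows)


def classify_state(
    region: GenomicInterval,
    k4me1: IntervalIndex,
    k27ac: IntervalIndex,
    k27me3: IntervalIndex,
    fold_other_into_active: bool = False,
) -> tuple[ChromatinState, bool]:
    """State of one region from >=1 bp overlap with condition-specific peaks.

    Precedence: active marks dominate (active, then primed), then repressed,
    then quiescent.  The multi-match flag records H3K27me3 co-occurring with
    an active or primed call (bivalent-like regions), preserved for audit.
    """
    has_k4 = k4me1.overlaps_interval(region)
    has_ac = k27ac.overlaps_interval(region)
    has_me3 = k27me3.overlaps_interval(region)
    if has_k4 and has_ac:
        return ChromatinState.ACTIVE, has_me3
    if has_k4:
        return ChromatinState.PRIMED, has_me3
    if has_me3:
        return ChromatinState.REPRESSED, False
    if has_ac:
        state = ChromatinState.ACTIVE if fold_other_into_active else ChromatinState.OTHER
        return state, has_me3 and state is ChromatinState.ACTIVE
    return ChromatinState.QUIESCENT, False


def promoter_window(gene: GeneModel) -> GenomicInterval:
    """Strand-aware promoter: 5 kb upstream through 500 bp downstream of the TSS."""
    tss = gene.tss
    if gene.interval.strand == "+":
        start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    else:
        start, end = tss + 1 - PROMOTER_DOWNSTREAM, tss + 1 + PROMOTER_UPSTREAM
    return GenomicInterval(gene.interval.chrom, max(0, start), end)


class GeneAnnotator:
    """Promoter / gene-body / distal annotation against a fixed gene set."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._promoters = IntervalIndex(promoter_window(g) for g in genes)
        self._bodies = IntervalIndex(g.interval for g in genes)

    def compartment(self, region: GenomicInterval) -> str:
        """Two-way annotation used by the state transition table."""
        return "promoter" if self._promoters.overlaps_interval(region) else "distal"

    def location(self, region: GenomicInterval) -> str:
        """Three-way annotation; promoter takes precedence over gene body."""
        if self._promoters.overlaps_interval(region):
            return "promoter"
        if self._bodies.overlaps_interval(region):
            return "gene_body"
        return "distal"


def call_states(
    universe: Sequence[GenomicInterval],
    peaks_by_mark: Mapping[str, Sequence[Peak]],
    condition: str,
    genes: Sequence[GeneModel] | GeneAnnotator = (),
    fold_other_into_active: bool = False,
) -> list[StateCall]:
    """Classify every universe region for one condition.

    ``peaks_by_mark`` must carry keys 'k4me1', 'k27ac', 'k27me3'.
    """
    idx = {
        mark: IntervalIndex(p.interval for p in peaks_by_mark.get(mark, []))
        for mark in ("k4me1", "k27ac", "k27me3")
    }
    annot = genes if isinstance(genes, GeneAnnotator) else GeneAnnotator(list(genes))
    calls = []
    for region in universe:
        state, flag = classify_state(
            region, idx["k4me1"], idx["k27ac"], idx["k27me3"], fold_other_into_active
        )
        calls.append(
            StateCall(region, state, condition, annot.compartment(region), flag)
        )
    return calls


def compute_transitions(
    calls_a: Sequence[StateCall], calls_b: Sequence[StateCall]
) -> pd.DataFrame:
    """Cross-condition transition counts per compartment.

    Returns a tidy frame with columns state_a, state_b, compartment, count.
    Counts partition the universe: their total equals the number of regions.
    """
    if [c.region for c in calls_a] != [c.region for c in calls_b]:
        raise ValidationError("state calls cover different region universes")
    df = pd.DataFrame(
        {
            "state_a": [c.state.value for c in calls_a],
            "state_b": [c.state.value for c in calls_b],
            "compartment": [c.compartment for c in calls_a],
        }
    )
    out = (
        df.groupby(["state_a", "state_b", "compartment"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out


def count_changed(transitions: pd.DataFrame) -> int:
    """Number of regions in off-diagonal cells (state-switching regions)."""
    off = transitions[transitions["state_a"] != transitions["state_b"]]
    return int(off["count"].sum())


def fraction_covered(
    targets: Sequence[GenomicInterval], peak_sets: Sequence[Sequence[Peak]]
) -> float:
    """Fraction of targets overlapping >=1 peak from the union of peak sets.

    Used for time-course accounting: e.g. the share of newly opened regions
    touched by TF binding at any profiled timepoint.
    """
    if not targets:
        return 0.0
    idx = IntervalIndex(p.interval for peaks in peak_sets for p in peaks)
    hit = sum(idx.overlaps_interval(t) for t in targets)
    return hit / len(targets)
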