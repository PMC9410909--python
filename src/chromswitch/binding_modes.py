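"""Summit-centered multi-track signal matrices and binding-mode clustering.

TF-bound regions are summarised as binned mean signal over a 4-kb window
around each peak summit, one block of bins per track (TF, ATAC per
condition, histone marks).  Columns are z-scored across regions and rows
clustered with Euclidean k-means (k = 4 by default).  Clusters receive
semantic labels from their centroid signal: C1 = accessible in both
conditions (TF binds already-open chromatin), C2 = opened in condition B
only (pioneer-style de novo opening), C3 = H3K27me3-marked, C4 = closed
with low signal everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import Peak, SignalTrack, ValidationError


@dataclass
class SignalMatrix:
    """Region x (track x bin) binned mean signal around peak summits."""

    values: np.ndarray  # shape (n_regions, n_tracks * n_bins)
    peaks: list[Peak]
    track_names: list[str]
    n_bins: int
    window: int
    clipped: np.ndarray = field(default=None)  # bool per region

    def track_block(self, name: str) -> np.ndarray:
        """The (n_regions, n_bins) sub-matrix of one track."""
        i = self.track_names.index(name)
        return self.values[:, i * self.n_bins : (i + 1) * self.n_bins]

    def track_window_means(self) -> pd.DataFrame:
        """Per-region whole-window mean per track."""
        return pd.DataFrame(
            {name: self.track_block(name).mean(axis=1) for name in self.track_names}
        )


@dataclass
class ModeAssignment:
    cluster: np.ndarray  # 1-based cluster index per region
    labels: dict[int, str]  # cluster index -> C1..C4 | unlabeled
    centroids: pd.DataFrame  # cluster index x track, raw window means
    inertia: float = float("nan")

    def label_of(self, region_idx: int) -> str:
        return self.labels[int(self.cluster[region_idx])]


def extract_matrix(
    peaks: Sequence[Peak],
    tracks: Mapping[str, SignalTrack],
    window: int = 4000,
    n_bins: int = 40,
) -> SignalMatrix:
    """Binned mean signal in the summit +/- window/2 region, per track.

    Windows extending past the chromosome start are zero-padded bin-wise
    and the region is flagged as clipped.
    """
    if n_bins < 1 or window % n_bins != 0:
        raise ValidationError("n_bins must divide window")
    bin_w = window // n_bins
    half = window // 2
    names = list(tracks)
    values = np.zeros((len(peaks), len(names) * n_bins), dtype=float)
    clipped = np.zeros(len(peaks), dtype=bool)
    for r, peak in enumerate(peaks):
        w_start = peak.summit - half
        if w_start < 0:
            clipped[r] = True
        for t, name in enumerate(names):
            track = tracks[name]
            for b in range(n_bins):
                s = w_start + b * bin_w
                e = s + bin_w
                if e <= 0:
                    continue  # fully off-chromosome: stays 0
                values[r, t * n_bins + b] = track.total(
                    peak.interval.chrom, max(s, 0), e
                ) / bin_w
    return SignalMatrix(values, list(peaks), names, n_bins, window, clipped)


def standardize(values: np.ndarray) -> np.ndarray:
    """Column z-scores across regions; zero-variance columns map to 0."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def cluster_modes(
    matrix: SignalMatrix,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> ModeAssignment:
    """Euclidean k-means on column-standardized profiles.

    Best of ``n_init`` restarts by within-cluster sum of squares; fully
    deterministic under a fixed seed.  Cluster indices are re-ordered by
    descending cluster size (ties by first occurrence) so replicate runs
    agree on numbering.
    """
    n = matrix.values.shape[0]
    if n < k:
        raise ValidationError(f"need >= {k} regions to form {k} clusters, got {n}")
    z = standardize(matrix.values)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(z)
    # stable renumbering: by size, then by first row index
    order = sorted(
        range(k),
        key=lambda c: (-np.sum(raw_labels == c), int(np.argmax(raw_labels == c))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    cluster = np.array([remap[c] for c in raw_labels], dtype=int)
    window_means = matrix.track_window_means()
    centroids = window_means.groupby(cluster).mean()
    centroids.index.name = "cluster"
    labels = {c: "unlabeled" for c in range(1, k + 1)}
    return ModeAssignment(cluster, labels, centroids, float(km.inertia_))


def label_clusters(
    assignment: ModeAssignment,
    atac_a: str,
    atac_b: str,
    k27me3: str = "k27me3_condA",
    margin: float = 1.5,
) -> ModeAssignment:
    """Attach C1-C4 semantics from centroid window means.

    Per track, a centroid is "high" when its window mean exceeds ``margin``
    times the across-cluster median.  Rule order: high ATAC in both
    conditions -> C1; not-high in A but high in B -> C2; else high H3K27me3
    -> C3; else low on all three informative tracks -> C4; anything else
    (or a label already taken) stays unlabeled.
    """
    cent = assignment.centroids
    for name in (atac_a, atac_b, k27me3):
        if name not in cent.columns:
            raise ValidationError(f"centroids lack required track {name!r}")
    med = cent.median(axis=0)

    def high(c: int, track: str) -> bool:
        return cent.loc[c, track] > margin * med[track]

    labels: dict[int, str] = {}
    taken: set[str] = set()
    for c in cent.index:
        if high(c, atac_a) and high(c, atac_b):
            label = "C1"
        elif not high(c, atac_a) and high(c, atac_b):
            label = "C2"
        elif high(c, k27me3):
            label = "C3"
        elif not high(c, atac_b) and not high(c, k27me3):
            label = "C4"
        else:
            label = "unlabeled"
        if label != "unlabeled" and label in taken:
            label = "unlabeled"
        taken.add(label)
        labels[int(c)] = label
    return ModeAssignment(
        assignment.cluster, labels, assignment.centroids, assignment.inertia
    )


def average_signal(
    peaks: Sequence[Peak], track: SignalTrack, window: int = 4000
) -> tuple[np.ndarray, float | None]:
    """Mean signal over each summit-centered window, plus the group mean.

    The group mean is the unweighted mean of region means; it is None for
    an empty region list.
    """
    half = window // 2
    means = np.array(
        [
            track.total(p.interval.chrom, max(0, p.summit - half), p.summit + half)
            / window
            for p in peaks
        ],
        dtype=float,
    )
    group = float(means.mean()) if len(means) else None
    return means, group
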