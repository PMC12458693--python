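"""Hydration-site analysis: cluster sampled water oxygens into sites, score
their occupancies, and compare against crystallographic waters.

Oxygen positions pooled over all frames are clustered by average-linkage
hierarchical clustering cut at a fixed linkage distance (2.4 A by default,
the conventional hydration-site cutoff); a site's occupancy is the fraction
of frames in which the cluster is populated, so it is capped at 1 even if a
site transiently holds two waters.  Prediction quality against a crystal
structure is summarised by the true positive rate

    TPR = TP / (TP + FN),

where a crystallographic site counts as TP when at least one predicted site
centroid lies within the match threshold (1.5 A by default, inclusive), and
FN otherwise.  The metric is per-crystal-site: one predicted site may satisfy
several crystal sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

__all__ = [
    "WaterSiteCluster",
    "SiteComparison",
    "cluster_water_sites",
    "filter_by_occupancy",
    "true_positive_rate",
    "DEFAULT_CLUSTER_CUTOFF",
    "DEFAULT_MATCH_THRESHOLD",
    "DEFAULT_OCCUPANCY_FILTER",
]

DEFAULT_CLUSTER_CUTOFF = 2.4  # A, average-linkage cut
DEFAULT_MATCH_THRESHOLD = 1.5  # A, predicted-vs-crystal match radius
DEFAULT_OCCUPANCY_FILTER = 0.30  # sites below this frame fraction are dropped


@dataclass
class WaterSiteCluster:
    """A clustered hydration site."""

    centroid: np.ndarray  # (3,), mean of member oxygen positions
    occupancy: float  # fraction of frames contributing >= 1 member
    n_members: int
    frames: np.ndarray  # sorted unique contributing frame indices

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def cluster_water_sites(
    frames: Sequence[np.ndarray], cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> list[WaterSiteCluster]:
    """Average-linkage clustering of oxygen positions pooled over frames.

    Returns clusters sorted by occupancy (descending), ties by member count
    then by centroid coordinates, so the ordering is deterministic and
    independent of frame order.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    pts, frame_idx = [], []
    for fi, fr in enumerate(frames):
        fr = np.asarray(fr, dtype=float).reshape(-1, 3)
        pts.append(fr)
        frame_idx.extend([fi] * len(fr))
    coords = np.vstack(pts) if pts else np.zeros((0, 3))
    frame_idx = np.array(frame_idx, dtype=int)
    n_frames = len(frames)
    if len(coords) == 0:
        return []
    if len(coords) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(coords, method="average"), t=cutoff, criterion="distance")

    clusters = []
    for lab in np.unique(labels):
        sel = labels == lab
        members = coords[sel]
        cf = np.unique(frame_idx[sel])
        clusters.append(
            WaterSiteCluster(
                centroid=members.mean(axis=0),
                occupancy=len(cf) / n_frames,
                n_members=int(sel.sum()),
                frames=cf,
            )
        )
    clusters.sort(
        key=lambda c: (-c.occupancy, -c.n_members, tuple(np.round(c.centroid, 9)))
    )
    return clusters


def filter_by_occupancy(
    clusters: Sequence[WaterSiteCluster], threshold: float = DEFAULT_OCCUPANCY_FILTER
) -> list[WaterSiteCluster]:
    """Keep clusters with occupancy >= threshold (inclusive boundary)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [c for c in clusters if c.occupancy >= threshold]


@dataclass
class SiteComparison:
    """Per-crystal-site comparison of predicted hydration sites."""

    tp: int
    fn: int
    tpr: float
    match_threshold: float
    matches: list  # per crystal site: list of matching predicted-site indices

    def __post_init__(self):
        if self.tp + self.fn > 0 and abs(self.tpr - self.tp / (self.tp + self.fn)) > 1e-12:
            raise ValueError("inconsistent TPR")


def true_positive_rate(
    predicted: Sequence[np.ndarray] | np.ndarray,
    crystal: Sequence[np.ndarray] | np.ndarray,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> SiteComparison:
    """TPR of predicted site centroids against crystallographic oxygens."""
    if threshold <= 0:
        raise ValueError("match threshold must be positive")
    crystal = np.atleast_2d(np.asarray(crystal, dtype=float))
    if crystal.size == 0:
        raise ValueError("TPR undefined: no crystallographic sites supplied")
    pred = [np.asarray(getattr(p, "centroid", p), dtype=float) for p in predicted]
    pred = np.vstack(pred) if pred else np.zeros((0, 3))
    if len(pred):
        d = cdist(crystal, pred)
        matches = [list(np.flatnonzero(row <= threshold)) for row in d]
    else:
        matches = [[] for _ in crystal]
    tp = sum(1 for m in matches if m)
    fn = len(matches) - tp
    return SiteComparison(tp, fn, tp / (tp + fn), threshold, matches)
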