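"""Boundary-vector layout feature models and dissimilarity matrices.

Two egocentric descriptions of the visible room boundaries:

* **Orientation model** — the wall-plane orientation O(phi), a piecewise
  constant function of viewing direction phi over the horizontal field of
  view, integrated against five triangular soft-histogram kernels
  F_i(phi) = max(0, (sigma - |phi - phi_i^c|)/sigma) with sigma = FOV/5:
  R_i = integral O(phi) F_i(phi) dphi.  Directions with no visible side
  wall contribute O(phi) = 0.
* **Relative distance model** — the proportion of side-wall pixels in
  each of five equal-width vertical strips of the segmentation map; more
  wall pixels in a strip means a nearer boundary in that direction.

Model RDMs are pairwise distances between feature vectors (city-block
for the layout models; Euclidean or cosine for external feature spaces);
neural RDMs are one minus the Pearson correlation between multivoxel
(or channel) patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .layout import LABEL_FIRST_WALL, AerialWallSpec, LayoutSegmentation

__all__ = [
    "FeatureVector",
    "RDM",
    "orientation_feature",
    "reldist_feature",
    "model_rdm",
    "neural_rdm",
]

_KNOWN_KINDS = ("orientation", "reldist", "pose", "generic")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with a kind tag."""

    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("feature vector must be 1D")
        if self.kind not in _KNOWN_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "pose" and v.size != 2:
            raise ValueError("pose features are (pitch, roll)")
        if self.kind == "reldist" and (np.any(v < 0) or np.any(v > 1)):
            raise ValueError("relative-distance values must lie in [0, 1]")


def orientation_feature(
    walls: list[AerialWallSpec],
    fov_deg: float,
    n_bins: int = 5,
    n_steps: int = 2000,
) -> FeatureVector:
    """Soft-histogram of wall-plane orientation across the field of view.

    Midpoint-rule integration on ``n_steps`` cells (default FOV/2000, about
    0.03 degrees for a 60-degree FOV — error far below any tolerance used
    here).  The grid is built symmetric about zero so mirrored scenes give
    exactly reversed feature vectors.  Overlapping wall spans are an
    inconsistent aerial view and raise ``ValueError``.
    """
    if fov_deg <= 0:
        raise ValueError("field of view must be positive")
    step = fov_deg / n_steps
    phi = (np.arange(n_steps) + 0.5 - n_steps / 2) * step  # midpoints, symmetric
    field_vals = np.zeros(n_steps)
    covered = np.zeros(n_steps, dtype=bool)
    for wall in walls:
        mask = (phi >= wall.phi_start_deg) & (phi < wall.phi_end_deg)
        if np.any(covered & mask):
            raise ValueError("overlapping wall spans: inconsistent aerial view")
        covered |= mask
        field_vals[mask] = wall.orientation_deg

    sigma = fov_deg / n_bins
    centers = (np.arange(n_bins) + 0.5 - n_bins / 2) * sigma
    kernels = np.maximum(0.0, (sigma - np.abs(phi[None, :] - centers[:, None])) / sigma)
    # fsum is summation-order independent (exactly rounded), so a mirrored
    # scene yields the exactly reversed feature vector.
    values = np.array([math.fsum(k * field_vals) * step for k in kernels])
    return FeatureVector(values, "orientation")


def reldist_feature(seg: LayoutSegmentation, n_bins: int = 5) -> FeatureVector:
    """Side-wall pixel proportion in equal vertical strips of the image.

    Strip boundaries are ``round(k W / n_bins)``; each strip's own pixel
    count is the denominator, so bins stay comparable when the width is
    not divisible by ``n_bins``.
    """
    h, w = seg.labels.shape
    if w < n_bins:
        raise ValueError(f"image width {w} smaller than {n_bins} strips")
    is_wall = seg.labels >= LABEL_FIRST_WALL
    bounds = [int(np.floor(k * w / n_bins + 0.5)) for k in range(n_bins + 1)]
    values = np.array(
        [float(np.mean(is_wall[:, bounds[k]: bounds[k + 1]])) for k in range(n_bins)]
    )
    return FeatureVector(values, "reldist")


@dataclass(frozen=True)
class RDM:
    """Square symmetric zero-diagonal dissimilarity matrix with condition labels."""

    matrix: np.ndarray
    condition_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        ids = self.condition_ids or tuple(f"cond_{i}" for i in range(m.shape[0]))
        ids = tuple(str(c) for c in ids)
        if len(ids) != m.shape[0]:
            raise ValueError("condition labels do not match matrix size")
        object.__setattr__(self, "condition_ids", ids)

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        """Off-diagonal entries in the standard condensed ordering."""
        return squareform(self.matrix, checks=False)

    @classmethod
    def from_vector(cls, vec: np.ndarray, condition_ids=()) -> "RDM":
        return cls(squareform(np.asarray(vec, dtype=float)), tuple(condition_ids))


_MODEL_METRICS = {"cityblock", "euclidean", "cosine"}


def model_rdm(features: np.ndarray, metric: str, condition_ids=()) -> RDM:
    """Pairwise-distance RDM over condition feature rows."""
    if metric not in _MODEL_METRICS:
        raise ValueError(f"metric must be one of {sorted(_MODEL_METRICS)}")
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2D feature matrix with at least 3 conditions")
    if metric == "cosine" and np.any(np.linalg.norm(x, axis=1) == 0):
        raise ValueError("cosine distance undefined for an all-zero feature row")
    d = squareform(pdist(x, metric=metric))
    np.fill_diagonal(d, 0.0)
    return RDM(d, tuple(condition_ids))


def neural_rdm(patterns: np.ndarray, condition_ids=()) -> RDM:
    """Correlation-distance RDM: 1 - Pearson r between condition patterns.

    Trial averaging (several presentations to one pattern per condition)
    is the caller's responsibility.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2D pattern matrix with at least 3 conditions")
    ids = tuple(condition_ids) or tuple(f"cond_{i}" for i in range(x.shape[0]))
    sd = x.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"condition {ids[i]!r} has a constant activation pattern")
    d = 1.0 - np.corrcoef(x)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(d, ids)
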