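"""Per-neuron summary metrics of intra-striatal end-points.

For each neuron: ipsi/contra counts, the natural log of the ipsilateral count
(undefined for zero counts, which are excluded from logarithmic analyses),
per-axis standard deviations of the ipsilateral cloud, its centroid, and the
standard deviation of Euclidean distances from each end-point to the centroid
(a scalar spread measure unifying the three axes).

SDs use (n-1) normalisation and are defined as exactly 0 for a single point,
so one-end-point neurons participate in dispersion histograms/correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .endpoints import EndpointSet

__all__ = ["NeuronMetrics", "endpoint_counts", "coordinate_sds", "distance_sd", "compute_metrics"]

Point = tuple[float, float, float]


@dataclass(frozen=True)
class NeuronMetrics:
    """Counts and dispersion metrics; NaN marks undefined (no ipsi end-point)."""

    n_ipsi: int
    n_contra: int
    ln_n_ipsi: float
    sd_x: float
    sd_y: float
    sd_z: float
    centroid: tuple[float, float, float]
    sd_dist: float


def _as_array(points: Sequence[Point]) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError("empty point set")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {arr.shape}")
    return arr


def _sd(values: np.ndarray) -> float:
    # (n-1) normalisation; single observation -> 0 by convention
    return 0.0 if values.shape[0] == 1 else float(np.std(values, ddof=1))


def endpoint_counts(es: EndpointSet) -> tuple[int, int, float]:
    """(n_ipsi, n_contra, ln n_ipsi); the log is NaN when n_ipsi = 0."""
    n_ipsi = len(es.ipsi_points)
    n_contra = len(es.contra_points)
    ln = math.log(n_ipsi) if n_ipsi >= 1 else math.nan
    return n_ipsi, n_contra, ln


def coordinate_sds(points: Sequence[Point]) -> tuple[float, float, float]:
    """Per-axis SD of a point cloud ((n-1) normalisation, 0 for n = 1)."""
    arr = _as_array(points)
    return tuple(_sd(arr[:, i]) for i in range(3))  # type: ignore[return-value]


def distance_sd(points: Sequence[Point]) -> tuple[tuple[float, float, float], float]:
    """Centroid (per-axis mean) and SD of point-to-centroid Euclidean distances."""
    arr = _as_array(points)
    centroid = arr.mean(axis=0)
    dists = np.linalg.norm(arr - centroid, axis=1)
    return tuple(centroid), _sd(dists)


def compute_metrics(es: EndpointSet) -> NeuronMetrics:
    """All per-neuron metrics; dispersion fields are NaN when there is no ipsi point."""
    n_ipsi, n_contra, ln = endpoint_counts(es)
    if n_ipsi == 0:
        nan = math.nan
        return NeuronMetrics(n_ipsi, n_contra, ln, nan, nan, nan, (nan, nan, nan), nan)
    sd_x, sd_y, sd_z = coordinate_sds(es.ipsi_points)
    centroid, sd_d = distance_sd(es.ipsi_points)
    return NeuronMetrics(n_ipsi, n_contra, ln, sd_x, sd_y, sd_z, centroid, sd_d)
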