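"""Edge/interior partitioning and distribution-heterogeneity statistics.

A cell midplane mask is split into an outer "edge" ring and an "interior"
core at a target area fraction using the Euclidean distance transform.
Three statistics quantify how receptor signal is distributed:

* the edge:interior mean-intensity ratio (and the integrated-intensity
  fraction at the edge),
* the Gini coefficient of pixel intensities (0 = perfectly even, 1 = all
  signal in one pixel, using the n/(n-1) normalisation so the one-pixel
  extreme is exactly 1),
* a greyscale Ripley's K function: the intensity-product pair mass within
  radius r, normalised by its expectation under a spatially random
  rearrangement of the same total intensity and scaled so that a
  homogeneous field gives the complete-spatial-randomness value pi r^2.
  Centre pixels are restricted to lie at least max(radii) from the cell
  boundary (erosion border correction).

The three-section position of a vesicle cluster relative to the cell
interface is also computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .imgmodel import Frame2D, PipelineParams

__all__ = [
    "CellRegions",
    "ClusterMetrics",
    "SectionPosition",
    "split_edge_interior",
    "gini_coefficient",
    "greyscale_ripley_k",
    "compute_cluster_metrics",
    "cluster_section",
]


@dataclass(frozen=True)
class CellRegions:
    """A cell mask partitioned into edge ring and interior core."""

    cell: np.ndarray
    edge: np.ndarray
    interior: np.ndarray
    target_fraction: float
    achieved_fraction: float
    edge_distance_px: float

    def __post_init__(self) -> None:
        if np.any(self.edge & self.interior):
            raise ValueError("edge and interior overlap")
        if not np.array_equal(self.edge | self.interior, self.cell):
            raise ValueError("edge and interior do not tile the cell")


@dataclass(frozen=True)
class ClusterMetrics:
    """Heterogeneity statistics for one cell."""

    edge_interior_ratio: float
    edge_integrated_fraction: float
    gini: float
    gini_unnormalized: float
    ripley_k: dict[int, float]
    ripley_k_norm: dict[int, float]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SectionPosition:
    """Which of three equal-depth bands (1 = interface-adjacent) holds a
    vesicle-cluster centroid."""

    section: int

    def __post_init__(self) -> None:
        if self.section not in (1, 2, 3):
            raise ValueError("section must be 1, 2 or 3")


def split_edge_interior(
    mask: np.ndarray, target_fraction: float = 0.35
) -> CellRegions:
    """Split a single cell mask into an outer edge ring and interior core.

    The edge is the set of pixels whose distance to the cell boundary is at
    most d*, where d* is the smallest distance for which the edge covers at
    least ``target_fraction`` of the cell area.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must lie in (0, 1]")
    n = int(mask.sum())
    if n < 25:
        raise ValueError(f"mask of {n} px is too small to partition")
    _, n_comp = ndi.label(mask)
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected instance, found {n_comp}")

    dist = ndi.distance_transform_edt(mask)
    inside = np.sort(dist[mask])
    k = int(np.ceil(target_fraction * n))
    d_star = float(inside[k - 1])
    if target_fraction < 1 and d_star < 1.0:
        raise ValueError("edge ring would be thinner than 1 px")
    edge = mask & (dist <= d_star)
    interior = mask & ~edge
    return CellRegions(
        cell=mask,
        edge=edge,
        interior=interior,
        target_fraction=target_fraction,
        achieved_fraction=float(edge.sum()) / n,
        edge_distance_px=d_star,
    )


def gini_coefficient(values: np.ndarray, normalized: bool = True) -> float:
    """Gini coefficient of a nonnegative sample.

    The unnormalised form is the mean absolute pairwise difference divided
    by twice the mean; with ``normalized=True`` it is multiplied by
    n/(n-1) so a one-hot sample scores exactly 1.  An all-zero sample is
    defined as perfectly even (0).
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    if np.any(x < 0):
        raise ValueError("Gini requires nonnegative values")
    total = x.sum()
    if total == 0:
        return 0.0
    i = np.arange(1, n + 1)
    g = (2.0 * np.sum(i * x) / (n * total)) - (n + 1.0) / n
    if normalized and n > 1:
        g *= n / (n - 1.0)
    return float(min(max(g, 0.0), 1.0))


def _disc_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = (yy**2 + xx**2 <= r**2).astype(float)
    k[r, r] = 0.0  # exclude the self pair
    return k


def greyscale_ripley_k(
    frame: np.ndarray,
    mask: np.ndarray,
    radii: tuple[int, ...] = tuple(range(1, 10)),
) -> tuple[dict[int, float], dict[int, float]]:
    """Intensity-weighted Ripley's K over a cell mask.

    For each radius r the observed cross-pair intensity mass
    sum_{i in C} w_i * sum_{0 < |j-i| <= r} w_j (centres C eroded by
    max(radii) so every disc lies inside the cell) is divided by its value
    for a homogeneous field of the same mean intensity and scaled by
    pi r^2.  A homogeneous cell therefore scores exactly pi r^2 at every
    radius, clustered signal scores above it, and an image whose signal
    sits in a single pixel has no cross pairs and scores 0.

    Returns ``(K, K_norm)`` where ``K_norm[r] = K[r] / (pi r^2)``.
    """
    w = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if w.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    radii = tuple(int(r) for r in radii)
    if not radii or any(r < 1 for r in radii):
        raise ValueError("radii must be integers >= 1")
    r_max = max(radii)
    dist = ndi.distance_transform_edt(mask)
    centres = dist > r_max  # full disc of every radius fits inside the mask
    if not centres.any():
        raise ValueError(
            f"cell too small for border correction at radius {r_max} px"
        )
    w_masked = np.where(mask, w, 0.0)
    mu = w_masked[mask].mean()
    k_out: dict[int, float] = {}
    k_norm: dict[int, float] = {}
    for r in radii:
        kern = _disc_kernel(r)
        neigh = ndi.convolve(w_masked, kern, mode="constant", cval=0.0)
        obs = float(np.sum(w_masked[centres] * neigh[centres]))
        n_r = kern.sum()
        csr = mu**2 * centres.sum() * n_r
        area = np.pi * r**2
        k_val = 0.0 if obs == 0 else area * obs / csr
        k_out[r] = k_val
        k_norm[r] = k_val / area
    return k_out, k_norm


def compute_cluster_metrics(
    frame: Frame2D,
    regions: CellRegions,
    radii: tuple[int, ...] | None = None,
    params: PipelineParams | None = None,
) -> ClusterMetrics:
    """Edge:interior ratio, Gini and greyscale Ripley's K for one cell.

    The frame is expected to be preprocessed (midplane selection, Gaussian
    smoothing, background subtraction) before measurement.
    """
    params = params or PipelineParams()
    radii = tuple(radii) if radii is not None else params.ripley_radii_px
    px = frame.pixels
    flags: list[str] = []

    edge_vals = px[regions.edge]
    int_vals = px[regions.interior]
    cell_vals = px[regions.cell]
    total = cell_vals.sum()

    if int_vals.size == 0 or int_vals.mean() == 0:
        flags.append("empty_interior")
        ratio = float("nan")
    else:
        ratio = float(edge_vals.mean() / int_vals.mean())
    edge_frac = float(edge_vals.sum() / total) if total > 0 else float("nan")
    if total == 0:
        flags.append("zero_signal")

    try:
        k, k_norm = greyscale_ripley_k(px, regions.cell, radii)
    except ValueError as exc:
        warnings.warn(str(exc), stacklevel=2)
        flags.append("ripley_unavailable")
        k, k_norm = {r: float("nan") for r in radii}, {r: float("nan") for r in radii}

    return ClusterMetrics(
        edge_interior_ratio=ratio,
        edge_integrated_fraction=edge_frac,
        gini=gini_coefficient(cell_vals, normalized=True),
        gini_unnormalized=gini_coefficient(cell_vals, normalized=False),
        ripley_k=k,
        ripley_k_norm=k_norm,
        flags=tuple(flags),
    )


def cluster_section(
    mask: np.ndarray,
    interface_point: tuple[float, float],
    interface_axis: tuple[float, float],
    cluster_centroid: tuple[float, float],
) -> SectionPosition:
    """Three-section position of a vesicle cluster behind the interface.

    The cell's extent along ``interface_axis`` (a vector pointing from the
    interface into the cell) is cut into three equal-depth bands starting
    at the interface; the band containing the cluster centroid is
    returned.  A centroid exactly on a band boundary is assigned to the
    nearer-interface band.
    """
    mask = np.asarray(mask, dtype=bool)
    axis = np.asarray(interface_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("interface_axis must be a nonzero vector")
    axis = axis / norm
    p0 = np.asarray(interface_point, dtype=float)

    coords = np.argwhere(mask).astype(float)
    if coords.size == 0:
        raise ValueError("empty mask")
    depths = (coords - p0) @ axis
    lo, hi = depths.min(), depths.max()
    d = float((np.asarray(cluster_centroid, dtype=float) - p0) @ axis)
    extent = hi - lo
    if extent <= 0:
        raise ValueError("degenerate cell extent along the interface axis")
    u = (d - lo) / extent
    if not -1e-9 <= u <= 1 + 1e-9:
        raise ValueError("cluster centroid lies outside the cell extent")
    if u <= 1.0 / 3.0:
        return SectionPosition(1)
    if u <= 2.0 / 3.0:
        return SectionPosition(2)
    return SectionPosition(3)
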