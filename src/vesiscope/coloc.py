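"""Pearson colocalization with the dual-colour TIRF and confocal
segmentation recipes.

Two segmentation routes feed the same correlation measurement:

* **TIRF route** — per-channel median filter, rolling-ball background
  subtraction and Sauvola local thresholding; fragments below 25 µm² and
  regions of circularity <= 0.2 removed; channels merged, watershed-split
  and connected-component labelled; cells kept in a 50-500 µm² area range
  and tracked through time, dropping short-lived tracks.
* **Confocal route** — with a nuclear stain, nuclei are segmented
  (median, background subtraction, Huang threshold, hole fill, size
  filter, solidification, watershed) and the cytoplasm is the binarized
  cell body minus nuclei, partitioned by nearest nucleus; without a
  nuclear stain, a membrane-focused recipe picks the best-focus slice by
  ridge content and binarizes an enhanced membrane probability.

PCC is always measured on the two *raw* channels inside each object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import sato, threshold_otsu, threshold_sauvola
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image, skeletonize
from skimage.segmentation import watershed

from .imgmodel import Frame2D, Movie, PipelineParams, Stack3D, rolling_ball_subtract

__all__ = [
    "SegmentedCell2D",
    "CytoplasmObject",
    "ColocResult",
    "pearson_coefficient",
    "huang_threshold",
    "segment_cells_tirf",
    "segment_cytoplasm_confocal",
    "tirf_coloc",
    "confocal_coloc",
]


@dataclass(frozen=True)
class SegmentedCell2D:
    """One tracked cell in a dual-colour TIRF movie."""

    track_id: int
    frames: tuple[int, ...]
    masks: tuple[np.ndarray, ...]          # full-frame boolean, one per frame
    areas_um2: tuple[float, ...]
    circularities: tuple[float, ...]

    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class CytoplasmObject:
    """Cytoplasm voxels of one cell (cell body minus nuclei), assigned to
    their nearest nucleus."""

    label: int
    nucleus_label: int
    mask: np.ndarray                       # (z, y, x) boolean
    mean_green: float


@dataclass(frozen=True)
class ColocResult:
    object_id: int
    frame: int | None
    pcc: float
    n_pixels: int
    flags: tuple[str, ...] = ()


def pearson_coefficient(
    ch1: Frame2D | np.ndarray,
    ch2: Frame2D | np.ndarray,
    region: np.ndarray,
) -> float:
    """Pearson correlation of the two raw channels within a region.

    Returns NaN (with a warning) when either channel has zero variance in
    the region.
    """
    a = ch1.pixels if isinstance(ch1, Frame2D) else np.asarray(ch1, dtype=float)
    b = ch2.pixels if isinstance(ch2, Frame2D) else np.asarray(ch2, dtype=float)
    region = np.asarray(region, dtype=bool)
    if a.shape != b.shape or a.shape != region.shape:
        raise ValueError("channel and region shapes differ")
    if not region.any():
        raise ValueError("empty region")
    x, y = a[region], b[region]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance channel in region; PCC undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def huang_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Huang's fuzzy-entropy threshold (minimum fuzziness criterion).

    For each candidate threshold the image is fuzzily partitioned into
    background/foreground with membership based on the distance of a grey
    level from its class mean; the threshold minimising total Shannon
    fuzziness is returned.  Not provided by scikit-image.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise ValueError("constant image has no threshold")
    hist, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w * centers)
    total_w, total_wx = cum_w[-1], cum_wx[-1]
    c = centers[-1] - centers[0]
    best_t, best_f = centers[0], np.inf
    for k in range(n_bins - 1):
        w0 = cum_w[k]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_wx[k] / w0
        mu1 = (total_wx - cum_wx[k]) / w1
        mu = np.where(np.arange(n_bins) <= k, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(centers - mu) / c)   # membership in [0.5, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -u * np.log(u) - (1 - u) * np.log(1 - u)
        s = np.where(np.isfinite(s), s, 0.0)
        f = float(np.sum(w * s))
        if f < best_f:
            best_f, best_t = f, centers[k]
    return float(best_t)


# -- dual-colour TIRF segmentation --------------------------------------------


def _circularity(region) -> float:
    p = region.perimeter_crofton
    return float(4 * np.pi * region.area / p**2) if p > 0 else 0.0


def _segment_channel_frame(
    img: np.ndarray, pixel_area_um2: float, params: PipelineParams
) -> np.ndarray:
    med = ndi.median_filter(img, size=2 * params.median_radius_px + 1)
    sub = rolling_ball_subtract(med, params.sauvola_radius_px)
    thr = threshold_sauvola(sub, window_size=2 * params.sauvola_radius_px + 1)
    binary = sub > thr
    min_px = max(1, int(round(params.min_fragment_um2 / pixel_area_um2)))
    # remove isolated fragments and fill holes below the fragment cut
    lab, n = ndi.label(binary)
    if n:
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_px
        keep[0] = False
        binary = keep[lab]
    lab, n = ndi.label(~binary)
    if n:
        sizes = np.bincount(lab.ravel())
        fill = sizes < min_px
        fill[0] = False
        binary |= fill[lab]
    # circularity filter
    lab, n = ndi.label(binary)
    out = np.zeros_like(binary)
    for r in regionprops(lab):
        if _circularity(r) > params.circularity_min:
            out[lab == r.label] = True
    return out


def segment_cells_tirf(
    ch1: Movie,
    ch2: Movie,
    params: PipelineParams | None = None,
) -> list[SegmentedCell2D]:
    """Segment and track cells in a dual-colour TIRF movie.

    Sizes printed as µm³ in the source recipe are treated as areas (µm²):
    the objects are 2D footprints.
    """
    params = params or PipelineParams()
    if ch1.shape != ch2.shape:
        raise ValueError("channels are not congruent")
    px_area = ch1.pixel_size_um**2
    lo, hi = params.cell_area_range_um2

    per_frame_labels: list[np.ndarray] = []
    for f1, f2 in zip(ch1.frames, ch2.frames):
        b1 = _segment_channel_frame(f1.pixels, px_area, params)
        b2 = _segment_channel_frame(f2.pixels, px_area, params)
        merged = ndi.median_filter(
            (b1 | b2).astype(np.uint8), size=2 * params.median_radius_px + 1
        ).astype(bool)
        dist = ndi.distance_transform_edt(merged)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(
            ndi.gaussian_filter(dist, 2.0), min_distance=10, labels=merged,
            exclude_border=False,
        )
        markers = np.zeros(merged.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        labels = (
            watershed(-dist, markers, mask=merged) if markers.max() else
            ndi.label(merged)[0]
        )
        keep = np.zeros_like(labels)
        nxt = 1
        for r in regionprops(labels):
            if lo <= r.area * px_area <= hi:
                keep[labels == r.label] = nxt
                nxt += 1
        per_frame_labels.append(keep)

    # greedy centroid tracking across frames
    tracks: list[dict] = []          # {"frames": [], "labels": [], "last_c": (y,x), "last_f": int}
    for t, labels in enumerate(per_frame_labels):
        regs = regionprops(labels)
        pairs = []
        for tr_i, tr in enumerate(tracks):
            if t - tr["last_f"] > 1:
                continue
            for r_i, r in enumerate(regs):
                d = np.hypot(tr["last_c"][0] - r.centroid[0], tr["last_c"][1] - r.centroid[1])
                if d <= params.linkage_threshold_px:
                    pairs.append((d, tr_i, r_i))
        pairs.sort(key=lambda p: p[0])
        used_t, used_r = set(), set()
        for d, tr_i, r_i in pairs:
            if tr_i in used_t or r_i in used_r:
                continue
            r = regs[r_i]
            tracks[tr_i]["frames"].append(t)
            tracks[tr_i]["labels"].append((t, r.label))
            tracks[tr_i]["last_c"] = r.centroid
            tracks[tr_i]["last_f"] = t
            used_t.add(tr_i)
            used_r.add(r_i)
        for r_i, r in enumerate(regs):
            if r_i not in used_r:
                tracks.append(
                    {"frames": [t], "labels": [(t, r.label)], "last_c": r.centroid, "last_f": t}
                )

    out: list[SegmentedCell2D] = []
    tid = 0
    for tr in tracks:
        if len(tr["frames"]) < params.min_track_frames:
            continue
        masks, areas, circs = [], [], []
        for t, lab in tr["labels"]:
            m = per_frame_labels[t] == lab
            masks.append(m)
            props = regionprops(m.astype(np.uint8))[0]
            areas.append(float(m.sum()) * px_area)
            circs.append(_circularity(props))
        out.append(
            SegmentedCell2D(
                track_id=tid,
                frames=tuple(tr["frames"]),
                masks=tuple(masks),
                areas_um2=tuple(areas),
                circularities=tuple(circs),
            )
        )
        tid += 1
    return out


def tirf_coloc(
    ch1: Movie, ch2: Movie, params: PipelineParams | None = None
) -> tuple[pd.DataFrame, list[SegmentedCell2D]]:
    """Per-cell, per-frame PCC of the two raw channels."""
    cells = segment_cells_tirf(ch1, ch2, params)
    rows = []
    for cell in cells:
        for t, mask in zip(cell.frames, cell.masks):
            pcc = pearson_coefficient(ch1.frames[t], ch2.frames[t], mask)
            rows.append(
                {"track_id": cell.track_id, "frame": t, "pcc": pcc, "n_pixels": int(mask.sum())}
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "pcc", "n_pixels"]), cells


# -- confocal cytoplasm segmentation ------------------------------------------


def _solidify(mask3d: np.ndarray) -> np.ndarray:
    """Per-slice convex-hull fill of a (near-convex) 3D object."""
    out = np.zeros_like(mask3d)
    for z in range(mask3d.shape[0]):
        if mask3d[z].any():
            out[z] = convex_hull_image(mask3d[z])
    return out


def _segment_nuclei(nuclei: Stack3D, params: PipelineParams) -> np.ndarray:
    vox = nuclei.voxels().astype(float)
    med = ndi.median_filter(vox, size=2 * params.median_radius_px + 1)
    sub = np.stack(
        [rolling_ball_subtract(s, params.paraboloid_radius_px) for s in med]
    )
    thr = huang_threshold(sub)
    binary = sub > thr
    binary = np.stack([ndi.binary_fill_holes(b) for b in binary])
    binary = np.stack(
        [ndi.median_filter(b.astype(np.uint8), size=2 * params.nuclei_median_radius_px + 1) for b in binary]
    ).astype(bool)
    lab, n = ndi.label(binary)
    voxel_um3 = nuclei.voxel_volume_um3()
    keep = np.zeros_like(lab)
    nxt = 1
    for k in range(1, n + 1):
        m = lab == k
        if m.sum() * voxel_um3 >= params.nucleus_min_um3:
            keep[_solidify(m)] = nxt
            nxt += 1
    if nxt == 1:
        return keep
    # split merged nuclei with a distance-based watershed
    fg = keep > 0
    dist = ndi.distance_transform_edt(fg)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        ndi.gaussian_filter(dist, 1.5), min_distance=5, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max():
        keep = watershed(-dist, markers, mask=fg)
    return keep


def segment_cytoplasm_confocal(
    gfp: Stack3D,
    nuclei: Stack3D | None = None,
    params: PipelineParams | None = None,
    mode: str = "nuclear",
    green_threshold: float | None = None,
    prob: Stack3D | None = None,
) -> list[CytoplasmObject]:
    """Cytoplasm (or membrane) objects for confocal colocalization.

    mode="nuclear" requires the nuclear-stain stack: cytoplasm = binarized
    cell foreground minus nuclei, partitioned by nearest nucleus, with
    objects below a mean green-intensity threshold (default: the 25th
    percentile of per-object means) excluded.

    mode="membrane" works without nuclei: a DoG filter picks the
    best-focus slice by summed ridge length, a membrane probability
    (pluggable via ``prob``; fallback: smoothed pseudo-probability) is
    median-filtered, Otsu-binarized and cleaned.
    """
    params = params or PipelineParams()
    if mode == "nuclear":
        if nuclei is None:
            raise ValueError("nuclear mode requires a nuclei stack")
        nuc_labels = _segment_nuclei(nuclei, params)
        if nuc_labels.max() == 0:
            raise ValueError("no nuclei found")
        vox = gfp.voxels().astype(float)
        med = ndi.median_filter(vox, size=2 * params.median_radius_px + 1)
        cell_fg = med > huang_threshold(med)
        cell_fg = np.stack([ndi.binary_fill_holes(b) for b in cell_fg])
        cyto = cell_fg & (nuc_labels == 0)
        # assign every cytoplasm voxel to its nearest nucleus
        nearest = watershed(
            ndi.distance_transform_edt(nuc_labels == 0), markers=nuc_labels, mask=cell_fg
        )
        objects: list[CytoplasmObject] = []
        nxt = 1
        for k in np.unique(nearest):
            if k == 0:
                continue
            region = (nearest == k) & cyto
            lab, n = ndi.label(region)
            for j in range(1, n + 1):
                m = lab == j
                objects.append(
                    CytoplasmObject(
                        label=nxt,
                        nucleus_label=int(k),
                        mask=m,
                        mean_green=float(vox[m].mean()) if m.any() else 0.0,
                    )
                )
                nxt += 1
        objects = [o for o in objects if o.mask.any()]
        if green_threshold is None and objects:
            green_threshold = float(
                np.percentile([o.mean_green for o in objects], 25.0)
            )
        return [o for o in objects if o.mean_green >= (green_threshold or 0.0)]

    if mode == "membrane":
        vox = gfp.voxels().astype(float)
        # best-focus slice: DoG enhancement, then summed ridge length
        best_z, best_len = 0, -1.0
        for z, sl in enumerate(vox):
            dog = ndi.gaussian_filter(sl, params.dog_radius_px / 2.0) - ndi.gaussian_filter(
                sl, params.dog_radius_px
            )
            ridge = sato(dog, sigmas=(2.0,), black_ridges=False)
            rt = ridge > max(ridge.max(), 1e-12) * 0.25
            length = float(skeletonize(rt).sum())
            if length > best_len:
                best_len, best_z = length, z
        if prob is None:
            from .membrane import pseudo_probability

            prob = pseudo_probability(gfp)
        pvox = prob.voxels()
        med = np.stack(
            [ndi.median_filter(s, size=2 * params.median_radius_px + 1) for s in pvox]
        )
        try:
            thr = threshold_otsu(med)
        except ValueError:
            return []
        binary = med > thr
        lab, n = ndi.label(binary)
        if n:
            sizes = np.bincount(lab.ravel())
            keep = sizes >= params.min_region_confocal_px3
            keep[0] = False
            binary = keep[lab]
        lab, n = ndi.label(~binary)
        if n:
            sizes = np.bincount(lab.ravel())
            fill = sizes < params.min_region_confocal_px3
            fill[0] = False
            binary |= fill[lab]
        struct = np.zeros((1, 2 * params.erode_radius_px + 1, 2 * params.erode_radius_px + 1), bool)
        yy, xx = np.mgrid[
            -params.erode_radius_px : params.erode_radius_px + 1,
            -params.erode_radius_px : params.erode_radius_px + 1,
        ]
        struct[0] = yy**2 + xx**2 <= params.erode_radius_px**2
        binary = ndi.binary_erosion(binary, structure=struct)
        lab, n = ndi.label(binary)
        out = []
        for k in range(1, n + 1):
            m = lab == k
            out.append(
                CytoplasmObject(
                    label=k,
                    nucleus_label=0,
                    mask=m,
                    mean_green=float(vox[m].mean()),
                )
            )
        return out

    raise ValueError(f"unknown mode {mode!r}")


def confocal_coloc(
    green: Stack3D,
    red: Stack3D,
    nuclei: Stack3D | None = None,
    params: PipelineParams | None = None,
    mode: str = "nuclear",
) -> tuple[pd.DataFrame, list[CytoplasmObject]]:
    """Per-object PCC of the raw green/red channels, both on the full 3D
    voxel set and on the object's central slice."""
    objects = segment_cytoplasm_confocal(green, nuclei, params, mode=mode)
    gv = green.voxels().astype(float)
    rv = red.voxels().astype(float)
    rows = []
    for o in objects:
        x, y = gv[o.mask], rv[o.mask]
        pcc3 = (
            float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 and y.std() > 0 else float("nan")
        )
        areas = o.mask.sum(axis=(1, 2))
        zc = int(np.argmax(areas))
        m2 = o.mask[zc]
        pcc2 = (
            pearson_coefficient(gv[zc], rv[zc], m2) if m2.any() else float("nan")
        )
        rows.append(
            {
                "object_id": o.label,
                "nucleus_label": o.nucleus_label,
                "pcc_3d": pcc3,
                "pcc_midplane": pcc2,
                "n_voxels": int(o.mask.sum()),
                "mean_green": o.mean_green,
            }
        )
    cols = ["object_id", "nucleus_label", "pcc_3d", "pcc_midplane", "n_voxels", "mean_green"]
    return pd.DataFrame(rows, columns=cols), objects
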