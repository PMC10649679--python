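"""Core image containers, physical calibration, TIFF I/O and shared preprocessing.

All computation is carried out in pixel units on 0-based ``(row, col)``
coordinates (``(z, row, col)`` for stacks, ``(t, row, col)`` for movies);
physical calibration (``pixel_size_um``, ``z_spacing_um``,
``frame_interval_s``) is only applied when results are reported in
micrometres or seconds.  The :class:`PipelineParams` registry holds every
numeric default used by the downstream analysis modules so that a single
object (or YAML/JSON file) fully specifies an analysis run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi
from skimage import restoration


__all__ = [
    "Frame2D",
    "Stack3D",
    "Movie",
    "LabelMask",
    "PipelineParams",
    "read_image",
    "write_image",
    "preprocess_midplane",
    "write_results",
    "gaussian_filter",
    "rolling_ball_subtract",
]


def _check_pixels(pixels: np.ndarray, ndim: int) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != ndim:
        raise ValueError(f"expected a {ndim}-D array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty pixel array")
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError(f"non-numeric pixel data of dtype {arr.dtype}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pixel intensities must be finite")
    if np.any(arr < 0):
        raise ValueError("pixel intensities must be nonnegative")
    return arr


@dataclass(frozen=True)
class Frame2D:
    """A single 2D intensity image with physical pixel calibration."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_pixels(self.pixels, 2))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass(frozen=True)
class Stack3D:
    """An ordered z-stack of congruent 2D frames (confocal acquisition)."""

    slices: tuple[Frame2D, ...]
    z_spacing_um: float

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise ValueError("a stack needs at least one slice")
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"slices disagree on shape: {shapes}")
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be > 0")
        object.__setattr__(self, "slices", slices)

    @property
    def pixel_size_um(self) -> float:
        return self.slices[0].pixel_size_um

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.slices),) + self.slices[0].shape

    def voxels(self) -> np.ndarray:
        """The stack as a ``(z, y, x)`` array (copy)."""
        return np.stack([s.pixels for s in self.slices])

    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_spacing_um

    @classmethod
    def from_array(
        cls, voxels: np.ndarray, pixel_size_um: float = 1.0, z_spacing_um: float = 1.0
    ) -> "Stack3D":
        voxels = np.asarray(voxels)
        return cls(
            tuple(Frame2D(v, pixel_size_um) for v in voxels), z_spacing_um=z_spacing_um
        )


@dataclass(frozen=True)
class Movie:
    """A time-lapse sequence of congruent 2D frames (TIRF acquisition)."""

    frames: tuple[Frame2D, ...]
    frame_interval_s: float
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("a movie needs at least one frame")
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames disagree on shape: {shapes}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.frames),) + self.frames[0].shape

    def pixels(self) -> np.ndarray:
        """The movie as a ``(t, y, x)`` array (copy)."""
        return np.stack([f.pixels for f in self.frames])

    def time_of(self, frame_index: int) -> float:
        return frame_index * self.frame_interval_s

    @classmethod
    def from_array(
        cls,
        frames: np.ndarray,
        frame_interval_s: float = 0.333,
        pixel_size_um: float = 1.0,
        channel_id: str = "ch0",
    ) -> "Movie":
        frames = np.asarray(frames)
        return cls(
            tuple(Frame2D(f, pixel_size_um) for f in frames),
            frame_interval_s=frame_interval_s,
            channel_id=channel_id,
        )


@dataclass(frozen=True)
class LabelMask:
    """Integer instance labels congruent with an image: 0 background, k>0 instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim not in (2, 3):
            raise ValueError("labels must be 2-D or 3-D")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.round(arr)):
                raise TypeError("labels must be integers")
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be nonnegative")
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def instance(self, k: int) -> np.ndarray:
        return self.labels == k


# -- parameter registry -------------------------------------------------------


@dataclass
class PipelineParams:
    """Every numeric default of the analysis recipes, in one place.

    Radii and thresholds quoted in pixels are applied in pixels; sizes in
    µm²/µm³ are converted with the image calibration at the point of use.
    """

    # edge/interior partition and clustering statistics
    edge_area_fraction: float = 0.35        # target edge share of midplane area
    gaussian_sigma_px: float = 1.0
    rollingball_radius_px: int = 100
    ripley_radii_px: tuple[int, ...] = tuple(range(1, 10))

    # membrane-fraction estimation (receptor-class dependent values carry
    # the inhibitory-receptor default; TCR-zeta / TIM3 variants are set via
    # `for_receptor_class`)
    surface_threshold_fraction: float = 0.30   # 0.30 inhibitory receptors, 0.50 TCR-zeta
    n_smallest_sigmas: int = 5                 # 5 inhibitory receptors, 20 TCR-zeta
    width_multiplier: float = 2.0              # 2 inhibitory receptors (but TIM3), 3 TIM3/TCR-zeta
    min_region_px3: int = 200
    max_cell_um3: float = 1800.0
    prob_binarize: float = 0.5

    # TIRF event detection
    otsu_scale: float = 0.90
    particle_p_threshold: float = 0.001
    xp_sigma_l_coeff: float = 4.0
    xp_sigma_g_coeff: float = 3.0
    n_local_minima: int = 3
    linkage_threshold_px: float = 22.0
    gap_frames: int = 3
    rate_window_frames: int = 100
    linescan_width_px: int = 20
    linescan_segments: int = 10

    # dual-colour TIRF cell segmentation
    sauvola_radius_px: int = 50
    min_fragment_um2: float = 25.0
    circularity_min: float = 0.2
    cell_area_range_um2: tuple[float, float] = (50.0, 500.0)
    min_track_frames: int = 5

    # confocal colocalization segmentation
    dog_radius_px: float = 6.0
    min_region_confocal_px3: int = 300
    erode_radius_px: int = 2
    paraboloid_radius_px: int = 30
    nucleus_min_um3: float = 20.0
    median_radius_px: int = 2
    nuclei_median_radius_px: int = 5

    def __post_init__(self) -> None:
        self.ripley_radii_px = tuple(int(r) for r in self.ripley_radii_px)
        if any(r < 1 for r in self.ripley_radii_px):
            raise ValueError("Ripley radii must be integers >= 1")
        for name in ("edge_area_fraction", "surface_threshold_fraction", "prob_binarize",
                     "otsu_scale", "particle_p_threshold", "circularity_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                raise ValueError(f"{f.name} must be strictly positive; got {v}")
        lo, hi = self.cell_area_range_um2
        if not 0 < lo < hi:
            raise ValueError("cell_area_range_um2 must be an increasing positive pair")

    @classmethod
    def for_receptor_class(cls, receptor_class: str, **overrides) -> "PipelineParams":
        """Parameter set for one of the three receptor classes.

        ``ir``   inhibitory receptors except TIM3: threshold 0.30, 5 sigmas, x2
        ``tim3`` TIM3:                             threshold 0.30, 5 sigmas, x3
        ``tcrz`` TCR-zeta:                         threshold 0.50, 20 sigmas, x3
        """
        presets = {
            "ir": dict(surface_threshold_fraction=0.30, n_smallest_sigmas=5, width_multiplier=2.0),
            "tim3": dict(surface_threshold_fraction=0.30, n_smallest_sigmas=5, width_multiplier=3.0),
            "tcrz": dict(surface_threshold_fraction=0.50, n_smallest_sigmas=20, width_multiplier=3.0),
        }
        if receptor_class not in presets:
            raise ValueError(f"unknown receptor class {receptor_class!r}; choose from {sorted(presets)}")
        kwargs = presets[receptor_class] | overrides
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ripley_radii_px"] = list(self.ripley_radii_px)
        d["cell_area_range_um2"] = list(self.cell_area_range_um2)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineParams":
        """Load parameters from a YAML or JSON mapping; unknown keys rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path} does not contain a parameter mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        data = dict(data)
        if "ripley_radii_px" in data:
            data["ripley_radii_px"] = tuple(data["ripley_radii_px"])
        if "cell_area_range_um2" in data:
            data["cell_area_range_um2"] = tuple(data["cell_area_range_um2"])
        return cls(**data)


# -- I/O ----------------------------------------------------------------------


def read_image(
    path: str | Path,
    kind: Literal["frame", "stack", "movie"],
    *,
    pixel_size_um: float = 1.0,
    z_spacing_um: float = 1.0,
    frame_interval_s: float = 0.333,
    channel_id: str = "ch0",
) -> Frame2D | Stack3D | Movie:
    """Read a single- or multi-page TIFF as a frame, z-stack or movie.

    Page count maps to z (``stack``) or t (``movie``); a ``frame`` requires
    exactly one page.  Physical calibration is attached from the keyword
    arguments, not parsed from TIFF metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of shape {pages.shape}")
    if kind == "frame":
        if pages.shape[0] != 1:
            raise ValueError(f"{path}: kind='frame' needs exactly 1 page, found {pages.shape[0]}")
        return Frame2D(pages[0], pixel_size_um)
    if kind == "stack":
        return Stack3D.from_array(pages, pixel_size_um, z_spacing_um)
    if kind == "movie":
        return Movie.from_array(pages, frame_interval_s, pixel_size_um, channel_id)
    raise ValueError(f"unknown kind {kind!r}")


def write_image(image: Frame2D | Stack3D | Movie | LabelMask, path: str | Path) -> Path:
    """Write an image container to a (multi-page) TIFF, preserving dtype."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, Frame2D):
        data = image.pixels
    elif isinstance(image, Stack3D):
        data = image.voxels()
    elif isinstance(image, Movie):
        data = image.pixels()
    elif isinstance(image, LabelMask):
        data = image.labels
    else:
        raise TypeError(f"cannot write object of type {type(image).__name__}")
    tifffile.imwrite(path, data)
    return path


def write_results(
    records: pd.DataFrame | Sequence[Mapping],
    path: str | Path,
    *,
    params: PipelineParams | None = None,
    seed: int | None = None,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write tabular results as CSV plus a JSON sidecar with params and seed.

    An empty record list still produces a header-only CSV (pass ``columns``
    to fix the header in that case).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    if columns is not None and df.empty:
        df = pd.DataFrame(columns=columns)
    df.to_csv(path, index=False)
    sidecar = {
        "n_records": int(len(df)),
        "seed": seed,
        "params": params.to_dict() if params is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


# -- shared preprocessing -----------------------------------------------------


def gaussian_filter(pixels: np.ndarray, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(np.asarray(pixels, dtype=float), sigma=sigma)


def rolling_ball_subtract(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Classical rolling-ball background subtraction; output clipped at 0.

    For large radii the background is estimated on a downsampled copy (the
    ball is smooth at that scale) and upsampled back, which keeps the cost
    independent of the radius.
    """
    img = np.asarray(pixels, dtype=float)
    shrink = max(1, int(radius) // 16)
    if shrink > 1:
        small = ndi.zoom(img, 1.0 / shrink, order=1)
        bg_small = restoration.rolling_ball(small, radius=max(1, radius // shrink))
        bg = ndi.zoom(bg_small, np.array(img.shape) / np.array(small.shape), order=1)
        # zoom rounding can mismatch by a pixel; crop/pad to the input shape
        bg = bg[: img.shape[0], : img.shape[1]]
        if bg.shape != img.shape:
            bg = np.pad(bg, ((0, img.shape[0] - bg.shape[0]), (0, img.shape[1] - bg.shape[1])), mode="edge")
    else:
        bg = restoration.rolling_ball(img, radius=radius)
    return np.clip(img - bg, 0.0, None)


def preprocess_midplane(stack: Stack3D, params: PipelineParams | None = None) -> Frame2D:
    """Extract and clean the analysis midplane from a z-stack.

    Selects the slice with the highest mean intensity, smooths it with a
    Gaussian filter (sigma 1 px by default) and removes diffuse background
    with rolling-ball subtraction (radius 100 px by default).
    """
    params = params or PipelineParams()
    means = [float(np.mean(s.pixels)) for s in stack.slices]
    if max(means) == 0:
        warnings.warn("all-zero stack; returning the first slice processed", stacklevel=2)
    idx = int(np.argmax(means))
    img = gaussian_filter(stack.slices[idx].pixels, params.gaussian_sigma_px)
    img = rolling_ball_subtract(img, params.rollingball_radius_px)
    return Frame2D(img, stack.pixel_size_um)
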