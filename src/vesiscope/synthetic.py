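"""Synthetic fluorescence-microscopy data with exact ground truth.

Every generator produces both the image container and a
:class:`SyntheticGroundTruth` record holding the noise-free quantities the
downstream analyses are supposed to recover (signal fractions, event lists,
channel correlation, the exact masks used).  All randomness flows from the
``seed`` field of the scene description, so identical specs give identical
arrays.

The scenes emulate the statistical structure of T-cell imaging data:
roughly circular/spherical cells, a configurable share of signal at the
cell edge or membrane, punctate vesicular clustering, TIRF footprints with
abrupt vesicle-insertion events and slowly ramping microclusters, Poisson
photon noise followed by Gaussian read noise.  They do not emulate optics
beyond a Gaussian PSF, nor photobleaching or cell motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage as ndi

from .imgmodel import Frame2D, LabelMask, Movie, Stack3D

__all__ = [
    "SceneSpec",
    "TirfSceneSpec",
    "InsertionEventSpec",
    "MicroclusterEventSpec",
    "SyntheticGroundTruth",
    "generate_confocal_cell",
    "generate_cell_stack",
    "generate_tirf_movie",
    "generate_correlated_pair",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Exact-by-construction truth attached to a generated dataset."""

    events: tuple = ()
    edge_signal_fraction: float | None = None
    membrane_fraction: float | None = None
    gini_regime: str | None = None
    rho: float | None = None
    masks: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _apply_noise(
    clean: np.ndarray,
    rng: np.random.Generator,
    poisson_gain: float,
    read_sigma: float,
) -> np.ndarray:
    """Photon shot noise (Poisson at `poisson_gain` photons per intensity
    unit) followed by additive Gaussian read noise; clipped at zero."""
    out = np.asarray(clean, dtype=float)
    if poisson_gain > 0:
        out = rng.poisson(out * poisson_gain).astype(float) / poisson_gain
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# -- confocal midplane cell ---------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Description of a single synthetic confocal cell.

    ``edge_signal_fraction`` is the share of total noise-free signal placed
    in the outer ring whose area is ``edge_area_fraction`` of the cell; the
    remainder is uniform in the interior unless ``n_puncta`` > 0, in which
    case it is concentrated into Gaussian puncta.  The default photon scale
    (about 200 photons at a typical cell pixel) reflects spinning-disk GFP
    imaging; shot noise then dominates read noise.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.25
    center: tuple[float, float] | None = None
    radius_px: float = 40.0
    edge_signal_fraction: float = 0.5
    edge_area_fraction: float = 0.35
    n_puncta: int = 0
    punctum_sigma_px: float = 2.0
    background: float = 10.0
    total_signal: float = 2.0e6
    poisson_gain: float = 1.0
    read_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.edge_signal_fraction <= 1:
            raise ValueError("edge_signal_fraction must lie in [0, 1]")
        if not 0 < self.edge_area_fraction <= 1:
            raise ValueError("edge_area_fraction must lie in (0, 1]")
        if self.punctum_sigma_px <= 0:
            raise ValueError("punctum_sigma_px must be > 0")
        cy, cx = self.effective_center()
        h, w = self.shape
        r = self.radius_px
        if cy - r < 0 or cx - r < 0 or cy + r >= h or cx + r >= w:
            raise ValueError("cell disk must fit inside the frame")

    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


def _edge_ring(mask: np.ndarray, edge_area_fraction: float) -> tuple[np.ndarray, float]:
    """Outer ring of `mask` covering at least `edge_area_fraction` of its area.

    Thresholds the Euclidean distance-to-background transform at the
    smallest distance that reaches the target share.
    """
    dist = ndi.distance_transform_edt(mask)
    inside = np.sort(dist[mask])
    n = inside.size
    k = int(np.ceil(edge_area_fraction * n))
    thinnest = int((dist[mask] <= 1.0).sum())
    if k < thinnest:
        raise ValueError(
            "edge ring thinner than 1 px: the requested edge area fraction "
            f"({edge_area_fraction}) is below the thinnest boundary ring "
            f"({thinnest / n:.2f} of the cell)"
        )
    d_star = inside[k - 1] if k >= 1 else 0.0
    ring = mask & (dist <= d_star)
    return ring, float(d_star)


def generate_confocal_cell(
    spec: SceneSpec,
) -> tuple[Frame2D, LabelMask, SyntheticGroundTruth]:
    """A disk-shaped cell with a prescribed edge/interior signal split."""
    rng = _rng(spec.seed)
    h, w = spec.shape
    cy, cx = spec.effective_center()
    yy, xx = np.mgrid[0:h, 0:w]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = dist2 <= spec.radius_px**2

    ring, d_star = _edge_ring(mask, spec.edge_area_fraction)
    if d_star < 1.0:
        raise ValueError("edge ring thinner than 1 px for this radius/fraction")
    interior = mask & ~ring

    clean = np.zeros((h, w), dtype=float)
    s_edge = spec.edge_signal_fraction * spec.total_signal
    s_int = (1.0 - spec.edge_signal_fraction) * spec.total_signal
    if ring.sum():
        clean[ring] = s_edge / ring.sum()
    if s_int > 0:
        if spec.n_puncta == 0:
            clean[interior] += s_int / max(interior.sum(), 1)
        else:
            # Gaussian puncta at random interior positions, scaled so the
            # in-interior punctum mass is exactly the interior share
            iy, ix = np.nonzero(interior)
            idx = rng.choice(iy.size, size=spec.n_puncta, replace=False)
            blob = np.zeros((h, w), dtype=float)
            for py, px in zip(iy[idx], ix[idx]):
                blob += np.exp(
                    -((yy - py) ** 2 + (xx - px) ** 2) / (2 * spec.punctum_sigma_px**2)
                )
            blob[~interior] = 0.0
            blob_sum = blob.sum()
            if blob_sum <= 0:
                raise RuntimeError("degenerate puncta placement")
            clean[interior] += blob[interior] * (s_int / blob_sum)

    noisy = _apply_noise(clean + spec.background * mask, rng, spec.poisson_gain, spec.read_sigma)
    frame = Frame2D(noisy, spec.pixel_size_um)
    label = LabelMask(mask.astype(np.int32))
    truth = SyntheticGroundTruth(
        edge_signal_fraction=spec.edge_signal_fraction,
        gini_regime="punctate" if spec.n_puncta else "uniform",
        masks={"cell": mask, "edge": ring, "interior": interior},
        extras={
            "clean": clean,
            "edge_ring_distance_px": d_star,
            "edge_mean_intensity": float(clean[ring].mean()) if ring.sum() else 0.0,
            "interior_mean_intensity": float(clean[interior].mean()) if interior.sum() else 0.0,
        },
    )
    return frame, label, truth


# -- 3D membrane/interior cell ------------------------------------------------


@dataclass(frozen=True)
class StackSceneSpec:
    """A spherical cell in a z-stack with a surface shell carrying a set
    fraction of the total signal.

    Geometry defaults mimic a T cell imaged at high resolution: radius
    about 4.3 µm (40 px at 0.108 µm/px), 0.25 µm z-spacing, a 1.5 px
    surface shell and a 1 px lateral PSF.  ``peak_photons`` sets the photon
    count at the blurred shell peak, hence the SNR (sqrt(peak_photons)).
    """

    shape: tuple[int, int, int] = (48, 128, 128)   # (z, y, x)
    pixel_size_um: float = 0.108
    z_spacing_um: float = 0.25
    center: tuple[float, float, float] | None = None
    radius_px: float = 40.0                        # lateral pixels
    membrane_fraction: float = 0.5
    shell_width_px: float = 1.5
    psf_sigma_px: float = 1.0
    background: float = 2.0
    peak_photons: float = 400.0
    read_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.membrane_fraction <= 1:
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if self.shell_width_px >= self.radius_px:
            raise ValueError("shell must fit inside the cell sphere")

    def effective_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        nz, ny, nx = self.shape
        return ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)

    def z_anisotropy(self) -> float:
        return self.z_spacing_um / self.pixel_size_um


def generate_cell_stack(
    spec: StackSceneSpec,
) -> tuple[Stack3D, SyntheticGroundTruth]:
    """Spherical cell: fraction f of signal in a surface shell, 1-f uniform
    inside, Gaussian PSF blur, then photon + read noise."""
    rng = _rng(spec.seed)
    nz, ny, nx = spec.shape
    cz, cy, cx = spec.effective_center()
    zfac = spec.z_anisotropy()
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    # physical distance in lateral-pixel units
    r = np.sqrt(((zz - cz) * zfac) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    shell = (r >= spec.radius_px - spec.shell_width_px) & (r <= spec.radius_px)
    interior = r < spec.radius_px - spec.shell_width_px

    clean = np.zeros(spec.shape, dtype=float)
    f = spec.membrane_fraction
    if shell.sum():
        clean[shell] = f / shell.sum()
    if interior.sum():
        clean[interior] = (1.0 - f) / interior.sum()

    if spec.psf_sigma_px > 0:
        sig = (spec.psf_sigma_px / zfac, spec.psf_sigma_px, spec.psf_sigma_px)
        blurred = ndi.gaussian_filter(clean, sigma=sig)
    else:
        blurred = clean
    peak = blurred.max()
    if peak <= 0:
        raise ValueError("empty cell")
    photons = blurred * (spec.peak_photons / peak) + spec.background
    noisy = _apply_noise(photons, rng, poisson_gain=1.0, read_sigma=spec.read_sigma)

    stack = Stack3D.from_array(noisy, spec.pixel_size_um, spec.z_spacing_um)
    truth = SyntheticGroundTruth(
        membrane_fraction=f,
        masks={"shell": shell, "interior": interior, "cell": shell | interior},
        extras={
            "clean": clean,
            "center": (cz, cy, cx),
            "radius_px": spec.radius_px,
            "shell_width_px": spec.shell_width_px,
            "psf_sigma_px": spec.psf_sigma_px,
        },
    )
    return stack, truth


# -- TIRF movies --------------------------------------------------------------


@dataclass(frozen=True)
class InsertionEventSpec:
    """Abrupt appearance then lateral dispersion: a 2D Gaussian appearing at
    full amplitude at `onset`, with sigma growing linearly and peak decaying
    exponentially."""

    onset: int
    position: tuple[float, float]
    amplitude: float = 60.0
    sigma0_px: float = 1.2
    sigma_growth_px_per_frame: float = 0.3
    decay_frames: float = 5.0
    kind: str = "insertion"


@dataclass(frozen=True)
class MicroclusterEventSpec:
    """Gradual appearance then persistence: amplitude ramps linearly over
    `ramp_frames` and is then sustained to the end of the movie."""

    onset: int
    position: tuple[float, float]
    amplitude: float = 60.0
    sigma_px: float = 1.5
    ramp_frames: int = 10
    kind: str = "microcluster"


@dataclass(frozen=True)
class TirfSceneSpec:
    """A TIRF movie of a cell footprint with insertion/microcluster events.

    Default amplitudes sit about five read/shot-noise standard deviations
    above the footprint background (SNR around 5).
    """

    shape: tuple[int, int, int] = (60, 128, 128)   # (t, y, x)
    pixel_size_um: float = 0.23
    frame_interval_s: float = 0.333
    footprint_center: tuple[float, float] | None = None
    footprint_radius_px: float | None = None       # None = whole frame
    background: float = 100.0
    background_outside: float = 70.0               # coverslip/scatter floor
    footprint_edge_sigma_px: float = 3.0           # evanescent-field taper at the rim
    speckle_amplitude: float = 0.04                # static membrane texture (fraction of background)
    speckle_sigma_px: float = 1.0
    insertion_events: tuple[InsertionEventSpec, ...] = ()
    microcluster_events: tuple[MicroclusterEventSpec, ...] = ()
    blurred_frames: tuple[int, ...] = ()
    blur_sigma_px: float = 3.0
    poisson_gain: float = 1.0
    read_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.shape[0]
        for ev in (*self.insertion_events, *self.microcluster_events):
            if not 0 <= ev.onset < t:
                raise ValueError(f"event onset {ev.onset} outside movie of {t} frames")
            if ev.amplitude <= 0:
                raise ValueError("event amplitudes must be > 0")
            y, x = ev.position
            if not (0 <= y < self.shape[1] and 0 <= x < self.shape[2]):
                raise ValueError(f"event position {ev.position} outside the frame")
        if any(not 0 <= b < t for b in self.blurred_frames):
            raise ValueError("blurred frame index outside movie")

    def all_events(self) -> tuple:
        return (*self.insertion_events, *self.microcluster_events)

    @classmethod
    def random(
        cls,
        *,
        n_insertion: int = 8,
        n_microcluster: int = 0,
        min_separation_px: float = 44.0,
        shape: tuple[int, int, int] = (60, 128, 128),
        margin_px: float = 12.0,
        onset_range: tuple[int, int] | None = None,
        blurred_frames: tuple[int, ...] = (),
        footprint_radius_px: float | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "TirfSceneSpec":
        """Scene with randomly placed events at pairwise separation
        >= `min_separation_px` and onsets spaced inside `onset_range`.

        With a cell footprint, events are placed inside the footprint at
        `margin_px` from its rim."""
        rng = _rng(seed)
        t, h, w = shape
        if onset_range is None:
            onset_range = (5, max(6, t - 25))
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r_place = None
        if footprint_radius_px is not None:
            r_place = footprint_radius_px - margin_px
            if r_place <= 0:
                raise ValueError("footprint too small for the placement margin")
        positions: list[tuple[float, float]] = []
        attempts = 0
        n_total = n_insertion + n_microcluster
        while len(positions) < n_total:
            if r_place is not None:
                rad = r_place * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                cand = (float(cy + rad * np.sin(ang)), float(cx + rad * np.cos(ang)))
            else:
                cand = (
                    float(rng.uniform(margin_px, h - margin_px)),
                    float(rng.uniform(margin_px, w - margin_px)),
                )
            if all(
                (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_separation_px**2
                for p in positions
            ):
                positions.append(cand)
            attempts += 1
            if attempts % 2000 == 0:
                positions.clear()  # dead-end packing; restart
            if attempts > 100000:
                raise ValueError("cannot place events at the requested separation")
        onsets = rng.integers(onset_range[0], onset_range[1] + 1, size=n_total)
        ins = tuple(
            InsertionEventSpec(onset=int(o), position=p)
            for o, p in zip(onsets[:n_insertion], positions[:n_insertion])
        )
        micro = tuple(
            MicroclusterEventSpec(onset=int(o), position=p)
            for o, p in zip(onsets[n_insertion:], positions[n_insertion:])
        )
        return cls(
            shape=shape,
            insertion_events=ins,
            microcluster_events=micro,
            blurred_frames=blurred_frames,
            footprint_radius_px=footprint_radius_px,
            seed=int(rng.integers(0, 2**31 - 1)),
            **kwargs,
        )


def _gaussian_blob(h: int, w: int, pos: tuple[float, float], sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / (2 * sigma**2))


def generate_tirf_movie(spec: TirfSceneSpec) -> tuple[Movie, SyntheticGroundTruth]:
    """Render a TIRF movie with known insertion/microcluster events.

    Noise-free event kinetics satisfy the detector's qualitative signature:
    after onset, insertion peaks decay strictly while their spatial extent
    strictly grows; microclusters ramp up and persist.
    """
    t, h, w = spec.shape
    # warn about event pairs a tracker cannot be expected to separate
    evs = spec.all_events()
    for i in range(len(evs)):
        for j in range(i + 1, len(evs)):
            d = np.hypot(
                evs[i].position[0] - evs[j].position[0],
                evs[i].position[1] - evs[j].position[1],
            )
            if d < 22.0:
                warnings.warn(
                    f"events {i} and {j} are {d:.1f} px apart, inside the "
                    "linkage threshold; tracking may merge them",
                    stacklevel=2,
                )

    if spec.footprint_radius_px is not None:
        cy, cx = spec.footprint_center or ((h - 1) / 2.0, (w - 1) / 2.0)
        yy, xx = np.mgrid[0:h, 0:w]
        footprint = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.footprint_radius_px**2
    else:
        footprint = np.ones((h, w), dtype=bool)

    rng = _rng(spec.seed)
    clean = np.zeros((t, h, w), dtype=float)
    base = np.where(footprint, spec.background, spec.background_outside).astype(float)
    if spec.footprint_radius_px is not None and spec.footprint_edge_sigma_px > 0:
        # membrane curvature leaves the evanescent field gradually, so the
        # footprint intensity tapers at the rim rather than stepping
        base = ndi.gaussian_filter(base, spec.footprint_edge_sigma_px)
    if spec.speckle_amplitude > 0:
        # static membrane-GFP texture: gives sharp frames genuine
        # fine-scale structure that defocus visibly removes
        speckle = ndi.gaussian_filter(rng.standard_normal((h, w)), spec.speckle_sigma_px)
        speckle /= max(speckle.std(), 1e-12)
        base = np.clip(base * (1.0 + spec.speckle_amplitude * speckle * footprint), 0.0, None)
    clean += base[None]
    for ev in spec.insertion_events:
        for k in range(ev.onset, t):
            dk = k - ev.onset
            sigma = ev.sigma0_px + ev.sigma_growth_px_per_frame * dk
            peak = ev.amplitude * np.exp(-dk / ev.decay_frames)
            clean[k] += peak * _gaussian_blob(h, w, ev.position, sigma)
    for ev in spec.microcluster_events:
        blob = _gaussian_blob(h, w, ev.position, ev.sigma_px)
        for k in range(ev.onset, t):
            ramp = min(1.0, (k - ev.onset + 1) / ev.ramp_frames)
            clean[k] += ev.amplitude * ramp * blob

    rendered = clean.copy()
    for b in spec.blurred_frames:
        rendered[b] = ndi.gaussian_filter(rendered[b], spec.blur_sigma_px)

    noisy = _apply_noise(rendered, rng, spec.poisson_gain, spec.read_sigma)
    movie = Movie.from_array(noisy, spec.frame_interval_s, spec.pixel_size_um)
    truth = SyntheticGroundTruth(
        events=evs,
        masks={"footprint": footprint},
        extras={
            "clean": clean,
            "blurred_frames": tuple(spec.blurred_frames),
            "footprint_area_um2": float(footprint.sum()) * spec.pixel_size_um**2,
        },
    )
    return movie, truth


# -- correlated dual-channel pair ---------------------------------------------


def generate_correlated_pair(
    shape: tuple[int, int],
    rho: float,
    seed: int = 0,
    *,
    mask: np.ndarray | None = None,
    mean: float = 1000.0,
    sd: float = 100.0,
    pixel_size_um: float = 0.25,
) -> tuple[Frame2D, Frame2D, SyntheticGroundTruth]:
    """Two frames with jointly Gaussian pixel intensities of population
    correlation `rho` inside a shared cell mask.

    A common latent field is mixed with independent noise; the offset is
    ten standard deviations so the nonnegativity clip is never active and
    the sample correlation is unbiased.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed)
    z1 = rng.standard_normal(shape)
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(shape)
    ch1 = mean + sd * z1
    ch2 = mean + sd * z2
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        ch1 = np.where(mask, ch1, 0.0)
        ch2 = np.where(mask, ch2, 0.0)
    f1 = Frame2D(np.clip(ch1, 0, None), pixel_size_um)
    f2 = Frame2D(np.clip(ch2, 0, None), pixel_size_um)
    truth = SyntheticGroundTruth(rho=rho, masks={"cell": mask})
    return f1, f2, truth
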