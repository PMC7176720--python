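"""Synthetic fluorescence scenes and a forward model for SIM raw stacks.

Structured-illumination microscopy (SIM) acquires ``n_angles x n_phases``
camera frames, each the widefield image of the sample multiplied by a
sinusoidal excitation pattern ``1 + m*cos(2*pi*k_p.r + psi)``.  This module
generates ground-truth fluorophore-density scenes (filamentous, punctate and
blob-like, mimicking common subcellular structures), builds the optical model
(incoherent widefield OTF plus illumination-pattern geometry), and simulates
raw stacks under a Poisson + Gaussian read-noise camera model at normal and
reduced photon dose.

The frame order contract is angle-major: a1p1..a1pP, a2p1..a2pP, ...
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter


class ConfigurationError(ValueError):
    """Invalid user-supplied parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

STRUCTURE_KINDS = ("filament", "puncta", "blob")


@dataclass
class Scene:
    """Continuous-domain fluorophore density sampled on the camera grid.

    ``density_map`` is nonnegative, in arbitrary photon-density units; the
    absolute scale is set later by :class:`AcquisitionSettings.photon_budget`.
    """

    density_map: np.ndarray
    structure_kind: str
    pixel_size_nm: float
    seed: int

    def __post_init__(self) -> None:
        self.density_map = np.asarray(self.density_map, dtype=np.float64)
        if self.density_map.ndim != 2:
            raise ConfigurationError("density_map must be 2-D")
        if np.any(self.density_map < 0):
            raise ConfigurationError("density_map must be nonnegative")

    @property
    def is_empty(self) -> bool:
        return not np.any(self.density_map > 0)


@dataclass
class OpticalModel:
    """Widefield OTF plus sinusoidal illumination geometry.

    ``otf`` lives on the unshifted (fft-order) frequency grid of ``shape`` and
    is 1 at DC, 0 beyond ``cutoff`` (cycles/px).  ``pattern_frequency`` holds
    one (ky, kx) vector in cycles/px per illumination angle.
    """

    numerical_aperture: float
    emission_wavelength_nm: float
    pixel_size_nm: float
    shape: tuple[int, int]
    n_angles: int
    n_phases: int
    angles: np.ndarray            # radians, length n_angles
    phases: np.ndarray            # radians, length n_phases
    pattern_frequency: np.ndarray  # (n_angles, 2) cycles/px, (ky, kx)
    modulation_depth: float
    cutoff: float                 # cycles/px
    otf: np.ndarray = field(repr=False)

    def frame_parameters(self) -> list[tuple[float, float]]:
        """(angle, phase) per frame in angle-major order."""
        return [(float(th), float(ps)) for th in self.angles for ps in self.phases]

    def otf_radial(self, freq: np.ndarray) -> np.ndarray:
        """Incoherent OTF evaluated at arbitrary |frequency| (cycles/px)."""
        return incoherent_otf(np.asarray(freq, dtype=float), self.cutoff)


@dataclass
class AcquisitionSettings:
    """Camera/illumination dose model.

    photon_budget
        Expected photons at the brightest pixel of the *widefield* (pattern-
        averaged) image of the scene, per frame, at full dose.
    low_light_factor
        Divisor >= 1 applied to the dose; 100 emulates dropping from
        10 % laser / 200 ms exposure to 1 % laser / 20 ms.
    shot_noise
        When False the expected photon counts are returned (expectation mode:
        no Poisson sampling and no read-noise draw).
    """

    photon_budget: float = 200.0
    read_noise_sd: float = 1.0
    background_level: float = 0.0
    low_light_factor: float = 1.0
    seed: int = 0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.photon_budget <= 0:
            raise ConfigurationError("photon_budget must be > 0")
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise ConfigurationError("noise levels must be >= 0")
        if self.low_light_factor < 1:
            raise ConfigurationError("low_light_factor must be >= 1")


@dataclass
class RawSimStack:
    """Angle-major stack of patterned-illumination frames plus metadata."""

    frames: np.ndarray            # (n_angles*n_phases, H, W), nonnegative
    frame_params: list[tuple[float, float]]   # (theta, psi) per frame
    optics: OpticalModel
    acquisition: AcquisitionSettings

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        n_expected = self.optics.n_angles * self.optics.n_phases
        if self.frames.shape[0] != n_expected:
            raise ConfigurationError(
                f"expected {n_expected} frames, got {self.frames.shape[0]}"
            )
        if len(self.frame_params) != self.frames.shape[0]:
            raise ConfigurationError("frame_params length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def average_projection(self) -> np.ndarray:
        """Per-pixel mean over frames: the widefield-equivalent image."""
        return self.frames.mean(axis=0)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(
    structure_kind: str,
    width: int = 512,
    height: int = 512,
    density_params: dict | None = None,
    seed: int = 0,
    pixel_size_nm: float = 60.0,
) -> Scene:
    """Generate a synthetic ground-truth scene.

    ``filament`` draws smooth random-walk curves of ~2 px width (microtubule /
    F-actin-like); ``puncta`` draws isolated diffraction-scale spots
    (adhesion-like); ``blob`` draws textured ellipsoidal patches
    (mitochondria-like).  Deterministic given ``seed``.
    """
    if structure_kind not in STRUCTURE_KINDS:
        raise ConfigurationError(
            f"unknown structure_kind {structure_kind!r}; expected one of {STRUCTURE_KINDS}"
        )
    if width < 64 or height < 64:
        raise ConfigurationError("scene must be at least 64x64")
    params = dict(density_params or {})
    rng = np.random.default_rng(seed)
    if structure_kind == "filament":
        img = _draw_filaments(height, width, rng, **params)
    elif structure_kind == "puncta":
        img = _draw_puncta(height, width, rng, **params)
    else:
        img = _draw_blobs(height, width, rng, **params)
    img = np.clip(img, 0.0, None)
    return Scene(img, structure_kind, pixel_size_nm, seed)


def _draw_filaments(h, w, rng, n_curves=8, step=1.0, curvature=0.15,
                    length_frac=1.2, width_px=1.0, amplitude_jitter=0.3):
    canvas = np.zeros((h, w))
    n_steps = int(length_frac * max(h, w) / step)
    for _ in range(int(n_curves)):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        phi = rng.uniform(0, 2 * np.pi)
        amp = 1.0 + amplitude_jitter * rng.standard_normal()
        amp = max(amp, 0.2)
        for _ in range(n_steps):
            phi += curvature * rng.standard_normal()
            y += step * np.sin(phi)
            x += step * np.cos(phi)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w:
                canvas[iy, ix] += amp
    return gaussian_filter(canvas, width_px * 0.8)


def _draw_puncta(h, w, rng, n_spots=150, spot_sigma=1.0, amplitude_jitter=0.5,
                 margin=4):
    canvas = np.zeros((h, w))
    for _ in range(int(n_spots)):
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        amp = 1.0 + amplitude_jitter * abs(rng.standard_normal())
        canvas[int(round(y)), int(round(x))] += amp
    return gaussian_filter(canvas, spot_sigma)


def _draw_blobs(h, w, rng, n_blobs=20, min_radius=4.0, max_radius=14.0,
                texture_strength=0.4):
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    canvas = np.zeros((h, w))
    for _ in range(int(n_blobs)):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(min_radius, max_radius)
        rx = rng.uniform(min_radius, max_radius)
        th = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        r2 = (u / ry) ** 2 + (v / rx) ** 2
        canvas += np.exp(-0.5 * r2 * 4.0)
    if texture_strength > 0 and canvas.max() > 0:
        texture = gaussian_filter(rng.standard_normal((h, w)), 2.0)
        if texture.std() > 0:
            texture = texture / texture.std()
        canvas *= np.clip(1.0 + texture_strength * texture, 0.1, None)
    return canvas


def two_point_scene(width: int, height: int, separation_px: float,
                    axis_angle: float = 0.0, pixel_size_nm: float = 60.0) -> Scene:
    """Two unit point emitters a given distance apart — resolution phantom."""
    img = np.zeros((height, width))
    cy, cx = height / 2.0, width / 2.0
    dy = separation_px / 2.0 * np.sin(axis_angle)
    dx = separation_px / 2.0 * np.cos(axis_angle)
    for sgn in (-1.0, 1.0):
        img[int(round(cy + sgn * dy)), int(round(cx + sgn * dx))] += 1.0
    return Scene(img, "puncta", pixel_size_nm, seed=0)


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

def incoherent_otf(freq: np.ndarray, cutoff: float) -> np.ndarray:
    """Diffraction-limited incoherent OTF (autocorrelation of a circular pupil).

    ``otf(0) = 1``; exactly 0 at and beyond ``cutoff``.
    """
    rho = np.clip(np.abs(freq) / cutoff, 0.0, 1.0)
    otf = (2.0 / np.pi) * (np.arccos(rho) - rho * np.sqrt(1.0 - rho ** 2))
    return np.where(rho < 1.0, otf, 0.0)


def make_optical_model(
    numerical_aperture: float = 1.45,
    wavelength_nm: float = 525.0,
    pixel_size_nm: float = 60.0,
    shape: tuple[int, int] = (512, 512),
    n_angles: int = 3,
    n_phases: int = 5,
    pattern_frequency_fraction: float = 0.85,
    modulation_depth: float = 0.8,
    angle_offset: float = 0.0,
    snap_pattern_to_grid: bool = True,
) -> OpticalModel:
    """Build the OTF and the illumination geometry.

    The widefield cutoff is ``2 NA / lambda`` converted to cycles/px.  Angles
    are evenly spaced over pi (a sinusoid at theta and theta+pi is the same
    pattern); phases evenly spaced over 2*pi.  The pattern frequency is a
    fixed fraction of the cutoff so the pattern itself passes the objective.

    With ``snap_pattern_to_grid`` (default) each pattern vector is rounded to
    the nearest DFT bin of ``shape`` so the sinusoid is exactly periodic on
    the simulation grid and the frequency orders separate without spectral
    leakage; disable to emulate arbitrary instrument pattern frequencies.
    """
    if not 0 < pattern_frequency_fraction < 1:
        raise ConfigurationError("pattern_frequency_fraction must be in (0, 1)")
    if n_angles < 1 or n_phases < 3:
        raise ConfigurationError("need n_angles >= 1 and n_phases >= 3")
    if not 0 <= modulation_depth <= 1:
        raise ConfigurationError("modulation_depth must be in [0, 1]")
    cutoff = 2.0 * numerical_aperture / wavelength_nm * pixel_size_nm
    if cutoff >= 0.5:
        raise ConfigurationError(
            f"OTF cutoff {cutoff:.3f} cycles/px exceeds Nyquist; decrease pixel size"
        )
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    otf = incoherent_otf(np.hypot(fy, fx), cutoff)

    angles = angle_offset + np.arange(n_angles) * np.pi / n_angles
    phases = np.arange(n_phases) * 2.0 * np.pi / n_phases
    k_mag = pattern_frequency_fraction * cutoff
    pattern = np.stack([k_mag * np.sin(angles), k_mag * np.cos(angles)], axis=1)
    if snap_pattern_to_grid:
        pattern[:, 0] = np.round(pattern[:, 0] * h) / h
        pattern[:, 1] = np.round(pattern[:, 1] * w) / w
    if np.any(np.hypot(pattern[:, 0], pattern[:, 1]) >= cutoff):
        raise ConfigurationError("pattern frequency must stay below the OTF cutoff")
    return OpticalModel(
        numerical_aperture=numerical_aperture,
        emission_wavelength_nm=wavelength_nm,
        pixel_size_nm=pixel_size_nm,
        shape=(h, w),
        n_angles=n_angles,
        n_phases=n_phases,
        angles=angles,
        phases=phases,
        pattern_frequency=pattern,
        modulation_depth=modulation_depth,
        cutoff=cutoff,
        otf=otf,
    )


def blur_with_otf(image: np.ndarray, otf: np.ndarray) -> np.ndarray:
    """Apply the OTF in frequency space (circular boundary)."""
    return np.real(np.fft.ifft2(np.fft.fft2(image) * otf))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def simulate_raw_stack(
    scene: Scene,
    optics: OpticalModel,
    acquisition: AcquisitionSettings,
) -> RawSimStack:
    """Simulate one angle-major SIM raw stack.

    Each frame is ``Poisson( blur_otf(scene * pattern) * dose + background )
    + N(0, read_noise_sd)``, where the dose scale maps the brightest widefield
    pixel to ``photon_budget / low_light_factor`` expected photons.  With
    ``shot_noise=False`` the expectation (no sampling) is returned.
    Deterministic given ``acquisition.seed``.
    """
    if scene.density_map.shape != optics.shape:
        raise ConfigurationError(
            f"scene grid {scene.density_map.shape} != optics grid {optics.shape}"
        )
    h, w = optics.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    m = optics.modulation_depth
    dose = acquisition.photon_budget / acquisition.low_light_factor

    widefield = blur_with_otf(scene.density_map, optics.otf)
    peak = widefield.max()
    scale = dose / peak if peak > 0 else 0.0

    rng = np.random.default_rng(acquisition.seed)
    frames = np.empty((optics.n_angles * optics.n_phases, h, w))
    frame_params = []
    i = 0
    for a in range(optics.n_angles):
        ky, kx = optics.pattern_frequency[a]
        carrier = 2.0 * np.pi * (ky * yy + kx * xx)
        for psi in optics.phases:
            pattern = 1.0 + m * np.cos(carrier + psi)
            expected = blur_with_otf(scene.density_map * pattern, optics.otf)
            expected = np.clip(expected, 0.0, None) * scale + acquisition.background_level
            if acquisition.shot_noise:
                frame = rng.poisson(expected).astype(np.float64)
                if acquisition.read_noise_sd > 0:
                    frame = frame + rng.normal(0.0, acquisition.read_noise_sd, size=frame.shape)
                frame = np.clip(frame, 0.0, None)
            else:
                frame = expected
            frames[i] = frame
            frame_params.append((float(optics.angles[a]), float(psi)))
            i += 1
    return RawSimStack(frames, frame_params, optics, acquisition)


def make_low_light_pair(
    scene: Scene,
    optics: OpticalModel,
    acquisition: AcquisitionSettings,
    low_light_factor: float = 100.0,
) -> tuple[RawSimStack, RawSimStack]:
    """Simulate the same scene at full dose and at dose/``low_light_factor``.

    The expected total photon count of the pair differs by exactly the factor
    (background excluded); this emulates dropping the laser power and the
    exposure time together.
    """
    if low_light_factor < 1:
        raise ConfigurationError("low_light_factor must be >= 1")
    normal = simulate_raw_stack(
        scene, optics, dataclasses.replace(acquisition, low_light_factor=1.0)
    )
    low = simulate_raw_stack(
        scene, optics, dataclasses.replace(acquisition, low_light_factor=float(low_light_factor))
    )
    return normal, low


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + sidecar metadata
# ---------------------------------------------------------------------------

def write_stack(stack: RawSimStack, tiff_path: str | Path) -> Path:
    """Write frames as a multi-page float32 TIFF plus a JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    opt = stack.optics
    acq = stack.acquisition
    meta = {
        "frame_order": "angle-major",
        "frame_params": [[th, ps] for th, ps in stack.frame_params],
        "optics": {
            "numerical_aperture": opt.numerical_aperture,
            "emission_wavelength_nm": opt.emission_wavelength_nm,
            "pixel_size_nm": opt.pixel_size_nm,
            "shape": list(opt.shape),
            "n_angles": opt.n_angles,
            "n_phases": opt.n_phases,
            "angles": list(map(float, opt.angles)),
            "phases": list(map(float, opt.phases)),
            "pattern_frequency": opt.pattern_frequency.tolist(),
            "modulation_depth": opt.modulation_depth,
            "cutoff": opt.cutoff,
        },
        "acquisition": {
            "photon_budget": acq.photon_budget,
            "read_noise_sd": acq.read_noise_sd,
            "background_level": acq.background_level,
            "low_light_factor": acq.low_light_factor,
            "seed": acq.seed,
            "shot_noise": acq.shot_noise,
        },
    }
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_stack(tiff_path: str | Path) -> RawSimStack:
    """Read a stack written by :func:`write_stack`."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(np.float64)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    om = meta["optics"]
    h, w = om["shape"]
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    optics = OpticalModel(
        numerical_aperture=om["numerical_aperture"],
        emission_wavelength_nm=om["emission_wavelength_nm"],
        pixel_size_nm=om["pixel_size_nm"],
        shape=(h, w),
        n_angles=om["n_angles"],
        n_phases=om["n_phases"],
        angles=np.asarray(om["angles"]),
        phases=np.asarray(om["phases"]),
        pattern_frequency=np.asarray(om["pattern_frequency"]),
        modulation_depth=om["modulation_depth"],
        cutoff=om["cutoff"],
        otf=incoherent_otf(np.hypot(fy, fx), om["cutoff"]),
    )
    acq = AcquisitionSettings(**meta["acquisition"])
    frame_params = [tuple(p) for p in meta["frame_params"]]
    return RawSimStack(frames, frame_params, optics, acq)
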