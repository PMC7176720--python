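"""Classical frequency-domain SIM reconstruction (Gustafsson-type).

The phase-stepped frames of each illumination angle are linearly unmixed into
frequency orders (0, +-1, ... ), each order is shifted back to its true
position in frequency space, and all orders are merged with a generalized
Wiener filter followed by apodization on a 2x output grid:

    SR(f) = A(f) * sum_q conj(otf_q(f)) c_q(f) / (sum_q |otf_q(f)|^2 + w^2)

where ``otf_q(f) = m_q * OTF(f + q k_p)`` with ``m_q = (m/2)^|q|``.  This is
the procedure the deep networks are trained to imitate, and the baseline they
are compared against.

Pattern parameters (k_p, starting phase, modulation depth) can either be taken
from simulator metadata ("known") or estimated from the data by sub-pixel
cross-correlation of the separated orders ("estimated").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .synth import ConfigurationError, OpticalModel, RawSimStack, incoherent_otf


class EstimationError(RuntimeError):
    """Pattern-parameter estimation failed; supply known parameters instead."""


@dataclass
class AnglePatternParams:
    """Illumination parameters of one angle: k_p in cycles/px (ky, kx),
    starting phase (rad) and modulation depth."""
    k_p: tuple[float, float]
    phase_offset: float
    modulation_depth: float


@dataclass
class SeparatedComponents:
    """Per-angle frequency-order components, fft-order arrays.

    ``components[a][q]`` estimates ``(m/2)^|q| e^{i q psi0} OTF(f) S(f - q k_p)``.
    """
    components: list[dict[int, np.ndarray]] = field(repr=False)
    orders: list[int]
    params: list[AnglePatternParams]
    shape: tuple[int, int]


@dataclass
class SRImage:
    """Super-resolution reconstruction on the 2x grid."""
    image: np.ndarray
    effective_cutoff: float     # cycles per *raw* px
    wiener_w: float


# ---------------------------------------------------------------------------
# order separation
# ---------------------------------------------------------------------------

def _phase_matrix(phases: np.ndarray, orders: list[int]) -> np.ndarray:
    return np.exp(1j * np.outer(phases, orders))


def separate_components(
    stack: RawSimStack,
    params: list[AnglePatternParams] | None = None,
) -> SeparatedComponents:
    """Unmix the phase-stepped frames of each angle into frequency orders.

    Solves, per angle and per pixel, ``frame_k(f) = sum_q e^{i q psi_k} c_q(f)``
    with orders ``q = -(P-1)/2 .. +(P-1)/2`` for P phases.  For evenly spaced
    phases the phase matrix is a (scaled) DFT matrix, hence perfectly
    conditioned.  If ``params`` is None, parameters are taken from the
    simulator metadata attached to the stack.
    """
    opt = stack.optics
    n_p = opt.n_phases
    if n_p < 3:
        raise ConfigurationError("need at least 3 phases to separate orders")
    max_order = (n_p - 1) // 2
    orders = list(range(-max_order, max_order + 1))
    if params is None:
        params = known_params(opt)

    comps: list[dict[int, np.ndarray]] = []
    for a in range(opt.n_angles):
        phases = np.array(
            [stack.frame_params[a * n_p + k][1] for k in range(n_p)], dtype=float
        )
        # duplicate phases (mod 2*pi) make the system singular
        wrapped = np.sort(np.mod(phases, 2 * np.pi))
        if np.any(np.diff(wrapped) < 1e-9) and n_p > 1:
            raise np.linalg.LinAlgError(
                "duplicate illumination phases: the mixing matrix is singular"
            )
        E = _phase_matrix(phases, orders)
        E_inv = np.linalg.pinv(E)
        spectra = np.stack(
            [np.fft.fft2(stack.frames[a * n_p + k]) for k in range(n_p)]
        )
        sep = np.tensordot(E_inv, spectra, axes=(1, 0))
        comps.append({q: sep[i] for i, q in enumerate(orders)})
    return SeparatedComponents(comps, orders, params, stack.shape)


def known_params(optics: OpticalModel) -> list[AnglePatternParams]:
    """Pattern parameters straight from the simulator metadata."""
    return [
        AnglePatternParams(
            k_p=(float(optics.pattern_frequency[a, 0]), float(optics.pattern_frequency[a, 1])),
            phase_offset=float(optics.phases[0]),
            modulation_depth=float(optics.modulation_depth),
        )
        for a in range(optics.n_angles)
    ]


# ---------------------------------------------------------------------------
# pattern-parameter estimation
# ---------------------------------------------------------------------------

def _zoomed_dft(g: np.ndarray, fy: np.ndarray, fx: np.ndarray) -> np.ndarray:
    """Evaluate the DFT of ``g`` on an arbitrary (fy, fx) frequency grid
    (cycles/px).  Direct matrix product; used to refine correlation peaks."""
    h, w = g.shape
    y = np.arange(h)
    x = np.arange(w)
    Ey = np.exp(-2j * np.pi * np.outer(fy, y))
    Ex = np.exp(-2j * np.pi * np.outer(x, fx))
    return Ey @ g @ Ex


def estimate_pattern_parameters(
    stack: RawSimStack,
    min_freq_fraction: float = 0.2,
    significance: float = 8.0,
) -> list[AnglePatternParams]:
    """Estimate (k_p, psi0, m) per angle from the data.

    The order-0 and order-(+1) components (separated assuming evenly spaced
    phases starting at 0) are cross-correlated; the pattern frequency is the
    sub-pixel location of the correlation peak, the starting phase is the
    complex argument there, and the modulation depth follows from the
    magnitude ratio to the order-0 autocorrelation.  Raises
    :class:`EstimationError` when no significant peak exists (e.g. pure
    noise), in which case known parameters must be supplied.
    """
    opt = stack.optics
    nominal = [
        AnglePatternParams((0.0, 0.0), 0.0, opt.modulation_depth)
        for _ in range(opt.n_angles)
    ]
    # separate with the nominal evenly spaced phases; a global phase offset
    # psi0 then shows up as a factor e^{i q psi0} on order q
    sep = separate_components(stack, params=nominal)
    h, w = stack.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx)
    mask = fr > min_freq_fraction * opt.cutoff

    out = []
    for a in range(opt.n_angles):
        c0 = sep.components[a][0]
        c1 = sep.components[a][1]
        u0 = np.fft.ifft2(c0)
        u1 = np.fft.ifft2(c1)
        g = np.conj(u0) * u1
        corr = np.fft.fft2(g)
        mag = np.abs(corr)
        mag_masked = np.where(mask, mag, 0.0)
        peak_idx = np.unravel_index(np.argmax(mag_masked), mag.shape)
        floor = np.median(mag[mask])
        if floor <= 0 or mag_masked[peak_idx] / floor < significance:
            raise EstimationError(
                f"no significant pattern peak for angle {a}; "
                "pass known parameters instead"
            )
        ky0 = float(fy[peak_idx[0], 0])
        kx0 = float(fx[0, peak_idx[1]])
        # two-stage sub-pixel refinement around the integer-bin peak
        step = 1.0 / h
        ky, kx = ky0, kx0
        for zoom in (10.0, 100.0):
            d = step / zoom
            gy = ky + d * np.arange(-10, 11)
            gx = kx + d * np.arange(-10, 11)
            z = np.abs(_zoomed_dft(g, gy, gx))
            iy, ix = np.unravel_index(np.argmax(z), z.shape)
            ky, kx = float(gy[iy]), float(gx[ix])
        # refine k_p by maximizing the coherence between the back-shifted
        # order-1 component and the order-0 spectrum over their OTF overlap;
        # the final complex regression coefficient yields psi0 and m:
        #   c1(f + kp) = (m/2) e^{i psi0} OTF(f + kp) S(f)
        yy, xx = np.mgrid[0:h, 0:w]
        otf_f = incoherent_otf(fr, opt.cutoff)
        otf_fk = incoherent_otf(np.hypot(fy + ky, fx + kx), opt.cutoff)
        overlap = (otf_f > 0.2) & (otf_fk > 0.2)
        s0 = c0[overlap] / otf_f[overlap]
        basis = s0 * otf_fk[overlap]
        bnorm = np.vdot(basis, basis).real

        def regression(k):
            c1_shift = np.fft.fft2(
                u1 * np.exp(-2j * np.pi * (k[0] * yy + k[1] * xx))
            )[overlap]
            b = np.vdot(basis, c1_shift) / max(bnorm, 1e-30)
            resid = np.vdot(c1_shift, c1_shift).real - np.abs(b) ** 2 * bnorm
            return b, resid

        # spectral leakage from sparse scenes can pull the correlation peak
        # into a sidelobe one bin away; scan the residual on a +-1-bin grid
        # first, then polish with Nelder-Mead
        step = 1.0 / h
        cands = [(ky + dy, kx + dx)
                 for dy in np.linspace(-step, step, 7)
                 for dx in np.linspace(-step, step, 7)]
        ky, kx = min(cands, key=lambda k: regression(k)[1])
        res = minimize(
            lambda k: regression(k)[1], x0=[ky, kx], method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 200},
        )
        ky, kx = float(res.x[0]), float(res.x[1])
        b, _ = regression(res.x)
        psi0 = float(np.angle(b))
        m_est = float(np.clip(2.0 * np.abs(b), 0.0, 1.0))
        out.append(AnglePatternParams((ky, kx), psi0, m_est))
    return out


# ---------------------------------------------------------------------------
# Wiener combination
# ---------------------------------------------------------------------------

def _pad_spectrum_2x(spec: np.ndarray) -> np.ndarray:
    """Embed an N x N fft-order spectrum in the centre of a 2N x 2N grid."""
    h, w = spec.shape
    out = np.zeros((2 * h, 2 * w), dtype=complex)
    s = np.fft.fftshift(spec)
    out[h // 2: h // 2 + h, w // 2: w // 2 + w] = s
    return np.fft.ifftshift(out)


def _shift_spectrum(spec_pad: np.ndarray, ky: float, kx: float) -> np.ndarray:
    """Return the spectrum evaluated at (f + k), i.e. shifted by -k.

    ``ky, kx`` in cycles per *raw* pixel; the array lives on the 2x grid.
    """
    if ky == 0.0 and kx == 0.0:
        return spec_pad
    h2, w2 = spec_pad.shape
    yy = np.arange(h2)[:, None]
    xx = np.arange(w2)[None, :]
    # raw-pixel frequency k corresponds to k/2 cycles per fine pixel
    ramp = np.exp(-2j * np.pi * ((ky / 2.0) * yy + (kx / 2.0) * xx))
    u = np.fft.ifft2(spec_pad)
    return np.fft.fft2(u * ramp)


def triangle_apodization(shape: tuple[int, int], cutoff_raw: float) -> np.ndarray:
    """Cone filter 1 - |f|/cutoff on the 2x grid (f in cycles per raw px)."""
    h2, w2 = shape
    fy = np.fft.fftfreq(h2)[:, None] * 2.0
    fx = np.fft.fftfreq(w2)[None, :] * 2.0
    fr = np.hypot(fy, fx)
    return np.clip(1.0 - fr / cutoff_raw, 0.0, None)


def wiener_combine(
    sep: SeparatedComponents,
    optics: OpticalModel,
    wiener_w: float = 0.05,
    apodization: str = "triangle",
    orders_to_use: tuple[int, ...] = (-1, 0, 1),
    clip_negative: bool = True,
) -> SRImage:
    """Shift each separated order to its true frequency position and merge.

    Orders beyond those listed in ``orders_to_use`` are ignored (a pure
    sinusoidal pattern carries no +-2 content even when 5 phases were
    acquired).  Output is on the 2x pixel grid, apodized to the enlarged
    support and clipped to nonnegative values.
    """
    if wiener_w <= 0:
        raise ConfigurationError("wiener_w must be > 0")
    h, w = sep.shape
    h2, w2 = 2 * h, 2 * w
    fy = np.fft.fftfreq(h2)[:, None] * 2.0   # cycles per raw px
    fx = np.fft.fftfreq(w2)[None, :] * 2.0

    numer = np.zeros((h2, w2), dtype=complex)
    denom = np.zeros((h2, w2), dtype=float)
    k_mags = []
    for a, per_angle in enumerate(sep.components):
        p = sep.params[a]
        ky, kx = p.k_p
        k_mags.append(float(np.hypot(ky, kx)))
        m_half = p.modulation_depth / 2.0
        for q in sep.orders:
            if q not in orders_to_use:
                continue
            m_q = m_half ** abs(q) if q != 0 else 1.0
            otf_q = incoherent_otf(np.hypot(fy + q * ky, fx + q * kx), optics.cutoff)
            c_shift = _shift_spectrum(_pad_spectrum_2x(per_angle[q]), q * ky, q * kx)
            c_shift = c_shift * np.exp(-1j * q * p.phase_offset)
            numer += m_q * np.conj(otf_q) * c_shift
            denom += (m_q * otf_q) ** 2

    max_order = max(abs(q) for q in orders_to_use)
    k_ext = max_order * max(k_mags) if k_mags else 0.0
    effective_cutoff = optics.cutoff + k_ext
    spec = numer / (denom + wiener_w ** 2)
    if apodization == "triangle":
        spec = spec * triangle_apodization((h2, w2), effective_cutoff)
    elif apodization not in (None, "none"):
        raise ConfigurationError(f"unknown apodization {apodization!r}")
    # 2x zero-padding halves ifft amplitude per axis; undo to keep intensities
    img = np.real(np.fft.ifft2(spec)) * 4.0
    if clip_negative:
        img = np.clip(img, 0.0, None)
    return SRImage(img, effective_cutoff, wiener_w)


def wiener_widefield(
    image: np.ndarray,
    optics: OpticalModel,
    wiener_w: float = 0.05,
    apod_cutoff: float | None = None,
) -> np.ndarray:
    """Wiener-filter a single widefield image on the 2x grid.

    Matches the order-0-only path of :func:`wiener_combine`, whose Wiener
    denominator sums the OTF**2 term once per illumination angle.
    """
    spec = _pad_spectrum_2x(np.fft.fft2(np.asarray(image, dtype=float)))
    h2, w2 = spec.shape
    fy = np.fft.fftfreq(h2)[:, None] * 2.0
    fx = np.fft.fftfreq(w2)[None, :] * 2.0
    otf = incoherent_otf(np.hypot(fy, fx), optics.cutoff)
    n_a = optics.n_angles
    out = spec * n_a * otf / (n_a * otf ** 2 + wiener_w ** 2)
    out *= triangle_apodization((h2, w2), apod_cutoff or optics.cutoff)
    return np.clip(np.real(np.fft.ifft2(out)) * 4.0, 0.0, None)


def reconstruct(
    stack: RawSimStack,
    params_mode: str = "known",
    wiener_w: float = 0.05,
    orders_to_use: tuple[int, ...] = (-1, 0, 1),
    apodization: str = "triangle",
    clip_negative: bool = True,
) -> SRImage:
    """Full classical reconstruction of one raw stack.

    ``params_mode='known'`` reads the pattern parameters from the simulator
    metadata (the default for synthetic data); ``'estimated'`` recovers them
    from the data by cross-correlation.
    """
    if params_mode == "known":
        params = known_params(stack.optics)
        sep = separate_components(stack, params=params)
    elif params_mode == "estimated":
        params = estimate_pattern_parameters(stack)
        # re-separate with nominal evenly spaced phases; the estimated psi0
        # is applied during combination
        nominal = [
            AnglePatternParams(p.k_p, p.phase_offset, p.modulation_depth)
            for p in params
        ]
        sep = separate_components(stack, params=nominal)
    else:
        raise ConfigurationError("params_mode must be 'known' or 'estimated'")
    return wiener_combine(
        sep, stack.optics, wiener_w=wiener_w, apodization=apodization,
        orders_to_use=orders_to_use, clip_negative=clip_negative,
    )


def fourier_support_radius(image: np.ndarray, threshold: float = 1e-3) -> float:
    """Largest frequency (cycles/px of the given grid) whose annulus still
    holds spectral amplitude above ``threshold`` times the peak annulus
    amplitude.  Measure un-apodized reconstructions to see the raw support."""
    spec = np.abs(np.fft.fft2(image - image.mean()))
    h, w = spec.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx).ravel()
    power = spec.ravel()
    n_bins = max(h, w)
    bins = np.linspace(0.0, fr.max() + 1e-12, n_bins + 1)
    idx = np.digitize(fr, bins) - 1
    prof = np.zeros(n_bins)
    np.maximum.at(prof, idx, power)
    prof /= prof.max()
    above = np.nonzero(prof > threshold)[0]
    if len(above) == 0:
        return 0.0
    return float(bins[above[-1] + 1])
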