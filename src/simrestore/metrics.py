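"""Image-quality assessment: PSNR, NRMSE, SSIM, decorrelation resolution,
and resolution-scaled error mapping.

PSNR and NRMSE follow the usual definitions on an 8-bit scale
(``20 log10(255 / RMSE)`` after mapping normalized data to [0, 255]); NRMSE
divides the RMSE by the standard deviation of the reference.  SSIM is the
global (whole-image) structural similarity with stabilizing constants
``C1 = (k1 L)^2``, ``C2 = (k2 L)^2``, ``k1 = 0.01``, ``k2 = 0.03``.

Resolution is estimated parameter-free by decorrelation analysis: the
position of the highest-frequency local maximum of normalized spectral
cross-correlation curves computed under low-pass masks and a bank of
high-pass pre-filters.

The resolution-scaled error (RSE) and resolution-scaled Pearson coefficient
(RSP) compare a super-resolution image against a diffraction-limited
reference (the average projection of the raw frames) after fitting a
resolution-scaling function: a Gaussian blur of width sigma plus a linear
intensity map alpha, beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize_scalar
from skimage.metrics import structural_similarity as _skimage_ssim
from skimage.transform import resize as _sk_resize


@dataclass
class SsimConstants:
    k1: float = 0.01
    k2: float = 0.03
    L: float = 1.0

    @property
    def C1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.L) ** 2


@dataclass
class MetricsReport:
    """Quality metrics for one (output, reference) pair."""
    psnr: float
    nrmse: float
    ssim: float
    resolution: float       # same units as the supplied pixel size
    rse: float
    rsp: float
    reference_kind: str = "ground_truth"

    def to_dict(self) -> dict:
        return {
            "psnr": self.psnr, "nrmse": self.nrmse, "ssim": self.ssim,
            "resolution": self.resolution, "rse": self.rse, "rsp": self.rsp,
            "reference_kind": self.reference_kind,
        }


def _check_shapes(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    return u, v


def psnr(u: np.ndarray, v: np.ndarray, data_range: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``20 log10(L / RMSE)`` in dB.

    Inputs are expected on the [0, L] scale (normalized images are multiplied
    by 255 before calling, matching the 8-bit convention).  Identical images
    return ``inf``.
    """
    u, v = _check_shapes(u, v)
    mse = np.mean((u - v) ** 2)
    if mse == 0:
        return float("inf")
    return float(20.0 * np.log10(data_range / np.sqrt(mse)))


def nrmse(u: np.ndarray, v: np.ndarray) -> float:
    """RMSE normalized by the standard deviation of the reference ``u``."""
    u, v = _check_shapes(u, v)
    sd = np.std(u)
    if sd == 0:
        raise ZeroDivisionError("reference image is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((u - v) ** 2)) / sd)


def ssim(
    u: np.ndarray,
    v: np.ndarray,
    constants: SsimConstants | None = None,
    sigma_means_variance: bool = False,
    windowed: bool = False,
) -> float:
    """Structural similarity index.

    Global (whole-image) statistics by default.  ``sigma_means_variance``
    switches to the non-standard reading in which the sigma symbols in the
    denominator of the contrast/structure term are variances rather than
    standard deviations; the standard convention is the default.
    ``windowed=True`` computes the conventional mean of local SSIM values
    (7x7 window) instead.
    """
    u, v = _check_shapes(u, v)
    c = constants or SsimConstants()
    if windowed:
        return float(
            _skimage_ssim(u, v, data_range=c.L, K1=c.k1, K2=c.k2)
        )
    mu_u, mu_v = u.mean(), v.mean()
    var_u, var_v = u.var(), v.var()
    cov = ((u - mu_u) * (v - mu_v)).mean()
    if sigma_means_variance:
        s_u, s_v = var_u ** 2, var_v ** 2
    else:
        s_u, s_v = var_u, var_v
    lum = (2 * mu_u * mu_v + c.C1) / (mu_u ** 2 + mu_v ** 2 + c.C1)
    struct = (2 * cov + c.C2) / (s_u + s_v + c.C2)
    return float(lum * struct)


# ---------------------------------------------------------------------------
# decorrelation resolution
# ---------------------------------------------------------------------------

def _decorrelation_curve(spec: np.ndarray, spec_norm: np.ndarray,
                         fr: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """d(r) = |<I, I_n * mask_r>| / (||I|| * ||I_n * mask_r||)."""
    denom_i = np.sqrt(np.sum(np.abs(spec) ** 2))
    d = np.zeros(len(radii))
    cross = np.real(spec * np.conj(spec_norm))
    pow_n = np.abs(spec_norm) ** 2
    order = np.argsort(fr.ravel())
    fr_sorted = fr.ravel()[order]
    cross_c = np.cumsum(cross.ravel()[order])
    pow_c = np.cumsum(pow_n.ravel()[order])
    idx = np.searchsorted(fr_sorted, radii, side="right") - 1
    valid = idx >= 0
    num = np.where(valid, cross_c[np.clip(idx, 0, None)], 0.0)
    den = np.sqrt(np.where(valid, pow_c[np.clip(idx, 0, None)], 0.0)) * denom_i
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, np.abs(num) / den, 0.0)
    return d


def _find_peak(d: np.ndarray, radii: np.ndarray) -> tuple[float, float]:
    """Peak of one decorrelation curve: the global maximum, taking the
    highest radius on a plateau (a noise-dominated curve rises monotonically
    and peaks at Nyquist).  Returns (radius, amplitude); (0, 0) for curves
    with no usable maximum."""
    if len(d) == 0 or d.max() <= 1e-2:
        return 0.0, 0.0
    i = int(np.flatnonzero(d >= d.max() - 1e-12)[-1])
    return float(radii[i]), float(d[i])


def decorrelation_resolution(
    image: np.ndarray,
    pixel_size: float = 1.0,
    n_radii: int = 50,
    n_filters: int = 10,
) -> float:
    """Parameter-free resolution estimate from spectral decorrelation.

    The image spectrum is correlated with its phase-only (amplitude
    normalized) counterpart restricted to growing low-pass masks; the highest
    local-maximum frequency across the plain curve and ``n_filters``
    Gaussian high-pass pre-filtered curves is taken as the effective cutoff
    ``f_c`` (in units of Nyquist), giving resolution ``2 * pixel_size / f_c``.
    Returns NaN (with a warning) for images without a spectral peak, e.g.
    constant images.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("need a 2-D image of at least 32x32 pixels")
    if np.ptp(img) == 0:
        warnings.warn("constant image: resolution undefined", RuntimeWarning)
        return float("nan")
    img = img - img.mean()
    # apodize the edges to suppress FFT boundary artifacts
    win_y = np.hanning(img.shape[0])[:, None]
    win_x = np.hanning(img.shape[1])[None, :]
    img = img * np.sqrt(win_y * win_x)

    spec = np.fft.fftshift(np.fft.fft2(img))
    h, w = spec.shape
    fy = (np.arange(h) - h // 2) / (h / 2.0)
    fx = (np.arange(w) - w // 2) / (w / 2.0)
    fr = np.hypot(fy[:, None], fx[None, :])   # 1.0 = Nyquist
    inside = fr <= 1.0
    spec = np.where(inside, spec, 0.0)
    mag = np.abs(spec)
    spec_norm = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)

    radii = np.linspace(0.02, 1.0, n_radii)
    peaks: list[tuple[float, float]] = []
    d0 = _decorrelation_curve(spec, spec_norm, fr, radii)
    peaks.append(_find_peak(d0, radii))
    # geometric ladder of high-pass widths, wide to narrow
    sigmas = np.geomspace(max(h, w) / 4.0, 1.0, n_filters)
    for s in sigmas:
        # Gaussian high-pass on the (shifted) spectrum
        hp = 1.0 - np.exp(-(fr * max(h, w) / 2.0) ** 2 / (2.0 * s ** 2))
        sp = spec * hp
        m2 = np.abs(sp)
        sp_n = np.where(m2 > 0, sp / np.where(m2 > 0, m2, 1.0), 0.0)
        d = _decorrelation_curve(sp, sp_n, fr, radii)
        peaks.append(_find_peak(d, radii))
    cutoffs = [r for r, a in peaks if r > 0]
    if not cutoffs:
        warnings.warn("no decorrelation maximum found", RuntimeWarning)
        return float("nan")
    f_c = max(cutoffs)
    return float(2.0 * pixel_size / f_c)


# ---------------------------------------------------------------------------
# resolution-scaled error mapping
# ---------------------------------------------------------------------------

def _affine_fit(blurred: np.ndarray, reference: np.ndarray) -> tuple[float, float, float]:
    """Closed-form (alpha, beta) minimizing ||alpha*blurred + beta - ref||."""
    x = blurred.ravel()
    y = reference.ravel()
    vx = x.var()
    if vx == 0:
        return 0.0, float(y.mean()), float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    alpha = float(np.cov(x, y, bias=True)[0, 1] / vx)
    beta = float(y.mean() - alpha * x.mean())
    rmse = float(np.sqrt(np.mean((alpha * x + beta - y) ** 2)))
    return alpha, beta, rmse


def rse_rsp(
    sr_image: np.ndarray,
    reference_image: np.ndarray,
    sigma_bounds: tuple[float, float] = (0.0, 10.0),
) -> tuple[float, float, np.ndarray]:
    """Resolution-scaled error and Pearson coefficient plus the error map.

    Fits the resolution-scaling function — Gaussian blur of width sigma and a
    linear intensity map — that best matches the super-resolution image to
    the diffraction-limited reference, then reports the residual RMSE (RSE),
    the Pearson correlation at the optimum (RSP) and the absolute error map.
    """
    sr, ref = _check_shapes(sr_image, reference_image)
    if np.std(ref) == 0:
        raise ValueError("constant reference image")

    def cost(sigma: float) -> float:
        b = gaussian_filter(sr, sigma) if sigma > 0 else sr
        return _affine_fit(b, ref)[2]

    res = minimize_scalar(cost, bounds=sigma_bounds, method="bounded",
                          options={"xatol": 1e-4})
    sigma_opt = float(res.x)
    # the bounded minimizer never evaluates exactly at the boundary; accept
    # sigma = 0 when it is at least as good
    if cost(0.0) <= res.fun:
        sigma_opt = 0.0
    blurred = gaussian_filter(sr, sigma_opt) if sigma_opt > 0 else sr
    alpha, beta, rse = _affine_fit(blurred, ref)
    transformed = alpha * blurred + beta
    if np.std(blurred) == 0:
        rsp = 0.0
    else:
        rsp = float(np.corrcoef(blurred.ravel(), ref.ravel())[0, 1])
    error_map = np.abs(transformed - ref)
    return float(rse), rsp, error_map


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------

def evaluate_pair(
    output: np.ndarray,
    ground_truth: np.ndarray,
    raw_stack=None,
    pixel_size: float = 1.0,
    data_range: float | None = None,
) -> MetricsReport:
    """Full metrics report for one reconstruction against its ground truth.

    PSNR/SSIM use an 8-bit scale after joint rescaling by the ground-truth
    maximum.  RSE/RSP are computed against the average projection of
    ``raw_stack`` (upsampled to the output grid) when a stack is supplied,
    otherwise against the ground truth.
    """
    out, gt = _check_shapes(output, ground_truth)
    scale = data_range if data_range is not None else (gt.max() if gt.max() > 0 else 1.0)
    u8 = gt / scale * 255.0
    v8 = out / scale * 255.0
    p = psnr(u8, v8, data_range=255.0)
    n = nrmse(u8, v8)
    s = ssim(u8, v8, SsimConstants(L=255.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = decorrelation_resolution(out, pixel_size)
    if raw_stack is not None:
        ref = raw_stack.average_projection()
        ref = _sk_resize(ref, out.shape, order=3, anti_aliasing=False)
        kind = "average_projection"
    else:
        ref = gt
        kind = "ground_truth"
    e, rp, _ = rse_rsp(out, ref)
    return MetricsReport(p, n, s, r, e, rp, reference_kind=kind)


def evaluate_batch(pairs, pixel_size: float = 1.0) -> pd.DataFrame:
    """Evaluate an iterable of (id, output, ground_truth, raw_stack_or_None);
    one row per pair."""
    rows = []
    for pid, out, gt, stack in pairs:
        rep = evaluate_pair(out, gt, stack, pixel_size=pixel_size)
        rows.append({"id": pid, **rep.to_dict()})
    return pd.DataFrame(rows)
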