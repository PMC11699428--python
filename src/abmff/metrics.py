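"""Full-reference image quality indices: RMSE/PSNR, global SSIM, FSIM.

PSNR is the classical peak signal-to-noise ratio 20*log10(255/RMSE) in
decibels (infinite for identical images).  SSIM here is the single
global-statistics form (whole-image means, variances and cross-covariance,
stabilized by C1 = C2 = 0.065 on intensities rescaled to [0, 1]), not the
windowed variant.  FSIM weights two per-pixel similarities - one on phase
congruency maps from a log-Gabor filter bank, one on Scharr gradient
magnitudes - by the maximum phase congruency, so that errors at
perceptually significant features dominate the score.

Label images are not directly comparable to intensity images under these
indices; ``render_segmentation`` maps each cluster label back to its
centroid intensity to produce a reference-comparable rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "QualityReport",
    "rmse",
    "psnr",
    "ssim",
    "fsim",
    "phase_congruency",
    "render_segmentation",
    "evaluate_pair",
]

_SCHARR_X = np.array([[3.0, 0.0, -3.0],
                      [10.0, 0.0, -10.0],
                      [3.0, 0.0, -3.0]]) / 16.0


@dataclass(frozen=True)
class QualityReport:
    """PSNR/SSIM/FSIM/RMSE for one (reference, test) pair."""

    psnr: float
    ssim: float
    fsim: float
    rmse: float

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(ref, test):
    a = np.asarray(ref, dtype=np.float64)
    b = np.asarray(test, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("images must be 2-D grayscale")
    return a, b


def rmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Root-mean-square intensity difference between two same-shaped images."""
    a, b = _pair(ref, test)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio 20*log10(255/RMSE) in dB; +inf if RMSE = 0."""
    e = rmse(ref, test)
    if e == 0.0:
        return float("inf")
    return float(20.0 * np.log10(255.0 / e))


def ssim(ref: np.ndarray, test: np.ndarray, c1: float = 0.065,
         c2: float = 0.065, use_covariance: bool = True) -> float:
    """Global structural similarity on intensities rescaled to [0, 1].

    With ``use_covariance`` (default) the second factor's numerator is
    2*cov(x, y) + C2, which yields exactly 1 for identical images; the
    switchable alternative uses the product of the two standard
    deviations instead.
    """
    a, b = _pair(ref, test)
    x, y = a / 255.0, b / 255.0
    mx, my = float(x.mean()), float(y.mean())
    ddof = 1 if x.size > 1 else 0
    sx, sy = float(x.std(ddof=ddof)), float(y.std(ddof=ddof))
    denom = (mx ** 2 + my ** 2 + c1) * (sx ** 2 + sy ** 2 + c2)
    if use_covariance:
        cov = float(np.sum((x - mx) * (y - my)) / max(x.size - 1, 1))
        num2 = 2.0 * cov + c2
    else:
        num2 = 2.0 * sx * sy + c2
    return float((2.0 * mx * my + c1) * num2 / denom)


@lru_cache(maxsize=8)
def _loggabor_bank(shape, nscale, norient, min_wavelength, mult,
                   sigma_onf, d_theta_on_sigma):
    """Frequency-domain log-Gabor filters (radial x angular), cached per shape."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); the DC component is zeroed anyway
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    radials = []
    for s in range(nscale):
        f0 = 1.0 / (min_wavelength * mult ** s)
        lg = np.exp(-(np.log(radius / f0) ** 2)
                    / (2.0 * np.log(sigma_onf) ** 2))
        lg[0, 0] = 0.0
        radials.append(lg)

    sigma_theta = (np.pi / norient) / d_theta_on_sigma
    spreads = []
    for o in range(norient):
        angle = o * np.pi / norient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta ** 2) / (2.0 * sigma_theta ** 2)))
    return tuple(radials), tuple(spreads)


def phase_congruency(image: np.ndarray, nscale: int = 4, norient: int = 4,
                     min_wavelength: float = 6.0, mult: float = 2.0,
                     sigma_onf: float = 0.55, d_theta_on_sigma: float = 1.2,
                     eps_rel: float = 1e-4) -> np.ndarray:
    """Phase congruency map PC(w) = sum_o E_o(w) / (eps + sum_{s,o} A_{s,o}(w)).

    E_o is the magnitude of the summed complex log-Gabor responses across
    scales for orientation o, and A are the individual response
    amplitudes, so PC lies in [0, 1] and is contrast invariant.  ``eps_rel``
    sets the division stabilizer relative to the filter-amplitude scale.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    radials, spreads = _loggabor_bank(img.shape, nscale, norient,
                                      float(min_wavelength), float(mult),
                                      float(sigma_onf), float(d_theta_on_sigma))
    f = np.fft.fft2(img)
    total_energy = np.zeros(img.shape)
    total_amp = np.zeros(img.shape)
    for spread in spreads:
        sum_re = np.zeros(img.shape)
        sum_im = np.zeros(img.shape)
        for lg in radials:
            eo = np.fft.ifft2(f * (lg * spread))
            total_amp += np.abs(eo)
            sum_re += eo.real
            sum_im += eo.imag
        total_energy += np.hypot(sum_re, sum_im)
    eps = eps_rel * float(total_amp.max()) + 1e-12
    return total_energy / (total_amp + eps)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(img, _SCHARR_X, mode="reflect")
    gy = ndimage.convolve(img, _SCHARR_X.T, mode="reflect")
    return np.hypot(gx, gy)


def fsim(ref: np.ndarray, test: np.ndarray, t1: float = 0.85,
         t2: float = 160.0, **pc_kwargs) -> float:
    """Feature similarity index in [0, 1].

    S_L(w) = S_PC(w) * S_G(w), where S_PC compares the two phase
    congruency maps (stabilizer ``t1``) and S_G the two Scharr gradient
    magnitudes (stabilizer ``t2``, on the 8-bit gradient scale); the
    per-pixel similarities are averaged with weights PCm = max(PC1, PC2).
    Images must be at least 16x16 for the filter bank support.
    """
    a, b = _pair(ref, test)
    if min(a.shape) < 16:
        raise ValueError("images must be at least 16x16 for FSIM")
    pc1 = phase_congruency(a, **pc_kwargs)
    pc2 = phase_congruency(b, **pc_kwargs)
    g1 = _gradient_magnitude(a)
    g2 = _gradient_magnitude(b)
    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    s_g = (2.0 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    sl = s_pc * s_g
    pcm = np.maximum(pc1, pc2)
    w = float(pcm.sum())
    if w == 0.0:  # featureless pair (e.g. two constant images)
        return float(sl.mean())
    return float((sl * pcm).sum() / w)


def render_segmentation(labels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Replace each cluster label 1..k by its centroid intensity (uint8)."""
    lab = np.asarray(labels)
    mu = np.asarray(centroids, dtype=np.float64)
    if lab.min() < 1 or lab.max() > mu.size:
        raise ValueError("labels must lie in 1..k")
    vals = np.clip(np.sign(mu) * np.floor(np.abs(mu) + 0.5), 0, 255)
    return vals.astype(np.uint8)[lab - 1]


def evaluate_pair(ref: np.ndarray, test: np.ndarray) -> QualityReport:
    """All four indices for one (reference, test) image pair."""
    return QualityReport(psnr=psnr(ref, test), ssim=ssim(ref, test),
                         fsim=fsim(ref, test), rmse=rmse(ref, test))
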