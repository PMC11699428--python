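"""Synthetic ground-truthed grayscale test images.

The generators here emulate the experimental inputs the segmentation method
is evaluated on: piecewise-constant region layouts whose pixel intensities
are drawn from per-region Gaussians, optionally contaminated with impulse
(salt-and-pepper) noise and/or additive Gaussian noise.  Every draw is
controlled by an explicit seed so that the same spec always produces a
bit-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SyntheticSpec",
    "vertical_split",
    "vertical_bands",
    "concentric_square",
    "two_region_spec",
    "three_band_spec",
    "generate_region_image",
    "add_salt_pepper",
    "add_gaussian_noise",
    "apply_noise",
    "generate",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (fixed convention)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _to_u8(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Region layouts (1-based region ids)
# ---------------------------------------------------------------------------

def vertical_split(height: int, width: int) -> np.ndarray:
    """Two half-plane regions: left = 1, right = 2."""
    _check_dims(height, width)
    rm = np.ones((height, width), dtype=np.int32)
    rm[:, width // 2:] = 2
    return rm


def vertical_bands(height: int, width: int, bands: int = 3) -> np.ndarray:
    """``bands`` equal-width vertical stripes labelled 1..bands."""
    _check_dims(height, width)
    if bands < 1 or bands > width:
        raise ValueError("bands must be in [1, width]")
    edges = np.linspace(0, width, bands + 1).astype(int)
    rm = np.empty((height, width), dtype=np.int32)
    for b in range(bands):
        rm[:, edges[b]:edges[b + 1]] = b + 1
    return rm


def concentric_square(height: int, width: int) -> np.ndarray:
    """Background region 1 with a centred square of half the side = region 2."""
    _check_dims(height, width)
    rm = np.ones((height, width), dtype=np.int32)
    h0, h1 = height // 4, height - height // 4
    w0, w1 = width // 4, width - width // 4
    rm[h0:h1, w0:w1] = 2
    return rm


def _check_dims(height: int, width: int) -> None:
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic test image.

    ``region_map`` assigns each pixel a 1-based region id; ``region_means``
    and ``region_stds`` give the Gaussian intensity law of each region.
    Impulse noise is specified either as an absolute pixel count
    (``sp_count``) or a density (``sp_density``, giving count = M*N*d);
    the two are mutually exclusive.  ``gaussian_sigma = 0`` disables the
    additive noise arm.
    """

    region_map: np.ndarray
    region_means: tuple
    region_stds: tuple
    sp_count: int | None = None
    sp_density: float | None = None
    gaussian_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rm = np.asarray(self.region_map)
        if rm.ndim != 2 or rm.size == 0:
            raise ValueError("region_map must be a non-empty 2-D array")
        object.__setattr__(self, "region_map", rm.astype(np.int32))
        means = tuple(float(m) for m in self.region_means)
        stds = tuple(float(s) for s in self.region_stds)
        object.__setattr__(self, "region_means", means)
        object.__setattr__(self, "region_stds", stds)
        if len(means) != len(stds):
            raise ValueError("region_means and region_stds differ in length")
        nreg = len(means)
        ids = np.unique(rm)
        if ids.min() < 1 or ids.max() > nreg or len(ids) != nreg:
            raise ValueError(
                f"region_map must cover ids 1..{nreg}, found {ids.tolist()}")
        if any(s < 0 for s in stds):
            raise ValueError("region stds must be >= 0")
        if self.sp_count is not None and self.sp_density is not None:
            raise ValueError("sp_count and sp_density are mutually exclusive")
        if self.sp_density is not None and not 0.0 <= self.sp_density <= 1.0:
            raise ValueError("sp_density must lie in [0, 1]")
        if self.sp_count is not None and self.sp_count < 0:
            raise ValueError("sp_count must be >= 0")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")

    @property
    def height(self) -> int:
        return self.region_map.shape[0]

    @property
    def width(self) -> int:
        return self.region_map.shape[1]

    @property
    def n_regions(self) -> int:
        return len(self.region_means)

    def impulse_count(self) -> int:
        """Number of impulse pixels Np implied by the noise settings."""
        if self.sp_count is not None:
            return int(self.sp_count)
        if self.sp_density is not None:
            return int(round(self.height * self.width * self.sp_density))
        return 0

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        """JSON-serialisable sidecar description of this spec."""
        return {
            "height": self.height,
            "width": self.width,
            "region_means": list(self.region_means),
            "region_stds": list(self.region_stds),
            "sp_count": self.sp_count,
            "sp_density": self.sp_density,
            "gaussian_sigma": self.gaussian_sigma,
            "seed": self.seed,
        }


def two_region_spec(height: int = 100, width: int = 100,
                    means: Sequence[float] = (50.0, 200.0),
                    stds: Sequence[float] = (20.0, 20.0),
                    **noise) -> SyntheticSpec:
    """Half-plane layout with dark/bright Gaussian regions (defaults 50/200, std 20)."""
    return SyntheticSpec(vertical_split(height, width), tuple(means),
                         tuple(stds), **noise)


def three_band_spec(height: int = 100, width: int = 100,
                    means: Sequence[float] = (40.0, 128.0, 215.0),
                    stds: Sequence[float] = (30.0, 30.0, 30.0),
                    **noise) -> SyntheticSpec:
    """Three vertical bands with heavily overlapping intensity laws (std 30)."""
    return SyntheticSpec(vertical_bands(height, width, 3), tuple(means),
                         tuple(stds), **noise)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_region_image(spec: SyntheticSpec):
    """Draw the clean (noise-free) image for ``spec``.

    Pixel (i, j) in region r is an independent draw from
    Normal(mean_r, std_r), rounded half-away-from-zero and clamped to
    [0, 255].  Returns ``(image, labels)`` where ``labels`` equals the
    spec's region map.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.region_map.shape)
    means = np.asarray(spec.region_means)[spec.region_map - 1]
    stds = np.asarray(spec.region_stds)[spec.region_map - 1]
    img = _to_u8(_round_half_away(means + stds * z))
    return img, spec.region_map.copy()


def add_salt_pepper(image: np.ndarray, count: int | None = None,
                    density: float | None = None, seed=None) -> np.ndarray:
    """Overwrite Np distinct pixels with extreme values 0 / 255.

    Np is ``count`` or ``round(M*N*density)``.  The impulses are split as
    evenly as possible: ceil(Np/2) pepper (0) and floor(Np/2) salt (255).
    Positions are a prefix of one random permutation of the pixel grid, so
    a larger Np at the same seed strictly extends the altered set.
    """
    img = np.asarray(image)
    if (count is None) == (density is None):
        raise ValueError("specify exactly one of count / density")
    if density is not None:
        if not 0.0 <= density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        count = int(round(img.size * density))
    count = int(count)
    if count < 0 or count > img.size:
        raise ValueError(f"impulse count {count} exceeds pixel count {img.size}")
    out = img.copy()
    if count == 0:
        return out
    pos = np.random.default_rng(seed).permutation(img.size)[:count]
    n_pepper = (count + 1) // 2
    flat = out.reshape(-1)
    flat[pos[:n_pepper]] = 0
    flat[pos[n_pepper:]] = 255
    return out


def add_gaussian_noise(image: np.ndarray, sigma: float = 1.0, seed=None) -> np.ndarray:
    """Perturb every pixel with independent Normal(0, sigma) noise.

    The default sigma of 1 matches the additive-noise evaluation protocol.
    Output is rounded and clamped back to 8-bit range.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(image)
    if sigma == 0:
        return img.copy()
    noise = np.random.default_rng(seed).normal(0.0, sigma, img.shape)
    return _to_u8(_round_half_away(img.astype(np.float64) + noise))


def apply_noise(image: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Apply the spec's noise arms to ``image`` (Gaussian first, impulses last)."""
    out = np.asarray(image).copy()
    if spec.gaussian_sigma > 0:
        out = add_gaussian_noise(out, spec.gaussian_sigma,
                                 seed=np.random.SeedSequence([spec.seed, 1]))
    np_count = spec.impulse_count()
    if np_count > 0:
        out = add_salt_pepper(out, count=np_count,
                              seed=np.random.SeedSequence([spec.seed, 2]))
    return out


def generate(spec: SyntheticSpec):
    """Generate ``(clean, noisy, labels)`` for one spec.

    ``clean`` is the noise-free region image (the reference for quality
    metrics), ``noisy`` has the spec's noise arms applied, and ``labels``
    is the ground-truth region map.
    """
    clean, labels = generate_region_image(spec)
    return clean, apply_noise(clean, spec), labels
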