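"""Anisotropy-aware 3D texture filter bank (11 families, 51 feature maps).

All Gaussian-based filters share a base scale ``s`` chosen so that the
physical standard deviation is ~12 nm in every axis despite anisotropic
voxels: ``s = (12/11.24, 12/11.24, 12/28)`` voxels for 11.24 x 11.24 x 28 nm
data.  Kernels are evaluated on an integer grid, the plain Gaussian is
sum-normalized (DC gain 1), and derivative kernels are the analytic
derivatives of the normalized Gaussian (not re-normalized).

Filter half-size per dimension follows ``f_d = round((sigma_d / s_d) *
ceil(2 * s_d))``, i.e. roughly 3 sigma in-plane and 1 voxel in z at the base
scale; kernels have extent ``2 f + 1``.

Map order (51 maps) is fixed and documented by :func:`map_descriptors`:
raw(1), structure-tensor eigenvalues (5 parameter pairs x 3), Hessian
eigenvalues (4 x 3), Gaussian smoothing (3), difference of Gaussians (5),
Laplacian of Gaussian (4), gradient magnitude (5), local standard deviation
(1), intensity/variance (2), local entropy (1), sphere average (2).
Eigenvalues are sorted by increasing absolute value (ties by signed value).
Volume borders are handled by replicate padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import VoxelVolume

#: reference base scale in voxels for 11.24 x 11.24 x 28 nm voxels
DEFAULT_BASE_SCALE = (12.0 / 11.24, 12.0 / 11.24, 12.0 / 28.0)


@dataclass
class FilterBankConfig:
    """Parameter lists of the 11 texture filter families.

    Scale parameters are given as multiples of the base scale ``s``.
    """

    s: tuple[float, float, float] = DEFAULT_BASE_SCALE
    # (sigma_w, sigma_D) multipliers
    structure_tensor: tuple = ((1, 1), (1, 2), (2, 1), (2, 2), (3, 3))
    hessian: tuple = (1, 2, 3, 4)
    smoothing: tuple = (1, 2, 3)
    dog: tuple = ((1, 1.5), (1, 2.0), (2, 1.5), (2, 2.0), (3, 1.5))
    log: tuple = (1, 2, 3, 4)
    gradient_magnitude: tuple = (1, 2, 3, 4, 5)
    local_std_size: int = 5
    intvar_sizes: tuple = (3, 5)
    entropy_size: int = 5
    sphere_radii: tuple = (3, 6)
    validate_counts: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.s):
            raise ValueError("base scale must be positive")
        if self.validate_counts:
            counts = (
                len(self.structure_tensor),
                len(self.hessian),
                len(self.smoothing),
                len(self.dog),
                len(self.log),
                len(self.gradient_magnitude),
                len(self.intvar_sizes),
                len(self.sphere_radii),
            )
            if counts != (5, 4, 3, 5, 4, 5, 2, 2):
                raise ValueError(
                    f"family instance counts {counts} differ from the reference bank"
                )

    def sigma(self, multiplier: float) -> tuple[float, float, float]:
        return tuple(multiplier * c for c in self.s)

    def half_size(self, multiplier: float) -> tuple[int, int, int]:
        """Kernel half-size ``f_d = round((sigma_d/s_d) * ceil(2 s_d))``."""
        return tuple(
            int(round(multiplier * np.ceil(2.0 * c))) for c in self.s
        )

    def max_reach_voxels(self) -> tuple[int, int, int]:
        """Largest kernel half-size over all families (tile-padding bound)."""
        mults = set(self.smoothing) | set(self.hessian) | set(self.log)
        mults |= set(self.gradient_magnitude)
        for sw, sd in self.structure_tensor:
            mults.add(sw + sd)  # derivative then window smoothing
        for m, k in self.dog:
            mults.add(m * k)
        f = np.array([0, 0, 0])
        for m in mults:
            f = np.maximum(f, self.half_size(m))
        f = np.maximum(f, [r for r in [max(self.sphere_radii)] * 3])
        f = np.maximum(f, [self.entropy_size // 2] * 3)
        return tuple(int(v) for v in f)


@dataclass
class TextureFeatureMaps:
    """The ordered 51 scalar maps, voxel-aligned with the raw volume."""

    maps: list[np.ndarray]
    descriptors: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.maps)


class _SeparableKernel:
    """A 3D kernel given as an outer product of per-axis 1D kernels."""

    def __init__(self, kx, ky, kz):
        self.parts = (np.asarray(kx, float), np.asarray(ky, float), np.asarray(kz, float))

    def dense(self) -> np.ndarray:
        kx, ky, kz = self.parts
        return kx[:, None, None] * ky[None, :, None] * kz[None, None, :]

    def convolve(self, vol: np.ndarray) -> np.ndarray:
        out = np.asarray(vol, dtype=np.float64)
        for axis, k in enumerate(self.parts):
            out = ndimage.convolve1d(out, k, axis=axis, mode="nearest")
        return out


def _gauss_1d(sigma: float, f: int) -> np.ndarray:
    x = np.arange(-f, f + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_kernel(sigma, half_size) -> np.ndarray:
    """Dense sum-normalized Gaussian kernel on the grid ``[-f, f]^3``."""
    if any(s <= 0 for s in sigma):
        raise ValueError(f"sigma must be positive, got {sigma}")
    if any(f < 0 for f in half_size):
        raise ValueError(f"half size must be non-negative, got {half_size}")
    return _SeparableKernel(
        _gauss_1d(sigma[0], half_size[0]),
        _gauss_1d(sigma[1], half_size[1]),
        _gauss_1d(sigma[2], half_size[2]),
    ).dense()


def _derivative_kernel(sigma, half_size, orders) -> _SeparableKernel:
    """Separable derivative-of-Gaussian kernel for multi-index ``orders``.

    The normalized Gaussian is multiplied per axis by ``-x/sigma^2`` (first
    order) or ``(x^2/sigma^2 - 1)/sigma^2`` (second order); derivative
    kernels are not re-normalized.
    """
    if sum(orders) > 2 or any(o < 0 for o in orders):
        raise ValueError(f"unsupported derivative orders {orders}")
    parts = []
    for sig, f, o in zip(sigma, half_size, orders):
        x = np.arange(-f, f + 1, dtype=float)
        g = _gauss_1d(sig, f)
        if o == 0:
            parts.append(g)
        elif o == 1:
            parts.append(g * (-x / sig**2))
        else:
            parts.append(g * (x**2 / sig**2 - 1.0) / sig**2)
    return _SeparableKernel(*parts)


def gaussian_smooth(vol, sigma, half_size) -> np.ndarray:
    return _SeparableKernel(
        _gauss_1d(sigma[0], half_size[0]),
        _gauss_1d(sigma[1], half_size[1]),
        _gauss_1d(sigma[2], half_size[2]),
    ).convolve(vol)


def gaussian_derivative_maps(vol, sigma, half_size, orders) -> np.ndarray:
    """Convolve with the analytic Gaussian-derivative kernel."""
    return _derivative_kernel(sigma, half_size, orders).convolve(vol)


def difference_of_gaussians(vol, config: FilterBankConfig, multiplier, k) -> np.ndarray:
    if k <= 0:
        raise ValueError("k must be positive")
    s1 = config.sigma(multiplier)
    s2 = tuple(k * v for v in s1)
    a = gaussian_smooth(vol, s1, config.half_size(multiplier))
    b = gaussian_smooth(vol, s2, config.half_size(multiplier * k))
    return a - b


def gradient_magnitude(vol, config: FilterBankConfig, multiplier) -> np.ndarray:
    sigma = config.sigma(multiplier)
    f = config.half_size(multiplier)
    acc = np.zeros(np.shape(vol), dtype=np.float64)
    for orders in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        d = gaussian_derivative_maps(vol, sigma, f, orders)
        acc += d * d
    return np.sqrt(acc)


def laplacian_of_gaussian(vol, config: FilterBankConfig, multiplier) -> np.ndarray:
    sigma = config.sigma(multiplier)
    f = config.half_size(multiplier)
    out = np.zeros(np.shape(vol), dtype=np.float64)
    for orders in ((2, 0, 0), (0, 2, 0), (0, 0, 2)):
        out += gaussian_derivative_maps(vol, sigma, f, orders)
    return out


def _sorted_eigenvalues(m_xx, m_yy, m_zz, m_xy, m_xz, m_yz):
    """Per-voxel eigenvalues of a symmetric 3x3 field, sorted by |lambda|.

    Ties in absolute value are broken by signed value ascending so the output
    is deterministic.
    """
    shape = m_xx.shape
    mat = np.empty(shape + (3, 3), dtype=np.float64)
    mat[..., 0, 0] = m_xx
    mat[..., 1, 1] = m_yy
    mat[..., 2, 2] = m_zz
    mat[..., 0, 1] = mat[..., 1, 0] = m_xy
    mat[..., 0, 2] = mat[..., 2, 0] = m_xz
    mat[..., 1, 2] = mat[..., 2, 1] = m_yz
    vals = np.linalg.eigvalsh(mat.reshape(-1, 3, 3))
    order = np.lexsort((vals, np.abs(vals)), axis=-1)
    vals = np.take_along_axis(vals, order, axis=-1)
    return [vals[:, i].reshape(shape) for i in range(3)]


def structure_tensor_eigenvalues(vol, config: FilterBankConfig, mult_w, mult_d):
    """Eigenvalue maps of ``S_ab = (I_a^{sigma_D} I_b^{sigma_D}) * g_{sigma_w}``."""
    sig_d = config.sigma(mult_d)
    f_d = config.half_size(mult_d)
    sig_w = config.sigma(mult_w)
    f_w = config.half_size(mult_w)
    grads = [
        gaussian_derivative_maps(vol, sig_d, f_d, o)
        for o in ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    ]
    prods = {}
    for (i, j) in ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)):
        prods[(i, j)] = gaussian_smooth(grads[i] * grads[j], sig_w, f_w)
    return _sorted_eigenvalues(
        prods[(0, 0)], prods[(1, 1)], prods[(2, 2)],
        prods[(0, 1)], prods[(0, 2)], prods[(1, 2)],
    )


def hessian_eigenvalues(vol, config: FilterBankConfig, multiplier):
    """Eigenvalue maps of the Gaussian Hessian ``H_ab = I_ab^sigma``."""
    sigma = config.sigma(multiplier)
    f = config.half_size(multiplier)
    second = {
        key: gaussian_derivative_maps(vol, sigma, f, orders)
        for key, orders in {
            (0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
            (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1),
        }.items()
    }
    return _sorted_eigenvalues(
        second[(0, 0)], second[(1, 1)], second[(2, 2)],
        second[(0, 1)], second[(0, 2)], second[(1, 2)],
    )


def local_entropy(vol, size: int = 5) -> np.ndarray:
    """Shannon entropy (bits) of the intensity histogram in a cubic window.

    Input must be integer-valued in [0, 255]; the histogram uses the relative
    frequency of each intensity level in the window (replicate padding at
    volume borders).
    """
    arr = np.asarray(vol)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("local entropy requires integer-valued input")
    arr = np.round(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    out = np.zeros(arr.shape, dtype=np.float64)
    for level in np.unique(arr):
        p = ndimage.uniform_filter((arr == level).astype(np.float64), size=size,
                                   mode="nearest")
        nz = p > 1e-12
        out[nz] -= p[nz] * np.log2(p[nz])
    return out


def local_stddev(vol, size: int = 5) -> np.ndarray:
    """Unbiased sample standard deviation over a cubic window."""
    arr = np.asarray(vol, dtype=np.float64)
    n = size**3
    s1 = ndimage.uniform_filter(arr, size=size, mode="nearest") * n
    s2 = ndimage.uniform_filter(arr * arr, size=size, mode="nearest") * n
    var = (s2 - s1 * s1 / n) / (n - 1)
    return np.sqrt(np.clip(var, 0.0, None))


def intensity_variance(vol, size: int = 3) -> np.ndarray:
    """The raw intensity/variance response ``sum(I^2) - (sum I)^2`` over a window.

    The expression is used exactly as stated (no 1/|U| normalization of the
    squared-sum term), evaluated in float64 to avoid overflow.
    """
    arr = np.asarray(vol, dtype=np.float64)
    n = size**3
    s1 = ndimage.uniform_filter(arr, size=size, mode="nearest") * n
    s2 = ndimage.uniform_filter(arr * arr, size=size, mode="nearest") * n
    return s2 - s1 * s1


def sphere_neighborhood(r: int) -> np.ndarray:
    """Binary ellipsoid mask ``x^2 + y^2 + (2z)^2 <= r^2`` (z-anisotropy-corrected)."""
    rz = r // 2
    x, y, z = np.meshgrid(
        np.arange(-r, r + 1), np.arange(-r, r + 1), np.arange(-rz, rz + 1),
        indexing="ij",
    )
    return (x**2 + y**2 + (2 * z) ** 2) <= r**2


def sphere_average(vol, r: int) -> np.ndarray:
    """Mean intensity over the anisotropy-corrected spherical neighborhood."""
    mask = sphere_neighborhood(r).astype(np.float64)
    mask /= mask.sum()
    return ndimage.convolve(np.asarray(vol, dtype=np.float64), mask, mode="nearest")


def map_descriptors(config: FilterBankConfig) -> list[dict]:
    """Canonical order of the 51 maps as (family, params, eigenvalue rank)."""
    desc = [{"family": "raw"}]
    for sw, sd in config.structure_tensor:
        for rank in range(3):
            desc.append({"family": "structure_tensor", "sigma_w": sw,
                         "sigma_d": sd, "ev_rank": rank})
    for m in config.hessian:
        for rank in range(3):
            desc.append({"family": "hessian", "sigma": m, "ev_rank": rank})
    for m in config.smoothing:
        desc.append({"family": "smoothing", "sigma": m})
    for m, k in config.dog:
        desc.append({"family": "dog", "sigma": m, "k": k})
    for m in config.log:
        desc.append({"family": "log", "sigma": m})
    for m in config.gradient_magnitude:
        desc.append({"family": "gradient_magnitude", "sigma": m})
    desc.append({"family": "local_std", "size": config.local_std_size})
    for u in config.intvar_sizes:
        desc.append({"family": "intvar", "size": u})
    desc.append({"family": "entropy", "size": config.entropy_size})
    for r in config.sphere_radii:
        desc.append({"family": "sphere_average", "r": r})
    return desc


def compute_filter_bank(volume, config: FilterBankConfig | None = None,
                        dtype=np.float32) -> TextureFeatureMaps:
    """Compute all 51 texture maps of a raw volume in the canonical order."""
    if config is None:
        config = FilterBankConfig()
    vol = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    raw = np.asarray(vol, dtype=np.float64)
    maps: list[np.ndarray] = [raw.astype(dtype)]

    for sw, sd in config.structure_tensor:
        maps.extend(m.astype(dtype)
                    for m in structure_tensor_eigenvalues(raw, config, sw, sd))
    for m in config.hessian:
        maps.extend(h.astype(dtype) for h in hessian_eigenvalues(raw, config, m))
    for m in config.smoothing:
        maps.append(gaussian_smooth(raw, config.sigma(m),
                                    config.half_size(m)).astype(dtype))
    for m, k in config.dog:
        maps.append(difference_of_gaussians(raw, config, m, k).astype(dtype))
    for m in config.log:
        maps.append(laplacian_of_gaussian(raw, config, m).astype(dtype))
    for m in config.gradient_magnitude:
        maps.append(gradient_magnitude(raw, config, m).astype(dtype))
    maps.append(local_stddev(raw, config.local_std_size).astype(dtype))
    for u in config.intvar_sizes:
        maps.append(intensity_variance(raw, u).astype(dtype))
    maps.append(local_entropy(raw, config.entropy_size).astype(dtype))
    for r in config.sphere_radii:
        maps.append(sphere_average(raw, r).astype(dtype))

    desc = map_descriptors(config)
    if len(maps) != len(desc):
        raise RuntimeError("filter bank produced an unexpected number of maps")
    return TextureFeatureMaps(maps=maps, descriptors=desc)
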