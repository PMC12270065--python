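"""Velocity and turbulence reconstruction for 4-point phase-contrast data.

The non-symmetric 4-point scheme acquires one motion-compensated reference
encoding S0 and three single-axis motion encodings S1..S3.  Velocity along
axis e is encoded in the phase difference

    v_e = (VENC / pi) * wrap(phase(S_e) - phase(S_0)),

where VENC is the velocity mapped to a phase shift of pi, and the intravoxel
velocity standard deviation (turbulence) is encoded in the magnitude ratio

    sigma_e^2 = (VENC / pi)^2 * ln(|S_0| / |S_e|),

from which the turbulent kinetic energy density is TKE = rho/2 * sum sigma^2.

This module also implements the standard post-processing steps: phase-wrap
(velocity aliasing) correction, static-tissue detection, and removal of the
residual background phase offset with a 4th-order polynomial fitted to static
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement

import numpy as np

#: Order of velocity components / motion encodings throughout the package.
DIRECTIONS = ("ap", "rl", "fh")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EncodingSet:
    """Four (or three plus predicted) complex 4D volumes with metadata.

    ``real`` and ``imag`` have shape ``(4, T, X, Y, Z)`` with encoding 0 the
    reference and 1..3 the motion encodings along AP, RL, FH.
    """

    real: np.ndarray
    imag: np.ndarray
    venc_m_s: float
    voxel_size_mm: tuple[float, float, float]
    dt_s: float
    preprocessed: bool = False
    # preprocessing statistics, recorded so the transform can be undone
    norm_scale: np.ndarray | None = None        # (4,) per-encoding magnitude max
    channel_means: np.ndarray | None = None     # (4, T) complex per-timeframe means

    def __post_init__(self) -> None:
        self.real = np.asarray(self.real, dtype=float)
        self.imag = np.asarray(self.imag, dtype=float)
        if self.real.shape != self.imag.shape:
            raise ValueError("real and imag grids disagree")
        if self.real.ndim != 5:
            raise ValueError("expected (n_enc, T, X, Y, Z) arrays")
        if self.venc_m_s <= 0:
            raise ValueError("venc_m_s must be positive")

    @property
    def n_encodings(self) -> int:
        return self.real.shape[0]

    @property
    def n_timeframes(self) -> int:
        return self.real.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.real.shape[2:])

    def complex(self, enc: int | slice = slice(None)) -> np.ndarray:
        return self.real[enc] + 1j * self.imag[enc]

    def magnitude(self, enc: int | slice = slice(None)) -> np.ndarray:
        return np.abs(self.complex(enc))

    def with_reference(self, ref_real: np.ndarray, ref_imag: np.ndarray) -> "EncodingSet":
        """Return a copy whose reference encoding (index 0) is replaced."""
        real = self.real.copy()
        imag = self.imag.copy()
        real[0] = ref_real
        imag[0] = ref_imag
        return replace(self, real=real, imag=imag)


@dataclass
class VelocityField:
    """Three-directional velocity in m/s on the image grid, per timeframe.

    ``v`` has shape ``(3, T, X, Y, Z)`` ordered (AP, RL, FH).
    """

    v: np.ndarray
    venc_m_s: float
    voxel_size_mm: tuple[float, float, float]
    dt_s: float
    corrected: dict = field(default_factory=lambda: {"wrap": False, "background": False})
    unreliable: np.ndarray | None = None    # voxels where |S| = 0


@dataclass
class TurbulenceMaps:
    """Per-direction intravoxel variance and scalar TKE density.

    ``sigma2`` has shape ``(3, T, X, Y, Z)`` in m^2/s^2, ``tke`` shape
    ``(T, X, Y, Z)`` in J/m^3.
    """

    sigma2: np.ndarray
    tke: np.ndarray
    rho_kg_m3: float = 1060.0
    capped: np.ndarray | None = None


@dataclass
class PolyField:
    """Per-timeframe, per-direction polynomial surface over the image grid."""

    order: int
    coefficients: np.ndarray          # (T, 3, n_terms)
    grid_shape: tuple[int, int, int]

    def evaluate(self) -> np.ndarray:
        """Evaluate the fitted surfaces; returns shape (3, T, X, Y, Z)."""
        basis = polynomial_basis(self.grid_shape, self.order)   # (n_vox, n_terms)
        T = self.coefficients.shape[0]
        out = np.empty((3, T) + self.grid_shape)
        for t in range(T):
            for d in range(3):
                out[d, t] = (basis @ self.coefficients[t, d]).reshape(self.grid_shape)
        return out


# ---------------------------------------------------------------------------
# polynomial basis (shared with the phantom's background-phase model)
# ---------------------------------------------------------------------------

def n_poly_terms(order: int) -> int:
    """Number of 3D monomials with total degree <= order: C(order+3, 3)."""
    return (order + 1) * (order + 2) * (order + 3) // 6


def normalized_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-centre coordinates scaled to [-1, 1] per axis; (n_vox, 3)."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def polynomial_basis(grid_shape: tuple[int, int, int], order: int,
                     coords: np.ndarray | None = None) -> np.ndarray:
    """Monomial design matrix x^i y^j z^k, i+j+k <= order, on [-1,1]^3 coords."""
    if coords is None:
        coords = normalized_coords(grid_shape)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    cols = []
    for total in range(order + 1):
        for combo in combinations_with_replacement(range(3), total):
            i = combo.count(0)
            j = combo.count(1)
            k = combo.count(2)
            cols.append(x**i * y**j * z**k)
    basis = np.column_stack(cols)
    assert basis.shape[1] == n_poly_terms(order)
    return basis


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_and_centralize(es: EncodingSet) -> EncodingSet:
    """Normalize magnitudes to [0, 1] and zero-mean each real/imag channel.

    Per encoding, real and imaginary images are divided by the maximum
    magnitude over all voxels and timeframes (phases unchanged); then, per
    timeframe, the volume mean of each real and each imaginary channel is
    subtracted.  Both statistics are recorded on the returned set so the
    transform can be inverted.  A set already flagged ``preprocessed`` is
    returned unchanged.
    """
    if es.preprocessed:
        return es
    mag = es.magnitude()
    scale = mag.reshape(es.n_encodings, -1).max(axis=1)      # (4,)
    if np.any(scale == 0):
        raise ValueError("all-zero magnitude for at least one encoding")
    real = es.real / scale[:, None, None, None, None]
    imag = es.imag / scale[:, None, None, None, None]
    means = (real + 1j * imag).reshape(es.n_encodings, es.n_timeframes, -1).mean(axis=2)
    real = real - means.real[:, :, None, None, None]
    imag = imag - means.imag[:, :, None, None, None]
    return replace(es, real=real, imag=imag, preprocessed=True,
                   norm_scale=scale, channel_means=means)


# ---------------------------------------------------------------------------
# velocity reconstruction
# ---------------------------------------------------------------------------

def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval (-pi, pi] (VENC maps to +pi)."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)


def reconstruct_velocity(es: EncodingSet) -> VelocityField:
    """Phase-difference velocity reconstruction.

    v_e = (VENC/pi) * wrap(phase(S_e) - phase(S_0)).  Voxels with zero
    magnitude in any involved encoding get v = 0 and are flagged in the
    ``unreliable`` mask.
    """
    if es.n_encodings < 4:
        raise ValueError("EncodingSet needs a reference (index 0) and 3 motion encodings")
    s = es.complex()
    phase = np.angle(s)
    dphi = wrap_phase(phase[1:4] - phase[0][None])
    v = (es.venc_m_s / np.pi) * dphi
    zero = (np.abs(s[0]) == 0)[None] | (np.abs(s[1:4]) == 0)
    v = np.where(zero, 0.0, v)
    return VelocityField(v=v, venc_m_s=es.venc_m_s, voxel_size_mm=es.voxel_size_mm,
                         dt_s=es.dt_s, unreliable=zero)


def unwrap_velocity(vf: VelocityField, mask: np.ndarray, max_passes: int = 10) -> VelocityField:
    """Correct velocity aliasing by comparison with the 26-neighbourhood median.

    Voxels inside ``mask`` whose velocity differs from the median of their
    masked 26-neighbourhood by more than VENC are shifted by the multiple of
    2*VENC that minimizes the difference; iterated to a fixpoint or
    ``max_passes`` passes.  Every change is an exact integer multiple of
    2*VENC.
    """
    mask = np.asarray(mask, dtype=bool)
    venc = vf.venc_m_s
    v = vf.v.copy()
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for d in range(v.shape[0]):
        for t in range(v.shape[1]):
            vol = v[d, t]
            for _ in range(max_passes):
                med = _masked_neighbor_median(vol, mask, offsets)
                diff = med - vol
                need = mask & np.isfinite(med) & (np.abs(diff) > venc)
                if not need.any():
                    break
                k = np.round(diff / (2.0 * venc))
                vol = np.where(need, vol + k * 2.0 * venc, vol)
            v[d, t] = vol
    corrected = dict(vf.corrected)
    corrected["wrap"] = True
    return VelocityField(v=v, venc_m_s=venc, voxel_size_mm=vf.voxel_size_mm,
                         dt_s=vf.dt_s, corrected=corrected, unreliable=vf.unreliable)


def _masked_neighbor_median(vol: np.ndarray, mask: np.ndarray, offsets) -> np.ndarray:
    stack = np.full((len(offsets),) + vol.shape, np.nan)
    vm = np.where(mask, vol, np.nan)
    for n, (i, j, k) in enumerate(offsets):
        src = vm[max(0, -i):vol.shape[0] - max(0, i),
                 max(0, -j):vol.shape[1] - max(0, j),
                 max(0, -k):vol.shape[2] - max(0, k)]
        stack[n][max(0, i):vol.shape[0] - max(0, -i),
                 max(0, j):vol.shape[1] - max(0, -j),
                 max(0, k):vol.shape[2] - max(0, -k)] = src
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmedian(stack, axis=0)


# ---------------------------------------------------------------------------
# static tissue and background correction
# ---------------------------------------------------------------------------

def static_tissue_mask(vf: VelocityField, magnitude: np.ndarray,
                       sd_threshold_m_s: float = 0.03,
                       magnitude_percentile: float = 25.0) -> np.ndarray:
    """Detect static tissue: bright voxels whose speed varies little in time.

    A voxel is static when its (time-averaged) magnitude exceeds the given
    percentile of nonzero magnitudes AND both the temporal SD of its speed and
    its mean speed are below ``sd_threshold_m_s`` (the mean-speed term rejects
    steadily moving voxels, whose temporal SD can also be small).
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.ndim == 4:                      # (T, X, Y, Z) -> time average
        magnitude = magnitude.mean(axis=0)
    speed = np.sqrt((vf.v ** 2).sum(axis=0))     # (T, X, Y, Z)
    tsd = speed.std(axis=0)
    tmean = speed.mean(axis=0)
    nz = magnitude[magnitude > 0]
    if nz.size == 0:
        raise ValueError("magnitude image is identically zero")
    bright = magnitude >= np.percentile(nz, magnitude_percentile)
    mask = bright & (tsd < sd_threshold_m_s) & (tmean < 3.0 * sd_threshold_m_s)
    if not mask.any():
        raise ValueError(
            "static-tissue mask is empty; raise sd_threshold_m_s or lower "
            "magnitude_percentile")
    return mask


def fit_background(vf: VelocityField, static_mask: np.ndarray, order: int = 4
                   ) -> tuple[PolyField, VelocityField]:
    """Fit and subtract a polynomial background velocity offset.

    Per timeframe and velocity direction, ordinary least squares of v over the
    3D monomial basis of total degree <= ``order`` in coordinates normalized
    to [-1, 1], restricted to ``static_mask``; the fitted surface is
    subtracted everywhere.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    grid = vf.v.shape[2:]
    nterms = n_poly_terms(order)
    if static_mask.sum() < 10 * nterms:
        raise ValueError(
            f"static mask has {int(static_mask.sum())} voxels; need >= {10 * nterms} "
            f"for a degree-{order} fit")
    basis_full = polynomial_basis(grid, order)
    basis_fit = basis_full[static_mask.ravel()]
    T = vf.v.shape[1]
    coeffs = np.empty((T, 3, nterms))
    corrected = np.empty_like(vf.v)
    for t in range(T):
        for d in range(3):
            y = vf.v[d, t][static_mask]
            c, _, rank, _ = np.linalg.lstsq(basis_fit, y, rcond=None)
            if rank < nterms:
                raise ValueError(f"rank-deficient background fit at timeframe {t}")
            coeffs[t, d] = c
            corrected[d, t] = vf.v[d, t] - (basis_full @ c).reshape(grid)
    flags = dict(vf.corrected)
    flags["background"] = True
    pf = PolyField(order=order, coefficients=coeffs, grid_shape=grid)
    out = VelocityField(v=corrected, venc_m_s=vf.venc_m_s,
                        voxel_size_mm=vf.voxel_size_mm, dt_s=vf.dt_s,
                        corrected=flags, unreliable=vf.unreliable)
    return pf, out


# ---------------------------------------------------------------------------
# turbulence mapping
# ---------------------------------------------------------------------------

def compute_tke(es: EncodingSet, rho: float = 1060.0,
                sigma_factor: str = "direct",
                sigma2_cap: float | None = None) -> TurbulenceMaps:
    """Intravoxel velocity variance and turbulent kinetic energy density.

    sigma_e^2 = f * (VENC/pi)^2 * ln(|S_0| / |S_e|), clipped below at 0, with
    f = 1 for the default estimator (the exact inverse of the simulator's
    forward model) and f = 2 for the classical Gaussian-model convention
    (``sigma_factor="classical"``); TKE = rho/2 * sum_e sigma_e^2 in
    J/m^3.  Voxels with |S_e| = 0 get sigma^2 set to ``sigma2_cap`` (default
    20 * (VENC/pi)^2) and are flagged in the ``capped`` mask.
    """
    if es.n_encodings < 4:
        raise ValueError("EncodingSet needs a reference and 3 motion encodings")
    if sigma_factor not in ("direct", "classical"):
        raise ValueError("sigma_factor must be 'direct' or 'classical'")
    f = 1.0 if sigma_factor == "direct" else 2.0
    k2 = (es.venc_m_s / np.pi) ** 2
    if sigma2_cap is None:
        sigma2_cap = 20.0 * k2
    mag = es.magnitude()
    s0, si = mag[0][None], mag[1:4]
    zero = si == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = f * k2 * np.log(np.where(zero, 1.0, s0 / np.where(zero, 1.0, si)))
    sigma2 = np.clip(np.nan_to_num(sigma2, nan=0.0, posinf=sigma2_cap), 0.0, None)
    sigma2 = np.where(zero, sigma2_cap, sigma2)
    tke = 0.5 * rho * sigma2.sum(axis=0)
    return TurbulenceMaps(sigma2=sigma2, tke=tke, rho_kg_m3=rho,
                          capped=zero.any(axis=0))


# ---------------------------------------------------------------------------
# referenceless recombination
# ---------------------------------------------------------------------------

def attach_predicted_reference(raw: EncodingSet, preprocessed: EncodingSet,
                               pred_real: np.ndarray, pred_imag: np.ndarray
                               ) -> EncodingSet:
    """Insert a network-predicted reference into a raw EncodingSet.

    The network operates in the normalized + centralized space.  The
    predicted reference is un-centralized by adding back the mean of the
    motion-encoding channel means (a computable proxy for the unknown
    reference mean) and un-normalized with the mean motion-encoding scale,
    then substituted for encoding 0 of the raw set.  The residual offset this
    proxy leaves is smooth and is removed by the background polynomial fit.
    """
    if preprocessed.channel_means is None or preprocessed.norm_scale is None:
        raise ValueError("preprocessed set lacks recorded statistics")
    c0 = preprocessed.channel_means[1:4].mean(axis=0)            # (T,) complex
    m0 = float(preprocessed.norm_scale[1:4].mean())
    pred = (np.asarray(pred_real) + 1j * np.asarray(pred_imag)
            + c0[:, None, None, None]) * m0
    return raw.with_reference(pred.real, pred.imag)
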