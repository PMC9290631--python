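"""3D-SHORE signal representation and ensemble-average-propagator indices.

The diffusion signal E(q) (normalized by the mean b=0 amplitude) is
expanded on the simple-harmonic-oscillator basis

    phi_nlm(q u) = kappa(zeta, n, l) (q^2/zeta)^(l/2) exp(-q^2 / (2 zeta))
                   L_{n-l}^{l+1/2}(q^2/zeta) Y_lm(u)

with l even, l <= n <= (N_max + l)/2 enumerated shell-wise (50 coefficients
at N_max = 6), kappa = sqrt(2 (n-l)! / (zeta^{3/2} Gamma(n + 3/2))), and
q = sqrt(b / (4 pi^2 tau)).  The basis is orthonormal over q-space.

Scalar EAP indices are obtained from q-space identities rather than from
an explicit propagator reconstruction:

* RTOP  = integral of E over q-space (EAP value at zero displacement),
* RTPP  = line integral of E along the reference axis (plane integral of
  the EAP through the origin),
* RTAP  = integral of E over the plane normal to the axis (line integral
  of the EAP along the axis); the in-plane circular average of a
  spherical harmonic reduces to 2 pi P_l(0) Y_lm(axis),
* MSD   = -laplacian(E)(0) / (4 pi^2), to which only l = 0 terms
  contribute,
* GFA   = std/rms of the constant-solid-angle ODF sampled on a fixed
  724-direction quasi-uniform sphere,
* PA    = sine of the angle between the coefficient vector and its
  isotropic (l = 0) part in the orthonormal basis, passed through the
  standard scaling sigmoid with exponent 0.4.

All radial integrals reduce to dimensionless constants (polynomials times
a Gaussian), precomputed once per radial order by Gauss-Legendre
quadrature and rescaled analytically with zeta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import (
    eval_legendre,
    gamma,
    genlaguerre,
    sph_harm_y,
    spherical_jn,
)

from .acquisition import AcquisitionScheme
from .dti import dti_md, fit_dti_block

__all__ = [
    "ShoreFit",
    "shore_index_list",
    "shore_matrix",
    "estimate_shore_scale",
    "fit_shore",
    "fit_shore_block",
    "shore_indices",
    "ShoreIndexEngine",
    "DEFAULT_TAU",
    "DEFAULT_RADIAL_ORDER",
    "DEFAULT_LAMBDA",
    "PA_EXPONENT",
]

log = logging.getLogger(__name__)

DEFAULT_TAU = 0.025          # diffusion time, s
DEFAULT_RADIAL_ORDER = 6
DEFAULT_LAMBDA = 1e-8        # radial/angular roughness weights
PA_EXPONENT = 0.4
_N_ODF_DIRECTIONS = 724


def shore_index_list(radial_order: int) -> list[tuple[int, int, int]]:
    """Basis index triples (n, l, m), l even, enumerated shell-wise."""
    if radial_order % 2 or radial_order < 0:
        raise ValueError("radial order must be a non-negative even integer")
    out = []
    for l in range(0, radial_order + 1, 2):
        for n in range(l, (radial_order + l) // 2 + 1):
            for m in range(-l, l + 1):
                out.append((n, l, m))
    return out


def real_sph_harm(indices, directions: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics at unit ``directions``.

    Returns a (n_directions, n_indices) matrix for (n, l, m) ``indices``
    (n is ignored; columns repeat across radial orders).
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    out = np.empty((directions.shape[0], len(indices)))
    cache: dict[tuple[int, int], np.ndarray] = {}
    for j, (_, l, m) in enumerate(indices):
        key = (l, abs(m))
        if key not in cache:
            cache[key] = sph_harm_y(l, abs(m), theta, phi)
        y = cache[key]
        if m == 0:
            out[:, j] = y.real
        elif m > 0:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
        else:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out


def _factorial(k: int) -> float:
    out = 1.0
    for i in range(2, k + 1):
        out *= i
    return out


def _kappa_const(n: int, l: int) -> float:
    """zeta-free part of the normalization: kappa = zeta^{-3/4} * k_nl."""
    return float(np.sqrt(2.0 * _factorial(n - l) / gamma(n + 1.5)))


@lru_cache(maxsize=None)
def _genlaguerre(k: int, alpha: float):
    return genlaguerre(k, alpha)


@lru_cache(maxsize=None)
def _scheme_sph(scheme: "AcquisitionScheme", radial_order: int) -> np.ndarray:
    """Per-scheme spherical-harmonic design (cached on scheme identity)."""
    return real_sph_harm(tuple(shore_index_list(radial_order)), scheme.bvecs)


def _radial_poly(n: int, l: int):
    """Dimensionless radial function u_nl(s) = s^l e^{-s^2/2} L_{n-l}^{l+1/2}(s^2)."""
    lag = _genlaguerre(n - l, l + 0.5)

    def u(s):
        s2 = s * s
        return s**l * np.exp(-s2 / 2.0) * lag(s2)

    return u


@lru_cache(maxsize=None)
def _radial_constants(radial_order: int):
    """Dimensionless per-(n, l) radial integrals used by the index formulas.

    Returns dict with arrays aligned to the basis index list:
    k (normalization), i_rtop, i_rtpp, i_rtap, g_msd (l=0 only, else 0),
    j_odf, plus P_l(0) values.
    """
    indices = shore_index_list(radial_order)
    nodes, weights = np.polynomial.legendre.leggauss(400)
    s = 6.0 * (nodes + 1.0)          # [0, 12]
    ws = 6.0 * weights
    x = 6.0 * (nodes + 1.0)
    wx = 6.0 * weights

    k = np.empty(len(indices))
    i_rtop = np.zeros(len(indices))
    i_rtpp = np.empty(len(indices))
    i_rtap = np.empty(len(indices))
    g_msd = np.zeros(len(indices))
    j_odf = np.empty(len(indices))
    p_l0 = np.empty(len(indices))

    pair_cache: dict[tuple[int, int], tuple] = {}
    for j, (n, l, m) in enumerate(indices):
        key = (n, l)
        if key not in pair_cache:
            u = _radial_poly(n, l)
            us = u(s)
            rtop = float((ws * us * s**2).sum()) if l == 0 else 0.0
            rtpp = float((ws * us).sum())
            rtap = float((ws * us * s).sum())
            if l == 0:
                gpoly = genlaguerre(n, 0.5)
                gp0 = float(-0.5 * gpoly(0.0) + gpoly.deriv()(0.0))
            else:
                gp0 = 0.0
            # ODF radial weight: iint x^2 s^2 u_nl(s) j_l(s x) ds dx
            jl = spherical_jn(l, np.outer(s, x))
            inner = (ws[:, None] * us[:, None] * s[:, None] ** 2 * jl).sum(axis=0)
            jodf = float((wx * x**2 * inner).sum()) * (-1.0) ** (l // 2)
            pair_cache[key] = (rtop, rtpp, rtap, gp0, jodf)
        rtop, rtpp, rtap, gp0, jodf = pair_cache[key]
        k[j] = _kappa_const(n, l)
        i_rtop[j] = rtop
        i_rtpp[j] = rtpp
        i_rtap[j] = rtap
        g_msd[j] = gp0
        j_odf[j] = jodf
        p_l0[j] = eval_legendre(l, 0.0)
    l_arr = np.array([l for (_, l, _) in indices])
    n_arr = np.array([n for (n, _, _) in indices])
    return {
        "indices": indices, "n": n_arr, "l": l_arr, "k": k,
        "i_rtop": i_rtop, "i_rtpp": i_rtpp, "i_rtap": i_rtap,
        "g_msd": g_msd, "j_odf": j_odf, "p_l0": p_l0,
    }


@lru_cache(maxsize=None)
def _odf_sphere(n: int = _N_ODF_DIRECTIONS) -> np.ndarray:
    """Fixed quasi-uniform full-sphere tessellation (antipodal pairs)."""
    from .acquisition import _fibonacci_hemisphere

    half = _fibonacci_hemisphere(n // 2)
    return np.vstack([half, -half])


@lru_cache(maxsize=None)
def _odf_design(radial_order: int) -> np.ndarray:
    """ODF sampling matrix on the fixed sphere (zeta-independent up to scale;
    constant prefactors drop out of GFA)."""
    const = _radial_constants(radial_order)
    y = real_sph_harm(const["indices"], _odf_sphere())
    return y * (const["k"] * const["j_odf"])[None, :]


def shore_matrix(scheme: AcquisitionScheme, zeta: float, tau: float,
                 radial_order: int = DEFAULT_RADIAL_ORDER) -> np.ndarray:
    """Basis design matrix at the scheme's q-space points."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    indices = shore_index_list(radial_order)
    q = scheme.qvals(tau)
    s2 = q**2 / zeta
    y = _scheme_sph(scheme, radial_order)
    b0 = scheme.b0_mask
    phi = np.empty((len(scheme), len(indices)))
    for j, (n, l, m) in enumerate(indices):
        lag = _genlaguerre(n - l, l + 0.5)
        radial = zeta**-0.75 * _kappa_const(n, l) * s2 ** (l / 2.0) * np.exp(-s2 / 2.0) * lag(s2)
        phi[:, j] = radial * y[:, j]
        if l > 0:
            phi[b0, j] = 0.0  # q = 0: direction undefined, radial part vanishes
    return phi


@lru_cache(maxsize=None)
def _regularizers(radial_order: int):
    const = _radial_constants(radial_order)
    n, l = const["n"], const["l"]
    r_n = (n * (n + 1.0)) ** 2
    r_l = (l * (l + 1.0)) ** 2
    return np.diag(r_n), np.diag(r_l)


@dataclass(frozen=True)
class ShoreFit:
    """Fitted 3D-SHORE expansion for one voxel."""

    coeffs: np.ndarray
    radial_order: int
    zeta: float          # mm^-2
    tau: float           # s
    lambda_n: float
    lambda_l: float
    b0: float            # mean b=0 amplitude used for normalization

    @property
    def indices(self) -> list[tuple[int, int, int]]:
        return shore_index_list(self.radial_order)

    def predict(self, scheme: AcquisitionScheme) -> np.ndarray:
        """Reconstructed normalized signal at the scheme's q-points."""
        return shore_matrix(scheme, self.zeta, self.tau, self.radial_order) @ self.coeffs


def estimate_shore_scale(signals: np.ndarray, scheme: AcquisitionScheme,
                         tau: float = DEFAULT_TAU) -> float:
    """Basis scale zeta = 1 / (8 pi^2 tau MD_typ).

    MD_typ is the median DTI mean diffusivity over the voxel set, so an
    isotropic Gaussian voxel at the typical diffusivity is represented
    exactly by the first basis function.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < 1:
        raise ValueError("need at least one voxel")
    evals, _, _ = fit_dti_block(signals, scheme)
    md = evals.mean(axis=1)
    if not np.isfinite(md).any():
        raise ValueError("all voxels failed DTI fitting; cannot estimate zeta")
    md_typ = float(np.nanmedian(md))
    if md_typ <= 0:
        raise ValueError(f"non-positive typical mean diffusivity {md_typ}")
    return 1.0 / (8.0 * np.pi**2 * tau * md_typ)


def _fit_operator(scheme, zeta, tau, radial_order, lambda_n, lambda_l):
    """Regularized least-squares solve operator A with c = A @ E."""
    phi = shore_matrix(scheme, zeta, tau, radial_order)
    if lambda_n == 0 and lambda_l == 0:
        if np.linalg.matrix_rank(phi) < phi.shape[1]:
            raise ValueError(
                "underdetermined SHORE system (rank < number of coefficients); "
                "regularization required"
            )
    r_n, r_l = _regularizers(radial_order)
    gram = phi.T @ phi + lambda_n * r_n + lambda_l * r_l
    return np.linalg.solve(gram, phi.T), phi


def fit_shore(signal: np.ndarray, scheme: AcquisitionScheme,
              radial_order: int = DEFAULT_RADIAL_ORDER,
              zeta: float | None = None, tau: float = DEFAULT_TAU,
              lambda_n: float = DEFAULT_LAMBDA,
              lambda_l: float = DEFAULT_LAMBDA) -> ShoreFit:
    """Fit the SHORE expansion to one voxel's measurements.

    The signal is normalized by its mean b=0 amplitude before fitting.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(scheme),):
        raise ValueError("signal length does not match scheme")
    if len(scheme.shells) < 2:
        raise ValueError("SHORE fitting needs at least two nonzero shells")
    if zeta is None:
        zeta = estimate_shore_scale(signal[None, :], scheme, tau)
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    b0 = float(signal[scheme.b0_mask].mean())
    if not b0 > 0:
        raise ValueError("mean b=0 amplitude must be positive")
    a, _ = _fit_operator(scheme, zeta, tau, radial_order, lambda_n, lambda_l)
    coeffs = a @ (signal / b0)
    return ShoreFit(coeffs=coeffs, radial_order=radial_order, zeta=float(zeta),
                    tau=tau, lambda_n=lambda_n, lambda_l=lambda_l, b0=b0)


def fit_shore_block(signals: np.ndarray, scheme: AcquisitionScheme,
                    radial_order: int = DEFAULT_RADIAL_ORDER,
                    zeta: float | None = None, tau: float = DEFAULT_TAU,
                    lambda_n: float = DEFAULT_LAMBDA,
                    lambda_l: float = DEFAULT_LAMBDA):
    """Batched SHORE fit over a (voxels, measurements) block.

    Voxels with non-positive b0 or non-finite signals yield NaN
    coefficient rows.  Returns (coeffs, zeta).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != len(scheme):
        raise ValueError("signal block does not match scheme length")
    if zeta is None:
        zeta = estimate_shore_scale(signals, scheme, tau)
    a, _ = _fit_operator(scheme, zeta, tau, radial_order, lambda_n, lambda_l)
    b0 = signals[:, scheme.b0_mask].mean(axis=1)
    valid = np.all(np.isfinite(signals), axis=1) & (b0 > 0)
    coeffs = np.full((signals.shape[0], a.shape[0]), np.nan)
    if valid.any():
        e = signals[valid] / b0[valid, None]
        coeffs[valid] = (a @ e.T).T
    return coeffs, float(zeta)


class ShoreIndexEngine:
    """Vectorized EAP-index evaluation for a fixed (radial order, zeta, tau)."""

    def __init__(self, radial_order: int, zeta: float, tau: float):
        if zeta <= 0:
            raise ValueError("zeta must be positive")
        self.radial_order = radial_order
        self.zeta = float(zeta)
        self.tau = float(tau)
        self.const = _radial_constants(radial_order)
        self._l0 = self.const["l"] == 0
        self._odf_matrix = _odf_design(radial_order)

    def rtop(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(coeffs)
        w = self.const["k"] * self.const["i_rtop"]
        return 2.0 * np.sqrt(np.pi) * self.zeta**0.75 * (c[:, self._l0] @ w[self._l0])

    def msd(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(coeffs)
        w = self.const["k"] * self.const["g_msd"]
        pref = -1.5 / (np.pi**2 * self.zeta**1.75 * np.sqrt(4.0 * np.pi))
        return pref * (c[:, self._l0] @ w[self._l0])

    def rtpp_rtap(self, coeffs: np.ndarray, axes: np.ndarray):
        c = np.atleast_2d(coeffs)
        axes = np.atleast_2d(axes)
        y = real_sph_harm(self.const["indices"], axes)  # (V, ncoef)
        w_pp = self.const["k"] * self.const["i_rtpp"]
        w_ap = self.const["k"] * self.const["i_rtap"] * self.const["p_l0"]
        rtpp = 2.0 * self.zeta**-0.25 * np.einsum("vj,vj->v", c, y * w_pp[None, :])
        rtap = 2.0 * np.pi * self.zeta**0.25 * np.einsum("vj,vj->v", c, y * w_ap[None, :])
        return rtpp, rtap

    def gfa(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(coeffs)
        odf = c @ self._odf_matrix.T  # (V, ndirs)
        mean = odf.mean(axis=1, keepdims=True)
        num = ((odf - mean) ** 2).mean(axis=1)
        den = (odf**2).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.sqrt(num / den)
        return np.where(den > 0, out, 0.0)

    def pa(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(coeffs)
        total = (c**2).sum(axis=1)
        aniso = (c[:, ~self._l0] ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.sqrt(aniso / total)
        t = np.where(total > 0, np.clip(t, 0.0, 1.0), 0.0)
        eps = PA_EXPONENT
        with np.errstate(invalid="ignore"):
            scaled = t ** (3 * eps) / (1.0 - 3.0 * t**eps + 3.0 * t ** (2 * eps))
        return np.where(t > 0, scaled, 0.0)

    def all_indices(self, coeffs: np.ndarray, axes: np.ndarray) -> dict[str, np.ndarray]:
        """rtop, rtap, rtpp, msd, gfa, pa for a coefficient block."""
        c = np.atleast_2d(coeffs)
        axes = np.atleast_2d(axes)
        valid = np.all(np.isfinite(c), axis=1) & np.all(np.isfinite(axes), axis=1)
        out = {k: np.full(c.shape[0], np.nan) for k in
               ("rtop", "rtap", "rtpp", "msd", "gfa", "pa")}
        if not valid.any():
            return out
        cv, av = c[valid], axes[valid]
        rtpp, rtap = self.rtpp_rtap(cv, av)
        out["rtop"][valid] = self.rtop(cv)
        out["rtap"][valid] = rtap
        out["rtpp"][valid] = rtpp
        out["msd"][valid] = self.msd(cv)
        out["gfa"][valid] = self.gfa(cv)
        out["pa"][valid] = self.pa(cv)
        return out


def shore_indices(fit: ShoreFit, axis: np.ndarray):
    """EAP indices (rtop, rtap, rtpp, msd, gfa, pa) for one fitted voxel.

    ``axis`` orients the RTAP line / RTPP plane (typically the DTI
    principal eigenvector).  Non-finite coefficients yield NaN outputs
    with a logged warning instead of raising.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be unit-norm")
    engine = ShoreIndexEngine(fit.radial_order, fit.zeta, fit.tau)
    if not np.all(np.isfinite(fit.coeffs)):
        log.warning("non-finite SHORE coefficients; indices set to NaN")
        nan = float("nan")
        return nan, nan, nan, nan, nan, nan
    res = engine.all_indices(fit.coeffs[None, :], axis[None, :])
    return tuple(float(res[k][0]) for k in ("rtop", "rtap", "rtpp", "msd", "gfa", "pa"))
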