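"""Adding-doubling slab optics: forward R/T and inversion for mua, mus.

The forward model computes total reflectance and transmittance of a
homogeneous plane-parallel slab under normal collimated incidence by the
adding-doubling technique: a very thin starting layer (optical thickness
tau0 <= 1e-5, first-order in tau0) is doubled repeatedly up to the slab's
optical thickness, with Henyey-Greenstein scattering discretized on a
Gauss-Radau quadrature that contains an exact node at mu = 1 so the
unscattered (ballistic) component is represented without interpolation.

Operators are stored in the flux representation: ``M[i, j]`` is the
fraction of flux incident in quadrature direction ``mu_j`` that leaves in
direction ``mu_i``, so layers compose by plain matrix products and energy
conservation is a column-sum identity. The discretized phase function is
renormalized (symmetric Sinkhorn iteration) so a conservative slab
(mua = 0) returns R + T = 1 to near machine precision.

The inverse problem (IAD) recovers (mua, mus) from a measured (R, T) pair
at fixed anisotropy g and refractive index, by a coarse log-spaced grid
search refined with Nelder-Mead on the log parameters.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import roots_jacobi

__all__ = [
    "BoundaryKind",
    "SlabSample",
    "RTMeasurement",
    "InversionResult",
    "forward_rt",
    "invert_rt",
    "slab_matrices",
    "add_layers",
    "radau_quadrature",
]

_TAU0_TARGET = 1e-5
_RT_SUM_TOL = 0.02


class BoundaryKind(str, enum.Enum):
    INDEX_MATCHED = "index_matched"
    GLASS_FREE_SURFACE = "glass_free_surface"


@dataclass(frozen=True)
class SlabSample:
    """Homogeneous slab geometry: thickness (mm), index, anisotropy."""

    thickness: float
    n: float = 1.0
    g: float = 0.9
    boundary: BoundaryKind = BoundaryKind.INDEX_MATCHED

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundary", BoundaryKind(self.boundary))
        if self.thickness <= 0:
            raise ValueError("slab thickness must be > 0")
        if not abs(self.g) < 1:
            raise ValueError("anisotropy must satisfy |g| < 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class RTMeasurement:
    """Total reflectance and transmittance at one wavelength."""

    reflectance: float
    transmittance: float
    wavelength: float = float("nan")

    def __post_init__(self) -> None:
        if self.reflectance < 0 or self.transmittance < 0:
            raise ValueError("R and T must be >= 0")
        if self.reflectance + self.transmittance > 1.0 + _RT_SUM_TOL:
            raise ValueError("R + T exceeds 1 beyond measurement slack")


@dataclass(frozen=True)
class InversionResult:
    mua: float  # mm^-1
    mus: float  # mm^-1
    converged: bool
    residual: float


def _radau_base(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Radau rule on [-1, 1] with a fixed node at +1."""
    if n < 2:
        raise ValueError("Radau rule needs n >= 2")
    # interior nodes: negated roots of Jacobi P^{(0,1)}_{n-1}
    xj, _ = roots_jacobi(n - 1, 0.0, 1.0)
    nodes = np.sort(np.concatenate([-xj, [1.0]]))
    # weights from exactness on the Legendre basis up to degree n-1
    V = np.polynomial.legendre.legvander(nodes, n - 1).T
    rhs = np.zeros(n)
    rhs[0] = 2.0
    weights = np.linalg.solve(V, rhs)
    return nodes, weights


def radau_quadrature(n: int, lo: float = 0.0, hi: float = 1.0):
    """Gauss-Radau nodes/weights on (lo, hi] with an exact node at hi."""
    x, w = _radau_base(n)
    mu = 0.5 * (lo + hi) + 0.5 * (hi - lo) * x
    return mu, w * 0.5 * (hi - lo)


def _gauss_legendre(n: int, lo: float, hi: float):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (lo + hi) + 0.5 * (hi - lo) * x, w * 0.5 * (hi - lo)


def _quadrature(order: int, n_index: float):
    """Cosine quadrature on (0, 1] with node at 1; split at the critical
    angle when the slab index is mismatched."""
    if n_index > 1.0:
        mu_c = math.sqrt(1.0 - 1.0 / (n_index * n_index))
        n1 = order // 2
        n2 = order - n1
        mu_a, w_a = _gauss_legendre(n1, 0.0, mu_c)
        mu_b, w_b = radau_quadrature(n2, mu_c, 1.0)
        return np.concatenate([mu_a, mu_b]), np.concatenate([w_a, w_b])
    return radau_quadrature(order, 0.0, 1.0)


@lru_cache(maxsize=32)
def _redistribution(g: float, order: int, n_index: float):
    """Normalized HG redistribution matrices (h_plus, h_minus) and the
    quadrature, cached per (g, order, n)."""
    mu, w = _quadrature(order, n_index)
    if g == 0.0:
        h_plus = np.ones((order, order))
        h_minus = np.ones((order, order))
    else:
        n_terms = max(8, int(math.ceil(math.log(1e-15) / math.log(abs(g)))))
        n_terms = min(n_terms, 4000)
        # Legendre values P_k(mu) by recurrence
        P = np.zeros((n_terms + 1, order))
        P[0] = 1.0
        P[1] = mu
        for k in range(1, n_terms):
            P[k + 1] = ((2 * k + 1) * mu * P[k] - k * P[k - 1]) / (k + 1)
        ks = np.arange(n_terms + 1)
        coef_p = (2 * ks + 1) * g**ks
        coef_m = (2 * ks + 1) * (-g) ** ks
        h_plus = (P * coef_p[:, None]).T @ P
        h_minus = (P * coef_m[:, None]).T @ P
    # symmetric renormalization: (1/2) sum_i w_i (h+ + h-)_{ij} = 1 for all j
    f = np.ones(order)
    for _ in range(200):
        M = 0.5 * (h_plus + h_minus) * np.outer(f, f)
        s = w @ M
        if np.max(np.abs(s - 1.0)) < 1e-15:
            break
        f = f / np.sqrt(s)
    scale = np.outer(f, f)
    h_plus = h_plus * scale
    h_minus = h_minus * scale
    mu.setflags(write=False)
    w.setflags(write=False)
    h_plus.setflags(write=False)
    h_minus.setflags(write=False)
    return mu, w, h_plus, h_minus


def add_layers(
    r1: np.ndarray, t1: np.ndarray, r2: np.ndarray, t2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Combine layer 1 (on top) with layer 2 (below).

    Both layers must be top/bottom symmetric (true for homogeneous slabs
    and specular boundaries). Returns (R, T) of the combined stack for
    illumination from above.
    """
    n = r1.shape[0]
    inv = np.linalg.inv(np.eye(n) - r1 @ r2)
    t = t2 @ inv @ t1
    r = r1 + t1 @ r2 @ inv @ t1
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise FloatingPointError("adding produced non-finite operators")
    return r, t


def _add_two_sided(a, b):
    """Adding for possibly asymmetric composites.

    Each argument is (r_top, t_down, r_bot, t_up): reflection/transmission
    for illumination from above (top, down) and from below (bot, up).
    Layer ``a`` sits on top of ``b``.
    """
    ra, ta, rpa, tpa = a
    rb, tb, rpb, tpb = b
    n = ra.shape[0]
    inv_ab = np.linalg.inv(np.eye(n) - rpa @ rb)
    inv_ba = np.linalg.inv(np.eye(n) - rb @ rpa)
    t_down = tb @ inv_ab @ ta
    r_top = ra + tpa @ rb @ inv_ab @ ta
    t_up = tpa @ inv_ba @ tpb
    r_bot = rpb + tb @ rpa @ inv_ba @ tpb
    for m in (r_top, t_down, r_bot, t_up):
        if not np.all(np.isfinite(m)):
            raise FloatingPointError("adding produced non-finite operators")
    return r_top, t_down, r_bot, t_up


def _thin_layer(tau0: float, albedo: float, mu, w, h_plus, h_minus):
    order = mu.size
    inv_mu = 1.0 / mu
    # flux representation: column j = incidence at mu_j
    scatter = 0.5 * albedo * tau0 * (w[:, None] * 1.0) * inv_mu[None, :]
    r = scatter * h_minus
    t = scatter * h_plus + np.diag(1.0 - tau0 * inv_mu)
    return r, t


def slab_matrices(
    mua: float, mus: float, slab: SlabSample, quadrature_order: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(R, T) operators of the bare slab (no boundaries) plus (mu, w)."""
    if quadrature_order < 4:
        raise ValueError("quadrature_order must be >= 4")
    if mua < 0 or mus < 0:
        raise ValueError("mua and mus must be >= 0")
    n_for_quad = slab.n if slab.boundary is BoundaryKind.GLASS_FREE_SURFACE else 1.0
    mu, w, h_plus, h_minus = _redistribution(float(slab.g), quadrature_order, n_for_quad)
    mut = mua + mus
    tau = mut * slab.thickness
    if tau == 0.0:
        n = mu.size
        return np.zeros((n, n)), np.eye(n), mu, w
    albedo = mus / mut
    k = max(1, math.ceil(math.log2(tau / _TAU0_TARGET)))
    tau0 = tau / 2.0**k
    r, t = _thin_layer(tau0, albedo, mu, w, h_plus, h_minus)
    for _ in range(k):
        r, t = add_layers(r, t, r, t)
    return r, t, mu, w


def _fresnel_unpolarized(mu_inside: np.ndarray, n_inside: float) -> np.ndarray:
    """Fresnel reflectance from inside the slab toward n = 1 outside."""
    ci = mu_inside
    si = np.sqrt(np.maximum(0.0, 1.0 - ci * ci))
    st = n_inside * si
    r = np.ones_like(ci)
    ok = st < 1.0
    ct = np.sqrt(np.maximum(0.0, 1.0 - st[ok] * st[ok]))
    n1, n2 = n_inside, 1.0
    rs = ((n1 * ci[ok] - n2 * ct) / (n1 * ci[ok] + n2 * ct)) ** 2
    rp = ((n1 * ct - n2 * ci[ok]) / (n1 * ct + n2 * ci[ok])) ** 2
    r[ok] = 0.5 * (rs + rp)
    return r


def forward_rt(
    mua: float,
    mus: float,
    slab: SlabSample,
    quadrature_order: int = 8,
    wavelength: float = float("nan"),
) -> RTMeasurement:
    """Total R and T of a homogeneous slab for normal collimated incidence."""
    r, t, mu, w = slab_matrices(mua, mus, slab, quadrature_order)
    if slab.boundary is BoundaryKind.GLASS_FREE_SURFACE and slab.n > 1.0:
        rb = np.diag(_fresnel_unpolarized(mu, slab.n))
        tb = np.eye(mu.size) - rb
        # Fresnel interfaces above and below; the intermediate composite is
        # asymmetric, so the two-sided adding form is required
        boundary = (rb, tb, rb, tb)
        stack = _add_two_sided(boundary, (r, t, r, t))
        r, t, *_ = _add_two_sided(stack, boundary)
    j = int(np.argmax(mu))  # exact mu = 1 node
    R = float(r[:, j].sum())
    T = float(t[:, j].sum())
    if not (np.isfinite(R) and np.isfinite(T)):
        raise FloatingPointError(
            f"doubling diverged for mua={mua}, mus={mus}, slab={slab}"
        )
    return RTMeasurement(max(R, 0.0), max(T, 0.0), wavelength)


def invert_rt(
    measurement: RTMeasurement,
    slab: SlabSample,
    quadrature_order: int = 8,
    residual_tol: float = 1e-3,
) -> InversionResult:
    """Recover (mua, mus) from a measured (R, T) pair (inverse AD).

    Minimizes the summed squared relative error of the forward model
    against the measurement over (mua, mus) >= 0, seeded from a 12x12
    log-spaced grid in optical thickness and refined by Nelder-Mead on the
    log parameters. ``converged`` requires a relative residual below
    ``residual_tol``.
    """
    R, T = measurement.reflectance, measurement.transmittance
    if R + T >= 1.0:
        raise ValueError("non-physical pair: R + T must be < 1 for inversion")
    d = slab.thickness

    def objective(logs: np.ndarray) -> float:
        mua = 10.0 ** logs[0]
        mus = 10.0 ** logs[1]
        try:
            m = forward_rt(mua, mus, slab, quadrature_order)
        except FloatingPointError:
            return 1e6
        er = (m.reflectance - R) / max(R, 0.01)
        et = (m.transmittance - T) / max(T, 0.01)
        return er * er + et * et

    tau_a = np.geomspace(1e-3, 10.0, 12) / d
    tau_s = np.geomspace(1e-2, 100.0, 12) / d
    best = None
    for ma in tau_a:
        for ms in tau_s:
            val = objective(np.log10([ma, ms]))
            if best is None or val < best[0]:
                best = (val, ma, ms)
    assert best is not None
    x0 = np.log10([best[1], best[2]])
    sol = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
    )
    mua = float(10.0 ** sol.x[0])
    mus = float(10.0 ** sol.x[1])
    residual = math.sqrt(float(sol.fun))
    return InversionResult(mua, mus, residual < residual_tol, residual)
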