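"""Building blocks of scaled inhomogeneous phase-type models.

Three ingredients compose every model in this package:

* :class:`PHRepresentation` -- the initial distribution ``pi`` and
  sub-intensity matrix ``T`` of a transient Markov jump process, whose
  absorption time ``Z`` is phase-type, ``Z ~ PH(pi, T)``;
* an intensity family -- a nonnegative baseline intensity ``lambda(t)`` with
  cumulative transform ``h^{-1}(y) = int_0^y lambda`` and inverse ``h``, so
  that ``h(Z)`` is inhomogeneous phase-type;
* a scaling family -- the law of a positive random effect ``Theta`` (the
  frailty analogue) acting multiplicatively on the intensity, entering all
  closed forms through its Laplace transform evaluated at matrix arguments.

The scaled model has survival ``S(y) = pi L_Theta(-h^{-1}(y) T) e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import gammaln


def logsumexp_last(x: np.ndarray) -> np.ndarray:
    """log(sum(exp(x))) over the last axis; fast, -inf-safe."""
    m = np.max(x, axis=-1)
    finite = np.isfinite(m)
    mm = np.where(finite, m, 0.0)
    with np.errstate(divide="ignore"):
        out = mm + np.log(np.sum(np.exp(x - mm[..., None]), axis=-1))
    return np.where(finite, out, -np.inf)

from .matfun import mat_fun, mat_frac_power

__all__ = [
    "PHRepresentation",
    "IntensityFamily",
    "ConstantIntensity",
    "ParetoIntensity",
    "WeibullIntensity",
    "LognormalIntensity",
    "LoglogisticIntensity",
    "GompertzIntensity",
    "make_intensity",
    "ScalingFamily",
    "Degenerate",
    "GammaScaling",
    "PositiveStable",
    "InverseStable",
    "InverseGaussianScaling",
    "PVFScaling",
    "CompoundPoissonGamma",
    "DiscreteScaling",
    "make_scaling",
    "ph_frac_moment",
    "PointMass",
]


# ---------------------------------------------------------------------------
# Phase-type representation
# ---------------------------------------------------------------------------

class PHRepresentation:
    """Initial vector ``pi`` and sub-intensity ``T`` of an absorbing chain.

    The exit-rate vector ``t = -T e`` is derived.  Validation enforces that
    ``pi`` is a probability vector, that ``T`` has nonnegative off-diagonal
    entries, negative diagonal and nonpositive row sums, and that absorption
    is almost sure (all eigenvalues of ``T`` in the open left half-plane).
    """

    __slots__ = ("pi", "T", "_eig")

    def __init__(self, pi, T, validate: bool = True):
        self.pi = np.asarray(pi, dtype=float).ravel()
        self.T = np.asarray(T, dtype=float)
        self._eig = None
        if validate:
            self._validate()

    def _validate(self) -> None:
        p = self.pi.size
        if self.T.shape != (p, p):
            raise ValueError(
                f"sub-intensity shape {self.T.shape} incompatible with "
                f"initial vector of length {p}"
            )
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector summing to 1")
        off = self.T - np.diag(np.diag(self.T))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal entries of T must be nonnegative")
        if np.any(np.diag(self.T) >= 0):
            raise ValueError("diagonal entries of T must be negative")
        if np.any(self.T.sum(axis=1) > 1e-10):
            raise ValueError("row sums of T must be nonpositive")
        if np.any(np.linalg.eigvals(self.T).real >= -1e-12):
            raise ValueError(
                "T must have eigenvalues with negative real part "
                "(absorption almost sure)"
            )

    @property
    def p(self) -> int:
        return self.pi.size

    @property
    def exit(self) -> np.ndarray:
        """Exit-rate vector ``t = -T e``."""
        return -self.T @ np.ones(self.p)

    def eig(self):
        """Cached eigendecomposition ``(lam, V, Vinv, pi V, Vinv t, Vinv e)``."""
        if self._eig is None:
            lam, V = np.linalg.eig(self.T)
            Vinv = np.linalg.inv(V)
            self._eig = (
                lam,
                V,
                Vinv,
                self.pi @ V,
                Vinv @ self.exit,
                Vinv @ np.ones(self.p),
            )
        return self._eig

    def mean(self) -> float:
        return float(self.pi @ np.linalg.solve(-self.T, np.ones(self.p)))

    def density(self, z):
        """PH density ``pi exp(Tz) t`` (vectorized)."""
        z = np.asarray(z, dtype=float)
        lam, _, _, piV, Vit, _ = self.eig()
        return np.maximum(
            np.einsum("i,...i->...", piV * Vit, np.exp(np.multiply.outer(z, lam))).real,
            0.0,
        )

    def survival(self, z):
        z = np.asarray(z, dtype=float)
        lam, _, _, piV, _, Vie = self.eig()
        vals = np.einsum(
            "i,...i->...", piV * Vie, np.exp(np.multiply.outer(z, lam))
        ).real
        return np.clip(vals, 0.0, 1.0)

    def sample(self, n: int, rng, return_stats: bool = False):
        """Simulate absorption times by running the embedded jump chain.

        With ``return_stats=True`` also returns the aggregated path
        statistics ``(B, Z, N, Nexit)`` over the sample: initial-state
        counts, occupation times, transition counts and exits to absorption.
        """
        p = self.p
        t = self.exit
        diag = -np.diag(self.T)
        # embedded jump chain: row k -> states 0..p-1 then absorption
        P = np.zeros((p, p + 1))
        for k in range(p):
            row = np.append(self.T[k].copy(), t[k])
            row[k] = 0.0
            P[k] = row / row.sum()
        cumP = np.cumsum(P, axis=1)
        cumpi = np.cumsum(self.pi)

        state = np.searchsorted(cumpi, rng.random(n), side="right")
        state = np.minimum(state, p - 1)
        times = np.zeros(n)
        alive = np.arange(n)
        if return_stats:
            B = np.bincount(state, minlength=p).astype(float)
            Z = np.zeros(p)
            N = np.zeros((p, p))
            Nexit = np.zeros(p)
        while alive.size:
            hold = rng.exponential(1.0, alive.size) / diag[state]
            times[alive] += hold
            if return_stats:
                np.add.at(Z, state, hold)
            u = rng.random(alive.size)
            nxt = (u[:, None] > cumP[state]).sum(axis=1)
            if return_stats:
                absorbed = nxt == p
                np.add.at(Nexit, state[absorbed], 1.0)
                surv = ~absorbed
                np.add.at(N, (state[surv], nxt[surv]), 1.0)
            keep = nxt < p
            alive = alive[keep]
            state = nxt[keep]
        if return_stats:
            return times, {"B": B, "Z": Z, "N": N, "Nexit": Nexit}
        return times

    def to_dict(self) -> dict:
        return {"pi": self.pi.tolist(), "T": self.T.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PHRepresentation":
        return cls(d["pi"], d["T"])

    def __repr__(self) -> str:  # pragma: no cover
        return f"PHRepresentation(p={self.p})"


def ph_frac_moment(ph: PHRepresentation, a: float) -> float:
    """Fractional moment ``E[Z^a] = Gamma(a+1) pi (-T)^{-a} e`` of a PH law."""
    if a <= 0:
        raise ValueError("moment order must be positive")
    M = mat_frac_power(-ph.T, a)  # (-T)^a; the moment needs its inverse
    return float(
        math.gamma(a + 1.0)
        * np.real(ph.pi @ np.linalg.solve(M, np.ones(ph.p)))
    )


# ---------------------------------------------------------------------------
# Intensity families (deterministic time transform)
# ---------------------------------------------------------------------------

class IntensityFamily:
    """Baseline intensity ``lambda(t)`` with transform pair ``(h, h^{-1})``.

    ``h^{-1}(y) = int_0^y lambda(t) dt`` is finite for all finite ``y`` and
    increases to infinity, so ``h(Z)`` is positive, unbounded and finite.
    """

    family: str = ""

    def lam(self, t):
        raise NotImplementedError

    def h(self, z):
        raise NotImplementedError

    def h_inv(self, y):
        raise NotImplementedError

    @property
    def params(self) -> tuple:
        return ()

    def with_params(self, params: Sequence[float]) -> "IntensityFamily":
        return make_intensity(self.family, list(params))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    def __repr__(self) -> str:  # pragma: no cover
        pars = ", ".join(f"{v:g}" for v in self.params)
        return f"{type(self).__name__}({pars})"


class ConstantIntensity(IntensityFamily):
    """``lambda == 1``: no deterministic time transform (plain scaled PH)."""

    family = "constant"

    def lam(self, t):
        return np.ones_like(np.asarray(t, dtype=float))

    def h(self, z):
        return np.asarray(z, dtype=float)

    def h_inv(self, y):
        return np.asarray(y, dtype=float)


class ParetoIntensity(IntensityFamily):
    """``lambda(t) = 1/(t + eta)``; ``h(z) = eta (e^z - 1)`` (Pareto-type)."""

    family = "pareto"

    def __init__(self, eta: float):
        if eta <= 0:
            raise ValueError("pareto intensity requires eta > 0")
        self.eta = float(eta)

    @property
    def params(self):
        return (self.eta,)

    def lam(self, t):
        return 1.0 / (np.asarray(t, dtype=float) + self.eta)

    def h(self, z):
        return self.eta * np.expm1(np.asarray(z, dtype=float))

    def h_inv(self, y):
        return np.log1p(np.asarray(y, dtype=float) / self.eta)


class WeibullIntensity(IntensityFamily):
    """``lambda(t) = eta t^{eta-1}``; ``h(z) = z^{1/eta}`` (Weibull-type)."""

    family = "weibull"

    def __init__(self, eta: float):
        if eta <= 0:
            raise ValueError("weibull intensity requires eta > 0")
        self.eta = float(eta)

    @property
    def params(self):
        return (self.eta,)

    def lam(self, t):
        return self.eta * np.asarray(t, dtype=float) ** (self.eta - 1.0)

    def h(self, z):
        return np.asarray(z, dtype=float) ** (1.0 / self.eta)

    def h_inv(self, y):
        return np.asarray(y, dtype=float) ** self.eta


class LognormalIntensity(IntensityFamily):
    """``lambda(t) = gamma log(t+1)^{gamma-1}/(t+1)`` (lognormal-type tails)."""

    family = "lognormal"

    def __init__(self, gamma: float):
        if gamma <= 1:
            raise ValueError("lognormal intensity requires gamma > 1")
        self.gamma = float(gamma)

    @property
    def params(self):
        return (self.gamma,)

    def lam(self, t):
        t = np.asarray(t, dtype=float)
        return self.gamma * np.log1p(t) ** (self.gamma - 1.0) / (t + 1.0)

    def h(self, z):
        return np.expm1(np.asarray(z, dtype=float) ** (1.0 / self.gamma))

    def h_inv(self, y):
        return np.log1p(np.asarray(y, dtype=float)) ** self.gamma


class LoglogisticIntensity(IntensityFamily):
    """``lambda(t) = eta t^{eta-1}/(t^eta + gamma^eta)`` (loglogistic-type)."""

    family = "loglogistic"

    def __init__(self, gamma: float, eta: float):
        if gamma <= 0 or eta <= 0:
            raise ValueError("loglogistic intensity requires gamma, eta > 0")
        self.gamma = float(gamma)
        self.eta = float(eta)

    @property
    def params(self):
        return (self.gamma, self.eta)

    def lam(self, t):
        t = np.asarray(t, dtype=float)
        return self.eta * t ** (self.eta - 1.0) / (t**self.eta + self.gamma**self.eta)

    def h(self, z):
        return self.gamma * np.expm1(np.asarray(z, dtype=float)) ** (1.0 / self.eta)

    def h_inv(self, y):
        return np.log1p((np.asarray(y, dtype=float) / self.gamma) ** self.eta)


class GompertzIntensity(IntensityFamily):
    """``lambda(t) = exp(eta t)``; ``h(z) = log(eta z + 1)/eta`` (Gompertz)."""

    family = "gompertz"

    def __init__(self, eta: float):
        if eta <= 0:
            raise ValueError("gompertz intensity requires eta > 0")
        self.eta = float(eta)

    @property
    def params(self):
        return (self.eta,)

    def lam(self, t):
        return np.exp(self.eta * np.asarray(t, dtype=float))

    def h(self, z):
        return np.log1p(self.eta * np.asarray(z, dtype=float)) / self.eta

    def h_inv(self, y):
        return np.expm1(self.eta * np.asarray(y, dtype=float)) / self.eta


_INTENSITIES = {
    "constant": ConstantIntensity,
    "pareto": ParetoIntensity,
    "weibull": WeibullIntensity,
    "lognormal": LognormalIntensity,
    "loglogistic": LoglogisticIntensity,
    "gompertz": GompertzIntensity,
}


def make_intensity(family: str, params: Sequence[float] = ()) -> IntensityFamily:
    try:
        cls = _INTENSITIES[family]
    except KeyError:
        raise ValueError(
            f"unknown intensity family {family!r}; "
            f"choose from {sorted(_INTENSITIES)}"
        ) from None
    return cls(*params)


# ---------------------------------------------------------------------------
# Scaling (frailty) families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointMass:
    """Discrete scaling law returned where a Lebesgue density does not exist."""

    points: tuple
    weights: tuple


def _bell_derivs(L0, gderivs, d):
    """Derivatives of ``exp(g)`` from derivatives of ``g``.

    Uses the recurrence ``y^{(n)} = sum_k C(n-1, k) y^{(k)} g^{(n-k)}`` with
    ``y = exp(g)``; returns ``y^{(d)}``.
    """
    ys = [L0]
    for n in range(1, d + 1):
        acc = 0.0
        for k in range(n):
            acc = acc + math.comb(n - 1, k) * ys[k] * gderivs[n - 1 - k]
        ys.append(acc)
    return ys[d]


class ScalingFamily:
    """Law of the positive random scaling ``Theta``.

    Subclasses provide the Laplace transform (scalar, complex and matrix
    argument), its derivatives up to order 4 (enough for 4-variate shared
    densities), a density or point-mass representation, and a sampler.
    """

    family: str = ""
    max_deriv_order: int = 4

    # -- Laplace transform ------------------------------------------------
    def _lap(self, z):
        """Unvalidated Laplace transform at complex argument."""
        raise NotImplementedError

    def _lap_deriv(self, z, d: int):
        """Unvalidated ``d``-th derivative at complex argument."""
        raise NotImplementedError

    def _domain_min(self) -> float:
        return 0.0

    def laplace(self, u):
        """``E[exp(-u Theta)]`` for real ``u`` in the transform's domain."""
        u = np.asarray(u, dtype=float)
        if np.any(u < self._domain_min()):
            raise ValueError(
                f"Laplace argument below domain minimum {self._domain_min()}"
            )
        out = np.real(self._lap(u.astype(complex)))
        return out if out.ndim else float(out)

    def laplace_deriv(self, u, d: int):
        if not (1 <= d <= self.max_deriv_order):
            raise ValueError(
                f"derivative order {d} unsupported (1..{self.max_deriv_order})"
            )
        u = np.asarray(u, dtype=float)
        if np.any(u < self._domain_min()):
            raise ValueError("Laplace argument outside domain")
        out = np.real(self._lap_deriv(u.astype(complex), d))
        return out if out.ndim else float(out)

    def laplace_matrix(self, U) -> np.ndarray:
        """``L_Theta(U)`` by functional calculus."""
        return mat_fun(U, self._lap)

    def laplace_deriv_matrix(self, U, d: int) -> np.ndarray:
        if not (1 <= d <= self.max_deriv_order):
            raise ValueError(
                f"derivative order {d} unsupported (1..{self.max_deriv_order})"
            )
        return mat_fun(U, lambda z: self._lap_deriv(z, d))

    # -- density / sampling ------------------------------------------------
    has_density = True

    def density(self, theta):
        raise NotImplementedError

    def log_density(self, theta):
        with np.errstate(divide="ignore"):
            return np.log(self.density(theta))

    def sample(self, n: int, rng) -> np.ndarray:
        raise NotImplementedError

    def mean(self) -> float:
        """``E[Theta] = -L'(0)``."""
        return float(-self.laplace_deriv(0.0, 1))

    def log_support(self) -> tuple:
        """Rough ``(log lo, log hi)`` bracket containing essentially all mass.

        Used to seed posterior quadrature grids; generous by design.
        """
        return (math.log(1e-8), math.log(1e4))

    # -- parameters / serialization ---------------------------------------
    @property
    def params(self) -> tuple:
        return ()

    def with_params(self, params: Sequence[float]) -> "ScalingFamily":
        return make_scaling(self.family, list(params))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    def __repr__(self) -> str:  # pragma: no cover
        pars = ", ".join(f"{v:g}" for v in np.ravel(self.params))
        return f"{type(self).__name__}({pars})"


class Degenerate(ScalingFamily):
    """``Theta == k``: no random scaling (recovers plain IPH/PH models)."""

    family = "degenerate"
    has_density = False

    def __init__(self, k: float = 1.0):
        if k <= 0:
            raise ValueError("degenerate scaling requires k > 0")
        self.k = float(k)

    @property
    def params(self):
        return (self.k,)

    def _domain_min(self):
        return -np.inf

    def _lap(self, z):
        return np.exp(-self.k * z)

    def _lap_deriv(self, z, d):
        return (-self.k) ** d * np.exp(-self.k * z)

    def density(self, theta):
        raise TypeError("degenerate scaling has no density; see point_masses()")

    def point_masses(self) -> PointMass:
        return PointMass((self.k,), (1.0,))

    def sample(self, n, rng):
        return np.full(n, self.k)

    def log_support(self):
        return (math.log(self.k) - 1e-6, math.log(self.k) + 1e-6)


class GammaScaling(ScalingFamily):
    """``Theta ~ Gamma(alpha, 1)``: Laplace ``(1+u)^{-alpha}``.

    The rate is fixed at 1: a general rate is absorbed by the sub-intensity
    matrix and is not identifiable.
    """

    family = "gamma"

    def __init__(self, alpha: float):
        if alpha <= 0:
            raise ValueError("gamma scaling requires alpha > 0")
        self.alpha = float(alpha)

    @property
    def params(self):
        return (self.alpha,)

    def _domain_min(self):
        return -1.0

    def _lap(self, z):
        return (1.0 + z) ** (-self.alpha)

    def _lap_deriv(self, z, d):
        a = self.alpha
        coef = (-1.0) ** d * math.exp(gammaln(a + d) - gammaln(a))
        return coef * (1.0 + z) ** (-a - d)

    max_deriv_order = 64  # closed form for any order

    def density(self, theta):
        theta = np.asarray(theta, dtype=float)
        with np.errstate(divide="ignore"):
            return np.exp(self.log_density(theta))

    def log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        a = self.alpha
        with np.errstate(divide="ignore"):
            return (a - 1.0) * np.log(theta) - theta - gammaln(a)

    def sample(self, n, rng):
        return rng.gamma(self.alpha, 1.0, n)

    def log_support(self):
        from scipy.stats import gamma as gamma_dist

        lo = gamma_dist.ppf(1e-14, self.alpha)
        hi = gamma_dist.isf(1e-14, self.alpha)
        return (math.log(max(lo, 1e-300)), math.log(hi))


def _check_stable_alpha(alpha: float) -> float:
    if not (0.0 < alpha <= 1.0):
        raise ValueError("stability parameter must lie in (0, 1]")
    return float(alpha)


_PHI_NODES, _PHI_WEIGHTS = leggauss(96)


def _kanter_log_a(phi: np.ndarray, alpha: float) -> np.ndarray:
    """``log a(phi)`` in Kanter's representation of the positive stable law."""
    return (
        alpha * np.log(np.sin(alpha * phi))
        + (1.0 - alpha) * np.log(np.sin((1.0 - alpha) * phi))
        - np.log(np.sin(phi))
    ) / (1.0 - alpha)


def sample_positive_stable(alpha: float, n: int, rng) -> np.ndarray:
    """Positive stable variates with Laplace transform ``exp(-u^alpha)``.

    Chambers--Mallows--Stuck construction specialised to the totally skewed
    positive case.
    """
    alpha = _check_stable_alpha(alpha)
    if alpha == 1.0:
        return np.ones(n)
    U = rng.uniform(0.0, np.pi, n)
    E = rng.exponential(1.0, n)
    return (
        np.sin(alpha * U)
        / np.sin(U) ** (1.0 / alpha)
        * (np.sin((1.0 - alpha) * U) / E) ** ((1.0 - alpha) / alpha)
    )


class PositiveStable(ScalingFamily):
    """Positive stable ``Theta`` with ``L(u) = exp(-u^alpha)``, alpha in (0,1].

    The density has no elementary closed form; it is evaluated by numerical
    quadrature of the Zolotarev/Kanter integral representation.
    """

    family = "positive_stable"

    def __init__(self, alpha: float):
        self.alpha = _check_stable_alpha(alpha)

    @property
    def params(self):
        return (self.alpha,)

    def _lap(self, z):
        if self.alpha == 1.0:
            return np.exp(-z)
        return np.exp(-(z ** self.alpha))

    def _gderivs(self, z, d):
        # g(u) = -u^alpha
        a = self.alpha
        out = []
        coef = -1.0
        for j in range(1, d + 1):
            coef *= a - (j - 1)
            out.append(coef * z ** (a - j))
        return out

    def _lap_deriv(self, z, d):
        if self.alpha == 1.0:
            return (-1.0) ** d * np.exp(-z)
        return _bell_derivs(self._lap(z), self._gderivs(z, d), d)

    def density(self, theta):
        with np.errstate(over="ignore"):
            return np.exp(self.log_density(theta))

    def log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        a = self.alpha
        if a == 1.0:
            raise TypeError(
                "alpha = 1 is the degenerate unit scaling; see point_masses()"
            )
        phi = (_PHI_NODES + 1.0) * (np.pi / 2.0)
        logw = np.log(_PHI_WEIGHTS * (np.pi / 2.0))
        log_a = _kanter_log_a(phi, a)
        r = a / (1.0 - a)
        with np.errstate(over="ignore", under="ignore", divide="ignore"):
            # exp(log_a) * theta^{-r} computed jointly in log space: either
            # factor alone may overflow where the product is negligible
            term = np.exp(log_a - r * np.log(theta)[..., None])
            expo = log_a + logw - term
            log_int = logsumexp_last(expo) - np.log(np.pi)
            out = np.log(r) - np.log(theta) / (1.0 - a) + log_int
        return np.where(np.isfinite(log_int) & (theta > 0), out, -np.inf)

    def point_masses(self) -> PointMass:
        if self.alpha != 1.0:
            raise TypeError("non-degenerate stable scaling has a density")
        return PointMass((1.0,), (1.0,))

    def sample(self, n, rng):
        return sample_positive_stable(self.alpha, n, rng)

    def mean(self) -> float:
        if self.alpha == 1.0:
            return 1.0
        return math.inf  # stable laws with alpha < 1 have no finite mean

    def log_support(self):
        a = self.alpha
        if a == 1.0:
            return (-1e-6, 1e-6)
        # S = (a(U)/E)^{(1-a)/a}: bracket from extreme quantiles of E and a(U)
        phi = (_PHI_NODES + 1.0) * (np.pi / 2.0)
        la = _kanter_log_a(phi, a)
        s = (1.0 - a) / a
        return (s * (la.min() - 45.0), s * (la.max() + 40.0))


class InverseStable(ScalingFamily):
    """``Theta = S_alpha^{-alpha}`` for a positive stable ``S_alpha``.

    This is the mixing law under which a power transform of a scaled PH
    variable follows the matrix Mittag-Leffler (fractional phase-type)
    distribution: the Laplace transform satisfies ``L(u) = E_alpha(-u)``
    with ``E_alpha`` the Mittag-Leffler function.  Laplace values and
    derivatives are computed by quadrature against the closed-form density
    below, which follows from Kanter's representation:

    ``f(theta) = theta^{a/(1-a)}/(1-a) * (1/pi) int_0^pi a(phi)
    exp(-a(phi) theta^{1/(1-a)}) dphi``.
    """

    family = "inverse_stable"

    def __init__(self, alpha: float):
        self.alpha = _check_stable_alpha(alpha)
        self._grid = None

    @property
    def params(self):
        return (self.alpha,)

    def _quad_grid(self):
        """Cached (theta nodes, probability weights) for Laplace quadrature."""
        if self._grid is None:
            lo, hi = self.log_support()
            # 500 log-spaced nodes reproduce the transform to ~1e-9 relative
            lg = np.linspace(lo, hi, 500)
            th = np.exp(lg)
            w = self.density(th) * th * np.gradient(lg)
            w = w / w.sum()  # normalize: quadrature of a density
            self._grid = (th, w)
        return self._grid

    @staticmethod
    def _mix(z, th, w):
        z = np.asarray(z)
        if np.iscomplexobj(z) and np.abs(z.imag).max() == 0.0:
            z = z.real
        return np.einsum("...j,j->...", np.exp(-np.multiply.outer(z, th)), w)

    def _lap(self, z):
        if self.alpha == 1.0:
            return np.exp(-np.asarray(z))
        th, w = self._quad_grid()
        return self._mix(z, th, w)

    def _lap_deriv(self, z, d):
        if self.alpha == 1.0:
            return (-1.0) ** d * np.exp(-np.asarray(z))
        th, w = self._quad_grid()
        return self._mix(z, th, w * (-th) ** d)

    def density(self, theta):
        with np.errstate(over="ignore"):
            return np.exp(self.log_density(theta))

    def log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        a = self.alpha
        if a == 1.0:
            raise TypeError(
                "alpha = 1 is the degenerate unit scaling; see point_masses()"
            )
        phi = (_PHI_NODES + 1.0) * (np.pi / 2.0)
        logw = np.log(_PHI_WEIGHTS * (np.pi / 2.0))
        log_a = _kanter_log_a(phi, a)
        r = 1.0 / (1.0 - a)
        with np.errstate(over="ignore", under="ignore", divide="ignore"):
            term = np.exp(log_a + r * np.log(theta)[..., None])
            expo = log_a + logw - term
            log_int = logsumexp_last(expo) - np.log(np.pi)
            out = np.log(r) + a * r * np.log(theta) + log_int
        return np.where(np.isfinite(log_int) & (theta > 0), out, -np.inf)

    def point_masses(self) -> PointMass:
        if self.alpha != 1.0:
            raise TypeError("non-degenerate inverse-stable scaling has a density")
        return PointMass((1.0,), (1.0,))

    def sample(self, n, rng):
        if self.alpha == 1.0:
            return np.ones(n)
        return sample_positive_stable(self.alpha, n, rng) ** (-self.alpha)

    def mean(self) -> float:
        # E[S^{-alpha}] = Gamma(2)/Gamma(1+alpha)
        return 1.0 / math.gamma(1.0 + self.alpha)

    def log_support(self):
        a = self.alpha
        if a == 1.0:
            return (-1e-6, 1e-6)
        phi = (_PHI_NODES + 1.0) * (np.pi / 2.0)
        la = _kanter_log_a(phi, a)
        # Theta = (E / a(U))^{1-a}
        return ((1.0 - a) * (-la.max() - 40.0), (1.0 - a) * (-la.min() + 45.0))


class InverseGaussianScaling(ScalingFamily):
    """Inverse Gaussian ``Theta`` with unit mean and variance ``sigma2``.

    ``L(u) = exp((1 - sqrt(1 + 2 sigma2 u))/sigma2)``.
    """

    family = "inverse_gaussian"

    def __init__(self, sigma2: float):
        if sigma2 <= 0:
            raise ValueError("inverse Gaussian scaling requires sigma2 > 0")
        self.sigma2 = float(sigma2)

    @property
    def params(self):
        return (self.sigma2,)

    def _lap(self, z):
        s2 = self.sigma2
        return np.exp((1.0 - np.sqrt(1.0 + 2.0 * s2 * z)) / s2)

    def _gderivs(self, z, d):
        s2 = self.sigma2
        root = 1.0 + 2.0 * s2 * z
        out = []
        coef = -1.0 / s2
        for j in range(1, d + 1):
            coef *= (0.5 - (j - 1)) * 2.0 * s2
            out.append(coef * root ** (0.5 - j))
        return out

    def _lap_deriv(self, z, d):
        return _bell_derivs(self._lap(z), self._gderivs(z, d), d)

    def density(self, theta):
        theta = np.asarray(theta, dtype=float)
        eta = 1.0 / self.sigma2
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            out = np.sqrt(eta / (2.0 * np.pi * theta**3)) * np.exp(
                -eta * (theta - 1.0) ** 2 / (2.0 * theta)
            )
        return np.where(theta > 0, out, 0.0)

    def log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        eta = 1.0 / self.sigma2
        with np.errstate(divide="ignore"):
            return (
                0.5 * np.log(eta / (2.0 * np.pi))
                - 1.5 * np.log(theta)
                - eta * (theta - 1.0) ** 2 / (2.0 * theta)
            )

    def sample(self, n, rng):
        return rng.wald(1.0, 1.0 / self.sigma2, n)

    def log_support(self):
        from scipy.stats import invgauss

        mu = self.sigma2  # scipy invgauss(mu, scale=lam) with lam = 1/sigma2
        lo = invgauss.ppf(1e-14, mu, scale=1.0 / self.sigma2)
        hi = invgauss.isf(1e-14, mu, scale=1.0 / self.sigma2)
        return (math.log(max(lo, 1e-300)), math.log(hi))


class PVFScaling(ScalingFamily):
    """Power-variance-function family (unit ``nu``), gamma/IG/stable bridge.

    ``L(u) = exp(c (1 - (1 + u/m)^gamma))`` with ``c = eta(1-gamma)/gamma``
    and ``m = eta(1-gamma)``; unit mean by construction.  Used through its
    Laplace transform only: no sampler or density is provided for the
    general case (the named special cases have their own families).
    """

    family = "pvf"
    has_density = False

    def __init__(self, eta: float, gamma: float):
        if eta <= 0 or not (0.0 < gamma <= 1.0):
            raise ValueError("PVF requires eta > 0 and gamma in (0, 1]")
        self.eta = float(eta)
        self.gamma = float(gamma)

    @property
    def params(self):
        return (self.eta, self.gamma)

    def _lap(self, z):
        c = self.eta * (1.0 - self.gamma) / self.gamma
        m = self.eta * (1.0 - self.gamma)
        return np.exp(c * (1.0 - (1.0 + z / m) ** self.gamma))

    def _gderivs(self, z, d):
        c = self.eta * (1.0 - self.gamma) / self.gamma
        m = self.eta * (1.0 - self.gamma)
        base = 1.0 + z / m
        out = []
        coef = -c
        for j in range(1, d + 1):
            coef *= (self.gamma - (j - 1)) / m
            out.append(coef * base ** (self.gamma - j))
        return out

    def _lap_deriv(self, z, d):
        return _bell_derivs(self._lap(z), self._gderivs(z, d), d)

    def density(self, theta):
        raise NotImplementedError(
            "general PVF density not implemented; use the gamma, "
            "inverse Gaussian or positive stable special cases"
        )

    def sample(self, n, rng):
        raise NotImplementedError(
            "general PVF sampling not implemented; use the gamma, "
            "inverse Gaussian or positive stable special cases"
        )


class CompoundPoissonGamma(ScalingFamily):
    """``Theta = sum_{i<=N} V_i`` with ``N ~ Poisson(rho)``, ``V ~ Gamma(alpha,1)``.

    ``L(u) = exp(-rho (1 - (1+u)^{-alpha}))``; ``L(u) -> exp(-rho)`` as
    ``u -> oo``, i.e. the scaled lifetime has a defective distribution with
    mass ``exp(-rho)`` escaping to infinity (a cure fraction).
    """

    family = "compound_poisson_gamma"
    has_density = False  # mixed law: atom at zero plus a continuous part

    def __init__(self, rho: float, alpha: float):
        if rho <= 0 or alpha <= 0:
            raise ValueError("compound Poisson-gamma requires rho, alpha > 0")
        self.rho = float(rho)
        self.alpha = float(alpha)

    @property
    def params(self):
        return (self.rho, self.alpha)

    def _lap(self, z):
        return np.exp(-self.rho * (1.0 - (1.0 + z) ** (-self.alpha)))

    def _gderivs(self, z, d):
        a = self.alpha
        out = []
        coef = self.rho
        for j in range(1, d + 1):
            coef *= -(a + (j - 1))
            out.append(coef * (1.0 + z) ** (-a - j))
        return out

    def _lap_deriv(self, z, d):
        return _bell_derivs(self._lap(z), self._gderivs(z, d), d)

    def density(self, theta):
        raise TypeError(
            "compound Poisson-gamma scaling has an atom at zero; "
            "no Lebesgue density exists"
        )

    def sample(self, n, rng):
        N = rng.poisson(self.rho, n)
        out = np.zeros(n)
        pos = N > 0
        out[pos] = rng.gamma(N[pos] * self.alpha, 1.0)
        return out


class DiscreteScaling(ScalingFamily):
    """Finitely supported ``Theta`` with ``P(Theta = eta_i) = alpha_i``."""

    family = "discrete"
    has_density = False

    def __init__(self, support: Sequence[float], weights: Sequence[float]):
        self.support = np.asarray(support, dtype=float).ravel()
        self.weights = np.asarray(weights, dtype=float).ravel()
        if self.support.size == 0 or self.support.size != self.weights.size:
            raise ValueError("support and weights must be equal-length, nonempty")
        if np.any(self.support <= 0):
            raise ValueError("support points must be positive")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def params(self):
        return (tuple(self.support), tuple(self.weights))

    def with_params(self, params):
        return DiscreteScaling(params[0], params[1])

    def to_dict(self):
        return {
            "family": self.family,
            "params": [self.support.tolist(), self.weights.tolist()],
        }

    def _domain_min(self):
        return -np.inf

    def _lap(self, z):
        return np.einsum(
            "...j,j->...",
            np.exp(-np.multiply.outer(np.asarray(z), self.support)),
            self.weights,
        )

    def _lap_deriv(self, z, d):
        return np.einsum(
            "...j,j->...",
            np.exp(-np.multiply.outer(np.asarray(z), self.support)),
            self.weights * (-self.support) ** d,
        )

    def density(self, theta):
        raise TypeError("discrete scaling has no density; see point_masses()")

    def point_masses(self) -> PointMass:
        return PointMass(tuple(self.support), tuple(self.weights))

    def sample(self, n, rng):
        idx = rng.choice(self.support.size, size=n, p=self.weights)
        return self.support[idx]

    def log_support(self):
        return (math.log(self.support.min()) - 1e-6, math.log(self.support.max()) + 1e-6)


_SCALINGS = {
    "degenerate": Degenerate,
    "gamma": GammaScaling,
    "positive_stable": PositiveStable,
    "inverse_stable": InverseStable,
    "inverse_gaussian": InverseGaussianScaling,
    "pvf": PVFScaling,
    "compound_poisson_gamma": CompoundPoissonGamma,
    "discrete": DiscreteScaling,
}


def make_scaling(family: str, params) -> ScalingFamily:
    try:
        cls = _SCALINGS[family]
    except KeyError:
        raise ValueError(
            f"unknown scaling family {family!r}; choose from {sorted(_SCALINGS)}"
        ) from None
    if family == "discrete":
        return DiscreteScaling(params[0], params[1])
    return cls(*np.ravel(params))
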