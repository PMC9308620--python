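"""Multivariate scaled phase-type models.

Two constructions, mirroring the shared and correlated frailty models:

* **Shared scaling** -- one positive variable ``Theta`` multiplies the
  intensity of ``d`` conditionally independent phase-type margins.  The
  joint survival collapses into a single matrix function of a Kronecker
  sum::

      S(y) = (pi_1 ⊗ ... ⊗ pi_d) L_Theta(-(T_1 h_1^{-1}(y_1) ⊕ ... )) e

  and the joint density uses the d-th Laplace derivative.

* **Correlated scaling** -- each margin has its own ``Theta_i``, built from
  shared and idiosyncratic gamma components (``Theta_i = (W_0 + G_i)/eta_i``
  with ``W_0 ~ Gamma(kappa_0, 1)``, ``G_i ~ Gamma(kappa_i, 1)``), giving an
  explicit joint survival as a product of three commuting matrix powers.

Upper tail dependence for shared regularly-varying scaling follows the
fractional-moment formula
``lambda_U = Gamma(a+1) (pi_1 ⊗ pi_2)(-(T~_1 ⊕ T~_2))^{-a} e`` with
``T~_i = T_i E(Z_i^a)^{1/a}``.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .components import (
    GammaScaling,
    IntensityFamily,
    PHRepresentation,
    ScalingFamily,
    ph_frac_moment,
)
from .matfun import kron_sum, mat_frac_power
from .univariate import SIPHModel

__all__ = [
    "SharedSIPHModel",
    "CorrelatedSIPHModel",
    "tail_dependence_upper",
    "empirical_tail_dependence",
]

Margin = Tuple[PHRepresentation, IntensityFamily]


def _joint_args(margins: Sequence[Margin], u: np.ndarray, weight: str):
    """Flattened Kronecker eigen-structure for a batch of arguments.

    ``u`` has shape (n, d) and holds the per-margin transformed arguments
    ``h_i^{-1}(y_i)``.  Returns ``(U, w)`` where ``U`` (n, P) holds
    ``sum_i u_i lam^{(i)}`` over the product of spectra and ``w`` (P,) the
    matching Kronecker weights (``pi V`` paired with ``V^{-1} t`` or
    ``V^{-1} e``).
    """
    n = u.shape[0]
    U = np.zeros((n, 1), dtype=complex)
    w = np.ones(1, dtype=complex)
    for i, (ph, _) in enumerate(margins):
        lam, _, _, piV, Vit, Vie = ph.eig()
        wi = piV * (Vit if weight == "t" else Vie)
        U = (U[:, :, None] + np.multiply.outer(u[:, i], lam)[:, None, :]).reshape(
            n, -1
        )
        w = np.multiply.outer(w, wi).ravel()
    return U, w


class SharedSIPHModel:
    """``d`` phase-type margins driven by one common scaling variable."""

    def __init__(
        self,
        margins: Sequence[Margin],
        scaling: ScalingFamily,
        beta=None,
    ):
        if len(margins) < 2:
            raise ValueError("a shared model needs at least two margins")
        self.margins: List[Margin] = [
            (ph if isinstance(ph, PHRepresentation) else PHRepresentation(*ph), it)
            for ph, it in margins
        ]
        self.scaling = scaling
        self.beta = None if beta is None else np.asarray(beta, dtype=float).ravel()

    @property
    def d(self) -> int:
        return len(self.margins)

    def margin(self, i: int) -> SIPHModel:
        """The i-th marginal law (same scaling, own PH and intensity)."""
        ph, intensity = self.margins[i]
        return SIPHModel(ph, intensity, self.scaling, beta=self.beta)

    def _uarg(self, y, x=None) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] != self.d:
            raise ValueError(f"expected {self.d} columns, got {y.shape[1]}")
        u = np.column_stack(
            [self.margins[i][1].h_inv(y[:, i]) for i in range(self.d)]
        )
        if self.beta is not None:
            if x is None:
                raise ValueError("model expects covariates")
            risk = np.exp(np.atleast_2d(np.asarray(x, float)) @ self.beta)
            u = u * risk[:, None]
        return u

    def survival(self, y, x=None):
        """Joint survival; margins recover the univariate survival."""
        scalar = np.asarray(y).ndim == 1
        yv = np.atleast_2d(np.asarray(y, dtype=float))
        if np.any(yv < 0):
            raise ValueError("survival is defined for y >= 0 entrywise")
        u = self._uarg(yv, x)
        U, w = _joint_args(self.margins, u, "e")
        vals = (self.scaling._lap(-U) @ w).real
        vals = np.clip(vals, 0.0, 1.0)
        return float(vals[0]) if scalar else vals

    def density(self, y, x=None):
        """Joint density via the order-d Laplace-transform derivative."""
        scalar = np.asarray(y).ndim == 1
        yv = np.atleast_2d(np.asarray(y, dtype=float))
        if np.any(yv <= 0):
            raise ValueError("density is defined for y > 0 entrywise")
        u = self._uarg(yv, x)
        U, w = _joint_args(self.margins, u, "t")
        d = self.d
        vals = ((-1.0) ** d) * (self.scaling._lap_deriv(-U, d) @ w).real
        pref = np.prod(
            np.column_stack(
                [self.margins[i][1].lam(yv[:, i]) for i in range(d)]
            ),
            axis=1,
        )
        if self.beta is not None:
            risk = np.exp(np.atleast_2d(np.asarray(x, float)) @ self.beta)
            pref = pref * risk**d
        vals = np.maximum(pref * vals, 0.0)
        return float(vals[0]) if scalar else vals

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Rows ``(h_1(Z_1/Theta), ..., h_d(Z_d/Theta))`` with shared Theta."""
        rng = seed if isinstance(seed, np.random.Generator) else (
            np.random.default_rng(seed))
        theta = self.scaling.sample(n, rng)
        cols = []
        for ph, intensity in self.margins:
            Z = ph.sample(n, rng)
            cols.append(intensity.h(Z / theta))
        return np.column_stack(cols)

    def tail_dependence_upper(self) -> float:
        return tail_dependence_upper(self)

    def to_dict(self) -> dict:
        return {
            "margins": [
                {**ph.to_dict(), "intensity": it.to_dict()}
                for ph, it in self.margins
            ],
            "scaling": self.scaling.to_dict(),
            "beta": None if self.beta is None else self.beta.tolist(),
        }


def tail_dependence_upper(model: SharedSIPHModel) -> float:
    """Coefficient of upper tail dependence of a bivariate shared model.

    Valid when ``1/Theta`` is regularly varying with index ``a``; for gamma
    scaling the index is the shape parameter.  The intensities do not enter:
    the time transforms are increasing, so the copula is that of the
    underlying scaled PH pair.
    """
    if model.d != 2:
        raise ValueError("tail dependence is computed for bivariate models")
    if not isinstance(model.scaling, GammaScaling):
        raise ValueError(
            "upper tail dependence requires scaling with regularly varying "
            "reciprocal (implemented: gamma)"
        )
    a = model.scaling.alpha
    (ph1, _), (ph2, _) = model.margins
    scaled = []
    for ph in (ph1, ph2):
        m = ph_frac_moment(ph, a)
        scaled.append(ph.T * m ** (1.0 / a))
    K = kron_sum(scaled[0], scaled[1])
    M = mat_frac_power(-K, a)
    val = math.gamma(a + 1.0) * float(
        np.real(np.kron(ph1.pi, ph2.pi) @ np.linalg.solve(M, np.ones(M.shape[0])))
    )
    return min(max(val, 0.0), 1.0)


def empirical_tail_dependence(sample: np.ndarray, q: float = 0.95) -> float:
    """Empirical conditional exceedance ``P(Y1 > q1 | Y2 > q2)``.

    Evaluated at the empirical marginal ``q``-quantiles; a diagnostic
    companion to :func:`tail_dependence_upper`.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or sample.shape[1] != 2:
        raise ValueError("expected an (n, 2) sample")
    q1, q2 = np.quantile(sample, q, axis=0)
    tail2 = sample[:, 1] > q2
    if not tail2.any():
        raise ValueError("no exceedances at the requested level")
    return float(np.mean(sample[tail2, 0] > q1))


class CorrelatedSIPHModel:
    """Bivariate model with correlated gamma scalings.

    ``Theta_1 = (W_0 + G_1)/eta_1`` and ``Theta_2 = (W_0 + G_2)/eta_2`` with
    independent ``W_0 ~ Gamma(kappa_0, 1)``, ``G_i ~ Gamma(kappa_i, 1)``.
    Under the default normalization ``eta_i = kappa_0 + kappa_i`` each
    ``Theta_i`` has unit mean, variance ``1/eta_i`` and
    ``Corr(Theta_1, Theta_2) = kappa_0/sqrt(eta_1 eta_2)``.
    """

    def __init__(
        self,
        margins: Sequence[Margin],
        kappa0: float,
        kappa1: float,
        kappa2: float,
        eta1: Optional[float] = None,
        eta2: Optional[float] = None,
    ):
        if len(margins) != 2:
            raise ValueError("correlated scaling is implemented for d = 2")
        if kappa0 < 0 or kappa1 < 0 or kappa2 < 0:
            raise ValueError("kappa parameters must be nonnegative")
        if kappa0 + kappa1 <= 0 or kappa0 + kappa2 <= 0:
            raise ValueError("each margin needs a positive total gamma shape")
        self.margins: List[Margin] = [
            (ph if isinstance(ph, PHRepresentation) else PHRepresentation(*ph), it)
            for ph, it in margins
        ]
        self.kappa0 = float(kappa0)
        self.kappa1 = float(kappa1)
        self.kappa2 = float(kappa2)
        self.eta1 = float(eta1) if eta1 is not None else self.kappa0 + self.kappa1
        self.eta2 = float(eta2) if eta2 is not None else self.kappa0 + self.kappa2

    @property
    def d(self) -> int:
        return 2

    def theta_corr(self) -> float:
        """``Corr(Theta_1, Theta_2) = kappa_0 / sqrt(eta_1 eta_2)``."""
        return self.kappa0 / math.sqrt(self.eta1 * self.eta2)

    def _uargs(self, y) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] != 2:
            raise ValueError("expected 2 columns")
        u1 = self.margins[0][1].h_inv(y[:, 0]) / self.eta1
        u2 = self.margins[1][1].h_inv(y[:, 1]) / self.eta2
        return np.column_stack([u1, u2])

    def survival(self, y):
        """Joint survival as a product of three commuting matrix powers."""
        scalar = np.asarray(y).ndim == 1
        yv = np.atleast_2d(np.asarray(y, dtype=float))
        if np.any(yv < 0):
            raise ValueError("survival is defined for y >= 0 entrywise")
        u = self._uargs(yv)
        (ph1, _), (ph2, _) = self.margins
        p1, p2 = ph1.p, ph2.p
        I1, I2 = np.eye(p1), np.eye(p2)
        pik = np.kron(ph1.pi, ph2.pi)
        e = np.ones(p1 * p2)
        out = np.empty(len(yv))
        for r in range(len(yv)):
            A1 = np.kron(u[r, 0] * ph1.T, I2)
            A2 = np.kron(I1, u[r, 1] * ph2.T)
            resid = np.abs(A1 @ A2 - A2 @ A1).max()
            scale = max(1.0, np.abs(A1).max() * np.abs(A2).max())
            if resid > 1e-10 * scale:  # pragma: no cover - structural guarantee
                raise ArithmeticError("Kronecker factors failed to commute")
            G = np.eye(p1 * p2)
            for M, k in (
                (np.eye(p1 * p2) - A1 - A2, self.kappa0),
                (np.eye(p1 * p2) - A1, self.kappa1),
                (np.eye(p1 * p2) - A2, self.kappa2),
            ):
                if k > 0:
                    G = G @ mat_frac_power(M, k)
            out[r] = float(np.real(pik @ np.linalg.solve(G, e)))
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def _scalar_factors(self, u: np.ndarray):
        """Eigen-route ingredients shared by survival and density."""
        (ph1, _), (ph2, _) = self.margins
        l1, _, _, piV1, _, Vie1 = ph1.eig()
        l2, _, _, piV2, _, Vie2 = ph2.eig()
        w1 = piV1 * Vie1
        w2 = piV2 * Vie2
        a1 = np.multiply.outer(u[:, 0], l1)[:, :, None]  # (n, p1, 1)
        a2 = np.multiply.outer(u[:, 1], l2)[:, None, :]  # (n, 1, p2)
        P0 = 1.0 - a1 - a2
        P1 = 1.0 - a1
        P2 = 1.0 - a2
        return w1, w2, a1, a2, P0, P1, P2

    def density(self, y):
        """Closed-form joint density (mixed second derivative of survival)."""
        scalar = np.asarray(y).ndim == 1
        yv = np.atleast_2d(np.asarray(y, dtype=float))
        if np.any(yv <= 0):
            raise ValueError("density is defined for y > 0 entrywise")
        u = self._uargs(yv)
        w1, w2, a1, a2, P0, P1, P2 = self._scalar_factors(u)
        k0, k1, k2 = self.kappa0, self.kappa1, self.kappa2
        l1 = a1 / u[:, 0][:, None, None]
        l2 = a2 / u[:, 1][:, None, None]
        core = (
            k0 * (k0 + 1.0) * P0 ** (-k0 - 2) * P1 ** (-k1) * P2 ** (-k2)
            + k0 * k2 * P0 ** (-k0 - 1) * P1 ** (-k1) * P2 ** (-k2 - 1)
            + k0 * k1 * P0 ** (-k0 - 1) * P1 ** (-k1 - 1) * P2 ** (-k2)
            + k1 * k2 * P0 ** (-k0) * P1 ** (-k1 - 1) * P2 ** (-k2 - 1)
        )
        vals = np.einsum("i,j,nij->n", w1, w2, l1 * l2 * core).real
        pref = (
            self.margins[0][1].lam(yv[:, 0]) / self.eta1
            * self.margins[1][1].lam(yv[:, 1]) / self.eta2
        )
        vals = np.maximum(pref * vals, 0.0)
        return float(vals[0]) if scalar else vals

    def sample_scalings(self, n: int, rng) -> np.ndarray:
        w0 = rng.gamma(self.kappa0, 1.0, n) if self.kappa0 > 0 else np.zeros(n)
        g1 = rng.gamma(self.kappa1, 1.0, n) if self.kappa1 > 0 else np.zeros(n)
        g2 = rng.gamma(self.kappa2, 1.0, n) if self.kappa2 > 0 else np.zeros(n)
        return np.column_stack([(w0 + g1) / self.eta1, (w0 + g2) / self.eta2])

    def sample(self, n: int, seed=None, return_scalings: bool = False):
        """Rows ``(h_1(Z_1/Theta_1), h_2(Z_2/Theta_2))``."""
        rng = seed if isinstance(seed, np.random.Generator) else (
            np.random.default_rng(seed))
        theta = self.sample_scalings(n, rng)
        cols = []
        for i, (ph, intensity) in enumerate(self.margins):
            Z = ph.sample(n, rng)
            cols.append(intensity.h(Z / theta[:, i]))
        out = np.column_stack(cols)
        return (out, theta) if return_scalings else out

    def to_dict(self) -> dict:
        return {
            "margins": [
                {**ph.to_dict(), "intensity": it.to_dict()}
                for ph, it in self.margins
            ],
            "kappa": [self.kappa0, self.kappa1, self.kappa2],
            "eta": [self.eta1, self.eta2],
        }
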