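"""Univariate scaled inhomogeneous phase-type (SIPH) distributions.

A SIPH variable arises as the absorption time of a transient Markov jump
process whose intensity is modulated both deterministically (a baseline
intensity ``lambda(t)``) and randomly (a positive scaling ``Theta``, the
matrix analogue of a frailty).  Equivalently ``Y = h(Z / Theta)`` for
``Z ~ PH(pi, T)`` independent of ``Theta``, with ``h`` the time transform
associated with ``lambda``.  All functionals are matrix-analytic:

    S(y) = pi L_Theta(-h^{-1}(y) T) e
    f(y) = -lambda(y) pi L'_Theta(-h^{-1}(y) T) t

With covariates ``x`` and coefficients ``beta`` the argument ``h^{-1}(y)``
is multiplied by ``exp(beta x)`` (proportional intensities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .components import (
    Degenerate,
    GammaScaling,
    IntensityFamily,
    InverseGaussianScaling,
    InverseStable,
    PHRepresentation,
    PositiveStable,
    PVFScaling,
    ScalingFamily,
    WeibullIntensity,
)

__all__ = ["SIPHModel", "TailClass", "matrix_mittag_leffler"]

# Survival values below this threshold are reported as exact zeros (with the
# `underflow` diagnostic on the model); they are meaningless in double
# precision arithmetic anyway.
_UNDERFLOW = 1e-300


@dataclass(frozen=True)
class TailClass:
    """Qualitative tail behaviour of a SIPH law.

    ``label`` is one of ``slowly_varying``, ``regularly_varying``,
    ``weibull_type``, ``lognormal_type``, ``exponential``, ``gumbel``;
    ``index`` carries the regular-variation index where one exists.
    """

    label: str
    index: Optional[float] = None


class SIPHModel:
    """A scaled inhomogeneous phase-type model ``SIPH(pi, T, lambda, Theta)``.

    Parameters
    ----------
    ph : PHRepresentation
    intensity : IntensityFamily
    scaling : ScalingFamily
    beta : array_like, optional
        Regression coefficients; covariates act proportionally on the
        integrated intensity.  No intercept: a constant is not identifiable
        (it is absorbed by the scale of ``Theta``/``T``).
    """

    def __init__(
        self,
        ph: PHRepresentation,
        intensity: IntensityFamily,
        scaling: ScalingFamily,
        beta=None,
    ):
        self.ph = ph
        self.intensity = intensity
        self.scaling = scaling
        self.beta = None if beta is None else np.asarray(beta, dtype=float).ravel()
        self.underflow = False

    # -- helpers -----------------------------------------------------------
    def _risk(self, x):
        """``exp(beta x)`` per observation (1.0 without covariates)."""
        if self.beta is None:
            if x is not None:
                raise ValueError("model has no regression coefficients")
            return 1.0
        if x is None:
            raise ValueError("model expects covariates of length "
                             f"{self.beta.size}")
        x = np.asarray(x, dtype=float)
        return np.exp(x @ self.beta if x.ndim > 1 else float(self.beta @ x))

    def _uarg(self, y, x=None):
        y = np.asarray(y, dtype=float)
        return self.intensity.h_inv(y) * self._risk(x)

    def _eig_ok(self) -> bool:
        lam, V, *_ = self.ph.eig()
        c = np.linalg.cond(V)
        return np.isfinite(c) and c < 1e8 and _distinct(lam)

    # -- evaluation --------------------------------------------------------
    def survival(self, y, x=None):
        """``S(y) = pi L_Theta(-h^{-1}(y) e^{beta x} T) e``."""
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("survival is defined for y >= 0")
        u = self._uarg(y, x)
        if self._eig_ok():
            lam, _, _, piV, _, Vie = self.ph.eig()
            vals = np.einsum(
                "i,...i->...",
                piV * Vie,
                self.scaling._lap(np.multiply.outer(u, -lam)),
            ).real
        else:
            vals = _matrix_route(self, u, deriv=0)
        vals = np.asarray(vals)
        if np.any(vals < _UNDERFLOW):
            self.underflow = True
        out = np.clip(np.where(vals < _UNDERFLOW, 0.0, vals), 0.0, 1.0)
        return out if out.ndim else float(out)

    def density(self, y, x=None):
        """``f(y) = -lambda(y) e^{beta x} pi L'_Theta(-h^{-1}(y) e^{beta x} T) t``."""
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("density is defined for y > 0")
        u = self._uarg(y, x)
        if self._eig_ok():
            lam, _, _, piV, Vit, _ = self.ph.eig()
            vals = -np.einsum(
                "i,...i->...",
                piV * Vit,
                self.scaling._lap_deriv(np.multiply.outer(u, -lam), 1),
            ).real
        else:
            vals = -_matrix_route(self, u, deriv=1)
        pref = self.intensity.lam(y) * self._risk(x)
        out = np.maximum(np.asarray(pref * vals), 0.0)
        return out if out.ndim else float(out)

    def hazard(self, y, x=None):
        """Hazard ``mu(y) = f(y)/S(y)``; infinite where S underflows to 0."""
        S = np.asarray(self.survival(y, x))
        f = np.asarray(self.density(y, x))
        if np.any(S == 0.0):
            warnings.warn("survival underflowed to 0; hazard reported as inf",
                          RuntimeWarning, stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(S > 0.0, f / np.where(S > 0, S, 1.0), np.inf)
        return out if out.ndim else float(out)

    def cumulative_hazard(self, y, x=None):
        """``M(y) = -log S(y)``."""
        S = np.asarray(self.survival(y, x))
        if np.any(S == 0.0):
            warnings.warn("survival underflowed to 0; cumulative hazard inf",
                          RuntimeWarning, stacklevel=2)
        with np.errstate(divide="ignore"):
            out = -np.log(S)
        return out if out.ndim else float(out)

    # -- simulation --------------------------------------------------------
    def sample(self, n: int, seed=None, x=None) -> np.ndarray:
        """Draw ``n`` variates via ``Y = h(e^{-beta x} Z / Theta)``."""
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        Z = self.ph.sample(n, rng)
        theta = self.scaling.sample(n, rng)
        risk = self._risk(x)
        return self.intensity.h(Z / (theta * risk))

    # -- tail classification ------------------------------------------------
    def tail_class(self) -> TailClass:
        return tail_class(self.scaling, self.intensity)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            **self.ph.to_dict(),
            "intensity": self.intensity.to_dict(),
            "scaling": self.scaling.to_dict(),
        }
        d["beta"] = None if self.beta is None else self.beta.tolist()
        return d

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SIPHModel(p={self.ph.p}, intensity={self.intensity!r}, "
            f"scaling={self.scaling!r})"
        )


def _distinct(lam, rtol=1e-9) -> bool:
    scale = max(1.0, np.abs(lam).max())
    d = np.abs(lam[:, None] - lam[None, :])
    np.fill_diagonal(d, np.inf)
    return d.min() > rtol * scale


def _matrix_route(model: SIPHModel, u, deriv: int):
    """Per-point evaluation through the matrix functional calculus.

    Slow path used when the sub-intensity is defective or nearly so.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    ph = model.ph
    e = np.ones(ph.p)
    vec = ph.exit if deriv else e
    out = np.empty(u.shape)
    for idx in np.ndindex(u.shape):
        U = -u[idx] * ph.T
        M = (
            model.scaling.laplace_matrix(U)
            if deriv == 0
            else model.scaling.laplace_deriv_matrix(U, deriv)
        )
        out[idx] = np.real(ph.pi @ M @ vec)
    return out


def matrix_mittag_leffler(pi, T, alpha: float) -> SIPHModel:
    """Matrix Mittag-Leffler (fractional phase-type) law ``MML(alpha, pi, T)``.

    Equals ``(Z S_alpha^alpha)^{1/alpha}`` for ``Z ~ PH(pi, T)`` and an
    independent positive stable ``S_alpha``; realised here as the SIPH model
    with power time transform ``h(x) = x^{1/alpha}`` and inverse-stable
    scaling ``Theta = S_alpha^{-alpha}``.  The time-transform exponent and
    the mixing law share the parameter ``alpha`` -- the feature that makes
    this family's estimation special.
    """
    ph = pi if isinstance(pi, PHRepresentation) else PHRepresentation(pi, T)
    return SIPHModel(ph, WeibullIntensity(alpha), InverseStable(alpha))


# ---------------------------------------------------------------------------
# Tail classification lookup
# ---------------------------------------------------------------------------

def tail_class(scaling: ScalingFamily, intensity: IntensityFamily) -> TailClass:
    """Qualitative tail class of the SIPH law from (scaling, intensity).

    A metadata lookup of the first-order survival asymptotics: the scaling
    law fixes how ``S(y) ~ C * phi(h^{-1}(y))`` decays and the intensity
    fixes the growth of ``h^{-1}``.  Constants are never estimated.
    """
    fam = intensity.family
    if isinstance(scaling, GammaScaling):
        a = scaling.alpha
        if fam == "constant":
            return TailClass("regularly_varying", a)
        if fam == "weibull":
            return TailClass("regularly_varying", a * intensity.params[0])
        if fam in ("pareto", "lognormal", "loglogistic"):
            return TailClass("slowly_varying")
        if fam == "gompertz":
            return TailClass("exponential")
    elif isinstance(scaling, (PositiveStable, PVFScaling)):
        # PVF survival decays like the stable case with gamma in place of
        # the stability parameter.
        a = scaling.alpha if isinstance(scaling, PositiveStable) else scaling.gamma
        if fam in ("constant", "weibull"):
            return TailClass("weibull_type")
        if fam in ("pareto", "loglogistic"):
            return TailClass("slowly_varying")
        if fam == "lognormal":
            ae = a * intensity.params[0]
            if ae < 1.0:
                return TailClass("slowly_varying")
            if ae == 1.0:
                return TailClass("regularly_varying", 1.0)
            return TailClass("lognormal_type")
        if fam == "gompertz":
            return TailClass("gumbel")
    elif isinstance(scaling, InverseGaussianScaling):
        # decay exp(-b sqrt(h^{-1}(y))): square-root Weibull-type kernel
        if fam in ("constant", "weibull"):
            return TailClass("weibull_type")
        if fam in ("pareto", "loglogistic"):
            return TailClass("slowly_varying")
        if fam == "lognormal":
            eta = intensity.params[0]
            if eta < 2.0:
                return TailClass("slowly_varying")
            if eta == 2.0:
                return TailClass("regularly_varying", None)
            return TailClass("lognormal_type")
        if fam == "gompertz":
            return TailClass("gumbel")
    elif isinstance(scaling, Degenerate):
        raise ValueError(
            "degenerate scaling gives plain IPH tails; classification by "
            "scaling family does not apply"
        )
    raise ValueError(
        f"tail class not tabulated for scaling {scaling.family!r} with "
        f"intensity {intensity.family!r}"
    )
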