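"""Phase-solubility (Higuchi-Connors, A_L-type) analysis.

For a 1:1 guest-CD complex, the gain in dissolved guest concentration at CD
concentration [CD] is

    dS = Ks * S0 / (1 + Ks * S0) * [CD]

with S0 the intrinsic solubility (M) and Ks the stability constant (M^-1).
A linear phase diagram (total dissolved guest vs [CD]) therefore has slope
m = Ks*S0/(1+Ks*S0) in [0, 1) and intercept S0, and Ks is recovered as
m / (S0 * (1 - m)).  All concentrations are molar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class PhaseDiagram:
    """Measured (CD concentration, total dissolved guest) pairs, in M."""

    cd_concentrations: tuple
    total_solubility: tuple
    temperature: float = 25.0
    ph: float = 7.0

    def __post_init__(self):
        cd = np.asarray(self.cd_concentrations, dtype=float)
        tot = np.asarray(self.total_solubility, dtype=float)
        if cd.size != tot.size or np.unique(cd).size < 2:
            raise ValueError("a phase diagram needs >= 2 distinct CD concentrations")
        if np.any(cd < 0):
            raise ValueError("CD concentrations must be non-negative")


def delta_solubility(k_s: float, s_0: float, cd_conc) -> float | np.ndarray:
    """Solubility gain dS (M) of a 1:1 complex at CD concentration ``cd_conc``."""
    cd = np.asarray(cd_conc, dtype=float)
    if k_s < 0 or s_0 < 0 or np.any(cd < 0):
        raise ValueError("Ks, S0 and [CD] must be non-negative")
    out = (k_s * s_0) / (1.0 + k_s * s_0) * cd
    return float(out) if np.isscalar(cd_conc) else out


def ks_from_slope(slope: float, s_0: float) -> float:
    """Invert the A_L slope to the stability constant: Ks = m/(S0*(1-m))."""
    if not 0 <= slope < 1:
        raise ValueError(f"invalid_AL_slope: slope must be in [0, 1), got {slope}")
    if s_0 <= 0:
        raise ValueError("S0 must be positive")
    return slope / (s_0 * (1.0 - slope))


@dataclass(frozen=True)
class PhaseSolubilityFit:
    slope: float
    intercept: float  # S0 estimate (M) when s0 was not supplied
    s_0: float
    k_s: float
    ln_ks: float
    residual_se: float
    n_points: int


class PhaseSolubilityRegressor(BaseEstimator, RegressorMixin):
    """Least-squares A_L phase-diagram fit yielding Ks and ln(Ks).

    ``fit(X, y)`` takes CD concentrations (M, shape (n,) or (n,1)) and total
    dissolved guest concentrations (M).  The intrinsic solubility comes from
    the regression intercept by default; pass ``s0`` to override when the
    sampled concentration window is too narrow for a stable intercept.

    Attributes (after fit): ``slope_``, ``intercept_``, ``s0_``, ``ks_``,
    ``ln_ks_``, ``residual_se_``.
    """

    def __init__(self, s0: float | None = None):
        self.s0 = s0

    def fit(self, X, y):
        cd = np.asarray(X, dtype=float).reshape(-1)
        total = np.asarray(y, dtype=float).reshape(-1)
        if cd.size != total.size or cd.size < 2:
            raise ValueError("need >= 2 aligned (cd_conc, solubility) points")
        if np.any(cd < 0):
            raise ValueError("CD concentrations must be non-negative")
        if np.unique(cd).size < 2:
            raise ValueError("degenerate_design: all CD concentrations identical")
        res = stats.linregress(cd, total)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        s_0 = self.intercept_ if self.s0 is None else float(self.s0)
        if s_0 <= 0:
            raise ValueError(f"non-positive intrinsic solubility estimate ({s_0:.3e} M)")
        self.s0_ = s_0
        self.ks_ = ks_from_slope(self.slope_, s_0)
        self.ln_ks_ = float(np.log(self.ks_)) if self.ks_ > 0 else -np.inf
        resid = total - (self.intercept_ + self.slope_ * cd)
        dof = max(cd.size - 2, 1)
        self.residual_se_ = float(np.sqrt((resid**2).sum() / dof))
        self.n_points_ = int(cd.size)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * np.asarray(X, dtype=float).reshape(-1)

    def result_(self) -> PhaseSolubilityFit:
        check_is_fitted(self, "slope_")
        return PhaseSolubilityFit(
            slope=self.slope_, intercept=self.intercept_, s_0=self.s0_,
            k_s=self.ks_, ln_ks=self.ln_ks_, residual_se=self.residual_se_,
            n_points=self.n_points_,
        )


def fit_phase_diagram(diagram, total_solubility=None, s0: float | None = None) -> PhaseSolubilityFit:
    """OLS A_L fit of a phase diagram (thin wrapper over the regressor).

    Accepts either a :class:`PhaseDiagram` or two aligned arrays.
    ``s0=None`` estimates the intrinsic solubility from the intercept.
    """
    if isinstance(diagram, PhaseDiagram):
        cd, tot = diagram.cd_concentrations, diagram.total_solubility
    else:
        cd, tot = diagram, total_solubility
    return PhaseSolubilityRegressor(s0=s0).fit(cd, tot).result_()
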