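"""Global nonlinear regression of initial-rate grids to the two-substrate
Hill equation.

The estimation problem is multimodal and the maximal-rate parameter is
strongly correlated with the half-saturation constants, so the published
procedure fits in two stages: (1) a uni-substrate Hill fit of rate vs.
glycine at the highest benzoyl-CoA level yields the maximal activity,
which is then (2) held fixed in a global fit of the two-substrate equation
to every replicate point of the full grid.  An all-parameters-free global
fit and a Michaelis-Menten-constrained fit (both Hill coefficients pinned
at 1) are provided alongside, the latter feeding a nested-model
cooperativity test.

The public surface follows the Model/Results convention: build a
:class:`HillBisubstrateModel` from an initial-rate table, call ``fit`` and
inspect the returned :class:`HillFitResults` (estimates, standard errors,
covariance, residual diagnostics, ``summary()``).  Thin functional
wrappers (``fit_two_stage`` etc.) cover the same operations.

Least squares is unweighted, on untransformed rates, fitted to all
replicate points.  Each fit is multi-started from a deterministic base
guess plus seeded jitters; the restart with the lowest SSR wins, ties
broken by the lower benzoyl-CoA half-saturation constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConvergenceError, DesignError, ValidationError
from .kinetic_model import (
    DEFAULT_MOLAR_MASS,
    HillBisubstrateParams,
    specific_activity_to_kcat,
)

__all__ = [
    "PARAM_NAMES",
    "HillBisubstrateModel",
    "HillFitResults",
    "UnisubstrateFitResult",
    "CooperativityTest",
    "fit_stage1_kcat",
    "fit_stage2_global",
    "fit_two_stage",
    "fit_global_free",
    "cooperativity_test",
]

PARAM_NAMES = ("vf", "s05_gly", "h_gly", "s05_benz", "h_benz")

_H_BOUNDS = (0.5, 6.0)
_S05_BOUNDS = (1e-9, 1e9)
_MAX_NFEV = 2000
_FIT_TOL = 1e-12  # ftol/xtol/gtol handed to the trust-region solver
_TIE_REL = 1e-9   # SSR ties within this relative band -> tie-break rule


def _hill_rate(vf, s05_g, h_g, s05_b, h_b, G, B):
    xg = (G / s05_g) ** h_g
    xb = (B / s05_b) ** h_b
    return vf * (xg / (1.0 + xg)) * (xb / (1.0 + xb))


def _half_max_level(levels: np.ndarray, means: np.ndarray) -> float:
    """Substrate level at half the maximal observed mean rate (interpolated)."""
    order = np.argsort(levels)
    levels, means = levels[order], means[order]
    target = 0.5 * means.max()
    above = np.nonzero(means >= target)[0]
    if above.size == 0:
        return float(np.median(levels))
    j = above[0]
    if j == 0 or means[j] == means[j - 1]:
        return float(levels[j])
    frac = (target - means[j - 1]) / (means[j] - means[j - 1])
    return float(levels[j - 1] + frac * (levels[j] - levels[j - 1]))


@dataclass(frozen=True)
class UnisubstrateFitResult:
    """Stage-1 result: uni-substrate Hill fit at the top benzoyl-CoA level."""

    vmax: float
    s05: float
    h: float
    bse: dict
    ssr: float
    nobs: int
    benz_uM: float
    converged: bool
    n_starts_used: int

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.vmax, self.s05, self.h)


class HillFitResults:
    """Estimates and diagnostics of one global Hill-equation fit.

    Attributes
    ----------
    params : HillBisubstrateParams
        Point estimates (kcat derived from vf via the model's molar mass).
    bse : pandas.Series
        Standard errors per parameter; exactly 0 for held parameters.
    fixed : tuple of str
        Names of parameters held during optimisation.
    ssr : float
        Sum of squared residuals at the optimum.
    stage1 : UnisubstrateFitResult or None
        Provenance of the fixed maximal activity for two-stage fits.
    """

    def __init__(self, model, params, bse, cov, fixed, ssr, nobs,
                 n_starts_used, converged, method, stage1=None,
                 at_bounds=()):
        self.model = model
        self.params = params
        self.bse = bse
        self._cov = cov
        self.fixed = tuple(fixed)
        self.ssr = float(ssr)
        self.nobs = int(nobs)
        self.n_starts_used = int(n_starts_used)
        self.converged = bool(converged)
        self.method = method
        self.stage1 = stage1
        self.at_bounds = tuple(at_bounds)

    @property
    def n_params_free(self) -> int:
        return len(PARAM_NAMES) - len(self.fixed)

    @property
    def df_resid(self) -> int:
        return self.nobs - self.n_params_free

    @property
    def aic(self) -> float:
        """Gaussian AIC up to an additive constant: n ln(SSR/n) + 2k."""
        ssr = max(self.ssr, 1e-300)
        return self.nobs * math.log(ssr / self.nobs) + 2 * self.n_params_free

    def cov_params(self) -> pd.DataFrame:
        return self._cov.copy()

    def predict(self, gly_mM=None, benz_uM=None):
        p = self.params
        if gly_mM is None:
            gly_mM, benz_uM = self.model.G, self.model.B
        return _hill_rate(p.vf, p.s05_gly, p.h_gly, p.s05_benz, p.h_benz,
                          np.asarray(gly_mM, float), np.asarray(benz_uM, float))

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.predict()

    def param_series(self) -> pd.Series:
        p = self.params
        return pd.Series({name: getattr(p, name) for name in PARAM_NAMES})

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-substrate Hill fit".center(58),
            "=" * 58,
            f"haplotype: {p.label:<24s} method: {self.method}",
            f"n obs: {self.nobs:<6d} free params: {self.n_params_free}   "
            f"SSR: {self.ssr:.6g}",
            f"converged: {self.converged}   restarts used: "
            f"{self.n_starts_used}",
            "-" * 58,
            f"{'parameter':<10s}{'estimate':>12s}{'std err':>12s}"
            f"{'held':>8s}{'units':>14s}",
        ]
        units = {"vf": "umol/min/mg", "s05_gly": "mM", "h_gly": "-",
                 "s05_benz": "uM", "h_benz": "-"}
        for name in PARAM_NAMES:
            se = self.bse[name]
            se_str = f"{se:12.4g}" if np.isfinite(se) else f"{'n/a':>12s}"
            lines.append(
                f"{name:<10s}{getattr(p, name):12.4g}{se_str}"
                f"{'yes' if name in self.fixed else 'no':>8s}"
                f"{units[name]:>14s}"
            )
        lines.append(f"{'kcat':<10s}{p.kcat_effective:12.4g}{'':>12s}"
                     f"{'':>8s}{'1/s':>14s}")
        if self.at_bounds:
            lines.append(f"note: at bounds: {', '.join(self.at_bounds)}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "label": p.label,
            "method": self.method,
            "estimates": {name: getattr(p, name) for name in PARAM_NAMES},
            "kcat": p.kcat_effective,
            "molar_mass": p.molar_mass,
            "bse": {name: float(self.bse[name]) for name in PARAM_NAMES},
            "fixed": list(self.fixed),
            "ssr": self.ssr,
            "nobs": self.nobs,
            "n_params_free": self.n_params_free,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "at_bounds": list(self.at_bounds),
        }


@dataclass(frozen=True)
class CooperativityTest:
    """Nested comparison of the free Hill fit against h_gly = h_benz = 1."""

    free: HillFitResults
    constrained: HillFitResults
    ssr_ratio: float      # constrained SSR / free SSR (inf if free SSR ~ 0)
    f_stat: float
    p_value: float
    delta_aic: float      # AIC(constrained) - AIC(free); > 0 favours free

    @property
    def favoured(self) -> str:
        return "free" if self.delta_aic > 0 else "constrained"


class HillBisubstrateModel:
    """Two-substrate Hill regression model over an initial-rate table.

    Parameters
    ----------
    rates : pandas.DataFrame
        Initial-rate table with columns ``gly_mM``, ``benz_uM``, ``rate``
        (``replicate`` optional); all replicate points are fitted, not
        replicate means.
    molar_mass : float
        Subunit molar mass (g/mol) used to derive kcat from the fitted
        maximal specific activity.
    label : str
        Haplotype name attached to the fitted parameter set.
    """

    def __init__(self, rates: pd.DataFrame,
                 molar_mass: float = DEFAULT_MOLAR_MASS,
                 label: str = "haplotype"):
        if rates is None or len(rates) == 0:
            raise DesignError("empty initial-rate table")
        missing = {"gly_mM", "benz_uM", "rate"} - set(rates.columns)
        if missing:
            raise ValidationError(f"rate table lacks columns {sorted(missing)}")
        df = rates.loc[:, [c for c in ("gly_mM", "benz_uM", "replicate",
                                       "rate") if c in rates.columns]].copy()
        for col in ("gly_mM", "benz_uM", "rate"):
            df[col] = pd.to_numeric(df[col])
            if not np.all(np.isfinite(df[col])):
                raise ValidationError(f"non-finite values in column {col}")
        if (df["gly_mM"] <= 0).any() or (df["benz_uM"] <= 0).any():
            raise ValidationError("substrate levels must be positive")
        # canonical row order makes every estimate invariant to input order
        df = df.sort_values(list(df.columns), kind="mergesort",
                            ignore_index=True)
        self.data = df
        self.G = df["gly_mM"].to_numpy(float)
        self.B = df["benz_uM"].to_numpy(float)
        self.y = df["rate"].to_numpy(float)
        self.molar_mass = float(molar_mass)
        self.label = label

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HillBisubstrateModel":
        return cls(df, **kwargs)

    # -- design helpers ----------------------------------------------------
    @property
    def gly_levels(self) -> np.ndarray:
        return np.unique(self.G)

    @property
    def benz_levels(self) -> np.ndarray:
        return np.unique(self.B)

    def _require_grid(self, min_levels: int = 2) -> None:
        for name, levels in (("glycine", self.gly_levels),
                             ("benzoyl-CoA", self.benz_levels)):
            if levels.size < min_levels:
                raise DesignError(
                    f"only {levels.size} distinct {name} level(s); the "
                    f"global fit needs at least {min_levels} to be "
                    "identifiable"
                )

    def _require_signal(self) -> None:
        if not np.any(self.y > 0):
            raise ConvergenceError(
                "all rates are <= 0; Hill parameters are unidentifiable"
            )

    # -- initial guesses and restarts --------------------------------------
    def _base_guess(self) -> dict:
        vmax0 = 1.2 * float(self.y.max())
        at_top_b = self.B == self.B.max()
        gly_means = pd.Series(self.y[at_top_b]).groupby(
            pd.Series(self.G[at_top_b])).mean()
        at_top_g = self.G == self.G.max()
        benz_means = pd.Series(self.y[at_top_g]).groupby(
            pd.Series(self.B[at_top_g])).mean()
        return {
            "vf": vmax0,
            "s05_gly": _half_max_level(gly_means.index.to_numpy(float),
                                       gly_means.to_numpy(float)),
            "h_gly": 1.5,
            "s05_benz": _half_max_level(benz_means.index.to_numpy(float),
                                        benz_means.to_numpy(float)),
            "h_benz": 1.5,
        }

    @staticmethod
    def _jitter(base: dict, rng: np.random.Generator) -> dict:
        out = dict(base)
        for key in out:
            if key.startswith("s05"):
                out[key] = out[key] * 2.0 ** rng.uniform(-1.0, 1.0)
            elif key.startswith("h"):
                out[key] = float(np.clip(out[key] + rng.uniform(-0.5, 0.5),
                                         *_H_BOUNDS))
        return out

    # -- optimiser core ----------------------------------------------------
    def _minimize_multistart(self, make_params, residual, base, n_starts,
                             seed, tie_key):
        rng = np.random.default_rng(seed)
        starts = [base] + [self._jitter(base, rng) for _ in range(n_starts)]
        best = None
        n_used = 0
        errors = []
        for start in starts:
            try:
                result = lmfit.minimize(
                    residual, make_params(start), method="least_squares",
                    max_nfev=_MAX_NFEV, ftol=_FIT_TOL, xtol=_FIT_TOL,
                    gtol=_FIT_TOL,
                )
            except Exception as exc:  # singular jacobian etc.
                errors.append(str(exc))
                continue
            if not result.success:
                errors.append(getattr(result, "message", "solver failure"))
                continue
            n_used += 1
            if best is None:
                best = result
                continue
            if result.chisqr < best.chisqr * (1.0 - _TIE_REL):
                best = result
            elif (abs(result.chisqr - best.chisqr)
                  <= _TIE_REL * max(best.chisqr, 1e-300)
                  and tie_key(result) < tie_key(best)):
                best = result
        if best is None:
            raise ConvergenceError(
                "no restart converged; solver messages: "
                + "; ".join(sorted(set(errors))[:3])
            )
        return best, n_used

    # -- public fits --------------------------------------------------------
    def fit_stage1(self, n_starts: int = 5, seed: int = 0) -> UnisubstrateFitResult:
        """Uni-substrate Hill fit of rate vs. glycine at the top benzoyl-CoA
        level; the fitted plateau is the maximal activity fixed downstream.

        Note the plateau equals the true Vf only if the top benzoyl-CoA
        level is saturating; at a merely high level the estimate is biased
        low by that level's saturation fraction.
        """
        b_top = float(self.B.max())
        mask = self.B == b_top
        G, y = self.G[mask], self.y[mask]
        if np.unique(G).size < 4:
            raise DesignError(
                f"stage 1 needs >= 4 distinct glycine levels at the top "
                f"benzoyl-CoA level, got {np.unique(G).size}"
            )
        if not np.any(y > 0):
            raise ConvergenceError("all stage-1 rates are <= 0")

        gly_means = pd.Series(y).groupby(pd.Series(G)).mean()
        base = {
            "vmax": 1.2 * float(y.max()),
            "s05": _half_max_level(gly_means.index.to_numpy(float),
                                   gly_means.to_numpy(float)),
            "h": 1.5,
        }

        def make_params(start: dict) -> lmfit.Parameters:
            p = lmfit.Parameters()
            p.add("vmax", value=start["vmax"], min=1e-12)
            p.add("s05", value=start["s05"], min=_S05_BOUNDS[0],
                  max=_S05_BOUNDS[1])
            p.add("h", value=start["h"], min=_H_BOUNDS[0], max=_H_BOUNDS[1])
            return p

        def residual(p):
            x = (G / p["s05"].value) ** p["h"].value
            return p["vmax"].value * x / (1.0 + x) - y

        best, n_used = self._minimize_multistart(
            make_params, residual, base, n_starts, seed,
            tie_key=lambda r: r.params["s05"].value,
        )
        bse = {k: (best.params[k].stderr if best.params[k].stderr is not None
                   else math.nan) for k in ("vmax", "s05", "h")}
        return UnisubstrateFitResult(
            vmax=best.params["vmax"].value, s05=best.params["s05"].value,
            h=best.params["h"].value, bse=bse, ssr=best.chisqr,
            nobs=int(y.size), benz_uM=b_top, converged=True,
            n_starts_used=n_used,
        )

    def _fit_bisubstrate(self, fixed: dict, n_starts: int, seed: int,
                         method_name: str, stage1=None) -> HillFitResults:
        self._require_grid()
        self._require_signal()
        base = self._base_guess()
        base.update(fixed)
        G, B, y = self.G, self.B, self.y

        def make_params(start: dict) -> lmfit.Parameters:
            p = lmfit.Parameters()
            p.add("vf", value=start["vf"], min=1e-12, vary="vf" not in fixed)
            for sub in ("gly", "benz"):
                p.add(f"s05_{sub}", value=start[f"s05_{sub}"],
                      min=_S05_BOUNDS[0], max=_S05_BOUNDS[1],
                      vary=f"s05_{sub}" not in fixed)
                p.add(f"h_{sub}", value=start[f"h_{sub}"],
                      min=_H_BOUNDS[0], max=_H_BOUNDS[1],
                      vary=f"h_{sub}" not in fixed)
            return p

        def residual(p):
            return _hill_rate(p["vf"].value, p["s05_gly"].value,
                              p["h_gly"].value, p["s05_benz"].value,
                              p["h_benz"].value, G, B) - y

        best, n_used = self._minimize_multistart(
            make_params, residual, base, n_starts, seed,
            tie_key=lambda r: r.params["s05_benz"].value,
        )

        estimates = {k: best.params[k].value for k in PARAM_NAMES}
        params = HillBisubstrateParams(
            label=self.label, molar_mass=self.molar_mass, **estimates
        )
        bse = pd.Series({
            k: (0.0 if k in fixed else
                (best.params[k].stderr if best.params[k].stderr is not None
                 else math.nan))
            for k in PARAM_NAMES
        })
        cov = pd.DataFrame(0.0, index=list(PARAM_NAMES),
                           columns=list(PARAM_NAMES))
        if best.covar is not None:
            for i, ni in enumerate(best.var_names):
                for j, nj in enumerate(best.var_names):
                    cov.loc[ni, nj] = best.covar[i, j]
        at_bounds = []
        for k in PARAM_NAMES:
            par = best.params[k]
            if not par.vary:
                continue
            for edge in (par.min, par.max):
                if np.isfinite(edge) and abs(par.value - edge) \
                        <= 1e-3 * max(abs(edge), 1e-12):
                    at_bounds.append(k)
                    break
        return HillFitResults(
            model=self, params=params, bse=bse, cov=cov,
            fixed=tuple(sorted(fixed)), ssr=best.chisqr, nobs=y.size,
            n_starts_used=n_used, converged=True, method=method_name,
            stage1=stage1, at_bounds=at_bounds,
        )

    def fit(self, method: str = "two-stage", fix_vf: float | None = None,
            n_starts: int = 5, seed: int = 0) -> HillFitResults:
        """Fit the model.

        method is one of ``"two-stage"`` (stage-1 plateau fixed in a global
        stage-2 fit), ``"free"`` (all five parameters free), ``"stage2"``
        (global fit with ``fix_vf`` held), or ``"constrained"``
        (Michaelis-Menten form: both Hill coefficients fixed at 1).
        """
        if method == "two-stage":
            stage1 = self.fit_stage1(n_starts=n_starts, seed=seed)
            return self._fit_bisubstrate(
                {"vf": stage1.vmax}, n_starts, seed, "two-stage",
                stage1=stage1,
            )
        if method == "stage2":
            if fix_vf is None or fix_vf <= 0:
                raise ValidationError("stage2 requires a positive fix_vf")
            return self._fit_bisubstrate({"vf": float(fix_vf)}, n_starts,
                                         seed, "stage2")
        if method == "free":
            return self._fit_bisubstrate({}, n_starts, seed, "free")
        if method == "constrained":
            return self._fit_bisubstrate({"h_gly": 1.0, "h_benz": 1.0},
                                         n_starts, seed, "constrained")
        raise ValidationError(f"unknown fit method {method!r}")

    def cooperativity_test(self, n_starts: int = 5, seed: int = 0) -> CooperativityTest:
        """F-test / AIC comparison of cooperative vs. hyperbolic kinetics."""
        free = self.fit(method="free", n_starts=n_starts, seed=seed)
        constrained = self.fit(method="constrained", n_starts=n_starts,
                               seed=seed)
        df_diff = free.n_params_free - constrained.n_params_free
        df_resid = free.df_resid
        if free.ssr < 1e-30:
            ssr_ratio = math.inf
            f_stat = math.inf
            p_value = 0.0
        else:
            ssr_ratio = constrained.ssr / free.ssr
            f_stat = ((constrained.ssr - free.ssr) / df_diff) \
                / (free.ssr / df_resid)
            p_value = float(sps.f.sf(f_stat, df_diff, df_resid)) \
                if f_stat >= 0 else 1.0
        return CooperativityTest(
            free=free, constrained=constrained, ssr_ratio=ssr_ratio,
            f_stat=f_stat, p_value=p_value,
            delta_aic=constrained.aic - free.aic,
        )


# -- functional wrappers over the model class -------------------------------

def fit_stage1_kcat(rates: pd.DataFrame, molar_mass: float = DEFAULT_MOLAR_MASS,
                    label: str = "haplotype", n_starts: int = 5,
                    seed: int = 0) -> UnisubstrateFitResult:
    """Stage 1: maximal-activity estimate from the top benzoyl-CoA level."""
    model = HillBisubstrateModel(rates, molar_mass=molar_mass, label=label)
    return model.fit_stage1(n_starts=n_starts, seed=seed)


def fit_stage2_global(rates: pd.DataFrame, fixed_vf: float,
                      molar_mass: float = DEFAULT_MOLAR_MASS,
                      label: str = "haplotype", n_starts: int = 5,
                      seed: int = 0) -> HillFitResults:
    """Stage 2: global fit of the remaining parameters with vf held."""
    model = HillBisubstrateModel(rates, molar_mass=molar_mass, label=label)
    return model.fit(method="stage2", fix_vf=fixed_vf, n_starts=n_starts,
                     seed=seed)


def fit_two_stage(rates: pd.DataFrame, molar_mass: float = DEFAULT_MOLAR_MASS,
                  label: str = "haplotype", n_starts: int = 5,
                  seed: int = 0) -> HillFitResults:
    """The published two-stage procedure (stage 1 then stage 2)."""
    model = HillBisubstrateModel(rates, molar_mass=molar_mass, label=label)
    return model.fit(method="two-stage", n_starts=n_starts, seed=seed)


def fit_global_free(rates: pd.DataFrame, molar_mass: float = DEFAULT_MOLAR_MASS,
                    label: str = "haplotype", n_starts: int = 5,
                    seed: int = 0) -> HillFitResults:
    """Reference estimator with all five parameters free (multi-start)."""
    model = HillBisubstrateModel(rates, molar_mass=molar_mass, label=label)
    return model.fit(method="free", n_starts=n_starts, seed=seed)


def cooperativity_test(rates: pd.DataFrame,
                       molar_mass: float = DEFAULT_MOLAR_MASS,
                       label: str = "haplotype", n_starts: int = 5,
                       seed: int = 0) -> CooperativityTest:
    """Nested-model test of cooperative vs. Michaelis-Menten kinetics."""
    model = HillBisubstrateModel(rates, molar_mass=molar_mass, label=label)
    return model.cooperativity_test(n_starts=n_starts, seed=seed)
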