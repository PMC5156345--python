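"""Statistical models linking prey encounters to diving behaviour.

Five models are supported, all built from the per-dive covariate table
(and, for transit durations, the phase table):

* **1a / 1b** — bottom prey-encounter count ~ diving behaviours, negative
  binomial GLM with log link, ``log(bottom minutes)`` as offset (so the
  modelled quantity is a rate) and individual identities as fixed-effect
  intercepts; fitted separately on daytime and night-time dives;
* **2** — surface horizontal speed ~ diving behaviours, linear mixed
  model with a random intercept per individual;
* **3** — dive efficiency ~ diving behaviours, variable-dispersion beta
  regression (logit mean, log precision) with individual fixed intercepts;
* **4** — transit-phase duration ~ phase type x (maximum depth, swimming
  effort), linear mixed model with a random intercept per individual.

Selection is a backward AIC elimination from the full model followed by
per-covariate polynomial escalation (orthogonal polynomials on the
standardized covariates, degree capped at 4).  Mixed models use maximum
likelihood during selection and are refit by REML at the end.  Temporal
autocorrelation is addressed by one-in-ten thinning; collinearity by a
VIF < 5 screen.  Goodness of fit: deviance explained D2 (negative
binomial), Nakagawa marginal/conditional R2 (mixed models) and the squared
Pearson correlation between link-transformed observations and the linear
predictor (any family).

The public surface follows the Model / Results idiom: build a
:class:`DiveModel` from a dataframe, ``fit()`` it (or ``select()`` to run
the full selection procedure) and read estimates, uncertainties and
pseudo-R2 off the returned :class:`DiveModelResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial as _NegBin
from statsmodels.othermod.betareg import BetaModel as _BetaModel

log = logging.getLogger(__name__)

MAX_POLY_DEGREE = 4

#: diving-behaviour covariates shared by models 1a, 1b, 2 and 3
BEHAVIOUR_COVARIATES = [
    "bottom_median_depth_m", "bottom_vertical_extent_m",
    "pct_bottom_wiggle", "pct_bottom_step",
    "mean_pitch_descent_deg", "mean_pitch_ascent_deg",
    "var_pitch_bottom", "var_heading_bottom",
]


# --------------------------------------------------------------------------
# table preparation

def standardize_covariates(table: pd.DataFrame,
                           covariates: list[str]) -> tuple[pd.DataFrame, dict]:
    """Centre each covariate and scale to unit SD; zero-variance ones dropped.

    Returns the transformed table and a ``{name: (mean, sd)}`` record for
    back-transformation of effect plots (raw slope = standardized / sd).
    """
    out = table.copy()
    scaling = {}
    for c in covariates:
        mu = float(out[c].mean())
        sd = float(out[c].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"covariate {c!r} has zero variance; dropped")
            out = out.drop(columns=c)
            continue
        out[c] = (out[c] - mu) / sd
        scaling[c] = (mu, sd)
    return out, scaling


def thin_every_k(table: pd.DataFrame, k: int = 10,
                 group: str = "individual_id") -> pd.DataFrame:
    """Keep rows 1, k+1, 2k+1, ... per individual (temporal decorrelation)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if group in table.columns:
        keep = table.groupby(group, sort=False).cumcount() % k == 0
        return table[keep].reset_index(drop=True)
    return table.iloc[::k].reset_index(drop=True)


def vif_screen(table: pd.DataFrame, covariates: list[str]) -> pd.Series:
    """Variance inflation factor per covariate (1 / (1 - R2_j)).

    Warns (does not fail) when any VIF >= 5; perfect collinearity reports
    infinity.
    """
    if len(covariates) < 2:
        raise ValueError("VIF needs at least 2 covariates")
    out = {}
    for c in covariates:
        others = [o for o in covariates if o != c]
        X = sm.add_constant(table[others].to_numpy(dtype=float))
        y = table[c].to_numpy(dtype=float)
        r2 = sm.OLS(y, X).fit().rsquared
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="VIF")
    high = s[s >= 5]
    if len(high):
        warnings.warn(f"VIF >= 5 for {list(high.index)}")
    return s


def orthopoly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthogonal polynomial basis (columns 1..degree), R ``poly()`` style
    but with each column rescaled to unit sample SD so coefficients stay on
    the per-SD scale of the (standardized) covariates."""
    x = np.asarray(x, dtype=float)
    v = np.vander(x - x.mean(), degree + 1, increasing=True)
    q, r = np.linalg.qr(v)
    q = q[:, 1:degree + 1].copy()
    sign = np.sign(np.diag(r)[1:degree + 1])
    sign[sign == 0] = 1.0
    q *= sign
    return q / q.std(axis=0)


# --------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model.

    ``covariates`` maps covariate name to polynomial degree.  ``offset``
    names a column whose log enters with coefficient fixed at 1 (negative
    binomial only).  ``interaction_factor`` names a two-level column whose
    indicator interacts with every covariate (transit-duration model);
    interactions can be dropped term-wise during selection via
    ``interactions`` (subset of covariate names).
    """

    family: str                                  # negbin | lmm | beta | gaussian
    response: str
    covariates: dict[str, int]
    offset: str | None = None
    groups: str | None = None                    # random-intercept column (lmm)
    individual_intercepts: str | None = None     # fixed-intercept column (negbin/beta)
    interaction_factor: str | None = None
    interactions: tuple[str, ...] = ()
    precision_covariates: tuple[str, ...] | None = None   # beta; None = mean covariates

    def __post_init__(self) -> None:
        if self.family not in ("negbin", "lmm", "beta", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if (self.offset is not None) != (self.family == "negbin"):
            raise ValueError("an offset is required for negbin and only negbin")
        if any(d < 1 for d in self.covariates.values()):
            raise ValueError("polynomial degrees must be >= 1")

    def drop(self, term: str) -> "ModelSpec":
        """Spec with one term removed (covariate or 'factor:covariate')."""
        if ":" in term:
            c = term.split(":", 1)[1]
            return replace(self, interactions=tuple(i for i in self.interactions if i != c))
        cov = {k: v for k, v in self.covariates.items() if k != term}
        inter = tuple(i for i in self.interactions if i != term)
        return replace(self, covariates=cov, interactions=inter)

    def terms(self) -> list[str]:
        """Droppable terms, interactions before their main effects."""
        t = [f"{self.interaction_factor}:{c}" for c in self.interactions]
        t += [c for c in self.covariates if c not in self.interactions]
        return t


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix: intercept, orthogonal-poly blocks, dummies, interactions."""
    n = len(data)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    if spec.interaction_factor is not None:
        levels = sorted(data[spec.interaction_factor].unique())
        if len(levels) != 2:
            raise ValueError("interaction factor must have exactly 2 levels")
        z = (data[spec.interaction_factor] == levels[1]).to_numpy(dtype=float)
        cols[f"{spec.interaction_factor}[{levels[1]}]"] = z
    for c, d in spec.covariates.items():
        if d == 1:          # linear terms enter raw (covariates are pre-standardized)
            p = data[c].to_numpy(dtype=float)[:, None]
        else:
            p = orthopoly(data[c].to_numpy(), d)
        for j in range(d):
            cols[f"{c}.{j + 1}" if d > 1 else c] = p[:, j]
        if spec.interaction_factor is not None and c in spec.interactions:
            for j in range(d):
                name = f"{spec.interaction_factor}:{c}" + (f".{j + 1}" if d > 1 else "")
                cols[name] = z * p[:, j]
    if spec.individual_intercepts is not None:
        ids = pd.Categorical(data[spec.individual_intercepts])
        for lev in ids.categories[1:]:
            cols[f"id[{lev}]"] = (np.asarray(ids) == lev).astype(float)
    return pd.DataFrame(cols, index=data.index)


# --------------------------------------------------------------------------
# results object

@dataclass
class DiveModelResults:
    """Estimates, uncertainties and diagnostics of one fitted model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    aic: float
    nobs: int
    linear_predictor: np.ndarray
    fitted_mean: np.ndarray
    theta: float | None = None                 # negbin dispersion
    null_deviance: float | None = None
    resid_deviance: float | None = None
    sigma2_random: float | None = None         # lmm variance components
    sigma2_residual: float | None = None
    precision_params: pd.Series | None = None  # beta precision submodel
    reml: bool = False
    selection_trace: list = field(default_factory=list)
    _data: pd.DataFrame | None = field(default=None, repr=False)

    # ---- goodness of fit -------------------------------------------------
    def deviance_explained(self) -> float:
        """D2 = 1 - residual/null deviance, as a percentage."""
        if self.null_deviance is None:
            raise ValueError("deviance explained is defined for negbin fits")
        if self.null_deviance <= 0:
            warnings.warn("null deviance is zero; D2 undefined")
            return float("nan")
        return 100.0 * (1.0 - self.resid_deviance / self.null_deviance)

    def nakagawa_r2(self) -> tuple[float, float]:
        """(marginal, conditional) variance explained of a mixed model."""
        if self.sigma2_random is None:
            raise ValueError("Nakagawa R2 is defined for mixed-model fits")
        s_f = float(np.var(self.linear_predictor))
        denom = s_f + self.sigma2_random + self.sigma2_residual
        return s_f / denom, (s_f + self.sigma2_random) / denom

    def pearson2(self) -> float:
        """Squared Pearson correlation of link(observed) with the linear predictor.

        Zero counts receive a half-count continuity adjustment before the
        log transform (logged).
        """
        y = self._data[self.spec.response].to_numpy(dtype=float)
        if self.spec.family == "negbin":
            nz = y == 0
            if nz.any():
                log.info("pearson2: %d zero counts adjusted to 0.5", int(nz.sum()))
            obs = np.log(np.where(nz, 0.5, y))
        elif self.spec.family == "beta":
            obs = np.log(y / (1.0 - y))
        else:
            obs = y
        lp = self.linear_predictor
        if np.std(obs) == 0 or np.std(lp) == 0:
            warnings.warn("pearson2 undefined: zero variance")
            return float("nan")
        r = np.corrcoef(obs, lp)[0, 1]
        return float(r * r)

    def summary(self) -> str:
        lines = [f"DiveModel ({self.spec.family}), response {self.spec.response!r}, "
                 f"n = {self.nobs}",
                 f"logLik = {self.llf:.2f}   AIC = {self.aic:.2f}"
                 + ("   (REML)" if self.reml else ""),
                 f"{'term':<32}{'coef':>12}{'se':>12}"]
        for name in self.params.index:
            lines.append(f"{name:<32}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        if self.theta is not None:
            lines.append(f"dispersion theta = {self.theta:.3f}")
        if self.sigma2_random is not None:
            lines.append(f"sigma2_random = {self.sigma2_random:.4f}   "
                         f"sigma2_residual = {self.sigma2_residual:.4f}")
            r2m, r2c = self.nakagawa_r2()
            lines.append(f"R2m = {r2m:.3f}   R2c = {r2c:.3f}")
        if self.null_deviance is not None:
            lines.append(f"D2 = {self.deviance_explained():.1f}%")
        if self.precision_params is not None:
            lines.append("precision submodel (log link): "
                         + ", ".join(f"{k}={v:.3f}"
                                     for k, v in self.precision_params.items()))
        return "\n".join(lines)


# --------------------------------------------------------------------------
# the model object

class DiveModel:
    """A model specification bound to a dive (or phase) table.

    Use :meth:`fit` for a single fit of the spec as given, or
    :meth:`select` for the full procedure (backward AIC, polynomial
    escalation, REML refit for mixed models).
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        need = [spec.response, *spec.covariates]
        if spec.offset:
            need.append(spec.offset)
        missing = [c for c in need if c not in data.columns]
        if missing:
            raise ValueError(f"table lacks columns {missing}")
        data = data.dropna(subset=need).reset_index(drop=True)
        if spec.family == "negbin":
            y = data[spec.response].to_numpy()
            if not np.allclose(y, np.round(y)):
                raise ValueError("negative-binomial response must be integer counts")
        if spec.family == "beta":
            y = data[spec.response].to_numpy(dtype=float)
            if np.any((y <= 0) | (y >= 1)):
                raise ValueError("beta response must lie strictly in (0, 1); "
                                 "check dive-efficiency flags")
        self.spec = spec
        self.data = data

    # ---- constructors for the five standard models -----------------------
    @classmethod
    def pee_rate(cls, dive_table: pd.DataFrame, daynight: str | None = None,
                 degrees: dict[str, int] | None = None) -> "DiveModel":
        """Models 1a/1b: bottom PEE count, NB GLM, log-exposure offset."""
        tbl = dive_table
        if daynight is not None:
            tbl = tbl[tbl["daynight"] == daynight]
        cov = {c: (degrees or {}).get(c, 1) for c in BEHAVIOUR_COVARIATES}
        many = tbl["individual_id"].nunique() > 1
        spec = ModelSpec("negbin", "bottom_pee_count", cov,
                         offset="bottom_duration_min",
                         individual_intercepts="individual_id" if many else None)
        return cls(spec, tbl)

    @classmethod
    def surface_speed(cls, dive_table: pd.DataFrame,
                      degrees: dict[str, int] | None = None) -> "DiveModel":
        """Model 2: surface horizontal speed, LMM with individual intercepts."""
        cov = {c: (degrees or {}).get(c, 1) for c in BEHAVIOUR_COVARIATES}
        spec = ModelSpec("lmm", "surface_speed_m_s", cov, groups="individual_id")
        return cls(spec, dive_table)

    @classmethod
    def efficiency(cls, dive_table: pd.DataFrame,
                   degrees: dict[str, int] | None = None) -> "DiveModel":
        """Model 3: dive efficiency, variable-dispersion beta regression."""
        cov = {c: (degrees or {}).get(c, 1) for c in BEHAVIOUR_COVARIATES}
        many = dive_table["individual_id"].nunique() > 1
        spec = ModelSpec("beta", "dive_efficiency", cov,
                         individual_intercepts="individual_id" if many else None)
        return cls(spec, dive_table)

    @classmethod
    def transit_duration(cls, phase_table: pd.DataFrame,
                         degrees: dict[str, int] | None = None) -> "DiveModel":
        """Model 4: transit duration ~ phase type x (depth, effort), LMM."""
        cov = {c: (degrees or {}).get(c, 1) for c in ("max_depth_m", "mean_effort")}
        spec = ModelSpec("lmm", "duration_s", cov, groups="individual_id",
                         interaction_factor="phase",
                         interactions=tuple(cov))
        return cls(spec, phase_table)

    # ---- fitting ---------------------------------------------------------
    def _offset(self) -> np.ndarray | None:
        if self.spec.offset is None:
            return None
        return np.log(self.data[self.spec.offset].to_numpy(dtype=float))

    def fit(self, reml: bool = False, spec: ModelSpec | None = None) -> DiveModelResults:
        spec = spec or self.spec
        data = self.data
        X = build_design(data, spec)
        y = data[spec.response].to_numpy(dtype=float)
        offset = self._offset()

        if spec.family == "negbin":
            res = _NegBin(y, X, offset=offset).fit(disp=0, maxiter=500)
            alpha = max(float(np.asarray(res.params)[-1]), 1e-10)
            theta = 1.0 / alpha
            lp = X.to_numpy() @ np.asarray(res.params)[:-1] + offset
            mu = np.exp(lp)
            out = DiveModelResults(
                spec, pd.Series(np.asarray(res.params)[:-1], index=X.columns),
                pd.Series(np.asarray(res.bse)[:-1], index=X.columns),
                float(res.llf), float(res.aic), len(y), lp, mu, theta=theta,
                resid_deviance=_nb_deviance(y, mu, theta),
                null_deviance=_nb_null_deviance(y, offset, theta), _data=data)
            return out

        if spec.family == "gaussian":
            res = sm.OLS(y, X).fit()
            lp = res.fittedvalues.to_numpy() if hasattr(res.fittedvalues, "to_numpy") \
                else np.asarray(res.fittedvalues)
            return DiveModelResults(
                spec, pd.Series(res.params, index=X.columns),
                pd.Series(res.bse, index=X.columns),
                float(res.llf), float(res.aic), len(y), lp, lp, _data=data)

        if spec.family == "lmm":
            groups = data[spec.groups]
            mod = sm.MixedLM(y, X, groups=groups)
            res = None
            # BFGS can hit a singular Hessian when the random-intercept
            # variance sits on the boundary; fall back to derivative-free
            for method in (None, "powell", "nm", "cg"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = (mod.fit(reml=reml) if method is None
                               else mod.fit(reml=reml, method=method, maxiter=2000))
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    break
            if res is None:
                raise RuntimeError("mixed model failed to fit with any optimizer")
            s2_u = float(np.asarray(res.cov_re)[0, 0])
            s2_e = float(res.scale)
            if s2_u < 1e-10:
                warnings.warn("singular random-intercept variance; retained at ~0")
            k = X.shape[1] + 2     # fixed effects + random-intercept var + residual var
            lp = X.to_numpy() @ np.asarray(res.fe_params)
            return DiveModelResults(
                spec, pd.Series(np.asarray(res.fe_params), index=X.columns),
                pd.Series(np.asarray(res.bse_fe), index=X.columns),
                float(res.llf), 2.0 * k - 2.0 * float(res.llf), len(y), lp, lp,
                sigma2_random=s2_u, sigma2_residual=s2_e, reml=reml, _data=data)

        # variable-dispersion beta regression
        prec_cov = spec.precision_covariates
        if prec_cov is None:
            prec_cov = tuple(spec.covariates)
        zcols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
        for c in prec_cov:
            zcols[c] = data[c].to_numpy(dtype=float)
        Z = pd.DataFrame(zcols, index=data.index)
        mod = _BetaModel(y, X, exog_precision=Z,
                         link_precision=sm.families.links.Log())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(disp=0)
        kx = X.shape[1]
        pvec = np.asarray(res.params)
        params = pd.Series(pvec[:kx], index=X.columns)
        lp = X.to_numpy() @ params.to_numpy()
        mu = 1.0 / (1.0 + np.exp(-lp))
        return DiveModelResults(
            spec, params, pd.Series(np.asarray(res.bse)[:kx], index=X.columns),
            float(res.llf), float(res.aic), len(y), lp, mu,
            precision_params=pd.Series(pvec[kx:], index=Z.columns),
            _data=data)

    # ---- selection procedure --------------------------------------------
    def _aic(self, spec: ModelSpec) -> float | None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return self.fit(spec=spec).aic
        except Exception as exc:          # non-convergence: candidate skipped
            log.warning("candidate fit failed (%s); skipped", exc)
            return None

    def stepwise_aic(self, spec: ModelSpec | None = None,
                     trace: list | None = None) -> ModelSpec:
        """Backward elimination: drop the term lowering AIC most, repeat."""
        spec = spec or self.spec
        current = self._aic(spec)
        if current is None:
            raise RuntimeError("full model failed to fit")
        if trace is not None:
            trace.append(("start", None, current))
        while True:
            best_term, best_aic = None, None
            for term in spec.terms():      # later-listed term wins AIC ties
                cand = self._aic(spec.drop(term))
                if cand is not None and cand < current and \
                        (best_aic is None or cand <= best_aic):
                    best_term, best_aic = term, cand
            if best_term is None:
                return spec
            spec, current = spec.drop(best_term), best_aic
            if trace is not None:
                trace.append(("drop", best_term, current))

    def polynomial_escalation(self, spec: ModelSpec,
                              trace: list | None = None) -> ModelSpec:
        """Raise each retained covariate's degree while AIC improves (cap 4)."""
        current = self._aic(spec)
        for c in list(spec.covariates):
            while spec.covariates[c] < MAX_POLY_DEGREE:
                cand_spec = replace(spec, covariates={**spec.covariates,
                                                      c: spec.covariates[c] + 1})
                cand = self._aic(cand_spec)
                if cand is None or cand >= current:
                    break
                spec, current = cand_spec, cand
                if trace is not None:
                    trace.append(("degree", f"{c}^{spec.covariates[c]}", current))
        return spec

    def select(self) -> DiveModelResults:
        """Backward AIC, then polynomial escalation, then final (REML) fit."""
        trace: list = []
        spec = self.stepwise_aic(trace=trace)
        spec = self.polynomial_escalation(spec, trace=trace)
        res = self.fit(reml=(spec.family == "lmm"), spec=spec)
        res.selection_trace = trace
        return res

    def per_covariate_nde(self, selected: DiveModelResults) -> pd.Series:
        """Null-deviance explained attributable to each covariate (single-term
        deletion from the selected negative-binomial model), in percent."""
        if selected.spec.family != "negbin":
            raise ValueError("NDE is defined for negative-binomial fits")
        d2_full = selected.deviance_explained()
        out = {}
        for c in selected.spec.covariates:
            res = self.fit(spec=selected.spec.drop(c))
            out[c] = d2_full - res.deviance_explained()
        return pd.Series(out, name="NDE_%")


# --------------------------------------------------------------------------
# negative-binomial deviance helpers

def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 deviance at dispersion theta (y log y/mu term vanishes at y=0)."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def _nb_null_deviance(y: np.ndarray, offset: np.ndarray, theta: float) -> float:
    """Deviance of the intercept(+offset) model at the same dispersion."""
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, np.ones((len(y), 1)), family=fam, offset=offset).fit()
    return float(res.deviance)


# --------------------------------------------------------------------------
# diagnostics

def residual_acf_report(residuals: np.ndarray, individuals: np.ndarray,
                        max_lag: int = 20) -> pd.DataFrame:
    """Per-individual residual autocorrelation at lags 0..max_lag.

    Columns: individual, lag, acf, bound (the +/-2/sqrt(n) reference).
    Report only; no automated rejection.
    """
    resid = np.asarray(residuals, dtype=float)
    ind = np.asarray(individuals)
    rows = []
    for g in pd.unique(ind):
        r = resid[ind == g]
        n = r.shape[0]
        r = r - r.mean()
        denom = np.sum(r * r)
        for lag in range(0, min(max_lag, n - 1) + 1):
            ac = 1.0 if lag == 0 else float(np.sum(r[lag:] * r[:-lag]) / denom)
            rows.append({"individual": g, "lag": lag, "acf": ac,
                         "bound": 2.0 / np.sqrt(n)})
    return pd.DataFrame(rows, columns=["individual", "lag", "acf", "bound"])
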