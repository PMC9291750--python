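"""Statistical stage: who disperses, how, how far and at what age.

The classified per-calf dispersal records feed four kinds of models:

* sex differences in dispersal propensity and type, as logistic regressions
  with a natal-community random intercept (``RandomInterceptLogit``, fitted
  by adaptive Gauss-Hermite quadrature);
* the four-level dispersal-type outcome (none / social / spatial /
  social-and-spatial, reference "none") as a multinomial logit
  (``DispersalTypeModel``); exponentiated coefficients are relative risk
  ratios;
* dispersal distance and age as Gaussian linear models (``fit_linear``);
* Welch t and Wilcoxon rank-sum comparisons (``compare_groups``).

Model sets are ranked with the small-sample Akaike information criterion,
AICc = -2*ll + 2k + 2k(k+1)/(n-k-1), and Akaike weights.  Continuous
covariates are standardised internally for numerical stability and the
coefficients reported back on the covariate's original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.api import MNLogit, OLS, Logit
from statsmodels.tools import numdiff

__all__ = [
    "aicc",
    "select_potential_dispersers",
    "RandomInterceptLogit",
    "RandomInterceptLogitResults",
    "DispersalTypeModel",
    "DispersalTypeResults",
    "fit_linear",
    "rank_models",
    "candidate_model_set",
    "fit_model_set",
    "compare_groups",
    "GroupComparison",
    "summarize_types",
    "TypeSummary",
]


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return float(-2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1))


# ---------------------------------------------------------------------------
# inclusion filter

def select_potential_dispersers(
    detections: pd.DataFrame,
    birth_years,
    interval_length: int = 3,
) -> list:
    """Calves with enough resight history to detect natal dispersal.

    Included individuals were (a) first sighted as calves in one of the
    ``birth_years`` and (b) detected at least once in every rolling
    ``interval_length``-year interval covering the study span (e.g. for a
    2012-2018 study with 3-year intervals: 2012-2014 through 2016-2018).
    """
    d = detections.sort_values(["id", "occasion"])
    first = d.groupby("id").first()
    calves = first.index[
        (first["age_class"] == "calf") & first["year"].isin(list(birth_years))
    ]
    years = sorted(detections["year"].unique())
    y0, y1 = years[0], years[-1]
    intervals = [
        (s, s + interval_length - 1) for s in range(y0, y1 - interval_length + 2)
    ]
    years_by_id = detections.groupby("id")["year"].agg(set)
    out = []
    for cid in calves:
        ys = years_by_id[cid]
        if all(any(a <= y <= b for y in ys) for a, b in intervals):
            out.append(cid)
    if not out:
        warnings.warn("inclusion filter selected no potential dispersers")
    return sorted(out)


# ---------------------------------------------------------------------------
# design-matrix construction shared by the regression models

def _expand_terms(predictors):
    """Resolve interaction shorthand: 'a*b' -> a, b and a:b."""
    terms = []
    for p in predictors:
        if "*" in p:
            a, b = [s.strip() for s in p.split("*")]
            for t in (a, b, f"{a}:{b}"):
                if t not in terms:
                    terms.append(t)
        elif p not in terms:
            terms.append(p)
    return terms


def _column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term == "sex":
        return (data["sex"] == "M").to_numpy(dtype=float)
    return data[term].to_numpy(dtype=float)


def build_design(data: pd.DataFrame, predictors) -> pd.DataFrame:
    """Design matrix with intercept; 'sex' becomes a male dummy ``sexM``;
    'a:b' / 'a*b' denote interactions."""
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for term in _expand_terms(predictors):
        if ":" in term:
            a, b = term.split(":")
            name = f"{'sexM' if a == 'sex' else a}:{'sexM' if b == 'sex' else b}"
            X[name] = _column(data, a) * _column(data, b)
        else:
            X["sexM" if term == "sex" else term] = _column(data, term)
    return X


class _Standardizer:
    """Column-wise z-scaling of a design matrix (constant and binary columns
    pass through), with the exact linear map back to the raw scale."""

    def __init__(self, X: pd.DataFrame):
        self.columns = list(X.columns)
        self.mean = {}
        self.scale = {}
        for c in self.columns:
            v = X[c].to_numpy()
            if c == "const" or set(np.unique(v)) <= {0.0, 1.0}:
                self.mean[c], self.scale[c] = 0.0, 1.0
            else:
                s = v.std(ddof=1)
                self.mean[c] = float(v.mean())
                self.scale[c] = float(s) if s > 0 else 1.0

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = X.copy()
        for c in self.columns:
            Z[c] = (Z[c] - self.mean[c]) / self.scale[c]
        return Z

    def unscale_matrix(self) -> np.ndarray:
        """T with beta_raw = T @ beta_std (intercept absorbs the centring)."""
        p = len(self.columns)
        T = np.zeros((p, p))
        for i, c in enumerate(self.columns):
            T[i, i] = 1.0 / self.scale[c]
        i0 = self.columns.index("const")
        for i, c in enumerate(self.columns):
            if c != "const":
                T[i0, i] = -self.mean[c] / self.scale[c]
        T[i0, i0] = 1.0
        return T


# ---------------------------------------------------------------------------
# random-intercept logistic regression (adaptive Gauss-Hermite quadrature)

class RandomInterceptLogit:
    """Logistic regression with a Gaussian random intercept per group.

    y_ij ~ Bernoulli(logit^-1(x_ij' beta + b_i)), b_i ~ N(0, sigma^2).
    The marginal likelihood integrates b_i out per group with adaptive
    Gauss-Hermite quadrature (nodes recentred at each group's posterior mode
    and rescaled by its curvature), and (beta, log sigma) are maximised
    jointly.  Use ``from_dataframe`` for the usual records + column-names
    entry point; ``fit`` returns :class:`RandomInterceptLogitResults`.
    """

    def __init__(self, endog, exog, groups, exog_names=None, n_quad: int = 15):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        self.groups = codes
        self.n_groups = len(self.group_labels)
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if self.endog.min() == self.endog.max():
            raise ValueError("response has no variation")
        z, w = special.roots_hermite(n_quad)
        self._qz, self._qw = z, w
        self._rows = [np.flatnonzero(self.groups == g) for g in range(self.n_groups)]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors, group: str,
                       n_quad: int = 15) -> "RandomInterceptLogit":
        X = build_design(data, predictors)
        return cls(
            data[response].to_numpy(dtype=float), X.to_numpy(),
            data[group].to_numpy(), exog_names=list(X.columns), n_quad=n_quad,
        )

    def _group_loglike(self, eta0, y, sigma):
        """log integral for one group given fixed-effect part eta0."""

        def g(b):
            eta = eta0 + b
            return float(
                np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * b * b / sigma**2
            )

        # posterior mode by Newton
        b = 0.0
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
            g1 = np.sum(y - p) - b / sigma**2
            g2 = -np.sum(p * (1 - p)) - 1.0 / sigma**2
            step = g1 / g2
            b -= step
            if abs(step) < 1e-10:
                break
        tau = 1.0 / np.sqrt(-g2)
        nodes = b + np.sqrt(2.0) * tau * self._qz
        vals = np.array([g(bk) for bk in nodes]) + self._qz**2
        log_int = special.logsumexp(vals + np.log(self._qw)) + 0.5 * np.log(2.0) + np.log(tau)
        return log_int - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)

    def loglike(self, params) -> float:
        beta = params[:-1]
        sigma = float(np.exp(params[-1]))
        eta = self.exog @ beta
        return float(
            sum(
                self._group_loglike(eta[r], self.endog[r], sigma)
                for r in self._rows
            )
        )

    def fit(self, start=None, penalty: float = 0.0) -> "RandomInterceptLogitResults":
        p = self.exog.shape[1]

        def nll(params):
            out = -self.loglike(params)
            if penalty > 0:
                out += penalty * np.sum(params[:-1] ** 2)
            return out

        if start is None:
            start = np.zeros(p + 1)
            start[-1] = np.log(0.5)
        res = optimize.minimize(
            nll, start, method="L-BFGS-B",
            bounds=[(None, None)] * p + [(-7.0, 3.0)],
        )
        separation = bool(np.any(np.abs(res.x[:p]) > 12.0)) or not res.success
        if separation and penalty == 0.0:
            # ridge fallback for (quasi-)separated data
            out = self.fit(start=start, penalty=1e-2)
            out.separation = True
            return out
        hess = numdiff.approx_hess1(res.x, nll)
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p + 1, np.nan)
        return RandomInterceptLogitResults(
            model=self,
            params=res.x[:p],
            bse=se[:p],
            sigma=float(np.exp(res.x[-1])),
            sigma_se=float(se[-1] * np.exp(res.x[-1])),  # delta method
            llf=float(self.loglike(res.x)),
            k_params=p + 1,
            nobs=len(self.endog),
            converged=bool(res.success),
            separation=separation and penalty > 0.0,
        )


@dataclass
class RandomInterceptLogitResults:
    """Estimates from :class:`RandomInterceptLogit`."""

    model: RandomInterceptLogit
    params: np.ndarray
    bse: np.ndarray
    sigma: float
    sigma_se: float
    llf: float
    k_params: int
    nobs: int
    converged: bool = True
    separation: bool = False

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    @property
    def aicc(self):
        return aicc(self.llf, self.k_params, self.nobs)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-intercept logistic regression (adaptive Gauss-Hermite)",
            f"n = {self.nobs}, groups = {self.model.n_groups}, "
            f"logLik = {self.llf:.3f}, AICc = {self.aicc:.3f}",
            f"{'term':<14}{'coef':>9}{'SE':>8}{'z':>8}{'p':>9}{'2.5%':>9}{'97.5%':>9}",
        ]
        for j, name in enumerate(self.model.exog_names):
            lines.append(
                f"{name:<14}{self.params[j]:>9.3f}{self.bse[j]:>8.3f}"
                f"{self.zvalues[j]:>8.2f}{self.pvalues[j]:>9.3g}"
                f"{ci[j, 0]:>9.3f}{ci[j, 1]:>9.3f}"
            )
        lines.append(f"random-intercept SD = {self.sigma:.3f}")
        if self.separation:
            lines.append("warning: separation detected; ridge-penalised fit")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# multinomial dispersal-type model

class DispersalTypeModel:
    """Multinomial logit for the four-level dispersal outcome.

    The reference level is "none"; the coefficients of the other levels are
    log odds versus not dispersing, and their exponents are relative risk
    ratios.  Continuous covariates are standardised internally and reported
    back-transformed.  ``fit`` returns :class:`DispersalTypeResults`.
    """

    def __init__(self, records: pd.DataFrame, predictors,
                 response: str = "dispersal_class", reference: str = "none"):
        self.records = records.reset_index(drop=True)
        self.predictors = list(predictors)
        self.response = response
        self.reference = reference
        y = self.records[response]
        present = [c for c in y.unique()]
        if reference not in present:
            raise ValueError(f"reference level {reference!r} absent from response")
        order = ["none", "social", "spatial", "social-and-spatial"]
        others = [c for c in order if c in present and c != reference]
        others += sorted(set(present) - set(order) - {reference})
        expected = set(order)
        empty = expected - set(present)
        if empty:
            warnings.warn(f"structural zero: empty outcome categories {sorted(empty)} dropped")
        self.categories = [reference] + others
        self._codes = y.map({c: i for i, c in enumerate(self.categories)}).to_numpy()
        X = build_design(self.records, self.predictors)
        self._std = _Standardizer(X)
        self._X = X
        self.exog_names = list(X.columns)

    @classmethod
    def from_dataframe(cls, records, predictors, **kw) -> "DispersalTypeModel":
        return cls(records, predictors, **kw)

    def fit(self, maxiter: int = 500) -> "DispersalTypeResults":
        Z = self._std.transform(self._X).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_res = MNLogit(self._codes, Z).fit(
                method="bfgs", maxiter=maxiter, disp=0, gtol=1e-7
            )
        K = Z.shape[1]
        J = len(self.categories)
        T = self._std.unscale_matrix()
        params = T @ np.asarray(sm_res.params)  # (K, J-1)
        converged = bool(sm_res.mle_retvals.get("converged", True))
        try:
            cov_std = np.asarray(sm_res.cov_params())  # ((J-1)K, (J-1)K)
            TT = np.kron(np.eye(J - 1), T)
            cov = TT @ cov_std @ TT.T
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(J - 1, K).T
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("singular information matrix; standard errors unavailable")
            bse = np.full((K, J - 1), np.nan)
            converged = False
        out_cols = self.categories[1:]
        return DispersalTypeResults(
            model=self,
            params=pd.DataFrame(params, index=self.exog_names, columns=out_cols),
            bse=pd.DataFrame(bse, index=self.exog_names, columns=out_cols),
            llf=float(sm_res.llf),
            k_params=int((J - 1) * K),
            nobs=len(self._codes),
            converged=converged,
            _params_std=np.asarray(sm_res.params),
        )

    def _probabilities(self, data: pd.DataFrame, params_std: np.ndarray) -> np.ndarray:
        X = build_design(data, self.predictors)
        Z = self._std.transform(X).to_numpy()
        eta = np.column_stack([np.zeros(len(Z)), Z @ params_std])
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class DispersalTypeResults:
    """Fitted multinomial dispersal-type model."""

    model: DispersalTypeModel
    params: pd.DataFrame  # terms x outcome categories (minus reference)
    bse: pd.DataFrame
    llf: float
    k_params: int
    nobs: int
    converged: bool = True
    _params_std: np.ndarray = field(default=None, repr=False)

    @property
    def zvalues(self) -> pd.DataFrame:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.DataFrame:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())) * pd.DataFrame(
            1.0, index=self.params.index, columns=self.params.columns
        )

    @property
    def rrr(self) -> pd.DataFrame:
        """Relative risk ratios: exponentiated coefficients."""
        return np.exp(self.params)

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k_params, self.nobs)

    def predicted_probabilities(
        self, focal: str, grid, by: str = "sex"
    ) -> pd.DataFrame:
        """Observed-value-averaged predicted probabilities along a covariate.

        For each grid value, the focal covariate is set to that value for
        every observed record, the four class probabilities are computed and
        averaged within each level of ``by`` (default: sex).  Probabilities
        sum to one at every grid point.
        """
        data = self.model.records
        if focal in data.columns:
            lo, hi = data[focal].min(), data[focal].max()
            if np.min(grid) < lo or np.max(grid) > hi:
                warnings.warn(f"grid extends beyond observed range of {focal}")
        rows = []
        for g in grid:
            mod = data.copy()
            if focal in mod.columns:
                mod[focal] = g
            p = self.model._probabilities(mod, self._params_std)
            for level, idx in mod.groupby(by).groups.items():
                pos = mod.index.get_indexer(idx)
                mean_p = p[pos].mean(axis=0)
                row = {focal: g, by: level}
                row.update(dict(zip(self.model.categories, mean_p)))
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multinomial dispersal-type model (reference level = "
            f"{self.model.reference!r})",
            f"n = {self.nobs}, k = {self.k_params}, logLik = {self.llf:.3f}, "
            f"AICc = {self.aicc:.3f}",
        ]
        z = self.zvalues
        p = self.pvalues
        for out in self.params.columns:
            lines.append(f"-- {out}")
            lines.append(f"{'term':<16}{'coef':>9}{'SE':>8}{'z':>8}{'p':>9}{'RRR':>9}")
            for term in self.params.index:
                lines.append(
                    f"{term:<16}{self.params.loc[term, out]:>9.3f}"
                    f"{self.bse.loc[term, out]:>8.3f}{z.loc[term, out]:>8.2f}"
                    f"{p.loc[term, out]:>9.3g}{np.exp(self.params.loc[term, out]):>9.3f}"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Gaussian linear models for dispersal distance and age

@dataclass
class LinearModelResults:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    llf: float
    k_params: int
    nobs: int
    rsquared_adj: float

    @property
    def aicc(self):
        return aicc(self.llf, self.k_params, self.nobs)

    def summary(self) -> str:
        lines = [
            f"Gaussian linear model: n = {self.nobs}, adj R^2 = "
            f"{self.rsquared_adj:.3f}, AICc = {self.aicc:.3f}",
            f"{'term':<16}{'coef':>9}{'SE':>8}{'t':>8}{'p':>9}",
        ]
        for term in self.params.index:
            lines.append(
                f"{term:<16}{self.params[term]:>9.3f}{self.bse[term]:>8.3f}"
                f"{self.tvalues[term]:>8.2f}{self.pvalues[term]:>9.3g}"
            )
        return "\n".join(lines)


def fit_linear(records: pd.DataFrame, response: str, predictors) -> LinearModelResults:
    """OLS fit of a continuous response (distance km, age months).

    The AICc parameter count includes the residual variance.
    """
    X = build_design(records, predictors)
    res = OLS(records[response].to_numpy(dtype=float), X.to_numpy()).fit()
    names = list(X.columns)
    return LinearModelResults(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        llf=float(res.llf),
        k_params=len(names) + 1,
        nobs=int(res.nobs),
        rsquared_adj=float(res.rsquared_adj),
    )


# ---------------------------------------------------------------------------
# model-set construction and AICc ranking

#: the four community covariates considered alongside sex
COVARIATES = ("forage", "dist_town", "dist_boma", "density")


def candidate_model_set() -> list:
    """The 20 a priori model structures: a null model, each covariate alone,
    sex plus each covariate, two sex interactions, all covariate pairs, and
    two three-term models.  Pairs whose covariates are correlated |r| > 0.5
    in the data at hand are dropped at fit time."""
    specs = [("null", [])]
    specs += [(c, [c]) for c in ("sex",) + COVARIATES]
    specs += [(f"sex+{c}", ["sex", c]) for c in COVARIATES]
    specs += [("sex*dist_town", ["sex*dist_town"]), ("sex*density", ["sex*density"])]
    pairs = [
        (a, b)
        for i, a in enumerate(COVARIATES)
        for b in COVARIATES[i + 1:]
    ]
    specs += [(f"{a}+{b}", [a, b]) for a, b in pairs]
    specs += [
        ("sex+dist_town+dist_boma", ["sex", "dist_town", "dist_boma"]),
        ("sex+forage+density", ["sex", "forage", "density"]),
    ]
    return specs


def _correlated_pair(records, predictors, r_max=0.5):
    numeric = [
        t for t in _expand_terms(predictors) if t != "sex" and ":" not in t
    ]
    for i, a in enumerate(numeric):
        for b in numeric[i + 1:]:
            r = np.corrcoef(records[a], records[b])[0, 1]
            if abs(r) > r_max:
                return a, b, r
    return None


def fit_model_set(records: pd.DataFrame, fitter, specs=None, r_max: float = 0.5) -> dict:
    """Fit a set of model structures with ``fitter(records, predictors)``.

    Specs containing a covariate pair correlated beyond ``r_max`` are
    dropped with a warning, mirroring the rule that highly correlated
    variables never enter the same model.
    """
    if specs is None:
        specs = candidate_model_set()
    fits = {}
    for name, predictors in specs:
        bad = _correlated_pair(records, predictors, r_max)
        if bad:
            warnings.warn(
                f"model {name!r} dropped: |r({bad[0]}, {bad[1]})| = {abs(bad[2]):.2f} > {r_max}"
            )
            continue
        fits[name] = fitter(records, predictors)
    return fits


def rank_models(fits: dict) -> pd.DataFrame:
    """AICc ranking table with delta-AICc and Akaike weights.

    All fits must share the same number of observations.
    """
    if not fits:
        raise ValueError("no fitted models to rank")
    ns = {f.nobs for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"models fitted on differing n: {sorted(ns)}")
    rows = [
        {"model": name, "k": f.k_params, "loglik": f.llf, "aicc": f.aicc}
        for name, f in fits.items()
    ]
    tab = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    rel = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = rel / rel.sum()
    return tab


# ---------------------------------------------------------------------------
# two-sample utilities

@dataclass
class GroupComparison:
    method: str
    statistic: float
    pvalue: float
    df: float | None = None


def compare_groups(x, y, method: str = "welch_t") -> GroupComparison:
    """Welch two-sample t test or Wilcoxon rank-sum test.

    Welch uses the Satterthwaite degrees of freedom; the rank-sum test uses
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if method == "welch_t":
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        res = stats.ttest_ind(x, y, equal_var=False)
        return GroupComparison("welch_t", float(res.statistic), float(res.pvalue),
                               df=float(res.df))
    if method == "wilcoxon":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# summary table over classified records

_CLASS_ORDER = ["none", "social", "spatial", "social-and-spatial"]


@dataclass
class TypeSummary:
    """Per-sex dispersal-class summary (counts, proportions, distances)."""

    counts: pd.DataFrame
    proportions: pd.DataFrame
    mean_final_km: pd.DataFrame
    mean_max_km: pd.DataFrame
    dispersed: pd.DataFrame
    share_among_dispersers: pd.DataFrame

    def summary(self) -> str:
        out = ["Counts (proportion within sex):"]
        for sex in self.counts.index:
            cells = [
                f"{cls}: {int(self.counts.loc[sex, cls])} "
                f"({self.proportions.loc[sex, cls]:.2f})"
                for cls in self.counts.columns
            ]
            out.append(f"  {sex}  " + "  ".join(cells))
        out.append("Dispersed:")
        for sex in self.dispersed.index:
            r = self.dispersed.loc[sex]
            out.append(
                f"  {sex}  {int(r['n_dispersed'])}/{int(r['n_total'])} "
                f"({100 * r['fraction']:.0f}%)"
            )
        return "\n".join(out)


def summarize_types(records: pd.DataFrame) -> TypeSummary:
    """Summary arithmetic over classified records.

    ``records`` needs ``sex`` and ``dispersal_class`` columns; ``final_km``
    and ``max_km`` are summarised when present.  Reports per-sex class
    counts and within-sex proportions, the dispersed fraction, each class's
    share among dispersers, and mean final / maximum distances per class.
    """
    classes = list(_CLASS_ORDER)
    classes += sorted(set(records["dispersal_class"]) - set(_CLASS_ORDER))
    sexes = sorted(records["sex"].unique())
    counts = (
        records.groupby(["sex", "dispersal_class"]).size()
        .unstack(fill_value=0)
        .reindex(index=sexes, columns=classes, fill_value=0)
    )
    totals = counts.sum(axis=1)
    proportions = counts.div(totals, axis=0).fillna(0.0)
    dispersed_n = totals - counts.get("none", 0)
    dispersed = pd.DataFrame(
        {
            "n_total": totals,
            "n_dispersed": dispersed_n,
            "fraction": (dispersed_n / totals).fillna(0.0),
        }
    )
    disp_counts = counts.drop(columns=["none"], errors="ignore")
    share = disp_counts.div(dispersed_n.replace(0, np.nan), axis=0).fillna(0.0)

    def _mean(col):
        if col not in records.columns:
            return pd.DataFrame(index=sexes, columns=classes, dtype=float)
        return (
            records.groupby(["sex", "dispersal_class"])[col].mean()
            .unstack()
            .reindex(index=sexes, columns=classes)
        )

    return TypeSummary(
        counts=counts,
        proportions=proportions,
        mean_final_km=_mean("final_km"),
        mean_max_km=_mean("max_km"),
        dispersed=dispersed,
        share_among_dispersers=share,
    )
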