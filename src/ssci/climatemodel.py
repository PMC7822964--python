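"""Climate–structure model selection on site tables.

All-subsets regression of a structural response (typically site-mean SSCI)
on climate and soil covariates, the way it is usually done in macroecology:

* candidate models are every non-empty predictor subset whose pairwise
  Pearson correlations stay below an |r| threshold (default 0.7) —
  collinear combinations are never fitted;
* each candidate is fitted as an OLS model and, optionally, as a linear
  mixed model with a biome random intercept (estimated by maximum
  likelihood so that AICc values are comparable across fixed-effect
  structures);
* a model is *rejected* when any predictor is non-significant at the
  configured level (default p < 0.05);
* surviving fits are ranked by AICc (small-sample-corrected Akaike
  criterion), and each carries RMSE and residual Moran's I diagnostics.

The public surface follows the statsmodels idiom:
``StructureClimateModel.from_dataframe(...).fit()`` returns a
:class:`StructureClimateResults` with the ranking table, ``summary()``,
leave-one-out cross-validation and biome-exclusion robustness checks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .geo import pairwise_haversine_km

OLS_FORM = "ols"
LMM_FORM = "lmm_biome_intercept"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response ~ predictors, fitted as ``form``."""

    response: str
    predictors: tuple[str, ...]
    form: str = OLS_FORM

    def __post_init__(self):
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")
        if self.form not in (OLS_FORM, LMM_FORM):
            raise ValueError(f"unknown model form {self.form!r}")


@dataclass
class ModelFit:
    """A fitted candidate model with its selection statistics."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    loglik: float
    k: int
    n: int
    aicc: float
    rmse: float
    rejected: bool
    delta_aicc: float = np.nan
    morans_i: float | None = None
    morans_p: float | None = None
    residuals: np.ndarray | None = None

    @property
    def label(self) -> str:
        return f"{'lme' if self.spec.form == LMM_FORM else 'lm'}: " + \
            " + ".join(self.spec.predictors)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 ln L + 2k + 2k(k+1)/(n-k-1); k counts every estimated
    parameter including the residual (and any random-effect) variance."""
    if n <= k + 1:
        raise ValueError("AICc needs n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def candidate_models(
    predictor_pool,
    table: pd.DataFrame,
    r_threshold: float = 0.7,
    response: str = "ssci",
    forms=(OLS_FORM,),
) -> list[ModelSpec]:
    """All non-empty predictor subsets free of collinearity.

    A subset survives when every pairwise Pearson |r| among its members
    (computed over the sites in ``table``) is strictly below ``r_threshold``.
    """
    pool = list(predictor_pool)
    if not pool:
        raise ValueError("predictor pool is empty")
    corr = table[pool].corr().abs()
    specs = []
    for size in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, size):
            ok = all(
                corr.loc[a, b] < r_threshold
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                for form in forms:
                    specs.append(ModelSpec(response, combo, form))
    return specs


def fit_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "biome",
) -> ModelFit:
    """Fit one candidate model by OLS or biome-random-intercept LMM (ML).

    The fit is flagged ``rejected`` when any predictor's p-value is >= alpha.
    For the mixed model, R^2 is the squared correlation between fitted
    (fixed + random) and observed values.
    """
    y = table[spec.response].to_numpy(dtype=float)
    X = table[list(spec.predictors)].to_numpy(dtype=float)
    n = len(y)
    for j, name in enumerate(spec.predictors):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
    p = len(spec.predictors)
    k = p + 2 if spec.form == OLS_FORM else p + 3
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 sites to fit {spec}")
    exog = sm.add_constant(pd.DataFrame(X, columns=list(spec.predictors)))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("rank-deficient design matrix")

    if spec.form == OLS_FORM:
        res = sm.OLS(y, exog).fit()
        fitted = res.fittedvalues.to_numpy()
        r2 = float(res.rsquared)
        loglik = float(res.llf)
        params, bse, pvalues = res.params, res.bse, res.pvalues
    else:
        if group_col not in table:
            raise ValueError(f"mixed model needs a {group_col!r} column")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            mod = sm.MixedLM(y, exog, groups=table[group_col].to_numpy())
            res = mod.fit(reml=False)
        fe = res.fe_params
        re = res.random_effects
        groups = table[group_col].to_numpy()
        fitted = exog.to_numpy() @ fe.to_numpy() + np.array(
            [float(np.asarray(re[g]).ravel()[0]) for g in groups]
        )
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        loglik = float(res.llf)
        params = fe
        bse = res.bse.loc[fe.index]
        pvalues = res.pvalues.loc[fe.index]

    resid = y - fitted
    pred_p = pd.Series(pvalues, index=params.index).drop("const", errors="ignore")
    rejected = bool((pred_p >= alpha).any() or pred_p.isna().any())
    return ModelFit(
        spec=spec,
        params=pd.Series(params),
        bse=pd.Series(bse),
        pvalues=pd.Series(pvalues),
        r2=r2,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        rejected=rejected,
        residuals=resid,
    )


def rank_models(fits: list[ModelFit]) -> tuple[list[ModelFit], list[ModelFit]]:
    """Sort non-rejected fits by ascending AICc and set their delta AICc.

    Returns ``(ranked, rejected)``; raises when every fit was rejected.
    """
    kept = [f for f in fits if not f.rejected]
    rejected = [f for f in fits if f.rejected]
    if not kept:
        labels = ", ".join(f.label for f in rejected)
        raise ValueError(f"all candidate models were rejected: {labels}")
    ranked = sorted(kept, key=lambda f: f.aicc)
    best = ranked[0].aicc
    ranked = [replace(f, delta_aicc=f.aicc - best) for f in ranked]
    return ranked, rejected


def morans_i(
    residuals,
    lons,
    lats,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Moran's I of residuals with inverse great-circle-distance weights.

    ``I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
    with ``w_ij = 1 / d_ij`` (km), zero diagonal, not row-standardized.
    The p-value is a two-sided permutation test with a fixed seed;
    coincident sites get their weight capped at the largest finite weight
    (with a warning).
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Moran's I needs at least 4 sites")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant residuals")
    d = pairwise_haversine_km(lons, lats)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        warnings.warn("coincident sites: capping their weights", stacklevel=2)
    with np.errstate(divide="ignore"):
        w = np.where(off, 1.0 / d, 0.0)
    finite = np.isfinite(w)
    if not np.all(finite):
        w[~finite] = w[finite & off].max() if np.any(finite & off) else 1.0
    w_sum = w.sum()

    def stat(v):
        dev = v - v.mean(axis=-1, keepdims=True)
        num = np.einsum("...i,ij,...j->...", dev, w, dev)
        return (n / w_sum) * num / np.einsum("...i,...i->...", dev, dev)

    i_obs = float(stat(x))
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    perms = stat(x[idx])
    p_hi = (1 + np.sum(perms >= i_obs)) / (n_permutations + 1)
    p_lo = (1 + np.sum(perms <= i_obs)) / (n_permutations + 1)
    return i_obs, float(min(1.0, 2.0 * min(p_hi, p_lo)))


def loocv(
    spec: ModelSpec,
    table: pd.DataFrame,
    alpha: float = 1.0,
    r2_method: str = "corr",
) -> tuple[float, float]:
    """Leave-one-out cross-validation of one model.

    Each site is predicted from a refit on the remaining sites.  Returns
    ``(rmse, r2)`` over held-out predictions; ``r2_method`` is ``"corr"``
    (squared Pearson correlation, the common cross-validation report) or
    ``"ss"`` (1 - SSE/SST).
    """
    n = len(table)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 sites")
    preds = np.empty(n)
    obs = table[spec.response].to_numpy(dtype=float)
    for i in range(n):
        train = table.drop(table.index[i])
        held = table.iloc[[i]]
        try:
            fit = fit_model(spec, train, alpha=alpha)
        except Exception as exc:
            raise RuntimeError(f"LOOCV refit failed on fold {i}: {exc}") from exc
        preds[i] = predict(fit, held)[0]
    resid = obs - preds
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if r2_method == "corr":
        r2 = float(np.corrcoef(preds, obs)[0, 1] ** 2)
    elif r2_method == "ss":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return rmse, r2


def predict(fit: ModelFit, table: pd.DataFrame, group_col: str = "biome"):
    """Predict the response for new sites from a fitted candidate model.

    Mixed-model predictions add the estimated biome intercept when the
    biome was present at fit time (population-level otherwise — here the
    random effects are not retained, so predictions are fixed-effects only)."""
    X = sm.add_constant(
        table[list(fit.spec.predictors)].astype(float), has_constant="add"
    )
    return X.to_numpy() @ fit.params.to_numpy()


def biome_exclusion(
    spec: ModelSpec,
    table: pd.DataFrame,
    group_col: str = "biome",
) -> pd.DataFrame:
    """Refit once per biome with that biome's sites held out entirely.

    Returns one row per biome present: the refit R^2 and RMSE on the
    remaining sites, the number excluded, and whether the refit was
    possible (small remainders are reported as not evaluable)."""
    if group_col not in table:
        raise ValueError(f"table has no {group_col!r} column")
    biomes = sorted(table[group_col].unique())
    if len(biomes) < 2:
        raise ValueError("biome exclusion needs at least 2 biomes")
    rows = []
    for b in biomes:
        rest = table[table[group_col] != b]
        row = {"biome": b, "n_excluded": int((table[group_col] == b).sum())}
        try:
            fit = fit_model(spec, rest, alpha=1.0)
            row.update(r2=fit.r2, rmse=fit.rmse, evaluable=True)
        except ValueError:
            row.update(r2=np.nan, rmse=np.nan, evaluable=False)
        rows.append(row)
    return pd.DataFrame(rows)


class StructureClimateModel:
    """All-subsets climate–structure model selection on a site table.

    Parameters
    ----------
    data : DataFrame
        One row per site with the response, the candidate predictors, and
        optionally ``lon``/``lat`` (for residual Moran's I) and ``biome``
        (for mixed models and biome exclusion).
    response : str
        Response column, default ``"ssci"``.
    predictors : sequence of str
        Candidate predictor pool.
    forms : sequence of str
        Model forms to fit; defaults to OLS plus the biome-intercept mixed
        model when a ``biome`` column is present.
    r_threshold : float
        Collinearity screen: subsets with any pairwise |r| >= threshold are
        never fitted.
    alpha : float
        Significance level of the predictor rejection rule.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors,
        response: str = "ssci",
        forms=None,
        r_threshold: float = 0.7,
        alpha: float = 0.05,
    ):
        self.data = data.reset_index(drop=True)
        self.response = response
        self.predictors = list(predictors)
        if forms is None:
            forms = (OLS_FORM, LMM_FORM) if "biome" in data else (OLS_FORM,)
        self.forms = tuple(forms)
        self.r_threshold = r_threshold
        self.alpha = alpha
        missing = [c for c in [response, *self.predictors] if c not in data]
        if missing:
            raise ValueError(f"missing columns: {missing}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, predictors, **kwargs):
        return cls(data, predictors, **kwargs)

    @classmethod
    def from_csv(cls, path, predictors, **kwargs):
        return cls(pd.read_csv(path), predictors, **kwargs)

    def fit(self, n_permutations: int = 999, seed: int = 0) -> "StructureClimateResults":
        """Fit and rank every collinearity-free candidate model."""
        specs = candidate_models(
            self.predictors, self.data, r_threshold=self.r_threshold,
            response=self.response, forms=self.forms,
        )
        fits = [fit_model(s, self.data, alpha=self.alpha) for s in specs]
        ranked, rejected = rank_models(fits)
        if "lon" in self.data and "lat" in self.data and len(self.data) >= 4:
            lons = self.data["lon"].to_numpy()
            lats = self.data["lat"].to_numpy()
            for f in ranked:
                f.morans_i, f.morans_p = morans_i(
                    f.residuals, lons, lats,
                    n_permutations=n_permutations, seed=seed,
                )
        return StructureClimateResults(self, ranked, rejected)


class StructureClimateResults:
    """Ranked model-selection results of :class:`StructureClimateModel`."""

    def __init__(self, model, ranked, rejected):
        self.model = model
        self.fits = ranked
        self.rejected = rejected

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    @property
    def table(self) -> pd.DataFrame:
        """Ranking table: one row per surviving model, ascending AICc."""
        return pd.DataFrame(
            {
                "form": ["lme" if f.spec.form == LMM_FORM else "lm"
                         for f in self.fits],
                "predictors": [" + ".join(f.spec.predictors) for f in self.fits],
                "r2": [f.r2 for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta_aicc": [f.delta_aicc for f in self.fits],
                "rmse": [f.rmse for f in self.fits],
                "morans_i": [f.morans_i for f in self.fits],
            }
        )

    def loocv(self, fit: ModelFit | None = None) -> tuple[float, float]:
        """Leave-one-out cross-validation of (by default) the best model."""
        spec = (fit or self.best).spec
        return loocv(spec, self.model.data)

    def biome_exclusion(self, fit: ModelFit | None = None) -> pd.DataFrame:
        spec = (fit or self.best).spec
        return biome_exclusion(spec, self.model.data)

    def summary(self) -> str:
        best = self.best
        lines = [
            "Climate-structure model selection",
            "=" * 70,
            f"response: {self.model.response}    sites: {best.n}    "
            f"candidates: {len(self.fits) + len(self.rejected)} "
            f"({len(self.rejected)} rejected)",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
            ),
            "",
            f"best model: {best.label}",
            "coefficients (SE):",
        ]
        for name in best.params.index:
            lines.append(
                f"  {name:>20s}  {best.params[name]: .6g} "
                f"({best.bse[name]:.3g}), p={best.pvalues[name]:.3g}"
            )
        if best.morans_i is not None:
            lines.append(
                f"residual Moran's I: {best.morans_i:.3f} (p={best.morans_p:.3g})"
            )
        return "\n".join(lines)
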