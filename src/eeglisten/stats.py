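"""Mixed-effect modelling of PC scores and exam z-scores.

Within-background models explain a component score by listening task and
scalp subregion at fixed background sound; within-task models swap the roles
of task and background.  Both carry a participant random intercept.  Tukey
post-hoc comparisons on the estimated marginal means of a factor control the
family-wise error rate over all pairwise contrasts via the studentized-range
distribution.

Exam z-scores reference every topic's keyword count to the cohort's
performance on that topic in pink noise (lecture in silence):
z = (keywords - mu_pink) / sigma_pink.  The exam prediction stage fits
constant, background-type, full-EEG (k PCs x 6 subregions) and
backward-AIC-stepwise models, as plain (fixed-effect) or participant
random-intercept (mixed-effect) regressions, and compares them by AIC and
likelihood-ratio chi-square tests for nested pairs.

AIC is always -2 logLik + 2 edf with edf counting fixed coefficients plus
variance components plus the residual variance, and all fits that enter AIC
or likelihood-ratio comparisons use ML (not REML).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """One regression to fit: response ~ 1 + fixed terms (+ participant
    random intercept when ``random_intercept`` is set)."""

    response: str
    fixed: list
    data: pd.DataFrame
    random_intercept: str | None = "participant"

    def __post_init__(self):
        cols = [self.response] + list(self.fixed)
        if self.random_intercept:
            cols.append(self.random_intercept)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        if self.random_intercept is not None:
            if self.data[self.random_intercept].nunique() < 2:
                raise ValueError("grouping factor needs >= 2 levels")

    @property
    def formula(self) -> str:
        rhs = " + ".join(["1"] + [f"Q('{t}')" if not t.isidentifier() else t
                                  for t in self.fixed])
        return f"Q('{self.response}') ~ {rhs}" if not self.response.isidentifier() \
            else f"{self.response} ~ {rhs}"


@dataclass
class ModelFit:
    """Results wrapper: coefficients, likelihood, AIC and fit metadata.

    ``edf`` counts every free parameter (fixed coefficients, random-effect
    variance if present, residual variance), so ``aic == -2*llf + 2*edf``
    holds exactly.
    """

    spec: ModelSpec
    result: object = field(repr=False)
    kind: str = "mixed"  # "mixed" | "ols"
    flags: list = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.result.params if self.kind == "ols" else self.result.fe_params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse[self.params.index]

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def n_fixed(self) -> int:
        return len(self.params)

    @property
    def edf(self) -> int:
        extra = 2 if self.kind == "mixed" else 1  # RE variance + residual
        return self.n_fixed + extra

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.edf

    @property
    def nobs(self) -> int:
        return int(self.result.nobs)

    @property
    def random_variance(self) -> float | None:
        if self.kind != "mixed":
            return None
        return float(np.asarray(self.result.cov_re).ravel()[0])

    @property
    def resid_df(self) -> int:
        return self.nobs - self.n_fixed

    def cov_fixed(self) -> np.ndarray:
        cov = np.asarray(self.result.cov_params())
        k = self.n_fixed
        return cov[:k, :k]

    def summary(self):
        return self.result.summary()


def fit_lmm(spec: ModelSpec, reml: bool = False) -> ModelFit:
    """Fit the model; ML by default so AIC/likelihood-ratio comparisons are
    valid (pass ``reml=True`` only for final coefficient reporting).

    A singular fit (random-intercept variance collapsing to zero) is kept
    and flagged, not raised.
    """
    if spec.random_intercept is None:
        res = smf.ols(spec.formula, data=spec.data).fit()
        return ModelFit(spec=spec, result=res, kind="ols")
    model = smf.mixedlm(spec.formula, data=spec.data,
                        groups=spec.data[spec.random_intercept])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml)
    fit = ModelFit(spec=spec, result=res, kind="mixed")
    if fit.random_variance is not None and fit.random_variance < 1e-8:
        fit.flags.append("singular: random-intercept variance ~ 0")
    if not res.converged:
        fit.flags.append("optimizer did not converge")
    return fit


# ---------------------------------------------------------------------------
# Tukey post-hoc on estimated marginal means
# ---------------------------------------------------------------------------

@dataclass
class TukeyTable:
    factor: str
    emmeans: pd.Series
    pairs: pd.DataFrame  # level_a, level_b, estimate, se, p_adj, direction
    max_level: str
    min_level: str

    def to_triangular(self) -> pd.DataFrame:
        """Square layout: upper triangle adjusted p-values, lower triangle an
        arrow toward the level with the higher marginal mean, diagonal
        max/min annotations."""
        levels = list(self.emmeans.index)
        out = pd.DataFrame("", index=levels, columns=levels)
        for _, row in self.pairs.iterrows():
            a, b = row["level_a"], row["level_b"]
            i, j = levels.index(a), levels.index(b)
            lo, hi = min(i, j), max(i, j)
            out.iloc[lo, hi] = _p_code(row["p_adj"])
            if row["p_adj"] < 0.05:
                higher = a if row["estimate"] > 0 else b
                out.iloc[hi, lo] = f"-> {higher}"
        for lev, tag in ((self.max_level, "max"), (self.min_level, "min")):
            i = levels.index(lev)
            out.iloc[i, i] = tag
        return out


def _p_code(p: float) -> str:
    for thr in (1e-5, 1e-4, 1e-3, 0.01, 0.05):
        if p < thr:
            return f"p<{thr:g}"
    return "n.s."


def _balanced_design_rows(fit: ModelFit, factor: str) -> dict:
    """Design-matrix row of each factor level, averaging the other model
    variables over a balanced grid (categoricals) / their mean (numeric)."""
    import patsy

    data = fit.spec.data
    design_info = fit.result.model.data.design_info
    levels = sorted(pd.unique(data[factor]))
    others = [t for t in fit.spec.fixed if t != factor]
    grids = []
    for t in others:
        col = data[t]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            grids.append([(t, v) for v in sorted(pd.unique(col))])
        else:
            grids.append([(t, float(col.mean()))])
    from itertools import product

    combos = list(product(*grids)) if grids else [()]
    rows = {}
    for lev in levels:
        frame = pd.DataFrame([dict(c, **{factor: lev}) for c in combos]
                             or [{factor: lev}])
        (mat,) = patsy.build_design_matrices([design_info], frame)
        rows[lev] = np.asarray(mat).mean(axis=0)
    return rows


def tukey_posthoc(fit: ModelFit, factor: str, alpha: float = 0.05) -> TukeyTable:
    """All pairwise comparisons of a categorical fixed factor.

    Marginal means are linear combinations of the fixed coefficients with
    the other factors held at balanced weights; adjusted p-values come from
    the studentized-range distribution with the residual degrees of freedom
    (a containment-style approximation for mixed fits).
    """
    rows = _balanced_design_rows(fit, factor)
    levels = list(rows)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    beta = np.asarray(fit.params)
    cov = fit.cov_fixed()
    emm = pd.Series({lev: float(rows[lev] @ beta) for lev in levels},
                    name="emmean")
    k = len(levels)
    df = max(fit.resid_df, 2)
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            L = rows[levels[i]] - rows[levels[j]]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            q = np.sqrt(2.0) * abs(est) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df))
            recs.append({"level_a": levels[i], "level_b": levels[j],
                         "estimate": est, "se": se, "p_adj": min(p, 1.0)})
    pairs = pd.DataFrame(recs)
    return TukeyTable(factor=factor, emmeans=emm, pairs=pairs,
                      max_level=str(emm.idxmax()), min_level=str(emm.idxmin()))


# ---------------------------------------------------------------------------
# model comparison and stepwise selection
# ---------------------------------------------------------------------------

def compare_models(fit_a: ModelFit, fit_b: ModelFit) -> dict:
    """Likelihood-ratio chi-square for nested ML fits, plus the AIC gap.

    ``fit_a`` must be nested in ``fit_b`` (terms a subset, same response and
    rows); otherwise only delta AIC is reported and the LRT slot is None.
    """
    delta_aic = fit_b.aic - fit_a.aic
    nested = (set(fit_a.spec.fixed) <= set(fit_b.spec.fixed)
              and fit_a.spec.response == fit_b.spec.response
              and fit_a.nobs == fit_b.nobs
              and fit_a.kind == fit_b.kind)
    if not nested:
        return {"chi2": None, "df": None, "p": None, "delta_aic": delta_aic,
                "nested": False}
    stat = max(2.0 * (fit_b.llf - fit_a.llf), 0.0)
    df = fit_b.edf - fit_a.edf
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0:
        p = 1.0
    return {"chi2": stat, "df": df, "p": p, "delta_aic": delta_aic,
            "nested": True}


def _numeric_terms(spec: ModelSpec) -> bool:
    return all(t in spec.data.columns
               and np.issubdtype(spec.data[t].dtype, np.number)
               for t in spec.fixed)


def _fit_ols_matrix(response: str, terms: list, data: pd.DataFrame) -> ModelFit:
    """Formula-free OLS on plain numeric columns (fast path for stepwise)."""
    exog = sm.add_constant(data[list(terms)], has_constant="add")
    exog = exog.rename(columns={"const": "Intercept"})
    res = sm.OLS(data[response].to_numpy(), exog).fit()
    spec = ModelSpec(response=response, fixed=list(terms), data=data,
                     random_intercept=None)
    return ModelFit(spec=spec, result=res, kind="ols")


def stepwise_backward(full_fit: ModelFit) -> tuple:
    """Backward elimination on AIC.

    Iteratively refits the model dropping each remaining term, removes the
    term whose deletion lowers AIC the most, and stops when every deletion
    would raise AIC.  Deterministic given the data.  Returns
    ``(reduced ModelFit, retained terms)``.
    """
    spec = full_fit.spec
    fast = spec.random_intercept is None and _numeric_terms(spec)

    def refit(terms):
        if fast:
            return _fit_ols_matrix(spec.response, terms, spec.data)
        return fit_lmm(ModelSpec(response=spec.response, fixed=list(terms),
                                 data=spec.data,
                                 random_intercept=spec.random_intercept))

    terms = list(spec.fixed)
    current = refit(terms) if fast else full_fit  # align llf conventions
    while terms:
        candidates = [(refit([x for x in terms if x != t]), t)
                      for t in terms]
        best_fit, dropped = min(candidates, key=lambda c: c[0].aic)
        if best_fit.aic < current.aic:
            current = best_fit
            terms = [x for x in terms if x != dropped]
        else:
            break
    return current, terms


# ---------------------------------------------------------------------------
# exam z-scores and exam prediction
# ---------------------------------------------------------------------------

def exam_zscores(exam: pd.DataFrame) -> pd.DataFrame:
    """Exam z-scores referenced to the pink-noise (silence) condition.

    For each topic, mu and sigma (sample SD) of ``keywords_correct`` are
    taken over the pink-noise rows of all participants; every row of that
    topic (pink included) is standardized with them.  Topics with fewer than
    two pink rows raise; a zero sigma flags the topic and leaves z undefined
    (NaN) there.
    """
    req = {"participant", "topic", "background", "keywords_correct"}
    missing = req - set(exam.columns)
    if missing:
        raise ValueError(f"exam table missing columns: {sorted(missing)}")
    out = exam.copy()
    stats_rows = {}
    for topic, grp in exam.groupby("topic"):
        pink = grp[grp["background"] == "PK"]["keywords_correct"]
        if len(pink) < 2:
            raise ValueError(f"topic {topic!r} has < 2 pink-noise rows")
        mu = float(pink.mean())
        sd = float(pink.std(ddof=1))
        stats_rows[topic] = {"mu_pink": mu, "sigma_pink": sd,
                             "degenerate": sd == 0.0}
    out["mu_pink"] = out["topic"].map(lambda t: stats_rows[t]["mu_pink"])
    out["sigma_pink"] = out["topic"].map(lambda t: stats_rows[t]["sigma_pink"])
    with np.errstate(divide="ignore", invalid="ignore"):
        out["z"] = np.where(
            out["sigma_pink"] > 0,
            (out["keywords_correct"] - out["mu_pink"]) / out["sigma_pink"],
            np.nan)
    out.attrs["pink_stats"] = stats_rows
    return out


def pivot_subregion_scores(subregion_df: pd.DataFrame,
                           k: int = 9) -> pd.DataFrame:
    """Wide predictor table: one row per LA fragment (participant, topic),
    one column per (subregion, PC) named ``<subregion>_PC<i>``."""
    la = subregion_df
    if "task" in la.columns:
        la = la[la["task"] == "LA"]
    pcs = [f"PC{i + 1}" for i in range(k)]
    idx = [c for c in ("participant", "topic", "background") if c in la.columns]
    wide = la.pivot_table(index=idx, columns="subregion", values=pcs,
                          observed=True)
    wide.columns = [f"{sub}_{pc}" for pc, sub in wide.columns]
    return wide.reset_index()


def predict_exam(examz: pd.DataFrame, subregion_df: pd.DataFrame, *,
                 mode: str = "mixed", k: int = 9) -> dict:
    """Exam prediction model family: constant, background-type, full-EEG,
    and backward-AIC stepwise-EEG regressions of the exam z-scores.

    ``mode='fixed'`` fits plain regressions; ``mode='mixed'`` adds a
    participant random intercept.  Rows are aligned on (participant, topic).
    Returns ``{"fits": {...}, "comparisons": DataFrame, "retained": [...]}``.
    """
    if mode not in ("fixed", "mixed"):
        raise ValueError("mode must be 'fixed' or 'mixed'")
    wide = pivot_subregion_scores(subregion_df, k)
    merged = examz.merge(wide.drop(columns=[c for c in ("background",)
                                            if c in wide.columns]),
                         on=["participant", "topic"], how="inner")
    merged = merged.dropna(subset=["z"]).reset_index(drop=True)
    predictors = [c for c in merged.columns if "_PC" in c]
    # drop degenerate and rank-deficient predictors (pivoted QR)
    keep = [c for c in predictors if merged[c].std(ddof=0) > 0]
    if keep:
        import warnings
        from scipy.linalg import qr

        Xp = merged[keep].to_numpy(dtype=float)
        Xp = (Xp - Xp.mean(0)) / Xp.std(0)
        max_p = max(1, len(merged) - 8)  # leave room for intercept + error df
        _, R, piv = qr(Xp, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))  # length min(n, p)
        ok = np.zeros(piv.size, dtype=bool)
        ok[: diag.size] = diag > 1e-8 * diag[0]
        ranked = [keep[j] for j in piv[ok][:max_p]]
        if len(ranked) < len(keep):
            warnings.warn(
                f"dropping {len(keep) - len(ranked)} rank-deficient or "
                "excess predictors from the exam model", stacklevel=2)
        keep = [c for c in keep if c in set(ranked)]
    dropped = sorted(set(predictors) - set(keep))
    group = "participant" if mode == "mixed" else None

    def make(fixed):
        return fit_lmm(ModelSpec(response="z", fixed=fixed, data=merged,
                                 random_intercept=group))

    fits = {
        "constant": make([]),
        "background": make(["background"]),
        "full_eeg": make(keep),
    }
    step_fit, retained = stepwise_backward(fits["full_eeg"])
    fits["stepwise_eeg"] = step_fit

    names = list(fits)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmp_ = compare_models(fits[a], fits[b])
            rows.append({"model_a": a, "model_b": b, **cmp_})
    comparisons = pd.DataFrame(rows)
    return {"fits": fits, "comparisons": comparisons, "retained": retained,
            "dropped_predictors": dropped, "data": merged}


# ---------------------------------------------------------------------------
# within-background / within-task model families
# ---------------------------------------------------------------------------

def score_models(subregion_df: pd.DataFrame, *, by: str = "background",
                 k: int = 9, channel_level: pd.DataFrame | None = None) -> dict:
    """Mixed models of PC scores, one per (PC, level of ``by``).

    ``by='background'`` gives within-background models
    (score ~ task + subregion + (1|participant)); ``by='task'`` gives
    within-task models (score ~ background + subregion + (1|participant)).
    Returns ``{(pc, level): {"fit": ModelFit, "tukey": TukeyTable}}`` with
    the Tukey table computed on the complementary factor.
    """
    if by not in ("background", "task"):
        raise ValueError("by must be 'background' or 'task'")
    other = "task" if by == "background" else "background"
    df = subregion_df
    out = {}
    for level, grp in df.groupby(by, observed=True):
        if grp[other].nunique() < 2:
            continue
        for i in range(k):
            pc = f"PC{i + 1}"
            spec = ModelSpec(response=pc, fixed=[other, "subregion"],
                             data=grp.reset_index(drop=True),
                             random_intercept="participant")
            fit = fit_lmm(spec)
            out[(pc, level)] = {"fit": fit,
                                "tukey": tukey_posthoc(fit, other)}
    return out
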