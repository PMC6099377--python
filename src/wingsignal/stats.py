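"""Honest-signalling and dimorphism statistics on the assembled specimen table.

Four analyses mirror the study design: (1) among-population regressions of
population-mean colour on population-mean toxin concentration, per sex;
(2) within-population multiple regression of toxin concentration on the wing
colour metrics, with a VIF guard, backward stepwise simplification at
alpha = 0.05, and a Cook's-distance (> 1) outlier rule; (3) sex x population
linear models per colour metric with Tukey HSD population comparisons; and
(4) linear mixed models (random intercept per individual) for conspicuousness
against plant backgrounds, with likelihood-ratio tests for the fixed effects
and a logit-transformed luminance response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence, variance_inflation_factor

ALPHA = 0.05


class CollinearityError(ValueError):
    """Raised when candidate predictors are too collinear to fit together.

    ``predictors`` names the offending metrics so a caller can drop one and
    refit, mirroring how collinear colour-metric pairs are handled in
    practice.
    """

    def __init__(self, message: str, predictors: list[str]):
        super().__init__(message)
        self.predictors = predictors


VIF_THRESHOLD = 10.0
COOKS_THRESHOLD = 1.0
SAT_HUE_CORR_GUARD = 0.995


@dataclass
class RegressionResult:
    """One fitted linear model with its headline nested-model F test."""

    response: str
    terms: list[str]
    F: float
    df: tuple[float, float]
    p: float
    r_squared_adj: float
    coefficients: pd.DataFrame
    excluded_outliers: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "response": self.response,
            "terms": "+".join(self.terms) if self.terms else "1",
            "F": self.F,
            "df1": self.df[0],
            "df2": self.df[1],
            "p": self.p,
            "r_squared_adj": self.r_squared_adj,
            "n_outliers_excluded": len(self.excluded_outliers),
        }


def _coef_table(res) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": res.params.index,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )


def ols_with_f_tests(
    y: np.ndarray,
    design_full: pd.DataFrame,
    design_reduced: pd.DataFrame | None = None,
    response: str = "y",
) -> RegressionResult:
    """OLS fit plus the nested-model F test against a reduced design.

    Both designs get an intercept; the default reduced model is
    intercept-only, so the headline F is the overall regression test.
    Adjusted R² is reported (it can be negative for uninformative models).
    """
    y = np.asarray(y, float)
    Xf = sm.add_constant(pd.DataFrame(design_full).reset_index(drop=True), has_constant="add")
    n = len(y)
    if n <= Xf.shape[1]:
        raise ValueError(f"n={n} too small for {Xf.shape[1]} model columns")
    if np.linalg.matrix_rank(Xf.to_numpy()) < Xf.shape[1]:
        raise ValueError("rank-deficient design matrix")
    full = sm.OLS(y, Xf).fit()
    if design_reduced is None:
        Xr = pd.DataFrame({"const": np.ones(n)})
    else:
        Xr = sm.add_constant(
            pd.DataFrame(design_reduced).reset_index(drop=True), has_constant="add"
        )
    reduced = sm.OLS(y, Xr).fit()
    if Xf.shape[1] == Xr.shape[1]:  # nothing to test (e.g. intercept-only model)
        F, p, df_diff = 0.0, 1.0, 0.0
    elif reduced.ssr - full.ssr <= 1e-12 * n * max(
        float(np.var(y)), float(np.mean(y**2)), 1e-300
    ):
        # the extra terms explain (numerically) nothing, incl. constant-y data
        F, p, df_diff = 0.0, 1.0, float(Xf.shape[1] - Xr.shape[1])
    else:
        F, p, df_diff = full.compare_f_test(reduced)
    return RegressionResult(
        response,
        [c for c in Xf.columns if c != "const"],
        float(F),
        (float(df_diff), float(full.df_resid)),
        float(p),
        float(full.rsquared_adj),
        _coef_table(full),
    )


def among_population_regression(
    records: pd.DataFrame,
    metric: str,
    sex: str,
    conc_col: str = "concentration_nmol_per_mg",
) -> RegressionResult:
    """Population means of a colour metric regressed on mean toxin concentration.

    Run separately per sex; one point per population, so this tests honesty
    at the between-population level.
    """
    sub = records[records["sex"] == sex]
    means = sub.groupby("population")[[metric, conc_col]].mean()
    if len(means) < 3:
        raise ValueError(f"need >= 3 populations with sex {sex}; got {len(means)}")
    res = ols_with_f_tests(
        means[metric].to_numpy(),
        pd.DataFrame({"mean_concentration": means[conc_col].to_numpy()}),
        response=metric,
    )
    res.response = f"{metric}[{sex}]"
    return res


@dataclass
class StepwiseResult:
    """Within-population stepwise regression: full and minimal models.

    ``refit_without_outliers`` repeats the whole procedure with Cook's-flagged
    points removed (None when nothing was flagged); both fits are reported so
    outlier influence can be judged, as in standard diagnostic practice.
    """

    full: RegressionResult
    minimal: RegressionResult
    outliers: list
    refit_without_outliers: "StepwiseResult | None" = None


def _check_collinearity(X: pd.DataFrame) -> None:
    cols = list(X.columns)
    corr = X.corr().abs()
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if corr.loc[a, b] > SAT_HUE_CORR_GUARD:
                raise CollinearityError(
                    f"predictors {a!r} and {b!r} are collinear "
                    f"(|r| = {corr.loc[a, b]:.4f} > {SAT_HUE_CORR_GUARD}); "
                    "include only one of them",
                    [a, b],
                )
    Xc = sm.add_constant(X, has_constant="add").to_numpy()
    vifs = {c: variance_inflation_factor(Xc, j + 1) for j, c in enumerate(cols)}
    bad = {c: v for c, v in vifs.items() if v >= VIF_THRESHOLD}
    if bad:
        worst = max(bad, key=bad.get)
        partner = corr.loc[worst].drop(worst).idxmax()
        raise CollinearityError(
            f"VIF >= {VIF_THRESHOLD} for {sorted(bad)} (worst pair: "
            f"{worst!r}/{partner!r}); drop one collinear metric",
            [worst, partner],
        )


def _backward_eliminate(
    y: np.ndarray, X: pd.DataFrame, response: str, alpha: float
) -> RegressionResult:
    keep = list(X.columns)
    while keep:
        fit = ols_with_f_tests(y, X[keep], response=response)
        pvals = fit.coefficients.set_index("term")["p"].drop("const")
        worst = pvals.idxmax()
        # dropping a single term: the t-test p equals the nested-model F-test p
        if pvals[worst] >= alpha:
            keep.remove(worst)
        else:
            return fit
    return ols_with_f_tests(y, pd.DataFrame(index=pd.RangeIndex(len(y))), response=response)


def within_population_regression(
    records: pd.DataFrame,
    channel_choice: str = "saturation",
    wing: str = "fw",
    predictors: list[str] | None = None,
    conc_col: str = "concentration_nmol_per_mg",
    alpha: float = ALPHA,
) -> StepwiseResult:
    """Toxin concentration regressed on wing colour metrics, one population.

    Saturation and hue are computed from the same catches and are nearly
    collinear, so only the one named by ``channel_choice`` enters. Candidate
    predictors default to the wing's luminance, saturation-or-hue, internal
    chromatic and luminance contrasts, and relative spot area. Backward
    elimination at ``alpha`` yields the minimal model; observations with
    Cook's distance > 1 in the full model trigger a complete re-run without
    them, reported alongside.
    """
    if channel_choice not in ("saturation", "hue"):
        raise ValueError("channel_choice must be 'saturation' or 'hue'")
    if predictors is None:
        predictors = [
            f"{wing}_luminance",
            f"{wing}_{channel_choice}",
            f"{wing}_chromatic_jnd",
            f"{wing}_luminance_jnd",
            f"{wing}_rel_spot_area",
        ]
    data = records.dropna(subset=predictors + [conc_col]).reset_index(drop=True)
    X = data[predictors].astype(float)
    y = data[conc_col].to_numpy(dtype=float)
    if len(data) <= len(predictors) + 2:
        raise ValueError(f"n={len(data)} too small for {len(predictors)} predictors")
    _check_collinearity(X)
    full = ols_with_f_tests(y, X, response=conc_col)
    Xc = sm.add_constant(X, has_constant="add")
    cooks = OLSInfluence(sm.OLS(y, Xc).fit()).cooks_distance[0]
    outliers = [data["specimen_id"].iloc[i] if "specimen_id" in data else int(i)
                for i in np.flatnonzero(cooks > COOKS_THRESHOLD)]
    minimal = _backward_eliminate(y, X, conc_col, alpha)
    result = StepwiseResult(full, minimal, outliers)
    if outliers:
        mask = ~np.isin(np.arange(len(data)), np.flatnonzero(cooks > COOKS_THRESHOLD))
        sub = data.loc[mask].reset_index(drop=True)
        full2 = ols_with_f_tests(
            sub[conc_col].to_numpy(dtype=float), sub[predictors].astype(float),
            response=conc_col,
        )
        minimal2 = _backward_eliminate(
            sub[conc_col].to_numpy(dtype=float), sub[predictors].astype(float),
            conc_col, alpha,
        )
        full2.excluded_outliers = outliers
        minimal2.excluded_outliers = outliers
        result.refit_without_outliers = StepwiseResult(full2, minimal2, outliers)
    return result


# ---------------------------------------------------------------------------
# sex x population dimorphism models with Tukey HSD
# ---------------------------------------------------------------------------

def _dimorphism_design(data: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    pops = sorted(data["population"].unique())
    X = pd.DataFrame(index=data.index)
    X["sex_M"] = (data["sex"] == "M").astype(float)
    pop_cols, int_cols = [], []
    for p in pops[1:]:
        pc, ic = f"pop_{p}", f"sexM_x_{p}"
        X[pc] = (data["population"] == p).astype(float)
        X[ic] = X["sex_M"] * X[pc]
        pop_cols.append(pc)
        int_cols.append(ic)
    return X, pop_cols, int_cols


def tukey_hsd_from_contrasts(
    fit, contrasts: dict[tuple[str, str], np.ndarray], df_resid: float
) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise tests from model contrast vectors.

    Each contrast vector picks a pairwise difference of adjusted (least-
    squares) group means; the studentized-range distribution with the model's
    residual df supplies family-wise adjusted p-values. Unbalanced groups are
    handled naturally because the standard error comes from the model's
    coefficient covariance.
    """
    k = len({lvl for pair in contrasts for lvl in pair})
    cov = np.asarray(fit.cov_params())
    params = np.asarray(fit.params)
    rows = []
    for (a, b), c in contrasts.items():
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        q = abs(est) / se * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df_resid))
        rows.append({"level_a": a, "level_b": b, "estimate": est, "se": se, "p_adj": p})
    return pd.DataFrame(rows)


@dataclass
class DimorphismResult:
    """Sex x population model for one colour metric, plus Tukey table."""

    metric: str
    interaction: tuple[float, float, float, float]  # F, df1, df2, p
    interaction_kept: bool
    sex: tuple[float, float, float, float]
    population: tuple[float, float, float, float]
    model: RegressionResult
    tukey_population: pd.DataFrame


def dimorphism_model(records: pd.DataFrame, metric: str) -> DimorphismResult:
    """Colour metric ~ sex x population with sequential simplification.

    The interaction is dropped when its nested F-test p >= 0.05; sex and
    population main effects are then tested by nested-model F against the
    retained model. Tukey HSD compares population adjusted means using the
    Tukey-Kramer standard-error form (populations are unbalanced in real
    sampling).
    """
    data = records.dropna(subset=[metric, "sex", "population"]).reset_index(drop=True)
    pops = sorted(data["population"].unique())
    if len(pops) < 2 or data["sex"].nunique() < 2:
        raise ValueError("need >= 2 populations and both sexes")
    cells = data.groupby(["sex", "population"]).size()
    if len(cells) < 2 * len(pops) or (cells == 0).any():
        raise ValueError("empty sex x population cell")
    X, pop_cols, int_cols = _dimorphism_design(data)
    y = data[metric].to_numpy(dtype=float)

    full = ols_with_f_tests(y, X, X[["sex_M"] + pop_cols], response=metric)
    inter = (full.F, full.df[0], full.df[1], full.p)
    keep_inter = full.p < ALPHA
    cols = list(X.columns) if keep_inter else ["sex_M"] + pop_cols

    # main effects are always tested marginally against the additive model
    # (Type II): in a (near-)balanced design the main-effect sums of squares
    # are orthogonal to the interaction, and making the test unconditional on
    # the interaction pre-test keeps its size at the nominal level
    sex_t = ols_with_f_tests(y, X[["sex_M"] + pop_cols], X[pop_cols], response=metric)
    pop_t = ols_with_f_tests(y, X[["sex_M"] + pop_cols], X[["sex_M"]], response=metric)
    model = ols_with_f_tests(y, X[cols], response=metric)

    fit = sm.OLS(y, sm.add_constant(X[cols], has_constant="add")).fit()
    names = list(fit.params.index)
    contrasts = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            c = np.zeros(len(names))
            for lvl, sign in ((a, 1.0), (b, -1.0)):
                if f"pop_{lvl}" in names:
                    c[names.index(f"pop_{lvl}")] = sign
                    if keep_inter and f"sexM_x_{lvl}" in names:
                        c[names.index(f"sexM_x_{lvl}")] = 0.5 * sign
            contrasts[(a, b)] = c
    tukey = tukey_hsd_from_contrasts(fit, contrasts, float(fit.df_resid))
    return DimorphismResult(
        metric,
        tuple(map(float, inter)),
        keep_inter,
        (sex_t.F, sex_t.df[0], sex_t.df[1], sex_t.p),
        (pop_t.F, pop_t.df[0], pop_t.df[1], pop_t.p),
        model,
        tukey,
    )


# ---------------------------------------------------------------------------
# mixed models for contrast against plant backgrounds
# ---------------------------------------------------------------------------

def logit_rescale(y: np.ndarray, eps_frac: float = 0.05) -> np.ndarray:
    """Map positive JND values into (0,1) by y/(max + eps), then logit.

    JNDs are unbounded above, so the logit needs a declared rescaling; eps is
    ``eps_frac`` of the maximum, keeping the largest value finite after the
    transform.
    """
    y = np.asarray(y, float)
    top = y.max() * (1.0 + eps_frac)
    z = y / top
    return np.log(z / (1.0 - z))


@dataclass
class MixedModelResult:
    """Random-intercept model for specimen x plant-type contrasts.

    ``tests`` maps each fixed term to (chi2, df, p). The chi-square is the
    maximum-likelihood LRT statistic; the p-value uses a small-sample F
    calibration (below) rather than the asymptotic chi-square tail, which is
    anticonservative for effects that vary between individuals at realistic
    cohort sizes. ``chi2_p`` keeps the asymptotic tail for comparability
    with the chi-square reporting convention.
    """

    response: str
    tests: dict[str, tuple[float, float, float]]  # term -> (chi2, df, p)
    chi2_p: dict[str, float]
    tukey: dict[str, pd.DataFrame]
    random_intercept_var: float
    residual_var: float
    fe_params: pd.Series


def _mixed_design(data: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    groups: dict[str, list[str]] = {"sex": ["sex_M"]}
    X["sex_M"] = (data["sex"] == "M").astype(float)
    for term, col in (("population", "population"), ("plant_type", "plant_type")):
        levels = sorted(data[col].unique())
        cols = []
        for lvl in levels[1:]:
            name = f"{term}_{lvl}"
            X[name] = (data[col] == lvl).astype(float)
            cols.append(name)
        groups[term] = cols
    return X, groups


def _fit_mixedlm(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X.to_numpy(), groups=groups)
        # boundary fits (random-intercept variance -> 0) can break a given
        # optimizer's Hessian step; fall through to more robust methods
        for method in ("lbfgs", None, "powell"):
            try:
                if method is None:
                    return model.fit(reml=False)
                return model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError("mixed-model fit failed with every optimizer")


def plant_contrast_mixed_model(
    contrasts: pd.DataFrame, response: str = "chromatic"
) -> MixedModelResult:
    """Conspicuousness against plant backgrounds: LMM with individual intercepts.

    Fixed effects are sex, population and plant type; individual ID is a
    random intercept (each specimen is measured against several plant
    backgrounds). The within-individual term (plant type) is tested by a
    maximum-likelihood likelihood-ratio chi-square. The between-individual
    terms (sex, population) are tested at the individual-mean level, where
    the nested F test is exact for balanced sampling — the asymptotic
    chi-square tail is anticonservative for such terms at realistic cohort
    sizes, so the reported chi2 for them is the mean-level deviance
    n_b * ln(RSS0/RSS1) with its F-based p. The luminance response is
    logit-transformed after rescaling into (0,1). Tukey tables compare plant
    types and populations.
    """
    col = {"chromatic": "chromatic_jnd", "luminance": "luminance_jnd"}[response]
    data = contrasts.dropna(subset=[col]).reset_index(drop=True)
    sizes = data.groupby("specimen_id").size()
    if (sizes < 2).all():
        raise ValueError(
            "every individual has a single observation: the random intercept "
            "is inestimable; use the fixed-effects analysis instead"
        )
    data["_y"] = data[col].to_numpy(dtype=float)
    if response == "luminance":
        data["_y"] = logit_rescale(data["_y"].to_numpy())
    y = data["_y"].to_numpy()
    X, terms = _mixed_design(data)
    ids = data["specimen_id"].to_numpy()
    full = _fit_mixedlm(y, X, ids)
    tests = {}
    chi2_p = {}

    # between-individual terms: individual means carry all their information
    means = (
        data.groupby("specimen_id")
        .agg(_y=("_y", "mean"), sex=("sex", "first"), population=("population", "first"))
        .reset_index()
    )
    n_b = len(means)
    bcols = pd.DataFrame({"sex_M": (means["sex"] == "M").astype(float)})
    for p_ in sorted(means["population"].unique())[1:]:
        bcols[f"pop_{p_}"] = (means["population"] == p_).astype(float)
    between = {"sex": ["sex_M"], "population": [c for c in bcols if c.startswith("pop_")]}
    for term, cols in between.items():
        fit = ols_with_f_tests(
            means["_y"].to_numpy(), bcols, bcols.drop(columns=cols), response=col
        )
        chi2 = n_b * np.log1p(fit.df[0] * fit.F / fit.df[1])  # mean-level deviance
        tests[term] = (float(chi2), fit.df[0], fit.p)
        chi2_p[term] = float(sps.chi2.sf(chi2, fit.df[0]))

    # within-individual term: ML likelihood-ratio chi-square
    red = _fit_mixedlm(y, X.drop(columns=terms["plant_type"]), ids)
    chi2 = max(2.0 * (full.llf - red.llf), 0.0)
    df1 = float(len(terms["plant_type"]))
    p_plant = float(sps.chi2.sf(chi2, df1))
    tests["plant_type"] = (float(chi2), df1, p_plant)
    chi2_p["plant_type"] = p_plant

    fe = pd.Series(np.asarray(full.fe_params), index=list(X.columns))
    df_resid = float(len(data) - len(X.columns) - 1)
    tukey: dict[str, pd.DataFrame] = {}
    for term, col_names in (("plant_type", "plant_type"), ("population", "population")):
        levels = sorted(data[col_names].unique())
        cvecs = {}
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                c = np.zeros(len(X.columns))
                for lvl, sign in ((a, 1.0), (b, -1.0)):
                    name = f"{term}_{lvl}"
                    if name in X.columns:
                        c[list(X.columns).index(name)] = sign
                cvecs[(a, b)] = c

        class _Wrap:  # adapt MixedLM results to the contrast helper
            params = fe.to_numpy()

            @staticmethod
            def cov_params():
                return np.asarray(full.cov_params())[: len(X.columns), : len(X.columns)]

        tukey[term] = tukey_hsd_from_contrasts(_Wrap, cvecs, df_resid)
    return MixedModelResult(
        response,
        tests,
        chi2_p,
        tukey,
        float(np.asarray(full.cov_re).ravel()[0]),
        float(full.scale),
        fe,
    )
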