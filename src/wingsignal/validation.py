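"""Simulation-based calibration of the statistical pipeline.

Null simulations matched to each analysis structure verify that nominal
alpha = 0.05 tests reject at ~5%, that Tukey HSD holds its family-wise
level, and that the within-population regression recovers a known honest
slope. These routines drive the acceptance checks and are reusable for
sensitivity analyses at other sample sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    CollinearityError,
    among_population_regression,
    dimorphism_model,
    ols_with_f_tests,
    plant_contrast_mixed_model,
    within_population_regression,
)
from .synthetic import ScenarioConfig, make_cohort

METRIC_COLS = (
    "fw_luminance",
    "fw_saturation",
    "fw_chromatic_jnd",
    "fw_luminance_jnd",
    "fw_rel_spot_area",
)


def _null_metric_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Specimens with colour metrics independent of toxin concentration."""
    df = pd.DataFrame({c: rng.normal(size=n) for c in METRIC_COLS})
    df["concentration_nmol_per_mg"] = np.exp(rng.normal(-0.5, 0.4, size=n))
    df["specimen_id"] = [f"S{i:04d}" for i in range(n)]
    return df


def type1_error_ols(n_reps: int = 2000, n: int = 20, seed: int = 0) -> float:
    """Rejection rate of the nested-model F test on pure-noise regressions."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        y = rng.normal(size=n)
        x = pd.DataFrame({"x": rng.normal(size=n)})
        if ols_with_f_tests(y, x).p < 0.05:
            hits += 1
    return hits / n_reps


def type1_error_among_population(
    n_reps: int = 2000, n_pops: int = 10, n_per_pop: int = 6, seed: int = 0
) -> float:
    """Among-population regression under no colour-toxin relationship."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        df = _null_metric_table(rng, n_pops * n_per_pop)
        df["population"] = np.repeat([f"p{i}" for i in range(n_pops)], n_per_pop)
        df["sex"] = "F"
        if among_population_regression(df, "fw_luminance", "F").p < 0.05:
            hits += 1
    return hits / n_reps


def type1_error_within_population(
    n_reps: int = 2000, n: int = 25, seed: int = 0
) -> float:
    """Full-model F of the within-population regression under the null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        df = _null_metric_table(rng, n)
        if within_population_regression(df, "saturation").full.p < 0.05:
            hits += 1
    return hits / n_reps


def calibrate_dimorphism(
    n_reps: int = 2000, n_pops: int = 3, n_per_cell: int = 10, seed: int = 0
) -> dict[str, float]:
    """Null sex x population models: sex-test and Tukey family-wise rates.

    Metric values are exchangeable across sexes and populations, so the sex
    main-effect test should reject at ~5% and at most ~5% of families should
    contain any significant Tukey population pair.
    """
    rng = np.random.default_rng(seed)
    sex_hits = tukey_hits = 0
    pops = np.repeat([f"p{i}" for i in range(n_pops)], 2 * n_per_cell)
    sexes = np.tile(np.repeat(["F", "M"], n_per_cell), n_pops)
    for _ in range(n_reps):
        df = pd.DataFrame(
            {"population": pops, "sex": sexes, "m": rng.normal(size=len(pops))}
        )
        res = dimorphism_model(df, "m")
        if res.sex[3] < 0.05:
            sex_hits += 1
        if (res.tukey_population["p_adj"] < 0.05).any():
            tukey_hits += 1
    return {"sex_test": sex_hits / n_reps, "tukey_familywise": tukey_hits / n_reps}


def type1_error_mixed_model(
    n_reps: int = 2000, n_individuals: int = 36, seed: int = 0
) -> dict[str, float]:
    """Fixed-effect tests of the plant-contrast LMM under a matched null.

    The simulated design is structurally matched to the focal cohort:
    individuals balanced over two sexes and three populations, each scored
    against three plant types, with a true between-individual random
    intercept (the default size is a half-cohort, which keeps 2,000
    replicates affordable; the between-individual tests are exact-F at any
    size). All labels are
    independent of the response, so each term's test should reject at ~5%.
    """
    rng = np.random.default_rng(seed)
    plants = ["leaf", "flower_a", "flower_b"]
    hits = {"sex": 0, "population": 0, "plant_type": 0}
    for _ in range(n_reps):
        rows = []
        for i in range(n_individuals):
            sex = "M" if i % 2 else "F"
            pop = f"p{(i // 2) % 3}"
            b = rng.normal(0.0, 1.0)
            for pt in plants:
                rows.append(
                    {
                        "specimen_id": f"S{i:03d}",
                        "sex": sex,
                        "population": pop,
                        "plant_type": pt,
                        "chromatic_jnd": 10.0 + b + rng.normal(0.0, 1.0),
                    }
                )
        res = plant_contrast_mixed_model(pd.DataFrame(rows), "chromatic")
        for term in hits:
            if res.tests[term][2] < 0.05:
                hits[term] += 1
    return {term: h / n_reps for term, h in hits.items()}


def slope_sign_recovery(
    n_reps: int = 400,
    n: int = 25,
    slope: float = 0.6,
    seed: int = 0,
    target_metric: str = "fw_luminance",
) -> float:
    """Fraction of honest-scenario cohorts whose fitted slope sign is correct.

    Cohorts of ``n`` specimens from one population are generated with the
    honesty slope acting on the luminance latent (standardized effect
    ``slope``); recovery means the full within-population model assigns the
    target metric a coefficient of the same sign.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    per_sex = int(np.ceil(n / 2))
    for _ in range(n_reps):
        cfg = ScenarioConfig(
            n_populations=1,
            n_per_pop_per_sex=per_sex,
            honesty_slope=slope,
            target_latent="luminance",
            seed=int(rng.integers(2**31 - 1)),
        )
        cohort = make_cohort(cfg, render_patches=False)
        truth = cohort.truth.iloc[:n]
        predictors = list(METRIC_COLS)
        while True:  # resolve sporadic small-sample collinearity as the pipeline does
            try:
                res = within_population_regression(truth, "saturation",
                                                   predictors=predictors)
                break
            except CollinearityError as err:
                victim = next(p for p in err.predictors if p != target_metric)
                predictors.remove(victim)
        coef = res.full.coefficients.set_index("term").loc[target_metric, "coef"]
        if np.sign(coef) == np.sign(slope):
            hits += 1
    return hits / n_reps
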