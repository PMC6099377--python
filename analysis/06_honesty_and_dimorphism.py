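"""The honesty and dimorphism analyses on the assembled specimen table.

Merges measured colour metrics with measured toxin levels, then runs:
among-population regressions of population means (per sex, on the
11-population survey), within-population stepwise multiple regressions with
VIF and Cook's-distance rules (each focal population), sex x population
models with Tukey HSD per colour metric, and the random-intercept mixed
models for plant-background contrasts (logit-transformed luminance).
Writes the stats tables under results/06_stats/ and prints the headlines.
"""

from pathlib import Path

import pandas as pd

from wingsignal.pipeline import FW_METRICS, HW_METRICS
from wingsignal.stats import (
    CollinearityError,
    among_population_regression,
    dimorphism_model,
    plant_contrast_mixed_model,
    within_population_regression,
)

OUT = Path("results/06_stats")


def load_table(cohort: str) -> pd.DataFrame:
    truth = pd.read_csv(
        "results/01_simulation/honest/"
        + ("cohort_truth.csv" if cohort == "focal" else "survey_truth.csv")
    )
    metrics = pd.read_csv(f"results/03_metrics/metrics_{cohort}.csv")
    toxins = pd.read_csv(f"results/05_toxins/toxins_{cohort}.csv")
    return (
        truth[["specimen_id", "population", "sex", "mass_mg"]]
        .merge(metrics, on="specimen_id")
        .merge(toxins, on="specimen_id")
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    focal, survey = load_table("focal"), load_table("survey")

    rows = []
    for metric in FW_METRICS + HW_METRICS:
        for sex in ("F", "M"):
            res = among_population_regression(survey, metric, sex)
            row = res.to_row()
            row.update({"metric": metric, "sex": sex})
            rows.append(row)
    among = pd.DataFrame(rows)
    among.to_csv(OUT / "among_population.csv", index=False)
    sig = among[among.p < 0.05]
    print(f"among populations (11 pops, per sex): {len(sig)}/{len(among)} "
          f"metric-sex regressions significant at alpha=0.05")

    rows = []
    for pop, group in focal.groupby("population"):
        predictors = ["fw_luminance", "fw_saturation", "fw_chromatic_jnd",
                      "fw_luminance_jnd", "fw_rel_spot_area"]
        dropped = []
        while True:
            try:
                res = within_population_regression(group, "saturation",
                                                   predictors=predictors)
                break
            except CollinearityError as err:
                dropped.append(err.predictors[0])
                predictors.remove(err.predictors[0])
        row = res.minimal.to_row()
        row.update({"population": pop, "outliers": ";".join(map(str, res.outliers)),
                    "dropped_for_collinearity": ";".join(dropped)})
        rows.append(row)
        print(f"within {pop}: minimal model terms [{row['terms']}] "
              f"F={row['F']:.2f} p={row['p']:.3g} adjR2={row['r_squared_adj']:.3f}")
    pd.DataFrame(rows).to_csv(OUT / "within_population.csv", index=False)

    rows, tukeys = [], []
    for metric in FW_METRICS + HW_METRICS:
        res = dimorphism_model(focal, metric)
        rows.append({"metric": metric, "sex_F": res.sex[0], "sex_p": res.sex[3],
                     "population_F": res.population[0], "population_p": res.population[3],
                     "interaction_p": res.interaction[3]})
        t = res.tukey_population.copy()
        t.insert(0, "metric", metric)
        tukeys.append(t)
    dim = pd.DataFrame(rows)
    dim.to_csv(OUT / "dimorphism.csv", index=False)
    pd.concat(tukeys, ignore_index=True).to_csv(OUT / "dimorphism_tukey.csv", index=False)
    sig = dim[dim.sex_p < 0.05].metric.tolist()
    print(f"sex differences (p<0.05) in: {', '.join(sig) if sig else 'none'}")

    contrasts = pd.read_csv("results/04_contrasts/plant_contrasts.csv")
    uvs_contrasts = contrasts[contrasts.system == "UVS"]
    rows = []
    for response in ("chromatic", "luminance"):
        res = plant_contrast_mixed_model(uvs_contrasts, response)
        for term, (chi2, df, p) in res.tests.items():
            rows.append({"response": response, "term": term,
                         "chi2": chi2, "df": df, "p": p})
        print(f"mixed model ({response}): " + ", ".join(
            f"{t} chi2={v[0]:.1f} p={v[2]:.3g}" for t, v in res.tests.items()))
    pd.DataFrame(rows).to_csv(OUT / "mixed_models.csv", index=False)


if __name__ == "__main__":
    main()
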