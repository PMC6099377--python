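"""End-to-end run: simulate, calibrate, map, measure, contrast, quantify, analyse.

The pipeline mirrors a field study of warning-signal honesty in burnet
moths: a focal set of three intensively sampled populations (within-
population honesty tests, dimorphism models, plant-background mixed models)
plus a wider survey of populations sampled more thinly (among-population
regressions on population means). Everything is driven by one master seed
and written as tidy CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import calibrate_patch_table
from .discrimination import background_conspicuousness, chromatic_jnd, luminance_jnd
from .lcms import fit_calibration, peak_area, quantify_specimen
from .metrics import hue_channel, standardize_catches, tetra_saturation
from .spectra import illuminant_d65like, make_camera, make_visual_system
from .stats import (
    CollinearityError,
    among_population_regression,
    dimorphism_model,
    plant_contrast_mixed_model,
    within_population_regression,
)
from .synthetic import (
    ScenarioConfig,
    make_calibration_standards,
    make_chromatogram,
    make_cohort,
    make_reflectance_library,
    render_patch,
    true_channel_reflectance,
)
from .visual import apply_catch_mapping, cone_catch_from_spectrum, fit_catch_mapping

HONESTY_SLOPES = {"honest": 0.6, "null": 0.0, "dishonest": -0.6}

#: plant backgrounds: template family -> label
PLANT_TYPES = {
    "green_leaf": "lotus_leaf",
    "yellow_petal": "lotus_flower",
    "purple_petal": "knautia_flower",
}

#: colour metrics analysed per wing (forewing also has a spot-area measure)
FW_METRICS = (
    "fw_luminance", "fw_saturation", "fw_hue",
    "fw_chromatic_jnd", "fw_luminance_jnd", "fw_rel_spot_area",
)
HW_METRICS = (
    "hw_luminance", "hw_saturation", "hw_hue", "hw_chromatic_jnd", "hw_luminance_jnd",
)

STANDARD_AMOUNTS_NMOL = (2.0, 5.0, 10.0, 20.0, 40.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def catches_table(channels: pd.DataFrame, mapping, channel_names, system) -> pd.DataFrame:
    rows = []
    for _, row in channels.iterrows():
        catch = apply_catch_mapping(mapping, row[list(channel_names)].to_numpy(float))
        rows.append(
            {
                "specimen_id": row["specimen_id"],
                "region": row["region"],
                "area_mm2": row["area_mm2"],
                "system": system.name,
                "q_uv": catch.q[0], "q_sw": catch.q[1],
                "q_mw": catch.q[2], "q_lw": catch.q[3],
                "q_double": catch.double,
            }
        )
    return pd.DataFrame(rows)


def measured_metrics(catches: pd.DataFrame, system) -> pd.DataFrame:
    """Per-specimen wing metrics from mapped catches of the four wing regions."""
    out = []
    for sid, group in catches.groupby("specimen_id", sort=True):
        g = group.set_index("region")
        row = {"specimen_id": sid}
        for wing in ("fw", "hw"):
            red = g.loc[f"{wing}_red"]
            black = g.loc[f"{wing}_black"]
            qr = red[["q_uv", "q_sw", "q_mw", "q_lw"]].to_numpy(float)
            qb = black[["q_uv", "q_sw", "q_mw", "q_lw"]].to_numpy(float)
            rel = standardize_catches(qr)
            row[f"{wing}_luminance"] = float(red["q_double"])
            row[f"{wing}_saturation"] = tetra_saturation(rel)
            row[f"{wing}_hue"] = hue_channel(rel)
            row[f"{wing}_chromatic_jnd"] = chromatic_jnd(qr, qb, system)
            row[f"{wing}_luminance_jnd"] = luminance_jnd(
                float(red["q_double"]), float(black["q_double"]), system.weber_omega
            )
            row[f"{wing}_rel_spot_area"] = float(red["area_mm2"] / black["area_mm2"])
        out.append(row)
    return pd.DataFrame(out)


def render_plants(camera, illum, seed: int, n_per_type: int = 5) -> pd.DataFrame:
    """Photograph leaf/flower samples through the same camera path."""
    rng = np.random.default_rng(seed)
    lib = make_reflectance_library(n_per_type, families=tuple(PLANT_TYPES), seed=rng)
    rows = []
    for i, (fam, spec) in enumerate(lib):
        patch = render_patch(
            spec, camera, illum, gain_jitter=rng.uniform(0.85, 1.15),
            noise_sd=0.002, seed=rng,
        )
        row = {
            "specimen_id": f"plant_{i:02d}",
            "region": "tissue",
            "plant_type": PLANT_TYPES[fam],
            "area_mm2": 1.0,
        }
        for j, ch in enumerate(camera.channel_names):
            row[ch] = patch.channel_values[j]
            row[f"std7_{ch}"] = patch.std7_values[j]
            row[f"std93_{ch}"] = patch.std93_values[j]
        rows.append(row)
    return pd.DataFrame(rows)


def quantify_cohort(truth: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Chromatograms for every specimen plus a standards series; quantify."""
    rng = np.random.default_rng(seed)
    standards = make_calibration_standards(
        np.array(STANDARD_AMOUNTS_NMOL), noise_sd=5.0, rel_noise=0.01, seed=rng
    )
    curves = {}
    for compound in ("linamarin", "lotaustralin"):
        ratios = [peak_area(c, compound) / peak_area(c, "amygdalin") for c in standards]
        curves[compound] = fit_calibration(
            np.array(STANDARD_AMOUNTS_NMOL), np.array(ratios), compound
        )
    rows = []
    for _, spec in truth.iterrows():
        chrom = make_chromatogram(
            {
                "linamarin": spec["linamarin_nmol"],
                "lotaustralin": spec["lotaustralin_nmol"],
            },
            drift=float(np.exp(rng.normal(0.0, 0.1))),
            noise_sd=5.0,
            rel_noise=0.01,
            seed=rng,
            specimen_id=spec["specimen_id"],
        )
        tox = quantify_specimen(chrom, curves, float(spec["mass_mg"]))
        rows.append(
            {
                "specimen_id": tox.specimen_id,
                "linamarin_nmol": tox.linamarin_nmol,
                "lotaustralin_nmol": tox.lotaustralin_nmol,
                "total_nmol": tox.total_nmol,
                "concentration_nmol_per_mg": tox.concentration_nmol_per_mg,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    seed: int,
    outdir: str | Path | None = None,
    scenario: str = "honest",
    n_focal_per_pop_per_sex: int = 12,
    n_survey_pops: int = 11,
    n_survey_per_pop_per_sex: int = 4,
    systems: tuple[str, ...] = ("UVS", "VS"),
) -> dict[str, pd.DataFrame]:
    """Run the whole measurement and analysis chain under one master seed.

    Returns the result tables keyed by name and, if ``outdir`` is given,
    writes each as ``<name>.csv`` plus a small JSON manifest of the seeds
    used. Deterministic: the same seed yields byte-identical CSVs.
    """
    if scenario not in HONESTY_SLOPES:
        raise ValueError(f"scenario must be one of {sorted(HONESTY_SLOPES)}")
    seeds = _child_seeds(seed, 6)
    camera = make_camera()
    illum = illuminant_d65like()
    sys_objs = {name: make_visual_system(name) for name in systems}
    primary = sys_objs[systems[0]]

    focal_cfg = ScenarioConfig(
        n_populations=3,
        n_per_pop_per_sex=n_focal_per_pop_per_sex,
        honesty_slope=HONESTY_SLOPES[scenario],
        seed=seeds[0],
    )
    survey_cfg = ScenarioConfig(
        n_populations=n_survey_pops,
        n_per_pop_per_sex=n_survey_per_pop_per_sex,
        honesty_slope=HONESTY_SLOPES[scenario],
        seed=seeds[1],
    )
    focal = make_cohort(focal_cfg, camera, illum, primary)
    survey = make_cohort(survey_cfg, camera, illum, primary)
    plants_raw = render_plants(camera, illum, seeds[2])

    # calibrate every photographed patch to reflectance-scale channels
    chan_cols = camera.channel_names
    focal_chan = calibrate_patch_table(focal.patches, chan_cols)
    survey_chan = calibrate_patch_table(survey.patches, chan_cols)
    plant_chan = calibrate_patch_table(plants_raw, chan_cols)

    # one polynomial catch mapping per visual system, trained on a broad library
    train = [s for _, s in make_reflectance_library(48, seed=seeds[3])]
    tables: dict[str, pd.DataFrame] = {
        "cohort_truth": focal.truth,
        "survey_truth": survey.truth,
        "patches_raw": focal.patches,
        "channels_normalized": focal_chan,
    }
    catches_all, metrics_by_system = [], {}
    plant_contrast_frames = []
    for name, system in sys_objs.items():
        mapping = fit_catch_mapping(train, camera, illum, system)
        fc = catches_table(focal_chan, mapping, chan_cols, system)
        sc = catches_table(survey_chan, mapping, chan_cols, system)
        pc = catches_table(plant_chan, mapping, chan_cols, system)
        pc["plant_type"] = plant_chan["plant_type"].to_numpy()
        catches_all.append(pd.concat([fc, sc], ignore_index=True))
        metrics_by_system[name] = {
            "focal": measured_metrics(fc, system),
            "survey": measured_metrics(sc, system),
        }
        fw_red = fc[fc["region"] == "fw_red"]
        contr = background_conspicuousness(fw_red, pc, system)
        plant_contrast_frames.append(contr)
    tables["catches"] = pd.concat(catches_all, ignore_index=True)
    plant_contrasts = pd.concat(plant_contrast_frames, ignore_index=True).merge(
        focal.truth[["specimen_id", "population", "sex"]], on="specimen_id"
    )
    tables["plant_contrasts"] = plant_contrasts

    toxins = quantify_cohort(focal.truth, seeds[4])
    survey_toxins = quantify_cohort(survey.truth, seeds[5])
    tables["toxins"] = toxins

    meta_cols = ["specimen_id", "population", "sex", "mass_mg"]
    primary_name = systems[0]
    specimen_table = (
        focal.truth[meta_cols]
        .merge(metrics_by_system[primary_name]["focal"], on="specimen_id")
        .merge(toxins, on="specimen_id")
    )
    survey_table = (
        survey.truth[meta_cols]
        .merge(metrics_by_system[primary_name]["survey"], on="specimen_id")
        .merge(survey_toxins, on="specimen_id")
    )
    tables["specimen_table"] = specimen_table
    tables["survey_table"] = survey_table

    # --- statistics -------------------------------------------------------
    among_rows = []
    for metric in FW_METRICS + HW_METRICS:
        for sex in ("F", "M"):
            res = among_population_regression(survey_table, metric, sex)
            row = res.to_row()
            row.update({"metric": metric, "sex": sex})
            among_rows.append(row)
    tables["stats_among_population"] = pd.DataFrame(among_rows)

    within_rows = []
    base_predictors = [
        "fw_luminance", "fw_saturation", "fw_chromatic_jnd",
        "fw_luminance_jnd", "fw_rel_spot_area",
    ]
    for pop, group in specimen_table.groupby("population", sort=True):
        predictors = list(base_predictors)
        dropped = []
        # collinear metric pairs are resolved by keeping only one member,
        # exactly as saturation/hue are never offered together
        while True:
            try:
                res = within_population_regression(group, "saturation",
                                                   predictors=predictors)
                break
            except CollinearityError as err:
                victim = err.predictors[0]
                predictors.remove(victim)
                dropped.append(victim)
        for label, fit in (("full", res.full), ("minimal", res.minimal)):
            row = fit.to_row()
            row.update({"population": pop, "model": label,
                        "outliers_flagged": ";".join(map(str, res.outliers)),
                        "dropped_for_collinearity": ";".join(dropped)})
            within_rows.append(row)
    tables["stats_within_population"] = pd.DataFrame(within_rows)

    dim_rows, tukey_rows = [], []
    for metric in FW_METRICS + HW_METRICS:
        res = dimorphism_model(specimen_table, metric)
        dim_rows.append(
            {
                "metric": metric,
                "interaction_F": res.interaction[0], "interaction_p": res.interaction[3],
                "interaction_kept": res.interaction_kept,
                "sex_F": res.sex[0], "sex_df1": res.sex[1],
                "sex_df2": res.sex[2], "sex_p": res.sex[3],
                "population_F": res.population[0], "population_p": res.population[3],
                "r_squared_adj": res.model.r_squared_adj,
            }
        )
        t = res.tukey_population.copy()
        t.insert(0, "metric", metric)
        tukey_rows.append(t)
    tables["stats_dimorphism"] = pd.DataFrame(dim_rows)
    tables["stats_dimorphism_tukey"] = pd.concat(tukey_rows, ignore_index=True)

    mm_rows, mm_tukey = [], []
    uvs_contrasts = plant_contrasts[plant_contrasts["system"] == primary_name]
    for response in ("chromatic", "luminance"):
        res = plant_contrast_mixed_model(uvs_contrasts, response)
        for term, (chi2, df, p) in res.tests.items():
            mm_rows.append(
                {"response": response, "term": term, "chi2": chi2, "df": df, "p": p,
                 "chi2_asymptotic_p": res.chi2_p[term],
                 "random_intercept_var": res.random_intercept_var,
                 "residual_var": res.residual_var}
            )
        for term, table in res.tukey.items():
            t = table.copy()
            t.insert(0, "term", term)
            t.insert(0, "response", response)
            mm_tukey.append(t)
    tables["stats_mixed_model"] = pd.DataFrame(mm_rows)
    tables["stats_mixed_model_tukey"] = pd.concat(mm_tukey, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "seed": seed,
            "scenario": scenario,
            "child_seeds": seeds,
            "systems": list(systems),
            "tables": sorted(tables),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return tables
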