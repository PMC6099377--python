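"""Simulate the study's raw inputs under three honesty scenarios.

Generates, for each scenario (honest / null / dishonest): a focal cohort of
three populations (12 per sex per population), a wider 11-population survey
cohort, the raw 4-channel camera patches with in-frame grey standards, and
photographed plant backgrounds. Writes tidy CSVs under
results/01_simulation/<scenario>/ and prints cohort summaries.
"""

import sys
from pathlib import Path

import numpy as np

from wingsignal.pipeline import HONESTY_SLOPES, render_plants
from wingsignal.spectra import illuminant_d65like, make_camera, make_visual_system
from wingsignal.synthetic import ScenarioConfig, make_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/01_simulation")


def main() -> None:
    camera = make_camera()
    illum = illuminant_d65like()
    uvs = make_visual_system("UVS")
    seeds = np.random.SeedSequence(SEED).generate_state(10) % (2**31 - 1)
    for i, (scenario, slope) in enumerate(sorted(HONESTY_SLOPES.items())):
        out = OUT / scenario
        out.mkdir(parents=True, exist_ok=True)
        focal = make_cohort(
            ScenarioConfig(3, 12, honesty_slope=slope, seed=int(seeds[2 * i])),
            camera, illum, uvs,
        )
        survey = make_cohort(
            ScenarioConfig(11, 4, honesty_slope=slope, seed=int(seeds[2 * i + 1])),
            camera, illum, uvs,
        )
        focal.truth.to_csv(out / "cohort_truth.csv", index=False)
        focal.patches.to_csv(out / "patches_raw.csv", index=False)
        survey.truth.to_csv(out / "survey_truth.csv", index=False)
        survey.patches.to_csv(out / "survey_patches_raw.csv", index=False)
        t = focal.truth
        r = np.corrcoef(np.log(t.concentration_nmol_per_mg), t.fw_luminance)[0, 1]
        print(
            f"{scenario:10s} slope={slope:+.1f}: {len(t)} focal + {len(survey.truth)} "
            f"survey specimens; corr(log conc, FW luminance) = {r:+.2f}; "
            f"mass F/M = {t[t.sex == 'F'].mass_mg.mean():.0f}/"
            f"{t[t.sex == 'M'].mass_mg.mean():.0f} mg"
        )
    plants = render_plants(camera, illum, int(seeds[9]))
    plants.to_csv(OUT / "plant_patches_raw.csv", index=False)
    print(f"plant backgrounds: {len(plants)} samples, "
          f"{plants.plant_type.nunique()} tissue types -> {OUT}/plant_patches_raw.csv")


if __name__ == "__main__":
    main()
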