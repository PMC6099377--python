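"""Receptor-noise-limited chromatic and luminance contrast."""

import numpy as np
import pandas as pd
import pytest

from conftest import rnl_distance_oracle
from wingsignal.discrimination import (
    background_conspicuousness,
    chromatic_jnd,
    dichromat_jnd,
    luminance_jnd,
    receptor_noise,
)
from wingsignal.spectra import VisualSystem, lognormal_sensitivity


class TestReceptorNoise:
    def test_most_abundant_cone_carries_omega(self, uvs):
        e = receptor_noise(uvs)
        assert e[3] == pytest.approx(0.05)  # LW is most abundant (2.7)

    def test_uv_cone_noise_hand_value(self, uvs):
        e = receptor_noise(uvs)
        assert e[0] == pytest.approx(0.05 * np.sqrt(2.7 / 1.0))  # ~0.0822

    def test_equal_abundances_give_equal_noise(self):
        s = lognormal_sensitivity(500.0)
        system = VisualSystem("UVS", (s, s, s, s), s, np.ones(4), 0.05)
        np.testing.assert_allclose(receptor_noise(system), 0.05)


class TestChromaticJnd:
    def test_identical_patches_zero(self, uvs):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        assert chromatic_jnd(q, q, uvs) == 0.0

    def test_achromatic_shift_zero(self, uvs):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        assert chromatic_jnd(q, 3.7 * q, uvs) == pytest.approx(0.0, abs=1e-12)

    def test_uv_only_difference_matches_oracle(self, uvs):
        q = np.array([0.2, 0.2, 0.3, 0.4])
        q2 = q.copy()
        q2[0] *= np.exp(0.1)  # ln-ratio 0.1 in the UV channel only
        expected = rnl_distance_oracle(q2, q, receptor_noise(uvs))
        assert chromatic_jnd(q2, q, uvs) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_pairs(self, uvs, vs):
        rng = np.random.default_rng(42)
        for system in (uvs, vs):
            e = receptor_noise(system)
            for _ in range(200):
                qa, qb = rng.uniform(0.01, 1.0, (2, 4))
                assert chromatic_jnd(qa, qb, system) == pytest.approx(
                    rnl_distance_oracle(qa, qb, e), abs=1e-10
                )

    def test_symmetric(self, uvs):
        rng = np.random.default_rng(3)
        qa, qb = rng.uniform(0.01, 1.0, (2, 4))
        assert chromatic_jnd(qa, qb, uvs) == pytest.approx(chromatic_jnd(qb, qa, uvs))

    def test_triangle_inequality_on_random_triples(self, uvs):
        rng = np.random.default_rng(7)
        for _ in range(300):
            qa, qb, qc = rng.uniform(0.01, 1.0, (3, 4))
            dab = chromatic_jnd(qa, qb, uvs)
            dbc = chromatic_jnd(qb, qc, uvs)
            dac = chromatic_jnd(qa, qc, uvs)
            assert dac <= dab + dbc + 1e-10

    def test_monotone_in_single_channel_log_ratio(self, uvs):
        base = np.array([0.2, 0.25, 0.3, 0.35])
        prev = 0.0
        for delta in np.linspace(0.0, 1.0, 11):
            q2 = base.copy()
            q2[0] *= np.exp(delta)
            d = chromatic_jnd(q2, base, uvs)
            assert d >= prev - 1e-12
            prev = d

    def test_reduces_to_dichromat_when_two_receptors_are_noise_swamped(self):
        s = lognormal_sensitivity(500.0)
        # receptors 3 and 4 given vanishing abundance => enormous noise
        system = VisualSystem(
            "UVS", (s, s, s, s), s, np.array([1.0, 1.0, 1e-12, 1e-12]), 0.05
        )
        qa = np.array([0.2, 0.5, 0.3, 0.3])
        qb = np.array([0.35, 0.4, 0.3, 0.3])
        e = receptor_noise(system)
        expected = dichromat_jnd(qa[:2], qb[:2], e[:2])
        assert chromatic_jnd(qa, qb, system) == pytest.approx(expected, rel=1e-9)

    def test_zero_catch_rejected(self, uvs):
        with pytest.raises(ValueError, match="floor"):
            chromatic_jnd(np.array([0.0, 0.1, 0.1, 0.1]), np.full(4, 0.1), uvs)


class TestDichromat:
    def test_closed_form(self):
        qa, qb = np.array([0.4, 0.2]), np.array([0.2, 0.3])
        e = np.array([0.05, 0.1])
        df = np.log(qa / qb)
        expected = abs(df[0] - df[1]) / np.hypot(*e)
        assert dichromat_jnd(qa, qb, e) == pytest.approx(expected)
        assert dichromat_jnd(qa, qb, e) == pytest.approx(
            rnl_distance_oracle(qa, qb, e)
        )


class TestLuminanceJnd:
    def test_equal_is_zero(self):
        assert luminance_jnd(0.3, 0.3, 0.05) == 0.0

    def test_ratio_two_closed_form(self):
        assert luminance_jnd(0.5, 0.25, 0.05) == pytest.approx(np.log(2) / 0.05)

    def test_symmetric(self):
        assert luminance_jnd(0.7, 0.2, 0.05) == luminance_jnd(0.2, 0.7, 0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            luminance_jnd(0.0, 0.5, 0.05)


class TestBackgroundConspicuousness:
    @staticmethod
    def _catch_row(sid, q, double, **extra):
        row = {"specimen_id": sid, "q_uv": q[0], "q_sw": q[1], "q_mw": q[2],
               "q_lw": q[3], "q_double": double}
        row.update(extra)
        return row

    def test_identical_marking_and_plant_gives_zero(self, uvs):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        spec = pd.DataFrame([self._catch_row("a", q, 0.3)])
        plants = pd.DataFrame(
            [self._catch_row(f"p{i}", q, 0.3, plant_type="leaf") for i in range(3)]
        )
        out = background_conspicuousness(spec, plants, uvs)
        assert out.chromatic_jnd.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out.luminance_jnd.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_red_marking_vs_leaf_exceeds_one_jnd(self, illum, uvs):
        from wingsignal.synthetic import green_leaf_spectrum, red_marking_spectrum
        from wingsignal.visual import cone_catch_from_spectrum

        red = cone_catch_from_spectrum(red_marking_spectrum(), illum, uvs)
        leaf = cone_catch_from_spectrum(green_leaf_spectrum(), illum, uvs)
        spec = pd.DataFrame([self._catch_row("m1", red.q, red.double)])
        plants = pd.DataFrame(
            [self._catch_row("p1", leaf.q, leaf.double, plant_type="leaf")]
        )
        out = background_conspicuousness(spec, plants, uvs)
        assert out.chromatic_jnd.iloc[0] > 1.0

    def test_row_cardinality_and_plant_averaging(self, uvs):
        rng = np.random.default_rng(5)
        spec = pd.DataFrame(
            [self._catch_row(f"s{i}", rng.uniform(0.1, 0.9, 4), 0.4) for i in range(4)]
        )
        plants = pd.DataFrame(
            [
                self._catch_row(f"p{i}{t}", rng.uniform(0.1, 0.9, 4), 0.4, plant_type=t)
                for t in ("leaf", "flower")
                for i in range(5)
            ]
        )
        out = background_conspicuousness(spec, plants, uvs)
        assert len(out) == 4 * 2

    def test_empty_plants_rejected(self, uvs):
        spec = pd.DataFrame([self._catch_row("a", np.full(4, 0.2), 0.2)])
        with pytest.raises(ValueError):
            background_conspicuousness(spec, spec.iloc[:0].assign(plant_type=[]), uvs)
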