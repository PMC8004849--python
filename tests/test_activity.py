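"""Activity models: ideal, UNIFAC combinatorial/residual, oracle checks."""

import numpy as np
import pytest

from eutectics.activity import (
    IdealSolution,
    UNIFAC,
    UNIFACParameterTable,
    get_model,
)
from eutectics.compounds import Compound

from reference_unifac import ln_gamma as reference_ln_gamma

ACETONE = Compound(name="acetone", formula={"C": 3, "H": 6, "O": 1},
                   mw=58.08, t_fus=178.5, dh_fus=5.77,
                   unifac_groups={"CH3": 1, "CH3CO": 1})
PENTANE = Compound(name="pentane", formula={"C": 5, "H": 12}, mw=72.15,
                   t_fus=143.5, dh_fus=8.4,
                   unifac_groups={"CH3": 2, "CH2": 3})


class TestIdeal:
    @pytest.mark.parametrize("x,t", [((0.5, 0.5), 298.0), ((1.0, 0.0), 400.0),
                                     ((0.25, 0.75), 150.0)])
    def test_unity_everywhere(self, x, t, registry):
        model = IdealSolution()
        assert np.array_equal(
            model.gamma(x, t, registry["Men:Bor"].compounds),
            np.ones(2))

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            IdealSolution().gamma([0.5, 0.6], 298.0, ())


class TestCombinatorial:
    def test_pure_component_limit_is_zero(self, unifac, registry):
        comps = registry["Men:Bor"].compounds
        ln_c = unifac.ln_gamma_combinatorial([1.0, 0.0], comps)
        assert ln_c[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_size_molecules_have_no_size_term(self, unifac):
        # two molecules with identical subgroup makeup -> identical r, q
        a = Compound(name="a", formula={}, mw=100.0, t_fus=300.0, dh_fus=10.0,
                     unifac_groups={"CH3": 2, "CH2": 4})
        b = Compound(name="b", formula={}, mw=101.0, t_fus=310.0, dh_fus=11.0,
                     unifac_groups={"CH3": 2, "CH2": 4})
        ln_c = unifac.ln_gamma_combinatorial([0.37, 0.63], (a, b))
        assert ln_c == pytest.approx([0.0, 0.0], abs=1e-12)


class TestResidual:
    def test_pure_component_limit_is_zero(self, unifac, registry):
        comps = registry["Thy:Cam"].compounds
        ln_r = unifac.ln_gamma_residual([1.0, 0.0], 298.0, comps)
        assert ln_r[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_interaction_parameters_kill_residual(self, registry):
        # a_mn = 0 for every pair -> psi = 1 -> ln gamma_R = 0
        import pandas as pd
        sub = pd.DataFrame([
            {"subgroup": "CH3", "subgroup_id": 1, "main_id": 1,
             "main_name": "CH2", "R": 0.9011, "Q": 0.848},
            {"subgroup": "CH2", "subgroup_id": 2, "main_id": 1,
             "main_name": "CH2", "R": 0.6744, "Q": 0.540},
            {"subgroup": "OH", "subgroup_id": 14, "main_id": 5,
             "main_name": "OH", "R": 1.0, "Q": 1.2},
            {"subgroup": "CH", "subgroup_id": 3, "main_id": 1,
             "main_name": "CH2", "R": 0.4469, "Q": 0.228},
            {"subgroup": "C", "subgroup_id": 4, "main_id": 1,
             "main_name": "CH2", "R": 0.2195, "Q": 0.0},
        ])
        inter = pd.DataFrame([{"main_i": 1, "main_j": 5, "a_ij": 0.0},
                              {"main_i": 5, "main_j": 1, "a_ij": 0.0}])
        model = UNIFAC(table=UNIFACParameterTable(sub, inter))
        comps = registry["Men:Bor"].compounds
        for x in (0.2, 0.5, 0.8):
            ln_r = model.ln_gamma_residual([x, 1.0 - x], 300.0, comps)
            assert ln_r == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_uncovered_interaction_names_the_pair(self, unifac):
        import pandas as pd
        sub = pd.DataFrame([
            {"subgroup": "CH3", "subgroup_id": 1, "main_id": 1,
             "main_name": "CH2", "R": 0.9011, "Q": 0.848},
            {"subgroup": "OH", "subgroup_id": 14, "main_id": 5,
             "main_name": "OH", "R": 1.0, "Q": 1.2},
        ])
        inter = pd.DataFrame([{"main_i": 1, "main_j": 5, "a_ij": 986.5}])
        model = UNIFAC(table=UNIFACParameterTable(sub, inter))
        a = Compound(name="a", formula={}, mw=100.0, t_fus=300.0,
                     dh_fus=10.0, unifac_groups={"CH3": 2})
        b = Compound(name="b", formula={}, mw=100.0, t_fus=300.0,
                     dh_fus=10.0, unifac_groups={"CH3": 1, "OH": 1})
        with pytest.raises(KeyError, match=r"\(5, 1\)"):
            model.ln_gamma_residual([0.5, 0.5], 300.0, (a, b))


class TestFullModel:
    def test_published_worked_example_acetone_pentane(self, unifac):
        """Dilute acetone in n-pentane at 307 K: gamma ~ (4.99, 1.005)."""
        g = unifac.gamma([0.047, 0.953], 307.0, (ACETONE, PENTANE))
        assert g[0] == pytest.approx(4.99, abs=0.01)
        assert g[1] == pytest.approx(1.005, abs=0.001)

    def test_pure_limits_give_unity_both_ends(self, unifac, registry):
        for label in ("Men:Bor", "Men:Cam", "Thy:Bor", "Thy:Cam"):
            comps = registry[label].compounds
            assert unifac.gamma([1.0, 0.0], 298.0, comps)[0] \
                == pytest.approx(1.0, abs=1e-12)
            assert unifac.gamma([0.0, 1.0], 298.0, comps)[1] \
                == pytest.approx(1.0, abs=1e-12)

    def test_alcohol_pair_stays_near_ideal(self, unifac, registry):
        # two terpene alcohols sharing the same main groups: gamma within
        # a percent of unity across the whole composition range
        comps = registry["Men:Bor"].compounds
        for x in np.linspace(0.01, 0.99, 25):
            g = unifac.gamma([x, 1.0 - x], 290.0, comps)
            assert np.all(g <= 1.01)
            assert np.all(g > 0.99)

    def test_thymol_pairs_show_negative_deviation(self, unifac, registry):
        # phenol-type donor with alcohol/ketone acceptor: gamma < 1 at
        # mid-composition, the signature of a deep-eutectic candidate
        for label in ("Thy:Bor", "Thy:Cam"):
            comps = registry[label].compounds
            g = unifac.gamma([0.5, 0.5], 300.0, comps)
            assert np.all(g < 1.0)

    @pytest.mark.parametrize("pair", [
        ("Men:Bor", 298.0), ("Thy:Cam", 310.0), ("Men:Cam", 285.0),
        ("Thy:Bor", 300.0)])
    def test_equivalence_with_independent_reference_transcription(
            self, unifac, registry, pair):
        """Vectorized implementation vs scalar-loop reference to 1e-6."""
        label, t = pair
        comps = registry[label].compounds
        mols = [dict(c.unifac_groups) for c in comps]
        for x in (0.1, 0.25, 0.5, 0.75, 0.9):
            got = (unifac.ln_gamma_combinatorial([x, 1.0 - x], comps)
                   + unifac.ln_gamma_residual([x, 1.0 - x], t, comps))
            want = reference_ln_gamma(mols, [x, 1.0 - x], t)
            assert got == pytest.approx(want, abs=1e-6)

    def test_gibbs_duhem_consistency(self, unifac, registry):
        """x1 dln(g1)/dx1 + x2 dln(g2)/dx1 ~ 0 across the 0.05...0.95 grid.

        Central differences with step 5e-4 (the residual converges
        quadratically in the step, so the 1e-6 band tests the model, not
        the discretization).
        """
        comps = registry["Thy:Cam"].compounds
        h = 5e-4
        for x1 in np.arange(0.05, 0.96, 0.05):
            lg_plus = np.log(unifac.gamma([x1 + h / 2, 1 - x1 - h / 2],
                                          300.0, comps))
            lg_minus = np.log(unifac.gamma([x1 - h / 2, 1 - x1 + h / 2],
                                           300.0, comps))
            d = (lg_plus - lg_minus) / h
            assert abs(x1 * d[0] + (1 - x1) * d[1]) < 1e-6

    def test_continuous_and_bounded_on_open_interval(self, unifac, registry):
        for label in ("Men:Bor", "Men:Cam", "Thy:Bor", "Thy:Cam"):
            comps = registry[label].compounds
            for t in (250.0, 300.0, 350.0):
                xs = np.linspace(1e-6, 1 - 1e-6, 401)
                g = np.array([unifac.gamma([x, 1 - x], t, comps)
                              for x in xs])
                assert np.all(np.isfinite(g))
                assert np.all(g > 0)
                # no jumps: successive values move smoothly
                assert np.all(np.abs(np.diff(np.log(g), axis=0)) < 0.1)


class TestFactory:
    def test_factory_names(self):
        assert get_model("ideal").name == "ideal"
        assert get_model("unifac").name == "unifac"
        with pytest.raises(ValueError):
            get_model("cosmo-rs")
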