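import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqgdemar import factorial
from fqgdemar.factorial import (
    GroupMedians,
    fit_bilinear,
    group_medians,
    interaction_effect,
    super_ratio,
    transform_super_ratio,
)
from fqgdemar.io_formats import ExpressionMatrix, code_design

from conftest import random_matrix_design


def gm_from_rows(rows):
    return GroupMedians(
        table=pd.DataFrame(rows, columns=["m_pp", "m_pm", "m_mp", "m_mm"])
    )


class TestGroupMedians:
    def test_constant_matrix(self, toy_matrix_design):
        matrix, design = toy_matrix_design
        matrix.values.iloc[:, :] = 5.5
        gm = group_medians(matrix, design)
        assert (gm.table.to_numpy() == 5.5).all()

    def test_median_definition_even_and_odd(self):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(7)],
                "age_years": [80, 80, 80, 80, 30, 30, 30],
                "sex": ["f", "f", "f", "f", "m", "m", "m"],
            }
        )
        design = code_design(meta)
        values = pd.DataFrame(
            [[1, 2, 3, 4, 1, 2, 3]], index=["p"], columns=meta["sample_id"], dtype=float
        )
        with pytest.raises(ValueError, match="no samples"):
            group_medians(ExpressionMatrix(values=values), design)
        # fill the empty cells with one sample each, keeping the medians visible
        meta2 = pd.concat(
            [
                meta,
                pd.DataFrame(
                    {"sample_id": ["x1", "x2"], "age_years": [80, 30], "sex": ["m", "f"]}
                ),
            ],
            ignore_index=True,
        )
        design2 = code_design(meta2)
        values2 = values.copy()
        values2[["x1", "x2"]] = [[9.0, 9.0]]
        gm = group_medians(ExpressionMatrix(values=values2), design2)
        assert gm.table.loc["p", "m_pp"] == 2.5  # median of {1,2,3,4}
        assert gm.table.loc["p", "m_mm"] == 2.0  # median of {1,2,3}

    def test_matches_brute_force_oracle(self):
        matrix, design = random_matrix_design(100, seed=21)
        gm = group_medians(matrix, design)
        for name, (i, j) in factorial.CELLS.items():
            samples = design.samples_in_cell(i, j)
            for probe in matrix.probe_ids:
                vals = sorted(matrix.values.loc[probe, samples])
                n = len(vals)
                oracle = (
                    vals[n // 2]
                    if n % 2
                    else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
                )
                assert gm.table.loc[probe, name] == pytest.approx(oracle, abs=0)


class TestInteractionEffect:
    def test_additive_null_and_hand_value(self):
        gm = gm_from_rows([[7, 7, 7, 7], [10, 8, 7, 9]])
        eff = interaction_effect(gm)
        assert eff.iloc[0] == 0.0
        assert eff.iloc[1] == pytest.approx(2.0)

    def test_swapping_sex_labels_flips_sign(self):
        gm = gm_from_rows([[10, 8, 7, 9]])
        swapped = gm_from_rows([[8, 10, 9, 7]])
        assert interaction_effect(swapped).iloc[0] == -interaction_effect(gm).iloc[0]

    @given(
        st.lists(st.floats(2, 14), min_size=4, max_size=4),
        st.floats(-5, 5),
    )
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_constant_shift(self, medians, c):
        gm = gm_from_rows([medians])
        shifted = gm_from_rows([[m + c for m in medians]])
        assert interaction_effect(shifted).iloc[0] == pytest.approx(
            interaction_effect(gm).iloc[0], abs=1e-9
        )


class TestSuperRatio:
    def test_unity_and_hand_value(self):
        gm = gm_from_rows([[7, 7, 7, 7], [8, 5, 4, 5]])
        sr = super_ratio(gm)
        assert sr["super_ratio"].iloc[0] == pytest.approx(1.0)
        assert sr["super_ratio"].iloc[1] == pytest.approx(2.0)

    def test_two_route_identity(self):
        """Age-ratio route equals sex-ratio route exactly (algebraic)."""
        rng = np.random.default_rng(13)
        rows = rng.uniform(2, 14, size=(500, 4))
        gm = gm_from_rows(rows)
        sr = super_ratio(gm)["super_ratio"]
        t = gm.table
        other = (t["m_pp"] / t["m_pm"]) / (t["m_mp"] / t["m_mm"])
        rel = np.abs(sr - other) / sr
        assert rel.max() <= 1e-12

    def test_scale_invariance(self):
        gm = gm_from_rows([[8, 5, 4, 5]])
        scaled = gm_from_rows([[16, 10, 8, 10]])
        assert super_ratio(scaled)["super_ratio"].iloc[0] == pytest.approx(
            super_ratio(gm)["super_ratio"].iloc[0]
        )

    def test_low_median_probe_flagged_not_dropped(self):
        gm = gm_from_rows([[8, 5, 4, 5], [8, 0.5, 4, 5]])
        sr = super_ratio(gm)
        assert not sr["excluded"].iloc[0]
        assert sr["excluded"].iloc[1]
        assert np.isnan(sr["super_ratio"].iloc[1])
        assert len(sr) == 2


class TestTransform:
    @pytest.mark.parametrize("sr,star", [(2.0, 2.0), (1.0, 1.0), (0.5, -2.0), (0.25, -4.0)])
    def test_branches(self, sr, star):
        assert transform_super_ratio(sr) == pytest.approx(star)

    def test_monotone_across_branches(self):
        xs = [0.1, 0.25, 0.5, 0.9, 1.0, 1.5, 3.0]
        ys = [transform_super_ratio(x) for x in xs]
        assert ys == sorted(ys)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            transform_super_ratio(0.0)
        with pytest.raises(ValueError):
            transform_super_ratio(np.array([2.0, -1.0]))


class TestBilinearFit:
    def test_constant_probe(self, toy_matrix_design):
        matrix, design = toy_matrix_design
        matrix.values.iloc[0, :] = 4.25
        fit = fit_bilinear(matrix, design).table
        assert fit.loc["p0", "mu"] == pytest.approx(4.25)
        for c in ("alpha", "beta", "gamma"):
            assert fit.loc["p0", c] == pytest.approx(0, abs=1e-12)

    def test_balanced_design_quarter_contrast(self, toy_matrix_design):
        """On a balanced design the OLS gamma is the quarter-contrast of
        cell means (normal-equations oracle)."""
        matrix, design = toy_matrix_design
        fit = fit_bilinear(matrix, design).table
        means = {}
        for name, (i, j) in factorial.CELLS.items():
            means[name] = matrix.values[design.samples_in_cell(i, j)].mean(axis=1)
        gamma = 0.25 * ((means["m_pp"] + means["m_mm"]) - (means["m_pm"] + means["m_mp"]))
        assert np.allclose(fit["gamma"], gamma)

    def test_matches_generic_ols_oracle(self):
        matrix, design = random_matrix_design(40, seed=8)
        fit = fit_bilinear(matrix, design).table
        i = design.table["age_code"].to_numpy(float)
        j = design.table["sex_code"].to_numpy(float)
        X = np.column_stack([np.ones_like(i), i, j, i * j])
        for probe in matrix.probe_ids:
            y = matrix.values.loc[probe, design.table["sample_id"]].to_numpy()
            oracle = np.linalg.pinv(X.T @ X) @ X.T @ y
            assert np.allclose(
                fit.loc[probe, ["mu", "alpha", "beta", "gamma"]].to_numpy(), oracle
            )

    def test_rank_deficient_design_rejected(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "age_years": [30, 30, 80, 80],
                "sex": ["m", "m", "f", "f"],  # age and sex confounded
            }
        )
        design = code_design(meta)
        values = pd.DataFrame(
            np.ones((2, 4)), index=["p0", "p1"], columns=meta["sample_id"]
        )
        with pytest.raises(ValueError, match="rank"):
            fit_bilinear(ExpressionMatrix(values=values), design)


class TestSharpRatios:
    def test_identical_groups_give_unity(self, toy_matrix_design):
        matrix, design = toy_matrix_design
        matrix.values.iloc[:, :] = 6.0
        assert (factorial.age_ratio_sharp(matrix, design) == 1.0).all()
        assert (factorial.sex_ratio_sharp(matrix, design) == 1.0).all()

    def test_hand_value_and_up_regulation_sign(self, toy_matrix_design):
        matrix, design = toy_matrix_design
        older = design.table.loc[design.table["age_code"] == 1, "sample_id"]
        younger = design.table.loc[design.table["age_code"] == -1, "sample_id"]
        matrix.values.loc["p0", older] = 8.0
        matrix.values.loc["p0", younger] = 4.0
        ar = factorial.age_ratio_sharp(matrix, design)
        assert ar["p0"] == pytest.approx(2.0)
        assert ar["p0"] > 1  # up-regulated in the Older group

    def test_effect_table_is_complete(self, small_sim):
        matrix, design, _ = small_sim
        table = factorial.effect_table(matrix, design)
        expected = {
            "gene", "m_pp", "m_pm", "m_mp", "m_mm", "interaction_effect",
            "age_ratio_f", "age_ratio_m", "super_ratio", "super_ratio_star",
            "age_ratio_sharp", "sex_ratio_sharp", "mu", "alpha", "beta",
            "gamma", "residual_scale", "excluded",
        }
        assert expected <= set(table.columns)
        assert len(table) == matrix.values.shape[0]
        ok = table["super_ratio"].notna()
        stars = table.loc[ok, "super_ratio_star"]
        assert ((stars >= 1) | (stars <= -1)).all()


class TestSignRecovery:
    def test_injected_interaction_sign_recovered(self):
        """With moderate noise and >= 9 samples per cell the median contrast
        recovers the injected interaction sign nearly always."""
        from fqgdemar.simulate import SimulationConfig, simulate_expression

        cfg = SimulationConfig(
            n_probes=6000, n_genes=5000, frac_age=0, frac_sex=0,
            frac_interaction=0.2, noise_sd=0.5, seed=17,
        )
        matrix, design, gt = simulate_expression(cfg)
        eff = interaction_effect(group_medians(matrix, design))
        affected = gt.table["true_class"].str.startswith("interaction")
        agree = (
            np.sign(eff[affected]) == np.sign(gt.table.loc[affected, "true_effect"])
        ).mean()
        assert agree >= 0.99
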