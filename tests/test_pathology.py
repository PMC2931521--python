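import numpy as np
import pandas as pd
import pytest

from autoassoc import (
    BiasClassification,
    NetworkConfig,
    PathologySpec,
    apply_pathology,
    classify_bias,
    evaluate_config,
    feedback_inhibition_strength,
    generate_cohort,
    interaction_surface,
    prescribe,
    single_pathology_curves,
    tolerable_limits,
    treat_cohort,
    uniform_treatment,
)
from autoassoc.pathology import PROPERTIES


@pytest.fixture
def cfg():
    return NetworkConfig(
        connectivity_level=0.5, g_max_ampa=10.0, gamma_ltd=0.5, relative_inhibition=2.0
    )


class TestApplyPathology:
    def test_identity(self, cfg):
        assert apply_pathology(cfg, PathologySpec()) == cfg

    def test_ltd_doubling(self, cfg):
        out = apply_pathology(cfg, PathologySpec(ltd_factor=2.0))
        assert out.gamma_ltd == pytest.approx(1.0)

    def test_inhibition_factor_halves_ggaba(self, cfg):
        out = apply_pathology(cfg, PathologySpec(inhibition_factor=0.5))
        assert feedback_inhibition_strength(out) == pytest.approx(
            0.5 * feedback_inhibition_strength(cfg)
        )

    def test_ggaba_tracks_ltp_and_connectivity(self, cfg):
        out = apply_pathology(
            cfg, PathologySpec(ltp_factor=2.0, connectivity_delta=0.25)
        )
        expected = out.g_max_ampa * 10 * out.connectivity_level * out.relative_inhibition
        assert feedback_inhibition_strength(out) == pytest.approx(expected)

    def test_connectivity_clipped_to_one(self, cfg):
        out = apply_pathology(cfg, PathologySpec(connectivity_delta=0.9))
        assert out.connectivity_level == 1.0

    def test_nonpositive_connectivity_rejected(self, cfg):
        with pytest.raises(ValueError):
            apply_pathology(cfg, PathologySpec(connectivity_delta=-0.5))

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            PathologySpec(ltp_factor=0.0)
        with pytest.raises(ValueError):
            PathologySpec(inhibition_factor=-1.0)


class TestClassifyBias:
    LIMITS = {"completion": 0.2, "separation": 0.3}

    @staticmethod
    def result(sep, comp):
        return {"separation_error_rate": sep, "completion_error_rate": comp}

    def test_balanced(self):
        assert classify_bias(self.result(0.1, 0.1), self.LIMITS).label == "balanced"

    def test_separation_bias(self):
        # intolerable completion error with clean separation
        assert classify_bias(self.result(0.0, 0.9), self.LIMITS).label == "separation_bias"

    def test_completion_bias(self):
        assert classify_bias(self.result(0.9, 0.0), self.LIMITS).label == "completion_bias"

    def test_both_exceed_larger_relative_exceedance(self):
        # completion exceeds 4x, separation 1.1x -> separation bias
        res = self.result(0.33, 0.8)
        assert classify_bias(res, self.LIMITS).label == "separation_bias"

    def test_limits_from_ensemble_mean(self):
        df = pd.DataFrame({"sep_err": [0.1, 0.3], "comp_err": [0.2, 0.4]})
        limits = tolerable_limits(df)
        assert limits == {"completion": pytest.approx(0.3), "separation": pytest.approx(0.2)}
        plus = tolerable_limits(df, mode="mean+sd")
        assert plus["separation"] > limits["separation"]

    def test_limit_invariant_to_duplicated_networks(self):
        df = pd.DataFrame({"sep_err": [0.1, 0.3], "comp_err": [0.2, 0.4]})
        dup = pd.concat([df, df], ignore_index=True)
        assert tolerable_limits(df) == tolerable_limits(dup)


class TestPrescribe:
    def test_separation_bias_directions(self):
        rx = prescribe(BiasClassification("separation_bias"))
        assert rx == {
            "ltp": "increase",
            "ltd": "decrease",
            "inhibition": "decrease",
            "connectivity": "increase",
        }

    def test_completion_bias_is_elementwise_opposite(self):
        a = prescribe(BiasClassification("separation_bias"))
        b = prescribe(BiasClassification("completion_bias"))
        flip = {"increase": "decrease", "decrease": "increase"}
        assert b == {k: flip[v] for k, v in a.items()}
        assert b["inhibition"] == "increase"

    def test_balanced_empty(self):
        assert prescribe(BiasClassification("balanced")) == {}


class TestSinglePathologyCurves:
    def test_identity_grid_reproduces_baseline(self, optimal_ensemble, table):
        df = single_pathology_curves(
            optimal_ensemble, "ltp", factor_grid=(1.0,), table=table, n_patterns=30
        )
        base = [evaluate_config(c, 30, table) for c in optimal_ensemble]
        assert df.comp_err.iloc[0] == pytest.approx(
            np.mean([r["completion_error_rate"] for r in base])
        )
        assert df.sep_err.iloc[0] == pytest.approx(
            np.mean([r["separation_error_rate"] for r in base])
        )

    @pytest.mark.parametrize(
        "prop,grid,comp_sign",
        [
            ("ltp", (0.5, 1.0, 2.0), -1),          # more LTP -> fewer completion errors
            ("connectivity", (-0.2, 0.0, 0.2), -1),
            ("ltd", (0.5, 1.0, 2.0), +1),          # more LTD -> more completion errors
            ("inhibition", (0.5, 1.0, 2.0), +1),
        ],
    )
    def test_tradeoff_directions(self, optimal_ensemble, table, prop, grid, comp_sign):
        df = single_pathology_curves(
            optimal_ensemble, prop, factor_grid=grid, table=table, n_patterns=30
        )
        comp = df.comp_err.to_numpy()
        sep = df.sep_err.to_numpy()
        if comp_sign < 0:
            assert comp[0] >= comp[1] >= comp[2]
            assert sep[0] <= sep[1] <= sep[2]
        else:
            assert comp[0] <= comp[1] <= comp[2]
            assert sep[0] >= sep[1] >= sep[2]

    def test_unknown_property(self, optimal_ensemble, table):
        with pytest.raises(ValueError, match="unknown property"):
            single_pathology_curves(optimal_ensemble, "sprouting", table=table)


class TestInteractionSurface:
    def test_center_cell_is_baseline(self, optimal_ensemble, table):
        df = interaction_surface(
            optimal_ensemble, ("ltp", "ltd"), grid_a=(0.5, 1.0, 2.0),
            grid_b=(0.5, 1.0, 2.0), table=table, n_patterns=30,
        )
        base = single_pathology_curves(
            optimal_ensemble, "ltp", factor_grid=(1.0,), table=table, n_patterns=30
        )
        center = df[(df.factor_a == 1.0) & (df.factor_b == 1.0)]
        assert center.max_err.iloc[0] == pytest.approx(base.max_err.iloc[0])

    def test_same_direction_pair_exacerbates(self, optimal_ensemble, table):
        # increased LTD and increased inhibition are both completion-impairing
        df = interaction_surface(
            optimal_ensemble, ("ltd", "inhibition"), grid_a=(1.0, 2.0),
            grid_b=(1.0, 2.0), table=table, n_patterns=30,
        )
        get = lambda a, b: df[(df.factor_a == a) & (df.factor_b == b)].max_err.iloc[0]
        assert get(2.0, 2.0) >= get(2.0, 1.0) - 1e-9
        assert get(2.0, 2.0) >= get(1.0, 2.0) - 1e-9

    def test_rescue_exists(self, optimal_ensemble, table):
        """An LTD pathology above tolerable limits is improved >=20% by LTP."""
        df = interaction_surface(
            optimal_ensemble, ("ltd", "ltp"), grid_a=(2.0,),
            grid_b=(0.5, 1.0, 2.0, 4.0), table=table, n_patterns=30,
        )
        untreated = df[df.factor_b == 1.0].max_err.iloc[0]
        best = df.max_err.min()
        assert best <= 0.8 * untreated

    def test_distinct_properties_required(self, optimal_ensemble, table):
        with pytest.raises(ValueError):
            interaction_surface(optimal_ensemble, ("ltp", "ltp"), table=table)


@pytest.fixture(scope="module")
def cohort_setup(optimal_ensemble, table):
    baseline = [evaluate_config(c, 30, table) for c in optimal_ensemble]
    limits = tolerable_limits(baseline)
    cohort = generate_cohort(optimal_ensemble, seed=7)
    return cohort, limits


class TestCohort:
    def test_identity_ranges_reproduce_optimal(self, optimal_ensemble):
        cohort = generate_cohort(
            optimal_ensemble,
            ranges={p: (1.0, 1.0) for p in PROPERTIES},
            seed=0,
        )
        for ind, cfg in zip(cohort, optimal_ensemble):
            assert ind.config == cfg

    def test_seed_determinism(self, optimal_ensemble):
        a = generate_cohort(optimal_ensemble, seed=3)
        b = generate_cohort(optimal_ensemble, seed=3)
        assert [i.config for i in a] == [i.config for i in b]

    def test_range_validation(self, optimal_ensemble):
        with pytest.raises(ValueError):
            generate_cohort(optimal_ensemble, ranges={"ltp": (0.0, 1.0)})

    def test_population_mean_completion_biased(self, cohort_setup, table):
        """The default cohort's mean error profile is a completion bias
        (intolerable separation error), the construction behind the
        population-level rescue by increased inhibition."""
        cohort, limits = cohort_setup
        res = [evaluate_config(i.config, 30, table) for i in cohort]
        mean_profile = {
            "separation_error_rate": np.mean([r["separation_error_rate"] for r in res]),
            "completion_error_rate": np.mean([r["completion_error_rate"] for r in res]),
        }
        assert classify_bias(mean_profile, limits).label == "completion_bias"

    def test_heterogeneity_minority_separation_biased(self, cohort_setup, table):
        cohort, limits = cohort_setup
        labels = [
            classify_bias(evaluate_config(i.config, 30, table), limits).label
            for i in cohort
        ]
        n_comp = labels.count("completion_bias")
        n_sep = labels.count("separation_bias")
        assert n_comp > n_sep  # majority completion-biased
        assert n_sep >= 1      # but heterogeneity produces the other bias too


class TestTreatCohort:
    def test_personalized_never_worsens(self, cohort_setup, table):
        cohort, limits = cohort_setup
        df = treat_cohort(cohort, table, limits, n_patterns=30)
        assert (df.treated_max <= df.untreated_max + 1e-12).all()

    def test_balanced_individual_untouched(self, optimal_ensemble, table):
        baseline = [evaluate_config(c, 30, table) for c in optimal_ensemble]
        # generous limits -> everyone balanced -> no treatment applied
        limits = {"completion": 1.1, "separation": 1.1}
        cohort = generate_cohort(optimal_ensemble, seed=1)
        df = treat_cohort(cohort, table, limits, n_patterns=30)
        assert (df.bias == "balanced").all()
        assert (df.treatment_factor == 1.0).all()
        np.testing.assert_allclose(df.treated_max, df.untreated_max)

    def test_personalized_beats_uniform(self, cohort_setup, table):
        cohort, limits = cohort_setup
        pers = treat_cohort(cohort, table, limits, n_patterns=30)
        unif = uniform_treatment(cohort, table, n_patterns=30)
        assert pers.treated_max.mean() <= unif.treated_max.mean() + 1e-12
        # uniform dosing worsens at least one individual in the default cohort
        assert (unif.treated_max > pers.untreated_max + 1e-12).any()
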