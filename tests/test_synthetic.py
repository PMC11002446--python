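import numpy as np
import pandas as pd
import pytest
from scipy import stats

from causalfoodq.dag import DAG, CycleError
from causalfoodq.synthetic import (
    SCMSpec,
    discretize_ordinal,
    food_template,
    implied_covariance,
    make_scm,
    sample_dataset,
)


class TestMakeScm:
    def test_coefficient_for_non_edge_rejected(self):
        dag = DAG(["A", "B"], [("A", "B")])
        with pytest.raises(ValueError, match="non-edge"):
            make_scm(dag, {("A", "B"): 1.0, ("B", "A"): 1.0})

    def test_missing_coefficient_rejected(self):
        dag = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        with pytest.raises(ValueError, match="without coefficients"):
            make_scm(dag, {("A", "B"): 1.0})

    def test_nonpositive_noise_rejected(self):
        dag = DAG(["A"], [])
        with pytest.raises(ValueError, match="positive"):
            make_scm(dag, {}, {"A": 0.0})

    def test_empty_edges_give_independent_columns(self):
        scm = make_scm(DAG(["A", "B", "C"], []), {})
        n = 20_000
        num = sample_dataset(scm, n, 4).to_numeric()
        corr = num.corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))

    def test_chain_implied_variance(self, chain_scm):
        # Sigma = (I-B)^-T D (I-B)^-1 gives Var(C) = 3 for the unit chain
        sigma = implied_covariance(chain_scm)
        assert sigma.loc["C", "C"] == pytest.approx(3.0)
        assert sigma.loc["A", "C"] == pytest.approx(1.0)


class TestSampling:
    def test_reseeding_reproduces_bit_exactly(self, chain_scm):
        a = sample_dataset(chain_scm, 500, 123).df
        b = sample_dataset(chain_scm, 500, 123).df
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_table(self, chain_scm):
        a = sample_dataset(chain_scm, 500, 123).df
        b = sample_dataset(chain_scm, 500, 124).df
        assert not a.equals(b)

    def test_sample_covariance_matches_closed_form(self, chain_scm):
        n = 50_000
        num = sample_dataset(chain_scm, n, 5).to_numeric()
        emp = num.cov().to_numpy()
        want = implied_covariance(chain_scm).to_numpy()
        rel = np.linalg.norm(emp - want) / np.linalg.norm(want)
        assert rel < 0.02

    def test_dairy_grade_levels(self, dairy_scm):
        ds = sample_dataset(dairy_scm, 5000, 2)
        assert set(ds.df["grade"]) == {"low", "medium", "high"}
        assert ds.kinds["grade"].levels == ("low", "medium", "high")


class TestDiscretizeOrdinal:
    def test_direct_binning(self):
        out = discretize_ordinal([-1.0, 0.5, 2.0], [0.0, 1.0], ["low", "med", "high"])
        assert out.tolist() == ["low", "med", "high"]

    def test_constant_below_first_cut(self):
        out = discretize_ordinal([-5.0] * 4, [0.0, 1.0], ["low", "med", "high"])
        assert set(out) == {"low"}

    def test_nonincreasing_cuts_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            discretize_ordinal([0.0], [1.0, 1.0], ["a", "b", "c"])

    def test_normal_quantile_cuts_give_equal_thirds(self):
        n = 30_000
        x = np.random.default_rng(0).normal(size=n)
        cuts = [stats.norm.ppf(1 / 3), stats.norm.ppf(2 / 3)]
        out = discretize_ordinal(x, cuts, ["a", "b", "c"])
        freq = pd.Series(out).value_counts(normalize=True)
        assert np.all(np.abs(freq.to_numpy() - 1 / 3) < 3 / np.sqrt(n))


class TestTemplates:
    def test_dairy_grade_parents(self, dairy_scm):
        assert set(dairy_scm.dag.parents("grade")) == {
            "temperature", "turbidity", "odour", "fat",
        }
        assert set(dairy_scm.dag.parents("taste")) == {"temperature", "colour", "fat"}

    def test_wheat_ten_causes_of_quality(self):
        scm = food_template("wheat")
        obs = scm.observed_dag()
        g = obs.to_networkx()
        import networkx as nx

        causes = nx.ancestors(g, "volume")
        assert len(causes) == 10
        assert len(obs.nodes) == 46  # 45 predictors + volume

    def test_wine_effect_signs(self, wine_scm):
        coeffs = wine_scm.mechanism_of("quality").coeff_map()
        assert coeffs["alcohol"] > 0
        assert coeffs["volatile_acidity"] < 0
        assert wine_scm.kind_of("quality").labels == tuple(str(i) for i in range(1, 11))

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="unknown template"):
            food_template("cheese")

    @pytest.mark.parametrize("name", ["wheat", "dairy", "wine"])
    def test_templates_acyclic_and_json_roundtrip(self, name):
        scm = food_template(name)
        back = SCMSpec.from_json(scm.to_json())
        assert back.dag == scm.dag
        assert dict(back.noise_sd) == dict(scm.noise_sd)
        a = sample_dataset(scm, 50, 1).df
        b = sample_dataset(back, 50, 1).df
        pd.testing.assert_frame_equal(a, b)
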