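import numpy as np
import pytest

from causalfoodq.causal import (
    ace_adjusted,
    backdoor_sets,
    d_separated,
    do_curve,
    path_coefficients,
    total_effect,
)
from causalfoodq.dag import DAG
from causalfoodq.exact import (
    d_separated_bruteforce,
    minimal_backdoor_sets_bruteforce,
    random_dag,
)
from causalfoodq.synthetic import make_scm, sample_dataset

CHAIN = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
COLLIDER = DAG(["A", "B", "C"], [("A", "C"), ("B", "C")])


class TestDSeparation:
    def test_chain(self):
        assert d_separated(CHAIN, {"A"}, {"C"}, {"B"})
        assert not d_separated(CHAIN, {"A"}, {"C"}, set())

    def test_collider(self):
        assert d_separated(COLLIDER, {"A"}, {"B"}, set())
        assert not d_separated(COLLIDER, {"A"}, {"B"}, {"C"})

    def test_collider_descendant_opens_path(self):
        dag = DAG(["A", "B", "C", "D"], [("A", "C"), ("B", "C"), ("C", "D")])
        assert d_separated(dag, {"A"}, {"B"}, set())
        assert not d_separated(dag, {"A"}, {"B"}, {"D"})

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            d_separated(CHAIN, {"A"}, {"A"}, set())

    def test_symmetry_and_local_markov(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            dag = random_dag([f"v{i}" for i in range(6)], 0.4, rng)
            nodes = list(dag.nodes)
            x, y = nodes[0], nodes[1]
            z = set(nodes[2:4])
            assert d_separated(dag, {x}, {y}, z) == d_separated(dag, {y}, {x}, z)
            # local Markov: parents separate a node from non-descendant non-parents
            for v in nodes:
                others = (
                    set(nodes)
                    - {v}
                    - set(dag.parents(v))
                    - set(dag.descendants(v))
                )
                if others:
                    assert d_separated(dag, {v}, others, set(dag.parents(v)))

    def test_agrees_with_bruteforce_on_random_dags(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            k = int(rng.integers(3, 9))
            dag = random_dag([f"v{i}" for i in range(k)], float(rng.uniform(0.2, 0.5)), rng)
            nodes = list(dag.nodes)
            for _ in range(10):
                x, y = rng.choice(nodes, size=2, replace=False)
                rest = [v for v in nodes if v not in (x, y)]
                z = set(rng.choice(rest, size=min(len(rest), int(rng.integers(0, 3))), replace=False))
                assert d_separated(dag, {x}, {y}, z) == d_separated_bruteforce(
                    dag, {x}, {y}, z
                )


class TestBackdoor:
    def test_triangle_confounder(self):
        dag = DAG(["Z", "T", "Y"], [("Z", "T"), ("Z", "Y"), ("T", "Y")])
        sets = backdoor_sets(dag, "T", "Y")
        assert sets[0].conditioning == frozenset({"Z"})
        assert sets[0].minimal

    def test_exogenous_treatment_needs_nothing(self):
        dag = DAG(["T", "Y", "M"], [("T", "M"), ("M", "Y")])
        sets = backdoor_sets(dag, "T", "Y")
        assert sets[0].conditioning == frozenset()

    def test_matches_bruteforce_on_random_dags(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            dag = random_dag([f"v{i}" for i in range(6)], 0.35, rng)
            nodes = list(dag.nodes)
            t, o = nodes[0], nodes[-1]
            mine = sorted(
                tuple(sorted(s.conditioning)) for s in backdoor_sets(dag, t, o)
            )
            brute = sorted(
                tuple(sorted(s)) for s in minimal_backdoor_sets_bruteforce(dag, t, o)
            )
            assert mine == brute


class TestLinearEffects:
    def test_single_edge_coefficient_recovered(self):
        dag = DAG(["A", "B"], [("A", "B")])
        scm = make_scm(dag, {("A", "B"): 0.7}, {"A": 1.0, "B": np.sqrt(1 - 0.49)})
        ds = sample_dataset(scm, 10_000, 0)
        pc = path_coefficients(ds, dag)
        est, se = pc[("A", "B")]
        assert est == pytest.approx(0.70, abs=0.03)
        assert 0 < se < 0.02

    def test_edgeless_dag_gives_empty_map(self, chain_scm):
        ds = sample_dataset(chain_scm, 200, 1)
        assert path_coefficients(ds, DAG(["A", "B", "C"], [])) == {}

    def test_total_effect_path_arithmetic(self):
        dag = DAG(["T", "M", "Y"], [("T", "M"), ("M", "Y"), ("T", "Y")])
        pc = {("T", "M"): (0.5, 0.0), ("M", "Y"): (0.4, 0.0), ("T", "Y"): (0.3, 0.0)}
        eff = total_effect(dag, pc, "T", "Y")
        assert eff.estimate == pytest.approx(0.5)
        assert eff.se == 0.0

    def test_no_path_gives_zero(self):
        dag = DAG(["T", "Y"], [])
        assert total_effect(dag, {}, "T", "Y").estimate == 0.0

    def test_path_sum_matches_interventional_sampling(self):
        # 6-node SCM: compare the path-sum against a randomized-do experiment
        nodes = ["u", "t", "m1", "m2", "y", "w"]
        edges = [("u", "t"), ("u", "y"), ("t", "m1"), ("t", "m2"),
                 ("m1", "y"), ("m2", "y"), ("w", "m2")]
        coeffs = {("u", "t"): 0.6, ("u", "y"): 0.5, ("t", "m1"): 0.7,
                  ("t", "m2"): -0.4, ("m1", "y"): 0.5, ("m2", "y"): 0.6, ("w", "m2"): 0.3}
        scm = make_scm(DAG(nodes, edges), coeffs)
        ds = sample_dataset(scm, 40_000, 3)
        pc = path_coefficients(ds, scm.dag, standardize=False)
        eff = total_effect(scm.dag, pc, "t", "y")
        # oracle: sever t's incoming edges and randomize it
        do_edges = [e for e in edges if e[1] != "t"]
        do_coeffs = {e: c for e, c in coeffs.items() if e[1] != "t"}
        do_scm = make_scm(DAG(nodes, do_edges), do_coeffs)
        do_ds = sample_dataset(do_scm, 40_000, 4).to_numeric()
        slope = np.polyfit(do_ds["t"], do_ds["y"], 1)[0]
        slope_se = np.sqrt(1.0 / len(do_ds))  # conservative order-of-magnitude se
        assert abs(eff.estimate - slope) < 2 * (eff.se + slope_se)


class TestAceAdjusted:
    def test_null_effect_recovered(self):
        dag = DAG(["T", "Y", "Z"], [("Z", "Y"), ("T", "Y")])
        scm = make_scm(dag, {("Z", "Y"): 1.0, ("T", "Y"): 0.0})
        inside = 0
        for s in range(10):
            ds = sample_dataset(scm, 5000, s)
            eff = ace_adjusted(ds, dag, "T", "Y", standardize=False)
            inside += abs(eff.estimate) < 2 * eff.se
        assert inside >= 8  # ~95% coverage of the planted null

    def test_confounding_removed(self, confounded_scm):
        ds = sample_dataset(confounded_scm, 5000, 6)
        num = ds.to_numeric()
        naive = np.polyfit(num["T"], num["Y"], 1)[0]
        # omitted-variable oracle: naive = 0.5 + Cov(T,Z)/Var(T) = 1.0
        assert naive == pytest.approx(1.0, abs=0.06)
        eff = ace_adjusted(ds, confounded_scm.dag, "T", "Y", standardize=False)
        assert eff.estimate == pytest.approx(0.5, abs=2 * eff.se)
        assert eff.adjustment == frozenset({"Z"})

    def test_invalid_adjustment_refused_with_path(self, confounded_scm):
        ds = sample_dataset(confounded_scm, 500, 7)
        with pytest.raises(ValueError, match="open backdoor path"):
            ace_adjusted(ds, confounded_scm.dag, "T", "Y", adjustment=[])


class TestDoCurve:
    def test_linear_scm_gives_straight_line(self, confounded_scm):
        ds = sample_dataset(confounded_scm, 4000, 8)
        curve = do_curve(ds, confounded_scm.dag, "T", "Y", n_members=10, seed=0)
        coef = np.polyfit(curve.grid, curve.mean, 1)
        fitted = np.polyval(coef, curve.grid)
        ss_res = ((curve.mean - fitted) ** 2).sum()
        ss_tot = ((curve.mean - curve.mean.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.99
        assert np.all(np.abs(curve.ace - 0.5) < 0.15)
        assert np.all(curve.lower <= curve.mean) and np.all(curve.mean <= curve.upper)

    def test_extrapolation_flagged(self, confounded_scm):
        ds = sample_dataset(confounded_scm, 1000, 9)
        with pytest.warns(UserWarning, match="outside the observed support"):
            curve = do_curve(
                ds, confounded_scm.dag, "T", "Y",
                grid=np.linspace(-50, 50, 5), n_members=3, seed=0,
            )
        assert curve.extrapolated[0] and curve.extrapolated[-1]

    def test_derivative_consistent_with_mean(self, confounded_scm):
        ds = sample_dataset(confounded_scm, 2000, 10)
        curve = do_curve(ds, confounded_scm.dag, "T", "Y", n_members=5, seed=1)
        inner = (curve.mean[2:] - curve.mean[:-2]) / (curve.grid[2:] - curve.grid[:-2])
        assert np.allclose(curve.ace[1:-1], inner, atol=1e-10)
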