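import numpy as np
import pytest

from causalfoodq.dag import DAG
from causalfoodq.synthetic import Transform, food_template, make_scm, sample_dataset


@pytest.fixture(scope="session")
def chain_scm():
    """A -> B -> C with unit coefficients and unit noise."""
    dag = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
    return make_scm(dag, {("A", "B"): 1.0, ("B", "C"): 1.0})


@pytest.fixture(scope="session")
def confounded_scm():
    """T = Z + e, Y = 0.5 T + Z + u (unit noises): naive slope is biased to 1."""
    dag = DAG(["Z", "T", "Y"], [("Z", "T"), ("Z", "Y"), ("T", "Y")])
    return make_scm(dag, {("Z", "T"): 1.0, ("Z", "Y"): 1.0, ("T", "Y"): 0.5})


@pytest.fixture(scope="session")
def saturating_scm():
    """Confounded treatment with a saturating response breaking at T = 60."""
    dag = DAG(["Z", "T", "Y"], [("Z", "T"), ("Z", "Y"), ("T", "Y")])
    return make_scm(
        dag,
        {("Z", "T"): 6.0, ("Z", "Y"): 0.8, ("T", "Y"): -3.0},
        {"Z": 1.0, "T": 10.0, "Y": 0.5},
        intercepts={"T": 47.0},
        transforms={("T", "Y"): Transform("saturating", center=60.0, scale=5.0)},
        name="saturating",
    )


@pytest.fixture(scope="session")
def dairy_scm():
    return food_template("dairy")


@pytest.fixture(scope="session")
def dairy_data(dairy_scm):
    return sample_dataset(dairy_scm, 5000, 11)


@pytest.fixture(scope="session")
def wine_scm():
    return food_template("wine")
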