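import pytest

import lineup2ht as l2


@pytest.fixture(scope="session")
def exp1():
    """Base spec and observed counts of the 3-vs-6-person study."""
    return l2.table1(1)


@pytest.fixture(scope="session")
def exp2():
    """Base spec and observed counts of the 2-vs-5-person study."""
    return l2.table1(2)


@pytest.fixture(scope="session")
def exp1_base_fit(exp1):
    spec, data = exp1
    return l2.fit(spec, data, l2.FitOptions(seed=0))


@pytest.fixture(scope="session")
def exp2_base_fit(exp2):
    spec, data = exp2
    return l2.fit(spec, data, l2.FitOptions(seed=0))


def small_condition(label="a", size=3, n=100, fmt="sequential"):
    return l2.LineupCondition(
        label=label, lineup_format=fmt, lineup_size=size, n_participants=n
    )


@pytest.fixture
def guessing_only_spec():
    """One condition, b and dA fixed to 0, free dP and g.

    This sub-model has a closed-form MLE, making it the workhorse for
    optimizer-vs-oracle checks.
    """
    cond = small_condition()
    return l2.ModelSpec(
        conditions=(cond,),
        restrictions={
            ("dP", "a"): "dP",
            ("g", "a"): "g",
            ("b", "a"): 0.0,
            ("dA", "a"): 0.0,
        },
        free_parameter_names=("dP", "g"),
    )
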