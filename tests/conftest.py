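import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    settings(max_examples=40, deadline=None, derandomize=True,
             suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def separated_table():
    """Decision table of the well-separated synthetic cohort (n=120)."""
    from respgran.experiments import separated_cohort_table

    return separated_cohort_table(n=120, seed=0)


@pytest.fixture(scope="session")
def consistent_toy_table():
    """Consistent 3-class table over two discrete attributes."""
    import numpy as np
    import pandas as pd

    rng = np.random.default_rng(1)
    t = pd.DataFrame({"u": rng.choice(list("lmh"), 30),
                      "v": rng.choice(list("xy"), 30)})
    dec_map = {("l", "x"): "A", ("l", "y"): "A", ("m", "x"): "B",
               ("m", "y"): "C", ("h", "x"): "C", ("h", "y"): "B"}
    t["decision"] = [dec_map[(u, v)] for u, v in zip(t.u, t.v)]
    return t
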