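import numpy as np
import pytest

from dalyvol.synthetic import PopulationSpec, TrendSpec, gen_burden_table


def cox_de_boor(t, j, k, x):
    """Brute-force Cox-de Boor recurrence, independent of scipy.

    Zero-degree functions are indicators of [t_j, t_{j+1}); the last
    nonempty interval is treated as closed so that the basis partitions
    unity on the whole boundary interval.
    """
    if k == 0:
        if t[j] <= x < t[j + 1]:
            return 1.0
        # closed right end of the last nonempty interval
        if x == t[-1] and t[j] < t[j + 1] and t[j + 1] == t[-1]:
            return 1.0
        return 0.0
    out = 0.0
    d1 = t[j + k] - t[j]
    if d1 > 0:
        out += (x - t[j]) / d1 * cox_de_boor(t, j, k - 1, x)
    d2 = t[j + k + 1] - t[j + 1]
    if d2 > 0:
        out += (t[j + k + 1] - x) / d2 * cox_de_boor(t, j + 1, k - 1, x)
    return out


@pytest.fixture(scope="session")
def small_world():
    """A 4+6-country noiseless world: exact ledger, fast to aggregate."""
    pop = PopulationSpec(
        n_low=4, n_high=6,
        female_dominant_frac={"low": 0.5, "high": 0.5},
    )
    trends = {
        "low": TrendSpec("exponential-decline", start=5000.0, rate=0.03),
        "high": TrendSpec("u-shape", start=120.0, floor=90.0, turn_year=1998),
    }
    records, ledger = gen_burden_table(pop, trends, (1990, 2017), seed=7)
    return records, ledger


@pytest.fixture(scope="session")
def noisy_sdi_data():
    """A fixed noisy (x, Y) dataset for fit/selection tests."""
    rng = np.random.default_rng(42)
    x = np.linspace(0.0, 1.0, 28)
    y = 3200 - 3000 * x - 1000 * x**2 + 1800 * x**3 + rng.normal(0, 70.0, x.size)
    return x, y
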