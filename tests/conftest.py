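import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mpaeval.surveys import NONE_SPECIES

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_records(rows):
    """Build a survey DataFrame from compact tuples.

    Each row: (site, zone, year, transect, group, species, count,
    length_cm, temperature, visibility, depth) — trailing fields
    optional.
    """
    cols = ["site", "zone", "year", "transect", "group", "species",
            "count", "length_cm", "temperature", "visibility", "depth"]
    full = [tuple(r) + (None,) * (len(cols) - len(r)) for r in rows]
    df = pd.DataFrame(full, columns=cols)
    for c in ("length_cm", "temperature", "visibility", "depth"):
        df[c] = pd.to_numeric(df[c])
    return df


@pytest.fixture
def toy_records():
    """4 transects x 2 zones x 2 years, 2 invertebrate species."""
    rows = []
    for zone in ("control", "reserve"):
        for year in (2005, 2007):
            for t in range(1, 5):
                rows.append((f"{zone}_s", zone, year, f"T{t}", "invertebrate",
                             "snail", 3 + t, None, 18.0, 8.0, 10.0))
                rows.append((f"{zone}_s", zone, year, f"T{t}", "invertebrate",
                             "urchin", 10, None, 18.0, 8.0, 10.0))
    return make_records(rows)


@pytest.fixture
def empty_transect_records():
    rows = [
        ("s", "control", 2005, "T1", "fish", "kelp_bass", 2, 20.0, 18, 8, 10),
        ("s", "control", 2005, "T2", "fish", NONE_SPECIES, 0, None, 17, 9, 10),
    ]
    return make_records(rows)


@pytest.fixture
def traits_df():
    return pd.DataFrame({
        "species": ["kelp_bass", "sheephead", "snail", "urchin"],
        "group": ["fish", "fish", "invertebrate", "invertebrate"],
        "lw_a": [0.01, 0.012, np.nan, np.nan],
        "lw_b": [3.0, 3.1, np.nan, np.nan],
        "trophic_level": [4.0, 3.7, np.nan, np.nan],
        "length_at_maturity_cm": [15.0, 20.0, np.nan, np.nan],
        "common_name": ["kelp bass", "sheephead", "snail", "urchin"],
    })


def did_2x2_oracle(table, implementation_year):
    """Textbook DiD: difference of group-mean differences (2 periods)."""
    post = table["year"] >= implementation_year
    res = table["zone"] == "reserve"
    m = lambda a, b: table.loc[a & b, "value"].mean()
    return (m(res, post) - m(res, ~post)) - (m(~res, post) - m(~res, ~post))


def sandwich_oracle(X, resid, flavor):
    """Term-by-term sandwich covariance, deliberately loop-based."""
    X = np.asarray(X, float)
    e = np.asarray(resid, float)
    n, k = X.shape
    xtx = np.zeros((k, k))
    for i in range(n):
        xtx += np.outer(X[i], X[i])
    bread = np.linalg.inv(xtx)
    meat = np.zeros((k, k))
    for i in range(n):
        h_i = X[i] @ bread @ X[i]
        if flavor == "HC0":
            w = 1.0
        elif flavor == "HC1":
            w = n / (n - k)
        elif flavor == "HC2":
            w = 1.0 / (1.0 - h_i)
        else:
            w = 1.0 / (1.0 - h_i) ** 2
        meat += w * e[i] ** 2 * np.outer(X[i], X[i])
    return bread @ meat @ bread
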