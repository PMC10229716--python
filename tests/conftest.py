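"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from riverbaci import SimulationConfig, simulate_experiment
from riverbaci.synthetic_experiment import RESPONDER_CLASSES


def spawn_seeds(base: int, stream: int, n: int) -> np.ndarray:
    """n well-separated 31-bit seeds for Monte-Carlo replicates.

    Sequential-arithmetic seeds (base + i) can yield subtly correlated
    replicate streams; hashing through SeedSequence avoids that.
    """
    return np.random.SeedSequence([base, stream]).generate_state(
        n, dtype=np.uint32
    ) % (2**31)


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A config with no treatment effect in distribution."""
    fractions = {c: 0.0 for c in RESPONDER_CLASSES}
    fractions["non_responder"] = 1.0
    kwargs = dict(seed=seed, treatment_multiplier=1.0,
                  responder_fractions=fractions)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def strong_experiment():
    """Default-size experiment with a clear (4x) treatment effect."""
    return simulate_experiment(SimulationConfig(seed=5, treatment_multiplier=4.0))


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_experiment(SimulationConfig(seed=11, n_taxa=30))


def random_response_table(
    rng: np.random.Generator, r: int = 3, s: int = 2, effect: float = 0.0
) -> pd.DataFrame:
    """A balanced random ResponseTable with r rivers and s sites per cell."""
    rows = []
    for river, treatment, site, period in itertools.product(
        [f"R{i}" for i in range(1, r + 1)],
        ["control", "manipulation"],
        [f"S{j}" for j in range(1, s + 1)],
        ["before", "after"],
    ):
        value = rng.normal(10.0, 2.0)
        if treatment == "manipulation" and period == "after":
            value += effect
        rows.append((river, treatment, site, period, value))
    return pd.DataFrame(rows, columns=["river", "treatment", "site", "period", "value"])


# ---------------------------------------------------------------------------
# independent least-squares projection oracle for the univariate ANOVA


def _hat(D: np.ndarray) -> np.ndarray:
    return D @ np.linalg.pinv(D)


def _dummies(codes: pd.Series) -> np.ndarray:
    return pd.get_dummies(codes).to_numpy(dtype=float)


def projection_anova_oracle(data: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Full-rank projection ANOVA: SS/df/F for every source, via hat matrices.

    Independent of the package's marginal-sums implementation: builds dummy
    design matrices, forms projectors by pseudo-inverse, and takes quadratic
    forms of the response.
    """
    d = data[data["treatment"] != "reference"].reset_index(drop=True)
    y = d["value"].to_numpy(dtype=float)
    n = len(d)
    riv, trt, per = d["river"], d["treatment"], d["period"]
    site = riv + "/" + trt + "/" + d["site"].astype(str)
    H1 = np.full((n, n), 1.0 / n)
    H = {
        "t": _hat(_dummies(trt)),
        "r": _hat(_dummies(riv)),
        "tr": _hat(_dummies(trt + ":" + riv)),
        "site": _hat(_dummies(site)),
        "p": _hat(_dummies(per)),
        "pt": _hat(_dummies(per + ":" + trt)),
        "pr": _hat(_dummies(per + ":" + riv)),
        "ptr": _hat(_dummies(per + ":" + trt + ":" + riv)),
    }
    P = {
        "Treatment": H["t"] - H1,
        "River": H["r"] - H1,
        "Treatment x River": H["tr"] - H["t"] - H["r"] + H1,
        "Between sites (within Treatment x River)": H["site"] - H["tr"],
        "Time": H["p"] - H1,
        "Time x Treatment": H["pt"] - H["t"] - H["p"] + H1,
        "Time x River": H["pr"] - H["r"] - H["p"] + H1,
        "Time x Treatment x River": (
            H["ptr"] - H["pt"] - H["pr"] - H["tr"] + H["t"] + H["r"] + H["p"] - H1
        ),
        "Residual": np.eye(n) - H["site"] - H["ptr"] + H["tr"],
    }
    r = riv.nunique()
    s = n // (4 * r)
    dfs = {
        "Treatment": 1, "River": r - 1, "Treatment x River": r - 1,
        "Between sites (within Treatment x River)": 2 * r * (s - 1),
        "Time": 1, "Time x Treatment": 1, "Time x River": r - 1,
        "Time x Treatment x River": r - 1, "Residual": 2 * r * (s - 1),
    }
    denom = {
        "Treatment": "Between sites (within Treatment x River)",
        "River": "Between sites (within Treatment x River)",
        "Treatment x River": "Between sites (within Treatment x River)",
        "Time": "Residual", "Time x Treatment": "Residual",
        "Time x River": "Residual", "Time x Treatment x River": "Residual",
    }
    out = {}
    for src, proj in P.items():
        ss = float(y @ proj @ y)
        out[src] = {"SS": ss, "df": dfs[src], "MS": ss / dfs[src]}
    for src, den in denom.items():
        out[src]["F"] = out[src]["MS"] / out[den]["MS"]
    return out


def glm_contrast_oracle(data: pd.DataFrame, scope: str = "pooled") -> float:
    """Contrast F from the projection oracle's residual MS and raw cell means."""
    oracle = projection_anova_oracle(data)
    ms_res = oracle["Residual"]["MS"]
    d = data[data["treatment"] != "reference"]
    if scope != "pooled":
        d = d[d["river"] == scope]
    cells = d.groupby(["period", "treatment"])["value"].agg(["mean", "size"])
    L = (
        cells.loc[("before", "control"), "mean"]
        + cells.loc[("before", "manipulation"), "mean"]
        + cells.loc[("after", "control"), "mean"]
        - 3 * cells.loc[("after", "manipulation"), "mean"]
    )
    n_cell = int(cells["size"].iloc[0])
    return float(L**2 / (ms_res * 12.0 / n_cell))
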