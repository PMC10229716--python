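"""Bio-equivalence of manipulation sites to the reference condition.

Instead of accepting a null hypothesis of "no difference", equivalence is
demonstrated by rejecting the one-tailed hypothesis that the ratio

    R = mean(manipulation sites, after) / mean(reference target)

is at or below a pre-set margin R_l (default 0.8).  The decision is read off
a 90% two-sided confidence interval for R (the usual correspondence with a
one-tailed test at alpha = 0.05): equivalence is shown when the lower bound
exceeds R_l.  The CI is Fieller's interval for a ratio of two independent
normal means, with the reference target's sampling variance taken across
the per-river reference-site values (reference sites are unreplicated
within rivers).  A seeded percentile bootstrap of the same ratio is provided
as a built-in cross-check.

For community composition, the analogous ratio compares the mean Bray-Curtis
similarity of manipulation sites to the reference site against the mean
similarity among control sites, with a one-tailed bootstrap test of
ratio <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EquivalenceResult",
    "reference_target",
    "equivalence_test",
    "bootstrap_ratio_ci",
    "CompositionEquivalence",
    "composition_equivalence",
]


def reference_target(reference_values_per_river: Mapping[str, float] | pd.Series) -> float:
    """Target mean: the arithmetic mean of the per-river reference-site values.

    Raises if any river's value is missing, since the target is defined over
    the full set of reference sites even for subset analyses.
    """
    s = pd.Series(reference_values_per_river, dtype=float)
    if not len(s):
        raise ValueError("no reference values supplied")
    if s.isna().any():
        raise ValueError(f"missing reference value for rivers: {list(s.index[s.isna()])}")
    return float(s.mean())


@dataclass
class EquivalenceResult:
    R: float
    ci_low: float
    ci_high: float
    R_l: float
    conf: float
    decision: str                   # 'equivalent' or 'not_shown'
    includes_full_equivalence: bool  # CI covers 1.0
    unbounded: bool                 # Fieller denominator not significantly > 0

    def recompute_decision(self) -> str:
        return "equivalent" if self.ci_low > self.R_l else "not_shown"


def equivalence_test(
    manip_after_values: Sequence[float],
    reference_values: Sequence[float] | float,
    R_l: float = 0.8,
    conf: float = 0.90,
) -> EquivalenceResult:
    """Fieller-interval equivalence test of R = mean(manip) / mean(reference).

    ``reference_values`` is the vector of per-river reference-site values
    (its mean is the target and its spread supplies the target's sampling
    variance); a bare float is treated as a known constant target.  The
    one-tailed hypothesis R <= R_l is rejected at alpha = (1-conf)/2 exactly
    when the lower bound of the two-sided ``conf`` interval exceeds R_l.
    """
    m = np.asarray(manip_after_values, dtype=float)
    if len(m) < 2:
        raise ValueError("need at least two manipulation-site values")
    if np.isscalar(reference_values) or np.ndim(reference_values) == 0:
        ref = np.array([float(reference_values)])
        v_r, df_r = 0.0, 0
    else:
        ref = np.asarray(reference_values, dtype=float)
        v_r = float(np.var(ref, ddof=1) / len(ref)) if len(ref) > 1 else 0.0
        df_r = max(len(ref) - 1, 0)
    t_bar = float(ref.mean())
    if t_bar <= 0:
        raise ValueError(f"reference target must be positive, got {t_bar}")
    m_bar = float(m.mean())
    v_m = float(np.var(m, ddof=1) / len(m))
    R = m_bar / t_bar

    if v_m == 0 and v_r == 0:
        ci_low = ci_high = R
        unbounded = False
    else:
        df = (len(m) - 1) + df_r
        tcrit = float(stats.t.ppf(1 - (1 - conf) / 2, df))
        g = tcrit**2 * v_r / t_bar**2
        if g >= 1:
            # reference mean not significantly above zero: interval unbounded
            ci_low, ci_high, unbounded = -np.inf, np.inf, True
        else:
            disc = t_bar**2 * v_m + m_bar**2 * v_r - tcrit**2 * v_m * v_r
            root = tcrit * np.sqrt(max(disc, 0.0))
            denom = t_bar**2 - tcrit**2 * v_r
            ci_low = (m_bar * t_bar - root) / denom
            ci_high = (m_bar * t_bar + root) / denom
            unbounded = False

    decision = "not_shown" if unbounded else (
        "equivalent" if ci_low > R_l else "not_shown"
    )
    return EquivalenceResult(
        R=R, ci_low=float(ci_low), ci_high=float(ci_high), R_l=R_l, conf=conf,
        decision=decision,
        includes_full_equivalence=bool(ci_low <= 1.0 <= ci_high),
        unbounded=unbounded,
    )


def bootstrap_ratio_ci(
    manip_after_values: Sequence[float],
    reference_values: Sequence[float],
    conf: float = 0.90,
    n_boot: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for the same ratio of means (cross-check)."""
    rng = np.random.default_rng(seed)
    m = np.asarray(manip_after_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    mi = rng.integers(0, len(m), size=(n_boot, len(m)))
    ri = rng.integers(0, len(ref), size=(n_boot, len(ref)))
    ratios = m[mi].mean(axis=1) / ref[ri].mean(axis=1)
    alpha = 1 - conf
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class CompositionEquivalence:
    ratio: float
    p_value: float           # one-tailed P for ratio <= 1
    n_boot: int
    mean_manip_to_ref: float
    mean_among_controls: float


def composition_equivalence(
    sim_manip_to_ref: Sequence[float],
    sim_among_controls: Sequence[float],
    n_boot: int = 9999,
    seed: int = 0,
) -> CompositionEquivalence:
    """Similarity-ratio equivalence of community composition.

    ``sim_manip_to_ref``: Bray-Curtis similarities (0-100) between each
    manipulation site and the reference site, after treatment.
    ``sim_among_controls``: pairwise similarities among control sites, after
    treatment (needs >= 2 control sites, i.e. >= 1 pair).  The ratio of the
    two means is tested one-tailed against <= 1 with a seeded bootstrap over
    the two sets of similarities: P is the bootstrap probability that the
    ratio does not exceed 1.  A significant result means manipulation sites
    are more similar to the reference than controls are to each other.
    """
    a = np.asarray(sim_manip_to_ref, dtype=float)
    b = np.asarray(sim_among_controls, dtype=float)
    if len(b) < 1:
        raise ValueError("need at least two control sites (one similarity pair)")
    for name, v in (("sim_manip_to_ref", a), ("sim_among_controls", b)):
        if ((v < 0) | (v > 100)).any():
            raise ValueError(f"{name} must be Bray-Curtis similarities in [0, 100]")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ratio = np.inf if mean_b == 0 else mean_a / mean_b

    rng = np.random.default_rng(seed)
    ai = rng.integers(0, len(a), size=(n_boot, len(a)))
    bi = rng.integers(0, len(b), size=(n_boot, len(b)))
    num = a[ai].mean(axis=1)
    den = b[bi].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = np.where(den > 0, num / den, np.inf)
    p = (np.sum(boot <= 1.0) + 1) / (n_boot + 1)
    return CompositionEquivalence(
        ratio=float(ratio), p_value=float(p), n_boot=n_boot,
        mean_manip_to_ref=mean_a, mean_among_controls=mean_b,
    )
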