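"""Three-factor repeated-measures BACI ANOVA with a priori contrasts.

The model: Treatment (fixed: control vs manipulation) crossed with River
(fixed) and Site nested within Treatment x River; the repeated measure Time
(before vs after) crossed with both.  On balanced data the sums of squares
follow the classical marginal-means decomposition, and the F denominators
are fixed by the design's error strata:

* Treatment, River, Treatment x River are tested over the Between-sites
  (within Treatment x River) mean square;
* Time and every Time interaction are tested over the Residual
  (Time x Site) mean square.

The treatment effect is probed with the single-df a priori contrast

    L = x_BC + x_BM + x_AC - 3 x_AM

(B/A = before/after, C/M = control/manipulation cell means), whose F ratio
is L^2 / (MS_residual * sum(c^2)/n_cell).  Effect size is reported on the
data scale as ES = 100 (x_AM - Y)/Y with Y = (x_BC + x_BM + x_AC)/3, using
back-transformed cell means when a log transform was applied.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCES",
    "BaciAnova",
    "ContrastResult",
    "fit_baci_anova",
    "apriori_contrast",
    "per_river_contrasts",
    "effect_size",
    "reconstruct_f",
    "one_way_anova_tukey",
    "classify_responders",
]

#: ANOVA source rows, in display order.
SOURCES = (
    "Treatment",
    "River",
    "Treatment x River",
    "Between sites (within Treatment x River)",
    "Time",
    "Time x Treatment",
    "Time x River",
    "Time x Treatment x River",
    "Residual",
)

_BETWEEN = "Between sites (within Treatment x River)"
_DENOMINATOR = {
    "Treatment": _BETWEEN,
    "River": _BETWEEN,
    "Treatment x River": _BETWEEN,
    "Time": "Residual",
    "Time x Treatment": "Residual",
    "Time x River": "Residual",
    "Time x Treatment x River": "Residual",
}

# aliases used by the multivariate table (River listed first)
_SOURCE_ALIASES = {
    "River x Treatment": "Treatment x River",
    "Time x River x Treatment": "Time x Treatment x River",
    "Between sites within (River x Treatment)": _BETWEEN,
}

_CONTRAST = {"BC": 1.0, "BM": 1.0, "AC": 1.0, "AM": -3.0}
_SUM_C2 = 12.0


# ---------------------------------------------------------------------------
# design encoding and balanced decomposition


@dataclass
class _Design:
    rivers: list
    sites: list            # (river, treatment, site) triples, in index order
    ri: np.ndarray         # river code per observation
    ti: np.ndarray         # treatment code (0 control, 1 manipulation)
    si: np.ndarray         # site code
    pi: np.ndarray         # period code (0 before, 1 after)
    r: int
    s: int                 # sites per Treatment x River cell
    n: int


def _encode_design(data: pd.DataFrame) -> _Design:
    required = {"river", "treatment", "site", "period"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"response table is missing columns: {sorted(missing)}")
    treatments = set(data["treatment"])
    if treatments != {"control", "manipulation"}:
        raise ValueError(
            "treatment must take exactly the levels {'control', 'manipulation'} "
            f"(reference sites enter only via bio-equivalence); got {sorted(treatments)}"
        )
    periods = set(data["period"])
    if periods != {"before", "after"}:
        raise ValueError(f"period must be {{'before', 'after'}}, got {sorted(periods)}")

    rivers = sorted(data["river"].unique())
    ri = data["river"].map({r: i for i, r in enumerate(rivers)}).to_numpy()
    ti = (data["treatment"] == "manipulation").to_numpy().astype(int)
    pi = (data["period"] == "after").to_numpy().astype(int)
    site_keys = list(zip(data["river"], data["treatment"], data["site"]))
    sites = sorted(set(site_keys))
    lut = {k: i for i, k in enumerate(sites)}
    si = np.array([lut[k] for k in site_keys])

    # balance checks
    cell_sites = {}
    for (river, treatment, _site) in sites:
        cell_sites.setdefault((river, treatment), 0)
        cell_sites[(river, treatment)] += 1
    s_values = set(cell_sites.values())
    if len(cell_sites) != 2 * len(rivers) or len(s_values) != 1:
        raise ValueError(
            "unbalanced design: every River x Treatment cell must contain the "
            f"same number of sites; got {cell_sites}"
        )
    s = s_values.pop()
    obs = pd.DataFrame({"si": si, "pi": pi}).groupby(["si", "pi"]).size()
    if not (obs == 1).all() or len(obs) != 2 * len(sites):
        raise ValueError(
            "unbalanced design: every site needs exactly one observation per period"
        )
    n = len(data)
    return _Design(rivers=rivers, sites=sites, ri=ri, ti=ti, si=si, pi=pi,
                   r=len(rivers), s=s, n=n)


def _balanced_ss(Y: np.ndarray, des: _Design) -> dict[str, np.ndarray]:
    """Sums of squares of each source for every column of Y (n x m)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = des.n
    C = Y.sum(axis=0) ** 2 / n

    def marg(idx: np.ndarray, groups: int) -> np.ndarray:
        S = np.zeros((groups, Y.shape[1]))
        np.add.at(S, idx, Y)
        return (S**2).sum(axis=0) / (n / groups) - C

    r = des.r
    m_t = marg(des.ti, 2)
    m_r = marg(des.ri, r)
    m_tr = marg(des.ti * r + des.ri, 2 * r)
    m_site = marg(des.si, len(des.sites))
    m_p = marg(des.pi, 2)
    m_pt = marg(des.pi * 2 + des.ti, 4)
    m_pr = marg(des.pi * r + des.ri, 2 * r)
    m_ptr = marg((des.pi * 2 + des.ti) * r + des.ri, 4 * r)
    ss_total = (Y**2).sum(axis=0) - C

    ss = {
        "Treatment": m_t,
        "River": m_r,
        "Treatment x River": m_tr - m_t - m_r,
        _BETWEEN: m_site - m_tr,
        "Time": m_p,
        "Time x Treatment": m_pt - m_t - m_p,
        "Time x River": m_pr - m_r - m_p,
        "Time x Treatment x River": m_ptr - m_tr - m_pt - m_pr + m_t + m_r + m_p,
        "Residual": ss_total - m_site - m_ptr + m_tr,
        "Total": ss_total,
    }
    return ss


def _dfs(r: int, s: int) -> dict[str, int]:
    return {
        "Treatment": 1,
        "River": r - 1,
        "Treatment x River": r - 1,
        _BETWEEN: 2 * r * (s - 1),
        "Time": 1,
        "Time x Treatment": 1,
        "Time x River": r - 1,
        "Time x Treatment x River": r - 1,
        "Residual": 2 * r * (s - 1),
    }


# ---------------------------------------------------------------------------
# transforms


def _heterogeneity_ratio(data: pd.DataFrame) -> float:
    """Max/min of the River x Treatment x Period cell variances."""
    var = data.groupby(["river", "treatment", "period"])["value"].var(ddof=1)
    var = var.dropna()
    if not len(var) or var.max() == 0:
        return 1.0
    vmin = var[var > 0].min() if (var > 0).any() else 0.0
    return np.inf if vmin == 0 else float(var.max() / vmin)


def _resolve_transform(data: pd.DataFrame, transform: str,
                       heterogeneity_threshold: float) -> str:
    if transform not in ("auto", "none", "log"):
        raise ValueError(f"transform must be 'auto', 'none' or 'log', got {transform!r}")
    if transform != "auto":
        return transform
    if (data["value"] < 0).any():
        return "none"
    return "log" if _heterogeneity_ratio(data) > heterogeneity_threshold else "none"


def _back_transform(x, transform: str):
    return np.power(10.0, x) - 1.0 if transform == "log" else x


# ---------------------------------------------------------------------------
# main fits


@dataclass
class BaciAnova:
    """Fitted BACI ANOVA: the source table plus what downstream tests need."""

    table: pd.DataFrame
    transform: str
    data: pd.DataFrame          # analysis-scale response table
    rivers: list
    sites_per_cell: int

    @property
    def residual_ms(self) -> float:
        return float(self.table.set_index("source").loc["Residual", "MS"])

    @property
    def residual_df(self) -> int:
        return int(self.table.set_index("source").loc["Residual", "df"])

    @property
    def between_sites_ms(self) -> float:
        return float(self.table.set_index("source").loc[_BETWEEN, "MS"])


def fit_baci_anova(
    data: pd.DataFrame,
    transform: str = "auto",
    heterogeneity_threshold: float = 4.0,
) -> BaciAnova:
    """Fit the three-factor repeated-measures BACI ANOVA on a balanced table.

    ``data`` needs columns river, site, treatment, period, value; reference
    rows are dropped.  ``transform='auto'`` applies log10(x+1) when the
    max/min ratio of River x Treatment x Period cell variances exceeds
    ``heterogeneity_threshold`` (override with 'none' or 'log').

    Raises on unbalanced data; a response that is constant everywhere yields
    all-zero SS with F and P reported as missing.
    """
    if "value" not in data.columns:
        raise ValueError("response table needs a 'value' column")
    data = data[data["treatment"] != "reference"].copy()
    des = _encode_design(data)
    used = _resolve_transform(data, transform, heterogeneity_threshold)
    if used == "log":
        if (data["value"] < 0).any():
            raise ValueError("log10(x+1) transform requires nonnegative values")
        data["value"] = np.log10(data["value"] + 1.0)

    ss = {k: float(v[0]) for k, v in _balanced_ss(data["value"].to_numpy(), des).items()}
    dfs = _dfs(des.r, des.s)
    total = ss.pop("Total")

    ms = {src: ss[src] / dfs[src] for src in SOURCES}
    constant = total <= 1e-12 * max(1.0, float((data["value"] ** 2).sum()))
    if not constant and ms["Residual"] == 0:
        raise ValueError("zero residual mean square: within-site replicates are identical")

    rows = []
    for src in SOURCES:
        denom = _DENOMINATOR.get(src)
        if denom is None or constant or ms[denom] == 0:
            F = P = np.nan
        else:
            F = ms[src] / ms[denom]
            P = float(stats.f.sf(F, dfs[src], dfs[denom]))
        rows.append(
            {
                "source": src,
                "df": dfs[src],
                "SS": ss[src],
                "MS": ms[src] if not constant else 0.0,
                "F": F,
                "P": P,
                "denominator": denom if denom else "",
            }
        )
    table = pd.DataFrame(rows)
    return BaciAnova(table=table, transform=used, data=data,
                     rivers=des.rivers, sites_per_cell=des.s)


def reconstruct_f(ms: Mapping[str, float]) -> dict[str, float]:
    """F ratios implied by the denominator mapping, from mean squares alone.

    Accepts either source naming convention (Treatment x River or
    River x Treatment).  Sources whose denominator MS is absent are skipped.
    """
    norm = {_SOURCE_ALIASES.get(k, k): v for k, v in ms.items()}
    out = {}
    for src, denom in _DENOMINATOR.items():
        if src in norm and denom in norm and norm[denom] > 0:
            out[src] = norm[src] / norm[denom]
    return out


# ---------------------------------------------------------------------------
# a priori contrast and effect sizes


@dataclass
class ContrastResult:
    scope: str                    # 'pooled' or a river name
    cell_means: dict[str, float]  # analysis-scale means: BC, BM, AC, AM
    estimate: float               # L = BC + BM + AC - 3 AM (analysis scale)
    F: float
    P: float
    df_num: int
    df_den: int
    n_cell: int
    direction: str                # 'increase' (L < 0), 'decrease', or 'none'
    effect_size_pct: float        # data-scale percentage
    Y: float                      # data-scale baseline mean


def _cell_means(data: pd.DataFrame, scope: str) -> tuple[dict[str, float], int]:
    sub = data if scope == "pooled" else data[data["river"] == scope]
    if not len(sub):
        raise ValueError(f"no data for scope {scope!r}")
    means, counts = {}, set()
    for (period, treatment), grp in sub.groupby(["period", "treatment"]):
        key = ("B" if period == "before" else "A") + (
            "C" if treatment == "control" else "M"
        )
        means[key] = float(grp["value"].mean())
        counts.add(len(grp))
    if set(means) != {"BC", "BM", "AC", "AM"} or len(counts) != 1:
        raise ValueError(f"scope {scope!r} does not contain all four balanced cells")
    return means, counts.pop()


def _es_from_cells(cells: Mapping[str, float], transform: str) -> tuple[float, float]:
    b = {k: float(_back_transform(v, transform)) for k, v in cells.items()}
    Y = (b["BC"] + b["BM"] + b["AC"]) / 3.0
    if Y == 0:
        return np.nan, 0.0
    return (b["AM"] - Y) / Y * 100.0, Y


def apriori_contrast(
    data: pd.DataFrame | None = None,
    scope: str = "pooled",
    anova: BaciAnova | None = None,
    transform: str = "auto",
) -> ContrastResult:
    """The single-df treatment contrast L = x_BC + x_BM + x_AC - 3 x_AM.

    F = L^2 / (MS_residual * 12 / n_cell) on 1 and the residual df; P is the
    (two-sided) F-tail probability, with the sign of L carried separately as
    the direction of the effect (negative L means manipulation-after sits
    above the other three cells).
    """
    if anova is None:
        if data is None:
            raise ValueError("provide a response table or a fitted BaciAnova")
        anova = fit_baci_anova(data, transform=transform)
    if scope != "pooled" and scope not in anova.rivers:
        raise ValueError(f"river {scope!r} not present; rivers: {anova.rivers}")
    cells, n_cell = _cell_means(anova.data, scope)
    L = sum(_CONTRAST[k] * cells[k] for k in _CONTRAST)
    ms_res, df_res = anova.residual_ms, anova.residual_df
    if ms_res > 0:
        F = L**2 / (ms_res * _SUM_C2 / n_cell)
        P = float(stats.f.sf(F, 1, df_res))
    else:
        F = P = np.nan
    es, Y = _es_from_cells(cells, anova.transform)
    direction = "none" if L == 0 else ("increase" if L < 0 else "decrease")
    return ContrastResult(
        scope=scope, cell_means=cells, estimate=float(L), F=float(F), P=P,
        df_num=1, df_den=df_res, n_cell=n_cell, direction=direction,
        effect_size_pct=float(es), Y=float(Y),
    )


def effect_size(
    data: pd.DataFrame | None = None,
    scope: str = "pooled",
    anova: BaciAnova | None = None,
    transform: str = "auto",
) -> float:
    """Data-scale effect size ES = 100 (x_AM - Y)/Y for the given scope."""
    if anova is None:
        anova = fit_baci_anova(data, transform=transform)
    cells, _ = _cell_means(anova.data, scope)
    es, _ = _es_from_cells(cells, anova.transform)
    return float(es)


@dataclass
class PerRiverContrasts:
    results: list[ContrastResult]
    excluded_river: str
    effect_sizes: dict[str, float]   # data-scale ES for every river


def per_river_contrasts(
    data: pd.DataFrame | None = None,
    anova: BaciAnova | None = None,
    transform: str = "auto",
) -> PerRiverContrasts:
    """Treatment contrasts for each river except the smallest-effect one.

    Effect sizes are computed for all rivers; the river with the smallest
    |ES| is excluded to keep the remaining contrasts independent (ties break
    alphabetically).  Each remaining river's contrast is tested against the
    pooled Residual MS.
    """
    if anova is None:
        anova = fit_baci_anova(data, transform=transform)
    if len(anova.rivers) < 2:
        raise ValueError("per-river contrasts need at least two rivers")
    es = {
        river: effect_size(anova=anova, scope=river)
        for river in anova.rivers
    }
    magnitude = {r: (np.inf if np.isnan(v) else abs(v)) for r, v in es.items()}
    if all(np.isinf(m) for m in magnitude.values()):
        excluded = sorted(anova.rivers)[0]
    else:
        excluded = min(sorted(magnitude), key=lambda r: (magnitude[r], r))
    logger.info("per-river contrasts: excluding river %s (smallest |ES|)", excluded)
    results = [
        apriori_contrast(anova=anova, scope=river)
        for river in anova.rivers
        if river != excluded
    ]
    return PerRiverContrasts(results=results, excluded_river=excluded,
                             effect_sizes=es)


# ---------------------------------------------------------------------------
# one-way ANOVA with Tukey HSD letters


@dataclass
class TukeyResult:
    means: pd.Series
    f: float
    p: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]


def _letter_display(names: Sequence[str], means: Mapping[str, float],
                    sig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups not significantly different share a letter; ``sig`` holds the
    significantly different pairs.
    """
    order = sorted(names, key=lambda g: -means[g])
    cols: list[set] = [set(order)]
    for a, b in sig:
        for col in list(cols):
            if a in col and b in col:
                cols.remove(col)
                for drop in (a, b):
                    new = col - {drop}
                    if new and not any(new <= other for other in cols):
                        cols.append(new)
    # absorb duplicates/subsets
    cols = [c for i, c in enumerate(cols)
            if not any(c < other or (c == other and j < i)
                       for j, other in enumerate(cols))]
    cols.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, col in zip(alphabet, cols):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in names}


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """One-way ANOVA plus Tukey HSD pairwise tests and a letter display.

    Groups whose means are not significantly different at ``alpha`` (by the
    studentised-range test) share a letter.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    f, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    pmat = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    sig = {
        (names[i], names[j])
        for i, j in itertools.combinations(range(len(names)), 2)
        if hsd.pvalue[i, j] < alpha
    }
    means = pd.Series({g: float(np.mean(groups[g])) for g in names})
    letters = _letter_display(names, means, sig)
    return TukeyResult(means=means, f=float(f), p=float(p),
                       pairwise_p=pmat, letters=letters)


# ---------------------------------------------------------------------------
# responder classification


@dataclass
class ResponderClassification:
    per_taxon: pd.DataFrame   # river, taxon, common, P, effect_size_pct, outcome
    summary: pd.DataFrame     # per-river counts and ES ranges


def classify_responders(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    min_total: int = 20,
    min_cells: int = 4,
) -> ResponderClassification:
    """Classify each common taxon's response to treatment, per river.

    Counts are analysed log10(x+1).  A taxon is "common" in a river when its
    total count there (all sites, reference included) is at least
    ``min_total`` and it is nonzero in at least ``min_cells`` site x period
    cells; the contrasts themselves use only control/manipulation sites.
    Each common taxon gets the per-river a priori contrast; significant taxa
    are classed as increased, new (absent at manipulation sites before,
    present after), decreased, or lost (present before, absent after); the
    rest are no_response.
    """
    all_counts = counts
    counts = counts[counts["treatment"] != "reference"]
    obs_key = ["river", "site", "treatment", "period"]
    X = counts.pivot_table(index=obs_key, columns="taxon", values="count",
                           aggfunc="sum", fill_value=0)
    obs = X.index.to_frame(index=False)
    obs["value"] = 0.0
    des = _encode_design(obs)
    taxa = list(X.columns)
    Y = np.log10(X.to_numpy(dtype=float) + 1.0)

    ss = _balanced_ss(Y, des)
    dfs = _dfs(des.r, des.s)
    ms_res = ss["Residual"] / dfs["Residual"]

    # per-river cell means on the log scale: (river, period x treatment)
    cell_idx = (des.pi * 2 + des.ti) * des.r + des.ri
    sums = np.zeros((4 * des.r, Y.shape[1]))
    np.add.at(sums, cell_idx, Y)
    cellmeans = sums / des.s          # rows: (p, t, river)
    raw_sums = np.zeros((4 * des.r, Y.shape[1]))
    np.add.at(raw_sums, cell_idx, X.to_numpy(dtype=float))

    def cell(p: int, t: int, r: int) -> np.ndarray:
        return cellmeans[(p * 2 + t) * des.r + r]

    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for r, river in enumerate(des.rivers):
            bc, bm = cell(0, 0, r), cell(0, 1, r)
            ac, am = cell(1, 0, r), cell(1, 1, r)
            L = bc + bm + ac - 3.0 * am
            F = L**2 / (ms_res * _SUM_C2 / des.s)
            P = stats.f.sf(F, 1, dfs["Residual"])
            b = [_back_transform(v, "log") for v in (bc, bm, ac, am)]
            Yb = (b[0] + b[1] + b[2]) / 3.0
            es = np.where(Yb > 0, (b[3] - Yb) / Yb * 100.0, np.nan)

            river_counts = all_counts[all_counts["river"] == river]
            totals = river_counts.groupby("taxon")["count"].sum().reindex(taxa, fill_value=0)
            ncells = (
                river_counts[river_counts["count"] > 0]
                .groupby("taxon")
                .size()
                .reindex(taxa, fill_value=0)
            )
            common = (totals >= min_total) & (ncells >= min_cells)
            mb = raw_sums[(0 * 2 + 1) * des.r + r]   # manipulation, before
            ma = raw_sums[(1 * 2 + 1) * des.r + r]   # manipulation, after

            for j, taxon in enumerate(taxa):
                if not common.iloc[j]:
                    outcome = "not_common"
                elif not (P[j] <= alpha):
                    outcome = "no_response"
                elif mb[j] == 0 and ma[j] > 0:
                    outcome = "new"
                elif mb[j] > 0 and ma[j] == 0:
                    outcome = "lost"
                elif es[j] > 0:
                    outcome = "increased"
                elif es[j] < 0:
                    outcome = "decreased"
                else:
                    outcome = "no_response"
                rows.append(
                    {
                        "river": river,
                        "taxon": taxon,
                        "common": bool(common.iloc[j]),
                        "P": float(P[j]),
                        "effect_size_pct": float(es[j]),
                        "outcome": outcome,
                    }
                )
    per_taxon = pd.DataFrame(rows)

    summaries = []
    for river, grp in per_taxon.groupby("river"):
        g = grp[grp["common"]]
        pos = g[g["outcome"].isin(["increased", "new"])]["effect_size_pct"].dropna()
        neg = g[g["outcome"].isin(["decreased", "lost"])]["effect_size_pct"].dropna()
        summaries.append(
            {
                "river": river,
                "n_common": len(g),
                "increased": int((g["outcome"] == "increased").sum()),
                "new": int((g["outcome"] == "new").sum()),
                "decreased": int((g["outcome"] == "decreased").sum()),
                "lost": int((g["outcome"] == "lost").sum()),
                "no_response": int((g["outcome"] == "no_response").sum()),
                "es_positive_min": float(pos.min()) if len(pos) else np.nan,
                "es_positive_max": float(pos.max()) if len(pos) else np.nan,
                "es_negative_min": float(neg.min()) if len(neg) else np.nan,
                "es_negative_max": float(neg.max()) if len(neg) else np.nan,
            }
        )
    return ResponderClassification(per_taxon=per_taxon,
                                   summary=pd.DataFrame(summaries))
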