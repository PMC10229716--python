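"""Permutational multivariate analyses of community composition.

The workflow mirrors the univariate BACI analysis on a distance matrix:
abundances are 4th-root transformed, converted to Bray-Curtis
dissimilarities (0-100 scale), and partitioned by the same three-factor
repeated-measures model.  Sums of squares come from the Gower-centred inner
product matrix G = -1/2 J D^2 J partitioned by the orthogonal projectors of
the balanced design (McArdle-Anderson identity: on Euclidean distances of a
univariate response this reproduces the classical ANOVA term-by-term).
Pseudo-F uses the same denominator mapping as the univariate table; P values
come from restricted permutations whose exchangeable units match each term's
null: whole sites within rivers (Treatment, Time x Treatment), within
treatment arms (River, Time x River), free site permutation of reduced-model
residuals (the interactions with no clean stratum), and within-site period
swaps of reduced-model residuals for the Time main effect.

Also here: two-group pairwise comparisons (t = sqrt(pseudo-F)), non-metric
multidimensional scaling by majorization (SMACOF with isotonic regression,
Kruskal stress-1), SIMPER decomposition of between-group dissimilarity into
per-taxon contributions, and before-to-after centroid trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "transform_abundance",
    "abundance_matrix",
    "bray_curtis_matrix",
    "PERMANOVA_SOURCES",
    "permanova",
    "pairwise_permanova",
    "NmdsResult",
    "nmds",
    "SimperResult",
    "simper",
    "centroid_trajectories",
]


def transform_abundance(counts):
    """4th-root transform, elementwise x**0.25 (downweights dominant taxa)."""
    x = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(
        counts, dtype=float
    )
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    out = np.power(x, 0.25)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def abundance_matrix(
    counts: pd.DataFrame, include_reference: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a long count table to samples x taxa, plus sample metadata.

    Samples are site x period units labelled ``river|site|period``; reference
    sites are dropped unless requested.
    """
    c = counts if include_reference else counts[counts["treatment"] != "reference"]
    X = c.pivot_table(index=["river", "site", "treatment", "period"],
                      columns="taxon", values="count", aggfunc="sum", fill_value=0)
    meta = X.index.to_frame(index=False)
    labels = meta["river"] + "|" + meta["site"] + "|" + meta["period"]
    X = X.set_axis(labels, axis=0)
    X.columns.name = None
    meta.index = labels
    return X, meta


def bray_curtis_matrix(transformed: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples on the 0-100 scale.

    d_ij = 100 * sum|x_ik - x_jk| / sum(x_ik + x_jk); similarity is
    100 - d.  Pairs of all-zero samples have undefined dissimilarity and are
    reported as NaN with a warning.
    """
    X = transformed.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least two samples")
    zero = X.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis")) * 100.0
    if zero.sum() >= 2:
        labels = list(transformed.index[zero])
        warnings.warn(
            f"dissimilarity undefined between all-zero samples {labels}; "
            "reported as NaN",
            stacklevel=2,
        )
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=transformed.index, columns=transformed.index)


# ---------------------------------------------------------------------------
# distance-based partition of the repeated-measures design

PERMANOVA_SOURCES = (
    "River",
    "Treatment",
    "River x Treatment",
    "Between sites within (River x Treatment)",
    "Time",
    "Time x Treatment",
    "Time x River",
    "Time x River x Treatment",
    "Residual",
)

_SITE_SRC = "Between sites within (River x Treatment)"
_PERM_DENOM = {
    "River": _SITE_SRC,
    "Treatment": _SITE_SRC,
    "River x Treatment": _SITE_SRC,
    "Time": "Residual",
    "Time x Treatment": "Residual",
    "Time x River": "Residual",
    "Time x River x Treatment": "Residual",
}
_BETWEEN_TERMS = ("River", "Treatment", "River x Treatment")
_WITHIN_TERMS = ("Time", "Time x Treatment", "Time x River",
                 "Time x River x Treatment")

# Per-term permutation: (exchangeable units, restriction stratum,
# residualise under the reduced model?).  Terms whose null leaves whole
# sites exchangeable within a stratum of the raw data get an exact
# restricted permutation; the interaction terms without such a stratum use
# Freedman-Lane permutation of reduced-model residuals.
_PERM_SCHEME = {
    "Treatment": ("sites", "river", False),
    "River": ("sites", "treatment", False),
    "River x Treatment": ("sites", None, True),
    "Time": ("flips", None, True),
    "Time x Treatment": ("sites", "river", False),
    "Time x River": ("sites", "treatment", False),
    "Time x River x Treatment": ("sites", None, True),
}


def _permute_within(rng: np.random.Generator, groups: np.ndarray) -> np.ndarray:
    """A random permutation of indices that stays within each group."""
    sigma = np.arange(len(groups))
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        sigma[members] = members[rng.permutation(len(members))]
    return sigma


def _hat(dummies: np.ndarray) -> np.ndarray:
    return dummies @ np.linalg.pinv(dummies)


def _indicator(codes: np.ndarray, levels: int) -> np.ndarray:
    M = np.zeros((len(codes), levels))
    M[np.arange(len(codes)), codes] = 1.0
    return M


@dataclass
class _PermDesign:
    projectors: dict[str, np.ndarray]
    dfs: dict[str, int]
    pos: np.ndarray            # pos[site, period] -> sample index
    n_sites: int
    site_river: np.ndarray     # river code per site
    site_treatment: np.ndarray  # treatment code per site


def _perm_design(meta: pd.DataFrame) -> _PermDesign:
    meta = meta.copy()
    if (meta["treatment"] == "reference").any():
        raise ValueError("reference sites must be excluded from the PERMANOVA design")
    rivers = sorted(meta["river"].unique())
    r = len(rivers)
    ri = meta["river"].map({x: i for i, x in enumerate(rivers)}).to_numpy()
    ti = (meta["treatment"] == "manipulation").to_numpy().astype(int)
    pi = (meta["period"] == "after").to_numpy().astype(int)
    site_keys = list(zip(meta["river"], meta["treatment"], meta["site"]))
    sites = sorted(set(site_keys))
    lut = {k: i for i, k in enumerate(sites)}
    si = np.array([lut[k] for k in site_keys])
    n = len(meta)
    n_sites = len(sites)
    s = n_sites // (2 * r)
    if n != 2 * n_sites or n_sites != 2 * r * s:
        raise ValueError("design is not a balanced site x period layout")

    n_levels = {"r": r, "t": 2, "tr": 2 * r, "site": n_sites, "p": 2,
                "pt": 4, "pr": 2 * r, "ptr": 4 * r}
    H = {
        "1": np.full((n, n), 1.0 / n),
        "r": _hat(_indicator(ri, r)),
        "t": _hat(_indicator(ti, 2)),
        "tr": _hat(_indicator(ti * r + ri, 2 * r)),
        "site": _hat(_indicator(si, n_sites)),
        "p": _hat(_indicator(pi, 2)),
        "pt": _hat(_indicator(pi * 2 + ti, 4)),
        "pr": _hat(_indicator(pi * r + ri, 2 * r)),
        "ptr": _hat(_indicator((pi * 2 + ti) * r + ri, 4 * r)),
    }
    P = {
        "River": H["r"] - H["1"],
        "Treatment": H["t"] - H["1"],
        "River x Treatment": H["tr"] - H["t"] - H["r"] + H["1"],
        _SITE_SRC: H["site"] - H["tr"],
        "Time": H["p"] - H["1"],
        "Time x Treatment": H["pt"] - H["t"] - H["p"] + H["1"],
        "Time x River": H["pr"] - H["r"] - H["p"] + H["1"],
        "Time x River x Treatment": (
            H["ptr"] - H["pt"] - H["pr"] - H["tr"] + H["t"] + H["r"] + H["p"] - H["1"]
        ),
        "Residual": np.eye(n) - H["site"] - H["ptr"] + H["tr"],
    }
    dfs = {
        "River": r - 1,
        "Treatment": 1,
        "River x Treatment": r - 1,
        _SITE_SRC: 2 * r * (s - 1),
        "Time": 1,
        "Time x Treatment": 1,
        "Time x River": r - 1,
        "Time x River x Treatment": r - 1,
        "Residual": 2 * r * (s - 1),
    }
    pos = np.full((n_sites, 2), -1, dtype=int)
    pos[si, pi] = np.arange(n)
    site_river = np.full(n_sites, -1, dtype=int)
    site_river[si] = ri
    site_treatment = np.full(n_sites, -1, dtype=int)
    site_treatment[si] = ti
    return _PermDesign(projectors=P, dfs=dfs, pos=pos, n_sites=n_sites,
                       site_river=site_river, site_treatment=site_treatment)


def _gower(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    J = np.eye(len(A)) - 1.0 / len(A)
    return J @ A @ J


def _tr(P: np.ndarray, G: np.ndarray) -> float:
    # tr(P G) for symmetric P, G
    return float(np.sum(P * G))


def permanova(
    dist: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA for the three-factor repeated-measures design.

    ``dist`` is a square dissimilarity matrix whose index matches the rows of
    ``design`` (columns river, site, treatment, period).  SS are partitioned
    from the Gower-centred matrix by the balanced design's projectors;
    pseudo-F uses the univariate denominator mapping.  P(perm) permutes each
    term's exchangeable units: whole sites within rivers for Treatment and
    Time x Treatment (each river keeps its 3+3 arms, so river and river-time
    effects cancel in the permuted statistic), whole sites within treatment
    arms for River and Time x River, free site permutation of reduced-model
    (Freedman-Lane) residuals for the two interactions without a clean
    stratum, and within-site period swaps of reduced-model residuals for the
    Time main effect; the scheme is recorded per row.
    P = (# permuted pseudo-F >= observed + 1) / (n_perm + 1).
    """
    if list(dist.index) != list(design.index):
        raise ValueError("distance matrix labels do not match the design rows")
    if np.isnan(dist.to_numpy()).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    pd_des = _perm_design(design)
    G = _gower(dist.to_numpy(dtype=float))
    P = pd_des.projectors
    dfs = pd_des.dfs

    ss = {src: _tr(P[src], G) for src in PERMANOVA_SOURCES}
    ms = {src: ss[src] / dfs[src] for src in PERMANOVA_SOURCES}
    rng = np.random.default_rng(seed)
    rows = []
    for src in PERMANOVA_SOURCES:
        denom = _PERM_DENOM.get(src)
        if denom is None:
            rows.append({"source": src, "df": dfs[src], "SS": ss[src],
                         "MS": ms[src], "pseudo_F": np.nan, "P_perm": np.nan,
                         "n_unique_perms": np.nan, "denominator": "",
                         "permutation_scheme": ""})
            continue
        f_obs = ms[src] / ms[denom] if ms[denom] > 0 else np.nan
        scheme, strata, residualise = _PERM_SCHEME[src]
        if residualise:
            # Freedman-Lane: residualise under the reduced model (all terms
            # except the tested one and its error strata)
            if src in _BETWEEN_TERMS:
                reduced = [t for t in _BETWEEN_TERMS if t != src] + list(_WITHIN_TERMS)
            else:
                reduced = list(_BETWEEN_TERMS) + [_SITE_SRC] + [
                    t for t in _WITHIN_TERMS if t != src
                ]
            H_red = np.full_like(G, 1.0 / len(G))
            for t in reduced:
                H_red = H_red + P[t]
            R = np.eye(len(G)) - H_red
            Gbase = R @ G @ R
        else:
            Gbase = G
        if strata == "river":
            groups = pd_des.site_river
        elif strata == "treatment":
            groups = pd_des.site_treatment
        else:
            groups = np.zeros(pd_des.n_sites, dtype=int)

        exceed = 0
        seen = set()
        for _ in range(n_perm):
            idx = np.empty(len(G), dtype=int)
            if scheme == "sites":
                sigma = _permute_within(rng, groups)
                idx[pd_des.pos[:, 0]] = pd_des.pos[sigma, 0]
                idx[pd_des.pos[:, 1]] = pd_des.pos[sigma, 1]
                seen.add(tuple(sigma))
            else:  # within-site period swaps
                flips = rng.integers(0, 2, pd_des.n_sites)
                idx[pd_des.pos[:, 0]] = np.where(flips, pd_des.pos[:, 1],
                                                 pd_des.pos[:, 0])
                idx[pd_des.pos[:, 1]] = np.where(flips, pd_des.pos[:, 0],
                                                 pd_des.pos[:, 1])
                seen.add(tuple(flips))
            Gp = Gbase[np.ix_(idx, idx)]
            den = _tr(P[denom], Gp) / dfs[denom]
            num = _tr(P[src], Gp) / dfs[src]
            f_perm = num / den if den > 0 else np.inf
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        label = {
            ("sites", "river"): "whole sites within rivers",
            ("sites", "treatment"): "whole sites within treatments",
            ("sites", None): "whole sites, reduced-model residuals",
            ("flips", None): "within-site period swaps, reduced-model residuals",
        }[(scheme, strata)]
        rows.append({"source": src, "df": dfs[src], "SS": ss[src], "MS": ms[src],
                     "pseudo_F": f_obs, "P_perm": p, "n_unique_perms": len(seen),
                     "denominator": denom, "permutation_scheme": label})
    return pd.DataFrame(rows)


def pairwise_permanova(
    dist: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-group comparison: t = sqrt(one-way pseudo-F), permutation P.

    ``groups`` assigns each sample (matching ``dist``'s labels) to one of two
    groups; group labels are permuted freely.
    """
    groups = groups.loc[dist.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("both groups need at least two samples")
    gi = (groups == levels[1]).to_numpy().astype(int)
    n = len(gi)
    G = _gower(dist.to_numpy(dtype=float))
    H1 = np.full((n, n), 1.0 / n)

    def f_stat(codes: np.ndarray) -> float:
        Hg = _hat(_indicator(codes, 2))
        ss_b = _tr(Hg - H1, G)
        ss_w = _tr(np.eye(n) - Hg, G)
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / 1.0) / (ss_w / (n - 2))

    f_obs = f_stat(gi)
    rng = np.random.default_rng(seed)
    exceed = sum(
        f_stat(rng.permutation(gi)) >= f_obs - 1e-12 for _ in range(n_perm)
    )
    p = (exceed + 1) / (n_perm + 1)
    return float(np.sqrt(f_obs)), float(p)


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling


@dataclass
class NmdsResult:
    coords: pd.DataFrame
    stress: float                  # Kruskal stress-1 of the best restart
    converged: bool
    n_restarts: int
    stress_history: list[float] = field(default_factory=list)


def nmds(
    dist: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS minimising Kruskal stress-1 by majorization (SMACOF).

    Disparities are the isotonic regression of configuration distances on
    the input dissimilarities; configurations start from seeded random
    layouts and the best of ``n_restarts`` is returned, centred and rotated
    to its principal axes.
    """
    D = dist.to_numpy(dtype=float)
    n = len(D)
    if n < 4:
        raise ValueError("NMDS needs at least four samples")
    delta = squareform(D, checks=False)
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best = None
    for _ in range(n_restarts):
        X = rng.standard_normal((n, k))
        history: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            d = pdist(X)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(delta[order], d[order])
            denom = float(np.sum(d**2))
            ss_dhat = float(np.sum(dhat**2))
            if denom <= 0 or ss_dhat <= 0:
                break
            # rescale disparities to the distances' norm: without this the
            # configuration can shrink into a degenerate zero-stress collapse
            dhat = dhat * np.sqrt(denom / ss_dhat)
            stress = float(np.sqrt(np.sum((d - dhat) ** 2) / denom))
            history.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        stress = history[-1] if history else np.inf
        if best is None or stress < best[0]:
            best = (stress, X, history, converged)

    stress, X, history, converged = best
    if stress < 1e-3 and n >= 10:
        warnings.warn(
            "NMDS stress is (nearly) zero: the dissimilarities are rank-"
            "separable into tight clusters and the ordination is degenerate "
            "(within-cluster structure is not resolved)",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xr = Xc @ Vt.T
    coords = pd.DataFrame(Xr, index=dist.index,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(coords=coords, stress=stress, converged=converged,
                      n_restarts=n_restarts, stress_history=history)


# ---------------------------------------------------------------------------
# SIMPER


@dataclass
class SimperResult:
    table: pd.DataFrame            # per taxon: average_contribution, sd, ratio, cum_pct
    average_dissimilarity: float   # mean between-group Bray-Curtis (0-100)
    groups: tuple[str, str]


def simper(transformed: pd.DataFrame, group_labels: pd.Series) -> SimperResult:
    """Per-taxon contributions to average between-group Bray-Curtis dissimilarity.

    For every between-group sample pair, taxon k contributes
    100 |x_ik - x_jk| / sum_k (x_ik + x_jk); contributions are averaged over
    pairs (all-zero pairs skipped with a warning) and ranked with their
    between-pair SD, ratio and cumulative percentage.  The contributions sum
    to the average between-group dissimilarity.
    """
    labels = group_labels.loc[transformed.index]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"SIMPER needs exactly two groups, got {levels}")
    A = transformed[labels == levels[0]].to_numpy(dtype=float)
    B = transformed[labels == levels[1]].to_numpy(dtype=float)
    contribs = []
    skipped = 0
    for i in range(len(A)):
        for j in range(len(B)):
            tot = float(np.sum(A[i] + B[j]))
            if tot == 0:
                skipped += 1
                continue
            contribs.append(100.0 * np.abs(A[i] - B[j]) / tot)
    if skipped:
        warnings.warn(f"skipped {skipped} all-zero sample pair(s) in SIMPER",
                      stacklevel=2)
    if not contribs:
        raise ValueError("no valid between-group pairs for SIMPER")
    C = np.array(contribs)
    avg = C.mean(axis=0)
    sd = C.std(axis=0, ddof=1) if len(C) > 1 else np.full(C.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, avg / sd, np.nan)
    table = pd.DataFrame(
        {"average_contribution": avg, "sd": sd, "ratio": ratio},
        index=transformed.columns,
    ).sort_values("average_contribution", ascending=False)
    total = table["average_contribution"].sum()
    table["cum_pct"] = (
        table["average_contribution"].cumsum() / total * 100.0 if total > 0 else np.nan
    )
    return SimperResult(table=table, average_dissimilarity=float(total),
                        groups=(levels[0], levels[1]))


# ---------------------------------------------------------------------------
# centroid trajectories


def centroid_trajectories(coords: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Before-to-after centroid displacement per (river, treatment) group.

    Returns one row per group with start/end centroids, the displacement
    vector and its length (arrow start = before centroid, end = after).
    """
    df = coords.join(meta[["river", "treatment", "period"]])
    axes = [c for c in coords.columns]
    rows = []
    for (river, treatment), grp in df.groupby(["river", "treatment"]):
        cent = grp.groupby("period")[axes].mean()
        if not {"before", "after"} <= set(cent.index):
            raise ValueError(f"group ({river}, {treatment}) lacks both periods")
        start = cent.loc["before"].to_numpy()
        end = cent.loc["after"].to_numpy()
        row = {"river": river, "treatment": treatment}
        for ax, s, e in zip(axes, start, end):
            row[f"{ax}_before"] = s
            row[f"{ax}_after"] = e
        delta = end - start
        row["displacement"] = float(np.linalg.norm(delta))
        rows.append(row)
    return pd.DataFrame(rows)
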