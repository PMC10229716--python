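"""Channel-retentiveness indices from line-intercept transect surveys.

A survey records, for each cross-sectional transect at a site, the length
(m) of each retentive-element type it intercepts and the length of detritus
(CPOM) found on that element.  From these we compute:

* Linear Coverage Index (LCI): mean m of an element intercepted per m of
  transect, per site and element type; detritus LCI likewise.
* Trapping Efficiency (TE): mean m of detritus retained per m of a given
  element type (ratio of sums within a site, averaged across sites).
* Effective retentiveness: the LCI of each element weighted by its TE and
  summed — the amount of *useful* retentive structure at a site.

Detritus standing stock in g m^-2 comes from the pooled Surber samples
(15 x 0.30 x 0.33 m^2 per site x period).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_experiment import ELEMENT_TYPES, POOLED_AREA_M2

__all__ = [
    "linear_coverage_index",
    "trapping_efficiency",
    "effective_retentiveness",
    "detritus_standing_stock",
    "site_summary",
    "RetentivenessSummary",
]

_SITE_KEY = ["river", "site"]


def _validate_survey(survey: pd.DataFrame) -> None:
    required = {"river", "site", "transect", "transect_length", "element_type",
                "intercept_m", "detritus_m"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey is missing columns: {sorted(missing)}")
    bad = survey[survey["transect_length"] <= 0]
    if len(bad):
        t = bad.iloc[0]
        raise ValueError(
            f"non-positive transect_length at river={t['river']} site={t['site']} "
            f"transect={t['transect']}"
        )
    for col in ("intercept_m", "detritus_m"):
        if (survey[col] < 0).any():
            raise ValueError(f"negative {col} in survey")
    dup = survey.duplicated(subset=_SITE_KEY + ["transect", "element_type"])
    if dup.any():
        raise ValueError("duplicate (site, transect, element_type) rows in survey")


def linear_coverage_index(survey: pd.DataFrame) -> pd.DataFrame:
    """Per-site, per-element coverage (m of element per m of transect).

    For each site and element type: mean over the site's transects of
    intercept_m / transect_length.  Transects with no row for an element
    contribute 0 for that element.  Returns a wide frame indexed by
    (river, site) with one column per element type, plus ``lci_total``
    (sum over elements) and ``detritus_lci``.
    """
    _validate_survey(survey)
    s = survey.copy()
    s["ratio"] = s["intercept_m"] / s["transect_length"]
    s["det_ratio"] = s["detritus_m"] / s["transect_length"]

    n_transects = s.groupby(_SITE_KEY)["transect"].nunique()
    # sum of per-transect ratios; dividing by the site's transect count makes
    # absent (element, transect) combinations count as zero
    el_sum = s.pivot_table(
        index=_SITE_KEY, columns="element_type", values="ratio", aggfunc="sum",
        fill_value=0.0,
    )
    for el in ELEMENT_TYPES:
        if el not in el_sum.columns:
            el_sum[el] = 0.0
    el_sum = el_sum[[c for c in ELEMENT_TYPES if c in el_sum.columns]
                    + [c for c in el_sum.columns if c not in ELEMENT_TYPES]]
    lci = el_sum.div(n_transects, axis=0)
    out = lci.copy()
    out["lci_total"] = lci.sum(axis=1)
    det = s.groupby(_SITE_KEY + ["transect"])["det_ratio"].sum()
    out["detritus_lci"] = det.groupby(level=_SITE_KEY).mean()
    out.columns.name = None
    return out


def trapping_efficiency(survey: pd.DataFrame, scope: str = "river") -> pd.DataFrame:
    """Trapping efficiency of each element type (m detritus per m element).

    Within each site, TE of element e is the ratio of summed detritus_m to
    summed intercept_m on e; sites where e is never intercepted are excluded.
    The per-site ratios are then averaged across sites, either within each
    river (``scope='river'``, the default) or across all sites
    (``scope='global'``).  An element never intercepted anywhere in scope has
    undefined TE and is reported as NaN, not zero.

    Returns a frame indexed by river (or a single row ``'all'``) with one
    column per element type.
    """
    _validate_survey(survey)
    if scope not in ("river", "global"):
        raise ValueError(f"scope must be 'river' or 'global', got {scope!r}")
    agg = (
        survey.groupby(_SITE_KEY + ["element_type"])[["intercept_m", "detritus_m"]]
        .sum()
        .reset_index()
    )
    agg = agg[agg["intercept_m"] > 0]
    agg["ratio"] = agg["detritus_m"] / agg["intercept_m"]
    group = "river" if scope == "river" else None
    if group is None:
        te = agg.groupby("element_type")["ratio"].mean().to_frame().T
        te.index = pd.Index(["all"], name="river")
    else:
        te = agg.pivot_table(index="river", columns="element_type",
                             values="ratio", aggfunc="mean")
        te = te.reindex(survey["river"].unique())
    for el in survey["element_type"].unique():
        if el not in te.columns:
            te[el] = np.nan
    te.columns.name = None
    return te


def effective_retentiveness(lci: pd.DataFrame, te: pd.DataFrame) -> pd.Series:
    """TE-weighted retentive structure per site: sum_e LCI_e x TE_e.

    ``lci`` is the output of :func:`linear_coverage_index`; ``te`` the output
    of :func:`trapping_efficiency`.  If an element has nonzero LCI at a site
    but no defined TE in that site's scope, an error names the element.
    """
    elements = [c for c in lci.columns if c not in ("lci_total", "detritus_lci")]
    values = {}
    global_scope = list(te.index) == ["all"]
    for key, row in lci[elements].iterrows():
        river = "all" if global_scope else key[0]
        if river not in te.index:
            raise ValueError(f"no trapping efficiencies for river {river!r}")
        te_row = te.loc[river]
        present = [e for e in elements if row[e] > 0]
        undefined = [e for e in present if e not in te_row.index or pd.isna(te_row[e])]
        if undefined:
            raise ValueError(
                f"trapping efficiency undefined for elements {undefined} present "
                f"at site {key}"
            )
        values[key] = float(sum(row[e] * te_row[e] for e in present))
    out = pd.Series(values, name="effective_retentiveness")
    out.index = pd.MultiIndex.from_tuples(out.index, names=_SITE_KEY)
    return out


def detritus_standing_stock(detritus: pd.DataFrame) -> pd.DataFrame:
    """Convert pooled dry mass (g) per site x period to g m^-2.

    Divides ``detritus_g`` by the pooled sampled area of the 15 Surber
    samples (15 x 0.30 x 0.33 = 1.485 m^2).
    """
    if "detritus_g" not in detritus.columns:
        raise ValueError("detritus table must have a 'detritus_g' column")
    if (detritus["detritus_g"] < 0).any():
        bad = detritus.index[detritus["detritus_g"] < 0][0]
        raise ValueError(f"negative detritus mass at row {bad}")
    out = detritus.copy()
    out["detritus_gm2"] = out["detritus_g"] / POOLED_AREA_M2
    return out


@dataclass
class RetentivenessSummary:
    """Per-site indices plus the per-element trapping efficiencies."""

    per_site: pd.DataFrame
    trapping_efficiency: pd.DataFrame


def site_summary(
    survey: pd.DataFrame,
    detritus: pd.DataFrame | None = None,
    te_scope: str = "river",
) -> RetentivenessSummary:
    """One row per site: lci_total, effective_retentiveness, detritus_lci,
    and (if a detritus mass table is given) mean detritus_gm2 across periods."""
    lci = linear_coverage_index(survey)
    te = trapping_efficiency(survey, scope=te_scope)
    eff = effective_retentiveness(lci, te)
    per_site = lci[["lci_total", "detritus_lci"]].copy()
    per_site.insert(1, "effective_retentiveness", eff)
    if detritus is not None:
        gm2 = (
            detritus_standing_stock(detritus)
            .groupby(_SITE_KEY)["detritus_gm2"]
            .mean()
        )
        per_site["detritus_gm2"] = gm2
    return RetentivenessSummary(per_site=per_site.reset_index(), trapping_efficiency=te)
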