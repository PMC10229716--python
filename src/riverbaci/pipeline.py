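"""End-to-end orchestration: simulate/read -> retentiveness -> univariate
BACI -> bio-equivalence -> community analyses, with a reproducible report.

Each run writes CSV tables in the style of the experiment's summary tables
(ANOVA with per-river contrasts, PERMANOVA, responder classification,
equivalence results) plus a manifest recording the resolved configuration,
its hash, the root seed and content hashes of every table, so a rerun with
identical config and seed reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baci_anova, bioequivalence, community, retentiveness
from .synthetic_experiment import (
    AbundanceTable,
    SimulatedExperiment,
    SimulationConfig,
    read_experiment,
    simulate_experiment,
    write_experiment,
)

logger = logging.getLogger(__name__)

DEFAULT_RESPONSES = ("detritus_gm2", "richness", "density")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``simulation`` / ``input_dir`` must be set.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    alpha: float = 0.05
    r_l: float = 0.8
    conf: float = 0.90
    n_perm: int = 9999
    nmds_restarts: int = 20
    transform: str = "auto"
    seed: int = 0
    outdir: str = "riverbaci_run"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("set exactly one of simulation or input_dir")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ReportBundle:
    outdir: Path
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# input validation and derived responses


def validate_inputs(
    design: pd.DataFrame,
    counts: pd.DataFrame,
    detritus: pd.DataFrame | None = None,
    transects: pd.DataFrame | None = None,
) -> list[dict]:
    """Machine-readable diagnostics: balance, label consistency, nonnegativity."""
    issues: list[dict] = []

    def issue(check: str, message: str, **extra) -> None:
        issues.append({"check": check, "message": message, **extra})

    for river, grp in design.groupby("river"):
        n_ref = (grp["treatment"] == "reference").sum()
        if n_ref != 1:
            issue("design", f"river {river} has {n_ref} reference sites (need 1)")
        nc = (grp["treatment"] == "control").sum()
        nm = (grp["treatment"] == "manipulation").sum()
        if nc != nm:
            issue("design", f"river {river} has {nc} control vs {nm} manipulation sites")

    design_sites = set(zip(design["river"], design["site"]))
    count_sites = set(zip(counts["river"], counts["site"]))
    for river, site in sorted(count_sites - design_sites):
        issue("labels", f"abundance table references unknown site {river}/{site}")

    neg = counts.index[counts["count"] < 0]
    for ix in neg:
        issue("nonnegativity", f"negative count at abundance row {ix}", row=int(ix))

    cells = counts.groupby(["river", "site"])["period"].nunique()
    for (river, site), nper in cells.items():
        if nper != 2:
            issue("unbalanced",
                  f"site {river}/{site} sampled in {nper} period(s), need both")
    missing = design_sites - count_sites
    for river, site in sorted(missing):
        issue("unbalanced", f"site {river}/{site} absent from the abundance table")

    if detritus is not None:
        neg = detritus.index[detritus["detritus_g"] < 0]
        for ix in neg:
            issue("nonnegativity", f"negative detritus mass at row {ix}", row=int(ix))
    if transects is not None:
        if (transects["transect_length"] <= 0).any():
            issue("transects", "non-positive transect_length present")
        if (transects[["intercept_m", "detritus_m"]] < 0).to_numpy().any():
            issue("nonnegativity", "negative intercept or detritus length in transects")
    return issues


def derive_responses(abundance: AbundanceTable) -> dict[str, pd.DataFrame]:
    """Site x period response tables: detritus g m^-2, taxon richness
    (taxa with count > 0), and total density of individuals."""
    key = ["river", "site", "treatment", "period"]
    counts = abundance.counts
    richness = (
        counts[counts["count"] > 0].groupby(key)["taxon"].nunique().rename("value")
    )
    # sites where nothing was found still have richness 0
    all_cells = counts[key].drop_duplicates().set_index(key).index
    richness = richness.reindex(all_cells, fill_value=0)
    density = counts.groupby(key)["count"].sum().rename("value")
    stock = retentiveness.detritus_standing_stock(abundance.detritus)
    detritus = stock.set_index(key)["detritus_gm2"].rename("value")
    return {
        "detritus_gm2": detritus.reset_index(),
        "richness": richness.reset_index(),
        "density": density.reset_index(),
    }


def _reference_values(resp: pd.DataFrame, period: str = "after") -> pd.Series:
    ref = resp[(resp["treatment"] == "reference") & (resp["period"] == period)]
    return ref.set_index("river")["value"]


def _contrast_row(cr: baci_anova.ContrastResult) -> dict:
    return {
        "scope": cr.scope,
        "estimate": cr.estimate,
        "F": cr.F,
        "P": cr.P,
        "df_num": cr.df_num,
        "df_den": cr.df_den,
        "direction": cr.direction,
        "effect_size_pct": cr.effect_size_pct,
        "Y": cr.Y,
        **{f"mean_{k}": v for k, v in cr.cell_means.items()},
    }


# ---------------------------------------------------------------------------
# the full run


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("riverbaci")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    tables: dict[str, pd.DataFrame] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    raise PipelineError(name, str(exc)) from exc
                logger.info("stage %s: done in %.3fs", name, timings[name])
                return False

        return _Stage()

    try:
        with stage("data"):
            if config.simulation is not None:
                exp = simulate_experiment(config.simulation)
                write_experiment(exp, outdir / "inputs")
            else:
                exp = read_experiment(config.input_dir)
            issues = validate_inputs(exp.design, exp.abundance.counts,
                                     exp.abundance.detritus, exp.transects)
            if issues:
                bad = "; ".join(i["message"] for i in issues[:5])
                raise ValueError(f"{len(issues)} input issue(s): {bad}")

        with stage("retentiveness"):
            summary = retentiveness.site_summary(exp.transects,
                                                 exp.abundance.detritus)
            tables["retentiveness_sites"] = summary.per_site
            tables["trapping_efficiency"] = summary.trapping_efficiency.reset_index()

        responses = derive_responses(exp.abundance)
        equiv_rows = []
        for name in config.responses:
            if name not in responses:
                raise PipelineError("baci", f"unknown response {name!r}")
            resp = responses[name]
            with stage(f"baci:{name}"):
                anova = baci_anova.fit_baci_anova(
                    resp, transform=config.transform
                )
                pooled = baci_anova.apriori_contrast(anova=anova)
                per_river = baci_anova.per_river_contrasts(anova=anova)
                tables[f"anova_{name}"] = anova.table.assign(
                    transform=anova.transform
                )
                contrast_rows = [_contrast_row(pooled)] + [
                    _contrast_row(c) for c in per_river.results
                ]
                tables[f"contrasts_{name}"] = pd.DataFrame(contrast_rows).assign(
                    excluded_river=per_river.excluded_river
                )
            with stage(f"equivalence:{name}"):
                ref = _reference_values(resp)
                target = bioequivalence.reference_target(ref)
                manip = resp[(resp["treatment"] == "manipulation")
                             & (resp["period"] == "after")]
                scopes = [("pooled", manip["value"].to_numpy())] + [
                    (river, grp["value"].to_numpy())
                    for river, grp in manip.groupby("river")
                ]
                for scope, values in scopes:
                    res = bioequivalence.equivalence_test(
                        values, ref.to_numpy(), R_l=config.r_l, conf=config.conf
                    )
                    equiv_rows.append({
                        "response": name, "scope": scope, "target": target,
                        "R": res.R, "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "R_l": res.R_l, "decision": res.decision,
                        "includes_full_equivalence": res.includes_full_equivalence,
                    })
        tables["equivalence"] = pd.DataFrame(equiv_rows)

        with stage("responders"):
            resp_cls = baci_anova.classify_responders(
                exp.abundance.counts, alpha=config.alpha
            )
            tables["responders_per_taxon"] = resp_cls.per_taxon
            tables["responders_summary"] = resp_cls.summary

        with stage("community"):
            X, meta = community.abundance_matrix(exp.abundance.counts)
            T = community.transform_abundance(X)
            D = community.bray_curtis_matrix(T)
            tables["permanova"] = community.permanova(
                D, meta, n_perm=config.n_perm, seed=config.seed
            )
            pw_rows = []
            for period in ("before", "after"):
                sel = meta.index[meta["period"] == period]
                t_stat, p = community.pairwise_permanova(
                    D.loc[sel, sel], meta.loc[sel, "treatment"],
                    n_perm=config.n_perm, seed=config.seed,
                )
                pw_rows.append({"period": period, "t": t_stat, "P_perm": p})
            tables["pairwise_permanova"] = pd.DataFrame(pw_rows)

            ord_res = community.nmds(D, n_restarts=config.nmds_restarts,
                                     seed=config.seed)
            coords = ord_res.coords.copy()
            coords.insert(0, "stress", ord_res.stress)
            tables["nmds_coords"] = coords.join(meta[["river", "treatment",
                                                      "period"]]).reset_index(
                names="sample")
            tables["nmds_trajectories"] = community.centroid_trajectories(
                ord_res.coords, meta
            )
            after = meta.index[meta["period"] == "after"]
            simp = community.simper(T.loc[after], meta.loc[after, "treatment"])
            tables["simper"] = simp.table.reset_index(names="taxon").assign(
                average_dissimilarity=simp.average_dissimilarity
            )

        with stage("composition_equivalence"):
            Xr, meta_r = community.abundance_matrix(
                exp.abundance.counts, include_reference=True
            )
            Dr = community.bray_curtis_matrix(community.transform_abundance(Xr))
            sim = 100.0 - Dr
            rows = []
            pooled_mr, pooled_cc = [], []
            after_meta = meta_r[meta_r["period"] == "after"]
            for river, grp in after_meta.groupby("river"):
                ref = grp.index[grp["treatment"] == "reference"]
                man = grp.index[grp["treatment"] == "manipulation"]
                ctl = list(grp.index[grp["treatment"] == "control"])
                if len(ref) != 1 or len(ctl) < 2:
                    continue
                mr = sim.loc[man, ref[0]].to_numpy(dtype=float)
                cc = np.array([
                    sim.loc[ctl[i], ctl[j]]
                    for i in range(len(ctl)) for j in range(i + 1, len(ctl))
                ])
                res = bioequivalence.composition_equivalence(
                    mr, cc, n_boot=config.n_perm, seed=config.seed
                )
                pooled_mr.extend(mr)
                pooled_cc.extend(cc)
                rows.append({"scope": river, "ratio": res.ratio,
                             "P": res.p_value,
                             "mean_manip_to_ref": res.mean_manip_to_ref,
                             "mean_among_controls": res.mean_among_controls})
            if pooled_mr:
                res = bioequivalence.composition_equivalence(
                    pooled_mr, pooled_cc, n_boot=config.n_perm, seed=config.seed
                )
                rows.append({"scope": "pooled", "ratio": res.ratio,
                             "P": res.p_value,
                             "mean_manip_to_ref": res.mean_manip_to_ref,
                             "mean_among_controls": res.mean_among_controls})
            tables["composition_equivalence"] = pd.DataFrame(rows)

        with stage("report"):
            hashes = {}
            for name, df in tables.items():
                path = outdir / f"{name}.csv"
                df.to_csv(path, index=False)
                hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
            cfg_dict = config.to_dict()
            manifest = {
                "config": cfg_dict,
                "config_hash": hashlib.sha256(
                    json.dumps(cfg_dict, sort_keys=True, default=str).encode()
                ).hexdigest(),
                "seed": config.seed,
                "versions": _versions(),
                "tables": hashes,
                "timings_s": timings,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
    finally:
        root.removeHandler(handler)
        handler.close()
    return ReportBundle(outdir=outdir, manifest=manifest, tables=tables)


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "riverbaci": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
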