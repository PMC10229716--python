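"""Synthetic six-river detritus-supplementation experiments.

Generates complete datasets with the structure of a whole-river BACI field
experiment: six rivers, each with one upstream reference site and six
treatment sites (three control, three manipulation, allocated stratified-
randomly along the reach), sampled before and after a detritus
supplementation.  Macroinvertebrate counts are overdispersed (gamma-Poisson)
with per-taxon river/site/period effects on the log scale; the treatment acts
as a multiplicative boost confined to manipulation-after cells and to the
taxa assigned to responding classes.  Detritus standing stock is lognormal.
Retentive-structure transect surveys are generated so that the expected
detritus intercepted on each element type equals its coverage times that
type's trapping efficiency.

All randomness flows from a single root seed through named substreams
(design, abundance, transects), so each table can be regenerated
independently and identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: The ten retentive-element types recorded by the line-intercept survey.
ELEMENT_TYPES = (
    "log_jam",
    "wood",
    "branch",
    "root_mat",
    "depositional_zone",
    "plant",
    "macrophyte",
    "cobble",
    "boulder",
    "bedrock_crevice",
)

#: Taxon response classes to the manipulation.
RESPONDER_CLASSES = ("increaser", "new_colonist", "decreaser", "lost", "non_responder")

TREATMENTS = ("reference", "control", "manipulation")
PERIODS = ("before", "after")

#: Area of one Surber sample (0.30 m x 0.33 m frame).
SURBER_AREA_M2 = 0.30 * 0.33
#: Number of pooled Surber samples per site and sampling period.
N_SURBER_SAMPLES = 15
#: Total benthic area pooled per site x period (m^2).
POOLED_AREA_M2 = N_SURBER_SAMPLES * SURBER_AREA_M2

# Substream identifiers hung off the root seed.
_STREAMS = {"design": 0, "abundance": 1, "transects": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def _default_responder_fractions() -> dict[str, float]:
    # Roughly half the common assemblage responds, mostly positively, with a
    # minority of new colonists and a few losses/declines.
    return {
        "increaser": 0.30,
        "new_colonist": 0.10,
        "decreaser": 0.05,
        "lost": 0.05,
        "non_responder": 0.50,
    }


def _default_detritus_params() -> dict[str, float]:
    return {
        # site x period standing stock of CPOM (g m^-2), lognormal
        "mean_gm2": 100.0,
        "sigma": 0.35,          # log-scale sd of site x period noise
        "river_sd": 0.25,       # log-scale sd of river effects
        "reference_uplift": 2.0,  # multiplier at reference sites
        # transect survey
        "te_mean": 0.30,        # mean trapping efficiency (m detritus per m element)
        "te_sd": 0.10,
        "coverage_mean": 0.50,  # mean intercepted m of each element per transect
        "coverage_cv": 0.60,
        "detritus_cv": 0.50,
        "reference_coverage_uplift": 1.5,
    }


@dataclass
class SimulationConfig:
    """Parameters of the simulated field experiment.

    Defaults reproduce the experiment's design: 6 rivers x (1 reference +
    3 control + 3 manipulation) sites x 2 periods, 80 taxa, 8 transects per
    site across 10 retentive-element types, and a 3-fold treatment boost at
    manipulation sites after supplementation.
    """

    n_rivers: int = 6
    n_control: int = 3
    n_manipulation: int = 3
    n_reference: int = 1
    n_taxa: int = 80
    n_transects: int = 8
    transect_length: float = 10.0
    baseline_abundance: float = 30.0
    taxon_sd: float = 1.0
    dispersion: float = 2.0
    river_sd: float = 0.4
    site_sd: float = 0.2
    period_sd: float = 0.15
    treatment_multiplier: float = 3.0
    reference_abundance_uplift: float = 1.5
    responder_fractions: dict[str, float] = field(default_factory=_default_responder_fractions)
    detritus_params: dict[str, float] = field(default_factory=_default_detritus_params)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_rivers": self.n_rivers,
            "n_control": self.n_control,
            "n_manipulation": self.n_manipulation,
            "n_reference": self.n_reference,
            "n_taxa": self.n_taxa,
            "n_transects": self.n_transects,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.n_reference != 1:
            raise ValueError("exactly one reference site per river is required")
        nonneg = {
            "transect_length": self.transect_length,
            "baseline_abundance": self.baseline_abundance,
            "taxon_sd": self.taxon_sd,
            "dispersion": self.dispersion,
            "river_sd": self.river_sd,
            "site_sd": self.site_sd,
            "period_sd": self.period_sd,
            "treatment_multiplier": self.treatment_multiplier,
            "reference_abundance_uplift": self.reference_abundance_uplift,
        }
        for name, value in nonneg.items():
            if not (value >= 0):
                raise ValueError(f"{name} must be nonnegative, got {value!r}")
        if self.transect_length <= 0:
            raise ValueError("transect_length must be positive")
        missing = set(RESPONDER_CLASSES) - set(self.responder_fractions)
        if missing:
            raise ValueError(f"responder_fractions missing classes: {sorted(missing)}")
        total = sum(self.responder_fractions[c] for c in RESPONDER_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"responder_fractions must sum to 1, got {total}")
        if any(self.responder_fractions[c] < 0 for c in RESPONDER_CLASSES):
            raise ValueError("responder_fractions must be nonnegative")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass
class AbundanceTable:
    """Long-format taxon counts plus site-level detritus mass.

    ``counts`` has columns river, site, treatment, period, taxon, count
    (counts are pooled over the 15 Surber samples of a site x period).
    ``detritus`` has columns river, site, treatment, period, detritus_g
    (pooled dry mass over the same samples).
    """

    counts: pd.DataFrame
    detritus: pd.DataFrame


@dataclass
class SimulatedExperiment:
    design: pd.DataFrame
    abundance: AbundanceTable
    transects: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# design


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Allocate treatments to sites, stratified along each river.

    Each river gets one upstream reference site plus ``n_control +
    n_manipulation`` experiment sites at ~1 km spacing.  Within each
    consecutive pair of experiment sites (upstream / middle / downstream
    strata), one site is control and one manipulation, in seeded random
    order.
    """
    config.validate()
    if config.n_control != config.n_manipulation:
        raise ValueError(
            "stratified allocation requires equal numbers of control and "
            f"manipulation sites per river, got {config.n_control} and "
            f"{config.n_manipulation}"
        )
    n_exp = config.n_control + config.n_manipulation
    if n_exp % 2:
        raise ValueError(
            f"odd number of non-reference sites per river ({n_exp}): "
            "pairwise stratification is undefined"
        )
    rng = _rng(config.seed, "design")
    rows = []
    for r in range(config.n_rivers):
        river = f"R{r + 1}"
        rows.append((river, "REF", "reference", 0.0))
        pair = np.array(["control", "manipulation"])
        for k in range(n_exp // 2):
            order = rng.permutation(pair)
            for j in range(2):
                pos = 2 * k + j + 1
                rows.append((river, f"S{pos}", order[j], float(pos)))
    return pd.DataFrame(rows, columns=["river", "site", "treatment", "position_km"])


# ---------------------------------------------------------------------------
# abundances and detritus


def _taxon_classes(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Exact class composition (largest-remainder rounding), shuffled."""
    n = config.n_taxa
    fr = config.responder_fractions
    raw = np.array([fr[c] * n for c in RESPONDER_CLASSES])
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - np.floor(raw)))
        counts[order[:short]] += 1
    classes = np.repeat(np.array(RESPONDER_CLASSES, dtype=object), counts)
    rng.shuffle(classes)
    return classes


def _draw_traits(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    taxa = np.array([f"t{i + 1:03d}" for i in range(config.n_taxa)], dtype=object)
    classes = _taxon_classes(rng, config)
    log_base = np.log(max(config.baseline_abundance, 1e-12)) + rng.normal(
        0.0, config.taxon_sd, config.n_taxa
    )
    return taxa, classes, log_base


def taxon_traits(config: SimulationConfig) -> pd.DataFrame:
    """The per-taxon response class and baseline used by the abundance stream.

    Replays the abundance substream deterministically, so the returned
    classes are exactly those realised by :func:`simulate_abundances` for the
    same config and seed.
    """
    rng = _rng(config.seed, "abundance")
    taxa, classes, log_base = _draw_traits(rng, config)
    return pd.DataFrame(
        {"taxon": taxa, "response_class": classes, "log_baseline": log_base}
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Gamma-Poisson (negative-binomial-type) counts; k -> inf is Poisson."""
    if math.isinf(k):
        return rng.poisson(mu)
    lam = rng.gamma(shape=k, scale=np.asarray(mu) / k)
    return rng.poisson(lam)


def simulate_abundances(design: pd.DataFrame, config: SimulationConfig) -> AbundanceTable:
    """Simulate pooled Surber counts per taxon and detritus mass per site x period.

    Log-scale mean count = baseline(taxon) + river effect + site effect +
    period effect + log(multiplier) in manipulation-after cells of responding
    taxa.  River/site/period effects are taxon-specific (independent across
    taxa), so aggregate responses average them out.  New colonists live only
    at the reference source until they appear at manipulation sites after
    treatment (structural zeros elsewhere, so control and manipulation
    communities are exchangeable before treatment); lost taxa are structural
    zeros at manipulation-after; decreasers get multiplier
    1/treatment_multiplier.  Reference sites carry a configurable abundance
    and detritus uplift.
    """
    config.validate()
    rng = _rng(config.seed, "abundance")
    nt = config.n_taxa
    taxa, classes, log_base = _draw_traits(rng, config)

    rivers = list(dict.fromkeys(design["river"]))
    river_ix = {r: i for i, r in enumerate(rivers)}
    river_eff = rng.normal(0.0, config.river_sd, (len(rivers), nt))
    site_eff = rng.normal(0.0, config.site_sd, (len(design), nt))
    period_eff = rng.normal(0.0, config.period_sd, nt)  # applies to "after"

    m = config.treatment_multiplier
    log_m = np.log(m) if m > 0 else -np.inf
    is_incr = np.isin(classes, ["increaser", "new_colonist"])
    is_decr = classes == "decreaser"

    frames = []
    for p_ix, period in enumerate(PERIODS):
        for s_ix, row in enumerate(design.itertuples(index=False)):
            eta = log_base + river_eff[river_ix[row.river]] + site_eff[s_ix]
            if p_ix == 1:
                eta = eta + period_eff
            if row.treatment == "reference":
                eta = eta + np.log(config.reference_abundance_uplift)
            manip_after = row.treatment == "manipulation" and period == "after"
            if manip_after and m != 1.0:
                eta = eta + np.where(is_incr, log_m, 0.0) - np.where(is_decr, log_m, 0.0)
            counts = _nb_draw(rng, np.exp(eta), config.dispersion)
            # structural zeros: colonists live only at the reference source
            # until they appear at manipulation sites after treatment; lost
            # taxa disappear from manipulation sites after treatment
            if row.treatment != "reference":
                if not manip_after:
                    counts = np.where(classes == "new_colonist", 0, counts)
                if row.treatment == "manipulation" and period == "after":
                    counts = np.where(classes == "lost", 0, counts)
            frames.append(
                pd.DataFrame(
                    {
                        "river": row.river,
                        "site": row.site,
                        "treatment": row.treatment,
                        "period": period,
                        "taxon": taxa,
                        "count": counts.astype(int),
                    }
                )
            )
    counts_df = pd.concat(frames, ignore_index=True)

    # detritus standing stock: lognormal, river effects, no persistent site
    # effect (stocks are redistributed between periods by spates)
    dp = config.detritus_params
    d_river = rng.normal(0.0, dp["river_sd"], len(rivers))
    det_rows = []
    for period in PERIODS:
        for row in design.itertuples(index=False):
            lmu = np.log(dp["mean_gm2"]) + d_river[river_ix[row.river]]
            if row.treatment == "reference":
                lmu += np.log(dp["reference_uplift"])
            if row.treatment == "manipulation" and period == "after" and m > 0:
                lmu += np.log(m)
            gm2 = float(np.exp(lmu + rng.normal(0.0, dp["sigma"])))
            det_rows.append(
                (row.river, row.site, row.treatment, period, gm2 * POOLED_AREA_M2)
            )
    detritus = pd.DataFrame(
        det_rows, columns=["river", "site", "treatment", "period", "detritus_g"]
    )
    return AbundanceTable(counts=counts_df, detritus=detritus)


# ---------------------------------------------------------------------------
# transects


def simulate_transects(design: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Line-intercept survey: per transect, intercepted m of each element type
    and the m of detritus retained on it.

    Per element type e, a trapping efficiency TE_e is drawn once; per site a
    mean coverage is drawn; per transect the intercepted length is gamma
    around the site mean (truncated at transect_length) and the detritus
    length is gamma with mean intercept x TE_e.
    """
    config.validate()
    rng = _rng(config.seed, "transects")
    dp = config.detritus_params
    n_el = len(ELEMENT_TYPES)
    te = np.clip(rng.normal(dp["te_mean"], dp["te_sd"], n_el), 0.0, None)
    cv2 = dp["coverage_cv"] ** 2
    dcv2 = dp["detritus_cv"] ** 2

    rows = []
    for row in design.itertuples(index=False):
        mean_cov = dp["coverage_mean"]
        if row.treatment == "reference":
            mean_cov *= dp["reference_coverage_uplift"]
        if mean_cov > 0:
            site_cov = rng.gamma(shape=1.0 / cv2, scale=mean_cov * cv2, size=n_el)
        else:
            site_cov = np.zeros(n_el)
        for t in range(config.n_transects):
            if mean_cov > 0:
                inter = rng.gamma(shape=1.0 / cv2, scale=site_cov * cv2)
            else:
                inter = np.zeros(n_el)
            inter = np.minimum(inter, config.transect_length)
            mu_det = inter * te
            det = np.where(
                mu_det > 0, rng.gamma(shape=1.0 / dcv2, scale=mu_det * dcv2), 0.0
            )
            det = np.minimum(det, config.transect_length)
            for e in range(n_el):
                rows.append(
                    (
                        row.river,
                        row.site,
                        f"T{t + 1}",
                        config.transect_length,
                        ELEMENT_TYPES[e],
                        float(inter[e]),
                        float(det[e]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "river",
            "site",
            "transect",
            "transect_length",
            "element_type",
            "intercept_m",
            "detritus_m",
        ],
    )


# ---------------------------------------------------------------------------
# convenience


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate design, abundances/detritus and transects from one config."""
    design = generate_design(config)
    return SimulatedExperiment(
        design=design,
        abundance=simulate_abundances(design, config),
        transects=simulate_transects(design, config),
        config=config,
    )


def null_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, AbundanceTable, pd.DataFrame]:
    """A dataset with no treatment effect in distribution.

    Forces treatment_multiplier = 1 and puts all responder mass on
    non_responder, leaving everything else (including the seed) unchanged.
    """
    fractions = {c: 0.0 for c in RESPONDER_CLASSES}
    fractions["non_responder"] = 1.0
    null_cfg = replace(config, treatment_multiplier=1.0, responder_fractions=fractions)
    exp = simulate_experiment(null_cfg)
    return exp.design, exp.abundance, exp.transects


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write design/abundance/detritus/transect CSVs plus the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": outdir / "design.csv",
        "abundance": outdir / "abundance.csv",
        "detritus": outdir / "detritus.csv",
        "transects": outdir / "transects.csv",
        "config": outdir / "config.yaml",
    }
    exp.design.to_csv(paths["design"], index=False)
    exp.abundance.counts.to_csv(paths["abundance"], index=False)
    exp.abundance.detritus.to_csv(paths["detritus"], index=False)
    exp.transects.to_csv(paths["transects"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(exp.config.to_dict(), fh, sort_keys=True)
    return paths


def read_experiment(indir: str | Path) -> SimulatedExperiment:
    """Read back an experiment directory written by :func:`write_experiment`."""
    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        config = SimulationConfig.from_dict(yaml.safe_load(fh))
    return SimulatedExperiment(
        design=pd.read_csv(indir / "design.csv"),
        abundance=AbundanceTable(
            counts=pd.read_csv(indir / "abundance.csv"),
            detritus=pd.read_csv(indir / "detritus.csv"),
        ),
        transects=pd.read_csv(indir / "transects.csv"),
        config=config,
    )
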