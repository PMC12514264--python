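"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a population-survey blood RNA-seq study: a gene x
sample negative-binomial count matrix with gene-specific baselines,
log-normal library-size variation and additive batch/plate shifts; a latent
"senescence burden" factor that loads on the designated senescence gene
sets, is shifted by socio-behavioral covariates, and drives aging-related
outcomes (epigenetic pace of aging, clock age acceleration, biological age,
cognition, multimorbidity, 6-year mortality via a 4-category vital status);
plus positive survey weights.  A :class:`TruthRecord` stores the latent
factor and every programmed effect so that downstream estimators can be
tested for parameter recovery.

Default marginals (sample size 3580, age/sex/race/education/BMI
distributions, mortality rate 0.162, score-relevant effect sizes) follow the
descriptive statistics of the population study the pipeline is modeled on;
they are configuration, not estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .containers import CountMatrix, GeneSet, GeneSetCollection, ValidationError
from .scoring import build_summary_set

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "SyntheticCohort",
    "ConfigurationError",
    "generate_gene_sets",
    "generate_phenotypes",
    "generate_counts",
    "generate_cohort",
]


class ConfigurationError(ValueError):
    """A cohort configuration is internally inconsistent."""


# Marginal distributions of the emulated survey population.
AGE_GROUPS = ("55-64", "65-74", "75-84", "85+")
AGE_PROBS = (0.405, 0.352, 0.172, 0.071)
AGE_BANDS = {"55-64": (56.0, 65.0), "65-74": (65.0, 75.0),
             "75-84": (75.0, 85.0), "85+": (85.0, 96.0)}
RACE_LEVELS = ("NH White", "NH Black", "Hispanic", "NH Other")
RACE_PROBS = (0.775, 0.102, 0.089, 0.034)
EDU_LEVELS = ("<HS", "HS", "Some College", "College+")
EDU_PROBS = (0.140, 0.299, 0.259, 0.302)
BMI_LEVELS = ("Normal", "Overweight", "Obese I", "Obese II")
BMI_PROBS = (0.238, 0.374, 0.227, 0.161)

FEMALE_P = 0.544
INSOMNIA_P = 0.204
PACK_YEARS_MEAN, PACK_YEARS_SD = 13.1, 20.7
DRINKS_MEAN, DRINKS_SD = 2.9, 6.3
COGNITION_MEAN, COGNITION_SD = 15.5, 4.3
PACE_MEAN, PACE_SD = 1.0, 0.1
CLOCK_AA_SD = 4.0
BIOAGE_AA_SD = 8.1
MULTIMORBIDITY_TRIALS = 5
MULTIMORBIDITY_BASE_P = 0.16

CELL_TYPES = ("granulocytes", "nk_cells", "b_cells", "cd4_t", "cd8_t", "monocytes")
CELL_ALPHA = (55.0, 8.0, 4.0, 15.0, 8.0, 10.0)

DEFAULT_GENE_SET_SIZES = {"CSP": 22, "SIP": 48, "SRP": 44, "SenMayo": 125}
DEFAULT_OVERLAPS = {
    ("SIP", "SRP"): 2,
    ("CSP", "SenMayo"): 1,
    ("SIP", "SenMayo"): 4,
    ("SRP", "SenMayo"): 22,
}
SENTINEL_GENES = ("IGFBP7", "AKT1")  # the designated SIP/SRP shared pair

# Standardized shifts of the latent factor per covariate (z-scored encoding).
DEFAULT_COVARIATE_EFFECTS = {
    "age_group": 0.10,
    "female": 0.04,
    "bmi_class": 0.08,
    "weekly_drinks": 0.03,
}
# Continuous outcomes: standardized beta per SD of the latent factor.
# multimorbidity / mortality: log-odds per SD of the latent factor.
DEFAULT_OUTCOME_EFFECTS = {
    "pace": 0.24,
    "clock_aa": 0.20,
    "bioage_aa": 0.20,
    "cognition": -0.07,
    "multimorbidity": 0.25,
    "mortality": math.log(1.5),
}
CONTINUOUS_OUTCOMES = ("pace", "clock_aa", "bioage_aa", "cognition")
VALID_OUTCOMES = CONTINUOUS_OUTCOMES + ("multimorbidity", "mortality")
VALID_COVARIATES = (
    "age_group", "age_years", "female", "race_ethnicity", "education",
    "bmi_class", "pack_years", "weekly_drinks", "insomnia",
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``covariate_effects`` / ``outcome_effects``: ``None`` selects the default
    population structure; pass ``{}`` for a null cohort with no programmed
    associations.
    """

    n_samples: int = 3580
    n_genes: int = 500
    gene_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_SET_SIZES))
    overlap_spec: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAPS))
    nb_dispersion: float = 10.0
    baseline_log_mean_range: tuple[float, float] = (1.5, 6.0)
    lib_size_log_sd: float = 0.2
    n_batches: int = 46
    batch_effect_sd: float = 0.1
    loading_scale: float = 0.15
    covariate_effects: Mapping[str, float] | None = None
    outcome_effects: Mapping[str, float] | None = None
    mortality_rate: float = 0.162
    presumed_alive_fraction: float = 0.10
    missing_vital_fraction: float = 0.007
    missing_bioage_fraction: float = 0.257
    weight_age_corr: float = 0.10
    include_cell_proportions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigurationError("n_samples and n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.lib_size_log_sd < 0 or self.batch_effect_sd < 0:
            raise ConfigurationError("scale parameters must be nonnegative")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be positive")
        for name, p in (("mortality_rate", self.mortality_rate),
                        ("presumed_alive_fraction", self.presumed_alive_fraction),
                        ("missing_vital_fraction", self.missing_vital_fraction),
                        ("missing_bioage_fraction", self.missing_bioage_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.mortality_rate < 1.0:
            raise ConfigurationError("mortality_rate must be in (0, 1)")
        for name, size in self.gene_set_sizes.items():
            if size < 1:
                raise ConfigurationError(f"gene set {name!r} has nonpositive size")
        lo, hi = self.baseline_log_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ConfigurationError("baseline_log_mean_range must be a finite interval")

    def resolved_covariate_effects(self) -> dict[str, float]:
        eff = (dict(DEFAULT_COVARIATE_EFFECTS) if self.covariate_effects is None
               else dict(self.covariate_effects))
        unknown = set(eff) - set(VALID_COVARIATES)
        if unknown:
            raise ConfigurationError(
                f"unknown covariate(s) in covariate_effects: {sorted(unknown)}; "
                f"valid: {list(VALID_COVARIATES)}"
            )
        total = sum(b * b for b in eff.values())
        if total >= 1.0:
            raise ConfigurationError(
                f"sum of squared covariate effects must be < 1, got {total:.3f}")
        return eff

    def resolved_outcome_effects(self) -> dict[str, float]:
        eff = (dict(DEFAULT_OUTCOME_EFFECTS) if self.outcome_effects is None
               else dict(self.outcome_effects))
        unknown = set(eff) - set(VALID_OUTCOMES)
        if unknown:
            raise ConfigurationError(
                f"unknown outcome(s) in outcome_effects: {sorted(unknown)}; "
                f"valid: {list(VALID_OUTCOMES)}"
            )
        for name in CONTINUOUS_OUTCOMES:
            b = eff.get(name, 0.0)
            if abs(b) >= 1.0:
                raise ConfigurationError(
                    f"standardized effect for {name!r} must be in (-1, 1), got {b}")
        return eff


@dataclass
class TruthRecord:
    """Ground truth of a synthetic cohort, for parameter-recovery tests."""

    latent_factor: pd.Series
    covariate_effects: dict[str, float]
    outcome_effects: dict[str, float]
    batch_assignments: pd.Series
    gene_loadings: pd.Series | None = None
    batch_shifts: np.ndarray | None = None
    baseline_log_means: pd.Series | None = None
    lib_offsets: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "latent_factor": self.latent_factor.round(10).to_dict(),
            "covariate_effects": self.covariate_effects,
            "outcome_effects": self.outcome_effects,
            "batch_assignments": self.batch_assignments.to_dict(),
            "gene_loadings": (None if self.gene_loadings is None
                              else self.gene_loadings.round(10).to_dict()),
            "batch_shifts": (None if self.batch_shifts is None
                             else [float(x) for x in self.batch_shifts]),
        }


@dataclass
class SyntheticCohort:
    """A fully consistent synthetic data set: counts + phenotypes + sets + truth."""

    counts: CountMatrix
    phenotypes: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: TruthRecord

    def __post_init__(self) -> None:
        ids = list(self.phenotypes.index)
        if list(self.counts.sample_ids) != ids:
            raise ValidationError("count matrix and phenotype table sample ids disagree")
        if list(self.truth.latent_factor.index) != ids:
            raise ValidationError("truth record sample ids disagree with phenotypes")


def _overlap_count(spec: Mapping, a: str, b: str) -> int:
    for key in ((a, b), (b, a)):
        if key in spec:
            return int(spec[key])
    return 0


def generate_gene_sets(config: CohortConfig) -> GeneSetCollection:
    """Build CSP/SIP/SRP/Summary/SenMayo lists with the configured geometry.

    The SIP/SRP shared genes start with the sentinel pair (IGFBP7, AKT1);
    SenMayo's overlaps with CSP, SIP and SRP are mutually disjoint and do not
    touch the sentinel pair (no three-way overlaps).  The summary set is the
    deduplicated union of CSP, SIP and SRP.
    """
    sizes = dict(DEFAULT_GENE_SET_SIZES)
    sizes.update(config.gene_set_sizes)
    spec = config.overlap_spec
    supported = {frozenset(k) for k in DEFAULT_OVERLAPS}
    for pair, count in spec.items():
        if count and frozenset(pair) not in supported:
            raise ConfigurationError(
                f"unsupported overlap pair {pair}: only SIP/SRP and "
                "SenMayo vs CSP/SIP/SRP overlaps are modeled"
            )
    o_sip_srp = _overlap_count(spec, "SIP", "SRP")
    o_csp_sm = _overlap_count(spec, "CSP", "SenMayo")
    o_sip_sm = _overlap_count(spec, "SIP", "SenMayo")
    o_srp_sm = _overlap_count(spec, "SRP", "SenMayo")
    checks = [
        ("SIP size >= SIP/SRP + SIP/SenMayo overlaps",
         sizes["SIP"] >= o_sip_srp + o_sip_sm),
        ("SRP size >= SIP/SRP + SRP/SenMayo overlaps",
         sizes["SRP"] >= o_sip_srp + o_srp_sm),
        ("CSP size >= CSP/SenMayo overlap", sizes["CSP"] >= o_csp_sm),
        ("SenMayo size >= sum of its overlaps",
         sizes["SenMayo"] >= o_csp_sm + o_sip_sm + o_srp_sm),
    ]
    for label, ok in checks:
        if not ok:
            raise ConfigurationError(f"infeasible overlap geometry: {label}")

    counter = [0]

    def fresh(n: int) -> list[str]:
        out = [f"G{counter[0] + i + 1:04d}" for i in range(n)]
        counter[0] += n
        return out

    shared = list(SENTINEL_GENES[:min(len(SENTINEL_GENES), o_sip_srp)])
    shared += fresh(o_sip_srp - len(shared))
    csp_sm = fresh(o_csp_sm)
    sip_sm = fresh(o_sip_sm)
    srp_sm = fresh(o_srp_sm)
    csp = csp_sm + fresh(sizes["CSP"] - o_csp_sm)
    sip = shared + sip_sm + fresh(sizes["SIP"] - o_sip_srp - o_sip_sm)
    srp = shared + srp_sm + fresh(sizes["SRP"] - o_sip_srp - o_srp_sm)
    senmayo = csp_sm + sip_sm + srp_sm + fresh(
        sizes["SenMayo"] - o_csp_sm - o_sip_sm - o_srp_sm)

    csp_set = GeneSet("CSP", tuple(csp), role="CSP")
    sip_set = GeneSet("SIP", tuple(sip), role="SIP")
    srp_set = GeneSet("SRP", tuple(srp), role="SRP")
    summary = build_summary_set(csp_set, sip_set, srp_set)
    sm_set = GeneSet("SenMayo", tuple(senmayo), role="SenMayo")
    collection = GeneSetCollection(sets={
        "CSP": csp_set, "SIP": sip_set, "SRP": srp_set,
        "Summary": summary, "SenMayo": sm_set,
    })
    universe = set()
    for gs in collection:
        universe.update(gs.members)
    if len(universe) > config.n_genes:
        raise ConfigurationError(
            f"gene universe too small: sets need {len(universe)} distinct genes "
            f"but n_genes = {config.n_genes}"
        )
    return collection


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate_phenotypes(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw covariates, the latent senescence factor, outcomes and weights.

    Continuous outcomes are built as ``beta * factor + sqrt(1 - beta^2) *
    noise`` on the standardized scale, so the programmed ``beta`` is the
    population standardized association.  Multimorbidity and mortality use a
    logit link with the programmed log-odds per SD of the factor; the
    mortality intercept is solved so the realized expected event rate equals
    ``mortality_rate``.  Vital status: 1 = alive (contacted), 2 = presumed
    alive, 3 = deceased this wave, 4 = deceased prior wave; deaths are
    statuses 3 and 4.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    n = config.n_samples
    cov_eff = config.resolved_covariate_effects()
    out_eff = config.resolved_outcome_effects()

    ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id")
    df = pd.DataFrame(index=ids)
    df["age_group"] = rng.choice(AGE_GROUPS, size=n, p=AGE_PROBS)
    lo = np.array([AGE_BANDS[g][0] for g in df["age_group"]])
    hi = np.array([AGE_BANDS[g][1] for g in df["age_group"]])
    df["age_years"] = np.round(lo + (hi - lo) * rng.uniform(size=n), 1)
    df["female"] = rng.binomial(1, FEMALE_P, size=n)
    df["race_ethnicity"] = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    df["education"] = rng.choice(EDU_LEVELS, size=n, p=EDU_PROBS)
    df["bmi_class"] = rng.choice(BMI_LEVELS, size=n, p=BMI_PROBS)

    def _skew_gamma(mean: float, sd: float) -> np.ndarray:
        shape = (mean / sd) ** 2
        return rng.gamma(shape, mean / shape, size=n)

    df["pack_years"] = np.round(_skew_gamma(PACK_YEARS_MEAN, PACK_YEARS_SD), 1)
    df["weekly_drinks"] = np.round(_skew_gamma(DRINKS_MEAN, DRINKS_SD), 1)
    df["insomnia"] = rng.binomial(1, INSOMNIA_P, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    df["batch"] = pd.Series([f"plate{b + 1:02d}" for b in batch], index=ids)

    # Latent senescence factor: standardized covariate shifts plus noise.
    codes = {
        "age_group": np.array([AGE_GROUPS.index(g) for g in df["age_group"]], float),
        "age_years": df["age_years"].to_numpy(float),
        "female": df["female"].to_numpy(float),
        "race_ethnicity": np.array(
            [RACE_LEVELS.index(r) for r in df["race_ethnicity"]], float),
        "education": np.array([EDU_LEVELS.index(e) for e in df["education"]], float),
        "bmi_class": np.array([BMI_LEVELS.index(b) for b in df["bmi_class"]], float),
        "pack_years": df["pack_years"].to_numpy(float),
        "weekly_drinks": df["weekly_drinks"].to_numpy(float),
        "insomnia": df["insomnia"].to_numpy(float),
    }
    signal = np.zeros(n)
    for name, beta in cov_eff.items():
        signal += beta * _zscore(codes[name])
    resid_sd = math.sqrt(max(0.0, 1.0 - sum(b * b for b in cov_eff.values())))
    factor = signal + resid_sd * rng.standard_normal(n)

    def _linked(beta: float) -> np.ndarray:
        noise = rng.standard_normal(n)
        return beta * factor + math.sqrt(1.0 - beta * beta) * noise

    df["pace"] = np.round(PACE_MEAN + PACE_SD * _linked(out_eff.get("pace", 0.0)), 4)
    df["clock_aa"] = np.round(CLOCK_AA_SD * _linked(out_eff.get("clock_aa", 0.0)), 3)
    bio_aa = BIOAGE_AA_SD * _linked(out_eff.get("bioage_aa", 0.0))
    df["bioage"] = np.round(df["age_years"] + bio_aa, 2)
    cog = COGNITION_MEAN + COGNITION_SD * _linked(out_eff.get("cognition", 0.0))
    df["cognition"] = np.clip(np.round(cog), 0, 27).astype(int)
    p_mm = expit(logit(MULTIMORBIDITY_BASE_P)
                 + out_eff.get("multimorbidity", 0.0) * factor)
    df["multimorbidity"] = rng.binomial(MULTIMORBIDITY_TRIALS, p_mm)

    gamma_mort = out_eff.get("mortality", 0.0)
    if gamma_mort == 0.0:
        alpha = float(logit(config.mortality_rate))
    else:
        alpha = brentq(
            lambda a: expit(a + gamma_mort * factor).mean() - config.mortality_rate,
            -20.0, 20.0)
    died = rng.binomial(1, expit(alpha + gamma_mort * factor)).astype(bool)
    status = np.where(died,
                      np.where(rng.uniform(size=n) < 0.5, 3, 4),
                      np.where(rng.uniform(size=n) < config.presumed_alive_fraction,
                               2, 1)).astype(float)
    status[rng.uniform(size=n) < config.missing_vital_fraction] = np.nan
    df["vital_status"] = status
    df["mortality"] = np.where(np.isnan(status), np.nan, (status >= 3).astype(float))

    if config.missing_bioage_fraction > 0:
        miss = rng.uniform(size=n) < config.missing_bioage_fraction
        df.loc[miss, "bioage"] = np.nan

    w = rng.gamma(4.0, 0.25, size=n)
    if config.weight_age_corr:
        tilt = 1.0 + config.weight_age_corr * _zscore(codes["age_group"])
        w = w * np.clip(tilt, 0.1, None)
    df["weight"] = w / w.mean()

    if config.include_cell_proportions:
        props = rng.dirichlet(CELL_ALPHA, size=n)
        for j, ct in enumerate(CELL_TYPES):
            df[f"prop_{ct}"] = np.round(props[:, j], 5)

    truth = TruthRecord(
        latent_factor=pd.Series(factor, index=ids, name="latent_factor"),
        covariate_effects=cov_eff,
        outcome_effects=out_eff,
        batch_assignments=df["batch"].copy(),
    )
    return df, truth


def generate_counts(
    config: CohortConfig,
    phenotypes: pd.DataFrame,
    truth: TruthRecord,
    gene_sets: GeneSetCollection | None = None,
) -> CountMatrix:
    """Negative-binomial counts with the latent factor loading on set genes.

    log mean = gene baseline + library offset + batch shift
               + loading x latent factor,
    with NB variance ``mu + mu^2 / nb_dispersion``.  Loadings are nonzero
    only for genes belonging to a senescence set (uniform in
    ``[0.5, 1.5] * loading_scale`` on the natural-log scale).
    """
    if gene_sets is None:
        gene_sets = generate_gene_sets(config)
    rng = np.random.default_rng([int(config.seed) % (2**31), 23])
    n = len(phenotypes)
    factor = truth.latent_factor.to_numpy(float)

    set_genes: list[str] = []
    seen: set[str] = set()
    for gs in gene_sets:
        for g in gs.members:
            if g not in seen:
                seen.add(g)
                set_genes.append(g)
    filler = [f"F{i + 1:04d}" for i in range(config.n_genes - len(set_genes))]
    gene_ids = pd.Index(set_genes + filler, name="gene_id")

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    loadings = np.zeros(config.n_genes)
    n_set = len(set_genes)
    loadings[:n_set] = config.loading_scale * rng.uniform(0.5, 1.5, size=n_set)
    offsets = config.lib_size_log_sd * rng.standard_normal(n)
    shifts = config.batch_effect_sd * rng.standard_normal(config.n_batches)
    batch_idx = np.array([int(b[5:]) - 1 for b in truth.batch_assignments], int)

    log_mu = (baseline[:, None] + offsets[None, :] + shifts[batch_idx][None, :]
              + loadings[:, None] * factor[None, :])
    if not np.all(np.isfinite(log_mu)):
        raise ConfigurationError("non-finite log-means in count generation")
    mu = np.exp(log_mu)
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    cm = CountMatrix(values=pd.DataFrame(counts, index=gene_ids,
                                         columns=phenotypes.index))
    truth.gene_loadings = pd.Series(loadings, index=gene_ids, name="loading")
    truth.batch_shifts = shifts
    truth.baseline_log_means = pd.Series(baseline, index=gene_ids)
    truth.lib_offsets = pd.Series(offsets, index=phenotypes.index)
    return cm


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Compose gene sets, phenotypes and counts into one consistent cohort."""
    gene_sets = generate_gene_sets(config)
    phenotypes, truth = generate_phenotypes(config)
    counts = generate_counts(config, phenotypes, truth, gene_sets=gene_sets)
    return SyntheticCohort(counts=counts, phenotypes=phenotypes,
                           gene_sets=gene_sets, truth=truth)
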