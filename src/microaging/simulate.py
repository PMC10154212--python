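"""Synthetic multi-study cohort generator with planted ground truth.

The generator emulates the statistical structure the analysis framework
assumes in real multi-cohort microbiome data:

* several study cohorts of varying size, labelled shotgun or amplicon and
  grouped into data repositories;
* compositional species tables drawn multinomially at a fixed sequencing
  depth from per-sample latent log-abundances;
* a planted coabundance architecture -- one health-associated core factor
  and two disease-associated subhub factors loading on disjoint taxon
  rosters;
* age-dependent abundance shifts active only above 60 years, with
  study-specific slopes (between-study heterogeneity);
* a dominance-reshuffling disruption: unhealthy samples have their
  top-ranked core taxa attenuated and rank-jittered, so that Kendall
  uniqueness rises with health loss while richness-driven uniqueness need
  not -- the mechanism by which loss of core microbiome structure is
  planted;
* clinical measures coupled to the disease-group abundance, including a
  deliberately inverted (cognition-like) measure to exercise polarity
  handling, and binary disease labels from a thresholded latent liability.

Ground truth (rosters, per-study slopes, loadings, couplings) is returned
alongside the data for recovery testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    AbundanceTable,
    SampleMetadata,
    StudyCollection,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohorts",
    "generate_clinical_measures",
    "generate_dataset",
    "dominance_reshuffling_community",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-cohort generator.

    Slopes are in clr-units per decade, active only above ``age_onset``;
    ``study_sd`` is the between-study standard deviation of those slopes.
    Default scale mirrors a desk-size version of a large multi-repository
    aging meta-analysis: 10 studies of 150-500 samples, 120 species, depth
    50,000.
    """

    n_studies: int = 10
    samples_per_study: tuple = (150, 500)
    n_taxa: int = 120
    n_health_core: int = 20
    n_disease_subhub_1: int = 8
    n_disease_subhub_2: int = 8
    loading_health: float = 0.8
    loading_disease: float = 0.8
    age_range: tuple = (18.0, 100.0)
    age_onset: float = 60.0
    age_slope_disease: float = 0.5  # clr-units / decade after onset
    age_slope_health: float = -0.25
    study_sd: float = 0.1  # between-study SD of the per-decade slopes
    clinical_coupling: float = 0.3
    n_continuous_measures: int = 4
    n_binary_measures: int = 2
    disease_prevalence: float = 0.3
    depth: int = 50_000
    zero_rate: float = 0.05
    noise_sd: float = 1.0
    disruption_attenuation: float = 1.0  # core-taxon log attenuation in unhealthy samples
    disruption_jitter: float = 1.0  # rank-reshuffling log noise in unhealthy samples
    n_repositories: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        rosters = self.n_health_core + self.n_disease_subhub_1 + self.n_disease_subhub_2
        if rosters > self.n_taxa:
            raise ValidationError("roster sizes exceed n_taxa")
        for name in ("loading_health", "loading_disease"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if abs(self.clinical_coupling) > 1:
            raise ValidationError("clinical_coupling must lie in [-1, 1]")
        if self.depth < 1_000:
            raise ValidationError("depth must be at least 1,000")


@dataclass
class SyntheticTruth:
    """Planted parameters: the recovery oracle for every downstream stage."""

    health_core: list
    disease_subhub_1: list
    disease_subhub_2: list
    neutral: list
    study_slopes: dict  # study -> {"health": per-decade slope, "disease": ...}
    loadings: dict
    clinical_coupling: float
    measure_polarity: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def disease_roster(self) -> list:
        return self.disease_subhub_1 + self.disease_subhub_2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _taxon_ids(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(n)]


def generate_cohorts(config: SyntheticConfig, rng=None) -> tuple[StudyCollection, SyntheticTruth]:
    """Draw a multi-study collection of count tables plus its ground truth.

    Per sample, the latent log-abundance of taxon j is

        baseline_j + study offset + loading_j * factor(group_j)
        + slope_{study,group(j)} * max(0, age - 60)/10 + Normal(0, noise_sd)

    attenuated/jittered for top core taxa in proportion to the sample's
    disruption score (a monotone transform of its disease liability), then
    passed through a softmax and a multinomial draw at ``depth``.  A
    ``zero_rate`` fraction of taxon-sample pairs is dropped to zero before
    closure, emulating detection limits.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n_taxa
    taxa = _taxon_ids(n)
    order = rng.permutation(n)
    hc = sorted(taxa[i] for i in order[: config.n_health_core])
    d1 = sorted(
        taxa[i] for i in order[config.n_health_core : config.n_health_core + config.n_disease_subhub_1]
    )
    off = config.n_health_core + config.n_disease_subhub_1
    d2 = sorted(taxa[i] for i in order[off : off + config.n_disease_subhub_2])
    neutral = sorted(set(taxa) - set(hc) - set(d1) - set(d2))

    # stable baseline hierarchy: core taxa dominate, disease taxa subdominant
    baseline = pd.Series(rng.normal(0.0, 0.8, size=n), index=taxa)
    baseline[hc] += 2.0
    baseline[d1] -= 0.5
    baseline[d2] -= 0.5
    loading = pd.Series(0.0, index=taxa)
    loading[hc] = config.loading_health
    loading[d1] = config.loading_disease
    loading[d2] = config.loading_disease
    factor_of = pd.Series("none", index=taxa)
    factor_of[hc] = "health"
    factor_of[d1] = "disease1"
    factor_of[d2] = "disease2"

    # the most dominant core taxa are the ones attenuated under disruption
    top_core = list(baseline[hc].sort_values(ascending=False).index[: max(5, len(hc) // 2)])

    study_slopes = {}
    tables = {}
    meta_rows = []
    lo, hi = config.samples_per_study
    repos = [f"repo{r + 1}" for r in range(config.n_repositories)]
    repository = {}
    disruption_scores = {}
    for s in range(config.n_studies):
        study = f"study{s + 1:02d}"
        repository[study] = repos[s % config.n_repositories]
        data_type = "shotgun" if s % 2 == 0 else "amplicon"
        n_s = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
        ages = rng.uniform(config.age_range[0], config.age_range[1], size=n_s)
        slopes = {
            "health": float(rng.normal(config.age_slope_health, config.study_sd)),
            "disease": float(rng.normal(config.age_slope_disease, config.study_sd)),
        }
        study_slopes[study] = slopes
        study_offset = rng.normal(0.0, 0.3, size=n)

        f_health = rng.normal(size=n_s)
        f_d1 = rng.normal(size=n_s)
        f_d2 = rng.normal(size=n_s)
        factors = {
            "none": np.zeros(n_s),
            "health": f_health,
            "disease1": f_d1,
            "disease2": f_d2,
        }
        decades_past = np.maximum(0.0, ages - config.age_onset) / 10.0
        slope_vec = np.zeros(n)
        for g, roster in (("health", hc), ("disease", d1 + d2)):
            slope_vec[[taxa.index(t) for t in roster]] = slopes[g]

        latent = (
            baseline.to_numpy()[:, None]
            + study_offset[:, None]
            + loading.to_numpy()[:, None] * np.vstack([factors[factor_of[t]] for t in taxa])
            + slope_vec[:, None] * decades_past[None, :]
            + rng.normal(0.0, config.noise_sd, size=(n, n_s))
        )
        # disruption: disease liability attenuates and rank-jitters top core taxa
        liability = (f_d1 + f_d2) / np.sqrt(2.0) + 0.3 * decades_past
        delta = 1.0 / (1.0 + np.exp(-liability))  # in (0, 1)
        disruption_scores[study] = delta
        top_idx = [taxa.index(t) for t in top_core]
        latent[top_idx, :] -= config.disruption_attenuation * delta[None, :]
        latent[top_idx, :] += rng.normal(
            0.0, config.disruption_jitter, size=(len(top_idx), n_s)
        ) * delta[None, :]

        if config.zero_rate > 0:
            drop = rng.random(size=(n, n_s)) < config.zero_rate
            latent = np.where(drop, -np.inf, latent)
        expl = np.exp(latent - latent.max(axis=0, keepdims=True))
        probs = expl / expl.sum(axis=0, keepdims=True)
        counts = np.column_stack(
            [rng.multinomial(config.depth, probs[:, i]) for i in range(n_s)]
        )
        sample_ids = [f"{study}_s{i:04d}" for i in range(n_s)]
        tables[study] = AbundanceTable(
            pd.DataFrame(counts.astype(float), index=taxa, columns=sample_ids),
            level="species",
            scale="counts",
        )
        for sid, age in zip(sample_ids, ages):
            meta_rows.append(
                dict(sample_id=sid, study_id=study, age=float(age), data_type=data_type,
                     health_status="unknown")
            )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    collection = StudyCollection(tables=tables, metadata=metadata, repository=repository)
    truth = SyntheticTruth(
        health_core=hc,
        disease_subhub_1=d1,
        disease_subhub_2=d2,
        neutral=neutral,
        study_slopes=study_slopes,
        loadings={"health": config.loading_health, "disease": config.loading_disease},
        clinical_coupling=config.clinical_coupling,
        seed=config.seed,
    )
    truth._disruption = disruption_scores  # internal: reused by clinical coupling
    return collection, truth


def _disease_group_signal(collection: StudyCollection, truth: SyntheticTruth) -> pd.Series:
    """Standardised per-sample disease-group clr abundance (per study)."""
    from .groups import _study_clr_tables

    clr_tables = _study_clr_tables(collection, "auto")
    parts = []
    for study in collection.study_ids:
        table = clr_tables[study]
        roster = [t for t in truth.disease_roster if t in table.values.index]
        mean_clr = table.values.loc[roster].mean(axis=0)
        z = (mean_clr - mean_clr.mean()) / mean_clr.std(ddof=0)
        parts.append(z)
    return pd.concat(parts)


def generate_clinical_measures(
    collection: StudyCollection,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng=None,
) -> StudyCollection:
    """Attach clinical measures coupled to the disease-group abundance.

    Continuous measures are ``rho * z + sqrt(1 - rho^2) * noise`` with ``z``
    the standardised disease-group clr abundance, so their correlation with
    the microbiome signal equals the configured coupling.  One measure is
    emitted inverted (higher = healthier, cognition-score style) and
    registered with negative polarity.  Binary disease labels threshold a
    latent liability at the configured prevalence; ``health_status`` is set
    to case/control accordingly.
    """
    rng = np.random.default_rng((config.seed + 1) if rng is None else rng)
    rho = config.clinical_coupling
    if abs(rho) > 1:
        raise ValidationError("clinical_coupling must lie in [-1, 1]")
    z = _disease_group_signal(collection, truth)
    meta = collection.metadata.frame.copy()
    meta = meta.loc[z.index]
    resid = np.sqrt(max(0.0, 1 - rho**2))
    polarity = {}
    for k in range(config.n_continuous_measures):
        vals = rho * z.to_numpy() + resid * rng.normal(size=len(z))
        if k == config.n_continuous_measures - 1 and config.n_continuous_measures > 1:
            name = "mmse_like"  # inverted: higher = healthier
            meta[name] = -vals
            polarity[name] = "unhealthy_negative"
        else:
            name = f"frailty_{k + 1}"
            meta[name] = vals
            polarity[name] = "unhealthy_positive"
    any_case = np.zeros(len(z), dtype=bool)
    for k in range(config.n_binary_measures):
        liability = rho * z.to_numpy() + resid * rng.normal(size=len(z))
        thresh = np.quantile(liability, 1 - config.disease_prevalence)
        flag = (liability > thresh).astype(float)
        name = f"disease_{k + 1}"
        meta[name] = flag
        polarity[name] = "unhealthy_positive"
        any_case |= flag.astype(bool)
    meta["health_status"] = np.where(any_case, "case", "control")
    truth.measure_polarity = polarity
    new_meta = SampleMetadata(meta.reset_index(drop=True))
    return StudyCollection(
        tables=collection.tables, metadata=new_meta, repository=dict(collection.repository)
    )


def generate_dataset(config: SyntheticConfig, rng=None) -> tuple[StudyCollection, SyntheticTruth]:
    """Cohorts plus clinical measures in one call (the pipeline entry point)."""
    base_rng = np.random.default_rng(config.seed if rng is None else rng)
    collection, truth = generate_cohorts(config, rng=base_rng)
    collection = generate_clinical_measures(collection, truth, config, rng=base_rng)
    return collection, truth


def dominance_reshuffling_community(
    n_samples: int = 1000,
    n_core: int = 40,
    rare_pool: int = 300,
    rare_range: tuple = (40, 100),
    core_mass: float = 0.5,
    gamma_base: float = 1.0,
    gamma_disruption: float = 2.0,
    shuffle_scale: float = 20.0,
    n_fixed_dominant: int = 4,
    depth: int = 50_000,
    seed: int = 0,
) -> tuple[AbundanceTable, pd.Series]:
    """Single-cohort generator where disruption reshuffles the dominance
    hierarchy.

    Two independent per-sample axes drive the community:

    * richness: a random subset of ``rare_range`` taxa from a large rare
      pool carries a mass share proportional to the number detected (up to
      ``1 - core_mass`` at the top of the range) -- more rare taxa mean
      higher Shannon diversity and more unshared abundance relative to any
      neighbour (Bray-Curtis/Jaccard uniqueness);
    * disruption delta ~ U(0, 1): the core power-law exponent steepens with
      delta (lower evenness, lower Shannon) while the assignment of
      *subdominant* core taxa to rank slots is jittered in proportion to
      delta (scrambling the abundance hierarchy, hence Kendall uniqueness).
      The ``n_fixed_dominant`` most dominant rank slots keep a fixed taxon
      identity, so disrupted samples still resemble each other in
      abundance-weighted (Bray-Curtis) space even as their hierarchy
      scrambles.

    Because disruption lowers diversity *and* scrambles ranks, Kendall
    uniqueness correlates negatively with Shannon on this community while
    the richness axis keeps Bray-Curtis uniqueness non-negatively
    correlated with it.  Returns the count table and the true per-sample
    disruption scores.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"core{i:03d}" for i in range(n_core)] + [f"rare{i:03d}" for i in range(rare_pool)]
    counts = np.zeros((n_core + rare_pool, n_samples))
    delta = rng.uniform(0.0, 1.0, size=n_samples)
    ranks = np.arange(1, n_core + 1, dtype=float)
    k_fix = min(n_fixed_dominant, n_core)
    for i in range(n_samples):
        gamma = gamma_base + gamma_disruption * delta[i]
        weights = ranks**-gamma
        # jitter which core taxon occupies which subdominant rank slot,
        # strength ~ delta; dominant slots keep fixed taxon identity
        n_tail = n_core - k_fix
        slot_keys = np.arange(n_tail) + delta[i] * shuffle_scale * rng.normal(size=n_tail)
        assignment = np.concatenate([np.arange(k_fix), k_fix + np.argsort(slot_keys)])
        core_p = np.zeros(n_core)
        core_p[assignment] = weights / weights.sum()
        n_rare = int(rng.integers(rare_range[0], rare_range[1] + 1))
        rare_idx = rng.choice(rare_pool, size=n_rare, replace=False)
        rare_p = rng.dirichlet(np.ones(n_rare))
        # rare mass grows with richness: unusual rare content makes a sample
        # both more diverse and more distant from any neighbour
        rare_mass = (1 - core_mass) * n_rare / rare_range[1]
        p = np.zeros(n_core + rare_pool)
        p[:n_core] = (1 - rare_mass) * core_p
        p[n_core + rare_idx] = rare_mass * rare_p
        counts[:, i] = rng.multinomial(depth, p)
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=taxa, columns=sample_ids), level="species", scale="counts"
    )
    return table, pd.Series(delta, index=sample_ids, name="disruption")
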