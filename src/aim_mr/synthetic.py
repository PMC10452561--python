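"""Synthetic admixed cohorts with the statistical structure the analysis assumes.

The generator emulates a four-way admixed population (a Mapuche-like target
population plus Aymara-, European- and African-like sources): reference-panel
allele frequencies diverge under a Balding-Nichols beta model, individual
ancestry proportions follow a Dirichlet distribution with a target-dominated
gradient, genotypes are binomial draws given the ancestry-weighted frequency,
and outcomes are generated directly on the ancestry proportion — a binary
disease on the log-odds scale and a continuous trait on the linear scale,
both per 1% of target ancestry, with small age and sex terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AlleleFrequencyTable,
    AncestryProportions,
    ConfigurationError,
    GenotypeMatrix,
)

#: Roles of the K=4 default source populations.
DEFAULT_POPULATIONS = ["MAPUCHE", "AYMARA", "EUROPEAN", "AFRICAN"]

FREQ_CLAMP = (0.01, 0.99)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study design the pipeline targets: K=4 source
    populations, a target(Mapuche)-dominated Dirichlet admixture gradient,
    and per-1%-ancestry causal effects of realistic epidemiological size
    (log-OR 0.008 per 1% for the binary disease, -0.006 units per 1% for the
    continuous trait).
    """

    n_populations: int = 4
    n_variants: int = 1000
    n_individuals: int = 1000
    divergence: float = 0.2
    dirichlet_alpha: tuple[float, ...] = (4.0, 2.0, 3.0, 0.5)
    causal_effect_binary: float = 0.008
    causal_effect_continuous: float = -0.006
    baseline_prevalence: float = 0.1
    noise_sd: float = 1.0
    age_effect_binary: float = 0.02
    sex_effect_binary: float = 0.3
    seed: int = 0
    populations: list[str] = field(default_factory=lambda: list(DEFAULT_POPULATIONS))
    target_population: str = "MAPUCHE"

    def validate(self) -> None:
        if self.n_populations < 2:
            raise ConfigurationError("need at least K=2 source populations")
        if self.n_variants <= 0 or self.n_individuals <= 0:
            raise ConfigurationError("n_variants and n_individuals must be positive")
        if not (0.0 <= self.divergence < 1.0):
            raise ConfigurationError("divergence must lie in [0, 1)")
        if len(self.dirichlet_alpha) != self.n_populations:
            raise ConfigurationError(
                "dirichlet_alpha length must equal n_populations"
            )
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigurationError("dirichlet_alpha entries must be positive")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ConfigurationError("baseline_prevalence must lie in (0, 1)")
        if len(self.populations) != self.n_populations:
            raise ConfigurationError("populations length must equal n_populations")
        if self.target_population not in self.populations:
            raise ConfigurationError("target_population must be one of populations")


@dataclass
class SyntheticCohort:
    """A simulated admixed sample with true ancestry and outcomes."""

    genotypes: GenotypeMatrix
    ancestry_true: AncestryProportions
    outcome_binary: np.ndarray
    outcome_continuous: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        n = self.genotypes.n_individuals
        for name in ("outcome_binary", "outcome_continuous", "age", "sex"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"{name} length does not match genotypes")


def simulate_reference_panel(config: SimulationConfig) -> AlleleFrequencyTable:
    """Draw a K x M reference allele-frequency table.

    The ancestral frequency of each variant is uniform on (0.05, 0.95); each
    population's frequency is a Balding-Nichols beta draw around it with
    dispersion ``divergence`` (F). ``divergence = 0`` is the zero-dispersion
    limit in which every population shares the ancestral frequency exactly.
    Frequencies are clamped to [0.01, 0.99] so no marker is fixed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k, m = config.n_populations, config.n_variants
    p_anc = rng.uniform(0.05, 0.95, size=m)
    if config.divergence == 0.0:
        freq = np.tile(p_anc, (k, 1))
    else:
        f = config.divergence
        scale = (1.0 - f) / f
        freq = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(k, m))
    freq = np.clip(freq, *FREQ_CLAMP)
    variant_ids = np.array([f"rs{i:06d}" for i in range(m)], dtype=object)
    effect = np.full(m, "A", dtype=object)
    other = np.full(m, "G", dtype=object)
    return AlleleFrequencyTable(
        variant_ids=variant_ids,
        populations=list(config.populations),
        freq=freq,
        effect_alleles=effect,
        other_alleles=other,
    )


def simulate_admixed_cohort(
    panel: AlleleFrequencyTable,
    config: SimulationConfig,
    seed: int | None = None,
) -> SyntheticCohort:
    """Simulate an admixed cohort given a reference panel.

    Per individual: ancestry q ~ Dirichlet(alpha), stored in percent; per
    variant, genotype ~ Binomial(2, f) with f the ancestry-weighted mixture
    of panel frequencies. The binary outcome follows a prospective logistic
    model with log-odds ``logit(prevalence) + effect * q_target`` plus small
    age/sex terms; the continuous outcome is linear in q_target with
    Gaussian noise.
    """
    config.validate()
    if panel.n_populations != len(config.dirichlet_alpha):
        raise ConfigurationError(
            f"panel has {panel.n_populations} populations but dirichlet_alpha "
            f"has length {len(config.dirichlet_alpha)}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    q = rng.dirichlet(config.dirichlet_alpha, size=n)  # fraction scale
    f_ind = q @ panel.freq  # n x M individual-specific frequencies
    dosage = rng.binomial(2, f_ind).astype(np.int8)

    age = rng.uniform(30.0, 80.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    q_target_pct = 100.0 * q[:, panel.population_index(config.target_population)]

    from scipy.special import expit, logit

    # Centre covariate terms so baseline_prevalence stays the prevalence at
    # the mean covariate value and zero target ancestry.
    eta = (
        logit(config.baseline_prevalence)
        + config.causal_effect_binary * q_target_pct
        + config.age_effect_binary * (age - age.mean())
        + config.sex_effect_binary * (sex - sex.mean())
    )
    outcome_binary = rng.binomial(1, expit(eta)).astype(np.int8)
    outcome_continuous = (
        25.0
        + config.causal_effect_continuous * q_target_pct
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    iids = np.array([f"ind{i:06d}" for i in range(n)], dtype=object)
    genotypes = GenotypeMatrix(
        individual_ids=iids,
        variant_ids=panel.variant_ids,
        dosage=dosage,
        effect_alleles=panel.effect_alleles,
        other_alleles=panel.other_alleles,
    )
    q_pct = 100.0 * q
    # exact-sum normalisation guards against float drift
    q_pct *= 100.0 / q_pct.sum(axis=1, keepdims=True)
    ancestry = AncestryProportions(
        individual_ids=iids, populations=list(panel.populations), q=q_pct
    )
    return SyntheticCohort(
        genotypes=genotypes,
        ancestry_true=ancestry,
        outcome_binary=outcome_binary,
        outcome_continuous=outcome_continuous,
        age=age,
        sex=sex,
    )


def case_control_sample(
    cohort: SyntheticCohort, n_pairs: int, seed: int
) -> tuple[SyntheticCohort, float]:
    """Down-sample a prospective cohort to a matched case-control design.

    Takes ``n_pairs`` cases and the same number of controls at random (the
    matched design of the study it emulates); returns the sampled cohort and
    the case sampling fraction, which callers should log.
    """
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(cohort.outcome_binary == 1)
    controls = np.flatnonzero(cohort.outcome_binary == 0)
    if len(cases) < n_pairs or len(controls) < n_pairs:
        raise ConfigurationError(
            f"cohort has {len(cases)} cases / {len(controls)} controls; "
            f"cannot sample {n_pairs} pairs"
        )
    pick = np.sort(
        np.concatenate(
            [
                rng.choice(cases, size=n_pairs, replace=False),
                rng.choice(controls, size=n_pairs, replace=False),
            ]
        )
    )
    g = cohort.genotypes
    sampled = SyntheticCohort(
        genotypes=GenotypeMatrix(
            individual_ids=g.individual_ids[pick],
            variant_ids=g.variant_ids,
            dosage=g.dosage[pick],
            effect_alleles=g.effect_alleles,
            other_alleles=g.other_alleles,
        ),
        ancestry_true=AncestryProportions(
            individual_ids=cohort.ancestry_true.individual_ids[pick],
            populations=cohort.ancestry_true.populations,
            q=cohort.ancestry_true.q[pick],
        ),
        outcome_binary=cohort.outcome_binary[pick],
        outcome_continuous=cohort.outcome_continuous[pick],
        age=cohort.age[pick],
        sex=cohort.sex[pick],
    )
    return sampled, n_pairs / max(len(cases), 1)
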