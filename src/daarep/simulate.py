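"""Seeded simulation of compositional microbiome count data with known truth.

The generator emulates the statistical structure of real taxonomic-profiling
datasets: a heavy-tailed baseline composition, a minority of taxa carrying a
group effect on the relative-abundance scale, uniformly varying library
sizes, and zero-heavy overdispersed (gamma-Poisson) counts.

The generative recipe:

1. baseline taxon mean relative abundances are drawn from a gamma
   distribution with shape ``base_abundance_dispersion`` and normalized to
   sum to one (small shape => heavy tail => many rare taxa);
2. a fraction ``frac_differential`` of taxa is flagged differential and its
   case-group means are multiplied by ``exp(+/- effect_log_fc)`` (sign drawn
   per taxon with equal probability), after which each sample's expected
   composition is renormalized — the planted truth is therefore a
   relative-abundance effect;
3. each sample's library size is drawn uniformly from
   ``library_size_range``;
4. counts are gamma-Poisson: ``Poisson(library * proportion * G)`` with
   ``G ~ Gamma(shape=taxon_dispersion, mean=1)`` drawn per cell, so smaller
   ``taxon_dispersion`` means more overdispersion and more zeros.

Zero inflation arises implicitly from low means plus overdispersion; an
explicit ``dropout`` probability is available for prevalence-structure
stress tests but defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, GROUP_COLUMN, CountDataset, GroundTruth


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class CovariateSpec:
    """A simulated per-sample confounder.

    ``effect_log_scale`` is the per-unit multiplicative effect (log scale) on
    the means of a random subset of taxa (fraction ``frac_taxa_affected``).
    ``kind`` is ``"continuous"`` (standard normal) or ``"binary"``
    (Bernoulli(0.5)).  ``group_correlation`` shifts the covariate mean in the
    case group to induce confounding.
    """

    name: str
    effect_log_scale: float = 0.0
    kind: str = "continuous"
    group_correlation: float = 0.0
    frac_taxa_affected: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults describe a mid-sized case/control study: 50 + 50 samples,
    150 taxa of which 10% carry a planted relative-abundance log fold-change
    of magnitude 1.5, library sizes 10k-50k reads.
    """

    n_case: int = 50
    n_control: int = 50
    n_taxa: int = 150
    frac_differential: float = 0.1
    effect_log_fc: float = 1.5
    base_abundance_dispersion: float = 0.3
    taxon_dispersion: float = 0.3
    library_size_range: tuple[int, int] = (10_000, 50_000)
    dropout: float = 0.0
    covariate_spec: tuple[CovariateSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1:
            raise ConfigurationError(f"n_case must be >= 1, got {self.n_case}")
        if self.n_control < 1:
            raise ConfigurationError(f"n_control must be >= 1, got {self.n_control}")
        if self.n_taxa < 1:
            raise ConfigurationError(f"n_taxa must be >= 1, got {self.n_taxa}")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigurationError(
                f"frac_differential must be in [0, 1], got {self.frac_differential}"
            )
        if self.effect_log_fc < 0:
            raise ConfigurationError(f"effect_log_fc must be >= 0, got {self.effect_log_fc}")
        if self.base_abundance_dispersion <= 0:
            raise ConfigurationError(
                f"base_abundance_dispersion must be > 0, got {self.base_abundance_dispersion}"
            )
        if self.taxon_dispersion <= 0:
            raise ConfigurationError(
                f"taxon_dispersion must be > 0, got {self.taxon_dispersion}"
            )
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                f"library_size_range must satisfy 0 < min <= max, got {self.library_size_range}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")


def draw_composition(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, float]:
    """Draw the expected group compositions and the per-taxon truth table.

    Returns ``(mean_control, mean_case, truth_table, closure_norm)`` where the
    mean vectors are expected relative abundances (each summing to 1) and
    ``closure_norm`` is the factor the case composition was divided by when
    re-closing it after the perturbation.
    """
    t = config.n_taxa
    base = rng.gamma(shape=config.base_abundance_dispersion, scale=1.0, size=t)
    base = np.maximum(base, 1e-12)
    base /= base.sum()

    n_diff = int(round(config.frac_differential * t))
    diff_idx = rng.choice(t, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_diff)

    log_fc = np.zeros(t)
    log_fc[diff_idx] = signs * config.effect_log_fc

    case_raw = base * np.exp(log_fc)
    closure_norm = case_raw.sum()
    case = case_raw / closure_norm

    taxon_ids = pd.Index([f"taxon_{i:04d}" for i in range(t)], name="taxon_id")
    is_diff = np.zeros(t, dtype=bool)
    is_diff[diff_idx] = True
    truth = pd.DataFrame(
        {
            "is_differential": is_diff,
            "true_direction": np.sign(log_fc).astype(int),
            "true_log_fc": log_fc,
            "mean_control": base,
            "mean_case": case,
        },
        index=taxon_ids,
    )
    return base, case, truth, float(closure_norm)


def sample_counts(
    mean_control: np.ndarray,
    mean_case: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw a count matrix given expected group compositions.

    Returns ``(counts, case_mask, covariates)`` with counts shaped
    (n_taxa, n_samples); control samples come first, then case samples.
    """
    t = config.n_taxa
    n = config.n_control + config.n_case
    case_mask = np.zeros(n, dtype=bool)
    case_mask[config.n_control :] = True

    # per-sample expected composition (taxa x samples)
    comp = np.where(case_mask[None, :], mean_case[:, None], mean_control[:, None]).astype(float)

    cov_table = {}
    for spec in config.covariate_spec:
        if spec.kind == "binary":
            z = rng.binomial(1, 0.5, size=n).astype(float)
        elif spec.kind == "continuous":
            z = rng.normal(size=n)
        else:
            raise ConfigurationError(f"unknown covariate kind {spec.kind!r} for {spec.name!r}")
        z = z + spec.group_correlation * case_mask
        affected = rng.random(t) < spec.frac_taxa_affected
        comp[affected, :] *= np.exp(spec.effect_log_scale * z[None, :])
        cov_table[spec.name] = z
    comp /= comp.sum(axis=0, keepdims=True)

    lo, hi = config.library_size_range
    libs = rng.integers(lo, hi + 1, size=n)

    k = config.taxon_dispersion
    gamma_noise = rng.gamma(shape=k, scale=1.0 / k, size=(t, n))
    lam = comp * libs[None, :] * gamma_noise
    counts = rng.poisson(lam)
    if config.dropout > 0:
        counts = np.where(rng.random((t, n)) < config.dropout, 0, counts)
    covariates = pd.DataFrame(cov_table)
    return counts, case_mask, covariates


def simulate_dataset(config: SimulationConfig) -> tuple[CountDataset, GroundTruth]:
    """Generate one seeded dataset together with its ground truth."""
    rng = np.random.default_rng(config.seed)
    mean_control, mean_case, truth, closure_norm = draw_composition(config, rng)
    counts, case_mask, covariates = sample_counts(mean_control, mean_case, config, rng)

    n = counts.shape[1]
    sample_ids = pd.Index([f"sample_{i:04d}" for i in range(n)], name="sample_id")
    meta = pd.DataFrame(
        {GROUP_COLUMN: np.where(case_mask, CASE, CONTROL)}, index=sample_ids
    )
    for name in covariates.columns:
        meta[name] = covariates[name].to_numpy()
    dataset = CountDataset(
        counts=pd.DataFrame(counts, index=truth.index, columns=sample_ids),
        metadata=meta,
        provenance=f"simulated(seed={config.seed})",
    )
    return dataset, GroundTruth(table=truth, closure_norm=closure_norm)


def simulate_null_dataset(config: SimulationConfig) -> tuple[CountDataset, GroundTruth]:
    """Same pipeline with ``frac_differential`` forced to zero (global null)."""
    return simulate_dataset(replace(config, frac_differential=0.0))


def permute_labels(dataset: CountDataset, seed: int) -> CountDataset:
    """Uniformly permute the group labels; counts and covariates stay put.

    Each sample keeps its counts and covariate values; only the case/control
    assignment is shuffled, preserving the group-size multiset.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.group.to_numpy().copy()
    rng.shuffle(labels)
    permuted = dataset.with_group(pd.Series(labels, index=dataset.metadata.index))
    permuted.provenance = f"{dataset.provenance}|permuted(seed={seed})"
    return permuted
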