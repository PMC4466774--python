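"""Synthetic genotype/phenotype data with known ground truth.

The generator emulates the statistical regime genomic-selection methods
assume: n individuals genotyped at p biallelic markers (n << p in
realistic settings), with a quantitative trait controlled by a small
number of causal loci (QTL) at a chosen narrow-sense heritability h².

Genotypes are allele counts drawn under Hardy–Weinberg equilibrium:
marker j gets an allele frequency f_j uniform over ``maf_range`` and
each individual's genotype is Binomial(2, f_j).  Markers are
independent (no linkage disequilibrium) unless ``ld_block_size`` > 1,
in which case each causal marker is duplicated into a block of noisy
copies as a parametric stand-in for LD.

Traits are built as genetic value plus Gaussian noise: ``n_qtl``
markers get standard-normal additive effects (the
additive-plus-epistatic architecture adds products of QTL genotype
pairs), and the noise variance is set to ``var(g) (1 - h²) / h²`` so
the realized heritability matches the request.  Traits are shifted
nonnegative at generation so NDCG applies directly.  Because the noise
is independent of g, the Pearson correlation of the true genetic values
with the trait approaches sqrt(h²) — the theoretical accuracy ceiling
of any marker-based predictor.

Separate deterministic random streams drive genotypes, effects and
noise, so e.g. regenerating the trait at a different h² leaves the
genotype matrix untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import Dataset, MarkerMatrix, TraitVector

__all__ = ["SimConfig", "SimulatedDataset", "simulate_genotypes",
           "simulate_trait", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults give a realistic n << p regime."""

    n: int = 400
    p: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 20
    heritability: float = 0.6
    architecture: str = "additive"
    encoding: str = "codominant-012"
    ld_block_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed p")
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must be in [0, 1]")
        if self.architecture not in ("additive", "additive-plus-epistatic"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated data plus its generating ground truth."""

    dataset: Dataset
    true_genetic_values: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray


def _streams(seed: int):
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(3)]


def simulate_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Draw an n x p allele-count genotype matrix under Hardy–Weinberg."""
    geno_rng, _, _ = _streams(cfg.seed)
    lo, hi = cfg.maf_range
    freqs = geno_rng.uniform(lo, hi, size=cfg.p)
    values = geno_rng.binomial(2, freqs, size=(cfg.n, cfg.p))
    if cfg.ld_block_size > 1:
        # parametric LD stand-in: repeat markers with random flips
        reps = np.repeat(np.arange(cfg.p), cfg.ld_block_size)[: cfg.p]
        base = values[:, reps]
        flips = geno_rng.random(base.shape) < 0.05
        noise = geno_rng.binomial(2, freqs[reps], size=base.shape)
        values = np.where(flips, noise, base)
    width = len(str(max(cfg.n, cfg.p)))
    return MarkerMatrix(
        values=values,
        sample_ids=[f"S{i:0{width}d}" for i in range(1, cfg.n + 1)],
        marker_ids=[f"M{j:0{width}d}" for j in range(1, cfg.p + 1)],
        encoding=cfg.encoding,
    )


def simulate_trait(X: MarkerMatrix, cfg: SimConfig) -> SimulatedDataset:
    """Simulate a trait on existing genotypes at the configured h²."""
    _, effect_rng, noise_rng = _streams(cfg.seed)
    qtl = np.sort(effect_rng.choice(X.p, size=cfg.n_qtl, replace=False))
    effects = effect_rng.standard_normal(cfg.n_qtl)
    G = X.values[:, qtl].astype(float)
    g = G @ effects
    if cfg.architecture == "additive-plus-epistatic":
        # pairwise interactions between consecutive QTL
        pair_effects = effect_rng.standard_normal(max(cfg.n_qtl - 1, 0))
        for idx in range(cfg.n_qtl - 1):
            g = g + pair_effects[idx] * G[:, idx] * G[:, idx + 1]
    var_g = float(np.var(g))
    h2 = cfg.heritability
    if h2 == 0:
        warnings.warn(
            "heritability 0: the trait is pure noise and carries no "
            "marker signal",
            RuntimeWarning,
            stacklevel=2,
        )
        noise_sd = np.sqrt(var_g) if var_g > 0 else 1.0
        y = noise_rng.standard_normal(X.n) * noise_sd
    elif h2 == 1:
        y = g.copy()
    else:
        noise_var = var_g * (1 - h2) / h2
        y = g + noise_rng.standard_normal(X.n) * np.sqrt(noise_var)
    trait = TraitVector(values=y - y.min(), trait_name="sim_trait")
    return SimulatedDataset(
        dataset=Dataset(markers=X, traits=[trait]),
        true_genetic_values=g,
        qtl_indices=qtl,
        qtl_effects=effects,
    )


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Genotypes and one trait in one call."""
    return simulate_trait(simulate_genotypes(cfg), cfg)
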