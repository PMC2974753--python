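"""Synthetic haploid biparental cross with planted genetic architectures.

Genotypes follow a two-state Markov chain along each chromosome: the
first marker of each chromosome is Bernoulli(0.5) per strain and every
subsequent marker flips parent with the recombination fraction (no
interference; chromosomes independent).  This emulates segregant panels
such as a yeast cross or the *P. falciparum* Hb3xDd2 progeny, and keeps
closed-form checks available: the allelic correlation between adjacent
markers is 1 - 2r.

Expression traits come in four classes with known ground truth:

* single-locus:  y = beta * g_m + eps
* polygenic:     y = sum_k beta_k * g_{m_k} + eps  (k loci, drawn
  without replacement; by default beta_k = beta / sqrt(k) so the total
  genetic variance matches the single-locus class)
* hotspot:       single-locus traits all sharing one designated marker
* null:          y = eps

with eps iid Normal(0, sd^2).  Effect sizes are interpreted as
beta / sd; with Var(g) = 1/4, a single locus with beta/sd = 2 explains
an expected r^2 of 0.5 of the trait's variance at n -> infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, GenotypeMatrix, MarkerMap, ValidationError


@dataclass
class SimConfig:
    """Study-design parameters for one simulated cross."""

    n_chromosomes: int = 5
    markers_per_chromosome: int = 20
    n_strains: int = 50
    recombination_fraction: float = 0.1
    n_single: int = 50
    single_beta: float = 2.0
    n_polygenic: int = 50
    polygenic_k: int = 5
    polygenic_beta: float | None = None  # default: single_beta / sqrt(k)
    n_null: int = 100
    noise_sd: float = 1.0
    hotspot_marker: str | None = None
    n_hotspot: int = 0
    missing_rate: float = 0.0
    cis_fraction: float | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chromosomes, self.markers_per_chromosome, self.n_strains) < 1:
            raise ValidationError("need >=1 chromosome, marker and strain")
        if not 0 < self.recombination_fraction <= 0.5:
            raise ValidationError("recombination_fraction must be in (0, 0.5]")
        if min(self.n_single, self.n_polygenic, self.n_null, self.n_hotspot) < 0:
            raise ValidationError("trait counts must be non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.polygenic_k > self.n_markers:
            raise ValidationError("more causal loci requested than markers exist")
        if self.n_hotspot > 0 and self.hotspot_marker is None:
            raise ValidationError("hotspot traits requested without a hotspot_marker")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    @property
    def n_traits(self) -> int:
        return self.n_single + self.n_polygenic + self.n_null + self.n_hotspot

    @property
    def polygenic_beta_effective(self) -> float:
        if self.polygenic_beta is not None:
            return self.polygenic_beta
        return self.single_beta / math.sqrt(self.polygenic_k)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(eq=False)
class GroundTruth:
    """Per-trait planted architecture: class, causal markers, effects, chromosome."""

    table: pd.DataFrame  # trait, label, causal_markers, effect_sizes, trait_chrom

    COLUMNS = ("trait", "label", "causal_markers", "effect_sizes", "trait_chrom")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"ground truth missing columns {missing}")

    def traits_of(self, label: str) -> list:
        return self.table.loc[self.table["label"] == label, "trait"].tolist()

    def causal_markers_of(self, trait: str) -> list:
        row = self.table.loc[self.table["trait"] == trait, "causal_markers"]
        if row.empty:
            raise KeyError(trait)
        value = row.iloc[0]
        return [] if value in ("", None) or pd.isna(value) else str(value).split(";")

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))


def _marker_map(cfg: SimConfig) -> MarkerMap:
    ids, chroms, pos = [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        for j in range(1, cfg.markers_per_chromosome + 1):
            ids.append(f"chr{c}_m{j:02d}")
            chroms.append(f"chr{c}")
            pos.append(float(j))
    return MarkerMap(tuple(ids), tuple(chroms), np.array(pos))


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw the segregant genotype matrix (no missing calls)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    m, n = cfg.markers_per_chromosome, cfg.n_strains
    blocks = []
    for _ in range(cfg.n_chromosomes):
        first = (rng.random(n) < 0.5).astype(np.int64)
        flips = (rng.random((m - 1, n)) < cfg.recombination_fraction).astype(np.int64)
        states = (first[None, :] + np.vstack([np.zeros((1, n), np.int64), np.cumsum(flips, axis=0)])) % 2
        blocks.append(states)
    calls = np.vstack(blocks).astype(float)
    strains = tuple(f"s{i:03d}" for i in range(1, n + 1))
    return GenotypeMatrix(_marker_map(cfg), strains, calls)


def _trait_chromosome(rng, cfg: SimConfig, causal_chrom: str | None) -> str:
    chroms = [f"chr{c}" for c in range(1, cfg.n_chromosomes + 1)]
    if causal_chrom is not None and cfg.cis_fraction is not None:
        if rng.random() < cfg.cis_fraction:
            return causal_chrom
        others = [c for c in chroms if c != causal_chrom] or chroms
        return others[rng.integers(len(others))]
    return chroms[rng.integers(len(chroms))]


def simulate_expression(
    geno: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw expression traits with planted architectures on *geno*.

    Trait ids are prefixed by class (hot_/null_/poly_/single_) and the
    planted truth is returned alongside.  Genotype means are used as-is;
    missing calls in *geno* would bias effects, so simulate expression
    before masking (see simulate_dataset).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    L = geno.n_markers
    if cfg.polygenic_k > L:
        raise ValidationError("more causal loci requested than markers exist")
    marker_ids = geno.markers.marker_id
    marker_chrom = dict(zip(marker_ids, geno.markers.chromosome))
    values, records = [], []

    def add_trait(name, label, causal_idx, betas):
        genetic = np.zeros(geno.n_strains)
        for j, b in zip(causal_idx, betas):
            genetic = genetic + b * geno.calls[j]
        y = genetic + rng.normal(0.0, cfg.noise_sd, geno.n_strains)
        causal_chrom = marker_chrom[marker_ids[causal_idx[0]]] if causal_idx else None
        chrom = _trait_chromosome(rng, cfg, causal_chrom)
        values.append(y)
        records.append(
            (
                name,
                label,
                ";".join(marker_ids[j] for j in causal_idx),
                ";".join(f"{b:g}" for b in betas),
                chrom,
            )
        )

    if cfg.n_hotspot:
        hot_idx = geno.markers.index_of(cfg.hotspot_marker)
        for i in range(cfg.n_hotspot):
            add_trait(f"hot_{i:04d}", "hotspot", [hot_idx], [cfg.single_beta * cfg.noise_sd])
    for i in range(cfg.n_single):
        j = int(rng.integers(L))
        add_trait(f"single_{i:04d}", "single", [j], [cfg.single_beta * cfg.noise_sd])
    beta_k = cfg.polygenic_beta_effective * cfg.noise_sd
    for i in range(cfg.n_polygenic):
        loci = sorted(rng.choice(L, size=cfg.polygenic_k, replace=False).tolist())
        add_trait(f"poly_{i:04d}", "polygenic", loci, [beta_k] * cfg.polygenic_k)
    for i in range(cfg.n_null):
        add_trait(f"null_{i:04d}", "null", [], [])

    truth = GroundTruth(pd.DataFrame(records, columns=list(GroundTruth.COLUMNS)))
    trait_chrom = dict(zip(truth.table["trait"], truth.table["trait_chrom"]))
    expr = ExpressionMatrix(
        tuple(truth.table["trait"]), geno.strains, np.vstack(values), trait_chrom
    )
    return expr, truth


def mask_missing(
    geno: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Observation dropout: set a random fraction of calls to missing."""
    if rate == 0:
        return geno
    mask = rng.random(geno.calls.shape) < rate
    calls = geno.calls.copy()
    calls[mask] = np.nan
    return GenotypeMatrix(geno.markers, geno.strains, calls)


def simulate_dataset(cfg: SimConfig):
    """Full draw: (GenotypeMatrix, ExpressionMatrix, GroundTruth).

    Expression is generated from the true (complete) genotypes; the
    missingness mask, if any, is applied afterwards so it represents
    genotyping dropout rather than a biological effect.
    """
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    expr, truth = simulate_expression(geno, cfg, rng)
    geno = mask_missing(geno, cfg.missing_rate, rng)
    return geno, expr, truth
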