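"""Island-model SNP genotype simulation.

Two generative modes:

* ``target_fst`` — the Balding–Nichols construction: ancestral minor-allele
  frequencies are Uniform(0.05, 0.95) and each population draws its own
  frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected
  Weir-Cockerham F_st equals F analytically.
* ``migration_matrix`` — a finite-island drift-migration recursion: all
  populations start at the ancestral frequency and evolve for a fixed
  number of non-overlapping generations under deterministic migration
  followed by binomial drift of 2N gene copies.  Asymmetric emigration
  weights produce directional structure for the migration-network tests.

Genotypes are Hardy-Weinberg draws from the population frequencies, with
independent per-call missingness and log-normal per-locus coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .._utils import MISSING, sub_rng
from ..datatypes import GenotypeMatrix


@dataclass
class GenotypeSimSpec:
    n_populations: int = 2
    n_individuals_per_pop: int = 50
    n_loci: int = 2000
    target_fst: float | None = None
    migration_matrix: np.ndarray | None = None  # [i, j] = emigration i -> j
    n_generations: int = 100
    effective_size: int = 250  # diploid N per population in migration mode
    missing_rate: float = 0.0
    coverage_range: tuple = (20, 200)
    site_names: list | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.target_fst is not None and self.migration_matrix is not None:
            raise ValueError("target_fst and migration_matrix are mutually exclusive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.target_fst is not None and not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if self.migration_matrix is not None:
            m = np.asarray(self.migration_matrix, float)
            if m.shape != (self.n_populations, self.n_populations):
                raise ValueError("migration_matrix must be n_populations square")
            if (m < 0).any():
                raise ValueError("migration weights must be non-negative")


def _population_frequencies(spec: GenotypeSimSpec, rng: np.random.Generator):
    r, L = spec.n_populations, spec.n_loci
    p_anc = rng.uniform(0.05, 0.95, L)
    if spec.migration_matrix is not None:
        m = np.asarray(spec.migration_matrix, float).copy()
        np.fill_diagonal(m, 0.0)
        # backward view: column j receives fraction m[i, j] from deme i
        stay = 1.0 - m.sum(axis=0)
        if (stay <= 0).any():
            raise ValueError("total immigration into a deme must be < 1")
        mix = m + np.diag(stay)  # mix[i, j] = share of j's parents from i
        p = np.tile(p_anc, (r, 1))
        two_n = 2 * spec.effective_size
        for _ in range(spec.n_generations):
            p = mix.T @ p
            p = rng.binomial(two_n, np.clip(p, 0, 1)) / two_n
        return p_anc, p
    f = 0.0 if spec.target_fst is None else spec.target_fst
    if f == 0:
        return p_anc, np.tile(p_anc, (r, 1))
    shape = (1 - f) / f
    p = rng.beta(p_anc * shape, (1 - p_anc) * shape, size=(r, L))
    return p_anc, p


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeMatrix:
    """Draw a genotype matrix; ground truth is attached as ``.truth``.

    ``truth`` records the ancestral and per-population allele frequencies
    and, in migration mode, the emigration matrix actually used.
    """
    rng = sub_rng(spec.seed, "genotypes")
    r, npp, L = spec.n_populations, spec.n_individuals_per_pop, spec.n_loci
    p_anc, p_pop = _population_frequencies(spec, rng)

    n_ind = r * npp
    calls = np.empty((n_ind, L), dtype=np.int8)
    sites = np.empty(n_ind, dtype=object)
    names = spec.site_names or [f"site_{k + 1}" for k in range(r)]
    if len(names) != r:
        raise ValueError("site_names length must equal n_populations")
    for k in range(r):
        rows = slice(k * npp, (k + 1) * npp)
        calls[rows] = rng.binomial(2, p_pop[k], size=(npp, L)).astype(np.int8)
        sites[rows] = names[k]

    if spec.missing_rate > 0:
        drop = rng.random((n_ind, L)) < spec.missing_rate
        calls[drop] = MISSING
        if (calls == MISSING).all(axis=0).any():
            warnings.warn("some loci lost all calls to missingness")

    lo, hi = spec.coverage_range
    mu = (np.log(lo) + np.log(hi)) / 2
    sigma = (np.log(hi) - np.log(lo)) / 4
    coverage = np.clip(rng.lognormal(mu, sigma, L), lo, hi)

    import pandas as pd

    g = GenotypeMatrix(
        calls=calls,
        locus_ids=np.array([f"L{i + 1:05d}" for i in range(L)], dtype=object),
        individual_ids=np.array([f"ind_{i + 1:04d}" for i in range(n_ind)], dtype=object),
        sites=sites,
        locus_meta=pd.DataFrame(
            {"coverage": coverage},
            index=pd.Index([f"L{i + 1:05d}" for i in range(L)], name="locus"),
        ),
    )
    g.truth = {
        "ancestral_freq": p_anc,
        "population_freq": p_pop,
        "target_fst": spec.target_fst,
        "migration_matrix": None
        if spec.migration_matrix is None
        else np.asarray(spec.migration_matrix, float),
        "site_names": names,
    }
    return g
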