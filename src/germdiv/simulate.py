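"""Seeded generators for genotype matrices and trait tables with planted truth.

The genotype generator follows the Balding-Nichols model of population
differentiation: each locus draws ancestral allele frequencies p from a
symmetric Dirichlet, each latent group draws its own frequencies from
Dirichlet(p (1 - F) / F) so that E[Fst] = F, and individuals are two
independent allele copies from their group's frequencies (Hardy-Weinberg
within groups).  Clone groups (synonyms) are planted by copying a genotype
bit-identically under new accession ids; homonym groups are sets of distinct
genotypes assigned a shared variety name.

The trait generator plants a low-rank factor structure: each accession has
scores on latent factors, core traits track one factor each, non-core
variable traits load weakly on a couple of random factors, and a fixed
number of traits is invariant.  Quantitative traits are observed as noisy
replicates and graded through the LSD machinery, so every downstream trait
operation sees data of the form it expects.

All randomness flows from a single seed, split per component with
numpy SeedSequence spawning so sub-results are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssr import MISSING, GenotypeMatrix
from .traits import TraitDescriptor, TraitTable, apply_grading, build_lsd_grading

__all__ = [
    "PopSimConfig",
    "TraitSimConfig",
    "simulate_populations",
    "simulate_traits",
    "paper_scale_fixture",
]


@dataclass
class PopSimConfig:
    """Parameters of the planted-structure genotype generator."""

    group_sizes: tuple[int, ...] = (40, 35, 30)
    n_loci: int = 19
    alleles_per_locus: tuple[int, int] = (4, 15)
    fst: float = 0.2
    clone_pairs: int = 0
    clone_group_sizes: tuple[tuple[int, int], ...] | None = None  # (group_index, size)
    homonym_groups: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        n = sum(self.group_sizes)
        n_cloned = 2 * self.clone_pairs + sum(
            s for _, s in (self.clone_group_sizes or ()))
        if n_cloned > n:
            raise ValueError("clone members exceed the number of accessions")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class TraitSimConfig:
    """Parameters of the planted low-rank trait generator."""

    n_accessions: int = 113
    n_traits: int = 50
    n_invariant: int = 10
    n_factors: int = 14
    n_core: int = 14
    replicate_count: int = 30      # five replicates of six plants
    noise_sd: float = 0.3          # replicate-level measurement noise
    core_residual_sd: float = 0.1  # residual sd of a core trait around its factor
    background_loading: float = 0.8   # mixture magnitude of non-core variable traits
    background_sd: float = 0.5     # residual sd of non-core variable traits
    factor_correlation: float = 0.3   # shared-factor correlation among latent factors
    factor_scale_range: tuple[float, float] = (1.2, 0.85)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_invariant >= self.n_traits:
            raise ValueError("n_invariant must be < n_traits")
        if self.n_factors > self.n_traits:
            raise ValueError("n_factors must be <= n_traits")
        if self.n_core > self.n_factors:
            raise ValueError("n_core must be <= n_factors (one factor per core trait)")


def _allele_sizes(n_alleles: int, rng: np.random.Generator) -> np.ndarray:
    """Di-nucleotide-ladder fragment sizes for one locus."""
    start = int(rng.integers(100, 300))
    return start + 2 * np.arange(n_alleles)


def simulate_populations(config: PopSimConfig):
    """Generate a GenotypeMatrix with planted groups, clones and homonyms.

    Returns (GenotypeMatrix, truth) where truth holds ``group_labels``
    (accession -> group name), ``clone_groups`` (lists of accession ids with
    identical genotypes), ``names`` (accession -> variety name) and
    ``homonym_names`` (names shared by distinct genotypes).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_loci, rng_ind, rng_extra = (np.random.default_rng(s) for s in ss.spawn(3))

    n = sum(config.group_sizes)
    g = config.n_groups
    lo, hi = config.alleles_per_locus
    f = config.fst
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    accessions = [f"ACC{i + 1:03d}" for i in range(n)]
    group_of = np.repeat(np.arange(g), config.group_sizes)

    a1 = np.empty((n, config.n_loci), dtype=np.int64)
    a2 = np.empty_like(a1)
    for j in range(config.n_loci):
        na = int(rng_loci.integers(lo, hi + 1))
        sizes = _allele_sizes(na, rng_loci)
        p_anc = rng_loci.dirichlet(np.ones(na))
        group_freqs = np.vstack([
            rng_loci.dirichlet(p_anc * (1 - f) / f) for _ in range(g)])
        for grp in range(g):
            sel = group_of == grp
            m = int(sel.sum())
            draws = rng_ind.choice(na, size=(m, 2), p=group_freqs[grp])
            pair = np.sort(sizes[draws], axis=1)
            a1[sel, j], a2[sel, j] = pair[:, 0], pair[:, 1]

    # plant clone groups: overwrite group-mates with bit-identical genotypes
    clone_specs = list(config.clone_group_sizes or ())
    clone_specs += [(i % g, 2) for i in range(config.clone_pairs)]
    clone_groups: list[list[str]] = []
    used: set[int] = set()
    for grp, size in clone_specs:
        members = [i for i in np.flatnonzero(group_of == grp) if i not in used]
        if len(members) < size:
            raise ValueError(f"group {grp} too small for a clone group of {size}")
        chosen = members[:size]
        used.update(chosen)
        src = chosen[0]
        for dst in chosen[1:]:
            a1[dst] = a1[src]
            a2[dst] = a2[src]
        clone_groups.append([accessions[i] for i in chosen])

    # variety names: unique by default; homonym groups share a name across
    # distinct genotypes (never within a clone group)
    names = {acc: f"Variety{i + 1:03d}" for i, acc in enumerate(accessions)}
    homonym_names: list[str] = []
    free = [i for i in range(n) if i not in used]
    rng_extra.shuffle(free)
    for h in range(config.homonym_groups):
        if len(free) < 2:
            raise ValueError("not enough non-clone accessions for homonym groups")
        a, b = free.pop(), free.pop()
        shared = f"SharedName{h + 1:02d}"
        names[accessions[a]] = shared
        names[accessions[b]] = shared
        homonym_names.append(shared)

    if config.missing_rate > 0:
        mask = rng_extra.random((n, config.n_loci)) < config.missing_rate
        a1[mask] = MISSING
        a2[mask] = MISSING

    gm = GenotypeMatrix(accessions, loci, a1, a2)
    truth = {
        "group_labels": {acc: f"G{group_of[i] + 1}" for i, acc in enumerate(accessions)},
        "clone_groups": clone_groups,
        "names": names,
        "homonym_names": homonym_names,
    }
    return gm, truth


def simulate_traits(config: TraitSimConfig):
    """Generate a TraitTable with a planted factor structure.

    Returns (TraitTable, truth) with truth holding ``core_traits``,
    ``invariant_traits`` and the factor ``loadings`` used.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_factors, rng_load, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    n, p = config.n_accessions, config.n_traits
    accessions = [f"ACC{i + 1:03d}" for i in range(n)]
    trait_ids = [f"T{j + 1}" for j in range(p)]

    # correlated latent factors with graded scales: a shared axis (trait
    # complexes co-vary in real germplasm) plus factor-specific variation,
    # factor importance declining gently so the eigen-spectrum is ordered
    rho = config.factor_correlation
    scales = np.linspace(*config.factor_scale_range, config.n_factors)
    shared = rng_factors.normal(size=(n, 1))
    specific = rng_factors.normal(size=(n, config.n_factors))
    factors = (np.sqrt(rho) * shared + np.sqrt(1 - rho) * specific) * scales

    n_var = p - config.n_invariant
    core_ids = trait_ids[:config.n_core]
    variable_ids = trait_ids[:n_var]
    invariant_ids = trait_ids[n_var:]

    loadings = np.zeros((p, config.n_factors))
    for j in range(config.n_core):
        loadings[j, j] = 1.0
    # background traits mix two factors each, assigned cyclically so every
    # factor keeps comparable support; magnitudes vary mildly and signs are
    # random
    for idx, j in enumerate(range(config.n_core, n_var)):
        picks = [idx % config.n_factors,
                 (idx + config.n_factors // 2) % config.n_factors]
        mags = config.background_loading * rng_load.uniform(0.8, 1.2, size=2)
        signs = rng_load.choice([-1.0, 1.0], size=2)
        loadings[j, picks] = mags * signs

    latent = factors @ loadings.T  # accession-level trait means, noise-free

    codes = pd.DataFrame(index=accessions, columns=trait_ids, dtype=float)
    descriptors: dict[str, TraitDescriptor] = {}
    raw = pd.DataFrame(index=accessions, columns=trait_ids, dtype=float)
    rep_records = []

    for j, tid in enumerate(variable_ids):
        is_core = tid in core_ids
        resid_sd = (config.core_residual_sd * scales[j] if is_core
                    else config.background_sd)
        acc_values = latent[:, j] + rng_noise.normal(0.0, resid_sd, size=n)
        # replicate-level observations around the accession value
        reps = acc_values[:, None] + rng_noise.normal(
            0.0, config.noise_sd, size=(n, config.replicate_count))
        means = reps.mean(axis=1)
        raw[tid] = means
        rep_df = pd.DataFrame(
            [(accessions[i], tid, r + 1, reps[i, r])
             for i in range(n) for r in range(config.replicate_count)],
            columns=["accession_id", "trait_id", "replicate", "value"])
        rep_records.append(rep_df)
        scheme = build_lsd_grading(rep_df, alpha=0.05, n_grades=7, trait_id=tid)
        codes[tid] = apply_grading(means, scheme)
        descriptors[tid] = TraitDescriptor(
            trait_id=tid, name=f"simulated trait {tid}",
            kind="quantitative", class_codes=scheme.codes, is_core=is_core)

    for tid in invariant_ids:
        codes[tid] = 1.0
        raw[tid] = 1.0
        descriptors[tid] = TraitDescriptor(
            trait_id=tid, name=f"simulated invariant trait {tid}",
            kind="qualitative", class_codes=(1,))

    replicates = pd.concat(rep_records, ignore_index=True)
    table = TraitTable(codes=codes, descriptors=descriptors, raw=raw,
                       replicates=replicates)
    truth = {
        "core_traits": core_ids,
        "invariant_traits": invariant_ids,
        "loadings": pd.DataFrame(loadings, index=trait_ids,
                                 columns=[f"F{i + 1}" for i in range(config.n_factors)]),
    }
    return table, truth


# Nine planted synonym (clone) groups: sizes mirror the published redundancy
# pattern (28 members in 9 groups -> 19 redundant accessions, 94 distinct).
_FIXTURE_CLONES = (
    (0, 6), (0, 2), (0, 3), (0, 4), (0, 3), (0, 3), (0, 2),   # largest cluster
    (2, 2),                                                   # six-member cluster
    (1, 3),                                                   # 27-member cluster
)


def paper_scale_fixture(seed: int = 0):
    """One call producing a study-scale dataset for end-to-end pipeline tests.

    113 accessions genotyped at 19 SSR loci in five latent groups sized
    (75, 27, 6, 3, 2), with 9 planted clone groups (19 redundant accessions)
    and 3 homonym groups, plus a 50-trait table (10 invariant) on the same
    accessions.  Deterministic in ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_trait = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    pop_cfg = PopSimConfig(group_sizes=(75, 27, 6, 3, 2), n_loci=19,
                           alleles_per_locus=(4, 15), fst=0.32,
                           clone_group_sizes=_FIXTURE_CLONES,
                           homonym_groups=3, missing_rate=0.0, seed=s_pop)
    gm, pop_truth = simulate_populations(pop_cfg)
    trait_cfg = TraitSimConfig(n_accessions=113, n_traits=50, n_invariant=10,
                               n_factors=14, n_core=14, seed=s_trait)
    table, trait_truth = simulate_traits(trait_cfg)
    table.codes.index = gm.accessions
    if table.raw is not None:
        table.raw.index = gm.accessions
    return {
        "genotypes": gm,
        "traits": table,
        "groups": pop_truth["group_labels"],
        "names": pop_truth["names"],
        "truth": {"population": pop_truth, "traits": trait_truth},
        "config": {"population": pop_cfg, "traits": trait_cfg},
    }
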