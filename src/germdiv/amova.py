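"""Hierarchical analysis of molecular variance (AMOVA) for codominant diploids.

Allele-level layout with three strata -- among groups, among individuals
within groups, within individuals -- so each individual contributes two
allele copies and the total df is 2N - 1.  The squared distance between two
allele copies is the mismatch indicator (0 same allele, 1 different), which
lets every sum of squares be computed from allele counts:

    SS(set of m copies) = (1/m) * sum over pairs of d^2
                        = (m^2 - sum_a c_a^2) / (2 m)

Variance components follow the standard nested-ANOVA expectations
(negative estimates truncated at 0), Phi_ST is the among-group share of the
total variance, and gene flow uses the island-model identity
Nm = (1 - Fst) / (4 Fst).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssr import MISSING, GenotypeMatrix

__all__ = ["AmovaResult", "amova", "gene_flow"]


@dataclass
class AmovaResult:
    df: dict[str, int]                  # among_groups, among_individuals, within_individuals
    ss: dict[str, float]
    ms: dict[str, float]
    variance_components: dict[str, float]
    percentages: dict[str, float]
    phi_st: float
    nm: float | None
    n0: float
    permutation_p: float | None = None


def _ss_from_counts(counts: np.ndarray) -> float:
    m = counts.sum()
    if m == 0:
        return 0.0
    return float((m ** 2 - np.sum(counts.astype(float) ** 2)) / (2.0 * m))


def _amova_ss(gm: GenotypeMatrix, labels: np.ndarray):
    """Summed-over-loci sums of squares for the three strata."""
    groups = np.unique(labels)
    ss_total = ss_within_ind = ss_group_sets = 0.0
    for j in range(len(gm.loci)):
        a1, a2 = gm.a1[:, j], gm.a2[:, j]
        typed = a1 != MISSING
        if typed.sum() < 2:
            continue
        copies = np.concatenate([a1[typed], a2[typed]])
        alleles, total_counts = np.unique(copies, return_counts=True)
        ss_total += _ss_from_counts(total_counts)
        # within individuals: heterozygous individual contributes 1/2
        ss_within_ind += 0.5 * float(np.sum(a1[typed] != a2[typed]))
        for g in groups:
            sel = typed & (labels == g)
            if not sel.any():
                continue
            gcopies = np.concatenate([a1[sel], a2[sel]])
            counts = np.unique(gcopies, return_counts=True)[1]
            ss_group_sets += _ss_from_counts(counts)
    ss_among_ind = ss_group_sets - ss_within_ind
    ss_among_groups = ss_total - ss_group_sets
    return ss_among_groups, ss_among_ind, ss_within_ind, ss_total


def _phi_from_ss(ss_g, ss_a, ss_w, n, g, n0):
    ms_g = ss_g / (g - 1)
    ms_a = ss_a / (n - g)
    ms_w = ss_w / n
    sigma_w = ms_w
    sigma_a = max(0.0, (ms_a - ms_w) / 2.0)
    sigma_g = max(0.0, (ms_g - ms_a) / (2.0 * n0))
    total = sigma_g + sigma_a + sigma_w
    phi = sigma_g / total if total > 0 else 0.0
    return (ms_g, ms_a, ms_w), (sigma_g, sigma_a, sigma_w), phi


def amova(gm: GenotypeMatrix, groups: dict[str, str],
          permutations: int = 0, seed: int | None = None) -> AmovaResult:
    """Three-level AMOVA of a diploid genotype matrix.

    ``groups`` maps accession id to group label; every group needs >= 2
    members.  With ``permutations`` > 0, a seeded permutation p-value for
    Phi_ST is computed by shuffling whole individuals across groups.
    """
    missing_labels = [a for a in gm.accessions if a not in groups]
    if missing_labels:
        raise ValueError(f"accessions without group labels: {missing_labels}")
    labels = np.array([groups[a] for a in gm.accessions])
    uniq, counts = np.unique(labels, return_counts=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        singles = uniq[counts < 2].tolist()
        raise ValueError(f"singleton groups not allowed: {singles}")
    n = gm.n
    n0 = (n - np.sum(counts.astype(float) ** 2) / n) / (g - 1)

    ss_g, ss_a, ss_w, _ = _amova_ss(gm, labels)
    (ms_g, ms_a, ms_w), (sg, sa, sw), phi = _phi_from_ss(ss_g, ss_a, ss_w, n, g, n0)
    total_var = sg + sa + sw
    pct = {k: (100.0 * v / total_var if total_var > 0 else 0.0)
           for k, v in zip(("among_groups", "among_individuals", "within_individuals"),
                           (sg, sa, sw))}
    nm = gene_flow(phi) if 0 < phi < 1 else None

    perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm_labels = rng.permutation(labels)
            pss = _amova_ss(gm, perm_labels)
            _, _, pphi = _phi_from_ss(pss[0], pss[1], pss[2], n, g, n0)
            if pphi >= phi:
                hits += 1
        perm_p = (1 + hits) / (1 + permutations)

    return AmovaResult(
        df={"among_groups": g - 1, "among_individuals": n - g,
            "within_individuals": n, "total": 2 * n - 1},
        ss={"among_groups": ss_g, "among_individuals": ss_a,
            "within_individuals": ss_w, "total": ss_g + ss_a + ss_w},
        ms={"among_groups": ms_g, "among_individuals": ms_a,
            "within_individuals": ms_w},
        variance_components={"among_groups": sg, "among_individuals": sa,
                             "within_individuals": sw, "total": total_var},
        percentages=pct, phi_st=phi, nm=nm, n0=float(n0),
        permutation_p=perm_p,
    )


def gene_flow(fst: float) -> float:
    """Island-model gene flow Nm = (1 - Fst) / (4 Fst) for 0 < Fst < 1."""
    if not 0 < fst < 1:
        raise ValueError("Fst must lie strictly between 0 and 1")
    return (1.0 - fst) / (4.0 * fst)
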