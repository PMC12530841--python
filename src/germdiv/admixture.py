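"""Bayesian model-based clustering of multilocus genotypes (Gibbs sampler).

The model is the classic admixture model for unlinked codominant loci with
uncorrelated allele frequencies: each cluster k carries per-locus allele
frequency vectors P_kl with a symmetric Dirichlet(lambda = 1) prior, each
individual i a membership vector q_i, and each allele copy an independent
cluster-of-origin Z.  One Gibbs sweep updates

1. P_kl | Z  ~ Dirichlet(lambda + cluster allele counts)
2. Z        ~ Categorical, Pr(Z = k) proportional to q_ik * P_kl[allele]
3. q_i | Z  ~ Dirichlet(alpha + per-cluster copy counts)   (admixture model)
   or a hard cluster per individual sampled from its likelihood
   (no-admixture model),

with the shared admixture parameter alpha updated by a random-walk
Metropolis step on a uniform(0, 10) prior.  Missing genotypes are treated as
uninformative.  The model-choice score ln P(X|K) is estimated as
mean(lnL) - var(lnL)/2 over post-burn-in sweeps, and the number of clusters
is chosen with the Evanno second-difference statistic
Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) across replicate runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .ssr import MISSING, GenotypeMatrix

__all__ = [
    "StructureRun",
    "StructureSweep",
    "run_structure",
    "sweep_k",
    "evanno_delta_k",
    "align_runs",
]


@dataclass
class StructureRun:
    k: int
    model: str
    seed: int
    burn_in: int
    iterations: int
    q: pd.DataFrame                  # accession x K posterior-mean memberships
    lnl_trace: np.ndarray            # thinned log-likelihood trace
    ln_prob_data: float
    alpha_trace: np.ndarray | None = None


@dataclass
class StructureSweep:
    table: pd.DataFrame              # per K: n_reps, mean_lnp, sd_lnp
    runs: dict[int, list[StructureRun]] = field(default_factory=dict)
    delta_k: pd.DataFrame | None = None
    best_k_deltak: int | None = None


def _encode(gm: GenotypeMatrix):
    """Flatten genotype calls into per-allele-copy index arrays."""
    n, L = gm.n, len(gm.loci)
    amax = 0
    allele_maps = []
    for j in range(L):
        vals = np.unique(np.concatenate([gm.a1[:, j], gm.a2[:, j]]))
        vals = vals[vals != MISSING]
        if len(vals) == 0:
            raise ValueError(f"locus {gm.loci[j]} is entirely missing")
        allele_maps.append({int(v): i for i, v in enumerate(vals)})
        amax = max(amax, len(vals))
    codes = np.full((n, L, 2), -1, dtype=np.int64)
    for j, amap in enumerate(allele_maps):
        for c, arr in enumerate((gm.a1, gm.a2)):
            col = arr[:, j]
            ok = col != MISSING
            codes[ok, j, c] = [amap[int(v)] for v in col[ok]]
    flat = codes.reshape(n, 2 * L)  # copy order: (locus, copy) pairs flattened
    codes_flat = codes.reshape(-1)
    valid = codes_flat >= 0
    copy_ind = np.repeat(np.arange(n), 2 * L)[valid]
    copy_loc = np.tile(np.repeat(np.arange(L), 2), n)[valid]
    copy_allele = codes_flat[valid]
    n_alleles = np.array([len(m) for m in allele_maps])
    return copy_ind, copy_loc, copy_allele, n_alleles, amax, flat


def run_structure(gm: GenotypeMatrix, k: int, model: str = "admixture",
                  burn_in: int = 5000, iterations: int = 20000,
                  seed: int = 0, lambda_prior: float = 1.0,
                  alpha_init: float = 1.0, alpha_step: float = 0.025,
                  alpha_max: float = 10.0, thin: int = 10) -> StructureRun:
    """Run the Gibbs sampler at a fixed K and return posterior summaries.

    ``iterations`` counts post-burn-in sweeps (the paper-scale convention:
    burn-in then replication).  Identical inputs and seed give bit-identical
    output.
    """
    if model not in ("admixture", "no_admixture"):
        raise ValueError("model must be 'admixture' or 'no_admixture'")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > gm.n:
        raise ValueError("k cannot exceed the number of accessions")
    rng = np.random.default_rng(seed)
    ind, loc, allele, n_alleles, amax, _ = _encode(gm)
    n, L = gm.n, len(gm.loci)
    C = len(ind)
    valid_allele = np.zeros((L, amax), dtype=bool)
    for j, a in enumerate(n_alleles):
        valid_allele[j, :a] = True

    z = rng.integers(0, k, size=C)
    q = np.full((n, k), 1.0 / k)
    alpha = alpha_init
    flat_idx = loc * amax + allele                  # per-copy (locus, allele) flat index

    q_sum = np.zeros((n, k))
    lnl_all = np.empty(iterations)
    lnl_trace = []
    alpha_trace = []
    total = burn_in + iterations
    eps = 1e-300

    for sweep in range(total):
        # 1. allele frequencies P | Z
        counts = np.bincount(z * (L * amax) + flat_idx,
                             minlength=k * L * amax).reshape(k, L, amax).astype(float)
        gam = rng.standard_gamma(lambda_prior + counts)
        gam *= valid_allele[None, :, :]
        p = gam / gam.sum(axis=2, keepdims=True)

        # 2. cluster of origin Z for every allele copy
        pk = p.reshape(k, L * amax)[:, flat_idx].T          # (C, k)
        w = q[ind] * pk
        w_sum = w.sum(axis=1, keepdims=True)
        u = rng.random(C) * w_sum[:, 0]
        z = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1)
        z = np.minimum(z, k - 1)

        # 3. memberships
        nik = np.bincount(ind * k + z, minlength=n * k).reshape(n, k).astype(float)
        if model == "admixture":
            gq = rng.standard_gamma(alpha + nik)
            q = gq / gq.sum(axis=1, keepdims=True)
            # Metropolis step for alpha (uniform prior on (0, alpha_max))
            prop = alpha + rng.normal(0.0, alpha_step)
            while prop < 0 or prop > alpha_max:
                if prop < 0:
                    prop = -prop
                if prop > alpha_max:
                    prop = 2 * alpha_max - prop
            if prop > 0:
                log_q_sum = float(np.log(np.maximum(q, eps)).sum())
                def log_dir(a):
                    return n * (gammaln(k * a) - k * gammaln(a)) + (a - 1) * log_q_sum
                if np.log(rng.random()) < log_dir(prop) - log_dir(alpha):
                    alpha = prop
        else:
            # hard assignment per individual from its marginal likelihood
            logp_copy = np.log(np.maximum(pk, eps))          # (C, k)
            ll_ind = np.zeros((n, k))
            np.add.at(ll_ind, ind, logp_copy)
            ll_ind -= ll_ind.max(axis=1, keepdims=True)
            wq = np.exp(ll_ind)
            uq = rng.random(n) * wq.sum(axis=1)
            ci = (np.cumsum(wq, axis=1) < uq[:, None]).sum(axis=1)
            ci = np.minimum(ci, k - 1)
            q = np.zeros((n, k))
            q[np.arange(n), ci] = 1.0
            z = ci[ind]

        # 4. data log-likelihood given current (P, Q)
        lnl = float(np.log(np.maximum((q[ind] * pk).sum(axis=1), eps)).sum())
        if sweep >= burn_in:
            t = sweep - burn_in
            lnl_all[t] = lnl
            q_sum += q
            if t % thin == 0:
                lnl_trace.append(lnl)
                if model == "admixture":
                    alpha_trace.append(alpha)

    q_mean = q_sum / iterations
    ln_prob_data = float(lnl_all.mean() - lnl_all.var() / 2.0)
    return StructureRun(
        k=k, model=model, seed=seed, burn_in=burn_in, iterations=iterations,
        q=pd.DataFrame(q_mean, index=gm.accessions,
                       columns=[f"Q{j + 1}" for j in range(k)]),
        lnl_trace=np.array(lnl_trace),
        ln_prob_data=ln_prob_data,
        alpha_trace=np.array(alpha_trace) if model == "admixture" else None,
    )


def sweep_k(gm: GenotypeMatrix, k_range, replicates: int = 2,
            seed: int = 0, model: str = "admixture",
            burn_in: int = 5000, iterations: int = 20000) -> StructureSweep:
    """Run all (K, replicate) combinations and collect ln P(X|K).

    Replicate seeds are spawned deterministically from ``seed``.  Delta K is
    attached when the K grid has >= 3 consecutive values and >= 2 replicates.
    """
    ks = sorted(k_range)
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be contiguous")
    runs: dict[int, list[StructureRun]] = {}
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(ks) * replicates)]
    it = iter(seeds)
    for k in ks:
        runs[k] = [run_structure(gm, k, model=model, burn_in=burn_in,
                                 iterations=iterations, seed=next(it))
                   for _ in range(replicates)]
    rows = []
    for k in ks:
        vals = np.array([r.ln_prob_data for r in runs[k]])
        rows.append({"k": k, "n_reps": len(vals), "mean_lnp": vals.mean(),
                     "sd_lnp": vals.std(ddof=1) if len(vals) > 1 else 0.0})
    table = pd.DataFrame(rows).set_index("k")
    sweep = StructureSweep(table=table, runs=runs)
    if len(ks) >= 3 and replicates >= 2:
        try:
            sweep.delta_k = evanno_delta_k(sweep)
            sweep.best_k_deltak = int(sweep.delta_k["delta_k"].idxmax())
        except ValueError:
            pass  # zero sd at an interior K: Delta K left undefined
    return sweep


def evanno_delta_k(sweep: StructureSweep) -> pd.DataFrame:
    """Evanno Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) at interior K."""
    tab = sweep.table.sort_index()
    ks = tab.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if (tab["n_reps"] < 2).any():
        raise ValueError("need >= 2 replicates per K for Delta K")
    L = tab["mean_lnp"].to_numpy()
    sd = tab["sd_lnp"].to_numpy()
    rows = []
    for i in range(1, len(ks) - 1):
        if sd[i] == 0:
            raise ValueError(f"zero sd of L(K) at interior K={ks[i]}: Delta K undefined")
        rows.append({"k": int(ks[i]),
                     "l_prime": L[i] - L[i - 1],
                     "l_doubleprime": L[i + 1] - 2 * L[i] + L[i - 1],
                     "delta_k": abs(L[i + 1] - 2 * L[i] + L[i - 1]) / sd[i]})
    return pd.DataFrame(rows).set_index("k")


def align_runs(runs: list[StructureRun]):
    """Align replicate Q matrices up to cluster-label permutation.

    Each run's columns are permuted to maximize the summed column-wise dot
    product with the first run (exhaustive over permutations for K <= 8,
    greedy beyond).  Returns (list of aligned Q DataFrames, element-wise mean).
    """
    if not runs:
        raise ValueError("no runs to align")
    k = runs[0].k
    if any(r.k != k for r in runs):
        raise ValueError("all runs must share the same K")
    ref = runs[0].q.to_numpy()
    cols = list(runs[0].q.columns)
    aligned = [runs[0].q.copy()]
    for r in runs[1:]:
        if list(r.q.index) != list(runs[0].q.index):
            raise ValueError("runs must share accession order")
        mat = r.q.to_numpy()
        score = ref.T @ mat  # score[i, j] = ref col i . run col j
        if k <= 8:
            best, best_perm = -np.inf, None
            for perm in itertools.permutations(range(k)):
                s = sum(score[i, perm[i]] for i in range(k))
                if s > best:
                    best, best_perm = s, perm
        else:
            best_perm, used = [], set()
            for i in range(k):
                j = max((j for j in range(k) if j not in used),
                        key=lambda j: score[i, j])
                best_perm.append(j)
                used.add(j)
            best_perm = tuple(best_perm)
        aligned.append(pd.DataFrame(mat[:, list(best_perm)],
                                    index=r.q.index, columns=cols))
    mean_q = sum(a.to_numpy() for a in aligned) / len(aligned)
    return aligned, pd.DataFrame(mean_q, index=runs[0].q.index, columns=cols)
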