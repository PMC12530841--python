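"""End-to-end orchestration of the two-arm germplasm characterization.

One RunConfig drives both arms: the morphological arm (trait statistics,
PCA-based core-trait selection, trait-distance clustering) and the molecular
arm (per-locus SSR diversity, HWE, genetic distances, UPGMA, duplicate and
homonym detection, AMOVA, admixture sweep).  Every stage writes plain-text
tables into the output directory and the run ends with a manifest recording
parameters, seeds and a content hash per emitted file, so re-runs with the
same inputs and seed are byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from .amova import amova as run_amova_analysis
from . import clustering as clu
from . import core_selection as core
from . import ssr
from . import traits as tr

__all__ = ["RunConfig", "run_pipeline", "cross_tabulate"]

log = logging.getLogger("germdiv")


@dataclass
class RunConfig:
    """Inputs, switches and thresholds of a full pipeline run.

    Defaults mirror the study conditions: significance at 0.05/0.01, stepwise
    entry/removal 0.05/0.10, duplicate threshold GD = 0, K swept 1-10 with 10
    replicates, burn-in 100,000 and 200,000 recorded sweeps.  Test-scale runs
    override the MCMC block.
    """

    out_dir: str = "germdiv_out"
    seed: int = 1

    # input paths (any may be None when the corresponding arm is disabled)
    traits_csv: str | None = None
    replicates_csv: str | None = None
    genotypes_csv: str | None = None
    groups_csv: str | None = None
    names_csv: str | None = None

    run_traits: bool = True
    run_core_selection: bool = True
    run_morpho_clustering: bool = True
    run_ssr_stats: bool = True
    run_hwe: bool = True
    run_clustering: bool = True
    run_duplicates: bool = True
    run_amova: bool = True
    run_structure: bool = True

    alpha: float = 0.05
    alpha_strict: float = 0.01
    p_enter: float = 0.05
    p_remove: float = 0.10
    gd_threshold: float = 0.0
    n_genetic_clusters: int = 5
    n_morpho_clusters: int = 3
    k_min: int = 1
    k_max: int = 10
    structure_replicates: int = 10
    burn_in: int = 100_000
    iterations: int = 200_000
    amova_permutations: int = 999

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _read_map(path, value_col: str) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["accession_id"].astype(str), df[value_col].astype(str)))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Reporter:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: list[str] = []
        self.stages: list[dict] = []

    def path(self, name: str) -> Path:
        self.files.append(name)
        return self.out_dir / name

    def stage(self, name: str, **info) -> None:
        log.info("stage %s: %s", name, info)
        self.stages.append({"stage": name, **info})


def run_pipeline(config: RunConfig,
                 trait_table: tr.TraitTable | None = None,
                 genotypes: ssr.GenotypeMatrix | None = None,
                 groups: dict[str, str] | None = None,
                 names: dict[str, str] | None = None) -> dict:
    """Execute all enabled stages and write the report bundle.

    Inputs may be passed in memory or read from the CSV paths in the config.
    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = _Reporter(out)
    results: dict = {}

    # ---- load inputs -----------------------------------------------------
    if trait_table is None and config.traits_csv:
        raise ValueError("reading trait CSVs requires descriptors; pass trait_table directly "
                         "or use germdiv.traits.read_trait_table first")
    if genotypes is None and config.genotypes_csv:
        genotypes = ssr.read_genotypes(config.genotypes_csv)
    if groups is None and config.groups_csv:
        groups = _read_map(config.groups_csv, "group")
    if names is None and config.names_csv:
        names = _read_map(config.names_csv, "name")

    morpho_assign = None
    genetic_assign = None

    # ---- morphological arm ----------------------------------------------
    if trait_table is not None and config.run_traits:
        stats = tr.trait_stats_table(trait_table)
        stats.to_csv(rep.path("trait_stats.csv"))
        rep.stage("trait_stats", n_traits=len(stats))
        results["trait_stats"] = stats

    if trait_table is not None and config.run_core_selection:
        z, dropped = core.standardize_traits(trait_table)
        pca_res = core.pca(z)
        eig = pd.DataFrame({
            "eigenvalue": pca_res.eigenvalues,
            "contribution": pca_res.contribution,
            "cumulative": pca_res.cumulative_contribution,
        }, index=pca_res.scores.columns)
        eig.to_csv(rep.path("pca_eigen.csv"))
        score = core.composite_score(pca_res)
        with open(rep.path("weights.json"), "w") as fh:
            json.dump({"weights": score.weights.tolist(),
                       "retained": pca_res.retained,
                       "dropped_invariant": dropped}, fh, indent=2)
        score.f_values.to_csv(rep.path("f_scores.csv"))
        core_set = core.stepwise_select(z, score, config.p_enter, config.p_remove)
        core_set.correlation_table.to_csv(rep.path("correlation_table.csv"))
        with open(rep.path("core_set.json"), "w") as fh:
            json.dump({"selected_traits": core_set.selected_traits,
                       "coefficients": core_set.coefficients.to_dict(),
                       "r_squared": core_set.r_squared,
                       "path": core_set.path}, fh, indent=2)
        rep.stage("core_selection", retained=pca_res.retained,
                  dropped=len(dropped), selected=len(core_set.selected_traits))
        results["pca"] = pca_res
        results["core_set"] = core_set

    if trait_table is not None and config.run_morpho_clustering:
        dm = clu.trait_distance_matrix(trait_table)
        tree = clu.upgma(dm)
        clu.write_newick(tree, rep.path("morpho_tree.newick"))
        morpho_assign = clu.cut_clusters(tree, config.n_morpho_clusters)
        pd.Series(morpho_assign, name="cluster").rename_axis("accession_id") \
            .to_csv(rep.path("morpho_clusters.csv"))
        rep.stage("morpho_clustering", k=config.n_morpho_clusters)
        results["morpho_clusters"] = morpho_assign

    # ---- molecular arm ---------------------------------------------------
    if genotypes is not None and config.run_ssr_stats:
        locus_stats = ssr.summarize_all(genotypes)
        locus_stats.to_csv(rep.path("locus_stats.csv"))
        rep.stage("ssr_stats", n_loci=len(genotypes.loci),
                  pic_gt_half=locus_stats.attrs["n_pic_gt_0.5"])
        results["locus_stats"] = locus_stats

    if genotypes is not None and config.run_hwe:
        rows = []
        for loc in genotypes.loci:
            h = ssr.hwe_test(genotypes, loc)
            rows.append({"locus": loc, "chi2": h.chi2, "df": h.df,
                         "p_value": h.p_value, "sig_05": h.significant_05,
                         "sig_01": h.significant_01})
        hwe_df = pd.DataFrame(rows).set_index("locus")
        hwe_df.to_csv(rep.path("hwe.csv"))
        rep.stage("hwe", n_loci=len(hwe_df))
        results["hwe"] = hwe_df

    dm = None
    if genotypes is not None and (config.run_clustering or config.run_duplicates):
        dm = clu.genetic_distance_matrix(genotypes)
        dm.write_csv(rep.path("genetic_distance.csv"))

    if genotypes is not None and config.run_clustering:
        tree = clu.upgma(dm)
        clu.write_newick(tree, rep.path("tree.newick"))
        genetic_assign = clu.cut_clusters(tree, config.n_genetic_clusters)
        pd.Series(genetic_assign, name="cluster").rename_axis("accession_id") \
            .to_csv(rep.path("clusters.csv"))
        coords, explained = clu.pcoa_from_distance(dm)
        coords.iloc[:, :10].to_csv(rep.path("pcoa_coords.csv"))
        rep.stage("clustering", k=config.n_genetic_clusters,
                  axis1_pct=float(100 * explained[0]))
        results["genetic_clusters"] = genetic_assign

    if genotypes is not None and config.run_duplicates:
        dup = clu.find_duplicates(dm, config.gd_threshold)
        with open(rep.path("duplicates.json"), "w") as fh:
            json.dump({"groups": dup.groups, "n_total": dup.n_total,
                       "n_distinct": dup.n_distinct,
                       "n_redundant": dup.n_redundant}, fh, indent=2)
        results["duplicates"] = dup
        rep.stage("duplicates", n_groups=len(dup.groups),
                  n_distinct=dup.n_distinct)
        if names:
            hom = clu.find_homonyms(names, dm)
            with open(rep.path("homonyms.json"), "w") as fh:
                json.dump({"flagged": hom.flagged,
                           "name_groups": {k: v for k, v in hom.name_groups.items()
                                           if len(v) > 1}}, fh, indent=2)
            results["homonyms"] = hom
            rep.stage("homonyms", n_flagged=len(hom.flagged))

    if genotypes is not None and groups and config.run_amova:
        res = run_amova_analysis(genotypes, groups,
                                 permutations=config.amova_permutations,
                                 seed=config.seed)
        amova_rows = pd.DataFrame({
            "df": res.df, "SS": res.ss,
            "MS": {**res.ms, "total": float("nan")},
            "est_var": res.variance_components,
            "pct": {**res.percentages, "total": 100.0},
        })
        amova_rows.to_csv(rep.path("amova.csv"))
        with open(rep.path("amova.json"), "w") as fh:
            json.dump({"phi_st": res.phi_st, "nm": res.nm,
                       "permutation_p": res.permutation_p,
                       "percentages": res.percentages}, fh, indent=2)
        rep.stage("amova", phi_st=res.phi_st)
        results["amova"] = res

    if genotypes is not None and config.run_structure:
        sweep = adm.sweep_k(genotypes, range(config.k_min, config.k_max + 1),
                            replicates=config.structure_replicates,
                            seed=config.seed, burn_in=config.burn_in,
                            iterations=config.iterations)
        tab = sweep.table.copy()
        if sweep.delta_k is not None:
            tab = tab.join(sweep.delta_k["delta_k"])
        tab.to_csv(rep.path("sweep.csv"))
        for k, runs in sweep.runs.items():
            for r_i, run in enumerate(runs):
                run.q.to_csv(rep.path(f"qmatrix_K{k}_rep{r_i + 1}.csv"))
            aligned, mean_q = adm.align_runs(runs)
            mean_q.to_csv(rep.path(f"aligned_mean_Q_K{k}.csv"))
        rep.stage("structure", best_k=sweep.best_k_deltak)
        results["structure_sweep"] = sweep

    if morpho_assign is not None and genetic_assign is not None:
        ct = cross_tabulate(morpho_assign, genetic_assign)
        ct.to_csv(rep.path("correspondence.csv"))
        rep.stage("correspondence", shape=list(ct.shape))
        results["correspondence"] = ct

    # ---- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "stages": rep.stages,
        "files": {name: _hash_file(out / name) for name in rep.files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results


def cross_tabulate(assignments_a: dict[str, int | str],
                   assignments_b: dict[str, int | str]) -> pd.DataFrame:
    """Contingency table of two partitions of the same accession set."""
    if set(assignments_a) != set(assignments_b):
        raise ValueError("assignments cover different accession sets")
    accs = sorted(assignments_a)
    a = pd.Series([assignments_a[x] for x in accs], name="a")
    b = pd.Series([assignments_b[x] for x in accs], name="b")
    return pd.crosstab(a, b)
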