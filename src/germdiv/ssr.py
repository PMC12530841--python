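"""Codominant SSR genotype matrices and per-locus diversity statistics.

Alleles are amplified-fragment sizes in bp, taken as already-binned integers.
Each accession carries an unordered diploid allele pair per locus; a single
detected peak is recorded as homozygous.  Per-locus statistics follow the
standard microsatellite toolkit:

* Na, observed allele count; Ne = 1 / sum(p^2), effective allele count
* Ho, observed heterozygote fraction
* Nei's gene diversity h = 1 - sum(p^2)
* He, the unbiased expected heterozygosity 2N(1 - sum p^2) / (2N - 1)
* Shannon information index I = -sum(p ln p)
* PIC = 1 - sum(p^2) - sum_{i<j} 2 p_i^2 p_j^2

Hardy-Weinberg equilibrium is tested per locus with a chi-square
goodness-of-fit over all genotype classes (df = a(a-1)/2 for a alleles),
optionally with a seeded Monte-Carlo p-value when expected counts are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "LocusSummary",
    "HWEResult",
    "read_genotypes",
    "write_genotypes",
    "write_structure",
    "allele_frequencies",
    "locus_summary",
    "summarize_all",
    "hwe_test",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls, accessions x loci.

    ``a1``/``a2`` are (n_accessions, n_loci) int arrays with a1 <= a2 and
    ``MISSING`` (-1) for untyped cells (both alleles missing together).
    """

    accessions: list[str]
    loci: list[str]
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        n, L = len(self.accessions), len(self.loci)
        self.a1 = np.asarray(self.a1, dtype=np.int64)
        self.a2 = np.asarray(self.a2, dtype=np.int64)
        if self.a1.shape != (n, L) or self.a2.shape != (n, L):
            raise ValueError("allele arrays must be (n_accessions, n_loci)")
        miss1, miss2 = self.a1 == MISSING, self.a2 == MISSING
        if not np.array_equal(miss1, miss2):
            raise ValueError("missing calls must drop both allele copies")
        lo = np.minimum(self.a1, self.a2)
        hi = np.maximum(self.a1, self.a2)
        self.a1, self.a2 = lo, hi

    @property
    def n(self) -> int:
        return len(self.accessions)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def typed_mask(self, locus: str) -> np.ndarray:
        return self.a1[:, self.locus_index(locus)] != MISSING

    def subset(self, accession_ids) -> "GenotypeMatrix":
        idx = [self.accessions.index(a) for a in accession_ids]
        return GenotypeMatrix(list(accession_ids), list(self.loci),
                              self.a1[idx].copy(), self.a2[idx].copy())


@dataclass
class AlleleFrequencies:
    locus: str
    n_typed: int
    freqs: dict[int, float] = field(default_factory=dict)


@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    na: int
    ne: float
    ho: float
    he: float
    nei: float
    shannon_i: float
    pic: float


@dataclass
class HWEResult:
    locus: str
    group: str | None
    chi2: float
    df: int
    p_value: float
    significant_05: bool
    significant_01: bool
    monte_carlo_p: float | None = None


def read_genotypes(path) -> GenotypeMatrix:
    """Read a genotype CSV, auto-detecting the dialect from the header.

    Long dialect: ``accession_id,locus,allele1,allele2`` (blank/NA allele2
    means homozygous; blank allele1 means missing).  Wide dialect: first
    column ``accession_id`` then two columns per locus named
    ``<locus>_1,<locus>_2``.
    """
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if {"accession_id", "locus", "allele1"}.issubset(cols):
        return _from_long(df)
    if cols and cols[0] == "accession_id" and all(
            c.endswith(("_1", "_2")) for c in cols[1:]):
        return _from_wide(df)
    raise ValueError(f"unknown genotype CSV dialect; columns: {cols}")


def _parse_allele(text, where: str) -> int:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return MISSING
    s = str(text).strip()
    if s in ("", "NA", "nan"):
        return MISSING
    try:
        v = int(s)
    except ValueError:
        raise ValueError(f"non-integer allele {s!r} at {where}") from None
    if v <= 0:
        raise ValueError(f"allele size must be positive at {where}, got {v}")
    return v


def _from_long(df: pd.DataFrame) -> GenotypeMatrix:
    accessions = list(dict.fromkeys(df["accession_id"]))
    loci = list(dict.fromkeys(df["locus"]))
    acc_idx = {a: i for i, a in enumerate(accessions)}
    loc_idx = {l: j for j, l in enumerate(loci)}
    a1 = np.full((len(accessions), len(loci)), MISSING, dtype=np.int64)
    a2 = np.full_like(a1, MISSING)
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.accession_id, row.locus)
        if key in seen:
            raise ValueError(f"duplicate genotype row for {key}")
        seen.add(key)
        where = f"{row.accession_id}/{row.locus}"
        x = _parse_allele(row.allele1, where)
        y = _parse_allele(getattr(row, "allele2", None), where)
        if x == MISSING and y != MISSING:
            x, y = y, MISSING
        if y == MISSING and x != MISSING:
            y = x  # single peak -> homozygous
        a1[acc_idx[row.accession_id], loc_idx[row.locus]] = x
        a2[acc_idx[row.accession_id], loc_idx[row.locus]] = y
    return GenotypeMatrix(accessions, loci, a1, a2)


def _from_wide(df: pd.DataFrame) -> GenotypeMatrix:
    loci = list(dict.fromkeys(c[:-2] for c in df.columns[1:]))
    accessions = list(df["accession_id"])
    if len(set(accessions)) != len(accessions):
        raise ValueError("duplicate accession_id rows in wide genotype CSV")
    a1 = np.full((len(accessions), len(loci)), MISSING, dtype=np.int64)
    a2 = np.full_like(a1, MISSING)
    for j, loc in enumerate(loci):
        for i, acc in enumerate(accessions):
            where = f"{acc}/{loc}"
            x = _parse_allele(df.at[i, f"{loc}_1"], where)
            y = _parse_allele(df.at[i, f"{loc}_2"], where)
            if x == MISSING and y != MISSING:
                x, y = y, MISSING
            if y == MISSING and x != MISSING:
                y = x
            a1[i, j], a2[i, j] = x, y
    return GenotypeMatrix(accessions, loci, a1, a2)


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "long") -> None:
    if dialect == "long":
        rows = []
        for i, acc in enumerate(gm.accessions):
            for j, loc in enumerate(gm.loci):
                x, y = gm.a1[i, j], gm.a2[i, j]
                rows.append({"accession_id": acc, "locus": loc,
                             "allele1": "" if x == MISSING else int(x),
                             "allele2": "" if y == MISSING else int(y)})
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "wide":
        data = {"accession_id": gm.accessions}
        for j, loc in enumerate(gm.loci):
            data[f"{loc}_1"] = [("" if v == MISSING else int(v)) for v in gm.a1[:, j]]
            data[f"{loc}_2"] = [("" if v == MISSING else int(v)) for v in gm.a2[:, j]]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(gm: GenotypeMatrix, path) -> None:
    """STRUCTURE-format export: two rows per individual (one per allele copy), -9 missing."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + gm.loci) + "\n")
        for i, acc in enumerate(gm.accessions):
            for copy in (gm.a1, gm.a2):
                alleles = ["-9" if v == MISSING else str(int(v)) for v in copy[i]]
                fh.write("\t".join([acc] + alleles) + "\n")


def allele_frequencies(gm: GenotypeMatrix, locus: str) -> AlleleFrequencies:
    """Allele relative frequencies over the 2N copies of typed individuals."""
    j = gm.locus_index(locus)
    mask = gm.a1[:, j] != MISSING
    n_typed = int(mask.sum())
    if n_typed == 0:
        raise ValueError(f"{locus}: no typed individuals")
    copies = np.concatenate([gm.a1[mask, j], gm.a2[mask, j]])
    alleles, counts = np.unique(copies, return_counts=True)
    freqs = {int(a): float(c) / (2 * n_typed) for a, c in zip(alleles, counts)}
    return AlleleFrequencies(locus=locus, n_typed=n_typed, freqs=freqs)


def _diversity_from_freqs(p: np.ndarray):
    """(ne, nei, shannon_i, pic) from an allele-frequency vector."""
    sum_p2 = float(np.sum(p ** 2))
    ne = 1.0 / sum_p2
    nei = 1.0 - sum_p2
    shannon_i = float(-(p * np.log(p)).sum())
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    pic = 1.0 - sum_p2 - (sum_p2 ** 2 - float(np.sum(p ** 4)))
    return ne, nei, shannon_i, pic


def locus_summary(gm: GenotypeMatrix, locus: str) -> LocusSummary:
    af = allele_frequencies(gm, locus)
    if af.n_typed < 2:
        raise ValueError(f"{locus}: need >= 2 typed individuals")
    j = gm.locus_index(locus)
    mask = gm.a1[:, j] != MISSING
    p = np.array(sorted(af.freqs.values(), reverse=True))
    ne, nei, shannon_i, pic = _diversity_from_freqs(p)
    ho = float(np.mean(gm.a1[mask, j] != gm.a2[mask, j]))
    n = af.n_typed
    he = 2 * n * nei / (2 * n - 1)
    return LocusSummary(locus=locus, n_typed=n, na=len(p), ne=ne, ho=ho,
                        he=he, nei=nei, shannon_i=shannon_i, pic=pic)


def summarize_all(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary rows plus Mean and Total rows (Table-3 layout).

    Mean is the arithmetic mean per statistic; Total the column sum.  The
    count of loci with PIC > 0.5 is stored in ``df.attrs['n_pic_gt_0.5']``.
    """
    if not gm.loci:
        raise ValueError("genotype matrix has no loci")
    rows = []
    for loc in gm.loci:
        s = locus_summary(gm, loc)
        rows.append({"locus": loc, "na": s.na, "ne": s.ne, "ho": s.ho,
                     "he": s.he, "nei": s.nei, "shannon_i": s.shannon_i,
                     "pic": s.pic})
    df = pd.DataFrame(rows).set_index("locus")
    df.loc["Mean"] = df.iloc[: len(gm.loci)].mean()
    df.loc["Total"] = df.iloc[: len(gm.loci)].sum()
    df.attrs["n_pic_gt_0.5"] = int((df.iloc[: len(gm.loci)]["pic"] > 0.5).sum())
    return df


def hwe_test(gm: GenotypeMatrix, locus: str, group=None,
             monte_carlo: int | None = None, seed: int | None = None) -> HWEResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg genotype proportions.

    Expected counts are N p_i^2 for homozygotes and 2 N p_i p_j for
    heterozygotes; df = a(a-1)/2 (genotype classes minus estimated allele
    frequencies minus 1).  When ``monte_carlo`` is set, a permutation p-value
    is computed by reshuffling the 2N allele copies into random diploids.
    A monomorphic subset yields a not-testable result (df = 0, p = NaN).
    """
    sub = gm if group is None else gm.subset(group)
    j = sub.locus_index(locus)
    mask = sub.a1[:, j] != MISSING
    x, y = sub.a1[mask, j], sub.a2[mask, j]
    n = int(mask.sum())
    alleles = np.unique(np.concatenate([x, y]))
    a = len(alleles)
    if a < 2:
        return HWEResult(locus, None if group is None else "subset",
                         chi2=0.0, df=0, p_value=float("nan"),
                         significant_05=False, significant_01=False)

    def chi2_stat(g1, g2):
        copies = np.concatenate([g1, g2])
        counts = pd.Series(copies).value_counts()
        p = counts.reindex(alleles, fill_value=0).to_numpy() / (2 * n)
        obs = {}
        for xi, yi in zip(g1, g2):
            obs[(xi, yi)] = obs.get((xi, yi), 0) + 1
        stat = 0.0
        for ii, ai in enumerate(alleles):
            for jj in range(ii, a):
                aj = alleles[jj]
                e = n * p[ii] ** 2 if ii == jj else 2 * n * p[ii] * p[jj]
                o = obs.get((min(ai, aj), max(ai, aj)), 0)
                if e > 0:
                    stat += (o - e) ** 2 / e
                elif o > 0:
                    stat += float("inf")
        return stat

    chi2 = chi2_stat(x, y)
    df = a * (a - 1) // 2
    p_value = float(sps.chi2.sf(chi2, df))
    mc_p = None
    if monte_carlo:
        rng = np.random.default_rng(seed)
        copies = np.concatenate([x, y])
        hits = 0
        for _ in range(monte_carlo):
            perm = rng.permutation(copies)
            g1, g2 = perm[:n], perm[n:]
            lo, hi = np.minimum(g1, g2), np.maximum(g1, g2)
            if chi2_stat(lo, hi) >= chi2:
                hits += 1
        mc_p = (1 + hits) / (1 + monte_carlo)
    return HWEResult(locus=locus, group=None if group is None else "subset",
                     chi2=float(chi2), df=df, p_value=p_value,
                     significant_05=p_value <= 0.05, significant_01=p_value <= 0.01,
                     monte_carlo_p=mc_p)
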