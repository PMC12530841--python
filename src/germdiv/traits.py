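"""DUS trait tables, LSD-based grading of quantitative traits, and diversity statistics.

Morphological characterization follows the DUS (distinctness, uniformity,
stability) framework: each trait is observed on every accession and expressed
as an integer class code.  Qualitative traits carry fixed code sets;
quantitative traits are graded into an odd number of classes whose width is
set from the least significant difference (LSD) of a one-way ANOVA across
accessions, with the grand mean at the midpoint of the central class.

Per-trait descriptive statistics use the population (divide-by-n) standard
deviation, and trait diversity is summarized with the Shannon-Weaver index
H' = -sum(p_i * ln p_i) over class frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TraitDescriptor",
    "GradingScheme",
    "TraitTable",
    "TraitStats",
    "read_trait_table",
    "build_lsd_grading",
    "apply_grading",
    "descriptive_stats",
    "shannon_weaver",
    "trait_correlation_matrix",
]


@dataclass(frozen=True)
class TraitDescriptor:
    """One DUS trait: identity, kind and legal class codes."""

    trait_id: str
    name: str
    kind: str  # "qualitative" | "quantitative"
    class_codes: tuple[int, ...]
    is_core: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("qualitative", "quantitative"):
            raise ValueError(f"{self.trait_id}: kind must be qualitative or quantitative")
        codes = tuple(int(c) for c in self.class_codes)
        if not codes:
            raise ValueError(f"{self.trait_id}: class_codes must be non-empty")
        if any(b <= a for a, b in zip(codes, codes[1:])):
            raise ValueError(f"{self.trait_id}: class_codes must be strictly increasing")
        object.__setattr__(self, "class_codes", codes)


@dataclass(frozen=True)
class GradingScheme:
    """Cut points turning a quantitative trait into ordered class codes.

    ``boundaries`` are the internal cut points (len(codes) - 1 of them); class
    intervals are half-open ``[b_i, b_{i+1})`` with the extreme classes
    unbounded.  ``class_width`` must exceed twice the LSD whenever the LSD is
    positive, and ``center`` (the trait grand mean) sits inside the middle
    class.
    """

    trait_id: str
    boundaries: tuple[float, ...]
    codes: tuple[int, ...]
    center: float
    class_width: float
    lsd_alpha: float = 0.05
    lsd_value: float = 0.0

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError(f"{self.trait_id}: boundaries must be strictly increasing")
        if len(self.codes) != len(b) + 1:
            raise ValueError(f"{self.trait_id}: need len(codes) == len(boundaries) + 1")
        if self.lsd_value > 0 and not self.class_width > 2 * self.lsd_value:
            raise ValueError(f"{self.trait_id}: class width must exceed 2*LSD")
        object.__setattr__(self, "boundaries", b)


@dataclass
class TraitTable:
    """Accession x trait matrix of graded codes, plus optional raw data.

    ``codes`` is a float DataFrame (NaN = missing) indexed by accession id
    with one column per trait.  ``raw`` optionally holds per-accession mean
    measurements and ``replicates`` the long-format replicate records
    (accession_id, trait_id, replicate, value).
    """

    codes: pd.DataFrame
    descriptors: dict[str, TraitDescriptor]
    raw: pd.DataFrame | None = None
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = [c for c in self.codes.columns if c not in self.descriptors]
        if unknown:
            raise ValueError(f"traits without descriptors: {unknown}")
        offenders = []
        for tid in self.codes.columns:
            legal = set(self.descriptors[tid].class_codes)
            col = self.codes[tid].dropna()
            bad = col[~col.isin(legal)]
            offenders.extend((tid, acc, v) for acc, v in bad.items())
        if offenders:
            msg = "; ".join(f"trait {t}, accession {a}: code {v:g}" for t, a, v in offenders[:20])
            raise ValueError(f"codes outside descriptor class sets: {msg}")

    @property
    def accessions(self) -> list[str]:
        return list(self.codes.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.codes.columns)


@dataclass
class TraitStats:
    """Descriptive summary of one trait (Table-1 style row)."""

    trait_id: str
    max: float
    min: float
    range: float
    mean: float
    sd: float
    cv_percent: float  # NaN when mean is 0
    shannon_h: float
    class_frequencies: dict[int, float] = field(default_factory=dict)


def read_trait_table(path, descriptors: list[TraitDescriptor],
                     replicates_path=None) -> TraitTable:
    """Read a wide trait CSV (first column ``accession_id``, NA = missing)."""
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed trait CSV {path}: {exc}") from exc
    desc = {d.trait_id: d for d in descriptors}
    missing_desc = [c for c in df.columns if c not in desc]
    if missing_desc:
        raise ValueError(f"trait columns without descriptors: {missing_desc}")
    codes = df.astype(float)
    reps = None
    if replicates_path is not None:
        reps = pd.read_csv(replicates_path)
        expected = {"accession_id", "trait_id", "replicate", "value"}
        if not expected.issubset(reps.columns):
            raise ValueError(f"replicates CSV must have columns {sorted(expected)}")
    return TraitTable(codes=codes, descriptors=desc, replicates=reps)


def _anova_oneway(values: np.ndarray, groups: np.ndarray):
    """Return (MSE, df_error, grand_mean, harmonic mean replicate count)."""
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    n = len(values)
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValueError("insufficient replication: every accession needs >= 2 replicates")
    means = np.bincount(inv, weights=values) / counts
    ss_within = float(np.sum((values - means[inv]) ** 2))
    df_error = n - k
    mse = ss_within / df_error
    r_harm = k / np.sum(1.0 / counts)
    return mse, df_error, float(values.mean()), float(r_harm)


def build_lsd_grading(replicates: pd.DataFrame, alpha: float = 0.05,
                      n_grades: int = 5, codes: tuple[int, ...] | None = None,
                      trait_id: str | None = None) -> GradingScheme:
    """Build a grading scheme for one quantitative trait from replicate data.

    LSD_alpha = t(1 - alpha/2, df_error) * sqrt(2 * MSE / r) from a one-way
    ANOVA of value on accession, with r the harmonic-mean replicate count.
    The class width is the smallest width exceeding 2*LSD that still spans the
    observed range within ``n_grades`` classes, and boundaries are laid out so
    the grand mean is the midpoint of the middle class.
    """
    if n_grades < 1 or n_grades % 2 == 0:
        raise ValueError("n_grades must be a positive odd integer")
    if trait_id is None:
        tids = replicates["trait_id"].unique()
        if len(tids) != 1:
            raise ValueError("replicates must cover exactly one trait (or pass trait_id)")
        trait_id = str(tids[0])
        sub = replicates
    else:
        sub = replicates[replicates["trait_id"] == trait_id]
    values = sub["value"].to_numpy(dtype=float)
    groups = sub["accession_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 accessions to compute the LSD")
    if codes is None:
        codes = tuple(range(1, 2 * n_grades, 2))
    if len(codes) != n_grades:
        raise ValueError("len(codes) must equal n_grades")

    mse, df_error, grand_mean, r = _anova_oneway(values, groups)
    lsd = float(sps.t.ppf(1 - alpha / 2, df_error) * math.sqrt(2 * mse / r)) if mse > 0 else 0.0

    obs_range = float(values.max() - values.min())
    if obs_range == 0.0 and lsd == 0.0:
        # degenerate: every observation identical -> a single class
        mid = codes[n_grades // 2]
        return GradingScheme(trait_id=trait_id, boundaries=(), codes=(mid,),
                             center=grand_mean, class_width=0.0,
                             lsd_alpha=alpha, lsd_value=0.0)

    width = max(obs_range / n_grades, 2 * lsd)
    if lsd > 0 and width <= 2 * lsd:
        width = float(np.nextafter(2 * lsd, np.inf))
    if width == 0.0:
        width = float(np.nextafter(0.0, np.inf))
    mid = n_grades // 2
    lower_mid = grand_mean - width / 2
    boundaries = tuple(lower_mid + width * k for k in range(-mid + 1, n_grades - mid))
    return GradingScheme(trait_id=trait_id, boundaries=boundaries, codes=tuple(codes),
                         center=grand_mean, class_width=width,
                         lsd_alpha=alpha, lsd_value=lsd)


def apply_grading(values, scheme: GradingScheme) -> np.ndarray:
    """Map values to class codes via half-open intervals [b_i, b_{i+1}).

    Values beyond the outer boundaries take the extreme codes; NaN propagates.
    """
    arr = np.asarray(values, dtype=float)
    idx = np.searchsorted(np.asarray(scheme.boundaries), arr, side="right")
    out = np.asarray(scheme.codes, dtype=float)[np.clip(idx, 0, len(scheme.codes) - 1)]
    out = np.where(np.isnan(arr), np.nan, out)
    return out


def shannon_weaver(table: TraitTable, trait_id: str) -> float:
    """Shannon-Weaver diversity H' = -sum(p ln p) over observed class frequencies."""
    col = table.codes[trait_id].dropna()
    if col.empty:
        raise ValueError(f"{trait_id}: no non-missing codes")
    p = col.value_counts(normalize=True).to_numpy()
    return float(-(p * np.log(p)).sum())


def descriptive_stats(table: TraitTable, trait_id: str, use_raw: bool = False) -> TraitStats:
    """Max/min/range/mean/SD/CV% and H' for one trait.

    SD is the population (divide-by-n) standard deviation; CV% = 100*SD/mean,
    reported as NaN when the mean is 0.
    """
    source = table.raw if use_raw else table.codes
    if source is None:
        raise ValueError("no raw matrix attached to this table")
    col = source[trait_id].dropna()
    if col.empty:
        raise ValueError(f"{trait_id}: all values missing")
    vals = col.to_numpy(dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    codes_col = table.codes[trait_id].dropna()
    freqs = {int(k): float(v) for k, v in
             codes_col.value_counts(normalize=True).sort_index().items()}
    return TraitStats(
        trait_id=trait_id,
        max=float(vals.max()), min=float(vals.min()),
        range=float(vals.max() - vals.min()),
        mean=mean, sd=sd, cv_percent=cv,
        shannon_h=shannon_weaver(table, trait_id),
        class_frequencies=freqs,
    )


def trait_stats_table(table: TraitTable) -> pd.DataFrame:
    """Table-1 style summary: one row per trait."""
    rows = []
    for tid in table.trait_ids:
        s = descriptive_stats(table, tid)
        rows.append({"trait_id": tid, "max": s.max, "min": s.min, "range": s.range,
                     "mean": s.mean, "sd": s.sd, "cv_percent": s.cv_percent,
                     "shannon_h": s.shannon_h})
    return pd.DataFrame(rows).set_index("trait_id")


def trait_correlation_matrix(table: TraitTable, alpha: float = 0.01):
    """Pairwise Pearson correlations on graded codes with two-sided t-test p-values.

    Missing codes are excluded pairwise.  Zero-variance traits are excluded
    with a warning; their rows/columns are NaN.  Returns (r, p, significant)
    DataFrames; ``significant`` flags p <= alpha off the diagonal.
    """
    if len(table.accessions) < 3:
        raise ValueError("need >= 3 accessions for correlation analysis")
    cols = table.trait_ids
    constant = [t for t in cols if table.codes[t].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"zero-variance traits excluded from correlations: {constant}")
    p_traits = len(cols)
    r = np.full((p_traits, p_traits), np.nan)
    p = np.full((p_traits, p_traits), np.nan)
    for i, ti in enumerate(cols):
        if ti in constant:
            continue
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, p_traits):
            tj = cols[j]
            if tj in constant:
                continue
            pair = table.codes[[ti, tj]].dropna()
            if len(pair) < 3 or pair[ti].nunique() <= 1 or pair[tj].nunique() <= 1:
                continue
            rij, pij = sps.pearsonr(pair[ti], pair[tj])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df <= alpha) & ~np.eye(p_traits, dtype=bool)
    return r_df, p_df, sig
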