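"""Trait grading, descriptive statistics and Shannon-Weaver diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import germdiv as gd
from germdiv.traits import trait_stats_table


def make_table(values_by_trait, codes_allowed):
    accs = [f"A{i}" for i in range(len(next(iter(values_by_trait.values()))))]
    codes = pd.DataFrame(values_by_trait, index=accs, dtype=float)
    desc = {t: gd.TraitDescriptor(t, t, "qualitative", tuple(codes_allowed[t]))
            for t in values_by_trait}
    return gd.TraitTable(codes=codes, descriptors=desc)


class TestTraitTableValidation:
    def test_roundtrip_of_constructed_csv(self, tmp_path):
        path = tmp_path / "traits.csv"
        pd.DataFrame({"accession_id": ["a", "b", "c"],
                      "T1": [5, 7, 5], "T2": [7, 7, 5]}).to_csv(path, index=False)
        desc = [gd.TraitDescriptor("T1", "t1", "qualitative", (5, 7)),
                gd.TraitDescriptor("T2", "t2", "qualitative", (5, 7))]
        table = gd.read_trait_table(path, desc)
        assert table.codes.shape == (3, 2)
        assert table.codes.loc["b", "T1"] == 7

    def test_illegal_code_names_trait_and_accession(self, tmp_path):
        path = tmp_path / "traits.csv"
        pd.DataFrame({"accession_id": ["a", "b"], "T1": [3, 4]}).to_csv(path, index=False)
        desc = [gd.TraitDescriptor("T1", "t1", "qualitative", (3, 5, 7))]
        with pytest.raises(ValueError, match="T1.*b.*4"):
            gd.read_trait_table(path, desc)

    def test_descriptor_codes_must_increase(self):
        with pytest.raises(ValueError):
            gd.TraitDescriptor("T1", "t1", "qualitative", (5, 3))

    def test_generated_table_passes_validation(self):
        table, _ = gd.simulate_traits(gd.TraitSimConfig(n_accessions=40, seed=0))
        # constructing TraitTable validates every code against its descriptor
        assert table.codes.shape == (40, 50)


class TestLsdGrading:
    def test_identical_values_give_single_class(self):
        reps = pd.DataFrame({"accession_id": ["a"] * 3 + ["b"] * 3,
                             "trait_id": "T1", "replicate": [1, 2, 3] * 2,
                             "value": [10.0] * 6})
        scheme = gd.build_lsd_grading(reps, n_grades=5)
        assert scheme.codes == (5,)
        assert scheme.lsd_value == 0.0
        assert scheme.boundaries == ()

    def test_zero_mse_splits_at_grand_mean(self):
        reps = pd.DataFrame({"accession_id": ["a", "a", "b", "b"],
                             "trait_id": "T1", "replicate": [1, 2, 1, 2],
                             "value": [1.0, 1.0, 3.0, 3.0]})
        scheme = gd.build_lsd_grading(reps, n_grades=3)
        assert scheme.lsd_value == 0.0
        assert scheme.center == pytest.approx(2.0)
        # middle class centered on the grand mean
        lo, hi = scheme.boundaries
        assert (lo + hi) / 2 == pytest.approx(2.0)

    def test_lsd_matches_brute_force_anova(self):
        rng = np.random.default_rng(42)
        accs, vals = [], []
        means = [10.0, 12.0, 9.0, 11.0, 10.5]
        for i, m in enumerate(means):
            accs += [f"a{i}"] * 5
            vals += list(rng.normal(m, 1.0, 5))
        reps = pd.DataFrame({"accession_id": accs, "trait_id": "T1",
                             "replicate": list(range(1, 6)) * 5, "value": vals})
        scheme = gd.build_lsd_grading(reps, alpha=0.05, n_grades=5)
        # brute-force one-way ANOVA sums of squares
        df = reps
        grand = df["value"].mean()
        ss_within = sum(
            ((grp["value"] - grp["value"].mean()) ** 2).sum()
            for _, grp in df.groupby("accession_id"))
        mse = ss_within / (25 - 5)
        lsd = sps.t.ppf(0.975, 20) * math.sqrt(2 * mse / 5)
        assert scheme.lsd_value == pytest.approx(lsd, abs=1e-9)
        assert scheme.class_width > 2 * scheme.lsd_value

    def test_insufficient_replication_errors(self):
        reps = pd.DataFrame({"accession_id": ["a", "a", "b"],
                             "trait_id": "T1", "replicate": [1, 2, 1],
                             "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="replicat"):
            gd.build_lsd_grading(reps, n_grades=3)


class TestApplyGrading:
    @pytest.mark.parametrize("value,expected", [
        (5.0, 5), (6.0, 7), (3.9, 3), (100.0, 7), (-100.0, 3)])
    def test_half_open_interval_mapping(self, value, expected):
        scheme = gd.GradingScheme("T1", (4.0, 6.0), (3, 5, 7),
                                  center=5.0, class_width=2.0)
        assert gd.apply_grading([value], scheme)[0] == expected

    def test_missing_propagates(self):
        scheme = gd.GradingScheme("T1", (4.0, 6.0), (3, 5, 7),
                                  center=5.0, class_width=2.0)
        out = gd.apply_grading([np.nan, 5.0], scheme)
        assert np.isnan(out[0]) and out[1] == 5

    def test_uniform_histogram_matches_interval_mass(self):
        rng = np.random.default_rng(7)
        scheme = gd.GradingScheme("T1", (0.25, 0.75), (1, 2, 3),
                                  center=0.5, class_width=0.5)
        vals = rng.random(1000)
        codes = gd.apply_grading(vals, scheme)
        counts = pd.Series(codes).value_counts()
        expected = {1: (vals < 0.25).sum(), 2: ((vals >= 0.25) & (vals < 0.75)).sum(),
                    3: (vals >= 0.75).sum()}
        for code, n in expected.items():
            assert counts.get(code, 0) == n

    def test_grading_composed_with_lsd_scheme_is_total(self):
        table, _ = gd.simulate_traits(gd.TraitSimConfig(n_accessions=30, seed=3))
        # every graded code is legal for its descriptor (validated on build)
        for tid, d in table.descriptors.items():
            assert set(table.codes[tid].dropna()).issubset(set(d.class_codes))


class TestDescriptiveStats:
    def test_t22_row(self, t22_table):
        s = gd.descriptive_stats(t22_table, "T22")
        assert round(s.mean, 2) == 0.97
        assert round(s.sd, 2) == 0.16
        assert round(s.cv_percent, 2) == 16.51
        assert round(s.shannon_h, 2) == 0.12

    def test_binary_trait_population_sd_closed_form(self, t22_table):
        # for counts (a, b): SD^2 = ab / (a+b)^2 under divide-by-n
        s = gd.descriptive_stats(t22_table, "T22")
        assert s.sd ** 2 == pytest.approx(110 * 3 / 113 ** 2, abs=1e-12)

    def test_constant_trait(self):
        t = make_table({"T1": [2, 2, 2]}, {"T1": (2,)})
        s = gd.descriptive_stats(t, "T1")
        assert s.sd == 0 and s.cv_percent == 0 and s.shannon_h == 0

    def test_divide_by_n_convention(self):
        t = make_table({"T1": [1, 2, 3]}, {"T1": (1, 2, 3)})
        s = gd.descriptive_stats(t, "T1")
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(0.816496580927726, abs=1e-12)
        assert s.cv_percent == pytest.approx(40.8248290463863, abs=1e-10)

    def test_order_invariance(self):
        t = make_table({"T1": [1, 2, 3, 1, 2]}, {"T1": (1, 2, 3)})
        shuffled = gd.TraitTable(codes=t.codes.iloc[[4, 2, 0, 1, 3]],
                                 descriptors=t.descriptors)
        s1, s2 = gd.descriptive_stats(t, "T1"), gd.descriptive_stats(shuffled, "T1")
        assert (s1.mean, s1.sd, s1.shannon_h) == (s2.mean, s2.sd, s2.shannon_h)

    def test_frequencies_sum_to_one(self):
        t = make_table({"T1": [1, 1, 2, 3, 3]}, {"T1": (1, 2, 3)})
        s = gd.descriptive_stats(t, "T1")
        assert sum(s.class_frequencies.values()) == pytest.approx(1.0, abs=1e-9)


class TestShannonWeaver:
    def test_uniform_maximum(self):
        t = make_table({"T1": [1, 2, 3]}, {"T1": (1, 2, 3)})
        assert gd.shannon_weaver(t, "T1") == pytest.approx(math.log(3))

    def test_monomorphic_zero(self):
        t = make_table({"T1": [5, 5, 5]}, {"T1": (5,)})
        assert gd.shannon_weaver(t, "T1") == 0.0

    def test_relabeling_invariance(self):
        t1 = make_table({"T1": [1, 1, 2, 3]}, {"T1": (1, 2, 3)})
        t2 = make_table({"T1": [7, 7, 5, 3]}, {"T1": (3, 5, 7)})
        assert gd.shannon_weaver(t1, "T1") == pytest.approx(gd.shannon_weaver(t2, "T1"))

    def test_bounded_by_log_class_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            vals = rng.integers(1, k + 1, size=50)
            t = make_table({"T1": vals}, {"T1": tuple(range(1, k + 1))})
            h = gd.shannon_weaver(t, "T1")
            assert 0 <= h <= math.log(k) + 1e-12


class TestTraitCorrelations:
    def test_self_correlation_and_perfect_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 4, 50).astype(float)
        t = make_table({"T1": x, "T2": 2 * x - 1}, {"T1": (1, 2, 3), "T2": (1, 3, 5)})
        r, p, sig = gd.trait_correlation_matrix(t)
        assert r.loc["T1", "T1"] == 1.0
        assert r.loc["T1", "T2"] == pytest.approx(1.0)
        assert p.loc["T1", "T2"] < 1e-10 and sig.loc["T1", "T2"]

    def test_zero_variance_trait_excluded_with_warning(self):
        t = make_table({"T1": [1, 2, 3, 1], "T2": [2, 2, 2, 2]},
                       {"T1": (1, 2, 3), "T2": (2,)})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p, sig = gd.trait_correlation_matrix(t)
        assert np.isnan(r.loc["T2", "T1"])

    def test_type_one_error_rate_for_independent_traits(self):
        # independent traits should be flagged nonsignificant (alpha=0.01)
        # in >= 95% of replicates
        rng = np.random.default_rng(99)
        flagged = 0
        n_reps = 1000
        for _ in range(n_reps):
            x, y = rng.integers(1, 5, 113), rng.integers(1, 5, 113)
            r, pval = sps.pearsonr(x, y)
            flagged += pval <= 0.01
        assert 1 - flagged / n_reps >= 0.95

    def test_stats_table_covers_all_traits(self):
        t = make_table({"T1": [1, 2, 3], "T2": [1, 1, 2]},
                       {"T1": (1, 2, 3), "T2": (1, 2)})
        df = trait_stats_table(t)
        assert list(df.index) == ["T1", "T2"]
        assert (df["range"] == df["max"] - df["min"]).all()
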