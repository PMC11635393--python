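"""Attention profiles, redundancy filtering, feature correlations,
hypergeometric enrichment, domain coverage, partial correlations."""

import math

import numpy as np
import pytest
from scipy import stats

from mgem.attention import (
    DomainRecord,
    bonferroni_threshold,
    correlate_profile_with_feature,
    correlation_distribution,
    domain_coverage,
    nonredundant_matrices,
    partial_correlation,
    profile_from_matrix,
    profiles_for_sequence,
    reduce_feature_set,
    structure_enrichment,
)
from mgem.synthetic import ResidueFeatureTable
from mgem.alphabet import AMINO_ACIDS


def _wrap_inner(inner):
    """Embed an inner residue-by-residue matrix in a full token matrix."""
    n = inner.shape[0]
    t = n + 2
    full = np.zeros((t, t))
    full[0] = 1.0 / t
    full[-1] = 1.0 / t
    for i in range(n):
        full[i + 1, 1:-1] = inner[i]
    return full


class TestProfile:
    def test_column_mean_toy_case(self):
        inner = np.array(
            [[0.2, 0.5, 0.3], [0.1, 0.6, 0.3], [0.4, 0.4, 0.2]]
        )
        prof = profile_from_matrix(_wrap_inner(inner))
        np.testing.assert_allclose(prof.values, [23.33, 50.0, 26.67], atol=0.01)

    def test_uniform_matrix_constant_profile_empty_pattern(self):
        t = 12
        prof = profile_from_matrix(np.full((t, t), 1.0 / t))
        np.testing.assert_allclose(prof.values, 100.0 / (t - 2))
        assert prof.pattern.size == 0
        np.testing.assert_array_equal(prof.z_scores, 0.0)

    def test_profiles_sum_to_one_hundred(self, rng):
        for _ in range(10):
            t = int(rng.integers(5, 40))
            m = rng.uniform(size=(t, t))
            m /= m.sum(axis=1, keepdims=True)
            prof = profile_from_matrix(m)
            assert prof.values.sum() == pytest.approx(100.0)
            assert prof.z_scores.mean() == pytest.approx(0.0, abs=1e-9)
            assert prof.z_scores.std() == pytest.approx(1.0, abs=1e-9)

    def test_transposed_orientation_flag(self, rng):
        t = 10
        m = rng.uniform(size=(t, t))
        m /= m.sum(axis=1, keepdims=True)
        a = profile_from_matrix(m, attended_by=True)
        b = profile_from_matrix(m, attended_by=False)
        assert not np.allclose(a.values, b.values)
        assert b.values.sum() == pytest.approx(100.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            profile_from_matrix(np.eye(2))
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError):
            profile_from_matrix(bad)


class TestNonredundant:
    def _structured(self, c, t=12):
        """Row-stochastic matrix whose flattened values vary only by column."""
        return np.full((t, t), 1.0 / t) + 0.01 * np.tile(c, (t, 1))

    def test_identical_matrices_all_dropped(self, rng):
        t = 10
        m = rng.uniform(size=(t, t))
        m /= m.sum(axis=1, keepdims=True)
        stack = np.stack([[m, m], [m, m]])
        assert nonredundant_matrices(stack) == []

    def test_single_orthogonal_matrix_survives(self):
        t = 12
        c1 = np.sin(2 * np.pi * np.arange(t) / t)
        c2 = np.cos(2 * np.pi * np.arange(t) / t)   # exactly uncorrelated with c1
        mats = [self._structured(c1, t) for _ in range(9)] + [self._structured(c2, t)]
        # brute-force verify the construction
        corr = np.corrcoef(np.stack([m.ravel() for m in mats]))
        assert abs(corr[0, -1]) < 1e-9 and corr[0, 1] == pytest.approx(1.0)
        kept = nonredundant_matrices(np.stack(mats)[None])
        assert kept == [(0, 9)]

    def test_constant_matrix_dropped(self):
        t = 8
        uniform = np.full((t, t), 1.0 / t)
        c = np.sin(np.arange(t))
        stack = np.stack([self._structured(c - c.mean(), t), uniform])[None]
        assert (0, 1) not in nonredundant_matrices(stack)


class TestFeatureCorrelation:
    def test_bonferroni_threshold_paper_arithmetic(self):
        assert bonferroni_threshold(0.05, 4750) == pytest.approx(1.053e-05,
                                                                 rel=1e-3)

    def test_profile_equal_to_track_gives_r_one(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        table = ResidueFeatureTable(
            "t", {a: float(i) for i, a in enumerate(AMINO_ACIDS)}
        )
        track = table.track(seq)
        values = 100.0 * track / track.sum()
        z = (values - values.mean()) / values.std()
        from mgem.attention import AttentionProfile

        prof = AttentionProfile("P1", 0, 0, values, z)
        out = correlate_profile_with_feature(
            {"P1": [prof]}, {"P1": seq}, table, alpha=0.05, n_tests=1
        )
        assert len(out) == 1
        assert out[0].r == pytest.approx(1.0)
        assert out[0].p < 1e-20

    def test_zero_variance_track_skipped(self):
        seq = "A" * 50
        table = ResidueFeatureTable(
            "t", {a: float(i) for i, a in enumerate(AMINO_ACIDS)}
        )
        from mgem.attention import AttentionProfile

        values = np.linspace(1, 2, 50)
        prof = AttentionProfile("P1", 0, 0, values,
                                (values - values.mean()) / values.std())
        out = correlate_profile_with_feature(
            {"P1": [prof]}, {"P1": seq}, table, alpha=0.05, n_tests=1
        )
        assert out == []

    def test_oracle_control_contrast(self, small_proteome, oracle,
                                     feature_tables, rng):
        """Planted-cost correlations collapse on shuffled sequences."""
        _, records, _ = small_proteome
        cost_table = feature_tables[0]
        real_p, real_s, shuf_p, shuf_s = {}, {}, {}, {}
        for r in records[:40]:
            real_p[r.id] = profiles_for_sequence(oracle, r.sequence, r.id)
            real_s[r.id] = r.sequence
            s = "".join(np.array(list(r.sequence))[rng.permutation(r.length)])
            shuf_p[r.id] = profiles_for_sequence(oracle, s, r.id)
            shuf_s[r.id] = s
        real = np.abs(correlation_distribution(real_p, real_s, cost_table))
        ctrl = np.abs(correlation_distribution(shuf_p, shuf_s, cost_table))
        assert real.mean() > 0.5
        assert ctrl.mean() < 0.15
        assert real.mean() > 3 * ctrl.mean()


class TestReduceFeatureSet:
    def _tables(self, rng, k=5):
        return [
            ResidueFeatureTable(f"t{i}", dict(zip(AMINO_ACIDS, rng.normal(size=20))))
            for i in range(k)
        ]

    def test_duplicate_plus_independent(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 80)) for _ in range(5)]
        a, b = self._tables(rng, 2)
        dup = ResidueFeatureTable("t0_copy", dict(a.values))
        kept = reduce_feature_set([a, dup, b], seqs, cutoff=0.5)
        names = {t.name for t in kept}
        assert len(kept) == 2 and "t1" in names
        assert len({"t0", "t0_copy"} & names) == 1

    def test_uncorrelated_tables_all_kept(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 200)) for _ in range(8)]
        tables = self._tables(rng, 4)
        kept = reduce_feature_set(tables, seqs, cutoff=0.99)
        assert len(kept) == 4

    def test_order_invariance(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 80)) for _ in range(5)]
        tables = self._tables(rng, 6)
        noisy = ResidueFeatureTable(
            "t0_noisy",
            {a: v + 0.1 * rng.normal() for a, v in tables[0].values.items()},
        )
        tables.append(noisy)
        kept_fwd = {t.name for t in reduce_feature_set(tables, seqs, cutoff=0.5)}
        kept_rev = {t.name for t in
                    reduce_feature_set(tables[::-1], seqs, cutoff=0.5)}
        assert kept_fwd == kept_rev


def exact_hypergeom_tails(x, M, K, n):
    """Enumeration oracle: P(X >= x) and P(X <= x) by explicit summation."""
    def pmf(k):
        if k < max(0, n - (M - K)) or k > min(K, n):
            return 0.0
        return (math.comb(K, k) * math.comb(M - K, n - k)) / math.comb(M, n)

    upper = sum(pmf(k) for k in range(x, n + 1))
    lower = sum(pmf(k) for k in range(0, x + 1))
    return upper, lower


class TestStructureEnrichment:
    def test_pvalues_match_exact_enumeration(self):
        # two 30-residue proteins; population 60 <= 60 so the enumeration
        # oracle is exact
        annotations = {"P1": "H" * 18 + "E" * 12, "P2": "H" * 12 + "E" * 18}
        patterns = {"P1": np.arange(1, 16)}   # 15 positions, all H
        results, _ = structure_enrichment(patterns, annotations, min_count=10)
        assert len(results) == 1
        res = results[0]
        assert res.letter == "H" and res.sample_count == 15
        up, low = exact_hypergeom_tails(15, 60, 30, 15)
        assert res.p_enriched == pytest.approx(up, rel=1e-12)
        assert res.p_depleted == pytest.approx(low, rel=1e-12)
        assert res.p_enriched < 0.05   # all-H pattern on a 50% background

    def test_count_threshold_boundary(self):
        annotations = {"P1": "H" * 40 + "E" * 40}
        res10, _ = structure_enrichment({"P1": np.arange(1, 11)}, annotations)
        assert res10 == []   # count 10 is excluded ("counts > 10")
        res11, _ = structure_enrichment({"P1": np.arange(1, 12)}, annotations)
        assert len(res11) == 1 and res11[0].sample_count == 11

    def test_full_coverage_pattern_is_unremarkable(self):
        ann = "H" * 30 + "E" * 30
        results, _ = structure_enrichment(
            {"P1": np.arange(1, 61)}, {"P1": ann}, min_count=10
        )
        for r in results:
            assert r.p_enriched >= 0.05 or r.p_depleted >= 0.05

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            structure_enrichment({"P1": np.array([100])}, {"P1": "HHH"})


class TestDomainCoverage:
    def test_window_count_floor(self):
        # length 100, domain residues 41..60 (1-based closed) -> 4 windows
        dom = DomainRecord("P1", "pfam", 40, 60)
        pattern = np.arange(61, 81)   # 20 hits, all outside
        detail, _ = domain_coverage({"P1": [pattern]}, [dom], {"P1": 100})
        assert len(detail) == 1
        row = detail.iloc[0]
        assert row.observed == 0.0
        assert row.expected == pytest.approx(20 / 4 / 20)   # hits / windows / length

    def test_pattern_inside_domain(self):
        dom = DomainRecord("P1", "pfam", 40, 60)
        detail, _ = domain_coverage({"P1": [np.arange(45, 56)]}, [dom], {"P1": 100})
        row = detail.iloc[0]
        assert row.observed > 0 and row.expected == 0.0

    def test_long_domains_filtered(self):
        dom = DomainRecord("P1", "pfam", 0, 60)
        detail, summary = domain_coverage({"P1": [np.arange(1, 10)]}, [dom],
                                          {"P1": 100})
        assert detail.empty

    def test_random_patterns_give_zero_mean_difference(self, rng):
        domains, patterns, lengths = [], {}, {}
        for i in range(500):
            pid = f"P{i}"
            lengths[pid] = 100
            domains.append(DomainRecord(pid, "db", 40, 60))
            patterns[pid] = [rng.choice(np.arange(1, 101), size=10,
                                        replace=False)]
        detail, summary = domain_coverage(patterns, domains, lengths)
        diff = (detail.observed - detail.expected).mean()
        assert diff == pytest.approx(0.0, abs=0.02)
        assert summary.p_adj.iloc[0] > 0.01


class TestPartialCorrelation:
    def test_common_driver_removed(self, rng):
        z = rng.normal(size=1000)
        x = z + rng.normal(size=1000)
        y = z + rng.normal(size=1000)
        r_plain, _ = partial_correlation(x, y)
        r_part, _ = partial_correlation(x, y, z)
        assert r_plain > 0.3
        assert abs(r_part) < 0.1

    def test_no_controls_equals_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref) and p == pytest.approx(p_ref)

    def test_self_correlation_is_one(self, rng):
        z = rng.normal(size=100)
        x = z + rng.normal(size=100)
        r, _ = partial_correlation(x, x, z)
        assert r == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=["x", "y", "z"])
        df["x"] += 0.5 * df["z"]
        df["y"] += 0.5 * df["z"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        r, p = partial_correlation(df.x, df.y, df.z)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_collinear_controls_warn(self, rng):
        z = rng.normal(size=50)
        controls = np.column_stack([z, z])
        with pytest.warns(UserWarning):
            partial_correlation(rng.normal(size=50), rng.normal(size=50),
                                controls)
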