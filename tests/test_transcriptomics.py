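"""Transcriptome statistics tests with independent oracles.

BH-FDR is checked against its brute-force definition (and statsmodels),
Fisher enrichment against the hypergeometric tail sum, Ward clustering
against an O(n^3) greedy agglomeration, and the slope t-test against a
direct two-regression computation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gasferm import transcriptomics as tx
from gasferm.synthetic import DEGConfig, simulate_counts
from gasferm.transcriptomics import (ExpressionMatrix, TranscriptomicsError,
                                     bh_fdr, cluster_profiles, deg_call,
                                     enrichment, filter_expressed,
                                     overlap_counts, rpkm,
                                     tight_control_selection,
                                     within_gas_comparisons)


def make_design(n_reps=3, gases=("CO", "syngas"), mus=(1.0, 2.0, 2.8)):
    rows = [{"sample_id": f"{g}_{m}_{r}", "gas": g, "mu": m, "replicate": r}
            for g in gases for m in mus for r in range(n_reps)]
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def planted_matrix():
    design = make_design()
    cfg = DEGConfig(n_up=100, n_down=100)
    counts, lengths, truth = simulate_counts(2000, design, cfg, seed=31)
    matrix = ExpressionMatrix(counts, lengths, design.set_index("sample_id"))
    return matrix, truth, design


# --------------------------------------------------------------------------
# RPKM and filtering
# --------------------------------------------------------------------------

class TestRPKM:
    def _frame(self, counts, lib, length):
        c = pd.DataFrame({"s1": [counts]}, index=["g1"])
        lengths = pd.Series([length], index=["g1"])
        libs = pd.Series([lib], index=["s1"])
        return rpkm(c, lengths, libs).iloc[0, 0]

    @pytest.mark.parametrize("counts,lib,length,expected", [
        (0, 1e6, 1000, 0.0),
        (100, 1e6, 1000, 100.0),
        (50, 5e6, 500, 20.0),
    ])
    def test_definition(self, counts, lib, length, expected):
        assert self._frame(counts, lib, length) == pytest.approx(expected)

    def test_zero_library_rejected(self):
        with pytest.raises(TranscriptomicsError):
            self._frame(10, 0.0, 1000)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.integers(2, 50))
    def test_linear_in_counts(self, scale):
        assert self._frame(7 * scale, 2e6, 800) == pytest.approx(
            scale * self._frame(7, 2e6, 800))


class TestFilterExpressed:
    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=[f"s{i}" for i in
                                           range(len(next(iter(rows.values()))))]
                            ).T if False else pd.DataFrame(rows).T

    def test_boundary_value_dropped(self):
        m = pd.DataFrame({"g": [10.0, 10.0, 10.0]}).T
        assert len(filter_expressed(m)) == 0

    def test_two_samples_above_threshold_kept(self):
        m = pd.DataFrame({"g": [11.0, 11.0, 0.0]}).T
        assert list(filter_expressed(m)) == ["g"]

    def test_single_extreme_sample_dropped(self):
        m = pd.DataFrame({"g": [1e6, 0.0, 0.0]}).T
        assert len(filter_expressed(m)) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.exponential(20, size=(50, 6)))
        kept = filter_expressed(m)
        assert list(filter_expressed(m.loc[kept])) == list(kept)


# --------------------------------------------------------------------------
# BH-FDR
# --------------------------------------------------------------------------

def bh_oracle(p):
    """q_i = min over j with p_(j) >= p_i of m p_(j) / rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for i in range(m):
        rank_i = np.searchsorted(p[order], p[i], side="left") + 1
        candidates = [m * p[order][j] / (j + 1)
                      for j in range(rank_i - 1, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_stepup_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_definition_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.random(n)
            assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_sm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(TranscriptomicsError):
            bh_fdr([0.5, 1.2])


# --------------------------------------------------------------------------
# DEG calling
# --------------------------------------------------------------------------

class TestDEGCall:
    def test_cross_gas_comparison_rejected(self, planted_matrix):
        matrix, _, _ = planted_matrix
        with pytest.raises(TranscriptomicsError, match="within one gas"):
            deg_call(matrix, ("CO", "syngas", 1.0, 1.0))

    def test_within_gas_design_has_three_comparisons(self):
        cmps = within_gas_comparisons([1.0, 2.0, 2.8])
        assert cmps == [(2.0, 1.0), (2.8, 1.0), (2.8, 2.0)]

    def test_null_false_positive_fraction_below_one_percent(self):
        design = make_design(n_reps=4, gases=("CO",))
        cfg = DEGConfig(n_up=0, n_down=0)
        counts, lengths, _ = simulate_counts(2000, design, cfg, seed=17)
        matrix = ExpressionMatrix(counts, lengths,
                                  design.set_index("sample_id"))
        table = deg_call(matrix, ("CO", 2.8, 1.0))
        assert table["is_deg"].mean() <= 0.01

    def test_planted_effects_recovered(self, planted_matrix):
        matrix, truth, _ = planted_matrix
        table = deg_call(matrix, ("syngas", 2.8, 1.0))
        truth_tested = truth.loc[table.index]
        positive = truth_tested["class"] != "flat"
        called = table["is_deg"]
        recall = (called & positive).sum() / positive.sum()
        precision = (called & positive).sum() / max(called.sum(), 1)
        assert recall >= 0.8
        assert precision >= 0.9

    def test_direction_of_planted_sign(self, planted_matrix):
        matrix, truth, _ = planted_matrix
        table = deg_call(matrix, ("CO", 2.8, 1.0))
        up = truth.index[truth["class"] == "up"].intersection(table.index)
        assert (table.loc[up, "log2_fc"] > 0).mean() > 0.95

    def test_q_at_least_p(self, planted_matrix):
        matrix, _, _ = planted_matrix
        table = deg_call(matrix, ("CO", 2.0, 1.0))
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()


class TestOverlap:
    def test_disjoint_sets(self):
        counts = overlap_counts({"A": {"a"}, "B": {"b"}})
        assert counts["A&B"] == 0

    def test_pairwise_intersection(self):
        counts = overlap_counts({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert counts["A&B"] == 2
        assert counts["A"] == 1 and counts["B"] == 1

    def test_three_set_regions_partition_union(self):
        sets = {"X": set("abcd"), "Y": set("cdef"), "Z": set("dafg")}
        counts = overlap_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))
        assert counts["X&Y&Z"] == 1  # only "d"


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def ward_oracle_heights(X):
    """Greedy O(n^3) Ward agglomeration; returns sorted merge heights.

    Height of merging clusters a, b is sqrt(2 |a||b| / (|a|+|b|)) times the
    distance between their centroids, matching the Lance-Williams update on
    Euclidean distances.
    """
    clusters = [[x] for x in np.asarray(X, float)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = np.array(clusters[i]), np.array(clusters[j])
                na, nb = len(a), len(b)
                d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(
                    a.mean(axis=0) - b.mean(axis=0))
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return np.sort(heights)


class TestClustering:
    def test_two_separated_blobs_found(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.05, size=(20, 6)) + np.linspace(-1, 1, 6)
        b = rng.normal(0.0, 0.05, size=(20, 6)) - np.linspace(-1, 1, 6)
        profiles = pd.DataFrame(np.vstack([a, b]))
        labels, k, _ = cluster_profiles(profiles)
        assert k == 2
        truth = np.array([0] * 20 + [1] * 20)
        # labels must separate the blobs perfectly (up to relabelling)
        assert len(set(zip(labels, truth))) == 2

    def test_identical_profiles_single_cluster(self):
        profiles = pd.DataFrame(np.tile(np.arange(5.0), (10, 1))
                                + np.arange(10)[:, None])
        labels, k, _ = cluster_profiles(profiles)
        assert k == 1
        assert (labels == 1).all()

    def test_constant_rows_excluded_with_warning(self):
        X = np.vstack([np.ones(4), [0, 1, 2, 3], [3, 2, 1, 0]])
        with pytest.warns(UserWarning, match="constant"):
            labels, _, _ = cluster_profiles(pd.DataFrame(X))
        assert 0 not in labels.index

    def test_ward_heights_match_bruteforce_oracle(self):
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(5)
        for n in (8, 20, 50):
            X = rng.normal(size=(n, 5))
            L = linkage(X, method="ward")
            assert np.allclose(np.sort(L[:, 2]), ward_oracle_heights(X),
                               atol=1e-8)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(TranscriptomicsError):
            cluster_profiles(pd.DataFrame([[1.0, 2.0]]))


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------

class TestEnrichment:
    def _annotation(self, members):
        return pd.DataFrame({"gene_id": list(members),
                             "term_id": ["T1"] * len(members)})

    def test_whole_universe_not_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        ann = self._annotation(list(universe)[:30])
        out = enrichment(universe, ann, universe)
        assert np.allclose(out["p_value"], 1.0)

    def test_matches_hypergeometric_oracle(self):
        # table: in-set&term 10, in-set only 90, out&term 10, out only 890
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:100]
        members = universe[:10] + universe[100:110]
        out = enrichment(gene_set, self._annotation(members), universe)
        p_oracle = stats.hypergeom.sf(9, 1000, 20, 100)
        assert out.loc[0, "p_value"] == pytest.approx(p_oracle, abs=1e-10)

    def test_oracle_agreement_on_random_tables(self):
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(300)]
        for _ in range(30):
            gene_set = list(rng.choice(universe, 60, replace=False))
            members = list(rng.choice(universe, int(rng.integers(5, 80)),
                                      replace=False))
            out = enrichment(gene_set, self._annotation(members), universe)
            a = len(set(gene_set) & set(members))
            p_oracle = stats.hypergeom.sf(a - 1, 300, len(members), 60)
            assert out.loc[0, "p_value"] == pytest.approx(p_oracle,
                                                          abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(TranscriptomicsError):
            enrichment(set(), self._annotation(["g1"]), set())

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(TranscriptomicsError):
            enrichment({"x"}, self._annotation(["g1"]), {"g1"})


# --------------------------------------------------------------------------
# tight-control selection
# --------------------------------------------------------------------------

class TestTightControl:
    def _deg_tables(self, matrix):
        expressed = filter_expressed(matrix.rpkm())
        tables = {}
        for gas in ("CO", "syngas"):
            for hi, lo in [(2.0, 1.0), (2.8, 2.0)]:
                tables[(gas, hi, lo)] = deg_call(matrix, (gas, hi, lo),
                                                 expressed=expressed)
        return tables

    def test_equal_slope_genes_retained(self, planted_matrix):
        matrix, truth, _ = planted_matrix
        out = tight_control_selection(matrix, self._deg_tables(matrix))
        retained = set(out.index[out["retained"]])
        assert retained, "no tight-control genes selected"
        tight_truth = set(truth.index[truth["is_tight"]])
        # selected genes are overwhelmingly from the equal-slope truth
        assert len(retained & tight_truth) / len(retained) >= 0.8

    def test_literal_polarity_flag_inverts_selection(self, planted_matrix):
        matrix, _, _ = planted_matrix
        tables = self._deg_tables(matrix)
        equal = tight_control_selection(matrix, tables,
                                        require_equal_slopes=True)
        literal = tight_control_selection(matrix, tables,
                                          require_equal_slopes=False)
        assert (equal["retained"] == ~literal["retained"]).all()

    def test_slope_t_matches_direct_regression(self, planted_matrix):
        matrix, _, _ = planted_matrix
        out = tight_control_selection(matrix, self._deg_tables(matrix))
        log2 = matrix.log2cpm()
        meta = matrix.sample_meta
        rng = np.random.default_rng(3)
        genes = rng.choice(out.index, size=min(100, len(out)), replace=False)
        for gene in genes:
            slopes, ses, dofs = [], [], []
            for gas in ("CO", "syngas"):
                cols = [s for s in log2.columns if meta.loc[s, "gas"] == gas]
                x = meta.loc[cols, "mu"].to_numpy(float)
                y = log2.loc[gene, cols].to_numpy(float)
                res = stats.linregress(x, y)
                slopes.append(res.slope)
                ses.append(res.stderr)
                dofs.append(len(x) - 2)
            t = (slopes[0] - slopes[1]) / np.hypot(*ses)
            p = 2 * stats.t.sf(abs(t), df=sum(dofs))
            assert out.loc[gene, "t_stat"] == pytest.approx(t, rel=1e-9)
            assert out.loc[gene, "p_value"] == pytest.approx(p, rel=1e-9)

    def test_missing_mu_level_rejected(self):
        design = make_design(mus=(1.0, 2.0))
        cfg = DEGConfig(n_up=10, n_down=10)
        counts, lengths, _ = simulate_counts(200, design, cfg, seed=4)
        matrix = ExpressionMatrix(counts, lengths,
                                  design.set_index("sample_id"))
        with pytest.raises(TranscriptomicsError, match="three mu levels"):
            tight_control_selection(matrix, {})


# --------------------------------------------------------------------------
# observed FDR on repeated nulls (reduced Monte-Carlo)
# --------------------------------------------------------------------------

def test_observed_fdr_controlled_on_repeated_nulls():
    """Across repeated global-null simulations the fraction of falsely
    called genes stays at or below the nominal level."""
    fps = []
    for rep in range(20):
        design = make_design(n_reps=3, gases=("CO",), mus=(1.0, 2.8))
        cfg = DEGConfig(n_up=0, n_down=0)
        counts, lengths, _ = simulate_counts(500, design, cfg, seed=100 + rep)
        matrix = ExpressionMatrix(counts, lengths,
                                  design.set_index("sample_id"))
        table = deg_call(matrix, ("CO", 2.8, 1.0))
        fps.append(table["is_deg"].mean())
    assert np.mean(fps) <= 0.05
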