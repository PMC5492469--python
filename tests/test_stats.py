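"""Distance matrices, PERMANOVA/MRPP against exhaustive oracles, screening."""

import itertools
import math

import numpy as np
import pytest

import bloomnet as bn
from bloomnet.io import OtuTable
from bloomnet.stats import DistanceMatrix


def dist_from(matrix, metric="bray_curtis"):
    matrix = np.asarray(matrix, dtype=float)
    ids = [f"S{i}" for i in range(matrix.shape[0])]
    return DistanceMatrix(ids, matrix, metric)


class TestDistanceMatrix:
    def test_identical_samples_zero(self):
        x = np.array([[0.2, 0.2], [0.8, 0.8]])
        d = bn.distance_matrix(x, ["a", "b"], "bray_curtis")
        assert d.d[0, 1] == 0.0

    def test_disjoint_compositions_one(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        d = bn.distance_matrix(x, ["a", "b"], "bray_curtis")
        assert d.d[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0]])
        d = bn.distance_matrix(x, ["a", "b"], "bray_curtis")
        assert d.d[0, 1] == pytest.approx(2 / 6)

    def test_euclidean(self):
        x = np.array([[0.0, 3.0], [0.0, 4.0]])
        d = bn.distance_matrix(x, ["a", "b"], "euclidean")
        assert d.d[0, 1] == pytest.approx(5.0)

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="metric"):
            bn.distance_matrix(np.eye(2), ["a", "b"], "manhattan")

    def test_agrees_with_skbio_beta_diversity(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(6, 4))          # 6 samples x 4 taxa
        rel = counts / counts.sum(axis=1, keepdims=True)
        ours = bn.distance_matrix(rel.T, [f"s{i}" for i in range(6)], "bray_curtis")
        ref = beta_diversity("braycurtis", rel, ids=[f"s{i}" for i in range(6)])
        assert np.allclose(ours.d, ref.data, atol=1e-12)


def permanova_f_oracle(d, groups):
    """Direct evaluation of the distance-based pseudo-F (independent of the
    package implementation)."""
    d = np.asarray(d, float)
    groups = np.asarray(groups)
    n = len(groups)
    labels = sorted(set(groups.tolist()))
    a = len(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for lab in labels:
        idx = [i for i in range(n) if groups[i] == lab]
        ss_w += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


TOY_D = np.array([
    [0.0, 0.1, 0.8, 0.7],
    [0.1, 0.0, 0.9, 0.6],
    [0.8, 0.9, 0.0, 0.2],
    [0.7, 0.6, 0.2, 0.0],
])


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        res = bn.permanova(dist_from(d), ["g1", "g1", "g2", "g2"], 99, seed=0)
        assert res.effect == pytest.approx(1.0)

    def test_exhaustive_p_matches_brute_force(self):
        """2+2 labels: enumerate all 3 distinct groupings by hand."""
        groupings = [("a", "a", "b", "b"), ("a", "b", "a", "b"), ("a", "b", "b", "a")]
        fs = [permanova_f_oracle(TOY_D, g) for g in groupings]
        expected_p = sum(f >= fs[0] - 1e-12 for f in fs) / len(fs)
        res = bn.permanova(dist_from(TOY_D), ["a", "a", "b", "b"], 999, seed=0)
        assert res.exhaustive
        assert res.p_value == pytest.approx(expected_p)
        assert res.statistic == pytest.approx(fs[0])

    def test_sampled_p_converges_to_exhaustive(self):
        """On a 6-sample instance, Monte-Carlo p approaches the exact p."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 1.5
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        groups = ["a"] * 3 + ["b"] * 3
        exact = bn.permanova(dist_from(d), groups, 999, seed=0)   # 20 relabelings
        assert exact.exhaustive
        sampled = bn.permanova(dist_from(d), groups, 9, seed=1)   # forces sampling
        assert not sampled.exhaustive
        assert abs(sampled.p_value - exact.p_value) < 0.35
        big = bn.permanova(dist_from(d), groups, 19, seed=2)
        assert not big.exhaustive or big.p_value == pytest.approx(exact.p_value)

    def test_type_one_error_calibrated(self):
        """Random labels under the null: reject at 5% in <= 2 of 20 runs."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(20):
            pts = rng.normal(size=(12, 4))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            groups = rng.permutation(["a"] * 6 + ["b"] * 6)
            res = bn.permanova(dist_from(d), groups, 199, seed=int(rng.integers(2**31)))
            rejections += res.p_value < 0.05
        assert rejections <= 2

    def test_r2_invariant_under_distance_scaling(self):
        groups = ["a", "a", "b", "b"]
        r1 = bn.permanova(dist_from(TOY_D), groups, 99, seed=0).effect
        r2 = bn.permanova(dist_from(TOY_D * 7.5), groups, 99, seed=0).effect
        assert r1 == pytest.approx(r2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            bn.permanova(dist_from(TOY_D), ["a", "a", "a", "a"], 99, seed=0)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM, permanova as skbio_permanova

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        pts[:4] += 1.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        groups = ["a"] * 4 + ["b"] * 4
        ours = bn.permanova(dist_from(d), groups, 99, seed=0)
        ref = skbio_permanova(SkbioDM(d), grouping=groups, permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"])


def mrpp_delta_oracle(d, groups):
    n = len(groups)
    delta = 0.0
    for lab in sorted(set(groups)):
        idx = [i for i in range(n) if groups[i] == lab]
        pairs = [(i, j) for i in idx for j in idx if i < j]
        delta += (len(idx) / n) * np.mean([d[i, j] for i, j in pairs])
    return delta


class TestMrpp:
    def test_zero_within_distance_gives_zero_delta(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        res = bn.mrpp(dist_from(d), ["a", "a", "b", "b"], 99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value <= 1 / 3 + 1e-9

    def test_equal_distances_give_a_near_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = bn.mrpp(dist_from(d), ["a"] * 3 + ["b"] * 3, 999, seed=0)
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_matches_brute_force(self):
        groupings = [("a", "a", "b", "b"), ("a", "b", "a", "b"), ("a", "b", "b", "a")]
        deltas = [mrpp_delta_oracle(TOY_D, g) for g in groupings]
        expected_p = sum(x <= deltas[0] + 1e-12 for x in deltas) / len(deltas)
        res = bn.mrpp(dist_from(TOY_D), ["a", "a", "b", "b"], 999, seed=0)
        assert res.exhaustive
        assert res.statistic == pytest.approx(deltas[0])
        assert res.p_value == pytest.approx(expected_p)

    def test_delta_decreases_with_tighter_groups(self):
        loose = TOY_D.copy()
        tight = TOY_D.copy()
        tight[0, 1] = tight[1, 0] = 0.01
        tight[2, 3] = tight[3, 2] = 0.01
        groups = ["a", "a", "b", "b"]
        assert bn.mrpp(dist_from(tight), groups, 9, seed=0).statistic < \
               bn.mrpp(dist_from(loose), groups, 9, seed=0).statistic


class TestSingleFactorScreen:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(20):
            pts = rng.normal(size=(12, 5))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            x = rng.normal(size=12)
            res = bn.single_factor_screen(dist_from(d), x, 199, seed=int(rng.integers(2**31)))
            rejections += res.p_value < 0.05
        assert rejections <= 2

    def test_power_on_linked_variable(self, planted_analysis):
        comm = planted_analysis.community
        records = bn.generate_env_table(comm, {"NO3_N": (1, 3.0)}, seed=0)
        rel = comm.counts.counts / comm.counts.counts.sum(axis=0, keepdims=True)
        dist = bn.distance_matrix(rel, comm.counts.sample_ids, "bray_curtis")
        res = bn.single_factor_screen(dist, [r.NO3_N for r in records], 999, seed=0)
        assert res.p_value <= 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        x = rng.normal(size=8)
        perm = rng.permutation(8)
        f1 = bn.single_factor_screen(dist_from(d), x, 9, seed=0).statistic
        f2 = bn.single_factor_screen(
            DistanceMatrix([f"S{i}" for i in range(8)], d[np.ix_(perm, perm)], "euclidean"),
            x[perm], 9, seed=0).statistic
        assert f1 == pytest.approx(f2)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bn.single_factor_screen(dist_from(TOY_D), [1.0] * 4, 9, seed=0)

    def test_agrees_with_vegan_adonis(self, tmp_path):
        """Cross-check the one-term pseudo-F against R vegan's adonis2."""
        import subprocess

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        x = rng.normal(size=10)
        np.savetxt(tmp_path / "d.tsv", d, delimiter="\t")
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        script = tmp_path / "adonis.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'd <- as.dist(as.matrix(read.table("{tmp_path}/d.tsv")))\n'
            f'x <- scan("{tmp_path}/x.tsv", quiet=TRUE)\n'
            'res <- adonis2(d ~ x, permutations = 99)\n'
            'cat(res$F[1], "\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             check=True)
        f_vegan = float(out.stdout.strip().split()[-1])
        ours = bn.single_factor_screen(dist_from(d), x, 9, seed=0)
        assert ours.statistic == pytest.approx(f_vegan, rel=1e-6)


class TestTaxonWise:
    def table(self, counts):
        counts = np.asarray(counts)
        return OtuTable([f"t{i}" for i in range(counts.shape[0])],
                        [f"s{j}" for j in range(counts.shape[1])], counts)

    def test_identical_tables_nothing_significant(self):
        rng = np.random.default_rng(0)
        t = self.table(rng.integers(1, 100, size=(10, 4)))
        results = bn.taxon_wise_comparison(t, t)
        assert sum(r.significant_raw for r in results) == 0

    def test_planted_fold_change_detected_with_direction(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 100, size=(6, 5))
        shifted = base.copy()
        shifted[2] *= 5
        results = bn.taxon_wise_comparison(self.table(shifted), self.table(base))
        by_taxon = {r.taxon: r for r in results}
        assert by_taxon["t2"].significant_raw
        assert by_taxon["t2"].direction == "higher in A"

    def test_zero_variance_equal_means_p_one(self):
        t = self.table(np.full((3, 4), 10))
        results = bn.taxon_wise_comparison(t, t)
        assert all(r.p_value == 1.0 for r in results)

    def test_differing_taxon_sets_rejected(self):
        a = self.table(np.ones((2, 3), dtype=int))
        b = OtuTable(["x", "y"], ["s0", "s1", "s2"], np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError, match="taxon sets"):
            bn.taxon_wise_comparison(a, b)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(2)
        a = self.table(rng.integers(1, 100, size=(20, 5)))
        b = self.table(rng.integers(1, 100, size=(20, 5)))
        for r in bn.taxon_wise_comparison(a, b):
            assert r.p_adjusted >= r.p_value - 1e-12


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert bn.spearman_screen(x, [2.0, 4.0, 8.0, 16.0, 32.0])[0] == pytest.approx(1.0)
        assert bn.spearman_screen(x, [5.0, 4.0, 3.0, 2.0, 1.0])[0] == pytest.approx(-1.0)

    def test_ties_use_midranks(self):
        from scipy.stats import rankdata

        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        y = [4.0, 4.0, 6.0, 7.0, 7.0, 9.0]
        rho, _ = bn.spearman_screen(x, y)
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            bn.spearman_screen([1, 2, 3, 4], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 4"):
            bn.spearman_screen([1, 2, 3], [1, 2, 3])
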