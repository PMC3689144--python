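import itertools

import numpy as np
import pytest

from tests.conftest import random_sequences
from uzonmlsa import (
    DistanceMatrix,
    fst_significance,
    mantel_spearman,
    pairwise_fst,
    pairwise_nt_differences,
)


def dm_from_sequences(seqs_by_label, **kw):
    return pairwise_nt_differences(seqs_by_label, **kw)


def toy_two_demes(seq_a, seq_b, n_a, n_b):
    seqs = {f"a{i}": seq_a for i in range(n_a)} | {f"b{i}": seq_b for i in range(n_b)}
    partition = {k: k[0] for k in seqs}
    return dm_from_sequences(seqs), partition


class TestPairwiseDifferences:
    def test_identical_pair_is_zero(self):
        dm = dm_from_sequences({"a": "ACGT", "b": "ACGT"})
        assert dm.get("a", "b") == 0.0

    def test_counts_and_p_distance(self):
        dm = dm_from_sequences({"a": "AAAA", "b": "TTAA"})
        assert dm.get("a", "b") == 2.0
        dmp = dm_from_sequences({"a": "AAAA", "b": "TTAA"}, p_distance=True)
        assert dmp.get("a", "b") == pytest.approx(0.5)

    def test_missing_data_pairwise_deletion(self):
        dm = dm_from_sequences({"a": "AN-T", "b": "TNAT"})
        assert dm.get("a", "b") == 1.0  # only columns 0 and 3 comparable

    def test_matches_brute_force_double_loop(self, rng):
        seqs = dict(zip("abcdefgh", random_sequences(rng, 8, 60, missing_frac=0.05)))
        dm = dm_from_sequences(seqs)
        for x, y in itertools.combinations(seqs, 2):
            brute = sum(
                p != q
                for p, q in zip(seqs[x], seqs[y])
                if p not in "N-" and q not in "N-"
            )
            assert dm.get(x, y) == brute


class TestPairwiseFst:
    def test_monomorphic_everywhere_is_zero(self):
        dm, part = toy_two_demes("ACGT" * 5, "ACGT" * 5, 6, 6)
        assert pairwise_fst(dm, part, "a", "b") == 0.0

    def test_fixed_difference_demes_give_one(self):
        seq_b = "T" * 5 + "ACGTACGTACGTACG"
        dm, part = toy_two_demes("A" * 20, seq_b, 10, 10)
        assert pairwise_fst(dm, part, "a", "b") == pytest.approx(1.0, abs=1e-12)

    def test_small_subset_is_na(self):
        dm, part = toy_two_demes("AAAA", "TTTT", 1, 5)
        assert np.isnan(pairwise_fst(dm, part, "a", "b"))

    def test_balanced_case_equals_classical_mean_distance_estimator(self, rng):
        """For equal deme sizes the AMOVA estimator reduces exactly to
        (pi_between - pi_within) / pi_between; check on random data."""
        n = 8
        seqs = dict(
            zip(
                [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
                random_sequences(rng, 2 * n, 80),
            )
        )
        partition = {k: k[0] for k in seqs}
        dm = dm_from_sequences(seqs)
        sq = dm.square()
        idx_a = [i for i, lab in enumerate(dm.labels) if lab.startswith("a")]
        idx_b = [i for i, lab in enumerate(dm.labels) if lab.startswith("b")]
        within = [sq[i, j] for g in (idx_a, idx_b) for i, j in itertools.combinations(g, 2)]
        between = [sq[i, j] for i in idx_a for j in idx_b]
        classical = (np.mean(between) - np.mean(within)) / np.mean(between)
        assert pairwise_fst(dm, partition, "a", "b") == pytest.approx(classical, abs=1e-9)

    def test_symmetric_in_subset_order(self, rng):
        seqs = dict(zip("abcdefgh", random_sequences(rng, 8, 40)))
        partition = dict(zip("abcdefgh", "xxxxyyyy"))
        dm = dm_from_sequences(seqs)
        assert pairwise_fst(dm, partition, "x", "y") == pytest.approx(
            pairwise_fst(dm, partition, "y", "x"), abs=1e-15
        )


class TestFstSignificance:
    def test_diverged_demes_significant(self):
        dm, part = toy_two_demes("A" * 30, "T" * 10 + "A" * 20, 10, 10)
        (res,) = fst_significance(dm, part, permutations=999, seed=5)
        assert res.fst == pytest.approx(1.0, abs=1e-12)
        assert res.p_value <= 0.01

    def test_shared_haplotype_everywhere(self):
        dm, part = toy_two_demes("ACGT", "ACGT", 5, 5)
        (res,) = fst_significance(dm, part, permutations=200, seed=5)
        assert res.fst == 0.0 and res.p_value == 1.0

    def test_deterministic_given_seed(self, rng):
        seqs = dict(zip("abcdefgh", random_sequences(rng, 8, 40)))
        part = dict(zip("abcdefgh", "xxxxyyyy"))
        dm = dm_from_sequences(seqs)
        p1 = fst_significance(dm, part, permutations=300, seed=9)[0].p_value
        p2 = fst_significance(dm, part, permutations=300, seed=9)[0].p_value
        assert p1 == p2

    def test_p_values_super_uniform_under_panmixia(self, rng):
        """Permutation P values under the null must not be anti-conservative:
        the empirical CDF stays near/below the uniform's (one-sided KS)."""
        pool = random_sequences(rng, 10, 50)
        pvals = []
        for run in range(300):
            labels = [f"s{i}" for i in range(16)]
            seqs = {lab: pool[i] for lab, i in zip(labels, rng.integers(0, 10, 16))}
            part = {lab: ("x" if i < 8 else "y") for i, lab in enumerate(labels)}
            dm = dm_from_sequences(seqs)
            (res,) = fst_significance(dm, part, permutations=100, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        d_plus = float(np.max(ecdf - pvals))
        # one-sided KS critical value at alpha = 0.01
        critical = np.sqrt(-np.log(0.01) / 2) / np.sqrt(len(pvals))
        assert d_plus < critical + 0.05  # generous: discrete, add-one corrected


class TestMantel:
    def _random_dm(self, rng, n, labels=None):
        sq = rng.random((n, n)) * 10
        sq = (sq + sq.T) / 2
        np.fill_diagonal(sq, 0)
        return DistanceMatrix.from_square(labels or [f"s{i}" for i in range(n)], sq)

    def test_self_correlation_is_one(self, rng):
        dm = self._random_dm(rng, 8)
        res = mantel_spearman(dm, dm, permutations=199, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.significance_percent <= 1.0

    def test_constant_matrix_undefined(self, rng, caplog):
        dm = self._random_dm(rng, 6)
        flat = DistanceMatrix(dm.labels, np.ones_like(dm.condensed))
        with caplog.at_level("WARNING", logger="uzonmlsa"):
            res = mantel_spearman(dm, flat, permutations=199, seed=0)
        assert np.isnan(res.rho) and res.significance_percent is None
        assert "undefined" in caplog.text

    def test_label_mismatch_rejected(self, rng):
        a = self._random_dm(rng, 5)
        b = self._random_dm(rng, 5, labels=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError, match="labels"):
            mantel_spearman(a, b, permutations=199, seed=0)

    def test_agrees_with_skbio_mantel(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        a = self._random_dm(rng, 10)
        b = self._random_dm(rng, 10)
        res = mantel_spearman(a, b, permutations=199, seed=1)
        ref_rho, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a.square(), a.labels),
            skbio_distance.DistanceMatrix(b.square(), b.labels),
            method="spearman",
            permutations=0,
            alternative="greater",
        )
        assert res.rho == pytest.approx(float(ref_rho), abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        a, b = self._random_dm(rng, 9), self._random_dm(rng, 9)
        r1 = mantel_spearman(a, b, permutations=299, seed=4)
        r2 = mantel_spearman(a, b, permutations=299, seed=4)
        assert r1.significance_percent == r2.significance_percent
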