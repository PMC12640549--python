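"""Partition-agreement metrics, internal indices, and Leiden clustering."""

import math

import numpy as np
import pytest

from vargg.domains import (ContingencyTable, adjusted_rand_index,
                           internal_indices, leiden_domains,
                           normalized_mutual_information)
from vargg.errors import InputError


# --- independent brute-force oracles (pair counting / direct summation) ----

def brute_ari(a, b):
    """ARI from explicit pair counting, independent of contingency code."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            ss += sa and sb
            sd += sa and not sb
            ds += (not sa) and sb
            dd += (not sa) and (not sb)
    expected = (ss + sd) * (ss + ds) / (ss + sd + ds + dd)
    maxi = 0.5 * ((ss + sd) + (ss + ds))
    if maxi == expected:
        return 1.0
    return (ss - expected) / (maxi - expected)


def brute_nmi(a, b):
    """NMI by direct summation over label values."""
    n = len(a)
    ua, ub = sorted(set(a)), sorted(set(b))
    mi = 0.0
    for x in ua:
        for y in ub:
            pxy = sum(1 for i in range(n) if a[i] == x and b[i] == y) / n
            px = sum(1 for i in range(n) if a[i] == x) / n
            py = sum(1 for i in range(n) if b[i] == y) / n
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    hu = -sum((sum(1 for v in a if v == x) / n) * math.log(sum(1 for v in a if v == x) / n)
              for x in ua)
    hv = -sum((sum(1 for v in b if v == y) / n) * math.log(sum(1 for v in b if v == y) / n)
              for y in ub)
    if hu + hv == 0:
        return 1.0
    return 2 * mi / (hu + hv)


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert adjusted_rand_index([0, 0, 1, 1], [5, 5, 2, 2]) == 1.0

    def test_hand_case_minus_half(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_degenerate_single_clusters(self):
        assert adjusted_rand_index([0, 0, 0], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            adjusted_rand_index([0, 1], [0, 1, 2])

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            a = rng.integers(0, 5, 30)
            b = rng.integers(0, 5, 30)
            assert adjusted_rand_index(a, b) <= 1.0 + 1e-12


class TestNMI:
    def test_identical_partitions(self):
        assert normalized_mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == \
            pytest.approx(1.0)

    def test_hand_case_point_eight(self):
        assert normalized_mutual_information([0, 0, 1, 1], [0, 0, 1, 2]) == \
            pytest.approx(0.8)

    def test_identical_single_cluster_defined_one(self):
        assert normalized_mutual_information([0, 0, 0], [0, 0, 0]) == 1.0

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(0)
        a = np.repeat([0, 1], 5000)
        b = rng.integers(0, 4, 10000)
        assert normalized_mutual_information(a, b) < 0.05

    def test_bounded_zero_one(self, rng):
        for _ in range(50):
            a = rng.integers(0, 6, 40)
            b = rng.integers(0, 6, 40)
            v = normalized_mutual_information(a, b)
            assert -1e-12 <= v <= 1.0 + 1e-12


class TestMetricProperties:
    def test_symmetry_and_permutation_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = rng.integers(0, 6, n)
            b = rng.integers(0, 6, n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_index(b, a), abs=1e-12)
            assert normalized_mutual_information(a, b) == pytest.approx(
                normalized_mutual_information(b, a), abs=1e-12)
            relabel = rng.permutation(6)
            assert adjusted_rand_index(relabel[a], b) == pytest.approx(
                adjusted_rand_index(a, b), abs=1e-12)
            assert normalized_mutual_information(relabel[a], b) == pytest.approx(
                normalized_mutual_information(a, b), abs=1e-12)

    def test_agreement_with_brute_force_oracles(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 40))
            a = rng.integers(0, 4, n).tolist()
            b = rng.integers(0, 4, n).tolist()
            assert adjusted_rand_index(a, b) == pytest.approx(
                brute_ari(a, b), abs=1e-12)
            assert normalized_mutual_information(a, b) == pytest.approx(
                brute_nmi(a, b), abs=1e-12)

    def test_contingency_margins_consistent(self, rng):
        a = rng.integers(0, 3, 25)
        b = rng.integers(0, 4, 25)
        ct = ContingencyTable.from_labels(a, b)
        assert ct.counts.sum() == ct.n == 25
        assert np.array_equal(ct.counts.sum(axis=1), ct.row_sums)
        assert np.array_equal(ct.counts.sum(axis=0), ct.col_sums)


# --- internal indices -------------------------------------------------------

def brute_silhouette(Z, labels):
    n = len(Z)
    D = np.linalg.norm(Z[:, None] - Z[None, :], axis=2)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(np.mean([D[i, j] for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_davies_bouldin(Z, labels):
    labs = sorted(set(labels))
    cents = {l: Z[labels == l].mean(axis=0) for l in labs}
    scatter = {l: np.mean(np.linalg.norm(Z[labels == l] - cents[l], axis=1))
               for l in labs}
    total = 0.0
    for li in labs:
        total += max((scatter[li] + scatter[lj])
                     / np.linalg.norm(cents[li] - cents[lj])
                     for lj in labs if lj != li)
    return total / len(labs)


def brute_calinski_harabasz(Z, labels):
    labs = sorted(set(labels))
    n, k = len(Z), len(labs)
    mean = Z.mean(axis=0)
    bss = sum(np.sum(labels == l) * np.sum((Z[labels == l].mean(axis=0) - mean) ** 2)
              for l in labs)
    wss = sum(np.sum((Z[labels == l] - Z[labels == l].mean(axis=0)) ** 2)
              for l in labs)
    return (bss / (k - 1)) / (wss / (n - k))


class TestInternalIndices:
    def test_coincident_far_clusters_perfect_silhouette(self):
        Z = np.vstack([np.zeros((5, 2)), np.full((5, 2), 100.0)])
        labels = np.repeat([0, 1], 5)
        assert internal_indices(Z, labels)["SC"] == pytest.approx(1.0)

    def test_random_labels_on_single_blob_near_zero(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((500, 5))
        labels = rng.integers(0, 3, 500)
        assert abs(internal_indices(Z, labels)["SC"]) < 0.1

    def test_agreement_with_brute_force(self, rng):
        for _ in range(5):
            Z = rng.standard_normal((40, 3))
            labels = rng.integers(0, 3, 40)
            if len(set(labels.tolist())) < 2:
                continue
            out = internal_indices(Z, labels)
            assert out["SC"] == pytest.approx(brute_silhouette(Z, labels), abs=1e-10)
            assert out["DBI"] == pytest.approx(brute_davies_bouldin(Z, labels), abs=1e-10)
            assert out["CH"] == pytest.approx(brute_calinski_harabasz(Z, labels), abs=1e-10)

    def test_single_cluster_not_computable_marker(self):
        out = internal_indices(np.random.default_rng(0).standard_normal((10, 2)),
                               np.zeros(10, int))
        assert all(math.isnan(v) for v in out.values())


class TestLeiden:
    def test_separated_clouds_recovered_purely(self, rng):
        Z = np.vstack([rng.normal(0, 0.1, (30, 2)),
                       rng.normal(50, 0.1, (30, 2))])
        res = leiden_domains(Z, target_domains=2, seed=0)
        assert res.n_domains == 2
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_index(truth, res.labels) == 1.0

    def test_seeded_determinism(self, rng):
        Z = rng.standard_normal((80, 4))
        a = leiden_domains(Z, resolution=1.0, seed=3)
        b = leiden_domains(Z, resolution=1.0, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_resolution_monotonicity(self, rng):
        Z = rng.standard_normal((150, 4))
        lo = leiden_domains(Z, resolution=0.1, seed=0)
        hi = leiden_domains(Z, resolution=2.0, seed=0)
        assert hi.n_domains >= lo.n_domains

    def test_labels_contiguous_from_zero(self, rng):
        Z = rng.standard_normal((60, 3))
        res = leiden_domains(Z, resolution=1.0, seed=1)
        assert set(res.labels.tolist()) == set(range(res.n_domains))
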