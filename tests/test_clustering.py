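"""Modified (polarity-invariant) k-means: recovery, diagnostics, oracle equivalence."""

import numpy as np
import pytest

from erpstates import global_explained_variance, modified_kmeans, within_dispersion
from erpstates.exceptions import InvalidInputError


def zero_mean_unit(rows):
    rows = np.asarray(rows, float)
    rows = rows - rows.mean(axis=1, keepdims=True)
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


def best_partition_gev(maps, k):
    """Exhaustive oracle: max over all k-partitions of GEV with eigenvector templates.

    For unit-norm maps with unit weights, GEV of a partition equals
    sum_clusters lambda_max(Gram) / n.
    """
    n = maps.shape[0]
    best = -np.inf
    # canonical assignments: map 0 always in cluster 0 etc. (restricted growth strings)
    def growth(prefix, used):
        if len(prefix) == n:
            if used == k:
                yield prefix
            return
        for c in range(min(used + 1, k)):
            yield from growth(prefix + [c], max(used, c + 1))

    for assign in growth([], 0):
        assign = np.asarray(assign)
        total = 0.0
        ok = True
        for c in range(k):
            members = maps[assign == c]
            if members.shape[0] == 0:
                ok = False
                break
            gram = members @ members.T
            total += float(np.linalg.eigvalsh(gram)[-1])
        if ok:
            best = max(best, total / n)
    return best


class TestRecovery:
    def test_rank_one_data(self, rng):
        t = zero_mean_unit(rng.standard_normal((1, 10)))[0]
        signs = rng.choice([-1, 1], size=50)
        amps = rng.uniform(0.5, 3.0, size=50)
        maps = np.outer(signs * amps, t)
        res = modified_kmeans(maps, k=1, seed=0)
        assert res.gev == pytest.approx(1.0)
        assert abs(float(res.templates[0] @ t)) == pytest.approx(1.0)
        assert res.dispersion_w == pytest.approx(0.0, abs=1e-20)

    def test_two_orthogonal_templates_separate_perfectly(self, rng):
        q = np.linalg.qr(rng.standard_normal((6, 6)))[0]
        t1, t2 = q[:, 0] - q[:, 0].mean(), q[:, 1] - q[:, 1].mean()
        t1, t2 = t1 / np.linalg.norm(t1), t2 / np.linalg.norm(t2)
        maps = np.vstack(
            [np.outer(rng.choice([-1, 1], 20) * rng.uniform(1, 2, 20), t1),
             np.outer(rng.choice([-1, 1], 20) * rng.uniform(1, 2, 20), t2)]
        )
        truth = np.repeat([0, 1], 20)
        res = modified_kmeans(maps, k=2, n_restarts=16, seed=1)
        assert res.gev == pytest.approx(1.0)
        # labels identical up to cluster renaming
        same = np.mean(res.labels == truth)
        assert same in (0.0, 1.0)

    def test_k_exceeding_distinct_maps_rejected(self, rng):
        t = zero_mean_unit(rng.standard_normal((1, 6)))[0]
        maps = np.outer([1.0, -2.0, 3.0], t)  # one distinct topography
        with pytest.raises(InvalidInputError):
            modified_kmeans(maps, k=2, seed=0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,c,k", [(8, 4, 2), (10, 4, 2), (9, 5, 3)])
    def test_matches_exhaustive_partition_search(self, n, c, k, rng):
        maps = zero_mean_unit(rng.standard_normal((n, c)))
        oracle = best_partition_gev(maps, k)
        res = modified_kmeans(maps, k=k, n_restarts=200, tol=0.0, seed=7)
        assert res.gev == pytest.approx(oracle, abs=1e-9)


class TestDiagnostics:
    def test_gev_one_for_noiseless_and_zero_for_orthogonal(self, rng):
        t = zero_mean_unit(rng.standard_normal((2, 8)))
        maps = np.outer(rng.uniform(1, 2, 10), t[0])
        labels = np.zeros(10, dtype=int)
        w = np.sqrt(np.mean(maps**2, axis=1))
        assert global_explained_variance(maps, w, t[:1], labels) == pytest.approx(1.0)
        # template orthogonal to all maps
        ortho = t[1] - (t[1] @ t[0]) * t[0]
        ortho /= np.linalg.norm(ortho)
        assert global_explained_variance(maps, w, ortho[None], labels) == pytest.approx(
            0.0, abs=1e-20
        )

    def test_gev_matches_term_by_term_formula(self, rng):
        maps = rng.standard_normal((7, 5))
        maps -= maps.mean(axis=1, keepdims=True)
        templates = zero_mean_unit(rng.standard_normal((2, 5)))
        labels = rng.integers(0, 2, size=7)
        w = np.sqrt(np.mean(maps**2, axis=1))
        num = den = 0.0
        for i in range(7):
            v = maps[i] / np.linalg.norm(maps[i])
            r = float(v @ templates[labels[i]])
            num += w[i] ** 2 * r**2
            den += w[i] ** 2
        assert global_explained_variance(maps, w, templates, labels) == pytest.approx(
            num / den, rel=1e-12
        )

    def test_dispersion_zero_when_each_map_its_own_cluster(self, rng):
        maps = zero_mean_unit(rng.standard_normal((4, 6)))
        labels = np.arange(4)
        polarity = np.ones(4, dtype=int)
        assert within_dispersion(maps, maps, labels, polarity) == pytest.approx(0.0)

    def test_dispersion_matches_brute_force_sum(self, rng):
        maps = rng.standard_normal((9, 5))
        maps -= maps.mean(axis=1, keepdims=True)
        templates = zero_mean_unit(rng.standard_normal((3, 5)))
        labels = rng.integers(0, 3, size=9)
        polarity = rng.choice([-1, 1], size=9)
        expected = 0.0
        for i in range(9):
            v = maps[i] / np.linalg.norm(maps[i])
            expected += float(np.sum((polarity[i] * v - templates[labels[i]]) ** 2))
        assert within_dispersion(maps, templates, labels, polarity) == pytest.approx(
            expected, rel=1e-12
        )


class TestPolarityInvariance:
    def test_sign_flips_change_nothing(self, rng):
        maps = rng.standard_normal((30, 12))
        maps -= maps.mean(axis=1, keepdims=True)
        flips = rng.choice([-1.0, 1.0], size=30)
        a = modified_kmeans(maps, k=3, n_restarts=20, seed=5)
        b = modified_kmeans(maps * flips[:, None], k=3, n_restarts=20, seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.gev == pytest.approx(b.gev, rel=1e-12)
        assert a.dispersion_w == pytest.approx(b.dispersion_w, rel=1e-10)
        assert np.allclose(a.templates, b.templates, atol=1e-8)
        assert np.array_equal(a.polarity * flips.astype(int), b.polarity)


class TestMonotonicity:
    def test_gev_nondecreasing_and_w_nonincreasing_in_k(self, rng):
        maps = rng.standard_normal((40, 10))
        maps -= maps.mean(axis=1, keepdims=True)
        gevs, ws = [], []
        for k in range(1, 6):
            res = modified_kmeans(maps, k=k, n_restarts=80, seed=11)
            gevs.append(res.gev)
            ws.append(res.dispersion_w)
        assert all(b >= a - 1e-9 for a, b in zip(gevs, gevs[1:]))
        assert all(b <= a + 1e-6 for a, b in zip(ws, ws[1:]))
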