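import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from haptonet import (
    ZotuTable,
    aggregate_taxa,
    distance_mlr_lmg,
    env_distances,
    haversine_km,
    mantel,
    taxa_env_spearman,
)
from haptonet.drivers import EnvDistanceSet, _lower_triangle


def _meta(values: dict, n: int) -> pd.DataFrame:
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame(values, index=idx)


class TestEnvDistances:
    def test_two_point_zscore_distance(self):
        meta = _meta({"temperature": [0.0, 10.0],
                      "latitude": [0, 0], "longitude": [0, 0]}, 2)
        env = env_distances(meta, ["temperature"])
        # z = (-1/sqrt(2), +1/sqrt(2)) -> |dz| = sqrt(2)
        assert env["temperature"][0, 1] == pytest.approx(math.sqrt(2), abs=1e-5)

    def test_identical_coordinates_zero_geo(self):
        meta = _meta({"temperature": [0, 1, 2],
                      "latitude": [71.0] * 3, "longitude": [-160.0] * 3}, 3)
        env = env_distances(meta, ["temperature"])
        assert np.allclose(env["geographic"].data, 0.0)

    def test_quarter_great_circle(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(6371 * math.pi / 2, rel=1e-6)

    def test_constant_variable_flagged(self):
        meta = _meta({"salinity": [32.0, 32.0, 32.0],
                      "latitude": [70, 71, 72], "longitude": [0, 0, 0]}, 3)
        env = env_distances(meta, ["salinity"])
        assert "salinity" in env.not_computed
        assert "salinity" not in env.matrices

    def test_missing_values_propagate_as_nan_pairs(self):
        meta = _meta({"NH4": [0.1, np.nan, 0.4],
                      "latitude": [70, 71, 72], "longitude": [0, 0, 0]}, 3)
        env = env_distances(meta, ["NH4"])
        assert np.isnan(env["NH4"].data[0, 1])
        assert not np.isnan(env["NH4"].data[0, 2])


def _mantel_r_bruteforce(A, B):
    iu = np.triu_indices(A.shape[0], k=1)
    return np.corrcoef(A[iu], B[iu])[0, 1]


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = mantel(dm, dm, 99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_enumeration_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        A = squareform(pdist(rng.normal(size=(4, 2))))
        B = squareform(pdist(rng.normal(size=(4, 2))))
        ids = list("abcd")
        res = mantel(DistanceMatrix(A, ids=ids), DistanceMatrix(B, ids=ids),
                     n_permutations="exact", seed=0)
        r_obs = _mantel_r_bruteforce(A, B)
        count = total = 0
        for perm in itertools.permutations(range(4)):
            p = np.asarray(perm)
            total += 1
            if _mantel_r_bruteforce(A, B[np.ix_(p, p)]) >= r_obs - 1e-12:
                count += 1
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        A = squareform(pdist(rng.normal(size=(6, 2))))
        B = squareform(pdist(rng.normal(size=(6, 2))))
        ids = [str(i) for i in range(6)]
        r_ab = mantel(DistanceMatrix(A, ids=ids), DistanceMatrix(B, ids=ids),
                      0, seed=0).r
        r_ba = mantel(DistanceMatrix(B, ids=ids), DistanceMatrix(A, ids=ids),
                      0, seed=0).r
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_label_mismatch_rejected(self):
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], float)
        with pytest.raises(ValueError):
            mantel(DistanceMatrix(d, ids=list("abcd")),
                   DistanceMatrix(d, ids=list("abce")), 99, seed=0)

    def test_matches_skbio_r(self):
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(3)
        A = squareform(pdist(rng.normal(size=(8, 2))))
        B = squareform(pdist(rng.normal(size=(8, 2))))
        ids = [str(i) for i in range(8)]
        ours = mantel(DistanceMatrix(A, ids=ids), DistanceMatrix(B, ids=ids),
                      99, seed=0)
        res = sk_mantel(DistanceMatrix(A, ids=ids), DistanceMatrix(B, ids=ids),
                        method="pearson", permutations=0)
        theirs_r = res[0] if isinstance(res, tuple) else res["correlation coefficient"]
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-10)


def _env_set_from_vectors(vectors: dict, ids) -> EnvDistanceSet:
    mats = {}
    for name, v in vectors.items():
        v = np.asarray(v, float)
        mats[name] = DistanceMatrix(np.abs(v[:, None] - v[None, :]), ids=ids)
    return EnvDistanceSet(matrices=mats)


class TestLmg:
    @staticmethod
    def _setup(n=10, p=3, seed=0):
        rng = np.random.default_rng(seed)
        ids = [str(i) for i in range(n)]
        vectors = {f"x{k}": rng.normal(size=n) for k in range(p)}
        env = _env_set_from_vectors(vectors, ids)
        w = rng.normal(size=p)
        X = np.column_stack([_lower_triangle(env[f"x{k}"]) for k in range(p)])
        y = X @ w + 0.3 * rng.normal(size=X.shape[0])
        # build a symmetric "community" matrix with that lower triangle
        iu = np.triu_indices(n, k=1)
        D = np.zeros((n, n))
        D[iu] = y - y.min() + 0.1
        D = D + D.T
        return DistanceMatrix(D, ids=ids), env, list(vectors)

    def test_shares_sum_to_full_r2(self):
        dm, env, names = self._setup()
        out = distance_mlr_lmg(dm, env, predictors=names)
        assert sum(out.contribution.values()) == pytest.approx(
            out.total_r_squared, abs=1e-10
        )

    def test_matches_bruteforce_ordering_average(self):
        dm, env, names = self._setup(n=9, p=3, seed=5)
        out = distance_mlr_lmg(dm, env, predictors=names)
        y = _lower_triangle(dm)
        X = np.column_stack([_lower_triangle(env[n_]) for n_ in names])

        def r2(cols):
            if not cols:
                return 0.0
            Z = np.column_stack([np.ones(y.size), X[:, cols]])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ beta
            return 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()

        shares = np.zeros(3)
        orders = list(itertools.permutations(range(3)))
        for order in orders:
            acc = []
            for k in order:
                shares[k] += r2(acc + [k]) - r2(acc)
                acc.append(k)
        shares /= len(orders)
        for k, name in enumerate(names):
            assert out.contribution[name] == pytest.approx(shares[k], abs=1e-10)

    def test_orthogonal_predictors_get_marginal_r2(self):
        # orthogonal unfolded predictors via explicit construction
        n_pairs = 6
        ids = list("abcd")
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        x2 -= x2 @ x1 / (x1 @ x1) * x1  # exact orthogonality, both centered-ish
        y = 2 * x1 + 1 * x2
        iu = np.triu_indices(4, k=1)

        def dm_from(v):
            D = np.zeros((4, 4))
            D[iu] = v - v.min() + 0.1
            return DistanceMatrix(D + D.T, ids=ids)

        env = EnvDistanceSet(matrices={"a": dm_from(x1), "b": dm_from(x2)})
        out = distance_mlr_lmg(dm_from(y), env, predictors=["a", "b"])

        def marginal(v):
            Z = np.column_stack([np.ones(n_pairs), v])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ beta
            return 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()

        assert out.contribution["a"] == pytest.approx(marginal(x1), abs=1e-10)
        assert out.contribution["b"] == pytest.approx(marginal(x2), abs=1e-10)

    def test_planted_single_driver_dominates(self):
        rng = np.random.default_rng(9)
        n = 12
        ids = [str(i) for i in range(n)]
        vectors = {"temperature": rng.normal(size=n),
                   "salinity": rng.normal(size=n),
                   "PO4": rng.normal(size=n)}
        env = _env_set_from_vectors(vectors, ids)
        t = _lower_triangle(env["temperature"])
        iu = np.triu_indices(n, k=1)
        D = np.zeros((n, n))
        D[iu] = t + 0.05 * rng.normal(size=t.size)
        D = D - D.min()
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix((D + D.T) / 2, ids=ids)
        out = distance_mlr_lmg(dm, env, predictors=list(vectors))
        assert out.contribution["temperature"] > 0.9 * out.total_r_squared

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(4)
        ids = [str(i) for i in range(6)]
        v = rng.normal(size=6)
        env = _env_set_from_vectors({"a": v, "b": 2 * v, "c": rng.normal(size=6)},
                                    ids)
        dm = env["c"]
        with pytest.raises(ValueError, match="'a' and 'b'|'b' and 'a'"):
            distance_mlr_lmg(dm, env, predictors=["a", "b", "c"])


class TestTaxaEnv:
    @staticmethod
    def _table():
        counts = np.array([[10, 10, 80], [20, 20, 60], [30, 30, 40], [40, 40, 20]])
        return ZotuTable(
            counts,
            [f"s{i}" for i in range(4)],
            ["Z1", "Z2", "Z3"],
            taxonomy=["k;g1", "k;g1", "k;g2"],
        )

    def test_aggregation_is_additive(self):
        taxa = aggregate_taxa(self._table(), rank=1)
        assert taxa.loc["s0", "g1"] == pytest.approx(0.2)
        assert taxa.loc["s3", "g2"] == pytest.approx(0.2)

    def test_monotone_taxon_rho_one(self):
        meta = _meta({"depth": [5, 10, 20, 40]}, 4)
        out = taxa_env_spearman(self._table(), 1, meta, ["depth"], fdr=False)
        g1 = out[(out.taxon == "g1") & (out.variable == "depth")]
        assert g1["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_taxon_flagged_not_zero(self):
        counts = np.array([[10, 10], [10, 10], [10, 10], [10, 10], [10, 10]])
        t = ZotuTable(counts, [f"s{i}" for i in range(5)], ["Z1", "Z2"],
                      taxonomy=["k;g1", "k;g2"])
        meta = _meta({"depth": [1, 2, 3, 4, 5]}, 5)
        out = taxa_env_spearman(t, 1, meta, ["depth"], fdr=False)
        assert (out["status"] == "not-computed").all()
        assert out["rho"].isna().all()

    def test_rank_absent_rejected(self):
        meta = _meta({"depth": [5, 10, 20, 40]}, 4)
        with pytest.raises(ValueError, match="rank 5"):
            taxa_env_spearman(self._table(), 5, meta, ["depth"])
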