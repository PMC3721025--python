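import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ventflow.beta import (
    BioenvResult,
    bioenv,
    bray_curtis,
    distance_matrix,
    fit_vectors,
    hier_cluster,
    kruskal_stress,
    nmds,
    theta_yc,
)
from ventflow.errors import ValidationError
from ventflow.io_model import OtuTable

from oracles import theta_yc_direct


class TestSimilarities:
    def test_identical_compositions(self):
        a = np.array([0.2, 0.3, 0.5])
        assert theta_yc(a, a) == pytest.approx(1.0)
        assert bray_curtis(a, a) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.5, 0.5])
        assert theta_yc(a, b) == pytest.approx(0.0)
        assert bray_curtis(a, b) == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.5, 0.0, 0.5])
        assert theta_yc(a, b) == pytest.approx(1.0 / 3.0)
        assert bray_curtis(a, b) == pytest.approx(0.5)

    def test_bounds_and_symmetry_random(self, rng):
        for _ in range(50):
            a = rng.dirichlet(np.ones(20))
            b = rng.dirichlet(np.ones(20))
            for sim in (theta_yc, bray_curtis):
                s = sim(a, b)
                assert 0.0 <= s <= 1.0
                assert s == pytest.approx(sim(b, a), abs=1e-12)

    def test_theta_matches_direct_oracle(self, rng):
        for _ in range(30):
            a = rng.dirichlet(np.ones(15))
            b = rng.dirichlet(np.ones(15))
            assert theta_yc(a, b) == pytest.approx(
                theta_yc_direct(list(a), list(b)), abs=1e-12
            )

    def test_zero_sum_rejected(self):
        with pytest.raises(ValidationError):
            theta_yc(np.zeros(3), np.array([0.5, 0.25, 0.25]))

    def test_unnormalised_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.array([0.5, 0.6]), np.array([0.5, 0.5]))


class TestDistanceMatrix:
    def test_from_table(self, tiny_table):
        dm = distance_matrix(tiny_table, "thetayc")
        assert dm.shape == (2, 2)
        assert dm.data[0, 0] == 0.0
        assert 0.0 <= dm.data[0, 1] <= 1.0


class TestHierCluster:
    def test_closest_pair_merges_first(self):
        dm = DistanceMatrix(
            [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]], ["A", "B", "C"]
        )
        dend = hier_cluster(dm)
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # A and B
        assert first[2] == pytest.approx(0.1)

    def test_ultrametric_heights_reproduced(self):
        # a strict ultrametric: d(A,B)=0.2, d(.,C)=0.6, d(.,D)=0.8
        m = np.array([
            [0.0, 0.2, 0.6, 0.8],
            [0.2, 0.0, 0.6, 0.8],
            [0.6, 0.6, 0.0, 0.8],
            [0.8, 0.8, 0.8, 0.0],
        ])
        dm = DistanceMatrix(m, list("ABCD"))
        for method in ("average", "complete", "single"):
            dend = hier_cluster(dm, method)
            coph = squareform(cophenet(dend.linkage))
            assert np.allclose(coph, m)

    def test_input_order_invariance(self, rng):
        ids = [f"S{i}" for i in range(6)]
        m = squareform(rng.uniform(0.1, 1.0, size=15))
        dm1 = DistanceMatrix(m, ids)
        perm = list(rng.permutation(ids))
        dm2 = dm1.filter(perm)
        d1, d2 = hier_cluster(dm1), hier_cluster(dm2)
        assert d1.ids == d2.ids
        assert np.allclose(d1.linkage, d2.linkage)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            hier_cluster(DistanceMatrix([[0.0]], ["A"]))


class TestNMDS:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(7, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"S{i}" for i in range(7)])
        result = nmds(dm, restarts=4, seed=0)
        assert result.stress < 1e-3

    def test_three_equidistant_points(self):
        dm = DistanceMatrix(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], ["A", "B", "C"]
        )
        result = nmds(dm, restarts=4, seed=0)
        assert result.stress < 1e-6

    def test_stress_invariant_under_rotation(self, rng):
        pts = rng.normal(size=(6, 2))
        d = pdist(pts)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        d_rot = pdist(pts @ R.T)
        disparities = d.copy()
        assert kruskal_stress(d, disparities) == pytest.approx(
            kruskal_stress(d_rot, disparities), abs=1e-9
        )

    def test_stress_non_increasing_within_restart(self, default_scenario, default_subtraction):
        sc = default_scenario
        vent_sets, _ = default_subtraction
        union = sorted(set().union(*[v.union for v in vent_sets.values()]))
        vents = [s for s in sc.table.sample_ids
                 if sc.metadata.data.loc[s, "habitat"] == "diffuse_flow"]
        dm = distance_matrix(sc.table.select_samples(vents).select_otus(union))
        result = nmds(dm, restarts=3, seed=5)
        path = result.stress_path
        assert np.all(np.diff(path) <= 1e-9)

    def test_coordinates_centered(self, rng):
        pts = rng.normal(size=(8, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"S{i}" for i in range(8)])
        result = nmds(dm, restarts=2, seed=0)
        assert np.allclose(result.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            nmds(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]), k=2)


class TestFitVectors:
    def _ordination(self, rng, n=12):
        pts = rng.normal(size=(n, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"S{i}" for i in range(n)])
        return nmds(dm, restarts=2, seed=1)

    def test_axis_aligned_variable(self, rng):
        ordination = self._ordination(rng)
        coords = ordination.coordinates
        variables = pd.DataFrame({"ax1copy": coords["axis1"]})
        fitted = fit_vectors(ordination, variables, kind="environment", transform=False)
        row = fitted.iloc[0]
        assert abs(row["r_axis1"]) == pytest.approx(1.0, abs=1e-9)
        assert abs(row["r_axis2"]) == pytest.approx(0.0, abs=1e-6)
        assert row["r"] == pytest.approx(1.0, abs=1e-9)

    def test_null_retention_rate_matches_chi2_tail(self, rng):
        """Permutation null for the r >= 0.6 magnitude filter at n = 12:
        r^2 is approximately 1/(n-1) x chi2(2), so the null retention rate
        is near exp(-(n-1) 0.36 / 2) ~ 0.138 -- small but not negligible."""
        n = 12
        ordination = self._ordination(rng, n=n)
        variable = rng.normal(size=n)
        hits = 0
        n_perm = 1000
        coords = ordination.coordinates.to_numpy()
        for _ in range(n_perm):
            v = rng.permutation(variable)
            r = np.array([np.corrcoef(v, coords[:, j])[0, 1] for j in range(2)])
            hits += np.sqrt((r**2).sum()) >= 0.6
        rate = hits / n_perm
        expected = np.exp(-(n - 1) * 0.36 / 2)
        assert abs(rate - expected) < 0.06

    def test_otu_sequence_floor(self, rng):
        ordination = self._ordination(rng)
        coords = ordination.coordinates
        variables = pd.DataFrame({"OtuX": coords["axis1"]})  # r = 1 by construction
        totals = pd.Series({"OtuX": 150})
        fitted = fit_vectors(ordination, variables, kind="otu", otu_totals=totals)
        assert not fitted.iloc[0]["retained"]
        totals = pd.Series({"OtuX": 250})
        fitted = fit_vectors(ordination, variables, kind="otu", otu_totals=totals)
        assert fitted.iloc[0]["retained"]

    def test_constant_variable_excluded(self, rng):
        ordination = self._ordination(rng)
        variables = pd.DataFrame({"flat": np.ones(12)},
                                 index=ordination.coordinates.index)
        with pytest.warns(UserWarning, match="constant"):
            fitted = fit_vectors(ordination, variables, kind="environment")
        assert fitted.empty


class TestBioenv:
    def test_recovers_embedded_coordinates(self, rng):
        pts = rng.uniform(1, 5, size=(10, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, [f"S{i}" for i in range(10)])
        chem = pd.DataFrame(
            {"emb1": pts[:, 0], "emb2": pts[:, 1],
             "noise1": rng.uniform(1, 5, 10), "noise2": rng.uniform(1, 5, 10)},
            index=dm.ids,
        )
        result = bioenv(dm, chem, transform=False)
        assert set(result.best_subset) == {"emb1", "emb2"}
        assert result.best_rho > 0.95

    def test_pure_noise_rho_near_zero(self, rng):
        best = []
        for _ in range(200):
            d = squareform(rng.uniform(0.1, 1.0, size=45))
            dm = DistanceMatrix(d, [f"S{i}" for i in range(10)])
            chem = pd.DataFrame(rng.uniform(1, 2, size=(10, 3)),
                                index=dm.ids, columns=["a", "b", "c"])
            best.append(bioenv(dm, chem, transform=False).best_rho)
        assert np.mean(np.abs(best)) < 0.35

    def test_single_candidate_variable(self, rng):
        d = squareform(rng.uniform(0.1, 1.0, size=6))
        dm = DistanceMatrix(d, list("ABCD"))
        chem = pd.DataFrame({"only": rng.uniform(1, 2, 4)}, index=dm.ids)
        result = bioenv(dm, chem)
        assert result.best_subset == ("only",)

    def test_variable_order_invariance(self, rng):
        d = squareform(rng.uniform(0.1, 1.0, size=45))
        dm = DistanceMatrix(d, [f"S{i}" for i in range(10)])
        chem = pd.DataFrame(rng.uniform(1, 2, size=(10, 4)),
                            index=dm.ids, columns=list("wxyz"))
        r1 = bioenv(dm, chem)
        r2 = bioenv(dm, chem[list("zyxw")])
        assert r1.best_subset == r2.best_subset
        assert r1.best_rho == pytest.approx(r2.best_rho, abs=1e-12)

    def test_no_usable_variables_rejected(self, rng):
        d = squareform(rng.uniform(0.1, 1.0, size=6))
        dm = DistanceMatrix(d, list("ABCD"))
        chem = pd.DataFrame({"x": [1.0, np.nan, 2.0, 3.0]}, index=dm.ids)
        with pytest.raises(ValidationError):
            bioenv(dm, chem)
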