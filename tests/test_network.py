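"""Correlation network: bicor, adjacency, TOM, module detection, LOESS."""

import numpy as np
import pandas as pd
import pytest

import afproteome as afp
from afproteome.network import detect_modules, loess_profile, select_hubs


class TestBicor:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        assert afp.bicor(x, x) == pytest.approx(1.0)
        assert afp.bicor(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_clean_gaussians(self):
        """On outlier-free data bicor tracks Pearson up to sampling noise."""
        rng = np.random.default_rng(1)
        n, p = 100, 60
        X = rng.normal(size=(n, p))
        b = afp.bicor_matrix(X)
        r = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices(p, k=1)
        diff = np.abs(b[iu] - r[iu])
        assert (diff < 0.05).mean() >= 0.95
        assert np.quantile(diff, 0.99) < 0.08
        assert np.median(diff) < 0.02

    def test_matches_independent_bicor_implementation(self):
        """Oracle: pingouin's biweight midcorrelation, same tuning constant."""
        from pingouin import corr

        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40)
            y[0] += 15.0  # include an outlier
            theirs = float(corr(x, y, method="bicor")["r"].iloc[0])
            assert afp.bicor(x, y) == pytest.approx(theirs, abs=1e-12)

    def test_robust_to_single_gross_outlier(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 0.9 * x + 0.3 * rng.normal(size=60)
        clean_pearson = np.corrcoef(x, y)[0, 1]
        y_bad = y.copy()
        y_bad[0] = 40.0
        contaminated_pearson = np.corrcoef(x, y_bad)[0, 1]
        robust = afp.bicor(x, y_bad)
        assert abs(robust - clean_pearson) < abs(contaminated_pearson - clean_pearson)

    def test_zero_mad_column_falls_back_to_pearson(self):
        # >50% identical values give MAD 0; Pearson fallback still correlates
        x = np.r_[np.zeros(20), [1.0, 2.0, 3.0, 4.0]]
        y = np.r_[np.zeros(20), [1.1, 2.2, 2.9, 4.2]]
        assert afp.bicor(x, y) > 0.9

    def test_needs_four_samples(self):
        with pytest.raises(afp.ValidationError, match="4 samples"):
            afp.bicor_matrix(np.ones((3, 2)))


class TestAdjacency:
    def test_extremes_and_midpoint(self):
        rho = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        a = afp.signed_adjacency(rho, beta=22)
        assert a[0, 2] == 0.0
        assert a[0, 1] == pytest.approx(0.5**22)
        assert (np.diag(a) == 1.0).all()

    def test_strictly_increasing_in_correlation(self):
        rhos = np.linspace(-0.999, 1, 200)
        vals = [
            afp.signed_adjacency(np.array([[1.0, r], [r, 1.0]]), beta=22)[0, 1]
            for r in rhos
        ]
        assert (np.diff(vals) > 0).all()

    def test_beta_below_one_rejected(self):
        with pytest.raises(afp.ValidationError, match="beta"):
            afp.signed_adjacency(np.eye(2), beta=0.5)


class TestTOM:
    def test_hand_computed_three_node_toy(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = afp.topological_overlap(a)
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_block_diagonal_stays_block_diagonal(self):
        a = np.zeros((4, 4))
        a[:2, :2] = 0.8
        a[2:, 2:] = 0.8
        np.fill_diagonal(a, 1.0)
        tom = afp.topological_overlap(a)
        assert tom[0, 2] == 0.0 and tom[1, 3] == 0.0
        assert tom[0, 1] > 0

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = afp.topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert (np.diag(tom) == 1.0).all()
        assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(afp.ValidationError, match="symmetric"):
            afp.topological_overlap(a)


def _network_on(expr):
    rho = afp.bicor_matrix(expr.to_numpy())
    return afp.topological_overlap(afp.signed_adjacency(rho, beta=22))


class TestDetectModules:
    def test_recovers_planted_modules(self, small_sim, small_norm):
        from sklearn.metrics import adjusted_rand_score

        _, _, _, truth = small_sim
        norm, _ = small_norm
        members = truth.analytes.index[truth.analytes["module_id"] > 0]
        rng = np.random.default_rng(0)
        pool = truth.analytes.index[
            (truth.analytes["module_id"] == 0)
            & ~truth.analytes["is_de"]
            & (truth.analytes["tissue_id"] == "")
            & ~truth.analytes["is_control"]
        ]
        ids = list(members) + list(rng.choice(pool, size=40, replace=False))
        expr = norm.subset(analytes=ids).data
        assignment = detect_modules(_network_on(expr), expr)
        ari = adjusted_rand_score(
            truth.analytes.loc[ids, "module_id"].to_numpy(),
            assignment.labels.to_numpy(),
        )
        assert len(assignment.module_ids) == 3
        assert ari >= 0.8

    def test_pure_noise_goes_to_background(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(size=(28, 150)), columns=[f"N{i}" for i in range(150)]
        )
        assignment = detect_modules(_network_on(expr), expr)
        assert (assignment.labels == 0).all()

    def test_highly_correlated_modules_merge(self):
        rng = np.random.default_rng(5)
        n = 40
        f = rng.normal(size=n)
        f2 = 0.97 * f + np.sqrt(1 - 0.97**2) * rng.normal(size=n)
        cols = {}
        for i in range(25):
            cols[f"M1_{i}"] = 0.9 * f + 0.2 * rng.normal(size=n)
        for i in range(25):
            cols[f"M2_{i}"] = 0.9 * f2 + 0.2 * rng.normal(size=n)
        expr = pd.DataFrame(cols)
        merged = detect_modules(_network_on(expr), expr, merge_corr=0.85)
        assert len(merged.module_ids) == 1

    def test_separated_modules_stay_apart(self):
        rng = np.random.default_rng(8)
        n = 40
        f1 = rng.normal(size=n)
        f2 = 0.3 * f1 + np.sqrt(1 - 0.3**2) * rng.normal(size=n)
        cols = {}
        for i in range(25):
            cols[f"M1_{i}"] = 0.9 * f1 + 0.2 * rng.normal(size=n)
            cols[f"M2_{i}"] = 0.9 * f2 + 0.2 * rng.normal(size=n)
        expr = pd.DataFrame(cols)
        apart = detect_modules(_network_on(expr), expr, merge_corr=0.85)
        assert len(apart.module_ids) == 2


class TestEigenprofilesAndHubs:
    def test_identical_profiles_give_unit_variance_and_kme(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=20)
        expr = pd.DataFrame({f"A{i}": v for i in range(5)})
        labels = pd.Series(1, index=expr.columns)
        eigs, kme = afp.module_eigenprofiles(expr, labels)
        assert eigs.variance_explained[1] == pytest.approx(1.0)
        assert np.allclose(kme[1], 1.0)

    def test_orientation_gives_nonnegative_mean_member_kme(self, small_sim, small_norm):
        _, _, _, truth = small_sim
        norm, _ = small_norm
        labels = truth.analytes.loc[norm.data.columns, "module_id"]
        labels = labels[labels > 0]
        eigs, kme = afp.module_eigenprofiles(norm.subset(analytes=labels.index).data, labels)
        for m in eigs.variance_explained:
            members = labels.index[labels == m]
            assert kme.loc[members, m].mean() >= 0

    def test_hub_selection_orders_by_kme(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=30)
        cols = {"HUB": f}
        for i in range(9):
            cols[f"A{i}"] = f + (0.3 + 0.1 * i) * rng.normal(size=30)
        expr = pd.DataFrame(cols)
        labels = pd.Series(1, index=expr.columns)
        assignment = afp.ModuleAssignment(labels=labels)
        _, kme = afp.module_eigenprofiles(expr, labels)
        hubs = select_hubs(kme, assignment, n=4)
        assert hubs[1][0] == "HUB"
        everyone = select_hubs(kme, assignment, n=10)
        assert set(everyone[1]) == set(expr.columns)

    def test_planted_hubs_have_larger_loadings(self, small_sim, small_norm):
        _, _, _, truth = small_sim
        norm, _ = small_norm
        labels = truth.analytes.loc[norm.data.columns, "module_id"]
        labels = labels[labels > 0]
        expr = norm.subset(analytes=labels.index).data
        assignment = afp.ModuleAssignment(labels=labels)
        _, kme = afp.module_eigenprofiles(expr, labels)
        hubs = select_hubs(kme, assignment, n=4)
        for m, hub_ids in hubs.items():
            members = set(assignment.members(m))
            rest = members - set(hub_ids)
            hub_load = truth.analytes.loc[hub_ids, "module_loading"].abs().mean()
            rest_load = truth.analytes.loc[sorted(rest), "module_loading"].abs().mean()
            assert hub_load > rest_load


class TestLoess:
    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(0, 10, 30)
        y = 2.0 * x - 1.0
        grid, fitted = loess_profile(x, y, span=0.75)
        assert np.abs(fitted - (2.0 * grid - 1.0)).max() < 1e-6

    def test_constant_data_gives_constant_fit(self):
        x = np.linspace(0, 1, 20)
        grid, fitted = loess_profile(x, np.full(20, 3.3))
        assert np.allclose(fitted, 3.3)

    def test_noiseless_quadratic_error_below_one_percent(self):
        x = np.linspace(-2, 2, 50)
        y = x**2
        grid, fitted = loess_profile(x, y, span=0.75)
        rng_y = y.max() - y.min()
        assert np.abs(fitted - grid**2).max() < 0.01 * rng_y

    def test_span_too_small_rejected(self):
        x = np.linspace(0, 1, 6)
        with pytest.raises(afp.ValidationError):
            loess_profile(x, x, span=0.0)
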