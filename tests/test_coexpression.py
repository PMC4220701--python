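"""Network construction, TOM, module detection and TF subnetwork export."""

import numpy as np
import pandas as pd
import pytest

import msetkit as mk
from msetkit.coexpression import UNASSIGNED, CoexpressionConfig
from msetkit.errors import InvalidInputError


def brute_force_tom(adj):
    """Triple-loop evaluation of topological overlap (unit-diagonal input)."""
    n = adj.shape[0]
    out = np.eye(n)
    for i in range(n):
        k_i = sum(adj[i, u] for u in range(n) if u != i)
        for j in range(n):
            if i == j:
                continue
            k_j = sum(adj[j, u] for u in range(n) if u != j)
            shared = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + adj[i, j]) / (min(k_i, k_j) + 1 - adj[i, j])
    return out


def random_adjacency(rng, n):
    cor = rng.uniform(0, 1, size=(n, n))
    adj = (cor + cor.T) / 2
    np.fill_diagonal(adj, 1.0)
    return adj


class TestAdjacency:
    def test_closed_forms(self):
        samples = [f"s{i}" for i in range(4)]
        x = np.array([1.0, 2.0, 3.0, 4.0])
        values = pd.DataFrame(
            [x, -x + 10, [5.0, 4.8, 5.3, 4.9]], index=["A", "B", "C"], columns=samples
        )
        adj = mk.adjacency(values, beta=6, network_type="unsigned")
        assert adj[0, 1] == pytest.approx(1.0)  # |cor| = 1 saturates any power
        assert np.all(np.diag(adj) == 1.0)
        # |cor| = 0.5 at beta 6 -> 0.5^6
        assert 0.5**6 == pytest.approx(0.015625)

    def test_signed_transform(self):
        samples = [f"s{i}" for i in range(4)]
        x = np.array([1.0, 2.0, 3.0, 4.0])
        values = pd.DataFrame([x, -x], index=["A", "B"], columns=samples)
        adj = mk.adjacency(values, beta=2, network_type="signed")
        assert adj[0, 1] == pytest.approx(0.0)  # cor=-1 -> ((1-1)/2)^beta

    def test_beta_below_one_rejected(self):
        values = pd.DataFrame(np.eye(3), index=list("ABC"))
        with pytest.raises(InvalidInputError):
            mk.adjacency(values, beta=0.5)


class TestTom:
    def test_complete_graph(self):
        adj = np.ones((6, 6))
        assert np.allclose(mk.tom_similarity(adj), 1.0)

    def test_empty_graph(self):
        adj = np.eye(5)
        tom = mk.tom_similarity(adj)
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_asymmetric_rejected(self):
        adj = np.eye(3)
        adj[0, 1] = 0.5
        with pytest.raises(InvalidInputError):
            mk.tom_similarity(adj)

    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_matches_brute_force_formula(self, rng, n):
        for _ in range(5):
            adj = random_adjacency(rng, n)
            assert np.allclose(
                mk.tom_similarity(adj), brute_force_tom(adj), atol=1e-10
            )

    def test_entries_bounded_and_symmetric(self, rng):
        adj = random_adjacency(rng, 12)
        tom = mk.tom_similarity(adj)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestSoftThreshold:
    def test_exact_power_law_fits_perfectly(self):
        """A degree sequence following an exact power law gives R^2 = 1."""
        from msetkit.coexpression import _scale_free_fit

        # construct k so that each log-bin has count proportional to k^-1.5
        ks, reps = [], []
        for i, k in enumerate(np.geomspace(1, 100, 10)):
            ks.append(k)
            reps.append(int(round(1000 * k**-1.5)))
        k_vec = np.repeat(ks, reps)
        r2, slope = _scale_free_fit(k_vec, n_bins=10)
        assert slope < 0
        assert r2 > 0.97

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_planted_modules_reach_threshold_somewhere(self):
        """On planted-module data some candidate power attains the scale-free
        fit threshold; the selected power always keeps the network connected
        (mean connectivity above the configured floor)."""
        u = mk.simulate_universe(mk.UniverseSpec(n_genes=120, seed=4))
        expr, _ = mk.simulate_modules(
            u, mk.ModuleSpec(module_sizes=[60, 60], eigengene_loading=0.8, n_samples=12, seed=4)
        )
        beta, fit = mk.pick_soft_threshold(expr)
        assert beta in range(1, 21)
        assert (fit.r_squared > 0.8).any()
        assert fit.set_index("beta").loc[beta, "mean_k"] >= 2.0

    def test_noise_falls_back_with_warning(self):
        u = mk.simulate_universe(mk.UniverseSpec(n_genes=60, seed=3))
        expr, _ = mk.simulate_modules(u, mk.ModuleSpec(module_sizes=[], n_samples=8, seed=4))
        config = CoexpressionConfig(scale_free_r2_threshold=0.99, min_module_size=10)
        with pytest.warns(UserWarning, match="falling back"):
            beta, fit = mk.pick_soft_threshold(expr, config)
        assert beta in range(1, 21)


class TestDetectModules:
    def test_two_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        u = mk.simulate_universe(mk.UniverseSpec(n_genes=110, seed=5))
        expr, truth = mk.simulate_modules(
            u, mk.ModuleSpec(module_sizes=[60, 50], eigengene_loading=0.8, n_samples=12, seed=5)
        )
        asg = mk.detect_modules(expr)
        assert len(asg.module_sizes) == 2
        assert adjusted_rand_score(truth.values, asg.labels.values) >= 0.9

    def test_shared_latent_modules_merge(self, rng):
        """Two blocks driven by latents with correlation > 0.75 end up in
        one module at merge threshold 0.25."""
        n_s = 12
        latent = rng.normal(size=n_s)
        latent2 = 0.95 * latent + np.sqrt(1 - 0.95**2) * rng.normal(size=n_s)
        latent2 = (latent2 - latent2.mean()) / latent2.std()
        lat = (latent - latent.mean()) / latent.std()
        rows = []
        for _ in range(40):
            rows.append(0.9 * lat + np.sqrt(1 - 0.81) * rng.normal(size=n_s))
        for _ in range(40):
            rows.append(0.9 * latent2 + np.sqrt(1 - 0.81) * rng.normal(size=n_s))
        values = pd.DataFrame(rows, index=[f"g{i}" for i in range(80)],
                              columns=[f"s{i}" for i in range(n_s)])
        asg = mk.detect_modules(values)
        assert len(asg.module_sizes) == 1
        assert asg.module_sizes.iloc[0] >= 75

    def test_pure_noise_mostly_unassigned(self):
        fracs = []
        for seed in range(20):
            u = mk.simulate_universe(mk.UniverseSpec(n_genes=100, seed=seed))
            expr, _ = mk.simulate_modules(
                u, mk.ModuleSpec(module_sizes=[], n_samples=12, seed=seed)
            )
            asg = mk.detect_modules(expr)
            fracs.append(float((asg.labels == UNASSIGNED).mean()))
        assert np.mean(fracs) >= 0.95

    def test_fewer_genes_than_min_size_all_unassigned(self):
        values = pd.DataFrame(
            np.random.default_rng(1).normal(size=(10, 8)),
            index=[f"g{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="unassigned"):
            asg = mk.detect_modules(values)
        assert (asg.labels == UNASSIGNED).all()

    def test_sample_permutation_leaves_partition(self):
        u = mk.simulate_universe(mk.UniverseSpec(n_genes=110, seed=6))
        expr, _ = mk.simulate_modules(
            u, mk.ModuleSpec(module_sizes=[60, 50], eigengene_loading=0.8, n_samples=12, seed=6)
        )
        asg1 = mk.detect_modules(expr)
        shuffled = expr.values[list(np.random.default_rng(0).permutation(expr.values.columns))]
        asg2 = mk.detect_modules(shuffled)
        assert (asg1.labels == asg2.labels).all()

    def test_eigengenes_unit_norm(self):
        u = mk.simulate_universe(mk.UniverseSpec(n_genes=110, seed=7))
        expr, _ = mk.simulate_modules(
            u, mk.ModuleSpec(module_sizes=[60, 50], eigengene_loading=0.8, n_samples=12, seed=7)
        )
        asg = mk.detect_modules(expr)
        for col in asg.eigengenes:
            assert np.linalg.norm(asg.eigengenes[col]) == pytest.approx(1.0)


class TestTfSubnetwork:
    def _module_fixture(self, rng, hub_loading=0.7):
        n_s = 12
        latent = rng.normal(size=n_s)
        latent = (latent - latent.mean()) / latent.std()
        names = ["TF_HUB"] + [f"g{i}" for i in range(39)]
        loadings = [hub_loading] + [0.7] * 39
        rows = [
            l * latent + np.sqrt(1 - l**2) * rng.normal(size=n_s) for l in loadings
        ]
        values = pd.DataFrame(rows, index=names, columns=[f"s{i}" for i in range(n_s)])
        asg = mk.detect_modules(values, CoexpressionConfig(min_module_size=10))
        return values, asg

    def test_tf_disjoint_from_modules_gives_empty(self, rng):
        values, asg = self._module_fixture(rng)
        with pytest.warns(UserWarning, match="no transcription factor"):
            edges = mk.tf_subnetwork(values, asg, ["ABSENT_TF"])
        assert edges.empty

    def test_single_tf_module_edge_count(self):
        # module of 3 genes, 1 TF -> exactly the 2 TF-gene pairs
        values = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6]] * 3 + [[0, 0, 0, 0, 0, 0]],
            index=["TF1", "A", "B", "C"],
            columns=[f"s{i}" for i in range(6)],
        ).astype(float)
        values.iloc[0] += np.random.default_rng(0).normal(0, 0.01, 6)
        values.iloc[1] += np.random.default_rng(1).normal(0, 0.01, 6)
        values.iloc[2] += np.random.default_rng(2).normal(0, 0.01, 6)
        labels = pd.Series(["M1", "M1", "M1", "unassigned"], index=values.index)
        asg = mk.ModuleAssignment(
            labels, pd.DataFrame(), 6, pd.DataFrame()
        )
        edges = mk.tf_subnetwork(values, asg, ["TF1"])
        assert edges.shape[0] == 2
        assert set(edges.source) | set(edges.target) == {"TF1", "A", "B"}

    def test_hub_tf_has_highest_mean_weight(self, rng):
        values, asg = self._module_fixture(rng, hub_loading=0.95)
        edges = mk.tf_subnetwork(values, asg, ["TF_HUB", "g0", "g1"])
        mean_w = {}
        for tf in ["TF_HUB", "g0", "g1"]:
            mask = (edges.source == tf) | (edges.target == tf)
            mean_w[tf] = edges.loc[mask, "abs_weight"].mean()
        assert mean_w["TF_HUB"] == max(mean_w.values())

    def test_no_self_edges_and_weight_bounds(self, rng):
        values, asg = self._module_fixture(rng)
        edges = mk.tf_subnetwork(values, asg, ["TF_HUB"])
        assert (edges.source != edges.target).all()
        assert (edges.abs_weight <= 1.0).all()
        assert (edges.tf_source | edges.tf_target).all()
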