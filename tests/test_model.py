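import numpy as np
import pandas as pd
import pytest

from tdaracne.fixtures import make_chain_network
from tdaracne.model import InferenceParams, TDAracne, infer_network
from tdaracne.simulate import SimulationParams, generate_random_network, simulate_expression

from conftest import FAST_FIT


class TestTDAracneFit:
    def test_chain_edges_recovered_and_indirect_pruned(self):
        matrix, truth, _ = make_chain_network(3, sigma2=0.01, n_timepoints=50, seed=1)
        res = TDAracne(matrix, **FAST_FIT).fit(seed=1)
        edges = set(res.network.edges())
        assert ("G1", "G2") in edges
        assert ("G2", "G3") in edges
        assert ("G1", "G3") not in edges  # indirect, DPI-pruned

    def test_deterministic_under_fixed_seed(self, small_matrix):
        matrix, _ = small_matrix
        a = TDAracne(matrix, **FAST_FIT).fit(seed=11)
        b = TDAracne(matrix, **FAST_FIT).fit(seed=11)
        assert sorted(a.network.edges(data=True)) == sorted(b.network.edges(data=True))
        assert a.threshold.i0 == b.threshold.i0

    def test_every_edge_weight_exceeds_threshold(self, small_matrix):
        matrix, _ = small_matrix
        res = TDAracne(matrix, **FAST_FIT).fit(seed=2)
        for _, _, data in res.network.edges(data=True):
            assert data["weight"] > res.threshold.i0
            assert 1 <= data["delay"] <= res.params.max_delay

    def test_row_order_invariance(self, small_matrix):
        matrix, _ = small_matrix
        shuffled = matrix.iloc[::-1]
        a = TDAracne(matrix, **FAST_FIT).fit(seed=5)
        b = TDAracne(shuffled, **FAST_FIT).fit(seed=5)
        assert set(a.network.edges()) == set(b.network.edges())

    def test_white_noise_genes_give_near_empty_network(self):
        r = np.random.default_rng(0)
        matrix = pd.DataFrame(r.random((8, 40)), index=[f"N{i}" for i in range(8)])
        res = TDAracne(matrix, **FAST_FIT).fit(seed=1)
        # 56 ordered pairs at a ~5% null rate: a handful of edges at most
        assert res.network.number_of_edges() <= 6

    def test_accepts_11x16_matrix_shape(self):
        # the shape of a small real cell-cycle subset must run end to end
        p = SimulationParams(11, 16, 0.02, seed=21)
        gen = np.random.default_rng(21)
        s = generate_random_network(p, rng=gen)
        matrix = simulate_expression(s, p, rng=gen)
        assert matrix.shape == (11, 16)
        res = TDAracne(matrix, **FAST_FIT).fit(seed=3)
        assert res.network.number_of_nodes() == 11

    def test_all_constant_matrix_gives_empty_network(self):
        matrix = pd.DataFrame(np.ones((4, 12)), index=list("ABCD"))
        res = TDAracne(matrix, **FAST_FIT).fit(seed=0)
        assert res.network.number_of_edges() == 0
        assert set(res.network.nodes()) == set("ABCD")

    def test_no_threshold_mode_skips_bootstrap(self, small_matrix):
        matrix, _ = small_matrix
        res = TDAracne(matrix, no_threshold=True).fit(seed=1)
        assert res.threshold is None
        assert res.network.number_of_edges() >= 1

    def test_influence_table_covers_admissible_pairs(self, small_matrix):
        matrix, _ = small_matrix
        res = TDAracne(matrix, **FAST_FIT).fit(seed=4)
        assert len(res.influence_table) == res.stage_counts["admissible_pairs"]
        assert (res.influence_table["influence"] >= 0).all()
        per_delay_cols = [c for c in res.influence_table.columns if c.startswith("mi_k")]
        best = res.influence_table[per_delay_cols].max(axis=1)
        assert np.allclose(best, res.influence_table["influence"])

    def test_invalid_data_rejected(self):
        with pytest.raises(ValueError):
            TDAracne(pd.DataFrame([[1.0]], index=["A"]))
        bad = pd.DataFrame(np.ones((2, 5)), index=["A", "A"])
        with pytest.raises(ValueError):
            TDAracne(bad)
        nan = pd.DataFrame(np.full((2, 5), np.nan), index=["A", "B"])
        with pytest.raises(ValueError):
            TDAracne(nan)

    def test_functional_wrapper_returns_digraph(self, small_matrix):
        matrix, _ = small_matrix
        g = infer_network(matrix, seed=1, **FAST_FIT)
        assert all("weight" in d for _, _, d in g.edges(data=True))


class TestResultsSurface:
    def test_summary_mentions_threshold_and_edges(self, small_matrix):
        matrix, _ = small_matrix
        res = TDAracne(matrix, **FAST_FIT).fit(seed=6)
        text = res.summary()
        assert "Threshold I0" in text
        assert "admissible" in text

    def test_save_writes_network_files(self, small_matrix, tmp_path):
        matrix, _ = small_matrix
        res = TDAracne(matrix, **FAST_FIT).fit(seed=6)
        res.save(tmp_path / "net")
        assert (tmp_path / "net.edges.tsv").exists()
        assert (tmp_path / "net.sif").exists()
        assert (tmp_path / "net.dot").exists()
        assert (tmp_path / "net.threshold.json").exists()

    def test_plot_returns_axes(self, small_matrix):
        import matplotlib

        matplotlib.use("Agg")
        matrix, _ = small_matrix
        res = TDAracne(matrix, **FAST_FIT).fit(seed=6)
        ax = res.plot()
        assert ax is not None


class TestInferenceParams:
    def test_defaults_match_documented_protocol(self):
        p = InferenceParams()
        assert p.tau_up == 1.2
        assert p.max_delay == 3
        assert p.n_boot == 500
        assert p.grid_size == 100
        assert p.dpi_tolerance == 0.15

    def test_overrides_via_model_kwargs(self, small_matrix):
        matrix, _ = small_matrix
        model = TDAracne(matrix, max_delay=2, dpi_tolerance=0.2)
        assert model.params.max_delay == 2
        assert model.params.dpi_tolerance == 0.2
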