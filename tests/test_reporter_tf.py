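"""Reporter-TF scoring: hand oracles, null calibration, planted recovery."""

import numpy as np
import pandas as pd
import pytest

from acidflux.de_stats import Contrast, DEGCall, call_degs, fit_contrast
from acidflux.io_formats import CountMatrix, DETable, NetworkEdgeList
from acidflux.reporter_tf import (
    abundance_filter,
    clean_network,
    direction_profile,
    gene_significance,
    reporter_analysis,
    reporter_z,
    sampling_null,
)
from acidflux.synthetic_data import SimConfig, simulate_counts, simulate_network


def edge_list(*rows):
    return NetworkEdgeList(tuple(rows))


FIVE_GENE_SIG = {f"g{i}": float(i) for i in range(5)}  # mean 2, pop sd sqrt(2)
FIVE_GENE_BG = tuple(f"g{i}" for i in range(5))


class TestCleanNetwork:
    def test_exact_duplicates_collapse(self):
        net = clean_network(
            edge_list(("A", "g1", "activation"), ("A", "g1", "activation"))
        )
        assert net.edges == (("A", "g1", "activation"),)
        assert net.n_redundant_removed == 1

    def test_activation_plus_repression_is_ambiguous_and_dropped(self):
        net = clean_network(
            edge_list(("A", "g1", "activation"), ("A", "g1", "repression"))
        )
        assert net.edges == ()
        assert net.n_ambiguous_removed == 1

    def test_dual_row_wins_over_conflicting_rows(self):
        net = clean_network(
            edge_list(("A", "g1", "dual"), ("A", "g1", "activation"))
        )
        assert net.edges == (("A", "g1", "dual"),)

    def test_self_loops_retained(self):
        net = clean_network(edge_list(("A", "A", "repression")))
        assert net.edges == (("A", "A", "repression"),)


class TestAbundanceFilter:
    def _counts(self, cpms):
        # single sample of depth 1e6 so counts == CPM
        arr = np.array([[int(c)] for c in cpms])
        pad = int(1e6 - arr.sum())
        arr = np.vstack([arr, [[pad]]])
        ids = tuple(f"g{i}" for i in range(len(cpms))) + ("filler",)
        return CountMatrix(ids, ("s1",), arr)

    def test_low_abundance_excluded_boundary_retained(self):
        counts = self._counts([0, 1, 50])
        bg = abundance_filter(counts)  # g0 has CPM 0 (<1), g1 exactly 1
        assert "g0" not in bg and "g1" in bg and "g2" in bg

    def test_background_restricted_to_tested_genes(self):
        counts = self._counts([10, 10])
        table = DETable(
            pd.DataFrame(
                {
                    "gene_id": ["g0"],
                    "log2fc": [0.0],
                    "p": [0.5],
                    "p_adj": [0.5],
                    "mean_cpm": [10.0],
                }
            )
        )
        bg = abundance_filter(counts, table)
        assert "g0" in bg and "g1" not in bg


class TestReporterZ:
    def test_hand_worked_example(self):
        net = clean_network(
            edge_list(("TF", "g3", "activation"), ("TF", "g4", "activation"))
        )
        results = reporter_z(net, FIVE_GENE_SIG, FIVE_GENE_BG, min_targets=2)
        r = results[0]
        assert r.mu_bg == pytest.approx(2.0)
        assert r.sigma_bg == pytest.approx(np.sqrt(2.0))
        assert r.z == pytest.approx(1.0607, abs=1e-4)

    def test_target_mean_equal_background_gives_zero(self):
        net = clean_network(
            edge_list(("TF", "g0", "activation"), ("TF", "g4", "activation"))
        )
        r = reporter_z(net, FIVE_GENE_SIG, FIVE_GENE_BG, min_targets=2)[0]
        assert r.z == pytest.approx(0.0, abs=1e-12)

    def test_too_few_targets_reported_unscored(self):
        net = clean_network(edge_list(("TF", "g3", "activation")))
        r = reporter_z(net, FIVE_GENE_SIG, FIVE_GENE_BG, min_targets=3)[0]
        assert r.z is None and "surviving targets" in r.skipped_reason

    def test_degenerate_background_rejected(self):
        net = clean_network(edge_list(("TF", "g0", "activation")))
        flat = {g: 1.0 for g in FIVE_GENE_BG}
        with pytest.raises(ValueError, match="degenerate"):
            reporter_z(net, flat, FIVE_GENE_BG)

    def test_global_background_includes_own_targets(self, rng):
        sig = {f"g{i}": float(rng.exponential(1.0)) for i in range(50)}
        bg = tuple(sig)
        net = clean_network(
            edge_list(*[("TF", f"g{i}", "activation") for i in range(5)])
        )
        r = reporter_z(net, sig, bg, min_targets=3)[0]
        s = np.array(list(sig.values()))
        assert r.mu_bg == pytest.approx(s.mean())
        assert r.sigma_bg == pytest.approx(s.std())
        r_lo = reporter_z(net, sig, bg, min_targets=3, leave_out_background=True)[0]
        rest = np.array([sig[f"g{i}"] for i in range(5, 50)])
        assert r_lo.mu_bg == pytest.approx(rest.mean())

    def test_invariant_to_gene_relabelling_and_background_order(self, rng):
        sig = {f"g{i}": float(rng.exponential(1.0)) for i in range(30)}
        bg = tuple(sig)
        net = clean_network(
            edge_list(*[("TF", f"g{i}", "activation") for i in range(4)])
        )
        z1 = reporter_z(net, sig, bg)[0].z
        shuffled_bg = tuple(np.array(bg)[np.random.default_rng(1).permutation(30)])
        z2 = reporter_z(net, sig, shuffled_bg)[0].z
        assert z1 == pytest.approx(z2, rel=1e-12)
        renamed_sig = {f"x_{k}": v for k, v in sig.items()}
        renamed_net = clean_network(
            edge_list(*[("TF", f"x_g{i}", "activation") for i in range(4)])
        )
        z3 = reporter_z(renamed_net, renamed_sig, tuple(renamed_sig))[0].z
        assert z1 == pytest.approx(z3, rel=1e-12)

    def test_null_z_sd_scales_as_inverse_sqrt_k(self, rng):
        # for random size-k sets the Z formula implies mean 0, sd ~ 1/sqrt(k)
        sig = {f"g{i}": float(rng.exponential(1.0)) for i in range(1000)}
        s = np.array(list(sig.values()))
        mu_bg, sigma_bg = s.mean(), s.std()
        for k in (5, 10, 20):
            idx = np.argsort(rng.random((10000, 1000)), axis=1)[:, :k]
            z = (s[idx].mean(axis=1) - mu_bg) / sigma_bg
            assert abs(z.mean()) < 0.02
            assert z.std() == pytest.approx(1 / np.sqrt(k), rel=0.15)


class TestSamplingNull:
    def test_maximal_target_mean_attains_minimum_p(self, rng):
        sig = {f"g{i}": float(i) for i in range(100)}
        bg = tuple(sig)
        top_mean = np.mean([99.0, 98.0, 97.0])
        p = sampling_null(3, top_mean, sig, bg, n_draws=2000, seed=1)
        assert p == pytest.approx(1 / 2001, abs=2e-3)

    def test_background_mean_target_sits_near_half(self, rng):
        # symmetric significance distribution -> p ~ 0.5 at mu_target = mu_bg
        sig = {f"g{i}": float(v) for i, v in enumerate(rng.normal(5, 1, 500))}
        bg = tuple(sig)
        mu_bg = np.mean(list(sig.values()))
        p = sampling_null(10, mu_bg, sig, bg, n_draws=5000, seed=2)
        assert p == pytest.approx(0.5, abs=0.05)

    def test_fixed_seed_is_reproducible(self):
        sig = {f"g{i}": float(i % 7) for i in range(50)}
        bg = tuple(sig)
        a = sampling_null(5, 4.0, sig, bg, n_draws=1000, seed=9)
        b = sampling_null(5, 4.0, sig, bg, n_draws=1000, seed=9)
        assert a == b

    def test_oversized_k_rejected(self):
        sig = {"g0": 1.0, "g1": 2.0}
        with pytest.raises(ValueError, match="exceeds background"):
            sampling_null(3, 1.0, sig, tuple(sig), n_draws=1000)


class TestDirectionProfile:
    def test_fractions(self):
        net = clean_network(
            edge_list(*[("TF", f"g{i}", "activation") for i in range(4)])
        )
        calls = [
            DEGCall("g0", "up"),
            DEGCall("g1", "up"),
            DEGCall("g2", "down"),
            DEGCall("g3", "ns"),
        ]
        assert direction_profile("TF", net, calls) == (0.5, 0.25, 0.25)

    def test_no_surviving_targets_is_missing(self):
        net = clean_network(edge_list(("TF", "gX", "activation")))
        assert direction_profile("TF", net, [DEGCall("g0", "ns")]) is None

    def test_all_ns(self):
        net = clean_network(
            edge_list(("TF", "g0", "dual"), ("TF", "g1", "repression"))
        )
        calls = [DEGCall("g0", "ns"), DEGCall("g1", "ns")]
        assert direction_profile("TF", net, calls) == (0.0, 0.0, 1.0)


class TestPlantedRecovery:
    def test_planted_tf_ranks_top_in_most_seeds(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_genes=800,
                regimes={"acute": (1.0,)},
                de_fraction=0.1,
                lfc_range=(2.0, 4.0),
                seed=seed,
            )
            counts, design, truth = simulate_counts(cfg)
            network, truth = simulate_network(cfg, truth)
            table = fit_contrast(
                counts, design, Contrast.from_design(design, "acute", 1.0)
            )
            bg = abundance_filter(counts, table)
            sig = gene_significance(table)
            results = reporter_z(clean_network(network), sig, bg)
            scored = [r for r in results if r.z is not None]
            best = max(scored, key=lambda r: r.z)
            hits += best.tf_id == "TF_planted_1"
        assert hits >= round(0.9 * n_seeds)

    def test_full_reporter_analysis_flags_planted_tf(self, small_dataset):
        cfg, counts, design, truth, network = small_dataset
        table = fit_contrast(
            counts, design, Contrast.from_design(design, "acute", 1.0)
        )
        results = reporter_analysis(
            network, table, counts, n_draws=2000, seed=0
        )
        planted = next(r for r in results if r.tf_id == "TF_planted_1")
        assert planted.z is not None and planted.p_adj is not None
        assert planted.p_adj < 0.05
        assert planted.up_frac is not None
        assert planted.up_frac + planted.down_frac + planted.ns_frac == pytest.approx(1.0)

    def test_decoy_sampling_p_uniform_under_null(self):
        from scipy import stats as sps

        cfg = SimConfig(
            n_genes=600,
            regimes={"acute": (1.0,)},
            de_fraction=0.0,
            n_planted_tfs=0,
            n_decoy_tfs=40,
            seed=21,
        )
        counts, design, truth = simulate_counts(cfg)
        network, truth = simulate_network(cfg, truth)
        table = fit_contrast(
            counts, design, Contrast.from_design(design, "acute", 1.0)
        )
        results = reporter_analysis(network, table, counts, n_draws=2000, seed=3)
        p = [r.p_sampling for r in results if r.p_sampling is not None]
        assert len(p) >= 30
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01
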