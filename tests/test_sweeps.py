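"""Sweep characterization: core picking, partitioning, pi, delta-pi,
profiles, length calling and hard/soft classification."""

import warnings

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_panel
from sweepscan.panel import GeneticMap
from sweepscan.simulate import SimulationConfig, SweepSpec, simulate_panel
from sweepscan.sweeps import (classify_sweep, delta_pi, delta_pi_background,
                              delta_pi_profile, partition_haplotypes,
                              pi_window, pick_core_snp, sweep_length)


def _region(fst, xpehh, positions=None):
    n = len(fst)
    return pd.DataFrame({"position": positions or list(range(0, 30 * n, 30)),
                         "fst_wc": fst, "xpehh_norm": xpehh})


class TestPickCoreSnp:
    def test_highest_fst_wins(self):
        core = pick_core_snp(_region([0.9, 0.8], [1.0, 5.0]))
        assert core["position"] == 0

    def test_fst_tie_broken_by_xpehh(self):
        core = pick_core_snp(_region([0.9, 0.9], [3.0, 5.0]))
        assert core["position"] == 30

    def test_full_tie_leftmost(self):
        core = pick_core_snp(_region([0.9, 0.9], [5.0, 5.0]))
        assert core["position"] == 0

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="no SNP"):
            pick_core_snp(_region([np.nan], [np.nan]))


class TestPartition:
    def test_counts_as_specified(self):
        # focal: 18 of 20 carry allele 1; background: 40 haplotypes
        col = np.r_[np.ones(18), np.zeros(2), np.zeros(40)].astype(np.int8)
        alleles = np.tile(col[:, None], (1, 3))
        # 60 haplotypes over 3 pops of 20
        panel = make_panel(alleles, pops=("f", "b", "b2"))
        sel, unsel = partition_haplotypes(panel, 30, "f", ("b", "b2"))
        assert len(sel) == 18
        assert len(unsel) == 2 + 40

    def test_fixed_focal_all_selected(self):
        col = np.r_[np.ones(20), np.zeros(40)].astype(np.int8)
        panel = make_panel(np.tile(col[:, None], (1, 2)), pops=("f", "b", "b2"))
        sel, unsel = partition_haplotypes(panel, 0, "f", ("b", "b2"))
        assert len(sel) == 20 and len(unsel) == 40

    def test_minor_allele_when_major_is_zero(self):
        col = np.r_[np.ones(3), np.zeros(17), np.ones(40)].astype(np.int8)
        panel = make_panel(np.tile(col[:, None], (1, 2)), pops=("f", "b", "b2"))
        sel, _ = partition_haplotypes(panel, 0, "f", ("b", "b2"))
        assert len(sel) == 17   # focal-major allele is 0

    def test_exact_half_errors(self):
        col = np.r_[np.ones(10), np.zeros(10), np.zeros(40)].astype(np.int8)
        panel = make_panel(np.tile(col[:, None], (1, 2)), pops=("f", "b", "b2"))
        with pytest.raises(ValueError, match="0.5"):
            partition_haplotypes(panel, 0, "f", ("b", "b2"))

    def test_matches_simulation_truth(self, sweep_sim):
        panel, _, truth, cfg = sweep_sim
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal",
                                          ("background", "outgroup"))
        j = np.searchsorted(panel.positions, core)
        f_idx = panel.haplotype_indices("focal")
        carriers = f_idx[panel.alleles[f_idx, j] == 1]
        np.testing.assert_array_equal(np.sort(sel), np.sort(carriers))
        assert len(sel) == round(0.95 * 20)


class TestPi:
    def test_identical_haplotypes_zero(self):
        assert pi_window(np.zeros((4, 10))) == 0.0

    def test_single_pair_counts_differences(self):
        H = np.zeros((2, 10), dtype=np.int8)
        H[1, [2, 5, 7]] = 1
        assert pi_window(H) == 3.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            H = rng.integers(0, 2, (int(rng.integers(2, 12)),
                                    int(rng.integers(1, 20))))
            assert pi_window(H) == pytest.approx(oracles.pi_brute(H))

    def test_single_haplotype_nan(self):
        assert np.isnan(pi_window(np.zeros((1, 5))))


class TestDeltaPi:
    @pytest.mark.parametrize("ps,pu,want", [(0.2, 0.8, -0.75), (0.5, 0.5, 0.0),
                                            (0.9, 0.3, 2.0)])
    def test_formula(self, ps, pu, want):
        assert delta_pi(ps, pu) == pytest.approx(want)

    def test_zero_unselected_nan(self):
        assert np.isnan(delta_pi(0.1, 0.0))

    def test_invariant_to_per_bp_normalization(self):
        # dividing both pi values by the window length cancels exactly
        assert delta_pi(0.2 / 1000, 0.8 / 1000) == pytest.approx(
            delta_pi(0.2, 0.8))


class TestProfileGeometry:
    def test_2000_windows_per_side_genetic_mode(self, sweep_sim):
        panel, gmap, truth, _ = sweep_sim
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal", "background")
        prof = delta_pi_profile(panel, core, sel, unsel, mode="genetic",
                                gmap=gmap)
        assert prof["k"].tolist() == list(range(2001))
        assert prof["distance"].iloc[-1] == pytest.approx(20.0)

    def test_2000_windows_per_side_physical_mode(self, sweep_sim):
        panel, gmap, truth, _ = sweep_sim
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal", "background")
        prof = delta_pi_profile(panel, core, sel, unsel, mode="physical")
        assert len(prof) == 2001
        assert prof["distance"].iloc[-1] == pytest.approx(2_000_000)

    def test_core_window_contains_core_and_is_negative(self, sweep_sim):
        panel, gmap, truth, _ = sweep_sim
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal", "background")
        prof = delta_pi_profile(panel, core, sel, unsel, mode="genetic",
                                gmap=gmap)
        assert prof.loc[0, "delta_pi"] < 0

    def test_folded_profile_averages_both_sides(self):
        """On a mirror-symmetric panel the folded value equals either side."""
        rng = np.random.default_rng(3)
        half = rng.integers(0, 2, (12, 40)).astype(np.int8)
        core_col = rng.integers(0, 2, (12, 1)).astype(np.int8)
        H = np.concatenate([half[:, ::-1], core_col, half], axis=1)
        positions = np.arange(81) * 30
        panel = make_panel(H, positions=positions, pops=("f", "b", "b2"))
        sel = np.arange(4)
        unsel = np.arange(4, 12)
        core = int(positions[40])
        prof = delta_pi_profile(panel, core, sel, unsel,
                                mode="physical", window=90, max_dist=900)
        for kk in range(1, 8):
            d = np.abs(positions.astype(float) - core)
            mask_dn = (positions > core) & (np.rint(d / 90) == kk)
            if not mask_dn.any():
                continue
            idx = np.flatnonzero(mask_dn)
            one_sided = delta_pi(pi_window(H[sel], idx), pi_window(H[unsel], idx))
            assert prof.loc[kk, "delta_pi"] == pytest.approx(one_sided,
                                                             nan_ok=True)


class TestBackgroundAndLength:
    def _profile(self, values, window=0.01):
        return pd.DataFrame({"k": np.arange(len(values)),
                             "distance": np.arange(len(values)) * window,
                             "delta_pi": values})

    def test_constant_profile_background_equals_constant(self):
        prof = self._profile(np.full(1500, 0.37))
        assert delta_pi_background([prof]) == pytest.approx(0.37)

    def test_pooling_two_sweeps_averages_both_tails(self):
        p1 = self._profile(np.full(1200, 1.0))
        p2 = self._profile(np.full(1200, 3.0))
        assert delta_pi_background([p1, p2]) == pytest.approx(2.0)

    def test_short_profile_uses_all_with_warning(self):
        prof = self._profile(np.full(300, 0.5))
        with pytest.warns(UserWarning, match="defined distant windows"):
            assert delta_pi_background([prof]) == pytest.approx(0.5)

    def test_length_midpoint_rule(self):
        prof = self._profile([-0.8, -0.6, -0.1, 0.02, 0.0, 0.01])
        L, k, flagged = sweep_length(prof, 0.0, window=0.01)
        assert (L, k) == (pytest.approx(0.035), 3)
        assert not flagged

    def test_minimal_length_at_first_window(self):
        prof = self._profile([-0.8, 0.1, 0.2])
        L, k, _ = sweep_length(prof, 0.0, window=0.01)
        assert L == pytest.approx(0.015)

    def test_degenerate_recovery_at_core_flagged(self):
        prof = self._profile([0.5, 0.6, 0.7])
        L, k, flagged = sweep_length(prof, 0.0, window=0.01)
        assert L == pytest.approx(0.005)
        assert flagged

    def test_never_recovering_profile_flagged_at_scan_range(self):
        prof = self._profile(np.full(10, -0.9))
        L, k, flagged = sweep_length(prof, 0.0, window=0.01)
        assert flagged and L == pytest.approx(0.095)


class TestClassification:
    def test_hard_sweep_freq_one(self):
        cfg = SimulationConfig(
            seed=3, chrom_length=100_000,
            sweeps=[SweepSpec(core_position=50_000, selected_freq_focal=1.0,
                              founder_haplotypes=1)])
        panel, gmap, truth = simulate_panel(cfg)
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal", "background")
        kind, dp = classify_sweep(panel, core, sel, unsel, gmap)
        assert kind == "hard"
        assert dp == pytest.approx(-100.0)

    def test_soft_sweep_k3(self):
        cfg = SimulationConfig(
            seed=4, chrom_length=100_000,
            sweeps=[SweepSpec(core_position=50_000, selected_freq_focal=0.95,
                              founder_haplotypes=3)])
        panel, gmap, truth = simulate_panel(cfg)
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal", "background")
        kind, dp = classify_sweep(panel, core, sel, unsel, gmap)
        assert kind == "soft"
        assert dp < 0

    def test_strong_sweep_core_deficit_below_minus_50(self, sweep_sim):
        panel, gmap, truth, _ = sweep_sim
        core = truth[0].core_position
        sel, unsel = partition_haplotypes(panel, core, "focal", "background")
        _, dp = classify_sweep(panel, core, sel, unsel, gmap)
        assert dp <= -50.0


def test_called_length_tracks_planted_footprint(sweep_sim):
    panel, gmap, truth, _ = sweep_sim
    core = truth[0].core_position
    sel, unsel = partition_haplotypes(panel, core, "focal", "background")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        prof = delta_pi_profile(panel, core, sel, unsel, mode="genetic",
                                gmap=gmap)
        dpb = delta_pi_background([prof])
    L, _, flagged = sweep_length(prof, dpb, window=0.01)
    assert not flagged
    assert 0.25 * truth[0].footprint_cm <= L <= 4 * truth[0].footprint_cm
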