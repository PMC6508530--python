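import numpy as np
import pytest

from nucleoshift.array_io import NUCLEOSOMAL, REFERENCE
import nucleoshift.synthetic_data as sim


class TestSimulateLayout:
    @pytest.mark.parametrize(
        "n_windows,span,plen,step,expected",
        [(1, 3000, 50, 50, 60), (400, 3000, 50, 50, 24000), (1, 600, 50, 100, 6)],
    )
    def test_probe_counts(self, n_windows, span, plen, step, expected):
        layout = sim.simulate_layout(n_windows, span, plen, step)
        assert layout.n_probes == expected
        assert len(layout.windows) == n_windows

    def test_same_seed_identical(self):
        a = sim.simulate_layout(5, seed=3)
        b = sim.simulate_layout(5, seed=3)
        assert a.windows == b.windows and a.probes == b.probes

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_layout(0)
        with pytest.raises(ValueError):
            sim.simulate_layout(1, span=40, probe_length=50)


class TestOccupancy:
    def test_no_nucleosomes_is_zero(self):
        layout = sim.simulate_layout(1, span=600)
        truth = sim.make_truth(layout, seed=0)
        truth.nucleosomes["WT"] = {"win0000": []}
        occ = sim.simulate_occupancy(layout, truth, "WT")
        assert np.all(occ["win0000"] == 0.0)

    def test_unit_height_peak_is_one_at_center(self):
        layout = sim.simulate_layout(1, span=600)
        truth = sim.make_truth(layout, seed=0)
        w = layout.windows[0]
        center = float(w.start + 300)
        truth.nucleosomes["WT"] = {"win0000": [(center, 30.0, 1.0)]}
        occ = sim.simulate_occupancy(layout, truth, "WT")
        assert occ["win0000"][int(center - w.start)] == pytest.approx(1.0)

    def test_overlapping_nucleosomes_sum_then_clamp(self):
        layout = sim.simulate_layout(1, span=600)
        truth = sim.make_truth(layout, seed=0)
        w = layout.windows[0]
        c1, c2 = float(w.start + 280), float(w.start + 320)
        truth.nucleosomes["WT"] = {"win0000": [(c1, 30.0, 0.4), (c2, 30.0, 0.4)]}
        occ = sim.simulate_occupancy(layout, truth, "WT")
        x = w.start + 300
        expected = 0.4 * np.exp(-(20.0**2) / 1800.0) * 2
        assert occ["win0000"][x - w.start] == pytest.approx(expected)
        # taller pair exceeds 1 and is clamped
        truth.nucleosomes["WT"] = {"win0000": [(c1, 30.0, 0.9), (c2, 30.0, 0.9)]}
        occ = sim.simulate_occupancy(layout, truth, "WT")
        assert occ["win0000"].max() == 1.0

    def test_unknown_genotype_rejected(self):
        layout = sim.simulate_layout(1, span=600)
        truth = sim.make_truth(layout, seed=0)
        with pytest.raises(KeyError):
            sim.simulate_occupancy(layout, truth, "nope")


class TestSimulateSignals:
    def test_zero_noise_no_changes_genotypes_identical(self):
        layout = sim.simulate_layout(4, seed=1)
        truth = sim.make_truth(layout, n_changes=0, noise_sd=0.0, seed=1)
        wt = sim.simulate_signals(layout, truth, "WT")
        mut = sim.simulate_signals(layout, truth, "mut")
        for a, b in zip(wt, mut):
            np.testing.assert_array_equal(a.values, b.values)

    def test_full_determinism_under_seed(self):
        layout = sim.simulate_layout(3, seed=2)
        truth = sim.make_truth(layout, n_changes=2, n_polymorphic=1,
                               noise_sd=0.3, seed=2)
        truth2 = sim.make_truth(layout, n_changes=2, n_polymorphic=1,
                                noise_sd=0.3, seed=2)
        assert truth.planted_changes == truth2.planted_changes
        a = sim.simulate_signals(layout, truth, "mut")
        b = sim.simulate_signals(layout, truth2, "mut")
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_polymorphism_perturbs_both_channels_inside_interval_only(self):
        layout = sim.simulate_layout(4, seed=3)
        truth = sim.make_truth(layout, n_polymorphic=1, noise_sd=0.0, seed=3)
        (poly,) = truth.planted_polymorphisms
        wt_nuc, wt_ref = sim.simulate_signals(layout, truth, "WT")  # reference haplotype
        m_nuc, m_ref = sim.simulate_signals(layout, truth, "mut")
        dref = m_ref.values[:, 0] - wt_ref.values[:, 0]
        dnuc = m_nuc.values[:, 0] - wt_nuc.values[:, 0]
        inside = np.array(
            [p.start <= poly.end and p.end >= poly.start for p in layout.probes]
        )
        assert np.all(dref[inside] == -poly.effect)
        assert np.all(dref[~inside] == 0.0)
        np.testing.assert_allclose(dnuc[inside], -poly.effect, atol=1e-12)
        assert np.all(dnuc[~inside] == 0.0)

    def test_planted_change_perturbs_only_nucleosomal_channel(self):
        layout = sim.simulate_layout(4, seed=4)
        truth = sim.make_truth(layout, n_changes=1, change_kinds=("loss",),
                               noise_sd=0.0, seed=4)
        wt_nuc, wt_ref = sim.simulate_signals(layout, truth, "WT")
        m_nuc, m_ref = sim.simulate_signals(layout, truth, "mut")
        np.testing.assert_array_equal(wt_ref.values, m_ref.values)
        assert np.any(wt_nuc.values != m_nuc.values)
        (planted,) = truth.planted_changes
        rows = layout.window_probe_rows(planted.window_id)
        diff_rows = np.where((m_nuc.values[:, 0] - wt_nuc.values[:, 0]) != 0)[0]
        assert set(diff_rows) <= set(rows)  # effect confined to the changed window

    def test_planted_loss_effect_matches_closed_form(self):
        """At zero noise the probe-level signal drop equals the model value."""
        layout = sim.simulate_layout(6, seed=5)
        truth = sim.make_truth(layout, n_changes=1, change_kinds=("loss",),
                               delta=1.0, noise_sd=0.0, seed=5)
        (planted,) = truth.planted_changes
        wt_occ = sim.simulate_occupancy(layout, truth, "WT")[planted.window_id]
        m_occ = sim.simulate_occupancy(layout, truth, "mut")[planted.window_id]
        w = layout.window(planted.window_id)
        wt_nuc, _ = sim.simulate_signals(layout, truth, "WT")
        m_nuc, _ = sim.simulate_signals(layout, truth, "mut")
        for r in layout.window_probe_rows(planted.window_id):
            p = layout.probes[r]
            sl = slice(p.start - w.start, p.end - w.start + 1)
            expected = np.log2(m_occ[sl].mean() * truth.dynamic_range + truth.floor) - \
                np.log2(wt_occ[sl].mean() * truth.dynamic_range + truth.floor)
            got = m_nuc.values[r, 0] - wt_nuc.values[r, 0]
            assert got == pytest.approx(expected, abs=1e-12)


class TestShiftAndNOL:
    def test_shift_recorded_as_linked_loss_plus_gain(self):
        layout = sim.simulate_layout(4, seed=6)
        truth = sim.make_truth(layout, n_changes=1, change_kinds=("shift",), seed=6)
        kinds = sorted(c.kind for c in truth.planted_changes)
        assert kinds == ["gain", "loss"]
        groups = {c.shift_group for c in truth.planted_changes}
        assert len(groups) == 1 and None not in groups
        wids = {c.window_id for c in truth.planted_changes}
        assert len(wids) == 1

    def test_nol_equals_favored_occupancy_at_zero_distortion(self):
        layout = sim.simulate_layout(2, seed=7)
        truth = sim.make_truth(layout, n_changes=1, noise_sd=0.0, seed=7)
        nol = sim.simulate_nol(layout, truth, "mut", distortion=0.0)
        occ = sim.simulate_occupancy(layout, truth, "mut")
        w = layout.windows[0]
        mids = np.array([layout.probes[r].midpoint
                         for r in layout.window_probe_rows(w.window_id)])
        got = nol.values_at(w.chrom, mids)
        # sampled every 10 bp; linear-interpolation error on a 30-bp-sd
        # Gaussian is bounded by ~ h * (step/2)^2 / (2 sd^2) ~ 0.015
        expected = np.array([occ[w.window_id][int(m - w.start)] for m in mids])
        np.testing.assert_allclose(got, expected, atol=0.02)

    def test_truth_json_round_trip(self, tmp_path):
        layout = sim.simulate_layout(3, seed=8)
        truth = sim.make_truth(layout, n_changes=2, n_polymorphic=1, seed=8)
        truth.to_json(tmp_path / "truth.json")
        back = sim.SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.planted_changes == truth.planted_changes
        assert back.planted_polymorphisms == truth.planted_polymorphisms
        assert back.nucleosomes == truth.nucleosomes
        assert back.noise_sd == truth.noise_sd
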