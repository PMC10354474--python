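"""Behavioural-regime classification, leadership and sweep tests."""

import numpy as np
import pytest

import burstglide as bg
from burstglide.regimes import RegimeLabel, SWEEP_SETTINGS

from conftest import synthetic_pair_trajectory

LIN = bg.ModelParams.linear_defaults
QUAD = bg.ModelParams.quadratic_defaults
PAIR_IC = (0.0, 0.0, 5.0, 0.0, 0.0, 0.0)


class TestLeadership:
    def test_synthetic_sine_switches_at_every_zero_crossing(self):
        t = np.arange(0, 30, 0.01)
        traj = synthetic_pair_trajectory(t, np.sin(t))
        rec = bg.leadership(traj, smooth=0.0)
        zero_crossings = np.floor(30 / np.pi)
        assert rec.n_switches == pytest.approx(zero_crossings, abs=1)
        assert np.all(np.diff(rec.switch_times) > 0)

    def test_empty_record_below_magnitude(self):
        t = np.arange(0, 30, 0.01)
        traj = synthetic_pair_trajectory(t, 0.01 * np.sin(t))
        rec = bg.leadership(traj, smooth=0.0)
        assert rec.n_switches == 0

    def test_periodic_switching_tenure_is_about_seven_bursts(self, pair_d02):
        """In the periodic regime the roles swap after ~7 bursts of the
        leading fish."""
        rec = bg.leadership(pair_d02)
        assert rec.n_switches >= 4
        interior = rec.bursts_per_tenure[1:-1] if len(rec.bursts_per_tenure) > 2 else rec.bursts_per_tenure
        assert np.median(interior) == pytest.approx(7, abs=1)

    def test_leader_follower_has_no_switches(self, pair_d05):
        rec = bg.leadership(pair_d05)
        assert rec.n_switches <= 1  # at most the initial transient crossing


class TestClassify:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.005, RegimeLabel.CONSTANT_TOGETHER),
            (0.01, RegimeLabel.APERIODIC_SWITCHING),
            (0.02, RegimeLabel.PERIODIC_SWITCHING),
            (0.05, RegimeLabel.LEADER_FOLLOWER),
            (0.07, RegimeLabel.NO_LEADER_TURNTAKING),
        ],
    )
    def test_linear_regime_sequence(self, d, expected):
        """The five behavioural regimes appear at their documented coupling
        strengths (linear drag, c=0.9255)."""
        traj = bg.simulate(PAIR_IC, LIN(c=0.9255), bg.CouplingParams(d=d), SWEEP_SETTINGS)
        assert bg.classify(traj) is expected

    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.0025, RegimeLabel.CONSTANT_TOGETHER),
            (0.0125, RegimeLabel.APERIODIC_SWITCHING),
            (0.1, RegimeLabel.LEADER_FOLLOWER),
            (0.2, RegimeLabel.NO_LEADER_TURNTAKING),
        ],
    )
    def test_quadratic_regime_sequence(self, d, expected):
        traj = bg.simulate(PAIR_IC, QUAD(c=0.7885), bg.CouplingParams(d=d), SWEEP_SETTINGS)
        assert bg.classify(traj) is expected

    def test_invariant_under_fish_relabelling(self):
        p, cp = LIN(c=0.9255), bg.CouplingParams(d=0.02)
        a = bg.simulate(PAIR_IC, p, cp, SWEEP_SETTINGS)
        b = bg.simulate((0, 0, 0, 0, 0, 5.0), p, cp, SWEEP_SETTINGS)
        assert bg.classify(a) is bg.classify(b)

    def test_short_window_unclassified(self):
        traj = bg.simulate(PAIR_IC, LIN(c=0.9255), bg.CouplingParams(d=0.02),
                           bg.SimSettings(t_end=300.0, transient=250.0))
        assert bg.classify(traj) is RegimeLabel.UNCLASSIFIED


class TestRegimeInvariants:
    def test_constant_regime_speed_matches_boosted_equilibrium(self):
        """Below the pair onset both fish cruise at the single-fish
        equilibrium speed for the boosted input c + f(0)."""
        p, cp = LIN(c=0.9255), bg.CouplingParams(d=0.005)
        traj = bg.simulate(PAIR_IC, p, cp, bg.SimSettings(t_end=1000.0, transient=800.0))
        c_eff = p.c + float(bg.response(0.0, cp))
        eqs = bg.find_equilibria(p, effective_c=c_eff)
        stable = [e for e in eqs
                  if bg.jacobian_eigen(p.with_c(c_eff), e)[2].real.max() < 0]
        assert len(stable) == 1
        v_end = traj.states[-1, [1, 4]]
        assert np.allclose(v_end, stable[0].v, atol=1e-3)

    def test_turn_taking_symmetry(self, pair_d07):
        """Leaderless turn-taking: zero mean separation and equal maximum
        speeds of the two fish (within 1%)."""
        sub = pair_d07.post_transient(800.0)
        assert abs(sub.separation().mean()) < 0.5
        v1max, v2max = sub.speed(0).max(), sub.speed(1).max()
        assert v1max == pytest.approx(v2max, rel=0.01)

    def test_leader_follower_displacement_ordering(self, pair_d05):
        """The follower covers no more ground per burst cycle than the
        leader (it would otherwise overtake for good)."""
        sub = pair_d05.post_transient(500.0)
        leader = 0 if sub.separation().mean() > 0 else 1
        disp = [None, None]
        for fish in (0, 1):
            seg = bg.segment_burst_glide(pair_d05, fish=fish, transient=500.0)
            cycles = seg.of_kind("burst")[1:-1]
            glides = seg.of_kind("glide")[1:-1]
            n = min(len(cycles), len(glides))
            disp[fish] = np.median([b.displacement + g.displacement
                                    for b, g in zip(cycles[:n], glides[:n])])
        assert disp[1 - leader] <= disp[leader] * 1.02


class TestSweeps:
    def test_period_vs_c_curve(self):
        df = bg.sweep_period_vs_c(LIN(), [0.9, 0.95, 1.0])
        assert np.isnan(df.loc[df.c == 0.9, "period"]).all()
        t95 = float(df.loc[df.c == 0.95, "period"].iloc[0])
        t100 = float(df.loc[df.c == 1.0, "period"].iloc[0])
        assert t95 > t100 > 0

    def test_degenerate_boundary_scan_is_empty(self):
        scan = bg.regime_boundaries(
            LIN(c=0.9255), bg.CouplingParams(), 0.02, 0.02,
            n_reps=1, settings=bg.SimSettings(t_end=600.0, transient=300.0))
        assert scan.boundaries == []
        assert len(scan.d_grid) == 1


class TestHeatmap:
    SETTINGS = bg.SimSettings(t_end=400.0, transient=200.0, rtol=1e-6, atol=1e-8)

    def test_bit_reproducible_for_fixed_seed(self):
        args = dict(d_grid=[0.02, 0.05], n_reps=2, seed=42, settings=self.SETTINGS)
        h1 = bg.heatmap_bifurcation(LIN(c=0.9255), bg.CouplingParams(), **args)
        h2 = bg.heatmap_bifurcation(LIN(c=0.9255), bg.CouplingParams(), **args)
        assert np.array_equal(h1.counts, h2.counts)
        assert np.array_equal(h1.d_grid, h2.d_grid)

    def test_bin_structure(self):
        h = bg.heatmap_bifurcation(LIN(c=0.9255), bg.CouplingParams(),
                                   d_grid=[0.05], n_reps=1, seed=1, settings=self.SETTINGS)
        assert h.counts.shape == (701, 1)
        assert h.bin_edges[0] == pytest.approx(-35.05)
        assert h.bin_edges[-1] == pytest.approx(35.05)
        assert np.allclose(np.diff(h.bin_edges), 0.1)

    def test_subcritical_symmetric_start_mass_at_zero(self):
        """With x1start=0 and d below onset the pair never separates: all
        extrema sit in the central bin (here: none are found at all)."""
        h = bg.heatmap_bifurcation(LIN(c=0.9255), bg.CouplingParams(),
                                   d_grid=[0.002], seed=0, x1_starts=[0.0],
                                   settings=self.SETTINGS)
        off_center = np.delete(h.counts[:, 0], 350)
        assert off_center.sum() == 0 and h.overflow.sum() == 0
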