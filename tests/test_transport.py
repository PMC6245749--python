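import math

import numpy as np
import pytest

import aerotree as at
from aerotree.airway_model import AirwaySegment, Lobe, Region
from aerotree.transport import (
    LOBAR_FRACTIONS, MechanismParams, ParticleEnsemble, ParticleSpec,
)


@pytest.fixture(scope="module")
def age5_dpi(trees, dpi_profiles):
    tree = trees[5]
    profile = dpi_profiles[5]
    ff = at.distribute_flow(tree, profile=profile)
    return tree, at.maneuver_defaults(5, at.Device.DPI), profile, ff


class TestDistributeFlow:
    def test_lobar_sums_and_conservation(self, age5_dpi):
        tree, _, _, ff = age5_dpi
        assert sum(ff.lobar_fractions.values()) == pytest.approx(1.0)
        assert ff.fractions[tree.trachea.id] == pytest.approx(1.0)
        # junction conservation at every interior segment
        for seg in tree.segments.values():
            if seg.child_ids:
                child_sum = sum(ff.fractions[c] for c in seg.child_ids)
                assert child_sum == pytest.approx(ff.fractions[seg.id])
        # per-lobe outlet fractions recompose the stated lobar splits
        for lobe, frac in LOBAR_FRACTIONS.items():
            total = sum(ff.fractions[s.id] for s in tree.outlets
                        if s.lobe is lobe)
            assert total == pytest.approx(frac)

    def test_rm_outlets_split_evenly(self, age5_dpi):
        tree, _, _, ff = age5_dpi
        rm = [s for s in tree.outlets if s.lobe is Lobe.RM]
        assert len(rm) == 6
        for s in rm:
            assert ff.fractions[s.id] == pytest.approx(0.07 / 6)

    def test_bad_fractions_rejected(self, trees):
        bad = dict(LOBAR_FRACTIONS)
        bad[Lobe.RU] += 0.01
        with pytest.raises(ValueError, match="sum to 1"):
            at.distribute_flow(trees[5], lobar_fractions=bad)


class TestMouthThroatFilter:
    def test_limits_and_midpoint(self):
        assert at.mouth_throat_efficiency(0.0) == 0.0
        assert at.mouth_throat_efficiency(0.075) == pytest.approx(0.5)
        assert at.mouth_throat_efficiency(10.0) > 0.999

    def test_calibration_point(self):
        """Default sigmoid reaches ~93% capture at Stk = 0.1."""
        assert at.mouth_throat_efficiency(0.1) == pytest.approx(0.93, abs=0.005)

    def test_monotone(self):
        stk = np.linspace(0.0, 0.5, 200)
        eta = at.mouth_throat_efficiency(stk)
        assert np.all(np.diff(eta) >= 0.0)


class TestSegmentClosures:
    def _segment(self, **kw):
        defaults = dict(id=99, region=Region.CONDUCTING, level=2, parent_id=1,
                        child_ids=(), length=0.02, diameter=0.01,
                        branching_angle=0.611, gravity_angle=0.0)
        return AirwaySegment(**{**defaults, **kw})

    def test_impaction_zero_for_straight_entry(self):
        seg = self._segment(branching_angle=0.0)
        p = at.impaction_probability(seg, 5.0, ParticleSpec(dp=10e-6))
        assert p == 0.0

    def test_impaction_value(self):
        """k=6, theta=0.611, Stk_seg=0.18 -> 1 - exp(-0.660) = 0.483."""
        params = MechanismParams()
        particle = ParticleSpec(dp=10e-6)
        seg = self._segment()
        cc = at.slip_correction(particle.dp)
        u = 0.18 * 18 * params.mu_air * seg.diameter / (
            particle.rho_p * particle.dp ** 2 * cc)
        p = at.impaction_probability(seg, u, particle, params)
        assert p == pytest.approx(1.0 - math.exp(-6 * 0.611 * 0.18), rel=1e-9)
        assert p == pytest.approx(0.483, abs=1e-3)

    def test_sedimentation_vanishes_for_vertical_tube(self):
        seg = self._segment(gravity_angle=math.pi / 2)
        p = at.sedimentation_probability(seg, 1.0, ParticleSpec(dp=10e-6))
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_sedimentation_value(self):
        """10 um in a horizontal 20 mm x 6.2 mm tube at 1 m/s: ~1.25%."""
        seg = self._segment(length=0.02, diameter=0.0062)
        p = at.sedimentation_probability(seg, 1.0, ParticleSpec(dp=10e-6))
        assert p == pytest.approx(0.0125, abs=2e-4)

    def test_sedimentation_requires_positive_velocity(self):
        with pytest.raises(ValueError):
            at.sedimentation_probability(self._segment(), 0.0,
                                         ParticleSpec(dp=10e-6))

    def test_submicron_particles_rejected(self):
        with pytest.raises(ValueError, match="Brownian"):
            ParticleSpec(dp=0.5e-6)


class TestReleaseTimes:
    def test_dpi_bolus_window(self, age5_dpi):
        _, params, profile, _ = age5_dpi
        t = at.sample_release_times(params, profile, 5000, seed=1)
        assert t.min() >= params.t_peak
        assert t.max() <= params.t_plateau_end

    def test_nebulizer_uniform_over_inspiration(self, neb_profiles):
        params = at.maneuver_defaults(10, at.Device.NEBULIZER)
        n = 100_000
        t = at.sample_release_times(params, neb_profiles[10], n, seed=2)
        se = params.t_insp / math.sqrt(12 * n)
        assert t.mean() == pytest.approx(params.t_insp / 2, abs=3 * se)

    def test_reproducible_under_seed(self, age5_dpi):
        _, params, profile, _ = age5_dpi
        a = at.sample_release_times(params, profile, 100, seed=7)
        b = at.sample_release_times(params, profile, 100, seed=7)
        assert np.array_equal(a, b)


class TestOracle:
    def test_total_probability(self, age5_dpi):
        tree, _, _, ff = age5_dpi
        for dp in (1e-6, 5e-6, 12e-6):
            probs = at.expected_deposition(
                tree, ff, ParticleSpec(dp=dp, release_time=0.5))
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_small_particles_mostly_escape(self, age5_dpi):
        tree, _, _, ff = age5_dpi
        probs = at.expected_deposition(
            tree, ff, ParticleSpec(dp=1e-6, release_time=0.5))
        assert probs["escaped"] > 0.8
        assert probs["mouth_throat"] < 0.01

    def test_mouth_throat_monotone_in_dp(self, age5_dpi):
        tree, _, _, ff = age5_dpi
        etas = [at.expected_deposition(
            tree, ff, ParticleSpec(dp=d * 1e-6, release_time=0.5))["mouth_throat"]
            for d in range(1, 13)]
        assert np.all(np.diff(etas) >= 0.0)


class TestMonteCarlo:
    @pytest.mark.parametrize("n", [1_000, 10_000, 100_000])
    def test_matches_oracle_within_binomial_error(self, age5_dpi, n):
        """MC regional efficiencies converge on the closed form at rate
        n^(-1/2): every region within 4 binomial standard errors."""
        tree, _, _, ff = age5_dpi
        dp = 5.5e-6
        expected = at.expected_deposition(
            tree, ff, ParticleSpec(dp=dp, release_time=0.5))
        ens = ParticleEnsemble(dp=dp, release_times=np.full(n, 0.5))
        result = at.simulate_deposition(tree, ff, ens, seed=11 + n)
        for region, p in expected.items():
            se = max(math.sqrt(p * (1 - p) / n), 1.0 / n)
            assert result.efficiency(region) == pytest.approx(p, abs=4 * se)

    def test_counts_conserve(self, age5_dpi):
        tree, params, profile, ff = age5_dpi
        t = at.sample_release_times(params, profile, 20_000, seed=3)
        res = at.simulate_deposition(
            tree, ff, ParticleEnsemble(dp=4e-6, release_times=t), seed=4)
        regional = sum(res.counts[r] for r in
                       ("mouth_throat", "trachea", "conducting", "escaped"))
        assert regional == res.counts["injected"] == 20_000
        assert sum(res.escaped_by_lobe.values()) == res.counts["escaped"]
        assert sum(res.segment_deposits.values()) == 20_000 - res.counts["escaped"]

    def test_same_seed_reproduces_exactly(self, age5_dpi):
        tree, params, profile, ff = age5_dpi
        t = at.sample_release_times(params, profile, 5_000, seed=5)
        ens = ParticleEnsemble(dp=6e-6, release_times=t)
        a = at.simulate_deposition(tree, ff, ens, seed=6)
        b = at.simulate_deposition(tree, ff, ens, seed=6)
        assert a.counts == b.counts
        assert a.segment_deposits == b.segment_deposits

    def test_very_large_particles_all_captured_orally(self, age5_dpi):
        tree, params, profile, ff = age5_dpi
        t = at.sample_release_times(params, profile, 2_000, seed=8)
        res = at.simulate_deposition(
            tree, ff, ParticleEnsemble(dp=100e-6, release_times=t), seed=9)
        assert res.efficiency("mouth_throat") > 0.999

    def test_empty_ensemble_rejected(self, age5_dpi):
        tree, _, _, ff = age5_dpi
        with pytest.raises(ValueError):
            at.simulate_deposition(
                tree, ff, ParticleEnsemble(dp=5e-6, release_times=np.array([])),
                seed=1)
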