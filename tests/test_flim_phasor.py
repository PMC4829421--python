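"""Phasor transform, abundance statistic, unmixing, and shot noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ranoise import flim_phasor as fp
from tests.conftest import decay_cube_from_hist, exponential_cube

OMEGA_NS = 2 * np.pi * 80e-3  # rad/ns at 80 MHz


class TestPhasorOfLifetime:
    @pytest.mark.parametrize(
        "tau,expected",
        [
            (0.0, (1.0, 0.0)),
            (1e9, (0.0, 0.0)),                       # tau -> inf limit
            (1.0 / OMEGA_NS, (0.5, 0.5)),            # semicircle midpoint
        ],
    )
    def test_closed_form(self, tau, expected):
        pt = fp.phasor_of_lifetime(tau)
        assert pt.g == pytest.approx(expected[0], abs=1e-8)
        assert pt.s == pytest.approx(expected[1], abs=1e-8)

    @given(tau=st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_universal_semicircle(self, tau):
        pt = fp.phasor_of_lifetime(tau)
        assert (pt.g - 0.5) ** 2 + pt.s**2 == pytest.approx(0.25, abs=1e-12)

    def test_negative_lifetime_rejected(self):
        with pytest.raises(ValueError):
            fp.phasor_of_lifetime(-0.1)


class TestHarmonicFrequency:
    @pytest.mark.parametrize("rep,h,out", [(80, 3, 240), (80, 1, 80), (100, 2, 200)])
    def test_values(self, rep, h, out):
        assert fp.harmonic_frequency(rep, h) == out

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fp.harmonic_frequency(-80, 1)
        with pytest.raises(ValueError):
            fp.harmonic_frequency(80, 0)


def test_total_integration_time_of_consecutive_frames():
    assert round(fp.total_integration_minutes(40, 4.0), 1) == 2.7


class TestComputePhasor:
    def test_delta_decay_maps_to_unit_g(self):
        hist = np.zeros(256, dtype=int)
        hist[0] = 10000
        pt = fp.compute_phasor(decay_cube_from_hist(hist))
        assert pt.g == pytest.approx(1.0, abs=1e-3)
        assert pt.s == pytest.approx(0.0, abs=0.02)

    def test_uniform_decay_maps_to_origin(self):
        pt = fp.compute_phasor(decay_cube_from_hist(np.full(256, 100)))
        assert pt.g == pytest.approx(0.0, abs=1e-12)
        assert pt.s == pytest.approx(0.0, abs=1e-12)

    def test_sampled_exponential_matches_closed_form(self):
        tau = 1.0 / OMEGA_NS  # 1.9894 ns at 80 MHz
        pt = fp.compute_phasor(exponential_cube(tau))
        assert pt.g == pytest.approx(0.5, abs=5e-3)
        assert pt.s == pytest.approx(0.5, abs=5e-3)

    def test_linearity_of_summed_decays(self, rng):
        h1 = rng.integers(0, 1000, 64).astype(float)
        h2 = rng.integers(0, 1000, 64).astype(float)
        p1 = fp.compute_phasor(decay_cube_from_hist(h1))
        p2 = fp.compute_phasor(decay_cube_from_hist(h2))
        p12 = fp.compute_phasor(decay_cube_from_hist(h1 + h2))
        w1 = h1.sum() / (h1 + h2).sum()
        assert p12.g == pytest.approx(w1 * p1.g + (1 - w1) * p2.g, abs=1e-9)
        assert p12.s == pytest.approx(w1 * p1.s + (1 - w1) * p2.s, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(0, 50, (32, 4, 5))
        cube = fp.DecayCube(counts=counts, rep_rate=80.0, bin_width=1e3 / 80 / 32)
        for harmonic in (1, 3):
            pt = fp.compute_phasor(cube, harmonic)
            # independent direct double-sum over photons
            g = s = tot = 0.0
            w = 2 * np.pi * 80e-3 * harmonic
            for k in range(32):
                t = (k + 0.5) * cube.bin_width
                n = counts[k].sum()
                g += n * np.cos(w * t)
                s += n * np.sin(w * t)
                tot += n
            assert pt.g == pytest.approx(g / tot, abs=1e-12)
            assert pt.s == pytest.approx(s / tot, abs=1e-12)

    def test_empty_region_raises(self):
        cube = decay_cube_from_hist(np.zeros(16, dtype=int))
        with pytest.raises(fp.EmptySignalError):
            fp.compute_phasor(cube)

    def test_mask_selects_pixels(self, rng):
        counts = np.zeros((16, 2, 2), dtype=int)
        counts[0, 0, 0] = 100      # delta decay in one pixel
        counts[:, 1, 1] = 10       # uniform decay in another
        cube = fp.DecayCube(counts=counts, rep_rate=80.0, bin_width=1e3 / 80 / 16)
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        assert fp.compute_phasor(cube, mask=mask).g > 0.9
        assert abs(fp.compute_phasor(cube, mask=~mask).g) < 1e-9

    def test_super_nyquist_harmonic_warns_not_fails(self):
        cube = decay_cube_from_hist(np.full(8, 10))
        with pytest.warns(UserWarning, match="Nyquist"):
            fp.compute_phasor(cube, harmonic=5)


class TestRelativeAbundance:
    def test_coincident_point_gives_one(self, two_refs):
        est = fp.relative_abundance(two_refs.ra, two_refs)
        assert est.one_minus_d == pytest.approx(1.0, abs=1e-12)

    def test_diametrically_opposite_point_gives_zero(self, two_refs):
        ra = two_refs.ra
        far = fp.PhasorPoint(g=ra.g - 1.0, s=ra.s)
        est = fp.relative_abundance(far, two_refs)
        assert est.one_minus_d == pytest.approx(0.0, abs=1e-12)
        assert est.d_ra == pytest.approx(1.0, abs=1e-12)

    def test_collinear_mixture_distance(self):
        # refs exactly 0.8 apart: d = (1-f)*0.8 at RA fraction f = 0.5
        ra = fp.PhasorPoint(g=0.9, s=0.1)
        bg = fp.PhasorPoint(g=0.1, s=0.1)
        assert ra.distance_to(bg) == pytest.approx(0.8)
        refs = fp.ReferenceSet(entries=(("RA", ra), ("bg", bg)))
        mixed = fp.mix_phasors([ra, bg], [0.5, 0.5])
        est = fp.relative_abundance(mixed, refs)
        assert est.one_minus_d == pytest.approx(0.6, abs=1e-12)

    def test_rotation_invariance(self, rng):
        # rotating measured point and references jointly leaves 1-d unchanged
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])

        def rotate(pt):
            g, s = rot @ pt.coords
            return fp.PhasorPoint(g=float(g), s=float(s), harmonic=pt.harmonic)

        ra = fp.PhasorPoint(g=0.9, s=0.05)
        m = fp.PhasorPoint(g=0.4, s=0.3)
        refs = fp.ReferenceSet(entries=(("RA", ra),))
        d0 = fp.relative_abundance(m, refs).one_minus_d
        # rotation preserves the distance, hence the abundance statistic
        assert rotate(m).distance_to(rotate(ra)) == pytest.approx(
            m.distance_to(ra), abs=1e-12
        )
        assert d0 == pytest.approx(1 - m.distance_to(ra), abs=1e-12)

    def test_harmonic_mismatch_rejected(self, two_refs):
        with pytest.raises(ValueError, match="harmonic"):
            fp.relative_abundance(fp.PhasorPoint(0.5, 0.3, harmonic=3), two_refs)

    def test_out_of_plot_point_clipped_to_zero(self, two_refs, caplog):
        far = fp.PhasorPoint(g=-1.0, s=0.0)
        est = fp.relative_abundance(far, two_refs)
        assert est.one_minus_d == 0.0
        assert est.d_ra > 1.0


class TestUnmix:
    def test_vertex_and_midpoint(self, two_refs):
        at_ra = fp.unmix(two_refs.ra, two_refs)
        assert at_ra["RA"] == pytest.approx(1.0, abs=1e-9)
        mid = fp.mix_phasors(list(two_refs.points), [0.5, 0.5])
        fr = fp.unmix(mid, two_refs)
        assert fr["RA"] == pytest.approx(0.5, abs=1e-9)
        assert fr["background"] == pytest.approx(0.5, abs=1e-9)

    def test_three_species_round_trip(self):
        pts = [
            fp.PhasorPoint(0.9, 0.1),
            fp.PhasorPoint(0.2, 0.35),
            fp.PhasorPoint(0.5, 0.48),
        ]
        refs = fp.ReferenceSet(entries=(("RA", pts[0]), ("b", pts[1]), ("c", pts[2])))
        target = (0.2, 0.3, 0.5)
        fr = fp.unmix(fp.mix_phasors(pts, target), refs)
        for name, f in zip(refs.labels, target):
            assert fr[name] == pytest.approx(f, abs=1e-6)

    def test_poisson_round_trip_within_shot_noise(self, rng, two_refs):
        f_true = 0.6
        p_ra = fp._wrapped_exponential(0.35, 80.0, 256)
        p_bg = fp._wrapped_exponential(2.5, 80.0, 256)
        n_photons = 200_000
        lam = n_photons * (f_true * p_ra + (1 - f_true) * p_bg)
        cube = decay_cube_from_hist(rng.poisson(lam))
        fr = fp.unmix(fp.compute_phasor(cube), two_refs)
        # fraction error bounded by 3x the propagated phasor shot noise
        sep = two_refs.ra.distance_to(two_refs["background"])
        bound = fp.shot_noise_bound(n_photons, decay=lam).sigma / sep
        assert abs(fr["RA"] - f_true) < 3 * bound

    def test_degenerate_references_rejected(self):
        a = fp.PhasorPoint(0.9, 0.1)
        refs2 = fp.ReferenceSet(entries=(("RA", a), ("b", fp.PhasorPoint(0.9, 0.1))))
        with pytest.raises(fp.DegenerateReferencesError):
            fp.unmix(fp.PhasorPoint(0.5, 0.3), refs2)
        collinear = fp.ReferenceSet(
            entries=(
                ("RA", fp.PhasorPoint(0.9, 0.1)),
                ("b", fp.PhasorPoint(0.5, 0.1)),
                ("c", fp.PhasorPoint(0.1, 0.1)),
            )
        )
        with pytest.raises(fp.DegenerateReferencesError):
            fp.unmix(fp.PhasorPoint(0.5, 0.3), collinear)

    def test_point_outside_hull_reports_residual(self, two_refs):
        outside = fp.PhasorPoint(0.5, 0.49)  # far off the two-ref segment
        fr = fp.unmix(outside, two_refs)
        assert fr.residual > 0.05
        assert sum(fr.fractions.values()) == pytest.approx(1.0)


class TestShotNoise:
    def test_scaling_slope_matches_monte_carlo(self, rng):
        # MC oracle: Poisson-resample a fixed decay at three photon budgets
        tau = 1.0 / OMEGA_NS
        p = fp._wrapped_exponential(tau, 80.0, 256)
        t = (np.arange(256) + 0.5) * (1e3 / 80 / 256)
        cos = np.cos(2 * np.pi * 80e-3 * t)
        ns = np.array([1e2, 1e4, 1e6])
        mc = []
        for n in ns:
            draws = rng.poisson(p * n, size=(400, 256))
            g = (draws @ cos) / draws.sum(axis=1)
            mc.append(g.std(ddof=1))
        slope_mc = np.polyfit(np.log10(ns), np.log10(mc), 1)[0]
        assert slope_mc == pytest.approx(-0.5, abs=0.05)
        bounds = [fp.shot_noise_bound(n, tau=tau).sigma_g for n in ns]
        slope_bound = np.polyfit(np.log10(ns), np.log10(bounds), 1)[0]
        assert slope_bound == pytest.approx(-0.5, abs=1e-6)

    def test_bound_matches_monte_carlo_spread(self, rng):
        tau = 1.0 / OMEGA_NS
        p = fp._wrapped_exponential(tau, 80.0, 256)
        t = (np.arange(256) + 0.5) * (1e3 / 80 / 256)
        cos = np.cos(2 * np.pi * 80e-3 * t)
        draws = rng.poisson(p * 1e4, size=(2000, 256))
        g = (draws @ cos) / draws.sum(axis=1)
        bound = fp.shot_noise_bound(1e4, tau=tau)
        assert bound.sigma_g == pytest.approx(g.std(ddof=1), rel=0.10)

    def test_vanishes_at_infinite_photons(self):
        assert fp.shot_noise_bound(1e12).sigma < 1e-5


class TestHarmonicConsistency:
    def _refs(self, harmonic):
        return fp.ReferenceSet(
            entries=(
                ("RA", fp.phasor_of_lifetime(0.35, harmonic=harmonic)),
                ("background", fp.phasor_of_lifetime(2.5, harmonic=harmonic)),
            ),
            harmonic=harmonic,
        )

    def _cube(self, f_ra, rng, photons=500_000):
        p_ra = fp._wrapped_exponential(0.35, 80.0, 128)
        p_bg = fp._wrapped_exponential(2.5, 80.0, 128)
        return decay_cube_from_hist(rng.poisson(photons * (f_ra * p_ra + (1 - f_ra) * p_bg)))

    def test_decreasing_fraction_series_agrees_across_harmonics(self, rng):
        cubes = [self._cube(f, rng) for f in np.linspace(0.9, 0.1, 9)]
        df = fp.harmonic_consistency(cubes, self._refs(1), self._refs(3))
        assert df.attrs["association_sign"] > 0
        assert df.attrs["spearman_rho"] > 0.9

    def test_constant_series_is_flat_within_shot_noise(self, rng):
        photons = 500_000
        cubes = [self._cube(0.5, rng, photons) for _ in range(6)]
        df = fp.harmonic_consistency(cubes, self._refs(1), self._refs(3))
        spread = df["one_minus_d_h1"].max() - df["one_minus_d_h1"].min()
        assert spread < 8 * fp.shot_noise_bound(photons).sigma

    def test_permuted_series_loses_association(self, rng):
        cubes = [self._cube(f, rng) for f in np.linspace(0.9, 0.1, 12)]
        df = fp.harmonic_consistency(cubes, self._refs(1), self._refs(3))
        perm = rng.permutation(df["one_minus_d_h3"].to_numpy())
        from scipy import stats

        rho, _ = stats.spearmanr(df["one_minus_d_h1"], perm)
        assert abs(rho) < abs(df.attrs["spearman_rho"])

    def test_too_few_cubes_rejected(self, rng):
        with pytest.raises(ValueError):
            fp.harmonic_consistency([self._cube(0.5, rng)] * 2, self._refs(1), self._refs(3))


class TestIO:
    def test_decay_cube_tiff_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 100, (16, 4, 4))
        cube = fp.DecayCube(counts=counts, rep_rate=80.0, bin_width=1e3 / 80 / 16,
                            meta={"ex_nm": 760})
        fp.write_decay_cube(tmp_path / "c.tif", cube)
        back = fp.read_decay_cube(tmp_path / "c.tif")
        assert np.array_equal(back.counts, counts)
        assert back.rep_rate == 80.0
        assert back.meta["ex_nm"] == 760

    def test_decay_cube_npz_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 100, (16, 3, 2))
        cube = fp.DecayCube(counts=counts, rep_rate=80.0, bin_width=1e3 / 80 / 16)
        fp.write_decay_cube(tmp_path / "c.npz", cube)
        back = fp.read_decay_cube(tmp_path / "c.npz")
        assert np.array_equal(back.counts, counts)

    def test_reference_table_round_trip(self, tmp_path, two_refs):
        fp.write_reference_table(tmp_path / "refs.csv", two_refs)
        back = fp.read_reference_table(tmp_path / "refs.csv")
        assert back.labels == two_refs.labels
        assert back.ra.g == pytest.approx(two_refs.ra.g)

    def test_references_from_cubes(self):
        cubes = {
            "RA": exponential_cube(0.35),
            "background": exponential_cube(2.5),
        }
        refs = fp.references_from_cubes(cubes)
        assert refs.ra.g == pytest.approx(fp.phasor_of_lifetime(0.35).g, abs=5e-3)


class TestInvariants:
    def test_decay_cube_validation(self):
        with pytest.raises(ValueError, match="laser period"):
            fp.DecayCube(counts=np.zeros((8, 1, 1), int), rep_rate=80.0, bin_width=1.0)
        with pytest.raises(ValueError, match="non-negative"):
            fp.DecayCube(
                counts=np.full((8, 1, 1), -1), rep_rate=80.0, bin_width=1e3 / 80 / 8
            )

    def test_reference_set_requires_short_lifetime_ra(self):
        with pytest.raises(ValueError, match="high-g"):
            fp.ReferenceSet(entries=(("RA", fp.PhasorPoint(0.1, 0.3)),))

    def test_mixture_fractions_validate(self):
        with pytest.raises(ValueError):
            fp.MixtureFractions(fractions={"a": 0.5, "b": 0.6})
        with pytest.raises(ValueError):
            fp.MixtureFractions(fractions={"a": -0.1, "b": 1.1})
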