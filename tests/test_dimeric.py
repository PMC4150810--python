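import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nucoff as nc
from nucoff.landscape import FreeEnergyLandscape, WrapRates, coarse_rates
from nucoff.markov import slowest_decay_rate, steady_state


class TestClosedForm:
    def test_fitted_rates_reproduce_measured_off_rate(self):
        assert nc.closed_form_naked_off_rate(1700, 1.7, 1.7) == pytest.approx(
            0.0034, rel=0.01
        )

    def test_zero_k3_means_no_full_release(self):
        assert nc.closed_form_naked_off_rate(1700.0, 1.7, 0.0) == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            nc.closed_form_naked_off_rate(-1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", [0])
    def test_equals_numeric_eigensolve_on_200_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            k1, k2, k3 = 10.0 ** rng.uniform(0.0, 2.0, 3)
            p = nc.DimericParams(k1, k2, k3, 0.0, k1 / k2, 1.0)
            eig = slowest_decay_rate(nc.build_naked_generator(p, conc=0.0)).off_rate
            assert nc.closed_form_naked_off_rate(k1, k2, k3) == pytest.approx(
                eig, rel=1e-9
            )

    @given(
        st.floats(0.1, 100.0),
        st.floats(0.1, 100.0),
        st.floats(0.1, 100.0),
        st.floats(0.01, 100.0),
    )
    def test_homogeneous_of_degree_one(self, k1, k2, k3, c):
        a = nc.closed_form_naked_off_rate(c * k1, c * k2, c * k3)
        b = c * nc.closed_form_naked_off_rate(k1, k2, k3)
        assert a == pytest.approx(b, rel=1e-9)


class TestFit:
    def test_recovers_published_rate_constants(self, fitted):
        assert fitted.k1 == pytest.approx(1700, rel=0.01)
        assert fitted.k2 == pytest.approx(1.7, rel=0.01)
        assert fitted.k3 == fitted.k2
        assert fitted.k4_per_conc == pytest.approx(0.025, rel=0.05)

    def test_scaling_the_target_scales_all_rates(self, fitted):
        doubled = nc.fit_naked_dimeric(target_off=2 * 0.0034)
        assert doubled.k1 == pytest.approx(2 * fitted.k1, rel=1e-9)
        assert doubled.k2 == pytest.approx(2 * fitted.k2, rel=1e-9)

    @pytest.mark.parametrize("target", np.logspace(-4, -1, 7))
    def test_round_trip_through_the_four_state_generator(self, target):
        p = nc.fit_naked_dimeric(target_off=target)
        gen = nc.build_naked_generator(p, conc=0.0)
        assert slowest_decay_rate(gen).off_rate == pytest.approx(target, rel=1e-9)

    def test_rejects_unreachable_target(self):
        with pytest.raises(ValueError):
            nc.fit_naked_dimeric(target_off=1e12)


class TestNakedGenerator:
    def test_zero_concentration_makes_unbound_absorbing(self, fitted):
        gen = nc.build_naked_generator(fitted, conc=0.0)
        assert "free" in gen.absorbing
        np.testing.assert_array_equal(gen.as_dense()[:, 3], 0.0)

    def test_association_only_structure(self):
        p = nc.DimericParams(0.0, 0.0, 0.0, 0.025, 1.0, 0.07)
        R = nc.build_naked_generator(p, conc=100.0).as_dense()
        k4 = 0.025 * 100
        assert R[1, 3] == pytest.approx(k4)
        assert R[2, 3] == pytest.approx(k4)
        assert np.count_nonzero(R) == 3  # two association entries plus diagonal

    @pytest.mark.parametrize("conc", [0.035, 0.07, 0.7])
    def test_equilibrium_occupancy_reproduces_kd(self, fitted, conc):
        gen = nc.build_naked_generator(fitted, conc=conc)
        pi = steady_state(gen)
        expect = conc / (conc + fitted.kd_full)
        assert pi[0] == pytest.approx(expect, rel=0.005)


class TestNucleosomeGenerator:
    def test_absorbing_off_state_column_is_zero(self, fitted):
        gen = nc.build_nucleosome_generator(fitted, coarse_rates(6.0), absorbing=True)
        R = gen.as_dense()
        i = gen.index("free@wrapped")
        np.testing.assert_array_equal(R[:, i], 0.0)
        j = gen.index("free@n_part")
        assert R[i, j] == pytest.approx(coarse_rates(6.0).k7)
        assert nc.validate_generator(gen) == []

    def test_non_absorbing_generator_has_k8_return(self, fitted):
        w = coarse_rates(6.0, dg_part_wrap=2.0)
        gen = nc.build_nucleosome_generator(fitted, w, absorbing=False)
        R = gen.as_dense()
        assert R[gen.index("free@n_part"), gen.index("free@wrapped")] == pytest.approx(
            w.k8
        )

    def test_frozen_wrap_rates_reduce_to_naked_decay(self, fitted):
        w = WrapRates(0.0, 0.0, 0.0, 0.0, n_full=34, n_part=19, n_wrap=0, ddg=6.0)
        gen = nc.build_nucleosome_generator(fitted, w, conc=0.0, absorbing=True)
        assert slowest_decay_rate(gen).off_rate == pytest.approx(0.0034, rel=1e-4)


class TestNucleosomeOffRate:
    def test_increases_monotonically_with_unwrapping_penalty(self, fitted):
        offs = [
            nc.nucleosome_off_rate(fitted, ddg).off_rate for ddg in np.arange(0.0, 8.5, 1.0)
        ]
        assert np.all(np.diff(offs) > 0)

    def test_bracketed_between_naked_rate_and_twice_k3(self, fitted):
        for ddg in np.arange(0.0, 8.5, 1.0):
            off = nc.nucleosome_off_rate(fitted, ddg).off_rate
            assert fitted.naked_off_rate <= off <= 2 * fitted.k3

    def test_midpoint_of_scan_lies_between_endpoints(self, fitted):
        lo = nc.nucleosome_off_rate(fitted, 5.0).off_rate
        mid = nc.nucleosome_off_rate(fitted, 6.0).off_rate
        hi = nc.nucleosome_off_rate(fitted, 7.0).off_rate
        assert lo < mid < hi

    def test_insensitive_to_concentration_over_four_decades(self, fitted):
        offs = [
            nc.nucleosome_off_rate(fitted, 6.0, conc=c).off_rate
            for c in (0.0, 50.0, 5000.0, 50000.0)
        ]
        assert max(offs) / min(offs) < 10.0

    def test_unwrap_extents_matter_far_less_than_the_free_energy(self, fitted):
        base = nc.nucleosome_off_rate(fitted, 6.0, n_full=34, n_part=19).off_rate
        wide = nc.nucleosome_off_rate(fitted, 6.0, n_full=49, n_part=19).off_rate
        ddg_effect = min(
            abs(nc.nucleosome_off_rate(fitted, 7.0).off_rate - base),
            abs(nc.nucleosome_off_rate(fitted, 5.0).off_rate - base),
        )
        assert abs(wide - base) < 0.2 * ddg_effect

    def test_scan_dataframe_covers_default_grid(self, fitted):
        df = nc.ddg_scan(fitted)
        assert len(df) == 9
        assert df.ddg_kBT.iloc[0] == 5.0 and df.ddg_kBT.iloc[-1] == 7.0
        assert (df.off_rate_s.diff().dropna() > 0).all()


class TestMutants:
    def test_both_variants_approach_single_monomer_release_rate(self, fitted):
        for variant in ("near_dyad_mutated", "far_mutated"):
            off = nc.mutant_half_site_off_rate(fitted, variant, ddg=6.0)
            assert off == pytest.approx(fitted.k3, rel=0.10)
            assert off / 0.0034 == pytest.approx(500, rel=0.10)

    def test_insensitive_to_unwrapping_free_energy(self, fitted):
        for variant in ("near_dyad_mutated", "far_mutated"):
            offs = [
                nc.mutant_half_site_off_rate(fitted, variant, ddg=d)
                for d in (5.0, 6.0, 7.0)
            ]
            assert max(offs) / min(offs) < 1.05

    def test_naked_half_site_releases_at_exactly_k3(self, fitted):
        off = nc.mutant_half_site_off_rate(fitted, "naked_half_site")
        assert off == pytest.approx(fitted.k3, rel=1e-12)

    def test_unknown_variant_rejected(self, fitted):
        with pytest.raises(ValueError):
            nc.mutant_half_site_off_rate(fitted, "dyad_flipped")


@pytest.fixture(scope="module")
def steep_landscape():
    # 0.6 kBT per bp: the inner half-site (10 bp) costs 6 kBT to expose
    return FreeEnergyLandscape(np.arange(31) * 0.6)


class TestEntryExit:

    def test_rate_is_finite_and_below_double_monomer_release(
        self, fitted, steep_landscape
    ):
        off = nc.entry_exit_off_rate(fitted, steep_landscape)
        assert 0.0 < off <= 2 * fitted.k3 * (1 + 1e-9)
        assert off > fitted.naked_off_rate

    def test_concentration_changes_rate_by_less_than_tenfold(
        self, fitted, steep_landscape
    ):
        lo = nc.entry_exit_off_rate(fitted, steep_landscape, conc=0.0)
        hi = nc.entry_exit_off_rate(fitted, steep_landscape, conc=50000.0)
        assert max(lo, hi) / min(lo, hi) < 10.0

    def test_impassable_landscape_traps_at_monomer_release_rate(self, fitted):
        steep = FreeEnergyLandscape(np.arange(31) * 50.0)
        off = nc.entry_exit_off_rate(fitted, steep)
        assert off == pytest.approx(fitted.k3, rel=0.05)

    def test_invalid_spans_rejected(self, fitted, steep_landscape):
        with pytest.raises(ValueError):
            nc.entry_exit_off_rate(fitted, steep_landscape, outside_span=(1, 5))
        with pytest.raises(ValueError):
            nc.entry_exit_off_rate(fitted, steep_landscape, inside_span=(0, 10))
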