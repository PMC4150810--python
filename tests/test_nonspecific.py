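import numpy as np
import pytest

import nucoff as nc
from nucoff.fixtures import TINY_LATTICE
from nucoff.markov import Generator, slowest_decay_rate
from nucoff.nonspecific import (
    LatticeSpec,
    _naked_transient_decay,
    build_naked_lattice,
    build_nucleosome_lattice,
    default_K_grid,
    default_k1_grid,
    fit_ks_off,
    lattice_off_rate,
    naked_off_rate,
    scan_nonspecific,
)


def tiny_spec(**overrides) -> LatticeSpec:
    kw = dict(
        K=TINY_LATTICE["K"], k1=TINY_LATTICE["k1"], ks_off=TINY_LATTICE["ks_off"],
        L=TINY_LATTICE["L"], site_start=TINY_LATTICE["site_start"],
        site_end=TINY_LATTICE["site_end"], footprint=TINY_LATTICE["footprint"],
        d=TINY_LATTICE["d"],
    )
    kw.update(overrides)
    return LatticeSpec(**kw)


class TestNakedLattice:
    def test_single_position_decays_at_specific_off_rate(self):
        spec = LatticeSpec(K=100, k1=0.0, ks_off=0.05, L=4, site_start=1,
                           site_end=4, footprint=4)
        assert slowest_decay_rate(build_naked_lattice(spec)).off_rate == pytest.approx(
            0.05, rel=1e-12
        )

    def test_frozen_sliding_decouples_positions(self):
        spec = LatticeSpec(K=100, k1=0.0, ks_off=0.05, L=12, site_start=3,
                           site_end=6, footprint=4)
        gen = build_naked_lattice(spec)
        eig = np.linalg.eigvals(gen.as_dense())
        mags = np.sort(np.abs(eig))
        # one zero (absorbing), the specific site at ks_off, the rest at K*ks_off
        assert mags[0] == pytest.approx(0.0, abs=1e-12)
        assert mags[1] == pytest.approx(0.05, rel=1e-10)
        assert mags[2] == pytest.approx(100 * 0.05, rel=1e-10)

    def test_generator_is_valid_and_absorbing_at_zero_conc(self):
        gen = build_naked_lattice(tiny_spec())
        assert nc.validate_generator(gen) == []
        assert "unbound" in gen.absorbing

    def test_association_targets_every_position_equally(self):
        spec = tiny_spec(conc=10.0)
        gen = build_naked_lattice(spec)
        R = gen.as_dense()
        kon = spec.kon_per_conc * 10.0
        u = gen.index("unbound")
        np.testing.assert_allclose(np.delete(R[:, u], u), kon)

    def test_footprint_longer_than_dna_rejected(self):
        with pytest.raises(ValueError):
            LatticeSpec(K=100, k1=1.0, ks_off=0.05, L=4, site_start=1,
                        site_end=4, footprint=6)


class TestFit:
    @pytest.mark.parametrize(
        "K,k1", [(1e2, 1e3), (1e2, 1e7), (1e5, 1e3), (1e5, 1e7), (10**3.5, 1e5)]
    )
    def test_round_trip_reproduces_measured_off_rate(self, K, k1):
        ks = fit_ks_off(K, k1)
        spec = LatticeSpec(K=K, k1=k1, ks_off=ks)
        assert naked_off_rate(spec) == pytest.approx(0.0034, rel=1e-6)

    def test_frozen_sliding_limit_fits_the_site_rate_directly(self):
        ks = fit_ks_off(1.0, 0.0, L=4, site_start=1, site_end=4)
        assert ks == pytest.approx(0.0034, rel=1e-9)

    def test_transient_block_solve_matches_full_eigensolve(self):
        spec = LatticeSpec(K=1e3, k1=1e4, ks_off=1e-4)
        full = slowest_decay_rate(build_naked_lattice(spec)).off_rate
        assert naked_off_rate(spec) == pytest.approx(full, rel=1e-7)


class TestJointLattice:
    @pytest.mark.parametrize("d", [0, 2])
    @pytest.mark.parametrize("total_dG", [0.5, 3.0])
    @pytest.mark.parametrize("conc", [0.0, 100.0])
    def test_matches_independent_dense_enumeration(
        self, d, total_dG, conc, joint_lattice_oracle
    ):
        spec = tiny_spec(d=d, conc=conc)
        lmb = nc.synthetic_landscape(TINY_LATTICE["n_max"], total_dG)
        k0 = TINY_LATTICE["k0"]
        gen = build_nucleosome_lattice(spec, lmb, k0=k0, truncation_margin=None)
        assert nc.validate_generator(gen) == []
        ours = slowest_decay_rate(gen, method="sparse").off_rate
        labels, R = joint_lattice_oracle(spec, lmb, k0)
        oracle = slowest_decay_rate(
            Generator(labels, R), method="dense"
        ).off_rate
        assert ours == pytest.approx(oracle, rel=1e-8)
        assert gen.n_states == len(labels)

    def test_truncation_error_is_bounded_by_the_boltzmann_margin(self):
        # dropping wrap states more than `margin` kBT above the site-exposing
        # free energy perturbs the decay rate by at most ~exp(-margin)
        from nucoff.nonspecific import TRUNCATION_MARGIN_KBT

        ks = fit_ks_off(1e3, 1e5)
        spec = LatticeSpec(K=1e3, k1=1e5, ks_off=ks, d=7)
        lmb = nc.synthetic_landscape()
        full = lattice_off_rate(spec, lmb, truncation_margin=None)
        cut = lattice_off_rate(spec, lmb)
        assert cut == pytest.approx(full, rel=2 * np.exp(-TRUNCATION_MARGIN_KBT))

    def test_flat_landscape_limit_matches_wrap_contracted_sliding_model(self):
        # with a vanishing landscape the wrap coordinate equilibrates fast and
        # uniformly; contracting it onto the TF position yields a plain
        # sliding model with occupancy-weighted step rates
        spec = tiny_spec(d=0, k1=20.0, ks_off=0.05)
        n_max = TINY_LATTICE["n_max"]
        lmb = nc.synthetic_landscape(n_max, 1e-6)
        joint = lattice_off_rate(spec, lmb, k0=1e5, truncation_margin=None)

        flank = spec.L - n_max
        f = spec.footprint
        npos = spec.n_positions
        need = np.maximum(np.arange(1, npos + 1) + f - 1 - flank, 0)
        labels = tuple(f"p{p}" for p in range(1, npos + 1)) + ("unbound",)
        R = np.zeros((npos + 1, npos + 1))
        for i, p in enumerate(range(1, npos + 1)):
            # n is uniform on [need(p), n_max] while the TF sits at p
            width = n_max - need[i] + 1
            slide = spec.k2 if p == spec.site_start else spec.k1
            for j in (i - 1, i + 1):
                if 0 <= j < npos:
                    frac = (n_max - need[j] + 1 if need[j] >= need[i] else width) / width
                    frac = min(frac, 1.0)
                    rate = slide * frac
                    R[j, i] += rate
                    R[i, i] -= rate
            off = spec.ks_off if p == spec.site_start else spec.kns_off
            R[npos, i] += off
            R[i, i] -= off
        contracted = slowest_decay_rate(Generator(labels, R)).off_rate
        assert joint == pytest.approx(contracted, rel=0.05)

    def test_mismatched_geometry_rejected(self):
        lmb = nc.synthetic_landscape(40, 5.0)
        with pytest.raises(ValueError):
            build_nucleosome_lattice(tiny_spec(), lmb)  # n_max exceeds L


@pytest.fixture(scope="module")
def small_scan():
    lmb = nc.synthetic_landscape(20, 5.0)
    return scan_nonspecific(
        lmb, d_values=range(0, 22), conc_values=(0.0,),
        L=40, site_start=23, site_end=28, footprint=6, target_off=0.05,
    )


class TestScan:

    def test_default_grid_emits_exactly_35_rows(self, small_scan):
        assert len(small_scan) == 35
        assert len(default_K_grid()) * len(default_k1_grid()) == 35

    def test_best_clearance_within_scanned_range(self, small_scan):
        assert small_scan.d_best.between(0, 21).all()
        assert (small_scan.off_rate_s > 0).all()
        np.testing.assert_allclose(
            small_scan.fold_change, small_scan.off_rate_s / 0.05
        )

    def test_scan_is_deterministic(self, small_scan):
        lmb = nc.synthetic_landscape(20, 5.0)
        again = scan_nonspecific(
            lmb, K_values=small_scan.K.unique()[:1], k1_values=[1e3],
            d_values=range(0, 22), conc_values=(0.0,),
            L=40, site_start=23, site_end=28, footprint=6, target_off=0.05,
        )
        row = small_scan[(small_scan.K == again.K[0]) & (small_scan.k1 == 1e3)]
        assert again.off_rate_s[0] == row.off_rate_s.iloc[0]

    def test_free_flanking_dna_acts_as_nonspecific_reservoir(self):
        # flanking positions outside the positioning sequence cost no
        # unwrapping energy; adding them shifts the bound ensemble toward
        # fast-dissociating non-specific DNA and raises the off-rate, which
        # is why the default lattice is the bare positioning sequence
        lmb = nc.synthetic_landscape()
        ks = fit_ks_off(1e3, 1e5)
        off_bare = lattice_off_rate(LatticeSpec(K=1e3, k1=1e5, ks_off=ks, d=7), lmb)
        ks_flank = fit_ks_off(1e3, 1e5, L=197, site_start=58, site_end=77)
        off_flank = lattice_off_rate(
            LatticeSpec(K=1e3, k1=1e5, ks_off=ks_flank, L=197, site_start=58,
                        site_end=77, d=7),
            lmb,
        )
        assert off_flank > off_bare
        assert off_bare / 0.0034 < 10.0


class TestGillespieAgreement:
    def test_five_grid_points_agree_with_eigenvalue_within_three_se(self):
        rng = np.random.default_rng(2024)
        Ks = default_K_grid()
        k1s = [1e3, 1e4]  # the SSA-tractable corner of the sliding-rate grid
        pairs = {(float(rng.choice(Ks)), float(rng.choice(k1s))) for _ in range(10)}
        lmb = nc.synthetic_landscape(TINY_LATTICE["n_max"], TINY_LATTICE["total_dG"])
        for K, k1 in sorted(pairs)[:5]:
            spec = tiny_spec(K=K, k1=k1)
            gen = build_nucleosome_lattice(
                spec, lmb, k0=TINY_LATTICE["k0"], truncation_margin=None
            )
            eig = slowest_decay_rate(gen).off_rate
            start = f"p{spec.site_start}@n{lmb.n_max}"
            est = nc.gillespie_decay(
                gen, start, {"free@n0"}, n_traj=400, seed=int(K) % 1000 + int(k1)
            )
            assert est.agrees_with(eig), (K, k1, est.rate, est.stderr, eig)

    def test_naked_lattice_agrees_with_eigenvalue(self):
        spec = tiny_spec(k1=200.0)
        gen = build_naked_lattice(spec)
        eig = slowest_decay_rate(gen).off_rate
        est = nc.gillespie_decay(
            gen, f"p{spec.site_start}", {"unbound"}, n_traj=1000, seed=3
        )
        assert est.agrees_with(eig)
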