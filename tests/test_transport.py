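import numpy as np
import pytest

from conftest import (
    flat_absorber_xs,
    layered_slab_phantom,
    monoline_spectrum,
    uniform_box_phantom,
)
from thyrodose.nuclear import load_spectrum, mean_energy_per_decay
from thyrodose.transport import (
    CrossSectionTable,
    TallyAccumulator,
    build_source_distribution,
    compute_dose_map,
    run_decay_histories,
    transport_electron,
    transport_photon,
)


def pencil_source(n, x0):
    """n photons starting at depth ~0 travelling along +z."""
    pos = np.tile(np.array([x0, x0, 1e-6]), (n, 1))
    dirs = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    return pos, dirs


class TestSourceDistribution:
    def test_two_region_normalisation(self, toy):
        sd = build_source_distribution(toy, {"core": 3.0, "shell": 1.0})
        assert dict(zip(sd.regions, sd.probabilities)) == {"core": 0.75, "shell": 0.25}

    def test_single_region_probability_one(self, toy):
        sd = build_source_distribution(toy, {"core": 42.0})
        assert list(sd.probabilities) == [1.0]

    def test_zero_activities_rejected(self, toy):
        with pytest.raises(ValueError):
            build_source_distribution(toy, {"core": 0.0})

    def test_empirical_selection_frequencies(self, toy, rng):
        sd = build_source_distribution(toy, {"core": 3.0, "shell": 1.0})
        n = 100_000
        pts = sd.sample_positions(n, rng)
        r = np.linalg.norm(pts - np.array(toy.extent_cm) / 2, axis=1)
        r_core = 0.30 * toy.extent_cm[0] / 2
        # count points in voxels belonging to the core
        idx = np.floor(pts / np.array(toy.voxel_size_cm)).astype(int)
        labs = toy.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        k = int((labs == 1).sum())
        sigma = np.sqrt(n * 0.75 * 0.25)
        assert abs(k - 0.75 * n) < 3 * sigma

    def test_points_always_inside_their_region(self, toy, rng):
        sd = build_source_distribution(toy, {"shell": 1.0})
        pts = sd.sample_positions(5000, rng)
        idx = np.floor(pts / np.array(toy.voxel_size_cm)).astype(int)
        labs = toy.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.all(labs == 2)


class TestPhotonTransport:
    def test_exponential_attenuation_profile(self):
        """Depth of first real interaction follows exp(-mu z) (3 sigma)."""
        mu_over_rho = 0.12
        mu = mu_over_rho * 1.05  # soft tissue density
        ph = layered_slab_phantom([1] * 30, voxel_mm=5.0, nxy=40)
        xs = flat_absorber_xs({"soft_tissue": mu_over_rho})
        tally = TallyAccumulator(ph, "photon", "collision_deposit", 1.0, n_batches=1)
        rng = np.random.default_rng(5)
        n = 100_000
        E0 = 0.3645
        pos, dirs = pencil_source(n, x0=ph.extent_cm[0] / 2)
        transport_photon(np.full(n, E0), pos, dirs, ph, xs, tally, rng,
                         mode="collision_deposit")
        dz = ph.voxel_size_cm[2]
        counts = np.array([tally.edep[0, iz + 1] / E0 for iz in range(30)])
        # survival beyond each layer boundary
        survive = n - np.cumsum(counts)
        for iz in (4, 9, 19):
            p = np.exp(-mu * (iz + 1) * dz)
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(survive[iz] - n * p) < 3 * sigma, f"layer {iz}"

    def test_woodcock_unbiased_in_checkerboard(self):
        """Two-material layered slab: survival matches the heterogeneous
        path integral exp(-sum mu_i L_i) (deterministic ray-march oracle)."""
        layers = [1, 3] * 10  # alternating soft tissue / bone
        ph = layered_slab_phantom(layers, voxel_mm=5.0, nxy=40)
        xs = flat_absorber_xs({"soft_tissue": 0.10, "bone": 0.25})
        mu_lin = {1: 0.10 * 1.05, 3: 0.25 * 1.30}
        tally = TallyAccumulator(ph, "photon", "collision_deposit", 1.0, n_batches=1)
        rng = np.random.default_rng(6)
        n = 100_000
        E0 = 0.2
        pos, dirs = pencil_source(n, x0=ph.extent_cm[0] / 2)
        transport_photon(np.full(n, E0), pos, dirs, ph, xs, tally, rng,
                         mode="collision_deposit")
        dz = ph.voxel_size_cm[2]
        optical_depth = np.cumsum([mu_lin[m] * dz for m in layers])
        interacted = np.cumsum(tally.edep[0, 1:] / E0)
        for iz in (3, 9, 15):
            p_surv = np.exp(-optical_depth[iz])
            k = n - interacted[iz]
            sigma = np.sqrt(n * p_surv * (1 - p_surv))
            assert abs(k - n * p_surv) < 3 * sigma, f"layer {iz}"

    def test_infinite_medium_equilibrium_kerma(self, xs):
        """Uniform source in a periodic medium: kerma/mass equals emitted
        energy/mass (radiative equilibrium closed form, 1%)."""
        ph = uniform_box_phantom(12, voxel_mm=8.0)
        spec = monoline_spectrum(0.3645)
        sd = build_source_distribution(ph, {"medium": 1.0})
        tally = run_decay_histories(ph, sd, spec, "photon", 100_000, seed=11,
                                    mode="track_length_kerma", xs=xs, periodic=True)
        kerma_per_decay = tally.dose_per_decay()["medium"] * ph.organ_mass("medium")
        assert kerma_per_decay == pytest.approx(0.3645, rel=0.01)

    def test_collision_mode_conserves_energy_when_escape_proof(self, xs):
        ph = uniform_box_phantom(12, voxel_mm=8.0)
        spec = load_spectrum("I-131")
        sd = build_source_distribution(ph, {"medium": 1.0})
        tally = run_decay_histories(ph, sd, spec, "photon", 20_000, seed=3,
                                    mode="collision_deposit", xs=xs, periodic=True)
        per_decay = tally.dose_per_decay()["medium"] * ph.organ_mass("medium")
        expected = mean_energy_per_decay(spec, "photon")
        rel_se = tally.rel_stderr()["medium"]
        assert abs(per_decay - expected) < 3 * rel_se * per_decay + 1e-9

    def test_estimator_equivalence_f6_vs_f8_analog(self, toy, xs):
        """Track-length kerma and collision estimators agree within 3 sigma."""
        spec = load_spectrum("I-131")
        sd = build_source_distribution(toy, {"core": 1.0})
        t_kerma = run_decay_histories(toy, sd, spec, "photon", 60_000, seed=21,
                                      mode="track_length_kerma", xs=xs)
        t_coll = run_decay_histories(toy, sd, spec, "photon", 60_000, seed=22,
                                     mode="collision_deposit", xs=xs)
        for organ in ("core", "shell"):
            a, b = t_kerma.dose_per_decay()[organ], t_coll.dose_per_decay()[organ]
            sa = t_kerma.rel_stderr()[organ] * a
            sb = t_coll.rel_stderr()[organ] * b
            assert abs(a - b) < 3 * np.hypot(sa, sb), organ

    def test_vacuumlike_phantom_gives_zero_tally(self):
        """A grid of near-zero density: histories escape, nothing scored."""
        ph = uniform_box_phantom(8, voxel_mm=8.0, material=4)  # air box
        xs = CrossSectionTable.from_package()
        tally = TallyAccumulator(ph, "photon", "collision_deposit", 1.0, 1)
        rng = np.random.default_rng(1)
        pos, dirs = pencil_source(2000, x0=ph.extent_cm[0] / 2)
        transport_photon(np.full(2000, 0.3645), pos, dirs, ph, xs, tally, rng,
                         mode="collision_deposit")
        assert tally.total_deposited_MeV < 2000 * 0.3645 * 1e-3

    def test_deterministic_for_fixed_seed(self, toy, xs):
        spec = load_spectrum("Tc-99m")
        sd = build_source_distribution(toy, {"core": 1.0})
        a = run_decay_histories(toy, sd, spec, "photon", 1000, seed=9, xs=xs)
        b = run_decay_histories(toy, sd, spec, "photon", 1000, seed=9, xs=xs)
        assert np.array_equal(a.edep, b.edep)

    def test_stderr_shrinks_as_sqrt_n(self, toy, xs):
        spec = monoline_spectrum(0.3645)
        sd = build_source_distribution(toy, {"core": 1.0})
        small = run_decay_histories(toy, sd, spec, "photon", 8_000, seed=31, xs=xs)
        large = run_decay_histories(toy, sd, spec, "photon", 32_000, seed=32, xs=xs)
        ratio = small.rel_stderr()["shell"] / large.rel_stderr()["shell"]
        assert 1.4 < ratio < 2.9  # ~2 expected, noisy batch statistics


class TestElectronTransport:
    def test_short_range_electron_fully_contained(self, toy, xs):
        """CSDA range << voxel size: all energy stays in the source organ."""
        tally = TallyAccumulator(toy, "electron", "collision_deposit", 1.0, 1)
        rng = np.random.default_rng(2)
        center = np.array(toy.extent_cm) / 2
        n = 500
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        transport_electron(np.full(n, 0.015), np.tile(center, (n, 1)), dirs,
                           toy, xs, tally, rng)
        assert tally.edep[0, 1] == pytest.approx(n * 0.015, rel=1e-9)

    def test_energy_bookkeeping_exact_without_escape(self, xs, rng):
        ph = uniform_box_phantom(12, voxel_mm=8.0)
        tally = TallyAccumulator(ph, "electron", "collision_deposit", 1.0, 1)
        n = 2000
        E = 0.1 + 0.5 * rng.random(n)
        center = np.array(ph.extent_cm) / 2
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        transport_electron(E, np.tile(center, (n, 1)), dirs, ph, xs, tally, rng)
        assert tally.total_deposited_MeV == pytest.approx(E.sum(), rel=1e-9)

    def test_thin_slab_deposit_matches_csda_integral(self, xs):
        """Deposited fraction in a slab thinner than the range vs the 1-D
        slowing-down integral of the same stopping-power table (2%)."""
        nz = 3
        ph = layered_slab_phantom([1] * nz, voxel_mm=5.0, nxy=40)  # 1.5 cm slab
        t_slab = nz * ph.voxel_size_cm[2]
        E0 = 0.6
        # deterministic 1-D oracle with fine steps on the same table
        E, x, h = E0, 0.0, 1e-4
        while x < t_slab and E > 0.01:
            E -= float(xs.stopping_power(np.array([0]), np.array([E]))[0]) * 1.05 * h
            x += h
        expected_deposit = E0 - max(E, 0.0)
        tally = TallyAccumulator(ph, "electron", "collision_deposit", 1.0, 1)
        rng = np.random.default_rng(4)
        n = 4000
        pos = np.tile([ph.extent_cm[0] / 2, ph.extent_cm[1] / 2, 1e-9], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        transport_electron(np.full(n, E0), pos, dirs, ph, xs, tally, rng, step_cm=0.02)
        per_hist = tally.total_deposited_MeV / n
        assert per_hist == pytest.approx(expected_deposit, rel=0.02)

    def test_electron_dose_equals_mean_energy_over_mass(self, xs):
        """Escape-proof single organ: dose/decay = <E>_electron / mass (3 sigma)."""
        ph = uniform_box_phantom(12, voxel_mm=8.0)
        spec = load_spectrum("I-131")
        sd = build_source_distribution(ph, {"medium": 1.0})
        tally = run_decay_histories(ph, sd, spec, "electron", 20_000, seed=13,
                                    xs=xs, periodic=True)
        got = tally.dose_per_decay()["medium"]
        expected = mean_energy_per_decay(spec, "electron") / ph.organ_mass("medium")
        rel_se = tally.rel_stderr()["medium"]
        assert abs(got - expected) < 3 * rel_se * got + 1e-12


class TestDoseMap:
    def test_voxel_sum_equals_total_energy(self, toy, xs):
        spec = monoline_spectrum(0.1, kind="electron")
        sd = build_source_distribution(toy, {"core": 1.0})
        grid = compute_dose_map(toy, sd, spec, "electron", 3000, seed=8, xs=xs)
        # all electrons stop inside the toy body: total = n * E * yield / n
        assert grid.total_energy_MeV() == pytest.approx(0.1, rel=1e-6)

    def test_per_mass_is_per_volume_over_density(self, toy, xs):
        spec = monoline_spectrum(0.3645)
        sd = build_source_distribution(toy, {"core": 1.0})
        grid = compute_dose_map(toy, sd, spec, "photon", 3000, seed=8, xs=xs)
        dens = grid.density
        pm = grid.energy_per_mass
        inside = dens > 0
        assert np.allclose(pm[inside], grid.energy_per_volume[inside] / dens[inside])
        assert np.all(pm[~inside] == 0.0)

    def test_electron_map_peaks_inside_source_organ(self, toy, xs):
        spec = monoline_spectrum(0.3, kind="electron")
        sd = build_source_distribution(toy, {"core": 1.0})
        grid = compute_dose_map(toy, sd, spec, "electron", 5000, seed=8, xs=xs)
        peak = np.unravel_index(np.argmax(grid.energy_per_mass), grid.energy_per_mass.shape)
        assert toy.labels[peak] == 1  # the core

    def test_misaligned_grid_rejected(self, toy, xs):
        spec = monoline_spectrum(0.3645)
        sd = build_source_distribution(toy, {"core": 1.0})
        with pytest.raises(ValueError, match="lattice"):
            compute_dose_map(toy, sd, spec, "photon", 10, seed=1, xs=xs, grid_spec="2mm")
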