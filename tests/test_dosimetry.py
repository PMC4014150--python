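import numpy as np
import pandas as pd
import pytest

from conftest import monoline_spectrum
from thyrodose.biokinetics import build_scenario, cumulated_activity_set
from thyrodose.dosimetry import (
    CLDResult,
    MGY_PER_MEV_PER_G,
    TissueWeightTable,
    assemble_organ_doses,
    compute_cld,
    effective_dose,
    load_organ_name_map,
    load_reference_dose_table,
    load_weight_table,
    map_organ_doses,
    pipeline_tissue_doses,
    thyroid_fraction_of_E,
    uptake_sweep,
)
from thyrodose.biokinetics import CumulatedActivitySet
from thyrodose.nuclear import load_spectrum
from thyrodose.phantom import OrganRecord, VoxelPhantom
from thyrodose.transport import TallyAccumulator, build_source_distribution, run_decay_histories


def _fake_tally(phantom, organ_values, kind, n=1000):
    """Tally with prescribed MeV/g-per-decay organ doses (yield folded in)."""
    t = TallyAccumulator(phantom, kind, "collision_deposit", 1.0, n_batches=2)
    for organ, val in organ_values.items():
        oid = phantom.organ(organ).organ_id
        mass = phantom.organ_mass(oid)
        t.edep[:, oid] = val * mass * n / 2.0  # split over 2 batches
    t.histories[:] = n // 2
    return t


class TestAssembly:
    def test_unit_arithmetic_one_source(self, toy):
        tallies = {"core": (_fake_tally(toy, {"core": 1.0}, "photon"),
                            _fake_tally(toy, {}, "electron"))}
        acts = CumulatedActivitySet("X", None, {"core": 1.0})
        table = assemble_organ_doses(tallies, acts)
        assert table.dose("core") == pytest.approx(1.0e6 * MGY_PER_MEV_PER_G)
        assert table.photon_pct("core") == pytest.approx(100.0)

    def test_linear_in_cumulated_activity(self, toy):
        tallies = {"core": (_fake_tally(toy, {"core": 0.3, "shell": 0.1}, "photon"),
                            _fake_tally(toy, {"core": 0.5}, "electron"))}
        t1 = assemble_organ_doses(tallies, CumulatedActivitySet("X", None, {"core": 2.0}))
        t2 = assemble_organ_doses(tallies, CumulatedActivitySet("X", None, {"core": 4.0}))
        assert np.allclose(2 * t1.organ_doses(), t2.organ_doses())

    def test_contributions_sum_to_100_and_match_hand_products(self, toy):
        """Three synthetic sources: fractions recomputed by brute force."""
        vals = {"core": {"core": 2.0, "shell": 0.5}, "shell": {"core": 0.2, "shell": 1.5}}
        tallies = {
            "core": (_fake_tally(toy, vals["core"], "photon"),
                     _fake_tally(toy, {}, "electron")),
            "shell": (_fake_tally(toy, vals["shell"], "photon"),
                      _fake_tally(toy, {}, "electron")),
        }
        atilde = {"core": 3.0, "shell": 7.0}
        table = assemble_organ_doses(tallies, CumulatedActivitySet("X", None, atilde))
        for organ in ("core", "shell"):
            expect = {s: atilde[s] * vals[s].get(organ, 0.0) for s in atilde}
            total = sum(expect.values())
            for s in atilde:
                assert table.source_pct(organ, s) == pytest.approx(100 * expect[s] / total)
            pct_sum = sum(table.source_pct(organ, s) for s in atilde)
            assert pct_sum == pytest.approx(100.0, abs=1e-9)

    def test_photon_plus_electron_percent_is_100(self, toy):
        tallies = {"core": (_fake_tally(toy, {"core": 0.7}, "photon"),
                            _fake_tally(toy, {"core": 1.3}, "electron"))}
        table = assemble_organ_doses(tallies, CumulatedActivitySet("X", None, {"core": 5.0}))
        assert table.photon_pct("core") + table.electron_pct("core") == pytest.approx(100.0)

    def test_self_dose_label(self, toy):
        tallies = {"core": (_fake_tally(toy, {"core": 1.0, "shell": 0.2}, "photon"),
                            _fake_tally(toy, {}, "electron"))}
        table = assemble_organ_doses(tallies, CumulatedActivitySet("X", None, {"core": 1.0}))
        assert table.frame.loc["core", "major_source"] == "Self-dose"
        assert table.frame.loc["shell", "major_source"] == "core"

    def test_missing_source_run_rejected(self, toy):
        tallies = {"core": (_fake_tally(toy, {"core": 1.0}, "photon"),
                            _fake_tally(toy, {}, "electron"))}
        acts = CumulatedActivitySet("X", None, {"core": 1.0, "shell": 2.0})
        with pytest.raises(ValueError, match="missing transport runs"):
            assemble_organ_doses(tallies, acts)


class TestEffectiveDose:
    def test_printed_reference_columns(self):
        w = load_weight_table()
        m = load_organ_name_map()
        doses = map_organ_doses(load_reference_dose_table("i131_iodide_15pct", "male"), m)
        assert effective_dose(doses, w) == pytest.approx(8.48, rel=0.01)

    def test_uniform_doses_return_that_dose(self):
        w = load_weight_table()
        tissues = list(w.weights) + list(w.remainder_tissues)
        tissues.remove("remainder") if "remainder" in tissues else None
        doses = pd.Series(3.7, index=[t for t in tissues if t != "remainder"])
        assert effective_dose(doses, w) == pytest.approx(3.7, rel=1e-12)

    def test_linearity_in_dose_scale(self):
        w = load_weight_table()
        m = load_organ_name_map()
        doses = map_organ_doses(load_reference_dose_table("i123_iodide_15pct", "male"), m)
        assert effective_dose(3 * doses, w) == pytest.approx(3 * effective_dose(doses, w))

    def test_degenerate_single_tissue_table(self):
        w = TissueWeightTable("one", {"thyroid": 1.0}, (), 0.0)
        assert effective_dose({"thyroid": 2.5}, w) == 2.5

    def test_missing_weighted_tissue_rejected(self):
        w = load_weight_table()
        with pytest.raises(ValueError, match="lacks weighted tissues"):
            effective_dose({"thyroid": 1.0}, w)

    def test_gender_averaged_mode(self):
        w = load_weight_table()
        m = load_organ_name_map()
        male = map_organ_doses(load_reference_dose_table("i131_iodide_15pct", "male"), m)
        female = map_organ_doses(load_reference_dose_table("i131_iodide_15pct", "female"), m)
        em, ef = effective_dose(male, w), effective_dose(female, w)
        eavg = effective_dose([male, female], w, mode="gender_averaged")
        assert em < eavg < ef

    def test_weight_table_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TissueWeightTable("bad", {"thyroid": 0.5}, (), 0.4)


class TestThyroidFraction:
    def test_printed_band(self):
        w = load_weight_table()
        m = load_organ_name_map()
        doses = map_organ_doses(load_reference_dose_table("i131_iodide_15pct", "male"), m)
        assert 95.0 <= thyroid_fraction_of_E(doses, w) <= 98.0

    def test_only_thyroid_nonzero_gives_100(self):
        w = load_weight_table()
        m = load_organ_name_map()
        doses = map_organ_doses(load_reference_dose_table("i131_iodide_15pct", "male"), m)
        only = doses * 0.0
        only["thyroid"] = 5.0
        assert thyroid_fraction_of_E(only, w) == pytest.approx(100.0)
        zero = doses.copy()
        zero["thyroid"] = 0.0
        assert thyroid_fraction_of_E(zero, w) == 0.0


class TestCLD:
    def test_single_voxel_pair_bounded_by_diagonal(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint16)
        labels[1, 1, 1] = 1
        ph = VoxelPhantom(labels, (0.4, 0.4, 0.4), [OrganRecord(1, "a", 1)])
        res = compute_cld(ph, "a", "a", n_pairs=5000, seed=1)
        diag = np.sqrt(3) * 0.4
        upper = res.bin_edges[1:][res.frequencies > 0].max()
        assert upper <= diag + 0.5
        assert res.mean_cm > 0

    def test_distant_single_voxels_mean_near_center_distance(self):
        labels = np.zeros((12, 4, 4), dtype=np.uint16)
        labels[1, 1, 1] = 1
        labels[10, 1, 1] = 2
        ph = VoxelPhantom(labels, (0.2, 0.2, 0.2),
                          [OrganRecord(1, "a", 1), OrganRecord(2, "b", 1)])
        res = compute_cld(ph, "a", "b", n_pairs=20000, seed=2, bin_width_cm=0.1)
        d_centers = 9 * 0.2
        assert res.mean_cm == pytest.approx(d_centers, abs=np.sqrt(3) * 0.2 / 2)

    def test_symmetry_under_region_swap(self, toy):
        ab = compute_cld(toy, "core", "shell", n_pairs=100_000, seed=3)
        ba = compute_cld(toy, "shell", "core", n_pairs=100_000, seed=4)
        se = np.hypot(ab.sd_cm / np.sqrt(ab.n_pairs), ba.sd_cm / np.sqrt(ba.n_pairs))
        assert abs(ab.mean_cm - ba.mean_cm) < 3 * se

    def test_histogram_matches_independent_brute_force(self, toy, rng):
        """Implementation CLD vs an independently coded dense sampler (KS)."""
        n = 200_000
        res = compute_cld(toy, "core", "shell", n_pairs=n, seed=5, bin_width_cm=0.25)
        # independent oracle: same definition, separate code path and stream
        vox = np.array(toy.voxel_size_cm)
        pts = []
        for name, lab in (("core", 1), ("shell", 2)):
            cells = np.argwhere(toy.labels == lab)
            pick = cells[rng.integers(0, len(cells), n)]
            pts.append((pick + rng.random((n, 3))) * vox)
        d_oracle = np.linalg.norm(pts[0] - pts[1], axis=1)
        hist, _ = np.histogram(d_oracle, bins=res.bin_edges)
        cdf_a = np.cumsum(res.frequencies)
        cdf_b = np.cumsum(hist / hist.sum())
        ks = np.abs(cdf_a - cdf_b).max()
        assert ks < 3 * np.sqrt((n + n) / (n * n) / 4)  # ~3 sigma two-sample bound
        se = np.hypot(res.sd_cm, d_oracle.std()) / np.sqrt(n)
        assert abs(res.mean_cm - d_oracle.mean()) < 4 * se

    def test_empty_region_rejected(self, toy):
        with pytest.raises((KeyError, ValueError)):
            compute_cld(toy, "nonexistent", "core", 10, 0)

    def test_frequencies_validated(self):
        with pytest.raises(ValueError):
            CLDResult("a", "b", np.array([0.0, 1.0]), np.array([0.5]), 0.5, 0.1, 10, 0)


class TestUptakeSweep:
    def test_thyroid_up_bladder_wall_down(self, male_phantom, xs):
        """Across 5% -> 55% uptake the thyroid dose rises and the bladder
        wall dose falls (shared tallies, so ordering is noise-free)."""
        table = uptake_sweep(male_phantom, (0.05, 0.25, 0.55), "I-131",
                             n_photon=4000, n_electron=4000, seed=7, xs=xs)
        thy = table[table.organ == "thyroid"].sort_values("uptake").dose_mGy_per_MBq.to_numpy()
        bla = table[table.organ == "bladder_wall"].sort_values("uptake").dose_mGy_per_MBq.to_numpy()
        assert np.all(np.diff(thy) > 0)
        assert np.all(np.diff(bla) < 0)

    def test_single_uptake_single_row_per_organ(self, male_phantom, xs):
        table = uptake_sweep(male_phantom, (0.15,), "I-131",
                             n_photon=1000, n_electron=1000, seed=7, xs=xs)
        assert table.groupby("organ").size().max() == 1


class TestPipelineTissueDoses:
    def test_proxy_mapping_covers_all_weighted_tissues(self, male_phantom, xs):
        spec = monoline_spectrum(0.3645)
        acts = cumulated_activity_set(build_scenario("iodide", "I-131", 0.15),
                                      load_spectrum("I-131"))
        sd = build_source_distribution(male_phantom, acts).restricted("thyroid")
        ph_t = run_decay_histories(male_phantom, sd, spec, "photon", 2000, seed=1, xs=xs)
        el_t = run_decay_histories(male_phantom, sd, monoline_spectrum(0.3, "electron"),
                                   "electron", 2000, seed=2, xs=xs)
        table = assemble_organ_doses({"thyroid": (ph_t, el_t)},
                                     CumulatedActivitySet("I-131", None, {"thyroid": 1000.0}))
        tissues = pipeline_tissue_doses(table)
        w = load_weight_table()
        e = effective_dose(tissues, w)  # raises if any weighted tissue missing
        assert e > 0
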