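"""Synthetic generator: trace kinetics, dataset bookkeeping, peak tables."""

import numpy as np
import pytest

import volsense as vs
from volsense.gcms import relative_abundance
from volsense.signal import ValidationError


@pytest.fixture
def profile():
    return vs.SensorProfile("S1", "SnO2", 1e5, 18.0, 70.0)


class TestSimulateTrace:
    def test_zero_amplitude_zero_noise_is_baseline(self, profile, schedule, quiet_noise):
        tr = vs.simulate_trace(profile, 0.0, schedule, quiet_noise)
        np.testing.assert_array_equal(tr.resistance_ohm, 1e5)
        assert len(tr) == schedule.n_points

    def test_instantaneous_response_minimum(self, schedule, quiet_noise):
        prof = vs.SensorProfile("S1", "SnO2", 1e5, 0.0, 0.0)
        tr = vs.simulate_trace(prof, 0.6, schedule, quiet_noise)
        lo, hi = vs.segment(tr).analysis
        assert tr.resistance_ohm[lo:hi].min() == pytest.approx(4e4)
        # stabilization and recovery stay at baseline when taus are 0
        assert tr.resistance_ohm[:lo].min() == 1e5
        assert tr.resistance_ohm[hi:].max() == 1e5

    def test_same_seed_identical(self, profile, schedule):
        noise = vs.NoiseModel(0.02, 1e-5, seed=3)
        t1 = vs.simulate_trace(profile, 0.5, schedule, noise)
        t2 = vs.simulate_trace(profile, 0.5, schedule, noise)
        np.testing.assert_array_equal(t1.resistance_ohm, t2.resistance_ohm)

    def test_minimum_monotone_in_amplitude(self, profile, schedule, quiet_noise):
        mins = []
        for a in np.linspace(0, 0.9, 10):
            tr = vs.simulate_trace(profile, a, schedule, quiet_noise)
            lo, hi = vs.segment(tr).analysis
            mins.append(tr.resistance_ohm[lo:hi].min())
        assert np.all(np.diff(mins) <= 0)

    def test_all_values_positive_with_noise(self, profile, schedule):
        tr = vs.simulate_trace(profile, 0.8, schedule, vs.NoiseModel(0.05, 1e-4, seed=0))
        assert np.all(tr.resistance_ohm > 0)

    def test_invalid_amplitude_rejected(self, profile, schedule, quiet_noise):
        with pytest.raises(ValidationError):
            vs.simulate_trace(profile, 1.0, schedule, quiet_noise)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValidationError):
            vs.SensorProfile("S1", "SnO2", -5.0, 18.0, 70.0)


class TestSimulateCycle:
    def test_six_traces_per_cycle(self, array, schedule, quiet_noise):
        crm = vs.default_response_matrix()
        cyc = vs.simulate_cycle(array, crm, "CK_LL", schedule, quiet_noise)
        assert len(cyc) == 6
        assert cyc.sensor_ids() == [p.sensor_id for p in array]
        assert cyc.class_label == "CK_LL"

    def test_unknown_class_rejected(self, array, schedule, quiet_noise):
        with pytest.raises(KeyError):
            vs.simulate_cycle(array, vs.default_response_matrix(), "FRIED_LL",
                              schedule, quiet_noise)

    def test_identical_columns_differ_only_by_noise(self, array, schedule):
        amps = np.tile(np.linspace(0.3, 0.6, 6)[:, None], (1, 2))
        crm = vs.ClassResponseMatrix(("A", "B"), amps)
        noise = vs.NoiseModel(0.0, 0.0, seed=0)
        ca = vs.simulate_cycle(array, crm, "A", schedule, noise)
        cb = vs.simulate_cycle(array, crm, "B", schedule, noise)
        for ta, tb in zip(ca.traces, cb.traces):
            np.testing.assert_array_equal(ta.resistance_ohm, tb.resistance_ohm)

    def test_noiseless_instant_cycle_recovers_amplitudes(self, schedule, quiet_noise):
        """ΔR/R0 through the full pipeline equals the class amplitude."""
        array = [vs.SensorProfile(f"S{i}", "SnO2", 1e5 * (i + 1), 0.0, 0.0)
                 for i in range(6)]
        crm = vs.default_response_matrix()
        cyc = vs.simulate_cycle(array, crm, "RAW_ST", schedule, quiet_noise)
        expected = crm.column("RAW_ST")
        for trace, a in zip(cyc.traces, expected):
            d = vs.delta_response(vs.normalize(trace))
            assert d == pytest.approx(a, abs=1e-12)


class TestSimulateDataset:
    def test_cycle_count_is_design_product(self, array, schedule):
        crm = vs.default_response_matrix()
        design = vs.ExperimentDesign(n_samples=24, enose_replicates=10)
        cycles, labels = vs.simulate_dataset(design, crm, array, schedule,
                                             vs.NoiseModel(seed=0))
        assert len(cycles) == 240
        assert len(labels) == 240
        # class-balanced: 3 samples x 10 replicates each
        for c in crm.classes:
            assert labels.count(c) == 30

    def test_regeneration_bit_identical(self, array, schedule):
        crm = vs.default_response_matrix()
        design = vs.ExperimentDesign(n_samples=8, enose_replicates=2)
        noise = vs.NoiseModel(seed=11)
        c1, _ = vs.simulate_dataset(design, crm, array, schedule, noise)
        c2, _ = vs.simulate_dataset(design, crm, array, schedule, noise)
        for a, b in zip(c1, c2):
            for ta, tb in zip(a.traces, b.traces):
                np.testing.assert_array_equal(ta.resistance_ohm, tb.resistance_ohm)

    def test_unbalanced_design_rejected(self, array, schedule):
        crm = vs.default_response_matrix()
        with pytest.raises(ValidationError):
            vs.simulate_dataset(vs.ExperimentDesign(n_samples=21), crm, array,
                                schedule, vs.NoiseModel(seed=0))

    def test_empty_class_list_rejected(self, array, schedule):
        with pytest.raises(ValidationError):
            vs.ClassResponseMatrix((), np.zeros((6, 0)))
        # a 0-class matrix cannot even be built; a mismatched array is the
        # nearest reachable invalid-design state
        crm = vs.default_response_matrix()
        with pytest.raises(ValidationError):
            vs.simulate_cycle(vs.default_sensor_array()[:3], crm, "CK_LL",
                              schedule, vs.NoiseModel(seed=0))


class TestDesignSummary:
    def test_study_totals(self):
        design = vs.ExperimentDesign(n_samples=48, gcms_replicates=3,
                                     enose_replicates=10, cycle_minutes=13)
        s = vs.design_summary(design)
        assert s["total_analyses"] == 624
        assert s["enose_session_minutes"] == 130

    def test_empty_design(self):
        s = vs.design_summary(vs.ExperimentDesign(n_samples=0))
        assert s["total_analyses"] == 0


class TestSeparationScaling:
    def test_zero_separation_collapses_classes(self):
        crm = vs.default_response_matrix(separation=0.0)
        eff = crm.effective_amplitudes()
        np.testing.assert_allclose(eff, np.repeat(eff[:, :1], eff.shape[1], axis=1))

    def test_unit_separation_is_identity(self):
        crm = vs.default_response_matrix(separation=1.0)
        np.testing.assert_allclose(crm.effective_amplitudes(), crm.amplitudes)


class TestSimulatePeakTable:
    def test_zero_dispersion_equals_means(self):
        lib = vs.default_compound_library(dispersion=0.0)
        table = vs.simulate_peak_table("CK_CONTROL", lib, seed=0)
        for _, row in table.data.iterrows():
            assert row["area"] == pytest.approx(lib["CK_CONTROL"][row["compound"]][1])

    def test_same_seed_identical(self):
        t1 = vs.simulate_peak_table("RAW_LL", seed=5)
        t2 = vs.simulate_peak_table("RAW_LL", seed=5)
        assert t1.data.equals(t2.data)

    def test_retention_times_increasing_and_areas_positive(self):
        table = vs.simulate_peak_table("CK_ST", seed=2)
        rt = table.data["retention_time_min"].to_numpy()
        assert np.all(np.diff(rt) >= 0)
        assert (table.data["area"] > 0).all()

    def test_hexanal_dominates_aldehydes_downstream(self):
        """Library means propagate: hexanal tops aldehyde relative abundance."""
        lib = vs.default_compound_library(dispersion=0.0)
        table = vs.simulate_peak_table("CK_LL", lib, seed=0)
        pct = relative_abundance(table)
        ald = table.data.loc[table.data["chemical_class"] == "aldehyde", "compound"]
        assert pct[ald].idxmax() == "hexanal"

    def test_empty_library_rejected(self):
        with pytest.raises(ValidationError):
            vs.simulate_peak_table("CK_LL", {"CK_LL": {}}, seed=0)
        with pytest.raises(KeyError):
            vs.simulate_peak_table("NOPE", seed=0)


def test_end_to_end_accuracy_monotone_in_separation(array, schedule):
    """Discrimination improves (weakly) as class separation grows."""
    from conftest import cooked_submatrix
    base = vs.default_response_matrix()
    mean_acc = []
    for sep in (0.0, 0.005, 1.0):
        accs = []
        for seed in range(3):
            crm = cooked_submatrix(base, sep)
            design = vs.ExperimentDesign(n_samples=16, enose_replicates=4)
            cycles, _ = vs.simulate_dataset(design, crm, array, schedule,
                                            vs.NoiseModel(seed=seed))
            X, y = vs.build_matrix(cycles)
            accs.append(vs.evaluate_split(X, y, seed=seed).accuracy)
        mean_acc.append(np.mean(accs))
    assert mean_acc[0] <= mean_acc[1] <= mean_acc[2]
    assert mean_acc[2] > 0.9
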