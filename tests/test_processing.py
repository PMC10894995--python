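"""Measurement chain: filtering, epoching, exclusion, montage, peaks."""

import numpy as np
import pandas as pd
import pytest

from seegvc import processing
from seegvc.analytic import ShellModel
from seegvc.phantom import (
    ElectrodeSet,
    Shaft,
    build_sphere_phantom,
    make_stimulation_plan,
    place_shafts,
)
from seegvc.processing import (
    EXCLUDED_EXTRACRANIAL,
    EXCLUDED_NEAR_STIM,
    EXCLUDED_VARIANCE,
    KEPT,
    Epochs,
    bipolar_montage,
    exclude_channels,
    extract_peak_table,
    preprocess,
    process_recording,
)
from seegvc.simulate import PulseModel, Recording, simulate_recording
from seegvc.pipeline import PipelineConfig, deep_pair_filter, truth_shell_model


def make_recording(data, events=None, fs=1000.0, channels=None):
    n_ch = data.shape[1]
    channels = channels or [f"C{i}" for i in range(n_ch)]
    events = events if events is not None else pd.DataFrame(
        {"pair_id": ["P00"], "sample": [len(data) // 2]}
    )
    return Recording(
        fs_hz=fs,
        data=data,
        channel_ids=channels,
        events=events,
        reference_position_mm=np.zeros(3),
    )


class TestPreprocess:
    def test_dc_offset_removed_twice_over(self):
        rec = make_recording(np.full((2000, 3), 0.42))
        ep = preprocess(rec)
        assert np.abs(ep.data).max() < 1e-12

    def test_50hz_passes_with_unit_gain(self):
        t = np.arange(4000) / 1000.0
        sig = np.sin(2 * np.pi * 50.0 * t)
        rec = make_recording(sig[:, None].copy(), events=pd.DataFrame(
            {"pair_id": ["P00"], "sample": [2000]}
        ))
        ep = preprocess(rec, baseline_window_ms=(-100.0, -10.0))
        seg = ep.data[0, 0]
        # compare epoch amplitude against the raw sinusoid in the same window
        raw = sig[1900:2201]
        ratio = np.max(np.abs(seg)) / np.max(np.abs(raw - raw[:90].mean()))
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_epoch_count_and_edge_dropping(self):
        events = pd.DataFrame({"pair_id": ["P00", "P00", "P00"], "sample": [50, 500, 1990]})
        rec = make_recording(np.zeros((2000, 2)), events=events)
        ep = preprocess(rec)  # -100..+200 ms windows: first and last fall off
        assert ep.n_epochs == 1

    def test_baseline_must_precede_event(self):
        rec = make_recording(np.zeros((1000, 1)))
        with pytest.raises(ValueError):
            preprocess(rec, baseline_window_ms=(-50.0, 50.0))


def toy_electrodes():
    """Two parallel shafts along x at y=0 and y=20, 5 contacts each."""
    rows = []
    for s, y in (("S0", 0.0), ("S1", 20.0)):
        for i in range(1, 6):
            rows.append(
                {"contact_id": f"{s}c{i:02d}", "shaft_id": s, "index": i,
                 "x_mm": 3.5 * (i - 1), "y_mm": y, "z_mm": 0.0}
            )
    shafts = [Shaft(s, np.zeros(3), np.array([1.0, 0, 0]), 5) for s in ("S0", "S1")]
    return ElectrodeSet(shafts=shafts, contacts=pd.DataFrame(rows))


@pytest.fixture(scope="module")
def exclusion_setting(study_phantom):
    electrodes = place_shafts(study_phantom, 3, 10, seed=21)
    plan = make_stimulation_plan(electrodes, 4, 2, 500, seed=22)
    cfg = PipelineConfig()
    truth = truth_shell_model(cfg)
    # a shallow contact on a shaft not used by the first stimulation pair
    first_shaft = plan.pairs.iloc[0]["anode"].split("c")[0]
    others = electrodes.contacts[electrodes.contacts["shaft_id"] != first_shaft]
    bad = others.sort_values("index")["contact_id"].iloc[-1]
    rec = simulate_recording(electrodes, plan, truth, bad_channels=[bad], seed=23)
    epochs = preprocess(rec)
    return study_phantom, electrodes, plan, rec, epochs, bad


class TestExclusion:

    def test_bad_channel_excluded_by_variance(self, exclusion_setting):
        vol, electrodes, plan, rec, epochs, bad = exclusion_setting
        pair = tuple(plan.pairs.iloc[0][["anode", "cathode"]])
        rep = exclude_channels(epochs, vol, electrodes, pair)
        assert rep.status[bad] in (EXCLUDED_VARIANCE, EXCLUDED_NEAR_STIM)
        if bad not in pair:
            assert rep.status[bad] == EXCLUDED_VARIANCE

    def test_stimulated_contacts_excluded(self, exclusion_setting):
        vol, electrodes, plan, rec, epochs, _ = exclusion_setting
        pair = tuple(plan.pairs.iloc[0][["anode", "cathode"]])
        rep = exclude_channels(epochs, vol, electrodes, pair)
        assert rep.status[pair[0]] == EXCLUDED_NEAR_STIM
        assert rep.status[pair[1]] == EXCLUDED_NEAR_STIM

    def test_extracranial_contact_excluded(self, exclusion_setting):
        vol, electrodes, plan, rec, epochs, _ = exclusion_setting
        # graft a contact into the scalp shell
        df = electrodes.contacts.copy()
        df.loc[len(df)] = {"contact_id": "S9c01", "shaft_id": "S9", "index": 1,
                           "x_mm": 0.0, "y_mm": 0.0, "z_mm": 48.0}
        elec2 = ElectrodeSet(shafts=electrodes.shafts, contacts=df)
        pair = tuple(plan.pairs.iloc[0][["anode", "cathode"]])
        rep = exclude_channels(epochs, vol, elec2, pair)
        assert rep.status["S9c01"] == EXCLUDED_EXTRACRANIAL

    def test_every_contact_reported_exactly_once(self, exclusion_setting):
        vol, electrodes, plan, rec, epochs, _ = exclusion_setting
        pair = tuple(plan.pairs.iloc[0][["anode", "cathode"]])
        rep = exclude_channels(epochs, vol, electrodes, pair)
        assert sorted(rep.status) == sorted(electrodes.contacts["contact_id"])

    def test_exclusion_monotone_in_threshold(self, exclusion_setting):
        vol, electrodes, plan, rec, epochs, _ = exclusion_setting
        pair = tuple(plan.pairs.iloc[0][["anode", "cathode"]])
        lo = exclude_channels(epochs, vol, electrodes, pair, variance_threshold_v=1e-6)
        hi = exclude_channels(epochs, vol, electrodes, pair, variance_threshold_v=10e-3)
        excluded_hi = {c for c, s in hi.status.items() if s != KEPT}
        excluded_lo = {c for c, s in lo.status.items() if s != KEPT}
        assert excluded_hi.issubset(excluded_lo)


class TestBipolarMontage:
    def test_common_mode_rejected(self):
        elec = toy_electrodes()
        tab = pd.DataFrame(
            {c: [1.0] for c in elec.contacts["contact_id"]}, index=["P00"]
        )
        out = bipolar_montage(tab, elec)
        shifted = bipolar_montage(tab + 5.0, elec)
        np.testing.assert_allclose(out.to_numpy(), shifted.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_channel_count(self):
        elec = toy_electrodes()
        assert len(elec.bipolar_channels()) == 8  # (5-1) per shaft x 2

    def test_montage_equals_direct_differencing(self, rng):
        elec = toy_electrodes()
        vals = pd.DataFrame(
            rng.normal(size=(3, 10)), columns=elec.contacts["contact_id"],
            index=["P00", "P01", "P02"],
        )
        out = bipolar_montage(vals, elec)
        for cid, a, b in elec.bipolar_channels():
            np.testing.assert_allclose(out[cid], vals[a] - vals[b])

    def test_channels_with_excluded_contact_dropped(self):
        elec = toy_electrodes()
        kept = [c for c in elec.contacts["contact_id"] if c != "S0c03"]
        tab = pd.DataFrame({c: [1.0] for c in elec.contacts["contact_id"]}, index=["P00"])
        out = bipolar_montage(tab, elec, kept_contacts=kept)
        assert len(out.columns) == 6  # S0 loses two channels


class TestPeakExtraction:
    def make_epochs(self, values_by_epoch, pair_ids):
        n_t = 21
        data = np.zeros((len(values_by_epoch), 1, n_t))
        t0 = 10
        for e, vals in enumerate(values_by_epoch):
            data[e, 0, t0 - 1 : t0 + 2] = vals
        times = (np.arange(n_t) - t0) * 1.0
        return Epochs(data=data, times_ms=times, channel_ids=["ch"],
                      pair_ids=pair_ids, fs_hz=1000.0)

    def make_plan(self, pair_ids):
        import pandas as pd
        pairs = pd.DataFrame({"pair_id": sorted(set(pair_ids)),
                              "anode": "a", "cathode": "b"})
        return type("P", (), {"pairs": pairs})()

    def test_signed_max_magnitude_pick(self):
        ep = self.make_epochs([[-3.0, 7.0, 2.0]], ["P00"])
        t = extract_peak_table(ep, self.make_plan(["P00"]))
        assert t.loc["P00", "ch"] == 7.0

    def test_negative_peak_keeps_sign(self):
        ep = self.make_epochs([[-9.0, 7.0, 2.0]], ["P00"])
        t = extract_peak_table(ep, self.make_plan(["P00"]))
        assert t.loc["P00", "ch"] == -9.0

    def test_epochs_averaged_per_pair(self):
        ep = self.make_epochs([[0, 4.0, 0], [0, 6.0, 0]], ["P00", "P00"])
        t = extract_peak_table(ep, self.make_plan(["P00"]))
        assert t.loc["P00", "ch"] == 5.0

    def test_pair_without_epochs_is_missing(self):
        ep = self.make_epochs([[0, 4.0, 0]], ["P00"])
        t = extract_peak_table(ep, self.make_plan(["P00", "P01"]))
        assert np.isnan(t.loc["P01", "ch"])


class TestFullChainIdentity:
    def test_zero_noise_chain_reproduces_scaled_truth(self, study_phantom):
        """With no noise and no filtering the measured table equals
        g x (analytic bipolar potentials) on every kept entry."""
        from seegvc.simulate import analytic_potential_table

        cfg = PipelineConfig()
        electrodes = place_shafts(study_phantom, 3, 10, seed=31)
        plan = make_stimulation_plan(
            electrodes, 5, 2, 500, seed=32,
            pair_filter=deep_pair_filter(study_phantom, cfg),
        )
        truth = truth_shell_model(cfg)
        g = 200.0
        rec = simulate_recording(
            electrodes, plan, truth, pulse=PulseModel(amplitude_gain=g),
            noise_sd_uV=0.0, seed=33,
        )
        proc = process_recording(rec, study_phantom, electrodes, plan, hp_hz=None)
        truth_table = analytic_potential_table(truth, electrodes, plan)
        meas = proc.table
        mask = meas.notna()
        assert mask.to_numpy().sum() > 50
        diff = (meas - g * truth_table)[mask].abs()
        scale = (g * truth_table)[mask].abs().max().max()
        assert np.nanmax(diff.to_numpy(float)) <= 1e-9 * scale
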