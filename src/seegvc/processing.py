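"""Measurement-side processing chain for sEEG stimulation artifacts.

High-pass filtering, epoching around stimulation events, baseline
correction, channel exclusion (noisy, extracranial, near-stimulation),
bipolar re-referencing, and stimulation-peak extraction — producing the
measured per-(stimulation pair x bipolar channel) potential table that the
simulated tables are validated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from seegvc.phantom import SCALP, SKULL, ElectrodeSet, LabeledVolume, StimulationPlan
from seegvc.simulate import REFERENCE_CHANNEL, Recording

logger = logging.getLogger(__name__)

KEPT = "kept"
EXCLUDED_VARIANCE = "excluded:variance"
EXCLUDED_EXTRACRANIAL = "excluded:extracranial"
EXCLUDED_NEAR_STIM = "excluded:near-stimulation"


@dataclass
class Epochs:
    """Segmented data: (n_epochs, n_channels, n_times), times in ms."""

    data: np.ndarray
    times_ms: np.ndarray
    channel_ids: list[str]
    pair_ids: list[str]  # stimulation pair of each epoch
    fs_hz: float

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)


@dataclass
class ChannelExclusionReport:
    """Per-channel status for one stimulation-pair context."""

    pair_id: str
    status: dict[str, str]  # contact_id -> KEPT / EXCLUDED_*
    variance_threshold_v: float
    near_stim_mm: float

    def kept(self) -> list[str]:
        return [c for c, s in self.status.items() if s == KEPT]


def highpass(
    data: np.ndarray, fs_hz: float, hp_hz: float | None, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass along axis 0; hp_hz in (0, fs/2)."""
    if not hp_hz:
        return np.asarray(data, dtype=float).copy()
    sos = scipy.signal.butter(order, hp_hz, btype="highpass", fs=fs_hz, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=0)


def preprocess(
    recording: Recording,
    hp_hz: float | None = 10.0,
    epoch_window_ms: tuple[float, float] = (-100.0, 200.0),
    baseline_window_ms: tuple[float, float] = (-100.0, -10.0),
    hp_order: int = 4,
) -> Epochs:
    """High-pass filter, segment around stimulation events, baseline correct.

    ``hp_hz=None`` (or 0) skips the filter.  Epochs whose window exceeds the
    record bounds are dropped with a logged warning.  The per-epoch mean of
    the baseline window is subtracted channel-wise; the baseline window must
    precede the event.
    """
    if baseline_window_ms[1] > 0:
        raise ValueError("baseline window must precede the event")
    if baseline_window_ms[0] < epoch_window_ms[0] or baseline_window_ms[1] > epoch_window_ms[1]:
        raise ValueError("baseline window must lie within the epoch window")
    fs = recording.fs_hz
    filtered = highpass(recording.data, fs, hp_hz, hp_order)
    w0 = int(round(epoch_window_ms[0] * fs / 1000.0))
    w1 = int(round(epoch_window_ms[1] * fs / 1000.0))
    times = np.arange(w0, w1 + 1) * 1000.0 / fs
    b0 = int(round(baseline_window_ms[0] * fs / 1000.0)) - w0
    b1 = int(round(baseline_window_ms[1] * fs / 1000.0)) - w0
    segs, pids = [], []
    for ev in recording.events.itertuples():
        s = int(ev.sample)
        if s + w0 < 0 or s + w1 >= recording.n_samples:
            logger.warning("dropping epoch at sample %d: window out of bounds", s)
            continue
        seg = filtered[s + w0 : s + w1 + 1].T  # (n_channels, n_times)
        seg = seg - seg[:, b0 : b1 + 1].mean(axis=1, keepdims=True)
        segs.append(seg)
        pids.append(ev.pair_id)
    data = np.stack(segs) if segs else np.empty((0, filtered.shape[1], len(times)))
    return Epochs(
        data=data,
        times_ms=times,
        channel_ids=list(recording.channel_ids),
        pair_ids=pids,
        fs_hz=fs,
    )


def screen_channels(
    epochs: Epochs,
    volume: LabeledVolume,
    electrodes: ElectrodeSet,
    variance_threshold_v: float = 10e-3,
    after_peak_window_ms: tuple[float, float] = (5.0, 200.0),
) -> dict[str, str]:
    """Pair-independent channel screen: after-peak signal spread and
    extracranial position.

    The after-peak criterion is the standard deviation of the post-event
    window, pooled over all epochs, exceeding the threshold (10 mV default).
    Contacts whose voxel label is skull, scalp or outside are extracranial.
    """
    tmask = (epochs.times_ms >= after_peak_window_ms[0]) & (
        epochs.times_ms <= after_peak_window_ms[1]
    )
    status: dict[str, str] = {}
    contact_ids = electrodes.contacts["contact_id"].tolist()
    labels = volume.label_at(electrodes.positions(contact_ids))
    for cid, lab in zip(contact_ids, labels):
        if lab in (0, SCALP, SKULL):
            status[cid] = EXCLUDED_EXTRACRANIAL
            continue
        if cid in epochs.channel_ids and epochs.n_epochs:
            seg = epochs.data[:, epochs.channel_index(cid), :][:, tmask]
            if seg.std() > variance_threshold_v:
                status[cid] = EXCLUDED_VARIANCE
                continue
        status[cid] = KEPT
    return status


def exclude_channels(
    epochs: Epochs,
    volume: LabeledVolume,
    electrodes: ElectrodeSet,
    pair: tuple[str, str],
    variance_threshold_v: float = 10e-3,
    near_stim_mm: float = 2.5,
    after_peak_window_ms: tuple[float, float] = (5.0, 200.0),
    base_status: dict[str, str] | None = None,
) -> ChannelExclusionReport:
    """Exclusion report for one stimulation pair.

    A contact is excluded when it (a) belongs to the stimulated pair, is
    adjacent to it on the same shaft, or lies within ``near_stim_mm`` of
    either stimulating contact; (b) sits in skull/scalp/outside; or (c) its
    after-peak signal spread exceeds the variance threshold.  Every contact
    appears exactly once; the first matching criterion (in the order
    near-stimulation, extracranial, variance) determines the status.
    """
    anode, cathode = pair
    if base_status is None:
        base_status = screen_channels(
            epochs, volume, electrodes, variance_threshold_v, after_peak_window_ms
        )
    contacts = electrodes.contacts.set_index("contact_id")
    pa, pc = electrodes.position(anode), electrodes.position(cathode)
    sa = contacts.loc[anode]
    sc = contacts.loc[cathode]
    status: dict[str, str] = {}
    for row in electrodes.contacts.itertuples():
        cid = row.contact_id
        near = cid in (anode, cathode)
        if not near and row.shaft_id == sa["shaft_id"]:
            near = abs(row.index - sa["index"]) <= 1 or abs(row.index - sc["index"]) <= 1
        if not near:
            p = np.array([row.x_mm, row.y_mm, row.z_mm])
            near = min(np.linalg.norm(p - pa), np.linalg.norm(p - pc)) <= near_stim_mm
        status[cid] = EXCLUDED_NEAR_STIM if near else base_status[cid]
    pid = None
    return ChannelExclusionReport(
        pair_id=pid if pid else f"{anode}|{cathode}",
        status=status,
        variance_threshold_v=variance_threshold_v,
        near_stim_mm=near_stim_mm,
    )


def bipolar_montage(
    obj: Epochs | pd.DataFrame,
    electrodes: ElectrodeSet,
    kept_contacts: list[str] | None = None,
):
    """Re-reference to the bipolar montage: one channel per adjacent
    kept-contact pair on each shaft, signal(contact k) - signal(contact k+1).

    Accepts epoched data (returns new :class:`Epochs`) or a table whose
    columns are monopolar contact values (returns the differenced table).
    Channels involving an excluded contact are dropped; an empty result is
    returned with a warning when no adjacent kept pair exists.
    """
    pairs = electrodes.adjacent_pairs()
    if kept_contacts is not None:
        kept = set(kept_contacts)
        pairs = [(a, b) for a, b in pairs if a in kept and b in kept]
    if not pairs:
        logger.warning("bipolar montage is empty: no adjacent kept-contact pairs")
    chan_ids = [f"{a}|{b}" for a, b in pairs]
    if isinstance(obj, Epochs):
        idx_a = [obj.channel_index(a) for a, _ in pairs]
        idx_b = [obj.channel_index(b) for _, b in pairs]
        data = obj.data[:, idx_a, :] - obj.data[:, idx_b, :]
        if not pairs:
            data = np.empty((obj.n_epochs, 0, len(obj.times_ms)))
        return Epochs(
            data=data,
            times_ms=obj.times_ms,
            channel_ids=chan_ids,
            pair_ids=list(obj.pair_ids),
            fs_hz=obj.fs_hz,
        )
    df = obj
    out = pd.DataFrame(index=df.index, columns=chan_ids, dtype=float)
    for (a, b), cid in zip(pairs, chan_ids):
        out[cid] = df[a] - df[b]
    return out


def extract_peak_table(
    epochs: Epochs,
    plan: StimulationPlan,
    peak_window_samples: int = 1,
) -> pd.DataFrame:
    """Measured potential table: per epoch and channel, the signed value of
    largest magnitude within +/-1 sample of the event, averaged across the
    epochs of each stimulation pair (rows = pairs, columns = channels, V)."""
    it0 = int(np.argmin(np.abs(epochs.times_ms)))
    sl = slice(max(it0 - peak_window_samples, 0), it0 + peak_window_samples + 1)
    win = epochs.data[:, :, sl]
    peak_idx = np.argmax(np.abs(win), axis=2)
    peaks = np.take_along_axis(win, peak_idx[:, :, None], axis=2)[:, :, 0]
    table = pd.DataFrame(
        index=plan.pairs["pair_id"].tolist(), columns=epochs.channel_ids, dtype=float
    )
    table.index.name = "pair_id"
    pair_arr = np.array(epochs.pair_ids)
    for pid in table.index:
        rows = peaks[pair_arr == pid]
        if len(rows) == 0:
            logger.warning("stimulation pair %s has no surviving epochs", pid)
            continue
        table.loc[pid] = rows.mean(axis=0)
    return table


@dataclass
class ProcessedMeasurement:
    """Output of the full measurement chain."""

    table: pd.DataFrame  # rows = pairs, cols = bipolar channels, V; NaN = excluded
    rms_v: float  # RMS over time and kept bipolar channels of the hp data
    exclusions: dict[str, ChannelExclusionReport]  # by pair_id
    montage: list[tuple[str, str, str]]  # (channel_id, contact_a, contact_b)
    global_status: dict[str, str] = field(default_factory=dict)


def process_recording(
    recording: Recording,
    volume: LabeledVolume,
    electrodes: ElectrodeSet,
    plan: StimulationPlan,
    hp_hz: float | None = 10.0,
    epoch_window_ms: tuple[float, float] = (-100.0, 200.0),
    baseline_window_ms: tuple[float, float] = (-100.0, -10.0),
    variance_threshold_v: float = 10e-3,
    near_stim_mm: float = 2.5,
) -> ProcessedMeasurement:
    """Full measurement chain: filter, epoch, baseline, exclude, bipolar
    re-reference, peak-extract; also computes the RMS normalizer over time
    and kept bipolar channels of the preprocessed continuous signal."""
    epochs = preprocess(recording, hp_hz, epoch_window_ms, baseline_window_ms)
    base_status = screen_channels(epochs, volume, electrodes, variance_threshold_v)
    montage = electrodes.bipolar_channels()
    bip = bipolar_montage(epochs, electrodes)  # full montage on epochs
    peaks = extract_peak_table(bip, plan)

    table = pd.DataFrame(index=peaks.index, columns=peaks.columns, dtype=float)
    table.index.name = "pair_id"
    exclusions: dict[str, ChannelExclusionReport] = {}
    for row in plan.pairs.itertuples():
        rep = exclude_channels(
            epochs,
            volume,
            electrodes,
            (row.anode, row.cathode),
            variance_threshold_v,
            near_stim_mm,
            base_status=base_status,
        )
        rep.pair_id = row.pair_id
        exclusions[row.pair_id] = rep
        kept = set(rep.kept())
        for cid, a, b in montage:
            if a in kept and b in kept:
                table.loc[row.pair_id, cid] = peaks.loc[row.pair_id, cid]

    # RMS normalizer: preprocessed continuous signal, bipolar channels whose
    # contacts pass the pair-independent screen
    cont = highpass(recording.data, recording.fs_hz, hp_hz)
    kept_global = {c for c, s in base_status.items() if s == KEPT}
    cols = []
    for cid, a, b in montage:
        if a in kept_global and b in kept_global:
            ia = recording.channel_ids.index(a)
            ib = recording.channel_ids.index(b)
            cols.append(cont[:, ia] - cont[:, ib])
    rms = float(np.sqrt(np.mean(np.square(cols)))) if cols else float("nan")
    return ProcessedMeasurement(
        table=table,
        rms_v=rms,
        exclusions=exclusions,
        montage=montage,
        global_status=base_status,
    )
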