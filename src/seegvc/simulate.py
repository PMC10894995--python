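"""Synthetic sEEG recordings of volume-conducted stimulation artifacts.

Emulates the acquisition of depth-electrode recordings during electric
stimulation mapping: brief (0.3 ms) stimulation pulses sampled at 1000 Hz so
that a single sample carries the main deflection, capacitive (first-order
high-pass) filter tails, a reference electrode in the white matter, additive
Gaussian noise, and occasional bad channels.  Ground truth comes from the
analytic concentric-sphere solver — deliberately independent of the FEM
path under test, so FEM discretization error stays measurable end to end.

The generator gain ``g`` is defined as the ratio between the recorded peak
and the true volume-conducted potential: the filtered, decimated pulse shape
is normalized to unit peak before it is scaled by ``g``.  The raw sampled
waveform (whose peak falls strictly below the continuous pulse amplitude —
the undersampling the validation scaling factor compensates) is available
from :func:`pulse_waveform`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seegvc.analytic import ShellModel, analytic_dipole_potential
from seegvc.errors import UnsupportedConfigurationError
from seegvc.fem import UNIT_CURRENT_A, pair_dipole
from seegvc.phantom import ElectrodeSet, StimulationPlan

logger = logging.getLogger(__name__)

#: channel id of the (synthetic) white-matter reference electrode
REFERENCE_CHANNEL = "REF"

#: default bad-channel noise standard deviation (V); comfortably above the
#: 10 mV variance-exclusion threshold so screening trips decisively
BAD_CHANNEL_SD_V = 25e-3


@dataclass
class PulseModel:
    """Stimulation pulse: duration, capacitive corner, ground-truth gain g."""

    duration_ms: float = 0.3
    highpass_corner_hz: float = 150.0
    amplitude_gain: float = 200.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be positive")


@dataclass
class Recording:
    """Multichannel sampled time series with stimulation events.

    ``data`` is samples x channels in volts; monopolar channels are contact
    potentials relative to the white-matter reference; the reference channel
    itself is identically zero before noise.
    """

    fs_hz: float
    data: np.ndarray  # (n_samples, n_channels), V
    channel_ids: list[str]
    events: pd.DataFrame  # columns: pair_id, sample
    reference_position_mm: np.ndarray
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.events) and self.events["sample"].max() >= len(self.data):
            raise ValueError("event sample outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[:, self.channel_ids.index(channel_id)]


def pulse_waveform(
    pulse: PulseModel, fs_hz: float = 1000.0, oversample: int = 20
) -> np.ndarray:
    """Sampled stimulation-artifact waveform (in units of the continuous
    pulse amplitude).

    A unit rectangular pulse of the stated duration is generated on an
    ``oversample``-times finer grid, passed through a first-order RC
    high-pass (the capacitive coupling whose tails outlast the pulse), and
    decimated to ``fs_hz``.  With a finite corner frequency the sampled peak
    is strictly below 1 — the sampling-related attenuation the validation
    scaling factor absorbs.
    """
    if oversample < 10:
        raise ValueError("oversample must be >= 10")
    dt = 1.0 / (fs_hz * oversample)
    if pulse.highpass_corner_hz > 0:
        tau = 1.0 / (2.0 * np.pi * pulse.highpass_corner_hz)
        tail_ms = max(8.0, 10.0 * tau * 1e3)
    else:
        tau = np.inf
        tail_ms = 8.0
    n_over = int(np.ceil((pulse.duration_ms + tail_ms) * 1e-3 / dt))
    t = np.arange(n_over) * dt
    x = (t < pulse.duration_ms * 1e-3).astype(float)
    if np.isfinite(tau):
        # exact first-order RC high-pass: y[k] = a*(y[k-1] + x[k] - x[k-1])
        a = tau / (tau + dt)
        y = np.empty_like(x)
        y[0] = a * x[0]
        for k in range(1, n_over):
            y[k] = a * (y[k - 1] + x[k] - x[k - 1])
    else:
        y = x
    return y[::oversample].copy()


def analytic_potential_table(
    truth_model: ShellModel,
    electrodes: ElectrodeSet,
    plan: StimulationPlan,
    montage: list[tuple[str, str, str]] | None = None,
    current_a: float = UNIT_CURRENT_A,
) -> pd.DataFrame:
    """Ground-truth bipolar potential table from the analytic sphere solver
    (rows = stimulation pairs, columns = bipolar channels, V).  Matched-model
    counterpart of the FEM table for end-to-end checks."""
    if montage is None:
        montage = electrodes.bipolar_channels()
    contact_ids = sorted({c for _, a, b in montage for c in (a, b)})
    pos = electrodes.positions(contact_ids)
    rows = {}
    for row in plan.pairs.itertuples():
        dip = pair_dipole(electrodes, row.anode, row.cathode, current_a)
        v = dict(zip(contact_ids, analytic_dipole_potential(truth_model, dip, pos)))
        rows[row.pair_id] = {cid: v[a] - v[b] for cid, a, b in montage}
    table = pd.DataFrame(rows).T.reindex(
        index=plan.pairs["pair_id"].tolist(), columns=[c[0] for c in montage]
    )
    table.index.name = "pair_id"
    return table


def simulate_recording(
    electrodes: ElectrodeSet,
    plan: StimulationPlan,
    truth_model: ShellModel,
    pulse: PulseModel | None = None,
    noise_sd_uV: float = 2.0,
    bad_channels: list[str] | None = None,
    duration_samples: int | None = None,
    seed: int = 0,
    fs_hz: float = 1000.0,
    reference_position_mm=(0.0, 0.0, 0.0),
    oversample: int = 20,
    current_a: float = UNIT_CURRENT_A,
) -> Recording:
    """Synthetic monopolar sEEG recording of the stimulation artifacts.

    For every event, each monopolar channel receives
    ``g * (V(contact) - V(reference)) * w`` with ``w`` the unit-peak sampled
    pulse, plus white Gaussian noise of ``noise_sd_uV``; channels listed in
    ``bad_channels`` are overwritten with large-variance noise.
    Deterministic given ``seed``.
    """
    if pulse is None:
        pulse = PulseModel()
    ref = np.asarray(reference_position_mm, dtype=float)
    if np.linalg.norm(ref) >= truth_model.radii_mm[0]:
        raise UnsupportedConfigurationError(
            "reference electrode must sit in the innermost (white matter) shell"
        )
    rng = np.random.default_rng(seed)
    contact_ids = electrodes.contacts["contact_id"].tolist()
    channel_ids = contact_ids + [REFERENCE_CHANNEL]
    positions = electrodes.positions(contact_ids)
    eval_points = np.vstack([positions, ref[None, :]])

    w = pulse_waveform(pulse, fs_hz=fs_hz, oversample=oversample)
    w = w / np.max(np.abs(w))  # unit peak: g is the recorded-peak gain
    if duration_samples is None:
        last = int(plan.events["sample"].max()) if len(plan.events) else 0
        duration_samples = last + len(w) + int(0.5 * fs_hz)

    data = rng.normal(0.0, noise_sd_uV * 1e-6, size=(duration_samples, len(channel_ids)))
    # volume-conducted artifact, per stimulation pair
    pair_potentials = {}
    for row in plan.pairs.itertuples():
        dip = pair_dipole(electrodes, row.anode, row.cathode, current_a)
        v = analytic_dipole_potential(truth_model, dip, eval_points)
        pair_potentials[row.pair_id] = v[:-1] - v[-1]  # monopolar vs reference
    g = pulse.amplitude_gain
    n_contacts = len(contact_ids)
    for ev in plan.events.itertuples():
        s0 = int(ev.sample)
        stop = min(s0 + len(w), duration_samples)
        data[s0:stop, :n_contacts] += g * np.outer(
            w[: stop - s0], pair_potentials[ev.pair_id]
        )
    bad_channels = list(bad_channels or [])
    for cid in bad_channels:
        j = channel_ids.index(cid)
        data[:, j] = rng.normal(0.0, BAD_CHANNEL_SD_V, size=duration_samples)
    return Recording(
        fs_hz=fs_hz,
        data=data,
        channel_ids=channel_ids,
        events=plan.events.copy(),
        reference_position_mm=ref,
        bad_channels=bad_channels,
    )
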