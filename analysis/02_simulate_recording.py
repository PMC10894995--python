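#!/usr/bin/env python
"""Stage 2: ground-truth sEEG recording.

Simulates the monopolar recording of the volume-conducted stimulation
artifacts with the analytic five-shell solver: 0.3 ms pulses at 1000 Hz
with capacitive tails, gain 200 between true potential and recorded peak,
2 uV noise, two bad channels, white-matter reference.  Writes recording.h5.
"""

from pathlib import Path

import numpy as np

from seegvc import io
from seegvc.pipeline import PipelineConfig, truth_shell_model
from seegvc.simulate import PulseModel, simulate_recording

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = PipelineConfig.from_dict(io.load_config_yaml(OUT / "config.yaml"))
    electrodes = io.load_electrodes_tsv(OUT / "electrodes.tsv")
    plan = io.load_plan_tsv(OUT / "stim_pairs.tsv", OUT / "stim_events.tsv")

    rng = np.random.default_rng(cfg.seed + 2)
    stim = set(plan.pairs["anode"]) | set(plan.pairs["cathode"])
    eligible = [c for c in electrodes.contacts["contact_id"] if c not in stim]
    bad = sorted(rng.choice(eligible, size=cfg.n_bad_channels, replace=False).tolist())

    rec = simulate_recording(
        electrodes,
        plan,
        truth_shell_model(cfg),
        pulse=PulseModel(cfg.pulse_duration_ms, cfg.pulse_corner_hz, cfg.amplitude_gain),
        noise_sd_uV=cfg.noise_sd_uV,
        bad_channels=bad,
        seed=cfg.seed + 3,
        fs_hz=cfg.fs_hz,
        reference_position_mm=cfg.reference_position_mm,
    )
    io.save_recording_h5(rec, OUT / "recording.h5")
    peak = np.abs(rec.data).max() * 1e6
    print(f"recording: {rec.n_samples} samples x {len(rec.channel_ids)} channels @ {rec.fs_hz:g} Hz")
    print(f"largest recorded deflection {peak:.0f} uV; bad channels {bad}")
    print(f"wrote recording.h5 to {OUT}")


if __name__ == "__main__":
    main()
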