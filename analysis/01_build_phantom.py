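#!/usr/bin/env python
"""Stage 1: synthetic anatomy and implantation.

Builds the five-shell sphere phantom (50 mm outer radius, 2 mm voxels),
places five converging depth-electrode shafts (12 contacts each, 3.5 mm
pitch), and draws 12 stimulated neighboring-contact pairs with 3 events
each.  Writes the NIfTI phantom, the electrode table, the stimulation plan,
and the study configuration under results/study/.
"""

import sys
from pathlib import Path

from seegvc import io
from seegvc.phantom import build_sphere_phantom, make_stimulation_plan, place_shafts
from seegvc.pipeline import PipelineConfig, deep_pair_filter

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    io.dump_config_yaml(cfg.to_dict(), OUT / "config.yaml")

    volume = build_sphere_phantom(cfg.radii_mm_by_tissue, cfg.voxel_size_mm)
    io.save_labeled_volume(volume, OUT / "phantom.nii.gz")
    electrodes = place_shafts(volume, cfg.n_shafts, cfg.contacts_per_shaft, seed=cfg.seed)
    io.save_electrodes_tsv(electrodes, OUT / "electrodes.tsv")
    plan = make_stimulation_plan(
        electrodes, cfg.n_pairs, cfg.n_events_per_pair, cfg.inter_event_samples,
        seed=cfg.seed + 1, pair_filter=deep_pair_filter(volume, cfg),
    )
    io.save_plan_tsv(plan, OUT / "stim_pairs.tsv", OUT / "stim_events.tsv")

    import numpy as np

    print(f"phantom: shape {volume.shape}, {int(np.count_nonzero(volume.labels))} head voxels")
    print(f"implantation: {len(electrodes.shafts)} shafts, {len(electrodes.contacts)} contacts")
    print(f"stimulation: {len(plan.pairs)} neighboring pairs, {len(plan.events)} events")
    print(f"wrote phantom.nii.gz, electrodes.tsv, stim_{{pairs,events}}.tsv to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
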