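"""File formats: NIfTI labeled volumes, TSV electrode/plan/potential tables,
HDF5 recordings and meshes, YAML pipeline configs.

All on-disk coordinates are millimeters in world space; labeled volumes
carry voxel size and origin in the NIfTI header (the pipeline assumes cubic
voxels and rejects anisotropic data with a resampling hint).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from seegvc.fem import HexMesh
from seegvc.phantom import ElectrodeSet, LabeledVolume, Shaft, StimulationPlan
from seegvc.simulate import Recording


def save_labeled_volume(volume: LabeledVolume, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] *= volume.voxel_size_mm
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    img.header.set_zooms((volume.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_labeled_volume(path) -> LabeledVolume:
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise ValueError(
            f"anisotropic voxels {zooms.tolist()} are not supported; resample "
            "the volume to cubic voxels (e.g. 1 mm) first"
        )
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6):
        raise ValueError("rotated/sheared affines are not supported; resample first")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("labeled volume must contain integer tissue labels")
        data = np.round(data).astype(np.int16)
    return LabeledVolume(
        labels=np.asarray(data, dtype=np.int16),
        voxel_size_mm=float(zooms[0]),
        origin_mm=affine[:3, 3].astype(float),
    )


def save_electrodes_tsv(electrodes: ElectrodeSet, path) -> None:
    electrodes.contacts.to_csv(path, sep="\t", index=False)


def load_electrodes_tsv(path) -> ElectrodeSet:
    df = pd.read_csv(path, sep="\t")
    required = {"contact_id", "shaft_id", "index", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"electrode table must have columns {sorted(required)}")
    shafts = []
    for sid, grp in df.groupby("shaft_id", sort=True):
        grp = grp.sort_values("index")
        pos = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        direction = pos[0] - pos[-1]  # shallow -> deep (tip)
        nrm = np.linalg.norm(direction)
        shafts.append(
            Shaft(
                shaft_id=str(sid),
                entry_mm=pos[-1],
                direction=direction / nrm if nrm > 0 else direction,
                n_contacts=len(grp),
            )
        )
    return ElectrodeSet(shafts=shafts, contacts=df)


def save_plan_tsv(plan: StimulationPlan, pairs_path, events_path) -> None:
    plan.pairs.to_csv(pairs_path, sep="\t", index=False)
    plan.events.to_csv(events_path, sep="\t", index=False)


def load_plan_tsv(pairs_path, events_path) -> StimulationPlan:
    pairs = pd.read_csv(pairs_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    known = set(pairs["pair_id"])
    if not set(events["pair_id"]).issubset(known):
        raise ValueError("events reference unknown stimulation pairs")
    return StimulationPlan(pairs=pairs, events=events)


def save_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="pair_id")


def load_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pair_id")


def save_recording_h5(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip")
        f.attrs["fs_hz"] = recording.fs_hz
        f.create_dataset(
            "channel_ids", data=np.array(recording.channel_ids, dtype="S")
        )
        f.create_dataset(
            "event_pair_ids", data=np.array(recording.events["pair_id"], dtype="S")
        )
        f.create_dataset("event_samples", data=recording.events["sample"].to_numpy())
        f.create_dataset("reference_position_mm", data=recording.reference_position_mm)
        f.create_dataset("bad_channels", data=np.array(recording.bad_channels, dtype="S"))


def load_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame(
            {
                "pair_id": [s.decode() for s in f["event_pair_ids"][()]],
                "sample": f["event_samples"][()].astype(int),
            }
        )
        return Recording(
            fs_hz=float(f.attrs["fs_hz"]),
            data=f["data"][()],
            channel_ids=[s.decode() for s in f["channel_ids"][()]],
            events=events,
            reference_position_mm=f["reference_position_mm"][()],
            bad_channels=[s.decode() for s in f["bad_channels"][()]],
        )


def save_mesh_h5(mesh: HexMesh, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes_mm", data=mesh.nodes_mm, compression="gzip")
        f.create_dataset("elements", data=mesh.elements, compression="gzip")
        f.create_dataset("element_label", data=mesh.element_label, compression="gzip")
        f.create_dataset("element_of_voxel", data=mesh.element_of_voxel, compression="gzip")
        f.create_dataset("origin_mm", data=mesh.origin_mm)
        f.attrs["voxel_size_mm"] = mesh.voxel_size_mm
        f.attrs["node_shift"] = mesh.node_shift


def load_mesh_h5(path) -> HexMesh:
    with h5py.File(path, "r") as f:
        return HexMesh(
            nodes_mm=f["nodes_mm"][()],
            elements=f["elements"][()],
            element_label=f["element_label"][()],
            voxel_size_mm=float(f.attrs["voxel_size_mm"]),
            origin_mm=f["origin_mm"][()],
            element_of_voxel=f["element_of_voxel"][()],
            node_shift=float(f.attrs["node_shift"]),
        )


def load_config_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_config_yaml(config: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")
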