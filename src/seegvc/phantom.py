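"""Synthetic head phantoms, electrode geometries, and stimulation plans.

Concentric-sphere phantoms stand in for segmented patient anatomy: nested
shells of scalp, skull, CSF, gray and white matter on a regular voxel grid.
Depth-electrode shafts are straight segments from a scalp entry point toward
a deep interior target, carrying equally spaced cylindrical contacts
(3.5 mm center-to-center: 2 mm contact + 1.5 mm gap).  Stimulation plans
select pairs of neighboring contacts on a shaft and lay their stimulation
events out on a regular sample grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seegvc.errors import DegenerateShellError, InvalidGeometryError, PlacementError

logger = logging.getLogger(__name__)

# Fixed integer label codes (stable file contract).
OUTSIDE, SCALP, SKULL, CSF, GRAY, WHITE = 0, 1, 2, 3, 4, 5

#: tissue name -> label, ordered outermost to innermost
TISSUE_LABELS = {"scalp": SCALP, "skull": SKULL, "csf": CSF, "gray": GRAY, "white": WHITE}
LABEL_NAMES = {v: k for k, v in TISSUE_LABELS.items()}

#: depth order, outermost first
TISSUE_ORDER = ("scalp", "skull", "csf", "gray", "white")

#: adult-head-like default shell radii (mm)
DEFAULT_RADII_MM = {"scalp": 92.0, "skull": 86.0, "csf": 80.0, "gray": 78.0, "white": 66.0}

#: contact pitch along a shaft: 2 mm contact + 1.5 mm gap
CONTACT_PITCH_MM = 3.5

# Conductivities in S/m for the three isotropic model levels.  5C resolves
# white and gray matter; 4C merges them into one brain compartment; 3C
# additionally treats CSF as brain.
CONDUCTIVITY_TABLES = {
    "5C": {WHITE: 0.14, GRAY: 0.33, CSF: 1.79, SKULL: 0.01, SCALP: 0.43},
    "4C": {WHITE: 0.33, GRAY: 0.33, CSF: 1.79, SKULL: 0.01, SCALP: 0.43},
    "3C": {WHITE: 0.33, GRAY: 0.33, CSF: 0.33, SKULL: 0.01, SCALP: 0.43},
}

MODEL_LEVELS = tuple(CONDUCTIVITY_TABLES)


@dataclass
class LabeledVolume:
    """Regular voxel grid of integer tissue labels.

    ``origin_mm`` is the world coordinate of the *center* of voxel (0,0,0);
    world coordinates are millimeters, right-handed, 0-based voxel indexing.
    """

    labels: np.ndarray  # integer array, shape (nx, ny, nz)
    voxel_size_mm: float
    origin_mm: np.ndarray  # (3,)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.voxel_size_mm <= 0:
            raise InvalidGeometryError("voxel_size_mm must be positive")
        if self.labels.ndim != 3:
            raise InvalidGeometryError("labels must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Voxel index containing each point (half-open voxel intervals)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.floor((p - self.origin_mm) / self.voxel_size_mm + 0.5).astype(int)

    def label_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Tissue label at each point; 0 for points off the grid."""
        idx = self.voxel_index(points_mm)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        ok = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        if ok.any():
            i = idx[ok]
            out[ok] = self.labels[i[:, 0], i[:, 1], i[:, 2]]
        return out

    def voxel_centers(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(ijk, dtype=float) * self.voxel_size_mm


@dataclass
class ConductivityProfile:
    """Map from tissue label to conductivity (S/m) for one model level."""

    model_level: str
    sigma_by_label: dict[int, float]

    def sigma_for(self, labels: np.ndarray) -> np.ndarray:
        lut = np.zeros(max(self.sigma_by_label) + 1)
        for lab, s in self.sigma_by_label.items():
            lut[lab] = s
        return lut[np.asarray(labels)]


@dataclass
class Shaft:
    shaft_id: str
    entry_mm: np.ndarray
    direction: np.ndarray  # unit vector, entry -> interior
    n_contacts: int


@dataclass
class ElectrodeSet:
    """Shafts plus a flat table of contact centers.

    ``contacts`` columns: contact_id, shaft_id, index (1 = deepest), x_mm,
    y_mm, z_mm.
    """

    shafts: list[Shaft] = field(default_factory=list)
    contacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["contact_id", "shaft_id", "index", "x_mm", "y_mm", "z_mm"]
        )
    )

    def positions(self, contact_ids=None) -> np.ndarray:
        df = self.contacts.set_index("contact_id")
        if contact_ids is None:
            return df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        return df.loc[list(contact_ids), ["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def position(self, contact_id: str) -> np.ndarray:
        return self.positions([contact_id])[0]

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """All (contact k, contact k+1) pairs on every shaft, deep to shallow."""
        pairs = []
        for sid, grp in self.contacts.groupby("shaft_id", sort=True):
            grp = grp.sort_values("index")
            ids = grp["contact_id"].tolist()
            pairs.extend(zip(ids[:-1], ids[1:]))
        return pairs

    def bipolar_channels(self) -> list[tuple[str, str, str]]:
        """Full bipolar montage: one channel per adjacent contact pair."""
        return [(f"{a}|{b}", a, b) for a, b in self.adjacent_pairs()]


@dataclass
class StimulationPlan:
    """Stimulated neighboring-contact pairs and their event times.

    ``pairs`` columns: pair_id, anode, cathode.
    ``events`` columns: pair_id, sample.
    """

    pairs: pd.DataFrame
    events: pd.DataFrame

    def pair_midpoints(self, electrodes: ElectrodeSet) -> pd.Series:
        mids = {}
        for row in self.pairs.itertuples():
            mids[row.pair_id] = 0.5 * (
                electrodes.position(row.anode) + electrodes.position(row.cathode)
            )
        return pd.Series(mids)


def build_sphere_phantom(
    radii_mm_by_tissue: dict[str, float] | None = None,
    voxel_size_mm: float = 1.0,
    grid_margin_mm: float = 2.0,
) -> LabeledVolume:
    """Concentric-sphere phantom: each voxel labeled by the innermost sphere
    containing its center; outside the scalp sphere -> 0.

    Radii must be strictly decreasing in depth order (scalp > skull > ... ).
    A subset of tissues is allowed (e.g. a four-shell scalp/skull/CSF/gray
    phantom); the grid is symmetric about the world origin, with a voxel
    centered exactly at (0,0,0).
    """
    if radii_mm_by_tissue is None:
        radii_mm_by_tissue = DEFAULT_RADII_MM
    if voxel_size_mm <= 0:
        raise InvalidGeometryError("voxel_size_mm must be positive")
    tissues = [t for t in TISSUE_ORDER if t in radii_mm_by_tissue]
    if not tissues:
        raise InvalidGeometryError("no known tissues in radii map")
    unknown = set(radii_mm_by_tissue) - set(TISSUE_ORDER)
    if unknown:
        raise InvalidGeometryError(f"unknown tissues: {sorted(unknown)}")
    radii = np.array([radii_mm_by_tissue[t] for t in tissues], dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) >= 0):
        raise InvalidGeometryError(
            "radii must be positive and strictly decreasing from scalp inward"
        )
    thickness = np.diff(-radii)  # shell thicknesses, outermost first
    if len(thickness) and voxel_size_mm > thickness.min():
        logger.warning(
            "voxel size %.2f mm exceeds thinnest shell (%.2f mm); "
            "shells may be poorly resolved",
            voxel_size_mm,
            thickness.min(),
        )

    r_out = radii[0]
    half = int(np.ceil((r_out + grid_margin_mm) / voxel_size_mm))
    n = 2 * half + 1
    origin = -half * voxel_size_mm * np.ones(3)
    ax = (np.arange(n) - half) * voxel_size_mm
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    labels = np.zeros((n, n, n), dtype=np.int16)
    # outermost first: inner assignments overwrite outer ones
    for t, r in zip(tissues, radii):
        labels[d2 <= r * r] = TISSUE_LABELS[t]
    for t in tissues:
        if not np.any(labels == TISSUE_LABELS[t]):
            raise DegenerateShellError(
                f"shell '{t}' produced no voxels at {voxel_size_mm} mm resolution"
            )
    return LabeledVolume(labels=labels, voxel_size_mm=voxel_size_mm, origin_mm=origin)


def assign_conductivities(
    model_level: str, overrides: dict[str, float] | None = None
) -> ConductivityProfile:
    """Conductivity profile for a model level (3C/4C/5C).

    ``overrides`` maps tissue names to replacement conductivities, applied on
    top of the level's table (e.g. for sensitivity studies).
    """
    if model_level not in CONDUCTIVITY_TABLES:
        raise ValueError(
            f"unknown model level {model_level!r}; expected one of {MODEL_LEVELS}"
        )
    sigma = dict(CONDUCTIVITY_TABLES[model_level])
    if overrides:
        for tissue, value in overrides.items():
            if tissue not in TISSUE_LABELS:
                raise ValueError(f"unknown tissue {tissue!r}")
            if value <= 0:
                raise ValueError("conductivities must be strictly positive")
            sigma[TISSUE_LABELS[tissue]] = float(value)
    return ConductivityProfile(model_level=model_level, sigma_by_label=sigma)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _surface_point(volume: LabeledVolume, center: np.ndarray, direction: np.ndarray):
    """Last inside-head point marching from ``center`` along ``direction``."""
    step = volume.voxel_size_mm / 4.0
    r_max = np.linalg.norm(np.array(volume.shape) * volume.voxel_size_mm)
    ts = np.arange(0.0, r_max, step)
    pts = center + ts[:, None] * direction
    labs = volume.label_at(pts)
    inside = np.nonzero(labs != OUTSIDE)[0]
    if len(inside) == 0:
        return None
    return pts[inside[-1]]


def place_shafts(
    volume: LabeledVolume,
    n_shafts: int,
    contacts_per_shaft: int,
    seed: int = 0,
    focus_radius_frac: float = 0.2,
    focus_spread_mm: float = 4.0,
    max_depth_mm: float = 70.0,
    max_attempts: int = 300,
) -> ElectrodeSet:
    """Place straight depth-electrode shafts inside the head.

    Each shaft enters at a random scalp point and runs to a deep tip at an
    interior target drawn within ``focus_spread_mm`` of a common focus —
    implantation plans cluster around the suspected epileptogenic zone, which
    also yields the close stimulation-recording encounters the near-distance
    analysis needs.  Contacts sit at exactly 3.5 mm pitch starting from the
    deep tip (index 1).  Deterministic given ``seed``.
    """
    if n_shafts < 0:
        raise ValueError("n_shafts must be >= 0")
    if n_shafts == 0:
        return ElectrodeSet()
    if not 2 <= contacts_per_shaft <= 16:
        raise ValueError("contacts_per_shaft must be in [2, 16]")
    rng = np.random.default_rng(seed)

    nz = np.argwhere(volume.labels != OUTSIDE)
    if len(nz) == 0:
        raise PlacementError("volume contains no head voxels")
    centers = volume.voxel_centers(nz)
    head_center = centers.mean(axis=0)
    head_radius = np.linalg.norm(centers - head_center, axis=1).max()
    focus = head_center + _random_unit(rng) * focus_radius_frac * head_radius

    span = (contacts_per_shaft - 1) * CONTACT_PITCH_MM
    shafts: list[Shaft] = []
    rows = []
    for s in range(n_shafts):
        sid = f"S{s}"
        placed = False
        for _ in range(max_attempts):
            entry = _surface_point(volume, head_center, _random_unit(rng))
            if entry is None:
                continue
            target = focus + rng.uniform(-1, 1, size=3) * focus_spread_mm
            direction = target - entry
            depth = np.linalg.norm(direction)
            if not (span + 2.0) <= depth <= max_depth_mm:
                continue
            direction = direction / depth
            tip = target
            k = np.arange(contacts_per_shaft)
            positions = tip - k[:, None] * CONTACT_PITCH_MM * direction
            if np.all(volume.label_at(positions) != OUTSIDE):
                shafts.append(
                    Shaft(sid, entry_mm=entry, direction=direction, n_contacts=contacts_per_shaft)
                )
                for i, p in enumerate(positions, start=1):
                    rows.append(
                        {
                            "contact_id": f"{sid}c{i:02d}",
                            "shaft_id": sid,
                            "index": i,
                            "x_mm": p[0],
                            "y_mm": p[1],
                            "z_mm": p[2],
                        }
                    )
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place shaft {sid} after {max_attempts} attempts"
            )
    return ElectrodeSet(shafts=shafts, contacts=pd.DataFrame(rows))


def make_stimulation_plan(
    electrodes: ElectrodeSet,
    n_pairs: int,
    n_events_per_pair: int,
    inter_event_samples: int,
    seed: int = 0,
    start_sample: int | None = None,
    pair_filter=None,
) -> StimulationPlan:
    """Draw stimulated neighboring-contact pairs and lay out their events.

    Pairs are drawn without replacement from the adjacent-contact pairs of
    every shaft; ``pair_filter(pos_a, pos_b) -> bool`` optionally restricts
    the candidates (e.g. to deep contacts).  Events sit on a regular grid of
    sample indices, cycling through the pairs, strictly increasing in time.
    """
    candidates = electrodes.adjacent_pairs()
    if pair_filter is not None:
        candidates = [
            (a, b)
            for a, b in candidates
            if pair_filter(electrodes.position(a), electrodes.position(b))
        ]
    if n_pairs > len(candidates):
        raise ValueError(
            f"requested {n_pairs} pairs but only {len(candidates)} "
            "neighboring-contact pairs are available"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = np.sort(rng.choice(len(candidates), size=n_pairs, replace=False))
    pairs = pd.DataFrame(
        [
            {"pair_id": f"P{k:02d}", "anode": candidates[i][0], "cathode": candidates[i][1]}
            for k, i in enumerate(chosen_idx)
        ]
    )
    if start_sample is None:
        start_sample = inter_event_samples
    rows = []
    for j in range(n_pairs * n_events_per_pair):
        rows.append(
            {
                "pair_id": pairs["pair_id"].iloc[j % n_pairs] if n_pairs else None,
                "sample": start_sample + j * inter_event_samples,
            }
        )
    events = pd.DataFrame(rows, columns=["pair_id", "sample"])
    return StimulationPlan(pairs=pairs, events=events)
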