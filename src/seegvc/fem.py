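"""Hexahedral finite-element forward solver for the EEG volume-conduction
problem.

One trilinear hexahedral element per nonzero-label voxel; tissue interfaces
are smoothed by a geometry-adapting node shift.  The quasi-static potential
solves  div(sigma grad u) = div(j_source)  with an insulating outer boundary;
point dipoles enter through the partial-integration load (moment dotted with
the basis gradients at the source point) and sensors are point-sensors
evaluated by trilinear interpolation.  The stiffness matrix is symmetric
positive semi-definite with the constants as nullspace; solves are
diagonally preconditioned conjugate gradients with a zero-mean gauge fix.

Coordinates are stored in mm (matching the phantom/electrode convention);
assembly and interpolation convert to SI meters internally, so potentials
are volts for moments in A*m and conductivities in S/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from seegvc.analytic import Dipole
from seegvc.errors import (
    ConvergenceError,
    IncompatibleLoadError,
    InvalidGeometryError,
    OutsideMeshError,
)
from seegvc.phantom import ConductivityProfile, ElectrodeSet, LabeledVolume, StimulationPlan

logger = logging.getLogger(__name__)

_MM = 1e-3

#: stimulation current magnitude (A) for the unit dipole; the overall
#: amplitude is arbitrary — it is absorbed by the validation scaling factor.
UNIT_CURRENT_A = 1e-6

# local corner order (VTK hexahedron), offsets within a voxel
_CORNER_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
    dtype=np.int64,
)
_XI_A = 2.0 * _CORNER_OFFSETS - 1.0  # reference corner coordinates in [-1,1]^3

_GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS_PTS = np.array([[x, y, z] for x in _GAUSS_1D for y in _GAUSS_1D for z in _GAUSS_1D])


def _shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at reference point(s) ``xi`` (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return (
        (1.0 + xi[..., None, 0] * _XI_A[:, 0])
        * (1.0 + xi[..., None, 1] * _XI_A[:, 1])
        * (1.0 + xi[..., None, 2] * _XI_A[:, 2])
        / 8.0
    )


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Reference gradients dN_a/dxi at ``xi`` (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    f = [1.0 + xi[..., None, i] * _XI_A[:, i] for i in range(3)]
    g = np.empty(xi.shape[:-1] + (8, 3))
    g[..., 0] = _XI_A[:, 0] * f[1] * f[2] / 8.0
    g[..., 1] = _XI_A[:, 1] * f[0] * f[2] / 8.0
    g[..., 2] = _XI_A[:, 2] * f[0] * f[1] / 8.0
    return g


@dataclass
class HexMesh:
    """Hexahedral mesh: nodes (mm), 8-node elements, per-element tissue label.

    ``element_of_voxel`` maps source-volume voxel indices to element ids
    (-1 where the voxel is outside the head) for point-containment lookups;
    containment uses the half-open voxel convention of the source grid.
    """

    nodes_mm: np.ndarray  # (n_nodes, 3)
    elements: np.ndarray  # (n_elem, 8) int
    element_label: np.ndarray  # (n_elem,)
    voxel_size_mm: float
    origin_mm: np.ndarray  # voxel (0,0,0) center of the source volume
    element_of_voxel: np.ndarray  # (nx, ny, nz) int, -1 = no element
    node_shift: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_mm)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


@dataclass
class StiffnessSystem:
    """Sparse symmetric stiffness operator; constants span the nullspace."""

    matrix: sp.csr_matrix  # SI units: K u = b with b in A, u in V
    diag: np.ndarray = field(init=False)

    def __post_init__(self):
        self.diag = self.matrix.diagonal()

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _jacobians(coords: np.ndarray) -> np.ndarray:
    """det J at the 8 Gauss points of each element, shape (n_elem, 8)."""
    dets = np.empty((len(coords), len(_GAUSS_PTS)))
    for g, xi in enumerate(_GAUSS_PTS):
        dN = _shape_gradients(xi)  # (8, 3)
        J = np.einsum("ai,maj->mij", dN, coords)
        dets[:, g] = np.linalg.det(J)
    return dets


def min_jacobian(mesh: HexMesh) -> float:
    """Minimum Jacobian determinant over all elements and Gauss points."""
    return float(_jacobians(mesh.nodes_mm[mesh.elements]).min())


def voxels_to_hex_mesh(volume: LabeledVolume, node_shift: float = 0.3) -> HexMesh:
    """One hexahedral element per nonzero-label voxel, nodes at shared voxel
    corners, with a geometry-adapting node shift at tissue interfaces.

    Node-shift rule: a node incident to voxels of two or more distinct labels
    (the exterior counts as label 0) is displaced by
    ``node_shift * voxel_size / 2`` toward the centroid of its incident
    voxels carrying the locally-minority label; displacements that would
    invert an element are retracted.  ``node_shift = 0`` yields the regular
    voxel-corner lattice.
    """
    if not 0.0 <= node_shift <= 0.49:
        raise ValueError("node_shift must be in [0, 0.49]")
    h = volume.voxel_size_mm
    labels = volume.labels
    vox = np.argwhere(labels != 0)
    if len(vox) == 0:
        raise InvalidGeometryError("volume has no nonzero-label voxels")

    corner_ids = -np.ones(tuple(np.array(labels.shape) + 1), dtype=np.int64)
    corners_ijk = np.unique(
        (vox[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 3), axis=0
    )
    corner_ids[tuple(corners_ijk.T)] = np.arange(len(corners_ijk))
    elem_corners = vox[:, None, :] + _CORNER_OFFSETS[None, :, :]
    elements = corner_ids[tuple(np.moveaxis(elem_corners, -1, 0))]

    nodes = volume.origin_mm + (corners_ijk - 0.5) * h
    element_label = labels[tuple(vox.T)].copy()
    element_of_voxel = -np.ones(labels.shape, dtype=np.int64)
    element_of_voxel[tuple(vox.T)] = np.arange(len(vox))

    if node_shift > 0.0:
        nodes = _apply_node_shift(nodes, corners_ijk, elements, volume, node_shift)

    return HexMesh(
        nodes_mm=nodes,
        elements=elements.astype(np.int64),
        element_label=element_label,
        voxel_size_mm=h,
        origin_mm=volume.origin_mm.copy(),
        element_of_voxel=element_of_voxel,
        node_shift=node_shift,
    )


def _apply_node_shift(nodes, corners_ijk, elements, volume, node_shift):
    labels = volume.labels
    h = volume.voxel_size_mm
    n_nodes = len(corners_ijk)
    n_labels = int(labels.max()) + 1
    counts = np.zeros((n_nodes, n_labels), dtype=np.int32)
    centroid = np.zeros((n_nodes, n_labels, 3))
    shape = np.array(labels.shape)
    all_idx = np.arange(n_nodes)
    for off in _CORNER_OFFSETS:
        vijk = corners_ijk - off  # incident voxel for this corner offset
        ok = np.all((vijk >= 0) & (vijk < shape), axis=1)
        lab = np.zeros(n_nodes, dtype=np.int64)
        lab[ok] = labels[tuple(vijk[ok].T)]
        centers = volume.voxel_centers(vijk)
        np.add.at(counts, (all_idx[ok], lab[ok]), 1)
        np.add.at(centroid, (all_idx[ok], lab[ok]), centers[ok])
        # voxels outside the grid count as exterior (label 0)
        out = ~ok
        np.add.at(counts, (all_idx[out], 0), 1)
        np.add.at(centroid, (all_idx[out], 0), centers[out])

    movable = (counts > 0).sum(axis=1) >= 2
    # locally-minority label: fewest incident voxels; ties -> deeper tissue
    masked = np.where(counts > 0, counts, np.iinfo(np.int32).max)
    minority = np.zeros(n_nodes, dtype=np.int64)
    best = np.full(n_nodes, np.iinfo(np.int32).max)
    for lab in range(n_labels):  # ascending; <= lets deeper labels win ties
        take = masked[:, lab] <= best
        minority[take] = lab
        best[take] = masked[take, lab]
    tgt = centroid[all_idx, minority] / counts[all_idx, minority].clip(1)[:, None]
    d = tgt - nodes
    nrm = np.linalg.norm(d, axis=1)
    ok = movable & (nrm > 1e-12)
    disp = np.zeros_like(nodes)
    disp[ok] = d[ok] / nrm[ok, None] * (node_shift * h / 2.0)

    shifted = nodes + disp
    for _ in range(10):
        dets = _jacobians(shifted[elements])
        bad = np.nonzero(dets.min(axis=1) <= 1e-9 * h**3)[0]
        if len(bad) == 0:
            return shifted
        retract = np.unique(elements[bad])
        logger.warning(
            "retracting node shift on %d nodes of %d degenerate elements",
            len(retract), len(bad),
        )
        shifted[retract] = nodes[retract]
    raise InvalidGeometryError(
        f"node shift produces inverted elements (e.g. element {bad[0]})"
    )


def element_stiffness(mesh: HexMesh) -> np.ndarray:
    """Per-element stiffness integrals for unit conductivity, (n_elem, 8, 8).

    Geometry-only: cache and reuse across conductivity profiles — between
    model levels only the labels (hence conductivities) change, the mesh
    stays identical.
    """
    coords = mesh.nodes_mm[mesh.elements] * _MM
    Ke = np.zeros((len(coords), 8, 8))
    for xi in _GAUSS_PTS:
        dN = _shape_gradients(xi)  # (8, 3)
        J = np.einsum("ai,maj->mij", dN, coords)  # J[i,j] = dx_j/dxi_i
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise InvalidGeometryError("non-positive Jacobian during assembly")
        Jinv = np.linalg.inv(J)
        g = np.einsum("ai,mki->mak", dN, Jinv)  # dN_a/dx_k
        Ke += np.einsum("mak,mbk->mab", g, g) * detJ[:, None, None]
    return Ke


def assemble_stiffness(
    mesh: HexMesh,
    profile: ConductivityProfile,
    element_matrices: np.ndarray | None = None,
) -> StiffnessSystem:
    """K_ij = sum_e sigma_e int grad(phi_i).grad(phi_j) over element e,
    trilinear isoparametric basis, 2x2x2 Gauss quadrature."""
    present = set(np.unique(mesh.element_label).tolist())
    missing = present - set(profile.sigma_by_label)
    if missing:
        raise ValueError(f"profile lacks conductivities for labels {sorted(missing)}")
    sigma = profile.sigma_for(mesh.element_label)
    if np.any(sigma <= 0):
        raise ValueError("conductivities must be strictly positive")
    if element_matrices is None:
        element_matrices = element_stiffness(mesh)
    Ke = element_matrices * sigma[:, None, None]
    rows = np.repeat(mesh.elements, 8, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 8)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return StiffnessSystem(matrix=K)


def _locate(mesh: HexMesh, point_mm: np.ndarray) -> tuple[int, np.ndarray]:
    """Containing element (half-open voxel convention) and local coordinates.

    On shifted meshes the trilinear map is inverted by Newton iteration,
    seeded with the regular-lattice local coordinates.
    """
    p = np.asarray(point_mm, dtype=float)
    h = mesh.voxel_size_mm
    ijk = np.floor((p - mesh.origin_mm) / h + 0.5).astype(int)
    shape = np.array(mesh.element_of_voxel.shape)
    if np.any(ijk < 0) or np.any(ijk >= shape):
        raise OutsideMeshError(f"point {p.tolist()} outside the mesh grid")
    e = int(mesh.element_of_voxel[tuple(ijk)])
    if e < 0:
        raise OutsideMeshError(f"point {p.tolist()} lies in an empty voxel")
    center = mesh.origin_mm + ijk * h
    xi = 2.0 * (p - center) / h
    if mesh.node_shift > 0.0:
        coords = mesh.nodes_mm[mesh.elements[e]]
        for _ in range(20):
            res = _shape_functions(xi) @ coords - p
            if np.max(np.abs(res)) < 1e-12 * h:
                break
            dN = _shape_gradients(xi)  # (8, 3): J[i,j] = dx_j/dxi_i
            J = np.einsum("ai,aj->ij", dN, coords)
            xi = xi - np.linalg.solve(J.T, res)
    return e, xi


def dipole_load_vector(mesh: HexMesh, dipole: Dipole) -> np.ndarray:
    """Partial-integration right-hand side: b_i = moment . grad phi_i at the
    dipole position; nonzero only on the containing element's 8 nodes and
    summing to zero (partition of unity)."""
    e, xi = _locate(mesh, dipole.position_mm)
    coords = mesh.nodes_mm[mesh.elements[e]] * _MM
    dN = _shape_gradients(xi)
    J = np.einsum("ai,aj->ij", dN, coords)
    g = np.einsum("ai,ki->ak", dN, np.linalg.inv(J))  # dN_a/dx_k
    b = np.zeros(mesh.n_nodes)
    b[mesh.elements[e]] = g @ dipole.moment_Am
    return b


def solve_potential(
    system: StiffnessSystem,
    load: np.ndarray,
    rel_tol: float = 1e-9,
    maxiter: int | None = None,
) -> np.ndarray:
    """Diagonally preconditioned CG solve of K u = load, returned in the
    zero-mean gauge.  The load must be compatible with the insulating
    boundary (entries summing to zero)."""
    b = np.asarray(load, dtype=float)
    n = system.n_nodes
    bn = np.linalg.norm(b)
    if bn == 0.0:
        return np.zeros(n)
    if abs(b.sum()) > 1e-8 * np.abs(b).sum():
        raise IncompatibleLoadError(
            f"load sums to {b.sum():.3e}; an insulated conductor requires zero net current"
        )
    b = b - b.mean()  # exact projection onto the compatible subspace
    if maxiter is None:
        maxiter = int(10 * np.sqrt(n)) + 1000
    Minv = 1.0 / system.diag
    M = spla.LinearOperator((n, n), matvec=lambda x: Minv * x)
    u, info = spla.cg(system.matrix, b, rtol=rel_tol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(system.matrix @ u - b) / bn)
    if info != 0 or not np.isfinite(res) or res > 10 * rel_tol:
        raise ConvergenceError(
            f"CG did not reach rel_tol={rel_tol:g} within {maxiter} iterations",
            residual=res,
        )
    return u - u.mean()


def interpolation_weights(mesh: HexMesh, points_mm: np.ndarray):
    """Per-point (node_indices, trilinear_weights) for point-sensor readout."""
    out = []
    for p in np.atleast_2d(np.asarray(points_mm, dtype=float)):
        e, xi = _locate(mesh, p)
        out.append((mesh.elements[e], _shape_functions(xi)))
    return out


def interpolate_at_points(
    mesh: HexMesh, potential: np.ndarray, points_mm: np.ndarray
) -> np.ndarray:
    """Trilinear interpolation of a nodal field at interior points."""
    u = np.asarray(potential, dtype=float)
    return np.array([w @ u[idx] for idx, w in interpolation_weights(mesh, points_mm)])


def pair_dipole(
    electrodes: ElectrodeSet, anode: str, cathode: str, current_a: float = UNIT_CURRENT_A
) -> Dipole:
    """Stimulating pair as a point dipole at the contact midpoint, moment
    along the anode->cathode axis times the contact separation."""
    pa = electrodes.position(anode)
    pc = electrodes.position(cathode)
    return Dipole(position_mm=0.5 * (pa + pc), moment_Am=current_a * (pc - pa) * _MM)


def simulate_potential_table(
    mesh: HexMesh,
    profile: ConductivityProfile,
    electrodes: ElectrodeSet,
    plan: StimulationPlan,
    montage: list[tuple[str, str, str]] | None = None,
    use_transfer: bool = False,
    rel_tol: float = 1e-9,
    current_a: float = UNIT_CURRENT_A,
    system: StiffnessSystem | None = None,
    element_matrices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulated bipolar potential table: rows = stimulation pairs, columns =
    bipolar channels, entry = potential at the channel's first contact minus
    at its second contact (V).

    ``use_transfer=True`` computes one reciprocal solve per channel (load
    +1/-1 distributed over the two contacts' interpolation weights) and dots
    it with each pair's dipole load; the direct path solves once per pair.
    Both paths agree by reciprocity of the symmetric stiffness operator.
    """
    if montage is None:
        montage = electrodes.bipolar_channels()
    if system is None:
        system = assemble_stiffness(mesh, profile, element_matrices)
    loads = {}
    for row in plan.pairs.itertuples():
        dip = pair_dipole(electrodes, row.anode, row.cathode, current_a)
        loads[row.pair_id] = dipole_load_vector(mesh, dip)
    chan_ids = [c[0] for c in montage]
    table = pd.DataFrame(
        index=plan.pairs["pair_id"].tolist(), columns=chan_ids, dtype=float
    )
    table.index.name = "pair_id"
    contact_ids = sorted({c for _, a, b in montage for c in (a, b)})
    weights = dict(
        zip(contact_ids, interpolation_weights(mesh, electrodes.positions(contact_ids)))
    )
    if use_transfer:
        for cid, a, b in montage:
            s = np.zeros(system.n_nodes)
            ia, wa = weights[a]
            ib, wb = weights[b]
            np.add.at(s, ia, wa)
            np.add.at(s, ib, -wb)
            u_ch = solve_potential(system, s, rel_tol=rel_tol)
            for pid, bvec in loads.items():
                table.loc[pid, cid] = float(u_ch @ bvec)
    else:
        for pid, bvec in loads.items():
            u = solve_potential(system, bvec, rel_tol=rel_tol)
            for cid, a, b in montage:
                ia, wa = weights[a]
                ib, wb = weights[b]
                table.loc[pid, cid] = float(wa @ u[ia] - wb @ u[ib])
    return table
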