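"""Trajectory geometry statistics for ligand-binding simulations.

Implements the analyses used to characterise LDHA:ligand trajectories:
mobile-loop state classification and populations, heavy-atom contact and
ionic-interaction occupancy, hydrogen-bond occupancy, Kabsch superposition,
RMSF about the mean structure, pairwise-RMSD matrices, gromos clustering
with an adaptive cutoff, and representative-structure / monomer selection.

All coordinates are in nm, frame times in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "LoopThresholds",
    "ClusterResult",
    "parse_selection",
    "loop_distance",
    "loop_distances",
    "classify_loop_state",
    "loop_populations",
    "contact_occupancy",
    "ionic_occupancy",
    "hbond_occupancy",
    "kabsch_superpose",
    "rmsf",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "adaptive_cluster_cutoff",
    "representative_structure",
    "least_rmsf_monomer",
]


# ---------------------------------------------------------------------------
# Trajectory container and atom selection
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (nm) with per-atom metadata.

    Metadata arrays (atom name, element, residue name, 1-based residue
    number, chain id) all have length equal to the atom count; ``times``
    holds one entry per frame in ps.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in trajectory")
        n = self.coords.shape[1]
        for attr in ("atom_names", "elements", "resnames", "resids", "chains"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != (n,):
                raise ValueError(f"{attr} length {arr.shape} does not match atom count {n}")
            setattr(self, attr, arr)
        self.resids = self.resids.astype(int)
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.coords.shape[0],):
                raise ValueError("times length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, query: str) -> np.ndarray:
        """Resolve a selection query (see :func:`parse_selection`) to indices."""
        return parse_selection(self, query)


def parse_selection(traj: Trajectory, query: str) -> np.ndarray:
    """Resolve a small text query to unique, sorted atom indices.

    The query is a conjunction of clauses joined by ``and``; each clause is a
    keyword followed by one or more values::

        chain A and resid 100-103 and name CA
        element N O
        resname LIG

    ``resid`` values may be single numbers or inclusive ``lo-hi`` ranges.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    query = query.strip()
    if not query:
        raise ValueError("empty selection query")
    for clause in query.split(" and "):
        tokens = clause.split()
        if len(tokens) < 2:
            raise ValueError(f"malformed selection clause: {clause!r}")
        key, values = tokens[0].lower(), tokens[1:]
        if key == "resid":
            sub = np.zeros(traj.n_atoms, dtype=bool)
            for v in values:
                if "-" in v[1:]:  # allow negative single ids, not ranges of them
                    lo, hi = v.split("-", 1)
                    sub |= (traj.resids >= int(lo)) & (traj.resids <= int(hi))
                else:
                    sub |= traj.resids == int(v)
            mask &= sub
        elif key in ("chain", "name", "element", "resname"):
            attr = {"chain": "chains", "name": "atom_names",
                    "element": "elements", "resname": "resnames"}[key]
            mask &= np.isin(getattr(traj, attr), values)
        else:
            raise ValueError(f"unknown selection keyword: {key!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection {query!r} matched no atoms")
    return idx


def _as_indices(traj: Trajectory, sel) -> np.ndarray:
    """Accept a query string or an index array; return validated indices."""
    if isinstance(sel, str):
        return parse_selection(traj, sel)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    if idx.size != np.unique(idx).size:
        raise ValueError("selection indices must be unique")
    if idx.min() < 0 or idx.max() >= traj.n_atoms:
        raise ValueError("selection index out of range")
    return idx


# ---------------------------------------------------------------------------
# Mobile-loop state classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopThresholds:
    """Distance thresholds (nm) separating closed / intermediate / open loop states.

    The mobile-loop coordinate is the centroid distance between the loop
    Calpha atoms (residues 100-103) and the Calpha atoms of Tyr238/Lys242 on
    the far side of the binding groove. Below ``closed_below`` the loop is
    closed, above ``open_above`` open, in between (boundaries included)
    intermediate.
    """

    closed_below: float = 0.9
    open_above: float = 1.05

    def __post_init__(self) -> None:
        if not self.closed_below < self.open_above:
            raise ValueError("closed_below must be smaller than open_above")


LOOP_STATES = ("closed", "intermediate", "open")


def loop_distance(frame: np.ndarray, loop_idx, anchor_idx) -> float:
    """Centroid-to-centroid distance (nm) between two atom sets in one frame."""
    frame = np.asarray(frame, dtype=float)
    loop_idx = np.asarray(loop_idx, dtype=int)
    anchor_idx = np.asarray(anchor_idx, dtype=int)
    if loop_idx.size == 0 or anchor_idx.size == 0:
        raise ValueError("empty selection for loop distance")
    c_loop = frame[loop_idx].mean(axis=0)
    c_anchor = frame[anchor_idx].mean(axis=0)
    return float(np.linalg.norm(c_loop - c_anchor))


def loop_distances(traj: Trajectory, loop_sel, anchor_sel) -> np.ndarray:
    """Per-frame loop centroid distance (nm)."""
    li = _as_indices(traj, loop_sel)
    ai = _as_indices(traj, anchor_sel)
    c_loop = traj.coords[:, li].mean(axis=1)
    c_anchor = traj.coords[:, ai].mean(axis=1)
    return np.linalg.norm(c_loop - c_anchor, axis=1)


def classify_loop_state(distance: float, thresholds: LoopThresholds = LoopThresholds()) -> str:
    """Classify one loop distance as ``closed``, ``intermediate`` or ``open``.

    Boundary values map to ``intermediate`` (the inequalities are strict).
    """
    if distance < 0:
        raise ValueError(f"negative distance: {distance}")
    if distance < thresholds.closed_below:
        return "closed"
    if distance > thresholds.open_above:
        return "open"
    return "intermediate"


def loop_populations(
    traj: Trajectory,
    loop_sel,
    anchor_sel,
    thresholds: LoopThresholds = LoopThresholds(),
) -> dict[str, float]:
    """Fraction of frames in each loop state; fractions sum to 1."""
    d = loop_distances(traj, loop_sel, anchor_sel)
    states = [classify_loop_state(x, thresholds) for x in d]
    n = len(states)
    return {s: states.count(s) / n for s in LOOP_STATES}


# ---------------------------------------------------------------------------
# Contact / ionic / hydrogen-bond occupancy
# ---------------------------------------------------------------------------

def contact_occupancy(traj: Trajectory, sel_a, sel_b, cutoff: float = 0.4) -> float:
    """Fraction of frames with ANY heavy-atom cross pair within ``cutoff`` (nm).

    Hydrogens are excluded from both selections; the distance criterion is
    inclusive (d <= cutoff counts as a contact).
    """
    ia = _heavy(traj, _as_indices(traj, sel_a))
    ib = _heavy(traj, _as_indices(traj, sel_b))
    a = traj.coords[:, ia]  # (F, na, 3)
    b = traj.coords[:, ib]
    diff = a[:, :, None, :] - b[:, None, :, :]
    dmin = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
    return float(np.mean(dmin <= cutoff))


def _heavy(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    heavy = idx[traj.elements[idx] != "H"]
    if heavy.size == 0:
        raise ValueError("selection contains no heavy atoms")
    return heavy


def ionic_occupancy(traj: Trajectory, charged_group_a, charged_group_b,
                    cutoff: float = 0.4) -> float:
    """Percentage of frames in which two charged groups form a salt bridge.

    A salt bridge exists when any heavy-atom pair between the groups (e.g.
    guanidinium NH1/NH2/NE vs carboxylate O/OXT) is within ``cutoff``.
    """
    return 100.0 * contact_occupancy(traj, charged_group_a, charged_group_b, cutoff)


def hbond_occupancy(
    traj: Trajectory,
    donor_atom: int,
    hydrogen: int,
    acceptor_atom: int,
    dist_cutoff: float = 0.35,
    angle_cutoff: float = 30.0,
) -> float:
    """Fraction of frames in which a donor-H...acceptor hydrogen bond exists.

    Criteria: donor-acceptor distance <= ``dist_cutoff`` (nm) and
    hydrogen-donor-acceptor angle (vertex at the donor) <= ``angle_cutoff``
    degrees.
    """
    for idx, label in ((donor_atom, "donor"), (hydrogen, "hydrogen"), (acceptor_atom, "acceptor")):
        if not 0 <= idx < traj.n_atoms:
            raise ValueError(f"{label} index {idx} out of range")
    d = traj.coords[:, donor_atom]
    h = traj.coords[:, hydrogen]
    a = traj.coords[:, acceptor_atom]
    da = a - d
    dh = h - d
    dist = np.linalg.norm(da, axis=1)
    cosang = (da * dh).sum(axis=1) / (
        np.linalg.norm(da, axis=1) * np.linalg.norm(dh, axis=1)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(np.mean((dist <= dist_cutoff) & (angle <= angle_cutoff)))


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile_coords: np.ndarray,
    ref_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile_coords`` onto ``ref_coords``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference, with a
    proper rotation (det = +1) and
    ``rmsd = sqrt(sum w_i |x_i' - y_i|^2 / sum w_i)``.
    """
    x = np.asarray(mobile_coords, dtype=float)
    y = np.asarray(ref_coords, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = x.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    cx = wn @ x
    cy = wn @ y
    x0 = x - cx
    y0 = y - cy
    h = (x0 * wn[:, None]).T @ y0
    u, s, vt = np.linalg.svd(h)
    # collinear input: rotation about the line is undetermined
    spread = np.linalg.svd(x0 * np.sqrt(wn[:, None]), compute_uv=False)
    if spread[1] <= 1e-10 * max(spread[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinates: superposition undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cy - rot @ cx
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - y) ** 2, axis=1)) / w.sum()))
    return rot, trans, rmsd


def _superpose_frames(coords: np.ndarray, ref: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``ref`` using the fit selection; move all atoms."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[f, fit_idx], ref[fit_idx])
        out[f] = coords[f] @ rot.T + trans
    return out


def rmsf(traj: Trajectory, selection=None, align_selection=None) -> np.ndarray:
    """Per-atom root-mean-squared fluctuation (nm) about the mean structure.

    Frames are superposed onto the running mean structure using
    ``align_selection`` (default: the analysis selection); the mean and the
    fit are iterated to a fixed point so the result is invariant under rigid
    motion of the input frames, then RMSF_i = sqrt(<|x_i - <x_i>|^2>) is
    evaluated over the analysis selection.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else _as_indices(traj, selection)
    fit = sel if align_selection is None else _as_indices(traj, align_selection)
    aligned = _superpose_frames(traj.coords, traj.coords.mean(axis=0), fit)
    for _ in range(100):
        ref = aligned.mean(axis=0)
        aligned_next = _superpose_frames(aligned, ref, fit)
        shift = np.max(np.abs(aligned_next - aligned))
        aligned = aligned_next
        if shift < 1e-12:
            break
    mean = aligned.mean(axis=0)
    dev2 = np.sum((aligned[:, sel] - mean[sel]) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


def pairwise_rmsd_matrix(traj: Trajectory, selection=None) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs (nm) over a selection."""
    if traj.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else _as_indices(traj, selection)
    sub = traj.coords[:, sel]
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(sub[j], sub[i])
            mat[i, j] = mat[j, i] = r
    return mat


# ---------------------------------------------------------------------------
# gromos clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Partition of frames into clusters in extraction order.

    ``assignment[f]`` is the cluster id of frame ``f`` (0 = first extracted,
    which is also the largest); ``centroids[c]`` is the max-neighbour frame
    that seeded cluster ``c``.
    """

    assignment: np.ndarray
    sizes: list[int] = field(default_factory=list)
    centroids: list[int] = field(default_factory=list)
    cutoff_used: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """gromos clustering of a pairwise-RMSD matrix.

    Repeatedly take the frame with the most neighbours within ``cutoff``
    (ties broken by lowest frame index) together with those neighbours as a
    cluster, remove them, and recurse on the remainder.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"distance matrix must be square, got {mat.shape}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = mat.shape[0]
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    sizes: list[int] = []
    centroids: list[int] = []
    within = mat <= cutoff
    cid = 0
    while remaining.any():
        counts = np.where(remaining, (within & remaining[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax returns the lowest tied index
        members = np.flatnonzero(within[center] & remaining)
        assignment[members] = cid
        sizes.append(int(members.size))
        centroids.append(center)
        remaining[members] = False
        cid += 1
    return ClusterResult(assignment=assignment, sizes=sizes,
                         centroids=centroids, cutoff_used=float(cutoff))


def adaptive_cluster_cutoff(
    matrix: np.ndarray,
    start: float = 0.05,
    step: float = 0.005,
) -> tuple[float, ClusterResult]:
    """Smallest cutoff on the grid whose largest cluster holds > 50% of frames.

    The cutoff grid is ``start, start + step, ...``; it is guaranteed to
    terminate because at ``cutoff >= max(matrix)`` everything joins one
    cluster.
    """
    mat = np.asarray(matrix, dtype=float)
    n = mat.shape[0]
    cutoff = start
    while True:
        result = gromos_cluster(mat, cutoff)
        if 2 * result.sizes[0] > n:
            return cutoff, result
        cutoff += step


def representative_structure(traj: Trajectory, selection=None) -> int:
    """Centroid frame of the largest cluster under the adaptive gromos cutoff."""
    if traj.n_frames == 1:
        return 0
    mat = pairwise_rmsd_matrix(traj, selection)
    _, result = adaptive_cluster_cutoff(mat)
    return result.centroids[0]


def least_rmsf_monomer(per_monomer_rmsf: Mapping[str, Sequence[float]]) -> str:
    """Monomer whose mean RMSF over the selection is smallest (ties: lexicographic)."""
    if not per_monomer_rmsf:
        raise ValueError("empty monomer map")
    best = None
    best_val = np.inf
    for key in sorted(per_monomer_rmsf):
        val = float(np.mean(per_monomer_rmsf[key]))
        if val < best_val:
            best, best_val = key, val
    return best
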