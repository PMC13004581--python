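"""Anion-centric trajectory analytics.

Contacts, cavity occupancy and residence segments, barrel-entry events,
RMSD/RMSF, geometric hydrogen bonds, Shrake–Rupley SASA and chromophore
planarity.  All distance computations use the minimum-image convention when
the frame carries a box.

Operational definitions (configurable throughout):

* a residue is *in contact* with the anion when its minimum heavy-to-anion
  atom distance is ≤ 4 Å;
* the anion is *cavity-bound* in a frame when it contacts at least three of
  the designated cavity residues simultaneously; residence runs separated by
  ≤ 2 unbound frames are merged into one segment;
* the anion has *entered the barrel* when its distance to the chromophore
  centroid drops below ``r_inside`` (8 Å) and stays there for a persistence
  window, with hysteresis: a new event needs a prior excursion beyond
  ``r_bulk`` (15 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .traj_io import Trajectory, minimum_image_displacement, pairwise_distances, resolve_selection

#: van der Waals radii (Å) for SASA; halide values follow the ionic radii
#: used throughout the solvation analyses.
DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "CL": 1.81, "BR": 1.96, "I": 2.20,
}


@dataclass
class ContactFingerprint:
    """Per-frame sets of residue ids within ``cutoff`` of the anion."""

    cutoff: float
    frames: list  # list[frozenset[int]]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class OccupancySeries:
    """Cavity-occupancy flags and gap-merged residence segments.

    ``bound`` holds the raw per-frame flag (≥ ``min_residues`` cavity
    contacts); ``segments`` are half-open ``[start, end)`` runs after
    merging across gaps of at most ``gap_tolerance`` unbound frames.
    """

    bound: np.ndarray
    segments: list
    cutoff: float
    min_residues: int
    gap_tolerance: int

    @property
    def n_frames(self) -> int:
        return len(self.bound)

    @property
    def n_bound_frames(self) -> int:
        return int(np.sum(self.bound))

    def in_segment(self) -> np.ndarray:
        """Boolean per frame: covered by a residence segment."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.segments:
            mask[a:b] = True
        return mask


@dataclass
class EntryEvent:
    """A barrel-entry event: first frame of a persistent interior visit."""

    frame: int
    gate_residues: tuple | None
    persistence: int


# ---------------------------------------------------------------------------
# contacts & occupancy
# ---------------------------------------------------------------------------

def contact_fingerprint(traj: Trajectory, anion_selection, protein_selection,
                        cutoff: float = 4.0) -> ContactFingerprint:
    """Residues of ``protein_selection`` within ``cutoff`` of the anion, per frame.

    A residue is included in a frame's set iff the minimum (minimum-image)
    distance from any anion atom to any selected atom of that residue is at
    most ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    anion_idx = resolve_selection(traj.topology, anion_selection)
    prot_idx = resolve_selection(traj.topology, protein_selection)
    if not anion_idx:
        raise ValueError("anion selection resolves to no atoms")
    resids = np.array([traj.topology.resids[i] for i in prot_idx], dtype=int)
    frames = []
    for fr in traj.frames:
        if prot_idx:
            d = pairwise_distances(fr.coords[anion_idx], fr.coords[prot_idx], fr.box)
            near = d.min(axis=0) <= cutoff
            frames.append(frozenset(int(r) for r in resids[near]))
        else:
            frames.append(frozenset())
    return ContactFingerprint(cutoff=float(cutoff), frames=frames)


def _bound_runs(bound: np.ndarray):
    """Maximal runs of True as half-open (start, end) pairs."""
    runs = []
    start = None
    for i, b in enumerate(bound):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(bound)))
    return runs


def cavity_occupancy(fingerprint: ContactFingerprint, cavity_residues,
                     min_residues: int = 3, gap_tolerance: int = 2) -> OccupancySeries:
    """Flag frames where the anion occupies the binding cavity.

    A frame is bound iff at least ``min_residues`` of ``cavity_residues``
    appear in that frame's contact set.  Bound runs separated by at most
    ``gap_tolerance`` unbound frames merge into one residence segment
    (recrossing-noise suppression).
    """
    cavity = set(int(r) for r in cavity_residues)
    if not cavity:
        raise ValueError("cavity_residues must be nonempty")
    if min_residues > len(cavity):
        raise ValueError("min_residues exceeds the number of cavity residues")
    bound = np.array(
        [len(s & cavity) >= min_residues for s in fingerprint.frames], dtype=bool
    )
    runs = _bound_runs(bound)
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= gap_tolerance:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return OccupancySeries(bound=bound, segments=merged,
                           cutoff=fingerprint.cutoff,
                           min_residues=min_residues,
                           gap_tolerance=gap_tolerance)


def detect_entry_events(traj: Trajectory, anion_selection, interior_center_selection,
                        r_inside: float = 8.0, r_bulk: float = 15.0,
                        min_persistence: int = 10,
                        gate_candidates=None) -> list:
    """Detect persistent anion entries into the barrel interior.

    The interior is operationalised as distance-to-centroid of
    ``interior_center_selection`` (typically the chromophore) below
    ``r_inside``; hysteresis requires an excursion past ``r_bulk`` before the
    next event can fire.  An event is reported at the first frame of each
    maximal interior run lasting at least ``min_persistence`` frames.  For
    each event, the candidate residue pair with the smallest summed
    minimum distance to the anion at the event frame is reported as the
    gate; with no candidates, ``gate_residues`` is None.
    """
    if r_inside >= r_bulk:
        raise ValueError("r_inside must be smaller than r_bulk")
    anion_idx = resolve_selection(traj.topology, anion_selection)
    center_idx = resolve_selection(traj.topology, interior_center_selection)
    if not anion_idx:
        raise ValueError("anion selection resolves to no atoms")
    if not center_idx:
        raise ValueError("interior center selection resolves to no atoms")

    dist = np.empty(traj.n_frames)
    for t, fr in enumerate(traj.frames):
        centroid = fr.coords[center_idx].mean(axis=0)
        anion = fr.coords[anion_idx].mean(axis=0)
        dist[t] = np.linalg.norm(minimum_image_displacement(anion - centroid, fr.box))

    inside_runs = _bound_runs(dist < r_inside)
    resid_atoms = {}
    if gate_candidates:
        for pair in gate_candidates:
            for rid in pair:
                if rid not in resid_atoms:
                    resid_atoms[rid] = [i for i in range(traj.n_atoms)
                                        if traj.topology.resids[i] == rid]

    events = []
    armed_from = 0  # search start for the required bulk excursion
    for start, end in inside_runs:
        if end - start < min_persistence:
            continue
        if start == 0:
            continue  # no prior bulk frame by definition
        if not np.any(dist[armed_from:start] > r_bulk):
            continue
        gate = None
        if gate_candidates:
            fr = traj.frames[start]
            best = np.inf
            for pair in gate_candidates:
                total = 0.0
                ok = True
                for rid in pair:
                    idx = resid_atoms.get(rid, [])
                    if not idx:
                        ok = False
                        break
                    d = pairwise_distances(fr.coords[anion_idx], fr.coords[idx], fr.box)
                    total += float(d.min())
                if ok and total < best:
                    best = total
                    gate = tuple(pair)
        events.append(EntryEvent(frame=start, gate_residues=gate,
                                 persistence=end - start))
        armed_from = end
    return events


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates; only proper rotations are
    considered (no reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must share a shape")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    if np.linalg.matrix_rank(P) < 2:
        raise ValueError("superposition needs non-collinear atoms")
    R = _kabsch_rotation(P, reference - rc)
    return P @ R.T + rc


def rmsd(frame_a: np.ndarray, frame_b: np.ndarray, selection=None,
         superpose_first: bool = True) -> float:
    """Root-mean-square deviation between two coordinate sets (Å).

    With ``superpose_first`` (default) the minimal RMSD over rigid
    rotations + translations is returned; otherwise the raw RMSD of the
    coordinates as given.  ``selection`` is an optional index list applied
    to both frames.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        sel = list(selection)
        a = a[sel]
        b = b[sel]
    if a.shape != b.shape:
        raise ValueError("selections have mismatched cardinality")
    if superpose_first:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, selection=None, ref_frame: int = 0,
                superpose_first: bool = True) -> np.ndarray:
    """RMSD of every frame relative to ``ref_frame`` over ``selection``."""
    idx = resolve_selection(traj.topology, selection)
    ref = traj.frames[ref_frame].coords[idx]
    return np.array([
        rmsd(fr.coords[idx], ref, superpose_first=superpose_first)
        for fr in traj.frames
    ])


def rmsf(traj: Trajectory, selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation over the trajectory (Å).

    Each frame's selected atoms are first superposed onto frame 0; the
    fluctuation of atom i is sqrt(mean_t |x_i(t) − x̄_i|²) over the
    superposed coordinates.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = resolve_selection(traj.topology, selection)
    ref = traj.frames[0].coords[idx]
    aligned = np.stack([superpose(fr.coords[idx], ref) for fr in traj.frames])
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hydrogen_bonds(traj: Trajectory, donor_list, acceptor_list,
                   d_cut: float = 3.5, angle_cut: float = 120.0) -> dict:
    """Geometric hydrogen-bond occupancies over a trajectory.

    ``donor_list`` holds (D_heavy, H) atom-index pairs; ``acceptor_list``
    holds heavy-atom indices.  A bond is present in a frame iff
    dist(D, A) ≤ ``d_cut`` and the D–H···A angle at H is ≥ ``angle_cut``
    degrees.  Donor pairs whose H strays beyond 1.5 Å from D in any frame
    are implausible as covalent pairs and are skipped with a warning.

    Returns {(d_heavy, h, acceptor): occupancy in [0, 1]}.
    """
    donors = []
    for d, h in donor_list:
        dh = max(
            np.linalg.norm(minimum_image_displacement(
                fr.coords[h] - fr.coords[d], fr.box))
            for fr in traj.frames
        )
        if dh > 1.5:
            warnings.warn(
                f"donor pair ({d}, {h}) skipped: H is {dh:.2f} Å from the "
                "heavy atom (not plausibly bonded)"
            )
            continue
        donors.append((d, h))

    occ = {}
    nf = traj.n_frames
    for d, h in donors:
        for a in acceptor_list:
            if a == d:
                continue
            hits = 0
            for fr in traj.frames:
                da = np.linalg.norm(minimum_image_displacement(
                    fr.coords[a] - fr.coords[d], fr.box))
                if da > d_cut:
                    continue
                v1 = minimum_image_displacement(fr.coords[d] - fr.coords[h], fr.box)
                v2 = minimum_image_displacement(fr.coords[a] - fr.coords[h], fr.box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang >= angle_cut:
                    hits += 1
            occ[(d, h, a)] = hits / nf
    return occ


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(coords: np.ndarray, elements, radii_map=None, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area, per atom (Å²).

    Test points are placed quasi-uniformly at radius r_i + probe around
    each atom; a point is accessible iff it lies outside every other atom's
    expanded sphere.  area_i = 4π(r_i + probe)² × accessible fraction.
    """
    radii_map = DEFAULT_RADII if radii_map is None else radii_map
    coords = np.asarray(coords, dtype=float)
    lut = {k.upper(): v for k, v in radii_map.items()}
    try:
        radii = np.array([lut[str(e).upper()] for e in elements], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no radius for element {exc.args[0]!r}") from None
    n = len(coords)
    expanded = radii + probe
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


# ---------------------------------------------------------------------------
# chromophore planarity
# ---------------------------------------------------------------------------

def chromophore_planarity(traj: Trajectory, ring_selection) -> np.ndarray:
    """Per-frame RMS deviation of the selected atoms from their best plane (Å)."""
    idx = resolve_selection(traj.topology, ring_selection)
    if len(idx) < 4:
        raise ValueError("planarity needs at least 4 atoms")
    out = np.empty(traj.n_frames)
    for t, fr in enumerate(traj.frames):
        X = fr.coords[idx]
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        normal = Vt[-1]
        out[t] = float(np.sqrt(np.mean((Xc @ normal) ** 2)))
    return out
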