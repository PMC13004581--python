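"""Synthetic inputs with planted ground truth.

Every pipeline stage can be exercised without simulation engines or wet-lab
data: generators here emit family alignments with planted pocket matches,
coarse-grained trajectories with a scripted anion entry path and structured
hydration shells, constant-pH state series with planted pKa and
binding-coupled protonation, and titration / pH-response curves built from
the one-site isotherm and Henderson–Hasselbalch models.

The anion presets carry the measured constants of the chloride-family
sensor this package characterises: dissociation constants of 25.2 mM
(chloride), 15.1 mM (bromide), 5.3 mM (iodide) and 10.7 mM (nitrate);
ionic radii 1.81 / 1.96 / 2.20 / 2.64 Å; gluconate as the non-binding
control.  Chromophore-pKa presets: 4.9 (apo), 5.2 (chloride-bound), and
3.6 / 4.0 for the gate-histidine alanine mutant.

The synthetic "barrel" is a coarse cylinder of pseudo-residues — enough
geometry for contact, entry and solvation analytics without pretending to
be physics.  Water is represented by its oxygen only.  Seeds are mandatory
state: no generator touches global RNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .photophysics import PHResponseCurve, TitrationCurve
from .pocket_mining import DEFAULT_HYDROPHOBIC, MultipleAlignment, PocketSpec
from .traj_io import Frame, TitrationStateSeries, Topology, Trajectory

_AVOGADRO = 6.02214076e23
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated artifact, sufficient to verify any
    downstream result exactly."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"kind": self.kind, "seed": self.seed, "params": self.params},
                       indent=2, default=_jsonable),
            encoding="utf-8",
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnionPreset:
    """Measured constants of one anion against the sensor."""

    name: str
    kd_mm: float | None        # dissociation constant, mM (None: non-binding)
    ionic_radius: float | None  # Å
    first_shell_radius: float | None  # Å, planted first-shell peak
    shell_count_hint: int       # waters coordinated in the first shell
    binds: bool

    def __post_init__(self):
        if self.binds and (self.kd_mm is None or self.kd_mm <= 0):
            raise ValueError("binding presets need a positive Kd")


ANION_PRESETS = {
    "chloride": AnionPreset("chloride", 25.2, 1.81, 3.5, 4, True),
    "bromide": AnionPreset("bromide", 15.1, 1.96, 3.6, 4, True),
    "iodide": AnionPreset("iodide", 5.3, 2.20, 3.7, 4, True),
    "nitrate": AnionPreset("nitrate", 10.7, 2.64, 3.5, 3, True),
    "gluconate": AnionPreset("gluconate", None, None, None, 0, False),
}

#: Chromophore pKa presets (50 %-retention scale).
PKA_PRESETS = {
    "apo": 4.9,
    "chloride_bound": 5.2,
    "h149a_apo": 3.6,
    "h149a_chloride_bound": 4.0,
}

_DEFAULT_CONCENTRATIONS = (0.0, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_NONHYDRO = "".join(sorted(set(_AA20) - set(DEFAULT_HYDROPHOBIC)))


def gen_alignment(n_members: int, pocket_spec: PocketSpec, planted,
                  gap_rate: float = 0.05, seed: int = 0,
                  length: int | None = None,
                  candidate_positions=None,
                  n_insert_columns: int = 3):
    """Generate a family alignment realizing planted pocket-match counts.

    Member 0 is the reference (``pocket_spec.reference_id``), gap-free and
    matching its own pattern everywhere.  ``planted`` gives, per remaining
    member, a ``(n_matches, is_candidate)`` pair; candidates present
    hydrophobic residues at every ``candidate_position`` (default: first
    and last pocket position), non-candidates never do.  Insert columns
    (all-gap in the reference) exercise the position-to-column mapping.

    Returns (MultipleAlignment, SyntheticTruth).
    """
    planted = list(planted)
    if len(planted) != n_members - 1:
        raise ValueError("planted must list n_members - 1 entries")
    positions = list(pocket_spec.positions)
    npos = len(positions)
    if candidate_positions is None:
        candidate_positions = [positions[0], positions[-1]]
    cand_set = set(candidate_positions)
    if not cand_set <= set(positions):
        raise ValueError("candidate_positions must be pocket positions")
    max_cand_matches = npos - len(cand_set)
    for p, e in zip(positions, pocket_spec.expected_residues):
        if p in cand_set and e.upper() in DEFAULT_HYDROPHOBIC:
            raise ValueError(
                "candidate positions with hydrophobic expected residues make "
                "the planted candidate flags ambiguous"
            )
    for n_match, is_cand in planted:
        if not 0 <= n_match <= npos:
            raise ValueError(f"infeasible plant: {n_match} matches for {npos} positions")
        if is_cand and n_match > max_cand_matches:
            raise ValueError(
                "infeasible plant: a candidate cannot match at candidate positions"
            )

    rng = np.random.default_rng(seed)
    L = length if length is not None else max(positions) + 7
    if L < max(positions):
        raise ValueError("length shorter than the largest pocket position")
    pos0 = [p - 1 for p in positions]

    ref_core = rng.choice(list(_AA20), size=L).tolist()
    for p, e in zip(pos0, pocket_spec.expected_residues):
        ref_core[p] = e.upper()

    hydro = sorted(DEFAULT_HYDROPHOBIC)
    cores = [ref_core]
    ids = [pocket_spec.reference_id]
    for m, (n_match, is_cand) in enumerate(planted):
        core = rng.choice(list(_AA20), size=L).tolist()
        # never let an off-pocket draw accidentally extend the plant: only
        # pocket columns are compared downstream, so off-pocket is free
        eligible = [i for i, p in enumerate(positions)
                    if not (is_cand and p in cand_set)]
        matched = set(rng.choice(eligible, size=n_match, replace=False).tolist()) \
            if n_match else set()
        for i, (p, pref, e) in enumerate(zip(pos0, positions,
                                             pocket_spec.expected_residues)):
            e = e.upper()
            if i in matched:
                core[p] = e
            elif is_cand and pref in cand_set:
                core[p] = str(rng.choice([h for h in hydro if h != e]))
            elif pref in cand_set:
                core[p] = str(rng.choice([c for c in _NONHYDRO if c != e]))
            else:
                core[p] = str(rng.choice([c for c in _AA20 if c != e]))
        if gap_rate > 0:
            for i in range(L):
                if i not in pos0 and rng.random() < gap_rate:
                    core[i] = "-"
        cores.append(core)
        ids.append(f"M{m + 1:04d}")

    insert_slots = sorted(rng.integers(0, L + 1, size=n_insert_columns).tolist(),
                          reverse=True) if n_insert_columns else []
    seqs = []
    for k, core in enumerate(cores):
        s = list(core)
        for slot in insert_slots:
            if k == 0:
                ch = "-"
            else:
                ch = str(rng.choice(list(_AA20))) if rng.random() < 0.5 else "-"
            s.insert(slot, ch)
        seqs.append("".join(s))

    aln = MultipleAlignment(members=tuple(zip(ids, seqs)))
    truth = SyntheticTruth(
        kind="alignment", seed=seed,
        params={
            "member_ids": ids[1:],
            "n_matches": [n for n, _ in planted],
            "is_candidate": [c for _, c in planted],
            "reference_id": pocket_spec.reference_id,
            "positions": positions,
            "candidate_positions": sorted(cand_set),
        },
    )
    return aln, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_CAVITY_NAMES = {64: "TYR", 66: "LEU", 67: "SER", 97: "ARG", 101: "PHE",
                 168: "LYS", 182: "HIS"}
DEFAULT_CAVITY_RESIDS = (64, 66, 67, 97, 101, 168, 182)
DEFAULT_GATE_PAIR = (208, 146)

_SHELL_DIRS = np.array([
    [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
    [1, 1, -1], [-1, -1, -1], [1, -1, 1], [-1, 1, 1],
], dtype=float) / np.sqrt(3.0)


def _cavity_directions(n):
    base = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ], dtype=float)
    extra = _SHELL_DIRS
    dirs = np.vstack([base, extra])
    if n > len(dirs):
        raise ValueError("too many cavity residues for the template")
    return dirs[:n]


def gen_trajectory(n_frames: int = 300, entry_frame: int = 120,
                   persistence: int | None = None,
                   anion_script: str = "bulk_to_cavity",
                   cavity_resids=DEFAULT_CAVITY_RESIDS,
                   gate_pair=DEFAULT_GATE_PAIR,
                   n_shell_waters: int = 4, shell_radius: float = 3.2,
                   box=(60.0, 60.0, 60.0), anion_element: str = "Cl",
                   thermal_sigma: float = 0.05, seed: int = 0):
    """A coarse β-barrel with a scripted anion path and hydration shell.

    Geometry: a planar chromophore ring sits at the box centre; the binding
    cavity lies a few Å beneath it, ringed by single-atom pseudo-residues
    carrying the requested ``cavity_resids``; a gate pair flanks the entry
    route on the barrel wall, with a decoy pair on the far side.  Under the
    default ``bulk_to_cavity`` script the anion approaches from beyond the
    bulk radius, crosses into the interior exactly at ``entry_frame`` and
    sits in the cavity for ``persistence`` frames (default: the remainder);
    ``bulk_only`` keeps it in bulk solvent throughout.  While cavity-bound,
    exactly ``n_shell_waters`` water oxygens ride at ``shell_radius`` from
    the anion; otherwise the waters are parked far away.

    Returns (Trajectory, SyntheticTruth).
    """
    if anion_script not in ("bulk_to_cavity", "bulk_only"):
        raise ValueError(f"unknown anion_script {anion_script!r}")
    if not 1 <= entry_frame < n_frames:
        raise ValueError("entry_frame must lie in [1, n_frames)")
    if persistence is None:
        persistence = n_frames - entry_frame
    if entry_frame + persistence > n_frames:
        raise ValueError("entry_frame + persistence exceeds n_frames")
    box = tuple(float(b) for b in box)
    center = np.array(box) / 2.0
    cavity_point = center + np.array([2.0, 0.0, -4.0])
    if np.any(cavity_point < 0) or np.any(cavity_point > np.array(box)):
        raise ValueError("cavity lies outside the box")
    if shell_radius >= 8.0:
        raise ValueError("shell_radius must stay inside the interior radius")

    rng = np.random.default_rng(seed)
    rows = []
    base = []

    def add_atom(name, element, resname, resid, xyz, chain="A"):
        rows.append((len(rows) + 1, name, element, resname, resid, chain))
        base.append(np.asarray(xyz, dtype=float))

    # chromophore: planar 5-ring at the centre
    for i in range(5):
        ang = 2 * np.pi * i / 5
        add_atom(f"C{i + 1}", "C", "CRO", 1,
                 center + 1.2 * np.array([np.cos(ang), np.sin(ang), 0.0]))
    # cavity pseudo-residues on a 3 Å shell around the cavity point
    dirs = _cavity_directions(len(cavity_resids))
    for rid, d in zip(cavity_resids, dirs):
        add_atom("CB", "C", _CAVITY_NAMES.get(rid, "GLY"), int(rid),
                 cavity_point + 3.0 * d)
    # gate pair on the barrel wall along the entry route, plus a decoy pair
    gate_a, gate_b = gate_pair
    add_atom("CB", "C", "PHE", int(gate_a), center + np.array([10.0, 1.5, -4.0]))
    add_atom("CB", "O", "SER", int(gate_b), center + np.array([10.0, -1.5, -4.0]))
    add_atom("CB", "C", "GLY", 300, center + np.array([-10.0, 1.5, -4.0]))
    add_atom("CB", "C", "GLY", 301, center + np.array([-10.0, -1.5, -4.0]))
    # barrel wall: CA pseudo-residues on a cylinder
    rid = 310
    for s in range(8):
        ang = 2 * np.pi * s / 8
        for z in np.linspace(-12.0, 12.0, 6):
            add_atom("CA", "C", "GLY", rid,
                     center + np.array([8.0 * np.cos(ang), 8.0 * np.sin(ang), z]))
            rid += 1
    n_protein = len(rows)
    # anion
    anion_resid = 400
    add_atom(anion_element.upper(), anion_element.capitalize(), "CLA",
             anion_resid, cavity_point)  # placeholder; scripted below
    # shell waters
    water_resid0 = 501
    for w in range(n_shell_waters):
        add_atom("O", "O", "WAT", water_resid0 + w, np.zeros(3))

    top = Topology.from_rows(rows)
    base = np.array(base)
    anion_idx = n_protein
    water_idx = list(range(n_protein + 1, n_protein + 1 + n_shell_waters))
    park = center + np.array([0.0, -25.0, 0.0])

    entry_dir = np.array([1.0, 0.0, 0.0])
    start_d, approach_d = 23.0, 9.0
    bound = np.zeros(n_frames, dtype=bool)
    if anion_script == "bulk_to_cavity":
        bound[entry_frame:entry_frame + persistence] = True

    frames = []
    shell_dirs = _SHELL_DIRS[:n_shell_waters]
    for t in range(n_frames):
        coords = base.copy()
        if thermal_sigma > 0:
            coords[:n_protein] += rng.normal(0.0, thermal_sigma, size=(n_protein, 3))
        if anion_script == "bulk_only":
            anion = cavity_point + entry_dir * (start_d + 2.0 * np.sin(t / 7.0))
        elif bound[t]:
            anion = cavity_point + rng.normal(0.0, 0.02, size=3)
        elif t < entry_frame:
            frac = t / max(entry_frame - 1, 1)
            anion = cavity_point + entry_dir * (start_d - (start_d - approach_d) * frac)
        else:  # post-residence exit back to bulk
            anion = cavity_point + entry_dir * (start_d - 1.0)
        coords[anion_idx] = anion
        if bound[t]:
            shells = anion + shell_radius * shell_dirs \
                + rng.normal(0.0, 0.02, size=(n_shell_waters, 3))
        else:
            shells = park + np.arange(n_shell_waters)[:, None] * np.array([3.0, 0, 0])
        for k, wi in enumerate(water_idx):
            coords[wi] = shells[k]
        frames.append(Frame(coords=coords, box=box))

    traj = Trajectory(topology=top, frames=frames)
    truth = SyntheticTruth(
        kind="trajectory", seed=seed,
        params={
            "anion_script": anion_script,
            "entry_frame": entry_frame if anion_script == "bulk_to_cavity" else None,
            "persistence": persistence if anion_script == "bulk_to_cavity" else 0,
            "bound_frames": np.nonzero(bound)[0].tolist(),
            "cavity_resids": list(cavity_resids),
            "gate_pair": list(gate_pair),
            "decoy_pair": [300, 301],
            "anion_resid": anion_resid,
            "n_shell_waters": n_shell_waters,
            "shell_radius": shell_radius,
            "water_resids": list(range(water_resid0, water_resid0 + n_shell_waters)),
        },
    )
    traj.truth = truth
    return traj, truth


def gen_solvation_box(n_targets: int, mode: str = "uniform",
                      box=(30.0, 30.0, 30.0), n_frames: int = 20,
                      r0: float = 3.5, k: int = 6, seed: int = 0) -> Trajectory:
    """A center particle plus target oxygens: an RDF test bed.

    ``uniform`` draws i.i.d. target positions each frame (ideal gas, g ≈ 1);
    ``planted_shell`` pins ``k`` targets on a sphere of radius ``r0`` around
    the centre and scatters the rest uniformly outside the ion's excluded
    volume (no background target closer than r0 + 0.5 Å to the centre), so
    the first g(r) feature is the planted shell itself.
    """
    if mode not in ("uniform", "planted_shell"):
        raise ValueError(f"unknown mode {mode!r}")
    box = tuple(float(b) for b in box)
    if mode == "planted_shell" and r0 >= min(box) / 2:
        raise ValueError("shell radius must be below half the box")
    if mode == "planted_shell" and k > n_targets:
        raise ValueError("k exceeds n_targets")
    rng = np.random.default_rng(seed)
    center = np.array(box) / 2.0
    rows = [(1, "CL", "Cl", "CLA", 1, "A")]
    for i in range(n_targets):
        rows.append((i + 2, "O", "O", "WAT", 100 + i, "A"))
    top = Topology.from_rows(rows)

    shell_dirs = None
    if mode == "planted_shell":
        pts = []
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(k):
            z = 1 - 2 * (i + 0.5) / k
            r = np.sqrt(1 - z * z)
            pts.append([r * np.cos(golden * i), r * np.sin(golden * i), z])
        shell_dirs = np.array(pts)

    frames = []
    for _ in range(n_frames):
        coords = np.empty((n_targets + 1, 3))
        coords[0] = center
        if mode == "uniform":
            coords[1:] = rng.uniform(0.0, box, size=(n_targets, 3))
        else:
            coords[1:k + 1] = center + r0 * shell_dirs
            n_bg = n_targets - k
            bg = np.empty((0, 3))
            while len(bg) < n_bg:
                cand = rng.uniform(0.0, box, size=(n_bg, 3))
                delta = cand - center
                delta -= np.array(box) * np.round(delta / np.array(box))
                keep = np.linalg.norm(delta, axis=1) >= r0 + 0.5
                bg = np.vstack([bg, cand[keep]])
            coords[k + 1:] = bg[:n_bg]
        frames.append(Frame(coords=coords, box=box))
    traj = Trajectory(topology=top, frames=frames)
    traj.truth = SyntheticTruth(
        kind="solvation_box", seed=seed,
        params={"mode": mode, "r0": r0 if mode == "planted_shell" else None,
                "k": k if mode == "planted_shell" else None,
                "n_targets": n_targets},
    )
    return traj


# ---------------------------------------------------------------------------
# constant-pH state series
# ---------------------------------------------------------------------------

def gen_cphmd_states(n_frames: int, residues, pH: float,
                     coupling: dict | None = None, occupancy=None,
                     seed: int = 0, two_site=()) -> TitrationStateSeries:
    """Per-frame protonation states with planted pKa and binding coupling.

    ``residues`` lists (residue_id, residue_name, pKa).  Each frame, a
    residue is protonated with probability 1/(1 + 10^(pH − pKa)); for
    residues named in ``coupling`` the probability on anion-bound frames
    (per ``occupancy``) is replaced by the coupled value.  Residues in
    ``two_site`` split their protonated records over state indices 1 and 2
    (a carboxylate's two oxygens); all others use 0/1.
    """
    import pandas as pd

    coupling = coupling or {}
    if coupling and occupancy is None:
        raise ValueError("coupling requires an occupancy series")
    if occupancy is not None:
        bound = np.asarray(getattr(occupancy, "bound", occupancy), dtype=bool)
        if len(bound) != n_frames:
            raise ValueError(
                f"occupancy covers {len(bound)} frames, series needs {n_frames}"
            )
    else:
        bound = np.zeros(n_frames, dtype=bool)
    for p in coupling.values():
        if not 0.0 <= p <= 1.0:
            raise ValueError("coupled probabilities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    two_site = set(two_site)
    records = []
    truth_params = {}
    for rid, rname, pka in residues:
        p_base = 1.0 / (1.0 + 10.0 ** (pH - pka))
        truth_params[int(rid)] = {
            "pKa": pka, "p_protonated": p_base,
            "coupled_p": coupling.get(rid),
        }
        for t in range(n_frames):
            p = coupling[rid] if (rid in coupling and bound[t]) else p_base
            prot = bool(rng.random() < p)
            if prot:
                state = int(rng.integers(1, 3)) if rid in two_site else 1
            else:
                state = 0
            records.append((t, int(rid), rname, state, prot, pH))
    df = pd.DataFrame(records, columns=["frame", "residue_id", "residue_name",
                                        "state_index", "is_protonated", "pH"])
    series = TitrationStateSeries(df=df)
    series.truth = SyntheticTruth(kind="cphmd_states", seed=seed,
                                  params={"pH": pH, "residues": truth_params})
    return series


# ---------------------------------------------------------------------------
# spectroscopy curves
# ---------------------------------------------------------------------------

def _resolve_preset(preset):
    if isinstance(preset, AnionPreset):
        return preset
    if isinstance(preset, str):
        try:
            return ANION_PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown anion preset {preset!r}") from None
    kd, fmin, fmax = preset
    return AnionPreset("custom", float(kd), None, None, 0, True), float(fmin), float(fmax)


def gen_titration(preset, concentrations=None, noise_sd: float = 0.0,
                  n_replicates: int = 1, seed: int = 0,
                  fmin: float = 1.0, fmax: float = 0.2) -> TitrationCurve:
    """Emission titration from the one-site isotherm, plus Gaussian noise.

    ``preset`` is an anion preset name/object or an explicit
    ``(Kd, Fmin, Fmax)`` triple.  Non-binding presets yield a flat series
    at Fmin (no dose response).  Returns a
    :class:`~anionscout.photophysics.TitrationCurve` with a ``truth``
    attribute recording the planted parameters.
    """
    resolved = _resolve_preset(preset)
    if isinstance(resolved, tuple):
        p, fmin, fmax = resolved
    else:
        p = resolved
    conc = np.asarray(
        _DEFAULT_CONCENTRATIONS if concentrations is None else concentrations,
        dtype=float,
    )
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if p.binds:
        ideal = conc * (fmax - fmin) / (p.kd_mm + conc) + fmin
    else:
        ideal = np.full_like(conc, fmin)
    intensities = ideal[:, None] + rng.normal(0.0, noise_sd,
                                              size=(len(conc), n_replicates))
    curve = TitrationCurve(anion=p.name, concentrations=conc,
                           intensities=intensities)
    curve.truth = SyntheticTruth(
        kind="titration", seed=seed,
        params={"anion": p.name, "kd_mm": p.kd_mm, "fmin": fmin,
                "fmax": fmax, "binds": p.binds, "noise_sd": noise_sd},
    )
    return curve


def gen_ph_curve(pka, ph_grid=None, noise_sd: float = 0.0, seed: int = 0,
                 amplitude: float = 1.0, baseline: float = 0.05) -> PHResponseCurve:
    """A Henderson–Hasselbalch pH-response curve, normalized to min/max.

    ``pka`` may be a number or a key of :data:`PKA_PRESETS`.  Raw intensity
    tracks the deprotonated (fluorescent phenolate) fraction
    1/(1 + 10^(pKa − pH)) scaled by ``amplitude`` over ``baseline``.
    """
    if isinstance(pka, str):
        try:
            pka = PKA_PRESETS[pka]
        except KeyError:
            raise ValueError(f"unknown pKa preset {pka!r}") from None
    ph = np.asarray(
        np.arange(3.5, 8.0 + 1e-9, 0.25) if ph_grid is None else ph_grid,
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    raw = baseline + amplitude / (1.0 + 10.0 ** (pka - ph))
    raw = raw + rng.normal(0.0, noise_sd, size=len(ph))
    curve = PHResponseCurve.from_raw(ph, raw)
    curve.truth = SyntheticTruth(kind="ph_curve", seed=seed,
                                 params={"pKa": float(pka), "noise_sd": noise_sd})
    return curve


# ---------------------------------------------------------------------------
# ion counts
# ---------------------------------------------------------------------------

def ion_counts_for_box(target_ionic_strength: float, box_volume: float,
                       protein_charge: int, anion_charge: int = -1,
                       cation_charge: int = 1):
    """Ion counts for a neutral box at a target ionic strength.

    For a salt of charges (z₋, z₊) at neutral stoichiometry the ionic
    strength is I = ½ Σ cᵢzᵢ², giving an anion concentration
    c₋ = 2I / (z₋² + |z₋|·z₊); for a monovalent pair this reduces to
    c₋ = I.  ``n_anion = round(c₋·V·N_A)``; the cation count is then set so
    total ionic charge cancels ``protein_charge``.  Volume in Å³,
    concentrations in mol/L.
    """
    if box_volume <= 0:
        raise ValueError("box volume must be positive")
    if anion_charge >= 0 or cation_charge <= 0:
        raise ValueError("anion charge must be negative, cation positive")
    za, zc = abs(anion_charge), cation_charge
    c_anion = 2.0 * target_ionic_strength / (za * za + za * zc)
    n_anion = int(round(c_anion * box_volume * 1e-27 * _AVOGADRO))
    needed = -protein_charge - n_anion * anion_charge
    if needed % cation_charge != 0 or needed < 0:
        raise ValueError(
            "charge neutrality unreachable with integer cation counts "
            f"(residual charge {needed}, cation charge {cation_charge})"
        )
    return n_anion, needed // cation_charge
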