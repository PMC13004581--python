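"""Structure, trajectory and constant-pH state carriers.

The in-memory model is deliberately small: a :class:`Topology` (atom
metadata), a list of :class:`Frame` objects (Å coordinates plus an optional
orthorhombic box) and, for constant-pH runs, a :class:`TitrationStateSeries`
table of per-frame protonation states.

On disk, trajectories travel as multi-model PDB (one ``MODEL`` block per
frame, ``CRYST1`` for the box) — universal and text-diffable.  Parsing and
writing are delegated to MDAnalysis; a light pre-scan enforces the error
contract (inconsistent atom counts across models, unparseable coordinate
fields) with messages that name the offending model or line.

Distances honour the minimum-image convention whenever a box is present:
every displacement component is wrapped into ``(-L/2, L/2]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class PDBFormatError(ValueError):
    """Raised when a PDB file violates the multi-model trajectory contract."""


class SelectionError(ValueError):
    """Raised on a syntax error in a selection expression."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Per-atom metadata shared by all frames of a trajectory.

    Atoms are stored column-wise.  Serials are unique and strictly
    increasing; residue ids follow PDB convention (1-based, not necessarily
    contiguous).
    """

    serials: tuple
    names: tuple
    elements: tuple
    resnames: tuple
    resids: tuple
    chains: tuple

    def __post_init__(self):
        n = len(self.serials)
        for attr in ("names", "elements", "resnames", "resids", "chains"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology column {attr!r} has wrong length")
        if n and any(b <= a for a, b in zip(self.serials, self.serials[1:])):
            raise ValueError("atom serials must be unique and increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "Topology":
        """Build from rows of (serial, name, element, resname, resid, chain)."""
        cols = list(zip(*rows)) or [(), (), (), (), (), ()]
        return cls(*(tuple(c) for c in cols))


@dataclass
class Frame:
    """One snapshot: ``coords`` (n_atoms, 3) in Å and an optional box.

    ``box`` is the orthorhombic edge-length triple (Lx, Ly, Lz) in Å, or
    ``None`` for a non-periodic snapshot.
    """

    coords: np.ndarray
    box: tuple | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = tuple(float(x) for x in self.box)
            if len(self.box) != 3 or any(x <= 0 for x in self.box):
                raise ValueError("box lengths must be three positive values")


@dataclass
class Trajectory:
    """A topology plus one or more frames."""

    topology: Topology
    frames: list

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != self.topology.n_atoms:
                raise ValueError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, topology has "
                    f"{self.topology.n_atoms}"
                )

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, selection=None) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_sel, 3)."""
        idx = resolve_selection(self.topology, selection)
        return np.stack([fr.coords[idx] for fr in self.frames])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def minimum_image_displacement(delta: np.ndarray, box) -> np.ndarray:
    """Wrap displacement components into the primary image ``(-L/2, L/2]``."""
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    wrapped = delta - box * np.round(delta / box)
    # banker's rounding can leave a component at exactly -L/2
    return np.where(wrapped <= -box / 2, wrapped + box, wrapped)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box=None) -> np.ndarray:
    """All a-to-b distances, minimum-image when ``box`` is given.

    Returns an (len(a), len(b)) matrix.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    diff = a[:, None, :] - b[None, :, :]
    diff = minimum_image_displacement(diff, box)
    return np.linalg.norm(diff, axis=-1)


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = {"N", "CA", "C", "O"}
_KEYWORDS = {"and", "or", "not", "name", "resname", "resid", "element",
             "backbone", "heavy", "all", "(", ")"}


def _tokenize(expr: str):
    out = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    """Recursive-descent parser over the tiny selection grammar.

    expr   := and_expr ('or' and_expr)*
    and    := not_expr ('and' not_expr)*
    not    := 'not' not | primary
    primary:= '(' expr ')' | backbone | heavy | all
              | name/resname/element VALUE+ | resid RANGE+
    """

    def __init__(self, tokens, topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self._names = np.array([n.upper() for n in topology.names])
        self._resnames = np.array([r.upper() for r in topology.resnames])
        self._elements = np.array([e.upper() for e in topology.elements])
        self._resids = np.array(topology.resids, dtype=int) if topology.n_atoms else np.array([], dtype=int)

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self):
        mask = self.not_expr()
        while self.peek() == "and":
            self.take()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self):
        if self.peek() == "not":
            self.take()
            return ~self.not_expr()
        return self.primary()

    def _values(self):
        vals = []
        while self.peek() is not None and self.peek().lower() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword needs at least one value")
        return vals

    def primary(self):
        tok = self.take()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        low = tok.lower()
        n = self.top.n_atoms
        if low == "(":
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parenthesis")
            return mask
        if low == "all":
            return np.ones(n, dtype=bool)
        if low == "backbone":
            return np.isin(self._names, sorted(_BACKBONE_NAMES))
        if low == "heavy":
            return self._elements != "H"
        if low == "name":
            vals = [v.upper() for v in self._values()]
            return np.isin(self._names, vals)
        if low == "resname":
            vals = [v.upper() for v in self._values()]
            return np.isin(self._resnames, vals)
        if low == "element":
            vals = [v.upper() for v in self._values()]
            return np.isin(self._elements, vals)
        if low == "resid":
            mask = np.zeros(n, dtype=bool)
            for val in self._values():
                try:
                    if ":" in val:
                        lo, hi = val.split(":")
                        mask |= (self._resids >= int(lo)) & (self._resids <= int(hi))
                    else:
                        mask |= self._resids == int(val)
                except ValueError as exc:
                    raise SelectionError(f"bad resid value {val!r}") from exc
            return mask
        raise SelectionError(f"unknown token {tok!r}")


def select(topology: Topology, expression: str):
    """Resolve a selection expression to an ordered list of atom indices.

    Supported terms: ``name``, ``resname``, ``element``, ``resid`` (single
    ids or ``lo:hi`` ranges), the named sets ``backbone`` (N, CA, C, O) and
    ``heavy`` (element ≠ H), ``all``, combined with ``and``/``or``/``not``
    and parentheses.  Empty selections are allowed.
    """
    mask = _Parser(_tokenize(expression), topology).parse()
    return [int(i) for i in np.nonzero(mask)[0]]


def resolve_selection(topology: Topology, selection):
    """Accept a selection string, an index sequence, or None (= all atoms)."""
    if selection is None:
        return list(range(topology.n_atoms))
    if isinstance(selection, str):
        return select(topology, selection)
    return [int(i) for i in selection]


# ---------------------------------------------------------------------------
# PDB carrier (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _scan_pdb(path: Path):
    """Pre-validate a (multi-model) PDB file.

    Checks that every ATOM/HETATM line carries parseable coordinates and
    that every MODEL block has the same atom count; errors name the line or
    model at fault.
    """
    model_counts = []
    loose_count = 0
    in_model = False
    current = 0
    cryst = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1" and cryst is None:
                try:
                    cryst = tuple(
                        float(line[start:end]) for start, end in
                        [(6, 15), (15, 24), (24, 33), (33, 40), (40, 47), (47, 54)]
                    )
                except (ValueError, IndexError):
                    raise PDBFormatError(
                        f"{path}: unparseable CRYST1 record on line {lineno}"
                    )
            elif rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                model_counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise PDBFormatError(
                        f"{path}: unparseable coordinate fields on line {lineno}"
                    )
                if in_model:
                    current += 1
                else:
                    loose_count += 1
    if model_counts:
        ref = model_counts[0]
        for i, c in enumerate(model_counts[1:], start=2):
            if c != ref:
                raise PDBFormatError(
                    f"{path}: MODEL {i} has {c} atoms, expected {ref}"
                )
        if ref == 0:
            raise PDBFormatError(f"{path}: MODEL blocks contain no atoms")
    elif loose_count == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    # a unitary cell is the conventional "no box" placeholder
    if cryst is not None and np.allclose(cryst[:3], 1.0):
        cryst = None
    return cryst


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_trajectory(path) -> Trajectory:
    """Read a PDB or multi-model PDB file into a :class:`Trajectory`.

    Each ``MODEL`` block becomes one frame sharing a single topology;
    ``CRYST1`` (if present and not a placeholder) populates the box.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_cryst = _scan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = u.atoms
        try:
            elements = [str(e) for e in atoms.elements]
        except Exception:
            elements = [_guess_element(n) for n in atoms.names]
        try:
            chains = [str(c) for c in atoms.chainIDs]
        except Exception:
            chains = [""] * len(atoms)
        top = Topology(
            serials=tuple(int(s) for s in atoms.ids),
            names=tuple(str(n) for n in atoms.names),
            elements=tuple(e.upper() if len(e) == 1 else e.capitalize() for e in elements),
            resnames=tuple(str(r) for r in atoms.resnames),
            resids=tuple(int(r) for r in atoms.resids),
            chains=tuple(chains),
        )
        frames = []
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None and header_cryst is not None:
                # multi-model readers only see per-MODEL CRYST1 records; a
                # single header CRYST1 applies to every frame
                dims = np.asarray(header_cryst, dtype=float)
            if dims is None or not np.all(np.asarray(dims[:3]) > 0):
                box = None
            else:
                if not np.allclose(dims[3:], 90.0):
                    raise PDBFormatError(
                        f"{path}: only orthorhombic boxes are supported"
                    )
                box = tuple(float(x) for x in dims[:3])
            frames.append(Frame(coords=ts.positions.astype(float).copy(), box=box))
    return Trajectory(topology=top, frames=frames)


def read_structure(path) -> Trajectory:
    """Read a single-model PDB; errors if the file holds multiple models."""
    traj = read_trajectory(path)
    if traj.n_frames != 1:
        raise PDBFormatError(
            f"{path}: expected a single structure, found {traj.n_frames} models"
        )
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (coordinates to 1e-3 Å)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    top = traj.topology
    boxed = [fr.box is not None for fr in traj.frames]
    if any(boxed) and not all(boxed):
        raise ValueError("all frames must agree on box presence for PDB output")

    # group consecutive atoms into residues on (chain, resid, resname) runs
    resindex = []
    res_keys = []
    for i in range(top.n_atoms):
        key = (top.chains[i], top.resids[i], top.resnames[i])
        if not res_keys or key != res_keys[-1]:
            res_keys.append(key)
        resindex.append(len(res_keys) - 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=top.n_atoms,
            n_residues=len(res_keys),
            atom_resindex=np.array(resindex, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("ids", np.array(top.serials, dtype=int))
        u.add_TopologyAttr("names", list(top.names))
        u.add_TopologyAttr("elements", list(top.elements))
        u.add_TopologyAttr("chainIDs", list(top.chains))
        u.add_TopologyAttr("resids", np.array([k[1] for k in res_keys], dtype=int))
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("occupancies", np.ones(top.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(top.n_atoms))

        coords = np.stack([fr.coords for fr in traj.frames]).astype(np.float32)
        if all(boxed):
            dims = np.array(
                [list(fr.box) + [90.0, 90.0, 90.0] for fr in traj.frames],
                dtype=np.float64,
            )
            u.load_new(coords, format=MemoryReader, dimensions=dims)
        else:
            u.load_new(coords, format=MemoryReader)
        with mda.Writer(str(path), n_atoms=top.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# constant-pH state table (TSV dialect)
# ---------------------------------------------------------------------------

_STATE_COLUMNS = ["frame", "residue_id", "residue_name", "state_index",
                  "is_protonated", "pH"]


@dataclass
class TitrationStateSeries:
    """Per-frame protonation states of titratable residues.

    Backed by a DataFrame with columns frame (0-based int), residue_id,
    residue_name, state_index (≥0), is_protonated (bool) and pH.  At most
    one record per (frame, residue_id).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in _STATE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"titration state table missing columns: {missing}")
        df = self.df.loc[:, _STATE_COLUMNS].copy()
        df["frame"] = df["frame"].astype(int)
        df["residue_id"] = df["residue_id"].astype(int)
        df["state_index"] = df["state_index"].astype(int)
        df["is_protonated"] = df["is_protonated"].astype(bool)
        df["pH"] = df["pH"].astype(float)
        if (df["state_index"] < 0).any():
            raise ValueError("state_index must be non-negative")
        dup = df.duplicated(subset=["frame", "residue_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate titration record for frame "
                f"{row['frame']}, residue {row['residue_id']}"
            )
        self.df = df

    @property
    def residue_ids(self):
        return sorted(self.df["residue_id"].unique().tolist())

    @property
    def n_records(self) -> int:
        return len(self.df)


def read_titration_states(path) -> TitrationStateSeries:
    """Read the TSV constant-pH state dialect."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _STATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    try:
        df["frame"] = df["frame"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer frame values") from exc
    if df["is_protonated"].dtype == object:
        df["is_protonated"] = df["is_protonated"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False, True: True, False: False}
        )
        if df["is_protonated"].isna().any():
            raise ValueError(f"{path}: unparseable is_protonated values")
    return TitrationStateSeries(df=df)


def write_titration_states(series: TitrationStateSeries, path) -> None:
    series.df.to_csv(path, sep="\t", index=False)
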