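"""Binding-pocket mining over family alignments.

Given a family alignment and a reference member whose anion-binding pocket
positions are known (for a YFP-like halide pocket: Q69, R96, Q183, Y203 in
the reference's own ungapped numbering), these operations map the pocket
positions to alignment columns, tabulate each member's residues there,
filter by minimum match count, summarise per-position residue diversity,
and pull out members presenting hydrophobic residues at chosen positions —
the route by which an anion-sensitive homolog can be singled out of a large
family.

Conventions: comparisons are case-insensitive; a gap at a pocket column is
never a match (a gapped member cannot present the residue); ambiguity codes
X/B/Z never match; ``.`` is normalised to ``-`` on input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

#: Standard nonpolar side chains used for hydrophobic-candidate ranking.
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFW")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = set("XBZ")
_ALPHABET = _AA20 | _AMBIGUOUS | {"-"}


@dataclass(frozen=True)
class MultipleAlignment:
    """An alignment as (member_id, aligned_seq) pairs of equal length."""

    members: tuple

    def __post_init__(self):
        ids = [m for m, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("member ids must be unique")
        lengths = {len(s) for _, s in self.members}
        if len(lengths) > 1:
            raise ValueError("all aligned sequences must share one length")
        if lengths and lengths.pop() < 1:
            raise ValueError("aligned sequences must be nonempty")
        for mid, seq in self.members:
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"member {mid!r} has invalid characters {sorted(bad)}")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        return len(self.members[0][1]) if self.members else 0

    def sequence(self, member_id: str) -> str:
        for mid, seq in self.members:
            if mid == member_id:
                return seq
        raise KeyError(f"member {member_id!r} not in alignment")


@dataclass(frozen=True)
class PocketSpec:
    """The reference pocket pattern to mine for.

    ``positions`` are 1-based ungapped indices into the reference member's
    own sequence; ``expected_residues`` align with them.
    """

    reference_id: str
    positions: tuple
    expected_residues: tuple
    min_matches: int = 2

    def __post_init__(self):
        if len(self.positions) != len(self.expected_residues):
            raise ValueError("positions and expected_residues must align")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based and must be ≥ 1")
        if self.min_matches < 0:
            raise ValueError("min_matches must be non-negative")


@dataclass
class PocketTable:
    """Per-member residues at the pocket columns and their match counts."""

    positions: tuple
    expected_residues: tuple
    member_ids: list
    residues: list  # list of tuples, one per member
    n_matches: list

    def rows(self):
        return zip(self.member_ids, self.residues, self.n_matches)


def read_alignment(path, fmt: str | None = None) -> MultipleAlignment:
    """Load an aligned FASTA or Stockholm file.

    Format is inferred from the suffix (``.sto``/``.stk`` → Stockholm,
    otherwise FASTA) unless given.  Sequences are uppercased and ``.``
    gaps normalised to ``-``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    members = tuple(
        (rec.id, str(rec.seq).upper().replace(".", "-")) for rec in aln
    )
    return MultipleAlignment(members=members)


def map_reference_positions(aln: MultipleAlignment, spec: PocketSpec):
    """Map ungapped reference positions to 1-based alignment columns.

    Column i of the result holds the reference residue whose ungapped index
    is ``spec.positions[i]``.
    """
    ref = aln.sequence(spec.reference_id)
    wanted = list(spec.positions)
    columns = {}
    count = 0
    for col, ch in enumerate(ref, start=1):
        if ch != "-":
            count += 1
            if count in wanted:
                columns[count] = col
    missing = [p for p in wanted if p not in columns]
    if missing:
        raise ValueError(
            f"position {missing[0]} exceeds the reference's ungapped length ({count})"
        )
    return [columns[p] for p in wanted]


def _matches(residue: str, expected: str) -> bool:
    r = residue.upper()
    if r == "-" or r in _AMBIGUOUS:
        return False
    return r == expected.upper()


def extract_pocket_table(aln: MultipleAlignment, spec: PocketSpec) -> PocketTable:
    """Tabulate every member's residues at the pocket columns."""
    cols = [c - 1 for c in map_reference_positions(aln, spec)]
    member_ids, residues, n_matches = [], [], []
    for mid, seq in aln.members:
        res = tuple(seq[c].upper() for c in cols)
        member_ids.append(mid)
        residues.append(res)
        n_matches.append(sum(
            _matches(r, e) for r, e in zip(res, spec.expected_residues)
        ))
    return PocketTable(
        positions=tuple(spec.positions),
        expected_residues=tuple(spec.expected_residues),
        member_ids=member_ids, residues=residues, n_matches=n_matches,
    )


def filter_members(table: PocketTable, min_matches: int):
    """Members with at least ``min_matches`` pocket matches, in input order."""
    if min_matches < 0:
        raise ValueError("min_matches must be non-negative")
    return [mid for mid, _, n in table.rows() if n >= min_matches]


def residue_distribution(table: PocketTable, position_index: int) -> Counter:
    """Residue counts at one pocket position (1-based index into positions).

    Gaps are tallied under ``'-'``; counts sum to the number of members.
    """
    if not 1 <= position_index <= len(table.positions):
        raise ValueError(
            f"position_index {position_index} out of range 1..{len(table.positions)}"
        )
    return Counter(res[position_index - 1] for res in table.residues)


def rank_hydrophobic_candidates(table: PocketTable, candidate_positions,
                                hydrophobic_set=DEFAULT_HYDROPHOBIC):
    """Members hydrophobic at *all* candidate positions.

    ``candidate_positions`` are reference positions (a subset of the pocket
    positions).  Returns (member_id, residues-at-candidate-positions) pairs.
    """
    hydro = {h.upper() for h in hydrophobic_set}
    if not hydro:
        raise ValueError("hydrophobic_set must be nonempty")
    try:
        idx = [table.positions.index(p) for p in candidate_positions]
    except ValueError as exc:
        raise ValueError(
            f"candidate positions must be a subset of pocket positions "
            f"{table.positions}"
        ) from exc
    out = []
    for mid, res, _ in table.rows():
        cand = tuple(res[i] for i in idx)
        if all(r.upper() in hydro for r in cand):
            out.append((mid, cand))
    return out
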