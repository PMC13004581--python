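"""Pocket-position mapping, match tabulation, filtering and candidate ranking."""

from collections import Counter

import numpy as np
import pytest

from anionscout.pocket_mining import (
    MultipleAlignment,
    PocketSpec,
    extract_pocket_table,
    filter_members,
    map_reference_positions,
    rank_hydrophobic_candidates,
    read_alignment,
    residue_distribution,
)
from anionscout.synthetic import gen_alignment

SPEC = PocketSpec("REF", (69, 96, 183, 203), ("Q", "R", "Q", "Y"), 2)


def brute_ungap_columns(aligned_seq, positions):
    """Oracle: walk the aligned string counting non-gaps."""
    out = []
    for target in positions:
        count = 0
        for col, ch in enumerate(aligned_seq, start=1):
            if ch != "-":
                count += 1
            if count == target and ch != "-":
                out.append(col)
                break
        else:
            raise AssertionError("position beyond ungapped length")
    return out


class TestPositionMapping:
    def test_gap_free_reference_is_identity(self):
        aln = MultipleAlignment(members=(("R1", "QRQY"),))
        spec = PocketSpec("R1", (1, 3), ("Q", "Q"))
        assert map_reference_positions(aln, spec) == [1, 3]

    def test_single_gap_shifts_column(self):
        aln = MultipleAlignment(members=(("R1", "A-CD"),))
        spec = PocketSpec("R1", (2,), ("C",))
        assert map_reference_positions(aln, spec) == [3]

    def test_matches_brute_force_ungap_walk(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            n = int(rng.integers(20, 60))
            seq = "".join(
                "-" if rng.random() < 0.3 else str(rng.choice(aa)) for _ in range(n)
            )
            ungapped = len(seq.replace("-", ""))
            if ungapped < 3:
                continue
            positions = sorted(rng.choice(np.arange(1, ungapped + 1),
                                          size=3, replace=False).tolist())
            ref = seq.replace("-", "")
            spec = PocketSpec("R", tuple(positions),
                              tuple(ref[p - 1] for p in positions))
            aln = MultipleAlignment(members=(("R", seq),))
            assert map_reference_positions(aln, spec) == brute_ungap_columns(seq, positions)

    def test_unknown_reference_and_overlong_position(self):
        aln = MultipleAlignment(members=(("R1", "QRQY"),))
        with pytest.raises(KeyError):
            map_reference_positions(aln, PocketSpec("NOPE", (1,), ("Q",)))
        with pytest.raises(ValueError, match="5"):
            map_reference_positions(aln, PocketSpec("R1", (5,), ("Q",)))


class TestPocketTable:
    def test_identical_member_matches_everywhere_and_gaps_never_match(self):
        ref = "QARBQCYD".replace("B", "W").replace("D", "K")  # QARWQCYK
        aln = MultipleAlignment(members=(
            ("REF", ref),
            ("SAME", ref),
            ("GAPPY", "-A-W-C-K"),
        ))
        spec = PocketSpec("REF", (1, 3, 5, 7), ("Q", "R", "Q", "Y"))
        table = extract_pocket_table(aln, spec)
        assert table.n_matches == [4, 4, 0]

    def test_invariant_to_all_gap_columns_outside_pocket(self):
        aln = MultipleAlignment(members=(("REF", "QRQY"), ("M1", "QAQF")))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        base = extract_pocket_table(aln, spec)
        padded = MultipleAlignment(members=(("REF", "Q-RQ-Y-"), ("M1", "Q-AQ-F-")))
        spec2 = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        other = extract_pocket_table(padded, spec2)
        assert base.n_matches == other.n_matches
        assert base.residues == other.residues

    def test_case_and_ambiguity_rules(self):
        aln = MultipleAlignment(members=(("REF", "QRQY"), ("M1", "QXQB")))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        assert extract_pocket_table(aln, spec).n_matches == [4, 2]


class TestFiltering:
    @pytest.fixture
    def planted(self):
        planted = [(2, False)] * 5 + [(1, False)] * 8 + [(0, False)] * 6
        aln, truth = gen_alignment(20, SPEC, planted, seed=7)
        return extract_pocket_table(aln, SPEC), truth

    def test_zero_threshold_keeps_all_and_overflow_keeps_none(self, planted):
        table, _ = planted
        assert filter_members(table, 0) == table.member_ids
        assert filter_members(table, len(SPEC.positions) + 1) == []

    def test_planted_members_with_two_matches_recovered(self, planted):
        table, truth = planted
        hits = filter_members(table, 2)
        expected = ["REF"] + [m for m, n in zip(truth.params["member_ids"],
                                                truth.params["n_matches"]) if n >= 2]
        assert hits == expected
        assert len(hits) == 6

    def test_monotone_in_threshold(self, planted):
        table, _ = planted
        chains = [set(filter_members(table, k)) for k in range(len(SPEC.positions) + 2)]
        for bigger, smaller in zip(chains, chains[1:]):
            assert smaller <= bigger

    def test_negative_threshold_rejected(self, planted):
        with pytest.raises(ValueError):
            filter_members(planted[0], -1)


class TestDistributionAndCandidates:
    def test_uniform_column(self):
        aln = MultipleAlignment(members=(("REF", "QRQY"), ("A", "FRQY"), ("B", "FRQY")))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        table = extract_pocket_table(aln, spec)
        assert residue_distribution(table, 2) == Counter({"R": 3})

    def test_planted_distribution_with_gaps(self):
        members = [("REF", "QRQY")]
        col1 = ["Q", "Q", "Q", "F", "F", "-"]
        for i, c in enumerate(col1):
            members.append((f"M{i}", c + "RQY"))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        table = extract_pocket_table(MultipleAlignment(members=tuple(members)), spec)
        dist = residue_distribution(table, 1)
        assert dist == Counter({"Q": 4, "F": 2, "-": 1})
        assert sum(dist.values()) == len(members)

    def test_position_index_out_of_range(self):
        aln = MultipleAlignment(members=(("REF", "QRQY"),))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        table = extract_pocket_table(aln, spec)
        with pytest.raises(ValueError):
            residue_distribution(table, 5)

    def test_hydrophobic_pair_selected_polar_not(self):
        aln = MultipleAlignment(members=(
            ("REF", "QRQY"), ("HYDRO", "FRQV"), ("POLAR", "QRQV"),
        ))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        table = extract_pocket_table(aln, spec)
        hits = rank_hydrophobic_candidates(table, [1, 4])
        assert hits == [("HYDRO", ("F", "V"))]

    def test_single_planted_candidate_among_fifty(self):
        planted = [(1, False)] * 49
        planted[31] = (1, True)
        aln, truth = gen_alignment(50, SPEC, planted, seed=5)
        table = extract_pocket_table(aln, SPEC)
        hits = rank_hydrophobic_candidates(table, [69, 203])
        assert [m for m, _ in hits] == ["M0032"]

    def test_empty_hydrophobic_set_rejected(self):
        aln = MultipleAlignment(members=(("REF", "QRQY"),))
        spec = PocketSpec("REF", (1, 2, 3, 4), ("Q", "R", "Q", "Y"))
        table = extract_pocket_table(aln, spec)
        with pytest.raises(ValueError):
            rank_hydrophobic_candidates(table, [1, 4], hydrophobic_set=set())


class TestIO:
    def test_fasta_and_stockholm_loaders_normalize_gaps(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">REF\nQRQY\n>M1\nq.qf\n")
        aln = read_alignment(fasta)
        assert aln.sequence("M1") == "Q-QF"
        sto = tmp_path / "aln.sto"
        sto.write_text(
            "# STOCKHOLM 1.0\nREF  QRQY\nM1   Q.QF\n//\n"
        )
        aln2 = read_alignment(sto)
        assert aln2.sequence("M1") == "Q-QF"
        assert aln2.sequence("REF") == aln.sequence("REF")
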