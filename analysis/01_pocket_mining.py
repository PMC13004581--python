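#!/usr/bin/env python
"""Mine a synthetic GFP-family alignment for anion-pocket homologs.

Emulates the discovery route: an 806-member family alignment is screened
against a YFP-like reference pocket (positions 69, 96, 183, 203; expected
residues Q, R, Q, Y), members with >= 2 pocket matches are kept, residue
diversity at the 69/203 positions is summarised, and members presenting
hydrophobic residues at both of those positions are flagged as candidate
anion sensors.  The generator plants 70 such members plus one hydrophobic
candidate, so the expected outcome is 71 survivors and a single candidate.

Writes results/pocket_report.tsv and results/mining_summary.json.
"""

import json
from pathlib import Path

from anionscout.pocket_mining import (
    PocketSpec,
    extract_pocket_table,
    filter_members,
    rank_hydrophobic_candidates,
    residue_distribution,
)
from anionscout.synthetic import gen_alignment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20190201  # the alignment vintage used as a reproducible seed

def main() -> None:
    spec = PocketSpec("YFP_H148Q_like", (69, 96, 183, 203),
                      ("Q", "R", "Q", "Y"), min_matches=2)
    n_members = 806
    # plant: 69 ordinary >= 2-match members + 1 hydrophobic candidate, the
    # reference itself makes 71; everyone else falls below the threshold
    planted = [(2, False)] * 50 + [(3, False)] * 19 + [(2, True)]
    planted += [(1, False)] * 400
    planted += [(0, False)] * (n_members - 1 - len(planted))
    aln, truth = gen_alignment(n_members, spec, planted, gap_rate=0.08, seed=SEED)

    table = extract_pocket_table(aln, spec)
    survivors = filter_members(table, spec.min_matches)
    candidates = rank_hydrophobic_candidates(table, [69, 203])

    print(f"alignment: {aln.n_members} members x {aln.length} columns")
    print(f"members with >= {spec.min_matches} pocket matches: {len(survivors)}")
    for pos_index, ref_pos in [(1, 69), (4, 203)]:
        dist = residue_distribution(table, pos_index)
        top = ", ".join(f"{r}:{c}" for r, c in dist.most_common(6))
        print(f"residue diversity at reference position {ref_pos}: {top}")
    print(f"hydrophobic candidates at 69+203: "
          f"{[(m, '/'.join(r)) for m, r in candidates]}")

    OUT.mkdir(exist_ok=True)
    with open(OUT / "pocket_report.tsv", "w", encoding="utf-8") as fh:
        cols = "\t".join(f"pos{p}" for p in spec.positions)
        fh.write(f"member_id\t{cols}\tn_matches\tcandidate\n")
        cand_ids = {m for m, _ in candidates}
        for mid, res, n in table.rows():
            fh.write(f"{mid}\t" + "\t".join(res) + f"\t{n}\t{mid in cand_ids}\n")
    summary = {
        "n_members": aln.n_members,
        "n_with_min_matches": len(survivors),
        "candidates": [{"member_id": m, "residues": list(r)} for m, r in candidates],
        "positions": list(spec.positions),
        "expected_residues": list(spec.expected_residues),
    }
    (OUT / "mining_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT / 'pocket_report.tsv'} and {OUT / 'mining_summary.json'}")


if __name__ == "__main__":
    main()
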