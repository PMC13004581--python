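#!/usr/bin/env python
"""Radial distribution functions and first-shell hydration of each anion.

For each binding anion preset, a solvation box is generated with the
preset's first-shell geometry planted (shell radius near 3.5-3.8 Å, shell
occupancy per preset) and the water-oxygen RDF around the anion is
computed, the first-shell peak and boundary located, and the coordination
number inside the boundary counted.  The expected picture: first-shell
peaks clustered within ~3.5-3.8 Å, shifted outward for the larger iodide,
with at least ~4 first-shell waters for the halides.

Writes results/rdf_<anion>.tsv and results/solvation_summary.json.
"""

import json
from pathlib import Path

from anionscout.solvation import coordination_count, first_shell_boundary, rdf
from anionscout.synthetic import ANION_PRESETS, gen_solvation_box

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summary = {}
    for i, (name, preset) in enumerate(ANION_PRESETS.items()):
        if not preset.binds:
            continue
        traj = gen_solvation_box(
            300, mode="planted_shell", r0=preset.first_shell_radius,
            k=preset.shell_count_hint, n_frames=30, seed=SEED + i,
        )
        prof = rdf(traj, "resname CLA", "name O", dr=0.1, r_max=10.0)
        r_peak, r_min = first_shell_boundary(prof)
        counts, mean_coord = coordination_count(traj, "resname CLA", "name O",
                                                r_cut=r_min)
        print(f"{name:<9} planted shell {preset.first_shell_radius:.1f} Å -> "
              f"peak {r_peak:.2f} Å, boundary {r_min:.2f} Å, "
              f"coordination {mean_coord:.1f}")
        with open(OUT / f"rdf_{name}.tsv", "w", encoding="utf-8") as fh:
            fh.write("r\tg\tn_cumulative\n")
            for r, g, nc in zip(prof.bin_centers, prof.g, prof.cumulative_number()):
                fh.write(f"{r:.2f}\t{g:.4f}\t{nc:.4f}\n")
        summary[name] = {
            "planted_shell_radius_A": preset.first_shell_radius,
            "first_shell_peak_A": r_peak,
            "first_shell_boundary_A": r_min,
            "mean_coordination": mean_coord,
            "ionic_radius_A": preset.ionic_radius,
        }
    peaks = {n: s["first_shell_peak_A"] for n, s in summary.items()}
    print(f"peak window: {min(peaks.values()):.2f}-{max(peaks.values()):.2f} Å; "
          f"iodide shifted outward: {peaks['iodide'] > peaks['chloride']}")
    (OUT / "solvation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT / 'solvation_summary.json'}")


if __name__ == "__main__":
    main()
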