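# Methods

This note records the models implemented in `anionscout`, the conventions
and defaults behind them, what the synthetic-data generators do and do not
emulate, and the design choices made where the underlying procedures are
commonly reported without full operational detail.

## Scope and shape

The package covers the three arms of an anion-sensor characterization:
sequence-level discovery (binding-pocket mining over a family alignment),
trajectory-level mechanism (contacts, entry, solvation, constant-pH
protonation), and spectroscopic quantification (binding isotherms,
chromophore pKa, extinction coefficients, quantum yields). It is organised
as an analysis project: all computation lives in the library under
`src/anionscout/`, and the numbered scripts in `analysis/` are thin
narrative drivers. No wet-lab or simulation-engine output is required;
the `synthetic` module generates every input with planted ground truth,
which is also how the test suite closes the loop (generate → analyse →
compare against the plant).

## Pocket mining

Given an alignment and a reference member with known pocket positions
(1-based indices into the reference's own ungapped sequence), positions
are mapped to alignment columns by walking the aligned reference string
and counting non-gaps. Per member, the residues at those columns are
tabulated and matches against the expected pattern counted.

Conventions (choices, configurable where it matters):

* a gap at a pocket column is never a match — a gapped member cannot
  present the residue;
* comparison is case-insensitive exact equality; ambiguity codes X/B/Z
  never match;
* the hydrophobic set for candidate ranking defaults to the standard
  nonpolar side chains {A, V, L, I, M, F, W};
* numbering is pinned to the supplied reference's own ungapped 1-based
  numbering (family literature often mixes numbering schemes between
  homologs; the mapper takes whatever positions the caller supplies);
* aligned FASTA and Stockholm are both accepted; `.` is normalised to
  `-` and sequences are uppercased.

`filter_members` is monotone in the threshold by construction;
`extract_pocket_table` is invariant to all-gap columns outside the pocket
columns. Both properties are tested.

## Trajectory data model and I/O

The in-memory model is a `Topology` (serial, name, element, residue
name/id, chain per atom), frames of Å coordinates, and an optional
orthorhombic box per frame. Frames are 0-based, residues 1-based (PDB
convention); coordinates are in Å throughout.

The on-disk carrier is multi-model PDB (one MODEL block per frame,
CRYST1 for the box): universal, text-diffable, and sufficient for the
coarse trajectories analysed here. Parsing and writing go through
MDAnalysis, with a light pre-scan that enforces the error contract —
inconsistent atom counts across MODEL blocks and unparseable coordinate
fields are reported with the offending model or line number, which the
generic parser does not do. A single header CRYST1 is applied to all
frames (the multi-model reader only honours per-MODEL records); a unitary
cell is treated as the conventional "no box" placeholder. Binary formats
(DCD/XTC) are out of scope; the data model admits adapters.

All distance computations use the minimum-image convention whenever a box
is present (each displacement component wrapped into (−L/2, L/2]), and
plain Euclidean distances otherwise. Only orthorhombic boxes are
supported.

Constant-pH records travel as a documented TSV dialect (columns: frame,
residue_id, residue_name, state_index, is_protonated, pH; at most one
record per frame/residue pair) rather than any engine-specific output
format: the dialect captures exactly what the analyses consume, and
engine-specific converters are deliberately left as adapters.

Selections use a small expression language over residue ids (single or
`lo:hi` ranges), residue names, atom names, elements, the named sets
`backbone` (N, CA, C, O) and `heavy` (element ≠ H), with
`and`/`or`/`not` and parentheses.

## Binding dynamics

**Contact fingerprints.** A residue is in contact with the anion in a
frame iff the minimum (minimum-image) distance from any anion atom to any
selected atom of the residue is ≤ the cutoff (default 4 Å, the
convention for anion–protein contact analysis).

**Cavity occupancy.** The binding cavity is a caller-supplied residue
set. A frame counts as bound when the anion contacts at least
`min_residues` of them simultaneously (default 3: contact analyses
typically state the distance cutoff but not a residue count, and
requiring three simultaneous contacts rejects grazing surface contacts).
Bound runs separated by ≤ `gap_tolerance` unbound frames (default 2)
merge into one residence segment, suppressing recrossing noise at the
cutoff boundary.

**Entry events.** "Inside the barrel" is operationalised as
distance-to-chromophore-centroid < `r_inside` (default 8 Å), with
hysteresis: after an event, the anion must retreat beyond `r_bulk`
(default 15 Å) before a new event can fire, and an event requires the
interior visit to persist ≥ `min_persistence` frames (default 10). An
anion that starts inside, with no prior bulk frame, produces no event by
definition. The gate assigned to an event is the candidate residue pair
with the smallest summed minimum distance to the anion at the event
frame. These thresholds are stated choices — entry is usually described
qualitatively — and all three are configurable.

**RMSD/RMSF.** Superposition is least-squares (Kabsch via SVD) with the
determinant corrected to +1, so reflections are never applied. RMSF
superposes every frame onto frame 0 over the selection, then takes the
per-atom root-mean-square deviation from the time-mean structure. Note
that superposition itself absorbs part of a single atom's motion (an
isolated oscillator of amplitude d among n atoms reports d·(1−1/n)); the
tests pin this down exactly.

**Hydrogen bonds.** Present in a frame iff dist(D, A) ≤ 3.5 Å and the
D–H···A angle at H ≥ 120° — a common permissive geometric criterion,
configurable. Donor pairs whose H sits more than 1.5 Å from its heavy
atom in any frame are not plausibly bonded and are skipped with a
warning.

**SASA.** Shrake–Rupley with a Fibonacci point lattice (default 960
points) and a 1.4 Å probe. Default radii: C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å, and ionic radii for the halides (Cl 1.81, Br 1.96,
I 2.20 Å). A missing element radius is an error naming the element.

**Chromophore planarity.** Per frame, the RMS distance of the selected
ring atoms from their least-squares plane (smallest-singular-vector
normal); rigid-motion invariant.

## Solvation

g(r) is computed from minimum-image pair distances, binned at dr
(default 0.1 Å) up to r_max ≤ half the smallest box edge, and normalised
as count / (n_frames · N_center · ρ · V_shell) with exact shell volumes
(4/3)π(r₂³−r₁³) and ρ the mean target density over the *full* box volume.
No protein-excluded-volume correction is applied; this convention is
stated so differences from other tools' defaults are explainable. The
normalisation makes the integral identity Σ g·ρ·V_shell·N_center·n_frames
= total pair count exact, which is tested. An optional frame mask
restricts the profile (e.g. to cavity-bound frames); the default is all
frames, and that default is deliberate rather than implied by any
convention. For molecular anions the caller picks the center atom
(nitrate: the nitrogen).

First-shell location: the profile is smoothed with a 3-bin moving average
(shrinking windows at the edges); the first local maximum with g > 1 is
the peak (ties broken toward smaller r), the first local minimum after it
the shell boundary. Coordination numbers count targets within a cutoff of
the center, per frame; the count is non-decreasing in the cutoff.

## Protonation

Per residue: protonated fraction, occupancy of each state index (summing
to 1), and transition count. Transitions are counted on state-index
changes, not only protonated/deprotonated flips, so a carboxylate hopping
between its two protonated oxygens registers. Missing frames are excluded
from every statistic, never imputed (constant-pH records are periodic
snapshots). The module never infers protonation chemistry: `is_protonated`
and the state-index meaning are fixed upstream by whatever produced the
record. Conditioned on an occupancy series, bound/unbound fractions obey
the law of total probability exactly (tested); a condition with zero
frames is reported as undefined, not 0. `fit_titration_pka` does a
least-squares Henderson–Hasselbalch fit of deprotonated fractions versus
pH, initialised at the pH nearest the half point.

## Photophysics

The binding fit averages replicates per concentration (per-replicate
fitting is a caller-side variation), initialises Fmin ← F(0),
Fmax ← F(highest concentration), Kd ← the concentration nearest the
half-change, constrains Kd > 0, and takes standard errors from the
Jacobian at the optimum. A series whose end-to-end signal change is below
the noise floor — three times the mean replicate SD, or 2 % of the mean
intensity when only single replicates exist — is rejected as having "no
saturable response"; this is the expected outcome for a non-binding
control such as gluconate, not a failure mode. Fmin/Fmax naming follows
the titration convention (intensity at zero and at saturating anion);
for a turn-off sensor Fmax < Fmin.

The 50 %-retention pKa estimator normalises the series to its min/max,
scans from high pH downward and linearly interpolates inside the first
bracketing pair crossing 0.5 (multiple crossings warn and report the
highest-pH one). Linear interpolation is a stated choice. The estimator
is accurate to well under 0.05 pH units when the scan brackets both
plateaus; a grid that truncates a plateau (pKa within ~0.5 units of the
scan edge) biases the normalisation, which is why the mutant presets are
scanned over a wider pH range in the analysis scripts.

Scalar helpers: fold change F_f/F_i; composition-based
ε280 = 5500·nTrp + 1490·nTyr + 125·n_cystine (cysteines assumed reduced
by default); ε_λ = ε280·A_λ/A280 at matched concentration and path
length; relative quantum yield Φ = Φ_ref·(slope/slope_ref)·(n²/n_ref²)
with the reference yield a required input, not a hard-coded constant;
batch averaging as mean with propagated SD sqrt(Σ sdᵢ²)/n.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every test and worked
example. The anion presets carry the measured constants of the
chloride-family sensor this package characterises: Kd 25.2 mM (chloride),
15.1 (bromide), 5.3 (iodide), 10.7 (nitrate); ionic radii
1.81/1.96/2.20/2.64 Å; first-shell radii 3.5/3.6/3.7/3.5 Å (within the
3.5–3.8 Å window typical of halide hydration, iodide shifted outward by
its size); shell occupancies 4/4/4/3 (halides coordinate at least four
first-shell waters; the planar nitrate slightly fewer); gluconate as the
non-binding control. Chromophore-pKa presets: apo 4.9, chloride-bound
5.2, and 3.6/4.0 for the gate-histidine alanine mutant. Titration
defaults F(0 mM) = 1.0, saturation 0.2 — a five-fold turn-off — at
concentrations 0, 1, 2.5, 5, 10, 25, 50, 100 mM.

* `gen_alignment` realises exact planted match counts per member, with a
  gap-free reference, configurable gap rate, and insert columns (all-gap
  in the reference) to exercise the position mapping. Candidate members
  get hydrophobic residues at all candidate positions; non-candidates are
  guaranteed at least one non-hydrophobic residue there.
* `gen_trajectory` builds a coarse barrel: a planar chromophore ring at
  the box centre, single-atom cavity pseudo-residues 3 Å around a cavity
  point a few Å beneath it, a gate pair (plus a decoy pair on the far
  side) on an 8 Å-radius wall of pseudo-CA strands, an anion scripted
  from bulk (> 15 Å) through the gate into the cavity exactly at the
  planted entry frame, and exactly k water oxygens riding at the planted
  shell radius while bound (parked far away otherwise). Gaussian thermal
  jitter (default σ 0.05 Å) keeps frames from being identical without
  threatening any margin.
* `gen_solvation_box` plants k targets on a sphere of radius r0 around a
  central ion plus uniform background outside the ion's excluded volume
  (no background target within r0 + 0.5 Å), or a pure ideal gas in
  uniform mode.
* `gen_cphmd_states` draws per-frame protonation as Bernoulli with
  p = 1/(1+10^(pH−pKa)), replaced by the coupled probability on
  anion-bound frames; two-site residues split protonated records over
  state indices 1 and 2.
* `gen_titration` / `gen_ph_curve` evaluate the isotherm /
  Henderson–Hasselbalch model and add i.i.d. Gaussian noise (replicate
  SDs in titration data are commonly reported without a noise model;
  additive Gaussian is the neutral choice).
* `ion_counts_for_box` converts a target ionic strength and box volume
  into integer ion counts with exact charge neutrality against the
  protein charge (e.g. a −8 protein with 67 monovalent anions takes 75
  monovalent cations).

All generators take a mandatory seed and touch no global RNG state; equal
seeds give byte-identical artifacts.

What the synthetic data does **not** emulate: force-field physics, water
structure beyond the planted shell, realistic protein flexibility,
electrostatics, anion desolvation on entry, or photophysical kinetics.
Passing tests therefore demonstrate that the *analytics* are correct
(they recover whatever structure is present, exactly where brute-force
oracles and closed forms say they should), not that any particular
protein behaves as scripted. Conclusions about a real system require real
trajectories and titrations fed through the same interfaces.

## Problem sizes and numerics

Test and script problem sizes are chosen so the whole suite runs in
seconds on one core while every check remains exact or statistically
sharp: trajectories of 150–400 frames and ~70 atoms, solvation boxes of
100–1000 targets over 20–400 frames, alignments of 16–806 members,
oracle-equivalence sweeps of 200 random instances of up to 100 atoms, and
100-seed round-trip sweeps. Optimiser defaults are scipy's `curve_fit`
with analytic-free Jacobians; zero-noise recoveries are exact to
optimiser tolerance (≪ 0.1 %). Statistical assertions use 3-standard-error
bands computed from the data (binomial or Poisson as appropriate); the
ideal-gas RDF check is applied to the plateau mean of the profile, whose
per-bin values are individually Poisson-noisy.

## Known limitations

* The PDB carrier caps serials/resids at PDB column widths; fine for the
  coarse models used here, not for large systems.
* SASA is O(N²·points) — intended for the small synthetic systems, not
  for full proteins at every frame.
* The entry-event definition (centroid distance + hysteresis) is a
  geometric proxy; alternative entry pathways that never approach the
  chromophore within `r_inside` are not counted as entries.
* RDF normalisation over the full box volume under-weights g(r) when a
  large solute excludes solvent volume; comparisons across systems should
  use the same convention.
* The 50 %-retention pKa estimator needs the pH scan to reach both
  plateaus; it does not extrapolate.
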