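"""Constant-pH trajectory analytics.

Summaries of per-residue protonation behaviour from a
:class:`~anionscout.traj_io.TitrationStateSeries`: protonated fractions,
state-index occupancies, transition counts, and — given a cavity-occupancy
series — protonation conditioned on anion-bound versus unbound frames.

Missing frames are excluded from every statistic (constant-pH records are
periodic snapshots, not a continuous signal); nothing is imputed.
Transitions are counted on state-index changes between consecutive recorded
frames, so a carboxylate hopping between its two protonated oxygens counts
even though both states are "protonated".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .traj_io import TitrationStateSeries


@dataclass
class ResidueProtonation:
    residue_id: int
    residue_name: str
    n_frames: int
    fraction_protonated: float
    state_occupancies: dict  # state_index -> fraction, sums to 1
    n_transitions: int


@dataclass
class ProtonationSummary:
    """Per-residue protonation statistics keyed by residue id."""

    residues: dict

    def __getitem__(self, residue_id: int) -> ResidueProtonation:
        return self.residues[residue_id]

    def residue_ids(self):
        return sorted(self.residues)


class CoupledFractions(NamedTuple):
    fraction_bound: float | None
    fraction_unbound: float | None
    n_bound_frames: int
    n_unbound_frames: int


def protonation_fractions(series: TitrationStateSeries) -> ProtonationSummary:
    """Protonated fraction, state occupancies and transition count per residue."""
    df = series.df
    if df.empty:
        raise ValueError("titration state series is empty")
    residues = {}
    for rid, grp in df.groupby("residue_id"):
        grp = grp.sort_values("frame")
        n = len(grp)
        states = grp["state_index"].to_numpy()
        occ = {int(s): float(c) / n
               for s, c in zip(*np.unique(states, return_counts=True))}
        residues[int(rid)] = ResidueProtonation(
            residue_id=int(rid),
            residue_name=str(grp["residue_name"].iloc[0]),
            n_frames=n,
            fraction_protonated=float(grp["is_protonated"].mean()),
            state_occupancies=occ,
            n_transitions=int(np.sum(states[1:] != states[:-1])),
        )
    return ProtonationSummary(residues=residues)


def binding_coupled_fractions(series: TitrationStateSeries, occupancy,
                              residue_id: int) -> CoupledFractions:
    """Protonated fraction of one residue conditioned on anion occupancy.

    ``occupancy`` supplies the per-frame bound flag
    (:class:`~anionscout.binding_dynamics.OccupancySeries` or any boolean
    array).  Frames outside the recorded series are ignored; a condition
    with zero frames yields ``None`` (undefined), never 0.
    """
    bound = np.asarray(getattr(occupancy, "bound", occupancy), dtype=bool)
    sub = series.df[series.df["residue_id"] == int(residue_id)]
    if sub.empty:
        raise ValueError(f"residue {residue_id} absent from the state series")
    frames = sub["frame"].to_numpy()
    if frames.max() >= len(bound):
        raise ValueError("state series references frames beyond the occupancy series")
    prot = sub["is_protonated"].to_numpy()
    is_bound = bound[frames]
    nb = int(is_bound.sum())
    nu = int((~is_bound).sum())
    fb = float(prot[is_bound].mean()) if nb else None
    fu = float(prot[~is_bound].mean()) if nu else None
    return CoupledFractions(fb, fu, nb, nu)


def fit_titration_pka(fractions_by_ph):
    """Least-squares Henderson–Hasselbalch fit of deprotonated fractions.

    ``fractions_by_ph`` is a sequence of (pH, deprotonated fraction) pairs
    covering at least 3 distinct pH values.  The model is
    f = 1 / (1 + 10^(pKa − pH)).  Returns (pKa, residual_norm).
    """
    pts = [(float(p), float(f)) for p, f in fractions_by_ph]
    ph = np.array([p for p, _ in pts])
    f = np.array([x for _, x in pts])
    if len(set(ph.tolist())) < 3:
        raise ValueError("need at least 3 distinct pH values")
    if np.allclose(f, f[0]):
        raise ValueError("degenerate titration data: all fractions equal")

    def model(p, pka):
        return 1.0 / (1.0 + 10.0 ** (pka - p))

    # midpoint-crossing pH is a robust starting guess
    p0 = ph[np.argmin(np.abs(f - 0.5))]
    popt, _ = curve_fit(model, ph, f, p0=[p0], maxfev=10000)
    resid = f - model(ph, popt[0])
    return float(popt[0]), float(np.linalg.norm(resid))
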