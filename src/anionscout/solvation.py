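"""Radial distribution functions and solvation-shell statistics.

g(r) is normalised against the mean target density over the full box volume
(no excluded-volume correction), with exact spherical shell volumes
(4/3)π(r₂³ − r₁³).  Shell boundaries are read off the 3-bin-smoothed
profile: the first local maximum with g > 1 is the first-shell peak, the
first local minimum after it the shell boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import Trajectory, pairwise_distances, resolve_selection


@dataclass
class RDFProfile:
    """A radial distribution function and the raw quantities behind it."""

    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    dr: float
    r_max: float
    n_frames: int
    n_centers: int
    rho: float  # mean target number density, Å⁻³

    def shell_volumes(self) -> np.ndarray:
        edges = np.arange(len(self.bin_centers) + 1) * self.dr
        return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    def cumulative_number(self) -> np.ndarray:
        """Running coordination number n(r) implied by the profile."""
        return np.cumsum(self.counts) / (self.n_frames * self.n_centers)


def rdf(traj: Trajectory, center_selection, target_selection,
        dr: float = 0.1, r_max: float | None = None,
        frame_mask=None) -> RDFProfile:
    """Radial distribution function of targets around centers.

    Pair distances use the minimum-image convention; every frame must carry
    a box, and ``r_max`` may not exceed half the smallest box edge.  Target
    atoms that also appear in the center selection are removed from the
    target set.  ``frame_mask`` (boolean per frame) restricts the analysis,
    e.g. to cavity-bound frames; default is all frames.
    """
    top = traj.topology
    centers = resolve_selection(top, center_selection)
    targets = resolve_selection(top, target_selection)
    targets = [i for i in targets if i not in set(centers)]
    if not centers or not targets:
        raise ValueError("center and target selections must be nonempty")
    boxes = []
    for t, fr in enumerate(traj.frames):
        if fr.box is None:
            raise ValueError(f"frame {t} has no box; RDF needs periodic frames")
        boxes.append(fr.box)
    half_min = min(min(b) for b in boxes) / 2.0
    if r_max is None:
        r_max = half_min
    if r_max > half_min + 1e-9:
        raise ValueError(f"r_max={r_max} exceeds half the smallest box edge ({half_min:.3f})")

    n_bins = int(round(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    use = range(traj.n_frames) if frame_mask is None else np.nonzero(np.asarray(frame_mask))[0]
    used = 0
    vols = []
    for t in use:
        fr = traj.frames[t]
        d = pairwise_distances(fr.coords[centers], fr.coords[targets], fr.box).ravel()
        hist, _ = np.histogram(d, bins=edges)
        counts += hist
        vols.append(np.prod(fr.box))
        used += 1
    if used == 0:
        raise ValueError("frame mask selects no frames")
    rho = float(np.mean([len(targets) / v for v in vols]))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (used * len(centers) * rho * shell_vol)
    return RDFProfile(
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        g=g, counts=counts, dr=float(dr), r_max=float(r_max),
        n_frames=used, n_centers=len(centers), rho=rho,
    )


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-bin moving average with shrinking windows at the edges."""
    out = np.empty_like(y, dtype=float)
    n = len(y)
    for i in range(n):
        lo = max(0, i - 1)
        hi = min(n, i + 2)
        out[i] = y[lo:hi].mean()
    return out


def first_shell_boundary(profile: RDFProfile):
    """Locate the first solvation shell: (r_peak, r_min).

    Operates on the 3-bin-smoothed g(r).  r_peak is the center of the first
    local maximum with g > 1 (ties broken toward smaller r); r_min the
    center of the first local minimum after the peak.
    """
    s = _smooth3(profile.g)
    n = len(s)
    peak = None
    for i in range(n):
        if s[i] <= 1.0:
            continue
        left_ok = i == 0 or s[i] > s[i - 1]
        right_ok = i == n - 1 or s[i] >= s[i + 1]
        if left_ok and right_ok:
            peak = i
            break
    if peak is None:
        raise ValueError("no solvation-shell peak (smoothed g never exceeds 1)")
    trough = None
    for j in range(peak + 1, n):
        left_ok = s[j] <= s[j - 1]
        right_ok = j == n - 1 or s[j] <= s[j + 1]
        if left_ok and right_ok and s[j] < s[peak]:
            trough = j
            break
    if trough is None:
        raise ValueError("no local minimum after the first-shell peak")
    return float(profile.bin_centers[peak]), float(profile.bin_centers[trough])


def coordination_count(traj: Trajectory, center_selection, target_selection,
                       r_cut: float, frame_mask=None):
    """Targets within ``r_cut`` of the center, per frame, plus the mean.

    Counts target atoms whose minimum-image distance to any center atom is
    at most ``r_cut``.  Returns (per_frame_counts, mean).
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    top = traj.topology
    centers = resolve_selection(top, center_selection)
    targets = resolve_selection(top, target_selection)
    targets = [i for i in targets if i not in set(centers)]
    if not centers or not targets:
        raise ValueError("center and target selections must be nonempty")
    use = range(traj.n_frames) if frame_mask is None else np.nonzero(np.asarray(frame_mask))[0]
    counts = []
    for t in use:
        fr = traj.frames[t]
        d = pairwise_distances(fr.coords[centers], fr.coords[targets], fr.box)
        counts.append(int(np.sum(d.min(axis=0) <= r_cut)))
    counts = np.array(counts, dtype=int)
    if len(counts) == 0:
        raise ValueError("frame mask selects no frames")
    return counts, float(counts.mean())
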