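"""Spectroscopy models for anion-sensitive fluorescent proteins.

The sensing readout is a *turn-off* response: anion binding shifts the
chromophore toward its protonated (phenol, non-fluorescent) form, so
emission falls with anion concentration.  Two fits carry the
characterization:

* the one-site binding isotherm
  ``F_obs([X]) = [X]·(Fmax − Fmin)/(Kd + [X]) + Fmin``
  where Fmin is the intensity at 0 mM anion and Fmax the saturation
  asymptote (Fmax < Fmin for a turn-off sensor);
* the chromophore pKa, estimated as the pH at which 50 % of the normalized
  fluorescence signal is retained, by linear interpolation on the measured
  pH-response series.

Helper operations cover fold change, ProtParam-style ε280, extinction
coefficients at other wavelengths from absorbance ratios, relative quantum
yields against a reference fluorophore, and batch averaging with propagated
standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class TitrationCurve:
    """Replicate emission intensities versus anion concentration (mM)."""

    anion: str
    concentrations: np.ndarray
    intensities: np.ndarray  # shape (n_conc, n_replicates)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[0] != len(self.concentrations):
            raise ValueError("one intensity row per concentration required")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.any(self.concentrations == 0):
            raise ValueError("a 0 mM point is required")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive")

    def mean_intensities(self) -> np.ndarray:
        return self.intensities.mean(axis=1)


@dataclass
class BindingFit:
    """Result of a one-site isotherm fit."""

    kd: float  # mM
    fmin: float
    fmax: float
    kd_se: float
    fmin_se: float
    fmax_se: float
    residual_norm: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return x * (self.fmax - self.fmin) / (self.kd + x) + self.fmin


@dataclass
class PHResponseCurve:
    """Normalized emission versus pH (normalized to the series min/max)."""

    ph: np.ndarray
    normalized: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError("pH values must be strictly increasing")
        if np.any((self.normalized < -1e-9) | (self.normalized > 1 + 1e-9)):
            raise ValueError("normalized values must lie in [0, 1]")

    @classmethod
    def from_raw(cls, ph, raw) -> "PHResponseCurve":
        raw = np.asarray(raw, dtype=float)
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            raise ValueError("flat pH series cannot be normalized")
        return cls(ph=np.asarray(ph, dtype=float), normalized=(raw - lo) / (hi - lo),
                   raw=raw)


@dataclass
class SpectralConstants:
    """Extinction coefficients (M⁻¹ cm⁻¹) and quantum yield of one form."""

    eps280: float
    eps394: float
    eps485: float
    phi: float

    def __post_init__(self):
        for name in ("eps280", "eps394", "eps485", "phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.phi > 1:
            raise ValueError("quantum yield cannot exceed 1")


# ---------------------------------------------------------------------------
# binding isotherm
# ---------------------------------------------------------------------------

def _isotherm(x, kd, fmin, fmax):
    return x * (fmax - fmin) / (kd + x) + fmin


def fit_binding_isotherm(curve: TitrationCurve) -> BindingFit:
    """Nonlinear least-squares fit of the one-site binding isotherm.

    Replicates are averaged per concentration before fitting.  Starting
    values: Fmin ← F(0), Fmax ← F at the highest concentration, Kd ← the
    concentration whose response is nearest the half-change; Kd is
    constrained positive.  Standard errors come from the Jacobian at the
    optimum.  A series whose total signal change does not exceed the noise
    floor (estimated from replicate scatter, or 2 % of the mean intensity
    for single replicates) has no saturable response and is rejected — the
    behaviour expected of a non-binding control such as gluconate.
    """
    x = curve.concentrations
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    f = curve.mean_intensities()
    order = np.argsort(x)
    x, f = x[order], f[order]

    if curve.intensities.shape[1] >= 2:
        noise_floor = 3.0 * float(np.mean(curve.intensities.std(axis=1, ddof=1)))
    else:
        noise_floor = 0.02 * float(np.mean(f))
    if abs(f[-1] - f[0]) < noise_floor:
        raise ValueError(
            f"no saturable response for {curve.anion!r}: signal change "
            f"{abs(f[-1] - f[0]):.3g} is below the noise floor {noise_floor:.3g}"
        )

    fmin0 = f[x == 0][0]
    fmax0 = f[-1]
    half = (fmin0 + fmax0) / 2.0
    nonzero = x > 0
    kd0 = float(x[nonzero][np.argmin(np.abs(f[nonzero] - half))])
    popt, pcov = curve_fit(
        _isotherm, x, f, p0=[max(kd0, 1e-6), fmin0, fmax0],
        bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.sqrt(np.abs(np.diag(pcov)))
    resid = f - _isotherm(x, *popt)
    return BindingFit(
        kd=float(popt[0]), fmin=float(popt[1]), fmax=float(popt[2]),
        kd_se=float(se[0]), fmin_se=float(se[1]), fmax_se=float(se[2]),
        residual_norm=float(np.linalg.norm(resid)),
    )


# ---------------------------------------------------------------------------
# chromophore pKa (50 %-retention estimator)
# ---------------------------------------------------------------------------

def estimate_pka_50pct(curve: PHResponseCurve) -> float:
    """pH at which 50 % of the normalized signal is retained.

    Scans the series from high pH downward and linearly interpolates within
    the first bracketing pair that crosses 0.5.  Multiple crossings trigger
    a warning; the highest-pH crossing is reported.
    """
    ph = curve.ph
    v = curve.normalized
    s = np.sign(v - 0.5)
    crossings = [float(ph[j]) for j in np.nonzero(s == 0)[0]]  # exact hits
    for j in range(len(ph) - 1):
        if s[j] * s[j + 1] < 0:
            a, b = v[j], v[j + 1]
            crossings.append(float(ph[j] + (0.5 - a) * (ph[j + 1] - ph[j]) / (b - a)))
    if not crossings:
        raise ValueError("normalized series never crosses 0.5")
    if len(crossings) > 1:
        warnings.warn(
            f"{len(crossings)} crossings of the 50% level; reporting the "
            "highest-pH crossing"
        )
    return max(crossings)


# ---------------------------------------------------------------------------
# scalar photophysics
# ---------------------------------------------------------------------------

def fold_change(f_initial: float, f_final: float) -> float:
    """F_f / F_i, the emission fold change on analyte addition."""
    if f_initial <= 0:
        raise ValueError("initial intensity must be positive")
    return f_final / f_initial


#: ProtParam chromophore-free coefficients at 280 nm, M⁻¹ cm⁻¹.
_EPS280 = {"W": 5500.0, "Y": 1490.0}
_CYSTINE = 125.0
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def extinction_from_sequence(sequence: str, n_cystines: int = 0) -> float:
    """ε280 from composition: 5500·nTrp + 1490·nTyr + 125·n_cystine.

    Cysteines are assumed reduced by default (``n_cystines=0``).
    """
    seq = sequence.upper()
    bad = set(seq) - _AA20
    if bad:
        raise ValueError(f"invalid amino-acid code(s): {sorted(bad)}")
    if n_cystines < 0 or n_cystines > seq.count("C") // 2:
        raise ValueError("implausible cystine count for this sequence")
    return (seq.count("W") * _EPS280["W"] + seq.count("Y") * _EPS280["Y"]
            + n_cystines * _CYSTINE)


def extinction_at_wavelength(eps280: float, a280: float, a_lambda: float) -> float:
    """ε_λ = ε280 · A_λ / A280 at matched path length and concentration."""
    if a280 <= 0:
        raise ValueError("A280 must be positive")
    return eps280 * a_lambda / a280


def relative_quantum_yield(slope_sample: float, slope_reference: float,
                           phi_reference: float,
                           n_sample: float = 1.333,
                           n_reference: float = 1.333) -> float:
    """Relative quantum yield from integrated-emission-vs-absorbance slopes.

    Φ = Φ_ref · (slope_sample / slope_ref) · (n_sample² / n_ref²).
    """
    if slope_sample <= 0 or slope_reference <= 0:
        raise ValueError("slopes must be positive")
    return phi_reference * (slope_sample / slope_reference) * (n_sample ** 2 / n_reference ** 2)


def combine_batches(estimates):
    """Average batch estimates with propagated standard deviation.

    ``estimates`` is a list of (value, sd).  Returns
    (mean of values, sqrt(Σ sdᵢ²)/n).
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    vals = np.array([v for v, _ in estimates], dtype=float)
    sds = np.array([s for _, s in estimates], dtype=float)
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    return float(vals.mean()), float(np.sqrt(np.sum(sds ** 2)) / len(estimates))
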