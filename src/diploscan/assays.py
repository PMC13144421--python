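"""Physiological assay computations: flow-cytometry C-values, net CO2
assimilation, and titratable acidity from two-wavelength titration curves.

Titratable acidity (TA) is the classic overnight-acidification readout of
crassulacean acid metabolism: an aliquot of hot-water leaf extract is
titrated with NaOH in 1-uL steps while a bromothymol-blue indicator is read
at 445 and 615 nm; the 615/445 ratio is converted to pH through a standard
curve, and the NaOH volume needed to reach pH 7.0 gives the H+ content,
scaled to umol per gram fresh weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

PH_TARGET = 7.0


def c_value(fi_object: float, fi_standard: float, c_standard: float) -> float:
    """Haploid genome size (pg/1C) from G0/1 peak fluorescence intensities.

    1C_object = (FI_object / FI_standard) * 1C_standard; homogeneous of
    degree 0 in the intensities and degree 1 in the standard value.
    """
    if fi_object <= 0 or fi_standard <= 0:
        raise ValueError("peak fluorescence intensities must be positive")
    if c_standard <= 0:
        raise ValueError("standard 1C value must be positive")
    return (fi_object / fi_standard) * c_standard


def net_assimilation(assimilation: float, respiration: float) -> float:
    """Net CO2 assimilation rate (umol m-2 s-1) = assimilation - respiration."""
    return assimilation - respiration


def smooth_gas_exchange(
    net: np.ndarray, conductance: np.ndarray, window: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """5-record block averaging with negative stomatal conductance clamped to 0
    before averaging (instrument artefacts at very low evapotranspiration)."""
    net = np.asarray(net, dtype=float)
    cond = np.maximum(np.asarray(conductance, dtype=float), 0.0)
    n = (len(net) // window) * window
    return (
        net[:n].reshape(-1, window).mean(axis=1),
        cond[:n].reshape(-1, window).mean(axis=1),
    )


@dataclass
class TitrationCurve:
    """One titration: cumulative NaOH volumes with dual-wavelength readings
    plus the buffer-standard calibration (pH, 615/445 ratio) pairs."""

    tissue_mass_g: float
    extract_volume_ul: float
    aliquot_volume_ul: float
    naoh_molarity: float  # mol/L
    steps: list[tuple[float, float, float]]  # (cumulative uL, A445, A615)
    calibration: list[tuple[float, float]]  # (pH, ratio 615/445)

    def __post_init__(self) -> None:
        vols = [v for v, _, _ in self.steps]
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("cumulative NaOH volumes must be strictly increasing")
        for ph, _ in self.calibration:
            if not 4.0 <= ph <= 9.0:
                raise ValueError(f"calibration pH {ph} outside plausible indicator range")


class InsufficientTitrationError(ValueError):
    pass


def _ratio_to_ph(calibration: list[tuple[float, float]], linear: bool = False):
    """Monotone interpolation of pH on the 615/445 ratio standard curve."""
    cal = sorted(calibration, key=lambda pr: pr[1])
    ratios = np.array([r for _, r in cal])
    phs = np.array([p for p, _ in cal])
    if np.any(np.diff(ratios) <= 0):
        raise ValueError("calibration ratios must be strictly monotone in pH")
    if linear:
        return lambda r: np.interp(r, ratios, phs)
    interp = PchipInterpolator(ratios, phs, extrapolate=False)

    def f(r):
        r = np.clip(r, ratios[0], ratios[-1])
        return interp(r)

    return f


def titratable_acidity(curve: TitrationCurve, linear_calibration: bool = False) -> float:
    """Titratable acidity in umol H+ per g fresh weight.

    Per step pH is interpolated from the 615/445 ratio; V* is the first
    cumulative volume reaching pH 7.0 (linear interpolation between the
    bracketing steps); TA = V* x [NaOH] scaled from aliquot to extract and
    per gram of tissue.  A non-monotone pH trace is isotonically corrected
    with a warning; a curve never reaching pH 7.0 is an error.
    """
    ratio_to_ph = _ratio_to_ph(curve.calibration, linear=linear_calibration)
    vols = np.array([v for v, _, _ in curve.steps], dtype=float)
    ratios = np.array([a615 / a445 for _, a445, a615 in curve.steps])
    ph = np.asarray(ratio_to_ph(ratios), dtype=float)
    if np.any(np.diff(ph) < 0):
        warnings.warn("non-monotone pH trace; applying isotonic correction")
        ph = np.maximum.accumulate(ph)
    if ph[0] >= PH_TARGET:
        v_star = 0.0
    else:
        above = np.flatnonzero(ph >= PH_TARGET)
        if len(above) == 0:
            raise InsufficientTitrationError("titration never reaches pH 7.0")
        j = above[0]
        ph0, ph1 = ph[j - 1], ph[j]
        v_star = vols[j - 1] + (PH_TARGET - ph0) / (ph1 - ph0) * (vols[j] - vols[j - 1])
    umol_aliquot = v_star * curve.naoh_molarity  # uL * mol/L = umol
    return (
        umol_aliquot
        * (curve.extract_volume_ul / curve.aliquot_volume_ul)
        / curve.tissue_mass_g
    )


# ---------------------------------------------------------------------------
# Forward titration simulator (synthetic oracle for recovery tests)

#: malate-like diprotic acid
ACID_PKAS = (3.40, 5.11)
PKW = 14.0
#: bromothymol blue response of the 615/445 ratio
INDICATOR_PK = 7.10
RATIO_RANGE = (0.05, 3.0)


def indicator_ratio(ph: float | np.ndarray) -> np.ndarray:
    """Synthetic sigmoid 615/445 response of the indicator."""
    lo, hi = RATIO_RANGE
    return lo + (hi - lo) / (1.0 + 10 ** (INDICATOR_PK - np.asarray(ph, dtype=float)))


def _solve_ph(acid_mol: float, base_mol: float, volume_l: float) -> float:
    """Charge balance for a diprotic acid + strong base, solved for pH."""
    ka1, ka2 = (10.0**-p for p in ACID_PKAS)
    ca = acid_mol / volume_l
    cb = base_mol / volume_l

    def balance(ph: float) -> float:
        h = 10.0**-ph
        oh = 10.0 ** (ph - PKW)
        denom = h * h + ka1 * h + ka1 * ka2
        a1 = ka1 * h / denom
        a2 = ka1 * ka2 / denom
        return cb + h - oh - ca * (a1 + 2 * a2)

    return brentq(balance, 0.5, 13.5, xtol=1e-10)


def simulate_titration(
    h_umol_extract: float,
    tissue_mass_g: float = 0.045,
    extract_volume_ul: float = 500.0,
    aliquot_volume_ul: float = 10.0,
    diluent_ul: float = 94.0,
    naoh_molarity: float = 0.010,
    rng: np.random.Generator | None = None,
    absorbance_scale: float = 1.0,
    calibration_step: float = 0.2,
) -> TitrationCurve:
    """Forward-model a titration of an extract with known H+ content.

    The aliquot carries its share of titratable protons as a malate-like
    diprotic acid; each 1-uL NaOH step re-solves the charge balance with
    dilution and reads the indicator.  ``absorbance_scale`` rescales both
    channels (TA must be invariant to it).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h_aliquot_umol = h_umol_extract * aliquot_volume_ul / extract_volume_ul
    acid_mol = (h_aliquot_umol / 2) * 1e-6  # two protons per acid molecule
    v0_l = (aliquot_volume_ul + diluent_ul) * 1e-6
    # titrate past the expected equivalence
    n_steps = int(np.ceil(h_aliquot_umol / naoh_molarity * 1.6)) + 10
    steps: list[tuple[float, float, float]] = []
    for v_ul in range(n_steps + 1):
        base_mol = v_ul * 1e-6 * naoh_molarity  # L x mol/L = mol
        ph = _solve_ph(acid_mol, base_mol, v0_l + v_ul * 1e-6)
        ratio = float(indicator_ratio(ph))
        steps.append((float(v_ul), absorbance_scale * 1.0, absorbance_scale * ratio))
    cal_ph = np.arange(4.6, 7.8 + 1e-9, calibration_step)
    calibration = [(float(p), float(indicator_ratio(p))) for p in cal_ph]
    return TitrationCurve(
        tissue_mass_g=tissue_mass_g,
        extract_volume_ul=extract_volume_ul,
        aliquot_volume_ul=aliquot_volume_ul,
        naoh_molarity=naoh_molarity,
        steps=steps,
        calibration=calibration,
    )
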