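"""Esterase-activity plate quantification: standards, curve, interpolation.

The assay reads optical density at 405 nm for a 1:3 serial-dilution
standard series (1000 down to ~1.37 mU/mL), duplicate sample wells and a
buffer blank.  The blank is subtracted from every reading, the corrected
standard ODs define a monotone OD-to-concentration map (piecewise linear
in log concentration by default, optionally a 4-parameter logistic), and
sample concentrations are interpolated after averaging duplicates.
Out-of-range ODs are flagged, never extrapolated.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "StandardCurve",
    "serial_dilution",
    "fit_standard_curve",
    "interpolate_samples",
]


def serial_dilution(start: float, factor: float, n: int) -> np.ndarray:
    """Concentrations of an ``n``-member 1:``factor`` dilution series."""
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    if n < 1:
        raise ValueError("series length must be >= 1")
    return start / factor ** np.arange(n, dtype=float)


@dataclasses.dataclass
class StandardCurve:
    """Blank-corrected standard series and its monotone OD->conc map."""

    standard_concs: np.ndarray  # descending
    standard_ods: np.ndarray  # blank-corrected, same order
    blank: float
    model: str
    monotone_adjusted: bool
    _params: tuple | None = None

    def od_to_conc(self, od: np.ndarray) -> np.ndarray:
        """Invert the curve; NaN outside the standard OD range."""
        od = np.asarray(od, dtype=float)
        asc_od = self.standard_ods[::-1]
        asc_logc = np.log10(self.standard_concs[::-1])
        out = np.full(od.shape, np.nan)
        inside = (od >= asc_od[0]) & (od <= asc_od[-1])
        if self.model == "linear-log":
            out[inside] = 10.0 ** np.interp(od[inside], asc_od, asc_logc)
        else:  # logistic4 in log10 concentration
            bottom, top, ec50, hill = self._params
            y = od[inside]
            frac = (top - bottom) / (y - bottom) - 1.0
            frac = np.clip(frac, 1e-12, None)
            out[inside] = 10.0 ** (ec50 - np.log(frac) / hill)
        return out


def _logistic4(logc, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(-hill * (logc - ec50)))


def fit_standard_curve(
    concs, ods, blank: float = 0.0, model: str = "linear-log"
) -> StandardCurve:
    """Blank-correct the standards and build the OD->concentration map.

    ODs must rise with concentration; violations (noise) are repaired by
    isotonic adjustment with a warning.  ``model`` is ``"linear-log"``
    (piecewise linear in log concentration, the default) or
    ``"logistic4"``.
    """
    concs = np.asarray(concs, dtype=float)
    ods = np.asarray(ods, dtype=float) - blank
    if len(concs) < 2:
        raise ValueError("at least two standards are required")
    if len(concs) != len(ods):
        raise ValueError("concs and ods must have equal length")
    order = np.argsort(-concs)  # descending concentration
    concs, ods = concs[order], ods[order]

    asc = ods[::-1]
    adjusted = False
    if np.any(np.diff(asc) < 0):
        warnings.warn("standard ODs not monotone; applying isotonic adjustment")
        asc = _isotonic(asc)
        # break exact ties so the map stays invertible
        for i in range(1, len(asc)):
            if asc[i] <= asc[i - 1]:
                asc[i] = asc[i - 1] + 1e-9
        ods = asc[::-1].copy()
        adjusted = True

    params = None
    if model == "logistic4":
        logc = np.log10(concs[::-1])
        p0 = (float(asc[0]), float(asc[-1]), float(np.median(logc)), 1.0)
        popt, _ = optimize.curve_fit(_logistic4, logc, asc, p0=p0, maxfev=20000)
        params = tuple(popt)
    elif model != "linear-log":
        raise ValueError(f"unknown curve model: {model!r}")
    return StandardCurve(
        standard_concs=concs, standard_ods=ods, blank=float(blank),
        model=model, monotone_adjusted=adjusted, _params=params,
    )


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators non-decreasing fit (unit weights)."""
    y = y.astype(float).copy()
    blocks = [[v, 1] for v in y]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0]:
            v = (blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1])
            w = blocks[i][1] + blocks[i + 1][1]
            blocks[i] = [v / w, w]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for v, w in blocks:
        out.extend([v] * w)
    return np.array(out)


def interpolate_samples(curve: StandardCurve, sample_ods) -> pd.DataFrame:
    """Average duplicate wells, blank-correct, and invert the curve.

    ``sample_ods`` is an (n_samples, n_replicates) array (or a 1-D array
    of single wells).  ODs below the lowest or above the highest standard
    are flagged ``below_range`` / ``above_range`` with NaN concentration.
    """
    sample_ods = np.asarray(sample_ods, dtype=float)
    if sample_ods.size == 0:
        raise ValueError("no sample ODs given")
    if sample_ods.ndim == 1:  # single wells, one per sample
        sample_ods = sample_ods[:, None]
    mean_od = sample_ods.mean(axis=1) - curve.blank
    lo = curve.standard_ods.min()
    hi = curve.standard_ods.max()
    conc = curve.od_to_conc(mean_od)
    flag = np.where(
        mean_od < lo, "below_range", np.where(mean_od > hi, "above_range", "ok")
    )
    return pd.DataFrame(
        {"od_corrected": mean_od, "conc_mU_per_mL": conc, "flag": flag}
    )
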