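"""Chromophoric DOM optics: spectral slope ratio and Coble peak distribution.

The slope ratio S_R is the ratio of log-linear absorption slopes over
275-295 nm and 350-400 nm and is inversely related to the dominant
molecular weight of the dissolved organic matter. Coble peaks are the
classical fluorescence excitation/emission windows: b and t protein-like
(tyrosine-, tryptophan-like), a, m and c humic-like. Inputs are assumed
instrument-corrected; no scatter/inner-filter handling happens here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .datamodel import ValidationError
from .synthetic import COBLE_WINDOWS

SHORT_RANGE = (275.0, 295.0)
LONG_RANGE = (350.0, 400.0)


def spectral_slope(spectrum: pd.DataFrame, wl_range: tuple[float, float]) -> float:
    """Spectral slope S (nm^-1): minus the OLS slope of ln(a) vs wavelength.

    Non-positive absorption points inside the range are excluded; fewer
    than 3 usable points is an error.
    """
    wl = spectrum["wavelength_nm"].to_numpy(float)
    a = spectrum["absorption"].to_numpy(float)
    lo, hi = wl_range
    mask = (wl >= lo) & (wl <= hi) & (a > 0)
    if mask.sum() < 3:
        raise ValidationError(
            f"need >=3 positive absorption points in {wl_range}, got {int(mask.sum())}"
        )
    fit = linregress(wl[mask], np.log(a[mask]))
    return float(-fit.slope)


def slope_ratio(spectrum: pd.DataFrame) -> float:
    """S_R = S(275-295) / S(350-400)."""
    s_short = spectral_slope(spectrum, SHORT_RANGE)
    s_long = spectral_slope(spectrum, LONG_RANGE)
    if s_long == 0:
        raise ValidationError("S(350-400) is zero: slope ratio undefined")
    return s_short / s_long


def coble_peak_distribution(
    eem: pd.DataFrame, windows: dict | None = None, statistic: str = "max"
) -> dict[str, float]:
    """Percentage of fluorescence in each Coble window.

    ``eem`` is indexed by excitation (nm) with emission (nm) columns. The
    per-window statistic is the maximum intensity (switchable to the
    mean); percentages are 100 * peak / sum(peaks).
    """
    windows = dict(COBLE_WINDOWS if windows is None else windows)
    ex = eem.index.to_numpy(float)
    em = eem.columns.to_numpy(float)
    vals = eem.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("EEM intensities must be finite")
    peaks = {}
    for name, ((ex_lo, ex_hi), (em_lo, em_hi)) in windows.items():
        rows = (ex >= ex_lo) & (ex <= ex_hi)
        cols = (em >= em_lo) & (em <= em_hi)
        if not rows.any() or not cols.any():
            raise ValidationError(f"EEM grid does not cover Coble window {name!r}")
        block = vals[np.ix_(rows, cols)]
        peaks[name] = float(block.max() if statistic == "max" else block.mean())
    total = sum(peaks.values())
    if total == 0:
        raise ValidationError("all Coble windows have zero intensity")
    return {name: 100.0 * v / total for name, v in peaks.items()}


def read_spectrum(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"wavelength_nm", "absorption"} <= set(df.columns):
        raise ValidationError("spectrum TSV needs wavelength_nm and absorption columns")
    wl = df["wavelength_nm"].to_numpy(float)
    if not np.all(np.diff(wl) > 0):
        raise ValidationError("wavelengths must be strictly increasing")
    return df


def read_eem(path) -> pd.DataFrame:
    eem = pd.read_csv(path, sep="\t", index_col=0)
    eem.index = eem.index.astype(float)
    eem.columns = eem.columns.astype(float)
    return eem
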