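"""Differential scanning fluorimetry (thermal shift) analysis.

The melting temperature Tm of each curve is the location of the maximum of
the first derivative dF/dT of the fluorescence trace, refined below the
temperature grid by parabolic interpolation.  Groups of replicate curves are
compared via their mean Tm, and a ΔTm between variants is converted to a
folding free-energy change through the empirical rule that 1 kcal/mol of
ΔΔG corresponds to a 3–4 K shift in Tm.  The equilibrium consequence of a
destabilization ΔΔG is an exp(ΔΔG/RT)-fold increase in the unfolded
fraction (dilute, two-state limit).

Temperatures are degrees Celsius at every interface; kelvin appears only
inside exponentials.  ΔTm is reported in K (numerically identical to a °C
difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987e-3

#: Default reference temperature [K] for unfolded-fraction fold changes.
T_REF_K = 298.0

CELSIUS_OFFSET = 273.15


@dataclass
class MeltCurve:
    """A fluorescence melting trace on a strictly increasing °C grid."""

    temperature: np.ndarray   # °C
    fluorescence: np.ndarray  # AU
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class MeltResult:
    """Extracted Tm plus the derivative trace it came from."""

    tm_C: float
    temperature: np.ndarray
    derivative: np.ndarray        # dF/dT, raw units (AU/°C)
    smoothing_window: int
    boundary_truncated: bool = False   # derivative maximum at the grid edge
    label: str = ""


@dataclass
class StabilityComparison:
    """Replicate Tm statistics for two groups and their difference."""

    mean_a_C: float
    sd_a_C: float | None
    n_a: int
    mean_b_C: float
    sd_b_C: float | None
    n_b: int

    @property
    def dtm_K(self) -> float:
        """Group A mean minus group B mean, in K."""
        return self.mean_a_C - self.mean_b_C


@dataclass
class StabilityEstimate:
    """ΔΔG range implied by a ΔTm, and its unfolded-fraction consequence."""

    ddg_low_kcal: float
    ddg_high_kcal: float
    k_per_kcal: tuple[float, float]
    reference_T_K: float
    fold_change_unfolded: float        # at the midpoint ΔΔG
    stabilizing: bool = False          # input ΔTm was negative

    @property
    def ddg_mid_kcal(self) -> float:
        return 0.5 * (self.ddg_low_kcal + self.ddg_high_kcal)


def extract_tm(curve: MeltCurve, smoothing_window: int = 5) -> MeltResult:
    """Locate Tm as the maximum of dF/dT.

    The derivative is taken with a local quadratic (Savitzky–Golay)
    differentiating filter of odd width ``smoothing_window`` followed by a
    smoothing pass of the same width (windows below 5 fall back to plain
    centered differences).  The maximum is refined below the grid spacing by
    a parabola fitted to the contiguous peak region where the derivative
    stays above 75% of its maximum.  The default window of 5 suits clean
    curves; noisy traces (noise at percent-of-amplitude scale) warrant
    windows of ~2 K width (e.g. 21 points on a 0.2 °C grid).  A maximum
    sitting on the grid boundary is flagged as truncated and returned
    unrefined.
    """
    t, f = curve.temperature, curve.fluorescence
    if t.size < 5:
        raise ValueError("need at least 5 points to extract a Tm")
    if smoothing_window % 2 == 0 or smoothing_window >= t.size:
        raise ValueError("smoothing window must be odd and smaller than the curve")
    if smoothing_window >= 5:
        h = float(np.median(np.diff(t)))
        deriv = savgol_filter(f, smoothing_window, 2, deriv=1, delta=h)
        deriv = savgol_filter(deriv, smoothing_window, 2)
    else:
        deriv = np.gradient(f, t)
    i = int(np.argmax(deriv))
    if i == 0 or i == t.size - 1:
        return MeltResult(tm_C=float(t[i]), temperature=t, derivative=deriv,
                          smoothing_window=smoothing_window,
                          boundary_truncated=True, label=curve.label)
    # parabolic vertex over the contiguous region above 75% of the peak
    threshold = 0.75 * deriv[i]
    lo, hi = i, i
    while lo > 0 and deriv[lo - 1] >= threshold:
        lo -= 1
    while hi < t.size - 1 and deriv[hi + 1] >= threshold:
        hi += 1
    lo, hi = min(lo, i - 1), max(hi, i + 1)
    coeffs = np.polyfit(t[lo:hi + 1], deriv[lo:hi + 1], 2)
    if coeffs[0] < 0:
        tm = -coeffs[1] / (2 * coeffs[0])
        tm = float(np.clip(tm, t[lo], t[hi]))
    else:
        tm = float(t[i])
    return MeltResult(tm_C=tm, temperature=t, derivative=deriv,
                      smoothing_window=smoothing_window, label=curve.label)


def normalize_derivatives(results: list[MeltResult]) -> list[np.ndarray]:
    """Express each dF/dT trace in % of the maximum across the whole set
    (display convention; does not affect the extracted Tm values)."""
    peak = max(float(np.max(r.derivative)) for r in results)
    if peak <= 0:
        raise ValueError("no positive derivative in the set")
    return [100.0 * r.derivative / peak for r in results]


def compare_groups(results_a: list[MeltResult],
                   results_b: list[MeltResult]) -> StabilityComparison:
    """Replicate mean and sample standard deviation per group; ΔTm = A − B.

    A single-replicate group reports ``None`` for its standard deviation
    rather than 0.
    """
    if not results_a or not results_b:
        raise ValueError("each group needs at least one replicate")
    a = np.array([r.tm_C for r in results_a])
    b = np.array([r.tm_C for r in results_b])
    sd_a = float(np.std(a, ddof=1)) if a.size > 1 else None
    sd_b = float(np.std(b, ddof=1)) if b.size > 1 else None
    return StabilityComparison(
        mean_a_C=float(a.mean()), sd_a_C=sd_a, n_a=int(a.size),
        mean_b_C=float(b.mean()), sd_b_C=sd_b, n_b=int(b.size),
    )


def ddg_from_dtm(dtm_K: float,
                 k_per_kcal: tuple[float, float] = (3.0, 4.0)
                 ) -> tuple[float, float, bool]:
    """Convert a ΔTm [K] into a ΔΔG range [kcal/mol].

    Uses the empirical 3–4 K per kcal/mol conversion; returns
    ``(dtm/k_max, dtm/k_min, stabilizing)``.  A negative ΔTm is converted on
    its magnitude with the stabilizing flag set.
    """
    k_lo, k_hi = k_per_kcal
    if k_lo <= 0 or k_hi <= 0 or k_lo > k_hi:
        raise ValueError("conversion range must be positive and ordered")
    stabilizing = dtm_K < 0
    mag = abs(dtm_K)
    return mag / k_hi, mag / k_lo, stabilizing


def unfolded_fold_change(ddg_kcal: float, T_K: float = T_REF_K) -> float:
    """Fold change in the unfolded-state population caused by a ΔΔG [kcal/mol]
    at temperature T [K]: exp(ΔΔG / (R*T)) in the dilute two-state limit."""
    if T_K <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(ddg_kcal / (R_KCAL * T_K))


def stability_estimate(dtm_K: float,
                       k_per_kcal: tuple[float, float] = (3.0, 4.0),
                       T_K: float = T_REF_K) -> StabilityEstimate:
    """Bundle the ΔΔG range for a ΔTm with the unfolded-fraction fold change
    evaluated at the midpoint of the range."""
    low, high, stabilizing = ddg_from_dtm(dtm_K, k_per_kcal)
    mid = 0.5 * (low + high)
    return StabilityEstimate(
        ddg_low_kcal=low, ddg_high_kcal=high, k_per_kcal=tuple(k_per_kcal),
        reference_T_K=T_K, fold_change_unfolded=unfolded_fold_change(mid, T_K),
        stabilizing=stabilizing,
    )


def read_melt_csv(path, label: str = "") -> MeltCurve:
    df = pd.read_csv(path)
    return MeltCurve(temperature=df["temperature_C"].to_numpy(),
                     fluorescence=df["fluorescence_AU"].to_numpy(),
                     label=label or str(path))


def write_melt_csv(curve: MeltCurve, path) -> None:
    pd.DataFrame({"temperature_C": curve.temperature,
                  "fluorescence_AU": curve.fluorescence}).to_csv(path, index=False)


def melting_table(groups: dict[str, list[MeltResult]]) -> pd.DataFrame:
    """Per-group Tm summary (label, mean, sd, n), one row per group."""
    rows = []
    for label, results in groups.items():
        tms = np.array([r.tm_C for r in results])
        rows.append({
            "label": label,
            "tm_mean_C": float(tms.mean()),
            "tm_sd_C": float(np.std(tms, ddof=1)) if tms.size > 1 else np.nan,
            "n_replicates": int(tms.size),
        })
    return pd.DataFrame(rows)
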