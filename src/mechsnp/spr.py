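"""Surface plasmon resonance binding analysis for a 1:1 interaction.

Closed-form 1:1 (Langmuir) binding kinetics, global multi-concentration
kinetic fitting, steady-state equilibrium / Scatchard analysis, initial-rate
calibration, and the solution-competition affinity model.

Unit conventions: analyte concentrations are nanomolar (nM) at every public
interface and converted to molar internally for the rate equations; rate
constants are kon [1/(M*s)] and koff [1/s]; responses are resonance units
(RU).  Dissociation constants are exposed both in molar (``kd``) and
nanomolar (``kd_nM``).

The association phase follows

    R(t) = Req * (1 - exp(-(kon*C + koff) * t)),   Req = Rmax*kon*C/(kon*C+koff)

and the dissociation phase decays single-exponentially with rate koff from
the response at the end of association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress


@dataclass(frozen=True)
class SensorgramSchedule:
    """Injection schedule: association and dissociation durations (s)."""

    t_assoc: float = 120.0
    t_dissoc: float = 120.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.t_assoc <= 0 or self.t_dissoc <= 0:
            raise ValueError("phase durations must be positive")
        if self.dt <= 0 or self.dt > min(self.t_assoc, self.t_dissoc):
            raise ValueError("sampling interval must be positive and <= phase durations")

    def time_grid(self) -> np.ndarray:
        total = self.t_assoc + self.t_dissoc
        n = int(round(total / self.dt))
        return np.linspace(0.0, total, n + 1)


@dataclass
class Sensorgram:
    """One time/response trace at a single analyte concentration."""

    time: np.ndarray          # s
    response: np.ndarray      # RU
    conc_nM: float
    t_assoc_end: float        # s, association/dissociation boundary

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] <= self.t_assoc_end <= self.time[-1]):
            raise ValueError("phase boundary outside the time span")


@dataclass
class SensorgramSet:
    """A concentration series of sensorgrams sharing one schedule."""

    curves: list[Sensorgram]
    schedule: SensorgramSchedule

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("empty sensorgram set")

    def __iter__(self):
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)

    @property
    def concentrations_nM(self) -> list[float]:
        return [c.conc_nM for c in self.curves]

    def write_csv(self, directory, prefix: str = "sensorgram") -> "pd.DataFrame":
        """Write one ``time_s,response_RU`` CSV per concentration plus a manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, curve in enumerate(self.curves):
            name = f"{prefix}_{i:02d}.csv"
            pd.DataFrame(
                {"time_s": curve.time, "response_RU": curve.response}
            ).to_csv(directory / name, index=False)
            rows.append(
                {"file": name, "conc_nM": curve.conc_nM,
                 "phase_boundary_s": curve.t_assoc_end}
            )
        manifest = pd.DataFrame(rows)
        manifest.to_csv(directory / f"{prefix}_manifest.csv", index=False)
        return manifest

    @classmethod
    def read_csv(cls, manifest_path) -> "SensorgramSet":
        from pathlib import Path

        manifest_path = Path(manifest_path)
        manifest = pd.read_csv(manifest_path)
        curves = []
        for _, row in manifest.iterrows():
            df = pd.read_csv(manifest_path.parent / row["file"])
            curves.append(
                Sensorgram(
                    time=df["time_s"].to_numpy(),
                    response=df["response_RU"].to_numpy(),
                    conc_nM=float(row["conc_nM"]),
                    t_assoc_end=float(row["phase_boundary_s"]),
                )
            )
        tb = curves[0].t_assoc_end
        t_end = curves[0].time[-1]
        dt = float(np.median(np.diff(curves[0].time)))
        return cls(curves, SensorgramSchedule(tb, t_end - tb, dt))


def _langmuir_eval(kon: float, koff: float, rmax: float, conc_nM: float,
                   time: np.ndarray, t_assoc_end: float) -> np.ndarray:
    c_molar = conc_nM * 1e-9
    kobs = kon * c_molar + koff
    req = rmax * kon * c_molar / kobs
    t = np.asarray(time, dtype=float)
    r = np.empty_like(t)
    mask = t <= t_assoc_end
    r[mask] = req * (1.0 - np.exp(-kobs * t[mask]))
    r_boundary = req * (1.0 - np.exp(-kobs * t_assoc_end))
    r[~mask] = r_boundary * np.exp(-koff * (t[~mask] - t_assoc_end))
    return r


def langmuir_response(kon: float, koff: float, rmax: float, conc_nM: float,
                      schedule: SensorgramSchedule) -> Sensorgram:
    """Noise-free 1:1 Langmuir sensorgram for one analyte concentration.

    Parameters
    ----------
    kon, koff, rmax
        Association rate [1/(M*s)], dissociation rate [1/s], and surface
        capacity [RU]; all strictly positive.
    conc_nM
        Analyte concentration in nM (> 0).
    schedule
        Association/dissociation durations and sampling interval.
    """
    if min(kon, koff, rmax, conc_nM) <= 0:
        raise ValueError("kon, koff, Rmax and concentration must be positive")
    t = schedule.time_grid()
    r = _langmuir_eval(kon, koff, rmax, conc_nM, t, schedule.t_assoc)
    return Sensorgram(time=t, response=r, conc_nM=conc_nM,
                      t_assoc_end=schedule.t_assoc)


@dataclass
class KineticFit:
    """Globally fitted 1:1 kinetic parameters shared across a concentration series."""

    kon: float                     # 1/(M*s)
    koff: float                    # 1/s
    rmax: float                    # RU
    residual_rms: dict[float, float] = field(default_factory=dict)  # per conc_nM
    converged: bool = True
    cost: float = 0.0
    message: str = ""

    @property
    def kd(self) -> float:
        """Dissociation constant koff/kon [M]."""
        return self.koff / self.kon

    @property
    def kd_nM(self) -> float:
        return self.kd * 1e9


class FitError(RuntimeError):
    """Non-convergent fit; carries the best iterate found."""

    def __init__(self, message: str, best: object = None):
        super().__init__(message)
        self.best = best


def _kinetic_residuals(logp: np.ndarray, curves: list[Sensorgram]) -> np.ndarray:
    kon, koff, rmax = np.exp(logp)
    parts = [
        _langmuir_eval(kon, koff, rmax, c.conc_nM, c.time, c.t_assoc_end) - c.response
        for c in curves
    ]
    return np.concatenate(parts)


def _kinetic_initial_guess(curves: list[Sensorgram]) -> tuple[float, float, float]:
    """Linearized starting values: koff from the dissociation decay, kon from a
    kobs-vs-C regression (kobs estimated from the time to 63% of the association
    plateau), Rmax from the occupancy-corrected plateaus."""
    koff_estimates = []
    kobs_points = []
    plateaus = []
    for c in curves:
        tb = c.t_assoc_end
        mask_d = c.time > tb
        td, rd = c.time[mask_d] - tb, c.response[mask_d]
        top = np.max(np.abs(c.response)) if c.response.size else 0.0
        ok = rd > max(1e-6, 0.02 * top)
        if ok.sum() >= 3:
            slope = np.polyfit(td[ok], np.log(rd[ok]), 1)[0]
            if slope < 0:
                koff_estimates.append(-slope)
        mask_a = c.time <= tb
        ta, ra = c.time[mask_a], c.response[mask_a]
        if ra.size < 3:
            continue
        req = float(ra[-1])
        plateaus.append((c.conc_nM * 1e-9, req))
        if req > 0:
            above = np.nonzero(ra >= 0.632 * req)[0]
            if above.size and ta[above[0]] > 0:
                kobs_points.append((c.conc_nM * 1e-9, 1.0 / ta[above[0]]))
    koff0 = float(np.median(koff_estimates)) if koff_estimates else 1e-2
    kon0 = 1e5
    if len(kobs_points) >= 3:
        cs, ks = np.array(kobs_points).T
        slope, intercept = np.polyfit(cs, ks, 1)
        if slope > 0:
            kon0 = slope
        if intercept > 0 and not koff_estimates:
            koff0 = intercept
    rmax_guesses = [req * (kon0 * c + koff0) / (kon0 * c)
                    for c, req in plateaus if req > 0]
    rmax0 = float(np.median(rmax_guesses)) if rmax_guesses else 100.0
    top = max(float(np.max(c.response)) for c in curves)
    rmax0 = max(rmax0, top)
    return kon0, koff0, rmax0


def fit_kinetics_global(curves: SensorgramSet | list[Sensorgram],
                        init: tuple[float, float, float] | None = None
                        ) -> KineticFit:
    """Globally fit one shared (kon, koff, Rmax) across all curves and phases.

    Parameters are fitted in log-space so positivity is structural.  The
    default initialization is a linearized early-phase estimate; a small
    deterministic multi-start grid is tried when the first solution leaves a
    visible residual.
    """
    curve_list = list(curves)
    if len(curve_list) < 3:
        raise ValueError("global kinetic fitting needs at least 3 concentrations")
    for c in curve_list:
        if not (c.time[0] < c.t_assoc_end < c.time[-1]):
            raise ValueError("each curve needs both association and dissociation phases")

    starts = [init if init is not None else _kinetic_initial_guess(curve_list)]
    top = max(float(np.max(c.response)) for c in curve_list)
    fallback_rmax = 2.0 * top
    for kon0 in (1e4, 1e5, 1e6):
        for koff0 in (1e-3, 1e-2, 1e-1):
            starts.append((kon0, koff0, fallback_rmax))

    best = None
    n_points = sum(c.time.size for c in curve_list)
    for kon0, koff0, rmax0 in starts:
        sol = least_squares(
            _kinetic_residuals,
            x0=np.log([kon0, koff0, rmax0]),
            args=(curve_list,),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if math.sqrt(2 * best.cost / n_points) < 1e-6 * max(top, 1.0):
            break

    kon, koff, rmax = np.exp(best.x)
    rms = {}
    for c in curve_list:
        res = _langmuir_eval(kon, koff, rmax, c.conc_nM, c.time, c.t_assoc_end) - c.response
        rms[c.conc_nM] = float(np.sqrt(np.mean(res**2)))
    fit = KineticFit(kon=float(kon), koff=float(koff), rmax=float(rmax),
                     residual_rms=rms, converged=bool(best.success),
                     cost=float(best.cost), message=str(best.message))
    if not best.success:
        raise FitError(f"global kinetic fit did not converge: {best.message}", best=fit)
    return fit


@dataclass
class EquilibriumFit:
    """Steady-state 1:1 isotherm fit with its Scatchard regression."""

    kd_nM: float
    rmax: float
    req_table: dict[float, float]          # conc_nM -> Req (input data)
    scatchard_slope: float                 # RU / (RU*nM) = 1/nM; equals -1/Kd_nM
    scatchard_intercept: float             # Rmax/Kd_nM
    residual_rms: float
    ill_conditioned: bool = False


def fit_equilibrium(req_table: dict[float, float],
                    init: tuple[float, float] | None = None) -> EquilibriumFit:
    """Least-squares fit of Req = Rmax*C/(Kd + C) to plateau responses.

    ``req_table`` maps analyte concentration [nM] to plateau response [RU].
    Also reports the ordinary Scatchard regression of Req/C against Req, whose
    slope is -1/Kd for ideal 1:1 data.  Flags the fit as ill-conditioned when
    the concentration series never reaches the fitted Kd.
    """
    if len(req_table) < 4:
        raise ValueError("equilibrium fitting needs at least 4 concentrations")
    conc = np.array(sorted(req_table), dtype=float)
    req = np.array([req_table[c] for c in conc], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    if init is None:
        rmax0 = 1.2 * float(req.max())
        half = 0.5 * float(req.max())
        kd0 = float(np.interp(half, req, conc))
        kd0 = max(kd0, 1e-3)
    else:
        kd0, rmax0 = init

    def residuals(logp):
        kd, rmax = np.exp(logp)
        return rmax * conc / (kd + conc) - req

    sol = least_squares(residuals, x0=np.log([kd0, rmax0]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    kd, rmax = np.exp(sol.x)
    reg = linregress(req, req / conc)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return EquilibriumFit(
        kd_nM=float(kd), rmax=float(rmax),
        req_table={float(c): float(r) for c, r in zip(conc, req)},
        scatchard_slope=float(reg.slope), scatchard_intercept=float(reg.intercept),
        residual_rms=rms, ill_conditioned=bool(conc.max() < kd),
    )


def steady_state_response(curve: Sensorgram, window: float = 5.0) -> float:
    """Plateau estimate: mean response over the final ``window`` s of association."""
    mask = (curve.time <= curve.t_assoc_end) & (curve.time >= curve.t_assoc_end - window)
    if not np.any(mask):
        raise ValueError("averaging window contains no association samples")
    return float(np.mean(curve.response[mask]))


def initial_rate(curve: Sensorgram, window: float = 5.0) -> float:
    """Initial binding rate [RU/s]: slope of response vs time over the first
    ``window`` seconds of association.  Approaches kon*C*Rmax as window -> 0."""
    if window <= 0:
        raise ValueError("window must be positive")
    if window > curve.t_assoc_end - curve.time[0]:
        raise ValueError("window longer than the association phase")
    mask = curve.time <= curve.time[0] + window
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    slope, _ = np.polyfit(curve.time[mask], curve.response[mask], 1)
    return float(slope)


@dataclass
class CalibrationCurve:
    """Linear map between analyte concentration and initial binding rate."""

    slope: float            # RU/(s*nM)
    intercept: float        # RU/s
    conc_min_nM: float
    conc_max_nM: float

    def rate_for_conc(self, conc_nM: float) -> float:
        return self.slope * conc_nM + self.intercept

    def conc_for_rate(self, rate: float) -> tuple[float, bool]:
        """Invert the calibration; the flag is True when the implied
        concentration falls inside the fitted validity range."""
        conc = (rate - self.intercept) / self.slope
        return float(conc), bool(self.conc_min_nM <= conc <= self.conc_max_nM)


def calibration_fit(rates: list[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration [nM], initial rate
    [RU/s]) points; stores the concentration range of validity."""
    if len(rates) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([c for c, _ in rates], dtype=float)
    rate = np.array([r for _, r in rates], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("degenerate calibration: all concentrations identical")
    slope, intercept = np.polyfit(conc, rate, 1)
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            conc_min_nM=float(conc.min()), conc_max_nM=float(conc.max()))


def solution_free_analyte(a_total_nM, s_total_nM, kd_nM):
    """Free analyte concentration [nM] at equilibrium in an A + S <-> AS mixture.

    Positive root of ``Af^2 + Af*(S0 + Kd - A0) - Kd*A0 = 0``; satisfies mass
    balance and Af*Sf = Kd*(A0 - Af).  Accepts scalars or arrays.
    """
    a0 = np.asarray(a_total_nM, dtype=float)
    s0 = np.asarray(s_total_nM, dtype=float)
    if np.any(a0 < 0) or np.any(s0 < 0) or kd_nM <= 0:
        raise ValueError("totals must be non-negative and Kd positive")
    b = s0 + kd_nM - a0
    af = 0.5 * (-b + np.sqrt(b * b + 4.0 * kd_nM * a0))
    if af.ndim == 0:
        return float(af)
    return af


@dataclass
class CompetitionSeries:
    """Free-analyte readout vs competitor concentration at fixed total analyte."""

    a_total_nM: float
    s_total_nM: np.ndarray
    free_nM: np.ndarray

    def __post_init__(self) -> None:
        self.s_total_nM = np.asarray(self.s_total_nM, dtype=float)
        self.free_nM = np.asarray(self.free_nM, dtype=float)
        if self.s_total_nM.shape != self.free_nM.shape:
            raise ValueError("S0 and free-analyte arrays must align")
        if np.any(self.free_nM < -1e-9) or np.any(self.free_nM > self.a_total_nM * (1 + 1e-6)):
            raise ValueError("free analyte must lie in [0, A0]")


@dataclass
class SolutionAffinityFit:
    kd_nM: float
    a_total_nM: float
    residual_rms: float
    ill_conditioned: bool = False


def fit_solution_affinity(series: CompetitionSeries,
                          fit_a0: bool = False) -> SolutionAffinityFit:
    """Fit the solution dissociation constant to a competition series.

    The total analyte concentration A0 is fixed at its nominal value by
    default; set ``fit_a0`` to co-fit it.  Flags the result as
    ill-conditioned when the competitor series does not bracket the fitted Kd.
    """
    if series.s_total_nM.size < 4:
        raise ValueError("competition fitting needs at least 4 competitor concentrations")
    s0 = series.s_total_nM
    measured = series.free_nM
    kd0 = float(np.median(s0[s0 > 0])) if np.any(s0 > 0) else 1.0

    if fit_a0:
        def residuals(logp):
            kd, a0 = np.exp(logp)
            return solution_free_analyte(a0, s0, kd) - measured
        x0 = np.log([kd0, series.a_total_nM])
    else:
        def residuals(logp):
            (kd,) = np.exp(logp)
            return solution_free_analyte(series.a_total_nM, s0, kd) - measured
        x0 = np.log([kd0])

    sol = least_squares(residuals, x0=x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if fit_a0:
        kd, a0 = np.exp(sol.x)
    else:
        (kd,), a0 = np.exp(sol.x), series.a_total_nM
    positive = s0[s0 > 0]
    ill = bool(positive.size == 0 or kd < positive.min() / 10 or kd > positive.max() * 10)
    return SolutionAffinityFit(kd_nM=float(kd), a_total_nM=float(a0),
                               residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
                               ill_conditioned=ill)
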