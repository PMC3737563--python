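"""1:1 Langmuir binding: kinetic cycle simulation and steady-state K_D fits.

Kinetics exist only to synthesise realistic sensorgrams; affinities are
estimated exclusively from the steady-state isotherm
R_eq = Rmax * C / (K_D + C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError
from .sensorgram import SensorgramCycle

__all__ = [
    "CONCENTRATION_SERIES_M",
    "KineticParams",
    "InjectionSchedule",
    "AffinityFit",
    "steady_state_response",
    "simulate_cycle",
    "fit_kd",
]

# Default protein concentration series for affinity experiments (molar):
# a two-fold dilution ladder from 50 nM down to 0.39 nM.
CONCENTRATION_SERIES_M = tuple(
    c * 1e-9 for c in (0.39, 0.78, 1.56, 3.13, 6.25, 12.5, 25.0, 50.0)
)


@dataclass(frozen=True)
class KineticParams:
    """1:1 rate constants plus the saturation response."""

    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # RU

    def __post_init__(self):
        if self.ka <= 0:
            raise ParameterError("ka must be positive")
        if self.kd < 0:
            raise ParameterError("kd must be non-negative")
        if self.rmax <= 0:
            raise ParameterError("rmax must be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant kd/ka (M)."""
        return self.kd / self.ka


@dataclass(frozen=True)
class InjectionSchedule:
    """Timing of one protein injection cycle (seconds).

    ``salt_washes`` are (start, end, removal_fraction) triples applied after
    the dissociation window; each wash instantaneously removes the stated
    fraction of the protein still bound.  ``strip_at`` returns the trace to
    baseline (surface regeneration).
    """

    concentration: float  # M
    t_on: float
    t_off: float
    t_end: float  # end of dissociation
    salt_washes: tuple[tuple[float, float, float], ...] = ()
    strip_at: float | None = None
    capture_response: float = 0.0  # plateau from the captured duplex itself
    capture_window: tuple[float, float] | None = None
    wash_window: tuple[float, float] | None = None

    def __post_init__(self):
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")
        if not (self.t_on < self.t_off < self.t_end):
            raise ParameterError("need t_on < t_off < t_end")
        for t0, t1, frac in self.salt_washes:
            if t0 < self.t_end or t1 < t0:
                raise ParameterError("salt washes must follow the dissociation window")
            if not 0 <= frac <= 1:
                raise ParameterError("salt-wash removal fraction must be in [0, 1]")


@dataclass(frozen=True)
class AffinityFit:
    """Result of the steady-state 1:1 fit."""

    kd_M: float
    rmax_ru: float
    se_kd_M: float
    se_rmax_ru: float
    residual_ss: float
    n_points: int
    converged: bool

    @property
    def kd_nM(self) -> float:
        return self.kd_M * 1e9


def steady_state_response(concentration: float, kd_M: float, rmax: float) -> float:
    """Equilibrium response of the 1:1 model: Rmax * C / (K_D + C)."""
    if kd_M <= 0:
        raise ParameterError("K_D must be positive")
    if concentration < 0:
        raise ParameterError("concentration must be >= 0")
    return rmax * concentration / (kd_M + concentration)


def simulate_cycle(
    params: KineticParams,
    schedule: InjectionSchedule,
    *,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 1.0,
    cycle_id: str = "sim",
    flow_cell: str = "FC_test",
) -> SensorgramCycle:
    """Synthesise one cycle of 1:1 binding kinetics.

    Association follows R(t) = R_eq (1 - exp(-(ka C + kd)(t - t_on))) with
    R_eq = ka C Rmax / (ka C + kd); dissociation decays exponentially with
    rate kd; each salt wash instantaneously removes its removal fraction of
    the remaining protein (decay continues through the wash); the strip
    returns the trace to baseline.  If ``capture_response`` is set, the
    captured-duplex plateau is present from the capture window until the
    strip, and the protein signal rides on top of it.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if dt <= 0:
        raise ParameterError("dt must be positive")

    t_start = 0.0
    if schedule.capture_window is not None:
        t_start = min(t_start, schedule.capture_window[0])
    stop = schedule.strip_at if schedule.strip_at is not None else None
    t_last = max(
        [schedule.t_end]
        + [t1 for _, t1, _ in schedule.salt_washes]
        + ([stop + 10.0] if stop is not None else [])
    )
    times = np.arange(t_start, t_last + dt / 2, dt)

    ka_c = params.ka * schedule.concentration
    k_obs = ka_c + params.kd
    r_eq = params.rmax * ka_c / k_obs if k_obs > 0 else 0.0

    protein = np.zeros_like(times)
    assoc = (times >= schedule.t_on) & (times <= schedule.t_off)
    if k_obs > 0:
        protein[assoc] = r_eq * (1.0 - np.exp(-k_obs * (times[assoc] - schedule.t_on)))
        r_off = r_eq * (1.0 - np.exp(-k_obs * (schedule.t_off - schedule.t_on)))
    else:
        r_off = 0.0
    after = times > schedule.t_off
    protein[after] = r_off * np.exp(-params.kd * (times[after] - schedule.t_off))
    for t0, _t1, frac in schedule.salt_washes:
        protein[times >= t0] *= 1.0 - frac

    capture = np.zeros_like(times)
    if schedule.capture_response:
        c_on = schedule.capture_window[0] if schedule.capture_window else t_start
        capture[times >= c_on] = schedule.capture_response

    signal = capture + protein
    if stop is not None:
        signal[times >= stop] = 0.0

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    phases: dict[str, tuple[float, float]] = {}
    if schedule.capture_window is not None:
        phases["capture"] = schedule.capture_window
    if schedule.wash_window is not None:
        phases["wash"] = schedule.wash_window
    phases["association"] = (schedule.t_on, schedule.t_off)
    phases["dissociation"] = (schedule.t_off, schedule.t_end)
    for i, (t0, t1, _f) in enumerate(schedule.salt_washes, start=1):
        phases[f"salt_wash_{i}"] = (t0, t1)
    if stop is not None:
        phases["strip"] = (stop, times[-1])

    return SensorgramCycle(
        cycle_id=cycle_id,
        flow_cell=flow_cell,
        times=times,
        responses=signal,
        phases=phases,
    )


def fit_kd(points: Sequence[tuple[float, float]]) -> AffinityFit:
    """Unweighted nonlinear least-squares fit of the steady-state isotherm
    R = Rmax C / (K_D + C) to (concentration [M], response [RU]) pairs.

    Replicates are fitted pooled.  Initialisation: Rmax0 = max(R), K_D0 = the
    concentration whose response is nearest to half of Rmax0.  Standard
    errors come from the Jacobian at the optimum.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ParameterError("need at least 3 (concentration, response) points")
    conc, resp = pts[:, 0], pts[:, 1]
    if np.any(conc < 0):
        raise ParameterError("concentrations must be >= 0")
    distinct = np.unique(conc)
    if distinct.size < 3:
        raise ParameterError("need responses at >= 3 distinct concentrations")

    rmax0 = float(np.max(resp))
    if rmax0 <= 0:
        raise FitError("all responses are non-positive; nothing to fit")
    kd0 = float(conc[np.argmin(np.abs(resp - rmax0 / 2.0))])
    if kd0 <= 0:
        kd0 = float(np.min(distinct[distinct > 0]))

    # Rescale concentrations to O(1) so both parameters share a scale;
    # nanomolar K_D against RU-sized Rmax otherwise stalls the optimizer.
    c_scale = float(np.median(distinct[distinct > 0]))
    conc_s = conc / c_scale

    def model(c, rmax, kd):
        return rmax * c / (kd + c)

    try:
        popt, pcov = curve_fit(
            model,
            conc_s,
            resp,
            p0=(rmax0, kd0 / c_scale),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"steady-state fit did not converge: {exc}") from exc

    rmax_hat, kd_hat = float(popt[0]), float(popt[1]) * c_scale
    perr = np.sqrt(np.diag(pcov))
    se_rmax, se_kd = float(perr[0]), float(perr[1]) * c_scale
    residuals = resp - model(conc_s, *popt)
    rss = float(np.sum(residuals**2))

    converged = bool(
        np.isfinite(kd_hat)
        and np.isfinite(se_kd)
        and kd_hat > float(np.min(distinct[distinct > 0])) * 1e-6
    )
    if converged and not (distinct.min() <= kd_hat <= distinct.max()):
        warnings.warn(
            f"fitted K_D {kd_hat:.3g} M lies outside the sampled concentration "
            "range; the series does not span the inflection",
            stacklevel=2,
        )
    return AffinityFit(
        kd_M=kd_hat,
        rmax_ru=rmax_hat,
        se_kd_M=se_kd,
        se_rmax_ru=se_rmax,
        residual_ss=rss,
        n_points=int(pts.shape[0]),
        converged=converged,
    )
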