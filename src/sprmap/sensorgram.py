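"""Sensorgram cycles, double referencing, report points and normalisation.

A cycle is one pass of the reusable-capture workflow: capture of the test
duplex, a stabilisation wash, protein association, dissociation, up to two
salt washes, and a strip that regenerates the surface.  Report points are
read off the (optionally double-referenced) trace at fixed offsets relative
to the phase boundaries, then expressed as a percentage of the theoretical
maximum response so that different capture levels and duplex lengths are
directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .errors import ParameterError, PhaseError

__all__ = [
    "PHASE_ORDER",
    "SensorgramCycle",
    "ReportConvention",
    "SCREENING",
    "AFFINITY",
    "ReportPoints",
    "RetentionFractions",
    "RmaxSpec",
    "double_reference",
    "extract_report_points",
    "theoretical_rmax",
    "normalize_response",
    "retention_fractions",
]

PHASE_ORDER = (
    "capture",
    "wash",
    "association",
    "dissociation",
    "salt_wash_1",
    "salt_wash_2",
    "strip",
)


@dataclass
class SensorgramCycle:
    """Time/response trace for one cycle in one flow cell, with named phase
    windows (seconds, [start, end])."""

    cycle_id: str
    flow_cell: str  # "FC_ref" or "FC_test"
    times: np.ndarray
    responses: np.ndarray
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.responses.shape:
            raise ParameterError("times and responses must be 1-D and equal length")
        if self.times.size < 2:
            raise ParameterError("a cycle needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        known = [p for p in PHASE_ORDER if p in self.phases]
        unknown = set(self.phases) - set(PHASE_ORDER)
        if unknown:
            raise PhaseError(f"unknown phase name(s): {sorted(unknown)}")
        prev_end, prev_name = None, None
        for name in known:
            t0, t1 = self.phases[name]
            if t1 < t0:
                raise PhaseError(f"phase {name!r} window [{t0}, {t1}] is reversed")
            if prev_end is not None and t0 < prev_end:
                raise PhaseError(
                    f"phase {name!r} overlaps or precedes phase {prev_name!r}"
                )
            prev_end, prev_name = t1, name

    def value_at(self, t: float, *, phase: str = "?") -> float:
        """Linearly interpolated response at time ``t``; error if outside."""
        if t < self.times[0] or t > self.times[-1]:
            raise PhaseError(
                f"report time {t:g} s for phase {phase!r} lies outside the "
                f"sampled range [{self.times[0]:g}, {self.times[-1]:g}] s "
                f"of cycle {self.cycle_id!r}"
            )
        return float(np.interp(t, self.times, self.responses))


@dataclass(frozen=True)
class ReportConvention:
    """Where the binding report point is read relative to the end of the
    protein injection: +10 s (screening) or -4 s (affinity)."""

    mode: str
    offset_s: float

    def __post_init__(self):
        if self.mode not in ("screening", "affinity"):
            raise ParameterError(f"unknown report mode {self.mode!r}")


SCREENING = ReportConvention("screening", +10.0)
AFFINITY = ReportConvention("affinity", -4.0)


@dataclass(frozen=True)
class ReportPoints:
    """Raw report-point responses (RU) for one cycle."""

    cycle_id: str
    capture_ru: float | None
    bind_ru: float
    dissoc_ru: float | None = None
    salt1_ru: float | None = None
    salt2_ru: float | None = None


@dataclass(frozen=True)
class RetentionFractions:
    """Fraction of the bound protein still present after dissociation and
    after each salt wash, as percentages of the binding report point."""

    retained_dissoc_pct: float
    retained_salt1_pct: float | None
    retained_salt2_pct: float | None
    valid: bool = True


@dataclass(frozen=True)
class RmaxSpec:
    """Inputs for the theoretical maximum response: analyte (protein dimer)
    and ligand (captured duplex, incl. overhang) masses, captured level, and
    analyte:ligand stoichiometry."""

    mw_analyte: float
    mw_ligand: float
    captured_response: float
    stoichiometry: float = 1.0

    def __post_init__(self):
        for name in ("mw_analyte", "mw_ligand", "captured_response", "stoichiometry"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def double_reference(
    test: SensorgramCycle,
    ref: SensorgramCycle,
    buffer_test: SensorgramCycle,
    buffer_ref: SensorgramCycle,
) -> SensorgramCycle:
    """Classic double referencing:
    corrected(t) = [test - ref](t) - [buffer_test - buffer_ref](t).

    All four traces are interpolated onto the test cycle's time grid,
    restricted to the overlap of all four time ranges.  Negative corrected
    responses are retained.
    """
    cycles = (test, ref, buffer_test, buffer_ref)
    t0 = max(c.times[0] for c in cycles)
    t1 = min(c.times[-1] for c in cycles)
    if t0 >= t1:
        raise ParameterError("cycles do not share an overlapping time range")
    grid = test.times[(test.times >= t0) & (test.times <= t1)]
    vals = [np.interp(grid, c.times, c.responses) for c in cycles]
    corrected = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return SensorgramCycle(
        cycle_id=f"{test.cycle_id}_corr",
        flow_cell=test.flow_cell,
        times=grid,
        responses=corrected,
        phases=dict(test.phases),
    )


def extract_report_points(
    cycle: SensorgramCycle, convention: ReportConvention
) -> ReportPoints:
    """Read the standard report points off one cycle.

    * capture: end of the post-capture wash window (falls back to the end of
      the capture window if no wash is recorded);
    * binding: end of the association window plus the convention's offset;
    * dissociation / salt washes: end of the respective windows.

    Lookups use linear interpolation between samples.
    """
    phases = cycle.phases
    if "association" not in phases:
        raise PhaseError(f"cycle {cycle.cycle_id!r} has no association phase")
    t_bind = phases["association"][1] + convention.offset_s
    bind = cycle.value_at(t_bind, phase="association")

    capture = None
    for name in ("wash", "capture"):
        if name in phases:
            capture = cycle.value_at(phases[name][1], phase=name)
            break

    def _end(name):
        if name not in phases:
            return None
        return cycle.value_at(phases[name][1], phase=name)

    return ReportPoints(
        cycle_id=cycle.cycle_id,
        capture_ru=capture,
        bind_ru=bind,
        dissoc_ru=_end("dissociation"),
        salt1_ru=_end("salt_wash_1"),
        salt2_ru=_end("salt_wash_2"),
    )


def theoretical_rmax(spec: RmaxSpec) -> float:
    """R_max = (MW_analyte / MW_ligand) x captured response x stoichiometry."""
    return (
        spec.mw_analyte / spec.mw_ligand
    ) * spec.captured_response * spec.stoichiometry


def normalize_response(bind_ru: float, rmax: float) -> float:
    """Express a binding response as a percentage of the theoretical maximum.
    Values above 100% are allowed (super-stoichiometric signal) but warned."""
    if rmax <= 0:
        raise ParameterError(f"rmax must be positive, got {rmax}")
    pct = 100.0 * bind_ru / rmax
    if pct > 100.0:
        warnings.warn(
            f"normalized response {pct:.1f}% exceeds the theoretical maximum",
            stacklevel=2,
        )
    return pct


def retention_fractions(points: ReportPoints, *, baseline_ru: float = 0.0) -> RetentionFractions:
    """Fractions of bound protein retained after dissociation and after each
    salt wash, relative to the binding report point.

    ``baseline_ru`` (e.g. the captured-DNA level for uncorrected traces) is
    subtracted from every report point before taking ratios.
    """
    bind = points.bind_ru - baseline_ru
    if bind == 0:
        warnings.warn(
            f"cycle {points.cycle_id!r}: binding response is zero; retention "
            "fractions undefined",
            stacklevel=2,
        )
        return RetentionFractions(float("nan"), float("nan"), float("nan"), valid=False)
    if points.dissoc_ru is None:
        raise PhaseError(f"cycle {points.cycle_id!r} has no dissociation report point")

    def _pct(value):
        if value is None:
            return None
        return 100.0 * (value - baseline_ru) / bind

    return RetentionFractions(
        retained_dissoc_pct=_pct(points.dissoc_ru),
        retained_salt1_pct=_pct(points.salt1_ru),
        retained_salt2_pct=_pct(points.salt2_ru),
    )
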