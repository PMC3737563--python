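"""From normalized responses to binding-site calls.

Screening hits are tiles reaching (approximately) the theoretical maximum
response at the top protein concentration; consecutive hits merge into a
starting oligomer for footprinting; truncation-series metrics (normalized
maximum response plus dissociation/salt-wash retention) then place each
boundary at the resolution of the truncation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ParameterError
from .seqdesign import OligoDuplex, TilingPanel, apply_footprint

__all__ = [
    "ScreeningResult",
    "TruncationMetrics",
    "MemberMetrics",
    "BoundaryCall",
    "call_hits",
    "merge_adjacent_hits",
    "call_boundary",
    "assemble_footprint",
]

DEFAULT_CONCENTRATIONS_M = (10e-9, 50e-9, 100e-9)


@dataclass(frozen=True)
class ScreeningResult:
    """Percent-of-Rmax per fragment per protein concentration.

    ``responses`` maps fragment name -> {concentration [M] -> %Rmax};
    ``fragment_order`` preserves the panel ordering by region_start.
    """

    concentrations: tuple[float, ...]
    fragment_order: tuple[str, ...]
    responses: Mapping[str, Mapping[float, float]]

    def __post_init__(self):
        if tuple(sorted(self.concentrations)) != tuple(self.concentrations):
            raise ParameterError("concentrations must be sorted ascending")
        for name in self.fragment_order:
            if name not in self.responses:
                raise ParameterError(f"no responses recorded for fragment {name!r}")


@dataclass(frozen=True)
class MemberMetrics:
    """Metrics for one truncation-series member."""

    delta: int
    norm_max_pct: float
    retained_dissoc_pct: float
    retained_salt1_pct: float
    retained_salt2_pct: float


@dataclass(frozen=True)
class TruncationMetrics:
    """Per-member metrics for one boundary's truncation series, ascending in
    delta; delta = 0 is the untruncated reference."""

    side: str
    members: tuple[MemberMetrics, ...]

    def __post_init__(self):
        deltas = [m.delta for m in self.members]
        if deltas != sorted(deltas):
            raise ParameterError("members must be ordered by ascending delta")
        if len(set(deltas)) != len(deltas):
            raise ParameterError("duplicate deltas in truncation metrics")

    def member(self, delta: int) -> MemberMetrics:
        for m in self.members:
            if m.delta == delta:
                return m
        raise KeyError(f"no member with delta {delta}")


@dataclass(frozen=True)
class BoundaryCall:
    """The chosen truncation for one footprint boundary, with the per-metric
    pass/fail record for every member."""

    side: str
    chosen_delta: int
    resolution: int
    rationale: tuple[dict, ...] = field(default_factory=tuple)


def call_hits(
    result: ScreeningResult,
    top_concentration: float | None = None,
    threshold_pct: float = 90.0,
) -> list[str]:
    """Fragments whose %Rmax at the top concentration meets the hit
    threshold (operationalising "approximately 100% of theoretical Rmax")."""
    top = top_concentration if top_concentration is not None else result.concentrations[-1]
    if top not in result.concentrations:
        raise ParameterError(
            f"concentration {top!r} not present in the screening result "
            f"(have {list(result.concentrations)})"
        )
    hits = []
    for name in result.fragment_order:
        per_conc = result.responses[name]
        if top not in per_conc:
            raise ParameterError(f"fragment {name!r} has no response at {top!r}")
        if per_conc[top] >= threshold_pct:
            hits.append(name)
    return hits


def merge_adjacent_hits(
    hits: Sequence[str], panel: TilingPanel, region: str
) -> list[OligoDuplex]:
    """Merge each run of consecutive hit fragments into one duplex spanning
    from the first hit's start to the last hit's end.  Non-consecutive runs
    are independent sites and yield separate duplexes."""
    if not hits:
        raise ParameterError("empty hit list")
    index = {f.name: i for i, f in enumerate(panel.fragments)}
    for h in hits:
        if h not in index:
            raise ParameterError(f"hit {h!r} is not a fragment of the panel")
    positions = sorted(index[h] for h in hits)

    runs: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])

    merged = []
    for run in runs:
        first = panel.fragments[run[0]]
        last = panel.fragments[run[-1]]
        start, end = first.region_start, last.region_end
        merged.append(
            OligoDuplex(
                name=f"{first.name}-{last.name}" if len(run) > 1 else first.name,
                forward=region[start - 1 : end].upper(),
                region_start=start,
                region_end=end,
            )
        )
    return merged


def call_boundary(
    metrics: TruncationMetrics,
    *,
    tol_response_pct: float = 10.0,
    tol_retention_pts: float = 10.0,
) -> BoundaryCall:
    """Choose the largest truncation that still behaves like the untruncated
    reference.

    A member passes when its normalized maximum response is at least
    (100 - tol_response_pct)% of the reference's, AND each retention metric
    (dissociation, salt wash 1, salt wash 2) is within tol_retention_pts
    percentage points of the reference.  The chosen delta is the largest
    passing one; every member's per-metric verdicts are recorded.
    """
    try:
        ref = metrics.member(0)
    except KeyError:
        raise ParameterError("truncation metrics must include the delta=0 reference")
    if ref.norm_max_pct < 50.0:
        raise ParameterError(
            f"reference member fails QC: norm_max {ref.norm_max_pct:.1f}% < 50%"
        )

    floor = ref.norm_max_pct * (100.0 - tol_response_pct) / 100.0
    rationale = []
    chosen = 0
    step = metrics.members[1].delta - metrics.members[0].delta if len(metrics.members) > 1 else 0
    for m in metrics.members:
        verdict = {
            "delta": m.delta,
            "norm_max_ok": m.norm_max_pct >= floor,
            "dissoc_ok": abs(m.retained_dissoc_pct - ref.retained_dissoc_pct)
            <= tol_retention_pts,
            "salt1_ok": abs(m.retained_salt1_pct - ref.retained_salt1_pct)
            <= tol_retention_pts,
            "salt2_ok": abs(m.retained_salt2_pct - ref.retained_salt2_pct)
            <= tol_retention_pts,
        }
        verdict["pass"] = all(
            verdict[k] for k in ("norm_max_ok", "dissoc_ok", "salt1_ok", "salt2_ok")
        )
        rationale.append(verdict)
        if verdict["pass"] and m.delta > chosen:
            chosen = m.delta

    return BoundaryCall(
        side=metrics.side,
        chosen_delta=chosen,
        resolution=step,
        rationale=tuple(rationale),
    )


def assemble_footprint(
    start: OligoDuplex, rh: BoundaryCall, lh: BoundaryCall
) -> OligoDuplex:
    """Apply both boundary calls to the starting oligomer."""
    if rh.side != "RH" or lh.side != "LH":
        raise ParameterError("assemble_footprint needs one RH call and one LH call")
    return apply_footprint(start, rh.chosen_delta, lh.chosen_delta)
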