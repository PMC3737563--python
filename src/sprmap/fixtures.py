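"""Seeded in-silico experiments with known ground truth.

Every analysis stage of the toolkit can be exercised without instrument data:
screening experiments plant binding sites in a synthetic region and tile it;
truncation experiments encode a known boundary by degrading kinetics once the
truncations cut into the site; affinity datasets are noisy draws from the
steady-state isotherm.  Bundles regenerate byte-identically from
(parameters, seed).

The partial-containment response model is a fixture convention, not a claim
about SPR physics: a tile containing fraction f of a site responds with
scale 0 for f < min_containment and (f - min_containment)/(1 - min_containment)
above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .binding import (
    CONCENTRATION_SERIES_M,
    InjectionSchedule,
    KineticParams,
    simulate_cycle,
    steady_state_response,
)
from .errors import ParameterError
from .footprint import (
    MemberMetrics,
    ScreeningResult,
    TruncationMetrics,
)
from .seqdesign import (
    LinkerSpec,
    OligoDuplex,
    TilingPanel,
    TruncationSeries,
    attach_linker,
    dna_mw,
    make_truncation_series,
    tile_region,
    validate_dna,
)
from .sensorgram import (
    AFFINITY,
    SCREENING,
    RmaxSpec,
    SensorgramCycle,
    extract_report_points,
    normalize_response,
    retention_fractions,
    theoretical_rmax,
)

__all__ = [
    "PlantedSite",
    "ExperimentBundle",
    "generate_screening_experiment",
    "generate_truncation_experiment",
    "generate_affinity_dataset",
    "screening_result",
    "truncation_metrics",
    "DEFAULT_MW_ANALYTE",
]

# Protein dimer mass used throughout the fixtures (2 x 20523 Da).
DEFAULT_MW_ANALYTE = 41046.0

# Canonical cycle timing (seconds).
CAPTURE_WINDOW = (0.0, 60.0)
WASH_WINDOW = (60.0, 120.0)
T_ON, T_OFF = 120.0, 300.0
T_DISS_END = 600.0
SALT1_WINDOW = (600.0, 630.0)
SALT2_WINDOW = (630.0, 660.0)
STRIP_AT = 700.0

# Default fixture kinetics: K_D = kd/ka = 1.3 nM with slow dissociation.
DEFAULT_KA = 3.85e5  # 1/(M s)
DEFAULT_KD_RATE = 5.0e-4  # 1/s


@dataclass(frozen=True)
class PlantedSite:
    """A binding site planted at a known location in a synthetic region."""

    name: str
    start: int  # 1-based on the region's forward strand
    length: int = 22
    ka: float = DEFAULT_KA
    kd: float = DEFAULT_KD_RATE
    min_containment: float = 0.6

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def containment_scale(self, frag_start: int, frag_end: int) -> float:
        """Response scale for a fragment covering [frag_start, frag_end]."""
        overlap = min(frag_end, self.end) - max(frag_start, self.start) + 1
        frac = max(overlap, 0) / self.length
        if frac < self.min_containment:
            return 0.0
        return (frac - self.min_containment) / (1.0 - self.min_containment)


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment produced, plus its ground truth."""

    kind: str  # "screening" | "truncation" | "affinity"
    seed: int
    truth: dict
    panel: TilingPanel | TruncationSeries | None = None
    cycles: list[SensorgramCycle] = field(default_factory=list)
    manifest: list[dict] = field(default_factory=list)  # per-cycle metadata
    region: str | None = None
    points: pd.DataFrame | None = None
    mw_analyte: float = DEFAULT_MW_ANALYTE
    duplexes: dict[str, OligoDuplex] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> list[Path]:
        """Emit the full plain-text file set; byte-identical per seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _add(path):
            written.append(path)
            return path

        if self.region:
            _io.write_fasta(_add(outdir / "region.fasta"), [("region", self.region)])
        if self.kind == "screening" and self.duplexes:
            # export the captured species (core + overhang), not the bare tiles,
            # so downstream mass-based normalisation sees what the chip sees
            _io.write_panel_tsv(_add(outdir / "panel.tsv"), list(self.duplexes.values()))
        elif self.panel is not None:
            _io.write_panel_tsv(_add(outdir / "panel.tsv"), self.panel)
        if self.cycles:
            _io.write_sensorgram_csv(_add(outdir / "sensorgram.csv"), self.cycles)
            _io.write_phases(_add(outdir / "phases.yaml"), self.cycles)
        if self.points is not None:
            self.points.to_csv(
                _add(outdir / "points.csv"), index=False, float_format="%.6f"
            )
        with open(_add(outdir / "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return written


def _cycle_id(name: str, conc_M: float) -> str:
    return f"{name}@{conc_M * 1e9:g}nM"


def _simulate_test_cycle(
    *,
    cycle_id: str,
    ka: float,
    kd: float,
    rmax: float,
    conc_M: float,
    capture_response: float,
    salt_removal: tuple[float, float],
    noise_sd: float,
    rng_seed,
) -> SensorgramCycle:
    schedule = InjectionSchedule(
        concentration=conc_M,
        t_on=T_ON,
        t_off=T_OFF,
        t_end=T_DISS_END,
        salt_washes=(
            (*SALT1_WINDOW, salt_removal[0]),
            (*SALT2_WINDOW, salt_removal[1]),
        ),
        strip_at=STRIP_AT,
        capture_response=capture_response,
        capture_window=CAPTURE_WINDOW,
        wash_window=WASH_WINDOW,
    )
    # rmax can be zero (no site in the fragment): simulate flat baseline.
    params = KineticParams(ka=ka, kd=kd, rmax=max(rmax, 1e-12))
    return simulate_cycle(
        params,
        schedule,
        noise_sd=noise_sd,
        seed=rng_seed,
        cycle_id=cycle_id,
    )


def generate_screening_experiment(
    region: str,
    sites: list[PlantedSite],
    *,
    fragment_length: int = 29,
    site_length: int = 22,
    concentrations: tuple[float, ...] = (10e-9, 50e-9, 100e-9),
    noise_sd: float = 1.0,
    seed: int = 0,
    capture_response: float = 400.0,
    mw_analyte: float = DEFAULT_MW_ANALYTE,
    linker: LinkerSpec | None = None,
) -> ExperimentBundle:
    """Tile ``region``, then synthesise one test cycle per (fragment,
    concentration) with 1:1 kinetics scaled by site containment."""
    region = validate_dna(region, context="region")
    linker = linker or LinkerSpec()
    for s in sites:
        if s.start < 1 or s.end > len(region):
            raise ParameterError(f"site {s.name} extends outside the region")
    ordered = sorted(sites, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ParameterError(f"sites {a.name} and {b.name} overlap")

    panel = tile_region(region, fragment_length, site_length)
    captured = {
        f.name: attach_linker(f, linker, "reverse_3prime") for f in panel.fragments
    }

    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(panel.fragments) * len(concentrations)))

    cycles, manifest = [], []
    true_hits = []
    for frag in panel.fragments:
        dup = captured[frag.name]
        rmax_frag = theoretical_rmax(
            RmaxSpec(mw_analyte, dna_mw(dup), capture_response)
        )
        scale = 0.0
        site_kin = (DEFAULT_KA, DEFAULT_KD_RATE)
        for s in sites:
            sc = s.containment_scale(frag.region_start, frag.region_end)
            if sc > scale:
                scale, site_kin = sc, (s.ka, s.kd)
        fully = any(
            frag.region_start <= s.start and s.end <= frag.region_end for s in sites
        )
        if fully:
            true_hits.append(frag.name)
        for conc in concentrations:
            cid = _cycle_id(frag.name, conc)
            cycles.append(
                _simulate_test_cycle(
                    cycle_id=cid,
                    ka=site_kin[0],
                    kd=site_kin[1],
                    rmax=rmax_frag * scale,
                    conc_M=conc,
                    capture_response=capture_response,
                    salt_removal=(0.2, 0.2),
                    noise_sd=noise_sd,
                    rng_seed=next(children),
                )
            )
            manifest.append(
                {"cycle": cid, "fragment": frag.name, "conc_M": conc}
            )

    truth = {
        "kind": "screening",
        "seed": seed,
        "sites": [
            {"name": s.name, "start": s.start, "end": s.end, "KD_M": s.kd / s.ka}
            for s in ordered
        ],
        "true_hit_fragments": true_hits,
        "containment_model": "0 below min_containment, linear ramp to 1 at full containment",
        "noise_sd": noise_sd,
    }
    return ExperimentBundle(
        kind="screening",
        seed=seed,
        truth=truth,
        panel=panel,
        cycles=cycles,
        manifest=manifest,
        region=region,
        mw_analyte=mw_analyte,
        duplexes=captured,
    )


def generate_truncation_experiment(
    start: OligoDuplex,
    side: str,
    true_delta: int,
    *,
    step: int = 2,
    max_delta: int,
    ka: float = DEFAULT_KA,
    kd: float = DEFAULT_KD_RATE,
    kd_factor: float = 3.0,
    salt_increment: float = 0.25,
    base_salt_removal: tuple[float, float] = (0.2, 0.2),
    concentration: float = 100e-9,
    noise_sd: float = 0.5,
    seed: int = 0,
    capture_response: float = 400.0,
    mw_analyte: float = DEFAULT_MW_ANALYTE,
    linker: LinkerSpec | None = None,
) -> ExperimentBundle:
    """Synthesise one boundary's truncation series.

    Members with delta <= ``true_delta`` share the reference kinetics; each
    truncation step beyond the boundary multiplies the dissociation rate by
    ``kd_factor`` and raises both salt-wash removal fractions by
    ``salt_increment`` (capped at 0.98).
    """
    if not 0 <= true_delta <= max_delta:
        raise ParameterError("true_delta must lie within the series range")
    series = make_truncation_series(
        start, side, step=step, max_delta=max_delta, linker=linker
    )
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(series.members)))

    cycles, manifest = [], []
    for delta, dup in series.members:
        steps_beyond = max(0, delta - true_delta) / step
        kd_member = kd * (kd_factor**steps_beyond)
        removal = tuple(
            min(0.98, r + salt_increment * steps_beyond) for r in base_salt_removal
        )
        rmax_member = theoretical_rmax(
            RmaxSpec(mw_analyte, dna_mw(dup), capture_response)
        )
        cid = _cycle_id(dup.name, concentration)
        cycles.append(
            _simulate_test_cycle(
                cycle_id=cid,
                ka=ka,
                kd=kd_member,
                rmax=rmax_member,
                conc_M=concentration,
                capture_response=capture_response,
                salt_removal=removal,
                noise_sd=noise_sd,
                rng_seed=next(children),
            )
        )
        manifest.append({"cycle": cid, "delta": delta, "conc_M": concentration})

    truth = {
        "kind": "truncation",
        "seed": seed,
        "side": side,
        "true_delta": true_delta,
        "step": step,
        "kd_factor": kd_factor,
        "salt_increment": salt_increment,
        "noise_sd": noise_sd,
    }
    return ExperimentBundle(
        kind="truncation",
        seed=seed,
        truth=truth,
        panel=series,
        cycles=cycles,
        manifest=manifest,
        mw_analyte=mw_analyte,
        duplexes={dup.name: dup for _, dup in series.members},
    )


def generate_affinity_dataset(
    kd_M: float,
    rmax: float,
    *,
    concentrations: tuple[float, ...] = CONCENTRATION_SERIES_M,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy steady-state responses, replicated, as a CLI-ready table with
    columns conc_nM, replicate, response_ru."""
    if kd_M <= 0 or rmax <= 0:
        raise ParameterError("kd_M and rmax must be positive")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        for rep in range(1, replicates + 1):
            r = steady_state_response(conc, kd_M, rmax)
            if noise_sd > 0:
                r += rng.normal(0.0, noise_sd)
            rows.append(
                {"conc_nM": conc * 1e9, "replicate": rep, "response_ru": r}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle analysis helpers (used by the round-trip tests and the CLI)
# ---------------------------------------------------------------------------

def _protein_points(cycle: SensorgramCycle, convention):
    """Report points referenced to the captured-DNA plateau."""
    pts = extract_report_points(cycle, convention)
    baseline = pts.capture_ru if pts.capture_ru is not None else 0.0
    return pts, baseline


def screening_result(bundle: ExperimentBundle) -> ScreeningResult:
    """Normalize every screening cycle to %Rmax and tabulate per fragment."""
    if bundle.kind != "screening":
        raise ParameterError("bundle is not a screening experiment")
    by_id = {c.cycle_id: c for c in bundle.cycles}
    responses: dict[str, dict[float, float]] = {}
    concs = sorted({m["conc_M"] for m in bundle.manifest})
    for m in bundle.manifest:
        cycle = by_id[m["cycle"]]
        dup = bundle.duplexes[m["fragment"]]
        pts, baseline = _protein_points(cycle, SCREENING)
        rmax = theoretical_rmax(
            RmaxSpec(bundle.mw_analyte, dna_mw(dup), baseline)
        )
        with np.errstate(all="ignore"):
            pct = normalize_response(pts.bind_ru - baseline, rmax)
        responses.setdefault(m["fragment"], {})[m["conc_M"]] = pct
    order = tuple(f.name for f in bundle.panel.fragments)
    return ScreeningResult(
        concentrations=tuple(concs), fragment_order=order, responses=responses
    )


def truncation_metrics(bundle: ExperimentBundle) -> TruncationMetrics:
    """Per-member normalized response and retention metrics."""
    if bundle.kind != "truncation":
        raise ParameterError("bundle is not a truncation experiment")
    by_id = {c.cycle_id: c for c in bundle.cycles}
    members = []
    for m in sorted(bundle.manifest, key=lambda d: d["delta"]):
        cycle = by_id[m["cycle"]]
        delta = m["delta"]
        dup_name = cycle.cycle_id.split("@")[0]
        dup = bundle.duplexes[dup_name]
        pts, baseline = _protein_points(cycle, SCREENING)
        rmax = theoretical_rmax(
            RmaxSpec(bundle.mw_analyte, dna_mw(dup), baseline)
        )
        pct = normalize_response(pts.bind_ru - baseline, rmax)
        ret = retention_fractions(pts, baseline_ru=baseline)
        members.append(
            MemberMetrics(
                delta=delta,
                norm_max_pct=pct,
                retained_dissoc_pct=ret.retained_dissoc_pct,
                retained_salt1_pct=ret.retained_salt1_pct,
                retained_salt2_pct=ret.retained_salt2_pct,
            )
        )
    return TruncationMetrics(side=bundle.truth["side"], members=tuple(members))
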