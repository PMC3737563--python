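"""File formats: FASTA, panel TSV, sensorgram CSV + phase sidecar, BED/GFF3.

The sensorgram CSV dialect is fixed: header ``cycle,flow_cell,time_s,
response_ru``, one sample per row.  Phase windows travel in a JSON or YAML
sidecar mapping cycle id -> {phase: [t0, t1]}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FeatureParseError, ParameterError
from .motif import Feature, MotifHit
from .seqdesign import OligoDuplex, TilingPanel, TruncationSeries
from .sensorgram import SensorgramCycle

SENSORGRAM_HEADER = ["cycle", "flow_cell", "time_s", "response_ru"]

PANEL_COLUMNS = [
    "name",
    "forward_5to3",
    "reverse_5to3",
    "overhang_host",
    "region_start",
    "region_end",
    "delta",
    "side",
]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs from a FASTA file."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParameterError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# -- Oligomer panels --------------------------------------------------------

def _duplex_row(d: OligoDuplex, delta: int | None = None, side: str = "") -> dict:
    return {
        "name": d.name,
        "forward_5to3": d.forward_full,
        "reverse_5to3": d.reverse_full,
        "overhang_host": d.overhang_host,
        "region_start": d.region_start,
        "region_end": d.region_end,
        "delta": "" if delta is None else delta,
        "side": side,
    }


def panel_to_frame(panel: TilingPanel | TruncationSeries | Sequence[OligoDuplex]) -> pd.DataFrame:
    if isinstance(panel, TilingPanel):
        rows = [_duplex_row(f) for f in panel.fragments]
    elif isinstance(panel, TruncationSeries):
        rows = [_duplex_row(d, delta, panel.side) for delta, d in panel.members]
    else:
        rows = [_duplex_row(d) for d in panel]
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel_tsv(path: str | Path, panel) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)


# -- Sensorgram CSV + phase sidecar ----------------------------------------

def write_sensorgram_csv(path: str | Path, cycles: Sequence[SensorgramCycle]) -> None:
    frames = []
    for c in cycles:
        frames.append(
            pd.DataFrame(
                {
                    "cycle": c.cycle_id,
                    "flow_cell": c.flow_cell,
                    "time_s": c.times,
                    "response_ru": c.responses,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_phases(path: str | Path, cycles: Sequence[SensorgramCycle]) -> None:
    """Phase sidecar: {cycle_id: {phase: [t0, t1]}}, JSON or YAML by suffix."""
    payload = {
        c.cycle_id: {name: [float(t0), float(t1)] for name, (t0, t1) in c.phases.items()}
        for c in cycles
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(payload, fh, sort_keys=True)


def read_phases(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    return {
        str(cid): {name: (float(w[0]), float(w[1])) for name, w in phases.items()}
        for cid, phases in raw.items()
    }


def read_sensorgram_csv(
    path: str | Path, phases: dict[str, dict[str, tuple[float, float]]] | None = None
) -> list[SensorgramCycle]:
    df = pd.read_csv(path)
    missing = [c for c in SENSORGRAM_HEADER if c not in df.columns]
    if missing:
        raise ParameterError(f"sensorgram CSV {path} lacks column(s) {missing}")
    phases = phases or {}
    cycles = []
    for (cid, fc), group in df.groupby(["cycle", "flow_cell"], sort=False):
        cycles.append(
            SensorgramCycle(
                cycle_id=str(cid),
                flow_cell=str(fc),
                times=group["time_s"].to_numpy(),
                responses=group["response_ru"].to_numpy(),
                phases=phases.get(str(cid), {}),
            )
        )
    return cycles


# -- Feature files ----------------------------------------------------------

def read_bed(path: str | Path) -> list[Feature]:
    """BED (>= 3 columns; name in column 4, strand in column 6).  BED is
    0-based half-open; coordinates are converted to 1-based inclusive."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FeatureParseError(str(path), lineno, "fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FeatureParseError(
                    str(path), lineno, f"non-integer coordinates {parts[1]!r}/{parts[2]!r}"
                )
            if end < start:
                raise FeatureParseError(str(path), lineno, "end before start")
            feats.append(
                Feature(
                    contig=parts[0],
                    start=start + 1,
                    end=end,
                    name=parts[3] if len(parts) > 3 else f"feature{lineno}",
                    strand=parts[5] if len(parts) > 5 and parts[5] in "+-" else "+",
                )
            )
    return feats


def read_gff3(path: str | Path, *, types: tuple[str, ...] = ("gene", "CDS")) -> list[Feature]:
    """Minimal GFF3 reader keeping only the requested feature types; the
    feature name is taken from ID=, Name= or locus_tag= in that order."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FeatureParseError(
                    str(path), lineno, f"expected 9 GFF3 columns, got {len(parts)}"
                )
            if types and parts[2] not in types:
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise FeatureParseError(str(path), lineno, "non-integer coordinates")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or attrs.get("locus_tag")
            feats.append(
                Feature(
                    contig=parts[0],
                    start=start,
                    end=end,
                    name=name or f"feature{lineno}",
                    strand=parts[6] if parts[6] in "+-" else "+",
                )
            )
    return feats


def read_features(path: str | Path) -> list[Feature]:
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    return read_bed(path)


# -- Motif hits --------------------------------------------------------------

def write_hits_bed(path: str | Path, hits: Sequence[MotifHit]) -> None:
    """BED6: name = matched sequence, score = number of defined-base matches."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start - 1}\t{h.end}\t{h.matched}\t{h.score}\t{h.strand}\n"
            )


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": h.contig,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "matched": h.matched,
                "score": h.score,
                "nearest_feature": h.nearest_feature,
                "distance": h.distance,
                "inside_feature": h.inside_feature,
            }
            for h in hits
        ]
    )


def write_hits_tsv(path: str | Path, hits: Sequence[MotifHit]) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
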