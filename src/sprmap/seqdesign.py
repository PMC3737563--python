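"""Design of the oligomer panels that drive indirect-capture SPR experiments.

This module generates every class of test duplex the method needs:

* overlapping tiling fragments that guarantee any binding site up to a chosen
  length is fully contained in at least one fragment;
* serial truncation series (2-nt steps by default) for footprint boundary
  mapping, including the strand-inversion trick needed to truncate the
  left-hand end while keeping the capture overhang distal;
* single-base substitution panels with wild-type replicate controls;
* molecular-weight utilities for duplexes (needed for theoretical-Rmax
  normalisation) and for proteins.

Coordinates are 1-based and inclusive on the forward strand of the source
region.  "RH"/"LH" boundaries are defined relative to the forward strand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .errors import AlphabetError, DesignError, ParameterError

__all__ = [
    "COMPLEMENT",
    "IUPAC_CODES",
    "DEFAULT_LINKER_COMPLEMENT",
    "OligoDuplex",
    "TilingPanel",
    "TruncationSeries",
    "SubstitutionPanel",
    "LinkerSpec",
    "validate_dna",
    "revcomp",
    "tile_region",
    "attach_linker",
    "strip_linker",
    "make_truncation_series",
    "apply_footprint",
    "make_substitution_panel",
    "strand_mw",
    "dna_mw",
    "protein_mw",
    "translate",
    "chip_budget",
]

# Watson-Crick complements for the full IUPAC nucleotide alphabet.
COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

IUPAC_CODES = frozenset(COMPLEMENT)
_UNAMBIGUOUS = frozenset("ACGT")

# Placeholder capture-linker complement (20 nt).  The real linker sequence is
# an instrument-setup detail and is always supplied via configuration; this
# default only fixes the length convention.
DEFAULT_LINKER_COMPLEMENT = "TCCTACCTACCTTCCATCCT"


def validate_dna(seq: str, *, allow_iupac: bool = False, context: str = "sequence") -> str:
    """Uppercase and validate a DNA string, naming the first bad symbol."""
    if not isinstance(seq, str):
        raise ParameterError(f"{context} must be a string, got {type(seq).__name__}")
    if not seq:
        raise ParameterError(f"{context} must be non-empty")
    up = seq.upper()
    alphabet = IUPAC_CODES if allow_iupac else _UNAMBIGUOUS
    for i, ch in enumerate(up, start=1):
        if ch not in alphabet:
            raise AlphabetError(ch, i, context)
    return up


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement; IUPAC ambiguity codes are mapped to
    their complements (e.g. R -> Y)."""
    up = validate_dna(seq, allow_iupac=True)
    return "".join(COMPLEMENT[ch] for ch in reversed(up))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_HOSTS = ("reverse_3prime", "forward_3prime", "none")


@dataclass(frozen=True)
class LinkerSpec:
    """The 20-nt sequence appended to one strand of a test duplex so that it
    can hybridise to the chip-bound single-stranded capture linker."""

    linker_complement: str = DEFAULT_LINKER_COMPLEMENT
    description: str = "capture-linker complement"

    def __post_init__(self):
        seq = validate_dna(self.linker_complement, context="linker_complement")
        object.__setattr__(self, "linker_complement", seq)
        if len(seq) != 20:
            raise ParameterError(
                f"linker complement must be exactly 20 nt, got {len(seq)}"
            )


@dataclass(frozen=True)
class OligoDuplex:
    """A double-stranded test oligomer, optionally carrying a single-stranded
    3' overhang on one strand for capture.

    ``forward`` and ``reverse`` are the *core* duplex strands, both written
    5'->3'; ``reverse`` is always the reverse complement of ``forward``.
    ``region_start``/``region_end`` locate the core on the source region's
    forward strand (1-based, inclusive).
    """

    name: str
    forward: str
    reverse: str = ""
    overhang: str = ""
    overhang_host: str = "none"
    region_start: int = 1
    region_end: int = 0

    def __post_init__(self):
        fwd = validate_dna(self.forward, context=f"{self.name} forward strand")
        object.__setattr__(self, "forward", fwd)
        rev = self.reverse or revcomp(fwd)
        rev = validate_dna(rev, context=f"{self.name} reverse strand")
        object.__setattr__(self, "reverse", rev)
        if rev != revcomp(fwd):
            raise DesignError(
                f"{self.name}: reverse strand is not the reverse complement of "
                f"the forward strand"
            )
        if self.overhang_host not in _HOSTS:
            raise ParameterError(
                f"overhang_host must be one of {_HOSTS}, got {self.overhang_host!r}"
            )
        if self.overhang:
            object.__setattr__(
                self, "overhang", validate_dna(self.overhang, context="overhang")
            )
            if self.overhang_host == "none":
                raise DesignError(f"{self.name}: overhang present but no host strand")
        elif self.overhang_host != "none":
            raise DesignError(f"{self.name}: overhang_host set but overhang empty")
        end = self.region_end if self.region_end else self.region_start + len(fwd) - 1
        object.__setattr__(self, "region_end", end)
        if end - self.region_start + 1 != len(fwd):
            raise DesignError(
                f"{self.name}: coordinates [{self.region_start},{end}] do not match "
                f"forward-strand length {len(fwd)}"
            )

    def __len__(self) -> int:
        return len(self.forward)

    @property
    def forward_full(self) -> str:
        """Forward strand including the overhang, if it lives there."""
        if self.overhang_host == "forward_3prime":
            return self.forward + self.overhang
        return self.forward

    @property
    def reverse_full(self) -> str:
        """Reverse strand including the overhang, if it lives there."""
        if self.overhang_host == "reverse_3prime":
            return self.reverse + self.overhang
        return self.reverse


@dataclass(frozen=True)
class TilingPanel:
    """Overlapping fragments covering a region such that every window of
    ``site_length`` nucleotides is fully contained in at least one fragment."""

    region_length: int
    fragment_length: int
    site_length: int
    fragments: tuple[OligoDuplex, ...]

    @property
    def step(self) -> int:
        return self.fragment_length - self.site_length

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


@dataclass(frozen=True)
class TruncationSeries:
    """Serially shortened versions of a starting duplex, used to map one
    footprint boundary.  ``members`` is ordered by ascending delta and always
    starts with the untruncated (delta = 0) duplex."""

    side: str  # "RH" or "LH"
    step: int
    members: tuple[tuple[int, OligoDuplex], ...]

    def deltas(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.members)

    def member(self, delta: int) -> OligoDuplex:
        for d, oligo in self.members:
            if d == delta:
                return oligo
        raise KeyError(f"no member with delta {delta}")


@dataclass(frozen=True)
class SubstitutionPanel:
    """Every single-base variant of the targeted positions, plus wild-type
    replicate controls re-analysed alongside them."""

    wild_type: OligoDuplex
    variants: tuple[tuple[int, str, OligoDuplex], ...]
    controls: tuple[OligoDuplex, ...]


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

def tile_region(
    region: str,
    fragment_length: int,
    site_length: int,
    *,
    name_prefix: str = "frag",
) -> TilingPanel:
    """Divide ``region`` into overlapping fragments of ``fragment_length`` nt
    stepped by ``fragment_length - site_length``, so that any site of up to
    ``site_length`` nt is fully contained in at least one fragment.

    If the last on-grid fragment does not reach the end of the region, one
    extra end-anchored fragment (ending exactly at the last base) is appended.
    """
    seq = validate_dna(region, context="region")
    n = len(seq)
    if fragment_length > n:
        raise ParameterError(
            f"fragment_length {fragment_length} exceeds region length {n}"
        )
    if site_length > fragment_length:
        raise ParameterError(
            f"site_length {site_length} exceeds fragment_length {fragment_length}"
        )
    if site_length < 1:
        raise ParameterError("site_length must be >= 1")

    step = fragment_length - site_length
    starts: list[int] = []
    if step == 0:
        if n > fragment_length:
            raise ParameterError(
                "site_length equal to fragment_length gives a zero step; "
                "coverage of a longer region is impossible"
            )
        starts.append(1)
    else:
        s = 1
        while s + fragment_length - 1 <= n:
            starts.append(s)
            s += step
    last_end = starts[-1] + fragment_length - 1
    if last_end < n:
        starts.append(n - fragment_length + 1)  # end-anchored final fragment

    frags = tuple(
        OligoDuplex(
            name=f"{name_prefix}{i + 1}",
            forward=seq[s - 1 : s - 1 + fragment_length],
            region_start=s,
            region_end=s + fragment_length - 1,
        )
        for i, s in enumerate(starts)
    )
    return TilingPanel(
        region_length=n,
        fragment_length=fragment_length,
        site_length=site_length,
        fragments=frags,
    )


def attach_linker(
    duplex: OligoDuplex, linker: LinkerSpec, host: str = "reverse_3prime"
) -> OligoDuplex:
    """Append the linker complement to the 3' end of the chosen strand.

    The standard orientation hosts the overhang on the reverse strand; the
    inverted orientation (forward_3prime) flips the duplex on the chip so the
    original left-hand boundary becomes distal to the linker.
    """
    if host == "none":
        warnings.warn("attach_linker called with host='none'; no-op", stacklevel=2)
        return duplex
    if host not in _HOSTS:
        raise ParameterError(f"unknown overhang host {host!r}")
    if duplex.overhang:
        raise DesignError(f"{duplex.name}: duplex already carries an overhang")
    return replace(duplex, overhang=linker.linker_complement, overhang_host=host)


def strip_linker(duplex: OligoDuplex) -> OligoDuplex:
    """Remove the overhang, restoring the bare core duplex."""
    return replace(duplex, overhang="", overhang_host="none")


def make_truncation_series(
    start: OligoDuplex,
    side: str,
    *,
    step: int = 2,
    max_delta: int,
    min_length: int = 10,
    linker: LinkerSpec | None = None,
) -> TruncationSeries:
    """Build the serial truncation panel for one footprint boundary.

    RH: the forward strand is trimmed from its 3' end (the reverse strand
    correspondingly from its 5' end); the capture overhang stays on the
    reverse strand.  LH: the duplex is first inverted on the linker (overhang
    moved to the forward strand's 3' end), then the forward strand is trimmed
    from its 5' end (reverse from its 3' end).
    """
    if side not in ("RH", "LH"):
        raise ParameterError(f"side must be 'RH' or 'LH', got {side!r}")
    if step < 1:
        raise ParameterError("step must be >= 1")
    if max_delta >= len(start):
        raise ParameterError(
            f"max_delta {max_delta} must be smaller than the duplex length {len(start)}"
        )
    if len(start) - max_delta < min_length:
        raise DesignError(
            f"truncation to {len(start) - max_delta} nt would fall below the "
            f"minimum duplex length of {min_length} nt"
        )

    linker = linker or LinkerSpec()
    wanted_host = "reverse_3prime" if side == "RH" else "forward_3prime"
    if start.overhang and start.overhang_host != wanted_host:
        base = attach_linker(strip_linker(start), LinkerSpec(start.overhang), wanted_host)
    elif not start.overhang:
        base = attach_linker(start, linker, wanted_host)
    else:
        base = start

    members = []
    for delta in range(0, max_delta + 1, step):
        if side == "RH":
            fwd = base.forward[: len(base.forward) - delta] if delta else base.forward
            rs, re_ = base.region_start, base.region_end - delta
        else:
            fwd = base.forward[delta:]
            rs, re_ = base.region_start + delta, base.region_end
        members.append(
            (
                delta,
                OligoDuplex(
                    name=f"{start.name}_{side}_d{delta}",
                    forward=fwd,
                    overhang=base.overhang,
                    overhang_host=base.overhang_host,
                    region_start=rs,
                    region_end=re_,
                ),
            )
        )
    return TruncationSeries(side=side, step=step, members=tuple(members))


def apply_footprint(start: OligoDuplex, delta_rh: int, delta_lh: int) -> OligoDuplex:
    """Trim ``delta_lh`` nt from the 5' end and ``delta_rh`` nt from the 3'
    end of the forward strand, adjusting coordinates.  The result is a bare
    core duplex (no overhang)."""
    if delta_rh < 0 or delta_lh < 0:
        raise ParameterError("truncation deltas must be non-negative")
    if delta_rh + delta_lh >= len(start):
        raise ParameterError(
            f"deltas {delta_rh}+{delta_lh} would remove the whole {len(start)}-nt duplex"
        )
    fwd = start.forward[delta_lh : len(start.forward) - delta_rh]
    return OligoDuplex(
        name=f"{start.name}_footprint",
        forward=fwd,
        region_start=start.region_start + delta_lh,
        region_end=start.region_end - delta_rh,
    )


def make_substitution_panel(
    wild_type: OligoDuplex,
    positions: Sequence[int],
    *,
    replicates: int = 1,
) -> SubstitutionPanel:
    """Replace each targeted base in turn with all three alternatives,
    keeping the reverse strand complementary; include ``replicates`` wild-type
    control duplexes for re-analysis alongside the variants."""
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if len(set(positions)) != len(positions):
        raise ParameterError("duplicate positions in substitution panel")
    variants = []
    for pos in positions:
        if not 1 <= pos <= len(wild_type):
            raise ParameterError(
                f"position {pos} outside wild-type duplex of length {len(wild_type)}"
            )
        ref = wild_type.forward[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            fwd = wild_type.forward[: pos - 1] + alt + wild_type.forward[pos:]
            variants.append(
                (
                    pos,
                    alt,
                    OligoDuplex(
                        name=f"{wild_type.name}_p{pos}{ref}{alt}",
                        forward=fwd,
                        overhang=wild_type.overhang,
                        overhang_host=wild_type.overhang_host,
                        region_start=wild_type.region_start,
                        region_end=wild_type.region_end,
                    ),
                )
            )
    controls = tuple(
        replace(wild_type, name=f"{wild_type.name}_wt_ctrl{i + 1}")
        for i in range(replicates)
    )
    return SubstitutionPanel(
        wild_type=wild_type, variants=tuple(variants), controls=controls
    )


# ---------------------------------------------------------------------------
# Molecular weights
# ---------------------------------------------------------------------------

# Average masses of the 2'-deoxyribonucleosides (Da).  A strand with 5'-OH and
# 3'-OH termini is the sum of its nucleosides plus one bridging phosphate
# (H3PO4 condensed with loss of two waters = +61.9659 Da) per internal linkage.
_NUCLEOSIDE_AVG = {
    "A": 251.2419,
    "C": 227.2172,
    "G": 267.2413,
    "T": 242.2286,
}
_BRIDGE_PHOSPHATE = 61.9659  # H3PO4 (97.995) - 2 x H2O (18.0153)

# Average residue masses (Da): amino acid minus water; add one water per chain.
_RESIDUE_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_AVG = 18.0153


def strand_mw(seq: str) -> float:
    """Average mass (Da) of one single strand, 5'-OH/3'-OH convention."""
    up = validate_dna(seq, context="strand")
    for i, ch in enumerate(up, start=1):
        if ch not in _NUCLEOSIDE_AVG:
            raise ParameterError(
                f"mass undefined for ambiguity code {ch!r} at position {i}"
            )
    return sum(_NUCLEOSIDE_AVG[ch] for ch in up) + (len(up) - 1) * _BRIDGE_PHOSPHATE


def dna_mw(duplex: OligoDuplex) -> float:
    """Average mass (Da) of the full captured species: both strands, including
    the single-stranded overhang (counted once on its host strand)."""
    return strand_mw(duplex.forward_full) + strand_mw(duplex.reverse_full)


def protein_mw(aa_seq: str) -> float:
    """Average mass (Da) of a protein chain: sum of residue masses plus one
    water.  The N-terminal Met is counted like any other residue."""
    if not aa_seq:
        raise ParameterError("amino-acid sequence must be non-empty")
    up = aa_seq.upper()
    total = _WATER_AVG
    for i, ch in enumerate(up, start=1):
        if ch not in _RESIDUE_AVG:
            raise AlphabetError(ch, i, "amino-acid sequence")
        total += _RESIDUE_AVG[ch]
    return total


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt_seq: str) -> str:
    """Translate frame 1 with the standard genetic code, stopping at the
    first stop codon.  A trailing partial codon is ignored with a warning."""
    seq = validate_dna(nt_seq, context="coding sequence")
    if len(seq) < 3:
        raise ParameterError("coding sequence must be at least one codon long")
    if len(seq) % 3:
        warnings.warn(
            f"trailing partial codon of {len(seq) % 3} nt ignored", stacklevel=2
        )
        seq = seq[: len(seq) - len(seq) % 3]
    out = []
    for i in range(0, len(seq), 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def chip_budget(n_injections: int, surfaces_per_chip: int = 3) -> int:
    """Number of direct-capture chips consumed by ``n_injections`` test-DNA
    captures when each chip offers ``surfaces_per_chip`` test surfaces.

    With indirect (regenerable) capture the answer is always 1; this utility
    quantifies the saving versus direct capture.
    """
    if n_injections < 0 or surfaces_per_chip < 1:
        raise ParameterError("need n_injections >= 0 and surfaces_per_chip >= 1")
    return math.ceil(n_injections / surfaces_per_chip)
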