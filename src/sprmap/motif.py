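"""Consensus derivation, palindrome annotation and degenerate motif scanning.

The consensus of two or more equal-orientation binding sites is the column-
wise agreement under the best ungapped offset, with disagreeing columns
written as ``n`` and ragged conserved ends trimmed away.  The resulting
degenerate motif can be scanned against whole genomes on both strands, and
hits can be annotated with their nearest downstream feature.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import AlphabetError, ParameterError
from .seqdesign import COMPLEMENT, revcomp, validate_dna

__all__ = [
    "ConsensusMotif",
    "PalindromePairing",
    "MotifHit",
    "Feature",
    "derive_consensus",
    "annotate_palindrome",
    "scan_sequence",
    "report_context",
]

_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate consensus: defined bases are conserved across all input
    sequences; ``n`` marks disagreeing columns.  ``offsets`` records where
    the motif starts (1-based) within each input sequence."""

    iupac: str
    offsets: tuple[int, ...] = ()
    min_block: int = 2

    def __post_init__(self):
        for i, ch in enumerate(self.iupac.upper(), start=1):
            if ch not in _IUPAC_CLASS:
                raise AlphabetError(ch, i, "motif")
        object.__setattr__(
            self, "iupac", self.iupac.upper().replace("N", "n") if self.iupac else ""
        )

    def __len__(self) -> int:
        return len(self.iupac)

    def __bool__(self) -> bool:
        return bool(self.iupac)

    @property
    def conserved_positions(self) -> tuple[int, ...]:
        """1-based positions holding a defined (non-n) base."""
        return tuple(i for i, ch in enumerate(self.iupac, start=1) if ch != "n")


@dataclass(frozen=True)
class PalindromePairing:
    """Symmetry pairing (i, M+1-i) of a site of length M, with a flag for
    each pair telling whether the two bases are defined and Watson-Crick
    complementary."""

    length: int
    pairs: tuple[tuple[int, int, bool], ...]

    @property
    def complementary_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple((i, j) for i, j, ok in self.pairs if ok)


@dataclass(frozen=True)
class MotifHit:
    """One match of a motif on a genome contig.  ``start`` is the 1-based
    coordinate of the leftmost matched base on the forward strand, for either
    strand."""

    contig: str
    start: int
    strand: str
    matched: str
    score: int
    nearest_feature: str | None = None
    distance: int | None = None
    inside_feature: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


@dataclass(frozen=True)
class Feature:
    """A genome feature (gene) from a BED or GFF3 file; 1-based inclusive."""

    contig: str
    start: int
    end: int
    name: str
    strand: str = "+"


def _identities_at_offset(anchor: str, other: str, offset: int) -> int:
    """Matching columns when ``other`` is shifted by ``offset`` relative to
    ``anchor`` (offset = start of other minus start of anchor)."""
    count = 0
    for i, ch in enumerate(anchor):
        j = i - offset
        if 0 <= j < len(other) and other[j] == ch:
            count += 1
    return count


def derive_consensus(
    sequences: Sequence[str], *, min_block: int = 2
) -> ConsensusMotif:
    """Column-agreement consensus of >= 2 equal-orientation sequences.

    Each sequence after the first is slid (ungapped) against the first to the
    offset maximising identities (ties resolved towards the smallest absolute
    offset, then the smaller signed offset).  Columns where every sequence
    agrees keep their base; all others become ``n``.  Finally the ends are
    trimmed inward until the motif both starts and ends with at least
    ``min_block`` consecutive defined bases; if no such window exists an
    empty motif is returned with a warning.
    """
    if len(sequences) < 2:
        raise ParameterError("need at least two sequences to derive a consensus")
    seqs = [validate_dna(s, context=f"input sequence {k + 1}") for k, s in enumerate(sequences)]

    anchor = seqs[0]
    offsets = [0]
    for other in seqs[1:]:
        span = range(-(len(other) - 1), len(anchor))
        best = max(
            span,
            key=lambda off: (_identities_at_offset(anchor, other, off), -abs(off), -off),
        )
        offsets.append(best)

    lo = min(offsets)
    hi = max(off + len(s) for off, s in zip(offsets, seqs))
    columns = []
    for pos in range(lo, hi):
        bases = set()
        covered = True
        for off, s in zip(offsets, seqs):
            j = pos - off
            if 0 <= j < len(s):
                bases.add(s[j])
            else:
                covered = False
                break
        columns.append(bases.pop() if covered and len(bases) == 1 else "n")

    consensus = "".join(columns)

    def _block_at(idx: int, direction: int) -> bool:
        seg = consensus[idx : idx + min_block] if direction > 0 else consensus[
            max(idx - min_block + 1, 0) : idx + 1
        ]
        return len(seg) == min_block and "n" not in seg

    start = 0
    while start <= len(consensus) - min_block and not _block_at(start, +1):
        start += 1
    end = len(consensus) - 1
    while end >= min_block - 1 and not _block_at(end, -1):
        end -= 1
    if start > end or start > len(consensus) - min_block:
        warnings.warn(
            f"no consensus window with {min_block} consecutive defined bases at "
            "both ends; returning an empty motif",
            stacklevel=2,
        )
        return ConsensusMotif(iupac="", offsets=(), min_block=min_block)

    trimmed = consensus[start : end + 1]
    # 1-based start of the trimmed motif within each input sequence
    motif_offsets = tuple((lo + start) - off + 1 for off in offsets)
    return ConsensusMotif(iupac=trimmed, offsets=motif_offsets, min_block=min_block)


def annotate_palindrome(site: str | ConsensusMotif) -> PalindromePairing:
    """Pair position i with M+1-i and flag the pair complementary iff both
    bases are defined (not ``n``) and Watson-Crick complementary."""
    seq = site.iupac if isinstance(site, ConsensusMotif) else site.upper().replace("N", "n")
    m = len(seq)
    if m < 2:
        raise ParameterError("palindrome annotation needs a site of length >= 2")
    pairs = []
    for i in range(1, m // 2 + 1):
        j = m + 1 - i
        a, b = seq[i - 1], seq[j - 1]
        ok = a != "n" and b != "n" and COMPLEMENT.get(a) == b
        pairs.append((i, j, ok))
    return PalindromePairing(length=m, pairs=tuple(pairs))


def _motif_regex(iupac: str) -> re.Pattern:
    body = "".join(_IUPAC_CLASS[ch if ch != "n" else "N"] for ch in iupac)
    return re.compile(f"(?=({body}))")  # lookahead -> overlapping matches


def scan_sequence(
    contigs: Sequence[tuple[str, str]] | str,
    motif: ConsensusMotif | str,
    *,
    strands: str = "both",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of the degenerate motif.

    ``contigs`` is either a bare sequence (scanned as contig "seq") or a list
    of (contig_id, sequence) pairs.  Reverse-strand hits carry the 1-based
    forward-strand coordinate of their leftmost base.  Hits are ordered by
    (contig, start, strand) and deduplicated on that key.
    """
    if isinstance(motif, str):
        motif = ConsensusMotif(iupac=motif)
    if not motif:
        raise ParameterError("cannot scan with an empty motif")
    if strands not in ("both", "+", "-"):
        raise ParameterError(f"strands must be 'both', '+' or '-', got {strands!r}")
    if isinstance(contigs, str):
        contigs = [("seq", contigs)]

    n_defined = len(motif.conserved_positions)
    fwd_re = _motif_regex(motif.iupac)
    rev_re = _motif_regex(revcomp(motif.iupac.replace("n", "N")))

    hits: dict[tuple[str, int, str], MotifHit] = {}
    for contig_id, seq in contigs:
        target = validate_dna(seq, context=f"contig {contig_id}")
        if strands in ("both", "+"):
            for m in fwd_re.finditer(target):
                key = (contig_id, m.start() + 1, "+")
                hits[key] = MotifHit(
                    contig=contig_id,
                    start=m.start() + 1,
                    strand="+",
                    matched=m.group(1),
                    score=n_defined,
                )
        if strands in ("both", "-"):
            for m in rev_re.finditer(target):
                key = (contig_id, m.start() + 1, "-")
                hits[key] = MotifHit(
                    contig=contig_id,
                    start=m.start() + 1,
                    strand="-",
                    matched=revcomp(m.group(1)),
                    score=n_defined,
                )
    return [hits[k] for k in sorted(hits, key=lambda k: (k[0], k[1], k[2]))]


def report_context(
    hits: Iterable[MotifHit],
    features: Sequence[Feature],
    *,
    window: int = 10000,
) -> list[MotifHit]:
    """Annotate each hit with the nearest feature start lying downstream of
    the hit (on either strand: rightward for '+' features, leftward for '-'),
    or flag it when nothing falls within ``window`` nt.

    A hit overlapping a feature gets distance 0 and ``inside_feature=True``.
    """
    feats = sorted(features, key=lambda f: (f.contig, f.start))
    out = []
    for hit in hits:
        best_name, best_dist, inside = None, None, False
        for f in feats:
            if f.contig != hit.contig:
                continue
            if f.start <= hit.end and hit.start <= f.end:
                best_name, best_dist, inside = f.name, 0, True
                break
            if f.strand == "+" and f.start > hit.end:
                d = f.start - hit.end - 1
            elif f.strand == "-" and f.end < hit.start:
                d = hit.start - f.end - 1
            else:
                continue
            if d <= window and (best_dist is None or d < best_dist):
                best_name, best_dist = f.name, d
        out.append(
            MotifHit(
                contig=hit.contig,
                start=hit.start,
                strand=hit.strand,
                matched=hit.matched,
                score=hit.score,
                nearest_feature=best_name,
                distance=best_dist,
                inside_feature=inside,
            )
        )
    return out
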