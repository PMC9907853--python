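"""Sequence-level AIM/LIR candidate detection and in-silico mutagenesis.

The canonical ATG8-interaction motif (AIM, also called the LC3-interacting
region, LIR) is the short linear motif [W/Y/F]-X-X-[L/I/V]: an aromatic
anchor, two spacer residues, and a hydrophobic anchor.  A naive consensus
scan over a protein of interest yields many candidate windows, most of them
non-functional; this module provides that scan plus the sequence surgery
used to interrogate candidates iteratively — alanine masking of the anchor
residues, truncation of the core window, and positional swapping of two
motif-bearing windows.

Coordinates are 1-based and inclusive throughout, matching the common
"(172)WxxL(175)" notation used when reporting motif loci.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "STANDARD_AA",
    "NONSTANDARD_AA",
    "ProteinRecord",
    "MotifPattern",
    "MotifHit",
    "CANONICAL_PATTERN",
    "scan",
    "flank_acidity",
    "mask_motif",
    "swap_windows",
    "read_fasta",
    "write_fasta",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Tolerated nonstandard codes (unknown, selenocysteine, ambiguity codes).
#: These are legal in sequences but never satisfy any position class.
NONSTANDARD_AA = frozenset("XUBZ")

_LEGAL = STANDARD_AA | NONSTANDARD_AA

#: Acidic residues counted by :func:`flank_acidity`.
ACIDIC = frozenset("DE")


class SequenceError(ValueError):
    """Raised for malformed sequences or out-of-range motif coordinates."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein of interest: identifier, sequence, optional organism tag.

    The sequence is upper-cased on construction and must consist of the 20
    standard one-letter codes plus ``X``, ``U``, ``B``, ``Z``.
    """

    id: str
    sequence: str
    organism: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        # Empty sequences are legal: truncating a motif spanning a whole
        # record must yield a record, and scanning it yields no hits.
        bad = set(seq) - _LEGAL
        if bad:
            raise SequenceError(
                f"{self.id!r}: illegal residue code(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Return residues ``start..end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self)):
            raise SequenceError(
                f"{self.id!r}: window {start}-{end} outside 1-{len(self)}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of amino-acid position classes.

    ``position_classes[i]`` is the set of residues allowed at core position
    ``i``; the full standard alphabet stands for "any residue" (spacer).
    Nonstandard codes never match a position class, including spacers.
    """

    name: str
    position_classes: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        classes = tuple(frozenset(c) for c in self.position_classes)
        object.__setattr__(self, "position_classes", classes)
        if len(classes) < 2:
            raise ValueError(f"pattern {self.name!r}: need >= 2 positions")
        for end in (classes[0], classes[-1]):
            if not end or not end < STANDARD_AA:
                raise ValueError(
                    f"pattern {self.name!r}: anchor classes must be non-empty "
                    "proper subsets of the standard alphabet"
                )

    def __len__(self) -> int:
        return len(self.position_classes)

    def matches(self, window: str) -> bool:
        if len(window) != len(self):
            return False
        return all(
            aa in cls for aa, cls in zip(window, self.position_classes)
        )

    @property
    def anchor_classes(self) -> tuple[frozenset[str], frozenset[str]]:
        """(first, last) position classes — the residues that dock."""
        return self.position_classes[0], self.position_classes[-1]


#: The canonical AIM/LIR consensus [W,Y,F]XX[L,I,V].
CANONICAL_PATTERN = MotifPattern(
    "canonical",
    (
        frozenset("WYF"),
        STANDARD_AA,
        STANDARD_AA,
        frozenset("LIV"),
    ),
)

_PATTERNS = {"canonical": CANONICAL_PATTERN}


def get_pattern(name: str) -> MotifPattern:
    """Look up a named pattern (currently only ``canonical``)."""
    try:
        return _PATTERNS[name]
    except KeyError:
        raise KeyError(
            f"unknown pattern {name!r}; available: {sorted(_PATTERNS)}"
        ) from None


@dataclass(frozen=True)
class MotifHit:
    """One candidate motif window on a protein (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    core: str
    pattern_name: str
    upstream_acidity: int = 0
    downstream_acidity: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.core):
            raise ValueError(
                f"hit {self.start}-{self.end} inconsistent with core "
                f"{self.core!r}"
            )


def scan(
    record: ProteinRecord,
    pattern: MotifPattern = CANONICAL_PATTERN,
    flank_window: int = 4,
) -> list[MotifHit]:
    """Report every window of ``record`` matching ``pattern``.

    Overlapping windows are all reported, sorted by start position.  Each
    hit carries the count of acidic residues (D/E) in the ``flank_window``
    residues on either side of the core.
    """
    seq = record.sequence
    k = len(pattern)
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if pattern.matches(window):
            hit = MotifHit(
                protein_id=record.id,
                start=i + 1,
                end=i + k,
                core=window,
                pattern_name=pattern.name,
            )
            up, down = flank_acidity(record, hit, window=flank_window)
            hits.append(
                replace(hit, upstream_acidity=up, downstream_acidity=down)
            )
    return hits


def _check_hit(record: ProteinRecord, hit: MotifHit) -> None:
    if not (1 <= hit.start <= hit.end <= len(record)):
        raise SequenceError(
            f"hit {hit.start}-{hit.end} outside {record.id!r} "
            f"(length {len(record)})"
        )
    if record.subsequence(hit.start, hit.end) != hit.core:
        raise SequenceError(
            f"hit core {hit.core!r} does not match {record.id!r} at "
            f"{hit.start}-{hit.end}"
        )


def flank_acidity(
    record: ProteinRecord, hit: MotifHit, window: int = 4
) -> tuple[int, int]:
    """Count acidic residues (D/E) flanking a motif core.

    Returns ``(upstream, downstream)`` counts over the ``window`` residues
    immediately before the core start and after the core end, truncated at
    the sequence boundaries.  Acidic flanks are a hallmark of functional
    AIM/LIRs: they form salt bridges with basic residues ringing the two
    docking pockets.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not (1 <= hit.start <= hit.end <= len(record)):
        raise SequenceError(
            f"hit {hit.start}-{hit.end} outside {record.id!r}"
        )
    seq = record.sequence
    up = seq[max(0, hit.start - 1 - window) : hit.start - 1]
    down = seq[hit.end : hit.end + window]
    return (
        sum(aa in ACIDIC for aa in up),
        sum(aa in ACIDIC for aa in down),
    )


def mask_motif(
    record: ProteinRecord, hit: MotifHit, strategy: str = "alanine"
) -> ProteinRecord:
    """Neutralise a motif in silico for the next discovery round.

    ``alanine`` substitutes A at the two anchor positions (first and last
    core residues) only, preserving length and register — e.g. a WEVV core
    becomes AEVA.  ``truncate`` deletes the whole core window.  Either way
    a re-scan of the result yields no hit with this core at this locus.
    """
    _check_hit(record, hit)
    seq = record.sequence
    i, j = hit.start - 1, hit.end  # 0-based half-open core span
    if strategy == "alanine":
        core = seq[i:j]
        masked = "A" + core[1:-1] + "A"
        new_seq = seq[:i] + masked + seq[j:]
    elif strategy == "truncate":
        new_seq = seq[:i] + seq[j:]
    else:
        raise ValueError(f"unknown masking strategy {strategy!r}")
    new_id = f"{record.id}_mask{hit.start}-{hit.end}_{strategy}"
    return ProteinRecord(new_id, new_seq, record.organism)


def _extended_span(
    record: ProteinRecord, hit: MotifHit, flank: int
) -> tuple[int, int]:
    """0-based half-open span of core +/- flank, truncated at boundaries."""
    return max(0, hit.start - 1 - flank), min(len(record), hit.end + flank)


def swap_windows(
    record: ProteinRecord, hit1: MotifHit, hit2: MotifHit, flank: int = 4
) -> ProteinRecord:
    """Exchange two flank-extended motif windows in place.

    Each window is the motif core extended by ``flank`` residues on either
    side (truncated at the sequence ends).  Swapping probes positional
    preference: a predictor that favours the more N-terminal of two
    functional motifs will switch allegiance when their loci are exchanged.
    The operation preserves sequence length and is an involution when the
    two extended windows have equal length.
    """
    _check_hit(record, hit1)
    _check_hit(record, hit2)
    if flank < 0:
        raise ValueError("flank must be >= 0")
    s1 = _extended_span(record, hit1, flank)
    s2 = _extended_span(record, hit2, flank)
    if s1[0] > s2[0]:
        s1, s2 = s2, s1
    if s1[1] > s2[0]:
        raise SequenceError(
            f"extended windows {s1} and {s2} overlap; cannot swap"
        )
    seq = record.sequence
    new_seq = (
        seq[: s1[0]]
        + seq[s2[0] : s2[1]]
        + seq[s1[1] : s2[0]]
        + seq[s1[0] : s1[1]]
        + seq[s2[1] :]
    )
    new_id = f"{record.id}_swap{hit1.start}x{hit2.start}"
    return ProteinRecord(new_id, new_seq, record.organism)


# --- FASTA I/O -------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA; ids are the first header token."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
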