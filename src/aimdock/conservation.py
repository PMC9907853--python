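"""Motif conservation across a homolog multiple sequence alignment.

Functional AIM/LIR motifs tend to be retained across species, and a
candidate whose anchor residues are conserved in distant homologs is a
far stronger bet for experimental validation than one found in a single
sequence.  Given a prepared MSA (Clustal Omega, MAFFT, ...) containing
the protein of interest, this module maps a motif hit from ungapped
reference coordinates to alignment columns and asks, per homolog, whether
the two anchor position classes (aromatic [W/Y/F] and hydrophobic
[L/I/V] for the canonical pattern) are retained.

Retention tests anchors only by default: the two spacer positions are
unconstrained in the consensus and are ignored.  A homolog with a gap at
an anchor column is excluded from the denominator — an unalignable region
is not evidence of motif loss — and flagged in the per-species report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .seqmotif import MotifHit, MotifPattern, CANONICAL_PATTERN

__all__ = [
    "AlignmentSet",
    "SpeciesCall",
    "ConservationProfile",
    "map_hit_to_columns",
    "conservation_score",
    "read_alignment",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentSet:
    """An MSA as (id, aligned sequence) rows plus a reference id."""

    rows: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        rows = tuple((rid, seq.upper()) for rid, seq in self.rows)
        object.__setattr__(self, "rows", rows)
        if self.reference_id not in {rid for rid, _ in rows}:
            raise ValueError(
                f"reference {self.reference_id!r} not among alignment rows"
            )

    @property
    def reference_row(self) -> str:
        for rid, seq in self.rows:
            if rid == self.reference_id:
                return seq
        raise AssertionError  # unreachable

    def ungapped_reference(self) -> str:
        return self.reference_row.replace(GAP, "")


@dataclass(frozen=True)
class SpeciesCall:
    sequence_id: str
    retained: bool
    observed_core: str
    gapped_anchor: bool = False


@dataclass(frozen=True)
class ConservationProfile:
    """Per-homolog retention of one motif plus the summary fraction."""

    motif: MotifHit
    columns: tuple[int, ...]
    per_species: tuple[SpeciesCall, ...]
    fraction_retained: float
    n_eligible: int


def map_hit_to_columns(msa: AlignmentSet, hit: MotifHit) -> tuple[int, ...]:
    """Alignment columns (1-based) holding the hit's core residues.

    The hit is stated on the ungapped reference sequence; reference gap
    columns are skipped while mapping, so the returned columns are
    ordered but need not be contiguous.
    """
    ref = msa.reference_row
    cols = []
    ungapped = 0
    for col, ch in enumerate(ref, start=1):
        if ch == GAP:
            continue
        ungapped += 1
        if hit.start <= ungapped <= hit.end:
            cols.append(col)
    if ungapped < hit.end:
        raise ValueError(
            f"hit {hit.start}-{hit.end} beyond ungapped reference length "
            f"{ungapped}"
        )
    return tuple(cols)


def conservation_score(
    msa: AlignmentSet,
    hit: MotifHit,
    pattern: MotifPattern = CANONICAL_PATTERN,
    strict_identity: bool = False,
) -> ConservationProfile:
    """Fraction of homologs retaining the motif's anchor classes.

    A non-reference row retains the motif when its residues at the first
    and last core columns satisfy the pattern's anchor classes (or, with
    ``strict_identity``, when its whole observed core equals the
    reference core) and neither anchor column is a gap.  Rows gapped at
    an anchor column are excluded from the denominator.
    """
    cols = map_hit_to_columns(msa, hit)
    if len(cols) != len(pattern):
        raise ValueError(
            f"hit length {len(cols)} != pattern length {len(pattern)}"
        )
    first_cls, last_cls = pattern.anchor_classes
    c_first, c_last = cols[0], cols[-1]

    calls = []
    retained_n = 0
    eligible = 0
    for rid, seq in msa.rows:
        if rid == msa.reference_id:
            continue
        observed = "".join(seq[c - 1] for c in cols)
        a_first, a_last = seq[c_first - 1], seq[c_last - 1]
        if a_first == GAP or a_last == GAP:
            calls.append(SpeciesCall(rid, False, observed, gapped_anchor=True))
            continue
        eligible += 1
        if strict_identity:
            retained = observed == hit.core
        else:
            retained = a_first in first_cls and a_last in last_cls
        retained_n += retained
        calls.append(SpeciesCall(rid, retained, observed))
    fraction = retained_n / eligible if eligible else 0.0
    return ConservationProfile(
        motif=hit,
        columns=cols,
        per_species=tuple(calls),
        fraction_retained=fraction,
        n_eligible=eligible,
    )


def read_alignment(path: str | Path, reference_id: str) -> AlignmentSet:
    """Read an aligned FASTA or Clustal file into an :class:`AlignmentSet`."""
    from Bio import AlignIO

    path = Path(path)
    fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError:
        alt = "fasta" if fmt == "clustal" else "clustal"
        aln = AlignIO.read(str(path), alt)
    rows = tuple((rec.id, str(rec.seq)) for rec in aln)
    return AlignmentSet(rows=rows, reference_id=reference_id)
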