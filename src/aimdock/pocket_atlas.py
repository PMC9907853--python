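"""The two AIM/LIR docking pockets of ATG8-family receptors.

Every ATG8/LC3/GABARAP protein presents two hydrophobic pockets on its
ubiquitin-like fold: the W-site (site 1), which receives the motif's
aromatic anchor, and the L-site (site 2), which receives the hydrophobic
anchor.  Pocket residues are strongly conserved across the family, so a
definition derived once from a reference receptor-peptide complex can be
transferred to any homolog by sequence alignment.

Pockets are defined operationally: a receptor residue belongs to a site
when any of its heavy atoms lies within a distance cutoff (default 5.0 A)
of any heavy atom of the corresponding bound anchor residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .complex_interface import Chain, ComplexModel, ModelError
from .seqmotif import ProteinRecord

__all__ = [
    "PocketDefinition",
    "PocketMappingReport",
    "EmptyPocketError",
    "derive_pockets",
    "map_pockets",
    "pocket_composition",
    "load_pockets",
    "save_pockets",
    "bundled_reference_pockets",
]


class EmptyPocketError(ModelError):
    """No receptor residue falls within the cutoff of an anchor."""


@dataclass(frozen=True)
class PocketDefinition:
    """W-site and L-site of one receptor, as 1-based residue positions.

    Positions follow the numbering of the structure (or sequence) they
    were defined on, so calls made against them are citable against the
    source file.  A residue may border both sites.  ``source`` records
    whether the definition came from a reference complex
    (``reference-derived``) or from alignment transfer (``mapped``).
    """

    receptor_id: str
    w_site: frozenset[int]
    l_site: frozenset[int]
    source: str = "reference-derived"

    def __post_init__(self) -> None:
        object.__setattr__(self, "w_site", frozenset(self.w_site))
        object.__setattr__(self, "l_site", frozenset(self.l_site))
        if not self.w_site or not self.l_site:
            raise EmptyPocketError(
                f"{self.receptor_id!r}: each pocket needs >= 1 residue"
            )


def _anchor_neighbours(
    receptor: Chain, anchor_coords: np.ndarray, cutoff: float
) -> frozenset[int]:
    tree = cKDTree(anchor_coords)
    hits = set()
    for res in receptor.residues:
        d, _ = tree.query(res.coords())
        if np.min(d) <= cutoff:
            hits.add(res.position)
    return frozenset(hits)


def derive_pockets(
    reference_complex: ComplexModel,
    receptor_chain: str,
    peptide_chain: str,
    anchor_aromatic: int,
    anchor_hydrophobic: int,
    cutoff_A: float = 5.0,
) -> PocketDefinition:
    """Define W/L sites from a receptor-peptide reference complex.

    ``anchor_aromatic`` and ``anchor_hydrophobic`` are the peptide
    positions of the bound motif's two anchors.  A receptor residue joins
    the W-site (L-site) when any of its heavy atoms lies within
    ``cutoff_A`` of any heavy atom of the aromatic (hydrophobic) anchor.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be > 0")
    receptor = reference_complex.chain(receptor_chain)
    peptide = reference_complex.chain(peptide_chain)
    by_pos = peptide.by_position()
    for name, pos in (
        ("aromatic", anchor_aromatic),
        ("hydrophobic", anchor_hydrophobic),
    ):
        if pos not in by_pos:
            raise ModelError(
                f"{name} anchor position {pos} absent from peptide chain "
                f"{peptide_chain!r}"
            )
    w = _anchor_neighbours(receptor, by_pos[anchor_aromatic].coords(), cutoff_A)
    l = _anchor_neighbours(
        receptor, by_pos[anchor_hydrophobic].coords(), cutoff_A
    )
    if not w or not l:
        empty = [nm for nm, s in (("W", w), ("L", l)) if not s]
        raise EmptyPocketError(
            f"empty pocket(s) {','.join(empty)} at cutoff {cutoff_A} A"
        )
    return PocketDefinition(
        receptor_id=f"{reference_complex.model_id}:{receptor_chain}",
        w_site=w,
        l_site=l,
        source="reference-derived",
    )


@dataclass(frozen=True)
class PocketMappingReport:
    """Outcome of transferring a pocket definition to a homolog."""

    definition: PocketDefinition
    identity: float
    dropped_w: frozenset[int]
    dropped_l: frozenset[int]


def map_pockets(
    ref_def: PocketDefinition,
    ref_seq: ProteinRecord,
    target_seq: ProteinRecord,
    min_identity: float = 0.30,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PocketMappingReport:
    """Transfer pocket positions onto a homologous receptor by alignment.

    A global pairwise alignment (BLOSUM62) links reference positions to
    target positions; pocket positions aligned to gaps are dropped and
    reported.  Alignment identity below ``min_identity`` raises, since
    the transfer is only meaningful between ATG8-family homologs.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for pos in sorted(ref_def.w_site | ref_def.l_site):
        if not (1 <= pos <= len(ref_seq)):
            raise ModelError(
                f"pocket position {pos} outside reference sequence "
                f"{ref_seq.id!r} (length {len(ref_seq)})"
            )

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(ref_seq.sequence, target_seq.sequence)[0]

    # column-wise reference -> target position map (1-based)
    pos_map: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (rs, re_), (ts, te) in zip(*aln.aligned):
        for k in range(re_ - rs):
            ri, ti = rs + k, ts + k
            pos_map[ri + 1] = ti + 1
            aligned_cols += 1
            if ref_seq.sequence[ri] == target_seq.sequence[ti]:
                matches += 1
    identity = matches / max(aligned_cols, 1)
    if identity < min_identity:
        raise ModelError(
            f"alignment identity {identity:.2f} below floor "
            f"{min_identity:.2f}: {target_seq.id!r} does not look like an "
            "ATG8-family homolog of the reference"
        )

    def transfer(site: frozenset[int]) -> tuple[set[int], set[int]]:
        mapped, dropped = set(), set()
        for p in site:
            if p in pos_map:
                mapped.add(pos_map[p])
            else:
                dropped.add(p)
        return mapped, dropped

    w, dw = transfer(ref_def.w_site)
    l, dl = transfer(ref_def.l_site)
    if not w or not l:
        raise EmptyPocketError(
            f"pocket transfer to {target_seq.id!r} left an empty site"
        )
    return PocketMappingReport(
        definition=PocketDefinition(
            receptor_id=target_seq.id,
            w_site=frozenset(w),
            l_site=frozenset(l),
            source="mapped",
        ),
        identity=identity,
        dropped_w=frozenset(dw),
        dropped_l=frozenset(dl),
    )


def pocket_composition(
    pockets: PocketDefinition, receptor: ProteinRecord | Chain
) -> dict[str, dict[str, int]]:
    """Amino-acid composition of each pocket, for eyeballing conservation.

    Pocket cores across the ATG8 family are built largely from F/L/V/I/Y/P
    with polar E/K/C guarding the rim; this report lets users check a
    derived or mapped definition against that expectation.
    """
    if isinstance(receptor, Chain):
        by_pos = {r.position: r.aa for r in receptor.residues}
    else:
        by_pos = {i + 1: aa for i, aa in enumerate(receptor.sequence)}
    out: dict[str, dict[str, int]] = {}
    for name, site in (("w_site", pockets.w_site), ("l_site", pockets.l_site)):
        counts: dict[str, int] = {}
        for p in sorted(site):
            aa = by_pos.get(p, "?")
            counts[aa] = counts.get(aa, 0) + 1
        out[name] = counts
    return out


# --- JSON persistence ------------------------------------------------------

def save_pockets(
    pockets: PocketDefinition, path: str | Path, provenance: str = ""
) -> None:
    payload = {
        "receptor_id": pockets.receptor_id,
        "w_site": sorted(pockets.w_site),
        "l_site": sorted(pockets.l_site),
        "source": pockets.source,
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_pockets(path: str | Path) -> PocketDefinition:
    raw = json.loads(Path(path).read_text())
    return PocketDefinition(
        receptor_id=raw["receptor_id"],
        w_site=frozenset(raw["w_site"]),
        l_site=frozenset(raw["l_site"]),
        source=raw.get("source", "reference-derived"),
    )


def bundled_reference_pockets() -> PocketDefinition:
    """The pocket definition shipped with the package.

    Derived from the bundled synthetic reference complex (see the
    fixtures module); regenerate with ``aimdock pockets`` against any
    real receptor-peptide reference structure to work in that
    structure's own numbering.
    """
    ref = resources.files("aimdock.data") / "reference_pockets.json"
    raw = json.loads(ref.read_text())
    return PocketDefinition(
        receptor_id=raw["receptor_id"],
        w_site=frozenset(raw["w_site"]),
        l_site=frozenset(raw["l_site"]),
        source=raw.get("source", "reference-derived"),
    )
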