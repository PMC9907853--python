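"""Synthetic planted-truth fixtures: complexes, model series, MSAs, sequences.

Everything in this module is synthetic and geometrically idealized.  The
complex generator builds a receptor chain as a straight C-alpha/C-beta
scaffold with two pocket "cages" and places a peptide chain above it so
that the two planted anchor residues — and only they — make heavy-atom
contacts with their cage residues.  That gives exact, manifest-recorded
ground truth for pocket occupancy, docking verdicts, confidence binning
and model ranking, with no download and no physical realism claimed:
these are test articles for deterministic geometric and sequence
computations, not plausible proteins.

The sequence surrogates at the bottom stand in for real validation-set
proteins whose sequences are not redistributable here; each carries its
documented motif loci planted into an aromatic-free background so that a
consensus scan finds exactly the planted windows.  They validate the
scanning machinery and coordinate bookkeeping — counts on a surrogate say
nothing about the real protein.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .complex_interface import Chain, ComplexModel, Residue, write_model
from .conservation import AlignmentSet
from .pocket_atlas import PocketDefinition
from .seqmotif import ProteinRecord

__all__ = [
    "FixtureSpec",
    "ComplexFixture",
    "build_complex_model",
    "make_complex_fixture",
    "make_model_series",
    "make_synthetic_msa",
    "make_surrogate_protein",
    "surrogate_validation_set",
    "SURROGATE_MOTIFS",
]

CA_SPACING = 3.8          # A between consecutive scaffold residues
PEPTIDE_HEIGHT = 6.5      # A, peptide backbone above the receptor line
ANCHOR_DROP = 3.5         # A, anchor side-chain reach below the backbone
CAGE_DX = 1.9             # A, lateral offset of cage atoms
CAGE_DY = 1.5             # A, cage atoms sit above the receptor line

#: Residue types lining real ATG8 pockets; used to label cage residues.
POCKET_RESIDUE_TYPES = "FLVIYPEKC"

#: Background alphabet free of aromatic and hydrophobic anchor classes, so
#: planted motifs are the only consensus matches in generated sequences.
NEUTRAL_ALPHABET = "ADEGKNPQRSTH"

_PRESET_PLDDT = {"uniform_high": 90.0, "uniform_low": 40.0}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic receptor-peptide complex."""

    seed: int = 0
    receptor_length: int = 60
    peptide_sequence: str = "SSSSWEELSSSS"
    planted_register: tuple[int, int] = (5, 8)  # (w_pos, l_pos), 1-based
    displacement_A: float = 0.0
    plddt_profile: str | Sequence[float] = "uniform_high"
    n_models: int = 1
    docked_model_index: int = 1

    def __post_init__(self) -> None:
        w, l = self.planted_register
        n = len(self.peptide_sequence)
        if not (1 <= w < l <= n):
            raise ValueError(
                f"planted register {self.planted_register} outside peptide "
                f"1-{n}"
            )
        if self.displacement_A < 0:
            raise ValueError("displacement must be >= 0")
        if not (1 <= self.docked_model_index <= self.n_models):
            raise ValueError("docked_model_index must be within n_models")


@dataclass(frozen=True)
class ComplexFixture:
    """One generated model plus its planted-truth manifest."""

    model: ComplexModel
    pockets: PocketDefinition
    structure_path: Path | None
    scores_path: Path | None
    manifest: dict


def _plddt_values(spec: FixtureSpec, n: int, rng: np.random.Generator) -> list[float]:
    prof = spec.plddt_profile
    if isinstance(prof, str):
        if prof == "mixed":
            vals = rng.uniform(30.0, 95.0, size=n)
        else:
            try:
                vals = np.full(n, _PRESET_PLDDT[prof])
            except KeyError:
                raise ValueError(
                    f"unknown pLDDT preset {prof!r}; "
                    f"use {sorted(_PRESET_PLDDT)} + ['mixed']"
                ) from None
    else:
        if len(prof) != n:
            raise ValueError(
                f"plddt_profile length {len(prof)} != {n} peptide residues"
            )
        vals = np.asarray(prof, dtype=float)
    return [round(float(v), 2) for v in vals]


def _receptor_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(NEUTRAL_ALPHABET), size=length))


def build_complex_model(
    spec: FixtureSpec, model_index: int = 1, docked: bool | None = None
) -> tuple[ComplexModel, PocketDefinition, dict]:
    """Build one in-memory complex with planted pocket geometry.

    Receptor chain A is a straight scaffold along x; pocket cages sit at
    receptor positions aligned under the planted peptide anchors.  When
    ``docked`` (default: displacement == 0) the anchor side-chain atoms
    land 3.5 A under the peptide backbone, within contact range of
    exactly their own cage atoms; otherwise the whole peptide is rigidly
    translated away by ``displacement_A`` (or 20 A when that field is 0).
    """
    rng = np.random.default_rng([spec.seed, model_index])
    w_pos, l_pos = spec.planted_register
    pep = spec.peptide_sequence.upper()
    sep = l_pos - w_pos

    # receptor cage positions mirror the anchor spacing
    pw = max(3, (spec.receptor_length - sep) // 2)
    pl = pw + sep
    if pl + 2 > spec.receptor_length:
        raise ValueError(
            f"receptor length {spec.receptor_length} too short for anchor "
            f"separation {sep}"
        )
    offset = pw - w_pos  # peptide residue j sits over receptor pos j+offset
    if offset + 1 < 1 or offset + len(pep) > spec.receptor_length:
        raise ValueError(
            "impossible geometry: peptide longer than the scaffold span"
        )

    if docked is None:
        docked = spec.displacement_A == 0.0
    dy = 0.0 if docked else (spec.displacement_A or 20.0)

    rec_seq = list(_receptor_sequence(spec.receptor_length, rng))
    cage_positions = {pw - 1, pw, pw + 1, pl - 1, pl, pl + 1}
    for k, p in enumerate(sorted(cage_positions)):
        rec_seq[p - 1] = POCKET_RESIDUE_TYPES[k % len(POCKET_RESIDUE_TYPES)]

    def x_of(pos: int) -> float:
        return round(CA_SPACING * (pos - 1), 3)

    rec_plddt = 90.0
    receptor_residues = []
    for i in range(1, spec.receptor_length + 1):
        atoms = [("CA", (x_of(i), 0.0, 0.0)), ("CB", (x_of(i), -2.0, 0.0))]
        # cage atoms flank each anchor landing site, pointing inward
        if i == pw - 1:
            atoms.append(("CG", (round(x_of(pw) - CAGE_DX, 3), CAGE_DY, 0.0)))
        if i == pw + 1:
            atoms.append(("CG", (round(x_of(pw) + CAGE_DX, 3), CAGE_DY, 0.0)))
        if i == pl - 1:
            atoms.append(("CG", (round(x_of(pl) - CAGE_DX, 3), CAGE_DY, 0.0)))
        if i == pl + 1:
            atoms.append(("CG", (round(x_of(pl) + CAGE_DX, 3), CAGE_DY, 0.0)))
        receptor_residues.append(
            Residue(i, rec_seq[i - 1], tuple(atoms), rec_plddt)
        )

    pep_plddt = _plddt_values(spec, len(pep), rng)
    peptide_residues = []
    for j in range(1, len(pep) + 1):
        x = x_of(j + offset)
        y = round(PEPTIDE_HEIGHT + dy, 3)
        atoms = [("CA", (x, y, 0.0))]
        if j in (w_pos, l_pos):
            atoms.append(("CB", (x, round(y - ANCHOR_DROP, 3), 0.0)))
        peptide_residues.append(
            Residue(j, pep[j - 1], tuple(atoms), pep_plddt[j - 1])
        )

    model = ComplexModel(
        model_id=f"fixture_seed{spec.seed}_rank_{model_index:03d}",
        rank=model_index,
        chains=(
            Chain("A", tuple(receptor_residues)),
            Chain("B", tuple(peptide_residues)),
        ),
    )
    pockets = PocketDefinition(
        receptor_id="A",
        w_site=frozenset({pw - 1, pw, pw + 1}),
        l_site=frozenset({pl - 1, pl, pl + 1}),
        source="reference-derived",
    )
    manifest = {
        "seed": spec.seed,
        "model_index": model_index,
        "docked": docked,
        "displacement_A": 0.0 if docked else dy,
        "receptor_chain": "A",
        "candidate_chain": "B",
        "planted_w_pos": w_pos,
        "planted_l_pos": l_pos,
        "planted_core": pep[w_pos - 1 : l_pos],
        "separation": sep,
        "w_site": sorted(pockets.w_site),
        "l_site": sorted(pockets.l_site),
        "peptide_plddt": pep_plddt,
        "expected_interface_plddt": round(
            float(np.mean(pep_plddt[w_pos - 1 : l_pos])), 6
        ),
    }
    return model, pockets, manifest


def make_complex_fixture(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> ComplexFixture:
    """Generate one complex fixture, optionally writing AF2-style files.

    When ``out_dir`` is given, writes a ColabFold-style ranked PDB with
    pLDDT in the B-factor column, a scores JSON with the per-residue
    ``plddt`` array, and a ``manifest.json`` recording the planted truth.
    Byte-identical across runs with the same spec.
    """
    model, pockets, manifest = build_complex_model(spec)
    structure_path = scores_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"fixture_seed{spec.seed}_unrelaxed_rank_001"
        structure_path = out_dir / f"{stem}.pdb"
        scores_path = out_dir / f"fixture_seed{spec.seed}_scores_rank_001.json"
        write_model(model, structure_path)
        plddts = [
            r.plddt for ch in model.chains for r in ch.residues
        ]
        scores_path.write_text(
            json.dumps({"plddt": plddts, "ptm": 0.8, "iptm": 0.7}) + "\n"
        )
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return ComplexFixture(model, pockets, structure_path, scores_path, manifest)


def make_model_series(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[list[ComplexFixture], PocketDefinition]:
    """A ranked model series where only ``docked_model_index`` is docked.

    Emulates the situation where the predictor's global rank-1 model
    misses the interface while a lower-ranked model docks the motif
    confidently: the docked model carries a high-confidence peptide,
    undocked ones a low-confidence displaced peptide.
    """
    fixtures = []
    pockets = None
    for idx in range(1, spec.n_models + 1):
        docked = idx == spec.docked_model_index
        sub = FixtureSpec(
            seed=spec.seed,
            receptor_length=spec.receptor_length,
            peptide_sequence=spec.peptide_sequence,
            planted_register=spec.planted_register,
            displacement_A=0.0 if docked else max(spec.displacement_A, 20.0),
            plddt_profile=spec.plddt_profile if docked else "uniform_low",
            n_models=spec.n_models,
            docked_model_index=spec.docked_model_index,
        )
        model, pockets, manifest = build_complex_model(
            sub, model_index=idx, docked=docked
        )
        structure_path = scores_path = None
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            stem = f"fixture_seed{spec.seed}_unrelaxed_rank_{idx:03d}"
            structure_path = out_dir / f"{stem}.pdb"
            write_model(model, structure_path)
            plddts = [r.plddt for ch in model.chains for r in ch.residues]
            scores_path = (
                out_dir / f"fixture_seed{spec.seed}_scores_rank_{idx:03d}.json"
            )
            scores_path.write_text(json.dumps({"plddt": plddts}) + "\n")
        fixtures.append(
            ComplexFixture(model, pockets, structure_path, scores_path, manifest)
        )
    assert pockets is not None
    return fixtures, pockets


# --- synthetic MSAs --------------------------------------------------------

def make_synthetic_msa(
    n_rows: int,
    core: str,
    retain_flags: Sequence[bool],
    seed: int = 0,
    flank: int = 10,
) -> AlignmentSet:
    """A gap-free MSA whose non-reference rows retain or break a motif.

    The reference row carries ``core`` at ungapped position ``flank + 1``.
    Each non-reference row keeps the core verbatim when its flag is true
    and has the aromatic anchor substituted by serine when false.
    Background columns are randomized from the neutral (anchor-free)
    alphabet, so retention is controlled solely by the flags.
    """
    if len(retain_flags) != n_rows - 1:
        raise ValueError("retain_flags must have n_rows - 1 entries")
    rng = np.random.default_rng(seed)
    width = flank * 2 + len(core)

    def background(n: int) -> str:
        return "".join(rng.choice(list(NEUTRAL_ALPHABET), size=n))

    rows = [("REF", background(flank) + core + background(flank))]
    for i, flag in enumerate(retain_flags):
        obs = core if flag else "S" + core[1:]
        rows.append((f"sp{i + 1}", background(flank) + obs + background(flank)))
    assert all(len(s) == width for _, s in rows)
    return AlignmentSet(rows=tuple(rows), reference_id="REF")


# --- sequence surrogates ---------------------------------------------------

def make_surrogate_protein(
    protein_id: str,
    length: int,
    planted: Sequence[tuple[int, str]],
    seed: int = 0,
    organism: str | None = None,
) -> ProteinRecord:
    """SYNTHETIC surrogate sequence with motifs planted at fixed loci.

    The background is drawn from an alphabet containing no aromatic
    (W/Y/F) and no hydrophobic-anchor (L/I/V) residues, so a canonical
    consensus scan of the result reports exactly the planted canonical
    windows at exactly their planted starts.  A stand-in for sequences
    that cannot be redistributed; results on a surrogate characterize
    the scanner, not the protein it is named after.
    """
    rng = np.random.default_rng([seed, len(protein_id), length])
    seq = list(rng.choice(list(NEUTRAL_ALPHABET), size=length))
    occupied: set[int] = set()
    for start, core in planted:
        end = start + len(core) - 1
        if not (1 <= start <= end <= length):
            raise ValueError(
                f"{protein_id}: planted motif {core!r} at {start} outside "
                f"1-{length}"
            )
        span = set(range(start, end + 1))
        if span & occupied:
            raise ValueError(
                f"{protein_id}: planted motifs overlap at {start}"
            )
        occupied |= span
        seq[start - 1 : end] = list(core)
    return ProteinRecord(protein_id, "".join(seq), organism)


def _spread_loci(n: int, length: int, width: int = 4, margin: int = 10) -> list[int]:
    """n non-overlapping 1-based start positions spread over a sequence."""
    usable = length - 2 * margin - width
    step = usable // max(n - 1, 1) if n > 1 else 0
    if n > 1 and step < width + 2:
        raise ValueError(f"cannot fit {n} motifs in length {length}")
    return [margin + 1 + i * step for i in range(n)]


#: Documented motif loci planted into the named surrogates (1-based starts).
SURROGATE_MOTIFS = {
    "NEDD4_surrogate": [(172, "WVVL"), (266, "WEII")],
    "ATI2_surrogate": [(17, "WEVV"), (265, "WQVV")],
    "AtC53_surrogate": [(304, "YEIV"), (335, "WDVSV")],
}

# (id, length, n_canonical_windows) for the anonymous members of the
# 36-protein surrogate battery; counts are construction parameters.
_GENERIC_COUNTS = [10] * 10 + [9] * 19


def surrogate_validation_set(seed: int = 0) -> list[ProteinRecord]:
    """SYNTHETIC 36-protein battery mirroring a canonical validation set.

    Seven named surrogates carry their documented motif loci and window
    counts (ATG7-like 16, NDP52-like 8, RavZ-like 8 with FDLL first,
    PexRD54-like 2 with WEIV last, NEDD4-like WVVL@172 + WEII@266,
    ATI2-like WEVV@17 + WQVV@265, C53-like YEIV@304 + WDVSV@335); 29
    anonymous surrogates fill the battery so canonical windows total 310.
    All sequences are synthetic: the totals validate window counting,
    nothing else.
    """
    records: list[ProteinRecord] = []

    def planted_canonicals(n: int, length: int, rng: np.random.Generator):
        loci = _spread_loci(n, length)
        cores = []
        for i, start in enumerate(loci):
            a = "WYF"[int(rng.integers(3))]
            h = "LIV"[int(rng.integers(3))]
            mid = "".join(rng.choice(list(NEUTRAL_ALPHABET), size=2))
            cores.append((start, a + mid + h))
        return cores

    rng = np.random.default_rng(seed)

    # ATG7-like: 16 canonical windows
    records.append(
        make_surrogate_protein(
            "ATG7_surrogate", 630, planted_canonicals(16, 630, rng), seed
        )
    )
    # NDP52-like: 8 canonical windows
    records.append(
        make_surrogate_protein(
            "NDP52_surrogate", 446, planted_canonicals(8, 446, rng), seed
        )
    )
    # RavZ-like: 8 canonical windows, FDLL the most N-terminal
    loci = _spread_loci(8, 502)
    cores = planted_canonicals(8, 502, rng)
    cores[0] = (loci[0], "FDLL")
    records.append(make_surrogate_protein("RavZ_surrogate", 502, cores, seed))
    # PexRD54-like: 2 canonical windows, functional WEIV C-terminal
    records.append(
        make_surrogate_protein(
            "PexRD54_surrogate", 381, [(120, "YSTL"), (370, "WEIV")], seed
        )
    )
    # NEDD4-like, ATI2-like, C53-like: documented loci
    records.append(
        make_surrogate_protein(
            "NEDD4_surrogate", 900, SURROGATE_MOTIFS["NEDD4_surrogate"], seed
        )
    )
    records.append(
        make_surrogate_protein(
            "ATI2_surrogate", 300, SURROGATE_MOTIFS["ATI2_surrogate"], seed
        )
    )
    records.append(
        make_surrogate_protein(
            "AtC53_surrogate", 549, SURROGATE_MOTIFS["AtC53_surrogate"], seed
        )
    )
    # 29 anonymous battery members
    for i, n in enumerate(_GENERIC_COUNTS):
        length = 200 + 17 * i
        records.append(
            make_surrogate_protein(
                f"battery{i + 1:02d}_surrogate",
                length,
                planted_canonicals(n, length, rng),
                seed,
            )
        )
    return records
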