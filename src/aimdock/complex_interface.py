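"""Interpretation of predicted receptor-candidate complex structures.

A complex predictor (AlphaFold2-multimer / ColabFold) emits ranked models
of an ATG8-family receptor bound to a candidate interactor, with a
per-residue confidence score (pLDDT, 0-100) stored in the B-factor column
and/or a scores JSON.  This module turns those files into motif calls:

* parse models into :class:`ComplexModel` objects;
* compute inter-chain heavy-atom contact maps;
* decide which candidate residue occupies each of the receptor's two
  AIM/LIR docking pockets (the W-site receiving the aromatic anchor and
  the L-site receiving the hydrophobic anchor);
* classify the docked motif as canonical ([W/Y/F]XX[L/I/V], anchor
  separation 3), extended-canonical (canonical anchors, other separation,
  e.g. the five-residue WDVSV), or noncanonical (anchors outside the
  consensus classes, e.g. ILVV, MLVV, YDFM, WxxT);
* score interface confidence as the mean pLDDT over the docked core and
  rank models by it — the model with the most confident motif region is
  more informative than the predictor's global rank-1;
* superpose models onto reference structures (Kabsch least squares).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover
    from .pocket_atlas import PocketDefinition
    from .seqmotif import MotifHit

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Chain",
    "ComplexModel",
    "ContactMap",
    "Occupant",
    "PocketOccupancy",
    "DockingVerdict",
    "ModelError",
    "load_model",
    "write_model",
    "contact_map",
    "pocket_occupancy",
    "call_docked_motif",
    "interface_confidence",
    "bin_plddt",
    "rank_models",
    "superpose_rmsd",
    "kabsch",
    "disorder_context",
]

AROMATIC_ANCHORS = frozenset("WYF")
HYDROPHOBIC_ANCHORS = frozenset("LIV")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEC": "U", "MSE": "M",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}


class ModelError(ValueError):
    """Raised for malformed or unusable complex model files."""


@dataclass(frozen=True)
class Residue:
    """One residue: author position, one-letter code, heavy atoms, pLDDT."""

    position: int
    aa: str
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    plddt: float

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ModelError(f"residue {self.aa}{self.position}: no atoms")
        if not (0.0 <= self.plddt <= 100.0):
            raise ModelError(
                f"residue {self.aa}{self.position}: pLDDT {self.plddt} "
                "outside [0, 100]"
            )

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float)

    def atom(self, name: str) -> np.ndarray | None:
        for nm, xyz in self.atoms:
            if nm == name:
                return np.asarray(xyz, dtype=float)
        return None


@dataclass(frozen=True)
class Chain:
    id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ModelError(f"chain {self.id!r}: no residues")

    def by_position(self) -> dict[int, Residue]:
        return {r.position: r for r in self.residues}

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass(frozen=True)
class ComplexModel:
    """A predicted multi-chain structure with per-residue confidence."""

    model_id: str
    rank: int
    chains: tuple[Chain, ...]
    scores: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ModelError(f"duplicate chain ids in {self.model_id!r}")
        if self.rank < 1:
            raise ModelError(f"rank must be >= 1, got {self.rank}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise ModelError(
            f"chain {chain_id!r} absent from {self.model_id!r} "
            f"(has {[c.id for c in self.chains]})"
        )

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


# --- reading and writing ---------------------------------------------------

_RANK_RE = re.compile(r"rank[_-]?0*(\d+)")


def parse_rank(name: str) -> int:
    """Model rank from ColabFold-style file naming, else 1."""
    m = _RANK_RE.search(name)
    return int(m.group(1)) if m else 1


def load_model(
    structure_path: str | Path, scores_path: str | Path | None = None
) -> ComplexModel:
    """Parse a predicted complex (PDB or mmCIF) into a :class:`ComplexModel`.

    pLDDT is taken from the scores JSON (ColabFold ``plddt`` array, one
    value per residue over all chains in order) when supplied, otherwise
    from the B-factor column.  A disagreement between the two sources is
    resolved in favour of the JSON and logged.  The model rank is parsed
    from ColabFold-style ``rank_N`` file naming when present.
    """
    import gemmi

    structure_path = Path(structure_path)
    st = gemmi.read_structure(str(structure_path))
    st.setup_entities()
    if len(st) == 0:
        raise ModelError(f"{structure_path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = []
            bvals = []
            for atom in gres:
                if atom.element.name == "H":
                    continue
                atoms.append(
                    (atom.name, (atom.pos.x, atom.pos.y, atom.pos.z))
                )
                bvals.append(atom.b_iso)
            if not atoms:
                continue
            plddt = float(bvals[0])
            if not (0.0 <= plddt <= 100.0):
                raise ModelError(
                    f"{structure_path}: residue {gres.name} "
                    f"{gres.seqid.num} in chain {gchain.name}: B-factor "
                    f"{plddt} is not a pLDDT in [0, 100]"
                )
            residues.append(
                Residue(
                    position=gres.seqid.num,
                    aa=_THREE_TO_ONE.get(gres.name.upper(), "X"),
                    atoms=tuple(atoms),
                    plddt=plddt,
                )
            )
        if residues:
            chains.append(Chain(gchain.name, tuple(residues)))

    if len(chains) < 2:
        raise ModelError(
            f"{structure_path}: complex analysis needs >= 2 chains, "
            f"found {len(chains)}"
        )

    scores: dict[str, object] = {}
    cm = ComplexModel(
        model_id=structure_path.stem,
        rank=parse_rank(structure_path.name),
        chains=tuple(chains),
        scores=scores,
    )

    if scores_path is not None:
        with open(scores_path) as fh:
            raw = json.load(fh)
        plddts = raw.get("plddt")
        if plddts is not None:
            if len(plddts) != cm.n_residues():
                raise ModelError(
                    f"{scores_path}: plddt array length {len(plddts)} != "
                    f"{cm.n_residues()} residues"
                )
            it = iter(plddts)
            new_chains = []
            n_mismatch = 0
            for ch in cm.chains:
                new_res = []
                for r in ch.residues:
                    v = float(next(it))
                    if not (0.0 <= v <= 100.0):
                        raise ModelError(
                            f"{scores_path}: pLDDT {v} for residue "
                            f"{r.aa}{r.position} outside [0, 100]"
                        )
                    if not math.isclose(v, r.plddt, abs_tol=0.05):
                        n_mismatch += 1
                    new_res.append(replace(r, plddt=v))
                new_chains.append(Chain(ch.id, tuple(new_res)))
            if n_mismatch:
                logger.warning(
                    "%s: scores JSON disagrees with B-factors at %d "
                    "residues; JSON taken as authoritative",
                    structure_path.name,
                    n_mismatch,
                )
            cm = replace(cm, chains=tuple(new_chains))
        for key in ("ptm", "iptm", "ranking_confidence"):
            if key in raw:
                scores[key] = raw[key]
    return cm


def write_model(model: ComplexModel, path: str | Path) -> None:
    """Write a model as PDB or mmCIF with pLDDT in the B-factor column."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for ch in model.chains:
        gc = gemmi.Chain(ch.id)
        for res in ch.residues:
            gr = gemmi.Residue()
            gr.name = _ONE_TO_THREE.get(res.aa, "UNK")
            gr.seqid = gemmi.SeqId(res.position, " ")
            for name, (x, y, z) in res.atoms:
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0])
                at.pos = gemmi.Position(x, y, z)
                at.b_iso = res.plddt
                at.occ = 1.0
                gr.add_atom(at)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# --- contacts and occupancy ------------------------------------------------

@dataclass(frozen=True)
class ContactMap:
    """Inter-chain residue pairs with min heavy-atom distance <= cutoff."""

    chain_a: str
    chain_b: str
    cutoff_A: float
    pairs: frozenset[tuple[tuple[str, int], tuple[str, int]]]

    def __contains__(self, pair) -> bool:
        a, b = pair
        return (a, b) in self.pairs or (b, a) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def _chain_atom_arrays(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """(coords [n_atoms, 3], residue index per atom)."""
    coords = []
    owner = []
    for i, res in enumerate(chain.residues):
        for _, xyz in res.atoms:
            coords.append(xyz)
            owner.append(i)
    return np.array(coords, dtype=float), np.array(owner, dtype=int)


def contact_map(
    model: ComplexModel, chain_a: str, chain_b: str, cutoff_A: float = 4.5
) -> ContactMap:
    """All inter-chain residue contacts at a heavy-atom distance cutoff."""
    if cutoff_A <= 0:
        raise ValueError("cutoff must be > 0")
    ca, cb = model.chain(chain_a), model.chain(chain_b)
    xa, oa = _chain_atom_arrays(ca)
    xb, ob = _chain_atom_arrays(cb)
    tree = cKDTree(xb)
    pairs = set()
    for ia, ib_list in enumerate(tree.query_ball_point(xa, cutoff_A)):
        for ib in ib_list:
            pairs.add(
                (
                    (chain_a, ca.residues[oa[ia]].position),
                    (chain_b, cb.residues[ob[ib]].position),
                )
            )
    return ContactMap(chain_a, chain_b, cutoff_A, frozenset(pairs))


@dataclass(frozen=True)
class Occupant:
    """The candidate residue engaging one pocket."""

    chain: str
    position: int
    aa: str
    n_contacts: int
    min_distance_A: float


@dataclass(frozen=True)
class PocketOccupancy:
    w_occupant: Occupant | None
    l_occupant: Occupant | None
    receptor_chain: str
    candidate_chain: Chain
    cutoff_A: float


def _pocket_occupant(
    pocket_positions: Iterable[int],
    receptor: Chain,
    candidate: Chain,
    candidate_chain_id: str,
    cutoff: float,
) -> Occupant | None:
    by_pos = receptor.by_position()
    pocket_coords = []
    for p in pocket_positions:
        if p not in by_pos:
            raise ModelError(
                f"pocket position {p} absent from receptor chain "
                f"{receptor.id!r}"
            )
        pocket_coords.append(by_pos[p].coords())
    if not pocket_coords:
        return None
    pocket_xyz = np.vstack(pocket_coords)
    tree = cKDTree(pocket_xyz)

    best: Occupant | None = None
    for res in candidate.residues:
        xyz = res.coords()
        dists, _ = tree.query(xyz)
        n = int(np.sum(tree.query_ball_point(xyz, cutoff, return_length=True)))
        if n == 0:
            continue
        cand = Occupant(
            chain=candidate_chain_id,
            position=res.position,
            aa=res.aa,
            n_contacts=n,
            min_distance_A=float(np.min(dists)),
        )
        if (
            best is None
            or cand.n_contacts > best.n_contacts
            or (
                cand.n_contacts == best.n_contacts
                and cand.min_distance_A < best.min_distance_A
            )
        ):
            # count desc, then min distance asc; residues are visited in
            # ascending position so earlier ties win the final tie-break
            best = cand
    return best


def pocket_occupancy(
    model: ComplexModel,
    pockets: "PocketDefinition",
    receptor_chain: str,
    candidate_chain: str,
    cutoff_A: float = 4.5,
) -> PocketOccupancy:
    """Which candidate residue engages each docking pocket, if any.

    The occupant of a pocket is the candidate residue with the greatest
    number of heavy-atom contacts (pairs within ``cutoff_A``) to the
    pocket's residues; ties are broken by smaller minimum distance, then
    by lower residue position.
    """
    receptor = model.chain(receptor_chain)
    candidate = model.chain(candidate_chain)
    w = _pocket_occupant(
        sorted(pockets.w_site), receptor, candidate, candidate_chain, cutoff_A
    )
    l = _pocket_occupant(
        sorted(pockets.l_site), receptor, candidate, candidate_chain, cutoff_A
    )
    return PocketOccupancy(
        w_occupant=w,
        l_occupant=l,
        receptor_chain=receptor_chain,
        candidate_chain=candidate,
        cutoff_A=cutoff_A,
    )


# --- verdicts --------------------------------------------------------------

@dataclass(frozen=True)
class DockingVerdict:
    """The motif call for one model.

    ``docked`` requires both pockets occupied by residues of the same
    candidate chain with the hydrophobic-anchor position 2 to 6 residues
    downstream of the aromatic-anchor position.  ``motif_class`` is
    ``canonical`` for [W/Y/F]..[L/I/V] anchors at separation 3,
    ``extended-canonical`` for the same anchor classes at another legal
    separation, and ``noncanonical`` otherwise.
    """

    docked: bool
    w_occupant: Occupant | None = None
    l_occupant: Occupant | None = None
    separation: int | None = None
    motif_class: str = "none"
    core_sequence: str | None = None
    interface_plddt: float | None = None
    confidence_bin: str = "none"
    confident_call: bool = False
    reason: str | None = None


def call_docked_motif(
    occupancy: PocketOccupancy,
    min_separation: int = 2,
    max_separation: int = 6,
) -> DockingVerdict:
    """Classify pocket occupancy into a docked-motif verdict."""
    w, l = occupancy.w_occupant, occupancy.l_occupant
    if w is None or l is None:
        missing = [nm for nm, o in (("W", w), ("L", l)) if o is None]
        return DockingVerdict(
            docked=False, w_occupant=w, l_occupant=l,
            reason=f"pocket(s) unoccupied: {','.join(missing)}",
        )
    if w.chain != l.chain:
        return DockingVerdict(
            docked=False, w_occupant=w, l_occupant=l,
            reason=f"occupants on different chains ({w.chain} vs {l.chain})",
        )
    sep = l.position - w.position
    if not (min_separation <= sep <= max_separation):
        return DockingVerdict(
            docked=False, w_occupant=w, l_occupant=l, separation=sep,
            reason=f"anchor separation {sep} outside "
                   f"[{min_separation}, {max_separation}]",
        )
    if w.aa in AROMATIC_ANCHORS and l.aa in HYDROPHOBIC_ANCHORS:
        motif_class = "canonical" if sep == 3 else "extended-canonical"
    else:
        motif_class = "noncanonical"
    by_pos = occupancy.candidate_chain.by_position()
    core = "".join(
        by_pos[p].aa if p in by_pos else "X"
        for p in range(w.position, l.position + 1)
    )
    return DockingVerdict(
        docked=True,
        w_occupant=w,
        l_occupant=l,
        separation=sep,
        motif_class=motif_class,
        core_sequence=core,
    )


def bin_plddt(value: float) -> str:
    """pLDDT bin: (90,100] very_high, (70,90] high, (50,70] low, <=50 very_low."""
    if value > 90:
        return "very_high"
    if value > 70:
        return "high"
    if value > 50:
        return "low"
    return "very_low"


def interface_confidence(
    model: ComplexModel,
    verdict: DockingVerdict,
    confident_above: float = 70.0,
) -> DockingVerdict:
    """Attach mean core pLDDT and its confidence bin to a docked verdict.

    The interface confidence is the arithmetic mean of pLDDT over the
    docked core (aromatic through hydrophobic anchor, inclusive, on the
    candidate chain).  A separate ``confident_call`` flag requires the
    mean to exceed ``confident_above``; confidence is necessary but not
    sufficient for a true interaction, so the verdict itself is reported
    regardless.
    """
    if not verdict.docked:
        return replace(verdict, interface_plddt=None, confidence_bin="none")
    assert verdict.w_occupant is not None and verdict.l_occupant is not None
    chain = model.chain(verdict.w_occupant.chain)
    by_pos = chain.by_position()
    vals = [
        by_pos[p].plddt
        for p in range(verdict.w_occupant.position,
                       verdict.l_occupant.position + 1)
        if p in by_pos
    ]
    if not vals:
        raise ModelError("no candidate residues under the docked core")
    mean = float(np.mean(vals))
    return replace(
        verdict,
        interface_plddt=mean,
        confidence_bin=bin_plddt(mean),
        confident_call=mean > confident_above,
    )


def rank_models(
    models: Sequence[ComplexModel],
    pockets: "PocketDefinition",
    receptor_chain: str,
    candidate_chain: str,
    cutoff_A: float = 4.5,
) -> list[tuple[ComplexModel, DockingVerdict]]:
    """Order models by how informative their motif interface is.

    Docked models come first, sorted by interface pLDDT descending (ties:
    original predictor rank ascending); undocked models follow in original
    rank order.  This surfaces a low-ranked model whose motif region is
    confidently docked ahead of a global rank-1 model that is not — the
    global score can be dominated by regions far from the interface.
    """
    if not models:
        raise ValueError("need at least one model")
    scored = []
    for m in models:
        occ = pocket_occupancy(
            m, pockets, receptor_chain, candidate_chain, cutoff_A
        )
        v = interface_confidence(m, call_docked_motif(occ))
        scored.append((m, v))
    docked = [t for t in scored if t[1].docked]
    undocked = [t for t in scored if not t[1].docked]
    docked.sort(key=lambda t: (-t[1].interface_plddt, t[0].rank))
    undocked.sort(key=lambda t: t[0].rank)
    return docked + undocked


# --- superposition ---------------------------------------------------------

def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of two point sets (least squares).

    Returns ``(rmsd, rotation, translation)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("point sets must have identical (n, 3) shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need >= 3 point pairs for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    p, q = mobile - mc, reference - rc
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return rmsd, rot, rc - mc @ rot.T  # translation in fitted frame


def superpose_rmsd(
    mobile_chain: Chain,
    reference_chain: Chain,
    residue_mapping: Sequence[tuple[int, int]] | None = None,
) -> float:
    """C-alpha RMSD after optimal rigid-body superposition.

    ``residue_mapping`` pairs mobile positions with reference positions;
    by default positions shared by both chains are paired identically.
    """
    mob, ref = mobile_chain.by_position(), reference_chain.by_position()
    if residue_mapping is None:
        residue_mapping = [(p, p) for p in sorted(set(mob) & set(ref))]
    pm, pr = [], []
    for mp, rp in residue_mapping:
        if mp not in mob or rp not in ref:
            raise ModelError(f"mapped pair ({mp}, {rp}) missing a residue")
        a, b = mob[mp].atom("CA"), ref[rp].atom("CA")
        if a is None or b is None:
            continue
        pm.append(a)
        pr.append(b)
    if len(pm) < 3:
        raise ModelError(
            f"superposition needs >= 3 mapped C-alpha pairs, got {len(pm)}"
        )
    rmsd, _, _ = kabsch(np.array(pm), np.array(pr))
    return rmsd


# --- disorder context ------------------------------------------------------

def disorder_context(
    monomer_plddt: Mapping[int, float] | Sequence[float],
    hit: "MotifHit",
    disorder_below: float = 50.0,
    order_above: float = 70.0,
) -> str:
    """Structural context of a motif window from monomer confidence.

    Low single-chain pLDDT is a practical proxy for intrinsic disorder,
    the typical sequence context of functional AIM/LIRs.  Returns
    ``disordered`` when every core residue scores below ``disorder_below``,
    ``ordered`` when every one scores at or above ``order_above``, and
    ``partially_disordered`` otherwise.
    """
    if isinstance(monomer_plddt, Mapping):
        getter = monomer_plddt
        have = set(monomer_plddt)
    else:
        getter = {i + 1: v for i, v in enumerate(monomer_plddt)}
        have = set(getter)
    wanted = set(range(hit.start, hit.end + 1))
    if not wanted <= have:
        raise ValueError(
            f"pLDDT coverage missing positions {sorted(wanted - have)}"
        )
    vals = [getter[p] for p in sorted(wanted)]
    if all(v < disorder_below for v in vals):
        return "disordered"
    if all(v >= order_above for v in vals):
        return "ordered"
    return "partially_disordered"
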