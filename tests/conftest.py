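"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: the
scan oracle tests windows character by character, the contact oracle
loops over every atom pair, and superposition is cross-checked against
scipy's rotation fitting.
"""

from __future__ import annotations

import numpy as np
import pytest

from aimdock.complex_interface import Chain, ComplexModel, Residue
from aimdock.fixtures import FixtureSpec, make_complex_fixture
from aimdock.seqmotif import MotifPattern, ProteinRecord


# --- independent oracles ---------------------------------------------------

def brute_force_scan(sequence: str, pattern: MotifPattern):
    """Every (start, end, core) whose residues satisfy the classes."""
    seq = sequence.upper()
    k = len(pattern.position_classes)
    out = []
    for i in range(len(seq) - k + 1):
        ok = True
        for j, cls in enumerate(pattern.position_classes):
            if seq[i + j] not in cls:
                ok = False
                break
        if ok:
            out.append((i + 1, i + k, seq[i : i + k]))
    return out


def brute_force_contacts(model: ComplexModel, ca: str, cb: str, cutoff: float):
    """All inter-chain residue pairs by exhaustive atom-pair scan."""
    a, b = model.chain(ca), model.chain(cb)
    pairs = set()
    for ra in a.residues:
        for rb in b.residues:
            hit = False
            for _, xa in ra.atoms:
                for _, xb in rb.atoms:
                    d = np.linalg.norm(np.subtract(xa, xb))
                    if d <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add(((ca, ra.position), (cb, rb.position)))
    return pairs


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def transform_model(
    model: ComplexModel, rot: np.ndarray, shift: np.ndarray
) -> ComplexModel:
    """Apply one rigid transform to every atom of every chain."""
    chains = []
    for ch in model.chains:
        residues = []
        for r in ch.residues:
            atoms = tuple(
                (name, tuple(rot @ np.asarray(xyz) + shift))
                for name, xyz in r.atoms
            )
            residues.append(Residue(r.position, r.aa, atoms, r.plddt))
        chains.append(Chain(ch.id, tuple(residues)))
    return ComplexModel(model.model_id, model.rank, tuple(chains), model.scores)


# --- hand-built model helper ----------------------------------------------

def make_model(chain_spec: dict, model_id: str = "hand", rank: int = 1):
    """Build a ComplexModel from {chain_id: [(pos, aa, atoms, plddt), ...]}.

    ``atoms`` may be a bare xyz triple (becomes a single CA atom) or a
    list of (name, xyz) pairs.
    """
    chains = []
    for cid, residues in chain_spec.items():
        rs = []
        for pos, aa, atoms, plddt in residues:
            if isinstance(atoms, tuple) and len(atoms) == 3 and not isinstance(
                atoms[0], (tuple, list)
            ):
                atoms = [("CA", atoms)]
            rs.append(
                Residue(pos, aa, tuple((n, tuple(x)) for n, x in atoms), plddt)
            )
        chains.append(Chain(cid, tuple(rs)))
    return ComplexModel(model_id, rank, tuple(chains))


# --- fixtures --------------------------------------------------------------

@pytest.fixture(scope="session")
def docked_fixture():
    return make_complex_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def decoy_fixture():
    return make_complex_fixture(FixtureSpec(seed=11, displacement_A=20.0))


@pytest.fixture()
def toy_record():
    return ProteinRecord("toy", "ADEKWAALSDTE")
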