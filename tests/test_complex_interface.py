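"""Model parsing, contacts, occupancy, verdicts, confidence, superposition."""

import json
import math

import numpy as np
import pytest

from aimdock.complex_interface import (
    Chain,
    ModelError,
    Occupant,
    PocketOccupancy,
    Residue,
    bin_plddt,
    call_docked_motif,
    contact_map,
    disorder_context,
    interface_confidence,
    kabsch,
    load_model,
    parse_rank,
    pocket_occupancy,
    rank_models,
    superpose_rmsd,
    write_model,
)
from aimdock.fixtures import FixtureSpec, build_complex_model, make_complex_fixture, make_model_series
from aimdock.pocket_atlas import PocketDefinition
from aimdock.seqmotif import MotifHit

from conftest import (
    brute_force_contacts,
    make_model,
    random_rotation,
    transform_model,
)


class TestLoadModel:
    def test_bfactor_becomes_plddt(self, tmp_path, docked_fixture):
        path = tmp_path / "m_rank_001.pdb"
        write_model(docked_fixture.model, path)
        m = load_model(path)
        assert all(
            r.plddt == pytest.approx(orig.plddt)
            for ch, och in zip(m.chains, docked_fixture.model.chains)
            for r, orig in zip(ch.residues, och.residues)
        )

    def test_scores_json_wins_over_bfactors(self, tmp_path, docked_fixture):
        path = tmp_path / "m_rank_001.pdb"
        write_model(docked_fixture.model, path)
        n = docked_fixture.model.n_residues()
        scores = tmp_path / "scores.json"
        scores.write_text(json.dumps({"plddt": [55.5] * n, "iptm": 0.66}))
        m = load_model(path, scores)
        assert {r.plddt for ch in m.chains for r in ch.residues} == {55.5}
        assert m.scores["iptm"] == 0.66

    def test_mmcif_round_trip(self, tmp_path, docked_fixture):
        path = tmp_path / "m_rank_002.cif"
        write_model(docked_fixture.model, path)
        m = load_model(path)
        assert m.rank == 2
        for ch, och in zip(m.chains, docked_fixture.model.chains):
            assert ch.id == och.id
            for r, orig in zip(ch.residues, och.residues):
                assert (r.position, r.aa) == (orig.position, orig.aa)
                assert np.allclose(r.coords(), orig.coords(), atol=1e-3)

    def test_single_chain_rejected(self, tmp_path):
        model = make_model(
            {"A": [(1, "G", (0.0, 0.0, 0.0), 50.0),
                   (2, "G", (3.8, 0.0, 0.0), 50.0)]}
        )
        # bypass the two-chain writer check by writing directly
        path = tmp_path / "single.pdb"
        import gemmi

        st = gemmi.Structure()
        gm = gemmi.Model("1")
        gc = gemmi.Chain("A")
        gr = gemmi.Residue()
        gr.name = "GLY"
        gr.seqid = gemmi.SeqId(1, " ")
        at = gemmi.Atom()
        at.name = "CA"
        at.element = gemmi.Element("C")
        at.pos = gemmi.Position(0, 0, 0)
        at.b_iso = 50.0
        gr.add_atom(at)
        gc.add_residue(gr)
        gm.add_chain(gc)
        st.add_model(gm)
        st.write_pdb(str(path))
        with pytest.raises(ModelError, match="2 chains"):
            load_model(path)

    def test_out_of_range_plddt_names_residue(self, tmp_path, docked_fixture):
        path = tmp_path / "m.pdb"
        write_model(docked_fixture.model, path)
        scores = tmp_path / "scores.json"
        bad = [90.0] * docked_fixture.model.n_residues()
        bad[3] = 140.0
        scores.write_text(json.dumps({"plddt": bad}))
        with pytest.raises(ModelError, match=r"\[0, 100\]"):
            load_model(path, scores)

    @pytest.mark.parametrize(
        "name, rank",
        [
            ("x_unrelaxed_rank_003_model.pdb", 3),
            ("x_rank-12.pdb", 12),
            ("plain.pdb", 1),
        ],
    )
    def test_colabfold_rank_parsing(self, name, rank):
        assert parse_rank(name) == rank


class TestContactMap:
    def _two_atom_model(self, d):
        return make_model(
            {
                "A": [(1, "G", (0.0, 0.0, 0.0), 50.0)],
                "B": [(1, "G", (d, 0.0, 0.0), 50.0)],
            }
        )

    def test_just_inside_cutoff(self):
        cm = contact_map(self._two_atom_model(4.4), "A", "B", 4.5)
        assert len(cm) == 1
        assert (("A", 1), ("B", 1)) in cm
        assert (("B", 1), ("A", 1)) in cm  # symmetric membership

    def test_just_outside_cutoff(self):
        cm = contact_map(self._two_atom_model(4.6), "A", "B", 4.5)
        assert len(cm) == 0

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(7)
        chains = {}
        for cid in "AB":
            chains[cid] = [
                (
                    i + 1,
                    "G",
                    [("CA", tuple(rng.uniform(0, 25, 3))),
                     ("CB", tuple(rng.uniform(0, 25, 3)))],
                    50.0,
                )
                for i in range(50)
            ]
        model = make_model(chains)
        cm = contact_map(model, "A", "B", 4.5)
        assert set(cm.pairs) == brute_force_contacts(model, "A", "B", 4.5)

    def test_unknown_chain(self, docked_fixture):
        with pytest.raises(ModelError):
            contact_map(docked_fixture.model, "A", "Q")


class TestPocketOccupancy:
    def test_planted_anchors_recovered(self, docked_fixture):
        man = docked_fixture.manifest
        occ = pocket_occupancy(
            docked_fixture.model, docked_fixture.pockets, "A", "B"
        )
        assert occ.w_occupant.position == man["planted_w_pos"]
        assert occ.l_occupant.position == man["planted_l_pos"]

    def test_displaced_peptide_contacts_nothing(self, decoy_fixture):
        occ = pocket_occupancy(
            decoy_fixture.model, decoy_fixture.pockets, "A", "B"
        )
        assert occ.w_occupant is None and occ.l_occupant is None

    def test_contact_count_tie_broken_by_min_distance(self):
        # two candidate residues each make one contact; res 2 is closer
        model = make_model(
            {
                "A": [(10, "F", (0.0, 0.0, 0.0), 90.0)],
                "B": [
                    (1, "W", (4.0, 0.0, 0.0), 80.0),
                    (2, "Y", (0.0, 3.0, 0.0), 80.0),
                ],
            }
        )
        pockets = PocketDefinition("A", frozenset({10}), frozenset({10}))
        occ = pocket_occupancy(model, pockets, "A", "B", cutoff_A=4.5)
        assert occ.w_occupant.position == 2
        assert occ.w_occupant.min_distance_A == pytest.approx(3.0)

    def test_full_tie_goes_to_lower_position(self):
        model = make_model(
            {
                "A": [(10, "F", (0.0, 0.0, 0.0), 90.0)],
                "B": [
                    (1, "W", (0.0, 3.0, 0.0), 80.0),
                    (2, "Y", (0.0, -3.0, 0.0), 80.0),
                ],
            }
        )
        pockets = PocketDefinition("A", frozenset({10}), frozenset({10}))
        occ = pocket_occupancy(model, pockets, "A", "B")
        assert occ.w_occupant.position == 1


def _occ(w, l, chain_obj=None):
    if chain_obj is None:
        chain_obj = Chain(
            "B",
            tuple(
                Residue(p, aa, (("CA", (float(p), 0.0, 0.0)),), 80.0)
                for p, aa in enumerate("SWEELSS", start=1)
            ),
        )
    return PocketOccupancy(w, l, "A", chain_obj, 4.5)


def _occupant(pos, aa, chain="B"):
    return Occupant(chain, pos, aa, n_contacts=3, min_distance_A=3.0)


class TestCallDockedMotif:
    def test_canonical_core(self):
        occ = _occ(_occupant(2, "W"), _occupant(5, "L"))
        v = call_docked_motif(occ)
        assert v.docked and v.motif_class == "canonical"
        assert v.core_sequence == "WEEL"
        assert v.separation == 3

    def test_extended_canonical_wdvsv(self):
        chain = Chain(
            "B",
            tuple(
                Residue(p, aa, (("CA", (float(p), 0.0, 0.0)),), 80.0)
                for p, aa in enumerate("WDVSV", start=335)
            ),
        )
        occ = _occ(_occupant(335, "W"), _occupant(339, "V"), chain)
        v = call_docked_motif(occ)
        assert v.docked and v.motif_class == "extended-canonical"
        assert v.core_sequence == "WDVSV"
        assert v.separation == 4

    @pytest.mark.parametrize(
        "core, w_aa, l_aa",
        [("ILVV", "I", "V"), ("MLVV", "M", "V"), ("YDFM", "Y", "M"),
         ("WLAT", "W", "T")],
    )
    def test_noncanonical_anchors(self, core, w_aa, l_aa):
        chain = Chain(
            "B",
            tuple(
                Residue(p, aa, (("CA", (float(p), 0.0, 0.0)),), 80.0)
                for p, aa in enumerate(core, start=1)
            ),
        )
        occ = _occ(_occupant(1, w_aa), _occupant(4, l_aa), chain)
        v = call_docked_motif(occ)
        assert v.docked and v.motif_class == "noncanonical"
        assert v.core_sequence == core

    def test_single_pocket_not_docked(self):
        v = call_docked_motif(_occ(_occupant(2, "W"), None))
        assert not v.docked and "unoccupied" in v.reason

    def test_cross_chain_occupants_not_docked(self):
        v = call_docked_motif(
            _occ(_occupant(2, "W", "B"), _occupant(5, "L", "C"))
        )
        assert not v.docked and "different chains" in v.reason

    def test_separation_bounds(self):
        v = call_docked_motif(_occ(_occupant(2, "W"), _occupant(3, "E")))
        assert not v.docked and "separation" in v.reason


class TestInterfaceConfidence:
    def _model_with_core_plddt(self, values):
        spec = FixtureSpec(
            seed=5,
            peptide_sequence="SSSSWEELSSSS",
            planted_register=(5, 8),
            plddt_profile=[70.0] * 4 + list(values) + [70.0] * 4,
        )
        model, pockets, _ = build_complex_model(spec)
        occ = pocket_occupancy(model, pockets, "A", "B")
        return model, call_docked_motif(occ)

    @pytest.mark.parametrize(
        "values, mean, bin_",
        [
            ([95.0] * 4, 95.0, "very_high"),
            ([60.0, 70.0, 80.0, 90.0], 75.0, "high"),
            ([50.0] * 4, 50.0, "very_low"),  # 50 falls in the lowest bin
        ],
    )
    def test_mean_and_bin(self, values, mean, bin_):
        model, verdict = self._model_with_core_plddt(values)
        v = interface_confidence(model, verdict)
        assert v.interface_plddt == pytest.approx(mean)
        assert v.confidence_bin == bin_
        assert min(values) <= v.interface_plddt <= max(values)

    def test_undocked_gets_none_bin(self, decoy_fixture):
        occ = pocket_occupancy(
            decoy_fixture.model, decoy_fixture.pockets, "A", "B"
        )
        v = interface_confidence(decoy_fixture.model, call_docked_motif(occ))
        assert v.interface_plddt is None and v.confidence_bin == "none"

    def test_confident_call_threshold(self):
        model, verdict = self._model_with_core_plddt([72.0] * 4)
        assert interface_confidence(model, verdict).confident_call
        model, verdict = self._model_with_core_plddt([50.0] * 4)
        assert not interface_confidence(model, verdict).confident_call

    def test_bin_boundaries_half_open(self):
        assert bin_plddt(90.0) == "high"
        assert bin_plddt(90.01) == "very_high"
        assert bin_plddt(70.0) == "low"
        assert bin_plddt(50.0) == "very_low"


class TestRankModels:
    def test_docked_rank3_surfaces_first(self):
        fixtures, pockets = make_model_series(
            FixtureSpec(seed=6, n_models=5, docked_model_index=3)
        )
        ranked = rank_models([f.model for f in fixtures], pockets, "A", "B")
        assert ranked[0][0].rank == 3
        assert ranked[0][1].docked
        assert [m.rank for m, _ in ranked[1:]] == [1, 2, 4, 5]

    def test_all_undocked_keeps_original_order(self):
        fixtures, pockets = make_model_series(
            FixtureSpec(seed=6, n_models=4, docked_model_index=1)
        )
        models = [f.model for f in fixtures[1:]]  # drop the docked one
        ranked = rank_models(models, pockets, "A", "B")
        assert [m.rank for m, _ in ranked] == [2, 3, 4]
        assert not any(v.docked for _, v in ranked)

    def test_equal_confidence_tie_prefers_lower_rank(self):
        specs = [
            FixtureSpec(seed=6, plddt_profile="uniform_high"),
            FixtureSpec(seed=6, plddt_profile="uniform_high"),
        ]
        models = []
        pockets = None
        for idx, s in enumerate(specs, start=1):
            m, pockets, _ = build_complex_model(s, model_index=idx)
            models.append(m)
        ranked = rank_models(models[::-1], pockets, "A", "B")
        assert [m.rank for m, _ in ranked] == [1, 2]


class TestSuperposition:
    def test_identity_is_zero(self, docked_fixture):
        ch = docked_fixture.model.chain("A")
        assert superpose_rmsd(ch, ch) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_zero(self, docked_fixture):
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        moved = transform_model(
            docked_fixture.model, rot, rng.uniform(-30, 30, 3)
        )
        rmsd = superpose_rmsd(
            moved.chain("A"), docked_fixture.model.chain("A")
        )
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_toy_displacement_matches_scipy_oracle(self):
        from scipy.spatial.transform import Rotation

        ref = np.array(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], dtype=float
        )
        mob = ref.copy()
        mob[3] += [1.0, 0.0, 0.0]
        rmsd, _, _ = kabsch(mob, ref)
        # independent fit: scipy aligns centred vectors by rotation
        mc, rc = mob - mob.mean(0), ref - ref.mean(0)
        rot, _ = Rotation.align_vectors(rc, mc)
        expected = float(
            np.sqrt(np.mean(np.sum((rot.apply(mc) - rc) ** 2, axis=1)))
        )
        assert rmsd == pytest.approx(expected, abs=1e-9)
        assert 0 < rmsd < 1.0

    def test_optimal_fit_beats_arbitrary_rotations(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(-10, 10, (8, 3))
        mob = ref + rng.normal(0, 0.5, (8, 3))
        best, _, _ = kabsch(mob, ref)
        mc, rc = mob - mob.mean(0), ref - ref.mean(0)
        for _ in range(50):
            r = random_rotation(rng)
            trial = float(
                np.sqrt(np.mean(np.sum((mc @ r.T - rc) ** 2, axis=1)))
            )
            assert best <= trial + 1e-12

    def test_too_few_pairs_rejected(self):
        ch = Chain(
            "A",
            tuple(
                Residue(p, "G", (("CA", (float(p), 0.0, 0.0)),), 50.0)
                for p in (1, 2)
            ),
        )
        with pytest.raises(ModelError, match=">= 3"):
            superpose_rmsd(ch, ch)


class TestDisorderContext:
    HIT = MotifHit("p", 2, 5, "WEEL", "canonical")

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([40, 35, 42, 48], "disordered"),
            ([80, 85, 90, 75], "ordered"),
            ([40, 80, 45, 60], "partially_disordered"),
        ],
    )
    def test_rule(self, values, expected):
        plddt = {i + 2: v for i, v in enumerate(values)}
        assert disorder_context(plddt, self.HIT) == expected

    def test_missing_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            disorder_context({2: 40.0, 3: 40.0}, self.HIT)


class TestRigidInvariance:
    def test_verdict_stable_under_random_rigid_transforms(self, docked_fixture):
        rng = np.random.default_rng(17)
        occ0 = pocket_occupancy(
            docked_fixture.model, docked_fixture.pockets, "A", "B"
        )
        base = call_docked_motif(occ0)
        for _ in range(10):
            moved = transform_model(
                docked_fixture.model,
                random_rotation(rng),
                rng.uniform(-50, 50, 3),
            )
            occ = pocket_occupancy(
                moved, docked_fixture.pockets, "A", "B"
            )
            v = call_docked_motif(occ)
            assert (v.docked, v.motif_class, v.core_sequence) == (
                base.docked, base.motif_class, base.core_sequence
            )
            assert v.w_occupant.position == base.w_occupant.position
            assert v.l_occupant.position == base.l_occupant.position
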