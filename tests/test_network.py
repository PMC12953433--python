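import json

import numpy as np
import pytest

from bmca.network import (
    LinkMatrix,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ReferenceState,
    load_model,
    reduce_model,
    remove_conserved_moieties,
    save_model_json,
)

CHAIN_JSON = {
    "metabolites": [
        {"id": "A_ext", "compartment": "e"},
        {"id": "B_ext", "compartment": "e"},
        {"id": "A"},
        {"id": "B"},
    ],
    "external": ["A_ext", "B_ext"],
    "reactions": [
        {"id": "r1", "stoichiometry": {"A_ext": -1, "A": 1}, "protein_ids": ["p1"]},
        {"id": "r2", "stoichiometry": {"A": -1, "B": 1}, "protein_ids": ["p2"]},
        {"id": "r3", "stoichiometry": {"B": -1, "B_ext": 1}},
    ],
    "target_reaction": "r3",
}


def _sbml_chain() -> str:
    """The same 3-reaction chain as SBML level 3 with fbc gene products."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    doc.enablePackage(libsbml.FbcExtension.getXmlnsL3V1V2(), "fbc", True)
    doc.setPackageRequired("fbc", False)
    m = doc.createModel("chain")
    mplug = m.getPlugin("fbc")
    mplug.setStrict(False)
    for cid in ("c", "e"):
        comp = m.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for sid, comp, bnd in (("A_ext", "e", True), ("B_ext", "e", True),
                           ("A", "c", False), ("B", "c", False)):
        sp = m.createSpecies()
        sp.setId(sid)
        sp.setCompartment(comp)
        sp.setBoundaryCondition(bnd)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
    for pid in ("p1", "p2"):
        gp = mplug.createGeneProduct()
        gp.setId(pid)
        gp.setLabel(pid)
    for rid, sub, prod, gene in (("r1", "A_ext", "A", "p1"),
                                 ("r2", "A", "B", "p2"),
                                 ("r3", "B", "B_ext", None)):
        rx = m.createReaction()
        rx.setId(rid)
        rx.setReversible(False)
        rx.setFast(False)
        sr = rx.createReactant()
        sr.setSpecies(sub)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        sr = rx.createProduct()
        sr.setSpecies(prod)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        if gene:
            gpa = rx.getPlugin("fbc").createGeneProductAssociation()
            ref = gpa.createGeneProductRef()
            ref.setGeneProduct(gene)
    return libsbml.writeSBMLToString(doc)


class TestLoadModel:
    def test_json_chain_counts(self, tmp_path):
        p = tmp_path / "chain.json"
        p.write_text(json.dumps(CHAIN_JSON))
        model = load_model(p, "json")
        assert model.n_internal == 2
        assert model.N.shape == (2, 3)
        assert model.reaction_ids == ["r1", "r2", "r3"]
        # exchange flag derived from external participation
        assert model.reaction("r1").is_exchange
        assert not model.reaction("r2").is_exchange

    def test_undeclared_metabolite_rejected(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["reactions"][0]["stoichiometry"]["GHOST"] = 1
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="undeclared"):
            load_model(p, "json")

    def test_missing_target_rejected(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["target_reaction"] = "nope"
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="target"):
            load_model(p, "json")

    def test_parse_failure(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ModelValidationError, match="parse"):
            load_model(p, "json")

    def test_sbml_and_json_dialects_agree(self, tmp_path):
        pj = tmp_path / "chain.json"
        pj.write_text(json.dumps(CHAIN_JSON))
        ps = tmp_path / "chain.xml"
        ps.write_text(_sbml_chain())
        mj = load_model(pj, "json")
        ms = load_model(ps, "sbml", target_reaction_id="r3")
        assert mj.reaction_ids == ms.reaction_ids
        assert mj.internal_ids == ms.internal_ids
        assert mj.external_ids == ms.external_ids
        np.testing.assert_array_equal(mj.N, ms.N)
        assert mj.reaction("r1").protein_ids == ms.reaction("r1").protein_ids

    def test_json_round_trip_bit_identical(self, tmp_path, chain3_model):
        p1 = tmp_path / "a.json"
        save_model_json(chain3_model, p1)
        again = load_model(p1, "json")
        np.testing.assert_array_equal(chain3_model.N, again.N)
        p2 = tmp_path / "b.json"
        save_model_json(again, p2)
        assert p1.read_text() == p2.read_text()


class TestReduceModel:
    @pytest.fixture
    def branched5(self):
        mets = [
            Metabolite(id="S_ext", role="external"),
            Metabolite(id="P_ext", role="external"),
            Metabolite(id="Q_ext", role="external"),
            Metabolite(id="A"),
            Metabolite(id="B"),
        ]
        rxns = [
            Reaction("r1", {"S_ext": -1, "A": 1}),
            Reaction("r2", {"A": -1, "P_ext": 1}),
            Reaction("r3", {"A": -1, "B": 1}),   # dead branch
            Reaction("r4", {"B": -1, "Q_ext": 1}),
            Reaction("r5", {"S_ext": -1, "A": 1}),
        ]
        return MetabolicModel(metabolites=mets, reactions=rxns,
                              target_reaction_id="r2")

    def test_zero_branch_dropped(self, branched5):
        flux = np.array([0.6, 1.0, 0.0, 0.0, 0.4])  # order r1..r5
        red, v = reduce_model(branched5, flux)
        assert red.n_reactions == 3
        assert "B" not in red.internal_ids
        assert "Q_ext" not in red.external_ids
        assert np.all(np.abs(v) > 1e-9)

    def test_all_nonzero_is_identity(self, chain3_model):
        red, v = reduce_model(chain3_model, np.ones(3))
        assert red.reaction_ids == chain3_model.reaction_ids
        np.testing.assert_array_equal(red.N, chain3_model.N)

    def test_zero_target_rejected(self, branched5):
        with pytest.raises(ModelValidationError, match="target"):
            reduce_model(branched5, np.array([1.0, 0.0, 0.5, 0.5, -1.0]))

    def test_reduction_idempotent(self, branched5):
        flux = np.array([0.6, 1.0, 0.0, 0.0, 0.4])
        red, v = reduce_model(branched5, flux)
        red2, v2 = reduce_model(red, v)
        assert red2.reaction_ids == red.reaction_ids
        np.testing.assert_array_equal(red2.N, red.N)

    def test_steady_state_preserved_after_reduction(self):
        truth = __import__("bmca.synth", fromlist=["make_toy_network"]).make_toy_network(
            "random", size=12, seed=7)
        model, v = truth.model, truth.ref.v_star
        # zero out nothing: reduction keeps the balanced flux balanced
        red, vr = reduce_model(model, v)
        assert np.abs(red.N @ vr).max() <= 1e-9


class TestConservedMoieties:
    def test_moiety_pair_removed(self):
        # ATP/ADP-like pair cycling between two reactions: their rows sum to 0
        mets = [
            Metabolite(id="S_ext", role="external"),
            Metabolite(id="P_ext", role="external"),
            Metabolite(id="A"),
            Metabolite(id="ATP"),
            Metabolite(id="ADP"),
        ]
        rxns = [
            Reaction("r1", {"S_ext": -1, "A": 1, "ATP": -1, "ADP": 1}),
            Reaction("r2", {"A": -1, "P_ext": 1}),
            Reaction("r3", {"ADP": -1, "ATP": 1}),  # regeneration loop
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns,
                               target_reaction_id="r2")
        red, link = remove_conserved_moieties(model)
        assert len(link.dropped_ids) == 1
        assert np.linalg.matrix_rank(red.N) == red.N.shape[0]
        # the link matrix reconstructs the original rows
        full_rows = {m: i for i, m in enumerate(model.internal_ids)}
        recon = link.L @ red.N
        np.testing.assert_allclose(recon, model.N, atol=1e-12)

    def test_full_rank_identity_link(self, chain3_model):
        red, link = remove_conserved_moieties(chain3_model)
        assert link.dropped_ids == []
        np.testing.assert_array_equal(link.L, np.eye(2))
        np.testing.assert_array_equal(red.N, chain3_model.N)

    def test_zero_matrix_rejected(self):
        mets = [Metabolite(id="X_ext", role="external"),
                Metabolite(id="Y_ext", role="external")]
        rxns = [Reaction("r1", {"X_ext": -1, "Y_ext": 1})]
        model = MetabolicModel(metabolites=mets, reactions=rxns,
                               target_reaction_id="r1")
        with pytest.raises(ModelValidationError):
            remove_conserved_moieties(model)


def test_reference_state_validation(chain3_model):
    ref = ReferenceState.from_fluxes(chain3_model, np.array([1.0, 1.0, 1.0]))
    ref.validate(chain3_model)
    bad = ReferenceState.from_fluxes(chain3_model, np.array([1.0, 2.0, 1.0]))
    with pytest.raises(ModelValidationError, match="steady state"):
        bad.validate(chain3_model)
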