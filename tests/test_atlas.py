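"""Atlas loading, reaction-map validation, and carbon-provenance tracing."""

import random

import networkx as nx
import pytest
import yaml

from ergolabel.atlas import (
    Atlas,
    AtlasValidationError,
    MoleculeSpec,
    PathwayRoute,
    ReactionMap,
    RouteError,
    Transition,
    load_atlas,
    packaged_atlas_path,
    trace_origin,
    unit_positions,
    validate_reaction,
)


class TestLoading:
    def test_packaged_atlas_validates(self, atlas):
        assert len(atlas.routes) == 2
        assert {"MVA", "MEP"} == set(atlas.routes)

    def test_ergosterol_skeleton_is_connected(self, ergosterol):
        g = nx.Graph(list(ergosterol.skeleton_bonds))
        assert g.number_of_nodes() == 28
        assert nx.is_connected(g)
        # four fused rings: |E| = |V| - 1 + 4
        assert g.number_of_edges() == 31

    def test_deleting_a_transition_fails_validation(self, tmp_path):
        doc = yaml.safe_load(packaged_atlas_path().read_text())
        pdh = next(r for r in doc["reactions"] if r["id"] == "pdh")
        pdh["transitions"] = [t for t in pdh["transitions"] if not t.startswith("pyr.C3")]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(doc))
        with pytest.raises(AtlasValidationError, match="unmapped substrate carbon"):
            load_atlas(bad)

    def test_malformed_document_is_a_parse_error(self, tmp_path):
        from ergolabel.atlas import AtlasParseError

        bad = tmp_path / "broken.yaml"
        bad.write_text("molecules: 3\n")
        with pytest.raises(AtlasParseError):
            load_atlas(bad)


class TestReactionValidation:
    def test_every_packaged_reaction_conserves_carbon(self, atlas):
        for r in atlas.reactions.values():
            assert validate_reaction(r, atlas.molecules) == []

    def test_pdh_decarboxylation(self, atlas):
        pdh = atlas.reactions["pdh"]
        assert validate_reaction(pdh, atlas.molecules) == []
        assert len(pdh.lost_carbons) == 1
        assert pdh.lost_carbons[0][2] == "CO2"

    def test_dxs_loses_pyruvate_c1(self, atlas):
        dxs = atlas.reactions["dxs"]
        assert validate_reaction(dxs, atlas.molecules) == []
        assert ("pyr", 1, "CO2") in dxs.lost_carbons

    def test_squalene_synthase_balances_30_carbons(self, atlas):
        sqs = atlas.reactions["squalene_synthase"]
        assert len(sqs.transitions) == 30
        assert validate_reaction(sqs, atlas.molecules) == []

    def test_duplicate_transition_is_one_violation(self, atlas):
        pdh = atlas.reactions["pdh"]
        dup = ReactionMap(
            id=pdh.id,
            name=pdh.name,
            substrates=pdh.substrates,
            products=pdh.products,
            transitions=pdh.transitions + (pdh.transitions[0],),
            lost_carbons=pdh.lost_carbons,
        )
        violations = validate_reaction(dup, atlas.molecules)
        assert sum("consumed 2 times" in v for v in violations) == 1


class TestTraceOrigin:
    def test_ipp_c5_traces_to_glucose_c1_and_c6(self, atlas):
        # IPP C5 <- MVA 3-methyl <- acetyl C2 <- pyruvate C3 <- glucose {C1, C6}
        origin = trace_origin(atlas, "ipp", "MVA")
        assert origin.glucose_fractions[5] == pytest.approx({1: 0.5, 6: 0.5})

    def test_dxp_backbone_provenance(self, atlas):
        # DXP C1 <- pyruvate C3 and DXP C5 <- GAP C3: both end at glucose C1/C6
        dxp = trace_origin(atlas, "dxp", "MEP")
        pyr = trace_origin(atlas, "pyruvate", "MEP")
        gap = trace_origin(atlas, "gap", "MEP")
        assert dxp.glucose_fractions[1] == pyr.glucose_fractions[3]
        assert dxp.glucose_fractions[5] == gap.glucose_fractions[3]
        assert dxp.glucose_fractions[1] == pytest.approx({1: 0.5, 6: 0.5})

    def test_ergosterol_has_27_isoprenoid_carbons_and_one_sam(self, atlas):
        for route in ("MVA", "MEP"):
            origin = trace_origin(atlas, "ergosterol", route)
            classes = [origin.origin_class(c) for c in range(1, 29)]
            assert classes.count("isoprenoid") == 27
            assert classes.count("SAM") == 1
            assert origin.origin_class(28) == "SAM"

    def test_backward_traces_never_dangle(self, atlas):
        # every carbon's mass reaches glucose or SAM in full
        for route in ("MVA", "MEP"):
            origin = trace_origin(atlas, "ergosterol", route)
            for c in range(1, 29):
                total = sum(origin.glucose_fractions[c].values()) + origin.sam_fraction[c]
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_target_raises(self, atlas):
        with pytest.raises(RouteError):
            trace_origin(atlas, "mevalonate", "MEP")

    def test_route_equivalence_downstream(self, atlas):
        # the squalene <- IPP unit decomposition is route-independent
        mva = trace_origin(atlas, "squalene", "MVA")
        mep = trace_origin(atlas, "squalene", "MEP")
        assert mva.units == mep.units


class TestUnitPositions:
    def test_decomposition_is_route_independent(self, atlas):
        a = unit_positions(trace_origin(atlas, "ergosterol", "MVA"))
        b = unit_positions(trace_origin(atlas, "ergosterol", "MEP"))
        assert a == b

    def test_six_units_with_three_positions_lost(self, atlas):
        up = unit_positions(trace_origin(atlas, "ergosterol", "MVA"))
        tags = [v for v in up.values() if v != "SAM"]
        assert len(tags) == 27
        assert {u for u, _ in tags} == {1, 2, 3, 4, 5, 6}
        # 6 units x 5 positions minus the three demethylation losses
        assert len(set(tags)) == 27

    def test_sam_carbon_belongs_to_no_unit(self, atlas):
        up = unit_positions(trace_origin(atlas, "ergosterol", "MVA"))
        assert up[28] == "SAM"


def _random_chain_atlas(rng: random.Random, n_carbons: int, n_reactions: int = 3):
    """A linear toy pathway whose maps are random permutations with one
    terminal carbon loss, for checking trace composition against naive
    substitution."""
    molecules = {
        f"m{i}": MoleculeSpec(
            id=f"m{i}",
            n_carbons=n_carbons if i == 0 else n_carbons - (1 if i == n_reactions else 0),
            numbering="toy",
            formula=f"C{n_carbons if i == 0 else n_carbons - (1 if i == n_reactions else 0)}"
            f"H{2 * n_carbons}O",
        )
        for i in range(n_reactions + 1)
    }
    reactions = {}
    perms = []
    for i in range(n_reactions):
        n_sub = molecules[f"m{i}"].n_carbons
        n_prod = molecules[f"m{i+1}"].n_carbons
        perm = list(range(1, n_sub + 1))
        rng.shuffle(perm)
        # map the first n_prod shuffled substrate carbons onto products,
        # drop the rest as CO2
        transitions = tuple(
            Transition("s", perm[j], "p", j + 1) for j in range(n_prod)
        )
        lost = tuple(("s", perm[j], "CO2") for j in range(n_prod, n_sub))
        reactions[f"r{i}"] = ReactionMap(
            id=f"r{i}",
            name=f"r{i}",
            substrates=((f"m{i}", "s"),),
            products=((f"m{i+1}", "p"),),
            transitions=transitions,
            lost_carbons=lost,
        )
        perms.append((perm, n_prod))
    route = PathwayRoute(id="toy", reactions=tuple(f"r{i}" for i in range(n_reactions)),
                         inputs=("m0",))
    atlas = Atlas(molecules=molecules, reactions=reactions, routes={"toy": route})
    return atlas, perms


@pytest.mark.parametrize("seed", range(5))
def test_trace_equals_stepwise_substitution_on_random_chains(seed):
    """Composed trace through random valid maps matches naive step-by-step
    substitution of carbon positions."""
    rng = random.Random(seed)
    n = rng.randint(3, 7)
    atlas, perms = _random_chain_atlas(rng, n)
    for r in atlas.reactions.values():
        assert validate_reaction(r, atlas.molecules) == []

    # naive substitution: follow each terminal carbon backward by inverting
    # each permutation step independently of the propagation engine
    target = f"m{len(perms)}"
    origin = trace_origin(atlas, target, "toy")
    for c in range(1, atlas.molecules[target].n_carbons + 1):
        back = c
        for perm, n_prod in reversed(perms):
            back = perm[back - 1]
        assert origin.glucose_fractions[c] == {back: 1.0}
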