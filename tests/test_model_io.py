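"""Model container, JSON/SBML round trips and GPR rule semantics."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protoflux as pf
from protoflux.model_io import (
    GprExpression,
    GprParseError,
    ModelValidationError,
    read_proteome_table,
)


def make_segment_json(tmp_path, **overrides):
    data = {
        "metabolites": [{"id": "A"}],
        "reactions": [
            {"id": "r1", "stoich": {"A": 1}, "lb": 0, "ub": 1, "gpr": None,
             "exchange": True},
            {"id": "r2", "stoich": {"A": -1}, "lb": 0, "ub": 1, "gpr": None,
             "exchange": True},
        ],
    }
    data.update(overrides)
    path = tmp_path / "model.json"
    path.write_text(json.dumps(data))
    return path


class TestReadWrite:
    def test_toy_json_transcription(self, tmp_path):
        model = pf.read_model(make_segment_json(tmp_path))
        assert model.n_metabolites == 1 and model.n_reactions == 2
        np.testing.assert_array_equal(model.S, [[1, -1]])
        np.testing.assert_array_equal(model.v_inf, [0, 0])
        np.testing.assert_array_equal(model.v_sup, [1, 1])

    @pytest.mark.parametrize("name", ["segment", "branch", "diamond",
                                      "toy_central_carbon"])
    def test_round_trip_identity(self, tmp_path, toys, name):
        path = tmp_path / f"{name}.json"
        pf.write_model(toys[name], str(path))
        assert pf.read_model(str(path)) == toys[name]

    def test_gpr_string_preserved(self, tmp_path):
        path = make_segment_json(tmp_path)
        model = pf.read_model(path)
        model.gpr["r1"] = pf.parse_gpr("(P1 AND P2) OR P3")
        out = tmp_path / "out.json"
        pf.write_model(model, str(out))
        again = pf.read_model(str(out))
        assert again.gpr["r1"] == model.gpr["r1"]
        assert again.gpr["r1"].to_string() == "(P1 AND P2) OR P3"

    def test_unknown_metabolite_rejected(self, tmp_path):
        path = make_segment_json(tmp_path, reactions=[
            {"id": "r1", "stoich": {"B": 1}, "lb": 0, "ub": 1, "gpr": None,
             "exchange": False}])
        with pytest.raises(ModelValidationError, match="unknown metabolite"):
            pf.read_model(path)

    def test_write_to_bad_path_raises(self, toys, tmp_path):
        with pytest.raises(OSError):
            pf.write_model(toys["segment"], str(tmp_path / "nope" / "x.json"))

    def test_inconsistent_bounds_rejected(self, tmp_path):
        path = make_segment_json(tmp_path, reactions=[
            {"id": "r1", "stoich": {"A": 1}, "lb": 2, "ub": 1, "gpr": None,
             "exchange": False}])
        with pytest.raises(ModelValidationError, match="v_inf > v_sup"):
            pf.read_model(path)

    def test_sbml_import_matches_json(self, tmp_path, central):
        cobra = pytest.importorskip("cobra")
        # build the same network in cobra and export to SBML
        cm = cobra.Model("toy")
        mets = {mid: cobra.Metabolite(mid, compartment="c")
                for mid in central.metabolite_ids}
        for j, rid in enumerate(central.reaction_ids):
            rxn = cobra.Reaction(rid)
            rxn.lower_bound = float(central.v_inf[j])
            rxn.upper_bound = float(central.v_sup[j])
            cm.add_reactions([rxn])
            rxn.add_metabolites({
                mets[mid]: central.S[i, j]
                for i, mid in enumerate(central.metabolite_ids)
                if central.S[i, j] != 0})
            if rid in central.gpr:
                rxn.gene_reaction_rule = central.gpr[rid].to_string().replace(
                    "AND", "and").replace("OR", "or")
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cm, str(path))
        imported = pf.read_model(str(path))
        assert imported.reaction_ids == central.reaction_ids
        # cobra may reorder metabolites; compare S row-by-row via ids
        perm = [imported.metabolite_ids.index(mid)
                for mid in central.metabolite_ids]
        np.testing.assert_allclose(imported.S[perm, :], central.S)
        np.testing.assert_allclose(imported.v_inf, central.v_inf)
        np.testing.assert_allclose(imported.v_sup, central.v_sup)
        assert imported.gpr == central.gpr


class TestGpr:
    def test_complex_with_isoenzyme(self):
        expr = pf.parse_gpr("(P1 AND P2) OR P3")
        assert expr.op == "or"
        assert expr.children[0].op == "and"
        assert {c.name for c in expr.children[0].children} == {"P1", "P2"}
        assert expr.children[1].name == "P3"

    def test_single_leaf(self):
        assert pf.parse_gpr("P1") == GprExpression("leaf", name="P1")

    def test_precedence_and_binds_tighter(self):
        expr = pf.parse_gpr("P1 OR P2 AND P3")
        assert expr.op == "or"
        assert expr.children[1].op == "and"

    @pytest.mark.parametrize("bad", ["P1 AND OR P2", "(P1 AND P2", "P1)", "",
                                     "AND P1", "P1 OR"])
    def test_parse_errors_carry_position(self, bad):
        with pytest.raises(GprParseError):
            pf.parse_gpr(bad)

    def test_min_sum_evaluation(self):
        expr = pf.parse_gpr("(P1 AND P2) OR P3")
        assert pf.evaluate_gpr(expr, {"P1": 0.2, "P2": 0.5, "P3": 0.1}) == pytest.approx(0.3)

    def test_incomplete_complex_is_unobserved(self):
        expr = pf.parse_gpr("P1 AND P2")
        assert pf.evaluate_gpr(expr, {"P1": 0.2}) is None
        assert pf.evaluate_gpr(expr, {"P1": 0.2}, partial_and="min") == pytest.approx(0.2)

    def test_or_drops_unobserved_branch(self):
        expr = pf.parse_gpr("P1 OR P2")
        assert pf.evaluate_gpr(expr, {"P2": 0.4}) == pytest.approx(0.4)
        assert pf.evaluate_gpr(expr, {}) is None

    def test_zero_abundance_is_observed(self):
        expr = pf.parse_gpr("P1 AND P2")
        assert pf.evaluate_gpr(expr, {"P1": 0.0, "P2": 1.0}) == 0.0


# random GPR trees for the property tests
def gpr_trees(depth=4):
    leaves = st.builds(GprExpression, st.just("leaf"),
                       st.sampled_from([f"P{i}" for i in range(6)]))

    def extend(children):
        return st.builds(
            lambda op, cs: GprExpression(op, children=tuple(cs)),
            st.sampled_from(["and", "or"]),
            st.lists(children, min_size=2, max_size=3))

    return st.recursive(leaves, extend, max_leaves=2**depth)


def direct_eval(expr, abundances):
    """Independent brute-force min/sum recursion (no sentinel shortcuts)."""
    if expr.op == "leaf":
        return abundances.get(expr.name)
    vals = [direct_eval(c, abundances) for c in expr.children]
    if expr.op == "and":
        return None if None in vals else min(vals)
    present = [v for v in vals if v is not None]
    return sum(present) if present else None


@given(expr=gpr_trees(),
       table=st.dictionaries(st.sampled_from([f"P{i}" for i in range(6)]),
                             st.floats(0, 10, allow_nan=False)))
@settings(max_examples=200, deadline=None)
def test_evaluate_matches_direct_recursion(expr, table):
    assert pf.evaluate_gpr(expr, table) == direct_eval(expr, table)


@given(expr=gpr_trees(),
       table=st.dictionaries(st.sampled_from([f"P{i}" for i in range(6)]),
                             st.floats(0, 10, allow_nan=False), min_size=6),
       bump=st.floats(0.01, 5),
       which=st.sampled_from([f"P{i}" for i in range(6)]))
@settings(max_examples=200, deadline=None)
def test_evaluate_is_monotone(expr, table, bump, which):
    before = pf.evaluate_gpr(expr, table)
    table2 = dict(table)
    table2[which] = table2[which] + bump
    after = pf.evaluate_gpr(expr, table2)
    if before is not None:
        assert after >= before


class TestConstraints:
    def test_irreversible_narrows_lower_bound(self, toys):
        model = toys["segment"].copy()
        model.v_inf[0] = -1.0
        out = pf.apply_constraints(model, pf.ConstraintSpec(irreversible_set=["r1"]))
        assert out.v_inf[0] == 0.0 and not out.reversible[0]

    def test_zeroed_set(self, segment):
        out = pf.apply_constraints(segment, pf.ConstraintSpec(zeroed_set=["r2"]))
        assert out.v_inf[1] == out.v_sup[1] == 0.0

    def test_fixed_exchange_recorded_not_applied(self, segment):
        spec = pf.ConstraintSpec(fixed_exchanges={"r2": (0.5, 0.005)})
        out = pf.apply_constraints(segment, spec)
        assert out.fixed_exchanges["r2"] == (0.5, 0.005)
        np.testing.assert_array_equal(out.v_sup, segment.v_sup)

    def test_observation_outside_bounds_rejected(self, segment):
        with pytest.raises(ModelValidationError, match="outside bounds"):
            pf.apply_constraints(
                segment, pf.ConstraintSpec(fixed_exchanges={"r2": (2.0, 0.01)}))

    def test_unknown_reaction_rejected(self, segment):
        with pytest.raises(ModelValidationError, match="unknown reaction"):
            pf.apply_constraints(segment, pf.ConstraintSpec(zeroed_set=["zz"]))

    def test_never_widens(self, central):
        spec = pf.ConstraintSpec(irreversible_set=["pgi", "adh"],
                                 zeroed_set=["gpd"])
        out = pf.apply_constraints(central, spec)
        assert np.all(out.v_inf >= central.v_inf)
        assert np.all(out.v_sup <= central.v_sup)


class TestReversibilitySummary:
    def test_segment_mixed(self, toys):
        model = toys["segment"].copy()
        model.v_inf[1] = -1.0
        counts = pf.reversibility_summary(model)
        assert (counts.n_reversible, counts.n_irreversible) == (1, 1)

    def test_all_zeroed(self, segment):
        model = pf.apply_constraints(
            segment, pf.ConstraintSpec(zeroed_set=["r1", "r2"]))
        counts = pf.reversibility_summary(model)
        assert counts == (0, 0, 2)


class TestMapProteome:
    def test_counts_only_covered_reactions(self, diamond):
        # proteins for 'top' (complex) and 'in' only
        profile = pf.map_proteome(diamond, {"Ta": 1.0, "Tb": 2.0, "E0": 3.0})
        assert set(profile.weightings) == {"in", "top"}
        assert profile.weightings["top"] == pytest.approx(1.0)
        assert profile.n_observed == 2

    def test_empty_table(self, central):
        profile = pf.map_proteome(central, {})
        assert profile.n_observed == 0 and not profile.observed_mask.any()

    def test_identity_proteome_reproduces_fluxes(self, central, central_posterior):
        # generator composed with the GPR evaluator must return |v| exactly
        abundances, truth = pf.synthetic_proteome(
            central, relation="identity", noise_sd=0.0, n_samples=3, seed=11,
            posterior=central_posterior)
        for col in abundances.columns:
            profile = pf.map_proteome(central, abundances[col].dropna().to_dict())
            v = truth[col].to_numpy()
            for rid, val in profile.weightings.items():
                i = central.reaction_index(rid)
                assert val == pytest.approx(abs(v[i]), abs=1e-12)
            assert set(profile.weightings) == set(central.gpr)


def test_proteome_table_round_trip(tmp_path, central, central_posterior):
    abundances, _ = pf.synthetic_proteome(central, relation="linear",
                                          n_samples=4, seed=3,
                                          posterior=central_posterior)
    path = tmp_path / "prot.tsv"
    abundances.rename_axis("protein").to_csv(path, sep="\t")
    again = read_proteome_table(str(path))
    np.testing.assert_allclose(again.to_numpy(), abundances.to_numpy())
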