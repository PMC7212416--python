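"""The bundled CD4 model: structure, classification, scenarios, census.

The compacted rule table comes with a second column giving each node's
fixed-point value purely in terms of the context variables (TCR, CD28, AMPK);
that column is used here as a row-by-row regression over every enumerated
attractor.
"""

import itertools

import pytest

from tcellnet.expr import evaluate
from tcellnet.model import (
    NotAFixedPointError,
    classify,
    enumerate_model_attractors,
    run_scenario,
)
from tcellnet.network import find_fixed_points, simulate, with_rules
from tcellnet.parse import parse_expr

# node -> fixed-point value over the context variables (activation core;
# exogenous cytokines absent)
CORE_STEADY = {
    "TCR": "TCR",
    "CD28": "CD8086",
    "CD25": "TCR and CD28",
    "IL2G": "TCR and CD28",
    "MTOR": "CD28",
    "CTLA4": "TCR and CD28",
    "CTLA4dim": "0",
    "NDRG1": "TCR and not CD28",
    "MTORC1": "CD28 and not AMPK",
    "MTORC2": "CD28 and AMPK",
    "AP1": "TCR and CD28",
    "STAT5": "TCR and CD28",
    "NFAT": "TCR",
    "NFKB": "TCR",
    "AKT": "CD28",
    "BCL2": "CD28",
    "DAG": "TCR",
    "SOS": "CD28",
    "RASGTPR": "TCR and CD28",
    "PDK1": "CD28",
    "LCK": "TCR",
    "ZAP70": "TCR",
    "LAT": "TCR",
    "PLC": "TCR",
    "PIP2": "TCR",
    "IP3": "TCR",
    "Ca": "TCR",
    "PKCT": "TCR",
}

# differentiation-module nodes, valid under their scenario's cytokine context
MODULE_STEADY = {
    "th1": {"TBET": "TCR and CD28 and not AMPK", "IFNG": "TCR and CD28 and not AMPK"},
    "th2": {"GATA3": "TCR and CD28 and AMPK", "IL4": "TCR and CD28 and AMPK"},
    "treg": {
        "FOXP3": "TCR and CD28 and AMPK",
        "IL10": "TCR and CD28 and AMPK",
        "TGFB": "TCR and CD28 and AMPK",
    },
    "th17": {
        "RORGT": "TCR and CD28 and not AMPK",
        "IL21": "TCR and CD28 and not AMPK",
        "IL17": "TCR and CD28 and not AMPK",
    },
}


class TestStructure:
    def test_node_counts(self, model):
        assert model.core.n_nodes == 30
        assert model.full.n_nodes == 46

    def test_core_is_prefix_closed_subnetwork(self, model):
        # every core rule only references core nodes
        assert set(model.core.names) <= set(model.full.names)
        for n in model.core.names:
            assert model.core.rules[n] == model.full.rules[n]

    def test_inputs_and_hybrid(self, model):
        assert set(model.core.inputs) == {"CD8086", "AMPK"}
        assert model.full.hybrid == "CD8086"
        assert set(model.full.inputs) == {
            "CD8086", "AMPK", "IL12e", "IFNGe", "IL4e", "TGFBe", "IL10e", "IL21e"
        }

    def test_metabolic_gate_rule(self, model):
        """mTORC1 is shut whenever the nutrient sensor is active."""
        rule = model.full.rules["MTORC1"]
        for mtor in (0, 1):
            assert evaluate(rule, {"MTOR": mtor, "AMPK": 1}) == 0
            assert evaluate(rule, {"MTOR": mtor, "AMPK": 0}) == mtor


class TestClassify:
    def test_effector_and_activation_labels(self, model):
        th1 = run_scenario("th1", model=model)
        assert classify(th1.final, {"TCR": 1}, model=model) == "Th1"
        act = run_scenario("activation", model=model)
        assert classify(act.final, {"TCR": 1}, model=model) == "activation"

    def test_anergy_signature_state(self, model):
        res = run_scenario("anergy_no_cd28", model=model)
        f = res.final
        assert (f["NFAT"], f["NFKB"], f["AP1"], f["IL2G"], f["NDRG1"]) == (1, 1, 0, 0, 1)
        assert res.label == "anergy_no_cd28"

    def test_all_off_is_no_activation(self, model):
        state = {n: 0 for n in model.full.names}
        assert classify(state, {}, model=model) == "no_activation"

    def test_transient_state_rejected(self, model):
        state = {n: 0 for n in model.full.names}
        state.update(TCR=1, CD8086=1, LCK=1)  # mid-cascade, not a fixed point
        with pytest.raises(NotAFixedPointError):
            classify(state, {"TCR": 1}, model=model)


class TestScenarios:
    @pytest.mark.parametrize(
        "name", ["activation", "anergy_no_cd28", "ndrg1_overexpression",
                 "checkpoint", "th1", "th2", "th17", "treg"]
    )
    def test_scenario_reaches_declared_class(self, model, name):
        res = run_scenario(name, model=model)
        assert res.trajectory.converged
        assert res.label == model.meta["scenarios"][name]["expected_class"]

    def test_ndrg1_overexpression_partial_activation(self, model):
        """Forcing the anergy factor on at the onset of stimulation keeps the
        three TFs active but kills IL-2 synthesis and its feedback arm."""
        f = run_scenario("ndrg1_overexpression", model=model).final
        assert (f["AP1"], f["NFAT"], f["NFKB"]) == (1, 1, 1)
        assert (f["IL2G"], f["CD25"], f["STAT5"]) == (0, 0, 0)

    def test_th2_output(self, model):
        f = run_scenario("th2", model=model).final
        assert f["GATA3"] == 1 and f["IL4"] == 1

    def test_unknown_scenario(self, model):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenario("nope", model=model)


@pytest.fixture(scope="module")
def census(model):
    return enumerate_model_attractors(model, seed=0)


class TestCensus:
    def test_eighteen_attractors(self, census):
        assert len(census) == 18

    def test_census_is_seed_independent(self, model, census):
        again = enumerate_model_attractors(model, seed=99)
        assert [(a.state, a.context) for a in again] == [
            (a.state, a.context) for a in census
        ]

    def test_class_multiplicities(self, census):
        counts = {}
        for a in census:
            counts[a.label] = counts.get(a.label, 0) + 1
        assert counts["activation"] == 2
        assert counts["checkpoint"] == 2
        assert counts["anergy_no_cd28"] == 2
        assert counts["Th1"] == counts["Th2"] == counts["Th17"] == counts["Treg"] == 1
        assert counts["no_activation"] == 8

    def test_checkpoint_pair_differs_only_in_ampk(self, census):
        chk = [a for a in census if a.label == "checkpoint"]
        assert len(chk) == 2
        s0, s1 = (a.state_dict() for a in chk)
        diff = {n for n in s0 if s0[n] != s1[n]}
        assert diff == {"AMPK"}

    def test_single_th2_attractor(self, census):
        th2ish = [a for a in census
                  if a.state_dict().get("GATA3") and a.state_dict().get("IL4")]
        assert len(th2ish) == 1

    def test_phenotype_exclusivity(self, census, model):
        """Cross-inhibition: no attractor carries two lineages' markers."""
        for a in census:
            s = a.state_dict()
            lineages = [
                lab for lab, ms in model.phenotype_markers.items()
                if all(s.get(m, 0) for m in ms)
            ]
            assert len(lineages) <= 1

    def test_metabolic_split_of_effectors(self, census):
        for a in census:
            s = a.state_dict()
            if a.label in ("Th1", "Th17"):
                assert s["MTORC1"] == 1 and s["AMPK"] == 0
            if a.label in ("Th2", "Treg"):
                assert s["MTORC2"] == 1 and s["AMPK"] == 1

    def test_anergy_attractors_keep_nfat_nfkb(self, census):
        for a in census:
            if a.label.startswith("anergy"):
                s = a.state_dict()
                assert s["NFAT"] == 1 and s["NFKB"] == 1
                assert s["AP1"] == 0 and s["IL2G"] == 0


class TestSteadyStateColumn:
    def test_core_column_holds_at_every_fixed_point(self, core):
        fps = find_fixed_points(core, method="solver")
        assert len(fps) == 8
        for fp in fps:
            ctx = {"TCR": fp["TCR"], "CD28": fp["CD28"],
                   "AMPK": fp["AMPK"], "CD8086": fp["CD8086"]}
            for node, text in CORE_STEADY.items():
                expected = evaluate(parse_expr(text), ctx)
                assert fp[node] == expected, (node, fp)

    @pytest.mark.parametrize("scen", ["th1", "th2", "treg", "th17"])
    def test_module_column_holds_in_its_scenario(self, model, scen):
        f = run_scenario(scen, model=model).final
        ctx = {"TCR": f["TCR"], "CD28": f["CD28"], "AMPK": f["AMPK"]}
        for node, text in MODULE_STEADY[scen].items():
            assert f[node] == evaluate(parse_expr(text), ctx), node
        for inp in model.meta["scenarios"][scen]["inputs"]:
            if inp.endswith("e"):
                assert f[inp] == 1


class TestMutationControl:
    def test_removing_akt_brake_on_ndrg1_abolishes_activation(self, model):
        """Negative control: drop the Akt-mediated inactivation of Ndrg1 and
        the activation fixed point disappears (Ndrg1 then fires under full
        stimulation and kills IL-2), changing the anergy landscape."""
        mutant = with_rules(model.core, {"NDRG1": parse_expr("NFAT")})
        fps = find_fixed_points(mutant, method="solver")
        assert all(not (s["IL2G"] and s["TCR"]) for s in fps)
        init = {n: 0 for n in mutant.names}
        init.update(TCR=1, CD8086=1)
        final = simulate(mutant, init).final
        assert final["NDRG1"] == 1 and final["IL2G"] == 0
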