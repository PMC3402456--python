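"""The forward-chaining engine: rule firings, chain enumeration, policies,
contradiction handling, and the independent chain validator."""

import pytest

from moarx import (
    EnginePolicy,
    KnowledgeBaseBuilder,
    Trigger,
    contradiction_triggers,
    infer,
    infer_all,
    inferred_drugs,
    initial_triggers,
    parse_fact_file,
    propagate,
    terminal_triggers,
    validate_chain,
)
from moarx.engine import EngineError, InferenceChain


def chain_signature(chain):
    return [(t.action, t.target, t.step, t.rule_id) for t in chain.triggers]


class TestInitialTriggers:
    def test_antagonist_target_inactivated(self, dipyridamole_kb):
        (t,) = initial_triggers(dipyridamole_kb, "dipyridamole")
        assert (t.action, t.target, t.step, t.rule_id) == ("inactivates", "ada", 1, "R1a")
        assert t.support == ("interaction(dipyridamole, inhibits, ada).",)

    def test_agonist_target_activated(self, tazarotene_kb):
        (t,) = initial_triggers(tazarotene_kb, "tazarotene")
        assert (t.action, t.target, t.step, t.rule_id) == ("activates", "rara", 1, "R1b")

    def test_drug_without_targets(self):
        kb = parse_fact_file("drug(water).")
        assert initial_triggers(kb, "water") == []

    def test_unregistered_drug_is_an_error(self, dipyridamole_kb):
        with pytest.raises(EngineError, match="aspirin"):
            initial_triggers(dipyridamole_kb, "aspirin")


class TestPropagate:
    def test_activated_inhibitor_inactivates_downstream(self, tazarotene_kb):
        t = initial_triggers(tazarotene_kb, "tazarotene")[0]
        (nxt,) = propagate(tazarotene_kb, t, EnginePolicy())
        assert (nxt.action, nxt.target, nxt.step, nxt.rule_id) == (
            "inactivates", "egfr", 2, "R2b")

    def test_no_outgoing_edges(self, dipyridamole_kb):
        t = initial_triggers(dipyridamole_kb, "dipyridamole")[0]
        assert propagate(dipyridamole_kb, t, EnginePolicy()) == []

    def test_inactivation_propagation_gate(self):
        kb = parse_fact_file(
            "drug(d). protein(p1). protein(p2).\n"
            "interaction(d, inhibits, p1). interaction(p1, induces, p2).")
        t = initial_triggers(kb, "d")[0]
        on = propagate(kb, t, EnginePolicy())
        assert [(x.action, x.target, x.rule_id) for x in on] == [("inactivates", "p2", "R2c")]
        off = propagate(kb, t, EnginePolicy(inactivation_propagation=False))
        assert off == []

    def test_double_negation_gate(self):
        kb = parse_fact_file(
            "drug(d). protein(p1). protein(p2).\n"
            "interaction(d, inhibits, p1). interaction(p1, inhibits, p2).")
        t = initial_triggers(kb, "d")[0]
        assert propagate(kb, t, EnginePolicy()) == []
        (x,) = propagate(kb, t, EnginePolicy(double_negation_rule=True))
        assert (x.action, x.rule_id) == ("activates", "R2d")

    def test_cycle_guard_terminates_three_cycle(self):
        kb = parse_fact_file(
            "drug(d). protein(a). protein(b). protein(c). suppressor(c).\n"
            "interaction(d, induces, a). interaction(a, induces, b).\n"
            "interaction(b, induces, c). interaction(c, induces, a).")
        chains, _ = infer(kb, "d", "cancer")
        assert [chain_signature(c) for c in chains] == [[
            ("activates", "a", 1, "R1b"),
            ("activates", "b", 2, "R2a"),
            ("activates", "c", 3, "R2a"),
            ("treats", "cancer", 4, "R5"),
        ]]
        for c in chains:
            proteins = [t.target for t in c.triggers[:-1]]
            assert len(proteins) == len(set(proteins))


class TestTerminalAndContradiction:
    def test_overexpression_relation_closes_chain(self, dipyridamole_kb, cancer_map):
        t = initial_triggers(dipyridamole_kb, "dipyridamole")[0]
        (tt,) = terminal_triggers(dipyridamole_kb, t, "cancer", cancer_map)
        assert (tt.action, tt.target, tt.step, tt.rule_id) == ("treats", "cancer", 2, "R3a")

    def test_inactivated_oncogene_closes_chain(self, tazarotene_kb, cancer_map):
        t = Trigger("tazarotene", "inactivates", "egfr", 2, "R2b",
                    ("interaction(rara, inhibits, egfr).",))
        (tt,) = terminal_triggers(tazarotene_kb, t, "cancer", cancer_map)
        assert (tt.step, tt.rule_id) == (3, "R4")
        assert tt.support == ("oncogene(egfr).",)

    def test_activated_oncogene_fires_no_terminal_rule(self, tazarotene_kb, cancer_map):
        t = Trigger("tazarotene", "activates", "egfr", 2, "R2a", ())
        assert terminal_triggers(tazarotene_kb, t, "cancer", cancer_map) == []

    def test_activated_promoting_bioprocess_promotes(self, cladribine_kb, cancer_map):
        t = initial_triggers(cladribine_kb, "cladribine")[0]
        (ct,) = contradiction_triggers(cladribine_kb, t, "cancer", cancer_map)
        assert (ct.action, ct.target, ct.step, ct.rule_id) == ("promotes", "cancer", 2, "C3")

    def test_sign_flip_symmetry_direct(self, cancer_map):
        """Flipping the drug-target verb swaps C-rule firings with R-rule
        firings on 2-step derivations (C1<->R4, C2<->R5, C3<->R6, C4<->R7,
        C5<->R3)."""
        base = ("protein(onc). protein(sup). protein(pb). protein(rb). protein(dx).\n"
                "oncogene(onc). suppressor(sup).\n"
                "cancer_promoting_bioprocess(bpp). cancer_resisting_bioprocess(bpr).\n"
                "relation(pb, is_associated, bpp). relation(rb, is_associated, bpr).\n"
                "disease(gastric_cancer).\n"
                "relation(overexpressed(dx), associated_with, gastric_cancer).\n"
                "drug(d).\n")
        targets = ("onc", "sup", "pb", "rb", "dx")
        mirror = {"C1": "R4", "C2": "R5", "C3": "R6", "C4": "R7", "C5": "R3a"}
        for target in targets:
            kb_ind = parse_fact_file(base + f"interaction(d, induces, {target}).")
            kb_inh = parse_fact_file(base + f"interaction(d, inhibits, {target}).")
            t_ind = initial_triggers(kb_ind, "d")[0]
            t_inh = initial_triggers(kb_inh, "d")[0]
            c_fires = {c.rule_id for c in contradiction_triggers(kb_ind, t_ind, "cancer", cancer_map)}
            c_fires |= {c.rule_id for c in contradiction_triggers(kb_inh, t_inh, "cancer", cancer_map)}
            r_fires = {r.rule_id for r in terminal_triggers(kb_inh, t_inh, "cancer", cancer_map)}
            r_fires |= {r.rule_id for r in terminal_triggers(kb_ind, t_ind, "cancer", cancer_map)}
            assert {mirror[c] for c in c_fires} == r_fires


class TestInfer:
    def test_direct_worked_example(self, dipyridamole_kb):
        chains, report = infer(dipyridamole_kb, "dipyridamole", "cancer")
        assert len(chains) == 1
        assert chain_signature(chains[0]) == [
            ("inactivates", "ada", 1, "R1a"), ("treats", "cancer", 2, "R3a")]
        assert chains[0].classification == "direct"
        assert report.verdict == "clean"

    def test_indirect_worked_example(self, tazarotene_kb):
        chains, _ = infer(tazarotene_kb, "tazarotene", "cancer")
        assert len(chains) == 1
        assert chain_signature(chains[0]) == [
            ("activates", "rara", 1, "R1b"),
            ("inactivates", "egfr", 2, "R2b"),
            ("treats", "cancer", 3, "R4")]
        assert chains[0].classification == "indirect"

    def test_classification_is_a_function_of_length(self, merged_examples_kb):
        for drug in ("dipyridamole", "tazarotene"):
            chains, _ = infer(merged_examples_kb, drug, "cancer")
            for c in chains:
                assert c.classification == ("direct" if len(c.triggers) == 2 else "indirect")

    def _contradictory_kb(self):
        # d inhibits a suppressor (C2) but also inhibits an oncogene (R4).
        return parse_fact_file(
            "drug(d). protein(s). protein(o). suppressor(s). oncogene(o).\n"
            "interaction(d, inhibits, s). interaction(d, inhibits, o).")

    def test_block_mode_suppresses_treats_chains(self):
        kb = self._contradictory_kb()
        chains, report = infer(kb, "d", "cancer", policy=EnginePolicy(contradiction_mode="block"))
        assert chains == []
        assert report.verdict == "contradictory"
        assert len(report.treating_chains) == 1  # retained inside the report
        assert report.promoting_chains[0].terminal_rule == "C2"

    def test_flag_mode_returns_chains_plus_report(self):
        kb = self._contradictory_kb()
        chains, report = infer(kb, "d", "cancer", policy=EnginePolicy(contradiction_mode="flag"))
        assert len(chains) == 1
        assert report.verdict == "contradictory"

    def test_ignore_mode_skips_anti_rules(self):
        kb = self._contradictory_kb()
        chains, report = infer(kb, "d", "cancer", policy=EnginePolicy(contradiction_mode="ignore"))
        assert len(chains) == 1
        assert report.promoting_chains == () and report.verdict == "clean"

    def test_block_inferred_subset_of_ignore(self):
        from moarx.synth import SynthParams, generate_kb

        for seed in range(20):
            kb, _ = generate_kb(SynthParams(n_drugs=6, n_proteins=20, seed=seed,
                                            p_drug_edge=0.1, p_ppi=0.08,
                                            frac_oncogene=0.1, frac_suppressor=0.1,
                                            n_planted_chains=1))
            blocked = inferred_drugs(infer_all(kb, "cancer", policy=EnginePolicy(contradiction_mode="block")))
            ignored = inferred_drugs(infer_all(kb, "cancer", policy=EnginePolicy(contradiction_mode="ignore")))
            assert blocked <= ignored

    def test_adding_facts_never_removes_chains_in_ignore_mode(self, tazarotene_kb):
        policy = EnginePolicy(contradiction_mode="ignore")
        before, _ = infer(tazarotene_kb, "tazarotene", "cancer", policy=policy)
        bigger = parse_fact_file(
            "drug(tazarotene). protein(rara). protein(egfr). protein(extra).\n"
            "oncogene(egfr). suppressor(extra).\n"
            "interaction(tazarotene, induces, rara). interaction(rara, inhibits, egfr).\n"
            "interaction(tazarotene, induces, extra).")
        after, _ = infer(bigger, "tazarotene", "cancer", policy=policy)
        assert {c.key for c in before} <= {c.key for c in after}

    def test_max_depth_bounds_chain_length(self):
        # a linear induces-cascade of 6 proteins, terminal fact at the end
        lines = ["drug(d)."]
        proteins = [f"p{i}" for i in range(1, 7)]
        lines += [f"protein({p})." for p in proteins]
        lines.append("suppressor(p6).")
        lines.append("interaction(d, induces, p1).")
        lines += [f"interaction(p{i}, induces, p{i+1})." for i in range(1, 6)]
        kb = parse_fact_file("\n".join(lines))
        chains, _ = infer(kb, "d", "cancer", policy=EnginePolicy(max_depth=5))
        assert chains == []  # p6 sits at step 6 > max_depth
        chains, _ = infer(kb, "d", "cancer", policy=EnginePolicy(max_depth=6))
        assert len(chains) == 1 and len(chains[0].triggers) == 7

    def test_max_depth_below_two_rejected(self, dipyridamole_kb):
        with pytest.raises(EngineError, match="max_depth"):
            infer(dipyridamole_kb, "dipyridamole", "cancer", policy=EnginePolicy(max_depth=1))

    def test_infer_all_on_merged_examples(self, merged_examples_kb):
        results = infer_all(merged_examples_kb, "cancer")
        assert inferred_drugs(results) == {"dipyridamole", "tazarotene"}
        assert list(results) == sorted(results)

    def test_infer_all_on_empty_kb(self):
        assert infer_all(parse_fact_file(""), "cancer") == {}


class TestTriggerInvariants:
    def test_step_one_exactly_for_initial_rules(self):
        with pytest.raises(EngineError):
            Trigger("d", "activates", "p", 2, "R1b")
        with pytest.raises(EngineError):
            Trigger("d", "activates", "p", 1, "R2a")

    def test_chain_requires_consecutive_steps_and_terminal_conclusion(self):
        t1 = Trigger("d", "activates", "p", 1, "R1b")
        with pytest.raises(EngineError, match="treats or promotes"):
            InferenceChain("d", (t1,))
        tt = Trigger("d", "treats", "cancer", 3, "R5")
        with pytest.raises(EngineError, match="consecutive"):
            InferenceChain("d", (t1, tt))


class TestValidator:
    def test_engine_output_revalidates(self, merged_examples_kb, cancer_map):
        for drug, (chains, _) in infer_all(merged_examples_kb, "cancer", cancer_map).items():
            for chain in chains:
                assert validate_chain(merged_examples_kb, chain, "cancer", cancer_map) == []

    def test_tampered_chain_is_rejected(self, tazarotene_kb, cancer_map):
        (chain,), _ = infer(tazarotene_kb, "tazarotene", "cancer", cancer_map)
        bad_support = InferenceChain(
            "tazarotene",
            chain.triggers[:-1]
            + (Trigger("tazarotene", "treats", "cancer", 3, "R4",
                       ("oncogene(rara).",)),))
        problems = validate_chain(tazarotene_kb, bad_support, "cancer", cancer_map)
        assert any("not in KB" in p for p in problems)
        wrong_rule = InferenceChain(
            "tazarotene",
            chain.triggers[:-1]
            + (Trigger("tazarotene", "treats", "cancer", 3, "R5",
                       ("oncogene(egfr).",)),))
        assert validate_chain(tazarotene_kb, wrong_rule, "cancer", cancer_map)

    def test_policy_violations_detected(self, cancer_map):
        kb = parse_fact_file(
            "drug(d). protein(p1). protein(p2). oncogene(p2).\n"
            "interaction(d, inhibits, p1). interaction(p1, induces, p2).")
        (chain,), _ = infer(kb, "d", "cancer", cancer_map)
        problems = validate_chain(kb, chain, "cancer", cancer_map,
                                  EnginePolicy(inactivation_propagation=False))
        assert any("R2c" in p for p in problems)
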