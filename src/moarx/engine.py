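"""Stepped forward-chaining inference over the drug-mechanism knowledge base.

A *trigger* records one inference step: ``trigger(Dr, Action, Prot, Step)``
says that drug ``Dr`` causes ``Action`` on ``Prot`` at step ``Step``. Chains
of triggers are grown from a drug's own targets outward:

* step 1 (initial): an antagonist drug inactivates its target (R1a), an
  agonist activates it (R1b);
* propagation: an activated protein that induces (inhibits) another protein
  activates (inactivates) it — R2a/R2b; an inactivated protein that induces
  another protein inactivates it (loss of an activator, R2c, on by default);
  inactivating an inhibitor may optionally activate its target (double
  negation, R2d, off by default);
* terminal rules conclude ``treats``: inactivating a protein whose
  overexpression is disease-associated (R3a), activating one whose
  underexpression is (R3b), inactivating an oncogene (R4), activating a tumor
  suppressor (R5), inactivating a protein in a cancer-promoting process (R6),
  activating one in a cancer-resisting process (R7).

Mirror anti-mechanism rules C1–C5 conclude ``promotes`` (e.g. activating an
oncogene), and the contradiction policy decides whether a drug with both
treats and promotes derivations is blocked, flagged, or the C-rules are
ignored entirely.

A chain reaching ``treats`` in 2 steps is a *direct* inference (the drug's
own target carries the disease link); 3 or more steps is *indirect*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .kb import (
    DiseaseClassMap,
    KBError,
    KnowledgeBase,
    map_disease_class,
    oncogene_fact,
    promoting_bp_fact,
    resisting_bp_fact,
    suppressor_fact,
)

ACTIVATES = "activates"
INACTIVATES = "inactivates"
TREATS = "treats"
PROMOTES = "promotes"

ACTIONS = (ACTIVATES, INACTIVATES, TREATS, PROMOTES)
INITIAL_RULES = ("R1a", "R1b")
PROPAGATION_RULES = ("R2a", "R2b", "R2c", "R2d")
TERMINAL_RULES = ("R3a", "R3b", "R4", "R5", "R6", "R7")
CONTRADICTION_RULES = ("C1", "C2", "C3", "C4", "C5")
RULE_IDS = INITIAL_RULES + PROPAGATION_RULES + TERMINAL_RULES + CONTRADICTION_RULES

CONTRADICTION_MODES = ("block", "flag", "ignore")


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class EnginePolicy:
    """Tunable reasoning policy.

    max_depth bounds the step index of propagation triggers, so a chain has
    at most max_depth+1 triggers (the terminal treats/promotes step may sit
    one past the bound). contradiction_mode controls the anti-mechanism
    check; inactivation_propagation enables R2c; double_negation_rule
    enables R2d.
    """

    max_depth: int = 5
    contradiction_mode: str = "block"
    double_negation_rule: bool = False
    inactivation_propagation: bool = True

    def validate(self) -> "EnginePolicy":
        if self.max_depth < 2:
            raise EngineError("max_depth must be >= 2 (a treats chain needs two steps)")
        if self.contradiction_mode not in CONTRADICTION_MODES:
            raise EngineError(
                f"contradiction_mode must be one of {CONTRADICTION_MODES}, "
                f"got {self.contradiction_mode!r}"
            )
        return self

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "contradiction_mode": self.contradiction_mode,
            "double_negation_rule": self.double_negation_rule,
            "inactivation_propagation": self.inactivation_propagation,
        }


@dataclass(frozen=True)
class Trigger:
    """One inference step: drug acts on a target at a step index.

    ``target`` is a protein for activates/inactivates and a disease class
    for treats/promotes. ``support`` holds the KB fact strings the rule
    firing consumed, in the fact dialect, sorted.
    """

    drug: str
    action: str
    target: str
    step: int
    rule_id: str
    support: tuple = ()

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise EngineError(f"unknown action {self.action!r}")
        if self.rule_id not in RULE_IDS:
            raise EngineError(f"unknown rule id {self.rule_id!r}")
        if self.step < 1:
            raise EngineError("step must be >= 1")
        if (self.step == 1) != (self.rule_id in INITIAL_RULES):
            raise EngineError("step == 1 exactly for initial rules R1a/R1b")
        object.__setattr__(self, "support", tuple(self.support))

    @property
    def key(self) -> tuple:
        return (self.action, self.target, self.step, self.rule_id, self.support)

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "target": self.target,
            "step": self.step,
            "rule": self.rule_id,
            "support": list(self.support),
        }

    def __str__(self) -> str:
        return f"trigger({self.drug}, {self.action}, {self.target}, {self.step})"


@dataclass(frozen=True)
class InferenceChain:
    """An ordered trigger sequence ending in a treats (or promotes) trigger."""

    drug: str
    triggers: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "triggers", tuple(self.triggers))
        if not self.triggers:
            raise EngineError("a chain needs at least one trigger")
        for i, t in enumerate(self.triggers, start=1):
            if t.step != i:
                raise EngineError("chain steps must be consecutive from 1")
            if t.drug != self.drug:
                raise EngineError("all triggers in a chain belong to one drug")
        if self.triggers[-1].action not in (TREATS, PROMOTES):
            raise EngineError("the last trigger must conclude treats or promotes")

    @property
    def classification(self) -> str:
        return "direct" if len(self.triggers) == 2 else "indirect"

    @property
    def terminal_rule(self) -> str:
        return self.triggers[-1].rule_id

    @property
    def conclusion(self) -> str:
        return self.triggers[-1].action

    @property
    def key(self) -> tuple:
        return tuple(t.key for t in self.triggers)

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "classification": self.classification,
            "terminal_rule": self.terminal_rule,
            "conclusion": self.conclusion,
            "triggers": [t.to_dict() for t in self.triggers],
        }


@dataclass(frozen=True)
class ContradictionReport:
    """Treats vs promotes derivations for one drug."""

    drug: str
    promoting_chains: tuple = ()
    treating_chains: tuple = ()

    @property
    def verdict(self) -> str:
        if self.promoting_chains and self.treating_chains:
            return "contradictory"
        if self.promoting_chains:
            return "promoting_only"
        return "clean"

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "verdict": self.verdict,
            "promoting_chains": [c.to_dict() for c in self.promoting_chains],
            "n_treating_chains": len(self.treating_chains),
        }


# ---------------------------------------------------------------------------
# Rule firings
# ---------------------------------------------------------------------------


def initial_triggers(kb: KnowledgeBase, drug: str) -> List[Trigger]:
    """R1a/R1b: a drug inactivates (activates) the targets it inhibits (induces)."""
    if drug not in kb.registry.drugs:
        raise EngineError(f"drug {drug!r} is not registered in the knowledge base")
    out = []
    for i in kb.interactions:
        if i.subject != drug:
            continue
        if i.verb == "inhibits":
            out.append(Trigger(drug, INACTIVATES, i.object, 1, "R1a", (i.fact(),)))
        else:
            out.append(Trigger(drug, ACTIVATES, i.object, 1, "R1b", (i.fact(),)))
    return out


_SIGN_TABLE = {
    # (current action, edge verb) -> (next action, rule id, policy gate)
    (ACTIVATES, "induces"): (ACTIVATES, "R2a", None),
    (ACTIVATES, "inhibits"): (INACTIVATES, "R2b", None),
    (INACTIVATES, "induces"): (INACTIVATES, "R2c", "inactivation_propagation"),
    (INACTIVATES, "inhibits"): (ACTIVATES, "R2d", "double_negation_rule"),
}


def propagate(kb: KnowledgeBase, t: Trigger, policy: EnginePolicy,
              visited: Optional[frozenset] = None) -> List[Trigger]:
    """R2x: push the trigger's sign one protein-protein hop downstream.

    ``visited`` holds proteins already assigned an action earlier in the same
    chain; they are never re-triggered (cycle guard). Defaults to the
    trigger's own target.
    """
    if t.action not in (ACTIVATES, INACTIVATES):
        raise EngineError("only activates/inactivates triggers propagate")
    if t.step >= policy.max_depth:
        return []
    if visited is None:
        visited = frozenset((t.target,))
    out = []
    for i in kb.interactions:
        if i.subject != t.target or i.object in visited:
            continue
        action, rule, gate = _SIGN_TABLE[(t.action, i.verb)]
        if gate is not None and not getattr(policy, gate):
            continue
        out.append(Trigger(t.drug, action, i.object, t.step + 1, rule, (i.fact(),)))
    return out


def terminal_triggers(kb: KnowledgeBase, t: Trigger, disease_class: str,
                      dmap: DiseaseClassMap) -> List[Trigger]:
    """R3–R7: conclude treats when the trigger hits disease-linked knowledge.

    One trigger is emitted per (rule, supporting fact) firing, so the same
    protein can close a chain several ways.
    """
    if t.action not in (ACTIVATES, INACTIVATES):
        raise EngineError("terminal rules fire on activates/inactivates triggers")
    out = []
    step = t.step + 1
    p = t.target
    for r in kb.disease_relations:
        if r.protein != p or map_disease_class(r.disease, dmap) != disease_class:
            continue
        if t.action == INACTIVATES and r.expression_state == "overexpressed":
            out.append(Trigger(t.drug, TREATS, disease_class, step, "R3a", (r.fact(),)))
        elif t.action == ACTIVATES and r.expression_state == "underexpressed":
            out.append(Trigger(t.drug, TREATS, disease_class, step, "R3b", (r.fact(),)))
    if t.action == INACTIVATES and p in kb.classes.oncogenes:
        out.append(Trigger(t.drug, TREATS, disease_class, step, "R4", (oncogene_fact(p),)))
    if t.action == ACTIVATES and p in kb.classes.suppressors:
        out.append(Trigger(t.drug, TREATS, disease_class, step, "R5", (suppressor_fact(p),)))
    for b in kb.bioprocess_relations:
        if b.protein != p:
            continue
        if t.action == INACTIVATES and b.bioprocess in kb.classes.promoting_bps:
            support = tuple(sorted((b.fact(), promoting_bp_fact(b.bioprocess))))
            out.append(Trigger(t.drug, TREATS, disease_class, step, "R6", support))
        if t.action == ACTIVATES and b.bioprocess in kb.classes.resisting_bps:
            support = tuple(sorted((b.fact(), resisting_bp_fact(b.bioprocess))))
            out.append(Trigger(t.drug, TREATS, disease_class, step, "R7", support))
    return out


def contradiction_triggers(kb: KnowledgeBase, t: Trigger, disease_class: str,
                           dmap: DiseaseClassMap) -> List[Trigger]:
    """C1–C5: mirrored anti-mechanism rules concluding promotes.

    Activating an oncogene (C1), inactivating a suppressor (C2), activating a
    protein in a cancer-promoting process (C3), inactivating one in a
    cancer-resisting process (C4), or pushing a disease-associated expression
    state the wrong way (C5) derives that the drug would promote the disease.
    """
    if t.action not in (ACTIVATES, INACTIVATES):
        raise EngineError("contradiction rules fire on activates/inactivates triggers")
    out = []
    step = t.step + 1
    p = t.target
    if t.action == ACTIVATES and p in kb.classes.oncogenes:
        out.append(Trigger(t.drug, PROMOTES, disease_class, step, "C1", (oncogene_fact(p),)))
    if t.action == INACTIVATES and p in kb.classes.suppressors:
        out.append(Trigger(t.drug, PROMOTES, disease_class, step, "C2", (suppressor_fact(p),)))
    for b in kb.bioprocess_relations:
        if b.protein != p:
            continue
        if t.action == ACTIVATES and b.bioprocess in kb.classes.promoting_bps:
            support = tuple(sorted((b.fact(), promoting_bp_fact(b.bioprocess))))
            out.append(Trigger(t.drug, PROMOTES, disease_class, step, "C3", support))
        if t.action == INACTIVATES and b.bioprocess in kb.classes.resisting_bps:
            support = tuple(sorted((b.fact(), resisting_bp_fact(b.bioprocess))))
            out.append(Trigger(t.drug, PROMOTES, disease_class, step, "C4", support))
    for r in kb.disease_relations:
        if r.protein != p or map_disease_class(r.disease, dmap) != disease_class:
            continue
        if t.action == ACTIVATES and r.expression_state == "overexpressed":
            out.append(Trigger(t.drug, PROMOTES, disease_class, step, "C5", (r.fact(),)))
        elif t.action == INACTIVATES and r.expression_state == "underexpressed":
            out.append(Trigger(t.drug, PROMOTES, disease_class, step, "C5", (r.fact(),)))
    return out


# ---------------------------------------------------------------------------
# Chain enumeration
# ---------------------------------------------------------------------------


def _chain_sort_key(chain: InferenceChain) -> tuple:
    return (len(chain.triggers), chain.key)


def infer(kb: KnowledgeBase, drug: str, disease_class: str,
          dmap: Optional[DiseaseClassMap] = None,
          policy: Optional[EnginePolicy] = None) -> Tuple[List[InferenceChain], ContradictionReport]:
    """Enumerate all distinct treats chains for one drug, plus the
    contradiction report.

    Chains are simple signed paths: a protein never appears twice in one
    chain, and propagation steps never exceed ``policy.max_depth``. Under
    ``contradiction_mode='block'`` a drug with both treats and promotes
    derivations yields zero treats chains (they stay inside the report);
    ``'flag'`` returns chains plus the report; ``'ignore'`` skips the C-rules.
    """
    dmap = dmap if dmap is not None else DiseaseClassMap(target_class=disease_class)
    policy = (policy or EnginePolicy()).validate()
    use_c = policy.contradiction_mode != "ignore"
    treats: Dict[tuple, InferenceChain] = {}
    promotes: Dict[tuple, InferenceChain] = {}

    def extend(path: tuple, visited: frozenset) -> None:
        last = path[-1]
        for tt in terminal_triggers(kb, last, disease_class, dmap):
            chain = InferenceChain(drug, path + (tt,))
            treats[chain.key] = chain
        if use_c:
            for ct in contradiction_triggers(kb, last, disease_class, dmap):
                chain = InferenceChain(drug, path + (ct,))
                promotes[chain.key] = chain
        if last.step < policy.max_depth:
            for nt in propagate(kb, last, policy, visited=visited):
                extend(path + (nt,), visited | {nt.target})

    for t0 in initial_triggers(kb, drug):
        extend((t0,), frozenset((t0.target,)))

    treating = tuple(sorted(treats.values(), key=_chain_sort_key))
    promoting = tuple(sorted(promotes.values(), key=_chain_sort_key))
    report = ContradictionReport(drug, promoting_chains=promoting, treating_chains=treating)
    if policy.contradiction_mode == "block" and report.verdict == "contradictory":
        return [], report
    return list(treating), report


def infer_all(kb: KnowledgeBase, disease_class: str,
              dmap: Optional[DiseaseClassMap] = None,
              policy: Optional[EnginePolicy] = None) -> Dict[str, Tuple[List[InferenceChain], ContradictionReport]]:
    """Run :func:`infer` for every registered drug, in lexicographic order."""
    return {
        drug: infer(kb, drug, disease_class, dmap, policy)
        for drug in sorted(kb.registry.drugs)
    }


def inferred_drugs(results: Dict[str, tuple]) -> set:
    """Drugs with at least one surviving treats chain in an infer_all result."""
    return {drug for drug, (chains, _report) in results.items() if chains}


# ---------------------------------------------------------------------------
# Independent chain validator
# ---------------------------------------------------------------------------


def _kb_fact_strings(kb: KnowledgeBase) -> set:
    facts = {f.fact() for f in kb.interactions}
    facts |= {f.fact() for f in kb.disease_relations}
    facts |= {f.fact() for f in kb.bioprocess_relations}
    facts |= {oncogene_fact(p) for p in kb.classes.oncogenes}
    facts |= {suppressor_fact(p) for p in kb.classes.suppressors}
    facts |= {promoting_bp_fact(b) for b in kb.classes.promoting_bps}
    facts |= {resisting_bp_fact(b) for b in kb.classes.resisting_bps}
    return facts


_EXPECTED_SIGNS = {
    "R1a": INACTIVATES, "R1b": ACTIVATES,
    "R2a": ACTIVATES, "R2b": INACTIVATES, "R2c": INACTIVATES, "R2d": ACTIVATES,
}


def validate_chain(kb: KnowledgeBase, chain: InferenceChain, disease_class: str,
                   dmap: Optional[DiseaseClassMap] = None,
                   policy: Optional[EnginePolicy] = None) -> List[str]:
    """Re-check a chain's soundness against the KB; returns a list of problems
    (empty when the chain is valid).

    Checks every support fact exists in the KB, each step's rule precondition
    holds, steps are consecutive, no protein is revisited, and the policy
    allows the rules used. Deliberately re-derives preconditions from the
    support strings rather than re-running the engine's firing code.
    """
    dmap = dmap if dmap is not None else DiseaseClassMap(target_class=disease_class)
    policy = (policy or EnginePolicy()).validate()
    problems: List[str] = []
    facts = _kb_fact_strings(kb)
    seen_proteins: set = set()
    prev: Optional[Trigger] = None

    for t in chain.triggers:
        for s in t.support:
            if s not in facts:
                problems.append(f"step {t.step}: support fact not in KB: {s}")
        if t.rule_id in ("R2c",) and not policy.inactivation_propagation:
            problems.append(f"step {t.step}: rule R2c disabled by policy")
        if t.rule_id in ("R2d",) and not policy.double_negation_rule:
            problems.append(f"step {t.step}: rule R2d disabled by policy")
        if t.action in (ACTIVATES, INACTIVATES):
            if t.step > policy.max_depth:
                problems.append(f"step {t.step}: exceeds max_depth {policy.max_depth}")
            if t.target in seen_proteins:
                problems.append(f"step {t.step}: protein {t.target} revisited")
            seen_proteins.add(t.target)
            expected = _EXPECTED_SIGNS.get(t.rule_id)
            if expected is None:
                problems.append(f"step {t.step}: rule {t.rule_id} cannot assign a protein action")
            elif t.action != expected:
                problems.append(f"step {t.step}: rule {t.rule_id} assigns {expected}, not {t.action}")
            if t.step == 1:
                verb = "inhibits" if t.rule_id == "R1a" else "induces"
                want = f"interaction({chain.drug}, {verb}, {t.target})."
                if want not in t.support:
                    problems.append(f"step 1: expected support {want}")
            else:
                if prev is None or prev.action not in (ACTIVATES, INACTIVATES):
                    problems.append(f"step {t.step}: no propagating predecessor")
                else:
                    verb = {"R2a": "induces", "R2b": "inhibits",
                            "R2c": "induces", "R2d": "inhibits"}.get(t.rule_id)
                    want = f"interaction({prev.target}, {verb}, {t.target})."
                    if want not in t.support:
                        problems.append(f"step {t.step}: expected support {want}")
                    need_prev = ACTIVATES if t.rule_id in ("R2a", "R2b") else INACTIVATES
                    if prev.action != need_prev:
                        problems.append(
                            f"step {t.step}: rule {t.rule_id} needs predecessor {need_prev}")
        else:  # treats / promotes
            if t.target != disease_class:
                problems.append(f"step {t.step}: terminal target {t.target} != {disease_class}")
            if prev is None or prev.action not in (ACTIVATES, INACTIVATES):
                problems.append(f"step {t.step}: terminal trigger without a protein predecessor")
            else:
                ok = _terminal_precondition_holds(kb, prev, t, disease_class, dmap)
                if not ok:
                    problems.append(
                        f"step {t.step}: precondition of {t.rule_id} does not hold for "
                        f"{prev.action}({prev.target})")
        prev = t
    return problems


def _terminal_precondition_holds(kb: KnowledgeBase, prev: Trigger, t: Trigger,
                                 disease_class: str, dmap: DiseaseClassMap) -> bool:
    p = prev.target
    a = prev.action
    rid = t.rule_id
    if rid in ("R3a", "R3b", "C5"):
        want_state = {
            "R3a": ("overexpressed", INACTIVATES),
            "R3b": ("underexpressed", ACTIVATES),
        }.get(rid)
        for r in kb.disease_relations:
            if r.protein != p or map_disease_class(r.disease, dmap) != disease_class:
                continue
            if r.fact() not in t.support:
                continue
            if rid == "C5":
                if (a == ACTIVATES and r.expression_state == "overexpressed") or \
                   (a == INACTIVATES and r.expression_state == "underexpressed"):
                    return True
            elif r.expression_state == want_state[0] and a == want_state[1]:
                return True
        return False
    if rid == "R4":
        return a == INACTIVATES and p in kb.classes.oncogenes
    if rid == "R5":
        return a == ACTIVATES and p in kb.classes.suppressors
    if rid == "C1":
        return a == ACTIVATES and p in kb.classes.oncogenes
    if rid == "C2":
        return a == INACTIVATES and p in kb.classes.suppressors
    if rid in ("R6", "R7", "C3", "C4"):
        want = {
            "R6": (INACTIVATES, kb.classes.promoting_bps),
            "R7": (ACTIVATES, kb.classes.resisting_bps),
            "C3": (ACTIVATES, kb.classes.promoting_bps),
            "C4": (INACTIVATES, kb.classes.resisting_bps),
        }[rid]
        if a != want[0]:
            return False
        for b in kb.bioprocess_relations:
            if b.protein == p and b.bioprocess in want[1] and b.fact() in t.support:
                return True
        return False
    return False


def results_to_json(results: Dict[str, tuple], disease_class: str,
                    policy: EnginePolicy) -> dict:
    """Serializable view of an infer_all result (stable ordering throughout)."""
    return {
        "disease_class": disease_class,
        "policy": policy.to_dict(),
        "drugs": {
            drug: {
                "chains": [c.to_dict() for c in chains],
                "report": report.to_dict(),
            }
            for drug, (chains, report) in sorted(results.items())
        },
    }
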