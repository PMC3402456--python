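"""Seeded synthetic knowledge bases with planted ground-truth chains, and an
exhaustive brute-force oracle used as the engine's correctness reference.

The generator emulates the shape of a real drug-mechanism knowledge base —
a sparse bipartite drug-target layer, a sparse directed signed protein-protein
layer, curated oncogene/suppressor labels, GO-style bioprocess memberships
and text-mined gene-disease relations — at roughly 1/50 the scale of a
DrugBank-era screen (defaults: 19 drugs, 80 proteins, drug-target and PPI
densities matched to 1704 interactions over 943 drugs and 16816 PPIs).
``n_planted_chains`` guaranteed treats chains are wired in explicitly so
recall against known ground truth is measurable.

The oracle (:func:`oracle_infer`) deliberately shares no traversal code with
the engine: it is a naive depth-first enumeration of simple signed paths over
the raw fact lists, re-applying each rule precondition inline, so agreement
between the two is a meaningful check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .engine import (
    ACTIVATES,
    INACTIVATES,
    PROMOTES,
    TREATS,
    ContradictionReport,
    EnginePolicy,
    InferenceChain,
    Trigger,
)
from .kb import (
    DiseaseClassMap,
    KnowledgeBase,
    KnowledgeBaseBuilder,
    map_disease_class,
    oncogene_fact,
    promoting_bp_fact,
    resisting_bp_fact,
    suppressor_fact,
)

#: Disease identifiers the default cancer map classifies into the class.
IN_CLASS_DISEASES = (
    "gastric_cancer",
    "breast_cancer",
    "acute_lymphoblastic_leukemia",
    "melanoma",
    "non_small_cell_lung_carcinoma",
)
#: Noise diseases outside the class.
OUT_OF_CLASS_DISEASES = ("depression", "hypertension", "rheumatoid_arthritis")


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthParams:
    """Knobs for the synthetic KB generator (see module docstring for the
    rationale behind the defaults)."""

    n_drugs: int = 19
    n_proteins: int = 80
    n_bioprocesses: int = 6
    p_drug_edge: float = 0.022
    p_ppi: float = 0.053
    frac_oncogene: float = 0.03
    frac_suppressor: float = 0.03
    frac_bioprocess_rel: float = 0.25
    frac_disease_rel: float = 0.10
    sign_split: float = 0.5
    n_planted_chains: int = 2
    planted_depth: int = 2
    seed: int = 0

    def validate(self) -> "SynthParams":
        for name in ("p_drug_edge", "p_ppi", "frac_oncogene", "frac_suppressor",
                     "frac_bioprocess_rel", "frac_disease_rel", "sign_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_drugs", "n_proteins", "n_bioprocesses", "n_planted_chains"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        if self.planted_depth < 2:
            raise SynthError("planted_depth must be >= 2")
        if self.n_planted_chains > 0:
            if self.n_drugs < 1:
                raise SynthError("planting chains requires at least one drug")
            if self.planted_depth - 1 > self.n_proteins:
                raise SynthError(
                    f"planted_depth {self.planted_depth} needs {self.planted_depth - 1} "
                    f"proteins but only {self.n_proteins} exist")
        return self


def _names(prefix: str, n: int) -> List[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_kb(params: SynthParams) -> Tuple[KnowledgeBase, List[InferenceChain]]:
    """Generate a KB plus the list of planted ground-truth treats chains.

    Identical parameters (including the seed) give byte-identical serialized
    output. Planted chains are derivable by the engine under
    ``contradiction_mode='ignore'`` with ``max_depth >= planted_depth - 1``
    and the default propagation policy; random surrounding facts can only add
    chains, never remove them, except through the contradiction check.
    Ground-truth disease relations use in-class diseases recognized by the
    default cancer :class:`DiseaseClassMap`.
    """
    params.validate()
    rng = random.Random(params.seed)
    b = KnowledgeBaseBuilder()

    drugs = _names("d", params.n_drugs)
    proteins = _names("p", params.n_proteins)
    bps = _names("bp", params.n_bioprocesses)
    b.drugs.update(drugs)
    b.proteins.update(proteins)
    b.bioprocesses.update(bps)
    diseases = list(IN_CLASS_DISEASES + OUT_OF_CLASS_DISEASES)
    b.diseases.update(diseases)

    # Class assertions: alternate promoting/resisting bioprocesses.
    for i, bp in enumerate(bps):
        (b.promoting_bps if i % 2 == 0 else b.resisting_bps).add(bp)
    for p in proteins:
        if rng.random() < params.frac_oncogene:
            b.oncogenes.add(p)
        if rng.random() < params.frac_suppressor:
            b.suppressors.add(p)

    def verb() -> str:
        return "induces" if rng.random() < params.sign_split else "inhibits"

    # Drug-target layer.
    for d in drugs:
        for p in proteins:
            if rng.random() < params.p_drug_edge:
                b.add_interaction(d, verb(), p, source="drugbank")
    # Protein-protein layer.
    for p1 in proteins:
        for p2 in proteins:
            if p1 != p2 and rng.random() < params.p_ppi:
                b.add_interaction(p1, verb(), p2, source="text_mining")
    # Gene-disease relations (in-class plus a little out-of-class noise).
    for p in proteins:
        if rng.random() < params.frac_disease_rel:
            b.add_disease_relation(
                p, rng.choice(("overexpressed", "underexpressed")),
                rng.choice(IN_CLASS_DISEASES), source="text_mining")
        if rng.random() < 0.5 * params.frac_disease_rel:  # out-of-class noise
            b.add_disease_relation(
                p, rng.choice(("overexpressed", "underexpressed")),
                rng.choice(OUT_OF_CLASS_DISEASES), source="text_mining")
    # Bioprocess memberships.
    for p in proteins:
        if bps and rng.random() < params.frac_bioprocess_rel:
            b.add_bioprocess_relation(p, rng.choice(bps), source="go")

    planted = [
        _plant_chain(rng, b, rng.choice(drugs), proteins, params.planted_depth)
        for _ in range(params.n_planted_chains)
    ]
    return b.build(), planted


def _plant_chain(rng: random.Random, b: KnowledgeBaseBuilder, drug: str,
                 proteins: List[str], depth: int) -> InferenceChain:
    """Insert the support facts for one treats chain and return it.

    The path visits ``depth - 1`` distinct proteins; hop signs avoid the
    double-negation rule so the chain is derivable under the default policy.
    """
    path = rng.sample(proteins, depth - 1)
    triggers: List[Trigger] = []

    v0 = rng.choice(("induces", "inhibits"))
    fact = b.add_interaction(drug, v0, path[0], source="drugbank")
    sign = ACTIVATES if v0 == "induces" else INACTIVATES
    triggers.append(Trigger(drug, sign, path[0], 1,
                            "R1b" if v0 == "induces" else "R1a", (fact.fact(),)))

    for i in range(1, depth - 1):
        prev_p, next_p = path[i - 1], path[i]
        if sign == ACTIVATES:
            v = rng.choice(("induces", "inhibits"))
            new_sign = ACTIVATES if v == "induces" else INACTIVATES
            rule = "R2a" if v == "induces" else "R2b"
        else:
            v = "induces"  # R2c; never rely on double negation
            new_sign = INACTIVATES
            rule = "R2c"
        fact = b.add_interaction(prev_p, v, next_p, source="text_mining")
        sign = new_sign
        triggers.append(Trigger(drug, sign, next_p, i + 1, rule, (fact.fact(),)))

    terminal = path[-1]
    if sign == INACTIVATES:
        choice = rng.choice(["oncogene", "disease", "bp"] if b.promoting_bps else ["oncogene", "disease"])
        if choice == "oncogene":
            b.oncogenes.add(terminal)
            tt = Trigger(drug, TREATS, "cancer", depth, "R4", (oncogene_fact(terminal),))
        elif choice == "disease":
            fact = b.add_disease_relation(terminal, "overexpressed",
                                          rng.choice(IN_CLASS_DISEASES), source="text_mining")
            tt = Trigger(drug, TREATS, "cancer", depth, "R3a", (fact.fact(),))
        else:
            bp = rng.choice(sorted(b.promoting_bps))
            fact = b.add_bioprocess_relation(terminal, bp, source="go")
            support = tuple(sorted((fact.fact(), promoting_bp_fact(bp))))
            tt = Trigger(drug, TREATS, "cancer", depth, "R6", support)
    else:
        choice = rng.choice(["suppressor", "disease", "bp"] if b.resisting_bps else ["suppressor", "disease"])
        if choice == "suppressor":
            b.suppressors.add(terminal)
            tt = Trigger(drug, TREATS, "cancer", depth, "R5", (suppressor_fact(terminal),))
        elif choice == "disease":
            fact = b.add_disease_relation(terminal, "underexpressed",
                                          rng.choice(IN_CLASS_DISEASES), source="text_mining")
            tt = Trigger(drug, TREATS, "cancer", depth, "R3b", (fact.fact(),))
        else:
            bp = rng.choice(sorted(b.resisting_bps))
            fact = b.add_bioprocess_relation(terminal, bp, source="go")
            support = tuple(sorted((fact.fact(), resisting_bp_fact(bp))))
            tt = Trigger(drug, TREATS, "cancer", depth, "R7", support)
    triggers.append(tt)
    return InferenceChain(drug, tuple(triggers))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

ORACLE_MAX_PROTEINS = 50


def _oracle_enumerate(kb: KnowledgeBase, drug: str, disease_class: str,
                      dmap: DiseaseClassMap, policy: EnginePolicy):
    """Naive exhaustive enumeration of all simple signed paths from the drug,
    collecting treats and promotes chains. Plain loops over the raw fact
    lists; no engine machinery."""
    treats = {}
    promotes = {}
    ppi_edges = [f for f in kb.interactions if f.subject in kb.registry.proteins]
    drug_edges = [f for f in kb.interactions if f.subject == drug]
    onc = kb.classes.oncogenes
    sup = kb.classes.suppressors
    pro_bp = kb.classes.promoting_bps
    res_bp = kb.classes.resisting_bps

    def terminal_and_contra(prefix, sign, prot):
        step = len(prefix) + 1
        found = []
        for r in kb.disease_relations:
            if r.protein != prot:
                continue
            if map_disease_class(r.disease, dmap) != disease_class:
                continue
            over = r.expression_state == "overexpressed"
            if sign == INACTIVATES and over:
                found.append((TREATS, "R3a", (r.fact(),)))
            if sign == ACTIVATES and not over:
                found.append((TREATS, "R3b", (r.fact(),)))
            if sign == ACTIVATES and over:
                found.append((PROMOTES, "C5", (r.fact(),)))
            if sign == INACTIVATES and not over:
                found.append((PROMOTES, "C5", (r.fact(),)))
        if prot in onc:
            if sign == INACTIVATES:
                found.append((TREATS, "R4", (oncogene_fact(prot),)))
            else:
                found.append((PROMOTES, "C1", (oncogene_fact(prot),)))
        if prot in sup:
            if sign == ACTIVATES:
                found.append((TREATS, "R5", (suppressor_fact(prot),)))
            else:
                found.append((PROMOTES, "C2", (suppressor_fact(prot),)))
        for rel in kb.bioprocess_relations:
            if rel.protein != prot:
                continue
            if rel.bioprocess in pro_bp:
                sup_facts = tuple(sorted((rel.fact(), promoting_bp_fact(rel.bioprocess))))
                if sign == INACTIVATES:
                    found.append((TREATS, "R6", sup_facts))
                else:
                    found.append((PROMOTES, "C3", sup_facts))
            if rel.bioprocess in res_bp:
                sup_facts = tuple(sorted((rel.fact(), resisting_bp_fact(rel.bioprocess))))
                if sign == ACTIVATES:
                    found.append((TREATS, "R7", sup_facts))
                else:
                    found.append((PROMOTES, "C4", sup_facts))
        for conclusion, rule, support in found:
            trig = Trigger(drug, conclusion, disease_class, step, rule, support)
            chain = InferenceChain(drug, tuple(prefix) + (trig,))
            (treats if conclusion == TREATS else promotes)[chain.key] = chain

    def walk(prefix):
        sign, prot = prefix[-1].action, prefix[-1].target
        terminal_and_contra(prefix, sign, prot)
        if len(prefix) >= policy.max_depth:
            return
        on_path = {t.target for t in prefix}
        for f in ppi_edges:
            if f.subject != prot or f.object in on_path:
                continue
            if sign == ACTIVATES and f.verb == "induces":
                nxt, rule = ACTIVATES, "R2a"
            elif sign == ACTIVATES and f.verb == "inhibits":
                nxt, rule = INACTIVATES, "R2b"
            elif sign == INACTIVATES and f.verb == "induces":
                if not policy.inactivation_propagation:
                    continue
                nxt, rule = INACTIVATES, "R2c"
            else:
                if not policy.double_negation_rule:
                    continue
                nxt, rule = ACTIVATES, "R2d"
            trig = Trigger(drug, nxt, f.object, len(prefix) + 1, rule, (f.fact(),))
            walk(prefix + [trig])

    for f in drug_edges:
        if f.verb == "inhibits":
            first = Trigger(drug, INACTIVATES, f.object, 1, "R1a", (f.fact(),))
        else:
            first = Trigger(drug, ACTIVATES, f.object, 1, "R1b", (f.fact(),))
        walk([first])

    order = lambda c: (len(c.triggers), c.key)
    return sorted(treats.values(), key=order), sorted(promotes.values(), key=order)


def oracle_infer(kb: KnowledgeBase, drug: str, disease_class: str,
                 dmap: Optional[DiseaseClassMap] = None,
                 policy: Optional[EnginePolicy] = None) -> List[InferenceChain]:
    """Exhaustive-path reference implementation of :func:`moarx.engine.infer`.

    Guard: refuses knowledge bases with more than 50 proteins. Applies the
    same contradiction policy semantics (block returns no treats chains when
    a promotes chain coexists; ignore skips the anti-rules).
    """
    if len(kb.registry.proteins) > ORACLE_MAX_PROTEINS:
        raise SynthError(
            f"oracle guard: {len(kb.registry.proteins)} proteins exceeds {ORACLE_MAX_PROTEINS}")
    if drug not in kb.registry.drugs:
        raise SynthError(f"drug {drug!r} is not registered")
    dmap = dmap if dmap is not None else DiseaseClassMap(target_class=disease_class)
    policy = (policy or EnginePolicy()).validate()
    treats, promotes = _oracle_enumerate(kb, drug, disease_class, dmap, policy)
    if policy.contradiction_mode == "ignore":
        return treats
    if policy.contradiction_mode == "block" and treats and promotes:
        return []
    return treats


def oracle_report(kb: KnowledgeBase, drug: str, disease_class: str,
                  dmap: Optional[DiseaseClassMap] = None,
                  policy: Optional[EnginePolicy] = None) -> ContradictionReport:
    """Oracle-side contradiction report (treats and promotes chains before
    any blocking is applied)."""
    if len(kb.registry.proteins) > ORACLE_MAX_PROTEINS:
        raise SynthError("oracle guard exceeded")
    dmap = dmap if dmap is not None else DiseaseClassMap(target_class=disease_class)
    policy = (policy or EnginePolicy()).validate()
    treats, promotes = _oracle_enumerate(kb, drug, disease_class, dmap, policy)
    if policy.contradiction_mode == "ignore":
        promotes = []
    return ContradictionReport(drug, promoting_chains=tuple(promotes),
                               treating_chains=tuple(treats))
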