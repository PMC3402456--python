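"""Optional answer-set-programming cross-check path.

:func:`emit_program` turns a knowledge base plus the mechanism rules into a
self-contained program for a stock ASP solver (clingo). The solver's set
semantics differ from the native engine's per-path chains in one way: the
solver derives trigger atoms as a set indexed by step, so a protein may be
re-derived at a later step through a cycle the engine's per-chain guard
forbids. The solver's derived ``treats`` drug set is therefore an
over-approximation of the engine's: engine-inferred drugs are always a
subset of solver-inferred drugs, and equality holds on acyclic interaction
graphs. The cross-check compares presence/absence of a treats conclusion per
drug, never per chain.
"""

from __future__ import annotations

import re
from typing import Optional, Set, Tuple

from .engine import EnginePolicy
from .kb import DiseaseClassMap, KnowledgeBase, serialize_facts

_BASE_RULES = """\
% Mechanism-of-action rules (R1: initial, R2: propagation, R3-R7: terminal).
trigger(Dr, inactivates, P, 1) :- drug(Dr), protein(P), interaction(Dr, inhibits, P).
trigger(Dr, activates, P, 1) :- drug(Dr), protein(P), interaction(Dr, induces, P).

trigger(Dr, activates, P2, S+1) :- trigger(Dr, activates, P1, S), protein(P2),
    interaction(P1, induces, P2), S < maxstep.
trigger(Dr, inactivates, P2, S+1) :- trigger(Dr, activates, P1, S), protein(P2),
    interaction(P1, inhibits, P2), S < maxstep.
"""

_R2C = """\
trigger(Dr, inactivates, P2, S+1) :- trigger(Dr, inactivates, P1, S), protein(P2),
    interaction(P1, induces, P2), S < maxstep.
"""

_R2D = """\
trigger(Dr, activates, P2, S+1) :- trigger(Dr, inactivates, P1, S), protein(P2),
    interaction(P1, inhibits, P2), S < maxstep.
"""

_TERMINAL_RULES = """\
trigger(Dr, treats, Class, S+1) :- trigger(Dr, inactivates, P, S),
    relation(overexpressed(P), associated_with, D), in_disease_class(D, Class).
trigger(Dr, treats, Class, S+1) :- trigger(Dr, activates, P, S),
    relation(underexpressed(P), associated_with, D), in_disease_class(D, Class).
trigger(Dr, treats, Class, S+1) :- trigger(Dr, inactivates, P, S), oncogene(P),
    disease_class(Class).
trigger(Dr, treats, Class, S+1) :- trigger(Dr, activates, P, S), suppressor(P),
    disease_class(Class).
trigger(Dr, treats, Class, S+1) :- trigger(Dr, inactivates, P, S),
    relation(P, is_associated, Bp), cancer_promoting_bioprocess(Bp), disease_class(Class).
trigger(Dr, treats, Class, S+1) :- trigger(Dr, activates, P, S),
    relation(P, is_associated, Bp), cancer_resisting_bioprocess(Bp), disease_class(Class).

treats(Dr, Class) :- trigger(Dr, treats, Class, S).
#show treats/2.
"""


def emit_program(kb: KnowledgeBase, disease_class: str = "cancer",
                 dmap: Optional[DiseaseClassMap] = None,
                 policy: Optional[EnginePolicy] = None) -> str:
    """Emit a complete clingo program: facts, disease-class mapping, rules."""
    dmap = dmap if dmap is not None else DiseaseClassMap(target_class=disease_class)
    policy = (policy or EnginePolicy()).validate()
    parts = [serialize_facts(kb)]
    parts.append(f"disease_class({disease_class}).")
    for d in sorted(kb.registry.diseases):
        if dmap.classify(d) == disease_class:
            parts.append(f"in_disease_class({d}, {disease_class}).")
    parts.append(f"#const maxstep={policy.max_depth}.")
    parts.append(_BASE_RULES)
    if policy.inactivation_propagation:
        parts.append(_R2C)
    if policy.double_negation_rule:
        parts.append(_R2D)
    parts.append(_TERMINAL_RULES)
    return "\n".join(parts)


_TREATS_ATOM_RE = re.compile(r"treats\(\s*([a-z][a-z0-9_]*)\s*,\s*([a-z][a-z0-9_]*)\s*\)")


def parse_model_output(text: str) -> Set[Tuple[str, str]]:
    """Extract (drug, disease_class) pairs from clingo's model output."""
    return {(m.group(1), m.group(2)) for m in _TREATS_ATOM_RE.finditer(text)}


def crosscheck_treats(engine_drugs: Set[str], solver_pairs: Set[Tuple[str, str]],
                      disease_class: str) -> bool:
    """True when every engine-inferred drug also appears in the solver's
    derived treats set (the solver over-approximates, so subset is the
    correct direction)."""
    solver_drugs = {d for d, c in solver_pairs if c == disease_class}
    return engine_drugs <= solver_drugs
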