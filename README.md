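# moarx

Rule-based mechanism-of-action (MOA) reasoning for drug repurposing.

`moarx` screens a knowledge base of typed biomedical facts — drug–target
interactions, signed protein–protein interactions, expression-qualified
gene–disease relations, oncogene / tumor-suppressor assertions, and GO-style
bioprocess memberships — and derives explicit, auditable hypotheses of the
form *drug X treats disease class D*, together with the exact causal chain of
inference steps that supports each hypothesis. It is aimed at computational
drug-repurposing groups who want mechanism-aware hypotheses (interaction type
and directionality respected) instead of co-occurrence networks.

## The model

Every inference step is a *trigger* `trigger(Dr, Action, Prot, Step)`: drug
`Dr` causes `Action` on `Prot` at step index `Step`. Chains are grown by
forward chaining over three rule groups:

- **Initial (R1a/R1b).** An antagonist drug inactivates its target; an
  agonist activates it: `interaction(Dr, inhibits, P)` ⟹
  `trigger(Dr, inactivates, P, 1)`.
- **Propagation (R2a–R2d).** Signs push one protein–protein hop downstream:
  an activated `P1` that induces (inhibits) `P2` activates (inactivates) it;
  an inactivated `P1` that induces `P2` inactivates it (loss of an activator,
  on by default); optionally, inactivating an inhibitor counts as activation
  (double negation, off by default). A chain never revisits a protein and is
  depth-bounded (default `max_depth = 5`).
- **Terminal (R3–R7).** `treats` concludes at step `S+1` when the drug has,
  at step `S`, inactivated a protein whose overexpression is
  disease-associated (R3a), activated one whose underexpression is (R3b),
  inactivated an oncogene (R4), activated a tumor suppressor (R5),
  inactivated a protein in a cancer-promoting bioprocess (R6), or activated
  one in a cancer-resisting bioprocess (R7).

Mirror anti-mechanism rules (C1–C5, e.g. *activating* an oncogene) conclude
`promotes`; the contradiction policy (`block` / `flag` / `ignore`) decides
whether a drug with both kinds of derivations is suppressed, annotated, or
screened without the check. A 2-step chain is a **direct** inference (the
drug's own target carries the disease link); ≥3 steps is **indirect**.

Facts travel in a plain AnsProlog-style fact dialect, e.g.

```prolog
drug(dipyridamole).
protein(ada).
disease(cancer).
interaction(dipyridamole, inhibits, ada). % source=drugbank
relation(overexpressed(ada), associated_with, cancer). % source=text_mining evidence=PMID:6981287
```

which is also valid input for a stock ASP solver (`moarx export-asp` emits a
complete solver program for cross-checking).

## Worked example

```python
from moarx import infer
from moarx.examples import tazarotene_kb

chains, report = infer(tazarotene_kb(), "tazarotene", "cancer")
for t in chains[0].triggers:
    print(t)
print(chains[0].classification, report.verdict)
```

prints

```
trigger(tazarotene, activates, rara, 1)
trigger(tazarotene, inactivates, egfr, 2)
trigger(tazarotene, treats, cancer, 3)
indirect clean
```

i.e. the agonist tazarotene activates its receptor RARA (step 1), activated
RARA inhibits the oncogene EGFR (step 2), and inhibition of an oncogene
concludes a potential cancer indication (step 3) — an indirect inference with
no contradicting anti-mechanism derivation. The same run from the shell:

```bash
moarx infer --kb tazarotene.lp --disease cancer --out chains.json
moarx validate --kb tazarotene.lp --chains chains.json   # independent re-check
```

Other entry points: `moarx synth` generates a seeded synthetic knowledge base
with planted ground-truth chains, `moarx evaluate` computes recall against a
labeled drug list (original indication vs clinical-trial evidence), and
`moarx ablate` re-runs the screen with terminal knowledge restricted to one
provenance source at a time (curated cancer genes / GO bioprocesses /
text-mined relations) to measure each source's contribution.

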