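# Methods

## Model and assumptions

`moarx` implements Boolean, mechanism-aware forward chaining over a typed
knowledge base. The state of a derivation is a *trigger* — drug, action
(`activates` / `inactivates` on proteins; `treats` / `promotes` on a disease
class), target, and a 1-based step index. A hypothesis is an *inference
chain*: a sequence of triggers with consecutive steps whose last trigger
concludes `treats` (or, for anti-mechanism derivations, `promotes`).

Assumptions baked into the rule set:

- Pharmacological action maps cleanly onto sign: agonist ⟹ induces,
  antagonist ⟹ inhibits. Drug–target rows without such an annotation are
  rejected by the loader rather than defaulted, since the sign is the entire
  content of the initial rule.
- Signed protein–protein edges compose transitively: activation propagates
  through induction (R2a) and flips through inhibition (R2b). The
  loss-of-activator reading — an *inactivated* protein that normally induces
  another leaves it inactivated (R2c) — is the biologically standard reading
  and is on by default. The double-negation reading (inhibiting an inhibitor
  activates its target, R2d) assumes basal activity of the downstream
  protein and is **off** by default; both are policy flags.
- Gene–disease relations are meaningful only with an expression state:
  "overexpressed P associated with D" supports treats-by-inactivation (R3a),
  "underexpressed P" supports treats-by-activation (R3b). Unqualified
  associations are rejected at load time because no rule can consume them.
- One disease class per run. Relations name specific diseases
  (`gastric_cancer`); a configurable `DiseaseClassMap` (explicit members
  first, then case-insensitive substring patterns; default lexicon: cancer,
  carcinoma, leukemia, lymphoma, tumor/tumour, melanoma, sarcoma, glioma)
  folds them into the goal class. The mapping is deterministic, idempotent
  and user-overridable via YAML/JSON.

## Chain semantics, cycles, determinism

The engine enumerates **all minimal causal paths** rather than a single
global derivation: one chain = one simple path from a drug-target edge to a
terminal fact. A chain never revisits a protein (cycle guard) and propagation
steps are bounded by `max_depth` (default 5; the canonical direct/indirect
examples need 2–3 steps, and deeper chains compound text-mining noise
multiplicatively). Chains are deduplicated on the full trigger sequence —
including rule ids and support facts, so the same conclusion reached through
different evidence is reported as distinct chains — and sorted by (length,
lexicographic trigger sequence). All outputs are byte-deterministic for
identical inputs.

## Contradiction handling

Each terminal rule has a mirrored anti-mechanism rule (C1: activates an
oncogene, C2: inactivates a suppressor, C3/C4: pushes a cancer-promoting /
-resisting bioprocess the wrong way, C5: pushes a disease-associated
expression state the wrong way). The per-drug report carries both chain
lists and a verdict: `contradictory` when treats and promotes derivations
coexist, `promoting_only` when only anti-mechanism derivations exist,
`clean` otherwise. Under the default `block` policy a contradictory drug
contributes no treats chains to the screen (they remain inspectable inside
the report); `flag` keeps them; `ignore` skips the C-rules. The C-rule set
mirrors the R-rules exactly; this symmetry is tested: on 2-step derivations,
flipping the drug-target verb swaps C-firings with R-firings one for one,
and the same holds on deeper chains whenever the propagation algebra is
sign-complete (R2c and R2d both enabled). Under the default policy (R2d
off) the deep-chain symmetry does not hold, which is why the property is
tested under those stated conditions.

## Synthetic knowledge bases

The generator emulates the *shape* of a curated-plus-text-mined KB at
roughly 1/50 the scale of a DrugBank-era screen: 19 drugs, 80 proteins, 6
signed bioprocesses; `p_drug_edge = 0.022` and `p_ppi = 0.053` reproduce the
≈1.8 drug-target edges per drug and ≈4 outgoing PPIs per protein of the
full-scale KB; 3% oncogene / 3% suppressor fractions, 25% of proteins with a
bioprocess membership, 10% with an in-class disease relation plus half that
rate of out-of-class noise relations; induces/inhibits split 50/50.
Provenance tags follow the natural origin of each layer (drug-target →
`drugbank`, PPIs and disease relations → `text_mining`, bioprocess
memberships → `go`, curated gene classes gated as `cancer_genes`).

Planted ground-truth chains are wired in explicitly (fresh drug-target edge,
hop edges avoiding the double-negation rule, one terminal fact matched to
the final sign), so they are derivable under `ignore` mode with
`max_depth ≥ planted_depth − 1` regardless of the random surroundings —
random facts can only add chains, never remove them, except through the
contradiction check, and that exception is itself asserted (every block-mode
loss coincides with a C-rule firing).

What the generator does **not** emulate: text-mining error models (false
relations, negation errors, wrong interactors), scale-free degree
distributions, gene-name ambiguity, and literature redundancy. Passing tests
therefore certify the reasoning machinery — rule semantics, enumeration
completeness, policy behavior, provenance gating — not the real-world
precision of any particular knowledge source.

## The brute-force oracle

`synth.oracle_infer` is an independent correctness reference: a naive
depth-first enumeration of all simple signed paths over the raw fact lists,
re-stating every rule precondition inline, sharing no traversal code with
the engine, and guarded to ≤ 50 proteins. The acceptance suite checks engine
= oracle chain-set equality on 1000 seeded KBs (20 proteins, 5 drugs) under
all 24 policy combinations (`max_depth` ∈ {3, 5} × 3 contradiction modes ×
2 × 2 propagation flags) — about 120,000 drug screens, a sweep sized to run
comfortably inside a routine test session.

## ASP cross-check

`moarx export-asp` emits the serialized facts, the disease-class membership
atoms, and the rule set as a complete program for a stock ASP solver. Solver
semantics derive trigger atoms as a *set* indexed by step, so a cyclic
interaction graph can re-derive a protein at a later step where the
per-chain cycle guard would not; the solver's per-drug treats set is
consequently an over-approximation of the engine's, and the cross-check
asserts the subset direction (equality on acyclic graphs). The packaged
round-trip test runs the solver only when one is on PATH.

## Evaluation and source ablation

`recall_metrics` reports recall against two disjoint label sets — drugs with
the target class as original indication, and drugs under clinical trials for
it — plus the confirmed fraction (confirmed / inferred), percentages to one
decimal, with empty-denominator metrics reported as undefined (`None`),
never zero. `source_ablation` re-runs the screen per provenance subset:
drug–target facts are always retained (a column with no initial triggers
could infer nothing), relational facts are gated by their own tag, and
class assertions by their natural source (`cancer_genes` for
oncogene/suppressor, `go` for the signed bioprocess classes). Subset
monotonicity (more sources ⟹ no fewer inferred drugs) holds in `ignore`
mode and is tested there; under `block` it can fail legitimately, because
removing a source can remove the contradiction that suppressed a drug. The
union of single-source screens equals the full screen only when every chain
is direct; indirect chains may need facts from two sources at once, so that
identity is tested on PPI-free KBs where it provably holds.

## Numerical / degenerate-input choices

- Atom normalization: lowercase, non-alphanumerics → `_`, non-letter-initial
  atoms prefixed with `x` (keeps output solver-parseable).
- Equality of knowledge bases is set-semantic on facts excluding the
  free-text evidence field; duplicates are dropped on construction.
- Empty KBs are valid everywhere: empty serialization, empty screen, exit 0.
- `max_depth < 2` is rejected (a treats chain needs two steps).
- Per-fact provenance rides in a trailing `% source=… evidence=…` comment —
  the dialect's only extension, invisible to an ASP solver.

## Known limitations

- Boolean inference: no weighting, ranking, or probability on chains.
- One disease class per run; multi-goal screens are separate runs.
- No gene-name normalization or alias resolution; identifiers are taken as
  given (one canonical symbol per gene).
- The contradiction verdict is computed from derivations within the KB; it
  cannot see conflicts the KB does not encode.
- Full literature-scale screens (hundreds of drugs over tens of thousands of
  text-mined relations) are supported by the data model but not shipped:
  loaders accept DrugBank-like and text-mining-shaped tables, and all
  metrics are computable on any supplied KB plus label file.
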