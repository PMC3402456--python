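"""Recall-style evaluation against labeled drug sets and knowledge-source
ablation.

Given a screen over a knowledge base (every drug run through the inference
engine), two labeled reference sets measure how well the inferred drug list
recovers known biology: drugs whose *original indication* is the target
disease class, and drugs without that indication currently in *clinical
trials* for it. The ablation re-runs the screen with the terminal knowledge
restricted to one provenance source at a time (curated cancer genes, GO
bioprocess memberships, text-mined relations) to measure each source's
contribution; drug-target facts are always retained because every chain
needs an initial trigger.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .engine import EnginePolicy, infer_all, inferred_drugs
from .kb import (
    ClassAssertions,
    DiseaseClassMap,
    KBError,
    KnowledgeBase,
    SOURCES,
    normalize_atom,
)

logger = logging.getLogger(__name__)

#: The three terminal-knowledge sources of the standard ablation.
ABLATION_SOURCES = ("cancer_genes", "go", "text_mining")


@dataclass(frozen=True)
class LabelSets:
    """Labeled drug sets: original-indication drugs, trial-evidence drugs,
    and the screened universe. The two labeled sets are disjoint (trial
    evidence is only counted for drugs without the original indication)."""

    original_indication: frozenset
    trial_evidence: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        for name in ("original_indication", "trial_evidence", "universe"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        if not self.original_indication <= self.universe:
            raise KBError("original-indication drugs must be within the universe")
        if not self.trial_evidence <= self.universe:
            raise KBError("trial-evidence drugs must be within the universe")
        overlap = self.original_indication & self.trial_evidence
        if overlap:
            raise KBError(f"label sets must be disjoint; overlap: {sorted(overlap)}")


def load_labels(path, universe: Iterable[str]) -> LabelSets:
    """Read a TSV with columns ``drug`` and ``label`` in {original, trial}."""
    original, trial = set(), set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            drug = normalize_atom(row["drug"])
            label = row["label"].strip().lower()
            if label == "original":
                original.add(drug)
            elif label == "trial":
                trial.add(drug)
            else:
                raise KBError(f"unknown label {label!r} for drug {drug!r}")
    return LabelSets(frozenset(original), frozenset(trial), frozenset(universe))


def _pct(numerator: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class RecallMetrics:
    """Recall against both label sets plus the confirmed fraction.

    Percentages are reported to one decimal; a metric over an empty label
    set is undefined and reported as None, never as zero.
    """

    n_inferred: int
    n_original_hit: int
    n_original: int
    n_trial_hit: int
    n_trial: int
    n_confirmed: int

    @property
    def recall_original_pct(self) -> Optional[float]:
        return _pct(self.n_original_hit, self.n_original)

    @property
    def recall_trial_pct(self) -> Optional[float]:
        return _pct(self.n_trial_hit, self.n_trial)

    @property
    def confirmed_pct(self) -> Optional[float]:
        return _pct(self.n_confirmed, self.n_inferred)

    def to_dict(self) -> dict:
        return {
            "total_inferences": self.n_inferred,
            "original_indication": {
                "hits": self.n_original_hit,
                "labeled": self.n_original,
                "recall_pct": self.recall_original_pct,
            },
            "trial_evidence": {
                "hits": self.n_trial_hit,
                "labeled": self.n_trial,
                "recall_pct": self.recall_trial_pct,
            },
            "confirmed": {
                "hits": self.n_confirmed,
                "confirmed_pct": self.confirmed_pct,
            },
        }


def recall_metrics(inferred: Iterable[str], labels: LabelSets) -> RecallMetrics:
    """Compute recall of the inferred drug set against both label sets."""
    inferred = frozenset(inferred)
    if not inferred <= labels.universe:
        raise KBError(
            f"inferred drugs outside the universe: {sorted(inferred - labels.universe)}")
    confirmed = inferred & (labels.original_indication | labels.trial_evidence)
    return RecallMetrics(
        n_inferred=len(inferred),
        n_original_hit=len(inferred & labels.original_indication),
        n_original=len(labels.original_indication),
        n_trial_hit=len(inferred & labels.trial_evidence),
        n_trial=len(labels.trial_evidence),
        n_confirmed=len(confirmed),
    )


# ---------------------------------------------------------------------------
# Source ablation
# ---------------------------------------------------------------------------


def filter_sources(kb: KnowledgeBase, tags: Iterable[str]) -> KnowledgeBase:
    """Restrict terminal knowledge to the given provenance tags.

    Drug-target interactions are always retained (a screen with no initial
    triggers could infer nothing). Protein-protein interactions, disease
    relations and bioprocess relations are kept when their own tag is in
    ``tags``; oncogene/suppressor assertions are gated by ``cancer_genes``
    and the signed bioprocess class assertions by ``go``. The registry is
    unchanged.
    """
    tags = frozenset(tags)
    unknown = tags - frozenset(SOURCES)
    if unknown:
        raise KBError(f"unknown source tags: {sorted(unknown)}")
    keep_genes = "cancer_genes" in tags
    keep_go = "go" in tags
    drugs = kb.registry.drugs
    return KnowledgeBase(
        registry=kb.registry,
        classes=ClassAssertions(
            oncogenes=kb.classes.oncogenes if keep_genes else frozenset(),
            suppressors=kb.classes.suppressors if keep_genes else frozenset(),
            promoting_bps=kb.classes.promoting_bps if keep_go else frozenset(),
            resisting_bps=kb.classes.resisting_bps if keep_go else frozenset(),
        ),
        interactions=tuple(
            i for i in kb.interactions if i.subject in drugs or i.source in tags
        ),
        disease_relations=tuple(r for r in kb.disease_relations if r.source in tags),
        bioprocess_relations=tuple(b for b in kb.bioprocess_relations if b.source in tags),
    )


@dataclass(frozen=True)
class SourceResult:
    """One ablation column: the inferred drug set plus its metrics."""

    sources: tuple
    inferred: tuple
    metrics: Optional[RecallMetrics]

    def to_dict(self) -> dict:
        return {
            "sources": list(self.sources),
            "inferred_drugs": list(self.inferred),
            "metrics": self.metrics.to_dict() if self.metrics else None,
        }


@dataclass(frozen=True)
class AblationResult:
    """Per-source-subset screens plus the full-KB screen."""

    per_source: tuple  # tuple of SourceResult
    full: SourceResult

    def to_dict(self) -> dict:
        return {
            "per_source": [s.to_dict() for s in self.per_source],
            "full": self.full.to_dict(),
        }

    def to_table(self) -> str:
        """Text table: one column per source subset plus 'All'."""
        cols = [s for s in self.per_source] + [self.full]
        headers = ["+".join(s.sources) if s is not self.full else "All" for s in cols]
        rows = [("", *headers)]

        def fmt(v):
            return "n/a" if v is None else (f"{v}" if isinstance(v, int) else f"{v:.1f}%")

        def metric_row(label, getter):
            rows.append((label, *[fmt(getter(c)) for c in cols]))

        metric_row("Original indication hits",
                   lambda c: c.metrics.n_original_hit if c.metrics else None)
        metric_row("Trial-evidence hits",
                   lambda c: c.metrics.n_trial_hit if c.metrics else None)
        metric_row("Total inferences", lambda c: len(c.inferred))
        metric_row("Recall (original)",
                   lambda c: c.metrics.recall_original_pct if c.metrics else None)
        metric_row("Recall (trial)",
                   lambda c: c.metrics.recall_trial_pct if c.metrics else None)
        metric_row("% confirmed",
                   lambda c: c.metrics.confirmed_pct if c.metrics else None)
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
        )


def _screen(kb: KnowledgeBase, disease_class: str, dmap, policy,
            labels: Optional[LabelSets], sources: tuple) -> SourceResult:
    results = infer_all(kb, disease_class, dmap, policy)
    inferred = tuple(sorted(inferred_drugs(results)))
    metrics = recall_metrics(inferred, labels) if labels is not None else None
    return SourceResult(sources=sources, inferred=inferred, metrics=metrics)


def source_ablation(kb: KnowledgeBase, source_subsets: Iterable[Iterable[str]],
                    disease_class: str, dmap: Optional[DiseaseClassMap] = None,
                    policy: Optional[EnginePolicy] = None,
                    labels: Optional[LabelSets] = None) -> AblationResult:
    """Run the screen once per source subset and once on the full KB."""
    dmap = dmap if dmap is not None else DiseaseClassMap(target_class=disease_class)
    policy = (policy or EnginePolicy()).validate()
    per_source = []
    for subset in source_subsets:
        subset = tuple(sorted(set(subset)))
        sub_kb = filter_sources(kb, subset)
        per_source.append(_screen(sub_kb, disease_class, dmap, policy, labels, subset))
    full = _screen(kb, disease_class, dmap, policy, labels, tuple(sorted(SOURCES)))
    return AblationResult(per_source=tuple(per_source), full=full)
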