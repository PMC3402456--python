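"""Typed knowledge base for drug mechanism-of-action reasoning.

The knowledge base holds four kinds of ground facts about the drug-mechanism
domain:

* drug-target and protein-protein interactions — directed, signed edges
  (``interaction(dipyridamole, inhibits, ada)``);
* gene-disease relations qualified by an expression state
  (``relation(overexpressed(ada), associated_with, cancer)``);
* gene-bioprocess memberships (``relation(pnp, is_associated,
  pos_reg_cell_proliferation)``);
* class assertions: oncogenes, tumor suppressors, and cancer-promoting /
  cancer-resisting biological processes.

Facts are exchanged in a small AnsProlog-style fact dialect: one ground atom
per line, lowercase atoms, a single level of functional nesting, a trailing
period. ``%`` starts a comment; a trailing ``% source=<tag>`` comment carries
per-fact provenance (the dialect itself has no provenance slot) and keeps the
file valid input for a stock ASP solver.

Every fact carries a provenance tag (``drugbank``, ``cancer_genes``, ``go``,
``text_mining`` or ``other``) so that knowledge-source ablations can gate
facts by origin.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import yaml

logger = logging.getLogger(__name__)

SOURCES = ("drugbank", "cancer_genes", "go", "text_mining", "other")
VERBS = ("induces", "inhibits")
EXPRESSION_STATES = ("overexpressed", "underexpressed")

#: Default drug-target pharmacological-action synonyms.
DEFAULT_ACTION_MAP = {"agonist": "induces", "antagonist": "inhibits"}

#: Default substring lexicon mapping specific malignancies into the class
#: ``cancer`` (text-mined relations name e.g. ``gastric_cancer`` while the
#: reasoning goal is the disease class itself).
DEFAULT_CANCER_PATTERNS = (
    "cancer",
    "carcinoma",
    "leukemia",
    "lymphoma",
    "tumor",
    "tumour",
    "melanoma",
    "sarcoma",
    "glioma",
)


class KBError(ValueError):
    """Base error for knowledge-base construction and parsing."""


class FactSyntaxError(KBError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownPredicateError(FactSyntaxError):
    pass


class ReferentialError(KBError):
    """A fact references an identifier missing from the registry."""


_ATOM_RE = re.compile(r"[a-z][a-z0-9_]*\Z")


def normalize_atom(name: str) -> str:
    """Normalize an external identifier to a lowercase logic atom.

    Non-alphanumeric characters become underscores; identifiers that do not
    start with a letter are prefixed with ``x`` so the result is a valid
    ASP constant (``Dipyridamole`` -> ``dipyridamole``, ``5-FU`` -> ``x5_fu``).
    """
    atom = re.sub(r"[^a-z0-9]", "_", str(name).strip().lower())
    if not atom or not atom.strip("_"):
        raise KBError(f"cannot normalize identifier {name!r} to an atom")
    if not atom[0].isalpha():
        atom = "x" + atom
    return atom


def _check_atom(atom: str, what: str) -> str:
    if not _ATOM_RE.match(atom):
        raise KBError(f"{what} {atom!r} is not a lowercase atom")
    return atom


def _check_source(source: str) -> str:
    if source not in SOURCES:
        raise KBError(f"unknown source tag {source!r} (expected one of {SOURCES})")
    return source


# ---------------------------------------------------------------------------
# Fact types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interaction:
    """Directed, signed edge: drug→protein or protein→protein."""

    subject: str
    verb: str
    object: str
    source: str = "other"
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        _check_atom(self.subject, "interaction subject")
        _check_atom(self.object, "interaction object")
        if self.verb not in VERBS:
            raise KBError(f"interaction verb must be one of {VERBS}, got {self.verb!r}")
        if self.subject == self.object:
            raise KBError(f"self-interaction {self.subject!r} is not allowed")
        _check_source(self.source)

    @property
    def key(self) -> tuple:
        return ("interaction", self.subject, self.verb, self.object, self.source)

    def fact(self) -> str:
        return f"interaction({self.subject}, {self.verb}, {self.object})."


@dataclass(frozen=True)
class DiseaseRelation:
    """Expression-state-qualified gene-disease association."""

    protein: str
    expression_state: str
    disease: str
    source: str = "other"
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        _check_atom(self.protein, "relation protein")
        _check_atom(self.disease, "relation disease")
        if self.expression_state not in EXPRESSION_STATES:
            raise KBError(
                f"expression state must be one of {EXPRESSION_STATES}, "
                f"got {self.expression_state!r}"
            )
        _check_source(self.source)

    @property
    def key(self) -> tuple:
        return ("relation_disease", self.protein, self.expression_state, self.disease, self.source)

    def fact(self) -> str:
        return f"relation({self.expression_state}({self.protein}), associated_with, {self.disease})."


@dataclass(frozen=True)
class BioprocessRelation:
    """Protein participates in a biological process."""

    protein: str
    bioprocess: str
    source: str = "other"
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        _check_atom(self.protein, "relation protein")
        _check_atom(self.bioprocess, "relation bioprocess")
        _check_source(self.source)

    @property
    def key(self) -> tuple:
        return ("relation_bioprocess", self.protein, self.bioprocess, self.source)

    def fact(self) -> str:
        return f"relation({self.protein}, is_associated, {self.bioprocess})."


Fact = Union[Interaction, DiseaseRelation, BioprocessRelation]


def oncogene_fact(protein: str) -> str:
    return f"oncogene({protein})."


def suppressor_fact(protein: str) -> str:
    return f"suppressor({protein})."


def promoting_bp_fact(bp: str) -> str:
    return f"cancer_promoting_bioprocess({bp})."


def resisting_bp_fact(bp: str) -> str:
    return f"cancer_resisting_bioprocess({bp})."


# ---------------------------------------------------------------------------
# Registry and class assertions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityRegistry:
    """The typed universe of identifiers: drugs, proteins, diseases, bioprocesses.

    The four sets are pairwise disjoint; every identifier any fact mentions
    must be registered in exactly one of them.
    """

    drugs: frozenset = frozenset()
    proteins: frozenset = frozenset()
    diseases: frozenset = frozenset()
    bioprocesses: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("drugs", "proteins", "diseases", "bioprocesses"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        sets = [self.drugs, self.proteins, self.diseases, self.bioprocesses]
        names = ["drug", "protein", "disease", "bioprocess"]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise KBError(
                        f"identifiers registered as both {names[i]} and {names[j]}: "
                        f"{sorted(overlap)}"
                    )
        for s, what in zip(sets, names):
            for atom in s:
                _check_atom(atom, what)

    def kind_of(self, ident: str) -> Optional[str]:
        if ident in self.drugs:
            return "drug"
        if ident in self.proteins:
            return "protein"
        if ident in self.diseases:
            return "disease"
        if ident in self.bioprocesses:
            return "bioprocess"
        return None


@dataclass(frozen=True)
class ClassAssertions:
    """Curated class knowledge: cancer genes and signed GO process classes."""

    oncogenes: frozenset = frozenset()
    suppressors: frozenset = frozenset()
    promoting_bps: frozenset = frozenset()
    resisting_bps: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("oncogenes", "suppressors", "promoting_bps", "resisting_bps"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        overlap = self.promoting_bps & self.resisting_bps
        if overlap:
            raise KBError(
                f"bioprocesses asserted both cancer-promoting and cancer-resisting: {sorted(overlap)}"
            )
        # NB: a protein may legitimately be asserted both oncogene and
        # suppressor — curated sources disagree for some genes.


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnowledgeBase:
    """All typed facts plus per-fact provenance, with set semantics.

    Fact lists are deduplicated on their identity key (everything except the
    free-text evidence field) and stored in a canonical sorted order, so two
    knowledge bases built from the same facts in any order compare equal.
    """

    registry: EntityRegistry = field(default_factory=EntityRegistry)
    classes: ClassAssertions = field(default_factory=ClassAssertions)
    interactions: tuple = ()
    disease_relations: tuple = ()
    bioprocess_relations: tuple = ()

    def __post_init__(self) -> None:
        for name in ("interactions", "disease_relations", "bioprocess_relations"):
            facts = getattr(self, name)
            seen = {}
            for f in facts:
                if f.key not in seen:
                    seen[f.key] = f
            object.__setattr__(self, name, tuple(sorted(seen.values(), key=lambda f: f.key)))
        self._validate()

    def _validate(self) -> None:
        reg = self.registry
        for p in self.classes.oncogenes | self.classes.suppressors:
            if p not in reg.proteins:
                raise ReferentialError(f"class assertion references unregistered protein {p!r}")
        for bp in self.classes.promoting_bps | self.classes.resisting_bps:
            if bp not in reg.bioprocesses:
                raise ReferentialError(f"class assertion references unregistered bioprocess {bp!r}")
        for i in self.interactions:
            if reg.kind_of(i.subject) not in ("drug", "protein"):
                raise ReferentialError(
                    f"interaction subject {i.subject!r} is not a registered drug or protein"
                )
            if i.object not in reg.proteins:
                raise ReferentialError(f"interaction object {i.object!r} is not a registered protein")
        for r in self.disease_relations:
            if r.protein not in reg.proteins:
                raise ReferentialError(f"relation protein {r.protein!r} is not registered")
            if r.disease not in reg.diseases:
                raise ReferentialError(f"relation disease {r.disease!r} is not registered")
        for b in self.bioprocess_relations:
            if b.protein not in reg.proteins:
                raise ReferentialError(f"relation protein {b.protein!r} is not registered")
            if b.bioprocess not in reg.bioprocesses:
                raise ReferentialError(f"relation bioprocess {b.bioprocess!r} is not registered")

    # -- queries ----------------------------------------------------------

    def drug_target_interactions(self, drug: Optional[str] = None):
        for i in self.interactions:
            if i.subject in self.registry.drugs and (drug is None or i.subject == drug):
                yield i

    def protein_interactions(self, subject: Optional[str] = None):
        for i in self.interactions:
            if i.subject in self.registry.proteins and (subject is None or i.subject == subject):
                yield i

    @property
    def n_facts(self) -> int:
        return (
            len(self.interactions)
            + len(self.disease_relations)
            + len(self.bioprocess_relations)
        )

    def fact_counts(self) -> dict:
        return {
            "drugs": len(self.registry.drugs),
            "proteins": len(self.registry.proteins),
            "diseases": len(self.registry.diseases),
            "bioprocesses": len(self.registry.bioprocesses),
            "oncogenes": len(self.classes.oncogenes),
            "suppressors": len(self.classes.suppressors),
            "interactions": len(self.interactions),
            "disease_relations": len(self.disease_relations),
            "bioprocess_relations": len(self.bioprocess_relations),
        }

    # -- equality (evidence excluded) --------------------------------------

    def _identity(self) -> tuple:
        return (
            self.registry,
            self.classes,
            tuple(f.key for f in self.interactions),
            tuple(f.key for f in self.disease_relations),
            tuple(f.key for f in self.bioprocess_relations),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self._identity() == other._identity()

    def __hash__(self) -> int:
        return hash(self._identity())


class KnowledgeBaseBuilder:
    """Mutable accumulator for assembling a :class:`KnowledgeBase`."""

    def __init__(self) -> None:
        self.drugs: set = set()
        self.proteins: set = set()
        self.diseases: set = set()
        self.bioprocesses: set = set()
        self.oncogenes: set = set()
        self.suppressors: set = set()
        self.promoting_bps: set = set()
        self.resisting_bps: set = set()
        self.interactions: list = []
        self.disease_relations: list = []
        self.bioprocess_relations: list = []

    def add_drug(self, name: str) -> str:
        atom = normalize_atom(name)
        self.drugs.add(atom)
        return atom

    def add_protein(self, name: str) -> str:
        atom = normalize_atom(name)
        self.proteins.add(atom)
        return atom

    def add_disease(self, name: str) -> str:
        atom = normalize_atom(name)
        self.diseases.add(atom)
        return atom

    def add_bioprocess(self, name: str) -> str:
        atom = normalize_atom(name)
        self.bioprocesses.add(atom)
        return atom

    def add_oncogene(self, name: str) -> str:
        atom = self.add_protein(name)
        self.oncogenes.add(atom)
        return atom

    def add_suppressor(self, name: str) -> str:
        atom = self.add_protein(name)
        self.suppressors.add(atom)
        return atom

    def add_promoting_bp(self, name: str) -> str:
        atom = self.add_bioprocess(name)
        self.promoting_bps.add(atom)
        return atom

    def add_resisting_bp(self, name: str) -> str:
        atom = self.add_bioprocess(name)
        self.resisting_bps.add(atom)
        return atom

    def add_interaction(self, subject: str, verb: str, obj: str, source: str = "other",
                        evidence: Optional[str] = None) -> Interaction:
        fact = Interaction(subject, verb, obj, source, evidence)
        self.interactions.append(fact)
        return fact

    def add_disease_relation(self, protein: str, expression_state: str, disease: str,
                             source: str = "other", evidence: Optional[str] = None) -> DiseaseRelation:
        fact = DiseaseRelation(protein, expression_state, disease, source, evidence)
        self.disease_relations.append(fact)
        return fact

    def add_bioprocess_relation(self, protein: str, bioprocess: str, source: str = "other",
                                evidence: Optional[str] = None) -> BioprocessRelation:
        fact = BioprocessRelation(protein, bioprocess, source, evidence)
        self.bioprocess_relations.append(fact)
        return fact

    def build(self) -> KnowledgeBase:
        return KnowledgeBase(
            registry=EntityRegistry(
                drugs=frozenset(self.drugs),
                proteins=frozenset(self.proteins),
                diseases=frozenset(self.diseases),
                bioprocesses=frozenset(self.bioprocesses),
            ),
            classes=ClassAssertions(
                oncogenes=frozenset(self.oncogenes),
                suppressors=frozenset(self.suppressors),
                promoting_bps=frozenset(self.promoting_bps),
                resisting_bps=frozenset(self.resisting_bps),
            ),
            interactions=tuple(self.interactions),
            disease_relations=tuple(self.disease_relations),
            bioprocess_relations=tuple(self.bioprocess_relations),
        )


# ---------------------------------------------------------------------------
# Fact-dialect parser
# ---------------------------------------------------------------------------

_FACT_HEAD_RE = re.compile(r"([a-z][a-z0-9_]*)\s*\((.*)\)\s*\.\s*\Z", re.S)
_SOURCE_RE = re.compile(r"source\s*=\s*([a-z_]+)")
_EVIDENCE_RE = re.compile(r"evidence\s*=\s*(\S.*?)\s*\Z")

_DECLARATION_PREDICATES = (
    "drug", "protein", "disease", "bioprocess",
    "cancer_promoting_bioprocess", "cancer_resisting_bioprocess",
)
_KNOWN_PREDICATES = _DECLARATION_PREDICATES + (
    "oncogene", "suppressor", "interaction", "relation",
)


def _split_statements(code: str, lineno: int):
    """Split a comment-free line into `pred(...).` statements."""
    depth = 0
    buf = []
    for ch in code:
        buf.append(ch)
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FactSyntaxError("unbalanced ')'", lineno)
        elif ch == "." and depth == 0:
            stmt = "".join(buf).strip()
            if stmt:
                yield stmt
            buf = []
    if "".join(buf).strip():
        raise FactSyntaxError(f"statement missing terminating period: {''.join(buf).strip()!r}", lineno)


def _split_args(argstr: str, lineno: int):
    depth = 0
    buf = []
    args = []
    for ch in argstr:
        if ch == "(":
            depth += 1
            buf.append(ch)
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FactSyntaxError("unbalanced ')' in arguments", lineno)
            buf.append(ch)
        elif ch == "," and depth == 0:
            args.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    if depth != 0:
        raise FactSyntaxError("unbalanced '(' in arguments", lineno)
    args.append("".join(buf).strip())
    if any(not a for a in args):
        raise FactSyntaxError("empty argument", lineno)
    return args


_FUNC_ARG_RE = re.compile(r"([a-z][a-z0-9_]*)\s*\(\s*([a-z][a-z0-9_]*)\s*\)\s*\Z")


def _parse_arg(arg: str, lineno: int):
    """Return (functor, atom) for `f(a)` or (None, atom) for a plain atom."""
    if _ATOM_RE.match(arg):
        return None, arg
    m = _FUNC_ARG_RE.match(arg)
    if m:
        return m.group(1), m.group(2)
    raise FactSyntaxError(f"malformed term {arg!r}", lineno)


def parse_fact_file(text: str, *, default_source: str = "other") -> KnowledgeBase:
    """Parse fact-dialect text into a :class:`KnowledgeBase`.

    One or more facts per line, ``%`` comments, blank lines allowed. A
    trailing ``% source=<tag> [evidence=<text>]`` comment sets provenance for
    the facts on that line. Raises :class:`FactSyntaxError`,
    :class:`UnknownPredicateError` or :class:`ReferentialError` on bad input.
    """
    _check_source(default_source)
    statements = []  # (lineno, pred, args [(functor, atom)], source, evidence)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        code, _, comment = raw.partition("%")
        source = default_source
        evidence = None
        m = _SOURCE_RE.search(comment)
        if m:
            source = _check_source(m.group(1))
        m = _EVIDENCE_RE.search(comment)
        if m:
            evidence = m.group(1)
        if not code.strip():
            continue
        for stmt in _split_statements(code, lineno):
            head = _FACT_HEAD_RE.match(stmt)
            if not head:
                raise FactSyntaxError(f"malformed fact {stmt!r}", lineno)
            pred, argstr = head.group(1), head.group(2)
            if pred not in _KNOWN_PREDICATES:
                raise UnknownPredicateError(f"unknown predicate {pred!r}", lineno)
            args = [_parse_arg(a, lineno) for a in _split_args(argstr, lineno)]
            statements.append((lineno, pred, args, source, evidence))

    builder = KnowledgeBaseBuilder()

    def expect_arity(pred, args, n, lineno):
        if len(args) != n:
            raise FactSyntaxError(f"{pred} expects {n} argument(s), got {len(args)}", lineno)

    def plain(arg, lineno):
        functor, atom = arg
        if functor is not None:
            raise FactSyntaxError(f"unexpected nested term {functor}({atom})", lineno)
        return atom

    # Pass 1: entity declarations (order-independent files).
    for lineno, pred, args, _source, _ev in statements:
        if pred not in _DECLARATION_PREDICATES:
            continue
        expect_arity(pred, args, 1, lineno)
        atom = plain(args[0], lineno)
        if pred == "drug":
            builder.drugs.add(atom)
        elif pred == "protein":
            builder.proteins.add(atom)
        elif pred == "disease":
            builder.diseases.add(atom)
        elif pred == "bioprocess":
            builder.bioprocesses.add(atom)
        elif pred == "cancer_promoting_bioprocess":
            builder.bioprocesses.add(atom)
            builder.promoting_bps.add(atom)
        elif pred == "cancer_resisting_bioprocess":
            builder.bioprocesses.add(atom)
            builder.resisting_bps.add(atom)

    # Pass 2: class assertions over proteins and relational facts.
    for lineno, pred, args, source, evidence in statements:
        if pred in _DECLARATION_PREDICATES:
            continue
        if pred in ("oncogene", "suppressor"):
            expect_arity(pred, args, 1, lineno)
            atom = plain(args[0], lineno)
            if atom not in builder.proteins:
                raise ReferentialError(
                    f"line {lineno}: {pred}({atom}) references unregistered protein {atom!r}"
                )
            (builder.oncogenes if pred == "oncogene" else builder.suppressors).add(atom)
        elif pred == "interaction":
            expect_arity(pred, args, 3, lineno)
            subject = plain(args[0], lineno)
            verb = plain(args[1], lineno)
            obj = plain(args[2], lineno)
            try:
                builder.add_interaction(subject, verb, obj, source, evidence)
            except KBError as exc:
                raise FactSyntaxError(str(exc), lineno) from exc
        elif pred == "relation":
            expect_arity(pred, args, 3, lineno)
            verb = plain(args[1], lineno)
            if verb == "associated_with":
                functor, protein = args[0]
                if functor not in EXPRESSION_STATES:
                    raise FactSyntaxError(
                        "associated_with relation requires an overexpressed(...)/"
                        f"underexpressed(...) first argument, got {args[0]}", lineno)
                disease = plain(args[2], lineno)
                try:
                    builder.add_disease_relation(protein, functor, disease, source, evidence)
                except KBError as exc:
                    raise FactSyntaxError(str(exc), lineno) from exc
            elif verb == "is_associated":
                protein = plain(args[0], lineno)
                bp = plain(args[2], lineno)
                try:
                    builder.add_bioprocess_relation(protein, bp, source, evidence)
                except KBError as exc:
                    raise FactSyntaxError(str(exc), lineno) from exc
            else:
                raise FactSyntaxError(
                    f"relation verb must be associated_with or is_associated, got {verb!r}",
                    lineno,
                )

    return builder.build()


def load_fact_file(path) -> KnowledgeBase:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_fact_file(fh.read())


# ---------------------------------------------------------------------------
# Serializer
# ---------------------------------------------------------------------------


def _annotate(base: str, source: str, evidence: Optional[str]) -> str:
    parts = [base, f"% source={source}"]
    if evidence:
        parts.append(f"evidence={evidence}")
    return " ".join(parts)


def serialize_facts(kb: KnowledgeBase) -> str:
    """Emit a knowledge base in the fact dialect, deterministically ordered.

    Lines are sorted by predicate name then lexicographic arguments, so
    serialization is a canonical form: ``parse_fact_file(serialize_facts(kb))
    == kb`` for every valid knowledge base.
    """
    lines = []  # (predicate, args-tuple, text)
    reg, cls = kb.registry, kb.classes
    for pred, atoms in (
        ("drug", reg.drugs),
        ("protein", reg.proteins),
        ("disease", reg.diseases),
        ("bioprocess", reg.bioprocesses - cls.promoting_bps - cls.resisting_bps),
        ("oncogene", cls.oncogenes),
        ("suppressor", cls.suppressors),
        ("cancer_promoting_bioprocess", cls.promoting_bps),
        ("cancer_resisting_bioprocess", cls.resisting_bps),
    ):
        for atom in atoms:
            lines.append((pred, (atom,), f"{pred}({atom})."))
    for i in kb.interactions:
        lines.append(
            ("interaction", (i.subject, i.verb, i.object, i.source),
             _annotate(i.fact(), i.source, i.evidence))
        )
    for r in kb.disease_relations:
        lines.append(
            ("relation", (f"{r.expression_state}({r.protein})", "associated_with",
                          r.disease, r.source),
             _annotate(r.fact(), r.source, r.evidence))
        )
    for b in kb.bioprocess_relations:
        lines.append(
            ("relation", (b.protein, "is_associated", b.bioprocess, b.source),
             _annotate(b.fact(), b.source, b.evidence))
        )
    lines.sort(key=lambda t: (t[0], t[1]))
    if not lines:
        return ""
    return "\n".join(t[2] for t in lines) + "\n"


def write_fact_file(kb: KnowledgeBase, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_facts(kb))


# ---------------------------------------------------------------------------
# Tabular loaders
# ---------------------------------------------------------------------------


def _as_records(rows) -> list:
    if hasattr(rows, "to_dict"):  # pandas DataFrame
        return rows.to_dict("records")
    return [dict(r) for r in rows]


def load_drug_target_table(rows, action_map: Optional[Mapping[str, str]] = None,
                           source: str = "drugbank") -> list:
    """Convert a DrugBank-like drug/target/action table to interactions.

    ``action_map`` maps pharmacological actions to interaction verbs
    (default: agonist→induces, antagonist→inhibits). Rows with an unmapped
    action are rejected and reported via logging; duplicates are silently
    dropped with the count logged.
    """
    amap = {k.lower(): v for k, v in (action_map or DEFAULT_ACTION_MAP).items()}
    out = []
    seen = set()
    rejected = dupes = 0
    for row in _as_records(rows):
        action = str(row["action"]).strip().lower()
        verb = amap.get(action)
        if verb is None:
            rejected += 1
            logger.warning("rejecting drug-target row with unmapped action %r: %s", action, row)
            continue
        fact = Interaction(
            normalize_atom(row["drug"]), verb, normalize_atom(row["target"]), source=source,
        )
        if fact.key in seen:
            dupes += 1
            continue
        seen.add(fact.key)
        out.append(fact)
    if dupes:
        logger.info("deduplicated %d drug-target rows", dupes)
    if rejected:
        logger.info("rejected %d drug-target rows with unmapped actions", rejected)
    return out


def load_relation_table(rows, default_source: str = "text_mining"):
    """Route text-mined relation triples into the three fact lists.

    Columns: subject, verb, object, qualifier, source. ``induces``/``inhibits``
    rows become protein-protein interactions, ``associated_with`` rows
    (which require an overexpressed/underexpressed qualifier) become disease
    relations, and ``is_associated`` rows become bioprocess relations.
    Rows with an unknown verb, or ``associated_with`` rows lacking an
    expression-state qualifier, are rejected and reported.
    """
    interactions, disease_rels, bp_rels = [], [], []
    rejected = 0
    for row in _as_records(rows):
        verb = str(row["verb"]).strip().lower()
        qualifier = str(row.get("qualifier") or "").strip().lower()
        if qualifier in ("-", "none", "nan"):
            qualifier = ""
        source = str(row.get("source") or default_source).strip().lower()
        subject = normalize_atom(row["subject"])
        obj = normalize_atom(row["object"])
        evidence = row.get("evidence") or None
        try:
            if verb in VERBS:
                if qualifier:
                    raise KBError(f"qualifier {qualifier!r} is only allowed with associated_with")
                interactions.append(Interaction(subject, verb, obj, source, evidence))
            elif verb == "associated_with":
                if qualifier not in EXPRESSION_STATES:
                    raise KBError(
                        "associated_with requires an overexpressed/underexpressed qualifier"
                    )
                disease_rels.append(DiseaseRelation(subject, qualifier, obj, source, evidence))
            elif verb == "is_associated":
                if qualifier:
                    raise KBError(f"qualifier {qualifier!r} is only allowed with associated_with")
                bp_rels.append(BioprocessRelation(subject, obj, source, evidence))
            else:
                raise KBError(f"unknown relation verb {verb!r}")
        except KBError as exc:
            rejected += 1
            logger.warning("rejecting relation row %s: %s", row, exc)
    if rejected:
        logger.info("rejected %d relation rows", rejected)
    return interactions, disease_rels, bp_rels


# ---------------------------------------------------------------------------
# Disease-class mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseClassMap:
    """Maps specific disease identifiers into a disease class.

    Text-mined relations name specific malignancies (``gastric_cancer``,
    ``acute_lymphoblastic_leukemia``) while the reasoning goal is a class
    (``cancer``). Explicit members take precedence; otherwise an ordered list
    of case-insensitive substring patterns decides membership.
    """

    target_class: str = "cancer"
    members: frozenset = frozenset()
    patterns: tuple = DEFAULT_CANCER_PATTERNS

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "patterns", tuple(str(p).lower() for p in self.patterns))
        _check_atom(self.target_class, "disease class")

    def classify(self, disease: str) -> Optional[str]:
        if disease in self.members:
            return self.target_class
        low = disease.lower()
        for pattern in self.patterns:
            if pattern in low:
                return self.target_class
        return None

    def __contains__(self, disease: str) -> bool:
        return self.classify(disease) is not None


def map_disease_class(disease: str, dmap: DiseaseClassMap) -> Optional[str]:
    """Return the class identifier for ``disease`` under ``dmap``, or None."""
    return dmap.classify(disease)


def load_disease_map(path) -> DiseaseClassMap:
    """Load a DiseaseClassMap from a YAML/JSON config with keys
    ``target_class``, ``members``, ``patterns``."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return DiseaseClassMap(
        target_class=cfg.get("target_class", "cancer"),
        members=frozenset(normalize_atom(m) for m in cfg.get("members", [])),
        patterns=tuple(cfg.get("patterns", DEFAULT_CANCER_PATTERNS)),
    )
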