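"""Packaged worked-example knowledge bases.

Three tiny fact files, each a complete self-contained KB:

* ``dipyridamole`` — a direct (2-step) inference: the drug inhibits ADA and
  overexpressed ADA is associated with cancer.
* ``tazarotene`` — an indirect (3-step) inference: the drug induces RARA,
  RARA inhibits the oncogene EGFR.
* ``cladribine`` — a contradiction: the drug induces PNP, which participates
  in the cancer-promoting process positive regulation of cell proliferation,
  so the only derivation is that the drug would promote the disease.
"""

from importlib import resources

from ..kb import KnowledgeBase, parse_fact_file

_NAMES = ("dipyridamole", "tazarotene", "cladribine")


def example_text(name: str) -> str:
    if name not in _NAMES:
        raise KeyError(f"unknown example {name!r}; choose from {_NAMES}")
    return (resources.files(__package__) / "data" / f"{name}.lp").read_text(encoding="utf-8")


def example_kb(name: str) -> KnowledgeBase:
    return parse_fact_file(example_text(name))


def dipyridamole_kb() -> KnowledgeBase:
    return example_kb("dipyridamole")


def tazarotene_kb() -> KnowledgeBase:
    return example_kb("tazarotene")


def cladribine_kb() -> KnowledgeBase:
    return example_kb("cladribine")
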