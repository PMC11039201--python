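"""Controlled vocabulary for Mendelian inheritance, allelic requirement and
inheritance qualifiers.

The vocabulary follows the harmonized HPO model: a ``Mode of inheritance``
(HP:0000005) hierarchy with three subcategories (Mendelian inheritance,
inheritance qualifier, non-Mendelian inheritance), eight allelic-requirement
tokens paired one-to-one with Mendelian inheritance terms (the two share a
single HPO identifier — the requirement token is recorded in HPO as an
*allelic requirement* synonym of the inheritance term), and a cross-cutting
set of inheritance qualifiers (penetrance, imprinting, anticipation, de novo
tendency, sex limitation, ...).
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "Ontology",
    "OntologyTermRef",
    "AllelicRequirement",
    "InheritanceQualifier",
    "QualifierTerm",
    "Vocabulary",
    "build_vocabulary",
    "map_requirement_inheritance",
    "UnknownTermError",
]

_CURIE_RE = {
    "HPO": re.compile(r"^HP:\d{7}$"),
    "SO": re.compile(r"^SO:\d{7}$"),
}


class Ontology(str, Enum):
    HPO = "HPO"
    SO = "SO"


@dataclass(frozen=True)
class OntologyTermRef:
    """A reference to an HPO or SO term: CURIE plus human-readable label."""

    curie: str
    label: str
    ontology: Ontology = Ontology.HPO

    def __post_init__(self) -> None:
        pattern = _CURIE_RE[self.ontology.value]
        if not pattern.match(self.curie):
            raise ValueError(
                f"curie {self.curie!r} does not match the {self.ontology.value} "
                "prefix/7-digit pattern"
            )
        if not self.label:
            raise ValueError("term label must be nonempty")


class UnknownTermError(KeyError):
    """Raised when a token, label or CURIE does not resolve in the vocabulary.

    Carries ``suggestions``: closest known names, to surface typos.
    """

    def __init__(self, query: str, suggestions: list[str]):
        self.query = query
        self.suggestions = suggestions
        hint = f"; did you mean {', '.join(suggestions)!s}?" if suggestions else ""
        super().__init__(f"unknown term {query!r}{hint}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True)
class AllelicRequirement:
    """One of the eight harmonized allelic-requirement / inheritance pairs.

    ``token`` is the allelic-requirement spelling (e.g. ``monoallelic_autosomal``)
    and ``inheritance_term`` the paired Mendelian inheritance term
    (e.g. Autosomal Dominant). Both share one HPO identifier.
    """

    token: str
    inheritance_term: OntologyTermRef
    chromosome_context: str  # autosomal | X | Y | MT | PAR
    copy_requirement: str  # monoallelic | biallelic | not_applicable
    x_zygosity_context: str = "not_applicable"  # heterozygous | hemizygous | not_applicable

    @property
    def curie(self) -> str:
        return self.inheritance_term.curie


# Table of the 8 harmonized pairs (children of Mendelian inheritance HP:0034345).
_REQUIREMENT_ROWS = [
    # token, inheritance label, HPO id, chrom context, copies, X zygosity
    ("monoallelic_autosomal", "Autosomal Dominant", "HP:0000006", "autosomal", "monoallelic", "not_applicable"),
    ("biallelic_autosomal", "Autosomal Recessive", "HP:0000007", "autosomal", "biallelic", "not_applicable"),
    ("monoallelic_X_heterozygous", "X-linked Dominant", "HP:0001423", "X", "monoallelic", "heterozygous"),
    ("monoallelic_X_hemizygous", "X-linked Recessive", "HP:0001419", "X", "monoallelic", "hemizygous"),
    ("monoallelic_Y_hemizygous", "Y-linked", "HP:0001450", "Y", "monoallelic", "not_applicable"),
    ("mitochondrial", "Mitochondrial", "HP:0001427", "MT", "monoallelic", "not_applicable"),
    ("monoallelic_PAR", "PAR dominant", "HP:0034340", "PAR", "monoallelic", "not_applicable"),
    ("biallelic_PAR", "PAR recessive", "HP:0034341", "PAR", "biallelic", "not_applicable"),
]

# Mode-of-inheritance top-level categories.
MODE_OF_INHERITANCE = OntologyTermRef("HP:0000005", "Mode of inheritance")
MENDELIAN_INHERITANCE = OntologyTermRef("HP:0034345", "Mendelian inheritance")
INHERITANCE_QUALIFIER = OntologyTermRef("HP:0034335", "Inheritance qualifier")
NON_MENDELIAN_INHERITANCE = OntologyTermRef("HP:0001426", "Non-Mendelian inheritance")

INHERITANCE_CATEGORIES = {
    MODE_OF_INHERITANCE.curie: MODE_OF_INHERITANCE,
    MENDELIAN_INHERITANCE.curie: MENDELIAN_INHERITANCE,
    INHERITANCE_QUALIFIER.curie: INHERITANCE_QUALIFIER,
    NON_MENDELIAN_INHERITANCE.curie: NON_MENDELIAN_INHERITANCE,
}


@dataclass(frozen=True)
class QualifierTerm:
    """An inheritance-qualifier vocabulary entry (a Table of parent/child terms)."""

    term: OntologyTermRef
    parent_curie: Optional[str] = None  # None for parent-level qualifiers

    @property
    def curie(self) -> str:
        return self.term.curie

    @property
    def label(self) -> str:
        return self.term.label


# Parent qualifiers, children indented under their parent CURIE.
_QUALIFIER_ROWS = [
    ("HP:0001442", "Typified by somatic mosaicism", None),
    ("HP:0025352", "Typically de novo", None),
    ("HP:0003829", "Typified by incomplete penetrance", None),
    ("HP:4000159", "Typified by moderate penetrance", "HP:0003829"),
    ("HP:4000158", "Typified by high penetrance", "HP:0003829"),
    ("HP:0034950", "Typified by complete penetrance", None),
    ("HP:0034857", "Typified by highly variable age of onset", None),
    ("HP:0003831", "Typified by age-related onset", None),
    ("HP:0034338", "Imprinted", None),
    ("HP:0012275", "With maternal imprinting", "HP:0034338"),
    ("HP:0012274", "With paternal imprinting", "HP:0034338"),
    ("HP:0003743", "Displays anticipation", None),
    ("HP:0034343", "Requires heterozygosity", None),
    ("HP:0001470", "Sex-limited expression", None),
    ("HP:0001475", "Male-limited expression", "HP:0001470"),
    ("HP:0034344", "Female-limited expression", "HP:0001470"),
    ("HP:0001466", "Contiguous gene syndrome", None),
]

# Qualifier pairs that must not be co-asserted on one curation.
MUTUALLY_EXCLUSIVE_QUALIFIERS = [
    ("HP:0034950", "HP:0003829"),  # complete vs incomplete penetrance
    ("HP:0034950", "HP:4000159"),
    ("HP:0034950", "HP:4000158"),
    ("HP:4000159", "HP:4000158"),  # moderate vs high penetrance bands
    ("HP:0012275", "HP:0012274"),  # maternal vs paternal imprinting
    ("HP:0001475", "HP:0034344"),  # male- vs female-limited
]


@dataclass(frozen=True)
class InheritanceQualifier:
    """A qualifier asserted on a curation: vocabulary term + optional free text."""

    term: OntologyTermRef
    note: Optional[str] = None

    @property
    def curie(self) -> str:
        return self.term.curie


class Vocabulary:
    """Lookup surface over the harmonized term tables.

    Tokens and labels resolve case-insensitively; CURIEs resolve exactly.
    """

    def __init__(
        self,
        requirements: Iterable[AllelicRequirement],
        qualifiers: Iterable[QualifierTerm],
    ):
        self.requirements: dict[str, AllelicRequirement] = {r.token: r for r in requirements}
        self.qualifiers: dict[str, QualifierTerm] = {q.curie: q for q in qualifiers}
        self.categories = dict(INHERITANCE_CATEGORIES)
        self._req_index: dict[str, AllelicRequirement] = {}
        for r in self.requirements.values():
            self._req_index[r.token.lower()] = r
            self._req_index[r.inheritance_term.label.lower()] = r
            self._req_index[r.curie] = r
        self._qual_index: dict[str, QualifierTerm] = {}
        for q in self.qualifiers.values():
            self._qual_index[q.curie] = q
            self._qual_index[q.label.lower()] = q

    # -- requirement lookups -------------------------------------------------

    def lookup(self, name: str) -> AllelicRequirement:
        """Resolve a requirement token, inheritance label or HPO CURIE."""
        key = name if name.startswith("HP:") else name.lower()
        try:
            return self._req_index[key]
        except KeyError:
            raise UnknownTermError(name, self._nearest(name, self._req_index)) from None

    def lookup_qualifier(self, name: str) -> QualifierTerm:
        key = name if name.startswith("HP:") else name.lower()
        try:
            return self._qual_index[key]
        except KeyError:
            raise UnknownTermError(name, self._nearest(name, self._qual_index)) from None

    def qualifier_parent(self, curie: str) -> Optional[str]:
        return self.qualifiers[curie].parent_curie

    @staticmethod
    def _nearest(query: str, index: dict) -> list[str]:
        candidates = [k for k in index if not k.startswith("HP:")]
        return difflib.get_close_matches(query.lower(), candidates, n=3, cutoff=0.6)

    def __contains__(self, name: str) -> bool:
        key = name if name.startswith("HP:") else name.lower()
        return key in self._req_index or key in self._qual_index

    def __len__(self) -> int:
        return len(self.requirements)


def build_vocabulary() -> Vocabulary:
    """Build the bundled vocabulary: 8 requirement/inheritance pairs,
    17 qualifier entries (11 parents + 6 children), 4 inheritance categories."""
    requirements = [
        AllelicRequirement(
            token=token,
            inheritance_term=OntologyTermRef(curie, label),
            chromosome_context=chrom,
            copy_requirement=copies,
            x_zygosity_context=xzyg,
        )
        for token, label, curie, chrom, copies, xzyg in _REQUIREMENT_ROWS
    ]
    qualifiers = [
        QualifierTerm(OntologyTermRef(curie, label), parent)
        for curie, label, parent in _QUALIFIER_ROWS
    ]
    return Vocabulary(requirements, qualifiers)


def map_requirement_inheritance(
    term: str, direction: str = "auto", vocabulary: Optional[Vocabulary] = None
) -> str:
    """Map an allelic-requirement token to its paired inheritance term, or back.

    ``direction``: ``"to_inheritance"``, ``"to_requirement"`` or ``"auto"``
    (infer from which side the input resolves on). The map is a bijection, so
    applying it twice returns the input.
    """
    vocab = vocabulary or build_vocabulary()
    entry = vocab.lookup(term)
    if direction == "auto":
        # exact spellings win (the mitochondrial token and label differ only
        # in case); otherwise a case-insensitive token match maps forward and
        # anything else (labels, CURIEs) maps back to the requirement token
        if term == entry.token:
            direction = "to_inheritance"
        elif term == entry.inheritance_term.label:
            direction = "to_requirement"
        else:
            direction = (
                "to_inheritance" if term.lower() == entry.token.lower() else "to_requirement"
            )
    if direction == "to_inheritance":
        return entry.inheritance_term.label
    if direction == "to_requirement":
        return entry.token
    raise ValueError(f"unknown direction {direction!r}")
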