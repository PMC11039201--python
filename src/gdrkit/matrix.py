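"""The disease-associated variant-consequence hierarchy and likelihood matrix.

Six high-level, predictable consequences (SO terms) describe what a variant
does to the gene product — its level (altered / decreased / absent /
increased), its sequence, or nothing ("functionally normal"). Each SO variant
class (missense_variant, stop_gained, ...) is mapped to each consequence on a
five-level ordinal likelihood scale (1: almost never ... 5: almost always).
stop_gained and frameshift_variant are split into NMD-triggering and
NMD-escaping rows, because a premature termination codon degraded by
nonsense-mediated decay lowers product level, while an NMD-escaping one yields
a sequence-altered (truncated) product.

The base class set is the 33-consequence vocabulary used by Ensembl VEP;
redundant terms (e.g. ``downstream_gene_variant``) carry no matrix row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .terms import OntologyTermRef, Ontology, UnknownTermError

__all__ = [
    "CONSEQUENCE_NAMES",
    "HighLevelConsequence",
    "CONSEQUENCES",
    "VEP_BASE_CLASSES",
    "MATRIX_BASE_CLASSES",
    "NMD_SPLIT_CLASSES",
    "VariantClass",
    "LikelihoodScore",
    "LIKELIHOOD_LABELS",
    "ConsequenceMatrix",
    "default_matrix",
    "load_matrix",
    "likelihood",
    "infer_consequences",
    "suggest_classes",
    "validate_matrix",
]


@dataclass(frozen=True)
class HighLevelConsequence:
    name: str
    term: OntologyTermRef
    parent: Optional[str] = None

    @property
    def curie(self) -> str:
        return self.term.curie


def _so(curie: str, label: str) -> OntologyTermRef:
    return OntologyTermRef(curie, label, Ontology.SO)


# The 6 matrix columns. Hierarchy: decreased and increased are children of
# altered level; absent is a child of decreased.
CONSEQUENCES: dict[str, HighLevelConsequence] = {
    c.name: c
    for c in [
        HighLevelConsequence("altered gene product level", _so("SO:0002314", "altered_gene_product_level")),
        HighLevelConsequence("decreased gene product level", _so("SO:0002316", "decreased_gene_product_level"), parent="altered gene product level"),
        HighLevelConsequence("absent gene product", _so("SO:0002317", "absent_gene_product"), parent="decreased gene product level"),
        HighLevelConsequence("increased gene product level", _so("SO:0002315", "increased_gene_product_level"), parent="altered gene product level"),
        HighLevelConsequence("altered gene product sequence", _so("SO:0002318", "altered_gene_product_sequence")),
        HighLevelConsequence("functionally normal", _so("SO:0002219", "functionally_normal")),
    ]
}

CONSEQUENCE_NAMES: tuple[str, ...] = tuple(CONSEQUENCES)

# SO hierarchy nodes that are not matrix columns (the matrix is fixed at 6).
HIERARCHY_NODES: dict[str, OntologyTermRef] = {
    t.label: t
    for t in [
        _so("SO:0001060", "sequence_variant"),
        _so("SO:0001536", "functional_effect_variant"),
        _so("SO:0002218", "functionally_abnormal"),
        _so("SO:0002220", "function_uncertain_variant"),
    ]
}

# The 33 variant-class terms of the classic Ensembl VEP consequence table, in
# severity order (rank 1 = most severe). This is the base set before the
# NMD-triggering/escaping splits.
VEP_BASE_CLASSES: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "splice_region_variant",
    "incomplete_terminal_codon_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "feature_elongation",
    "feature_truncation",
    "intergenic_variant",
)

SEVERITY_RANK: dict[str, int] = {t: i + 1 for i, t in enumerate(VEP_BASE_CLASSES)}

# Redundant terms culled from the matrix: flags and catch-alls
# (NMD_transcript_variant, coding_sequence_variant, ...), structural classes
# other than transcript_ablation, and terms subsumed by a retained row
# (downstream_gene_variant, intergenic_variant, ...).
CULLED_CLASSES: frozenset[str] = frozenset(
    {
        "transcript_amplification",
        "incomplete_terminal_codon_variant",
        "coding_sequence_variant",
        "NMD_transcript_variant",
        "non_coding_transcript_variant",
        "downstream_gene_variant",
        "TFBS_ablation",
        "TFBS_amplification",
        "regulatory_region_ablation",
        "regulatory_region_amplification",
        "feature_elongation",
        "feature_truncation",
        "intergenic_variant",
    }
)

MATRIX_BASE_CLASSES: tuple[str, ...] = tuple(
    t for t in VEP_BASE_CLASSES if t not in CULLED_CLASSES
)

# PTC-producing classes that get NMD-triggering / NMD-escaping rows.
NMD_SPLIT_CLASSES: frozenset[str] = frozenset({"stop_gained", "frameshift_variant"})

LIKELIHOOD_LABELS: dict[int, str] = {
    1: "almost never",
    2: "unlikely",
    3: "possible",
    4: "probable",
    5: "almost always",
}

DEFAULT_SUGGESTION_THRESHOLD = 4


@dataclass(frozen=True, order=True)
class LikelihoodScore:
    """Ordinal likelihood that a variant class produces a consequence."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in LIKELIHOOD_LABELS:
            raise ValueError(f"likelihood value must be 1-5, got {self.value}")

    @property
    def label(self) -> str:
        return LIKELIHOOD_LABELS[self.value]

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class VariantClass:
    """A matrix row: SO base term plus optional NMD qualifier."""

    base_so_term: str
    nmd_qualifier: str = "not_applicable"  # triggering | escaping | not_applicable

    def __post_init__(self) -> None:
        if self.nmd_qualifier not in ("triggering", "escaping", "not_applicable"):
            raise ValueError(f"bad NMD qualifier {self.nmd_qualifier!r}")
        if self.nmd_qualifier != "not_applicable" and self.base_so_term not in NMD_SPLIT_CLASSES:
            raise ValueError(f"{self.base_so_term} has no NMD split")

    @property
    def name(self) -> str:
        if self.nmd_qualifier == "not_applicable":
            return self.base_so_term
        return f"{self.base_so_term}|NMD_{self.nmd_qualifier}"

    @property
    def severity_rank(self) -> int:
        # escaping PTCs rank just below their triggering counterpart
        base = SEVERITY_RANK.get(self.base_so_term, len(VEP_BASE_CLASSES) + 1)
        return base * 2 + (1 if self.nmd_qualifier == "escaping" else 0)

    @classmethod
    def parse(cls, name: str) -> "VariantClass":
        if "|" in name:
            base, suffix = name.split("|", 1)
            if suffix not in ("NMD_triggering", "NMD_escaping"):
                raise ValueError(f"bad NMD suffix in {name!r}")
            return cls(base, suffix.removeprefix("NMD_"))
        return cls(name)


from .report import ValidationReport, Violation  # noqa: E402


class ConsequenceMatrix:
    """Variant classes x 6 high-level consequences on the 1-5 likelihood scale.

    ``cells[(row_name, consequence_name)] -> int``; every cell carries a
    provenance tag (``paper_text`` for cells fixed by the published text,
    ``expert_default`` for the bundled defaults, ``user`` for overrides).
    """

    def __init__(
        self,
        rows: Iterable[VariantClass],
        cells: Mapping[tuple[str, str], int],
        provenance: Optional[Mapping[tuple[str, str], str]] = None,
    ):
        rows = list(rows)
        names = [r.name for r in rows]
        self.duplicate_rows: frozenset[str] = frozenset(
            n for n in names if names.count(n) > 1
        )
        self.rows: dict[str, VariantClass] = {r.name: r for r in rows}
        self.cells: dict[tuple[str, str], int] = dict(cells)
        self.provenance: dict[tuple[str, str], str] = {
            key: (provenance or {}).get(key, "expert_default") for key in self.cells
        }
        missing = [
            (r, c)
            for r in self.rows
            for c in CONSEQUENCE_NAMES
            if (r, c) not in self.cells
        ]
        if missing:
            raise ValueError(f"matrix missing cells: {missing[:5]} ...")

    # -- lookups -------------------------------------------------------------

    def resolve_class(self, variant_class) -> str:
        name = variant_class.name if isinstance(variant_class, VariantClass) else str(variant_class)
        if name not in self.rows:
            import difflib

            raise UnknownTermError(name, difflib.get_close_matches(name, self.rows, n=3, cutoff=0.6))
        return name

    def likelihood(self, variant_class, consequence: str) -> LikelihoodScore:
        name = self.resolve_class(variant_class)
        if consequence not in CONSEQUENCES:
            import difflib

            raise UnknownTermError(
                consequence, difflib.get_close_matches(consequence, CONSEQUENCE_NAMES, n=3, cutoff=0.6)
            )
        return LikelihoodScore(self.cells[(name, consequence)])

    def row_profile(self, variant_class) -> dict[str, int]:
        name = self.resolve_class(variant_class)
        return {c: self.cells[(name, c)] for c in CONSEQUENCE_NAMES}

    # -- inference -----------------------------------------------------------

    def infer_consequences(self, observed_classes: Iterable[str]) -> dict[str, int]:
        """Element-wise max of the rows of the observed classes.

        Empty input yields an empty profile.
        """
        names = [self.resolve_class(c) for c in observed_classes]
        if not names:
            return {}
        return {
            c: max(self.cells[(n, c)] for n in names) for c in CONSEQUENCE_NAMES
        }

    def suggest_classes(
        self,
        observed_pathogenic_classes: Iterable[str],
        threshold: int = DEFAULT_SUGGESTION_THRESHOLD,
    ) -> list[VariantClass]:
        """Novel variant classes plausibly sharing the observed classes' consequences.

        A class is suggested when it scores >= ``threshold`` for at least one
        consequence that itself reaches >= ``threshold`` in the profile
        inferred from the observed classes. Output is disjoint from the input
        and sorted by severity rank (ties by name).
        """
        if not 1 <= threshold <= 5:
            raise ValueError(f"threshold must be in 1-5, got {threshold}")
        observed = {self.resolve_class(c) for c in observed_pathogenic_classes}
        profile = self.infer_consequences(observed)
        active = [c for c, v in profile.items() if v >= threshold]
        out = [
            self.rows[name]
            for name in self.rows
            if name not in observed
            and any(self.cells[(name, c)] >= threshold for c in active)
        ]
        return sorted(out, key=lambda r: (r.severity_rank, r.name))

    # -- validation ----------------------------------------------------------

    def validate(self) -> ValidationReport:
        """Range, hierarchy-monotonicity and duplicate-row checks.

        Monotonicity encodes the consequence hierarchy: a class can produce a
        child consequence at most as readily as its parent — for every row,
        altered level >= max(decreased, increased) and decreased >= absent.
        """
        violations: list[Violation] = []
        for (row, col), value in self.cells.items():
            if not 1 <= value <= 5:
                violations.append(
                    Violation("error", "value_out_of_range", f"cell ({row}, {col}) = {value} outside 1-5", row)
                )
        for name in self.rows:
            alt = self.cells[(name, "altered gene product level")]
            dec = self.cells[(name, "decreased gene product level")]
            inc = self.cells[(name, "increased gene product level")]
            absent = self.cells[(name, "absent gene product")]
            if alt < max(dec, inc):
                violations.append(
                    Violation(
                        "error",
                        "hierarchy_monotonicity",
                        f"{name}: altered level {alt} < max(decreased {dec}, increased {inc})",
                        name,
                    )
                )
            if dec < absent:
                violations.append(
                    Violation(
                        "error",
                        "hierarchy_monotonicity",
                        f"{name}: decreased level {dec} < absent {absent}",
                        name,
                    )
                )
        for name in sorted(self.duplicate_rows):
            violations.append(
                Violation("error", "duplicate_row", f"variant class {name} listed more than once", name)
            )
        return ValidationReport(violations)

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        records = []
        for name in self.rows:
            rec: dict[str, object] = {"variant_class": name}
            rec.update({c: self.cells[(name, c)] for c in CONSEQUENCE_NAMES})
            tags = [
                f"{c}:{self.provenance[(name, c)]}"
                for c in CONSEQUENCE_NAMES
                if self.provenance[(name, c)] != "expert_default"
            ]
            rec["provenance"] = ";".join(tags)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsequenceMatrix):
            return NotImplemented
        return (
            self.rows == other.rows
            and self.cells == other.cells
            and self.provenance == other.provenance
        )

    def __len__(self) -> int:
        return len(self.rows)


def _matrix_from_frame(df: pd.DataFrame, default_provenance: str) -> ConsequenceMatrix:
    if "variant_class" not in df.columns:
        raise ValueError("matrix TSV must have a 'variant_class' first column")
    missing_cols = [c for c in CONSEQUENCE_NAMES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"matrix TSV missing consequence column(s): {missing_cols}")
    rows: list[VariantClass] = []
    cells: dict[tuple[str, str], int] = {}
    provenance: dict[tuple[str, str], str] = {}
    for _, rec in df.iterrows():
        vc = VariantClass.parse(str(rec["variant_class"]))
        if vc.base_so_term not in VEP_BASE_CLASSES:
            raise UnknownTermError(vc.base_so_term, [])
        rows.append(vc)
        for c in CONSEQUENCE_NAMES:
            try:
                value = int(rec[c])
            except (TypeError, ValueError):
                raise ValueError(f"non-integer cell at ({vc.name}, {c}): {rec[c]!r}") from None
            if not 1 <= value <= 5:
                raise ValueError(f"cell ({vc.name}, {c}) = {value} outside 1-5")
            cells[(vc.name, c)] = value
            provenance[(vc.name, c)] = default_provenance
        tag_field = rec.get("provenance")
        if isinstance(tag_field, str) and tag_field:
            for entry in tag_field.split(";"):
                cname, _, tag = entry.rpartition(":")
                if cname not in CONSEQUENCE_NAMES:
                    raise ValueError(f"bad provenance entry {entry!r} for {vc.name}")
                provenance[(vc.name, cname)] = tag
    return ConsequenceMatrix(rows, cells, provenance)


def default_matrix() -> ConsequenceMatrix:
    """The bundled matrix. Text-anchored cells are tagged ``paper_text``;
    all remaining cells are authored expert defaults (``expert_default``)."""
    with resources.files("gdrkit.data").joinpath("default_matrix.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return _matrix_from_frame(df, default_provenance="expert_default")


def load_matrix(path) -> ConsequenceMatrix:
    """Load a user matrix TSV (same layout as the bundled default).

    The parsed matrix must pass :func:`validate_matrix`, else loading fails.
    """
    df = pd.read_csv(path, sep="\t")
    matrix = _matrix_from_frame(df, default_provenance="user")
    report = matrix.validate()
    if report.has_errors:
        raise ValueError(f"matrix fails validation: {report.summary()}")
    return matrix


# -- module-level functional wrappers ----------------------------------------

def likelihood(matrix: ConsequenceMatrix, variant_class, consequence: str) -> LikelihoodScore:
    return matrix.likelihood(variant_class, consequence)


def infer_consequences(matrix: ConsequenceMatrix, observed_classes: Iterable[str]) -> dict[str, int]:
    return matrix.infer_consequences(observed_classes)


def suggest_classes(
    matrix: ConsequenceMatrix,
    observed_pathogenic_classes: Iterable[str],
    threshold: int = DEFAULT_SUGGESTION_THRESHOLD,
) -> list[VariantClass]:
    return matrix.suggest_classes(observed_pathogenic_classes, threshold)


def validate_matrix(matrix: ConsequenceMatrix) -> ValidationReport:
    return matrix.validate()
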