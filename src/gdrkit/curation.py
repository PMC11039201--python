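"""Gene-disease curation records: schema, validation and TSV/JSON I/O.

A curation record captures, for one gene-disease pair, the allelic
requirement (how many affected alleles cause disease and on which chromosome
context), optional inheritance qualifiers (penetrance, imprinting, de novo
tendency, ...), the disease-associated high-level consequences, and the
variant classes reported pathogenic.

The flat schema (columns ``gene, gene_id, disease, disease_id,
allelic_requirement, qualifiers, disease_associated_consequences,
known_pathogenic_variant_classes, mechanism_note, source``) is
toolkit-defined; multi-valued fields are semicolon-separated in TSV, lists in
JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .report import ValidationReport, Violation
from .terms import (
    InheritanceQualifier,
    MUTUALLY_EXCLUSIVE_QUALIFIERS,
    UnknownTermError,
    Vocabulary,
    build_vocabulary,
)

__all__ = [
    "GeneDiseaseCuration",
    "validate_curation",
    "read_curations",
    "write_curations",
    "CurationParseError",
]

_TSV_COLUMNS = [
    "gene",
    "gene_id",
    "disease",
    "disease_id",
    "allelic_requirement",
    "qualifiers",
    "disease_associated_consequences",
    "known_pathogenic_variant_classes",
    "mechanism_note",
    "source",
]


class CurationParseError(ValueError):
    """A curation file field failed to parse; names the record and field."""

    def __init__(self, record_index: int, field_name: str, message: str):
        self.record_index = record_index
        self.field_name = field_name
        super().__init__(f"record {record_index}, field {field_name!r}: {message}")


@dataclass(frozen=True)
class GeneDiseaseCuration:
    """One curated gene-disease pair."""

    gene_symbol: str
    disease_label: str
    allelic_requirement: str  # requirement token, e.g. "monoallelic_autosomal"
    gene_id: Optional[str] = None
    disease_id: Optional[str] = None
    qualifiers: frozenset[str] = frozenset()  # HPO CURIEs
    disease_associated_consequences: frozenset[str] = frozenset()
    known_pathogenic_variant_classes: frozenset[str] = frozenset()
    mechanism_note: Optional[str] = None
    provenance: Optional[str] = None

    def with_consequences(self, consequences: Iterable[str]) -> "GeneDiseaseCuration":
        return replace(self, disease_associated_consequences=frozenset(consequences))


def validate_curation(
    record: GeneDiseaseCuration, vocabulary: Optional[Vocabulary] = None
) -> ValidationReport:
    """Check one record against the vocabulary and qualifier compatibility rules.

    Error-severity violations: unresolvable requirement / qualifier /
    consequence / variant-class names; mutually exclusive qualifier children
    co-asserted (complete vs incomplete penetrance, maternal vs paternal
    imprinting, male- vs female-limited expression); empty gene or disease.

    Warning-severity: "requires heterozygosity" together with a biallelic
    requirement (such disorders are currently all X-linked, but the
    cellular-interference mechanism is not impossible elsewhere); a record
    listing pathogenic variant classes but no disease-associated consequence.
    """
    from .matrix import CONSEQUENCES, NMD_SPLIT_CLASSES, VEP_BASE_CLASSES, VariantClass

    vocab = vocabulary or build_vocabulary()
    violations: list[Violation] = []

    if not record.gene_symbol:
        violations.append(Violation("error", "missing_gene", "gene symbol is empty", "gene"))
    if not record.disease_label:
        violations.append(Violation("error", "missing_disease", "disease label is empty", "disease"))

    requirement = None
    if not record.allelic_requirement:
        violations.append(
            Violation("error", "missing_allelic_requirement", "allelic_requirement is empty", "allelic_requirement")
        )
    else:
        try:
            requirement = vocab.lookup(record.allelic_requirement)
        except UnknownTermError as exc:
            violations.append(
                Violation("error", "unknown_allelic_requirement", str(exc), "allelic_requirement")
            )

    resolved_qualifiers: set[str] = set()
    for name in sorted(record.qualifiers):
        try:
            resolved_qualifiers.add(vocab.lookup_qualifier(name).curie)
        except UnknownTermError as exc:
            violations.append(Violation("error", "unknown_qualifier", str(exc), "qualifiers"))

    for a, b in MUTUALLY_EXCLUSIVE_QUALIFIERS:
        if a in resolved_qualifiers and b in resolved_qualifiers:
            la = vocab.qualifiers[a].label
            lb = vocab.qualifiers[b].label
            violations.append(
                Violation(
                    "error",
                    "mutually_exclusive_qualifiers",
                    f"{la} ({a}) and {lb} ({b}) cannot be co-asserted",
                    "qualifiers",
                )
            )

    for name in sorted(record.disease_associated_consequences):
        if name not in CONSEQUENCES:
            violations.append(
                Violation(
                    "error",
                    "unknown_consequence",
                    f"unknown consequence {name!r}",
                    "disease_associated_consequences",
                )
            )

    for name in sorted(record.known_pathogenic_variant_classes):
        try:
            vc = VariantClass.parse(name)
        except ValueError as exc:
            violations.append(
                Violation("error", "unknown_variant_class", str(exc), "known_pathogenic_variant_classes")
            )
            continue
        if vc.base_so_term not in VEP_BASE_CLASSES:
            violations.append(
                Violation(
                    "error",
                    "unknown_variant_class",
                    f"unknown variant class {name!r}",
                    "known_pathogenic_variant_classes",
                )
            )

    if requirement is not None and "HP:0034343" in resolved_qualifiers:
        if requirement.copy_requirement == "biallelic":
            violations.append(
                Violation(
                    "warning",
                    "requires_heterozygosity_with_biallelic",
                    "'Requires heterozygosity' asserted with a biallelic requirement; "
                    "known requires-heterozygosity disorders are X-linked monoallelic",
                    "qualifiers",
                )
            )

    if record.known_pathogenic_variant_classes and not record.disease_associated_consequences:
        violations.append(
            Violation(
                "warning",
                "consequences_empty",
                "pathogenic variant classes listed but no disease-associated consequence; "
                "consider infer_consequences over the known classes",
                "disease_associated_consequences",
            )
        )

    # Deterministic, order-independent output.
    violations.sort(key=lambda v: (v.severity, v.code, v.field, v.message))
    return ValidationReport(violations)


# -- I/O ----------------------------------------------------------------------

def _split_multi(value: object) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    if isinstance(value, (list, tuple, set, frozenset)):
        return frozenset(str(v).strip() for v in value if str(v).strip())
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(part.strip() for part in text.split(";") if part.strip())


def _opt(value: object) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _record_from_mapping(index: int, data: dict) -> GeneDiseaseCuration:
    try:
        return GeneDiseaseCuration(
            gene_symbol=str(data.get("gene") or "").strip(),
            gene_id=_opt(data.get("gene_id")),
            disease_label=str(data.get("disease") or "").strip(),
            disease_id=_opt(data.get("disease_id")),
            allelic_requirement=str(data.get("allelic_requirement") or "").strip(),
            qualifiers=_split_multi(data.get("qualifiers")),
            disease_associated_consequences=_split_multi(data.get("disease_associated_consequences")),
            known_pathogenic_variant_classes=_split_multi(data.get("known_pathogenic_variant_classes")),
            mechanism_note=_opt(data.get("mechanism_note")),
            provenance=_opt(data.get("source")),
        )
    except (TypeError, ValueError) as exc:  # defensive: schema drift
        raise CurationParseError(index, "record", str(exc)) from exc


def read_curations(
    path,
    format: Optional[str] = None,
    vocabulary: Optional[Vocabulary] = None,
    strict: bool = True,
) -> list[GeneDiseaseCuration]:
    """Read curation records from TSV or JSON (format inferred from suffix).

    With ``strict`` (default), any record with error-severity violations
    raises :class:`CurationParseError` naming the record index and the first
    offending field; otherwise all structurally parseable records are
    returned.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        raw = df.to_dict(orient="records")
    elif fmt == "json":
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise CurationParseError(0, "root", "JSON curation file must be a list of objects")
    else:
        raise ValueError(f"unknown curation format {fmt!r}")

    vocab = vocabulary or build_vocabulary()
    records = []
    for i, data in enumerate(raw):
        record = _record_from_mapping(i, data)
        if strict:
            report = validate_curation(record, vocab)
            if report.has_errors:
                first = report.errors[0]
                raise CurationParseError(i, first.field, first.message)
        records.append(record)
    return records


def write_curations(records: Iterable[GeneDiseaseCuration], path, format: Optional[str] = None) -> None:
    """Write records to TSV or JSON. ``read_curations(write_curations(x)) == x``
    for valid records (multi-valued fields are serialized sorted)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    rows = [
        {
            "gene": r.gene_symbol,
            "gene_id": r.gene_id or "",
            "disease": r.disease_label,
            "disease_id": r.disease_id or "",
            "allelic_requirement": r.allelic_requirement,
            "qualifiers": ";".join(sorted(r.qualifiers)),
            "disease_associated_consequences": ";".join(sorted(r.disease_associated_consequences)),
            "known_pathogenic_variant_classes": ";".join(sorted(r.known_pathogenic_variant_classes)),
            "mechanism_note": r.mechanism_note or "",
            "source": r.provenance or "",
        }
        for r in records
    ]
    if fmt == "tsv":
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown curation format {fmt!r}")
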