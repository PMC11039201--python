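"""Validation reporting shared by the vocabulary, curation and matrix layers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["Violation", "ValidationReport"]


@dataclass(frozen=True)
class Violation:
    severity: str  # error | warning
    code: str
    message: str
    field: str = ""

    def __post_init__(self) -> None:
        if self.severity not in ("error", "warning"):
            raise ValueError(f"severity must be error or warning, got {self.severity!r}")


@dataclass
class ValidationReport:
    """A deterministic list of violations; empty means valid."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    @property
    def has_errors(self) -> bool:
        return any(v.severity == "error" for v in self.violations)

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]

    def summary(self) -> str:
        if self.is_valid:
            return "valid"
        return "; ".join(f"{v.severity}:{v.code}({v.field}) {v.message}" for v in self.violations)

    def extend(self, violations: Iterable[Violation]) -> None:
        self.violations.extend(violations)

    def to_tsv(self) -> str:
        lines = ["severity\tcode\tfield\tmessage"]
        lines += [f"{v.severity}\t{v.code}\t{v.field}\t{v.message}" for v in self.violations]
        return "\n".join(lines) + "\n"
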