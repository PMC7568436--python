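"""Core data model for the BIDS genetics descriptor.

This module defines the in-memory types for the three dataset-level files the
genetics extension touches (``dataset_description.json``'s ``Genetics`` block,
``genetic_info.json``, ``participants.tsv``), the controlled vocabularies the
descriptor draws its terms from, and the fixed catalogue of validation issue
codes.  Severities mirror BIDS normative levels: REQUIRED rules map to ERROR,
RECOMMENDED rules to WARNING.

Types here are deliberately permissive: readers construct them from whatever
the files contain, and every semantic rule lives in :mod:`bidsgene.validator`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping


class DescriptorError(ValueError):
    """Structural problem with a descriptor file (wrong JSON shape, bad table)."""


class TableParseError(DescriptorError):
    """Tabular file violates the TSV dialect; carries the 1-based row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ConfigurationError(ValueError):
    """A vocabulary or registry was referenced that does not exist."""


class Severity(str, enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


class IssueCode(str, enum.Enum):
    # errors — violations of REQUIRED structure or vocabulary
    JSON_PARSE_ERROR = "JSON_PARSE_ERROR"
    TSV_RAGGED_ROW = "TSV_RAGGED_ROW"
    PT_MISSING_FILE = "PT_MISSING_FILE"
    PT_BAD_HEADER = "PT_BAD_HEADER"
    PT_DUPLICATE_PARTICIPANT = "PT_DUPLICATE_PARTICIPANT"
    GI_MISSING_FILE = "GI_MISSING_FILE"
    GI_MISSING_GENETICLEVEL = "GI_MISSING_GENETICLEVEL"
    GI_MISSING_SAMPLEORIGIN = "GI_MISSING_SAMPLEORIGIN"
    GI_INVALID_GENETICLEVEL = "GI_INVALID_GENETICLEVEL"
    GI_INVALID_SAMPLEORIGIN = "GI_INVALID_SAMPLEORIGIN"
    GI_INVALID_TISSUEORIGIN = "GI_INVALID_TISSUEORIGIN"
    GI_INVALID_BRAINLOCATION = "GI_INVALID_BRAINLOCATION"
    DD_MISSING_GENETICS_DATASET = "DD_MISSING_GENETICS_DATASET"
    DD_INVALID_URL = "DD_INVALID_URL"
    # warnings — RECOMMENDED practice or suspicious-but-legal content
    GI_TISSUEORIGIN_RECOMMENDED = "GI_TISSUEORIGIN_RECOMMENDED"
    GI_TISSUEORIGIN_WITHOUT_BRAIN = "GI_TISSUEORIGIN_WITHOUT_BRAIN"
    GI_BRAINLOCATION_CONTEXT = "GI_BRAINLOCATION_CONTEXT"
    GI_CELLTYPE_PATTERN = "GI_CELLTYPE_PATTERN"
    GI_ANALYTICAPPROACH_UNKNOWN = "GI_ANALYTICAPPROACH_UNKNOWN"
    GI_ORPHAN_FILE = "GI_ORPHAN_FILE"
    PT_DUPLICATE_GENETIC_ID = "PT_DUPLICATE_GENETIC_ID"
    PT_NO_GENETIC_ID_COLUMN = "PT_NO_GENETIC_ID_COLUMN"


# code -> (severity, description); insertion order is the catalogue order
_CATALOGUE: dict[IssueCode, tuple[Severity, str]] = {
    IssueCode.JSON_PARSE_ERROR: (
        Severity.ERROR, "A JSON descriptor file could not be parsed."),
    IssueCode.TSV_RAGGED_ROW: (
        Severity.ERROR, "A participants.tsv row has a different number of cells than the header."),
    IssueCode.PT_MISSING_FILE: (
        Severity.ERROR, "participants.tsv is absent from the dataset root."),
    IssueCode.PT_BAD_HEADER: (
        Severity.ERROR, "The first participants.tsv column is not participant_id."),
    IssueCode.PT_DUPLICATE_PARTICIPANT: (
        Severity.ERROR, "A participant_id value occurs more than once."),
    IssueCode.GI_MISSING_FILE: (
        Severity.ERROR, "A Genetics block is declared but genetic_info.json is absent."),
    IssueCode.GI_MISSING_GENETICLEVEL: (
        Severity.ERROR, "genetic_info.json lacks the required GeneticLevel key."),
    IssueCode.GI_MISSING_SAMPLEORIGIN: (
        Severity.ERROR, "genetic_info.json lacks the required SampleOrigin key."),
    IssueCode.GI_INVALID_GENETICLEVEL: (
        Severity.ERROR, "A GeneticLevel term is outside the controlled vocabulary."),
    IssueCode.GI_INVALID_SAMPLEORIGIN: (
        Severity.ERROR, "A SampleOrigin term is outside the controlled vocabulary."),
    IssueCode.GI_INVALID_TISSUEORIGIN: (
        Severity.ERROR, "A TissueOrigin term is outside the controlled vocabulary."),
    IssueCode.GI_INVALID_BRAINLOCATION: (
        Severity.ERROR, "BrainLocation is neither a well-formed MNI coordinate triple nor an atlas label."),
    IssueCode.DD_MISSING_GENETICS_DATASET: (
        Severity.ERROR, "The Genetics block lacks the required Dataset URL."),
    IssueCode.DD_INVALID_URL: (
        Severity.ERROR, "A Genetics URL field fails the syntactic URL rule."),
    IssueCode.GI_TISSUEORIGIN_RECOMMENDED: (
        Severity.WARNING, "SampleOrigin includes brain; adding TissueOrigin is recommended."),
    IssueCode.GI_TISSUEORIGIN_WITHOUT_BRAIN: (
        Severity.WARNING, "TissueOrigin is present although no sample originates from brain."),
    IssueCode.GI_BRAINLOCATION_CONTEXT: (
        Severity.WARNING, "BrainLocation is given outside a gray matter/white matter/csf tissue context."),
    IssueCode.GI_CELLTYPE_PATTERN: (
        Severity.WARNING, "CellType does not look like a Cell Ontology identifier (CL: + 7 digits)."),
    IssueCode.GI_ANALYTICAPPROACH_UNKNOWN: (
        Severity.WARNING, "An AnalyticApproach term is not in the bundled dbGaP-derived list."),
    IssueCode.GI_ORPHAN_FILE: (
        Severity.WARNING, "genetic_info.json is present but no Genetics block declares it."),
    IssueCode.PT_DUPLICATE_GENETIC_ID: (
        Severity.WARNING, "A genetic_id value is shared by more than one participant."),
    IssueCode.PT_NO_GENETIC_ID_COLUMN: (
        Severity.WARNING, "A Genetics block is present but participants.tsv has no genetic_id column."),
}


def issue_catalogue() -> list[tuple[IssueCode, Severity, str]]:
    """Return the complete, fixed issue catalogue in stable order."""
    return [(code, sev, desc) for code, (sev, desc) in _CATALOGUE.items()]


def issue_severity(code: IssueCode) -> Severity:
    return _CATALOGUE[code][0]


@dataclass(frozen=True, order=True)
class ValidationIssue:
    """One coded finding, located in a file relative to the dataset root."""

    file: str
    location: str
    code: IssueCode
    severity: Severity
    message: str


def make_issue(code: IssueCode, file: str, location: str, message: str) -> ValidationIssue:
    """Build an issue with the severity the catalogue fixes for ``code``."""
    return ValidationIssue(file=file, location=location, code=code,
                           severity=issue_severity(code), message=message)


@dataclass(frozen=True)
class ValidationReport:
    """Deterministic list of findings; ``valid`` means zero ERROR issues."""

    issues: tuple[ValidationIssue, ...]

    @property
    def error_count(self) -> int:
        return sum(1 for i in self.issues if i.severity is Severity.ERROR)

    @property
    def warning_count(self) -> int:
        return sum(1 for i in self.issues if i.severity is Severity.WARNING)

    @property
    def valid(self) -> bool:
        return self.error_count == 0

    def codes(self) -> set[IssueCode]:
        return {i.code for i in self.issues}

    def to_dict(self) -> dict[str, Any]:
        return {
            "valid": self.valid,
            "error_count": self.error_count,
            "warning_count": self.warning_count,
            "issues": [
                {"code": i.code.value, "severity": i.severity.value,
                 "file": i.file, "location": i.location, "message": i.message}
                for i in self.issues
            ],
        }

    def to_table(self) -> str:
        """Render the report as an aligned text table for human reading."""
        if not self.issues:
            return "no issues\n"
        rows = [(i.severity.value, i.code.value, f"{i.file}:{i.location}", i.message)
                for i in self.issues]
        widths = [max(len(r[c]) for r in rows) for c in range(3)]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(r[:3], widths)) + "  " + r[3]
                 for r in rows]
        return "\n".join(lines) + "\n"


@dataclass
class GeneticInfo:
    """Parsed content of ``genetic_info.json``.

    Multi-valued fields (``genetic_level``, ``sample_origin``, ``tissue_origin``,
    ``analytic_approach``) are normalized to lists on read; a bare JSON string
    becomes a one-element list.  ``extra_fields`` preserves unrecognised keys
    verbatim so that writing never loses information.
    """

    genetic_level: list[Any] | None = None
    sample_origin: list[Any] | None = None
    tissue_origin: list[Any] | None = None
    cell_type: Any | None = None
    brain_location: Any | None = None
    analytic_approach: list[Any] | None = None
    extra_fields: dict[str, Any] = field(default_factory=dict)


@dataclass
class GeneticsDescription:
    """The ``Genetics`` pointer block inside ``dataset_description.json``."""

    dataset_url: Any | None = None
    database_url: Any | None = None
    descriptors: list[Any] | None = None


PARTICIPANT_ID_PATTERN = re.compile(r"sub-[A-Za-z0-9]+")

#: Missing-value marker of the BIDS TSV dialect.
MISSING = "n/a"


@dataclass
class ParticipantRecord:
    """One participants.tsv row; ``genetic_id`` is None when the cell is n/a."""

    participant_id: str
    genetic_id: str | None = None
    extras: dict[str, str | None] = field(default_factory=dict)


@dataclass
class ParticipantLinkTable:
    header: list[str]
    records: list[ParticipantRecord]

    @property
    def has_genetic_id_column(self) -> bool:
        return "genetic_id" in self.header


@dataclass(frozen=True)
class BrainLocationValue:
    """A brain sampling location: MNI millimetre coordinates or an atlas label."""

    kind: str  # "mni_coordinates" | "atlas_label"
    coordinates: tuple[float, float, float] | None = None
    label: str | None = None

    def __post_init__(self):
        if self.kind == "mni_coordinates":
            assert self.coordinates is not None and self.label is None
        elif self.kind == "atlas_label":
            assert self.label is not None and self.coordinates is None
        else:  # pragma: no cover - construction is internal
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass
class DatasetLayout:
    """What dataset discovery found at a BIDS root.

    A parsed component is populated only if its file was present and parsed;
    parse failures are recorded as issues and leave the component unset.
    """

    root: Path
    dataset_description_present: bool = False
    genetic_info_present: bool = False
    participants_present: bool = False
    dataset_name: str | None = None
    genetics_description: GeneticsDescription | None = None
    genetic_info: GeneticInfo | None = None
    participants: ParticipantLinkTable | None = None
    parse_issues: list[ValidationIssue] = field(default_factory=list)


class VocabularyRegistry:
    """Named controlled vocabularies with a total, case-insensitive lookup.

    The four vocabularies ship as plain-text package resources (one lowercase
    canonical term per line) so they are auditable; the dbGaP-derived
    AnalyticApproach list is additionally extensible at run time.
    """

    VOCAB_FILES = {
        "GeneticLevel": "genetic_level.txt",
        "SampleOrigin": "sample_origin.txt",
        "TissueOrigin": "tissue_origin.txt",
        "AnalyticApproach": "analytic_approach.txt",
    }

    def __init__(self, vocabularies: Mapping[str, Iterable[str]]):
        self._vocabs = {name: tuple(terms) for name, terms in vocabularies.items()}

    @classmethod
    def default(cls) -> "VocabularyRegistry":
        vocabs = {}
        for name, fname in cls.VOCAB_FILES.items():
            text = resources.files("bidsgene").joinpath("vocab", fname).read_text("utf-8")
            vocabs[name] = [line for line in text.splitlines() if line.strip()]
        return cls(vocabs)

    def names(self) -> tuple[str, ...]:
        return tuple(self._vocabs)

    def terms(self, name: str) -> tuple[str, ...]:
        try:
            return self._vocabs[name]
        except KeyError:
            raise ConfigurationError(f"unknown vocabulary {name!r}") from None

    def normalize(self, value: Any, name: str) -> str | None:
        """Canonicalize ``value`` against vocabulary ``name``.

        Trims, lowercases, and collapses internal whitespace runs, then exact-
        matches; returns the canonical term or None (explicit no-match).
        Non-string values never match.
        """
        terms = self.terms(name)
        if not isinstance(value, str):
            return None
        canon = " ".join(value.strip().lower().split())
        return canon if canon in terms else None

    def extend(self, name: str, extra_terms: Iterable[str]) -> "VocabularyRegistry":
        """Return a registry with extra canonical terms appended to ``name``."""
        base = dict(self._vocabs)
        existing = self.terms(name)
        added = tuple(" ".join(t.strip().lower().split()) for t in extra_terms)
        base[name] = existing + tuple(t for t in added if t not in existing)
        return VocabularyRegistry(base)


DEFAULT_REGISTRY = VocabularyRegistry.default()
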