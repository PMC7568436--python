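"""Rule engine for the genetics descriptor.

Implements the required/recommended/conditional field rules: GeneticLevel and
SampleOrigin are required and must draw from their vocabularies; TissueOrigin
is recommended when a sample originates from brain; BrainLocation belongs in a
gray matter / white matter / csf tissue context and is either an MNI
coordinate triple or a free-text atlas label; CellType should look like a Cell
Ontology identifier; AnalyticApproach terms outside the bundled dbGaP-derived
list are flagged but allowed.

Every rule emits coded :class:`~bidsgene.model.ValidationIssue` findings; all
applicable issues are reported (no short-circuiting), except that vocabulary
checks are skipped for a field already reported missing.  Reports are
deterministic: issues sort by (file, location, code).
"""

from __future__ import annotations

import re
from typing import Any

from .io import DATASET_DESCRIPTION, GENETIC_INFO, PARTICIPANTS
from .model import (
    DEFAULT_REGISTRY,
    BrainLocationValue,
    DatasetLayout,
    GeneticInfo,
    GeneticsDescription,
    IssueCode,
    ParticipantLinkTable,
    ValidationIssue,
    ValidationReport,
    VocabularyRegistry,
    make_issue,
)

# tissue compartments in which a BrainLocation is meaningful
LOCATION_TISSUES = frozenset({"gray matter", "white matter", "csf"})

# CL:0000540-style identifier; "_" accepted as separator variant
CELL_ONTOLOGY_PATTERN = re.compile(r"CL[:_]\d{7}")

_NUM = r"[+-]?(?:\d+(?:\.\d*)?|\.\d+)"
_COORD_RE = re.compile(rf"\[\s*({_NUM})\s*,\s*({_NUM})\s*,\s*({_NUM})\s*\]")

_URL_RE = re.compile(r"(?:https?|ftp|s3|doi)://\S+")
_DOI_RE = re.compile(r"doi:\S+")


def normalize_term(value: Any, vocabulary: str,
                   registry: VocabularyRegistry = DEFAULT_REGISTRY) -> str | None:
    """Canonicalize ``value`` against a named vocabulary; None means no match."""
    return registry.normalize(value, vocabulary)


def parse_brain_location(value: Any) -> BrainLocationValue | None:
    """Interpret a BrainLocation string; None means invalid.

    ``[x, y, z]`` with three decimal numbers parses as MNI millimetre
    coordinates.  A leading ``[`` commits to the coordinate grammar — a
    malformed bracketed value is invalid, not a label.  Any other non-empty
    string is accepted as a free-text atlas label.
    """
    if not isinstance(value, str):
        return None
    s = value.strip()
    if not s:
        return None
    if s.startswith("["):
        m = _COORD_RE.fullmatch(s)
        if m is None:
            return None
        return BrainLocationValue(kind="mni_coordinates",
                                  coordinates=tuple(float(g) for g in m.groups()))
    return BrainLocationValue(kind="atlas_label", label=s)


def _is_url(value: Any, allow_doi_prefix: bool = False) -> bool:
    if not isinstance(value, str):
        return False
    if _URL_RE.fullmatch(value.strip()):
        return True
    return bool(allow_doi_prefix and _DOI_RE.fullmatch(value.strip()))


def _norm_set(values: list[Any] | None, vocabulary: str,
              registry: VocabularyRegistry) -> set[str]:
    if values is None:
        return set()
    return {t for v in values if (t := registry.normalize(v, vocabulary)) is not None}


def _check_terms(values: list[Any], vocabulary: str, key: str, code: IssueCode,
                 registry: VocabularyRegistry) -> list[ValidationIssue]:
    issues = []
    for i, value in enumerate(values):
        if registry.normalize(value, vocabulary) is None:
            issues.append(make_issue(
                code, GENETIC_INFO, f"/{key}/{i}",
                f"{value!r} is not a recognised {vocabulary} term"))
    return issues


def validate_genetic_info(gi: GeneticInfo,
                          registry: VocabularyRegistry = DEFAULT_REGISTRY,
                          ) -> list[ValidationIssue]:
    """Apply the required and conditional rules to a parsed genetic_info.json."""
    issues: list[ValidationIssue] = []

    if gi.genetic_level is None:
        issues.append(make_issue(IssueCode.GI_MISSING_GENETICLEVEL, GENETIC_INFO,
                                 "/GeneticLevel", "required key GeneticLevel is absent"))
    else:
        issues += _check_terms(gi.genetic_level, "GeneticLevel", "GeneticLevel",
                               IssueCode.GI_INVALID_GENETICLEVEL, registry)

    if gi.sample_origin is None:
        issues.append(make_issue(IssueCode.GI_MISSING_SAMPLEORIGIN, GENETIC_INFO,
                                 "/SampleOrigin", "required key SampleOrigin is absent"))
    else:
        issues += _check_terms(gi.sample_origin, "SampleOrigin", "SampleOrigin",
                               IssueCode.GI_INVALID_SAMPLEORIGIN, registry)

    samples = _norm_set(gi.sample_origin, "SampleOrigin", registry)
    tissues = _norm_set(gi.tissue_origin, "TissueOrigin", registry)

    if gi.tissue_origin is not None:
        issues += _check_terms(gi.tissue_origin, "TissueOrigin", "TissueOrigin",
                               IssueCode.GI_INVALID_TISSUEORIGIN, registry)
        if "brain" not in samples:
            issues.append(make_issue(
                IssueCode.GI_TISSUEORIGIN_WITHOUT_BRAIN, GENETIC_INFO,
                "/TissueOrigin",
                "TissueOrigin given although no SampleOrigin term is 'brain'"))
    elif "brain" in samples:
        issues.append(make_issue(
            IssueCode.GI_TISSUEORIGIN_RECOMMENDED, GENETIC_INFO, "/TissueOrigin",
            "SampleOrigin includes 'brain'; adding TissueOrigin is recommended"))

    if gi.brain_location is not None:
        if parse_brain_location(gi.brain_location) is None:
            issues.append(make_issue(
                IssueCode.GI_INVALID_BRAINLOCATION, GENETIC_INFO, "/BrainLocation",
                f"{gi.brain_location!r} is neither an MNI coordinate triple nor an atlas label"))
        if not (tissues & LOCATION_TISSUES):
            issues.append(make_issue(
                IssueCode.GI_BRAINLOCATION_CONTEXT, GENETIC_INFO, "/BrainLocation",
                "BrainLocation given without a gray matter/white matter/csf TissueOrigin"))

    if gi.cell_type is not None:
        ct = gi.cell_type
        if not (isinstance(ct, str) and CELL_ONTOLOGY_PATTERN.fullmatch(ct.strip())):
            issues.append(make_issue(
                IssueCode.GI_CELLTYPE_PATTERN, GENETIC_INFO, "/CellType",
                f"{ct!r} does not match the Cell Ontology identifier pattern"))

    if gi.analytic_approach is not None:
        for i, value in enumerate(gi.analytic_approach):
            if registry.normalize(value, "AnalyticApproach") is None:
                issues.append(make_issue(
                    IssueCode.GI_ANALYTICAPPROACH_UNKNOWN, GENETIC_INFO,
                    f"/AnalyticApproach/{i}",
                    f"{value!r} is not in the bundled dbGaP-derived approach list"))
    return issues


def validate_genetics_description(gd: GeneticsDescription | None,
                                  ) -> list[ValidationIssue]:
    """Check the Genetics pointer block; an absent block raises nothing."""
    if gd is None:
        return []
    issues: list[ValidationIssue] = []
    if not (isinstance(gd.dataset_url, str) and gd.dataset_url.strip()):
        issues.append(make_issue(
            IssueCode.DD_MISSING_GENETICS_DATASET, DATASET_DESCRIPTION,
            "/Genetics/Dataset", "Genetics block lacks the required Dataset URL"))
    elif not _is_url(gd.dataset_url):
        issues.append(make_issue(
            IssueCode.DD_INVALID_URL, DATASET_DESCRIPTION, "/Genetics/Dataset",
            f"{gd.dataset_url!r} is not a valid URL"))
    if gd.database_url is not None and not _is_url(gd.database_url):
        issues.append(make_issue(
            IssueCode.DD_INVALID_URL, DATASET_DESCRIPTION, "/Genetics/Database",
            f"{gd.database_url!r} is not a valid URL"))
    if gd.descriptors is not None:
        for i, d in enumerate(gd.descriptors):
            if not _is_url(d, allow_doi_prefix=True):
                issues.append(make_issue(
                    IssueCode.DD_INVALID_URL, DATASET_DESCRIPTION,
                    f"/Genetics/Descriptors/{i}",
                    f"{d!r} is not a valid URL or doi reference"))
    return issues


def validate_participants(table: ParticipantLinkTable | None,
                          ) -> list[ValidationIssue]:
    """Check table shape and pseudo-ID uniqueness."""
    if table is None:
        return [make_issue(IssueCode.PT_MISSING_FILE, PARTICIPANTS, "/",
                           "participants.tsv is absent")]
    issues: list[ValidationIssue] = []
    if not table.header or table.header[0] != "participant_id":
        issues.append(make_issue(
            IssueCode.PT_BAD_HEADER, PARTICIPANTS, "row 1",
            f"first column is {table.header[0]!r}, expected 'participant_id'"))
    seen_pid: dict[str, int] = {}
    seen_gid: dict[str, int] = {}
    for rownum, rec in enumerate(table.records, start=2):
        if rec.participant_id in seen_pid:
            issues.append(make_issue(
                IssueCode.PT_DUPLICATE_PARTICIPANT, PARTICIPANTS,
                f"row {rownum}",
                f"participant_id {rec.participant_id!r} already used in "
                f"row {seen_pid[rec.participant_id]}"))
        else:
            seen_pid[rec.participant_id] = rownum
        if rec.genetic_id is not None:
            if rec.genetic_id in seen_gid:
                issues.append(make_issue(
                    IssueCode.PT_DUPLICATE_GENETIC_ID, PARTICIPANTS,
                    f"row {rownum}",
                    f"genetic_id {rec.genetic_id!r} already used in "
                    f"row {seen_gid[rec.genetic_id]}"))
            else:
                seen_gid[rec.genetic_id] = rownum
    return issues


def validate_cross(layout: DatasetLayout) -> list[ValidationIssue]:
    """Consistency rules between the three files."""
    issues: list[ValidationIssue] = []
    block = layout.genetics_description is not None
    if block and not layout.genetic_info_present:
        issues.append(make_issue(
            IssueCode.GI_MISSING_FILE, GENETIC_INFO, "/",
            "Genetics block declared but genetic_info.json is absent"))
    if layout.genetic_info_present and not block:
        issues.append(make_issue(
            IssueCode.GI_ORPHAN_FILE, GENETIC_INFO, "/",
            "genetic_info.json present but dataset_description.json has no Genetics block"))
    if block and layout.participants is not None and not layout.participants.has_genetic_id_column:
        issues.append(make_issue(
            IssueCode.PT_NO_GENETIC_ID_COLUMN, PARTICIPANTS, "row 1",
            "Genetics block present but participants.tsv has no genetic_id column"))
    return issues


def validate_dataset(layout: DatasetLayout,
                     registry: VocabularyRegistry = DEFAULT_REGISTRY,
                     ) -> ValidationReport:
    """Aggregate parse findings and all rule sets into a deterministic report."""
    issues = list(layout.parse_issues)
    issues += validate_genetics_description(layout.genetics_description)
    if layout.genetic_info is not None:
        issues += validate_genetic_info(layout.genetic_info, registry)
    if not layout.participants_present:
        issues += validate_participants(None)
    elif layout.participants is not None:
        issues += validate_participants(layout.participants)
    issues += validate_cross(layout)
    issues.sort(key=lambda i: (i.file, i.location, i.code.value))
    return ValidationReport(issues=tuple(issues))
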