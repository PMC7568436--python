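"""Readers and writers for the three genetics descriptor files.

Reads are tolerant: they map whatever the files contain onto the model types
and never reject on vocabulary grounds — only on structure (malformed JSON,
non-object documents, ragged TSV rows).  Writes are canonical: fixed key
order, 4-space indent, trailing newline, single-element lists collapsed to
bare strings, so that identical content yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

from .model import (
    MISSING,
    DatasetLayout,
    DescriptorError,
    GeneticInfo,
    GeneticsDescription,
    IssueCode,
    ParticipantLinkTable,
    ParticipantRecord,
    TableParseError,
    make_issue,
)

DATASET_DESCRIPTION = "dataset_description.json"
GENETIC_INFO = "genetic_info.json"
PARTICIPANTS = "participants.tsv"

#: genetic_info.json keys with reserved meaning, in canonical write order.
GENETIC_INFO_KEYS = ("GeneticLevel", "SampleOrigin", "TissueOrigin",
                     "CellType", "BrainLocation", "AnalyticApproach")

_LIST_FIELDS = {"GeneticLevel": "genetic_level", "SampleOrigin": "sample_origin",
                "TissueOrigin": "tissue_origin", "AnalyticApproach": "analytic_approach"}


def _reject_duplicate_keys(pairs):
    seen = {}
    for key, value in pairs:
        if key in seen:
            raise ValueError(f"duplicate key {key!r}")
        seen[key] = value
    return seen


def parse_json_strict(text: str) -> Any:
    """Parse JSON, rejecting duplicate object keys instead of silently keeping one."""
    return json.loads(text, object_pairs_hook=_reject_duplicate_keys)


def _as_list(value: Any) -> list[Any]:
    return list(value) if isinstance(value, list) else [value]


def read_genetic_info(raw: Any) -> GeneticInfo:
    """Map a parsed genetic_info.json object onto :class:`GeneticInfo`.

    No validation happens here; unknown keys are preserved in ``extra_fields``
    and bare strings in multi-valued fields become one-element lists.
    """
    if not isinstance(raw, Mapping):
        raise DescriptorError(
            f"genetic_info must be a JSON object, got {type(raw).__name__}")
    gi = GeneticInfo()
    for key, value in raw.items():
        if key in _LIST_FIELDS:
            setattr(gi, _LIST_FIELDS[key], _as_list(value))
        elif key == "CellType":
            gi.cell_type = value
        elif key == "BrainLocation":
            gi.brain_location = value
        else:
            gi.extra_fields[key] = value
    return gi


def read_genetics_description(raw: Any) -> GeneticsDescription | None:
    """Extract the ``Genetics`` block from a parsed dataset_description.json.

    Returns None when the block is absent; missing sub-keys stay unset.
    """
    if not isinstance(raw, Mapping):
        raise DescriptorError(
            f"dataset_description must be a JSON object, got {type(raw).__name__}")
    if "Genetics" not in raw:
        return None
    block = raw["Genetics"]
    if not isinstance(block, Mapping):
        raise DescriptorError(
            f"Genetics must be a JSON object, got {type(block).__name__}")
    descriptors = block.get("Descriptors")
    if descriptors is not None:
        descriptors = _as_list(descriptors)
    return GeneticsDescription(dataset_url=block.get("Dataset"),
                               database_url=block.get("Database"),
                               descriptors=descriptors)


def read_participants_table(text: str) -> ParticipantLinkTable:
    """Parse participants.tsv text in the BIDS TSV dialect.

    Exactly one tab separates cells, no quoting, ``n/a`` is the only missing
    marker, final newline optional.  The first column is taken as the
    participant identifier regardless of its name (a wrong header name is a
    validator finding, not a parse failure).
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise DescriptorError("participants table is empty")
    header = lines[0].split("\t")
    gid_col = header.index("genetic_id") if "genetic_id" in header else None
    records = []
    for rownum, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableParseError(
                f"row {rownum} has {len(cells)} cells, header has {len(header)}",
                row=rownum)
        genetic_id = None
        if gid_col is not None and cells[gid_col] != MISSING:
            genetic_id = cells[gid_col]
        extras = {name: (None if cell == MISSING else cell)
                  for i, (name, cell) in enumerate(zip(header, cells))
                  if i != 0 and i != gid_col}
        records.append(ParticipantRecord(participant_id=cells[0],
                                         genetic_id=genetic_id, extras=extras))
    return ParticipantLinkTable(header=header, records=records)


def write_genetic_info(gi: GeneticInfo) -> str:
    """Serialize canonically: known keys first, extras alphabetically after."""
    doc: dict[str, Any] = {}
    for key in GENETIC_INFO_KEYS:
        if key in _LIST_FIELDS:
            value = getattr(gi, _LIST_FIELDS[key])
            if value is not None:
                doc[key] = value[0] if len(value) == 1 else list(value)
        elif key == "CellType" and gi.cell_type is not None:
            doc[key] = gi.cell_type
        elif key == "BrainLocation" and gi.brain_location is not None:
            doc[key] = gi.brain_location
    for key in sorted(gi.extra_fields):
        doc[key] = gi.extra_fields[key]
    return json.dumps(doc, indent=4, ensure_ascii=False) + "\n"


def write_genetics_block(gd: GeneticsDescription) -> dict[str, Any]:
    """Render the ``Genetics`` block for embedding in dataset_description.json."""
    block: dict[str, Any] = {}
    if gd.dataset_url is not None:
        block["Dataset"] = gd.dataset_url
    if gd.database_url is not None:
        block["Database"] = gd.database_url
    if gd.descriptors is not None:
        block["Descriptors"] = (gd.descriptors[0] if len(gd.descriptors) == 1
                                else list(gd.descriptors))
    return block


def write_dataset_description(name: str, genetics: GeneticsDescription | None,
                              bids_version: str = "1.4.0") -> str:
    doc: dict[str, Any] = {"Name": name, "BIDSVersion": bids_version}
    if genetics is not None:
        doc["Genetics"] = write_genetics_block(genetics)
    return json.dumps(doc, indent=4, ensure_ascii=False) + "\n"


def write_participants_table(table: ParticipantLinkTable) -> str:
    """Serialize a link table; missing cells become ``n/a``; read∘write = id."""
    header = table.header
    lines = ["\t".join(header)]
    for rec in table.records:
        cells = []
        for i, name in enumerate(header):
            if i == 0:
                cells.append(rec.participant_id)
            elif name == "genetic_id":
                cells.append(rec.genetic_id if rec.genetic_id is not None else MISSING)
            else:
                if name not in rec.extras:
                    raise DescriptorError(
                        f"record {rec.participant_id!r} lacks column {name!r}")
                value = rec.extras[name]
                cells.append(value if value is not None else MISSING)
        for cell in cells:
            if "\t" in cell or "\n" in cell:
                raise DescriptorError("cell values may not contain tabs or newlines")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _locate_json_error(exc: Exception) -> str:
    if isinstance(exc, json.JSONDecodeError):
        return f"line {exc.lineno}, column {exc.colno}"
    return "/"


def discover_dataset(root: Path | str) -> DatasetLayout:
    """Locate and parse the three descriptor files at the dataset root.

    Discovery is root-only (the files are dataset-level in BIDS).  Parse
    failures are recorded as issues on the layout and leave the corresponding
    component unset; semantic validation is a separate step.
    """
    root = Path(root)
    if not root.is_dir():
        raise DescriptorError(f"dataset root {root} is not a directory")
    layout = DatasetLayout(root=root)

    dd_path = root / DATASET_DESCRIPTION
    layout.dataset_description_present = dd_path.is_file()
    if layout.dataset_description_present:
        try:
            raw = parse_json_strict(dd_path.read_text("utf-8"))
            layout.genetics_description = read_genetics_description(raw)
            name = raw.get("Name")
            layout.dataset_name = name if isinstance(name, str) else None
        except (ValueError, DescriptorError) as exc:
            layout.parse_issues.append(make_issue(
                IssueCode.JSON_PARSE_ERROR, DATASET_DESCRIPTION,
                _locate_json_error(exc), str(exc)))

    gi_path = root / GENETIC_INFO
    layout.genetic_info_present = gi_path.is_file()
    if layout.genetic_info_present:
        try:
            raw = parse_json_strict(gi_path.read_text("utf-8"))
            layout.genetic_info = read_genetic_info(raw)
        except (ValueError, DescriptorError) as exc:
            layout.parse_issues.append(make_issue(
                IssueCode.JSON_PARSE_ERROR, GENETIC_INFO,
                _locate_json_error(exc), str(exc)))

    pt_path = root / PARTICIPANTS
    layout.participants_present = pt_path.is_file()
    if layout.participants_present:
        try:
            layout.participants = read_participants_table(pt_path.read_text("utf-8"))
        except TableParseError as exc:
            layout.parse_issues.append(make_issue(
                IssueCode.TSV_RAGGED_ROW, PARTICIPANTS,
                f"row {exc.row}", str(exc)))
        except DescriptorError as exc:
            layout.parse_issues.append(make_issue(
                IssueCode.TSV_RAGGED_ROW, PARTICIPANTS, "row 1", str(exc)))
    return layout
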