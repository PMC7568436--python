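"""Deterministic synthetic BIDS dataset trees for genetics-descriptor testing.

Generates minimal dataset roots — ``dataset_description.json`` with a Genetics
pointer block, ``genetic_info.json``, and ``participants.tsv`` — shaped like
the published UK Biobank genetics example: a descriptor URL into a controlled-
access repository plus a participants table carrying ``genetic_id`` pseudo-IDs.
The same spec and seed always produce a byte-identical tree, so every rule in
the validator can be exercised reproducibly, including via single-violation
mutants produced by :func:`inject_violation`.

No imaging files are written: no rule in scope inspects imaging data.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

from . import io
from .model import (
    DEFAULT_REGISTRY,
    DatasetLayout,
    GeneticsDescription,
    IssueCode,
    VocabularyRegistry,
)
from .validator import LOCATION_TISSUES


class FixtureSpecError(ValueError):
    """The requested fixture is internally inconsistent or uses unknown terms."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    Terms must be canonical vocabulary members.  ``brain_location``
    requires a tissue term in which a location is meaningful (gray matter,
    white matter, or csf); ``tissue_origins`` requires ``brain`` among the
    sample origins, so that generated datasets validate without warnings
    unless the brain-without-tissue case is deliberately requested.
    """

    n_subjects: int = 4
    genetic_levels: tuple[str, ...] = ("genomic",)
    sample_origins: tuple[str, ...] = ("saliva",)
    tissue_origins: tuple[str, ...] | None = None
    cell_type: str | None = None
    brain_location: str | None = None
    analytic_approaches: tuple[str, ...] | None = None
    name: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        kwargs = dict(d)
        for key in ("genetic_levels", "sample_origins", "tissue_origins",
                    "analytic_approaches"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _check_spec(spec: FixtureSpec, registry: VocabularyRegistry) -> None:
    if spec.n_subjects < 1:
        raise FixtureSpecError("n_subjects must be positive")
    for terms, vocab in ((spec.genetic_levels, "GeneticLevel"),
                        (spec.sample_origins, "SampleOrigin"),
                        (spec.tissue_origins or (), "TissueOrigin"),
                        (spec.analytic_approaches or (), "AnalyticApproach")):
        for term in terms:
            if registry.normalize(term, vocab) != term:
                raise FixtureSpecError(f"{term!r} is not canonical in {vocab}")
    if spec.tissue_origins is not None and "brain" not in spec.sample_origins:
        raise FixtureSpecError("tissue_origins requires 'brain' among sample_origins")
    if spec.brain_location is not None:
        qualifying = set(spec.tissue_origins or ()) & LOCATION_TISSUES
        if not qualifying:
            raise FixtureSpecError(
                "brain_location requires a gray matter/white matter/csf tissue term")


def generate_valid_dataset(spec: FixtureSpec, target: Path | str,
                           registry: VocabularyRegistry = DEFAULT_REGISTRY,
                           ) -> DatasetLayout:
    """Write a dataset tree that validates with zero errors.

    Participant labels are ``sub-01`` …; genetic pseudo-IDs are ``G``-prefixed
    four-digit numbers drawn without replacement from a generator seeded with
    ``spec.seed``, so the same spec and seed yield a byte-identical tree.
    """
    _check_spec(spec, registry)
    root = Path(target)
    root.mkdir(parents=True, exist_ok=True)

    name = spec.name or f"synthetic-genetics-{spec.seed}"
    genetics = GeneticsDescription(
        dataset_url=f"https://repo.example.org/genetics/{name}",
        database_url="https://repo.example.org/",
        descriptors=[f"doi:10.9999/{name}"],
    )
    (root / io.DATASET_DESCRIPTION).write_text(
        io.write_dataset_description(name, genetics), "utf-8")

    gi = io.read_genetic_info({})
    gi.genetic_level = list(spec.genetic_levels)
    gi.sample_origin = list(spec.sample_origins)
    if spec.tissue_origins is not None:
        gi.tissue_origin = list(spec.tissue_origins)
    gi.cell_type = spec.cell_type
    gi.brain_location = spec.brain_location
    if spec.analytic_approaches is not None:
        gi.analytic_approach = list(spec.analytic_approaches)
    (root / io.GENETIC_INFO).write_text(io.write_genetic_info(gi), "utf-8")

    rng = random.Random(spec.seed)
    numbers = rng.sample(range(1, 10000), spec.n_subjects)
    width = max(2, len(str(spec.n_subjects)))
    from .model import ParticipantLinkTable, ParticipantRecord
    records = [ParticipantRecord(participant_id=f"sub-{i + 1:0{width}d}",
                                 genetic_id=f"G{num:04d}")
               for i, num in enumerate(numbers)]
    table = ParticipantLinkTable(header=["participant_id", "genetic_id"],
                                 records=records)
    (root / io.PARTICIPANTS).write_text(io.write_participants_table(table), "utf-8")
    return io.discover_dataset(root)


# --- single-violation mutations ------------------------------------------

def _edit_json(path: Path, fn) -> None:
    doc = json.loads(path.read_text("utf-8"))
    fn(doc)
    path.write_text(json.dumps(doc, indent=4, ensure_ascii=False) + "\n", "utf-8")


def _edit_lines(path: Path, fn) -> None:
    lines = path.read_text("utf-8").splitlines()
    fn(lines)
    path.write_text("\n".join(lines) + "\n", "utf-8")


def _mut_json_parse_error(root: Path) -> None:
    path = root / io.GENETIC_INFO
    path.write_text(path.read_text("utf-8")[:-3], "utf-8")


def _mut_ragged_row(root: Path) -> None:
    _edit_lines(root / io.PARTICIPANTS, lambda lines: lines.__setitem__(
        1, lines[1] + "\textra-cell"))


def _mut_bad_header(root: Path) -> None:
    def fn(lines):
        cells = lines[0].split("\t")
        cells[0] = "subject_id"
        lines[0] = "\t".join(cells)
    _edit_lines(root / io.PARTICIPANTS, fn)


def _mut_duplicate_participant(root: Path) -> None:
    _edit_lines(root / io.PARTICIPANTS, lambda lines: lines.append(lines[1]))


def _mut_duplicate_genetic_id(root: Path) -> None:
    def fn(lines):
        cells = lines[1].split("\t")
        cells[0] = "sub-dup"
        lines.append("\t".join(cells))
    _edit_lines(root / io.PARTICIPANTS, fn)


def _mut_no_genetic_id_column(root: Path) -> None:
    def fn(lines):
        header = lines[0].split("\t")
        keep = [i for i, h in enumerate(header) if h != "genetic_id"]
        for n, line in enumerate(lines):
            cells = line.split("\t")
            lines[n] = "\t".join(cells[i] for i in keep)
    _edit_lines(root / io.PARTICIPANTS, fn)


def _del_gi_key(key):
    return lambda root: _edit_json(root / io.GENETIC_INFO,
                                   lambda doc: doc.pop(key, None))


def _set_gi(key, value):
    return lambda root: _edit_json(root / io.GENETIC_INFO,
                                   lambda doc: doc.__setitem__(key, value))


def _mut_tissue_recommended(root: Path) -> None:
    def fn(doc):
        doc["SampleOrigin"] = "brain"
        for key in ("TissueOrigin", "BrainLocation", "CellType"):
            doc.pop(key, None)
    _edit_json(root / io.GENETIC_INFO, fn)


def _mut_tissue_without_brain(root: Path) -> None:
    def fn(doc):
        doc["SampleOrigin"] = "saliva"
        doc["TissueOrigin"] = "meninges"
        doc.pop("BrainLocation", None)
    _edit_json(root / io.GENETIC_INFO, fn)


def _mut_brainlocation_context(root: Path) -> None:
    def fn(doc):
        doc["SampleOrigin"] = "brain"
        doc["TissueOrigin"] = "meninges"
        doc["BrainLocation"] = "Left hippocampus"
    _edit_json(root / io.GENETIC_INFO, fn)


def _mut_invalid_brainlocation(root: Path) -> None:
    def fn(doc):
        doc["SampleOrigin"] = "brain"
        doc["TissueOrigin"] = "gray matter"
        doc["BrainLocation"] = "[1, 2]"  # brackets commit to the coordinate grammar
    _edit_json(root / io.GENETIC_INFO, fn)


def _mut_dd_missing_dataset(root: Path) -> None:
    _edit_json(root / io.DATASET_DESCRIPTION,
               lambda doc: doc["Genetics"].pop("Dataset", None))


def _mut_dd_invalid_url(root: Path) -> None:
    _edit_json(root / io.DATASET_DESCRIPTION,
               lambda doc: doc["Genetics"].__setitem__("Dataset", "not a url"))


def _mut_orphan_file(root: Path) -> None:
    _edit_json(root / io.DATASET_DESCRIPTION,
               lambda doc: doc.pop("Genetics", None))


#: minimal documented mutation per catalogue code
MUTATIONS = {
    IssueCode.JSON_PARSE_ERROR: _mut_json_parse_error,
    IssueCode.TSV_RAGGED_ROW: _mut_ragged_row,
    IssueCode.PT_MISSING_FILE: lambda root: (root / io.PARTICIPANTS).unlink(),
    IssueCode.PT_BAD_HEADER: _mut_bad_header,
    IssueCode.PT_DUPLICATE_PARTICIPANT: _mut_duplicate_participant,
    IssueCode.GI_MISSING_FILE: lambda root: (root / io.GENETIC_INFO).unlink(),
    IssueCode.GI_MISSING_GENETICLEVEL: _del_gi_key("GeneticLevel"),
    IssueCode.GI_MISSING_SAMPLEORIGIN: _del_gi_key("SampleOrigin"),
    IssueCode.GI_INVALID_GENETICLEVEL: _set_gi("GeneticLevel", "astrologic"),
    IssueCode.GI_INVALID_SAMPLEORIGIN: _set_gi("SampleOrigin", "plasma"),
    IssueCode.GI_INVALID_TISSUEORIGIN: lambda root: _edit_json(
        root / io.GENETIC_INFO,
        lambda doc: (doc.__setitem__("SampleOrigin", "brain"),
                     doc.__setitem__("TissueOrigin", "cortex"),
                     doc.pop("BrainLocation", None))),
    IssueCode.GI_INVALID_BRAINLOCATION: _mut_invalid_brainlocation,
    IssueCode.DD_MISSING_GENETICS_DATASET: _mut_dd_missing_dataset,
    IssueCode.DD_INVALID_URL: _mut_dd_invalid_url,
    IssueCode.GI_TISSUEORIGIN_RECOMMENDED: _mut_tissue_recommended,
    IssueCode.GI_TISSUEORIGIN_WITHOUT_BRAIN: _mut_tissue_without_brain,
    IssueCode.GI_BRAINLOCATION_CONTEXT: _mut_brainlocation_context,
    IssueCode.GI_CELLTYPE_PATTERN: _set_gi("CellType", "neuron"),
    IssueCode.GI_ANALYTICAPPROACH_UNKNOWN: _set_gi("AnalyticApproach", "crystal ball"),
    IssueCode.GI_ORPHAN_FILE: _mut_orphan_file,
    IssueCode.PT_DUPLICATE_GENETIC_ID: _mut_duplicate_genetic_id,
    IssueCode.PT_NO_GENETIC_ID_COLUMN: _mut_no_genetic_id_column,
}


def inject_violation(layout: DatasetLayout, code: IssueCode) -> DatasetLayout:
    """Apply the minimal mutation for ``code`` to the dataset on disk.

    The mutated tree, re-validated, is guaranteed to report ``code``; callers
    restore a clean dataset by regenerating from the original spec.
    """
    try:
        mutation = MUTATIONS[IssueCode(code)]
    except (KeyError, ValueError):
        raise FixtureSpecError(f"unknown issue code {code!r}") from None
    mutation(layout.root)
    return io.discover_dataset(layout.root)


def random_spec(rng: random.Random, seed: int,
                registry: VocabularyRegistry = DEFAULT_REGISTRY) -> FixtureSpec:
    """Draw a random self-consistent fixture spec (for corpus generation)."""
    levels = tuple(sorted(rng.sample(registry.terms("GeneticLevel"),
                                     rng.randint(1, 3))))
    origins = set(rng.sample(registry.terms("SampleOrigin"), rng.randint(1, 2)))
    tissue = None
    location = None
    if rng.random() < 0.5:
        origins.add("brain")
    if "brain" in origins and rng.random() < 0.8:
        tissue = tuple(sorted(rng.sample(registry.terms("TissueOrigin"),
                                         rng.randint(1, 2))))
        if set(tissue) & LOCATION_TISSUES and rng.random() < 0.5:
            location = "[-30, -22, 10]"
    approaches = None
    if rng.random() < 0.6:
        approaches = tuple(sorted(rng.sample(registry.terms("AnalyticApproach"),
                                             rng.randint(1, 2))))
    return FixtureSpec(
        n_subjects=rng.randint(1, 6),
        genetic_levels=levels,
        sample_origins=tuple(sorted(origins)),
        tissue_origins=tissue,
        brain_location=location,
        cell_type="CL:0000540" if tissue and rng.random() < 0.3 else None,
        analytic_approaches=approaches,
        seed=seed,
    )
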