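"""Catalogue building and faceted search over many BIDS datasets.

Each dataset is flattened into a :class:`DatasetIndexEntry` carrying canonical
facet terms for genetic level, sample origin, tissue origin, and analytic
approach.  A query is a per-facet set of required terms with subset (AND)
semantics: a dataset matches when it has genetics metadata and every requested
facet term is present.  Brain location and cell type are stored descriptor
fields but not searchable facets (free-text / pattern values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

from .model import DEFAULT_REGISTRY, DatasetLayout, ValidationReport, VocabularyRegistry

#: facet name -> vocabulary name
FACETS = {
    "genetic_level": "GeneticLevel",
    "sample_origin": "SampleOrigin",
    "tissue_origin": "TissueOrigin",
    "analytic_approach": "AnalyticApproach",
}


class QueryError(ValueError):
    """A filter term does not belong to its facet's vocabulary."""


@dataclass(frozen=True)
class DatasetIndexEntry:
    root: str
    name: str
    facets: dict[str, frozenset[str]]
    has_genetics: bool
    dataset_url: str | None
    valid: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "root": self.root,
            "name": self.name,
            "facets": {f: sorted(terms) for f, terms in self.facets.items()},
            "has_genetics": self.has_genetics,
            "dataset_url": self.dataset_url,
            "valid": self.valid,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DatasetIndexEntry":
        return cls(root=d["root"], name=d["name"],
                   facets={f: frozenset(d["facets"].get(f, ())) for f in FACETS},
                   has_genetics=d["has_genetics"],
                   dataset_url=d.get("dataset_url"), valid=d["valid"])


@dataclass(frozen=True)
class QueryFilter:
    """Per-facet required term sets; empty sets mean 'no constraint'."""

    genetic_level: frozenset[str] = frozenset()
    sample_origin: frozenset[str] = frozenset()
    tissue_origin: frozenset[str] = frozenset()
    analytic_approach: frozenset[str] = frozenset()
    require_valid: bool = False

    def facet_terms(self) -> dict[str, frozenset[str]]:
        return {f: getattr(self, f) for f in FACETS}

    def normalized(self, registry: VocabularyRegistry = DEFAULT_REGISTRY,
                   ) -> "QueryFilter":
        """Canonicalize all filter terms, rejecting unknown ones up front."""
        canon: dict[str, frozenset[str]] = {}
        for facet, vocab in FACETS.items():
            terms = set()
            for term in getattr(self, facet):
                match = registry.normalize(term, vocab)
                if match is None:
                    raise QueryError(
                        f"{term!r} is not a valid {vocab} term (facet {facet})")
                terms.add(match)
            canon[facet] = frozenset(terms)
        return QueryFilter(require_valid=self.require_valid, **canon)


def index_dataset(layout: DatasetLayout, report: ValidationReport,
                  registry: VocabularyRegistry = DEFAULT_REGISTRY,
                  ) -> DatasetIndexEntry:
    """Flatten one discovered+validated dataset into a catalogue entry.

    Facet terms are canonical; terms that fail normalization are excluded
    rather than indexed verbatim.  Datasets without genetics still yield an
    entry (has_genetics=False, empty facets).
    """
    facets: dict[str, frozenset[str]] = {f: frozenset() for f in FACETS}
    gi = layout.genetic_info
    if gi is not None:
        raw = {"genetic_level": gi.genetic_level, "sample_origin": gi.sample_origin,
               "tissue_origin": gi.tissue_origin, "analytic_approach": gi.analytic_approach}
        for facet, values in raw.items():
            if values:
                facets[facet] = frozenset(
                    t for v in values
                    if (t := registry.normalize(v, FACETS[facet])) is not None)
    gd = layout.genetics_description
    dataset_url = gd.dataset_url if gd is not None and isinstance(gd.dataset_url, str) else None
    return DatasetIndexEntry(
        root=str(layout.root),
        name=layout.dataset_name or "",
        facets=facets,
        has_genetics=gd is not None or layout.genetic_info_present,
        dataset_url=dataset_url,
        valid=report.valid,
    )


def matches(entry: DatasetIndexEntry, filt: QueryFilter) -> bool:
    """The match predicate: genetics present, validity gate, facet subsets."""
    if not entry.has_genetics:
        return False
    if filt.require_valid and not entry.valid:
        return False
    return all(terms <= entry.facets[facet]
               for facet, terms in filt.facet_terms().items())


def search(entries: Sequence[DatasetIndexEntry], filt: QueryFilter,
           registry: VocabularyRegistry = DEFAULT_REGISTRY,
           ) -> list[DatasetIndexEntry]:
    """Return the entries matching the filter, ordered by name then root."""
    filt = filt.normalized(registry)
    hits = [e for e in entries if matches(e, filt)]
    hits.sort(key=lambda e: (e.name, e.root))
    return hits


def build_index(roots: Iterable[Path | str],
                registry: VocabularyRegistry = DEFAULT_REGISTRY,
                ) -> list[DatasetIndexEntry]:
    """Discover, validate, and index each dataset root."""
    from .io import discover_dataset
    from .validator import validate_dataset

    entries = []
    for root in roots:
        layout = discover_dataset(root)
        report = validate_dataset(layout, registry)
        entries.append(index_dataset(layout, report, registry))
    return entries


def save_catalogue(entries: Sequence[DatasetIndexEntry], path: Path | str) -> None:
    payload = {"bidsgene_catalogue": 1, "datasets": [e.to_dict() for e in entries]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", "utf-8")


def load_catalogue(path: Path | str) -> list[DatasetIndexEntry]:
    payload = json.loads(Path(path).read_text("utf-8"))
    return [DatasetIndexEntry.from_dict(d) for d in payload["datasets"]]
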