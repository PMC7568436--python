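# Methods

## The descriptor model

`bidsgene` implements the genetics descriptor of BIDS as three dataset-root
files and the rules between them.

`genetic_info.json` is the core descriptor. Two keys are REQUIRED:
`GeneticLevel` (the molecular analysis level) and `SampleOrigin` (the
biosample source). Both — like `TissueOrigin` and `AnalyticApproach` —
accept a single string or a list of strings, because one study commonly
holds several levels (e.g. genomic and transcriptomic); internally a bare
string is a one-element list, and canonical writing collapses one-element
lists back to bare strings, so read∘write is the identity. Unrecognised
keys are preserved verbatim in `extra_fields`: the validator may not know a
field, but a writer must never lose it.

The conditional chain mirrors the standard's RECOMMENDED levels: a brain
`SampleOrigin` without `TissueOrigin` is a WARNING; `TissueOrigin` without a
brain sample is a WARNING (suspicious but legal); `BrainLocation` outside a
gray matter / white matter / csf tissue context is a WARNING. Severity
mapping is fixed in a 22-code catalogue (14 ERRORs, 8 WARNINGs); a report is
`valid` iff it contains zero ERRORs, and issues sort deterministically by
(file, location, code).

## Controlled vocabularies

The four vocabularies ship as plain-text package resources, one lowercase
canonical term per line, so they are auditable and overridable.
Normalization is deliberately minimal and total: trim, lowercase, collapse
internal whitespace, then exact match — returning either the canonical term
or an explicit no-match. Real datasets vary in case ("Genomic"), so matching
is case-insensitive with lowercase canonical output. The
`AnalyticApproach` list is dbGaP-derived (seven assay terms) and clearly
non-exhaustive, so unknown terms warn rather than error, and the registry
can be extended at run time (`--vocab-config` on the CLI). `csf` appears in
both `SampleOrigin` and `TissueOrigin`; the two enumerations are
independent and no cross-constraint is applied.

## Numerical and parsing choices

- **BrainLocation grammar**: `[x, y, z]` with three decimal numbers
  (optional sign and fraction, commas, optional spaces) parses as MNI
  millimetre coordinates. A leading `[` commits to the coordinate grammar:
  `[1, 2]` is invalid, not an atlas label. Any other non-empty string is
  accepted as a free-text atlas label, since no enumerable atlas subset is
  bundled — consequently the invalid-location ERROR fires only on empty
  strings, non-strings, and malformed bracketed syntax.
- **CellType** is checked by identifier pattern (`CL:` or `CL_` plus exactly
  seven digits), not by ontology membership; shipping the Cell Ontology is
  out of scope and pattern failure is a WARNING.
- **URLs** are checked purely syntactically (scheme in {http, https, ftp,
  s3, doi} plus `://` and a non-empty remainder; `doi:` prefixes allowed for
  descriptor references). The targets are controlled-access repositories, so
  no network access is ever attempted.
- **TSV dialect**: exactly one tab between cells, no quoting, `n/a` as the
  only missing marker, final newline optional on read — the BIDS
  convention, implemented directly so ragged rows are reported with their
  row number. Duplicate JSON keys are a parse error rather than last-wins,
  because silent loss would mask descriptor mistakes.
- **Tolerant read / strict validate**: readers reject only structural
  problems; every vocabulary or rule finding belongs to the validator. This
  is why plain dataclasses are used rather than validate-on-construct
  models.

## Linkage

`participants.tsv` carries the only bridge between repositories:
`participant_id` ↔ `genetic_id`. The link map keeps a forward mapping of
linked rows and its exact transpose; duplicated genetic_ids are preserved
as multi-entries (and surfaced by the validator as warnings), never merged.
Merging an external link file fills missing genetic_ids only: a pair that
contradicts an existing mapping, or names an unknown participant, is
reported as a conflict and not applied, making the merge idempotent and
never destructive. Personal identifiers are entirely out of scope. One
participant maps to at most one genetic_id (the single-column table forces
this); repeat-sample multiplicity is not modelled.

## Faceted search

Each dataset flattens to canonical facet sets for genetic level, sample
origin, tissue origin, and analytic approach; terms that fail normalization
are excluded rather than indexed verbatim. Query semantics is subset-AND:
a dataset matches when it has genetics metadata and every requested term is
present in the corresponding facet (OR is expressible by running several
queries). `brain_location` and `cell_type` are stored but not searchable —
free-text and pattern fields make poor facets. Results order by dataset
name then root, so searches are deterministic, and the search is tested
against a brute-force scan as an independent oracle.

## Synthetic datasets

The fixture generator emulates the published UK Biobank-style layout: a
`Genetics` pointer block with a repository URL, a `genetic_info.json`
honouring the requested fields, and a participants table with `sub-NN`
labels and `G`-prefixed four-digit pseudo-IDs drawn without replacement
from a seeded generator — the same spec and seed always produce a
byte-identical tree. Specs are checked for internal consistency up front
(a brain location requires a qualifying tissue term; tissue requires a
brain sample), so generated datasets validate with zero errors and, unless
the brain-without-tissue case is deliberately requested, zero warnings.
`inject_violation` maps each of the 22 catalogue codes to exactly one
minimal documented mutation of such a tree, which makes the rule engine
exhaustively testable. Fixtures contain only the three descriptor files —
no imaging volumes and no genotype content — so passing tests demonstrate
the metadata machinery, not robustness to messy real-world imaging data or
to descriptor files written by other tools with other formatting habits.

Default problem sizes used by the test suite and the acceptance script —
50-dataset corpora, 100 random filters, 200 round-trip instances per
format — were chosen as comfortably exercising every code path while
keeping runs fast and deterministic.

## Known limitations

- The participant label pattern (`sub-` + alphanumeric) is not enforced:
  the fixed issue catalogue has no code for it, and inventing one would
  change the validator's contract.
- Whether `BrainLocation` is *required* (rather than merely allowed) in a
  qualifying tissue context is not specified by the standard; it is treated
  as allowed, with a context warning when misplaced.
- `CellType` carries no contextual rule (e.g. requiring `TissueOrigin`);
  only its identifier pattern is checked.
- Discovery is root-only; descriptor files elsewhere in the tree are
  ignored by design.
- No imaging validation, no URL resolution, no credentialed retrieval, and
  no federation across remote servers.
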