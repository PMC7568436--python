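# bidsgene

A toolkit for the genetics descriptor of the Brain Imaging Data Structure
(BIDS): the dataset-level metadata that links a brain-imaging dataset to
genetic data held in a separate (usually controlled-access) repository and
describes succinctly what kind of molecular data is available.

## Who this is for

Imaging-genetics studies typically split their data: brain images in an open
or authorized-access BIDS repository, genotypes and expression data behind
controlled access elsewhere. Three small dataset-level files tie the two
sides together:

- `dataset_description.json` gains a `Genetics` block whose `Dataset` key is
  the URL of the genetic data (optionally `Database` and `Descriptors`);
- `genetic_info.json` declares what molecular data exist, minimally via the
  REQUIRED keys **GeneticLevel** (genetic, genomic, epigenomic,
  transcriptomic, metabolomic, proteomic) and **SampleOrigin** (blood,
  saliva, brain, csf, breast milk, bile, amniotic fluid, other biospecimen);
- `participants.tsv` links the imaging pseudo-ID (`participant_id`) to the
  genetic pseudo-ID (`genetic_id`) without ever touching personal data.

`bidsgene` reads and writes these files, validates them against the
controlled vocabularies and conditional rules of the standard (ERROR for
REQUIRED rules, WARNING for RECOMMENDED ones), builds participant↔genetic
link maps, and indexes collections of datasets for faceted search ("which
datasets have transcriptomic data from brain gray matter?").

The conditional chain for brain samples: if a `SampleOrigin` is `brain`,
adding **TissueOrigin** (gray matter, white matter, csf, meninges,
macrovascular, microvascular) is recommended; **CellType** takes Cell
Ontology identifiers (`CL:` + 7 digits); **BrainLocation** — either MNI
millimetre coordinates `[x, y, z]` or a free-text Allen Brain Atlas label —
belongs with gray matter, white matter, or csf tissue. **AnalyticApproach**
takes dbGaP-style assay terms (SNP genotyping array, whole genome
sequencing, ...); unknown terms are flagged but allowed.

## Worked example

```python
from bidsgene import discover_dataset, validate_dataset

report = validate_dataset(discover_dataset("my_dataset"))
print(report.to_table())
print(f"valid={report.valid}  errors={report.error_count}  warnings={report.warning_count}")
```

For a dataset whose `genetic_info.json` declares a brain sample but omits
`TissueOrigin`, this prints:

```
WARNING  GI_TISSUEORIGIN_RECOMMENDED  genetic_info.json:/TissueOrigin  SampleOrigin includes 'brain'; adding TissueOrigin is recommended
valid=True  errors=0  warnings=1
```

`valid=True` means no REQUIRED rule is broken; the warning flags the
RECOMMENDED tissue field as missing. Runnable narrative scripts live in
`examples/` — validation (`validate_dataset.py`), pseudo-ID link merging
(`link_pseudo_ids.py`), and faceted corpus search (`search_datasets.py`).

The same functionality is available from the shell:

```sh
bidsgene validate my_dataset --json       # exit 0 valid, 1 errors, 2 usage/IO
bidsgene init new_dataset                 # scaffold template descriptors
bidsgene link my_dataset --pairs links.tsv
bidsgene index ds1 ds2 ds3 -o catalogue.json
bidsgene query catalogue.json --genetic-level transcriptomic --sample-origin brain
bidsgene fixture --out demo --seed 7 [--inject GI_MISSING_GENETICLEVEL]
```

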