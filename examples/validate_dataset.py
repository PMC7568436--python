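"""Validate the genetics descriptor of a BIDS dataset.

Builds a small dataset in a temporary directory whose genetic_info.json
declares a brain sample but omits the recommended TissueOrigin field, then
runs the validator and prints the report.  The single WARNING shows the
conditional rule at work: brain samples should say which tissue compartment
(gray matter, white matter, csf, ...) the biosample came from.
"""

import json
import tempfile
from pathlib import Path

from bidsgene import discover_dataset, validate_dataset

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    (root / "dataset_description.json").write_text(json.dumps({
        "Name": "example-brain-study",
        "BIDSVersion": "1.4.0",
        "Genetics": {"Dataset": "https://repo.example.org/genetics/brain-study"},
    }, indent=4))
    (root / "genetic_info.json").write_text(json.dumps({
        "GeneticLevel": "transcriptomic",
        "SampleOrigin": "brain",
        "AnalyticApproach": "RNA Sequencing",
    }, indent=4))
    (root / "participants.tsv").write_text(
        "participant_id\tgenetic_id\nsub-01\tG0001\nsub-02\tn/a\n")

    report = validate_dataset(discover_dataset(root))
    print(report.to_table())
    print(f"valid={report.valid}  errors={report.error_count}  "
          f"warnings={report.warning_count}")
    # valid=True with one warning: errors would mean the descriptor breaks a
    # REQUIRED rule; warnings flag RECOMMENDED metadata that is missing.
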