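"""Rule engine: normalization, conditional chains, report determinism."""

import pytest
from hypothesis import given, settings, strategies as st

from bidsgene import io
from bidsgene.model import (
    ConfigurationError,
    GeneticInfo,
    GeneticsDescription,
    IssueCode,
    ParticipantLinkTable,
    ParticipantRecord,
    Severity,
    issue_catalogue,
)
from bidsgene.validator import (
    normalize_term,
    parse_brain_location,
    validate_cross,
    validate_dataset,
    validate_genetic_info,
    validate_genetics_description,
    validate_participants,
)


def codes(issues):
    return [i.code for i in issues]


class TestNormalizeTerm:
    @pytest.mark.parametrize("value, vocab, expected", [
        ("Genomic", "GeneticLevel", "genomic"),
        ("gray  matter ", "TissueOrigin", "gray matter"),
        ("  BREAST   MILK ", "SampleOrigin", "breast milk"),
        ("plasma", "SampleOrigin", None),
        ("", "GeneticLevel", None),
    ])
    def test_whitespace_and_case_folding(self, value, vocab, expected):
        assert normalize_term(value, vocab) == expected

    def test_unknown_vocabulary_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            normalize_term("x", "NotAVocab")


class TestParseBrainLocation:
    @pytest.mark.parametrize("value, kind", [
        ("[-30, -22, 10]", "mni_coordinates"),
        ("[ 1.5 , -0.25 , +3 ]", "mni_coordinates"),
        ("Left hippocampus", "atlas_label"),
        ("CA1", "atlas_label"),
    ])
    def test_coordinate_grammar_vs_atlas_label(self, value, kind):
        loc = parse_brain_location(value)
        assert loc is not None and loc.kind == kind

    def test_coordinates_parsed_in_millimetres(self):
        loc = parse_brain_location("[-30, -22, 10]")
        assert loc.coordinates == (-30.0, -22.0, 10.0)

    @pytest.mark.parametrize("value", ["", "   ", "[1, 2]", "[1, 2, 3, 4]",
                                       "[a, b, c]", None, 42])
    def test_invalid_values(self, value):
        # brackets commit to the coordinate grammar; empty strings are invalid
        assert parse_brain_location(value) is None


class TestValidateGeneticInfo:
    def test_minimal_valid_descriptor_has_no_findings(self):
        gi = io.read_genetic_info({"GeneticLevel": "genomic", "SampleOrigin": "saliva"})
        assert validate_genetic_info(gi) == []

    def test_missing_required_keys(self):
        gi = io.read_genetic_info({"SampleOrigin": "saliva"})
        assert codes(validate_genetic_info(gi)) == [IssueCode.GI_MISSING_GENETICLEVEL]
        gi = io.read_genetic_info({"GeneticLevel": "genomic"})
        assert codes(validate_genetic_info(gi)) == [IssueCode.GI_MISSING_SAMPLEORIGIN]

    def test_brain_sample_without_tissue_is_recommended_warning(self):
        gi = io.read_genetic_info(
            {"GeneticLevel": "transcriptomic", "SampleOrigin": "brain"})
        issues = validate_genetic_info(gi)
        assert codes(issues) == [IssueCode.GI_TISSUEORIGIN_RECOMMENDED]
        assert issues[0].severity is Severity.WARNING

    def test_tissue_without_brain_sample_is_flagged(self):
        gi = io.read_genetic_info({"GeneticLevel": "genomic",
                                   "SampleOrigin": "saliva",
                                   "TissueOrigin": "meninges"})
        assert codes(validate_genetic_info(gi)) == \
            [IssueCode.GI_TISSUEORIGIN_WITHOUT_BRAIN]

    def test_full_brain_chain_is_clean(self):
        gi = io.read_genetic_info({
            "GeneticLevel": "transcriptomic", "SampleOrigin": "brain",
            "TissueOrigin": "gray matter", "BrainLocation": "[-30, -22, 10]",
            "CellType": "CL:0000540", "AnalyticApproach": "RNA Sequencing"})
        assert validate_genetic_info(gi) == []

    def test_brainlocation_outside_qualifying_tissue_is_context_warning(self):
        gi = io.read_genetic_info({
            "GeneticLevel": "genomic", "SampleOrigin": "brain",
            "TissueOrigin": "meninges", "BrainLocation": "Left hippocampus"})
        assert IssueCode.GI_BRAINLOCATION_CONTEXT in codes(validate_genetic_info(gi))

    def test_one_invalid_issue_per_offending_term(self):
        gi = io.read_genetic_info({"GeneticLevel": ["genomic", "x", "y"],
                                   "SampleOrigin": "saliva"})
        assert codes(validate_genetic_info(gi)) == \
            [IssueCode.GI_INVALID_GENETICLEVEL] * 2

    @pytest.mark.parametrize("cell_type, ok", [
        ("CL:0000540", True), ("CL_0000540", True),
        ("CL:123", False), ("neuron", False), ("cl:0000540", False),
    ])
    def test_cell_ontology_identifier_pattern(self, cell_type, ok):
        gi = io.read_genetic_info({"GeneticLevel": "genomic",
                                   "SampleOrigin": "saliva", "CellType": cell_type})
        found = IssueCode.GI_CELLTYPE_PATTERN in codes(validate_genetic_info(gi))
        assert found != ok

    def test_unknown_analytic_approach_is_warning_only(self):
        gi = io.read_genetic_info({"GeneticLevel": "genomic",
                                   "SampleOrigin": "saliva",
                                   "AnalyticApproach": ["SNP Genotyping Array",
                                                        "crystal ball"]})
        issues = validate_genetic_info(gi)
        assert codes(issues) == [IssueCode.GI_ANALYTICAPPROACH_UNKNOWN]
        assert all(i.severity is Severity.WARNING for i in issues)


class TestValidateGeneticsDescription:
    def test_valid_block(self):
        gd = GeneticsDescription(dataset_url="https://ega.example/EGAD1")
        assert validate_genetics_description(gd) == []

    def test_absent_block_raises_nothing(self):
        assert validate_genetics_description(None) == []

    def test_missing_dataset_url(self):
        gd = GeneticsDescription(database_url="https://db.example/x")
        assert codes(validate_genetics_description(gd)) == \
            [IssueCode.DD_MISSING_GENETICS_DATASET]

    @pytest.mark.parametrize("url", ["not a url", "httpx://x", "doi:10.1/x"])
    def test_dataset_url_must_have_scheme_and_authority(self, url):
        gd = GeneticsDescription(dataset_url=url)
        assert codes(validate_genetics_description(gd)) == [IssueCode.DD_INVALID_URL]

    def test_descriptors_accept_doi_prefix(self):
        gd = GeneticsDescription(dataset_url="s3://bucket/key",
                                 descriptors=["doi:10.1093/gigascience",
                                              "ftp://host/path", "nope"])
        issues = validate_genetics_description(gd)
        assert codes(issues) == [IssueCode.DD_INVALID_URL]
        assert issues[0].location == "/Genetics/Descriptors/2"


class TestValidateParticipants:
    def _table(self, rows):
        return ParticipantLinkTable(
            header=["participant_id", "genetic_id"],
            records=[ParticipantRecord(p, g) for p, g in rows])

    def test_well_formed_table(self):
        assert validate_participants(
            self._table([("sub-01", "G1"), ("sub-02", "G2")])) == []

    def test_absent_file(self):
        assert codes(validate_participants(None)) == [IssueCode.PT_MISSING_FILE]

    def test_bad_header(self):
        table = ParticipantLinkTable(header=["subject", "genetic_id"],
                                     records=[])
        assert codes(validate_participants(table)) == [IssueCode.PT_BAD_HEADER]

    def test_duplicate_participant_is_error(self):
        issues = validate_participants(self._table([("sub-01", "G1"),
                                                    ("sub-01", "G2")]))
        assert codes(issues) == [IssueCode.PT_DUPLICATE_PARTICIPANT]

    def test_duplicate_genetic_id_is_warning(self):
        issues = validate_participants(self._table([("sub-01", "G1"),
                                                    ("sub-02", "G1")]))
        assert codes(issues) == [IssueCode.PT_DUPLICATE_GENETIC_ID]
        assert issues[0].severity is Severity.WARNING

    def test_missing_genetic_ids_are_not_duplicates(self):
        assert validate_participants(self._table([("sub-01", None),
                                                  ("sub-02", None)])) == []


class TestValidateCross:
    def test_consistent_dataset(self, valid_dataset):
        _, layout = valid_dataset
        assert validate_cross(layout) == []

    def test_block_without_sidecar(self, valid_dataset):
        _, layout = valid_dataset
        (layout.root / io.GENETIC_INFO).unlink()
        again = io.discover_dataset(layout.root)
        assert codes(validate_cross(again)) == [IssueCode.GI_MISSING_FILE]

    def test_sidecar_without_block(self, valid_dataset):
        _, layout = valid_dataset
        (layout.root / io.DATASET_DESCRIPTION).write_text('{"Name": "ds"}', "utf-8")
        again = io.discover_dataset(layout.root)
        assert codes(validate_cross(again)) == [IssueCode.GI_ORPHAN_FILE]

    def test_block_but_no_genetic_id_column(self, valid_dataset):
        _, layout = valid_dataset
        (layout.root / io.PARTICIPANTS).write_text(
            "participant_id\nsub-01\n", "utf-8")
        again = io.discover_dataset(layout.root)
        assert IssueCode.PT_NO_GENETIC_ID_COLUMN in codes(validate_cross(again))


class TestValidateDataset:
    def test_valid_fixture_is_clean(self, valid_dataset):
        _, layout = valid_dataset
        report = validate_dataset(layout)
        assert report.valid and report.error_count == 0 and report.warning_count == 0

    def test_report_is_deterministic(self, brain_dataset):
        _, layout = brain_dataset
        assert validate_dataset(layout) == validate_dataset(layout)

    def test_valid_means_zero_errors_and_severities_match_catalogue(self, valid_dataset):
        _, layout = valid_dataset
        (layout.root / io.GENETIC_INFO).write_text(
            '{"GeneticLevel": "genomic", "SampleOrigin": "plasma"}', "utf-8")
        report = validate_dataset(io.discover_dataset(layout.root))
        assert not report.valid
        catalogue = {c: s for c, s, _ in issue_catalogue()}
        assert all(i.severity is catalogue[i.code] for i in report.issues)

    def test_json_and_table_renderings_cover_all_issues(self, valid_dataset):
        _, layout = valid_dataset
        (layout.root / io.GENETIC_INFO).write_text(
            '{"SampleOrigin": "brain"}', "utf-8")
        report = validate_dataset(io.discover_dataset(layout.root))
        d = report.to_dict()
        assert d["error_count"] == report.error_count
        assert len(d["issues"]) == len(report.issues)
        assert len(report.to_table().rstrip("\n").split("\n")) == len(report.issues)


# Optional, vocabulary-conformant additions never turn a valid descriptor invalid.
@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_monotonicity_optional_conformant_fields_add_no_errors(data):
    from bidsgene.model import DEFAULT_REGISTRY as reg

    gi = GeneticInfo(genetic_level=["genomic"], sample_origin=["brain"])
    add_tissue = data.draw(st.booleans())
    if add_tissue:
        gi.tissue_origin = data.draw(
            st.lists(st.sampled_from(reg.terms("TissueOrigin")), min_size=1,
                     max_size=2, unique=True))
    if data.draw(st.booleans()):
        gi.cell_type = f"CL:{data.draw(st.integers(0, 10**7 - 1)):07d}"
    if add_tissue and set(gi.tissue_origin) & {"gray matter", "white matter", "csf"}:
        if data.draw(st.booleans()):
            gi.brain_location = "[-30, -22, 10]"
    if data.draw(st.booleans()):
        gi.analytic_approach = data.draw(
            st.lists(st.sampled_from(reg.terms("AnalyticApproach")), min_size=1,
                     max_size=2, unique=True))
    assert all(i.severity is not Severity.ERROR for i in validate_genetic_info(gi))
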