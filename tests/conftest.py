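import random
import string

import pytest

from bidsgene import FixtureSpec, generate_valid_dataset
from bidsgene.model import (
    GeneticInfo,
    ParticipantLinkTable,
    ParticipantRecord,
    VocabularyRegistry,
)


@pytest.fixture(scope="session")
def registry():
    return VocabularyRegistry.default()


@pytest.fixture
def valid_dataset(tmp_path):
    """A minimal valid dataset tree (genomic / saliva, 3 subjects)."""
    spec = FixtureSpec(n_subjects=3, seed=11)
    return spec, generate_valid_dataset(spec, tmp_path / "ds")


@pytest.fixture
def brain_dataset(tmp_path):
    """A valid brain-sample dataset with tissue, location, cell type, approach."""
    spec = FixtureSpec(
        n_subjects=2,
        genetic_levels=("transcriptomic",),
        sample_origins=("brain",),
        tissue_origins=("gray matter",),
        brain_location="[-30, -22, 10]",
        cell_type="CL:0000540",
        analytic_approaches=("rna sequencing",),
        seed=23,
    )
    return spec, generate_valid_dataset(spec, tmp_path / "brainds")


def random_genetic_info(rng: random.Random, registry: VocabularyRegistry) -> GeneticInfo:
    """A random well-formed GeneticInfo, including extras and multi-valued fields."""
    gi = GeneticInfo()
    gi.genetic_level = rng.sample(registry.terms("GeneticLevel"), rng.randint(1, 3))
    gi.sample_origin = rng.sample(registry.terms("SampleOrigin"), rng.randint(1, 2))
    if rng.random() < 0.5:
        gi.tissue_origin = rng.sample(registry.terms("TissueOrigin"), rng.randint(1, 2))
    if rng.random() < 0.3:
        gi.cell_type = f"CL:{rng.randrange(10**7):07d}"
    if rng.random() < 0.3:
        gi.brain_location = rng.choice(["[-30, -22, 10]", "Left hippocampus"])
    if rng.random() < 0.4:
        gi.analytic_approach = rng.sample(registry.terms("AnalyticApproach"),
                                          rng.randint(1, 2))
    for _ in range(rng.randint(0, 3)):
        key = "".join(rng.choices(string.ascii_letters, k=6))
        gi.extra_fields[key] = rng.choice([1, "free text", [1, 2], {"a": True}, None])
    return gi


def random_link_table(rng: random.Random) -> ParticipantLinkTable:
    """A random participants table with n/a cells and extra columns."""
    extra_cols = ["age", "group"][: rng.randint(0, 2)]
    header = ["participant_id", "genetic_id"] + extra_cols
    n = rng.randint(1, 8)
    records = []
    for i in range(n):
        gid = None if rng.random() < 0.3 else f"G{rng.randrange(10000):04d}"
        extras = {c: (None if rng.random() < 0.2 else str(rng.randrange(100)))
                  for c in extra_cols}
        records.append(ParticipantRecord(participant_id=f"sub-{i + 1:02d}",
                                         genetic_id=gid, extras=extras))
    return ParticipantLinkTable(header=header, records=records)
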