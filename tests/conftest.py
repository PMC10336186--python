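import pathlib

import pytest

from enzpam.crossref import PresenceAbsenceMatrix
from enzpam.fixtures import FixtureConfig, NoiseOpts, generate_fixture
from enzpam.pipeline import PipelineConfig, run_pipeline
from enzpam.spec_io import EnzymeSpec, make_enzyme_id, validate_ec


def make_spec(name, pathway, ecs=("1.13.11.1",), kos=("K03381",)):
    return EnzymeSpec(
        enzyme_id=make_enzyme_id(pathway, name),
        standard_name=name,
        ec_numbers=tuple(validate_ec(e) for e in ecs),
        ko_ids=tuple(kos),
        pathway=pathway,
    )


def run_bundle(bundle, workdir, mode="exact", curation_path=None):
    """Run the full pipeline (no external annotator) on a fixture bundle."""
    cfg = PipelineConfig(
        workdir=str(workdir),
        spec_table=str(bundle.spec_table),
        source_kind="snapshot",
        source_location=str(bundle.snapshot_dir),
        annotations_dir=str(bundle.genomes_dir),
        match_mode=mode,
        curation_path=str(curation_path) if curation_path else "",
    )
    run_pipeline(cfg)
    return PresenceAbsenceMatrix.read(
        pathlib.Path(workdir) / "matrix.tsv", pathlib.Path(workdir) / "matrix_provenance.tsv"
    )


@pytest.fixture
def small_bundle(tmp_path):
    """A compact noise-free bundle: 2 pathways x 3 enzymes x 3 synonyms, 4 genomes."""
    cfg = FixtureConfig(
        n_pathways=2,
        enzymes_per_pathway=3,
        synonyms_per_enzyme=3,
        n_genomes=4,
        presence_prob=0.5,
        n_decoys_per_genome=10,
        seed=11,
    )
    return generate_fixture(cfg, tmp_path / "bundle")


@pytest.fixture
def noisy_bundle(tmp_path):
    cfg = FixtureConfig(
        n_pathways=2,
        enzymes_per_pathway=3,
        synonyms_per_enzyme=3,
        n_genomes=4,
        presence_prob=0.6,
        n_decoys_per_genome=10,
        noise_opts=NoiseOpts.all_on(),
        seed=23,
    )
    return generate_fixture(cfg, tmp_path / "noisy")
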