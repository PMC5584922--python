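import csv
from pathlib import Path

import pytest

from guidescreen import reference_io, scoring
from guidescreen.synth import SyntheticSpec, generate_fixture


def make_asm(**seqs) -> reference_io.ReferenceAssembly:
    return reference_io.ReferenceAssembly({k: v.upper() for k, v in seqs.items()})


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """Default synthetic fixture, generated once per session (seed 7)."""
    out = tmp_path_factory.mktemp("fixture")
    generate_fixture(SyntheticSpec(seed=7), out)
    return out


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir):
    with open(fixture_dir / "truth.tsv") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@pytest.fixture(scope="session")
def fixture_bundle(fixture_dir):
    """Loaded fixture: assembly, gene models, region index, variants, track."""
    asm = reference_io.read_genome(fixture_dir / "genome.fa")
    genes = reference_io.read_gene_models(fixture_dir / "genes.gff3", asm)
    return {
        "dir": fixture_dir,
        "asm": asm,
        "genes": {g.gene_id: g for g in genes},
        "index": reference_io.RegionIndex.build(genes),
        "variants": reference_io.read_variants(
            fixture_dir / "snps.vcf", fixture_dir / "somatic.tsv"
        ),
        "conservation": reference_io.read_conservation(
            fixture_dir / "conservation.bedGraph"
        ),
        "efficiency": scoring.default_efficiency_model(),
        "penalty": scoring.default_specificity_penalty(),
    }
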