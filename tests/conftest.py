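import pytest

from ssrkit import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_genome():
    """Small two-contig genome with plants covering every region class."""
    plants = [
        sd.Plant("AAAG", 11, "chr1", ("intron",)),
        sd.Plant("AATG", 20, "chr1", ("TE",)),
        sd.Plant("AT", 8, "chr1", ("intergenic",)),
        sd.Plant("A", 14, "chr1", ("intergenic",)),
        sd.Plant("AAAT", 12, "chr2", ("intron", "TE")),
        sd.Plant("ATCC", 15, "chr2", ("CDS",)),
        sd.Plant("AAC", 7, "chr2", ("UTR5",)),
        sd.Plant("AAAGG", 6, "chr2", ("UTR3",)),
    ]
    spec = sd.PlantSpec(
        contigs={"chr1": 8000, "chr2": 8000}, plants=plants, seed=11
    )
    return sd.make_genome(spec)


@pytest.fixture(scope="session")
def genome_files(planted_genome, tmp_path_factory):
    out = tmp_path_factory.mktemp("genome") / "synth"
    return planted_genome.write(out)


@pytest.fixture(scope="session")
def hwe_panel():
    """Clean HWE panel: 200 individuals, three loci of varying diversity."""
    spec = sd.PanelSpec(
        loci={
            "biallelic": {100: 0.5, 104: 0.5},
            "skewed": {200: 0.7, 204: 0.3},
            "rich": {300: 0.4, 304: 0.3, 308: 0.2, 312: 0.1},
        },
        n_individuals=200,
        seed=7,
    )
    return sd.make_genotypes(spec)
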