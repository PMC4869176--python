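import numpy as np
import pandas as pd
import pytest

from methylseg import GenomeConfig, build_annotation, build_genome_spec

TINY_GENOME_CONFIG = GenomeConfig(chromosomes=(("chr1", 200_000),), n_genes=4,
                                  islands_per_mb=8.0)


# function-scoped: plant_dmrs mutates the genome's site table in place
@pytest.fixture
def tiny_genome():
    return build_genome_spec(TINY_GENOME_CONFIG, seed=11)


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-laid annotation on a 1 Mb chromosome: a plus-strand gene with
    two exons and a minus-strand gene, plus one CpG island."""
    genes = pd.DataFrame([
        {"chrom": "chr1", "tss": 100_000, "tes": 139_999, "strand": "+",
         "gene_id": "geneA",
         "exons": [(100_000, 110_000), (130_000, 140_000)]},
        {"chrom": "chr1", "tss": 699_999, "tes": 660_000, "strand": "-",
         "gene_id": "geneB", "exons": []},
    ])
    islands = pd.DataFrame([{"chrom": "chr1", "start": 98_500, "end": 99_800}])
    return build_annotation(genes, islands, {"chr1": 1_000_000})


def make_sites(positions, diffs=None, chrom="chr1", context="CpG"):
    """Minimal differential-site frame for clustering tests."""
    n = len(positions)
    diffs = diffs if diffs is not None else [-20.0] * n
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=int),
        "strand": "+",
        "context": context,
        "pct_a": 50.0,
        "pct_b": 50.0 + np.asarray(diffs, dtype=float),
        "diff": np.asarray(diffs, dtype=float),
        "p": 1e-6,
        "q": 1e-4,
        "direction": np.where(np.asarray(diffs) > 0, "hyper", "hypo"),
        "is_dm": True,
    })


def make_regions(triples):
    """(chrom, start, end) tuples -> region frame."""
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])
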