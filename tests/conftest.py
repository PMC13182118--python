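import numpy as np
import pytest

from milkvar.gene_models import GeneModel, bovine_milk_gene_models


@pytest.fixture(scope="session")
def milk_models():
    return bovine_milk_gene_models()


def make_toy_gene(strand: str = "+", cds_sequence: str = "ATGGCTGATCCA") -> GeneModel:
    """Tiny two-exon gene with CDS exons (101-106) and (201-206).

    The 12-bp CDS covers the exons exactly (no UTR), flanked by the gene
    bounds 101..206. For the reverse-strand mirror the same coordinates are
    kept and the CDS is read from the high end.
    """
    return GeneModel(
        name="TOY",
        chrom="1",
        start=101,
        end=206,
        strand=strand,
        exons=[(101, 106), (201, 206)],
        cds_start=101,
        cds_end=206,
        signal_peptide_len=0,
        cds_sequence=cds_sequence,
        flank=50,
        reference_variant_name="R",
    )


@pytest.fixture
def toy_forward():
    return make_toy_gene("+")


@pytest.fixture
def toy_reverse():
    # same transcript on the minus strand: the genomic plus-strand bases are
    # the reverse complement, the transcribed CDS is identical
    return make_toy_gene("-", "ATGGCTGATCCA")
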