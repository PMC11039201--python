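import pytest

from gdrkit import build_vocabulary, default_matrix, synth_transcript
from gdrkit.transcripts import TranscriptModel


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary()


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def toy_tx():
    """A default 3-exon toy transcript (forward strand)."""
    return synth_transcript(n_exons=3, seed=1)


@pytest.fixture(scope="session")
def hand_tx():
    """A tiny hand-built 3-exon transcript with fully known structure.

    layout (1-based genomic):
      flank 1-10, exon1 11-22 (5'UTR 11-16 GGGCCC, CDS ATGGCT 17-22),
      intron1 23-42 (GT..AG), exon2 43-54 (CDS GAGCAGTTTAAA),
      intron2 55-74 (GT..AG), exon3 75-92 (CDS GATTGGTAA 75-83, 3'UTR 84-92),
      flank 93-102.
    CDS = ATG GCT GAG CAG TTT AAA GAT TGG TAA -> protein MAEQFKDW*
    """
    chrom = (
        "AAAAAAAAAA"          # 1-10 flank
        "GGGCCC" "ATGGCT"     # 11-22 exon1
        "GT" + "C" * 16 + "AG"  # 23-42 intron1
        "GAGCAGTTTAAA"        # 43-54 exon2
        "GT" + "C" * 16 + "AG"  # 55-74 intron2
        "GATTGGTAA" "CCCCCCCCC"  # 75-92 exon3
        "AAAAAAAAAA"          # 93-102 flank
    )
    return TranscriptModel(
        transcript_id="HAND-tx1",
        gene_symbol="HAND1",
        chromosome="chrT",
        strand="+",
        exons=((11, 22), (43, 54), (75, 92)),
        cds_start=17,
        cds_end=83,
        chrom_seq=chrom,
    )
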