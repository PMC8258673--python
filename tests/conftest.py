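import numpy as np
import pytest

from trfclash import GeneIndex, Thresholds, TranscriptIndex, TranscriptModel, TRNAGeneModel


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture()
def toy_gene() -> TRNAGeneModel:
    rng = np.random.default_rng(11)
    return TRNAGeneModel(
        gene_id="GluCTC-002",
        origin="N",
        sequence=random_seq(rng, 72),
        anticodon_loop=(33, 39),
        trailer="ACGTTGCAAT",
        cca_added=True,
    )


@pytest.fixture(scope="session")
def small_reference():
    """Five deterministic gene models plus a small transcriptome."""
    rng = np.random.default_rng(202)
    genes = [
        TRNAGeneModel(
            gene_id=f"Toy{chr(65 + i)}-00{i + 1}",
            origin="N",
            sequence=random_seq(rng, 70 + 5 * i),
            anticodon_loop=(33, 39),
            trailer=random_seq(rng, 12),
            cca_added=True,
        )
        for i in range(5)
    ]
    transcripts = [
        TranscriptModel(
            transcript_id="tx-mrna-1",
            category="mRNA",
            sequence=random_seq(rng, 300),
            regions=[("5UTR", (1, 60)), ("CDS", (61, 240)), ("3UTR", (241, 300))],
        ),
        TranscriptModel(
            transcript_id="tx-rrna-1", category="rRNA", sequence=random_seq(rng, 200)
        ),
    ]
    return genes, transcripts


@pytest.fixture(scope="session")
def small_indexes(small_reference):
    genes, transcripts = small_reference
    return GeneIndex(genes), TranscriptIndex(transcripts)
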