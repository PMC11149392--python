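import random

import pytest

from orthoclique.transcripts import Isotig, Transcriptome

BASES = "ACGT"


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def mutate(rng: random.Random, seq: str, p: float) -> str:
    out = []
    for c in seq:
        if rng.random() < p:
            out.append(rng.choice(BASES.replace(c, "")))
        else:
            out.append(c)
    return "".join(out)


def make_transcriptome(sample_id: str, genes: dict, coverages: dict | None = None) -> Transcriptome:
    """Build a transcriptome from {gene_id: sequence or [sequences]}."""
    isotigs = []
    for gene_id, seqs in genes.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        cov = (coverages or {}).get(gene_id, 10.0)
        for iso_id, seq in enumerate(seqs):
            isotigs.append(
                Isotig(
                    sample_id=sample_id,
                    gene_id=gene_id,
                    isotig_id=iso_id,
                    sequence=seq,
                    kmer_coverage=cov,
                )
            )
    return Transcriptome.from_isotigs(sample_id, isotigs)


def clone_transcriptome(t: Transcriptome, new_sample_id: str) -> Transcriptome:
    """Same sequences under a different sample label."""
    isotigs = [
        Isotig(
            sample_id=new_sample_id,
            gene_id=iso.gene_id,
            isotig_id=iso.isotig_id,
            sequence=iso.sequence,
            kmer_coverage=iso.kmer_coverage,
            record_id=None,
        )
        for iso in t.iter_isotigs()
    ]
    return Transcriptome.from_isotigs(new_sample_id, isotigs)


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def pair_500bp(rng):
    """Two 10-gene transcriptomes, ~95% identical gene-for-gene."""
    genes_a = {g: random_dna(rng, 500) for g in range(10)}
    genes_b = {g: mutate(rng, seq, 0.05) for g, seq in genes_a.items()}
    return make_transcriptome("A", genes_a), make_transcriptome("B", genes_b)
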