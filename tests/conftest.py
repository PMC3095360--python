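import numpy as np
import pytest

from homoeolog.seqio import AnnotatedRegion, GeneModel
from homoeolog.pairwise_align import AlignmentParams
from homoeolog.synthetic_data import SimParams, DeletionSpec, simulate_pair


@pytest.fixture(scope="session")
def params() -> AlignmentParams:
    return AlignmentParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def make_region(name: str, genes_spec, intergenic: int = 200, seed: int = 7,
                sub_genome: str = "unknown") -> AnnotatedRegion:
    """Assemble a small annotated region from (function, cds, n_exons,
    strand) gene specs, splitting each CDS into equal-ish exons separated
    by fixed introns."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def rand(n):
        return rng.choice(bases, size=n).tobytes().decode()

    seq_parts = []
    genes = []
    pos = 0
    for gi, (function, cds, n_exons, strand) in enumerate(genes_spec):
        filler = rand(intergenic)
        seq_parts.append(filler)
        pos += intergenic
        cut = len(cds) // n_exons
        pieces = [cds[k * cut:(k + 1) * cut] for k in range(n_exons - 1)]
        pieces.append(cds[(n_exons - 1) * cut:])
        intron = "GT" + rand(60) + "AG"
        layout = []
        off = 0
        parts = []
        for k, piece in enumerate(pieces):
            parts.append(piece)
            layout.append((off, off + len(piece) - 1))
            off += len(piece)
            if k < n_exons - 1:
                parts.append(intron)
                off += len(intron)
        block = "".join(parts)
        if strand == "-":
            comp = str.maketrans("ACGTN", "TGCAN")
            block = block.translate(comp)[::-1]
            L = len(block)
            layout = [(L - 1 - e, L - 1 - s) for s, e in reversed(layout)]
        exons = [(pos + s + 1, pos + e + 1) for s, e in layout]
        genes.append(GeneModel(id=f"{name}_g{gi + 1}", strand=strand,
                               exons=exons, function=function))
        seq_parts.append(block)
        pos += len(block)
    seq_parts.append(rand(intergenic))
    return AnnotatedRegion(name=name, sequence="".join(seq_parts), genes=genes,
                           sub_genome=sub_genome)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    from homoeolog.codon_evolution import SENSE_CODONS
    idx = rng.integers(0, 61, size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded region pair with one deleted gene, shared by tests."""
    params = SimParams(n_genes=6, target_gene_incidence=2500, seed=1234,
                       deletion_spec=DeletionSpec(genes=["g003"]))
    return simulate_pair(params)
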