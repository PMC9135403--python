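import numpy as np
import pytest

from rmesim import AlleleModel, GeneModel, GenotypeConfig


def make_gene(gene_id: str, p1: float, p2: float) -> GeneModel:
    a1 = AlleleModel(f"{gene_id}.a1", p1,
                     allele_class="knockout" if p1 == 0 else "wildtype")
    a2 = AlleleModel(f"{gene_id}.a2", p2,
                     allele_class="knockout" if p2 == 0 else "wildtype")
    return GeneModel(gene_id=gene_id, alleles=(a1, a2))


def make_genotype(label: str, **gene_probs: tuple[float, float]) -> GenotypeConfig:
    genes = tuple(make_gene(g, p1, p2) for g, (p1, p2) in gene_probs.items())
    return GenotypeConfig(genes=genes, label=label)


@pytest.fixture
def het_genotype() -> GenotypeConfig:
    """F1-hybrid-like heterozygote: both alleles functional at p = 0.31."""
    return make_genotype("het", Klra7=(0.31, 0.31))


@pytest.fixture
def hemi_genotype() -> GenotypeConfig:
    """Hemizygote: one functional allele, one null."""
    return make_genotype("hemi", Klrk1=(0.4255, 0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
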