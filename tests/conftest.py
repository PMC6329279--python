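import numpy as np
import pytest

from exprembed.model import EmbeddingConfig, EmbeddingModel


def build_model(G, S, b_gene=None, b_sample=None, gene_ids=None, sample_ids=None):
    """Assemble an EmbeddingModel directly from arrays (test helper)."""
    G = np.asarray(G, dtype=float)
    S = np.asarray(S, dtype=float)
    k, m = G.shape
    n = S.shape[0]
    return EmbeddingModel(
        gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(k)],
        sample_ids=sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
        G=G,
        S=S,
        b_gene=np.zeros(k) if b_gene is None else np.asarray(b_gene, dtype=float),
        b_sample=np.zeros(n) if b_sample is None else np.asarray(b_sample, dtype=float),
        config=EmbeddingConfig(dim=m),
    )


def random_model(rng, n_samples, n_genes, dim, scale=1.0):
    return build_model(
        G=rng.normal(0, scale, (n_genes, dim)),
        S=rng.normal(0, scale, (n_samples, dim)),
        b_gene=rng.normal(0, scale, n_genes),
        b_sample=rng.normal(0, scale, n_samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
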