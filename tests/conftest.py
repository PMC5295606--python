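import numpy as np
import pytest

from netgi import FunctionalNetwork, InteractionRecord


def make_random_network(rng, n_genes=60, n_edges=150, quantize=None):
    """Random weighted network; ``quantize`` rounds weights to force ties."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    net = FunctionalNetwork()
    for g in genes:
        net.add_gene(g)
    seen = set()
    while len(seen) < n_edges:
        i, j = rng.integers(n_genes, size=2)
        if i == j:
            continue
        pair = (min(i, j), max(i, j))
        if pair in seen:
            continue
        seen.add(pair)
        w = float(rng.uniform(0, 5))
        if quantize:
            w = round(w / quantize) * quantize
        net.add_edge(genes[pair[0]], genes[pair[1]], w)
    return net, genes


def make_random_records(rng, genes, n=50, types=("Synthetic Lethality", "Negative Genetic")):
    recs = []
    while len(recs) < n:
        i, j = rng.integers(len(genes), size=2)
        if i == j:
            continue
        recs.append(
            InteractionRecord(
                genes[i], genes[j],
                interaction_type=types[int(rng.integers(len(types)))],
                organism="test",
                year=int(rng.integers(1990, 2020)),
            )
        )
    return recs


def pairwise_auc_oracle(scores, labels):
    """Exhaustive positive x negative comparison; ties count 1/2."""
    genes = list(labels)
    pos = np.array([scores[g] for g in genes if labels[g] == 1])
    neg = np.array([scores[g] for g in genes if labels[g] == 0])
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean()


@pytest.fixture
def rng():
    return np.random.default_rng(20160)
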