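import dendropy
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_sample():
    """A 20-tree monophyly posterior sample over the default 4 species."""
    from tspscan import ScenarioConfig, simulate_posterior_sample

    cfg = ScenarioConfig(scenario="monophyly", epsilon=0.0, n_trees=20, seed=11)
    sample, truth = simulate_posterior_sample(cfg)
    return sample, truth


@pytest.fixture
def divergent_alignment():
    """A 6-sequence alignment with sister-pair structure, plus its tree."""
    from tspscan import simulate_alignment

    tree = "((D:0.05,Dp:0.05):0.15,((A:0.05,Ap:0.05):0.15,(O1:0.15,O2:0.15):0.05):0.02)"
    aln, truth = simulate_alignment(tree, 300, seed=3)
    return aln, tree


def tree_from_newick(nwk: str, ns=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=nwk if nwk.endswith(";") else nwk + ";",
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=ns,
    )


def sample_from_newicks(newicks):
    """Build a TreeSample from newick strings sharing one namespace."""
    from tspscan import TreeSample

    ns = dendropy.TaxonNamespace()
    trees = [tree_from_newick(n, ns) for n in newicks]
    return TreeSample(trees=trees, provenance=[("fix", i) for i in range(len(trees))])


def random_newick(labels, rng: np.random.Generator) -> str:
    """Uniform-ish random binary topology with unit branch lengths."""
    items = [f"{lab}:1" for lab in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        items.append(f"({a},{b}):1")
    return items[0] + ";"
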