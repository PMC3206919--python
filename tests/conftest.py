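import dendropy
import numpy as np
import pytest

import mitopart as mp


@pytest.fixture
def small_alignment():
    return mp.Alignment.from_strings(
        ["taxA", "taxB", "taxC"],
        ["ACGTACGTACGT", "ACGTACGAACGT", "ACGAACGTACGA"],
    )


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def balanced_tree():
    """Ultrametric 8-taxon tree with comfortably resolvable branches (My)."""
    return make_tree(
        "(((a:0.5,b:0.5):1.0,(c:0.5,d:0.5):1.0):0.5,"
        "((e:0.5,f:0.5):1.0,(g:0.5,h:0.5):1.0):0.5);"
    )


@pytest.fixture(scope="session")
def strong_study():
    """Shared small synthetic posterior with strong signal.

    Fixed 8-taxon ultrametric tree, strict-ish clock at a mitochondrial-like
    rate scaled so 4000 sites resolve every clade.
    """
    tree = dendropy.Tree.get(
        data=(
            "(((a:0.5,b:0.5):1.0,(c:0.5,d:0.5):1.0):0.5,"
            "((e:0.5,f:0.5):1.0,(g:0.5,h:0.5):1.0):0.5);"
        ),
        schema="newick",
    )
    rated = mp.assign_ucln_rates(tree, clock_mean=0.02, clock_cov=0.2, seed=101)
    aln = mp.simulate_alignment(
        rated, mp.SubstModel(kind="JC69"), length=4000, seed=102
    )
    ensemble, trace = mp.emulate_posterior(
        aln, rated, ensemble_size=200, seed=103,
        clock_mean=0.02, clock_cov=0.2,
        node_names={"root": frozenset("abcdefgh") - frozenset()},
    )
    return {
        "tree": tree,
        "rated": rated,
        "alignment": aln,
        "ensemble": ensemble,
        "trace": trace,
    }
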