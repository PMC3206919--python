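"""Synthetic study generator: every input the pipeline consumes, with truth.

The generator emulates the study design the pipeline targets: mitogenome
haplotypes of closely related lineages (My-scale root ages), per-gene
alignments evolved under nucleotide models with gene-specific rates, an
uncorrelated-lognormal (UCLN) relaxed clock, posterior tree ensembles with
controllable clade support, and node-age posterior samples with a plantable
log-scale bias.

Posterior ensembles are *emulated*, not sampled by MCMC: topologies come from
a nonparametric bootstrap of alignment columns followed by NJ on JC69
distances, so clade frequencies track signal strength the way posterior
clade probabilities do; node ages are lognormal jitters around the true
ages. This reproduces the statistical shape every downstream summary needs
(controllable support, ages, trace scalars) without any pretense of matching
a specific sampler's posterior.

All generators are deterministic for a fixed seed; one study seed fans out to
per-component child seeds through ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .alignment import Alignment, GeneAnnotation, write_annotations
from .distances import distance_matrix, nj_tree
from .likelihood import SubstModel, log_likelihood
from .stats import TraceLog, write_trace
from .trees import TreeEnsemble, node_ages

_STATES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: name, length (nt), model kind, relative rate."""

    name: str
    length: int
    model: SubstModel
    relative_rate: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Defaults describe a desk-scale mitogenome haplotype study: a dozen
    lineages radiating within a few My, a clock near typical mitochondrial
    rates, and moderate among-branch rate variation.
    """

    n_taxa: int = 12
    birth_rate: float = 1.0  # 1/My
    root_age: float = 2.0  # My
    clock_mean: float = 2.6e-3  # substitutions/site/My
    clock_cov: float = 0.5
    gene_specs: tuple[GeneSpec, ...] = ()
    ensemble_size: int = 500
    seed: int = 0


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_yule(
    n_taxa: int, birth_rate: float, root_age: float, seed: int
) -> dendropy.Tree:
    """Ultrametric pure-birth tree conditioned on ``n_taxa``, root at ``root_age``.

    The process starts at the root with two lineages; while k lineages exist
    a uniformly chosen one splits after an Exp(k * birth_rate) wait. After the
    n-th lineage appears, one further Exp(n * birth_rate) wait separates the
    last split from the present, and all node times are rescaled so the root
    sits exactly at ``root_age`` (tips at 0).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)

    # Each active lineage is a node whose subtree is still a single tip.
    root = tree.seed_node
    active = []
    t = 0.0
    split_time = {id(root): 0.0}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    k = 2
    while k < n_taxa:
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(0, len(active))
        node = active.pop(idx)
        split_time[id(node)] = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
        k += 1
    t_present = t + rng.exponential(1.0 / (k * birth_rate))

    scale = root_age / t_present
    # Assign taxa to tips in namespace order for determinism.
    tips = [n for n in tree.leaf_node_iter()]
    for taxon, tip in zip(ns, tips):
        tip.taxon = taxon
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        start = split_time[id(node.parent_node)]
        end = split_time.get(id(node), t_present)
        node.edge.length = (end - start) * scale
    return tree


def assign_ucln_rates(
    tree: dendropy.Tree, clock_mean: float, clock_cov: float, seed: int
) -> dendropy.Tree:
    """Draw iid lognormal branch rates with real-space mean and CoV as given.

    ``clock_cov = 0`` degenerates to the strict clock. Rates are stored on
    each edge as ``edge.rate`` and are independent of branch lengths.
    """
    if clock_mean <= 0:
        raise ValueError("clock_mean must be positive")
    if clock_cov < 0:
        raise ValueError("clock_cov must be nonnegative")
    rng = np.random.default_rng(seed)
    if clock_cov == 0:
        sigma2 = 0.0
    else:
        sigma2 = np.log1p(clock_cov**2)
    mu = np.log(clock_mean) - sigma2 / 2
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        edge.rate = float(np.exp(mu + np.sqrt(sigma2) * rng.standard_normal())) \
            if sigma2 > 0 else clock_mean
    return out


def branch_rates(tree: dendropy.Tree) -> list[float]:
    return [
        e.rate
        for e in tree.preorder_edge_iter()
        if e.head_node.parent_node is not None and hasattr(e, "rate")
    ]


def simulate_alignment(
    tree: dendropy.Tree, model: SubstModel, length: int, seed: int
) -> Alignment:
    """Evolve sequences down a tree carrying UCLN branch rates.

    Root states are drawn from the model's base frequencies; along each
    branch the expected number of substitutions per site is branch time x
    branch rate x site-category rate, with the gamma/invariant mixture drawn
    once per site.
    """
    from .likelihood import _transition_matrix

    rng = np.random.default_rng(seed)
    pi = np.asarray(model.base_freqs)
    if model.kind in {"JC69", "K80"}:
        pi = np.full(4, 0.25)
    Q = model.rate_matrix()
    rates, weights = model.site_rates()
    site_cat = rng.choice(len(rates), size=length, p=weights)

    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(4, size=length, p=pi)
    }
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rate = getattr(node.edge, "rate", 1.0)
        d = (node.edge.length or 0.0) * rate
        parent = states[id(node.parent_node)]
        child = parent.copy()
        for c, r in enumerate(rates):
            mask = site_cat == c
            if not mask.any():
                continue
            if d * r <= 0:
                continue
            P = _transition_matrix(Q, pi, d * r)
            sub = parent[mask]
            u = rng.random(sub.shape[0])
            cdf = np.cumsum(P[sub], axis=1)
            child[mask] = (u[:, None] > cdf).sum(axis=1)
        states[id(node)] = child

    labels = []
    rows = []
    for leaf in tree.leaf_node_iter():
        labels.append(leaf.taxon.label)
        rows.append("".join(_STATES[states[id(leaf)]]))
    return Alignment.from_strings(labels, rows)


def _make_ultrametric(
    tree: dendropy.Tree,
    true_ages: dict[frozenset[str], float],
    age_log_sd: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Assign heights to a (possibly conflicting) topology.

    Clades shared with the true tree get the true age jittered lognormally
    (multiplied by exp(N(0, age_log_sd))); novel clades sit just above their
    tallest child. Monotonicity root-to-leaf is enforced.
    """
    out = tree.clone(depth=1)
    out.is_rooted = True
    age_of: dict[int, float] = {}
    below: dict[int, frozenset[str]] = {}
    root_age = max(true_ages.values())
    for node in out.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            age_of[id(node)] = 0.0
            continue
        s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = s
        child_max = max(age_of[id(c)] for c in node.child_nodes())
        if s in true_ages:
            age = true_ages[s] * float(
                np.exp(age_log_sd * rng.standard_normal())
            )
        else:
            age = child_max + 0.05 * root_age
        age_of[id(node)] = max(age, child_max * 1.01 + 1e-9)
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age_of[id(node.parent_node)] - age_of[id(node)]
    return out


def _root_like(tree: dendropy.Tree, outgroup: frozenset[str]) -> dendropy.Tree:
    """Root an unrooted sample tree compatibly with the true root split.

    If the true root's smaller child clade is present in the sample, the root
    goes on its subtending edge (so rooted clade support tracks topological
    signal rather than rooting noise); otherwise midpoint rooting is used.
    Zero-length trees (degenerate bootstrap replicates) are left on their
    arbitrary basal node.
    """
    t = tree.clone(depth=1)
    all_leaves = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    complement = all_leaves - outgroup
    target = None
    below: dict[int, frozenset[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
        if below[id(node)] in (outgroup, complement) and \
                node.parent_node is not None:
            target = node
    if target is not None:
        length = target.edge.length or 0.0
        t.reroot_at_edge(
            target.edge, length1=length / 2, length2=length / 2,
            update_bipartitions=False,
        )
    elif t.length() > 0:
        t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def emulate_posterior(
    aln: Alignment,
    true_tree: dendropy.Tree,
    ensemble_size: int = 500,
    age_log_sd: float = 0.1,
    seed: int = 0,
    clock_mean: float = 2.6e-3,
    clock_cov: float = 0.5,
    node_names: dict[str, frozenset[str]] | None = None,
) -> tuple[TreeEnsemble, TraceLog]:
    """Emulated posterior: bootstrap+NJ topologies with jittered node ages.

    Each sample bootstraps alignment columns, builds an NJ tree on JC69
    distances, midpoint-roots it, and turns it ultrametric with node ages
    jittered lognormally (sd ``age_log_sd`` on the log scale) around the true
    tree's ages for shared clades. The trace log carries the state index, a
    posterior-density scalar (the sample's data log-likelihood under JC69 on
    the sampled tree, branch lengths in substitutions/site via
    ``clock_mean``), a likelihood column (same scalar), a mean branch rate,
    its coefficient of variation, and one age column per named node.
    """
    if ensemble_size < 100:
        raise ValueError("ensemble_size must be at least 100")
    rng_boot, rng_age, rng_rate = _spawn(seed, 3)
    true_ages = node_ages(true_tree)
    root_children = [
        frozenset(lf.taxon.label for lf in c.leaf_iter())
        for c in true_tree.seed_node.child_nodes()
    ]
    outgroup = min(root_children, key=lambda s: (len(s), sorted(s)))
    jc = SubstModel(kind="JC69")
    if node_names is None:
        node_names = {}

    trees: list[dendropy.Tree] = []
    posterior: list[float] = []
    age_cols: dict[str, list[float]] = {name: [] for name in node_names}
    mean_rates: list[float] = []
    rate_covs: list[float] = []

    sigma2 = np.log1p(clock_cov**2) if clock_cov > 0 else 0.0
    mu = np.log(clock_mean) - sigma2 / 2
    n_branch = sum(
        1 for e in true_tree.preorder_edge_iter()
        if e.head_node.parent_node is not None
    )

    for _ in range(ensemble_size):
        cols = rng_boot.integers(0, aln.n_sites, size=aln.n_sites)
        boot = Alignment(aln.taxon_labels, aln.matrix[:, cols])
        dm = distance_matrix(boot, model="JC69")
        if not np.all(np.isfinite(dm.values)):
            raise ValueError("bootstrap pair saturated; shorten the tree")
        topo = _root_like(nj_tree(dm), outgroup)
        sample = _make_ultrametric(topo, true_ages, age_log_sd, rng_age)
        trees.append(sample)

        sample_ages = node_ages(sample)

        def clade_age(taxa: frozenset[str]) -> float:
            # age of the MRCA of the named taxa in this sample
            best = None
            for clade, age in sample_ages.items():
                if taxa <= clade and (best is None or len(clade) < best[0]):
                    best = (len(clade), age)
            return best[1] if best else max(sample_ages.values())

        for name, taxa in node_names.items():
            age_cols[name].append(clade_age(taxa))

        # posterior scalar: JC69 data log-likelihood on the sampled tree
        subs = sample.clone(depth=1)
        for e in subs.preorder_edge_iter():
            if e.head_node.parent_node is not None:
                e.length = (e.length or 0.0) * clock_mean
        posterior.append(log_likelihood(aln, subs, jc))

        draws = (
            np.exp(mu + np.sqrt(sigma2) * rng_rate.standard_normal(n_branch))
            if sigma2 > 0
            else np.full(n_branch, clock_mean)
        )
        mean_rates.append(float(draws.mean()))
        rate_covs.append(
            float(draws.std(ddof=1) / draws.mean()) if sigma2 > 0 else 0.0
        )

    columns: dict[str, Sequence[float]] = {
        "posterior": posterior,
        "likelihood": posterior,
        "meanRate": mean_rates,
        "coefficientOfVariation": rate_covs,
    }
    for name, ages in age_cols.items():
        columns[f"age_{name}"] = ages
    trace = TraceLog(list(range(ensemble_size)), columns)
    ensemble = TreeEnsemble(trees, posterior=posterior, log_likelihood=posterior)
    return ensemble, trace


def simulate_tmrca(
    mu: float, sigma: float, delta: float, n: int, seed: int
) -> np.ndarray:
    """n draws from LogNormal(mu + delta, sigma): a node-age posterior with
    a planted log-scale shift ``delta`` relative to the reference."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 100:
        raise ValueError("need n >= 100")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu + delta, sigma, size=n)


def default_gene_specs() -> tuple[GeneSpec, ...]:
    """Eight coding genes, 600 nt each, HKY with gene-specific relative rates.

    Relative rates span the spread observed across mitochondrial coding
    genes (roughly 4x between slowest and fastest).
    """
    freqs = (0.32, 0.28, 0.13, 0.27)  # typical mtDNA light-strand bias
    rates = [0.5, 0.7, 0.9, 1.0, 1.1, 1.3, 1.6, 2.0]
    return tuple(
        GeneSpec(
            name=f"gene{i + 1}",
            length=600,
            model=SubstModel(kind="HKY", kappa=8.0, base_freqs=freqs),
            relative_rate=r,
        )
        for i, r in enumerate(rates)
    )


def simulate_study(config: SimConfig | None = None) -> dict:
    """Generate a full synthetic study in memory.

    Returns a dict with the true tree (with UCLN rates), per-gene alignments,
    the concatenated "mitogenome" alignment with its annotation table, and
    the per-gene posterior emulations (ensemble + trace).
    """
    from .alignment import concatenate

    cfg = config or SimConfig(gene_specs=default_gene_specs())
    specs = cfg.gene_specs or default_gene_specs()
    rngs = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_tree, seed_rates, seed_genes, seed_post = (
        int(s.generate_state(1)[0] % (2**31)) for s in rngs
    )

    tree = simulate_yule(cfg.n_taxa, cfg.birth_rate, cfg.root_age, seed_tree)
    rated = assign_ucln_rates(tree, cfg.clock_mean, cfg.clock_cov, seed_rates)

    gene_alns: dict[str, Alignment] = {}
    annotations: list[GeneAnnotation] = []
    offset = 0
    for i, spec in enumerate(specs):
        scaled = rated.clone(depth=1)
        for e_scaled, e_src in zip(
            scaled.preorder_edge_iter(), rated.preorder_edge_iter()
        ):
            if e_src.head_node.parent_node is not None:
                e_scaled.rate = e_src.rate * spec.relative_rate
        gene_alns[spec.name] = simulate_alignment(
            scaled, spec.model, spec.length, seed_genes + i
        )
        annotations.append(
            GeneAnnotation(
                name=spec.name,
                start=offset + 1,
                end=offset + spec.length,
                strand="+",
                coding=True,
                reading_frame_offset=0,
            )
        )
        offset += spec.length

    names = [s.name for s in specs]
    mito, scheme = concatenate([gene_alns[n] for n in names], names)

    node_names = {
        f"n{i + 1}": clade
        for i, clade in enumerate(sorted(node_ages(tree), key=len))
    }

    posteriors: dict[str, tuple[TreeEnsemble, TraceLog]] = {}
    targets = list(names) + ["mitogenome"]
    for j, name in enumerate(targets):
        aln = mito if name == "mitogenome" else gene_alns[name]
        posteriors[name] = emulate_posterior(
            aln,
            rated,
            ensemble_size=cfg.ensemble_size,
            seed=seed_post + j,
            clock_mean=cfg.clock_mean,
            clock_cov=cfg.clock_cov,
            node_names=node_names,
        )

    return {
        "config": cfg,
        "true_tree": rated,
        "gene_alignments": gene_alns,
        "mitogenome": mito,
        "scheme": scheme,
        "annotations": annotations,
        "node_names": node_names,
        "posteriors": posteriors,
    }


def write_study_folder(study: dict, outdir: str | Path) -> None:
    """Write a study dict as the on-disk folder the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study["mitogenome"].to_fasta(out / "mitogenome.fasta")
    for name, aln in study["gene_alignments"].items():
        aln.to_fasta(out / f"{name}.fasta")
    write_annotations(study["annotations"], out / "annotations.tsv")
    (out / "scheme.partitions").write_text(study["scheme"].to_raxml())
    study["true_tree"].write(
        path=str(out / "true_tree.nwk"), schema="newick",
        suppress_rooting=True,
    )
    for name, (ensemble, trace) in study["posteriors"].items():
        tl = dendropy.TreeList(ensemble.trees)
        tl.write(path=str(out / f"{name}.trees.nex"), schema="nexus")
        write_trace(trace, out / f"{name}.log", comment=f"partition {name}")
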