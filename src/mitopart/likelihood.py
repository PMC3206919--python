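"""Felsenstein-pruning likelihoods and BIC model selection for nucleotides.

The model space is {JC69, K80, HKY, GTR} x {plain, +I, +G, +I+G}, which
covers the models a mitochondrial dataset of this kind realistically selects.
Rate matrices are scaled to one expected substitution per site per unit
branch length; among-site rate variation uses the discrete-gamma
approximation with 4 equal-probability categories represented by their means,
and invariant sites add a zero-rate class with the remaining categories
rescaled so the mixture mean stays 1.

Fitting optimizes the free model parameters plus a single branch-length
multiplier on a fixed guide tree (NJ on JC69 distances by default); per-branch
optimization is deliberately out of scope — model *ranking* is robust to
guide-tree detail, which is all the selection stage needs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import Alignment
from .errors import FitError

KAPPA_CAP = 1e4

_STATES = "ACGT"
# IUPAC codes -> allowed-state masks; gaps and unknowns are fully ambiguous.
_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", ".": "ACGT", "?": "ACGT",
}
_MASKS = {
    code: np.array([1.0 if s in allowed else 0.0 for s in _STATES])
    for code, allowed in _AMBIG.items()
}


@dataclass(frozen=True)
class SubstModel:
    """A nucleotide substitution model, optionally with +I / +G mixtures."""

    kind: str  # JC69 | K80 | HKY | GTR
    kappa: float | None = None
    exchangeabilities: tuple[float, ...] | None = None  # AC,AG,AT,CG,CT,GT; GT=1
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    p_invariant: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"JC69", "K80", "HKY", "GTR"}:
            raise FitError(f"unknown model kind: {self.kind!r}")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise FitError("base frequencies must sum to 1")
        if self.kind in {"K80", "HKY"} and self.kappa is None:
            raise FitError(f"{self.kind} requires kappa")
        if self.kind == "GTR" and self.exchangeabilities is None:
            raise FitError("GTR requires exchangeabilities")
        if self.p_invariant is not None and not 0 <= self.p_invariant < 1:
            raise FitError("p_invariant must be in [0, 1)")

    @property
    def label(self) -> str:
        s = self.kind
        if self.p_invariant is not None:
            s += "+I"
        if self.gamma_shape is not None:
            s += "+G"
        return s

    def n_free_parameters(self) -> int:
        """Free model parameters (excluding the branch-scale multiplier)."""
        k = {"JC69": 0, "K80": 1, "HKY": 4, "GTR": 8}[self.kind]
        if self.gamma_shape is not None:
            k += 1
        if self.p_invariant is not None:
            k += 1
        return k

    def rate_matrix(self) -> np.ndarray:
        """4x4 rate matrix scaled to mean rate 1."""
        pi = np.asarray(self.base_freqs)
        if self.kind == "JC69":
            ex = np.ones(6)
            pi = np.full(4, 0.25)
        elif self.kind == "K80":
            # transitions: AG (index 1) and CT (index 4)
            ex = np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
            pi = np.full(4, 0.25)
        elif self.kind == "HKY":
            ex = np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        else:
            ex = np.asarray(self.exchangeabilities, dtype=float)
        # order of pairs: AC, AG, AT, CG, CT, GT
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(ex, pairs):
            Q[i, j] = r * pi[j]
            Q[j, i] = r * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(np.dot(pi, np.diag(Q)))
        return Q / mean_rate

    def site_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the among-site rate mixture, mean rate 1."""
        p_inv = self.p_invariant or 0.0
        if self.gamma_shape is not None:
            cats = discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
        else:
            cats = np.array([1.0])
        k = len(cats)
        if p_inv > 0:
            rates = np.concatenate(([0.0], cats / (1.0 - p_inv)))
            weights = np.concatenate(([p_inv], np.full(k, (1 - p_inv) / k)))
        else:
            rates = cats
            weights = np.full(k, 1.0 / k)
        return rates, weights


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability discrete-gamma categories (mean 1)."""
    if shape <= 0:
        raise FitError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    # mean of Gamma(a, rate=a) over (lo, hi), times k (bin mass 1/k)
    upper = gammainc(shape + 1, shape * edges[1:])
    lower = gammainc(shape + 1, shape * edges[:-1])
    return k * (upper - lower)


@dataclass(frozen=True)
class ModelFit:
    model: SubstModel
    lnL: float
    k: int
    n: int
    bic: float
    branch_scale: float = 1.0
    warnings: tuple[str, ...] = ()


def bic(lnL: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, -2 lnL + k ln n."""
    return -2.0 * lnL + k * math.log(n)


def empirical_base_freqs(aln: Alignment) -> tuple[float, float, float, float]:
    counts = np.array([(aln.matrix == s).sum() for s in _STATES], dtype=float)
    if counts.sum() == 0:
        raise FitError("no unambiguous bases in alignment")
    freqs = counts / counts.sum()
    return tuple(freqs)  # type: ignore[return-value]


def _compress_patterns(
    aln: Alignment, taxa: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Unique site columns (restricted to ``taxa``) and their counts."""
    rows = [aln.matrix[aln.taxon_labels.index(t)] for t in taxa]
    cols = np.stack(rows, axis=0).T  # (n_sites, n_taxa)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts.astype(float)


class _Eigen:
    """Cached symmetric eigendecomposition of a reversible rate matrix.

    With D = diag(pi), B = D^(1/2) Q D^(-1/2) is symmetric for reversible Q;
    P(t) = L exp(w t) R with L = D^(-1/2) U and R = U^T D^(1/2).
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray) -> None:
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2)
        self.w = w
        self.L = U / d[:, None]
        self.R = U.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.L * np.exp(self.w * t)) @ self.R
        return np.clip(P, 0.0, None)


def _transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the symmetric eigendecomposition of a reversible Q."""
    return _Eigen(Q, pi).transition_matrix(t)


def log_likelihood(
    aln: Alignment, tree: dendropy.Tree, model: SubstModel
) -> float:
    """Pruning log-likelihood of the alignment on a fixed tree.

    Branch lengths are in expected substitutions per site. Gaps and IUPAC
    ambiguities are treated as missing data (partial likelihood 1 over all
    compatible states). Discrete-gamma and invariant-site mixtures are summed
    per site. Per-node rescaling keeps partials in range, so the result is
    finite for any usable input.
    """
    if aln.n_sites == 0:
        raise FitError("empty alignment")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(leaves) - set(aln.taxon_labels)
    if missing:
        raise FitError(f"tree leaves not in alignment: {sorted(missing)}")
    patterns, counts = _compress_patterns(aln, leaves)
    leaf_index = {t: i for i, t in enumerate(leaves)}
    npat = patterns.shape[0]

    pi = np.asarray(model.base_freqs)
    if model.kind in {"JC69", "K80"}:
        pi = np.full(4, 0.25)
    Q = model.rate_matrix()
    rates, weights = model.site_rates()

    tip_partials = {
        t: np.stack([_MASKS.get(patterns[p, i], _MASKS["N"])
                     for p in range(npat)])
        for t, i in leaf_index.items()
    }

    eigen = _Eigen(Q, pi)
    site_like = np.zeros(npat)
    cat_contrib = []
    for rate, weight in zip(rates, weights):
        partial, log_scale = _prune(tree, tip_partials, eigen, rate)
        cat_contrib.append((weight, partial @ pi, log_scale))
    # combine categories on a common log scale per pattern
    max_scale = np.max([c[2] for c in cat_contrib], axis=0)
    for weight, like, log_scale in cat_contrib:
        site_like += weight * like * np.exp(log_scale - max_scale)
    if np.any(site_like <= 0):
        raise FitError("non-finite site likelihood")
    lnL = float(np.dot(counts, np.log(site_like) + max_scale))
    if not math.isfinite(lnL):
        raise FitError("non-finite log-likelihood")
    return lnL


def _prune(
    tree: dendropy.Tree,
    tip_partials: dict[str, np.ndarray],
    eigen: _Eigen,
    rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Postorder pruning pass for one rate category, with rescaling."""
    partials: dict[int, np.ndarray] = {}
    log_scale: dict[int, np.ndarray] = {}
    npat = next(iter(tip_partials.values())).shape[0]
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = tip_partials[node.taxon.label]
            log_scale[id(node)] = np.zeros(npat)
            continue
        acc = np.ones((npat, 4))
        scale = np.zeros(npat)
        for child in node.child_nodes():
            b = (child.edge.length or 0.0) * rate
            P = eigen.transition_matrix(b) if b > 0 else np.eye(4)
            acc = acc * (partials[id(child)] @ P.T)
            scale = scale + log_scale[id(child)]
        m = acc.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        partials[id(node)] = acc / m[:, None]
        log_scale[id(node)] = scale + np.log(m)
    root = tree.seed_node
    return partials[id(root)], log_scale[id(root)]


_CANDIDATE_SPACE = [
    (kind, flags)
    for kind in ("JC69", "K80", "HKY", "GTR")
    for flags in ("", "+I", "+G", "+I+G")
]


def candidate_models() -> list[tuple[str, str]]:
    """The 16 (kind, flags) combinations in the default model space."""
    return list(_CANDIDATE_SPACE)


def _build_model(
    kind: str,
    flags: str,
    freqs: tuple[float, float, float, float],
    kappa: float = 2.0,
    exch: tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
    shape: float = 0.5,
    p_inv: float = 0.1,
) -> SubstModel:
    return SubstModel(
        kind=kind,
        kappa=kappa if kind in {"K80", "HKY"} else None,
        exchangeabilities=exch if kind == "GTR" else None,
        base_freqs=freqs if kind in {"HKY", "GTR"} else (0.25,) * 4,
        gamma_shape=shape if "+G" in flags else None,
        p_invariant=p_inv if "+I" in flags else None,
    )


def fit_model(
    aln: Alignment,
    guide: dendropy.Tree,
    kind: str,
    flags: str = "",
    n_override: int | None = None,
    max_restarts: int = 3,
) -> ModelFit:
    """Optimize a model's free parameters (and one branch-scale) by ML.

    Base frequencies are empirical. The optimizer is bounded L-BFGS-B on
    log-transformed parameters with up to ``max_restarts`` spread starting
    points; kappa is capped at 1e4 and a warning is recorded when the cap
    binds. ``n_override`` substitutes the BIC sample size (the default is the
    number of alignment sites).
    """
    freqs = empirical_base_freqs(aln)
    fit_warnings: list[str] = []

    names: list[str] = ["scale"]
    if kind in {"K80", "HKY"}:
        names.append("kappa")
    if kind == "GTR":
        names += [f"ex{i}" for i in range(5)]  # GT fixed to 1
    if "+G" in flags:
        names.append("shape")
    if "+I" in flags:
        names.append("p_inv")

    bounds = []
    for nm in names:
        if nm == "scale":
            bounds.append((math.log(1e-4), math.log(1e3)))
        elif nm == "kappa":
            bounds.append((math.log(1e-4), math.log(KAPPA_CAP)))
        elif nm.startswith("ex"):
            bounds.append((math.log(1e-4), math.log(1e3)))
        elif nm == "shape":
            bounds.append((math.log(1e-2), math.log(1e2)))
        else:  # p_inv, logit-free: optimize raw in (1e-6, 0.95)
            bounds.append((math.log(1e-6), math.log(0.95)))

    work = guide.clone(depth=1)
    base_lengths = [e.length or 0.0 for e in work.preorder_edge_iter()]

    def unpack(x: np.ndarray) -> tuple[SubstModel, float]:
        vals = dict(zip(names, np.exp(x)))
        scale = vals["scale"]
        model = _build_model(
            kind,
            flags,
            freqs,
            kappa=vals.get("kappa", 2.0),
            exch=tuple(vals.get(f"ex{i}", 1.0) for i in range(5)) + (1.0,),
            shape=vals.get("shape", 0.5),
            p_inv=vals.get("p_inv", 0.1),
        )
        return model, scale

    def neg_lnL(x: np.ndarray) -> float:
        model, scale = unpack(x)
        for e, b in zip(work.preorder_edge_iter(), base_lengths):
            e.length = b * scale
        try:
            return -log_likelihood(aln, work, model)
        except FitError:
            return 1e12

    starts = []
    base = {"scale": 0.0, "kappa": math.log(2), "shape": math.log(0.5),
            "p_inv": math.log(0.1)}
    for spread in (0.0, 1.0, -1.0):
        starts.append(
            np.array([base.get(nm, 0.0) + spread for nm in names])
        )

    best = None
    for x0 in starts[: max(1, max_restarts)]:
        res = optimize.minimize(
            neg_lnL, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError(f"{kind}{flags}: optimizer failed to converge")

    model, scale = unpack(best.x)
    if model.kappa is not None and model.kappa > 0.99 * KAPPA_CAP:
        fit_warnings.append("kappa-at-bound")
        warnings.warn(
            f"{kind}{flags}: kappa hit its upper bound ({KAPPA_CAP:g}); "
            "transition/transversion ratio is effectively unidentifiable",
            stacklevel=2,
        )
    lnL = -float(best.fun)
    k = model.n_free_parameters() + 1  # + the branch-scale multiplier
    n = n_override if n_override is not None else aln.n_sites
    return ModelFit(
        model=model, lnL=lnL, k=k, n=n, bic=bic(lnL, k, n),
        branch_scale=scale, warnings=tuple(fit_warnings),
    )


def select_model(
    aln: Alignment,
    guide: dendropy.Tree,
    candidates: list[tuple[str, str]] | None = None,
    n_override: int | None = None,
) -> tuple[ModelFit, "pd.DataFrame"]:
    """Fit every candidate and return the minimum-BIC fit plus the ranking."""
    import pandas as pd

    if candidates is None:
        candidates = candidate_models()
    if not candidates:
        raise FitError("no candidate models")
    fits: list[ModelFit] = []
    failures: list[str] = []
    for kind, flags in candidates:
        try:
            fits.append(fit_model(aln, guide, kind, flags, n_override))
        except FitError as exc:
            failures.append(f"{kind}{flags}: {exc}")
    if not fits:
        raise FitError("all candidate models failed: " + "; ".join(failures))
    fits.sort(key=lambda f: f.bic)
    best = fits[0]
    report = pd.DataFrame(
        [
            {
                "model": f.model.label,
                "lnL": f.lnL,
                "k": f.k,
                "n": f.n,
                "BIC": f.bic,
                "delta_BIC": f.bic - best.bic,
                "warnings": ";".join(f.warnings),
            }
            for f in fits
        ]
    )
    return best, report
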