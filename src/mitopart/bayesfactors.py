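"""Harmonic-mean marginal likelihoods and Bayes factors between partitionings.

The harmonic-mean estimator of the log marginal likelihood is
``ln N - logsumexp(-l_i)`` over post-burn-in log-likelihood samples. It is
known to be unstable and to lean towards richer parameterizations; that
caveat is carried in the estimate's metadata rather than corrected, because
the comparison being reproduced used exactly this estimator. All arithmetic
is done in log space so traces near -2e4 do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

DEFAULT_BOOTSTRAP_REPS = 1000


@dataclass(frozen=True)
class MarginalEstimate:
    """Log marginal likelihood with optional bootstrap standard error."""

    ln_marginal: float
    n_samples: int
    bootstrap_se: float | None = None
    reps: int | None = None
    note: str = (
        "harmonic-mean estimator; upward-unstable and known to favor "
        "models with more parameters"
    )


def harmonic_mean_lnL(loglik) -> float:
    """Log of the harmonic mean of likelihoods, from log-likelihood samples.

    Burn-in removal is the caller's duty (the shared 10% default); applying
    it here too would remove it twice.
    """
    ll = np.asarray(loglik, dtype=float)
    if len(ll) < 10:
        raise ValueError("need at least 10 likelihood samples")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood samples")
    return float(np.log(len(ll)) - logsumexp(-ll))


def ln_bayes_factor(m1: MarginalEstimate, m2: MarginalEstimate) -> float:
    """Natural-log Bayes factor of model 1 over model 2."""
    if not (np.isfinite(m1.ln_marginal) and np.isfinite(m2.ln_marginal)):
        raise ValueError("marginal estimates must be finite")
    return m1.ln_marginal - m2.ln_marginal


def bootstrap_se(
    samples,
    statistic: str = "harmonic_mean",
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a trace statistic.

    Resamples the full vector with replacement ``reps`` times (seeded) and
    returns the sd of the statistic across replicates.
    """
    if statistic != "harmonic_mean":
        raise ValueError(f"unknown statistic: {statistic!r}")
    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    x = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    n = len(x)
    for r in range(reps):
        vals[r] = harmonic_mean_lnL(x[rng.integers(0, n, size=n)])
    return float(vals.std(ddof=1))


def estimate_marginal(
    loglik,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> MarginalEstimate:
    """Harmonic-mean estimate plus its bootstrap SE in one call."""
    ll = np.asarray(loglik, dtype=float)
    return MarginalEstimate(
        ln_marginal=harmonic_mean_lnL(ll),
        n_samples=len(ll),
        bootstrap_se=bootstrap_se(ll, reps=reps, seed=seed),
        reps=reps,
    )
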