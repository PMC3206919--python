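"""MCMC trace statistics and divergence-time suitability analyses.

Covers the summaries a dating study reads off posterior traces: effective
sample size (ESS), highest-posterior-density (HPD) intervals, the coefficient
of among-branch rate variation, and the node-age comparisons used to judge
whether a data partition dates clades the way the whole mitogenome does:

* a lognormal *target* is fitted to the reference (whole-mitogenome) node-age
  sample on the natural-log scale;
* each observed node-age draw x gets q = Phi((ln x - mu) / sigma), its
  probability of lying above the target;
* the *bias* statistic is the fraction of draws with q strictly above 0.5
  (equivalently ln x > mu). 0.5 means unbiased, above 0.5 overestimation,
  below 0.5 underestimation.

Natural logs are used throughout; the fitted-normal construction makes the
bias value base-independent, but reported mu/sigma are in log-My (natural).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import TraceError


@dataclass(frozen=True)
class CalibrationPrior:
    """Lognormal node-age calibration: ln(age - offset) ~ N(log_mean, log_sd)."""

    name: str
    log_mean: float
    log_sd: float
    offset: float = 0.0
    clade: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    def _frozen(self) -> sps.rv_continuous:
        return sps.lognorm(
            s=self.log_sd, scale=math.exp(self.log_mean), loc=self.offset
        )

    def cdf(self, x: float) -> float:
        return float(self._frozen().cdf(x))

    def pdf(self, x: float) -> float:
        return float(self._frozen().pdf(x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.offset + rng.lognormal(self.log_mean, self.log_sd, size=n)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class BiasResult:
    """Per (node, partition) date-estimation bias summary."""

    node: str
    partition: str
    target_mu: float
    target_sigma: float
    bias: float
    median_tmrca: float
    hpd95: tuple[float, float]


class TraceLog:
    """Named columns of MCMC parameter samples with a state counter."""

    def __init__(self, states: Sequence[int], columns: Mapping[str, Sequence[float]]):
        states = list(states)
        if any(b <= a for a, b in zip(states, states[1:])):
            raise TraceError("state indices must be strictly increasing")
        for name, col in columns.items():
            if len(col) != len(states):
                raise TraceError(f"column {name!r} length mismatch")
        self.states = states
        self.columns = {k: np.asarray(v, dtype=float) for k, v in columns.items()}

    def __len__(self) -> int:
        return len(self.states)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.columns[name]
        except KeyError:
            raise TraceError(f"no trace column named {name!r}") from None

    def burnin(self, fraction: float = 0.10) -> "TraceLog":
        cut = int(fraction * len(self))
        return TraceLog(
            self.states[cut:], {k: v[cut:] for k, v in self.columns.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"state": self.states})
        for k, v in self.columns.items():
            df[k] = v
        return df


def read_trace(path: str | Path) -> TraceLog:
    """Read a tab-separated MCMC log (Tracer/BEAST dialect).

    Lines starting with ``#`` are comments; the first data line is the
    header and its first column the state counter.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceError(f"could not parse trace {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceError("trace needs a state column plus at least one parameter")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise TraceError(f"non-numeric values in column {col!r}")
    state_col = df.columns[0]
    return TraceLog(
        df[state_col].astype(int).tolist(),
        {c: df[c].to_numpy(float) for c in df.columns[1:]},
    )


def write_trace(trace: TraceLog, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        cols = list(trace.columns)
        fh.write("state\t" + "\t".join(cols) + "\n")
        for i, s in enumerate(trace.states):
            vals = "\t".join(repr(float(trace.columns[c][i])) for c in cols)
            fh.write(f"{s}\t{vals}\n")


def ess(x: Sequence[float]) -> float:
    """Effective sample size with initial-positive-sequence truncation.

    ESS = N / (1 + 2 * sum(rho_k)), summing sample autocorrelations until the
    first non-positive estimate. A constant trace reports ESS = N with a
    zero-variance warning.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise TraceError("need at least 10 samples for an ESS estimate")
    var = x.var()
    if var == 0:
        warnings.warn("zero-variance trace; ESS reported as N", stacklevel=2)
        return float(n)
    centered = x - x.mean()
    # FFT autocovariance, biased normalization (divide by n).
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(centered, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1 + 2 * s))


def hpd(x: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ``level`` mass.

    Endpoints are elements of ``x``; the interval contains
    ``ceil(level * N)`` points.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    k = int(math.ceil(level * n))
    widths = xs[k - 1 :] - xs[: n - k + 1]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + k - 1])


def rate_cov(rates: Sequence[float]) -> float:
    """Coefficient of rate variation: sd(rates) / mean(rates).

    Values near 0 indicate clock-like evolution; values well above 1 usually
    mean too few substitutions to inform branch rates. Sample sd (n-1).
    """
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    if len(r) < 2:
        raise ValueError("need at least 2 rates")
    return float(r.std(ddof=1) / r.mean())


def fit_log_target(target: Sequence[float]) -> tuple[float, float]:
    """Fit a normal to the natural logs of a node-age sample.

    Returns (mu, sigma), the moment fit on the log scale (identical to the
    lognormal MLE). A degenerate sample yields sigma = 0 with a warning.
    """
    t = np.asarray(target, dtype=float)
    if len(t) < 20:
        raise ValueError("need at least 20 samples to fit a target")
    if np.any(t <= 0):
        raise ValueError("node ages must be positive")
    logs = np.log(t)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=1))
    if sigma == 0:
        warnings.warn("degenerate target sample (zero log-scale spread)",
                      stacklevel=2)
    return mu, sigma


def tmrca_bias(observed: Sequence[float], target_fit: tuple[float, float]) -> float:
    """Fraction of observed node ages with probability > 0.5 of exceeding the target.

    For each observation x, q = Phi((ln x - mu) / sigma); the bias is the
    proportion with q strictly greater than 0.5, which reduces to the
    proportion with ln x > mu. Exactly 0.5 counts as not-over.
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("node ages must be positive")
    mu, sigma = target_fit
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        warnings.warn("sigma = 0 target; bias from ln x > mu only", stacklevel=2)
    return float(np.mean(np.log(obs) > mu))


def anova_log_tmrca(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA on log-transformed node-age samples.

    MCMC draws are treated as independent observations, as is conventional in
    this kind of comparison; the pseudo-replication caveat stands and p-values
    are best read as descriptive.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    logged = []
    for name, g in groups.items():
        arr = np.asarray(g, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs at least 2 samples")
        if np.any(arr <= 0):
            raise ValueError(f"group {name!r} has nonpositive ages")
        logged.append(np.log(arr))
    F, p = sps.f_oneway(*logged)
    k = len(logged)
    n = sum(len(g) for g in logged)
    return AnovaResult(
        F=float(F), df_between=k - 1, df_within=n - k, p_value=float(p)
    )


def prior_overlap(posterior: Sequence[float], prior: CalibrationPrior) -> float:
    """Mass of a removed calibration prior inside the posterior's 95% HPD.

    The cross-validation removes one fossil calibration, re-estimates the
    node's age from the remaining calibrations, and asks how much of the
    removed prior's area under the curve falls within the posterior 95% HPD
    interval. 1 means the prior is fully recoverable from the other
    calibrations; 0 means it conflicts with them.
    """
    post = np.asarray(posterior, dtype=float)
    if len(post) < 100:
        raise ValueError("need at least 100 posterior samples")
    lo, hi = hpd(post, 0.95)
    mass = prior.cdf(hi) - prior.cdf(lo)
    if mass < 0:
        warnings.warn("prior undefined over the HPD interval", stacklevel=2)
        return 0.0
    return float(mass)


def hpd_containment(posterior: Sequence[float], prior: CalibrationPrior,
                    level: float = 0.95) -> bool:
    """Alternative overlap check: is the prior's central 95% inside the HPD?"""
    lo, hi = hpd(posterior, level)
    frozen = sps.lognorm(
        s=prior.log_sd, scale=math.exp(prior.log_mean), loc=prior.offset
    )
    p_lo, p_hi = frozen.ppf([(1 - level) / 2, (1 + level) / 2])
    return bool(lo <= p_lo and p_hi <= hi)


def summarize_rate(rates: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and 95% HPD of a substitution-rate trace column."""
    r = np.asarray(rates, dtype=float)
    if len(r) < 20:
        raise ValueError("need at least 20 samples")
    return float(np.median(r)), hpd(r, 0.95)


def percent_excess(observed_median: float, reference_median: float) -> float:
    """Percent by which an observed median exceeds the reference median."""
    if reference_median <= 0:
        raise ValueError("reference median must be positive")
    return 100.0 * (observed_median - reference_median) / reference_median
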