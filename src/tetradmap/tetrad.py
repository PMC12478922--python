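"""Weinstein tetrad analysis: exchange-rank inference from chromatid classes.

In Drosophila female meiosis only one of the four chromatids of a bivalent is
recovered in each offspring, so the distribution of tetrad exchange ranks
(E_k = frequency of bivalents with exactly k exchanges) must be inferred from
the observed crossover classes of recovered chromatids.  Under no chromatid
interference each exchange involves one randomly chosen chromatid per
homolog, so a chromatid sampled from an E_k tetrad carries j crossovers with
probability C(k,j)/2^k.  Stacking these binomial kernels gives the forward
map

    p_j = sum_{k >= j} E_k * C(k, j) / 2^k,

an upper-triangular linear system.  Two estimators are provided:

* :func:`weinstein_direct` — the classical closed-form inversion of the
  triangular system at the empirical class frequencies.  It can return
  negative E_k (reported unclamped with ``feasible=False``).
* :func:`weinstein_mle` — constrained multinomial maximum likelihood on the
  simplex via expectation-maximization over the latent tetrad rank of each
  chromatid.  The M-step is closed-form and keeps the iterate on the simplex,
  so no projection is needed.  When the direct solution is feasible the model
  is saturated and the two estimators agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import comb

from .markers import ClassCounts

__all__ = [
    "ExchangeRanks",
    "ConvergenceError",
    "recovery_matrix",
    "class_probabilities",
    "weinstein_direct",
    "weinstein_mle",
    "total_map_length",
    "mean_exchanges",
    "multinomial_loglik",
    "bootstrap_exchange_ranks",
]


class ConvergenceError(RuntimeError):
    """EM failed to converge; ``best`` carries the final iterate."""

    def __init__(self, message: str, best: np.ndarray):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class ExchangeRanks:
    """Tetrad exchange-rank frequencies E_0..E_kmax.

    ``feasible`` records whether all components were non-negative before any
    constraint handling; the direct estimator reports infeasible solutions
    unclamped so they remain diagnostically visible.
    """

    E: np.ndarray
    method: str
    loglik: float | None = None
    feasible: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", arr)
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"exchange ranks must sum to 1, got {arr.sum()!r}")
        if self.method == "mle" and np.any(arr < 0):
            raise ValueError("MLE exchange ranks must be non-negative")

    @property
    def kmax(self) -> int:
        return len(self.E) - 1


def recovery_matrix(kmax: int) -> np.ndarray:
    """Upper-triangular matrix M with M[j, k] = C(k, j) / 2^k.

    ``p = M @ E`` maps exchange-rank frequencies to recovered-chromatid class
    probabilities.  Columns sum to 1, so the map preserves the simplex.
    """
    k = np.arange(kmax + 1)
    return comb(k[None, :], k[:, None]) / 2.0 ** k[None, :]


def class_probabilities(E: ExchangeRanks | np.ndarray) -> np.ndarray:
    """Recovered-chromatid class probabilities p_0..p_kmax implied by E."""
    e = np.asarray(E.E if isinstance(E, ExchangeRanks) else E, dtype=float)
    if np.any(e < 0):
        raise ValueError("exchange ranks must be non-negative")
    if abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("exchange ranks must sum to 1")
    return recovery_matrix(len(e) - 1) @ e


def _prepare(counts: ClassCounts, kmax: int | None) -> tuple[np.ndarray, float, int]:
    if counts.n <= 0:
        raise ValueError("N must be positive")
    observed_kmax = int(np.max(np.nonzero(counts.counts)[0]))
    if kmax is None:
        kmax = observed_kmax
    elif kmax < observed_kmax:
        raise ValueError(
            f"kmax={kmax} below largest observed class {observed_kmax}"
        )
    return counts.padded(kmax), counts.n, kmax


def multinomial_loglik(counts: ClassCounts, E: np.ndarray) -> float:
    """Multinomial log-likelihood kernel sum_j n_j log p_j(E).

    The combinatorial constant is omitted; only differences matter for
    comparing fits of the same data.
    """
    kmax = max(counts.kmax, len(np.asarray(E)) - 1)
    n = counts.padded(kmax)
    e = np.zeros(kmax + 1)
    e[: len(np.asarray(E))] = np.asarray(E, dtype=float)
    p = recovery_matrix(kmax) @ e
    mask = n > 0
    with np.errstate(divide="ignore"):
        terms = n[mask] * np.log(p[mask])
    return float(terms.sum())


def weinstein_direct(counts: ClassCounts, kmax: int | None = None) -> ExchangeRanks:
    """Closed-form Weinstein inversion of observed class frequencies.

    Solves the triangular system p_hat = M E top-down.  Because the columns
    of M sum to one, the solution automatically sums to one; individual
    components can be negative when the data are incompatible with the
    no-chromatid-interference model, in which case ``feasible`` is False and
    the values are returned unclamped.
    """
    n, total, kmax = _prepare(counts, kmax)
    p_hat = n / total
    E = solve_triangular(recovery_matrix(kmax), p_hat, lower=False)
    feasible = bool(np.all(E >= 0))
    loglik = multinomial_loglik(counts, E) if feasible else None
    return ExchangeRanks(E, "direct", loglik=loglik, feasible=feasible)


def weinstein_mle(
    counts: ClassCounts,
    kmax: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
) -> ExchangeRanks:
    """Constrained multinomial MLE of exchange ranks via EM.

    Latent variable: the tetrad rank k of each recovered chromatid.  The
    E-step computes responsibilities r_{jk} = E_k M[j,k] / p_j and the M-step
    averages them over the observed counts.  Starts from the uniform simplex
    point; the fixed point from that start is the reported estimate (ties at
    the boundary are resolved deterministically, with no randomness).
    Boundary optima are approached at a linear rate, which can take a few
    hundred thousand of these very cheap iterations; the default cap is
    sized accordingly.

    Converges when the largest component change drops below ``tol``; raises
    :class:`ConvergenceError` (carrying the best iterate) after ``max_iter``.
    """
    n, total, kmax = _prepare(counts, kmax)
    M = recovery_matrix(kmax)
    E = np.full(kmax + 1, 1.0 / (kmax + 1))
    for _ in range(max_iter):
        p = M @ E
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = M * E[None, :] / p[:, None]
        resp[p == 0, :] = 0.0  # classes with zero model mass carry no data
        E_new = (n @ resp) / total
        if np.max(np.abs(E_new - E)) < tol:
            E = E_new
            break
        E = E_new
    else:
        raise ConvergenceError(
            f"EM did not converge within {max_iter} iterations", best=E
        )
    # Normalize away accumulated floating-point drift (E stays on the simplex
    # analytically) and clip exact-zero negatives from roundoff.
    E = np.clip(E, 0.0, None)
    E = E / E.sum()
    return ExchangeRanks(E, "mle", loglik=multinomial_loglik(counts, E), feasible=True)


def total_map_length(counts: ClassCounts) -> float:
    """Total genetic map length in cM: 100 * sum_j j*n_j / N.

    Each crossover on a recovered chromatid lies in exactly one scored
    interval, so interval map lengths sum to this total.
    """
    if counts.n <= 0:
        raise ValueError("N must be positive")
    j = np.arange(len(counts.counts))
    return float(100.0 * (j @ counts.counts) / counts.n)


def mean_exchanges(E: ExchangeRanks | np.ndarray) -> float:
    """Mean number of exchanges per tetrad, sum_k k*E_k.

    Under the recovery model a chromatid from an E_k tetrad carries k/2
    crossovers on average, so mean exchanges = 2 * total map length / 100.
    """
    e = np.asarray(E.E if isinstance(E, ExchangeRanks) else E, dtype=float)
    return float(np.arange(len(e)) @ e)


def bootstrap_exchange_ranks(
    counts: ClassCounts,
    n_boot: int = 1000,
    seed: int | None = None,
    kmax: int | None = None,
) -> np.ndarray:
    """Optional extra: multinomial bootstrap replicates of the MLE.

    Returns an ``(n_boot, kmax+1)`` array of resampled estimates.  Point
    estimates are the primary output of this package; the bootstrap is a
    convenience for exploratory uncertainty assessment only.
    """
    _, total, kmax = _prepare(counts, kmax)
    p_hat = counts.padded(kmax) / total
    rng = np.random.default_rng(seed)
    out = np.empty((n_boot, kmax + 1))
    n_int = int(round(total))
    for b in range(n_boot):
        resampled = rng.multinomial(n_int, p_hat)
        out[b] = weinstein_mle(ClassCounts(resampled.astype(float)), kmax=kmax).E
    return out
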