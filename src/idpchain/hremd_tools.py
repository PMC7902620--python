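"""Replica-ladder planning, exchange bookkeeping and time-series
diagnostics for Hamiltonian replica-exchange (solute-tempering) runs.

In replica exchange with solute tempering, replica i runs with solute
interactions scaled by lambda_i < 1, equivalent to an effective temperature
T_i = T0 / lambda_i.  The ladder

    lambda_i = exp(-(i / (n - 1)) * ln(Tmax / T0)),   i = 0 .. n-1

is geometric in T_i, interpolating from the unscaled physical replica
(lambda_0 = 1, T_0) to the hottest replica (lambda_{n-1} = T0/Tmax, Tmax).
Only the schedule and the logged outcomes of a run are handled here; the
exchange engine itself is out of scope.

The module also provides the block standard error (five contiguous equal
blocks by default) used as the uncertainty estimate for all trajectory
averages in this package, and the normalised autocorrelation function used
to compare sampling efficiency between simulation protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import IdpChainError

__all__ = [
    "ScalarSeries",
    "ReplicaLadder",
    "ExchangeStats",
    "BlockErrorResult",
    "effective_temperature_ladder",
    "average_exchange_probability",
    "block_standard_error",
    "autocorrelation",
    "TMAX_RECOMMENDED_K",
]

#: Effective-temperature band (K) recommended for the hottest replica when
#: sampling disordered proteins: hot enough to decorrelate, below the point
#: where scaled replicas start sampling artificially collapsed states.
TMAX_RECOMMENDED_K = (450.0, 500.0)


@dataclass
class ScalarSeries:
    """A per-frame scalar observable (e.g. Rg in nm, or a contact count)."""

    t: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape or self.value.ndim != 1:
            raise IdpChainError("t and value must be equal-length 1-D arrays")
        if not np.isfinite(self.value).all():
            raise IdpChainError("series values must be finite")

    def __len__(self) -> int:
        return self.value.size


@dataclass
class ReplicaLadder:
    """A solute-tempering schedule: scaling factors and effective temperatures."""

    n: int
    T0: float
    Tmax: float
    lambdas: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.lambdas.size != self.n or self.temperatures.size != self.n:
            raise IdpChainError("ladder arrays must have length n")
        if not np.isclose(self.lambdas[0], 1.0):
            raise IdpChainError("lambda_0 must be 1 (unscaled replica)")
        if np.any(np.diff(self.lambdas) >= 0):
            raise IdpChainError("lambdas must be strictly decreasing")


@dataclass
class ExchangeStats:
    """Per-neighbour-pair exchange acceptance statistics.

    ``p_ex[i]`` is the acceptance fraction for the (i, i+1) swap; pairs
    with zero attempts are reported as NaN (missing), never as 0.
    ``lowest_rank_p_ex`` is the 0-1 pair, the conventional headline number.
    """

    attempts: np.ndarray
    acceptances: np.ndarray
    p_ex: np.ndarray

    @property
    def lowest_rank_p_ex(self) -> float:
        return float(self.p_ex[0])


@dataclass
class BlockErrorResult:
    """Block-averaging error estimate of a trajectory mean."""

    block_means: np.ndarray
    mean: float
    stderr: float
    n_blocks: int
    n_dropped: int = 0


def effective_temperature_ladder(
    T0: float, Tmax: float, n: int
) -> ReplicaLadder:
    """Geometric effective-temperature ladder for solute tempering.

    lambda_i = exp(-(i/(n-1)) ln(Tmax/T0)); T_i = T0/lambda_i.  Endpoints
    are exact: lambda_0 = 1 and lambda_{n-1} = T0/Tmax.  A warning (not an
    error) is emitted when Tmax lies outside the recommended 450-500 K
    band for disordered-protein sampling.
    """
    if n < 2:
        raise IdpChainError("need at least 2 replicas")
    if not 0 < T0 < Tmax:
        raise IdpChainError("require Tmax > T0 > 0")
    lo, hi = TMAX_RECOMMENDED_K
    if not lo <= Tmax <= hi:
        warnings.warn(
            f"Tmax = {Tmax} K is outside the recommended [{lo:.0f}, "
            f"{hi:.0f}] K band for the hottest effective temperature",
            stacklevel=2,
        )
    i = np.arange(n)
    lambdas = np.exp(-(i / (n - 1)) * np.log(Tmax / T0))
    lambdas[0] = 1.0  # exact by construction; pin against rounding
    lambdas[-1] = T0 / Tmax
    return ReplicaLadder(n=n, T0=T0, Tmax=Tmax, lambdas=lambdas,
                         temperatures=T0 / lambdas)


def average_exchange_probability(
    attempts: np.ndarray, acceptances: np.ndarray
) -> ExchangeStats:
    """Acceptance fraction per neighbour pair from swap counts."""
    attempts = np.asarray(attempts, dtype=float)
    acceptances = np.asarray(acceptances, dtype=float)
    if attempts.shape != acceptances.shape or attempts.ndim != 1:
        raise IdpChainError("attempts and acceptances must be equal-length 1-D")
    if np.any(attempts < 0) or np.any(acceptances < 0):
        raise IdpChainError("counts must be non-negative")
    if np.any(acceptances > attempts):
        raise IdpChainError("acceptances cannot exceed attempts")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(attempts > 0, acceptances / attempts, np.nan)
    return ExchangeStats(attempts=attempts, acceptances=acceptances, p_ex=p)


def block_standard_error(
    series: ScalarSeries | np.ndarray, n_blocks: int = 5
) -> BlockErrorResult:
    """Standard error of a trajectory mean from contiguous equal blocks.

    The series is split in time order into ``n_blocks`` equal blocks
    (default five); with block means m_i and grand mean m-bar the error is

        stderr = sqrt( 1/(n(n-1)) * sum_i (m_i - m-bar)^2 ).

    When the length is not divisible by ``n_blocks`` the trailing frames
    are dropped (blocks must be equal); the count is reported in
    ``n_dropped``.
    """
    x = series.value if isinstance(series, ScalarSeries) else np.asarray(
        series, dtype=float
    )
    if n_blocks < 2:
        raise IdpChainError("n_blocks must be >= 2")
    if x.size < n_blocks:
        raise IdpChainError(
            f"series of length {x.size} too short for {n_blocks} blocks"
        )
    usable = x.size - x.size % n_blocks
    m = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    mbar = float(m.mean())
    stderr = float(np.sqrt(((m - mbar) ** 2).sum() / (n_blocks * (n_blocks - 1))))
    return BlockErrorResult(block_means=m, mean=mbar, stderr=stderr,
                            n_blocks=n_blocks, n_dropped=x.size - usable)


def autocorrelation(
    series: ScalarSeries | np.ndarray,
    max_lag: int,
    unbiased: bool = False,
) -> "CorrelationProfile":
    """Normalised autocorrelation C_t(tau) of a scalar time series.

    C_t(tau) = cov(x_t, x_{t+tau}) / var(x), so C_t(0) = 1.  By default
    the biased estimator (sums divided by the full length L) is used — the
    stable convention for diagnostic decay plots; ``unbiased=True``
    divides each lag sum by L - tau instead.
    """
    from .chain_statistics import CorrelationProfile  # avoid import cycle

    x = series.value if isinstance(series, ScalarSeries) else np.asarray(
        series, dtype=float
    )
    L = x.size
    if not 0 <= max_lag < L / 2:
        raise IdpChainError("require 0 <= max_lag < length/2")
    xc = x - x.mean()
    var = float((xc**2).mean())
    if var == 0:
        raise IdpChainError(
            "series has zero variance; autocorrelation undefined"
        )
    lags = np.arange(max_lag + 1)
    vals = np.empty(max_lag + 1)
    for tau in lags:
        s = float((xc[: L - tau] * xc[tau:]).sum())
        denom = (L - tau) if unbiased else L
        vals[tau] = s / denom / var
    return CorrelationProfile(s=lags, value=vals, label="C_t")
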