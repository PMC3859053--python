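"""Exploratory diagnostics: autocorrelation, lag pairs, residual whiteness.

Strong positive autocorrelation — lag plots clustered along the diagonal,
autocorrelation decaying slowly from a high lag-1 value — is the signature
that a signal is generated by an autoregressive process, and is exactly
what triaxial acceleration signals of everyday activities exhibit. The same
machinery, applied to the residuals of a fitted AR model, provides the
model-validation check: a well-specified model leaves white residuals with
no significant autocorrelation at any lag.

The biased sample autocorrelation used throughout is

    r_xx[k] = (1/N) * sum_{n=1}^{N-k} x[n] * x[n+k]

optionally after mean subtraction and optionally normalized by r_xx[0].
The whiteness decision codifies the visual check: a lag is "significant"
when its normalized autocorrelation falls outside +-1.96/sqrt(N), and the
series counts as white when at most a threshold fraction (default 10%) of
the first L lags (default 20) are significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError, ParameterError


@dataclass
class AutocorrelationSeries:
    """Sample autocorrelation r_xx[k] at lags 0..max_lag."""

    lags: np.ndarray
    values: np.ndarray
    n: int
    normalized: bool


@dataclass
class WhitenessReport:
    """Outcome of the band-exceedance whiteness check on a series."""

    band_halfwidth: float
    fraction_outside: float
    lags_tested: int
    is_white: bool


def autocorrelation(
    x,
    max_lag: int,
    normalized: bool = False,
    demean: bool = False,
) -> AutocorrelationSeries:
    """Biased sample autocorrelation of ``x`` at lags 0..max_lag.

    ``demean`` subtracts the sample mean first (appropriate for residual
    diagnostics); ``normalized`` divides by r_xx[0], which must then be
    nonzero.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ParameterError(f"need at least 2 samples, got {n}")
    if not 0 <= max_lag < n:
        raise ParameterError(f"max_lag must be in [0, {n - 1}], got {max_lag}")
    if demean:
        x = x - x.mean()
    full = np.correlate(x, x, mode="full")
    r = full[n - 1 : n + max_lag] / n
    if normalized:
        if r[0] == 0.0:
            raise DegenerateSignalError("cannot normalize: r_xx[0] is zero")
        r = r / r[0]
    return AutocorrelationSeries(
        lags=np.arange(max_lag + 1), values=r, n=n, normalized=normalized
    )


def lag_pairs(x, lag: int = 1) -> np.ndarray:
    """Ordered pairs (x[i-lag], x[i]) as an (N - lag, 2) array.

    Scatter-plotting column 0 against column 1 is the classical lag plot:
    diagonal clustering indicates strong positive autocorrelation, a
    structureless cloud indicates randomness.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 1 <= lag < n:
        raise ParameterError(f"lag must be in [1, {n - 1}], got {lag}")
    return np.column_stack([x[:-lag], x[lag:]])


def whiteness_test(x, lags_tested: int = 20, threshold: float = 0.10) -> WhitenessReport:
    """Decide whether a series is white noise via autocorrelation bands.

    The normalized, demeaned autocorrelation at lags 1..L is compared with
    the approximate 95% band +-1.96/sqrt(N); the verdict is white when the
    fraction of exceeding lags is at most ``threshold``. A constant series
    is reported not-white with fraction_outside = 1 (its autocorrelation is
    degenerate).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= lags_tested + 1:
        raise ParameterError(
            f"need more than lags_tested + 1 = {lags_tested + 1} samples, got {n}"
        )
    band = 1.96 / np.sqrt(n)
    try:
        acf = autocorrelation(x, max_lag=lags_tested, normalized=True, demean=True)
    except DegenerateSignalError:
        return WhitenessReport(
            band_halfwidth=band, fraction_outside=1.0, lags_tested=lags_tested, is_white=False
        )
    outside = np.abs(acf.values[1:]) > band
    fraction = float(outside.mean())
    return WhitenessReport(
        band_halfwidth=band,
        fraction_outside=fraction,
        lags_tested=lags_tested,
        is_white=fraction <= threshold,
    )
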