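"""Autoregressive modeling of activity acceleration signals.

An AR model of order M predicts each sample as a weighted sum of the M
previous samples plus an innovation term:

    x[n] = sum_{i=1..M} a_i * x[n-i] + eps[n]

The per-axis coefficient vectors (a_1..a_p) are the activity features: a
window's feature vector is the x-, y-, z-axis coefficients concatenated,
length 3p. Coefficients are estimated with Burg's maximum-entropy lattice
recursion, which minimizes the combined forward/backward prediction error
and always yields a stable model (reflection coefficients strictly inside
(-1, 1)).

Model-order selection minimizes the Akaike information criterion

    AIC = -2 L_m + 2 m,

with the Gaussian conditional log-likelihood L_m computed from the Burg
residual variance and m = order + 1 parameters, averaged over the three
axes. Window-length selection uses the signal-to-noise ratio of the
model-reproduced signal,

    SNR = 10 log10( sum v(i)^2 / sum (v(i) - vbar(i))^2 )   [dB],

where vbar is the one-step prediction sequence; the selected window is the
one at which the SNR curve flattens out. A fitted model is validated by
checking that its one-step residuals on a held-out sample are white.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import lfilter

from .eda import WhitenessReport, whiteness_test
from .exceptions import DegenerateSignalError, ParameterError, StabilityError
from .signal_io import AccelerometerRecording, SignalWindow, segment

_AXES = ("x", "y", "z")


@dataclass
class ARModel:
    """Fitted AR model: coefficients in predictor convention (a_i positive
    when past values contribute positively) and the innovation variance."""

    order: int
    coefficients: np.ndarray
    innovation_variance: float
    axis: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.order,):
            raise ParameterError(
                f"expected {self.order} coefficients, got {self.coefficients.shape}"
            )
        if self.innovation_variance < 0:
            raise ParameterError("innovation_variance must be >= 0")

    def poles(self) -> np.ndarray:
        """Roots of the characteristic polynomial z^M - a_1 z^{M-1} - ... - a_M."""
        return np.roots(np.concatenate([[1.0], -self.coefficients]))

    def is_stable(self, tol: float = 0.0) -> bool:
        if self.order == 0:
            return True
        return bool(np.all(np.abs(self.poles()) < 1.0 - tol))


@dataclass
class AICCurve:
    """Axis- and window-averaged AIC per candidate order, with the selection."""

    orders: np.ndarray
    scores: np.ndarray
    selected_order: int


@dataclass
class SNRCurve:
    """Axis- and window-averaged SNR (dB) per candidate window length."""

    window_lengths: np.ndarray
    snr_values: np.ndarray
    selected_window: float


@dataclass
class FeatureVector:
    """Concatenated per-axis AR coefficients [a_x1..a_xp, a_y.., a_z..]."""

    values: np.ndarray
    order: int
    activity_label: str | None = None
    position_label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3 * self.order,):
            raise ParameterError(
                f"feature vector must have length 3*order = {3 * self.order}, "
                f"got {self.values.shape}"
            )


def fit_ar_burg(x, order: int, demean: bool = True, axis: str | None = None) -> ARModel:
    """Estimate AR coefficients by Burg's maximum-entropy method.

    The lattice recursion picks each reflection coefficient to minimize the
    sum of forward and backward prediction-error power; by Cauchy-Schwarz
    every reflection coefficient lies in (-1, 1), so the fitted model is
    stable. The innovation variance is the final prediction-error power.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    if n <= 2 * order:
        raise ParameterError(f"need more than 2*order = {2 * order} samples, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError("cannot fit an AR model to a constant series")
    if demean:
        x = x - x.mean()

    # error-filter polynomial A(z) = 1 - a_1 z^-1 - ... (stored with leading 1)
    a_poly = np.array([1.0])
    f = x.copy()  # forward prediction errors
    b = x.copy()  # backward prediction errors
    energy = float(np.dot(x, x)) / n
    for m in range(1, order + 1):
        ff = f[m:]
        bb = b[m - 1 : n - 1]
        den = float(np.dot(ff, ff) + np.dot(bb, bb))
        if den == 0.0:
            raise DegenerateSignalError(
                f"prediction-error power vanished at stage {m}; series is degenerate"
            )
        k = -2.0 * float(np.dot(ff, bb)) / den
        a_poly = np.concatenate([a_poly, [0.0]])
        a_poly = a_poly + k * a_poly[::-1]
        f_new = f.copy()
        b_new = b.copy()
        f_new[m:] = ff + k * bb
        b_new[m:] = bb + k * ff
        f, b = f_new, b_new
        energy *= 1.0 - k * k
    return ARModel(
        order=order,
        coefficients=-a_poly[1:],
        innovation_variance=max(energy, 0.0),
        axis=axis,
    )


def predict_one_step(model: ARModel, x) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead predictions and residuals of ``model`` on ``x``.

    For n > order, ``xhat[n] = sum_i a_i x[n-i]`` and
    ``eps[n] = x[n] - xhat[n]``; both outputs have length N - order.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    p = model.order
    if n <= p:
        raise ParameterError(f"series length {n} must exceed model order {p}")
    preds = np.zeros(n - p)
    for i in range(1, p + 1):
        preds += model.coefficients[i - 1] * x[p - i : n - i]
    return preds, x[p:] - preds


def simulate_ar(
    model: ARModel, n: int, seed: int, burn_in: int | None = None
) -> np.ndarray:
    """Simulate ``n`` samples from a stable AR model with Gaussian innovations.

    The first ``burn_in`` samples (default 10 * order) are discarded so the
    returned series is approximately stationary. Deterministic given
    ``seed``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not model.is_stable():
        raise StabilityError("cannot simulate: model has poles on/outside the unit circle")
    if burn_in is None:
        burn_in = 10 * model.order
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(model.innovation_variance)
    eps = rng.normal(0.0, sigma, size=n + burn_in) if sigma > 0 else np.zeros(n + burn_in)
    denom = np.concatenate([[1.0], -model.coefficients])
    x = lfilter([1.0], denom, eps)
    return x[burn_in:]


def aic_score(residual_variance: float, n_effective: int, m: int) -> float:
    """Akaike information criterion for a Gaussian AR fit.

    ``L_m = -(n/2) (ln(2 pi sigma^2) + 1)`` and ``AIC = -2 L_m + 2 m``.
    Constant terms are retained; they cancel in any comparison at fixed n.
    """
    if residual_variance <= 0:
        raise ParameterError(f"residual_variance must be > 0, got {residual_variance}")
    if n_effective <= 0:
        raise ParameterError(f"n_effective must be > 0, got {n_effective}")
    log_lik = -0.5 * n_effective * (math.log(2.0 * math.pi * residual_variance) + 1.0)
    return -2.0 * log_lik + 2.0 * m


def plateau_select(values, candidates, threshold: float, maximize: bool) -> int:
    """Index of the candidate at which a selection curve flattens out.

    Scanning left to right, the first step whose relative improvement —
    gain for ``maximize=True`` (SNR), drop for ``maximize=False`` (AIC) —
    falls below ``threshold`` marks the start of the plateau; the candidate
    *before* that step is selected. If every step improves by at least the
    threshold, the last candidate is selected.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(candidates):
        raise ParameterError("values and candidates must align")
    for i in range(1, values.shape[0]):
        step = values[i] - values[i - 1] if maximize else values[i - 1] - values[i]
        denom = abs(values[i - 1])
        rel = step / denom if denom > 0 else (math.inf if step > 0 else 0.0)
        if rel < threshold:
            return i - 1
    return len(candidates) - 1


def select_order(
    windows: Sequence[SignalWindow],
    candidate_orders: Iterable[int],
    rule: str = "min",
    improvement_threshold: float = 0.01,
) -> AICCurve:
    """Select the AR model order by axis-averaged AIC over signal windows.

    Every candidate order is fitted per axis per window; AIC scores are
    averaged (unweighted) over the three axes and over windows. ``rule="min"``
    picks the argmin (ties toward the smaller order); ``rule="elbow"`` picks
    the order at which the averaged AIC curve evens out (relative drop below
    ``improvement_threshold``).
    """
    orders = np.asarray(sorted(candidate_orders), dtype=int)
    if orders.size == 0:
        raise ParameterError("candidate_orders is empty")
    windows = list(windows)
    if not windows:
        raise ParameterError("window list is empty")
    max_order = int(orders[-1])
    for w in windows:
        if w.n_samples <= 2 * max_order:
            raise ParameterError(
                f"window of {w.n_samples} samples too short for order {max_order}"
            )
    scores = np.zeros(orders.size)
    for w in windows:
        n_eff = w.n_samples
        for j in range(3):
            series = w.axis(j)
            for k, order in enumerate(orders):
                model = fit_ar_burg(series, int(order), axis=_AXES[j])
                scores[k] += aic_score(
                    model.innovation_variance, n_eff, int(order) + 1
                )
    scores /= 3 * len(windows)
    if rule == "min":
        selected = int(orders[int(np.argmin(scores))])
    elif rule == "elbow":
        selected = int(orders[plateau_select(scores, orders, improvement_threshold, maximize=False)])
    else:
        raise ParameterError(f"unknown rule {rule!r}; expected 'min' or 'elbow'")
    return AICCurve(orders=orders, scores=scores, selected_order=selected)


def snr(original, fitted) -> float:
    """Signal-to-noise ratio in dB between a signal and its reproduction.

    ``10 log10(sum v^2 / sum (v - vbar)^2)``; returns ``inf`` when the
    reproduction is exact and ``-inf`` when the signal itself is zero but
    the error is not.
    """
    v = np.asarray(original, dtype=float)
    vbar = np.asarray(fitted, dtype=float)
    if v.shape != vbar.shape or v.ndim != 1:
        raise ParameterError(f"shape mismatch: {v.shape} vs {vbar.shape}")
    if v.size < 1:
        raise ParameterError("need at least one sample")
    err = float(np.sum((v - vbar) ** 2))
    sig = float(np.sum(v**2))
    if err == 0.0:
        return math.inf
    if sig == 0.0:
        return -math.inf
    return 10.0 * math.log10(sig / err)


def select_window_length(
    rec: AccelerometerRecording,
    candidates: Sequence[float] = tuple(range(1, 11)),
    order: int = 10,
    improvement_threshold: float = 0.01,
) -> SNRCurve:
    """Select the window length by the flattening of the SNR curve.

    For each candidate length the recording is segmented, an order-``order``
    model is fitted per axis per window, and the SNR between the window's
    signal and the model's one-step predictions is averaged across axes and
    windows. The selected length is the one at which further enlargement
    gains less than ``improvement_threshold`` relative SNR.
    """
    candidates = sorted(float(c) for c in candidates)
    if not candidates:
        raise ParameterError("candidate list is empty")
    largest = int(round(candidates[-1] * rec.sampling_rate))
    if rec.n_samples < largest:
        raise ParameterError(
            f"recording of {rec.n_samples} samples shorter than the largest "
            f"candidate window ({largest} samples)"
        )
    values = np.zeros(len(candidates))
    for k, seconds in enumerate(candidates):
        windows = segment(rec, window_seconds=seconds)
        total, count = 0.0, 0
        for w in windows:
            if w.n_samples <= 2 * order:
                raise ParameterError(
                    f"candidate window {seconds} s has {w.n_samples} samples; "
                    f"too short for order {order}"
                )
            for j in range(3):
                series = w.axis(j)
                model = fit_ar_burg(series, order, axis=_AXES[j])
                centered = series - series.mean()
                preds, _ = predict_one_step(model, centered)
                value = snr(centered[order:], preds)
                if math.isfinite(value):
                    total += value
                    count += 1
        values[k] = total / count if count else math.nan
    idx = plateau_select(values, candidates, improvement_threshold, maximize=True)
    return SNRCurve(
        window_lengths=np.asarray(candidates),
        snr_values=values,
        selected_window=candidates[idx],
    )


def validate_model(model: ARModel, heldout, **whiteness_kwargs) -> WhitenessReport:
    """Whiteness check of a model's one-step residuals on a held-out series.

    The held-out series must come from a different sample than the one the
    model was fitted on (a protocol contract the function cannot verify).
    """
    _, residuals = predict_one_step(model, np.asarray(heldout, dtype=float))
    return whiteness_test(residuals, **whiteness_kwargs)


def extract_features(window: SignalWindow, order: int = 10) -> FeatureVector:
    """Burg-fit each axis of a window and concatenate the coefficients.

    The result is the length-3p activity feature vector
    [a_x1..a_xp, a_y1..a_yp, a_z1..a_zp], with the window's labels attached.
    """
    if window.n_samples <= 2 * order:
        raise ParameterError(
            f"window of {window.n_samples} samples too short for order {order}"
        )
    parts = [
        fit_ar_burg(window.axis(j), order, axis=_AXES[j]).coefficients for j in range(3)
    ]
    return FeatureVector(
        values=np.concatenate(parts),
        order=order,
        activity_label=window.activity_label,
        position_label=window.position_label,
        subject_id=window.subject_id,
    )
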