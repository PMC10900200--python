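"""Exponential fitting of Z/E ratio curves.

The observable used throughout the study is not an individual enamine
concentration but the *ratio* of the two HSQC cross-peak integrals.  Because
both integrals share one proportionality constant to concentration, the
signal ratio equals the concentration ratio, and it converges asymptotically
to the equilibrium constant ``Keq``.  The ratio curve is modelled as

    [Z]/[E](t) = Keq + A * exp(-t / c)

or, when one exponential is insufficient,

    [Z]/[E](t) = Keq + A1 * exp(-t / c1) + A2 * exp(-t / c2).

The fitted asymptote estimates ``Keq`` and the extrapolated t = 0 value
``Keq + sum(A_i)`` estimates the initial formation-rate ratio ``k1Z/k1E``.

:class:`RatioExponentialModel` follows the statsmodels model/results idiom:
construct from data, call :meth:`~RatioExponentialModel.fit`, read estimates
and uncertainties off the returned :class:`RatioFitResults` (or print its
``summary()``).  The module-level helpers :func:`fit_ratio_exponential` and
:func:`select_fit` are thin functional wrappers used by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit

__all__ = [
    "KineticSeries",
    "RatioExponentialModel",
    "RatioFitResults",
    "InsufficientDataError",
    "build_ratio_series",
    "fit_ratio_exponential",
    "select_fit",
]


class InsufficientDataError(ValueError):
    """Too few usable points to build or fit a ratio curve."""


@dataclass
class KineticSeries:
    """A Z/E integral time series with its experiment metadata.

    ``z_signal`` and ``e_signal`` are cross-peak integrals in one common
    arbitrary unit, so their pointwise ratio equals the concentration ratio.
    """

    t: np.ndarray
    z_signal: np.ndarray
    e_signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z_signal = np.asarray(self.z_signal, dtype=float)
        self.e_signal = np.asarray(self.e_signal, dtype=float)
        if not (self.t.size == self.z_signal.size == self.e_signal.size):
            raise ValueError("t, z_signal and e_signal must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.z_signal < 0) or np.any(self.e_signal < 0):
            raise ValueError("signal integrals must be non-negative")

    def __len__(self) -> int:
        return self.t.size


def build_ratio_series(
    series: KineticSeries, min_signal_fraction: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Form the Z/E ratio curve, guarding the division against weak signals.

    Points where the E integral falls below ``min_signal_fraction`` of its
    maximum are excluded: early in a run both integrals sit at the noise
    floor and their ratio is meaningless.  Returns ``(times, ratios)``.

    Raises
    ------
    InsufficientDataError
        If fewer than 4 points survive the guard.
    """
    if not 0 <= min_signal_fraction < 1:
        raise ValueError("min_signal_fraction must lie in [0, 1)")
    e_max = series.e_signal.max() if len(series) else 0.0
    mask = series.e_signal >= min_signal_fraction * e_max
    mask &= series.e_signal > 0
    t, ratio = series.t[mask], series.z_signal[mask] / series.e_signal[mask]
    if t.size < 4:
        raise InsufficientDataError(
            f"only {t.size} usable ratio points after the weak-signal guard "
            f"(need >= 4)"
        )
    return t, ratio


def _model_values(t, keq, amplitudes, timescales):
    out = np.full_like(np.asarray(t, dtype=float), keq)
    for a, c in zip(amplitudes, timescales):
        out = out + a * np.exp(-np.asarray(t, dtype=float) / c)
    return out


@dataclass
class RatioFitResults:
    """Estimates, uncertainties and diagnostics of one ratio-curve fit."""

    keq: float
    amplitudes: tuple[float, ...]
    timescales: tuple[float, ...]
    initial_ratio: float
    n_exponentials: int
    residual_sse: float
    converged: bool
    nobs: int
    aicc: float
    stderr: dict[str, float | None]
    t: np.ndarray
    ratio: np.ndarray

    @property
    def nparams(self) -> int:
        return 1 + 2 * self.n_exponentials

    def predict(self, t=None) -> np.ndarray:
        t = self.t if t is None else t
        return _model_values(t, self.keq, self.amplitudes, self.timescales)

    def residuals(self) -> np.ndarray:
        return self.ratio - self.predict()

    def summary(self) -> str:
        lines = [
            "Z/E ratio exponential fit",
            "=" * 41,
            f"model:            Keq + sum_i A_i exp(-t/c_i), {self.n_exponentials} exp",
            f"observations:     {self.nobs}",
            f"converged:        {self.converged}",
            f"residual SSE:     {self.residual_sse:.6g}",
            f"AICc:             {self.aicc:.4g}",
            "-" * 41,
            _param_line("Keq", self.keq, self.stderr.get("keq")),
        ]
        for i, (a, c) in enumerate(zip(self.amplitudes, self.timescales), 1):
            lines.append(_param_line(f"A{i}", a, self.stderr.get(f"a{i}")))
            lines.append(_param_line(f"c{i} (min)", c, self.stderr.get(f"c{i}")))
        lines.append(_param_line("Z/E at t=0", self.initial_ratio, None))
        return "\n".join(lines)


def _param_line(name: str, value: float, err: float | None) -> str:
    if err is None or not math.isfinite(err):
        return f"{name:<12s} {value:>12.6g}"
    return f"{name:<12s} {value:>12.6g} +/- {err:.3g}"


def _aicc(sse: float, n: int, k: int, floor: float) -> float:
    """Corrected Akaike criterion for a Gaussian least-squares fit."""
    if n <= k + 1:
        return math.inf
    sse = max(sse, floor)
    return n * math.log(sse / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


class RatioExponentialModel:
    """Exponential relaxation model for a Z/E ratio curve.

    Parameters
    ----------
    t : array_like
        Sample times, min, strictly increasing.
    ratio : array_like
        Z/E ratio at each time.
    n_exponentials : {1, 2}
        Number of exponential relaxation terms.

    Notes
    -----
    The fit is unweighted nonlinear least squares (Levenberg-Marquardt via
    lmfit) with ``Keq > 0`` and timescales ``c_i > 0`` enforced through
    bounds; amplitudes are unconstrained (negative amplitudes describe
    curves rising toward equilibrium).  Initial guesses assume a
    monotone-ish curve: ``Keq`` from the last observed ratio, amplitude from
    first-minus-last, timescale one third of the time span.  On
    non-convergence the fit is restarted up to 5 times from deterministic
    perturbations of the guesses and the best solution kept; a result that
    still has not converged is returned flagged, never fabricated.
    """

    #: points required for an identifiable fit, per exponential count
    MIN_POINTS = {1: 4, 2: 6}

    def __init__(self, t, ratio, n_exponentials: int = 1):
        if n_exponentials not in (1, 2):
            raise ValueError("n_exponentials must be 1 or 2")
        self.t = np.asarray(t, dtype=float)
        self.ratio = np.asarray(ratio, dtype=float)
        if self.t.size != self.ratio.size:
            raise ValueError("t and ratio must have equal length")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("ratio curve must be finite everywhere")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")
        self.n_exponentials = n_exponentials
        if self.t.size < self.MIN_POINTS[n_exponentials]:
            raise InsufficientDataError(
                f"{self.t.size} points is too few for a "
                f"{n_exponentials}-exponential fit "
                f"(need >= {self.MIN_POINTS[n_exponentials]})"
            )

    # -- fitting ----------------------------------------------------------

    #: timescale identifiability window, as multiples of the observation
    #: span (upper: slower components are indistinguishable from a constant
    #: offset and would absorb the asymptote, driving Keq to zero) and of
    #: the first positive observation time (lower: faster components are
    #: unconstrained by any data point and explode the t = 0 extrapolation)
    MAX_TIMESCALE_SPANS = 1.0
    MIN_TIMESCALE_FIRST_T = 0.5

    def _timescale_bounds(self) -> tuple[float, float]:
        span = max(self.t[-1] - self.t[0], 1.0)
        positive = self.t[self.t > 0]
        c_min = 1e-9
        if positive.size:
            c_min = max(c_min, self.MIN_TIMESCALE_FIRST_T * float(positive[0]))
        c_max = max(self.MAX_TIMESCALE_SPANS * span, 2.0 * c_min)
        return c_min, c_max

    def _initial_params(self) -> lmfit.Parameters:
        span = max(self.t[-1] - self.t[0], 1.0)
        c_min, c_max = self._timescale_bounds()
        clamp = lambda c: min(max(c, 2 * c_min), c_max)
        last = float(self.ratio[-1])
        first = float(self.ratio[0])
        params = lmfit.Parameters()
        params.add("keq", value=max(last, 1e-6), min=1e-12)
        if self.n_exponentials == 1:
            params.add("a1", value=first - last)
            params.add("c1", value=clamp(span / 3.0), min=c_min, max=c_max)
        else:
            params.add("a1", value=0.7 * (first - last))
            params.add("c1", value=clamp(span / 10.0), min=c_min, max=c_max)
            params.add("a2", value=0.3 * (first - last))
            params.add("c2", value=clamp(span / 2.0), min=c_min, max=c_max)
        return params

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        keq = params["keq"].value
        amps = [params[f"a{i}"].value for i in range(1, self.n_exponentials + 1)]
        taus = [params[f"c{i}"].value for i in range(1, self.n_exponentials + 1)]
        return _model_values(self.t, keq, amps, taus) - self.ratio

    def fit(self, restarts: int = 5) -> RatioFitResults:
        """Fit the model, restarting from perturbed guesses if needed."""
        params = self._initial_params()
        best = lmfit.minimize(self._residual, params, method="leastsq")
        rng = np.random.default_rng(0)  # deterministic restart stream
        tries = 0
        while not best.success and tries < restarts:
            tries += 1
            perturbed = self._initial_params()
            for p in perturbed.values():
                p.value *= float(rng.uniform(0.3, 3.0))
            attempt = lmfit.minimize(self._residual, perturbed, method="leastsq")
            if attempt.success or (
                attempt.chisqr is not None and attempt.chisqr < best.chisqr
            ):
                best = attempt
        return self._package(best)

    def _package(self, mres: lmfit.minimizer.MinimizerResult) -> RatioFitResults:
        p = mres.params
        keq = float(p["keq"].value)
        amps = tuple(float(p[f"a{i}"].value) for i in range(1, self.n_exponentials + 1))
        taus = tuple(float(p[f"c{i}"].value) for i in range(1, self.n_exponentials + 1))
        sse = float(np.sum(self._residual(p) ** 2))
        scale = max(1.0, float(np.abs(self.ratio).max()))
        floor = self.t.size * (1e-10 * scale) ** 2
        stderr = {name: (p[name].stderr if p[name].stderr else None) for name in p}
        return RatioFitResults(
            keq=keq,
            amplitudes=amps,
            timescales=taus,
            initial_ratio=max(keq + sum(amps), 0.0),
            n_exponentials=self.n_exponentials,
            residual_sse=sse,
            converged=bool(mres.success),
            nobs=self.t.size,
            aicc=_aicc(sse, self.t.size, 1 + 2 * self.n_exponentials, floor),
            stderr=stderr,
            t=self.t,
            ratio=self.ratio,
        )


def fit_ratio_exponential(curve, n_exponentials: int = 1) -> RatioFitResults:
    """Fit ``(t, ratio)`` with ``n_exponentials`` relaxation terms."""
    t, ratio = curve
    return RatioExponentialModel(t, ratio, n_exponentials).fit()


def select_fit(curve, aicc_margin: float = 2.0) -> RatioFitResults:
    """Fit one and two exponentials and keep the better-supported model.

    The single-exponential form is the default; the double form is retained
    only when it lowers the corrected AIC by more than ``aicc_margin``
    (parsimony guard: a second exponential adds two parameters and on
    well-behaved curves buys nothing).  A single-exponential fit whose
    residual is already at numerical noise short-circuits the comparison.
    """
    t, ratio = curve
    t = np.asarray(t, dtype=float)
    if t.size < 6:
        raise InsufficientDataError(
            f"model selection needs >= 6 points, got {t.size}"
        )
    fit1 = RatioExponentialModel(t, ratio, 1).fit()
    scale = max(1.0, float(np.abs(np.asarray(ratio)).max()))
    if fit1.residual_sse <= t.size * (1e-9 * scale) ** 2:
        return fit1
    fit2 = RatioExponentialModel(t, ratio, 2).fit()
    # a ratio curve converges to its asymptote, so a double-exponential
    # solution whose Keq collapsed far below the late observations is a
    # degenerate reparametrisation, not a better model
    late = float(np.median(np.asarray(ratio, dtype=float)[-3:]))
    degenerate = fit2.keq < 0.05 * abs(late)
    if fit2.converged and not degenerate and fit1.aicc - fit2.aicc > aicc_margin:
        return fit2
    return fit1
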