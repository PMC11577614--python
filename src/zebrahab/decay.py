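"""Exponential-decay fitting of escape-response series and model selection.

The escape distance of one larva over the 30-stimulus habituation train is
summarised by a single-exponential decay

    f(x) = a * exp(-b * x) + c,      x = n - 1 (0-based stimulus index),

from which three behavioural parameters are read off:

* **amplitude** -- escape distance at the first habituating stimulus,
  ``f(0) = a + c``;
* **decay constant** -- ``1/b``, the number of stimuli for the response to
  fall to 1/e of its initial value (speed of habituation);
* **offset** -- ``c``, the steady-state responsivity after habituation.

:class:`HabituationDecay` is the model class; :meth:`HabituationDecay.fit`
returns a :class:`DecayFitResults` carrying estimates, standard errors,
diagnostics and a ``summary()`` table, and
:meth:`HabituationDecay.fit_candidates` ranks a family of candidate curves
(linear, restricted single exponentials, double exponential) with
information criteria (AIC, AICc, CAIC, BIC), log-likelihood and adjusted
R^2 under a Gaussian error model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ResponseSeries",
    "DecayFitResults",
    "CandidateFit",
    "ModelComparison",
    "HabituationDecay",
    "fit_single_exponential",
    "fit_double_exponential",
    "fit_candidates",
    "information_criteria",
]

_B_LO, _B_HI = 1e-6, 10.0
_PHASE_LENGTHS = {"subthreshold": 10, "prehabituation": 10, "habituation": 30}


@dataclass
class ResponseSeries:
    """One larva's escape distances over the stimuli of one assay phase."""

    larva_id: str
    phase: str
    distances: np.ndarray
    responded: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.phase not in _PHASE_LENGTHS:
            raise ValueError(f"unknown phase {self.phase!r}")
        if np.any(self.distances < 0):
            raise ValueError("escape distances must be non-negative")
        expected = _PHASE_LENGTHS[self.phase]
        if len(self.distances) != expected:
            raise ValueError(
                f"phase {self.phase!r} expects {expected} stimuli, "
                f"got {len(self.distances)}"
            )
        if self.responded is not None:
            self.responded = np.asarray(self.responded, dtype=bool)


def _single_exp(x, a, b, c):
    return a * np.exp(-b * x) + c


def _double_exp(x, a1, b1, a2, b2, c):
    return a1 * np.exp(-b1 * x) + a2 * np.exp(-b2 * x) + c


def information_criteria(rss: float, n: int, k: int) -> dict:
    """Gaussian-likelihood fit metrics from a residual sum of squares.

    ``k`` is the total free-parameter count *including* the error variance.
    The log-likelihood is the profile Gaussian likelihood
    ``logL = -n/2 (ln(2 pi rss / n) + 1)``.  AICc is undefined (returned as
    NaN) when ``n <= k + 1``.
    """
    if n <= 0 or rss < 0:
        raise ValueError("need n > 0 and rss >= 0")
    rss = max(rss, 1e-300)  # guard log(0) for exact fits
    loglik = -n / 2.0 * (math.log(2 * math.pi * rss / n) + 1.0)
    aic = 2 * k - 2 * loglik
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else math.nan
    bic = k * math.log(n) - 2 * loglik
    caic = k * (math.log(n) + 1) - 2 * loglik
    return {"loglik": loglik, "aic": aic, "aicc": aicc, "caic": caic, "bic": bic}


def _adj_r2(rss: float, y: np.ndarray, n_coef: int) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    if tss == 0 or n - n_coef - 1 <= 0:
        return math.nan
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_coef - 1)


class DecayFitResults:
    """Results of a single-exponential decay fit.

    Attributes
    ----------
    params : dict
        Curve coefficients ``a`` (mm), ``b`` (per stimulus), ``c`` (mm).
    bse : dict
        Asymptotic standard errors from the Jacobian (NaN if unavailable).
    amplitude : float
        ``a + c``, the fitted distance at the first habituating stimulus.
    decay_constant : float
        ``1/b`` in stimuli.
    offset : float
        ``c``, the steady-state responsivity.
    rss : float
        Residual sum of squares.
    converged : bool
        False for degenerate fits (constant input, optimizer failure, or
        rate pinned at its bound).
    """

    def __init__(self, model, a, b, c, pcov, rss, converged):
        self.model = model
        self.params = {"a": float(a), "b": float(b), "c": float(c)}
        if pcov is not None and np.all(np.isfinite(pcov)):
            se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        else:
            se = [math.nan] * 3
        self.bse = dict(zip(("a", "b", "c"), (float(s) for s in se)))
        self.rss = float(rss)
        self.converged = bool(converged)

    @property
    def a(self) -> float:
        return self.params["a"]

    @property
    def b(self) -> float:
        return self.params["b"]

    @property
    def c(self) -> float:
        return self.params["c"]

    @property
    def amplitude(self) -> float:
        return self.a + self.c

    @property
    def decay_constant(self) -> float:
        return math.inf if self.b == 0 else 1.0 / self.b

    @property
    def offset(self) -> float:
        return self.c

    def fittedvalues(self) -> np.ndarray:
        return _single_exp(self.model.x, self.a, self.b, self.c)

    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues()

    def summary(self) -> str:
        lines = [
            "Single-exponential decay fit: f(x) = a*exp(-b*x) + c",
            f"  n points:   {len(self.model.y)}",
            f"  converged:  {self.converged}",
            f"  rss:        {self.rss:.6g}",
            "",
            f"  {'coef':<12}{'estimate':>12}{'std err':>12}",
        ]
        for name in ("a", "b", "c"):
            lines.append(
                f"  {name:<12}{self.params[name]:>12.6g}{self.bse[name]:>12.4g}"
            )
        lines += [
            "",
            f"  amplitude (a+c):     {self.amplitude:.6g} mm",
            f"  decay constant (1/b): {self.decay_constant:.6g} stimuli",
            f"  offset (c):          {self.offset:.6g} mm",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x + 1, self.model.y, "o", label="observed", alpha=0.6)
        xs = np.linspace(self.model.x.min(), self.model.x.max(), 200)
        ax.plot(xs + 1, _single_exp(xs, self.a, self.b, self.c), label="fit")
        ax.set_xlabel("stimulus $n$")
        ax.set_ylabel("escape distance (mm)")
        ax.legend()
        return ax


@dataclass
class CandidateFit:
    """One candidate curve's fit and goodness-of-fit metrics."""

    name: str
    k: int  # free parameters incl. error variance
    params: dict
    rss: float
    loglik: float
    aic: float
    aicc: float
    caic: float
    bic: float
    adj_r2: float
    converged: bool
    error: Optional[str] = None


@dataclass
class ModelComparison:
    """Goodness-of-fit comparison across the candidate curve family."""

    candidates: list
    best_by: dict = field(default_factory=dict)

    def __post_init__(self):
        ok = [c for c in self.candidates if c.error is None]
        if ok:
            for metric in ("aic", "aicc", "caic", "bic"):
                vals = [(getattr(c, metric), c.name) for c in ok
                        if not math.isnan(getattr(c, metric))]
                if vals:
                    self.best_by[metric] = min(vals)[1]
            for metric in ("loglik", "adj_r2"):
                vals = [(getattr(c, metric), c.name) for c in ok
                        if not math.isnan(getattr(c, metric))]
                if vals:
                    self.best_by[metric] = max(vals)[1]

    def __getitem__(self, name: str) -> CandidateFit:
        for c in self.candidates:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "model": c.name,
                    "k": c.k,
                    "rss": c.rss,
                    "loglik": c.loglik,
                    "aic": c.aic,
                    "aicc": c.aicc,
                    "caic": c.caic,
                    "bic": c.bic,
                    "adj_r2": c.adj_r2,
                    "converged": c.converged,
                    "error": c.error,
                }
            )
        return pd.DataFrame(rows)


class HabituationDecay:
    """Single-exponential habituation model for one escape-distance series.

    Parameters
    ----------
    y : array-like
        Escape distances per stimulus, in presentation order.
    allow_negative_offset : bool, default False
        Permit c < 0.  Empirical distances require c >= 0; noiseless model
        traces (which may go negative) need the unbounded offset.

    The fit is nonlinear least squares with a deterministic multi-start:
    starting values ``a0 = y[0] - mean(last 5)``, ``c0 = mean(last 5)``
    crossed with a rate grid ``b0 in {0.05, 0.2, 0.5, 1.0}``; the converged
    start with the lowest residual sum of squares wins.  Rates are bounded
    to [1e-6, 10] per stimulus.
    """

    _B0_GRID = (0.05, 0.2, 0.5, 1.0)

    def __init__(self, y: Sequence[float], allow_negative_offset: bool = False):
        self.y = np.asarray(y, dtype=float)
        if len(self.y) < 4:
            raise ValueError("need at least 4 points to fit a decay curve")
        if not allow_negative_offset and np.any(self.y < 0):
            raise ValueError(
                "negative distances; pass allow_negative_offset=True for "
                "model traces"
            )
        self.x = np.arange(len(self.y), dtype=float)
        self.allow_negative_offset = allow_negative_offset

    @classmethod
    def from_series(cls, series: ResponseSeries, **kw) -> "HabituationDecay":
        return cls(series.distances, **kw)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        larva_id=None,
        phase: str = "habituation",
        value_col: str = "distance_mm",
        **kw,
    ) -> "HabituationDecay":
        """Build from a tidy table (larva_id, phase, stimulus_index, distance)."""
        sub = df[df["phase"] == phase]
        if larva_id is not None:
            sub = sub[sub["larva_id"] == larva_id]
        sub = sub.sort_values("stimulus_index")
        return cls(sub[value_col].to_numpy(), **kw)

    # -- fitting ----------------------------------------------------------
    def _starts(self):
        tail = float(np.mean(self.y[-5:]))
        a0 = float(self.y[0] - tail)
        c0 = tail
        if not self.allow_negative_offset:
            a0, c0 = max(a0, 0.0), max(c0, 0.0)
        for b0 in self._B0_GRID:
            yield (a0 if a0 != 0 else max(np.ptp(self.y), 1e-3), b0, c0)

    def _bounds(self):
        c_lo = -np.inf if self.allow_negative_offset else 0.0
        return ([0.0, _B_LO, c_lo], [np.inf, _B_HI, np.inf])

    def fit(self) -> DecayFitResults:
        """Least-squares fit; degenerate inputs yield converged=False."""
        if np.ptp(self.y) == 0.0:
            # constant series: no decay; report the offset honestly
            return DecayFitResults(
                self, 0.0, _B_LO, float(self.y[0]), None,
                0.0, converged=False,
            )
        best = None
        for p0 in self._starts():
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        _single_exp, self.x, self.y, p0=p0,
                        bounds=self._bounds(), maxfev=20000,
                    )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((self.y - _single_exp(self.x, *popt)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            c = float(np.mean(self.y))
            rss = float(np.sum((self.y - c) ** 2))
            return DecayFitResults(self, 0.0, _B_LO, c, None, rss, converged=False)
        popt, pcov, rss = best
        converged = _B_LO * 1.01 < popt[1] < _B_HI * 0.99
        return DecayFitResults(self, *popt, pcov, rss, converged)

    def fit_double(self) -> dict:
        """Double-exponential fit a1 e^{-b1 x} + a2 e^{-b2 x} + c.

        Multi-start over ordered rate pairs, seeded additionally from the
        single-exponential solution so the nested-model inequality
        rss(double) <= rss(single) holds by construction.  Rates are
        returned sorted ``b1 < b2``.
        """
        single = self.fit()
        lo = [0.0, _B_LO, 0.0, _B_LO,
              -np.inf if self.allow_negative_offset else 0.0]
        hi = [np.inf, _B_HI, np.inf, _B_HI, np.inf]
        starts = [
            (single.a, single.b, 1e-3, min(2 * max(single.b, 0.1), _B_HI / 2),
             single.c),
        ]
        amp = max(np.ptp(self.y), 1e-3)
        for b1, b2 in ((0.1, 0.8), (0.05, 0.3), (0.2, 1.0), (0.3, 2.0)):
            starts.append((amp / 2, b1, amp / 2, b2,
                           single.c if self.allow_negative_offset
                           else max(single.c, 0.0)))
        best = None
        for p0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _double_exp, self.x, self.y, p0=p0,
                        bounds=(lo, hi), maxfev=40000,
                    )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((self.y - _double_exp(self.x, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        if best is None:
            return {"params": None, "rss": math.inf, "converged": False}
        (a1, b1, a2, b2, c), rss = best
        if b1 > b2:  # identifiability: enforce b1 < b2
            a1, b1, a2, b2 = a2, b2, a1, b1
        return {
            "params": {"a1": a1, "b1": b1, "a2": a2, "b2": b2, "c": c},
            "rss": rss,
            "converged": True,
        }

    # -- model comparison --------------------------------------------------
    def fit_candidates(self) -> ModelComparison:
        """Fit the candidate family and rank it with all six fit metrics.

        Candidates (free curve coefficients in parentheses; every criterion
        adds +1 for the error variance):

        * ``linear``: m*x + q (2)
        * ``single_exp``: a e^{-b x} + c (3)
        * ``single_exp_no_c``: a e^{-b x} (2)
        * ``single_exp_unit_a``: e^{-b x} + c (2)
        * ``constant``: c — the rate-pinned pure-offset degenerate (1)
        * ``double_exp``: a1 e^{-b1 x} + a2 e^{-b2 x} + c (5)

        A candidate whose optimizer fails is recorded with its error and
        excluded from the rankings rather than aborting the comparison.
        """
        n = len(self.y)
        out = []
        for name, n_coef, fitter in (
            ("linear", 2, self._fit_linear),
            ("single_exp", 3, self._fit_single_wrap),
            ("single_exp_no_c", 2, self._fit_no_c),
            ("single_exp_unit_a", 2, self._fit_unit_a),
            ("constant", 1, self._fit_constant),
            ("double_exp", 5, self._fit_double_wrap),
        ):
            try:
                params, rss, converged = fitter()
            except Exception as exc:  # per-candidate failure is not fatal
                out.append(
                    CandidateFit(name, n_coef + 1, {}, math.nan, math.nan,
                                 math.nan, math.nan, math.nan, math.nan,
                                 math.nan, False, error=str(exc))
                )
                continue
            k = n_coef + 1
            ic = information_criteria(rss, n, k)
            out.append(
                CandidateFit(
                    name, k, params, rss, ic["loglik"], ic["aic"], ic["aicc"],
                    ic["caic"], ic["bic"], _adj_r2(rss, self.y, n_coef),
                    converged,
                )
            )
        return ModelComparison(out)

    def _fit_linear(self):
        m, q = np.polyfit(self.x, self.y, 1)
        rss = float(np.sum((self.y - (m * self.x + q)) ** 2))
        return {"m": m, "q": q}, rss, True

    def _fit_single_wrap(self):
        res = self.fit()
        return res.params, res.rss, res.converged

    def _fit_no_c(self):
        return self._curvefit_restricted(lambda x, a, b: a * np.exp(-b * x),
                                         [(max(self.y[0], 1e-3), b0)
                                          for b0 in self._B0_GRID],
                                         ([0.0, _B_LO], [np.inf, _B_HI]),
                                         names=("a", "b"))

    def _fit_unit_a(self):
        c_lo = -np.inf if self.allow_negative_offset else 0.0
        return self._curvefit_restricted(lambda x, b, c: np.exp(-b * x) + c,
                                         [(b0, float(np.mean(self.y[-5:])))
                                          for b0 in self._B0_GRID],
                                         ([_B_LO, c_lo], [_B_HI, np.inf]),
                                         names=("b", "c"))

    def _fit_constant(self):
        c = float(np.mean(self.y))
        rss = float(np.sum((self.y - c) ** 2))
        return {"c": c}, rss, True

    def _fit_double_wrap(self):
        res = self.fit_double()
        if res["params"] is None:
            raise RuntimeError("double-exponential fit failed to converge")
        return res["params"], res["rss"], res["converged"]

    def _curvefit_restricted(self, fn, starts, bounds, names):
        best = None
        for p0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(fn, self.x, self.y, p0=p0,
                                        bounds=bounds, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((self.y - fn(self.x, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        if best is None:
            raise RuntimeError("no start converged")
        return dict(zip(names, best[0])), best[1], True


# -- functional wrappers ---------------------------------------------------

def fit_single_exponential(series, allow_negative_offset: bool = False) -> DecayFitResults:
    """Fit f(x) = a e^{-b x} + c to a :class:`ResponseSeries` or array."""
    y = series.distances if isinstance(series, ResponseSeries) else series
    return HabituationDecay(y, allow_negative_offset=allow_negative_offset).fit()


def fit_double_exponential(series, allow_negative_offset: bool = False) -> dict:
    y = series.distances if isinstance(series, ResponseSeries) else series
    return HabituationDecay(y, allow_negative_offset=allow_negative_offset).fit_double()


def fit_candidates(series, allow_negative_offset: bool = False) -> ModelComparison:
    """Rank the candidate curve family on one series."""
    y = series.distances if isinstance(series, ResponseSeries) else series
    return HabituationDecay(y, allow_negative_offset=allow_negative_offset).fit_candidates()
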