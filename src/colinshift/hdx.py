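"""Hydrogen-deuterium exchange: decay fitting and protection factors.

Amide peak intensities after dissolution in D2O decay exponentially with the
observed exchange rate k_exchange.  Protection is reported on a log scale,
logP = log10(k_intrinsic / k_exchange), against the intrinsic free-peptide
rate of the same amide (supplied by the user from a standard intrinsic-rate
table).  Protection summed over the specificity-surface residues (SigmaLogP)
tracks how strongly the bound peptide shields that surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize


@dataclass
class HdxSeries:
    """Intensity time course of one residue's amide peak (times in minutes)."""

    residue_id: int
    times: Sequence[float]
    intensities: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities differ in length")
        if len(self.times) < 5:
            raise ValueError("need at least 5 time points to fit a decay")
        if self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be nonnegative")


@dataclass
class DecayFit:
    """Fitted exponential decay; rate is None when flagged out of window."""

    residue_id: int
    k_exchange: Optional[float]  # 1/min
    amplitude: Optional[float]
    baseline: Optional[float]
    k_stderr: Optional[float]
    flag: str  # "" | "slow_exchanger" | "fast_exchanger"
    model: str  # "simple" | "plateau"


def fit_decay(series: HdxSeries, model: str = "simple") -> DecayFit:
    """Fit I(t) = A exp(-k t) (+ b for the plateau model) by least squares.

    Rates outside the observable window are flagged, not reported as numbers:
    a trace that has not dropped 2-fold by the end (or whose fitted half-life
    exceeds the experiment duration) is a ``slow_exchanger``; a trace already
    at baseline by the first sampling interval is a ``fast_exchanger``.
    ``model="auto"`` picks simple vs plateau per-series by AIC.
    """
    if model == "auto":
        fits = []
        for m in ("simple", "plateau"):
            try:
                fits.append((_aic(series, m), fit_decay(series, m)))
            except (RuntimeError, ValueError):
                continue
        if not fits:
            raise RuntimeError(f"residue {series.residue_id}: no decay model fits")
        return min(fits, key=lambda t: t[0])[1]
    if model not in ("simple", "plateau"):
        raise ValueError(f"unknown decay model {model!r}")

    t = np.asarray(series.times, dtype=float)
    I = np.asarray(series.intensities, dtype=float)
    i0 = I[0] if I[0] > 0 else I.max()
    duration = t[-1] - t[0]
    first_interval = (t[1] - t[0]) if len(t) > 1 else duration

    # windowing: essentially flat -> too slow to quantify
    if i0 > 0 and I[-1] > 0.5 * i0:
        return DecayFit(series.residue_id, None, None, None, None,
                        "slow_exchanger", model)
    # already decayed at the first measurable point
    if i0 <= 0 or (len(I) > 1 and I[1] < 0.05 * i0 and I[0] < 0.05 * I.max()):
        return DecayFit(series.residue_id, None, None, None, None,
                        "fast_exchanger", model)

    popt, perr = _fit(t, I, model)
    k = float(popt[1])
    if k <= 0:
        raise ValueError(f"residue {series.residue_id}: nonpositive fitted rate")
    half_life = math.log(2.0) / k
    if half_life < first_interval:
        return DecayFit(series.residue_id, None, None, None, None,
                        "fast_exchanger", model)
    if half_life > duration:
        return DecayFit(series.residue_id, None, None, None, None,
                        "slow_exchanger", model)
    baseline = float(popt[2]) if model == "plateau" else None
    return DecayFit(
        series.residue_id, k, float(popt[0]), baseline,
        float(perr[1]), "", model,
    )


def _fit(t: np.ndarray, I: np.ndarray, model: str):
    a0, k0 = float(I.max()), math.log(2.0) / max((t[-1] - t[0]) / 4.0, 1e-9)
    if model == "simple":
        def f(tv, a, k):
            return a * np.exp(-k * tv)
        p0, bounds = [a0, k0], ([0, 1e-12], [np.inf, np.inf])
    else:
        def f(tv, a, k, b):
            return a * np.exp(-k * tv) + b
        p0, bounds = [a0, k0, 0.0], ([0, 1e-12, 0], [np.inf, np.inf, np.inf])
    try:
        popt, pcov = optimize.curve_fit(f, t, I, p0=p0, bounds=bounds,
                                        maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit failed to converge: {exc}") from exc
    return popt, np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))


def _aic(series: HdxSeries, model: str) -> float:
    t = np.asarray(series.times, dtype=float)
    I = np.asarray(series.intensities, dtype=float)
    popt, _ = _fit(t, I, model)
    if model == "simple":
        pred = popt[0] * np.exp(-popt[1] * t)
        n_par = 2
    else:
        pred = popt[0] * np.exp(-popt[1] * t) + popt[2]
        n_par = 3
    rss = float(np.sum((I - pred) ** 2))
    n = len(t)
    return n * math.log(max(rss / n, 1e-300)) + 2 * n_par


@dataclass
class ProtectionResult:
    """Protection factor of one amide on the log10 scale."""

    residue_id: int
    k_exchange: float  # 1/min
    k_intrinsic: float  # 1/min
    logP: float
    fit_error: Optional[float] = None


def protection_factor(k_exchange: float, k_intrinsic: float) -> float:
    """log10 protection factor from observed and intrinsic exchange rates."""
    if k_exchange <= 0 or k_intrinsic <= 0:
        raise ValueError("exchange rates must be positive")
    return math.log10(k_intrinsic / k_exchange)


def protection_from_fits(
    fits: Sequence[DecayFit], k_intrinsic: Dict[int, float]
) -> List[ProtectionResult]:
    """Convert quantifiable decay fits to protection factors.

    Residues flagged fast/slow or lacking an intrinsic rate are skipped with
    a warning.
    """
    out = []
    for fit in fits:
        if fit.k_exchange is None:
            warnings.warn(
                f"residue {fit.residue_id}: {fit.flag or 'no rate'} — "
                "excluded from protection analysis", stacklevel=2,
            )
            continue
        if fit.residue_id not in k_intrinsic:
            warnings.warn(
                f"residue {fit.residue_id}: no intrinsic rate supplied",
                stacklevel=2,
            )
            continue
        ki = k_intrinsic[fit.residue_id]
        out.append(ProtectionResult(
            fit.residue_id, fit.k_exchange, ki,
            protection_factor(fit.k_exchange, ki), fit.k_stderr,
        ))
    return out


#: default specificity-surface summation set for SigmaLogP
SII_PROTECTION_RESIDUES = (17, 32, 33, 36)

#: wider loop-residue set also quantifiable in these complexes
SII_PROTECTION_RESIDUES_WIDE = (13, 14, 15, 16, 17, 32, 33, 35, 36, 49)


def sum_logp(
    results: Sequence[ProtectionResult],
    members: Sequence[int] = SII_PROTECTION_RESIDUES,
) -> float:
    """Sum of log10 protection factors over a residue set (SigmaLogP).

    Members lacking a quantifiable rate are excluded with a warning.
    """
    if not members:
        raise ValueError("empty member list")
    by_res = {r.residue_id: r for r in results}
    total = 0.0
    for res in members:
        if res not in by_res:
            warnings.warn(
                f"residue {res}: no quantifiable protection — excluded from "
                "SigmaLogP", stacklevel=2,
            )
            continue
        total += by_res[res].logP
    return total
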