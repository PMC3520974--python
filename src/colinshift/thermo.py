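"""Binding thermodynamics: isotherm fits, saturation, dG, dCp and correlations.

Single-site binding of peptide L to protein P with dissociation constant Kd
obeys the exact mass-balance quadratic

    [PL] = ((P0 + L0 + Kd) - sqrt((P0 + L0 + Kd)^2 - 4 P0 L0)) / 2,

used throughout instead of the weak-binding hyperbola because protein and
peptide concentrations here are comparable (tens of uM protein, uM-range Kd).
Titration shifts are fitted to shift_free + shift_max * fraction_bound; Kd is
converted to binding free energy via dG = R T ln(Kd); the heat-capacity
change is the OLS slope of dH versus temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

#: gas constant, kcal/(mol K)
R_KCAL = 0.0019872

#: default analysis temperature (the 30 C of the calorimetry), K
DEFAULT_TEMPERATURE = 303.15


def fraction_bound(kd: float, protein_total: float, ligand_total: float) -> float:
    """Bound fraction of protein from the exact single-site quadratic.

    All concentrations in the same units (uM); result in [0, 1].
    """
    if protein_total <= 0:
        raise ValueError("protein_total must be positive")
    if kd < 0 or ligand_total < 0:
        raise ValueError("kd and ligand_total must be nonnegative")
    if ligand_total == 0.0:
        return 0.0
    b = protein_total + ligand_total + kd
    disc = b * b - 4.0 * protein_total * ligand_total
    pl = (b - math.sqrt(max(disc, 0.0))) / 2.0
    return min(max(pl / protein_total, 0.0), 1.0)


def ligand_for_saturation(
    kd: float, protein_total: float, target: float = 0.99
) -> float:
    """Minimal total ligand giving at least the target bound fraction.

    Closed-form inversion of the quadratic: with [PL] = target * P0,
    L0 = [PL] + Kd * [PL] / (P0 - [PL]) = target * P0 + Kd * target / (1 - target).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target saturation must be in (0, 1)")
    if protein_total <= 0:
        raise ValueError("protein_total must be positive")
    return target * protein_total + kd * target / (1.0 - target)


def kd_to_dG(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy dG = R T ln(Kd [M]) in kcal/mol, for Kd in uM."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return R_KCAL * temperature * math.log(kd * 1e-6)


def dG_to_kd(dG: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`kd_to_dG`: Kd in uM from dG in kcal/mol."""
    return math.exp(dG / (R_KCAL * temperature)) * 1e6


# ---------------------------------------------------------------------------
# Titration fitting
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """One residue's shift response over a ligand titration."""

    protein_total: float  # uM
    points: List[Tuple[float, float]]  # (ligand_total uM, observed shift ppm)
    followed_residue: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 4:
            raise ValueError("need at least 4 titration points to fit")
        ligands = [l for l, _ in self.points]
        if any(b < a for a, b in zip(ligands, ligands[1:])):
            warnings.warn("ligand concentrations are not nondecreasing",
                          stacklevel=2)


@dataclass
class BindingFit:
    """Results of a single-site titration fit."""

    kd: float  # uM
    shift_max: float  # ppm
    shift_free: float  # ppm
    kd_ci95: float
    shift_max_ci95: float
    degenerate: bool = False
    model: "BindingModel" = field(default=None, repr=False)

    def predict(self, ligand_total: np.ndarray) -> np.ndarray:
        frac = np.array(
            [fraction_bound(self.kd, self.model.series.protein_total, L)
             for L in np.atleast_1d(ligand_total)]
        )
        return self.shift_free + self.shift_max * frac

    def summary(self) -> str:
        lines = [
            "Single-site binding fit",
            "=======================",
            f"n points        : {len(self.model.series.points)}",
            f"protein total   : {self.model.series.protein_total:g} uM",
            f"Kd              : {self.kd:.4g} uM  (+/- {self.kd_ci95:.2g}, 95% CI)",
            f"shift_max       : {self.shift_max:.4g} ppm  (+/- {self.shift_max_ci95:.2g})",
            f"shift_free      : {self.shift_free:.4g} ppm",
            f"dG (303.15 K)   : {kd_to_dG(self.kd):.3f} kcal/mol",
        ]
        if self.degenerate:
            lines.append("WARNING: flat response — fit is degenerate")
        return "\n".join(lines)


class BindingModel:
    """Single-site fast-exchange titration model for one followed resonance.

    ``fit()`` runs nonlinear least squares of
    shift(L) = shift_free + shift_max * fraction_bound(Kd, P0, L), fixing
    shift_free at the zero-ligand point when one is present.
    """

    def __init__(self, series: TitrationSeries):
        self.series = series

    def fit(self) -> BindingFit:
        L = np.array([p[0] for p in self.series.points], dtype=float)
        shift = np.array([p[1] for p in self.series.points], dtype=float)
        P0 = self.series.protein_total

        zero_idx = np.where(L == 0.0)[0]
        fix_free = len(zero_idx) > 0
        shift_free0 = float(shift[zero_idx[0]]) if fix_free else float(shift[0])

        span = float(shift.max() - shift.min())
        degenerate = span < 1e-6

        def frac(Lv: np.ndarray, kd: float) -> np.ndarray:
            return np.array([fraction_bound(kd, P0, x) for x in Lv])

        if fix_free:
            def model(Lv, kd, smax):
                return shift_free0 + smax * frac(Lv, kd)
            p0 = [max(P0 / 2.0, 1e-3), shift[-1] - shift_free0]
            bounds = ([1e-9, -np.inf], [np.inf, np.inf])
            n_par = 2
        else:
            def model(Lv, kd, smax, sfree):
                return sfree + smax * frac(Lv, kd)
            p0 = [max(P0 / 2.0, 1e-3), shift[-1] - shift_free0, shift_free0]
            bounds = ([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
            n_par = 3

        try:
            popt, pcov = optimize.curve_fit(
                model, L, shift, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"titration fit failed to converge: {exc}; "
                f"n={len(L)}, span={span:.4g} ppm"
            ) from exc
        dof = max(len(L) - n_par, 1)
        tcrit = stats.t.ppf(0.975, dof)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        kd, smax = float(popt[0]), float(popt[1])
        sfree = shift_free0 if fix_free else float(popt[2])
        if kd <= 2e-9:
            warnings.warn("fitted Kd at the lower bound", stacklevel=2)
        if degenerate:
            warnings.warn("flat titration response: degenerate fit",
                          stacklevel=2)
        return BindingFit(
            kd=kd,
            shift_max=abs(smax),
            shift_free=sfree,
            kd_ci95=float(tcrit * perr[0]),
            shift_max_ci95=float(tcrit * perr[1]),
            degenerate=degenerate,
            model=self,
        )


def fit_kd(series: TitrationSeries) -> BindingFit:
    """Convenience wrapper: ``BindingModel(series).fit()``."""
    return BindingModel(series).fit()


# ---------------------------------------------------------------------------
# Calorimetry and correlations
# ---------------------------------------------------------------------------

def fit_delta_cp(
    dH_by_T: Sequence[Tuple[float, float]]
) -> Tuple[float, float]:
    """Heat-capacity change as the OLS slope of dH (kcal/mol) vs T (K).

    Returns (slope, standard error of the slope); needs >= 3 temperatures.
    """
    if len(dH_by_T) < 3:
        raise ValueError("need at least 3 (temperature, dH) points")
    T = np.array([t for t, _ in dH_by_T], dtype=float)
    dH = np.array([h for _, h in dH_by_T], dtype=float)
    fit = stats.linregress(T, dH)
    return float(fit.slope), float(fit.stderr)


@dataclass
class CorrelationResult:
    """OLS correlation between two per-complex quantities."""

    x_name: str
    y_name: str
    slope: float
    intercept: float
    r_squared: float
    n: int

    def summary(self) -> str:
        return (
            f"{self.y_name} ~ {self.x_name}: slope={self.slope:.4g}, "
            f"intercept={self.intercept:.4g}, R^2={self.r_squared:.4f} "
            f"(rounded {self.r_squared:.2f}), n={self.n}"
        )


def correlate(
    x: Dict[str, float],
    y: Dict[str, float],
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """OLS of y on x over the complexes present (and finite) in both maps."""
    shared = sorted(
        k for k in set(x) & set(y)
        if np.isfinite(x[k]) and np.isfinite(y[k])
    )
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared complexes, got {len(shared)}")
    xv = np.array([x[k] for k in shared])
    yv = np.array([y[k] for k in shared])
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    fit = stats.linregress(xv, yv)
    return CorrelationResult(
        x_name, y_name, float(fit.slope), float(fit.intercept),
        float(fit.rvalue ** 2), len(shared),
    )


@dataclass
class GrowthThreshold:
    """Threshold-style reading of CCSP vs coded cell growth."""

    max_nongrower: Optional[float]
    min_grower: Optional[float]
    threshold: Optional[float]
    exceptions: List[str]
    separable: bool


def growth_threshold_analysis(
    ccsp_sii: Dict[str, float], growth: Dict[str, int]
) -> GrowthThreshold:
    """Estimate the SII engagement threshold separating growth from no growth.

    Growth codes are ordinal labels: 0 no growth, 3/6 partial/intermediate,
    8 full.  Non-growers are code 0; growers are code >= 6 (codes of 3 sit in
    the transition zone and do not define the threshold).  Non-growers whose
    CCSP reaches the grower range are reported as exceptions (peptides whose
    loss of function is not explained by SII engagement); the threshold is
    the midpoint between the remaining non-grower maximum and the grower
    minimum.
    """
    shared = sorted(k for k in set(ccsp_sii) & set(growth))
    if len(shared) < 4:
        raise ValueError("need >= 4 complexes with both CCSP and growth data")
    nongrow = {k: ccsp_sii[k] for k in shared if growth[k] == 0}
    grow = {k: ccsp_sii[k] for k in shared if growth[k] >= 6}
    if not nongrow or not grow:
        return GrowthThreshold(
            max_nongrower=max(nongrow.values()) if nongrow else None,
            min_grower=min(grow.values()) if grow else None,
            threshold=None, exceptions=[], separable=False,
        )
    min_grow = min(grow.values())
    exceptions = sorted(k for k, v in nongrow.items() if v >= min_grow)
    clean_nongrow = {k: v for k, v in nongrow.items() if k not in exceptions}
    max_nongrow = max(clean_nongrow.values()) if clean_nongrow else None
    exceptions += sorted(
        k for k, v in grow.items()
        if max_nongrow is not None and v <= max_nongrow
    )
    threshold = (
        (max_nongrow + min_grow) / 2.0 if max_nongrow is not None else None
    )
    return GrowthThreshold(
        max_nongrower=max_nongrow,
        min_grower=min_grow,
        threshold=threshold,
        exceptions=exceptions,
        separable=not exceptions,
    )
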