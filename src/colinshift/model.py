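"""Model/Results interface tying projection, screening and grouping together.

:class:`CCSPAnalysis` is constructed from assembled resonance series (or raw
peak sets) plus the analysis settings; ``fit()`` computes every per-complex
projection, applies the contamination screen, clusters the selected residues
and averages the configured groups, returning a :class:`CCSPResults` that
carries the tables, diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geometry, screening
from .geometry import CcspResult, ccsp_matrix, compute_series_results
from .grouping import (
    Dendrogram,
    GroupSpec,
    cluster_residues,
    default_groups,
    group_average_table,
    pairwise_group_r2,
)
from .io import assemble_series
from .peaks import ResonanceSeries, SeriesKey, ShiftUncertainty
from .screening import ScreenDecision, screen_dataset, screening_report
from .thermo import CorrelationResult, correlate


class CCSPAnalysis:
    """Co-linear chemical shift perturbation analysis of one dataset.

    Parameters
    ----------
    series : list of ResonanceSeries
        Per-residue peak series across free state, reference state and
        complexes (see :func:`colinshift.io.assemble_series`).
    groups : list of GroupSpec, optional
        Residue groups to average; defaults to the SI / SII / SII_RT sets.
    sigma : float
        Combined positional uncertainty per resonance, ppm (default 0.0051).
    min_delta, min_frac, rel_p_cut : float
        Contamination-screen thresholds (defaults 0.03 ppm, 0.60, 0.10).
    x_scale : float
        Scale factor applied to the indirect dimension (default 0.1).
    """

    def __init__(
        self,
        series: Sequence[ResonanceSeries],
        groups: Optional[Sequence[GroupSpec]] = None,
        sigma: float = 0.0051,
        min_delta: float = screening.DEFAULT_MIN_DELTA,
        min_frac: float = screening.DEFAULT_MIN_FRAC,
        rel_p_cut: float = screening.DEFAULT_REL_P_CUT,
        x_scale: float = geometry.DEFAULT_X_SCALE,
    ):
        if not series:
            raise ValueError("no resonance series supplied")
        self.series = list(series)
        self.groups = list(groups) if groups is not None else default_groups()
        self.sigma = sigma
        self.min_delta = min_delta
        self.min_frac = min_frac
        self.rel_p_cut = rel_p_cut
        self.x_scale = x_scale

    @classmethod
    def from_peak_sets(
        cls,
        free,
        ref,
        complexes,
        **kwargs,
    ) -> "CCSPAnalysis":
        """Build directly from free/reference/complex peak entry lists."""
        series, _ = assemble_series(free, ref, complexes)
        return cls(series, **kwargs)

    def fit(
        self,
        errors: str = "mc",
        n_draws: int = 10_000,
        seed: int = 0,
    ) -> "CCSPResults":
        """Run the full analysis.

        ``errors="mc"`` propagates the positional uncertainty through every
        projection by Monte Carlo (``n_draws`` draws, reproducible under
        ``seed``); ``errors="none"`` skips it.
        """
        if errors not in ("mc", "none"):
            raise ValueError("errors must be 'mc' or 'none'")
        unc = ShiftUncertainty(self.sigma) if errors == "mc" else None

        results_by_series: Dict[SeriesKey, List[CcspResult]] = {}
        degenerate: List[SeriesKey] = []
        for i, sr in enumerate(sorted(self.series, key=lambda s: s.key)):
            if not sr.complex_peaks:
                continue
            try:
                results_by_series[sr.key] = compute_series_results(
                    sr, unc=unc, n_draws=n_draws,
                    seed=seed + 1000 * i, x_scale=self.x_scale,
                )
            except geometry.DegenerateLineError:
                degenerate.append(sr.key)

        selected, rejected, class_summary = screen_dataset(
            results_by_series, self.min_delta, self.min_frac, self.rel_p_cut
        )
        selected_keys = {(d.residue_id, d.atom_tag) for d in selected}
        by_key = {sr.key: sr for sr in self.series}
        matrix_all = ccsp_matrix(
            [by_key[k] for k in results_by_series], x_scale=self.x_scale
        )
        matrix_sel = (
            ccsp_matrix([by_key[k] for k in sorted(selected_keys)],
                        x_scale=self.x_scale)
            if selected_keys else pd.DataFrame()
        )
        dendrogram = (
            cluster_residues(matrix_sel) if len(matrix_sel) >= 2 else None
        )
        group_table = (
            group_average_table(matrix_sel, self.groups)
            if len(matrix_sel) else None
        )
        return CCSPResults(
            model=self,
            results_by_series=results_by_series,
            degenerate_series=degenerate,
            screen_selected=selected,
            screen_rejected=rejected,
            screen_class_summary=class_summary,
            ccsp_all=matrix_all,
            ccsp_selected=matrix_sel,
            dendrogram=dendrogram,
            group_averages=group_table,
        )


@dataclass
class CCSPResults:
    """Fitted CCSP analysis: matrices, screen decisions, tree, group averages."""

    model: CCSPAnalysis
    results_by_series: Dict[SeriesKey, List[CcspResult]]
    degenerate_series: List[SeriesKey]
    screen_selected: List[ScreenDecision]
    screen_rejected: List[ScreenDecision]
    screen_class_summary: pd.DataFrame
    ccsp_all: pd.DataFrame
    ccsp_selected: pd.DataFrame
    dendrogram: Optional[Dendrogram]
    group_averages: Optional[pd.DataFrame]

    # -- accessors ---------------------------------------------------------

    @property
    def selected_keys(self) -> List[SeriesKey]:
        return sorted(
            (d.residue_id, d.atom_tag) for d in self.screen_selected
        )

    def group_means(self, group: str) -> Dict[str, float]:
        """Per-complex mean CCSP for one group (NaN cells omitted)."""
        if self.group_averages is None:
            raise ValueError("no group averages computed")
        col = self.group_averages[(group, "mean")]
        return {cid: float(v) for cid, v in col.items() if np.isfinite(v)}

    def screening_table(self) -> pd.DataFrame:
        return screening_report(self.screen_selected + self.screen_rejected)

    def cut_clusters(self, n_clusters: int) -> Dict[str, int]:
        if self.dendrogram is None:
            raise ValueError("no dendrogram (fewer than 2 selected residues)")
        return self.dendrogram.cut(n_clusters)

    # -- downstream statistics --------------------------------------------

    def correlate_groups(self, group_x: str, group_y: str) -> CorrelationResult:
        """OLS between two groups' per-complex average CCSP values."""
        slope, intercept, r2 = pairwise_group_r2(
            self.group_means(group_x), self.group_means(group_y)
        )
        n = len(
            set(self.group_means(group_x)) & set(self.group_means(group_y))
        )
        return CorrelationResult(
            f"CCSP[{group_x}]", f"CCSP[{group_y}]", slope, intercept, r2, n
        )

    def correlate_with(
        self, values: Dict[str, float], group: str = "SII",
        value_name: str = "value",
    ) -> CorrelationResult:
        """OLS between a group's average CCSP and an external per-complex map."""
        return correlate(
            self.group_means(group), values,
            x_name=f"CCSP[{group}]", y_name=value_name,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        n_series = len(self.model.series)
        lines = [
            "Co-linear chemical shift perturbation analysis",
            "==============================================",
            f"resonance series            : {n_series}",
            f"complexes                   : {self.ccsp_all.shape[1]}",
            f"degenerate lines (z = 0)    : {len(self.degenerate_series)}",
            f"screen thresholds           : z >= {self.model.min_delta} ppm, "
            f">= {100 * self.model.min_frac:.0f}% of complexes with p/z < "
            f"{self.model.rel_p_cut}",
            "",
            "Screen outcome by resonance class:",
            self.screen_class_summary.to_string(index=False),
            "",
            f"selected series             : {len(self.screen_selected)} "
            f"({', '.join(d.label for d in self.screen_selected)})",
        ]
        if self.group_averages is not None:
            lines += ["", "Group-average CCSP (%) by complex:",
                      self._group_summary_table().to_string()]
        return "\n".join(lines)

    def _group_summary_table(self) -> pd.DataFrame:
        out = {}
        for spec in self.model.groups:
            mean = self.group_averages[(spec.name, "mean")]
            ci = self.group_averages[(spec.name, "ci95")]
            out[spec.name] = mean.round(1).astype(str) + " +/- " + ci.round(1).astype(str)
        return pd.DataFrame(out)
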