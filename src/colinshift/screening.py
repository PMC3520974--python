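"""Contamination screen: which resonance series give trustworthy CCSP values.

Binding-surface residues can be perturbed directly by peptide sequence
differences ("contamination"), scattering their peaks off the CCSP line.  Two
rules decide whether a series is analysed further:

* the free->reference shift must be at least ``min_delta`` (default 0.03 ppm
  combined) — smaller lines cannot be examined accurately;
* at least ``min_frac`` (default 60%) of the complexes must sit close to the
  line, where "close" means a perpendicular distance below ``rel_p_cut``
  (default 10%) of the line length.

Both thresholds are inclusive (>=); nearness is strict (<).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .geometry import CcspResult

DEFAULT_MIN_DELTA = 0.03   # ppm, combined free->reference shift
DEFAULT_MIN_FRAC = 0.60    # fraction of complexes near the line
DEFAULT_REL_P_CUT = 0.10   # perpendicular distance / line length


class RejectReason(str, Enum):
    NONE = "none"
    SMALL_SHIFT = "small_shift"
    OFF_LINE = "off_line"


@dataclass
class ScreenDecision:
    """Outcome of the contamination screen for one resonance series."""

    residue_id: int
    atom_tag: str
    delta_free_ref: float
    n_complexes: int
    n_near_line: int
    selected: bool
    reject_reason: RejectReason

    @property
    def frac_near(self) -> float:
        return self.n_near_line / self.n_complexes if self.n_complexes else 0.0

    @property
    def label(self) -> str:
        return f"{self.residue_id}{'s' if self.atom_tag == 's' else ''}"


def screen_series(
    results: Sequence[CcspResult],
    min_delta: float = DEFAULT_MIN_DELTA,
    min_frac: float = DEFAULT_MIN_FRAC,
    rel_p_cut: float = DEFAULT_REL_P_CUT,
) -> ScreenDecision:
    """Apply the contamination screen to one series' per-complex results.

    Complexes with missing peaks never appear in ``results`` and therefore
    count in neither the numerator nor the denominator of the near-line
    fraction: absence of a peak is not evidence of contamination.
    """
    if not results:
        raise ValueError("cannot screen an empty result list")
    first = results[0]
    if any(
        (r.residue_id, r.atom_tag) != (first.residue_id, first.atom_tag)
        for r in results
    ):
        raise ValueError("results mix multiple series")
    z = first.z
    n = len(results)
    n_near = sum(1 for r in results if r.rel_perp < rel_p_cut)
    if z < min_delta:
        return ScreenDecision(
            first.residue_id, first.atom_tag, z, n, n_near,
            selected=False, reject_reason=RejectReason.SMALL_SHIFT,
        )
    if n_near / n >= min_frac:
        return ScreenDecision(
            first.residue_id, first.atom_tag, z, n, n_near,
            selected=True, reject_reason=RejectReason.NONE,
        )
    return ScreenDecision(
        first.residue_id, first.atom_tag, z, n, n_near,
        selected=False, reject_reason=RejectReason.OFF_LINE,
    )


def screen_dataset(
    results_by_series: Dict[Tuple[int, str], Sequence[CcspResult]],
    min_delta: float = DEFAULT_MIN_DELTA,
    min_frac: float = DEFAULT_MIN_FRAC,
    rel_p_cut: float = DEFAULT_REL_P_CUT,
) -> Tuple[List[ScreenDecision], List[ScreenDecision], pd.DataFrame]:
    """Screen every series; return (selected, rejected, per-class summary).

    The summary counts selections, small-shift rejections and off-line
    rejections separately for backbone NH, side-chain NH, and other (CH)
    series — the headline numbers of the screen.
    """
    selected: List[ScreenDecision] = []
    rejected: List[ScreenDecision] = []
    for key in sorted(results_by_series):
        decision = screen_series(
            results_by_series[key], min_delta, min_frac, rel_p_cut
        )
        (selected if decision.selected else rejected).append(decision)

    def _klass(tag: str) -> str:
        return {"bb": "backbone NH", "s": "side-chain NH"}.get(tag, "CH")

    rows = []
    for klass in ("backbone NH", "side-chain NH", "CH"):
        decisions = [
            d for d in selected + rejected if _klass(d.atom_tag) == klass
        ]
        if not decisions:
            continue
        rows.append({
            "class": klass,
            "n_series": len(decisions),
            "selected": sum(d.selected for d in decisions),
            "small_shift": sum(
                d.reject_reason == RejectReason.SMALL_SHIFT for d in decisions
            ),
            "off_line": sum(
                d.reject_reason == RejectReason.OFF_LINE for d in decisions
            ),
        })
    return selected, rejected, pd.DataFrame(rows)


def screening_report(decisions: Sequence[ScreenDecision]) -> pd.DataFrame:
    """Tabular report: one row per series with the screen's evidence."""
    return pd.DataFrame(
        {
            "residue": [d.label for d in decisions],
            "delta_free_ref_ppm": [d.delta_free_ref for d in decisions],
            "n_complexes": [d.n_complexes for d in decisions],
            "n_near_line": [d.n_near_line for d in decisions],
            "frac_near": [d.frac_near for d in decisions],
            "selected": [d.selected for d in decisions],
            "reject_reason": [d.reject_reason.value for d in decisions],
        }
    )
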