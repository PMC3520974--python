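"""Core data containers for 2D correlation peak positions and resonance series.

A resonance series collects the same amide (or CH) cross-peak of one residue
across a peptide-free spectrum, a reference fully-bound spectrum, and any
number of saturated complex spectra.  It is the unit on which co-linear
chemical shift perturbation (CCSP) analysis operates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple


class Nucleus(str, Enum):
    """Identity of the indirect dimension of the 2D correlation."""

    N15 = "N15"
    C13 = "C13"


#: Default plausibility windows (ppm) for amide correlations.  Peaks outside
#: trigger a warning only — unusual shifts are legal, just suspicious.
H_WINDOW = (4.0, 13.0)
N_WINDOW = (95.0, 140.0)


@dataclass(frozen=True)
class Peak2D:
    """One cross-peak position: proton shift plus a 15N or 13C shift (ppm)."""

    h_shift: float
    x_shift: float
    x_nucleus: Nucleus = Nucleus.N15

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.h_shift) and math.isfinite(self.x_shift)):
            raise ValueError("peak shifts must be finite")
        if self.x_nucleus == Nucleus.N15:
            if not (H_WINDOW[0] <= self.h_shift <= H_WINDOW[1]) or not (
                N_WINDOW[0] <= self.x_shift <= N_WINDOW[1]
            ):
                warnings.warn(
                    f"peak ({self.h_shift:.3f}, {self.x_shift:.3f}) ppm outside "
                    f"the usual amide window {H_WINDOW} x {N_WINDOW}",
                    stacklevel=2,
                )


# A series is keyed by (residue_id, atom_tag).  atom_tag is "bb" for the
# backbone NH, "s" for a side-chain NH (the "36s" convention), or a CH atom
# name such as "CA-HA" for aliphatic correlations.
SeriesKey = Tuple[int, str]


@dataclass
class ResonanceSeries:
    """One residue's peak across the free state, reference state and complexes."""

    residue_id: int
    atom_tag: str
    free_peak: Peak2D
    ref_peak: Peak2D
    complex_peaks: Dict[str, Peak2D] = field(default_factory=dict)

    @property
    def key(self) -> SeriesKey:
        return (self.residue_id, self.atom_tag)

    @property
    def label(self) -> str:
        """Human-readable label: '31' for backbone, '36s' for side chain."""
        if self.atom_tag == "bb":
            return str(self.residue_id)
        if self.atom_tag == "s":
            return f"{self.residue_id}s"
        return f"{self.residue_id}{self.atom_tag}"

    def n_complexes(self) -> int:
        return len(self.complex_peaks)


@dataclass
class ComplexRecord:
    """Per-complex metadata: peptide identity, binding thermodynamics, phenotype.

    ``growth_code`` uses the four-level coding of the plate-growth assay:
    0 no growth, 3 partial, 6 intermediate, 8 full growth.
    """

    complex_id: str
    peptide_name: str = ""
    peptide_sequence: Optional[str] = None
    saturation_fraction: Optional[float] = None
    kd: Optional[float] = None  # uM
    dG_B: Optional[float] = None  # kcal/mol
    dH_by_T: Optional[List[Tuple[float, float]]] = None  # (K, kcal/mol)
    dCp: Optional[float] = None  # kcal/(mol K)
    growth_code: Optional[int] = None

    #: minimum bound fraction for a complex to be usable in CCSP analysis
    SATURATION_CUTOFF = 0.99

    def __post_init__(self) -> None:
        if self.growth_code is not None and self.growth_code not in (0, 3, 6, 8):
            raise ValueError(
                f"growth_code must be one of 0/3/6/8, got {self.growth_code}"
            )
        if self.saturation_fraction is not None:
            if not 0.0 <= self.saturation_fraction <= 1.0:
                raise ValueError("saturation_fraction must be in [0, 1]")
            if self.saturation_fraction < self.SATURATION_CUTOFF:
                warnings.warn(
                    f"complex {self.complex_id!r} is only "
                    f"{100 * self.saturation_fraction:.1f}% saturated; shifts "
                    "may reflect free/bound exchange rather than bound-state "
                    "equilibria — excluded from CCSP unless overridden",
                    stacklevel=2,
                )

    @property
    def usable_for_ccsp(self) -> bool:
        return (
            self.saturation_fraction is None
            or self.saturation_fraction >= self.SATURATION_CUTOFF
        )


@dataclass(frozen=True)
class ShiftUncertainty:
    """Combined (1H, scaled 15N) positional uncertainty of one resonance, ppm.

    The default of 0.0051 ppm is the reproducibility of reference resonances
    that do not move across complexes (2.5 Hz at 500 MHz).
    """

    sigma_combined: float = 0.0051

    def __post_init__(self) -> None:
        if not self.sigma_combined > 0:
            raise ValueError("sigma_combined must be positive")
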