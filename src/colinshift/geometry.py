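"""CCSP geometry: combined shift distances, projections and error propagation.

All geometry lives in the scaled coordinate space (1H ppm, 0.1 x 15N ppm), in
which the combined chemical-shift difference

    deltaDelta = sqrt((0.1 * dN)^2 + dH^2)

between two peaks is the Euclidean distance.  For a residue whose peak moves
between a free-state endpoint and a fully-engaged reference endpoint, the
observed peak in any saturated complex is decomposed into a scalar projection
``s`` along the free->reference line (the CCSP line, length ``z``) and a
perpendicular distance ``p`` off it:

    s = (z^2 + x^2 - y^2) / (2 z)        (law of cosines)
    p = sqrt(x^2 - s^2)
    CCSP% = 100 * s / z

where x = |free->obs| and y = |obs->reference|.  Under two-state fast
exchange CCSP% estimates the population of the engaged conformer; ``p``
measures departure from two-state behaviour (e.g. sequence contamination).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import math

import numpy as np
import pandas as pd

from .peaks import Peak2D, ResonanceSeries, SeriesKey, ShiftUncertainty

#: scale applied to the indirect (15N or 13C) dimension before any geometry
DEFAULT_X_SCALE = 0.1

#: tolerance for clamping tiny negative x^2 - s^2 before the square root
_PERP_CLAMP = 1e-12


class DegenerateLineError(ValueError):
    """The free and reference peaks coincide: no CCSP line exists."""


@dataclass
class CcspResult:
    """Projection of one observed peak onto one residue's CCSP line.

    Lengths are ppm in scaled coordinates; ``ccsp_percent`` may legitimately
    fall outside [0, 100] when the observation lies beyond an endpoint.
    """

    residue_id: int
    atom_tag: str
    complex_id: str
    z: float
    x: float
    y: float
    s: float
    p: float
    ccsp_percent: float
    ccsp_error: Optional[float] = None

    @property
    def rel_perp(self) -> float:
        """Perpendicular distance as a fraction of the CCSP line length."""
        return self.p / self.z


def scaled_coords(peak: Peak2D, x_scale: float = DEFAULT_X_SCALE) -> np.ndarray:
    """Map a peak to the (H, x_scale * X) coordinate plane."""
    return np.array([peak.h_shift, x_scale * peak.x_shift])


def combined_shift_delta(
    a: Peak2D, b: Peak2D, x_scale: float = DEFAULT_X_SCALE
) -> float:
    """Combined 1H/15N (or 13C) chemical-shift distance between two peaks, ppm.

    The same indirect-dimension scale factor is applied to 13C as to 15N
    (configurable via ``x_scale``).
    """
    if a.x_nucleus != b.x_nucleus:
        raise ValueError(
            f"nucleus mismatch: {a.x_nucleus.value} vs {b.x_nucleus.value}"
        )
    return math.hypot(a.h_shift - b.h_shift, x_scale * (a.x_shift - b.x_shift))


def _project_lengths(z: float, x: float, y: float) -> Tuple[float, float]:
    """Law-of-cosines decomposition of the triangle with sides z, x, y."""
    s = (z * z + x * x - y * y) / (2.0 * z)
    p_sq = x * x - s * s
    if p_sq < 0.0:
        if p_sq < -_PERP_CLAMP:
            raise ValueError(
                f"triangle inequality violated beyond tolerance: x^2-s^2={p_sq}"
            )
        p_sq = 0.0
    return s, math.sqrt(p_sq)


def project_onto_line(
    free: Peak2D,
    ref: Peak2D,
    obs: Peak2D,
    *,
    residue_id: int = 0,
    atom_tag: str = "bb",
    complex_id: str = "",
    x_scale: float = DEFAULT_X_SCALE,
) -> CcspResult:
    """Project an observed peak onto the free->reference CCSP line.

    Observations beyond either endpoint are legal: they yield s < 0 or s > z
    and hence CCSP outside [0, 100]%, reported as computed.
    """
    z = combined_shift_delta(free, ref, x_scale)
    if z == 0.0:
        raise DegenerateLineError(
            f"residue {residue_id}{atom_tag}: free and reference peaks "
            "coincide (z = 0)"
        )
    x = combined_shift_delta(free, obs, x_scale)
    y = combined_shift_delta(obs, ref, x_scale)
    s, p = _project_lengths(z, x, y)
    return CcspResult(
        residue_id=residue_id,
        atom_tag=atom_tag,
        complex_id=complex_id,
        z=z,
        x=x,
        y=y,
        s=s,
        p=p,
        ccsp_percent=100.0 * s / z,
    )


def project_onto_line_vector(
    free: Peak2D, ref: Peak2D, obs: Peak2D, x_scale: float = DEFAULT_X_SCALE
) -> Tuple[float, float]:
    """Coordinate-space dot-product projection: independent route to (s, p).

    Used to cross-check the law-of-cosines formulas; both must agree to
    numerical precision.
    """
    f = scaled_coords(free, x_scale)
    r = scaled_coords(ref, x_scale)
    o = scaled_coords(obs, x_scale)
    line = r - f
    z = float(np.linalg.norm(line))
    if z == 0.0:
        raise DegenerateLineError("free and reference peaks coincide (z = 0)")
    d = o - f
    s = float(np.dot(d, line) / z)
    p = float(abs(d[0] * line[1] - d[1] * line[0]) / z)
    return s, p


def propagate_ccsp_error(
    free: Peak2D,
    ref: Peak2D,
    obs: Peak2D,
    unc: ShiftUncertainty = ShiftUncertainty(),
    n_draws: int = 10_000,
    seed: int = 0,
    x_scale: float = DEFAULT_X_SCALE,
) -> float:
    """Monte-Carlo propagated uncertainty of one CCSP value, percent.

    Each of the three peaks is perturbed by isotropic Gaussian noise of
    standard deviation ``unc.sigma_combined`` in scaled coordinates; the
    half-width of the central 95% interval of the resulting CCSP distribution
    is returned.  Reproducible under a fixed seed.  Draws in which the
    perturbed line degenerates are discarded; more than 10% discards raises.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    rng = np.random.default_rng(seed)
    pts = np.stack(
        [scaled_coords(free, x_scale), scaled_coords(ref, x_scale),
         scaled_coords(obs, x_scale)]
    )  # (3, 2)
    draws = pts[None, :, :] + rng.normal(
        0.0, unc.sigma_combined, size=(n_draws, 3, 2)
    )
    f, r, o = draws[:, 0, :], draws[:, 1, :], draws[:, 2, :]
    line = r - f
    z = np.linalg.norm(line, axis=1)
    # a drawn line shorter than the noise itself carries no direction
    # information; the projection onto it is meaningless
    ok = z > unc.sigma_combined
    n_discard = int(n_draws - ok.sum())
    if n_discard > 0.10 * n_draws:
        raise ValueError(
            f"{n_discard}/{n_draws} degenerate draws — line length comparable "
            "to the noise level; CCSP error undefined"
        )
    d = o - f
    s = np.einsum("ij,ij->i", d[ok], line[ok]) / z[ok]
    ccsp = 100.0 * s / z[ok]
    lo, hi = np.percentile(ccsp, [2.5, 97.5])
    return float((hi - lo) / 2.0)


def compute_series_results(
    series: ResonanceSeries,
    *,
    unc: Optional[ShiftUncertainty] = None,
    n_draws: int = 10_000,
    seed: int = 0,
    x_scale: float = DEFAULT_X_SCALE,
) -> List[CcspResult]:
    """All per-complex CCSP results for one series (optionally with errors)."""
    results = []
    for i, (cid, obs) in enumerate(sorted(series.complex_peaks.items())):
        res = project_onto_line(
            series.free_peak,
            series.ref_peak,
            obs,
            residue_id=series.residue_id,
            atom_tag=series.atom_tag,
            complex_id=cid,
            x_scale=x_scale,
        )
        # errors are only meaningful when the line dwarfs the noise; series
        # with shorter lines fail the small-shift screen regardless
        if unc is not None and res.z >= 4.0 * unc.sigma_combined:
            res.ccsp_error = propagate_ccsp_error(
                series.free_peak, series.ref_peak, obs, unc,
                n_draws=n_draws, seed=seed + i, x_scale=x_scale,
            )
        results.append(res)
    return results


def ccsp_matrix(
    series: Sequence[ResonanceSeries],
    selection: Optional[Set[SeriesKey]] = None,
    x_scale: float = DEFAULT_X_SCALE,
) -> pd.DataFrame:
    """Residue x complex table of CCSP percentages.

    Rows are labelled '31' / '36s'; cells are NaN where the complex lacks a
    peak for that series.  ``selection`` restricts rows to the given
    (residue, atom_tag) keys and raises if a key matches no series.
    """
    by_key = {sr.key: sr for sr in series}
    if selection is not None:
        unknown = set(selection) - set(by_key)
        if unknown:
            raise KeyError(f"selection references unknown series: {sorted(unknown)}")
        chosen = [by_key[k] for k in sorted(selection)]
    else:
        chosen = sorted(series, key=lambda sr: sr.key)
    complex_ids = sorted({cid for sr in chosen for cid in sr.complex_peaks})
    data = {}
    for sr in chosen:
        row = {}
        for cid in complex_ids:
            if cid in sr.complex_peaks:
                row[cid] = project_onto_line(
                    sr.free_peak, sr.ref_peak, sr.complex_peaks[cid],
                    residue_id=sr.residue_id, atom_tag=sr.atom_tag,
                    complex_id=cid, x_scale=x_scale,
                ).ccsp_percent
            else:
                row[cid] = np.nan
        data[sr.label] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=complex_ids)


def reference_resonance_sigma(
    series: Sequence[ResonanceSeries],
    reference_keys: Sequence[SeriesKey],
    x_scale: float = DEFAULT_X_SCALE,
) -> float:
    """Estimate the combined positional uncertainty from immobile resonances.

    Resonances that do not move across complexes scatter only by measurement
    noise, so their pooled per-coordinate standard deviation (in scaled
    coordinates, around each series' mean position) estimates the isotropic
    positional uncertainty sigma_combined of a single peak.  This is the
    quantity that defaults to 0.0051 ppm.
    """
    by_key = {sr.key: sr for sr in series}
    sq_sum, dof = 0.0, 0
    for key in reference_keys:
        sr = by_key[key]
        coords = np.array(
            [scaled_coords(p, x_scale) for p in sr.complex_peaks.values()]
        )
        n = len(coords)
        if n < 3:
            raise ValueError(f"series {key}: need >= 3 complexes")
        sq_sum += float(((coords - coords.mean(axis=0)) ** 2).sum())
        dof += 2 * (n - 1)  # two coordinates per peak
    return math.sqrt(sq_sum / dof)
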