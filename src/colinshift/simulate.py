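"""Synthetic data: planted fast-exchange ensembles, titrations and HDX decays.

The generative model mirrors the two-state fast-exchange picture underlying
CCSP analysis.  Every residue has a free-conformer endpoint and an
engaged-conformer endpoint in the scaled (1H, 0.1 x 15N) plane; in a complex
where its group's engaged population is pi, its peak sits at

    obs = free + pi * (engaged - free)          (population-weighted average)

plus an optional perpendicular contamination offset and isotropic Gaussian
positional noise.  Because the planted pi, offsets and endpoints are
recorded, every pipeline stage (projection, screening, clustering, group
averaging) can be tested for exact recovery without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .grouping import GroupSpec, default_groups
from .io import PeakEntry
from .peaks import Nucleus, Peak2D
from .thermo import TitrationSeries, fraction_bound
from .hdx import HdxSeries

SeriesKey = Tuple[int, str]

#: default line-length (ppm) ranges per group; the PxxP surface moves on
#: average ~4x less than the specificity surface
Z_RANGE_SI = (0.03, 0.12)
Z_RANGE_SII = (0.1, 0.5)


@dataclass
class SyntheticConfig:
    """Planted ground truth for one synthetic CCSP dataset.

    Residues not in any group are "inert" (zero line length; their peaks only
    jitter with noise) when ``allow_inert`` is set, mimicking the majority of
    a domain that does not respond to binding.
    """

    seed: int = 0
    n_residues: int = 59
    n_complexes: int = 24
    groups: List[GroupSpec] = field(default_factory=default_groups)
    noise_sigma: float = 0.0051  # ppm, per scaled coordinate
    #: per-group z range overrides; groups named SI* that are not the
    #: specificity surface default to the small-shift range
    z_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: engaged population per complex per group; generated if None
    populations: Optional[pd.DataFrame] = None  # index complex, columns group
    #: ((residue_id, atom_tag), complex_id) -> perpendicular offset, ppm
    contamination: Dict[Tuple[SeriesKey, str], float] = field(
        default_factory=dict
    )
    allow_inert: bool = True

    def complex_ids(self) -> List[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_complexes)]

    def group_of(self, key: SeriesKey) -> Optional[str]:
        for spec in self.groups:
            if key in spec.members:
                return spec.name
        return None

    def z_range(self, group: str) -> Tuple[float, float]:
        if group in self.z_ranges:
            return self.z_ranges[group]
        return Z_RANGE_SI if group == "SI" else Z_RANGE_SII


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _draw_populations(config: SyntheticConfig) -> pd.DataFrame:
    """Engaged populations per (complex, group), one draw per cell.

    Complexes span weak to full engagement (U[0.2, 1.0]), the observed range
    across real peptide variants; groups are drawn independently so that each
    group has a distinct profile.
    """
    rng = _rng(config.seed, 7)
    data = rng.uniform(
        0.2, 1.0, size=(config.n_complexes, len(config.groups))
    )
    return pd.DataFrame(
        data, index=config.complex_ids(),
        columns=[g.name for g in config.groups],
    )


def _endpoints(
    config: SyntheticConfig,
) -> Dict[SeriesKey, Tuple[np.ndarray, np.ndarray]]:
    """Per-series (free, engaged) endpoints in scaled coordinates.

    Free positions fall in the usual amide window; the engaged endpoint lies
    at a per-residue random angle so no two residues are accidentally
    collinear.
    """
    keys: List[SeriesKey] = [(r, "bb") for r in range(1, config.n_residues + 1)]
    for spec in config.groups:
        for key in spec.members:
            if key not in keys:
                keys.append(key)
    endpoints = {}
    for key in sorted(keys):
        residue, tag = key
        rng = _rng(config.seed, 11, residue, 0 if tag == "bb" else 1)
        f = np.array([rng.uniform(7.0, 9.5), 0.1 * rng.uniform(107.0, 130.0)])
        group = config.group_of(key)
        if group is None:
            if not config.allow_inert:
                raise ValueError(
                    f"residue {residue}{tag} belongs to no group and inert "
                    "residues are disabled"
                )
            z = 0.0
        else:
            z = rng.uniform(*config.z_range(group))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        a = f + z * np.array([math.cos(theta), math.sin(theta)])
        endpoints[key] = (f, a)
    return endpoints


def _to_peak(pos: np.ndarray) -> Peak2D:
    return Peak2D(float(pos[0]), float(pos[1] / 0.1), Nucleus.N15)


def generate_peaklists(
    config: SyntheticConfig,
) -> Tuple[List[PeakEntry], List[PeakEntry],
           Dict[str, List[PeakEntry]], pd.DataFrame]:
    """Generate (free, reference, per-complex peak sets, ground truth).

    The reference set is the fully-engaged complex (pi = 1 for every group);
    the free set has pi = 0.  All emitted peaks — including free and
    reference — carry isotropic Gaussian noise of ``noise_sigma`` per scaled
    coordinate, as every spectrum is a measurement.  Ground truth records the
    planted population, contamination offset, line length and group per
    (series, complex) cell.
    """
    populations = (
        config.populations
        if config.populations is not None
        else _draw_populations(config)
    )
    endpoints = _endpoints(config)
    cids = config.complex_ids()

    def noisy(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if config.noise_sigma == 0.0:
            return pos
        return pos + rng.normal(0.0, config.noise_sigma, size=2)

    free_set: List[PeakEntry] = []
    ref_set: List[PeakEntry] = []
    complex_sets: Dict[str, List[PeakEntry]] = {cid: [] for cid in cids}
    truth_rows = []
    for key in sorted(endpoints):
        residue, tag = key
        f, a = endpoints[key]
        z = float(np.linalg.norm(a - f))
        group = config.group_of(key)
        line = (a - f) / z if z > 0 else np.zeros(2)
        perp = np.array([-line[1], line[0]])
        rng_free = _rng(config.seed, 13, residue, 0 if tag == "bb" else 1)
        free_set.append((residue, tag, _to_peak(noisy(f, rng_free))))
        ref_set.append((residue, tag, _to_peak(noisy(a, rng_free))))
        for ci, cid in enumerate(cids):
            pi = float(populations.loc[cid, group]) if group else 0.0
            offset = config.contamination.get((key, cid), 0.0)
            pos = f + pi * (a - f) + offset * perp
            rng_c = _rng(config.seed, 17, residue,
                         0 if tag == "bb" else 1, ci)
            complex_sets[cid].append((residue, tag, _to_peak(noisy(pos, rng_c))))
            truth_rows.append({
                "residue": residue, "atom_tag": tag, "complex_id": cid,
                "group": group or "inert", "pi": pi, "z": z,
                "perp_offset": offset,
            })
    truth = pd.DataFrame(truth_rows)
    return free_set, ref_set, complex_sets, truth


def with_contaminated_residues(
    config: SyntheticConfig,
    keys: Sequence[SeriesKey],
    rel_offset: float = 0.2,
) -> SyntheticConfig:
    """Return a config that contaminates the given series in every complex.

    The perpendicular offset is ``rel_offset`` times the residue's planted
    line length — the worst case for the screen, since purely parallel
    contamination is undetectable by construction.
    """
    endpoints = _endpoints(config)
    contamination = dict(config.contamination)
    for key in keys:
        f, a = endpoints[key]
        z = float(np.linalg.norm(a - f))
        if z == 0.0:
            raise ValueError(f"series {key} is inert; contamination undefined")
        for cid in config.complex_ids():
            contamination[(key, cid)] = rel_offset * z
    return SyntheticConfig(
        seed=config.seed, n_residues=config.n_residues,
        n_complexes=config.n_complexes, groups=config.groups,
        noise_sigma=config.noise_sigma, z_ranges=config.z_ranges,
        populations=config.populations, contamination=contamination,
        allow_inert=config.allow_inert,
    )


def generate_multistate_peaklists(
    config: SyntheticConfig,
    memberships: Dict[SeriesKey, Set[str]],
    weights: pd.DataFrame,  # index complex, columns macro-states
) -> Tuple[List[PeakEntry], List[PeakEntry],
           Dict[str, List[PeakEntry]], pd.DataFrame]:
    """Generate peak lists from a multi-macro-state ensemble.

    ``memberships[key]`` names the macro-states in which that residue sits in
    its engaged conformer; a residue's CCSP in a complex is the summed weight
    of those states.  Distinct membership sets therefore produce distinct
    CCSP values inside one complex — evidence of more than two macro-states.
    """
    if not np.allclose(weights.sum(axis=1), 1.0):
        raise ValueError("macro-state weights must sum to 1 per complex")
    ccsp = pd.DataFrame(
        {
            str(key): weights[sorted(states)].sum(axis=1)
            for key, states in memberships.items()
        },
        index=weights.index,
    )
    populations = pd.DataFrame(index=weights.index)
    groups = []
    for key, states in sorted(memberships.items()):
        name = f"ms_{key[0]}{key[1]}"
        groups.append(GroupSpec(name, [key]))
        populations[name] = ccsp[str(key)]
    sub = SyntheticConfig(
        seed=config.seed, n_residues=config.n_residues,
        n_complexes=len(weights), groups=groups,
        noise_sigma=config.noise_sigma,
        z_ranges={g.name: config.z_range("SII") for g in groups},
        populations=populations.set_axis(
            [f"C{i + 1:02d}" for i in range(len(weights))]
        ),
        allow_inert=True,
    )
    free, ref, complexes, truth = generate_peaklists(sub)
    truth["complex_label"] = truth["complex_id"].map(
        dict(zip(sub.complex_ids(), weights.index))
    )
    return free, ref, complexes, truth


def generate_titration(
    kd: float,
    protein_total: float,
    shift_max: float,
    ligand_schedule: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    shift_free: float = 0.0,
) -> TitrationSeries:
    """Exact single-site binding curve plus Gaussian shift noise."""
    rng = _rng(seed, 23)
    points = []
    for L in ligand_schedule:
        shift = shift_free + shift_max * fraction_bound(kd, protein_total, L)
        if noise_sigma > 0:
            shift += rng.normal(0.0, noise_sigma)
        points.append((float(L), float(shift)))
    return TitrationSeries(protein_total, points)


def generate_hdx(
    k_true: Dict[int, float],
    sampling_minutes: float = 20.0,
    duration_minutes: float = 24 * 60.0,
    amplitude: float = 1000.0,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> List[HdxSeries]:
    """Exponential intensity decays with multiplicative Gaussian noise.

    Default sampling emulates one spectrum every 20 minutes over 24 hours.
    """
    times = np.arange(
        sampling_minutes, duration_minutes + sampling_minutes / 2,
        sampling_minutes,
    )
    out = []
    for residue, k in sorted(k_true.items()):
        if k < 0:
            raise ValueError("exchange rates must be nonnegative")
        rng = _rng(seed, 29, residue)
        ideal = amplitude * np.exp(-k * times)
        if noise_fraction > 0:
            ideal = ideal * (1.0 + rng.normal(0.0, noise_fraction,
                                              size=times.shape))
        out.append(HdxSeries(residue, times.tolist(),
                             np.clip(ideal, 0.0, None).tolist()))
    return out
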