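"""The planted fast-exchange generator: exactness, determinism, multi-state."""

import warnings

import numpy as np
import pandas as pd
import pytest

from colinshift import (
    CCSPAnalysis,
    GroupSpec,
    SyntheticConfig,
    generate_multistate_peaklists,
    generate_peaklists,
    generate_titration,
    fit_kd,
)
from colinshift.geometry import project_onto_line
from colinshift.io import assemble_series, write_peak_table


def _noise_free_config(pi_values, **kwargs):
    groups = [GroupSpec("SII", [(30, "bb"), (31, "bb"), (32, "bb")])]
    pops = pd.DataFrame(
        {"SII": pi_values},
        index=[f"C{i + 1:02d}" for i in range(len(pi_values))],
    )
    return SyntheticConfig(
        seed=3, n_residues=32, n_complexes=len(pi_values), groups=groups,
        noise_sigma=0.0, populations=pops, **kwargs,
    )


class TestGeneratePeaklists:
    def test_noise_free_population_maps_exactly_to_ccsp(self):
        config = _noise_free_config(pi_values=[0.6, 1.0])
        free, ref, complexes, truth = generate_peaklists(config)
        series, _ = assemble_series(free, ref, complexes)
        for sr in series:
            if sr.residue_id not in (30, 31, 32):
                continue
            r1 = project_onto_line(sr.free_peak, sr.ref_peak,
                                   sr.complex_peaks["C01"])
            r2 = project_onto_line(sr.free_peak, sr.ref_peak,
                                   sr.complex_peaks["C02"])
            assert r1.ccsp_percent == pytest.approx(60.0, abs=1e-9)
            assert r1.p == pytest.approx(0.0, abs=1e-12)
            assert r2.ccsp_percent == pytest.approx(100.0, abs=1e-9)

    def test_seed_determinism_byte_identical(self, tmp_path):
        files = []
        for run in ("a", "b"):
            config = SyntheticConfig(seed=17, n_complexes=4)
            free, _, _, _ = generate_peaklists(config)
            path = tmp_path / f"free_{run}.csv"
            write_peak_table(free, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_different_seeds_differ(self):
        a = generate_peaklists(SyntheticConfig(seed=1, n_complexes=2))[0]
        b = generate_peaklists(SyntheticConfig(seed=2, n_complexes=2))[0]
        assert any(pa.h_shift != pb.h_shift
                   for (_, _, pa), (_, _, pb) in zip(a, b))

    def test_ground_truth_records_planted_values(self):
        config = _noise_free_config(pi_values=[0.25, 0.75])
        _, _, _, truth = generate_peaklists(config)
        cell = truth[(truth.residue == 31) & (truth.complex_id == "C01")]
        assert cell.pi.item() == 0.25
        assert cell.group.item() == "SII"

    def test_inert_disallowed_raises(self):
        config = SyntheticConfig(seed=0, n_residues=59, allow_inert=False)
        with pytest.raises(ValueError, match="no group"):
            generate_peaklists(config)

    def test_small_line_groups_get_wider_ccsp_errors(self):
        """Groups with small shift changes carry larger propagated errors."""
        from colinshift import ShiftUncertainty, propagate_ccsp_error

        config = SyntheticConfig(seed=21, n_complexes=3)
        free, ref, complexes, truth = generate_peaklists(config)
        series, _ = assemble_series(free, ref, complexes)
        by_key = {sr.key: sr for sr in series}
        unc = ShiftUncertainty()

        def mean_error(keys):
            errs = []
            for key in keys:
                sr = by_key[key]
                for obs in sr.complex_peaks.values():
                    errs.append(propagate_ccsp_error(
                        sr.free_peak, sr.ref_peak, obs, unc,
                        n_draws=2000, seed=5))
            return np.mean(errs)

        si = mean_error([(9, "bb"), (11, "bb"), (25, "bb")])
        sii = mean_error([(30, "bb"), (31, "bb"), (37, "bb")])
        assert si > sii


class TestMultiState:
    WEIGHTS = pd.DataFrame(
        {"W": [0.4], "X": [0.2], "Y": [0.2], "Z": [0.2]}, index=["mix"]
    )

    def _ccsp_of(self, memberships, weights):
        config = SyntheticConfig(seed=4, n_residues=10, noise_sigma=0.0)
        free, ref, complexes, truth = generate_multistate_peaklists(
            config, memberships, weights
        )
        series, _ = assemble_series(free, ref, complexes)
        out = {}
        for sr in series:
            if sr.key not in memberships:  # inert residues have no line
                continue
            obs = sr.complex_peaks["C01"]
            out[sr.key] = project_onto_line(
                sr.free_peak, sr.ref_peak, obs
            ).ccsp_percent
        return out

    def test_membership_sets_sum_weights(self):
        memberships = {(1, "bb"): {"Z"}, (2, "bb"): {"X", "Y", "Z"}}
        ccsp = self._ccsp_of(memberships, self.WEIGHTS)
        assert ccsp[(1, "bb")] == pytest.approx(20.0, abs=1e-9)
        assert ccsp[(2, "bb")] == pytest.approx(60.0, abs=1e-9)

    def test_shared_membership_single_value(self):
        memberships = {(1, "bb"): {"Z"}, (2, "bb"): {"Z"}, (3, "bb"): {"Z"}}
        ccsp = self._ccsp_of(memberships, self.WEIGHTS)
        assert len({round(v, 6) for v in ccsp.values()}) == 1

    def test_all_weight_on_free_state_gives_zero(self):
        weights = pd.DataFrame(
            {"W": [1.0], "X": [0.0], "Y": [0.0], "Z": [0.0]}, index=["w"]
        )
        ccsp = self._ccsp_of({(1, "bb"): {"Z"}}, weights)
        assert ccsp[(1, "bb")] == pytest.approx(0.0, abs=1e-9)

    def test_unnormalised_weights_raise(self):
        weights = pd.DataFrame(
            {"W": [0.5], "X": [0.2], "Y": [0.2], "Z": [0.2]}, index=["bad"]
        )
        with pytest.raises(ValueError, match="sum to 1"):
            generate_multistate_peaklists(
                SyntheticConfig(seed=0, n_residues=5),
                {(1, "bb"): {"Z"}}, weights,
            )


class TestTitrationGenerator:
    def test_noiseless_round_trip(self):
        series = generate_titration(25.0, 100.0, 0.30,
                                    [0, 10, 25, 50, 100, 200, 400, 800])
        fit = fit_kd(series)
        assert abs(fit.kd - 25.0) / 25.0 < 1e-3

    def test_zero_ligand_point_is_shift_free(self):
        series = generate_titration(25.0, 100.0, 0.30, [0, 50, 100, 200],
                                    shift_free=8.1)
        assert series.points[0] == (0.0, 8.1)

    def test_seed_determinism(self):
        a = generate_titration(25.0, 100.0, 0.3, [0, 50, 100, 200],
                               noise_sigma=0.01, seed=6)
        b = generate_titration(25.0, 100.0, 0.3, [0, 50, 100, 200],
                               noise_sigma=0.01, seed=6)
        assert a.points == b.points
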