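"""End-to-end pipeline: config in, report bundle out.

A run configuration (YAML) names the free and reference peak lists, every
complex's peak list and optional metadata (Kd, binding free energy, growth
code), the screen thresholds and the output directory.  ``run_full``
assembles the series, fits the CCSP model and writes, in order: the CCSP
matrix, the screening report, the dendrogram, the group-average table, a
correlation table (when metadata permit) and a manifest recording versions,
seed, thresholds and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .grouping import GroupSpec, default_groups
from .io import load_run_config, read_peak_table, read_nmrstar_shifts
from .model import CCSPAnalysis, CCSPResults

log = logging.getLogger("colinshift")


@dataclass
class RunConfig:
    """Validated run configuration."""

    free_path: Path
    ref_complex: str
    complex_paths: Dict[str, Path]
    dialects: Dict[str, str] = field(default_factory=dict)
    metadata: Dict[str, dict] = field(default_factory=dict)
    groups: List[GroupSpec] = field(default_factory=default_groups)
    min_delta: float = 0.03
    min_frac: float = 0.60
    rel_p_cut: float = 0.10
    sigma: float = 0.0051
    temperature: float = 303.15
    outdir: Path = Path("colinshift_out")
    seed: int = 0
    errors: str = "mc"
    n_draws: int = 10_000

    def __post_init__(self) -> None:
        if self.ref_complex not in self.complex_paths:
            raise ValueError(
                f"reference complex {self.ref_complex!r} not among complexes "
                f"{sorted(self.complex_paths)}"
            )
        if not 0 < self.min_frac <= 1 or not 0 < self.rel_p_cut < 1:
            raise ValueError("screen thresholds out of range")
        if self.min_delta < 0 or self.sigma <= 0:
            raise ValueError("min_delta must be >= 0 and sigma > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = load_run_config(path)
        base = Path(path).parent
        complexes = cfg.get("complexes", {})
        default_dialect = cfg.get("dialect", "csv")
        paths, metadata = {}, {}
        dialects = {"__free__": default_dialect}
        for cid, entry in complexes.items():
            if isinstance(entry, str):
                paths[cid] = base / entry
                dialects[cid] = default_dialect
            else:
                paths[cid] = base / entry["path"]
                dialects[cid] = entry.get("dialect", default_dialect)
                metadata[cid] = entry.get("meta", {})
        groups = default_groups()
        if "groups" in cfg:
            groups = [
                GroupSpec(name, [tuple(m) if isinstance(m, list)
                                 else (int(m), "bb") for m in members])
                for name, members in cfg["groups"].items()
            ]
        screen = cfg.get("screen", {})
        return cls(
            free_path=base / cfg["free"],
            ref_complex=cfg["reference_complex"],
            complex_paths=paths,
            dialects=dialects,
            metadata=metadata,
            groups=groups,
            min_delta=screen.get("min_delta", 0.03),
            min_frac=screen.get("min_frac", 0.60),
            rel_p_cut=screen.get("rel_p_cut", 0.10),
            sigma=cfg.get("sigma", 0.0051),
            temperature=cfg.get("temperature", 303.15),
            outdir=Path(cfg.get("outdir", "colinshift_out")),
            seed=cfg.get("seed", 0),
            errors=cfg.get("errors", "mc"),
            n_draws=cfg.get("n_draws", 10_000),
        )


def _read(path: Path, dialect: str):
    if dialect == "nmrstar":
        return read_nmrstar_shifts(path)
    return read_peak_table(path, dialect)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> Dict[str, Path]:
    """Run the complete analysis; returns a name -> path map of artifacts.

    Any stage failure raises with a stage-named message; artifacts written
    before the failure are retained.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("read")
        free = _read(config.free_path, config.dialects.get("__free__", "csv"))
        complexes = {
            cid: _read(path, config.dialects.get(cid, "csv"))
            for cid, path in sorted(config.complex_paths.items())
        }
        ref = complexes[config.ref_complex]
        log.info("read %d free peaks, %d complexes", len(free), len(complexes))
    except Exception as exc:
        raise RuntimeError(f"[read] {exc}") from exc

    try:
        _stage("fit")
        analysis = CCSPAnalysis.from_peak_sets(
            free, ref, complexes,
            groups=config.groups, sigma=config.sigma,
            min_delta=config.min_delta, min_frac=config.min_frac,
            rel_p_cut=config.rel_p_cut,
        )
        results = analysis.fit(
            errors=config.errors, n_draws=config.n_draws, seed=config.seed
        )
        log.info(
            "screen: %d selected, %d rejected",
            len(results.screen_selected), len(results.screen_rejected),
        )
    except Exception as exc:
        raise RuntimeError(f"[fit] {exc}") from exc

    try:
        _stage("write")
        p = outdir / "ccsp_matrix.csv"
        results.ccsp_all.to_csv(p)
        artifacts["ccsp_matrix"] = p

        p = outdir / "ccsp_selected.csv"
        results.ccsp_selected.to_csv(p)
        artifacts["ccsp_selected"] = p

        p = outdir / "screening.tsv"
        results.screening_table().to_csv(p, sep="\t", index=False)
        artifacts["screening"] = p

        if results.dendrogram is not None:
            p = outdir / "dendrogram.newick"
            p.write_text(results.dendrogram.to_newick() + "\n")
            artifacts["dendrogram"] = p

        if results.group_averages is not None:
            p = outdir / "group_averages.csv"
            results.group_averages.to_csv(p)
            artifacts["group_averages"] = p

        p = outdir / "summary.txt"
        p.write_text(results.summary() + "\n")
        artifacts["summary"] = p
    except Exception as exc:
        raise RuntimeError(f"[write] {exc}") from exc

    try:
        _stage("correlate")
        corr_rows = []
        groups = [g.name for g in config.groups]
        for i, gx in enumerate(groups):
            for gy in groups[i + 1:]:
                try:
                    c = results.correlate_groups(gx, gy)
                    corr_rows.append({
                        "x": c.x_name, "y": c.y_name, "slope": c.slope,
                        "intercept": c.intercept, "r_squared": c.r_squared,
                        "n": c.n,
                    })
                except ValueError as exc:
                    log.warning("correlation %s~%s skipped: %s", gx, gy, exc)
        for quantity in ("dG_B", "dCp", "growth_code"):
            values = {
                cid: meta[quantity]
                for cid, meta in config.metadata.items()
                if meta.get(quantity) is not None
            }
            if len(values) >= 3:
                try:
                    c = results.correlate_with(values, "SII", quantity)
                    corr_rows.append({
                        "x": c.x_name, "y": c.y_name, "slope": c.slope,
                        "intercept": c.intercept, "r_squared": c.r_squared,
                        "n": c.n,
                    })
                except ValueError as exc:
                    log.warning("correlation vs %s skipped: %s", quantity, exc)
        if corr_rows:
            p = outdir / "correlations.tsv"
            pd.DataFrame(corr_rows).to_csv(p, sep="\t", index=False)
            artifacts["correlations"] = p
    except Exception as exc:
        raise RuntimeError(f"[correlate] {exc}") from exc

    _stage("manifest")
    manifest = {
        "colinshift_version": __version__,
        "seed": config.seed,
        "sigma": config.sigma,
        "thresholds": {
            "min_delta": config.min_delta,
            "min_frac": config.min_frac,
            "rel_p_cut": config.rel_p_cut,
        },
        "reference_complex": config.ref_complex,
        "n_series": len(analysis.series),
        "n_selected": len(results.screen_selected),
        "artifacts": {k: _sha256(v) for k, v in sorted(artifacts.items())},
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = p
    return artifacts
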