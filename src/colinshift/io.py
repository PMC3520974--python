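"""Readers and writers for peak lists, NMR-STAR shift loops, and run configs.

Supported inputs:

* NMR-STAR v2/v3 chemical-shift depositions (BMRB dialect) — only the
  assigned-chemical-shift loop is consumed; H and N (or C) shifts are paired
  per residue into 2D peaks.
* Sparky-style whitespace peak lists (``F31N-H  120.45  8.21``).
* CSV peak tables with header ``residue,atom,h_ppm,x_ppm``.
* YAML run configuration mapping free/reference/complex peak lists plus
  per-complex metadata.
"""

from __future__ import annotations

import csv
import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import yaml

from .peaks import ComplexRecord, Nucleus, Peak2D, ResonanceSeries, SeriesKey

PeakEntry = Tuple[int, str, Peak2D]


class PeakListFormatError(ValueError):
    """Raised when an input file cannot be parsed as a peak list."""


class EmptyResultError(ValueError):
    """Raised when a parse succeeds but yields no usable peaks."""


# ---------------------------------------------------------------------------
# NMR-STAR
# ---------------------------------------------------------------------------

# v3 and v2 tag names for the columns we need, lower-cased.
_STAR_TAGS = {
    "seq": ("_atom_chem_shift.comp_index_id", "_atom_chem_shift.seq_id",
            "_residue_seq_code"),
    "atom": ("_atom_chem_shift.atom_id", "_atom_name"),
    "value": ("_atom_chem_shift.val", "_chem_shift_value"),
    "chain": ("_atom_chem_shift.entity_assembly_id", "_mol_system_component_name"),
}

#: side-chain NH pairings recognised when pairing H with N per residue
_SIDECHAIN_PAIRS = (("NE1", "HE1"), ("ND2", "HD21"), ("NE2", "HE21"),
                    ("ND1", "HD1"), ("NE", "HE"))


def _iter_star_loops(text: str):
    """Yield (tags, rows) for every loop in an NMR-STAR file.

    This is a purposely small reader: it understands ``loop_`` / ``stop_``
    blocks with whitespace-delimited values, which covers BMRB chemical-shift
    loops in both v2 and v3 dialects.
    """
    tokens: List[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        tokens.extend(stripped.split())
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags: List[str] = []
        while i < n and tokens[i].startswith("_"):
            tags.append(tokens[i].lower())
            i += 1
        values: List[str] = []
        while i < n and tokens[i].lower() not in ("stop_", "loop_") \
                and not tokens[i].startswith("save_"):
            values.append(tokens[i])
            i += 1
        if i < n and tokens[i].lower() == "stop_":
            i += 1
        if tags and values and len(values) % len(tags) == 0:
            rows = [values[j:j + len(tags)] for j in range(0, len(values), len(tags))]
            yield tags, rows


def _find_column(tags: Sequence[str], names: Sequence[str]) -> int:
    for name in names:
        if name in tags:
            return tags.index(name)
    return -1


def read_nmrstar_shifts(path, chain_selector: str = "") -> List[PeakEntry]:
    """Read an NMR-STAR chemical-shift deposition and pair shifts into 2D peaks.

    Parameters
    ----------
    path : path-like
        NMR-STAR v2 or v3 file containing an assigned-chemical-shift loop.
    chain_selector : str
        If nonempty, keep only rows whose chain/entity column equals it.

    Returns
    -------
    list of (residue_id, atom_tag, Peak2D)
        One entry per residue for which both the H and the N (or C) dimension
        are present.  Residues with unpairable shifts are reported through
        ``warnings.warn`` rather than silently dropped.
    """
    text = Path(path).read_text()
    shift_rows: List[Tuple[int, str, float]] = []
    for tags, rows in _iter_star_loops(text):
        seq_col = _find_column(tags, _STAR_TAGS["seq"])
        atom_col = _find_column(tags, _STAR_TAGS["atom"])
        val_col = _find_column(tags, _STAR_TAGS["value"])
        if min(seq_col, atom_col, val_col) < 0:
            continue
        chain_col = _find_column(tags, _STAR_TAGS["chain"])
        for row in rows:
            if chain_selector and chain_col >= 0 and row[chain_col] != chain_selector:
                continue
            try:
                seq = int(row[seq_col])
                value = float(row[val_col])
            except ValueError:
                continue
            shift_rows.append((seq, row[atom_col].upper(), value))
    if not shift_rows:
        if "loop_" not in text.lower():
            raise PeakListFormatError(f"{path}: no NMR-STAR loops found")
        raise EmptyResultError(f"{path}: no chemical-shift rows parsed")

    by_residue: Dict[int, Dict[str, float]] = {}
    for seq, atom, value in shift_rows:
        by_residue.setdefault(seq, {})[atom] = value

    entries: List[PeakEntry] = []
    for seq in sorted(by_residue):
        atoms = by_residue[seq]
        paired = set()
        if "H" in atoms and "N" in atoms:
            entries.append((seq, "bb", Peak2D(atoms["H"], atoms["N"], Nucleus.N15)))
            paired.update(("H", "N"))
        for n_atom, h_atom in _SIDECHAIN_PAIRS:
            if n_atom in atoms and h_atom in atoms:
                entries.append(
                    (seq, "s", Peak2D(atoms[h_atom], atoms[n_atom], Nucleus.N15))
                )
                paired.update((n_atom, h_atom))
        leftovers = [a for a in atoms if a not in paired and a in
                     ("H", "N") + tuple(x for pair in _SIDECHAIN_PAIRS for x in pair)]
        if leftovers:
            warnings.warn(
                f"residue {seq}: unpaired shift(s) {leftovers} skipped",
                stacklevel=2,
            )
    if not entries:
        raise EmptyResultError(f"{path}: no pairable H/N shifts")
    return entries


# ---------------------------------------------------------------------------
# Peak tables (Sparky / CSV)
# ---------------------------------------------------------------------------

_SPARKY_LABEL = re.compile(r"^[A-Za-z]{0,3}(\d+)(s?)[A-Za-z0-9\-]*$")


def _parse_label(label: str) -> Tuple[int, str]:
    """Extract (residue_id, atom_tag) from a peak label.

    Accepts Sparky assignments (``F31N-H``), bare numbers (``31``) and the
    side-chain convention (``36s`` or ``N59sN-H``).
    """
    m = _SPARKY_LABEL.match(label)
    if not m:
        raise PeakListFormatError(f"cannot parse peak label {label!r}")
    residue = int(m.group(1))
    tag = "s" if m.group(2) == "s" or label.endswith("s") else "bb"
    return residue, tag


def read_peak_table(path, dialect: str = "sparky") -> List[PeakEntry]:
    """Read a Sparky whitespace peak list or a CSV peak table.

    Sparky rows are ``label  x_ppm(15N/13C)  h_ppm``; CSV files carry a header
    ``residue,atom,h_ppm,x_ppm`` where ``atom`` is ``bb`` (or blank) for the
    backbone NH and ``s`` for the side-chain NH.

    Raises on a duplicate (residue, atom_tag) within one file, naming it.
    """
    path = Path(path)
    entries: List[PeakEntry] = []
    seen: set = set()

    def _add(residue: int, tag: str, peak: Peak2D) -> None:
        key = (residue, tag)
        if key in seen:
            raise PeakListFormatError(
                f"{path}: duplicate peak for residue {residue} tag {tag!r}"
            )
        seen.add(key)
        entries.append((residue, tag, peak))

    if dialect == "sparky":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "Assignment", "w1")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise PeakListFormatError(f"{path}: short row {line!r}")
            residue, tag = _parse_label(parts[0])
            x_ppm, h_ppm = float(parts[1]), float(parts[2])
            _add(residue, tag, Peak2D(h_ppm, x_ppm))
    elif dialect == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"residue", "h_ppm", "x_ppm"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise PeakListFormatError(
                    f"{path}: CSV must have columns residue,atom,h_ppm,x_ppm"
                )
            for row in reader:
                label = str(row["residue"]).strip()
                atom = (row.get("atom") or "").strip()
                if label.endswith("s") and not atom:
                    residue, tag = int(label[:-1]), "s"
                else:
                    residue = int(label)
                    tag = atom if atom else "bb"
                _add(residue, tag, Peak2D(float(row["h_ppm"]), float(row["x_ppm"])))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return entries


def write_peak_table(entries: Iterable[PeakEntry], path, dialect: str = "csv") -> None:
    """Write a peak table; CSV preserves shifts to 10 decimal places."""
    path = Path(path)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["residue", "atom", "h_ppm", "x_ppm"])
            for residue, tag, peak in entries:
                writer.writerow(
                    [residue, tag, f"{peak.h_shift:.10f}", f"{peak.x_shift:.10f}"]
                )
    elif dialect == "sparky":
        with path.open("w") as fh:
            fh.write("Assignment  w1  w2\n")
            for residue, tag, peak in entries:
                label = f"X{residue}{'s' if tag == 's' else ''}N-H"
                fh.write(f"{label}  {peak.x_shift:.10f}  {peak.h_shift:.10f}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Series assembly
# ---------------------------------------------------------------------------

def assemble_series(
    free: Sequence[PeakEntry],
    ref: Sequence[PeakEntry],
    complexes: Dict[str, Sequence[PeakEntry]],
) -> Tuple[List[ResonanceSeries], Dict[SeriesKey, int]]:
    """Assemble per-residue resonance series across free, reference and complexes.

    A series exists for every (residue, atom_tag) present in BOTH the free and
    the reference peak set; complexes missing that residue simply lack an
    entry.  Returns the series list plus a completeness report mapping each
    series key to the number of complexes carrying its peak.

    Raises
    ------
    ValueError
        If the free and reference sets share no residues (numbering mismatch).
    """
    free_map = {(r, t): p for r, t, p in free}
    ref_map = {(r, t): p for r, t, p in ref}
    shared = sorted(set(free_map) & set(ref_map))
    if not shared:
        raise ValueError(
            "free and reference peak sets share no (residue, atom) keys — "
            "check residue numbering"
        )
    complex_maps = {
        cid: {(r, t): p for r, t, p in entries} for cid, entries in complexes.items()
    }
    only_complexes = set().union(*complex_maps.values()) - set(shared) \
        if complex_maps else set()
    if only_complexes:
        warnings.warn(
            f"{len(only_complexes)} (residue, atom) keys appear in complexes "
            f"but not in both free and reference sets: "
            f"{sorted(only_complexes)[:8]}...",
            stacklevel=2,
        )
    series_list: List[ResonanceSeries] = []
    report: Dict[SeriesKey, int] = {}
    for key in shared:
        residue, tag = key
        peaks = {
            cid: cmap[key] for cid, cmap in complex_maps.items() if key in cmap
        }
        series_list.append(
            ResonanceSeries(residue, tag, free_map[key], ref_map[key], peaks)
        )
        report[key] = len(peaks)
    return series_list, report


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_run_config(path) -> dict:
    """Load a YAML run configuration (file paths, thresholds, metadata).

    The schema is documented in :mod:`colinshift.pipeline`.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PeakListFormatError(f"{path}: run config must be a mapping")
    return cfg


def complex_records_from_config(cfg: dict) -> Dict[str, ComplexRecord]:
    """Build ComplexRecord metadata from the ``complexes`` config section."""
    records = {}
    for cid, entry in cfg.get("complexes", {}).items():
        meta = entry.get("meta", {}) if isinstance(entry, dict) else {}
        records[cid] = ComplexRecord(
            complex_id=cid,
            peptide_name=meta.get("peptide_name", cid),
            peptide_sequence=meta.get("peptide_sequence"),
            saturation_fraction=meta.get("saturation_fraction"),
            kd=meta.get("kd"),
            dG_B=meta.get("dG_B"),
            dCp=meta.get("dCp"),
            growth_code=meta.get("growth_code"),
        )
    return records
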