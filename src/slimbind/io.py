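"""Readers and writers for the package's text file dialects.

All inputs are plain delimited text so that datasets and results remain
diffable and portable:

* peak tables -- one row per (residue, ligand point):
  ``residue,h_ppm,n_ppm,intensity,ligand_uM,protein_uM`` with a header
  and optional ``#`` comments;
* dispersion tables -- ``residue,field_mhz,nu_cpmg_hz,intensity`` rows
  plus a ``# t_cpmg_s: <value>`` header line; rows with
  ``nu_cpmg_hz == 0`` carry the reference intensities I0 per
  (residue, field);
* disorder masks -- ``protein_id<TAB>start<TAB>end`` with 0-based,
  half-open coordinates (stated in the header comment);
* proteomes -- standard FASTA via Biopython;
* trajectories -- a whitespace XYZ-per-frame dialect with an inline
  atom table and a declared unit.

Readers validate invariants on load and fail with row context rather
than returning partially parsed objects.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import TitrationPoint, TitrationSeries
from .census import DisorderMask, ProteomeSet
from .cpmg import DispersionCurve, DispersionDataset, r2eff_from_intensity
from .traj import PeptideTrajectory

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peak_table",
    "write_peak_table",
    "read_dispersion_table",
    "write_dispersion_table",
    "read_mask",
    "write_mask",
    "read_trajectory",
    "write_trajectory",
]


def _require_file(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.stat().st_size == 0:
        raise ValueError(f"{p}: empty input file")
    return p


def read_fasta(path) -> ProteomeSet:
    """FASTA -> ProteomeSet; ids taken up to the first whitespace,
    sequences uppercased, duplicate ids rejected."""
    p = _require_file(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(p), "fasta"):
        pid = rec.id
        if pid in records:
            raise ValueError(f"{p}: duplicate protein id {pid!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{p}: empty sequence for {pid!r}")
        records[pid] = seq
    if not records:
        raise ValueError(f"{p}: no FASTA records found")
    return ProteomeSet(records=records, provenance=str(p))


def write_fasta(proteome: ProteomeSet, path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.records.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


_PEAK_COLS = ["residue", "h_ppm", "n_ppm", "intensity", "ligand_uM", "protein_uM"]


def read_peak_table(path) -> TitrationSeries:
    p = _require_file(path)
    df = pd.read_csv(p, comment="#", skip_blank_lines=True)
    missing = set(_PEAK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{p}: missing columns {sorted(missing)}")
    points = []
    for row in df.itertuples(index=False):
        try:
            points.append(
                TitrationPoint(
                    residue_id=str(row.residue),
                    shift_h=float(row.h_ppm),
                    shift_n=float(row.n_ppm),
                    intensity=float(row.intensity),
                    ligand_total=float(row.ligand_uM),
                    protein_total=float(row.protein_uM),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{p}: bad row {tuple(row)!r}: {exc}") from exc
    return TitrationSeries.from_points(points)


def write_peak_table(series: TitrationSeries, path) -> None:
    rows = []
    for rid in series.residues:
        for pt in series.points[rid]:
            rows.append(
                (pt.residue_id, pt.shift_h, pt.shift_n, pt.intensity,
                 pt.ligand_total, pt.protein_total)
            )
    df = pd.DataFrame(rows, columns=_PEAK_COLS)
    with open(path, "w") as fh:
        fh.write("# amide peak table: one row per (residue, titration point)\n")
        df.to_csv(fh, index=False)


def read_dispersion_table(path, sigma_floor: float = 0.3) -> DispersionDataset:
    """Dispersion table -> DispersionDataset.

    Rows with ``nu_cpmg_hz == 0`` supply the reference intensity I0 of
    their (residue, field) block; every other intensity is converted to
    R2,eff through the fixed-delay log-ratio.
    """
    p = _require_file(path)
    t_cpmg = None
    with open(p) as fh:
        for line in fh:
            if line.startswith("#") and "t_cpmg_s:" in line:
                t_cpmg = float(line.split("t_cpmg_s:")[1].strip())
    if t_cpmg is None:
        raise ValueError(f"{p}: missing '# t_cpmg_s: <value>' header")
    df = pd.read_csv(p, comment="#", skip_blank_lines=True)
    need = {"residue", "field_mhz", "nu_cpmg_hz", "intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"{p}: missing columns {sorted(need - set(df.columns))}")
    curves = []
    for (rid, field), grp in df.groupby(["residue", "field_mhz"], sort=False):
        ref = grp[grp.nu_cpmg_hz == 0]
        if len(ref) != 1:
            raise ValueError(
                f"{p}: residue {rid} at {field} MHz needs exactly one "
                f"nu_cpmg_hz == 0 reference row, found {len(ref)}"
            )
        i0 = float(ref.intensity.iloc[0])
        rest = grp[grp.nu_cpmg_hz > 0]
        if rest.empty:
            raise ValueError(f"{p}: residue {rid} at {field} MHz has no CPMG rows")
        r2 = np.array(
            [r2eff_from_intensity(float(i), i0, t_cpmg) for i in rest.intensity]
        )
        curves.append(
            DispersionCurve(
                residue_id=str(rid),
                field_mhz=float(field),
                t_cpmg=t_cpmg,
                nu_cpmg=rest.nu_cpmg_hz.to_numpy(dtype=float),
                r2_eff=r2,
                i0=i0,
            )
        )
    return DispersionDataset(curves)


def write_dispersion_table(dataset: DispersionDataset, path) -> None:
    if not dataset.curves:
        raise ValueError("empty dispersion dataset")
    t_cpmg = dataset.curves[0].t_cpmg
    rows = []
    for c in dataset.curves:
        if c.t_cpmg != t_cpmg:
            raise ValueError("one file carries a single t_cpmg; split datasets")
        rows.append((c.residue_id, c.field_mhz, 0.0, c.i0))
        for nu, r2 in zip(c.nu_cpmg, c.r2_eff):
            rows.append((c.residue_id, c.field_mhz, nu, c.i0 * math.exp(-r2 * t_cpmg)))
    df = pd.DataFrame(rows, columns=["residue", "field_mhz", "nu_cpmg_hz", "intensity"])
    with open(path, "w") as fh:
        fh.write("# CPMG dispersion intensities; nu_cpmg_hz == 0 rows are I0 references\n")
        fh.write(f"# t_cpmg_s: {t_cpmg}\n")
        df.to_csv(fh, index=False)


def read_mask(path, proteome: ProteomeSet | None = None) -> DisorderMask:
    """3-column disorder mask (protein_id, start, end), 0-based
    half-open; validated against ``proteome`` when given."""
    p = _require_file(path)
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(p) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{p}:{ln}: expected 3 columns, got {len(parts)}")
            pid, start, end = parts[0], int(parts[1]), int(parts[2])
            intervals.setdefault(pid, []).append((start, end))
    for pid in intervals:
        intervals[pid].sort()
    mask = DisorderMask(intervals=intervals)
    if proteome is not None:
        mask.validate_against(proteome)
    return mask


def write_mask(mask: DisorderMask, path) -> None:
    with open(path, "w") as fh:
        fh.write("# disorder intervals, 0-based half-open: protein_id start end\n")
        for pid, ivals in mask.intervals.items():
            for a, b in ivals:
                fh.write(f"{pid}\t{a}\t{b}\n")


def read_trajectory(path) -> PeptideTrajectory:
    """Whitespace XYZ-per-frame trajectory with inline atom table.

    Header declares the unit (``angstrom`` or ``nm``; nm is converted
    to angstrom on read), the atom table lists
    ``atom <idx> <resid> <resname> <atomname>``, and each ``frame``
    block carries one ``x y z`` line per atom.
    """
    p = _require_file(path)
    unit = "angstrom"
    dt_ps = 1.0
    atoms: list[tuple[int, str, str]] = []
    frames: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    with open(p) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("unit:"):
                    unit = body.split(":", 1)[1].strip().lower()
                    if unit not in ("angstrom", "nm"):
                        raise ValueError(f"{p}:{ln}: unknown unit {unit!r}")
                elif body.startswith("dt_ps:"):
                    dt_ps = float(body.split(":", 1)[1])
                elif body.startswith("atom "):
                    _, _idx, resid, resname, atomname = body.split()
                    atoms.append((int(resid), resname, atomname))
                elif body.startswith("frame"):
                    if current is not None:
                        frames.append(current)
                    current = []
                continue
            if current is None:
                raise ValueError(f"{p}:{ln}: coordinate line before any '# frame'")
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{p}:{ln}: expected 'x y z', got {line!r}")
            current.append([float(v) for v in parts])
    if current is not None:
        frames.append(current)
    if not atoms:
        raise ValueError(f"{p}: no atom table in header")
    if not frames:
        raise ValueError(f"{p}: no frames")
    coords = np.asarray(frames, dtype=float)
    if coords.shape[1] != len(atoms):
        raise ValueError(
            f"{p}: frame atom count {coords.shape[1]} != atom table {len(atoms)}"
        )
    if unit == "nm":
        coords = coords * 10.0
    return PeptideTrajectory(coords=coords, atoms=atoms, dt_ps=dt_ps)


def write_trajectory(traj: PeptideTrajectory, path, unit: str = "angstrom") -> None:
    if unit not in ("angstrom", "nm"):
        raise ValueError(f"unknown unit {unit!r}")
    scale = 1.0 if unit == "angstrom" else 0.1
    buf = _io.StringIO()
    buf.write(f"# slimbind trajectory\n# unit: {unit}\n# dt_ps: {traj.dt_ps}\n")
    for i, (resid, resname, atomname) in enumerate(traj.atoms):
        buf.write(f"# atom {i} {resid} {resname} {atomname}\n")
    for f in range(traj.n_frames):
        buf.write(f"# frame {f}\n")
        for xyz in traj.coords[f] * scale:
            buf.write(f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    Path(path).write_text(buf.getvalue())
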