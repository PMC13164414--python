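"""I/O for time-resolved powder diffraction series and analysis results.

Two on-disk dialects are supported:

* one two-column ASCII diffractogram (2theta, intensity) per frame plus a
  manifest listing ``frame-file, time`` records (common beamline .xy exports;
  whitespace- or comma-separated, ``#`` comments skipped);
* a single matrix CSV whose first row is the 2theta grid and first column the
  frame times in minutes (cell (0,0) ignored).

Floats are written with ``%.17g`` so a write/read round trip is bit-exact.
Intensities are in arbitrary units throughout: curve resolution is scale
ambiguous, so no absolute-scale meaning is attached anywhere downstream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["DiffractionSeries", "read_xy_series", "read_matrix", "write_matrix",
           "write_result"]

_FMT = "%.17g"  # repr-faithful: round-trips IEEE doubles exactly
GRID_ATOL = 1e-6  # degrees; frames must share the 2theta grid to this tolerance


@dataclass
class DiffractionSeries:
    """Frames x channels intensity matrix with time and angle axes.

    times are minutes (strictly increasing), two_theta degrees (strictly
    increasing, not necessarily uniform), intensities an (m, n) matrix of
    counts in arbitrary units.
    """

    times: np.ndarray
    two_theta: np.ndarray
    intensities: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.two_theta = np.asarray(self.two_theta, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.times.size, self.two_theta.size):
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match "
                f"{self.times.size} times x {self.two_theta.size} channels"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.two_theta) <= 0):
            raise ValueError("two_theta must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.labels is not None and len(self.labels) != self.times.size:
            raise ValueError("labels length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_channels(self) -> int:
        return self.two_theta.size

    def masked(self, exclude: Sequence[tuple[float, float]]) -> "DiffractionSeries":
        """Drop channels inside any of the given (lo, hi) 2theta windows.

        Used to excise jar-material reflections from in situ milling data.
        """
        keep = np.ones(self.two_theta.size, dtype=bool)
        for lo, hi in exclude:
            keep &= ~((self.two_theta >= lo) & (self.two_theta <= hi))
        return DiffractionSeries(self.times, self.two_theta[keep],
                                 self.intensities[:, keep], self.labels)


def _check_negative(intensities: np.ndarray, allow_negative: bool, where: str) -> None:
    if not allow_negative and np.any(intensities < 0):
        raise ValueError(
            f"negative intensities in {where}; pass allow_negative=True for "
            "baseline-subtracted data"
        )


def _load_xy(path: Path) -> np.ndarray:
    """Load one two-column diffractogram; accepts whitespace or commas."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_xy_series(
    manifest: str | os.PathLike,
    allow_negative: bool = False,
    exclude: Sequence[tuple[float, float]] = (),
) -> DiffractionSeries:
    """Assemble a series from a manifest of ``frame-file, time`` records.

    Frame paths are resolved relative to the manifest location.  All frames
    must share the 2theta grid of the first file to within 1e-6 degrees;
    frames are reordered by ascending time.
    """
    manifest = Path(manifest)
    records: list[tuple[Path, float]] = []
    with open(manifest) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = [p.strip() for p in body.replace("\t", " ").split(",")]
            if len(parts) == 1:
                parts = body.split()
            if len(parts) != 2:
                raise ValueError(f"{manifest}:{lineno}: expected 'file, time'")
            try:
                t = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{manifest}:{lineno}: unparseable time {parts[1]!r}") from exc
            records.append((manifest.parent / parts[0], t))
    if not records:
        raise ValueError(f"empty manifest {manifest}")
    times = [t for _, t in records]
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate frame times in manifest {manifest}")

    records.sort(key=lambda r: r[1])
    grid = None
    frames, labels = [], []
    for path, t in records:
        xy = _load_xy(path)
        if grid is None:
            grid = xy[:, 0]
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{path}: 2theta grid not strictly increasing")
        else:
            if xy.shape[0] != grid.size or np.any(np.abs(xy[:, 0] - grid) > GRID_ATOL):
                raise ValueError(f"{path}: 2theta grid mismatch with first frame")
        frames.append(xy[:, 1])
        labels.append(path.name)
    intensities = np.vstack(frames)
    _check_negative(intensities, allow_negative, str(manifest))
    series = DiffractionSeries(np.asarray([t for _, t in records]), grid,
                               intensities, labels)
    return series.masked(exclude) if exclude else series


def read_matrix(
    path: str | os.PathLike,
    allow_negative: bool = False,
    exclude: Sequence[tuple[float, float]] = (),
) -> DiffractionSeries:
    """Read the matrix-CSV dialect (header row = 2theta, first column = time)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one frame")
    table = [ln.split(",") for ln in lines]
    width = len(table[0])
    parsed = np.empty((len(table), width))
    for i, row in enumerate(table):
        if len(row) != width:
            raise ValueError(f"{path}: row {i} has {len(row)} cells, expected {width}")
        for j, cell in enumerate(row):
            if i == 0 and j == 0:
                parsed[i, j] = np.nan  # corner cell carries no data
                continue
            try:
                parsed[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell at row {i}, column {j}") from exc
    two_theta = parsed[0, 1:]
    times = parsed[1:, 0]
    intensities = parsed[1:, 1:]
    _check_negative(intensities, allow_negative, str(path))
    series = DiffractionSeries(times, two_theta, intensities)
    return series.masked(exclude) if exclude else series


def write_matrix(series: DiffractionSeries, path: str | os.PathLike) -> None:
    """Write the matrix-CSV dialect; round-trips with :func:`read_matrix`."""
    m, n = series.intensities.shape
    block = np.empty((m + 1, n + 1))
    block[0, 0] = np.nan
    block[0, 1:] = series.two_theta
    block[1:, 0] = series.times
    block[1:, 1:] = series.intensities
    header = "time_min," + ",".join(_FMT % v for v in series.two_theta)
    body = "\n".join(
        ",".join(_FMT % v for v in row) for row in block[1:]
    )
    Path(path).write_text(header + "\n" + body + "\n")


def write_result(result, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Persist an MCR result: C and S as CSV plus a JSON diagnostics report.

    Returns the mapping of artifact name to written path.  Raises on an
    unfitted result (0 iterations) or an unwritable directory.
    """
    if result.iterations == 0:
        raise ValueError("unfitted result")
    C, S = result.C, result.S
    if C.shape[1] != S.shape[1]:
        raise ValueError("inconsistent result: C and S component counts differ")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"unwritable output directory {out_dir}") from exc

    q = C.shape[1]
    comp_names = [f"component_{i + 1}" for i in range(q)]

    c_path = out_dir / "C.csv"
    with open(c_path, "w") as fh:
        fh.write("time_min," + ",".join(comp_names) + "\n")
        for t, row in zip(result.times, C):
            fh.write(",".join(_FMT % v for v in (t, *row)) + "\n")

    s_path = out_dir / "S.csv"
    with open(s_path, "w") as fh:
        fh.write("two_theta_deg," + ",".join(comp_names) + "\n")
        for x, row in zip(result.two_theta, S):
            fh.write(",".join(_FMT % v for v in (x, *row)) + "\n")

    report = {
        "lof_percent": result.lof_percent,
        "r2": result.r2,
        "iterations": result.iterations,
        "converged": result.converged,
        "n_components": q,
    }
    if result.fitted_theta is not None:
        report["fitted_theta"] = {k: float(v) for k, v in result.fitted_theta.items()}
    r_path = out_dir / "report.json"
    r_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {"C": c_path, "S": s_path, "report": r_path}
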