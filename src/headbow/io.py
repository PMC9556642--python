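"""File formats: marker tables, beat annotations, ground truth, config.

Marker tables are tab- or comma-separated with the header
``time_s, <name>_x, <name>_y, <name>_z`` per marker, positions in mm,
missing samples encoded as empty fields.  A reader shim skips
metadata preamble lines (as exported by common motion-capture software)
whose first token is non-numeric and not our header.  Beat annotations
are CSV with columns ``take_id, step_index, onset_s, bar, played``.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .core import BeatGrid, MarkerTrajectory

MARKER_NAMES = ("head1", "head2", "head3", "bow")
_COORDS = ("x", "y", "z")


def write_marker_table(
    path: str | Path,
    markers: dict[str, MarkerTrajectory],
    delimiter: str = "\t",
) -> None:
    """Write marker trajectories to one table; missing = empty fields."""
    path = Path(path)
    names = list(markers)
    n = next(iter(markers.values())).n_samples
    rate = next(iter(markers.values())).rate
    header = ["time_s"] + [f"{nm}_{c}" for nm in names for c in _COORDS]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(header)
        for i in range(n):
            row = [f"{i / rate:.3f}"]
            for nm in names:
                p = markers[nm].positions[i]
                if np.isnan(p).any():
                    row.extend(["", "", ""])
                else:
                    row.extend(f"{v:.6f}" for v in p)
            w.writerow(row)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_marker_table(
    path: str | Path, rate: float = 100.0, expected: tuple[str, ...] = MARKER_NAMES
) -> dict[str, MarkerTrajectory]:
    """Read a marker table; lossless for present samples.

    Metadata preamble lines (first token neither numeric nor ``time_s``)
    are skipped.  A marker with a partially filled coordinate triple, or
    an unknown marker name in the header, is a parse error reporting the
    offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header = None
    header_lineno = 0
    for i, line in enumerate(lines):
        tok = line.split(_sniff_delimiter(line))[0].strip()
        if tok == "time_s":
            header = line
            header_lineno = i
            break
        try:
            float(tok)
            raise ValueError(f"{path}: line {i + 1}: data row before header")
        except ValueError as err:
            if "before header" in str(err):
                raise
            continue  # preamble line, skip
    if header is None:
        raise ValueError(f"{path}: no header line starting with 'time_s'")
    delim = _sniff_delimiter(header)
    cols = [c.strip() for c in header.split(delim)]
    names = []
    for c in cols[1:]:
        if "_" not in c:
            raise ValueError(f"{path}: malformed column {c!r}")
        nm, coord = c.rsplit("_", 1)
        if coord not in _COORDS:
            raise ValueError(f"{path}: malformed column {c!r}")
        if nm not in names:
            names.append(nm)
    unknown = set(names) - set(expected)
    if unknown:
        raise ValueError(
            f"{path}: unknown marker name(s) {sorted(unknown)}; expected {list(expected)}"
        )
    data_rows = []
    for lineno, line in enumerate(lines[header_lineno + 1:], header_lineno + 2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != len(cols):
            raise ValueError(f"{path}: line {lineno}: expected {len(cols)} fields")
        vals = []
        for nm_i, nm in enumerate(names):
            triple = fields[1 + 3 * nm_i: 4 + 3 * nm_i]
            empties = sum(1 for f in triple if f == "")
            if empties not in (0, 3):
                raise ValueError(
                    f"{path}: line {lineno}: marker {nm!r} has a partial "
                    "coordinate triple"
                )
            vals.append(
                [np.nan] * 3 if empties == 3 else [float(f) for f in triple]
            )
        data_rows.append(vals)
    arr = np.array(data_rows, dtype=float)  # (n, markers, 3)
    return {
        nm: MarkerTrajectory(arr[:, i, :], rate, name=nm)
        for i, nm in enumerate(names)
    }


def write_beat_csv(path: str | Path, grid: BeatGrid, take_id: str) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["take_id", "step_index", "onset_s", "bar", "played"])
        for i in range(grid.n_steps):
            w.writerow(
                [take_id, i, f"{grid.onsets[i]:.6f}", int(grid.bar[i]),
                 int(grid.played[i])]
            )


def read_beat_csv(path: str | Path) -> tuple[str, BeatGrid]:
    rows = list(csv.DictReader(Path(path).open()))
    if not rows:
        raise ValueError(f"{path}: empty beat annotation file")
    take_id = rows[0]["take_id"]
    onsets = np.array([float(r["onset_s"]) for r in rows])
    bar = np.array([int(r["bar"]) for r in rows])
    played = np.array([bool(int(r["played"])) for r in rows])
    return take_id, BeatGrid(onsets=onsets, bar=bar, played=played)


def write_truth_json(path: str | Path, truth: dict) -> None:
    """Ground truth as JSON (array fields are converted to lists;
    bulky waveform fields are dropped)."""
    out = {}
    for k, v in truth.items():
        if k == "noiseless_head_speed":
            continue
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    Path(path).write_text(json.dumps(out, indent=1))


def load_yaml(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
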