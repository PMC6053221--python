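"""Reading and writing traced terminal annotations.

A *terminal annotation* is the coordinate output of manual tracing of a
transmission-EM micrograph of one presynaptic bouton: a closed perimeter
trace, zero or more postsynaptic-density (PSD) traces, zero or more glial
process traces, and the marked centre point of every vesicle, together with
a nm-per-pixel calibration. Two on-disk dialects are supported:

* a structured JSON bundle (one file, many terminals), and
* a directory of two-column XY coordinate text files as exported by
  ImageJ's "Save XY Coordinates", named ``<terminal_id>__<role>[_<i>].txt``.

All coordinates are converted from pixels to nanometres exactly once, at
load time; every downstream computation works in nm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ConditionReport

#: Canonical condition labels (paper order: unstimulated, 0.033 Hz, 1 Hz).
CONDITIONS = ("unstimulated", "low_freq", "high_freq")

_CONDITION_ALIASES = {
    "us": "unstimulated",
    "unstimulated": "unstimulated",
    "0.033hz": "low_freq",
    "0.033 hz": "low_freq",
    "low_freq": "low_freq",
    "1hz": "high_freq",
    "1 hz": "high_freq",
    "high_freq": "high_freq",
}

#: Default vesicle radius (nm) used for the outside-perimeter tolerance;
#: half of the 52.5 nm mean vesicle diameter measured in this preparation.
DEFAULT_VESICLE_RADIUS_NM = 52.5 / 2

_ROLES = ("perimeter", "psd", "glial", "vesicles")


def normalize_condition(label: str) -> str:
    """Map a condition label (e.g. ``"US"``, ``"0.033Hz"``) to canonical form."""
    key = str(label).strip().lower()
    if key not in _CONDITION_ALIASES:
        raise ValueError(
            f"unknown condition {label!r}; expected one of {CONDITIONS} "
            "or aliases US / 0.033Hz / 1Hz"
        )
    return _CONDITION_ALIASES[key]


@dataclass
class Trace:
    """An ordered polyline in nm; ``closed`` traces implicitly join last to first.

    Consecutive duplicate vertices are dropped on construction (zero-length
    segments break nearest-point computations). A closed trace whose last
    vertex repeats the first has that vertex dropped, the closure being
    implicit.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("trace points must be an (N, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace contains non-finite coordinates")
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        pts = pts[keep]
        if self.closed and len(pts) > 2 and np.all(pts[-1] == pts[0]):
            pts = pts[:-1]
        if len(pts) < 2:
            raise ValueError("trace must contain at least 2 distinct points")
        self.points = pts

    @property
    def vertices(self) -> np.ndarray:
        """Vertex array with the closing vertex appended for closed traces."""
        if self.closed:
            return np.vstack([self.points, self.points[:1]])
        return self.points

    @property
    def length(self) -> float:
        """Total arc length in nm (including the closing segment if closed)."""
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def transformed(self, matrix: np.ndarray, offset: Sequence[float]) -> "Trace":
        return Trace(self.points @ np.asarray(matrix).T + np.asarray(offset, float), self.closed)


@dataclass
class TerminalAnnotation:
    """One traced presynaptic terminal, in nm.

    ``compartments`` optionally carries explicit membrane-compartment arc
    extents (nm along the perimeter from vertex 0), mirroring a manual
    demarcation; when present they bypass the distance-threshold classifier.
    Format: ``{"active_zone": [[s0, s1], ...], "glial_facing": [[s0, s1], ...]}``
    with ``s1 > s0`` and ``s1`` allowed past the perimeter length to wrap.
    """

    terminal_id: str
    condition: str
    perimeter: Trace
    psd: list[Trace] = field(default_factory=list)
    glial: list[Trace] = field(default_factory=list)
    vesicles: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    scale: float = 1.0
    compartments: dict | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale (nm per pixel) must be positive")
        if not self.perimeter.closed:
            raise ValueError("perimeter trace must be closed")
        if self.enclosed_area() <= 0:
            raise ValueError("perimeter must enclose a positive area")
        self.vesicles = np.asarray(self.vesicles, dtype=float).reshape(-1, 2)
        self.condition = normalize_condition(self.condition)

    def enclosed_area(self) -> float:
        """Unsigned shoelace area of the perimeter polygon, nm^2."""
        p = self.perimeter.points
        x, y = p[:, 0], p[:, 1]
        return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2

    def transformed(self, matrix: np.ndarray, offset: Sequence[float]) -> "TerminalAnnotation":
        """Rigidly transformed copy (used for invariance checks)."""
        off = np.asarray(offset, float)
        m = np.asarray(matrix, float)
        return TerminalAnnotation(
            terminal_id=self.terminal_id,
            condition=self.condition,
            perimeter=self.perimeter.transformed(m, off),
            psd=[t.transformed(m, off) for t in self.psd],
            glial=[t.transformed(m, off) for t in self.glial],
            vesicles=self.vesicles @ m.T + off if len(self.vesicles) else self.vesicles,
            scale=self.scale,
            compartments=self.compartments,
        )


def check_vesicles(
    annotation: TerminalAnnotation,
    tolerance_nm: float = DEFAULT_VESICLE_RADIUS_NM,
    strict: bool = False,
) -> TerminalAnnotation:
    """Warn about (or in strict mode drop) vesicles far outside the perimeter.

    Tracing noise routinely puts a vesicle centre marginally outside the
    membrane trace, so centres within one vesicle radius of the polygon are
    accepted silently; anything farther raises a warning and is retained
    unless ``strict``.
    """
    import shapely

    if len(annotation.vesicles) == 0:
        warnings.warn(
            f"terminal {annotation.terminal_id}: empty vesicle list", stacklevel=2
        )
        return annotation
    poly = shapely.Polygon(annotation.perimeter.points)
    pts = shapely.points(annotation.vesicles)
    dist = shapely.distance(pts, poly)  # 0 inside the polygon
    outside = dist > tolerance_nm
    if outside.any():
        warnings.warn(
            f"terminal {annotation.terminal_id}: {int(outside.sum())} vesicle(s) "
            f"more than {tolerance_nm:.1f} nm outside the perimeter",
            stacklevel=2,
        )
        if strict:
            annotation.vesicles = annotation.vesicles[~outside]
    return annotation


# ---------------------------------------------------------------------------
# readers


def read_annotation_bundle(
    path: str | Path,
    scale: float | None = None,
    strict: bool = False,
    condition: str = "unstimulated",
) -> list[TerminalAnnotation]:
    """Read annotations from a JSON bundle file or an XY-coordinate directory.

    Parameters
    ----------
    path
        Either a JSON bundle (list of terminals, pixel coordinates, each with
        its ``scale_nm_per_px``) or a directory of ImageJ-style two-column
        text files named ``<terminal_id>__<role>[_<i>].txt``.
    scale
        nm-per-pixel calibration. Required for the text-file dialect;
        for JSON bundles it overrides the per-terminal value when given.
    strict
        Drop vesicles lying more than one vesicle radius outside the
        perimeter instead of merely warning.
    condition
        Condition label applied to text-dialect terminals (the filename
        convention does not encode it).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.is_dir():
        if scale is None:
            raise ValueError("scale (nm per pixel) is required for XY-coordinate directories")
        return _read_xy_directory(p, scale, strict, condition)
    return _read_json_bundle(p, scale, strict)


def _read_json_bundle(
    path: Path, scale: float | None, strict: bool
) -> list[TerminalAnnotation]:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: JSON bundle must be a top-level list of terminals")
    out = []
    for entry in raw:
        tid = str(entry.get("id", f"terminal_{len(out)}"))
        s = float(scale if scale is not None else entry.get("scale_nm_per_px", 1.0))
        if "perimeter" not in entry or not entry["perimeter"]:
            raise ValueError(f"{path}: terminal {tid!r} lacks a perimeter trace")
        ann = TerminalAnnotation(
            terminal_id=tid,
            condition=entry.get("condition", "unstimulated"),
            perimeter=Trace(np.asarray(entry["perimeter"], float) * s, closed=True),
            psd=[Trace(np.asarray(t, float) * s) for t in entry.get("psd", [])],
            glial=[Trace(np.asarray(t, float) * s) for t in entry.get("glial", [])],
            vesicles=np.asarray(entry.get("vesicles", []), float).reshape(-1, 2) * s,
            scale=s,
            compartments=entry.get("compartments_nm"),
        )
        out.append(check_vesicles(ann, strict=strict))
    return out


def _parse_xy_file(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            try:
                if len(fields) < 2:
                    raise ValueError("expected two columns")
                rows.append((float(fields[0]), float(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinate line: {line!r}") from exc
    return np.asarray(rows, dtype=float).reshape(-1, 2)


def _read_xy_directory(
    path: Path, scale: float, strict: bool, condition: str
) -> list[TerminalAnnotation]:
    grouped: dict[str, dict[str, list[np.ndarray]]] = {}
    for f in sorted(path.glob("*.txt")):
        stem = f.stem
        if "__" not in stem:
            raise ValueError(f"{f}: filename must match <terminal_id>__<role>[_<i>].txt")
        tid, rest = stem.split("__", 1)
        role = rest
        for r in _ROLES:
            if rest == r or rest.startswith(r + "_"):
                role = r
                break
        else:
            raise ValueError(f"{f}: unknown role {rest!r}; expected one of {_ROLES}")
        grouped.setdefault(tid, {r: [] for r in _ROLES})[role].append(_parse_xy_file(f))
    out = []
    for tid in sorted(grouped):
        parts = grouped[tid]
        if not parts["perimeter"]:
            raise ValueError(f"terminal {tid!r} lacks a perimeter trace file")
        vesicles = (
            np.vstack(parts["vesicles"]) if parts["vesicles"] else np.empty((0, 2))
        )
        ann = TerminalAnnotation(
            terminal_id=tid,
            condition=condition,
            perimeter=Trace(parts["perimeter"][0] * scale, closed=True),
            psd=[Trace(t * scale) for t in parts["psd"]],
            glial=[Trace(t * scale) for t in parts["glial"]],
            vesicles=vesicles * scale,
            scale=scale,
        )
        out.append(check_vesicles(ann, strict=strict))
    return out


# ---------------------------------------------------------------------------
# writers


def write_annotation_bundle(
    annotations: Iterable[TerminalAnnotation], path: str | Path
) -> Path:
    """Write annotations back to the JSON bundle dialect (pixel coordinates)."""
    payload = []
    for ann in annotations:
        s = ann.scale
        entry = {
            "id": ann.terminal_id,
            "condition": ann.condition,
            "scale_nm_per_px": s,
            "perimeter": (ann.perimeter.points / s).tolist(),
            "psd": [(t.points / s).tolist() for t in ann.psd],
            "glial": [(t.points / s).tolist() for t in ann.glial],
            "vesicles": (ann.vesicles / s).tolist(),
        }
        if ann.compartments is not None:
            entry["compartments_nm"] = ann.compartments
        payload.append(entry)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
    return path


def write_condition_report(report: "ConditionReport", out_dir: str | Path) -> dict[str, Path]:
    """Write a per-condition analysis report as a set of TSV tables.

    Emits ``per_terminal.tsv`` (one row per terminal), ``pooled_distances.tsv``
    (one row per vesicle), ``pool_peaks.tsv`` (peak location / density /
    probability per compartment) and ``contingency.tsv`` (near-membrane
    counts in the within-50 nm / total layout).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in (
        ("per_terminal", report.per_terminal),
        ("pooled_distances", report.pooled),
        ("pool_peaks", report.peak_table),
        ("contingency", report.contingency_table),
    ):
        dest = out / f"{name}.tsv"
        frame.to_csv(dest, sep="\t", index=False)
        written[name] = dest
    return written


def read_pooled_distances(path: str | Path) -> pd.DataFrame:
    """Read a ``pooled_distances.tsv`` table back into a DataFrame."""
    return pd.read_csv(path, sep="\t")
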