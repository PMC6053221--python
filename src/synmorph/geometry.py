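"""Membrane-compartment classification and distance morphometry.

The terminal perimeter is resampled at a fixed arc-length step and every
sample is labelled ``active_zone`` if it lies within ``tau_az_nm`` of a
postsynaptic-density trace, else ``glial_facing`` if within ``tau_glial_nm``
of a glial process trace, else ``other`` — a distance-threshold surrogate
for the manual demarcation of apposed membrane. On top of the segmentation
the module computes, per vesicle, the shortest Euclidean distance to the
whole membrane and to each compartment, plus the coverage and apposition-gap
metrics used to characterise the glial ensheathment of the terminal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .io_annotations import TerminalAnnotation, Trace

ACTIVE_ZONE = "active_zone"
GLIAL_FACING = "glial_facing"
OTHER = "other"
COMPARTMENTS = (ACTIVE_ZONE, GLIAL_FACING, OTHER)

# integer label codes used internally; OTHER lowest so AZ wins ties by order
_CODE = {OTHER: 0, ACTIVE_ZONE: 1, GLIAL_FACING: 2}
_NAME = {v: k for k, v in _CODE.items()}


@dataclass
class ClassificationParams:
    """Parameters of the membrane classifier.

    tau_az_nm, tau_glial_nm
        Apposition thresholds: a perimeter sample within this distance of a
        PSD / glial trace counts as active-zone / glial-facing membrane.
        30 nm by default — comfortably above the ~6 nm terminal–glia gaps
        and the ~20 nm synaptic cleft, well below inter-structure spacing.
    resample_step_nm
        Target arc-length spacing of perimeter samples (the classifier's
        "pixel size").
    min_run_nm
        Label runs shorter than this are merged into the flanking label,
        suppressing single-sample flicker at region boundaries.
    """

    tau_az_nm: float = 30.0
    tau_glial_nm: float = 30.0
    resample_step_nm: float = 1.0
    min_run_nm: float = 10.0


@dataclass
class Region:
    """One maximal contiguous run of same-labelled perimeter samples."""

    compartment: str
    index: int
    sample_indices: np.ndarray  # indices into the segmentation's samples
    arc_length_nm: float
    start_arc_nm: float


@dataclass
class MembraneSegmentation:
    """Arc-length labelling of a terminal perimeter into compartments."""

    samples: np.ndarray  # (N, 2) resampled perimeter points, nm
    spacing_nm: float  # uniform arc spacing between consecutive samples
    labels: np.ndarray  # (N,) int codes, see _CODE
    regions: list[Region]
    perimeter_length_nm: float

    @property
    def arc_positions(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.spacing_nm

    def label_names(self) -> np.ndarray:
        return np.array([_NAME[c] for c in self.labels])

    def compartment_samples(self, compartment: str) -> np.ndarray:
        return self.samples[self.labels == _CODE[compartment]]

    def _length(self, compartment: str) -> float:
        return float(np.count_nonzero(self.labels == _CODE[compartment]) * self.spacing_nm)

    @property
    def active_zone_length(self) -> float:
        return self._length(ACTIVE_ZONE)

    @property
    def glial_facing_length(self) -> float:
        return self._length(GLIAL_FACING)

    @property
    def other_length(self) -> float:
        return self._length(OTHER)

    def compartment_regions(self, compartment: str) -> list[Region]:
        return [r for r in self.regions if r.compartment == compartment]


@dataclass
class GlialAppositionRecord:
    """Midpoint gap between one glial-facing membrane region and its glial process."""

    terminal_id: str
    region_index: int
    arc_length_nm: float
    midpoint_gap_nm: float


# ---------------------------------------------------------------------------
# primitive geometry


def _closed_resample(trace: Trace, step: float) -> tuple[np.ndarray, float, float]:
    """Uniformly resample a closed trace; returns (samples, spacing, length)."""
    verts = trace.vertices
    seg = np.diff(verts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    length = float(cum[-1])
    if length <= 0:
        raise ValueError("degenerate trace: zero arc length")
    n = max(int(np.ceil(length / step)), 4)
    spacing = length / n
    s = np.arange(n) * spacing
    x = np.interp(s, cum, verts[:, 0])
    y = np.interp(s, cum, verts[:, 1])
    return np.column_stack([x, y]), spacing, length


def resample_trace(trace: Trace, step: float) -> np.ndarray:
    """Resample a trace at arc-length spacing ``<= step`` (nm), keeping vertices.

    Every original vertex is a sample; each segment is subdivided into
    ``ceil(len/step)`` equal parts, so consecutive samples are collinear and
    the chord-length sum of the output equals the exact arc length. Open
    traces keep both endpoints; closed traces wrap (the first sample is not
    repeated at the end).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    verts = trace.vertices
    seg = np.diff(verts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if seglen.sum() <= 0:
        raise ValueError("degenerate trace: zero arc length")
    chunks = [verts[:1]]
    for i, ln in enumerate(seglen):
        n_i = max(int(np.ceil(ln / step)), 1)
        t = np.linspace(0.0, 1.0, n_i + 1)[1:, None]
        chunks.append(verts[i] + t * seg[i])
    pts = np.vstack(chunks)
    if trace.closed:
        pts = pts[:-1]  # closing vertex duplicates the first
    return pts


def _as_linestring(trace: Trace) -> shapely.LineString:
    return shapely.LineString(trace.vertices)


def point_to_trace_distance(p: Sequence[float], trace: Trace) -> float:
    """Exact shortest Euclidean distance (nm) from a point to a trace.

    The minimum is taken over the trace's segments (including the closing
    segment of a closed trace), not merely its vertices.
    """
    return float(shapely.distance(shapely.Point(p), _as_linestring(trace)))


def points_to_trace_distance(points: np.ndarray, trace: Trace) -> np.ndarray:
    """Vectorised exact point-to-trace distances for an (N, 2) array."""
    pts = shapely.points(np.asarray(points, float))
    return shapely.distance(pts, _as_linestring(trace))


def _min_distance_to_traces(points: np.ndarray, traces: Sequence[Trace]) -> np.ndarray:
    d = np.full(len(points), np.inf)
    for t in traces:
        np.minimum(d, points_to_trace_distance(points, t), out=d)
    return d


# ---------------------------------------------------------------------------
# classification


def _circular_runs(labels: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Maximal circular runs of equal labels as (label, index-array) pairs."""
    n = len(labels)
    starts = np.flatnonzero(labels != np.roll(labels, 1))
    if len(starts) == 0:
        return [(int(labels[0]), np.arange(n))]
    runs = []
    for i, s0 in enumerate(starts):
        s1 = starts[(i + 1) % len(starts)]
        idx = np.arange(s0, s1 if s1 > s0 else s1 + n) % n
        runs.append((int(labels[s0]), idx))
    return runs


def _merge_short_runs(labels: np.ndarray, spacing: float, min_run: float) -> np.ndarray:
    """Iteratively absorb runs shorter than ``min_run`` into a flanking label."""
    labels = labels.copy()
    for _ in range(len(labels)):
        runs = _circular_runs(labels)
        if len(runs) <= 1:
            break
        short = [
            (len(idx), k) for k, (lab, idx) in enumerate(runs) if len(idx) * spacing < min_run
        ]
        if not short:
            break
        _, k = min(short)
        prev_lab, prev_idx = runs[(k - 1) % len(runs)]
        next_lab, next_idx = runs[(k + 1) % len(runs)]
        if prev_lab == next_lab or len(prev_idx) >= len(next_idx):
            labels[runs[k][1]] = prev_lab
        else:
            labels[runs[k][1]] = next_lab
    return labels


def _labels_from_intervals(
    arc: np.ndarray, length: float, compartments: dict
) -> np.ndarray:
    labels = np.zeros(len(arc), dtype=int)
    # glial first so an overlapping active-zone interval wins
    for name in (GLIAL_FACING, ACTIVE_ZONE):
        for s0, s1 in compartments.get(name, []):
            rel = (arc - s0) % length
            labels[rel <= (s1 - s0)] = _CODE[name]
    return labels


def classify_membrane(
    annotation: TerminalAnnotation,
    params: ClassificationParams | None = None,
    use_explicit: bool = True,
) -> MembraneSegmentation:
    """Label the resampled perimeter into membrane compartments.

    When the annotation carries explicit compartment arc extents (a manual
    demarcation) and ``use_explicit`` is true, those are applied directly;
    otherwise each sample is labelled by its distance to the PSD and glial
    traces. Active zone takes precedence over glial-facing where both
    thresholds are met (glia never overlie the synaptic cleft).
    """
    params = params or ClassificationParams()
    samples, spacing, length = _closed_resample(
        annotation.perimeter, params.resample_step_nm
    )
    if annotation.compartments is not None and use_explicit:
        arc = np.arange(len(samples)) * spacing
        labels = _labels_from_intervals(arc, length, annotation.compartments)
    else:
        labels = np.zeros(len(samples), dtype=int)
        if annotation.glial:
            d_gl = _min_distance_to_traces(samples, annotation.glial)
            labels[d_gl <= params.tau_glial_nm] = _CODE[GLIAL_FACING]
        if annotation.psd:
            d_az = _min_distance_to_traces(samples, annotation.psd)
            labels[d_az <= params.tau_az_nm] = _CODE[ACTIVE_ZONE]
        labels = _merge_short_runs(labels, spacing, params.min_run_nm)

    regions: list[Region] = []
    counters = {name: 0 for name in COMPARTMENTS}
    for lab, idx in _circular_runs(labels):
        name = _NAME[lab]
        regions.append(
            Region(
                compartment=name,
                index=counters[name],
                sample_indices=idx,
                arc_length_nm=len(idx) * spacing,
                start_arc_nm=float(idx[0] * spacing),
            )
        )
        counters[name] += 1
    return MembraneSegmentation(
        samples=samples,
        spacing_nm=spacing,
        labels=labels,
        regions=regions,
        perimeter_length_nm=length,
    )


# ---------------------------------------------------------------------------
# metrics


def vesicle_distances(
    annotation: TerminalAnnotation, seg: MembraneSegmentation
) -> pd.DataFrame:
    """Per-vesicle shortest distances to membrane and compartments (nm).

    ``d_membrane`` is the exact distance to the perimeter polyline;
    ``d_active_zone`` and ``d_glial`` are minima over the resampled samples
    of the corresponding compartment (NaN when the compartment is empty),
    emulating a nearest-pixel computation at the resample step.
    """
    v = annotation.vesicles
    n = len(v)
    d_mem = (
        points_to_trace_distance(v, annotation.perimeter) if n else np.empty(0)
    )
    out = {
        "terminal_id": [annotation.terminal_id] * n,
        "condition": [annotation.condition] * n,
        "vesicle_index": np.arange(n),
        "d_membrane": d_mem,
    }
    for col, comp in (("d_active_zone", ACTIVE_ZONE), ("d_glial", GLIAL_FACING)):
        pts = seg.compartment_samples(comp)
        if len(pts) == 0 or n == 0:
            out[col] = np.full(n, np.nan)
        else:
            out[col] = cKDTree(pts).query(v)[0]
    return pd.DataFrame(out)


def glial_coverage_fraction(seg: MembraneSegmentation) -> float:
    """Fraction of the terminal perimeter that is glial-facing, in [0, 1]."""
    if seg.perimeter_length_nm <= 0:
        raise ValueError("zero perimeter length")
    return seg.glial_facing_length / seg.perimeter_length_nm


def midpoint_gap_distances(
    annotation: TerminalAnnotation, seg: MembraneSegmentation
) -> list[GlialAppositionRecord]:
    """Terminal-to-glia gap at the arc-length midpoint of each glial-facing region.

    The gap is the exact distance from the region's midpoint sample to the
    nearest glial trace. Returns an empty list when no glial-facing
    membrane exists.
    """
    records = []
    for region in seg.compartment_regions(GLIAL_FACING):
        mid = seg.samples[region.sample_indices[len(region.sample_indices) // 2]]
        gap = min(point_to_trace_distance(mid, t) for t in annotation.glial)
        records.append(
            GlialAppositionRecord(
                terminal_id=annotation.terminal_id,
                region_index=region.index,
                arc_length_nm=region.arc_length_nm,
                midpoint_gap_nm=gap,
            )
        )
    return records
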