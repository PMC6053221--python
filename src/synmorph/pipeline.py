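"""End-to-end analysis: annotations in, per-condition reports out.

``analyze_condition`` runs the full morphometry on every terminal of one
condition — membrane classification, vesicle distances, coverage and
apposition gaps — then pools vesicle distances across terminals (the
contingency analysis pools vesicles, it does not average per terminal) and
fits the pool distributions. ``compare_conditions`` applies the study's
statistics across conditions: Fisher's exact tests on the near-membrane
counts and Kruskal-Wallis/Dunn on the per-terminal metrics and gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .geometry import ClassificationParams, MembraneSegmentation
from .group_stats import (
    FisherResult,
    GroupComparison,
    build_condition_contingency,
    fisher_exact_2x2,
    kruskal_wallis_dunn,
)
from .io_annotations import TerminalAnnotation
from .pools import (
    NEAR_MEMBRANE_THRESHOLD_NM,
    NearMembraneCount,
    PoolDistribution,
    near_membrane_fraction,
    pool_distribution,
)

_DIST_COLUMNS = {"active_zone": "d_active_zone", "glial_facing": "d_glial"}


@dataclass
class ConditionReport:
    """Aggregate analysis of all terminals of one stimulation condition."""

    condition: str
    per_terminal: pd.DataFrame
    pooled: pd.DataFrame  # one row per vesicle: distances to each compartment
    gap_records: pd.DataFrame  # one row per glial-facing region
    distributions: dict[str, PoolDistribution] = field(default_factory=dict)
    near_counts: dict[str, NearMembraneCount] = field(default_factory=dict)

    @property
    def peak_table(self) -> pd.DataFrame:
        rows = [
            {
                "compartment": comp,
                "condition": self.condition,
                "peak_nm": pk.location,
                "density_per_nm": pk.density,
                "probability_pct": pk.probability,
            }
            for comp, dist in self.distributions.items()
            for pk in dist.peaks
        ]
        return pd.DataFrame(
            rows,
            columns=["compartment", "condition", "peak_nm", "density_per_nm", "probability_pct"],
        )

    @property
    def contingency_table(self) -> pd.DataFrame:
        rows = [
            {
                "condition": self.condition,
                "compartment": comp,
                "n_within_50nm": c.n_within,
                "n_total": c.n_total,
                "fraction": round(c.fraction, 3),
            }
            for comp, c in self.near_counts.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["condition", "compartment", "n_within_50nm", "n_total", "fraction"],
        )


def analyze_terminal(
    annotation: TerminalAnnotation, params: ClassificationParams | None = None
) -> tuple[MembraneSegmentation, pd.DataFrame, list]:
    """Segmentation, vesicle-distance table and apposition gaps for one terminal."""
    seg = geometry.classify_membrane(annotation, params)
    distances = geometry.vesicle_distances(annotation, seg)
    gaps = geometry.midpoint_gap_distances(annotation, seg)
    return seg, distances, gaps


def analyze_condition(
    annotations: Sequence[TerminalAnnotation],
    params: ClassificationParams | None = None,
    bin_width: float = 10.0,
    near_threshold: float = NEAR_MEMBRANE_THRESHOLD_NM,
    min_prominence: float = 0.05,
) -> ConditionReport:
    """Run the full pipeline over one condition's terminals."""
    if not annotations:
        raise ValueError("no annotations supplied")
    condition = annotations[0].condition
    terminal_rows, pooled_frames, gap_rows = [], [], []
    for ann in annotations:
        seg, distances, gaps = analyze_terminal(ann, params)
        pooled_frames.append(distances)
        terminal_rows.append(
            {
                "terminal_id": ann.terminal_id,
                "condition": ann.condition,
                "n_vesicles": len(ann.vesicles),
                "perimeter_length_nm": seg.perimeter_length_nm,
                "active_zone_length_nm": seg.active_zone_length,
                "glial_facing_length_nm": seg.glial_facing_length,
                "glial_coverage": geometry.glial_coverage_fraction(seg),
                "n_glial_regions": len(seg.compartment_regions(geometry.GLIAL_FACING)),
            }
        )
        gap_rows.extend(
            {
                "terminal_id": g.terminal_id,
                "condition": ann.condition,
                "region_index": g.region_index,
                "arc_length_nm": g.arc_length_nm,
                "midpoint_gap_nm": g.midpoint_gap_nm,
            }
            for g in gaps
        )
    pooled = pd.concat(pooled_frames, ignore_index=True)
    report = ConditionReport(
        condition=condition,
        per_terminal=pd.DataFrame(terminal_rows),
        pooled=pooled,
        gap_records=pd.DataFrame(
            gap_rows,
            columns=["terminal_id", "condition", "region_index", "arc_length_nm", "midpoint_gap_nm"],
        ),
    )
    for comp, col in _DIST_COLUMNS.items():
        d = pooled[col].to_numpy()
        d = d[np.isfinite(d)]
        if len(d) >= 2:
            report.distributions[comp] = pool_distribution(
                d,
                bin_width=bin_width,
                min_prominence=min_prominence,
                compartment=comp,
                condition=condition,
            )
        if len(d) >= 1:
            report.near_counts[comp] = near_membrane_fraction(
                d, threshold=near_threshold, compartment=comp, condition=condition
            )
    return report


def compare_conditions(
    reports: Mapping[str, ConditionReport],
    pair: tuple[str, str] = ("low_freq", "high_freq"),
) -> dict:
    """Cross-condition statistics on pooled counts and per-terminal metrics.

    Returns a dict with ``fisher`` (per compartment: the 2x2 table and
    FisherResult for ``pair``) and ``kruskal`` (per metric: Kruskal-Wallis
    with Dunn post hoc across all supplied conditions).
    """
    out: dict = {"fisher": {}, "kruskal": {}}
    counts = [c for r in reports.values() for c in r.near_counts.values()]
    for comp in _DIST_COLUMNS:
        try:
            table = build_condition_contingency(counts, pair, comp)
        except ValueError:
            continue
        out["fisher"][comp] = (table, fisher_exact_2x2(table))
    metrics = [
        "n_vesicles",
        "perimeter_length_nm",
        "active_zone_length_nm",
        "glial_coverage",
    ]
    for metric in metrics:
        groups = {
            cond: r.per_terminal[metric].to_numpy()
            for cond, r in reports.items()
            if len(r.per_terminal) >= 2
        }
        if len(groups) >= 2:
            out["kruskal"][metric] = kruskal_wallis_dunn(groups, metric=metric)
    gap_groups = {
        cond: r.gap_records["midpoint_gap_nm"].to_numpy()
        for cond, r in reports.items()
        if len(r.gap_records) >= 2
    }
    if len(gap_groups) >= 2:
        out["kruskal"]["midpoint_gap_nm"] = kruskal_wallis_dunn(
            gap_groups, metric="midpoint_gap_nm"
        )
    return out


def load_params(path: str | Path) -> ClassificationParams:
    """Read classifier parameters from a YAML config block.

    Recognised keys: ``tau_az_nm``, ``tau_glial_nm``, ``resample_step_nm``,
    ``min_run_nm`` (at top level or under ``classification:``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    block = raw.get("classification", raw)
    known = {f for f in ClassificationParams.__dataclass_fields__}
    return ClassificationParams(**{k: v for k, v in block.items() if k in known})
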