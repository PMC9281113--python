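"""Recovery scoring of pipeline output against phantom ground truth.

Used by the simulation studies: components are matched to planted plaques
by centroid distance (unambiguous when plaques are farther apart than the
match radius), then sensitivity, false-positive count and volume-recovery
errors are summarized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import PlaqueTruth
from .volumetry import PlaqueComponent, QuantReport

__all__ = ["RecoveryMetrics", "match_to_truth", "recovery_metrics"]

#: plaques at least this many in-plane voxels across count as size-resolved
MIN_RESOLVED_DIAMETER_VOXELS = 3


@dataclass
class RecoveryMetrics:
    """Per-volume recovery summary against ground truth."""

    n_truth: int
    n_detected: int
    n_false_positive: int
    sensitivity: float
    total_volume_true: float
    total_volume_recovered: float  # over matched components only
    per_plaque_rel_error: dict[int, float] = field(default_factory=dict)
    resolved_truth_indices: list[int] = field(default_factory=list)

    @property
    def total_volume_rel_error(self) -> float:
        return (self.total_volume_recovered - self.total_volume_true) / self.total_volume_true

    @property
    def resolved_abs_rel_errors(self) -> list[float]:
        """|relative volume error| of matched, size-resolved plaques."""
        return [
            abs(self.per_plaque_rel_error[i])
            for i in self.resolved_truth_indices
            if i in self.per_plaque_rel_error
        ]


def match_to_truth(
    components: list[PlaqueComponent],
    truths: list[PlaqueTruth],
    max_dist: float = 0.5,
) -> tuple[dict[int, float], int]:
    """Assign components to the nearest truth center within ``max_dist`` mm.

    Returns (truth index -> summed recovered volume, false-positive count).
    Several components may map to one plaque (a region split by noise);
    their volumes add.
    """
    matched: dict[int, float] = {}
    false_pos = 0
    for comp in components:
        if not truths:
            false_pos += 1
            continue
        dists = [math.dist(comp.centroid_mm, t.center) for t in truths]
        best = int(np.argmin(dists))
        if dists[best] <= max_dist:
            matched[best] = matched.get(best, 0.0) + comp.volume_mm3
        else:
            false_pos += 1
    return matched, false_pos


def recovery_metrics(
    report: QuantReport,
    truths: list[PlaqueTruth],
    in_plane_spacing: float = 0.0625,
    max_dist: float = 0.5,
) -> RecoveryMetrics:
    """Score one quantification run against the generating truth."""
    matched, fp = match_to_truth(report.components, truths, max_dist)
    min_radius = MIN_RESOLVED_DIAMETER_VOXELS * in_plane_spacing / 2.0
    per_plaque = {
        i: (v - truths[i].true_volume) / truths[i].true_volume for i, v in matched.items()
    }
    return RecoveryMetrics(
        n_truth=len(truths),
        n_detected=len(matched),
        n_false_positive=fp,
        sensitivity=len(matched) / len(truths) if truths else float("nan"),
        total_volume_true=sum(t.true_volume for t in truths),
        total_volume_recovered=sum(matched.values()),
        per_plaque_rel_error=per_plaque,
        resolved_truth_indices=[
            i for i, t in enumerate(truths) if t.radius >= min_radius
        ],
    )
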