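"""Set algebra over signed DEG calls across timepoints and regimes.

Each gene's per-timepoint direction calls (up / down / ns) form a
trajectory vector.  Named classes cover the patterns reported for
time-course stress experiments: persistently up- or down-regulated
genes, and "switchers" that flip sign between the first and last
timepoint.  Exclusive UpSet-style intersections and cross-regime
overlaps at a shared timepoint complete the algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .de_stats import DEGCall

__all__ = [
    "TrajectoryLabel",
    "CrossRegimeOverlap",
    "classify_trajectories",
    "upset_intersections",
    "cross_regime_overlap",
]


@dataclass(frozen=True)
class TrajectoryLabel:
    """A gene's per-timepoint direction vector and derived class label."""

    gene_id: str
    vector: tuple[str, ...]  # directions ordered by timepoint
    label: str


@dataclass(frozen=True)
class CrossRegimeOverlap:
    """Signed DEG overlap between two regimes at a shared timepoint."""

    timepoint_h: float
    co_induced: tuple[str, ...]
    co_repressed: tuple[str, ...]
    down_in_a_up_in_b: tuple[str, ...]
    up_in_a_down_in_b: tuple[str, ...]


def _calls_to_map(calls: Sequence[DEGCall]) -> dict[str, str]:
    return {c.gene_id: c.direction for c in calls}


def _harmonise_universes(
    calls_by_timepoint: Mapping[float, Sequence[DEGCall]],
) -> tuple[list[float], list[str], dict[float, dict[str, str]]]:
    """Common gene universe across timepoints.

    Genes absent from some timepoints (e.g. dropped for having zero
    counts there) are treated as ns at those timepoints, with a warning;
    the universe is the union.
    """
    if len(calls_by_timepoint) < 2:
        raise ValueError("need calls for at least two timepoints")
    timepoints = sorted(calls_by_timepoint)
    maps = {tp: _calls_to_map(calls_by_timepoint[tp]) for tp in timepoints}
    universes = [set(m) for m in maps.values()]
    union = set.union(*universes)
    if any(u != union for u in universes):
        warnings.warn(
            "gene universes differ across timepoints; missing genes "
            "treated as ns",
            stacklevel=3,
        )
    genes = sorted(union)
    return timepoints, genes, maps


def _class_label(vector: tuple[str, ...]) -> str | None:
    """Named class for a direction vector; None when ns everywhere."""
    if all(v == "ns" for v in vector):
        return None
    if all(v == "up" for v in vector):
        return "persistent_up"
    if all(v == "down" for v in vector):
        return "persistent_down"
    if vector[0] == "down" and vector[-1] == "up":
        return "down_to_up"
    if vector[0] == "up" and vector[-1] == "down":
        return "up_to_down"
    return "_".join(vector)


def classify_trajectories(
    calls_by_timepoint: Mapping[float, Sequence[DEGCall]],
) -> list[TrajectoryLabel]:
    """Label every gene DE at >= 1 timepoint by its direction vector.

    Two-timepoint vectors map onto the named classes persistent_up,
    persistent_down, down_to_up and up_to_down; all other patterns are
    labelled by the vector itself (e.g. ``up_ns_up``).  Genes that are
    ns at every timepoint are excluded.
    """
    timepoints, genes, maps = _harmonise_universes(calls_by_timepoint)
    labels = []
    for g in genes:
        vector = tuple(maps[tp].get(g, "ns") for tp in timepoints)
        label = _class_label(vector)
        if label is not None:
            labels.append(TrajectoryLabel(g, vector, label))
    return labels


def upset_intersections(
    calls_by_timepoint: Mapping[float, Sequence[DEGCall]],
    signed: bool = True,
) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts over per-timepoint DEG sets.

    Every gene DE at >= 1 timepoint belongs to exactly one pattern: its
    signed membership vector (direction per timepoint) when ``signed``,
    or its unsigned membership vector ('de'/'ns') otherwise.  Counts
    therefore sum to the size of the DEG union.
    """
    timepoints, genes, maps = _harmonise_universes(calls_by_timepoint)
    counts: dict[tuple[str, ...], int] = {}
    for g in genes:
        vector = tuple(maps[tp].get(g, "ns") for tp in timepoints)
        if all(v == "ns" for v in vector):
            continue
        if not signed:
            vector = tuple("de" if v != "ns" else "ns" for v in vector)
        counts[vector] = counts.get(vector, 0) + 1
    return counts


def cross_regime_overlap(
    calls_regime_a: Sequence[DEGCall],
    calls_regime_b: Sequence[DEGCall],
    timepoint_h: float,
) -> CrossRegimeOverlap:
    """Signed DEG overlap between two regimes at one shared timepoint."""
    a = _calls_to_map(calls_regime_a)
    b = _calls_to_map(calls_regime_b)
    shared = sorted(set(a) | set(b))

    def sel(dir_a: str, dir_b: str) -> tuple[str, ...]:
        return tuple(
            g
            for g in shared
            if a.get(g, "ns") == dir_a and b.get(g, "ns") == dir_b
        )

    return CrossRegimeOverlap(
        timepoint_h=float(timepoint_h),
        co_induced=sel("up", "up"),
        co_repressed=sel("down", "down"),
        down_in_a_up_in_b=sel("down", "up"),
        up_in_a_down_in_b=sel("up", "down"),
    )
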