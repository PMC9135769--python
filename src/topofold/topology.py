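"""Topological refactoring plans: segment rewiring and junction geometry.

A four-helix-bundle (or any segmented scaffold) can be rewired by reordering
its secondary-structure segments along the chain and bridging each new
junction with a short de novo loop. For N segments there are N·(N−1)! = N!
orderings. This module enumerates those arrangements, measures the
backbone C→N distance across each junction on the unmoved template, and
suggests how many loop residues are needed to bridge it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

from .structures import Structure, StructureError

__all__ = [
    "SegmentSpec",
    "JunctionGap",
    "ArchitecturePlan",
    "enumerate_rewirings",
    "junction_gaps",
    "suggest_loop_length",
    "read_segment_specs",
    "write_plan",
]

# Distance bridgeable per loop residue, Å. Just below the fully extended
# 3.8 Å Cα–Cα spacing, so a 10 Å gap maps to 3 residues and 13 Å to 4.
SPAN_PER_RESIDUE = 3.5


@dataclass(frozen=True)
class SegmentSpec:
    """A contiguous scaffold segment, addressed by author residue numbers."""

    label: str
    chain: str
    start: int
    end: int
    epitope: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.label}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class JunctionGap:
    preceding: str
    following: str
    gap: float | None = None          # Å, backbone C -> N across the junction
    loop_length: int | None = None    # suggested de novo loop residues


@dataclass(frozen=True)
class ArchitecturePlan:
    """An ordered N→C arrangement of segments with its N−1 junctions."""

    segments: tuple[SegmentSpec, ...]
    junctions: tuple[JunctionGap, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a plan needs at least one segment")
        if self.junctions and len(self.junctions) != len(self.segments) - 1:
            raise ValueError("junction count must be N-1")
        if not self.junctions:
            object.__setattr__(
                self,
                "junctions",
                tuple(
                    JunctionGap(a.label, b.label)
                    for a, b in zip(self.segments, self.segments[1:])
                ),
            )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.segments)


def enumerate_rewirings(segments: Sequence[SegmentSpec]) -> list[ArchitecturePlan]:
    """All N·(N−1)! = N! distinct segment orderings, lexicographic by label.

    Circular permutations are already contained in this count; segments are
    never direction-reversed.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    labels = [s.label for s in segments]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate segment labels: {sorted(labels)}")
    ordered = sorted(segments, key=lambda s: s.label)
    return [ArchitecturePlan(segments=p) for p in permutations(ordered)]


def junction_gaps(template: Structure, plan: ArchitecturePlan) -> ArchitecturePlan:
    """Fill each junction's gap: the Euclidean distance from the backbone C
    atom of the preceding segment's last residue to the backbone N atom of
    the following segment's first residue, on the unmoved template.

    Suggested loop lengths are filled alongside via
    :func:`suggest_loop_length`.
    """
    by_label = {s.label: s for s in plan.segments}
    junctions = []
    for j in plan.junctions:
        prev_seg = by_label[j.preceding]
        next_seg = by_label[j.following]
        c_res = template.residue(prev_seg.chain, prev_seg.end)
        n_res = template.residue(next_seg.chain, next_seg.start)
        if not c_res.has_atom("C"):
            raise StructureError(
                f"junction {j.preceding}->{j.following}: residue "
                f"{prev_seg.chain}:{prev_seg.end} has no C atom"
            )
        if not n_res.has_atom("N"):
            raise StructureError(
                f"junction {j.preceding}->{j.following}: residue "
                f"{next_seg.chain}:{next_seg.start} has no N atom"
            )
        gap = float(
            math.dist(c_res.atom("C").coords, n_res.atom("N").coords)
        )
        junctions.append(
            JunctionGap(j.preceding, j.following, gap=gap, loop_length=suggest_loop_length(gap))
        )
    return replace(plan, junctions=tuple(junctions))


def suggest_loop_length(gap: float) -> int:
    """Residues needed to bridge a junction gap: ceil(gap / 3.5 Å), min 1."""
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    return max(1, math.ceil(gap / SPAN_PER_RESIDUE))


# ---------------------------------------------------------------------------
# Tabular serialisation
# ---------------------------------------------------------------------------

def read_segment_specs(path: str | Path) -> list[SegmentSpec]:
    """Read segment specs from TSV columns: label, chain, start, end[, epitope]."""
    specs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("label"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise ValueError(f"segment row needs label, chain, start, end: {line!r}")
        epitope = len(parts) > 4 and parts[4].lower() in ("1", "true", "yes", "epitope")
        specs.append(
            SegmentSpec(parts[0], parts[1], int(parts[2]), int(parts[3]), epitope)
        )
    if not specs:
        raise ValueError(f"{path}: no segment rows")
    return specs


def write_plan(plan: ArchitecturePlan, path: str | Path) -> None:
    """Write a plan as a small tabular text file: segment rows then junction rows."""
    lines = ["# segment\tlabel\tchain\tstart\tend\tepitope"]
    for s in plan.segments:
        lines.append(f"segment\t{s.label}\t{s.chain}\t{s.start}\t{s.end}\t{int(s.epitope)}")
    lines.append("# junction\tpreceding\tfollowing\tgap_A\tloop_length")
    for j in plan.junctions:
        gap = "" if j.gap is None else f"{j.gap:.2f}"
        ll = "" if j.loop_length is None else str(j.loop_length)
        lines.append(f"junction\t{j.preceding}\t{j.following}\t{gap}\t{ll}")
    Path(path).write_text("\n".join(lines) + "\n")
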