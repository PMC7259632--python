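"""Per-contact occupancy over a trajectory.

Occupancy is the fraction of frames in which a given interface contact
exists. Rows are keyed by the full (kind, partner group) identity so two
distinct hydrogen bonds between the same residues stay separate; a
residue-pair roll-up is available for coarser reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fingerprint import InteractionCutoffs, InteractionRecord, InterfaceSplit, Partner, fingerprint
from .structure import Trajectory

__all__ = ["OccupancyRow", "OccupancyTable", "occupancy_table", "label_occupancy",
           "DEFAULT_HIGH_THRESHOLD"]

DEFAULT_HIGH_THRESHOLD = 0.6

RowKey = tuple[str, Partner, Partner]


@dataclass
class OccupancyRow:
    kind: str
    partner_a: Partner
    partner_b: Partner
    count: int
    n_frames: int
    mean_distance: float
    label: str | None = None

    @property
    def occupancy(self) -> float:
        return self.count / self.n_frames

    @property
    def distance(self) -> float:
        return self.mean_distance

    @property
    def key(self) -> RowKey:
        return (self.kind, self.partner_a, self.partner_b)


@dataclass
class OccupancyTable:
    rows: list[OccupancyRow]
    n_frames: int
    high_threshold: float | None = None

    def row(self, kind: str, partner_a: Partner, partner_b: Partner) -> OccupancyRow | None:
        for r in self.rows:
            if r.key == (kind, partner_a, partner_b):
                return r
        return None

    def residue_pair_rollup(self) -> dict[tuple[str, tuple, tuple], float]:
        """Max occupancy per (kind, residue_a, residue_b), collapsing groups."""
        out: dict[tuple[str, tuple, tuple], float] = {}
        for r in self.rows:
            key = (r.kind, r.partner_a.residue_key, r.partner_b.residue_key)
            out[key] = max(out.get(key, 0.0), r.occupancy)
        return out


def occupancy_table(traj: Trajectory, split: InterfaceSplit,
                    cutoffs: InteractionCutoffs = InteractionCutoffs(),
                    frame_range: tuple[int, int] | None = None) -> OccupancyTable:
    """Count, for every contact observed in any frame of the window, the
    fraction of window frames containing it.

    ``frame_range`` is a half-open [start, stop) window over frame indices;
    ``None`` means all frames.
    """
    if frame_range is None:
        frames = list(traj.frames)
    else:
        start, stop = frame_range
        frames = traj.frames[start:stop]
    if not frames:
        raise ValueError("empty frame range")
    counts: dict[RowKey, int] = {}
    dist_sums: dict[RowKey, float] = {}
    for frame in frames:
        seen: set[RowKey] = set()
        for rec in fingerprint(frame, split, cutoffs):
            key = (rec.kind, rec.partner_a, rec.partner_b)
            if key in seen:  # identical key cannot repeat within a frame
                continue
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
            dist_sums[key] = dist_sums.get(key, 0.0) + rec.distance
    n = len(frames)
    rows = [
        OccupancyRow(kind=k[0], partner_a=k[1], partner_b=k[2], count=c,
                     n_frames=n, mean_distance=dist_sums[k] / c)
        for k, c in sorted(counts.items())
    ]
    return OccupancyTable(rows=rows, n_frames=n)


def label_occupancy(table: OccupancyTable,
                    high_threshold: float = DEFAULT_HIGH_THRESHOLD) -> OccupancyTable:
    """Label each row 'high' iff occupancy ≥ high_threshold, else 'low'."""
    if not (0 < high_threshold <= 1):
        raise ValueError("high_threshold must lie in (0, 1]")
    for row in table.rows:
        row.label = "high" if row.occupancy >= high_threshold else "low"
    table.high_threshold = high_threshold
    return table
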