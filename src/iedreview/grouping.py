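"""Merging per-template nominations into certainty-ranked IED groups.

Many templates fire on the same underlying discharge, so raw nominations are
condensed in two steps: (1) on each channel, nominations whose intervals
overlap by more than 75% (of the shorter interval) are merged by single
linkage, and merged events with fewer than three member nominations are
discarded; (2) the surviving channel-groups are merged across channels when
their onsets fall within one second of the earliest (seed) group.

Each resulting group carries a certainty in [0, 1] aggregated from its
members' correlations c and template reliabilities r.  The default
aggregator is a noisy-OR, ``1 - prod(1 - c_i * r_i)``: bounded, using exactly
the two stated evidence factors, and rewarding corroboration by several
reliable templates.  ``mean`` and ``max`` aggregators are available should a
different combination rule be preferred.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Callable, Iterable

import numpy as np

from .config import (
    DEFAULT_MERGE_WINDOW_S,
    DEFAULT_MIN_MEMBERS,
    DEFAULT_OVERLAP,
    TARGET_RATE,
)
from .detection import Nomination
from .template_db import TemplateDatabase

GROUP_STATUSES = ("pending", "confirmed", "rejected", "unsure")


@dataclasses.dataclass
class NominationGroup:
    """A merged cross-channel nomination presented to the reviewer as one event."""

    group_id: str
    members: list[Nomination]
    certainty: float = 0.0
    status: str = "pending"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a nomination group needs at least one member")
        if self.status not in GROUP_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def onset_s(self) -> float:
        return self.start / TARGET_RATE

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / TARGET_RATE

    @property
    def channels(self) -> frozenset[str]:
        return frozenset(m.channel for m in self.members)

    def set_status(self, status: str) -> None:
        if status not in GROUP_STATUSES:
            raise ValueError(f"unknown status {status!r}")
        if self.status != "pending":
            raise ValueError(
                f"group {self.group_id} already {self.status}; only pending groups can change"
            )
        self.status = status


def _overlap_fraction(a: Nomination, b: Nomination) -> float:
    """Overlap length over the shorter interval's length."""
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / min(a.length, b.length)


def merge_same_channel(
    noms: list[Nomination], overlap: float = DEFAULT_OVERLAP
) -> list[list[Nomination]]:
    """Single-linkage merge of overlapping nominations per (montage, channel).

    Two nominations link iff their overlap exceeds ``overlap`` of the shorter
    one (strict).  Returns channel-groups in deterministic order regardless
    of input order.
    """
    by_channel: dict[tuple[str, str], list[Nomination]] = defaultdict(list)
    for n in noms:
        by_channel[(n.montage, n.channel)].append(n)

    groups: list[list[Nomination]] = []
    for key in sorted(by_channel):
        items = sorted(by_channel[key], key=lambda n: (n.start, n.end, n.template_id))
        parent = list(range(len(items)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if items[j].start >= items[i].end:
                    break  # sorted by start; no further overlap with i
                if _overlap_fraction(items[i], items[j]) > overlap:
                    parent[find(j)] = find(i)
        clusters: dict[int, list[Nomination]] = defaultdict(list)
        for i, n in enumerate(items):
            clusters[find(i)].append(n)
        groups.extend(clusters[root] for root in sorted(clusters))
    return groups


def filter_small_groups(
    groups: list[list[Nomination]], min_members: int = DEFAULT_MIN_MEMBERS
) -> list[list[Nomination]]:
    """Discard channel-groups with fewer than ``min_members`` nominations."""
    return [g for g in groups if len(g) >= min_members]


def merge_across_channels(
    groups: list[list[Nomination]], window_s: float = DEFAULT_MERGE_WINDOW_S
) -> list[NominationGroup]:
    """Greedy onset-window merge of channel-groups into final groups.

    Channel-groups are sorted by onset; the earliest unmerged one seeds a
    group and absorbs every later channel-group whose onset starts strictly
    within ``window_s`` of the seed's onset.
    """
    window = int(round(window_s * TARGET_RATE))

    def onset(g: list[Nomination]) -> int:
        return min(n.start for n in g)

    ordered = sorted(groups, key=lambda g: (onset(g), g[0].montage, g[0].channel))
    out: list[NominationGroup] = []
    i = 0
    while i < len(ordered):
        seed_onset = onset(ordered[i])
        members = list(ordered[i])
        j = i + 1
        while j < len(ordered) and onset(ordered[j]) - seed_onset < window:
            members.extend(ordered[j])
            j += 1
        members.sort(key=lambda n: (n.start, n.montage, n.channel, n.template_id))
        out.append(NominationGroup(group_id=f"g{len(out):04d}", members=members))
        i = j
    return out


def group_certainty(
    group: NominationGroup,
    db: TemplateDatabase | None = None,
    aggregator: str = "noisy_or",
    reliability_fn: Callable[[str], float] | None = None,
) -> float:
    """Aggregate member evidence c_i * r_i into a group certainty in [0, 1].

    Reliabilities come from ``reliability_fn`` if given (used for
    session-local updates during review), else from the database's current
    counts, else from the value stamped on each nomination at detection time.
    Correlations are clamped to [0, 1]: anticorrelated evidence counts as none.
    """
    if not group.members:
        raise ValueError("cannot compute certainty of an empty group")
    evidence = []
    for m in group.members:
        if reliability_fn is not None:
            r = reliability_fn(m.template_id)
        elif db is not None:
            r = db.template_reliability(m.template_id)
        else:
            r = m.reliability
        evidence.append(max(0.0, min(1.0, m.correlation)) * r)
    ev = np.array(evidence)
    if aggregator == "noisy_or":
        return float(1.0 - np.prod(1.0 - ev))
    if aggregator == "mean":
        return float(ev.mean())
    if aggregator == "max":
        return float(ev.max())
    raise ValueError(f"unknown aggregator {aggregator!r}")


def group_nominations(
    noms: list[Nomination],
    db: TemplateDatabase | None = None,
    overlap: float = DEFAULT_OVERLAP,
    min_members: int = DEFAULT_MIN_MEMBERS,
    window_s: float = DEFAULT_MERGE_WINDOW_S,
    aggregator: str = "noisy_or",
) -> list[NominationGroup]:
    """Full grouping pipeline: merge, filter, cross-channel merge, certainty."""
    channel_groups = filter_small_groups(merge_same_channel(noms, overlap), min_members)
    groups = merge_across_channels(channel_groups, window_s)
    for g in groups:
        g.certainty = group_certainty(g, db, aggregator)
    return groups


def write_groups(groups: Iterable[NominationGroup], path) -> None:
    """Persist groups alongside nominations (one CSV row per group)."""
    import pandas as pd

    rows = [
        {
            "group_id": g.group_id,
            "start_s": f"{g.onset_s:.6f}",
            "duration_s": f"{g.duration_s:.6f}",
            "channels": ";".join(sorted(g.channels)),
            "n_members": len(g.members),
            "certainty": f"{g.certainty:.9f}",
            "status": g.status,
        }
        for g in groups
    ]
    pd.DataFrame(
        rows,
        columns=["group_id", "start_s", "duration_s", "channels", "n_members", "certainty", "status"],
    ).to_csv(path, index=False)
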