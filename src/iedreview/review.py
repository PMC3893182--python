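"""The iterative certainty-ranked review loop.

Groups are presented in batches (default ten) in descending certainty.  The
reviewer confirms, rejects, or marks each presented group unsure.  Feedback
acts at two levels: within the session, the contributing templates'
effective reliabilities are recomputed from session-local count deltas and
all remaining pending groups are re-ranked, so one rejected template family
sinks every group that depends on it; at ``finalize`` the deltas are applied
to the persistent database (the global update for sustained learning) and
the confirmed groups are exported as event annotations.  An abandoned
session therefore never touches the database.

Counting is per detection: confirming or rejecting a group adds one true or
false count per member nomination, so a template contributing twice moves by
two — the same bookkeeping used to accumulate counts during training.
"unsure" contributes no deltas and the group is excluded from the export.

``simulate_review`` replaces the human with an automatic reviewer that
confirms a presented group iff it temporally overlaps a ground-truth event,
producing per-iteration cumulative recall — the machine analogue of scoring
a review against a previously marked recording.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path

import numpy as np

from .config import DEFAULT_BATCH_SIZE
from .eeg_io import EventAnnotation
from .grouping import NominationGroup, group_certainty
from .synthetic import GroundTruth
from .template_db import TemplateDatabase, apply_count_deltas, reliability


class Outcome(enum.Enum):
    CONFIRM = "confirm"
    REJECT = "reject"
    UNSURE = "unsure"


_STATUS_FOR_OUTCOME = {
    Outcome.CONFIRM: "confirmed",
    Outcome.REJECT: "rejected",
    Outcome.UNSURE: "unsure",
}


@dataclasses.dataclass
class ReviewSession:
    """State of one recording's review: pool, feedback log, pending deltas."""

    recording_id: str
    groups: dict[str, NominationGroup]
    base_counts: dict[str, tuple[int, int]]
    fallback_reliability: dict[str, float]
    batch_size: int = DEFAULT_BATCH_SIZE
    aggregator: str = "noisy_or"
    smoothing: bool = False
    iteration_index: int = 0
    feedback_log: list[dict] = dataclasses.field(default_factory=list)
    pending_deltas: dict[str, list[int]] = dataclasses.field(default_factory=dict)
    last_batch: list[str] = dataclasses.field(default_factory=list)
    deltas_applied: bool = False

    @property
    def pending(self) -> list[NominationGroup]:
        return [g for g in self.groups.values() if g.status == "pending"]

    @property
    def is_complete(self) -> bool:
        return not self.pending

    @property
    def available_iterations(self) -> int:
        """Batches needed to present every currently pending group."""
        return -(-len(self.pending) // self.batch_size)

    def current_reliability(self, template_id: str) -> float:
        """Session-local effective reliability: base counts plus deltas."""
        if template_id not in self.base_counts:
            return self.fallback_reliability.get(template_id, 0.0)
        t, f = self.base_counts[template_id]
        dt, df = self.pending_deltas.get(template_id, (0, 0))
        return reliability(t + dt, f + df, self.smoothing)


def start_session(
    groups: list[NominationGroup],
    db: TemplateDatabase,
    batch_size: int = DEFAULT_BATCH_SIZE,
    aggregator: str = "noisy_or",
) -> ReviewSession:
    """Open a review over one recording's groups, all pending.

    Certainties are (re)computed from the database's current reliabilities so
    a session always starts from the template's latest global state.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    member_ids = {m.template_id for g in groups for m in g.members}
    base_counts = {
        tid: (db.templates[tid].t_count, db.templates[tid].f_count)
        for tid in member_ids
        if tid in db.templates
    }
    fallback = {
        m.template_id: m.reliability
        for g in groups
        for m in g.members
        if m.template_id not in base_counts
    }
    recording_ids = {m.template_id.split(":")[0] for g in groups for m in g.members}
    session = ReviewSession(
        recording_id=next(iter(recording_ids)) if len(recording_ids) == 1 else "",
        groups={g.group_id: g for g in groups},
        base_counts=base_counts,
        fallback_reliability=fallback,
        batch_size=batch_size,
        aggregator=aggregator,
        smoothing=db.smoothing,
    )
    for g in session.groups.values():
        g.certainty = group_certainty(g, aggregator=aggregator,
                                      reliability_fn=session.current_reliability)
    return session


def _ranked_pending(session: ReviewSession) -> list[NominationGroup]:
    return sorted(session.pending, key=lambda g: (-g.certainty, g.start, g.group_id))


def next_batch(
    session: ReviewSession,
    order: str = "certainty",
    rng: np.random.Generator | None = None,
) -> list[NominationGroup]:
    """The next groups to present: highest certainty first (default).

    ``order='random'`` draws a uniformly random batch instead (a baseline
    presentation policy); it requires a seeded generator for replayability.
    """
    if session.is_complete:
        session.last_batch = []
        return []
    if order == "certainty":
        batch = _ranked_pending(session)[: session.batch_size]
    elif order == "random":
        if rng is None:
            raise ValueError("random order requires a numpy Generator")
        pool = sorted(session.pending, key=lambda g: g.group_id)
        pick = rng.choice(len(pool), size=min(session.batch_size, len(pool)), replace=False)
        batch = [pool[i] for i in sorted(pick)]
    else:
        raise ValueError(f"unknown presentation order {order!r}")
    session.last_batch = [g.group_id for g in batch]
    return batch


def submit_feedback(session: ReviewSession, outcomes: dict[str, Outcome]) -> ReviewSession:
    """Record one completed batch of outcomes and re-rank the pool.

    Every presented group must receive exactly one outcome; outcomes for
    groups outside the last batch are rejected.
    """
    presented = set(session.last_batch)
    given = set(outcomes)
    if given - presented:
        raise ValueError(f"outcomes for non-presented groups: {sorted(given - presented)}")
    if presented - given:
        raise ValueError(f"missing outcomes for presented groups: {sorted(presented - given)}")

    for gid in session.last_batch:
        outcome = outcomes[gid]
        if not isinstance(outcome, Outcome):
            outcome = Outcome(outcome)
        group = session.groups[gid]
        session.feedback_log.append(
            {
                "iteration": session.iteration_index,
                "group_id": gid,
                "certainty": group.certainty,
                "outcome": outcome.value,
            }
        )
        group.set_status(_STATUS_FOR_OUTCOME[outcome])
        if outcome is Outcome.UNSURE:
            continue
        slot = 0 if outcome is Outcome.CONFIRM else 1
        for m in group.members:
            delta = session.pending_deltas.setdefault(m.template_id, [0, 0])
            delta[slot] += 1

    for g in session.pending:
        g.certainty = group_certainty(g, aggregator=session.aggregator,
                                      reliability_fn=session.current_reliability)
    session.iteration_index += 1
    session.last_batch = []
    return session


def finalize(
    session: ReviewSession, db: TemplateDatabase
) -> tuple[list[EventAnnotation], TemplateDatabase]:
    """Export confirmed groups and apply the count deltas to the database.

    Idempotent: a second call exports the same annotations but applies no
    further deltas.
    """
    annotations = [
        EventAnnotation(
            recording_id=session.recording_id,
            onset_s=g.onset_s,
            duration_s=g.duration_s,
            label="ied",
            channel=";".join(sorted(g.channels)),
        )
        for g in sorted(session.groups.values(), key=lambda g: (g.start, g.group_id))
        if g.status == "confirmed"
    ]
    if not session.deltas_applied:
        deltas = {
            tid: (dt, df)
            for tid, (dt, df) in session.pending_deltas.items()
            if tid in db.templates
        }
        apply_count_deltas(db, deltas)
        session.deltas_applied = True
    return annotations, db


def write_session_log(session: ReviewSession, path: str | Path) -> None:
    """JSON-lines log: one record per presented group."""
    with open(path, "w") as fh:
        for rec in session.feedback_log:
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Simulated reviewer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulationResult:
    """Per-iteration cumulative outcome of a simulated review."""

    n_truth: int
    n_detectable: int
    confirmed_truth: list[int]  # distinct truth events found, cumulative
    presented: list[int]  # groups presented, cumulative
    confirmed_groups: list[int]  # groups confirmed, cumulative

    @property
    def iterations(self) -> int:
        return len(self.confirmed_truth)

    def recall(self, of_detectable: bool = False) -> np.ndarray:
        denom = self.n_detectable if of_detectable else self.n_truth
        if denom == 0:
            return np.zeros(self.iterations)
        return np.array(self.confirmed_truth) / denom

    def iterations_to_recall(self, level: float, of_detectable: bool = True) -> int | None:
        """First iteration (1-based) reaching the recall level, or None."""
        rec = self.recall(of_detectable)
        hits = np.nonzero(rec >= level)[0]
        return int(hits[0]) + 1 if hits.size else None


def _overlaps_truth(group: NominationGroup, truth: GroundTruth, tol_s: float) -> list[int]:
    """Indices of truth events the group's interval overlaps (with tolerance)."""
    out = []
    g0, g1 = group.onset_s, group.onset_s + group.duration_s
    for i, ev in enumerate(truth.events):
        if g0 < ev.onset_s + ev.duration_s + tol_s and ev.onset_s - tol_s < g1:
            out.append(i)
    return out


def simulate_review(
    session: ReviewSession,
    truth: GroundTruth,
    max_iterations: int = 15,
    match_tolerance_s: float = 0.0,
    order: str = "certainty",
    seed: int | None = None,
) -> SimulationResult:
    """Run the review with an automatic ground-truth reviewer.

    A presented group is confirmed iff its interval overlaps a truth event
    (truth carries no channel detail, so matching is temporal only) and
    rejected otherwise.  Returns the cumulative count of distinct truth
    events confirmed after each iteration.
    """
    rng = np.random.default_rng(seed) if order == "random" else None
    detectable = set()
    for g in session.groups.values():
        detectable.update(_overlaps_truth(g, truth, match_tolerance_s))

    found: set[int] = set()
    confirmed_truth, presented, confirmed_groups = [], [], []
    n_presented = n_confirmed = 0
    for _ in range(max_iterations):
        batch = next_batch(session, order=order, rng=rng)
        if not batch:
            # pool exhausted: repeat the final state for remaining iterations
            confirmed_truth.append(len(found))
            presented.append(n_presented)
            confirmed_groups.append(n_confirmed)
            continue
        outcomes = {}
        for g in batch:
            hits = _overlaps_truth(g, truth, match_tolerance_s)
            if hits:
                outcomes[g.group_id] = Outcome.CONFIRM
                found.update(hits)
                n_confirmed += 1
            else:
                outcomes[g.group_id] = Outcome.REJECT
        n_presented += len(batch)
        submit_feedback(session, outcomes)
        confirmed_truth.append(len(found))
        presented.append(n_presented)
        confirmed_groups.append(n_confirmed)
    return SimulationResult(
        n_truth=len(truth.events),
        n_detectable=len(detectable),
        confirmed_truth=confirmed_truth,
        presented=presented,
        confirmed_groups=confirmed_groups,
    )
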