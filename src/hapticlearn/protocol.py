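"""Targets, scoring, set composition and the two-session study schedule.

A *set* is 20 walls approaching at 1 m/s with 1 m spacing, so one target is
crossed every second.  Each wall carries a target at lateral offset
``b`` from the centerline, drawn from {-0.12, 0, +0.12} m.  The score per
wall is a linear ramp in the absolute lateral miss, and a set score is the
mean over its 20 walls.

The full protocol comprises two sessions: familiarization, baseline (BL),
training (TR, two rounds of 15 sets with catch and mirrored sets), a washout
set, short-term retention (STR) in session one, and long-term retention
(LTR) one to three days later.  BL/STR/LTR each contain two sets of the main
task (mn), two of the position transfer task (t1, fresh target sequences)
and two of the dynamics transfer task (t2, same targets, rod shortened to
70% so the natural frequency rises from 0.573 to 0.685 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .pendulum import PendulumParams, PendulumState

__all__ = [
    "WallTarget",
    "WallSchedule",
    "PlanEntry",
    "ProtocolPlan",
    "ProtocolConfig",
    "score",
    "set_score",
    "generate_wall_schedule",
    "mirror",
    "build_protocol",
    "error_at_crossing",
    "STAGES",
    "TASKS",
    "GROUPS",
]

STAGES = ("FAM", "BL", "TR", "WASHOUT", "STR", "LTR")
TASKS = ("mn", "t1", "t2")
GROUPS = ("Control", "Experimental")

#: Score cutoff: misses of 0.2 m or more score zero.
SCORE_CUTOFF = 0.2
SCORE_SLOPE = 500.0


@dataclass(frozen=True)
class WallTarget:
    """One wall target within a set."""

    wall_index: int
    offset_b: float
    crossing_time: float
    #: wall identity within the position transfer task (0 outside t1)
    new_walls: int = 0


@dataclass(frozen=True)
class WallSchedule:
    """An ordered sequence of wall targets forming one set."""

    targets: tuple[WallTarget, ...]
    mirrored: bool = False
    catch: bool = False
    task_kind: str = "mn"

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([t.offset_b for t in self.targets])

    @property
    def crossing_times(self) -> np.ndarray:
        return np.array([t.crossing_time for t in self.targets])

    @property
    def new_walls(self) -> np.ndarray:
        return np.array([t.new_walls for t in self.targets])


@dataclass(frozen=True)
class PlanEntry:
    """One set within the study protocol."""

    stage: str
    task: str
    s_index: int
    schedule: WallSchedule
    guidance_on: bool
    rod_scale: float = 1.0
    analysis: bool = True


@dataclass(frozen=True)
class ProtocolPlan:
    """The ordered full protocol of one participant."""

    group: str
    entries: tuple[PlanEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def stage_entries(self, stage: str) -> list[PlanEntry]:
        return [e for e in self.entries if e.stage == stage]


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the study schedule; defaults reproduce the deployed protocol."""

    n_walls: int = 20
    offsets: tuple[float, ...] = (-0.12, 0.0, 0.12)
    wall_spacing: float = 1.0  # m
    wall_speed: float = 1.0  # m/s
    n_baseline_sets_per_task: int = 2
    n_training_rounds: int = 2
    sets_per_round: int = 15
    #: 1-based catch-set indices within each training round (guidance off)
    catch_sets: tuple[int, ...] = (1, 6, 11)
    #: 1-based mirrored-set indices within each training round
    mirrored_sets: tuple[int, ...] = (3, 8, 13)
    transfer_rod_scale: float = 0.7
    include_familiarization: bool = True

    @property
    def wall_interval(self) -> float:
        """Time between consecutive crossings (s)."""
        return self.wall_spacing / self.wall_speed


def score(abs_error: float) -> float:
    """Per-wall score on [0, 100]: ``100 - 500 |Error|``, floored at 0.

    Continuous at the 0.2 m cutoff and non-increasing in the miss.
    """
    if abs_error < 0:
        raise ValueError("abs_error must be non-negative")
    if abs_error >= SCORE_CUTOFF:
        return 0.0
    return 100.0 - SCORE_SLOPE * abs_error


def set_score(per_wall_scores: Sequence[float]) -> float:
    """Final set score: the mean of its 20 per-wall scores."""
    if len(per_wall_scores) != 20:
        raise ValueError(f"a set has 20 walls, got {len(per_wall_scores)}")
    return float(np.mean(per_wall_scores))


def generate_wall_schedule(
    rng: np.random.Generator,
    n_walls: int = 20,
    offsets: Iterable[float] = (-0.12, 0.0, 0.12),
    wall_spacing: float = 1.0,
    wall_speed: float = 1.0,
    task_kind: str = "mn",
) -> WallSchedule:
    """Draw a schedule with uniform independent target offsets."""
    offsets = tuple(offsets)
    if n_walls < 1:
        raise ValueError("n_walls must be >= 1")
    if not offsets:
        raise ValueError("offset set must be non-empty")
    interval = wall_spacing / wall_speed
    picks = rng.integers(0, len(offsets), size=n_walls)
    targets = tuple(
        WallTarget(wall_index=k, offset_b=offsets[p], crossing_time=(k + 1) * interval)
        for k, p in enumerate(picks)
    )
    return WallSchedule(targets=targets, task_kind=task_kind)


def mirror(schedule: WallSchedule) -> WallSchedule:
    """Negate every target offset about the centerline; times preserved."""
    targets = tuple(
        replace(t, offset_b=-t.offset_b) for t in schedule.targets
    )
    return WallSchedule(
        targets=targets,
        mirrored=not schedule.mirrored,
        catch=schedule.catch,
        task_kind=schedule.task_kind,
    )


def error_at_crossing(
    state: PendulumState, target: WallTarget, params: PendulumParams | None = None
) -> float:
    """Absolute lateral miss ``|mass_y - b|`` at the wall crossing (m)."""
    params = params or PendulumParams()
    mass_y, _ = state.mass_position(params)
    return abs(mass_y - target.offset_b)


def _with_new_walls(schedule: WallSchedule, start: int) -> WallSchedule:
    targets = tuple(
        replace(t, new_walls=start + k) for k, t in enumerate(schedule.targets)
    )
    return WallSchedule(
        targets=targets,
        mirrored=schedule.mirrored,
        catch=schedule.catch,
        task_kind=schedule.task_kind,
    )


def build_protocol(
    group: str,
    rng: np.random.Generator,
    config: ProtocolConfig | None = None,
) -> ProtocolPlan:
    """Assemble the full two-session plan for one participant.

    The main-task target sequence is drawn once and reused in every mn
    repetition (BL, TR, washout, STR, LTR) except mirrored training sets;
    t2 reuses it with the shortened rod; t1 gets fresh sequences, drawn once
    per participant and reused across BL/STR/LTR so its walls keep a stable
    identity (``new_walls`` 1..40).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group: {group!r}")
    cfg = config or ProtocolConfig()
    for idx in cfg.catch_sets:
        if idx in cfg.mirrored_sets:
            raise ValueError("mirrored sets must be non-catch sets")

    def draw(task: str) -> WallSchedule:
        return generate_wall_schedule(
            rng,
            n_walls=cfg.n_walls,
            offsets=cfg.offsets,
            wall_spacing=cfg.wall_spacing,
            wall_speed=cfg.wall_speed,
            task_kind=task,
        )

    mn = draw("mn")
    mn_mirrored = mirror(mn)
    t1_sets = [
        _with_new_walls(draw("t1"), start=1 + i * cfg.n_walls)
        for i in range(cfg.n_baseline_sets_per_task)
    ]
    t2 = WallSchedule(targets=mn.targets, task_kind="t2")

    entries: list[PlanEntry] = []

    if cfg.include_familiarization:
        entries.append(
            PlanEntry(
                stage="FAM",
                task="mn",
                s_index=0,
                schedule=draw("mn"),
                guidance_on=False,
                analysis=False,
            )
        )

    def retention_block(stage: str) -> None:
        for s in range(cfg.n_baseline_sets_per_task):
            entries.append(PlanEntry(stage, "mn", s, mn, guidance_on=False))
        for s in range(cfg.n_baseline_sets_per_task):
            entries.append(PlanEntry(stage, "t1", s, t1_sets[s], guidance_on=False))
        for s in range(cfg.n_baseline_sets_per_task):
            entries.append(
                PlanEntry(
                    stage, "t2", s, t2, guidance_on=False,
                    rod_scale=cfg.transfer_rod_scale,
                )
            )

    retention_block("BL")

    s_index = 0
    for _ in range(cfg.n_training_rounds):
        for j in range(1, cfg.sets_per_round + 1):
            catch = j in cfg.catch_sets
            mirrored = j in cfg.mirrored_sets
            sched = mn_mirrored if mirrored else mn
            sched = WallSchedule(
                targets=sched.targets,
                mirrored=mirrored,
                catch=catch,
                task_kind="mn",
            )
            guidance = group == "Experimental" and not catch
            entries.append(
                PlanEntry("TR", "mn", s_index, sched, guidance_on=guidance)
            )
            s_index += 1

    entries.append(PlanEntry("WASHOUT", "mn", 0, mn, guidance_on=False))
    retention_block("STR")
    retention_block("LTR")

    return ProtocolPlan(group=group, entries=tuple(entries))
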