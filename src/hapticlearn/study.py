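"""Execute a synthetic cohort through the full two-session protocol.

``run_study`` is the data-collection stage: every participant is driven
through their protocol plan with the compiled closed-loop engine, and one
trial record per wall is emitted in the long format of the statistical
analysis (one row per target crossing).  Everything is reproducible from
``(config, seed)``: a master ``SeedSequence`` spawns one stream per
participant, and all draws happen in a fixed order.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .cohort import EffectConfig, HriAnswers, ParticipantSpec, reliance, sample_cohort
from .config import StudyConfig
from .protocol import PlanEntry, build_protocol, score

logger = logging.getLogger(__name__)

__all__ = ["StudyData", "run_study", "simulate_study", "TRIAL_COLUMNS"]

#: the long-format column model of the trial table
TRIAL_COLUMNS = [
    "ID", "wIndex", "Task", "Stage", "sIndex",
    "TC_c", "TB_c", "AC_c", "FS_c", "LOC_c",
    "NewWalls", "abs_error", "int_force", "Group", "score",
]

_TASK_INDEX = {"mn": 0, "t1": 1, "t2": 2}


@dataclass
class StudyData:
    """Output of one study run: the trial table and the HRI answers."""

    trials: pd.DataFrame
    hri: pd.DataFrame
    seed: int | None = None


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _hri_answers(spec: ParticipantSpec, cfg: EffectConfig,
                 rng: np.random.Generator) -> HriAnswers:
    """Guidance-experience answers: logistic in reliance and Free Spirit."""
    rel = reliance(spec, cfg)
    fs = spec.traits.fs
    xi = rng.normal(0.0, 0.5, size=3)
    return HriAnswers(
        frustration=_expit(-0.6 + 1.2 * rel + 1.5 * fs + xi[0]),
        disturbance=_expit(-0.8 + 1.5 * rel + 0.8 * fs + xi[1]),
        restrictiveness=_expit(-0.4 + 2.0 * rel + 0.5 * fs + xi[2]),
    )


def _stage_error_scale(entry: PlanEntry, spec: ParticipantSpec, cfg: EffectConfig,
                       tc_c: float, loc_c: float, fs_c: float, frust_c: float,
                       tr_practice: int) -> float:
    gi = cfg.group_index(spec.group)
    r_str = cfg.error_ratio_str[gi]
    r_ltr = cfg.error_ratio_ltr[gi]
    stage = entry.stage
    if stage in ("BL", "FAM"):
        s = 1.0
    elif stage == "TR":
        s = r_str + (1.0 - r_str) * math.exp(-cfg.learning_rate * tr_practice)
    elif stage == "WASHOUT":
        s = r_str
    elif stage == "STR":
        s = r_str
    elif stage == "LTR":
        s = r_ltr
    else:
        raise ValueError(f"unknown stage {stage!r}")
    if stage in ("STR", "LTR") and spec.group == "Control":
        s *= 10.0 ** (-cfg.gamma_tc_err * tc_c)
    if stage == "LTR" and spec.group == "Control":
        s *= 10.0 ** (cfg.gamma_loc_err * loc_c)
    if stage == "LTR" and spec.group == "Experimental":
        s *= 10.0 ** (cfg.gamma_frustration_fs * frust_c * fs_c)
    return s


def _stage_force_scale(entry: PlanEntry, spec: ParticipantSpec, cfg: EffectConfig,
                       tc_c: float, tr_practice: int) -> float:
    gi = cfg.group_index(spec.group)
    rf_str = cfg.force_ratio_str[gi]
    rf_ltr = cfg.force_ratio_ltr[gi]
    stage = entry.stage
    if stage in ("BL", "FAM"):
        s = 1.0
    elif stage == "TR":
        s = rf_str + (1.0 - rf_str) * math.exp(-cfg.learning_rate * tr_practice)
    elif stage in ("WASHOUT", "STR"):
        s = rf_str
    elif stage == "LTR":
        s = rf_ltr
    else:
        raise ValueError(f"unknown stage {stage!r}")
    if stage in ("STR", "LTR"):
        if spec.group == "Control":
            s *= 10.0 ** (-cfg.gamma_tc_force * tc_c)
        else:
            s *= 10.0 ** (cfg.beta_loc_force * spec.traits.loc)
    return s


def run_study(
    cohort: list[ParticipantSpec],
    config: StudyConfig | None = None,
    seed: int = 0,
) -> StudyData:
    """Simulate every participant through the two-session protocol.

    Returns the long-format trial table (familiarization excluded; washout
    rows carry Stage="WASHOUT" and are dropped by the analysis filters) and
    the HRI answers of the Experimental group.  A numerically diverged set
    aborts that trial: its rows keep NaN outcomes and a warning is logged;
    the run continues.
    """
    config = config or StudyConfig()
    cfg = config.effects
    pend = config.pendulum
    sim = config.sim

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(cohort))

    # centered trait copies over the full cohort (the analysis convention)
    tc_m = float(np.mean([p.traits.tc for p in cohort]))
    tb_m = float(np.mean([p.traits.tb for p in cohort]))
    ac_m = float(np.mean([p.traits.ac for p in cohort]))
    fs_m = float(np.mean([p.traits.fs for p in cohort]))
    loc_m = float(np.mean([p.traits.loc for p in cohort]))

    # HRI answers first (the frustration coupling feeds back into LTR errors)
    hri_rows = []
    hri_map: dict[int, HriAnswers] = {}
    for spec, cs in zip(cohort, child_seeds):
        if spec.group != "Experimental":
            continue
        rng_h = np.random.default_rng(cs.spawn(1)[0])
        ans = _hri_answers(spec, cfg, rng_h)
        hri_map[spec.id] = ans
        hri_rows.append(
            {"ID": spec.id, "frustration": ans.frustration,
             "disturbance": ans.disturbance,
             "restrictiveness": ans.restrictiveness}
        )
    hri = pd.DataFrame(hri_rows, columns=["ID", "frustration", "disturbance",
                                          "restrictiveness"])
    frust_m = float(hri["frustration"].mean()) if len(hri) else 0.0

    records: dict[str, list] = {c: [] for c in TRIAL_COLUMNS}
    n_walls = config.protocol.n_walls
    interval = config.protocol.wall_interval

    for spec, cs in zip(cohort, child_seeds):
        rng = np.random.default_rng(cs)
        plan = build_protocol(spec.group, rng, config.protocol)
        tc_c = spec.traits.tc - tc_m
        tb_c = spec.traits.tb - tb_m
        ac_c = spec.traits.ac - ac_m
        fs_c = spec.traits.fs - fs_m
        loc_c = spec.traits.loc - loc_m
        frust_c = (
            hri_map[spec.id].frustration - frust_m
            if spec.id in hri_map else 0.0
        )
        rel = reliance(spec, cfg)

        tr_practice = 0
        for entry in plan:
            guided = entry.guidance_on and spec.group == "Experimental"
            err_scale = _stage_error_scale(
                entry, spec, cfg, tc_c, loc_c, fs_c, frust_c, tr_practice
            )
            force_scale = _stage_force_scale(entry, spec, cfg, tc_c, tr_practice)
            if entry.stage == "TR":
                tr_practice += 1

            task_scale = cfg.task_error_scale[_TASK_INDEX[entry.task]]
            sigma = spec.sigma0 * err_scale * task_scale
            amp = spec.effort_scale
            khp, khd = spec.hand_kp, spec.hand_kd
            if guided:
                khp *= 1.0 - rel
                khd *= 1.0 - rel
                amp *= 1.0 - rel

            noise_z = rng.standard_normal(n_walls)
            tonic_phase = rng.uniform(0.0, 2.0 * np.pi, n_walls)
            fs_phase = float(rng.uniform(0.0, 2.0 * np.pi))
            # wall-to-wall exertion variability of the grip amplitude
            amp_walls = amp * 10.0 ** rng.normal(
                0.0, cfg.wall_force_log10, n_walls
            )

            L = pend.l * entry.rod_scale
            abs_error, int_force, ok = _engine.simulate_set_fast(
                sim.dt, n_walls, interval,
                L, pend.m, pend.g, pend.c,
                spec.m_e, spec.b_e,
                khp, khd,
                config.guidance.kp if guided else 0.0,
                config.guidance.kd if guided else 0.0,
                guided,
                entry.schedule.offsets, noise_z,
                np.full(n_walls, sigma),
                amp_walls, cfg.tonic_freq, tonic_phase,
                cfg.gamma_fs_jitter * spec.traits.fs, cfg.fs_jitter_freq, fs_phase,
                sim.move_frac, sim.n_lin_steps,
            )
            if not ok:
                warnings.warn(
                    f"simulation diverged: participant {spec.id}, "
                    f"{entry.stage}/{entry.task} set {entry.s_index}"
                )
                logger.warning("diverged trial flagged: ID=%d %s", spec.id, entry)
            if not entry.analysis:
                continue

            nw = entry.schedule.new_walls
            for w in range(n_walls):
                records["ID"].append(spec.id)
                records["wIndex"].append(w)
                records["Task"].append(entry.task)
                records["Stage"].append(entry.stage)
                records["sIndex"].append(entry.s_index)
                records["TC_c"].append(tc_c)
                records["TB_c"].append(tb_c)
                records["AC_c"].append(ac_c)
                records["FS_c"].append(fs_c)
                records["LOC_c"].append(loc_c)
                records["NewWalls"].append(int(nw[w]))
                records["abs_error"].append(abs_error[w])
                # the configured effort effects act as a multiplicative
                # intensity on the whole exchanged force (isometric effort
                # scales force output at unchanged kinematics), keeping the
                # injected log10-scale effects exact
                records["int_force"].append(int_force[w] * force_scale)
                records["Group"].append(spec.group)
                records["score"].append(
                    score(abs_error[w]) if np.isfinite(abs_error[w]) else np.nan
                )

    trials = pd.DataFrame(records, columns=TRIAL_COLUMNS)
    return StudyData(trials=trials, hri=hri, seed=seed)


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Sample a cohort and run it: the one-call entry point of the pipeline."""
    config = config or StudyConfig()
    ss = np.random.SeedSequence([seed, 424243])
    rng = np.random.default_rng(ss)
    cohort = sample_cohort(config.n_participants, rng, config.effects)
    return run_study(cohort, config, seed=seed)
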