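"""Synthetic participants: trait profiles, group allocation, behavior model.

The generator's job is to emulate the statistical structure of the deposited
study — per-wall errors and interaction forces for a two-group cohort with
trait-linked effects — with *configurable, known* effect sizes, not to be a
cognitively faithful human model.  Each synthetic subject is a noisy pursuit
controller:

* an internal planner produces a swing-compensated minimum-jerk pivot path
  toward each upcoming target (the same closed-form planner the fast
  guidance backend uses);
* motor noise enters as a per-wall *target aiming error*: the subject
  misperceives the target by a zero-mean Gaussian offset and executes that
  aim accurately, so the realized miss is the aiming error itself; its
  standard deviation follows the configured learning curve
  ``sigma(s) = sigma_inf + (sigma0 - sigma_inf) exp(-k s)`` across training
  sets, with stage-level ratios setting the baseline -> retention change;
* the recorded interaction force combines the tracking force with a
  motion-neutral grip/co-contraction component (the dominant force floor,
  with wall-to-wall exertion variability), and the configured force effects
  multiply the recorded force as an isometric effort intensity;
* trait couplings: Locus of Control sets reliance on the guidance force
  (external LOC leans on it), Transform of Challenge sets effort economy,
  Free Spirit adds low-frequency exploratory jitter.

Because the injected effects are multiplicative on the emitted error and
force scales, the log10-scale truths recovered by the mixed models are known
exactly; the invariants in the test-suite verify this recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .guidance import minjerk_eval

__all__ = [
    "TraitProfile",
    "ParticipantSpec",
    "HriAnswers",
    "EffectConfig",
    "sample_cohort",
    "reliance",
    "hand_policy",
    "HandPlan",
]


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


@dataclass(frozen=True)
class TraitProfile:
    """Normalized personality trait scores of one participant.

    TC/TB/AC/FS are seven-point questionnaire scores normalized to [0, 1]
    (Transform of Challenge, Transform of Boredom, Achiever, Free Spirit);
    LOC is the 0-23 Locus of Control sum rescaled linearly to [-1, 1]
    (internal -1 ... external +1).  ``sex`` is used only to balance the
    group allocation.
    """

    tc: float
    tb: float
    ac: float
    fs: float
    loc: float
    sex: str = "F"

    def __post_init__(self) -> None:
        for name in ("tc", "tb", "ac", "fs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"trait {name}={v} outside [0, 1]")
        if not -1.0 <= self.loc <= 1.0:
            raise ValueError(f"loc={self.loc} outside [-1, 1]")

    @staticmethod
    def loc_from_raw(raw_score: float) -> float:
        """Rescale the raw 0-23 questionnaire sum linearly to [-1, 1]."""
        if not 0 <= raw_score <= 23:
            raise ValueError("raw LOC score must be in [0, 23]")
        return 2.0 * raw_score / 23.0 - 1.0


@dataclass(frozen=True)
class HriAnswers:
    """Normalized answers to the three guidance-experience questions."""

    frustration: float
    disturbance: float
    restrictiveness: float

    def __post_init__(self) -> None:
        for name in ("frustration", "disturbance", "restrictiveness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class EffectConfig:
    """Configured effect sizes of the synthetic cohort.

    The defaults are the study conditions the generator emulates: stage-level
    error ratios matching the reported percent changes (38 %/39 % error
    reduction for Control BL->STR/LTR, ~28 %/31.5 % for Experimental), force
    reductions with learning, a positive Group x LOC x Stage force coupling
    (external LOC leaning on guidance) and an effort-economy coupling for
    Transform of Challenge.  Exponent-style couplings are in log10 units so
    the mixed models' linear predictors recover them exactly.
    """

    # error (aiming noise) structure
    sigma0: float = 0.05  # BL per-wall miss sd (m)
    error_ratio_str: tuple[float, float] = (0.62, 0.72)  # (Control, Experimental)
    error_ratio_ltr: tuple[float, float] = (0.61, 0.685)
    task_error_scale: tuple[float, float, float] = (1.0, 1.0, 0.85)  # mn, t1, t2
    learning_rate: float = 0.2  # per training set
    gamma_tc_err: float = 0.22  # Control STR/LTR: x 10^(-g*TC_c)
    gamma_loc_err: float = 0.05  # Control LTR: x 10^(+g*LOC_c)
    gamma_frustration_fs: float = 0.5  # Exp LTR: x 10^(+g*frust_c*FS_c)

    # interaction force (grip component) structure
    tonic_amp0: float = 6.0  # N
    tonic_freq: float = 2.0  # Hz
    force_ratio_str: tuple[float, float] = (0.70, 0.80)
    force_ratio_ltr: tuple[float, float] = (0.68, 0.80)
    beta_loc_force: float = 0.15  # Exp STR/LTR: x 10^(beta*LOC), raw LOC
    gamma_tc_force: float = 0.25  # Control STR/LTR: x 10^(-g*TC_c)

    # guidance reliance and exploration
    gamma_loc_reliance: float = 0.7  # reliance = clip(g*(LOC+1)/2, 0, 0.9)
    #: exploratory jitter is kept small relative to the aiming noise so the
    #: configured stage ratios stay recoverable on the log scale
    gamma_fs_jitter: float = 0.005  # m of exploratory jitter per unit FS
    fs_jitter_freq: float = 0.3  # Hz

    # participant heterogeneity (log10 sd of multiplicative ID effects)
    id_sigma_log10: float = 0.065
    id_force_log10: float = 0.05
    #: wall-to-wall exertion variability of the grip amplitude (log10 sd);
    #: the dominant, independent per-wall force noise
    wall_force_log10: float = 0.12

    @classmethod
    def null(cls) -> "EffectConfig":
        """No learning, no trait couplings: for type-I error calibration."""
        return cls(
            error_ratio_str=(1.0, 1.0),
            error_ratio_ltr=(1.0, 1.0),
            task_error_scale=(1.0, 1.0, 1.0),
            learning_rate=0.0,
            gamma_tc_err=0.0,
            gamma_loc_err=0.0,
            gamma_frustration_fs=0.0,
            force_ratio_str=(1.0, 1.0),
            force_ratio_ltr=(1.0, 1.0),
            beta_loc_force=0.0,
            gamma_tc_force=0.0,
            gamma_loc_reliance=0.0,
            gamma_fs_jitter=0.0,
        )

    def group_index(self, group: str) -> int:
        return 0 if group == "Control" else 1


@dataclass(frozen=True)
class ParticipantSpec:
    """One synthetic subject: traits, allocation, and control-policy parameters."""

    id: int
    group: str
    traits: TraitProfile
    sigma0: float = 0.05  # baseline aiming sd (m)
    sigma_inf: float = 0.03  # asymptotic aiming sd (m)
    learning_rate: float = 0.2  # per practice set
    effort_scale: float = 3.0  # grip force amplitude (N)
    m_e: float = 0.5  # hand + end-effector admittance mass (kg)
    b_e: float = 5.0  # admittance damping (N s/m)
    hand_kp: float = 40.0  # hand tracking gains
    hand_kd: float = 12.0

    def __post_init__(self) -> None:
        if self.sigma_inf > self.sigma0:
            raise ValueError("sigma_inf must not exceed sigma0")
        for name in ("m_e", "b_e", "hand_kp", "hand_kd", "effort_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def reliance(spec: ParticipantSpec, cfg: EffectConfig) -> float:
    """Guidance reliance: external LOC (+1) leans on the assistance force."""
    return min(max(cfg.gamma_loc_reliance * (spec.traits.loc + 1.0) / 2.0, 0.0), 0.9)


@dataclass(frozen=True)
class HandPlan:
    """The participant's internal plan over one inter-wall interval."""

    coeffs: np.ndarray  # quintic min-jerk coefficients of the pivot path
    move_time: float
    tonic_amp: float = 0.0
    tonic_freq: float = 2.0
    tonic_phase: float = 0.0
    fs_amp: float = 0.0
    fs_freq: float = 0.3
    fs_phase: float = 0.0


def hand_policy(
    spec: ParticipantSpec,
    pivot_y: float,
    pivot_vy: float,
    plan: HandPlan,
    t: float,
    guidance_on: bool,
    cfg: EffectConfig | None = None,
) -> tuple[float, float]:
    """Human force on the end-effector (y, z components, N) at time ``t``.

    PD pursuit of the internally planned pivot path; under guidance the
    whole voluntary force is scaled by ``1 - reliance``.  The exploratory
    Free Spirit jitter perturbs the pursued reference.  The z-component is
    zero: the synthetic subject holds the vertical position fixed.
    """
    cfg = cfg or EffectConfig()
    u, ud, _ = minjerk_eval(plan.coeffs, plan.move_time, t)
    if plan.fs_amp > 0.0:
        w = 2.0 * math.pi * plan.fs_freq
        u += plan.fs_amp * math.sin(w * t + plan.fs_phase)
        ud += plan.fs_amp * w * math.cos(w * t + plan.fs_phase)
    f = spec.hand_kp * (u - pivot_y) + spec.hand_kd * (ud - pivot_vy)
    if guidance_on:
        f *= 1.0 - reliance(spec, cfg)
    return f, 0.0


def _sample_traits(rng: np.random.Generator) -> TraitProfile:
    tc, tb, ac, fs = rng.beta(3.5, 2.5, size=4)
    # approximately Gaussian, centered near zero, truncated to [-1, 1]
    loc = float(rng.normal(0.0, 0.45))
    while not -1.0 <= loc <= 1.0:
        loc = float(rng.normal(0.0, 0.45))
    sex = "F" if rng.random() < 0.5 else "M"
    return TraitProfile(tc=float(tc), tb=float(tb), ac=float(ac), fs=float(fs),
                        loc=loc, sex=sex)


def _loc_tercile(loc: float) -> int:
    if loc < -0.2:
        return 0
    if loc <= 0.2:
        return 1
    return 2


def sample_cohort(
    n: int = 40,
    rng: np.random.Generator | None = None,
    effect_config: EffectConfig | None = None,
    n_random_phase: int = 20,
) -> list[ParticipantSpec]:
    """Draw a trait-parameterized cohort with adaptive group allocation.

    The first ``n_random_phase`` participants are allocated uniformly at
    random; the rest by minimization on the (sex, LOC-tercile) marginals
    with a dominant overall-balance term, mirroring the adaptive
    randomization of the deployed study.
    """
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = rng if rng is not None else np.random.default_rng()
    cfg = effect_config or EffectConfig()

    traits = [_sample_traits(rng) for _ in range(n)]
    groups: list[str] = []
    counts = {  # [Control, Experimental] per factor level
        "sex": {"F": [0, 0], "M": [0, 0]},
        "loc": {0: [0, 0], 1: [0, 0], 2: [0, 0]},
        "total": [0, 0],
    }

    def register(i_group: int, tr: TraitProfile) -> None:
        counts["sex"][tr.sex][i_group] += 1
        counts["loc"][_loc_tercile(tr.loc)][i_group] += 1
        counts["total"][i_group] += 1

    for i, tr in enumerate(traits):
        if i < n_random_phase:
            gi = int(rng.integers(0, 2))
        else:
            scores = []
            for gi_cand in (0, 1):
                sex_c = counts["sex"][tr.sex].copy()
                loc_c = counts["loc"][_loc_tercile(tr.loc)].copy()
                tot_c = counts["total"].copy()
                sex_c[gi_cand] += 1
                loc_c[gi_cand] += 1
                tot_c[gi_cand] += 1
                scores.append(
                    abs(sex_c[0] - sex_c[1])
                    + abs(loc_c[0] - loc_c[1])
                    + 3.0 * abs(tot_c[0] - tot_c[1])
                )
            if scores[0] < scores[1]:
                gi = 0
            elif scores[1] < scores[0]:
                gi = 1
            else:
                gi = int(rng.integers(0, 2))
        register(gi, tr)
        groups.append("Control" if gi == 0 else "Experimental")

    cohort = []
    for i, (tr, grp) in enumerate(zip(traits, groups)):
        # mild multiplicative participant heterogeneity (the ID random effect)
        sig_mult = 10.0 ** rng.normal(0.0, cfg.id_sigma_log10)
        amp_mult = 10.0 ** rng.normal(0.0, cfg.id_force_log10)
        gi = cfg.group_index(grp)
        r_min = min(cfg.error_ratio_str[gi], cfg.error_ratio_ltr[gi], 1.0)
        cohort.append(
            ParticipantSpec(
                id=i + 1,
                group=grp,
                traits=tr,
                sigma0=cfg.sigma0 * sig_mult,
                sigma_inf=cfg.sigma0 * sig_mult * r_min,
                learning_rate=cfg.learning_rate,
                effort_scale=cfg.tonic_amp0 * amp_mult,
            )
        )
    return cohort
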