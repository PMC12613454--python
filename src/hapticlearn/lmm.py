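"""Linear mixed models of motor learning and their percent-change contrasts.

Three models are fitted to the long-format trial table (one row per wall
crossing), all with crossed random intercepts and treatment coding with
reference levels Control / BL / mn:

``M1.1``  log10|Error| ~ Group x (Task + Stage)
          + (TC_c + LOC_c) x (Task + Stage + sIndex) + Task x Stage
          + Group x TC_c x Stage + (1|ID) + (1|wIndex:NewWalls)

``M1.2``  the same for log10|IntForce|, plus Group x LOC_c x Stage.

``M2``    log10|Error| ~ (AC_c + FS_c + TC_c + LOC_c) x HRIQ_c x Stage
          + (1|ID) + (1|wIndex), fitted per HRI question on the
          Experimental group's main-task data across all four stages.

M1.1/M1.2 are fitted on BL/STR/LTR (the guidance-confounded training phase
is excluded); M2 includes all stages.  The wall random effect groups on the
pair (wIndex, NewWalls) so position-transfer walls get their own levels.

Effects are reported as percent changes between two fully specified
conditions: ``100 (1 - 10^D)`` with ``D`` the difference of the fixed-effect
linear predictors, Wald confidence intervals mapped through the same
monotone transform, and Bonferroni correction over the reported family.
p-values use the normal (Wald) approximation; with thousands of rows per
fit the difference from Satterthwaite degrees of freedom is negligible,
and exact p-values are not what the percent-change estimates rest on.

REML is used for reported fits; AIC/BIC comparisons refit by ML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrices
from scipy import stats
import statsmodels.formula.api as smf

from .metrics import log10_transform

__all__ = [
    "LmmSpec",
    "MotorLearningModel",
    "MotorLearningResults",
    "EffectEstimate",
    "model_spec",
    "build_design",
    "fit_lmm",
    "percent_change_from_delta",
    "bonferroni",
    "model_compare",
    "report_effects",
    "default_contrast_plan",
    "MODEL_IDS",
]

MODEL_IDS = ("M1.1", "M1.2", "M2")

_M1_BASE = (
    "Group*(Task + Stage) + (TC_c + LOC_c)*(Task + Stage + sIndex) "
    "+ Task:Stage + Group:TC_c + Group:TC_c:Stage"
)

_HRI_QUESTIONS = ("frustration", "disturbance", "restrictiveness")


@dataclass(frozen=True)
class LmmSpec:
    """What to fit: response, fixed-effect formula, random groupings, filter."""

    model_id: str
    response: str
    rhs: str
    vc: tuple[str, ...]  # random-intercept grouping columns
    stages: tuple[str, ...]
    tasks: tuple[str, ...] | None
    groups: tuple[str, ...] | None
    question: str | None = None

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.rhs}"

    @property
    def required_condition_fields(self) -> tuple[str, ...]:
        if self.model_id == "M2":
            return ("Stage", "AC_c", "FS_c", "TC_c", "LOC_c", "HRIQ_c")
        return ("Group", "Task", "Stage", "sIndex", "TC_c", "LOC_c")


def model_spec(model_id: str, question: str = "frustration") -> LmmSpec:
    if model_id == "M1.1":
        return LmmSpec(
            model_id, "log10_abs_error", _M1_BASE,
            vc=("ID", "wall_key"),
            stages=("BL", "STR", "LTR"), tasks=None, groups=None,
        )
    if model_id == "M1.2":
        return LmmSpec(
            model_id, "log10_int_force",
            _M1_BASE + " + Group:LOC_c + Group:LOC_c:Stage",
            vc=("ID", "wall_key"),
            stages=("BL", "STR", "LTR"), tasks=None, groups=None,
        )
    if model_id == "M2":
        if question not in _HRI_QUESTIONS:
            raise ValueError(f"unknown HRI question {question!r}")
        return LmmSpec(
            "M2", "log10_abs_error",
            "(AC_c + FS_c + TC_c + LOC_c)*HRIQ_c*Stage",
            vc=("ID", "wIndex"),
            stages=("BL", "TR", "STR", "LTR"), tasks=("mn",),
            groups=("Experimental",), question=question,
        )
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def _prepare(records: pd.DataFrame, spec: LmmSpec,
             hri: pd.DataFrame | None) -> pd.DataFrame:
    df = records.copy()
    missing = {"ID", "wIndex", "Task", "Stage", "sIndex", "NewWalls",
               "abs_error", "int_force", "Group"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")

    df = df[df["Stage"].isin(spec.stages)]
    if spec.tasks is not None:
        df = df[df["Task"].isin(spec.tasks)]
    if spec.groups is not None:
        df = df[df["Group"].isin(spec.groups)]
    if spec.model_id == "M2":
        if hri is None:
            raise ValueError("M2 requires the HRI answers table")
        q = spec.question
        df = df.merge(hri[["ID", q]], on="ID", how="inner")
        df["HRIQ_c"] = df[q] - _participant_mean(df, q)
    df = df.dropna(subset=["abs_error", "int_force"]).copy()
    if not len(df):
        raise ValueError("no rows left after filtering")

    df = log10_transform(df)
    df["wall_key"] = (
        df["wIndex"].astype(str) + ":" + df["NewWalls"].astype(str)
    )
    # traits centered on the analyzed cohort
    for col in ("TC_c", "TB_c", "AC_c", "FS_c", "LOC_c"):
        if col in df.columns:
            df[col] = df[col] - _participant_mean(df, col)

    for col, levels in (
        ("Group", ("Control", "Experimental")),
        ("Task", ("mn", "t1", "t2")),
        ("Stage", ("BL", "TR", "STR", "LTR")),
    ):
        present = [l for l in levels if l in set(df[col])]
        if len(present) < 2 and col in spec.rhs:
            warnings.warn(f"factor {col} has a single level: {present}")
        df[col] = pd.Categorical(df[col], categories=present)
    df["sIndex"] = df["sIndex"].astype(float)
    return df.reset_index(drop=True)


def _participant_mean(df: pd.DataFrame, col: str) -> float:
    return float(df.drop_duplicates("ID")[col].mean())


def build_design(records: pd.DataFrame, spec: LmmSpec,
                 hri: pd.DataFrame | None = None):
    """Expand the model formula on a trial table.

    Returns ``(y, X, vc_frame, data)``: response vector, fixed-effect design
    (a patsy DataFrame whose ``design_info`` drives contrast construction),
    the random-intercept grouping columns, and the prepared data.
    """
    data = _prepare(records, spec, hri)
    y, X = dmatrices(spec.formula, data, return_type="dataframe")
    vc_frame = data[list(spec.vc)].astype(str)
    return y, X, vc_frame, data


@dataclass
class EffectEstimate:
    """A percent-change contrast between two fully specified conditions."""

    description: str
    delta_log10: float
    se_log10: float
    percent_change: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_corrected: float
    family_size: int = 1


def percent_change_from_delta(delta: float) -> float:
    """The reporting convention: ``100 (1 - 10^delta)``.

    Positive values are reductions of the outcome (e.g. a 38 % error
    reduction corresponds to delta = log10(0.62)).
    """
    return 100.0 * (1.0 - 10.0 ** delta)


def bonferroni(p_values, family_size: int):
    """Bonferroni correction: ``min(1, m p)`` element-wise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, family_size * p)
    return float(out) if out.ndim == 0 else out


def fit_lmm(
    formula: str,
    data: pd.DataFrame,
    vc_formula: Mapping[str, str] | None = None,
    groups=None,
    reml: bool = True,
    method: str = "lbfgs",
    start_params=None,
    maxiter: int = 500,
    zero_variance: bool = False,
    refine: bool = False,
):
    """Fit a mixed model with random intercepts via profiled (RE)ML.

    ``groups=None`` uses a single all-encompassing group so the variance
    components in ``vc_formula`` act as crossed random intercepts.  With
    ``zero_variance=True`` the variance components are pinned at zero, which
    reduces the fit to ordinary least squares on the fixed effects.
    ``refine=True`` restarts the optimizer at the solution for a
    high-precision optimum (used when matching closed-form estimators).
    """
    if groups is None:
        groups = np.ones(len(data))
    model = smf.mixedlm(
        formula, data=data, groups=groups,
        vc_formula=dict(vc_formula) if vc_formula else None,
        re_formula="0" if vc_formula else None,
    )
    if zero_variance:
        # pin the variance components at a negligible value: V ~ sigma^2 I,
        # so the GLS fixed effects go through the mixed-model solver but
        # must coincide with ordinary least squares
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        k_fe = model.exog.shape[1]
        k_re, k_vc = model.k_re, model.k_vc
        eps = 1e-12
        free = MixedLMParams.from_components(
            fe_params=np.ones(k_fe),
            cov_re=np.zeros((k_re, k_re)) if k_re else np.zeros((0, 0)),
            vcomp=np.zeros(k_vc),
        )
        start = MixedLMParams.from_components(
            fe_params=np.zeros(k_fe),
            cov_re=eps * np.eye(k_re) if k_re else np.zeros((0, 0)),
            vcomp=np.full(k_vc, eps),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return model.fit(free=free, start_params=start, reml=reml,
                                 maxiter=maxiter, method=method)
            except np.linalg.LinAlgError:
                # the post-fit hessian can be singular with pinned
                # components; the profiled fixed effects are still exact
                from types import SimpleNamespace

                fe_params, *_ = np.linalg.lstsq(model.exog, model.endog,
                                                rcond=None)
                resid = model.endog - model.exog @ fe_params
                scale = float(resid @ resid) / (len(model.endog) - k_fe)
                return SimpleNamespace(
                    fe_params=pd.Series(fe_params, index=model.exog_names),
                    vcomp=np.full(k_vc, eps),
                    scale=scale,
                    converged=True,
                )

    fit_kwargs: dict[str, Any] = dict(reml=reml, maxiter=maxiter)
    if start_params is not None:
        fit_kwargs.update(start_params=start_params)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method=method, **fit_kwargs)
        if refine:
            # restart at the solution for a high-precision optimum
            res = model.fit(method="powell", reml=reml, maxiter=maxiter,
                            start_params=res.params_object,
                            xtol=1e-12, ftol=1e-12)
            res = model.fit(method="lbfgs", reml=reml, maxiter=maxiter,
                            start_params=res.params_object)
    return res


class MotorLearningModel:
    """A mixed model of the pendulum-task outcomes, statsmodels-style.

    Build it from the long-format trial table, then ``fit()`` to obtain a
    :class:`MotorLearningResults` carrying estimates, uncertainties and the
    percent-change contrast machinery.
    """

    def __init__(self, records: pd.DataFrame, model_id: str = "M1.1",
                 hri: pd.DataFrame | None = None,
                 question: str = "frustration") -> None:
        self.spec = model_spec(model_id, question)
        self.records = records
        self.hri = hri
        self.y, self.X, self.vc_frame, self.data = build_design(
            records, self.spec, hri
        )
        self.design_info = self.X.design_info
        for col in self.spec.vc:
            if self.vc_frame[col].nunique() < 2:
                raise ValueError(
                    f"random-effect factor {col} needs >= 2 levels"
                )

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, model_id: str = "M1.1",
                       **kwargs) -> "MotorLearningModel":
        return cls(records, model_id=model_id, **kwargs)

    def _vc_formula(self) -> dict[str, str]:
        return {name: f"0 + C({name})" for name in self.spec.vc}

    def fit(self, reml: bool = True, method: str = "lbfgs",
            start_params=None, maxiter: int = 500) -> "MotorLearningResults":
        res = fit_lmm(
            self.spec.formula, self.data, vc_formula=self._vc_formula(),
            reml=reml, method=method, start_params=start_params,
            maxiter=maxiter,
        )
        return MotorLearningResults(self, res, reml=reml)


class MotorLearningResults:
    """Fitted mixed model: estimates, variance components, contrasts."""

    def __init__(self, model: MotorLearningModel, sm_results, reml: bool) -> None:
        self.model = model
        self.sm_results = sm_results
        self.reml = reml
        self._ml_results = None if reml else sm_results

    # -- basic accessors ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.sm_results.fe_params

    def cov_params(self) -> pd.DataFrame:
        k = len(self.params)
        return self.sm_results.cov_params().iloc[:k, :k]

    @property
    def vcomp(self) -> dict[str, float]:
        return dict(zip(self.model.spec.vc, np.asarray(self.sm_results.vcomp)))

    @property
    def scale(self) -> float:
        return float(self.sm_results.scale)

    @property
    def llf(self) -> float:
        return float(self.sm_results.llf)

    @property
    def converged(self) -> bool:
        return bool(self.sm_results.converged)

    @property
    def singular(self) -> bool:
        """A variance component collapsed to (near) zero."""
        v = np.asarray(self.sm_results.vcomp)
        return bool(np.any(v < 1e-8 * max(self.scale, 1e-12)))

    def summary(self):
        return self.sm_results.summary()

    # -- information criteria (ML-based) -----------------------------------
    def _ml(self):
        if self._ml_results is None:
            self._ml_results = self.model.fit(
                reml=False, start_params=self.sm_results.params_object
            ).sm_results
        return self._ml_results

    def information_criteria(self) -> dict[str, float]:
        """ML-based AIC/BIC (mixed models fitted by REML are refitted by ML)."""
        ml = self._ml()
        k = len(ml.fe_params) + len(np.asarray(ml.vcomp)) + 1
        n = self.model.data.shape[0]
        llf = float(ml.llf)
        return {
            "llf_ml": llf,
            "k_params": k,
            "aic": -2.0 * llf + 2.0 * k,
            "bic": -2.0 * llf + np.log(n) * k,
        }

    @property
    def aic(self) -> float:
        return self.information_criteria()["aic"]

    @property
    def bic(self) -> float:
        return self.information_criteria()["bic"]

    # -- contrasts ---------------------------------------------------------
    def design_row(self, condition: Mapping[str, Any]) -> np.ndarray:
        """Fixed-effect design row of one fully specified condition."""
        required = self.model.spec.required_condition_fields
        missing = [f for f in required if f not in condition]
        if missing:
            raise ValueError(
                f"condition is missing required fields: {missing}"
            )
        row = pd.DataFrame([dict(condition)])
        (mat,) = build_design_matrices([self.model.design_info], row)
        return np.asarray(mat)[0]

    def delta(self, cond_ref: Mapping[str, Any], cond_new: Mapping[str, Any]
              ) -> tuple[float, float]:
        """log10-scale contrast (estimate, se) between two conditions."""
        c = self.design_row(cond_new) - self.design_row(cond_ref)
        beta = np.asarray(self.params)
        V = np.asarray(self.cov_params())
        d = float(c @ beta)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        return d, se

    def percent_change(self, cond_ref: Mapping[str, Any],
                       cond_new: Mapping[str, Any],
                       family_size: int = 1, alpha: float = 0.05,
                       description: str = "") -> EffectEstimate:
        """Percent change of the outcome from ``cond_ref`` to ``cond_new``.

        ``100 (1 - 10^D)`` with a Wald CI mapped through the same monotone
        transform (so CI endpoints keep their order and coverage).
        """
        d, se = self.delta(cond_ref, cond_new)
        return self._effect(d, se, family_size, alpha, description)

    def difference_of_changes(self, pair_a, pair_b, family_size: int = 1,
                              alpha: float = 0.05,
                              description: str = "") -> EffectEstimate:
        """Contrast of two condition changes (a 'comparison of comparisons').

        ``pair_a`` and ``pair_b`` are (ref, new) condition tuples; the
        estimate is D_a - D_b on the log10 scale, reported through the
        percent-change transform.
        """
        ca = self.design_row(pair_a[1]) - self.design_row(pair_a[0])
        cb = self.design_row(pair_b[1]) - self.design_row(pair_b[0])
        c = ca - cb
        beta = np.asarray(self.params)
        V = np.asarray(self.cov_params())
        d = float(c @ beta)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        return self._effect(d, se, family_size, alpha, description)

    def _effect(self, d: float, se: float, family_size: int, alpha: float,
                description: str) -> EffectEstimate:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        if se > 0:
            p = 2.0 * stats.norm.sf(abs(d) / se)
        else:
            p = 1.0 if d == 0 else 0.0
        lo = percent_change_from_delta(d + z * se)
        hi = percent_change_from_delta(d - z * se)
        return EffectEstimate(
            description=description,
            delta_log10=d,
            se_log10=se,
            percent_change=percent_change_from_delta(d),
            ci_low=min(lo, hi),
            ci_high=max(lo, hi),
            p_raw=float(p),
            p_corrected=float(bonferroni(p, family_size)),
            family_size=family_size,
        )


def model_compare(results: Sequence[MotorLearningResults]) -> pd.DataFrame:
    """AIC/BIC comparison table (ML refits) with deltas to the best model."""
    ns = {r.model.data.shape[0] for r in results}
    resp = {r.model.spec.response for r in results}
    if len(ns) != 1 or len(resp) != 1:
        raise ValueError("model comparison requires identical datasets")
    rows = []
    for r in results:
        ic = r.information_criteria()
        rows.append({
            "model": r.model.spec.model_id,
            "llf_ml": ic["llf_ml"],
            "k_params": ic["k_params"],
            "aic": ic["aic"],
            "bic": ic["bic"],
        })
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["delta_bic"] = out["bic"] - out["bic"].min()
    return out


# ---------------------------------------------------------------------------
# default contrast plans (the bar-plot analogues)
# ---------------------------------------------------------------------------

def _m1_condition(group: str, stage: str, task: str = "mn",
                  tc: float = 0.0, loc: float = 0.0,
                  s_index: float = 0.0) -> dict[str, Any]:
    return {"Group": group, "Task": task, "Stage": stage, "sIndex": s_index,
            "TC_c": tc, "LOC_c": loc}


def default_contrast_plan(model_id: str,
                          loc_mean: float = 0.0) -> list[dict[str, Any]]:
    """Enumerate the default reported bars: group x stage x trait level.

    Trait levels follow the reporting convention: 'high/low' is +/-0.1 on
    the normalized scale, except LOC which is evaluated at the endpoints
    (raw -1 internal, +1 external, centered with the cohort mean).
    """
    if model_id not in ("M1.1", "M1.2"):
        raise ValueError("default plans exist for M1.1 and M1.2")
    plan = []
    for stage in ("STR", "LTR"):
        for group in ("Control", "Experimental"):
            base = dict(tc=0.0, loc=0.0)
            variants: list[tuple[str, dict[str, float]]] = [
                ("average", base),
                ("high TC", dict(tc=0.1, loc=0.0)),
                ("low TC", dict(tc=-0.1, loc=0.0)),
            ]
            if model_id == "M1.2" or group == "Control":
                variants += [
                    ("external LOC", dict(tc=0.0, loc=1.0 - loc_mean)),
                    ("internal LOC", dict(tc=0.0, loc=-1.0 - loc_mean)),
                ]
            for label, tl in variants:
                plan.append({
                    "label": f"{group} BL->{stage} ({label})",
                    "ref": _m1_condition(group, "BL", **tl),
                    "new": _m1_condition(group, stage, **tl),
                })
    return plan


def report_effects(results: MotorLearningResults,
                   contrast_plan: Iterable[Mapping[str, Any]] | None = None
                   ) -> pd.DataFrame:
    """Evaluate a contrast plan into the reported effect table.

    Each plan entry has ``label``, ``ref`` and ``new`` conditions; the
    Bonferroni family is the full plan.
    """
    plan = list(contrast_plan) if contrast_plan is not None else \
        default_contrast_plan(results.model.spec.model_id)
    m = len(plan)
    rows = []
    for entry in plan:
        eff = results.percent_change(
            entry["ref"], entry["new"], family_size=m,
            description=entry.get("label", ""),
        )
        rows.append({
            "label": eff.description,
            "delta_log10": eff.delta_log10,
            "percent_change": eff.percent_change,
            "ci_low": eff.ci_low,
            "ci_high": eff.ci_high,
            "p_raw": eff.p_raw,
            "p_corrected": eff.p_corrected,
        })
    return pd.DataFrame(rows)
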