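"""Circadian model assembly: from ABPM profiles to fitted spline mixed models.

Wires the spline basis and the LMM engine into the three model layers used
for 24-h BP analysis:

* a base model — intercept + five piecewise-linear segment slopes (all
  random), AR(1) residuals;
* a covariate-adjusted model — plus age, sex, BMI and a binary group
  indicator (e.g. microalbuminuria) as fixed effects;
* a group-interaction model — plus group x segment-slope interactions,
  optionally group-specific residual variance and an independent random
  block for the interactions.

Fits can use the unconstrained basis (five free slopes) or the
periodicity-constrained basis, in which the first-segment slope is not a
free parameter but derived from the constraint; its point estimate and
delta-method SE are reported at the cohort-mean segment widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .basis import (
    DEFAULT_COMMON_KNOTS,
    KnotSet,
    constrain,
    eval_splines,
    make_knots,
)

__all__ = [
    "ModelSpec",
    "CircadianFit",
    "SEGMENT_LABELS",
    "build",
    "fit_circadian",
    "compare_groups",
    "predict_population",
    "predict_subject",
]

SEGMENT_LABELS = (
    "12:00-18:00",
    "18:00-sleep",
    "sleep-04:00",
    "04:00-wake",
    "wake-12:00",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition."""

    constrained: bool = False
    covariates: tuple = ()  # fixed-effect covariate names from profile.covariates
    group: str | None = None  # binary group covariate name
    group_spline_interactions: bool = False
    random_terms: str = "all"  # "all" (intercept + every spline term) | "intercept"
    ar1: bool = True
    group_residual_variance: bool = False
    random_group_interactions: bool = False
    response: str = "sbp"

    def validate(self) -> None:
        if self.group_spline_interactions and self.group is None:
            raise ValueError("group_spline_interactions requires a group covariate")
        if self.random_group_interactions and not self.group_spline_interactions:
            raise ValueError(
                "random_group_interactions requires group_spline_interactions"
            )
        if self.group_residual_variance and self.group is None:
            raise ValueError("group_residual_variance requires a group covariate")
        if self.random_terms not in ("all", "intercept"):
            raise ValueError("random_terms must be 'all' or 'intercept'")


@dataclass
class CircadianFit:
    """A fitted circadian spline model plus its reporting layer."""

    fitted: lmm.FittedModel
    spec: ModelSpec
    data: lmm.MixedModelData
    mean_widths: np.ndarray  # cohort-mean segment widths (reporting convention)
    slope_table: pd.DataFrame  # per-segment slope, SE, derived flag
    periodicity_check: float  # population prediction at t=48 minus t=0
    common_knots: tuple = DEFAULT_COMMON_KNOTS
    _eblups: pd.DataFrame | None = None

    @property
    def eblups(self) -> pd.DataFrame:
        if self._eblups is None:
            self._eblups = lmm.eblup(self.fitted, self.data)
        return self._eblups

    def sigma6(self) -> np.ndarray:
        """Random-effect covariance over (intercept, all 5 segment slopes).

        For an unconstrained fit with all terms random this is the free 6x6
        estimate.  For a constrained fit the free matrix is 5x5 (intercept +
        segments 2-5); the first-segment row is derived through the
        constraint at the cohort-mean widths and the result is labelled as
        such by the ``derived`` flag in ``slope_table``.
        """
        Sb = self.fitted.Sigma_b
        if not self.spec.constrained or Sb.shape[0] != 5:
            return Sb
        w = self.mean_widths
        c = -w[1:] / w[0]
        T = np.zeros((6, 5))
        T[0, 0] = 1.0
        T[1, 1:] = c
        T[2:, 1:] = np.eye(4)
        return T @ Sb[:5, :5] @ T.T


def _spline_columns(profile, constrained: bool, common_knots) -> tuple[np.ndarray, KnotSet]:
    knots = make_knots(profile.wake_time, profile.sleep_time, common_knots)
    s = eval_splines(np.asarray(profile.slots, dtype=float), knots)
    if constrained:
        s = constrain(s, knots)
    return s, knots


def build(
    profiles, spec: ModelSpec, common_knots=DEFAULT_COMMON_KNOTS
) -> lmm.MixedModelData:
    """Assemble the stacked mixed-model design from QC-passed profiles."""
    spec.validate()
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")

    spline_names = (
        [f"s{k}*" for k in range(2, 6)] if spec.constrained else [f"s{k}" for k in range(1, 6)]
    )
    cov_names = list(spec.covariates)
    if spec.group is not None and spec.group not in cov_names:
        cov_names.append(spec.group)
    x_names = ["intercept"] + spline_names + cov_names
    if spec.group_spline_interactions:
        x_names += [f"{spec.group}:{s}" for s in spline_names]
    z_names = ["intercept"] + (spline_names if spec.random_terms == "all" else [])
    if spec.random_group_interactions:
        z_names = z_names + [f"{spec.group}:{s}" for s in spline_names]

    # covariate sanity: present everywhere, non-constant, group binary
    cov_matrix = {}
    for c in cov_names:
        vals = []
        for p in profiles:
            if c not in p.covariates:
                raise ValueError(f"profile {p.subject_id} lacks covariate {c!r}")
            vals.append(float(p.covariates[c]))
        vals = np.asarray(vals)
        if np.all(vals == vals[0]):
            raise ValueError(f"covariate {c!r} is constant")
        cov_matrix[c] = vals
    if spec.group is not None:
        gv = set(cov_matrix[spec.group])
        if not gv <= {0.0, 1.0}:
            raise ValueError(f"group covariate {spec.group!r} must be binary 0/1, saw {sorted(gv)}")

    blocks = []
    n_spline = len(spline_names)
    for i, p in enumerate(profiles):
        if not p.has_diary:
            raise ValueError(f"profile {p.subject_id} lacks diary times")
        S, _ = _spline_columns(p, spec.constrained, common_knots)
        ones = np.ones(p.n_readings)
        cols = [ones, S]
        for c in cov_names:
            cols.append(np.full(p.n_readings, cov_matrix[c][i]))
        g = float(cov_matrix[spec.group][i]) if spec.group is not None else 0.0
        if spec.group_spline_interactions:
            cols.append(g * S)
        X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
        z_cols = [ones]
        if spec.random_terms == "all":
            z_cols.append(S)
        if spec.random_group_interactions:
            z_cols.append(g * S)
        Z = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in z_cols])
        blocks.append(
            lmm.SubjectBlock(
                subject_id=p.subject_id,
                y=np.asarray(p.values, dtype=float),
                X=X,
                Z=Z,
                slots=np.asarray(p.slots, dtype=float),
                var_group=int(g) if spec.group_residual_variance else 0,
            )
        )
    q_main = 1 + (n_spline if spec.random_terms == "all" else 0)
    re_blocks = (q_main, n_spline) if spec.random_group_interactions else (q_main,)
    return lmm.MixedModelData(
        blocks=blocks,
        x_names=x_names,
        z_names=z_names,
        re_blocks=re_blocks,
        n_var_groups=2 if spec.group_residual_variance else 1,
    )


def _mean_widths(profiles, common_knots) -> np.ndarray:
    widths = [
        make_knots(p.wake_time, p.sleep_time, common_knots).widths for p in profiles
    ]
    return np.asarray(widths, dtype=float).mean(axis=0)


def _slope_table(fitted: lmm.FittedModel, spec: ModelSpec, mean_w: np.ndarray) -> pd.DataFrame:
    if not spec.constrained:
        names = [f"s{k}" for k in range(1, 6)]
        est = [float(fitted.beta[n]) for n in names]
        se = [float(fitted.se[n]) for n in names]
        derived = [False] * 5
    else:
        names = [f"s{k}*" for k in range(2, 6)]
        est_rest = np.array([float(fitted.beta[n]) for n in names])
        # first-segment slope implied by the constraint at cohort-mean widths;
        # linear in beta, so the delta-method SE is exact
        c = -mean_w[1:] / mean_w[0]
        cov = fitted.cov_beta.loc[names, names].to_numpy()
        b1 = float(c @ est_rest)
        se1 = float(np.sqrt(c @ cov @ c))
        est = [b1] + est_rest.tolist()
        se = [se1] + [float(fitted.se[n]) for n in names]
        derived = [True, False, False, False, False]
    return pd.DataFrame(
        {
            "segment": list(SEGMENT_LABELS),
            "slope": est,
            "se": se,
            "derived": derived,
        }
    )


def fit_circadian(
    profiles,
    spec: ModelSpec = ModelSpec(),
    seed: int | None = None,
    criterion: str = "REML",
    common_knots=DEFAULT_COMMON_KNOTS,
    **fit_kwargs,
) -> CircadianFit:
    """Build and fit one circadian spline model; see :func:`build`."""
    profiles = list(profiles)
    data = build(profiles, spec, common_knots)
    fitted = lmm.fit(data, criterion=criterion, ar1=spec.ar1, seed=seed, **fit_kwargs)
    mean_w = _mean_widths(profiles, common_knots)
    table = _slope_table(fitted, spec, mean_w)
    cfit = CircadianFit(
        fitted=fitted,
        spec=spec,
        data=data,
        mean_widths=mean_w,
        slope_table=table,
        periodicity_check=0.0,
        common_knots=common_knots,
    )
    grid = np.array([0.0, 48.0])
    traj = predict_population(cfit, grid=grid)
    cfit.periodicity_check = float(traj["mean"].iloc[1] - traj["mean"].iloc[0])
    return cfit


def compare_groups(
    profiles, spec: ModelSpec, seed: int | None = None, **fit_kwargs
) -> dict:
    """Group-comparison workflow: main effect, per-segment interactions, LRTs.

    The group main effect and its 95% CI come from the REML no-interaction
    fit; the interaction test compares ML refits (REML log-likelihoods are
    not comparable across different fixed effects).  When the spec requests
    them, also reports the group residual-SD ratio and the LRT for the
    independent random-interaction block.
    """
    spec.validate()
    if spec.group is None:
        raise ValueError("compare_groups requires spec.group")
    profiles = list(profiles)
    gvals = [float(p.covariates.get(spec.group, np.nan)) for p in profiles]
    n1 = int(np.nansum(gvals))
    if n1 < 2 or len(profiles) - n1 < 2:
        raise ValueError(f"each {spec.group!r} level needs >= 2 subjects")

    base_spec = replace(
        spec,
        group_spline_interactions=False,
        random_group_interactions=False,
    )
    inter_spec = replace(spec, group_spline_interactions=True)

    base = fit_circadian(profiles, base_spec, seed=seed, criterion="REML", **fit_kwargs)
    est = float(base.fitted.beta[spec.group])
    se = float(base.fitted.se[spec.group])
    zcrit = float(stats.norm.ppf(0.975))
    wald_p = 2 * float(stats.norm.sf(abs(est / se))) if se > 0 else np.nan

    base_ml = fit_circadian(profiles, base_spec, seed=seed, criterion="ML", **fit_kwargs)
    inter_ml = fit_circadian(
        profiles,
        replace(inter_spec, random_group_interactions=False, group_residual_variance=False),
        seed=seed,
        criterion="ML",
        **fit_kwargs,
    )
    test = lmm.lrt(base_ml.fitted, inter_ml.fitted)

    spline_names = (
        [f"s{k}*" for k in range(2, 6)] if spec.constrained else [f"s{k}" for k in range(1, 6)]
    )
    inter_rows = []
    for name in spline_names:
        col = f"{spec.group}:{name}"
        inter_rows.append(
            {
                "term": col,
                "estimate": float(inter_ml.fitted.beta[col]),
                "se": float(inter_ml.fitted.se[col]),
            }
        )

    report = {
        "group": spec.group,
        "n_group1": n1,
        "n_group0": len(profiles) - n1,
        "group_effect": est,
        "group_effect_se": se,
        "group_effect_ci95": (est - zcrit * se, est + zcrit * se),
        "group_effect_p": wald_p,
        "interactions": pd.DataFrame(inter_rows),
        "lrt_interaction": {"statistic": test.statistic, "df": test.df, "p": test.p},
        "loglik_ml_null": base_ml.fitted.loglik,
        "loglik_ml_interaction": inter_ml.fitted.loglik,
        "base_fit": base,
        "interaction_fit": inter_ml,
    }

    if spec.group_residual_variance:
        hetero = fit_circadian(
            profiles,
            replace(base_spec, group_residual_variance=True),
            seed=seed,
            criterion="REML",
            **fit_kwargs,
        )
        test_var = lmm.lrt(base.fitted, hetero.fitted)  # same fixed effects: REML OK
        report["group_sd_ratio"] = float(hetero.fitted.var_ratio[1])
        report["lrt_group_variance"] = {
            "statistic": test_var.statistic,
            "df": test_var.df,
            "p": test_var.p,
            "p_boundary": test_var.p_boundary,
        }
    if spec.random_group_interactions:
        rnd_int = fit_circadian(
            profiles,
            replace(inter_spec, random_group_interactions=True, group_residual_variance=False),
            seed=seed,
            criterion="ML",
            **fit_kwargs,
        )
        test_rnd = lmm.lrt(inter_ml.fitted, rnd_int.fitted)
        report["lrt_random_interactions"] = {
            "statistic": test_rnd.statistic,
            "df": test_rnd.df,
            "p": test_rnd.p,
            "p_boundary": test_rnd.p_boundary,
        }
    return report


def predict_population(
    cfit: CircadianFit,
    wake: float = 40.0,
    sleep: float = 22.0,
    covariate_values: dict | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Population trajectory with pointwise 95% CI at display knots.

    Display knots default to sleep 23:00 / wake 08:00.  Covariate values
    default to 0 (so for the base model this is the modelled mean curve).
    """
    knots = make_knots(wake, sleep, cfit.common_knots)
    t = np.linspace(0.0, 48.0, 97) if grid is None else np.asarray(grid, dtype=float)
    S = eval_splines(t, knots)
    if cfit.spec.constrained:
        S = constrain(S, knots)
    cov_vals = covariate_values or {}
    names = cfit.fitted.x_names
    n_spline = S.shape[1]
    X = np.zeros((t.size, len(names)))
    X[:, 0] = 1.0
    X[:, 1 : 1 + n_spline] = S
    for j, name in enumerate(names[1 + n_spline :], start=1 + n_spline):
        if ":" in name:  # group x spline interaction
            gname, sname = name.split(":", 1)
            g = float(cov_vals.get(gname, 0.0))
            k = names.index(sname)
            X[:, j] = g * X[:, k]
        else:
            X[:, j] = float(cov_vals.get(name, 0.0))
    beta = cfit.fitted.beta.to_numpy()
    mean = X @ beta
    var = np.einsum("ij,jk,ik->i", X, cfit.fitted.cov_beta.to_numpy(), X)
    half = 1.959963984540054 * np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame({"t": t, "mean": mean, "lo": mean - half, "hi": mean + half})


def fit_summary(cfit: CircadianFit) -> dict:
    """JSON-ready summary mirroring the usual reporting layout: fixed
    effects with SEs, the per-segment slope table, the random-effect
    variance/correlation split, sigma, rho, R^2 and the log-likelihood."""
    f = cfit.fitted
    r2m, r2c = lmm.r2(f, cfit.data)
    S6 = cfit.sigma6()
    m = S6.shape[0]
    sd = np.sqrt(np.maximum(np.diag(S6), 1e-300))
    corr = S6 / np.outer(sd, sd)
    labels = (["intercept"] + list(SEGMENT_LABELS))[:m] if m <= 6 else list(cfit.fitted.z_names)
    return {
        "criterion": f.criterion,
        "converged": bool(f.converged),
        "fixed_effects": {n: [float(f.beta[n]), float(f.se[n])] for n in f.x_names},
        "slope_table": cfit.slope_table.to_dict(orient="records"),
        "random_effects": {
            "labels": labels,
            "variances": np.diag(S6).tolist(),
            "correlations": [
                [round(float(corr[i, j]), 6) for j in range(i)] for i in range(1, m)
            ],
            "segment1_derived": bool(cfit.spec.constrained),
        },
        "sigma": float(f.sigma),
        "rho": float(f.rho),
        "var_ratio": np.asarray(f.var_ratio).tolist(),
        "loglik": float(f.loglik),
        "r2_marginal": float(r2m),
        "r2_conditional": float(r2c),
        "periodicity_check": float(cfit.periodicity_check),
        "mean_widths": cfit.mean_widths.tolist(),
        "constrained": bool(cfit.spec.constrained),
    }


def predict_subject(cfit: CircadianFit, subject_id: str) -> pd.DataFrame:
    """EBLUP-based trajectory for one fitted subject on its own knots."""
    for b in cfit.data.blocks:
        if b.subject_id == subject_id:
            bi = cfit.eblups.loc[subject_id].to_numpy()
            fit_vals = b.X @ cfit.fitted.beta.to_numpy() + b.Z @ bi
            return pd.DataFrame({"t": b.slots, "value": fit_vals})
    raise KeyError(f"unknown subject {subject_id!r}")
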