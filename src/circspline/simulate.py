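"""Synthetic ABPM cohort generator.

Emulates the design of a 24-h ambulatory monitoring study: 49 readings per
subject at 30-min intervals from noon to noon, diary wake/sleep times, and
a linear mixed-model data-generating process on the unconstrained piecewise
linear spline basis with subject-specific knots:

    y_ij = (b0 + b_{0i}) + sum_k (beta_k + b_{ki}) s_k(t_ij) + eps_ij,

with ``b_i ~ MVN(0, Sigma_b)`` (intercept + 5 slopes, unstructured) and
AR(1) Gaussian residuals, optionally scaled by a group SD ratio.  The
default parameters are the published SBP estimates this package was built
around: intercept 134 mmHg, segment slopes (0.02, -1.00, -1.93, 1.69,
2.23) mmHg/30 min, the 6x6 random-effect covariance assembled from the
printed variances (223.6, 0.51, 0.55, 1.39, 0.66, 2.05) and correlations,
residual SD 12.3 mmHg and AR(1) rho 0.27.

The generator is deliberately *unconstrained*: the five default slopes do
not satisfy the periodicity identity for any fixed width set, so they can
be used verbatim as generating truth; the constrained model's correctness
is checked through its algebraic properties instead.

Wake/sleep diary times are truncated-normal draws (means 08:00 and 23:00,
i.e. 40 and 22 half-slots) restricted to the knot-ordering windows.
Missingness (independent per-slot dropout plus optional planted gap runs)
is off by default and exists to exercise the QC rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import DEFAULT_COMMON_KNOTS, eval_splines, make_knots
from .profiles import ABPMProfile

log = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "default_config", "simulate_cohort", "apply_missingness"]

#: printed random-effect variances: intercept then the 5 segment slopes
DEFAULT_VARIANCES = (223.6, 0.51, 0.55, 1.39, 0.66, 2.05)
#: printed lower-triangle correlations, rows 2..6
DEFAULT_CORRELATIONS = (
    (-0.23,),
    (-0.23, -0.10),
    (-0.23, -0.45, 0.03),
    (0.46, -0.28, -0.74, -0.05),
    (0.34, -0.06, -0.21, -0.78, 0.19),
)
DEFAULT_SLOPES = (0.02, -1.00, -1.93, 1.69, 2.23)


def _assemble_cov(variances, correlations, eig_floor: float = 1e-8) -> np.ndarray:
    """Covariance from variances + lower-triangle correlations, projected to
    the nearest PSD matrix (eigenvalue clipping) if rounding broke PSD-ness."""
    m = len(variances)
    C = np.eye(m)
    for i, row in enumerate(correlations, start=1):
        for j, r in enumerate(row):
            C[i, j] = C[j, i] = r
    sd = np.sqrt(np.asarray(variances, dtype=float))
    S = sd[:, None] * C * sd[None, :]
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < eig_floor:
        clipped = np.clip(vals, eig_floor, None)
        S_fixed = vecs @ np.diag(clipped) @ vecs.T
        log.info(
            "covariance repaired to PSD: eigenvalue delta %.3e, Frobenius delta %.3e",
            float(eig_floor - vals.min()),
            float(np.linalg.norm(S_fixed - S)),
        )
        S = S_fixed
    return S


@dataclass(frozen=True)
class CovariateModel:
    """Simple marginal covariate generators matched to the study cohort:
    age ~ N(59.9, 5.5) years, sex ~ Bernoulli(0.45) (male), BMI ~ N(28.5,
    4.5) kg/m^2.  Effects on BP default to zero (covariates as noise)."""

    age_mean: float = 59.9
    age_sd: float = 5.5
    male_prob: float = 0.45
    bmi_mean: float = 28.5
    bmi_sd: float = 4.5
    effects: tuple = (0.0, 0.0, 0.0)  # additive mmHg per (year, male, kg/m^2)


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 300
    slots: tuple = tuple(range(49))  # nominal half-hour grid, noon to noon
    intercept: float = 134.0  # mmHg at 12:00
    slopes: tuple = DEFAULT_SLOPES  # mmHg per 30 min, segments 1..5
    Sigma_b: np.ndarray = field(
        default_factory=lambda: _assemble_cov(DEFAULT_VARIANCES, DEFAULT_CORRELATIONS)
    )
    sigma: float = 12.3  # residual SD, mmHg
    rho: float = 0.27  # AR(1) over one nominal 30-min slot
    wake_mean: float = 40.0  # 08:00
    wake_sd: float = 2.0  # 1 h
    sleep_mean: float = 22.0  # 23:00
    sleep_sd: float = 2.0
    wake_range: tuple = (33.0, 47.5)
    sleep_range: tuple = (12.5, 31.5)
    common_knots: tuple = DEFAULT_COMMON_KNOTS
    group_prevalence: float = 0.0
    group_effect: float = 0.0  # additive mmHg for group == 1
    group_slope_effects: tuple | None = None  # per-segment slope shifts for group 1
    group_sd_ratio: float = 1.0  # residual SD ratio group1 / group0
    covariates: CovariateModel = CovariateModel()
    dropout: float = 0.0  # independent per-slot missingness probability
    gap_prob: float = 0.0  # probability of one planted gap run per subject
    gap_length: int = 5  # slots removed per planted gap
    seed: int | None = None

    def validate(self) -> None:
        Sb = np.asarray(self.Sigma_b, dtype=float)
        if Sb.shape != (6, 6):
            raise ValueError("Sigma_b must be 6x6 (intercept + 5 slopes)")
        if np.linalg.eigvalsh((Sb + Sb.T) / 2).min() < -1e-8:
            raise ValueError("Sigma_b is not PSD; run the repair step")
        if not 0.0 <= self.group_prevalence <= 1.0:
            raise ValueError("group_prevalence must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.sigma < 0 or self.group_sd_ratio <= 0:
            raise ValueError("sigma must be >= 0 and group_sd_ratio > 0")
        t = np.asarray(self.slots, dtype=float)
        if t.min() < 0 or t.max() > 48:
            raise ValueError("slot grid must lie within [0, 48]")
        if len(self.slopes) != 5:
            raise ValueError("need 5 segment slopes")


def default_config(**overrides) -> SimulationConfig:
    """The published-parameter configuration (see module docstring);
    keyword overrides replace individual fields."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    # rejection sampling: windows are several SDs wide, acceptance is high
    out = rng.normal(mean, sd, size=size)
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out <= lo) | (out >= hi)
    return out


def _ar1_noise(rng, slots: np.ndarray, rho: float, n: int) -> np.ndarray:
    """n draws of a unit-variance AR(1) vector with corr rho^|slot diff|."""
    if rho == 0.0:
        return rng.standard_normal((n, slots.size))
    D = np.abs(slots[:, None] - slots[None, :])
    L = np.linalg.cholesky(rho**D + 1e-12 * np.eye(slots.size))
    return rng.standard_normal((n, slots.size)) @ L.T


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[ABPMProfile], pd.DataFrame]:
    """Draw a cohort; returns (profiles, truth table).

    The truth table has one row per subject: the drawn random effects
    (``b0, b1..b5``), diary times, group/covariate values, and — after any
    missingness — the expected QC outcome, for recovery and QC tests.
    Deterministic given config + seed (seed argument wins over config.seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    if n < 1:
        raise ValueError("n_subjects must be >= 1")
    slots = np.asarray(config.slots, dtype=float)

    wake = _truncnorm(rng, config.wake_mean, config.wake_sd, *config.wake_range, size=n)
    sleep = _truncnorm(
        rng, config.sleep_mean, config.sleep_sd, *config.sleep_range, size=n
    )
    group = (rng.random(n) < config.group_prevalence).astype(int)
    cm = config.covariates
    age = rng.normal(cm.age_mean, cm.age_sd, size=n)
    sex = (rng.random(n) < cm.male_prob).astype(int)
    bmi = rng.normal(cm.bmi_mean, cm.bmi_sd, size=n)

    b = rng.multivariate_normal(
        np.zeros(6), np.asarray(config.Sigma_b, dtype=float), size=n,
        method="eigh",  # tolerates exactly-singular covariances
    )
    noise = _ar1_noise(rng, slots, config.rho, n)

    betas = np.asarray(config.slopes, dtype=float)
    profiles = []
    rows = []
    for i in range(n):
        knots = make_knots(wake[i], sleep[i], config.common_knots)
        S = eval_splines(slots, knots)  # (m, 5)
        slope_i = betas + b[i, 1:]
        if group[i] and config.group_slope_effects is not None:
            slope_i = slope_i + np.asarray(config.group_slope_effects, dtype=float)
        mean = (
            config.intercept
            + b[i, 0]
            + S @ slope_i
            + group[i] * config.group_effect
            + cm.effects[0] * age[i]
            + cm.effects[1] * sex[i]
            + cm.effects[2] * bmi[i]
        )
        sd_i = config.sigma * (config.group_sd_ratio if group[i] else 1.0)
        y = mean + sd_i * noise[i]
        profiles.append(
            ABPMProfile(
                subject_id=f"S{i + 1:04d}",
                slots=slots.copy(),
                values=y,
                wake_time=float(wake[i]),
                sleep_time=float(sleep[i]),
                covariates={
                    "age": float(age[i]),
                    "sex": int(sex[i]),
                    "bmi": float(bmi[i]),
                    "group": int(group[i]),
                },
            )
        )
        rows.append(
            {
                "subject_id": f"S{i + 1:04d}",
                "b0": b[i, 0],
                **{f"b{k}": b[i, k] for k in range(1, 6)},
                "wake_time": wake[i],
                "sleep_time": sleep[i],
                "group": int(group[i]),
                "age": age[i],
                "sex": int(sex[i]),
                "bmi": bmi[i],
            }
        )
    truth = pd.DataFrame(rows).set_index("subject_id")

    if config.dropout > 0 or config.gap_prob > 0:
        profiles, gap_log = apply_missingness(profiles, config, rng=rng)
        truth = truth.join(gap_log)
    return profiles, truth


def _expected_qc(profile: ABPMProfile, min_day=20, min_night=7, max_gap=4):
    """Book-keeping re-statement of the inclusion rules for the truth log
    (kept independent of the qc_filter implementation on purpose)."""
    t = profile.slots
    night = (t >= profile.sleep_time) & (t < profile.wake_time)
    n_day = int(np.sum(~night))
    n_night = int(np.sum(night))
    present = np.zeros(49, dtype=bool)
    present[np.round(t).astype(int)] = True
    run = best = 0
    for p_ in present:
        run = 0 if p_ else run + 1
        best = max(best, run)
    if n_day < min_day:
        return False, "min_day"
    if n_night < min_night:
        return False, "min_night"
    if best > max_gap:
        return False, "max_gap"
    return True, ""


def apply_missingness(
    profiles,
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ABPMProfile], pd.DataFrame]:
    """Thin profiles by independent dropout plus optional planted gap runs.

    Returns the thinned profiles and a truth log with the number of removed
    slots and the expected QC decision per profile under the default rules.
    """
    if not 0.0 <= config.dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    rows = []
    for p in profiles:
        keep = rng.random(p.n_readings) >= config.dropout
        gap_start = -1
        if config.gap_prob > 0 and rng.random() < config.gap_prob:
            gap_start = int(rng.integers(0, max(p.n_readings - config.gap_length, 1)))
            keep[gap_start : gap_start + config.gap_length] = False
        if keep.sum() < 2:  # keep degenerate profiles representable
            keep[:2] = True
        thinned = replace(p, slots=p.slots[keep], values=p.values[keep])
        kept_expected, reason = _expected_qc(thinned)
        out.append(thinned)
        rows.append(
            {
                "subject_id": p.subject_id,
                "n_removed": int((~keep).sum()),
                "gap_start": gap_start,
                "qc_expected_keep": kept_expected,
                "qc_expected_reason": reason,
            }
        )
    return out, pd.DataFrame(rows).set_index("subject_id")
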