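"""Longitudinal growth statistics on measured intracranial volumes.

Per wave, ICV is modelled with a linear mixed model

    icv ~ sex + age_c + age_c² + (1 | subject)

with age centred at the wave mean (conditioning only; the sex coefficient is
unaffected), fitted by maximum likelihood so that the likelihood-ratio test
of the sex effect against the null model without sex is valid.

Longitudinal daily growth rates use, per subject and wave, the sweep with
the highest QC score; the rate is (ICV at 30 w − ICV at 20 w) / interval in
days, and per-sex rates are compared with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "WaveModelFit",
    "GrowthRecord",
    "fit_wave_model",
    "best_scan_per_wave",
    "change_rates",
    "welch_t",
    "two_proportion_test",
]


@dataclass(frozen=True)
class WaveModelFit:
    """Mixed-model fit of one wave.

    ``coefficients``/``std_errors`` are indexed by name (intercept, sex,
    age, age2); ``sex`` is the age-adjusted boy–girl difference in mL.
    """

    wave: str
    coefficients: dict
    std_errors: dict
    random_intercept_var: float
    residual_var: float
    log_likelihood: float
    lrt_statistic: float
    lrt_p: float
    n_obs: int
    n_subjects: int
    converged: bool


@dataclass(frozen=True)
class GrowthRecord:
    """Per-subject longitudinal change, converted to a daily rate."""

    subject_id: str
    sex: str
    delta_icv_ml: float
    interval_days: int
    rate_ml_per_day: float


def _design(sub: pd.DataFrame):
    age_c = sub["age_days"].astype(float) - sub["age_days"].astype(float).mean()
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "sex": (sub["sex"] == "boy").astype(float),
            "age": age_c,
            "age2": age_c**2,
        },
        index=sub.index,
    )
    return X, sub["icv_ml"].astype(float)


def fit_wave_model(table: pd.DataFrame, wave: str) -> WaveModelFit:
    """Fit the per-wave mixed model by maximum likelihood.

    Requires at least 2 subjects of each sex at the wave.  The sex effect is
    additionally tested with a likelihood-ratio test against the null model
    without sex (both fitted by ML).
    """
    sub = table[table["wave"] == wave]
    if sub.empty:
        raise ValueError(f"no rows for wave {wave!r}")
    for sex in ("girl", "boy"):
        if sub.loc[sub["sex"] == sex, "subject_id"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects of each sex at wave {wave}")
    X, y = _design(sub)
    groups = sub["subject_id"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = MixedLM(y, X, groups=groups).fit(reml=False)
        null = MixedLM(y, X.drop(columns="sex"), groups=groups).fit(reml=False)

    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(sps.chi2.sf(lrt, df=1))
    return WaveModelFit(
        wave=wave,
        coefficients={k: float(v) for k, v in full.fe_params.items()},
        std_errors={k: float(full.bse_fe[k]) for k in full.fe_params.index},
        random_intercept_var=float(np.asarray(full.cov_re)[0, 0]),
        residual_var=float(full.scale),
        log_likelihood=float(full.llf),
        lrt_statistic=float(lrt),
        lrt_p=p,
        n_obs=int(len(sub)),
        n_subjects=int(sub["subject_id"].nunique()),
        converged=bool(full.converged),
    )


def best_scan_per_wave(table: pd.DataFrame) -> pd.DataFrame:
    """One row per (subject, wave): the sweep with the highest QC score.

    Ties break to the larger ICV, then first occurrence — deterministic
    regardless of input row order.
    """
    if table.empty:
        return table.copy()
    df = table.reset_index(drop=True)
    df["_order"] = np.arange(len(df))
    df = df.sort_values(
        ["subject_id", "wave", "qc_dsc", "icv_ml", "_order"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    best = df.groupby(["subject_id", "wave"], as_index=False, sort=True).head(1)
    return best.drop(columns="_order").reset_index(drop=True)


def change_rates(best: pd.DataFrame) -> list[GrowthRecord]:
    """Daily ICV change rates for subjects seen at both waves.

    ``best`` should contain one row per (subject, wave) (see
    :func:`best_scan_per_wave`).  Records with a non-positive interval are
    excluded with a warning.
    """
    out: list[GrowthRecord] = []
    for sid, grp in best.groupby("subject_id", sort=True):
        waves = dict(zip(grp["wave"], grp.index))
        if "20w" not in waves or "30w" not in waves:
            continue
        r1 = grp.loc[waves["20w"]]
        r2 = grp.loc[waves["30w"]]
        interval = int(r2["age_days"]) - int(r1["age_days"])
        if interval <= 0:
            warnings.warn(
                f"subject {sid}: non-positive interval {interval} d; excluded"
            )
            continue
        delta = float(r2["icv_ml"]) - float(r1["icv_ml"])
        out.append(
            GrowthRecord(
                subject_id=str(sid),
                sex=str(r1["sex"]),
                delta_icv_ml=delta,
                interval_days=interval,
                rate_ml_per_day=delta / interval,
            )
        )
    return out


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, p)``.

    Zero variance in both groups with equal means returns ``t = 0, p = 1``
    by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    se2a, se2b = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def two_proportion_test(count1: int, n1: int, count2: int, n2: int):
    """Two-sample equal-proportion chi-square test (z² formulation).

    Returns ``(chi2, p)``.  Provided for demographic tables; carries no
    reference comparisons.
    """
    if min(n1, n2) <= 0:
        raise ValueError("group sizes must be positive")
    p_pool = (count1 + count2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (count1 / n1 - count2 / n2) / se
    chi2 = float(z**2)
    return chi2, float(sps.chi2.sf(chi2, df=1))
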