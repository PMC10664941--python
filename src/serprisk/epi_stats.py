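"""Registry descriptive statistics and small inferential pieces.

Validation of case registries against the closed attribute vocabulary,
count/percentage tabulations, annual averages, relative risk with a 95%
log-normal CI, chi-squared association with Cramér's V, and a Poisson
log-linear elevation-incidence fit by IRLS with a population offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AGE_BANDS = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59",
             "60-69", "70-79", "80+", "missing")

SYNDROMES = ("asymptomatic", "mild swelling", "painful progressive swelling",
             "venom ophthalmia", "progressive weakness", "bleeding")

CYTOTOXIC_SYNDROMES = ("mild swelling", "painful progressive swelling",
                       "venom ophthalmia")
#: syndromes that clinically warrant antivenom
ANTIVENOM_WARRANTED = ("painful progressive swelling",
                       "progressive weakness", "bleeding")

TABULATION_DIMENSIONS = (
    "month", "hour", "age_band", "sex", "occupation", "bite_site",
    "activity", "location", "syndrome", "first_aid_any", "antivenom",
    "outcome",
)


def age_to_band(age) -> str:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return "missing"
    age = float(age)
    if age < 0:
        raise ValueError("age must be >= 0")
    if age >= 80:
        return "80+"
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def validate_registry(registry) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a registry CSV path or DataFrame.

    Returns (accepted rows, rejections with a ``reason`` column). A row is
    rejected on its first violated invariant.
    """
    df = (pd.read_csv(registry) if not isinstance(registry, pd.DataFrame)
          else registry.copy())
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    if "hour" in df:
        hour = pd.to_numeric(df["hour"], errors="coerce")
        flag(hour.notna() & ((hour < 0) | (hour > 23)), "hour out of range")
    if "age" in df:
        age = pd.to_numeric(df["age"], errors="coerce")
        flag(age.notna() & (age < 0), "negative age")
    if "syndrome" in df:
        flag(df["syndrome"].notna() & ~df["syndrome"].isin(SYNDROMES),
             "unknown syndrome")
    if "vials" in df and "antivenom" in df:
        vials = pd.to_numeric(df["vials"], errors="coerce")
        av = df["antivenom"].astype(bool)
        flag(vials.notna() & ~av, "vials recorded without antivenom")
        flag(av & vials.notna() & ((vials < 1) | (vials > 25)),
             "vials out of range")

    rejected = df[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    accepted = df[reasons == ""].copy()
    if "age_band" not in accepted.columns and "age" in accepted.columns:
        accepted["age_band"] = accepted["age"].map(age_to_band)
    return accepted, rejected


def tabulate(cases: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Counts and percentage-of-total per category; missing values are
    their own category. Percentages are exact; round at presentation."""
    if len(cases) == 0:
        raise ValueError("empty registry")
    if dimension not in TABULATION_DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    col = cases[dimension] if dimension in cases.columns else None
    if col is None and dimension == "age_band":
        col = cases["age"].map(age_to_band)
    if col is None:
        raise ValueError(f"registry lacks column {dimension!r}")
    col = col.where(col.notna(), "missing")
    counts = col.value_counts(dropna=False).sort_index()
    out = counts.rename("count").reset_index()
    out.columns = ["category", "count"]
    out["pct"] = 100.0 * out["count"] / len(cases)
    return out


def proportion_pct(numerator: int, denominator: int) -> float:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def annual_average(cases, period_years: float) -> float:
    """Total case count divided by the period in years."""
    if period_years <= 0:
        raise ValueError("period_years must be positive")
    n = len(cases) if hasattr(cases, "__len__") else int(cases)
    return n / period_years


def relative_risk(cases_a: int, pop_a: int, cases_b: int, pop_b: int) -> dict:
    """Risk ratio of group a vs b with a 95% log-normal CI."""
    if pop_a < cases_a or pop_b < cases_b:
        raise ValueError("population cannot be smaller than case count")
    if pop_a <= 0 or pop_b <= 0 or cases_b == 0:
        raise ValueError("undefined relative risk")
    rr = (cases_a / pop_a) / (cases_b / pop_b)
    if cases_a == 0:
        return {"rr": rr, "ci_low": float("nan"), "ci_high": float("nan"),
                "ci_defined": False}
    se = math.sqrt(1 / cases_a - 1 / pop_a + 1 / cases_b - 1 / pop_b)
    return {
        "rr": rr,
        "ci_low": math.exp(math.log(rr) - 1.96 * se),
        "ci_high": math.exp(math.log(rr) + 1.96 * se),
        "ci_defined": True,
    }


def chi2_cramers_v(table) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction), df, Cramér's V."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, _, dof, _ = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    v = math.sqrt(chi2 / (n * (min(obs.shape) - 1)))
    return float(chi2), int(dof), float(v)


@dataclass
class RateFitResult:
    coef_per_100m: float         # log rate-ratio per 100 m
    se: float
    percent_change_per_100m: float  # 100 * (1 - exp(coef))
    n_iter: int
    converged: bool


def poisson_elevation_fit(counts, elevation_m, population,
                          max_iter: int = 50,
                          tol: float = 1e-8) -> RateFitResult:
    """Poisson log-linear fit of per-EA counts on elevation/100 m with a
    log-population offset, by iteratively reweighted least squares.

    log mu_i = offset_i + alpha + beta * elevation_i / 100
    """
    y = np.asarray(counts, dtype=float)
    elev = np.asarray(elevation_m, dtype=float) / 100.0
    pop = np.asarray(population, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 EAs")
    if np.any(y < 0) or np.any(pop <= 0):
        raise ValueError("counts must be >= 0 and populations > 0")
    X = np.column_stack([np.ones_like(elev), elev])
    offset = np.log(pop)
    beta = np.array([math.log(max(y.sum(), 1.0) / pop.sum()), 0.0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = offset + X @ beta
        mu = np.exp(eta)
        z = eta - offset + (y - mu) / mu      # working response
        W = mu
        XtWX = X.T @ (X * W[:, None])
        new_beta = np.linalg.solve(XtWX, X.T @ (W * z))
        step = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if step < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError("IRLS did not converge")
    mu = np.exp(offset + X @ beta)
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    se = float(np.sqrt(cov[1, 1]))
    coef = float(beta[1])
    return RateFitResult(
        coef_per_100m=coef, se=se,
        percent_change_per_100m=100.0 * (1.0 - math.exp(coef)),
        n_iter=it, converged=converged)


def expand_counts(counts: dict, column: str) -> pd.DataFrame:
    """Build a one-column registry DataFrame repeating each category by its
    count (worked-example fixtures from printed tables)."""
    values = []
    for category, n in counts.items():
        values.extend([category] * int(n))
    return pd.DataFrame({column: values})
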