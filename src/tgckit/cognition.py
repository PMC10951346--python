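"""Cognitive scoring: N-back d-prime, control-referenced z-scores, domain and
global composites, and the age-corrected 2-back z used to define impairment.

Scoring conventions
-------------------
* d' = z(hit rate) - z(false-alarm rate), with extreme rates 0 and 1 replaced
  by 1/(2N) and 1 - 1/(2N) (N the relevant trial count) before the
  inverse-normal transform, the standard correction that keeps d' finite.
* Every raw test score is z-scored against the non-psychiatric control group
  and sign-flipped where a larger raw score means worse performance, so a
  larger z always means better performance.
* Domain composites average the member tests' z-scores; the global composite
  averages the six domain composites.
* 2-back impairment: d' is referenced to an age-expected value from an OLS
  regression of d' on age in the control group; the residual-standardised z
  at or below -1 is "impaired".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import battery


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Signal-detection sensitivity d' = Phi^-1(hit) - Phi^-1(fa).

    Rates must lie strictly inside (0, 1); apply an extreme-rate correction
    (see :func:`dprime_from_counts`) before calling with boundary rates.
    """
    for name, r in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
        if r in (0.0, 1.0):
            raise ValueError(
                f"{name} of {r} gives infinite d'; correct extreme rates first"
            )
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def corrected_rate(successes: int, n: int) -> float:
    """Proportion with 0 and n pulled to 1/(2n) and 1 - 1/(2n)."""
    if n <= 0:
        raise ValueError(f"trial count must be > 0, got {n}")
    if not 0 <= successes <= n:
        raise ValueError(f"{successes} successes out of {n} trials")
    return float(np.clip(successes / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))


def dprime_from_counts(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """d' from raw N-back counts, with the 1/(2N) extreme-rate correction."""
    n_targets = hits + misses
    n_nontargets = false_alarms + correct_rejections
    return dprime(
        corrected_rate(hits, n_targets), corrected_rate(false_alarms, n_nontargets)
    )


class ControlZScorer(BaseEstimator, TransformerMixin):
    """Transformer that z-scores raw test scores against a control sample.

    Fit on the control participants only; transform any participant table.
    Tests flagged higher-is-worse are sign-flipped after standardisation so
    that larger z always means better performance.

    Parameters
    ----------
    tests : test names (columns) to score; defaults to the full battery.
    higher_is_better : per-test direction flags; defaults to the battery's.

    Attributes
    ----------
    means_, sds_ : pd.Series of per-test control mean and SD (ddof=1).
    """

    def __init__(self, tests=None, higher_is_better=None):
        self.tests = tests
        self.higher_is_better = higher_is_better

    def fit(self, X: pd.DataFrame, y=None):
        tests = list(self.tests) if self.tests is not None else list(battery.TESTS)
        missing = [t for t in tests if t not in X.columns]
        if missing:
            raise ValueError(f"control table lacks test columns: {missing}")
        sub = X[tests].astype(float)
        if len(sub) < 2:
            raise ValueError("need at least 2 control participants")
        self.means_ = sub.mean()
        self.sds_ = sub.std(ddof=1)
        zero = self.sds_[self.sds_ <= 0]
        if len(zero):
            raise ValueError(f"zero control SD for tests: {list(zero.index)}")
        flags = (
            dict(self.higher_is_better)
            if self.higher_is_better is not None
            else battery.HIGHER_IS_BETTER
        )
        self.directions_ = pd.Series(
            {t: 1.0 if flags.get(t, True) else -1.0 for t in tests}
        )
        self.tests_ = tests
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        missing = [t for t in self.tests_ if t not in X.columns]
        if missing:
            raise ValueError(f"table lacks test columns: {missing}")
        z = (X[self.tests_].astype(float) - self.means_) / self.sds_
        return z * self.directions_


def control_z(raw: float, norms: ControlZScorer, test_name: str) -> float:
    """z-score one raw test value against fitted control norms."""
    check_is_fitted(norms, "means_")
    if test_name not in norms.tests_:
        raise KeyError(f"unknown test name: {test_name!r}")
    return float(
        (raw - norms.means_[test_name])
        / norms.sds_[test_name]
        * norms.directions_[test_name]
    )


def composites(
    z_by_test: pd.DataFrame,
    domain_map: dict[str, str] | None = None,
    min_tests: int = 1,
) -> pd.DataFrame:
    """Domain composites (mean of member-test z) and the global composite
    (mean of the six domain composites).

    A domain with fewer than ``min_tests`` non-missing member scores is NaN,
    and any missing domain makes the global composite NaN for that row.
    """
    dmap = domain_map or battery.DOMAIN_MAP
    domains = sorted(set(dmap.values()), key=list(battery.DOMAINS).index) if set(
        dmap.values()
    ) <= set(battery.DOMAINS) else sorted(set(dmap.values()))
    out = pd.DataFrame(index=z_by_test.index)
    for d in domains:
        members = [t for t in z_by_test.columns if dmap.get(t) == d]
        if not members:
            out[d] = np.nan
            continue
        sub = z_by_test[members]
        enough = sub.notna().sum(axis=1) >= min_tests
        out[d] = sub.mean(axis=1).where(enough)
    out["global_cognition"] = out[domains].mean(axis=1).where(
        out[domains].notna().all(axis=1)
    )
    return out


class AgeNormRegressor(BaseEstimator):
    """Regression-based age norm for 2-back d' fitted on controls.

    OLS of d' on age in the control group; ``transform`` standardises a
    participant's d' against the age-expected value using the residual SD.

    Parameters
    ----------
    resid_ddof : "n-2" (regression degrees of freedom, default) or "n-1";
        the denominator convention is stamped into outputs via get_params.

    Attributes
    ----------
    intercept_, slope_ : regression coefficients (d' units, d'/year).
    resid_sd_ : residual standard deviation.
    n_controls_ : fitting sample size.
    """

    def __init__(self, resid_ddof: str = "n-2"):
        self.resid_ddof = resid_ddof

    def fit(self, X, y):
        ages = np.asarray(X, dtype=float).ravel()
        d = np.asarray(y, dtype=float).ravel()
        if ages.shape != d.shape:
            raise ValueError("ages and d' must have equal length")
        n = ages.size
        if n < 3:
            raise ValueError(f"need at least 3 controls to fit an age norm, got {n}")
        if np.var(ages) == 0:
            raise ValueError("control ages are constant; age norm unidentifiable")
        if self.resid_ddof not in ("n-2", "n-1"):
            raise ValueError("resid_ddof must be 'n-2' or 'n-1'")
        slope, intercept = np.polyfit(ages, d, 1)
        resid = d - (intercept + slope * ages)
        ddof = 2 if self.resid_ddof == "n-2" else 1
        resid_sd = float(np.sqrt(np.sum(resid**2) / (n - ddof)))
        if resid_sd <= 1e-12:
            raise ValueError(
                "degenerate age norm: residual SD is zero (perfectly linear d')"
            )
        self.intercept_ = float(intercept)
        self.slope_ = float(slope)
        self.resid_sd_ = resid_sd
        self.n_controls_ = int(n)
        return self

    def expected(self, age):
        check_is_fitted(self, "resid_sd_")
        return self.intercept_ + self.slope_ * np.asarray(age, dtype=float)

    def transform(self, ages, dprimes):
        """Age-corrected z = (d' - age-expected d') / residual SD."""
        check_is_fitted(self, "resid_sd_")
        return (np.asarray(dprimes, dtype=float) - self.expected(ages)) / self.resid_sd_


@dataclass
class AgeNorm:
    """Plain record of a fitted control age norm."""

    intercept: float
    slope: float
    resid_sd: float
    n_controls: int

    @classmethod
    def from_estimator(cls, est: AgeNormRegressor) -> "AgeNorm":
        return cls(est.intercept_, est.slope_, est.resid_sd_, est.n_controls_)


def fit_age_norm(control_ages, control_dprimes, resid_ddof: str = "n-2") -> AgeNorm:
    """OLS age norm on the control sample (thin wrapper over the estimator)."""
    est = AgeNormRegressor(resid_ddof=resid_ddof).fit(control_ages, control_dprimes)
    return AgeNorm.from_estimator(est)


def age_corrected_z(dprime_value: float, age: float, norm_: AgeNorm) -> float:
    if norm_.resid_sd <= 0:
        raise ValueError("residual SD must be > 0")
    return float((dprime_value - (norm_.intercept + norm_.slope * age)) / norm_.resid_sd)


def impairment_label(z) -> np.ndarray | str:
    """"impaired" iff the age-corrected z is <= -1 (boundary included)."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("age-corrected z must be finite")
    labels = np.where(arr <= -1.0, "impaired", "not_impaired")
    return labels if arr.ndim else str(labels[()])


def remove_outliers(values, ids=None, n_sd: float = 3.0):
    """Single-pass +-3 SD screen on one variable.

    Mean and SD are computed once on all values; entries more than ``n_sd``
    SDs from the mean are dropped. Returns (retained values, list of removed
    ids). Zero-variance input is returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"need at least 3 values, got {v.size}")
    idx = np.asarray(ids) if ids is not None else np.arange(v.size)
    sd = v.std(ddof=1)
    if sd == 0:
        return v, []
    keep = np.abs(v - v.mean()) <= n_sd * sd
    return v[keep], list(idx[~keep])


SCORE_COLUMNS = ("dprime_2back", "age_corrected_z", "impairment")


def score_cohort(
    cohort: pd.DataFrame, resid_ddof: str = "n-2", min_tests: int = 1
) -> pd.DataFrame:
    """Full cognitive scoring of a participant table.

    Fits control norms (test z-scores and the d'-on-age regression) on the
    ``group == "control"`` rows, then adds to every row: ``dprime_2back``,
    ``age_corrected_z``, ``impairment``, the six domain composites and
    ``global_cognition``.
    """
    required = {"group", "age", "hits", "misses", "false_alarms", "correct_rejections"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    controls = cohort[cohort["group"] == "control"]
    if len(controls) < 3:
        raise ValueError("need at least 3 control participants for norms")

    scorer = ControlZScorer().fit(controls)
    z = scorer.transform(cohort)
    comps = composites(z, min_tests=min_tests)

    d2b = cohort.apply(
        lambda r: dprime_from_counts(
            int(r["hits"]), int(r["misses"]), int(r["false_alarms"]),
            int(r["correct_rejections"]),
        ),
        axis=1,
    )
    age_norm = AgeNormRegressor(resid_ddof=resid_ddof).fit(
        controls["age"], d2b.loc[controls.index]
    )
    acz = age_norm.transform(cohort["age"], d2b)

    scored = cohort.copy()
    scored["dprime_2back"] = d2b
    scored["age_corrected_z"] = acz
    scored["impairment"] = impairment_label(acz)
    for c in comps.columns:
        scored[c] = comps[c]
    return scored
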