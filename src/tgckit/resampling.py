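"""Bootstrap confidence intervals for the TGC cutoff, its operating
characteristics, and the rival Cohen's d's; plus the bootstrapped
train/validation-split cross-validation variant.

Both pipelines resample the n patients with replacement B times (the
published analysis used B = 5000 draws of n = 211). In the plain bootstrap
each resample re-derives the Youden-optimal cutoff and recomputes every
statistic on that same resample. In the cross-validation variant each
resample is randomly split into a training half (floor(n/2)) that derives
the cutoff and a validation half (ceil(n/2)) on which the operating
characteristics and effect sizes are evaluated — quantifying how the cutoff
generalises to data it was not derived on.

Confidence intervals are 95% percentile intervals (2.5th/97.5th percentiles
of the bootstrap distribution). Impairment labels, z-scores and outlier
screening are fixed participant attributes and are NOT recomputed inside
iterations; only the cutoff and the effect sizes are. Iterations whose
resample (or half-split) fails a precondition — a single-class label set, or
a split leaving a group with fewer than two members — are dropped from the
percentiles and counted. Point estimates always come from the full,
non-resampled cohort. One master seed drives a per-iteration
``SeedSequence`` child, so iteration i is reproducible in isolation.

Significance of the d_tgc - d_diagnosis contrast is read off the percentile
CI of the difference: significant iff the interval excludes zero. The two
d's are computed on the same participants and are positively correlated, so
overlapping individual CIs do not imply a non-significant difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutoff import _youden_scan
from .effects import DEFAULT_OUTCOMES

CUTOFF_STATS = ("c", "sensitivity", "specificity", "j")


def _d_magnitude(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned pooled-SD Cohen's d; NaN when a group has < 2 members.

    Degenerate zero-variance, zero-difference splits give 0 (matches
    :func:`tgckit.effects.cohens_d`).
    """
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return np.nan
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        return 0.0 if diff == 0 else np.nan
    return abs(diff) / np.sqrt(sp2)


@dataclass
class BootstrapSummary:
    """Percentile-bootstrap summary of the cutoff pipeline.

    ``stats`` maps each statistic name (``c``, ``sensitivity``,
    ``specificity``, ``j`` and ``d_tgc``/``d_diagnosis``/``d_difference``
    per outcome) to point estimate (full cohort), percentile bounds, and the
    bootstrap mean.
    """

    stats: dict[str, dict[str, float]]
    B: int
    seed: int
    n: int
    n_valid: int
    n_dropped: int
    kind: str  # "bootstrap" or "crossval"
    ci_method: str = "percentile"
    ci_level: float = 0.95
    outcomes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "B": self.B,
            "seed": self.seed,
            "n": self.n,
            "n_valid": self.n_valid,
            "n_dropped": self.n_dropped,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "outcomes": list(self.outcomes),
            "stats": self.stats,
        }


def _prepare(scored: pd.DataFrame, outcomes, patient_groups):
    patients = scored[scored["group"].isin(patient_groups)]
    for col in ("tgc", "impairment"):
        if col not in patients.columns:
            raise ValueError(f"scored cohort lacks column {col!r}")
    missing = [o for o in outcomes if o not in patients.columns]
    if missing:
        raise ValueError(f"scored cohort lacks outcome columns: {missing}")
    x = patients["tgc"].to_numpy(dtype=float)
    imp = patients["impairment"].astype(str).to_numpy() == "impaired"
    diag = patients["group"].astype(str).to_numpy() == patient_groups[0]
    Y = patients[list(outcomes)].to_numpy(dtype=float)
    if imp.all() or not imp.any():
        raise ValueError("full cohort has single-class impairment labels")
    return x, imp, diag, Y


def _stat_names(outcomes) -> list[str]:
    names = list(CUTOFF_STATS)
    for o in outcomes:
        names += [f"d_tgc:{o}", f"d_diagnosis:{o}", f"d_difference:{o}"]
    return names


def _evaluate(x, imp, diag, Y, fit_x=None, fit_imp=None) -> np.ndarray | None:
    """One pipeline pass: derive the cutoff on (fit_x, fit_imp) — default the
    evaluation data itself — then evaluate sens/spec/J and all effect sizes
    on (x, imp, diag, Y). Returns the stat vector, or None if a
    precondition fails."""
    fx = x if fit_x is None else fit_x
    fi = imp if fit_imp is None else fit_imp
    if fi.all() or not fi.any() or not imp.any() or imp.all():
        return None
    c, _, _, _, _, _ = _youden_scan(fx, fi)
    low = x < c
    sens = (low & imp).sum() / imp.sum()
    spec = (~low & ~imp).sum() / (~imp).sum()
    out = [c, sens, spec, sens + spec - 1.0]
    for k in range(Y.shape[1]):
        y = Y[:, k]
        ok = ~np.isnan(y)
        d_t = _d_magnitude(y[low & ok], y[~low & ok])
        d_d = _d_magnitude(y[diag & ok], y[~diag & ok])
        if np.isnan(d_t) or np.isnan(d_d):
            return None
        out += [d_t, d_d, d_t - d_d]
    return np.array(out)


def _summarise(point, draws, names, B, seed, n, kind, outcomes, ci_level=0.95):
    draws = np.asarray(draws)
    n_valid = draws.shape[0]
    alpha = (1.0 - ci_level) / 2.0
    stats: dict[str, dict[str, float]] = {}
    for j, name in enumerate(names):
        col = draws[:, j] if n_valid else np.array([np.nan])
        lo, hi = np.percentile(col, [100 * alpha, 100 * (1 - alpha)])
        stats[name] = {
            "point": float(point[j]),
            "lower": float(lo),
            "upper": float(hi),
            "boot_mean": float(col.mean()),
        }
    return BootstrapSummary(
        stats=stats, B=B, seed=seed, n=n, n_valid=n_valid,
        n_dropped=B - n_valid, kind=kind, ci_level=ci_level,
        outcomes=tuple(outcomes),
    )


def bootstrap_pipeline(
    scored: pd.DataFrame,
    B: int = 5000,
    seed: int = 0,
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
    patient_groups: tuple[str, str] = ("MCI", "MCI+rMDD"),
) -> BootstrapSummary:
    """Percentile-bootstrap CIs for the cutoff, its operating
    characteristics, and the per-outcome effect sizes.

    Each of the B iterations draws n patients with replacement, re-derives
    the Youden-optimal cutoff on the resample, and recomputes every
    statistic on that resample.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x, imp, diag, Y = _prepare(scored, outcomes, patient_groups)
    n = x.size
    point = _evaluate(x, imp, diag, Y)
    if point is None:
        raise ValueError("full-cohort pipeline failed a precondition")
    draws = []
    for child in np.random.SeedSequence(seed).spawn(B):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, n)
        row = _evaluate(x[idx], imp[idx], diag[idx], Y[idx])
        if row is not None:
            draws.append(row)
    return _summarise(
        point, draws, _stat_names(outcomes), B, seed, n, "bootstrap", outcomes
    )


def crossval_pipeline(
    scored: pd.DataFrame,
    B: int = 5000,
    seed: int = 0,
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
    patient_groups: tuple[str, str] = ("MCI", "MCI+rMDD"),
) -> BootstrapSummary:
    """Bootstrapped half-split cross-validation of the cutoff pipeline.

    Each iteration resamples n with replacement, randomly splits the
    resample into a training half (floor(n/2)) and a validation half
    (ceil(n/2)), derives the cutoff on the training half and evaluates the
    operating characteristics and effect sizes on the validation half.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x, imp, diag, Y = _prepare(scored, outcomes, patient_groups)
    n = x.size
    n_train = n // 2
    point = _evaluate(x, imp, diag, Y)
    draws = []
    for child in np.random.SeedSequence(seed).spawn(B):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, n)
        perm = rng.permutation(n)
        tr, va = idx[perm[:n_train]], idx[perm[n_train:]]
        row = _evaluate(
            x[va], imp[va], diag[va], Y[va], fit_x=x[tr], fit_imp=imp[tr]
        )
        if row is not None:
            draws.append(row)
    return _summarise(
        point, draws, _stat_names(outcomes), B, seed, n, "crossval", outcomes
    )


def significance_of_difference(summary: BootstrapSummary, outcome: str) -> str:
    """"significant" iff the 95% CI of d_difference excludes 0 for the outcome."""
    key = f"d_difference:{outcome}"
    if key not in summary.stats:
        raise KeyError(f"summary has no d_difference entry for outcome {outcome!r}")
    lo, hi = summary.stats[key]["lower"], summary.stats[key]["upper"]
    return "significant" if (lo > 0.0 or hi < 0.0) else "not_significant"
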