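"""Effect sizes and descriptive group comparisons.

The central quantity is the pooled-SD Cohen's d between two groups on a
cognitive outcome, computed for two rival splits of the same patients —
low vs high TGC at a biomarker cutoff, and MCI vs MCI+rMDD by clinical
diagnosis — together with their difference d_tgc - d_diagnosis. Effect
magnitudes are reported unsigned (the comparable quantity); the direction is
carried separately.

Summary-statistic t-tests (Welch by default, pooled optional) and Pearson
chi-square without continuity correction reproduce published
group-comparison tables from printed means/SDs/counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .battery import DOMAINS
from .cutoff import assign_tgc_groups

DEFAULT_OUTCOMES: tuple[str, ...] = ("global_cognition",) + DOMAINS


def cohens_d(group_a, group_b) -> tuple[float, int]:
    """Pooled-SD standardised mean difference.

    Returns (magnitude, direction) where direction = sign(mean_a - mean_b).
    d = |mean_a - mean_b| / s_p, s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) /
    (n_a + n_b - 2).

    Two identical degenerate groups (zero pooled variance, zero mean
    difference) return (0.0, 0); zero pooled variance with distinct means is
    an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 observations, got {a.size} and {b.size}"
        )
    diff = a.mean() - b.mean()
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 <= 0:
        if diff == 0:
            return 0.0, 0
        raise ValueError("zero pooled variance with unequal means; d undefined")
    d = diff / np.sqrt(sp2)
    return float(abs(d)), int(np.sign(d))


@dataclass
class EffectComparison:
    """Per-outcome Cohen's d under the TGC split and the diagnosis split."""

    outcome: str
    d_tgc: float
    d_diagnosis: float
    d_difference: float
    direction_tgc: int
    direction_diagnosis: int
    n_low: int
    n_high: int
    n_mci: int
    n_rmdd: int


def effect_comparison(
    scored: pd.DataFrame,
    c: float,
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
    patient_groups: tuple[str, str] = ("MCI", "MCI+rMDD"),
) -> pd.DataFrame:
    """Cohen's d per outcome for the TGC split at cutoff ``c`` and for the
    diagnostic split, restricted to the patient groups.

    Returns one row per outcome with columns d_tgc, d_diagnosis,
    d_difference (= d_tgc - d_diagnosis on magnitudes), directions and group
    sizes. An outcome whose split leaves an empty (or singleton) group is
    flagged with NaN effects.
    """
    patients = scored[scored["group"].isin(patient_groups)]
    if "tgc" not in patients.columns:
        raise ValueError("scored cohort lacks a 'tgc' column")
    tgc_group = assign_tgc_groups(patients["tgc"].to_numpy(), c)
    rows = []
    for outcome in outcomes:
        if outcome not in patients.columns:
            raise ValueError(f"scored cohort lacks outcome column {outcome!r}")
        y = patients[outcome].to_numpy(dtype=float)
        try:
            d_t, s_t = cohens_d(y[tgc_group == "low"], y[tgc_group == "high"])
            d_d, s_d = cohens_d(
                y[patients["group"] == patient_groups[0]],
                y[patients["group"] == patient_groups[1]],
            )
            rows.append(
                EffectComparison(
                    outcome, d_t, d_d, d_t - d_d, s_t, s_d,
                    int((tgc_group == "low").sum()), int((tgc_group == "high").sum()),
                    int((patients["group"] == patient_groups[0]).sum()),
                    int((patients["group"] == patient_groups[1]).sum()),
                )
            )
        except ValueError:
            rows.append(
                EffectComparison(
                    outcome, np.nan, np.nan, np.nan, 0, 0,
                    int((tgc_group == "low").sum()), int((tgc_group == "high").sum()),
                    int((patients["group"] == patient_groups[0]).sum()),
                    int((patients["group"] == patient_groups[1]).sum()),
                )
            )
    return pd.DataFrame([vars(r) for r in rows]).set_index("outcome")


def summary_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sample t statistic and df from summary statistics.

    ``welch`` (default): unequal-variance t with Welch-Satterthwaite df;
    ``pooled``: classical equal-variance t with df = n_a + n_b - 2.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be > 0")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if variant == "welch":
        t = (mean_a - mean_b) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    elif variant == "pooled":
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    else:
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    return float(t), float(df)


def pearson_chi_square(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df for an r x c count table.

    No continuity correction (required to reproduce published 2 x 2 values).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    stat, _, df, _ = chi2_contingency(obs, correction=False)
    return float(stat), int(df)
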