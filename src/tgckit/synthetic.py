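"""Synthetic cohorts and synthetic phase-amplitude-coupled EEG.

The cohort generator emulates a three-group study of older adults —
non-psychiatric controls, mild cognitive impairment (MCI), and MCI with
remitted major depressive disorder (MCI+rMDD) — in which a single latent
prefrontal-function factor drives both a theta-gamma-coupling (TGC) biomarker
and performance across a neuropsychological battery, while the clinical
diagnosis label carries (by construction) no cognitive signal beyond the
shared patient-level deficit. This is the world in which a biomarker-based
split should separate cognition and a diagnosis-based split should not.

Model, per participant i with group g(i):

* latent factor        L_i ~ N(0, 1)
* age                  age_i ~ N(mu_g, sd_g)
* TGC                  T_i = b_T + a_T L_i + s_T eta_i, clipped to >= 1e-6
* test z-scale score   z_it = delta_g + lambda_d(t) L_i + sigma eps_it
  (raw score = control mean + direction * control SD * z_it)
* 2-back d'            D_i = beta0 + beta1 (age_i - age_ref) + delta'_g
                              + gamma L_i + s_D xi_i
* N-back counts        hits ~ Bin(n_targets, Phi(D_i / 2)),
                       false alarms ~ Bin(n_nontargets, Phi(-D_i / 2))
  — an equal-bias (criterion c = 0) signal-detection response model.

delta_g is 0 for controls and a common deficit for both patient groups, so
the MCI vs MCI+rMDD contrast has population Cohen's d = 0 on every cognitive
outcome, while the TGC median split has the closed-form d given by
:func:`split_cohens_d_from_rho`.

All randomness flows from one integer seed through ``numpy.random
.SeedSequence`` children (a counter-based splitting scheme), so identical
specs give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .battery import (
    CONTROL_CALIBRATION,
    DOMAINS,
    DOMAIN_MAP,
    HIGHER_IS_BETTER,
    TESTS,
    tests_in_domain,
)
from .eeg import EpochedEEG, FRONTAL_ELECTRODES

GROUPS = ("control", "MCI", "MCI+rMDD")

_M = 2.0 * math.sqrt(2.0 / math.pi)  # mean gap between half-normal halves
_K = 2.0 / math.pi  # variance absorbed by a median split


def split_cohens_d_from_rho(rho: float) -> float:
    """Population Cohen's d between the halves of a median split.

    For a bivariate normal (T, Y) with correlation ``rho``, splitting on the
    median of T and comparing Y between the halves gives
    ``d = m * rho / sqrt(1 - k * rho**2)`` with ``m = 2 sqrt(2/pi)``
    (the gap between the means of the upper and lower half-normal) and
    ``k = 2/pi`` (the between-half variance removed from each half).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {rho}")
    return _M * rho / math.sqrt(1.0 - _K * rho * rho)


def rho_from_split_cohens_d(d: float) -> float:
    """Inverse of :func:`split_cohens_d_from_rho` (d >= 0)."""
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    return d / math.sqrt(_M * _M + _K * d * d)


def _composite_noise_sd(noise_sd: float) -> float:
    # global composite noise: mean over 6 domains of per-domain mean noise
    inv = sum(1.0 / len(tests_in_domain(d)) for d in DOMAINS)
    return noise_sd / len(DOMAINS) * math.sqrt(inv)


def domain_loadings_for_split_d(
    target_d: float = 0.6,
    noise_sd: float = 0.8,
    tgc_reliability: float = 0.65,
) -> dict[str, float]:
    """Solve for equal per-domain latent loadings giving a planted effect.

    Returns loadings lambda such that the population Cohen's d on the global
    cognition composite between low/high-TGC halves (median split) equals
    ``target_d``, given per-test noise SD and the TGC-latent correlation
    (``tgc_reliability``).
    """
    rho = rho_from_split_cohens_d(target_d)
    rho_y = rho / tgc_reliability
    if not rho_y < 1.0:
        raise ValueError(
            f"target d {target_d} unreachable at TGC reliability {tgc_reliability}"
        )
    sigma_g = _composite_noise_sd(noise_sd)
    lam = rho_y * sigma_g / math.sqrt(1.0 - rho_y * rho_y)
    return {d: lam for d in DOMAINS}


@dataclass
class CohortSpec:
    """Stated world for a synthetic cohort.

    Defaults emulate the published sample: 128 MCI, 83 MCI+rMDD and 78
    controls; TGC centred at 0.0018 with SD 0.0012; patient deficit -0.8 z
    on cognition and -0.8 d' units on the 2-back; and latent loadings solved
    so the population TGC-median-split d on the global composite is 0.6.
    """

    n_control: int = 78
    n_mci: int = 128
    n_rmdd: int = 83
    age_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"control": 71.5, "MCI": 71.96, "MCI+rMDD": 70.83}
    )
    age_sd_by_group: dict[str, float] = field(
        default_factory=lambda: {"control": 6.0, "MCI": 7.23, "MCI+rMDD": 4.74}
    )
    latent_effect_tgc: float | None = None  # a_T; resolved from reliability if None
    latent_effect_domains: dict[str, float] | None = None  # lambda_d; solved if None
    noise_sd: float = 0.8  # sigma, per-test z-scale noise
    dprime_slope: float = 0.5  # gamma, d' units per latent unit
    seed: int = 0

    # TGC marginal calibration
    tgc_baseline: float = 0.0018
    tgc_sd: float = 0.0012
    tgc_reliability: float = 0.65  # corr(TGC, latent); splits tgc_sd into a_T, s_T
    tgc_floor: float = 1e-6

    # planted effect on the global composite (used only when loadings are None)
    target_split_d: float = 0.6

    # cognition / d' calibration
    patient_deficit_z: float = -0.8
    patient_deficit_dprime: float = -0.8
    dprime_base: float = 2.0
    dprime_age_slope: float = -0.03  # d' per year
    dprime_age_ref: float = 71.5
    dprime_noise_sd: float = 0.5  # s_D
    n_targets: int = 60
    n_nontargets: int = 120
    prop_male: float = 0.39

    def __post_init__(self) -> None:
        for name in ("n_control", "n_mci", "n_rmdd"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        for g in GROUPS:
            if self.age_sd_by_group[g] <= 0:
                raise ValueError(f"age SD for {g} must be > 0")
        for name in ("noise_sd", "tgc_sd", "dprime_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.tgc_reliability < 1.0:
            raise ValueError("tgc_reliability must be in (0, 1)")
        if self.latent_effect_tgc is None:
            self.latent_effect_tgc = self.tgc_reliability * self.tgc_sd
        if self.latent_effect_domains is None:
            self.latent_effect_domains = domain_loadings_for_split_d(
                self.target_split_d, self.noise_sd, self.tgc_reliability
            )
        missing = set(DOMAINS) - set(self.latent_effect_domains)
        if missing:
            raise ValueError(f"loadings missing for domains: {sorted(missing)}")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_mci + self.n_rmdd

    def population_split_d(self) -> float:
        """Closed-form population d on the global composite for a TGC median split.

        Ignores the positivity clip on TGC, which relabels no one at a median
        split (clipped values are already in the low half).
        """
        lam_bar = float(np.mean([self.latent_effect_domains[d] for d in DOMAINS]))
        sigma_g = _composite_noise_sd(self.noise_sd)
        s_y = math.hypot(lam_bar, sigma_g)
        a_t = self.latent_effect_tgc
        s_t = math.sqrt(max(self.tgc_sd**2 - a_t**2, 0.0))
        rho = lam_bar * a_t / (s_y * math.hypot(a_t, s_t))
        return split_cohens_d_from_rho(rho)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort; one row per participant.

    Columns: ``participant_id``, ``group``, ``age``, ``sex``, N-back counts
    (``hits``, ``misses``, ``false_alarms``, ``correct_rejections``), one raw
    score per battery test, ``tgc`` (weighted MI units) and the generating
    ``latent_factor`` (kept for diagnostics; never used downstream).
    """
    ss = np.random.SeedSequence(spec.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("age", "latent", "sex", "tgc", "tests", "dprime", "counts"),
            ss.spawn(7),
        )
    }
    n = spec.n_total
    groups = np.array(
        ["control"] * spec.n_control + ["MCI"] * spec.n_mci + ["MCI+rMDD"] * spec.n_rmdd
    )
    age = np.empty(n)
    for g in GROUPS:
        mask = groups == g
        age[mask] = rngs["age"].normal(
            spec.age_mean_by_group[g], spec.age_sd_by_group[g], mask.sum()
        )
    latent = rngs["latent"].standard_normal(n)
    sex = np.where(rngs["sex"].random(n) < spec.prop_male, "M", "F")
    is_patient = groups != "control"

    a_t = spec.latent_effect_tgc
    s_t = math.sqrt(max(spec.tgc_sd**2 - a_t**2, 0.0))
    tgc = spec.tgc_baseline + a_t * latent + s_t * rngs["tgc"].standard_normal(n)
    tgc = np.maximum(tgc, spec.tgc_floor)

    cols: dict[str, np.ndarray] = {}
    deficit = np.where(is_patient, spec.patient_deficit_z, 0.0)
    for t in TESTS:
        mean, sd = CONTROL_CALIBRATION[t]
        lam = spec.latent_effect_domains[DOMAIN_MAP[t]]
        z = deficit + lam * latent + spec.noise_sd * rngs["tests"].standard_normal(n)
        direction = 1.0 if HIGHER_IS_BETTER[t] else -1.0
        cols[t] = mean + direction * sd * z

    dprime = (
        spec.dprime_base
        + spec.dprime_age_slope * (age - spec.dprime_age_ref)
        + np.where(is_patient, spec.patient_deficit_dprime, 0.0)
        + spec.dprime_slope * latent
        + spec.dprime_noise_sd * rngs["dprime"].standard_normal(n)
    )
    hit_p = norm.cdf(dprime / 2.0)
    fa_p = norm.cdf(-dprime / 2.0)
    hits = rngs["counts"].binomial(spec.n_targets, hit_p)
    fas = rngs["counts"].binomial(spec.n_nontargets, fa_p)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "group": groups,
            "age": age,
            "sex": sex,
            "hits": hits,
            "misses": spec.n_targets - hits,
            "false_alarms": fas,
            "correct_rejections": spec.n_nontargets - fas,
            **cols,
            "tgc": tgc,
            "latent_factor": latent,
        }
    )


@dataclass
class SignalSpec:
    """Stated world for a synthetic theta-gamma phase-amplitude-coupled signal.

    ``chi`` is the modulation depth: 0 gives a gamma envelope constant over
    theta phase, 1 makes the envelope span [0, a_gamma] once per theta cycle.
    ``snr`` is the theta amplitude (1.0) over the white-noise SD.
    """

    f_theta: float = 6.0  # Hz
    f_gamma: float = 40.0  # Hz
    chi: float = 0.5
    sample_rate: float = 1000.0  # Hz
    epoch_length: float = 2.0  # seconds
    n_epochs: int = 30
    snr: float = 5.0
    seed: int = 0
    a_gamma: float = 1.0
    n_channels: int = 9
    channel_labels: tuple[str, ...] | None = None
    trial_proportions: tuple[float, float, float, float] = (0.4, 0.1, 0.4, 0.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError(f"chi must be in [0, 1], got {self.chi}")
        if not 0.0 < self.f_theta < self.f_gamma:
            raise ValueError("need f_gamma > f_theta > 0")
        if self.sample_rate <= 2.0 * self.f_gamma:
            raise ValueError(
                f"sample rate {self.sample_rate} Hz violates the Nyquist "
                f"condition for f_gamma = {self.f_gamma} Hz"
            )
        if self.n_epochs < 1 or self.epoch_length <= 0 or self.snr <= 0:
            raise ValueError("n_epochs >= 1, epoch_length > 0, snr > 0 required")
        if self.channel_labels is None:
            self.channel_labels = FRONTAL_ELECTRODES[: self.n_channels]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")


def generate_coupled_eeg(spec: SignalSpec) -> EpochedEEG:
    """Synthesise epoched EEG with parametric theta-gamma coupling.

    Each epoch is ``s(t) = A(t) sin(2 pi f_gamma t) + sin(2 pi f_theta t)
    + noise`` with gamma envelope ``A(t) = a_gamma * [(1 - chi) + chi * (1 +
    cos(2 pi f_theta t)) / 2]``; channels share the deterministic carrier and
    receive independent white noise of SD ``1/snr``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_samples = int(round(spec.epoch_length * spec.sample_rate))
    t = np.arange(n_samples) / spec.sample_rate
    envelope = spec.a_gamma * (
        (1.0 - spec.chi) + spec.chi * (1.0 + np.cos(2 * np.pi * spec.f_theta * t)) / 2.0
    )
    carrier = envelope * np.sin(2 * np.pi * spec.f_gamma * t) + np.sin(
        2 * np.pi * spec.f_theta * t
    )
    noise = rng.standard_normal((spec.n_epochs, spec.n_channels, n_samples)) / spec.snr
    data = carrier[None, None, :] + noise
    trial_result = rng.choice(4, size=spec.n_epochs, p=spec.trial_proportions)
    return EpochedEEG(
        data=data,
        sample_rate=spec.sample_rate,
        channel_labels=spec.channel_labels,
        trial_result=trial_result,
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def spec_to_dict(spec) -> dict:
    """Serializable view of a spec dataclass (for run logs)."""
    return asdict(spec)
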