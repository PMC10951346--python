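"""Theta-gamma coupling: the entropy-based modulation index and its
aggregation into one participant-level TGC value.

The modulation index (MI) quantifies how non-uniformly gamma-band amplitude
is distributed over theta-band phase. Phases are binned into ``n_phase_bins``
equal bins on (-pi, pi]; the mean gamma amplitude per bin is normalised to a
distribution P; and ``MI = (log N - H(P)) / log N`` with H the Shannon
entropy. MI is 0 when amplitude is flat across phase and approaches 1 when
all amplitude mass concentrates in one bin.

A participant's TGC value is built in three steps: MI per electrode and
N-back trial-result type (pooling the phase/amplitude series of that type's
epochs), the arithmetic mean over the nine frontal electrodes, and a
trial-result-weighted combination of the four frontal-average MI values
using the proportion of task epochs of each type. Two weightings are
implemented: ``literal`` (the default) averages the four products p_i * MI_i
(i.e. divides their sum by 4); ``normalized`` sums them, which is the convex
combination. The choice rescales every participant identically, so the
optimal cutoff's group assignment is unaffected, but the cutoff itself is
scale-dependent; the mode is stamped into all outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .eeg import EpochedEEG, FRONTAL_ELECTRODES, TRIAL_RESULT_CODES

_EPS = 1e-12  # epsilon mass substituted for empty phase bins

WEIGHTING_MODES = ("literal", "normalized")


@dataclass
class TGCBandConfig:
    """Band and filter settings for phase-amplitude extraction.

    Band edges are design defaults (theta 4-8 Hz, gamma 30-50 Hz), not
    universal constants; both are configurable. ``n_phase_bins`` defaults to
    the conventional 18 (20-degree bins). Filtering is zero-phase
    (forward-backward Butterworth of order ``filter_order`` each way) and
    ``transient_tau_factor`` time constants of the theta filter are trimmed
    from each end of every extracted series.
    """

    theta_band: tuple[float, float] = (4.0, 8.0)
    gamma_band: tuple[float, float] = (30.0, 50.0)
    n_phase_bins: int = 18
    filter_order: int = 4
    transient_tau_factor: float = 3.0

    def __post_init__(self) -> None:
        tl, th = self.theta_band
        gl, gh = self.gamma_band
        if not 0 < tl < th:
            raise ValueError(f"invalid theta band {self.theta_band}")
        if not tl < th <= gl < gh:
            raise ValueError("gamma band must lie strictly above the theta band")
        if self.n_phase_bins < 4:
            raise ValueError(f"n_phase_bins must be >= 4, got {self.n_phase_bins}")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    def trim_samples(self, sample_rate: float) -> int:
        # filter time constant ~ 1 / (2 pi * bandwidth) of the theta filter
        bw = self.theta_band[1] - self.theta_band[0]
        tau = 1.0 / (2.0 * np.pi * bw)
        return int(np.ceil(self.transient_tau_factor * tau * sample_rate))

    def min_samples(self, sample_rate: float) -> int:
        # 3 cycles of the theta low edge must survive the two-sided trim
        return int(np.ceil(3.0 * sample_rate / self.theta_band[0])) + 2 * self.trim_samples(
            sample_rate
        )


@dataclass
class TGCResult:
    """Participant-level TGC: per-trial-type frontal MI and the weighted MI."""

    mi_by_trial_type: dict[str, float]
    epoch_proportions: dict[str, float]
    weighted_mi: float
    weighting: str
    n_epochs: int = 0
    band_config: TGCBandConfig = field(default_factory=TGCBandConfig)


def modulation_index(
    phase_series: np.ndarray, amplitude_series: np.ndarray, n_phase_bins: int = 18
) -> float:
    """Entropy-based modulation index of an amplitude series over a phase series.

    Parameters
    ----------
    phase_series : array of radians in (-pi, pi]
    amplitude_series : non-negative amplitudes, same length
    n_phase_bins : number of equal phase bins (>= 4)

    Returns
    -------
    MI in [0, 1]; 0 for amplitude flat over phase, -> 1 as all amplitude
    mass concentrates in a single bin. Invariant to positive rescaling of
    the amplitude series.
    """
    phase = np.asarray(phase_series, dtype=float)
    amp = np.asarray(amplitude_series, dtype=float)
    if phase.shape != amp.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-D arrays")
    if n_phase_bins < 4:
        raise ValueError(f"n_phase_bins must be >= 4, got {n_phase_bins}")
    if np.any(amp < 0):
        raise ValueError("amplitudes must be >= 0")
    if not np.any(amp > 0):
        raise ValueError("amplitude series is all zero; MI undefined")

    edges = np.linspace(-np.pi, np.pi, n_phase_bins + 1)
    # (-pi, pi]: right-closed bins
    idx = np.clip(np.searchsorted(edges, phase, side="left") - 1, 0, n_phase_bins - 1)
    sums = np.bincount(idx, weights=amp, minlength=n_phase_bins)
    counts = np.bincount(idx, minlength=n_phase_bins)
    mean_amp = np.full(n_phase_bins, _EPS)
    filled = counts > 0
    if not filled.all():
        warnings.warn(
            f"{int((~filled).sum())} of {n_phase_bins} phase bins empty; "
            "substituting epsilon mass",
            RuntimeWarning,
            stacklevel=2,
        )
    mean_amp[filled] = sums[filled] / counts[filled]
    mean_amp = np.maximum(mean_amp, _EPS)
    p = mean_amp / mean_amp.sum()
    entropy = -np.sum(p * np.log(p))
    return float((np.log(n_phase_bins) - entropy) / np.log(n_phase_bins))


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {nyq} Hz")
    b, a = butter(order, [band[0] / nyq, band[1] / nyq], btype="bandpass")
    return filtfilt(b, a, x)


def extract_phase_amplitude(
    epoch: np.ndarray, sample_rate: float, band_cfg: TGCBandConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Theta-band phase and gamma-band amplitude envelope of one epoch.

    Zero-phase band-pass filters (Butterworth, forward-backward) followed by
    the analytic signal; the filter-transient region (``trim_samples`` per
    side) is removed identically from both series.

    Returns (phase in (-pi, pi], amplitude >= 0), each of length
    ``len(epoch) - 2 * trim``.
    """
    cfg = band_cfg or TGCBandConfig()
    x = np.asarray(epoch, dtype=float).squeeze()
    if x.ndim != 1:
        raise ValueError("epoch must be a 1-D sample array")
    min_n = cfg.min_samples(sample_rate)
    if x.size < min_n:
        raise ValueError(
            f"epoch of {x.size} samples is too short: minimum {min_n} samples "
            f"(3 cycles of the {cfg.theta_band[0]} Hz theta low edge plus "
            f"2 x {cfg.trim_samples(sample_rate)} transient samples) at "
            f"{sample_rate} Hz"
        )
    theta = _bandpass(x, cfg.theta_band, sample_rate, cfg.filter_order)
    gamma = _bandpass(x, cfg.gamma_band, sample_rate, cfg.filter_order)
    phase = np.angle(hilbert(theta))
    amplitude = np.abs(hilbert(gamma))
    trim = cfg.trim_samples(sample_rate)
    if trim:
        phase = phase[trim:-trim]
        amplitude = amplitude[trim:-trim]
    return phase, amplitude


def frontal_average(mi_per_electrode: dict[str, float]) -> float:
    """Arithmetic mean of MI over the nine frontal electrodes.

    Requires F7, F8, F5, F6, F3, F4, F1, F2 and Fz; raises listing any
    missing label.
    """
    missing = [c for c in FRONTAL_ELECTRODES if c not in mi_per_electrode]
    if missing:
        raise ValueError(f"missing frontal electrodes: {missing}")
    return float(np.mean([mi_per_electrode[c] for c in FRONTAL_ELECTRODES]))


def weighted_mi(
    mi_by_trial_type: np.ndarray,
    epoch_proportions: np.ndarray,
    weighting: str = "literal",
) -> float:
    """Trial-result-weighted MI.

    ``literal`` mode returns mean_i(p_i * MI_i) = (1/4) sum_i p_i MI_i;
    ``normalized`` mode returns sum_i p_i MI_i (a convex combination of the
    four MI values).
    """
    mi = np.asarray(mi_by_trial_type, dtype=float)
    p = np.asarray(epoch_proportions, dtype=float)
    if mi.shape != (4,) or p.shape != (4,):
        raise ValueError("need exactly four MI values and four proportions")
    if np.any(mi < 0):
        raise ValueError("MI values must be >= 0")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must be >= 0 and sum to 1, got sum {p.sum()}")
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}")
    total = float(np.dot(p, mi))
    return total / 4.0 if weighting == "literal" else total


def compute_participant_tgc(
    eeg: EpochedEEG,
    band_cfg: TGCBandConfig | None = None,
    weighting: str = "literal",
    electrodes: tuple[str, ...] = FRONTAL_ELECTRODES,
) -> TGCResult:
    """Full per-participant TGC: MI per electrode x trial type, frontal
    average, and the trial-proportion-weighted MI.

    Phase/amplitude are extracted per epoch (so filter transients never span
    epoch boundaries) and pooled within each trial-result type before MI is
    computed. Trial types with no epochs contribute MI 0 with weight 0.
    """
    cfg = band_cfg or TGCBandConfig()
    missing = [c for c in electrodes if c not in eeg.channel_labels]
    if missing:
        raise ValueError(f"missing frontal electrodes: {missing}")
    ch_idx = {c: eeg.channel_labels.index(c) for c in electrodes}

    mi_by_type: dict[str, float] = {}
    proportions: dict[str, float] = {}
    mi_vec = np.zeros(4)
    p_vec = np.zeros(4)
    for code, name in TRIAL_RESULT_CODES.items():
        epochs = np.flatnonzero(eeg.trial_result == code)
        p_vec[code] = len(epochs) / eeg.n_epochs
        proportions[name] = float(p_vec[code])
        if len(epochs) == 0:
            mi_by_type[name] = 0.0
            continue
        per_electrode: dict[str, float] = {}
        for c, i in ch_idx.items():
            phases, amps = [], []
            for e in epochs:
                ph, am = extract_phase_amplitude(eeg.data[e, i], eeg.sample_rate, cfg)
                phases.append(ph)
                amps.append(am)
            per_electrode[c] = modulation_index(
                np.concatenate(phases), np.concatenate(amps), cfg.n_phase_bins
            )
        mi_by_type[name] = (
            frontal_average(per_electrode)
            if tuple(electrodes) == FRONTAL_ELECTRODES
            else float(np.mean(list(per_electrode.values())))
        )
        mi_vec[code] = mi_by_type[name]

    return TGCResult(
        mi_by_trial_type=mi_by_type,
        epoch_proportions=proportions,
        weighted_mi=weighted_mi(mi_vec, p_vec, weighting),
        weighting=weighting,
        n_epochs=eeg.n_epochs,
        band_config=cfg,
    )
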