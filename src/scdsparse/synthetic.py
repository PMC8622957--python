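"""Synthetic data generators.

Two families of fixtures drive verification:

* :func:`make_planted_sparse_set` — signals built from a known random
  dictionary with exactly ``s`` nonzero coefficients each, the ground truth
  for sparse-coding and dictionary-recovery experiments.
* :func:`make_ecg_recording` — an ECG-like single-lead trace built from a
  five-Gaussian PQRST beat model with beat-to-beat R-R jitter, optional
  class-dependent morphology shifts that strengthen toward a synthetic event
  onset, and additive white Gaussian noise.  The generator returns the exact
  R-peak sample indices it planted, so detector and pipeline accuracy can be
  scored against ground truth.

The morphology shift emulates the rhythm/repolarization drift reported ahead
of ventricular-fibrillation events: T-wave amplitude gain, an S-T phase
offset, and extra R-R jitter.  It is a caricature for algorithm testing, not
a physiological VF model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError
from .preprocess import ECGRecording
from .sparse_core import Dictionary, init_dictionary

__all__ = [
    "PlantedSparseSet",
    "GaussianBump",
    "MorphologyShift",
    "SyntheticECGSpec",
    "ECGGroundTruth",
    "DEFAULT_MORPHOLOGY",
    "STRONG_SHIFT",
    "make_planted_sparse_set",
    "make_ecg_recording",
]


@dataclass
class PlantedSparseSet:
    """Signals with known sparse codes over a known dictionary."""

    dictionary: Dictionary
    signals: np.ndarray       # n x M
    codes: np.ndarray         # m x M, exactly s nonzeros per column
    sparsity: int
    noise_sigma: float
    seed: int

    @property
    def supports(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.codes[:, t]) for t in range(self.codes.shape[1])]


def make_planted_sparse_set(
    n: int,
    m: int,
    M: int,
    s: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PlantedSparseSet:
    """Draw a random unit-norm dictionary and M signals, each an s-sparse
    combination of its atoms.

    Supports are uniform without replacement; coefficients are uniform on
    ``+-[0.1, 1]`` (magnitudes bounded away from zero so every planted atom
    contributes detectable energy).  Gaussian noise of ``noise_sigma`` is
    added per sample.  Fully reproducible from ``seed``.
    """
    if not (1 <= s <= n <= m):
        raise InvalidArgumentError(f"need 1 <= s <= n <= m, got s={s}, n={n}, m={m}")
    if M < 1:
        raise InvalidArgumentError(f"M must be >= 1, got {M}")
    D = init_dictionary(n, m, seed)
    rng = np.random.default_rng(seed + 1)
    codes = np.zeros((m, M))
    for t in range(M):
        idx = rng.choice(m, size=s, replace=False)
        mags = rng.uniform(0.1, 1.0, size=s)
        signs = rng.choice([-1.0, 1.0], size=s)
        codes[idx, t] = signs * mags
    signals = D.atoms @ codes
    if noise_sigma > 0:
        signals = signals + rng.normal(0.0, noise_sigma, size=signals.shape)
    return PlantedSparseSet(
        dictionary=D,
        signals=signals,
        codes=codes,
        sparsity=s,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass(frozen=True)
class GaussianBump:
    """One PQRST wave component: amplitude in mV, center as a fraction of
    the beat phase in [0, 1), width as a fraction of the R-R interval."""

    amplitude_mv: float
    center_phase: float
    width_phase: float


# P, Q, R, S, T — centers strictly increasing, R strictly largest |amplitude|
DEFAULT_MORPHOLOGY: tuple[GaussianBump, ...] = (
    GaussianBump(0.12, 0.15, 0.045),   # P
    GaussianBump(-0.08, 0.26, 0.015),  # Q
    GaussianBump(1.00, 0.30, 0.018),   # R
    GaussianBump(-0.20, 0.34, 0.018),  # S
    GaussianBump(0.35, 0.55, 0.075),   # T
)


@dataclass(frozen=True)
class MorphologyShift:
    """Class-dependent deformation applied at strength g in [0, 1]:
    T amplitude scaled by (1 + g*t_amp_gain), S and T centers delayed by
    g*st_phase_offset beat-phase units, R-R jitter increased by
    g*jitter_add_pct percentage points."""

    t_amp_gain: float = 0.0
    st_phase_offset: float = 0.0
    jitter_add_pct: float = 0.0


# A deformation large enough to be clearly learnable at low noise while the
# waveform still reads as an ECG: +50% T amplitude, 0.05-phase S-T delay,
# +3 percentage points of R-R jitter.
STRONG_SHIFT = MorphologyShift(t_amp_gain=0.5, st_phase_offset=0.05, jitter_add_pct=3.0)


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Recipe for one synthetic recording.

    For ``group="scd"`` the shift strength ramps linearly from 0 at the
    start of the recording to ``shift_strength`` at the synthetic onset
    (placed at ``onset_at_s``, default the end of the recording).  For
    ``group="normal"`` the strength is constant at ``shift_strength``
    (default 0), which also lets a single shifted class be generated
    directly.
    """

    fs: float = 128.0
    duration_s: float = 60.0
    heart_rate_bpm: float = 70.0
    rr_jitter_pct: float = 2.0
    morphology: tuple[GaussianBump, ...] = DEFAULT_MORPHOLOGY
    shift: MorphologyShift = MorphologyShift()
    shift_strength: float = 0.0
    noise_sigma: float = 0.01
    class_label: str = "NSR"
    group: str = "normal"
    subject_id: str = ""
    onset_at_s: float | None = None
    first_beat_offset_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        centers = [b.center_phase for b in self.morphology]
        if sorted(centers) != centers or len(set(centers)) != len(centers):
            raise InvalidArgumentError("bump centers must be strictly increasing")
        if not all(0.0 <= c < 1.0 for c in centers):
            raise InvalidArgumentError("bump centers must lie in [0, 1)")
        amps = np.abs([b.amplitude_mv for b in self.morphology])
        if np.argmax(amps) != 2 or amps[2] <= np.max(np.delete(amps, 2)):
            raise InvalidArgumentError("the R bump must have the strictly largest |amplitude|")
        if self.heart_rate_bpm / 60.0 * self.duration_s < 2:
            raise InvalidArgumentError("duration must cover at least 2 beats at the given rate")
        if self.group not in ("normal", "scd"):
            raise InvalidArgumentError(f"group must be 'normal' or 'scd', got {self.group!r}")


@dataclass
class ECGGroundTruth:
    """What the generator planted: exact R-peak sample indices, per-beat
    class labels, and the onset index (None for controls)."""

    r_peaks: np.ndarray
    beat_labels: list[str]
    onset_index: int | None
    rr_seconds: np.ndarray
    seed: int


def _beat_label(spec: SyntheticECGSpec, t_r: float, onset_s: float | None) -> str:
    if spec.group == "normal":
        return spec.class_label
    lead = onset_s - t_r
    for minutes in (5, 10, 15, 20, 25, 30):
        lo = minutes * 60.0
        if lo - 60.0 < lead <= lo:
            return f"{minutes}min"
    return spec.class_label


def make_ecg_recording(spec: SyntheticECGSpec) -> tuple[ECGRecording, ECGGroundTruth]:
    """Synthesize one recording from the five-Gaussian beat model.

    Beats are laid down sequentially: beat k spans ``[s_k, s_k + rr_k)``
    seconds with its five bumps at fixed beat-phase fractions, so the R peak
    lands at ``s_k + c_R * rr_k``.  R-R intervals are drawn per beat from a
    Gaussian jitter model around ``60/heart_rate_bpm``.  Returns the
    recording and the planted ground truth.
    """
    fs = spec.fs
    n_samples = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    base_rr = 60.0 / spec.heart_rate_bpm

    onset_s: float | None = None
    onset_index: int | None = None
    if spec.group == "scd":
        onset_s = spec.duration_s if spec.onset_at_s is None else spec.onset_at_s
        onset_index = min(int(round(onset_s * fs)), n_samples - 1)

    x = np.zeros(n_samples)
    t_grid = np.arange(n_samples) / fs
    r_center = spec.morphology[2].center_phase

    r_peaks: list[int] = []
    labels: list[str] = []
    rrs: list[float] = []

    t = spec.first_beat_offset_s
    while t < spec.duration_s:
        if spec.group == "scd":
            g = spec.shift_strength * min(max(t / onset_s, 0.0), 1.0)
        else:
            g = spec.shift_strength

        jitter = spec.rr_jitter_pct + g * spec.shift.jitter_add_pct
        rr = base_rr * (1.0 + jitter / 100.0 * rng.standard_normal())
        rr = float(np.clip(rr, 0.3, 2.0))

        for k, bump in enumerate(spec.morphology):
            amp = bump.amplitude_mv
            center = bump.center_phase
            if k == 4:  # T
                amp *= 1.0 + g * spec.shift.t_amp_gain
                center += g * spec.shift.st_phase_offset
            elif k == 3:  # S
                center += g * spec.shift.st_phase_offset
            mu = t + center * rr
            sigma = bump.width_phase * rr
            lo = max(0, int(np.floor((mu - 5 * sigma) * fs)))
            hi = min(n_samples, int(np.ceil((mu + 5 * sigma) * fs)) + 1)
            if lo < hi:
                tt = t_grid[lo:hi]
                x[lo:hi] += amp * np.exp(-0.5 * ((tt - mu) / sigma) ** 2)

        t_r = t + r_center * rr
        idx = int(round(t_r * fs))
        if idx < n_samples:
            r_peaks.append(idx)
            labels.append(_beat_label(spec, t_r, onset_s))
            rrs.append(rr)
        t += rr

    if spec.noise_sigma > 0:
        x = x + rng.normal(0.0, spec.noise_sigma, size=n_samples)

    rec = ECGRecording(
        samples=x,
        fs=fs,
        subject_id=spec.subject_id,
        group=spec.group,
        onset_index=onset_index,
    )
    truth = ECGGroundTruth(
        r_peaks=np.asarray(r_peaks, dtype=int),
        beat_labels=labels,
        onset_index=onset_index,
        rr_seconds=np.asarray(rrs),
        seed=spec.seed,
    )
    return rec, truth


def shifted_spec(spec: SyntheticECGSpec, **changes) -> SyntheticECGSpec:
    """Convenience wrapper over dataclasses.replace for frozen specs."""
    return replace(spec, **changes)
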