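"""Synthetic labeled lower-leg acceleration signals.

Generates triaxial calf-accelerometer recordings of steady treadmill walking
with per-sample gait-phase labels, emulating the statistical structure of
200 Hz Kalman-filtered IMU output: periodic cycles split into the four
ordered phases heel strike (HS), flat foot (FF), heel off (HO) and swing
(SW), stance occupying ~60% of the cycle and swing ~40%, amplitudes inside
the empirically observed -1 g .. 2 g envelope, speed-dependent cadence,
per-subject variation and smooth additive noise.

Phase codes follow the evaluation convention: 0=HS, 1=FF, 2=HO, 3=SW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "PHASE_NAMES",
    "N_PHASES",
    "DEFAULT_PHASE_FRACTIONS",
    "GaitProfile",
    "AccelRecording",
    "make_phase_schedule",
    "synthesize_recording",
    "simulate_cohort",
    "write_recording",
    "read_recording",
    "RecordingParseError",
]

PHASE_NAMES = ("HS", "FF", "HO", "SW")
N_PHASES = 4

#: Default split of one gait cycle: short initial-contact HS, long FF plateau,
#: push-off HO, then swing.  HS+FF+HO = 0.6 (stance), SW = 0.4 (swing).
DEFAULT_PHASE_FRACTIONS = (0.08, 0.32, 0.20, 0.40)

#: Cycles per second per (m/s) of walking speed.
CADENCE_PER_SPEED = 0.9

#: Study treadmill speeds, m/s.
STUDY_SPEEDS = (0.78, 1.0, 1.25)

_G_LO, _G_HI = -1.0, 2.0


class RecordingParseError(ValueError):
    """Raised when a recording CSV violates the expected schema."""


@dataclass(frozen=True)
class GaitProfile:
    """Kinematic description of one subject walking at one speed.

    Parameters
    ----------
    speed:
        Treadmill speed in m/s.  Any positive value is accepted; the study
        set is ``{0.78, 1.0, 1.25}``.
    cadence:
        Gait cycles per second.  ``None`` derives it as ``0.9 * speed``.
    phase_fractions:
        Fractions of one cycle spent in (HS, FF, HO, SW); must be positive
        and sum to 1.  Defaults put stance (HS+FF+HO) at 0.6 and swing at 0.4.
    amp_scale:
        Per-axis amplitude multipliers (x, y, z), unitless.
    noise_sd:
        Stationary standard deviation of the additive AR(1) noise, in g.
    seed:
        RNG seed controlling noise; same seed => bit-identical recording.
    """

    speed: float = 1.0
    cadence: float | None = None
    phase_fractions: tuple[float, float, float, float] = DEFAULT_PHASE_FRACTIONS
    amp_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError(f"speed must be positive, got {self.speed}")
        if self.effective_cadence <= 0:
            raise ValueError("cadence must be positive")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.shape != (4,) or np.any(fr <= 0):
            raise ValueError("phase_fractions must be 4 positive numbers")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"phase_fractions must sum to 1, got {fr.sum()!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def effective_cadence(self) -> float:
        """Cycles per second, derived from speed when not set explicitly."""
        if self.cadence is not None:
            return float(self.cadence)
        return CADENCE_PER_SPEED * self.speed


@dataclass
class AccelRecording:
    """Triaxial acceleration time series with per-sample phase labels.

    ``ax``, ``ay``, ``az`` are in g; ``labels`` holds phase codes
    0=HS, 1=FF, 2=HO, 3=SW.  All four arrays share length ``T``.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    labels: np.ndarray
    subject_id: str = "s0"
    speed: float = 1.0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.ax)
        if not (len(self.ay) == len(self.az) == len(self.labels) == n):
            raise ValueError("ax, ay, az and labels must have equal length")
        for arr in (self.ax, self.ay, self.az):
            if not np.all(np.isfinite(arr)):
                raise ValueError("acceleration samples must be finite")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 3):
            raise ValueError("labels must be in {0, 1, 2, 3}")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def signal(self) -> np.ndarray:
        """(T, 3) array with columns ax, ay, az."""
        return np.stack([self.ax, self.ay, self.az], axis=1)


def _cycle_pattern(profile: GaitProfile, fs: float) -> np.ndarray:
    """Per-sample phase codes for one gait cycle.

    Cycle length is ``round(fs / cadence)`` samples; each of HS, FF, HO gets
    ``round(fraction * cycle_len)`` samples and SW takes the remainder so the
    cycle length is exact (with the defaults the remainder equals the rounded
    SW duration).
    """
    cadence = profile.effective_cadence
    if fs <= 0 or cadence <= 0:
        raise ValueError("sampling rate and cadence must be positive")
    cycle_len = int(round(fs / cadence))
    if cycle_len < 4:
        raise ValueError(
            f"cycle of {cycle_len} samples cannot hold 4 phases "
            f"(fs={fs}, cadence={cadence})"
        )
    durations = [int(round(f * cycle_len)) for f in profile.phase_fractions[:3]]
    durations.append(cycle_len - sum(durations))
    if min(durations) < 1:
        raise ValueError(
            f"phase durations {durations} must all be >= 1 sample; "
            "increase cycle length or rebalance phase_fractions"
        )
    return np.repeat(np.arange(N_PHASES), durations)


def make_phase_schedule(
    profile: GaitProfile, n_samples: int, fs: float = 200.0
) -> np.ndarray:
    """Per-sample phase labels obeying the cyclic order HS->FF->HO->SW.

    Returns ``n_samples`` int codes.  Within each cycle the four phases
    appear once, in order, with durations proportional to
    ``profile.phase_fractions``.
    """
    return _schedule_with_progress(profile, n_samples, fs)[0]


def _schedule_with_progress(
    profile: GaitProfile, n_samples: int, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus within-phase progress tau in [0, 1).

    tau is defined against the nominal phase duration, so a recording
    truncated mid-phase keeps the same waveform as a full cycle.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    pattern = _cycle_pattern(profile, fs)
    durations = np.bincount(pattern, minlength=N_PHASES)
    tau_pattern = np.concatenate(
        [np.arange(d) / d for d in durations]
    )
    reps = math.ceil(n_samples / len(pattern))
    return (
        np.tile(pattern, reps)[:n_samples],
        np.tile(tau_pattern, reps)[:n_samples],
    )


# Per-(phase, axis) waveform templates over within-phase progress tau in [0, 1):
# (bump amplitude, bump center, bump width, sine amplitude, sine phase, offset).
# Values in g, chosen to mimic lower-leg accelerometry: a sharp impact
# transient at heel strike, a quiet flat-foot plateau near rest, a push-off
# ramp at heel-off, and a smooth pendular swing oscillation; distinct across
# phases and axes so each phase has a recognisable signature.
_TEMPLATES: dict[int, tuple[tuple[float, float, float, float, float, float], ...]] = {
    0: (  # HS: impact spike, strongest on the longitudinal axis
        (1.6, 0.35, 0.18, 0.10, 0.0, 0.15),
        (-0.9, 0.40, 0.20, 0.05, 1.0, -0.05),
        (0.7, 0.30, 0.15, 0.10, 2.0, 0.05),
    ),
    1: (  # FF: foot flat, near-static with small residual sway
        (0.15, 0.50, 0.30, 0.06, 0.5, -0.10),
        (0.10, 0.45, 0.25, 0.05, 1.5, 0.05),
        (-0.20, 0.55, 0.30, 0.04, 0.0, 0.00),
    ),
    2: (  # HO: push-off ramp building toward toe-off
        (0.9, 0.75, 0.25, 0.15, 0.0, 0.05),
        (0.6, 0.70, 0.22, 0.10, 2.5, -0.10),
        (-0.7, 0.80, 0.25, 0.08, 1.0, 0.05),
    ),
    3: (  # SW: smooth pendular oscillation of the airborne shank
        (-0.6, 0.25, 0.30, 0.45, 0.0, 0.10),
        (0.5, 0.60, 0.35, 0.30, 1.2, 0.00),
        (0.4, 0.50, 0.40, 0.35, 2.2, -0.05),
    ),
}

#: AR(1) coefficient of the additive noise; high value mimics the smoothness
#: of the sensor's in-built Kalman filtering.
AR_COEF = 0.9


def _template_value(phase: int, axis: int, tau: np.ndarray) -> np.ndarray:
    amp, c, w, s_amp, s_ph, off = _TEMPLATES[phase][axis]
    return (
        amp * np.exp(-0.5 * ((tau - c) / w) ** 2)
        + s_amp * np.sin(2 * np.pi * tau + s_ph)
        + off
    )


def synthesize_recording(
    profile: GaitProfile,
    duration_s: float,
    subject_id: str = "s0",
    fs: float = 200.0,
) -> AccelRecording:
    """Simulate one steady-walking recording.

    Each axis is the sum of phase-specific smooth templates (a Gaussian bump
    plus a single sinusoid per phase/axis) evaluated on within-phase progress,
    plus AR(1) noise, clipped to the observed [-1, 2] g envelope.
    Deterministic for a fixed ``profile.seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    labels, tau = _schedule_with_progress(profile, n, fs)

    rng = np.random.default_rng(profile.seed)
    sig = np.empty((n, 3))
    for axis in range(3):
        clean = np.empty(n)
        for phase in range(N_PHASES):
            mask = labels == phase
            clean[mask] = _template_value(phase, axis, tau[mask])
        clean *= profile.amp_scale[axis]
        if profile.noise_sd > 0:
            innov_sd = profile.noise_sd * math.sqrt(1.0 - AR_COEF**2)
            e = rng.normal(0.0, innov_sd, size=n)
            x0 = rng.normal(0.0, profile.noise_sd)  # stationary start
            noise = lfilter([1.0], [1.0, -AR_COEF], e, zi=[AR_COEF * x0])[0]
            clean = clean + noise
        sig[:, axis] = np.clip(clean, _G_LO, _G_HI)

    return AccelRecording(
        fs=fs,
        ax=sig[:, 0],
        ay=sig[:, 1],
        az=sig[:, 2],
        labels=labels,
        subject_id=subject_id,
        speed=profile.speed,
    )


def simulate_cohort(
    speed: float,
    n_subjects: int,
    duration_s: float,
    seed: int = 0,
    n_repeats: int = 1,
    fs: float = 200.0,
    base_profile: GaitProfile | None = None,
) -> list[AccelRecording]:
    """Simulate a cohort of subjects walking at one treadmill speed.

    Subject heterogeneity: per-axis amplitude multipliers ~ U(0.8, 1.2) and
    cadence jitter of +/-5%, both drawn once per subject from a seed-derived
    stream.  Repeats of one subject share the subject's morphology but use
    independent noise, and are returned as separate recordings (never to be
    windowed across boundaries).
    """
    if n_subjects < 1 or n_repeats < 1:
        raise ValueError("need at least one subject and one repeat")
    base = base_profile if base_profile is not None else GaitProfile(speed=speed)
    master = np.random.SeedSequence(seed)
    subject_seqs = master.spawn(n_subjects)
    recordings: list[AccelRecording] = []
    for s, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        amps = tuple(rng.uniform(0.8, 1.2, size=3))
        jitter = rng.uniform(0.95, 1.05)
        cadence = base.effective_cadence * jitter
        for r in range(n_repeats):
            noise_seed = int(rng.integers(0, 2**31 - 1))
            prof = replace(
                base,
                speed=speed,
                cadence=cadence,
                amp_scale=amps,
                seed=noise_seed,
            )
            recordings.append(
                synthesize_recording(
                    prof, duration_s, subject_id=f"s{s:02d}r{r}", fs=fs
                )
            )
    return recordings


# ---------------------------------------------------------------------------
# CSV persistence: header t,ax,ay,az,phase; t in seconds; 9 decimal places so
# a write/read round trip preserves accelerations to 1e-9.

def write_recording(rec: AccelRecording, path) -> None:
    """Write a recording as CSV with columns ``t, ax, ay, az, phase``."""
    t = np.arange(len(rec)) / rec.fs
    df = pd.DataFrame(
        {"t": t, "ax": rec.ax, "ay": rec.ay, "az": rec.az, "phase": rec.labels}
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_recording(path, subject_id: str = "s0", speed: float = 1.0) -> AccelRecording:
    """Read a recording CSV written by :func:`write_recording`.

    Raises :class:`RecordingParseError` naming the offending line for a
    missing column, a non-numeric cell or a phase code outside {0, 1, 2, 3}.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise RecordingParseError(f"{path}: malformed CSV: {exc}") from exc
    required = ["t", "ax", "ay", "az", "phase"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingParseError(
            f"{path}: line 1: missing required column(s) {missing}"
        )
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(numeric.isna().to_numpy() & df[col].notna().to_numpy())
        nan_bad = np.flatnonzero(df[col].isna().to_numpy())
        bad = np.concatenate([bad, nan_bad])
        if bad.size:
            line = int(bad.min()) + 2  # +1 header, +1 one-based
            raise RecordingParseError(
                f"{path}: line {line}: non-numeric value in column '{col}'"
            )
        df[col] = numeric
    phase = df["phase"].to_numpy()
    bad = np.flatnonzero((phase != np.floor(phase)) | (phase < 0) | (phase > 3))
    if bad.size:
        line = int(bad[0]) + 2
        raise RecordingParseError(
            f"{path}: line {line}: unknown phase code {phase[bad[0]]!r} "
            "(legal codes: 0, 1, 2, 3)"
        )
    if len(df) >= 2:
        fs = 1.0 / np.median(np.diff(df["t"].to_numpy()))
    else:
        fs = 200.0
    return AccelRecording(
        fs=float(np.round(fs, 6)),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        labels=phase.astype(np.int64),
        subject_id=subject_id,
        speed=speed,
    )
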