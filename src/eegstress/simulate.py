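"""Seeded synthetic frontal-EEG cohort generator.

Emulates the block-design stress-induction study the analysis pipeline
assumes: 22 subjects wearing a 7-electrode frontal montage (Fp1, Fp2, F7,
F3, F4, Fz, F8) at 256 Hz, five blocks of 30 s mental-arithmetic task
followed by 20 s of rest, and a pre/post salivary alpha-amylase assay that
labels each subject.

Signal model
------------
Each channel is a sum over the six canonical bands of

    A[cond, band, ch] * cos(phi_band_ch(t))

with ``phi_band_ch(t) = phi_driver(t) + lag_ch + theta_ch(t)``: a shared
per-band driver advancing at the band's center frequency (plus a small
random-walk frequency wander common to all channels), a fixed per-channel
lag, and a per-channel random-walk phase ``theta_ch`` obtained by
integrating a frequency detuning ``delta_ch(t)`` that is piecewise
constant over one-second segments and drawn i.i.d. per segment with SD
``sigma_f`` Hz.  Within one analysis epoch of T seconds the phase
difference of a pair then drifts linearly at ``d = delta_i - delta_j``
Hz, so the epoch-level phase-locking value is |sinc(d T)|, and its
expectation over ``d ~ N(0, 2 sigma_f^2)`` is inverted numerically to
choose ``sigma_f`` for a per-band PLV target.  Detuning-based coupling
survives narrow-band filtering (the drift stays inside the band), which
fast phase jitter does not; i.i.d. segments keep epochs exchangeable, so
a null configuration carries no temporal structure a classifier could
exploit.  ``generate_coupled_phases`` additionally provides the classic
constant-lag + Gaussian-jitter pair model with
``exp(-sigma**2/2) = target``, exact for phases observed without
band-limiting.  Pink (1/f) background noise, raised-cosine blink bumps on
Fp1/Fp2 and an optional 50 Hz line sinusoid give the preprocessing stages
something to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bands import BAND_NAMES, BandDefinition, CANONICAL_BANDS
from .exceptions import ConfigurationError, DomainError

DEFAULT_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "F4", "Fz", "F8")

STRESS = "stress"
REST = "rest"
WORKING = "working"

#: Assay statistics of salivary alpha-amylase by condition (mean, SD).
AMYLASE_STATS: dict[str, tuple[float, float]] = {
    REST: (24.45, 4.44),
    STRESS: (93.64, 13.99),
}

#: Subject-labelling thresholds on the post-task amylase level.
AMYLASE_STRESS_THRESHOLD = 60.0
AMYLASE_REST_THRESHOLD = 30.0

# Smallest representable coupling; sigma = sqrt(-ln(floor)) stays finite.
_PLV_FLOOR = 1e-8

# AR(1) coefficient of the phase-jitter process.  Unit marginal variance is
# preserved, so PLV calibration is unaffected; the smoothing only keeps the
# instantaneous frequency physically plausible.
_JITTER_AR1 = 0.9

# Random-walk step SD (radians/sample) of the driver-frequency wander.
_DRIVER_WANDER = 0.01


def default_block_schedule(
    n_blocks: int = 5, task_s: float = 30.0, rest_s: float = 20.0
) -> tuple[tuple[str, float], ...]:
    """Five blocks of 30 s task + 20 s rest, the study's block design."""
    sched: list[tuple[str, float]] = []
    for _ in range(n_blocks):
        sched.append((STRESS, task_s))
        sched.append((REST, rest_s))
    return tuple(sched)


def _per_channel(value, n_channels: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_channels, float(arr))
    if arr.shape != (n_channels,):
        raise ConfigurationError(
            f"per-channel value has shape {arr.shape}, expected ({n_channels},)"
        )
    return arr.copy()


def default_band_amplitudes(
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-condition, per-band, per-channel oscillation amplitudes (uV).

    Rest amplitudes follow the usual frontal resting spectrum (alpha- and
    delta-dominant).  Under stress the affected channels move in the
    directions the analysis is meant to recover: alpha relative power drops
    over the prefrontal/right cortex (Fp1, Fp2, F4), high-beta and theta
    rise over Fp1/Fp2/F3/F4, and sigma rises slightly at F7.  Effect sizes
    are chosen to give roughly one pooled-SD separation per affected
    epoch-level feature.
    """
    names = list(channel_names)
    n = len(names)

    def mask(chs: Sequence[str], factor: float) -> np.ndarray:
        arr = np.ones(n)
        for ch in chs:
            if ch in names:
                arr[names.index(ch)] = factor
        return arr

    rest_amp = {
        "delta": 6.0,
        "theta": 4.0,
        "alpha": 8.0,
        "sigma": 2.5,
        "low_beta": 2.0,
        "high_beta": 1.5,
    }
    rest = {b: np.full(n, a) for b, a in rest_amp.items()}
    stress = {
        "delta": rest["delta"].copy(),
        "theta": rest["theta"] * mask(("Fp1", "Fp2", "F3", "F4"), 1.25),
        "alpha": rest["alpha"] * mask(("Fp1", "Fp2", "F4"), 0.70),
        "sigma": rest["sigma"] * mask(("F7",), 1.30),
        "low_beta": rest["low_beta"].copy(),
        "high_beta": rest["high_beta"] * mask(("Fp1", "Fp2", "F3", "F4"), 1.30),
    }
    return {REST: rest, STRESS: stress}


def default_plv_targets() -> dict[str, dict[str, float]]:
    """Per-condition, per-band PLV targets (applied to every channel pair).

    Delta and alpha synchronization drop under stress while high-beta
    synchronization rises; the remaining bands are condition-neutral.
    """
    rest = {
        "delta": 0.55,
        "theta": 0.35,
        "alpha": 0.60,
        "sigma": 0.35,
        "low_beta": 0.35,
        "high_beta": 0.22,
    }
    stress = dict(rest)
    stress["delta"] = 0.28
    stress["alpha"] = 0.28
    stress["high_beta"] = 0.55
    return {REST: rest, STRESS: stress}


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic cohort.

    ``band_amplitudes`` maps condition -> band -> scalar or per-channel
    array of oscillation amplitudes (uV).  ``plv_targets`` maps condition ->
    band -> target phase-locking value in [0, 1], realized uniformly over
    all channel pairs through a shared per-band driver (arbitrary per-pair
    targets are not independently realizable under a single driver).
    """

    n_subjects: int = 22
    fs: float = 256.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    block_schedule: tuple[tuple[str, float], ...] = field(
        default_factory=default_block_schedule
    )
    band_amplitudes: Mapping[str, Mapping[str, object]] | None = None
    plv_targets: Mapping[str, Mapping[str, float]] | None = None
    noise_scale: float = 3.0
    blink_rate_per_min: float = 4.0
    blink_amplitude: float = 50.0
    line_noise_amplitude: float = 2.0
    line_noise_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if not self.block_schedule:
            raise ConfigurationError("block schedule is empty")
        for cond, dur in self.block_schedule:
            if cond not in (STRESS, REST):
                raise ConfigurationError(f"unknown condition {cond!r} in schedule")
            if dur <= 0:
                raise ConfigurationError(f"non-positive block duration {dur}")
        for cond, bands in self.resolved_plv_targets().items():
            for band, target in bands.items():
                if not 0.0 <= target <= 1.0:
                    raise ConfigurationError(
                        f"plv target {cond}/{band}={target} outside [0, 1]"
                    )
        if self.noise_scale < 0 or self.blink_rate_per_min < 0:
            raise ConfigurationError("noise_scale and blink rate must be >= 0")

    # -- resolved views -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.block_schedule))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def resolved_band_amplitudes(self) -> dict[str, dict[str, np.ndarray]]:
        raw = self.band_amplitudes
        if raw is None:
            return default_band_amplitudes(self.channel_names)
        out: dict[str, dict[str, np.ndarray]] = {}
        for cond in (REST, STRESS):
            cond_map = raw.get(cond, {}) if hasattr(raw, "get") else {}
            out[cond] = {
                band: _per_channel(cond_map.get(band, 0.0), self.n_channels)
                for band in BAND_NAMES
            }
        return out

    def resolved_plv_targets(self) -> dict[str, dict[str, float]]:
        raw = self.plv_targets
        if raw is None:
            return default_plv_targets()
        out: dict[str, dict[str, float]] = {}
        for cond in (REST, STRESS):
            cond_map = raw.get(cond, {}) if hasattr(raw, "get") else {}
            out[cond] = {band: float(cond_map.get(band, 0.3)) for band in BAND_NAMES}
        return out

    def condition_windows(self) -> list[tuple[str, float, float]]:
        windows: list[tuple[str, float, float]] = []
        t = 0.0
        for cond, dur in self.block_schedule:
            windows.append((cond, t, t + dur))
            t += dur
        return windows


def null_config(**overrides) -> SynthConfig:
    """A cohort with no condition effect: identical amplitudes and PLV
    targets under task and rest blocks.  Downstream classification on such
    a cohort should sit at chance."""
    amps = default_band_amplitudes(
        overrides.get("channel_names", DEFAULT_CHANNELS)
    )
    amps[STRESS] = {b: a.copy() for b, a in amps[REST].items()}
    plv = default_plv_targets()
    plv[STRESS] = dict(plv[REST])
    overrides.setdefault("band_amplitudes", amps)
    overrides.setdefault("plv_targets", plv)
    return SynthConfig(**overrides)


@dataclass(frozen=True)
class AmylaseSample:
    """One salivary alpha-amylase assay result."""

    level: float
    phase: str  # "baseline" or "post"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise DomainError(f"amylase level must be >= 0, got {self.level}")
        if self.phase not in ("baseline", "post"):
            raise DomainError(f"unknown assay phase {self.phase!r}")


@dataclass
class SubjectRecord:
    """One generated session: signal, schedule, assay pair and label."""

    subject_id: str
    data: np.ndarray  # channels x samples, uV
    fs: float
    channel_names: tuple[str, ...]
    condition_windows: list[tuple[str, float, float]]
    amylase_baseline: AmylaseSample
    amylase_post: AmylaseSample
    label: str
    seed: int

    def __post_init__(self) -> None:
        dur = self.data.shape[1] / self.fs
        last_end = 0.0
        for cond, start, end in self.condition_windows:
            if start < last_end - 1e-9 or end > dur + 1e-6:
                raise ConfigurationError(
                    "condition windows must be non-overlapping and inside the recording"
                )
            last_end = end


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------


def pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    spec[1:] /= np.sqrt(freqs[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1_unit(n: int, rng: np.random.Generator, a: float = _JITTER_AR1) -> np.ndarray:
    """AR(1) series with unit marginal variance (stationary start)."""
    from scipy.signal import lfilter

    x0 = rng.standard_normal()
    if n == 1:
        return np.array([x0])
    eps = rng.standard_normal(n - 1)
    c = np.sqrt(1.0 - a * a)
    # y[t] = a*y[t-1] + c*eps[t], seeded with the stationary draw x0
    rest, _ = lfilter([c], [1.0, -a], eps, zi=np.array([a * x0]))
    return np.concatenate(([x0], rest))


def _sigma_for_plv(target: float) -> float:
    """Per-channel jitter SD realizing a pairwise PLV of ``target``."""
    return float(np.sqrt(-np.log(max(target, _PLV_FLOOR))))


# -- epoch-level PLV calibration of the session generator -------------------
#
# Narrow-band filtering removes any phase jitter faster than the band
# width, so fast Gaussian jitter cannot lower the PLV measured on filtered
# 1 s epochs.  The session generator therefore realizes coupling through
# slow per-channel frequency detuning: within one epoch the pair's phase
# difference drifts almost linearly at d Hz, giving an epoch PLV of
# |sinc(d T)|; with d ~ N(0, s^2) across time the expected epoch PLV is
# E|sinc(d T)|, which is inverted numerically to find s for a target.

_EPOCH_S = 1.0  # nominal analysis epoch the calibration assumes


_HERMEGAUSS = np.polynomial.hermite_e.hermegauss(151)


def _expected_epoch_plv(s: float, epoch_s: float = _EPOCH_S) -> float:
    """E_{d~N(0,s^2)} |sinc(d * epoch_s)| via Gauss-Hermite quadrature."""
    if s <= 0:
        return 1.0
    nodes, weights = _HERMEGAUSS
    d = s * nodes
    return float(np.abs(np.sinc(d * epoch_s)) @ weights / np.sqrt(2 * np.pi))


@lru_cache(maxsize=128)
def _detuning_sd_for_target(target: float, epoch_s: float = _EPOCH_S) -> float:
    """Per-channel detuning SD (Hz) whose pair difference realizes the
    requested expected epoch PLV."""
    from scipy.optimize import brentq

    if target >= 1.0:
        return 0.0
    target = max(target, 0.02)
    hi = 60.0
    if _expected_epoch_plv(hi, epoch_s) > target:
        return hi / np.sqrt(2.0)
    s_pair = brentq(
        lambda s: _expected_epoch_plv(s, epoch_s) - target, 1e-9, hi, xtol=1e-6
    )
    return float(s_pair / np.sqrt(2.0))


def generate_coupled_phases(
    plv_target: float,
    n_samples: int,
    band: BandDefinition,
    seed: int,
    fs: float = 256.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-amplitude oscillations whose phase difference is a constant
    lag plus Gaussian jitter calibrated so the expected PLV equals
    ``plv_target`` (jitter SD ``sigma`` with ``exp(-sigma**2/2) = target``).

    A target of exactly 0 yields two independent uniform-phase signals; a
    target of 1 yields a fixed lag and an empirical PLV of exactly 1.
    """
    if not 0.0 <= plv_target <= 1.0:
        raise DomainError(f"plv_target={plv_target} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 7]))
    t = np.arange(n_samples) / fs
    base = 2 * np.pi * band.center * t
    lag = rng.uniform(-np.pi, np.pi)
    if plv_target == 0.0:
        phi_x = rng.uniform(-np.pi, np.pi, n_samples)
        phi_y = rng.uniform(-np.pi, np.pi, n_samples)
        return np.cos(base + phi_x), np.cos(base + phi_y)
    if plv_target == 1.0:
        return np.cos(base), np.cos(base + lag)
    sigma_diff = np.sqrt(-2.0 * np.log(plv_target))
    jitter = sigma_diff * _ar1_unit(n_samples, rng)
    return np.cos(base), np.cos(base + lag + jitter)


def generate_amylase(condition: str, n: int, seed: int) -> list[AmylaseSample]:
    """Draw ``n`` assay values from the condition's truncated-at-zero
    normal distribution (rest: M 24.45, SD 4.44; stress: M 93.64, SD
    13.99)."""
    if condition not in AMYLASE_STATS:
        raise DomainError(f"unknown condition {condition!r}")
    if n < 1:
        raise DomainError("n must be >= 1")
    from scipy.stats import truncnorm

    mean, sd = AMYLASE_STATS[condition]
    a = (0.0 - mean) / sd
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 11]))
    levels = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    phase = "post" if condition == STRESS else "baseline"
    return [AmylaseSample(float(lv), phase) for lv in levels]


def label_subject(post_level: float) -> str:
    """Label a subject from the post-task amylase level: >60 stress,
    30-60 working, <30 rest."""
    if post_level < 0:
        raise DomainError(f"amylase level must be >= 0, got {post_level}")
    if post_level > AMYLASE_STRESS_THRESHOLD:
        return STRESS
    if post_level >= AMYLASE_REST_THRESHOLD:
        return WORKING
    return REST


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------


def _condition_per_sample(config: SynthConfig) -> np.ndarray:
    """Index array: 0 where the schedule says rest, 1 where stress."""
    idx = np.zeros(config.n_samples, dtype=np.int8)
    for cond, start, end in config.condition_windows():
        if cond == STRESS:
            i0 = int(round(start * config.fs))
            i1 = int(round(end * config.fs))
            idx[i0:i1] = 1
    return idx


def generate_session(config: SynthConfig, subject_seed: int) -> SubjectRecord:
    """Synthesize one subject's full session.

    Deterministic for a fixed (config.seed, subject_seed) pair; the
    recording length equals the scheduled duration times the sampling rate.
    """
    if config.fs <= 0 or not config.block_schedule:
        raise ConfigurationError("invalid SynthConfig")
    n = config.n_samples
    n_ch = config.n_channels
    fs = config.fs
    ss = np.random.SeedSequence([abs(int(config.seed)), abs(int(subject_seed))])
    rngs = [np.random.default_rng(child) for child in ss.spawn(5)]
    rng_phase, rng_noise, rng_blink, rng_amy_base, rng_amy_post = rngs

    cond_idx = _condition_per_sample(config)  # 0 rest, 1 stress
    amps = config.resolved_band_amplitudes()
    plvs = config.resolved_plv_targets()
    t = np.arange(n) / fs

    # detuning is piecewise-constant over 1 s segments and drawn i.i.d.
    # per segment: within an analysis epoch the pair's phase drift is then
    # exactly linear (PLV = |sinc(d T)|) and epochs are exchangeable, so a
    # null configuration carries no temporal structure beyond condition
    seg_len = int(round(_EPOCH_S * fs))
    n_seg = -(-n // seg_len)  # ceil
    seg_cond = cond_idx[::seg_len][:n_seg]
    data = np.zeros((n_ch, n))
    for band in CANONICAL_BANDS:
        # shared driver: center frequency plus slow random-walk wander
        wander = np.cumsum(_DRIVER_WANDER * rng_phase.standard_normal(n))
        phi_driver = 2 * np.pi * band.center * t + wander
        # per-condition detuning SD (Hz), expanded per segment
        sigf_seg = np.array(
            [
                _detuning_sd_for_target(plvs[REST][band.name]),
                _detuning_sd_for_target(plvs[STRESS][band.name]),
            ]
        )[seg_cond]
        amp = np.stack(
            [amps[REST][band.name], amps[STRESS][band.name]]
        )  # (2, n_ch)
        for ch in range(n_ch):
            lag = rng_phase.uniform(-np.pi, np.pi)
            d_seg = sigf_seg * rng_phase.standard_normal(n_seg)
            detune = np.repeat(d_seg, seg_len)[:n]
            theta = np.cumsum(detune) * (2 * np.pi / fs)
            phase = phi_driver + lag + theta
            data[ch] += amp[cond_idx, ch] * np.cos(phase)

    if config.noise_scale > 0:
        for ch in range(n_ch):
            data[ch] += config.noise_scale * pink_noise(n, rng_noise)

    if config.line_noise_amplitude > 0:
        line = config.line_noise_amplitude * np.sin(
            2 * np.pi * config.line_noise_hz * t + rng_noise.uniform(0, 2 * np.pi)
        )
        data += line  # common-mode mains pickup

    _add_blinks(data, config, rng_blink)

    baseline = generate_amylase(REST, 1, int(rng_amy_base.integers(2**31)))[0]
    baseline = AmylaseSample(baseline.level, "baseline")
    post = generate_amylase(STRESS, 1, int(rng_amy_post.integers(2**31)))[0]
    post = AmylaseSample(post.level, "post")

    return SubjectRecord(
        subject_id=f"S{subject_seed:02d}",
        data=data,
        fs=fs,
        channel_names=tuple(config.channel_names),
        condition_windows=config.condition_windows(),
        amylase_baseline=baseline,
        amylase_post=post,
        label=label_subject(post.level),
        seed=int(subject_seed),
    )


def _add_blinks(
    data: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> None:
    """Raised-cosine 0.5 s blink bumps on Fp1/Fp2 (in place)."""
    if config.blink_rate_per_min <= 0 or config.blink_amplitude <= 0:
        return
    frontal = [
        i for i, name in enumerate(config.channel_names) if name in ("Fp1", "Fp2")
    ]
    if not frontal:
        return
    n = data.shape[1]
    fs = config.fs
    width = int(round(0.5 * fs))
    bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    n_events = rng.poisson(config.blink_rate_per_min * (n / fs) / 60.0)
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n - width)))
        scale = config.blink_amplitude * rng.uniform(0.85, 1.15)
        for ch in frontal:
            data[ch, start : start + width] += scale * rng.uniform(0.9, 1.1) * bump


def generate_cohort(config: SynthConfig) -> list[SubjectRecord]:
    """All subjects of the configured cohort, subject seeds 0..n-1."""
    return [generate_session(config, i) for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# plain-text export
# ---------------------------------------------------------------------------


def write_session_csv(record: SubjectRecord, path: str | Path) -> Path:
    """One column per channel (header row of names), one row per sample."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ",".join(record.channel_names)
    np.savetxt(
        path, record.data.T, delimiter=",", header=header, comments="", fmt="%.6f"
    )
    return path


def write_manifest(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    """Per-subject TSV manifest: id, seed, assay pair, label."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["subject_id\tseed\tamylase_baseline\tamylase_post\tlabel"]
    for rec in records:
        lines.append(
            f"{rec.subject_id}\t{rec.seed}\t{rec.amylase_baseline.level:.2f}"
            f"\t{rec.amylase_post.level:.2f}\t{rec.label}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def config_to_dict(config: SynthConfig) -> dict:
    """JSON-serializable view of a config (arrays become lists)."""
    d = dataclasses.asdict(config)
    d["band_amplitudes"] = {
        cond: {b: np.asarray(a).tolist() for b, a in bands.items()}
        for cond, bands in config.resolved_band_amplitudes().items()
    }
    d["plv_targets"] = config.resolved_plv_targets()
    return d
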