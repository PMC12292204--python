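"""Synthetic epoched-EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes: 1/f
background activity, band-limited oscillatory class signatures planted in
chosen scalp regions, ocular/EMG artifacts, and a subject -> trial variance
hierarchy that makes subject-wise cross-validation meaningfully different
from trial-wise splits.

The default cohort mirrors the study population: three genotype groups
(N = non-carriers, A+P- = APOE-only risk carriers, A+P+ = APOE+PICALM
carriers) of 21/18/12 subjects, with per-group trial totals under the MSIT
and Sternberg (STMT) task conditions distributed as evenly as possible
across subjects so group totals are exact.  Risk carriers receive extra
theta/alpha oscillatory power over parietal and temporal channels;
non-carriers receive a frontal signature; the dual-risk group reuses the
single-risk signatures at a shifted amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.random import SeedSequence, default_rng

from .bands import get_band
from .montage import Montage, build_montage

GROUPS = ("N", "A+P-", "A+P+")
TASKS = ("MSIT", "STMT")
#: groups used for classifier training/validation; A+P+ is the held-out set
TRAINING_GROUPS = ("N", "A+P-")
RISK_GROUP = "A+P-"
HELDOUT_GROUP = "A+P+"

# Per-group trial totals per task condition (cohort bookkeeping defaults).
DEFAULT_TRIAL_TOTALS: Dict[str, Dict[str, int]] = {
    "N": {"MSIT": 3176, "STMT": 2442},
    "A+P-": {"MSIT": 2720, "STMT": 2151},
    "A+P+": {"MSIT": 1738, "STMT": 1364},
}

DEFAULT_GROUP_SIZES: Dict[str, int] = {"N": 21, "A+P-": 18, "A+P+": 12}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochSpec:
    """Geometry of one epoched trial.

    The default is a 60-channel, 320-sample window from -80 to 1200 ms
    around stimulus onset at 250 Hz.
    """

    fs: float = 250.0
    t_start: float = -80.0   # ms
    t_end: float = 1200.0    # ms
    n_channels: int = 60
    n_samples: int = 320

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_channels <= 0:
            raise ValueError("n_channels and n_samples must be positive")
        expected = (self.t_end - self.t_start) / 1000.0 * self.fs
        if abs(expected - self.n_samples) > 1e-9:
            raise ValueError(
                f"inconsistent epoch geometry: ({self.t_end}-{self.t_start}) ms at "
                f"{self.fs} Hz gives {expected} samples, not {self.n_samples}"
            )

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t_start / 1000.0 + np.arange(self.n_samples) / self.fs


@dataclass
class Epoch:
    """One trial: channels x samples voltages (uV) plus its labels."""

    data: np.ndarray
    subject_id: str
    group: str
    task: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    def copy(self) -> "Epoch":
        return Epoch(self.data.copy(), self.subject_id, self.group, self.task)


@dataclass(frozen=True)
class BandSignature:
    """A band-limited oscillation planted in one or more scalp regions.

    ``amplitude`` is the population-mean oscillation amplitude (uV);
    ``amplitude_sd`` its SD across subjects and ``per_trial_jitter`` the SD
    across trials within a subject.
    """

    band: str
    region: Tuple[str, ...]
    amplitude: float
    amplitude_sd: float = 0.0
    per_trial_jitter: float = 0.0

    def __post_init__(self) -> None:
        get_band(self.band)  # validates the name
        object.__setattr__(self, "region", tuple(
            (self.region,) if isinstance(self.region, str) else self.region))
        if self.amplitude < 0 or self.amplitude_sd < 0 or self.per_trial_jitter < 0:
            raise ValueError("amplitude and its SDs must be nonnegative")


def default_signatures() -> Dict[str, List[BandSignature]]:
    """The stated class signatures.

    Risk carriers (A+P-) carry theta and alpha oscillations over parietal
    and temporal channels; non-carriers (N) carry a frontal alpha feature;
    the dual-risk group (A+P+) reuses the risk signatures at 0.75x amplitude
    ("similar yet still differing").
    """
    post = ("parietal", "temporal")
    return {
        "N": [BandSignature("alpha", ("frontal",), 4.0, 1.0, 1.0)],
        "A+P-": [
            BandSignature("theta", post, 4.0, 1.0, 1.0),
            BandSignature("alpha", post, 4.0, 1.0, 1.0),
        ],
        "A+P+": [
            BandSignature("theta", post, 3.0, 1.0, 1.0),
            BandSignature("alpha", post, 3.0, 1.0, 1.0),
        ],
    }


@dataclass
class CohortSpec:
    """Everything needed to synthesize a cohort deterministically."""

    group_sizes: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    trial_totals: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {g: dict(t) for g, t in DEFAULT_TRIAL_TOTALS.items()})
    signatures: Dict[str, List[BandSignature]] = field(default_factory=default_signatures)
    noise_exponent: float = 1.0
    noise_scale: float = 10.0          # uV RMS of the 1/f background
    artifact_rates: Dict[str, float] = field(
        default_factory=lambda: {"ocular": 0.05, "emg": 0.05})
    artifact_amplitudes: Dict[str, float] = field(
        default_factory=lambda: {"ocular": 100.0, "emg": 30.0})
    scale: float = 1.0                 # multiplies trial totals (desk-scale runs)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be nonnegative")
        for kind, p in self.artifact_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"artifact rate for {kind!r} must be in [0,1]")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    epochs: List[Epoch]

    def __post_init__(self) -> None:
        for ep in self.epochs:
            if ep.subject_id != self.subject_id or ep.group != self.group:
                raise ValueError("epoch labels inconsistent with subject record")


@dataclass
class Dataset:
    spec: EpochSpec
    montage: Montage
    subjects: List[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        shape = (self.spec.n_channels, self.spec.n_samples)
        for s in self.subjects:
            for ep in s.epochs:
                if ep.data.shape != shape:
                    raise ValueError(
                        f"epoch of {s.subject_id} has shape {ep.data.shape}, "
                        f"spec requires {shape}")

    def subjects_in_group(self, group: str) -> List[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def epochs(self, groups: Sequence[str] | None = None,
               subject_ids: Sequence[str] | None = None,
               task: str | None = None) -> List[Epoch]:
        """Flat trial list, optionally filtered by group/subject/task."""
        out: List[Epoch] = []
        sid = set(subject_ids) if subject_ids is not None else None
        for s in self.subjects:
            if groups is not None and s.group not in groups:
                continue
            if sid is not None and s.subject_id not in sid:
                continue
            for ep in s.epochs:
                if task is not None and task != "ALL" and ep.task != task:
                    continue
                out.append(ep)
        return out

    def n_trials(self, **kw) -> int:
        return len(self.epochs(**kw))


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def generate_background(spec: EpochSpec, exponent: float, scale: float,
                        seed: int) -> np.ndarray:
    """Zero-mean 1/f^exponent background noise, (n_channels, n_samples).

    Gaussian spectral synthesis: white complex coefficients shaped by
    f^(-exponent/2), inverse-FFT'd, then normalized per channel to RMS
    ``scale`` (uV).  Bit-reproducible for a given seed.
    """
    if exponent < 0 or scale < 0:
        raise ValueError("exponent and scale must be nonnegative")
    n, c = spec.n_samples, spec.n_channels
    if n <= 0:
        raise ValueError("n_samples must be positive")
    if scale == 0.0:
        return np.zeros((c, n))
    rng = default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    coef = (rng.standard_normal((c, freqs.size))
            + 1j * rng.standard_normal((c, freqs.size))) * shape
    x = np.fft.irfft(coef, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms * scale


def plant_band_signature(epoch: Epoch, sig: BandSignature, montage: Montage,
                         spec: EpochSpec, seed: int,
                         amplitude: float | None = None) -> Epoch:
    """Add a random-phase band-limited sinusoid to the signature's regions.

    One frequency is drawn uniformly within the band per call (per trial);
    each target channel gets an independent uniform phase.  Channels outside
    ``sig.region`` are untouched.  ``amplitude`` overrides ``sig.amplitude``
    (used by the hierarchical cohort generator).
    """
    idx = montage.channels_in_region(sig.region)
    if idx.size == 0:
        raise ValueError(f"no channels in region(s) {sig.region} of this montage")
    band = get_band(sig.band)
    if band.f_hi > spec.fs / 2:
        raise ValueError(f"band {band.name!r} exceeds Nyquist ({spec.fs / 2} Hz)")
    amp = sig.amplitude if amplitude is None else amplitude
    if amp < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = default_rng(seed)
    f = rng.uniform(band.f_lo, band.f_hi)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=idx.size)
    out = epoch.copy()
    if amp == 0.0:
        return out
    t = np.arange(spec.n_samples) / spec.fs
    out.data[idx, :] += amp * np.sin(
        2.0 * np.pi * f * t[None, :] + phases[:, None])
    return out


def add_artifact(epoch: Epoch, kind: str, amplitude: float, montage: Montage,
                 spec: EpochSpec, seed: int) -> Epoch:
    """Contaminate an epoch with a stereotyped non-neural artifact.

    ``ocular``: a blink-like low-frequency (< 4 Hz) Gaussian transient on
    frontal channels, with weights decaying away from the prefrontal pole.
    ``emg``: a broadband high-frequency (> 20 Hz) muscle burst confined to
    temporal channels.  ``amplitude`` is the peak (ocular) or burst RMS
    (emg) in uV on the most-affected channel.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if kind not in ("ocular", "emg"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    out = epoch.copy()
    if amplitude == 0.0:
        return out
    rng = default_rng(seed)
    t = np.arange(spec.n_samples) / spec.fs
    dur = spec.n_samples / spec.fs
    if kind == "ocular":
        idx = montage.channels_in_region("frontal")
        # blink dipoles sit at the eyes, just beyond the scalp circle
        eyes = np.array([[-0.35, 1.0], [0.35, 1.0]])
        d = np.linalg.norm(montage.positions[idx][:, None, :] - eyes[None],
                           axis=2)
        weights = np.exp(-d / 0.25).sum(axis=1)
        weights /= weights.max()
        t0 = rng.uniform(0.15 * dur, 0.85 * dur)
        width = 0.1  # s -> spectral content well below 4 Hz
        wave = np.exp(-0.5 * ((t - t0) / width) ** 2)
        out.data[idx, :] += amplitude * weights[:, None] * wave[None, :]
    else:  # emg
        from scipy.signal import butter, filtfilt, windows

        idx = montage.channels_in_region("temporal")
        b, a = butter(4, 25.0 / (spec.fs / 2.0), btype="highpass")
        noise = rng.standard_normal((idx.size, spec.n_samples))
        burst = filtfilt(b, a, noise, axis=1)
        # confine the burst to a ~0.3 s window at a random onset
        w = np.zeros(spec.n_samples)
        w_len = max(4, int(round(0.3 * spec.fs)))
        start = rng.integers(0, max(1, spec.n_samples - w_len))
        w[start:start + w_len] = windows.tukey(w_len, alpha=0.5)
        burst *= w[None, :]
        active = burst[:, w > 0]
        rms = active.std(axis=1, keepdims=True) if active.size else np.ones((idx.size, 1))
        rms[rms == 0] = 1.0
        gains = rng.uniform(0.5, 1.0, size=(idx.size, 1))
        out.data[idx, :] += amplitude * gains * burst / rms
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def group_task_totals(cohort: CohortSpec) -> Dict[str, Dict[str, int]]:
    """Scaled per-group/per-task trial totals (rounded once, on the total)."""
    return {
        g: {task: int(round(total * cohort.scale)) for task, total in per_task.items()}
        for g, per_task in cohort.trial_totals.items()
        if cohort.group_sizes.get(g, 0) > 0
    }


def trial_plan(cohort: CohortSpec) -> Dict[str, Dict[str, List[int]]]:
    """Per-subject trial counts: group totals distributed by largest remainder.

    Guarantees the per-group totals are met exactly (sum over subjects equals
    the scaled group total) while keeping subjects within one trial of each
    other.
    """
    plan: Dict[str, Dict[str, List[int]]] = {}
    totals = group_task_totals(cohort)
    for g, per_task in totals.items():
        n_subj = cohort.group_sizes[g]
        plan[g] = {}
        for task, total in per_task.items():
            base, extra = divmod(total, n_subj)
            plan[g][task] = [base + (1 if i < extra else 0) for i in range(n_subj)]
    return plan


def _subject_ids(group: str, n: int) -> List[str]:
    tag = {"N": "N", "A+P-": "AP", "A+P+": "APP"}[group]
    return [f"{tag}{i + 1:02d}" for i in range(n)]


def generate_cohort(cohort: CohortSpec, epoch_spec: EpochSpec,
                    montage: Montage | None = None) -> Dataset:
    """Synthesize the full cohort deterministically from ``master_seed``.

    Hierarchy: per (subject, signature) a Gaussian amplitude offset
    (SD ``amplitude_sd``); per trial an additional Gaussian jitter
    (SD ``per_trial_jitter``); realized amplitudes truncated at 0.
    Artifacts occur independently per trial with the configured rates.
    """
    if montage is None:
        montage = build_montage(epoch_spec.n_channels)
    if len(montage) != epoch_spec.n_channels:
        raise ValueError("montage size inconsistent with epoch spec")
    plan = trial_plan(cohort)
    root = SeedSequence(cohort.master_seed)
    subjects: List[SubjectRecord] = []
    group_seeds = {g: child for g, child in
                   zip(GROUPS, root.spawn(len(GROUPS)))}
    for g in GROUPS:
        n_subj = cohort.group_sizes.get(g, 0)
        if n_subj == 0:
            continue
        sigs = cohort.signatures.get(g, [])
        subj_seeds = group_seeds[g].spawn(n_subj)
        for i, sid in enumerate(_subject_ids(g, n_subj)):
            rng = default_rng(subj_seeds[i])
            offsets = [rng.normal(0.0, s.amplitude_sd) for s in sigs]
            epochs: List[Epoch] = []
            for task in TASKS:
                counts = plan.get(g, {}).get(task, [0] * n_subj)
                for _ in range(counts[i]):
                    bg = generate_background(
                        epoch_spec, cohort.noise_exponent, cohort.noise_scale,
                        int(rng.integers(2 ** 31)))
                    ep = Epoch(bg, sid, g, task)
                    for s, off in zip(sigs, offsets):
                        amp = s.amplitude + off + rng.normal(0.0, s.per_trial_jitter)
                        ep = plant_band_signature(
                            ep, s, montage, epoch_spec,
                            int(rng.integers(2 ** 31)), amplitude=max(0.0, amp))
                    for kind, rate in cohort.artifact_rates.items():
                        if rate > 0 and rng.random() < rate:
                            ep = add_artifact(
                                ep, kind, cohort.artifact_amplitudes.get(kind, 0.0),
                                montage, epoch_spec, int(rng.integers(2 ** 31)))
                    epochs.append(ep)
            subjects.append(SubjectRecord(sid, g, epochs))
    return Dataset(epoch_spec, montage, subjects)
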