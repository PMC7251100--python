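"""Seeded synthetic data: EEG-like recordings and coupled oscillators.

The recording generator emulates the phenomenology the detection pipeline
must separate, not the physiology of scalp EEG:

* background: pink (1/f) activity from a few zero-lag shared sources
  mixed into all channels (a volume-conduction-like component that gives
  large common power but near-zero phase lags), a small channel-specific
  pink jitter, and a weak 9-11 Hz rhythm with i.i.d. phases per channel.
  The jitter and rhythm set the resting level and variance of the
  synchronization network's lambda_2.
* seizures: coherent band-limited oscillations (default 6 Hz) on all
  channels with fixed nonzero inter-channel phase lags and elevated
  amplitude -- the hypersynchronous regime lambda_2 is designed to catch.
* artifacts: short high-power incoherent bursts confined to a few
  channels -- they dominate the summed band power but, lacking a global
  lag structure, barely move lambda_2.

Everything is a pure function of (config, seed).  The oscillator
simulator provides ground-truth coupling matrices for validating the
coupling-function inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import (
    Recording,
    SeizureInterval,
    write_annotations,
    write_csv_recording,
    write_edf,
)

__all__ = [
    "BackgroundSpec",
    "SeizureSpec",
    "ArtifactSpec",
    "SynthConfig",
    "GroundTruth",
    "OscillatorSpec",
    "gen_recording",
    "default_suite",
    "simulate_oscillators",
    "write_fixture",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Resting-state background parameters (amplitudes in microvolts).

    shared_rms: RMS of each zero-lag shared pink source; n_sources of
    them are mixed into every channel with random positive gains.
    jitter_rms: RMS of the channel-specific independent pink component
    (controls resting phase-lag variance, hence resting lambda_2).
    rhythm_rms: RMS of the per-channel rhythm with i.i.d. phases drawn
    from rhythm_band (its 10 Hz edge sits inside the 2-10 Hz analysis
    band and drives window-to-window lambda_2 fluctuation).
    """

    shared_rms: float = 5.0
    n_sources: int = 3
    jitter_rms: float = 1.0
    rhythm_rms: float = 1.0
    rhythm_band: tuple[float, float] = (9.0, 11.0)
    slope: float = 1.0  # 1/f^slope power spectrum


@dataclass(frozen=True)
class SeizureSpec:
    """A planted seizure: coherent lagged oscillation on all channels."""

    onset: float
    offset: float
    f0: float = 6.0
    amplitude: float = 300.0  # microvolts
    max_lag: float = np.pi / 4  # channel i lags by max_lag * i / n_channels
    ramp: float = 1.0  # onset/offset amplitude ramp, seconds


@dataclass(frozen=True)
class ArtifactSpec:
    """A high-power incoherent transient on a small channel subset."""

    onset: float
    offset: float
    channels: tuple[int, ...]
    amplitude: float = 1500.0  # microvolts RMS
    band: tuple[float, float] = (2.0, 24.0)


@dataclass(frozen=True)
class SynthConfig:
    n_channels: int = 23
    fs: float = 256.0
    duration: float = 600.0
    seed: int = 0
    background: BackgroundSpec = BackgroundSpec()
    seizures: tuple[SeizureSpec, ...] = ()
    artifacts: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self) -> None:
        for iv in list(self.seizures) + list(self.artifacts):
            if not (0 <= iv.onset < iv.offset <= self.duration):
                raise ValueError(
                    f"interval [{iv.onset}, {iv.offset}] outside recording "
                    f"of {self.duration} s"
                )
        for art in self.artifacts:
            if any(not 0 <= c < self.n_channels for c in art.channels):
                raise ValueError("artifact channel index out of range")


@dataclass
class GroundTruth:
    """What the generator actually planted (or simulated)."""

    seizures: list[SeizureInterval] = field(default_factory=list)
    artifacts: list[SeizureInterval] = field(default_factory=list)
    artifact_channels: list[list[int]] = field(default_factory=list)
    coupling: np.ndarray | None = None
    omegas: np.ndarray | None = None

    def to_json(self) -> str:
        payload = {
            "seizures": [[s.onset, s.offset] for s in self.seizures],
            "artifacts": [[a.onset, a.offset] for a in self.artifacts],
            "artifact_channels": self.artifact_channels,
            "coupling": None if self.coupling is None else self.coupling.tolist(),
            "omegas": None if self.omegas is None else self.omegas.tolist(),
        }
        return json.dumps(payload, indent=2)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, slope: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f^slope noise via frequency-domain shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-slope / 2.0)
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited white noise (hard spectral mask)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.where(mask, rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size), 0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def gen_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate a recording with planted seizures and artifacts.

    Deterministic for a fixed config (seed included).  The returned
    Recording carries the seizure intervals as annotations; artifacts are
    listed only in the GroundTruth.
    """
    rng = np.random.default_rng(config.seed)
    n_ch, fs = config.n_channels, config.fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    bg = config.background

    data = np.zeros((n_ch, n))
    # zero-lag shared pink sources with random positive channel gains
    mixing = rng.uniform(0.6, 1.4, size=(n_ch, bg.n_sources))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    sources = np.stack([_pink_noise(rng, n, fs, bg.slope) for _ in range(bg.n_sources)])
    data += bg.shared_rms * (mixing @ sources)
    # channel-specific pink jitter
    for i in range(n_ch):
        data[i] += bg.jitter_rms * _pink_noise(rng, n, fs, bg.slope)
    # weak rhythm, i.i.d. frequency and phase per channel
    f_r = rng.uniform(*bg.rhythm_band, size=n_ch)
    ph_r = rng.uniform(0, 2 * np.pi, size=n_ch)
    data += bg.rhythm_rms * np.sqrt(2) * np.sin(2 * np.pi * f_r[:, None] * t[None, :] + ph_r[:, None])

    for sz in config.seizures:
        lags = sz.max_lag * np.arange(n_ch) / n_ch
        mask = (t >= sz.onset) & (t < sz.offset)
        env = np.clip(
            np.minimum(t[mask] - sz.onset, sz.offset - t[mask]) / max(sz.ramp, 1e-9),
            0.0,
            1.0,
        )
        for i in range(n_ch):
            data[i, mask] += sz.amplitude * env * np.sin(
                2 * np.pi * sz.f0 * t[mask] - lags[i]
            )

    for art in config.artifacts:
        mask = (t >= art.onset) & (t < art.offset)
        m = int(mask.sum())
        if m < 8:
            raise ValueError("artifact interval too short")
        for c in art.channels:
            data[c, mask] += art.amplitude * _band_noise(rng, m, fs, art.band)

    rec = Recording(
        data=data,
        fs=fs,
        labels=[f"SYN{i:02d}" for i in range(n_ch)],
        annotations=[SeizureInterval(s.onset, s.offset) for s in config.seizures],
    )
    gt = GroundTruth(
        seizures=list(rec.annotations),
        artifacts=[SeizureInterval(a.onset, a.offset) for a in config.artifacts],
        artifact_channels=[list(a.channels) for a in config.artifacts],
    )
    return rec, gt


def default_suite(
    duration: float = 3600.0,
    n_seizures: int = 10,
    n_artifacts: int = 20,
    seed: int = 0,
    n_channels: int = 23,
    fs: float = 256.0,
    seizure_duration: float = 20.0,
    artifact_duration: float = 2.0,
) -> SynthConfig:
    """Standard acceptance-style recording: evenly spaced seizure slots
    with jittered onsets, artifacts scattered between them on random
    2-channel subsets.  Pure function of the arguments."""
    rng = np.random.default_rng(seed)
    n_events = n_seizures + n_artifacts
    slot = duration / (n_events + 1)
    starts = (np.arange(1, n_events + 1) * slot) + rng.uniform(-0.2 * slot, 0.2 * slot, n_events)
    which = rng.permutation(n_events) < n_seizures
    seizures, artifacts = [], []
    for s, is_sz in zip(starts, which):
        if is_sz:
            seizures.append(
                SeizureSpec(onset=float(s), offset=float(min(s + seizure_duration, duration)))
            )
        else:
            chans = tuple(int(c) for c in rng.choice(n_channels, size=2, replace=False))
            artifacts.append(
                ArtifactSpec(
                    onset=float(s), offset=float(min(s + artifact_duration, duration)), channels=chans
                )
            )
    return SynthConfig(
        n_channels=n_channels,
        fs=fs,
        duration=duration,
        seed=seed,
        seizures=tuple(seizures),
        artifacts=tuple(artifacts),
    )


# ---------------------------------------------------------------------------
# Coupled oscillators


@dataclass(frozen=True)
class OscillatorSpec:
    """Network of phase oscillators dx_i = w_i + sum_j K_ij g(x_j - x_i).

    K is directed (rows = target) with zero diagonal; the default
    coupling g = sin keeps the interaction inside the trigonometric
    basis span.  noise_std is the per-sqrt-second standard deviation of
    additive Gaussian noise.
    """

    omegas: tuple[float, ...]
    coupling: tuple[tuple[float, ...], ...]
    step: float = 0.01
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        K = np.asarray(self.coupling, dtype=float)
        n = len(self.omegas)
        if K.shape != (n, n):
            raise ValueError("coupling matrix shape must match omegas")
        if np.any(np.diag(K) != 0):
            raise ValueError("coupling matrix must have zero diagonal")
        wmax = max(abs(w) for w in self.omegas) or 1.0
        if self.step > 1.0 / (10.0 * wmax):
            raise ValueError(
                f"integration step {self.step} too large for max |omega| "
                f"{wmax} (need step <= {1.0 / (10.0 * wmax):.4g})"
            )


def random_oscillator_network(
    n: int = 6,
    seed: int = 0,
    gain: float = 1.0,
    edge_prob: float = 0.3,
    weight_range: tuple[float, float] = (0.3, 0.6),
    omega_range: tuple[float, float] = (1.5, 6.0),
    noise_std: float = 0.005,
    step: float = 0.005,
) -> OscillatorSpec:
    """A random directed network in the identifiable drift regime.

    Natural frequencies are spread evenly over ``omega_range`` (with
    jitter) and coupling weights kept below the pairwise frequency
    differences, so no pair phase-locks: a locked pair's phase
    difference is constant, its coupling term indistinguishable from
    self-dynamics, and the edge unrecoverable in principle.  The small
    dynamical noise aids state-space exploration.  ``gain`` scales the
    whole coupling matrix.
    """
    rng = np.random.default_rng(seed)
    K = np.zeros((n, n))
    edges = rng.random((n, n)) < edge_prob
    np.fill_diagonal(edges, False)
    if not edges.any():
        edges[0, 1] = True
    K[edges] = gain * rng.uniform(*weight_range, edges.sum())
    omegas = np.linspace(*omega_range, n) + rng.uniform(-0.1, 0.1, n)
    return OscillatorSpec(
        omegas=tuple(float(w) for w in omegas),
        coupling=tuple(map(tuple, K)),
        step=step,
        noise_std=noise_std,
        seed=seed,
    )


def simulate_oscillators(
    spec: OscillatorSpec,
    duration: float,
    coupling_fn: Callable[[np.ndarray], np.ndarray] = np.sin,
    export: str = "phase",
) -> tuple[Recording, GroundTruth]:
    """Integrate the network with fixed-step RK4 plus optional additive
    noise per step.

    export="phase" returns unwrapped phases (use wrap_phase=True when
    inferring); export="sin" returns sin(phase) to mimic amplitude
    signals.  Raises if the trajectory blows up (unstable step).
    """
    if export not in {"phase", "sin"}:
        raise ValueError(f"unknown export mode: {export!r}")
    rng = np.random.default_rng(spec.seed)
    K = np.asarray(spec.coupling, dtype=float)
    omega = np.asarray(spec.omegas, dtype=float)
    n = omega.size
    dt = spec.step
    steps = int(round(duration / dt))

    def deriv(x: np.ndarray) -> np.ndarray:
        diff = x[None, :] - x[:, None]  # diff[i, j] = x_j - x_i
        return omega + np.sum(K * coupling_fn(diff), axis=1)

    x = rng.uniform(-np.pi, np.pi, size=n)
    traj = np.empty((n, steps + 1))
    traj[:, 0] = x
    max_step = 10.0 * (np.max(np.abs(omega)) + np.sum(np.abs(K), axis=1).max() + 1.0)
    for s in range(steps):
        k1 = deriv(x)
        k2 = deriv(x + 0.5 * dt * k1)
        k3 = deriv(x + 0.5 * dt * k2)
        k4 = deriv(x + dt * k3)
        inc = (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.max(np.abs(inc)) > max_step * dt:
            raise RuntimeError(
                "trajectory blow-up detected; use a smaller integration step"
            )
        x = x + inc
        if spec.noise_std > 0:
            x = x + spec.noise_std * np.sqrt(dt) * rng.standard_normal(n)
        traj[:, s + 1] = x

    data = np.sin(traj) if export == "sin" else traj
    rec = Recording(
        data=data, fs=1.0 / dt, labels=[f"osc{i:02d}" for i in range(n)]
    )
    gt = GroundTruth(coupling=K.copy(), omegas=omega.copy())
    return rec, gt


def write_fixture(
    rec: Recording, gt: GroundTruth, directory: str | Path, fmt: str = "csv"
) -> dict[str, Path]:
    """Write signal + annotations + ground truth into a directory.

    fmt="edf" writes 16-bit EDF (lossy to one quantization step);
    fmt="csv" round-trips exactly.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "edf":
        sig = directory / "recording.edf"
        write_edf(rec, sig)
    elif fmt == "csv":
        sig = directory / "recording.csv"
        write_csv_recording(rec, sig)
    else:
        raise ValueError(f"unknown fixture format: {fmt!r}")
    ann = directory / "annotations.csv"
    write_annotations(rec.annotations, ann)
    truth = directory / "ground_truth.json"
    truth.write_text(gt.to_json())
    return {"signal": sig, "annotations": ann, "ground_truth": truth}
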