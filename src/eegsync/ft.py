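"""Spectral synchronization network and its algebraic connectivity.

Per short window (0.25-1 s), each channel's one-sided FFT gives magnitudes
p_in and phases phi_in on a 1/w Hz grid.  Restricted to a band (default
2-10 Hz, where epileptiform rhythms concentrate), they combine into

* power coupling      sigma_p[i,j]   = P_i + P_j, with P_i = sum_n p_in^2
* phase-lag coupling  sigma_phi[i,j] = (1/N) sum_n sin(phi_jn - phi_in)
* adjacency           a_ij = 1 - exp(-|sigma_p*sigma_phi|^gamma)

The Laplacian L = D - A then yields the Fiedler eigenvalue lambda_2
(algebraic connectivity), which rises when many channels carry coherent
in-band power with consistent nonzero phase lags -- the signature of
seizure-like hypersynchronization -- but stays low for high-power
incoherent transients confined to a few channels.

Note the phase coupling is a *lag* measure: perfectly zero-lag (or
anti-phase) channels give sigma_phi = 0 and contribute no edge, like a
phase-lag index.  This makes the network blind to exactly phase-aligned
sources by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .io import Recording, WindowPlan, normalize_range, preprocess, segment

__all__ = [
    "SpectralFrame",
    "BandPower",
    "NetworkFrame",
    "ConnectivitySeries",
    "FTConfig",
    "compute_spectrum",
    "band_restrict",
    "band_power",
    "coupling_matrices",
    "adjacency",
    "fiedler",
    "network_frames",
    "lambda2_series",
]


@dataclass
class SpectralFrame:
    """One window's per-channel one-sided spectrum.

    ``p`` are magnitudes (or squared magnitudes under the periodogram
    convention), ``phi`` phases in (-pi, pi].  ``band`` records the
    (f_lo, f_hi) restriction applied by :func:`band_restrict`, if any.
    """

    freqs: np.ndarray
    p: np.ndarray
    phi: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.p.shape != self.phi.shape:
            raise ValueError("p and phi must share shape")
        if self.p.shape[1] != self.freqs.size:
            raise ValueError("frequency grid does not match spectrum width")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.p < 0):
            raise ValueError("magnitudes must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.p.shape[0]

    def band_mask(self) -> np.ndarray:
        """Boolean mask of in-band bins (all bins if no band applied);
        band edges are inclusive."""
        if self.band is None:
            return np.ones(self.freqs.size, dtype=bool)
        lo, hi = self.band
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass(frozen=True)
class BandPower:
    """Per-channel in-band energy P_i = sum_n p_in^2 and the bin count N."""

    P: np.ndarray
    band: tuple[float, float] | None
    n_band: int

    def __post_init__(self) -> None:
        if self.n_band < 1:
            raise ValueError("band contains no frequency bins")
        if np.any(self.P < 0):
            raise ValueError("band power must be nonnegative")


@dataclass
class NetworkFrame:
    """All per-window network matrices for one time step t_k."""

    t_k: float
    sigma_p: np.ndarray
    sigma_phi: np.ndarray
    d: np.ndarray
    A: np.ndarray
    D: np.ndarray
    L: np.ndarray
    gamma: float


@dataclass
class ConnectivitySeries:
    """lambda_2 (and optionally lambda_n, eigenratio) per window."""

    times: np.ndarray
    lambda2: np.ndarray
    lambda_n: np.ndarray | None = None
    eigenratio: np.ndarray | None = None

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FTConfig:
    """Parameters of the spectral-network pipeline.

    window/hop in seconds; band in Hz (inclusive edges); gamma the
    adjacency exponent; power_def selects p=|X| ("magnitude", default)
    or p=|X|^2 ("periodogram"); normalize is the [-1,1] scaling mode
    applied before analysis (None to skip); prefilter optionally applies
    the 1-50 Hz preprocessing first (the spectral path works on raw data
    by default since the band restriction does its own filtering).
    """

    window: float = 1.0
    hop: float | None = None
    band: tuple[float, float] = (2.0, 10.0)
    gamma: float = 2.0
    power_def: str = "magnitude"
    normalize: str | None = "per_channel"
    prefilter: bool = False

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.power_def not in {"magnitude", "periodogram"}:
            raise ValueError(f"unknown power_def: {self.power_def!r}")
        if not (0 <= self.band[0] < self.band[1]):
            raise ValueError(f"invalid band: {self.band}")


def compute_spectrum(window: np.ndarray, fs: float, power_def: str = "magnitude") -> SpectralFrame:
    """One-sided DFT of a channels x samples window (rectangular window,
    no zero-padding): p = |X| (or |X|^2), phi = arg(X)."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] < 2:
        raise ValueError("window must have at least 2 samples")
    X = np.fft.rfft(window, axis=1)
    freqs = np.fft.rfftfreq(window.shape[1], d=1.0 / fs)
    mag = np.abs(X)
    p = mag if power_def == "magnitude" else mag**2
    return SpectralFrame(freqs=freqs, p=p, phi=np.angle(X))


def band_restrict(frame: SpectralFrame, f_lo: float = 2.0, f_hi: float = 10.0) -> SpectralFrame:
    """Zero out-of-band magnitudes (phases retained); edges inclusive."""
    if not (f_lo < f_hi):
        raise ValueError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    mask = (frame.freqs >= f_lo) & (frame.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz contains no frequency bins")
    p = frame.p.copy()
    p[:, ~mask] = 0.0
    return replace(frame, p=p, phi=frame.phi.copy(), band=(f_lo, f_hi))


def band_power(frame: SpectralFrame) -> BandPower:
    """P_i = sum of squared magnitudes over the in-band bins."""
    mask = frame.band_mask()
    n_band = int(mask.sum())
    if n_band == 0:
        raise ValueError("no in-band frequency bins")
    P = np.sum(frame.p[:, mask] ** 2, axis=1)
    return BandPower(P=P, band=frame.band, n_band=n_band)


def coupling_matrices(
    frame: SpectralFrame, bp: BandPower
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Power coupling, phase-lag coupling and their product d.

    sigma_p[i,j] = P_i + P_j (symmetric, >= 0);
    sigma_phi[i,j] = mean over in-band bins of sin(phi_j - phi_i)
    (antisymmetric, |.| <= 1);  d = sigma_p * sigma_phi with zero diagonal.
    """
    if bp.n_band < 1:
        raise ValueError("empty band")
    P = bp.P
    sigma_p = P[:, None] + P[None, :]
    mask = frame.band_mask()
    phi = frame.phi[:, mask]  # channels x in-band bins
    # sin(phi_j - phi_i) averaged over bins, vectorized over channel pairs
    diff = phi[None, :, :] - phi[:, None, :]
    sigma_phi = np.mean(np.sin(diff), axis=2)
    d = sigma_p * sigma_phi
    np.fill_diagonal(d, 0.0)
    return sigma_p, sigma_phi, d


def adjacency(d: np.ndarray, gamma: float = 2.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map couplings to a weighted graph: a_ij = 1 - exp(-|d_ij|^gamma).

    Returns (A, D, L) with D = diag(row sums of A) and L = D - A.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d = np.asarray(d, dtype=float)
    if np.any(np.diag(d) != 0):
        raise ValueError("d must have zero diagonal")
    A = 1.0 - np.exp(-np.abs(d) ** gamma)
    # exp underflow would give exactly 1.0; keep the open interval [0, 1)
    A = np.minimum(A, np.nextafter(1.0, 0.0))
    np.fill_diagonal(A, 0.0)
    D = np.diag(A.sum(axis=1))
    L = D - A
    return A, D, L


def fiedler(L: np.ndarray, tol: float = 1e-8) -> tuple[float, float, float]:
    """(lambda_2, lambda_n, eigenratio) of a symmetric Laplacian.

    Eigenvalues are clamped at a -1e-12 numerical floor; the eigenratio
    lambda_2/lambda_n is 0 for an empty graph.
    """
    L = np.asarray(L, dtype=float)
    if L.shape[0] != L.shape[1]:
        raise ValueError("L must be square")
    if np.max(np.abs(L - L.T)) > tol * max(1.0, np.max(np.abs(L))):
        raise ValueError("L is not symmetric within tolerance")
    w = np.linalg.eigvalsh((L + L.T) / 2)
    w = np.where((w < 0) & (w > -1e-12), 0.0, w)
    lam2 = float(w[1]) if w.size > 1 else 0.0
    lam_n = float(w[-1])
    ratio = lam2 / lam_n if lam_n > 0 else 0.0
    return lam2, lam_n, ratio


def _prepare(rec: Recording, config: FTConfig) -> Recording:
    if config.prefilter:
        rec = preprocess(rec)
    if config.normalize is not None:
        rec = normalize_range(rec, mode=config.normalize)
    return rec


def network_frames(rec: Recording, config: FTConfig = FTConfig()) -> Iterator[NetworkFrame]:
    """Run the full per-window pipeline, yielding one NetworkFrame per
    window: spectrum -> band -> power -> couplings -> adjacency."""
    rec = _prepare(rec, config)
    plan = WindowPlan(config.window, config.hop)
    for t_k, win in segment(rec, plan):
        frame = compute_spectrum(win, rec.fs, power_def=config.power_def)
        frame = band_restrict(frame, *config.band)
        bp = band_power(frame)
        sigma_p, sigma_phi, d = coupling_matrices(frame, bp)
        A, D, L = adjacency(d, gamma=config.gamma)
        yield NetworkFrame(
            t_k=t_k, sigma_p=sigma_p, sigma_phi=sigma_phi, d=d, A=A, D=D, L=L,
            gamma=config.gamma,
        )


def lambda2_series(rec: Recording, config: FTConfig = FTConfig()) -> ConnectivitySeries:
    """Fiedler-eigenvalue time series of the spectral synchronization
    network, one value per window (time stamped at window end)."""
    times, l2s, lns, ratios = [], [], [], []
    for nf in network_frames(rec, config):
        lam2, lam_n, ratio = fiedler(nf.L)
        times.append(nf.t_k)
        l2s.append(lam2)
        lns.append(lam_n)
        ratios.append(ratio)
    return ConnectivitySeries(
        times=np.asarray(times),
        lambda2=np.asarray(l2s),
        lambda_n=np.asarray(lns),
        eigenratio=np.asarray(ratios),
    )


def band_power_series(rec: Recording, config: FTConfig = FTConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Total in-band power sum_i P_i per window on the *raw* (unscaled)
    signal -- the simple power feature the synchronization network is
    designed to improve on (artifacts inflate it; lambda_2 rejects them)."""
    raw_cfg = FTConfig(
        window=config.window, hop=config.hop, band=config.band, gamma=config.gamma,
        power_def=config.power_def, normalize=None, prefilter=config.prefilter,
    )
    times, totals = [], []
    plan = WindowPlan(raw_cfg.window, raw_cfg.hop)
    rec2 = _prepare(rec, raw_cfg)
    for t_k, win in segment(rec2, plan):
        frame = compute_spectrum(win, rec2.fs, power_def=raw_cfg.power_def)
        frame = band_restrict(frame, *raw_cfg.band)
        totals.append(float(band_power(frame).P.sum()))
        times.append(t_k)
    return np.asarray(times), np.asarray(totals)


__all__.append("band_power_series")
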