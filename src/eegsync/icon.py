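"""Coupling-function network inference by Fourier-basis regression (ICON).

Each channel's dynamics is modeled as

    dx_i/dt = sum_k a_k Q_k(x_i) + sum_{j != i} sum_{k,l} b_ij^{kl} P_k(x_i) P_l(x_j)

with {Q_k} = {P_k} a truncated trigonometric set (r terms, default 5:
1, sin(2*pi*u), cos(2*pi*u), sin(4*pi*u), cos(4*pi*u) on the state mapped
to u in [0, 1]).  Given the measured derivative of channel i over a
sliding window, the coefficients are a linear least-squares problem per
channel, solvable independently (hence trivially in parallel).  The
directed coupling strength from j to i is the root-sum-square of the
2-D coefficient block, alpha_ij = sqrt(sum_kl (b_ij^{kl})^2) -- by
Parseval, the RMS power of the estimated interaction function.  The
matrix J = [alpha_ij] is symmetrized to a weighted Laplacian whose
Fiedler eigenvalue tracks network synchronizability; an exponential
moving average smooths the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .io import Recording, WindowPlan, segment

__all__ = [
    "BasisSpec",
    "DesignProblem",
    "CouplingModel",
    "SynchronizabilitySeries",
    "estimate_derivative",
    "build_design",
    "solve_inverse",
    "coupling_strengths",
    "infer_network",
    "average_coupling",
    "synchronizability",
    "edge_ranking_auc",
]


@dataclass(frozen=True)
class BasisSpec:
    """Truncated trigonometric basis on the normalized state.

    Term 0 is the constant 1; terms (2m-1, 2m) are sin(2*pi*m*u),
    cos(2*pi*m*u) for m = 1, 2, ...  The state x in [-1, 1] is mapped to
    u = (x + 1)/2 in [0, 1], so for phase data scaled by pi the basis
    spans sin/cos of the phase itself.
    """

    r: int = 5

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"need at least one basis term, got r={self.r}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix: len(x) rows, r columns."""
        x = np.asarray(x, dtype=float)
        u = (x + 1.0) / 2.0
        cols = [np.ones_like(u)]
        m = 1
        while len(cols) < self.r:
            cols.append(np.sin(2 * np.pi * m * u))
            if len(cols) < self.r:
                cols.append(np.cos(2 * np.pi * m * u))
            m += 1
        return np.stack(cols, axis=-1)


@dataclass
class DesignProblem:
    """Per-channel linear inverse problem y ~ A z.

    ``column_map`` lists, per column, either ("self", k) or (j, k, l) for
    the product term P_k(x_i) P_l(x_j) of source channel j.
    """

    y: np.ndarray
    A: np.ndarray
    column_map: list[tuple]
    channel: int
    n_channels: int
    r: int

    @property
    def n_columns(self) -> int:
        return self.A.shape[1]


@dataclass
class CouplingModel:
    """Estimated self coefficients and directed coupling strengths.

    ``a[i]`` is channel i's r-vector of self coefficients; ``b[i, j]`` the
    r x r coefficient block of the coupling from j into i; ``alpha`` the
    strength matrix (rows = target, columns = source, zero diagonal).
    alpha need not be symmetric: coupling j->i can differ from i->j.
    """

    a: np.ndarray
    b: np.ndarray
    alpha: np.ndarray
    t_k: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.alpha < 0):
            raise ValueError("coupling strengths must be nonnegative")
        if np.any(np.diag(self.alpha) != 0):
            raise ValueError("alpha must have zero diagonal")


@dataclass
class SynchronizabilitySeries:
    times: np.ndarray
    lambda2: np.ndarray
    ema: np.ndarray
    beta: float


def estimate_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """First-order derivative: central differences in the interior,
    one-sided at the endpoints (units: signal per second)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples to estimate a derivative")
    return np.gradient(x, 1.0 / fs, axis=-1)


def build_design(
    window: np.ndarray,
    channel: int,
    basis: BasisSpec = BasisSpec(),
    y: np.ndarray | None = None,
    fs: float | None = None,
) -> DesignProblem:
    """Assemble the design matrix for one channel of one window.

    Columns: r self-basis columns Q_k(x_i), then for each source channel
    j != i (ascending) the r^2 products P_k(x_i) P_l(x_j) in (k, l)
    row-major order -- C = r + r^2 (N_ch - 1) columns in total.  ``y``
    defaults to the estimated derivative of channel i (requires ``fs``).
    """
    window = np.asarray(window, dtype=float)
    n_ch, M = window.shape
    r = basis.r
    C = r + r * r * (n_ch - 1)
    if M < C:
        raise ValueError(
            f"window of {M} samples is underdetermined for {C} coefficients; "
            f"use a longer window (need M >= {C})"
        )
    if y is None:
        if fs is None:
            raise ValueError("fs is required when y is not supplied")
        y = estimate_derivative(window[channel], fs)
    y = np.asarray(y, dtype=float)

    B = np.stack([basis.evaluate(window[j]) for j in range(n_ch)])  # n_ch x M x r
    cols = [B[channel]]  # self block
    column_map: list[tuple] = [("self", k) for k in range(r)]
    Pi = B[channel]
    for j in range(n_ch):
        if j == channel:
            continue
        # outer product per sample, flattened (k, l) row-major
        block = (Pi[:, :, None] * B[j][:, None, :]).reshape(M, r * r)
        cols.append(block)
        column_map.extend((j, k, l) for k in range(r) for l in range(r))
    A = np.concatenate(cols, axis=1)
    return DesignProblem(y=y, A=A, column_map=column_map, channel=channel,
                         n_channels=n_ch, r=r)


def solve_inverse(problem: DesignProblem, ridge: float = 0.0, rcond: float | None = None) -> np.ndarray:
    """Minimum-norm least-squares solution of y ~ A z.

    ``rcond`` is the relative singular-value cutoff of the SVD solve
    (None: machine precision).  A sliding-window design built from a
    trajectory that covers only part of the joint state space has a long
    tail of tiny singular values; inverting those amplifies derivative
    noise into spurious couplings, so noisy data wants a coarse cutoff
    (see :func:`infer_network`).  With ridge > 0 the normal equations
    (A'A + ridge*I) z = A'y are solved instead; if they are numerically
    singular the ridge is escalated to 1e-8 * trace(A'A)/C with a
    warning.
    """
    A, y = problem.A, problem.y
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValueError("design matrix or data vector contains non-finite entries")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if ridge == 0:
        z, *_ = np.linalg.lstsq(A, y, rcond=rcond)
        return z
    G = A.T @ A
    rhs = A.T @ y
    lam = ridge
    eye = np.eye(G.shape[0])
    try:
        return np.linalg.solve(G + lam * eye, rhs)
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(G) / G.shape[0]
        warnings.warn(f"normal matrix singular; ridge escalated to {lam:.3e}")
        return np.linalg.solve(G + lam * eye, rhs)


def coupling_strengths(z: np.ndarray, problem: DesignProblem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a coefficient vector into (a_self, b blocks, alpha row).

    Returns ``(a, b, alpha_row)`` where ``a`` is the r-vector of self
    coefficients, ``b`` is n_ch x r x r (zero block for the channel
    itself) and ``alpha_row[j]`` = Frobenius norm of block j.

    Coefficients are put in *canonical form* first: the product columns
    P_k(x_i) * P_0(x_j) do not depend on the source channel at all (the
    first basis function is the constant 1), so they duplicate the self
    columns and the least-squares solution is only determined up to
    shuffling weight between those copies.  The canonical form folds
    every b_ij^{k0} into a_k and zeroes the l=0 column of each block;
    this map annihilates exactly the null space of the design, so the
    canonical coefficients are identifiable (and coupling strengths are
    not inflated by self-dynamics leaking into constant products).
    """
    z = np.asarray(z, dtype=float)
    if z.size != len(problem.column_map):
        raise ValueError(
            f"coefficient vector length {z.size} does not match column map "
            f"({len(problem.column_map)})"
        )
    r, n_ch, i = problem.r, problem.n_channels, problem.channel
    a = z[:r].copy()
    b = np.zeros((n_ch, r, r))
    alpha_row = np.zeros(n_ch)
    pos = r
    for j in range(n_ch):
        if j == i:
            continue
        block = z[pos : pos + r * r].reshape(r, r).copy()
        a += block[:, 0]  # constant-source products belong to the self dynamics
        block[:, 0] = 0.0
        b[j] = block
        alpha_row[j] = np.sqrt(np.sum(block**2))
        pos += r * r
    return a, b, alpha_row


def infer_network(
    rec: Recording,
    window: float = 10.0,
    hop: float | None = None,
    basis: BasisSpec = BasisSpec(),
    ridge: float = 0.0,
    rcond: float = 1e-3,
    wrap_phase: bool = False,
    channel_order: Sequence[int] | None = None,
) -> list[CouplingModel]:
    """Estimate one directed coupling network per sliding window.

    Channels are estimated independently (the result does not depend on
    the order they are processed in).  ``wrap_phase=True`` treats the
    signal as an unwrapped phase: derivatives are taken on the raw
    signal, while the basis is evaluated on the phase wrapped to
    [-pi, pi) and scaled by 1/pi into the basis domain.  Otherwise the
    signal is assumed already normalized to [-1, 1].

    ``rcond`` truncates design singular values below ``rcond * s_max``:
    measured derivatives always carry noise and the window only covers
    part of the joint state space, so the poorly-observed directions are
    dropped rather than inverted.  Set rcond=None for the pure
    minimum-norm solution (appropriate for noiseless consistency
    checks).
    """
    models: list[CouplingModel] = []
    plan = WindowPlan(window, hop)
    n_ch, r = rec.n_channels, basis.r
    order = list(channel_order) if channel_order is not None else list(range(n_ch))
    if sorted(order) != list(range(n_ch)):
        raise ValueError("channel_order must be a permutation of all channels")
    for t_k, win in segment(rec, plan):
        derivs = estimate_derivative(win, rec.fs)
        if wrap_phase:
            states = np.mod(win + np.pi, 2 * np.pi) - np.pi
            states /= np.pi
        else:
            states = win
            if np.max(np.abs(states)) > 1 + 1e-9:
                warnings.warn(
                    "signal exceeds the [-1, 1] basis domain; normalize first"
                )
        a = np.zeros((n_ch, r))
        b = np.zeros((n_ch, n_ch, r, r))
        alpha = np.zeros((n_ch, n_ch))
        for i in order:
            prob = build_design(states, i, basis=basis, y=derivs[i])
            z = solve_inverse(prob, ridge=ridge, rcond=rcond)
            a_i, b_i, alpha_row = coupling_strengths(z, prob)
            a[i] = a_i
            b[i] = b_i
            alpha[i] = alpha_row
        models.append(CouplingModel(a=a, b=b, alpha=alpha, t_k=t_k))
    return models


def average_coupling(models: Sequence[CouplingModel]) -> np.ndarray:
    """Coupling-strength matrix from window-averaged coefficients.

    The per-window coefficient blocks b are averaged *before* taking the
    root-sum-square: alpha is a norm, so estimation noise inflates it
    additively in every window and would survive averaging of the
    per-window alphas, whereas the signed coefficients cancel.
    """
    if len(models) == 0:
        raise ValueError("no coupling models given")
    b_mean = np.mean([m.b for m in models], axis=0)
    alpha = np.sqrt(np.sum(b_mean**2, axis=(2, 3)))
    np.fill_diagonal(alpha, 0.0)
    return alpha


def synchronizability(
    models: Sequence[CouplingModel], beta: float = 0.2
) -> SynchronizabilitySeries:
    """Fiedler eigenvalue of each recovered network plus its EMA.

    The directed strength matrix is symmetrized, W = (J + J')/2, since a
    Fiedler eigenvalue needs a symmetric Laplacian; the EMA recursion is
    ema_t = beta*lambda2_t + (1-beta)*ema_{t-1} with ema_0 = lambda2_0.
    """
    if not 0 < beta <= 1:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if len(models) == 0:
        raise ValueError("no coupling models given")
    times = np.array([m.t_k for m in models])
    l2 = np.empty(len(models))
    for idx, m in enumerate(models):
        J = m.alpha
        if np.any(J < 0):
            raise ValueError("negative coupling strength")
        W = (J + J.T) / 2
        L = np.diag(W.sum(axis=1)) - W
        w = np.linalg.eigvalsh(L)
        l2[idx] = max(float(w[1]) if w.size > 1 else 0.0, 0.0)
    ema = np.empty_like(l2)
    ema[0] = l2[0]
    for t in range(1, l2.size):
        ema[t] = beta * l2[t] + (1 - beta) * ema[t - 1]
    return SynchronizabilitySeries(times=times, lambda2=l2, ema=ema, beta=beta)


def edge_ranking_auc(alpha: np.ndarray, true_adjacency: np.ndarray) -> float:
    """ROC AUC of ranking ordered pairs by recovered strength against the
    true edge set (off-diagonal entries), via the Mann-Whitney U identity."""
    alpha = np.asarray(alpha, dtype=float)
    K = np.asarray(true_adjacency, dtype=float)
    mask = ~np.eye(alpha.shape[0], dtype=bool)
    scores = alpha[mask]
    labels = K[mask] != 0
    if labels.all() or not labels.any():
        raise ValueError("need both edges and non-edges to compute an AUC")
    pos, neg = scores[labels], scores[~labels]
    u = _stats.mannwhitneyu(pos, neg, alternative="greater").statistic
    return float(u / (len(pos) * len(neg)))
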