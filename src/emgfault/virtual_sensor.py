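"""Virtual sensor: MCC channel weighting, TVARMA and Kalman reconstruction.

A degraded channel is replaced by a model-based substitute built from the
remaining clean channels.  The multichannel cross-correlation (MCC) matrix
holds, for each target channel, the percentage contribution of every other
channel's zero-lag correlation:

    p_xy = c_xy / sum_i c_xy,i   (x != y),   p_xx = 0,

with c the magnitude of the Pearson correlation.  The MCC-weighted sum of
the clean channels,

    u_t(n) = sum_{x != t} p_{x,t} y_x(n),

is the exogenous input of two reconstruction models:

* TVARMA - a time-varying ARMA(P=4, Q=2) whose coefficients are expanded on
  a finite basis f(n, m), m = 0..V:  a(i,n) = sum_m alpha(i,m) f(n,m) (and
  likewise b(j,n)), estimated by least squares on the clean history buffer.
* TVK - a Kalman state estimator with identity state matrices whose
  steady-state innovation gain M = P C' (C P C' + R)^-1 comes from the
  discrete algebraic Riccati equation; during contamination the measured
  (contaminated) samples are fed with inflated measurement noise R so the
  estimate leans on the MCC-driven prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import eval_legendre

from .detector import activation_trace
from .preprocess import PreprocessConfig
from .synthetic import EmgRecording

__all__ = [
    "MccMatrix",
    "BasisConfig",
    "TvarmaModel",
    "TvkModel",
    "cross_corr_coeff",
    "mcc_matrix",
    "mcc_input",
    "basis_f",
    "basis_matrix",
    "fit_tvarma",
    "predict_tvarma",
    "kalman_gain",
    "make_tvk",
    "tvk_estimate",
    "reconstruct_channel",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# multichannel cross-correlation
# ---------------------------------------------------------------------------

def cross_corr_coeff(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation at zero lag| in [0, 1].

    The absolute value makes contributions usable as nonnegative weights
    (an anticorrelated channel is as informative as a correlated one).
    A constant input has undefined correlation; defined as 0 and logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        log.warning("constant input to cross_corr_coeff; returning 0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return abs(r)


@dataclass(frozen=True)
class MccMatrix:
    """Percentage-contribution matrix; entry [x, t] weights source x for target t."""

    p: np.ndarray
    excluded: frozenset

    @property
    def n_channels(self) -> int:
        return self.p.shape[0]

    def column(self, target: int) -> np.ndarray:
        return self.p[:, target]


def mcc_matrix(signals: np.ndarray, excluded=()) -> MccMatrix:
    """Build the MCC matrix from a clean multichannel segment.

    ``signals`` is (n_samples x M).  Channels in ``excluded`` (0-based) are
    treated as contaminated: their correlation rows are zeroed and the
    per-target normalization is redone over the remaining sources, so the
    contributions toward every target still sum to one.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be samples x channels")
    M = signals.shape[1]
    excluded = frozenset(int(e) for e in excluded)
    available = [c for c in range(M) if c not in excluded]
    if len(available) < 2:
        raise ValueError("need at least 2 available channels")

    c = np.zeros((M, M))
    for x in range(M):
        for y in range(x + 1, M):
            c[x, y] = c[y, x] = cross_corr_coeff(signals[:, x], signals[:, y])
    c[list(excluded), :] = 0.0  # contaminated sources contribute nothing
    np.fill_diagonal(c, 0.0)

    p = np.zeros((M, M))
    for t in range(M):
        col = c[:, t].copy()
        col[t] = 0.0
        s = col.sum()
        if s > 0:
            p[:, t] = col / s
    return MccMatrix(p=p, excluded=excluded)


def mcc_input(mcc: MccMatrix, signals: np.ndarray, target: int) -> np.ndarray:
    """Exogenous input for ``target``: the MCC-weighted sum of the sources."""
    signals = np.asarray(signals, dtype=float)
    col = mcc.column(target)
    if col.sum() == 0:
        raise ValueError(f"target {target} has no available sources")
    return signals @ col


# ---------------------------------------------------------------------------
# basis expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisConfig:
    """Finite basis f(n, m) on time normalized to [-1, 1] over N samples."""

    N: int
    V: int = 2
    family: str = "legendre"

    def __post_init__(self) -> None:
        if self.V < 0 or self.N < 1:
            raise ValueError("need V >= 0 and N >= 1")
        if self.family not in ("legendre", "fourier", "time_power"):
            raise ValueError(f"unknown basis family {self.family!r}")


def _normalized_time(n, N: int):
    if N == 1:
        return np.zeros_like(np.asarray(n, dtype=float))
    return 2.0 * np.asarray(n, dtype=float) / (N - 1) - 1.0


def basis_f(n: int, m: int, cfg: BasisConfig) -> float:
    """Value of basis function m at sample n; f(n, 0) = 1 for every family."""
    if not 0 <= m <= cfg.V:
        raise ValueError("basis index out of range")
    if not 0 <= n < cfg.N:
        raise ValueError("sample index out of range")
    t = _normalized_time(n, cfg.N)
    if m == 0:
        return 1.0
    if cfg.family == "legendre":
        return float(eval_legendre(m, t))
    if cfg.family == "time_power":
        return float(t**m)
    k = (m + 1) // 2
    if m % 2:
        return float(np.sin(np.pi * k * t))
    return float(np.cos(np.pi * k * t))


def basis_matrix(cfg: BasisConfig) -> np.ndarray:
    """(N x (V+1)) matrix of basis values."""
    t = _normalized_time(np.arange(cfg.N), cfg.N)
    cols = [np.ones(cfg.N)]
    for m in range(1, cfg.V + 1):
        if cfg.family == "legendre":
            cols.append(eval_legendre(m, t))
        elif cfg.family == "time_power":
            cols.append(t**m)
        else:
            k = (m + 1) // 2
            cols.append(np.sin(np.pi * k * t) if m % 2 else np.cos(np.pi * k * t))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# TVARMA
# ---------------------------------------------------------------------------

@dataclass
class TvarmaModel:
    """Fitted basis-expanded time-varying ARMA model.

    ``fit_method`` records how the coefficients were estimated and decides
    how :func:`predict_tvarma` evaluates the mean prediction: "joint" runs
    the full output recursion; "two_stage" treats the AR part as residual
    dynamics (zero-mean in the mean prediction), so the reconstruction is
    the exogenous-input filter.
    """

    alpha: np.ndarray  # (P, V+1)
    beta: np.ndarray | None  # (Q, V+1) or None when Q = 0
    basis: BasisConfig
    resid_var: float
    fit_method: str = "joint"
    meta: dict = field(default_factory=dict)

    @property
    def P(self) -> int:
        return self.alpha.shape[0]

    @property
    def Q(self) -> int:
        return 0 if self.beta is None else self.beta.shape[0]


def _tvarma_regressors(
    y: np.ndarray, u: np.ndarray | None, F: np.ndarray, P: int, Q: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix of the linearized model; rows n = n0..N-1.

    Column order: (i=1..P) x (m=0..V) of y(n-i) f(n,m), then
    (j=1..Q) x (m=0..V) of u(n-j) f(n,m).
    """
    N = len(y)
    n0 = max(P, Q)
    rows = np.arange(n0, N)
    cols = []
    for i in range(1, P + 1):
        lagged = y[rows - i]
        for m in range(F.shape[1]):
            cols.append(lagged * F[rows, m])
    for j in range(1, Q + 1):
        lagged = u[rows - j]
        for m in range(F.shape[1]):
            cols.append(lagged * F[rows, m])
    return np.column_stack(cols), y[rows], n0


def _solve_ls(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    theta, _, rank, _ = np.linalg.lstsq(X, target, rcond=None)
    if rank < X.shape[1]:
        lam = 1e-8 * np.trace(X.T @ X) / X.shape[1]
        log.warning("rank-deficient TVARMA design; ridge fallback lambda=%.3e", lam)
        theta = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ target)
    return theta


def fit_tvarma(
    y_history: np.ndarray,
    u_history: np.ndarray | None = None,
    basis: BasisConfig | None = None,
    P: int = 4,
    Q: int = 2,
    method: str = "two_stage",
) -> TvarmaModel:
    """Least-squares fit of the expansion coefficients on clean history.

    The basis-expanded model is linear in alpha(i, m) and beta(j, m), so
    estimation is (ordinary) least squares; a rank-deficient design falls
    back to ridge with a logged regularization strength.  Two estimators:

    * ``method="joint"`` - one-step-ahead regression on y(n-i) f(n,m) and
      u(n-j) f(n,m) jointly.  This is the classical system-identification
      estimator and recovers the generating coefficients when the data come
      from the model, but on strongly autocorrelated signals it explains
      almost everything by the AR lags (which are unavailable once the
      channel is degraded), leaving a free-running prediction that ignores
      the cross-channel input.
    * ``method="two_stage"`` (default) - first regress y on the lagged
      exogenous input alone (beta), then fit the AR part on the residual
      (alpha).  The mean prediction is then input-driven, which is what a
      virtual sensor that has lost its own channel needs.
    """
    y = np.asarray(y_history, dtype=float)
    if Q > 0:
        if u_history is None:
            raise ValueError("u_history required when Q > 0")
        u = np.asarray(u_history, dtype=float)
        if u.shape != y.shape:
            raise ValueError("y and u histories must align")
    else:
        u = None
        method = "joint"  # no exogenous stage to separate
    if method not in ("joint", "two_stage"):
        raise ValueError("method must be 'joint' or 'two_stage'")
    if basis is None:
        basis = BasisConfig(N=len(y))
    if basis.N > len(y):
        raise ValueError("basis length exceeds the history")
    V1 = basis.V + 1
    if len(y) <= (P + Q) * V1 + max(P, Q):
        raise ValueError("history too short for the requested model order")

    F = basis_matrix(basis)
    if basis.N < len(y):  # periodic (per-window) basis over a longer history
        F = F[np.arange(len(y)) % basis.N]
    if method == "joint":
        X, target, _ = _tvarma_regressors(y, u, F, P, Q)
        theta = _solve_ls(X, target)
        resid = target - X @ theta
        alpha = theta[: P * V1].reshape(P, V1)
        beta = theta[P * V1 :].reshape(Q, V1) if Q > 0 else None
    else:
        n0 = max(P, Q)
        rows = np.arange(n0, len(y))
        Xe = np.column_stack(
            [u[rows - j] * F[rows, m] for j in range(1, Q + 1) for m in range(V1)]
        )
        theta_b = _solve_ls(Xe, y[rows])
        beta = theta_b.reshape(Q, V1)
        r = np.zeros(len(y))
        r[rows] = y[rows] - Xe @ theta_b
        Xa = np.column_stack(
            [r[rows - i] * F[rows, m] for i in range(1, P + 1) for m in range(V1)]
        )
        keep = rows >= n0 + P  # AR lags of r defined only past the burn-in
        theta_a = _solve_ls(Xa[keep], r[rows[keep]])
        alpha = theta_a.reshape(P, V1)
        resid = r[rows[keep]] - Xa[keep] @ theta_a
    return TvarmaModel(
        alpha=alpha,
        beta=beta,
        basis=basis,
        resid_var=float(np.mean(resid**2)),
        fit_method=method,
        meta={"n_history": len(y)},
    )


def predict_tvarma(
    model: TvarmaModel,
    u: np.ndarray | None,
    y_seed: np.ndarray | None = None,
    guard: float | None = None,
) -> np.ndarray:
    """Mean prediction (noise term = 0) over a reconstruction span.

    ``u`` covers the span (may be None when Q = 0); ``y_seed`` supplies the
    last P samples before the span.  A basis shorter than the span (the
    per-window convention) is tiled periodically; otherwise it is
    re-normalized to the span length.  For a "joint" model this is the full output recursion of the
    ARMA difference equation; for a "two_stage" model the AR part describes
    residual dynamics whose mean free response is zero, so the prediction is
    the exogenous-input part alone.  If the recursion exceeds the guard
    bound the output is clipped and the event logged.
    """
    P, Q = model.P, model.Q
    if Q > 0 and u is None:
        raise ValueError("u required for a model with Q > 0")
    N = len(u) if u is not None else None
    if N is None:
        raise ValueError("span length undefined; pass u")
    if y_seed is None:
        y_seed = np.zeros(P)
    y_seed = np.asarray(y_seed, dtype=float)
    if len(y_seed) < P:
        y_seed = np.concatenate([np.zeros(P - len(y_seed)), y_seed])

    Fb = basis_matrix(model.basis)
    if N == model.basis.N:
        F = Fb
    elif model.basis.N < N:
        F = Fb[np.arange(N) % model.basis.N]  # periodic per-window basis
    else:
        cfg = BasisConfig(N=N, V=model.basis.V, family=model.basis.family)
        F = basis_matrix(cfg)
    a = F @ model.alpha.T  # (N, P)
    b = F @ model.beta.T if Q > 0 else None  # (N, Q)
    if guard is None:
        scale = max(
            1.0,
            float(np.max(np.abs(y_seed))) if len(y_seed) else 0.0,
            float(np.max(np.abs(u))) if u is not None and len(u) else 0.0,
        )
        guard = 50.0 * scale

    ulist = u if u is not None else np.zeros(N)

    if model.fit_method == "two_stage":
        # exogenous filter: y(n) = sum_j b(j,n) u(n-j); vectorized over lags
        y = np.zeros(N)
        for j in range(1, Q + 1):
            lagged = np.concatenate([np.zeros(j), ulist[:-j]]) if j < N else np.zeros(N)
            y += b[:, j - 1] * lagged
        np.clip(y, -guard, guard, out=y)
        return y

    y = np.empty(N)
    clipped = False
    for n in range(N):
        acc = 0.0
        for i in range(1, P + 1):
            past = y[n - i] if n - i >= 0 else y_seed[n - i]
            acc += a[n, i - 1] * past
        for j in range(1, Q + 1):
            if n - j >= 0:
                acc += b[n, j - 1] * ulist[n - j]
        if acc > guard:
            acc, clipped = guard, True
        elif acc < -guard:
            acc, clipped = -guard, True
        y[n] = acc
    if clipped:
        log.warning("predict_tvarma: unstable recursion clipped at +-%.3g", guard)
    return y


# ---------------------------------------------------------------------------
# time-varying Kalman estimator
# ---------------------------------------------------------------------------

def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x.reshape(1, 1) if x.ndim == 0 else np.atleast_2d(x)


def kalman_gain(A, C, G, Qw, R, tol: float = 1e-10, max_iter: int = 100_000):
    """Steady-state Riccati solution and innovation gain.

    Iterates the discrete Riccati recursion

        P <- A (P - P C'(C P C' + R)^-1 C P) A' + G Qw G'

    to a fixed point (residual < ``tol``), with a direct DARE solver
    fallback, and returns (Pss, Mgain) with Mgain = Pss C'(C Pss C' + R)^-1.
    """
    A, C, G, Qw, R = map(_as_matrix, (A, C, G, Qw, R))
    if np.any(np.linalg.eigvalsh((R + R.T) / 2) <= 0):
        raise ValueError("R must be positive definite")
    Qn = G @ Qw @ G.T
    P = Qn.copy() + np.eye(A.shape[0]) * 1e-12
    converged = False
    for _ in range(max_iter):
        S = C @ P @ C.T + R
        K = np.linalg.solve(S.T, (P @ C.T).T).T  # P C' S^-1
        P_new = A @ (P - K @ C @ P) @ A.T + Qn
        if np.max(np.abs(P_new - P)) < tol:
            P = P_new
            converged = True
            break
        P = P_new
    if not converged:
        try:
            P = sla.solve_discrete_are(A.T, C.T, Qn, R)
        except Exception as exc:  # pragma: no cover - degenerate systems
            raise RuntimeError("Riccati iteration did not converge") from exc
    S = C @ P @ C.T + R
    Mgain = P @ C.T @ np.linalg.inv(S)
    return P, Mgain


@dataclass
class TvkModel:
    """Kalman estimator with (by default) identity state matrices."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    Qw: np.ndarray
    R: np.ndarray
    Pss: np.ndarray = None
    Mgain: np.ndarray = None

    def __post_init__(self) -> None:
        self.A, self.B, self.C, self.G, self.Qw, self.R = map(
            _as_matrix, (self.A, self.B, self.C, self.G, self.Qw, self.R)
        )
        if self.Pss is None or self.Mgain is None:
            self.Pss, self.Mgain = kalman_gain(self.A, self.C, self.G, self.Qw, self.R)


def make_tvk(qw: float, r: float) -> TvkModel:
    """Scalar identity-matrix estimator with the given noise covariances."""
    return TvkModel(A=1.0, B=1.0, C=1.0, G=1.0, Qw=qw, R=r)


def tvk_estimate(
    model: TvkModel,
    u: np.ndarray,
    y_meas: np.ndarray,
    x0: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Filtered estimate over a span, given the input and the measurements.

    Runs the one-step predictor
        xhat(n+1|n) = A xhat(n|n-1) + B u(n) + M (y(n) - C xhat(n|n-1))
    and returns the filtered output
        yhat(n|n) = C (I - M C) xhat(n|n-1) + C M y(n).
    """
    u = np.asarray(u, dtype=float)
    y_meas = np.asarray(y_meas, dtype=float)
    if u.shape != y_meas.shape:
        raise ValueError("u and y_meas must align")
    A, B, C, Mg = model.A, model.B, model.C, model.Mgain
    scalar = A.shape == (1, 1) and C.shape == (1, 1)
    n = len(u)
    out = np.empty(n)
    if scalar:
        a, b, c, m = float(A[0, 0]), float(B[0, 0]), float(C[0, 0]), float(Mg[0, 0])
        x = float(np.atleast_1d(x0)[0])
        one_minus = 1.0 - m * c
        for k in range(n):
            out[k] = c * one_minus * x + c * m * y_meas[k]
            x = a * x + b * u[k] + m * (y_meas[k] - c * x)
    else:
        dim = A.shape[0]
        x = np.zeros(dim) if np.isscalar(x0) else np.asarray(x0, dtype=float)
        I = np.eye(dim)
        for k in range(n):
            out[k] = float(C @ (I - Mg @ C) @ x + C @ Mg @ np.atleast_1d(y_meas[k]))
            x = A @ x + (B @ np.atleast_1d(u[k])).ravel() + (
                Mg @ np.atleast_1d(y_meas[k] - float(C @ x))
            ).ravel()
    return out


# ---------------------------------------------------------------------------
# channel reconstruction
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """Contiguous True runs of a boolean mask as (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def reconstruct_channel(
    recording: EmgRecording,
    flags: np.ndarray,
    method: str = "tvarma",
    cfg: PreprocessConfig | None = None,
    history: np.ndarray | None = None,
    basis_v: int = 2,
    basis_family: str = "legendre",
    P: int = 4,
    Q: int = 2,
    r_inflation: float = 10.0,
    qw_factor: float = 0.1,
    horizon_windows: int = 37,
    activate_frac: float = 0.70,
) -> tuple[EmgRecording, dict]:
    """Replace degraded spans of flagged channels with model output.

    ``flags`` is the (n_windows x n_channels) SFTD window-flag matrix on the
    sliding-window grid of ``cfg``.  The activation rule (>70% of the
    trailing 3 s of windows flagged) is streamed over the flags; samples of
    windows that are both flagged and covered by an active state are
    replaced.  Un-flagged samples and clean channels are untouched.

    ``history`` is the pre-degradation clean buffer (samples x channels,
    same preprocessing as the recording); it supplies the MCC matrix and the
    model fit.  When omitted, the leading 3 s of the recording are used.
    For the TVK method the MCC input is amplitude-calibrated by the
    least-squares gain of the history fit and its increments drive the
    identity-matrix state recursion.
    """
    if method not in ("tvarma", "tvk"):
        raise ValueError("method must be 'tvarma' or 'tvk'")
    if cfg is None:
        cfg = PreprocessConfig(fs=recording.fs)
    flags = np.asarray(flags, dtype=bool)
    n_windows, C = flags.shape
    if C != recording.n_channels:
        raise ValueError("flags channel count mismatch")
    W, S = cfg.window_samples, cfg.increment_samples

    active = activation_trace(flags, horizon_windows, activate_frac)
    degraded = [c for c in range(C) if active[:, c].any()]
    out = recording.copy()
    provenance = {"method": method, "channels": {}}
    if not degraded:
        return out, provenance
    if len(degraded) >= C:
        raise ValueError("all channels degraded simultaneously; no sources")

    if history is None:
        n_hist = min(int(3.0 * recording.fs), recording.n_samples)
        history = recording.signal[:n_hist]
    history = np.asarray(history, dtype=float)

    mcc = mcc_matrix(history, excluded=degraded)

    for c in degraded:
        y_hist = history[:, c]
        u_hist = mcc_input(mcc, history, c)
        # per-window basis: coefficients vary within a 300 ms window and
        # repeat across windows, matching the per-window model application
        basis = BasisConfig(
            N=min(cfg.window_samples, len(y_hist)), V=basis_v, family=basis_family
        )
        tv = fit_tvarma(y_hist, u_hist, basis, P=P, Q=Q)

        u_full = mcc_input(mcc, recording.signal, c)

        replace = np.zeros(recording.n_samples, dtype=bool)
        idx = np.flatnonzero(flags[:, c] & active[:, c])
        for i in idx:
            s = i * S
            replace[s : s + W] = True

        spans = _runs(replace)
        for a0, b0 in spans:
            if method == "tvarma":
                seed = recording.signal[max(0, a0 - P) : a0, c]
                out.signal[a0:b0, c] = predict_tvarma(
                    tv, u_full[a0:b0], y_seed=seed
                )
            else:
                lam_den = float(np.dot(u_hist, u_hist))
                lam = float(np.dot(y_hist, u_hist)) / lam_den if lam_den > 0 else 1.0
                r0 = float(np.mean((y_hist - lam * u_hist) ** 2))
                r0 = max(r0, 1e-12)
                model = make_tvk(qw=qw_factor * r0, r=r_inflation * r0)
                u_cal = lam * u_full[a0:b0]
                du = np.diff(u_cal, prepend=u_cal[0] if b0 > a0 else 0.0)
                out.signal[a0:b0, c] = tvk_estimate(
                    model, du, recording.signal[a0:b0, c], x0=u_cal[0] if b0 > a0 else 0.0
                )
        provenance["channels"][c] = {
            "spans": [(int(a0), int(b0)) for a0, b0 in spans],
            "n_windows_replaced": int(len(idx)),
            "resid_var": tv.resid_var,
        }
    out.meta["reconstruction"] = provenance
    return out, provenance
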