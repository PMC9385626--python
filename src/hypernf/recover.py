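"""Data-driven hypernetwork detection from phase time series.

Pipeline: extract unwrapped phases θ_k(t) and instantaneous frequencies
θ̇_k(t); smooth θ̇ with a first-order Savitzky–Golay filter (a moving
local-linear fit) to remove in-cycle ripple; regress θ̇_k onto a slowly
drifting baseline ``ω̂_k(t) = ω̂⁰ + ω̂¹t + ω̂²t²`` plus sine/cosine of candidate
resonance combinations with an L1 (LASSO) penalty; the surviving combinations
and their amplitudes ``H = √(C² + D²)`` are the recovered hypernetwork.

The drift columns are never penalized: they are projected out of both the
response and the oscillatory columns first (exact for an unpenalized block),
the LASSO selects the support, and an ordinary refit on the selected support
removes shrinkage bias so amplitudes are comparable across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.linear_model import LassoCV, Lasso

from .hypernet import ResonanceCombo, SlowPhaseModel
from .simulate import Trajectory

__all__ = [
    "PhaseSeries",
    "TripletFit",
    "NodeFit",
    "extract_phases",
    "smooth_frequency",
    "fit_triplet_model",
    "fit_slow_phase_field",
    "default_window",
]

#: Reference oscillation of the laboratory system whose 45 s smoothing window
#: the default transfers: base period 1/0.385 Hz ≈ 2.6 s, i.e. ≈ 17.3 cycles.
_REFERENCE_WINDOW_CYCLES = 45.0 * 0.385


def default_window(mean_omega: float) -> float:
    """Smoothing window in time units: ≈ 17.3 mean periods, the experimental
    45 s window rescaled by the ratio of mean oscillation periods."""
    return _REFERENCE_WINDOW_CYCLES * 2 * np.pi / abs(mean_omega)


@dataclass
class PhaseSeries:
    """Unwrapped phases and instantaneous frequencies on a uniform grid."""

    times: np.ndarray
    theta: np.ndarray  # (T, n), radians, unwrapped
    dtheta: np.ndarray  # (T, n), rad / time unit
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.theta.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def extract_phases(traj: Trajectory, min_amplitude: float = 1e-9) -> PhaseSeries:
    """Phases from complex states: continuous argument, unwrapped; frequencies
    by central differences.  A state passing through the origin has no phase
    and raises ``ValueError``."""
    Z = traj.states
    if np.iscomplexobj(Z):
        if np.any(np.abs(Z) < min_amplitude):
            raise ValueError("state passes through 0: phase undefined")
        theta = np.unwrap(np.angle(Z), axis=0)
    else:
        theta = np.asarray(Z, dtype=float)  # already phases
    dtheta = np.gradient(theta, traj.times, axis=0)
    return PhaseSeries(traj.times, theta, dtheta, dict(traj.metadata))


def smooth_frequency(
    ps: PhaseSeries, window: float, order: int = 1, passes: int = 1
) -> PhaseSeries:
    """Savitzky–Golay smoothing of θ̇ with *window* in time units.

    ``passes`` cascades the filter: each pass multiplies the stop-band
    attenuation (a single first-order pass suppresses a ripple of period p by
    only ~p/(πW)), while components much slower than the window pass through
    nearly unchanged.  Endpoints use scipy's polynomial extension.
    """
    dt = ps.dt
    wlen = int(round(window / dt))
    wlen += 1 - wlen % 2  # odd
    if wlen < 3:
        raise ValueError("window shorter than 3 samples")
    if order < 1:
        raise ValueError("order must be ≥ 1")
    if wlen > ps.theta.shape[0]:
        raise ValueError("window longer than the series")
    sm = ps.dtheta
    for _ in range(passes):
        sm = savgol_filter(sm, wlen, order, axis=0, mode="interp")
    meta = dict(ps.metadata)
    meta.update({"sg_window": window, "sg_order": order, "sg_passes": passes})
    return PhaseSeries(ps.times, ps.theta, sm, meta)


# ---------------------------------------------------------------------------
# LASSO triplet fit


@dataclass
class NodeFit:
    drift: np.ndarray  # ω̂⁰, ω̂¹, ω̂² (time centered at t=0 of the series)
    C: np.ndarray  # sine amplitudes per candidate
    D: np.ndarray  # cosine amplitudes per candidate
    H: np.ndarray  # √(C² + D²)
    support: np.ndarray  # boolean per candidate
    threshold: float
    resid_mad: float
    penalty: float


@dataclass
class TripletFit:
    candidates: list[ResonanceCombo]
    nodes: list[NodeFit]

    def support_pattern(self) -> dict[int, tuple[int, ...]]:
        """Per node (0-based), indices of candidate combos in the support."""
        return {
            k: tuple(int(i) for i in np.flatnonzero(nf.support))
            for k, nf in enumerate(self.nodes)
        }

    def to_json_dict(self) -> dict:
        return {
            "candidates": [list(c.coeffs) for c in self.candidates],
            "nodes": [
                {
                    "drift": [float(x) for x in nf.drift],
                    "C": [float(x) for x in nf.C],
                    "D": [float(x) for x in nf.D],
                    "H": [float(x) for x in nf.H],
                    "support": [bool(s) for s in nf.support],
                    "threshold": float(nf.threshold),
                    "penalty": float(nf.penalty),
                }
                for nf in self.nodes
            ],
        }


def _drift_basis(times: np.ndarray) -> np.ndarray:
    tc = times - times.mean()
    ts = tc / max(tc.max(), 1e-12)
    return np.column_stack([np.ones_like(ts), ts, ts**2])


def fit_triplet_model(
    ps: PhaseSeries,
    candidates: Sequence[ResonanceCombo],
    penalty: float | str = "cv",
    threshold: float | str = "3mad",
    rel_threshold: float = 0.1,
    min_amplitude: float = 1e-7,
    seed: int | None = 0,
) -> TripletFit:
    """Per node, L1-penalized regression of θ̇_k on drift + sin/cos columns.

    *penalty*: ``"cv"`` (5-fold cross-validation over a log grid) or a number.
    *threshold*: ``"3mad"`` declares a candidate in-support when its debiased
    amplitude H exceeds 3× the median absolute deviation of the fit residual;
    a float is used directly.  *rel_threshold* additionally floors the
    per-node threshold at that fraction of the node's largest amplitude,
    guarding against near-collinear candidates whose leakage amplitudes sit
    above a very clean residual (set 0 to disable).  *min_amplitude* (rad per
    unit time) is the smallest modulation treated as physical: on noise-free
    simulated data the residual can shrink to the integrator/differentiation
    floor, where arbitrarily small systematic leakage would otherwise count as
    support.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate combination")
    T = _drift_basis(ps.times)
    # QR projector for the unpenalized drift block
    Qd, _ = np.linalg.qr(T)

    def residualize(M):
        return M - Qd @ (Qd.T @ M)

    angles = np.stack([c.angle(ps.theta) for c in candidates], axis=1)  # (T, m)
    X = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)  # (T, 2m)
    Xr = residualize(X)
    norms = np.linalg.norm(Xr, axis=0) / np.sqrt(len(ps.times))
    if np.any(norms < 1e-12):
        bad = [candidates[i % len(candidates)].label() for i in np.flatnonzero(norms < 1e-12)]
        raise ValueError(f"rank-deficient design after drift removal: {sorted(set(bad))}")
    m = len(candidates)
    fits = []
    for k in range(ps.n):
        y = ps.dtheta[:, k]
        yr = residualize(y)
        if penalty == "cv":
            las = LassoCV(cv=5, fit_intercept=False, alphas=40, random_state=seed)
        else:
            las = Lasso(alpha=float(penalty), fit_intercept=False)
        las.fit(Xr, yr)
        sel = np.flatnonzero(las.coef_)
        # debias: ordinary refit of drift + selected columns
        Xsel = np.concatenate([T, X[:, sel]], axis=1)
        beta, *_ = np.linalg.lstsq(Xsel, y, rcond=None)
        coefs = np.zeros(2 * m)
        coefs[sel] = beta[T.shape[1]:]
        resid = y - Xsel @ beta
        C, D = coefs[:m], coefs[m:]
        H = np.hypot(C, D)
        mad = float(np.median(np.abs(resid - np.median(resid))))
        thr = 3.0 * mad if threshold == "3mad" else float(threshold)
        if rel_threshold and H.size:
            thr = max(thr, rel_threshold * float(H.max()))
        thr = max(thr, min_amplitude)
        fits.append(
            NodeFit(
                drift=beta[: T.shape[1]],
                C=C,
                D=D,
                H=H,
                support=H > thr,
                threshold=thr,
                resid_mad=mad,
                penalty=float(getattr(las, "alpha_", getattr(las, "alpha", np.nan))),
            )
        )
    return TripletFit(candidates=candidates, nodes=fits)


# ---------------------------------------------------------------------------
# slow-phase vector-field fit


def fit_slow_phase_field(
    times: np.ndarray,
    phi: np.ndarray,
    combos: Sequence[ResonanceCombo],
    l1_penalty: float | None = None,
) -> tuple[SlowPhaseModel, dict]:
    """Fit ``φ̇_i = Ω_i + Σ_j a_ij cos φ_j + b_ij sin φ_j`` to slow-phase data.

    φ̇ is estimated by central differences (one-sided at the endpoints).
    Returns the fitted field and a goodness-of-fit report (per-equation R²).
    """
    phi = np.asarray(phi, dtype=float)
    times = np.asarray(times, dtype=float)
    m = phi.shape[1]
    if len(combos) != m:
        raise ValueError("one combo per slow phase required")
    if phi.shape[0] < 5:
        raise ValueError("insufficient span for derivative estimation")
    dphi = np.gradient(phi, times, axis=0)
    X = np.concatenate([np.ones((phi.shape[0], 1)), np.cos(phi), np.sin(phi)], axis=1)
    drift = np.empty(m)
    a = np.empty((m, m))
    b = np.empty((m, m))
    r2 = np.empty(m)
    for i in range(m):
        y = dphi[:, i]
        if l1_penalty:
            las = Lasso(alpha=float(l1_penalty), fit_intercept=False)
            las.fit(X, y)
            beta = las.coef_
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        drift[i] = beta[0]
        a[i] = beta[1 : 1 + m]
        b[i] = beta[1 + m :]
        pred = X @ beta
        ss = np.sum((y - y.mean()) ** 2)
        r2[i] = 1.0 - np.sum((y - pred) ** 2) / ss if ss > 0 else 1.0
    model = SlowPhaseModel(combos=list(combos), drift=drift, a=a, b=b)
    return model, {"r2": r2}
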