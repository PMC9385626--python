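"""Numerical ground truth: Stuart–Landau networks, truncated normal forms,
phase and slow-phase models, microscopic Kuramoto ensembles and their
Ott–Antonsen mean fields, plus the built-in study fixtures.

All complex ODEs are integrated either with a fixed-step RK4 kernel (bit
deterministic, used for the long runs the recovery pipeline consumes) or with
an adaptive embedded Runge–Kutta method via :func:`scipy.integrate.solve_ivp`
(used when strict local error control matters, e.g. the order-of-accuracy
measurements).  The microscopic Kuramoto ensemble uses the mean-field form of
the drive, ``ψ̇ = ω + Im[(K z_k + K_inter Σ A_kℓ z_ℓ) e^{−iψ}]``, for O(N)
cost per step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .polycore import Polynomial, compile_poly
from .normalform import (
    CouplingFunction,
    NetworkSpec,
    NodeDynamics,
    NormalFormResult,
)
from .hypernet import PhaseModel, SlowPhaseModel

__all__ = [
    "Trajectory",
    "KuramotoEnsembleSpec",
    "simulate_network",
    "simulate_normal_form",
    "simulate_kuramoto",
    "simulate_oa",
    "sample_lorentzian",
    "kuramoto_to_network",
    "transform_states",
    "fixture",
    "FIXTURE_NAMES",
]


class BlowUpError(RuntimeError):
    """State magnitude exceeded the safety bound during integration."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class Trajectory:
    """Uniformly sampled solution: ``states[i, k]`` is node k at ``times[i]``.

    ``states`` is complex for oscillator states and real for phase models;
    ``metadata`` records the integrator settings and seed for reproducibility.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times contain NaN/Inf")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain NaN/Inf")

    @property
    def n(self) -> int:
        return self.states.shape[1]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        if np.iscomplexobj(self.states):
            cols = [self.times]
            header = ["t"]
            for k in range(self.n):
                cols += [self.states[:, k].real, self.states[:, k].imag]
                header += [f"re_z{k + 1}", f"im_z{k + 1}"]
        else:
            cols = [self.times] + [self.states[:, k] for k in range(self.n)]
            header = ["t"] + [f"x{k + 1}" for k in range(self.n)]
        np.savetxt(path, np.column_stack(cols), delimiter=",", header=",".join(header), comments="")
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.metadata, indent=2, default=str)
        )

    @staticmethod
    def from_csv(path: str | Path) -> "Trajectory":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        times = data[:, 0]
        if any(h.startswith("re_") for h in header):
            n = (data.shape[1] - 1) // 2
            states = data[:, 1::2] + 1j * data[:, 2::2]
            states = states[:, :n]
        else:
            states = data[:, 1:]
        return Trajectory(times, states, meta)


# ---------------------------------------------------------------------------
# polynomial-field RK4 kernel (shared by network and normal-form integration)


@njit(cache=True)
def _poly_rhs(z, gamma, beta, coefs, exps, node_of, out):
    n = z.shape[0]
    for k in range(n):
        out[k] = gamma[k] * z[k] + beta[k] * z[k] * z[k] * np.conj(z[k])
    for m in range(coefs.shape[0]):
        v = coefs[m]
        for j in range(n):
            a = exps[m, j, 0]
            b = exps[m, j, 1]
            if a:
                v *= z[j] ** a
            if b:
                v *= np.conj(z[j]) ** b
        out[node_of[m]] += v


@njit(cache=True)
def _rk4_poly(z0, gamma, beta, coefs, exps, node_of, dt, nsteps, store_every, bound):
    n = z0.shape[0]
    nstore = nsteps // store_every + 1
    out = np.empty((nstore, n), dtype=np.complex128)
    out[0] = z0
    z = z0.copy()
    k1 = np.empty(n, np.complex128)
    k2 = np.empty(n, np.complex128)
    k3 = np.empty(n, np.complex128)
    k4 = np.empty(n, np.complex128)
    tmp = np.empty(n, np.complex128)
    idx = 1
    for s in range(1, nsteps + 1):
        _poly_rhs(z, gamma, beta, coefs, exps, node_of, k1)
        for j in range(n):
            tmp[j] = z[j] + 0.5 * dt * k1[j]
        _poly_rhs(tmp, gamma, beta, coefs, exps, node_of, k2)
        for j in range(n):
            tmp[j] = z[j] + 0.5 * dt * k2[j]
        _poly_rhs(tmp, gamma, beta, coefs, exps, node_of, k3)
        for j in range(n):
            tmp[j] = z[j] + dt * k3[j]
        _poly_rhs(tmp, gamma, beta, coefs, exps, node_of, k4)
        for j in range(n):
            z[j] = z[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        for j in range(n):
            if not (abs(z[j]) <= bound):  # catches NaN as well
                return out[:idx], s
        if s % store_every == 0:
            out[idx] = z
            idx += 1
    return out[:idx], 0


def _field_arrays(n: int, polys: Sequence[Polynomial], subs, alpha_value: float):
    """Concatenate per-node polynomials into flat (coefs, exps, node_of) arrays."""
    coefs_l, exps_l, node_l = [], [], []
    for k, p in enumerate(polys):
        c, e = compile_poly(p, n, subs=subs, alpha_value=alpha_value)
        coefs_l.append(c)
        exps_l.append(e)
        node_l.append(np.full(len(c), k, dtype=np.int64))
    if coefs_l:
        return (
            np.concatenate(coefs_l),
            np.concatenate(exps_l) if sum(len(c) for c in coefs_l) else np.zeros((0, n, 2), np.int64),
            np.concatenate(node_l),
        )
    return np.zeros(0, np.complex128), np.zeros((0, n, 2), np.int64), np.zeros(0, np.int64)


def _coupling_field(net: NetworkSpec) -> list[Polynomial]:
    """Per-node coupling polynomial α Σ_ℓ A_kℓ h(z_k, z_ℓ), with the coupling
    strength carried as the formal α¹ marker (folded in numerically later)."""
    out = []
    for k in range(net.n):
        pk = Polynomial.zero()
        for ell in range(net.n):
            if net.adjacency[k, ell] != 0:
                pk = pk + net.coupling.instantiate(k, ell).scale(float(net.adjacency[k, ell]))
        out.append(pk.shift_alpha(1))
    return out


def default_ic(net_or_n, r: Sequence[float] | None = None, seed: int | None = None) -> np.ndarray:
    """On-attractor initial condition ``z_k(0) = r_k e^{iθ0_k}`` with seeded
    uniform initial phases (shortens transients; overridable everywhere)."""
    if isinstance(net_or_n, NetworkSpec):
        n = net_or_n.n
        r = np.array([max(d.r_star, 1e-3) for d in net_or_n.dynamics]) if r is None else np.asarray(r)
    else:
        n = int(net_or_n)
        r = np.ones(n) if r is None else np.asarray(r)
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0, 2 * np.pi, n)
    return r * np.exp(1j * theta0)


def _integrate_poly_field(
    n,
    gamma,
    beta,
    polys,
    subs,
    alpha_value,
    T,
    dt,
    ic,
    method,
    rtol,
    atol,
    save_dt,
    metadata,
):
    coefs, exps, node_of = _field_arrays(n, polys, subs, alpha_value)
    gamma = np.asarray(gamma, dtype=np.complex128)
    beta = np.asarray(beta, dtype=np.complex128)
    z0 = np.asarray(ic, dtype=np.complex128)
    if method == "rk4":
        store_every = max(1, int(round(save_dt / dt)))
        nsteps = int(round(T / dt))
        nsteps -= nsteps % store_every
        states, bad = _rk4_poly(
            z0, gamma, beta, coefs, exps, node_of, dt, nsteps, store_every, 1e3
        )
        if bad:
            raise BlowUpError(f"|z| exceeded bound at step {bad} (t≈{bad * dt:.3g})")
        times = np.arange(states.shape[0]) * (store_every * dt)
    elif method == "rk45":
        def rhs(t, y):
            z = y[:n] + 1j * y[n:]
            dz = np.empty(n, np.complex128)
            _poly_rhs(z, gamma, beta, coefs, exps, node_of, dz)
            return np.concatenate([dz.real, dz.imag])

        times = np.arange(0, T + 0.5 * save_dt, save_dt)
        sol = solve_ivp(
            rhs,
            (0.0, float(T)),
            np.concatenate([z0.real, z0.imag]),
            t_eval=times,
            rtol=rtol,
            atol=atol,
            method="RK45",
            max_step=np.inf,
        )
        if not sol.success:
            raise BlowUpError(sol.message)
        states = (sol.y[:n] + 1j * sol.y[n:]).T
        times = sol.t
    else:
        raise ValueError(f"unknown method {method!r}")
    return Trajectory(times, states, metadata)


def simulate_network(
    net: NetworkSpec,
    T: float,
    dt: float = 0.01,
    ic: Sequence[complex] | None = None,
    seed: int | None = None,
    method: str = "rk4",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    save_dt: float | None = None,
) -> Trajectory:
    """Integrate the original network ``ż_k = f_k(z_k) + α Σ A_kℓ h(z_k, z_ℓ)``."""
    import warnings

    if any(d.lambda_ <= 0 for d in net.dynamics):
        warnings.warn("λ ≤ 0 for some node: no sustained oscillation", stacklevel=2)
    if ic is None:
        ic = default_ic(net, seed=seed)
    if save_dt is None:
        save_dt = max(dt, 0.05)
    meta = {
        "model": "network",
        "n": net.n,
        "alpha": net.alpha,
        "method": method,
        "dt": dt,
        "save_dt": save_dt,
        "seed": seed,
        "coupling": net.coupling.serialize(),
    }
    return _integrate_poly_field(
        net.n,
        net.gammas,
        net.betas,
        _coupling_field(net),
        net.gamma_subs(),
        net.alpha,
        T,
        dt,
        ic,
        method,
        rtol,
        atol,
        save_dt,
        meta,
    )


def simulate_normal_form(
    model: NormalFormResult | PhaseModel | SlowPhaseModel,
    T: float,
    dt: float = 0.01,
    ic: Sequence[complex] | Sequence[float] | None = None,
    seed: int | None = None,
    method: str = "rk45",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    save_dt: float | None = None,
) -> Trajectory:
    """Integrate a reduced model: the truncated α² normal form (complex
    states), the averaged phase model, or the slow-phase field."""
    if save_dt is None:
        save_dt = max(dt, 0.05)
    if isinstance(model, NormalFormResult):
        net = model.net
        if ic is None:
            ic = default_ic(net, seed=seed)
        meta = {
            "model": "normal_form",
            "n": net.n,
            "alpha": net.alpha,
            "method": method,
            "dt": dt,
            "save_dt": save_dt,
            "seed": seed,
        }
        return _integrate_poly_field(
            net.n,
            net.gammas,
            net.betas,
            model.order2_field,
            net.gamma_subs(),
            net.alpha,
            T,
            dt,
            ic,
            method,
            rtol,
            atol,
            save_dt,
            meta,
        )
    if isinstance(model, PhaseModel):
        x0 = np.zeros(model.n) if ic is None else np.asarray(ic, dtype=float)
        rhs = lambda t, x: model.rhs(x)
        kind = "phase_model"
        n_out = model.n
    elif isinstance(model, SlowPhaseModel):
        x0 = np.zeros(model.m) if ic is None else np.asarray(ic, dtype=float)
        rhs = lambda t, x: model.rhs(x)
        kind = "slow_phase_model"
        n_out = model.m
    else:
        raise TypeError(f"cannot simulate {type(model).__name__}")
    times = np.arange(0, T + 0.5 * save_dt, save_dt)
    sol = solve_ivp(rhs, (0.0, float(T)), x0, t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise BlowUpError(sol.message)
    return Trajectory(sol.t, sol.y.T.copy(), {"model": kind, "n": n_out, "dt": save_dt})


def simulate_polynomial_field(
    net: NetworkSpec,
    fields: Sequence[Polynomial],
    T: float,
    dt: float = 0.01,
    ic: Sequence[complex] | None = None,
    seed: int | None = None,
    method: str = "rk45",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    save_dt: float | None = None,
) -> Trajectory:
    """Integrate ``u̇_k = f_k(u_k) + field_k(u)`` for an arbitrary per-node
    interaction polynomial (α markers folded in with ``net.alpha``)."""
    if ic is None:
        ic = default_ic(net, seed=seed)
    if save_dt is None:
        save_dt = max(dt, 0.05)
    meta = {"model": "polynomial_field", "n": net.n, "alpha": net.alpha, "method": method}
    return _integrate_poly_field(
        net.n,
        net.gammas,
        net.betas,
        fields,
        net.gamma_subs(),
        net.alpha,
        T,
        dt,
        ic,
        method,
        rtol,
        atol,
        save_dt,
        meta,
    )


def transform_states(nf: NormalFormResult, states: np.ndarray) -> np.ndarray:
    """Map original-coordinate states through ``u = w − αQ(w), w = z − αP(z)``
    (for comparing an original-network trajectory with the normal form)."""
    net = nf.net
    n = net.n
    subs = net.gamma_subs()
    Pc = [compile_poly(p, n, subs=subs) for p in nf.P]
    Qc = [compile_poly(q, n, subs=subs) for q in nf.Q]

    def eval_c(cmp_, Z):
        coefs, exps = cmp_
        out = np.zeros(Z.shape[0], np.complex128)
        for c, e in zip(coefs, exps):
            v = np.full(Z.shape[0], c, np.complex128)
            for j in range(n):
                if e[j, 0]:
                    v *= Z[:, j] ** e[j, 0]
                if e[j, 1]:
                    v *= np.conj(Z[:, j]) ** e[j, 1]
            out += v
        return out

    Z = np.asarray(states, dtype=np.complex128)
    W = Z - net.alpha * np.column_stack([eval_c(Pc[k], Z) for k in range(n)])
    U = W - net.alpha * np.column_stack([eval_c(Qc[k], W) for k in range(n)])
    return U


# ---------------------------------------------------------------------------
# Kuramoto ensembles and the Ott–Antonsen reduction


@dataclass(frozen=True)
class KuramotoEnsembleSpec:
    """Four (or more) subpopulations of N Kuramoto oscillators: all-to-all
    internal coupling μ, inter-subpopulation coupling α over ``adjacency``,
    Lorentzian frequency distributions ρ(ω; Ω_k, σ_k).

    ``mu`` and ``alpha`` are the *mean-field* coupling constants: the
    Ott–Antonsen order-parameter equation is ``ż_k = (iΩ_k + μ − σ_k) z_k −
    μ z_k|z_k|² + α Σ A_kℓ (z_ℓ − z̄_ℓ z_k²)`` with coherent radius
    ``√((μ−σ_k)/μ)``.  Because the textbook reduction of sine coupling K/N
    yields K/2 in the order-parameter equation, the microscopic simulation
    uses sine-coupling constants 2μ and 2α."""

    adjacency: np.ndarray
    N: int
    mu: float
    alpha: float
    Omegas: tuple[float, ...]
    sigmas: tuple[float, ...]
    seed: int = 0
    deterministic_quantiles: bool = True

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "Omegas", tuple(float(x) for x in self.Omegas))
        object.__setattr__(self, "sigmas", tuple(float(x) for x in self.sigmas))
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.Omegas):
            raise ValueError("adjacency/Omegas size mismatch")
        if len(self.sigmas) != len(self.Omegas):
            raise ValueError("sigmas/Omegas size mismatch")
        if self.N < 1:
            raise ValueError("N must be positive")

    @property
    def n_subpops(self) -> int:
        return len(self.Omegas)

    def r_fixed_points(self) -> np.ndarray:
        """Coherent-state radii √((μ−σ_k)/μ) of the uncoupled subpopulations
        (requires μ > σ_k; 0 otherwise)."""
        r = np.zeros(self.n_subpops)
        for k, s in enumerate(self.sigmas):
            if self.mu > s:
                r[k] = np.sqrt((self.mu - s) / self.mu)
        return r


def sample_lorentzian(
    Omega: float,
    sigma: float,
    N: int,
    seed: int | None = None,
    deterministic_quantiles: bool = False,
) -> np.ndarray:
    """Cauchy/Lorentzian frequencies: random draws, or the N mid-point
    quantiles (variance-free, reproducible without a seed)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if deterministic_quantiles:
        p = (np.arange(N) + 0.5) / N
        return Omega + sigma * np.tan(np.pi * (p - 0.5))
    rng = np.random.default_rng(seed)
    return Omega + sigma * rng.standard_cauchy(N)


@njit(cache=True)
def _kuramoto_heun(psi, omega, A, mu, alpha, dt, nsteps, store_every, nsub, N):
    nstore = nsteps // store_every + 1
    zs = np.empty((nstore, nsub), np.complex128)
    d1 = np.empty(psi.shape[0])
    d2 = np.empty(psi.shape[0])
    z = np.empty(nsub, np.complex128)
    drive = np.empty(nsub, np.complex128)

    def _fields(ps, z):
        for k in range(nsub):
            acc = 0.0 + 0.0j
            base = k * N
            for m in range(N):
                acc += np.exp(1j * ps[base + m])
            z[k] = acc / N

    def _deriv(ps, z, out):
        for k in range(nsub):
            drv = mu * z[k]
            for l in range(nsub):
                if A[k, l] != 0.0:
                    drv += alpha * A[k, l] * z[l]
            drive[k] = drv
        for k in range(nsub):
            base = k * N
            for m in range(N):
                e = np.exp(-1j * ps[base + m])
                out[base + m] = omega[base + m] + (drive[k] * e).imag

    _fields(psi, z)
    zs[0] = z
    idx = 1
    tmp = np.empty(psi.shape[0])
    for s in range(1, nsteps + 1):
        _fields(psi, z)
        _deriv(psi, z, d1)
        for i in range(psi.shape[0]):
            tmp[i] = psi[i] + dt * d1[i]
        _fields(tmp, z)
        _deriv(tmp, z, d2)
        for i in range(psi.shape[0]):
            psi[i] = psi[i] + 0.5 * dt * (d1[i] + d2[i])
        if s % store_every == 0:
            _fields(psi, z)
            zs[idx] = z
            idx += 1
    return zs[:idx], psi


def _kuramoto_ic(spec: KuramotoEnsembleSpec, omegas: np.ndarray) -> np.ndarray:
    """Near-stationary start: locked oscillators at their phase-locked angle,
    drifting ones uniform — avoids the long coherence transient."""
    rng = np.random.default_rng(spec.seed + 1)
    r_tgt = spec.r_fixed_points()
    K = 2.0 * spec.mu  # microscopic sine-coupling constant
    psi = np.empty(spec.n_subpops * spec.N)
    for k in range(spec.n_subpops):
        base = k * spec.N
        th0 = rng.uniform(0, 2 * np.pi)
        r = max(r_tgt[k], 1e-3)
        dev = omegas[base : base + spec.N] - spec.Omegas[k]
        lock = np.abs(dev) <= K * r
        psi[base : base + spec.N] = np.where(
            lock,
            th0 + np.arcsin(np.clip(dev / (K * r), -1, 1)),
            rng.uniform(0, 2 * np.pi, spec.N),
        )
    return psi


def simulate_kuramoto(
    spec: KuramotoEnsembleSpec,
    T: float,
    dt: float = 0.01,
    save_dt: float | None = None,
    ic: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Integrate the microscopic ensemble (Heun scheme, mean-field drive) and
    record the subpopulation order parameters ``z_k = (1/N) Σ e^{iψ}``.

    Returns ``(mean-field trajectory, final phases ψ)``."""
    if dt <= 0 or (save_dt is not None and save_dt < dt):
        raise ValueError("need 0 < dt ≤ save_dt")
    if save_dt is None:
        save_dt = max(dt, 0.1)
    omegas = np.concatenate(
        [
            sample_lorentzian(
                spec.Omegas[k],
                spec.sigmas[k],
                spec.N,
                seed=spec.seed + k,
                deterministic_quantiles=spec.deterministic_quantiles,
            )
            for k in range(spec.n_subpops)
        ]
    )
    psi0 = _kuramoto_ic(spec, omegas) if ic is None else np.asarray(ic, dtype=float).copy()
    store_every = max(1, int(round(save_dt / dt)))
    nsteps = int(round(T / dt))
    nsteps -= nsteps % store_every
    zs, psi = _kuramoto_heun(
        psi0.copy(),
        omegas,
        spec.adjacency,
        2.0 * spec.mu,
        2.0 * spec.alpha,
        dt,
        nsteps,
        store_every,
        spec.n_subpops,
        spec.N,
    )
    times = np.arange(zs.shape[0]) * (store_every * dt)
    meta = {
        "model": "kuramoto_microscopic",
        "N": spec.N,
        "mu": spec.mu,
        "alpha": spec.alpha,
        "dt": dt,
        "seed": spec.seed,
        "deterministic_quantiles": spec.deterministic_quantiles,
    }
    return Trajectory(times, zs, meta), psi


def kuramoto_to_network(
    spec: KuramotoEnsembleSpec, oa_convention: str = "textbook"
) -> NetworkSpec:
    """Ott–Antonsen mean-field network ``ż_k = γ_k z_k − μ z_k|z_k|² +
    α Σ A_kℓ h(z_k, z_ℓ)`` with ``γ_k = (μ − σ_k) + iΩ_k``.

    ``oa_convention`` selects the coupling function: ``"textbook"`` (default)
    is ``h = w − z²·conj(w)``, the sign the standard reduction of microscopic
    sine coupling produces (validated against the microscopic ensemble);
    ``"as-printed"`` is ``h = w + z²·conj(w)``.  α is read as a bifurcation
    parameter, so the linear coupling term is eliminated through the
    normal-form machinery (``linear_mode="eliminate"``).
    """
    dyn = [
        NodeDynamics(lambda_=spec.mu - s, omega=W, beta=-spec.mu)
        for W, s in zip(spec.Omegas, spec.sigmas)
    ]
    if oa_convention == "textbook":
        h = CouplingFunction.from_string("w - z^2*conj(w)", linear_mode="eliminate")
    elif oa_convention == "as-printed":
        h = CouplingFunction.from_string("w + z^2*conj(w)", linear_mode="eliminate")
    else:
        raise ValueError("oa_convention must be 'textbook' or 'as-printed'")
    return NetworkSpec(spec.adjacency, spec.alpha, dyn, h)


def simulate_oa(
    spec: KuramotoEnsembleSpec,
    T: float,
    dt: float = 0.05,
    ic: Sequence[complex] | None = None,
    seed: int | None = None,
    method: str = "rk45",
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the Ott–Antonsen mean-field ODEs for the order parameters."""
    net = kuramoto_to_network(spec)
    if ic is None:
        ic = default_ic(net, r=np.maximum(spec.r_fixed_points(), 1e-3), seed=spec.seed if seed is None else seed)
    traj = simulate_network(net, T, dt=min(dt, 0.01), ic=ic, method=method, rtol=rtol, atol=atol, save_dt=dt)
    traj.metadata.update({"model": "oa_mean_field", "mu": spec.mu})
    return traj


# ---------------------------------------------------------------------------
# fixtures


FIXTURE_NAMES = ("ring4", "path3", "ring6", "kuramoto4")


def _ring_adj(n: int) -> np.ndarray:
    A = np.zeros((n, n))
    for k in range(n):
        A[k, (k + 1) % n] = A[k, (k - 1) % n] = 1.0
    return A


def fixture(name: str, **overrides):
    """Built-in study configurations.

    ``ring4``     4 Stuart–Landau oscillators on an undirected ring,
                  ω = (1, 2.53, 1.56, 2.53), λ = 0.01, β = −1, α = 0.05,
                  h(z, w) = z·conj(w) + z²·conj(w).  Triplet detunings
                  ω₁−ω₂+ω₃ = ω₁−ω₄+ω₃ = 0.03; pairwise ω₂−ω₄ = 0.
    ``path3``     3-node path 1–2–3, ω = (1, 2.5, 1.5) (exact triplet
                  resonance), otherwise as ring4.
    ``ring6``     6-node ring, ω = (1, 2.5, 1.5, 2.5, 1.5, 2.5), otherwise as
                  ring4.
    ``kuramoto4`` 4 Kuramoto subpopulations on a ring: Ω = (2, 3, 4, 1),
                  μ = 0.5, σ_k = 0.48, α = 0.1, N = 10000.  The coherent radius
                  is √((μ−σ)/μ) = 0.2.

    Keyword overrides: ``alpha``, ``lambda_``, ``beta``, ``omegas``,
    ``coupling`` for the oscillator fixtures; ``N``, ``mu``, ``alpha``,
    ``sigmas``, ``Omegas``, ``seed`` for ``kuramoto4``.
    """
    if name == "kuramoto4":
        kw = dict(
            adjacency=_ring_adj(4),
            N=10_000,
            mu=0.5,
            alpha=0.1,
            Omegas=(2.0, 3.0, 4.0, 1.0),
            sigmas=(0.48,) * 4,
            seed=0,
        )
        kw.update(overrides)
        if np.isscalar(kw["sigmas"]):
            kw["sigmas"] = (float(kw["sigmas"]),) * 4
        return KuramotoEnsembleSpec(**kw)

    presets = {
        "ring4": (_ring_adj(4), (1.0, 2.53, 1.56, 2.53)),
        "path3": (np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float), (1.0, 2.5, 1.5)),
        "ring6": (_ring_adj(6), (1.0, 2.5, 1.5, 2.5, 1.5, 2.5)),
    }
    if name not in presets:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    A, omegas = presets[name]
    omegas = tuple(overrides.pop("omegas", omegas))
    lam = overrides.pop("lambda_", 0.01)
    beta = overrides.pop("beta", -1.0)
    alpha = overrides.pop("alpha", 0.05)
    coupling = overrides.pop("coupling", None)
    if coupling is None:
        coupling = CouplingFunction.from_string("z*conj(w) + z^2*conj(w)")
    elif isinstance(coupling, str):
        coupling = CouplingFunction.from_string(coupling)
    if overrides:
        raise TypeError(f"unknown overrides {sorted(overrides)}")
    dyn = [NodeDynamics(lam, w, beta) for w in omegas]
    return NetworkSpec(A, alpha, dyn, coupling)
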