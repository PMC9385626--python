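"""From normal form to emergent hypernetwork, phase model, and slow phases.

Averaging keeps only the order-α² monomials whose frequency combination
``Σ_j (a_j − b_j) ω_j − ω_k`` is small: everything else oscillates fast and is
discarded.  The survivors are hyperedges — genuine multi-node interactions —
and writing ``u_k = r_k e^{iθ_k}`` turns each into a sine/cosine coupling of an
integer phase combination (a triplet phase difference such as
``ϕ₁ = θ₁ − θ₂ + θ₃``).  Summing member phase equations gives the closed
slow-phase vector field ``φ̇_i = Ω_i + Σ_j a_ij cos φ_j + b_ij sin φ_j``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp

from .polycore import Monomial, Polynomial
from .normalform import NormalFormResult, nonres_residual

__all__ = [
    "ResonanceCombo",
    "Hyperedge",
    "Hypernetwork",
    "PhaseModel",
    "SlowPhaseModel",
    "resonance_filter",
    "build_hypernetwork",
    "phase_reduce",
    "slow_phase_reduce",
    "detect_resonances",
    "default_filter_tol",
]


def default_filter_tol(omegas) -> float:
    """Averaging tolerance: 5% of the mean frequency magnitude, wide enough to
    classify detunings of a few percent (the experimental regime) as slow."""
    return 0.05 * float(np.mean(np.abs(np.asarray(omegas, dtype=float))))


# ---------------------------------------------------------------------------
# resonance combinations


@dataclass(frozen=True)
class ResonanceCombo:
    """Integer phase combination ``Σ_j c_j θ_j`` with residual ``Σ_j c_j ω_j``.

    Stored in canonical sign (first nonzero coefficient positive); ``flip``
    records whether canonicalization negated the original combination.
    """

    coeffs: tuple[int, ...]
    residual: float
    tol: float

    @staticmethod
    def make(coeffs: Sequence[int], omegas: Sequence[float], tol: float) -> "ResonanceCombo":
        combo, _ = _canonical_sign(tuple(int(c) for c in coeffs))
        res = float(np.dot(combo, np.asarray(omegas, dtype=float)))
        return ResonanceCombo(combo, res, float(tol))

    @staticmethod
    def from_monomial(
        m: Monomial, target: int, omegas: Sequence[float], tol: float
    ) -> tuple["ResonanceCombo", int]:
        """Combo of the phase argument of monomial *m* in node *target*'s
        equation: ``c_j = (a_j − b_j) − δ_{j,target}``.  Returns the canonical
        combo and the sign ``s`` with ``Φ_monomial = s · (combo · θ)``."""
        n = len(omegas)
        c = [0] * n
        for j, a, b in m.exponents:
            c[j] += a - b
        c[target] -= 1
        combo, s = _canonical_sign(tuple(c))
        res = float(np.dot(combo, np.asarray(omegas, dtype=float)))
        return ResonanceCombo(combo, res, float(tol)), s

    @property
    def is_resonant(self) -> bool:
        return abs(self.residual) <= self.tol

    @property
    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coeffs)

    def angle(self, theta: np.ndarray) -> np.ndarray:
        """Evaluate ``Σ c_j θ_j`` on a phase array (… × n)."""
        return np.asarray(theta) @ np.asarray(self.coeffs, dtype=float)

    def label(self) -> str:
        parts = []
        for j, c in enumerate(self.coeffs):
            if c == 0:
                continue
            mag = "" if abs(c) == 1 else str(abs(c))
            parts.append(("+" if c > 0 and parts else "-" if c < 0 else "") + mag + f"th{j + 1}")
        return "".join(parts) if parts else "0"


def _canonical_sign(c: tuple[int, ...]) -> tuple[tuple[int, ...], int]:
    for x in c:
        if x > 0:
            return c, 1
        if x < 0:
            return tuple(-y for y in c), -1
    return c, 1


def detect_resonances(
    omegas: Sequence[float],
    tol: float,
    max_abs_coeff: int = 2,
    max_nodes_involved: int = 3,
) -> list[ResonanceCombo]:
    """Scan all primitive integer combinations with at most *max_nodes_involved*
    participating nodes and |c_j| ≤ *max_abs_coeff* for near-resonances."""
    if max_abs_coeff < 1:
        raise ValueError("max_abs_coeff must be ≥ 1")
    if max_nodes_involved not in (2, 3):
        raise ValueError("max_nodes_involved must be 2 or 3")
    omegas = np.asarray(omegas, dtype=float)
    n = len(omegas)
    seen: set[tuple[int, ...]] = set()
    out: list[ResonanceCombo] = []
    for r in range(2, max_nodes_involved + 1):
        for nodes in itertools.combinations(range(n), r):
            for vals in itertools.product(
                [v for v in range(-max_abs_coeff, max_abs_coeff + 1) if v != 0], repeat=r
            ):
                c = [0] * n
                for j, v in zip(nodes, vals):
                    c[j] = v
                g = math.gcd(*[abs(v) for v in vals])
                if g > 1:
                    c = [v // g for v in c]
                combo, _ = _canonical_sign(tuple(c))
                if combo in seen:
                    continue
                res = float(np.dot(combo, omegas))
                if abs(res) <= tol:
                    seen.add(combo)
                    out.append(ResonanceCombo(combo, res, float(tol)))
    out.sort(key=lambda rc: (abs(rc.residual), rc.coeffs))
    return out


# ---------------------------------------------------------------------------
# filtering and hyperedges


def resonance_filter(
    order2_field: Sequence[Polynomial],
    omegas: Sequence[float],
    tol: float | None = None,
) -> tuple[list[Polynomial], list[Polynomial]]:
    """Split each node's α² field into (kept, discarded) by the averaging rule:
    keep a monomial iff |Σ_j (a_j − b_j) ω_j − ω_k| ≤ tol."""
    if tol is None:
        tol = default_filter_tol(omegas)
    kept, discarded = [], []
    for k, poly in enumerate(order2_field):
        kk, dd = [], []
        for m in poly:
            (kk if abs(nonres_residual(m, k, omegas)) <= tol else dd).append(m)
        kept.append(Polynomial(kk))
        discarded.append(Polynomial(dd))
    return kept, discarded


@dataclass(frozen=True)
class Hyperedge:
    """A surviving resonant interaction monomial in node *target*'s equation.

    ``coefficient`` follows the worked-example convention: the equation reads
    ``u̇_k = f_k(u_k) − α² · coefficient · monomial`` (so the ring's η and ζ
    values are stored as printed, positive real parts).
    """

    target: int
    sources: tuple[int, ...]
    signs: tuple[int, ...]
    exponents: tuple[tuple[int, int, int], ...]
    coefficient: complex
    coefficient_sym: sp.Expr
    combo: ResonanceCombo
    combo_sign: int


@dataclass
class Hypernetwork:
    n: int
    alpha: float
    omegas: np.ndarray
    r_stars: np.ndarray
    hyperedges: list[Hyperedge] = field(default_factory=list)

    def combos(self) -> list[ResonanceCombo]:
        out: list[ResonanceCombo] = []
        for e in self.hyperedges:
            if not e.combo.is_zero and e.combo not in out:
                out.append(e.combo)
        return out

    def resonance_codimension(self) -> int:
        """Rank of the integer combo matrix of the emergent hypernetwork: the
        codimension of the resonance variety the frequencies sit on."""
        cs = [e.combo.coeffs for e in self.hyperedges if not e.combo.is_zero]
        if not cs:
            return 0
        return int(np.linalg.matrix_rank(np.array(sorted(set(cs)), dtype=float)))

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "alpha": self.alpha,
            "omegas": [float(w) for w in self.omegas],
            "hyperedges": [
                {
                    "target": e.target,
                    "sources": list(e.sources),
                    "signs": list(e.signs),
                    "exponents": [list(x) for x in e.exponents],
                    "coefficient": {"re": e.coefficient.real, "im": e.coefficient.imag},
                    "coefficient_sym": sp.sstr(sp.together(e.coefficient_sym)).replace(
                        "conjugate", "conj"
                    ),
                    "combo": list(e.combo.coeffs),
                    "combo_residual": e.combo.residual,
                }
                for e in self.hyperedges
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_json_dict(), indent=2, **kw)

    def edge_list_text(self) -> str:
        """Plain-text dump (one hyperedge per line) for quick plotting."""
        lines = []
        for e in self.hyperedges:
            srcs = ",".join(str(s + 1) for s in e.sources)
            lines.append(
                f"{e.target + 1} <- {{{srcs}}}  combo={e.combo.label()}  "
                f"|coef|={abs(e.coefficient):.6g}"
            )
        return "\n".join(lines)


def build_hypernetwork(
    nf: NormalFormResult,
    omegas: Sequence[float] | None = None,
    tol: float | None = None,
) -> Hypernetwork:
    """Aggregate the resonant α² monomials into hyperedges.

    Hyperedge identity is (target, exponent signature); coefficients from
    different G terms have already been summed in the assembled field.  Every
    hyperedge necessarily traces back to an admissible ¹G/²G walk because the
    field was built exclusively from them.
    """
    if omegas is None:
        omegas = nf.shifted_omegas
    if tol is None:
        tol = default_filter_tol(omegas)
    kept, _ = resonance_filter(nf.order2_field, omegas, tol)
    subs = nf.net.gamma_subs()
    hn = Hypernetwork(
        n=nf.net.n,
        alpha=nf.net.alpha,
        omegas=np.asarray(omegas, dtype=float),
        r_stars=np.array([d.r_star for d in nf.net.dynamics]),
    )
    for k, poly in enumerate(kept):
        for m in poly:
            combo, s = ResonanceCombo.from_monomial(m, k, omegas, tol)
            coef_sym = sp.together(-m.coeff)  # u̇ = f − α²·coef·monomial
            coef = complex(sp.sympify(coef_sym).subs(subs))
            sources = tuple(j for j in m.nodes if j != k) or (k,)
            signs = tuple(
                1 if (m.exponent(j)[0] - m.exponent(j)[1]) >= 0 else -1 for j in sources
            )
            hn.hyperedges.append(
                Hyperedge(
                    target=k,
                    sources=sources,
                    signs=signs,
                    exponents=m.exponents,
                    coefficient=coef,
                    coefficient_sym=coef_sym,
                    combo=combo,
                    combo_sign=s,
                )
            )
    return hn


# ---------------------------------------------------------------------------
# phase reduction


@dataclass(frozen=True)
class PhaseTerm:
    node: int
    combo: ResonanceCombo
    a_cos: float
    b_sin: float


@dataclass
class PhaseModel:
    """Averaged phase equations ``θ̇_k = ω_k + Σ [a cos(combo·θ) + b sin(combo·θ)]``.

    ``omegas`` are the effective frequencies: natural (possibly shifted)
    frequencies plus the constant contributions of zero-combo resonant terms
    (amplitude-dependent frequency corrections).  With no hyperedges the model
    is exactly ``θ̇_k = ω_k``.
    """

    omegas: np.ndarray
    r0: np.ndarray
    terms: list[PhaseTerm] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.omegas)

    def rhs(self, theta: np.ndarray) -> np.ndarray:
        dth = self.omegas.astype(float).copy()
        for t in self.terms:
            x = t.combo.angle(theta)
            dth[t.node] += t.a_cos * np.cos(x) + t.b_sin * np.sin(x)
        return dth

    def combos(self) -> list[ResonanceCombo]:
        out: list[ResonanceCombo] = []
        for t in self.terms:
            if t.combo not in out:
                out.append(t.combo)
        return out


def phase_reduce(hn: Hypernetwork, r0: float | Sequence[float] | None = None) -> PhaseModel:
    """Average the hypernetwork equations on the stationary orbit radii.

    Substituting ``u_k = r_k e^{iθ_k}`` into ``u̇_k = … − α² c m(u)`` and taking
    the imaginary part of ``u̇_k / u_k`` gives, per hyperedge,
    ``θ̇_k ∋ −α² R [Re(c) sin Φ + Im(c) cos Φ]`` with
    ``R = Π_j r_j^{a_j+b_j} / r_k`` and Φ the monomial's phase combination;
    for a quartic monomial with equal radii this is the familiar α²r₀³ scaling.
    Zero-combination terms contribute constant frequency shifts.
    """
    if r0 is None:
        r = hn.r_stars.astype(float)
    else:
        r = np.broadcast_to(np.asarray(r0, dtype=float), (hn.n,)).copy()
    if np.any(r <= 0):
        raise ValueError("r0 must be positive (node not oscillating)")
    omegas = hn.omegas.astype(float).copy()
    acc: dict[tuple[int, tuple[int, ...]], tuple[ResonanceCombo, float, float]] = {}
    a2 = hn.alpha**2
    for e in hn.hyperedges:
        if not e.combo.is_resonant:
            raise ValueError(f"non-resonant hyperedge present: {e}")
        R = 1.0
        for j, a, b in e.exponents:
            R *= r[j] ** (a + b)
        R /= r[e.target]
        c_field = -e.coefficient  # back to the signed field coefficient
        if e.combo.is_zero:
            omegas[e.target] += a2 * R * c_field.imag
            continue
        key = (e.target, e.combo.coeffs)
        combo, a_c, b_s = acc.get(key, (e.combo, 0.0, 0.0))
        a_c += a2 * R * c_field.imag
        b_s += a2 * R * e.combo_sign * c_field.real
        acc[key] = (combo, a_c, b_s)
    terms = [
        PhaseTerm(node=k, combo=combo, a_cos=a_c, b_sin=b_s)
        for (k, _), (combo, a_c, b_s) in sorted(acc.items())
    ]
    return PhaseModel(omegas=omegas, r0=r, terms=terms)


# ---------------------------------------------------------------------------
# slow-phase reduction


@dataclass
class SlowPhaseModel:
    """Closed vector field for the slow phases:
    ``φ̇_i = Ω_i + Σ_j a_ij cos φ_j + b_ij sin φ_j``."""

    combos: list[ResonanceCombo]
    drift: np.ndarray  # Ω_i = Σ_k c_k ω_k
    a: np.ndarray  # (i, j)
    b: np.ndarray  # (i, j)

    @property
    def m(self) -> int:
        return len(self.combos)

    def rhs(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        return self.drift + self.a @ np.cos(phi) + self.b @ np.sin(phi)


def slow_phase_reduce(pm: PhaseModel, combos: Sequence[ResonanceCombo]) -> SlowPhaseModel:
    """Differentiate the slow combinations through the phase model:
    ``φ̇_i = Σ_k c_ik θ̇_k``.  Every coupling term's combination must be one of
    the supplied slow phases for the field to close."""
    combos = list(combos)
    n = pm.n
    for c in combos:
        if len(c.coeffs) != n:
            raise ValueError("combo dimension does not match phase model")
    index = {c.coeffs: i for i, c in enumerate(combos)}
    drift = np.array([float(np.dot(c.coeffs, pm.omegas)) for c in combos])
    a = np.zeros((len(combos), len(combos)))
    b = np.zeros((len(combos), len(combos)))
    for t in pm.terms:
        j = index.get(t.combo.coeffs)
        if j is None:
            raise ValueError(
                f"phase-model term with combination {t.combo.label()} is not among "
                "the supplied slow phases; the slow field does not close"
            )
        for i, c in enumerate(combos):
            w = c.coeffs[t.node]
            if w:
                a[i, j] += w * t.a_cos
                b[i, j] += w * t.b_sin
    return SlowPhaseModel(combos=combos, drift=drift, a=a, b=b)
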