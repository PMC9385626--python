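"""Normal-form reduction of coupled oscillator networks near a Hopf bifurcation.

The network

.. math::

    \\dot z_k = \\gamma_k z_k + \\beta_k z_k |z_k|^2
               + \\alpha \\sum_\\ell A_{k\\ell}\\, h(z_k, z_\\ell),
    \\qquad \\gamma_k = \\lambda + i\\omega_k,

with polynomial pairwise coupling ``h`` is brought to a normal form by two
near-identity transformations ``w = z - αP(z)`` and ``u = w - αQ(w)``.  The
first removes the order-α coupling terms whose frequency combination is
non-resonant, via the replacement rule that divides each coupling monomial by
its homological denominator; the second removes the order-α terms that the
cubic Hopf term regenerates.  What survives at order α² is a sum of emergent
three-node coupling functions ¹G and ²G whose resonant monomials constitute the
emergent hypernetwork.

Sign convention: expanding the transformed vector field gives the α² field
``-α² Σ_{ℓ,p} [A_kℓ A_kp ¹G_k^{ℓp} + A_kℓ A_ℓp ²G_k^{ℓp}]`` — both families
carry a minus sign (``metadata["sign_convention"] = "all-minus"``); the
convention is validated by the trajectory order-of-accuracy test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import sympy as sp

from .polycore import Monomial, Polynomial, gamma_symbol

__all__ = [
    "NodeDynamics",
    "CouplingFunction",
    "NetworkSpec",
    "GTerm",
    "LedgerEntry",
    "NormalFormResult",
    "ResonantMonomialError",
    "ForbiddenTermError",
    "NormalFormError",
    "nonres_residual",
    "homological_denominator",
    "tilde_coupling",
    "build_first_transform",
    "compute_G",
    "assemble_order2",
    "count_interaction_terms",
    "residual_order1",
    "build_second_transform",
    "shift_frequencies",
    "normal_form",
    "verify_alpha1_cancellation",
]


# ---------------------------------------------------------------------------
# errors


class NormalFormError(Exception):
    """Aggregate failure of the normal-form construction."""


class ResonantMonomialError(NormalFormError):
    """A coupling monomial cannot be eliminated: its frequency combination
    (the imaginary part of the homological denominator at λ = 0) vanishes
    within tolerance."""

    def __init__(self, monomial: Monomial, residual: float, context: str = ""):
        self.monomial = monomial
        self.residual = residual
        self.context = context
        super().__init__(
            f"resonant monomial {monomial.exponents} (residual {residual:.3g})"
            + (f" in {context}" if context else "")
        )


class ForbiddenTermError(NormalFormError):
    """Requested emergent coupling term whose generating walk does not exist
    in the original graph (e.g. ²G needs the path k←ℓ←p)."""


class PairingAmbiguityError(NormalFormError):
    """Eigenvalue-to-node pairing is ambiguous (degenerate frequencies)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class NodeDynamics:
    """Isolated Hopf normal form of one node: ``ż = γz + βz|z|²``.

    ``lambda_`` is the bifurcation parameter (λ > 0: stable limit cycle for
    Re β < 0), ``omega`` the natural frequency in radians per unit time, and
    ``beta`` the cubic coefficient (−1 in the reference configurations).
    """

    lambda_: float
    omega: float
    beta: complex = -1.0 + 0.0j

    def __post_init__(self):
        if self.beta == 0:
            raise ValueError("beta must be nonzero")

    @property
    def gamma(self) -> complex:
        return complex(self.lambda_, self.omega)

    @property
    def r_star(self) -> float:
        """Stationary orbit radius of the isolated oscillator (√λ for β=−1)."""
        rb = complex(self.beta).real
        if self.lambda_ <= 0 or rb >= 0:
            return 0.0
        return float(np.sqrt(-self.lambda_ / rb))


@dataclass(frozen=True)
class CouplingFunction:
    """Pairwise coupling ``h(z, w)``: a polynomial in slot 0 (the receiving
    node's state ``z``) and slot 1 (the neighbour's state ``w``) and their
    conjugates, with zero constant term.

    ``linear_mode`` controls the treatment of degree-1 monomials:

    * ``"shift"`` (default) — the complex-linear part ``DH(0)`` is kept in the
      equation and absorbed into shifted natural frequencies; only the
      nonlinear monomials are eliminated.
    * ``"eliminate"`` — linear monomials run through the same replacement rule
      as everything else, provided they are non-resonant.  This is how the
      Ott–Antonsen mean-field coupling ``αz_ℓ + αz̄_ℓ z_k²`` is handled when α
      is read as a bifurcation parameter.
    """

    poly: Polynomial
    linear_mode: Literal["shift", "eliminate"] = "shift"

    def __post_init__(self):
        for m in self.poly:
            if m.degree == 0:
                raise ValueError("coupling function must have vanishing constant term")
            bad = [j for j in m.nodes if j not in (0, 1)]
            if bad:
                raise ValueError(f"coupling polynomial uses slots {bad}; only 0 and 1 allowed")

    @staticmethod
    def from_string(text: str, linear_mode: Literal["shift", "eliminate"] = "shift") -> "CouplingFunction":
        """Parse e.g. ``"z*conj(w) + z^2*conj(w)"`` (slot names ``z``/``w``)."""
        src = text.replace("z", "s1").replace("w", "s2")
        return CouplingFunction(Polynomial.parse(src, prefix="s"), linear_mode)

    def serialize(self) -> str:
        return self.poly.serialize(prefix="s").replace("s1", "z").replace("s2", "w")

    @property
    def nonlinear(self) -> Polynomial:
        return Polynomial(m for m in self.poly if m.degree >= 2)

    @property
    def linear(self) -> Polynomial:
        return Polynomial(m for m in self.poly if m.degree == 1)

    def linear_coeffs(self) -> tuple[sp.Expr, sp.Expr, sp.Expr, sp.Expr]:
        """Coefficients (c_z, c_z̄, c_w, c_w̄) of the degree-1 monomials."""
        return (
            self.poly.coeff_of({0: (1, 0)}),
            self.poly.coeff_of({0: (0, 1)}),
            self.poly.coeff_of({1: (1, 0)}),
            self.poly.coeff_of({1: (0, 1)}),
        )

    def instantiate(self, k: int, ell: int, nonlinear_only: bool = False) -> Polynomial:
        """Place the coupling on the node pair (k, ℓ): slot 0 → k, slot 1 → ℓ."""
        if k == ell:
            raise ValueError("coupling requires distinct nodes")
        p = self.nonlinear if nonlinear_only else self.poly
        return p.relabel({0: k, 1: ell})

    def eliminable(self) -> Polynomial:
        """The part of h that the first transformation removes."""
        return self.nonlinear if self.linear_mode == "shift" else self.poly


@dataclass(frozen=True)
class NetworkSpec:
    """A coupled oscillator network: adjacency, coupling strength α, per-node
    Hopf parameters and a shared coupling function."""

    adjacency: np.ndarray
    alpha: float
    dynamics: tuple[NodeDynamics, ...]
    coupling: CouplingFunction

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "dynamics", tuple(self.dynamics))
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency entries must be finite")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops (nonzero adjacency diagonal) are not supported")
        if len(self.dynamics) != A.shape[0]:
            raise ValueError("need one NodeDynamics per node")
        if self.alpha < 0:
            raise ValueError("alpha must be ≥ 0")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def omegas(self) -> np.ndarray:
        return np.array([d.omega for d in self.dynamics])

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([d.lambda_ for d in self.dynamics])

    @property
    def gammas(self) -> np.ndarray:
        return np.array([d.gamma for d in self.dynamics])

    @property
    def betas(self) -> np.ndarray:
        return np.array([complex(d.beta) for d in self.dynamics])

    def gamma_subs(self) -> dict[sp.Symbol, sp.Expr]:
        """Numeric substitution map for the symbolic γ coefficients."""
        return {
            gamma_symbol(k): sp.Float(d.lambda_) + sp.I * sp.Float(d.omega)
            for k, d in enumerate(self.dynamics)
        }

    def gamma_subs_exact(self) -> dict[sp.Symbol, sp.Expr]:
        """Exact-rational substitution map (for symbolic cancellation checks)."""
        return {
            gamma_symbol(k): sp.nsimplify(d.lambda_, rational=True)
            + sp.I * sp.nsimplify(d.omega, rational=True)
            for k, d in enumerate(self.dynamics)
        }


@dataclass(frozen=True)
class GTerm:
    """One emergent three-node coupling polynomial ¹G or ²G for target node k
    generated through the ordered pair (ℓ, p)."""

    kind: Literal[1, 2]
    target: int
    pair: tuple[int, int]
    poly: Polynomial
    n_products: int  # elementary (h̃-derivative monomial × h monomial) products


@dataclass(frozen=True)
class LedgerEntry:
    monomial: Monomial
    node: int
    action: str  # "eliminated" | "eliminated-residual" | "retained-resonant" | "discarded-fast"
    denominator: sp.Expr | None
    residual: float


@dataclass
class NormalFormResult:
    """Everything the two transformations produce: the transformation
    polynomials P and Q, the emergent G terms, the order-α² interaction field
    (α markers attached; sign included so that ``u̇_k = f_k(u_k) + field_k``),
    and a ledger recording the fate of every monomial."""

    net: NetworkSpec
    P: list[Polynomial]
    Q: list[Polynomial]
    g_terms: list[GTerm]
    order2_field: list[Polynomial]
    ledger: list[LedgerEntry]
    shifted_omegas: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def poly_entry(p: Polynomial) -> list[dict]:
            return [
                {
                    "exponents": [list(e) for e in m.exponents],
                    "alpha_order": m.alpha,
                    "coefficient": sp.sstr(sp.together(m.coeff)).replace("conjugate", "conj"),
                }
                for m in p
            ]

        return {
            "n": self.net.n,
            "alpha": self.net.alpha,
            "metadata": dict(self.metadata),
            "shifted_omegas": [float(w) for w in self.shifted_omegas],
            "P": [poly_entry(p) for p in self.P],
            "Q": [poly_entry(q) for q in self.Q],
            "order2_field": [poly_entry(p) for p in self.order2_field],
            "ledger": [
                {
                    "node": e.node,
                    "action": e.action,
                    "exponents": [list(x) for x in e.monomial.exponents],
                    "denominator": None if e.denominator is None else sp.sstr(e.denominator).replace("conjugate", "conj"),
                    "residual": float(e.residual),
                }
                for e in self.ledger
            ],
        }


# ---------------------------------------------------------------------------
# resonance arithmetic


def nonres_residual(m: Monomial, target: int, omegas: Sequence[float]) -> float:
    """Frequency combination Σ_j (a_j − b_j) ω_j − ω_target.

    This is the imaginary part of the homological denominator at λ = 0; the
    monomial is eliminable iff it is nonzero (the non-resonance condition).
    """
    omegas = np.asarray(omegas, dtype=float)
    s = -omegas[target]
    for j, a, b in m.exponents:
        s += (a - b) * omegas[j]
    return float(s)


def homological_denominator(m: Monomial, target: int, gammas) -> sp.Expr | complex:
    """Generalized homological denominator Σ_j (a_j γ_j + b_j γ̄_j) − γ_target.

    *gammas* may be a complex vector (numeric result) or a sequence of sympy
    expressions (symbolic result).  For a pairwise monomial on (k, ℓ) this is
    the replacement-rule denominator (d₁−1)γ_k + d₂γ̄_k + d₃γ_ℓ + d₄γ̄_ℓ.
    """
    symbolic = any(isinstance(g, sp.Basic) for g in gammas)
    if symbolic:
        s: sp.Expr = -sp.sympify(gammas[target])
        for j, a, b in m.exponents:
            g = sp.sympify(gammas[j])
            s += a * g + b * sp.conjugate(g)
        return sp.expand(s)
    s = -complex(gammas[target])
    for j, a, b in m.exponents:
        g = complex(gammas[j])
        s += a * g + b * g.conjugate()
    return s


def _gamma_syms(n: int) -> list[sp.Symbol]:
    return [gamma_symbol(k) for k in range(n)]


def _c_expr(c: complex) -> sp.Expr:
    """Exact-rational sympy form of a complex constant (β's, adjacency weights)."""
    c = complex(c)
    return sp.nsimplify(c.real, rational=True) + sp.I * sp.nsimplify(c.imag, rational=True)


def tilde_coupling(
    h: CouplingFunction, k: int, ell: int, omegas: Sequence[float], tol: float
) -> Polynomial:
    """Apply the replacement rule to the eliminable part of h on edge (k, ℓ).

    Each monomial is divided by its symbolic homological denominator (in the
    γ symbols); a monomial whose ω-residual vanishes within *tol* raises
    :class:`ResonantMonomialError` — it cannot be removed and must be retained.
    """
    gsyms = _gamma_syms(max(k, ell) + 1)
    inst = h.eliminable().relabel({0: k, 1: ell})
    out = []
    for m in inst:
        res = nonres_residual(m, k, _pad_omegas(omegas, max(k, ell) + 1))
        if abs(res) <= tol:
            raise ResonantMonomialError(m, res, context=f"edge ({k + 1},{ell + 1})")
        den = homological_denominator(m, k, gsyms)
        out.append(Monomial(m.exponents, m.coeff / den, m.alpha))
    return Polynomial(out)


def _pad_omegas(omegas, n):
    w = np.asarray(omegas, dtype=float)
    if len(w) >= n:
        return w
    raise ValueError("omegas vector shorter than highest node index")


def default_elimination_tol(omegas) -> float:
    return 1e-6 * float(np.max(np.abs(omegas)))


# ---------------------------------------------------------------------------
# first transformation


def build_first_transform(net: NetworkSpec, tol: float | None = None) -> list[Polynomial]:
    """P_k = Σ_ℓ A_kℓ h̃_kℓ(z_k, z_ℓ): the generator of ``w = z − αP``.

    Resonance failures are aggregated across edges into one report.
    """
    if tol is None:
        tol = default_elimination_tol(net.omegas)
    P: list[Polynomial] = []
    failures: list[str] = []
    for k in range(net.n):
        pk = Polynomial.zero()
        for ell in range(net.n):
            if net.adjacency[k, ell] == 0:
                continue
            try:
                pk = pk + tilde_coupling(net.coupling, k, ell, net.omegas, tol).scale(
                    _c_expr(net.adjacency[k, ell])
                )
            except ResonantMonomialError as e:
                failures.append(str(e))
        P.append(pk)
    if failures:
        raise NormalFormError(
            "network non-resonance conditions violated:\n  " + "\n  ".join(failures)
        )
    return P


# ---------------------------------------------------------------------------
# emergent coupling functions (order α²)


def compute_G(
    net: NetworkSpec,
    k: int,
    ell: int,
    p: int,
    kind: Literal[1, 2],
    tol: float | None = None,
    degree_cut: int | None = None,
) -> GTerm:
    """The emergent three-node coupling polynomial ¹G_k^{ℓp} or ²G_k^{ℓp}.

    ¹G pairs the h̃-derivative w.r.t. the *target* with ``h(u_k, u_p)`` and
    requires both ℓ and p to be in-neighbours of k; ²G pairs the derivative
    w.r.t. the *mediator* ℓ with ``h(u_ℓ, u_p)`` and requires the walk k←ℓ←p.
    A combination without its generating walk is forbidden and raises
    :class:`ForbiddenTermError`.
    """
    if tol is None:
        tol = default_elimination_tol(net.omegas)
    A = net.adjacency
    if kind == 1:
        if A[k, ell] == 0 or A[k, p] == 0:
            raise ForbiddenTermError(
                f"1G_{k + 1}^({ell + 1},{p + 1}) forbidden: needs edges k←ℓ and k←p"
            )
    elif kind == 2:
        if A[k, ell] == 0 or A[ell, p] == 0:
            raise ForbiddenTermError(
                f"2G_{k + 1}^({ell + 1},{p + 1}) forbidden: needs the walk k←ℓ←p"
            )
    else:
        raise ValueError("kind must be 1 or 2")

    ht = tilde_coupling(net.coupling, k, ell, net.omegas, tol)
    diff_node = k if kind == 1 else ell
    base = k if kind == 1 else ell
    h_inst = net.coupling.instantiate(base, p)
    d_plain = ht.diff(diff_node, wrt_conjugate=False)
    d_conj = ht.diff(diff_node, wrt_conjugate=True)
    n_products = (len(d_plain) + len(d_conj)) * len(h_inst)
    poly = d_plain * h_inst + d_conj * h_inst.conj()
    if degree_cut is not None:
        poly = poly.truncate(degree_cut=degree_cut)
    return GTerm(kind, k, (ell, p), poly, n_products)


def assemble_order2(
    net: NetworkSpec,
    tol: float | None = None,
    degree_cut: int = 4,
    return_g_terms: bool = False,
):
    """Order-α² interaction field per node (sign and α² marker included):

    ``field_k = -α² Σ_{ℓ,p} [A_kℓ A_kp ¹G_k^{ℓp} + A_kℓ A_ℓp ²G_k^{ℓp}]``,
    truncated at *degree_cut*.
    """
    A = net.adjacency
    fields: list[Polynomial] = []
    g_terms: list[GTerm] = []
    for k in range(net.n):
        fk = Polynomial.zero()
        for ell in range(net.n):
            if A[k, ell] == 0 or ell == k:
                continue
            for p in range(net.n):
                if A[k, p] != 0 and p != k:
                    g1 = compute_G(net, k, ell, p, 1, tol, degree_cut=degree_cut)
                    g_terms.append(g1)
                    fk = fk + g1.poly.scale(-_c_expr(A[k, ell] * A[k, p]))
                if A[ell, p] != 0 and p != ell:
                    g2 = compute_G(net, k, ell, p, 2, tol, degree_cut=degree_cut)
                    g_terms.append(g2)
                    fk = fk + g2.poly.scale(-_c_expr(A[k, ell] * A[ell, p]))
        fields.append(fk.shift_alpha(2).normalize())
    if return_g_terms:
        return fields, g_terms
    return fields


def count_interaction_terms(
    net: NetworkSpec, node: int, tol: float | None = None, distinct_only: bool = True
) -> int:
    """Number of elementary interaction products in node *node*'s order-α²
    expansion before resonance filtering and truncation.

    Each product of one monomial of an h̃-derivative with one monomial of h is
    counted once; with ``distinct_only`` only genuine triplet terms (k, ℓ, p
    pairwise distinct) are counted, which is the convention under which a ring
    node has 16 interaction terms.
    """
    A = net.adjacency
    k = node
    total = 0
    for ell in range(net.n):
        if A[k, ell] == 0 or ell == k:
            continue
        for p in range(net.n):
            if distinct_only and (p == k or p == ell):
                continue
            if A[k, p] != 0 and p != k:
                total += compute_G(net, k, ell, p, 1, tol).n_products
            if A[ell, p] != 0 and p != ell:
                total += compute_G(net, k, ell, p, 2, tol).n_products
    return total


def beta_cross_order2(
    net: NetworkSpec, P: Sequence[Polynomial], degree_cut: int = 5
) -> list[Polynomial]:
    """Degree-≥5 order-α² terms generated by the cubic Hopf term interacting
    twice with the first transformation:

    ``β_k [z̄_k P_k² + 2 z_k P_k P̄_k + 2 z_k z̄_k R_k + z_k² R̄_k] − D_P(L_B P_k)``

    with ``R_k = Σ_j (∂P_k/∂z_j P_j + ∂P_k/∂z̄_j P̄_j)``.  The emergent G terms
    alone are the complete α² field only up to total degree 4; adding these
    completes it through degree 5 (they contain zero-frequency combinations
    that renormalize radius and frequency at order α²r⁴, which matters for
    trajectory-accuracy measurements).  Sign/α conventions as in
    :func:`assemble_order2`.
    """
    out = []
    for k in range(net.n):
        bk = _c_expr(net.dynamics[k].beta)
        pk = P[k]
        R = Polynomial.zero()
        for j in pk.nodes:
            R = R + pk.diff(j) * P[j] + pk.diff(j, True) * P[j].conj()
        lbp = Polynomial.zero()
        for j in pk.nodes:
            bj = _c_expr(net.dynamics[j].beta)
            lbp = lbp + pk.diff(j) * Polynomial.monomial({j: (2, 1)}, bj)
            lbp = lbp + pk.diff(j, True) * Polynomial.monomial({j: (1, 2)}, sp.conjugate(bj))
        dplbp = Polynomial.zero()
        for m in lbp.nodes:
            dplbp = dplbp + lbp.diff(m) * P[m] + lbp.diff(m, True) * P[m].conj()
        extra = (
            Polynomial.monomial({k: (0, 1)}, bk) * pk * pk
            + Polynomial.monomial({k: (1, 0)}, 2 * bk) * pk * pk.conj()
            + Polynomial.monomial({k: (1, 1)}, 2 * bk) * R
            + Polynomial.monomial({k: (2, 0)}, bk) * R.conj()
            - dplbp
        )
        out.append(extra.truncate(degree_cut=degree_cut).shift_alpha(2).normalize())
    return out


# ---------------------------------------------------------------------------
# second transformation


def residual_order1(net: NetworkSpec, P: Sequence[Polynomial]) -> list[Polynomial]:
    """Order-α terms regenerated by the cubic Hopf term after ``w = z − αP``:

    ``S_k = β_k (2 w_k w̄_k P_k + w_k² conj(P_k))
            − Σ_j [∂P_k/∂z_j · β_j w_j² w̄_j + ∂P_k/∂z̄_j · β̄_j w̄_j² w_j]``.
    """
    out = []
    for k in range(net.n):
        beta_k = _c_expr(net.dynamics[k].beta)
        pk = P[k]
        s = (
            Polynomial.monomial({k: (1, 1)}, 2 * beta_k) * pk
            + Polynomial.monomial({k: (2, 0)}, beta_k) * pk.conj()
        )
        for j in pk.nodes:
            bj = _c_expr(net.dynamics[j].beta)
            s = s - pk.diff(j) * Polynomial.monomial({j: (2, 1)}, bj)
            s = s - pk.diff(j, True) * Polynomial.monomial({j: (1, 2)}, sp.conjugate(bj))
        out.append(s.normalize())
    return out


def build_second_transform(
    net: NetworkSpec, residual: Sequence[Polynomial], tol: float | None = None
) -> list[Polynomial]:
    """Q_k eliminating every residual order-α monomial via the generalized
    homological denominator.  A resonant residual monomial raises
    :class:`ResonantMonomialError`: under the theorem's hypotheses the first
    transformation's non-resonance conditions make this unreachable, so
    reaching it indicates a resonance-tolerance misconfiguration."""
    if tol is None:
        tol = default_elimination_tol(net.omegas)
    gsyms = _gamma_syms(net.n)
    out = []
    for k in range(net.n):
        terms = []
        for m in residual[k]:
            res = nonres_residual(m, k, net.omegas)
            if abs(res) <= tol:
                raise ResonantMonomialError(m, res, context=f"second transform, node {k + 1}")
            den = homological_denominator(m, k, gsyms)
            terms.append(Monomial(m.exponents, m.coeff / den, m.alpha))
        out.append(Polynomial(terms))
    return out


# ---------------------------------------------------------------------------
# linear coupling → frequency shift


def shift_frequencies(dh0: np.ndarray, omegas: Sequence[float], alpha: float) -> np.ndarray:
    """Natural frequencies of the coupled system: imaginary parts of the
    eigenvalues of ``iΩ + α·DH(0)``, paired to nodes by maximal eigenvector
    overlap with the uncoupled (α = 0) basis."""
    omegas = np.asarray(omegas, dtype=float)
    dh0 = np.asarray(dh0, dtype=complex)
    if alpha == 0 or not np.any(dh0):
        return omegas.copy()
    n = len(omegas)
    if len(np.unique(omegas)) != n:
        raise PairingAmbiguityError(
            "degenerate natural frequencies: supply an explicit eigenvalue-node pairing"
        )
    M = 1j * np.diag(omegas) + alpha * dh0
    vals, vecs = np.linalg.eig(M)
    from scipy.optimize import linear_sum_assignment

    overlap = np.abs(vecs)  # rows: node component, cols: eigenvector
    row, col = linear_sum_assignment(-overlap.T)  # assign eigenvectors to nodes
    shifted = np.empty(n)
    for ev_idx, node in zip(row, col):
        shifted[node] = vals[ev_idx].imag
    return shifted


def coupling_dh0(net: NetworkSpec) -> np.ndarray:
    """Complex-linear Jacobian DH(0) of the aggregate coupling H_k = Σ A_kℓ h."""
    c_z, c_zbar, c_w, c_wbar = net.coupling.linear_coeffs()
    if c_zbar != 0 or c_wbar != 0:
        raise NormalFormError(
            "antilinear (conjugate) linear coupling terms have no complex-linear "
            "DH(0); use linear_mode='eliminate' if they are non-resonant"
        )
    A = net.adjacency
    dh0 = complex(c_w) * A.astype(complex)
    dh0 += np.diag(complex(c_z) * A.sum(axis=1))
    return dh0


# ---------------------------------------------------------------------------
# orchestration


def normal_form(
    net: NetworkSpec,
    degree_cut: int = 4,
    tol: float | None = None,
    filter_tol: float | None = None,
    complete_beta_cross: bool | None = None,
) -> NormalFormResult:
    """Run both transformations and assemble the order-α² normal form.

    *tol* gates elimination (default ``1e-6·max|ω|``); *filter_tol* is the
    averaging tolerance used only to classify the surviving α² monomials in
    the ledger (default ``0.05·mean|ω|``, matching the experimental detunings).
    When the degree cut admits quintic terms, *complete_beta_cross* (default:
    on for ``degree_cut ≥ 5``) adds the β-generated α² corrections of
    :func:`beta_cross_order2` so the field is complete through degree 5.
    """
    if tol is None:
        tol = default_elimination_tol(net.omegas)
    if filter_tol is None:
        filter_tol = 0.05 * float(np.mean(np.abs(net.omegas)))

    shifted = net.omegas.copy()
    if not net.coupling.linear.is_zero and net.coupling.linear_mode == "shift":
        shifted = shift_frequencies(coupling_dh0(net), net.omegas, net.alpha)

    gsyms = _gamma_syms(net.n)
    ledger: list[LedgerEntry] = []
    P = build_first_transform(net, tol)
    for k in range(net.n):
        for m in P[k]:
            den = homological_denominator(
                Monomial(m.exponents, sp.S.One, 0), k, gsyms
            )
            ledger.append(
                LedgerEntry(m, k, "eliminated", den, nonres_residual(m, k, net.omegas))
            )

    S = residual_order1(net, P)
    Q = build_second_transform(net, S, tol)
    for k in range(net.n):
        for m in Q[k]:
            den = homological_denominator(Monomial(m.exponents, sp.S.One, 0), k, gsyms)
            ledger.append(
                LedgerEntry(m, k, "eliminated-residual", den, nonres_residual(m, k, net.omegas))
            )

    fields, g_terms = assemble_order2(net, tol, degree_cut, return_g_terms=True)
    if complete_beta_cross is None:
        complete_beta_cross = degree_cut >= 5
    if complete_beta_cross:
        extra = beta_cross_order2(net, P, degree_cut)
        fields = [(f + e).normalize() for f, e in zip(fields, extra)]
    for k in range(net.n):
        for m in fields[k]:
            res = nonres_residual(m, k, shifted)
            action = "retained-resonant" if abs(res) <= filter_tol else "discarded-fast"
            ledger.append(LedgerEntry(m, k, action, None, res))

    return NormalFormResult(
        net=net,
        P=P,
        Q=Q,
        g_terms=g_terms,
        order2_field=fields,
        ledger=ledger,
        shifted_omegas=shifted,
        metadata={
            "degree_cut": degree_cut,
            "tol": tol,
            "filter_tol": filter_tol,
            "sign_convention": "all-minus",
            "linear_mode": net.coupling.linear_mode,
        },
    )


class _NumPoly:
    """Lightweight numeric-coefficient polynomial used internally for the
    composed pushforward (same exponent/α-marker layout as
    :class:`~hypernf.polycore.Polynomial`, complex coefficients, no sympy)."""

    __slots__ = ("terms",)

    def __init__(self, terms: dict | None = None):
        self.terms = terms or {}  # {(exps, alpha): complex}

    @staticmethod
    def from_poly(p: Polynomial, subs) -> "_NumPoly":
        t = {}
        for m in p:
            c = complex(sp.sympify(m.coeff).subs(subs)) if subs else complex(m.coeff)
            if c != 0:
                t[(m.exponents, m.alpha)] = t.get((m.exponents, m.alpha), 0.0) + c
        return _NumPoly(t)

    def to_poly(self, prune: float = 1e-12) -> Polynomial:
        return Polynomial(
            Monomial(e, sp.Float(c.real) + sp.I * sp.Float(c.imag), al)
            for (e, al), c in sorted(self.terms.items())
            if abs(c) > prune
        )

    def __add__(self, o):
        t = dict(self.terms)
        for k, c in o.terms.items():
            t[k] = t.get(k, 0.0) + c
        return _NumPoly(t)

    def __sub__(self, o):
        t = dict(self.terms)
        for k, c in o.terms.items():
            t[k] = t.get(k, 0.0) - c
        return _NumPoly(t)

    def mul(self, o, alpha_cut, degree_cut):
        t = {}
        for (e1, a1), c1 in self.terms.items():
            for (e2, a2), c2 in o.terms.items():
                al = a1 + a2
                if al > alpha_cut:
                    continue
                d = dict((j, (a, b)) for j, a, b in e1)
                deg = 0
                for j, a, b in e2:
                    pa, pb = d.get(j, (0, 0))
                    d[j] = (pa + a, pb + b)
                exps = tuple((j, ab[0], ab[1]) for j, ab in sorted(d.items()) if ab != (0, 0))
                deg = sum(a + b for _, a, b in exps)
                if deg > degree_cut:
                    continue
                key = (exps, al)
                t[key] = t.get(key, 0.0) + c1 * c2
        return _NumPoly(t)

    def shift_alpha(self, d):
        return _NumPoly({(e, al + d): c for (e, al), c in self.terms.items()})

    def conj(self):
        return _NumPoly(
            {
                (tuple((j, b, a) for j, a, b in e), al): c.conjugate()
                for (e, al), c in self.terms.items()
            }
        )

    def diff(self, node, wrt_conj=False):
        t = {}
        for (e, al), c in self.terms.items():
            d = dict((j, (a, b)) for j, a, b in e)
            a, b = d.get(node, (0, 0))
            p = b if wrt_conj else a
            if p == 0:
                continue
            d[node] = (a, b - 1) if wrt_conj else (a - 1, b)
            exps = tuple((j, ab[0], ab[1]) for j, ab in sorted(d.items()) if ab != (0, 0))
            t[(exps, al)] = t.get((exps, al), 0.0) + c * p
        return _NumPoly(t)

    def relabel(self, mapping):
        t = {}
        for (e, al), c in self.terms.items():
            exps = tuple(sorted((mapping.get(j, j), a, b) for j, a, b in e))
            t[(exps, al)] = c
        return _NumPoly(t)

    def substitute(self, node, rep, alpha_cut, degree_cut):
        one = _NumPoly({((), 0): 1.0})
        pows = {0: one}
        pows_c = {0: one}

        def pw(table, base, e):
            if e not in table:
                table[e] = pw(table, base, e - 1).mul(base, alpha_cut, degree_cut)
            return table[e]

        rep_c = rep.conj()
        out = _NumPoly()
        for (e, al), c in self.terms.items():
            d = dict((j, (a, b)) for j, a, b in e)
            a, b = d.pop(node, (0, 0))
            exps = tuple((j, ab[0], ab[1]) for j, ab in sorted(d.items()))
            term = _NumPoly({(exps, al): c})
            if a:
                term = term.mul(pw(pows, rep, a), alpha_cut, degree_cut)
            if b:
                term = term.mul(pw(pows_c, rep_c, b), alpha_cut, degree_cut)
            out = out + term
        return out

    @property
    def nodes(self):
        s = set()
        for e, _ in self.terms:
            s.update(j for j, _, _ in e)
        return sorted(s)


def composed_alpha2_field(
    net: NetworkSpec,
    degree_cut: int = 8,
    tol: float | None = None,
) -> list[Polynomial]:
    """The full order-α² normal form: push the vector field through both
    transformations, truncating in α only (α ≤ 2) up to *degree_cut*.

    Unlike :func:`assemble_order2` (the emergent-G double sum, which is the
    complete α² field only through total degree 5), this keeps every composed
    term: the α² tail of higher degree and the degree-≥6 order-α remainder
    that only a third transformation could remove.  Coefficients are numeric
    (γ values substituted).  Returned per node with the Hopf part ``f_k``
    stripped, so ``u̇_k = f_k(u_k) + field_k(u)`` with α markers ∈ {1, 2}.

    Use this for trajectory-accuracy measurements; the hypernetwork
    construction itself works from the G terms.
    """
    n = net.n
    if tol is None:
        tol = default_elimination_tol(net.omegas)
    P = build_first_transform(net, tol)
    Q = build_second_transform(net, residual_order1(net, P), tol)
    subs = net.gamma_subs()
    Pn = [_NumPoly.from_poly(p, subs) for p in P]
    Qn = [_NumPoly.from_poly(q, subs) for q in Q]
    F = []
    for k in range(n):
        fnum = _NumPoly(
            {
                (((k, 1, 0),), 0): complex(net.dynamics[k].gamma),
                (((k, 2, 1),), 0): complex(net.dynamics[k].beta),
            }
        )
        for ell in range(n):
            if net.adjacency[k, ell] != 0:
                hp = _NumPoly.from_poly(net.coupling.instantiate(k, ell), None)
                fnum = fnum + _NumPoly(
                    {k2: c * net.adjacency[k, ell] for k2, c in hp.shift_alpha(1).terms.items()}
                )
        F.append(fnum)

    A_CUT = 2

    def push(vf, T):
        # second-order inverse z = y + αT(y) + α² (DT·T)(y)
        R = []
        for j in range(n):
            r = _NumPoly()
            for m2 in T[j].nodes:
                r = r + T[j].diff(m2).mul(T[m2], A_CUT, degree_cut)
                r = r + T[j].diff(m2, True).mul(T[m2].conj(), A_CUT, degree_cut)
            R.append(r)
        shift = {j: n + j for j in range(n)}
        out = []
        for k in range(n):
            g = vf[k]
            for j in range(n):
                dj = T[k].diff(j)
                djc = T[k].diff(j, True)
                if dj.terms:
                    g = g - dj.mul(vf[j], A_CUT - 1, degree_cut).shift_alpha(1)
                if djc.terms:
                    g = g - djc.mul(vf[j].conj(), A_CUT - 1, degree_cut).shift_alpha(1)
            g = _NumPoly({k2: c for k2, c in g.terms.items() if k2[1] <= A_CUT}).relabel(shift)
            for j in range(n):
                rep = (
                    _NumPoly({(((j, 1, 0),), 0): 1.0})
                    + T[j].shift_alpha(1)
                    + R[j].shift_alpha(2)
                )
                g = g.substitute(n + j, rep, A_CUT, degree_cut)
            out.append(g)
        return out

    composed = push(push(F, Pn), Qn)
    return [
        _NumPoly({k2: c for k2, c in g.terms.items() if k2[1] >= 1}).to_poly(prune=1e-12)
        for g in composed
    ]


# ---------------------------------------------------------------------------
# symbolic verification of the α¹ cancellation (used by tests)


def verify_alpha1_cancellation(
    net: NetworkSpec,
    P: Sequence[Polynomial] | None = None,
    Q: Sequence[Polynomial] | None = None,
    degree_cut: int | None = None,
    exact: bool = True,
) -> Polynomial:
    """Compose both transformations with the vector field symbolically and
    return the surviving order-α part of ``u̇`` (stacked over nodes, node k's
    terms relabelled into block k).  Under the non-resonance conditions the
    result must be identically zero.

    The degree cap defaults to ``min_deg(h) + 3``: the cubic Hopf term
    regenerates order-α terms starting at ``min_deg(h) + 2`` (removed by Q),
    and the next generation starts at ``min_deg(h) + 4``, which would need a
    third transformation the truncated normal form does not use.  With
    ``exact=True`` the γ values must be exactly representable (rational λ, ω),
    making the zero test exact.
    """
    n = net.n
    if degree_cut is None:
        degree_cut = net.coupling.eliminable().min_degree() + 3
    tol = default_elimination_tol(net.omegas)
    if P is None:
        P = build_first_transform(net, tol)
    if Q is None:
        Q = build_second_transform(net, residual_order1(net, P), tol)

    subs = net.gamma_subs_exact() if exact else net.gamma_subs()

    def num(p: Polynomial) -> Polynomial:
        return p.subs_coeffs(subs).normalize()

    Pn = [num(p) for p in P]
    Qn = [num(q) for q in Q]

    # full vector field F_k(z), coupling carrying the α marker
    F = []
    for k in range(n):
        gk = subs[gamma_symbol(k)]
        bk = _c_expr(net.dynamics[k].beta)
        fk = Polynomial.monomial({k: (1, 0)}, gk) + Polynomial.monomial({k: (2, 1)}, bk)
        coup = Polynomial.zero()
        for ell in range(n):
            if net.adjacency[k, ell] != 0:
                coup = coup + net.coupling.instantiate(k, ell).scale(
                    _c_expr(net.adjacency[k, ell])
                )
        F.append(fk + coup.shift_alpha(1))

    def push(vecfield: list[Polynomial], T: Sequence[Polynomial]) -> list[Polynomial]:
        # new_k = [F_k - α Σ_j (∂T_k/∂z_j F_j + ∂T_k/∂z̄_j conj(F_j))] ∘ (z = y + αT(y))
        out = []
        shift = {j: n + j for j in range(n)}
        for k in range(n):
            g = vecfield[k]
            for j in range(n):
                dj = T[k].diff(j)
                djc = T[k].diff(j, True)
                if not dj.is_zero:
                    g = g - (dj * vecfield[j]).shift_alpha(1)
                if not djc.is_zero:
                    g = g - (djc * vecfield[j].conj()).shift_alpha(1)
            g = g.truncate(alpha_order_cut=1, degree_cut=degree_cut)
            # capture-free substitution z_j -> y_j + α T_j(y), via shadow indices
            g = g.relabel(shift)
            for j in range(n):
                rep = Polynomial.variable(j) + T[j].shift_alpha(1)
                g = g.substitute(n + j, rep, alpha_order_cut=1, degree_cut=degree_cut)
            out.append(g.normalize())
        return out

    stage1 = push(F, Pn)
    stage2 = push(stage1, Qn)

    leftover = Polynomial.zero()
    for k in range(n):
        a1 = Polynomial(m for m in stage2[k] if m.alpha == 1)
        # keep resonant coupling terms out of the check when h has a retained linear part
        if net.coupling.linear_mode == "shift" and not net.coupling.linear.is_zero:
            a1 = Polynomial(m for m in a1 if m.degree != 1)
        leftover = leftover + a1.relabel({j: j + k * n for j in range(n)})
    return leftover.normalize()
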