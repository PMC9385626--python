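"""Exact algebra of complex polynomials in node variables and their conjugates.

Every quantity the normal-form machinery manipulates — coupling functions,
transformation polynomials, emergent interaction terms — is a polynomial in the
node states ``z_1 … z_n`` and their complex conjugates, with coefficients that
are exact rational functions of the per-node Hopf parameters ``γ_k``.  This
module provides that substrate.

Conventions
-----------
* A :class:`Monomial` stores, per node ``j``, a pair of non-negative integer
  exponents ``(a_j, b_j)``: the power of ``z_j`` and of ``conj(z_j)``.  Pairs
  equal to ``(0, 0)`` are never stored.
* Coefficients are :mod:`sympy` expressions so that exact complex rationals and
  rational functions of the symbols ``g1 … gn`` (the ``γ_k``) coexist.  Use
  :func:`gamma_symbol` to obtain the canonical symbol for node ``k``.
* The formal coupling-strength order in ``α`` is carried as an integer marker
  per monomial (``alpha``), never as a numeric factor, so truncation "up to
  higher order in α" is exact.
* Canonical term order is graded lexicographic: ascending α order, then total
  degree, then the exponent map with nodes ascending and ``z`` before
  ``conj(z)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

import sympy as sp

__all__ = [
    "Monomial",
    "Polynomial",
    "gamma_symbol",
    "var_symbol",
    "compile_poly",
]

#: Exponent map: sorted tuple of (node index, power of z, power of conj z).
Exponents = tuple[tuple[int, int, int], ...]

_ALPHA = sp.Symbol("alpha", positive=True)


def gamma_symbol(k: int) -> sp.Symbol:
    """Canonical symbol for the Hopf parameter γ of node ``k`` (0-based)."""
    return sp.Symbol(f"g{k + 1}")


def var_symbol(k: int, prefix: str = "u") -> sp.Symbol:
    """Canonical symbol for the state variable of node ``k`` (0-based)."""
    return sp.Symbol(f"{prefix}{k + 1}")


def _canon_exponents(exps: Mapping[int, tuple[int, int]]) -> Exponents:
    out = []
    for j in sorted(exps):
        a, b = exps[j]
        if a < 0 or b < 0:
            raise ValueError(f"negative exponent for node {j}: {(a, b)}")
        if (a, b) != (0, 0):
            out.append((j, int(a), int(b)))
    return tuple(out)


def _as_coeff(c) -> sp.Expr:
    return sp.sympify(c)


@dataclass(frozen=True)
class Monomial:
    """A single term ``coeff * α^alpha * Π_j z_j^a_j conj(z_j)^b_j``."""

    exponents: Exponents
    coeff: sp.Expr
    alpha: int = 0

    @staticmethod
    def make(exps: Mapping[int, tuple[int, int]], coeff=1, alpha: int = 0) -> "Monomial":
        return Monomial(_canon_exponents(exps), _as_coeff(coeff), int(alpha))

    @property
    def degree(self) -> int:
        """Total degree Σ_j (a_j + b_j)."""
        return sum(a + b for _, a, b in self.exponents)

    def exponent(self, node: int) -> tuple[int, int]:
        for j, a, b in self.exponents:
            if j == node:
                return (a, b)
        return (0, 0)

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(j for j, _, _ in self.exponents)

    def conj(self) -> "Monomial":
        exps = tuple((j, b, a) for j, a, b in self.exponents)
        return Monomial(exps, sp.conjugate(self.coeff), self.alpha)

    def to_expr(self, prefix: str = "u") -> sp.Expr:
        e: sp.Expr = self.coeff * _ALPHA ** self.alpha
        for j, a, b in self.exponents:
            v = var_symbol(j, prefix)
            e *= v ** a * sp.conjugate(v) ** b
        return e


class Polynomial:
    """Canonical sum of :class:`Monomial` terms (like terms combined)."""

    __slots__ = ("_terms",)

    def __init__(self, terms: Iterable[Monomial] = ()):
        acc: dict[tuple[Exponents, int], sp.Expr] = {}
        for m in terms:
            key = (m.exponents, m.alpha)
            acc[key] = acc[key] + m.coeff if key in acc else m.coeff
        self._terms = {k: c for k, c in acc.items() if not _is_syntactic_zero(c)}

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def zero() -> "Polynomial":
        return Polynomial()

    @staticmethod
    def monomial(exps: Mapping[int, tuple[int, int]], coeff=1, alpha: int = 0) -> "Polynomial":
        return Polynomial([Monomial.make(exps, coeff, alpha)])

    @staticmethod
    def variable(node: int, conjugated: bool = False) -> "Polynomial":
        return Polynomial.monomial({node: (0, 1) if conjugated else (1, 0)})

    # -- inspection ----------------------------------------------------------

    def __iter__(self) -> Iterator[Monomial]:
        for (exps, al), c in sorted(
            self._terms.items(),
            key=lambda kv: (kv[0][1], sum(a + b for _, a, b in kv[0][0]), kv[0][0]),
        ):
            yield Monomial(exps, c, al)

    def __len__(self) -> int:
        return len(self._terms)

    @property
    def is_zero(self) -> bool:
        return not self._terms

    def coeff_of(self, exps: Mapping[int, tuple[int, int]], alpha: int = 0) -> sp.Expr:
        return self._terms.get((_canon_exponents(exps), alpha), sp.S.Zero)

    def min_degree(self) -> int:
        """Minimum total degree over stored monomials (0 for the zero polynomial)."""
        if not self._terms:
            return 0
        return min(sum(a + b for _, a, b in exps) for exps, _ in self._terms)

    def max_degree(self) -> int:
        if not self._terms:
            return 0
        return max(sum(a + b for _, a, b in exps) for exps, _ in self._terms)

    def max_alpha(self) -> int:
        return max((al for _, al in self._terms), default=0)

    @property
    def nodes(self) -> tuple[int, ...]:
        s: set[int] = set()
        for exps, _ in self._terms:
            s.update(j for j, _, _ in exps)
        return tuple(sorted(s))

    # -- ring operations -----------------------------------------------------

    def __add__(self, other: "Polynomial") -> "Polynomial":
        p = Polynomial()
        acc = dict(self._terms)
        for k, c in other._terms.items():
            acc[k] = acc[k] + c if k in acc else c
        p._terms = {k: c for k, c in acc.items() if not _is_syntactic_zero(c)}
        return p

    def __neg__(self) -> "Polynomial":
        p = Polynomial()
        p._terms = {k: -c for k, c in self._terms.items()}
        return p

    def __sub__(self, other: "Polynomial") -> "Polynomial":
        return self + (-other)

    def __mul__(self, other: "Polynomial") -> "Polynomial":
        out: dict[tuple[Exponents, int], sp.Expr] = {}
        for (e1, a1), c1 in self._terms.items():
            d1 = dict((j, (a, b)) for j, a, b in e1)
            for (e2, a2), c2 in other._terms.items():
                merged = dict(d1)
                for j, a, b in e2:
                    pa, pb = merged.get(j, (0, 0))
                    merged[j] = (pa + a, pb + b)
                key = (_canon_exponents(merged), a1 + a2)
                c = c1 * c2
                out[key] = out[key] + c if key in out else c
        p = Polynomial()
        p._terms = {k: c for k, c in out.items() if not _is_syntactic_zero(c)}
        return p

    def scale(self, c) -> "Polynomial":
        c = _as_coeff(c)
        p = Polynomial()
        p._terms = {} if _is_syntactic_zero(c) else {k: c * v for k, v in self._terms.items()}
        return p

    def shift_alpha(self, d: int) -> "Polynomial":
        """Multiply by the formal marker α^d."""
        p = Polynomial()
        p._terms = {(e, al + d): c for (e, al), c in self._terms.items()}
        return p

    def conj(self) -> "Polynomial":
        return Polynomial(m.conj() for m in self)

    def diff(self, node: int, wrt_conjugate: bool = False) -> "Polynomial":
        """Formal Wirtinger derivative ∂/∂z_node (or ∂/∂conj(z_node)).

        ``z_j`` and ``conj(z_j)`` are treated as independent variables, which is
        exactly what the emergent coupling formulas require.
        """
        out = []
        for m in self:
            a, b = m.exponent(node)
            e = a if not wrt_conjugate else b
            if e == 0:
                continue
            exps = dict((j, (x, y)) for j, x, y in m.exponents)
            if wrt_conjugate:
                exps[node] = (a, b - 1)
            else:
                exps[node] = (a - 1, b)
            out.append(Monomial.make(exps, m.coeff * e, m.alpha))
        return Polynomial(out)

    # -- composition ---------------------------------------------------------

    def truncate(self, alpha_order_cut: int | None = None, degree_cut: int | None = None) -> "Polynomial":
        p = Polynomial()
        p._terms = {
            (e, al): c
            for (e, al), c in self._terms.items()
            if (alpha_order_cut is None or al <= alpha_order_cut)
            and (degree_cut is None or sum(a + b for _, a, b in e) <= degree_cut)
        }
        return p

    def substitute(
        self,
        node: int,
        replacement: "Polynomial",
        alpha_order_cut: int | None = None,
        degree_cut: int | None = None,
    ) -> "Polynomial":
        """Replace ``z_node`` by ``replacement`` (and its conjugate accordingly).

        The result is truncated to ``α``-order ≤ *alpha_order_cut* and total
        degree ≤ *degree_cut*; below the cuts the composition is exact.
        """
        if degree_cut is not None and degree_cut < 1:
            raise ValueError("degree_cut must be ≥ 1")
        rep = replacement
        rep_c = replacement.conj()
        pow_cache: dict[tuple[bool, int], Polynomial] = {}

        def _power(base: Polynomial, conjugated: bool, e: int) -> Polynomial:
            key = (conjugated, e)
            if key not in pow_cache:
                if e == 0:
                    pow_cache[key] = Polynomial.monomial({})
                else:
                    prev = _power(base, conjugated, e - 1)
                    pow_cache[key] = (prev * base).truncate(alpha_order_cut, degree_cut)
            return pow_cache[key]

        out = Polynomial()
        for m in self:
            a, b = m.exponent(node)
            rest = {j: (x, y) for j, x, y in m.exponents if j != node}
            term = Polynomial.monomial(rest, m.coeff, m.alpha)
            if a:
                term = (term * _power(rep, False, a)).truncate(alpha_order_cut, degree_cut)
            if b:
                term = (term * _power(rep_c, True, b)).truncate(alpha_order_cut, degree_cut)
            out = out + term
        return out.truncate(alpha_order_cut, degree_cut)

    def relabel(self, mapping: Mapping[int, int]) -> "Polynomial":
        """Rename node indices (used for slot instantiation and capture-free
        substitution); indices absent from *mapping* are kept."""
        out = []
        for m in self:
            exps = {mapping.get(j, j): (a, b) for j, a, b in m.exponents}
            if len(exps) != len(m.exponents):
                raise ValueError("relabel collision")
            out.append(Monomial.make(exps, m.coeff, m.alpha))
        return Polynomial(out)

    # -- coefficient normalization & comparison ------------------------------

    def map_coeffs(self, fn: Callable[[sp.Expr], sp.Expr]) -> "Polynomial":
        p = Polynomial()
        p._terms = {k: v for k, v in ((k, fn(c)) for k, c in self._terms.items())
                    if not _is_syntactic_zero(v)}
        return p

    def normalize(self) -> "Polynomial":
        """Canonicalize coefficients as rational functions (sympy ``cancel``)."""
        return self.map_coeffs(lambda c: sp.cancel(sp.together(c)))

    def equals(self, other: "Polynomial") -> bool:
        """Exact equality up to rational-function coefficient simplification."""
        diff = (self - other).map_coeffs(lambda c: sp.cancel(sp.together(c)))
        if diff.is_zero:
            return True
        return all(sp.simplify(m.coeff) == 0 for m in diff)

    # -- numeric substitution ------------------------------------------------

    def subs_coeffs(self, mapping: Mapping[sp.Symbol, complex]) -> "Polynomial":
        """Substitute numeric values for coefficient symbols (e.g. γ's)."""
        return self.map_coeffs(lambda c: sp.sympify(c).subs(mapping))

    def eval(self, values: Mapping[int, complex], alpha_value: float = 1.0) -> complex:
        """Evaluate numerically at ``z_j = values[j]`` (coefficients must be numeric)."""
        total = 0j
        for m in self:
            c = complex(m.coeff)
            v = c * alpha_value ** m.alpha
            for j, a, b in m.exponents:
                zj = complex(values[j])
                v *= zj ** a * zj.conjugate() ** b
            total += v
        return total

    # -- serialization -------------------------------------------------------

    def to_expr(self, prefix: str = "u") -> sp.Expr:
        return sp.Add(*[m.to_expr(prefix) for m in self])

    def serialize(self, prefix: str = "u") -> str:
        """Plain-text expression, e.g. ``(1/(g1 + conj(g2)))*u1^2*conj(u2)*u3``."""
        if self.is_zero:
            return "0"
        parts = []
        for m in self:
            factors = []
            c = sp.together(m.coeff)
            if c != 1 or (not m.exponents and m.alpha == 0):
                factors.append(f"({sp.sstr(c)})")
            if m.alpha:
                factors.append("alpha" if m.alpha == 1 else f"alpha^{m.alpha}")
            for j, a, b in m.exponents:
                name = f"{prefix}{j + 1}"
                if a:
                    factors.append(name if a == 1 else f"{name}^{a}")
                if b:
                    factors.append(f"conj({name})" if b == 1 else f"conj({name})^{b}")
            parts.append("*".join(factors))
        return (" + ".join(parts)).replace("conjugate", "conj")

    @staticmethod
    def parse(text: str, prefix: str = "u") -> "Polynomial":
        """Inverse of :meth:`serialize` (also accepts ``**`` and ``conjugate``)."""
        src = text.replace("^", "**").replace("conj(", "conjugate(")
        expr = sp.parse_expr(src, evaluate=True)
        return Polynomial.from_expr(sp.expand(expr), prefix)

    @staticmethod
    def from_expr(expr: sp.Expr, prefix: str = "u") -> "Polynomial":
        expr = sp.expand(expr)
        terms = expr.args if isinstance(expr, sp.Add) else (expr,)
        out = []
        for t in terms:
            exps: dict[int, tuple[int, int]] = {}
            alpha = 0
            coeff = sp.S.One
            for base, e in t.as_powers_dict().items():
                node, conjugated = _classify_var(base, prefix)
                if node is not None:
                    a, b = exps.get(node, (0, 0))
                    if conjugated:
                        exps[node] = (a, b + int(e))
                    else:
                        exps[node] = (a + int(e), b)
                elif base == _ALPHA:
                    alpha = int(e)
                else:
                    coeff *= base ** e
            out.append(Monomial.make(exps, coeff, alpha))
        return Polynomial(out)


def _classify_var(base: sp.Expr, prefix: str) -> tuple[int | None, bool]:
    if isinstance(base, sp.Symbol):
        name = base.name
        if name.startswith(prefix) and name[len(prefix):].isdigit():
            return int(name[len(prefix):]) - 1, False
    if isinstance(base, sp.conjugate) and isinstance(base.args[0], sp.Symbol):
        node, _ = _classify_var(base.args[0], prefix)
        if node is not None:
            return node, True
    return None, False


def _is_syntactic_zero(c: sp.Expr) -> bool:
    return getattr(c, "is_zero", False) is True or c == 0


# -- numeric compilation -----------------------------------------------------


def compile_poly(
    poly: Polynomial,
    n: int,
    subs: Mapping[sp.Symbol, complex] | None = None,
    alpha_value: float = 1.0,
):
    """Flatten a polynomial to ``(coeffs, exps)`` arrays for fast evaluation.

    Returns a pair ``(coeffs, exps)`` where ``coeffs`` is complex128 of shape
    ``(m,)`` (α markers folded in as powers of *alpha_value*) and ``exps`` is
    int64 of shape ``(m, n, 2)`` holding the ``(a_j, b_j)`` exponents.
    """
    import numpy as np

    ms = list(poly)
    coeffs = np.empty(len(ms), dtype=np.complex128)
    exps = np.zeros((len(ms), n, 2), dtype=np.int64)
    for i, m in enumerate(ms):
        c = m.coeff if subs is None else sp.sympify(m.coeff).subs(subs)
        coeffs[i] = complex(c) * alpha_value ** m.alpha
        for j, a, b in m.exponents:
            exps[i, j, 0] = a
            exps[i, j, 1] = b
    return coeffs, exps
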