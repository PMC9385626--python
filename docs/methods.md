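# Methods

## The model

`hypernf` works with networks of oscillators close to a Hopf bifurcation,

$$\dot z_k = \gamma_k z_k + \beta_k z_k |z_k|^2
  + \alpha \sum_{\ell} A_{k\ell}\, h(z_k, z_\ell),
  \qquad \gamma_k = \lambda + i\omega_k,$$

with complex node states $z_k$, a polynomial pairwise coupling function
$h$ with vanishing constant term, and weak coupling $\alpha$.  The question
the package answers is *which higher-order (triplet) interactions govern the
phase dynamics of such a network* — even though the physical coupling is
strictly pairwise — and whether those interactions can be recovered from
phase time series alone.

## Normal-form derivation

Two near-identity coordinate changes, $w = z - \alpha P(z)$ and
$u = w - \alpha Q(w)$, remove the order-$\alpha$ coupling terms.

* **Replacement rule.**  $P_k = \sum_\ell A_{k\ell} \tilde h_{k\ell}$, where
  $\tilde h_{k\ell}$ divides each monomial
  $z^{d_1}\bar z^{d_2} w^{d_3}\bar w^{d_4}$ of $h$ by its homological
  denominator $(d_1-1)\gamma_k + d_2\bar\gamma_k + d_3\gamma_\ell +
  d_4\bar\gamma_\ell$.  A monomial is *eliminable* iff the imaginary part of
  that denominator at $\lambda = 0$ — the frequency combination
  $(d_1{-}d_2{-}1)\omega_k + (d_3{-}d_4)\omega_\ell$ — is nonzero: the
  non-resonance condition.  Elimination eligibility is decided on the
  frequencies alone with tolerance `tol = 1e-6·max|ω|`, while the division
  uses the full $\gamma$ (so $\lambda > 0$ regularizes nothing that the
  frequency test has not already admitted; near-resonant terms are retained,
  never divided by a small number).
* **Second transformation.**  Removing $\alpha H$ makes the cubic Hopf term
  regenerate order-$\alpha$ terms
  $S_k = \beta_k(2 w_k \bar w_k P_k + w_k^2 \bar P_k) - \sum_j
  (\partial_{z_j} P_k\,\beta_j z_j^2\bar z_j + \partial_{\bar z_j} P_k\,
  \bar\beta_j \bar z_j^2 z_j)$; $Q$ eliminates them with the generalized
  denominator $\sum_j (a_j\gamma_j + b_j\bar\gamma_j) - \gamma_k$.  The same
  non-resonance conditions suffice; a resonant residual monomial raises an
  error rather than being silently divided.
* **Emergent interactions.**  At order $\alpha^2$ the surviving interaction
  field is
  $-\alpha^2 \sum_{\ell,p} \big[A_{k\ell}A_{kp}\,{}^1G_k^{\ell p}
  + A_{k\ell}A_{\ell p}\,{}^2G_k^{\ell p}\big]$, with
  ${}^1G = \partial_{u_k}\tilde h_{k\ell}\, h(u_k,u_p) +
  \partial_{\bar u_k}\tilde h_{k\ell}\, \overline{h(u_k,u_p)}$ and ${}^2G$
  the analogue differentiated along the mediator $\ell$.  **Both families
  carry a minus sign.**  Expanding the composed vector field by hand gives
  the cross term $-\alpha^2\sum_j(\partial_{z_j}P_k\,H_j +
  \partial_{\bar z_j}P_k\,\bar H_j)$, whose $j{=}k$ part is the $^1G$ sum and
  whose $j{=}\ell$ part is the $^2G$ sum, and the worked ring example's
  printed coefficients ($\eta_{pq} = 1/(\gamma_p + \bar\gamma_q)$ with an
  overall $-\alpha^2$) are only consistent with this convention.  The test
  suite verifies it twice: symbolically (the assembled field equals the
  composed pushforward exactly through total degree 4) and numerically (the
  trajectory order-of-accuracy test below).  The convention is recorded in
  `NormalFormResult.metadata["sign_convention"]`.
* **Truncation.**  The default degree cut is 4, which keeps every quartic
  resonant monomial of the worked example.  The G terms are the *complete*
  $\alpha^2$ field only through total degree 5 (with the
  `beta_cross_order2` corrections for the quintic part); beyond that, terms
  generated by the cubic interacting with $Q$ appear, which only a third
  transformation could remove.  For trajectory-accuracy work the package
  therefore also exposes `composed_alpha2_field`, the exact pushforward of
  the vector field through both transformations truncated *in α only*
  (default degree ≤ 7, numeric coefficients).  With it the gap between the
  original network and the reduced model scales as $\alpha^3$ (measured
  log–log slope 3.0 across $\alpha \in \{0.02, 0.04, 0.08\}$ on the ring);
  with the degree-4 G field alone the gap floors near
  $\alpha^2 r^6/\lambda$-scale frequency shifts amplified by near-resonant
  denominators $4\lambda \pm i\,\delta$ ($\delta$ the triplet detuning),
  an intrinsic property of degree truncation at $\lambda = 0.01$, not an
  implementation defect.
* **Linear coupling.**  When $h$ has a complex-linear part, the default
  (`linear_mode="shift"`) keeps it and shifts the natural frequencies to the
  imaginary parts of the eigenvalues of $i\Omega + \alpha\,DH(0)$, paired to
  nodes by maximal eigenvector overlap with the uncoupled basis.  For the
  Kuramoto mean-field pathway, α is read as a bifurcation parameter and the
  linear monomial runs through the same elimination machinery
  (`linear_mode="eliminate"`); this is what produces the degree-3 resonant
  triplets $u_\ell^2\bar u_p$ behind the slow phases
  $\varphi_1 = \theta_1 - 2\theta_2 + \theta_3$,
  $\varphi_2 = \theta_2 - 2\theta_1 + \theta_4$.

## Averaging and the hypernetwork

A surviving $\alpha^2$ monomial $\prod_j u_j^{a_j}\bar u_j^{b_j}$ in node
$k$'s equation oscillates at $\sum_j (a_j-b_j)\omega_j - \omega_k$.  The
averaging filter keeps it only if that combination is small:
`filter_tol = 0.05·mean|ω|` by default, chosen so the experimentally
motivated detunings of ~3% of the base frequency classify as resonant.
Kept monomials are the hyperedges; writing $u_k = r_k e^{i\theta_k}$ on the
stationary radii ($r^* = \sqrt{-\lambda/\mathrm{Re}\,\beta}$, i.e.
$\sqrt\lambda$ for $\beta = -1$, and $\sqrt{(\mu-\sigma_k)/\mu}$ for the
Kuramoto order parameters) gives

$$\dot\theta_k = \omega_k + \alpha^2 R\,[\,\mathrm{Im}(c)\cos\Phi +
  \mathrm{Re}(c)\sin\Phi\,], \qquad R = \tfrac{1}{r_k}\prod_j r_j^{a_j+b_j},$$

per hyperedge ($c$ the signed field coefficient, $\Phi$ the phase
combination) — the $\alpha^2 r_0^3$ scaling for quartic monomials.
Zero-combination hyperedges contribute constant frequency shifts.  Summing
member equations yields the closed slow-phase field
$\dot\phi_i = \Omega_i + \sum_j a_{ij}\cos\phi_j + b_{ij}\sin\phi_j$, and a
symbolic consistency test checks that differentiating the combinations
through the phase model reproduces it exactly.

## Simulation

Complex ODEs are integrated as polynomial vector fields, either with a
fixed-step RK4 kernel (numba; bit-deterministic, used for the long recovery
runs; `dt = 0.01` resolves the fastest period by ≈ 250 steps) or with
adaptive RK45 (`rtol = 1e-8` default, tightened to `1e-11` in accuracy
measurements).  Initial conditions default to the stationary radii with
seeded uniform phases.

The microscopic Kuramoto ensembles use the mean-field form of the drive for
O(N) cost and a Heun scheme.  The printed $\mu$, $\alpha$ are *mean-field*
constants: the microscopic sine-coupling constants are $2\mu$, $2\alpha$,
because the textbook Ott–Antonsen reduction of sine coupling $K/N$ yields
$K/2$ in the order-parameter equation.  (With sine coupling $\mu = 0.5$
directly, the ensemble would sit below threshold, $K_c = 2\sigma = 0.96$,
and decohere — verified numerically.)  Similarly the mean-field coupling is
implemented as $\alpha(z_\ell - \bar z_\ell z_k^2)$, the sign the standard
reduction produces; the opposite printed sign is available as
`oa_convention="as-printed"`, and the microscopic-agreement test adjudicates
in favour of the textbook form.  Lorentzian frequencies default to
deterministic mid-point quantiles (variance-free reproducibility); seeded
Cauchy sampling is available.  Ensemble comparisons equilibrate first
(T = 150 ≈ 3/(μ−σ)): started cold, the empirical distribution lies off the
OA manifold and the order parameter transiently overshoots to ≈ 0.4 before
relaxing to $\sqrt{(\mu-\sigma)/\mu} = 0.2$.

## Recovery

Phases are the unwrapped arguments of the complex states; instantaneous
frequencies come from central differences.  A first-order Savitzky–Golay
filter smooths $\dot\theta$; its window defaults to ≈ 17.3 mean periods (a
45 s window at a 0.385 Hz base frequency, rescaled by the period ratio) and
is cascaded (`passes = 4` in the studies) because a single first-order pass
attenuates in-cycle ripple only by ~p/(πW).  The LASSO regresses
$\dot\theta_k$ on an unpenalized quadratic drift (projected out exactly via
QR — valid for an unpenalized block) plus sin/cos of candidate integer
phase combinations (by default all near-resonances with $|c_j| \le 2$ over
up to 3 nodes, including the pairwise ones); cross-validation selects the
penalty, an ordinary refit on the selected support debiases the amplitudes
$H = \sqrt{C^2 + D^2}$.  Support requires
$H > \max(3\,\mathrm{MAD}(\text{residual}),\ 0.1\,H_\text{max},\ 10^{-7})$:
the MAD term is the basic noise gate; the relative floor guards against
leakage between nearly collinear candidates; the absolute floor encodes the
numerical noise level of the default pipeline on noise-free data, below
which "detections" are integration artifacts.

**Identifiability of the ring study.**  With $\omega_2 = \omega_4$ exactly,
$\phi_1 - \phi_2 = \theta_4 - \theta_2$ is constant to $O(\alpha^2)$, so the
two triplet regressors are collinear and no method can attribute node 2 to
$\phi_1$ rather than $\phi_2$ from a single noiseless trajectory.  Real
oscillators are never tuned exactly; the recovery studies therefore use
$\omega = (1, 2.53, 1.56, 2.54)$ — a 1% pairwise detuning, far inside the
averaging tolerance (0.095), leaving the predicted hypernetwork unchanged
while decorrelating the regressors over the simulated horizon (T = 2500 ≈
4 beat cycles of the detuning).  The pairwise candidate $\theta_2-\theta_4$
remains in the library and is rejected by the fit, as in the laboratory
recovery.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions: the 4-ring of Stuart–Landau
oscillators at $\lambda = 0.01$, $\beta = -1$, $\omega = (1, 2.53, 1.56,
2.53)$, $\alpha = 0.05$ with $h = z\bar w + z^2\bar w$; a 3-node path and a
6-node ring with exactly resonant triplets; and the 4-subpopulation Kuramoto
ring ($\Omega = (2,3,4,1)$, $\mu = 0.5$, $\sigma = 0.48$, $\alpha = 0.1$,
$N = 10^4$).  It does *not* emulate measurement noise, electrode drift, the
feedback delay (replaced, as in the theory, by conjugate-variable coupling),
or protophase effects of non-circular limit cycles.  Passing tests
therefore demonstrate the correctness of the derivation, the reduction and
the recovery machinery under clean conditions, not robustness to laboratory
noise; the drift columns and the MAD-based threshold are the hooks real
data would exercise.

## Numerical choices and degenerate inputs

* Coefficients are exact symbolic rational functions of the $\gamma_k$
  throughout the derivation; numerics substitute values only at simulation
  or reporting time.
* Canonical term order: ascending α order, total degree, then exponent
  maps; phase combinations are stored with the first nonzero coefficient
  positive.
* Self-loops are rejected; a coupling constant term is rejected; a state
  passing through the origin makes the phase undefined and raises; blow-up
  (|z| > 10³) aborts integration with the offending step.
* Degenerate natural frequencies make the eigenvalue-to-node pairing of the
  frequency-shift computation ambiguous and raise an error demanding an
  explicit pairing.

## Problem sizes

The shipped studies use: T = 60 with RK45 at `rtol 1e-11` for the
order-of-accuracy slope; T = 2500 (≈ 12 slow cycles) per recovery run, five
seeds at $\alpha = 0.05$ plus three α values for the $H \propto \alpha^2$
slope; T = 150 at $N = 10^4$ for the microscopic coherence check and
T = 15000 for the mean-field slow-phase study.  These lengths give each
statistic several characteristic periods of its slowest process while
keeping a full run of the suite on one core in a few minutes.

## Known limitations

* The normal form is first-order in the two transformations; systems with
  $\alpha \gtrsim \lambda$ show $O(\alpha^2)$ radius modulations that the
  phase reduction on fixed radii ignores (the slow-phase *structure* is
  unaffected; amplitudes shift).
* Near-resonant homological denominators ($|{\rm residual}| \to$ tol)
  inflate transformation coefficients; the elimination tolerance guards the
  division but the truncated model degrades smoothly as detunings shrink.
* The resonance scanner enumerates combinations with $\sum$-bounded integer
  coefficients over at most 3 nodes; exotic higher-order resonances are out
  of scope, as are stability/bifurcation analyses of the slow-phase fields.
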