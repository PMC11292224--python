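"""Equilibrium and local stability analysis of the two-delay model.

The two-delay Michaelis-Menten system has a unique equilibrium, the
substrate-and-complex-free equilibrium (SCFE): all substrate consumed, all
enzyme free, product at its plateau.  Linearizing there gives a
characteristic quasi-polynomial chi(lambda) = lambda**2 * chi1(lambda) with

    chi1(l) = l**2 + k_m1*l + k1*(nS_bar + nE_bar)*l*exp(-l*tau1)
              + k2*l*exp(-l*tau2) + k1*k2*nE_bar*exp(-l*(tau1+tau2)).

The structural lambda**2 factor comes from the two conserved quantities
(total enzyme and total substrate material): it pins a double root on the
imaginary axis, so the SCFE can never be asymptotically stable — at best
*marginally* stable, which is exactly the operating regime of a biosensor
(each substrate dose settles at its own product plateau).

Roots of chi1 are located by seeding Newton's method (on the exact
quasi-polynomial, analytic termwise derivative) with the numerator roots of
the (1,1) Pade rational approximation exp(-l*tau) ~ (1 - l*tau/2)/(1 + l*tau/2).

The delayed exponential function e_tau^{lambda x} — the fundamental solution
of x'(t) = lambda x(t - tau) — provides sufficient positivity conditions for
the nonlinear system; it can itself turn negative, which is the mechanism of
positivity loss at large delays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.special import lambertw

from .model_core import RateParamsMM

__all__ = [
    "Equilibrium",
    "QuasiPolynomial",
    "Classification",
    "StabilityVerdict",
    "scfe",
    "build_chi1",
    "pade_reduce",
    "find_roots",
    "classify",
    "delayed_exp",
    "positivity_check",
    "PositivityReport",
]


# --------------------------------------------------------------------------
# equilibrium
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Equilibrium:
    """SCFE: (0, total enzyme, 0, product plateau) in mM."""

    nS_bar: float
    nE_bar: float
    nC_bar: float
    nP_bar: float


def scfe(total_enzyme: float, nP_limit: float = 0.0) -> Equilibrium:
    """Substrate-and-complex-free equilibrium.

    ``total_enzyme`` is the conserved nE(0) + nC(0); the product plateau is
    whatever Eq-integral value the trajectory converged to (it does not feed
    back into the dynamics).
    """
    if not total_enzyme > 0:
        raise ValueError("total enzyme must be positive")
    return Equilibrium(nS_bar=0.0, nE_bar=total_enzyme, nC_bar=0.0,
                       nP_bar=nP_limit)


# --------------------------------------------------------------------------
# quasi-polynomial
# --------------------------------------------------------------------------

@dataclass
class QuasiPolynomial:
    """Sum of polynomial terms, each lagged by m1*tau1 + m2*tau2.

    ``terms`` is a list of (ascending-coefficient array, (m1, m2)) pairs,
    i.e. p(l) * exp(-l * (m1*tau1 + m2*tau2)).  Keeping the delay as integer
    multiplicities of the two physical delays lets the Pade reduction use
    the right rational factor for each exponential (the tau1+tau2 term gets
    both).
    """

    terms: list
    tau1: float = 0.0
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("delays must be >= 0")
        self.terms = [
            (np.atleast_1d(np.asarray(c, dtype=float)), (int(m1), int(m2)))
            for c, (m1, m2) in self.terms
        ]

    def delay_of(self, mult: tuple) -> float:
        return mult[0] * self.tau1 + mult[1] * self.tau2

    def __call__(self, lam):
        lam = np.asarray(lam, dtype=complex)
        out = np.zeros_like(lam)
        for coeffs, mult in self.terms:
            out = out + P.polyval(lam, coeffs) * np.exp(-lam * self.delay_of(mult))
        if out.ndim == 0:
            return complex(out)
        return out

    def derivative(self, lam):
        """Termwise analytic derivative: (p' - d*p) * exp(-l*d)."""
        lam = np.asarray(lam, dtype=complex)
        out = np.zeros_like(lam)
        for coeffs, mult in self.terms:
            d = self.delay_of(mult)
            val = P.polyval(lam, P.polyder(coeffs)) - d * P.polyval(lam, coeffs)
            out = out + val * np.exp(-lam * d)
        if out.ndim == 0:
            return complex(out)
        return out

    def zero_delay_poly(self) -> np.ndarray:
        """Ascending coefficients of the polynomial obtained at tau1=tau2=0."""
        deg = max(len(c) for c, _ in self.terms)
        out = np.zeros(deg)
        for coeffs, _ in self.terms:
            out[: len(coeffs)] += coeffs
        return out

    def coefficient(self, power: int, mult: tuple) -> float:
        """Coefficient of l**power * exp(-l*(m1*tau1 + m2*tau2))."""
        total = 0.0
        for coeffs, m in self.terms:
            if m == tuple(mult) and power < len(coeffs):
                total += coeffs[power]
        return total


def build_chi1(p: RateParamsMM, eq: Equilibrium) -> QuasiPolynomial:
    """Characteristic quasi-polynomial chi1 of the SCFE linearization."""
    return QuasiPolynomial(
        terms=[
            (np.array([0.0, 0.0, 1.0]), (0, 0)),              # l**2
            (np.array([0.0, p.k_m1]), (0, 0)),                # k_m1 * l
            (np.array([0.0, p.k1 * (eq.nS_bar + eq.nE_bar)]), (1, 0)),
            (np.array([0.0, p.k2]), (0, 1)),
            (np.array([p.k1 * p.k2 * eq.nE_bar]), (1, 1)),
        ],
        tau1=p.tau1,
        tau2=p.tau2,
    )


def pade_reduce(q: QuasiPolynomial):
    """(1,1)-Pade rational approximation of the quasi-polynomial.

    Each exp(-l*tau) factor is replaced by (1 - l*tau/2)/(1 + l*tau/2);
    all terms are expressed over the common denominator
    (1 + l*tau1/2)**M1 * (1 + l*tau2/2)**M2 where M1, M2 are the largest
    multiplicities present.  Returns ascending-coefficient arrays
    (numerator, denominator).  At zero delays the numerator is the exact
    polynomial and the denominator is 1.
    """
    M1 = max((m1 for _, (m1, _) in q.terms), default=0)
    M2 = max((m2 for _, (_, m2) in q.terms), default=0)
    plus1 = np.array([1.0, q.tau1 / 2.0])
    minus1 = np.array([1.0, -q.tau1 / 2.0])
    plus2 = np.array([1.0, q.tau2 / 2.0])
    minus2 = np.array([1.0, -q.tau2 / 2.0])

    def ppow(base, k):
        out = np.array([1.0])
        for _ in range(k):
            out = P.polymul(out, base)
        return out

    num = np.array([0.0])
    for coeffs, (m1, m2) in q.terms:
        term = np.asarray(coeffs, dtype=float)
        term = P.polymul(term, ppow(minus1, m1))
        term = P.polymul(term, ppow(plus1, M1 - m1))
        term = P.polymul(term, ppow(minus2, m2))
        term = P.polymul(term, ppow(plus2, M2 - m2))
        num = P.polyadd(num, term)
    den = P.polymul(ppow(plus1, M1), ppow(plus2, M2))
    return np.trim_zeros(num, "b"), np.trim_zeros(den, "b")


def find_roots(q: QuasiPolynomial, tol: float = 1e-12,
               dedupe_tol: float = 1e-8, max_iter: int = 100,
               full: bool = False):
    """Roots of the quasi-polynomial by Pade seeding + damped Newton.

    The numerator roots of :func:`pade_reduce` seed Newton iteration on the
    *exact* quasi-polynomial (analytic termwise derivative, step halved up
    to 20 times whenever the residual would grow), refined until
    ``|chi1(l)| < tol`` and deduplicated within ``dedupe_tol``.  Seeds that
    fail to converge are dropped with a warning rather than raising.

    With ``full=True`` returns (roots, residuals, failed_seeds).
    """
    num, _ = pade_reduce(q)
    seeds = P.polyroots(num) if len(num) > 1 else np.array([], dtype=complex)
    roots: list[complex] = []
    residuals: list[float] = []
    failed: list[complex] = []
    for seed in seeds:
        lam = complex(seed)
        ok = False
        fval = q(lam)
        for _ in range(max_iter):
            if abs(fval) < tol:
                ok = True
                break
            dval = q.derivative(lam)
            if dval == 0:
                break
            step = fval / dval
            # damped update: never accept a residual increase
            new_lam, new_f = lam, fval
            scale = 1.0
            for _ in range(20):
                cand = lam - scale * step
                cf = q(cand)
                if abs(cf) < abs(fval):
                    new_lam, new_f = cand, cf
                    break
                scale *= 0.5
            if new_lam == lam:
                break
            lam, fval = new_lam, new_f
        if not ok and abs(fval) < tol:
            ok = True
        if not ok:
            failed.append(complex(seed))
            continue
        if any(abs(lam - r) < dedupe_tol for r in roots):
            continue
        roots.append(lam)
        residuals.append(abs(fval))
    if failed:
        warnings.warn(
            f"{len(failed)} Pade seed(s) did not converge under Newton refinement",
            RuntimeWarning,
        )
    order = np.argsort([r.real for r in roots])
    roots = [roots[i] for i in order]
    residuals = [residuals[i] for i in order]
    if full:
        return roots, residuals, failed
    return roots


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

class Classification(str, Enum):
    ASYMPTOTICALLY_STABLE = "asymptotically_stable"
    MARGINALLY_STABLE = "marginally_stable"
    PERIODIC_BOUNDARY = "periodic_boundary"
    UNSTABLE = "unstable"


@dataclass
class StabilityVerdict:
    classification: Classification
    rightmost_root: complex
    roots: list
    rationale: str = ""


def classify(roots, residual_tol: float = 1e-9) -> StabilityVerdict:
    """Stability verdict for the SCFE given the chi1 roots.

    The full characteristic function is lambda**2 * chi1(lambda): the
    structural double root at the origin (two conserved quantities) sits on
    the imaginary axis, so even when every chi1 root has negative real part
    the equilibrium is only *marginally* stable, never asymptotically.  A
    chi1 root with positive real part makes it unstable; a nonzero
    conjugate pair within ``residual_tol`` of the axis marks the periodic
    (Hopf) boundary.
    """
    roots = [complex(r) for r in roots]
    if not roots:
        raise ValueError("empty root list")
    rightmost = max(roots, key=lambda r: r.real)
    if any(r.real > residual_tol for r in roots):
        cls = Classification.UNSTABLE
        why = "a chi1 root lies in the open right half-plane"
    elif any(abs(r.real) <= residual_tol and abs(r.imag) > residual_tol
             for r in roots):
        cls = Classification.PERIODIC_BOUNDARY
        why = ("a nonzero conjugate pair sits on the imaginary axis "
               "(periodic-solution boundary)")
    else:
        cls = Classification.MARGINALLY_STABLE
        why = (
            "all chi1 roots lie in the open left half-plane; the structural "
            "lambda**2 factor of chi = lambda**2 * chi1 keeps a double root "
            "on the imaginary axis, so the verdict is marginal, not "
            "asymptotic, stability"
        )
    return StabilityVerdict(classification=cls, rightmost_root=rightmost,
                            roots=roots, rationale=why)


# --------------------------------------------------------------------------
# delayed exponential and positivity
# --------------------------------------------------------------------------

_MAX_TERMS = 1_000_000


def delayed_exp(lam: float, tau: float, x: float) -> float:
    """Delayed exponential e_tau^{lam x} = sum_{n<=x/tau} lam^n (x-n tau)^n / n!.

    Equals 1 on [0, tau) and 0 for x < 0; satisfies the shift property
    d/dx e_tau^{lam x} = lam * e_tau^{lam (x - tau)}.  Unlike the ordinary
    exponential it can become negative for lam < 0 — the signature of
    positivity loss in pure-delay dynamics.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (math.isfinite(lam) and math.isfinite(x)):
        raise ValueError("arguments must be finite")
    if x < 0:
        return 0.0
    n_max = int(math.floor(x / tau + 1e-12))
    if n_max > _MAX_TERMS:
        raise OverflowError(
            "delayed_exp would need more than 1e6 terms; use the "
            "non-oscillation criterion |lam|*tau <= 1/e instead"
        )
    return 1.0 + sum(
        lam ** n * (x - n * tau) ** n / math.factorial(n)
        for n in range(1, n_max + 1)
    )


def _delayed_exp_grid(lam: float, tau: float, x: np.ndarray) -> np.ndarray:
    """Vectorized delayed exponential over a non-negative grid."""
    out = np.zeros_like(x)
    nz = x >= 0
    xs = x[nz]
    vals = np.ones_like(xs)
    n_max = int(math.floor(float(xs.max()) / tau + 1e-12)) if len(xs) else 0
    logl = math.log(abs(lam)) if lam != 0 else -math.inf
    for n in range(1, n_max + 1):
        arg = xs - n * tau
        mask = arg >= 0
        if not mask.any():
            break
        # lam^n arg^n / n! via logs for overflow safety
        with np.errstate(divide="ignore"):
            logterm = n * logl + n * np.log(np.where(mask, arg, 1.0)) - math.lgamma(n + 1)
        sign = (1.0 if lam >= 0 else (-1.0) ** n)
        vals = vals + np.where(mask, sign * np.exp(logterm), 0.0)
    out[nz] = vals
    return out


@dataclass
class PositivityReport:
    """Outcome of the three delayed-exponential positivity conditions."""

    holds: bool
    first_violation: float | None
    margins: dict = field(default_factory=dict)


def positivity_check(p: RateParamsMM, nE0: float, nS_max: float,
                     horizon: float, resolution: float = 1e-2) -> PositivityReport:
    """Scan the sufficient positivity conditions of the two-delay model.

    The three conditions require the delayed exponentials
    e_tau1^{-k1 nE0 t}, e_tau1^{-k1 nS_max t} and e_tau2^{-k2 nE0 t} to stay
    positive on [0, horizon].  Zero delays are treated as the ordinary
    (always positive) exponential limit.  When |lam|*tau <= 1/e the delayed
    exponential is provably non-oscillatory and positive for all t (the
    classical 1/e threshold of x'(t) = lam x(t-tau)), so the scan is skipped
    and the margin reported from the Lambert-W asymptotic decay rate.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    conditions = {
        "substrate_vs_enzyme": (-p.k1 * nE0, p.tau1),
        "substrate_vs_substrate_peak": (-p.k1 * nS_max, p.tau1),
        "complex_release": (-p.k2 * nE0, p.tau2),
    }
    margins: dict[str, float] = {}
    first_violation: float | None = None
    holds = True
    grid = np.arange(0.0, horizon + resolution, resolution)
    for name, (lam, tau) in conditions.items():
        if tau == 0.0 or lam == 0.0:
            margins[name] = math.exp(lam * horizon)
            continue
        if abs(lam) * tau <= 1.0 / math.e:
            # non-oscillatory regime: positive forever; asymptotic decay
            # rate s solves s = lam * exp(-s tau), i.e. s = W(lam tau)/tau
            s = float(np.real(lambertw(lam * tau))) / tau
            margins[name] = math.exp(s * horizon) / (1.0 + abs(s) * tau)
            continue
        vals = _delayed_exp_grid(lam, tau, grid)
        margins[name] = float(vals.min())
        bad = np.nonzero(vals <= 0.0)[0]
        if len(bad):
            holds = False
            i = bad[0]
            if i > 0:
                # linear refinement of the sign change
                x0, x1 = grid[i - 1], grid[i]
                v0, v1 = vals[i - 1], vals[i]
                t_star = x0 - v0 * (x1 - x0) / (v1 - v0) if v1 != v0 else x1
            else:
                t_star = grid[0]
            if first_violation is None or t_star < first_violation:
                first_violation = float(t_star)
    return PositivityReport(holds=holds, first_violation=first_violation,
                            margins=margins)
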