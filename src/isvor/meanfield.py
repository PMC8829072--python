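"""Mean-field dynamics of the ISVOR rumor model.

The five role densities I(t), S(t), V(t), O(t), R(t) evolve under a
mass-action approximation in which every individual meets ``k`` others per
unit time.  Two right-hand-side variants are provided:

``as_printed``
    The published equation system verbatim.  Its forgetting term removes
    oysters at rate ``theta*O*(S+V+O+R)`` but credits recoveries at rate
    ``theta*O``, so on the unit simplex the total density drifts at rate
    ``theta*O*I`` (an exact symbolic identity, checked in the tests).

``conserving``
    Identical except forgetting is spontaneous on both sides
    (``-theta*O`` from O, ``+theta*O`` into R), which matches the verbal
    definition of forgetting and makes the components sum to zero
    identically.  This is the default for simulation experiments.

The rumor-free states E1 = (I1, 0, 0, 0, 1-I1) form the only feasible
equilibrium family.  Linearizing around E1 in the reduced (S, V, O)
coordinates gives a 3x3 Jacobian whose diagonal carries the quantities

    U1 = mu1*k*I1 - mu1*k - xi1 - gamma + alpha*k*I1
    U2 = mu2*k*I1 - mu2*k - xi2   + lam*k*I1
    B  = theta*I1 - (beta1 + beta2)

entering the Routh–Hurwitz determinants of the characteristic cubic

    chi^3 - (U1+U2+B) chi^2 + [(U1+U2)B + U1*U2] chi - U1*U2*B = 0.

That cubic treats the Jacobian as if it were triangular; the off-diagonal
couplings (gamma, eta terms vanish at E1 only partially: beta1, beta2, xi1,
xi2, gamma remain) shift the true eigenvalues.  The numerically computed
eigenvalues of the full matrix are therefore authoritative for the
stability verdict; the Hurwitz determinants are reported alongside with a
concordance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import NumericalError, ParameterError
from .params import IsvorParams
from .trajectory import ISVOR_COLUMNS, StateVector, Trajectory

__all__ = [
    "isvor_rhs",
    "integrate",
    "equilibria",
    "Equilibrium",
    "jacobian_at_E1",
    "stability_report",
    "stability_interval",
    "StabilityReport",
    "IntervalReport",
    "closed_form_bounds",
]

Variant = Literal["as_printed", "conserving"]
_VARIANTS = ("as_printed", "conserving")

#: Tolerance below which an eigenvalue real part counts as zero (marginal).
MARGINAL_TOL = 1e-9


def _check_variant(variant: str) -> None:
    if variant not in _VARIANTS:
        raise ParameterError(
            f"unknown variant {variant!r}; expected one of {_VARIANTS}"
        )


def isvor_rhs(
    state: StateVector | Sequence[float],
    p: IsvorParams,
    variant: Variant = "conserving",
    include_epsilon: bool = False,
) -> np.ndarray:
    """Time derivative of the five densities.

    ``include_epsilon`` adds the ignorant-to-recovery contact term
    ``-k*eps*I*S`` to dI and ``+k*eps*I*S`` to dR (off by default: the
    published system omits epsilon).
    """
    _check_variant(variant)
    I, S, V, O, R = (state.as_array() if isinstance(state, StateVector)
                     else np.asarray(state, dtype=float))
    k = p.k
    active = S + V + O + R  # contact pool of the non-ignorant

    dI = -k * p.alpha * I * S - k * p.lam * I * V
    dS = (-p.mu1 * k * S * active - (p.xi1 + p.gamma) * S
          + p.alpha * k * I * S + p.beta1 * O - p.eta * k * S * V)
    dV = (-p.mu2 * k * V * active - p.xi2 * V + p.gamma * S
          + k * p.lam * I * V + p.eta * k * S * V + p.beta2 * O)
    if variant == "as_printed":
        dO = (-(p.beta1 + p.beta2) * O + p.xi1 * S + p.xi2 * V
              - p.theta * O * active)
    else:
        dO = (-(p.beta1 + p.beta2) * O + p.xi1 * S + p.xi2 * V
              - p.theta * O)
    dR = (p.theta * O + p.mu1 * k * S * active + p.mu2 * k * V * active)
    if include_epsilon and p.epsilon:
        dI -= k * p.epsilon * I * S
        dR += k * p.epsilon * I * S
    return np.array([dI, dS, dV, dO, dR])


def integrate(
    p: IsvorParams,
    init: StateVector | Sequence[float],
    t_max: float,
    variant: Variant = "conserving",
    method: Literal["rk_adaptive", "euler_dt"] = "rk_adaptive",
    dt: float = 1.0,
    n_out: int = 501,
    include_epsilon: bool = False,
) -> Trajectory:
    """Integrate the mean-field system from ``init`` to ``t_max``.

    ``rk_adaptive`` uses an adaptive Runge–Kutta (RK45, rtol 1e-8 /
    atol 1e-10) sampled at ``n_out`` evenly spaced times; ``euler_dt`` takes
    fixed explicit-Euler steps of size ``dt``, mirroring the discrete-time
    probability semantics of the agent-based chain.
    """
    _check_variant(variant)
    if not t_max > 0:
        raise ParameterError(f"t_max={t_max!r} must be positive")
    y0 = (init.as_array() if isinstance(init, StateVector)
          else np.asarray(init, dtype=float))

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return isvor_rhs(y, p, variant, include_epsilon)

    meta: dict[str, Any] = {
        "variant": variant, "method": method, "params": p.as_dict(),
        "include_epsilon": include_epsilon,
    }
    if method == "rk_adaptive":
        t_eval = np.linspace(0.0, t_max, n_out)
        sol = solve_ivp(rhs, (0.0, t_max), y0, method="RK45",
                        rtol=1e-8, atol=1e-10, t_eval=t_eval)
        if not sol.success:
            raise NumericalError(f"RK45 failed: {sol.message}")
        times, data = sol.t, sol.y.T
    elif method == "euler_dt":
        if not dt > 0:
            raise ParameterError(f"dt={dt!r} must be positive")
        n_steps = int(np.ceil(t_max / dt))
        times = np.arange(n_steps + 1) * dt
        data = np.empty((n_steps + 1, 5))
        data[0] = y0
        y = y0.copy()
        for i in range(n_steps):
            y = y + dt * rhs(times[i], y)
            data[i + 1] = y
        meta["dt"] = dt
    else:
        raise ParameterError(f"unknown integration method {method!r}")
    return Trajectory(times, data, ISVOR_COLUMNS, meta)


# ---------------------------------------------------------------------------
# Equilibria

@dataclass(frozen=True)
class Equilibrium:
    """One equilibrium candidate with its feasibility analysis."""

    label: str                 # "E1", "E2", "E3"
    description: str
    feasible: bool
    reason: str
    degenerate: bool = False


def equilibria(p: IsvorParams) -> list[Equilibrium]:
    """Enumerate the stationary-state candidates of the mean-field flow.

    The rumor-free family E1 = (I1, 0, 0, 0, 1-I1) is feasible for every
    I1 in [0, 1].  Candidates with active compartments are infeasible:
    summing the stationarity conditions forces mu1*k*S + mu2*k*V + theta*O
    = 0, so any strictly positive S, V or O contradicts stationarity (E2);
    with I > 0 as well, dI = 0 forces alpha*k*I*S + lam*k*I*V = 0, again a
    contradiction (E3).  If every rate is zero the flow vanishes and all
    states are stationary; that degeneracy is flagged.
    """
    degenerate = all(
        getattr(p, name) == 0.0 for name in p.probability_fields
    )
    out = [
        Equilibrium(
            "E1", "(I1, 0, 0, 0, 1-I1) for any I1 in [0, 1]",
            feasible=True,
            reason="all contact and transition terms vanish when S=V=O=0",
            degenerate=degenerate,
        ),
        Equilibrium(
            "E2", "(0, S2, V2, O2, 1-S2-V2-O2) with S2,V2,O2 > 0",
            feasible=degenerate,
            reason=("stationarity forces mu1*k*S2 + mu2*k*V2 + theta*O2 = 0, "
                    "impossible for positive compartments"
                    if not degenerate else
                    "all rates zero: every state is stationary"),
            degenerate=degenerate,
        ),
        Equilibrium(
            "E3", "(I3, S3, V3, O3, ...) with every compartment > 0",
            feasible=degenerate,
            reason=("dI = 0 forces alpha*k*I3*S3 + lam*k*I3*V3 = 0, "
                    "impossible for positive compartments"
                    if not degenerate else
                    "all rates zero: every state is stationary"),
            degenerate=degenerate,
        ),
    ]
    return out


def jacobian_at_E1(p: IsvorParams, I1: float) -> np.ndarray:
    """Reduced (S, V, O) Jacobian of the linearization at E1(I1).

    Published convention: the (3,3) entry is ``theta*I1 - (beta1+beta2)``
    (see :func:`stability_report` for the alternative linearization of the
    as-printed forgetting term).
    """
    if not (0.0 <= I1 <= 1.0):
        raise ParameterError(f"I1={I1!r} outside [0, 1]")
    k = p.k
    u1 = p.mu1 * k * I1 - p.mu1 * k - p.xi1 - p.gamma + p.alpha * k * I1
    u2 = p.mu2 * k * I1 - p.mu2 * k - p.xi2 + p.lam * k * I1
    b = p.theta * I1 - (p.beta1 + p.beta2)
    return np.array([
        [u1, 0.0, p.beta1],
        [p.gamma, u2, p.beta2],
        [p.xi1, p.xi2, b],
    ])


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability analysis of E1(I1)."""

    I1: float
    U1: float
    U2: float
    B: float
    B_linearized: float        # theta*I1 - theta - (beta1+beta2)
    delta1: float
    delta2: float
    delta3: float
    eigenvalues: np.ndarray
    verdict: Literal["stable", "unstable", "marginal"]
    hurwitz_positive: bool
    hurwitz_concordant: bool   # Hurwitz-positive implies eigenvalue-stable?
    b_sign_flip: bool          # printed B and linearized B disagree in sign


def _uub(p: IsvorParams, I1: float) -> tuple[float, float, float]:
    k = p.k
    u1 = p.mu1 * k * I1 - p.mu1 * k - p.xi1 - p.gamma + p.alpha * k * I1
    u2 = p.mu2 * k * I1 - p.mu2 * k - p.xi2 + p.lam * k * I1
    b = p.theta * I1 - (p.beta1 + p.beta2)
    return u1, u2, b


def stability_report(p: IsvorParams, I1: float) -> StabilityReport:
    """Hurwitz determinants and numerical eigenvalues of E1(I1).

    The verdict follows the maximum eigenvalue real part (stable below
    ``-MARGINAL_TOL``, unstable above ``+MARGINAL_TOL``, marginal between);
    the Hurwitz block is reported as printed and a flag records whether its
    positivity agrees with the eigenvalue verdict.
    """
    if not (0.0 <= I1 <= 1.0):
        raise ParameterError(f"I1={I1!r} outside [0, 1]")
    u1, u2, b = _uub(p, I1)
    d1 = -(u1 + u2 + b)
    d2 = -(u1 + u2 + b) * ((u1 + u2) * b + u1 * u2) - u1 * u2 * b
    d3 = -u1 * u2 * b
    eig = np.linalg.eigvals(jacobian_at_E1(p, I1))
    mx = float(np.max(eig.real))
    if mx < -MARGINAL_TOL:
        verdict = "stable"
    elif mx > MARGINAL_TOL:
        verdict = "unstable"
    else:
        verdict = "marginal"
    hurwitz_positive = d1 > 0 and d2 > 0 and d3 > 0
    b_lin = p.theta * I1 - p.theta - (p.beta1 + p.beta2)
    return StabilityReport(
        I1=I1, U1=u1, U2=u2, B=b, B_linearized=b_lin,
        delta1=d1, delta2=d2, delta3=d3,
        eigenvalues=eig, verdict=verdict,
        hurwitz_positive=hurwitz_positive,
        hurwitz_concordant=(not hurwitz_positive) or verdict == "stable",
        b_sign_flip=(b > 0) != (b_lin > 0) and abs(b) > 0,
    )


def closed_form_bounds(p: IsvorParams) -> dict[str, float]:
    """Closed-form I1 values where U1, U2 and B change sign.

    ``u2_crossing`` solves U2 = 0, i.e. (mu2*k + xi2)/(mu2*k + lam*k); the
    published two-case bound instead prints (mu2*k + xi1 + gamma)/(mu2*k +
    lam*k), which is returned as ``u2_crossing_printed_comparison`` — U2 is
    the quantity that actually enters the Hurwitz conditions.
    """
    k = p.k
    out: dict[str, float] = {}
    den1 = p.mu1 * k + p.alpha * k
    den2 = p.mu2 * k + p.lam * k
    if den1 > 0:
        out["u1_crossing"] = (p.mu1 * k + p.xi1 + p.gamma) / den1
    if den2 > 0:
        out["u2_crossing"] = (p.mu2 * k + p.xi2) / den2
        out["u2_crossing_printed_comparison"] = (
            (p.mu2 * k + p.xi1 + p.gamma) / den2
        )
    if p.theta > 0:
        out["b_crossing"] = (p.beta1 + p.beta2) / p.theta
    return out


@dataclass(frozen=True)
class IntervalReport:
    """Stable I1 ranges of E1 plus the closed-form crossing candidates."""

    stable_intervals: tuple[tuple[float, float], ...]
    candidate_bounds: dict[str, float]
    degenerate: bool = False


def stability_interval(
    p: IsvorParams, grid: int = 2001, tol: float = 1e-12
) -> IntervalReport:
    """Scan I1 in [0, 1] for eigenvalue-stable stretches of E1.

    The maximum eigenvalue real part is evaluated on a uniform grid;
    boundaries between stable and unstable stretches are refined by
    bisection to ``tol``.  The closed-form sign-change candidates of U1,
    U2 and B are reported alongside for comparison.
    """
    degenerate = all(getattr(p, f) == 0.0 for f in p.probability_fields)
    bounds = closed_form_bounds(p)
    if degenerate:
        return IntervalReport((), bounds, degenerate=True)

    def spectral_abscissa(i1: float) -> float:
        return float(np.max(np.linalg.eigvals(jacobian_at_E1(p, i1)).real))

    xs = np.linspace(0.0, 1.0, grid)
    vals = np.array([spectral_abscissa(x) for x in xs])
    stable = vals < 0
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < grid:
        if stable[i]:
            j = i
            while j + 1 < grid and stable[j + 1]:
                j += 1
            lo, hi = xs[i], xs[j]
            # refine the boundaries where a sign change brackets them
            if i > 0 and not stable[i - 1]:
                lo = brentq(spectral_abscissa, xs[i - 1], xs[i], xtol=tol)
            if j + 1 < grid and not stable[j + 1]:
                hi = brentq(spectral_abscissa, xs[j], xs[j + 1], xtol=tol)
            intervals.append((float(lo), float(hi)))
            i = j + 1
        else:
            i += 1
    return IntervalReport(tuple(intervals), bounds, degenerate=False)
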