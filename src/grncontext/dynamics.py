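"""ODE model of the three-repressor cascade with transcriptional read-through.

Each repressor X is produced by its own promoter and degraded linearly:

    dX/dt = A'_X + rchi_X - delta * X

with own-promoter activities

    A'_L = A'_T = max(0, k_L - (1 - I1) * L / (K + L))      (P_lac, LacI, IPTG)
    A'_C         = max(0, k_C - (1 - I2) * T / (K + T))      (P_tet, TetR, aTc)

Repression is subtractive, exactly in this form, clamped at zero so variant
parameters (e.g. a promoter knockout, k_C = 0) stay physical.

``rchi_X`` is the transcriptional read-through into X: if the slot
immediately upstream of X *in X's transcription direction* holds a TU of
the same orientation, RNA polymerase reading through the junction
terminator contributes ``mu_junction * A'_upstream``, where A' is the
upstream TU's own-promoter activity.  Convergent or divergent neighbours
contribute nothing, and read-through does not chain past one junction
unless the optional second-order term is enabled (then a same-orientation
TU two slots upstream adds ``mu1 * mu2 * A''``).

Reduced parameterization: k_L = k_C = 1, delta = 1, K_L = K_T = K, leaving
the half-repression point K and the read-through rate mu as the two free
parameters; the logic threshold on cI is tau = 2/5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .arrangements import (
    FORWARD,
    GENES,
    Arrangement,
    PROMOTER_BY_GENE,
    TerminatorSpec,
)

__all__ = [
    "ModelParameters",
    "InducerState",
    "CANONICAL_STATES",
    "STATE_NAMES",
    "SteadyState",
    "ReadthroughInput",
    "TruthTableResult",
    "DoseResponseParams",
    "promoter_activity",
    "readthrough_inputs",
    "rhs",
    "steady_state",
    "truth_table",
    "truth_table_grid",
    "apply_variant",
    "lac_induction_curve",
]


@dataclass(frozen=True)
class ModelParameters:
    """Reduced model parameters (all dimensionless).

    k_L : constitutive rate of the two P_lac-driven TUs (lacI, tetR)
    k_C : constitutive rate of the P_tet-driven TU (cI)
    delta : first-order degradation/dilution rate
    K : half-repression point shared by P_lac and P_tet
    mu : default junction read-through rate in [0, 1]
    tau : logic threshold on normalized cI, in (0, 1)
    chain_readthrough : enable the second-order mu^2 chain term (default off)
    """

    k_L: float = 1.0
    k_C: float = 1.0
    delta: float = 1.0
    K: float = 0.1
    mu: float = 0.0
    tau: float = 0.4
    chain_readthrough: bool = False

    def __post_init__(self) -> None:
        if min(self.k_L, self.k_C, self.delta) < 0:
            raise ValueError("rates must be non-negative")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must be in (0, 1)")
        if self.delta == 0:
            raise ValueError("delta must be positive (steady state undefined otherwise)")

    def with_(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class InducerState:
    """Inducer occupancies: iptg = I1 (lifts LacI), atc = I2 (lifts TetR).

    Binary {0, 1} in the core model; fractional values in [0, 1] are allowed
    for the dose-response extension.
    """

    iptg: float
    atc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.iptg <= 1.0 and 0.0 <= self.atc <= 1.0):
            raise ValueError("inducer values must lie in [0, 1]")


#: Canonical environment order: (none, IPTG, aTc, IPTG+aTc).
CANONICAL_STATES = (
    InducerState(0, 0),
    InducerState(1, 0),
    InducerState(0, 1),
    InducerState(1, 1),
)
STATE_NAMES = ("none", "IPTG", "aTc", "both")


@dataclass(frozen=True)
class SteadyState:
    L: float
    T: float
    C: float
    residual: float
    converged: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.T, self.C])


@dataclass(frozen=True)
class ReadthroughInput:
    """Additive read-through production terms per gene."""

    rchi_L: float
    rchi_T: float
    rchi_C: float

    def for_gene(self, gene: str) -> float:
        return {"lacI": self.rchi_L, "tetR": self.rchi_T, "cI": self.rchi_C}[gene]


def promoter_activity(
    promoter: str,
    repressor_conc: float,
    inducer_value: float,
    params: ModelParameters,
) -> float:
    """Own-promoter transcription rate: max(0, k - (1-I) * R / (K + R))."""
    if repressor_conc < 0:
        raise ValueError(f"negative repressor concentration {repressor_conc}")
    k = params.k_L if promoter == "P_lac" else params.k_C
    rep = (1.0 - inducer_value) * repressor_conc / (params.K + repressor_conc)
    return max(0.0, k - rep)


def _upstream_slot(a: Arrangement, i: int) -> int | None:
    """Slot immediately upstream of slot i in its transcription direction,
    if it exists and shares slot i's orientation."""
    ori = a.slots[i][1]
    j = i - 1 if ori == FORWARD else i + 1
    if 0 <= j < 3 and a.slots[j][1] == ori:
        return j
    return None


def readthrough_inputs(
    a: Arrangement,
    activities_by_slot: Sequence[float],
    rates_by_junction: Sequence[float],
    chain: bool = False,
) -> ReadthroughInput:
    """Read-through terms given current own-promoter activities per slot.

    ``rates_by_junction`` are the two numeric junction rates (already
    evaluated at the model mu).  With ``chain`` enabled, a same-orientation
    TU two junctions upstream contributes the product of both rates.
    """
    rchi = {g: 0.0 for g in GENES}
    for i, (gene, _) in enumerate(a.slots):
        j = _upstream_slot(a, i)
        if j is None:
            continue
        r1 = rates_by_junction[min(i, j)]
        rchi[gene] += r1 * activities_by_slot[j]
        if chain:
            k2 = _upstream_slot(a, j)
            if k2 is not None:
                r2 = rates_by_junction[min(j, k2)]
                rchi[gene] += r1 * r2 * activities_by_slot[k2]
    return ReadthroughInput(rchi["lacI"], rchi["tetR"], rchi["cI"])


def _junction_rates(a: Arrangement, params: ModelParameters) -> tuple[float, float]:
    return tuple(spec.rate(params.mu) for spec in a.junctions)  # type: ignore[return-value]


def _slot_activities(
    a: Arrangement, L: float, T: float, env: InducerState, params: ModelParameters
) -> list[float]:
    acts = []
    for gene, _ in a.slots:
        promoter = PROMOTER_BY_GENE[gene]
        if promoter == "P_lac":
            acts.append(promoter_activity(promoter, max(L, 0.0), env.iptg, params))
        else:
            acts.append(promoter_activity(promoter, max(T, 0.0), env.atc, params))
    return acts


def rhs(
    state: Sequence[float],
    a: Arrangement,
    env: InducerState,
    params: ModelParameters,
) -> np.ndarray:
    """Time derivatives (dL, dT, dC) at ``state`` = (L, T, C)."""
    L, T, C = state
    acts = _slot_activities(a, L, T, env, params)
    rchi = readthrough_inputs(
        a, acts, _junction_rates(a, params), chain=params.chain_readthrough
    )
    conc = {"lacI": L, "tetR": T, "cI": C}
    deriv = {}
    for i, (gene, _) in enumerate(a.slots):
        deriv[gene] = acts[i] + rchi.for_gene(gene) - params.delta * conc[gene]
    return np.array([deriv["lacI"], deriv["tetR"], deriv["cI"]])


def _production(
    state: np.ndarray, a: Arrangement, env: InducerState, params: ModelParameters
) -> np.ndarray:
    """Total production vector (A' + rchi) per gene, in (L, T, C) order."""
    return rhs(state, a, env, params) + params.delta * np.asarray(state, dtype=float)


_DAMPING = 0.4  # keeps the picard map contractive for mu up to 1 (see methods note)


def _fixed_point(
    a: Arrangement,
    env: InducerState,
    params: ModelParameters,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> np.ndarray:
    x = np.array([params.k_L, params.k_L, params.k_C]) / params.delta if x0 is None else np.asarray(x0, float)
    for _ in range(max_iter):
        nxt = _production(x, a, env, params) / params.delta
        if np.max(np.abs(nxt - x)) < tol:
            return nxt
        x = (1.0 - _DAMPING) * x + _DAMPING * nxt
    return x


def steady_state(
    a: Arrangement,
    env: InducerState,
    params: ModelParameters,
    method: str = "fixed_point",
    tol: float = 1e-10,
    t_max: float = 1e4,
    x0: Sequence[float] | None = None,
) -> SteadyState:
    """Steady state of the cascade in one inducer environment.

    ``method="fixed_point"`` (default): damped Picard iteration on the
    production map, polished by a Newton-type root find — fast and exact
    for this monotone system.  ``method="ode"``: stiff-safe integration
    from the origin (or ``x0``) until the residual drops below ``tol``,
    cross-validated by the same root polish.  Non-convergence is flagged,
    never silent.
    """
    fun = lambda x: rhs(x, a, env, params)

    if method == "fixed_point":
        x = _fixed_point(a, env, params)
    elif method == "ode":
        x = np.zeros(3) if x0 is None else np.asarray(x0, dtype=float)
        t = 0.0
        span = 50.0
        while t < t_max:
            sol = solve_ivp(
                lambda _t, y: fun(y),
                (0.0, span),
                x,
                method="LSODA",
                rtol=1e-10,
                atol=1e-12,
            )
            x = sol.y[:, -1]
            t += span
            span *= 4.0
            if np.max(np.abs(fun(x))) < tol:
                break
    else:
        raise ValueError(f"unknown method {method!r}")

    # Root polish; reject a polish that wanders away from the integrator end.
    polished = root(fun, x, method="hybr", tol=1e-13)
    if polished.success and np.max(np.abs(polished.x - x)) < 1e-6:
        x = polished.x
    x = np.where(np.abs(x) < 1e-13, 0.0, x)
    residual = float(np.max(np.abs(fun(x))))
    converged = residual <= tol and bool(np.all(x >= -1e-9))
    return SteadyState(float(x[0]), float(x[1]), float(x[2]), residual, converged)


@dataclass(frozen=True)
class TruthTableResult:
    """Steady states over the four canonical environments + raw cI vector."""

    arrangement: Arrangement
    states: tuple[SteadyState, SteadyState, SteadyState, SteadyState]
    cI: np.ndarray  # shape (4,), canonical state order

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.states)


def truth_table(
    a: Arrangement, params: ModelParameters, method: str = "fixed_point"
) -> TruthTableResult:
    """Raw cI steady-state values in canonical order (none, IPTG, aTc, both).

    Normalization and thresholding live in :mod:`grncontext.phenotype`.
    """
    states = tuple(steady_state(a, env, params, method=method) for env in CANONICAL_STATES)
    cI = np.array([s.C for s in states])
    return TruthTableResult(a, states, cI)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Vectorized grid path (used by the (K, mu) grid search)
# ---------------------------------------------------------------------------

def readthrough_config(a: Arrangement, chain: bool = False):
    """Hashable read-through wiring of an arrangement.

    Per gene (L, T, C order): tuple of terms ``(source_promoter, coeff,
    mu_power)`` with junction rate = coeff * mu**mu_power; coeff None means 1.
    Arrangements with equal configs have identical truth tables — notably
    every arrangement and its whole-cassette flip.
    """
    terms = {g: [] for g in GENES}

    def _spec_key(spec: TerminatorSpec):
        return (spec.readthrough_rate, spec.mu_power)

    for i, (gene, _) in enumerate(a.slots):
        j = _upstream_slot(a, i)
        if j is None:
            continue
        src = PROMOTER_BY_GENE[a.slots[j][0]]
        coeff, power = _spec_key(a.junctions[min(i, j)])
        terms[gene].append((src, coeff, power))
        if chain:
            k2 = _upstream_slot(a, j)
            if k2 is not None:
                src2 = PROMOTER_BY_GENE[a.slots[k2][0]]
                c2, p2 = _spec_key(a.junctions[min(j, k2)])
                cc = (1.0 if coeff is None else coeff) * (1.0 if c2 is None else c2)
                terms[gene].append((src2, cc, power + p2))
    return tuple(tuple(terms[g]) for g in GENES)


def _grid_steady(config, K, mu, env: InducerState, params: ModelParameters):
    """Vectorized steady state over broadcast K/mu arrays for one wiring.

    Returns (L, T, C) arrays.  The (L, T) subsystem is closed (cI feeds
    back on nothing), so C follows explicitly once (L, T) converge.
    """
    K = np.asarray(K, dtype=float)
    mu = np.asarray(mu, dtype=float)
    K, mu = np.broadcast_arrays(K, mu)
    I1, I2 = env.iptg, env.atc
    kL, kC, delta = params.k_L, params.k_C, params.delta

    def g(L):
        return np.maximum(0.0, kL - (1.0 - I1) * L / (K + L))

    def h(T):
        return np.maximum(0.0, kC - (1.0 - I2) * T / (K + T))

    def rchi(gene_terms, L, T):
        total = 0.0
        for src, coeff, power in gene_terms:
            c = 1.0 if coeff is None else coeff
            act = g(L) if src == "P_lac" else h(T)
            total = total + c * mu**power * act
        return total

    cfg_L, cfg_T, cfg_C = config
    L = np.full(K.shape, kL / delta)
    T = np.full(K.shape, kL / delta)
    for _ in range(4000):
        gL = g(L)
        nL = (gL + rchi(cfg_L, L, T)) / delta
        nT = (gL + rchi(cfg_T, L, T)) / delta
        err = max(np.max(np.abs(nL - L)), np.max(np.abs(nT - T)))
        if err < 1e-13:
            L, T = nL, nT
            break
        L = (1.0 - _DAMPING) * L + _DAMPING * nL
        T = (1.0 - _DAMPING) * T + _DAMPING * nT
    else:  # pragma: no cover - safety net
        raise RuntimeError("vectorized steady-state iteration did not converge")
    C = (h(T) + rchi(cfg_C, L, T)) / delta
    return L, T, C


def truth_table_grid(a_or_config, K, mu, params: ModelParameters | None = None) -> np.ndarray:
    """Raw cI values for the four canonical environments over a (K, mu) grid.

    Returns an array of shape ``(4,) + broadcast(K, mu).shape``.  Accepts an
    :class:`Arrangement` or a precomputed :func:`readthrough_config`.
    """
    params = params or ModelParameters()
    config = (
        readthrough_config(a_or_config, chain=params.chain_readthrough)
        if isinstance(a_or_config, Arrangement)
        else a_or_config
    )
    return np.stack(
        [_grid_steady(config, K, mu, env, params)[2] for env in CANONICAL_STATES]
    )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def apply_variant(
    a: Arrangement,
    params: ModelParameters,
    variant: str,
    junction: int | None = None,
    spec: TerminatorSpec | None = None,
    spec2: TerminatorSpec | None = None,
) -> tuple[Arrangement, ModelParameters]:
    """Model variants probing the read-through mechanism.

    - ``"ptet_minus10"``: the -10 box of P_tet is mutated away; cI's
      own-promoter rate k_C becomes 0 while read-through into cI is intact.
    - ``"terminator_swap"``: replace the terminator at ``junction`` with
      ``spec``.
    - ``"double_terminator"``: put ``spec`` and ``spec2`` in series at
      ``junction``; read-through probabilities multiply.
    """
    if variant == "ptet_minus10":
        return a, params.with_(k_C=0.0)
    if variant == "terminator_swap":
        if junction is None or spec is None:
            raise ValueError("terminator_swap needs junction and spec")
        return a.with_junction(junction, spec), params
    if variant == "double_terminator":
        if junction is None or spec is None or spec2 is None:
            raise ValueError("double_terminator needs junction, spec and spec2")
        return a.with_junction(junction, spec.combined(spec2)), params
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Continuous-induction extension (chromosomal lacI context)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseParams:
    """IPTG dose-response mapping to fractional LacI inactivation.

    Hill coefficient and EC50 (in µM) are package defaults for the
    continuous-induction extension, not fitted quantities.
    """

    hill: float = 2.0
    ec50: float = 100.0

    def occupancy(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        with np.errstate(divide="ignore", invalid="ignore"):
            occ = np.where(
                c > 0, c**self.hill / (c**self.hill + self.ec50**self.hill), 0.0
            )
        return occ


def lac_induction_curve(
    mu_upstream: float,
    upstream_activity: float,
    iptg_concentrations: Sequence[float],
    params: ModelParameters | None = None,
    dose: DoseResponseParams | None = None,
) -> np.ndarray:
    """P_lac reporter output vs IPTG when lacI sits downstream of an active TU.

    Models the single-repressor chromosomal-context experiment: LacI supply
    is its autoregulated own production plus ``mu_upstream *
    upstream_activity`` read-through from the gene upstream of its locus;
    the readout is the activity of a separately integrated P_lac-yfp
    reporter.  A weaker upstream terminator (larger ``mu_upstream``)
    depresses the mid-range of the induction curve.
    """
    if not 0.0 <= mu_upstream <= 1.0:
        raise ValueError("mu_upstream must be in [0, 1]")
    params = params or ModelParameters()
    dose = dose or DoseResponseParams()
    extra = mu_upstream * upstream_activity
    out = []
    for I1 in dose.occupancy(iptg_concentrations):
        def balance(L: float) -> float:
            return promoter_activity("P_lac", L, I1, params) + extra - params.delta * L

        hi = (params.k_L + extra) / params.delta + 1.0
        L_star = brentq(balance, 0.0, hi, xtol=1e-14)
        out.append(promoter_activity("P_lac", L_star, I1, params))
    return np.array(out)
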