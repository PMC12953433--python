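"""Exchange-rate estimation and expression-constrained flux prediction.

Strain-specific uptake/excretion rates are estimated from batch
time-series via an exponential growth model and the integrated mass
balance; intracellular fluxes are then predicted with E-Flux2:
proteomics-scaled flux bounds, objective maximization, and a
minimum-norm flux among the optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.linalg
import scipy.optimize

from .network import MetabolicModel, Reaction

__all__ = [
    "GrowthFit",
    "ExchangeRateSet",
    "FluxEstimate",
    "fit_exponential_growth",
    "estimate_exchange_rate",
    "reaction_expression",
    "eflux2",
]


@dataclass
class GrowthFit:
    """Exponential growth fit X(t) = X0 exp(mu t)."""

    mu: float  # specific growth rate, 1/h
    X0: float  # initial biomass, gDCW/L
    r_squared: float


@dataclass
class ExchangeRateSet:
    """Specific exchange rates in mmol gDCW^-1 h^-1.

    Sign convention: uptake negative, excretion positive, matching the
    usual exchange-reaction orientation (positive flux exports)."""

    strain_id: str
    rates: dict[str, float]


@dataclass
class FluxEstimate:
    strain_id: str
    v: np.ndarray | None
    objective_value: float
    status: str  # "optimal" | "infeasible"


def fit_exponential_growth(times: np.ndarray, biomass: np.ndarray) -> GrowthFit:
    """Least-squares fit of log X = log X0 + mu t."""
    t = np.asarray(times, dtype=float)
    X = np.asarray(biomass, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    if np.any(X <= 0):
        raise ValueError("biomass must be strictly positive")
    coef = np.polynomial.polynomial.polyfit(t, np.log(X), 1)
    logX0, mu = coef
    pred = logX0 + mu * t
    ss_res = float(np.sum((np.log(X) - pred) ** 2))
    ss_tot = float(np.sum((np.log(X) - np.log(X).mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GrowthFit(mu=float(mu), X0=float(np.exp(logX0)), r_squared=r2)


def estimate_exchange_rate(
    times: np.ndarray, concentration: np.ndarray, growth: GrowthFit
) -> float:
    """Specific exchange rate q from the integrated batch mass balance.

    With exponential biomass X(t) = X0 exp(mu t), a constant specific
    rate q gives S(t) = S0 + (q X0 / mu)(exp(mu t) - 1); q and S0 are
    obtained by linear least squares.  For mu ~ 0 the balance
    degenerates to S(t) = S0 + q X0 t.  Negative q is uptake, positive
    is excretion.
    """
    t = np.asarray(times, dtype=float)
    S = np.asarray(concentration, dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        raise ValueError("degenerate time grid")
    if abs(growth.mu) > 1e-12:
        basis = (np.exp(growth.mu * t) - 1.0) * growth.X0 / growth.mu
    else:
        basis = growth.X0 * t
    A = np.column_stack([np.ones_like(t), basis])
    coef, *_ = np.linalg.lstsq(A, S, rcond=None)
    return float(coef[1])


def exchange_rates_from_series(
    model: MetabolicModel, timeseries, strain: str
) -> tuple[GrowthFit, ExchangeRateSet]:
    """Per-strain exchange rates from a long-format batch time-series.

    ``timeseries`` columns: strain, replicate, time_h, analyte, value
    with a ``biomass`` analyte (gDCW/L) plus one analyte per measured
    external metabolite (mmol/L).  Replicates are averaged per time
    point before fitting (rates are a strain-level quantity here).
    Species rates are converted to exchange-reaction fluxes through the
    reaction's stoichiometric coefficient for that species.
    """
    sub = timeseries[timeseries["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no time-series rows for strain {strain!r}")
    mean = (sub.groupby(["analyte", "time_h"])["value"].mean().reset_index())
    bio = mean[mean["analyte"] == "biomass"].sort_values("time_h")
    growth = fit_exponential_growth(bio["time_h"].values, bio["value"].values)
    rates: dict[str, float] = {}
    species_rate: dict[str, float] = {}
    for analyte, grp in mean[mean["analyte"] != "biomass"].groupby("analyte"):
        grp = grp.sort_values("time_h")
        species_rate[analyte] = estimate_exchange_rate(
            grp["time_h"].values, grp["value"].values, growth)
    for rxn in model.reactions:
        if not rxn.is_exchange:
            continue
        for met, coef in rxn.stoichiometry.items():
            if met in species_rate:
                rates[rxn.id] = species_rate[met] / coef
                break
    return growth, ExchangeRateSet(strain_id=strain, rates=rates)


# ---------------------------------------------------------------------------
# E-Flux2
# ---------------------------------------------------------------------------

def reaction_expression(
    rxn: Reaction, protein_values: Mapping[str, float]
) -> float | None:
    """Aggregate protein abundances onto a reaction through its GPR.

    Isozyme groups (OR) sum; subunits within a complex (AND) take the
    minimum.  Returns None when the reaction has no associated protein
    or none of its proteins were measured (-> unconstrained bound).
    """
    if not rxn.gpr:
        return None
    groups = []
    for grp in rxn.gpr:
        vals = [protein_values[p] for p in grp if p in protein_values]
        if len(vals) == len(grp):
            groups.append(min(vals))
    if not groups:
        return None
    return float(sum(groups))


def eflux2(
    model: MetabolicModel,
    expression: Mapping[str, float],
    exchange_rates: ExchangeRateSet,
    objective_reaction: str,
    *,
    flux_ceiling: float = 100.0,
    exchange_band: float = 0.05,
    unbounded_value: float | None = None,
) -> FluxEstimate:
    """Two-phase expression-constrained flux estimate.

    Phase 1 maximizes the objective flux subject to N v = 0, measured
    exchange fluxes held inside a +-``exchange_band`` relative band, and
    |v_i| <= bound_i where bound_i = flux_ceiling x (expression_i / max
    expression).  Phase 2 returns, among the phase-1 optima, the flux of
    minimum Euclidean norm (the E-Flux2 uniqueness criterion).

    ``expression`` maps reaction ids to non-negative per-reaction
    expression values (see :func:`reaction_expression`); reactions
    absent from the map are bounded only by the flux ceiling.
    """
    nr = model.n_reactions
    if unbounded_value is None:
        unbounded_value = flux_ceiling
    expr = {k: float(v) for k, v in expression.items()}
    if any(v < 0 for v in expr.values()):
        raise ValueError("expression values must be non-negative")
    emax = max(expr.values()) if expr else 1.0
    if emax <= 0:
        emax = 1.0

    lb = np.empty(nr)
    ub = np.empty(nr)
    for j, rxn in enumerate(model.reactions):
        if rxn.id in expr:
            bound = flux_ceiling * expr[rxn.id] / emax
        else:
            bound = unbounded_value
        ub[j] = bound
        lb[j] = -bound if rxn.reversible else 0.0
    # measured exchange fluxes: tolerance band around the measurement
    for rid, rate in exchange_rates.rates.items():
        j = model.reaction_index(rid)
        if not model.reactions[j].is_exchange:
            raise ValueError(f"{rid!r} is not an exchange reaction")
        half = exchange_band * abs(rate)
        lb[j], ub[j] = rate - half, rate + half

    jobj = model.reaction_index(objective_reaction)
    c = np.zeros(nr)
    c[jobj] = -1.0  # maximize
    res = scipy.optimize.linprog(
        c, A_eq=model.N, b_eq=np.zeros(model.n_internal),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if not res.success:
        return FluxEstimate(exchange_rates.strain_id, None, np.nan, "infeasible")
    opt = -res.fun

    # phase 2: min ||v||^2 with the objective pinned at its optimum
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[jobj] = ub2[jobj] = opt
    v = _min_norm_flux(model.N, lb2, ub2, res.x)
    return FluxEstimate(exchange_rates.strain_id, v, float(opt), "optimal")


def _min_norm_flux(
    N: np.ndarray, lb: np.ndarray, ub: np.ndarray, start: np.ndarray
) -> np.ndarray:
    """Minimize ||v||^2 s.t. N v = 0 and lb <= v <= ub.

    Fixed coordinates (lb == ub) are eliminated; the unconstrained-KKT
    (pure equality) solution is used when it respects the box, otherwise
    SLSQP refines from the phase-1 vertex.
    """
    fixed = np.isclose(lb, ub)
    free = ~fixed
    # equality system over free coords: N_f v_f = -N_fix v_fix
    rhs = -N[:, fixed] @ lb[fixed] if fixed.any() else np.zeros(N.shape[0])
    Nf = N[:, free]
    v = np.zeros(len(lb))
    v[fixed] = lb[fixed]
    # min-norm solution of Nf v_f = rhs
    vf = np.linalg.lstsq(Nf, rhs, rcond=None)[0]
    if np.all(vf >= lb[free] - 1e-9) and np.all(vf <= ub[free] + 1e-9):
        v[free] = np.clip(vf, lb[free], ub[free])
        return v

    res = scipy.optimize.minimize(
        lambda x: float(x @ x),
        np.clip(start[free], lb[free], ub[free]),
        jac=lambda x: 2.0 * x,
        constraints=[{
            "type": "eq",
            "fun": lambda x: Nf @ x - rhs,
            "jac": lambda x: Nf,
        }],
        bounds=list(zip(lb[free], ub[free])),
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    v[free] = res.x
    return v
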