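"""Lin-log kinetics: rate law, steady-state solve, and control coefficients.

The rate law linearizes enzyme kinetics around a reference steady state:

    v = diag(v*) (e/e*) o (1 + eps_x log(x/x*) + eps_y log(y/y*))

where ``o`` is the elementwise product, ``eps_x`` / ``eps_y`` are the
elasticity matrices toward internal and external metabolites, and the
asterisked quantities define the reference state.  Because the rate is
linear in the log metabolite deviations, the steady-state condition
``N v = 0`` is a single linear system in ``log(x/x*)``, and flux and
concentration control coefficients follow analytically from the
implicit function theorem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MetabolicModel, ReferenceState

__all__ = [
    "ElasticityMatrices",
    "PerturbationState",
    "SteadyStateSolution",
    "ControlCoefficients",
    "linlog_rates",
    "solve_steady_state",
    "control_coefficients",
    "simulate_strain",
    "save_elasticities",
    "load_elasticities",
    "KNOCKOUT_FLOOR",
    "SingularSystemError",
]

#: enzyme fold-change used to represent a deletion; the lin-log rate law
#: is undefined at e = 0, so knockouts are encoded as strong repression.
KNOCKOUT_FLOOR = 0.05

#: condition number above which a steady-state solve is flagged singular
COND_THRESHOLD = 1e10


class SingularSystemError(np.linalg.LinAlgError):
    """Steady-state system is singular and pseudoinverse mode is off."""


@dataclass
class ElasticityMatrices:
    """Scaled elasticities: eps_x is (reactions x internal metabolites),
    eps_y is (reactions x external metabolites); both dimensionless
    (d ln v / d ln concentration at the reference state)."""

    eps_x: np.ndarray
    eps_y: np.ndarray

    def validate(self, model: MetabolicModel) -> None:
        if self.eps_x.shape != (model.n_reactions, model.n_internal):
            raise ValueError(
                f"eps_x shape {self.eps_x.shape} != "
                f"({model.n_reactions}, {model.n_internal})"
            )
        if self.eps_y.shape != (model.n_reactions, model.n_external):
            raise ValueError(
                f"eps_y shape {self.eps_y.shape} != "
                f"({model.n_reactions}, {model.n_external})"
            )
        if not (np.isfinite(self.eps_x).all() and np.isfinite(self.eps_y).all()):
            raise ValueError("elasticities must be finite")


@dataclass
class PerturbationState:
    """A strain's deviation from the reference: relative enzyme levels
    ``e_rel = e/e*`` (> 0; deletions floored) and external log-deviations
    ``y_log = log(y/y*)``."""

    e_rel: np.ndarray
    y_log: np.ndarray

    def __post_init__(self) -> None:
        self.e_rel = np.asarray(self.e_rel, dtype=float)
        self.y_log = np.asarray(self.y_log, dtype=float)
        if np.any(self.e_rel <= 0):
            raise ValueError("e_rel must be strictly positive (floor knockouts)")


@dataclass
class SteadyStateSolution:
    x_log: np.ndarray
    v: np.ndarray
    singular_flag: bool = False


@dataclass
class ControlCoefficients:
    """Flux (CJ) and concentration (CX) control coefficients at the
    reference state.  ``CJ[j, k] = d ln J_j / d ln e_k``; each CJ row
    sums to 1 (summation theorem) and ``CJ @ eps_x = 0`` (connectivity
    theorem)."""

    CJ: np.ndarray
    CX: np.ndarray
    singular_flag: bool = False


def linlog_rates(
    ref: ReferenceState,
    eps: ElasticityMatrices,
    pert: PerturbationState,
    x_log: np.ndarray,
) -> np.ndarray:
    """Evaluate the lin-log rate law at given internal log-deviations."""
    x_log = np.asarray(x_log, dtype=float)
    r, m = eps.eps_x.shape
    if x_log.shape != (m,) or pert.e_rel.shape != (r,):
        raise ValueError("shape mismatch in lin-log rate evaluation")
    lin = 1.0 + eps.eps_x @ x_log + eps.eps_y @ pert.y_log
    return ref.v_star * pert.e_rel * lin


def solve_steady_state(
    model: MetabolicModel,
    ref: ReferenceState,
    eps: ElasticityMatrices,
    pert: PerturbationState,
    *,
    pinv_fallback: bool = False,
) -> SteadyStateSolution:
    """Solve ``N v(x_log) = 0`` for the internal log-deviations.

    With ``w = v* o e_rel`` the system is ``A x_log = b`` where
    ``A = N diag(w) eps_x`` and ``b = -N (w o (1 + eps_y y_log))``.
    Requires ``N`` to have full row rank (conserved moieties removed).
    A solve whose condition number exceeds 1e10 is flagged; a singular
    ``A`` raises unless ``pinv_fallback`` enables the Moore-Penrose
    solution (flagged).
    """
    w = ref.v_star * pert.e_rel
    A = model.N @ (w[:, None] * eps.eps_x)
    b = -model.N @ (w * (1.0 + eps.eps_y @ pert.y_log))
    singular = False
    try:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > COND_THRESHOLD:
            singular = True
        x_log = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        singular = True
        if not pinv_fallback:
            raise SingularSystemError(
                "steady-state system is singular; enable pinv_fallback to "
                "use the Moore-Penrose solution"
            ) from None
        x_log = np.linalg.pinv(A) @ b
    if singular and not pinv_fallback:
        # ill-conditioned but solvable: keep the solution, flag it
        pass
    v = linlog_rates(ref, eps, pert, x_log)
    return SteadyStateSolution(x_log=x_log, v=v, singular_flag=singular)


def control_coefficients(
    model: MetabolicModel,
    ref: ReferenceState,
    eps_x: np.ndarray,
    *,
    pinv_fallback: bool = False,
) -> ControlCoefficients:
    """Analytic control coefficients at the reference state.

    From the implicit function theorem on the lin-log steady state:

        CX = -(N diag(v*) eps_x)^-1 N diag(v*)
        CJ = I + eps_x CX

    ``CX[i, k] = d ln x_i / d ln e_k`` and ``CJ[j, k] = d ln J_j /
    d ln e_k``.  Both MCA theorems hold identically under this formula
    (the summation theorem uses ``N v* = 0``).
    """
    NV = model.N * ref.v_star[None, :]
    A = NV @ eps_x
    singular = False
    try:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > COND_THRESHOLD:
            singular = True
            if not pinv_fallback:
                raise SingularSystemError(
                    f"control-coefficient system ill-conditioned (cond={cond:.3g})"
                )
        Ainv = np.linalg.inv(A) if not singular else np.linalg.pinv(A)
    except np.linalg.LinAlgError:
        if not pinv_fallback:
            raise SingularSystemError("control-coefficient system is singular") from None
        singular = True
        Ainv = np.linalg.pinv(A)
    CX = -Ainv @ NV
    CJ = np.eye(model.n_reactions) + eps_x @ CX
    return ControlCoefficients(CJ=CJ, CX=CX, singular_flag=singular)


def save_elasticities(eps: ElasticityMatrices, model: MetabolicModel, path) -> None:
    """Sparse TSV (reaction_id, metabolite_id, value); zeros implicit."""
    import pandas as pd

    rows = []
    for mat, ids in ((eps.eps_x, model.internal_ids), (eps.eps_y, model.external_ids)):
        r, c = np.nonzero(mat)
        rows += [(model.reaction_ids[j], ids[i], float(mat[j, i]))
                 for j, i in zip(r, c)]
    pd.DataFrame(rows, columns=["reaction_id", "metabolite_id", "value"]).to_csv(
        path, sep="\t", index=False)


def load_elasticities(path, model: MetabolicModel) -> ElasticityMatrices:
    """Inverse of :func:`save_elasticities`; absent entries are zero."""
    import pandas as pd

    tab = pd.read_csv(path, sep="\t")
    ex = np.zeros((model.n_reactions, model.n_internal))
    ey = np.zeros((model.n_reactions, model.n_external))
    mi = {m: i for i, m in enumerate(model.internal_ids)}
    ei = {m: i for i, m in enumerate(model.external_ids)}
    for _, row in tab.iterrows():
        j = model.reaction_index(row["reaction_id"])
        met = row["metabolite_id"]
        if met in mi:
            ex[j, mi[met]] = row["value"]
        elif met in ei:
            ey[j, ei[met]] = row["value"]
        else:
            raise ValueError(f"unknown metabolite {met!r} in elasticity table")
    return ElasticityMatrices(eps_x=ex, eps_y=ey)


def simulate_strain(
    model: MetabolicModel,
    ref: ReferenceState,
    eps: ElasticityMatrices,
    design: dict[str, float],
    *,
    y_log: np.ndarray | None = None,
    knockout_floor: float = KNOCKOUT_FLOOR,
    pinv_fallback: bool = False,
) -> SteadyStateSolution:
    """Steady state of a designed strain.

    ``design`` maps reaction ids to enzyme fold-changes; fold-changes of
    0 (deletions) are floored at ``knockout_floor``.  Unlisted reactions
    stay at the reference level.
    """
    e_rel = np.ones(model.n_reactions)
    for rid, fold in design.items():
        e_rel[model.reaction_index(rid)] = max(float(fold), knockout_floor)
    if y_log is None:
        y_log = np.zeros(model.n_external)
    pert = PerturbationState(e_rel=e_rel, y_log=np.asarray(y_log, dtype=float))
    return solve_steady_state(model, ref, eps, pert, pinv_fallback=pinv_fallback)
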