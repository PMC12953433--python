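"""Metabolic network container, loading, validation and reduction.

The model is a stoichiometric network with an explicit internal/external
metabolite partition.  Internal metabolites are balanced at steady state
(rows of ``N``); external metabolites (medium components, secreted
products, boundary species) act as fixed boundary conditions whose
log-deviations enter the lin-log rate law through the external
elasticity matrix.

Metabolites and reactions are kept in lexicographic id order so that
every derived matrix is reproducible across runs and serializations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ReferenceState",
    "LinkMatrix",
    "load_model",
    "save_model_json",
    "reduce_model",
    "remove_conserved_moieties",
    "load_reference_fluxes",
]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; ``role`` fixes whether it is balanced (internal)
    or a boundary condition (external)."""

    id: str
    name: str = ""
    compartment: str = "c"
    role: str = "internal"  # "internal" | "external"

    def __post_init__(self) -> None:
        if self.role not in ("internal", "external"):
            raise ModelValidationError(f"bad metabolite role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry and protein associations.

    ``gpr`` encodes the gene-protein-reaction rule as an OR-of-ANDs list
    of isozyme groups; each inner list is a complex whose subunits are
    all required.  ``protein_ids`` is the flattened set, kept for
    reporting.
    """

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    protein_ids: tuple[str, ...] = ()
    gpr: tuple[tuple[str, ...], ...] = ()
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")

    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    """Validated stoichiometric model.

    ``N`` is the (internal metabolites x reactions) stoichiometric
    matrix; row/column order follows the lexicographically sorted
    ``internal_ids`` / ``reaction_ids``.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    target_reaction_id: str
    name: str = "model"

    # derived, filled in __post_init__
    N: np.ndarray = field(init=False, repr=False)
    internal_ids: list[str] = field(init=False, repr=False)
    external_ids: list[str] = field(init=False, repr=False)
    reaction_ids: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.metabolites = sorted(self.metabolites, key=lambda m: m.id)
        self.reactions = sorted(self.reactions, key=lambda r: r.id)
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ModelValidationError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites: {sorted(missing)}"
                )
        if self.target_reaction_id not in set(rids):
            raise ModelValidationError(
                f"target reaction {self.target_reaction_id!r} not in model"
            )
        self.internal_ids = [m.id for m in self.metabolites if m.role == "internal"]
        self.external_ids = [m.id for m in self.metabolites if m.role == "external"]
        # exchange flag: any reaction touching an external species
        ext = set(self.external_ids)
        self.reactions = [
            replace(r, is_exchange=bool(ext & set(r.stoichiometry)))
            for r in self.reactions
        ]
        self.reaction_ids = [r.id for r in self.reactions]
        participating: set[str] = set()
        for rxn in self.reactions:
            participating |= set(rxn.stoichiometry)
        orphans = set(self.internal_ids) - participating
        if orphans:
            raise ModelValidationError(
                f"internal metabolites in no reaction: {sorted(orphans)}"
            )
        ridx = {m: i for i, m in enumerate(self.internal_ids)}
        N = np.zeros((len(self.internal_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if met in ridx:
                    N[ridx[met], j] = coef
        self.N = N

    # -- convenience indexing -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_internal(self) -> int:
        return len(self.internal_ids)

    @property
    def n_external(self) -> int:
        return len(self.external_ids)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index(rid)]

    def Ny(self) -> np.ndarray:
        """(external metabolites x reactions) stoichiometry, used to fix
        elasticity sign structure for boundary species."""
        ridx = {m: i for i, m in enumerate(self.external_ids)}
        Ny = np.zeros((len(self.external_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if met in ridx:
                    Ny[ridx[met], j] = coef
        return Ny


@dataclass
class ReferenceState:
    """The linearization point: reference fluxes, enzyme and metabolite
    levels.  Enzyme levels are 1 by convention (proteomics are relative),
    and metabolite levels are relative to themselves, so only ``v_star``
    carries units (mmol gDCW^-1 h^-1)."""

    v_star: np.ndarray
    e_star: np.ndarray
    x_star: np.ndarray
    y_star: np.ndarray

    @classmethod
    def from_fluxes(cls, model: MetabolicModel, v_star: np.ndarray) -> "ReferenceState":
        v_star = np.asarray(v_star, dtype=float)
        if v_star.shape != (model.n_reactions,):
            raise ValueError("v_star shape does not match model reactions")
        return cls(
            v_star=v_star,
            e_star=np.ones(model.n_reactions),
            x_star=np.ones(model.n_internal),
            y_star=np.ones(model.n_external),
        )

    def validate(self, model: MetabolicModel, tol: float = 1e-8) -> None:
        resid = np.abs(model.N @ self.v_star).max() if model.n_internal else 0.0
        if resid > tol:
            raise ModelValidationError(
                f"reference flux violates steady state: |N v*|_inf = {resid:.3g} > {tol:g}"
            )
        for name, vec in (("e_star", self.e_star), ("x_star", self.x_star), ("y_star", self.y_star)):
            if np.any(np.asarray(vec) <= 0):
                raise ModelValidationError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _model_from_json_dict(doc: Mapping) -> MetabolicModel:
    external = set(doc.get("external", []))
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", m["id"]),
            compartment=m.get("compartment", "c"),
            role="external" if m["id"] in external else "internal",
        )
        for m in doc["metabolites"]
    ]
    rxns = []
    for r in doc["reactions"]:
        gpr = tuple(tuple(g) for g in r.get("gpr", []))
        prots = tuple(r.get("protein_ids", [p for grp in gpr for p in grp]))
        if gpr == () and prots:
            gpr = tuple((p,) for p in prots)  # default: isozymes
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                reversible=bool(r.get("reversible", False)),
                protein_ids=prots,
                gpr=gpr,
            )
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        target_reaction_id=doc["target_reaction"],
        name=doc.get("name", "model"),
    )


def model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "external": list(model.external_ids),
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "reversible": r.reversible,
                "protein_ids": list(r.protein_ids),
                "gpr": [list(g) for g in r.gpr],
            }
            for r in model.reactions
        ],
        "target_reaction": model.target_reaction_id,
    }


def save_model_json(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_json_dict(model), indent=1, sort_keys=True))


def _load_sbml(path: str | Path, target_reaction_id: str | None,
               external_ids: Iterable[str] | None) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelValidationError(
            f"SBML parse failure: {doc.getError(0).getMessage()}"
        )
    sbml = doc.getModel()
    if sbml is None:
        raise ModelValidationError("SBML file contains no model")
    explicit_external = set(external_ids or ())
    mets = []
    for sp in sbml.getListOfSpecies():
        external = (
            sp.getBoundaryCondition()
            or sp.getId() in explicit_external
            or sp.getCompartment() in ("e", "ext", "extracellular")
        )
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment() or "c",
                role="external" if external else "internal",
            )
        )
    rxns = []
    for rx in sbml.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        gpr: tuple[tuple[str, ...], ...] = ()
        fbc = rx.getPlugin("fbc")
        if fbc is not None and fbc.isSetGeneProductAssociation():
            gpr = _parse_fbc_association(fbc.getGeneProductAssociation().getAssociation())
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                reversible=rx.getReversible(),
                protein_ids=tuple(dict.fromkeys(p for grp in gpr for p in grp)),
                gpr=gpr,
            )
        )
    if target_reaction_id is None:
        raise ModelValidationError("target_reaction_id is required for SBML input")
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        target_reaction_id=target_reaction_id,
        name=sbml.getId() or "model",
    )


def _parse_fbc_association(assoc) -> tuple[tuple[str, ...], ...]:
    """Flatten an fbc association into OR-of-ANDs isozyme groups.

    Nested structures beyond one OR-of-ANDs level are flattened
    conservatively (all gene products of an AND subtree form one group).
    """
    import libsbml

    if assoc is None:
        return ()
    if isinstance(assoc, libsbml.GeneProductRef):
        return ((assoc.getGeneProduct(),),)
    if isinstance(assoc, libsbml.FbcOr):
        groups: list[tuple[str, ...]] = []
        for i in range(assoc.getNumAssociations()):
            groups.extend(_parse_fbc_association(assoc.getAssociation(i)))
        return tuple(groups)
    if isinstance(assoc, libsbml.FbcAnd):
        members: list[str] = []
        for i in range(assoc.getNumAssociations()):
            for grp in _parse_fbc_association(assoc.getAssociation(i)):
                members.extend(grp)
        return (tuple(members),)
    return ()


def load_model(
    path: str | Path,
    dialect: str = "json",
    *,
    target_reaction_id: str | None = None,
    external_ids: Iterable[str] | None = None,
) -> MetabolicModel:
    """Load a model from the JSON dialect or SBML (Level 3, fbc GPRs).

    For JSON the target reaction and external list live in the file; for
    SBML the target must be given and external species are those with
    ``boundaryCondition``, an extracellular compartment, or listed in
    ``external_ids``.
    """
    if dialect == "json":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"JSON parse failure: {exc}") from exc
        model = _model_from_json_dict(doc)
        if target_reaction_id is not None and target_reaction_id != model.target_reaction_id:
            model = MetabolicModel(
                metabolites=model.metabolites,
                reactions=model.reactions,
                target_reaction_id=target_reaction_id,
                name=model.name,
            )
        return model
    if dialect == "sbml":
        return _load_sbml(path, target_reaction_id, external_ids)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def reduce_model(
    model: MetabolicModel, flux: np.ndarray, zero_tol: float = 1e-9
) -> tuple[MetabolicModel, np.ndarray]:
    """Drop reactions carrying (numerically) zero flux at the reference
    state, then any metabolite left without a participating reaction.

    Returns the reduced model and the flux vector restricted to the
    surviving reactions (in the reduced model's reaction order).
    """
    flux = np.asarray(flux, dtype=float)
    if flux.shape != (model.n_reactions,):
        raise ValueError("flux vector must be indexed like model reactions")
    keep = np.abs(flux) > zero_tol
    tgt = model.reaction_index(model.target_reaction_id)
    if not keep[tgt]:
        raise ModelValidationError(
            f"target reaction {model.target_reaction_id!r} has zero reference flux"
        )
    kept_rxns = [r for r, k in zip(model.reactions, keep) if k]
    used = set()
    for r in kept_rxns:
        used |= set(r.stoichiometry)
    kept_mets = [m for m in model.metabolites if m.id in used]
    reduced = MetabolicModel(
        metabolites=kept_mets,
        reactions=kept_rxns,
        target_reaction_id=model.target_reaction_id,
        name=model.name,
    )
    v = np.array([flux[model.reaction_index(r)] for r in reduced.reaction_ids])
    return reduced, v


@dataclass
class LinkMatrix:
    """Linear map reconstructing dependent internal-metabolite rows.

    ``full = L @ reduced`` for any vector/matrix indexed by the reduced
    model's internal metabolites; ``dropped_ids`` are the conserved-
    moiety rows removed from the balance system.
    """

    L: np.ndarray
    kept_ids: list[str]
    dropped_ids: list[str]


def remove_conserved_moieties(
    model: MetabolicModel, rank_tol: float = 1e-9
) -> tuple[MetabolicModel, LinkMatrix]:
    """Remove linearly dependent rows of ``N`` (conserved moieties) so
    the steady-state and control-coefficient systems are nonsingular.

    Row selection uses QR with column pivoting on ``N.T``; rank is the
    number of singular values above ``rank_tol`` (relative to the
    largest).  Dependent metabolites are removed from the model (their
    balances are implied by conservation); the returned link matrix maps
    reduced-row quantities back to all original internal rows.
    """
    import scipy.linalg

    N = model.N
    if N.size == 0 or not np.any(N):
        raise ModelValidationError("stoichiometric matrix is empty or all-zero")
    sv = scipy.linalg.svdvals(N)
    rank = int(np.sum(sv > rank_tol * sv[0]))
    if rank == N.shape[0]:
        link = LinkMatrix(np.eye(N.shape[0]), list(model.internal_ids), [])
        return model, link
    _, _, piv = scipy.linalg.qr(N.T, mode="economic", pivoting=True)
    keep_rows = sorted(piv[:rank])
    kept_ids = [model.internal_ids[i] for i in keep_rows]
    dropped_ids = [m for i, m in enumerate(model.internal_ids) if i not in keep_rows]
    Nr = N[keep_rows, :]
    # full rows as linear combinations of kept rows: N = L @ Nr
    L = N @ np.linalg.pinv(Nr)
    dropped_set = set(dropped_ids)
    mets = [m for m in model.metabolites
            if not (m.role == "internal" and m.id in dropped_set)]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={k: v for k, v in r.stoichiometry.items()
                           if k not in dropped_set},
            reversible=r.reversible,
            protein_ids=r.protein_ids,
            gpr=r.gpr,
        )
        for r in model.reactions
    ]
    reduced = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        target_reaction_id=model.target_reaction_id,
        name=model.name,
    )
    return reduced, LinkMatrix(L, kept_ids, dropped_ids)


def load_reference_fluxes(path: str | Path, model: MetabolicModel) -> np.ndarray:
    """Read a (reaction_id, v_star) TSV into a flux vector in model order."""
    import pandas as pd

    tab = pd.read_csv(path, sep="\t")
    series = tab.set_index(tab.columns[0])[tab.columns[1]]
    try:
        return np.array([float(series[r]) for r in model.reaction_ids])
    except KeyError as exc:
        raise ModelValidationError(f"reference flux missing reaction {exc}") from exc
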