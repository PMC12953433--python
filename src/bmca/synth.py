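"""Synthetic ground-truth networks and simulated multi-omics datasets.

The ``branched_3hp`` preset emulates the structure of a central-carbon +
beta-alanine production network: glucose feeds pyruvate, which splits
between the product route (pyruvate carboxylase -> aspartate ->
beta-alanine -> malonic semialdehyde -> 3-HP export), a competing
malonic-semialdehyde dehydrogenase drain to acetyl-CoA, a TCA-like
succinyl-CoA loop, and an ethanol drain.  A panel of strains combining
pathway dosage, single overexpressions and deletions is simulated at
steady state, observed with replicate noise, partial coverage and
clipping, together with batch time-series from which exchange rates can
be re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ObservedSample, clip_observations
from .linlog import (
    KNOCKOUT_FLOOR,
    ControlCoefficients,
    ElasticityMatrices,
    control_coefficients,
    simulate_strain,
)
from .network import MetabolicModel, Metabolite, Reaction, ReferenceState

__all__ = ["SyntheticTruth", "NoiseSpec", "make_toy_network", "simulate_dataset"]

#: sampling times (h) for the batch time-series: inoculation plus days 3/5/7
SAMPLING_TIMES_H = (0.0, 72.0, 120.0, 168.0)


@dataclass
class SyntheticTruth:
    """A model with known elasticities, reference state, strain designs
    and the analytic control coefficients they imply."""

    model: MetabolicModel
    ref: ReferenceState
    eps_true: ElasticityMatrices
    fcc_true: ControlCoefficients
    designs: dict[str, dict[str, float]]
    y_log_by_strain: dict[str, np.ndarray]
    reference_strain: str = "ref"
    mu_by_strain: dict[str, float] = field(default_factory=dict)
    X0: float = 0.3  # gDCW/L at inoculation
    S0: dict[str, float] = field(default_factory=dict)  # mmol/L in fresh medium

    def true_log_e_rel(self, strain: str) -> np.ndarray:
        ell = np.zeros(self.model.n_reactions)
        for rid, fold in self.designs[strain].items():
            ell[self.model.reaction_index(rid)] = np.log(max(fold, KNOCKOUT_FLOOR))
        return ell

    def target_fcc_row(self) -> np.ndarray:
        jt = self.model.reaction_index(self.model.target_reaction_id)
        return self.fcc_true.CJ[jt]


@dataclass
class NoiseSpec:
    """Observation model for the simulated assays (log-scale sds)."""

    sd_protein: float = 0.1
    sd_metabolite: float = 0.1
    sd_flux: float = 0.1
    obs_fraction_protein: float = 0.8
    obs_fraction_metabolite: float = 0.8
    replicates: int = 3
    clip_bound: float = 2.0
    seed: int = 0
    sd_conc: float = 0.0  # relative noise on time-series concentrations


# ---------------------------------------------------------------------------
# network presets
# ---------------------------------------------------------------------------

def _draw_elasticities(
    model: MetabolicModel, rng: np.random.Generator
) -> ElasticityMatrices:
    """Sign-consistent random elasticities: substrates Uniform(0.3, 1.2),
    products Uniform(-1.2, -0.3), zero elsewhere."""
    Ex = np.zeros((model.n_reactions, model.n_internal))
    Ey = np.zeros((model.n_reactions, model.n_external))
    mi = {m: i for i, m in enumerate(model.internal_ids)}
    ei = {m: i for i, m in enumerate(model.external_ids)}
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            mag = rng.uniform(0.3, 1.2)
            val = mag if coef < 0 else -mag
            if met in mi:
                Ex[j, mi[met]] = val
            else:
                Ey[j, ei[met]] = val
    return ElasticityMatrices(eps_x=Ex, eps_y=Ey)


def _finalize_truth(
    model: MetabolicModel,
    v_star: np.ndarray,
    designs: dict[str, dict[str, float]],
    rng: np.random.Generator,
    *,
    sign_checks: dict[str, int] | None = None,
    max_tries: int = 50,
    cond_limit: float = 1e6,
) -> SyntheticTruth:
    """Draw elasticities until the system is well conditioned, every
    design strain is solvable, and any required FCC signs hold."""
    ref = ReferenceState.from_fluxes(model, v_star)
    ref.validate(model, tol=1e-9)
    jt = model.reaction_index(model.target_reaction_id)
    y_log = {s: np.zeros(model.n_external) for s in designs}
    glc = [i for i, m in enumerate(model.external_ids) if m.startswith("GLC")]
    for strain in designs:
        if strain != "ref" and glc:
            y_log[strain][glc[0]] = rng.normal(0.0, 0.2)
    for _ in range(max_tries):
        eps = _draw_elasticities(model, rng)
        A = (model.N * v_star[None, :]) @ eps.eps_x
        if np.linalg.cond(A) > cond_limit:
            continue
        fcc = control_coefficients(model, ref, eps.eps_x)
        if sign_checks and any(
            np.sign(fcc.CJ[jt, model.reaction_index(rid)]) != want
            for rid, want in sign_checks.items()
        ):
            continue
        try:
            for strain, design in designs.items():
                simulate_strain(model, ref, eps, design, y_log=y_log[strain])
        except np.linalg.LinAlgError:
            continue
        mu = {s: 0.015 * float(np.exp(rng.normal(0.0, 0.15))) for s in designs}
        S0 = {m: 0.0 for m in model.external_ids}
        for m in model.external_ids:
            if m.startswith("GLC") or m.endswith("_src"):
                S0[m] = 555.0  # ~100 g/L glucose
        return SyntheticTruth(
            model=model, ref=ref, eps_true=eps, fcc_true=fcc,
            designs=designs, y_log_by_strain=y_log, mu_by_strain=mu, S0=S0,
        )
    raise RuntimeError("could not construct a well-conditioned synthetic truth")


def _branched_3hp_model() -> tuple[MetabolicModel, np.ndarray]:
    """~15-reaction central-carbon + beta-alanine toy with a hand-balanced
    reference flux (mmol gDCW^-1 h^-1)."""
    ext = ["GLC_e", "HP3_e", "ETOH_e", "SUC_e"]
    internal = ["PYR", "OAA", "ASP", "BAL", "MSA", "HP3", "ACCOA", "SUCA",
                "SUC", "ETOH"]
    mets = [Metabolite(id=m, role="external", compartment="e") for m in ext]
    mets += [Metabolite(id=m, role="internal") for m in internal]
    R = Reaction
    rxns = [
        R("r_glc_uptake", {"GLC_e": -1, "PYR": 1}, protein_ids=("p_glk",),
          gpr=(("p_glk",),)),
        R("r_pyc", {"PYR": -1, "OAA": 1}, protein_ids=("p_pyc",),
          gpr=(("p_pyc",),)),
        R("r_aat", {"OAA": -1, "ASP": 1}, protein_ids=("p_aat",),
          gpr=(("p_aat",),)),
        R("r_pand", {"ASP": -1, "BAL": 1}, protein_ids=("p_pand",),
          gpr=(("p_pand",),)),
        R("r_bapat", {"BAL": -1, "MSA": 1}, protein_ids=("p_bapat",),
          gpr=(("p_bapat",),)),
        R("r_hpdh", {"MSA": -1, "HP3": 1}, protein_ids=("p_hpdh",),
          gpr=(("p_hpdh",),)),
        R("r_3hp_export", {"HP3": -1, "HP3_e": 1}, protein_ids=("p_mct",),
          gpr=(("p_mct",),)),
        R("r_ald6", {"MSA": -1, "ACCOA": 1}, protein_ids=("p_ald6",),
          gpr=(("p_ald6",),)),
        R("r_pdh", {"PYR": -1, "ACCOA": 1},
          protein_ids=("p_pdh_a", "p_pdh_b"), gpr=(("p_pdh_a", "p_pdh_b"),)),
        R("r_cits", {"ACCOA": -1, "OAA": -1, "SUCA": 1},
          protein_ids=("p_cit",), gpr=(("p_cit",),)),
        R("r_sucl", {"SUCA": -1, "SUC": 1},
          protein_ids=("p_sucl1", "p_sucl2"),
          gpr=(("p_sucl1",), ("p_sucl2",))),
        R("r_mdh", {"SUC": -1, "OAA": 1}, protein_ids=("p_mdh",),
          gpr=(("p_mdh",),)),
        R("r_adh", {"PYR": -1, "ETOH": 1}, protein_ids=("p_adh",),
          gpr=(("p_adh",),)),
        R("r_etoh_export", {"ETOH": -1, "ETOH_e": 1}),
        R("r_suc_export", {"SUC": -1, "SUC_e": 1}),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           target_reaction_id="r_3hp_export",
                           name="branched_3hp")
    flux_by_id = {
        "r_glc_uptake": 1.0, "r_pyc": 0.4, "r_aat": 0.3, "r_pand": 0.3,
        "r_bapat": 0.3, "r_hpdh": 0.2, "r_3hp_export": 0.2, "r_ald6": 0.1,
        "r_pdh": 0.3, "r_cits": 0.4, "r_sucl": 0.4, "r_mdh": 0.3,
        "r_adh": 0.3, "r_etoh_export": 0.3, "r_suc_export": 0.1,
    }
    v_star = np.array([flux_by_id[r] for r in model.reaction_ids])
    return model, v_star


_PATHWAY = ("r_pand", "r_bapat", "r_hpdh")


def _branched_3hp_designs() -> dict[str, dict[str, float]]:
    """17 strains: reference, a no-pathway wild type, pathway dosage,
    single overexpressions (x5), deletions (floored), and stacks."""
    pw = {r: 2.0 for r in _PATHWAY}
    ko = KNOCKOUT_FLOOR
    return {
        "ref": {},
        "wt": {r: ko for r in _PATHWAY},
        "pw_2x": dict(pw),
        "pyc_oe": {"r_pyc": 5.0},
        "pw2_pyc": {**pw, "r_pyc": 5.0},
        "aat_oe": {"r_aat": 5.0},
        "ald6_ko": {"r_ald6": ko},
        "pyc_ald6": {"r_pyc": 5.0, "r_ald6": ko},
        "mdh_oe": {"r_mdh": 5.0},
        "sucl_ko": {"r_sucl": ko},
        "adh_ko": {"r_adh": ko},
        "pdh_lo": {"r_pdh": 0.5},
        "pw2_aat": {**pw, "r_aat": 5.0},
        "cits_lo": {"r_cits": 0.2},
        "mct_oe": {"r_3hp_export": 2.0},
        "pw2_pyc_ald6": {**pw, "r_pyc": 5.0, "r_ald6": ko},
        "sucx_2x": {"r_suc_export": 2.0},
    }


def _two_step_truth() -> SyntheticTruth:
    """Two-step chain with fixed elasticities (-1, 0.5) toward the single
    internal metabolite; closed-form FCCs (1/3, 2/3)."""
    mets = [
        Metabolite(id="A_ext", role="external", compartment="e"),
        Metabolite(id="B_ext", role="external", compartment="e"),
        Metabolite(id="X", role="internal"),
    ]
    rxns = [
        Reaction("r1", {"A_ext": -1, "X": 1}, protein_ids=("p1",), gpr=(("p1",),)),
        Reaction("r2", {"X": -1, "B_ext": 1}, protein_ids=("p2",), gpr=(("p2",),)),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           target_reaction_id="r2", name="two_step")
    ref = ReferenceState.from_fluxes(model, np.array([1.0, 1.0]))
    eps = ElasticityMatrices(
        eps_x=np.array([[-1.0], [0.5]]),
        eps_y=np.array([[0.5, 0.0], [0.0, -0.3]]),
    )
    fcc = control_coefficients(model, ref, eps.eps_x)
    designs = {
        "ref": {},
        "r1_2x": {"r1": 2.0},
        "r2_2x": {"r2": 2.0},
        "r1_half": {"r1": 0.5},
        "both_2x": {"r1": 2.0, "r2": 2.0},
    }
    return SyntheticTruth(
        model=model, ref=ref, eps_true=eps, fcc_true=fcc, designs=designs,
        y_log_by_strain={s: np.zeros(2) for s in designs},
        mu_by_strain={s: 0.015 for s in designs},
        S0={"A_ext": 555.0, "B_ext": 0.0},
    )


def _random_truth(size: int, rng: np.random.Generator) -> SyntheticTruth:
    """Random pathway-with-branches network of about ``size`` reactions,
    with a steady state constructed by superposing flux paths."""
    size = max(3, int(size))
    n_int = max(2, size // 2)
    internal = [f"M{i}" for i in range(n_int)]
    stoich: dict[str, dict[str, float]] = {}
    flux: dict[str, float] = {}
    # backbone chain SRC -> M0 -> ... -> M(k-1) -> SNK with unit flux
    chain = []
    for i in range(n_int + 1):
        rid = f"r{i:02d}"
        src = "SRC_e" if i == 0 else internal[i - 1]
        dst = "SNK_e" if i == n_int else internal[i]
        stoich[rid] = {src: -1.0, dst: 1.0}
        flux[rid] = 1.0
        chain.append(rid)
    externals = {"SRC_e", "SNK_e"}
    n_extra = size - len(chain)
    for k in range(max(0, n_extra)):
        f = float(rng.uniform(0.3, 1.0))
        i = int(rng.integers(0, n_int))
        rid = f"rb{k:02d}"
        if rng.random() < 0.5:  # export branch from M_i; feed upstream chain
            ext = f"X{k}_e"
            externals.add(ext)
            stoich[rid] = {internal[i]: -1.0, ext: 1.0}
            for j in range(i + 1):
                flux[chain[j]] += f
        else:  # feeder branch into M_i; drain downstream chain
            ext = f"F{k}_src"
            externals.add(ext)
            stoich[rid] = {ext: -1.0, internal[i]: 1.0}
            for j in range(i + 1, n_int + 1):
                flux[chain[j]] += f
        flux[rid] = f
    mets = [Metabolite(id=m, role="internal") for m in internal]
    mets += [Metabolite(id=m, role="external", compartment="e")
             for m in sorted(externals)]
    rxns = [Reaction(rid, st, protein_ids=(f"p_{rid}",), gpr=((f"p_{rid}",),))
            for rid, st in stoich.items()]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           target_reaction_id=chain[-1], name="random_toy")
    v_star = np.array([flux[r] for r in model.reaction_ids])
    designs = {"ref": {}}
    for s in range(3):
        rid = model.reaction_ids[int(rng.integers(0, model.n_reactions))]
        designs[f"pert{s}"] = {rid: float(rng.choice([0.5, 2.0, 5.0]))}
    return _finalize_truth(model, v_star, designs, rng)


def make_toy_network(
    preset: str = "branched_3hp", size: int = 15, seed: int = 0
) -> SyntheticTruth:
    """Build a ground-truth network.

    Presets: ``two_step`` (fixed closed-form chain), ``branched_3hp``
    (the production-network emulation with its 17-strain design panel),
    ``random`` (seeded random pathway-with-branches of ~``size``
    reactions).  Deterministic given (preset, size, seed).
    """
    rng = np.random.default_rng(seed)
    if preset == "two_step":
        return _two_step_truth()
    if preset == "branched_3hp":
        model, v_star = _branched_3hp_model()
        return _finalize_truth(
            model, v_star, _branched_3hp_designs(), rng,
            sign_checks={"r_ald6": -1, "r_pyc": +1},
        )
    if preset == "random":
        return _random_truth(size, rng)
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    truth: SyntheticTruth, noise: NoiseSpec | None = None
) -> tuple[list[ObservedSample], pd.DataFrame]:
    """Simulate the multi-omics dataset and batch time-series.

    Per strain, the steady state under its design is observed in
    ``replicates`` noisy samples: protein log-ratios around the true
    log enzyme levels (only reactions with an associated protein),
    metabolite log-ratios around the steady-state deviations, and
    fluxes around the steady-state rates (noise scaled by |v*|).
    Observations are thinned to the observation fractions and clipped.
    Extracellular time-series follow the exponential-growth closed form
    at inoculation and days 3/5/7, so the generating exchange rates can
    be re-derived downstream.  All randomness comes from ``noise.seed``.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    model, ref = truth.model, truth.ref
    has_protein = np.array([bool(r.protein_ids) for r in model.reactions])
    Ny = model.Ny()
    samples: list[ObservedSample] = []
    ts_rows = []
    for strain in sorted(truth.designs):
        design = truth.designs[strain]
        y_log = truth.y_log_by_strain[strain]
        sol = simulate_strain(model, ref, truth.eps_true, design, y_log=y_log)
        ell = truth.true_log_e_rel(strain)
        for rep in range(1, noise.replicates + 1):
            p = ell + rng.normal(0.0, noise.sd_protein, model.n_reactions)
            m = sol.x_log + rng.normal(0.0, noise.sd_metabolite, model.n_internal)
            f = sol.v + rng.normal(0.0, noise.sd_flux, model.n_reactions) * np.abs(ref.v_star)
            pmask = has_protein & (rng.random(model.n_reactions)
                                   < noise.obs_fraction_protein)
            mmask = rng.random(model.n_internal) < noise.obs_fraction_metabolite
            fmask = np.ones(model.n_reactions, dtype=bool)
            samples.append(ObservedSample(
                sample_id=f"{strain}_rep{rep}", strain_id=strain,
                protein_log=np.where(pmask, p, np.nan), protein_mask=pmask,
                metabolite_log=np.where(mmask, m, np.nan), metabolite_mask=mmask,
                flux_obs=f, flux_mask=fmask,
            ))
        # batch time-series from the exponential-growth closed form
        mu, X0 = truth.mu_by_strain[strain], truth.X0
        q = Ny @ sol.v  # specific rate per external species
        for rep in range(1, noise.replicates + 1):
            for t in SAMPLING_TIMES_H:
                X = X0 * np.exp(mu * t)
                ts_rows.append((strain, rep, t, "biomass",
                                X * (1.0 + rng.normal(0.0, noise.sd_conc))))
                for i, met in enumerate(model.external_ids):
                    S = truth.S0.get(met, 0.0) + q[i] * X0 / mu * (np.exp(mu * t) - 1.0)
                    ts_rows.append((strain, rep, t, met,
                                    S * (1.0 + rng.normal(0.0, noise.sd_conc))))
    samples = clip_observations(samples, noise.clip_bound, v_star=ref.v_star)
    ts = pd.DataFrame(ts_rows,
                      columns=["strain", "replicate", "time_h", "analyte", "value"])
    return samples, ts
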