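"""Core ODE model: rate laws, quasi-steady-state resource competition, growth.

The cell expresses a set of genes that compete for a shared pool of RNA
polymerases (all genes, including the rRNA operon) and ribosomes (all
mRNA-bearing genes).  Promoter–RNAP and mRNA–ribosome binding are assumed
fast relative to elongation, so transcription complexes ``k~_j`` and
translation complexes ``c~_j`` are computed algebraically from the totals:

    k~_j = K_jX * P_tot / (1 + sum_i K_iX),   K_jX = g_j R_j / kappa_Xj
    c~_j = K_jL * R_tot / (1 + sum_i K_iL),   K_jL = m_j / kappa_Lj

Growth is the total translational flux over cell mass,
``lambda = gamma_X(t_c) * sum_j c~_j / M0``, which feeds back on gene
dosage, dilution, and — through the charged/uncharged tRNA ratio
``theta = t_c / t_u`` (a ppGpp proxy; high theta means low alarmone) — on
the transcriptional regulation of every gene class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import (
    CultureMode,
    GeneDefinition,
    ModelParameters,
    PathwaySpec,
    ValidationError,
)

__all__ = [
    "CellModel",
    "CellState",
    "DerivedQuantities",
    "transcription_elongation",
    "translation_elongation",
    "ppgpp_proxy",
    "regulation_factor",
    "effective_copy_number",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary rate laws (scalar, reusable outside the assembled model)
# ---------------------------------------------------------------------------

def transcription_elongation(M: float, params: ModelParameters,
                             lengths: Optional[np.ndarray] = None):
    """Global mRNA elongation rate tau_X(M) and optional per-gene rates.

    tau_X = tau_max * M / (K_tau + M) in nt/h; a gene of length n amino
    acids (3n nt) completes mRNAs at tau_j = tau_X / (3 n) per complex per
    hour.  Returns ``tau_X`` or ``(tau_X, tau_j)`` if lengths are given.
    """
    if M < 0:
        raise ValueError(f"metabolite count M must be >= 0, got {M}")
    tau_X = params.tau_max * M / (params.K_tau + M)
    if lengths is None:
        return tau_X
    return tau_X, tau_X / (3.0 * np.asarray(lengths, dtype=float))


def rrna_elongation(M: float, params: ModelParameters) -> float:
    """rRNA completion rate tau_r per transcribing polymerase (rRNA/h).

    Default reading: the constant tau_r,max / n_r.  With
    ``params.rrna_elongation_M_dependent`` the rRNA chain shares the
    metabolite saturation of mRNA elongation.
    """
    n_r = next(g.n for g in params.genes if g.is_rRNA)
    if params.rrna_elongation_M_dependent:
        if M < 0:
            raise ValueError("M must be >= 0")
        return params.tau_r_max * (M / (params.K_tau + M)) / n_r
    return params.tau_r_max / n_r


def translation_elongation(t_c: float, params: ModelParameters,
                           lengths: Optional[np.ndarray] = None):
    """Global peptide elongation rate gamma_X(t_c) and per-gene rates.

    gamma_X = D_gamma * gamma_max * t_c / (K_gamma + t_c) in aa/h; a
    protein of n amino acids completes at gamma_j = gamma_X / n per
    translating ribosome per hour.
    """
    if t_c < 0:
        raise ValueError(f"charged tRNA count must be >= 0, got {t_c}")
    gamma_X = params.D_gamma * params.gamma_max * t_c / (params.K_gamma + t_c)
    if lengths is None:
        return gamma_X
    return gamma_X, gamma_X / np.asarray(lengths, dtype=float)


def ppgpp_proxy(t_c: float, t_u: float, D_g: float = 1.0,
                floor: float = 1.0e-9) -> float:
    """Effective regulation variable theta_eff = D_g * t_c / t_u.

    theta is the charged/uncharged tRNA ratio, the inverse of the ppGpp
    level; D_g rescales it to emulate alarmone-pathway mutants.  t_u is
    floored (default 1e-9 molecules) so integrator trial states at the
    boundary stay finite.
    """
    if t_c < 0:
        raise ValueError("t_c must be >= 0")
    return D_g * t_c / max(t_u, floor)


def regulation_factor(gene: GeneDefinition, p_Q: float, theta_eff: float,
                      params: ModelParameters) -> float:
    """Transcriptional regulation R_j in [0, 1] for one gene.

    housekeeping_Q:     1 / (1 + (p_Q / kappa_q)^h_q)   (negative feedback)
    resource_activated: theta / (theta + kappa_theta)   (P, r-protein, rRNA)
    enzyme_repressed:   kappa_theta / (theta + kappa_theta)
    circuit:            enzyme-type factor scaled by the induction u
    """
    if p_Q < 0 or theta_eff < 0:
        raise ValueError("regulation inputs must be >= 0")
    cls = gene.regulation_class
    if cls == "housekeeping_Q":
        return 1.0 / (1.0 + (p_Q / params.kappa_q) ** params.h_q)
    if cls == "resource_activated":
        return theta_eff / (theta_eff + params.kappa_theta)
    if cls == "enzyme_repressed":
        return params.kappa_theta / (theta_eff + params.kappa_theta)
    if cls == "circuit":
        u = gene.u
        if u is None or not (0.0 <= u <= 1.0):
            raise ValidationError(f"circuit gene {gene.name}: u must be in [0, 1]")
        return params.kappa_theta / (theta_eff + params.kappa_theta) * u
    raise ValidationError(f"unknown regulation class {cls!r}")


def effective_copy_number(g0: float, q_x: float, lam: float,
                          D_r: float = 1.0) -> float:
    """Growth-rate-expanded gene dosage g_j = D_r * g0 * exp(q_x * lambda).

    The exponential captures replication-associated pseudo-copy expansion
    at fast growth; D_r (default 1) additionally scales rRNA operon dosage.
    """
    if lam < 0:
        raise ValueError("growth rate must be >= 0")
    return D_r * g0 * math.exp(q_x * lam)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

@dataclass
class DerivedQuantities:
    """Algebraic quantities implied by a state: growth, regulation, complexes."""

    growth_rate: float
    theta: float
    tau_X: float
    gamma_X: float
    ktilde: dict[str, float]        # transcription complexes per gene
    ctilde: dict[str, float]        # translation complexes per translated gene
    free_rnap: float
    free_ribosomes: float
    regulation: dict[str, float]
    copy_number: dict[str, float]


class CellState:
    """A named view over the flat state vector of a :class:`CellModel`.

    The layout is fixed by ``model.species``:
    ``S, N, M, tu, tc, m_<gene>..., p_<gene>... (Ptot for gene P, p_R for
    gene R), r, Rtot, Pab, Rab[, X]``.  Round-trip through ``.vector`` is
    lossless.
    """

    def __init__(self, model: "CellModel", vector: np.ndarray):
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (model.n_species,):
            raise ValueError(
                f"state vector has shape {vector.shape}, expected ({model.n_species},)"
            )
        self.model = model
        self.vector = vector

    def __getitem__(self, name: str) -> float:
        return float(self.vector[self.model.index(name)])

    def __setitem__(self, name: str, value: float) -> None:
        self.vector[self.model.index(name)] = value

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.model.species, self.vector)}

    def copy(self) -> "CellState":
        return CellState(self.model, self.vector.copy())

    def __repr__(self) -> str:
        items = ", ".join(f"{k}={v:.4g}" for k, v in self.as_dict().items())
        return f"CellState({items})"


class CellModel:
    """The assembled whole-cell ODE model.

    Parameters, culture mode and an optional product pathway are immutable
    once the model is built; use :meth:`with_params`, ``circuits.add_circuit``
    etc. to derive variants.
    """

    def __init__(self, params: ModelParameters,
                 culture: Optional[CultureMode] = None,
                 pathway: Optional[PathwaySpec] = None):
        params.check()
        culture = culture or CultureMode()
        errs = culture.validate()
        if pathway is not None:
            errs += pathway.validate()
            names = [g.name for g in params.genes]
            if pathway.enzyme not in names:
                errs.append(f"pathway enzyme gene {pathway.enzyme!r} not in gene table")
            elif params.gene(pathway.enzyme).regulation_class != "circuit":
                errs.append(f"pathway enzyme gene {pathway.enzyme!r} must be a circuit gene")
        if errs:
            raise ValidationError("; ".join(errs))
        self.params = params
        self.culture = culture
        self.pathway = pathway
        self._build()

    # -- construction -------------------------------------------------------

    def _build(self) -> None:
        p = self.params
        self.genes = list(p.genes)
        self.tx_genes = self.genes                       # all compete for RNAP
        self.tl_genes = [g for g in self.genes if not g.is_rRNA]
        self.rrna_gene = next(g for g in self.genes if g.is_rRNA)

        names = ["S", "N", "M", "tu", "tc"]
        names += [f"m_{g.name}" for g in self.tl_genes]
        names += [self.protein_species(g.name) for g in self.tl_genes]
        names += ["r", "Rtot", "Pab", "Rab"]
        if self.pathway is not None:
            names.append("X")
        self.species: list[str] = names
        self.n_species = len(names)
        self._idx = {n: i for i, n in enumerate(names)}

        # cached per-gene arrays (tl = translated genes, tx = all genes)
        tl = self.tl_genes
        self._n_tl = np.array([g.n for g in tl], dtype=float)
        self._krf = np.array([g.kr_f for g in tl], dtype=float)
        self._krr = np.array([g.kr_r for g in tl], dtype=float)
        self._g0_tx = np.array([g.g0 for g in self.tx_genes], dtype=float)
        self._kpf = np.array([g.kp_f for g in self.tx_genes], dtype=float)
        self._kpr = np.array([g.kp_r for g in self.tx_genes], dtype=float)
        self._n_tx = np.array([g.n for g in self.tx_genes], dtype=float)
        self._is_rrna = np.array([g.is_rRNA for g in self.tx_genes])
        self._is_circuit = np.array(
            [g.regulation_class == "circuit" for g in self.tx_genes]
        )
        self._tl_in_tx = np.array(
            [i for i, g in enumerate(self.tx_genes) if not g.is_rRNA]
        )
        self._rrna_in_tx = next(
            i for i, g in enumerate(self.tx_genes) if g.is_rRNA
        )
        # static kinetic precomputations for the hot path
        self._inv_n_tl = 1.0 / self._n_tl
        ntx = len(self.tx_genes)
        self._ix_Q = np.array([i for i, g in enumerate(self.tx_genes)
                               if g.regulation_class == "housekeeping_Q"])
        self._ix_act = np.array([i for i, g in enumerate(self.tx_genes)
                                 if g.regulation_class == "resource_activated"])
        self._ix_rep = np.array([i for i, g in enumerate(self.tx_genes)
                                 if g.regulation_class == "enzyme_repressed"])
        self._ix_circ = np.array([i for i, g in enumerate(self.tx_genes)
                                  if g.regulation_class == "circuit"], dtype=int)
        self._u_circ = np.array([g.u for g in self.tx_genes
                                 if g.regulation_class == "circuit"], dtype=float)
        # gene dosage: D_r folded into the rrn entry; expansion flag is 0 for
        # circuit genes when copy expansion is disabled for them
        g0s = self._g0_tx.copy()
        g0s[self._rrna_in_tx] *= p.D_r
        self._g0_scaled = g0s
        expand = np.ones(ntx)
        if not p.circuit_copy_expansion:
            expand[self._is_circuit] = 0.0
        self._expand_flag = expand
        # transcription completion rates: tau_X * inv3n (mRNA genes) plus the
        # rRNA amplitude (constant, or metabolite-saturated if configured)
        inv3n = 1.0 / (3.0 * self._n_tx)
        inv3n[self._rrna_in_tx] = 0.0
        self._inv3n = inv3n
        taur_vec = np.zeros(ntx)
        taur_vec[self._rrna_in_tx] = p.tau_r_max / self.rrna_gene.n
        self._taur_vec = taur_vec
        # plain-list mirrors of the per-gene constants: gene counts are tiny
        # (<= ~8), so scalar loops beat numpy in the integrator hot path
        code = {"housekeeping_Q": 0, "resource_activated": 1,
                "enzyme_repressed": 2, "circuit": 3}
        self._ntl = len(tl)
        self._ntx = ntx
        self._L_invn_tl = [1.0 / g.n for g in tl]
        self._L_krf = [g.kr_f for g in tl]
        self._L_krr = [g.kr_r for g in tl]
        self._L_kpf = list(self._kpf)
        self._L_kpr = list(self._kpr)
        self._L_inv3n = list(inv3n)
        self._L_taur = list(taur_vec)
        self._L_g0s = list(g0s)
        self._L_expand = list(expand)
        self._L_regcode = [code[g.regulation_class] for g in self.tx_genes]
        self._L_u = [g.u if g.u is not None else 0.0 for g in self.tx_genes]
        self._L_tl_in_tx = [int(i) for i in self._tl_in_tx]
        self._m_sl = slice(5, 5 + len(tl))
        self._p_sl = slice(5 + len(tl), 5 + 2 * len(tl))
        self._i_r = self._idx["r"]
        self._i_Rtot = self._idx["Rtot"]
        self._i_Pab = self._idx["Pab"]
        self._i_Rab = self._idx["Rab"]
        self._i_X = self._idx.get("X")
        self._i_pQ = self._idx[self.protein_species("Q")]
        self._i_pE = self._idx[self.protein_species("E")]
        self._i_Ptot = self._idx[self.protein_species("P")]
        self._i_pR = self._idx[self.protein_species("R")]
        self._j_P = next(i for i, g in enumerate(tl) if g.name == "P")
        self._j_R = next(i for i, g in enumerate(tl) if g.name == "R")
        if self.pathway is not None:
            self._i_p1 = self._idx[self.protein_species(self.pathway.enzyme)]
        self._warned_negative = False

    @staticmethod
    def protein_species(gene_name: str) -> str:
        """State-vector name of a gene's protein pool (Ptot / p_R aliases)."""
        if gene_name == "P":
            return "Ptot"
        return f"p_{gene_name}"

    def index(self, name: str) -> int:
        try:
            return self._idx[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}; layout: {self.species}") from None

    # -- variants -----------------------------------------------------------

    def with_params(self, **updates) -> "CellModel":
        return CellModel(self.params.with_(**updates), self.culture, self.pathway)

    def with_culture(self, **updates) -> "CellModel":
        from dataclasses import replace
        return CellModel(self.params, replace(self.culture, **updates), self.pathway)

    def with_gene(self, name: str, **updates) -> "CellModel":
        return CellModel(self.params.with_gene(name, **updates),
                         self.culture, self.pathway)

    def state(self, vector: np.ndarray) -> CellState:
        return CellState(self, vector)

    # -- core algebra -------------------------------------------------------

    def _core(self, y: np.ndarray):
        """All algebraic quantities at a state (shared by rhs/fluxes/derived).

        Evaluation order: peptide elongation -> translation complexes ->
        growth rate -> regulation and copy numbers -> transcription rates ->
        transcription complexes.  The translation side never depends on
        gene dosage, so lambda is well-defined before g_j(lambda) is used.
        """
        p = self.params
        yl = y.tolist()
        ymin = min(yl)
        if ymin < 0.0:
            if ymin < -1.0e-6 and not self._warned_negative:
                log.warning("state fell below -1e-6 during integration (min %g); "
                            "clipping negatives to zero in rate laws", ymin)
                self._warned_negative = True
            yl = [v if v > 0.0 else 0.0 for v in yl]

        S, N, M, tu, tc = yl[0], yl[1], yl[2], yl[3], yl[4]
        m = yl[self._m_sl]
        prot = yl[self._p_sl]
        r = yl[self._i_r]
        Rtot = yl[self._i_Rtot]
        Ptot = yl[self._i_Ptot]
        p_Q = yl[self._i_pQ]
        p_E = yl[self._i_pE]
        p_R = yl[self._i_pR]

        # translation side
        gamma_X = p.D_gamma * p.gamma_max * tc / (p.K_gamma + tc)
        k_cm = p.k_cm
        ntl = self._ntl
        gamma_j = [gamma_X * inv for inv in self._L_invn_tl]
        K_L = [0.0] * ntl
        sKL = 0.0
        for j in range(ntl):
            v = m[j] * self._L_krf[j] / (self._L_krr[j] + gamma_j[j] + k_cm)
            K_L[j] = v
            sKL += v
        free_rib = Rtot / (1.0 + sKL)
        ctilde = [v * free_rib for v in K_L]
        ctilde_sum = sKL * free_rib
        lam = gamma_X * ctilde_sum / p.M0

        # regulation
        theta = p.D_g * tc / (tu if tu > p.theta_floor else p.theta_floor)
        act = theta / (theta + p.kappa_theta)
        rep = 1.0 - act
        R_Q = 1.0 / (1.0 + (p_Q / p.kappa_q) ** p.h_q)
        lookup = (R_Q, act, rep)
        Rj = [lookup[c] if c < 3 else rep * u
              for c, u in zip(self._L_regcode, self._L_u)]

        # gene dosage (expansion flag disables g(lambda) where configured);
        # the exponent is capped so integrator/solver trial states with
        # unphysically large lambda cannot overflow
        ex = p.q_x * lam
        expansion = math.exp(ex if ex < 30.0 else 30.0) - 1.0

        # transcription side
        sat = M / (p.K_tau + M)
        tau_X = p.tau_max * sat
        rr_sat = sat if p.rrna_elongation_M_dependent else 1.0
        k_rf = p.k_rf
        ntx = self._ntx
        tau_all = [0.0] * ntx
        K_X = [0.0] * ntx
        g_eff = [0.0] * ntx
        sKX = 0.0
        for i in range(ntx):
            tau_i = tau_X * self._L_inv3n[i] + self._L_taur[i] * rr_sat
            g_i = self._L_g0s[i] * (1.0 + expansion * self._L_expand[i])
            v = g_i * Rj[i] * self._L_kpf[i] / (self._L_kpr[i] + tau_i + k_rf)
            tau_all[i] = tau_i
            g_eff[i] = g_i
            K_X[i] = v
            sKX += v
        free_rnap = Ptot / (1.0 + sKX)
        ktilde = [v * free_rnap for v in K_X]

        return dict(
            S=S, N=N, M=M, tu=tu, tc=tc, m=m, prot=prot, r=r, Rtot=Rtot,
            Ptot=Ptot, p_Q=p_Q, p_E=p_E, p_R=p_R,
            Pab=yl[self._i_Pab], Rab=yl[self._i_Rab],
            gamma_X=gamma_X, gamma_j=gamma_j, ctilde=ctilde,
            ctilde_sum=ctilde_sum, free_rib=free_rib, lam=lam, theta=theta,
            Rj=Rj, g_eff=g_eff, tau_X=tau_X, tau_all=tau_all, ktilde=ktilde,
            free_rnap=free_rnap, y=yl,
        )

    # -- public derived view ------------------------------------------------

    def derived(self, state) -> DerivedQuantities:
        """Growth rate, theta, complexes and free pools at a state."""
        y = state.vector if isinstance(state, CellState) else np.asarray(state, float)
        c = self._core(y)
        return DerivedQuantities(
            growth_rate=c["lam"],
            theta=c["theta"],
            tau_X=c["tau_X"],
            gamma_X=c["gamma_X"],
            ktilde={g.name: float(k) for g, k in zip(self.tx_genes, c["ktilde"])},
            ctilde={g.name: float(v) for g, v in zip(self.tl_genes, c["ctilde"])},
            free_rnap=float(c["free_rnap"]),
            free_ribosomes=float(c["free_rib"]),
            regulation={g.name: float(v) for g, v in zip(self.tx_genes, c["Rj"])},
            copy_number={g.name: float(v) for g, v in zip(self.tx_genes, c["g_eff"])},
        )

    def growth_rate(self, state) -> float:
        y = state.vector if isinstance(state, CellState) else np.asarray(state, float)
        return self._core(y)["lam"]

    # -- fluxes and derivatives ---------------------------------------------

    def fluxes(self, state) -> dict[str, float]:
        """Named process fluxes at a state (molecules per cell per hour).

        The tRNA charging flux appears once here and enters dt_c/dt with +,
        dt_u/dt and dM/dt with -, so flux conservation is structural.
        """
        y = state.vector if isinstance(state, CellState) else np.asarray(state, float)
        c = self._core(y)
        p = self.params
        S, M, tu, tc = c["S"], c["M"], c["tu"], c["tc"]
        import_rate = p.v_E * S * c["p_E"] / (p.kappa_E + S)
        if tu <= 0.0 or M <= 0.0:
            charging = 0.0
        else:
            charging = p.v_T * c["p_E"] / (1.0 + p.K_u / tu + p.K_M / M)
        translation = c["gamma_X"] * c["ctilde_sum"]
        theta_act = c["theta"] / (c["theta"] + p.kappa_theta)
        trna_production = p.D_psi * p.psi_max * theta_act
        if self.pathway is not None:
            p1 = y[self._i_p1] if y[self._i_p1] > 0 else 0.0
            pathway_flux = self.pathway.v_ME * M * p1 / (self.pathway.kappa_ME + M)
        else:
            pathway_flux = 0.0
        assembly = p.beta_rho * c["p_R"] * c["r"]
        disassembly = p.mu_rho * c["Rtot"]
        return dict(
            substrate_import=import_rate,
            trna_charging=charging,
            translation_trna_use=translation,
            trna_production=trna_production,
            pathway_flux=pathway_flux,
            ribosome_assembly=assembly,
            ribosome_disassembly=disassembly,
            growth_rate=c["lam"],
        )

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the full state vector (t is unused; autonomous)."""
        y = np.asarray(y, dtype=float)
        if not math.isfinite(float(y.sum())):
            raise FloatingPointError(
                f"non-finite state passed to rhs at t={t}: "
                + ", ".join(f"{n}={v!r}" for n, v in zip(self.species, y))
            )
        p = self.params
        c = self._core(y)
        lam = c["lam"]
        S, N, M, tu, tc = c["S"], c["N"], c["M"], c["tu"], c["tc"]

        import_rate = p.v_E * S * c["p_E"] / (p.kappa_E + S)
        if tu <= 0.0 or M <= 0.0:
            charging = 0.0
        else:
            charging = p.v_T * c["p_E"] / (1.0 + p.K_u / tu + p.K_M / M)
        translation = c["gamma_X"] * c["ctilde_sum"]
        theta_act = c["theta"] / (c["theta"] + p.kappa_theta)
        trna_production = p.D_psi * p.psi_max * theta_act

        dy = np.empty_like(y)
        mode = self.culture.mode
        if mode == "single_cell":
            dy[0] = 0.0
            dy[1] = 0.0
        elif mode == "batch":
            dy[0] = -import_rate * N
            dy[1] = lam * N
        else:  # chemostat
            dy[0] = self.culture.k_in - import_rate * N - self.culture.delta * S
            dy[1] = (lam - self.culture.delta) * N

        pathway_flux = 0.0
        if self.pathway is not None:
            p1 = c["y"][self._i_p1]
            pathway_flux = self.pathway.v_ME * M * p1 / (self.pathway.kappa_ME + M)
            dy[self._i_X] = pathway_flux - lam * c["y"][self._i_X]

        dy[2] = p.phi * import_rate - charging - lam * M - pathway_flux
        dy[3] = trna_production - charging + translation - lam * tu
        dy[4] = charging - translation - lam * tc

        # mRNAs and proteins of translated genes
        tau_all, ktilde = c["tau_all"], c["ktilde"]
        gamma_j, ctilde = c["gamma_j"], c["ctilde"]
        m_l, prot = c["m"], c["prot"]
        dm_decay = p.delta_m + lam
        assembly = p.beta_rho * c["p_R"] * c["r"]
        disassembly = p.mu_rho * c["Rtot"]
        dy[self._m_sl] = [
            tau_all[i] * ktilde[i] - dm_decay * m_l[j]
            for j, i in enumerate(self._L_tl_in_tx)
        ]
        dprot = [gamma_j[j] * ctilde[j] - lam * prot[j] for j in range(self._ntl)]
        dprot[self._j_P] -= p.k_rf * c["Ptot"]
        dprot[self._j_R] += -assembly + disassembly
        dy[self._p_sl] = dprot

        # rRNA, ribosomes, sequestered pools
        k_rrna = ktilde[self._rrna_in_tx]
        tau_r = tau_all[self._rrna_in_tx]
        dy[self._i_r] = tau_r * k_rrna - lam * c["r"] - assembly + disassembly
        dy[self._i_Rtot] = assembly - disassembly - (lam + p.k_cm) * c["Rtot"]
        dy[self._i_Pab] = p.k_rf * c["Ptot"] - lam * c["Pab"]
        dy[self._i_Rab] = p.k_cm * c["Rtot"] - lam * c["Rab"]
        return dy
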