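"""Brute-force oracle: the cell model with explicit binding kinetics.

Instead of the quasi-steady-state complex algebra, this model integrates
every promoter–RNAP complex C_j and mRNA–ribosome complex D_j as a dynamic
species with mass-action binding to the free polymerase/ribosome pools:

    dC_j/dt = kp_f * P_free * g_j * R_j - (kp_r + tau_j) * C_j
    dD_j/dt = kr_f * R_free * m_j       - (kr_r + gamma_j) * D_j

with P_free = P_tot - sum(C) and R_free = R_tot - sum(D).  Elongation
completion (tau_j, gamma_j per complex) releases the polymerase/ribosome
and emits one mRNA/protein.  All rate laws (elongation saturation,
regulation, growth, tRNA charging) are written out independently here, so
steady states of this model are an implementation-independent reference:
when binding is much faster than elongation the QSS model must agree.

Antibiotic sequestration is not modelled (use k_rf = k_cm = 0).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


class MechanisticCell:
    """Explicit-binding counterpart of a CellModel (single-cell mode only)."""

    def __init__(self, params, S0: float):
        assert params.k_rf == 0.0 and params.k_cm == 0.0, \
            "oracle does not model antibiotic sequestration"
        self.p = params
        self.S0 = S0
        self.genes = list(params.genes)
        self.tl = [g for g in self.genes if not g.is_rRNA]
        self.rrna = next(g for g in self.genes if g.is_rRNA)
        # layout: M, tu, tc, C_j (all genes), m_j (tl), D_j (tl), p_j (tl),
        #         r, Rtot
        self.n_tx = len(self.genes)
        self.n_tl = len(self.tl)
        self.names = (["M", "tu", "tc"]
                      + [f"C_{g.name}" for g in self.genes]
                      + [f"m_{g.name}" for g in self.tl]
                      + [f"D_{g.name}" for g in self.tl]
                      + [f"p_{g.name}" for g in self.tl]
                      + ["r", "Rtot"])
        self.idx = {n: i for i, n in enumerate(self.names)}

    def initial_state(self) -> np.ndarray:
        y = np.zeros(len(self.names))
        y[self.idx["M"]] = 1e3
        y[self.idx["tu"]] = 1e3
        y[self.idx["tc"]] = 1e3
        for g in self.tl:
            y[self.idx[f"p_{g.name}"]] = 100.0
        y[self.idx["Rtot"]] = 100.0
        return y

    def rhs(self, t, y):
        p = self.p
        y = np.maximum(y, 0.0)
        i = self.idx
        M, tu, tc = y[i["M"]], y[i["tu"]], y[i["tc"]]
        C = y[3:3 + self.n_tx]
        m = y[3 + self.n_tx:3 + self.n_tx + self.n_tl]
        D = y[3 + self.n_tx + self.n_tl:3 + self.n_tx + 2 * self.n_tl]
        prot = y[3 + self.n_tx + 2 * self.n_tl:3 + self.n_tx + 3 * self.n_tl]
        r, Rtot = y[i["r"]], y[i["Rtot"]]
        pdict = {g.name: prot[j] for j, g in enumerate(self.tl)}
        Ptot_free_pool = pdict["P"]      # p_P counts FREE RNAP here
        # NB: in the QSS model Ptot counts free + bound polymerase; here the
        # protein state p_P is the total and free = p_P - sum(C).
        P_free = max(Ptot_free_pool - C.sum(), 0.0)
        R_free = max(Rtot - D.sum(), 0.0)

        gamma_X = p.D_gamma * p.gamma_max * tc / (p.K_gamma + tc)
        gamma_j = np.array([gamma_X / g.n for g in self.tl])
        lam = gamma_X * D.sum() / p.M0

        theta = p.D_g * tc / max(tu, p.theta_floor)
        act = theta / (theta + p.kappa_theta)
        rep = 1.0 - act
        R_Q = 1.0 / (1.0 + (pdict["Q"] / p.kappa_q) ** p.h_q)

        def reg(g):
            c = g.regulation_class
            if c == "housekeeping_Q":
                return R_Q
            if c == "resource_activated":
                return act
            if c == "enzyme_repressed":
                return rep
            return rep * g.u

        sat = M / (p.K_tau + M)
        tau_X = p.tau_max * sat

        def tau_of(g):
            if g.is_rRNA:
                base = p.tau_r_max / g.n
                return base * sat if p.rrna_elongation_M_dependent else base
            return tau_X / (3.0 * g.n)

        expansion = math.exp(min(p.q_x * lam, 30.0))

        def dosage(g):
            e = expansion
            if g.regulation_class == "circuit" and not p.circuit_copy_expansion:
                e = 1.0
            return g.g0 * e * (p.D_r if g.is_rRNA else 1.0)

        dy = np.zeros_like(y)
        # promoter complexes
        dC = np.empty(self.n_tx)
        for j, g in enumerate(self.genes):
            dC[j] = (g.kp_f * P_free * dosage(g) * reg(g)
                     - (g.kp_r + tau_of(g)) * C[j] - lam * C[j])
        # mRNAs and ribosome complexes
        dm = np.empty(self.n_tl)
        dD = np.empty(self.n_tl)
        dp = np.empty(self.n_tl)
        for j, g in enumerate(self.tl):
            jc = self.genes.index(g)
            dm[j] = tau_of(g) * C[jc] - (p.delta_m + lam) * m[j]
            dD[j] = g.kr_f * R_free * m[j] - (g.kr_r + gamma_j[j]) * D[j] \
                - lam * D[j]
            dp[j] = gamma_j[j] * D[j] - lam * prot[j]

        S = self.S0
        p_E = pdict["E"]
        import_rate = p.v_E * S * p_E / (p.kappa_E + S)
        charging = 0.0
        if tu > 0 and M > 0:
            charging = p.v_T * p_E / (1.0 + p.K_u / tu + p.K_M / M)
        translation = gamma_X * D.sum()
        trna_production = p.D_psi * p.psi_max * act

        assembly = p.beta_rho * pdict["R"] * r
        disassembly = p.mu_rho * Rtot
        jR = self.tl.index(next(g for g in self.tl if g.name == "R"))
        dp[jR] += -assembly + disassembly
        jrr = self.genes.index(self.rrna)
        dr = tau_of(self.rrna) * C[jrr] - lam * r - assembly + disassembly
        dRtot = assembly - disassembly - lam * Rtot

        dy[i["M"]] = p.phi * import_rate - charging - lam * M
        dy[i["tu"]] = trna_production - charging + translation - lam * tu
        dy[i["tc"]] = charging - translation - lam * tc
        dy[3:3 + self.n_tx] = dC
        dy[3 + self.n_tx:3 + self.n_tx + self.n_tl] = dm
        dy[3 + self.n_tx + self.n_tl:3 + self.n_tx + 2 * self.n_tl] = dD
        dy[3 + self.n_tx + 2 * self.n_tl:3 + self.n_tx + 3 * self.n_tl] = dp
        dy[i["r"]] = dr
        dy[i["Rtot"]] = dRtot
        return dy

    def steady_state(self, t_max: float = 2000.0) -> dict[str, float]:
        y = self.initial_state()
        sol = solve_ivp(self.rhs, (0.0, t_max), y, method="LSODA",
                        rtol=1e-8, atol=1e-8, t_eval=(t_max,))
        assert sol.success, sol.message
        y = np.maximum(sol.y[:, -1], 0.0)
        # polish to a true fixed point in log space over the positive states
        pos = y > 0
        z0 = np.log(y[pos])

        def fun(z):
            yy = y.copy()
            yy[pos] = np.exp(np.minimum(np.maximum(z, -35.0), 35.0))
            return self.rhs(0.0, yy)[pos] / yy[pos]

        res = root(fun, z0, method="hybr", options={"maxfev": 4000})
        if np.all(np.isfinite(res.x)):
            y2 = y.copy()
            y2[pos] = np.exp(res.x)
            if np.max(np.abs(self.rhs(0.0, y2))) < np.max(np.abs(self.rhs(0.0, y))):
                y = y2
        return dict(zip(self.names, y))
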