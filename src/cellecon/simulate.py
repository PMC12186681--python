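"""Integration, steady-state solving, mass fractions and sweep protocols.

Steady states are found by time marching: integrate with a stiff solver
over a horizon that doubles (starting at 100 h) until the maximal absolute
state derivative falls below 1e-3.  An
optional Newton polish (root solve in log-space on the non-frozen,
non-structurally-zero species) accelerates convergence; its result is only
accepted if it passes the same derivative criterion, so the contract is
identical with or without it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import CellModel, CellState
from .params import CultureMode

__all__ = [
    "default_initial_state",
    "integrate",
    "solve_steady_state",
    "mass_fractions",
    "isocost_sweep",
    "sweep",
    "SteadyStateResult",
    "SweepResult",
    "IntegrationError",
]

log = logging.getLogger(__name__)

STEADY_STATE_TOL = 1.0e-3   # max |derivative| at convergence
T_START = 100.0             # first integration horizon (h)
T_CAP = 1.0e6               # horizon cap (h)


class IntegrationError(RuntimeError):
    """Integration failed; carries the last good state."""

    def __init__(self, message: str, last_state: Optional[CellState] = None):
        super().__init__(message)
        self.last_state = last_state


def default_initial_state(model: CellModel) -> CellState:
    """Standard initial condition: 100 molecules of every protein species
    (including ribosomes), 1e3 molecules of M, t_u and t_c; mRNAs, free
    rRNA, sequestered pools and pathway product start at zero.  S and N
    come from the culture mode.
    """
    y = np.zeros(model.n_species)
    st = model.state(y)
    st["S"] = model.culture.S0
    st["N"] = model.culture.N0
    st["M"] = 1.0e3
    st["tu"] = 1.0e3
    st["tc"] = 1.0e3
    for g in model.tl_genes:
        st[model.protein_species(g.name)] = 100.0
    st["Rtot"] = 100.0
    return st


def integrate(model: CellModel, state0: CellState, t_span,
              t_eval: Optional[Sequence[float]] = None,
              rtol: float = 1.0e-6, atol: float = 1.0e-3,
              method: str = "LSODA") -> pd.DataFrame:
    """Integrate the model and return a tidy trajectory table.

    One row per time point; columns are every species plus the derived
    ``lambda``, ``theta`` and mass-fraction (``Phi_*``) columns.
    """
    t_span = tuple(float(t) for t in t_span)
    if t_span[1] == t_span[0]:
        rows = [state0.vector]
        times = [t_span[0]]
    else:
        sol = solve_ivp(model.rhs, t_span, state0.vector, method=method,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            last = model.state(sol.y[:, -1]) if sol.y.size else state0
            raise IntegrationError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t_span[0]}: "
                f"{sol.message}", last_state=last)
        rows = sol.y.T
        times = sol.t
    recs = []
    for t, y in zip(times, rows):
        st = model.state(np.asarray(y))
        rec = {"time": t, **st.as_dict()}
        rec["lambda"] = model.growth_rate(st)
        rec["theta"] = model.derived(st).theta
        for k, v in mass_fractions(st, model).items():
            rec[f"Phi_{k}"] = v
        recs.append(rec)
    return pd.DataFrame(recs)


def mass_fractions(state: CellState, model: CellModel) -> dict[str, float]:
    """Proteome mass fractions by gene class.

    Each class's mass is protein length times total copies — free protein
    plus antibiotic-sequestered pools; ribosomal mass counts the r-protein
    content of assembled (and sequestered) ribosomes plus free r-protein.
    Keys: ``p`` (RNA polymerase), ``r`` (ribosomal), ``E``, ``Q`` and one
    per circuit gene; values sum to 1.
    """
    masses: dict[str, float] = {}
    for g in model.tl_genes:
        copies = state[model.protein_species(g.name)]
        if g.name == "P":
            copies += state["Pab"]
            key = "p"
        elif g.name == "R":
            copies += state["Rtot"] + state["Rab"]
            key = "r"
        else:
            key = g.name
        masses[key] = g.n * copies
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("total protein mass is zero; mass fractions undefined")
    return {k: v / total for k, v in masses.items()}


@dataclass
class SteadyStateResult:
    """A converged (or flagged) fixed point of the model."""

    state: CellState
    growth_rate: float
    theta: float
    mass_fractions: dict[str, float]
    max_abs_derivative: float
    horizon: float
    converged: bool
    lambda_gap: Optional[float] = None   # |lambda - delta| in chemostat mode

    def __getitem__(self, name: str) -> float:
        return self.state[name]


# -- Newton fast path --------------------------------------------------------

def _solved_indices(model: CellModel) -> np.ndarray:
    """Indices solved by the Newton polish: drop frozen and structurally-zero
    species (their fixed-point values are known exactly)."""
    p = model.params
    skip: set[int] = set()
    if model.culture.mode == "single_cell":
        skip |= {model.index("S"), model.index("N")}
    if p.k_rf == 0.0:
        skip.add(model.index("Pab"))
    if p.k_cm == 0.0:
        skip.add(model.index("Rab"))
    off = set()
    for g in model.tl_genes:
        if g.regulation_class == "circuit" and (g.u or 0.0) == 0.0:
            off.add(g.name)
            skip.add(model.index(f"m_{g.name}"))
            skip.add(model.index(model.protein_species(g.name)))
    if model.pathway is not None and model.pathway.enzyme in off:
        skip.add(model.index("X"))
    return np.array([i for i in range(model.n_species) if i not in skip])


def _newton_polish(model: CellModel, y0: np.ndarray) -> Optional[np.ndarray]:
    """Try to converge y0 to an exact fixed point; None on failure.

    Solves rhs(x)/x = 0 in log-space over the non-pinned species, which
    enforces positivity and equalises scales across species spanning many
    orders of magnitude.
    """
    idx = _solved_indices(model)
    pinned = np.setdiff1d(np.arange(model.n_species), idx)
    y_base = y0.copy()
    # pinned structurally-zero species sit exactly at zero; frozen S,N keep y0
    for i in pinned:
        if model.species[i] not in ("S", "N"):
            y_base[i] = 0.0
    # solved species stuck at zero (e.g. a warm start from a model where they
    # were off) are seeded at one molecule; log-space steps recover the scale
    zero = y_base[idx] <= 0.0
    if zero.any():
        y_base[idx[zero]] = 1.0

    def fun(z):
        y = y_base.copy()
        # keep trial states in (~1e-16, ~1.6e15); np.minimum/maximum beat np.clip
        x = np.exp(np.minimum(np.maximum(z, -35.0), 35.0))
        y[idx] = x
        dy = model.rhs(0.0, y)
        return dy[idx] / x

    z0 = np.log(y_base[idx])
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = root(fun, z0, method="hybr", options={"xtol": 1e-12, "maxfev": 1200})
    except FloatingPointError:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    y = y_base.copy()
    y[idx] = np.exp(np.minimum(np.maximum(sol.x, -35.0), 35.0))
    if not np.all(np.isfinite(y)) or y.max() > 1e15:
        return None
    return y


def _chemostat_shortcut(model: CellModel, tol: float) -> Optional[np.ndarray]:
    """Construct the interior chemostat fixed point from single-cell solves.

    At a chemostat steady state the intracellular equations coincide with
    the single-cell model held at the (unknown) residual substrate S*, so
    S* solves lambda(S*) = delta by a 1-D bracketing search over fast
    single-cell steady states, and N* follows from the substrate balance
    k_in = import(S*) * N* + delta * S*.  Returns None when no interior
    fixed point is found (washout); the caller then falls back to time
    marching.
    """
    from scipy.optimize import brentq

    delta, k_in = model.culture.delta, model.culture.k_in
    cache: dict = {}

    def lam(S: float) -> float:
        m = CellModel(model.params,
                      CultureMode(mode="single_cell", S0=S), model.pathway)
        res = steady_state_from(m, cache.get("warm"))
        if res.converged:
            cache["warm"] = res.state
            cache[S] = res
        return res.growth_rate if res.converged else math.nan

    S_hi = max(model.culture.S0, 100.0 * model.params.kappa_E)
    if k_in > 0:
        S_hi = min(S_hi, k_in / delta)   # S* can never exceed the feed limit
    try:
        lam_hi = lam(S_hi)
        if not (lam_hi > delta):
            return None                  # dilution exceeds growth capacity
        S_lo = S_hi
        lam_lo = lam_hi
        for _ in range(40):
            S_lo /= 8.0
            lam_lo = lam(S_lo)
            if math.isnan(lam_lo):
                return None
            if lam_lo < delta:
                break
        else:
            return None
        S_star = brentq(lambda s: lam(s) - delta, S_lo, S_hi, rtol=1e-12)
    except (ValueError, IntegrationError, FloatingPointError):
        return None
    res = cache.get(S_star)
    if res is None:
        m = CellModel(model.params,
                      CultureMode(mode="single_cell", S0=S_star), model.pathway)
        res = steady_state_from(m, cache.get("warm"))
        if not res.converged:
            return None
    st = res.state
    p = model.params
    p_E = st[model.protein_species("E")]
    import_rate = p.v_E * S_star * p_E / (p.kappa_E + S_star)
    if import_rate <= 0:
        return None
    N_star = (k_in - delta * S_star) / import_rate
    if N_star <= 0:
        return None
    y = st.vector.copy()
    y[model.index("S")] = S_star
    y[model.index("N")] = N_star
    y_n = _newton_polish(model, y)
    if y_n is not None and _max_abs_deriv(model, y_n) < tol:
        return y_n
    if _max_abs_deriv(model, y) < tol:
        return y
    return None


def solve_steady_state(model: CellModel, state0: Optional[CellState] = None,
                       tol: float = STEADY_STATE_TOL,
                       t_start: float = T_START, t_cap: float = T_CAP,
                       newton: bool = True) -> SteadyStateResult:
    """Run the model to steady state.

    Horizon-doubling time integration (100 h start, 1e6 h cap) with the
    convergence criterion max |dy/dt| < tol (default 1e-3); an optional
    Newton polish that must satisfy the same criterion.  In chemostat mode
    an algebraic shortcut (single-cell fixed point at the residual substrate
    S* with lambda(S*) = delta) is tried first; it must pass the same
    derivative criterion.  The result reports |lambda* - delta| in chemostat
    mode.  A hit of the horizon cap returns a flagged, not raised, result.
    Batch cultures have no fixed point and are rejected.
    """
    if model.culture.mode == "batch":
        raise ValueError("batch cultures deplete substrate and have no steady state")
    if model.culture.mode == "chemostat" and newton and state0 is None:
        y_fast = _chemostat_shortcut(model, tol)
        if y_fast is not None:
            return _package_result(model, y_fast, horizon=0.0, tol=tol)
    y = (state0 or default_initial_state(model)).vector.copy()
    horizon = 0.0
    t = t_start
    best = y
    best_res = _max_abs_deriv(model, y)
    while True:
        if newton:
            y_n = _newton_polish(model, best)
            if y_n is not None:
                res_n = _max_abs_deriv(model, y_n)
                if res_n < best_res and _plausible(model, best, y_n):
                    best, best_res = y_n, res_n
        if best_res < tol:
            break
        if horizon >= t_cap:
            log.warning("steady state not reached by t=%g (max|dy/dt|=%g)",
                        horizon, best_res)
            break
        try:
            # endpoint-only output: long horizons would otherwise store
            # millions of internal steps
            sol = solve_ivp(model.rhs, (0.0, t), best, method="LSODA",
                            rtol=1e-7, atol=1e-6, t_eval=(t,))
        except FloatingPointError:
            sol = None
        if sol is not None and sol.success:
            y_end = np.maximum(sol.y[:, -1], 0.0)
            res_end = _max_abs_deriv(model, y_end)
            best, best_res = y_end, res_end
        horizon += t
        t *= 2.0
    return _package_result(model, best, horizon=horizon, tol=tol,
                           residual=best_res)


def _package_result(model: CellModel, y: np.ndarray, horizon: float,
                    tol: float, residual: Optional[float] = None
                    ) -> SteadyStateResult:
    if residual is None:
        residual = _max_abs_deriv(model, y)
    st = model.state(np.maximum(y, 0.0))
    der = model.derived(st)
    gap = None
    if model.culture.mode == "chemostat":
        gap = abs(der.growth_rate - model.culture.delta)
    return SteadyStateResult(
        state=st,
        growth_rate=der.growth_rate,
        theta=der.theta,
        mass_fractions=mass_fractions(st, model),
        max_abs_derivative=residual,
        horizon=horizon,
        converged=residual < tol,
        lambda_gap=gap,
    )


def _max_abs_deriv(model: CellModel, y: np.ndarray) -> float:
    try:
        return float(np.max(np.abs(model.rhs(0.0, y))))
    except FloatingPointError:
        return math.inf


def _plausible(model: CellModel, y_ref: np.ndarray, y_new: np.ndarray) -> bool:
    """Reject Newton jumps to a different basin (e.g. the trivial dead state)."""
    lam_ref = model.growth_rate(y_ref)
    lam_new = model.growth_rate(y_new)
    if lam_ref > 1e-3 and lam_new < 1e-6:
        return False
    return True


def steady_state_from(model: CellModel, warm: Optional[CellState],
                      tol: float = STEADY_STATE_TOL,
                      t_cap: float = T_CAP) -> SteadyStateResult:
    """Steady state with a warm start (used along sweeps); falls back to the
    cold protocol if the warm start does not converge.  ``t_cap`` bounds the
    integration horizon (callers that probe many throwaway parameter sets,
    e.g. a fitting swarm, pass a smaller cap so hopeless candidates fail
    fast)."""
    if warm is not None and warm.model.n_species == model.n_species:
        y0 = warm.vector.copy()
        if model.culture.mode == "single_cell":
            # S and N are frozen in this mode: they must come from the model's
            # own culture, not from the warm state's
            y0[model.index("S")] = model.culture.S0
            y0[model.index("N")] = model.culture.N0
        y_n = _newton_polish(model, y0)
        if y_n is not None:
            res_n = _max_abs_deriv(model, y_n)
            if res_n < tol and _plausible(model, y0, y_n):
                return _package_result(model, y_n, horizon=0.0, tol=tol,
                                       residual=res_n)
        try:
            # short legs first: a few hours of integration usually brings a
            # perturbed warm state back into the Newton basin
            res = solve_steady_state(model, state0=model.state(y0),
                                     tol=tol, t_start=5.0,
                                     t_cap=min(2.0e5, t_cap))
            if res.converged:
                return res
        except (IntegrationError, FloatingPointError):
            pass
    return solve_steady_state(model, tol=tol, t_cap=t_cap)


# -- sweeps ------------------------------------------------------------------

@dataclass
class SweepResult:
    """Steady states tabulated over a swept control variable."""

    control: str
    grid: np.ndarray
    results: list[SteadyStateResult]
    slope: Optional[float] = None       # isocost fit of p2 on p1
    intercept: Optional[float] = None
    r_squared: Optional[float] = None
    flagged: list[int] = field(default_factory=list)  # non-converged grid indices

    def table(self) -> pd.DataFrame:
        recs = []
        for v, r in zip(self.grid, self.results):
            rec = {self.control: v, "lambda": r.growth_rate, "theta": r.theta,
                   "converged": r.converged,
                   "max_abs_derivative": r.max_abs_derivative}
            for k, f in r.mass_fractions.items():
                rec[f"Phi_{k}"] = f
            for name in r.state.model.species:
                rec[name] = r.state[name]
            recs.append(rec)
        return pd.DataFrame(recs)


def _set_control(model: CellModel, control: str, value: float) -> CellModel:
    if control in ("delta", "lambda_set"):
        return model.with_culture(mode="chemostat", delta=float(value),
                                  k_in=model.culture.k_in)
    if control in ("k_rf", "k_cm", "D_r", "D_gamma", "D_psi", "D_g", "phi"):
        return model.with_params(**{control: float(value)})
    if control.startswith("u:"):
        return model.with_gene(control[2:], u=float(value))
    raise ValueError(f"unknown sweep control {control!r}")


def sweep(model: CellModel, control: str, grid: Iterable[float],
          warm_start: bool = True) -> SweepResult:
    """Steady state per grid point of a control variable.

    ``control`` is one of delta/lambda_set (chemostat dilution), k_rf, k_cm,
    D_r, D_gamma, D_psi, D_g, phi, or ``u:<gene>`` for a circuit induction.
    Points are warm-started from the previous point's state; the first point
    starts from the default initial condition.
    """
    grid = np.asarray(list(grid), dtype=float)
    if len(grid) and not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("sweep grid must be strictly monotone")
    results, flagged = [], []
    warm: Optional[CellState] = None
    for i, v in enumerate(grid):
        m = _set_control(model, control, v)
        res = steady_state_from(m, warm if warm_start else None)
        if not res.converged:
            flagged.append(i)
            log.warning("sweep %s=%g did not converge (max|dy/dt|=%g)",
                        control, v, res.max_abs_derivative)
        else:
            warm = res.state
        results.append(res)
    return SweepResult(control=control, grid=grid, results=results, flagged=flagged)


def isocost_sweep(model: CellModel, u1_grid: Optional[Iterable[float]] = None,
                  u2: float = 1.0, normalize: bool = False) -> SweepResult:
    """The two-reporter isocost protocol.

    Sweeps the induction u_1 of the first circuit gene over [0, 1] while the
    second is held at ``u2`` (default 1), collects steady-state protein
    levels (p_1*, p_2*), and fits the isocost line by ordinary least squares
    of p_2 on p_1 (slope, intercept, R^2).  With ``normalize`` the fit is on
    levels divided by each reporter's maximum over the sweep.
    """
    circuits = [g for g in model.tl_genes if g.regulation_class == "circuit"]
    if len(circuits) != 2:
        raise ValueError(
            f"isocost sweep needs exactly two circuit genes, found {len(circuits)}")
    g1, g2 = circuits
    if u1_grid is None:
        u1_grid = np.linspace(0.0, 1.0, 11)
    m = model.with_gene(g2.name, u=float(u2))
    out = sweep(m, f"u:{g1.name}", u1_grid)
    ok = [i for i in range(len(out.grid)) if i not in out.flagged]
    p1 = np.array([out.results[i].state[model.protein_species(g1.name)] for i in ok])
    p2 = np.array([out.results[i].state[model.protein_species(g2.name)] for i in ok])
    if normalize:
        p1 = p1 / p1.max() if p1.max() > 0 else p1
        p2 = p2 / p2.max() if p2.max() > 0 else p2
    if len(ok) >= 2:
        A = np.vstack([p1, np.ones_like(p1)]).T
        (slope, intercept), res_ss, *_ = np.linalg.lstsq(A, p2, rcond=None)
        ss_tot = float(np.sum((p2 - p2.mean()) ** 2))
        ss_res = float(res_ss[0]) if len(res_ss) else float(
            np.sum((p2 - A @ [slope, intercept]) ** 2))
        out.slope = float(slope)
        out.intercept = float(intercept)
        out.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return out
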