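"""Growth-law calibration: simulated growth-law curves, the weighted
normalized-SSE cost, and particle-swarm parameter fitting.

Growth rate is varied in the exponential (single-cell) regime through the
nutrient-quality yield ``phi`` and the ribosome-sequestration rate ``k_cm``;
each condition's steady state yields the observables growth rate ``lambda``,
ribosomal mass fraction ``Phi_R``, global peptide elongation rate ``Gamma``
(aa/h) and the charged/uncharged tRNA ratio ``theta``.  Observed growth-law
tables (two literature sources, labelled ``DB`` and ``Scott``) are compared
against condition-matched simulations through per-observable sums of squared
errors, each normalized by the sum of squares of the observations, combined
with weights 10 (lambda, DB), 5 (lambda, Scott), 5 (Phi_R, Scott) and 1 each
for Phi_R, Gamma and theta from DB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CellModel
from .params import CultureMode, ModelParameters
from .simulate import steady_state_from

__all__ = [
    "GrowthLawDataset",
    "FitConfig",
    "FitResult",
    "COST_WEIGHTS",
    "growth_law_curves",
    "normalized_sse",
    "fit_cost",
    "fit_parameters",
    "synth_growth_law_dataset",
    "read_growth_law_table",
    "write_growth_law_table",
]

log = logging.getLogger(__name__)

OBSERVABLES = ("lambda", "phi_R", "gamma", "theta")

#: (source, observable) -> weight in the fitting cost.
COST_WEIGHTS = {
    ("DB", "lambda"): 10.0,
    ("Scott", "lambda"): 5.0,
    ("Scott", "phi_R"): 5.0,
    ("DB", "phi_R"): 1.0,
    ("DB", "gamma"): 1.0,
    ("DB", "theta"): 1.0,
}

PENALTY_COST = 1.0e6   # assigned when a candidate's simulation fails


@dataclass
class GrowthLawDataset:
    """Observed or simulated growth-law observables over culture conditions.

    ``table`` columns: ``condition`` (id), ``phi``, ``k_cm`` (the condition
    coordinates) and any subset of ``lambda``, ``phi_R``, ``gamma``,
    ``theta`` (missing observables may be absent or NaN).
    """

    source: str
    table: pd.DataFrame

    def __post_init__(self):
        for col in ("condition", "phi", "k_cm"):
            if col not in self.table.columns:
                raise ValueError(f"growth-law table needs a {col!r} column")
        present = [c for c in OBSERVABLES if c in self.table.columns]
        if not present:
            raise ValueError("growth-law table has no observable columns")
        bad = self.table[present].lt(0).any()
        if bad.any():
            raise ValueError(f"negative observables in columns "
                             f"{list(bad[bad].index)}")

    def require_fit_ready(self) -> "GrowthLawDataset":
        """Validate the minimum support for fitting: >= 3 rows per used
        observable (simulated single-point tables are fine elsewhere)."""
        for c in self.observables:
            n = self.table[c].notna().sum()
            if n < 3:
                raise ValueError(
                    f"observable {c!r} has only {n} rows; at least 3 required "
                    f"for fitting")
        return self

    @property
    def observables(self) -> list[str]:
        return [c for c in OBSERVABLES
                if c in self.table.columns and self.table[c].notna().any()]

    def conditions(self) -> list[tuple[float, float]]:
        return [(float(r.phi), float(r.k_cm)) for r in self.table.itertuples()]


def growth_law_curves(params: ModelParameters,
                      phi_grid: Sequence[float],
                      kcm_grid: Sequence[float] = (0.0,),
                      source: str = "simulated",
                      conditions: Optional[Sequence[tuple[float, float]]] = None,
                      _warm: Optional[dict] = None,
                      _t_cap: float = 1.0e6) -> GrowthLawDataset:
    """Simulate growth-law observables over a (phi, k_cm) condition grid.

    One exponential-regime steady state per condition; rows of
    (lambda, Phi_R, Gamma, theta).  ``conditions`` overrides the grid
    product with an explicit condition list.  Non-converged conditions are
    dropped with a warning.  ``_warm`` is an internal warm-start cache
    reused across repeated calls with similar parameters.
    """
    if conditions is None:
        if not len(phi_grid) or not len(kcm_grid):
            raise ValueError("phi_grid and kcm_grid must be non-empty")
        conditions = [(float(p), float(k)) for k in kcm_grid for p in phi_grid]
    warm = _warm if _warm is not None else {}
    rows = []
    prev = None
    for i, (phi, kcm) in enumerate(conditions):
        model = CellModel(params.with_(phi=phi, k_cm=kcm),
                          CultureMode(mode="single_cell"))
        res = steady_state_from(model, warm.get(i, prev), t_cap=_t_cap)
        if not res.converged:
            log.warning("growth-law condition phi=%g k_cm=%g did not converge; "
                        "dropped", phi, kcm)
            continue
        warm[i] = res.state
        prev = res.state
        der = model.derived(res.state)
        rows.append(dict(condition=f"phi={phi:g},kcm={kcm:g}", phi=phi,
                         k_cm=kcm, **{"lambda": res.growth_rate},
                         phi_R=res.mass_fractions["r"], gamma=der.gamma_X,
                         theta=res.theta))
    return GrowthLawDataset(source=source, table=pd.DataFrame(rows))


def normalized_sse(sim: Iterable[float], exp: Iterable[float]) -> float:
    """sigma = sum((sim - exp)^2) / sum(exp^2).

    Zero iff sim == exp; equals 1 for an all-zero prediction; invariant
    under a common rescaling of both vectors.
    """
    sim = np.asarray(list(sim), dtype=float)
    exp = np.asarray(list(exp), dtype=float)
    if sim.shape != exp.shape:
        raise ValueError(f"length mismatch: {sim.shape} vs {exp.shape}")
    denom = float(np.sum(exp ** 2))
    if denom <= 0.0:
        raise ValueError("experimental vector is all zeros; sigma undefined")
    return float(np.sum((sim - exp) ** 2) / denom)


def fit_cost(params: ModelParameters,
             datasets: Sequence[GrowthLawDataset],
             _warm: Optional[dict] = None) -> float:
    """Weighted growth-law cost of a parameter set against datasets.

    cost = 10*sigma(lambda,DB) + 5*sigma(lambda,Scott) + 5*sigma(phi_R,Scott)
         + sigma(phi_R,DB) + sigma(gamma,DB) + sigma(theta,DB)

    Datasets whose source is neither DB nor Scott contribute with weight 1
    per observable.  Missing observable series contribute 0 with a warning.
    Simulation failure at any condition yields a large finite penalty so a
    swarm can continue.
    """
    total = 0.0
    warm_all = _warm if _warm is not None else {}
    for ds in datasets:
        mask = None
        try:
            sim = growth_law_curves(params, phi_grid=(), kcm_grid=(),
                                    conditions=ds.conditions(),
                                    _warm=warm_all.setdefault(ds.source, {}),
                                    _t_cap=2.0e4)
        except Exception as exc:            # pragma: no cover - defensive
            log.warning("simulation failed for %s: %s; penalty cost", ds.source, exc)
            return PENALTY_COST
        if len(sim.table) != len(ds.table):
            # non-converged conditions: candidate cannot reproduce the data
            return PENALTY_COST
        for obs in OBSERVABLES:
            weight = COST_WEIGHTS.get((ds.source, obs),
                                      1.0 if ds.source not in ("DB", "Scott")
                                      else None)
            if weight is None:
                continue
            if obs not in ds.table.columns or not ds.table[obs].notna().any():
                if (ds.source, obs) in COST_WEIGHTS:
                    log.warning("dataset %s lacks %s; term contributes 0",
                                ds.source, obs)
                continue
            mask = ds.table[obs].notna().to_numpy()
            total += weight * normalized_sse(sim.table[obs].to_numpy()[mask],
                                             ds.table[obs].to_numpy()[mask])
    return total


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Particle-swarm settings.

    Defaults: 500 particles, 500 generations; inertia 0.729 and
    cognitive/social weights 1.49 are the standard constriction values.
    """

    free_params: tuple[str, ...] = ()
    bounds: tuple[tuple[float, float], ...] = ()
    n_particles: int = 500
    n_generations: int = 500
    seed: int = 0
    inertia: float = 0.729
    cognitive: float = 1.49
    social: float = 1.49

    def __post_init__(self):
        if not self.free_params:
            raise ValueError("at least one free parameter is required")
        if len(self.bounds) != len(self.free_params):
            raise ValueError("one (lower, upper) bound pair per free parameter")
        for name, (lo, hi) in zip(self.free_params, self.bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")


@dataclass
class FitResult:
    params: ModelParameters
    best_values: dict[str, float]
    best_cost: float
    cost_trace: np.ndarray          # best-so-far cost per generation
    n_evaluations: int


def fit_parameters(datasets: Sequence[GrowthLawDataset],
                   config: FitConfig,
                   base_params: Optional[ModelParameters] = None) -> FitResult:
    """Global fit of the free parameters by gbest particle swarm.

    Deterministic for a fixed seed; the returned cost trace (best-so-far
    per generation) is monotone non-increasing.  Positions are reflected at
    the bounds; each particle keeps a steady-state warm-start cache so
    successive cost evaluations are cheap.
    """
    from .params import default_parameters
    for ds in datasets:
        ds.require_fit_ready()
    base = base_params if base_params is not None else default_parameters()
    rng = np.random.default_rng(config.seed)
    d = len(config.free_params)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo

    pos = lo + span * rng.random((config.n_particles, d))
    vel = span * (rng.random((config.n_particles, d)) - 0.5) * 0.2
    warm_caches = [dict() for _ in range(config.n_particles)]
    n_eval = 0

    def cost_of(x: np.ndarray, i: int) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            p = base.with_(**{k: float(v) for k, v in zip(config.free_params, x)})
            p.check()
        except Exception:
            return PENALTY_COST
        return fit_cost(p, datasets, _warm=warm_caches[i])

    pbest = pos.copy()
    pbest_cost = np.array([cost_of(pos[i], i) for i in range(config.n_particles)])
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])
    trace = [gbest_cost]

    for _ in range(config.n_generations):
        r1 = rng.random((config.n_particles, d))
        r2 = rng.random((config.n_particles, d))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest - pos))
        pos = pos + vel
        # reflect at the bounds
        over_lo = pos < lo
        pos = np.where(over_lo, 2 * lo - pos, pos)
        vel = np.where(over_lo, -vel, vel)
        over_hi = pos > hi
        pos = np.where(over_hi, 2 * hi - pos, pos)
        vel = np.where(over_hi, -vel, vel)
        pos = np.clip(pos, lo, hi)      # guard double reflections
        for i in range(config.n_particles):
            c = cost_of(pos[i], i)
            if c < pbest_cost[i]:
                pbest_cost[i] = c
                pbest[i] = pos[i]
                if c < gbest_cost:
                    gbest_cost = float(c)
                    gbest = pos[i].copy()
        trace.append(gbest_cost)

    best_values = {k: float(v) for k, v in zip(config.free_params, gbest)}
    return FitResult(
        params=base.with_(**best_values),
        best_values=best_values,
        best_cost=gbest_cost,
        cost_trace=np.asarray(trace),
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# synthetic data and table I/O
# ---------------------------------------------------------------------------

def synth_growth_law_dataset(true_params: ModelParameters,
                             phi_grid: Sequence[float],
                             kcm_grid: Sequence[float] = (0.0,),
                             noise_sd: float = 0.0,
                             seed: int = 0,
                             source: str = "DB") -> GrowthLawDataset:
    """Generate a synthetic growth-law table from known true parameters.

    Simulates the condition grid, then applies i.i.d. multiplicative
    Gaussian noise (1 + sd*Z), clipped at zero.  With ``noise_sd=0`` the
    output equals :func:`growth_law_curves` exactly; reproducible by seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ds = growth_law_curves(true_params, phi_grid, kcm_grid, source=source)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tab = ds.table.copy()
        for obs in OBSERVABLES:
            factors = 1.0 + noise_sd * rng.standard_normal(len(tab))
            tab[obs] = np.maximum(tab[obs] * factors, 0.0)
        ds = GrowthLawDataset(source=ds.source, table=tab)
    return ds


def write_growth_law_table(datasets: Sequence[GrowthLawDataset],
                           path: str | Path) -> None:
    """Write datasets to one delimited table with a ``source`` column."""
    frames = []
    for ds in datasets:
        t = ds.table.copy()
        t.insert(0, "source", ds.source)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_growth_law_table(path: str | Path) -> list[GrowthLawDataset]:
    """Read a delimited growth-law table, one dataset per ``source`` value.

    Expected header: ``source,condition,phi,k_cm,lambda,phi_R,gamma,theta``
    (observable cells may be empty).  ``phi``/``k_cm`` give each condition's
    coordinates for condition-matched simulation.
    """
    tab = pd.read_csv(path)
    if "source" not in tab.columns:
        raise ValueError(f"{path}: missing 'source' column")
    out = []
    for source, group in tab.groupby("source", sort=False):
        out.append(GrowthLawDataset(source=str(source),
                                    table=group.drop(columns="source")
                                    .reset_index(drop=True)))
    return out
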