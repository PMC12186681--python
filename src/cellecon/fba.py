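"""Genome-scale protein-production capacity: FBA/FVA on an SBML network.

A metabolic reconstruction (iJO1366 or the built-in toy fixture) is
augmented with a translation-demand reaction that consumes a protein's
amino-acid composition plus GTP (hydrolysed to GDP + Pi) per peptide bond
and produces one unit of a pseudo-metabolite ``protein``.  Maximal protein
flux is computed by linear programming over grids of carbon-source uptake
and (fixed) biomass flux; flux variability analysis classifies reactions as
flexible when their admissible flux range at the optimum exceeds
0.001 mmol/gDCW/h, and per-subsystem signed net fluxes summarize where the
inflexible backbone of the solution runs.

Networks are handled as :class:`cobra.Model` objects throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

__all__ = [
    "FLEXIBILITY_THRESHOLD",
    "AA_METABOLITES",
    "CapacityGrid",
    "FvaReport",
    "InfeasibleError",
    "read_network",
    "write_network",
    "add_protein_demand",
    "max_protein_flux",
    "capacity_grid",
    "run_fva",
    "subsystem_net_flux",
    "toy_network_fixture",
    "synthetic_gfp_like_sequence",
    "read_protein_fasta",
]

log = logging.getLogger(__name__)

#: |max - min| above which an FVA flux range counts as flexible (mmol/gDCW/h).
FLEXIBILITY_THRESHOLD = 0.001

#: One-letter code -> cytosolic metabolite id (BiGG convention).
AA_METABOLITES = {
    "A": "ala__L_c", "R": "arg__L_c", "N": "asn__L_c", "D": "asp__L_c",
    "C": "cys__L_c", "Q": "gln__L_c", "E": "glu__L_c", "G": "gly_c",
    "H": "his__L_c", "I": "ile__L_c", "L": "leu__L_c", "K": "lys__L_c",
    "M": "met__L_c", "F": "phe__L_c", "P": "pro__L_c", "S": "ser__L_c",
    "T": "thr__L_c", "W": "trp__L_c", "Y": "tyr__L_c", "V": "val__L_c",
}

PROTEIN_DEMAND_ID = "PROTEIN_SYNTH"
PROTEIN_SINK_ID = "DM_protein_c"


class InfeasibleError(RuntimeError):
    """The LP at a grid point has no feasible solution."""


def read_network(path: str | Path) -> Model:
    """Read an SBML (FBC) metabolic reconstruction into a cobra model."""
    try:
        return cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse SBML file {path}: {exc}") from exc


def write_network(model: Model, path: str | Path) -> None:
    """Serialize a network to SBML (FBC v2).

    Subsystem labels survive the round trip as SBML groups (the convention
    cobra reads them back from), created here if absent.
    """
    from cobra.core import Group
    model = model.copy()
    existing = {g.name for g in model.groups}
    subs: dict[str, list] = {}
    for r in model.reactions:
        if r.subsystem and r.subsystem not in existing:
            subs.setdefault(r.subsystem, []).append(r)
    for name in sorted(subs):
        grp = Group(name.replace(" ", "_"), name=name, members=subs[name])
        grp.kind = "partonomy"
        model.add_groups([grp])
    cobra.io.write_sbml_model(model, str(path))
    # cobra keeps group members in a set, so their serialization order is
    # arbitrary; sort the member lines to make output byte-deterministic
    lines = Path(path).read_text().splitlines(keepends=True)
    out, block = [], []
    for line in lines:
        if "<groups:member " in line:
            block.append(line)
            continue
        if block:
            out.extend(sorted(block))
            block = []
        out.append(line)
    out.extend(sorted(block))
    Path(path).write_text("".join(out))


def read_protein_fasta(path: str | Path) -> str:
    """Read the first protein sequence from a FASTA file."""
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise ValueError(f"no sequence found in {path}")
    return str(rec.seq).upper()


def add_protein_demand(model: Model, sequence: str, gtp_per_bond: float = 2.0,
                       aa_map: Optional[dict[str, str]] = None) -> Model:
    """Augment a network with a translation-demand reaction for a protein.

    The reaction consumes count(aa) of each amino-acid metabolite in the
    sequence and ``gtp_per_bond * (L - 1)`` GTP (+ H2O, yielding GDP, Pi and
    H+), and produces one unit of the pseudo-metabolite ``protein_c``, which
    leaves through the sink ``DM_protein_c``.  The input model is copied,
    not mutated.  ``aa_map`` overrides the default BiGG id mapping for
    reconstructions with other conventions.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("protein sequence is empty")
    mapping = dict(AA_METABOLITES)
    if aa_map:
        mapping.update(aa_map)
    unknown = sorted({c for c in sequence if c not in mapping})
    if unknown:
        raise ValueError(f"unknown residue letters in sequence: {unknown}")
    model = model.copy()
    missing = []
    stoich: dict[Metabolite, float] = {}
    for letter in sorted(set(sequence)):
        met_id = mapping[letter]
        if met_id not in model.metabolites:
            missing.append(met_id)
            continue
        stoich[model.metabolites.get_by_id(met_id)] = -float(sequence.count(letter))
    if missing:
        raise ValueError(
            "network lacks amino-acid metabolites required by the sequence: "
            + ", ".join(missing))
    n_bonds = len(sequence) - 1
    gtp_total = gtp_per_bond * n_bonds
    if gtp_total > 0:
        for met_id, coeff in (("gtp_c", -gtp_total), ("h2o_c", -gtp_total),
                              ("gdp_c", gtp_total), ("pi_c", gtp_total),
                              ("h_c", gtp_total)):
            if met_id not in model.metabolites:
                raise ValueError(f"network lacks energy metabolite {met_id}")
            stoich[model.metabolites.get_by_id(met_id)] = coeff
    protein = Metabolite("protein_c", name="nascent protein",
                         compartment="c")
    stoich[protein] = 1.0
    rxn = Reaction(PROTEIN_DEMAND_ID, name="translation demand",
                   lower_bound=0.0, upper_bound=1000.0)
    rxn.add_metabolites(stoich)
    rxn.subsystem = "Protein Production"
    model.add_reactions([rxn])
    sink = Reaction(PROTEIN_SINK_ID, name="protein sink",
                    lower_bound=0.0, upper_bound=1000.0)
    sink.add_metabolites({protein: -1.0})
    sink.subsystem = "Protein Production"
    model.add_reactions([sink])
    model.objective = PROTEIN_DEMAND_ID
    return model


def _configure(model: Model, uptake_reaction: str, uptake: float,
               biomass_reaction: Optional[str], biomass: float) -> None:
    rx = model.reactions.get_by_id(uptake_reaction)
    rx.lower_bound = -abs(uptake)     # exchange convention: uptake is negative
    if biomass_reaction is not None:
        bm = model.reactions.get_by_id(biomass_reaction)
        bm.lower_bound = bm.upper_bound = float(biomass)


def max_protein_flux(model: Model, uptake_reaction: str, uptake: float,
                     biomass_reaction: Optional[str] = None,
                     biomass: float = 0.0) -> float:
    """LP-maximal protein-demand flux at a given uptake bound.

    The carbon-source exchange is bounded above at ``uptake`` (in the
    uptake direction); the biomass reaction, if given, is FIXED at
    ``biomass`` (equality).  Raises :class:`InfeasibleError` for infeasible
    combinations rather than returning 0.
    """
    if PROTEIN_DEMAND_ID not in model.reactions:
        raise ValueError("model has no translation-demand reaction; "
                         "call add_protein_demand first")
    with model:
        _configure(model, uptake_reaction, uptake, biomass_reaction, biomass)
        model.objective = PROTEIN_DEMAND_ID
        sol = model.optimize()
        if sol.status != "optimal":
            raise InfeasibleError(
                f"LP not optimal (status {sol.status}) at uptake={uptake}, "
                f"biomass={biomass}")
        return float(sol.objective_value)


@dataclass
class CapacityGrid:
    """Maximal protein fluxes over uptake x biomass grids (NaN = infeasible)."""

    uptake_reaction: str
    uptake_grid: np.ndarray
    biomass_grid: np.ndarray
    flux: np.ndarray                 # shape (len(uptake), len(biomass))

    def table(self) -> pd.DataFrame:
        recs = []
        for i, u in enumerate(self.uptake_grid):
            for j, b in enumerate(self.biomass_grid):
                recs.append({"uptake": u, "biomass": b,
                             "protein_flux": self.flux[i, j]})
        return pd.DataFrame(recs)


def capacity_grid(model: Model, uptake_reaction: str,
                  uptake_grid: Sequence[float],
                  biomass_reaction: Optional[str] = None,
                  biomass_grid: Sequence[float] = (0.0,)) -> CapacityGrid:
    """Maximal protein flux at every (uptake, biomass) combination."""
    U = np.asarray(list(uptake_grid), dtype=float)
    B = np.asarray(list(biomass_grid), dtype=float)
    out = np.full((len(U), len(B)), np.nan)
    for i, u in enumerate(U):
        for j, b in enumerate(B):
            try:
                out[i, j] = max_protein_flux(model, uptake_reaction, u,
                                             biomass_reaction, b)
            except InfeasibleError:
                log.warning("infeasible at uptake=%g biomass=%g", u, b)
    return CapacityGrid(uptake_reaction=uptake_reaction, uptake_grid=U,
                        biomass_grid=B, flux=out)


@dataclass
class FvaReport:
    """Per-reaction flux ranges at the constrained optimum."""

    table: pd.DataFrame              # index: reaction id; min, max, flexible
    threshold: float
    fraction_of_optimum: float

    @property
    def flexible_reactions(self) -> list[str]:
        return list(self.table.index[self.table["flexible"]])


def run_fva(model: Model, uptake_reaction: str, uptake: float,
            biomass_reaction: Optional[str] = None, biomass: float = 0.0,
            fraction_of_optimum: float = 1.0,
            threshold: float = FLEXIBILITY_THRESHOLD) -> FvaReport:
    """Flux variability analysis with the protein objective held at its
    optimum (fraction 1.0 by default); flexibility classified at the given
    |max - min| threshold."""
    from cobra.flux_analysis import flux_variability_analysis
    with model:
        _configure(model, uptake_reaction, uptake, biomass_reaction, biomass)
        model.objective = PROTEIN_DEMAND_ID
        fva = flux_variability_analysis(
            model, fraction_of_optimum=fraction_of_optimum, processes=1)
    tab = fva.rename(columns={"minimum": "min", "maximum": "max"})
    tab["flexible"] = (tab["max"] - tab["min"]).abs() > threshold
    return FvaReport(table=tab, threshold=threshold,
                     fraction_of_optimum=fraction_of_optimum)


def subsystem_net_flux(model: Model, fluxes: pd.Series,
                       fva: Optional[FvaReport] = None) -> pd.DataFrame:
    """Signed net flux per subsystem, with an inflexible-only restriction.

    ``net_flux`` sums the signed rates of all reactions in each subsystem;
    ``inflexible_net_flux`` restricts the sum to reactions whose FVA range
    is below the flexibility threshold (NaN when no FVA report is given).
    """
    inflexible: Optional[set] = None
    if fva is not None:
        inflexible = set(fva.table.index[~fva.table["flexible"]])
    rows: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        sub = rxn.subsystem or "unassigned"
        v = float(fluxes.get(rxn.id, 0.0))
        rec = rows.setdefault(sub, {"net_flux": 0.0, "inflexible_net_flux": 0.0,
                                    "n_reactions": 0, "n_inflexible": 0})
        rec["net_flux"] += v
        rec["n_reactions"] += 1
        if inflexible is not None and rxn.id in inflexible:
            rec["inflexible_net_flux"] += v
            rec["n_inflexible"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if inflexible is None:
        out["inflexible_net_flux"] = np.nan
        out["n_inflexible"] = np.nan
    return out


def metabolite_net_flux(model: Model, fluxes: pd.Series,
                        fva: FvaReport) -> pd.DataFrame:
    """Per-metabolite production through inflexible reactions only.

    For each metabolite, sums max(0, coeff * flux) over inflexible reactions
    (production) and min(0, coeff * flux) (consumption).
    """
    inflexible = set(fva.table.index[~fva.table["flexible"]])
    rows: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        if rxn.id not in inflexible:
            continue
        v = float(fluxes.get(rxn.id, 0.0))
        for met, coeff in rxn.metabolites.items():
            rate = coeff * v
            rec = rows.setdefault(met.id, {"produced": 0.0, "consumed": 0.0})
            if rate >= 0:
                rec["produced"] += rate
            else:
                rec["consumed"] += rate
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# toy fixture
# ---------------------------------------------------------------------------

def synthetic_gfp_like_sequence(length: int = 239, seed: int = 2020) -> str:
    """A deterministic synthetic GFP-sized protein sequence.

    A stand-in for a real fluorescent-protein sequence: residues are drawn
    reproducibly from the 20 canonical amino acids with an initial Met.
    Only the length and composition arithmetic matter to the demand
    reaction, not the actual residue order.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(sorted(AA_METABOLITES))
    body = rng.choice(letters, size=length - 1)
    return "M" + "".join(body)


def toy_network_fixture() -> Model:
    """A desk-scale stand-in for a genome-scale reconstruction.

    Two carbon sources feed a precursor pool with different yields (rich:
    2 precursor per unit; poor: 1), the precursor reaches an intermediate
    through two parallel equivalent reactions (the flexible motif), the
    intermediate is converted 1:1 into each of the 20 amino acids, and the
    precursor also yields GTP.  Subsystems: Uptake, Central Metabolism,
    Amino Acid Biosynthesis, Energy.  Analytic optimum for a length-L
    protein with g GTP per bond, rich uptake u and biomass flux b:

        protein_flux = (2u - b) / (L + g*(L - 1))        (poor: u instead of 2u)

    Deterministic: repeated calls build identical models.
    """
    m = Model("toy_capacity_network")

    def met(mid, comp):
        mm = Metabolite(mid, compartment=comp)
        m.add_metabolites([mm])
        return mm

    rich_e = met("rich_e", "e")
    poor_e = met("poor_e", "e")
    prec = met("prec_c", "c")
    inter = met("inter_c", "c")
    gtp = met("gtp_c", "c")
    gdp = met("gdp_c", "c")
    pi = met("pi_c", "c")
    h = met("h_c", "c")
    h2o = met("h2o_c", "c")
    aas = {letter: met(mid, "c") for letter, mid in AA_METABOLITES.items()}

    def rxn(rid, stoich, subsystem, lb=0.0, ub=1000.0):
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        r.subsystem = subsystem
        m.add_reactions([r])
        return r

    rxn("EX_rich_e", {rich_e: -1}, "Uptake", lb=0.0)
    rxn("EX_poor_e", {poor_e: -1}, "Uptake", lb=0.0)
    rxn("T_RICH", {rich_e: -1, prec: 2}, "Central Metabolism")
    rxn("T_POOR", {poor_e: -1, prec: 1}, "Central Metabolism")
    # the flexible parallel motif
    rxn("P_PATH1", {prec: -1, inter: 1}, "Central Metabolism")
    rxn("P_PATH2", {prec: -1, inter: 1}, "Central Metabolism")
    for letter, aa in sorted(aas.items()):
        rxn(f"AA_SYNTH_{letter}", {inter: -1, aa: 1}, "Amino Acid Biosynthesis")
    rxn("GTP_SYNTH", {prec: -1, h2o: -1, gtp: 1}, "Energy")
    rxn("GDP_DRAIN", {gdp: -1}, "Energy")
    rxn("PI_DRAIN", {pi: -1}, "Energy")
    rxn("H_DRAIN", {h: -1}, "Energy")
    rxn("EX_h2o_e", {h2o: 1}, "Uptake", lb=0.0, ub=1000.0)
    rxn("BIOMASS_toy", {prec: -1}, "Central Metabolism")
    m.objective = "BIOMASS_toy"
    return m
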