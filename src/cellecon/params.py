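"""Parameter and gene-definition types for the coarse-grained cell model.

The model describes a single lumped bacterial cell with five native
transcription units — metabolic enzymes (``E``), bulk housekeeping protein
(``Q``), RNA polymerase (``P``), ribosomal protein (``R``) and the rRNA
operon (``rrn``) — plus any number of heterologous circuit genes.  All
intracellular species are molecule counts per cell; all rates are per hour;
cell mass ``M0`` is in amino-acid equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "GeneDefinition",
    "ModelParameters",
    "CultureMode",
    "PathwaySpec",
    "PerturbationSet",
    "REGULATION_CLASSES",
    "default_genes",
    "default_parameters",
]

#: Recognised regulation classes.
#:   housekeeping_Q    — negative autogenous feedback 1 / (1 + (p_Q/kappa_q)^h_q)
#:   resource_activated — ppGpp-relief activation theta / (theta + kappa_theta)
#:   enzyme_repressed  — ppGpp activation of enzymes kappa_theta / (theta + kappa_theta)
#:   circuit           — enzyme-like factor scaled by the induction input u
REGULATION_CLASSES = (
    "housekeeping_Q",
    "resource_activated",
    "enzyme_repressed",
    "circuit",
)


class ValidationError(ValueError):
    """A parameter set or gene table violates a model invariant."""


@dataclass(frozen=True)
class GeneDefinition:
    """One transcription/translation unit.

    Parameters
    ----------
    name
        Unique identifier; the native cell uses E, Q, P, R and rrn.
    g0
        Copy number per chromosome (before growth-rate dosage expansion).
    n
        Protein length in amino acids; for the rRNA gene, transcript length
        in nucleotides.
    kp_f, kp_r
        RNAP–promoter association / dissociation rates (per molecule per
        hour, per hour).
    kr_f, kr_r
        Ribosome–mRNA association / dissociation rates.  Ignored for the
        rRNA gene, which is never translated.
    regulation_class
        One of :data:`REGULATION_CLASSES`.
    is_rRNA
        The single rRNA gene competes for RNA polymerase but has no mRNA or
        translation stage; its transcript is the free rRNA pool.
    u
        Induction input in [0, 1]; only meaningful for circuit genes.
    """

    name: str
    g0: float
    n: float
    kp_f: float
    kp_r: float
    kr_f: float = 0.0
    kr_r: float = 0.0
    regulation_class: str = "housekeeping_Q"
    is_rRNA: bool = False
    u: Optional[float] = None

    def validate(self) -> list[str]:
        errs = []
        if not self.name:
            errs.append("gene name must be non-empty")
        if not self.g0 > 0:
            errs.append(f"gene {self.name}: g0 must be > 0 (got {self.g0})")
        if not self.n >= 1:
            errs.append(f"gene {self.name}: length n must be >= 1 (got {self.n})")
        for k in ("kp_f", "kp_r", "kr_f", "kr_r"):
            if getattr(self, k) < 0:
                errs.append(f"gene {self.name}: {k} must be >= 0")
        if self.kp_f <= 0:
            errs.append(f"gene {self.name}: kp_f must be > 0 (RNAP can never bind)")
        if not self.is_rRNA and self.kr_f <= 0:
            errs.append(f"gene {self.name}: kr_f must be > 0 for a translated gene")
        if self.regulation_class not in REGULATION_CLASSES:
            errs.append(
                f"gene {self.name}: unknown regulation_class "
                f"{self.regulation_class!r}"
            )
        if self.regulation_class == "circuit":
            if self.u is None or not (0.0 <= self.u <= 1.0):
                errs.append(f"gene {self.name}: circuit induction u must be in [0, 1]")
        elif self.u is not None:
            errs.append(f"gene {self.name}: u is only valid for circuit genes")
        return errs


@dataclass(frozen=True)
class PathwaySpec:
    """A lumped heterologous metabolic pathway draining M into a product X.

    ``enzyme`` names a circuit gene whose protein p_1 carries the flux
    v_ME * M * p_1 / (kappa_ME + M).
    """

    enzyme: str
    v_ME: float
    kappa_ME: float

    def validate(self) -> list[str]:
        errs = []
        if self.v_ME < 0:
            errs.append("pathway.v_ME must be >= 0")
        if self.kappa_ME < 0:
            errs.append("pathway.kappa_ME must be >= 0")
        return errs


@dataclass(frozen=True)
class PerturbationSet:
    """The model's perturbation knobs.

    D_r scales rRNA gene dosage (rrn deletions/amplifications), D_gamma the
    maximum peptide elongation rate, D_psi the maximum tRNA production rate,
    D_g the ppGpp proxy theta; k_rf and k_cm are rifampicin-like RNAP and
    chloramphenicol-like ribosome sequestration rates (per hour).  Defaults
    are the unperturbed cell.
    """

    D_r: float = 1.0
    D_gamma: float = 1.0
    D_psi: float = 1.0
    D_g: float = 1.0
    k_rf: float = 0.0
    k_cm: float = 0.0

    def validate(self) -> list[str]:
        errs = []
        for k in ("D_r", "D_gamma", "D_psi", "D_g"):
            if not getattr(self, k) > 0:
                errs.append(f"perturb.{k} must be > 0")
        for k in ("k_rf", "k_cm"):
            if getattr(self, k) < 0:
                errs.append(f"perturb.{k} must be >= 0")
        return errs


@dataclass(frozen=True)
class CultureMode:
    """Culture regime: single_cell, batch, or chemostat.

    single_cell freezes dS/dt = dN/dt = 0 (mid-exponential growth at fixed
    external substrate).  Batch depletes a finite S0 while N grows.  The
    chemostat feeds substrate at k_in and dilutes at rate delta; at an
    interior steady state the growth rate equals delta.
    """

    mode: str = "single_cell"
    S0: float = 2.0e10
    N0: float = 1.0
    k_in: float = 1.0e10
    delta: float = 0.0

    def validate(self) -> list[str]:
        errs = []
        if self.mode not in ("single_cell", "batch", "chemostat"):
            errs.append(f"culture.mode must be single_cell/batch/chemostat, got {self.mode!r}")
        if self.mode == "chemostat":
            if not self.delta > 0:
                errs.append("culture.delta must be > 0 in chemostat mode")
            if self.k_in < 0:
                errs.append("culture.k_in must be >= 0")
        if self.S0 < 0 or self.N0 < 0:
            errs.append("culture.S0 and culture.N0 must be >= 0")
        return errs


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic constants of the host cell plus perturbation knobs.

    Units: molecules per cell and hours throughout; M0 in amino-acid
    equivalents per cell.
    """

    # substrate import and conversion
    v_E: float = 2000.0         # substrate turnover per enzyme (/h)
    kappa_E: float = 1.0e9      # import half-saturation (external substrate units)
    phi: float = 1.0            # M molecules per substrate molecule (nutrient quality)
    # tRNA charging
    v_T: float = 3.6e3          # charging turnover per enzyme (/h)
    K_u: float = 1.0e5          # uncharged-tRNA half-constant
    K_M: float = 1.0e6          # metabolite half-constant
    psi_max: float = 1.3e6      # maximum tRNA synthesis rate (molecules/h)
    # transcription
    delta_m: float = 6.0        # mRNA decay rate (/h), ~7 min half-life
    tau_max: float = 1.8e5      # max mRNA elongation rate (nt/h), ~50 nt/s
    K_tau: float = 1.0e6        # metabolite half-constant of elongation
    tau_r_max: float = 3.06e5   # max rRNA elongation (nt/h), ~85 nt/s
    # translation
    gamma_max: float = 7.2e4    # max peptide elongation rate (aa/h), ~20 aa/s
    K_gamma: float = 3.0e5      # charged-tRNA half-constant
    # gene dosage and regulation
    q_x: float = 0.35           # copy-number expansion coefficient (h)
    kappa_q: float = 3.0e5      # Q-gene negative-feedback constant (molecules)
    h_q: float = 1.0            # Q-gene Hill exponent
    kappa_theta: float = 2.0    # ppGpp-proxy regulation half-constant
    # ribosome assembly
    beta_rho: float = 1.0e-2    # assembly rate (/molecule/h)
    mu_rho: float = 0.1         # disassembly rate (/h)
    # cell scale
    M0: float = 2.0e8           # mid-exponential cell mass (aa equivalents)
    # antibiotics
    k_rf: float = 0.0           # RNAP sequestration rate (rifampicin proxy, /h)
    k_cm: float = 0.0           # ribosome sequestration rate (chloramphenicol proxy, /h)
    # perturbation scalings
    D_r: float = 1.0
    D_gamma: float = 1.0
    D_psi: float = 1.0
    D_g: float = 1.0
    # numerical guards / interpretation switches
    theta_floor: float = 1.0e-9       # floor on t_u inside theta = t_c/t_u
    rrna_elongation_M_dependent: bool = True   # rRNA chain elongation shares tau's M-saturation
    circuit_copy_expansion: bool = False       # plasmid copy number does not follow g(lambda)
    # gene table
    genes: tuple[GeneDefinition, ...] = field(default_factory=tuple)

    _POSITIVE = ("M0", "kappa_theta", "kappa_q")
    _NONNEG = (
        "v_E", "kappa_E", "phi", "v_T", "K_u", "K_M", "psi_max", "delta_m",
        "tau_max", "K_tau", "tau_r_max", "gamma_max", "K_gamma", "q_x",
        "h_q", "beta_rho", "mu_rho", "k_rf", "k_cm",
    )

    def validate(self) -> list[str]:
        errs = []
        for k in self._POSITIVE:
            if not getattr(self, k) > 0:
                errs.append(f"params.{k} must be > 0 (got {getattr(self, k)})")
        for k in self._NONNEG:
            if getattr(self, k) < 0:
                errs.append(f"params.{k} must be >= 0 (got {getattr(self, k)})")
        for k in ("D_r", "D_gamma", "D_psi", "D_g"):
            if not getattr(self, k) > 0:
                errs.append(f"params.{k} must be > 0 (got {getattr(self, k)})")
        if not self.genes:
            errs.append("params.genes must contain at least one gene")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            errs.append(f"duplicate gene names in table: {names}")
        n_rrna = sum(g.is_rRNA for g in self.genes)
        if n_rrna != 1:
            errs.append(f"exactly one gene must be flagged is_rRNA (got {n_rrna})")
        for g in self.genes:
            errs.extend(g.validate())
        return errs

    def check(self) -> "ModelParameters":
        """Validate, raising :class:`ValidationError` listing every violation."""
        errs = self.validate()
        if errs:
            raise ValidationError("; ".join(errs))
        return self

    def with_(self, **updates) -> "ModelParameters":
        return replace(self, **updates)

    def gene(self, name: str) -> GeneDefinition:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"no gene named {name!r}")

    def with_gene(self, name: str, **updates) -> "ModelParameters":
        """Return a copy with one gene's fields replaced."""
        found = False
        new = []
        for g in self.genes:
            if g.name == name:
                g = replace(g, **updates)
                found = True
            new.append(g)
        if not found:
            raise KeyError(f"no gene named {name!r}")
        return replace(self, genes=tuple(new))


def default_genes() -> tuple[GeneDefinition, ...]:
    """The default five-gene host cell.

    Lengths are E. coli ballparks: a 400-aa lumped enzyme, 300-aa bulk
    protein, the ~3400-aa RNAP core enzyme, the ~7500-aa summed ribosomal
    protein complement and a 4566-nt rRNA operon transcript.
    """
    return (
        GeneDefinition("E", g0=20, n=400, kp_f=1.2, kp_r=1000.0,
                       kr_f=0.22, kr_r=100.0,
                       regulation_class="enzyme_repressed"),
        GeneDefinition("Q", g0=40, n=300, kp_f=1.0, kp_r=1000.0,
                       kr_f=0.22, kr_r=100.0,
                       regulation_class="housekeeping_Q"),
        GeneDefinition("P", g0=3, n=3400, kp_f=5.0, kp_r=1000.0,
                       kr_f=0.22, kr_r=100.0,
                       regulation_class="resource_activated"),
        GeneDefinition("R", g0=15, n=7500, kp_f=10.0, kp_r=1000.0,
                       kr_f=0.22, kr_r=100.0,
                       regulation_class="resource_activated"),
        GeneDefinition("rrn", g0=7, n=4566, kp_f=9.0, kp_r=1000.0,
                       regulation_class="resource_activated", is_rRNA=True),
    )


def default_parameters() -> ModelParameters:
    """The shipped default cell (unperturbed, no circuit)."""
    return ModelParameters(genes=default_genes()).check()
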