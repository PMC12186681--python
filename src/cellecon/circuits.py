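"""Circuit genes, product pathways and perturbation knobs.

All three operations are pure augmentations: they return a new
:class:`~cellecon.model.CellModel` and leave the input untouched.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Optional

from .model import CellModel
from .params import GeneDefinition, PathwaySpec, PerturbationSet, ValidationError

__all__ = [
    "circuit_gene",
    "add_circuit",
    "remove_circuit",
    "add_pathway",
    "apply_perturbations",
    "two_reporter_circuit",
    "PathwaySpec",
    "PerturbationSet",
]


def circuit_gene(name: str, u: float, template: Optional[GeneDefinition] = None,
                 **overrides) -> GeneDefinition:
    """Build a circuit gene.

    Unless overridden, lengths and binding rates copy the given template
    (typically the host enzyme gene), so isocost slopes reflect induction
    rather than hidden kinetic differences.  Default: a 10-copy plasmid
    gene of 240 codons (a fluorescent-reporter size).
    """
    base = dict(g0=10, n=240,
                kp_f=template.kp_f if template else 1.2,
                kp_r=template.kp_r if template else 1000.0,
                kr_f=template.kr_f if template else 0.22,
                kr_r=template.kr_r if template else 100.0)
    base.update(overrides)
    return GeneDefinition(name=name, regulation_class="circuit", u=u, **base)


def add_circuit(model: CellModel, genes: Iterable[GeneDefinition]) -> CellModel:
    """Append circuit genes to the model.

    The new genes enter both the RNAP and ribosome competition sums and the
    growth-rate sum; new m/p species are appended to the state layout.
    """
    genes = list(genes)
    existing = {g.name for g in model.params.genes}
    for g in genes:
        if g.regulation_class != "circuit":
            raise ValidationError(f"gene {g.name}: add_circuit requires circuit genes")
        if g.name in existing:
            raise ValidationError(f"duplicate gene name {g.name!r}")
        existing.add(g.name)
    params = model.params.with_(genes=model.params.genes + tuple(genes))
    return CellModel(params, model.culture, model.pathway)


def remove_circuit(model: CellModel, names: Iterable[str]) -> CellModel:
    """Remove circuit genes by name (inverse of :func:`add_circuit`)."""
    names = set(names)
    for n in names:
        g = model.params.gene(n)
        if g.regulation_class != "circuit":
            raise ValidationError(f"{n!r} is a host gene and cannot be removed")
    if model.pathway is not None and model.pathway.enzyme in names:
        raise ValidationError("cannot remove the pathway's enzyme gene")
    genes = tuple(g for g in model.params.genes if g.name not in names)
    return CellModel(model.params.with_(genes=genes), model.culture, model.pathway)


def two_reporter_circuit(model: CellModel, u1: float = 0.0, u2: float = 1.0,
                         **overrides) -> CellModel:
    """Attach the standard two-reporter competition circuit (genes c1, c2).

    c1 plays the inducible reporter (induction u1, swept in isocost
    protocols); c2 the constitutive one (u2, held at 1).
    """
    template = model.params.gene("E")
    return add_circuit(model, [
        circuit_gene("c1", u=u1, template=template, **overrides),
        circuit_gene("c2", u=u2, template=template, **overrides),
    ])


def add_pathway(model: CellModel, spec: PathwaySpec) -> CellModel:
    """Attach a lumped product pathway draining M through a circuit enzyme.

    Adds the product species X with dX/dt = v_ME*M*p_1/(kappa_ME+M) - lambda*X
    and subtracts the identical flux from dM/dt (term-level mass balance).
    """
    return CellModel(model.params, model.culture, spec)


def apply_perturbations(model: CellModel, pert: PerturbationSet) -> CellModel:
    """Apply a perturbation set; defaults leave the model unchanged.

    D_* knobs compose multiplicatively, antibiotic sequestration rates
    additively, so applying two sets is order-independent.
    """
    errs = pert.validate()
    if errs:
        raise ValidationError("; ".join(errs))
    p = model.params
    params = p.with_(
        D_r=p.D_r * pert.D_r,
        D_gamma=p.D_gamma * pert.D_gamma,
        D_psi=p.D_psi * pert.D_psi,
        D_g=p.D_g * pert.D_g,
        k_rf=p.k_rf + pert.k_rf,
        k_cm=p.k_cm + pert.k_cm,
    )
    return CellModel(params, model.culture, model.pathway)
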