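"""Configuration loading/validation, serialization and run manifests.

A run is described by one YAML (or JSON) document with sections ``params``,
``genes``, ``culture``, ``circuit``, ``pathway``, ``perturb`` and
``options``; every key is validated and unknown keys are rejected with
their full path, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .circuits import add_pathway, apply_perturbations
from .model import CellModel
from .params import (
    CultureMode,
    GeneDefinition,
    ModelParameters,
    PathwaySpec,
    PerturbationSet,
    ValidationError,
    default_parameters,
)

__all__ = ["load_config", "dump_config", "config_to_model", "model_to_config",
           "RunManifest"]

_SECTIONS = ("params", "genes", "culture", "circuit", "pathway", "perturb",
             "options")
_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)} - {"genes"}
_GENE_FIELDS = {f.name for f in dataclasses.fields(GeneDefinition)}
_CULTURE_FIELDS = {f.name for f in dataclasses.fields(CultureMode)}
_PATHWAY_FIELDS = {f.name for f in dataclasses.fields(PathwaySpec)}
_PERTURB_FIELDS = {f.name for f in dataclasses.fields(PerturbationSet)}


def _check_keys(mapping: dict, allowed: set, path: str, errors: list[str]):
    for k in mapping:
        if k not in allowed:
            errors.append(f"unknown key {path}.{k}")


def load_config(path: str | Path) -> tuple[CellModel, dict]:
    """Load and validate a config file into a model plus command options.

    Returns ``(model, options)`` where options is the free-form ``options``
    section (command-specific settings such as sweep grids).  Every
    validation failure is reported, each with the offending key path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    return config_to_model(doc, origin=str(path))


def config_to_model(doc: dict, origin: str = "<config>") -> tuple[CellModel, dict]:
    errors: list[str] = []
    _check_keys(doc, set(_SECTIONS), origin, errors)

    params = default_parameters()
    sec = doc.get("params") or {}
    _check_keys(sec, _PARAM_FIELDS, f"{origin}:params", errors)
    if not errors and sec:
        params = params.with_(**sec)

    sec = doc.get("genes") or {}
    for name, fields in sec.items():
        if not isinstance(fields, dict):
            errors.append(f"{origin}:genes.{name} must be a mapping")
            continue
        _check_keys(fields, _GENE_FIELDS - {"name"}, f"{origin}:genes.{name}",
                    errors)
        if errors:
            continue
        try:
            params = params.with_gene(name, **fields)
        except KeyError:
            errors.append(f"{origin}:genes.{name}: no such host gene")

    circuit = doc.get("circuit") or []
    if not isinstance(circuit, list):
        errors.append(f"{origin}:circuit must be a list of gene mappings")
        circuit = []
    genes = list(params.genes)
    for i, entry in enumerate(circuit):
        _check_keys(entry, _GENE_FIELDS, f"{origin}:circuit[{i}]", errors)
        if "name" not in entry:
            errors.append(f"{origin}:circuit[{i}]: missing name")
            continue
        entry = dict(entry)
        entry.setdefault("regulation_class", "circuit")
        entry.setdefault("u", 0.0)
        # circuit kinetics default to the enzyme gene's (documented choice)
        tmpl = params.gene("E")
        for k, v in (("g0", 10), ("n", 240), ("kp_f", tmpl.kp_f),
                     ("kp_r", tmpl.kp_r), ("kr_f", tmpl.kr_f),
                     ("kr_r", tmpl.kr_r)):
            entry.setdefault(k, v)
        genes.append(GeneDefinition(**entry))
    params = params.with_(genes=tuple(genes))

    sec = doc.get("culture") or {}
    _check_keys(sec, _CULTURE_FIELDS, f"{origin}:culture", errors)
    culture = CultureMode(**sec) if not errors else CultureMode()
    errors.extend(f"{origin}:culture.{e}" for e in culture.validate())

    pathway = None
    sec = doc.get("pathway")
    if sec:
        _check_keys(sec, _PATHWAY_FIELDS, f"{origin}:pathway", errors)
        if not errors:
            pathway = PathwaySpec(**sec)
            errors.extend(f"{origin}:{e}" for e in pathway.validate())

    pert = None
    sec = doc.get("perturb")
    if sec:
        _check_keys(sec, _PERTURB_FIELDS, f"{origin}:perturb", errors)
        if not errors:
            pert = PerturbationSet(**sec)
            errors.extend(f"{origin}:{e}" for e in pert.validate())

    if not errors:
        errors.extend(f"{origin}:params.{e}" for e in params.validate())
    if errors:
        raise ValidationError("; ".join(errors))

    model = CellModel(params, culture)
    if pert is not None:
        model = apply_perturbations(model, pert)
    if pathway is not None:
        model = add_pathway(model, pathway)
    options = doc.get("options") or {}
    return model, options


def model_to_config(model: CellModel, options: Optional[dict] = None) -> dict:
    """Serialize a model back to a config document (inverse of loading)."""
    defaults = default_parameters()
    params = {}
    for f in dataclasses.fields(ModelParameters):
        if f.name == "genes":
            continue
        v = getattr(model.params, f.name)
        if v != getattr(defaults, f.name):
            params[f.name] = v
    host, circuit = {}, []
    default_by_name = {g.name: g for g in defaults.genes}
    for g in model.params.genes:
        d = dataclasses.asdict(g)
        if g.regulation_class == "circuit":
            d = {k: v for k, v in d.items()
                 if k != "is_rRNA" and v is not None}
            circuit.append(d)
        else:
            ref = default_by_name.get(g.name)
            diff = {k: v for k, v in d.items()
                    if k not in ("name",) and ref is not None
                    and v != getattr(ref, k)}
            if diff:
                host[g.name] = diff
    doc: dict[str, Any] = {}
    if params:
        doc["params"] = params
    if host:
        doc["genes"] = host
    if circuit:
        doc["circuit"] = circuit
    doc["culture"] = dataclasses.asdict(model.culture)
    if model.pathway is not None:
        doc["pathway"] = dataclasses.asdict(model.pathway)
    if options:
        doc["options"] = options
    return doc


def dump_config(model: CellModel, path: str | Path,
                options: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_config(model, options), fh, sort_keys=False)


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a job: resolved config, seed, versions."""

    command: str
    config: dict
    seed: Optional[int]
    versions: dict
    convergence: list[dict]
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, model: CellModel, seed: Optional[int] = None,
               options: Optional[dict] = None) -> "RunManifest":
        import numpy
        import scipy
        return cls(
            command=command,
            config=model_to_config(model, options),
            seed=seed,
            versions={"cellecon": __version__, "numpy": numpy.__version__,
                      "scipy": scipy.__version__},
            convergence=[],
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def record(self, label: str, converged: bool, residual: float) -> None:
        self.convergence.append({"point": label, "converged": bool(converged),
                                 "max_abs_derivative": float(residual)})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)
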