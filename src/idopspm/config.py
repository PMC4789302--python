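"""Loading of packaged and user parameter files.

Parameter files are YAML-formatted key-value text (``.cfg``): one file
per treatment mirroring the experimental estimate table, plus one file
of predation-geometry defaults.  No numeric defaults are buried in
code — everything tunable lives in ``idopspm/params/``.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import yaml

from .process_models import (
    GrowthParams,
    MortalityParams,
    PredationParams,
    ReproductionParams,
    SexParams,
    SpeciesParams,
)

__all__ = [
    "TREATMENTS",
    "load_species_params",
    "load_table3",
    "load_predation_defaults",
    "species_params_from_dict",
]

TREATMENTS = ("reference", "tides")


def _packaged(name: str) -> str:
    return files("idopspm").joinpath("params", name).read_text()


def species_params_from_dict(species: str, d: dict) -> SpeciesParams:
    def sex(block: dict) -> SexParams:
        return SexParams(
            growth=GrowthParams(**block["growth"]),
            mortality=MortalityParams(**block["mortality"]),
        )

    return SpeciesParams(
        species=species,
        female=sex(d["female"]),
        male=sex(d["male"]),
        reproduction=ReproductionParams(**d["reproduction"]),
    )


def load_species_params(path: str | Path) -> dict[str, SpeciesParams]:
    """Load a per-treatment parameter file: {species: SpeciesParams}."""
    raw = yaml.safe_load(Path(path).read_text())
    return {sp: species_params_from_dict(sp, block) for sp, block in raw.items()}


def load_table3(treatment: str) -> dict[str, SpeciesParams]:
    """Packaged experimental estimates for one treatment
    ('reference' = permanent submersion, 'tides' = 5 h daily emergence)."""
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    raw = yaml.safe_load(_packaged(f"table3_{treatment}.cfg"))
    return {sp: species_params_from_dict(sp, block) for sp, block in raw.items()}


def load_predation_defaults(**overrides) -> PredationParams:
    """Packaged predation geometry, optionally overriding fields
    (typically the rates upsilon / upsilon_ig / tau)."""
    raw = yaml.safe_load(_packaged("predation_defaults.cfg"))
    raw.update(overrides)
    return PredationParams(**raw)
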