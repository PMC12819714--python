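"""Configuration loading with printed defaults and unit handling.

An empty file (or missing sections) resolves to the full default
parameter set: myocardial conductivities 0.6/0.2/0.1 mm^2/ms, fiber
angles -60/+60 degrees, the Windkessel constants C = 3.128 mL/mmHg,
Rp = 0.6652, Rc = 0.0914 mmHg s/mL, the material cards, and the recorded
blood properties (density 1060 kg/m^3, viscosity 0.0035/0.004 Pa s, kept
as documentation for the excluded 3D flow stage).  Quantities may be
written as bare numbers (canonical units) or "value unit" strings
(e.g. "10 mmHg"), converted exactly on load.  All schema violations are
collected and reported together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .active_stress import ActiveStressParams
from .ep import EPParams
from .geometry import CASES, LVCaseSpec
from .materials import LeafletMaterial, MyocardiumMaterial
from .units import parse_quantity, UnitError
from .windkessel import WindkesselParams


class ConfigError(ValueError):
    pass


#: fields whose YAML value may carry a unit string; converted to canonical
_QUANTITY_FIELDS = {"edv", "long_axis", "lvid", "lvot_radius", "mu", "lam",
                    "k1", "C10", "C01", "kappa_vol", "ed_pressure",
                    "aortic_diastolic_pressure"}

#: recorded-for-documentation constants (unused by the 0D surrogate)
BLOOD_PROPERTIES = {
    "density_kg_m3": 1060.0,
    "viscosity_lv_pa_s": 0.004,
    "viscosity_aorta_pa_s": 0.0035,
}


@dataclass(frozen=True)
class FiberParams:
    theta_epi_max: float = -60.0   # deg at basal epicardium
    theta_endo_max: float = 60.0   # deg at basal endocardium
    beta_method: str = "distance"

    def validate(self) -> None:
        if self.beta_method not in ("distance", "harmonic"):
            raise ValueError("beta_method must be 'distance' or 'harmonic'")


@dataclass
class ParameterSet:
    case: LVCaseSpec
    ep: EPParams
    active: ActiveStressParams
    myocardium: MyocardiumMaterial
    leaflet: LeafletMaterial
    windkessel: WindkesselParams
    fibers: FiberParams


_SECTIONS = {
    "case": LVCaseSpec,
    "ep": EPParams,
    "active": ActiveStressParams,
    "myocardium": MyocardiumMaterial,
    "leaflet": LeafletMaterial,
    "windkessel": WindkesselParams,
    "fibers": FiberParams,
}


def load_config(path=None, overrides: dict | None = None) -> ParameterSet:
    """Load a YAML/JSON parameter file on top of the printed defaults.

    Raises ConfigError listing *all* problems (unknown sections or keys,
    unit mistakes, out-of-range values) rather than the first one.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top level of the config must be a mapping")
    if overrides:
        for sec, kv in overrides.items():
            raw.setdefault(sec, {}).update(kv)

    problems: list[str] = []
    built = {}
    for sec_name, cls in _SECTIONS.items():
        sec_raw = raw.pop(sec_name, {}) or {}
        if not isinstance(sec_raw, dict):
            problems.append(f"section {sec_name!r} must be a mapping")
            continue
        built[sec_name] = _build_section(sec_name, cls, sec_raw, problems)
    for extra in raw:
        problems.append(f"unknown top-level section {extra!r}")
    if problems:
        raise ConfigError("invalid configuration:\n  - "
                          + "\n  - ".join(problems))
    return ParameterSet(case=built["case"], ep=built["ep"],
                        active=built["active"],
                        myocardium=built["myocardium"],
                        leaflet=built["leaflet"],
                        windkessel=built["windkessel"],
                        fibers=built["fibers"])


def _build_section(sec_name, cls, sec_raw, problems):
    if cls is LVCaseSpec:
        case_id = sec_raw.pop("case_id", 1)
        if case_id in CASES:
            default = CASES[case_id]
        else:
            problems.append(f"case.case_id must be one of {sorted(CASES)}")
            default = CASES[1]
        obj = default
    else:
        obj = cls()
    known = {f.name for f in dataclasses.fields(cls)}
    updates = {}
    for key, val in sec_raw.items():
        if key not in known:
            problems.append(f"unknown key {sec_name}.{key}")
            continue
        if isinstance(val, str) and key in _QUANTITY_FIELDS:
            try:
                val = parse_quantity(val)
            except (UnitError, ValueError) as exc:
                problems.append(f"{sec_name}.{key}: {exc}")
                continue
        if isinstance(val, list):
            val = tuple(val)
        updates[key] = val
    try:
        obj = dataclasses.replace(obj, **updates)
        if hasattr(obj, "validate"):
            obj.validate()
    except (TypeError, ValueError) as exc:
        problems.append(f"{sec_name}: {exc}")
    return obj
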