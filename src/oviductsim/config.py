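"""Structured-text (YAML) configuration for tube, flow, agents and design.

A full simulation is described by one document with four sections:
``tube``, ``flow``, ``agents`` and ``design``. The factory
:func:`canonical_configs` emits the six canonical configurations
(3 age groups x {normal, endometriosis}) plus the 3/7/10-lesion variants,
all derived from the built-in parameter set.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .flow_mechanics import CiliaField, MucusProperties, PeristalsisWave, WallMaterial
from .oocyte_model import OocyteModel
from .transport_engine import EngineParams, SimulationDesign
from .tube_geometry import AGE_GROUPS, TubeModel, build_tube


def resolve(doc: dict):
    """Build runtime objects from a config document.

    Returns (tube, design, params, oocyte, flow_kwargs)."""
    tube_doc = dict(doc.get("tube", {}))
    age = tube_doc.pop("age_group", "20s")
    endo = tube_doc.pop("with_endometriosis", False)
    lesion_count = tube_doc.pop("lesion_count", 5)
    tube = build_tube(age, endo, lesion_count, overrides=tube_doc or None)

    design_doc = dict(doc.get("design", {}))
    design = SimulationDesign(age_group=age, with_endometriosis=endo,
                              lesion_count=lesion_count, **design_doc)

    agents_doc = dict(doc.get("agents", {}))
    params = EngineParams(**agents_doc.get("engine", {}))
    oocyte = OocyteModel(**agents_doc.get("oocyte", {}))

    flow_doc = dict(doc.get("flow", {}))
    flow_kwargs = {}
    if "material" in flow_doc:
        flow_kwargs["material"] = WallMaterial(**flow_doc["material"])
    if "cilia" in flow_doc:
        flow_kwargs["cilia"] = CiliaField(**flow_doc["cilia"])
    if "mucus" in flow_doc:
        flow_kwargs["mucus"] = MucusProperties(**flow_doc["mucus"])
    if "waves" in flow_doc:
        flow_kwargs["waves"] = [PeristalsisWave(**w) for w in flow_doc["waves"]]
    return tube, design, params, oocyte, flow_kwargs


def document(age_group: str, with_endometriosis: bool, lesion_count: int = 5,
             **design_kwargs) -> dict:
    """A fully explicit config document for one canonical condition."""
    design = SimulationDesign(age_group=age_group,
                              with_endometriosis=with_endometriosis,
                              lesion_count=lesion_count, **design_kwargs)
    tube = build_tube(age_group, with_endometriosis, lesion_count)
    return {
        "tube": {
            "age_group": age_group,
            "with_endometriosis": with_endometriosis,
            "lesion_count": lesion_count if with_endometriosis else 0,
            "total_length": tube.total_length_L,
            "cilia_density": tube.cilia_density,
        },
        "flow": {
            "cilia": asdict(CiliaField(density=tube.cilia_density)),
            "mucus": asdict(MucusProperties()),
            "material": asdict(WallMaterial(L_ref=tube.total_length_L)),
        },
        "agents": {
            "oocyte": asdict(OocyteModel()),
            "engine": asdict(EngineParams()),
        },
        "design": {k: v for k, v in asdict(design).items()
                   if k not in ("age_group", "with_endometriosis", "lesion_count")},
    }


def canonical_configs(out_dir, lesion_variants: tuple[int, ...] = (3, 7, 10)) -> list:
    """Write the six canonical configs plus appendix lesion variants."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for age in AGE_GROUPS:
        for endo in (False, True):
            tag = "endo5" if endo else "normal"
            p = out_dir / f"{age}_{tag}.yaml"
            save(document(age, endo), p)
            written.append(p)
    for n in lesion_variants:
        p = out_dir / f"20s_endo{n}.yaml"
        save(document("20s", True, lesion_count=n), p)
        written.append(p)
    return written


def save(doc: dict, path):
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
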