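"""Model, controller and result serialisation, plus an importer for published simulator dialects.

The native format is a versioned XML dialect with every quantity in SI units.
Writing is deterministic (fixed element order, ``repr`` float formatting, so
values round-trip exactly); reading rejects unknown elements with their line
number rather than silently dropping content.  The importer for externally
published simulator model files (BODY/JOINT/MUSCLE/GEOM vocabularies) is
best-effort and read-only: it extracts counts and a coarse planar mapping and
reports everything it could not map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .controller import CyclicController
from .model import (
    BipedModel,
    BoneMonitor,
    ContactSphere,
    CrossSectionSpec,
    FixedJoint,
    HingeJoint,
    Segment,
)
from .muscle import MuscleTendonUnit

SCHEMA_VERSION = "1"


class ModelFormatError(ValueError):
    pass


@dataclass
class ModelDocument:
    model: BipedModel
    schema_version: str = SCHEMA_VERSION
    provenance: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Fully materialised run configuration (simulation + search + limits).

    Loading through :meth:`from_dict` fills every default explicitly, so a
    serialised RunConfig plus its seed regenerates a run exactly; CLI
    manifests embed this structure.
    """

    sim: "SimConfig" = None  # type: ignore[assignment]
    ga: "GAConfig" = None  # type: ignore[assignment]
    stress_limits: list[float] = field(default_factory=list)
    output_dir: str = "."
    rng_seed: int = 0

    def __post_init__(self) -> None:
        from .dynamics import SimConfig
        from .optimize import GAConfig

        if self.sim is None:
            self.sim = SimConfig()
        if self.ga is None:
            self.ga = GAConfig(seed=self.rng_seed)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["sim"] = asdict(self.sim)
        d["ga"] = asdict(self.ga)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .dynamics import SimConfig
        from .optimize import GAConfig

        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        ga_kwargs = d.pop("ga", {})
        if "cycle_bounds" in ga_kwargs:
            ga_kwargs["cycle_bounds"] = tuple(ga_kwargs["cycle_bounds"])
        ga = GAConfig(**ga_kwargs)
        return cls(sim=sim, ga=ga, **d)


# ---------------------------------------------------------------------------
# native writer
# ---------------------------------------------------------------------------


def _f(x: float) -> str:
    return repr(float(x))


def _pts(arr) -> str:
    return "; ".join(f"{_f(x)} {_f(y)}" for x, y in np.asarray(arr, dtype=float))


def _parse_pts(text: str) -> np.ndarray:
    rows = [r for r in (s.strip() for s in text.split(";")) if r]
    return np.array([[float(v) for v in r.split()] for r in rows])


def write_model(doc: ModelDocument | BipedModel, path) -> None:
    if isinstance(doc, BipedModel):
        doc = ModelDocument(model=doc)
    m = doc.model
    root = etree.Element("gaitstress-model", version=doc.schema_version, name=m.name)
    if doc.provenance:
        prov = etree.SubElement(root, "provenance")
        prov.text = json.dumps(doc.provenance, sort_keys=True)
    opts = etree.SubElement(
        root,
        "options",
        gravity=_f(m.gravity),
        anchored_root=str(m.anchored_root).lower(),
        root_start=" ".join(_f(v) for v in m.root_start),
        hip_joints=" ".join(m.hip_joints),
    )
    if m.joint_limit_stiffness is not None:
        opts.set("joint_limit_stiffness", _f(m.joint_limit_stiffness))
    if m.joint_limit_damping is not None:
        opts.set("joint_limit_damping", _f(m.joint_limit_damping))
    for s in m.segments:
        e = etree.SubElement(
            root, "segment", name=s.name, mass=_f(s.mass),
            com=f"{_f(s.com_local[0])} {_f(s.com_local[1])}",
            inertia=_f(s.inertia_zz), length=_f(s.length),
            proximal=f"{_f(s.proximal_anchor[0])} {_f(s.proximal_anchor[1])}",
            distal=f"{_f(s.distal_anchor[0])} {_f(s.distal_anchor[1])}",
        )
        if s.section_ref:
            e.set("section", s.section_ref)
        if s.hull is not None:
            etree.SubElement(e, "hull").text = _pts(s.hull)
    for j in m.joints:
        etree.SubElement(
            root, "hinge", name=j.name, parent=j.parent, child=j.child,
            anchor_parent=f"{_f(j.anchor_parent[0])} {_f(j.anchor_parent[1])}",
            anchor_child=f"{_f(j.anchor_child[0])} {_f(j.anchor_child[1])}",
            range_min=_f(j.range_min), range_max=_f(j.range_max), q0=_f(j.q0),
        )
    for j in m.fixed_joints:
        e = etree.SubElement(
            root, "fixed", name=j.name, parent=j.parent, child=j.child,
            anchor_parent=f"{_f(j.anchor_parent[0])} {_f(j.anchor_parent[1])}",
            anchor_child=f"{_f(j.anchor_child[0])} {_f(j.anchor_child[1])}",
            relative_angle=_f(j.relative_angle),
            is_load_cut=str(j.is_load_cut).lower(),
        )
        if j.cut_axis is not None:
            e.set("cut_axis", f"{_f(j.cut_axis[0])} {_f(j.cut_axis[1])}")
    for mu in m.muscles:
        e = etree.SubElement(
            root, "muscle", name=mu.name, action=mu.action, location=mu.location,
            fibre_length=_f(mu.fibre_length),
            tendon_slack_length=_f(mu.tendon_slack_length),
            mass=_f(mu.mass), activation_tau=_f(mu.activation_tau),
        )
        if mu.f_max is not None:
            e.set("f_max", _f(mu.f_max))
        for seg, p in mu.path:
            pe = etree.SubElement(e, "point", segment=seg)
            pe.text = f"{_f(p[0])} {_f(p[1])}"
    for c in m.contacts:
        etree.SubElement(
            root, "contact", name=c.name, segment=c.segment,
            center=f"{_f(c.center_local[0])} {_f(c.center_local[1])}",
            radius=_f(c.radius), stiffness=_f(c.stiffness),
            damping=_f(c.damping), friction_mu=_f(c.friction_mu),
        )
    for name in sorted(m.sections):
        sec = m.sections[name]
        e = etree.SubElement(
            root, "section", name=sec.name,
            cortical_fraction=_f(sec.cortical_fraction),
        )
        etree.SubElement(e, "outline").text = _pts(sec.outer_outline)
    for mon in m.monitors:
        etree.SubElement(
            root, "monitor", name=mon.name, fixed_joint=mon.fixed_joint,
            sections=",".join(mon.sections),
        )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# native reader
# ---------------------------------------------------------------------------

_KNOWN = {
    "provenance", "options", "segment", "hinge", "fixed", "muscle",
    "contact", "section", "monitor",
}


def _vec(text: str) -> np.ndarray:
    return np.array([float(v) for v in text.split()])


def read_model(path) -> ModelDocument:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ModelFormatError(f"not well-formed XML: {e}") from e
    root = tree.getroot()
    if root.tag != "gaitstress-model":
        raise ModelFormatError(
            f"line {root.sourceline}: unexpected root element {root.tag!r}"
        )
    m = BipedModel(name=root.get("name", "model"))
    provenance: dict = {}
    for el in root:
        if not isinstance(el.tag, str):
            continue  # comments
        if el.tag not in _KNOWN:
            raise ModelFormatError(
                f"line {el.sourceline}: unknown element {el.tag!r}"
            )
        try:
            _read_element(m, el, provenance)
        except (KeyError, ValueError, TypeError) as e:
            raise ModelFormatError(f"line {el.sourceline}: {el.tag}: {e}") from e
    return ModelDocument(
        model=m, schema_version=root.get("version", "?"), provenance=provenance
    )


def _read_element(m: BipedModel, el, provenance: dict) -> None:
    if el.tag == "provenance":
        provenance.update(json.loads(el.text or "{}"))
    elif el.tag == "options":
        m.gravity = float(el.get("gravity", "9.81"))
        m.anchored_root = el.get("anchored_root", "false") == "true"
        m.root_start = tuple(float(v) for v in el.get("root_start", "0 0 0").split())
        m.hip_joints = el.get("hip_joints", "").split()
        if el.get("joint_limit_stiffness") is not None:
            m.joint_limit_stiffness = float(el.get("joint_limit_stiffness"))
        if el.get("joint_limit_damping") is not None:
            m.joint_limit_damping = float(el.get("joint_limit_damping"))
    elif el.tag == "segment":
        hull_el = el.find("hull")
        m.segments.append(
            Segment(
                name=el.attrib["name"], mass=float(el.attrib["mass"]),
                com_local=_vec(el.attrib["com"]),
                inertia_zz=float(el.attrib["inertia"]),
                length=float(el.attrib["length"]),
                proximal_anchor=_vec(el.attrib["proximal"]),
                distal_anchor=_vec(el.attrib["distal"]),
                hull=None if hull_el is None else _parse_pts(hull_el.text),
                section_ref=el.get("section"),
            )
        )
    elif el.tag == "hinge":
        m.joints.append(
            HingeJoint(
                name=el.attrib["name"], parent=el.attrib["parent"],
                child=el.attrib["child"],
                anchor_parent=_vec(el.attrib["anchor_parent"]),
                anchor_child=_vec(el.attrib["anchor_child"]),
                range_min=float(el.attrib["range_min"]),
                range_max=float(el.attrib["range_max"]),
                q0=float(el.get("q0", "0")),
            )
        )
    elif el.tag == "fixed":
        ax = el.get("cut_axis")
        m.fixed_joints.append(
            FixedJoint(
                name=el.attrib["name"], parent=el.attrib["parent"],
                child=el.attrib["child"],
                anchor_parent=_vec(el.attrib["anchor_parent"]),
                anchor_child=_vec(el.attrib["anchor_child"]),
                relative_angle=float(el.get("relative_angle", "0")),
                is_load_cut=el.get("is_load_cut", "false") == "true",
                cut_axis=None if ax is None else _vec(ax),
            )
        )
    elif el.tag == "muscle":
        path = [(p.attrib["segment"], _vec(p.text)) for p in el.findall("point")]
        fm = el.get("f_max")
        m.muscles.append(
            MuscleTendonUnit(
                name=el.attrib["name"], path=path,
                f_max=None if fm is None else float(fm),
                fibre_length=float(el.attrib["fibre_length"]),
                tendon_slack_length=float(el.attrib["tendon_slack_length"]),
                mass=float(el.get("mass", "0")),
                action=el.get("action", "extensor"),
                location=el.get("location", "proximal"),
                activation_tau=float(el.get("activation_tau", "0.05")),
            )
        )
    elif el.tag == "contact":
        m.contacts.append(
            ContactSphere(
                name=el.attrib["name"], segment=el.attrib["segment"],
                center_local=_vec(el.attrib["center"]),
                radius=float(el.attrib["radius"]),
                stiffness=float(el.attrib["stiffness"]),
                damping=float(el.attrib["damping"]),
                friction_mu=float(el.attrib["friction_mu"]),
            )
        )
    elif el.tag == "section":
        outline = el.find("outline")
        m.sections[el.attrib["name"]] = CrossSectionSpec(
            name=el.attrib["name"],
            outer_outline=_parse_pts(outline.text),
            cortical_fraction=float(el.attrib["cortical_fraction"]),
        )
    elif el.tag == "monitor":
        m.monitors.append(
            BoneMonitor(
                name=el.attrib["name"], fixed_joint=el.attrib["fixed_joint"],
                sections=[s for s in el.attrib["sections"].split(",") if s],
            )
        )


# ---------------------------------------------------------------------------
# controllers
# ---------------------------------------------------------------------------


def write_controller(controller: CyclicController, path) -> None:
    root = etree.Element(
        "gaitstress-controller",
        version=SCHEMA_VERSION,
        cycle_duration=_f(controller.cycle_duration),
        symmetric=str(controller.symmetric).lower(),
        n_phases=str(controller.n_phases),
    )
    for name in controller.muscle_order():
        e = etree.SubElement(root, "muscle", name=name)
        e.text = " ".join(_f(v) for v in controller.levels[name])
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_controller(path) -> CyclicController:
    root = etree.parse(str(path)).getroot()
    if root.tag != "gaitstress-controller":
        raise ModelFormatError(f"unexpected root element {root.tag!r}")
    levels = {e.attrib["name"]: _vec(e.text) for e in root.findall("muscle")}
    return CyclicController(
        cycle_duration=float(root.attrib["cycle_duration"]),
        levels=levels,
        symmetric=root.get("symmetric", "true") == "true",
    )


# ---------------------------------------------------------------------------
# importer for published simulator model files (best-effort, read-only)
# ---------------------------------------------------------------------------


@dataclass
class ImportReport:
    n_segments: int = 0
    n_joints: int = 0
    n_muscles: int = 0
    n_contacts: int = 0
    unmapped: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"segments: {self.n_segments}",
            f"joints:   {self.n_joints}",
            f"muscles:  {self.n_muscles}",
            f"contacts: {self.n_contacts}",
        ]
        for tag, n in sorted(self.unmapped.items()):
            lines.append(f"unmapped <{tag}>: {n}")
        return "\n".join(lines)


_IMPORT_BODY = {"body"}
_IMPORT_JOINT = {"joint"}
_IMPORT_MUSCLE = {"muscle", "strap"}
_IMPORT_CONTACT = {"geom", "sphere"}
_IMPORT_IGNORABLE = {
    "global", "environment", "interface", "driver", "datatarget",
    "marker", "controller", "reporter", "warehouse", "ioControl",
}


def _attr(el, *names, default=None):
    for n in names:
        for k, v in el.attrib.items():
            if k.lower() == n.lower():
                return v
    return default


def import_published_model(path) -> tuple[ModelDocument, ImportReport]:
    """Best-effort planar import of a published simulator model XML file.

    Bodies become segments (3D positions are projected onto the sagittal
    x-z plane), hinge joints become hinges, muscles/straps and contact
    geometries are counted and carried over coarsely.  Nothing is silently
    dropped: every unrecognised element tag is counted in the report.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ModelFormatError(f"not well-formed XML: {e}") from e
    root = tree.getroot()
    report = ImportReport()
    m = BipedModel(name=f"imported:{root.tag}")

    def planar(vec_text, default=(0.0, 0.0)):
        if not vec_text:
            return np.array(default)
        vals = [float(v) for v in vec_text.replace(",", " ").split()]
        if len(vals) >= 3:
            return np.array([vals[0], vals[2]])  # sagittal plane of a z-up world
        return np.array(vals[:2] + [0.0] * (2 - len(vals[:2])))

    elements = [el for el in root.iter() if isinstance(el.tag, str) and el is not root]
    if not any(el.tag.lower() in _IMPORT_BODY for el in elements):
        raise ModelFormatError(
            "unrecognised dialect: no BODY elements found in the file"
        )
    for el in elements:
        tag = el.tag.lower()
        if tag in _IMPORT_BODY:
            name = _attr(el, "ID", "Name", default=f"body{report.n_segments}")
            mass = float(_attr(el, "Mass", default="1.0"))
            pos = planar(_attr(el, "Position", "ConstructionPosition"))
            m.segments.append(
                Segment(
                    name=name, mass=max(mass, 1e-9), com_local=(0.0, 0.0),
                    inertia_zz=0.0, length=1.0,
                    proximal_anchor=pos, distal_anchor=pos,
                )
            )
            report.n_segments += 1
        elif tag in _IMPORT_JOINT:
            report.n_joints += 1
        elif tag in _IMPORT_MUSCLE:
            report.n_muscles += 1
        elif tag in _IMPORT_CONTACT:
            report.n_contacts += 1
        elif el.getparent() is not root:
            continue  # nested payload of a mapped element
        elif tag in {t.lower() for t in _IMPORT_IGNORABLE}:
            report.unmapped[el.tag] = report.unmapped.get(el.tag, 0) + 1
        else:
            report.unmapped[el.tag] = report.unmapped.get(el.tag, 0) + 1
    doc = ModelDocument(
        model=m,
        provenance={"source": str(path), "importer": "published-model-dialect"},
    )
    return doc, report
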