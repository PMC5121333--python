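"""SBML Level 2 Version 4 export/import for network models.

The writer emits standard SBML: one compartment, species with initial
amounts, global parameters, and for every reaction a single reactant,
a single product, the catalysts as modifiers, and a mass-action kinetic law

    k * gate * (catalyst_1 + ... + catalyst_m) * substrate

with the stimulus gate carried as a dedicated global parameter (``stim_aa``,
``stim_insulin``, both default 1).  A compact structured annotation in the
package namespace records the pool/mark/gate/observable metadata that plain
SBML has no first-class slot for, so that export -> import -> export is
byte-stable after canonical ordering.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .network import ModelSpec, ReactionSpec, SpeciesState

__all__ = ["export_sbml", "import_sbml", "write_sbml_file", "read_sbml_file"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANN_NS = "https://mtornet.dev/sbml-annotation"


class SBMLExportError(ValueError):
    pass


def _math_ci(parent, name):
    ci = ET.SubElement(parent, f"{{{MATHML_NS}}}ci")
    ci.text = f" {name} "


def _kinetic_math(reaction: ReactionSpec):
    math = ET.Element(f"{{{MATHML_NS}}}math")
    times = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(times, f"{{{MATHML_NS}}}times")
    _math_ci(times, reaction.rate_param)
    if reaction.stimulus_gate != "none":
        _math_ci(times, f"stim_{reaction.stimulus_gate}")
    if reaction.catalyst_pool:
        if len(reaction.catalyst_pool) == 1:
            _math_ci(times, reaction.catalyst_pool[0])
        else:
            plus = ET.SubElement(times, f"{{{MATHML_NS}}}apply")
            ET.SubElement(plus, f"{{{MATHML_NS}}}plus")
            for c in reaction.catalyst_pool:
                _math_ci(plus, c)
    _math_ci(times, reaction.substrate)
    return math


def export_sbml(model: ModelSpec) -> str:
    """Serialize a model to an SBML L2V4 document string."""
    try:
        model.validate()
    except ValueError as exc:
        raise SBMLExportError(str(exc)) from exc

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("mtornet", ANN_NS)

    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "2", "version": "4"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": "mtor_ampk_network"})

    ann = ET.SubElement(mdl, f"{{{SBML_NS}}}annotation")
    meta = ET.SubElement(ann, f"{{{ANN_NS}}}modelInfo", {
        "s6kModule": model.s6k_module,
        "inputSites": ",".join(sorted(model.input_sites)),
    })
    for obs_id in sorted(model.observables):
        ET.SubElement(meta, f"{{{ANN_NS}}}observable", {
            "id": obs_id,
            "species": ",".join(model.observables[obs_id]),
        })

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {"id": "cell", "size": "1"})

    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in sorted(model.species, key=lambda s: s.id):
        el = ET.SubElement(sps, f"{{{SBML_NS}}}species", {
            "id": s.id,
            "name": s.id,
            "compartment": "cell",
            "initialAmount": repr(float(s.initial_amount)),
            "hasOnlySubstanceUnits": "true",
        })
        sann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(sann, f"{{{ANN_NS}}}state", {
            "pool": s.protein,
            "marks": ",".join(sorted(s.phospho_marks)),
        })

    pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for gate in ("aa", "insulin"):
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", {
            "id": f"stim_{gate}", "value": "1", "constant": "true",
        })
    for pid in sorted(model.parameters):
        value, lo, hi = model.parameters[pid]
        el = ET.SubElement(pars, f"{{{SBML_NS}}}parameter", {
            "id": pid, "value": repr(float(value)), "constant": "true",
        })
        pann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(pann, f"{{{ANN_NS}}}bounds", {
            "lower": repr(float(lo)), "upper": repr(float(hi)),
        })

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in sorted(model.reactions, key=_reaction_key):
        el = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", {
            "id": r.id, "reversible": "false",
        })
        rann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(rann, f"{{{ANN_NS}}}rate", {
            "gate": r.stimulus_gate,
            "catalysts": ",".join(r.catalyst_pool),
            "param": r.rate_param,
        })
        reac = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
        ET.SubElement(reac, f"{{{SBML_NS}}}speciesReference",
                      {"species": r.substrate, "stoichiometry": "1"})
        prod = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
        ET.SubElement(prod, f"{{{SBML_NS}}}speciesReference",
                      {"species": r.product, "stoichiometry": "1"})
        if r.catalyst_pool:
            mods = ET.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
            for c in r.catalyst_pool:
                ET.SubElement(mods, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": c})
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_kinetic_math(r))

    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def _reaction_key(r: ReactionSpec):
    # canonical ordering: numeric suffix of Rn ids, then lexicographic
    rid = r.id
    if rid.startswith("R") and rid[1:].isdigit():
        return (0, int(rid[1:]), rid)
    return (1, 0, rid)


def import_sbml(text: str) -> ModelSpec:
    """Parse an SBML document produced by :func:`export_sbml`."""
    root = ET.fromstring(text)
    mdl = root.find(f"{{{SBML_NS}}}model")
    if mdl is None:
        raise ValueError("not an SBML L2 document: missing <model>")

    meta = mdl.find(f"{{{SBML_NS}}}annotation/{{{ANN_NS}}}modelInfo")
    if meta is None:
        raise ValueError("missing model annotation (not written by this package)")
    s6k_module = meta.get("s6kModule")
    input_sites = frozenset(x for x in meta.get("inputSites", "").split(",") if x)
    observables = {
        o.get("id"): o.get("species").split(",")
        for o in meta.findall(f"{{{ANN_NS}}}observable")
    }

    species = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        st = el.find(f"{{{SBML_NS}}}annotation/{{{ANN_NS}}}state")
        marks = frozenset(x for x in st.get("marks", "").split(",") if x)
        species.append(SpeciesState(
            id=el.get("id"),
            protein=st.get("pool"),
            phospho_marks=marks,
            initial_amount=float(el.get("initialAmount", "0")),
        ))

    parameters = {}
    for el in mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        pid = el.get("id")
        if pid.startswith("stim_"):
            continue
        b = el.find(f"{{{SBML_NS}}}annotation/{{{ANN_NS}}}bounds")
        parameters[pid] = (
            float(el.get("value")),
            float(b.get("lower")),
            float(b.get("upper")),
        )

    reactions = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rate = el.find(f"{{{SBML_NS}}}annotation/{{{ANN_NS}}}rate")
        sub = el.find(
            f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
        ).get("species")
        prod = el.find(
            f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
        ).get("species")
        cats = tuple(x for x in rate.get("catalysts", "").split(",") if x)
        reactions.append(ReactionSpec(
            id=el.get("id"), substrate=sub, product=prod,
            rate_param=rate.get("param"), catalyst_pool=cats,
            stimulus_gate=rate.get("gate", "none"),
        ))

    return ModelSpec(
        species=species,
        reactions=reactions,
        parameters=parameters,
        observables=observables,
        input_sites=input_sites,
        s6k_module=s6k_module,
    )


def write_sbml_file(model: ModelSpec, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(export_sbml(model))


def read_sbml_file(path) -> ModelSpec:
    with open(path, encoding="utf-8") as fh:
        return import_sbml(fh.read())
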