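"""SBML Level 3 export / import of the network model.

Writes the model as SBML L3V2 core: one compartment, the 27 forms as
species (boundary-condition flags on the clamped IPTG and SS inputs), every
kinetic constant as a global parameter (the dotted key preserved in the
``name`` attribute), and the 55 unidirectional reactions with their rate
laws as content MathML.  The reader reconstructs a fully functional
:class:`~spornet.network.NetworkModel` from such a file; a written-then-read
model reproduces simulations of the original to high accuracy.

This is a deliberately small SBML subset — enough to faithfully exchange
this model family, not a general-purpose SBML toolkit.
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp
from lxml import etree

from .network import (
    FORMS,
    NetworkModel,
    RateLaw,
    Reaction,
    _SPECIES_SYMBOLS,
    param_symbol,
)
from .params import BOUNDARY_FORMS, ParameterSet

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(key: str) -> str:
    """Valid SBML SId for a dotted parameter or reaction id."""
    return key.replace(".", "_")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _expr_to_mathml(expr: sp.Expr, param_ids: dict[str, str]) -> etree._Element:
    """Content-MathML element for a sympy rate expression."""

    def build(e: sp.Expr) -> etree._Element:
        E = lambda tag: etree.SubElement  # noqa: E731
        if isinstance(e, sp.Symbol):
            name = e.name
            el = etree.Element(f"{{{MATHML_NS}}}ci")
            el.text = f" {param_ids.get(name, name)} "
            return el
        if isinstance(e, (sp.Integer, sp.Float, sp.Rational)) or e.is_Number:
            el = etree.Element(f"{{{MATHML_NS}}}cn")
            if isinstance(e, sp.Integer):
                el.set("type", "integer")
                el.text = f" {int(e)} "
            else:
                el.text = f" {float(e)!r} "
            return el
        if isinstance(e, sp.Add):
            return apply_of("plus", e.args)
        if isinstance(e, sp.Mul):
            # keep the factor structure so a parse rebuilds the same tree
            return apply_of("times", e.args)
        if isinstance(e, sp.Pow):
            base, exp = e.args
            if exp.is_Number and exp < 0:
                return apply_of("divide", (sp.Integer(1), sp.Pow(base, -exp)))
            return apply_of("power", (base, exp))
        raise ValueError(f"cannot serialize expression node {e!r}")

    def apply_of(op: str, args) -> etree._Element:
        el = etree.Element(f"{{{MATHML_NS}}}apply")
        etree.SubElement(el, f"{{{MATHML_NS}}}{op}")
        for a in args:
            el.append(build(sp.sympify(a)))
        return el

    math = etree.Element(f"{{{MATHML_NS}}}math")
    math.append(build(expr))
    return math


def write_sbml(model: NetworkModel, path: str | Path) -> None:
    """Serialize *model* (structure, parameters, rate laws) as SBML L3V2."""
    nsmap = {None: SBML_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "2")
    mdl = etree.SubElement(sbml, f"{{{SBML_NS}}}model")
    mdl.set("id", "sporulation_initiation")

    comps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")

    species_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for form in FORMS:
        s = etree.SubElement(species_list, f"{{{SBML_NS}}}species")
        s.set("id", form)
        s.set("compartment", "cell")
        s.set("initialConcentration", "0")
        s.set("hasOnlySubstanceUnits", "false")
        s.set("boundaryCondition", "true" if form in BOUNDARY_FORMS else "false")
        s.set("constant", "false")

    # every parameter of the set, dotted key preserved in @name
    param_ids: dict[str, str] = {}
    params_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for key in sorted(model.params.values):
        pid = "par_" + _sid(key)
        param_ids[param_symbol(key).name] = pid
        p = etree.SubElement(params_list, f"{{{SBML_NS}}}parameter")
        p.set("id", pid)
        p.set("name", key)
        if key.startswith("deg."):
            value = model.params.degradation_rate(key.split(".")[1])
        else:
            value = model.params[key]
        p.set("value", repr(value))
        p.set("constant", "true")
    # materialize the resolved per-form degradation rates as well
    for rxn in model.reactions:
        for key in rxn.rate_law.param_keys:
            sym = param_symbol(key).name
            if sym not in param_ids:
                pid = "par_" + _sid(key)
                param_ids[sym] = pid
                p = etree.SubElement(params_list, f"{{{SBML_NS}}}parameter")
                p.set("id", pid)
                p.set("name", key)
                value = (
                    model.params.degradation_rate(key.split(".")[1])
                    if key.startswith("deg.") else model.params[key]
                )
                p.set("value", repr(value))
                p.set("constant", "true")

    rxns_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        r = etree.SubElement(rxns_list, f"{{{SBML_NS}}}reaction")
        r.set("id", "rxn_" + _sid(rxn.id))
        r.set("name", rxn.rate_law.kind)
        r.set("reversible", "false")
        if rxn.consumed:
            lst = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for form, n in rxn.consumed.items():
                sr = etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", form)
                sr.set("stoichiometry", str(n))
                sr.set("constant", "true")
        if rxn.produced:
            lst = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for form, n in rxn.produced.items():
                sr = etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", form)
                sr.set("stoichiometry", str(n))
                sr.set("constant", "true")
        if rxn.modifiers:
            lst = etree.SubElement(r, f"{{{SBML_NS}}}listOfModifiers")
            for form in rxn.modifiers:
                sr = etree.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference")
                sr.set("species", form)
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_expr_to_mathml(rxn.rate_law.expr, param_ids))

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _mathml_to_expr(node: etree._Element, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        return _mathml_to_expr(children[0], symbols)
    if tag == "ci":
        name = node.text.strip()
        if name not in symbols:
            raise ValueError(f"unknown identifier {name!r} in kinetic law")
        return symbols[name]
    if tag == "cn":
        ctype = node.get("type", "real")
        if ctype == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return sp.Float(float(parts[0]) * 10.0 ** float(parts[1]))
        text = node.text.strip()
        return sp.Integer(int(text)) if ctype == "integer" else sp.Float(float(text))
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_expr(c, symbols) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return sp.Pow(args[0], args[1])
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


def read_sbml(path: str | Path) -> NetworkModel:
    """Reconstruct a :class:`NetworkModel` from a file written by write_sbml."""
    ns = {"s": SBML_NS, "m": MATHML_NS}
    tree = etree.parse(str(path))
    root = tree.getroot()

    species = [
        s.get("id") for s in root.findall(".//s:listOfSpecies/s:species", ns)
    ]
    if tuple(species) != FORMS:
        raise ValueError("species list does not match the canonical 27 forms")
    boundary = {
        s.get("id")
        for s in root.findall(".//s:listOfSpecies/s:species", ns)
        if s.get("boundaryCondition") == "true"
    }
    if boundary != set(BOUNDARY_FORMS):
        raise ValueError(f"unexpected boundary species {sorted(boundary)}")

    values: dict[str, float] = {}
    id_to_key: dict[str, str] = {}
    for p in root.findall(".//s:listOfParameters/s:parameter", ns):
        key = p.get("name") or p.get("id")
        values[key] = float(p.get("value"))
        id_to_key[p.get("id")] = key

    symbols: dict[str, sp.Symbol] = dict(_SPECIES_SYMBOLS)
    for pid, key in id_to_key.items():
        symbols[pid] = param_symbol(key)

    reactions: list[Reaction] = []
    for r in root.findall(".//s:listOfReactions/s:reaction", ns):
        rid = r.get("id").removeprefix("rxn_")
        # reaction SIds flatten '.' to '_'; restore the degradation prefix
        if rid.startswith("deg_"):
            rid = "deg." + rid[len("deg_"):]
        consumed = {
            sr.get("species"): int(float(sr.get("stoichiometry", "1")))
            for sr in r.findall("s:listOfReactants/s:speciesReference", ns)
        }
        produced = {
            sr.get("species"): int(float(sr.get("stoichiometry", "1")))
            for sr in r.findall("s:listOfProducts/s:speciesReference", ns)
        }
        modifiers = tuple(
            sr.get("species")
            for sr in r.findall("s:listOfModifiers/s:modifierSpeciesReference", ns)
        )
        math = r.find("s:kineticLaw/m:math", ns)
        if math is None:
            raise ValueError(f"reaction {rid} has no kinetic law")
        expr = _mathml_to_expr(math, symbols)
        symname_to_key = {param_symbol(k).name: k for k in values}
        pkeys = tuple(
            sorted(
                symname_to_key[s.name]
                for s in expr.free_symbols
                if s.name in symname_to_key
            )
        )
        reactions.append(
            Reaction(rid, consumed, produced, modifiers,
                     RateLaw(r.get("name") or "imported", expr, pkeys, modifiers))
        )
    return NetworkModel(reactions, ParameterSet(values))
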