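"""Minimal SBML import/export for ODE-expressible models.

Supports the core constructs needed to exchange kinetic models: species
(states), compartments, global parameters, reactions with mass-action-style
kinetic laws, and rate rules.  Content MathML is translated to sympy
expressions.  Anything outside that subset — events, function definitions,
assignment/algebraic rules, initial assignments, constraints — is rejected
with an explicit error naming the construct, never silently dropped.

Because SBML has no notion of measured outputs or external input channels,
the exporter records the output expressions in a ``denet`` annotation and
marks input channels as non-constant parameters; the importer understands
both conventions and otherwise defaults to observing every species.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import sympy as sp
from lxml import etree

from .models import OdeModel

__all__ = ["load_sbml", "write_sbml", "SbmlImportError", "UnsupportedSbmlError"]

_DENET_NS = "https://denet.invalid/sbml-annotations"


class SbmlImportError(ValueError):
    """The file is not usable SBML."""


class UnsupportedSbmlError(SbmlImportError):
    """The file uses an SBML construct outside the ODE-expressible subset."""

    def __init__(self, construct: str):
        super().__init__(f"unsupported SBML construct: {construct}")
        self.construct = construct


def _local(el) -> str:
    return etree.QName(el).localname


def _children(el, name):
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def _find(el, name):
    found = _children(el, name)
    return found[0] if found else None


# ---------------------------------------------------------------------------
# content MathML <-> sympy
# ---------------------------------------------------------------------------

_MATHML_OPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
    "minus": lambda *a: a[0] - a[1] if len(a) == 2 else -a[0],
    "divide": lambda a, b: a / b,
    "power": lambda a, b: a ** b,
    "exp": sp.exp,
    "ln": sp.log,
    "log": sp.log,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "sqrt": sp.sqrt,
    "abs": sp.Abs,
}


def _mathml_to_sympy(el, symbols: dict) -> sp.Expr:
    name = _local(el)
    if name == "math":
        kids = [c for c in el if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise SbmlImportError("math element must contain one expression")
        return _mathml_to_sympy(kids[0], symbols)
    if name == "ci":
        ident = el.text.strip()
        return symbols.setdefault(ident, sp.Symbol(ident))
    if name == "cn":
        ctype = el.attrib.get("type", "real")
        if ctype in ("real", "integer", "double"):
            return sp.Float(el.text.strip()) if ctype != "integer" else sp.Integer(el.text.strip())
        if ctype == "e-notation":
            sep = _find(el, "sep")
            mant = el.text.strip()
            expo = sep.tail.strip()
            return sp.Float(f"{mant}e{expo}")
        if ctype == "rational":
            sep = _find(el, "sep")
            return sp.Rational(int(el.text.strip()), int(sep.tail.strip()))
        raise UnsupportedSbmlError(f"cn type {ctype!r}")
    if name == "csymbol":
        url = el.attrib.get("definitionURL", "")
        if url.endswith("/time"):
            return symbols.setdefault("t", sp.Symbol("t"))
        raise UnsupportedSbmlError(f"csymbol {url!r}")
    if name == "pi":
        return sp.pi
    if name == "exponentiale":
        return sp.E
    if name == "apply":
        kids = [c for c in el if isinstance(c.tag, str)]
        op = _local(kids[0])
        if op not in _MATHML_OPS:
            raise UnsupportedSbmlError(f"MathML operator <{op}>")
        args = [_mathml_to_sympy(c, symbols) for c in kids[1:]]
        return _MATHML_OPS[op](*args)
    raise UnsupportedSbmlError(f"MathML element <{name}>")


_MML = "http://www.w3.org/1998/Math/MathML"


def _sympy_to_mathml(expr: sp.Expr) -> etree._Element:
    def build(e):
        if e is sp.pi:
            return etree.SubElement(None, "x")  # unreachable for our models
        if isinstance(e, sp.Symbol):
            el = etree.Element(f"{{{_MML}}}ci")
            el.text = str(e)
            return el
        if isinstance(e, (sp.Integer, sp.Float, sp.Rational)) or e.is_Number:
            if isinstance(e, sp.Rational) and not isinstance(e, sp.Integer):
                el = etree.Element(f"{{{_MML}}}apply")
                el.append(_op("divide"))
                el.append(_num(sp.Integer(e.p)))
                el.append(_num(sp.Integer(e.q)))
                return el
            return _num(e)
        if isinstance(e, sp.Add):
            return _apply("plus", e.args)
        if isinstance(e, sp.Mul):
            return _apply("times", e.args)
        if isinstance(e, sp.Pow):
            return _apply("power", e.args)
        if isinstance(e, sp.exp):
            return _apply("exp", e.args)
        if isinstance(e, sp.log):
            return _apply("ln", e.args)
        if isinstance(e, (sp.sin, sp.cos, sp.tan)):
            return _apply(type(e).__name__.lower(), e.args)
        raise SbmlImportError(f"cannot export expression node {type(e).__name__}")

    def _op(name):
        return etree.Element(f"{{{_MML}}}{name}")

    def _num(e):
        el = etree.Element(f"{{{_MML}}}cn")
        if isinstance(e, sp.Integer):
            el.set("type", "integer")
            el.text = str(int(e))
        else:
            el.text = repr(float(e))
        return el

    def _apply(op, args):
        el = etree.Element(f"{{{_MML}}}apply")
        el.append(_op(op))
        for a in args:
            el.append(build(a))
        return el

    math = etree.Element(f"{{{_MML}}}math")
    math.append(build(sp.sympify(expr)))
    return math


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

_REJECTED_LISTS = {
    "listOfEvents": "event",
    "listOfFunctionDefinitions": "functionDefinition",
    "listOfInitialAssignments": "initialAssignment",
    "listOfConstraints": "constraint",
}


def load_sbml(path) -> OdeModel:
    """Import an SBML (Level 2/3 core subset) file as an :class:`OdeModel`.

    Species become states (rate = sum of stoichiometry-weighted kinetic laws
    plus any rate rule), constant species and compartments become fixed
    values, and non-constant parameters become known-input channels.
    Unsupported constructs raise :class:`UnsupportedSbmlError`.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SbmlImportError(f"cannot parse {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root) != "sbml":
        raise SbmlImportError("root element is not <sbml>")
    model_el = _find(root, "model")
    if model_el is None:
        raise SbmlImportError("no <model> element")

    for lst, construct in _REJECTED_LISTS.items():
        found = _find(model_el, lst)
        if found is not None and len(found):
            raise UnsupportedSbmlError(construct)

    symbols: dict[str, sp.Symbol] = {}
    consts: dict[str, float] = {}

    comp_el = _find(model_el, "listOfCompartments")
    for c in _children(comp_el, "compartment") if comp_el is not None else []:
        consts[c.attrib["id"]] = float(c.attrib.get("size", c.attrib.get("volume", 1.0)))

    states, x0, constant_species = [], [], {}
    sp_el = _find(model_el, "listOfSpecies")
    for s in _children(sp_el, "species") if sp_el is not None else []:
        sid = s.attrib["id"]
        init = float(s.attrib.get("initialConcentration",
                                  s.attrib.get("initialAmount", 0.0)))
        if s.attrib.get("constant", "false") == "true":
            constant_species[sid] = init
        else:
            states.append(sid)
            x0.append(init)
    if not states:
        raise SbmlImportError("model declares no dynamic species")

    params, inputs = {}, []
    par_el = _find(model_el, "listOfParameters")
    for p in _children(par_el, "parameter") if par_el is not None else []:
        pid = p.attrib["id"]
        if p.attrib.get("constant", "true") == "true":
            params[pid] = float(p.attrib.get("value", 0.0))
        else:
            inputs.append(pid)

    rates = {sid: sp.Integer(0) for sid in states}

    rxn_el = _find(model_el, "listOfReactions")
    n_reactions = 0
    for r in _children(rxn_el, "reaction") if rxn_el is not None else []:
        n_reactions += 1
        kl = _find(r, "kineticLaw")
        if kl is None:
            raise SbmlImportError(f"reaction {r.attrib.get('id')} has no kinetic law")
        local = {}
        lop = _find(kl, "listOfLocalParameters") or _find(kl, "listOfParameters")
        for p in _children(lop, "localParameter") + _children(lop, "parameter") if lop is not None else []:
            local[p.attrib["id"]] = float(p.attrib.get("value", 0.0))
        math = _find(kl, "math")
        expr = _mathml_to_sympy(math, symbols)
        expr = expr.subs({sp.Symbol(k): v for k, v in local.items()})
        for side, sign in (("listOfReactants", -1), ("listOfProducts", +1)):
            lst = _find(r, side)
            for ref in _children(lst, "speciesReference") if lst is not None else []:
                sid = ref.attrib["species"]
                stoich = float(ref.attrib.get("stoichiometry", 1.0))
                if sid in rates:
                    rates[sid] = rates[sid] + sign * stoich * expr

    rules_el = _find(model_el, "listOfRules")
    for rule in list(rules_el) if rules_el is not None else []:
        kind = _local(rule)
        if kind != "rateRule":
            raise UnsupportedSbmlError(kind)
        var = rule.attrib["variable"]
        if var not in rates:
            raise SbmlImportError(f"rate rule targets unknown species {var!r}")
        rates[var] = rates[var] + _mathml_to_sympy(_find(rule, "math"), symbols)

    fixed = {sp.Symbol(k): v for k, v in {**consts, **constant_species}.items()}
    rate_exprs = [sp.simplify(rates[sid].subs(fixed)) for sid in states]

    # outputs: denet annotation if present, else observe every species
    outputs = None
    ann = _find(model_el, "annotation")
    if ann is not None:
        for el in ann.iter():
            if isinstance(el.tag, str) and etree.QName(el).namespace == _DENET_NS \
                    and etree.QName(el).localname == "output":
                outputs = outputs or []
                outputs.append(el.attrib["expr"])
    if outputs is None:
        outputs = list(states)

    if not inputs:
        inputs = ["_u_unused"]
    model = OdeModel.from_expressions(
        states=states,
        rates=[str(e) for e in rate_exprs],
        outputs=outputs,
        parameters=params if params else {"_one": 1.0},
        initial_state=x0,
        inputs=inputs,
        name=model_el.attrib.get("id", path.stem),
    )
    model.diag_n_reactions = n_reactions
    return model


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_SBML_L2 = "http://www.sbml.org/sbml/level2/version4"


def write_sbml(model: OdeModel, path) -> None:
    """Export a symbolically-defined model as SBML Level 2 using rate rules.

    The ODE right-hand sides are written as rate rules (no reaction network
    reconstruction is attempted); output expressions go into a ``denet``
    annotation so that :func:`load_sbml` round-trips the full model.
    """
    if model.sym_rates is None:
        raise SbmlImportError("only symbolically-defined models can be exported")
    nsmap = {None: _SBML_L2}
    root = etree.Element(f"{{{_SBML_L2}}}sbml", nsmap=nsmap, level="2", version="4")
    m = etree.SubElement(root, f"{{{_SBML_L2}}}model", id=model.name)

    ann = etree.SubElement(m, f"{{{_SBML_L2}}}annotation")
    outs = etree.SubElement(ann, f"{{{_DENET_NS}}}outputs", nsmap={"denet": _DENET_NS})
    for expr in model.sym_outputs:
        etree.SubElement(outs, f"{{{_DENET_NS}}}output", expr=str(expr))

    lc = etree.SubElement(m, f"{{{_SBML_L2}}}listOfCompartments")
    etree.SubElement(lc, f"{{{_SBML_L2}}}compartment", id="cell", size="1")

    ls = etree.SubElement(m, f"{{{_SBML_L2}}}listOfSpecies")
    for sid, init in zip(model.state_labels, model.initial_state):
        etree.SubElement(ls, f"{{{_SBML_L2}}}species", id=str(sid), compartment="cell",
                         initialConcentration=repr(float(init)),
                         boundaryCondition="true")

    lp = etree.SubElement(m, f"{{{_SBML_L2}}}listOfParameters")
    for name, val in model.parameters.items():
        etree.SubElement(lp, f"{{{_SBML_L2}}}parameter", id=str(name),
                         value=repr(float(val)), constant="true")
    for usym in model.sym_inputs:
        etree.SubElement(lp, f"{{{_SBML_L2}}}parameter", id=str(usym),
                         value="0", constant="false")

    lr = etree.SubElement(m, f"{{{_SBML_L2}}}listOfRules")
    for sid, expr in zip(model.state_labels, model.sym_rates):
        rule = etree.SubElement(lr, f"{{{_SBML_L2}}}rateRule", variable=str(sid))
        rule.append(_sympy_to_mathml(expr))

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
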