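"""SBML Level 3 Version 1 export and import of commitment models.

The model is a phenomenological ODE system, so it is exchanged as rate
rules (one per gene species) rather than a reaction network: each rule
carries the full Shea-Ackers production-minus-decay expression in
content MathML, and the normalised Notch signal is an assignment rule
driven by the csymbol ``time``.  Parameters keep the field's symbol
names (eta1N, delta2, kappa1, gammaT, ...).  The writer and reader are
self-contained; when the libsbml bindings happen to be importable the
document is additionally run through their consistency checks.

The logic configuration travels in a package annotation so that a
re-imported document reconstructs the identical ``ModelSpec``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Dict, List, Optional, Tuple, Union

from .logic import get_configuration
from .model import GENES, GeneState, ModelParameters, ModelSpec, NotchSignal

__all__ = ["export_sbml", "import_sbml", "validate_sbml", "fitted_parameter_ids"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"
ANNOT_NS = "https://tcommit.readthedocs.io/sbml-annotation"

_SPECIES = {"T": "TCF1", "G": "GATA3", "B": "BCL11B", "P": "PU1"}

#: canonical fitted-parameter inventory of the TGB+Notch subsystem
_TGB_PARAM_IDS = (
    ["eta1N", "eta2", "eta3", "eta4", "fT", "gammaT",
     "delta1N", "delta2", "delta3", "fG", "gammaG",
     "fB", "gammaB", "alpha"]
)
_PU1_PARAM_IDS = ["rho1", "rho2", "rho3", "rho4", "fP", "gammaP"]


# ---------------------------------------------------------------------------
# Tiny content-MathML expression builder
# ---------------------------------------------------------------------------


def _m(tag: str, *children, text: Optional[str] = None, **attrib) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}{tag}", attrib)
    if text is not None:
        el.text = text
    el.extend(children)
    return el


def _ci(name: str) -> ET.Element:
    return _m("ci", text=f" {name} ")


def _cn(value: float) -> ET.Element:
    if float(value).is_integer() and abs(value) < 1e15:
        return _m("cn", text=f" {int(value)} ", type="integer")
    return _m("cn", text=f" {value!r} ")


def _time() -> ET.Element:
    return _m("csymbol", text=" t ", encoding="text",
              definitionURL=TIME_CSYMBOL)


def _apply(op: str, *args: ET.Element) -> ET.Element:
    return _m("apply", _m(op), *args)


def _plus(*args):
    return args[0] if len(args) == 1 else _apply("plus", *args)


def _times(*args):
    return args[0] if len(args) == 1 else _apply("times", *args)


def _minus(a, b):
    return _apply("minus", a, b)


def _divide(a, b):
    return _apply("divide", a, b)


def _power(a, n: int):
    return a if n == 1 else _apply("power", a, _cn(n))


def _math(expr: ET.Element) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(expr)
    return math


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _occupancy_expr(numerator_terms: List[ET.Element],
                    denominator_extra: List[ET.Element]) -> ET.Element:
    num = _plus(*numerator_terms)
    den = _plus(_cn(1), *(numerator_terms_copy(numerator_terms) + denominator_extra))
    return _divide(num, den)


def numerator_terms_copy(terms: List[ET.Element]) -> List[ET.Element]:
    import copy

    return [copy.deepcopy(t) for t in terms]


def export_sbml(
    spec: ModelSpec,
    subsystem: str = "full",
    initial_state: Optional[GeneState] = None,
) -> str:
    """Serialise a model to an SBML L3V1 document string.

    ``subsystem="tgb"`` omits the PU.1 species and parameters, matching
    the published parameter tables for the Notch-driven subsystem;
    ``"full"`` includes all four genes.  The returned text validates
    with :func:`validate_sbml`.
    """
    if subsystem not in ("full", "tgb"):
        raise ValueError("subsystem must be 'full' or 'tgb'")
    p = spec.params
    rate_law = spec.rate_law
    if len(p.kappa) != rate_law.n_minterms:  # defensive; ModelSpec validates too
        raise ValueError("kappa length does not match the compiled rate law")

    genes = ["T", "G", "B"] if subsystem == "tgb" else list(GENES)
    if initial_state is None:
        initial_state = GeneState(
            *(0.02 * p.ceiling(g) if g != "P" else 0.5 * p.ceiling("P") if p.f[3] > 0 else 0.0
              for g in GENES)
        )

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {
        "id": f"tcell_commitment_{spec.logic.variant_id}",
        "name": f"T-cell commitment GRN, configuration {spec.logic.variant_id}",
    })

    annot = ET.SubElement(model, f"{{{SBML_NS}}}annotation")
    info = ET.SubElement(annot, f"{{{ANNOT_NS}}}tcommit")
    info.set("variant", spec.logic.variant_id)
    info.set("gate", spec.logic.gate)
    info.set("n_T", str(spec.logic.n_T))
    info.set("n_G", str(spec.logic.n_G))
    info.set("rateLaw", rate_law.canonical_string())
    info.set("subsystem", subsystem)

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {
        "id": "cell", "size": "1", "constant": "true", "spatialDimensions": "3",
    })

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for g in genes:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": _SPECIES[g],
            "name": {"T": "TCF-1", "G": "GATA-3", "B": "BCL11B", "P": "PU.1"}[g],
            "compartment": "cell",
            "initialConcentration": repr(float(initial_state[GENES.index(g)])),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false",
            "constant": "false",
        })

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")

    def add_param(pid: str, value: float, constant: bool = True):
        ET.SubElement(params_el, f"{{{SBML_NS}}}parameter", {
            "id": pid, "value": repr(float(value)),
            "constant": "true" if constant else "false",
        })

    add_param("eta1N", p.eta[0])
    add_param("eta2", p.eta[1])
    add_param("eta3", p.eta[2])
    add_param("eta4", p.eta[3])
    add_param("fT", p.f[0])
    add_param("gammaT", p.gamma[0])
    add_param("delta1N", p.delta[0])
    add_param("delta2", p.delta[1])
    add_param("delta3", p.delta[2])
    add_param("fG", p.f[1])
    add_param("gammaG", p.gamma[1])
    for j, kappa in enumerate(p.kappa, start=1):
        add_param(f"kappa{j}", kappa)
    add_param("fB", p.f[2])
    add_param("gammaB", p.gamma[2])
    add_param("alpha", spec.notch.alpha)
    if subsystem == "full":
        for j, rho in enumerate(p.rho, start=1):
            add_param(f"rho{j}", rho)
        add_param("fP", p.f[3])
        add_param("gammaP", p.gamma[3])
        add_param("runxInput", p.runx_input)
    # structural Notch-shape constants
    add_param("notchMax", spec.notch.n_max)
    add_param("notchFloor", spec.notch.floor)
    add_param("tHalf", spec.notch.t_half)
    add_param("notchScale", spec.notch.scale(0.0), constant=False)

    rules = ET.SubElement(model, f"{{{SBML_NS}}}listOfRules")

    # notchScale := (floor + (n_max - floor)/(1 + exp(-(t - tHalf)/alpha))) / n_max
    logistic = _divide(
        _minus(_ci("notchMax"), _ci("notchFloor")),
        _plus(_cn(1), _apply(
            "exp",
            _divide(_minus(_ci("tHalf"), _time()), _ci("alpha")),
        )),
    )
    scale_expr = _divide(_plus(_ci("notchFloor"), logistic), _ci("notchMax"))
    assignment = ET.SubElement(rules, f"{{{SBML_NS}}}assignmentRule",
                               {"variable": "notchScale"})
    assignment.append(_math(scale_expr))

    def production_minus_decay(num_terms, den_extra, f_id, gamma_id, species_id):
        return _minus(
            _times(_ci(f_id), _occupancy_expr(num_terms, den_extra)),
            _times(_ci(gamma_id), _ci(species_id)),
        )

    def rate_rule(species_id: str, expr: ET.Element):
        rr = ET.SubElement(rules, f"{{{SBML_NS}}}rateRule", {"variable": species_id})
        rr.append(_math(expr))

    t_terms = [
        _times(_ci("eta1N"), _ci("notchScale")),
        _times(_ci("eta2"), _ci("TCF1")),
        _times(_ci("eta3"), _ci("GATA3")),
    ]
    t_extra = [_times(_ci("eta4"), _ci("PU1"))] if subsystem == "full" else []
    rate_rule("TCF1", production_minus_decay(t_terms, t_extra, "fT", "gammaT", "TCF1"))

    g_terms = [
        _times(_ci("delta1N"), _ci("notchScale")),
        _times(_ci("delta2"), _ci("TCF1")),
    ]
    g_extra = [_times(_ci("delta3"), _ci("PU1"))] if subsystem == "full" else []
    rate_rule("GATA3", production_minus_decay(g_terms, g_extra, "fG", "gammaG", "GATA3"))

    b_terms = []
    for j, minterm in enumerate(rate_law.minterms, start=1):
        factors = [_ci(f"kappa{j}")]
        for name, expo in minterm.items():
            if name == "Notch":
                factors.append(_ci("notchScale"))
            elif name == "TCF-1":
                factors.append(_power(_ci("TCF1"), expo))
            else:
                factors.append(_power(_ci("GATA3"), expo))
        b_terms.append(_times(*factors))
    rate_rule("BCL11B", production_minus_decay(b_terms, [], "fB", "gammaB", "BCL11B"))

    if subsystem == "full":
        p_terms = [_times(_ci("rho1"), _ci("PU1")), _ci("runxInput")]
        p_extra = [
            _times(_ci("rho2"), _ci("TCF1")),
            _times(_ci("rho3"), _ci("GATA3")),
            _times(_ci("rho4"), _ci("BCL11B")),
        ]
        rate_rule("PU1", production_minus_decay(p_terms, p_extra, "fP", "gammaP", "PU1"))

    ET.indent(sbml)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        sbml, encoding="unicode"
    )


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------


def import_sbml(document: str) -> ModelSpec:
    """Reconstruct a :class:`ModelSpec` from a document written by
    :func:`export_sbml`."""
    rootel = ET.fromstring(document)
    model = rootel.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError("document has no <model> element")
    info = model.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}tcommit")
    if info is None:
        raise ValueError("document lacks the tcommit annotation with the logic variant")
    config = get_configuration(info.get("variant"))
    subsystem = info.get("subsystem", "full")

    values: Dict[str, float] = {}
    for el in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        values[el.get("id")] = float(el.get("value"))

    n_kappa = len([k for k in values if k.startswith("kappa")])
    kappa = tuple(values[f"kappa{j}"] for j in range(1, n_kappa + 1))
    if subsystem == "full":
        rho = tuple(values[f"rho{j}"] for j in range(1, 5))
        f_P, gamma_P = values["fP"], values["gammaP"]
        runx = values.get("runxInput", 0.0)
    else:
        rho, f_P, gamma_P, runx = (0.0,) * 4, 0.0, 1.0, 0.0
    params = ModelParameters(
        eta=(values["eta1N"], values["eta2"], values["eta3"], values["eta4"]),
        delta=(values["delta1N"], values["delta2"], values["delta3"]),
        kappa=kappa,
        f=(values["fT"], values["fG"], values["fB"], f_P),
        gamma=(values["gammaT"], values["gammaG"], values["gammaB"], gamma_P),
        rho=rho,
        runx_input=runx,
    )
    notch = NotchSignal(
        n_max=values["notchMax"], alpha=values["alpha"],
        t_half=values["tHalf"], floor=values["notchFloor"],
    )
    return ModelSpec(logic=config, params=params, notch=notch)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def fitted_parameter_ids(document: str) -> List[str]:
    """Ids of the fitted kinetic parameters present in a document.

    Counts the canonical inventory (eta*, delta*, kappa*, f/gamma pairs,
    alpha, and the PU.1 parameters when present), excluding structural
    Notch-shape constants.
    """
    rootel = ET.fromstring(document)
    ids = [
        el.get("id")
        for el in rootel.findall(
            f"{{{SBML_NS}}}model/{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"
        )
    ]
    inventory = set(_TGB_PARAM_IDS) | set(_PU1_PARAM_IDS) | {
        f"kappa{j}" for j in range(1, 4)
    }
    return [i for i in ids if i in inventory]


def _collect_ci_names(math_el: ET.Element) -> List[str]:
    return [
        (el.text or "").strip()
        for el in math_el.iter(f"{{{MATHML_NS}}}ci")
    ]


def validate_sbml(document: str, use_libsbml: bool = True) -> List[str]:
    """Structural validation; returns a list of error strings (empty = valid).

    Checks the SBML L3V1 skeleton: root element and level/version, unique
    ids, species/compartment references, one rate rule per non-boundary
    species, and that every MathML identifier resolves to a declared
    species or parameter.  If the libsbml bindings are importable the
    document is additionally run through their internal consistency
    checks and any errors (severity >= error) are appended.
    """
    errors: List[str] = []
    try:
        rootel = ET.fromstring(document)
    except ET.ParseError as exc:
        return [f"XML parse error: {exc}"]
    if rootel.tag != f"{{{SBML_NS}}}sbml":
        errors.append(f"root element is {rootel.tag}, not sbml (L3V1 namespace)")
        return errors
    if rootel.get("level") != "3" or rootel.get("version") != "1":
        errors.append("level/version attributes are not 3/1")
    model = rootel.find(f"{{{SBML_NS}}}model")
    if model is None:
        return errors + ["missing <model>"]

    comp_ids = {
        el.get("id")
        for el in model.findall(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")
    }
    species = model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    sp_ids = [el.get("id") for el in species]
    param_ids = [
        el.get("id")
        for el in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
    ]
    all_ids = sp_ids + param_ids + list(comp_ids)
    dupes = {i for i in all_ids if all_ids.count(i) > 1}
    if dupes:
        errors.append(f"duplicate ids: {sorted(dupes)}")
    for el in species:
        if el.get("compartment") not in comp_ids:
            errors.append(f"species {el.get('id')} references unknown compartment")
        for attr in ("constant", "boundaryCondition", "hasOnlySubstanceUnits"):
            if el.get(attr) is None:
                errors.append(f"species {el.get('id')} missing required attribute {attr}")

    known = set(sp_ids) | set(param_ids)
    rate_targets = []
    for rule in model.findall(f"{{{SBML_NS}}}listOfRules/*"):
        var = rule.get("variable")
        tag = rule.tag.split("}")[-1]
        if var not in known:
            errors.append(f"{tag} targets unknown variable {var}")
        if tag == "rateRule":
            rate_targets.append(var)
        math_el = rule.find(f"{{{MATHML_NS}}}math")
        if math_el is None:
            errors.append(f"{tag} for {var} has no MathML body")
            continue
        for name in _collect_ci_names(math_el):
            if name not in known:
                errors.append(f"{tag} for {var} references unknown identifier {name!r}")
    for sid in sp_ids:
        if rate_targets.count(sid) != 1:
            errors.append(f"species {sid} must have exactly one rate rule")

    if use_libsbml and not errors:
        try:
            import libsbml  # optional; not a declared dependency
        except ImportError:
            pass
        else:
            doc = libsbml.readSBMLFromString(document)
            doc.checkInternalConsistency()
            doc.checkConsistency()
            for i in range(doc.getNumErrors()):
                err = doc.getError(i)
                if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                    errors.append(f"libsbml: {err.getMessage().strip()}")
    return errors
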