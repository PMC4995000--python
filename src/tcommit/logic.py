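"""Combinatorial regulatory logic compiled into Shea-Ackers rate laws.

The BCL11B promoter is modelled as integrating three activating inputs --
Notch signalling, TCF-1 and GATA-3 -- through one of eight two-operator
logic gates (AND/OR combinations).  Each of TCF-1 and GATA-3 may act as a
monomer (Hill coefficient 1) or a dimer (Hill coefficient 2), giving
8 x 4 = 32 distinct regulatory configurations.

A gate is compiled to its disjunctive normal form: every OR branch, after
full expansion, becomes one *minterm* (a product of input concentrations
raised to their valencies) carrying its own kinetic weight ``kappa_j``.
The production rate is then the thermodynamic occupancy ratio

    S / (1 + S),    S = sum_j kappa_j * prod_i x_i^{e_ij}

which is bounded in [0, 1) and monotone in every weight and activator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ATOMS",
    "GATE_FORMS",
    "VALENCY_LETTERS",
    "LogicConfig",
    "RateLaw",
    "GateParseError",
    "parse_gate",
    "enumerate_configurations",
    "get_configuration",
    "compile_rate_law",
    "production_ratio",
]

#: Canonical input ordering used everywhere (Notch first, then TCF-1, GATA-3).
ATOMS: Tuple[str, str, str] = ("Notch", "TCF-1", "GATA-3")

#: The eight gate forms over {Notch, TCF-1, GATA-3}, numbered 1..8.
GATE_FORMS: Dict[int, str] = {
    1: "Notch OR TCF-1 OR GATA-3",
    2: "(Notch AND TCF-1) OR GATA-3",
    3: "(Notch AND GATA-3) OR TCF-1",
    4: "Notch OR (TCF-1 AND GATA-3)",
    5: "Notch AND (TCF-1 OR GATA-3)",
    6: "TCF-1 AND (Notch OR GATA-3)",
    7: "GATA-3 AND (Notch OR TCF-1)",
    8: "Notch AND TCF-1 AND GATA-3",
}

#: Valency letters: a..d map to (n_T, n_G) monomer/dimer combinations.
VALENCY_LETTERS: Dict[str, Tuple[int, int]] = {
    "a": (1, 1),
    "b": (1, 2),
    "c": (2, 1),
    "d": (2, 2),
}


class GateParseError(ValueError):
    """Raised when a gate expression cannot be parsed."""


# ---------------------------------------------------------------------------
# Gate parsing: a tiny recursive-descent parser producing a nested-tuple AST
# ("and"|"or", left, right) with atom names at the leaves.
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|AND|OR|Notch|TCF-1|GATA-3", re.IGNORECASE)


def _tokenize(text: str) -> List[str]:
    tokens: List[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        gap = text[pos : m.start()].strip()
        if gap:
            raise GateParseError(f"unexpected token {gap!r} in gate {text!r}")
        tok = m.group(0)
        up = tok.upper()
        if up in ("AND", "OR", "(", ")"):
            tokens.append(up)
        else:
            # normalise atom capitalisation
            for atom in ATOMS:
                if up == atom.upper():
                    tokens.append(atom)
                    break
        pos = m.end()
    tail = text[pos:].strip()
    if tail:
        raise GateParseError(f"unexpected token {tail!r} in gate {text!r}")
    return tokens


def parse_gate(text: str):
    """Parse an AND/OR gate over {Notch, TCF-1, GATA-3} into a tuple AST.

    OR binds loosest, AND tighter; both are left-associative.  Only the
    three named atoms are accepted.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GateParseError("empty gate expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect(tok):
        nonlocal pos
        if peek() != tok:
            raise GateParseError(f"expected {tok!r}, found {peek()!r} in gate {text!r}")
        pos += 1

    def parse_or():
        node = parse_and()
        while peek() == "OR":
            expect("OR")
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_atom()
        while peek() == "AND":
            expect("AND")
            node = ("and", node, parse_atom())
        return node

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok == "(":
            expect("(")
            node = parse_or()
            expect(")")
            return node
        if tok in ATOMS:
            pos += 1
            return tok
        raise GateParseError(f"expected input name or '(', found {tok!r} in gate {text!r}")

    ast = parse_or()
    if pos != len(tokens):
        raise GateParseError(f"trailing tokens {tokens[pos:]} in gate {text!r}")
    return ast


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicConfig:
    """One of the 32 combinatorial variants of BCL11B regulation.

    ``variant_id`` is a label like ``"6d"``: the digit selects the gate
    form (1-8), the letter the valency pair (a-d) of TCF-1 and GATA-3.
    """

    variant_id: str
    gate: str
    n_T: int
    n_G: int

    def __post_init__(self) -> None:
        if self.n_T not in (1, 2) or self.n_G not in (1, 2):
            raise ValueError("Hill coefficients must be 1 (monomer) or 2 (dimer)")

    @property
    def ast(self):
        return parse_gate(self.gate)

    def describe(self) -> str:
        t = "dimer TCF-1" if self.n_T == 2 else "TCF-1"
        g = "dimer GATA-3" if self.n_G == 2 else "GATA-3"
        return self.gate.replace("TCF-1", t).replace("GATA-3", g)


def enumerate_configurations() -> List[LogicConfig]:
    """All 32 configurations, ordered 1a, 1b, ... 8d."""
    configs = []
    for num in sorted(GATE_FORMS):
        for letter in "abcd":
            n_T, n_G = VALENCY_LETTERS[letter]
            configs.append(
                LogicConfig(
                    variant_id=f"{num}{letter}",
                    gate=GATE_FORMS[num],
                    n_T=n_T,
                    n_G=n_G,
                )
            )
    return configs


def get_configuration(variant_id: str) -> LogicConfig:
    """Look up a single configuration by its label (e.g. ``"6d"``)."""
    m = re.fullmatch(r"([1-8])([a-d])", variant_id.strip())
    if not m:
        raise KeyError(
            f"unknown variant {variant_id!r}; expected a digit 1-8 followed by a letter a-d"
        )
    num, letter = int(m.group(1)), m.group(2)
    n_T, n_G = VALENCY_LETTERS[letter]
    return LogicConfig(variant_id=f"{num}{letter}", gate=GATE_FORMS[num], n_T=n_T, n_G=n_G)


# ---------------------------------------------------------------------------
# Rate-law compilation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateLaw:
    """A compiled Shea-Ackers production ratio as weighted minterms.

    ``minterms`` is an ordered tuple; each entry maps input name to its
    integer exponent.  Minterm *j* carries kinetic weight ``kappa_{j+1}``;
    Notch-containing minterms sort first so that ``kappa_1`` always
    multiplies the Notch term where one exists.
    """

    minterms: Tuple[Mapping[str, int], ...]

    @property
    def n_minterms(self) -> int:
        return len(self.minterms)

    def evaluate_numerator(
        self, kappas: Sequence[float], concentrations: Mapping[str, float]
    ) -> float:
        """The unnormalised occupancy sum S = sum_j kappa_j * prod x^e."""
        if len(kappas) != len(self.minterms):
            raise ValueError(
                f"expected {len(self.minterms)} kinetic weights, got {len(kappas)}"
            )
        s = 0.0
        for kappa, minterm in zip(kappas, self.minterms):
            if kappa < 0:
                raise ValueError("kinetic weights must be nonnegative")
            term = kappa
            for name, expo in minterm.items():
                x = concentrations.get(name, 0.0)
                if x < 0:
                    raise ValueError(f"concentration of {name} must be nonnegative")
                term *= x**expo
            s += term
        return s

    def canonical_string(self) -> str:
        """Plain-text form, e.g. ``"k1*N*T^2 + k2*T^2*G^2"``."""
        short = {"Notch": "N", "TCF-1": "T", "GATA-3": "G"}
        parts = []
        for j, minterm in enumerate(self.minterms, start=1):
            factors = [f"k{j}"]
            for name in ATOMS:
                if name in minterm:
                    e = minterm[name]
                    factors.append(short[name] if e == 1 else f"{short[name]}^{e}")
            parts.append("*".join(factors))
        return " + ".join(parts)


def _dnf(ast) -> List[frozenset]:
    """Expand a gate AST into DNF: a list of atom sets (one per OR branch)."""
    if isinstance(ast, str):
        return [frozenset([ast])]
    op, left, right = ast
    ldnf, rdnf = _dnf(left), _dnf(right)
    if op == "or":
        out = ldnf + rdnf
    else:  # and: cross product of branches
        out = [l | r for l in ldnf for r in rdnf]
    # drop exact duplicates, preserving first occurrence
    seen, unique = set(), []
    for term in out:
        if term not in seen:
            seen.add(term)
            unique.append(term)
    return unique


def _minterm_sort_key(atoms: frozenset) -> Tuple[int, ...]:
    # presence tuple over canonical atom order: Notch-containing first,
    # then TCF-1-containing, then GATA-3-only
    return tuple(0 if a in atoms else 1 for a in ATOMS)


def compile_rate_law(config: LogicConfig) -> RateLaw:
    """Compile a configuration's gate into its DNF minterm list.

    Each OR branch (after full expansion) becomes one minterm; the Hill
    exponents of the configuration apply to the TCF-1 and GATA-3 factors,
    never to Notch.
    """
    branches = sorted(_dnf(config.ast), key=_minterm_sort_key)
    exponent_of = {"Notch": 1, "TCF-1": config.n_T, "GATA-3": config.n_G}
    minterms = []
    for atoms in branches:
        if not atoms:
            raise GateParseError("empty minterm in gate expansion")
        minterms.append({a: exponent_of[a] for a in ATOMS if a in atoms})
    return RateLaw(minterms=tuple(minterms))


def production_ratio(
    rate_law: RateLaw,
    kappas: Sequence[float],
    concentrations: Mapping[str, float],
) -> float:
    """Thermodynamic occupancy S/(1+S) of the compiled promoter, in [0, 1)."""
    s = rate_law.evaluate_numerator(kappas, concentrations)
    saturated = math.nextafter(1.0, 0.0)  # strictly < 1 even when S overflows
    if not math.isfinite(s):
        return saturated
    return min(s / (1.0 + s), saturated)
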