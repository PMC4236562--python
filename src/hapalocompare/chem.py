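"""Molecular-formula mass utilities.

Small helpers for verifying a proposed intermediate against high
resolution mass spectrometry: parse a Hill-notation formula, compute the
neutral monoisotopic mass (sum of most-abundant-isotope masses, no
electron correction), the integer nominal m/z of simple adducts, and the
parts-per-million deviation between observed and expected masses.

The pathway's early intermediate, the indole-isonitrile
3-(2-isocyanovinyl)indole, is C11H8N2: monoisotopic 168.0687 Da, nominal
[M-H] m/z 167.
"""

from __future__ import annotations

import re

#: Monoisotopic masses of the most abundant isotope (Da), CODATA/AME2020.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
    "Cl": 34.96885268,
}

#: Integer nominal isotope numbers.
NOMINAL = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "P": 31, "Cl": 35}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

Formula = dict[str, int]


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation molecular formula into element counts.

    Implicit count 1 is supported (``"H2O"`` → ``{"H": 2, "O": 1}``).
    Elements outside the embedded mass table are an error.
    """
    counts: Formula = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos + 1}")
        pos = m.end()
        element, num = m.group(1), m.group(2)
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos + 1}")
    return counts


def monoisotopic_mass(f: Formula | str) -> float:
    """Neutral monoisotopic mass in Da, reported to 4 decimals."""
    if isinstance(f, str):
        f = parse_formula(f)
    return round(sum(MONOISOTOPIC[el] * n for el, n in f.items()), 4)


def _apply_adduct(f: Formula, adduct: str) -> Formula:
    out = dict(f)
    if adduct == "M":
        return out
    if adduct in {"M-H", "M+H"}:
        delta = -1 if adduct == "M-H" else 1
        have = out.get("H", 0) + delta
        if have < 0:
            raise ValueError(f"adduct {adduct} removes an absent H from {f}")
        if have == 0:
            out.pop("H", None)
        else:
            out["H"] = have
        return out
    raise ValueError(f"unknown adduct {adduct!r}")


def nominal_ion_mz(f: Formula | str, adduct: str = "M") -> int:
    """Integer nominal m/z of the adduct-adjusted composition.

    ``"M-H"`` subtracts one hydrogen, ``"M+H"`` adds one; charge is taken
    as one so m/z equals the nominal mass.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    adj = _apply_adduct(f, adduct)
    return sum(NOMINAL[el] * n for el, n in adj.items())


def ppm_difference(observed: float, expected: float) -> float:
    """|observed - expected| / expected, in parts per million."""
    if expected <= 0:
        raise ValueError("expected mass must be positive")
    return 1e6 * abs(observed - expected) / expected
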