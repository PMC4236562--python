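"""PROSITE-style degenerate motif scanning.

The cluster comparison uses short degenerate motifs as functional
evidence: the FAD-binding motif GxGxxG and tryptophan-binding motif
WxWxIP of flavin-dependent halogenases, the Mg-dependent prenyl
diphosphate binding motif (N/D)DxxD (whose *absence* from the P1
prenyltransferases is itself evidence), and the [2Fe-2S] Rieske motif
CxH-x(15,17)-CxxH of Rieske-type oxygenases.

Patterns use PROSITE-like syntax: ``x`` matches any residue, ``[..]``
lists alternatives, ``x(m,n)`` repeats bounded; elements may be separated
by dashes.  Matching is case-insensitive; an ``X`` (unknown residue) in
the protein never satisfies a literal, so low-quality translations do not
produce spurious motif calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_ELEMENT_RE = re.compile(
    r"""
    (?P<any>x)
    | \[(?P<alts>[A-Za-z]+)\]
    | (?P<lit>[A-WYZa-wyz])
    """,
    re.VERBOSE,
)
_REP_RE = re.compile(r"\((?P<m>\d+)(?:,(?P<n>\d+))?\)")


class PatternSyntaxError(ValueError):
    """Raised when a PROSITE-style pattern cannot be compiled."""


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate motif with its compiled matcher."""

    name: str
    pattern: str
    regex: re.Pattern

    def __repr__(self) -> str:  # regex object is noise
        return f"MotifPattern(name={self.name!r}, pattern={self.pattern!r})"


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: 1-based start residue and the matched span."""

    protein_id: str
    motif_name: str
    start: int
    matched_subsequence: str


def compile_pattern(prosite: str, name: str = "") -> MotifPattern:
    """Compile a PROSITE-style pattern into a matcher.

    Supports ``x`` (any residue), literal residues, ``[...]``
    alternatives, and ``x(m,n)`` / element``(m)`` bounded repetition.
    Unknown residues (``X``) in the scanned protein never match a literal
    or an alternative set; only the wildcard ``x`` accepts them.
    """
    pos = 0
    parts: list[str] = []
    text = prosite.strip()
    while pos < len(text):
        ch = text[pos]
        if ch in "- ":
            pos += 1
            continue
        m = _ELEMENT_RE.match(text, pos)
        if not m:
            raise PatternSyntaxError(
                f"cannot parse pattern {prosite!r} at position {pos + 1}"
            )
        pos = m.end()
        if m.group("any"):
            atom = "."
        elif m.group("alts"):
            atom = f"[{m.group('alts').upper()}]"
        else:
            atom = m.group("lit").upper()
        rep = _REP_RE.match(text, pos)
        if rep:
            lo = int(rep.group("m"))
            hi = int(rep.group("n")) if rep.group("n") else lo
            if lo > hi:
                raise PatternSyntaxError(
                    f"repetition bounds ({lo},{hi}) invalid at position "
                    f"{pos + 1} of {prosite!r}: m > n"
                )
            # leftmost-shortest for variable repeats
            atom = f"{atom}{{{lo},{hi}}}?" if lo != hi else f"{atom}{{{lo}}}"
            pos = rep.end()
        parts.append(atom)
    if not parts:
        raise PatternSyntaxError(f"empty pattern {prosite!r}")
    try:
        regex = re.compile("".join(parts))
    except re.error as exc:  # pragma: no cover
        raise PatternSyntaxError(f"pattern {prosite!r}: {exc}") from exc
    return MotifPattern(name=name or prosite, pattern=prosite, regex=regex)


def scan(protein: str, pattern: MotifPattern, protein_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences in a protein.

    Scans every start position; variable repeats match leftmost-shortest.
    An empty list means the motif is absent — for the (N/D)DxxD prenyl
    diphosphate motif that absence is the reported evidence.
    """
    seq = protein.upper()
    hits: list[MotifHit] = []
    for start in range(len(seq)):
        m = pattern.regex.match(seq, start)
        if m and "X" not in _literal_positions(pattern, m):
            hits.append(
                MotifHit(
                    protein_id=protein_id,
                    motif_name=pattern.name,
                    start=start + 1,
                    matched_subsequence=m.group(0),
                )
            )
    return hits


def _literal_positions(pattern: MotifPattern, match: re.Match) -> str:
    # Characters of the match that must satisfy a literal/alternative:
    # re-run the regex against the matched text with X's masked; if the
    # masked text no longer matches, an X sat on a constrained position.
    text = match.group(0)
    if "X" not in text:
        return ""
    # replace X with a character outside the amino-acid alphabet ('1');
    # wildcard '.' still matches it, literals and classes do not.
    masked = text.replace("X", "1")
    return "" if pattern.regex.fullmatch(masked) else "X"


DEFAULT_MOTIFS: dict[str, str] = {
    "FAD_binding": "G-x-G-x-x-G",
    "Trp_binding": "W-x-W-x-I-P",
    "prenyl_PP": "[ND]-D-x-x-D",
    "Rieske_2Fe2S": "C-x-H-x(15,17)-C-x-x-H",
}


def builtin_motifs(extra: dict[str, str] | None = None) -> list[MotifPattern]:
    """The default motif library, optionally extended with user patterns.

    Contains the FAD-binding (GxGxxG), tryptophan-binding (WxWxIP),
    Mg-dependent prenyl diphosphate binding ((N/D)DxxD) and Rieske
    [2Fe-2S] (CxH-x(15,17)-CxxH) motifs.  ``extra`` maps name -> pattern.
    The isonitrile-synthase core motifs are not machine-readable from any
    published source and are left to the user-supplied set.
    """
    library = dict(DEFAULT_MOTIFS)
    if extra:
        library.update(extra)
    return [compile_pattern(p, name=n) for n, p in library.items()]


def scan_all(
    proteins: dict[str, str], patterns: list[MotifPattern]
) -> list[MotifHit]:
    """Scan every protein against every pattern."""
    hits: list[MotifHit] = []
    for pid, seq in proteins.items():
        for pat in patterns:
            hits.extend(scan(seq, pat, protein_id=pid))
    return hits


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmotif\tstart\tmatch\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.motif_name}\t{h.start}\t"
                     f"{h.matched_subsequence}\n")
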