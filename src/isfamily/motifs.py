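"""Catalytic-domain motif logic for DDE transposases.

The catalytic triad is two aspartates and a glutamate, written DD(n)E where
n counts the residues between the second D and the E (34 for the reference
transposase, 33 or other values in particular clades).  Downstream of the E,
family-diagnostic signatures are scanned with single-residue wildcards:

* bacterial E-DH---K : E, x, D, H, x, x, x, K
* bacterial E-SH---R : E, x, S, H, x, x, x, R
* archaeal  E--F---K-R : E, x, x, F, x, x, x, K, x, R

All positions reported by this module are 1-based on the protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence


class MotifError(ValueError):
    pass


class TriadNotFound(LookupError):
    """Raised by locate_triad; ``reason`` is missing_E / missing_D2 / missing_D1."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass(frozen=True)
class SignaturePattern:
    """Anchored residue constraints: (offset from the anchoring E, allowed set)."""

    name: str
    constraints: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.constraints]
        if any(o <= 0 for o in offsets) or sorted(offsets) != offsets or len(set(offsets)) != len(offsets):
            raise MotifError("constraint offsets must be strictly increasing and positive")

    @property
    def reach(self) -> int:
        return max(o for o, _ in self.constraints)


def _pat(name: str, spec: dict[int, str]) -> SignaturePattern:
    return SignaturePattern(name, tuple((o, frozenset(spec[o])) for o in sorted(spec)))


BACTERIAL_DHK = _pat("bacterial_DHK", {2: "D", 3: "H", 7: "K"})
BACTERIAL_SHR = _pat("bacterial_SHR", {2: "S", 3: "H", 7: "R"})
ARCHAEAL_FKR = _pat("archaeal_FKR", {3: "F", 7: "K", 9: "R"})

BUILTIN_PATTERNS = {p.name: p for p in (BACTERIAL_DHK, BACTERIAL_SHR, ARCHAEAL_FKR)}


def scan_signature(protein: str, pattern: SignaturePattern) -> list[int]:
    """1-based positions p with protein[p] = E satisfying every constraint.

    Anchors whose pattern would run past the C-terminus are not reported.
    """
    if "-" in protein:
        raise MotifError("protein must be ungapped")
    hits = []
    n = len(protein)
    for p in range(1, n + 1):
        if protein[p - 1] != "E":
            continue
        if p + pattern.reach > n:
            continue
        if all(protein[p + off - 1] in allowed for off, allowed in pattern.constraints):
            hits.append(p)
    return hits


@dataclass(frozen=True)
class TriadLocation:
    """1-based D1, D2, E positions plus the matched signature name."""

    d1: int
    d2: int
    e: int
    signature: str

    def __post_init__(self) -> None:
        if not self.d1 < self.d2 < self.e:
            raise MotifError("triad positions must satisfy D1 < D2 < E")

    @property
    def spacing(self) -> int:
        """Residues between D2 and E: the n of DD(n)E."""
        return self.e - self.d2 - 1


def dde_spacing(triad: TriadLocation) -> int:
    return triad.spacing


def locate_triad(protein: str,
                 patterns: Optional[Sequence[SignaturePattern]] = None,
                 d2_window: tuple[int, int] = (25, 45),
                 d1_window: tuple[int, int] = (50, 130)) -> TriadLocation:
    """Locate the DDE triad anchored on a signature-matching E.

    The anchoring E is the first signature match in the C-terminal half of
    the protein (patterns tried in the given precedence order at each
    position).  D2 is the D nearest to E with E - D2 in ``d2_window``; D1 is
    a D with D2 - D1 in ``d1_window``, preferring one immediately followed by
    E (the conserved D-E(T) feature), otherwise the candidate nearest D2.

    Raises TriadNotFound with reason missing_E, missing_D2 or missing_D1.
    """
    if "-" in protein:
        raise MotifError("protein must be ungapped")
    if patterns is None:
        patterns = (BACTERIAL_DHK, BACTERIAL_SHR, ARCHAEAL_FKR)
    n = len(protein)
    half_start = n // 2 + 1
    anchor = None
    matched = None
    for p in range(half_start, n + 1):
        if protein[p - 1] != "E":
            continue
        for pat in patterns:
            if p + pat.reach <= n and all(
                    protein[p + off - 1] in allowed for off, allowed in pat.constraints):
                anchor, matched = p, pat.name
                break
        if anchor is not None:
            break
    if anchor is None:
        raise TriadNotFound("missing_E", "no signature-anchored E in the C-terminal half")
    lo = max(1, anchor - d2_window[1])
    hi = anchor - d2_window[0]
    d2_candidates = [q for q in range(hi, lo - 1, -1) if 1 <= q and protein[q - 1] == "D"]
    if not d2_candidates:
        raise TriadNotFound("missing_D2",
                            f"no D within {d2_window} residues upstream of E at {anchor}")
    d2 = d2_candidates[0]  # nearest to E
    lo1 = max(1, d2 - d1_window[1])
    hi1 = d2 - d1_window[0]
    d1_candidates = [q for q in range(hi1, lo1 - 1, -1) if 1 <= q and protein[q - 1] == "D"]
    if not d1_candidates:
        raise TriadNotFound("missing_D1",
                            f"no D within {d1_window} residues upstream of D2 at {d2}")
    preferred = [q for q in d1_candidates if q < n and protein[q] == "E"]
    d1 = preferred[0] if preferred else d1_candidates[0]
    return TriadLocation(d1, d2, anchor, matched)


def nterm_fy_scan(protein: str, window: int = 15) -> Optional[tuple[int, int]]:
    """First (p, p+5) pair in the N-terminal window with F at p and F/Y at
    p+5 (four residues between the planar pair); None when absent."""
    if "-" in protein:
        raise MotifError("protein must be ungapped")
    for p in range(1, min(window, len(protein) - 5) + 1):
        if protein[p - 1] == "F" and protein[p + 4] in "FY":
            return (p, p + 5)
    return None


def signature_census(proteins: Iterable[tuple[str, str]],
                     patterns: Optional[Sequence[SignaturePattern]] = None
                     ) -> dict[str, object]:
    """Count proteins carrying each signature, with first-match precedence.

    ``proteins`` yields (name, sequence) pairs; records (and RecordSet
    objects) may be passed instead, in which case the translated transposase
    is scanned.  A protein is assigned to the first pattern (in precedence
    order, default DHK > SHR > archaeal FKR) with at least one anchor, so the
    per-pattern classes are disjoint.
    """
    if patterns is None:
        patterns = (BACTERIAL_DHK, BACTERIAL_SHR, ARCHAEAL_FKR)
    counts = {pat.name: 0 for pat in patterns}
    assignment: dict[str, Optional[str]] = {}
    for item in proteins:
        if isinstance(item, tuple):
            name, seq = item
        else:
            name, seq = item.name, item.tnp
        assigned = None
        for pat in patterns:
            if scan_signature(seq, pat):
                assigned = pat.name
                break
        if assigned:
            counts[assigned] += 1
        assignment[name] = assigned
    return {"counts": counts, "assignment": assignment}
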