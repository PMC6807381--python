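"""Pairwise and progressive alignment with affine gap costs.

Alignment parameters follow the family analysis convention: BLOSUM62 for
transposase (amino-acid) comparisons, +5/-4 for nucleotides, gap open 10 and
gap extend 0.1, where a gap run of length L costs ``open + extend * (L - 1)``.
The dynamic program is the three-state Gotoh algorithm; traceback ties are
broken deterministically (diagonal, then up, then left).

Percent identity excludes terminal-overhang gap columns from the denominator
(internal gap columns still count); percent similarity additionally counts
columns whose residue pair scores > 0 in the substitution matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

NEG = -1e30  # effectively -infinity, safe under addition
_TOL = 1e-6


class AlignmentError(ValueError):
    pass


@lru_cache(maxsize=None)
def _blosum62() -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    return alphabet, np.asarray(mat, dtype=float)


@dataclass(frozen=True)
class AlignParams:
    """Substitution model plus affine gap costs (both costs are positive)."""

    matrix: Literal["blosum62", "nt"] = "blosum62"
    gap_open: float = 10.0
    gap_extend: float = 0.1
    nt_match: float = 5.0
    nt_mismatch: float = -4.0

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    @classmethod
    def protein(cls, **kw) -> "AlignParams":
        return cls(matrix="blosum62", **kw)

    @classmethod
    def nucleotide(cls, **kw) -> "AlignParams":
        return cls(matrix="nt", **kw)

    def alphabet_and_scores(self) -> tuple[str, np.ndarray]:
        """Alphabet string and square score matrix over it."""
        if self.matrix == "blosum62":
            return _blosum62()
        alphabet = "ACGTN"
        m = np.full((5, 5), self.nt_mismatch)
        np.fill_diagonal(m, self.nt_match)
        # N never matches anything, itself included
        m[4, :] = self.nt_mismatch
        m[:, 4] = self.nt_mismatch
        return alphabet, m


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lookup = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lookup[ord(c)] = i
    idx = lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(idx < 0)[0]})
        raise AlignmentError(f"characters {bad} not in alignment alphabet {alphabet!r}")
    return idx


def _gotoh_fill(S: np.ndarray, open_: float, ext: float):
    """Fill Gotoh matrices for a pairwise score matrix S (n x m).

    State M consumes one symbol from each side, Ix consumes a row symbol
    against a gap ("up"), Iy consumes a column symbol against a gap ("left").
    All inter-state transitions are allowed; a new gap run always pays
    ``open_`` and each continuation pays ``ext``.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = -(open_ + ext * np.arange(m))
    ext_ramp = ext * np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        Ix[i] = np.maximum(np.maximum(M[i - 1], Iy[i - 1]) - open_, Ix[i - 1] - ext)
        b = np.maximum(M[i], Ix[i]) - open_ + ext_ramp
        Iy[i, 1:] = np.maximum.accumulate(b)[:-1] - ext_ramp[1:] + ext
        Iy[i, 0] = NEG
    return M, Ix, Iy


def _gotoh_traceback(M, Ix, Iy, S, open_, ext):
    """Deterministic traceback; returns list of ops 'D' (diag), 'U', 'L'."""
    i, j = M.shape[0] - 1, M.shape[1] - 1
    finals = (M[i, j], Ix[i, j], Iy[i, j])
    best = max(finals)
    state = ("M", "Ix", "Iy")[[k for k in range(3) if finals[k] >= best - _TOL][0]]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            cands = (M[i, j], Ix[i, j], Iy[i, j])
        elif state == "Ix":
            ops.append("U")
            target = Ix[i, j]
            i = i - 1
            cands = (M[i, j] - open_, Ix[i, j] - ext, Iy[i, j] - open_)
        else:
            ops.append("L")
            target = Iy[i, j]
            j = j - 1
            cands = (M[i, j] - open_, Ix[i, j] - open_, Iy[i, j] - ext)
        if i == 0 and j == 0:
            break
        for k, name in enumerate(("M", "Ix", "Iy")):
            if cands[k] >= target - _TOL:
                state = name
                break
        else:  # pragma: no cover - would indicate a DP fill bug
            raise RuntimeError("traceback lost the optimal path")
    ops.reverse()
    return ops


@dataclass
class PairAlignment:
    """A scored global alignment of two ungapped input sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams
    identity_pct: float = field(init=False)
    similarity_pct: float = field(init=False)

    def __post_init__(self) -> None:
        # NaN when the optimal alignment has no aligned core columns (only
        # possible for short, unrelated inputs); the explicit percent_*
        # functions treat that zero denominator as an error.
        try:
            self.identity_pct = percent_identity(self)
            self.similarity_pct = percent_similarity(self)
        except AlignmentError:
            self.identity_pct = float("nan")
            self.similarity_pct = float("nan")

    def __len__(self) -> int:
        return len(self.aligned_a)


def global_align(a: str, b: str, params: Optional[AlignParams] = None) -> PairAlignment:
    """Optimal Needleman-Wunsch/Gotoh global alignment of two sequences."""
    if params is None:
        params = AlignParams()
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    if "-" in a or "-" in b:
        raise AlignmentError("inputs must be ungapped")
    alphabet, scores = params.alphabet_and_scores()
    ia, ib = _encode(a, alphabet), _encode(b, alphabet)
    S = scores[np.ix_(ia, ib)]
    M, Ix, Iy = _gotoh_fill(S, params.gap_open, params.gap_extend)
    score = float(max(M[-1, -1], Ix[-1, -1], Iy[-1, -1]))
    ops = _gotoh_traceback(M, Ix, Iy, S, params.gap_open, params.gap_extend)
    ra, rb, i, j = [], [], 0, 0
    for op in ops:
        if op == "D":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == "U":
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    assert i == len(a) and j == len(b)
    return PairAlignment("".join(ra), "".join(rb), score, params)


def _core_columns(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """Column range [start, stop) excluding terminal-overhang gap columns."""
    n = len(aligned_a)
    start, stop = 0, n
    while start < n and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    while stop > start and (aligned_a[stop - 1] == "-" or aligned_b[stop - 1] == "-"):
        stop -= 1
    return start, stop


def percent_identity(pair: PairAlignment) -> float:
    """Identical columns / columns, excluding terminal overhangs."""
    start, stop = _core_columns(pair.aligned_a, pair.aligned_b)
    if stop <= start:
        raise AlignmentError("alignment has no aligned core columns")
    a, b = pair.aligned_a[start:stop], pair.aligned_b[start:stop]
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-" and x != "N")
    return 100.0 * ident / (stop - start)


def percent_similarity(pair: PairAlignment) -> float:
    """Like identity but a column also counts when its pair scores > 0."""
    start, stop = _core_columns(pair.aligned_a, pair.aligned_b)
    if stop <= start:
        raise AlignmentError("alignment has no aligned core columns")
    alphabet, scores = pair.params.alphabet_and_scores()
    idx = {c: i for i, c in enumerate(alphabet)}
    sim = 0
    for x, y in zip(pair.aligned_a[start:stop], pair.aligned_b[start:stop]):
        if x == "-" or y == "-":
            continue
        if x == "N" or y == "N":
            continue
        if x == y or scores[idx[x], idx[y]] > 0:
            sim += 1
    return 100.0 * sim / (stop - start)


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percentage matrix with its provenance parameters."""

    values: pd.DataFrame
    level: Literal["nt", "aa"]
    stat: Literal["identity", "similarity"]
    params: AlignParams

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.values.loc[pair[0], pair[1]])

    @property
    def names(self) -> list[str]:
        return list(self.values.index)


def identity_matrix(records, level: Literal["nt", "aa"] = "nt",
                    params: Optional[AlignParams] = None,
                    stat: Optional[str] = None) -> IdentityMatrix:
    """All-against-all percentages from independent pairwise alignments.

    ``records`` is a RecordSet or a sequence of (name, sequence) pairs.  At
    the nucleotide level the reported statistic defaults to identity, at the
    amino-acid level to BLOSUM62-positive similarity (the pair of statistics
    the ISFinder isoform rule combines).
    """
    named = _as_named_sequences(records, level)
    if len(named) < 2:
        raise AlignmentError("need at least 2 records")
    names = [n for n, _ in named]
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate record names")
    if params is None:
        params = AlignParams.nucleotide() if level == "nt" else AlignParams.protein()
    if stat is None:
        stat = "identity" if level == "nt" else "similarity"
    n = len(named)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(named[i][1], named[j][1], params)
            v = pair.identity_pct if stat == "identity" else pair.similarity_pct
            vals[i, j] = vals[j, i] = v
    df = pd.DataFrame(vals, index=names, columns=names)
    return IdentityMatrix(df, level, stat, params)


def _as_named_sequences(records, level: str) -> list[tuple[str, str]]:
    out = []
    for r in records:
        if isinstance(r, tuple):
            out.append((r[0], r[1]))
        else:
            out.append((r.name, r.sequence if level == "nt" else r.tnp))
    return out


# ---------------------------------------------------------------------------
# progressive multiple alignment


@dataclass
class MSA:
    """Named gapped rows of equal length."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("MSA rows differ in length")
        if len(self.names) != len(self.rows):
            raise AlignmentError("names/rows length mismatch")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def degapped(self, name: str) -> str:
        return self.row(name).replace("-", "")


def _profile_freqs(rows: Sequence[str], alphabet: str) -> np.ndarray:
    """Per-column non-gap residue frequencies, rows weighted equally."""
    L = len(rows[0])
    F = np.zeros((L, len(alphabet)))
    idx = {c: i for i, c in enumerate(alphabet)}
    for row in rows:
        for pos, c in enumerate(row):
            if c != "-":
                F[pos, idx[c]] += 1.0
    return F / len(rows)


def _align_profiles(rows_a: Sequence[str], rows_b: Sequence[str],
                    params: AlignParams) -> tuple[list[str], list[str]]:
    """Affine profile-profile alignment with column-average scores."""
    alphabet, scores = params.alphabet_and_scores()
    Fa = _profile_freqs(rows_a, alphabet)
    Fb = _profile_freqs(rows_b, alphabet)
    S = Fa @ scores @ Fb.T
    M, Ix, Iy = _gotoh_fill(S, params.gap_open, params.gap_extend)
    ops = _gotoh_traceback(M, Ix, Iy, S, params.gap_open, params.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        take_a = op in ("D", "U")
        take_b = op in ("D", "L")
        for k, row in enumerate(rows_a):
            out_a[k].append(row[i] if take_a else "-")
        for k, row in enumerate(rows_b):
            out_b[k].append(row[j] if take_b else "-")
        i += take_a
        j += take_b
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(records, params: Optional[AlignParams] = None,
                    level: Literal["nt", "aa"] = "aa") -> MSA:
    """Guide-tree progressive alignment.

    The guide tree is neighbour joining on (100 - identity)/100 pairwise
    distances from independent global alignments; profiles are merged in
    post-order with profile-profile affine alignment using column-average
    substitution scores.  Output row order equals input order.
    """
    named = _as_named_sequences(records, level)
    if len(named) < 2:
        raise AlignmentError("need at least 2 sequences")
    if params is None:
        params = AlignParams.nucleotide() if level == "nt" else AlignParams.protein()
    if len(named) == 2:
        pair = global_align(named[0][1], named[1][1], params)
        msa = MSA([named[0][0], named[1][0]], [pair.aligned_a, pair.aligned_b])
        return msa
    from isfamily.phylogeny import nj  # deferred: phylogeny does not import us

    idm = identity_matrix(named, level="nt" if params.matrix == "nt" else "aa",
                          params=params, stat="identity")
    dist = (100.0 - idm.values) / 100.0
    np.fill_diagonal(dist.values, 0.0)
    guide = nj(dist)
    seq_by_name = dict(named)
    merged: dict[int, tuple[list[str], list[str]]] = {}
    for node in guide.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            merged[id(node)] = ([name], [seq_by_name[name]])
        else:
            children = [merged[id(c)] for c in node.child_nodes()]
            names, rows = children[0]
            for more_names, more_rows in children[1:]:
                rows, other = _align_profiles(rows, more_rows, params)
                rows = rows + other
                names = names + more_names
            merged[id(node)] = (names, rows)
    names, rows = merged[id(guide.seed_node)]
    order = {n: i for i, n in enumerate(names)}
    msa_rows = [rows[order[n]] for n, _ in named]
    msa = MSA([n for n, _ in named], msa_rows)
    for (name, seq), row in zip(named, msa.rows):
        assert row.replace("-", "") == seq, f"row for {name} does not de-gap to input"
    return msa


# ---------------------------------------------------------------------------
# column conservation


CONS_CLASSES = ("100", "80-99", "60-79", "below")


@dataclass
class ConservationProfile:
    """Per-column conservation classes and all-but-k flags for an MSA."""

    classes: list[str]
    majority: list[str]
    majority_count: list[int]
    similar_fraction: list[float]
    n_rows: int
    k: int
    conserved_all_but_k: list[bool] = field(init=False)

    def __post_init__(self) -> None:
        self.conserved_all_but_k = self.flags(self.k)

    def flags(self, k: int) -> list[bool]:
        """conserved_all_but_k: majority residue in >= n_rows - k rows."""
        return [c >= self.n_rows - k for c in self.majority_count]


def conservation(msa: MSA, params: Optional[AlignParams] = None, k: int = 3) -> ConservationProfile:
    """Classify each MSA column by its similarity fraction.

    The majority residue is the plurality residue over non-gap rows
    (alphabetical tie-break); the similarity fraction counts rows whose
    residue is identical to it or scores > 0 against it.  Classes follow the
    shading convention 100 / 80-99 / 60-79 / below.  The all-but-k flag uses
    exact residue counts over all rows (a gap row counts as a difference).
    """
    if len(msa) < 2:
        raise AlignmentError("need an MSA with at least 2 rows")
    if params is None:
        params = AlignParams.protein()
    alphabet, scores = params.alphabet_and_scores()
    idx = {c: i for i, c in enumerate(alphabet)}
    classes, majors, counts, fracs = [], [], [], []
    for col in range(msa.n_columns):
        residues = [row[col] for row in msa.rows if row[col] != "-"]
        if not residues:
            classes.append("below"); majors.append("-"); counts.append(0); fracs.append(0.0)
            continue
        tally: dict[str, int] = {}
        for c in residues:
            tally[c] = tally.get(c, 0) + 1
        top = max(tally.values())
        maj = min(c for c, v in tally.items() if v == top)
        sim = sum(1 for c in residues if c == maj or scores[idx[c], idx[maj]] > 0)
        frac = sim / len(residues)
        if frac >= 1.0:
            cls = "100"
        elif frac >= 0.8:
            cls = "80-99"
        elif frac >= 0.6:
            cls = "60-79"
        else:
            cls = "below"
        classes.append(cls)
        majors.append(maj)
        counts.append(tally[maj])
        fracs.append(frac)
    return ConservationProfile(classes, majors, counts, fracs, len(msa), k)
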