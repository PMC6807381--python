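"""Terminal inverted repeat (TIR) extraction, consensus and end redefinition.

Both ends of an element are read outer-to-inner: the left end as the first k
bases, the right end as the reverse complement of the last k bases.  Pooled
over a family, per-position base counts yield a consensus with conservation
flags; the family analysis convention is a 20 bp window capturing a 14 bp
(short bacterial) or 18 bp (long/archaeal) consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from isfamily.records_io import ISRecord, reverse_complement

BASES = "ACGT"


class TIRError(ValueError):
    pass


@dataclass
class TIREndPair:
    """Outer k bases of both ends of one element, both read outer->inner."""

    name: str
    left: str
    right_rc: str

    @property
    def k(self) -> int:
        return len(self.left)


def extract_ends(record, k: int = 20) -> TIREndPair:
    """First k bases and reverse complement of the last k bases."""
    if isinstance(record, ISRecord):
        name, seq = record.name, record.sequence
    else:
        name, seq = record
    if k < 1 or 2 * k > len(seq):
        raise TIRError(f"{name}: window k={k} exceeds half the sequence length {len(seq)}")
    return TIREndPair(name, seq[:k], reverse_complement(seq[-k:]))


@dataclass
class TIRConsensusProfile:
    """Per-position base counts over pooled ends, with consensus and flags.

    Position 1 is the outermost base.  ``conserved_all`` marks positions where
    a single base occupies every pooled end; ``conserved_all_but_1`` allows
    one deviation.  Plurality ties are broken alphabetically and flagged.
    """

    counts: pd.DataFrame            # index 1..k, columns A C G T
    n_ends: int
    consensus: str = field(init=False)
    conserved_all: list[bool] = field(init=False)
    conserved_all_but_1: list[bool] = field(init=False)
    ambiguous: list[bool] = field(init=False)

    def __post_init__(self) -> None:
        cons, amb, call, call1 = [], [], [], []
        for _, row in self.counts.iterrows():
            top = row.max()
            winners = [b for b in BASES if row[b] == top]
            cons.append(winners[0])
            amb.append(len(winners) > 1)
            total = int(row.sum())
            call.append(bool(top == total and total == self.n_ends))
            call1.append(bool(top >= self.n_ends - 1))
        self.consensus = "".join(cons)
        self.ambiguous = amb
        self.conserved_all = call
        self.conserved_all_but_1 = call1

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["consensus"] = list(self.consensus)
        df["conserved_all"] = self.conserved_all
        df["conserved_all_but_1"] = self.conserved_all_but_1
        df["ambiguous_plurality"] = self.ambiguous
        return df


def consensus_profile(end_pairs: Sequence[TIREndPair], pool: str = "both") -> TIRConsensusProfile:
    """Position-wise consensus over pooled left and right ends.

    ``pool`` may be "both" (default: left and right_rc pooled into one
    profile), "left" or "right" for per-side profiles.  N bases are excluded
    from the counts at their position.
    """
    if not end_pairs:
        raise TIRError("need at least one end pair")
    k = end_pairs[0].k
    if any(p.k != k for p in end_pairs):
        raise TIRError("end pairs have differing window sizes")
    ends: list[str] = []
    for p in end_pairs:
        if pool in ("both", "left"):
            ends.append(p.left)
        if pool in ("both", "right"):
            ends.append(p.right_rc)
    counts = np.zeros((k, 4), dtype=int)
    for end in ends:
        for pos, base in enumerate(end):
            if base in BASES:
                counts[pos, BASES.index(base)] += 1
    df = pd.DataFrame(counts, index=range(1, k + 1), columns=list(BASES))
    return TIRConsensusProfile(df, n_ends=len(ends))


def perfect_tir_length(record) -> int:
    """Largest k with the first k bases equal to the reverse complement of
    the last k bases; 0 when the termini are not complementary."""
    seq = record.sequence if isinstance(record, ISRecord) else record
    limit = len(seq) // 2
    rc_right = reverse_complement(seq[-limit:]) if limit else ""
    k = 0
    while k < limit and seq[k] == rc_right[k] and seq[k] != "N":
        k += 1
    return k


@dataclass
class EndRedefinition:
    """Candidate one-base end trim produced by redefine_ends."""

    record: Optional[ISRecord]
    trimmed: bool
    rationale: str


def redefine_ends(record: ISRecord) -> EndRedefinition:
    """Candidate single-base end trim for elements that do not begin GG.

    If the left end does not begin with GG, trim exactly one base from each
    end; the candidate is accepted iff the trimmed sequence begins GG and
    ends CC.  The input record is never mutated; a flagged copy (CDS shifted
    one base left) is returned.  Corroborating the trim against additional
    genomic sequence is external evidence outside this function's scope.
    """
    seq = record.sequence
    if seq.startswith("GG"):
        return EndRedefinition(None, False, "ends already begin GG; no candidate")
    trimmed_seq = seq[1:-1]
    if not (trimmed_seq.startswith("GG") and trimmed_seq.endswith("CC")):
        return EndRedefinition(None, False,
                               "one-base trim does not produce GG...CC ends; no candidate")
    # the CDS is interior, so both coordinates shift one base left; the
    # transposase itself is untouched by an end trim, so it is carried over
    new_start = max(0, record.cds_start - 1)
    new_end = min(new_start + (record.cds_end - record.cds_start), len(trimmed_seq))
    trimmed = ISRecord(
        name=record.name,
        sequence=trimmed_seq,
        cds_start=new_start,
        cds_end=new_end,
        strand=record.strand,
        tnp=record.tnp,
        domain_of_life=record.domain_of_life,
        taxon_group=record.taxon_group,
        clade=record.clade,
        accession=record.accession,
        recorded_tir_len=record.recorded_tir_len,
        recorded_tsd_len=record.recorded_tsd_len,
    )
    return EndRedefinition(trimmed, True,
                           "trimmed 1 base at each end; new ends GG...CC")
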