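"""Record validation and isoform collapsing under the ISFinder thresholds.

An IS is excluded when its transposase is truncated, contains an internal
stop, or lacks one of the catalytic DDE residues.  Two ISs are isoforms of
one another when they share >95 % nucleotide identity and/or >98 % amino
acid similarity; because this rule is comparator-relative, the module
supports both comparator mode (status against a named reference) and a
transitive single-linkage mode that yields a proper partition, plus a report
of the pairs whose status flips between two comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from isfamily.motifs import TriadNotFound, locate_triad
from isfamily.records_io import ISRecord, RecordSet

EXCLUSION_REASONS = ("truncated_tnp", "internal_stop", "missing_D1", "missing_D2",
                     "missing_E", "too_short", "ok")


@dataclass(frozen=True)
class CurationPolicy:
    """Isoform thresholds (percent) and transposase-intactness requirements."""

    nt_isoform_threshold: float = 95.0
    aa_isoform_threshold: float = 98.0
    require_intact_tnp: bool = True
    require_triad: bool = True
    min_tnp_len: int = 150

    def __post_init__(self) -> None:
        for th in (self.nt_isoform_threshold, self.aa_isoform_threshold):
            if not 0 < th <= 100:
                raise ValueError("thresholds must lie in (0, 100]")


@dataclass
class ValidationEntry:
    name: str
    status: Literal["pass", "excluded"]
    reason: str
    tnp_len: int


@dataclass
class ValidationReport:
    entries: list[ValidationEntry]

    def passing(self) -> list[str]:
        return [e.name for e in self.entries if e.status == "pass"]

    def excluded(self) -> dict[str, str]:
        return {e.name: e.reason for e in self.entries if e.status == "excluded"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def validate(record: ISRecord, policy: Optional[CurationPolicy] = None,
             triad_locator: Callable = locate_triad) -> ValidationEntry:
    """Classify one record as pass/excluded with the first failing reason.

    Reason precedence is fixed for determinism: transposase length, then
    internal stop, then the triad check (whose locator reports which DDE
    component is missing).  Exclusion is a result, not an error.
    """
    if policy is None:
        policy = CurationPolicy()
    tnp = record.tnp
    if policy.require_intact_tnp:
        if len(tnp.replace("*", "")) < policy.min_tnp_len:
            return ValidationEntry(record.name, "excluded", "truncated_tnp", len(tnp))
        if "*" in tnp:
            return ValidationEntry(record.name, "excluded", "internal_stop", len(tnp))
    if policy.require_triad:
        try:
            triad_locator(tnp)
        except TriadNotFound as miss:
            return ValidationEntry(record.name, "excluded", miss.reason, len(tnp))
    return ValidationEntry(record.name, "pass", "ok", len(tnp))


def validate_set(records: RecordSet, policy: Optional[CurationPolicy] = None,
                 triad_locator: Callable = locate_triad) -> ValidationReport:
    return ValidationReport([validate(r, policy, triad_locator) for r in records])


Combine = Literal["any", "all", "nt", "aa"]


@dataclass
class IsoformGrouping:
    """Result of isoform collapsing.

    ``groups`` partitions the record names.  In comparator mode the group of
    the comparator holds it and everything exceeding a threshold against it;
    all remaining records are singletons.  ``flips`` lists the pairs whose
    isoform status differs between two requested comparators.
    """

    mode: Literal["comparator", "transitive"]
    groups: list[list[str]]
    comparator: Optional[str] = None
    isoforms_of_comparator: list[str] = field(default_factory=list)
    flips: list[tuple[str, bool, bool]] = field(default_factory=list)

    def group_of(self, name: str) -> list[str]:
        for g in self.groups:
            if name in g:
                return g
        raise KeyError(name)

    def pairs(self) -> set[frozenset[str]]:
        """All unordered within-group pairs (the collapsed isoform calls)."""
        out = set()
        for g in self.groups:
            for i, a in enumerate(g):
                for b in g[i + 1:]:
                    out.add(frozenset((a, b)))
        return out


def _isoform_predicate(nt: Optional[pd.DataFrame], aa: Optional[pd.DataFrame],
                       policy: CurationPolicy, combine: Combine) -> np.ndarray:
    """Boolean matrix: pair exceeds the isoform threshold(s)."""
    if combine in ("any", "all") and (nt is None or aa is None):
        raise ValueError(f"combine={combine!r} needs both matrices")
    if combine == "nt" and nt is None or combine == "aa" and aa is None:
        raise ValueError(f"combine={combine!r}: required matrix missing")
    hit_nt = None if nt is None else nt.to_numpy() > policy.nt_isoform_threshold
    hit_aa = None if aa is None else aa.to_numpy() > policy.aa_isoform_threshold
    if combine == "any":
        return hit_nt | hit_aa
    if combine == "all":
        return hit_nt & hit_aa
    return hit_nt if combine == "nt" else hit_aa


def collapse_isoforms(matrix_nt: Optional[pd.DataFrame] = None,
                      matrix_aa: Optional[pd.DataFrame] = None,
                      policy: Optional[CurationPolicy] = None,
                      mode: Literal["comparator", "transitive"] = "transitive",
                      comparator: Optional[str] = None,
                      second_comparator: Optional[str] = None,
                      combine: Combine = "any") -> IsoformGrouping:
    """Collapse isoforms from pairwise percentage matrices.

    ``combine`` selects how the nucleotide-identity and amino-acid-similarity
    criteria are combined: "any" (the ISFinder rule: either threshold marks
    an isoform), "all" (both required), "nt" or "aa" (single criterion).

    Comparator mode flags every record exceeding the predicate against the
    named comparator; with ``second_comparator`` the flips report lists
    records whose status differs between the two references.  Transitive
    mode single-links the same pairwise predicate into a partition that does
    not depend on any chosen reference (or on input order).
    """
    if policy is None:
        policy = CurationPolicy()
    ref = matrix_nt if matrix_nt is not None else matrix_aa
    if ref is None:
        raise ValueError("need at least one matrix")
    names = [str(c) for c in ref.columns]
    for m in (matrix_nt, matrix_aa):
        if m is not None and [str(c) for c in m.columns] != names:
            raise ValueError("matrices are over different name sets")
    pred = _isoform_predicate(matrix_nt, matrix_aa, policy, combine)
    np.fill_diagonal(pred, False)
    idx = {n: i for i, n in enumerate(names)}
    if mode == "comparator":
        if comparator is None:
            raise ValueError("comparator mode requires a comparator name")
        if comparator not in idx:
            raise KeyError(f"comparator {comparator!r} absent from matrices")
        row = pred[idx[comparator]]
        isoforms = [n for n in names if n != comparator and row[idx[n]]]
        groups = [[comparator] + isoforms] + [[n] for n in names
                                              if n != comparator and n not in isoforms]
        flips: list[tuple[str, bool, bool]] = []
        if second_comparator is not None:
            if second_comparator not in idx:
                raise KeyError(f"comparator {second_comparator!r} absent from matrices")
            row2 = pred[idx[second_comparator]]
            for n in names:
                if n in (comparator, second_comparator):
                    continue
                s1, s2 = bool(row[idx[n]]), bool(row2[idx[n]])
                if s1 != s2:
                    flips.append((n, s1, s2))
        return IsoformGrouping("comparator", groups, comparator, isoforms, flips)
    # transitive: single-linkage on the pairwise predicate
    graph = csr_matrix(pred.astype(np.int8))
    n_comp, labels = connected_components(graph, directed=False)
    groups = [[] for _ in range(n_comp)]
    for n, lab in zip(names, labels):
        groups[lab].append(n)
    groups.sort(key=lambda g: min(idx[n] for n in g))
    return IsoformGrouping("transitive", groups)
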