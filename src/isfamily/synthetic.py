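"""Seeded IS-family simulator with complete ground truth.

The generator emulates the statistical structure the pipeline assumes: a
family of elements descending from one ancestral IS along a pure-birth tree,
each element being left TIR + spacer + transposase ORF + spacer + right TIR
(the reverse complement of the left).  The ancestral transposase carries a
planted N-terminal F/F-Y planar pair, a DD(n)E catalytic triad with a
configured spacing and a downstream family signature.  Evolution is
per-site nucleotide substitution with no indels, so the true alignment is
the trivial stacking of the leaf sequences; near-identical isoform copies
are appended after the tree walk.

Two bookkeeping choices keep the planted truth identifiable: aspartate and
glutamate are reserved for the planted catalytic positions (the ancestral
protein avoids them elsewhere and substitutions proposing a D, E or stop
codon are redirected to another base), and the triad, signature, initiator
and stop positions are locked against substitution while the conserved-site
mask and the N-terminal F/Y pair evolve at a strongly suppressed rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from isfamily.records_io import ISRecord, RecordSet, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA18 = "".join(c for c in AA20 if c not in "DE")  # D/E reserved for the triad

_CODONS: dict[str, list[str]] = {}
_FWD: dict[str, str] = {}


def _tables() -> tuple[dict[str, list[str]], dict[str, str]]:
    if not _CODONS:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11]
        for codon, aa in table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
            _FWD[codon] = aa
        for aa in _CODONS:
            _CODONS[aa].sort()
        for stop in table.stop_codons:
            _FWD[stop] = "*"
    return _CODONS, _FWD


STOPS = ("TAA", "TAG", "TGA")
INITIATORS = ("ATG", "GTG", "TTG")

SIGNATURE_PLANTS = {
    "bacterial_DHK": {2: "D", 3: "H", 7: "K"},
    "bacterial_SHR": {2: "S", 3: "H", 7: "R"},
    "archaeal_FKR": {3: "F", 7: "K", 9: "R"},
}

DEFAULT_TIR = "GGTTCTGTTGCAAA"               # 14 bp short bacterial consensus
DEFAULT_TIR_ARCHAEAL = "GGTTCTGTTGCAAAGTGA"  # 18 bp variant

_NT = np.array(list("ACGT"))
_NT_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family.

    Defaults emulate the curated short bacterial family: ~65 elements of
    820 bp with a 234 aa transposase, 14 bp TIRs around the GGTTCTGTTGCAAA
    consensus, DD(34)E with the bacterial E-DH---K signature, and a couple
    of injected near-identical isoform copies.  ``subst_prob_per_branch`` is
    the per-nucleotide-site substitution probability applied on every edge
    of the tree, so sister leaves sit roughly two edge-lengths of divergence
    apart -- comfortably outside the isoform thresholds at the default rate.
    """

    seed: int = 0
    n_taxa: int = 65
    tree_height: float = 1.0
    subst_prob_per_branch: float = 0.05
    conserved_site_mask_rate: float = 0.10
    conserved_suppression: float = 0.02
    tir_consensus: Optional[str] = None
    tir_noise: float = 0.05
    triad_spacing: int = 34
    tnp_len: int = 234
    element_length: int = 820
    isoform_pairs: int = 2
    isoform_divergence: float = 0.02
    signature: Optional[str] = None
    archaeal_mode: bool = False
    clade_cut_depth: int = 2

    def __post_init__(self) -> None:
        for p in (self.subst_prob_per_branch, self.conserved_site_mask_rate,
                  self.tir_noise, self.isoform_divergence, self.conserved_suppression):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        tir = self.resolved_tir()
        if self.element_length < 3 * (self.tnp_len + 1) + 2 * len(tir) + 2:
            raise ValueError("element_length too small for TIRs + ORF + spacers")
        sig = self.resolved_signature()
        if sig not in SIGNATURE_PLANTS:
            raise ValueError(f"unknown signature {sig!r}")
        d1, d2, e = self.triad_positions()
        if not (10 < d1 < d2 < e and e > self.tnp_len // 2
                and e + max(SIGNATURE_PLANTS[sig]) <= self.tnp_len):
            raise ValueError("transposase too short for the requested triad spacing")

    def resolved_tir(self) -> str:
        if self.tir_consensus is not None:
            return self.tir_consensus
        return DEFAULT_TIR_ARCHAEAL if self.archaeal_mode else DEFAULT_TIR

    def resolved_signature(self) -> str:
        if self.signature is not None:
            return self.signature
        return "archaeal_FKR" if self.archaeal_mode else "bacterial_DHK"

    def triad_positions(self) -> tuple[int, int, int]:
        """Planted 1-based (D1, D2, E) positions on the transposase.

        The anchoring E sits 32 residues before the C terminus, D2 the
        configured spacing upstream of it, and D1 60 residues above D2
        (inside the locator's D1 search window).
        """
        e = self.tnp_len - 32
        d2 = e - self.triad_spacing - 1
        return (d2 - 60, d2, e)


class _Node:
    __slots__ = ("children", "length", "name")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.children: list[_Node] = []
        self.length = length
        self.name = name

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["_Node"]:
        if self.is_leaf():
            return [self]
        out: list[_Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _yule_tree(n: int, height: float, rng: np.random.Generator) -> _Node:
    """Pure-birth (rate 1) topology, branch lengths rescaled to the target
    root-to-leaf height (the tree is ultrametric)."""
    root = _Node()
    root.children = [_Node(), _Node()]
    active = list(root.children)
    while len(active) < n:
        dt = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += dt
        split = active.pop(int(rng.integers(len(active))))
        split.children = [_Node(), _Node()]
        active.extend(split.children)
    dt = rng.exponential(1.0 / len(active))
    for node in active:
        node.length += dt

    def depth(node: _Node) -> float:
        if node.is_leaf():
            return node.length
        return node.length + max(depth(c) for c in node.children)

    h = depth(root)
    scale = height / h if h > 0 else 1.0

    def rescale(node: _Node) -> None:
        node.length *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    root.length = 0.0
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.name = f"SYN{i:03d}"
    return root


def _clade_labels(root: _Node, cut_depth: int) -> dict[str, str]:
    """Subtrees rooted at the configured topological depth become clades;
    leaves branching off above that depth are 'solo'."""
    labels: dict[str, str] = {}
    counter = [0]

    def walk(node: _Node, depth: int) -> None:
        if node.is_leaf():
            labels[node.name] = "solo"
            return
        if depth == cut_depth:
            counter[0] += 1
            lab = f"C{counter[0]}"
            for leaf in node.leaves():
                labels[leaf.name] = lab
            return
        for c in node.children:
            walk(c, depth + 1)

    walk(root, 0)
    return labels


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated family."""

    tree_newick: str
    clade_labels: dict[str, str]
    isoform_pairs: list[tuple[str, str]]
    triad_positions: dict[str, tuple[int, int, int]]
    triad_spacing: int
    signature: str
    tir_consensus: str
    tir_boundaries: dict[str, tuple[int, int, int, int]]  # 1-based inclusive
    tir_ends: dict[str, tuple[str, str]]  # realised (left, right_rc) per record
    fy_pair: tuple[int, int]
    pairwise_nt_divergence: pd.DataFrame

    def tree(self):
        import dendropy

        return dendropy.Tree.get(data=self.tree_newick, schema="newick",
                                 preserve_underscores=True)

    def to_json(self, path) -> None:
        payload = {
            "tree_newick": self.tree_newick,
            "clade_labels": self.clade_labels,
            "isoform_pairs": [list(p) for p in self.isoform_pairs],
            "triad_positions": {k: list(v) for k, v in self.triad_positions.items()},
            "triad_spacing": self.triad_spacing,
            "signature": self.signature,
            "tir_consensus": self.tir_consensus,
            "tir_boundaries": {k: list(v) for k, v in self.tir_boundaries.items()},
            "tir_ends": {k: list(v) for k, v in self.tir_ends.items()},
            "fy_pair": list(self.fy_pair),
            "pairwise_nt_divergence": {
                "names": list(self.pairwise_nt_divergence.index),
                "values": self.pairwise_nt_divergence.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _ancestral_protein(cfg: SimulationConfig, rng: np.random.Generator
                       ) -> tuple[list[str], set[int], set[int]]:
    """Ancestral transposase plus locked / suppressed 0-based codon sets."""
    T = cfg.tnp_len
    d1, d2, e = cfg.triad_positions()
    aa = [AA18[i] for i in rng.integers(len(AA18), size=T)]
    locked = {0, d1 - 1, d1, d1 + 1, d2 - 1, e - 1}
    aa[0] = "M"
    aa[d1 - 1], aa[d1], aa[d1 + 1] = "D", "E", "T"   # conserved D-E(T) feature
    aa[d2 - 1] = "D"
    aa[e - 1] = "E"
    for off, res in SIGNATURE_PLANTS[cfg.resolved_signature()].items():
        aa[e - 1 + off] = res
        locked.add(e - 1 + off)
    # planar F / F-Y pair near the N terminus (1-based 3 and 8)
    aa[2], aa[7] = "F", "F"
    suppressed = {2, 7}
    # conserved G and P between the D residues, evolving at the suppressed rate
    aa[d1 + 19], aa[d1 + 29] = "G", "P"
    suppressed.update((d1 + 19, d1 + 29))
    free = [i for i in range(T) if i not in locked and i not in suppressed]
    n_mask = int(round(cfg.conserved_site_mask_rate * T))
    if n_mask and free:
        picks = rng.choice(len(free), size=min(n_mask, len(free)), replace=False)
        suppressed.update(free[int(i)] for i in picks)
    return aa, locked, suppressed


class _ElementModel:
    """Ancestral non-TIR core (spacer1 + ORF + spacer2) with per-site rates."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        codons_of, _ = _tables()
        tir = cfg.resolved_tir()
        T = cfg.tnp_len
        self.orf_nt = 3 * (T + 1)
        spacer_total = cfg.element_length - 2 * len(tir) - self.orf_nt
        self.s1_len = spacer_total // 2
        self.s2_len = spacer_total - self.s1_len
        aa, locked, suppressed = _ancestral_protein(cfg, rng)
        codons = [codons_of[a][int(rng.integers(len(codons_of[a])))] for a in aa]
        codons[0] = INITIATORS[int(rng.integers(len(INITIATORS)))]
        codons.append(STOPS[int(rng.integers(len(STOPS)))])
        core = _nt_encode("".join(codons))
        sp1 = rng.integers(4, size=self.s1_len)
        sp2 = rng.integers(4, size=self.s2_len)
        self.core = np.concatenate([sp1, core, sp2])
        factor = np.ones(self.core.size)
        for c in range(T + 1):
            if c in locked or c == T:  # stop codon locked too
                f = 0.0
            elif c in suppressed:
                f = cfg.conserved_suppression
            else:
                f = 1.0
            factor[self.s1_len + 3 * c: self.s1_len + 3 * c + 3] = f
        self.rate_factor = factor
        self.orf_span = (self.s1_len, self.s1_len + self.orf_nt)

    def mutate(self, core: np.ndarray, prob: float, rng: np.random.Generator) -> None:
        """One in-place substitution round at per-site probability
        ``prob * rate_factor``; ORF proposals creating a stop, D or E codon
        are redirected to another base (or skipped if none is admissible)."""
        _, fwd = _tables()
        hits = np.nonzero(rng.random(core.size) < prob * self.rate_factor)[0]
        lo, hi = self.orf_span
        for site in hits:
            current = int(core[site])
            order = rng.permutation(3)
            for k in order:
                cand = (current + 1 + int(k)) % 4
                if lo <= site < hi:
                    c0 = lo + 3 * ((site - lo) // 3)
                    codon = core[c0:c0 + 3].copy()
                    codon[site - c0] = cand
                    aa = fwd["".join(_NT[codon])]
                    if aa in ("*", "D", "E"):
                        continue
                core[site] = cand
                break


def _nt_encode(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX[b] for b in seq], dtype=np.int64)


def _nt_str(arr: np.ndarray) -> str:
    return "".join(_NT[arr])


def _noisy_tir(tir: str, noise: float, rng: np.random.Generator) -> str:
    out = list(tir)
    for i in range(len(out)):
        if rng.random() < noise:
            alt = [b for b in "ACGT" if b != out[i]]
            out[i] = alt[int(rng.integers(3))]
    return "".join(out)


def simulate_family(config: Optional[SimulationConfig] = None, **kw
                    ) -> tuple[RecordSet, SyntheticTruth]:
    """Simulate one IS family; deterministic for a fixed config seed."""
    cfg = config if config is not None else SimulationConfig(**kw)
    rng = np.random.default_rng(cfg.seed)
    tir = cfg.resolved_tir()
    d1, d2, e = cfg.triad_positions()

    root = _yule_tree(cfg.n_taxa, cfg.tree_height, rng)
    clades = _clade_labels(root, cfg.clade_cut_depth)
    model = _ElementModel(cfg, rng)

    leaf_cores: dict[str, np.ndarray] = {}

    def evolve(node: _Node, core: np.ndarray) -> None:
        core = core.copy()
        # one substitution round per edge: the per-branch probability applies
        # uniformly, so every split stays phylogenetically informative
        model.mutate(core, cfg.subst_prob_per_branch, rng)
        if node.is_leaf():
            leaf_cores[node.name] = core
            return
        for child in node.children:
            evolve(child, core)

    for child in root.children:
        evolve(child, model.core)

    names = [leaf.name for leaf in root.leaves()]
    iso_pairs: list[tuple[str, str]] = []
    if cfg.isoform_pairs:
        donors = rng.choice(len(names), size=min(cfg.isoform_pairs, len(names)),
                            replace=False)
        for di in sorted(int(i) for i in donors):
            donor = names[di]
            core = leaf_cores[donor].copy()
            model.mutate(core, cfg.isoform_divergence, rng)
            iso_name = f"{donor}i"
            leaf_cores[iso_name] = core
            clades[iso_name] = clades[donor]
            iso_pairs.append((donor, iso_name))

    all_names = names + [iso for _, iso in iso_pairs]
    records = []
    tir_ends: dict[str, tuple[str, str]] = {}
    tir_bounds: dict[str, tuple[int, int, int, int]] = {}
    triads: dict[str, tuple[int, int, int]] = {}
    for idx, name in enumerate(all_names, start=1):
        core = leaf_cores[name]
        left = _noisy_tir(tir, cfg.tir_noise, rng)
        right_inner = _noisy_tir(tir, cfg.tir_noise, rng)
        seq = left + _nt_str(core) + reverse_complement(right_inner)
        cds_start0 = len(tir) + model.s1_len
        rec = ISRecord(
            name=name,
            sequence=seq,
            cds_start=cds_start0,
            cds_end=cds_start0 + model.orf_nt,
            strand="+",
            domain_of_life="archaea" if cfg.archaeal_mode else "bacteria",
            taxon_group="synthetic",
            clade=clades.get(name, "solo"),
            accession=f"SYN{idx:05d}",
            recorded_tir_len=(len(tir), len(tir)),
            recorded_tsd_len=8,
        )
        records.append(rec)
        tir_ends[name] = (left, right_inner)
        L = len(seq)
        tir_bounds[name] = (1, len(tir), L - len(tir) + 1, L)
        triads[name] = (d1, d2, e)

    record_set = RecordSet(records, {"generator": "isfamily.synthetic",
                                     "seed": cfg.seed})
    n_all = len(all_names)
    div = np.zeros((n_all, n_all))
    seq_arrays = {r.name: np.frombuffer(r.sequence.encode(), dtype=np.uint8)
                  for r in records}
    for i in range(n_all):
        for j in range(i + 1, n_all):
            a, b = seq_arrays[all_names[i]], seq_arrays[all_names[j]]
            div[i, j] = div[j, i] = float(np.mean(a != b))
    truth = SyntheticTruth(
        tree_newick=root.newick(),
        clade_labels=clades,
        isoform_pairs=iso_pairs,
        triad_positions=triads,
        triad_spacing=cfg.triad_spacing,
        signature=cfg.resolved_signature(),
        tir_consensus=tir,
        tir_boundaries=tir_bounds,
        tir_ends=tir_ends,
        fy_pair=(3, 8),
        pairwise_nt_divergence=pd.DataFrame(div, index=all_names, columns=all_names),
    )
    return record_set, truth


def truth_check(truth: SyntheticTruth, *, tree=None, grouping=None,
                consensus: Optional[str] = None,
                triads: Optional[dict[str, tuple[int, int, int]]] = None,
                tir_ends: Optional[dict[str, tuple[str, str]]] = None,
                clades: Optional[dict[str, str]] = None) -> dict[str, float]:
    """Score pipeline outputs against the generator's ground truth.

    Any subset of outputs may be supplied; the report contains a score per
    supplied output: Robinson-Foulds distance to the generating tree,
    isoform precision/recall, TIR consensus Hamming distance, exact triad
    and TIR-end recovery fractions, and clade-label mismatch count.
    """
    from isfamily.phylogeny import robinson_foulds

    report: dict[str, float] = {}
    if tree is not None:
        report["rf_distance"] = float(robinson_foulds(tree, truth.tree()))
    if grouping is not None:
        true_pairs = {frozenset(p) for p in truth.isoform_pairs}
        pred_pairs = grouping.pairs()
        tp = len(true_pairs & pred_pairs)
        report["isoform_precision"] = tp / len(pred_pairs) if pred_pairs else 1.0
        report["isoform_recall"] = tp / len(true_pairs) if true_pairs else 1.0
    if consensus is not None:
        want = truth.tir_consensus
        got = consensus[:len(want)]
        if len(got) != len(want):
            raise ValueError("consensus shorter than the planted consensus")
        report["consensus_hamming"] = float(sum(a != b for a, b in zip(got, want)))
    if triads is not None:
        missing = set(triads) - set(truth.triad_positions)
        if missing:
            raise ValueError(f"triad results for unknown records: {sorted(missing)}")
        hits = [1.0 if tuple(triads[n]) == tuple(truth.triad_positions[n]) else 0.0
                for n in triads]
        report["triad_exact_fraction"] = float(np.mean(hits)) if hits else 1.0
    if tir_ends is not None:
        missing = set(tir_ends) - set(truth.tir_ends)
        if missing:
            raise ValueError(f"TIR results for unknown records: {sorted(missing)}")
        hits = []
        for n, (left, right) in tir_ends.items():
            want_l, want_r = truth.tir_ends[n]
            k = len(want_l)
            hits.append(1.0 if left[:k] == want_l and right[:k] == want_r else 0.0)
        report["tir_end_exact_fraction"] = float(np.mean(hits)) if hits else 1.0
    if clades is not None:
        mism = sum(1 for n, lab in clades.items()
                   if truth.clade_labels.get(n) != lab)
        report["clade_mismatches"] = float(mism)
    return report
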