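"""Data model for insertion-sequence records and all file input/output.

An :class:`ISRecord` holds one IS: its nucleotide sequence, the transposase
CDS interval, and the provenance metadata that ISFinder-style catalogues
carry (domain of life, taxon group, clade, recorded TIR/TSD lengths,
accession).  Metadata files use 1-based inclusive CDS coordinates (GenBank
convention); internally coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# translation table 11 (bacterial/archaeal); initiators rendered M
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_INITIATORS = {"ATG", "GTG", "TTG"}


class LoadError(ValueError):
    """A record could not be loaded; the message names the offending record."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds_nucleotides: str) -> str:
    """Translate a strand-resolved CDS under the bacterial/archaeal code.

    Conventions: initiator codons ATG/GTG/TTG are rendered M; a terminal stop
    codon is dropped; any codon containing N translates to X; internal stops
    appear as '*' (their detection is the curation module's job).
    """
    s = cds_nucleotides.upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"CDS length {len(s)} is not divisible by 3")
    if not set(s) <= NT_ALPHABET:
        bad = sorted(set(s) - NT_ALPHABET)
        raise ValueError(f"non-nucleotide characters in CDS: {bad}")
    aas = []
    for i in range(0, len(s), 3):
        codon = s[i:i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _TABLE11.stop_codons:
            aas.append("*")
        else:
            aas.append(_TABLE11.forward_table[codon])
    if s[:3] in _INITIATORS:
        aas[0] = "M"
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


@dataclass
class ISRecord:
    """One insertion sequence with its transposase CDS and metadata."""

    name: str
    sequence: str
    cds_start: int  # 0-based inclusive
    cds_end: int    # 0-based exclusive
    strand: str = "+"
    domain_of_life: str = "bacteria"
    taxon_group: str = ""
    clade: Optional[str] = None
    accession: str = ""
    recorded_tir_len: Optional[tuple[int, int]] = None
    recorded_tsd_len: Optional[int] = None
    tnp: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not set(self.sequence) <= NT_ALPHABET:
            bad = sorted(set(self.sequence) - NT_ALPHABET)
            raise LoadError(f"{self.name}: non-nucleotide characters {bad}")
        if len(self.sequence) < 100:
            raise LoadError(f"{self.name}: sequence shorter than 100 bp")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise LoadError(
                f"{self.name}: CDS interval [{self.cds_start}, {self.cds_end}) "
                f"outside sequence of length {len(self.sequence)}"
            )
        if self.strand not in "+-":
            raise LoadError(f"{self.name}: strand must be + or -, got {self.strand!r}")
        if self.recorded_tir_len is not None:
            for v in self.recorded_tir_len:
                if not 1 <= v <= 40:
                    raise LoadError(f"{self.name}: recorded TIR length {v} outside [1, 40]")
        if not self.tnp:
            self.tnp = translate(self.cds_nucleotides())

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_nucleotides(self) -> str:
        """Strand-resolved CDS nucleotide string."""
        s = self.sequence[self.cds_start:self.cds_end]
        return reverse_complement(s) if self.strand == "-" else s


@dataclass
class RecordSet:
    """Ordered collection of uniquely named records plus load provenance."""

    records: list[ISRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise LoadError(f"duplicate record names: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ISRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> ISRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def subset(self, names: Sequence[str]) -> "RecordSet":
        keep = set(names)
        return RecordSet([r for r in self.records if r.name in keep], dict(self.provenance))


METADATA_COLUMNS = [
    "name", "accession", "cds_start", "cds_end", "strand", "domain_of_life",
    "taxon_group", "clade", "tir_len_left", "tir_len_right", "tsd_len",
]


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in ("", "nd", "NA", "nan", "None"):
        return None
    return int(float(text))


def read_records(fasta_path, metadata_path) -> RecordSet:
    """Load a FASTA of IS sequences plus its per-record metadata table.

    Every FASTA identifier must have a metadata row and vice versa.  CDS
    coordinates in the table are 1-based inclusive.  Sequences are upper-cased
    and U is mapped to T; no biological validation beyond the basic record
    invariants happens here (that is curation's job).
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise LoadError(f"duplicate FASTA identifier {rec.id}")
        seqs[rec.id] = str(rec.seq)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"name": str}, keep_default_na=False,
                       na_values=[""])
    if "name" not in meta.columns:
        raise LoadError(f"{metadata_path}: metadata table lacks a 'name' column")
    meta_names = list(meta["name"])
    if len(meta_names) != len(set(meta_names)):
        raise LoadError("duplicate names in metadata table")
    missing_meta = [n for n in seqs if n not in set(meta_names)]
    if missing_meta:
        raise LoadError(f"FASTA records with no metadata row: {missing_meta}")
    missing_seq = [n for n in meta_names if n not in seqs]
    if missing_seq:
        raise LoadError(f"metadata rows with no FASTA record: {missing_seq}")
    by_name = meta.set_index("name")
    records = []
    for name in seqs:  # FASTA order is the set order
        row = by_name.loc[name]
        try:
            start_1 = int(row["cds_start"])
            end_1 = int(row["cds_end"])
        except (ValueError, TypeError) as exc:
            raise LoadError(f"{name}: malformed CDS interval ({exc})") from exc
        if start_1 < 1 or end_1 < start_1:
            raise LoadError(f"{name}: malformed CDS interval [{start_1}, {end_1}]")
        tir_l = _opt_int(row.get("tir_len_left"))
        tir_r = _opt_int(row.get("tir_len_right"))
        tir = (tir_l, tir_r) if tir_l is not None and tir_r is not None else None
        clade = row.get("clade")
        if isinstance(clade, float) and pd.isna(clade):
            clade = None
        records.append(ISRecord(
            name=name,
            sequence=seqs[name],
            cds_start=start_1 - 1,
            cds_end=end_1,
            strand=str(row.get("strand", "+")),
            domain_of_life=str(row.get("domain_of_life", "bacteria")),
            taxon_group=str(row.get("taxon_group", "")),
            clade=None if clade in (None, "", "nan") else str(clade),
            accession=str(row.get("accession", "")),
            recorded_tir_len=tir,
            recorded_tsd_len=_opt_int(row.get("tsd_len")),
        ))
    prov = {"fasta": str(fasta_path), "metadata": str(metadata_path),
            "loaded": pd.Timestamp.now().isoformat()}
    return RecordSet(records, prov)


def write_records(record_set: RecordSet, fasta_path, metadata_path) -> None:
    """Write sequences as FASTA and metadata as TSV (read_records inverse)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.name, description="")
                   for r in record_set]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    rows = []
    for r in record_set:
        rows.append({
            "name": r.name,
            "accession": r.accession,
            "cds_start": r.cds_start + 1,
            "cds_end": r.cds_end,
            "strand": r.strand,
            "domain_of_life": r.domain_of_life,
            "taxon_group": r.taxon_group,
            "clade": r.clade if r.clade is not None else "",
            "tir_len_left": r.recorded_tir_len[0] if r.recorded_tir_len else "",
            "tir_len_right": r.recorded_tir_len[1] if r.recorded_tir_len else "",
            "tsd_len": r.recorded_tsd_len if r.recorded_tsd_len is not None else "",
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def write_fasta(named_sequences: Sequence[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs as FASTA; gapped rows allowed ('-')."""
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in named_sequences]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a named square matrix as TSV with a header row/column, 2 dp."""
    matrix.to_csv(path, sep="\t", float_format="%.2f")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tree(tree, path) -> None:
    """Write a dendropy tree as Newick (support values as node labels)."""
    Path(path).write_text(tree_to_newick(tree))


def read_tree(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def tree_to_newick(tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
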