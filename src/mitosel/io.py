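"""Sequence, alignment, tree and metadata I/O with mitochondrial CDS conventions.

Conventions established here and relied on downstream:

* residues are uppercased; U is mapped to T; IUPAC ambiguity codes other than
  N are mapped to N with a logged warning;
* CDS validation uses the mitochondrial ATN start convention and accepts
  complete (TAA/TAG) or truncated (trailing TA or T) stop codons;
* internal coordinates are 0-based half-open; user-facing tables are 1-based;
* gene alignments are in frame (columns divisible by 3) with a shared taxon
  set across genes.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import pandas as pd
from Bio import SeqIO

from .code import GeneticCode, get_code
from .tree import Tree

logger = logging.getLogger(__name__)

PCG_NAMES = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)

_ALLOWED = set("ACGTN-")
_AMBIGUITY = set("RYSWKMBDHV")
BIO_COLUMNS = tuple(f"BIO{i}" for i in range(1, 20))


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (possibly gapped)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CDSReport:
    """Validation summary for one coding sequence."""

    start_codon: str
    start_ok: bool
    stop_class: str  # one of TAA, TAG, TA, T, none
    internal_stops: tuple[int, ...]  # 0-based codon indices
    trimmed_length: int

    @property
    def is_valid(self) -> bool:
        return self.start_ok and not self.internal_stops and self.stop_class != "none"


@dataclass
class GeneAlignment:
    """In-frame codon alignment of one protein-coding gene."""

    gene: str
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"alignment {self.gene!r} has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"alignment {self.gene!r} is ragged: lengths {sorted(lengths)}")
        if self.length % 3 != 0:
            raise ValueError(
                f"alignment {self.gene!r} length {self.length} not divisible by 3"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"alignment {self.gene!r} has duplicate ids")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, taxon: str) -> str:
        for r in self.records:
            if r.id == taxon:
                return r.residues
        raise KeyError(taxon)

    def subset(self, taxa: Iterable[str]) -> "GeneAlignment":
        keep = set(taxa)
        return GeneAlignment(self.gene, [r for r in self.records if r.id in keep])

    def codon(self, taxon: str, codon_index: int) -> str:
        row = self.row(taxon)
        return row[3 * codon_index : 3 * codon_index + 3]


@dataclass
class PartitionedAlignment:
    """Concatenation of gene alignments with recorded gene boundaries."""

    matrix: GeneAlignment
    boundaries: dict[str, tuple[int, int]]

    def gene_slice(self, gene: str) -> GeneAlignment:
        lo, hi = self.boundaries[gene]
        return GeneAlignment(
            gene, [SequenceRecord(r.id, r.residues[lo:hi]) for r in self.matrix.records]
        )


def _normalise_residues(raw: str, context: str) -> str:
    out = []
    warned = set()
    for ch in raw.upper():
        if ch == "U":
            ch = "T"
        if ch in _AMBIGUITY:
            if ch not in warned:
                logger.warning("%s: ambiguity code %s mapped to N", context, ch)
                warned.add(ch)
            ch = "N"
        if ch not in _ALLOWED:
            raise ValueError(f"{context}: invalid residue {ch!r}")
        out.append(ch)
    return "".join(out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly aligned) FASTA file into normalised records."""
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalise_residues(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def validate_and_trim_cds(
    record: SequenceRecord, code: Optional[GeneticCode] = None
) -> tuple[SequenceRecord, CDSReport]:
    """Trim the stop codon off an unaligned CDS and report its conventions.

    Complete trailing stops (TAA/TAG under code 5) are stripped; a sequence
    out of frame by 1 or 2 nt may end in a truncated stop (T or TA), which is
    stripped instead.  Internal stops are reported (0-based codon indices)
    but never removed.  The returned sequence length is divisible by 3, and
    the operation is idempotent.
    """
    code = code or get_code(5)
    seq = record.residues
    if "-" in seq:
        raise ValueError(f"{record.id}: gapped sequence passed to CDS validation")
    if len(seq) < 6:
        raise ValueError(f"{record.id}: CDS shorter than 6 nt")

    stop_class = "none"
    rem = len(seq) % 3
    if rem == 2:
        if seq.endswith("TA"):
            seq, stop_class = seq[:-2], "TA"
        else:
            raise ValueError(f"{record.id}: length % 3 == 2 with no trailing TA")
    elif rem == 1:
        if seq.endswith("T"):
            seq, stop_class = seq[:-1], "T"
        else:
            raise ValueError(f"{record.id}: length % 3 == 1 with no trailing T")
    else:
        # strip trailing complete stops; repeated so the operation is idempotent
        while len(seq) >= 6 and code.is_stop(seq[-3:]):
            stop_class = seq[-3:]
            seq = seq[:-3]

    if len(seq) % 3 != 0 or len(seq) < 3:
        raise ValueError(f"{record.id}: untrimmable frame")

    start = seq[:3]
    internal = tuple(
        i for i in range(len(seq) // 3) if code.is_stop(seq[3 * i : 3 * i + 3])
    )
    report = CDSReport(
        start_codon=start,
        start_ok=code.is_valid_start(start),
        stop_class=stop_class,
        internal_stops=internal,
        trimmed_length=len(seq),
    )
    return SequenceRecord(record.id, seq), report


def read_gene_alignments(
    paths: Mapping[str, str | Path], strict: bool = True
) -> dict[str, GeneAlignment]:
    """Read one aligned FASTA per gene, enforcing a shared taxon set.

    With ``strict=False`` a gene missing some taxa is padded with all-gap
    rows (logged), tolerating incomplete mitogenomes.
    """
    if not paths:
        raise ValueError("no gene alignment paths given")
    alignments = {g: GeneAlignment(g, read_fasta(p)) for g, p in paths.items()}
    all_taxa = sorted(set().union(*(set(a.ids) for a in alignments.values())))
    for gene, aln in alignments.items():
        missing = set(all_taxa) - set(aln.ids)
        if missing:
            if strict:
                raise ValueError(
                    f"gene {gene}: taxon sets differ; missing {sorted(missing)}"
                )
            logger.warning("gene %s: padding %s with gaps", gene, sorted(missing))
            pad = "-" * aln.length
            aln.records.extend(SequenceRecord(t, pad) for t in sorted(missing))
    return alignments


def concatenate_partitions(gene_map: Mapping[str, GeneAlignment]) -> PartitionedAlignment:
    """Concatenate gene alignments in alphabetical gene order.

    Boundaries are 0-based half-open column intervals tiling the matrix.
    """
    if not gene_map:
        raise ValueError("empty gene map")
    genes = sorted(gene_map)
    taxa = sorted(gene_map[genes[0]].ids)
    for g in genes:
        if sorted(gene_map[g].ids) != taxa:
            raise ValueError(f"gene {g}: taxon set differs from {genes[0]}")
    boundaries: dict[str, tuple[int, int]] = {}
    pos = 0
    rows = {t: [] for t in taxa}
    for g in genes:
        aln = gene_map[g]
        boundaries[g] = (pos, pos + aln.length)
        pos += aln.length
        for t in taxa:
            rows[t].append(aln.row(t))
    matrix = GeneAlignment(
        "concatenated", [SequenceRecord(t, "".join(rows[t])) for t in taxa]
    )
    return PartitionedAlignment(matrix=matrix, boundaries=boundaries)


def read_newick(path: str | Path, resolve_seed: int = 0) -> Tree:
    """Read a rooted Newick tree, resolving polytomies to binary.

    Polytomies are resolved by inserting zero-length branches in a seeded
    (hence reproducible) order.  Missing branch lengths are an error because
    the contrasts machinery needs them.
    """
    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(f"{path}: branch without length (required for PIC)")
    if any(len(n.child_nodes()) > 2 for n in dtree.preorder_node_iter()):
        logger.warning("%s: resolving polytomies with zero-length branches", path)
        dtree.resolve_polytomies(rng=random.Random(resolve_seed))
        for edge in dtree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
    return Tree.from_dendropy(dtree)


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Read the species metadata table (group, altitude_m, BIO1..BIO19).

    Delimiter is sniffed from the extension (.csv -> comma, else tab).
    Returns a DataFrame indexed by species_id.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["species_id", "group", "altitude_m", *BIO_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["species_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate species_id values")
    return df.set_index("species_id")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    comments: Iterable[str] = (),
    index: bool = False,
) -> None:
    """Write a TSV report with '#'-prefixed provenance comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
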