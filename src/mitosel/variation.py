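"""Alignment variation statistics: site classes, nucleotide diversity, and
synonymous/nonsynonymous mutation counts with mutation-versus-length fits.

Nucleotide diversity (Pi) is the mean over all unordered sequence pairs of
the per-site difference proportion, with pairwise deletion of gap/N columns,
and is also reported in sliding windows along the alignment.  "Mutations"
are minimum-change counts per variable site (distinct states minus one),
matching segregating-site style counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .code import GeneticCode, get_code
from .codon_usage import RegressionResult
from .io import GeneAlignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SiteClassCounts:
    n_sites: int  # columns with at least one countable base
    conserved: int
    variable: int
    singleton: int
    parsimony_informative: Optional[int]  # None when < 4 rows


@dataclass
class DiversityResult:
    pi: float
    windows: list[tuple[float, float]]  # (window midpoint, pi), NaN where empty
    window_size: Optional[int]
    step: Optional[int]


@dataclass(frozen=True)
class MutationCounts:
    gene: str
    total_mutations: int
    synonymous: int
    nonsynonymous: int
    mixed_flagged: int


def _matrix(aln: GeneAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Byte matrix and validity mask (True where A/C/G/T)."""
    arr = np.frombuffer(
        "".join(r.residues for r in aln.records).encode(), dtype=np.uint8
    ).reshape(len(aln.records), aln.length)
    valid = np.isin(arr, _BASES)
    return arr, valid


def classify_sites(aln: GeneAlignment) -> SiteClassCounts:
    """Classify columns as conserved / singleton / parsimony-informative.

    Only A/C/G/T states are counted.  A column is conserved when it shows a
    single state, parsimony-informative when at least two states each occur
    in at least two sequences, and a singleton otherwise.  Columns with no
    countable state are excluded from ``n_sites``.
    """
    arr, valid = _matrix(aln)
    informative_defined = len(aln.records) >= 4
    n_sites = conserved = singleton = informative = 0
    for j in range(aln.length):
        col = arr[valid[:, j], j]
        if col.size == 0:
            continue
        n_sites += 1
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 1:
            conserved += 1
        elif informative_defined and (counts >= 2).sum() >= 2:
            informative += 1
        else:
            singleton += 1
    variable = n_sites - conserved
    return SiteClassCounts(
        n_sites,
        conserved,
        variable,
        singleton if informative_defined else variable,
        informative if informative_defined else None,
    )


def nucleotide_diversity(
    aln: GeneAlignment,
    window: Optional[int] = 100,
    step: Optional[int] = 25,
) -> DiversityResult:
    """Average pairwise difference proportion, overall and in sliding windows.

    Pairwise deletion: each pair is compared over its own gap/N-free columns.
    Window midpoints are reported in 1-based alignment coordinates; windows
    with no comparable site in any pair get Pi = NaN.
    """
    if len(aln.records) < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    if window is not None and window > aln.length:
        raise ValueError(f"window {window} exceeds alignment length {aln.length}")
    arr, valid = _matrix(aln)
    pairs = list(itertools.combinations(range(len(aln.records)), 2))
    diff = np.empty((len(pairs), aln.length), dtype=bool)
    comp = np.empty((len(pairs), aln.length), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        comp[k] = valid[i] & valid[j]
        diff[k] = comp[k] & (arr[i] != arr[j])

    def mean_pi(lo: int, hi: int) -> float:
        d = diff[:, lo:hi].sum(axis=1).astype(float)
        c = comp[:, lo:hi].sum(axis=1).astype(float)
        ok = c > 0
        if not ok.any():
            return float("nan")
        return float((d[ok] / c[ok]).mean())

    overall = mean_pi(0, aln.length)
    windows: list[tuple[float, float]] = []
    if window is not None:
        step = step or window
        for lo in range(0, aln.length - window + 1, step):
            mid = lo + (window + 1) / 2  # 1-based midpoint
            windows.append((mid, mean_pi(lo, lo + window)))
    return DiversityResult(overall, windows, window, step)


def count_syn_nonsyn_mutations(
    aln: GeneAlignment, code: Optional[GeneticCode] = None
) -> MutationCounts:
    """Classify variable nucleotide sites of an in-frame alignment.

    A variable site is synonymous when every pair of observed codons that
    differ only at that site encodes the same amino acid, nonsynonymous when
    every such pair changes the amino acid, and mixed otherwise (including
    sites whose codon context always varies at multiple positions at once).
    ``total_mutations`` is the minimum-change count: distinct states minus
    one, summed over variable sites.
    """
    code = code or get_code(5)
    arr, valid = _matrix(aln)
    total = syn = nonsyn = mixed = 0
    for site in range(aln.length):
        col = arr[valid[:, site], site]
        states = np.unique(col)
        if states.size < 2:
            continue
        total += states.size - 1
        cidx = site // 3
        pos = site % 3
        codons = set()
        for r in range(len(aln.records)):
            codon = aln.records[r].residues[3 * cidx : 3 * cidx + 3]
            if set(codon) <= set("ACGT"):
                codons.add(codon)
        effects = set()
        for c1, c2 in itertools.combinations(sorted(codons), 2):
            diffs = [p for p in range(3) if c1[p] != c2[p]]
            if diffs == [pos]:
                effects.add("syn" if code.is_synonymous(c1, c2) else "nonsyn")
        if effects == {"syn"}:
            syn += 1
        elif effects == {"nonsyn"}:
            nonsyn += 1
        else:
            mixed += 1
    return MutationCounts(aln.gene, total, syn, nonsyn, mixed)


def mutation_length_regressions(
    per_gene: Sequence[tuple[float, float, float, float]],
) -> dict[str, RegressionResult]:
    """The four neutral-evolution fits across genes.

    Input rows are (alignment length, total, synonymous, nonsynonymous)
    mutation counts per gene; output keys: ``total_vs_length``,
    ``nonsyn_vs_length``, ``syn_vs_length``, ``syn_vs_nonsyn``.
    """
    if len(per_gene) < 3:
        raise ValueError("need at least 3 genes for the regressions")
    length, total, synonymous, nonsynonymous = (
        np.asarray(col, dtype=float) for col in zip(*per_gene)
    )

    def fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
        if np.allclose(x, x[0]):
            raise ValueError("degenerate predictor variance")
        res = stats.linregress(x, y)
        return RegressionResult(res.slope, res.intercept, res.rvalue**2, res.pvalue, len(x))

    return {
        "total_vs_length": fit(length, total),
        "nonsyn_vs_length": fit(length, nonsynonymous),
        "syn_vs_length": fit(length, synonymous),
        "syn_vs_nonsyn": fit(nonsynonymous, synonymous),
    }
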