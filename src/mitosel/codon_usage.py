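"""Codon-usage-bias suite: composition/skews, RSCU, ENC, neutrality and PR2.

The metrics follow the standard definitions used throughout the codon-bias
literature:

* AT skew = (A-T)/(A+T), GC skew = (G-C)/(G+C);
* RSCU(codon) = observed count / (family total / family size);
* Wright's effective number of codons (ENC), generalised to the degeneracy
  classes of the genetic code in use (for the invertebrate mitochondrial
  code: twelve 2-fold, six 4-fold, one 6-fold (Leu) and one 8-fold (Ser)
  family, so ENC ranges from 20 to 62);
* the expected-ENC curve ENC(s) = 2 + s + 29 / (s^2 + (1-s)^2) for a gene
  whose bias is driven purely by GC3s;
* the neutrality plot (OLS of GC12 on GC3s: slope near 1 = mutation-driven,
  near 0 = selection-driven bias);
* parity-rule-2 coordinates A3/(A3+T3) vs G3/(G3+C3) over four-fold
  degenerate families, with (0.5, 0.5) the no-strand-bias parity point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .code import GeneticCode, get_code
from .io import SequenceRecord

_ACGT = set("ACGT")


@dataclass(frozen=True)
class CompositionSummary:
    a: float
    t: float
    c: float
    g: float
    at_content: float
    at_skew: float  # NaN when A+T == 0
    gc_skew: float  # NaN when G+C == 0
    n_counted: int


@dataclass
class CodonCounts:
    """Sense-codon counts; stops and unreadable codons tallied separately."""

    counts: dict[str, int]
    code: GeneticCode
    n_codons: int
    n_stop: int = 0
    n_skipped: int = 0


@dataclass
class RSCUTable:
    rscu: dict[str, float]
    family_sizes: dict[str, int]
    absent_families: frozenset[str] = frozenset()


@dataclass
class CodonUsageSummary:
    enc: float  # NaN when undefined (empty degeneracy class)
    gc3s: float
    gc12: float
    pr2_x: float  # G3/(G3+C3) over four-fold families; NaN if denominator 0
    pr2_y: float  # A3/(A3+T3)
    enc_defined: bool = True


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def composition_and_skew(seq: SequenceRecord | str) -> CompositionSummary:
    """Base fractions and strand skews over non-gap, non-N positions."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    counts = {b: 0 for b in "ACGT"}
    for ch in residues:
        if ch in _ACGT:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable (A/C/G/T) bases in sequence")
    a, t, c, g = (counts[b] / total for b in "ATCG")
    at_skew = (a - t) / (a + t) if (a + t) > 0 else math.nan
    gc_skew = (g - c) / (g + c) if (g + c) > 0 else math.nan
    return CompositionSummary(a, t, c, g, a + t, at_skew, gc_skew, total)


def count_codons(
    seqs: str | SequenceRecord | Iterable[str | SequenceRecord],
    code: Optional[GeneticCode] = None,
) -> CodonCounts:
    """Tally in-frame codons over one sequence or a pool of sequences.

    Codons containing any non-ACGT symbol (gaps, N) are skipped; stop codons
    are tallied separately and excluded from usage statistics.
    """
    code = code or get_code(5)
    if isinstance(seqs, (str, SequenceRecord)):
        seqs = [seqs]
    counts: dict[str, int] = {}
    n_codons = n_stop = n_skipped = 0
    for seq in seqs:
        residues = seq.residues if isinstance(seq, SequenceRecord) else seq
        if len(residues) % 3 != 0:
            raise ValueError("sequence length not divisible by 3")
        for i in range(0, len(residues), 3):
            codon = residues[i : i + 3]
            if not set(codon) <= _ACGT:
                n_skipped += 1
            elif code.is_stop(codon):
                n_stop += 1
            else:
                counts[codon] = counts.get(codon, 0) + 1
                n_codons += 1
    return CodonCounts(counts, code, n_codons, n_stop, n_skipped)


def rscu(counts: CodonCounts) -> RSCUTable:
    """Relative synonymous codon usage: observed over equal-usage expectation.

    Families with zero total usage get RSCU 0 for each codon and are flagged.
    """
    table: dict[str, float] = {}
    sizes: dict[str, int] = {}
    absent = set()
    for aa, codons in counts.code.family.items():
        size = len(codons)
        total = sum(counts.counts.get(c, 0) for c in codons)
        sizes[aa] = size
        if total == 0:
            absent.add(aa)
            for c in codons:
                table[c] = 0.0
        else:
            expected = total / size
            for c in codons:
                table[c] = counts.counts.get(c, 0) / expected
    return RSCUTable(table, sizes, frozenset(absent))


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, generalised by degeneracy class.

    Per amino acid with n >= 2 codons observed the homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); each degeneracy class contributes
    (number of amino acids in class) / (mean F of class).  An entirely
    absent class (or one whose mean F is nonpositive) makes ENC undefined
    (NaN).  The result is capped at the total sense-codon count.
    """
    if counts.n_codons == 0:
        raise ValueError("cannot compute ENC from empty codon counts")
    f_by_class: dict[int, list[float]] = {}
    for aa, codons in counts.code.family.items():
        n = sum(counts.counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1) / (n - 1)
        f_by_class.setdefault(len(codons), []).append(f)
    value = 0.0
    for size, n_aas in counts.code.degeneracy_classes.items():
        fs = f_by_class.get(size)
        if not fs:
            return math.nan
        mean_f = sum(fs) / len(fs)
        if mean_f <= 0:
            return math.nan
        value += n_aas / mean_f
    # finite counts can push the estimate above the code's sense-codon
    # capacity (62 for the invertebrate mitochondrial code); cap there and
    # at the number of codons actually observed
    capacity = float(len(counts.code.sense_codons))
    return min(value, capacity, float(counts.n_codons))


def enc_expected(gc3s: float) -> float:
    """Expected ENC under pure GC3s-driven (mutational) bias."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError("gc3s must lie in [0, 1]")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def positional_gc_and_pr2(
    seqs: str | SequenceRecord | Iterable[str | SequenceRecord],
    code: Optional[GeneticCode] = None,
) -> CodonUsageSummary:
    """GC3s, GC12 and PR2 coordinates for one species (pooled in-frame seqs).

    GC3s is computed over the third positions of synonymously variable
    codons (under the invertebrate mitochondrial code that is every sense
    codon, since no family is a singleton); PR2 uses third positions of
    four-fold degenerate families only.  ENC is filled in separately by
    :func:`codon_usage_summary`.
    """
    code = code or get_code(5)
    counts = count_codons(seqs, code)
    gc12_hits = gc12_total = 0
    gc3_hits = gc3_total = 0
    third = {b: 0 for b in "ACGT"}
    fourfold_codons = {
        c for codons in code.fourfold_families().values() for c in codons
    }
    for codon, n in counts.counts.items():
        for pos in (0, 1):
            gc12_total += n
            if codon[pos] in "GC":
                gc12_hits += n
        gc3_total += n
        if codon[2] in "GC":
            gc3_hits += n
        if codon in fourfold_codons:
            third[codon[2]] += n
    if gc3_total == 0:
        raise ValueError("no countable codons")
    gc3s = gc3_hits / gc3_total
    gc12 = gc12_hits / gc12_total
    at3 = third["A"] + third["T"]
    gc3 = third["G"] + third["C"]
    pr2_y = third["A"] / at3 if at3 > 0 else math.nan
    pr2_x = third["G"] / gc3 if gc3 > 0 else math.nan
    return CodonUsageSummary(math.nan, gc3s, gc12, pr2_x, pr2_y, enc_defined=False)


def codon_usage_summary(
    seqs: str | SequenceRecord | Iterable[str | SequenceRecord],
    code: Optional[GeneticCode] = None,
) -> CodonUsageSummary:
    """Full per-species summary: ENC, GC3s, GC12 and PR2 coordinates."""
    code = code or get_code(5)
    if isinstance(seqs, (str, SequenceRecord)):
        seqs = [seqs]
    seqs = list(seqs)
    summary = positional_gc_and_pr2(seqs, code)
    value = enc(count_codons(seqs, code))
    summary.enc = value
    summary.enc_defined = not math.isnan(value)
    return summary


def neutrality_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of GC12 on GC3s across species (the neutrality plot)."""
    if len(points) < 3:
        raise ValueError("neutrality regression needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in GC3s")
    fit = stats.linregress(x, y)
    return RegressionResult(fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue, len(x))
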