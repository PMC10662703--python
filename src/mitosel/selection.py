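"""Counting-based selection machinery.

This module provides counting analogues of the likelihood methods usually
run for dN/dS scans, chosen because they are fully specified, fast and
desk-verifiable:

* Nei-Gojobori (1986) pairwise dN/dS: fractional synonymous/nonsynonymous
  site counts per codon, pathway averaging over multi-position codon
  differences (paths through stop codons excluded), Jukes-Cantor correction
  d = -(3/4) ln(1 - (4/3) p), omega = dN/dS;
* Fitch-Sankoff ancestral reconstruction with codons as atomic unit-cost
  states, enumerating all most-parsimonious reconstructions (MPRs) up to a
  cap and weighting substitution events uniformly across them;
* a SLAC-style per-site test: a binomial null on the nonsynonymous fraction
  of reconstructed events, with the expected fraction N/(N+S) taken from the
  NG86 site counts of the codons observed at the site;
* a foreground/background omega contrast over terminal branches with a
  label-permutation null, the counting analogue of a two-ratio branch model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import special

from .code import GeneticCode, get_code
from .io import GeneAlignment
from .tree import Node, Tree

_ACGT = "ACGT"
_CLEAN = set(_ACGT)

MPR_CAP = 10_000


# --------------------------------------------------------------------------
# NG86 counting
# --------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, code_id: int) -> tuple[float, float]:
    code = get_code(code_id)
    if code.is_stop(codon) or not set(codon) <= _CLEAN:
        raise ValueError(f"NG86 site counts need a sense codon, got {codon!r}")
    s = n = 0.0
    for pos in range(3):
        for base in _ACGT:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(neighbor):
                continue  # stop neighbors contribute to neither class
            if code.is_synonymous(codon, neighbor):
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def ng86_site_counts(codon: str, code: Optional[GeneticCode] = None) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 of a site
    to the synonymous or nonsynonymous total; neighbours that are stop
    codons are excluded, so s + n = 3 x (non-stop neighbour fraction).
    """
    code = code or get_code(5)
    return _site_counts_cached(codon, code.code_id)


@lru_cache(maxsize=None)
def _pathway_counts_cached(c1: str, c2: str, code_id: int) -> tuple[float, float, int]:
    """(Sd, Nd, n_valid_paths) between two sense codons, pathway-averaged."""
    code = get_code(code_id)
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0, 1
    syn_total = nonsyn_total = 0.0
    n_valid = 0
    for order in itertools.permutations(diffs):
        current = c1
        steps: list[tuple[str, str]] = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if blocked:
            continue
        n_valid += 1
        for a, b in steps:
            if code.is_synonymous(a, b):
                syn_total += 1
            else:
                nonsyn_total += 1
    if n_valid == 0:
        return 0.0, 0.0, 0
    return syn_total / n_valid, nonsyn_total / n_valid, n_valid


def ng86_pathway_counts(
    c1: str, c2: str, code: Optional[GeneticCode] = None
) -> tuple[float, float, int]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    All orderings of the differing positions are averaged with equal weight;
    orderings passing through a stop codon are excluded and the remainder
    re-weighted.  Returns (Sd, Nd, number of valid paths); Sd + Nd equals the
    number of differing positions whenever at least one path is valid.
    """
    code = code or get_code(5)
    return _pathway_counts_cached(c1, c2, code.code_id)


@dataclass(frozen=True)
class NG86Result:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when saturated
    dN: float
    omega: float  # NaN when undefined (dS == 0 or saturated)
    n_codons: int  # codon pairs compared
    flags: frozenset[str] = frozenset()


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_pairwise(
    seq1: str, seq2: str, code: Optional[GeneticCode] = None
) -> NG86Result:
    """Nei-Gojobori dN/dS between two equal-length in-frame sequences.

    Codon pairs containing gaps, N, or a stop codon in either sequence are
    excluded pairwise.  Site totals S and N are averaged over the two
    sequences; proportions are Jukes-Cantor corrected.  Flags: ``identical``
    (no differences), ``dS_zero``, ``saturated`` (p >= 3/4), ``no_data``.
    """
    code = code or get_code(5)
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    n_codons = 0
    flags = set()
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (set(c1) <= _CLEAN and set(c2) <= _CLEAN):
            continue
        if code.is_stop(c1) or code.is_stop(c2):
            continue
        s1, n1 = ng86_site_counts(c1, code)
        s2, n2 = ng86_site_counts(c2, code)
        sd, nd, n_valid = ng86_pathway_counts(c1, c2, code)
        if c1 != c2 and n_valid == 0:
            flags.add("blocked_path")
            continue
        S1 += s1
        N1 += n1
        S2 += s2
        N2 += n2
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        return NG86Result(0, 0, 0, 0, math.nan, math.nan, math.nan, math.nan,
                          math.nan, 0, frozenset({"no_data"}))
    S = (S1 + S2) / 2
    N = (N1 + N2) / 2
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    dS = _jc_correct(pS) if not math.isnan(pS) else math.nan
    dN = _jc_correct(pN) if not math.isnan(pN) else math.nan
    if Sd == 0 and Nd == 0:
        flags.add("identical")
    if math.isnan(dS) or math.isnan(dN):
        flags.add("saturated")
    omega = math.nan
    if not (math.isnan(dS) or math.isnan(dN)):
        if dS == 0:
            flags.add("dS_zero")
        else:
            omega = dN / dS
    return NG86Result(S, N, Sd, Nd, pS, pN, dS, dN, omega, n_codons, frozenset(flags))


# --------------------------------------------------------------------------
# Fitch-Sankoff ancestral reconstruction (codons as atomic states)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    branch: int  # postorder index of the child node of the branch
    site: int  # 0-based codon site
    from_codon: str
    to_codon: str
    kind: str  # "syn" or "nonsyn"
    weight: float


@dataclass
class AncestralReconstruction:
    site: int
    min_changes: int
    mpr_count: int
    sampled: bool  # True when MPRs were sampled beyond the cap
    node_states: dict[int, frozenset[str]]  # node index -> optimal states used
    events: list[Event]


def fitch_ancestral(
    tree: Tree,
    site_states: Mapping[str, str],
    code: Optional[GeneticCode] = None,
    site: int = 0,
    cap: int = MPR_CAP,
    seed: int = 0,
) -> AncestralReconstruction:
    """Unit-cost parsimony over codon states with full MPR enumeration.

    Tips absent from ``site_states`` are treated as missing (they constrain
    nothing and never host events).  All most-parsimonious reconstructions
    are enumerated up to ``cap``; beyond it, ``cap`` reconstructions are
    sampled uniformly with the given seed.  Each changed branch contributes
    one unit of event weight per reconstruction (1/mpr_count overall), split
    between synonymous and nonsynonymous using NG86 pathway fractions when
    the two codons differ at several positions — so event weights sum
    exactly to the minimum change count.
    """
    code = code or get_code(5)
    observed = sorted(set(site_states.values()))
    if len([t for t in tree.tips if t.name in site_states]) < 2:
        raise ValueError("fewer than 2 tips with observed codons")
    k = len(observed)
    state_index = {s: i for i, s in enumerate(observed)}
    INF = 10**9

    # bottom-up Sankoff costs
    cost = np.zeros((len(tree.nodes), k), dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            if node.name in site_states:
                cost[node.index, :] = INF
                cost[node.index, state_index[site_states[node.name]]] = 0
            # missing tip: all-zero row (constrains nothing)
        else:
            for child in node.children:
                child_cost = cost[child.index]
                # cost of child subtree given parent state s:
                # min over s' of child_cost[s'] + (s != s')
                best = child_cost.min()
                trans = np.minimum(child_cost, best + 1)
                cost[node.index] += trans

    root_cost = cost[tree.root.index]
    min_changes = int(root_cost.min())

    # per-(node, parent_state) optimal child states and MPR counts
    n_mpr = np.zeros((len(tree.nodes), k), dtype=float)  # counts (float: can be big)
    choice: dict[tuple[int, int], np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            n_mpr[node.index, :] = 1.0
            continue
        for s in range(k):
            total = 1.0
            for child in node.children:
                child_cost = cost[child.index]
                opts = child_cost + (np.arange(k) != s)
                best = opts.min()
                states = np.flatnonzero(opts == best)
                choice[(child.index, s)] = states
                total *= n_mpr[child.index, states].sum()
            n_mpr[node.index, s] = total

    root_opts = np.flatnonzero(root_cost == min_changes)
    # root "choice": weight by subtree counts
    total_mpr = float(n_mpr[tree.root.index, root_opts].sum())
    sampled = total_mpr > cap

    events_acc: dict[tuple[int, str, str], float] = {}
    node_state_sets: dict[int, set[str]] = {n.index: set() for n in tree.nodes}

    def record(assignment: dict[int, int], weight: float) -> None:
        for node in tree.nodes:
            node_state_sets[node.index].add(observed[assignment[node.index]])
            if node.parent is not None:
                a = assignment[node.parent.index]
                b = assignment[node.index]
                if a != b:
                    key = (node.index, observed[a], observed[b])
                    events_acc[key] = events_acc.get(key, 0.0) + weight
        # missing tips keep the parent state by optimality; already handled

    if not sampled:
        weight = 1.0 / total_mpr

        def enumerate_assignments(
            pending: list[Node], assignment: dict[int, int]
        ) -> None:
            if not pending:
                record(assignment, weight)
                return
            node = pending[0]
            rest = pending[1:]
            opts = choice[(node.index, assignment[node.parent.index])]
            for s in opts:
                assignment[node.index] = int(s)
                enumerate_assignments(rest, assignment)

        order = [n for n in tree.preorder() if n.parent is not None]
        for s in root_opts:
            enumerate_assignments(order, {tree.root.index: int(s)})
        mpr_count: float = total_mpr
    else:
        rng = np.random.default_rng(seed)
        weight = 1.0 / cap
        order = [n for n in tree.preorder() if n.parent is not None]
        root_w = n_mpr[tree.root.index, root_opts]
        for _ in range(cap):
            assignment = {
                tree.root.index: int(rng.choice(root_opts, p=root_w / root_w.sum()))
            }
            for node in order:
                opts = choice[(node.index, assignment[node.parent.index])]
                w = n_mpr[node.index, opts]
                assignment[node.index] = int(rng.choice(opts, p=w / w.sum()))
            record(assignment, weight)
        mpr_count = total_mpr

    events: list[Event] = []
    for (branch, a, b), w in sorted(events_acc.items()):
        sd, nd, n_valid = (
            ng86_pathway_counts(a, b, code)
            if not (code.is_stop(a) or code.is_stop(b))
            else (0.0, 0.0, 0)
        )
        d = sd + nd
        if d > 0:
            syn_frac = sd / d
        else:  # all paths blocked or stop endpoint: classify by endpoints
            syn_frac = 1.0 if code.codon_to_aa[a] == code.codon_to_aa[b] else 0.0
        if syn_frac > 0:
            events.append(Event(branch, site, a, b, "syn", w * syn_frac))
        if syn_frac < 1:
            events.append(Event(branch, site, a, b, "nonsyn", w * (1 - syn_frac)))

    return AncestralReconstruction(
        site=site,
        min_changes=min_changes,
        mpr_count=int(total_mpr) if total_mpr < 2**62 else -1,
        sampled=sampled,
        node_states={i: frozenset(s) for i, s in node_state_sets.items()},
        events=events,
    )


# --------------------------------------------------------------------------
# SLAC-style site test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSelectionResult:
    codon_index: int  # 1-based
    observed_syn: float
    observed_nonsyn: float
    expected_nonsyn_fraction: float
    p_positive: float
    p_negative: float
    classification: str  # positive / negative / neutral


def _binom_upper_tail(k: float, n: float, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), continuous in k and n via betainc."""
    if k <= 0:
        return 1.0
    k = min(k, n)
    if p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    return float(special.betainc(k, n - k + 1.0, p))


def _site_codon_states(
    aln: GeneAlignment, code: GeneticCode, site: int
) -> dict[str, str]:
    states = {}
    for rec in aln.records:
        codon = rec.residues[3 * site : 3 * site + 3]
        if set(codon) <= _CLEAN and not code.is_stop(codon):
            states[rec.id] = codon
    return states


def slac_site_test(
    aln: GeneAlignment,
    tree: Tree,
    code: Optional[GeneticCode] = None,
    threshold: float = 0.1,
    cap: int = MPR_CAP,
    seed: int = 0,
) -> list[SiteSelectionResult]:
    """Per-codon-site selection test from parsimony-reconstructed events.

    For each codon site the reconstructed synonymous/nonsynonymous event
    weights are compared with a binomial expectation whose nonsynonymous
    fraction is N/(N+S) averaged over the codons observed at the site.
    ``p_positive`` is the upper-tail probability of at least the observed
    nonsynonymous weight; ``p_negative`` the symmetric synonymous tail.
    Sites are classified at ``threshold`` (default 0.1, the usual SLAC/FEL
    reporting convention).
    """
    code = code or get_code(5)
    if set(tree.tip_labels) != set(aln.ids):
        raise ValueError("tree tips and alignment ids differ")
    results = []
    for site in range(aln.n_codons):
        states = _site_codon_states(aln, code, site)
        fracs = []
        for codon in states.values():
            s, n = ng86_site_counts(codon, code)
            fracs.append(n / (s + n))
        expected = float(np.mean(fracs)) if fracs else math.nan
        if len(states) < 2 or len(set(states.values())) == 1:
            results.append(
                SiteSelectionResult(site + 1, 0.0, 0.0, expected, 1.0, 1.0, "neutral")
            )
            continue
        rec = fitch_ancestral(tree, states, code, site=site, cap=cap, seed=seed + site)
        obs_syn = sum(e.weight for e in rec.events if e.kind == "syn")
        obs_nonsyn = sum(e.weight for e in rec.events if e.kind == "nonsyn")
        total = obs_syn + obs_nonsyn
        if total <= 0:
            results.append(
                SiteSelectionResult(site + 1, 0.0, 0.0, expected, 1.0, 1.0, "neutral")
            )
            continue
        p_pos = _binom_upper_tail(obs_nonsyn, total, expected)
        p_neg = _binom_upper_tail(obs_syn, total, 1.0 - expected)
        if p_pos < threshold:
            cls = "positive"
        elif p_neg < threshold:
            cls = "negative"
        else:
            cls = "neutral"
        results.append(
            SiteSelectionResult(site + 1, obs_syn, obs_nonsyn, expected, p_pos, p_neg, cls)
        )
    return results


# --------------------------------------------------------------------------
# Foreground/background omega contrast (permutation analogue of two-ratio)
# --------------------------------------------------------------------------


@dataclass
class BranchOmega:
    tip: str
    syn_events: float
    nonsyn_events: float
    S_sites: float
    N_sites: float
    omega: float  # NaN when undefined (no synonymous events)


@dataclass
class GroupContrastResult:
    gene: str
    omega_foreground: float
    omega_background: float
    delta: float
    p_perm: float
    n_perm: int
    seed: int
    branch_omegas: list[BranchOmega] = field(default_factory=list)


def terminal_branch_omegas(
    aln: GeneAlignment,
    tree: Tree,
    code: Optional[GeneticCode] = None,
    cap: int = MPR_CAP,
    seed: int = 0,
) -> list[BranchOmega]:
    """Counting omega per terminal branch.

    Events on each tip's branch are accumulated over all codon sites from
    the MPR-weighted reconstruction; the tip's own NG86 site counts
    normalise them: omega = (Nd/N) / (Sd/S).  A branch with zero synonymous
    events has undefined omega (NaN).
    """
    code = code or get_code(5)
    if set(tree.tip_labels) != set(aln.ids):
        raise ValueError("tree tips and alignment ids differ")
    tip_index = {t.name: t.index for t in tree.tips}
    syn = {name: 0.0 for name in tip_index}
    nonsyn = {name: 0.0 for name in tip_index}
    index_tip = {i: n for n, i in tip_index.items()}
    for site in range(aln.n_codons):
        states = _site_codon_states(aln, code, site)
        if len(states) < 2 or len(set(states.values())) == 1:
            continue
        rec = fitch_ancestral(tree, states, code, site=site, cap=cap, seed=seed + site)
        for e in rec.events:
            name = index_tip.get(e.branch)
            if name is not None:
                if e.kind == "syn":
                    syn[name] += e.weight
                else:
                    nonsyn[name] += e.weight
    out = []
    for rec_ in aln.records:
        S = N = 0.0
        for i in range(0, len(rec_.residues), 3):
            codon = rec_.residues[i : i + 3]
            if set(codon) <= _CLEAN and not code.is_stop(codon):
                s, n = ng86_site_counts(codon, code)
                S += s
                N += n
        sd, nd = syn[rec_.id], nonsyn[rec_.id]
        if sd > 0 and S > 0 and N > 0:
            omega = (nd / N) / (sd / S)
        else:
            omega = math.nan
        out.append(BranchOmega(rec_.id, sd, nd, S, N, omega))
    return out


def group_omega_contrast(
    aln: GeneAlignment,
    tree: Tree,
    labels: Mapping[str, int],
    n_perm: int = 999,
    seed: int = 0,
    code: Optional[GeneticCode] = None,
    branch_omegas: Optional[Sequence[BranchOmega]] = None,
) -> GroupContrastResult:
    """Foreground (1) vs background (0) mean terminal-branch omega contrast.

    The observed difference in group means is compared with a null built by
    relabeling tips at random while preserving group sizes; the p-value is
    two-sided, (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    groups = set(labels.values())
    if not {0, 1} <= groups:
        raise ValueError("both foreground (1) and background (0) tips required")
    if branch_omegas is None:
        branch_omegas = terminal_branch_omegas(aln, tree, code, seed=seed)
    defined = [(b.tip, b.omega) for b in branch_omegas if not math.isnan(b.omega)]
    if not defined:
        raise ValueError("no terminal branch has a defined omega")
    omegas = np.array([w for _, w in defined])
    lab = np.array([labels[t] for t, _ in defined])
    if lab.sum() == 0 or lab.sum() == len(lab):
        raise ValueError("one group has no tips with defined omega")

    def delta(lv: np.ndarray) -> float:
        return float(omegas[lv == 1].mean() - omegas[lv == 0].mean())

    obs = delta(lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        if abs(delta(perm)) >= abs(obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    fg = float(omegas[lab == 1].mean())
    bg = float(omegas[lab == 0].mean())
    return GroupContrastResult(
        aln.gene, fg, bg, obs, p, n_perm, seed, list(branch_omegas)
    )
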