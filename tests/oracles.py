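"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions, without
reusing any package internals beyond the genetic-code table, so that
agreement with the package is a meaningful cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

from mitosel.code import GeneticCode

ACGT = "ACGT"


# ---- NG86 --------------------------------------------------------------


def brute_site_counts(codon: str, code: GeneticCode) -> tuple[float, float]:
    s = n = 0.0
    for pos, base in itertools.product(range(3), ACGT):
        if base == codon[pos]:
            continue
        nb = codon[:pos] + base + codon[pos + 1 :]
        if code.codon_to_aa[nb] == "*":
            continue
        if code.codon_to_aa[nb] == code.codon_to_aa[codon]:
            s += 1.0 / 3.0
        else:
            n += 1.0 / 3.0
    return s, n


def brute_pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Average syn/nonsyn step counts over stop-free substitution paths."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in itertools.permutations(positions):
        cur, steps, ok = c1, [], True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if code.codon_to_aa[nxt] == "*":
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    for steps in paths:
        for a, b in steps:
            if code.codon_to_aa[a] == code.codon_to_aa[b]:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(paths), nonsyn / len(paths)


# ---- parsimony ---------------------------------------------------------


def brute_parsimony(tree, site_states: dict[str, str]):
    """Exhaustive minimum-change count / MPR count / per-branch expected
    changes, enumerating every labeling of internal nodes over the observed
    state set."""
    states = sorted(set(site_states.values()))
    internal = [n for n in tree.postorder() if not n.is_leaf]
    best_cost = None
    labelings = []
    for combo in itertools.product(states, repeat=len(internal)):
        assign = {n.index: s for n, s in zip(internal, combo)}
        for t in tree.tips:
            if t.name in site_states:
                assign[t.index] = site_states[t.name]
        cost = 0
        for node in tree.postorder():
            if node.parent is None:
                continue
            if node.is_leaf and node.name not in site_states:
                continue
            if assign[node.index] != assign[node.parent.index]:
                cost += 1
        if best_cost is None or cost < best_cost:
            best_cost = cost
            labelings = [assign]
        elif cost == best_cost:
            labelings.append(assign)
    branch_changes: dict[int, float] = {}
    for assign in labelings:
        for node in tree.postorder():
            if node.parent is None:
                continue
            if node.is_leaf and node.name not in site_states:
                continue
            if assign[node.index] != assign[node.parent.index]:
                branch_changes[node.index] = (
                    branch_changes.get(node.index, 0.0) + 1.0 / len(labelings)
                )
    return best_cost, len(labelings), branch_changes


# ---- alignment statistics ----------------------------------------------


def brute_pi(rows: list[str]) -> float:
    vals = []
    for a, b in itertools.combinations(rows, 2):
        comp = diff = 0
        for x, y in zip(a, b):
            if x in ACGT and y in ACGT:
                comp += 1
                if x != y:
                    diff += 1
        if comp:
            vals.append(diff / comp)
    return float(np.mean(vals))


def brute_site_classes(rows: list[str]):
    n_sites = conserved = informative = singleton = 0
    for col in zip(*rows):
        states = [c for c in col if c in ACGT]
        if not states:
            continue
        n_sites += 1
        uniq = set(states)
        if len(uniq) == 1:
            conserved += 1
        elif sum(1 for s in uniq if states.count(s) >= 2) >= 2:
            informative += 1
        else:
            singleton += 1
    return n_sites, conserved, singleton, informative


# ---- Wright's ENC -------------------------------------------------------


def brute_enc(codon_counts: dict[str, int], code: GeneticCode) -> float:
    by_aa: dict[str, list[int]] = {}
    for aa, codons in code.family.items():
        by_aa[aa] = [codon_counts.get(c, 0) for c in codons]
    class_f: dict[int, list[float]] = {}
    for aa, counts in by_aa.items():
        n = sum(counts)
        if n < 2:
            continue
        f = (n * sum((c / n) ** 2 for c in counts) - 1) / (n - 1)
        class_f.setdefault(len(counts), []).append(f)
    total = 0.0
    for size, n_aa in code.degeneracy_classes.items():
        fs = class_f.get(size)
        if not fs or np.mean(fs) <= 0:
            return float("nan")
        total += n_aa / np.mean(fs)
    return min(total, float(len(code.sense_codons)),
               float(sum(codon_counts.values())))


# ---- PIC ----------------------------------------------------------------


def tree_covariance(tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance: shared root-to-MRCA path length."""
    tips = tree.tips
    paths = {}
    for tip in tips:
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = list(reversed(path))
    labels = [t.name for t in tips]
    V = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = 0.0
            for x, y in zip(paths[a], paths[b]):
                if x is y:
                    shared += x.length
                else:
                    break
            V[i, j] = shared
    return labels, V
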