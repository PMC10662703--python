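"""Ground-truth codon-evolution simulator for validating the pipeline.

Trees are Yule trees rescaled to a target root-to-tip depth; sequences
evolve site-independently under an MG94xHKY-style codon model simulated
with the Gillespie algorithm, so every substitution event (branch, site,
from, to, synonymous or not, time) is logged exactly.  Codon frequencies
are F1x4 built from an AT fraction (default 0.80, the AT-richness typical
of hymenopteran mitochondrial protein-coding genes), with stop codons
renormalised out; omega may differ between a foreground clade and the
background, emulating an alpine/lowland contrast.  Environmental metadata
(altitude plus 19 bioclimatic variables linear in altitude with noise) are
generated for the same tips.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .code import GeneticCode, get_code
from .io import (
    PCG_NAMES,
    GeneAlignment,
    SequenceRecord,
    write_fasta,
)
from .tree import Node, Tree

#: Default per-gene codon counts, matching the alignment lengths (nt / 3) of
#: the 13 mitochondrial PCGs of the chalcidoid dataset this package models
#: (concatenated length 10,995 nt).
DEFAULT_GENE_CODONS = {
    "ATP6": 259, "ATP8": 97, "COX1": 528, "COX2": 341, "COX3": 344,
    "CYTB": 397, "ND1": 319, "ND2": 403, "ND3": 168, "ND4": 510,
    "ND4L": 146, "ND5": 606, "ND6": 254,
}

SCENARIOS = ("neutral", "purifying", "foreground_elevated", "null_env")


@dataclass
class SimulationConfig:
    seed: int
    n_tips: int = 29
    birth_rate: float = 1.0
    depth: float = 0.3  # substitutions per codon site, root to tip
    n_codons: int = 300
    kappa: float = 2.0
    at_fraction: float = 0.80
    omega_foreground: float = 0.2
    omega_background: float = 0.2
    foreground_fraction: float = 11 / 29
    scattered_foreground: bool = False
    code_id: int = 5

    def __post_init__(self) -> None:
        if self.omega_foreground < 0 or self.omega_background < 0:
            raise ValueError("omega must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")
        if not 0 < self.at_fraction < 1:
            raise ValueError("AT fraction must be in (0, 1)")

    def nucleotide_freqs(self) -> dict[str, float]:
        at = self.at_fraction / 2
        gc = (1 - self.at_fraction) / 2
        return {"A": at, "T": at, "G": gc, "C": gc}


@dataclass
class SimEvent:
    branch: int  # postorder index of child node
    site: int
    from_codon: str
    to_codon: str
    kind: str  # syn / nonsyn
    time: float  # position along the branch


@dataclass
class SimulationTruth:
    newick: str
    root_sequence: str
    events: list[SimEvent]
    branch_totals: dict[int, dict[str, float]]
    true_omega: dict[str, float]  # branch class -> omega
    foreground_branches: frozenset[int]
    config: SimulationConfig


def codon_equilibrium(config: SimulationConfig, code: GeneticCode) -> dict[str, float]:
    """F1x4 codon frequencies renormalised over sense codons."""
    nt = config.nucleotide_freqs()
    raw = {c: nt[c[0]] * nt[c[1]] * nt[c[2]] for c in code.sense_codons}
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


class _RateTable:
    """Per-codon exit rates and neighbour targets for one omega class,
    normalised so branch lengths are expected substitutions per codon site."""

    def __init__(self, config: SimulationConfig, code: GeneticCode, omega: float):
        self.codons = list(code.sense_codons)
        index = {c: i for i, c in enumerate(self.codons)}
        nt = config.nucleotide_freqs()
        pi = codon_equilibrium(config, code)
        targets: list[np.ndarray] = []
        rates: list[np.ndarray] = []
        for codon in self.codons:
            tg, rt = [], []
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    nb = codon[:pos] + base + codon[pos + 1 :]
                    if code.is_stop(nb):
                        continue
                    r = nt[base]
                    if _is_transition(codon[pos], base):
                        r *= config.kappa
                    if not code.is_synonymous(codon, nb):
                        r *= omega
                    if r > 0:
                        tg.append(index[nb])
                        rt.append(r)
            targets.append(np.array(tg, dtype=np.int64))
            rates.append(np.array(rt, dtype=float))
        rho = sum(
            pi[c] * rates[i].sum() for i, c in enumerate(self.codons)
        )
        self.targets = targets
        self.rates = [r / rho for r in rates]
        self.total = np.array([r.sum() for r in self.rates])
        self.index = index
        self.syn = [
            np.array(
                [code.is_synonymous(self.codons[i], self.codons[j]) for j in targets[i]]
            )
            for i in range(len(self.codons))
        ]


def simulate_tree(config: SimulationConfig) -> Tree:
    """Seeded Yule tree with tips s1..sn, rescaled to the configured depth.

    Group labels: by default one internal clade whose size is closest to
    ``foreground_fraction`` of the tips is the foreground (label 1);
    with ``scattered_foreground`` the same number of tips is drawn at
    random instead, emulating a non-monophyletic alpine set.
    """
    from dendropy.simulate import treesim

    rng = random.Random(config.seed)
    dtree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_tips,
        rng=rng,
    )
    tree = Tree.from_dendropy(dtree)
    for i, tip in enumerate(tree.tips, start=1):
        tip.name = f"s{i}"
    depth = tree.max_depth()
    if depth <= 0:
        raise ValueError("degenerate simulated tree")
    tree.scale(config.depth / depth)

    n_fg = max(1, min(config.n_tips - 1, round(config.foreground_fraction * config.n_tips)))
    if config.scattered_foreground:
        chosen = set(rng.sample([t.name for t in tree.tips], n_fg))
    else:
        best, best_node = None, None
        for node in tree.postorder():
            if node.is_leaf or node is tree.root:
                continue
            size = len(tree.clade_tips(node))
            score = abs(size - n_fg)
            if best is None or score < best:
                best, best_node = score, node
        chosen = {t.name for t in tree.clade_tips(best_node)}
    for tip in tree.tips:
        tip.group = 1 if tip.name in chosen else 0
    return tree


def foreground_branch_set(tree: Tree) -> frozenset[int]:
    """Branches whose entire subtree is foreground (includes the clade stem)."""
    fg = set()
    status: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            status[node.index] = node.group == 1
        else:
            status[node.index] = all(status[c.index] for c in node.children)
        if status[node.index] and node is not tree.root:
            fg.add(node.index)
    return frozenset(fg)


def simulate_codon_evolution(
    tree: Tree,
    config: SimulationConfig,
    gene: str = "GENE",
    n_codons: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[GeneAlignment, SimulationTruth]:
    """Gillespie simulation of codon evolution along the tree.

    The root sequence is drawn from the F1x4 equilibrium; along each branch
    each site waits exponential times and jumps to a single-nucleotide
    neighbour with probability proportional to its MG94 rate.  Every event
    is logged with its synonymous/nonsynonymous label, and the log replayed
    from the root reproduces the tip sequences exactly.
    """
    code = get_code(config.code_id)
    n_codons = n_codons or config.n_codons
    rng = rng or np.random.default_rng(config.seed)
    fg = foreground_branch_set(tree)
    tables = {
        "foreground": _RateTable(config, code, config.omega_foreground),
        "background": _RateTable(config, code, config.omega_background),
    }
    codons = tables["background"].codons
    pi = codon_equilibrium(config, code)
    probs = np.array([pi[c] for c in codons])
    root_seq = rng.choice(len(codons), size=n_codons, p=probs)

    seqs: dict[int, np.ndarray] = {tree.root.index: root_seq}
    events: list[SimEvent] = []
    branch_totals: dict[int, dict[str, float]] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        table = tables["foreground" if node.index in fg else "background"]
        seq = seqs[node.parent.index].copy()
        totals = {"syn": 0.0, "nonsyn": 0.0}
        blen = node.length
        for site in range(n_codons):
            state = seq[site]
            t = rng.exponential(1.0 / table.total[state]) if table.total[state] > 0 else np.inf
            while t < blen:
                r = table.rates[state]
                j = rng.choice(len(r), p=r / r.sum())
                target = int(table.targets[state][j])
                kind = "syn" if table.syn[state][j] else "nonsyn"
                events.append(
                    SimEvent(node.index, site, codons[state], codons[target], kind, t)
                )
                totals[kind] += 1
                state = target
                dt = rng.exponential(1.0 / table.total[state]) if table.total[state] > 0 else np.inf
                t += dt
            seq[site] = state
        seqs[node.index] = seq
        branch_totals[node.index] = totals

    records = [
        SequenceRecord(tip.name, "".join(codons[i] for i in seqs[tip.index]))
        for tip in tree.tips
    ]
    truth = SimulationTruth(
        newick=tree.to_newick(),
        root_sequence="".join(codons[i] for i in root_seq),
        events=events,
        branch_totals=branch_totals,
        true_omega={
            "foreground": config.omega_foreground,
            "background": config.omega_background,
        },
        foreground_branches=fg,
        config=config,
    )
    return GeneAlignment(gene, records), truth


def replay_events(truth: SimulationTruth, tree: Tree) -> dict[str, str]:
    """Replay the event log from the root; returns tip name -> sequence."""
    n = len(truth.root_sequence) // 3
    root = [truth.root_sequence[3 * i : 3 * i + 3] for i in range(n)]
    by_branch: dict[int, list[SimEvent]] = {}
    for e in truth.events:
        by_branch.setdefault(e.branch, []).append(e)
    seqs = {tree.root.index: root}
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        seq = list(seqs[node.parent.index])
        for e in sorted(by_branch.get(node.index, []), key=lambda e: e.time):
            if seq[e.site] != e.from_codon:
                raise ValueError("event log inconsistent with sequence state")
            seq[e.site] = e.to_codon
        seqs[node.index] = seq
        if node.is_leaf:
            out[node.name] = "".join(seq)
    return out


# --------------------------------------------------------------------------
# Environmental metadata
# --------------------------------------------------------------------------


@dataclass
class EnvSimConfig:
    """Altitude-driven bioclimatic table generator.

    Temperature-type variables (BIO1-BIO11, WorldClim units of degC x 10)
    decrease with altitude at a standard lapse rate of 6.5 degC per km;
    precipitation-type variables (BIO12-BIO19, mm) increase mildly.  Noise
    is Gaussian per variable.  ``lapse_scale=0`` gives an
    altitude-independent (null) environment.
    """

    seed: int
    alt_foreground: float = 4500.0
    alt_background: float = 200.0
    altitude_sd: float = 200.0
    lapse_scale: float = 1.0
    noise_sd_temperature: float = 10.0  # degC x 10 units
    noise_sd_precipitation: float = 30.0  # mm

    def coefficients(self) -> dict[str, tuple[float, float]]:
        """BIO variable -> (intercept at sea level, per-metre slope)."""
        coef = {}
        for i in range(1, 12):  # temperature block
            coef[f"BIO{i}"] = (150.0 + 10.0 * i, -0.065 * self.lapse_scale)
        for i in range(12, 20):  # precipitation block
            coef[f"BIO{i}"] = (300.0 + 20.0 * i, 0.02 * self.lapse_scale)
        return coef


def simulate_env_metadata(
    tips: dict[str, int], config: EnvSimConfig
) -> pd.DataFrame:
    """Environment table for labelled tips (group 1 = high altitude)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    coef = config.coefficients()
    for name in tips:
        group = int(tips[name])
        base_alt = config.alt_foreground if group == 1 else config.alt_background
        alt = max(0.0, base_alt + rng.normal(0.0, config.altitude_sd))
        row = {"species_id": name, "group": group, "altitude_m": alt}
        for i in range(1, 20):
            a, b = coef[f"BIO{i}"]
            sd = config.noise_sd_temperature if i <= 11 else config.noise_sd_precipitation
            row[f"BIO{i}"] = a + b * alt + rng.normal(0.0, sd)
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id")


# --------------------------------------------------------------------------
# Fixture bundles
# --------------------------------------------------------------------------


def scenario_config(scenario: str, seed: int, **overrides) -> tuple[SimulationConfig, EnvSimConfig]:
    """Study-condition presets for the four validation scenarios."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    omega = {
        "neutral": (1.0, 1.0),
        "purifying": (0.2, 0.2),
        "foreground_elevated": (0.6, 0.2),
        "null_env": (0.2, 0.2),
    }[scenario]
    sim = SimulationConfig(
        seed=seed, omega_foreground=omega[0], omega_background=omega[1], **overrides
    )
    env = EnvSimConfig(
        seed=seed + 1, lapse_scale=0.0 if scenario == "null_env" else 1.0
    )
    return sim, env


def make_fixture_bundle(
    out_dir: str | Path,
    scenario: str,
    seed: int,
    gene_codons: Optional[dict[str, int]] = None,
    n_tips: int = 29,
    include_events: bool = False,
) -> dict[str, Path]:
    """Write a complete synthetic dataset: 13 gene FASTAs, tree, env, truth.

    The same (scenario, seed) always produces byte-identical files; a
    manifest with SHA-256 checksums is written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_codons = gene_codons or DEFAULT_GENE_CODONS
    sim_cfg, env_cfg = scenario_config(scenario, seed, n_tips=n_tips)
    tree = simulate_tree(sim_cfg)
    files: dict[str, Path] = {}
    truth_summary = {
        "scenario": scenario,
        "seed": seed,
        "omega_foreground": sim_cfg.omega_foreground,
        "omega_background": sim_cfg.omega_background,
        "at_fraction": sim_cfg.at_fraction,
        "kappa": sim_cfg.kappa,
        "depth": sim_cfg.depth,
        "n_tips": n_tips,
        "tip_groups": {t.name: t.group for t in tree.tips},
        "genes": {},
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_147_000]))
    for gene in sorted(gene_codons):
        aln, truth = simulate_codon_evolution(
            tree, sim_cfg, gene=gene, n_codons=gene_codons[gene], rng=rng
        )
        path = out / f"{gene}.fasta"
        write_fasta(aln.records, path)
        files[gene] = path
        totals = {"syn": 0.0, "nonsyn": 0.0}
        for t in truth.branch_totals.values():
            totals["syn"] += t["syn"]
            totals["nonsyn"] += t["nonsyn"]
        entry: dict = {"n_codons": gene_codons[gene], "event_totals": totals}
        if include_events:
            entry["events"] = [asdict(e) for e in truth.events]
        truth_summary["genes"][gene] = entry

    tree_path = out / "tree.nwk"
    tree_path.write_text(tree.to_newick() + "\n")
    files["tree"] = tree_path

    env = simulate_env_metadata({t.name: t.group for t in tree.tips}, env_cfg)
    env_path = out / "env.tsv"
    env.reset_index().to_csv(env_path, sep="\t", index=False, float_format="%.6g")
    files["env"] = env_path

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_summary, indent=1, sort_keys=True))
    files["truth"] = truth_path

    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tsha256\n")
        for name in sorted(files):
            digest = hashlib.sha256(files[name].read_bytes()).hexdigest()
            fh.write(f"{files[name].name}\t{digest}\n")
    files["manifest"] = manifest
    return files
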