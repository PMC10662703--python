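"""End-to-end orchestration: inputs (real or simulated) through codon usage,
variation, selection and the comparative layer, emitting TSV report tables.

Every stage receives a child seed derived deterministically from the single
pipeline seed (numpy ``SeedSequence([seed, stage_offset])``), so a rerun
with the same config and inputs is byte-identical apart from the run log's
timestamp, and each stage is individually reproducible.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .code import get_code
from .codon_usage import (
    composition_and_skew,
    codon_usage_summary,
    count_codons,
    neutrality_regression,
    rscu,
)
from .comparative import (
    env_distance_matrix,
    glm_env,
    mantel_test,
    pic_contrasts,
    pic_regression,
    trait_distance_matrix,
)
from .io import (
    GeneAlignment,
    concatenate_partitions,
    read_env_table,
    read_gene_alignments,
    read_newick,
    write_tsv,
)
from .selection import (
    group_omega_contrast,
    ng86_pairwise,
    slac_site_test,
    terminal_branch_omegas,
)
from .simulate import make_fixture_bundle
from .tree import Tree
from .variation import (
    classify_sites,
    count_syn_nonsyn_mutations,
    mutation_length_regressions,
    nucleotide_diversity,
)

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {"simulate": 11, "selection": 13, "comparative": 17}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence([seed, _STAGE_OFFSETS.get(stage, 97)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str | Path
    # real-input mode
    alignments: Optional[dict[str, str | Path]] = None
    tree_path: Optional[str | Path] = None
    env_path: Optional[str | Path] = None
    # synthetic mode
    scenario: Optional[str] = None
    n_tips: int = 29
    gene_codons: Optional[dict[str, int]] = None
    # analysis parameters
    code_id: int = 5
    site_threshold: float = 0.1
    window: int = 100
    step: int = 25
    n_perm_contrast: int = 999
    n_perm_mantel: int = 9999
    run_site_tests: bool = True

    def __post_init__(self) -> None:
        real = self.alignments is not None and self.tree_path is not None
        if not real and self.scenario is None:
            raise ValueError("either real inputs or a synthetic scenario must be set")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path] = field(default_factory=dict)
    run_log: Optional[Path] = None


def _provenance(config: PipelineConfig) -> list[str]:
    return [
        f"mitosel {__version__}",
        f"seed={config.seed} code_id={config.code_id} scenario={config.scenario}",
    ]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage in dependency order and write the report tables.

    A missing environment table degrades gracefully: the comparative tables
    are skipped with a log message while everything upstream is still
    emitted.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = get_code(config.code_id)
    comments = _provenance(config)

    # ---- inputs ----------------------------------------------------------
    if config.scenario is not None:
        input_dir = out / "inputs"
        files = make_fixture_bundle(
            input_dir,
            config.scenario,
            stage_seed(config.seed, "simulate"),
            gene_codons=config.gene_codons,
            n_tips=config.n_tips,
        )
        aln_paths = {g: p for g, p in files.items() if p.suffix == ".fasta"}
        tree = read_newick(files["tree"])
        env = read_env_table(files["env"])
    else:
        aln_paths = dict(config.alignments)
        tree = read_newick(config.tree_path)
        env = read_env_table(config.env_path) if config.env_path else None

    genes = read_gene_alignments(aln_paths, strict=False)
    concat = concatenate_partitions(genes)
    taxa = concat.matrix.ids
    tables: dict[str, pd.DataFrame] = {}

    # ---- codon usage -----------------------------------------------------
    comp_rows = []
    for rec in concat.matrix.records:
        c = composition_and_skew(rec)
        comp_rows.append(
            dict(species=rec.id, gene="concatenated", A=c.a, T=c.t, C=c.c, G=c.g,
                 at_content=c.at_content, at_skew=c.at_skew, gc_skew=c.gc_skew)
        )
    for gene, aln in sorted(genes.items()):
        for rec in aln.records:
            try:
                c = composition_and_skew(rec)
            except ValueError:
                continue
            comp_rows.append(
                dict(species=rec.id, gene=gene, A=c.a, T=c.t, C=c.c, G=c.g,
                     at_content=c.at_content, at_skew=c.at_skew, gc_skew=c.gc_skew)
            )
    tables["composition"] = pd.DataFrame(comp_rows)

    usage_rows, rscu_rows, points = [], [], []
    for rec in concat.matrix.records:
        summary = codon_usage_summary(rec, code)
        usage_rows.append(
            dict(species=rec.id, enc=summary.enc, gc3s=summary.gc3s,
                 gc12=summary.gc12, pr2_x=summary.pr2_x, pr2_y=summary.pr2_y)
        )
        points.append((summary.gc3s, summary.gc12))
        table = rscu(count_codons(rec.residues, code))
        row = {"species": rec.id}
        for codon in sorted(table.rscu):
            row[codon] = table.rscu[codon]
        rscu_rows.append(row)
    tables["codon_usage_summary"] = pd.DataFrame(usage_rows)
    tables["rscu_matrix"] = pd.DataFrame(rscu_rows)
    fit = neutrality_regression(points)
    tables["neutrality_regression"] = pd.DataFrame(
        [dict(slope=fit.slope, intercept=fit.intercept, r_squared=fit.r_squared,
              p_value=fit.p_value, n=fit.n)]
    )

    # ---- variation -------------------------------------------------------
    var_rows, pi_rows, per_gene = [], [], []
    groups = {t.name: t.group for t in tree.tips if t.group is not None}
    if not groups and env is not None and "group" in env.columns:
        groups = {s: int(env.loc[s, "group"]) for s in env.index if s in taxa}
    for gene, aln in sorted(genes.items()):
        sc = classify_sites(aln)
        mc = count_syn_nonsyn_mutations(aln, code)
        window = min(config.window, aln.length)
        div = nucleotide_diversity(aln, window=window, step=config.step)
        var_rows.append(
            dict(gene=gene, length=aln.length, n_sites=sc.n_sites,
                 conserved=sc.conserved, variable=sc.variable,
                 singleton=sc.singleton,
                 parsimony_informative=sc.parsimony_informative,
                 pi=div.pi, total_mutations=mc.total_mutations,
                 synonymous=mc.synonymous, nonsynonymous=mc.nonsynonymous,
                 mixed=mc.mixed_flagged)
        )
        per_gene.append((aln.length, mc.total_mutations, mc.synonymous, mc.nonsynonymous))
        subsets = {"all": aln}
        if groups:
            for label, name in ((1, "alpine"), (0, "lowland")):
                members = [t for t in aln.ids if groups.get(t) == label]
                if len(members) >= 2:
                    subsets[name] = aln.subset(members)
        for name, sub in subsets.items():
            d = nucleotide_diversity(sub, window=window, step=config.step)
            for mid, pi in d.windows:
                pi_rows.append(dict(gene=gene, group=name, midpoint=mid, pi=pi))
    tables["variation"] = pd.DataFrame(var_rows)
    tables["sliding_pi"] = pd.DataFrame(pi_rows)
    fits = mutation_length_regressions(per_gene)
    tables["regressions"] = pd.DataFrame(
        [dict(fit=k, slope=v.slope, intercept=v.intercept, r_squared=v.r_squared,
              p_value=v.p_value, n=v.n) for k, v in fits.items()]
    )

    # ---- selection -------------------------------------------------------
    sel_seed = stage_seed(config.seed, "selection")
    ng_rows, site_rows, contrast_rows = [], [], []
    omega_by_gene: dict[str, dict[str, float]] = {}
    for gene, aln in sorted(genes.items()):
        for a, b in combinations(aln.records, 2):
            res = ng86_pairwise(a.residues, b.residues, code)
            ng_rows.append(
                dict(gene=gene, seq1=a.id, seq2=b.id, S=res.S_sites, N=res.N_sites,
                     Sd=res.Sd, Nd=res.Nd, dS=res.dS, dN=res.dN, omega=res.omega,
                     flags=";".join(sorted(res.flags)))
            )
        branch = terminal_branch_omegas(aln, tree, code, seed=sel_seed)
        omega_by_gene[gene] = {b.tip: b.omega for b in branch}
        if config.run_site_tests:
            for site in slac_site_test(
                aln, tree, code, threshold=config.site_threshold, seed=sel_seed
            ):
                if site.classification != "neutral" or site.observed_nonsyn > 0:
                    site_rows.append(
                        dict(gene=gene, codon=site.codon_index,
                             syn=site.observed_syn, nonsyn=site.observed_nonsyn,
                             expected_nonsyn_fraction=site.expected_nonsyn_fraction,
                             p_positive=site.p_positive, p_negative=site.p_negative,
                             classification=site.classification)
                    )
        if groups and len(set(groups.values())) == 2:
            try:
                contrast = group_omega_contrast(
                    aln, tree, groups, n_perm=config.n_perm_contrast,
                    seed=sel_seed, code=code, branch_omegas=branch,
                )
            except ValueError as exc:
                logger.warning("gene %s: group contrast skipped: %s", gene, exc)
                continue
            contrast_rows.append(
                dict(gene=gene, omega_foreground=contrast.omega_foreground,
                     omega_background=contrast.omega_background,
                     delta=contrast.delta, p_perm=contrast.p_perm,
                     n_perm=contrast.n_perm, seed=contrast.seed)
            )
    tables["ng86_pairwise"] = pd.DataFrame(ng_rows)
    if config.run_site_tests:
        tables["site_selection"] = pd.DataFrame(site_rows)
    if contrast_rows:
        tables["group_contrast"] = pd.DataFrame(contrast_rows)

    # ---- comparative -----------------------------------------------------
    if env is not None:
        comp_seed = stage_seed(config.seed, "comparative")
        altitude = {s: float(env.loc[s, "altitude_m"]) for s in env.index if s in taxa}
        pic_rows = []
        for gene in sorted(omega_by_gene):
            omegas = omega_by_gene[gene]
            usable = [t for t in taxa
                      if t in altitude and not math.isnan(omegas.get(t, math.nan))]
            if len(usable) < 4:
                continue
            sub = _prune_to(tree, usable)
            x = pic_contrasts(sub, altitude)
            y = pic_contrasts(sub, omegas)
            fit = pic_regression(x, y)
            pic_rows.append(
                dict(gene=gene, slope=fit.slope, r_squared=fit.r_squared,
                     p_value=fit.p_value, n_contrasts=fit.n)
            )
        tables["pic"] = pd.DataFrame(pic_rows)

        omega_df = pd.DataFrame(omega_by_gene).loc[[t for t in taxa if t in env.index]]
        complete = omega_df.dropna()
        if len(complete) >= 4:
            m_omega = trait_distance_matrix(complete)
            m_env = env_distance_matrix(env.loc[complete.index])
            mantel = mantel_test(m_omega, m_env, n_perm=config.n_perm_mantel,
                                 seed=comp_seed)
            tables["mantel"] = pd.DataFrame(
                [dict(r=mantel.r, p=mantel.p, n_perm=mantel.n_perm,
                      n_species=len(complete), seed=mantel.seed)]
            )
        glm_rows = []
        for gene in sorted(omega_by_gene):
            try:
                (res,) = glm_env({gene: omega_by_gene[gene]}, env)
            except ValueError as exc:
                logger.warning("gene %s: GLM skipped: %s", gene, exc)
                continue
            for var in res.retained:
                glm_rows.append(
                    dict(gene=res.gene, variable=var,
                         coefficient=res.coefficients[var],
                         p_value=res.p_values[var], n=res.n)
                )
            if not res.retained:
                glm_rows.append(dict(gene=res.gene, variable="(none)",
                                     coefficient=math.nan, p_value=math.nan,
                                     n=res.n))
        tables["glm"] = pd.DataFrame(glm_rows)
    else:
        logger.warning("no environment table: comparative stage skipped")

    # ---- write -----------------------------------------------------------
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        write_tsv(df, path, comments=comments)
        paths[name] = path
    run_log = out / "run_log.txt"
    with open(run_log, "w") as fh:
        fh.write(f"mitosel {__version__}\n")
        fh.write(f"config: {config}\n")
        fh.write(f"elapsed_s: {time.time() - t0:.2f}\n")
    return ReportBundle(tables, paths, run_log)


def _prune_to(tree: Tree, keep: list[str]) -> Tree:
    """Binary subtree restricted to the given tips (lengths summed through
    removed unary nodes)."""
    keep_set = set(keep)

    def build(node):
        if node.is_leaf:
            return (node.name, node.length) if node.name in keep_set else None
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            name, length = kids[0]
            return (name, length + node.length)
        return (kids, node.length)

    from .tree import Node

    def to_nodes(shape, length):
        if isinstance(shape, str):
            return Node(shape, length)
        node = Node(None, length)
        for child_shape, child_len in shape:
            node.add(to_nodes(child_shape, child_len))
        return node

    top = build(tree.root)
    if top is None:
        raise ValueError("no tips retained")
    shape, _ = top
    if isinstance(shape, str):
        raise ValueError("cannot prune to a single tip")
    root = to_nodes(shape, 0.0)
    pruned = Tree(root)
    groups = {t.name: t.group for t in tree.tips}
    for tip in pruned.tips:
        tip.group = groups.get(tip.name)
    return pruned
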