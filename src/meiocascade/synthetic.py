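"""Seeded generators for every input the pipeline consumes.

Each generator plants a recoverable ground truth — upregulated genes,
apex regulators with zero regulatory in-degree, over-represented
annotation terms, and codon alignment pairs evolved under a target
nonsynonymous/synonymous acceptance ratio — so downstream stages have
parameter-recovery tests without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ExpressionDataset
from .molevo import (
    _AA,
    CodonAlignmentPair,
    OrthologPair,
    SENSE_CODONS,
    STOP_CODONS,
)

_BASES = "ACGT"

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_networks",
    "simulate_codon_pair",
    "simulate_annotations",
    "simulate_ortholog_study",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    n_samples_per_condition: int = 5
    n_planted_up: int = 50
    planted_lfc: float = 2.0
    noise_sd: float = 0.3
    n_tfs: int = 8
    n_planted_mrs: int = 3
    ppin_edge_prob: float = 0.01
    ppin_attachment: str = "erdos-renyi"  # or "preferential"
    ppin_m: int = 3  # edges per node for preferential attachment
    n_terms: int = 50
    term_size: int = 30
    planted_term_fraction: float = 0.8
    n_codons: int = 300
    branch_mutation_attempts: float = 0.4  # expected substitution attempts per codon
    omega_by_group: dict[str, float] = field(
        default_factory=lambda: {"initiation": 0.3, "commitment": 0.1}
    )

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples_per_condition, self.n_tfs) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_planted_up < 0 or self.n_planted_up > self.n_genes:
            raise ConfigurationError("n_planted_up out of range")
        if not (1 <= self.n_planted_mrs <= self.n_tfs <= self.n_genes):
            raise ConfigurationError("need 1 <= n_planted_mrs <= n_tfs <= n_genes")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if any(w <= 0 for w in self.omega_by_group.values()):
            raise ConfigurationError("planted omega values must be > 0")


@dataclass
class GroundTruth:
    up_gene_ids: dict[str, set[str]] = field(default_factory=dict)  # contrast -> genes
    mr_ids: set[str] = field(default_factory=set)
    tf_ids: set[str] = field(default_factory=set)
    enriched_term_ids: set[str] = field(default_factory=set)
    omega_true: dict[str, float] = field(default_factory=dict)  # pair id -> omega


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_expression(
    config: SimulationConfig,
    contrast_label: str = "contrast",
    planted_gene_ids: set[str] | None = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Two-condition expression matrix with planted upregulated genes.

    Intensities are generated on the log2 scale (Gaussian noise around
    per-gene baselines, planted genes shifted by planted_lfc in the
    treatment group) and exponentiated, so the screening stage's log
    transform round-trips.
    """
    config.validate()
    if config.n_samples_per_condition < 2:
        raise ConfigurationError("need >= 2 samples per condition")
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n = config.n_samples_per_condition
    samples = [f"ctl_{i+1}" for i in range(n)] + [f"trt_{i+1}" for i in range(n)]
    condition_of = {s: ("control" if s.startswith("ctl") else "treatment") for s in samples}

    # Gaussian baseline: a sparse upper tail limits the reference-distortion
    # quantile normalization suffers when differential expression is one-sided
    baseline = rng.normal(9.0, 1.8, size=config.n_genes)
    if planted_gene_ids is None:
        planted_idx = rng.choice(config.n_genes, size=config.n_planted_up, replace=False)
    else:
        index = {g: i for i, g in enumerate(genes)}
        stray = set(planted_gene_ids) - set(index)
        if stray:
            raise ConfigurationError(f"planted genes outside universe: {sorted(stray)[:5]}")
        planted_idx = np.array(sorted(index[g] for g in planted_gene_ids), dtype=int)
    shift = np.zeros(config.n_genes)
    shift[planted_idx] = config.planted_lfc

    log2 = np.empty((config.n_genes, 2 * n))
    log2[:, :n] = baseline[:, None] + rng.normal(0, config.noise_sd, (config.n_genes, n))
    log2[:, n:] = (baseline + shift)[:, None] + rng.normal(
        0, config.noise_sd, (config.n_genes, n)
    )
    matrix = pd.DataFrame(np.exp2(log2), index=genes, columns=samples)
    truth = GroundTruth(
        up_gene_ids={contrast_label: {genes[i] for i in planted_idx}}
    )
    return ExpressionDataset(matrix=matrix, condition_of=condition_of), truth


def simulate_networks(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Interaction and regulation edge tables with planted master regulators.

    Planted MRs receive no incoming regulatory edge and regulate >= 1
    target; every non-MR TF receives >= 1 incoming regulatory edge.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    tf_idx = rng.choice(config.n_genes, size=config.n_tfs, replace=False)
    tfs = [genes[i] for i in tf_idx]
    mrs = set(rng.choice(tfs, size=config.n_planted_mrs, replace=False).tolist())
    non_mr_tfs = [t for t in tfs if t not in mrs]
    non_tf_genes = [g for g in genes if g not in set(tfs)]
    if not non_tf_genes:
        raise ConfigurationError("no non-TF genes available as targets")

    reg_edges: set[tuple[str, str]] = set()
    # every TF regulates a handful of non-TF targets (never a planted MR)
    for tf in tfs:
        k = int(rng.integers(2, max(3, min(8, len(non_tf_genes)))))
        for tgt in rng.choice(non_tf_genes, size=min(k, len(non_tf_genes)), replace=False):
            reg_edges.add((tf, str(tgt)))
    # every non-MR TF gets >= 1 incoming edge from a planted MR
    mr_list = sorted(mrs)
    for tf in non_mr_tfs:
        src = mr_list[int(rng.integers(len(mr_list)))]
        reg_edges.add((src, tf))
    assert all(tgt not in mrs for _, tgt in reg_edges)

    # undirected interactions over the gene universe
    ppin_edges: set[tuple[str, str]] = set()
    if config.ppin_attachment == "preferential":
        import networkx as nx

        g = nx.barabasi_albert_graph(
            config.n_genes, min(config.ppin_m, config.n_genes - 1),
            seed=int(rng.integers(2**31)),
        )
        for a, b in g.edges:
            ppin_edges.add(tuple(sorted((genes[a], genes[b]))))
    else:
        n = config.n_genes
        iu, ju = np.triu_indices(n, k=1)
        hit = rng.random(iu.size) < config.ppin_edge_prob
        for a, b in zip(iu[hit], ju[hit]):
            ppin_edges.add((genes[a], genes[b]))

    interactions = pd.DataFrame(sorted(ppin_edges), columns=["gene_a", "gene_b"])
    regulation = pd.DataFrame(sorted(reg_edges), columns=["tf", "target"])
    truth = GroundTruth(mr_ids=set(mrs), tf_ids=set(tfs))
    return interactions, regulation, truth


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _evolve(
    codons: list[str],
    attempts: int,
    omega: float,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Propose ``attempts`` uniform single-base changes; accept synonymous
    always, nonsynonymous with probability omega; never create stops."""
    seq = list(codons)
    n = len(seq)
    n_syn = n_nonsyn = 0
    for _ in range(attempts):
        i = int(rng.integers(n))
        pos = int(rng.integers(3))
        codon = seq[i]
        base = _BASES[int(rng.integers(4))]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if _AA[mutant] == _AA[codon]:
            seq[i] = mutant
            n_syn += 1
        elif rng.random() < omega:
            seq[i] = mutant
            n_nonsyn += 1
    return seq, n_syn, n_nonsyn


def simulate_codon_pair(
    n_codons: int,
    omega_target: float,
    divergence: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    meta: OrthologPair | None = None,
) -> tuple[CodonAlignmentPair, dict[str, float]]:
    """Evolve two lineages from a random sense-codon ancestor.

    ``divergence`` is the expected number of substitution attempts per
    codon summed over both branches. Returns the gap-free alignment and a
    record of the target omega and realized accepted change counts.
    """
    if n_codons < 50:
        raise ConfigurationError("n_codons must be >= 50")
    if omega_target <= 0:
        raise ConfigurationError("omega_target must be > 0")
    if omega_target > 1:
        raise ConfigurationError(
            "omega_target > 1 unsupported (purifying/neutral regimes only)"
        )
    if divergence < 0:
        raise ConfigurationError("divergence must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor = _random_sense_codons(rng, n_codons)
    per_branch = divergence * n_codons / 2.0
    attempts_a = int(rng.poisson(per_branch))
    attempts_b = int(rng.poisson(per_branch))
    seq_a, syn_a, non_a = _evolve(ancestor, attempts_a, omega_target, rng)
    seq_b, syn_b, non_b = _evolve(ancestor, attempts_b, omega_target, rng)
    pair = CodonAlignmentPair("".join(seq_a), "".join(seq_b), meta=meta)
    realized = {
        "omega_target": omega_target,
        "accepted_syn": float(syn_a + syn_b),
        "accepted_nonsyn": float(non_a + non_b),
    }
    return pair, realized


def simulate_annotations(
    config: SimulationConfig,
    target_set: set[str],
    n_planted_terms: int = 2,
) -> tuple[dict[str, list[str]], GroundTruth]:
    """GMT-style term -> member map with planted over-represented terms.

    Null terms draw members uniformly from the gene universe; each planted
    term draws ``planted_term_fraction`` of its members from target_set.
    """
    config.validate()
    if n_planted_terms > 0 and not target_set:
        raise ConfigurationError("planted terms requested but target_set is empty")
    if n_planted_terms > config.n_terms:
        raise ConfigurationError("more planted terms than terms")
    if config.term_size > config.n_genes:
        raise ConfigurationError("term size exceeds gene universe")
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    universe = set(genes)
    stray = target_set - universe
    if stray:
        raise ConfigurationError(f"target genes outside universe: {sorted(stray)[:5]}")

    target = sorted(target_set)
    background = sorted(universe - target_set)
    terms: dict[str, list[str]] = {}
    planted_ids: set[str] = set()
    for t in range(config.n_terms):
        term_id = f"T{t+1:04d}"
        if t < n_planted_terms:
            k_target = min(
                int(round(config.planted_term_fraction * config.term_size)), len(target)
            )
            members = set(
                rng.choice(target, size=k_target, replace=False).tolist()
            )
            fill = config.term_size - len(members)
            if fill > 0:
                members |= set(rng.choice(background, size=fill, replace=False).tolist())
            planted_ids.add(term_id)
        else:
            members = set(rng.choice(genes, size=config.term_size, replace=False).tolist())
        terms[term_id] = sorted(members)
    truth = GroundTruth(enriched_term_ids=planted_ids)
    return terms, truth


def simulate_ortholog_study(
    config: SimulationConfig,
    n_pairs_by_group: dict[str, int],
    species: str = "SpX",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, CodonAlignmentPair], GroundTruth]:
    """Ortholog metadata plus codon alignments for a two-phase comparison.

    Pair omega targets come from ``config.omega_by_group``; divergence from
    ``config.branch_mutation_attempts`` (per codon, both branches pooled).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    alignments: dict[str, CodonAlignmentPair] = {}
    truth = GroundTruth()
    for group, n_pairs in sorted(n_pairs_by_group.items()):
        omega = config.omega_by_group[group]
        for i in range(n_pairs):
            pair_id = f"{group}_{species}_{i+1:04d}"
            meta = OrthologPair(
                gene_a=f"{pair_id}_a",
                gene_b=f"{pair_id}_b",
                species=species,
                orthology_type="one-to-one",
                confidence=1.0,
                percent_identity=100.0,
                group_label=group,
            )
            aln, _ = simulate_codon_pair(
                config.n_codons,
                omega,
                config.branch_mutation_attempts,
                rng=rng,
                meta=meta,
            )
            alignments[pair_id] = aln
            truth.omega_true[pair_id] = omega
            rows.append(
                (pair_id, meta.gene_a, meta.gene_b, species, meta.orthology_type,
                 meta.confidence, meta.percent_identity, group)
            )
    pairs = pd.DataFrame(
        rows,
        columns=["pair_id", "gene_a", "gene_b", "species", "orthology_type",
                 "confidence", "percent_identity", "group_label"],
    )
    return pairs, alignments, truth
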