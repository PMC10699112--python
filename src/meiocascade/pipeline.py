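"""End-to-end orchestration: synthetic study emission and the run-all driver.

``simulate_study`` writes a complete two-phase study (expression contrasts,
edge tables, annotations, ortholog alignments, ground truth and a pipeline
config) to a directory; ``run_all`` consumes such a config, executes the
screening -> network -> enrichment -> comparison -> evolution stages and
writes a machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .cascade_compare import compare_cascades, summarize_cascade
from .diffexpr import commitment_gene_set, initiation_gene_set, test_differential
from .enrich import enriched_gene_pool, hypergeom_enrich
from .molevo import SaturationError, codon_z_test, filter_orthologs, ng86_pair, compare_phase_evolution
from .netbuild import build_grn, build_ppin, identify_mrs, integrate_cascade, top_tfs
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    simulate_annotations,
    simulate_expression,
    simulate_networks,
    simulate_ortholog_study,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "simulate_study", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


@dataclass
class ContrastSpec:
    matrix: str
    conditions: str
    control: str
    treatment: str


@dataclass
class PhaseSpec:
    label: str
    contrasts: list[ContrastSpec]
    set_logic: str  # intersect_up | up_minus_down
    ppin: str
    grn: str
    gmt: str | None = None


@dataclass
class EvolutionSpec:
    pairs: str
    aln_dir: str
    group_by_phase: dict[str, str] = field(default_factory=dict)  # phase label -> group_label


@dataclass
class Thresholds:
    alpha_deg: float = 0.05
    lfc_min: float = 1.0
    moderation: float = 0.0
    enrich_alpha: float = 0.05
    gesd_alpha: float = 0.05
    k_max: int = 5
    n_boot: int = 500
    confidence_min: float = 1.0
    identity_default: float = 30.0
    identity_by_species: dict[str, float] = field(default_factory=dict)
    require_significant: bool = True
    expand_neighbors: bool = True


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    phases: list[PhaseSpec]
    evolution: EvolutionSpec | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "deg": True, "network": True, "enrich": True,
            "compare": True, "evolution": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        phases = [
            PhaseSpec(
                label=p["label"],
                contrasts=[ContrastSpec(**c) for c in p["contrasts"]],
                set_logic=p["set_logic"],
                ppin=p["ppin"],
                grn=p["grn"],
                gmt=p.get("gmt"),
            )
            for p in raw["phases"]
        ]
        evolution = None
        if raw.get("evolution"):
            evolution = EvolutionSpec(**raw["evolution"])
        thresholds = Thresholds(**raw.get("thresholds", {}))
        cfg = cls(
            seed=int(raw["seed"]),
            outdir=raw["outdir"],
            phases=phases,
            evolution=evolution,
            thresholds=thresholds,
        )
        cfg.stages.update(raw.get("stages", {}))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "seed": self.seed,
            "outdir": self.outdir,
            "phases": [
                {
                    "label": p.label,
                    "contrasts": [dataclasses.asdict(c) for c in p.contrasts],
                    "set_logic": p.set_logic,
                    "ppin": p.ppin,
                    "grn": p.grn,
                    "gmt": p.gmt,
                }
                for p in self.phases
            ],
            "evolution": dataclasses.asdict(self.evolution) if self.evolution else None,
            "thresholds": dataclasses.asdict(self.thresholds),
            "stages": self.stages,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# Synthetic study emission
# ---------------------------------------------------------------------------

def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    sim: SimulationConfig | None = None,
    n_pairs_by_group: dict[str, int] | None = None,
) -> PipelineConfig:
    """Write a complete synthetic two-phase study and its pipeline config.

    Initiation: two replicate contrasts sharing one planted up-set
    (intersection logic). Commitment: one up contrast plus one
    return-to-growth contrast planting a partially overlapping down-set
    (subtraction logic). One regulatory/interaction universe serves both
    phases; ortholog pairs carry phase-specific target omega values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alns").mkdir(exist_ok=True)
    sim = sim or SimulationConfig(seed=seed)
    n_pairs_by_group = n_pairs_by_group or {"initiation": 60, "commitment": 60}

    truth = GroundTruth()

    # --- expression: initiation (two replicate runs, shared planted set)
    cfg1 = dataclasses.replace(sim, seed=seed)
    ds1, t1 = simulate_expression(cfg1, "init_run1")
    planted_init = t1.up_gene_ids["init_run1"]
    cfg2 = dataclasses.replace(sim, seed=seed + 1)
    ds2, _ = simulate_expression(cfg2, "init_run2", planted_gene_ids=planted_init)
    truth.up_gene_ids["initiation"] = set(planted_init)

    # --- expression: commitment (up contrast + overlapping down contrast)
    cfg3 = dataclasses.replace(sim, seed=seed + 2)
    ds3, t3 = simulate_expression(cfg3, "commit_up")
    planted_commit_up = t3.up_gene_ids["commit_up"]
    overlap = set(sorted(planted_commit_up)[: max(1, len(planted_commit_up) // 3)])
    cfg4 = dataclasses.replace(
        sim, seed=seed + 3, planted_lfc=-abs(sim.planted_lfc),
        n_planted_up=len(overlap),
    )
    ds4, _ = simulate_expression(cfg4, "commit_down", planted_gene_ids=overlap)
    truth.up_gene_ids["commitment"] = planted_commit_up - overlap

    for name, ds in (("init_run1", ds1), ("init_run2", ds2),
                     ("commit_up", ds3), ("commit_down", ds4)):
        mio.write_expression_tsv(ds, outdir / f"{name}.matrix.tsv",
                                 outdir / f"{name}.conditions.tsv")

    # --- networks (shared universe)
    net_cfg = dataclasses.replace(sim, seed=seed + 4)
    interactions, regulation, net_truth = simulate_networks(net_cfg)
    truth.mr_ids = net_truth.mr_ids
    truth.tf_ids = net_truth.tf_ids
    interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    regulation.to_csv(outdir / "regulation.tsv", sep="\t", index=False)

    # --- annotations (planted terms drawn from the initiation up-set)
    ann_cfg = dataclasses.replace(sim, seed=seed + 5)
    terms, ann_truth = simulate_annotations(ann_cfg, truth.up_gene_ids["initiation"])
    truth.enriched_term_ids = ann_truth.enriched_term_ids
    mio.write_gmt(terms, outdir / "annotations.gmt")

    # --- ortholog study
    evo_cfg = dataclasses.replace(sim, seed=seed + 6)
    pairs, alignments, evo_truth = simulate_ortholog_study(evo_cfg, n_pairs_by_group)
    truth.omega_true = evo_truth.omega_true
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    for pair_id, aln in alignments.items():
        mio.write_fasta_pair(
            aln, outdir / "alns" / f"{pair_id}.fasta",
            id_a=f"SCER|{aln.meta.gene_a}", id_b=f"{aln.meta.species}|{aln.meta.gene_b}",
        )

    mio.write_json_report(
        {
            "up_gene_ids": {k: sorted(v) for k, v in truth.up_gene_ids.items()},
            "mr_ids": sorted(truth.mr_ids),
            "tf_ids": sorted(truth.tf_ids),
            "enriched_term_ids": sorted(truth.enriched_term_ids),
            "omega_true": truth.omega_true,
        },
        outdir / "truth.json",
    )

    config = PipelineConfig(
        seed=seed,
        outdir=str(outdir / "results"),
        phases=[
            PhaseSpec(
                label="initiation",
                contrasts=[
                    ContrastSpec(str(outdir / "init_run1.matrix.tsv"),
                                 str(outdir / "init_run1.conditions.tsv"),
                                 "control", "treatment"),
                    ContrastSpec(str(outdir / "init_run2.matrix.tsv"),
                                 str(outdir / "init_run2.conditions.tsv"),
                                 "control", "treatment"),
                ],
                set_logic="intersect_up",
                ppin=str(outdir / "interactions.tsv"),
                grn=str(outdir / "regulation.tsv"),
                gmt=str(outdir / "annotations.gmt"),
            ),
            PhaseSpec(
                label="commitment",
                contrasts=[
                    ContrastSpec(str(outdir / "commit_up.matrix.tsv"),
                                 str(outdir / "commit_up.conditions.tsv"),
                                 "control", "treatment"),
                    ContrastSpec(str(outdir / "commit_down.matrix.tsv"),
                                 str(outdir / "commit_down.conditions.tsv"),
                                 "control", "treatment"),
                ],
                set_logic="up_minus_down",
                ppin=str(outdir / "interactions.tsv"),
                grn=str(outdir / "regulation.tsv"),
                gmt=str(outdir / "annotations.gmt"),
            ),
        ],
        evolution=EvolutionSpec(
            pairs=str(outdir / "pairs.tsv"),
            aln_dir=str(outdir / "alns"),
            group_by_phase={"initiation": "initiation", "commitment": "commitment"},
        ),
    )
    config.to_yaml(outdir / "config.yaml")
    return config


# ---------------------------------------------------------------------------
# run-all driver
# ---------------------------------------------------------------------------

def _preflight(config: PipelineConfig) -> None:
    paths: list[str] = []
    for phase in config.phases:
        for c in phase.contrasts:
            paths += [c.matrix, c.conditions]
        paths += [phase.ppin, phase.grn]
        if phase.gmt:
            paths.append(phase.gmt)
    if config.evolution and config.stages.get("evolution", True):
        paths += [config.evolution.pairs, config.evolution.aln_dir]
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise StageError(f"[preflight] missing inputs: {missing}")


def _phase_gene_set(phase: PhaseSpec, th: Thresholds) -> tuple[set[str], dict]:
    runs = []
    for c in phase.contrasts:
        ds = mio.read_expression_tsv(c.matrix, c.conditions)
        runs.append(
            test_differential(ds, c.control, c.treatment,
                              alpha=th.alpha_deg, lfc_min=th.lfc_min,
                              moderation=th.moderation)
        )
    if phase.set_logic == "intersect_up":
        genes = initiation_gene_set(runs)
    elif phase.set_logic == "up_minus_down":
        if len(runs) != 2:
            raise ValueError("up_minus_down needs exactly two contrasts")
        up = {r.gene_id for r in runs[0] if r.direction == "up"}
        down = {r.gene_id for r in runs[1] if r.direction == "down"}
        genes = commitment_gene_set(up, down)
    else:
        raise ValueError(f"unknown set_logic {phase.set_logic!r}")
    info = {
        "n_up_per_run": [sum(r.direction == "up" for r in run) for run in runs],
        "n_genes": len(genes),
    }
    return genes, info


def _grn_with_tf_closure(pool: set[str], binding, max_rounds: int = 10):
    """Restrict the binding table to the pool, then close over active TFs
    so TF->TF edges among retained regulators are kept."""
    targets = set(pool)
    grn = build_grn(targets, binding)
    for _ in range(max_rounds):
        closed = targets | grn.tfs
        if closed == targets:
            break
        targets = closed
        grn = build_grn(targets, binding)
    return grn


def run_all(config: PipelineConfig) -> dict:
    """Execute all enabled stages and write report.json under config.outdir."""
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {"seed": config.seed, "phases": {}}
    summaries = {}

    for phase in config.phases:
        tag = phase.label
        phase_report: dict = {}
        try:
            genes, deg_info = _phase_gene_set(phase, th)
            phase_report["deg"] = deg_info
            mio.write_gene_list(genes, outdir / f"{tag}.genes.txt")
        except Exception as exc:
            raise StageError(f"[deg:{tag}] {exc}") from exc

        if not config.stages.get("network", True):
            report["phases"][tag] = phase_report
            continue
        try:
            global_ppin = mio.read_interaction_tsv(phase.ppin)
            binding = mio.read_regulation_tsv(phase.grn)
            ppin = build_ppin(genes, global_ppin, expand_neighbors=th.expand_neighbors)
        except Exception as exc:
            raise StageError(f"[network:{tag}] {exc}") from exc

        pool = ppin.nodes
        if config.stages.get("enrich", True) and phase.gmt:
            try:
                annotations = mio.read_gmt(phase.gmt)
                query = pool & annotations.universe
                records = hypergeom_enrich(query, annotations, alpha=th.enrich_alpha)
                enriched = {r.term_id for r in records if r.enriched}
                enriched_pool = enriched_gene_pool(enriched, annotations, query)
                mio.write_enrichment_tsv(records, outdir / f"{tag}.enrichment.tsv")
                phase_report["enrich"] = {
                    "n_terms_tested": len(records),
                    "n_enriched_terms": len(enriched),
                    "enriched_terms": sorted(enriched),
                    "n_pool": len(enriched_pool),
                }
                if enriched_pool:
                    pool = enriched_pool
            except Exception as exc:
                raise StageError(f"[enrich:{tag}] {exc}") from exc

        try:
            grn = _grn_with_tf_closure(pool, binding)
            top, cutoff = top_tfs(grn)
            cascade = integrate_cascade(grn, ppin)
            mrs = identify_mrs(cascade)
            summaries[tag] = summarize_cascade(cascade, tag)
            mio.write_cascade_tables(cascade, outdir / f"{tag}.nodes.tsv",
                                     outdir / f"{tag}.edges.tsv")
            mio.export_graphml(cascade, outdir / f"{tag}.graphml")
            mio.export_sif(cascade, outdir / f"{tag}.sif")
            phase_report["network"] = {
                "n_ppin_nodes": len(ppin.nodes),
                "n_ppin_edges": len(ppin),
                "n_grn_tfs": len(grn.tfs),
                "n_grn_edges": len(grn),
                "top_tf_cutoff": cutoff,
                "top_tfs": sorted(top),
                "mr_ids": sorted(mrs),
                "n_cascade_nodes": len(cascade.nodes),
                "n_cascade_edges": len(cascade.edges),
            }
        except Exception as exc:
            raise StageError(f"[integrate:{tag}] {exc}") from exc
        report["phases"][tag] = phase_report

    if config.stages.get("compare", True) and len(summaries) == 2:
        try:
            (la, sa), (lb, sb) = summaries.items()
            cmp = compare_cascades(sa, sb)
            report["comparison"] = {
                "phase_a": la,
                "phase_b": lb,
                "counts": cmp.counts(),
                "unique_total_a": cmp.unique_total("a"),
                "unique_total_b": cmp.unique_total("b"),
            }
        except Exception as exc:
            raise StageError(f"[compare] {exc}") from exc

    if config.stages.get("evolution", True) and config.evolution:
        try:
            report["evolution"] = _run_evolution(config)
        except Exception as exc:
            raise StageError(f"[evolution] {exc}") from exc

    mio.write_json_report(report, outdir / "report.json")
    return report


def _run_evolution(config: PipelineConfig) -> dict:
    th = config.thresholds
    evo = config.evolution
    assert evo is not None
    frame = mio.read_ortholog_tsv(evo.pairs)
    pairs = mio.ortholog_pairs_from_frame(frame)
    metas = [m for _, m in pairs]
    kept = set(
        id(m) for m in filter_orthologs(
            metas, th.identity_by_species,
            confidence_min=th.confidence_min,
            identity_default=th.identity_default,
        )
    )
    group_by_phase = evo.group_by_phase or {
        p.label: p.label for p in config.phases
    }
    phase_labels = list(group_by_phase)
    results: dict[str, list] = {label: [] for label in phase_labels}
    n_saturated = 0
    for pair_id, meta in pairs:
        if id(meta) not in kept:
            continue
        phase = next(
            (pl for pl, gl in group_by_phase.items() if gl == meta.group_label), None
        )
        if phase is None:
            continue
        aln = mio.read_fasta_pair(Path(evo.aln_dir) / f"{pair_id}.fasta", meta=meta)
        try:
            est = ng86_pair(aln)
            sel = codon_z_test(aln, n_boot=th.n_boot, seed=config.seed)
        except SaturationError:
            n_saturated += 1
            continue
        results[phase].append((meta, est, sel))

    if len(phase_labels) != 2:
        raise ValueError("evolution comparison needs exactly two phases")
    a_label, b_label = phase_labels
    reports = compare_phase_evolution(
        results[a_label], results[b_label],
        alpha=0.05, require_significant=th.require_significant,
        gesd_alpha=th.gesd_alpha, k_max=th.k_max,
    )
    return {
        "phase_a": a_label,
        "phase_b": b_label,
        "n_saturated": n_saturated,
        "species": [dataclasses.asdict(r) for r in reports],
    }
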