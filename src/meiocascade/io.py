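"""Flat-file readers and writers for every format the pipeline touches.

All tables are UTF-8 TSV with header rows; gene ids are opaque strings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import DEGRecord, ExpressionDataset, deg_table
from .enrich import AnnotationSet, EnrichmentRecord
from .molevo import CodonAlignmentPair, OrthologPair
from .netbuild import IntegratedCascade, InteractionNetwork, RegulatoryNetwork


class ParseError(ValueError):
    """Malformed input file."""


# --- expression --------------------------------------------------------------

def read_expression_tsv(matrix_path: str | Path, conditions_path: str | Path) -> ExpressionDataset:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t")
    if cond.shape[1] < 2:
        raise ParseError("condition map needs two columns: sample id, condition")
    condition_of = dict(zip(cond.iloc[:, 0].astype(str), cond.iloc[:, 1].astype(str)))
    return ExpressionDataset(matrix=matrix, condition_of=condition_of)


def write_expression_tsv(
    dataset: ExpressionDataset, matrix_path: str | Path, conditions_path: str | Path
) -> None:
    dataset.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id", float_format="%.6f")
    pd.DataFrame(
        sorted(dataset.condition_of.items()), columns=["sample_id", "condition"]
    ).to_csv(conditions_path, sep="\t", index=False)


def write_deg_tsv(records: Iterable[DEGRecord], path: str | Path) -> None:
    deg_table(records).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


# --- networks ----------------------------------------------------------------

def read_interaction_tsv(path: str | Path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError("interaction table needs two columns")
    return InteractionNetwork(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    )


def write_interaction_tsv(net: InteractionNetwork, path: str | Path) -> None:
    pd.DataFrame(sorted(net.edges), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_regulation_tsv(path: str | Path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError("regulation table needs two columns: tf, target")
    return RegulatoryNetwork(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    )


def write_regulation_tsv(grn: RegulatoryNetwork, path: str | Path) -> None:
    pd.DataFrame(sorted(grn.edges), columns=["tf", "target"]).to_csv(
        path, sep="\t", index=False
    )


def write_cascade_tables(
    cascade: IntegratedCascade, node_path: str | Path, edge_path: str | Path
) -> None:
    nodes = pd.DataFrame(
        [(n.gene_id, n.in_deg, n.out_deg, n.v, n.role) for n in cascade.nodes.values()],
        columns=["gene_id", "in", "out", "v", "role"],
    ).sort_values("gene_id")
    nodes.to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(cascade.edges, columns=["source", "target", "layer"]).to_csv(
        edge_path, sep="\t", index=False
    )


def cascade_to_graph(cascade: IntegratedCascade) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in cascade.nodes.values():
        g.add_node(node.gene_id, in_deg=node.in_deg, out_deg=node.out_deg,
                   v=node.v, role=node.role)
    for src, tgt, layer in cascade.edges:
        g.add_edge(src, tgt, layer=layer)
    return g


def export_graphml(cascade: IntegratedCascade, path: str | Path) -> None:
    nx.write_graphml(cascade_to_graph(cascade), path)


def export_sif(cascade: IntegratedCascade, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, tgt, layer in cascade.edges:
            fh.write(f"{src}\t{layer}\t{tgt}\n")


# --- annotations -------------------------------------------------------------

def read_gmt(path: str | Path) -> AnnotationSet:
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty GMT file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: need >= 3 tab-separated fields")
        term, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
        if term in terms:
            raise ParseError(f"{path}:{lineno}: duplicate term id {term!r}")
        if not members:
            raise ParseError(f"{path}:{lineno}: term {term!r} has no members")
        terms[term] = (desc, frozenset(members))
    universe = frozenset().union(*(m for _, m in terms.values()))
    return AnnotationSet(terms=terms, universe=universe)


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc = (descriptions or {}).get(term, term)
            members = "\t".join(sorted(set(terms[term])))
            fh.write(f"{term}\t{desc}\t{members}\n")


def write_enrichment_tsv(records: Iterable[EnrichmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.term_id, r.description, r.k, r.K, r.n, r.N_u, r.p_raw, r.p_adj, r.enriched)
         for r in records],
        columns=["term_id", "description", "k", "K", "n", "N_u", "p_raw", "p_adj", "enriched"],
    ).to_csv(path, sep="\t", index=False)


# --- codon alignments & orthologs -------------------------------------------

def read_fasta_pair(path: str | Path, meta: OrthologPair | None = None) -> CodonAlignmentPair:
    """Read a two-record aligned FASTA into a codon alignment pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ParseError(f"{path}: expected exactly two records, got {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ParseError(f"{path}: aligned lengths differ ({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise ParseError(f"{path}: alignment length {len(a)} not divisible by 3")
    try:
        return CodonAlignmentPair(a, b, meta=meta)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta_pair(pair: CodonAlignmentPair, path: str | Path,
                     id_a: str = "a", id_b: str = "b") -> None:
    records = [
        SeqRecord(Seq(pair.seq_a), id=id_a, description=""),
        SeqRecord(Seq(pair.seq_b), id=id_b, description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_ortholog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "gene_a", "gene_b", "species", "orthology_type",
                "confidence", "percent_identity", "group_label"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def ortholog_pairs_from_frame(df: pd.DataFrame) -> list[tuple[str, OrthologPair]]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            (str(row.pair_id),
             OrthologPair(
                 gene_a=str(row.gene_a), gene_b=str(row.gene_b),
                 species=str(row.species), orthology_type=str(row.orthology_type),
                 confidence=float(row.confidence),
                 percent_identity=float(row.percent_identity),
                 group_label=str(row.group_label),
             ))
        )
    return out


# --- reports -----------------------------------------------------------------

def write_json_report(report: Mapping, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_default) + "\n")
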