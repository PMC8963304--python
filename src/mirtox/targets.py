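"""Target prioritization: from significant miRNAs to neuro-relevant mRNAs.

The funnel mirrors a pathway-analysis triage: take the experimentally
validated mRNA targets of the significant miRNAs, keep those annotated in a
neurological catalog, drop targets with no biomarker or canonical-pathway
relationships, drop targets tied to exactly one specific condition, predict
each survivor's expression direction from the fold changes of the miRNAs
that repress it, and finally reconstruct a signaling network by tracing
linear cascades between seed molecules through a signed interaction graph.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AnnotationCatalog, InteractionGraph, TargetNetwork


def select_validated_targets(
    sig_mirnas, network: TargetNetwork
) -> pd.DataFrame:
    """Union of validated targets of the significant miRNAs, with provenance.

    Returns one row per gene with the sorted list of supporting miRNAs
    (those with a validated edge to the gene).
    """
    sig = set(sig_mirnas)
    edges = network.edges
    keep = edges[(edges["evidence"] == "validated") & (edges["mirna"].isin(sig))]
    rows = [
        (gene, sorted(grp["mirna"])) for gene, grp in keep.groupby("gene")
    ]
    return pd.DataFrame(rows, columns=["gene", "supporting_mirnas"]).sort_values(
        "gene", kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class PrioritizedTarget:
    """A surviving mRNA target with its annotation counts and direction."""

    gene: str
    supporting_mirnas: list[str]
    mirna_log2fc: dict[str, float] = field(default_factory=dict)
    n_biomarker_terms: int = 0
    n_pathway_terms: int = 0
    predicted_direction: str = "ambiguous"
    rationale: str = ""


def filter_neuro_targets(
    targets: pd.DataFrame, catalog: AnnotationCatalog
) -> tuple[list[PrioritizedTarget], pd.DataFrame]:
    """Three-step annotation funnel over the validated-target table.

    1. keep genes with >= 1 term in the (neurologically scoped) catalog;
    2. drop genes with zero biomarker AND zero canonical-pathway terms;
    3. drop genes whose biomarker+pathway associations name exactly one
       specific condition (single-condition rule).
    Returns the survivors and a per-gene audit table of the step outcomes.
    """
    survivors: list[PrioritizedTarget] = []
    audit = []
    for row in targets.itertuples():
        gene = row.gene
        all_terms = catalog.terms_of(gene)
        if not all_terms:
            audit.append((gene, "dropped", "no neurological annotation"))
            continue
        bio = catalog.terms_of(gene, ["disease_biomarker"])
        pw = catalog.terms_of(gene, ["canonical_pathway"])
        if not bio and not pw:
            audit.append((gene, "dropped", "no biomarker or pathway relationship"))
            continue
        if len(bio | pw) == 1:
            audit.append((gene, "dropped", "associated with a single condition only"))
            continue
        survivors.append(
            PrioritizedTarget(
                gene=gene,
                supporting_mirnas=list(row.supporting_mirnas),
                n_biomarker_terms=len(bio),
                n_pathway_terms=len(pw),
                rationale=(
                    f"{len(bio)} biomarker and {len(pw)} pathway term(s)"
                ),
            )
        )
        audit.append((gene, "kept", ""))
    audit_df = pd.DataFrame(audit, columns=["gene", "outcome", "reason"])
    return survivors, audit_df


def predict_direction(target: PrioritizedTarget) -> str:
    """Predict the target's expression direction from its miRNAs' changes.

    miRNAs repress their targets, so each supporting miRNA votes opposite to
    its own direction, weighted by |log2 FC|; the sign of the weighted sum
    decides (zero sum -> ambiguous). The result is stored on the target and
    returned.
    """
    votes = 0.0
    for m in target.supporting_mirnas:
        fc = target.mirna_log2fc.get(m)
        if fc is None:
            continue
        votes += -np.sign(fc) * abs(fc)
    if votes > 0:
        direction = "up"
    elif votes < 0:
        direction = "down"
    else:
        direction = "ambiguous"
    target.predicted_direction = direction
    return direction


def prioritize_targets(
    sig_mirnas,
    mirna_log2fc: dict[str, float],
    network: TargetNetwork,
    catalog: AnnotationCatalog,
) -> tuple[list[PrioritizedTarget], pd.DataFrame]:
    """Full funnel: validated targets -> neuro filter -> direction calls."""
    validated = select_validated_targets(sig_mirnas, network)
    survivors, audit = filter_neuro_targets(validated, catalog)
    for t in survivors:
        t.mirna_log2fc = {
            m: mirna_log2fc[m] for m in t.supporting_mirnas if m in mirna_log2fc
        }
        predict_direction(t)
    return survivors, audit


def targets_table(survivors: list[PrioritizedTarget]) -> pd.DataFrame:
    """Flat table of prioritized targets for writing out."""
    rows = [
        (
            t.gene,
            ";".join(t.supporting_mirnas),
            t.n_biomarker_terms,
            t.n_pathway_terms,
            t.predicted_direction,
            t.rationale,
        )
        for t in survivors
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "supporting_mirnas",
            "n_biomarker_terms",
            "n_pathway_terms",
            "predicted_direction",
            "rationale",
        ],
    )


def trace_cascades(
    graph: InteractionGraph, seed_set_a, seed_set_b, max_len: int = 4
) -> list[list[str]]:
    """All simple directed paths from A-seeds to B-seeds with <= max_len edges.

    Deterministically ordered: paths sorted lexicographically as node tuples.
    Raises if any seed is missing from the graph, listing the missing ids.
    """
    a = sorted(set(seed_set_a))
    b = sorted(set(seed_set_b))
    g = graph.graph
    missing = [x for x in (*a, *b) if x not in g]
    if missing:
        raise KeyError(f"seed nodes not in graph: {missing}")
    paths: list[list[str]] = []
    targets = set(b)
    for src in a:
        reachable_targets = targets - {src}
        if not reachable_targets:
            continue
        for path in nx.all_simple_paths(g, src, reachable_targets, cutoff=max_len):
            paths.append(list(path))
    paths.sort(key=tuple)
    return paths


def merge_cascades(
    paths: list[list[str]],
    graph: InteractionGraph,
    catalog: AnnotationCatalog | None = None,
    notable_mirnas_by_gene: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union of path edges (signs preserved) plus per-node annotation flags.

    Returns (edge table: source/sign/target, node table: node, categories
    annotating it, notable miRNAs targeting it).
    """
    edge_set: set[tuple[str, str, str]] = set()
    nodes: set[str] = set()
    for path in paths:
        for u, v in zip(path, path[1:]):
            sign = graph.graph[u][v]["sign"]
            edge_set.add((u, sign, v))
        nodes.update(path)
    edges = pd.DataFrame(sorted(edge_set), columns=["source", "sign", "target"])
    records = []
    for node in sorted(nodes):
        if catalog is not None:
            cats = sorted(set(catalog.table.loc[catalog.table["gene"] == node, "category"]))
        else:
            cats = []
        notable = sorted((notable_mirnas_by_gene or {}).get(node, []))
        records.append((node, ";".join(cats), ";".join(notable)))
    node_table = pd.DataFrame(records, columns=["node", "categories", "notable_mirnas"])
    return edges, node_table
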