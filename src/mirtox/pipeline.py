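"""End-to-end orchestration: configuration, the default synthetic scenario,
and the run-all driver.

The pipeline reproduces the study workflow on synthetic data with planted
ground truth: apical dose-response analysis selects a low/high test
concentration per chemical; a 754-feature Ct panel is simulated for every
selected exposure with spiked fold changes on a known miRNA subset; paired
differential testing with the joint fold-change + raw-p filter yields the
significant set; annotation mapping drops non-human/discontinued assays;
fold-change clustering, dual bias-corrected pathway enrichment (with a
planted pathway whose recovery rank the manifest reports), cluster-wise
pathway-union enrichment, and the neuro-target prioritization funnel follow.
Identical config + seed give byte-identical output tables.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import apical, clustering, diffexp, enrichment, io, synthdata, targets
from .containers import AnnotationCatalog, InteractionGraph
from .synthdata import (
    ApicalSimConfig,
    CtSimConfig,
    HillParams,
    OntologySimConfig,
    PLANTED_PATHWAY,
    Spike,
)

STAGES = (
    "apical", "ct", "ontology", "annotation", "catalog", "interactions",
)


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream; adding stages never perturbs the others."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (seed * 1_000_003 + h) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters and thresholds, with the study's printed defaults."""

    seed: int = 0
    out_dir: str = "results/run"
    # differential expression
    detection_limit: float = 35.0
    fc_up: float = 1.5
    fc_down: float = 1 / 1.5
    p_raw: float = 0.01
    # apical selection
    dunnett_alpha: float = 0.05
    decrease_pct: float = 20.0
    # clustering
    min_cluster_size: int = 3
    deep_split: int = 1
    # enrichment
    bh_alpha: float = 0.01
    report_alpha: float = 0.001
    top_n: int = 20
    union_alpha: float = 0.05
    # prioritization
    max_cascade_len: int = 4
    # scenario size knobs
    n_mirnas: int = 754
    n_spiked: int = 40
    n_replicate_pairs: int = 4
    replicate_sd: float = 0.4
    # the gene universe must dwarf the planted pathway's target core, or the
    # miRNA-level enrichment method loses discrimination (nearly every miRNA
    # would touch the pathway)
    n_genes: int = 6000
    n_pathways: int = 50
    planted_overlap: float = 0.8

    def validate(self) -> None:
        if not (0 < self.p_raw < 1):
            raise ValueError("p threshold must lie strictly between 0 and 1")
        if not (0 < self.fc_down <= 1 <= self.fc_up):
            raise ValueError("fold-change thresholds must bracket 1")
        for a in (self.dunnett_alpha, self.bh_alpha, self.report_alpha, self.union_alpha):
            if not (0 < a < 1):
                raise ValueError("alpha levels must lie strictly between 0 and 1")
        if self.min_cluster_size < 1 or self.max_cascade_len < 1 or self.top_n < 1:
            raise ValueError("size parameters must be positive")
        if self.n_replicate_pairs < 2:
            raise ValueError("paired testing needs at least 2 replicate pairs")
        if not (0 <= self.planted_overlap <= 1):
            raise ValueError("planted_overlap must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Default synthetic scenario

#: Hill parameters per chemical and endpoint: flat viability for the
#: microtubule poisons (col/ptx), steep neurite loss at low dose for
#: col/ptx/rot, delayed loss for bis, a flat negative control (acet).
_FLAT = HillParams()


def default_apical_config(seed: int) -> ApicalSimConfig:
    def chem(neurite: HillParams, atp: HillParams, density: HillParams | None = None):
        return {
            "ATP": atp,
            "neurite_length": neurite,
            "neurite_count": dataclasses.replace(neurite, bottom=neurite.bottom + 5),
            "neurons_per_field": density or _FLAT,
        }

    chemicals = {
        "acet": chem(_FLAT, _FLAT),
        "bis": chem(
            HillParams(bottom=30, ec50=8, slope=2), HillParams(bottom=20, ec50=50, slope=3)
        ),
        "col": chem(HillParams(bottom=30, ec50=0.03, slope=2), _FLAT),
        "dox": chem(
            HillParams(bottom=25, ec50=0.5, slope=2),
            HillParams(bottom=10, ec50=12, slope=3),
            HillParams(bottom=50, ec50=60, slope=3),
        ),
        "ptx": chem(HillParams(bottom=40, ec50=0.04, slope=1.5), _FLAT),
        "rot": chem(
            HillParams(bottom=35, ec50=0.03, slope=2),
            HillParams(bottom=15, ec50=5, slope=2),
            HillParams(bottom=55, ec50=80, slope=3),
        ),
    }
    return ApicalSimConfig(chemicals=chemicals, seed=seed)


@dataclass
class Scenario:
    """The generated inputs plus all planted ground truth."""

    apical_records: pd.DataFrame
    ct: synthdata.CtSimResult
    network: "synthdata.TargetNetwork"
    ontology: "synthdata.PathwayOntology"
    annotation: pd.DataFrame
    catalog: AnnotationCatalog
    interactions: InteractionGraph
    pairs: dict
    spiked_mirnas: list[str]
    hub_genes: list[str]


# spike magnitude bands mirroring strong-down / mild-down / mild-up / strong-up
_SPIKE_BANDS = ((-3.5, -2.5), (-2.2, -1.6), (1.6, 2.2), (2.5, 3.5))


def build_scenario(cfg: PipelineConfig) -> Scenario:
    """Generate every pipeline input for one seed, with planted truth."""
    ap_cfg = default_apical_config(_stage_seed(cfg.seed, "apical"))
    apical_records = synthdata.gen_apical(ap_cfg)
    normalized = apical.normalize_percent_of_control(apical_records)
    dn = apical.dunnett_all(normalized)
    pairs = apical.select_concentrations(dn, cfg.dunnett_alpha, cfg.decrease_pct)

    exposures: list[str] = []
    for chem in sorted(pairs):
        pr = pairs[chem]
        if pr.low is not None:
            exposures.append(f"{chem}@{pr.low:g}")
        if pr.high is not None:
            exposures.append(f"{chem}@{pr.high:g}")
    spike_exposures = [e for e in exposures if not e.startswith("acet")]

    # a shared neurodegeneration signature: every spiked miRNA responds to
    # every toxicant exposure, with its per-exposure magnitude drawn within
    # one of four bands (strong down / mild down / mild up / strong up)
    rng = np.random.default_rng(_stage_seed(cfg.seed, "spikes"))
    spiked_idx = np.sort(rng.choice(cfg.n_mirnas, size=cfg.n_spiked, replace=False))
    spikes: list[Spike] = []
    per_band = max(1, cfg.n_spiked // len(_SPIKE_BANDS))
    for j, idx in enumerate(spiked_idx):
        lo, hi = _SPIKE_BANDS[min(j // per_band, len(_SPIKE_BANDS) - 1)]
        for exposure in spike_exposures:
            spikes.append(Spike(int(idx), exposure, float(rng.uniform(lo, hi))))

    ct_cfg = CtSimConfig(
        n_mirnas=cfg.n_mirnas,
        n_plates=len(exposures),
        treatments=tuple((e, cfg.n_replicate_pairs) for e in exposures),
        baseline_mean_ct=30.0,
        baseline_sd_between_mirnas=3.0,
        replicate_sd=cfg.replicate_sd,
        plate_shift_sd=0.3,
        detection_limit=cfg.detection_limit,
        spikes=tuple(spikes),
        seed=_stage_seed(cfg.seed, "ct"),
    )
    ct = synthdata.gen_ct_matrix(ct_cfg)
    spiked_names = sorted({str(ct.ct.mirnas[i]) for i in spiked_idx})

    # light out-degrees and a capped pathway size keep the planted pathway's
    # gene-level footprint small enough for the miRNA-level enrichment method
    # to discriminate it from background
    onto_cfg = OntologySimConfig(
        n_genes=cfg.n_genes,
        n_mirnas=cfg.n_mirnas,
        degree_distribution=(3, 20, 2.0),
        n_pathways=cfg.n_pathways,
        pathway_size_range=(20, 300),
        planted_pathway_overlap=cfg.planted_overlap,
        seed=_stage_seed(cfg.seed, "ontology"),
    )
    network = synthdata.gen_target_network(onto_cfg)
    ontology = synthdata.gen_pathway_ontology(onto_cfg, spiked_names, network)

    annotation = synthdata.gen_mirna_annotation(
        [str(m) for m in ct.ct.mirnas],
        non_human=[spiked_names[0]],
        discontinued=[spiked_names[1]],
    )
    catalog_genes = sorted(network.gene_universe())
    catalog = synthdata.gen_annotation_catalog(
        catalog_genes, seed=_stage_seed(cfg.seed, "catalog")
    )

    hub_genes = sorted(ontology[PLANTED_PATHWAY])[:5]
    graph_nodes = sorted(set(catalog_genes[: len(catalog_genes) // 4]) | set(hub_genes))
    interactions = synthdata.gen_interaction_graph(
        n_genes=len(graph_nodes),
        edge_density=0.02,
        seed=_stage_seed(cfg.seed, "interactions"),
        genes=graph_nodes,
    )
    return Scenario(
        apical_records=apical_records,
        ct=ct,
        network=network,
        ontology=ontology,
        annotation=annotation,
        catalog=catalog,
        interactions=interactions,
        pairs=pairs,
        spiked_mirnas=spiked_names,
        hub_genes=hub_genes,
    )


# ---------------------------------------------------------------------------
# Run-all


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    return len(df)


def run_pipeline(cfg: PipelineConfig, scenario: Scenario | None = None) -> dict:
    """Execute all stages, write stage tables, and return the run manifest."""
    cfg.validate()
    out = io.ensure_dir(cfg.out_dir)
    if scenario is None:
        scenario = build_scenario(cfg)
    manifest: dict = {"seed": cfg.seed, "parameters": dataclasses.asdict(cfg), "stages": {}}

    # -- apical ------------------------------------------------------------
    normalized = apical.normalize_percent_of_control(scenario.apical_records)
    dn = apical.dunnett_all(normalized)
    pairs = apical.select_concentrations(dn, cfg.dunnett_alpha, cfg.decrease_pct)
    corr = apical.correlate_endpoints(apical.endpoint_log2_foldchanges(normalized))
    pair_table = pd.DataFrame(
        [
            (c, p.low if p.low is not None else "", p.high, p.low_rationale, p.high_rationale)
            for c, p in sorted(pairs.items())
        ],
        columns=["chemical", "low_uM", "high_uM", "low_rationale", "high_rationale"],
    )
    manifest["stages"]["apical"] = {
        "n_dunnett_rows": _write(dn, out / "dunnett.tsv"),
        "n_pairs": _write(pair_table, out / "concentration_pairs.tsv"),
        "n_correlations": _write(corr, out / "endpoint_correlations.tsv"),
    }

    # -- differential expression -------------------------------------------
    capped = diffexp.cap_detection_limit(scenario.ct.ct)
    norm = diffexp.mean_center_normalize(capped)
    table = diffexp.differential_table(norm, capped)
    amap, retained = diffexp.map_annotations(
        sorted(table.loc[table["significant"], "mirna"].unique()), scenario.annotation
    )
    table["mapped"] = table["mirna"].isin(retained)
    sig = sorted(set(table.loc[table["significant"], "mirna"]) & set(retained))
    volcano = table[["mirna", "exposure", "fold_change", "p"]].copy()
    volcano["log2_fc"] = np.log2(volcano.pop("fold_change"))
    volcano["neg_log10_p"] = -np.log10(volcano.pop("p"))
    manifest["stages"]["diffexp"] = {
        "n_records": _write(table, out / "differential.tsv"),
        "n_volcano": _write(volcano, out / "volcano.tsv"),
        "n_annotation_rows": _write(amap, out / "annotation_map.tsv"),
        "n_significant_raw": int(table.loc[table["significant"], "mirna"].nunique()),
        "n_significant_mapped": len(sig),
        "n_spiked_recovered": len(set(sig) & set(scenario.spiked_mirnas)),
    }
    if not sig:
        raise RuntimeError("stage diffexp: no significant miRNAs survive mapping")

    # -- clustering ----------------------------------------------------------
    sig_table = diffexp.select_significant(table[table["mirna"].isin(sig)])
    profile = clustering.build_profile(sig_table)
    z, leaves = clustering.average_linkage_dendrogram(profile)
    assignment = clustering.dynamic_tree_cut(
        z, leaves, cfg.min_cluster_size, cfg.deep_split
    )
    cluster_table = assignment.labels.rename("cluster").reset_index()
    (out / "dendrogram.nwk").write_text(clustering.dendrogram_newick(z, leaves) + "\n")
    manifest["stages"]["clustering"] = {
        "n_clustered": _write(cluster_table, out / "clusters.tsv"),
        "n_clusters": assignment.n_clusters,
        "cluster_sizes": [
            len(assignment.members(c)) for c in range(1, assignment.n_clusters + 1)
        ],
    }

    # -- enrichment ----------------------------------------------------------
    p1 = enrichment.enrich_targets_method1(sig, scenario.network, scenario.ontology)
    p2 = enrichment.enrich_mirna_sets_method2(sig, scenario.network, scenario.ontology)
    dual = enrichment.combine_dual(p1, p2, cfg.bh_alpha, cfg.report_alpha, cfg.top_n)
    planted = dual.set_index("pathway").loc[PLANTED_PATHWAY]
    cluster_sets = {}
    for c in range(1, assignment.n_clusters + 1):
        members = assignment.members(c)
        union = enrichment.pathway_union_enrichment(
            members, scenario.network, scenario.ontology, cfg.union_alpha
        )
        cluster_sets[c] = set(union.loc[union["significant"], "pathway"])
    common = (
        enrichment.common_pathways(cluster_sets) if cluster_sets else []
    )
    manifest["stages"]["enrichment"] = {
        "n_pathways": _write(dual.sort_values("pathway"), out / "enrichment.tsv"),
        "n_significant_both": int(dual["significant_both"].sum()),
        "planted_pathway_rank": int(planted["rank"]),
        "planted_significant_both": bool(planted["significant_both"]),
        "per_cluster_significant": {str(c): sorted(s) for c, s in cluster_sets.items()},
        "common_pathways": common,
        "planted_in_common": PLANTED_PATHWAY in common,
    }

    # -- prioritization ------------------------------------------------------
    mean_l2fc = (
        sig_table[sig_table["significant"]]
        .assign(l2=lambda d: np.log2(d["fold_change"]))
        .groupby("mirna")["l2"]
        .mean()
        .to_dict()
    )
    survivors, audit = targets.prioritize_targets(
        sig, mean_l2fc, scenario.network, scenario.catalog
    )
    ttable = targets.targets_table(survivors)
    graph_nodes = set(scenario.interactions.graph.nodes)
    seed_a = sorted(set(ttable["gene"]) & graph_nodes)
    seed_b = sorted(set(scenario.hub_genes) & graph_nodes)
    if seed_a and seed_b:
        cascades = targets.trace_cascades(
            scenario.interactions, seed_a, seed_b, cfg.max_cascade_len
        )
    else:
        cascades = []
    edges, node_table = targets.merge_cascades(
        cascades,
        scenario.interactions,
        scenario.catalog,
        {t.gene: t.supporting_mirnas for t in survivors},
    )
    manifest["stages"]["prioritization"] = {
        "n_validated_targets": int(len(targets.select_validated_targets(sig, scenario.network))),
        "n_prioritized": _write(ttable, out / "prioritized_targets.tsv"),
        "n_audit": _write(audit, out / "target_audit.tsv"),
        "n_cascades": len(cascades),
        "n_network_edges": _write(edges, out / "cascade_network.tsv"),
        "n_network_nodes": _write(node_table, out / "cascade_nodes.tsv"),
    }

    manifest["truth"] = {
        "spiked_mirnas": scenario.spiked_mirnas,
        "planted_pathway": PLANTED_PATHWAY,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
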