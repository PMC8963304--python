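"""Synthetic data generators emulating the study's data structure.

Every generator is a pure function of its config (including the seed) and
returns its ground truth alongside the data, so every downstream stage can be
tested for recovery of planted signal without any external data:

* ``gen_ct_matrix`` — a TaqMan-style miRNA array-card experiment: per-miRNA
  baseline Ct, per-plate location shifts, paired treated/control biological
  replicates, well noise, and treatment effects injected on the Ct scale as
  ``-log2_effect`` (one PCR cycle = a 2-fold expression change, and lower Ct
  means higher expression).
* ``gen_apical`` — well-level viability/morphology endpoints around Hill
  dose-response means over a micromolar concentration range, with vehicle
  control wells at the 100% level on every plate.
* ``gen_target_network`` / ``gen_pathway_ontology`` — a bipartite miRNA->gene
  target network with heavy-tailed out-degree and named gene sets, one of
  which ("planted") receives a configurable fraction of the spiked miRNAs'
  target union.
* ``gen_interaction_graph`` — a signed directed gene-interaction graph.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    APICAL_ENDPOINTS,
    AnnotationCatalog,
    CtMatrix,
    InteractionGraph,
    PathwayOntology,
    TargetNetwork,
)

# ---------------------------------------------------------------------------
# Ct matrices


@dataclass(frozen=True)
class Spike:
    """A planted treatment effect: miRNA row index, treatment name, log2 effect.

    Positive log2_effect = up-regulation = the raw Ct of treated samples is
    lowered by ``log2_effect`` cycles.
    """

    mirna_index: int
    treatment: str
    log2_effect: float


@dataclass(frozen=True)
class CtSimConfig:
    n_mirnas: int = 754
    n_plates: int = 1
    treatments: Sequence[tuple[str, int]] = (("treated", 3),)
    baseline_mean_ct: float = 28.0
    baseline_sd_between_mirnas: float = 3.0
    replicate_sd: float = 0.5
    plate_shift_sd: float = 0.3
    detection_limit: float = 35.0
    spikes: Sequence[Spike] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0 or self.n_plates <= 0:
            raise ValueError("counts must be positive")
        if not self.treatments:
            raise ValueError("at least one treatment is required")
        for name, n_rep in self.treatments:
            if n_rep <= 0:
                raise ValueError(f"treatment {name!r} needs a positive replicate count")
        names = [t for t, _ in self.treatments]
        if len(names) != len(set(names)):
            raise ValueError("duplicate treatment names")
        for sd in (self.baseline_sd_between_mirnas, self.replicate_sd, self.plate_shift_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        for sp in self.spikes:
            if not (0 <= sp.mirna_index < self.n_mirnas):
                raise ValueError(
                    f"spike miRNA index {sp.mirna_index} out of range [0, {self.n_mirnas})"
                )
            if sp.treatment not in names:
                raise ValueError(f"spike names unknown treatment {sp.treatment!r}")


@dataclass
class CtSimResult:
    ct: CtMatrix
    spikes: pd.DataFrame  # mirna, treatment, log2_effect (ground truth)


def mirna_names(n: int) -> pd.Index:
    return pd.Index([f"miR-{i:04d}" for i in range(n)], name="mirna")


def gen_ct_matrix(cfg: CtSimConfig) -> CtSimResult:
    """Simulate a raw Ct matrix with a paired treated/control design.

    Each treatment occupies one plate (round-robin over ``n_plates``) holding
    both its treated and control samples, so the plate mean cancels within
    pairs, mirroring one array card per compound. Values at or above the
    detection limit are emitted as-is; capping is the consumer's first step.
    """
    rng = np.random.default_rng(cfg.seed)
    mirnas = mirna_names(cfg.n_mirnas)
    baseline = rng.normal(cfg.baseline_mean_ct, cfg.baseline_sd_between_mirnas, cfg.n_mirnas)
    plate_shift = rng.normal(0.0, cfg.plate_shift_sd, cfg.n_plates)

    effect: dict[str, np.ndarray] = {
        name: np.zeros(cfg.n_mirnas) for name, _ in cfg.treatments
    }
    for sp in cfg.spikes:
        effect[sp.treatment][sp.mirna_index] -= sp.log2_effect

    columns: list[str] = []
    sheet_rows: list[tuple[str, str, str, int, str]] = []
    data: list[np.ndarray] = []
    for t_idx, (name, n_rep) in enumerate(cfg.treatments):
        plate = f"plate{t_idx % cfg.n_plates}"
        shift = plate_shift[t_idx % cfg.n_plates]
        for role, offset in (("treated", effect[name]), ("control", 0.0)):
            for rep in range(1, n_rep + 1):
                sid = f"{name}.{role[0].upper()}{rep}"
                noise = rng.normal(0.0, cfg.replicate_sd, cfg.n_mirnas)
                data.append(baseline + shift + offset + noise)
                columns.append(sid)
                sheet_rows.append((sid, plate, name, rep, role))
    values = pd.DataFrame(np.column_stack(data), index=mirnas, columns=columns)
    samples = pd.DataFrame(
        sheet_rows, columns=["sample", "plate", "treatment", "replicate", "role"]
    ).set_index("sample")
    truth = pd.DataFrame(
        [(mirnas[sp.mirna_index], sp.treatment, sp.log2_effect) for sp in cfg.spikes],
        columns=["mirna", "treatment", "log2_effect"],
    )
    ct = CtMatrix(values=values, samples=samples, detection_limit=cfg.detection_limit)
    return CtSimResult(ct=ct, spikes=truth)


# ---------------------------------------------------------------------------
# Apical endpoints


@dataclass(frozen=True)
class HillParams:
    """Four-parameter Hill dose-response in percent-of-control units."""

    top: float = 100.0
    bottom: float = 100.0
    ec50: float = 1.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")

    def mean_at(self, conc_uM: float) -> float:
        if conc_uM <= 0:
            return self.top
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (conc_uM / self.ec50) ** self.slope
        )


@dataclass(frozen=True)
class ApicalSimConfig:
    # chemical -> endpoint -> Hill parameters
    chemicals: dict[str, dict[str, HillParams]] = field(default_factory=dict)
    concentrations: Sequence[float] = (0.1, 1.0, 10.0, 30.0, 100.0)
    wells_per_group: int = 3
    well_cv: float = 0.1
    n_plates: int = 2
    baseline_signal: float = 1000.0  # raw instrument units at 100%
    seed: int = 0

    def __post_init__(self) -> None:
        conc = list(self.concentrations)
        if any(c <= 0 for c in conc) or sorted(conc) != conc:
            raise ValueError("concentrations must be positive and sorted")
        if self.wells_per_group < 2:
            raise ValueError("need at least 2 wells per group")
        if self.n_plates <= 0:
            raise ValueError("n_plates must be positive")
        for chem, endpoints in self.chemicals.items():
            for ep in endpoints:
                if ep not in APICAL_ENDPOINTS:
                    raise ValueError(f"unknown endpoint {ep!r} for chemical {chem!r}")


def gen_apical(cfg: ApicalSimConfig) -> pd.DataFrame:
    """Well-level apical endpoint records around Hill-curve means.

    Columns: chemical, concentration_uM, plate, well, endpoint, value (raw
    instrument units; the vehicle-control mean is ``baseline_signal`` scaled
    per plate). Vehicle wells (concentration 0) appear on every plate.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for chem in sorted(cfg.chemicals):
        endpoints = cfg.chemicals[chem]
        for p in range(cfg.n_plates):
            plate = f"plate{p}"
            # plate-specific raw scale emulates day-to-day instrument gain
            scale = cfg.baseline_signal * (1.0 + 0.2 * p)
            for ep in sorted(endpoints):
                hill = endpoints[ep]
                for conc in (0.0, *cfg.concentrations):
                    mean_pct = 100.0 if conc == 0 else hill.mean_at(conc)
                    mean_raw = scale * mean_pct / 100.0
                    for w in range(cfg.wells_per_group):
                        value = mean_raw * (1.0 + cfg.well_cv * rng.standard_normal())
                        rows.append(
                            (chem, conc, plate, f"{chem}.{ep}.{conc:g}.{p}.{w}", ep, value)
                        )
    return pd.DataFrame(
        rows,
        columns=["chemical", "concentration_uM", "plate", "well", "endpoint", "value"],
    )


# ---------------------------------------------------------------------------
# Networks and ontologies


@dataclass(frozen=True)
class OntologySimConfig:
    n_genes: int = 2000
    n_mirnas: int = 200
    degree_distribution: tuple[int, int, float] = (5, 50, 2.0)  # min, max, tail exponent
    validated_fraction: float = 0.6
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (20, 200)
    planted_pathway_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, _alpha = self.degree_distribution
        if not (1 <= lo <= hi):
            raise ValueError("degree range must satisfy 1 <= min <= max")
        if lo > self.n_genes:
            raise ValueError("min_targets exceeds the number of genes")
        if not 0 <= self.validated_fraction <= 1:
            raise ValueError("validated_fraction must be in [0, 1]")
        smin, smax = self.pathway_size_range
        if not (1 <= smin <= smax <= self.n_genes):
            raise ValueError("pathway sizes must satisfy 1 <= min <= max <= n_genes")
        if not 0 <= self.planted_pathway_overlap <= 1:
            raise ValueError("planted_pathway_overlap must be in [0, 1]")
        if self.n_pathways < 1 or self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("counts must be positive")


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _truncated_power_law(rng, lo: int, hi: int, alpha: float, size: int) -> np.ndarray:
    """Integer draws in [lo, hi] with P(k) proportional to k**(-alpha)."""
    support = np.arange(lo, hi + 1, dtype=float)
    weights = support ** (-alpha)
    weights /= weights.sum()
    return rng.choice(support.astype(int), size=size, p=weights)


def gen_target_network(cfg: OntologySimConfig) -> TargetNetwork:
    """Bipartite miRNA->gene edges with truncated-power-law out-degrees."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi, alpha = cfg.degree_distribution
    genes = np.array(gene_names(cfg.n_genes))
    mirnas = [f"miR-{i:04d}" for i in range(cfg.n_mirnas)]
    degrees = _truncated_power_law(rng, lo, min(hi, cfg.n_genes), alpha, cfg.n_mirnas)
    rows = []
    for m, k in zip(mirnas, degrees):
        targets = rng.choice(genes, size=k, replace=False)
        validated = rng.random(k) < cfg.validated_fraction
        for g, v in zip(targets, validated):
            rows.append((m, g, "validated" if v else "predicted"))
    return TargetNetwork(pd.DataFrame(rows, columns=["mirna", "gene", "evidence"]))


PLANTED_PATHWAY = "PW_planted"


def gen_pathway_ontology(
    cfg: OntologySimConfig, spiked_mirnas: Sequence[str], network: TargetNetwork
) -> PathwayOntology:
    """Gene sets with one planted pathway enriched for spiked-miRNA targets.

    The planted pathway receives ``planted_pathway_overlap`` of the union of
    the spiked miRNAs' targets (rounded up), padded with uniform genes up to a
    size drawn from ``pathway_size_range``; the other pathways are uniform
    draws. Raises if the overlap demands more genes than the maximum size.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    missing = [m for m in spiked_mirnas if not network.targets_of(m)]
    if missing:
        raise ValueError(f"spiked miRNAs not in network: {missing}")
    genes = np.array(gene_names(cfg.n_genes))
    smin, smax = cfg.pathway_size_range
    union = sorted(network.targets_of_set(spiked_mirnas))
    n_core = int(np.ceil(cfg.planted_pathway_overlap * len(union)))
    if n_core > smax:
        raise ValueError(
            f"planted overlap needs {n_core} genes but pathway size max is {smax}"
        )
    pathways: dict[str, list[str]] = {}
    size = max(int(rng.integers(smin, smax + 1)), n_core)
    core = list(rng.choice(np.array(union), size=n_core, replace=False)) if n_core else []
    pad_pool = np.array(sorted(set(genes) - set(core)))
    pad = list(rng.choice(pad_pool, size=size - n_core, replace=False))
    pathways[PLANTED_PATHWAY] = core + pad
    for i in range(cfg.n_pathways - 1):
        size = int(rng.integers(smin, smax + 1))
        pathways[f"PW_{i:03d}"] = list(rng.choice(genes, size=size, replace=False))
    return PathwayOntology(pathways)


def gen_interaction_graph(
    n_genes: int,
    edge_density: float,
    sign_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    seed: int = 0,
    genes: Sequence[str] | None = None,
) -> InteractionGraph:
    """Random signed directed gene graph; density over ordered pairs.

    ``genes`` overrides the default synthetic node names (it must then have
    length ``n_genes``), letting callers wire the graph to an existing gene
    namespace.
    """
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    if abs(sum(sign_fractions) - 1.0) > 1e-9:
        raise ValueError("sign fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = gene_names(n_genes)
    elif len(genes) != n_genes:
        raise ValueError("genes list does not match n_genes")
    n_possible = n_genes * (n_genes - 1)
    n_edges = int(round(edge_density * n_possible))
    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[int, int]] = set()
    signs = np.array(InteractionGraph.SIGNS)
    while len(edges) < n_edges:
        i, j = (int(x) for x in rng.integers(0, n_genes, size=2))
        if i == j or (i, j) in seen:
            continue
        seen.add((i, j))
        sign = str(rng.choice(signs, p=np.asarray(sign_fractions)))
        edges.append((genes[i], sign, genes[j]))
    return InteractionGraph.from_edges(edges)


# ---------------------------------------------------------------------------
# Annotation plumbing for the mapping and prioritization stages


def gen_mirna_annotation(
    mirnas: Sequence[str],
    non_human: Sequence[str] = (),
    discontinued: Sequence[str] = (),
) -> pd.DataFrame:
    """Assay-name annotation table mapping panel names to synthetic gene ids.

    Names listed in ``non_human`` or ``discontinued`` are flagged accordingly
    (and carry no usable gene id), emulating panel assays that fail to map.
    """
    rows = []
    for i, name in enumerate(mirnas):
        if name in set(non_human):
            rows.append((name, f"MIMAT{i:07d}", "", "non-human"))
        elif name in set(discontinued):
            rows.append((name, f"MIMAT{i:07d}", "", "discontinued"))
        else:
            rows.append((name, f"MIMAT{i:07d}", f"{100000 + i}", "mapped"))
    return pd.DataFrame(rows, columns=["assay_name", "accession", "gene_id", "status"])


_TERM_POOLS = {
    "disease_biomarker": [f"neuro_biomarker_{i:02d}" for i in range(25)],
    "canonical_pathway": [f"neuro_pathway_{i:02d}" for i in range(25)],
    "go_process": [f"go_neuro_process_{i:02d}" for i in range(15)],
    "toxic_pathology": [f"tox_pathology_{i:02d}" for i in range(10)],
}


def gen_annotation_catalog(
    genes: Sequence[str],
    seed: int = 0,
    p_annotated: float = 0.7,
) -> AnnotationCatalog:
    """Synthetic neurological annotation catalog over a gene namespace.

    A fraction ``p_annotated`` of genes receive terms; term counts per
    category are Poisson-ish so that some genes carry rich multi-term
    annotation (funnel survivors) and others only a single condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if rng.random() >= p_annotated:
            continue
        for cat, pool in _TERM_POOLS.items():
            n = int(rng.poisson(0.9 if cat in ("disease_biomarker", "canonical_pathway") else 0.4))
            n = min(n, len(pool))
            for term in rng.choice(pool, size=n, replace=False):
                rows.append((g, str(term), cat))
    table = pd.DataFrame(rows, columns=["gene", "term", "category"])
    return AnnotationCatalog(table)


# ---------------------------------------------------------------------------
# Planted fold-change profiles for clustering recovery


def gen_foldchange_profiles(
    centroids: Sequence[float],
    sizes: Sequence[int],
    n_exposures: int = 11,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """log2 fold-change profiles around constant per-cluster centroids.

    Returns (profile matrix [miRNA x exposure], true cluster labels). Used to
    test recovery of the strong-down / mild-down / mild-up / strong-up
    grouping structure.
    """
    if len(centroids) != len(sizes):
        raise ValueError("centroids and sizes must align")
    rng = np.random.default_rng(seed)
    rows, labels, names = [], [], []
    idx = 0
    exposures = [f"exp{j}" for j in range(n_exposures)]
    for label, (c, n) in enumerate(zip(centroids, sizes), start=1):
        for _ in range(n):
            rows.append(c + rng.normal(0.0, noise_sd, n_exposures))
            labels.append(label)
            names.append(f"miR-{idx:04d}")
            idx += 1
    profile = pd.DataFrame(rows, index=pd.Index(names, name="mirna"), columns=exposures)
    return profile, pd.Series(labels, index=profile.index, name="true_cluster")
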