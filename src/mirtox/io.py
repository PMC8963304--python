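"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: Ct matrix CSV (rows = miRNA, columns = sample id) with a companion
sample sheet TSV (sample, plate, treatment, replicate, role); apical endpoint
CSV; target network TSV (mirna, gene, evidence); pathway ontologies as GMT
(name, description, member genes); annotation catalogs and tables as TSV;
interaction graphs as SIF-like TSV (source, sign, target). Parsers are
strict and report the offending line number.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import AnnotationCatalog, CtMatrix, InteractionGraph, PathwayOntology, TargetNetwork

FLOAT_FORMAT = "%.10g"  # fixed formatting keeps outputs byte-stable


# -- Ct matrices ------------------------------------------------------------

def write_ct_matrix(ct: CtMatrix, values_path, samples_path) -> None:
    ct.values.to_csv(values_path, float_format=FLOAT_FORMAT)
    ct.samples.to_csv(samples_path, sep="\t")


def read_ct_matrix(values_path, samples_path, detection_limit: float = 35.0) -> CtMatrix:
    values = pd.read_csv(values_path, index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    values.columns.name = samples.index.name
    return CtMatrix(values=values, samples=samples, detection_limit=detection_limit)


# -- apical endpoints -------------------------------------------------------

APICAL_COLUMNS = ["chemical", "concentration_uM", "plate", "well", "endpoint", "value"]


def write_apical(records: pd.DataFrame, path) -> None:
    records[APICAL_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_apical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in APICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # whole numbers round-trip as integers otherwise
    df["concentration_uM"] = df["concentration_uM"].astype(float)
    df["value"] = df["value"].astype(float)
    return df


# -- target networks --------------------------------------------------------

def write_network(network: TargetNetwork, path) -> None:
    network.edges.sort_values(["mirna", "gene"], kind="mergesort").to_csv(
        path, sep="\t", index=False
    )


def read_network(path) -> TargetNetwork:
    df = pd.read_csv(path, sep="\t")
    return TargetNetwork(df)


# -- GMT gene sets ----------------------------------------------------------

def write_gmt(ontology: PathwayOntology, path) -> None:
    with open(path, "w") as fh:
        for name in ontology:
            desc = ontology.descriptions.get(name, "na")
            genes = "\t".join(sorted(ontology[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> PathwayOntology:
    """Parse GMT: name, description, then member genes (>= 1 required)."""
    pathways: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (needs name, "
                    f"description and at least one gene; got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = genes
            descriptions[name] = desc
    return PathwayOntology(pathways, descriptions)


# -- annotation catalogs (gene, term, category) ------------------------------

def write_catalog(catalog: AnnotationCatalog, path) -> None:
    catalog.table.sort_values(["gene", "category", "term"], kind="mergesort").to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path) -> AnnotationCatalog:
    return AnnotationCatalog(pd.read_csv(path, sep="\t"))


# -- miRNA annotation tables (assay_name, accession, gene_id, status) --------

def write_annotation(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"assay_name", "accession", "gene_id", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- interaction graphs (SIF-like TSV) ---------------------------------------

def write_interactions(graph: InteractionGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tsign\ttarget\n")
        for source, sign, target in graph.to_edges():
            fh.write(f"{source}\t{sign}\t{target}\n")


def read_interactions(path) -> InteractionGraph:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "sign", "target"]:
            raise ValueError(f"{path}:1: expected header source/sign/target")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            source, sign, target = fields
            if sign not in InteractionGraph.SIGNS:
                raise ValueError(f"{path}:{lineno}: unknown sign {sign!r}")
            edges.append((source, sign, target))
    return InteractionGraph.from_edges(edges)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
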