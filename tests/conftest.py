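"""Shared fixtures: small hand-built experimental objects."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirtox.containers import AnnotationCatalog, CtMatrix, InteractionGraph, TargetNetwork


def make_ct(values: np.ndarray, samples: pd.DataFrame, limit: float = 35.0) -> CtMatrix:
    mirnas = pd.Index([f"miR-{i:04d}" for i in range(values.shape[0])], name="mirna")
    df = pd.DataFrame(values, index=mirnas, columns=samples.index)
    return CtMatrix(values=df, samples=samples, detection_limit=limit)


def paired_sheet(treatment: str, n_pairs: int, plate: str = "plate0") -> pd.DataFrame:
    rows = []
    for role in ("treated", "control"):
        for rep in range(1, n_pairs + 1):
            sid = f"{treatment}.{role[0].upper()}{rep}"
            rows.append((sid, plate, treatment, rep, role))
    return pd.DataFrame(
        rows, columns=["sample", "plate", "treatment", "replicate", "role"]
    ).set_index("sample")


@pytest.fixture
def tiny_network() -> TargetNetwork:
    edges = pd.DataFrame(
        [
            ("m1", "g1", "validated"),
            ("m1", "g2", "predicted"),
            ("m2", "g3", "validated"),
            ("m2", "g4", "validated"),
            ("m3", "g1", "validated"),
        ],
        columns=["mirna", "gene", "evidence"],
    )
    return TargetNetwork(edges)


@pytest.fixture
def tiny_catalog() -> AnnotationCatalog:
    table = pd.DataFrame(
        [
            # rich gene: survives the funnel
            ("g1", "parkinsons", "disease_biomarker"),
            ("g1", "axon_guidance", "canonical_pathway"),
            # single-condition gene: dropped at step 3
            ("g2", "alzheimers", "disease_biomarker"),
            # gene with only a GO term: dropped at step 2
            ("g3", "synapse_assembly", "go_process"),
        ],
        columns=["gene", "term", "category"],
    )
    return AnnotationCatalog(table)


@pytest.fixture
def line_graph() -> InteractionGraph:
    return InteractionGraph.from_edges(
        [
            ("a", "activating", "b"),
            ("b", "inhibiting", "c"),
            ("a", "unknown", "c"),
            ("c", "activating", "d"),
        ]
    )
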