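"""Shared in-memory containers for the pipeline stages.

All tabular data is held in pandas objects; these light dataclasses bundle the
tables with the metadata the stages need (detection limits, sample sheets,
index structures) and enforce the structural invariants once, at construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("plate", "treatment", "replicate", "role")
ROLES = ("treated", "control")

APICAL_ENDPOINTS = ("ATP", "neurite_length", "neurite_count", "neurons_per_field")

ANNOTATION_STATUSES = ("mapped", "unmapped", "discontinued", "non-human")

CATALOG_CATEGORIES = (
    "disease_biomarker",
    "canonical_pathway",
    "go_process",
    "toxic_pathology",
)


@dataclass
class CtMatrix:
    """Raw or capped threshold-cycle values with the experimental design.

    ``values`` is miRNA x sample (cycles). ``samples`` is indexed by sample id
    with columns (plate, treatment, replicate, role); each treated sample is
    paired with the control sample carrying the same (plate, treatment,
    replicate index). ``censored`` is None until detection-limit capping has
    been applied, after which it flags entries at or above the limit.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    detection_limit: float = 35.0
    censored: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        unknown = set(self.samples["role"]) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown sample roles: {sorted(unknown)}")
        if list(self.values.columns) != list(self.samples.index):
            # allow any order but demand the same sample set
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("values columns and sample sheet disagree")
            self.samples = self.samples.loc[self.values.columns]
        if (self.values <= 0).any().any():
            raise ValueError("Ct values must be positive")

    @property
    def mirnas(self) -> pd.Index:
        return self.values.index

    def pairs(self, treatment: str) -> pd.DataFrame:
        """Treated/control sample-id pairs for one treatment, by replicate."""
        sheet = self.samples[self.samples["treatment"] == treatment]
        if sheet.empty:
            raise KeyError(f"treatment {treatment!r} not in sample sheet")
        treated = {r.replicate: sid for sid, r in sheet[sheet["role"] == "treated"].iterrows()}
        control = {r.replicate: sid for sid, r in sheet[sheet["role"] == "control"].iterrows()}
        common = sorted(set(treated) & set(control))
        if not common:
            raise ValueError(f"treatment {treatment!r} has no complete pairs")
        out = pd.DataFrame(
            {
                "treated": [treated[r] for r in common],
                "control": [control[r] for r in common],
            },
            index=pd.Index(common, name="replicate"),
        )
        plates_t = self.samples.loc[out["treated"], "plate"].to_numpy()
        plates_c = self.samples.loc[out["control"], "plate"].to_numpy()
        if (plates_t != plates_c).any():
            raise ValueError(f"pairs for {treatment!r} span plates")
        return out


@dataclass
class NormalizedExpression:
    """Mean-centered expression: plate mean (over non-censored Ct) minus raw Ct.

    Higher value = higher expression. ``censored`` marks entries that sat at
    the detection limit before normalization.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    plate_means: pd.Series
    samples: pd.DataFrame


class TargetNetwork:
    """Bipartite miRNA -> gene edges with an evidence grade per edge."""

    EVIDENCE = ("validated", "predicted")

    def __init__(self, edges: pd.DataFrame):
        required = {"mirna", "gene", "evidence"}
        if not required.issubset(edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        bad = set(edges["evidence"]) - set(self.EVIDENCE)
        if bad:
            raise ValueError(f"unknown evidence grades: {sorted(bad)}")
        if edges.duplicated(["mirna", "gene"]).any():
            dups = edges[edges.duplicated(["mirna", "gene"])]
            raise ValueError(
                f"duplicate (mirna, gene) edges, e.g. {dups.iloc[0].tolist()[:2]}"
            )
        self.edges = edges.reset_index(drop=True)
        self._targets: dict[str, frozenset[str]] = {
            m: frozenset(g["gene"]) for m, g in edges.groupby("mirna")
        }

    @property
    def mirnas(self) -> list[str]:
        return sorted(self._targets)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self._targets.get(mirna, frozenset())

    def targets_of_set(
        self, mirnas: Iterable[str], evidence: str | None = None
    ) -> set[str]:
        if evidence is None:
            out: set[str] = set()
            for m in mirnas:
                out |= self._targets.get(m, frozenset())
            return out
        sub = self.edges[self.edges["evidence"] == evidence]
        keep = sub[sub["mirna"].isin(set(mirnas))]
        return set(keep["gene"])

    def gene_universe(self) -> frozenset[str]:
        """Genes with at least one miRNA association."""
        return frozenset(self.edges["gene"])


class PathwayOntology:
    """Named gene sets (GMT semantics: name, description, members)."""

    def __init__(
        self,
        pathways: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self.pathways: dict[str, frozenset[str]] = {}
        for name, genes in pathways.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            self.pathways[name] = genes
        self.descriptions = dict(descriptions or {})

    def __iter__(self):
        return iter(sorted(self.pathways))

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]


@dataclass
class InteractionGraph:
    """Directed signed gene-interaction graph (activating/inhibiting/unknown)."""

    graph: nx.DiGraph

    SIGNS = ("activating", "inhibiting", "unknown")
    # specificity order used when collapsing parallel edges
    _SPECIFICITY = {"activating": 2, "inhibiting": 2, "unknown": 1}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "InteractionGraph":
        g = nx.DiGraph()
        for source, sign, target in edges:
            if sign not in cls.SIGNS:
                raise ValueError(f"unknown interaction sign {sign!r}")
            if source == target:
                continue  # no self-loops
            if g.has_edge(source, target):
                old = g[source][target]["sign"]
                if cls._SPECIFICITY[sign] > cls._SPECIFICITY[old]:
                    g[source][target]["sign"] = sign
            else:
                g.add_edge(source, target, sign=sign)
        return cls(g)

    def to_edges(self) -> list[tuple[str, str, str]]:
        return sorted(
            (u, d["sign"], v) for u, v, d in self.graph.edges(data=True)
        )


@dataclass
class AnnotationCatalog:
    """Gene -> (term, category) annotations for the prioritization funnel.

    Categories: disease_biomarker, canonical_pathway, go_process,
    toxic_pathology. The catalog is assumed to be pre-filtered to
    neurologically relevant terms, so catalog membership is the
    neuro-association test.
    """

    table: pd.DataFrame  # columns: gene, term, category

    def __post_init__(self) -> None:
        required = {"gene", "term", "category"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"catalog needs columns {sorted(required)}")
        bad = set(self.table["category"]) - set(CATALOG_CATEGORIES)
        if bad:
            raise ValueError(f"unknown catalog categories: {sorted(bad)}")
        self.table = self.table.drop_duplicates(["gene", "term", "category"]).reset_index(
            drop=True
        )

    def terms_of(self, gene: str, categories: Iterable[str] | None = None) -> set[str]:
        rows = self.table[self.table["gene"] == gene]
        if categories is not None:
            rows = rows[rows["category"].isin(set(categories))]
        return set(rows["term"])

    def genes(self) -> set[str]:
        return set(self.table["gene"])
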