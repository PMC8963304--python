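# mirtox

A workflow for discovering secreted microRNA (miRNA) biomarkers of
chemical-induced neurodegeneration, exercised end to end on synthetic data
with planted ground truth.

Cultured human neurons exposed to neurotoxicants release miRNAs into the
medium; changes in that secreted profile can report neurite damage before
cell death. The workflow mirrors a screening study of that design:

1. **Apical endpoints** — viability (ATP) and morphology (neurite length,
   neurite count, neurons per field) are measured over a concentration range,
   normalized to percent of same-plate vehicle control, and compared to
   vehicle with Dunnett's many-to-one test. A *low* test concentration is the
   smallest with minimal viability loss but a significant ≥ 20% neurite
   decrease; the *high* one is the smallest with significant decreases in
   both (falling back to the maximum tested concentration for microtubule
   poisons that never depress viability).
2. **Differential expression** — a qPCR array panel of secreted miRNAs per
   exposure. Threshold-cycle (Ct) values at/above the 35-cycle detection
   limit are right-censored; each plate is normalized by subtracting raw Ct
   from the plate mean of non-censored Ct; paired t-tests (treated vs control
   replicates) with a joint filter — fold change ≥ 1.5 or ≤ 0.67 **and** raw
   p < .01 — select candidates. BH-adjusted p and Storey q-values ride along
   for reporting. Panel assays that map to discontinued or non-human
   identifiers are dropped.
3. **Clustering** — significant miRNAs are clustered on their log2
   fold-change profiles across exposures (UPGMA, Euclidean distance) with an
   adaptive dendrogram cut that splits merges standing well clear of their
   branches' internal heights, recovering strong-down / mild-down / mild-up /
   strong-up response groups without a fixed cut height.
4. **Dual pathway enrichment** — miRNAs are sparsely represented in pathway
   collections, so over-representation is tested twice: at the gene level on
   the targets of the significant miRNAs over a miRNA-associated gene
   universe (biased toward high-degree miRNAs) and at the miRNA level against
   each pathway's associated miRNA set (biased the other way). Pathways
   BH-significant in both are ranked by Fisher-combined p. Cluster-wise
   pathway-union enrichment and the pathways common to all clusters are also
   reported.
5. **Target prioritization** — validated mRNA targets of the significant
   miRNAs are filtered for neurological relevance (annotated in the catalog,
   ≥ 1 biomarker or canonical-pathway relationship, more than one associated
   condition), each survivor's expression direction is predicted from its
   repressing miRNAs' fold changes, and signaling cascades between survivors
   are traced through a signed interaction graph.

Every generator plants known truth (spiked miRNAs, a planted pathway holding
most of their targets, Hill dose-response curves), so each stage is testable
for recovery, calibration, and determinism without external data.

## Usage

Everything is driven by one seed; identical seed and configuration give
byte-identical outputs.

```
mirtox run-all --seed 0 --out results/run
```

writes all stage tables plus `manifest.json` summarizing counts, cluster
sizes, the planted pathway's enrichment rank, and ground truth. Individual
stages are exposed as subcommands (`mirtox simulate`, `apical`, `diffexp`,
`cluster`, `enrich`, `prioritize`); see `mirtox --help`.

The same stages exist as numbered drivers under `analysis/`, chained through
`results/`:

```
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_apical_selection.py
python analysis/03_differential_expression.py
python analysis/04_cluster_profiles.py
python analysis/05_pathway_enrichment.py
python analysis/06_prioritize_targets.py
```

Output of the run above:

```
acet: low=None high=100.0
bis: low=10.0 high=100.0
col: low=0.1 high=100.0
dox: low=1.0 high=10.0
ptx: low=0.1 high=100.0
rot: low=0.1 high=10.0
61 significant miRNA(s), 59 after annotation mapping
5 cluster(s) with sizes [11, 9, 22, 7, 10] over 59 miRNAs
1 pathway(s) significant in both methods
  rank 1: PW_planted (combined p = 9.08e-187)
common to all clusters: none
59 significant miRNA(s) -> 74 prioritized target(s), 28726 cascade(s), 7072 merged edge(s)
```

The negative control (acet) is reported with no qualifying low concentration;
the planted pathway is recovered at enrichment rank 1; the four spiked
magnitude bands appear as four clusters plus one central false-positive
group.

## Tests and acceptance

```
python -m pytest -q tests/
python scripts/acceptance.py --seed 0 --out results/acceptance.json
```

The acceptance script writes the headline quantities (oracle equivalence
errors, normalization invariant, null p-value calibration, spike recovery,
planted-pathway rank recovery at overlap 0.8 vs 0, Dunnett family-wise error,
clustering Rand indices, and the end-to-end determinism digest) as JSON; see
`docs/methods.md` for the statistical models, parameter defaults, and known
power limits of the joint filter at three replicate pairs.

## Layout

- `src/mirtox/` — the library: `synthdata`, `apical`, `diffexp`,
  `clustering`, `enrichment`, `targets`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered stage drivers.
- `scripts/acceptance.py` — headline quantities as JSON.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — models and parameter rationale.
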