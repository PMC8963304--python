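"""Dual bias-corrected pathway enrichment and Fisher-combined ranking.

miRNA signaling is sparsely represented in curated pathway collections, so a
direct over-representation test of miRNAs is biased. Two complementary
hypergeometric tests correct this from opposite directions:

* Method 1 (gene level): pathways are tested for enrichment of the *targets*
  of the significant miRNAs, over a universe restricted to genes with at
  least one miRNA association in the supplied network. Biased toward miRNAs
  with many targets.
* Method 2 (miRNA level): each pathway is transformed into the set of miRNAs
  with at least one target gene in it, and the significant-miRNA set is
  tested against it over the miRNA universe. Biased toward miRNAs with few
  targets.

Pathways significant in both (BH-adjusted p < .01 within each method) are
retained and ranked by the Fisher-combined p across the two methods. A
separate cluster-wise "pathway union" enrichment combines per-miRNA
hypergeometric p-values with Fisher's method per pathway, and the pathways
shared by all clusters are intersected.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PathwayOntology, TargetNetwork
from .diffexp import bh_adjust


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    Drawing n items from a universe of N containing K marked items, the
    probability of seeing at least k marked. k=0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_combine(pvalues) -> float:
    """Fisher's method: -2 sum(ln p) against chi-square with 2k df."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(arr))
    return float(stats.chi2.sf(x, 2 * arr.size))


def enrich_targets_method1(
    sig_mirnas, network: TargetNetwork, ontology: PathwayOntology
) -> pd.DataFrame:
    """Gene-level enrichment of significant-miRNA targets per pathway.

    Universe N = genes with >= 1 miRNA association in the network; query
    n = union of the significant miRNAs' targets; per pathway K = pathway
    genes inside the universe, k = query genes inside the pathway. Pathways
    disjoint from the universe are recorded with K=0 and p=1.
    """
    sig = sorted(set(sig_mirnas))
    universe = network.gene_universe()
    if not universe:
        raise ValueError("empty gene universe: the network has no edges")
    query = network.targets_of_set(sig) & universe
    rows = []
    for name in ontology:
        pw = ontology[name] & universe
        K, n, N = len(pw), len(query), len(universe)
        k = len(query & pw)
        p = hypergeom_upper(k, K, n, N) if K else 1.0
        rows.append((name, p, k, K, n, N))
    return pd.DataFrame(rows, columns=["pathway", "p", "k", "K", "n", "N"])


def enrich_mirna_sets_method2(
    sig_mirnas, network: TargetNetwork, ontology: PathwayOntology
) -> pd.DataFrame:
    """miRNA-level enrichment against pathway-associated miRNA sets.

    Each pathway becomes the miRNA set {m : targets(m) intersects pathway};
    universe N = all miRNAs in the network (config-overridable upstream by
    restricting the network), n = significant miRNAs, k = their overlap with
    the pathway's miRNA set.
    """
    sig = sorted(set(sig_mirnas))
    if not sig:
        raise ValueError("significant miRNA set is empty")
    all_mirnas = network.mirnas
    if not all_mirnas:
        raise ValueError("empty miRNA universe: the network has no edges")
    N = len(all_mirnas)
    n = len(set(sig) & set(all_mirnas))
    if n == 0:
        raise ValueError("no significant miRNA appears in the network")
    rows = []
    for name in ontology:
        pw = ontology[name]
        pw_mirnas = {m for m in all_mirnas if network.targets_of(m) & pw}
        K = len(pw_mirnas)
        k = len(pw_mirnas & set(sig))
        p = hypergeom_upper(k, K, n, N) if K else 1.0
        rows.append((name, p, k, K, n, N))
    return pd.DataFrame(rows, columns=["pathway", "p", "k", "K", "n", "N"])


def combine_dual(
    p1: pd.DataFrame,
    p2: pd.DataFrame,
    bh_alpha: float = 0.01,
    report_alpha: float = 0.001,
    top_n: int = 20,
) -> pd.DataFrame:
    """Intersect the two enrichment methods and rank by Fisher-combined p.

    BH adjustment is applied within each method across pathways;
    ``significant_both`` requires BH p < ``bh_alpha`` in both. Ranks (1..m,
    no gaps) are assigned only among significant_both pathways, ascending in
    the Fisher-combined p of the two raw p-values. The ``reported`` flag
    marks the visualization subset: the ``top_n`` ranked pathways with raw
    p < ``report_alpha`` in both methods.
    """
    if set(p1["pathway"]) != set(p2["pathway"]):
        raise ValueError("method 1 and 2 tables cover different pathway sets")
    a = p1.set_index("pathway").sort_index()
    b = p2.set_index("pathway").sort_index()
    out = pd.DataFrame(
        {
            "p_method1": a["p"],
            "p_method2": b["p"],
            "k1": a["k"], "K1": a["K"], "n1": a["n"], "N1": a["N"],
            "k2": b["k"], "K2": b["K"], "n2": b["n"], "N2": b["N"],
        }
    )
    out["bh1"] = bh_adjust(out["p_method1"])
    out["bh2"] = bh_adjust(out["p_method2"])
    out["fisher_combined_p"] = [
        fisher_combine((r.p_method1, r.p_method2)) for r in out.itertuples()
    ]
    out["significant_both"] = (out["bh1"] < bh_alpha) & (out["bh2"] < bh_alpha)
    out["rank"] = 0
    sig = out[out["significant_both"]].sort_values(
        ["fisher_combined_p", "p_method1"], kind="mergesort"
    )
    out.loc[sig.index, "rank"] = np.arange(1, len(sig) + 1)
    out["reported"] = (
        out["significant_both"]
        & (out["rank"] > 0)
        & (out["rank"] <= top_n)
        & (out["p_method1"] < report_alpha)
        & (out["p_method2"] < report_alpha)
    )
    return out.reset_index().rename(columns={"index": "pathway"})


def pathway_union_enrichment(
    cluster_mirnas,
    network: TargetNetwork,
    ontology: PathwayOntology,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cluster-wise pathway-union enrichment (per-miRNA Fisher combination).

    For each (miRNA, pathway) a hypergeometric test of that miRNA's targets
    against the pathway over the gene universe; per pathway the p-values of
    the cluster's miRNAs with non-empty target sets are combined with
    Fisher's method. A pathway is significant when the combined p < alpha and
    at least one cluster miRNA contributes a target to it.
    """
    cluster = sorted(set(cluster_mirnas))
    if not cluster:
        raise ValueError("cluster is empty")
    universe = network.gene_universe()
    if not universe:
        raise ValueError("empty gene universe: the network has no edges")
    N = len(universe)
    rows = []
    for name in ontology:
        pw = ontology[name] & universe
        if not pw:
            continue
        pvals = []
        n_contributing = 0
        for m in cluster:
            targets = network.targets_of(m) & universe
            if not targets:
                continue
            k = len(targets & pw)
            if k:
                n_contributing += 1
            pvals.append(hypergeom_upper(k, len(pw), len(targets), N))
        if not pvals or n_contributing == 0:
            continue
        combined = fisher_combine(pvals)
        rows.append((name, combined, n_contributing, len(pvals)))
    out = pd.DataFrame(
        rows, columns=["pathway", "p_combined", "n_mirnas_with_targets", "n_mirnas_tested"]
    )
    out["significant"] = out["p_combined"] < alpha
    return out.sort_values("pathway", kind="mergesort").reset_index(drop=True)


def common_pathways(per_cluster_significant: dict[int, set[str]] | list[set[str]]) -> list[str]:
    """Intersection of per-cluster significant pathway sets, name-sorted."""
    if isinstance(per_cluster_significant, dict):
        sets = list(per_cluster_significant.values())
    else:
        sets = list(per_cluster_significant)
    if not sets:
        raise ValueError("need at least one cluster set")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    return sorted(common)
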