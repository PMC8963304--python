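"""Censored Ct normalization and paired differential expression.

The qPCR array workflow: raw threshold-cycle (Ct) values at or above the
detection limit (35 cycles by default) are capped at the limit and flagged as
right-censored; each plate (one array card holding all samples of one
compound) is normalized by subtracting every raw Ct from the plate mean
computed over *non-censored* entries only, so higher normalized values mean
higher expression; paired t-tests compare treated vs control replicates;
fold change is 2 raised to the difference of mean normalized expression.
Multiple testing is summarized by both Benjamini-Hochberg adjusted p-values
and Storey q-values, but the candidate-selection filter deliberately uses the
raw p (< .01) together with a fold-change screen (>= 1.5 or <= 0.67), relying
on downstream pathway-level convergence to control the false-positive risk.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ANNOTATION_STATUSES, CtMatrix, NormalizedExpression

FC_UP = 1.5
FC_DOWN = 1 / FC_UP  # 0.666..., printed as 0.67
P_RAW = 0.01


def cap_detection_limit(raw: CtMatrix) -> CtMatrix:
    """Cap values at the detection limit and flag them as censored."""
    limit = raw.detection_limit
    censored = raw.values >= limit
    values = raw.values.where(~censored, other=limit)
    return CtMatrix(
        values=values,
        samples=raw.samples.copy(),
        detection_limit=limit,
        censored=censored,
    )


def mean_center_normalize(capped: CtMatrix) -> NormalizedExpression:
    """Plate-mean-centered expression from a capped Ct matrix.

    The plate mean is computed over non-censored entries only; the normalized
    value ``plate_mean - raw Ct`` is produced for *all* entries, censored
    included (their attenuated values stay in downstream tests, flagged).
    """
    if capped.censored is None:
        capped = cap_detection_limit(capped)
    values = capped.values
    censored = capped.censored
    plate_means = {}
    out = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for plate, sheet in capped.samples.groupby("plate"):
        cols = sheet.index
        block = values[cols]
        mask = ~censored[cols]
        n_ok = int(mask.to_numpy().sum())
        if n_ok == 0:
            raise ValueError(f"plate {plate!r} is fully censored")
        mean = float(block.to_numpy()[mask.to_numpy()].mean())
        plate_means[plate] = mean
        out[cols] = mean - block
    return NormalizedExpression(
        values=out,
        censored=censored.copy(),
        plate_means=pd.Series(plate_means, name="plate_mean"),
        samples=capped.samples.copy(),
    )


def _paired_arrays(
    norm: NormalizedExpression, ct: CtMatrix, treatment: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    pairs = ct.pairs(treatment)
    treated = norm.values[pairs["treated"]].to_numpy()
    control = norm.values[pairs["control"]].to_numpy()
    return treated, control, pairs


def fold_change(
    norm: NormalizedExpression, ct: CtMatrix, treatment: str
) -> pd.Series:
    """Per-miRNA fold change 2**(mean treated - mean control normalized)."""
    treated, control, _ = _paired_arrays(norm, ct, treatment)
    delta = treated.mean(axis=1) - control.mean(axis=1)
    return pd.Series(2.0 ** delta, index=norm.values.index, name="fold_change")


def paired_t(
    norm: NormalizedExpression, ct: CtMatrix, treatment: str
) -> pd.DataFrame:
    """Vectorized paired t-test per miRNA: treated vs control replicates.

    Degenerate rows (zero variance of differences) are reported rather than
    erroring: zero mean gives t=0, p=1; nonzero mean gives the smallest
    positive double with a ``degenerate`` flag.
    """
    treated, control, pairs = _paired_arrays(norm, ct, treatment)
    n = treated.shape[1]
    if n < 2:
        raise ValueError(f"treatment {treatment!r} has {n} pair(s); need >= 2")
    d = treated - control
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = sd == 0
    zero_both = degenerate & (mean == 0)
    t = np.where(zero_both, 0.0, t)
    p = np.where(zero_both, 1.0, p)
    nonzero_degen = degenerate & (mean != 0)
    p = np.where(nonzero_degen, np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "t_stat": t,
            "df": df,
            "p": p,
            "n_pairs": n,
            "degenerate": degenerate,
        },
        index=norm.values.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def storey_q(
    p: np.ndarray | pd.Series, lam: float = 0.5, pi0: float | None = None
) -> np.ndarray:
    """Storey q-values with a fixed lambda (no smoother).

    pi0 = min(1, #{p > lam} / ((1 - lam) * m)); with fewer than 10 p-values
    pi0 is fixed at 1 (where the estimator is useless), and an explicit
    ``pi0`` overrides the estimate (pi0=1 reduces q exactly to BH). q_i is
    the minimum of pi0 * m * t / #{p <= t} over thresholds t >= p_i,
    evaluated at the observed p-values, which makes q monotone in p.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = arr.size
    if pi0 is not None:
        if not (0 < pi0 <= 1):
            raise ValueError("pi0 must lie in (0, 1]")
    elif m < 10:
        pi0 = 1.0
    else:
        pi0 = min(1.0, np.sum(arr > lam) / ((1.0 - lam) * m))
    order = np.argsort(arr, kind="mergesort")
    ps = arr[order]
    # FDR estimate at each observed threshold, then running min from the top
    fdr = pi0 * m * ps / np.arange(1, m + 1)
    qs = np.minimum.accumulate(fdr[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    return out


def differential_table(
    norm: NormalizedExpression, ct: CtMatrix, treatments: list[str] | None = None
) -> pd.DataFrame:
    """Full differential record per (miRNA, exposure).

    Columns: mirna, exposure, fold_change, t_stat, df, p, q_storey, p_bh,
    significant, n_pairs, censored_fraction. FDR quantities are computed
    across miRNAs within each exposure.
    """
    if treatments is None:
        treatments = sorted(
            set(ct.samples.loc[ct.samples["role"] == "treated", "treatment"])
        )
    blocks = []
    for trt in treatments:
        tt = paired_t(norm, ct, trt)
        fc = fold_change(norm, ct, trt)
        pairs = ct.pairs(trt)
        used = list(pairs["treated"]) + list(pairs["control"])
        cens_frac = norm.censored[used].mean(axis=1)
        block = pd.DataFrame(
            {
                "mirna": norm.values.index,
                "exposure": trt,
                "fold_change": fc.to_numpy(),
                "t_stat": tt["t_stat"].to_numpy(),
                "df": tt["df"].to_numpy(),
                "p": tt["p"].to_numpy(),
                "q_storey": storey_q(tt["p"].to_numpy()),
                "p_bh": bh_adjust(tt["p"].to_numpy()),
                "n_pairs": tt["n_pairs"].to_numpy(),
                "censored_fraction": cens_frac.to_numpy(),
                "degenerate": tt["degenerate"].to_numpy(),
            }
        )
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)
    return select_significant(table)


def select_significant(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the joint effect-size and raw-p filter.

    significant <=> (fold_change >= 1.5 or <= 1/1.5) and p < .01. The q and
    BH columns ride along for reporting but do not drive the flag.
    """
    records = records.copy()
    fc = records["fold_change"]
    records["significant"] = ((fc >= FC_UP) | (fc <= FC_DOWN)) & (records["p"] < P_RAW)
    return records


def map_annotations(
    assay_names: list[str], annotation: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Classify assay names against an annotation table; drop non-mappable ones.

    ``annotation`` columns: assay_name, accession, gene_id, status. Names
    absent from the table are 'unmapped'; rows whose status is 'discontinued'
    or 'non-human', or with an empty gene_id, are excluded downstream.
    Returns (annotation map with a reason column, retained assay names).
    """
    required = {"assay_name", "accession", "gene_id", "status"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    if annotation["assay_name"].duplicated().any():
        dup = annotation.loc[annotation["assay_name"].duplicated(), "assay_name"].iloc[0]
        raise ValueError(f"duplicate assay name in annotation table: {dup!r}")
    bad = set(annotation["status"]) - set(ANNOTATION_STATUSES)
    if bad:
        raise ValueError(f"unknown annotation statuses: {sorted(bad)}")
    lookup = annotation.set_index("assay_name")
    rows = []
    retained = []
    for name in assay_names:
        if name not in lookup.index:
            rows.append((name, "", "", "unmapped", "absent from annotation table"))
            continue
        rec = lookup.loc[name]
        status = rec["status"]
        gene = "" if pd.isna(rec["gene_id"]) else str(rec["gene_id"])
        if status == "mapped" and not gene:
            status, reason = "unmapped", "no gene id"
        elif status == "mapped":
            reason = ""
        elif status == "discontinued":
            reason = "maps to a discontinued gene id"
        elif status == "non-human":
            reason = "not a human miRNA"
        else:
            reason = "declared unmapped"
        rows.append((name, rec["accession"], gene, status, reason))
        if status == "mapped":
            retained.append(name)
    amap = pd.DataFrame(
        rows, columns=["assay_name", "accession", "gene_id", "status", "reason"]
    )
    return amap, retained
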