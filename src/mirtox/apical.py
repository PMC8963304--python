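"""Apical endpoint analysis and test-concentration selection.

Cell viability (ATP) and morphology endpoints (neurite length, neurite count,
neurons per field) are normalized to percent of the same-plate vehicle mean,
pooled across plates, and compared to vehicle with Dunnett's many-to-one test.
The low/high concentrations forwarded to miRNA profiling follow the screening
rule: the low concentration is the smallest with no/minimal viability loss
(ATP decrease <= 20%) but a statistically significant >= 20% decrease in a
neurite outgrowth endpoint; the high concentration is the smallest with
significant >= 20% decreases in both viability and neurite endpoints, falling
back to the maximum tested concentration for compounds (microtubule poisons)
that never meaningfully depress viability.

Dunnett adjusted p-values are computed by seeded Monte-Carlo integration of
the null distribution of the maximum |t| over the many-to-one comparisons
(pooled variance, arbitrary group sizes); with a single treated group the
exact central-t tail is used, so the test reduces to the classic pooled
two-sample t.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NEURITE_ENDPOINTS = ("neurite_length", "neurite_count")

_NULL_CACHE: dict[tuple, np.ndarray] = {}
DUNNETT_DRAWS = 100_000
DUNNETT_SEED = 913_451  # fixed stream for the null integration


def normalize_percent_of_control(records: pd.DataFrame) -> pd.DataFrame:
    """Scale well values to percent of the same-plate vehicle mean.

    Requires >= 2 vehicle wells (concentration 0) per (chemical, endpoint,
    plate). After normalization the vehicle mean on every plate is exactly
    100, so plates with different raw scales become poolable. Idempotent.
    """
    required = {"chemical", "concentration_uM", "plate", "endpoint", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    out = records.copy()
    out["pct_of_control"] = np.nan
    for (chem, ep, plate), idx in out.groupby(
        ["chemical", "endpoint", "plate"]
    ).groups.items():
        block = out.loc[idx]
        vehicle = block.loc[block["concentration_uM"] == 0, "value"]
        if len(vehicle) < 2:
            raise ValueError(
                f"fewer than 2 vehicle wells for plate {plate!r}, endpoint {ep!r}"
                f" (chemical {chem!r})"
            )
        out.loc[idx, "pct_of_control"] = block["value"] / vehicle.mean() * 100.0
    return out


def _max_abs_t_null(ns: tuple[int, ...], df: int, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo sample of max_j |T_j| under the many-to-one null.

    ns = (n_control, n_1, ..., n_k). Group means are drawn independently, the
    pooled variance as chi-square(df)/df, reproducing the equicorrelated (or
    general, at unequal n) multivariate-t dependence across comparisons.
    """
    key = (ns, df, n_draws, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        n0, *rest = ns
        z = rng.standard_normal((n_draws, len(ns)))
        means = z / np.sqrt(np.asarray(ns))
        s = np.sqrt(rng.chisquare(df, n_draws) / df)
        se = np.sqrt(1.0 / np.asarray(rest) + 1.0 / n0)
        t = (means[:, 1:] - means[:, [0]]) / (s[:, None] * se)
        _NULL_CACHE[key] = np.sort(np.abs(t).max(axis=1))
    return _NULL_CACHE[key]


def dunnett_pvalues(
    groups: list[np.ndarray],
    control: np.ndarray,
    n_draws: int = DUNNETT_DRAWS,
    seed: int = DUNNETT_SEED,
) -> pd.DataFrame:
    """Two-sided Dunnett many-to-one comparisons against a shared control.

    Returns a frame with the per-group t statistic (pooled variance) and the
    family-wise adjusted p-value P(max_j |T_j| >= |t_i|) under the joint null.
    """
    if not groups:
        raise ValueError("need at least one treated group")
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(control) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    k = len(groups)
    ns = (len(control), *(len(g) for g in groups))
    n_total = sum(ns)
    df = n_total - (k + 1)
    ss = float(np.sum((control - control.mean()) ** 2)) + sum(
        float(np.sum((g - g.mean()) ** 2)) for g in groups
    )
    if ss == 0:
        raise ValueError("zero pooled variance; data are degenerate")
    s2 = ss / df
    t = np.array(
        [
            (g.mean() - control.mean()) / np.sqrt(s2 * (1.0 / len(g) + 1.0 / len(control)))
            for g in groups
        ]
    )
    if k == 1:
        p_adj = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        null = _max_abs_t_null(ns, df, n_draws, seed)
        # (count + 1)/(N + 1) keeps adjusted p in (0, 1]
        exceed = len(null) - np.searchsorted(null, np.abs(t), side="left")
        p_adj = (exceed + 1.0) / (len(null) + 1.0)
    return pd.DataFrame({"t_stat": t, "df": df, "p_adj": np.minimum(p_adj, 1.0)})


def dunnett_critical_value(
    ns: tuple[int, ...],
    alpha: float = 0.05,
    n_draws: int = DUNNETT_DRAWS,
    seed: int = DUNNETT_SEED,
) -> float:
    """Two-sided critical max-|t| at family-wise level alpha for design ns."""
    df = sum(ns) - len(ns)
    null = _max_abs_t_null(tuple(ns), df, n_draws, seed)
    return float(np.quantile(null, 1.0 - alpha))


def dunnett_test(normalized: pd.DataFrame, endpoint: str, chemical: str) -> pd.DataFrame:
    """Dunnett comparisons of each concentration vs vehicle for one endpoint.

    Works on pooled percent-of-control values. Returns one row per treated
    concentration with mean_pct, n, t_stat, df, p_adj, sorted by concentration.
    """
    block = normalized[
        (normalized["chemical"] == chemical) & (normalized["endpoint"] == endpoint)
    ]
    if block.empty:
        raise KeyError(f"no records for chemical {chemical!r}, endpoint {endpoint!r}")
    control = block.loc[block["concentration_uM"] == 0, "pct_of_control"].to_numpy()
    concs = sorted(c for c in block["concentration_uM"].unique() if c > 0)
    if not concs:
        raise ValueError(f"no treated concentrations for {chemical!r}/{endpoint!r}")
    groups = [
        block.loc[block["concentration_uM"] == c, "pct_of_control"].to_numpy()
        for c in concs
    ]
    res = dunnett_pvalues(groups, control)
    res.insert(0, "concentration_uM", concs)
    res.insert(1, "mean_pct", [g.mean() for g in groups])
    res.insert(2, "n", [len(g) for g in groups])
    res.insert(0, "endpoint", endpoint)
    res.insert(0, "chemical", chemical)
    return res


def dunnett_all(normalized: pd.DataFrame) -> pd.DataFrame:
    """Dunnett tables for every (chemical, endpoint) present, concatenated."""
    blocks = []
    for chem in sorted(normalized["chemical"].unique()):
        sub = normalized[normalized["chemical"] == chem]
        for ep in sorted(sub["endpoint"].unique()):
            blocks.append(dunnett_test(normalized, ep, chem))
    return pd.concat(blocks, ignore_index=True)


def lowest_effect_concentration(results: pd.DataFrame, alpha: float = 0.05) -> float | None:
    """Smallest concentration with adjusted p < alpha, or None."""
    res = results.sort_values("concentration_uM")
    hits = res[res["p_adj"] < alpha]
    if hits.empty:
        return None
    return float(hits["concentration_uM"].iloc[0])


def endpoint_log2_foldchanges(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per (chemical, concentration) log2 fold change vs vehicle per endpoint."""
    treated = normalized[normalized["concentration_uM"] > 0]
    means = (
        treated.groupby(["chemical", "concentration_uM", "endpoint"])["pct_of_control"]
        .mean()
        .unstack("endpoint")
    )
    return np.log2(means / 100.0)


def correlate_endpoints(fc_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-condition log2 fold changes between endpoints.

    One row per unordered endpoint pair with r and the two-sided p from the
    t transform with n-2 degrees of freedom. Raises on zero variance.
    """
    endpoints = list(fc_table.columns)
    rows = []
    for i, a in enumerate(endpoints):
        for b in endpoints[i + 1 :]:
            sub = fc_table[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 paired points for {a!r} vs {b!r}")
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"zero variance in {a!r} or {b!r}")
            r, p = stats.pearsonr(x, y)
            p = max(float(p), np.finfo(float).tiny)
            rows.append((a, b, float(r), p, len(sub)))
    return pd.DataFrame(rows, columns=["endpoint_a", "endpoint_b", "r", "p", "n"])


@dataclass
class ConcentrationPair:
    """Selected low/high test concentrations for one chemical."""

    chemical: str
    low: float | None
    high: float | None
    low_rationale: str
    high_rationale: str

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError(f"{self.chemical}: low {self.low} exceeds high {self.high}")


def select_concentrations(
    dunnett_results: pd.DataFrame, alpha: float = 0.05, decrease_pct: float = 20.0
) -> dict[str, ConcentrationPair]:
    """Apply the low/high concentration-selection rule per chemical.

    A "significant decrease >= 20%" means pooled group mean <= 80% of control
    AND Dunnett adjusted p < .05 (pooled means; the per-plate alternative is
    noted in the rationale strings). Low: smallest concentration with ATP
    decrease <= 20% and a significant neurite decrease. High: smallest
    concentration with significant decreases in both ATP and a neurite
    endpoint; if none qualifies the maximum tested concentration is used.
    A chemical with no qualifying low concentration is reported explicitly
    (low None), never silently defaulted.
    """
    floor = 100.0 - decrease_pct
    out: dict[str, ConcentrationPair] = {}
    for chem in sorted(dunnett_results["chemical"].unique()):
        sub = dunnett_results[dunnett_results["chemical"] == chem]
        concs = sorted(sub["concentration_uM"].unique())
        atp = sub[sub["endpoint"] == "ATP"].set_index("concentration_uM")
        neurite = sub[sub["endpoint"].isin(NEURITE_ENDPOINTS)]
        low = high = None
        low_why = high_why = ""
        for c in concs:
            if c not in atp.index:
                continue
            nb = neurite[neurite["concentration_uM"] == c]
            neuro_sig = bool(((nb["mean_pct"] <= floor) & (nb["p_adj"] < alpha)).any())
            atp_mild = atp.loc[c, "mean_pct"] >= floor
            atp_sig = (atp.loc[c, "mean_pct"] <= floor) and (atp.loc[c, "p_adj"] < alpha)
            if low is None and atp_mild and neuro_sig:
                low = float(c)
                low_why = (
                    f"ATP decrease <= {decrease_pct:g}% (pooled mean "
                    f"{atp.loc[c, 'mean_pct']:.1f}%) with a significant neurite "
                    f"decrease >= {decrease_pct:g}% at {c:g} uM"
                )
            if high is None and atp_sig and neuro_sig:
                high = float(c)
                high_why = (
                    f"significant >= {decrease_pct:g}% decreases in both ATP and a "
                    f"neurite endpoint at {c:g} uM"
                )
        if low is None:
            low_why = "no qualifying low concentration"
        if high is None:
            high = float(max(concs))
            high_why = (
                "no concentration met the joint viability+neurite rule; maximum "
                f"tested concentration {high:g} uM selected"
            )
        if low is not None and low > high:
            low, low_why = None, "no qualifying low concentration at or below high"
        out[chem] = ConcentrationPair(chem, low, high, low_why, high_why)
    return out
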