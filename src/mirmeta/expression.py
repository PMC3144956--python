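"""Microarray expression profiling and qPCR relative quantification.

Array signals from two metamorphic stages (17 and 29 days post hatching,
three replicate probes each) are background-subtracted, normalized with a
cyclic LOWESS filter, thresholded for detection, and tested for
differential expression probe-by-probe with a two-sided t-test at n=3 per
stage. Significant probes (p < 0.01, matching the published analysis,
which applied no multiple-testing correction) are split into high- and
low-signal tiers at a mean signal of 500 and presented as a row-scaled,
hierarchically clustered matrix. qPCR Ct triplicates are quantified with
the comparative-threshold 2^-ddCt method against a 5S rRNA reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess

DETECTION_THRESHOLD = 32.0
REFERENCE_GENE = "5S_rRNA"


def subtract_background(signals: pd.DataFrame, background) -> pd.DataFrame:
    """Subtract a per-array scalar or per-probe background, flooring at 0."""
    if background is None:
        raise ValueError("background estimate is required")
    corrected = signals.sub(background) if np.isscalar(background) \
        else signals.sub(background, axis=0)
    return corrected.clip(lower=0.0)


def normalize_cyclic_lowess(
    arrays: pd.DataFrame,
    *,
    frac: float = 0.3,
    max_iter: int = 5,
    tol: float = 1e-3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Cyclic LOWESS normalization across arrays (columns).

    For every pair of arrays, cyclically, a locally weighted regression of
    M = log2-ratio on A = mean log2-intensity is fitted and half the
    fitted bias moved out of each array. Iteration stops when the largest
    absolute median M over all pairs drops below ``tol`` or after
    ``max_iter`` passes. Signals are offset by ``pseudocount`` before the
    log and returned on the original scale (floored at zero).
    """
    if arrays.shape[1] < 2:
        raise ValueError("cyclic LOWESS needs at least 2 arrays")
    logged = np.log2(arrays.to_numpy(dtype=float) + pseudocount)
    n_arrays = logged.shape[1]
    for _ in range(max_iter):
        worst = 0.0
        for i in range(n_arrays):
            for j in range(i + 1, n_arrays):
                m = logged[:, i] - logged[:, j]
                a = 0.5 * (logged[:, i] + logged[:, j])
                fitted = lowess(m, a, frac=frac, return_sorted=False)
                logged[:, i] -= fitted / 2.0
                logged[:, j] += fitted / 2.0
                worst = max(worst, abs(float(np.median(m))))
        if worst < tol:
            break
    out = np.maximum(2.0 ** logged - pseudocount, 0.0)
    return pd.DataFrame(out, index=arrays.index, columns=arrays.columns)


def call_detection(signals: pd.DataFrame, *, stages=("17dph", "29dph"),
                   threshold: float = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Per-stage detection flags: mean replicate signal strictly > threshold."""
    flags = {}
    for stage in stages:
        cols = [c for c in signals.columns if c.startswith(stage)]
        flags[stage] = signals[cols].mean(axis=1) > threshold
    return pd.DataFrame(flags)


def differential_expression(
    signals: pd.DataFrame,
    *,
    stages=("17dph", "29dph"),
    alpha: float = 0.01,
    tier_cut: float = 500.0,
    equal_var: bool = True,
    fdr: bool = False,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Two-sample t-tests between stages for every detected probe.

    Probes detected in neither stage are reported undetected and excluded
    from testing. Zero variance in both groups with equal means yields
    p = 1 by convention. ``fdr=True`` adds Benjamini-Hochberg adjusted
    p-values (off by default: the published analysis thresholded raw p).
    """
    cols_a = [c for c in signals.columns if c.startswith(stages[0])]
    cols_b = [c for c in signals.columns if c.startswith(stages[1])]
    detected = call_detection(signals, stages=stages,
                              threshold=detection_threshold)
    rows = []
    for probe, row in signals.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        is_detected = bool(detected.loc[probe].any())
        if not is_detected:
            p = np.nan
        elif a.std() == 0.0 and b.std() == 0.0:
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        larger = max(mean_a, mean_b)
        rows.append({
            "probe": probe,
            f"mean_{stages[0]}": mean_a,
            f"mean_{stages[1]}": mean_b,
            "detected": is_detected,
            "p_value": p,
            "significant": is_detected and p < alpha,
            "tier": "high" if larger > tier_cut else "low",
            "direction": (f"up_{stages[0]}" if mean_a > mean_b
                          else f"up_{stages[1]}"),
        })
    df = pd.DataFrame(rows).set_index("probe")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        mask = df["p_value"].notna()
        adj = np.full(len(df), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                df.loc[mask, "p_value"], method="fdr_bh")[1]
        df["p_adjusted"] = adj
    return df


def cluster_and_scale(
    matrix: pd.DataFrame, *, clip: float = 1.5,
) -> tuple[pd.DataFrame, list[str], hierarchy.ClusterNode | None]:
    """Row-scale a DE signal matrix and order rows by hierarchical clustering.

    Rows are z-scaled (constant rows become all zeros) and clipped to
    [-clip, +clip]; average-linkage clustering on Euclidean distance
    determines the leaf order. Rows are pre-sorted by name so ties merge
    deterministically. Returns (scaled matrix in leaf order, leaf names,
    root ClusterNode).
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    matrix = matrix.sort_index()
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    scaled = np.where(sd > 0, (values - mu) / np.where(sd == 0, 1, sd), 0.0)
    scaled = np.clip(scaled, -clip, clip)
    link = hierarchy.linkage(pdist(scaled, metric="euclidean"),
                             method="average")
    order = hierarchy.leaves_list(link)
    names = [matrix.index[i] for i in order]
    frame = pd.DataFrame(scaled, index=matrix.index,
                         columns=matrix.columns).loc[names]
    return frame, names, hierarchy.to_tree(link)


def dendrogram_newick(node: hierarchy.ClusterNode, names: list[str]) -> str:
    """Serialize a scipy cluster tree to a Newick string."""
    def walk(n: hierarchy.ClusterNode) -> str:
        if n.is_leaf():
            return names[n.id]
        return f"({walk(n.left)},{walk(n.right)}):{n.dist:.4g}"

    return walk(node) + ";"


def ddct_quantify(
    ct: pd.DataFrame,
    *,
    target: str,
    reference: str = REFERENCE_GENE,
    test_stage: str = "29dph",
    calibrator_stage: str = "17dph",
    alpha: float = 0.05,
) -> dict:
    """Relative expression by the comparative-threshold (2^-ddCt) method.

    dCt = mean(target Ct) - mean(reference Ct) per stage; ddCt =
    dCt(test) - dCt(calibrator); fold = 2^-ddCt. Significance is a paired
    t-test across replicate dCt values (replicate i of the test stage
    paired with replicate i of the calibrator), threshold p < ``alpha``.
    ``ct`` is long-form with columns gene, stage, replicate, ct.
    """
    def triplicate(gene: str, stage: str) -> np.ndarray:
        sel = ct[(ct["gene"] == gene) & (ct["stage"] == stage)]
        vals = sel.sort_values("replicate")["ct"].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"no Ct values for {gene} at {stage}")
        return vals

    d_ct = {}
    d_ct_reps = {}
    for stage in (calibrator_stage, test_stage):
        t = triplicate(target, stage)
        r = triplicate(reference, stage)
        if len(t) != len(r):
            raise ValueError("target and reference replicate counts differ")
        d_ct[stage] = float(t.mean() - r.mean())
        d_ct_reps[stage] = t - r
    ddct = d_ct[test_stage] - d_ct[calibrator_stage]
    fold = float(2.0 ** (-ddct))
    if np.allclose(d_ct_reps[test_stage], d_ct_reps[calibrator_stage]):
        p = 1.0
    else:
        p = float(stats.ttest_rel(d_ct_reps[test_stage],
                                  d_ct_reps[calibrator_stage]).pvalue)
    return {"target": target, "ddct": float(ddct), "fold_change": fold,
            "p_value": p, "significant": p < alpha}
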