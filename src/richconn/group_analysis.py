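"""Group statistics for edgewise connectivity, rich-club curves, behavior
and radiomic correlations, and segmentation reliability.

Edge values are analyzed on the Fisher-z scale (variance stabilization for
correlations).  The testing scheme follows common connectome practice:
a per-edge one-way ANOVA across the three groups acts as a gate; edges
passing the gate get post-hoc two-sample t-tests of each patient group
against the control group, with Benjamini-Hochberg FDR applied per
contrast across that contrast's tested edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "one_way_anova",
    "bh_fdr",
    "edgewise_group_stats",
    "curvewise_phinorm_stats",
    "significant_window",
    "aberrant_node_frequency",
    "behavior_correlation",
    "ICCResult",
    "icc_absolute_agreement",
]


def one_way_anova(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way fixed-effects ANOVA over columns.

    Each element of ``groups`` is an (n_i, m) array; F and p are returned
    per column.  Columns with zero within-group variance get NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.ndim != 2 for g in groups):
        groups = [np.atleast_2d(g.astype(float)).reshape(len(g), -1) for g in groups]
    n_i = np.array([g.shape[0] for g in groups])
    if np.any(n_i < 2):
        raise ValueError("every group needs at least 2 observations")
    n_total = int(n_i.sum())
    n_groups = len(groups)
    all_data = np.concatenate(groups, axis=0)
    grand = all_data.mean(axis=0)
    means = np.stack([g.mean(axis=0) for g in groups])
    ss_between = (n_i[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    df_b = n_groups - 1
    df_w = n_total - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = np.where(ss_within > 0, f, np.nan)
    p = np.where(np.isfinite(f), stats.f.sf(f, df_b, df_w), np.nan)
    return f, p


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj


def edgewise_group_stats(
    z_by_group: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    q: float = 0.05,
    control: str = "HC",
    gate: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-edge ANOVA plus gated post-hoc patient-vs-control t-tests.

    Parameters
    ----------
    z_by_group : mapping group name -> (n_subjects, n_edges) Fisher-z array.
    alpha : ANOVA gate level for post-hoc testing.
    q : FDR level, applied per contrast across its tested edges.
    gate : if False, t-tests run on every edge regardless of the ANOVA p.
    equal_var : pooled-variance t-test by default; False gives Welch.

    Returns a DataFrame with one row per edge: ``F``, ``p_anova``,
    ``tested``, and per patient group ``t_<g>``, ``p_<g>``, ``q_<g>``,
    ``sig_<g>``, ``decreased_<g>`` (patient mean below control mean).
    Edges with zero within-group variance are skipped (NaN, logged).
    """
    if control not in z_by_group:
        raise ValueError(f"control group {control!r} missing")
    names = list(z_by_group)
    patients = [g for g in names if g != control]
    arrays = {g: np.asarray(v, dtype=float) for g, v in z_by_group.items()}
    f, p_anova = one_way_anova([arrays[g] for g in names])
    n_skipped = int(np.sum(~np.isfinite(f)))
    if n_skipped:
        log.info("edgewise ANOVA skipped %d zero-variance edges", n_skipped)
    tested = np.isfinite(p_anova) & ((p_anova < alpha) | (not gate))
    out = pd.DataFrame({"F": f, "p_anova": p_anova, "tested": tested})
    hc = arrays[control]
    for g in patients:
        t, p = stats.ttest_ind(arrays[g], hc, axis=0, equal_var=equal_var)
        t = np.where(tested, t, np.nan)
        p = np.where(tested, p, np.nan)
        qv = np.full_like(p, np.nan)
        sig = np.zeros(len(p), dtype=bool)
        idx = np.flatnonzero(tested & np.isfinite(p))
        if len(idx):
            rej, adj = bh_fdr(p[idx], q=q)
            qv[idx] = adj
            sig[idx] = rej
        out[f"t_{g}"] = t
        out[f"p_{g}"] = p
        out[f"q_{g}"] = qv
        out[f"sig_{g}"] = sig
        out[f"decreased_{g}"] = arrays[g].mean(axis=0) < hc.mean(axis=0)
    return out


def curvewise_phinorm_stats(
    phinorm_by_group: Mapping[str, np.ndarray],
    k_levels: np.ndarray | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
    control: str = "HC",
) -> pd.DataFrame:
    """Per-k group statistics on subject-level phi_norm summary curves.

    Each group maps to an (n_subjects, n_k) array; NaN marks k levels that
    are undefined for a subject and is excluded.  A k level is skipped
    when any group has fewer than 2 defined subjects there.  Post-hoc
    patient-vs-control t-tests are BH-FDR corrected across k levels.
    """
    names = list(phinorm_by_group)
    arrays = {g: np.asarray(v, dtype=float) for g, v in phinorm_by_group.items()}
    n_k = arrays[names[0]].shape[1]
    if k_levels is None:
        k_levels = np.arange(1, n_k + 1)
    patients = [g for g in names if g != control]
    rows = []
    for ki in range(n_k):
        cols = {g: arrays[g][:, ki][np.isfinite(arrays[g][:, ki])] for g in names}
        row: dict = {"k": int(k_levels[ki])}
        if any(len(c) < 2 for c in cols.values()):
            row.update({"F": np.nan, "p_anova": np.nan, "skipped": True})
            for g in patients:
                row[f"t_{g}"] = row[f"p_{g}"] = np.nan
            rows.append(row)
            continue
        try:
            fk, pk = one_way_anova([c[:, None] for c in cols.values()])
            row.update({"F": float(fk[0]), "p_anova": float(pk[0]),
                        "skipped": False})
        except ValueError:
            row.update({"F": np.nan, "p_anova": np.nan, "skipped": True})
        for g in patients:
            t, p = stats.ttest_ind(cols[g], cols[control])
            row[f"t_{g}"] = float(t)
            row[f"p_{g}"] = float(p)
            row[f"higher_{g}"] = bool(cols[g].mean() > cols[control].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    for g in patients:
        pvals = out[f"p_{g}"].to_numpy()
        qv = np.full_like(pvals, np.nan)
        sig = np.zeros(len(pvals), dtype=bool)
        idx = np.flatnonzero(np.isfinite(pvals))
        if len(idx):
            rej, adj = bh_fdr(pvals[idx], q=q)
            qv[idx] = adj
            sig[idx] = rej
        out[f"q_{g}"] = qv
        out[f"sig_{g}"] = sig
    return out


def significant_window(table: pd.DataFrame, group: str) -> tuple[int, int] | None:
    """The contiguous run of significant k containing the smallest one.

    Returns (k_lo, k_hi) or None when nothing is significant for the
    contrast; mirrors reporting a low-degree significant window.
    """
    sig = table[table[f"sig_{group}"] == True]  # noqa: E712
    if sig.empty:
        return None
    ks = np.sort(sig["k"].to_numpy())
    lo = hi = int(ks[0])
    for k in ks[1:]:
        if k == hi + 1:
            hi = int(k)
        else:
            break
    return lo, hi


def aberrant_node_frequency(
    edge_stats: pd.DataFrame,
    edge_i: np.ndarray,
    edge_j: np.ndarray,
    n_nodes: int,
    contrasts: list[str],
    top_m: int = 2,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Count significantly *decreased* edges incident to each node.

    Returns the per-node count table (one column per contrast, plus rank
    columns) and, per contrast, the ``top_m`` node indices ranked by
    count (ties to the lower node index).
    """
    counts = pd.DataFrame({"node": np.arange(n_nodes)})
    top: dict[str, list[int]] = {}
    for g in contrasts:
        hit = (edge_stats[f"sig_{g}"] & edge_stats[f"decreased_{g}"]).to_numpy()
        c = np.bincount(edge_i[hit], minlength=n_nodes) + \
            np.bincount(edge_j[hit], minlength=n_nodes)
        counts[f"count_{g}"] = c
        order = np.lexsort((np.arange(n_nodes), -c))
        counts[f"rank_{g}"] = np.empty(n_nodes, dtype=int)
        counts.loc[order, f"rank_{g}"] = np.arange(1, n_nodes + 1)
        top[g] = order[:top_m].tolist()
    return counts, top


def behavior_correlation(
    values: pd.DataFrame,
    scores: pd.DataFrame,
    fdr_q: float | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each value column with each score column.

    Rows of ``values`` and ``scores`` are paired subjects.  Constant
    vectors make the correlation undefined; those pairs are reported with
    NaN r/p and a reason in the ``note`` column.  With ``fdr_q`` set, a
    BH-adjusted ``q`` column is added across the defined pairs.
    """
    if len(values) != len(scores):
        raise ValueError("values and scores must have the same subjects")
    rows = []
    for feat in values.columns:
        for sc in scores.columns:
            x = values[feat].to_numpy(dtype=float)
            y = scores[sc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            n = len(x)
            row = {"feature": feat, "score": sc, "n": n}
            if n < 3:
                row.update(r=np.nan, p=np.nan, note="fewer than 3 pairs")
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                row.update(r=np.nan, p=np.nan, note="constant input")
            else:
                r, p = stats.pearsonr(x, y)
                row.update(r=float(r), p=float(p), note="")
            rows.append(row)
    out = pd.DataFrame(rows)
    if fdr_q is not None:
        qv = np.full(len(out), np.nan)
        idx = np.flatnonzero(np.isfinite(out["p"].to_numpy()))
        if len(idx):
            _, adj = bh_fdr(out["p"].to_numpy()[idx], q=fdr_q)
            qv[idx] = adj
        out["q"] = qv
    return out


@dataclass
class ICCResult:
    """Absolute-agreement intraclass correlation between raters."""

    icc: float
    model: str = "two-way random, absolute agreement, single measures (ICC(2,1))"
    threshold: float = 0.75
    reliable: bool = False


def icc_absolute_agreement(ratings: np.ndarray, threshold: float = 0.75) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an items x raters table.  From the two-way ANOVA mean
    squares (rows = items/targets, columns = raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Systematic rater offsets enter via MSC and lower the coefficient,
    which is what distinguishes absolute agreement from consistency.
    Returns NaN (not reliable) when the total variance is zero.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 raters")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return ICCResult(icc=float("nan"), threshold=threshold, reliable=False)
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(icc=float(icc), threshold=threshold,
                     reliable=bool(icc > threshold))
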