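"""MeD-seq-style promoter methylation analysis.

Counts are reads per region per sample, proportional to CpG methylation.
Rates are normalized to counts per million region reads within each sample,
so a global methylation shift (or sequencing-depth difference) cancels.
Differential methylation between conditions is a pooled two-proportion
chi-square test (with continuity correction; Fisher exact when expected
counts are small), Benjamini-Hochberg corrected over all tested regions.
Promoter clustering and the repeat-flank comparison reproduce the study's
negative controls: reactivated promoters neither cluster apart nor show
flank-methylation differences unless such an effect is planted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval, RepeatElement
from .features import GroupComparison, mann_whitney

logger = logging.getLogger(__name__)

METH_COLUMNS = ["region_id", "sample_id", "condition", "count"]


def load_methylation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative methylation count")
    return df


def promoter_regions(genes: list[GeneModel], flank_bp: int = 1000) -> pd.DataFrame:
    """Promoter registry: one region per gene spanning TSS +/- flank.

    Genes sharing a TSS get distinct region ids over the same interval.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive (empty promoter region)")
    rows = []
    for g in genes:
        start = max(g.tss - flank_bp, 0)
        rows.append(
            ("prom_" + g.gene_id, g.gene_id, g.interval.chrom, start,
             g.tss + flank_bp, g.strand)
        )
    return pd.DataFrame(
        rows, columns=["region_id", "gene_id", "chrom", "start", "end", "strand"]
    )


def normalize_methylation(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million region reads within each sample.

    Raises (naming the sample) when a sample's total is zero; multiplying a
    sample's counts by any positive constant leaves its rates unchanged.
    """
    totals = counts.groupby("sample_id")["count"].transform("sum")
    zero = counts.loc[totals == 0, "sample_id"].unique()
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {sorted(zero)}")
    out = counts.copy()
    out["rate_cpm"] = out["count"] / totals * 1e6
    return out


def _pooled_two_proportion(a, b, c, d) -> float:
    """Two-sided test of region proportion, control (a of a+b) vs treated
    (c of c+d); chi-square with continuity correction, Fisher when any
    expected cell count is below 5."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0 or table.sum(axis=1).min() == 0:
        return float("nan")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if expected.min() < 5:
        return float(stats.fisher_exact(table.astype(np.int64))[1])
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def differential_methylation(
    counts: pd.DataFrame,
    control_condition: str = "control",
    treated_condition: str = "tomato_high",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region differential methylation, treated vs control.

    Counts are pooled across replicates within each condition; each region's
    pooled count is tested against the rest of its condition's reads. Regions
    with zero pooled counts in both conditions are recorded untested (NaN p).
    Returns normalized rates, log2 fold change, p, BH FDR and the
    ``significantly_lower`` flag (FDR < alpha and treated rate < control).
    """
    for cond in (control_condition, treated_condition):
        if cond not in set(counts["condition"]):
            raise ValueError(f"condition {cond!r} absent from counts")
    sub = counts[counts["condition"].isin([control_condition, treated_condition])]
    pooled = (
        sub.groupby(["region_id", "condition"], sort=False)["count"]
        .sum()
        .unstack("condition")
        .fillna(0)
    )
    a = pooled[control_condition].to_numpy(dtype=np.int64)
    c = pooled[treated_condition].to_numpy(dtype=np.int64)
    tot_a, tot_c = int(a.sum()), int(c.sum())
    b, d = tot_a - a, tot_c - c

    rate_ctrl = a / tot_a * 1e6
    rate_trt = c / tot_c * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fold = np.log2(rate_trt / rate_ctrl)

    # vectorized chi-square with continuity correction; Fisher for small cells
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        det = np.abs(a.astype(float) * d - b.astype(float) * c)
        det_cc = np.maximum(det - n / 2.0, 0.0)
        denom = (
            (a + b).astype(float) * (c + d) * (a + c) * (b + d)
        )
        chi2 = np.where(denom > 0, n * det_cc**2 / np.where(denom > 0, denom, 1), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    row_min_expected = np.minimum.reduce(
        [
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ]
    )
    small = row_min_expected < 5
    for i in np.flatnonzero(small):
        p[i] = _pooled_two_proportion(a[i], b[i], c[i], d[i])
    untested = (a + c) == 0
    p[untested] = np.nan

    out = pd.DataFrame(
        {
            "region_id": pooled.index,
            "control_normalized_rate": rate_ctrl,
            "treated_normalized_rate": rate_trt,
            "log2_fold": log2_fold,
            "p_value": p,
        }
    )
    tested = out["p_value"].notna()
    fdr = np.full(len(out), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = multipletests(out.loc[tested, "p_value"],
                                               method="fdr_bh")[1]
    out["fdr"] = fdr
    out["significantly_lower"] = (
        (out["fdr"] < alpha)
        & (out["treated_normalized_rate"] < out["control_normalized_rate"])
    )
    out.loc[~tested, "significantly_lower"] = False
    return out.reset_index(drop=True)


def cluster_promoters(
    rates: pd.DataFrame,
    classes: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Hierarchical clustering of promoter methylation; does the reactivated
    class segregate?

    ``rates`` must carry region_id / gene_id / sample_id / rate_cpm for the
    reactivated and non-reactivated promoters. Average-linkage Euclidean
    clustering on per-region z-scored rates, cut at k=2; purity is the larger
    fraction of reactivated promoters captured by one cluster, with a
    permutation p-value from shuffling class labels.
    """
    merged = rates.merge(classes[["gene_id", "status"]], on="gene_id")
    merged = merged[merged["status"].isin(["reactivated", "non_reactivated"])]
    mat = merged.pivot_table(index=["region_id", "status"], columns="sample_id",
                             values="rate_cpm")
    if len(mat) < 4:
        raise ValueError("need at least 4 promoter regions to cluster")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.all(sd == 0):
        return {"purity": float("nan"), "permutation_p": float("nan"),
                "order": [], "labels": {}}
    keep = sd > 0
    mat = mat[keep]
    x = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]

    link = hierarchy.linkage(x, method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    is_re = np.array([s == "reactivated" for _, s in mat.index])
    n_re = int(is_re.sum())
    if n_re == 0:
        raise ValueError("no reactivated promoters in the matrix")

    def purity(lab):
        return max(
            (is_re & (lab == k)).sum() / n_re for k in np.unique(lab)
        )

    obs = float(purity(labels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(is_re)
        null[i] = max(
            (perm & (labels == k)).sum() / n_re for k in np.unique(labels)
        )
    p = float((1 + np.sum(null >= obs - 1e-12)) / (1 + n_permutations))
    return {
        "purity": obs,
        "permutation_p": p,
        "order": [mat.index[i][0] for i in order],
        "labels": dict(zip((r for r, _ in mat.index), labels.tolist())),
    }


def _cluster_permutation_p(
    values: np.ndarray,
    clusters: np.ndarray,
    is_a_cluster: dict,
    rng: np.random.Generator,
    n_permutations: int = 1000,
) -> float:
    """Two-sided p for the rank-sum statistic, calibrated by permuting
    class labels over clusters (genes), not elements.

    Elements near the same gene share flanking DNA and counted regions, so
    element-level exchangeability fails; the gene is the randomization unit.
    """
    ranks = stats.rankdata(values)
    n_total = len(values)
    cluster_ids = np.unique(clusters)
    ranksum = np.array([ranks[clusters == c].sum() for c in cluster_ids])
    size = np.array([(clusters == c).sum() for c in cluster_ids])
    labels = np.array([bool(is_a_cluster[c]) for c in cluster_ids])

    def standardized(lab):
        na = size[lab].sum()
        nb = n_total - na
        if na == 0 or nb == 0:
            return None
        return (ranksum[lab].sum() - na * (n_total + 1) / 2) / math.sqrt(na * nb)

    obs = standardized(labels)
    if obs is None:
        return float("nan")
    hits = 1
    for _ in range(n_permutations):
        s = standardized(rng.permutation(labels))
        if s is not None and abs(s) >= abs(obs) - 1e-12:
            hits += 1
    return hits / (n_permutations + 1)


def repeat_flank_methylation(
    repeats: list[RepeatElement],
    counts: pd.DataFrame,
    classes: pd.DataFrame,
    genes: list[GeneModel],
    flank_bp: int = 1000,
    near_window_bp: int = 100_000,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[GroupComparison]:
    """Methylation of DNA flanking SINEs/LINEs near reactivated vs
    non-reactivated genes.

    Each element with midpoint within ``near_window_bp`` of a classified TSS
    is assigned to the class of its nearest such TSS. Its flank methylation
    is the coverage-normalized methylation density over
    [start - flank, start) + [end, end + flank): region counts are CPM
    normalized per sample, averaged across samples, then overlap-weighted
    and divided by the covered bases (regions may overlap, so a raw sum
    would track local region geometry rather than methylation level). One
    rank-sum comparison per repeat class, with the p-value calibrated by a
    permutation of class labels over the nearest genes (elements near the
    same gene share flanking DNA, so genes are the exchangeable unit);
    classes with fewer than two genes' worth of elements are skipped with a
    warning.
    """
    status = classes.set_index("gene_id")["status"]
    anchor = [
        (g.tss, status.get(g.gene_id), g.gene_id)
        for g in genes
        if status.get(g.gene_id) in ("reactivated", "non_reactivated")
    ]
    if not anchor:
        return []
    anchor.sort()
    a_pos = np.array([t for t, _, _ in anchor], dtype=np.int64)
    a_cls = np.array([c for _, c, _ in anchor], dtype=object)
    a_gid = np.array([g for _, _, g in anchor], dtype=object)

    norm = normalize_methylation(counts)
    regions = (
        norm[["region_id", "start", "end"]]
        .drop_duplicates("region_id")
        .sort_values("start")
    )
    r_start = regions["start"].to_numpy(dtype=np.int64)
    r_end = regions["end"].to_numpy(dtype=np.int64)
    rate_by_region = (
        norm.groupby("region_id")["rate_cpm"].mean().reindex(regions["region_id"])
        .to_numpy()
    )

    def flank_mass(iv_lo: int, iv_hi: int) -> tuple[float, float]:
        """(overlap-weighted rate mass, covered bp) over [iv_lo, iv_hi)."""
        if iv_hi <= iv_lo:
            return 0.0, 0.0
        i0 = np.searchsorted(r_end, iv_lo, side="right")
        i1 = np.searchsorted(r_start, iv_hi, side="left")
        total = cov = 0.0
        for i in range(i0, i1):
            ov = min(iv_hi, r_end[i]) - max(iv_lo, r_start[i])
            if ov > 0:
                total += rate_by_region[i] * ov / (r_end[i] - r_start[i])
                cov += ov
        return total, cov

    per_class: dict[str, list[tuple[float, str, str]]] = {}
    for rep in repeats:
        mid = rep.midpoint
        j = np.searchsorted(a_pos, mid)
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(a_pos):
                d = abs(int(a_pos[k]) - mid)
                if best is None or d < best[0]:
                    best = (d, a_cls[k], a_gid[k])
        if best is None or best[0] > near_window_bp:
            continue
        s, e = rep.interval.start, rep.interval.end
        m1, c1 = flank_mass(max(s - flank_bp, 0), s)
        m2, c2 = flank_mass(e, e + flank_bp)
        # coverage-normalized density: counted regions may overlap (a
        # promoter window on top of a background bin), so a raw sum would
        # scale with local region geometry rather than methylation level
        rate = (m1 + m2) * flank_bp / (c1 + c2) if (c1 + c2) > 0 else 0.0
        per_class.setdefault(rep.repeat_class, []).append((rate, best[1], best[2]))

    rng = np.random.default_rng(seed)
    comparisons = []
    for rclass, rows in sorted(per_class.items()):
        values = np.array([v for v, _, _ in rows])
        grp = np.array([c for _, c, _ in rows], dtype=object)
        clusters = np.array([g for _, _, g in rows], dtype=object)
        a = values[grp == "reactivated"]
        b = values[grp == "non_reactivated"]
        a_genes = set(clusters[grp == "reactivated"])
        b_genes = set(clusters[grp == "non_reactivated"])
        if len(a) < 2 or len(b) < 2 or len(a_genes) < 2 or len(b_genes) < 2:
            logger.warning(
                "repeat class %s: a class has < 2 elements or genes; skipped", rclass
            )
            continue
        base = mann_whitney(
            a, b, mode="normal", feature=f"{rclass}_flank_methylation",
            group_a="near_reactivated", group_b="near_non_reactivated",
        )
        if not np.all(values == values[0]):
            is_a = {g: (g in a_genes) for g in a_genes | b_genes}
            base.p_value = _cluster_permutation_p(
                values, clusters, is_a, rng, n_permutations
            )
        comparisons.append(base)
    return comparisons
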