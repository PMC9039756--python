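"""Per-gene genomic/epigenomic features and class-wise comparisons.

Features: CpG count in the 2-kb window upstream of the TSS, SINE/LINE counts
(midpoint rule) in +/- 100 kb around the TSS with LINE stratification by
evolutionary age rank and by full length (>= 6 kb), TSS-to-TSS distance to
the nearest escapee and to the Xist locus, and metagene signal profiles over
TSS flanks or scaled gene bodies. Group differences use the Mann-Whitney U
test (exact by enumeration for small samples, normal approximation with tie
and continuity correction otherwise).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, RepeatElement, SignalTrack, tss_window

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-gene features
# ---------------------------------------------------------------------------


def count_cpg_upstream(
    gene: GeneModel, cpg_starts: np.ndarray, window_bp: int = 2000
) -> int:
    """CpG positions falling in the strand-aware upstream window.

    The window is half-open at the TSS, so the TSS base itself is excluded.
    ``cpg_starts`` must be a sorted array of CpG start positions.
    """
    win = tss_window(gene, upstream=window_bp, downstream=0)
    lo = np.searchsorted(cpg_starts, win.start, side="left")
    hi = np.searchsorted(cpg_starts, win.end, side="left")
    return int(hi - lo)


def count_repeats_near_tss(
    gene: GeneModel,
    repeats: list[RepeatElement],
    repeat_class: str | None = None,
    window_bp: int = 100_000,
    _midpoints=None,
) -> int:
    """Elements of a class whose midpoint lies within [tss - w, tss + w]
    (closed window). ``repeat_class=None`` counts every element."""
    if _midpoints is None:
        _midpoints = _class_midpoints(repeats, repeat_class)
    lo = np.searchsorted(_midpoints, gene.tss - window_bp, side="left")
    hi = np.searchsorted(_midpoints, gene.tss + window_bp, side="right")
    return int(hi - lo)


def _class_midpoints(repeats, repeat_class) -> np.ndarray:
    mids = [
        r.midpoint
        for r in repeats
        if repeat_class is None or r.repeat_class == repeat_class
    ]
    return np.sort(np.array(mids, dtype=np.int64))


def stratify_lines(
    repeats: list[RepeatElement], by: str = "size", full_length_min_bp: int = 6000
) -> dict:
    """Split the LINEs by size (full-length >= 6 kb vs shorter) or age rank.

    Non-LINE elements are ignored. ``by="age"`` raises if any LINE lacks an
    age rank, listing the offenders.
    """
    lines = [r for r in repeats if r.repeat_class == "LINE"]
    if by == "size":
        return {
            "full_length": [r for r in lines if r.length_bp >= full_length_min_bp],
            "short": [r for r in lines if r.length_bp < full_length_min_bp],
        }
    if by == "age":
        missing = [r for r in lines if r.age_rank is None]
        if missing:
            locs = [f"{r.interval.chrom}:{r.interval.start}" for r in missing[:5]]
            raise ValueError(
                f"{len(missing)} LINE(s) without age_rank (e.g. {locs})"
            )
        out: dict = {}
        for r in lines:
            out.setdefault(r.age_rank, []).append(r)
        return dict(sorted(out.items()))
    raise ValueError(f"unknown stratification {by!r}")


def distance_to_nearest(
    gene: GeneModel, anchors: list[tuple[str, int]]
) -> float:
    """Min TSS-to-TSS distance to the anchors, excluding the gene itself.

    ``anchors`` is a list of (gene_id, tss). Returns NaN when the anchor set
    (after self-exclusion) is empty.
    """
    pos = [t for gid, t in anchors if gid != gene.gene_id]
    if not pos:
        return float("nan")
    return float(min(abs(gene.tss - t) for t in pos))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

_ENUM_LIMIT = 300_000  # max combinations for tied-exact enumeration


@dataclass
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    direction: str  # which group is larger by median: "a_higher"/"b_higher"/"none"


def _u_from_ranks(values: np.ndarray, n_a: int) -> float:
    ranks = stats.rankdata(values)
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)


def mann_whitney(
    values_a, values_b, mode: str = "auto",
    feature: str = "", group_a: str = "a", group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` (or auto with n1*n2 <= 400) uses the exact permutation
    null: the no-tie distribution via the standard exact method, or full
    enumeration of group assignments when ties are present and the
    combination count is tractable; otherwise the normal approximation with
    tie and continuity correction. Identical samples give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "a_higher" if med_a > med_b else "b_higher" if med_b > med_a else "none"
    u_obs = _u_from_ranks(pooled, n1)

    if np.all(pooled == pooled[0]):
        return GroupComparison(feature, group_a, group_b, n1, n2, u_obs, 1.0, "none")

    has_ties = len(np.unique(pooled)) < n1 + n2
    want_exact = mode == "exact" or (mode == "auto" and n1 * n2 <= 400)
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    if want_exact and not has_ties:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    elif want_exact and math.comb(n1 + n2, n1) <= _ENUM_LIMIT:
        p = _exact_enumeration_p(pooled, n1)
    else:
        if want_exact:
            logger.warning(
                "exact Mann-Whitney with ties infeasible at n=(%d,%d); "
                "using normal approximation", n1, n2,
            )
        p = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return GroupComparison(feature, group_a, group_b, n1, n2, u_obs, min(p, 1.0), direction)


def _exact_enumeration_p(pooled: np.ndarray, n_a: int) -> float:
    """P(|U - mu| >= |U_obs - mu|) over all group assignments (handles ties)."""
    n = len(pooled)
    mu = n_a * (n - n_a) / 2
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    d_obs = abs(u_obs - mu)
    hits = total = 0
    offset = n_a * (n_a + 1) / 2
    for combo in itertools.combinations(range(n), n_a):
        u = float(sum(ranks[i] for i in combo)) - offset
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


def metagene_profile(
    genes: list[GeneModel],
    track: SignalTrack,
    mode: str = "tss",
    flank_bp: int = 3000,
    bin_bp: int = 50,
    n_body_bins: int = 100,
) -> np.ndarray:
    """Mean signal profile across genes, strand-oriented.

    ``tss`` mode: per-gene mean signal per ``bin_bp`` bin over
    [tss - flank, tss + flank), minus-strand genes reversed, averaged over
    genes. ``scaled_body`` mode: upstream flank bins, the gene body rescaled
    to ``n_body_bins`` bins, then downstream flank bins, all in
    transcriptional orientation. Genes shorter than ``n_body_bins`` bases are
    skipped with a warning.
    """
    if not genes:
        raise ValueError("empty gene list")
    if mode not in ("tss", "scaled_body"):
        raise ValueError(f"unknown mode {mode!r}")
    profiles = []
    n_flank = 2 * flank_bp // bin_bp if mode == "tss" else flank_bp // bin_bp
    for gene in genes:
        if mode == "tss":
            edges = gene.tss - flank_bp + np.arange(0, 2 * flank_bp + bin_bp, bin_bp)
            if edges[0] < 0:
                continue
            prof = track.mean_over(edges[:-1], edges[1:])
        else:
            if gene.length < n_body_bins:
                logger.warning(
                    "gene %s shorter than n_body_bins (%d < %d); skipped",
                    gene.gene_id, gene.length, n_body_bins,
                )
                continue
            s, e = gene.interval.start, gene.interval.end
            left = s - flank_bp + np.arange(0, flank_bp + bin_bp, bin_bp)
            right = e + np.arange(0, flank_bp + bin_bp, bin_bp)
            body = np.linspace(s, e, n_body_bins + 1).astype(np.int64)
            if left[0] < 0:
                continue
            up = track.mean_over(left[:-1], left[1:])
            bd = track.mean_over(body[:-1], body[1:])
            dn = track.mean_over(right[:-1], right[1:])
            prof = np.concatenate([up, bd, dn])
        if gene.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no usable genes for the profile")
    return np.nanmean(np.vstack(profiles), axis=0)


# ---------------------------------------------------------------------------
# feature table + class comparison
# ---------------------------------------------------------------------------

DEFAULT_COMPARE = ["cpg_upstream_2kb", "sine_100kb", "line_100kb",
                   "line_full_length_100kb", "line_short_100kb",
                   "dist_nearest_escapee_bp"]


def build_feature_table(
    genes: list[GeneModel],
    cpg_starts: np.ndarray,
    repeats: list[RepeatElement],
    escapee_ids: set[str],
    xist_tss: int | None = None,
    tracks: dict[str, SignalTrack] | None = None,
    cpg_window_bp: int = 2000,
    repeat_window_bp: int = 100_000,
    profile_flank_bp: int = 3000,
) -> pd.DataFrame:
    """One row per gene with every per-gene feature."""
    cpg_starts = np.sort(np.asarray(cpg_starts, dtype=np.int64))
    sine_mid = _class_midpoints(repeats, "SINE")
    line_mid = _class_midpoints(repeats, "LINE")
    size_strata = stratify_lines(repeats, by="size")
    full_mid = _class_midpoints(size_strata["full_length"], None)
    short_mid = _class_midpoints(size_strata["short"], None)
    try:
        age_strata = stratify_lines(repeats, by="age")
    except ValueError:
        age_strata = {}
    age_mids = {a: _class_midpoints(rs, None) for a, rs in age_strata.items()}
    sine_fams = sorted({r.family for r in repeats if r.repeat_class == "SINE"})
    fam_mids = {
        f: _class_midpoints([r for r in repeats if r.repeat_class == "SINE"
                             and r.family == f], None)
        for f in sine_fams
    }
    anchors = [(g.gene_id, g.tss) for g in genes if g.gene_id in escapee_ids]

    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "tss": g.tss,
            "cpg_upstream_2kb": count_cpg_upstream(g, cpg_starts, cpg_window_bp),
            "sine_100kb": count_repeats_near_tss(
                g, repeats, "SINE", repeat_window_bp, _midpoints=sine_mid),
            "line_100kb": count_repeats_near_tss(
                g, repeats, "LINE", repeat_window_bp, _midpoints=line_mid),
            "line_full_length_100kb": count_repeats_near_tss(
                g, repeats, None, repeat_window_bp, _midpoints=full_mid),
            "line_short_100kb": count_repeats_near_tss(
                g, repeats, None, repeat_window_bp, _midpoints=short_mid),
            "dist_nearest_escapee_bp": distance_to_nearest(g, anchors),
            "dist_to_xist_bp": (
                float(abs(g.tss - xist_tss)) if xist_tss is not None else float("nan")
            ),
        }
        for a, mids in age_mids.items():
            row[f"line_age{a}_100kb"] = count_repeats_near_tss(
                g, repeats, None, repeat_window_bp, _midpoints=mids)
        for f, mids in fam_mids.items():
            row[f"sine_{f}_100kb"] = count_repeats_near_tss(
                g, repeats, None, repeat_window_bp, _midpoints=mids)
        rows.append(row)
    df = pd.DataFrame(rows)

    if tracks:
        for name, track in tracks.items():
            tss = df["tss"].to_numpy()
            lo = np.clip(tss - profile_flank_bp, 0, None)
            hi = tss + profile_flank_bp
            df[f"{name}_tss_mean"] = track.mean_over(lo, hi)
    return df


def compare_classes(
    features: pd.DataFrame,
    classes: pd.DataFrame,
    feature_names: list[str] | None = None,
    mode: str = "auto",
) -> list[GroupComparison]:
    """Mann-Whitney of reactivated vs non-reactivated for each feature.

    Escapees and uninformative genes are excluded. Features with fewer than
    two members in a class are skipped with a warning; missing values are
    dropped per feature.
    """
    if feature_names is None:
        feature_names = [f for f in DEFAULT_COMPARE if f in features.columns]
    merged = features.merge(classes[["gene_id", "status"]], on="gene_id")
    grp_a = merged[merged["status"] == "reactivated"]
    grp_b = merged[merged["status"] == "non_reactivated"]
    out = []
    for feat in feature_names:
        a = grp_a[feat].dropna().to_numpy()
        b = grp_b[feat].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.warning("feature %s: a class has < 2 members; skipped", feat)
            continue
        out.append(
            mann_whitney(a, b, mode=mode, feature=feat,
                         group_a="reactivated", group_b="non_reactivated")
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
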