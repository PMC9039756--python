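"""Per-TAD binomial enrichment/depletion of reactivated genes.

Each TAD's reactivated-gene fraction is compared with the chromosome-wide
fraction by a two-sided exact binomial test (minimum-likelihood method: the
p-value sums every outcome whose probability does not exceed that of the
observed count). Signed -log10 p is positive for TADs above the
chromosome-wide fraction and negative below, the convention used for
genome-browser display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, SignalTrack, TadSet
from .features import GroupComparison, mann_whitney

logger = logging.getLogger(__name__)


def assign_genes_to_tads(genes: list[GeneModel], tads: TadSet) -> dict[str, int]:
    """Map gene_id -> TAD index for genes whose TSS falls inside a TAD.

    TAD intervals are half-open; a TSS in an inter-TAD gap is unassigned.
    """
    starts = np.array([iv.start for iv in tads], dtype=np.int64)
    ends = np.array([iv.end for iv in tads], dtype=np.int64)
    out: dict[str, int] = {}
    for g in genes:
        i = int(np.searchsorted(starts, g.tss, side="right")) - 1
        if i >= 0 and g.tss < ends[i]:
            out[g.gene_id] = i
    return out


def tad_binomial_test(
    n_reactivated: int, n_genes: int, p0: float, alpha: float = 0.05
) -> tuple[float, float, bool, bool]:
    """Two-sided binomial test by minimum-likelihood summation.

    Returns (p, signed -log10 p, enriched flag, depleted flag). The sign is
    positive iff n_reactivated/n_genes exceeds p0, zero at exact equality.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= n_reactivated <= n_genes):
        raise ValueError("require 0 <= n_reactivated <= n_genes")
    pmf = stats.binom.pmf(np.arange(n_genes + 1), n_genes, p0)
    p = float(min(1.0, pmf[pmf <= pmf[n_reactivated] * (1 + 1e-9)].sum()))
    ratio = n_reactivated / n_genes
    sign = 0.0 if ratio == p0 else (1.0 if ratio > p0 else -1.0)
    signed = sign * (-np.log10(max(p, 1e-300)))
    enriched = bool(p < alpha and sign > 0)
    depleted = bool(p < alpha and sign < 0)
    return p, float(signed), enriched, depleted


def run_tad_enrichment(
    classes: pd.DataFrame,
    genes: list[GeneModel],
    tads: TadSet,
    alpha: float = 0.05,
    include_escapees_in_denominator: bool = False,
    bh_correct: bool = False,
    tad_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One record per TAD with >= 1 classified gene.

    The chromosome-wide fraction p0 uses reactivated / classified genes
    inside TADs, where "classified" means reactivated + non_reactivated
    (escapees and uninformative excluded from numerator and denominator
    unless ``include_escapees_in_denominator``). ``bh_correct`` applies
    Benjamini-Hochberg across TADs before flagging (off by default,
    matching the raw p = alpha display convention).
    """
    status = classes.set_index("gene_id")["status"]
    assign = assign_genes_to_tads(genes, tads)
    denom_statuses = {"reactivated", "non_reactivated"}
    if include_escapees_in_denominator:
        denom_statuses.add("escapee")

    per_tad: dict[int, dict[str, int]] = {}
    tot_re = tot_cls = 0
    for gid, ti in assign.items():
        st = status.get(gid)
        if st is None:
            continue
        d = per_tad.setdefault(ti, {"n_genes": 0, "n_reactivated": 0, "n_escapees": 0})
        if st == "escapee":
            d["n_escapees"] += 1
        if st in denom_statuses:
            d["n_genes"] += 1
            tot_cls += 1
            if st == "reactivated":
                d["n_reactivated"] += 1
                tot_re += 1
    if tot_cls == 0:
        raise ValueError("no TAD contains classified genes")
    p0 = tot_re / tot_cls
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"degenerate chromosome-wide fraction p0={p0}")

    rows = []
    ivs = tads.intervals
    for ti in sorted(per_tad):
        d = per_tad[ti]
        if d["n_genes"] < 1:
            continue
        p, signed, enr, dep = tad_binomial_test(
            d["n_reactivated"], d["n_genes"], p0, alpha
        )
        tid = tad_ids[ti] if tad_ids else f"TAD{ti + 1:03d}"
        rows.append(
            (tid, ivs[ti].chrom, ivs[ti].start, ivs[ti].end, d["n_genes"],
             d["n_reactivated"], d["n_escapees"], p, signed, enr, dep)
        )
    out = pd.DataFrame(
        rows,
        columns=["tad_id", "chrom", "start", "end", "n_genes", "n_reactivated",
                 "n_escapees", "p_binomial", "signed_minus_log10_p",
                 "significant_enriched", "significant_depleted"],
    )
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests(out["p_binomial"], method="fdr_bh")[1]
        out["fdr"] = fdr
        ratio_above = out["n_reactivated"] / out["n_genes"] > p0
        out["significant_enriched"] = (fdr < alpha) & ratio_above
        out["significant_depleted"] = (fdr < alpha) & (
            out["n_reactivated"] / out["n_genes"] < p0
        )
    return out


def write_signed_p_bedgraph(tad_records: pd.DataFrame, path) -> None:
    """Signed -log10 p per TAD as a bedGraph for genome-browser display."""
    with open(path, "w") as fh:
        for r in tad_records.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.signed_minus_log10_p:g}\n")


def tad_feature_summary(
    tad_records: pd.DataFrame,
    repeats=None,
    cpg_starts=None,
    tracks: dict[str, SignalTrack] | None = None,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-TAD densities (per Mb) and mean track signal, plus Mann-Whitney of
    significantly enriched TADs vs non-significant TADs for each aggregate.

    Comparisons are skipped with a warning when a group has fewer than two
    TADs; the depleted TAD is excluded from the non-significant group.
    """
    df = tad_records.copy()
    mb = (df["end"] - df["start"]) / 1e6
    if repeats is not None:
        for cls in ("SINE", "LINE"):
            mids = np.sort(
                np.array([r.midpoint for r in repeats if r.repeat_class == cls])
            )
            n = np.searchsorted(mids, df["end"]) - np.searchsorted(mids, df["start"])
            df[f"{cls.lower()}_per_mb"] = n / mb
    if cpg_starts is not None:
        cp = np.sort(np.asarray(cpg_starts, dtype=np.int64))
        n = np.searchsorted(cp, df["end"]) - np.searchsorted(cp, df["start"])
        df["cpg_per_mb"] = n / mb
    if tracks:
        for name, track in tracks.items():
            df[f"{name}_mean"] = track.mean_over(
                df["start"].to_numpy(), df["end"].to_numpy()
            )

    agg_cols = [c for c in df.columns if c.endswith(("_per_mb", "_mean"))]
    enr = df[df["significant_enriched"]]
    rest = df[~df["significant_enriched"] & ~df["significant_depleted"]]
    comparisons = []
    for col in agg_cols:
        if len(enr) < 2 or len(rest) < 2:
            logger.warning("TAD comparison %s skipped: group with < 2 TADs", col)
            continue
        comparisons.append(
            mann_whitney(
                enr[col].to_numpy(), rest[col].to_numpy(), mode="auto",
                feature=col, group_a="enriched_tads", group_b="other_tads",
            )
        )
    return df, comparisons
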