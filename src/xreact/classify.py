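"""Allelic-ratio filtering, escapee calling and the reactivation test.

The classifier partitions X-linked genes into four states:

``uninformative``
    insufficient allelic coverage (mean cast+bl6 reads below threshold in at
    least one analysed condition);
``escapee``
    expressed from the inactive X already in the control (mean control cast
    ratio at or above the escape threshold, default 0.10);
``reactivated``
    informative non-escapee with a significant *increase* of the cast
    fraction in the treated condition (beta-binomial likelihood-ratio test,
    Benjamini-Hochberg FDR below alpha, positive delta-ratio);
``non_reactivated``
    everything else that is informative.

The reactivation test models replicate cast counts as beta-binomial with a
per-gene dispersion shared between conditions: under H1 each condition has
its own mean cast fraction, under H0 the two are equal. The dispersion is
estimated by maximum likelihood under H1 and held fixed for the null fit;
the likelihood-ratio statistic is referred to chi-square with 1 df. A pooled
Fisher exact test is available as ``method="fisher"`` and serves as the
independent oracle in the test-suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, gammaln, xlog1py, xlogy
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STATUSES = ("uninformative", "escapee", "reactivated", "non_reactivated")

COUNT_COLUMNS = ["gene_id", "condition", "replicate", "cast_count", "bl6_count"]


def load_count_table(path) -> pd.DataFrame:
    """Read and validate the allelic count TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return validate_count_table(df)


def validate_count_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("cast_count", "bl6_count"):
        if (df[col] < 0).any():
            raise ValueError(f"negative {col}")
        if not np.issubdtype(df[col].dtype, np.integer):
            if not np.allclose(df[col] % 1, 0):
                raise ValueError(f"non-integer {col}")
            df = df.copy()
            df[col] = df[col].astype(np.int64)
    dup = df.duplicated(["gene_id", "condition", "replicate"])
    if dup.any():
        raise ValueError(
            f"duplicate (gene_id, condition, replicate) rows: "
            f"{df.loc[dup, 'gene_id'].head().tolist()}"
        )
    return df


def allelic_ratio(cast, bl6):
    """cast / (cast + bl6); NaN when the total is zero (no exception)."""
    cast = np.asarray(cast, dtype=float)
    bl6 = np.asarray(bl6, dtype=float)
    total = cast + bl6
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, cast / np.where(total > 0, total, 1), np.nan)
    return out if out.ndim else float(out)


def filter_informative(
    table: pd.DataFrame,
    min_allelic_reads: float = 10.0,
    conditions: tuple[str, ...] = ("control", "tomato_high"),
) -> set[str]:
    """Genes whose mean (cast+bl6) across replicates reaches the threshold in
    every listed condition."""
    known = set(table["condition"].unique())
    unknown = [c for c in conditions if c not in known]
    if unknown:
        raise ValueError(f"unknown condition(s) {unknown}; table has {sorted(known)}")
    sub = table[table["condition"].isin(conditions)].copy()
    sub["total"] = sub["cast_count"] + sub["bl6_count"]
    means = sub.groupby(["gene_id", "condition"], sort=False)["total"].mean()
    ok = (means >= min_allelic_reads).groupby("gene_id").agg(
        lambda s: s.all() and len(s) == len(conditions)
    )
    # genes absent from a condition are dropped
    per_gene_nc = means.groupby("gene_id").size()
    ok &= per_gene_nc == len(conditions)
    return set(ok.index[ok])


def _pooled_ratio(sub: pd.DataFrame) -> float:
    total = sub["cast_count"].sum() + sub["bl6_count"].sum()
    return float(sub["cast_count"].sum() / total) if total > 0 else float("nan")


def classify_escapees(
    table: pd.DataFrame,
    informative_genes: set[str],
    escape_ratio_threshold: float = 0.10,
    control_condition: str = "control",
) -> set[str]:
    """Escapee iff the mean over control replicates of the per-replicate cast
    ratio is at or above the threshold."""
    sub = table[
        table["gene_id"].isin(informative_genes)
        & (table["condition"] == control_condition)
    ].copy()
    sub["ratio"] = allelic_ratio(sub["cast_count"], sub["bl6_count"])
    mean_ratio = sub.groupby("gene_id")["ratio"].mean()
    return set(mean_ratio.index[mean_ratio >= escape_ratio_threshold])


# ---------------------------------------------------------------------------
# beta-binomial likelihood-ratio test
# ---------------------------------------------------------------------------

_RHO_FLOOR = 1e-6
_MU_EPS = 1e-9


def _bb_loglik(k: np.ndarray, n: np.ndarray, mu: float, rho: float) -> float:
    """Beta-binomial log-likelihood, mean/correlation parametrization.

    rho below ``_RHO_FLOOR`` falls back to the binomial limit.
    """
    mu = min(max(mu, _MU_EPS), 1 - _MU_EPS)
    if rho < _RHO_FLOOR:
        return float(np.sum(xlogy(k, mu) + xlogy(n - k, 1 - mu)))
    s = (1 - rho) / rho
    a, b = mu * s, (1 - mu) * s
    return float(
        np.sum(
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + betaln(k + a, n - k + b)
            - betaln(a, b)
        )
    )


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x > -700 else 0.0


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def _fit_rho(kc, nc, kt, nt) -> tuple[float, float]:
    """ML fit of (mu_c, mu_t, shared rho) under H1; returns (rho_hat, ll1)."""
    mu_c0 = (kc.sum() + 0.5) / (nc.sum() + 1.0)
    mu_t0 = (kt.sum() + 0.5) / (nt.sum() + 1.0)

    def nll1(x):
        mc, mt = _expit(x[0]), _expit(x[1])
        rho = _expit(x[2]) * 0.5  # rho in (0, 0.5)
        return -(_bb_loglik(kc, nc, mc, rho) + _bb_loglik(kt, nt, mt, rho))

    x0 = np.array([_logit(mu_c0), _logit(mu_t0), _logit(0.02)])
    res = optimize.minimize(nll1, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400})
    return float(_expit(res.x[2]) * 0.5), float(-res.fun)


def _max_ll_mu(k, n, rho, *more) -> float:
    """Profile log-likelihood over a single mean, dispersion fixed.

    ``more`` may carry a second (k, n) pair constrained to the same mean.
    """
    pairs = [(k, n)] + [(more[i], more[i + 1]) for i in range(0, len(more), 2)]

    def nll(y):
        mu = _expit(y)
        return -sum(_bb_loglik(kk, nn, mu, rho) for kk, nn in pairs)

    res = optimize.minimize_scalar(nll, bounds=(-25.0, 25.0), method="bounded",
                                   options={"xatol": 1e-7})
    tot_k = sum(float(np.sum(kk)) for kk, _ in pairs)
    tot_n = sum(float(np.sum(nn)) for _, nn in pairs)
    mom = _logit((tot_k + 0.5) / (tot_n + 1.0))
    return -min(res.fun, nll(mom))


def betabinom_lrt(
    cast_c: np.ndarray,
    total_c: np.ndarray,
    cast_t: np.ndarray,
    total_t: np.ndarray,
    rho: float | None = None,
) -> tuple[float, float]:
    """LRT of equal cast fraction in the two conditions.

    Returns (p_value, lrt_statistic). The dispersion is shared between
    conditions: estimated under the alternative by maximum likelihood when
    ``rho`` is None, otherwise held at the supplied (e.g. moderated) value.
    p from chi-square(1).
    """
    kc, nc = np.asarray(cast_c, float), np.asarray(total_c, float)
    kt, nt = np.asarray(cast_t, float), np.asarray(total_t, float)
    if nc.sum() == 0 or nt.sum() == 0:
        return float("nan"), float("nan")

    if rho is None:
        rho, ll1 = _fit_rho(kc, nc, kt, nt)
    else:
        ll1 = _max_ll_mu(kc, nc, rho) + _max_ll_mu(kt, nt, rho)
    ll0 = _max_ll_mu(kc, nc, rho, kt, nt)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lrt, df=1)), float(lrt)


def fisher_pooled_test(
    cast_c: np.ndarray, total_c: np.ndarray, cast_t: np.ndarray, total_t: np.ndarray
) -> float:
    """Fisher exact test on the pooled 2x2 (cast/bl6 x condition) table."""
    kc, nc = int(np.sum(cast_c)), int(np.sum(total_c))
    kt, nt = int(np.sum(cast_t)), int(np.sum(total_t))
    if nc == 0 or nt == 0:
        return float("nan")
    _, p = stats.fisher_exact([[kc, nc - kc], [kt, nt - kt]])
    return float(p)


def test_reactivation(
    table: pd.DataFrame,
    informative_non_escapees: set[str],
    treated_condition: str = "tomato_high",
    control_condition: str = "control",
    alpha: float = 0.05,
    method: str = "betabinom",
) -> pd.DataFrame:
    """Per-gene differential allelic-fraction test, treated vs control.

    Returns one row per tested gene: control/treated pooled cast ratios,
    delta_ratio, p_value, fdr (Benjamini-Hochberg across tested genes) and
    the reactivated flag (fdr < alpha and delta_ratio > 0).
    """
    if method not in ("betabinom", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    sub = table[table["gene_id"].isin(informative_non_escapees)]
    per_gene = []
    for gene_id, g in sub.groupby("gene_id", sort=True):
        gc = g[g["condition"] == control_condition]
        gt = g[g["condition"] == treated_condition]
        cc, nc = gc["cast_count"].to_numpy(), (gc["cast_count"] + gc["bl6_count"]).to_numpy()
        ct, nt = gt["cast_count"].to_numpy(), (gt["cast_count"] + gt["bl6_count"]).to_numpy()
        per_gene.append((gene_id, cc, nc, ct, nt))

    rho_mod: dict[str, float] = {}
    if method == "betabinom":
        # per-gene ML dispersions are very noisy with few replicates;
        # moderate them toward the across-gene median (prior weight d0)
        # before the final fixed-dispersion LRT
        d0, d = 20.0, 4.0
        rho_hat = {}
        for gene_id, cc, nc, ct, nt in per_gene:
            if nc.sum() > 0 and nt.sum() > 0:
                rho_hat[gene_id], _ = _fit_rho(
                    np.asarray(cc, float), np.asarray(nc, float),
                    np.asarray(ct, float), np.asarray(nt, float),
                )
        common = float(np.median(list(rho_hat.values()))) if rho_hat else 0.0
        rho_mod = {
            gid: (d0 * common + d * r) / (d0 + d) for gid, r in rho_hat.items()
        }

    rows = []
    for gene_id, cc, nc, ct, nt in per_gene:
        r_c = allelic_ratio(cc.sum(), (nc - cc).sum())
        r_t = allelic_ratio(ct.sum(), (nt - ct).sum())
        if nc.sum() == 0 or nt.sum() == 0:
            p = float("nan")
        elif method == "fisher":
            p = fisher_pooled_test(cc, nc, ct, nt)
        else:
            p, _ = betabinom_lrt(cc, nc, ct, nt, rho=rho_mod[gene_id])
        delta = (r_t - r_c) if not (math.isnan(r_t) or math.isnan(r_c)) else float("nan")
        rows.append((gene_id, r_c, r_t, delta, p))
    res = pd.DataFrame(
        rows, columns=["gene_id", "control_cast_ratio", "treated_cast_ratio",
                       "delta_ratio", "p_value"]
    )
    tested = res["p_value"].notna()
    fdr = np.full(len(res), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = multipletests(
            res.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    res["fdr"] = fdr
    res["reactivated"] = (res["fdr"] < alpha) & (res["delta_ratio"] > 0)
    res.loc[~tested, "reactivated"] = False
    return res


def classify_genes(
    table: pd.DataFrame,
    gene_ids: list[str],
    min_allelic_reads: float = 10.0,
    escape_ratio_threshold: float = 0.10,
    treated_condition: str = "tomato_high",
    control_condition: str = "control",
    alpha: float = 0.05,
    method: str = "betabinom",
) -> pd.DataFrame:
    """Full classification: one row per annotated gene, exactly one status."""
    informative = filter_informative(
        table, min_allelic_reads, (control_condition, treated_condition)
    )
    escapees = classify_escapees(
        table, informative, escape_ratio_threshold, control_condition
    )
    tested = informative - escapees
    res = test_reactivation(
        table, tested, treated_condition, control_condition, alpha, method
    ).set_index("gene_id")

    # control ratios for escapees (descriptive)
    esc_tab = table[table["gene_id"].isin(escapees)]
    esc_ratio = {
        gid: _pooled_ratio(g[g["condition"] == control_condition])
        for gid, g in esc_tab.groupby("gene_id")
    }

    rows = []
    for gid in gene_ids:
        if gid not in informative:
            rows.append((gid, "uninformative", np.nan, np.nan, np.nan, np.nan, np.nan))
        elif gid in escapees:
            r = esc_ratio.get(gid, np.nan)
            rows.append((gid, "escapee", r, np.nan, np.nan, np.nan, np.nan))
        else:
            r = res.loc[gid]
            status = "reactivated" if bool(r["reactivated"]) else "non_reactivated"
            rows.append(
                (gid, status, r["control_cast_ratio"], r["treated_cast_ratio"],
                 r["delta_ratio"], r["p_value"], r["fdr"])
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "status", "control_cast_ratio", "treated_cast_ratio",
                 "delta_ratio", "p_value", "fdr"],
    )
    extra = (informative | escapees) - set(gene_ids)
    if extra:
        logger.warning("%d genes in counts but not in annotation; ignored", len(extra))
    return out


def rank_reactivated(
    classifications: pd.DataFrame, reference_gene_id: str
) -> tuple[pd.DataFrame, int]:
    """Reactivated genes ordered by significance; count strictly above the
    reference.

    Sort key: ascending p, ties broken by descending delta_ratio then
    gene_id. Raises if the reference is not itself reactivated.
    """
    re = classifications[classifications["status"] == "reactivated"].copy()
    if reference_gene_id not in set(re["gene_id"]):
        raise ValueError(f"reference gene {reference_gene_id!r} is not reactivated")
    re = re.sort_values(
        ["p_value", "delta_ratio", "gene_id"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    pos = int(re.index[re["gene_id"] == reference_gene_id][0])
    return re, pos


def delta_ratio_profile(
    table: pd.DataFrame,
    genes: pd.DataFrame,
    informative_genes: set[str],
    treated_condition: str = "tomato_high",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Per-gene (TSS position, delta_ratio) ordered along the chromosome.

    ``genes`` needs columns gene_id and tss. Delta is the treated pooled cast
    ratio minus the control pooled cast ratio.
    """
    sub = table[table["gene_id"].isin(informative_genes)]
    rows = []
    for gid, g in sub.groupby("gene_id"):
        rc = _pooled_ratio(g[g["condition"] == control_condition])
        rt = _pooled_ratio(g[g["condition"] == treated_condition])
        rows.append((gid, rt - rc))
    prof = pd.DataFrame(rows, columns=["gene_id", "delta_ratio"])
    prof = prof.merge(genes[["gene_id", "tss"]], on="gene_id", how="inner")
    return prof.sort_values("tss", kind="stable")[
        ["gene_id", "tss", "delta_ratio"]
    ].reset_index(drop=True)


def normalized_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million of total (cast+bl6) per sample — display only."""
    df = table.copy()
    df["total"] = df["cast_count"] + df["bl6_count"]
    lib = df.groupby(["condition", "replicate"])["total"].transform("sum")
    for col in ("cast_count", "bl6_count"):
        df[col.replace("_count", "_cpm")] = df[col] / lib * 1e6
    return df.drop(columns=["total"])
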