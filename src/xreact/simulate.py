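"""Synthetic data bundle with planted X-reactivation structure.

Generates everything the downstream stages consume — gene annotation, allelic
count table, repeat and CpG BEDs, TAD intervals, TSS/gene-body signal tracks
and a MeD-seq-style methylation count table — together with the ground truth
used by recovery tests.

Count model: per gene, condition and replicate the total allelic read count is
negative binomial; the cast read count given the total is binomial with the
gene's true cast fraction for that condition. Silenced genes carry a residual
cast fraction near zero, escapees a high cast fraction in every condition, and
reactivated genes an elevated cast fraction in the treated (tomato_high)
condition only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    SignalTrack,
    repeats_to_bed,
    write_bed,
    write_bedgraph,
    write_gene_table,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "tomato_low", "tomato_med", "tomato_high")
MALE_CONDITION = "male_xa"
CLASSES = ("uninformative", "escapee", "reactivated", "non_reactivated")

TRACK_NAMES = ("ctcf", "rad21", "h3k4me3", "h3k27me3")
BODY_TRACK = "xist_chart"


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic bundle; defaults emulate the study design.

    The default class sizes reproduce the analysed population: 2,612 X-linked
    genes of which 447 carry sufficient allelic information, 45 escapees, 86
    reactivated genes (one designated ``Mecp2`` with a mid-range effect and 7
    with strictly larger effects), 16 hypomethylated reactivated promoters,
    and 112 TADs of which 4 are seeded enriched and 1 depleted.
    """

    seed: int = 1
    chrom: str = "chrX"
    chrom_length_bp: int = 171_000_000
    n_genes: int = 2612
    n_informative: int = 447
    n_escapees: int = 45
    n_reactivated: int = 86
    n_above_mecp2: int = 7
    n_hypomethylated_promoters: int = 16
    n_replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    treated_condition: str = "tomato_high"

    # sequencing-depth model (per gene per replicate)
    mean_total_reads_per_gene: float = 200.0
    uninformative_mean_reads: float = 1.0
    nb_dispersion: float = 1.0 / 60.0  # var = m + disp * m^2

    # allelic cast fractions
    cast_fraction_inactive: float = 0.001
    cast_fraction_escapee_range: tuple[float, float] = (0.15, 0.50)
    cast_fraction_reactivated_high: tuple[float, float] = (0.08, 0.30)
    cast_fraction_reactivated_regular: tuple[float, float] = (0.08, 0.09)
    cast_fraction_mecp2: float = 0.18
    cast_fraction_strong: tuple[float, float] = (0.28, 0.30)
    xist_cast_fraction: float = 0.95

    # feature effect sizes (means of planted per-gene counts)
    cpg_mean_reactivated: float = 35.0
    cpg_mean_non: float = 15.0
    sine_mean_reactivated: float = 55.0
    sine_mean_non: float = 25.0
    line_mean_reactivated: float = 10.0
    line_mean_non: float = 32.0
    escapee_proximity_bias: float = 0.6

    # TADs
    n_tads: int = 112
    n_tads_enriched: int = 4
    n_tads_depleted: int = 1

    # methylation
    methylation_depth: float = 150.0
    hypomethylation_fold: float = 0.4
    promoter_flank_bp: int = 1000
    tile_bp: int = 2000
    neighborhood_bp: int = 102_000

    def __post_init__(self) -> None:
        if self.n_escapees + self.n_reactivated > self.n_informative:
            raise ConfigError("n_escapees + n_reactivated must be <= n_informative")
        if self.n_informative > self.n_genes:
            raise ConfigError("n_informative must be <= n_genes")
        if self.n_reactivated > 0 and self.n_above_mecp2 >= self.n_reactivated:
            raise ConfigError("n_above_mecp2 must be < n_reactivated")
        if self.n_reactivated == 0 and self.n_above_mecp2 != 0:
            raise ConfigError("n_above_mecp2 requires reactivated genes")
        if self.n_hypomethylated_promoters > self.n_reactivated:
            raise ConfigError("n_hypomethylated_promoters must be <= n_reactivated")
        if self.n_tads_enriched + self.n_tads_depleted >= self.n_tads:
            raise ConfigError("designated TADs must be fewer than n_tads")
        fracs = [
            self.cast_fraction_inactive,
            *self.cast_fraction_escapee_range,
            *self.cast_fraction_reactivated_high,
            *self.cast_fraction_reactivated_regular,
            self.cast_fraction_mecp2,
            *self.cast_fraction_strong,
            self.xist_cast_fraction,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigError("all cast fractions must lie in [0, 1]")
        if self.n_escapees > 0 and not (
            self.cast_fraction_inactive < self.cast_fraction_escapee_range[0]
        ):
            raise ConfigError(
                "cast_fraction_inactive must be below the escapee range"
            )
        if self.treated_condition not in self.conditions:
            raise ConfigError("treated_condition must be one of conditions")

    @property
    def n_classified(self) -> int:
        """Informative non-escapee genes — the tested population."""
        return self.n_informative - self.n_escapees

    def zero_effect(self) -> "SimulationConfig":
        """Copy with reactivation effect sizes nulled (for calibration runs)."""
        d = asdict(self)
        p = self.cast_fraction_inactive
        d["cast_fraction_reactivated_high"] = (p, p)
        d["cast_fraction_reactivated_regular"] = (p, p)
        d["cast_fraction_mecp2"] = p
        d["cast_fraction_strong"] = (p, p)
        d["hypomethylation_fold"] = 1.0
        return SimulationConfig(**d)


@dataclass
class GroundTruth:
    """Planted per-gene truth plus the designated TAD statuses."""

    genes: pd.DataFrame  # gene_id, name, true_class, tier, frac_<cond>..., mean_total_reads, hypomethylated, tad_id
    tads: pd.DataFrame  # tad_id, chrom, start, end, status

    def class_counts(self) -> dict[str, int]:
        return self.genes["true_class"].value_counts().to_dict()

    def validate_against(self, config: SimulationConfig) -> None:
        counts = self.class_counts()
        expect = {
            "escapee": config.n_escapees,
            "reactivated": config.n_reactivated,
            "non_reactivated": config.n_classified - config.n_reactivated,
            "uninformative": config.n_genes - config.n_informative,
        }
        for cls, n in expect.items():
            if counts.get(cls, 0) != n:
                raise ConfigError(
                    f"ground truth has {counts.get(cls, 0)} {cls} genes, "
                    f"config expects {n}"
                )

    def write(self, gene_path, tad_path) -> None:
        self.genes.to_csv(gene_path, sep="\t", index=False)
        self.tads.to_csv(tad_path, sep="\t", index=False)

    @classmethod
    def read(cls, gene_path, tad_path) -> "GroundTruth":
        genes = pd.read_csv(gene_path, sep="\t")
        genes["tad_id"] = genes["tad_id"].fillna("")
        return cls(genes=genes, tads=pd.read_csv(tad_path, sep="\t"))


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------


def _binom_minlike_p(k: int, n: int, p0: float) -> float:
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()))


def _make_tads(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    start0 = 3_000_000
    span = config.chrom_length_bp - 2 * start0
    widths = rng.uniform(0.8, 1.2, size=config.n_tads)
    widths = np.floor(widths / widths.sum() * span).astype(np.int64)
    edges = start0 + np.concatenate([[0], np.cumsum(widths)])
    df = pd.DataFrame(
        {
            "tad_id": [f"TAD{i + 1:03d}" for i in range(config.n_tads)],
            "chrom": config.chrom,
            "start": edges[:-1],
            "end": edges[1:],
        }
    )
    designated = rng.choice(
        config.n_tads, size=config.n_tads_enriched + config.n_tads_depleted, replace=False
    )
    status = np.array(["background"] * config.n_tads, dtype=object)
    status[designated[: config.n_tads_enriched]] = "enriched"
    status[designated[config.n_tads_enriched:]] = "depleted"
    df["status"] = status
    return df


def _tad_allocation(config: SimulationConfig, rng: np.random.Generator):
    """Per-TAD counts of (classified genes, reactivated genes).

    Enriched TADs receive a large excess of reactivated genes; the depleted
    TAD many genes and none; the remaining reactivated genes are spread over
    background TADs by largest-remainder apportionment so every background
    TAD's reactivated fraction sits near the chromosome-wide fraction.
    """
    n_cls, n_re = config.n_classified, config.n_reactivated
    n_enr, n_dep = config.n_tads_enriched, config.n_tads_depleted
    p0 = n_re / max(n_cls, 1)

    r_e = 0
    if n_enr > 0 and n_re > 0:
        r_e = max(2, round(n_re / (3 * n_enr)))
        r_e = min(r_e, (n_re - 1) // n_enr if n_enr else n_re)
        # grow until the planted ratio is decisively significant
        while (
            r_e + 1 <= n_re // max(n_enr, 1)
            and _binom_minlike_p(r_e, r_e + 1, p0) >= 0.01
        ):
            r_e += 1
    d_n = 0
    if n_dep > 0 and 0 < p0 < 1:
        d_n = int(np.ceil(np.log(0.01) / np.log(1 - p0)))
    genes_enriched = n_enr * (r_e + 1)
    if genes_enriched + d_n * n_dep > n_cls - (n_re - n_enr * r_e):
        raise ConfigError(
            "config too small to seed enriched/depleted TADs; reduce "
            "n_tads_enriched/n_tads_depleted or raise n_informative"
        )

    n_bg = config.n_tads - n_enr - n_dep
    g_bg = n_cls - genes_enriched - d_n * n_dep
    r_bg = n_re - n_enr * r_e

    base, extra = divmod(g_bg, n_bg)
    n_per = np.full(n_bg, base, dtype=int)
    if extra:
        n_per[rng.choice(n_bg, size=extra, replace=False)] += 1
    # largest-remainder apportionment of the remaining reactivated genes
    quota = n_per * (r_bg / max(g_bg, 1))
    k_per = np.floor(quota).astype(int)
    k_per = np.minimum(k_per, np.maximum(n_per - 1, 0))
    short = r_bg - k_per.sum()
    if short > 0:
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        for i in order:
            if short == 0:
                break
            if k_per[i] < max(n_per[i] - 1, 0):
                k_per[i] += 1
                short -= 1
        if short > 0:  # last resort: allow full TADs
            for i in order:
                if short == 0:
                    break
                if k_per[i] < n_per[i]:
                    k_per[i] += 1
                    short -= 1
    return r_e, d_n, n_per, k_per


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def _build_population(config: SimulationConfig, rng: np.random.Generator):
    """Lay out genes, TADs and per-gene truth; returns (genes_df, tads_df)."""
    tads = _make_tads(config, rng)
    enr_idx = np.flatnonzero(tads["status"].to_numpy() == "enriched")
    dep_idx = np.flatnonzero(tads["status"].to_numpy() == "depleted")
    bg_idx = np.flatnonzero(tads["status"].to_numpy() == "background")

    r_e, d_n, n_per_bg, k_per_bg = _tad_allocation(config, rng)

    # (tad_row, is_reactivated) slots for the classified genes
    slots: list[tuple[int, bool]] = []
    for ti in enr_idx:
        slots.extend([(ti, True)] * r_e + [(ti, False)])
    for ti in dep_idx:
        slots.extend([(ti, False)] * d_n)
    for j, ti in enumerate(bg_idx):
        slots.extend([(ti, True)] * k_per_bg[j])
        slots.extend([(ti, False)] * (n_per_bg[j] - k_per_bg[j]))
    assert len(slots) == config.n_classified
    assert sum(1 for _, r in slots if r) == config.n_reactivated

    tstart = tads["start"].to_numpy()
    tend = tads["end"].to_numpy()

    rows = []  # (pos, true_class, tier, tad_row)
    react_positions = []
    mecp2_assigned = False
    strong_left = config.n_above_mecp2
    # deterministic pass over slots; Mecp2 goes to the first enriched slot
    # (or first reactivated slot if no enriched TADs), strong tier next
    for ti, is_re in slots:
        lo, hi = tstart[ti] + 2000, tend[ti] - 2000
        pos = int(rng.integers(lo, max(hi, lo + 1)))
        if is_re:
            if not mecp2_assigned:
                tier = "mecp2"
                mecp2_assigned = True
            elif strong_left > 0:
                tier = "strong"
                strong_left -= 1
            else:
                tier = "regular"
            rows.append((pos, "reactivated", tier, ti))
            react_positions.append(pos)
        else:
            rows.append((pos, "non_reactivated", "none", ti))

    # escapees: a fraction placed near reactivated genes (proximity bias)
    for i in range(config.n_escapees):
        if (
            react_positions
            and rng.random() < config.escapee_proximity_bias
        ):
            anchor = int(rng.choice(react_positions))
            off = int(rng.integers(50_000, 400_000)) * (1 if rng.random() < 0.5 else -1)
            pos = int(np.clip(anchor + off, 1_000_000, config.chrom_length_bp - 1_000_000))
        else:
            pos = int(rng.integers(1_000_000, config.chrom_length_bp - 1_000_000))
        tier = "xist" if i == 0 else "none"
        rows.append((pos, "escapee", tier, -1))

    for _ in range(config.n_genes - config.n_informative):
        pos = int(rng.integers(1_000_000, config.chrom_length_bp - 1_000_000))
        rows.append((pos, "uninformative", "none", -1))

    df = pd.DataFrame(rows, columns=["tss", "true_class", "tier", "tad_row"])
    df["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    lengths = np.clip(
        rng.lognormal(mean=np.log(25_000), sigma=0.8, size=len(df)), 2_000, 300_000
    ).astype(np.int64)
    df["length"] = lengths
    start = np.where(
        df["strand"] == "+", df["tss"], df["tss"] - df["length"] + 1
    )
    start = np.clip(start, 0, None)
    end = np.where(df["strand"] == "+", start + df["length"], df["tss"] + 1)
    df["start"], df["end"] = start, end
    # re-derive tss from the clipped interval (clipping can move a minus-strand
    # start; tss itself is never clipped because genes sit >= 1 Mb in)
    df = df.sort_values("tss", kind="stable").reset_index(drop=True)
    ids = [f"G{i + 1:04d}" for i in range(len(df))]
    df.insert(0, "gene_id", ids)
    name = np.array(ids, dtype=object)
    name[df.index[df["tier"] == "mecp2"]] = "Mecp2"
    name[df.index[df["tier"] == "xist"]] = "Xist"
    df.insert(1, "name", name)
    df["tad_id"] = np.where(
        df["tad_row"] >= 0, tads["tad_id"].to_numpy()[df["tad_row"].clip(lower=0)], ""
    )

    # true cast fractions per condition
    frac = {c: np.full(len(df), config.cast_fraction_inactive) for c in config.conditions}
    esc = df["true_class"] == "escapee"
    esc_frac = rng.uniform(*config.cast_fraction_escapee_range, size=int(esc.sum()))
    for c in config.conditions:
        frac[c][esc.to_numpy()] = esc_frac
    xist = (df["tier"] == "xist").to_numpy()
    for c in config.conditions:
        frac[c][xist] = config.xist_cast_fraction
    reg = (df["tier"] == "regular").to_numpy()
    strong = (df["tier"] == "strong").to_numpy()
    mecp2 = (df["tier"] == "mecp2").to_numpy()
    tr = config.treated_condition
    frac[tr][reg] = rng.uniform(*config.cast_fraction_reactivated_regular, size=int(reg.sum()))
    frac[tr][strong] = rng.uniform(*config.cast_fraction_strong, size=int(strong.sum()))
    frac[tr][mecp2] = config.cast_fraction_mecp2
    for c in config.conditions:
        df[f"frac_{c}"] = frac[c]

    df["mean_total_reads"] = np.where(
        df["true_class"] == "uninformative",
        config.uninformative_mean_reads,
        config.mean_total_reads_per_gene,
    )

    hypo = np.zeros(len(df), dtype=bool)
    re_idx = df.index[df["true_class"] == "reactivated"].to_numpy()
    if config.n_hypomethylated_promoters and len(re_idx):
        hypo[rng.choice(re_idx, size=config.n_hypomethylated_promoters, replace=False)] = True
    df["hypomethylated"] = hypo
    return df.drop(columns=["tad_row"]), tads


def _sample_counts(
    config: SimulationConfig, truth_genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Allelic count table (gene x condition x replicate) from the truth."""
    if config.mean_total_reads_per_gene == 0:
        warnings.warn("mean_total_reads_per_gene is 0: all counts will be zero")
    means = truth_genes["mean_total_reads"].to_numpy(dtype=float)
    size = 1.0 / config.nb_dispersion
    frames = []
    for cond in config.conditions:
        fr = truth_genes[f"frac_{cond}"].to_numpy(dtype=float)
        for rep in range(1, config.n_replicates + 1):
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(means > 0, size / (size + means), 1.0)
            totals = rng.negative_binomial(size, p)
            cast = rng.binomial(totals, fr)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": truth_genes["gene_id"],
                        "condition": cond,
                        "replicate": rep,
                        "cast_count": cast,
                        "bl6_count": totals - cast,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _methylation_registry(
    config: SimulationConfig, truth_genes: pd.DataFrame
) -> pd.DataFrame:
    """Region registry: per-gene promoters plus a 2-kb tile grid over the
    +/- 102 kb neighborhoods of informative genes (so repeat-flank intervals
    are always covered by counted regions)."""
    tss = truth_genes["tss"].to_numpy()
    prom = pd.DataFrame(
        {
            "region_id": "prom_" + truth_genes["gene_id"],
            "chrom": config.chrom,
            "start": np.clip(tss - config.promoter_flank_bp, 0, None),
            "end": tss + config.promoter_flank_bp,
            "kind": "promoter",
            "gene_id": truth_genes["gene_id"],
        }
    )
    informative = truth_genes["true_class"] != "uninformative"
    t = tss[informative.to_numpy()]
    w, b = config.neighborhood_bp, config.tile_bp
    cells = np.unique(
        np.concatenate(
            [np.arange((x - w) // b, (x + w) // b + 1) for x in t]
        )
        if len(t)
        else np.array([], dtype=np.int64)
    )
    cells = cells[cells >= 0]
    tiles = pd.DataFrame(
        {
            "region_id": [f"tile_{c}" for c in cells],
            "chrom": config.chrom,
            "start": cells * b,
            "end": (cells + 1) * b,
            "kind": "tile",
            "gene_id": "",
        }
    )
    return pd.concat([prom, tiles], ignore_index=True)


def _methylation_rates(
    config: SimulationConfig, truth_genes: pd.DataFrame, registry: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-region relative methylation rate for each condition."""
    cls = truth_genes.set_index("gene_id")["true_class"]
    hypo = truth_genes.set_index("gene_id")["hypomethylated"]
    # female base rates are spatially flat (promoters and tiles alike): the
    # planted promoter hypomethylation is the only female effect, so the
    # repeat-flank comparison is null by construction; the expressed-gene
    # hypomethylation signal is carried by the male Xa baseline sample
    base = np.full(len(registry), 1.0)
    is_prom = (registry["kind"] == "promoter").to_numpy()
    gcls = cls.reindex(registry.loc[is_prom, "gene_id"]).to_numpy()

    rates = {}
    for cond in config.conditions:
        r = base.copy()
        if cond == config.treated_condition:
            ghypo = hypo.reindex(registry.loc[is_prom, "gene_id"]).to_numpy()
            pr = base[is_prom].copy()
            pr[ghypo.astype(bool)] *= config.hypomethylation_fold
            r[is_prom] = pr
        rates[cond] = r
    male = base.copy()
    minf = np.isin(gcls, ["escapee", "reactivated", "non_reactivated"])
    pr = base[is_prom].copy()
    pr[minf] = 0.2  # expressed on the single active X
    male[is_prom] = pr
    rates[MALE_CONDITION] = male
    return rates


def _sample_methylation(
    config: SimulationConfig,
    truth_genes: pd.DataFrame,
    rng: np.random.Generator,
    promoters_only: bool = False,
) -> pd.DataFrame:
    registry = _methylation_registry(config, truth_genes)
    if promoters_only:
        registry = registry[registry["kind"] == "promoter"].reset_index(drop=True)
    rates = _methylation_rates(config, truth_genes, registry)
    samples = [
        (f"{cond}_r{rep}", cond)
        for cond in config.conditions
        for rep in range(1, config.n_replicates + 1)
    ] + [(f"{MALE_CONDITION}_r1", MALE_CONDITION)]
    frames = []
    for sample_id, cond in samples:
        counts = rng.poisson(config.methylation_depth * rates[cond])
        frames.append(
            pd.DataFrame(
                {
                    "region_id": registry["region_id"],
                    "chrom": registry["chrom"],
                    "start": registry["start"],
                    "end": registry["end"],
                    "sample_id": sample_id,
                    "condition": cond,
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sample_cpgs(
    config: SimulationConfig, truth_genes: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """CpG positions: planted upstream-2kb density by class."""
    cls = truth_genes["true_class"].to_numpy()
    mean = np.where(
        np.isin(cls, ["reactivated", "escapee"]),
        config.cpg_mean_reactivated,
        config.cpg_mean_non,
    )
    counts = rng.poisson(mean)
    tss = truth_genes["tss"].to_numpy()
    minus = (truth_genes["strand"] == "-").to_numpy()
    pos = []
    for t, m, k in zip(tss, minus, counts):
        if k == 0:
            continue
        if m:
            lo, hi = t + 1, t + 2001
        else:
            lo, hi = max(t - 2000, 0), t
        pos.append(rng.integers(lo, hi, size=k))
    return np.sort(np.concatenate(pos)) if pos else np.array([], dtype=np.int64)


_SINE_FAMILIES = ("B1", "B2", "B4")
_LINE_FAMILIES = {1: "L1Md_T", 2: "L1Md_A", 3: "L1Md_F", 4: "L1_Mus"}


def _sample_repeats(
    config: SimulationConfig, truth_genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Repeat elements planted around every gene TSS with class-dependent
    SINE/LINE densities in the +/- 100 kb window."""
    cls = truth_genes["true_class"].to_numpy()
    tss = truth_genes["tss"].to_numpy()
    is_re = np.isin(cls, ["reactivated", "escapee"])
    sine_mean = np.where(is_re, config.sine_mean_reactivated, config.sine_mean_non)
    line_mean = np.where(is_re, config.line_mean_reactivated, config.line_mean_non)
    rows = []
    L = config.chrom_length_bp
    for t, ns, nl in zip(tss, rng.poisson(sine_mean), rng.poisson(line_mean)):
        if ns:
            mids = rng.integers(max(t - 100_000, 500), min(t + 100_000, L - 8000), size=ns)
            lens = rng.integers(100, 400, size=ns)
            fams = rng.choice(len(_SINE_FAMILIES), size=ns)
            for m, ln, f in zip(mids, lens, fams):
                rows.append(("SINE", _SINE_FAMILIES[f], int(m), int(ln), 0))
        if nl:
            mids = rng.integers(max(t - 100_000, 500), min(t + 100_000, L - 8000), size=nl)
            full = rng.random(nl) < 0.25
            lens = np.where(
                full, rng.integers(6000, 7001, size=nl), rng.integers(500, 6000, size=nl)
            )
            ages = rng.integers(1, 5, size=nl)
            for m, ln, a in zip(mids, lens, ages):
                rows.append(("LINE", _LINE_FAMILIES[int(a)], int(m), int(ln), int(a)))
    df = pd.DataFrame(rows, columns=["repeat_class", "family", "mid", "length", "age_rank"])
    df["start"] = np.maximum(df["mid"] - df["length"] // 2, 0)
    df["end"] = df["start"] + df["length"]
    return df.sort_values("start", kind="stable").reset_index(drop=True)


_TRACK_AMPLITUDE = {
    # class -> peak height at TSS
    "ctcf": {"escapee": 8.0, "reactivated": 5.0, "non_reactivated": 3.0},
    "rad21": {"escapee": 5.0, "reactivated": 3.5, "non_reactivated": 2.0},
    "h3k4me3": {"escapee": 10.0, "reactivated": 7.0, "non_reactivated": 4.0},
    "h3k27me3": {"escapee": 1.0, "reactivated": 4.0, "non_reactivated": 6.0},
}
_BODY_LEVEL = {"escapee": 1.0, "reactivated": 5.0, "non_reactivated": 4.0}
_TRACK_RES = 100  # bp per grid cell


def _grid_to_track(chrom: str, grid: np.ndarray) -> SignalTrack:
    """Run-length encode a dense grid (resolution _TRACK_RES) into a track."""
    change = np.flatnonzero(np.diff(grid) != 0) + 1
    bounds = np.concatenate([[0], change, [len(grid)]])
    starts, ends, vals = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        v = grid[a]
        if v != 0:
            starts.append(a * _TRACK_RES)
            ends.append(b * _TRACK_RES)
            vals.append(v)
    return SignalTrack(chrom, np.array(starts), np.array(ends), np.array(vals))


def _sample_tracks(
    config: SimulationConfig, truth_genes: pd.DataFrame
) -> dict[str, SignalTrack]:
    ncell = config.chrom_length_bp // _TRACK_RES + 1
    informative = truth_genes[truth_genes["true_class"] != "uninformative"]
    tss = informative["tss"].to_numpy() // _TRACK_RES
    cls = informative["true_class"].to_numpy()
    offsets = np.arange(-20, 21)  # +/- 2 kb at 100 bp
    shape = np.exp(-0.5 * (offsets * _TRACK_RES / 500.0) ** 2)
    tracks: dict[str, SignalTrack] = {}
    for name in TRACK_NAMES:
        grid = np.zeros(ncell)
        amp = np.vectorize(_TRACK_AMPLITUDE[name].get)(cls).astype(float)
        for t, a in zip(tss, amp):
            grid[t + offsets] += a * shape
        tracks[name] = _grid_to_track(config.chrom, np.round(grid, 4))
    grid = np.zeros(ncell)
    starts = informative["start"].to_numpy() // _TRACK_RES
    ends = informative["end"].to_numpy() // _TRACK_RES + 1
    level = np.vectorize(_BODY_LEVEL.get)(cls).astype(float)
    for s, e, v in zip(starts, ends, level):
        grid[s:e] += v
    tracks[BODY_TRACK] = _grid_to_track(config.chrom, grid)
    return tracks


def simulate_dataset(
    config: SimulationConfig, out_dir, write_tracks: bool = True
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the full synthetic bundle under ``out_dir``.

    Deterministic for a fixed (config, seed). Returns the file manifest and
    the planted :class:`GroundTruth`. Validates feasibility before writing.
    """
    rng = np.random.default_rng(config.seed)
    truth_genes, tads = _build_population(config, rng)
    truth = GroundTruth(genes=truth_genes, tads=tads)
    truth.validate_against(config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    genes = [
        GeneModel(
            gene_id=r.gene_id,
            name=r.name,
            interval=GenomicInterval(config.chrom, int(r.start), int(r.end), r.strand),
        )
        for r in truth_genes.itertuples(index=False)
    ]
    bundle["genes"] = out / "genes.tsv"
    write_gene_table(genes, bundle["genes"])

    counts = _sample_counts(config, truth_genes, rng)
    bundle["counts"] = out / "allelic_counts.tsv"
    counts.to_csv(bundle["counts"], sep="\t", index=False)

    cpgs = _sample_cpgs(config, truth_genes, rng)
    bundle["cpg"] = out / "cpg.bed"
    write_bed(
        [{"interval": GenomicInterval(config.chrom, int(p), int(p) + 2)} for p in cpgs],
        bundle["cpg"],
    )

    rep_df = _sample_repeats(config, truth_genes, rng)
    repeats = [
        RepeatElement(
            interval=GenomicInterval(config.chrom, int(r.start), int(r.end)),
            repeat_class=r.repeat_class,
            family=r.family,
            length_bp=int(r.length),
            age_rank=int(r.age_rank) if r.repeat_class == "LINE" else None,
        )
        for r in rep_df.itertuples(index=False)
    ]
    bundle["repeats"] = out / "repeats.bed"
    repeats_to_bed(repeats, bundle["repeats"])

    bundle["tads"] = out / "tads.bed"
    write_bed(
        [
            {"interval": GenomicInterval(r.chrom, int(r.start), int(r.end)), "name": r.tad_id}
            for r in tads.itertuples(index=False)
        ],
        bundle["tads"],
    )

    meth = _sample_methylation(config, truth_genes, rng)
    bundle["methylation"] = out / "methylation.tsv"
    meth.to_csv(bundle["methylation"], sep="\t", index=False)

    if write_tracks:
        for name, track in _sample_tracks(config, truth_genes).items():
            bundle[f"track_{name}"] = out / f"{name}.bedgraph"
            write_bedgraph(track, bundle[f"track_{name}"])

    bundle["truth_genes"] = out / "ground_truth.tsv"
    bundle["truth_tads"] = out / "ground_truth_tads.tsv"
    truth.write(bundle["truth_genes"], bundle["truth_tads"])
    logger.info("synthetic bundle written to %s (%d files)", out, len(bundle))
    return bundle, truth


def regenerate_counts_only(
    config: SimulationConfig,
    truth: GroundTruth,
    new_seed: int,
    out_path=None,
) -> pd.DataFrame:
    """Fresh allelic-count noise over an existing ground truth.

    Same truth, new negative-binomial/binomial realizations — used for power
    and stability estimation across seeds.
    """
    truth.validate_against(config)
    rng = np.random.default_rng(new_seed)
    counts = _sample_counts(config, truth.genes, rng)
    if out_path is not None:
        counts.to_csv(out_path, sep="\t", index=False)
    return counts


def resample_promoter_methylation(
    config: SimulationConfig, truth: GroundTruth, new_seed: int
) -> pd.DataFrame:
    """Fresh promoter methylation noise over an existing ground truth."""
    truth.validate_against(config)
    rng = np.random.default_rng(new_seed)
    return _sample_methylation(config, truth.genes, rng, promoters_only=True)
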