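"""Overlap statistics between gene classes and external gene lists.

Gene symbols are case-normalized before comparison; percentages are reported
rounded to the nearest integer (matching the conventional Venn-diagram
style) with the unrounded values retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneList:
    label: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_symbols(cls, label: str, symbols) -> "GeneList":
        return cls(label, frozenset(s.strip().casefold() for s in symbols if s.strip()))

    @classmethod
    def from_file(cls, path, label: str | None = None) -> "GeneList":
        with open(path) as fh:
            syms = [line.split("\t")[0] for line in fh if line.strip()]
        return cls.from_symbols(label or str(path), syms)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class OverlapResult:
    n_overlap: int
    pct_of_a: float  # unrounded
    pct_of_b: float
    pct_of_a_rounded: int
    pct_of_b_rounded: int


def overlap_stats(list_a: GeneList, list_b: GeneList) -> OverlapResult:
    """|A intersect B| with the percentage of each list covered."""
    if not len(list_a) or not len(list_b):
        raise ValueError("both gene lists must be non-empty")
    n = len(list_a.symbols & list_b.symbols)
    pa = 100.0 * n / len(list_a)
    pb = 100.0 * n / len(list_b)
    return OverlapResult(n, pa, pb, round(pa), round(pb))


def hypergeometric_enrichment(
    n_overlap: int, size_a: int, size_b: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= n_overlap)."""
    if not (0 <= n_overlap <= min(size_a, size_b) <= universe_size):
        raise ValueError(
            f"inconsistent sizes: overlap={n_overlap}, |A|={size_a}, "
            f"|B|={size_b}, universe={universe_size}"
        )
    if max(size_a, size_b) > universe_size:
        raise ValueError("list larger than the universe")
    return float(stats.hypergeom.sf(n_overlap - 1, universe_size, size_a, size_b))


def multi_overlap_report(
    class_lists: dict[str, GeneList],
    external_lists: list[GeneList],
    unions: list[tuple[str, list[str]]] | None = None,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """One row per (class, external list) pair, plus optional union rows.

    ``unions`` are (label, [external labels]) pairs whose symbol sets are
    united before overlap (e.g. escapee + early-reactivating). A symbol
    appearing in several external lists is counted in each (logged).
    """
    ext = {l.label: l for l in external_lists}
    seen: dict[str, list[str]] = {}
    for l in external_lists:
        for s in l.symbols:
            seen.setdefault(s, []).append(l.label)
    multi = {s: ls for s, ls in seen.items() if len(ls) > 1}
    if multi:
        logger.info("%d symbols occur in multiple external lists", len(multi))

    targets: list[GeneList] = list(external_lists)
    for label, members in unions or []:
        merged = frozenset().union(*(ext[m].symbols for m in members))
        targets.append(GeneList(label, merged))

    rows = []
    for cname, clist in class_lists.items():
        for t in targets:
            if not len(clist) or not len(t):
                continue
            r = overlap_stats(clist, t)
            row = {
                "class": cname,
                "external": t.label,
                "n_class": len(clist),
                "n_external": len(t),
                "n_overlap": r.n_overlap,
                "pct_of_class": r.pct_of_a_rounded,
                "pct_of_external": r.pct_of_b_rounded,
                "pct_of_class_unrounded": r.pct_of_a,
                "pct_of_external_unrounded": r.pct_of_b,
            }
            if universe_size:
                row["hypergeom_p"] = hypergeometric_enrichment(
                    r.n_overlap, len(clist), len(t), universe_size
                )
            rows.append(row)
    return pd.DataFrame(rows)
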