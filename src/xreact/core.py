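"""Coordinate-aware domain types and readers/writers for the standard formats.

All coordinates are 0-based half-open (BED convention). A gene's TSS is a
single 0-based base: ``interval.start`` on the plus strand and
``interval.end - 1`` on the minus strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in an input file (message names the line)."""


class ValidationError(ValueError):
    """Record violates a domain-type invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start and end sites."""

    gene_id: str
    name: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class RepeatElement:
    """A SINE or LINE annotation with family, length and optional age rank."""

    interval: GenomicInterval
    repeat_class: str  # "SINE" | "LINE"
    family: str
    length_bp: int
    age_rank: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp != len(self.interval):
            raise ValidationError(
                f"repeat length {self.length_bp} != interval span {len(self.interval)}"
            )

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class SignalTrack:
    """Sorted, non-overlapping (interval, value) bins on one chromosome.

    Positions not covered by any bin carry signal zero. Supports O(log n)
    integral queries used by the metagene-profile code.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValidationError("starts/ends/values length mismatch")
        if len(self.starts):
            if np.any(self.ends <= self.starts):
                raise ValidationError("signal bin with end <= start")
            if np.any(np.diff(self.starts) < 0):
                raise ValidationError("signal bins not sorted by start")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValidationError("overlapping signal bins")
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("non-finite signal value")
            if np.any(self.values < 0):
                raise ValidationError("negative signal value")
        # cumulative mass at each bin end, prefixed with 0
        self._cum = np.concatenate(
            [[0.0], np.cumsum(self.values * (self.ends - self.starts))]
        )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_mass(self) -> float:
        """Sum of value x width over all bins."""
        return float(self._cum[-1])

    def _cdf(self, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over (-inf, x)."""
        x = np.asarray(x, dtype=np.int64)
        if not len(self.starts):
            return np.zeros(x.shape, dtype=float)
        idx = np.searchsorted(self.starts, x, side="right") - 1
        safe = np.clip(idx, 0, None)
        covered = np.minimum(
            np.maximum(x - self.starts[safe], 0), self.ends[safe] - self.starts[safe]
        )
        out = self._cum[safe] + self.values[safe] * covered
        return np.where(idx < 0, 0.0, out)

    def integral(self, start, end) -> np.ndarray:
        """Signal mass over [start, end); accepts scalars or arrays."""
        a = np.atleast_1d(np.asarray(start, dtype=np.int64))
        b = np.atleast_1d(np.asarray(end, dtype=np.int64))
        res = self._cdf(b) - self._cdf(a)
        return res if np.ndim(start) else float(res[0])

    def mean_over(self, start, end):
        """Mean signal over [start, end) treating gaps as zero."""
        a = np.atleast_1d(np.asarray(start, dtype=np.int64))
        b = np.atleast_1d(np.asarray(end, dtype=np.int64))
        width = (b - a).astype(float)
        res = np.where(width > 0, (self._cdf(b) - self._cdf(a)) / width, np.nan)
        return res if np.ndim(start) else float(res[0])

    def rebin(self, bin_bp: int) -> "SignalTrack":
        """Re-bin onto a regular ``bin_bp`` grid spanning the covered range.

        Total mass is conserved exactly (each new bin receives the integral of
        the old track over its extent).
        """
        if bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        if not len(self):
            return SignalTrack(self.chrom, [], [], [])
        lo = (self.starts[0] // bin_bp) * bin_bp
        hi = -(-int(self.ends[-1]) // bin_bp) * bin_bp
        edges = np.arange(lo, hi + bin_bp, bin_bp, dtype=np.int64)
        mass = self.integral(edges[:-1], edges[1:])
        keep = mass != 0
        return SignalTrack(
            self.chrom, edges[:-1][keep], edges[1:][keep], mass[keep] / bin_bp
        )


@dataclass
class TadSet:
    """Sorted, non-overlapping TAD intervals on one chromosome."""

    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        ivs = self.intervals
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"overlapping TADs at {prev.chrom}:{prev.start}-{prev.end}"
                )
            if cur.start < prev.start:
                raise ValidationError("TADs not sorted")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path) -> list[dict]:
    """Read a BED3+ file into records with a validated ``interval``.

    Returns one dict per line: ``interval`` plus optional ``name``, ``score``
    and any further columns under ``extra`` (a tuple of strings). Blank and
    comment lines are skipped.
    """
    records = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
        strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
        try:
            interval = GenomicInterval(chrom, start, end, strand)
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
        rec = {"interval": interval}
        if len(fields) > 3:
            rec["name"] = fields[3]
        if len(fields) > 4:
            rec["score"] = fields[4]
        if len(fields) > 6:
            rec["extra"] = tuple(fields[6:])
        records.append(rec)
    return records


def write_bed(records, path) -> None:
    """Write records (as produced by :func:`read_bed`) back to BED.

    Canonical 3-column input round-trips byte-identically.
    """
    with open(path, "w") as fh:
        for rec in records:
            iv = rec["interval"]
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_extra = "extra" in rec and rec["extra"]
            if "name" in rec or "score" in rec or iv.strand != "." or has_extra:
                fields.append(str(rec.get("name", ".")))
            if "score" in rec or iv.strand != "." or has_extra:
                fields.append(str(rec.get("score", ".")))
            if iv.strand != "." or has_extra:
                fields.append(iv.strand)
            if has_extra:
                fields.extend(str(x) for x in rec["extra"])
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path, chrom: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Records are sorted by start; overlapping records or negative values raise
    :class:`ValidationError`. With ``chrom`` given, other chromosomes are
    ignored; otherwise the file must be single-chromosome.
    """
    rows = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        c = fields[0]
        if chrom is not None and c != chrom:
            continue
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad record") from exc
        if value < 0:
            raise ValidationError(f"{path}: line {lineno}: negative value {value}")
        rows.append((c, start, end, value))
    if not rows:
        return SignalTrack(chrom or "chrX", [], [], [])
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValidationError(
            f"{path}: multiple chromosomes {sorted(chroms)}; pass chrom= to select one"
        )
    rows.sort(key=lambda r: (r[1], r[2]))
    starts = np.array([r[1] for r in rows], dtype=np.int64)
    ends = np.array([r[2] for r in rows], dtype=np.int64)
    values = np.array([r[3] for r in rows], dtype=float)
    if np.any(starts[1:] < ends[:-1]):
        i = int(np.argmax(starts[1:] < ends[:-1]))
        raise ValidationError(
            f"{path}: overlapping bins around {rows[i][0]}:{rows[i][1]}-{rows[i][2]}"
        )
    return SignalTrack(rows[0][0], starts, ends, values)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:g}\n")


GENE_TABLE_COLUMNS = ["gene_id", "name", "chrom", "start", "end", "strand"]


def read_gene_table(path) -> list[GeneModel]:
    """Read the gene-annotation TSV (gene_id, name, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "name": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene_id(s): {sorted(set(dup))[:5]}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                name=row.name,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            )
        )
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = [
        (g.gene_id, g.name, g.interval.chrom, g.interval.start, g.interval.end, g.strand)
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tads(path) -> TadSet:
    recs = read_bed(path)
    ivs = sorted((r["interval"] for r in recs), key=lambda iv: iv.start)
    ivs = [GenomicInterval(iv.chrom, iv.start, iv.end, ".") for iv in ivs]
    return TadSet(ivs)


# ---------------------------------------------------------------------------
# window arithmetic
# ---------------------------------------------------------------------------


def tss_window(gene: GeneModel, upstream: int, downstream: int) -> GenomicInterval:
    """Strand-aware window around the TSS, clipped at position zero.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand the
    mirror image ``[tss - downstream + 1, tss + upstream + 1)``. With
    ``downstream = 0`` the TSS base itself is excluded on either strand
    (half-open at the TSS), matching the upstream-promoter convention.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    tss = gene.tss
    if gene.strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        start, end = tss - upstream, tss + downstream
    start = max(start, 0)
    if end <= start:
        raise ValidationError(
            f"empty TSS window for {gene.gene_id} (upstream={upstream}, "
            f"downstream={downstream})"
        )
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


def repeats_from_bed(path) -> list[RepeatElement]:
    """Read the extended repeat BED (name=class:family, score=age_rank, col7=length)."""
    out = []
    for rec in read_bed(path):
        name = rec.get("name", "")
        if ":" in name:
            rclass, family = name.split(":", 1)
        else:
            rclass, family = name, ""
        score = rec.get("score", ".")
        age = None if score in (".", "", None) else int(score)
        extra = rec.get("extra", ())
        length = int(extra[0]) if extra else len(rec["interval"])
        out.append(
            RepeatElement(
                interval=rec["interval"],
                repeat_class=rclass,
                family=family,
                length_bp=length,
                age_rank=age,
            )
        )
    return out


def repeats_to_bed(repeats: list[RepeatElement], path) -> None:
    recs = []
    for r in repeats:
        recs.append(
            {
                "interval": r.interval,
                "name": f"{r.repeat_class}:{r.family}",
                "score": "." if r.age_rank is None else str(r.age_rank),
                "extra": (str(r.length_bp),),
            }
        )
    write_bed(recs, path)
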