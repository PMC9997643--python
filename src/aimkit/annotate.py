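"""Genomic-region classification, window densities, enrichment tests and
array-overlap reporting.

Gene-model coordinates are 0-based half-open internally; incoming VCF
positions (1-based) are shifted on entry. Region categories follow the
usual annotator precedence so each variant gets exactly one call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import ArrayManifest, VariantRecord

__all__ = [
    "Transcript",
    "GeneModel",
    "RegionCall",
    "WindowConfig",
    "classify_regions",
    "window_density",
    "region_enrichment",
    "fisher_exact_2x2",
    "platform_overlap",
    "OverlapReport",
    "read_refgene",
    "read_gtf",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "exonic",
    "splicing",
    "5'UTR",
    "3'UTR",
    "ncRNA_exonic",
    "intronic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_PRECEDENCE = {cat: i for i, cat in enumerate(CATEGORIES)}

SPLICE_WINDOW = 2  # bp from an exon boundary, inside the intron


@dataclass(frozen=True)
class Transcript:
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open transcript span
    end: int
    cds_start: int  # cds_start == cds_end -> noncoding
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene}")
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise ValueError(f"CDS outside transcript span for {self.gene}")
        prev = -1
        for s, e in self.exons:
            if s >= e or s < prev:
                raise ValueError(f"exon intervals bad/unsorted for {self.gene}")
            prev = e

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start


@dataclass
class GeneModel:
    transcripts: list[Transcript]
    flank: int = 1000  # upstream/downstream distance

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            by_chrom.setdefault(tx.chrom, []).append(tx)
        self._by_chrom = by_chrom

    def chrom_transcripts(self, chrom: str) -> list[Transcript]:
        return self._by_chrom.get(chrom, [])

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)


@dataclass
class RegionCall:
    variant_id: str
    chrom: str
    pos: int
    category: str
    gene: str  # containing or nearest gene ('' if none on chromosome)


def _classify_in_transcript(p: int, tx: Transcript, flank: int) -> str | None:
    """Category contributed by one transcript at 0-based position p."""
    if tx.start <= p < tx.end:
        in_exon = any(s <= p < e for s, e in tx.exons)
        if in_exon:
            if not tx.coding:
                return "ncRNA_exonic"
            if tx.cds_start <= p < tx.cds_end:
                return "exonic"
            if p < tx.cds_start:
                return "5'UTR" if tx.strand == "+" else "3'UTR"
            return "3'UTR" if tx.strand == "+" else "5'UTR"
        # intronic side
        if tx.coding:
            for s, e in tx.exons:
                if s - SPLICE_WINDOW <= p < s or e <= p < e + SPLICE_WINDOW:
                    return "splicing"
            return "intronic"
        return "ncRNA_intronic"
    if tx.strand == "+":
        if tx.start - flank <= p < tx.start:
            return "upstream"
        if tx.end <= p < tx.end + flank:
            return "downstream"
    else:
        if tx.end <= p < tx.end + flank:
            return "upstream"
        if tx.start - flank <= p < tx.start:
            return "downstream"
    return None


def _nearest_gene(p: int, txs: Sequence[Transcript]) -> str:
    best, best_d = "", None
    for tx in txs:
        d = 0 if tx.start <= p < tx.end else min(abs(p - tx.start), abs(p - (tx.end - 1)))
        if best_d is None or d < best_d:
            best, best_d = tx.gene, d
    return best


def classify_regions(
    variants: Sequence[VariantRecord], model: GeneModel
) -> list[RegionCall]:
    """One precedence-resolved region category per variant."""
    uncovered = {v.chrom for v in variants} - model.chromosomes
    if uncovered:
        warnings.warn(
            f"chromosomes without gene-model coverage treated as intergenic: "
            f"{sorted(uncovered)}",
            stacklevel=2,
        )
    calls: list[RegionCall] = []
    for v in variants:
        p = v.pos - 1
        txs = model.chrom_transcripts(v.chrom)
        best_cat, best_gene = "intergenic", ""
        for tx in txs:
            cat = _classify_in_transcript(p, tx, model.flank)
            if cat is not None and _PRECEDENCE[cat] < _PRECEDENCE[best_cat]:
                best_cat, best_gene = cat, tx.gene
        if best_cat == "intergenic":
            best_gene = _nearest_gene(p, txs)
        calls.append(RegionCall(v.id, v.chrom, v.pos, best_cat, best_gene))
    return calls


def category_counts(calls: Sequence[RegionCall]) -> dict[str, int]:
    out = {cat: 0 for cat in CATEGORIES}
    for c in calls:
        out[c.category] += 1
    return out


@dataclass
class WindowConfig:
    length: int = 1_000_000  # bp per tile, 0-based half-open tiling

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")


def window_density(
    variants: Sequence[VariantRecord],
    cfg: WindowConfig,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Variant counts per fixed-length tile; columns chrom/start/end/count.

    The last (possibly partial) tile is retained; a variant beyond the
    stated chromosome length is assigned to the last tile with a warning.
    """
    frames = []
    for chrom, length in chrom_lengths.items():
        n_tiles = max(1, -(-length // cfg.length))
        starts = np.arange(n_tiles) * cfg.length
        ends = np.minimum(starts + cfg.length, length)
        counts = np.zeros(n_tiles, dtype=np.int64)
        for v in variants:
            if v.chrom != chrom:
                continue
            tile = (v.pos - 1) // cfg.length
            if v.pos - 1 >= length:
                warnings.warn(
                    f"variant {v.id} at {chrom}:{v.pos} beyond chromosome "
                    f"length {length}; assigned to last tile",
                    stacklevel=2,
                )
                tile = n_tiles - 1
            counts[tile] += 1
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "count": counts}
            )
        )
    stray = {v.chrom for v in variants} - set(chrom_lengths)
    if stray:
        warnings.warn(f"variants on chromosomes without lengths ignored: {sorted(stray)}")
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "count"]
    )


@lru_cache(maxsize=100_000)
def _hypergeom_pmf(n_total: int, k_success: int, n_draw: int) -> tuple[np.ndarray, int]:
    lo = max(0, n_draw + k_success - n_total)
    hi = min(n_draw, k_success)
    support = np.arange(lo, hi + 1)
    return hypergeom.pmf(support, n_total, k_success, n_draw), lo


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and sample odds ratio for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one, using the
    customary (1 + 1e-7) relative tie tolerance. A zero margin gives
    p = 1 and an undefined (NaN) odds ratio.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return 1.0, float("nan")
    pmf, lo = _hypergeom_pmf(n_total, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    p = min(1.0, p)
    if b == 0 or c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return p, odds


@dataclass
class EnrichmentResult:
    category: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float


def region_enrichment(
    panel_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
    category: str,
) -> EnrichmentResult:
    """Two-sided exact test of one region category, panel vs background."""
    a = int(panel_counts.get(category, 0))
    b = sum(int(v) for k, v in panel_counts.items() if k != category)
    c = int(background_counts.get(category, 0))
    d = sum(int(v) for k, v in background_counts.items() if k != category)
    p, odds = fisher_exact_2x2(((a, b), (c, d)))
    return EnrichmentResult(category, ((a, b), (c, d)), p, odds)


@dataclass
class OverlapReport:
    per_platform: pd.DataFrame  # platform, n_matched, fraction
    panel_size: int
    union_count: int
    imputable_count: int | None = None


def platform_overlap(
    panel_ids: Sequence[str],
    manifests: Sequence[ArrayManifest],
    panel_positions: Sequence[tuple[str, int]] | None = None,
    imputable_ids: frozenset[str] | set[str] | None = None,
) -> OverlapReport:
    """Overlap of the AIMs panel with each array manifest.

    Markers are matched by rsID first; when a manifest carries positions,
    unmatched panel markers fall back to (chrom, pos) matching. The union
    count across platforms avoids double counting.
    """
    panel_ids = list(panel_ids)
    n = len(panel_ids)
    positions = list(panel_positions) if panel_positions is not None else [None] * n
    rows = []
    union: set[int] = set()
    for mani in manifests:
        matched: set[int] = set()
        for i, (rsid, pos) in enumerate(zip(panel_ids, positions)):
            if rsid in mani.marker_ids:
                matched.add(i)
            elif mani.positions is not None and pos is not None and pos in mani.positions:
                matched.add(i)
        union |= matched
        rows.append(
            {
                "platform": mani.platform_name,
                "n_matched": len(matched),
                "fraction": len(matched) / n if n else 0.0,
            }
        )
    report = pd.DataFrame(rows).sort_values(
        "fraction", ascending=False, ignore_index=True
    )
    imputable = (
        sum(1 for rsid in panel_ids if rsid in imputable_ids)
        if imputable_ids is not None
        else None
    )
    return OverlapReport(report, n, len(union), imputable)


# ---------------------------------------------------------------------------
# gene-model readers


def read_refgene(path) -> list[Transcript]:
    """refGene-style TSV: name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds, name2 (optional leading bin
    column tolerated). Coordinates are already 0-based half-open."""
    txs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0].isdigit() and len(parts) >= 12:
                parts = parts[1:]  # UCSC bin column
            try:
                (name, chrom, strand, tx_s, tx_e, cds_s, cds_e, n_ex, ex_s, ex_e) = (
                    parts[:10]
                )
                gene = parts[10] if len(parts) > 10 else name
                starts = [int(x) for x in ex_s.rstrip(",").split(",")]
                ends = [int(x) for x in ex_e.rstrip(",").split(",")]
                if len(starts) != int(n_ex) or len(ends) != int(n_ex):
                    raise ValueError("exon count mismatch")
                txs.append(
                    Transcript(
                        gene=gene,
                        chrom=chrom,
                        strand=strand,
                        start=int(tx_s),
                        end=int(tx_e),
                        cds_start=int(cds_s),
                        cds_end=int(cds_e),
                        exons=tuple(zip(starts, ends)),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {line_no}: bad gene model: {exc}")
    return txs


def read_gtf(path) -> list[Transcript]:
    """Minimal GTF reader: groups exon/CDS features by transcript_id.

    GTF is 1-based inclusive; intervals are converted to 0-based
    half-open. A transcript with no CDS features is noncoding.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {line_no}: not a GTF record")
            chrom, _src, feat, start, end, _score, strand, _frame, attrs = parts[:9]
            if feat not in ("exon", "CDS"):
                continue
            fields = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in attrs.rstrip(";").split(";")
                if kv.strip()
            )
            tid = fields.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: line {line_no}: missing transcript_id")
            gene = fields.get("gene_name", fields.get("gene_id", tid))
            meta.setdefault(tid, (gene, chrom, strand))
            iv = (int(start) - 1, int(end))
            (exons if feat == "exon" else cds).setdefault(tid, []).append(iv)
    txs = []
    for tid, (gene, chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            continue
        cd = sorted(cds.get(tid, []))
        txs.append(
            Transcript(
                gene=gene,
                chrom=chrom,
                strand=strand,
                start=ex[0][0],
                end=ex[-1][1],
                cds_start=cd[0][0] if cd else ex[0][0],
                cds_end=cd[-1][1] if cd else ex[0][0],
                exons=tuple(ex),
            )
        )
    return txs
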