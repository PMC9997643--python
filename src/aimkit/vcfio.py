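"""Readers and writers for VCF, sample-panel, manifest and ID-list files.

VCF parsing is delegated to cyvcf2 (htslib); only the writer is local so
that CHROM/POS/ID/REF/ALT/GT round-trip byte-identically. Coordinates are
1-based inclusive internally, matching VCF itself.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import MISSING, ArrayManifest, GenotypeMatrix, SamplePanel, VariantRecord

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
    "read_manifest",
    "read_id_list",
    "VcfParseError",
]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


def _count_header_lines(path: str) -> int:
    """Header lines (through #CHROM) in a plain or bgzipped VCF, so parse
    errors can name the offending file line."""
    import gzip

    opener = gzip.open if path.endswith((".gz", ".bgz")) else open
    n = 0
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            if line.startswith("#CHROM"):
                break
    return n


def read_vcf(
    path: str | os.PathLike,
    region: str | None = None,
    samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Load a VCF 4.x file (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF file path.
    region
        Optional chromosome label; only records on it are kept.
    samples
        Optional subset of header samples (order taken from this list).

    Notes
    -----
    Multiallelic records are kept whole (``n_alleles > 2``). Both phased
    and unphased separators are accepted; half-missing genotypes (e.g.
    ``./1``) are recorded as fully missing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    reader = VCF(path, strict_gt=False)
    header_samples = list(reader.samples)
    if samples is not None:
        unknown = [s for s in samples if s not in header_samples]
        if unknown:
            raise KeyError(f"samples not in VCF header: {unknown}")
        reader.set_samples(list(samples))
    kept_samples = list(reader.samples)
    n_header_lines = _count_header_lines(path)

    variants: list[VariantRecord] = []
    allele_rows: list[np.ndarray] = []
    ploidy_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    n_s = len(kept_samples)

    record_no = 0
    while True:
        try:
            var = next(reader, None)
        except Exception as exc:  # htslib-level failure
            raise VcfParseError(
                f"{path}: malformed VCF record at line "
                f"{n_header_lines + record_no + 1}: {exc}"
            ) from exc
        if var is None:
            break
        record_no += 1
        line_no = n_header_lines + record_no
        if region is not None and var.CHROM != region:
            continue
        try:
            rec = VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID or ".",
                ref=var.REF,
                alts=tuple(var.ALT),
            )
        except ValueError as exc:
            raise VcfParseError(f"{path}: line {line_no}: {exc}") from exc

        al = np.full((n_s, 2), MISSING, dtype=np.int16)
        pl = np.full(n_s, 2, dtype=np.uint8)
        ph = np.zeros(n_s, dtype=bool)
        for s, gt in enumerate(var.genotypes):
            *idx, phased = gt
            ph[s] = bool(phased)
            if len(idx) == 1:
                pl[s] = 1
                if idx[0] >= 0:
                    al[s, 0] = idx[0]
            elif len(idx) == 2:
                if idx[0] >= 0 and idx[1] >= 0:
                    al[s] = idx
                # half-missing stays fully missing
            else:
                raise VcfParseError(
                    f"{path}: line {line_no}: unsupported ploidy {len(idx)}"
                )
        if n_s and (al.max(initial=-1) >= rec.n_alleles):
            raise VcfParseError(
                f"{path}: line {line_no}: GT allele index out of range"
            )
        variants.append(rec)
        allele_rows.append(al)
        ploidy_rows.append(pl)
        phased_rows.append(ph)

    if variants:
        alleles = np.stack(allele_rows, axis=1)
        ploidy = np.stack(ploidy_rows, axis=1)
        phased = np.stack(phased_rows, axis=1)
    else:
        alleles = np.zeros((n_s, 0, 2), dtype=np.int16)
        ploidy = np.zeros((n_s, 0), dtype=np.uint8)
        phased = np.zeros((n_s, 0), dtype=bool)
    return GenotypeMatrix(variants, kept_samples, alleles, ploidy, phased)


def _format_gt(alleles: np.ndarray, ploidy: int, phased: bool) -> str:
    sep = "|" if phased else "/"
    if ploidy == 1:
        return "." if alleles[0] == MISSING else str(alleles[0])
    a, b = alleles
    left = "." if a == MISSING else str(a)
    right = "." if b == MISSING else str(b)
    return f"{left}{sep}{right}"


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> Path:
    """Write ``g`` as an uncompressed VCF 4.2 file with GT-only records."""
    path = Path(path)
    chroms = list(dict.fromkeys(v.chrom for v in g.variants))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=aimkit",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.samples)
    )
    for j, v in enumerate(g.variants):
        gts = "\t".join(
            _format_gt(g.alleles[i, j], int(g.ploidy[i, j]), bool(g.phased[i, j]))
            for i in range(g.n_samples)
        )
        row = f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{','.join(v.alts)}\t.\t.\t.\tGT"
        lines.append(row + "\t" + gts if g.n_samples else row)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_panel(path: str | os.PathLike) -> SamplePanel:
    """Parse a 1KGP-style sample panel (columns: sample, pop, super_pop).

    Extra columns are ignored; both tab- and whitespace-delimited dialects
    are accepted.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("sample", "pop", "super_pop") if c not in cols]
    if missing:
        raise ValueError(f"{path}: panel file missing columns {missing}")
    samples = df[cols["sample"]]
    dup = samples[samples.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample ids in panel: {sorted(set(dup))}")
    entries = {
        row[cols["sample"]]: (row[cols["pop"]], row[cols["super_pop"]])
        for _, row in df.iterrows()
    }
    return SamplePanel(entries)


def write_panel(panel: SamplePanel, path: str | os.PathLike) -> Path:
    path = Path(path)
    rows = ["sample\tpop\tsuper_pop"]
    rows += [f"{s}\t{p}\t{sp}" for s, (p, sp) in panel.entries.items()]
    path.write_text("\n".join(rows) + "\n")
    return path


def read_manifest(
    path: str | os.PathLike,
    platform_name: str,
    id_column: str = "Name",
    chrom_column: str | None = None,
    pos_column: str | None = None,
    sep: str = ",",
) -> ArrayManifest:
    """Load a genotyping-array manifest table into an :class:`ArrayManifest`.

    ``id_column`` names the marker-identifier column; duplicate ids are
    collapsed. If both ``chrom_column`` and ``pos_column`` are given, the
    position key set is populated as well.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty manifest file") from exc
    if id_column not in df.columns:
        raise ValueError(
            f"{path}: identifier column {id_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    raw = df[id_column].dropna()
    ids = frozenset(raw)
    if not ids:
        raise ValueError(f"{path}: no marker identifiers in column {id_column!r}")
    positions = None
    if chrom_column and pos_column:
        if chrom_column not in df.columns or pos_column not in df.columns:
            raise ValueError(f"{path}: position columns not found")
        pos_df = df[[chrom_column, pos_column]].dropna()
        positions = frozenset(
            (str(c), int(p)) for c, p in zip(pos_df[chrom_column], pos_df[pos_column])
        )
    return ArrayManifest(platform_name, ids, positions)


def read_id_list(path: str | os.PathLike) -> frozenset[str]:
    """Plain-text marker-ID list, one per line (e.g. imputable-SNP lists)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
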