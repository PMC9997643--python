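"""Per-site Weir–Cockerham FST and per-group minor-allele frequencies.

The FST estimator is the two-level per-locus variance-component form for
r sampled populations: with ``n_i`` called diploids, allele frequency
``p_i`` and observed heterozygosity ``h_i`` in population i,

    nbar = mean(n_i)                    nc = (r*nbar - sum(n_i^2)/(r*nbar)) / (r-1)
    pbar = sum(n_i p_i) / (r*nbar)      S2 = sum(n_i (p_i - pbar)^2) / ((r-1)*nbar)
    hbar = sum(n_i h_i) / (r*nbar)

    a = (nbar/nc) * [S2 - (pbar(1-pbar) - ((r-1)/r) S2 - hbar/4) / (nbar-1)]
    b = (nbar/(nbar-1)) * [pbar(1-pbar) - ((r-1)/r) S2 - ((2 nbar - 1)/(4 nbar)) hbar]
    c = hbar / 2

    fst = a / (a + b + c)

Per-site estimates are left unclamped (negative values allowed); a site
is undefined when ``a + b + c == 0`` (monomorphic) or a group has no
called genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix

__all__ = ["FstRecord", "weir_fst", "weighted_fst", "maf"]

log = logging.getLogger(__name__)


@dataclass
class FstRecord:
    variant_id: str
    chrom: str
    pos: int
    a: float
    b: float
    c: float
    fst: float  # NaN when undefined
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float


def _group_stats(
    g: GenotypeMatrix, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, p_alt, h_obs) per variant for one diploid group."""
    sub = g.alleles[idx]  # (n, M, 2)
    diploid = g.ploidy[idx] == 2
    called = (sub[:, :, 0] >= 0) & diploid
    n = called.sum(axis=0).astype(float)
    alt = ((sub == 1).sum(axis=2)) * called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt.sum(axis=0) / (2.0 * n)
        het = (((sub[:, :, 0] != sub[:, :, 1]) & called).sum(axis=0)) / n
    return n, p, het


def weir_fst(
    g: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    biallelic_only: bool = True,
    autosomes_only: bool = True,
) -> list[FstRecord]:
    """Per-site Weir–Cockerham FST across >= 2 groups.

    With the default flags, multiallelic and non-autosomal variants are
    skipped (counts logged). Haploid calls are excluded from the estimator,
    which is defined for diploid samples.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    keep = np.ones(g.n_variants, dtype=bool)
    n_multi = n_nonauto = 0
    for i, v in enumerate(g.variants):
        if biallelic_only and not v.is_biallelic:
            keep[i] = False
            n_multi += 1
        elif autosomes_only and not v.is_autosomal:
            keep[i] = False
            n_nonauto += 1
    if n_multi or n_nonauto:
        log.info(
            "weir_fst: skipped %d multiallelic and %d non-autosomal variants",
            n_multi,
            n_nonauto,
        )
    v_idx = np.flatnonzero(keep)
    sub = g.subset(variant_idx=v_idx)

    r = len(groups)
    stats = [
        _group_stats(sub, sub.sample_indices(members))
        for members in groups.values()
    ]
    n = np.stack([s[0] for s in stats])  # (r, M)
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])

    defined = (n > 0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n.mean(axis=0)
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
        denom = a + b + c
        fst = np.where(defined & (denom != 0), a / denom, np.nan)
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    n_undef = int(np.isnan(fst).sum())
    if n_undef:
        log.info("weir_fst: %d of %d sites undefined", n_undef, sub.n_variants)

    return [
        FstRecord(
            variant_id=v.id,
            chrom=v.chrom,
            pos=v.pos,
            a=float(a[j]),
            b=float(b[j]),
            c=float(c[j]),
            fst=float(fst[j]),
            n_bar=float(n_bar[j]),
            n_c=float(n_c[j]),
            p_bar=float(p_bar[j]),
            s2=float(s2[j]),
            h_bar=float(h_bar[j]),
        )
        for j, v in enumerate(sub.variants)
    ]


def weighted_fst(records: Sequence[FstRecord]) -> float:
    """Genome-wide ratio-of-sums summary: sum(a) / sum(a + b + c)."""
    a = np.array([r.a for r in records])
    tot = np.array([r.a + r.b + r.c for r in records])
    ok = ~np.isnan(tot)
    denom = tot[ok].sum()
    return float(a[ok].sum() / denom) if denom != 0 else float("nan")


def fst_frame(records: Sequence[FstRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "id": [r.variant_id for r in records],
            "a": [r.a for r in records],
            "b": [r.b for r in records],
            "c": [r.c for r in records],
            "fst": [r.fst for r in records],
        }
    )


def maf(
    g: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    designate_by: str | None = None,
) -> pd.DataFrame:
    """Per-group frequency of the designated minor allele at biallelic sites.

    The minor allele is designated by pooled frequency across all groups
    (default) or within the single group named by ``designate_by``; ties at
    0.5 resolve to the alt allele. Per-group frequencies of the designated
    allele may exceed 0.5 — designation is shared so groups are comparable.
    """
    for i, v in enumerate(g.variants):
        if not v.is_biallelic:
            raise ValueError(f"maf requires biallelic sites; {v.id} has {v.n_alleles}")
    labels = list(groups)
    counts = {}
    for label in labels:
        idx = g.sample_indices(groups[label])
        counts[label] = g.allele_counts(idx)[:, :2].astype(float)  # (M, 2)
    if designate_by is None:
        pooled = sum(counts.values())
    else:
        if designate_by not in counts:
            raise KeyError(f"unknown designation group {designate_by!r}")
        pooled = counts[designate_by]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt_pool = pooled[:, 1] / pooled.sum(axis=1)
    # minor allele index: alt (1) when p_alt <= 0.5 (tie -> alt), else ref
    minor = np.where(np.nan_to_num(p_alt_pool, nan=0.0) <= 0.5, 1, 0)
    data: dict[str, object] = {
        "chrom": [v.chrom for v in g.variants],
        "pos": [v.pos for v in g.variants],
        "id": [v.id for v in g.variants],
        "minor_allele": [
            (v.alts[0] if m == 1 else v.ref) for v, m in zip(g.variants, minor)
        ],
    }
    rows = np.arange(g.n_variants)
    for label in labels:
        cnt = counts[label]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = cnt[rows, minor] / cnt.sum(axis=1)
        data[label] = np.nan_to_num(freq, nan=0.0)
    df = pd.DataFrame(data)
    df.attrs["designation"] = designate_by or "pooled"
    return df
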