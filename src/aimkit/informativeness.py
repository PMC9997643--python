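"""Per-group allele frequencies and the informativeness-for-assignment
statistic.

For K groups with allele-frequency vectors ``p_i`` over J alleles the
statistic is

    In = sum_j ( -pbar_j * ln(pbar_j) + (1/K) * sum_i p_ij * ln(p_ij) )

with ``0 * ln 0 = 0`` and ``pbar_j`` the *unweighted* mean of ``p_ij``
across groups. It is measured in nats, is zero iff every group shares the
same frequency vector, and is bounded above by ``ln K``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix

__all__ = [
    "FrequencyTable",
    "InScore",
    "estimate_frequencies",
    "informativeness_in",
    "compute_in",
    "pooled_grouping",
]


@dataclass
class FrequencyTable:
    """Allele frequencies for one variant across K groups."""

    variant_id: str
    groups: tuple[str, ...]
    p: np.ndarray  # (K, J), rows sum to 1 where n_called > 0
    n_called: np.ndarray  # (K,) counted allele copies per group
    insufficient: bool = False

    @property
    def p_bar(self) -> np.ndarray:
        """Unweighted across-group mean frequency per allele."""
        return self.p.mean(axis=0)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class InScore:
    variant_id: str
    value: float
    groups: tuple[str, ...]
    insufficient: bool = False


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with the 0*ln(0) = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def _in_from_p(p: np.ndarray) -> np.ndarray:
    """Vectorized statistic for a (K, J, ...) frequency stack."""
    p_bar = p.mean(axis=0)
    return (-_xlogx(p_bar) + _xlogx(p).mean(axis=0)).sum(axis=0)


def group_allele_counts(
    g: GenotypeMatrix, grouping: Mapping[str, Sequence[str]]
) -> dict[str, np.ndarray]:
    """Allele-copy counts per group: label -> (n_variants, J_max)."""
    _check_grouping(grouping)
    return {
        label: g.allele_counts(g.sample_indices(members))
        for label, members in grouping.items()
    }


def _check_grouping(grouping: Mapping[str, Sequence[str]]) -> None:
    if not grouping:
        raise ValueError("at least one group required")
    seen: set[str] = set()
    for label, members in grouping.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {label!r} is empty")
        overlap = seen.intersection(members)
        if overlap:
            raise ValueError(f"groups overlap on samples {sorted(overlap)[:5]}")
        seen.update(members)


def estimate_frequencies(
    g: GenotypeMatrix,
    grouping: Mapping[str, Sequence[str]],
    min_called: int = 1,
) -> list[FrequencyTable]:
    """Per-variant allele frequencies for each group.

    Missing allele copies are excluded from denominators; a variant is
    flagged ``insufficient`` when any group has fewer than ``min_called``
    counted allele copies.
    """
    counts = group_allele_counts(g, grouping)
    labels = tuple(grouping)
    tables: list[FrequencyTable] = []
    for v_idx, variant in enumerate(g.variants):
        j = variant.n_alleles
        k = len(labels)
        p = np.zeros((k, j))
        n_called = np.zeros(k, dtype=np.int64)
        for i, label in enumerate(labels):
            row = counts[label][v_idx, :j]
            n = int(row.sum())
            n_called[i] = n
            if n > 0:
                p[i] = row / n
        tables.append(
            FrequencyTable(
                variant_id=variant.id,
                groups=labels,
                p=p,
                n_called=n_called,
                insufficient=bool((n_called < min_called).any()),
            )
        )
    return tables


def informativeness_in(f: FrequencyTable) -> InScore:
    """Informativeness-for-assignment of one frequency table (nats)."""
    if f.insufficient:
        return InScore(f.variant_id, float("nan"), f.groups, insufficient=True)
    value = float(_in_from_p(f.p[:, :, None])[0])
    # clip away -0.0 / tiny negative round-off on identical rows
    if value < 0 and value > -1e-12:
        value = 0.0
    return InScore(f.variant_id, value, f.groups)


def pooled_grouping(
    grouping: Mapping[str, Sequence[str]],
    pools: Mapping[str, Sequence[str]],
) -> dict[str, list[str]]:
    """Merge population groups into pooled super-groups.

    ``pools`` maps a pooled label to the population labels it absorbs.
    Pooling happens before frequency estimation, so pooled frequencies are
    allele-count (sample-size) weighted within each pool.
    """
    out: dict[str, list[str]] = {}
    for pooled, members in pools.items():
        samples: list[str] = []
        for pop in members:
            if pop not in grouping:
                raise KeyError(f"population {pop!r} not in grouping")
            samples.extend(grouping[pop])
        out[pooled] = samples
    return out


def compute_in(
    g: GenotypeMatrix,
    grouping: Mapping[str, Sequence[str]],
    min_called: int = 1,
) -> pd.DataFrame:
    """Vectorized per-variant informativeness over the whole matrix.

    Returns a frame with columns ``chrom, pos, id, in_score, insufficient``
    in file variant order.
    """
    counts = group_allele_counts(g, grouping)
    labels = tuple(grouping)
    k = len(labels)
    j_max = next(iter(counts.values())).shape[1]
    stack = np.stack([counts[label] for label in labels])  # (K, M, J)
    n_called = stack.sum(axis=2)  # (K, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stack / n_called[:, :, None]
    p = np.nan_to_num(p)
    values = _in_from_p(np.moveaxis(p, 2, 1))  # -> (K, J, M) then sum
    values = np.where(values < 0, np.where(values > -1e-12, 0.0, values), values)
    insufficient = (n_called < min_called).any(axis=0)
    values = np.where(insufficient, np.nan, values)
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in g.variants],
            "pos": [v.pos for v in g.variants],
            "id": [v.id for v in g.variants],
            "in_score": values,
            "insufficient": insufficient,
        }
    )
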