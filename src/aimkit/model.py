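"""Core data structures shared by every stage of the toolkit.

The genotype substrate is a dense samples x variants array of allele
indices; group membership is carried separately by :class:`SamplePanel`
so the same matrix can be sliced by any population scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "SamplePanel",
    "ArrayManifest",
    "MISSING",
]

#: Sentinel allele index for a missing allele copy (also fills the second
#: slot of haploid calls; the ``ploidy`` array disambiguates).
MISSING: int = -1

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return _norm_chrom(chrom) in AUTOSOMES


@dataclass(frozen=True)
class VariantRecord:
    """A single variant site: coordinates plus its allele inventory."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if not self.alts:
            raise ValueError("at least one alt allele required")
        if any(not a for a in self.alts):
            raise ValueError("alt alleles must be non-empty")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"duplicate alt alleles at {self.chrom}:{self.pos}")
        if self.ref in self.alts:
            raise ValueError(f"ref allele repeated in alts at {self.chrom}:{self.pos}")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_biallelic(self) -> bool:
        return self.n_alleles == 2

    @property
    def is_autosomal(self) -> bool:
        return is_autosome(self.chrom)

    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        """Identity used for panel intersection: position + alleles.

        Positions are stabler than rsIDs across annotation dialects, so the
        rsID is metadata rather than part of the key.
        """
        return (_norm_chrom(self.chrom), self.pos, self.ref, tuple(sorted(self.alts)))


class GenotypeMatrix:
    """Dense allele-index calls for ``samples x variants``.

    Parameters
    ----------
    variants
        Ordered variant records (file order is preserved by readers).
    samples
        Ordered sample identifiers.
    alleles
        ``(n_samples, n_variants, 2)`` integer array of allele indices;
        ``MISSING`` marks an absent allele copy. Haploid calls put their
        single allele in slot 0 and ``MISSING`` in slot 1.
    ploidy
        ``(n_samples, n_variants)`` array in {1, 2}; defaults to all-diploid.
    phased
        ``(n_samples, n_variants)`` bool array recording the GT separator
        so writers can round-trip ``|`` vs ``/``.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        alleles: np.ndarray,
        ploidy: np.ndarray | None = None,
        phased: np.ndarray | None = None,
    ) -> None:
        self.variants = list(variants)
        self.samples = list(samples)
        alleles = np.asarray(alleles, dtype=np.int16)
        if alleles.shape != (len(self.samples), len(self.variants), 2):
            raise ValueError(
                f"alleles shape {alleles.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.alleles = alleles
        n_s, n_v = len(self.samples), len(self.variants)
        if ploidy is None:
            ploidy = np.full((n_s, n_v), 2, dtype=np.uint8)
        if phased is None:
            phased = np.zeros((n_s, n_v), dtype=bool)
        self.ploidy = np.asarray(ploidy, dtype=np.uint8)
        self.phased = np.asarray(phased, dtype=bool)
        if self.ploidy.shape != (n_s, n_v) or self.phased.shape != (n_s, n_v):
            raise ValueError("ploidy/phased shape mismatch")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        if len(self._sample_index) != n_s:
            raise ValueError("duplicate sample identifiers")
        max_allele = np.array([v.n_alleles for v in self.variants], dtype=np.int16)
        if n_v and ((self.alleles >= max_allele[None, :, None]).any()):
            raise ValueError("allele index exceeds variant allele count")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def subset(
        self,
        samples: Sequence[str] | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        s_idx = (
            np.arange(self.n_samples)
            if samples is None
            else self.sample_indices(samples)
        )
        v_idx = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=np.intp)
        )
        return GenotypeMatrix(
            [self.variants[i] for i in v_idx],
            [self.samples[i] for i in s_idx],
            self.alleles[np.ix_(s_idx, v_idx)],
            self.ploidy[np.ix_(s_idx, v_idx)],
            self.phased[np.ix_(s_idx, v_idx)],
        )

    # -- counting -------------------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-variant allele-copy counts ``(n_variants, max_alleles)``.

        Missing copies are excluded, so the row sum equals
        ``2 * diploid_called + 1 * haploid_called`` for each variant.
        """
        if sample_idx is None:
            sub = self.alleles
        else:
            sub = self.alleles[np.asarray(sample_idx, dtype=np.intp)]
        n_v = self.n_variants
        j_max = max((v.n_alleles for v in self.variants), default=2)
        counts = np.zeros((n_v, j_max), dtype=np.int64)
        col = np.broadcast_to(np.arange(n_v), sub.shape[:2])
        for slot in (0, 1):
            a = sub[:, :, slot]
            ok = a >= 0
            np.add.at(counts, (col[ok], a[ok].astype(np.intp)), 1)
        return counts

    def dosage(self, alt_index: int = 1) -> np.ndarray:
        """Alt-allele dosage matrix ``(n_samples, n_variants)`` as float;
        missing calls are NaN. Intended for biallelic sites."""
        d = (self.alleles == alt_index).sum(axis=2).astype(float)
        d[self.alleles[:, :, 0] == MISSING] = np.nan
        return d

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a non-missing call, per variant."""
        called = self.alleles[:, :, 0] != MISSING
        return called.mean(axis=0) if self.n_samples else np.zeros(self.n_variants)

    def variant_keys(self) -> list[tuple]:
        return [v.key() for v in self.variants]

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.ploidy, other.ploidy)
            and np.array_equal(self.phased, other.phased)
        )


@dataclass
class SamplePanel:
    """Sample -> (population, super-population) mapping."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sample, (pop, spop) in self.entries.items():
            if pop in seen and seen[pop] != spop:
                raise ValueError(
                    f"population {pop!r} mapped to both {seen[pop]!r} and {spop!r}"
                )
            seen[pop] = spop

    def populations(self) -> list[str]:
        return sorted({pop for pop, _ in self.entries.values()})

    def super_populations(self) -> list[str]:
        return sorted({spop for _, spop in self.entries.values()})

    def members(self, pop: str) -> list[str]:
        """Samples in a population or super-population code."""
        out = [
            s for s, (p, sp) in self.entries.items() if p == pop or sp == pop
        ]
        if not out:
            raise KeyError(f"no samples for population {pop!r}")
        return out

    def population_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def grouping(self, pops: Sequence[str]) -> dict[str, list[str]]:
        return {p: self.members(p) for p in pops}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sample: str) -> bool:
        return sample in self.entries


@dataclass
class ArrayManifest:
    """Marker inventory of one genotyping platform."""

    platform_name: str
    marker_ids: frozenset[str]
    positions: frozenset[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError(f"manifest {self.platform_name!r} has no markers")

    def __len__(self) -> int:
        return len(self.marker_ids)


def validate_panel_coverage(
    g: GenotypeMatrix, panel: SamplePanel
) -> list[str]:
    """Samples present in the genotype matrix but absent from the panel."""
    return [s for s in g.samples if s not in panel]
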