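"""Synthetic genotype datasets with known population structure.

Population allele frequencies diverge from a shared ancestral frequency
under the Balding–Nichols model: for ancestral frequency ``p0`` and drift
parameter ``F``, each population draws

    p ~ Beta(p0 * (1 - F) / F,  (1 - p0) * (1 - F) / F)

which has mean ``p0`` and yields an expected FST of roughly ``F``.
Diploid genotypes are Binomial(2, p). Admixed individuals draw each of
their two allele copies from a source population chosen by their ancestry
proportion vector, then Bernoulli from that population's frequency.
A configurable subset of markers is "spiked" with fixed per-population
target frequencies to act as ground-truth ancestry-informative loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, SamplePanel, VariantRecord
from .vcfio import write_panel, write_vcf

__all__ = [
    "PopulationSpec",
    "AdmixedSpec",
    "SpikeSpec",
    "SimulationConfig",
    "TruthSet",
    "simulate",
    "write_fixture",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n: int
    f: float = 0.1  # Balding–Nichols drift parameter
    super_pop: str = "SIM"

    def __post_init__(self) -> None:
        if not (0 <= self.f < 1):
            raise ValueError(f"drift F must be in [0, 1), got {self.f}")
        if self.n < 0:
            raise ValueError("population size must be >= 0")


@dataclass(frozen=True)
class AdmixedSpec:
    label: str
    n: int
    alpha: tuple[float, ...]  # ancestry proportions over source populations
    super_pop: str = "ADM"

    def __post_init__(self) -> None:
        if abs(sum(self.alpha) - 1.0) > 1e-9:
            raise ValueError("ancestry proportions must sum to 1")
        if any(a < 0 for a in self.alpha):
            raise ValueError("ancestry proportions must be non-negative")


@dataclass(frozen=True)
class SpikeSpec:
    count: int
    freqs: Mapping[str, float]  # population label -> fixed target frequency

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("spike count must be >= 0")
        for label, p in self.freqs.items():
            if not (0 <= p <= 1):
                raise ValueError(f"spike frequency for {label!r} out of [0,1]")


@dataclass
class SimulationConfig:
    populations: tuple[PopulationSpec, ...]
    n_markers: int
    seed: int
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    spike: SpikeSpec | None = None
    admixed: tuple[AdmixedSpec, ...] = ()
    n_chromosomes: int = 1
    chrom_length: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("need at least one marker")
        if self.spike is not None and self.spike.count > self.n_markers:
            raise ValueError("spike count exceeds marker count")
        lo, hi = self.ancestral_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("ancestral_range must satisfy 0 <= lo < hi <= 1")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for adm in self.admixed:
            if len(adm.alpha) != len(self.populations):
                raise ValueError(
                    f"admixed group {adm.label!r}: alpha length must equal "
                    f"the number of source populations"
                )


@dataclass
class TruthSet:
    spiked_ids: tuple[str, ...]
    spiked_keys: tuple[tuple, ...]
    pop_freqs: pd.DataFrame  # variant id x population true frequencies
    ancestry: pd.DataFrame  # sample x source-population ancestry proportions

    def to_files(self, outdir: Path) -> dict[str, Path]:
        freq_path = outdir / "truth_freqs.tsv"
        anc_path = outdir / "truth_ancestry.tsv"
        self.pop_freqs.to_csv(freq_path, sep="\t", index=False)
        self.ancestry.to_csv(anc_path, sep="\t", index=False)
        return {"freqs": freq_path, "ancestry": anc_path}


def _balding_nichols(
    rng: np.random.Generator, p0: np.ndarray, f: float
) -> np.ndarray:
    if f == 0:
        return p0.copy()
    ratio = (1.0 - f) / f
    return rng.beta(p0 * ratio, (1.0 - p0) * ratio)


def _draw_ancestral(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    p0 = rng.uniform(lo, hi, size=n)
    # degenerate Beta parameters are impossible for p0 in (0,1); resample
    # boundary draws defensively when the range touches 0 or 1
    bad = (p0 <= 0) | (p0 >= 1)
    while bad.any():
        p0[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        bad = (p0 <= 0) | (p0 >= 1)
    return p0


def simulate(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SamplePanel, TruthSet]:
    """Generate genotypes, a sample panel, and the ground-truth record.

    Deterministic given ``cfg.seed``; spiked markers use their target
    frequencies verbatim (no Beta draw).
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers
    k = len(cfg.populations)
    lo, hi = cfg.ancestral_range

    p0 = _draw_ancestral(rng, m, lo, hi)
    pop_freq = np.stack(
        [_balding_nichols(rng, p0, spec.f) for spec in cfg.populations]
    )  # (K, M)

    spiked_idx = np.array([], dtype=np.intp)
    if cfg.spike is not None and cfg.spike.count:
        spiked_idx = np.sort(
            rng.choice(m, size=cfg.spike.count, replace=False)
        ).astype(np.intp)
        for i, spec in enumerate(cfg.populations):
            if spec.label in cfg.spike.freqs:
                pop_freq[i, spiked_idx] = cfg.spike.freqs[spec.label]

    # variant scaffold: markers spread evenly over chromosomes, sorted
    # unique positions per chromosome
    variants: list[VariantRecord] = []
    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    serial = 0
    for c, idx in enumerate(per_chrom, start=1):
        if idx.size == 0:
            continue
        pos = np.sort(rng.choice(cfg.chrom_length, size=idx.size, replace=False)) + 1
        for p in pos:
            serial += 1
            ref, alt = rng.choice(4, size=2, replace=False)
            variants.append(
                VariantRecord(
                    chrom=str(c),
                    pos=int(p),
                    id=f"rs{1_000_000 + serial}",
                    ref=_BASES[ref],
                    alts=(_BASES[alt],),
                )
            )
    # markers were assigned to chromosomes in index order; keep pop_freq
    # aligned with the (chromosome-major, position-sorted) variant order
    order = np.concatenate([idx for idx in per_chrom if idx.size])
    pop_freq = pop_freq[:, order]
    spike_mask = np.zeros(m, dtype=bool)
    spike_mask[spiked_idx] = True
    spike_mask = spike_mask[order]

    samples: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    blocks: list[np.ndarray] = []
    anc_rows: list[dict] = []
    src_labels = [spec.label for spec in cfg.populations]

    for i, spec in enumerate(cfg.populations):
        copies = (rng.random((spec.n, m, 2)) < pop_freq[i][None, :, None]).astype(
            np.int16
        )
        blocks.append(copies)
        for s in range(spec.n):
            name = f"{spec.label}_{s:04d}"
            samples.append(name)
            entries[name] = (spec.label, spec.super_pop)
            anc_rows.append(
                {"sample": name, **{lb: float(lb == spec.label) for lb in src_labels}}
            )

    for adm in cfg.admixed:
        alpha = np.asarray(adm.alpha)
        anc = rng.choice(k, size=(adm.n, m, 2), p=alpha)
        p_draw = pop_freq[anc, np.arange(m)[None, :, None]]
        copies = (rng.random((adm.n, m, 2)) < p_draw).astype(np.int16)
        blocks.append(copies)
        for s in range(adm.n):
            name = f"{adm.label}_{s:04d}"
            samples.append(name)
            entries[name] = (adm.label, adm.super_pop)
            anc_rows.append(
                {"sample": name, **dict(zip(src_labels, map(float, alpha)))}
            )

    alleles = (
        np.concatenate(blocks, axis=0)
        if blocks
        else np.zeros((0, m, 2), dtype=np.int16)
    )
    g = GenotypeMatrix(variants, samples, alleles)
    panel = SamplePanel(entries)

    ids = [v.id for v in variants]
    truth = TruthSet(
        spiked_ids=tuple(np.array(ids)[spike_mask]),
        spiked_keys=tuple(
            v.key() for v, sp in zip(variants, spike_mask) if sp
        ),
        pop_freqs=pd.DataFrame(
            {
                "id": ids,
                "spiked": spike_mask,
                **{lb: pop_freq[i] for i, lb in enumerate(src_labels)},
            }
        ),
        ancestry=pd.DataFrame(anc_rows),
    )
    return g, panel, truth


def write_fixture(
    g: GenotypeMatrix,
    panel: SamplePanel,
    truth: TruthSet | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write VCF + panel (+ truth TSVs) so any stage can be re-run from disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(g, outdir / "simulated.vcf"),
        "panel": write_panel(panel, outdir / "samples.panel"),
    }
    if truth is not None:
        paths.update(truth.to_files(outdir))
    return paths
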