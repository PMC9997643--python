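"""Build AIM panels: population subset schemes, score thresholding, and
subset intersection.

The default scheme compares every leave-one-out combination of the
ancestral-side populations (plus the full set) against a pooled reference
side, thresholds the per-variant informativeness at tau, and intersects
the per-subset marker sets so that markers informative for only a single
subpopulation are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .informativeness import compute_in, pooled_grouping
from .model import GenotypeMatrix, SamplePanel, VariantRecord

__all__ = [
    "PanelConfig",
    "AimsPanel",
    "build_subsets",
    "threshold_scores",
    "intersect_panels",
    "build_panel",
]

DEFAULT_AFR = ("GWD", "ESN", "LWK", "MSL", "YRI")
DEFAULT_EUR = ("CEU", "FIN", "GBR", "IBS", "TSI")


@dataclass
class PanelConfig:
    """Configuration of the subset scheme and threshold."""

    afr_populations: tuple[str, ...] = DEFAULT_AFR
    eur_populations: tuple[str, ...] = DEFAULT_EUR
    subsets: tuple[tuple[str, ...], ...] | None = None  # None -> default scheme
    threshold: float = 0.25
    restrict_to: str | None = None  # optional chromosome filter
    pool_afr: bool = True  # K=2 pooled mode vs per-population groups
    min_called: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.subsets is not None:
            known = set(self.afr_populations)
            for sub in self.subsets:
                if not sub:
                    raise ValueError("empty subset in scheme")
                bad = set(sub) - known
                if bad:
                    raise ValueError(f"subset uses unknown populations {sorted(bad)}")


def build_subsets(cfg: PanelConfig) -> list[tuple[str, tuple[str, ...]]]:
    """Labelled population subsets for the configured scheme.

    Default: for n populations, the n leave-one-out subsets (dropping the
    1st, 2nd, ... population in order) followed by the full set, labelled
    ``AFR-S1 .. AFR-S{n+1}``. An explicit ``cfg.subsets`` list overrides
    the default.
    """
    pops = tuple(cfg.afr_populations)
    if cfg.subsets is not None:
        return [
            (f"AFR-S{i + 1}", tuple(sub)) for i, sub in enumerate(cfg.subsets)
        ]
    if len(pops) < 2:
        raise ValueError("default scheme needs >= 2 populations")
    subsets = [tuple(p for p in pops if p != drop) for drop in pops]
    subsets.append(pops)
    return [(f"AFR-S{i + 1}", sub) for i, sub in enumerate(subsets)]


def threshold_scores(scores: Mapping, tau: float) -> set:
    """Markers whose score passes the (inclusive) threshold."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return {k for k, v in scores.items() if v == v and v >= tau}


@dataclass
class AimsPanel:
    """Per-subset marker sets, their scores, and the intersection panel."""

    subset_labels: tuple[str, ...]
    subset_members: dict[str, tuple[str, ...]]
    subset_sets: dict[str, set]
    subset_scores: dict[str, dict]
    intersection: set
    variants: dict = field(default_factory=dict)  # key -> VariantRecord

    @property
    def subset_sizes(self) -> dict[str, int]:
        return {label: len(s) for label, s in self.subset_sets.items()}

    def summary(self) -> dict:
        return {
            "subset_sizes": self.subset_sizes,
            "intersection_size": len(self.intersection),
        }

    # -- exports --------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        keys = sorted(
            {k for s in self.subset_sets.values() for k in s},
            key=lambda k: (k[0], k[1]),
        )
        rows = []
        for key in keys:
            var: VariantRecord | None = self.variants.get(key)
            row = {
                "chrom": key[0],
                "pos": key[1],
                "id": var.id if var else ".",
                "ref": key[2],
                "alts": ",".join(key[3]),
            }
            for label in self.subset_labels:
                row[f"in_{label}"] = self.subset_scores[label].get(key)
            row["in_final_panel"] = key in self.intersection
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")
        return path

    def write_rsids(self, path: str | Path) -> Path:
        path = Path(path)
        ids = sorted(
            self.variants[k].id for k in self.intersection if k in self.variants
        )
        path.write_text("\n".join(ids) + ("\n" if ids else ""))
        return path

    def write_bed(self, path: str | Path) -> Path:
        """0-based half-open BED of the final panel."""
        path = Path(path)
        rows = sorted((k[0], k[1] - 1, k[1]) for k in self.intersection)
        lines = [f"{c}\t{s}\t{e}" for c, s, e in rows]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path


def intersect_panels(
    sets: Sequence[set],
    labels: Sequence[str] | None = None,
    scores: Sequence[Mapping] | None = None,
    variants: Mapping | None = None,
    members: Mapping[str, tuple[str, ...]] | None = None,
) -> AimsPanel:
    """Intersect per-subset marker sets into the final panel.

    Order-independent and deterministic; a single set intersects to
    itself.
    """
    sets = [set(s) for s in sets]
    if not sets:
        raise ValueError("at least one marker set required")
    if labels is None:
        labels = tuple(f"S{i + 1}" for i in range(len(sets)))
    inter = set.intersection(*sets)
    return AimsPanel(
        subset_labels=tuple(labels),
        subset_members=dict(members or {lb: () for lb in labels}),
        subset_sets=dict(zip(labels, sets)),
        subset_scores=(
            {lb: dict(sc) for lb, sc in zip(labels, scores)}
            if scores is not None
            else {lb: {} for lb in labels}
        ),
        intersection=inter,
        variants=dict(variants or {}),
    )


def build_panel(
    g: GenotypeMatrix,
    panel: SamplePanel,
    cfg: PanelConfig | None = None,
) -> AimsPanel:
    """End-to-end panel construction from genotypes + population panel.

    For each configured subset, the subset populations (pooled by default)
    are compared against the pooled reference side; scores are thresholded
    at ``cfg.threshold`` (inclusive) and the per-subset sets intersected.
    """
    cfg = cfg or PanelConfig()
    if cfg.restrict_to is not None:
        keep = [
            i for i, v in enumerate(g.variants) if v.chrom == cfg.restrict_to
        ]
        g = g.subset(variant_idx=keep)
    keys = g.variant_keys()
    var_by_key = dict(zip(keys, g.variants))
    pop_samples = {
        p: panel.members(p) for p in (*cfg.afr_populations, *cfg.eur_populations)
    }
    eur_pool = pooled_grouping(pop_samples, {"EUR": cfg.eur_populations})

    subsets = build_subsets(cfg)
    subset_sets: list[set] = []
    subset_scores: list[dict] = []
    for label, pops in subsets:
        if cfg.pool_afr:
            grouping = pooled_grouping(pop_samples, {label: pops})
        else:
            grouping = {p: pop_samples[p] for p in pops}
        grouping.update(eur_pool)
        frame = compute_in(g, grouping, min_called=cfg.min_called)
        scores = dict(zip(keys, frame["in_score"].to_numpy()))
        subset_scores.append(scores)
        subset_sets.append(threshold_scores(scores, cfg.threshold))

    return intersect_panels(
        subset_sets,
        labels=[label for label, _ in subsets],
        scores=subset_scores,
        variants=var_by_key,
        members={label: pops for label, pops in subsets},
    )
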