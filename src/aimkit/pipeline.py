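"""End-to-end orchestration: simulate/ingest -> informativeness -> panel
-> FST / PCA / annotation / overlap, driven by one structured config.

Every stage records its parameters, input hashes and output files in a
machine-readable run manifest; reruns with an identical config and seed
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate as ann
from . import vcfio
from .model import GenotypeMatrix, SamplePanel
from .panel import AimsPanel, PanelConfig, build_panel
from .pca import PruneConfig, ld_prune, pca
from .popgen import fst_frame, maf, weighted_fst, weir_fst
from .simulate import (
    AdmixedSpec,
    PopulationSpec,
    SimulationConfig,
    SpikeSpec,
    simulate,
    write_fixture,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    # exactly one of the two input modes
    inputs: dict[str, Any] | None = None  # vcf, panel, gene_model?, manifests?...
    simulation: SimulationConfig | None = None
    panel_config: PanelConfig = field(default_factory=PanelConfig)
    prune_config: PruneConfig = field(default_factory=PruneConfig)
    window_config: ann.WindowConfig = field(default_factory=ann.WindowConfig)
    n_components: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of 'inputs' or 'simulation' must be configured"
            )
        self.outdir = Path(self.outdir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.stages: list[dict] = []

    def record(self, name: str, params: dict, inputs: list[Path], outputs: list[Path]):
        self.stages.append(
            {
                "stage": name,
                "params": params,
                "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
                "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
            }
        )

    def write(self) -> Path:
        path = self.outdir / "run_manifest.json"
        path.write_text(json.dumps({"stages": self.stages}, indent=2) + "\n")
        return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in dependency order.

    Returns the manifest dict. On stage failure a :class:`PipelineError`
    naming the stage is raised; outputs written so far stay on disk next
    to a ``<stage>.partial`` marker.
    """
    logging.basicConfig(level=cfg.log_level)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg.outdir)
    t0 = time.time()
    stage = "setup"
    try:
        # -- stage: acquire genotypes ----------------------------------
        if cfg.simulation is not None:
            stage = "simulate"
            g, panel, truth = simulate(cfg.simulation)
            paths = write_fixture(g, panel, truth, cfg.outdir)
            manifest.record(
                stage,
                {"seed": cfg.simulation.seed, "n_markers": cfg.simulation.n_markers},
                [],
                list(paths.values()),
            )
        else:
            stage = "load"
            vcf_path = Path(cfg.inputs["vcf"])
            panel_path = Path(cfg.inputs["panel"])
            g = vcfio.read_vcf(vcf_path)
            panel = vcfio.read_panel(panel_path)
            manifest.record(
                stage,
                {"vcf": str(vcf_path), "panel": str(panel_path)},
                [vcf_path, panel_path],
                [],
            )
        log.info("%s: %d samples x %d variants", stage, g.n_samples, g.n_variants)

        # -- stage: informativeness + panel ----------------------------
        stage = "build_panel"
        aims = build_panel(g, panel, cfg.panel_config)
        panel_tsv = aims.write_tsv(cfg.outdir / "aims_panel.tsv")
        rsid_txt = aims.write_rsids(cfg.outdir / "aims_panel.rsids.txt")
        bed = aims.write_bed(cfg.outdir / "aims_panel.bed")
        manifest.record(
            stage,
            {
                "threshold": cfg.panel_config.threshold,
                "subset_sizes": aims.subset_sizes,
                "intersection_size": len(aims.intersection),
            },
            [],
            [panel_tsv, rsid_txt, bed],
        )
        log.info(
            "build_panel: subsets %s -> intersection %d",
            aims.subset_sizes,
            len(aims.intersection),
        )

        aim_keys = aims.intersection
        aim_idx = [i for i, k in enumerate(g.variant_keys()) if k in aim_keys]
        g_aims = g.subset(variant_idx=aim_idx)

        # -- stage: FST + MAF on the panel -----------------------------
        stage = "fst"
        afr = cfg.panel_config.afr_populations
        eur = cfg.panel_config.eur_populations
        eur_samples = [s for p in eur for s in panel.members(p)]
        fst_paths = []
        for pop in afr:
            recs = weir_fst(
                g_aims, {pop: panel.members(pop), "EUR": eur_samples}
            )
            frame = fst_frame(recs)
            out = cfg.outdir / f"fst_{pop}_vs_EUR.tsv"
            frame.to_csv(out, sep="\t", index=False)
            fst_paths.append(out)
            log.info(
                "fst %s vs EUR: weighted %.4f over %d sites",
                pop,
                weighted_fst(recs),
                len(recs),
            )
        manifest.record(stage, {"populations": list(afr)}, [], fst_paths)

        stage = "maf"
        groups = {p: panel.members(p) for p in (*afr, *eur)}
        biallelic = [i for i, v in enumerate(g_aims.variants) if v.is_biallelic]
        maf_df = maf(g_aims.subset(variant_idx=biallelic), groups)
        maf_path = cfg.outdir / "maf_matrix.tsv"
        maf_df.to_csv(maf_path, sep="\t", index=False)
        manifest.record(stage, {"groups": list(groups)}, [], [maf_path])

        # -- stage: LD prune + PCA -------------------------------------
        stage = "pca"
        bial = g_aims.subset(variant_idx=biallelic)
        if bial.n_variants >= 2 and bial.n_samples >= 3:
            retained = ld_prune(bial, cfg.prune_config)
            k = min(cfg.n_components, bial.n_samples - 1, retained.size)
            result = pca(bial, retained, k=k)
            scores = result.scores
            score_df = pd.DataFrame(
                scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
            )
            score_df.insert(0, "sample", result.samples)
            score_df.insert(
                1, "population", [panel.entries.get(s, ("?", "?"))[0] for s in result.samples]
            )
            pca_path = cfg.outdir / "pca_scores.tsv"
            score_df.to_csv(pca_path, sep="\t", index=False)
            eig_df = pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(len(result.eigenvalues))],
                    "eigenvalue": result.eigenvalues,
                    "variance_fraction": result.variance_fraction,
                }
            )
            eig_path = cfg.outdir / "pca_eigenvalues.tsv"
            eig_df.to_csv(eig_path, sep="\t", index=False)
            manifest.record(
                stage,
                {"pruned_to": int(retained.size), "k": int(k), **vars(cfg.prune_config)},
                [],
                [pca_path, eig_path],
            )
        else:
            log.warning("pca: panel too small, stage skipped")
            manifest.record(stage, {"skipped": "panel too small"}, [], [])

        # -- stage: window density -------------------------------------
        stage = "window_density"
        if cfg.inputs and "chrom_lengths" in (cfg.inputs or {}):
            lengths = dict(cfg.inputs["chrom_lengths"])
        elif cfg.simulation is not None:
            lengths = {
                str(c): cfg.simulation.chrom_length
                for c in range(1, cfg.simulation.n_chromosomes + 1)
            }
        else:
            lengths = {
                c: max(v.pos for v in g_aims.variants if v.chrom == c)
                for c in {v.chrom for v in g_aims.variants}
            }
        dens = ann.window_density(g_aims.variants, cfg.window_config, lengths)
        dens_path = cfg.outdir / "window_density.tsv"
        dens.to_csv(dens_path, sep="\t", index=False)
        manifest.record(stage, {"window": cfg.window_config.length}, [], [dens_path])

        # -- optional stages -------------------------------------------
        if cfg.inputs and cfg.inputs.get("gene_model"):
            stage = "annotate"
            gm_path = Path(cfg.inputs["gene_model"])
            reader = (
                ann.read_gtf if gm_path.suffix.lower() == ".gtf" else ann.read_refgene
            )
            model = ann.GeneModel(reader(gm_path))
            calls = ann.classify_regions(g_aims.variants, model)
            call_df = pd.DataFrame(
                {
                    "id": [c.variant_id for c in calls],
                    "chrom": [c.chrom for c in calls],
                    "pos": [c.pos for c in calls],
                    "category": [c.category for c in calls],
                    "gene": [c.gene for c in calls],
                }
            )
            call_path = cfg.outdir / "region_calls.tsv"
            call_df.to_csv(call_path, sep="\t", index=False)
            manifest.record(stage, {"gene_model": str(gm_path)}, [gm_path], [call_path])

        if cfg.inputs and cfg.inputs.get("manifests"):
            stage = "overlap"
            manifests = [
                vcfio.read_manifest(m["path"], m["name"], **m.get("options", {}))
                for m in cfg.inputs["manifests"]
            ]
            imputable = (
                vcfio.read_id_list(cfg.inputs["imputable_ids"])
                if cfg.inputs.get("imputable_ids")
                else None
            )
            ids = [aims.variants[k].id for k in sorted(aims.intersection)]
            positions = [(k[0], k[1]) for k in sorted(aims.intersection)]
            report = ann.platform_overlap(ids, manifests, positions, imputable)
            ov_path = cfg.outdir / "platform_overlap.tsv"
            report.per_platform.to_csv(ov_path, sep="\t", index=False)
            manifest.record(
                stage,
                {
                    "panel_size": report.panel_size,
                    "union_count": report.union_count,
                    "imputable_count": report.imputable_count,
                },
                [],
                [ov_path],
            )
    except Exception as exc:
        (cfg.outdir / f"{stage}.partial").write_text(str(exc) + "\n")
        manifest.write()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = manifest.write()
    log.info("pipeline done in %.1fs -> %s", time.time() - t0, manifest_path)
    return {"stages": manifest.stages, "manifest_path": str(manifest_path)}


# ---------------------------------------------------------------------------
# config file loading


def _simulation_from_dict(d: dict, default_seed: int) -> SimulationConfig:
    pops = tuple(
        PopulationSpec(
            label=p["label"],
            n=int(p["n"]),
            f=float(p.get("f", 0.1)),
            super_pop=p.get("super_pop", "SIM"),
        )
        for p in d["populations"]
    )
    spike = None
    if d.get("spike"):
        spike = SpikeSpec(
            count=int(d["spike"]["count"]), freqs=dict(d["spike"]["freqs"])
        )
    admixed = tuple(
        AdmixedSpec(
            label=a["label"],
            n=int(a["n"]),
            alpha=tuple(float(x) for x in a["alpha"]),
            super_pop=a.get("super_pop", "ADM"),
        )
        for a in d.get("admixed", [])
    )
    return SimulationConfig(
        populations=pops,
        n_markers=int(d["n_markers"]),
        seed=int(d.get("seed", default_seed)),
        ancestral_range=tuple(d.get("ancestral_range", (0.05, 0.95))),
        spike=spike,
        admixed=admixed,
        n_chromosomes=int(d.get("n_chromosomes", 1)),
        chrom_length=int(d.get("chrom_length", 10_000_000)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seed = int(raw.get("seed", 0))
    sim = (
        _simulation_from_dict(raw["simulation"], seed)
        if raw.get("simulation")
        else None
    )
    panel_cfg = PanelConfig(**{
        k: (tuple(map(tuple, v)) if k == "subsets" and v is not None else
            tuple(v) if isinstance(v, list) else v)
        for k, v in raw.get("panel", {}).items()
    })
    prune_cfg = PruneConfig(**raw.get("prune", {}))
    window_cfg = ann.WindowConfig(**raw.get("window", {}))
    return RunConfig(
        outdir=Path(raw["outdir"]),
        seed=seed,
        inputs=raw.get("inputs"),
        simulation=sim,
        panel_config=panel_cfg,
        prune_config=prune_cfg,
        window_config=window_cfg,
        n_components=int(raw.get("n_components", 10)),
        log_level=raw.get("log_level", "INFO"),
    )
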