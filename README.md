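# aimkit

Toolkit for discovering and validating **ancestry-informative markers
(AIMs)** from multi-sample VCF genotype data.

The pipeline scores every variant with the informativeness-for-assignment
statistic (`In`, in nats) between combinations of ancestral-side
populations and a pooled reference group, thresholds the scores
(`In >= 0.25` by default), and intersects the per-combination marker sets
into a final panel. The panel is then validated with per-site
Weir–Cockerham FST, LD-pruned principal component analysis,
genomic-region annotation with Fisher-exact enrichment, per-window marker
density, and genotyping-array overlap reports. A Balding–Nichols genotype
simulator (with admixture and spiked ground-truth AIMs) makes every stage
testable without any external data.

## Package layout

| Module                  | Purpose                                                             |
| ----------------------- | ------------------------------------------------------------------- |
| `aimkit.model`          | `VariantRecord`, `GenotypeMatrix`, `SamplePanel`, `ArrayManifest`   |
| `aimkit.vcfio`          | VCF / sample-panel / manifest / ID-list readers and writers         |
| `aimkit.informativeness`| per-group allele frequencies and the `In` statistic                 |
| `aimkit.panel`          | subset schemes, thresholding, intersection, panel exports           |
| `aimkit.popgen`         | per-site Weir–Cockerham FST and minor-allele-frequency matrices     |
| `aimkit.pca`            | greedy windowed LD pruning and frequency-standardized PCA           |
| `aimkit.annotate`       | region classification, window density, exact tests, array overlap   |
| `aimkit.simulate`       | Balding–Nichols simulator with admixture and spiked AIMs            |
| `aimkit.pipeline`       | end-to-end orchestration with a hashed run manifest                 |

## CLI

All commands are available under a single entry point:

```bash
aimkit simulate    --config config.yaml
aimkit build-panel --vcf data.vcf --panel samples.panel \
                   --afr GWD,ESN,LWK,MSL,YRI --eur CEU,FIN,GBR,IBS,TSI \
                   --threshold 0.25 --out panel_out/
aimkit fst         --vcf data.vcf --panel samples.panel --pop YRI --out fst.tsv
aimkit pca         --vcf data.vcf --panel samples.panel --out scores.tsv
aimkit annotate    --vcf data.vcf --gene-model genes.txt --out regions.tsv
aimkit overlap     --panel-ids aims.txt --manifest OmniX=manifest.csv --out ov.tsv
aimkit run-all     --config config.yaml
```

Exit codes: `0` ok, `1` user error, `2` internal error.

An example `run-all` config:

```yaml
seed: 7
outdir: runs/demo
simulation:
  populations:
    - {label: AFR1, n: 50, f: 0.02, super_pop: AFR}
    - {label: AFR2, n: 50, f: 0.02, super_pop: AFR}
    - {label: EUR1, n: 50, f: 0.02, super_pop: EUR}
  n_markers: 1000
  spike: {count: 100, freqs: {AFR1: 0.9, AFR2: 0.9, EUR1: 0.1}}
panel:
  afr_populations: [AFR1, AFR2]
  eur_populations: [EUR1]
```

Real data runs replace `simulation:` with
`inputs: {vcf: ..., panel: ..., gene_model: ..., manifests: [...]}`.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (statistic
oracles, estimator cross-checks, simulation parameter recovery, spike-in
panel recovery, PCA separation, exact-test enumeration, determinism and
round-trips), each with an independent reference implementation in
`tests/oracles.py`.

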