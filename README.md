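# ystr

Y-chromosomal population-structure and descent-cluster analysis:

* **Haplogroup assignment** from a 35-marker binary panel (hierarchical,
  with `X*-M(xY)` paragroup notation) and population × haplogroup
  frequency tables with Nei's unbiased diversity (HD).
* **Population structure**: Nei genetic distances, great-circle geographic
  distances, metric MDS (SMACOF with Kruskal stress-1), PCA, three-level
  AMOVA with permutation Φ-statistics, and the Mantel test.
* **STR descent clusters**: step distances over 15-locus haplotypes
  (DYS389b = DYS389II − DYS389I, DYS385a/b excluded), modal-haplotype
  detection (N\*), related-haplotype search within a mutational-step radius
  (N\*\*), median-joining networks, and zone-based descent-cluster
  delineation (N\*\*\*).
* **TMRCA dating** of clusters via the rho statistic (with Saillard-style
  branch variance on a rooted network, star fallback) and the ASD
  estimator, calibrated at 2.1×10⁻³ mutations/locus/generation and
  30-year generations.
* **Simulators** for clan expansions under the single-step mutation model
  (star or Galton–Watson genealogies, full ground-truth replay) and for
  grouped populations with tunable between-group divergence.

## CLI

```bash
ystr simulate clan --n 67 --depth-gen 20 --seed 1 --out clan.tsv
ystr modal   --samples clan.tsv --threshold 10 --out modal.json
ystr related --samples clan.tsv --radius 4 --out related.json
ystr network --samples clan.tsv --haplogroup C2b1a2-M48 --out net.graphml
ystr cluster --samples clan.tsv --haplogroup C2b1a2-M48 \
             --seed-pop SIM1 --out cluster.json

ystr simulate populations --groups 2 --pops-per-group 3 \
                          --out pops.tsv --meta-out meta.tsv
ystr freqs     --samples pops.tsv --out freqs.tsv
ystr distances --samples pops.tsv --out nei.tsv
ystr mds       --samples pops.tsv -k 2 --out mds.json
ystr amova     --samples pops.tsv --meta meta.tsv --scheme sim_group \
               --perms 9999 --seed 1 --out amova.json
ystr mantel    --samples pops.tsv --meta meta.tsv --out mantel.json

ystr run --config config.yaml --out results/   # full pipeline + manifest
```

The pipeline writes a `manifest.json` listing every output with its
SHA-256 hash; identical config + seed yields byte-identical manifests.
Per-stage seeds derive from the global seed by hashing
`"<seed>:<stage-name>"`, so adding stages never perturbs existing ones.

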