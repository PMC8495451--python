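# slamtraj

Tools for single-cell metabolic RNA labeling (scSLAM-seq) trajectory
analysis, built around five computations:

- **Molecule classification** (`slamtraj.slam`): per-read T→C conversion
  counting with SNP masking, UMI collapsing with discordant-position
  exclusion, and the nascent/old call (≥1 surviving conversion ⇒ nascent),
  aggregated into a layered gene×cell count matrix.
- **Two-layer kinetics** (`slamtraj.kinetics`): the coupled ODE
  du/dt = α − βu, ds/dt = βu − γs with induction/repression switching,
  per-gene alternating fits on KNN-smoothed moments, root-prior
  regularization for one-sided genes, per-cell latent time, velocities and
  the velocity graph.
- **SCNA clone scoring** (`slamtraj.scna`): reference-centered genomic
  smoothing, Ward clone cutting at k=2, the clone score (mean per-cell
  genomic SD over the pooled-normal mean), strict-threshold aberrance
  calling, and Bonferroni-corrected hypergeometric region enrichment.
- **Condition similarity** (`slamtraj.similarity`): average shared-neighbor
  fraction between conditions on a pooled KNN graph, plus average-linkage
  clustering of the similarity matrix.
- **Gradient statistics** (`slamtraj.gradient`): signature-score binning
  (40 quantile bins by default), per-bin state fractions, Pearson r with
  t-based significance, head-vs-rest chi-squared enrichment (BH adjusted),
  and Kruskal–Wallis + post hoc rank-sum cluster tests.

`slamtraj.synthetic` generates all inputs with known ground truth
(barcoded reads with conversions and sequencing error, kinetic cell
populations, clonal copy-number expression, multi-condition embeddings),
`slamtraj.preprocess` provides filtering/normalization/HVG/scoring/
cell-cycle regression/per-condition moments, and `slamtraj.io` reads and
writes the on-disk formats (MatrixMarket + sidecars, minimal VCF, BED,
tagged SAM text dialect, TSV).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance properties
(oracle equivalences, closed-form checks, recovery studies, determinism);
the rest are per-module unit and property tests with independent
brute-force oracles.

## CLI

```bash
slamtraj simulate --seed 7 --out out/sim            # synthetic reads + VCF/BED/SAM
slamtraj quantify --reads out/sim/reads.sam \
    --vcf out/sim/snps.vcf --bed out/sim/genes.bed \
    --out out/quant                                  # nascent/old/total matrices
slamtraj similarity --embedding emb.tsv --labels labels.tsv --out out/sim
slamtraj run --config configs/demo.yaml --seed 7 --out out/demo   # all stages
```

`slamtraj run` executes simulate → quantify → moments → kinetic fits /
latent time / velocity graph → SCNA scoring → condition similarity →
gradient statistics, writing TSV/MTX artifacts, a resolved config and a
JSONL run log. Reruns with the same seed are byte-identical.

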