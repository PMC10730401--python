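# mitopath

Tested, reusable implementations of a transcriptome / mitochondrial-function
analysis stack:

- **`mitopath.enrichment`** — running-sum pathway enrichment on a log2
  fold-change-ranked gene list: per-rank increments (`balanced` zero-sum
  default or the literal `as_printed` sign convention), the signed running-sum
  extremum score (MES), a membership-permutation null (exact enumeration for
  small problems, add-one-corrected Monte-Carlo otherwise), Benjamini-Hochberg
  FDR across the tested collection, joint significance calls
  (p < 0.05 and q < 0.1), and signed standard-normal Z conversion for heatmaps.
- **`mitopath.annotations`** — GO keyword gene-set construction
  (case-insensitive substring on term names, e.g. `"mitochondri"`), one-sided
  Fisher-exact overrepresentation with Bonferroni correction, and DEG calling
  at adjusted p < 0.1.
- **`mitopath.assays`** — plate-assay derivations: injection-phase
  segmentation, respiratory states II/III/IIIu/IVo after residual subtraction
  (+ RCR), electron-flow complex I–IV activities, calcium retention capacity
  from pulsed indicator traces (uptake-deficit and above-baseline AUC modes),
  kinetic H₂O₂ slopes, log-log luminescence standard-curve inversion, ER
  aspect ratio, exact small-sample Mann-Whitney U, and effect size ± SEM.
- **`mitopath.synthetic`** — generators for every input with recorded ground
  truth: DE tables with planted up/down gene sets, phase-structured OCR
  traces, pulsed Ca²⁺ traces with hard uptake capacity, linear H₂O₂ traces.
- **`mitopath.pipeline` / CLI** — end-to-end orchestration with deterministic
  manifests.

## CLI

The console entry point is `appki-pipeline`:

```sh
# full run from a YAML config (simulate -> enrich -> assays -> report)
appki-pipeline run --config run.yaml [--seed 7]

# individual stages
appki-pipeline simulate --config run.yaml
appki-pipeline enrich --de de.tsv --gmt sets.gmt --out results/ --n-perm 1000 --seed 1
appki-pipeline annot keyword --annotations ann.tsv --kw mitochondri --out mito.gmt
appki-pipeline annot fisher --annotations ann.tsv --de de.tsv --out fisher.tsv
appki-pipeline assay ocr   --trace trace.csv --schedule schedule.yaml --out states.tsv
appki-pipeline assay eflow --trace trace.csv --schedule schedule.yaml --out cx.tsv
appki-pipeline assay crc   --trace trace.csv --schedule schedule.yaml --out crc.tsv
appki-pipeline assay h2o2  --trace trace.csv --out slopes.tsv
appki-pipeline assay atp   --standards standards.csv --luminescence 316.2
appki-pipeline report --results enrichment_results.tsv --out report/
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. A minimal run
config:

```yaml
seed: 7
out_dir: out
simulate:
  contrasts: [c1, c2]
  de:
    n_genes: 400
    null_sd: 0.5
    planted_sets:
      - {name: planted_up, size: 25, delta: 1.2, direction: up}
      - {name: planted_down, size: 25, delta: 1.2, direction: down}
  decoy_sets: {count: 5, size: 20}
  ocr: {phase_means: {baseline: 50, ADP: 120, oligomycin: 40, FCCP: 130, antimycin: 10}}
  crc: {amplitude: 10, uptake_rate: 0.05, n_pulses: 5}
  h2o2: {slope: 2.0}
enrichment: {n_perm: 1000}
```

File formats: DE tables are TSV (`gene`, `log2fc`, `pvalue`, `padj`); gene
sets are GMT; annotations are TSV (`gene`, `go_id`, `go_name`, `ontology`);
traces are long CSV (`well`, `time_s`, `signal`); schedules are YAML.

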