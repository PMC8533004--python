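# chromgraph

Prediction of short- and long-range chromatin interactions from single-cell
open-chromatin read-count matrices.

The method treats binned, log-transformed accessibility profiles as samples
from a Gaussian graphical model and estimates a sparse precision matrix with
a graphical Lasso whose L1 penalty is set **per bin pair** from averaged
Hi-C contact maps: `rho_ij = delta / (h_ij + eps)`, so pairs with prior
contact evidence are shrunk less. Off-diagonal partial correlations of the
fitted precision matrix become interaction calls. An optional
majorization-minimization low-rank matrix completion step denoises the
count matrix before covariance estimation. A constant-penalty baseline
(`rho = 0.01`) is included for comparison, along with the evaluation
protocol (top-N / length-proportional contact-map positive sets) and
paired-loci annotation with a two-proportion z-test.

## Quick start

Generate a synthetic benchmark with known planted interactions, predict,
and evaluate:

```sh
chromgraph simulate --out-dir sim --n-bins 200 --n-cells 400 --seed 1
chromgraph predict \
    --matrix sim/matrix.tsv --chrom-sizes sim/chrom.sizes \
    --hic sim/prior.txt --delta 0.2 --out-dir run
chromgraph evaluate \
    --bedpe run/predictions.bedpe --hic sim/prior.txt \
    --n 100 --out eval.json
```

`predict` writes `predictions.bedpe` (10-column BEDPE), a UCSC
interact-format track, and a JSON run report; every output carries the tool
version and a configuration hash, and identical configurations produce
byte-identical BEDPE.

Real inputs: a dense TSV (cells x peaks, peak ids `chrom:start-end`) or a
matrix-market file plus a peak BED; a standard `chrom.sizes` file; and one
or more per-chromosome 3-column Hi-C text dumps (`start1 start2 value`,
fixed resolution — e.g. juicer dump output; repeat `--hic` to average cell
types, or use `--constant-rho 0.01` for the baseline). Binary `.hic`/`.cool`
files are not parsed — dump them to text first. `chromgraph convert` turns
a 3-column dump into 7-column paired-loci text, and `chromgraph annotate`
intersects calls with paired features (eQTL/GWAS SNPs vs promoters, HARs).

Useful knobs on `predict`: `--bin-size` (default 25000), `--delta`
(prediction-count sensitivity), `--eps` (pseudo-count), `--no-impute`,
`--rank`, `--mask-zeros`, `--min-abs-score`, `--sign-mode`,
`--max-distance`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance properties (solver
correctness against an independent proximal-gradient oracle and a scalar
reference, MM monotonicity/recovery, prior-vs-baseline edge recovery on
five seeded scenarios, evaluation/annotation hand calculations,
determinism); the five-seed benchmark takes a few minutes.

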