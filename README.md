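# introscape

A tested, reusable pipeline for detecting and characterizing introgressed
genomic regions between two nonsister species in a rooted four-taxon
quartet (outgroup `O`, ingroup `P`, `D`, `F`; species tree `(O,(P,(D,F)))`,
introgression tree `(O,(F,(D,P)))`).

The pipeline is driven end-to-end by a synthetic-data generator, so it
runs — and is tested — without any external sequencing data:

1. **simulate** — synthetic study: quartet SNV alignments with planted
   introgression tracts (JC69 down either parent tree), diploid genotypes
   with GQ/DP/RGQ quality fields, read-depth tracks, gene models with a
   multi-copy gene family and positively-selected-gene (PSG) flags, and a
   ground-truth tract set.
2. **detect** — a six-state phylogenetic HMM (two parent trees × three
   rooted triplet gene trees, the discordant states modelling incomplete
   lineage sorting). Baum–Welch from random restarts, forward–backward
   posterior decoding, per-site introgression posterior averaged over
   restarts.
3. **call-tracts** — maximal runs of ≥2 consecutive sites with posterior
   ≥ threshold; per-species mean-depth filter (keep within [5, 100]×);
   split at inter-genotype gaps > 25 kb; genome summaries and the
   scaffold-level introgression/gene-density Spearman correlation.
4. **background** — species-tree background regions (posterior of the
   species tree ≥ threshold), same run rule and filters, used as the null
   comparison set everywhere.
5. **stats** — interval d_XY between the two non-introgressing taxa
   (haploid pair, invariant sites in the denominator, GQ<30/DP<8/RGQ<30
   masking) and per-gene dN/dS (Nei–Gojobori 1986 counting with
   Jukes–Cantor correction; pluggable estimator) behind the four gene
   filters (mean depth, 1×/10× breadth, premature stops).
6. **test** — the four resampling procedures: pooled bootstrap comparison
   of means (100,000 resamples, two-sided p with the +1/(n+1) correction),
   constrained interval permutation into the background, feature-density
   bootstrap/permutation comparison (genes/Mb, coding fraction, PSGs/Mb),
   gene-family enrichment by random same-size gene draws, and the
   chromosome-absence block test (10 kb blocks sampled without
   replacement).
7. **report** — a single TSV of tract/gene values against background
   confidence intervals.

## Run the pipeline

Commands chain through a workspace directory of fixed file names:

```sh
introscape simulate    -w ws --seed 1          # optionally --config cfg.yaml
introscape detect      -w ws --restarts 25
introscape call-tracts -w ws --threshold 0.9
introscape background  -w ws
introscape stats       -w ws
introscape test        -w ws
introscape report      -w ws
```

`cfg.yaml` may carry `simulation:` and `run:` sections overriding any
field of `SimulationConfig` / `RunConfig` (see `src/introscape/config.py`).
All outputs are deterministic given the seed and configuration; reports
embed both.

Formats: FASTA (per-taxon pseudo-haploid chromosomes), multi-sample VCF
with invariant sites and GQ/DP/RGQ, GFF3, BED3/6, step-function depth TSV,
posterior-track TSV, PHYLIP + position table. Internal coordinates are
0-based half-open; VCF/GFF3 are converted at the boundary.

## Library use

```python
from introscape import hmm, simulate, tracts
from introscape.config import SimulationConfig

study = simulate.simulate_study(SimulationConfig(seed=1))
fit = hmm.fit(study.alignments[0], n_restarts=25, seed=1)
called = tracts.call_tracts(fit.track, threshold=0.9)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the binding acceptance criteria:
exact brute-force oracles for the forward–backward and pruning
likelihoods, EM monotonicity, planted-tract recovery on a 5 Mb genome
(sensitivity ≥ 0.8, false-positive site fraction ≤ 0.01), per-record
oracles for every filter, bootstrap type-I/power calibration,
permutation-engine audits, closed-form checks, and end-to-end
determinism. The full suite runs in about 6 minutes on one CPU.

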