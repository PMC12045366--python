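# Methods

`sirnakit` models the in-silico side of a divalent siRNA therapeutic
program against a dosage-sensitive, alternatively spliced gene (the
motivating case is MECP2, whose E1 isoform carries an exclusive first
exon absent from E2). This note records the models, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions.

## Target-site model

Transcripts are RNA strings with transcript-relative exon boundaries and
an optional CDS, all 0-based half-open. Candidate sites are every
k-mer window of a transcript (default k = 20, the guide-complement
length of the asymmetric scaffold family; configurable). Region labels
(5'UTR / ORF / 3'UTR) follow the CDS; a window straddling a boundary is
labeled by majority overlap with ties resolved toward the 5' region, a
deterministic rule chosen because any label for straddling windows is a
convention.

Isoform exclusivity and cross-species conservation are both decided by
exact, same-strand substring matching of the full site sequence. For
conservation this deliberately encodes the strictest reading of
"completely conserved": one mismatch anywhere in the site breaks the
species flag. The scan runs over transcript sets, not genomes, so a
site conserved at the genomic level but absent from the supplied
ortholog transcripts will be reported unconserved — supply full
transcript collections per species when this matters.

## Design scoring

Per candidate the package computes:

* **G+C fraction** of the site; pass window default [0.30, 0.55]
  (standard practice for active siRNAs).
* **Duplex end asymmetry** ddG = dG(guide-5'-end stacks) −
  dG(guide-3'-end stacks), summing nearest-neighbor dG37 values over the
  terminal 4 base pairs at each end (no initiation term, so the ends are
  directly comparable). Positive ddG means the guide 5' end is the less
  stable duplex end, which biases RISC toward loading the guide strand;
  the pass threshold defaults to 0. Stack free energies are the unified
  Turner-lab RNA/RNA Watson-Crick dG37 set, shipped as a versioned TSV
  (`data/nn_dg37.tsv`) and swappable.
* **Self-complementarity**: the maximum Watson-Crick pair count over all
  gapless alignments of the site against its own reverse complement — a
  cheap hairpin/self-dimer propensity proxy, default cap 8.
* **Seed off-target load**: occurrences (overlap-counted) of the
  reverse complement of guide positions 2–8 (the conventional 7-mer
  seed; configurable) in off-target mRNA and lncRNA sets. By default
  only annotated 3'UTRs are scanned, the canonical region for
  miRNA-like off-target repression; a full-transcript scan is a flag.
  No universal count threshold exists, so the seed filter is off until
  a limit is configured.

Passing candidates are ranked by a composite of z-scored criteria
(asymmetry +, GC-centrality within the allowed window +,
self-complementarity −, seed load −; equal weights by default). The
published screens this mirrors never disclose scoring weights, so the
ranking reproduces the structure of "top-scoring" selection, not any
particular published candidate list. Ties break deterministically by
fewer seed matches, higher asymmetry, then lower start coordinate, and
the ranking is invariant to input order.

## Scaffold chemistry and mass accounting

Strands are encoded position-by-position with a compact grammar
(`mU# fU# mA ...`): sugar code (`m` 2'-O-methyl, `f` 2'-fluoro, `r`
ribo), base, and `#` for a phosphorothioate linkage to the next
residue. Termini are 5'-OH / phosphate / vinylphosphonate and 3'-OH /
cholesterol-TEG / linker attachment. A divalent construct is two
identical guide:passenger duplexes whose passenger 3' ends join at a
tetraethylene glycol branch; the asymmetric defaults are a 20-nt guide
and a 16-nt passenger annealed to the guide 5' region (4-nt guide 3'
overhang).

Masses are average (vendor-style) masses assembled from per-residue
monophosphate masses plus sugar/linkage deltas, with terminal and
conjugate corrections; every constant is documented in
`data/mass_table.tsv`. The cholesterol-TEG and branch-linker masses are
documented best estimates, which is why mass-based checks carry a ±5%
tolerance. The packaged construct files are **synthetic stand-ins**
(marked `synthetic` in their names): the original program's strand
sequences are not public, so the files carry realistic sequences with
modification patterns engineered to the published whole-construct
properties — ~59% (scaffold 1) and ~76% (scaffold 2) 2'-O-methyl
content and a divalent mass of ~24.2 kg/mol, consistent with the
printed 12.5 nmol ≈ 315 μg and 1 nmol ≈ 25 μg conversions. Note that
with 36 monomer positions per duplex the 2'-OMe percentage is quantized
in steps of 1/36 ≈ 2.8 points; the nearest achievable values are 58.3%
and 75.0%.

## Screen analytics

Wells are normalized as (target / housekeeping signal), scaled by the
mean of the same-probe control ratios (control group NTC by default;
untreated wells and the median statistic are config options, since
published screens rarely state which was used). The control-group mean
is 1.0 by construction.

Isoform selectivity is S = 100 × max(0, 1 − E1_remaining /
E2_remaining). No published formula exists for this quantity; this
definition is adopted because it is scale-invariant and yields ~95%
when E1 is reduced to ~5% with E2 intact, matching how the number is
quoted in practice. Hit calling takes compounds whose mean remaining
expression is ≤ a configured threshold (default 0.5), boundary
inclusive.

Potency is a least-squares 4PL fit r(c) = bottom + (top − bottom) /
(1 + (c/IC50)^h), parameterized internally in log-IC50 with box bounds
(plateaus ≥ 0, Hill in [0.1, 10], IC50 within 10^4× of the tested dose
range) and initialized from the data range and geometric-mean dose.
Unidentifiable fits (constant responses, non-finite covariance) return
`converged=False` instead of raising. Noiseless synthetic data is
recovered to ~1e-6 relative, and the fit is exactly equivariant under
rescaling all concentrations.

**Precision caveat.** Under the default screen-mirroring design — 7
two-fold dilutions from 1.5 μM, 3 replicates, 10% multiplicative noise,
IC50 near 200 nM — neither plateau of the curve is sampled, and the
per-experiment IC50 error has a median around 16–19% for every
estimator we evaluated (bounded/unbounded least squares, log-residual,
relative-weighted). The estimator is essentially unbiased, though: the
median of fitted IC50s across 100 such experiments recovers the
generating value to within a few percent, which is the quantity the
acceptance script reports. Single-experiment IC50s from this design
should be read with ±20% humility.

## Imaging quantification

The per-nucleus pipeline mirrors an ImageJ-style workflow but replaces
every interactive step with a deterministic default: DAPI threshold by
Otsu (fixed-value override available), 8-connected components, size
filter (min area 20 px), raster-order labels, no watershed — touching
nuclei merge into one ROI, a documented limitation. Marker background
is removed by grayscale opening with a disk of radius 50 px (a
documented approximation of the classic rolling-ball estimate), output
clipped at 0; the white-top-hat is idempotent on constant-background
images. Per-ROI mean and median intensities are both emitted because
the positivity criterion of the original analysis is unstated; the
default classifier is an exact Otsu split of the per-nucleus means
(computed on the sorted sample rather than a histogram, which misplaces
the threshold for small samples with wide empty gaps), with a fixed
threshold as the alternative. ROIs map to regions by the pixel under
their rounded centroid; overlapping region masks are an error, and
empty regions report a null percentage rather than dividing by zero.
Every run records the thresholds and parameters actually used in a
provenance JSON.

## Synthetic data: what it emulates, and what it does not

* **Gene/orthologs**: a two-isoform gene (exclusive first exon, default
  120 nt, vs an alternative start, plus shared downstream exons) with
  i.i.d.-uniform sequence; ortholog divergence is substitution-only at a
  per-species rate, with protected intervals exempt from mutation, so
  exact-match conservation ground truth is unambiguous. Real
  transcripts have composition bias, repeats, and indels; none are
  modeled, so passing tests show correctness of the matching logic, not
  robustness to alignment-requiring divergence.
* **Screens**: housekeeping signal lognormal around a constant, target
  = housekeeping × true fraction × unit-mean lognormal noise (CV 10%
  default, the typical plate CV for branched-DNA readouts; positive
  support matches luminescence). At CV 0 the normalizer returns the
  truth table exactly. Plate-position effects and edge artifacts are
  not modeled.
* **Dose-response**: 7 two-fold dilutions from 1.5 μM (mirroring the
  screen concentration), 3 replicates, 4PL truth with bottom 0.1, top
  1.0, Hill 1.
* **Slides**: non-overlapping disk nuclei (radius 4–7 px) on a 1024²
  canvas, 750 per region by default (the 500–1000 nuclei/region regime
  of real tiled scans), two vertical-strip regions with planted
  positive fractions {A: 0.1, B: 0.5}, marker amplitude = SNR × noise
  SD (SNR 10 default; recovery is specified at SNR ≥ 5). Real nuclei
  touch, vary in shape, and sit on textured tissue backgrounds; an
  allow-touching mode exists only implicitly via dense placement, and
  texture is not modeled, so the ±3-point end-to-end recovery shows the
  pipeline's bookkeeping is right, not that it segments real tissue.

All generators are deterministic given (config, seed) and emit their
ground truth alongside the data.

## Problem sizes

Defaults keep every stage cheap: design on ~0.5–1 kb synthetic
transcripts (hundreds of candidates) runs in well under a second; the
IC50 recovery study is 100 experiments × 21 points; the end-to-end
imaging suite quantifies 20 slides of 1,500 nuclei each. These sizes
were chosen as the smallest at which the statistical claims (median
recovery, ±3-point positivity error) are stable across seeds.

## Known limitations

* Conservation and off-target scans are transcript-set based; there is
  no genome-scale or gapped alignment.
* Self-complementarity is a gapless proxy, not a folding energy; no
  partition-function structure prediction.
* The composite ranking weights are conventions, not fitted to any
  efficacy data.
* Mass constants for conjugates/linkers are documented estimates (±5%).
* No watershed splitting of touching nuclei; merged ROIs bias counts
  low at high density.
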