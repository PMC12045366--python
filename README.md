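# sirnakit

Tools for the computational side of an siRNA therapeutics program
against a dosage-sensitive, alternatively spliced gene: selecting
isoform-selective and multi-species-conserved target sites, accounting
for fully chemically modified scaffold chemistry, analyzing in vitro
knockdown screens (normalization, selectivity, IC50), and quantifying
per-nucleus immunofluorescence positivity. The motivating application
is MECP2 — whose E1 isoform carries an exclusive first exon absent from
E2, so E1-selective silencing can trim total MECP2 without dose
titration — but every stage is generic.

Who it is for: RNA-therapeutics groups designing siRNA panels and
analyzing the screens and histology that follow, and anyone needing a
reproducible, scriptable replacement for the usual mix of spreadsheets
and interactive ImageJ sessions.

## What it computes

* **Site design.** Candidate sites are all k-mers (default k = 20) of a
  transcript across 5'UTR, ORF and 3'UTR. Isoform-exclusive windows
  and cross-species conservation use exact substring matching. Sites
  are scored on G+C fraction, duplex end asymmetry
  ΔΔG = ΔG°₃₇(guide 5'-end stacks) − ΔG°₃₇(guide 3'-end stacks)
  from nearest-neighbor parameters (positive ⇒ guide-loading favored),
  gapless self-complementarity, and seed (guide 2–8) match counts in
  off-target mRNA/lncRNA sets; passing sites are ranked by a composite
  z-score.
* **Chemistry.** Strands are per-position modified (2'-O-methyl /
  2'-fluoro sugars, phosphorothioate linkages, 5'-vinylphosphonate,
  cholesterol-TEG), assembled into monovalent duplexes or divalent
  constructs joined by a tetraethylene glycol branch; the package
  reports modification content, average mass, and nmol→μg doses.
* **Screens.** Housekeeping-normalized relative expression, E1-vs-E2
  selectivity S = 100·max(0, 1 − E1/E2), threshold hit calls, and
  four-parameter logistic fits
  r(c) = bottom + (top − bottom)/(1 + (c/IC50)^h).
* **Imaging.** DAPI Otsu segmentation → rolling-ball-style background
  subtraction (disk opening, radius 50 px) → per-nucleus marker
  intensity → Otsu or fixed-threshold positivity → percent positive
  nuclei per region, with full provenance.
* **Synthetic data.** Deterministic generators with ground truth for
  every input above, so the whole pipeline is testable offline.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

Generate a two-isoform gene, design E1-exclusive candidates, simulate
and analyze a screen, and inspect the divalent scaffold-1 construct:

```bash
sirnakit simulate gene --seed 7 --out g
sirnakit design --targets g/gene.fasta --structure g/gene_structure.tsv \
    --target-id GENE-E1 --exclude-isoform GENE-E2 --out d
# -> 20 passing candidates of 120; outputs in d

sirnakit simulate screen --seed 7 --noise-cv 0.05 --out plate.csv
sirnakit screen --plate plate.csv --out s
# -> hits: siRNA_1764, siRNA_1759; outputs in s

sirnakit chem-report
```

The design run reports 120 candidates — exactly the E1 sites whose
20-mers never occur in E2 (the 120-nt exclusive first exon under the
overlap rule) — of which 20 pass the default GC/asymmetry/self-structure
filters. The screen run flags the two compounds whose simulated true
knockdown (75% and 70%) clears the 50%-remaining threshold, ordered by
potency. The chemistry report prints, among other fields:

```
"2OMe": 58,            # percent of positions 2'-O-methyl
"average_mass_g_per_mol": 24171.51,
"doses_ug": {"1.0": 24.17, "12.5": 302.14}
```

i.e. the scaffold-1 divalent construct is ~58% 2'-O-methyl and a
12.5 nmol dose is ~302 μg. The packaged construct files are synthetic
stand-ins with realistic patterns; see `docs/methods.md`.

From Python the same stages are plain functions:

```python
from sirnakit import synthetic_data as syn, fit_4pl

table = syn.simulate_dose_response(ic50=201e-9, noise_cv=0.10, seed=1)
fit = fit_4pl(table["concentration"], table["response"])
print(f"IC50 = {fit.ic50 * 1e9:.0f} nM")   # IC50 = 215 nM for this seed
```

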