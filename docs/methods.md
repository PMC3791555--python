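# Methods and design notes

This document records the models implemented by `chapflux`, the
parameters they expose, and the reasoning behind the non-obvious design
decisions.

## 1. Absolute quantification (`chapflux.srm`)

**Model.** A heavy isotope-labelled standard peptide is spiked at a known
amount onto a digest of a known number of cell equivalents. The observed
light:heavy ratio converts to copies per cell:

```
cpc = ratio × spike_fmol × 1e-15 × N_A / cells_loaded
```

With a 0.2 fmol spike over 2×10⁵ cells a 1:1 ratio is ≈ 602.2 cpc, so a
peptide that is detectable but fails gating at that spike is bounded
above by ≈ 600 cpc (≈ 6000 cpc at 2 fmol) — this is what
`detection_limit_cpc` returns and what Type B bounds are built from.

**Replicate gating.** Measurements are taken over a spike ladder and
four biological replicates. Per replicate, the passing measurement with
log₁₀-ratio nearest zero is selected (ratios far from 1:1 sit outside the
assay's linear range). A peptide is **Type A** when ≥ 3 of 4 replicates
pass both the FDR filter and a signal-to-noise threshold (strictly
\> 5); **Type B** when the analyte is seen but gating fails (reported as
an upper bound at the lowest spike where the standard was observed); and
**Type C** when the standard itself is never seen (`standard_detected`
exists on measurements precisely because B vs C is undecidable without
it).

**Protein rule.** Each protein is covered by two surrogate peptides;
digestion losses can only depress a peptide's apparent abundance, so the
protein estimate is the **maximum** of the sibling peptide means. Type B
bounds combine by minimum (the tightest bound wins).

**Banded rounding.** Reported values are rounded to the nearest 10 below
1000 cpc, nearest 50 up to 10 000, nearest 500 above, using round-half-up
(`floor(x/band + 0.5) × band`). This keeps reported precision roughly
proportional to measurement precision.

**Peptide vetting.** `flag_cleavage_context` flags dibasic (KK/KR/RK/RR)
and interspersed-dibasic cleavage sites and acidic (D/E) residues
adjacent to the cleavage sites — contexts where trypsin is slow or
unreliable, which biases single-peptide quantification low.

## 2. Abundance harmonisation (`chapflux.abundance`)

Datasets arrive in ppm of total protein molecules or directly in cpc;
under the standard 6×10⁷-molecule cell, 1 ppm ≙ 60 cpc. Comparisons use
Spearman rank correlation on pairwise-complete ORF intersections (rank
correlation is invariant to the unit mismatch and to any monotone
calibration error); pairs with fewer than `min_overlap` (default 10)
shared proteins get NaN. Dataset clustering is average linkage on
d = 1 − ρ, with names sorted first so the tree is input-order invariant;
trees serialise to Newick. `complex_cv` (sample SD / mean over the
subunits of a fixed-stoichiometry complex such as CCT/TRiC) is an
internal calibration control — the packaged table gives CV ≈ 0.68.

## 3. High-quality interactome (`chapflux.interactome`)

Three source archetypes: two **directed** bait→prey screens
("biogrid-like", "mips-like") and one **scored**, inherently undirected
association source ("string-like"). Per source, in order:

1. duplicate directed observations collapse to one (highest confidence
   wins for scored sources);
2. keep only pairs linking exactly one chaperone to a non-chaperone —
   chaperone–chaperone contacts are mostly co-chaperone interactions,
   not substrates;
3. directed pairs survive only if the reciprocal observation exists
   **within the same source** (cross-source reciprocity is available via
   `within_source=False`; scored sources are exempt by default, strict
   mode via `strict_reciprocity=True`);
4. scored edges survive only with confidence **strictly** above 0.7.

Survivors union into one undirected (chaperone, substrate) network with
per-pair source provenance. The filters commute, which the tests verify
on random edge lists, and the whole cascade is validated against an
independent set-algebra oracle.

## 4. Flux model (`chapflux.flux`)

At steady state, synthesis balances degradation: k_syn = k_deg × cpc,
with k_deg = ln 2 / t½ (an optional dilution rate adds growth-driven
turnover). Proteins without measured half-lives get the **geometric
mean** of observed k_deg (degradation rates are roughly log-normal, so
the geometric mean is the natural central value).

Per chaperone c: substrate volume V_c = Σ cpc over its substrates, and
workload F_c = Σ k_syn. Two sharing conventions:

- `full` — each substrate's whole k_syn counts toward every interacting
  chaperone (upper-bound reading, matches published per-chaperone
  rankings);
- `equal_split` (default) — k_syn divides equally among a substrate's
  chaperones, so Σ_c F_c exactly conserves total substrate flux (this
  conservation is an acceptance property, verified to ~1e-15 relative
  error).

Per-copy efficiency is F_c / cpc_c; the top reference-table chaperone
works at ≈ 13.7 → 14 molecules per minute per chaperone copy. Workload
tables sort by F_c descending with ties broken by ORF ascending, so
output order is fully deterministic. `class_fractions` computes
chaperone-mediated proteome fractions by count/volume/flux (denominators:
all proteins vs quantified proteins), per-class pro-rata shares (split
equally over the *distinct classes* targeting each substrate), and
essentiality cross-fractions.

## 5. Localisation (`chapflux.localisation`)

Profiles are **pro-rata**: a protein annotated to k loci contributes
w/k to each, where w is 1, cpc, or k_syn (`basis`). Class profiles are
conditional — a substrate shared by two classes contributes fully to
both.

**Enrichment** uses the EASE-modified one-sided Fisher test: the overlap
cell is decremented by one before taking the hypergeometric tail
(`hypergeom.sf(k−2, N, K, n)`), so enrichments supported by 0 or 1 genes
are never significant. This conservatism is deliberate for small
substrate lists. Bonferroni adjustment runs over all (class, location)
tests. Correctness is checked exhaustively against exact integer
arithmetic over every 2×2 table with background ≤ 60.

**Specialisation** is a per-location Kruskal–Wallis test of
per-chaperone target fractions across classes (classes need ≥ 2
chaperones), Bonferroni-adjusted, with the overall p taken as the
minimum adjusted per-location p (union–intersection: "classes differ
somewhere"). Locations with zero variation get H = 0, p = 1 rather than
an undefined statistic.

## 6. Synthetic generator (`chapflux.simulate`)

All randomness flows from `numpy.random.SeedSequence(entropy=seed,
spawn_key=(stage,))` substreams, so stages are independently reproducible
and adding a stage never perturbs earlier ones.

Default scales are the package's own modelling choices, picked to mimic
a realistic single-celled eukaryote:

- **Chaperone panel** — 63 chaperones in 8 classes (SMALL 7, PFD 6,
  HSP90 2, HSP70 14, HSP60 1, HSP40 22, CCT 8, AAA+ 3).
- **Abundance** — substrate log₁₀ cpc ~ N(3.0, 1.0); chaperones
  ~ N(3.75, 0.85) clipped at 250 cpc (chaperones sit in the abundant
  tail of the proteome).
- **Turnover** — half-life log-normal, median 43 min, log₁₀ SD 0.4;
  20 % of k_deg values are masked to exercise imputation.
- **Interactome** — edge probability ∝ cpc^γ (`workload_exponent`,
  default 1), scaled to a mean of 30 targets per chaperone; γ = 1 plants
  an abundance–workload correlation, γ = 0 plants independence. Planted
  class-location biases (e.g. prefoldin → vacuolar membrane ×12,
  HSP90 → mitochondrion ×4) give the enrichment tests true signal.
- **Evidence channels** — per-source detection probability, reciprocity
  probability and noise-edge count; the scored source draws confidences
  from Beta(8,2) for true edges and Beta(2,8) for noise.
- **SRM** — 2 peptides × 4 replicates × spikes {0.2, 2, 20} fmol at
  2×10⁵ cells, ratio CV 0.1, S/N = 100 × ratio, 2 % random FDR
  failures. With noise switched off the quantification pipeline recovers
  every planted cpc exactly after rounding (an acceptance property).

**Scope/limitations.** The generator plants *marginal* structure
(abundance, turnover, degree, localisation bias) but no higher-order
correlations (e.g. abundance–half-life coupling, co-complex membership);
it is a test harness for the analysis stages, not a cell model.

## 7. Pipeline and determinism (`chapflux.pipeline`, `chapflux.cli`)

`run_pipeline` chains simulate → quantify → network → flux → localise and
writes TSV/JSON artefacts plus a run report and manifest (config hash,
stage summaries, no timestamps). Floats serialise via `%.10g`. All
set-valued intermediates are iterated in sorted order before any float
accumulation — Python's per-process hash randomisation otherwise changes
summation order and breaks byte-level reproducibility of last digits.
Two runs with the same seed are byte-identical, which the acceptance
suite verifies with `filecmp`.

Problem sizes in tests and examples (hundreds to ~1200 substrates) are
chosen to keep the full suite under ~2 minutes while leaving enough
statistical power for the planted-signal assertions.

### Statistical-power note on the γ = 0 tests

The null Spearman statistic over ~60 chaperones has SD ≈ 1/√62 ≈ 0.13,
so a single-run |ρ| < 0.15 assertion would fail on roughly a quarter of
seeds by chance alone. The γ = 0 checks therefore average ρ over five
independent simulations (null SD ≈ 0.06), making the ±0.15 band a
meaningful test of the planted independence rather than a coin flip.
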