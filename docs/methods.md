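# Methods

## Composition model

A benchmark design is a set of samples, each described by species mass
fractions in percent of total protein mass (w/w), non-negative and summing
to 100 within 1e-9. Dilution is exact mass balance: mixing `p` parts of a
base with `q` parts of diluent gives fractions
`(p·f_base + q·f_dil)/(p+q)`. A "1:k" dilution means 1 part sample plus
k−1 parts diluent (final k parts); this is the only reading under which the
bundled design's 1:9 level carries 10/9 ≈ 1.1% non-human mass, matching its
published description. Because the A and B members of a pair are diluted
identically, every spike-species log₂(A/B) is invariant across levels — an
assertable property, not an assumption.

The bundled `pye` design (`presets/pye_design.yaml`): base pair
A = 90/2/8 and B = 90/6/4 percent human/yeast/E. coli, levels at 1:1, 1:3
and 1:9 against a pure-plasma diluent. Expected ratios: human 1:1, yeast
1:3 (log₂ = −1.585), *E. coli* 2:1 (log₂ = 1). The constructor is
data-driven; any multispecies design with one background species can be
described in the same YAML schema. Fractions are treated as interchangeable
peptide/protein mass fractions (digestion efficiency is not modelled).

## Canonical table and dialects

All readers produce one long table: one row per (setup, sample, replicate
run, protein group) carrying intensity, peptide count, optional q-value
gates (`q_value`, `pg_q_value`, `lib_q_value`, `lib_pg_q_value`), optional
retention time, and decoy/contaminant flags. Zero or empty intensities
become NaN on read: quantification software writes 0 for non-detections,
and a literal zero would corrupt CV and missingness statistics. Replicate
indices always come from the declared run-to-sample map, never from file
order.

Dialect notes:

* *generic* — tidy TSV with canonical column names; lossless round-trip
  (floats are parsed with a shortest-round-trip parser).
* *maxquant* — wide proteinGroups-style layout; per-run "LFQ intensity"
  columns are melted, "+" markers populate the flags. The layout cannot
  carry per-run RT or q-values, so reader equivalence across dialects is
  defined on the representable core (keys, intensity, peptide count,
  flags).
* *diann* — long precursor-level layout aggregated to protein-per-run:
  intensity is the reported protein-group quantity taken once (never
  summed), RT is the median precursor RT, peptide count is the number of
  distinct stripped sequences, and each q-value gate is the minimum across
  precursors (a protein is identified if its best precursor passes).
  Reading never filters.

Species assignment maps each protein-group member through an explicit
accession map (e.g. from FASTA `OS=` organism fields, which take
precedence) or ordered identifier regex rules (default: the
`_HUMAN`/`_YEAST`/`_ECOLI` entry-name suffixes). Groups matching more than
one species are labelled `mixed`, unmatched ones `unknown`; both are
excluded from ratio metrics but still count toward identification totals.

## Filter cascade

Defaults: drop decoys and contaminants; require ≥ 2 peptides; when q-value
gates are present, require every gate ≤ 0.01 (absent gates — the DDA path —
skip the check); for ratio metrics, require quantification in ≥ 3 replicate
runs of each compared condition, applied as one global rule regardless of
how many replicates a setup ran. Audit counts attribute each removed record
to its first failing rule in the fixed order decoy → contaminant →
peptides → q-gates, so `records_in = records_out + Σ removals` always
holds. Whether the 2-peptide rule counts distinct sequences or precursors
is a genuine ambiguity for DIA reports; distinct stripped sequences is the
choice here.

## Metric definitions and numerical conventions

* Quantiles: linear interpolation between closest ranks (numpy default),
  verified against a brute-force sort-and-interpolate oracle.
* CVs are computed on raw (not log) intensities, sample sd (ddof = 1) over
  mean × 100, per protein across the replicate runs of one sample; proteins
  with < 2 detections are skipped. RT CVs pool the A and B runs of a level.
* Completeness categories over a level's runs: complete (all runs), ≥ 50%
  (but not all), sparse (< 50%, more than one), unique (exactly one);
  disjoint by construction. IDs-per-minute is the complete count divided by
  the gradient length.
* The per-protein A/B ratio is log₂ of the mean detected intensity over A
  replicates over the mean over B replicates (means, not medians — tolerant
  to missing replicates once eligibility holds). Accuracy = Q50 − expected;
  precision = Q75 − Q25. Results from < 3 proteins are flagged unstable.
* Tertiles split the eligible proteins of one (setup, level, species) call
  into thirds by mean log₁₀ intensity pooled over the A and B runs, ties
  broken by protein identifier.
* Missingness: the reference table defines the protein set and ranking
  (mean of per-setup max-normalized intensities, descending, ties by
  identifier); the query supplies detection counts over all its runs;
  proteins absent from the query score 1. The 50%-crossing rank uses a
  centred rolling mean (window 51 by default, truncated at the edges) —
  the smoothing is a declared convention, as rank curves are otherwise
  step functions.
* Dynamic range: per-setup mean intensities over a level's runs normalized
  to the setup maximum (= 100%), combined across setups as the mean of
  available values per protein, reported on a log₁₀ percent scale.
* Cross-dilution correlation: per-level arithmetic means (the choice of
  arithmetic over geometric is a convention), per-setup max-normalization
  × 100, R² of log₁₀ values per species; the expected identity-line offset
  is 0 for the background and log₁₀ of the spike dilution fold otherwise.
* Response bins: proteins ranked ascending by reference-sample mean
  abundance, split into 10 equal-sized bins (remainder to the lowest bins,
  ties by identifier); per bin × sample the median of member means over
  detected replicates; a bin × sample is below LOD when more than half its
  members are undetected in that sample.
* Peak capacity = 1 + gradient/(mean FWHM × 1.699) (Gaussian FWHM → 4σ base
  width); data points per peak = FWHM/cycle time. Both are declared
  conventions — the field uses several — and enter only the cross-metric
  correlation.

## Synthetic-data generator

The generator works at protein-per-run granularity (no spectra, peaks, or
peptide-level identification; peptide counts are sampled integers ≥ 2).
Per species, base abundances are lognormal on log₁₀ scale with a clamp:
human mean 6.5, sd 1.3, range 3.5–9.5 (six orders, heavier-tailed to mimic
plasma); yeast and *E. coli* mean 5.8, sd 0.9, range 3.8–7.8 (four orders).
Default counts 400/2000/1500 human/yeast/E. coli. Expected intensity in a
sample is base × mass fraction/100, so every A/B ratio is exact by
construction. Observed intensity multiplies by mean-1 lognormal noise with
the configured CV. Detection is Bernoulli with probability
`expit((log10 I − midpoint)/steepness)`, times a per-run sampling factor
(< 1 for DDA, modelling stochastic precursor selection). Retention times
are a per-protein constant plus per-run drift (sd 0.05 min) and
per-observation jitter (sd 0.02 min) over a 60-min elution span. An
optional compression knob κ ∈ [0,1] shrinks the spike log₂ deviation
toward 0 with a logistic weight that decreases with abundance — an
interference-like distortion knob, not a mechanistic claim. A single seed
drives everything through per-run substreams; identical configs are
byte-identical.

Presets. The DIA preset uses 6% replicate CV (inside the observed DIA
median-CV range of 3.3–9.8%), dropout midpoint 2.8, full sampling; the DDA
preset uses 15% CV (inside the observed 6.4–54.7% DDA range), midpoint 3.8
(one log₁₀ unit higher), steepness 0.3 and sampling factor 0.95 — at which
roughly half of the well-detected proteins are complete over 12 runs, the
magnitude reported for DDA workflows. The midpoints were placed using the
composition algebra so the lowest *E. coli* response decile falls below the
DDA detection midpoint at the 1:3 dilution while remaining quantifiable in
DIA, reproducing the qualitative LOD contrast between the modes. Six
replicates per sample by default.

What the generator does not emulate: correlated peptide-level noise,
normalization artefacts across runs, chromatographic carry-over,
protein-inference ambiguity (every synthetic group is single-species), and
real q-value distributions (a constant fill value). Passing tests
therefore demonstrate the correctness of the metric pipeline under
controlled conditions, not the behaviour of any real instrument platform.

## Known numerical caveats

The median of per-protein sample CVs is biased low at n = 6 (the c₄
correction factor ≈ 0.95, plus skewness of the lognormal CV distribution).
At 6% injected CV the recovered median is ≈ 5.5–5.6%; at 40% the bias
reaches ~13%, which is a property of the estimator, not of the
implementation — the test suite checks that point against an independent
Monte-Carlo simulation of the same estimator. CVs, eligibility and ratios
all treat absent intensities as missing, never as zero.

## Problem sizes

Tests and examples run the generator at its default scale (3900 proteins ×
36 runs, ≈ 140k records, well under a second to generate) or smaller; the
recovery suites use 2000 spike proteins × 6 replicates per sample, the
scale at which the stated tolerances were derived.
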