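# Methods

## The measurement model

Both layers of a venom system are relative measurements. RNA-seq yields read
counts whose total is set by the instrument, not the tissue; label-free MS
yields intensities on an arbitrary scale. Abundance vectors are therefore
treated as compositions: closed to sum 1 and mapped to real space by the
centered log-ratio (clr) transform, `clr(x)_i = ln(x_i / g(x))` with `g(x)`
the geometric mean. clr shifts each vector's logs by a per-vector constant,
so Spearman's ρ is exactly invariant and Pearson's R equals its log-scale
value; all correlations are computed on clr values over the ids quantified
in both layers, with closure recomputed on that matched subset (clr is
subcomposition-sensitive, so closure must follow restriction, never precede
it). Zeros are rejected rather than pseudocounted: comparisons use only
toxins actually quantified in both layers, and detection failures are
analysed separately (see silencing below).

## Protein quantification

Peptide intensity tables carry rows of (replicate, protein, peptide, score,
intensity, FPR). Two internal-standard response-factor estimators are
implemented, each calibrated per replicate so that between-run sensitivity
drifts cancel (both are exactly invariant to rescaling all intensities of a
replicate):

* **Top-3.** RF = load_fmol / Σ(standard's three highest-scoring peptide
  intensities); protein fmol = RF × Σ(its top-3). Proteins with fewer than
  three peptides in a replicate are not quantified in that replicate.
  Score ties break by higher intensity, then peptide lexicographic order.
* **All-peptide (iBAQ-like).** RF = load_fmol × MW_std / Σ(all standard
  intensities), in fg per intensity unit; protein fg = RF × Σ(all its
  intensities); fmol = fg / MW. Molecular weights are average (not
  monoisotopic) masses — conventional at protein scale — via Biopython.

Per-replicate estimates are averaged; the replicate CV (sample sd / mean) is
reported as QC but high-CV proteins are only flagged, never auto-removed.
Proteins not detected in every replicate are excluded from quantitative
comparisons. Bradykinin-potentiating and C-type natriuretic peptides are
excluded by default because extensive proteolytic processing makes their
predicted tryptic peptides unrepresentative of the secreted product. Shared
peptides are counted for every protein they are assigned to; no reassignment
algorithm is attempted (the all-peptide measure is the less sensitive of the
two to this).

In-silico trypsin cleaves after K/R except before P; with `missed = m`,
concatenations of up to `m + 1` adjacent fragments are also emitted.

## Transcript quantification

Coding sequences are clustered by single linkage at pairwise divergence
< 1%, keeping the highest-abundance member (ties: smallest id) — cluster
members represent alleles, recent paralogs, or error-bearing contigs.
Divergence is (mismatches + gapped columns) / alignment length under global
alignment with match +1, mismatch −1, gap −2; the alignment is computed by an
in-house Needleman–Wunsch with a canonical diagonal > up > left traceback so
the reported counts are deterministic, and arguments are ordered canonically
so the measure is symmetric. Nucleotide (not amino-acid) divergence is used.

TPM_i = 10⁶ (count_i/length_i) / Σ_j (count_j/length_j). Two filters remove
untrustworthy estimates before any comparison: transcripts whose per-site
coverage CV exceeds 1 (sample sd; an all-zero profile is excluded as
undefined), and transcripts whose relative share differs ≥ 10-fold between
two estimation methods (shares, not raw values, since methods report on
different scales; a share of zero in exactly one method is a maximal
disagreement and is excluded, zero in both is retained as agreement).
Filters only ever remove ids; retained values are never altered.

## Buffering and silencing tests

Orthologs between two taxa are matched by reciprocal best hits under local
alignment (BLOSUM62, gap open 11 / extend 1, via Biopython); score ties break
by longer alignment, then smaller id. A curated two-column ortholog table can
be supplied instead. Over pairs quantified in all four vectors, the two
cross-taxon Pearson correlations (clr scale, Fisher-z 95% CIs) are compared
by the CI-mutual-exclusion rule: the layers differ when each R lies outside
the other's CI, and buffering is called only when additionally
R_protein > R_transcript. This rule is deliberately conservative (measured
type-I rate ≲ 1% at nominal 5%); a two-sample Fisher-z z-test is reported as
a secondary, clearly-labelled statistic for users who want a calibrated
p-value, but the verdict always uses the CI rule.

Silencing: over all transcripts with positive TPM, undetected ones (no
peptide row at 0% FPR in any replicate) are compared with detected ones by a
one-sided Mann–Whitney test (exact when both groups are < 20 and untied,
normal approximation otherwise; average ranks for ties). Also reported: the
abundance rank of the most-expressed undetected transcript and whether the
top quartile (configurable k) was fully detected. A pure detection threshold
predicts low p and a fully detected top quartile; silencing of highly
expressed toxins would violate both.

## The synthetic-data generator

The generator emulates the statistical structure of a venom study so that
every statistic can be validated by recovery:

| parameter | default | meaning |
|---|---|---|
| `n_toxins` | 60 | toxins per venom (observed venom systems run ~33–76) |
| `seq_len_range` | (80, 300) | toxin length in residues |
| `abundance_sigma` | 1.5 | sd of natural-log abundances (compositions span orders of magnitude) |
| `transcript_protein_rho` | 0.9 | correlation of log transcript vs log protein abundance |
| `n_replicates` | 3 | MS replicates |
| `replicate_cv` | 0.2 | CV of the multiplicative lognormal noise per peptide intensity |
| `detection_threshold` | 10³ | intensity below which a peptide goes unreported |
| `standard_load_fmol` | 50 | spiked internal-standard load |
| `fmol_scale` | 30 | median toxin load in fmol |
| `total_reads` | 5×10⁶ | reads distributed multinomially ∝ composition × length |
| `divergence_sigma` | 0.5 | sd of per-toxin log transcript shift between taxa |
| `buffering_beta` | 0 | fraction by which protein-level divergence is shrunk |
| `protein_noise_sigma` | 0.1 | independent protein-layer noise in the taxon pair |

Log transcript abundances are Normal(0, σ²), closed to a composition; log
protein abundances are ρ·z_t + √(1−ρ²)·z_e with independent z_e of equal
variance, so the population log-correlation equals ρ (verified empirically to
±0.03 at n = 10⁴). Read counts are multinomial with probabilities ∝
composition × CDS length; coverage is Poisson and near-uniform, except that
designated anomalous transcripts concentrate their coverage on 8% of sites
(coverage CV > 3), exercising the coverage filter. Toxin protein sequences
are random with K/R upweighted and are rejection-sampled to guarantee ≥ 4
internal cleavage sites and ≥ 4 distinct tryptic peptides; CDSs are random
reverse-translations. The internal standard is a fixed synthetic 106-residue
sequence (13 tryptic peptides, ~11.9 kDa) — quantification needs only
digestibility and molecular weight, and a real standard sequence (e.g. yeast
ADH1) can be supplied instead.

Peptide intensities: each protein's total intensity fmol × MW is split across
its distinct tryptic peptides by a symmetric Dirichlet(α = 2) share profile
(heterogeneous ionization, no zero shares, stable across replicates), then
multiplied by iid lognormal noise with CV = `replicate_cv` per peptide per
replicate. Because a protein estimate aggregates several peptides, its
replicate-level CV lands well below the per-peptide CV — with the default
0.2, well over 90% of quantified proteins show CVs < 0.3, the regime
reported for real venom MS data. Peptides below the detection threshold are
omitted from that replicate; the standard is always reported in full.

The default detection threshold (10³, ~0.2% of a median protein's total
intensity) is set so that censoring is confined to the rarest toxins: the
quantified set is then essentially unbiased, matching the observed behaviour
of real venom studies where nearly all toxins are detected and quantification
QC is tight, while the weakest transcripts still drop out and exercise the
silencing analysis. Raising the threshold is the intended way to study
detection bias itself.

**Ideal mode** allocates intensities so that both quantification methods are
exact: the three top-ranked peptides of every protein (standard included)
carry a summed intensity of exactly c × fmol for a global constant c, and the
total over all peptides is exactly fmol × MW. A literally identical share
vector across proteins would *not* make the top-3 method exact (its estimate
would carry a factor MW_p·s3_p / MW_std·s3_std), so exactness is pinned by
construction instead; this gives the whole pipeline an algebraic oracle —
both methods recover true fmol to ≤ 10⁻⁹ relative error.

Taxon pairs: per-toxin log transcript shifts d ~ Normal(0,
`divergence_sigma`²) are applied to taxon B; the protein layer receives
(1 − β)·d plus independent Normal(0, `protein_noise_sigma`²) noise. β = 0
makes protein divergence mirror transcript divergence; β = 1 buffers protein
levels fully toward taxon A. β acts only on the protein layer so the
buffering hypothesis is isolated as a single recoverable parameter. Orthology
ground truth is the identity map.

### What the generator does not emulate

Raw reads, assembly, and mapping (counts and coverage are generated
directly); chromatography, spectra, and spectral search (intensity tables are
generated directly, FPR is always 0); a nontoxin background proteome; shared
peptides between paralogs (every generated peptide row is assigned to one
protein — real venom gene families share tryptic peptides, which inflates
top-3 estimates in ways the tests here cannot detect); correlated noise
between replicates (batch effects); and length/composition biases of real
ionization. Passing recovery tests therefore demonstrates correctness of the
estimators and statistics under the stated noise model, not robustness to
every artifact of real LC-MS or RNA-seq data.

## Numerical choices and degenerate inputs

* CVs use the sample standard deviation (n − 1); CV of fewer than two values
  is NaN, never silently zero.
* `close`/`clr` reject zeros and negative values; clr input must sum to 1
  within 1e-8; clr outputs sum to 0 within 1e-9 by construction.
* Pearson CIs are degenerate (r, r) at |r| = 1; Fisher-z CIs require n ≥ 4.
* Spearman on a constant vector raises rather than returning NaN.
* Alignment divergence between co-optimal alignments is made deterministic by
  the canonical traceback; the divergence bound |len(a)−len(b)|/(len(a)+len(b))
  ≥ threshold prunes hopeless pairs before any DP work during clustering.
* The cross-method filter treats a ratio of exactly 10 as a discrepancy
  ("10-fold or higher"); the coverage filter retains CV exactly 1.
* All generators are deterministic functions of explicit integer seeds
  (numpy `default_rng`); pipeline reruns with identical config and seed are
  bit-identical, and reports carry a config hash.

## Problem sizes

Recovery simulations in the test suite use 60-toxin systems (500 seeds for
concordance recovery per target correlation and for each buffering error
rate, 200 seeds per buffering level for the monotonicity check, 200 seeds for
replicate-QC emulation); `scripts/acceptance.py` uses 50 systems for
concordance and QC summaries, 200 seeds per buffering rate, and 100 for the
detection-threshold summary. These sizes give Monte-Carlo standard errors
comfortably below the margins being asserted.
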