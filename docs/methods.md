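# Methods

`panrep` analyses multi-round in-vivo phage-display selections of VHH
(single-domain antibody) libraries and ships a simulator that generates the
same kind of data with known ground truth.  This note records the models,
the defaults and why, the numerical choices, and what the synthetic data do
and do not establish about real data.

## The selection model

A library of `n_clones` VHH clones carries initial frequencies drawn from a
lognormal abundance law (μ = 0, σ = 1; only the shape matters, frequencies
are normalized).  Each biopanning round r and cell subtype s performs

1. **capture** — a multinomial draw of `capture_size` phage with per-clone
   probability ∝ frequency × affinity(s).  Non-binders have affinity 1
   (`background_affinity`); each planted binder carries a multiplier
   κ ~ lognormal(ln 8, 0.3) for its target subtype *and for the bulk CD45
   pool*, since its target cells sit inside the bulk population;
2. **amplification** — captured counts are perturbed per clone by
   exp(N(0, `amplification_noise_sd`)) (default 0.3) and renormalized.

The amplified **bulk (CD45) pool seeds the next round**; the five sorted
subtype streams are measurements of the current pool, not lineages.  BP0 is
the bulk capture of the naive library before the first full round.
Replicate "mice" are independent lineages from the same library.

Capture sizes are drawn uniformly from the experimental per-subtype phage
yield range 4×10⁶–6×10⁷, scaled by `capture_scale` (default 10⁻³) to desk
size.  Sequencing draws `reads_per_sample` read pairs (default 4,500, a
1:100 scaling of the experimental ~450,000) multinomially from the captured
counts.

**Binder rarity.** In a ~2×10⁹-clone library any individual binder is far
below the mean clone frequency.  A desk-scale library of 10³–10⁴ clones
cannot represent that ratio directly, so planted binders' initial
frequencies are additionally scaled by `binder_rarity` (default 0.02).
Without this, binders saturate the pool before BP2 and the late-over-early
screen — which presumes that early rounds are still pre-saturation —
degenerates.  With it, the simulator reproduces the experimentally observed
dynamics: strong enrichment between BP1 and BP2, saturation at BP3–BP4,
disappearance of the initially most abundant clones, and a sharp diversity
drop after BP1.

## Library composition and amplicon geometry

CDR3 lengths follow a discretized normal (mean 18, sd 4) truncated to
1–36 aa, giving an exact median of 18 aa, the profile of the naive library;
CDR1 and CDR2 lengths are uniform on 5–8 and 6–9 aa.  CDR residues are
uniform over the 19 standard amino acids excluding cysteine (unpaired
cysteines would shadow the framework anchors).  Framework segments are a
fixed VHH consensus scaffold; every residue's codon is chosen uniformly
among synonymous codons per clone, so distinct nucleotide clonotypes
collapse onto shared amino-acid clonotypes.

Amplicons are `FLANK_5P + CDS + FLANK_3P` with fixed flanks of 90 and
85 nt.  With the default CDR ranges, amplicon lengths span 457–580 nt, so
every amplicon is mergeable from 2×300 nt reads with the 20 nt minimum
overlap (2×300 − 20 = 580).  This deliberately departs from the wet-lab
550–850 bp gel band: real amplicons in that band beyond ~580 nt cannot be
overlap-merged from PE300 reads at all and are instead assembled against a
germline reference by tools like MiXCR.  `length_filter` keeps the wet-lab
550/850 defaults for real data; the simulated pipeline uses 450/850.

Sequencing errors are independent per-base substitutions at
`seq_error_rate`, with Phred strings encoding that rate.  The default 10⁻⁴
is the *effective* rate of a merged, quality-filtered amplicon (raw MiSeq
substitution rates are ~10-fold higher; mean-quality filtering and
quality-weighted overlap consensus absorb much of that).  Indels, chimeras
and helper-phage contamination are not modeled.

## Reconstruction and annotation

Read pairs are merged by scanning alignment offsets with overlap ≥
`min_overlap` (20 nt) and accepting the lowest mismatch rate if ≤
`max_mismatch_rate` (5%); overlap disagreements resolve to the
higher-quality base (ties to read 1).  A k-mer seed search makes the common
case fast; an exhaustive offset scan is the fallback, so results do not
depend on the seeds.  Merged amplicons below mean Phred 20 are dropped
(conventional threshold, declared rather than inferred).

The CDS between the flanks is translated in the anchored frame and
annotated against the scaffold by locating FR2, FR3 and FR4 with
mismatch-tolerant search (≤ 3 mismatches per segment) inside CDR-length
windows wider than any library design (CDR1/2: 1–20, CDR3: 1–40 aa);
boundaries transfer from scaffold coordinates as 0-based half-open
amino-acid intervals.  A record is **complete** iff the four anchors match
(FR1-terminal Cys, FR2-initial Trp, FR3-terminal Cys, FR4 [WF]-G-x-G),
there is no internal stop, no ambiguous residue falls in a CDR, and the
CDR3 length is 1–36 aa.  Partial records are removed before clonotyping.

This single-scaffold annotator replaces a germline-database aligner and is
exact for single-framework (synthetic or immunized single-clan) libraries;
**real repertoires with framework diversity need a germline aligner
(MiXCR/IgBLAST) at this stage** — everything downstream operates on
clonotype tables and is unchanged.

## Diversity statistics

For clonotype proportions pᵢ: Shannon H = −Σ pᵢ ln pᵢ (nats; divide by
ln 2 for bits), Simpson Σ pᵢ², inverse Simpson, and Hill numbers
D_q = (Σ pᵢ^q)^{1/(1−q)} with D₁ = e^H by continuity; D₀ = S_obs and
D₂ = 1/Σ pᵢ² are identities asserted in tests at 10⁻⁹.  Rarefaction uses
the analytic hypergeometric expectation E[S(m)] = S_obs − Σᵢ C(n−xᵢ, m)/
C(n, m), evaluated via log-gamma for stability; extrapolation is
Chao1-based: f̂₀ = ((n−1)/n) f₁²/(2f₂) (or ((n−1)/n) f₁(f₁−1)/2 when
f₂ = 0), S(n+m*) = S_obs + f̂₀[1 − (1 − f₁/(n f̂₀+f₁))^{m*}], flat when
f₁ = 0, and capped at 2n by default (standard practice; configurable).
Rank bins default to [1–10], [11–100], [101–10³], [10³–10⁴], [10⁴+] and
count bins to {1}, {2–3}, {4–10}, {11–30}, {31–100}, {101+} — common
repertoire-analysis conventions, configurable.  Bootstrap confidence
intervals are not implemented.

## Enrichment screen and selectivity

Counts are pooled across replicates by summation first; a pseudocount
(default 0.5) is then added to every clone in every round of a stream, and
per-round proportions computed.  A clone's enrichment ratio is
(p₃+p₄)/(p₁+p₂); it **passes** when the ratio exceeds `min_ratio` (default
1) and its raw BP3+BP4 count reaches `min_late_count` (default 2).  The
screen is depth-invariant exactly at pseudocount 0 and to O(pc/n)
otherwise.  It is a screen, not a significance test — the experiment
provides no replicate-variance model.  Under a neutral null the per-clone
pass probability is bounded by P(late reads ≥ min_late_count), the
documented false-positive bound the tests check against.

Selectivity: for each passing clone, a_{c,s} = mean pseudocounted BP3/BP4
proportion in subtype s; shares r_{c,s} = a_{c,s}/Σ_{s'} a_{c,s'} (rows sum
to 1; a z-score mode exists behind a flag).  The assigned subtype is the
arg-max share, with exact ties flagged ambiguous and broken by the fixed
roster order.  Share-of-total was chosen over z-scores for
interpretability; the normalization is this package's choice.  Sanger
comparison deduplicates annotated inserts at the CDR3 amino-acid level and
asks whether each CDR3 occurs in any BP3/BP4 table, matching how picked
clones are matched to sequencing in practice.

## Documented end-to-end scenario

`panrep.pipeline.default_scenario_config(seed)`: 1,000 clones, 10 planted
binders per subtype, 3 replicates, 4,500 read pairs per sample,
`capture_scale` 10⁻² (so the per-clone captured copy number of ~40–600
does not extinguish average clones at this library size; founder loss then
affects only the rare tail, as at full scale).  Two screen constants are
recalibrated for desk depth: `min_late_count` 5 (at ~13,500 reads per
round and stream, near-detection-limit clones are invisible early yet
sporadically yield 2–3 late reads by shot noise — a floor absent at
450,000-read depth) and `min_ratio` 2 (per-round amplification drift alone
produces spurious ratios up to ~1.5, while affinity-driven enrichment gives
ratios ≥ 10 in this geometry).  At this scenario the screen recovers
planted binders with precision ≈ 1.0 and recall ≈ 0.95, and the
selectivity matrix assigns essentially all recovered binders to their true
subtype; the tests assert ≥ 0.9 for all three at a fixed seed.  Binders
lost to recall are founder-loss extinctions (initial frequency ~10⁻⁶,
expected captured copies ≪ 1), which also occur in the real experiment.

## Determinism and numerics

All randomness derives from one integer seed; per-sample substreams are
keyed by (seed, replicate, round, subtype), so outputs are byte-identical
across runs and independent of processing order.  Clonotype ordering is
count-descending with lexicographic tie-break; rank-bin and arg-max ties
are broken deterministically.  Frequency vectors are validated to sum to 1
within 10⁻⁹.  Empty tables reject statistics with explicit errors.

## What the simulator does not show

Passing tests on synthetic data demonstrate the pipeline's correctness
against its own generative model, not performance on real data: the
simulator has a single framework scaffold (no germline diversity or
somatic hypermutation), substitution-only errors (no indels or PCR
chimeras), a memoryless lognormal amplification bias, subtype-disjoint
binders by default (a `shared_binders` switch exists), and no modeling of
absolute phage titers.  Reads-per-unique-VHH ratios observed in any
particular experiment are likewise not calibration targets; only the CDR3
length profile and the qualitative selection dynamics are.
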