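# Methods

`hydsel` reimplements, as a tested pipeline on synthetic data, the
computational analyses surrounding a genetic selection for O₂-tolerant
FeFe-hydrogenases: simulating error-prone PCR (epPCR) mutant libraries,
testing charge-change classes of isolated mutations for enrichment against a
Monte Carlo null, mapping mutations onto linear protein architecture
(truncations, surface-accessible windows), fitting O₂-inactivation kinetics
and colony-size dose-response curves, and quantifying colonies on plate
images. This note records the models, the defaults and why they were chosen,
what the generators do and do not emulate, and the numerical decisions that
were genuinely open.

## The epPCR error model

A mutagenized clone of a CDS of length L nt acquires a number of
substitutions K ~ Poisson(μL/1000), truncated at L, where μ is the kit's
target rate in mutations/kb (default 4.5, a standard epPCR operating point).
The Poisson law follows from treating per-site errors as independent and
rare; the vendor protocols state only the target frequency. Substitution
positions are uniform without replacement (a physical base mutates once per
clone); the replacement base is drawn from the spectrum row of the reference
base. The spectrum is a 4×4 nonnegative weight matrix with zero diagonal,
row-normalized to conditional probabilities.

Kit-specific substitution preferences are generally unpublished, so the
default matrix is uniform over the 12 substitution types. A documented
alternative, `MutationSpectrum.eppcr_biased(transition_weight=3)`, favors
transitions three-fold — the dominant qualitative bias of Taq-family
polymerases — and any matrix can be supplied as YAML for faithful
reproduction of a particular kit. Results depend on the spectrum; both the
spectrum and the seed are echoed into every report.

Sampling is vectorized: position sets are drawn by rejection (clones with an
intra-clone duplicate are redrawn wholesale, which is exact), falling back
to permutation sampling for the pathological regime K ≳ L/4.

## Mutation classification and the charge taxonomy

Each substitution is classified by translating the parent codon and the
fully mutated codon with the standard genetic code: silent, missense, or
nonsense. Missense changes are labelled by the charges of the original and
replacement residues — positive {K, R}, negative {D, E}, neutral everything
else — giving nine charge-change classes. Histidine is neutral by default
(its protonation is ambiguous at physiological pH) and can be moved to the
positive set; none of the headline counts involve histidine. When two
substitutions hit one codon, both are judged against the jointly translated
codon — the simplest rule consistent with the final protein.

Two bookkeeping corners deserve note. Mutations striking the CDS's terminal
stop codon can produce a sense codon (stop-loss); these fit none of the nine
classes, nonsense, or silent, and are tallied in their own bucket so that
class counts + nonsense + silent + stop-loss always equals the number of
mutations. The enrichment test ignores the bucket. Mutations downstream of
an introduced stop are still classified codon-by-codon; truncation analysis,
not classification, accounts for the lost tail.

## The Monte Carlo null and enrichment test

Selection returns a batch of n_batch clones. To ask whether a charge-change
class is overrepresented, N replicate batches of the same size are simulated
from the epPCR model with no selection, every mutation is classified, and
pooled per-class counts are recorded per replicate. Confidence intervals are
percentile intervals of the replicate counts (2.5/97.5 for 95%). The
p-value is the add-one empirical upper tail, p = (r + 1)/(N + 1) with r the
number of replicates at or above the observed count — never zero, and
conservative (super-uniform) under the null. No multiple-testing correction
is applied across the nine classes; reports carry the number of classes so
a reader can apply one.

The library default is N = 10⁵ replicate batches; the test suite and
acceptance runs use N = 10⁴ (and 5·10³ for the type-I audit), sizes at which
the per-class means are stable to a few percent and a batch-12 null builds
in about two seconds. Silent and nonsense mutations are simulated and then
set aside, not prevented, so the nonsilent load per clone is realistic.

Calibration is tested three ways: (i) conditioning batch-size-1 replicates
on exactly one mutation, class frequencies match an exhaustive enumeration
over all (position, replacement) pairs to within binomial error — and
per-class *means* match enumeration × expected load up to the analytically
bounded rate of same-codon double hits, which single-mutation enumeration
cannot see; (ii) feeding null-generated batches back through the test keeps
the rejection rate at α = 0.05 below α + 3 SE; (iii) a 3× planted
positive→neutral bias at batch 12 is flagged (p < 0.05) in ≥ 90% of trials.

## Planted-bias generation

The alternative hypothesis generator enriches one target class by a factor
b ≥ 1 while leaving everything else untouched. It exploits an exact
property of the (truncated) Poisson mutation process: tilting the law by
b^(number of target-class mutations) is equivalent to superposing
non-target mutations at their null rate λ(1 − q) with target-class
mutations at rate λqb, where q is the null probability that a mutation
falls in the target class (computable from the spectrum and parent
composition). Each component samples its (position, replacement) pairs from
the corresponding conditional law; clones with duplicate positions are
redrawn. At b = 1 the two components recombine into exactly the null
process, and the expected target count is exactly b times the null mean —
both properties are regression-tested. Batch-level rejection sampling with
weights b^T was considered and discarded: the weights are unbounded and,
for realistic means (λq ≈ 9 at batch 12), no feasible proposal pool
realizes the tilted mean.

## The emulated mutant summary

No raw sequences or per-variant tables are distributed with the study this
pipeline emulates, so `generate_mutant_summary` constructs a synthetic
selection outcome with the published accounting as its specification: 23
variants on a 574-residue parent (2 fully active, 9 partially active, 12
with no detectable activity) carrying 110 nonsilent mutations — 18 altering
lysines (4 K→R, 5 K→N, residue 390 hit twice, once to Ile and once to Asn),
9 nonsense mutations forming a truncation ladder (deepest member retaining
103 of 574 residues; late stops shedding 33 and 82 residues), and the rest
random missense. Lysine and truncation sites are planted by overwriting
codons (AAA, and CAA for C→T stop creation) in a generated CDS; all counts
are then *recovered by classification*, not asserted — the test suite and
any consumer recount them from the TSV through the ordinary classification
path. A fixture domain architecture (four N-terminal ferredoxin-like
domains, one C-terminal catalytic domain, illustrative coordinates) supports
the truncation reports.

The summary uses a single synthetic parent: the published counts pool two
parent genes, but pooling across parents adds nothing to the arithmetic
being exercised and the enrichment machinery requires a common parent.
Batch sizes (8 and 12) remain free configuration of the null model.

## Truncation and surface mapping

Scanning the fully mutated CDS 5′→3′, the first stop at codon index s
leaves s − 1 residues; the parent's own terminal stop is not "introduced".
A named domain is lost if it starts at or beyond the stop, disrupted if the
stop falls inside it. The report agrees, by construction and by test, with
direct translation of the mutated sequence.

Per-residue diffusion-accessibility scores (consumed, not computed) are
smoothed with a centered moving average of window w = 5 residues — edges
use the truncated window, the simplest defensible rule — and thresholded:
maximal runs of smoothed score ≥ τ become surface regions. τ defaults to
the smoothed-profile mean (no published value exists) and is always
recorded in output. Regions shrink monotonically as τ rises (tested).

Clustering of mutated residues on surface regions is assessed by a
permutation test: redraw the same number of residues uniformly (with
replacement — a residue can be hit in several variants) from an eligible
set, defaulting to all residues, and take the add-one upper tail of the
in-region count. This is a formalization chosen here; the original
clustering claim has no published procedure. The planted-case p agrees with
the closed-form binomial tail and the test is super-uniform under uniform
placement.

## Kinetics and dose-response fits

O₂ inactivation follows first-order kinetics, A(t) = A₀·exp(−kt), fit by
nonlinear least squares in linear space (log-linear regression is available
as a cross-check but is biased by noisy low activities); the half-life is
t½ = ln 2 / k, and the identity t½·k = ln 2 is exact in every returned fit.
Replicate time courses are pooled. Data with no measurable decay over the
observed span (k·Δt ≤ 10⁻⁹) yield a flagged result with infinite half-life
and a warning, not an exception.

Colony size versus O₂ follows the decreasing sigmoid
area = a / (1 + exp(b·(O₂ − c))) — plateau a (area units), steepness b
(per % O₂), half-maximal inhibitory level c (% O₂); the fitted curve equals
a/2 at O₂ = c identically. Initialization: a₀ = max response, c₀ = dose
nearest a₀/2, b₀ = 1. A flat response is flagged non-identifiable; a
convergence failure raises an error carrying the initialization. No
four-parameter floor variant is offered: the model's floor is zero by
design. `compare_conditions` reports the shift Δc between two atmospheres
with a bootstrap CI of the difference.

Uncertainty for both fitters comes from a seeded residual bootstrap, 1000
resamples by default. The shipped flavor resamples *relative* residuals
(residual / fitted value), scales them by the small-sample leverage factor
√(n/(n − p)), and reapplies them multiplicatively before refitting. This
choice was made by a coverage audit: with 6 dose points and 3 parameters,
plain additive residual shuffling undercovers severely (≈50–58% for c at
nominal 95%) because residuals are shrunk and the noise in activity and
colony-size data is proportional to the signal; the relative-residual
scheme achieves ≈96% (decay t½) and ≈99% (sigmoid c) at assay-like designs
(3×5 time points at 8% CV; 6 doses × 50 colonies at 10% CV). The additive
variant remains available (`residual_mode="additive"`). Whether the
original study's ± intervals were resampling- or covariance-based is
unknown; this package's intervals are its own.

## Plate rendering and colony detection

The renderer draws n ≈ 50 colonies as disks with a logistic edge roll-off
(scale 1 px) at amplitude 0.6 over a tilted background (0.15 ± gradient)
with additive Gaussian noise σ = 0.05 — SNR ≈ 12 at the defaults, and ≥ 5
throughout the tested range — placed with a minimum rim-to-rim separation
inside a circular plate mask (95% of the half-width). Ground truth
(centers, radii) is returned for every rendered plate. Radii are normal,
mean 6 px, CV ≈ 17%, matching same-strain colony-size dispersion on a
multi-day plate.

Detection: median-filter background subtraction (31 px kernel), a global
Otsu threshold floored at 3.5 MAD-σ of the background (Otsu alone
manufactures a split even in pure noise, so signal-free plates must read
empty), connected components, an area filter, and optional watershed
splitting of touching blobs (off by default; ~50 colonies are plated
precisely to avoid crowding). Because the detection threshold sits below
the half-maximum of a soft-edged disk, raw component areas overestimate
disk areas; each call is therefore re-sized at half its robust peak height
on a 4× bilinearly upsampled patch (subpixel FWHM sizing). For colonies of
radius ≥ 4 px this keeps per-colony area error within 15%; below that,
pixel quantization dominates (a one-pixel rim on a 3 px colony is ~20% of
its area) and sizes should be read as indicative. Detection itself (recall
and precision ≥ 95% against ground truth with 3 px centroid matching) is
unaffected. Colonies are assumed brighter than background, as on an
inverted camera stage; a polarity flag inverts this.

The full dose-response loop — render plates whose mean colony area follows
the sigmoid across six O₂ levels (0–12.5%), detect, summarize, fit —
recovers c within ±0.5% O₂. At high O₂ the implied colony radius falls
below the detection limit and plates correctly read zero, mirroring plates
with no visible growth; the rendered plateau (400 px²) keeps the mid-curve
doses well resolved.

## What the generators do not emulate

Synthetic CDSs are random sequences with controlled GC, not hydrogenase
homologs: no codon-usage structure, no conserved motifs, no real
accessions. The mutant summary's random missense filler is uniform over
codon neighborhoods rather than spectrum-weighted, so the emulated table
exercises counting and truncation arithmetic, not spectrum inference.
Accessibility profiles are noise plus boxcar bumps, not physical surface
calculations. Plate images contain no condensation, reflections, satellite
colonies or barcode artifacts. Passing tests therefore demonstrate that the
*algorithms* are correct and calibrated under the stated statistical
assumptions, not that the assumptions hold for any particular real
instrument or gene.

## Problem sizes and reproducibility

Default analysis scales: null model N = 10⁵ (tests use 10⁴); bootstrap
1000 resamples (coverage audits use 200 × 200–300 trials); libraries of
10⁵ clones for rate checks; plates of 384² px with ~50 colonies. Every
stochastic entry point takes an explicit seed, uses a single
`numpy.random.Generator`, and echoes the seed into its outputs; generator
manifests record parameters and SHA-256 checksums so any artifact can be
regenerated bit-for-bit.

## Known limitations

Indels, PCR lineage effects and cloning artifacts are outside the error
model (the analyses concern point substitutions and stop truncations only).
The enrichment test treats batches as exchangeable pools; there is no
per-residue positional null. The permutation clustering test is this
package's formalization, not a published procedure. Exact reproduction of
any historical enrichment p-value would additionally require the true
parent gene sequences, the kit's actual substitution spectrum, and
replication far beyond desk scale; none are published, which is why the
null-model guarantees here are calibration properties rather than numeric
matches.
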