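# Methods

This note documents the models, decision rules and numerical choices
behind each pipeline stage, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Read preprocessing

Raw reads are collapsed to unique sequences with copy counts; T and U are
canonicalized to RNA so DNA-alphabet and RNA-alphabet inputs collapse
together. The retention cascade keeps unique sequences that are 15–26 nt
long, observed at ≥ 3 copies, and not low-complexity. Filters are
evaluated in a fixed order — length, then copy count, then complexity —
so a read failing several carries a deterministic first reason; the
partition (retained + discarded = input) is asserted by property tests,
and re-filtering a retained set is a no-op.

"Low-complexity" is inherently under-specified in small-RNA work; here a
sequence is masked if it has ≤ 2 distinct bases or any single base
exceeding 80 % of positions. Both cut-offs are parameters of
`is_low_complexity`. The main filter window defaults to 15–26 nt while
the discovery stage applies its own 16–26 nt window (`match_conserved`'s
`min_len`/`max_len`); both conventions appear in practice and both are
exposed as parameters rather than reconciled silently.

## Annotation removal

Reads matching mRNA, rRNA, tRNA, snRNA, snoRNA or repeat references are
removed before discovery. External alignment tools are replaced by
full-length ungapped substring matching: at 15–26 nt, local alignment
adds nothing, and an exact `str.find` scan (or an explicit ≤ k-mismatch
scan, default k = 0) is deterministic and dependency-free. Repeat
references are searched on both strands (consensus orientation is
arbitrary); other classes forward-only, configurable. A read hitting
several classes is assigned by fixed precedence rRNA > tRNA > snoRNA >
snRNA > repeat > mRNA, on the reasoning that structural-ncRNA catalogs
are higher-confidence annotations than mRNA fragments. Exact-mode calls
are verified in tests against a brute-force every-reference-every-offset
oracle.

## Conserved miRNA calling

A read is assigned to a known mature when its best single-offset ungapped
alignment has ≤ 1 substitution **and** an exactly matching seed (mature
positions 2–8). The seed-exact requirement operationalizes the biology —
conserved miRNAs share seeds — and resolves the ambiguity of where the
one tolerated mismatch may fall: anywhere outside positions 2–8.
Substitution-only counting (no indels) matches both the read lengths and
the "one mismatch" convention. Read ends may differ from the catalog
mature by up to 2 nt, since isomiR 5′/3′ end variation is ubiquitous;
overhanging bases are not counted as mismatches but reduce a reported
overlap score. Assignment is a function (one read → at most one mature):
ties break by fewest mismatches, largest overlap, then a configurable
species-priority list (zebrafish first, as the nearest well-annotated
fish), then name. Per-miRNA expression is the sum of assigned unique-read
counts, flagged when strictly above 10,000 reads.

Family assignment strips the species prefix, arm suffix (-5p/-3p/-star),
trailing paralog letters and locus copy numbers, so let-7a…let-7j → let-7
and mir-199-1/-199-2 → mir-199; miR/mir normalize to "mir". Unparseable
names become flagged singletons rather than errors.

## miRNA:miRNA\* duplex detection

"Aligned to the 5′ or 3′ end region" is made precise through the folded
structure: the terminal loop of the precursor's MFE hairpin delimits the
two arms, independent of sequence length. A star call requires (a) an
exact read occurrence entirely within the arm opposite the annotated
mature, (b) ≥ 10 base pairs (configurable) between the read span and the
mature region in the folded structure, and (c) highest abundance among
qualifying reads, ties to the 5′-most. The canonical 2-nt 3′-overhang
geometry of Dicer products is deliberately **not** enforced — it is not
part of the stated decision rule, and end-heterogeneous reads would fail
it spuriously. Star conservation against a known-star catalog uses the
same alignment scan without the seed requirement: ≤ 3 mismatches →
conserved, otherwise needs-validation.

## Hairpin folding

The folder replaces an external MFE program with an internal dynamic
program restricted to structures with **no multibranch loops**: chains of
nested pairs forming one helix with bulges/internal loops and a single
terminal loop. Every precursor structure of interest is a simple
stem-loop, and the restriction makes the search space small enough that
`enumerate_structures` can exhaustively list it for sequences ≤ 18 nt —
the oracle that certifies the DP (200 random sequences per run, exact
energy agreement).

Energy model: nearest-neighbor stacking free energies for the 6 pair
types {AU, UA, GC, CG, GU, UG} plus size-dependent initiation penalties
for hairpin, bulge and internal loops, with Jacobson–Stockmayer
log-extrapolation beyond the tabulated sizes and a capped asymmetry
penalty for internal loops. Watson–Crick stack values follow Xia et
al. (1998); wobble stacks and loop tables are approximate Turner-2004-
style values. Constants ship as YAML package data
(`mirmeta/data/nn_energies.yaml`) so another parameter set can be swapped
in without code changes. Omitted on purpose: terminal AU/GU penalties,
dangling ends, coaxial stacking, sequence-dependent loop bonuses,
pseudoknots. Consequently absolute ΔG values differ from mfold or
ViennaRNA; only the ≤ −15 kcal/mol criterion behaviour is treated as
reproducible, and an RNAfold cross-check test asserts threshold agreement,
not energy equality.

Numerics: energies are integer centi-kcal/mol internally, making ties
exact; ties prefer more pairs, then the first option in the fixed
traceback scan order, so output is byte-deterministic. Minimum terminal
loop 3 nt; internal loops capped at 30 unpaired nt total (comfortably
above the 18-nt criterion bound); folding domain 30–200 nt (overridable),
O(n²·c²) time — all 20 fixture precursors fold in about 2 s.

Criteria interpretation. Criterion 2 ("errors in one bulge ≤ 18") is read
as: no single bulge/internal loop may contain more than 18 unpaired
nucleotides summed over both sides — almost certainly what the original
rule intended, but an interpretation, and configurable. The "stem" for
criterion 4 is every position between the outermost pair and the terminal
loop on either arm, so mature bases inside stem-side bulges still count
as "in the stem". A zero-pair structure fails all structural criteria but
still yields a complete report.

## Microarray analysis

Background (per-array scalar or per-probe vector) is subtracted and
floored at zero; a pseudocount of 1.0 makes floored signals loggable.
Cyclic LOWESS normalization iterates over all array pairs, fitting a
locally weighted regression of M (log2 ratio) on A (mean log2 intensity)
with span 0.3 and moving half the fitted bias out of each array;
iteration stops when the largest |median M| falls below 1e−3 or after 5
passes. Detection is mean replicate signal strictly above 32. Differential
expression uses a Student (equal-variance) two-sided t-test on 3 vs 3
replicates — Welch degrees of freedom are unstable at n = 3; Welch is
available by flag — with significance at raw p < 0.01 and no
multiple-testing correction, mirroring the original analysis; a BH-FDR
flag exists for reuse beyond reproduction. Zero variance in both groups
with equal means gives p = 1 by convention. Significant probes split into
high/low tiers at mean signal 500 (larger stage mean). For presentation,
rows are z-scaled, clipped to ±1.5, and ordered by average-linkage
hierarchical clustering on Euclidean distance with rows pre-sorted by
name for deterministic tie-breaks.

## qPCR quantification

ΔCt = mean(target Ct) − mean(reference Ct) per stage against the 5S rRNA
control; ΔΔCt = ΔCt(test) − ΔCt(calibrator); fold = 2^−ΔΔCt. Significance
is a paired t-test across replicate-wise ΔCt values (replicate i of each
stage paired), p < 0.05. Shift invariance — adding any constant to every
Ct leaves the fold unchanged — holds exactly and is property-tested.

## Phylogenetic conservation

Families are classified by their lineage-presence pattern over
{mammals, birds, amphibians, fish, insects, nematodes} into: all-six;
five-no-nematode; vertebrate-tetrapod-fish (exactly the four vertebrate
lineages); fish-restricted (fish only); vertebrate-specific (any other
nematode/insect-free vertebrate subset). At lineage resolution the
tetrapod+fish template and "vertebrate-specific" would otherwise
coincide; mapping the exact four-lineage pattern to the former and proper
subsets to the latter keeps the five groups disjoint. Unmatched patterns
are labelled "other" with the raw pattern, and groups always partition
the input.

The packaged 91-row presence matrix encodes the published group sizes
(5 / 13 / 6 / 7 / 60) and every named member (the five pan-bilaterian
families; the seven fish-only miRNAs). The identities of the unnamed
families in the 13-, 6- and 60-row groups are not recoverable from text,
so those rows carry clearly synthetic placeholder ids (`nn-*`, `tf-*`,
`vs-*`); per-species refinements (e.g. families absent in human and
mouse) are representable as sub-annotations, not extra groups.

Substitution scans operate on pre-aligned equal-length matures ('-'
tolerated as a fifth symbol): a clade-specific position requires every
clade internally monomorphic with differing consensuses (clades with < 2
members are skipped with a warning); singleton divergence reports
positions where one focal sequence differs from an otherwise-monomorphic
background.

## Synthetic data: what it emulates, and what it does not

The generator produces, under one seeded config whose identical inputs
yield byte-identical outputs: hairpin precursors built as mature + loop +
noisy reverse complement (guaranteeing a foldable stem, arms placed 5′ or
3′ at random, lengths within 53–90 nt); reads drawn as error-perturbed
arm copies, contaminant-reference substrings, low-complexity junk and
random background, in configured proportions, with zeta-distributed copy
counts (exponent 1.5) so the ≥ 3-copy filter removes a real tail; read
lengths over 14–28 nt so both sides of the 15/26 window are exercised;
two-stage arrays where DE probes differ by a planted log2 effect
(default 3) under multiplicative log-normal replicate noise (CV 0.1) and
a probe subset is forced sub-threshold; and Ct plates where planted fold
changes become −log2(fold) cycle shifts around a constant reference.
FASTQ qualities are a constant high value: quality filtering happens
upstream of this pipeline in practice, so masking is a no-op hook.

Deliberately not emulated: sequencing-instrument artifacts and
base-calling error profiles, adapter chemistry, indels, ligation and PCR
biases, cross-hybridization, probe-specific affinity differences, and
genuine biological copy-number structure. Passing tests therefore show
the decision rules are implemented correctly and recover planted truth
under idealized noise — not that the pipeline's thresholds are optimal
for any real library.

## Problem sizes and default conditions

The analysis drivers use a 50,000-read library over 20 precursors with a
1 % per-base error rate, a 100-probe array with 10 planted 8-fold
effects, and triplicate Ct plates — a desk-scale study that exercises
every rule (including filter discards in all three classes and
sub-threshold probes). Statistical checks in the suite use 2,000-probe
null arrays for type-I calibration (99.9 % binomial envelope around 0.01)
and 10 × 10 planted effects for power (≥ 90 % observed at log2 effect 3,
CV 0.1, n = 3). Headline counts of the original full-scale study
(millions of reads, 140 conserved miRNAs, 57 star pairs, 66 DE calls)
require the deposited raw libraries and are outside what synthetic data
can or should reproduce.

## Known limitations

- The energy parameters are a minimal stacking+loops model; ΔG values are
  comparable only within this model.
- The folder's single-stem restriction cannot represent branched
  precursors (none occur in its intended inputs).
- Family parsing covers miRBase-style names; exotic nomenclature falls
  back to flagged singletons.
- Star detection requires an exact read occurrence in the precursor;
  sequencing errors on the star arm suppress calls rather than producing
  wrong ones.
- Cyclic LOWESS with few probes (< ~100) can absorb part of a large
  planted effect into the bias fit; the DE power checks are therefore
  defined on unnormalized planted arrays, and normalization checks use
  dedicated bias-injection fixtures.
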