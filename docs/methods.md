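# Methods

## Problem and model

Mature miRNAs sequenced from tissue are not a single sequence: reads carry
5′/3′ end variants (isomiRs) produced by imprecise Drosha/Dicer cleavage and
by post-transcriptional nucleotide addition. `isomirkit` explains each
small-RNA read as its reference mature sequence plus a small set of edits
and classifies the 3′ edits as **templated** (matching the parental hairpin
— a cleavage-position variant) or **non-templated** (absent from the hairpin
at that position — a tailing product, e.g. a 3′ adenosine). The hairpin is
the entire templated universe: genomic flank beyond the hairpin is not
modeled, so a 3′ extension is judged only against hairpin sequence. All
coordinates are 0-based half-open on the hairpin's 5′→3′ strand, in RNA
alphabet (input T is normalized to U).

Mature coordinates are recovered by exact substring search of the mature
FASTA within the hairpin FASTA (the minimal miRBase distribution carries no
coordinates); a GFF3 reader can override them. The arm (5p/3p) is assigned
by the interval midpoint relative to the hairpin midpoint.

## The decomposition

A read `r` is decomposed against a mature annotation `[start, end)` inside
hairpin `H` as

    shift5  — read 5′ start minus mature start (negative: 5′ extension)
    trim3   — templated bases missing from the mature 3′ end
    ext3    — templated bases beyond the mature 3′ end (match H)
    tail    — non-templated 3′ bases (do not match H, or H is exhausted)
    subs    — internal substitutions, (read position, ref, alt)

For each candidate `shift5 ∈ [−max_5p_shift, +max_5p_shift]` the read is
anchored at `start + shift5`; the decomposition at a fixed shift is then
unique: a read ending before the mature end yields `trim3`, an overhang is
split by greedy maximal matching against the hairpin's downstream context
(matched prefix → `ext3`, remainder → `tail`). Mismatches inside the core
anchor region — default mature positions [1, 18), which contains the seed
(positions 1–7 shared by all 3′ isomiRs) — disqualify the candidate; up to
`max_mismatch` (default 1) substitutions are allowed elsewhere. The winning
candidate minimizes total edits `|shift5| + trim3 + ext3 + |tail| + #subs`,
ties broken by smaller `|shift5|`, then smaller `|tail|`, then (across
matures) lexicographic mature id. Greedy maximal templated matching is
equivalent to this minimization — an `ext3`/`tail` split of fixed overhang
length has constant edit count, and the `|tail|` tie-break selects the
maximal templated prefix — and it makes "templated wherever possible" the
normative reading of the hairpin test.

Default limits: `max_5p_shift=2`, `max_3p_trim=5`, `max_3p_ext=5`,
`max_mismatch=1`. These are this package's reproducibility parameters, not
values taken from any particular aligner. When a mature is shorter than the
default core end, the core is clipped to the mature interval. Mixed
trim-then-tail forms are representable but disabled by default
(`allow_trim_tail`): the heart isoform inventory this package targets never
combines them, and enabling them enlarges the label space.

`reconstruct` inverts the decomposition from the reference and is the
round-trip oracle: for every error-free read, `reconstruct(decompose(r)) ==
r` exactly. The test suite additionally checks `decompose` against a
brute-force enumeration of *all* admissible decompositions on random
references up to 60 nt.

Labels are descriptive: `canonical`; `Trim <bases>` with the removed bases
listed from the 3′ terminus inward (a mature ending `…UGA` gives `Trim A`,
`Trim AG`, `Trim AGU`); `Plus <tail>` for non-templated additions; `Ext+n`
for templated extensions; a `5p±n` prefix for 5′ variants; and
`;sub<pos><ref>><alt>` suffixes for substitutions, concatenated in 5′, 3′,
substitution order. `structural_class` strips substitution suffixes, giving
the 5′/3′ structural class — the right unit when substitutions are
sequencing noise rather than biology.

## QC and counting

Reads are kept iff their length lies in [15, 30] nt and their mean Phred
score is ≥ 20. The length window is the standard mature-miRNA analysis
window (shorter reads are background, longer ones other RNA species); the
quality floor is a conventional default and deliberately explicit in
`QCParams` because no single community value exists. Length is checked
before quality, so the rejection statistics are an exact partition of the
input. Adapter trimming and UMIs are out of scope — input is assumed
adapter-free. Identical sequences are collapsed and counted; every read
counts wholly toward one isoform (no fractional multi-mapping). Profiles
report raw counts and RPM over assigned reads (sums to 10⁶).

## Profile comparison

Cross-sample comparison is descriptive: shared labels, per-label counts and
RPM, and top-n rank agreement `|top-n(a) ∩ top-n(b)|/n`. RPM is used across
samples because library sizes differ; no significance test is attached at
the isoform level. Cross-species remapping *is* the decomposition applied
to one species' canonical mature against the other species' reference, so a
one-base-shorter canonical reads as `Trim <base>` and a non-templated
one-base-longer canonical as `Plus <base>`.

## Gene-set overlap stage

`bh_adjust` is the Benjamini–Hochberg step-up procedure (delegated to
statsmodels; cross-checked in tests against a literal implementation).
`de_sets` builds up/down gene sets with the boundary semantics *fold change
≥ threshold* (inclusive) and *adjusted p < α* (strict; an inclusive ≤ is
available by flag since both conventions appear in practice). The fold
comparison runs in log2 space — `log2fc ≥ log2(1.5)` — which is exact in
floating point and identical mathematically. Tables that already carry an
externally computed `padj` are used as-is; BH is applied only when `padj`
is absent.

`venn_partition` returns the exact disjoint region partition of two or
three named gene sets; three is the maximum because that is the overlap
design this stage serves. `ddct_fold_change` implements 2^−ΔΔCt with per-row
ΔCt = target − reference Ct and group means.

`naive_count_test` exists so synthetic count matrices can be pushed through
the stage end-to-end: joint median-of-ratios size factors, log2 fold change
of normalized means, and a two-sided Welch t-test on log2(normalized + 1)
counts, with exact handling of zero within-group variance (p = 0 if means
differ, 1 otherwise). It is a stand-in with no dispersion model or
shrinkage, and is underpowered at triplicate scale: at NB dispersion 0.05
with 3 replicates per group its BH-corrected sensitivity for 2.8-fold
planted effects is only a few percent, rising to ~100% at 10 replicates
(`scripts/acceptance.py` reports both). Quantitative recovery guarantees
are therefore stated — and tested — in the zero-noise limit; real data
should be analyzed with a dedicated DE tool and its result table fed in
directly.

## Synthetic data

`make_reference` draws a hairpin `flank5 + mature + flank3` (defaults 8 +
22 + 8 nt). The mature is forced to end `…UGA` so the planted one-, two-
and three-base trims carry the names `Trim A`, `Trim AG`, `Trim AGU`, and
the first 3′-flank base is forced to differ from the tail nucleotide so a
planted `Plus A` is non-templated by construction. No secondary structure
is modeled — the caller uses only sequence and coordinates.

`sample_reads` draws each read's class from the planted distribution
(defaults: canonical 0.30, Trim A 0.25, Plus A 0.20, Trim AG 0.10,
Trim AGU 0.10, Ext+1 0.05 — trims may out-rank the canonical, as observed
in heart tissue), builds the exact class sequence, then applies independent
per-base substitution errors (default rate 0.005) and truncated-normal
Phred scores (mean 35, sd 3, clamped to [2, 41]). The error model is
substitution-only: indel errors would be indistinguishable from trim or
extension classes, and this confound is deliberately excluded. A truth
table records each read's class and error status; all generators are
byte-deterministic under the seed.

Recovery behavior: at error rate 0 the caller reproduces the truth table
exactly (all planted classes, zero unassigned). At rate 0.005 a read with
an error in the core region becomes a no-call (≈8% of reads at 22 nt) and
an error elsewhere adds a `;sub` suffix; recovered *structural-class*
fractions among assigned reads stay within 3 binomial standard errors of
the planted proportions at n = 10,000. What passing these tests does *not*
show: robustness to adapter contamination, ligation bias, indel error, or
multi-locus miRNA families — none of which the generator emulates.

`simulate_counts` produces per-group count matrices (default six groups —
a mimic control plus five treatments — with 3 replicates, 2,000 genes) with
lognormal per-gene baseline means (clamped ≥ 1) and planted gene sets whose
means are scaled by 2^±1.5 in their treatment. The default planted design
is the concordant/divergent structure of interest: three treatments share a
120-gene down core (plus 20 private each), two others share a disjoint
200-gene core (plus 50 private each), with an analogous up-regulated
layout. `dispersion` is NB dispersion (variance μ + φμ²); φ = 0 is the
exact zero-noise limit in which counts are floored means — with means ≥ 1
and |lfc| = 1.5, control and planted floors can never coincide, so the
pipeline recovers planted sets and Venn regions exactly.

## Numerical and degenerate-input choices

- Duplicate FASTA ids, out-of-alphabet characters (with position), missing
  matures and truncated FASTQ records (with record index) are hard errors.
- A mature occurring multiply in a hairpin uses the leftmost occurrence and
  logs a warning.
- `rank_isoforms` and `collapse` break count ties lexicographically, making
  every ordering deterministic.
- Empty profiles yield empty RPM maps (no division by zero); an empty
  reference set is a configuration error.
- p-values outside [0, 1] are domain errors; BH on an empty vector returns
  an empty vector.

## Limitations

- The templated test stops at the hairpin boundary; an extension templated
  only in genomic flank would be classified as a tail.
- One reference set, whole-read assignment: families of near-identical
  miRNA loci are resolved by the deterministic tie-break, not by
  probabilistic reassignment.
- The DE stand-in is for plumbing and zero-noise validation only (see
  above).
- Proportional Venn *rendering* is out of scope; the partition table is the
  output.
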