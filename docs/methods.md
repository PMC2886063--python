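# Methods

## The question and the design

After a whole-genome duplication (WGD), each retained gene exists as a pair
of paralogs A and B; a diploid outgroup that split off before the WGD
contributes a single ortholog C. The three pairwise evolutionary distances
within such a *gene trio* over-determine the three branches radiating from
the duplication node O, so each rate x ∈ {dS, dN} can be decomposed exactly:

    x(O→A) = (x_AB + x_AC − x_BC) / 2
    x(O→B) = (x_AB + x_BC − x_AC) / 2
    x(O→C) = (x_AC + x_BC − x_AB) / 2

These identities are definitional (they hold to machine precision by
construction) and can produce slightly negative branch values when the
three pairwise estimates are mutually inconsistent through sampling noise
or convergent substitutions; such values are reported as-is, never clamped,
so that downstream summaries see the estimator's true behaviour. A branch ω
is dN_branch/dS_branch and is flagged undefined when dS_branch ≤ 0
(dividing two noisy near-zero quantities is meaningless, and silently
substituting 0 or 1 would bias the fold-change statistics). Of the two
post-duplication branches, the one with lower ω is labelled *slow* and the
other *fast* (tie → O→A slow, deterministically); the trio's fold change is
ω_fast/ω_slow, +∞ when ω_slow = 0 with ω_fast > 0, undefined when either
branch ω is undefined. Infinite folds count as "high asymmetry" in the
fold grouping (they are evidence of extreme asymmetry, not missing data);
fully undefined folds are excluded and counted.

## Pairwise dN/dS

Two estimators are implemented against the universal genetic code, both
operating on codon alignments with pairwise deletion of codon columns
containing a gap, N or stop. Within a trio, columns are deleted *completely*
(a column missing in any of the three sequences is dropped for all three
pairwise comparisons) so the three estimates use identical data — an
assumption the decomposition identities quietly rely on.

**NG86** (equal-weight pathway counting). Per codon position, the
synonymous site fraction is the share of the single-base changes —
stop-codon targets excluded, per-position normalization, so S + N = 3 per
codon exactly — that preserve the amino acid; site counts are averaged over
the two sequences. Codon pairs differing at 2–3 positions are averaged over
all orderings of single steps; orderings passing through a stop codon are
excluded (if every ordering does, all are kept with stop-crossing steps
counted nonsynonymous — this never occurs for sense-codon pairs in the
universal code but is handled defensively). pS and pN receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 flags saturation.
NG86 is deliberately simple enough to verify by brute-force enumeration,
which is exactly how the test suite uses it.

**YN00** (the main estimator). The Yang–Nielsen (2000) approximate method
as a transparent reimplementation:

* κ (transition/transversion rate ratio, α/β) is estimated from the data:
  positions fourfold-degenerate in both codons and positions nondegenerate
  in both are pooled into two site classes; each class's transition and
  transversion difference proportions get a K80 correction (κ = 2·a/b with
  a the transition and b the transversion distance), and the two estimates
  are combined weighted by the number of observed differences in each class
  (the differences, not the sites, carry the information). Fallback κ = 2
  when neither class is informative; κ clipped to [0.01, 99].
* Synonymous/nonsynonymous site counts weight transitions by κ with the
  same per-position normalization as NG86 (so the S + N = 3·L identity is
  preserved, and at κ = 1 the counts coincide with NG86's).
* Codon frequencies are estimated from the data by F3×4 and enter the
  pathway weighting: a multi-step pathway is weighted by
  κ^(transitions) · ω^(nonsynonymous steps) · Π π(codons entered).
* dS and dN come from K80-style two-parameter corrections applied
  separately to the synonymous and nonsynonymous transition/transversion
  proportions, iterating ω = dN/dS to a fixed point (tolerance 1e-8 on
  successive (dS, dN), ≤100 iterations, non-convergence flagged with the
  last iterate).

Identical sequences return dN = dS = 0 with ω undefined (0/0). Exact
numerical identity with the original PAML binary is not claimed: the
method's defining components (data-driven κ, frequency- and κ-weighted
sites and pathways, iterative correction) are implemented, and correctness
is established against the NG86 brute-force oracle in the no-bias limit
(κ = 1, uniform codon usage), where the two methods must and do coincide.
That comparison is run on 2,000-codon pairs: with realistic (500-codon)
sequences the data-driven κ estimate itself has sampling noise of ±0.2
which moves dS by a few thousandths either way in *any* faithful YN00
implementation; longer pairs tighten κ and isolate the methodological
difference, which is what the check is about.

## The codon simulator

Trios are generated under a continuous-time Markov codon model on the 61
sense codons: q_ij ∝ κ^[transition] · ω^[nonsynonymous] · π_j for
single-nucleotide changes, zero otherwise (rates into stop codons are zero,
so simulated coding sequence never gains an in-frame stop). A root sequence
drawn from π evolves independently along O→A, O→B and O→C with per-branch
(dS, ω). Branch duration is calibrated so that the expected number of
synonymous substitutions per synonymous site equals the requested dS —
i.e. branch lengths are stated in the same units the estimators report,
which makes parameter-recovery experiments directly interpretable. The
transition matrix e^(Qt) is computed once per branch and reused across
trios.

Generator defaults are the study conditions: 408 trios, 500 codons,
post-duplication branches (dS, ω) = (0.0926, 0.0760) and (0.0942, 0.2063),
pre-duplication branch (0.3162, 0.0896) — the medians of the real trio
set — and κ = 2.0, a typical vertebrate coding-sequence value (the study
does not report a κ estimate). Codon frequencies default to uniform, which
makes the rate matrix symmetric and the uniform distribution stationary.
Because the A/B labels of real paralogs carry no information, the simulator
assigns the two post-duplication parameter sets to A and B in random order
per trio (`randomize_paralog_labels`, on by default); this makes the two
ortholog comparison sets exchangeable, as observed in real data. Recovery
experiments that check per-branch estimates against a fixed asymmetric
assignment switch it off.

What the simulator does *not* emulate: indels (no gaps are generated;
gap-column robustness is tested by injecting gaps post hoc), site-to-site
rate heterogeneity, selection variation along the sequence, biased codon
usage (available via `codon_freqs` but not default), and — important for
interpreting the fold-change group sizes — *between-gene* variation in
branch parameters: every simulated trio shares one parameter set, so the
spread of estimated fold changes reflects estimation noise only, and the
counts falling above 3× or below 1.75× do not match a real, heterogeneous
gene set. Passing tests therefore demonstrate estimator correctness and
pipeline integrity, not that real data would produce these group sizes.

Toy transcripts for the annotation stages plant a known structure:
geometric 5'/3' UTR lengths (means 120/300 bp, near the real full-length
cDNA set), ORFs of 50–400 codons with no internal in-frame stop, an
in-frame stop codon capping the 5' UTR with no in-frame ATG between it and
the true start (making the start-codon rule's answer unique), A-runs
elsewhere capped below the polyA threshold, and a polyA tail of 15–30 A's
with probability 0.5. Each transcript carries a homology hit covering its
whole protein and a forward/reverse 600-bp read pair, so clone completeness
(overlap vs gap) follows deterministically from transcript length.

## Annotation rules and their edge cases

* polyA masking: a run of ≥15 A's whose end lies within the final 50 bp
  (or reaches the end) is removed together with everything downstream;
  trimming repeats until no qualifying run remains, which makes the
  operation idempotent. The 50-bp window pins down "3' region" so genuine
  internal poly-lysine runs survive.
* Full-length candidacy: a hit aligning subject residues s1..s2 of a
  protein of length L at query offset q needs 3·(s1−1) nt upstream and
  3·(L−s2)+3 nt downstream (missing residues plus a stop). The ten best
  hits with e ≤ 1e-5 are tried in succession, the first that fits wins.
  The 14-column hit dialect has no subject-length column, so subject
  lengths default to s2 (alignment assumed to reach the C-terminus) and can
  be supplied explicitly.
* Start codon: nearest in-frame ATG at/upstream of the inferred subject
  start, else within 30 bp downstream (inclusive); then extended to the
  most 5' in-frame ATG below the first bounding in-frame stop. The
  downstream window may move the start past subject residue 1 (taken as
  written). Codons containing N never match ATG or stop patterns.
* Reverse-frame hits: the transcript is reverse-complemented before
  annotation and the orientation recorded (directional libraries make
  forward the default; the choice is conventional).
* Redundancy/confirmation "similarity" is percent identity over the aligned
  region of a local alignment (match +1, mismatch −2, gap −5/−2), the
  reproducible reading; redundancy is closed transitively (connected
  components) with the longest member as representative. The 200 bp in the
  redundancy rule is the alignment length. Contig confirmation looks for a
  100%-identity local match (equivalently a longest common substring)
  covering ≥95% of the reference.
* Trimming maps query-protein coordinates onto members assuming the hit
  region is colinear (ungapped); members are visited by decreasing
  alignment length (ties: higher percent-positives, then id), the ≥75%
  positives filter applies to the original hit before trimming, and a
  member that would push the common region below 100 aa / 300 nt is
  removed rather than shrinking the region.
* Pair screening drops the shorter sequence of a violating pair (later id
  on ties): dropping the shorter member retains maximal information and is
  deterministic; screening iterates to a fixed point.
* The built-in protein aligner is a star alignment around the longest
  sequence (BLOSUM62, gap open −11 / extend −1, "once a gap always a
  gap"); it exists so the pipeline runs without external tools, and an
  externally computed protein MSA is accepted wherever one is available.

## Statistics

Kruskal–Wallis uses the standard rank statistic with tie correction
(scipy), with the all-values-identical degenerate case mapped to H = 0,
p = 1; p-values come from the χ² upper tail with df = k−1, adequate at
these group sizes (n ≈ 400). Fold-change groups use the strict inequalities
as printed (> 3×, < 1.75×). Category proportions are count/group-total
percentages rounded to one decimal, with unmapped genes counted as
"unannotated" and an optional alias table for collapsing categories.

## Problem sizes

The default test-and-reproduction sizes are 408 trios × 500 codons for
study-scale runs, 300 trios for parameter recovery, 100 pairs × 2,000
codons for the no-bias estimator comparison, and 200 toy transcripts for
annotation accuracy; a full acceptance run completes in well under a
minute on one CPU.

## Known limitations

* YN00 here is a faithful reimplementation of the method, not a
  bit-for-bit port of the PAML program; third-decimal differences in dS on
  real data are expected.
* The trio builder trusts hit coordinates for trimming rather than
  realigning; heavily gapped homologies would be trimmed imprecisely.
* Branch decomposition assumes rate additivity across branches; strong
  multiple-hit saturation (flagged) or convergent evolution degrades it.
* The fold-change group sizes on simulated data are not comparable to a
  heterogeneous real gene set (see the simulator section).
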