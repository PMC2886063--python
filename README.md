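# paralogpace

Rates and asymmetry of molecular evolution after a whole-genome duplication
(WGD), built around the Atlantic salmon / northern pike system.

Salmonids carry the remains of an autotetraploidization that occurred
25–100 Mya in their common ancestor, and many duplicated gene copies
(paralogs) survive. Comparing each pair of salmon (*Salmo salar*) paralogs
with the single-copy ortholog of a diploid outgroup — northern pike (*Esox
lucius*), whose lineage split off before the WGD — makes it possible to ask
how selective pressure changed after duplication, and whether it changed
symmetrically on the two copies.

`paralogpace` implements the full analysis as a tested pipeline:

1. **Full-length cDNA annotation** (`orf_annotator`, `clone_resolver`,
   `io_formats`): decide whether an assembled transcript can contain the
   entire homologous reference protein (e-value ≤ 10⁻⁵, top 10 hits), place
   the start codon from the alignment with an upstream-extension rule,
   close the ORF at the first in-frame stop, mask polyA tails (≥15
   terminal-region A's), classify paired-read clones complete/incomplete,
   collapse redundancy (≥98% identity over ≥200 bp) and confirm references
   against contigs (100% identity over ≥95% of length).
2. **Gene-trio construction** (`trio_builder`): cluster translated-search
   hits per protein query (e ≤ 10⁻¹⁰, ≤100 hits, ≥50% query coverage), trim
   members to a common aligned region (≥300 bp / ≥100 aa, ≥75% positives),
   codon-align through a protein MSA, screen out alleles (>98% identity),
   distant homologs (<60%) and short alignments (<90% of the longer
   sequence), and keep clusters with exactly two salmon paralogs (A, B) and
   one pike ortholog (C).
3. **Rate estimation** (`rate_estimator`): pairwise dN, dS and ω = dN/dS by
   the Yang–Nielsen (2000) approximate method (data-driven κ, F3×4 codon
   frequencies), with Nei–Gojobori (1986) counting as an independent
   oracle. The three pairwise distances are placed on the branches
   radiating from the duplication node O by the half-sum relative-rate
   formulae

       x(O→A) = (x_AB + x_AC − x_BC) / 2
       x(O→B) = (x_AB + x_BC − x_AC) / 2
       x(O→C) = (x_AC + x_BC − x_AB) / 2     for x ∈ {dS, dN},

   giving per-branch ω for the two post-duplication branches and the
   pre-duplication (ancestral) branch.
4. **Asymmetry statistics** (`asymmetry_analysis`): per trio, the
   lower-ω post-duplication branch is the *slow* branch and the other the
   *fast* branch; distribution medians, Kruskal–Wallis comparisons, ω
   fold-change groups (>3× vs <1.75×) and gene-category proportion tables.
5. **Synthetic data** (`synthetic_data`): a continuous-time Markov codon
   simulator (HKY-style κ, ω, rates into stops zero) whose branch lengths
   are calibrated in dS units, plus toy transcripts with planted UTR / ORF
   / polyA structure, homology hits and paired clone reads — so every stage
   is testable with known ground truth and no downloads.

## Worked example

```python
from paralogpace import TrioSimConfig, simulate_trio_set
from paralogpace.pipeline import trios_to_rate_table, analysis_report

cfg = TrioSimConfig(n_trios=50, n_codons=500, seed=1)   # study-like defaults
trios, truth = simulate_trio_set(cfg)
table = trios_to_rate_table(trios, method="yn00")
report = analysis_report(table)
med = report["summary"]["medians"]
```

prints (via the snippet in `docs/methods.md`):

```
trios analysed        : 50
median paralog dS     : 0.1875
median ortholog dS    : 0.4219
median paralog omega  : 0.1481
median ortholog omega : 0.0972
median slow-branch omega : 0.0825
median fast-branch omega : 0.1982
median ancestral omega   : 0.0886
Kruskal-Wallis paralog vs ortholog omega: H=52.80, p=3.7e-13
```

Read: paralogs are much closer to each other (dS ≈ 0.19) than either is to
the pike ortholog (dS ≈ 0.42) — the duplication postdates the species
split. All ω ≪ 1, so purifying selection dominates, but paralog ω exceeds
ortholog ω (selection relaxed after duplication), and the per-branch view
shows the relaxation is asymmetric: the slow branch stays near the
ancestral ω while the fast branch runs ~2.5× higher.

The same pipeline runs from the shell:

```bash
paralogpace --seed 7 simulate-trios --out sim --n-trios 408
paralogpace rates --trios sim/trios.fasta --method yn00 --out rates.tsv
paralogpace analyze --rates rates.tsv --out report/
```

## Layout

```
src/paralogpace/
  io_formats.py        FASTA / trio supplement / 14-column hit tables, polyA masking
  orf_annotator.py     full-length candidacy, start-codon placement, ORF/UTR summary
  clone_resolver.py    clone completeness, reference selection, redundancy, confirmation
  trio_builder.py      clustering, trimming, codon alignment, screening, trio selection
  rate_estimator.py    NG86 and YN00 pairwise dN/dS, branch decomposition, fast/slow
  asymmetry_analysis.py medians, Kruskal–Wallis, fold groups, category proportions
  synthetic_data.py    codon-model trio simulator, toy transcript generator
  pipeline.py          end-to-end drivers
  cli.py               `paralogpace` command-line interface
```

See `docs/methods.md` for the model, parameter and design details.
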