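"""Brute-force Nei–Gojobori (1986) oracle, written independently of the
package implementation: plain per-codon loops, explicit pathway
enumeration via itertools.permutations, translation via Bio.Seq.

Rules (matching the classical method):
* per codon position, the synonymous site fraction is the share of the
  single-base changes (stop-codon targets excluded) that preserve the
  amino acid; site counts are averaged over the two sequences;
* codon pairs differing at k positions are averaged over all k! orderings
  of single steps, skipping orderings that pass through a stop codon
  (unless every ordering does, in which case all count and stop-crossing
  steps are nonsynonymous);
* codons containing non-ACGT characters are deleted pairwise;
* pS and pN receive the Jukes–Cantor correction d = -3/4 ln(1 - 4p/3).
"""

import itertools
import math

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate(codon):
    return str(Seq(codon).translate())


def syn_sites(codon):
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOPS:
                continue
            valid += 1
            if translate(alt) == translate(codon):
                syn += 1
        if valid:
            s += syn / valid
    return s


def path_steps(c1, c2, order):
    cur = c1
    steps = []
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
        steps.append((cur, nxt))
        cur = nxt
    return steps


def count_diffs(c1, c2):
    """(expected synonymous diffs, expected nonsynonymous diffs)."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    all_paths = [path_steps(c1, c2, order)
                 for order in itertools.permutations(positions)]
    # intermediate stops disqualify a pathway; keep all if none survive
    usable = [p for p in all_paths
              if not any(b in STOPS for a, b in p if b != c2)]
    if not usable:
        usable = all_paths
    sd = nd = 0.0
    for path in usable:
        for a, b in path:
            if a in STOPS or b in STOPS:
                nd += 1
            elif translate(a) == translate(b):
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def jukes_cantor(p):
    if p <= 0:
        return 0.0
    arg = 1 - 4 * p / 3
    if arg <= 0:
        return float("nan")
    return -0.75 * math.log(arg)


def ng86_brute_force(seq1, seq2):
    """Returns (dN, dS, S_sites, N_sites, codons_used)."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    codons = []
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k:k + 3].upper(), seq2[k:k + 3].upper()
        if set(c1) | set(c2) <= set("ACGT") and c1 not in STOPS and c2 not in STOPS:
            codons.append((c1, c2))
    if not codons:
        raise ValueError("no usable codons")
    S = sum(syn_sites(c1) + syn_sites(c2) for c1, c2 in codons) / 2
    N = 3 * len(codons) - S
    Sd = Nd = 0.0
    for c1, c2 in codons:
        sd, nd = count_diffs(c1, c2)
        Sd += sd
        Nd += nd
    dS = jukes_cantor(Sd / S) if S else 0.0
    dN = jukes_cantor(Nd / N) if N else 0.0
    return dN, dS, S, N, len(codons)
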