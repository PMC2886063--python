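"""Precomputed universal-genetic-code machinery shared by the rate estimators
and the codon simulator.

Everything here is derived once, at import time, from the standard (universal)
codon table:

* the 61 sense codons and their integer encoding;
* per-codon, per-position synonymous/nonsynonymous mutational-opportunity
  counts split by transition vs transversion (used for site counting);
* for every ordered pair of sense codons, the mutational pathways between
  them (orderings of the differing positions), with stop-codon-crossing
  pathways excluded, stored in flat CSR-style arrays so pairwise estimates
  can be fully vectorised.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

ALL_CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True for A<->G or C<->T changes."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _mutate(codon: str, pos: int, base: str) -> str:
    return codon[:pos] + base + codon[pos + 1:]


def _build_site_counts() -> np.ndarray:
    """Per codon, per position: (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) counts
    over the single-base mutational neighborhood, mutations into stop codons
    excluded."""
    out = np.zeros((N_SENSE, 3, 4))
    for i, codon in enumerate(SENSE_CODONS):
        aa = AMINO_ACID[i]
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                target = _mutate(codon, pos, base)
                if target in STOP_CODONS:
                    continue
                syn = AMINO_ACID[CODON_INDEX[target]] == aa
                ts = is_transition(codon[pos], base)
                out[i, pos, (0 if syn else 2) + (0 if ts else 1)] += 1
    return out


SITE_COUNTS = _build_site_counts()

# NG86 site counts (kappa = 1): per-position synonymous fraction among
# non-stop single-base changes, summed over the three positions.
_denom = SITE_COUNTS.sum(axis=2)
_syn_frac = np.divide(
    SITE_COUNTS[:, :, 0] + SITE_COUNTS[:, :, 1], _denom,
    out=np.zeros_like(_denom), where=_denom > 0,
)
NG86_SYN_SITES = _syn_frac.sum(axis=1)  # shape (61,), in [0, 3]


def _enumerate_pathways(ci: str, cj: str) -> list[list[tuple[str, str]]]:
    """All orderings of the differing positions as lists of (from, to) codon
    steps; pathways passing through a stop codon are dropped unless every
    ordering does."""
    diffs = [p for p in range(3) if ci[p] != cj[p]]
    paths, blocked = [], []
    for order in itertools.permutations(diffs):
        cur, steps, hit_stop = ci, [], False
        for pos in order:
            nxt = _mutate(cur, pos, cj[pos])
            steps.append((cur, nxt))
            if nxt in STOP_CODONS:
                hit_stop = True
            cur = nxt
        (blocked if hit_stop else paths).append(steps)
    return paths if paths else blocked


class _PathwayTables:
    """CSR layout over ordered sense-codon pairs (i*61+j).

    For pathway k:
      n_ts[k], n_nonsyn[k] -- transition / nonsynonymous step counts
      counts[k]            -- (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) step totals
      inter[k]             -- up to two intermediate sense-codon indices, -1 pad
    """

    def __init__(self) -> None:
        offsets = [0]
        n_ts, n_nonsyn, counts, inter = [], [], [], []
        ng_sd = np.zeros((N_SENSE, N_SENSE))
        ng_nd = np.zeros((N_SENSE, N_SENSE))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    offsets.append(len(n_ts))
                    continue
                paths = _enumerate_pathways(ci, cj)
                per_path = []
                for steps in paths:
                    c = np.zeros(4)
                    ts_tot = nonsyn_tot = 0
                    inters = []
                    for a, b in steps:
                        pos = next(p for p in range(3) if a[p] != b[p])
                        ts = is_transition(a[pos], b[pos])
                        if b in STOP_CODONS or a in STOP_CODONS:
                            syn = False  # stop-crossing fallback pathway
                        else:
                            syn = AMINO_ACID[CODON_INDEX[a]] == AMINO_ACID[CODON_INDEX[b]]
                        c[(0 if syn else 2) + (0 if ts else 1)] += 1
                        ts_tot += ts
                        nonsyn_tot += not syn
                        if b != cj and b not in STOP_CODONS:
                            inters.append(CODON_INDEX[b])
                    n_ts.append(ts_tot)
                    n_nonsyn.append(nonsyn_tot)
                    counts.append(c)
                    inter.append((inters + [-1, -1])[:2])
                    per_path.append(c)
                offsets.append(len(n_ts))
                mean = np.mean(per_path, axis=0)
                ng_sd[i, j] = mean[0] + mean[1]
                ng_nd[i, j] = mean[2] + mean[3]
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.n_ts = np.asarray(n_ts, dtype=np.float64)
        self.n_nonsyn = np.asarray(n_nonsyn, dtype=np.float64)
        self.counts = np.asarray(counts, dtype=np.float64)
        self.inter = np.asarray(inter, dtype=np.int64)
        # pair id for each pathway (inverse of offsets), for segment reductions
        self.pair_of_path = np.repeat(
            np.arange(N_SENSE * N_SENSE), np.diff(self.offsets)
        )
        self.ng_sd = ng_sd
        self.ng_nd = ng_nd


PATHWAYS = _PathwayTables()

# Degeneracy class per codon per position: number of synonymous single-base
# changes at that position (0, 1, 2 or 3).  4-fold degenerate <=> 3;
# nondegenerate <=> 0.  Used by the YN00 kappa estimator.
DEGENERACY = (SITE_COUNTS[:, :, 0] + SITE_COUNTS[:, :, 1]).astype(np.int64)

# Transition partner of each base at a position (for K80-style bookkeeping).
TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string (length divisible by 3) as sense-codon
    indices; codons containing a gap, N or a stop map to -1 (missing)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    seq = seq.upper()
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        out[k // 3] = CODON_INDEX.get(seq[k:k + 3], -1)
    return out
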