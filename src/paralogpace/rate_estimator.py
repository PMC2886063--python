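"""Pairwise dN/dS estimation and three-point branch decomposition.

Two pairwise estimators are provided:

* :func:`ng86_pairwise` — Nei–Gojobori (1986) equal-weight pathway counting
  with Jukes–Cantor correction.  Simple and fully enumerable, it serves as
  the independent oracle for the main estimator.
* :func:`yn00_pairwise` — the Yang–Nielsen (2000) approximate method: the
  transition/transversion rate ratio kappa is estimated from the data
  (fourfold-degenerate and nondegenerate site classes, K80 corrections),
  synonymous and nonsynonymous site counts are kappa-weighted, codon
  differences are partitioned over mutational pathways weighted by kappa,
  omega and F3x4 codon frequencies, and dS/dN come from K80-style two-
  parameter corrections applied separately to the synonymous and
  nonsynonymous classes, iterating omega to a fixed point.

Given the three pairwise rates within a trio (paralogs A, B and outgroup
ortholog C), the half-sum relative-rate formulae place substitutions on the
branches radiating from the duplication node O:

    x_OA = (x_AB + x_AC - x_BC) / 2
    x_OB = (x_AB + x_BC - x_AC) / 2
    x_OC = (x_AC + x_BC - x_AB) / 2      for x in {dS, dN}

Negative branch values (sampling noise / convergent substitutions) are
preserved, not clamped.  Per-branch omega is dN_branch/dS_branch; of the two
post-duplication branches the one with the lower omega is labelled *slow*,
the other *fast*, and their ratio is the trio's fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _codon_tables as ct
from .io_formats import GeneTrio

YN00_TOL = 1e-8
YN00_MAX_ITER = 100
DEFAULT_KAPPA = 2.0  # fallback when the site-class estimator is undefined


@dataclass
class PairwiseRates:
    dN: float
    dS: float
    omega: float            # nan when undefined (dS <= 0 or 0/0)
    S_sites: float
    N_sites: float
    codons_used: int
    kappa: float = float("nan")   # estimated by YN00 only
    saturated: bool = False
    converged: bool = True
    method: str = ""

    @property
    def omega_defined(self) -> bool:
        return not math.isnan(self.omega)


@dataclass
class BranchRates:
    dS_OA: float
    dS_OB: float
    dS_OC: float
    dN_OA: float
    dN_OB: float
    dN_OC: float
    omega_OA: float
    omega_OB: float
    omega_OC: float
    slow_branch: str | None = None   # {"OA", "OB"}
    fast_branch: str | None = None
    fold_change: float = float("nan")  # inf allowed; nan = undefined
    saturated: bool = False

    @property
    def labels_defined(self) -> bool:
        return self.slow_branch is not None


def _pair_counts(ia: np.ndarray, ib: np.ndarray) -> tuple[np.ndarray, int]:
    """Joint codon-pair counts over columns where both codons are sense
    codons (pairwise deletion of gap/N/stop columns)."""
    ok = (ia >= 0) & (ib >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no codon columns left after deletion")
    idx = ia[ok] * ct.N_SENSE + ib[ok]
    return np.bincount(idx, minlength=ct.N_SENSE * ct.N_SENSE).astype(float), n


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor multiple-hit correction; (distance, saturated)."""
    if p <= 0:
        return 0.0, False
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan"), True
    return -0.75 * math.log(arg), False


def _k80_correct(p: float, q: float) -> tuple[float, bool]:
    """Kimura two-parameter distance from transition (p) and transversion
    (q) proportions; (distance, saturated)."""
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0 or a2 <= 0:
        return float("nan"), True
    return -0.5 * math.log(a1) - 0.25 * math.log(a2), False


def _omega_of(dn: float, ds: float) -> float:
    if math.isnan(dn) or math.isnan(ds):
        return float("nan")
    if ds <= 0:
        return float("nan")
    return dn / ds


def ng86_pairwise(seq1: str, seq2: str) -> PairwiseRates:
    """Nei–Gojobori (1986) dN/dS.

    Synonymous/nonsynonymous site fractions come from the single-step
    mutational neighborhood of each codon (stop-codon targets excluded,
    per-position normalization); codons differing at several positions are
    averaged over all orderings of single steps, pathways through stop
    codons excluded.  pS and pN are corrected by d = -3/4 ln(1 - 4p/3).
    """
    ia, ib = ct.encode_codons(seq1), ct.encode_codons(seq2)
    if len(ia) != len(ib):
        raise ValueError("sequences differ in codon length")
    counts, n_codons = _pair_counts(ia, ib)

    marg_a = counts.reshape(ct.N_SENSE, ct.N_SENSE).sum(axis=1)
    marg_b = counts.reshape(ct.N_SENSE, ct.N_SENSE).sum(axis=0)
    S = 0.5 * (marg_a @ ct.NG86_SYN_SITES + marg_b @ ct.NG86_SYN_SITES)
    N = 3.0 * n_codons - S

    Sd = float(counts @ ct.PATHWAYS.ng_sd.ravel())
    Nd = float(counts @ ct.PATHWAYS.ng_nd.ravel())

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, satS = _jc_correct(pS)
    dN, satN = _jc_correct(pN)
    if Sd == 0 and Nd == 0:
        omega = float("nan")  # identical: 0/0
    else:
        omega = _omega_of(dN, dS)
    return PairwiseRates(dN=dN, dS=dS, omega=omega, S_sites=S, N_sites=N,
                         codons_used=n_codons, saturated=satS or satN, method="ng86")


def _f3x4_freqs(counts: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies (over the 61 sense codons) from the joint
    codon-pair counts of the two sequences."""
    marg = (counts.reshape(ct.N_SENSE, ct.N_SENSE).sum(axis=1)
            + counts.reshape(ct.N_SENSE, ct.N_SENSE).sum(axis=0))
    pos_freq = np.zeros((3, 4))
    base_idx = {b: k for k, b in enumerate(ct.BASES)}
    for i, codon in enumerate(ct.SENSE_CODONS):
        for pos in range(3):
            pos_freq[pos, base_idx[codon[pos]]] += marg[i]
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freq[0, base_idx[c[0]]] * pos_freq[1, base_idx[c[1]]] * pos_freq[2, base_idx[c[2]]]
        for c in ct.SENSE_CODONS
    ])
    return pi / pi.sum()


def _estimate_kappa(ia: np.ndarray, ib: np.ndarray) -> float:
    """Kappa from fourfold-degenerate and nondegenerate site classes.

    Positions that are fourfold degenerate (or nondegenerate) in both
    codons are pooled; transition/transversion difference proportions in
    each class get a K80 correction, and the two kappa estimates are
    combined weighted by the number of observed differences in each class
    (the events carry the information about the ts/tv ratio).
    """
    ok = (ia >= 0) & (ib >= 0)
    ia, ib = ia[ok], ib[ok]
    L = {0: 0.0, 4: 0.0}
    ts = {0: 0.0, 4: 0.0}
    tv = {0: 0.0, 4: 0.0}
    for i, j, n in zip(*_nonzero_pairs(ia, ib)):
        ci, cj = ct.SENSE_CODONS[i], ct.SENSE_CODONS[j]
        for pos in range(3):
            deg_i, deg_j = ct.DEGENERACY[i, pos], ct.DEGENERACY[j, pos]
            if deg_i == 3 and deg_j == 3:
                cls = 4
            elif deg_i == 0 and deg_j == 0:
                cls = 0
            else:
                continue
            L[cls] += n
            if ci[pos] != cj[pos]:
                if ct.is_transition(ci[pos], cj[pos]):
                    ts[cls] += n
                else:
                    tv[cls] += n

    estimates, weights = [], []
    for cls in (0, 4):
        if L[cls] < 1:
            continue
        p, q = ts[cls] / L[cls], tv[cls] / L[cls]
        a1 = 1.0 - 2.0 * p - q
        a2 = 1.0 - 2.0 * q
        if a1 <= 0 or a2 <= 0:
            continue
        A = -0.5 * math.log(a1) + 0.25 * math.log(a2)  # transition distance
        B = -0.5 * math.log(a2)                        # transversion distance
        if B <= 0:
            continue
        # kappa = alpha/beta; ts flow is alpha, tv flow 2*beta => 2A/B
        estimates.append(2.0 * A / B)
        weights.append(ts[cls] + tv[cls])
    if not estimates or sum(weights) == 0:
        return DEFAULT_KAPPA
    kappa = float(np.average(estimates, weights=weights))
    return min(max(kappa, 0.01), 99.0)


def _nonzero_pairs(ia: np.ndarray, ib: np.ndarray):
    counts = np.bincount(ia * ct.N_SENSE + ib, minlength=ct.N_SENSE ** 2)
    nz = np.nonzero(counts)[0]
    return nz // ct.N_SENSE, nz % ct.N_SENSE, counts[nz]


def _yn00_sites(marg: np.ndarray, kappa: float) -> tuple[float, float]:
    """Kappa-weighted synonymous site count (per-position normalization),
    averaged over codon usage given by ``marg`` counts."""
    sc = ct.SITE_COUNTS  # (61, 3, 4): syn_ts, syn_tv, nonsyn_ts, nonsyn_tv
    num = kappa * sc[:, :, 0] + sc[:, :, 1]
    den = kappa * (sc[:, :, 0] + sc[:, :, 2]) + sc[:, :, 1] + sc[:, :, 3]
    frac = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    syn_per_codon = frac.sum(axis=1)
    total = marg.sum()
    S = float(marg @ syn_per_codon)
    return S, 3.0 * total - S


def _yn00_diffs(counts: np.ndarray, kappa: float, omega: float,
                pi: np.ndarray) -> np.ndarray:
    """Expected (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) difference counts,
    averaging each codon pair over its mutational pathways weighted by
    kappa^{ts steps} * omega^{nonsyn steps} * prod(pi of codons entered)."""
    P = ct.PATHWAYS
    pi_ext = np.append(pi, 1.0)  # index -1 -> neutral weight
    w = (kappa ** P.n_ts) * (omega ** P.n_nonsyn) \
        * pi_ext[P.inter[:, 0]] * pi_ext[P.inter[:, 1]]
    denom = np.zeros(ct.N_SENSE ** 2)
    np.add.at(denom, P.pair_of_path, w)
    denom_per_path = denom[P.pair_of_path]
    share = np.where(denom_per_path > 0, w / np.where(denom_per_path > 0, denom_per_path, 1.0), 0.0)
    weighted = share[:, None] * P.counts  # (K, 4)
    out = np.zeros((ct.N_SENSE ** 2, 4))
    np.add.at(out, P.pair_of_path, weighted)
    return counts @ out  # (4,)


def yn00_pairwise(seq1: str, seq2: str) -> PairwiseRates:
    """Yang–Nielsen (2000) approximate dN/dS (universal code, F3x4)."""
    ia, ib = ct.encode_codons(seq1), ct.encode_codons(seq2)
    if len(ia) != len(ib):
        raise ValueError("sequences differ in codon length")
    counts, n_codons = _pair_counts(ia, ib)
    marg = (counts.reshape(ct.N_SENSE, ct.N_SENSE).sum(axis=1)
            + counts.reshape(ct.N_SENSE, ct.N_SENSE).sum(axis=0)) / 2.0

    if np.array_equal(ia[(ia >= 0) & (ib >= 0)], ib[(ia >= 0) & (ib >= 0)]):
        kappa = _estimate_kappa(ia, ib)
        S, N = _yn00_sites(marg, kappa)
        return PairwiseRates(dN=0.0, dS=0.0, omega=float("nan"), S_sites=S,
                             N_sites=N, codons_used=n_codons, kappa=kappa,
                             method="yn00")

    kappa = _estimate_kappa(ia, ib)
    pi = _f3x4_freqs(counts)
    S, N = _yn00_sites(marg, kappa)

    omega = 0.5
    dS = dN = float("nan")
    saturated = False
    converged = False
    prev = (math.inf, math.inf)
    for _ in range(YN00_MAX_ITER):
        sd_ts, sd_tv, nd_ts, nd_tv = _yn00_diffs(counts, kappa, omega, pi)
        dS, satS = _k80_correct(sd_ts / S, sd_tv / S)
        dN, satN = _k80_correct(nd_ts / N, nd_tv / N)
        saturated = satS or satN
        if saturated:
            break
        if abs(dS - prev[0]) < YN00_TOL and abs(dN - prev[1]) < YN00_TOL:
            converged = True
            break
        prev = (dS, dN)
        if dS > 0:
            omega = max(dN / dS, 1e-6)
    omega_out = _omega_of(dN, dS)
    return PairwiseRates(dN=dN, dS=dS, omega=omega_out, S_sites=S, N_sites=N,
                         codons_used=n_codons, kappa=kappa, saturated=saturated,
                         converged=converged or saturated, method="yn00")


def decompose_branches(r_ab: PairwiseRates, r_ac: PairwiseRates,
                       r_bc: PairwiseRates) -> BranchRates:
    """Half-sum three-point decomposition of the pairwise rates onto the
    branches O->A, O->B, O->C.  Exact by construction; negative values are
    preserved.  Branch omega is dN_branch/dS_branch, undefined (nan) when
    dS_branch <= 0."""
    saturated = r_ab.saturated or r_ac.saturated or r_bc.saturated

    def half(x_ab, x_ac, x_bc):
        return ((x_ab + x_ac - x_bc) / 2.0,
                (x_ab + x_bc - x_ac) / 2.0,
                (x_ac + x_bc - x_ab) / 2.0)

    ds_oa, ds_ob, ds_oc = half(r_ab.dS, r_ac.dS, r_bc.dS)
    dn_oa, dn_ob, dn_oc = half(r_ab.dN, r_ac.dN, r_bc.dN)
    return BranchRates(
        dS_OA=ds_oa, dS_OB=ds_ob, dS_OC=ds_oc,
        dN_OA=dn_oa, dN_OB=dn_ob, dN_OC=dn_oc,
        omega_OA=_omega_of(dn_oa, ds_oa),
        omega_OB=_omega_of(dn_ob, ds_ob),
        omega_OC=_omega_of(dn_oc, ds_oc),
        saturated=saturated,
    )


def assign_fast_slow(branch: BranchRates) -> BranchRates:
    """Label the lower-omega post-duplication branch *slow* and the other
    *fast* (tie -> OA slow); fold change = omega_fast / omega_slow, +inf
    when omega_slow is 0 and omega_fast > 0, nan when either is undefined."""
    oa, ob = branch.omega_OA, branch.omega_OB
    if math.isnan(oa) or math.isnan(ob):
        branch.slow_branch = branch.fast_branch = None
        branch.fold_change = float("nan")
        return branch
    if oa <= ob:
        branch.slow_branch, branch.fast_branch = "OA", "OB"
        slow, fast = oa, ob
    else:
        branch.slow_branch, branch.fast_branch = "OB", "OA"
        slow, fast = ob, oa
    if slow == 0:
        branch.fold_change = float("inf") if fast > 0 else 1.0
    else:
        branch.fold_change = fast / slow
    return branch


PAIRWISE_METHODS = {"ng86": ng86_pairwise, "yn00": yn00_pairwise}


def trio_rates(trio: GeneTrio, method: str = "yn00") -> dict:
    """All three pairwise estimates plus the branch decomposition for one
    trio.

    Codon columns containing a gap, N or stop in ANY of the three sequences
    are deleted before every pairwise comparison (complete deletion), so all
    three estimates use identical columns — which the additivity identities
    of the decomposition implicitly assume.
    """
    f = PAIRWISE_METHODS[method]
    ia = ct.encode_codons(trio.A)
    ib = ct.encode_codons(trio.B)
    ic = ct.encode_codons(trio.C)
    ok = (ia >= 0) & (ib >= 0) & (ic >= 0)

    def rebuild(idx: np.ndarray) -> str:
        return "".join(ct.SENSE_CODONS[k] for k in idx[ok])

    a, b, c = rebuild(ia), rebuild(ib), rebuild(ic)
    if not a:
        raise ValueError(f"trio {trio.query_id}: no codon columns after complete deletion")
    r_ab, r_ac, r_bc = f(a, b), f(a, c), f(b, c)
    branches = assign_fast_slow(decompose_branches(r_ab, r_ac, r_bc))
    return {"query_id": trio.query_id, "pair_AB": r_ab, "pair_AC": r_ac,
            "pair_BC": r_bc, "branches": branches}
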