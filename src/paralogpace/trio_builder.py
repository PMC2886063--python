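"""Construction of outgroup+paralog-pair gene trios from translated-search
hits.

Protein queries (translated full-length ORFs) hit the combined salmon+pike
contig database; the hit contigs are clustered per query, trimmed to a
common aligned region with respect to the query protein, codon-aligned
through a protein MSA, screened to remove alleles (>98% identity),
distant homologs (<60% identity) and short-aligning members (<90% of the
longer sequence), and clusters retaining exactly one pike plus two salmon
members become gene trios.  Clusters with additional salmon members are
counted separately, not analyzed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GeneTrio, HomologyHit, Transcript, species_from_id

logger = logging.getLogger(__name__)

CLUSTER_EVALUE_MAX = 1e-10   #: translated-search significance threshold
CLUSTER_MAX_HITS = 100       #: hits considered per query
CLUSTER_MIN_COVERAGE = 0.5   #: fraction of the query protein the hit must cover
MIN_COMMON_NT = 300          #: minimum common region, nucleotides
MIN_COMMON_AA = 100          #: minimum common region, residues
MIN_PCT_POSITIVE = 75.0      #: original-hit positives threshold
SCREEN_MAX_IDENTITY = 98.0   #: above -> allele, drop
SCREEN_MIN_IDENTITY = 60.0   #: below -> distant homolog, drop
SCREEN_MIN_COVERAGE = 0.9    #: alignment / longer-sequence-length threshold


@dataclass
class ClusterMember:
    transcript_id: str
    species: str
    nt_seq: str                  # hit-region nucleotide subsequence (in frame)
    aa_seq: str                  # its translation
    q_interval: tuple[int, int]  # 1-based inclusive residues on the query protein
    pct_positive: float
    align_length: int
    evalue: float


@dataclass
class HomologCluster:
    query_id: str
    query_protein: str
    members: list[ClusterMember] = field(default_factory=list)
    trimmed_region: tuple[int, int] | None = None  # 1-based inclusive, query coords
    discarded: bool = False

    def species_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.species] = out.get(m.species, 0) + 1
        return out


def dedupe_queries(queries: Sequence[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """(query_id, accession, protein) -> one query per annotation accession,
    first by id order kept."""
    seen: set[str] = set()
    out = []
    for qid, acc, prot in sorted(queries, key=lambda q: q[0]):
        if acc in seen:
            continue
        seen.add(acc)
        out.append((qid, acc, prot))
    return out


def _extract_member(hit: HomologyHit, contig: Transcript) -> ClusterMember:
    """Cut the hit region out of the contig in the hit's frame and translate.

    For a translated search with protein queries, the subject coordinates
    (s_start, s_end; here stored on the contig via q_* after normalization)
    delimit nucleotides and the frame orients translation.
    """
    nt = contig.sequence[hit.q_start:hit.q_end]
    if hit.frame < 0:
        nt = str(Seq(nt).reverse_complement())
    nt = nt[: 3 * (len(nt) // 3)]
    aa = str(Seq(nt).translate())
    return ClusterMember(
        transcript_id=contig.id, species=contig.species, nt_seq=nt, aa_seq=aa,
        q_interval=(hit.s_start, hit.s_end), pct_positive=hit.pct_positive,
        align_length=hit.align_length, evalue=hit.evalue,
    )


def build_clusters(
    queries: Sequence[tuple[str, str, str]],
    hits: Sequence[HomologyHit],
    contigs: Mapping[str, Transcript],
) -> list[HomologCluster]:
    """One cluster per query from its significant, well-covering hits.

    Hits need e-value <= 1e-10; at most the 100 best per query are
    considered, and a hit joins the cluster only if the alignment covers at
    least half of the query protein.  Here the hit's ``query_id`` is the
    protein query and its query-side nucleotide coordinates address the
    subject contig (translated-search orientation).
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.evalue <= CLUSTER_EVALUE_MAX:
            by_query.setdefault(h.query_id, []).append(h)
    clusters = []
    for qid, acc, prot in queries:
        cluster = HomologCluster(query_id=qid, query_protein=prot)
        cands = sorted(by_query.get(qid, []), key=lambda h: (h.evalue, -h.bitscore))
        for h in cands[:CLUSTER_MAX_HITS]:
            covered = h.s_end - h.s_start + 1
            if covered < CLUSTER_MIN_COVERAGE * len(prot):
                continue
            contig = contigs.get(h.subject_id)
            if contig is None:
                logger.warning("cluster %s: hit subject %s not in contig set; skipped",
                               qid, h.subject_id)
                continue
            cluster.members.append(_extract_member(h, contig))
        clusters.append(cluster)
    return clusters


def trim_common_region(cluster: HomologCluster) -> HomologCluster:
    """Trim members to a common aligned region in query-protein coordinates.

    Members are visited by decreasing alignment length; the common region is
    iteratively intersected with each member's interval, and a member whose
    inclusion would push the region below 100 residues (300 nt) is removed
    entirely.  Members whose original hit had <75% positive matches are
    removed first.  Clusters that cannot keep >= 3 members with a legal
    region are flagged discarded.
    """
    members = [m for m in cluster.members if m.pct_positive >= MIN_PCT_POSITIVE]
    members.sort(key=lambda m: (-m.align_length, -m.pct_positive, m.transcript_id))
    kept: list[ClusterMember] = []
    region: tuple[int, int] | None = None
    for m in members:
        lo, hi = m.q_interval
        if region is None:
            cand = (lo, hi)
        else:
            cand = (max(region[0], lo), min(region[1], hi))
        if cand[1] - cand[0] + 1 < MIN_COMMON_AA:
            continue  # member removed entirely; region unchanged
        region = cand
        kept.append(m)

    cluster.trimmed_region = region
    if region is None or len(kept) < 3:
        cluster.members = kept
        cluster.discarded = True
        return cluster

    lo, hi = region
    trimmed = []
    for m in kept:
        off = lo - m.q_interval[0]           # residues to cut from the member 5' end
        n_res = hi - lo + 1
        aa = m.aa_seq[off:off + n_res]
        nt = m.nt_seq[3 * off: 3 * (off + n_res)]
        trimmed.append(ClusterMember(
            transcript_id=m.transcript_id, species=m.species, nt_seq=nt, aa_seq=aa,
            q_interval=region, pct_positive=m.pct_positive,
            align_length=m.align_length, evalue=m.evalue,
        ))
    cluster.members = trimmed
    return cluster


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def star_protein_msa(seqs: Mapping[str, str]) -> dict[str, str]:
    """Minimal progressive (star) protein MSA.

    The longest sequence anchors; every other sequence is globally aligned
    to it and the pairwise gap patterns are merged on the anchor's
    coordinates ("once a gap, always a gap").  Exists so the pipeline runs
    without an external aligner; any externally computed protein MSA can be
    supplied instead.
    """
    ids = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    center = ids[0]
    if len(ids) == 1:
        return {center: seqs[center]}
    aligner = _protein_aligner()
    # pairwise alignments to the center, as (center_row, other_row) strings
    pair_rows: dict[str, tuple[str, str]] = {}
    for other in ids[1:]:
        aln = aligner.align(seqs[center], seqs[other])[0]
        rows = str(aln).splitlines()
        c_row, o_row = aln[0], aln[1]
        pair_rows[other] = (c_row, o_row)

    # number of gap columns to insert after each center position
    n = len(seqs[center])
    ins = [0] * (n + 1)  # ins[k]: columns inserted before center residue k
    per_other = {}
    for other, (c_row, o_row) in pair_rows.items():
        counts = [0] * (n + 1)
        k = 0
        for ch in c_row:
            if ch == "-":
                counts[k] += 1
            else:
                k += 1
        per_other[other] = counts
        for k in range(n + 1):
            ins[k] = max(ins[k], counts[k])

    def expand(row_center: str, row_other: str, counts: list[int]) -> str:
        # rebuild the other's row on the master coordinate system
        out = []
        k = 0  # center residue index
        i = 0  # column in pairwise alignment
        pending = ins[0] - counts[0]
        out.append("-" * pending)
        for c_ch, o_ch in zip(row_center, row_other):
            if c_ch == "-":
                out.append(o_ch)
            else:
                out.append(o_ch)
                k += 1
                if k <= n:
                    out.append("-" * (ins[k] - counts[k]))
        return "".join(out)

    msa = {}
    # center's own row
    out = []
    for k in range(n):
        out.append("-" * ins[k])
        out.append(seqs[center][k])
    out.append("-" * ins[n])
    msa[center] = "".join(out)
    for other in ids[1:]:
        msa[other] = expand(*pair_rows[other], per_other[other])
    width = {len(v) for v in msa.values()}
    assert len(width) == 1, "star MSA rows differ in width"
    return msa


def back_translate(protein_row: str, nt_seq: str) -> str:
    """Thread a nucleotide sequence through its protein row's gap pattern
    (3 nt per residue, gaps as ``---``)."""
    n_res = sum(1 for c in protein_row if c != "-")
    if len(nt_seq) < 3 * n_res:
        raise ValueError(
            f"nucleotide sequence ({len(nt_seq)} nt) shorter than 3x protein length ({n_res} aa)"
        )
    out = []
    k = 0
    for ch in protein_row:
        if ch == "-":
            out.append("---")
        else:
            out.append(nt_seq[3 * k: 3 * k + 3])
            k += 1
    return "".join(out)


def align_and_backtranslate(
    cluster: HomologCluster, protein_msa: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Codon alignment of a trimmed cluster via a protein MSA.

    Uses a supplied protein MSA when given (e.g. from an external aligner);
    otherwise the built-in star aligner.  Column count is 3x the MSA length.
    """
    seqs = {m.transcript_id: m.aa_seq.rstrip("*") for m in cluster.members}
    if protein_msa is None:
        protein_msa = star_protein_msa(seqs)
    nt_by_id = {m.transcript_id: m.nt_seq for m in cluster.members}
    out = {}
    for tid, row in protein_msa.items():
        try:
            out[tid] = back_translate(row, nt_by_id[tid])
        except ValueError as e:
            raise ValueError(f"member {tid}: {e}") from e
    return out


def _pair_stats(seq1: str, seq2: str) -> tuple[float, float]:
    """(percent identity, alignment length / longer sequence length) from a
    global nucleotide alignment."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -2
    aln = a.align(seq1, seq2)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    ident = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    coverage = aligned_cols / max(len(seq1), len(seq2))
    return ident, coverage


def screen_pairs(cluster: HomologCluster) -> HomologCluster:
    """Drop alleles, distant homologs and short-aligning members.

    Every member pair is aligned; a pair showing >98% identity, <60%
    identity, or an alignment shorter than 90% of the longer sequence
    triggers a drop of the shorter member (ties: lexicographically later
    id).  Screening repeats until no violations remain (a fixed point).
    """
    members = list(cluster.members)
    changed = True
    while changed:
        changed = False
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                m1, m2 = members[i], members[j]
                ident, cov = _pair_stats(m1.nt_seq, m2.nt_seq)
                if ident > SCREEN_MAX_IDENTITY or ident < SCREEN_MIN_IDENTITY \
                        or cov < SCREEN_MIN_COVERAGE:
                    # drop the shorter; on a length tie the later id
                    if len(m1.nt_seq) != len(m2.nt_seq):
                        drop = m1 if len(m1.nt_seq) < len(m2.nt_seq) else m2
                    else:
                        drop = m1 if m1.transcript_id > m2.transcript_id else m2
                    members.remove(drop)
                    changed = True
                    break
            if changed:
                break
    cluster.members = members
    return cluster


def select_trios(clusters: Sequence[HomologCluster]) -> tuple[list[GeneTrio], int]:
    """Clusters with exactly one pike + two salmon members become trios;
    clusters with one pike and >2 salmon are counted as surplus (reported,
    not analyzed).  Returns (trios, surplus_count)."""
    trios = []
    surplus = 0
    for cl in clusters:
        if cl.discarded:
            continue
        counts = cl.species_counts()
        n_ssal, n_eluc = counts.get("ssal", 0), counts.get("eluc", 0)
        if n_eluc == 1 and n_ssal == 2:
            codon_aln = align_and_backtranslate(cl)
            ssal = [m for m in cl.members if m.species == "ssal"]
            eluc = [m for m in cl.members if m.species == "eluc"][0]
            a, b = sorted(ssal, key=lambda m: m.transcript_id)
            trios.append(GeneTrio(
                query_id=cl.query_id,
                a_id=a.transcript_id, b_id=b.transcript_id, c_id=eluc.transcript_id,
                A=codon_aln[a.transcript_id], B=codon_aln[b.transcript_id],
                C=codon_aln[eluc.transcript_id],
            ))
        elif n_eluc == 1 and n_ssal > 2:
            surplus += 1
    return trios, surplus
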