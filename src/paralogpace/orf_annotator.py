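"""Full-length ORF annotation of transcripts against homologous reference
proteins.

A transcript is a full-length cDNA candidate only if it is long enough to
contain the *entire* homologous subject protein implied by its best hits:
enough 5' sequence upstream of the aligned region for the subject's missing
N-terminal residues, and enough 3' sequence for the missing C-terminal
residues plus a stop codon.  The start codon is then placed from the hit
(the nearest in-frame ATG at or upstream of the inferred subject start, or
within 30 bp downstream), extended 5'-ward to the most upstream in-frame ATG
below the bounding in-frame stop, and the ORF is closed at the first
downstream in-frame stop.

Codons containing N never match ATG or stop patterns.  Reverse-frame hits
are handled by reverse-complementing the transcript before annotation;
output coordinates refer to the reoriented sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import HomologyHit, Transcript, mask_polya

EVALUE_MAX = 1e-5          #: hit significance threshold for FLcDNA candidacy
MAX_HITS_PER_QUERY = 10    #: best hits examined in succession per transcript
DOWNSTREAM_ATG_WINDOW = 30  #: bp downstream of the aligned subject start (inclusive)

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfAnnotation:
    """Located ORF and UTR structure of one transcript."""

    transcript_id: str
    status: str                 # {"full_length", "not_full_length", "no_orf"}
    start: int | None = None    # 0-based ATG offset
    end: int | None = None      # one past the in-frame stop codon
    frame: int | None = None    # start % 3 on the (possibly reoriented) strand
    utr5_len: int | None = None
    utr3_len: int | None = None
    orf_len: int | None = None
    reverse_oriented: bool = False

    def validate(self, seq_len: int | None = None) -> None:
        if self.status != "full_length":
            return
        assert self.start is not None and self.end is not None
        assert self.orf_len == self.end - self.start
        assert self.orf_len % 3 == 0
        assert self.utr5_len == self.start
        if seq_len is not None:
            assert self.utr5_len + self.orf_len + self.utr3_len == seq_len


def _codon(seq: str, i: int) -> str:
    c = seq[i:i + 3]
    return c if len(c) == 3 and "N" not in c else ""


def filter_flcdna_candidates(
    transcripts: Sequence[Transcript],
    hits: Sequence[HomologyHit],
    subject_lengths: Mapping[str, int] | None = None,
) -> list[tuple[Transcript, HomologyHit]]:
    """Pair each transcript with the first of its ten best significant hits
    under which it could contain the entire subject protein.

    For a hit aligning subject residues ``s_start..s_end`` of a protein of
    length ``L`` at query offset ``q_start``: the transcript needs
    ``3*(s_start-1)`` nt upstream of ``q_start`` and ``3*(L-s_end)+3`` nt
    (missing residues plus a stop) downstream of ``q_end``.  Transcripts
    failing for all examined hits are dropped from full-length consideration.
    """
    by_id = {t.id: t for t in transcripts}
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query_id not in by_id:
            raise KeyError(f"hit references unknown transcript {h.query_id!r}")
        if h.evalue <= EVALUE_MAX:
            by_query.setdefault(h.query_id, []).append(h)

    retained: list[tuple[Transcript, HomologyHit]] = []
    for t in transcripts:
        cands = sorted(by_query.get(t.id, []), key=lambda h: (-h.bitscore, h.evalue))
        for h in cands[:MAX_HITS_PER_QUERY]:
            slen = (subject_lengths or {}).get(h.subject_id, h.subject_length)
            need_5p = 3 * (h.s_start - 1)
            need_3p = 3 * (slen - h.s_end) + 3
            if h.q_start >= need_5p and len(t) - h.q_end >= need_3p:
                retained.append((t, h))
                break
    return retained


def _oriented(transcript: Transcript, hit: HomologyHit) -> tuple[str, int]:
    """Sequence on the hit's strand and the 0-based offset of the transcript
    position corresponding to subject residue 1."""
    seq = transcript.sequence
    if hit.frame < 0:
        seq = str(Seq(seq).reverse_complement())
        q_start = len(seq) - hit.q_end
    else:
        q_start = hit.q_start
    return seq, q_start - 3 * (hit.s_start - 1)


def locate_start_codon(transcript: Transcript, hit: HomologyHit) -> int | None:
    """Pick the ORF start codon implied by a homology hit.

    Candidate: the nearest in-frame ATG at or upstream of the inferred
    subject-start position, else an in-frame ATG within 30 bp downstream.
    The candidate is then extended to the most 5' in-frame ATG lying below
    the first bounding in-frame stop (or the transcript 5' end).
    Returns an offset on the hit's strand, or None.
    """
    seq, subj_start = _oriented(transcript, hit)
    frame = subj_start % 3

    candidate = None
    for i in range(subj_start, frame - 3, -3):
        if i < 0:
            break
        if _codon(seq, i) == "ATG":
            candidate = i
            break
        if _codon(seq, i) in STOPS and i < subj_start:
            break  # an upstream in-frame stop bounds the upstream search
    if candidate is None:
        for i in range(subj_start + 3, subj_start + DOWNSTREAM_ATG_WINDOW + 1, 3):
            if i >= 0 and _codon(seq, i) == "ATG":
                candidate = i
                break
    if candidate is None:
        return None

    # Upstream extension: scan from the candidate toward 5' until the first
    # in-frame stop; the most 5' ATG in that window wins.
    best = candidate
    for i in range(candidate - 3, -1, -3):
        c = _codon(seq, i)
        if c in STOPS:
            break
        if c == "ATG":
            best = i
    return best


def locate_orf(transcript: Transcript, start: int, reverse_oriented: bool = False) -> OrfAnnotation:
    """Close the ORF at the first in-frame stop downstream of ``start``."""
    seq = transcript.sequence
    if reverse_oriented:
        seq = str(Seq(seq).reverse_complement())
    if seq[start:start + 3] != "ATG":
        raise ValueError(f"{transcript.id}: no ATG at offset {start}")
    for i in range(start + 3, len(seq) - 2, 3):
        if _codon(seq, i) in STOPS:
            end = i + 3
            return OrfAnnotation(
                transcript_id=transcript.id, status="full_length",
                start=start, end=end, frame=start % 3,
                utr5_len=start, utr3_len=len(seq) - end, orf_len=end - start,
                reverse_oriented=reverse_oriented,
            )
    return OrfAnnotation(transcript_id=transcript.id, status="no_orf",
                         reverse_oriented=reverse_oriented)


def annotate_transcript(
    transcript: Transcript, hit: HomologyHit,
) -> OrfAnnotation:
    """mask polyA -> locate start from the hit -> close the ORF."""
    masked = Transcript(
        id=transcript.id, sequence=mask_polya(transcript.sequence),
        species=transcript.species, polya_masked=True, source=transcript.source,
    )
    start = locate_start_codon(masked, hit)
    if start is None:
        return OrfAnnotation(transcript_id=transcript.id, status="no_orf",
                             reverse_oriented=hit.frame < 0)
    return locate_orf(masked, start, reverse_oriented=hit.frame < 0)


def annotate_all(
    transcripts: Sequence[Transcript],
    hits: Sequence[HomologyHit],
    subject_lengths: Mapping[str, int] | None = None,
) -> list[OrfAnnotation]:
    """Candidate filter + annotation over a whole collection.

    Transcripts that fail the candidacy filter are reported with status
    ``not_full_length``.
    """
    pairs = filter_flcdna_candidates(transcripts, hits, subject_lengths)
    paired = {t.id: h for t, h in pairs}
    out = []
    for t in transcripts:
        if t.id in paired:
            out.append(annotate_transcript(t, paired[t.id]))
        else:
            out.append(OrfAnnotation(transcript_id=t.id, status="not_full_length"))
    return out


def summarize_utr_orf(annotations: Iterable[OrfAnnotation]) -> pd.DataFrame:
    """Mean +/- population SD and range of total, 5' UTR, ORF and 3' UTR
    lengths over full-length annotations (polyA tails already masked)."""
    anns = [a for a in annotations]
    if not anns:
        raise ValueError("no annotations to summarize")
    if any(a.status != "full_length" for a in anns):
        raise ValueError("summaries are defined over full_length annotations only")
    cols = {
        "total": [a.utr5_len + a.orf_len + a.utr3_len for a in anns],
        "utr5": [a.utr5_len for a in anns],
        "orf": [a.orf_len for a in anns],
        "utr3": [a.utr3_len for a in anns],
    }
    rows = []
    for name, vals in cols.items():
        v = np.asarray(vals, dtype=float)
        rows.append({"region": name, "n": len(v), "mean": v.mean(),
                     "sd": v.std(ddof=0), "min": v.min(), "max": v.max()})
    return pd.DataFrame(rows).set_index("region")
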