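"""Readers and writers for the pipeline's plain-text formats.

Covers multi-record FASTA (via Biopython), the aligned gene-trio supplement
convention (consecutive blocks of three records, one pike ``eluc_*`` plus two
salmon ``ssal_*`` sequences), 14-column tabular protein-homology hits
(the standard 12-column hit format plus percent-positives and frame), and
polyA-tail masking.

All internal coordinates are 0-based, half-open.  Tabular hit inputs are
1-based inclusive and are converted on read; hits on the reverse frame have
their query coordinates normalized so that ``q_start < q_end`` while the
frame sign is retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SPECIES_PREFIXES = {"ssal": "ssal", "eluc": "eluc"}

#: polyA definition: a run of >= 15 consecutive A residues ...
POLYA_MIN_RUN = 15
#: ... whose end lies within this many bases of the 3' end of the sequence.
POLYA_TAIL_WINDOW = 50


@dataclass
class Transcript:
    """An assembled contig, clone insert or simulated transcript."""

    id: str
    sequence: str
    species: str = "other"  # {"ssal", "eluc", "other"}
    polya_masked: bool = False
    source: str = "contig"  # {"contig", "clone", "simulated"}

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HomologyHit:
    """One row of a translated-search tabular report.

    Coordinates are stored 0-based half-open on the query nucleotide sequence
    and 1-based inclusive residue positions on the subject protein, matching
    how the two ends of a BLASTX-style hit are naturally addressed.
    ``subject_length`` is not part of the 14-column dialect; when unknown it
    defaults to ``s_end`` (the alignment is assumed to reach the subject
    C-terminus).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int  # 0-based
    q_end: int    # half-open
    s_start: int  # 1-based residue
    s_end: int    # inclusive residue
    evalue: float
    bitscore: float
    pct_positive: float
    frame: int
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: empty query interval")
        if not (0.0 <= self.pct_identity <= self.pct_positive <= 100.0):
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: "
                f"need 0 <= identity ({self.pct_identity}) <= positives ({self.pct_positive}) <= 100"
            )
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.subject_length is None:
            self.subject_length = self.s_end


@dataclass
class GeneTrio:
    """A codon alignment of two salmon paralogs (A, B) and the pike ortholog
    (C); the duplication node O is implied, not observed."""

    query_id: str
    a_id: str
    b_id: str
    c_id: str
    A: str
    B: str
    C: str

    def __post_init__(self) -> None:
        lens = {len(self.A), len(self.B), len(self.C)}
        if len(lens) != 1:
            raise ValueError(f"trio {self.query_id}: unequal alignment lengths {lens}")
        (n,) = lens
        if n % 3:
            raise ValueError(f"trio {self.query_id}: alignment length {n} not divisible by 3")
        self.A, self.B, self.C = self.A.upper(), self.B.upper(), self.C.upper()

    @property
    def alignment_length(self) -> int:
        return len(self.A)


def species_from_id(seq_id: str) -> str:
    prefix = seq_id.split("_", 1)[0].lower()
    return SPECIES_PREFIXES.get(prefix, "other")


def read_fasta(path: str | Path, source: str = "contig") -> list[Transcript]:
    """Read a FASTA file into Transcripts.

    Species is parsed from the ``eluc_``/``ssal_`` header prefix convention;
    anything else is tagged ``other``.  Sequences are upper-cased.  Duplicate
    ids raise, since ids must be unique within a collection.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(
            Transcript(id=rec.id, sequence=str(rec.seq), species=species_from_id(rec.id),
                       source=source)
        )
    return out


def write_fasta(transcripts: Iterable[Transcript | tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write (id, sequence) pairs or Transcripts as wrapped FASTA."""
    records = []
    for t in transcripts:
        tid, seq = (t.id, t.sequence) if isinstance(t, Transcript) else t
        records.append(SeqRecord(Seq(seq), id=tid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_A_RUN = re.compile("A{%d,}" % POLYA_MIN_RUN)


def mask_polya(seq: str) -> str:
    """Remove a 3' polyA tail and everything downstream of it.

    A tail is a run of >= 15 consecutive A's whose end falls within the final
    50 bp of the sequence (or reaches the end).  The earliest qualifying run
    and all subsequent downstream sequence are deleted.  Internal A-runs far
    from the 3' end are left alone (they may encode poly-lysine).
    Trimming repeats until no qualifying run remains (removing one tail can
    expose another A-run to the 3' window), which makes the operation
    idempotent.
    """
    seq = seq.upper()
    while True:
        for m in _A_RUN.finditer(seq):
            if m.end() >= len(seq) - POLYA_TAIL_WINDOW:
                seq = seq[: m.start()]
                break
        else:
            return seq


def parse_trio_file(path: str | Path) -> list[GeneTrio]:
    """Parse an aligned gene-trio FASTA (supplement convention).

    Records are grouped in consecutive blocks of three.  A block must contain
    exactly one ``eluc_`` and two ``ssal_`` sequences of equal, codon-sized
    length; blocks with the wrong species composition are skipped with a
    warning, while a qualifying block whose lengths are broken raises.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 3:
        logger.warning("%s: %d records is not a multiple of 3; trailing records ignored",
                       path, len(records))
    trios: list[GeneTrio] = []
    skipped = 0
    for k in range(0, len(records) - len(records) % 3, 3):
        block = records[k:k + 3]
        by_species: dict[str, list] = {"ssal": [], "eluc": [], "other": []}
        for rec in block:
            by_species[species_from_id(rec.id)].append(rec)
        if len(by_species["eluc"]) != 1 or len(by_species["ssal"]) != 2:
            skipped += 1
            logger.warning("trio block starting at record %d (%s): species composition "
                           "is not 1 eluc + 2 ssal; skipped", k, block[0].id)
            continue
        c = by_species["eluc"][0]
        a, b = by_species["ssal"]
        trios.append(
            GeneTrio(query_id=a.id, a_id=a.id, b_id=b.id, c_id=c.id,
                     A=str(a.seq), B=str(b.seq), C=str(c.seq))
        )
    if skipped:
        logger.warning("%s: skipped %d malformed trio block(s)", path, skipped)
    return trios


def write_trio_file(trios: Iterable[GeneTrio], path: str | Path) -> None:
    """Write trios in the supplement convention (A, B then C per block)."""
    pairs = []
    for t in trios:
        pairs += [(t.a_id, t.A), (t.b_id, t.B), (t.c_id, t.C)]
    write_fasta(pairs, path)


_HIT_COLUMNS = 14


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read 14-column tab-separated homology hits.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value, bitscore, %positives,
    frame.  Query coordinates are 1-based inclusive on input; reverse-frame
    hits arrive with q_start > q_end and are normalized to forward 0-based
    half-open coordinates with the frame sign retained.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HIT_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns "
                    f"(12 standard + pct_positive + frame), got {len(cols)}"
                )
            q_start, q_end = int(cols[6]), int(cols[7])
            if q_start > q_end:  # reverse-frame convention
                q_start, q_end = q_end, q_start
            hits.append(
                HomologyHit(
                    query_id=cols[0], subject_id=cols[1],
                    pct_identity=float(cols[2]), align_length=int(cols[3]),
                    mismatches=int(cols[4]), gap_opens=int(cols[5]),
                    q_start=q_start - 1, q_end=q_end,
                    s_start=int(cols[8]), s_end=int(cols[9]),
                    evalue=float(cols[10]), bitscore=float(cols[11]),
                    pct_positive=float(cols[12]), frame=int(cols[13]),
                )
            )
    return hits


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back in the 14-column dialect (1-based inclusive coords)."""
    with open(path, "w") as fh:
        for h in hits:
            q1, q2 = h.q_start + 1, h.q_end
            if h.frame < 0:
                q1, q2 = q2, q1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, h.pct_identity, h.align_length,
                h.mismatches, h.gap_opens, q1, q2, h.s_start, h.s_end,
                h.evalue, h.bitscore, h.pct_positive, h.frame,
            ])) + "\n")
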