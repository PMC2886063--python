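"""Reference-clone identification from paired-read mappings, redundancy
collapse and contig confirmation.

A cDNA clone whose forward and reverse reads map to the same transcript with
overlapping intervals is *complete* (its insert is spanned by the two
reads); reads on the same transcript separated by a gap mark an *incomplete*
clone.  Among complete clones that flank a transcript's entire predicted
ORF, one reference clone per transcript is kept: the longest, ties broken
alphabetically by clone id.  Sequence-level redundancy (>= 98% identity over
>= 200 aligned bp) is collapsed to the longest representative of each
connected redundancy component, and references are confirmed against the
contig assembly when a contig matches at 100% identity over >= 95% of the
reference length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .orf_annotator import OrfAnnotation

REDUNDANCY_MIN_IDENTITY = 98.0  # percent
REDUNDANCY_MIN_LENGTH = 200     # aligned bp
CONFIRM_MIN_COVERAGE = 0.95     # fraction of reference length at 100% identity


@dataclass
class CloneReadPair:
    """5' and 3' read mappings of one clone (None = unmapped)."""

    clone_id: str
    transcript_fwd: str | None = None
    fwd_interval: tuple[int, int] | None = None
    transcript_rev: str | None = None
    rev_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for iv in (self.fwd_interval, self.rev_interval):
            if iv is not None and iv[0] >= iv[1]:
                raise ValueError(f"clone {self.clone_id}: malformed interval {iv}")


@dataclass
class ReferenceClone:
    clone_id: str
    transcript_id: str
    completeness: str  # {"complete", "incomplete"}
    length: int
    span: tuple[int, int] | None = None  # union of read intervals on the transcript


def classify_clone(pair: CloneReadPair) -> str | None:
    """complete / incomplete / None per the paired-read overlap rule."""
    if (pair.transcript_fwd is None or pair.transcript_rev is None
            or pair.transcript_fwd != pair.transcript_rev):
        return None
    (f0, f1), (r0, r1) = pair.fwd_interval, pair.rev_interval
    return "complete" if min(f1, r1) > max(f0, r0) else "incomplete"


def reference_clone_from_pair(pair: CloneReadPair) -> ReferenceClone | None:
    """Build a ReferenceClone record for a mapped pair (None if unusable)."""
    status = classify_clone(pair)
    if status is None:
        return None
    (f0, f1), (r0, r1) = pair.fwd_interval, pair.rev_interval
    span = (min(f0, r0), max(f1, r1))
    return ReferenceClone(clone_id=pair.clone_id, transcript_id=pair.transcript_fwd,
                          completeness=status, length=span[1] - span[0], span=span)


def select_reference_clones(
    complete_clones: Sequence[ReferenceClone],
    orf_annotations: Mapping[str, OrfAnnotation] | Iterable[OrfAnnotation],
) -> list[ReferenceClone]:
    """One reference clone per transcript: complete, spanning the entire
    predicted ORF, longest (alphabetical clone id on ties)."""
    if not isinstance(orf_annotations, Mapping):
        orf_annotations = {a.transcript_id: a for a in orf_annotations}
    eligible: dict[str, list[ReferenceClone]] = {}
    for c in complete_clones:
        if c.completeness != "complete":
            continue
        ann = orf_annotations.get(c.transcript_id)
        if ann is None or ann.status != "full_length":
            continue
        if c.span is not None and not (c.span[0] <= ann.start and c.span[1] >= ann.end):
            continue  # must flank the entire predicted ORF region
        eligible.setdefault(c.transcript_id, []).append(c)
    chosen = []
    for tid, clones in eligible.items():
        chosen.append(min(clones, key=lambda c: (-c.length, c.clone_id)))
    return sorted(chosen, key=lambda c: c.transcript_id)


def _local_aligner() -> Align.PairwiseAligner:
    # standard local alignment used when precomputed alignments are absent;
    # parameters recorded in output metadata by the CLI layer
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


ALIGNER_PARAMS = {"match": 1, "mismatch": -2, "gap_open": -5, "gap_extend": -2}


def _identity_and_length(seq1: str, seq2: str) -> tuple[float, int]:
    """Percent identity over the aligned region of the best local alignment,
    and the alignment length (columns)."""
    aligner = _local_aligner()
    try:
        aln = aligner.align(seq1, seq2)[0]
    except IndexError:
        return 0.0, 0
    counts = aln.counts()
    length = aln.length
    if length == 0:
        return 0.0, 0
    return 100.0 * counts.identities / length, length


def is_redundant_pair(seq1: str, seq2: str) -> bool:
    ident, length = _identity_and_length(seq1, seq2)
    return ident >= REDUNDANCY_MIN_IDENTITY and length >= REDUNDANCY_MIN_LENGTH


def collapse_redundant(sequences: Mapping[str, str]) -> dict[str, str]:
    """All-vs-all redundancy collapse.

    Redundancy (>= 98% identity over >= 200 aligned bp) is made transitive
    via connected components; each component is represented by its longest
    sequence (ties: alphabetically first id).
    """
    ids = sorted(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if is_redundant_pair(sequences[a], sequences[b]):
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for i in ids:
        components.setdefault(find(i), []).append(i)
    out = {}
    for members in components.values():
        rep = min(members, key=lambda m: (-len(sequences[m]), m))
        out[rep] = sequences[rep]
    return out


def _longest_exact_match(ref: str, contig: str) -> int:
    """Length of the longest common substring (100%-identity local match)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    # forbid mismatches and gaps so the local score IS the longest exact match
    a.mismatch_score = -1e9
    a.open_gap_score = -1e9
    a.extend_gap_score = -1e9
    try:
        return int(a.score(ref, contig))
    except Exception:
        return 0


def confirm_against_contigs(
    references: Mapping[str, str], contigs: Mapping[str, str],
) -> dict:
    """Score each reference confirmed (some contig matches it at 100%
    identity over >= 95% of the reference length) or unique."""
    confirmed = []
    unique = []
    contig_seqs = list(contigs.values())
    for rid in sorted(references):
        ref = references[rid]
        need = CONFIRM_MIN_COVERAGE * len(ref)
        ok = any(_longest_exact_match(ref, c) >= need for c in contig_seqs)
        (confirmed if ok else unique).append(rid)
    return {
        "confirmed_count": len(confirmed),
        "unique_count": len(unique),
        "confirmed_ids": confirmed,
        "unique_ids": unique,
    }
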