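"""Candidate lncRNA handling: a coding-potential stand-in based on longest
open reading frame, positional classification of lncRNAs relative to the
annotation, and cis-target prediction with a window-plus-network rule.

The coding filter here is deliberately simple (longest forward-frame ORF vs
a codon threshold). Dedicated coding-potential classifiers can be plugged in
through the ``external_labels`` hook of :func:`filter_noncoding`.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

from .types import Annotation, CisTargetPair, Gene, TranscriptModel

MIN_LNCRNA_LENGTH = 200  # community convention for lncRNA candidacy (nt)

_VALID = re.compile(r"^[ACGTN]*$")
_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> int:
    """Length in codons (start codon included, stop excluded) of the longest
    ATG..stop ORF over the three forward frames. An ORF without an in-frame
    stop runs to the end of the sequence."""
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start: Optional[int] = None
        n_codons = (len(seq) - frame) // 3
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
            if start is None:
                if codon == "ATG":
                    start = ci
            elif codon in _STOPS:
                best = max(best, ci - start)
                start = None
        if start is not None:
            best = max(best, n_codons - start)
    return best


def coding_potential(sequence: str, min_orf: int = 100) -> tuple[str, int]:
    """Label a candidate sequence coding/noncoding by its longest ORF.

    Returns ``(label, longest_orf_codons)``; label is ``"coding"`` iff the
    longest ORF is at least ``min_orf`` codons. Sequences shorter than 200 nt
    are rejected as lncRNA candidates.
    """
    seq = sequence.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    if len(seq) < MIN_LNCRNA_LENGTH:
        raise ValueError(
            f"sequence of {len(seq)} nt is below the {MIN_LNCRNA_LENGTH} nt "
            "candidate minimum"
        )
    orf = longest_orf(seq)
    return ("coding" if orf >= min_orf else "noncoding"), orf


def filter_noncoding(
    sequences: dict[str, str],
    min_orf: int = 100,
    external_labels: Optional[dict[str, str]] = None,
) -> dict[str, tuple[str, int]]:
    """Batch coding filter. ``external_labels`` (id -> 'coding'/'noncoding')
    overrides the ORF stand-in where present, so output from dedicated
    coding-potential tools can be substituted."""
    out = {}
    for tid, seq in sequences.items():
        label, orf = coding_potential(seq, min_orf=min_orf)
        if external_labels and tid in external_labels:
            label = external_labels[tid]
        out[tid] = (label, orf)
    return out


# ---------------------------------------------------------------------------
# positional classification
# ---------------------------------------------------------------------------

def _exonic_overlap_bp(exons_a, exons_b) -> int:
    return sum(
        max(0, min(ea, eb) - max(sa, sb))
        for sa, ea in exons_a
        for sb, eb in exons_b
    )


def classify_position(
    transcript: Optional[TranscriptModel], annotation: Annotation
) -> str:
    """Positional class of a lncRNA relative to the gene annotation.

    Precedence: ``sense`` (>=1 bp exonic overlap, same strand) >
    ``antisense`` (exonic overlap, opposite strand) > ``intronic`` (fully
    inside a gene span, either strand, without exonic overlap) >
    ``intergenic``. Unplaced transcripts are ``unmapped``.
    """
    if transcript is None:
        return "unmapped"
    sense = antisense = intronic = False
    for gene in annotation.by_chrom.get(transcript.chrom, []):
        if gene.end <= transcript.start or gene.start >= transcript.end:
            continue
        ov = _exonic_overlap_bp(transcript.exons, gene.exon_union())
        if ov > 0:
            if gene.strand == transcript.strand:
                sense = True
            else:
                antisense = True
        elif gene.start <= transcript.start and transcript.end <= gene.end:
            intronic = True
    if sense:
        return "sense"
    if antisense:
        return "antisense"
    if intronic:
        return "intronic"
    return "intergenic"


# ---------------------------------------------------------------------------
# cis-target prediction
# ---------------------------------------------------------------------------

def _cis_window(gene: Gene, window_up: int, window_down: int) -> tuple[int, int]:
    """Strand-aware window from ``window_up`` bp upstream of the gene TSS to
    ``window_down`` bp past its 3' end."""
    if gene.strand == "+":
        return gene.start - window_up, gene.end + window_down
    return gene.start - window_down, gene.end + window_up


def _signed_distance(gene: Gene, lnc: TranscriptModel) -> int:
    """Gene-oriented distance from the gene TSS to the nearest lncRNA edge;
    negative means the lncRNA lies upstream of the TSS, 0 means it covers it."""
    tss = gene.start if gene.strand == "+" else gene.end - 1  # TSS base
    if lnc.start <= tss < lnc.end:
        return 0
    if gene.strand == "+":
        # downstream: gap from TSS to lnc start; upstream: negative gap
        return lnc.start - tss if lnc.start > tss else lnc.end - 1 - tss
    return tss - (lnc.end - 1) if lnc.end - 1 < tss else tss - lnc.start


def predict_cis_targets(
    lncrnas: Iterable[TranscriptModel],
    annotation: Annotation,
    network_edges: Iterable[tuple[str, str, float]],
    window_up: int = 10_000,
    window_down: int = 100_000,
    min_score: float = 0.2,
) -> list[CisTargetPair]:
    """Cis targets: a (lncRNA, gene) pair is emitted iff the lncRNA placement
    intersects the window from ``window_up`` upstream of the gene TSS to
    ``window_down`` downstream of its 3' end (strand-aware on the gene) AND
    the co-expression network holds an edge between the two with score
    strictly greater than ``min_score``."""
    scores: dict[frozenset, float] = {}
    for a, b, s in network_edges:
        s = float(s)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"network edge score {s} outside [0, 1]")
        key = frozenset((a, b))
        scores[key] = max(s, scores.get(key, 0.0))

    pairs: list[CisTargetPair] = []
    for lnc in sorted(lncrnas, key=lambda t: t.id):
        for gene in annotation.by_chrom.get(lnc.chrom, []):
            lo, hi = _cis_window(gene, window_up, window_down)
            if lnc.end <= lo or lnc.start >= hi:
                continue
            score = scores.get(frozenset((lnc.id, gene.id)), 0.0)
            if score > min_score:
                pairs.append(
                    CisTargetPair(
                        lncrna_id=lnc.id,
                        gene_id=gene.id,
                        signed_distance=_signed_distance(gene, lnc),
                        network_score=score,
                    )
                )
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs
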