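"""Isoform catalog: collapse of aligned transcript models into non-redundant
isoforms, comparison to the reference annotation, classification of the five
alternative-splicing event categories, alternative-polyadenylation site
clustering, and condition-specific isoform calls.

Isoform identity for multi-exon models is the intron chain: the ordered
(donor, acceptor) coordinates of every intron. Terminal exon outer boundaries
are ragged in long reads and are merged into TSS/TES ranges rather than used
for identity. Mono-exon models have no chain and are grouped by reciprocal
overlap instead.

AS event vocabulary (relative to a reference transcript at the same locus):

* ``ES``   exon skipping — an internal reference exon absent from the
  isoform, its flanking introns fused into one isoform intron;
* ``IR``   intron retention — one isoform exon spans a reference intron plus
  parts of both flanking exons;
* ``A3S``  alternative 3' splice site — exactly the intron boundary nearer
  the transcript's 3' side differs (strand-aware);
* ``A5S``  alternative 5' splice site — the 5'-side boundary differs;
* ``IESC`` internal exon size change — both boundaries of an internal exon
  differ.

Terminal-exon outer-boundary differences never yield an event.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    Annotation,
    APASite,
    ASEvent,
    Isoform,
    TranscriptModel,
    chain_id,
)


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _single_exon_clusters(models: list[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Single-linkage clusters under >=50% reciprocal overlap (connected
    components, so the result is independent of input order)."""
    models = sorted(models, key=lambda m: (m.start, m.end, m.id))
    parent = list(range(len(models)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            if models[j].start >= models[i].end:
                break
            if _reciprocal_overlap(models[i].exons[0], models[j].exons[0]) >= 0.5:
                parent[find(i)] = find(j)
    groups: dict[int, list[TranscriptModel]] = defaultdict(list)
    for i, m in enumerate(models):
        groups[find(i)].append(m)
    return [groups[k] for k in sorted(groups, key=lambda k: groups[k][0].start)]


def _build_isoform(members: list[TranscriptModel], end_fuzz: int) -> Isoform:
    m0 = members[0]
    chain = m0.introns
    starts = [m.start for m in members]
    ends = [m.end for m in members]
    span = (min(starts), max(ends))
    if chain:
        exons = ((span[0], chain[0][0]),) + tuple(
            (chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)
        ) + ((chain[-1][1], span[1]),)
        extra = ""
    else:
        exons = (span,)
        # mono-exon isoforms carry their (fuzz-rounded) span in the id so the
        # id is stable under member order permutation and small end raggedness
        fuzz = max(end_fuzz, 1)
        extra = f"{span[0] // fuzz}-{span[1] // fuzz}"
    if m0.strand == "+":
        tss_range = (min(starts), max(starts))
        tes_range = (min(ends), max(ends))
    else:
        tss_range = (min(ends), max(ends))
        tes_range = (min(starts), max(starts))
    return Isoform(
        id=chain_id(m0.chrom, m0.strand, chain, extra),
        chrom=m0.chrom,
        strand=m0.strand,
        chain=chain,
        exons=exons,
        tss_range=tss_range,
        tes_range=tes_range,
        members=tuple(sorted(m.id for m in members)),
    )


def collapse_transcripts(
    models: Sequence[TranscriptModel], end_fuzz: int = 5
) -> list[Isoform]:
    """Collapse aligned transcript models into non-redundant isoforms.

    Multi-exon models are grouped by exact (chrom, strand, intron chain);
    terminal ends are merged into TSS/TES ranges. Mono-exon models on the
    same strand are grouped by >=50% reciprocal overlap (single linkage).
    Every input model appears in exactly one isoform's member list.
    """
    multi: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    mono: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        if len(m.exons) > 1:
            multi[(m.chrom, m.strand, m.introns)].append(m)
        else:
            mono[(m.chrom, m.strand)].append(m)
    isoforms = [_build_isoform(v, end_fuzz) for v in multi.values()]
    for group in mono.values():
        for cluster in _single_exon_clusters(group):
            isoforms.append(_build_isoform(cluster, end_fuzz))
    isoforms.sort(key=lambda i: (i.chrom, i.start, i.end, i.id))
    return isoforms


# ---------------------------------------------------------------------------
# locus assignment / class codes
# ---------------------------------------------------------------------------

def _exonic_overlap(exons_a, exons_b) -> int:
    total = 0
    for sa, ea in exons_a:
        for sb, eb in exons_b:
            total += max(0, min(ea, eb) - max(sa, sb))
    return total


def assign_loci(isoforms: Iterable[Isoform], annotation: Annotation) -> list[Isoform]:
    """Assign each isoform to the same-strand annotated gene with maximal
    exonic overlap and set its class code.

    ``reference_match``: the intron chain equals some annotated transcript's
    chain exactly (mono-exon: >=50% reciprocal overlap with a mono-exon
    annotated transcript). ``novel_isoform``: assigned to a gene but no chain
    match. ``novel_locus``: no gene with >=1 bp same-strand exonic overlap.
    """
    out = []
    for iso in isoforms:
        best_gene, best_ov = None, 0
        for gene in annotation.by_chrom.get(iso.chrom, []):
            if gene.strand != iso.strand or gene.end <= iso.start or gene.start >= iso.end:
                continue
            ov = _exonic_overlap(iso.exons, gene.exon_union())
            if ov > best_ov or (ov == best_ov and ov > 0 and gene.id < best_gene.id):
                best_gene, best_ov = gene, ov
        if best_gene is None:
            iso.locus_id, iso.class_code = None, "novel_locus"
        else:
            iso.locus_id = best_gene.id
            iso.class_code = "novel_isoform"
            for t in best_gene.transcripts:
                if iso.chain and t.introns == iso.chain:
                    iso.class_code = "reference_match"
                    break
                if not iso.chain and len(t.exons) == 1 and \
                        _reciprocal_overlap(iso.exons[0], t.exons[0]) >= 0.5:
                    iso.class_code = "reference_match"
                    break
        out.append(iso)
    return out


# ---------------------------------------------------------------------------
# AS event classification
# ---------------------------------------------------------------------------

def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _events_from_geometry(
    ref_exons: Sequence[tuple[int, int]],
    iso_exons: Sequence[tuple[int, int]],
    strand: str,
) -> list[tuple[str, int, int]]:
    """Pure geometry comparison; returns (event_type, start, end) tuples.

    Exposed separately from :func:`classify_as_events` so it can be swept
    exhaustively against an independent enumerator in the test suite.
    """
    ref_introns = [(ref_exons[i][1], ref_exons[i + 1][0]) for i in range(len(ref_exons) - 1)]
    iso_introns = [(iso_exons[i][1], iso_exons[i + 1][0]) for i in range(len(iso_exons) - 1)]
    events: list[tuple[str, int, int]] = []

    # exon skipping: internal reference exon with no overlapping isoform exon
    # whose two flanking reference introns are fused into one isoform intron
    for k in range(1, len(ref_exons) - 1):
        r = ref_exons[k]
        if any(_overlaps(r, e) for e in iso_exons):
            continue
        left, right = ref_introns[k - 1], ref_introns[k]
        if any(j[0] <= left[0] and j[1] >= right[1] for j in iso_introns):
            events.append(("ES", r[0], r[1]))

    # intron retention: an isoform exon spans a reference intron plus parts
    # of both flanking reference exons
    for ri in ref_introns:
        if any(e[0] < ri[0] and e[1] > ri[1] for e in iso_exons):
            events.append(("IR", ri[0], ri[1]))

    # one-to-one intron matching by overlap for boundary-shift events
    matches: list[tuple[int, int]] = []  # (iso intron idx, ref intron idx)
    for ji, j in enumerate(iso_introns):
        hits = [ki for ki, k in enumerate(ref_introns) if _overlaps(j, k)]
        if len(hits) != 1:
            continue
        ki = hits[0]
        back = [x for x, jj in enumerate(iso_introns) if _overlaps(jj, ref_introns[ki])]
        if back == [ji]:
            matches.append((ji, ki))

    diff: dict[int, set[str]] = {}  # iso intron idx -> differing genomic sides
    ref_of = dict(matches)
    for ji, ki in matches:
        d = set()
        if iso_introns[ji][0] != ref_introns[ki][0]:
            d.add("left")
        if iso_introns[ji][1] != ref_introns[ki][1]:
            d.add("right")
        if d:
            diff[ji] = d

    # internal exon size change: consecutive matched intron pairs (in both
    # transcripts) whose facing boundaries both shifted; consumes those shifts
    consumed: set[tuple[int, str]] = set()
    for ji, ki in matches:
        if (ji + 1, ki + 1) not in matches:
            continue
        if "right" in diff.get(ji, ()) and "left" in diff.get(ji + 1, ()):
            events.append(("IESC", iso_introns[ji][1], iso_introns[ji + 1][0]))
            consumed.add((ji, "right"))
            consumed.add((ji + 1, "left"))

    # remaining single-boundary shifts: A5S at the donor (5' splice) side,
    # A3S at the acceptor (3' splice) side, strand-aware
    for ji, sides in sorted(diff.items()):
        for side in sorted(sides):
            if (ji, side) in consumed:
                continue
            if strand == "+":
                etype = "A5S" if side == "left" else "A3S"
            else:
                etype = "A3S" if side == "left" else "A5S"
            j = iso_introns[ji]
            events.append((etype, j[0], j[1]))

    order = {"ES": 0, "IR": 1, "A3S": 2, "A5S": 3, "IESC": 4}
    events.sort(key=lambda e: (e[1], e[2], order[e[0]]))
    return events


def pick_reference(
    isoform: Isoform, refs: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Reference transcript sharing the most introns with the isoform
    (ties broken by longer genomic span, then id)."""
    if not refs:
        raise ValueError("reference transcript set must be non-empty")
    chain = set(isoform.chain)

    def key(t: TranscriptModel):
        return (len(chain & set(t.introns)), t.end - t.start, t.id)

    return max(refs, key=key)


def classify_as_events(
    isoform: Isoform, refs: Sequence[TranscriptModel]
) -> list[ASEvent]:
    """Classify the AS events of a novel isoform against the best-matching
    reference transcript at its locus.

    A mono-exon isoform compared to a multi-exon reference yields no events
    (such isoforms are tallied as 'unclassified mono-exon' by the callers).
    """
    ref = pick_reference(isoform, refs)
    if len(isoform.exons) == 1 and len(ref.exons) > 1:
        return []
    raw = _events_from_geometry(ref.exons, isoform.exons, isoform.strand)
    return [
        ASEvent(isoform_id=isoform.id, ref_transcript_id=ref.id, event_type=t,
                chrom=isoform.chrom, strand=isoform.strand, start=s, end=e)
        for t, s, e in raw
    ]


# ---------------------------------------------------------------------------
# alternative polyadenylation
# ---------------------------------------------------------------------------

def detect_apa(
    members: Sequence[TranscriptModel],
    locus_id: str,
    cluster_distance: int = 50,
) -> list[APASite]:
    """Cluster strand-aware transcript 3' ends by single linkage
    (gap <= ``cluster_distance`` chains) into alternative polyadenylation
    sites; one site per cluster at the support-weighted median end."""
    if not members:
        return []
    ends = sorted(m.three_prime for m in members)
    clusters: list[list[int]] = [[ends[0]]]
    for x in ends[1:]:
        if x - clusters[-1][-1] <= cluster_distance:
            clusters[-1].append(x)
        else:
            clusters.append([x])
    sites = []
    for c in clusters:
        pos = c[(len(c) - 1) // 2]  # lower median, deterministic
        sites.append(APASite(locus_id=locus_id, position=pos, support=len(c),
                             cluster_span=c[-1] - c[0]))
    return sites


def detect_apa_by_locus(
    isoforms: Sequence[Isoform],
    models_by_id: dict[str, TranscriptModel],
    cluster_distance: int = 50,
) -> dict[str, list[APASite]]:
    """APA sites for every assigned locus, pooling all member models."""
    per_locus: dict[str, list[TranscriptModel]] = defaultdict(list)
    for iso in isoforms:
        if iso.locus_id is None:
            continue
        per_locus[iso.locus_id].extend(models_by_id[m] for m in iso.members)
    return {
        locus: detect_apa(ms, locus, cluster_distance)
        for locus, ms in sorted(per_locus.items())
    }


# ---------------------------------------------------------------------------
# condition-specific isoforms
# ---------------------------------------------------------------------------

def condition_specific_isoforms(
    quant: pd.DataFrame,
    design: dict[str, str],
    expressed_min: float = 0.5,
    conditions: Optional[Sequence[str]] = None,
) -> dict[str, set[str]]:
    """Isoforms expressed (mean FPKM >= ``expressed_min``) in exactly one
    condition. ``design`` maps sample column -> condition label."""
    conditions = list(conditions) if conditions else sorted(set(design.values()))
    means = {}
    for cond in conditions:
        cols = [s for s, c in design.items() if c == cond]
        if not cols:
            raise ValueError(f"condition {cond!r} has no replicate columns")
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} needs >=2 replicates")
        means[cond] = quant[cols].mean(axis=1)
    expressed = pd.DataFrame({c: means[c] >= expressed_min for c in conditions})
    n_expr = expressed.sum(axis=1)
    out: dict[str, set[str]] = {}
    for cond in conditions:
        out[cond] = set(quant.index[(n_expr == 1) & expressed[cond]])
    return out
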