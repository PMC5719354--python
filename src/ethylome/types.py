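"""Core domain types shared across the pipeline stages.

All internal coordinates are 0-based, half-open intervals ``[start, end)``.
Conversion to the 1-based inclusive convention of GFF3/GTF happens only at
file emission/parsing time (see :mod:`ethylome.io`), so there is a single
conversion boundary in the whole package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-")

#: the five alternative-splicing event categories
AS_EVENT_TYPES = ("A3S", "A5S", "ES", "IR", "IESC")

#: positional classes for lncRNAs
LNCRNA_CLASSES = ("sense", "antisense", "intronic", "intergenic", "unmapped")

#: cytosine sequence contexts (H = A, C or T)
CONTEXTS = ("CG", "CHG", "CHH")

#: default treatment labels: control, low- and high-concentration ethephon
CONDITIONS = ("CK", "LE", "HE")


def _check_exons(exons) -> tuple[tuple[int, int], ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError("a transcript model needs at least one exon")
    prev_end = None
    for s, e in exons:
        if e <= s:
            raise ValueError(f"malformed exon ({s}, {e}): end must exceed start")
        if prev_end is not None and s < prev_end:
            raise ValueError("exons must be sorted and non-overlapping")
        prev_end = e
    return exons


@dataclass(frozen=True)
class TranscriptModel:
    """An aligned transcript: ordered exon intervals on a strand.

    This is the unit that gets collapsed into isoforms and compared against
    the reference annotation.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source_condition: Optional[str] = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        object.__setattr__(self, "exons", _check_exons(self.exons))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (empty for single-exon models)."""
        ex = self.exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    @property
    def three_prime(self) -> int:
        """Strand-aware 3' end coordinate (end for +, start for -)."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nt."""
        return sum(e - s for s, e in self.exons)


@dataclass
class Gene:
    """An annotated gene: a span plus its annotated transcripts."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exonic intervals over all transcripts of the gene."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


class Annotation:
    """A reference annotation: genes indexed by id and by chromosome."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {g.id: g for g in genes}
        self.by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self for t in g.transcripts]


def chain_id(chrom: str, strand: str, introns: tuple, extra: str = "") -> str:
    """Stable isoform identifier keyed on the intron chain, not input order."""
    payload = f"{chrom}|{strand}|{introns!r}|{extra}"
    return "ISO_" + hashlib.md5(payload.encode()).hexdigest()[:10]


@dataclass
class Isoform:
    """A non-redundant isoform: the collapse of transcript models that share
    an intron chain (or, for mono-exon models, a reciprocal-overlap cluster)."""

    id: str
    chrom: str
    strand: str
    chain: tuple[tuple[int, int], ...]
    exons: tuple[tuple[int, int], ...]
    tss_range: tuple[int, int]
    tes_range: tuple[int, int]
    members: tuple[str, ...]
    locus_id: Optional[str] = None
    class_code: Optional[str] = None  # reference_match | novel_isoform | novel_locus

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing difference between an isoform and a reference
    transcript. ``event_type`` is one of A3S, A5S, ES, IR, IESC."""

    isoform_id: str
    ref_transcript_id: str
    event_type: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.event_type not in AS_EVENT_TYPES:
            raise ValueError(f"unknown AS event type {self.event_type!r}")


@dataclass(frozen=True)
class APASite:
    """A clustered transcript 3' end at a locus (alternative polyadenylation
    site). A locus with >= 2 sites is 'multi-APS'."""

    locus_id: str
    position: int
    support: int
    cluster_span: int


@dataclass
class LncRNARecord:
    id: str
    length: int
    exon_count: Optional[int]  # None iff unmapped
    positional_class: str
    transcript: Optional[TranscriptModel] = None

    def __post_init__(self):
        if self.positional_class not in LNCRNA_CLASSES:
            raise ValueError(f"unknown lncRNA class {self.positional_class!r}")
        if (self.exon_count is None) != (self.positional_class == "unmapped"):
            raise ValueError("exon_count must be None iff class is 'unmapped'")


@dataclass(frozen=True)
class CisTargetPair:
    lncrna_id: str
    gene_id: str
    signed_distance: int  # negative = lncRNA upstream of the gene TSS
    network_score: float


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region between two conditions in one
    context. ``direction`` is hyper/hypo in condition B relative to A."""

    chrom: str
    start: int
    end: int
    context: str
    pair: tuple[str, str]
    direction: str  # 'hyper' | 'hypo'
    level_a: float
    level_b: float
    delta: float
    p_value: float
    q_value: float
    n_cytosines: int
    annotation: Optional[str] = None  # gene-body|gene-upstream|gene-downstream|TE|intergenic
    gene_ids: tuple[str, ...] = ()


@dataclass
class CoexpressionModule:
    """A gene cluster with an eigengene and signed condition associations."""

    id: str
    members: tuple[str, ...]
    eigengene: "object"  # pandas Series indexed by sample
    condition_association: dict = field(default_factory=dict)  # cond -> (r, q, sign)
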