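"""Synthetic data with machine-readable ground truth for every pipeline stage.

The generator emulates the five input kinds of the real study — genome,
annotation, aligned long-read transcript models, per-condition WGBS
cytosine tables, and an FPKM expression matrix over three conditions
(control plus low/high ethephon, CK/LE/HE) with replicates — and records
the planted truth (AS events of the five categories, multi-APS loci,
lncRNA positional classes, DMRs with direction, co-expressed modules with
condition effects) so downstream stages can be scored for recovery.

It simulates *summaries*, not reads: methylation is drawn per cytosine as
Poisson coverage with binomial methylated counts, and expression as latent
condition profiles plus Gaussian noise clipped at zero. Long-read error
models and bisulfite conversion chemistry are out of scope by design.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .methylome import cytosine_sites
from .types import Annotation, CONDITIONS, CONTEXTS, Gene, TranscriptModel

#: gene-profile archetypes for the 4-way methylation clustering:
#: 1 high upstream CG; 2 body above upstream in every context;
#: 3 low everywhere; 4 high CG+CHG in both regions with low CHH
ARCHETYPE_LEVELS = {
    1: {"upstream": {"CG": 0.90, "CHG": 0.05, "CHH": 0.03},
        "body": {"CG": 0.20, "CHG": 0.05, "CHH": 0.03}},
    2: {"upstream": {"CG": 0.10, "CHG": 0.05, "CHH": 0.02},
        "body": {"CG": 0.70, "CHG": 0.50, "CHH": 0.30}},
    3: {"upstream": {"CG": 0.02, "CHG": 0.02, "CHH": 0.02},
        "body": {"CG": 0.02, "CHG": 0.02, "CHH": 0.02}},
    4: {"upstream": {"CG": 0.80, "CHG": 0.60, "CHH": 0.02},
        "body": {"CG": 0.80, "CHG": 0.60, "CHH": 0.02}},
}


@dataclass
class TruthTable:
    """Planted ground truth for all stages."""

    #: (model_id, event_type, gene_id, start, end) — coords follow the
    #: classifier's reporting convention per event type
    planted_as_events: list = field(default_factory=list)
    #: (gene_id, sorted tuple of planted 3' end positions)
    planted_apa: list = field(default_factory=list)
    #: (lncrna_id, positional class)
    planted_lncrnas: list = field(default_factory=list)
    #: (chrom, start, end, context, (cond_a, cond_b), direction)
    planted_dmrs: list = field(default_factory=list)
    #: (tuple of gene ids, condition, sign)
    planted_modules: list = field(default_factory=list)
    #: (gene_id, (cond_a, cond_b), 'up'/'down')
    planted_de: list = field(default_factory=list)
    #: gene_id -> methylation archetype (1..4), when planted
    planted_archetypes: dict = field(default_factory=dict)

    def merge(self, other: "TruthTable") -> "TruthTable":
        for f in self.__dataclass_fields__:
            mine = getattr(self, f)
            theirs = getattr(other, f)
            if isinstance(mine, dict):
                mine.update(theirs)
            else:
                mine.extend(theirs)
        return self

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_length: int = 100_000,
    gc_fraction: float = 0.4,
) -> dict[str, str]:
    """Random genome: ``n_chrom`` chromosomes of ``chrom_length`` bp with
    iid bases at the requested GC fraction. Deterministic for a fixed seed."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for i in range(n_chrom):
        draw = rng.choice(bases, size=chrom_length, p=[at, gc, gc, at])
        out[f"chr{i + 1}"] = draw.tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    genome: dict[str, str],
    seed: int,
    n_genes: int = 50,
    exons_per_gene: tuple[int, int] = (2, 5),
    intergenic_gap: int = 500,
    exon_length: tuple[int, int] = (150, 400),
    intron_length: tuple[int, int] = (80, 300),
) -> Annotation:
    """Pack genes onto the chromosomes left to right with random gaps of at
    least ``intergenic_gap`` bp; ~50/50 strand assignment; one transcript
    per gene with sorted, non-overlapping exon chains."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    cursors = {c: 0 for c in chroms}
    genes: list[Gene] = []
    lo_e, hi_e = exons_per_gene
    for gi in range(n_genes):
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        ex_lens = rng.integers(exon_length[0], exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_length[0], intron_length[1] + 1, size=max(n_ex - 1, 0))
        span = int(ex_lens.sum() + in_lens.sum())
        chrom = chroms[gi % len(chroms)]
        gap = int(intergenic_gap + rng.integers(0, intergenic_gap + 1))
        start = cursors[chrom] + gap
        if start + span > len(genome[chrom]):
            raise ValueError(
                f"cannot place gene {gi + 1}/{n_genes} on {chrom}: "
                f"needs {start + span} bp, chromosome has {len(genome[chrom])}"
            )
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{gi + 1:04d}"
        gene = Gene(id=gid, chrom=chrom, strand=strand, start=start, end=pos)
        gene.transcripts.append(
            TranscriptModel(id=f"{gid}.t1", chrom=chrom, strand=strand,
                            exons=tuple(exons))
        )
        genes.append(gene)
        cursors[chrom] = pos
    return Annotation(genes)


def _intergenic_gaps(genome, annotation, margin: int = 100) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom in sorted(genome):
        genes = annotation.by_chrom.get(chrom, [])
        prev = 0
        for g in genes:
            if g.start - prev > 2 * margin:
                gaps.append((chrom, prev + margin, g.start - margin))
            prev = max(prev, g.end)
        if len(genome[chrom]) - prev > 2 * margin:
            gaps.append((chrom, prev + margin, len(genome[chrom]) - margin))
    return gaps


# ---------------------------------------------------------------------------
# long-read transcript models with planted AS / APA / lncRNAs
# ---------------------------------------------------------------------------

def _jitter_ends(exons, rng, jitter: int):
    if jitter <= 0:
        return tuple(exons)
    exons = [list(e) for e in exons]
    d5 = int(rng.integers(-jitter, jitter + 1))
    d3 = int(rng.integers(-jitter, jitter + 1))
    exons[0][0] = min(exons[0][0] + d5, exons[0][1] - 1)
    exons[-1][1] = max(exons[-1][1] + d3, exons[-1][0] + 1)
    if exons[0][0] < 0:
        exons[0][0] = 0
    return tuple((s, e) for s, e in exons)


def generate_isoform_reads(
    annotation: Annotation,
    seed: int,
    as_rates: Optional[dict[str, float]] = None,
    apa_rate: float = 0.0,
    apa_shift: int = 60,
    novel_locus_rate: float = 0.0,
    lncrna_spec: Optional[dict[str, int]] = None,
    genome: Optional[dict[str, str]] = None,
    min_shift: int = 9,
    jitter: int = 0,
    n_baseline_reads: int = 2,
) -> tuple[list[TranscriptModel], TruthTable]:
    """Emit aligned transcript models per gene plus planted perturbations.

    Every gene emits ``n_baseline_reads`` models matching its annotated
    intron chain (terminal ends optionally jittered). For each AS category
    with a positive rate, a gene is perturbed with that probability into an
    extra model carrying exactly one geometrically valid event; splice
    boundary shifts for A3S/A5S/IESC are at least ``min_shift`` bp. With
    probability ``apa_rate`` a gene emits an extra model whose 3' end lies
    more than ``apa_shift`` bp away. ``lncrna_spec`` plants transcripts of
    the requested positional classes; ``novel_locus_rate`` plants models in
    intergenic space.
    """
    as_rates = dict(as_rates or {})
    lncrna_spec = dict(lncrna_spec or {})
    for name, rate in list(as_rates.items()) + [("apa", apa_rate), ("novel", novel_locus_rate)]:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    models: list[TranscriptModel] = []

    for gene in sorted(annotation, key=lambda g: g.id):
        ref = gene.transcripts[0]
        exons = list(ref.exons)
        n_ex = len(exons)
        for r in range(n_baseline_reads):
            models.append(TranscriptModel(
                id=f"{gene.id}.read{r + 1}", chrom=gene.chrom, strand=gene.strand,
                exons=_jitter_ends(exons, rng, jitter),
            ))

        apa_positions = {ref.three_prime}
        for etype in ("ES", "IR", "A3S", "A5S", "IESC"):
            rate = as_rates.get(etype, 0.0)
            if rate <= 0.0 or rng.random() >= rate:
                continue
            new = None
            if etype == "ES" and n_ex >= 3:
                j = int(rng.integers(1, n_ex - 1))
                new = exons[:j] + exons[j + 1:]
                coords = exons[j]
            elif etype == "IR" and n_ex >= 3:
                # >=3-exon parents only: retaining the sole intron of a
                # 2-exon gene leaves a mono-exon model, which is by design
                # unclassifiable against a multi-exon reference
                j = int(rng.integers(0, n_ex - 1))
                coords = (exons[j][1], exons[j + 1][0])
                new = exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2:]
            elif etype in ("A3S", "A5S") and n_ex >= 2:
                j = int(rng.integers(0, n_ex - 1))
                donor, acceptor = exons[j][1], exons[j + 1][0]
                shift = min_shift + int(rng.integers(0, 4))
                # which genomic boundary is the 3'-side of this intron
                move_acceptor = (gene.strand == "+") == (etype == "A3S")
                if move_acceptor:
                    new_a = acceptor + shift  # shrink downstream exon
                    if new_a >= exons[j + 1][1] - 1:
                        continue
                    new = exons[:j + 1] + [(new_a, exons[j + 1][1])] + exons[j + 2:]
                    coords = (donor, new_a)
                else:
                    new_d = donor - shift  # shrink upstream exon
                    if new_d <= exons[j][0] + 1:
                        continue
                    new = exons[:j] + [(exons[j][0], new_d)] + exons[j + 1:]
                    coords = (new_d, acceptor)
            elif etype == "IESC" and n_ex >= 3:
                j = int(rng.integers(1, n_ex - 1))
                s_old, e_old = exons[j]
                d1 = min_shift + int(rng.integers(0, 4))
                d2 = min_shift + int(rng.integers(0, 4))
                s_new, e_new = s_old + d1, e_old - d2
                if e_new - s_new < 2:
                    continue
                new = exons[:j] + [(s_new, e_new)] + exons[j + 1:]
                coords = (s_new, e_new)
            if new is None:
                continue
            mid = f"{gene.id}.{etype.lower()}"
            models.append(TranscriptModel(
                id=mid, chrom=gene.chrom, strand=gene.strand,
                exons=_jitter_ends(new, rng, jitter),
            ))
            truth.planted_as_events.append((mid, etype, gene.id, coords[0], coords[1]))

        if apa_rate > 0.0 and rng.random() < apa_rate:
            shift = apa_shift + 1 + int(rng.integers(0, 20))
            new = [list(e) for e in exons]
            if gene.strand == "+":
                new_end = min(exons[-1][1] + shift, len_of(genome, gene.chrom) or exons[-1][1] + shift)
                new[-1][1] = new_end
                apa_positions.add(new_end)
            else:
                new_start = max(exons[0][0] - shift, 0)
                new[0][0] = new_start
                apa_positions.add(new_start)
            mid = f"{gene.id}.apa"
            models.append(TranscriptModel(
                id=mid, chrom=gene.chrom, strand=gene.strand,
                exons=tuple(tuple(e) for e in new),
            ))
        if len(apa_positions) > 1:
            truth.planted_apa.append((gene.id, tuple(sorted(apa_positions))))

    gaps = _available_gaps(genome, annotation)
    gap_cursor = 0

    def _take_gap(length: int) -> Optional[tuple[str, int]]:
        nonlocal gap_cursor
        for k in range(len(gaps)):
            idx = (gap_cursor + k) % len(gaps)
            chrom, s, e = gaps[idx]
            if e - s >= length:
                gaps[idx] = (chrom, s + length + 50, e)
                gap_cursor = idx + 1
                return chrom, s
        return None

    if novel_locus_rate > 0.0:
        for gi in range(len(annotation.genes)):
            if rng.random() >= novel_locus_rate:
                continue
            spot = _take_gap(400)
            if spot is None:
                break
            chrom, s = spot
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(TranscriptModel(
                id=f"novel{gi + 1:03d}", chrom=chrom, strand=strand,
                exons=((s, s + 180), (s + 280, s + 400)),
            ))

    _plant_lncrnas(annotation, lncrna_spec, rng, models, truth, _take_gap)

    models.sort(key=lambda m: m.id)
    return models, truth


def len_of(genome, chrom):
    if genome is None:
        return None
    return len(genome[chrom])


def _available_gaps(genome, annotation):
    if genome:
        return _intergenic_gaps(genome, annotation)
    # without a genome, infer free space up to the last gene plus slack
    gaps = []
    for chrom, genes in annotation.by_chrom.items():
        prev = 0
        for g in genes:
            if g.start - prev > 300:
                gaps.append((chrom, prev + 100, g.start - 100))
            prev = max(prev, g.end)
        gaps.append((chrom, prev + 100, prev + 5000))
    gaps.sort()
    return gaps


def _plant_lncrnas(annotation, lncrna_spec, rng, models, truth, take_gap):
    genes = sorted(annotation, key=lambda g: g.id)
    multi = [g for g in genes
             if any(e - s >= 260 for s, e in g.transcripts[0].introns)]
    counters = {}
    for cls, count in sorted(lncrna_spec.items()):
        for k in range(count):
            counters[cls] = counters.get(cls, 0) + 1
            lid = f"lnc_{cls}{counters[cls]:03d}"
            if cls == "unmapped":
                truth.planted_lncrnas.append((lid, cls))
                continue
            if cls in ("sense", "antisense"):
                gene = genes[(k * 7 + (0 if cls == "sense" else 3)) % len(genes)]
                ex = gene.transcripts[0].exons[0]
                s = ex[0] + 10
                e = max(s + 250, ex[0] + min(250, ex[1] - ex[0]))
                strand = gene.strand if cls == "sense" else ("-" if gene.strand == "+" else "+")
                models.append(TranscriptModel(id=lid, chrom=gene.chrom,
                                              strand=strand, exons=((s, e),)))
            elif cls == "intronic":
                if not multi:
                    raise ValueError(
                        "lncrna_spec requests an intronic lncRNA but no gene "
                        "has an intron of at least 260 bp"
                    )
                gene = multi[k % len(multi)]
                intr = next(i for i in gene.transcripts[0].introns if i[1] - i[0] >= 260)
                s = intr[0] + 20
                e = s + 220
                strand = "+" if rng.random() < 0.5 else "-"
                models.append(TranscriptModel(id=lid, chrom=gene.chrom,
                                              strand=strand, exons=((s, e),)))
            elif cls == "intergenic":
                spot = take_gap(300)
                if spot is None:
                    raise ValueError("no intergenic space left for a planted lncRNA")
                chrom, s = spot
                strand = "+" if rng.random() < 0.5 else "-"
                models.append(TranscriptModel(id=lid, chrom=chrom,
                                              strand=strand, exons=((s, s + 300),)))
            else:
                raise ValueError(f"unknown lncRNA class {cls!r}")
            truth.planted_lncrnas.append((lid, cls))


def noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence guaranteed free of ATG (hence ORF-less)."""
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    seq = bytearray(arr.tobytes())
    while True:
        i = bytes(seq).find(b"ATG")
        if i < 0:
            return bytes(seq).decode()
        seq[i + 2] = ord("C")


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DMRSpec:
    """Specification for one batch of planted DMRs."""

    count: int
    length: int
    context: str
    delta: float
    pair: tuple[str, str]


DEFAULT_PROFILES = {
    "CK": {"CG": 0.30, "CHG": 0.15, "CHH": 0.05},
    "LE": {"CG": 0.30, "CHG": 0.15, "CHH": 0.08},
    "HE": {"CG": 0.30, "CHG": 0.15, "CHH": 0.12},
}


def generate_methylome(
    genome: dict[str, str],
    annotation: Optional[Annotation],
    seed: int,
    condition_profiles: Optional[dict[str, dict[str, float]]] = None,
    planted_dmrs: Sequence[DMRSpec] = (),
    coverage: float = 30.0,
    conversion_error: float = 0.005,
    gene_archetypes: Optional[dict[str, int]] = None,
    flank: int = 2000,
    min_dmr_gap: int = 400,
) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """Per-condition cytosine call tables with planted DMRs.

    Every cytosine of the genome gets Poisson(``coverage``) total counts and
    Binomial(total, level + conversion_error) methylated counts, where the
    level comes from the condition's per-context base profile, overridden
    inside planted DMRs (the hyper condition of the pair gets base + delta)
    and, when ``gene_archetypes`` is given, inside gene upstream/body
    regions by the archetype level tables. Planted DMR intervals are
    mutually non-overlapping and separated by at least ``min_dmr_gap`` bp.
    """
    profiles = condition_profiles or DEFAULT_PROFILES
    for cond, prof in profiles.items():
        for ctx, lev in prof.items():
            if not 0.0 <= lev <= 1.0:
                raise ValueError(f"base level {lev} for {cond}/{ctx} outside [0, 1]")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    truth = TruthTable()

    sites = cytosine_sites(genome)
    chrom_arrays = {}
    for chrom, sub in sites.groupby("chrom", sort=True):
        chrom_arrays[chrom] = sub

    # place planted DMRs without overlap, away from each other
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    placements = []  # (chrom, start, end, context, pair, direction, delta)
    for spec in planted_dmrs:
        if spec.context not in CONTEXTS:
            raise ValueError(f"bad DMR context {spec.context!r}")
        for cond in spec.pair:
            base = profiles[cond][spec.context]
            if not 0.0 <= base + spec.delta <= 1.0:
                raise ValueError(
                    f"base level {base} + delta {spec.delta} for {cond}/"
                    f"{spec.context} leaves [0, 1]"
                )
        placed = 0
        attempts = 0
        chroms = sorted(genome)
        while placed < spec.count:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("could not place all planted DMRs; genome too small")
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            clen = len(genome[chrom])
            if clen <= spec.length + 2:
                raise ValueError(f"planted DMR of {spec.length} bp falls off {chrom}")
            s = int(rng.integers(0, clen - spec.length))
            e = s + spec.length
            if any(s - min_dmr_gap < oe and os_ - min_dmr_gap < e
                   for os_, oe in occupied[chrom]):
                continue
            occupied[chrom].append((s, e))
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            placements.append((chrom, s, e, spec.context, spec.pair, direction,
                               spec.delta))
            truth.planted_dmrs.append((chrom, s, e, spec.context, spec.pair, direction))
            placed += 1

    out: dict[str, pd.DataFrame] = {}
    for cond in profiles:
        frames = []
        for chrom in sorted(genome):
            sub = chrom_arrays.get(chrom)
            if sub is None or sub.empty:
                continue
            pos = sub["pos0"].to_numpy()
            ctx = sub["context"].to_numpy()
            level = np.zeros(len(sub))
            for c in CONTEXTS:
                level[ctx == c] = profiles[cond].get(c, 0.0)
            # archetype gene-region overrides (condition-independent)
            if gene_archetypes and annotation is not None:
                for gene in annotation.by_chrom.get(chrom, []):
                    arch = gene_archetypes.get(gene.id)
                    if arch is None:
                        continue
                    table = ARCHETYPE_LEVELS[arch]
                    if gene.strand == "+":
                        regions = {"upstream": (max(gene.start - flank, 0), gene.start),
                                   "body": (gene.start, gene.end)}
                    else:
                        regions = {"upstream": (gene.end, gene.end + flank),
                                   "body": (gene.start, gene.end)}
                    for region, (s, e) in regions.items():
                        m = (pos >= s) & (pos < e)
                        for c in CONTEXTS:
                            level[m & (ctx == c)] = table[region][c]
            # planted DMR overrides
            for pchrom, s, e, pctx, pair, direction, delta in placements:
                if pchrom != chrom:
                    continue
                high = pair[1] if direction == "hyper" else pair[0]
                if cond != high:
                    continue
                m = (pos >= s) & (pos < e) & (ctx == pctx)
                level[m] = level[m] + delta
            p = np.clip(level + conversion_error, 0.0, 1.0)
            total = rng.poisson(coverage, size=len(sub))
            m_count = rng.binomial(total, p)
            df = sub.copy()
            df["m_count"] = m_count
            df["total_count"] = total
            frames.append(df[df["total_count"] > 0])
        cond_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "pos0", "strand", "context", "m_count", "total_count"])
        out[cond] = cond_df.reset_index(drop=True)
    return out, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

STANDARD_PAIRS = [("CK", "LE"), ("CK", "HE"), ("LE", "HE")]


def generate_expression(
    annotation: Annotation,
    seed: int,
    n_modules: int = 3,
    module_size: int = 30,
    condition_effects: Optional[Sequence[tuple[str, int]]] = None,
    n_reps: int = 3,
    noise_sd: float = 0.2,
    conditions: Sequence[str] = CONDITIONS,
    baseline_range: tuple[float, float] = (3.0, 8.0),
    effect_magnitude: float = 3.0,
    extra_ids: Sequence[str] = (),
    correlated_extra: Optional[dict[str, str]] = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """FPKM matrix over ``conditions`` x ``n_reps`` replicates.

    Genes of a planted module share a latent profile: the gene's baseline
    multiplied by ``1 + effect_magnitude`` (sign +1) or divided by it
    (sign -1) in the module's condition, plus Gaussian noise of
    ``noise_sd``; values are clipped at zero. The multiplicative effect
    keeps planted fold changes comparable across baselines. Remaining genes are
    independent noise around their own baselines. ``extra_ids`` adds rows
    (e.g. lncRNAs) of independent noise, except ids in ``correlated_extra``
    which track the named gene's profile (for cis-target tests).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2: downstream correlation is undefined")
    gene_ids = sorted(annotation.genes)
    if n_modules * module_size > len(gene_ids):
        raise ValueError("n_modules * module_size exceeds the number of genes")
    if condition_effects is not None:
        effects = list(condition_effects)
    else:
        # default: one module per condition, treatment modules induced,
        # the control module repressed; distinct conditions keep planted
        # modules separable under unsigned power adjacency
        rev = list(conditions)[::-1]
        effects = [
            (rev[i % len(rev)], -1 if rev[i % len(rev)] == conditions[0] else 1)
            for i in range(n_modules)
        ]
    if len(effects) != n_modules:
        raise ValueError("condition_effects must give one (condition, sign) per module")

    rng = np.random.default_rng(seed)
    truth = TruthTable()
    samples = [f"{c}_{r + 1}" for c in conditions for r in range(n_reps)]
    cond_of = np.array([c for c in conditions for _ in range(n_reps)])

    perm = rng.permutation(len(gene_ids))
    values = {}
    module_assignment = {}
    for mi in range(n_modules):
        cond, sign = effects[mi]
        members = tuple(sorted(gene_ids[p] for p in
                               perm[mi * module_size:(mi + 1) * module_size]))
        truth.planted_modules.append((members, cond, int(sign)))
        for g in members:
            module_assignment[g] = (cond, int(sign))
        for pa, pb in STANDARD_PAIRS:
            if cond == pb:
                d = "up" if sign > 0 else "down"
            elif cond == pa:
                d = "down" if sign > 0 else "up"
            else:
                continue
            for g in members:
                truth.planted_de.append((g, (pa, pb), d))

    for g in gene_ids:
        base = rng.uniform(*baseline_range)
        profile = np.full(len(samples), base)
        if g in module_assignment:
            cond, sign = module_assignment[g]
            fold = 1.0 + effect_magnitude
            factor = fold if sign > 0 else 1.0 / fold
            profile = np.where(cond_of == cond, profile * factor, profile)
        values[g] = np.clip(profile + rng.normal(0, noise_sd, len(samples)), 0, None)

    for x in extra_ids:
        if correlated_extra and x in correlated_extra:
            target = values[correlated_extra[x]]
            values[x] = np.clip(target + rng.normal(0, noise_sd, len(samples)), 0, None)
        else:
            base = rng.uniform(*baseline_range)
            values[x] = np.clip(base + rng.normal(0, noise_sd, len(samples)), 0, None)

    matrix = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    matrix.index.name = "gene_id"
    return matrix, truth


def design_of(matrix: pd.DataFrame) -> dict[str, str]:
    """Sample -> condition map recovered from 'COND_rep' column names."""
    return {s: s.rsplit("_", 1)[0] for s in matrix.columns}
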