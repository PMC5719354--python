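"""Independent oracles used by the test suite.

Each oracle re-derives an expected result through a different route than the
package implementation: brute-force enumeration over exon/intron sets for AS
events, binomial-coefficient arithmetic for Fisher tails, Biopython
translation for ORFs, and reverse-complement string logic for cytosine
contexts. They are deliberately simple and slow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb

H = set("ACT")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def context_oracle(tri: str) -> str | None:
    """Context of a 5'->3' trinucleotide starting at a cytosine."""
    assert tri[0] == "C"
    if tri[1] == "G":
        return "CG"
    if tri[1] in H and tri[2] == "G":
        return "CHG"
    if tri[1] in H and tri[2] in H:
        return "CHH"
    return None


# ---------------------------------------------------------------------------
# AS event enumeration
# ---------------------------------------------------------------------------

def _introns(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def _ov(a, b):
    return a[0] < b[1] and b[0] < a[1]


def as_events_oracle(ref_exons, iso_exons, strand):
    """Brute-force enumeration of AS events between two exon chains.

    Tests every candidate location of every event category against its
    definition; boundary shifts are resolved through an explicit bijective
    intron-overlap matching with internal-exon (IESC) consumption.
    """
    ref_in, iso_in = _introns(ref_exons), _introns(iso_exons)
    found = []

    # exon skipping over each internal reference exon
    for k, rex in enumerate(ref_exons):
        if k == 0 or k == len(ref_exons) - 1:
            continue
        untouched = all(not _ov(rex, e) for e in iso_exons)
        fused = any(j[0] <= ref_in[k - 1][0] and j[1] >= ref_in[k][1] for j in iso_in)
        if untouched and fused:
            found.append(("ES",) + rex)

    # intron retention over each reference intron
    for ri in ref_in:
        if any(e[0] < ri[0] and e[1] > ri[1] for e in iso_exons):
            found.append(("IR",) + ri)

    # bijective intron matching: iso intron j <-> ref intron k when each
    # overlaps the other and nothing else
    overlap_matrix = {
        (ji, ki): _ov(j, k)
        for ji, j in enumerate(iso_in)
        for ki, k in enumerate(ref_in)
    }
    matched = {}
    for ji in range(len(iso_in)):
        partners = [ki for ki in range(len(ref_in)) if overlap_matrix[(ji, ki)]]
        if len(partners) == 1:
            ki = partners[0]
            rev = [x for x in range(len(iso_in)) if overlap_matrix[(x, ki)]]
            if rev == [ji]:
                matched[ji] = ki

    shifted = {}  # (iso intron, genomic side) -> True
    for ji, ki in matched.items():
        if iso_in[ji][0] != ref_in[ki][0]:
            shifted[(ji, "L")] = True
        if iso_in[ji][1] != ref_in[ki][1]:
            shifted[(ji, "R")] = True

    eaten = set()
    for ji, ki in matched.items():
        if matched.get(ji + 1) == ki + 1 and (ji, "R") in shifted and (ji + 1, "L") in shifted:
            found.append(("IESC", iso_in[ji][1], iso_in[ji + 1][0]))
            eaten |= {(ji, "R"), (ji + 1, "L")}

    for (ji, side) in shifted:
        if (ji, side) in eaten:
            continue
        donor_side = side == ("L" if strand == "+" else "R")
        found.append((("A5S" if donor_side else "A3S"),) + iso_in[ji])

    order = {"ES": 0, "IR": 1, "A3S": 2, "A5S": 3, "IESC": 4}
    return sorted(found, key=lambda e: (e[1], e[2], order[e[0]]))


def enumerate_chains(points, max_exons):
    """All strictly increasing exon chains with <= max_exons exons drawn
    from a boundary grid."""
    from itertools import combinations

    chains = []
    for k in range(1, max_exons + 1):
        for cut in combinations(points, 2 * k):
            chains.append(tuple((cut[2 * i], cut[2 * i + 1]) for i in range(k)))
    return chains


# ---------------------------------------------------------------------------
# Fisher / binomial tails
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p from binomial-coefficient arithmetic."""
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0:
        return 1.0
    denom = comb(N, n, exact=True)

    def pmf(k):
        return comb(K, k, exact=True) * comb(N - K, n - k, exact=True) / denom

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, n - (N - K)), min(K, n) + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def binom_tail_oracle(m, n, p):
    """P(X >= m) for X ~ Binomial(n, p) by direct summation."""
    total = 0.0
    for k in range(m, n + 1):
        total += comb(n, k, exact=True) * p**k * (1 - p) ** (n - k)
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# ORF scanning via translation
# ---------------------------------------------------------------------------

def orf_oracle(seq: str) -> int:
    """Longest forward-frame ORF in codons via Biopython translation:
    the longest 'M...' run without a stop in any frame (open-ended runs
    count to the end of the frame)."""
    import re

    from Bio.Seq import Seq

    best = 0
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        protein = str(Seq(sub).translate())
        for match in re.finditer(r"M[^*]*", protein):
            best = max(best, len(match.group(0)))
    return best
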