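"""Whole-genome bisulfite methylome analysis.

Per-cytosine calls (chrom, 0-based position, strand, context, methylated
count, total count) are held in pandas DataFrames with the columns of
:data:`ethylome.io.METH_COLUMNS`. The stage covers:

* sequence-context assignment (CG / CHG / CHH, H = A, C or T) read from the
  genome on either strand;
* binomial methylated-cytosine calling against the bisulfite
  non-conversion error rate, BH-corrected per condition;
* cross-condition categorisation of methylated sites (constitutive,
  condition-specific, varied);
* pooled region methylation levels, per-gene upstream/body/downstream
  profiles and k-means grouping of gene profiles;
* sliding-window DMR calling with a two-sided Fisher exact test, BH
  correction, delta thresholds per context and merging of adjacent
  significant windows;
* DMR annotation against genes/TEs and DMR set overlap.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DMR, Annotation, CONTEXTS

log = logging.getLogger(__name__)

#: default minimum |methylation difference| for a DMR window, per context.
#: These follow common WGBS practice (CG most stringent, CHH least).
DEFAULT_MIN_DELTA = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}

_H = set(b"ACT")  # 'H' = A, C or T
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------

def assign_context(genome: dict[str, str], chrom: str, pos0: int, strand: str) -> Optional[str]:
    """Sequence context of the cytosine at (chrom, pos0, strand).

    On the + strand the context reads bases pos0..pos0+2 left to right; on
    the - strand it reads the complemented bases pos0..pos0-2 (5'->3' on the
    minus strand). Returns 'CG', 'CHG', 'CHH', or None when the needed bases
    run off the sequence end or hit an N. Raises if the strand-adjusted base
    at pos0 is not a cytosine.
    """
    seq = genome[chrom].upper().encode()
    if not 0 <= pos0 < len(seq):
        raise IndexError(f"position {pos0} outside {chrom}")
    if strand == "+":
        tri = seq[pos0 : pos0 + 3]
    elif strand == "-":
        lo = max(pos0 - 2, 0)
        tri = seq[lo : pos0 + 1][::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"bad strand {strand!r}")
    if tri[0:1] != b"C":
        raise ValueError(f"base at ({chrom}, {pos0}, {strand}) is not a cytosine")
    if len(tri) >= 2 and tri[1:2] == b"G":
        return "CG"
    if len(tri) < 3 or tri[1] not in _H:
        return None  # needed base missing or N
    if tri[2:3] == b"G":
        return "CHG"
    if tri[2] in _H:
        return "CHH"
    return None


def cytosine_sites(genome: dict[str, str]) -> pd.DataFrame:
    """All cytosines of the genome (both strands) with assigned context.

    Vectorised over the whole sequence; sites whose context cannot be
    determined (sequence end, adjacent N) are omitted.
    """
    frames = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].upper().encode(), dtype=np.uint8)
        n = arr.size
        nxt = np.empty(n, dtype=np.uint8)
        nxt[:-1], nxt[-1] = arr[1:], 0
        nx2 = np.empty(n, dtype=np.uint8)
        nx2[:-2], nx2[-2:] = arr[2:], 0
        prv = np.empty(n, dtype=np.uint8)
        prv[1:], prv[0] = arr[:-1], 0
        pv2 = np.empty(n, dtype=np.uint8)
        pv2[2:], pv2[:2] = arr[:-2], 0

        def _mask(base, a, b, plus: bool):
            isH = np.isin(a, list(_H)) if plus else np.isin(a, [ord(c) for c in "TGA"])
            isH2 = np.isin(b, list(_H)) if plus else np.isin(b, [ord(c) for c in "TGA"])
            g = ord("G") if plus else ord("C")
            cg = a == g
            chg = isH & (b == g)
            chh = isH & isH2
            return cg, chg, chh

        for strand, cbase, a, b in (("+", ord("C"), nxt, nx2), ("-", ord("G"), prv, pv2)):
            isc = arr == cbase
            cg, chg, chh = _mask(cbase, a, b, strand == "+")
            for ctx, m in (("CG", cg), ("CHG", chg), ("CHH", chh)):
                sel = isc & m
                # positions whose context window runs off the chromosome end
                if strand == "+":
                    if ctx == "CG":
                        sel[-1:] = False
                    else:
                        sel[-2:] = False
                else:
                    if ctx == "CG":
                        sel[:1] = False
                    else:
                        sel[:2] = False
                pos = np.nonzero(sel)[0]
                if pos.size:
                    frames.append(pd.DataFrame({
                        "chrom": chrom, "pos0": pos, "strand": strand, "context": ctx,
                    }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos0", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["chrom", "pos0", "strand"], inplace=True, kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# mC calling and cross-condition categories
# ---------------------------------------------------------------------------

def call_methylated(
    calls: pd.DataFrame,
    error_rate: float = 0.01,
    alpha: float = 0.01,
    min_cov: int = 4,
) -> pd.Series:
    """Methylation status per cytosine of one condition.

    'no-data' below ``min_cov`` coverage; otherwise 'methylated' iff the
    one-sided binomial tail P(X >= m | n = total, p = error_rate) stays
    below ``alpha`` after BH correction across all tested sites.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    status = pd.Series("no-data", index=calls.index, dtype=object)
    covered = calls["total_count"].to_numpy() >= min_cov
    m = calls["m_count"].to_numpy()[covered]
    n = calls["total_count"].to_numpy()[covered]
    p = stats.binom.sf(m - 1, n, error_rate)
    q = stats.false_discovery_control(p, method="bh") if p.size else p
    lab = np.where(q < alpha, "methylated", "unmethylated")
    status.iloc[np.nonzero(covered)[0]] = lab
    return status


def classify_mc_across_conditions(
    statuses: dict[str, str], control: str = "CK"
) -> Optional[str]:
    """Category of one site from its per-condition methylation statuses.

    Returns 'constitutive' (methylated in all three), '<cond>-specific'
    (methylated in exactly one non-control condition), 'varied' (any other
    pattern methylated somewhere, including control-only), or None when the
    site is methylated nowhere or has a 'no-data' status in any condition.
    """
    if control not in statuses:
        raise KeyError(f"unknown control condition {control!r}")
    if any(s == "no-data" for s in statuses.values()):
        return None
    meth = {c for c, s in statuses.items() if s == "methylated"}
    if not meth:
        return None
    if meth == set(statuses):
        return "constitutive"
    if len(meth) == 1:
        only = next(iter(meth))
        if only != control:
            return f"{only}-specific"
    return "varied"


def categorize_sites(
    status_by_condition: dict[str, pd.DataFrame], control: str = "CK"
) -> pd.DataFrame:
    """Cross-condition mC categories for all sites.

    ``status_by_condition`` maps condition -> calls DataFrame carrying a
    'status' column. Sites are joined on (chrom, pos0, strand); a site
    missing from a condition's table counts as 'no-data' and is excluded.
    """
    conds = list(status_by_condition)
    merged: Optional[pd.DataFrame] = None
    for cond, df in status_by_condition.items():
        sub = df[["chrom", "pos0", "strand", "context", "status"]].rename(
            columns={"status": f"status_{cond}"}
        )
        merged = sub if merged is None else merged.merge(
            sub, on=["chrom", "pos0", "strand", "context"], how="outer"
        )
    assert merged is not None
    scols = [f"status_{c}" for c in conds]
    merged[scols] = merged[scols].fillna("no-data")
    ok = ~(merged[scols] == "no-data").any(axis=1)
    meth = merged[scols] == "methylated"
    nm = meth.sum(axis=1)
    category = pd.Series(None, index=merged.index, dtype=object)
    somewhere = ok & (nm > 0)
    category[somewhere & (nm == len(conds))] = "constitutive"
    for cond in conds:
        if cond == control:
            continue
        only = somewhere & (nm == 1) & meth[f"status_{cond}"]
        category[only] = f"{cond}-specific"
    category[somewhere & category.isna()] = "varied"
    merged["category"] = category
    return merged


# ---------------------------------------------------------------------------
# region levels and gene profiles
# ---------------------------------------------------------------------------

def region_level(calls: pd.DataFrame, context: Optional[str] = None) -> Optional[float]:
    """Pooled methylation level of a set of cytosine calls:
    sum(m) / sum(total), optionally restricted to one context.
    Returns None when no covered cytosine contributes."""
    df = calls if context is None else calls[calls["context"] == context]
    tot = int(df["total_count"].sum())
    if tot == 0:
        return None
    return float(df["m_count"].sum()) / tot


def _gene_regions(gene, flank: int, chrom_len: Optional[int]) -> dict[str, tuple[int, int]]:
    if gene.strand == "+":
        up = (gene.start - flank, gene.start)
        down = (gene.end, gene.end + flank)
    else:
        up = (gene.end, gene.end + flank)
        down = (gene.start - flank, gene.start)
    body = (gene.start, gene.end)
    out = {}
    for name, (s, e) in (("upstream", up), ("body", body), ("downstream", down)):
        s2 = max(s, 0)
        e2 = min(e, chrom_len) if chrom_len is not None else e
        if (s2, e2) != (s, e):
            log.info("gene %s: %s flank truncated to chromosome bounds", gene.id, name)
        out[name] = (s2, max(e2, s2))
    return out


def gene_profiles(
    annotation: Annotation,
    calls: pd.DataFrame,
    flank: int = 2000,
    bins: int = 20,
    chrom_sizes: Optional[dict[str, int]] = None,
    with_curves: bool = False,
):
    """Per-gene methylation profile: pooled level for {upstream, body,
    downstream} x {CG, CHG, CHH} (strand-aware regions, ``flank`` bp flanks)
    plus, optionally, per-bin metagene curves with ``bins`` fractional bins
    per region.

    Returns a DataFrame indexed by gene id with columns 'upstream_CG' ...
    'downstream_CHH'; with ``with_curves`` a long-format curve table is
    returned as well.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    by_chrom = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        sub = sub.sort_values("pos0", kind="mergesort")
        by_chrom[chrom] = (
            sub["pos0"].to_numpy(),
            sub["context"].to_numpy(),
            sub["m_count"].to_numpy(),
            sub["total_count"].to_numpy(),
        )
    rows, curves = {}, []
    for gene in annotation:
        data = by_chrom.get(gene.chrom)
        row: dict[str, float] = {}
        regions = _gene_regions(
            gene, flank, chrom_sizes.get(gene.chrom) if chrom_sizes else None
        )
        for region, (s, e) in regions.items():
            if data is None or e <= s:
                for ctx in CONTEXTS:
                    row[f"{region}_{ctx}"] = np.nan
                continue
            pos, ctxs, m, t = data
            i0, i1 = np.searchsorted(pos, (s, e))
            rpos, rctx, rm, rt = pos[i0:i1], ctxs[i0:i1], m[i0:i1], t[i0:i1]
            for ctx in CONTEXTS:
                sel = rctx == ctx
                tot = rt[sel].sum()
                row[f"{region}_{ctx}"] = rm[sel].sum() / tot if tot > 0 else np.nan
                if with_curves:
                    frac = (rpos[sel] - s) / (e - s)
                    b = np.minimum((frac * bins).astype(int), bins - 1)
                    if gene.strand == "-":
                        b = bins - 1 - b
                    mm = np.bincount(b, weights=rm[sel], minlength=bins)
                    tt = np.bincount(b, weights=rt[sel], minlength=bins)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        lev = mm / tt
                    for bi in range(bins):
                        curves.append((gene.id, region, ctx, bi,
                                       lev[bi] if tt[bi] > 0 else np.nan))
        rows[gene.id] = row
    profiles = pd.DataFrame.from_dict(rows, orient="index")
    profiles = profiles[[f"{r}_{c}" for r in ("upstream", "body", "downstream")
                         for c in CONTEXTS]]
    if with_curves:
        curve_df = pd.DataFrame(curves, columns=["gene_id", "region", "context",
                                                 "bin", "level"])
        return profiles, curve_df
    return profiles


def cluster_gene_profiles(
    profiles: pd.DataFrame, k: int = 4, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Group genes by their upstream/body methylation profile with k-means.

    Uses the six upstream/body features (CG, CHG, CHH); genes with any
    missing feature are dropped. Features are standardised; k-means runs 10
    restarts with a fixed seed, and clusters are relabelled 1..k in
    decreasing order of upstream-CG mean so 'cluster 1' is reproducible.
    """
    from sklearn.cluster import KMeans
    from sklearn.preprocessing import StandardScaler

    feats = [f"{r}_{c}" for r in ("upstream", "body") for c in CONTEXTS]
    usable = profiles[feats].dropna()
    if len(usable) < k:
        raise ValueError(f"need >= {k} genes with complete profiles, have {len(usable)}")
    X = StandardScaler().fit_transform(usable.to_numpy())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    raw = pd.Series(km.labels_, index=usable.index)
    means = usable.groupby(raw).mean()
    order = means["upstream_CG"].sort_values(ascending=False).index
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = raw.map(relabel).rename("cluster")
    cluster_means = means.rename(index=relabel).sort_index()
    return labels, cluster_means


# ---------------------------------------------------------------------------
# Fisher exact test (vectorised) and DMR calling
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables [[a, b], [c, d]], vectorised.

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed that of the observed
    table (with a small relative tolerance for floating-point ties, as is
    conventional for this test).
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    N = a + b + c + d
    K = a + c          # first-column margin
    n = a + b          # first-row margin
    kmin = np.maximum(0, n - (N - K))
    kmax = np.minimum(K, n)
    width = int((kmax - kmin).max()) + 1 if a.size else 0
    ks = kmin[:, None] + np.arange(width)[None, :]
    valid = ks <= kmax[:, None]
    ksafe = np.where(valid, ks, kmin[:, None])
    logpmf = stats.hypergeom.logpmf(ksafe, N[:, None], K[:, None], n[:, None])
    log_obs = stats.hypergeom.logpmf(a, N, K, n)
    include = valid & (logpmf <= log_obs[:, None] + 1e-7)
    with np.errstate(under="ignore"):
        p = np.where(include, np.exp(logpmf), 0.0).sum(axis=1)
    p = np.where(N == 0, 1.0, p)  # empty table carries no evidence
    return np.minimum(p, 1.0)


def _window_table(pos, vals, starts, width):
    """Pooled per-window sums via cumulative sums; returns (n_sites, sums...)."""
    i0 = np.searchsorted(pos, starts)
    i1 = np.searchsorted(pos, starts + width)
    out = [i1 - i0]
    for v in vals:
        cs = np.concatenate([[0], np.cumsum(v)])
        out.append(cs[i1] - cs[i0])
    return out


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    context: str,
    pair: tuple[str, str] = ("A", "B"),
    window: int = 200,
    step: int = 50,
    min_c: int = 4,
    min_cov: int = 4,
    min_delta: Optional[dict[str, float]] = None,
    alpha: float = 0.05,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[DMR]:
    """Sliding-window DMR calling between two conditions in one context.

    A window is testable iff >= ``min_c`` cytosines of the context have
    coverage >= ``min_cov`` in BOTH conditions. Each testable window gets a
    two-sided Fisher exact p on the pooled (methylated, unmethylated) x
    (condition A, condition B) table; BH correction runs across all testable
    windows of the context. Windows with q <= ``alpha`` and |delta| >=
    ``min_delta[context]`` are merged when overlapping or book-ended with the
    same direction, and each merged region is re-scored on its pooled
    counts. ``direction`` is hyper/hypo in condition B relative to A.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    min_delta = dict(DEFAULT_MIN_DELTA if min_delta is None else min_delta)
    thr = min_delta[context]

    ca = calls_a[calls_a["context"] == context]
    cb = calls_b[calls_b["context"] == context]
    joined = ca.merge(
        cb, on=["chrom", "pos0", "strand"], suffixes=("_a", "_b")
    )
    joined = joined[
        (joined["total_count_a"] >= min_cov) & (joined["total_count_b"] >= min_cov)
    ]

    windows = []  # (chrom, start, end, ma, ta, mb, tb, n, p)
    for chrom, sub in joined.groupby("chrom", sort=True):
        sub = sub.sort_values("pos0", kind="mergesort")
        pos = sub["pos0"].to_numpy()
        size = chrom_sizes.get(chrom) if chrom_sizes else int(pos.max()) + 1
        starts = np.arange(0, max(size - 1, 1), step)
        n, ma, ta, mb, tb = _window_table(
            pos,
            [sub["m_count_a"].to_numpy(), sub["total_count_a"].to_numpy(),
             sub["m_count_b"].to_numpy(), sub["total_count_b"].to_numpy()],
            starts, window,
        )
        ok = n >= min_c
        if not ok.any():
            continue
        starts, n = starts[ok], n[ok]
        ma, ta, mb, tb = ma[ok], ta[ok], mb[ok], tb[ok]
        p = fisher_exact_two_sided(ma, ta - ma, mb, tb - mb)
        for i in range(starts.size):
            windows.append((chrom, int(starts[i]), min(int(starts[i]) + window, size),
                            int(ma[i]), int(ta[i]), int(mb[i]), int(tb[i]),
                            int(n[i]), float(p[i])))
    if not windows:
        return []

    pvals = np.array([w[8] for w in windows])
    qvals = stats.false_discovery_control(pvals, method="bh")
    sig = []
    for w, q in zip(windows, qvals):
        chrom, s, e, ma, ta, mb, tb, n, p = w
        delta = mb / tb - ma / ta
        if q <= alpha and abs(delta) >= thr:
            sig.append((chrom, s, e, np.sign(delta), float(q)))
    if not sig:
        return []

    # merge overlapping/book-ended same-direction windows, then re-score
    sig.sort()
    merged: list[list] = []
    for chrom, s, e, sgn, q in sig:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] and sgn == merged[-1][3]:
            merged[-1][2] = max(merged[-1][2], e)
            merged[-1][4] = min(merged[-1][4], q)
        else:
            merged.append([chrom, s, e, sgn, q])

    by_chrom = {
        chrom: sub.sort_values("pos0", kind="mergesort")
        for chrom, sub in joined.groupby("chrom", sort=False)
    }
    dmrs = []
    for chrom, s, e, sgn, q in merged:
        sub = by_chrom[chrom]
        pos = sub["pos0"].to_numpy()
        i0, i1 = np.searchsorted(pos, (s, e))
        ma = int(sub["m_count_a"].to_numpy()[i0:i1].sum())
        ta = int(sub["total_count_a"].to_numpy()[i0:i1].sum())
        mb = int(sub["m_count_b"].to_numpy()[i0:i1].sum())
        tb = int(sub["total_count_b"].to_numpy()[i0:i1].sum())
        la, lb = ma / ta, mb / tb
        delta = lb - la
        if abs(delta) < thr:
            continue  # pooled delta can dip below threshold after merging
        p = float(fisher_exact_two_sided(ma, ta - ma, mb, tb - mb)[0])
        dmrs.append(DMR(
            chrom=chrom, start=s, end=e, context=context, pair=pair,
            direction="hyper" if delta > 0 else "hypo",
            level_a=la, level_b=lb, delta=delta, p_value=p, q_value=float(q),
            n_cytosines=int(i1 - i0),
        ))
    return dmrs


# ---------------------------------------------------------------------------
# DMR annotation and overlap
# ---------------------------------------------------------------------------

def _iv_overlap(s1, e1, s2, e2) -> bool:
    return s1 < e2 and s2 < e1


def annotate_dmrs(
    dmrs: Sequence[DMR],
    annotation: Annotation,
    te_track: Optional[Sequence[tuple[str, int, int]]] = None,
    flank: int = 2000,
) -> list[DMR]:
    """Tag each DMR with exactly one genomic compartment, by precedence
    gene-body > gene-upstream > gene-downstream > TE > intergenic (>= 1 bp
    overlap), and record all overlapped gene ids."""
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in te_track or []:
        te_by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for d in dmrs:
        tag = "intergenic"
        gene_ids = []
        hit_body = hit_up = hit_down = False
        for gene in annotation.by_chrom.get(d.chrom, []):
            regions = _gene_regions(gene, flank, None)
            any_hit = False
            if _iv_overlap(d.start, d.end, *regions["body"]):
                hit_body = any_hit = True
            if _iv_overlap(d.start, d.end, *regions["upstream"]):
                hit_up = any_hit = True
            if _iv_overlap(d.start, d.end, *regions["downstream"]):
                hit_down = any_hit = True
            if any_hit:
                gene_ids.append(gene.id)
        if hit_body:
            tag = "gene-body"
        elif hit_up:
            tag = "gene-upstream"
        elif hit_down:
            tag = "gene-downstream"
        elif any(_iv_overlap(d.start, d.end, s, e)
                 for s, e in te_by_chrom.get(d.chrom, [])):
            tag = "TE"
        out.append(replace(d, annotation=tag, gene_ids=tuple(gene_ids)))
    return out


def overlap_dmrs(
    dmrs_x: Sequence[DMR], dmrs_y: Sequence[DMR]
) -> tuple[float, float, list[tuple[DMR, DMR]]]:
    """Fraction of X DMRs overlapping some Y DMR by >= 1 bp, and vice versa,
    plus the list of overlapping pairs."""
    pairs = [
        (x, y)
        for x in dmrs_x
        for y in dmrs_y
        if x.chrom == y.chrom and _iv_overlap(x.start, x.end, y.start, y.end)
    ]
    fx = len({id(x) for x, _ in pairs}) / len(dmrs_x) if dmrs_x else 0.0
    fy = len({id(y) for _, y in pairs}) / len(dmrs_y) if dmrs_y else 0.0
    return fx, fy, pairs
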