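"""Expression plumbing and a simplified co-expression network stage.

The module detection here is a minimal, fully specified analogue of the
weighted co-expression approach (power adjacency |r|^beta, average-linkage
clustering of 1 - adjacency, eigengene = leading principal direction), with
module-condition association computed as the correlation between a module
eigengene and the condition indicator vector. It deliberately omits
topological-overlap similarity, dynamic tree cutting and network-rewiring
scores, and should not be read as a reproduction of those methods.

The differential-expression rule (Welch t across replicates on FPKM with a
0.1 pseudocount for the fold change, BH corrected) is likewise a declared
stand-in with a hook for externally computed DE calls.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import CoexpressionModule

#: WGCNA-style color labels, assigned to modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]

PSEUDOCOUNT = 0.1  # FPKM zeros are common; keeps fold changes finite


def differential_expression(
    matrix: pd.DataFrame,
    design: dict[str, str],
    pair: tuple[str, str],
    min_abs_log2fc: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    Returns a DataFrame indexed like ``matrix`` with columns log2fc (B over
    A, pseudocount 0.1 on the means), p_value, q_value (BH), and ``de``
    ('up'/'down' in B, or None). Zero-variance genes with equal means are
    not DE; zero-variance genes with different means are (the t statistic
    degenerates, the mean difference does not).
    """
    cond_a, cond_b = pair
    cols_a = [s for s, c in design.items() if c == cond_a]
    cols_b = [s for s, c in design.items() if c == cond_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"both conditions of {pair} need >= 2 replicates")
    A = matrix[cols_a].to_numpy(dtype=float)
    B = matrix[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    lfc = np.log2(mean_b + PSEUDOCOUNT) - np.log2(mean_a + PSEUDOCOUNT)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows degenerate the t statistic; they are resolved below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(mean_a == mean_b, 1.0, 0.0), p)
    q = stats.false_discovery_control(p, method="bh")
    de = np.where((np.abs(lfc) >= min_abs_log2fc) & (q < alpha),
                  np.where(lfc > 0, "up", "down"), None)
    return pd.DataFrame(
        {"log2fc": lfc, "p_value": p, "q_value": q, "de": de}, index=matrix.index
    )


def _eigengene(sub: pd.DataFrame) -> pd.Series:
    """Leading principal-direction per-sample scores of a standardised
    member submatrix, sign-oriented so the mean member correlation is >= 0."""
    X = sub.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=1, keepdims=True))
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = Xs / sd
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    eig = vt[0]
    if (Xs @ eig).mean() < 0:
        eig = -eig
    return pd.Series(eig, index=sub.columns)


def build_modules(
    matrix: pd.DataFrame,
    beta: float = 6.0,
    min_module: int = 30,
    cut_height: float = 0.25,
    seed: int = 0,
) -> list[CoexpressionModule]:
    """Detect co-expression modules.

    Gene rows are standardised; adjacency is |pearson r|^beta; dissimilarity
    1 - adjacency goes through average-linkage hierarchical clustering cut
    at ``cut_height``. Clusters smaller than ``min_module`` are pooled into
    an unassigned remainder (not returned as modules). Module ids are
    color-style labels assigned by decreasing size. The procedure is fully
    deterministic; ``seed`` is accepted for interface uniformity and stored
    nowhere.
    """
    from scipy.cluster import hierarchy

    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples for meaningful correlation")
    variances = matrix.var(axis=1)
    usable = matrix.loc[variances > 0]
    if len(usable) < min_module:
        return []
    r = np.corrcoef(usable.to_numpy(dtype=float))
    adj = np.abs(r) ** beta
    diss = np.clip(1.0 - adj, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    condensed = diss[np.triu_indices_from(diss, k=1)]
    link = hierarchy.average(condensed)
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    modules = []
    for lab in np.unique(labels):
        members = usable.index[labels == lab]
        if len(members) < min_module:
            continue
        modules.append((tuple(sorted(members)), _eigengene(usable.loc[members])))
    modules.sort(key=lambda m: (-len(m[0]), m[0]))
    return [
        CoexpressionModule(
            id=MODULE_COLORS[i % len(MODULE_COLORS)] if i < len(MODULE_COLORS)
            else f"module{i + 1}",
            members=members, eigengene=eig,
        )
        for i, (members, eig) in enumerate(modules)
    ]


def module_condition_association(
    modules: Sequence[CoexpressionModule],
    design: dict[str, str],
    sig_alpha: float = 0.05,
) -> pd.DataFrame:
    """Signed module-condition association.

    For every module x condition, r = Pearson(eigengene, indicator vector of
    the condition's samples); p comes from the correlation t statistic and
    is BH-corrected across the whole grid. The sign (+1/-1) is reported only
    for associations with q < ``sig_alpha``, else 0. Results are also stored
    on each module's ``condition_association``.
    """
    conditions = sorted(set(design.values()))
    rows = []
    for mod in modules:
        samples = list(mod.eigengene.index)
        missing = [s for s in samples if s not in design]
        if missing:
            raise KeyError(f"samples missing from design: {missing}")
        eig = mod.eigengene.to_numpy(dtype=float)
        for cond in conditions:
            ind = np.array([1.0 if design[s] == cond else 0.0 for s in samples])
            if eig.std() == 0 or ind.std() == 0:
                rows.append((mod.id, cond, np.nan, 1.0))
                continue
            r, p = stats.pearsonr(eig, ind)
            rows.append((mod.id, cond, r, p))
    df = pd.DataFrame(rows, columns=["module", "condition", "r", "p_value"])
    df["q_value"] = stats.false_discovery_control(df["p_value"].fillna(1.0), method="bh")
    df["sign"] = np.where(
        (df["q_value"] < sig_alpha) & df["r"].notna(), np.sign(df["r"]), 0
    ).astype(int)
    for mod in modules:
        sub = df[df["module"] == mod.id]
        mod.condition_association = {
            row.condition: (row.r, row.q_value, row.sign)
            for row in sub.itertuples()
        }
    return df


def extract_subnetwork(
    matrix: pd.DataFrame,
    modules: Sequence[CoexpressionModule],
    seeds: Iterable[str],
    min_abs_r: float = 0.8,
) -> nx.Graph:
    """Correlation subnetwork around seed genes.

    Retains edges with |r| >= ``min_abs_r`` among the seeds and their direct
    neighbors; every kept node is connected to at least one seed through
    retained edges. Nodes carry a 'module' attribute ('unassigned' when the
    gene belongs to no module) and a boolean 'seed' attribute.
    """
    seeds = [s for s in seeds if s in matrix.index]
    if not seeds:
        import warnings

        warnings.warn("no seed gene present in the expression matrix")
        return nx.Graph()
    variances = matrix.var(axis=1)
    usable = matrix.loc[variances > 0]
    live_seeds = [s for s in seeds if s in usable.index]
    module_of = {g: m.id for m in modules for g in m.members}

    G = nx.Graph()
    for s in seeds:
        G.add_node(s, module=module_of.get(s, "unassigned"), seed=True)
    if live_seeds:
        X = usable.to_numpy(dtype=float)
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        idx = {g: i for i, g in enumerate(usable.index)}
        nsamp = X.shape[1]
        seed_rows = np.array([idx[s] for s in live_seeds])
        r_seed = (Xs[seed_rows] @ Xs.T) / nsamp
        neighbors: set[str] = set(live_seeds)
        for si, s in enumerate(live_seeds):
            hits = np.nonzero(np.abs(r_seed[si]) >= min_abs_r)[0]
            neighbors.update(usable.index[h] for h in hits)
        nodes = sorted(neighbors)
        rows = np.array([idx[g] for g in nodes])
        r_all = (Xs[rows] @ Xs[rows].T) / nsamp
        for i, gi in enumerate(nodes):
            for j in range(i + 1, len(nodes)):
                gj = nodes[j]
                if abs(r_all[i, j]) >= min_abs_r:
                    G.add_node(gi, module=module_of.get(gi, "unassigned"),
                               seed=gi in set(seeds))
                    G.add_node(gj, module=module_of.get(gj, "unassigned"),
                               seed=gj in set(seeds))
                    G.add_edge(gi, gj, r=float(r_all[i, j]))
    # drop components containing no seed
    seed_set = set(seeds)
    for comp in list(nx.connected_components(G)):
        if not comp & seed_set:
            G.remove_nodes_from(comp)
    return G
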