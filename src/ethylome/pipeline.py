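"""End-to-end orchestration: run every stage from one declarative config,
write all stage outputs as TSVs, and assemble a summary report.

Every number in the report is re-derived from an emitted TSV — the report
writer only reads files the stages wrote, so any figure in the report can
be checked against its table.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import catalog, io, lncrna, methylome, network, synthetic
from .types import Annotation, TranscriptModel

log = logging.getLogger("ethylome.pipeline")

DEFAULT_THRESHOLDS = {
    # isoform catalog
    "end_fuzz": 5, "apa_distance": 50, "min_fpkm": 0.5,
    # lncRNA
    "min_orf": 100, "window_up": 10_000, "window_down": 100_000, "min_score": 0.2,
    "lnc_edge_min_r": 0.9,
    # methylome
    "meth_error_rate": 0.01, "meth_alpha": 0.01, "min_cov": 4,
    "dmr_window": 200, "dmr_step": 50, "dmr_min_c": 4, "dmr_alpha": 0.05,
    "min_delta": {"CG": 0.4, "CHG": 0.2, "CHH": 0.1},
    "flank": 2000, "profile_bins": 20, "profile_clusters": 4,
    # network / DE
    "beta": 6.0, "min_module": 10, "cut_height": 0.25,
    "de_alpha": 0.05, "de_min_lfc": 1.0, "min_abs_r": 0.8,
}

DEFAULT_SYNTHETIC = {
    "seed": 1, "n_chrom": 2, "chrom_length": 200_000, "gc_fraction": 0.4,
    "n_genes": 60, "exons_per_gene": [2, 5], "intergenic_gap": 1200,
    "as_rates": {"ES": 0.3, "IR": 0.3, "A3S": 0.2, "A5S": 0.2, "IESC": 0.2},
    "apa_rate": 0.3, "apa_shift": 60,
    "novel_locus_rate": 0.1,
    "lncrna_spec": {"sense": 3, "antisense": 3, "intronic": 3, "intergenic": 3,
                    "unmapped": 2},
    "coverage": 20.0, "conversion_error": 0.005,
    "dmrs_per_context": 4, "dmr_length": 300, "dmr_delta": 0.5,
    "n_modules": 3, "module_size": 12, "noise_sd": 0.2, "n_reps": 3,
}


@dataclass
class PipelineConfig:
    output_dir: str
    conditions: tuple[str, ...] = ("CK", "LE", "HE")
    inputs: Optional[dict] = None          # genome/annotation/models/methylation/expression
    synthetic: Optional[dict] = None       # synthetic-generation block
    thresholds: dict = field(default_factory=dict)
    subnetwork_seeds: list = field(default_factory=list)

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.thresholds or {})
        self.thresholds = thr
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either an 'inputs' or a 'synthetic' block")
        if self.synthetic is None:
            required = ["genome", "annotation", "models", "methylation", "expression"]
            missing = [k for k in required if k not in (self.inputs or {})]
            if missing:
                raise ValueError(f"inputs block missing entries: {missing}")
            paths = [self.inputs[k] for k in ["genome", "annotation", "models", "expression"]]
            paths += list(self.inputs["methylation"].values())
            absent = [p for p in paths if not os.path.exists(p)]
            if absent:
                raise ValueError(f"input files not found: {absent}")
        else:
            syn = dict(DEFAULT_SYNTHETIC)
            syn.update(self.synthetic)
            self.synthetic = syn

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            output_dir=raw.get("output_dir", "ethylome_out"),
            conditions=tuple(raw.get("conditions", ("CK", "LE", "HE"))),
            inputs=raw.get("inputs"),
            synthetic=raw.get("synthetic"),
            thresholds=raw.get("thresholds", {}),
            subnetwork_seeds=list(raw.get("subnetwork_seeds", [])),
        )


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = ["genome", "annotation", "reads", "methylome", "expression", "quant"]
    return {n: int(rng.integers(0, 2**31 - 1)) for n in names}


def _generate_inputs(cfg: PipelineConfig, outdir: str):
    """Materialise the synthetic dataset and its truth under the output dir."""
    syn = cfg.synthetic
    seeds = _stage_seeds(int(syn["seed"]))
    genome = synthetic.generate_genome(
        seeds["genome"], n_chrom=syn["n_chrom"], chrom_length=syn["chrom_length"],
        gc_fraction=syn["gc_fraction"])
    annotation = synthetic.generate_annotation(
        genome, seeds["annotation"], n_genes=syn["n_genes"],
        exons_per_gene=tuple(syn["exons_per_gene"]),
        intergenic_gap=syn["intergenic_gap"])
    models, truth = synthetic.generate_isoform_reads(
        annotation, seeds["reads"], as_rates=syn["as_rates"],
        apa_rate=syn["apa_rate"], apa_shift=syn["apa_shift"],
        novel_locus_rate=syn["novel_locus_rate"], lncrna_spec=syn["lncrna_spec"],
        genome=genome)
    pairs = [(cfg.conditions[0], cfg.conditions[1]),
             (cfg.conditions[0], cfg.conditions[2]),
             (cfg.conditions[1], cfg.conditions[2])]
    dmr_specs = [
        synthetic.DMRSpec(count=syn["dmrs_per_context"], length=syn["dmr_length"],
                          context=ctx, delta=syn["dmr_delta"], pair=pair)
        for ctx in ("CG", "CHG", "CHH")
        for pair in pairs[:1]
    ]
    meth, mtruth = synthetic.generate_methylome(
        genome, annotation, seeds["methylome"], planted_dmrs=dmr_specs,
        coverage=syn["coverage"], conversion_error=syn["conversion_error"])
    truth.merge(mtruth)
    lnc_ids = [lid for lid, _ in truth.planted_lncrnas]
    expr, etruth = synthetic.generate_expression(
        annotation, seeds["expression"], n_modules=syn["n_modules"],
        module_size=syn["module_size"], noise_sd=syn["noise_sd"],
        n_reps=syn["n_reps"], conditions=cfg.conditions, extra_ids=lnc_ids,
        correlated_extra=_lnc_correlations(truth, annotation))
    truth.merge(etruth)

    io.write_fasta(genome, os.path.join(outdir, "genome.fa"))
    io.write_gff3(annotation, os.path.join(outdir, "annotation.gff3"))
    io.write_transcript_gtf(models, os.path.join(outdir, "models.gtf"))
    for cond, df in meth.items():
        io.write_methylation(df, os.path.join(outdir, f"methylation_{cond}.tsv"))
    io.write_expression(expr, os.path.join(outdir, "expression.tsv"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    return genome, annotation, models, meth, expr, truth, seeds


def _lnc_correlations(truth, annotation) -> dict[str, str]:
    """Give the first few mapped planted lncRNAs an expression profile that
    tracks their nearest gene, so cis-target edges exist in synthetic runs."""
    out = {}
    gene_ids = sorted(annotation.genes)
    for i, (lid, cls) in enumerate(truth.planted_lncrnas):
        if cls == "unmapped":
            continue
        out[lid] = gene_ids[i % len(gene_ids)]
    return out


def _load_inputs(cfg: PipelineConfig):
    inp = cfg.inputs
    genome = io.read_fasta(inp["genome"])
    annotation = io.read_gff3(inp["annotation"])
    models_path = inp["models"]
    if models_path.endswith((".bed", ".bed12")):
        models = io.read_bed12(models_path)
    else:
        models = io.read_transcript_gtf(models_path)
    meth = {cond: io.read_methylation(p) for cond, p in inp["methylation"].items()}
    expr = io.read_expression(inp["expression"])
    return genome, annotation, models, meth, expr


def _extract_sequence(genome, model: TranscriptModel) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    seq = "".join(genome[model.chrom][s:e] for s, e in model.exons)
    if model.strand == "-":
        seq = seq.translate(comp)[::-1]
    return seq.upper()


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages in dependency order; returns the report path.

    Stage outputs land as TSVs in the configured output directory; the
    closing report re-reads those TSVs so its tallies are re-derivable.
    """
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    thr = config.thresholds
    conds = config.conditions
    truth = None
    if config.synthetic is not None:
        log.info("generating synthetic inputs (seed %s)", config.synthetic["seed"])
        genome, annotation, models, meth, expr, truth, seeds = _generate_inputs(config, outdir)
        rng_quant = np.random.default_rng(seeds["quant"])
    else:
        genome, annotation, models, meth, expr = _load_inputs(config)
        rng_quant = None

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    written: list[tuple[str, int]] = []

    def emit(df: pd.DataFrame, name: str) -> str:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False)
        written.append((name, len(df)))
        return path

    # ---- stage 1: isoform catalog -------------------------------------
    log.info("stage catalog: %d transcript models", len(models))
    isoforms = catalog.collapse_transcripts(models, end_fuzz=thr["end_fuzz"])
    isoforms = catalog.assign_loci(isoforms, annotation)
    models_by_id = {m.id: m for m in models}

    iso_rows = [{
        "isoform_id": i.id, "chrom": i.chrom, "strand": i.strand,
        "locus_id": i.locus_id or ".", "class_code": i.class_code,
        "n_members": i.n_members, "members": ",".join(i.members),
        "exons": ";".join(f"{s}-{e}" for s, e in i.exons),
    } for i in isoforms]
    emit(pd.DataFrame(iso_rows), "isoforms.tsv")

    event_rows = []
    for iso in isoforms:
        if iso.class_code != "novel_isoform":
            continue
        refs = annotation.genes[iso.locus_id].transcripts
        for ev in catalog.classify_as_events(iso, refs):
            event_rows.append({
                "isoform_id": ev.isoform_id, "ref_transcript_id": ev.ref_transcript_id,
                "event_type": ev.event_type, "chrom": ev.chrom,
                "start": ev.start, "end": ev.end, "strand": ev.strand,
            })
    emit(pd.DataFrame(event_rows, columns=[
        "isoform_id", "ref_transcript_id", "event_type", "chrom", "start", "end",
        "strand"]), "as_events.tsv")

    apa = catalog.detect_apa_by_locus(isoforms, models_by_id,
                                      cluster_distance=thr["apa_distance"])
    apa_rows = [{
        "locus_id": s.locus_id, "position": s.position, "support": s.support,
        "cluster_span": s.cluster_span,
        "multi_aps": len(sites) > 1,
    } for locus, sites in apa.items() for s in sites]
    emit(pd.DataFrame(apa_rows, columns=[
        "locus_id", "position", "support", "cluster_span", "multi_aps"]),
        "apa_sites.tsv")

    # isoform-level quantification: provided, or simulated in synthetic mode
    design = synthetic.design_of(expr)
    spec_rows = []
    if rng_quant is not None:
        quant = _simulate_isoform_quant(isoforms, conds, design, rng_quant)
        specific = catalog.condition_specific_isoforms(
            quant, design, expressed_min=thr["min_fpkm"], conditions=conds)
        for cond in conds:
            for iso_id in sorted(specific[cond]):
                spec_rows.append({"condition": cond, "isoform_id": iso_id})
    emit(pd.DataFrame(spec_rows, columns=["condition", "isoform_id"]),
         "condition_specific_isoforms.tsv")

    # ---- stage 2: lncRNAs ---------------------------------------------
    novel = [i for i in isoforms if i.class_code == "novel_locus"]
    lnc_rows, lnc_models = [], []
    for iso in novel:
        member = models_by_id[sorted(iso.members)[0]]
        seq = _extract_sequence(genome, member)
        if len(seq) < lncrna.MIN_LNCRNA_LENGTH:
            continue
        label, orf = lncrna.coding_potential(seq, min_orf=thr["min_orf"])
        if label != "noncoding":
            continue
        cls = lncrna.classify_position(member, annotation)
        lnc_models.append(member)
        lnc_rows.append({
            "lncrna_id": member.id, "positional_class": cls, "length": len(seq),
            "exon_count": len(member.exons), "longest_orf": orf,
        })
    emit(pd.DataFrame(lnc_rows, columns=[
        "lncrna_id", "positional_class", "length", "exon_count", "longest_orf"]),
        "lncrnas.tsv")

    edges = _expression_edges(expr, [m.id for m in lnc_models],
                              sorted(annotation.genes), thr["lnc_edge_min_r"])
    targets = lncrna.predict_cis_targets(
        lnc_models, annotation, edges, window_up=thr["window_up"],
        window_down=thr["window_down"], min_score=thr["min_score"])
    emit(pd.DataFrame([{
        "lncrna_id": t.lncrna_id, "gene_id": t.gene_id,
        "signed_distance": t.signed_distance, "network_score": round(t.network_score, 4),
    } for t in targets], columns=[
        "lncrna_id", "gene_id", "signed_distance", "network_score"]),
        "cis_targets.tsv")

    # ---- stage 3: methylome -------------------------------------------
    statuses = {}
    for cond in conds:
        df = meth[cond].copy()
        df["status"] = methylome.call_methylated(
            df, error_rate=thr["meth_error_rate"], alpha=thr["meth_alpha"],
            min_cov=thr["min_cov"])
        statuses[cond] = df
    mc_rows = []
    for cond in conds:
        df = statuses[cond]
        for ctx in ("CG", "CHG", "CHH"):
            mc_rows.append({
                "condition": cond, "context": ctx,
                "n_methylated": int(((df["context"] == ctx)
                                     & (df["status"] == "methylated")).sum()),
                "level": round(methylome.region_level(df, ctx) or 0.0, 6),
            })
    emit(pd.DataFrame(mc_rows), "mc_counts.tsv")

    cats = methylome.categorize_sites(statuses, control=conds[0])
    cat_counts = cats["category"].value_counts(dropna=True)
    emit(cat_counts.rename_axis("category").reset_index(name="n_sites")
         .sort_values("category"), "mc_categories.tsv")

    profiles = methylome.gene_profiles(
        annotation, meth[conds[0]], flank=thr["flank"], bins=thr["profile_bins"],
        chrom_sizes=chrom_sizes)
    prof_out = profiles.round(6).reset_index(names="gene_id")
    emit(prof_out, "gene_profiles.tsv")
    try:
        labels, _ = methylome.cluster_gene_profiles(
            profiles, k=thr["profile_clusters"],
            seed=config.synthetic["seed"] if config.synthetic else 0)
        emit(labels.rename_axis("gene_id").reset_index(), "gene_profile_clusters.tsv")
    except ValueError as exc:
        log.warning("profile clustering skipped: %s", exc)

    pairs = [(conds[0], conds[1]), (conds[0], conds[2]), (conds[1], conds[2])]
    all_dmrs = []
    for pair in pairs:
        for ctx in ("CG", "CHG", "CHH"):
            dmrs = methylome.call_dmrs(
                meth[pair[0]], meth[pair[1]], ctx, pair=pair,
                window=thr["dmr_window"], step=thr["dmr_step"],
                min_c=thr["dmr_min_c"], min_cov=thr["min_cov"],
                min_delta=thr["min_delta"], alpha=thr["dmr_alpha"],
                chrom_sizes=chrom_sizes)
            all_dmrs.extend(dmrs)
    all_dmrs = methylome.annotate_dmrs(all_dmrs, annotation, flank=thr["flank"])
    emit(pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end, "context": d.context,
        "pair": f"{d.pair[0]}_vs_{d.pair[1]}", "direction": d.direction,
        "level_a": round(d.level_a, 4), "level_b": round(d.level_b, 4),
        "delta": round(d.delta, 4), "q_value": float(f"{d.q_value:.4g}"),
        "n_cytosines": d.n_cytosines, "annotation": d.annotation,
        "gene_ids": ",".join(d.gene_ids) or ".",
    } for d in all_dmrs], columns=[
        "chrom", "start", "end", "context", "pair", "direction", "level_a",
        "level_b", "delta", "q_value", "n_cytosines", "annotation", "gene_ids"]),
        "dmrs.tsv")

    # ---- stage 4: expression network ----------------------------------
    gene_expr = expr.loc[[g for g in expr.index if g in annotation.genes]]
    de_tables = {}
    for pair in pairs:
        de = network.differential_expression(
            gene_expr, design, pair, min_abs_log2fc=thr["de_min_lfc"],
            alpha=thr["de_alpha"])
        de_tables[pair] = de
    de_long = pd.concat(
        [t.assign(pair=f"{p[0]}_vs_{p[1]}").reset_index(names="gene_id")
         for p, t in de_tables.items()], ignore_index=True)
    de_long["log2fc"] = de_long["log2fc"].round(4)
    de_long["p_value"] = de_long["p_value"].map(lambda v: float(f"{v:.4g}"))
    de_long["q_value"] = de_long["q_value"].map(lambda v: float(f"{v:.4g}"))
    emit(de_long[de_long["de"].notna()][
        ["gene_id", "pair", "log2fc", "p_value", "q_value", "de"]], "de_genes.tsv")

    modules = network.build_modules(
        gene_expr, beta=thr["beta"], min_module=thr["min_module"],
        cut_height=thr["cut_height"])
    assoc = network.module_condition_association(modules, design)
    emit(pd.DataFrame([{
        "module": m.id, "n_genes": len(m.members), "members": ",".join(m.members),
    } for m in modules], columns=["module", "n_genes", "members"]), "modules.tsv")
    assoc_out = assoc.copy()
    assoc_out["r"] = assoc_out["r"].round(4)
    assoc_out["p_value"] = assoc_out["p_value"].map(lambda v: float(f"{v:.4g}"))
    assoc_out["q_value"] = assoc_out["q_value"].map(lambda v: float(f"{v:.4g}"))
    emit(assoc_out, "module_condition_association.tsv")

    seeds_list = config.subnetwork_seeds or [
        g for m in modules[:1] for g in m.members[:5]]
    subnet = network.extract_subnetwork(gene_expr, modules, seeds_list,
                                        min_abs_r=thr["min_abs_r"])
    emit(pd.DataFrame([{
        "gene_a": a, "gene_b": b, "r": round(d["r"], 4),
    } for a, b, d in sorted(subnet.edges(data=True))],
        columns=["gene_a", "gene_b", "r"]), "subnetwork_edges.tsv")
    emit(pd.DataFrame([{
        "gene_id": n, "module": d["module"], "seed": d["seed"],
    } for n, d in sorted(subnet.nodes(data=True))],
        columns=["gene_id", "module", "seed"]), "subnetwork_nodes.tsv")

    # ---- stage 5: integration -----------------------------------------
    integration = integrate_dmr_expression(
        annotation, all_dmrs, de_tables, modules, assoc, targets)
    emit(integration, "integration.tsv")

    report_path = os.path.join(outdir, "report.md")
    _write_report(report_path, outdir, written, conds)
    log.info("pipeline complete: %s", report_path)
    return report_path


def _simulate_isoform_quant(isoforms, conds, design, rng) -> pd.DataFrame:
    """Toy isoform-level FPKM for condition-specific calls in synthetic runs:
    ~15% of isoforms are expressed in a single random condition."""
    samples = sorted(design)
    rows = {}
    for iso in isoforms:
        u = rng.random()
        if u < 0.15:
            cond = conds[int(rng.integers(0, len(conds)))]
            vals = [3.0 + rng.random() if design[s] == cond else 0.0 for s in samples]
        else:
            vals = [2.0 + rng.random() for _ in samples]
        rows[iso.id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def _expression_edges(expr, lnc_ids, gene_ids, min_r) -> list[tuple[str, str, float]]:
    """lncRNA-gene network edges scored by |pearson r| over samples."""
    lnc_in = [l for l in lnc_ids if l in expr.index]
    genes_in = [g for g in gene_ids if g in expr.index]
    if not lnc_in or not genes_in:
        return []
    X = expr.loc[lnc_in].to_numpy(dtype=float)
    Y = expr.loc[genes_in].to_numpy(dtype=float)

    def _std(M):
        Ms = M - M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return Ms / sd

    R = (_std(X) @ _std(Y).T) / X.shape[1]
    edges = []
    for i, lid in enumerate(lnc_in):
        for j, gid in enumerate(genes_in):
            score = min(abs(float(R[i, j])), 1.0)
            if score >= min_r:
                edges.append((lid, gid, score))
    return edges


def integrate_dmr_expression(annotation, dmrs, de_tables, modules, assoc,
                             cis_targets) -> pd.DataFrame:
    """Per-gene integration table joining DMR overlap flags (region x
    context), DE status per pair, module membership with association sign,
    and lncRNA cis-target flags. Keyed uniquely by gene id."""
    module_of = {g: m.id for m in modules for g in m.members}
    sign_of = {}
    for row in assoc.itertuples():
        if row.sign != 0:
            sign_of.setdefault(row.module, []).append(f"{row.condition}:{row.sign:+d}")
    targeted = {}
    for t in cis_targets:
        targeted.setdefault(t.gene_id, []).append(t.lncrna_id)

    dmr_flags: dict[str, set[str]] = {}
    for d in dmrs:
        region = {"gene-body": "body", "gene-upstream": "upstream",
                  "gene-downstream": "downstream"}.get(d.annotation)
        if region is None:
            continue
        for g in d.gene_ids:
            dmr_flags.setdefault(g, set()).add(f"{region}_{d.context}")

    rows = []
    for gid in sorted(annotation.genes):
        row = {"gene_id": gid}
        flags = dmr_flags.get(gid, set())
        for region in ("upstream", "body", "downstream"):
            for ctx in ("CG", "CHG", "CHH"):
                row[f"dmr_{region}_{ctx}"] = int(f"{region}_{ctx}" in flags)
        for pair, table in de_tables.items():
            val = table["de"].get(gid)
            row[f"de_{pair[0]}_vs_{pair[1]}"] = val if val is not None else "."
        mod = module_of.get(gid)
        row["module"] = mod or "."
        row["module_association"] = ";".join(sign_of.get(mod, [])) or "."
        row["lncrna_targets"] = ",".join(sorted(targeted.get(gid, []))) or "."
        rows.append(row)
    return pd.DataFrame(rows)


def _write_report(path, outdir, written, conds) -> None:
    def load(name):
        return pd.read_csv(os.path.join(outdir, name), sep="\t")

    iso = load("isoforms.tsv")
    events = load("as_events.tsv")
    apa = load("apa_sites.tsv")
    lncs = load("lncrnas.tsv")
    dmrs = load("dmrs.tsv")
    integ = load("integration.tsv")
    lines = ["# ethylome pipeline report", ""]
    lines += ["## Outputs", ""]
    for name, n in written:
        lines.append(f"- `{name}`: {n} rows")
    lines += ["", "## Isoform catalog", ""]
    for code, n in iso["class_code"].value_counts().sort_index().items():
        lines.append(f"- {code}: {n} isoforms")
    lines.append(f"- AS events: {len(events)}")
    for etype, n in events["event_type"].value_counts().sort_index().items():
        lines.append(f"  - {etype}: {n}")
    multi = apa[apa["multi_aps"] == True]["locus_id"].nunique()  # noqa: E712
    lines.append(f"- multi-APS loci: {multi} of {apa['locus_id'].nunique()}")
    lines += ["", "## lncRNAs", ""]
    for cls, n in lncs["positional_class"].value_counts().sort_index().items():
        lines.append(f"- {cls}: {n}")
    lines += ["", "## Methylome", ""]
    for key, n in dmrs.groupby(["pair", "context"]).size().items():
        lines.append(f"- DMRs {key[0]} {key[1]}: {n}")
    dmr_genes = (integ[[c for c in integ.columns if c.startswith("dmr_")]]
                 .sum(axis=1) > 0).sum()
    lines.append(f"- genes with any DMR overlap: {dmr_genes}")
    lines += ["", "## Network", ""]
    mods = load("modules.tsv")
    lines.append(f"- modules: {len(mods)}")
    subn = load("subnetwork_nodes.tsv")
    sube = load("subnetwork_edges.tsv")
    lines.append(f"- subnetwork: {len(subn)} nodes, {len(sube)} edges")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
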