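"""End-to-end orchestration: identify -> seqprops -> phylo -> dupkaks ->
promoter -> expression, with per-stage TSV outputs and a summary report.

Stages whose inputs are absent are skipped (and logged in the report);
any stage error aborts the run with a stage-named message. Given the
same inputs and seed the emitted bundle is byte-identical.
"""
from __future__ import annotations

import os
from dataclasses import asdict, dataclass

from . import align, dupkaks, expression, identify, io, phylo, promoter
from . import seqprops

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run.

    Threshold defaults are the conventional family-survey settings:
    lectin e-value < 0.001, duplicate coverage and identity > 0.70,
    tandem gap < 100 kb with <= 5 intervening genes, 1500-bp promoters,
    FPKM thresholds 1.0 (constitutive) / 2.0 (expressed), synonymous
    clock r = 1.5e-8 /site/year, p cutoff 0.05.
    """
    outdir: str
    domains: str | None = None
    domains_dialect: str = "tsv"
    proteins: str | None = None
    cds: str | None = None
    gff: str | None = None
    genome: str | None = None
    motif_catalog: str | None = None
    fpkm: str | None = None
    qpcr: str | None = None

    evalue_cutoff: float = 0.001
    coverage_min: float = 0.70
    identity_min: float = 0.70
    tandem_gap_bp: int = 100_000
    max_intervening: int = 5
    promoter_length: int = 1500
    fpkm_constitutive: float = 1.0
    fpkm_expressed: float = 2.0
    venn_tissues: tuple | None = None
    rate_r: float = 1.5e-8
    p_cutoff: float = 0.05
    n_bootstrap: int = 1000
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "evalue_cutoff": self.evalue_cutoff,
            "coverage_min": self.coverage_min,
            "identity_min": self.identity_min,
            "tandem_gap_bp": self.tandem_gap_bp,
            "promoter_length": self.promoter_length,
            "fpkm_constitutive": self.fpkm_constitutive,
            "fpkm_expressed": self.fpkm_expressed,
            "rate_r": self.rate_r,
            "p_cutoff": self.p_cutoff,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, "
                                 f"got {value}")
        if self.max_intervening < 0 or self.n_bootstrap < 0:
            raise ValueError("counts must be non-negative")
        for name in ("domains", "proteins", "cds", "gff", "genome",
                     "motif_catalog", "fpkm", "qpcr"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"input {name}: {path} not found")


def _fmt(x, nd=4):
    return "NA" if x is None else f"{x:.{nd}f}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage whose inputs are present; write per-stage TSVs,
    a Newick tree and report.txt under ``config.outdir``; return a result
    dictionary with the main objects and summary quantities."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = os.path.join
    results: dict = {"skipped": []}
    report: list[str] = ["# famscan pipeline report", ""]
    report.append("## thresholds")
    for key, val in asdict(config).items():
        if key in ("outdir",):
            continue
        report.append(f"{key} = {val}")
    report.append("")

    members = None
    proteins_by_id = {}
    gene_of = lambda pid: pid.rsplit(".", 1)[0]  # noqa: E731

    # ---- identify -------------------------------------------------------
    if config.domains:
        try:
            hits = io.read_domain_table(config.domains,
                                        config.domains_dialect)
            members = identify.classify_members(hits, config.evalue_cutoff)
            arch = identify.architecture_summary(members)
        except Exception as exc:
            raise PipelineError("identify", str(exc))
        with open(out(config.outdir, "members.tsv"), "w") as fh:
            fh.write("gene_id\tprotein_id\tsubfamily\thas_signal\tn_tm\t"
                     "has_egf\thas_pan\thas_s_locus\tlectin_evalue\n")
            for m in members:
                fh.write(f"{m.gene_id}\t{m.protein_id}\t{m.subfamily}\t"
                         f"{int(m.has_signal)}\t{m.n_tm}\t{int(m.has_egf)}"
                         f"\t{int(m.has_pan)}\t{int(m.has_s_locus)}\t"
                         f"{m.lectin_evalue:g}\n")
        arch.to_csv(out(config.outdir, "architecture.tsv"), sep="\t")
        results["members"] = members
        counts = {s: sum(1 for m in members if m.subfamily == s)
                  for s in "LGC"}
        results["subfamily_counts"] = counts
        report += ["## members",
                   f"retained: {len(members)} "
                   f"(L={counts['L']}, G={counts['G']}, C={counts['C']})",
                   ""]
    else:
        results["skipped"].append("identify")
        report += ["## members", "skipped (no domain table)", ""]

    member_pids = {m.protein_id for m in members} if members else None

    # ---- seqprops -------------------------------------------------------
    structure_stats = None
    props = None
    gene_models = None
    if config.proteins:
        try:
            prot_records = io.read_fasta(config.proteins, "protein")
            proteins_by_id = {r.id: r for r in prot_records}
            use = [r for r in prot_records
                   if member_pids is None or r.id in member_pids]
            props = [seqprops.protein_props(r) for r in use]
        except Exception as exc:
            raise PipelineError("seqprops", str(exc))
    if config.gff:
        try:
            gene_models = io.read_gff3(config.gff)
            member_gids = {gene_of(p) for p in member_pids} \
                if member_pids else None
            structure_stats = [
                seqprops.gene_structure(g) for g in gene_models
                if member_gids is None or g.gene_id in member_gids]
        except Exception as exc:
            raise PipelineError("seqprops", str(exc))
    if props or structure_stats:
        struct_by_gene = {s.gene_id: s for s in (structure_stats or [])}
        with open(out(config.outdir, "props.tsv"), "w") as fh:
            fh.write("protein_id\tlength_aa\tmw_kda\tpi\tn_exons\t"
                     "cds_len_bp\n")
            for p in sorted(props or [], key=lambda q: q.protein_id):
                s = struct_by_gene.get(gene_of(p.protein_id))
                fh.write(f"{p.protein_id}\t{p.length_aa}\t"
                         f"{p.mw_kda:.1f}\t{p.pi:.2f}\t"
                         f"{s.n_exons if s else 'NA'}\t"
                         f"{s.cds_len_bp if s else 'NA'}\n")
        if structure_stats:
            summary = seqprops.family_structure_report(structure_stats,
                                                       props)
            results["structure_report"] = summary
            report += ["## structure",
                       f"CDS length {summary.cds_len_min}-"
                       f"{summary.cds_len_max} bp; mean introns "
                       f"{summary.mean_introns:.2f}; max exons "
                       f"{summary.max_exons}"]
            if summary.mw_min_kda is not None:
                report.append(
                    f"MW {summary.mw_min_kda:.1f} ({summary.mw_min_id}) - "
                    f"{summary.mw_max_kda:.1f} kDa ({summary.mw_max_id})")
            report.append("")
        results["props"] = props
    else:
        results["skipped"].append("seqprops")
        report += ["## structure", "skipped (no proteins/annotation)", ""]

    # ---- phylo ----------------------------------------------------------
    if config.proteins and member_pids and len(member_pids) >= 4:
        try:
            fam = [proteins_by_id[p] for p in sorted(member_pids)
                   if p in proteins_by_id]
            ids, rows = align.star_msa(fam)
            aln = phylo.MultipleAlignment(ids, rows)
            tree = phylo.bootstrap_supports(aln, config.n_bootstrap,
                                            config.seed)
            newick = phylo.write_newick(tree)
        except Exception as exc:
            raise PipelineError("phylo", str(exc))
        with open(out(config.outdir, "tree.nwk"), "w") as fh:
            fh.write(newick + "\n")
        results["tree"] = tree
        report += ["## phylogeny",
                   f"NJ tree over {len(ids)} proteins, "
                   f"{config.n_bootstrap} bootstrap replicates", ""]
    else:
        results["skipped"].append("phylo")
        report += ["## phylogeny", "skipped (needs members + proteins)", ""]

    # ---- dupkaks --------------------------------------------------------
    if config.proteins and config.cds and config.gff and member_pids:
        try:
            cds_records = {r.id: r for r in io.read_fasta(config.cds,
                                                          "dna")}
            fam = [proteins_by_id[p] for p in sorted(member_pids)
                   if p in proteins_by_id]
            pairs = dupkaks.find_duplicates(fam, config.coverage_min,
                                            config.identity_min)
            events = []
            for pair in pairs:
                ev = dupkaks.classify_duplication(
                    pair, gene_models, protein_to_gene=gene_of,
                    max_gap_bp=config.tandem_gap_bp,
                    max_intervening=config.max_intervening)
                try:
                    ka, ks, omega = dupkaks.kaks_pair(
                        cds_records[pair.id_a].sequence,
                        cds_records[pair.id_b].sequence, pair)
                    ev.ka, ev.ks, ev.omega = ka, ks, omega
                    ev.t_mya = dupkaks.divergence_time(ks, config.rate_r)
                except dupkaks.SaturationError:
                    pass  # Ks beyond saturation: left undefined
                events.append(ev)
            events.sort(key=lambda e: (e.id_a, e.id_b))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("dupkaks", str(exc))
        with open(out(config.outdir, "duplications.tsv"), "w") as fh:
            fh.write("id_a\tid_b\tclass\tgap_bp\tn_intervening\tidentity\t"
                     "coverage\tka\tks\tomega\tt_mya\n")
            for e in events:
                fh.write(
                    f"{e.id_a}\t{e.id_b}\t{e.dup_class}\t"
                    f"{e.gap_bp if e.gap_bp is not None else 'NA'}\t"
                    f"{e.n_intervening if e.n_intervening is not None else 'NA'}"
                    f"\t{e.identity:.4f}\t{e.coverage:.4f}\t"
                    f"{_fmt(e.ka)}\t{_fmt(e.ks)}\t{_fmt(e.omega)}\t"
                    f"{_fmt(e.t_mya, 2)}\n")
        results["dup_events"] = events
        report.append("## duplications")
        for e in events:
            report.append(
                f"{e.id_a} ~ {e.id_b}: {e.dup_class}, Ks={_fmt(e.ks)}, "
                f"Ka={_fmt(e.ka)}, T={_fmt(e.t_mya, 2)} MYA")
        report.append("")
    else:
        results["skipped"].append("dupkaks")
        report += ["## duplications", "skipped (needs proteins+CDS+GFF)",
                   ""]

    # ---- promoter -------------------------------------------------------
    if config.genome and config.gff and config.motif_catalog:
        try:
            genome = {r.id: r for r in io.read_fasta(config.genome, "dna")}
            catalog = promoter.read_motif_catalog(config.motif_catalog)
            member_gids = {gene_of(p) for p in member_pids} \
                if member_pids else {g.gene_id for g in gene_models}
            hits = []
            for g in sorted(gene_models, key=lambda x: x.gene_id):
                if g.gene_id not in member_gids:
                    continue
                prom = promoter.extract_upstream(g, genome,
                                                 config.promoter_length)
                hits.extend(promoter.scan_motifs(prom, catalog))
            per_gene_types, per_gene_inst, family_types = \
                promoter.categorize_elements(hits, catalog)
        except Exception as exc:
            raise PipelineError("promoter", str(exc))
        cat_of = {m.name: m.category for m in catalog}
        with open(out(config.outdir, "promoter_hits.tsv"), "w") as fh:
            fh.write("gene_id\tmotif\tposition\tstrand\tcategory\n")
            for h in hits:
                fh.write(f"{h.gene_id}\t{h.motif}\t{h.position}\t"
                         f"{h.strand}\t{cat_of[h.motif]}\n")
        with open(out(config.outdir, "promoter_categories.tsv"),
                  "w") as fh:
            cats = promoter.CATEGORIES
            fh.write("gene_id\t" + "\t".join(cats) + "\n")
            for gid in sorted(per_gene_types):
                fh.write(gid + "\t" + "\t".join(
                    str(per_gene_types[gid][c]) for c in cats) + "\n")
        results["promoter_hits"] = hits
        results["promoter_family_types"] = family_types
        report += ["## promoter elements",
                   "distinct elements per category: " + ", ".join(
                       f"{c}={family_types[c]}"
                       for c in promoter.CATEGORIES), ""]
    else:
        results["skipped"].append("promoter")
        report += ["## promoter elements",
                   "skipped (needs genome+GFF+catalog)", ""]

    # ---- expression -----------------------------------------------------
    if config.fpkm:
        try:
            mat = io.read_expression_matrix(config.fpkm)
            constitutive, expressed = expression.expression_flags(
                mat, config.fpkm_constitutive, config.fpkm_expressed,
                list(config.venn_tissues) if config.venn_tissues else None)
            groups = expression.group_expression(mat, 3, config.seed)
            venn = expression.venn_membership(expressed) \
                if 2 <= len(expressed) <= 5 else None
        except Exception as exc:
            raise PipelineError("expression", str(exc))
        with open(out(config.outdir, "expression_flags.tsv"), "w") as fh:
            fh.write("gene_id\tconstitutive\tgroup\n")
            group_of = {g: grp.label for grp in groups for g in grp.members}
            for gid in mat.genes:
                fh.write(f"{gid}\t{int(constitutive[gid])}\t"
                         f"{group_of[gid]}\n")
        with open(out(config.outdir, "expression_groups.tsv"), "w") as fh:
            fh.write("group\tn_genes\tmean_fpkm\tmembers\n")
            for grp in groups:
                fh.write(f"{grp.label}\t{len(grp.members)}\t"
                         f"{grp.mean_fpkm:.2f}\t"
                         f"{','.join(sorted(grp.members))}\n")
        if venn is not None:
            with open(out(config.outdir, "venn.tsv"), "w") as fh:
                fh.write("region\tcount\n")
                for combo in sorted(venn):
                    fh.write("&".join(combo) + f"\t{venn[combo]}\n")
        results["expression_groups"] = groups
        results["constitutive"] = constitutive
        results["venn"] = venn
        report += ["## expression",
                   "groups: " + "; ".join(
                       f"{g.label}: n={len(g.members)} mean FPKM "
                       f"{g.mean_fpkm:.2f}" for g in groups),
                   f"constitutive genes: {int(constitutive.sum())}", ""]
    else:
        results["skipped"].append("expression")
        report += ["## expression", "skipped (no FPKM matrix)", ""]

    if config.qpcr:
        try:
            table = io.read_qpcr_table(config.qpcr)
            fcs = expression.all_fold_changes(table,
                                              p_cutoff=config.p_cutoff)
        except Exception as exc:
            raise PipelineError("qpcr", str(exc))
        with open(out(config.outdir, "fold_changes.tsv"), "w") as fh:
            fh.write("gene_id\tcondition\tfold_change\tp_value\tcall\n")
            for fc in fcs:
                fh.write(f"{fc.gene_id}\t{fc.condition}\t"
                         f"{fc.fold_change:.4f}\t{fc.p_value:.4g}\t"
                         f"{fc.call}\n")
        n_up = sum(1 for fc in fcs if fc.call == "up")
        n_down = sum(1 for fc in fcs if fc.call == "down")
        results["fold_changes"] = fcs
        results["n_up"], results["n_down"] = n_up, n_down
        report += ["## qPCR",
                   f"{n_up} upregulation and {n_down} downregulation "
                   f"events (p <= {config.p_cutoff})", ""]
    else:
        results["skipped"].append("qpcr")
        report += ["## qPCR", "skipped (no Ct table)", ""]

    if results["skipped"]:
        report.append("skipped stages: " + ", ".join(results["skipped"]))
    with open(out(config.outdir, "report.txt"), "w") as fh:
        fh.write("\n".join(report) + "\n")
    return results
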