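"""End-to-end orchestration: single config, staged execution, and a
machine-readable summary report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, domain_conservation as dc, expression_screen as es
from . import family_identification as fi
from . import phylogeny as ph
from . import qpcr_stats as qs
from . import structure_and_cis as sc
from ._util import read_fasta, write_fasta
from .errors import ConfigurationError, FamscanError

ALL_STAGES = ("identify", "conserve", "tree", "structure", "cis", "screen", "qpcr")
_STAGE_DEPS = {
    "conserve": ("identify",),
    "tree": ("identify", "conserve"),
    "structure": ("identify",),
    "screen": ("identify",),
}


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str
    proteins: Optional[str] = None
    gff3: Optional[str] = None
    promoters: Optional[str] = None
    expression: Optional[str] = None
    go: Optional[str] = None
    qpcr: Optional[str] = None
    seed_alignment: Optional[str] = None
    reference_alignment: Optional[str] = None
    reference_labels: Optional[str] = None
    catalog: Optional[str] = None
    prefix: str = "CpbHLH"
    min_covered: int = fi.DEFAULT_MIN_COVERED
    score_threshold: float = fi.DEFAULT_SCORE_THRESHOLD
    pseudocount: float = 1.0
    min_abundance: float = 1.0
    fc_threshold: float = 3.0
    k_clusters: int = 8
    alpha: float = 0.05
    promoter_length: int = 2000
    bootstrap: int = 0
    seed: int = 1
    control: str = "CK"
    calibrator: str = "CK"
    reference_gene: str = "18sRNA"
    salt_terms: tuple[str, ...] = es.DEFAULT_SALT_TERMS
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self):
        if not (0 < self.min_covered <= fi.MODEL_LENGTH):
            raise ConfigurationError("min_covered outside (0, 79]")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if self.min_abundance < 0:
            raise ConfigurationError("min_abundance must be >= 0")
        if self.fc_threshold <= 1:
            raise ConfigurationError("fc_threshold must be > 1")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha outside (0, 1)")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be >= 1")
        if self.bootstrap < 0:
            raise ConfigurationError("bootstrap must be >= 0")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("stages", "salt_terms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class ReportBundle:
    summary: dict
    manifest: dict
    config_hash: str
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _with_dependencies(stages) -> list[str]:
    wanted = set(stages)
    for s in stages:
        wanted.update(_STAGE_DEPS.get(s, ()))
    return [s for s in ALL_STAGES if s in wanted]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the requested stages in dependency order.

    Any stage failure aborts with a stage-tagged error; identical config
    and inputs reproduce identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = _with_dependencies(config.stages)
    summary: dict = {}
    manifest: dict = {}
    state: dict = {}
    runners = {
        "identify": _stage_identify,
        "conserve": _stage_conserve,
        "tree": _stage_tree,
        "structure": _stage_structure,
        "cis": _stage_cis,
        "screen": _stage_screen,
        "qpcr": _stage_qpcr,
    }
    for stage in stages:
        try:
            runners[stage](config, outdir, state, summary, manifest)
        except FamscanError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise FamscanError(f"stage {stage!r} failed: {exc}") from exc
    _consistency_checks(summary)
    report = ReportBundle(
        summary=summary, manifest=manifest, config_hash=config.hash()
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    manifest["report"] = str(outdir / "report.json")
    return report


def _require(config: PipelineConfig, stage: str, **paths):
    missing = [k for k, v in paths.items() if v is None]
    if missing:
        raise ConfigurationError(f"stage {stage!r} needs inputs: {missing}")


def _stage_identify(config, outdir, state, summary, manifest):
    _require(
        config, "identify",
        proteins=config.proteins, gff3=config.gff3,
        seed_alignment=config.seed_alignment,
    )
    proteins = [
        fi.ProteinRecord(id=i, sequence=s)
        for i, s in read_fasta(config.proteins).items()
    ]
    gene_models = sc.parse_gene_models(config.gff3)
    seed_rows = read_fasta(config.seed_alignment)
    profile = fi.build_profile(
        seed_rows, pseudocount=config.pseudocount, threshold=config.score_threshold
    )
    hits = {p.id: fi.scan_sequence(profile, p) for p in proteins}
    retained = fi.filter_and_dedup(proteins, hits, min_covered=config.min_covered)
    members = fi.assign_gene_names(
        retained, gene_models, config.prefix, hits=hits
    )
    state.update(
        proteins={p.id: p for p in proteins},
        gene_models=gene_models,
        hits=hits,
        members=members,
    )
    path = outdir / "members.tsv"
    rows = []
    for m in members:
        rows.append({
            "name": m.name,
            "protein_id": m.protein_id,
            "gene_id": m.gene_id,
            "chromosome": m.chromosome,
            "start": m.start + 1,  # 1-based on disk
            "domain_score": round(m.hit.score, 3) if m.hit else "",
            "covered_columns": m.hit.covered if m.hit else "",
            "length": m.physchem.length,
            "molecular_weight": round(m.physchem.molecular_weight, 2),
            "isoelectric_point": round(m.physchem.isoelectric_point, 2),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    manifest["members"] = str(path)
    summary["family_size"] = len(members)
    summary["n_putative"] = len(proteins)


def _stage_conserve(config, outdir, state, summary, manifest):
    members = state["members"]
    proteins = state["proteins"]
    alignment = {
        m.name: dc.align_to_model(m.hit, proteins[m.protein_id])
        for m in members
    }
    state["member_alignment"] = alignment
    write_fasta(outdir / "domain_alignment.fasta", alignment)
    profile = dc.build_consensus(alignment)
    highly, extremely = dc.call_conserved_residues(profile)
    with open(outdir / "consensus.tsv", "w") as fh:
        fh.write("column\tresidue\tratio\tregion\thighly_conserved\textremely_conserved\n")
        for col in profile:
            fh.write(
                f"{col.position}\t{col.residue}\t{col.ratio:.4f}\t{col.region}\t"
                f"{int(col.highly_conserved)}\t{int(col.extremely_conserved)}\n"
            )
    calls, census = dc.classify_alignment(alignment)
    with open(outdir / "binding.tsv", "w") as fh:
        fh.write("member\tres9\tres13\tres16\tres17\tclass\n")
        for call in calls:
            r9, r13, r16, r17 = call.residues
            fh.write(f"{call.member}\t{r9}\t{r13}\t{r16}\t{r17}\t{call.klass}\n")
    state["binding_calls"] = calls
    manifest["domain_alignment"] = str(outdir / "domain_alignment.fasta")
    manifest["consensus"] = str(outdir / "consensus.tsv")
    manifest["binding"] = str(outdir / "binding.tsv")
    summary["binding_census"] = census
    summary["n_highly_conserved"] = len(highly)
    summary["n_extremely_conserved"] = len(extremely)


def _stage_tree(config, outdir, state, summary, manifest):
    _require(
        config, "tree",
        reference_alignment=config.reference_alignment,
        reference_labels=config.reference_labels,
    )
    refs = read_fasta(config.reference_alignment)
    labels = {}
    with open(config.reference_labels) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2 and parts[0] != "taxon":
                labels[parts[0]] = parts[1]
    alignment = dict(state["member_alignment"]) | refs
    if config.bootstrap > 0:
        tree = ph.bootstrap_support(alignment, config.bootstrap, config.seed)
    else:
        tree = ph.neighbor_joining(ph.pairwise_pdistance(alignment))
    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    assignment = ph.assign_subfamily(alignment, labels, method="nearest")
    with open(outdir / "subfamilies.tsv", "w") as fh:
        fh.write("member\tsubfamily\n")
        for member in sorted(assignment, key=lambda m: m):
            fh.write(f"{member}\t{assignment[member]}\n")
    state["subfamilies"] = assignment
    counts: dict[str, int] = {}
    for label in assignment.values():
        counts[label] = counts.get(label, 0) + 1
    manifest["tree"] = str(outdir / "tree.nwk")
    manifest["subfamilies"] = str(outdir / "subfamilies.tsv")
    summary["subfamily_counts"] = dict(sorted(counts.items()))


def _stage_structure(config, outdir, state, summary, manifest):
    members = state["members"]
    gene_models = state["gene_models"]
    sub_by_gene = {}
    if "subfamilies" in state:
        name_to_gene = {m.name: m.gene_id for m in members}
        for name, label in state["subfamilies"].items():
            if name in name_to_gene:
                sub_by_gene[name_to_gene[name]] = label
    result = sc.exon_intron_summary(
        gene_models, [m.gene_id for m in members], subfamilies=sub_by_gene
    )
    name_of = {m.gene_id: m.name for m in members}
    with open(outdir / "structure.tsv", "w") as fh:
        fh.write("gene_id\tname\tchromosome\tstrand\texon_count\tintron_count\n")
        for m in members:
            gm = gene_models[m.gene_id]
            fh.write(
                f"{m.gene_id}\t{name_of[m.gene_id]}\t{gm.chromosome}\t"
                f"{gm.strand}\t{gm.exon_count}\t{gm.intron_count}\n"
            )
    manifest["structure"] = str(outdir / "structure.tsv")
    summary["n_intronless"] = result.n_intronless
    summary["pct_intronless"] = result.pct_intronless
    summary["n_one_intron"] = result.n_one_intron
    summary["exon_count_range"] = [result.min_exons, result.max_exons]


def _stage_cis(config, outdir, state, summary, manifest):
    _require(config, "cis", promoters=config.promoters)
    promoters = read_fasta(config.promoters)
    catalog = sc.load_cis_catalog(config.catalog)
    hits, element_counts, category_counts = sc.scan_cis_elements(promoters, catalog)
    with open(outdir / "cis_hits.tsv", "w") as fh:
        fh.write("gene_id\telement\toffset\tstrand\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.element}\t{h.offset}\t{h.strand}\n")
    category_of = {e.name: e.category for e in catalog}
    with open(outdir / "cis_summary.tsv", "w") as fh:
        fh.write("element\tcategory\tcount\n")
        for name in sorted(element_counts):
            fh.write(f"{name}\t{category_of[name]}\t{element_counts[name]}\n")
    manifest["cis_hits"] = str(outdir / "cis_hits.tsv")
    manifest["cis_summary"] = str(outdir / "cis_summary.tsv")
    summary["cis_category_counts"] = category_counts
    summary["cis_total_hits"] = len(hits)


def _stage_screen(config, outdir, state, summary, manifest):
    _require(config, "screen", expression=config.expression)
    matrix = pd.read_csv(config.expression, sep="\t", index_col="gene")
    members = state.get("members")
    name_of = {}
    if members:
        member_ids = [m.gene_id for m in members if m.gene_id in matrix.index]
        matrix = matrix.loc[member_ids]
        name_of = {m.gene_id: m.name for m in members}
    filtered, log2m = es.filter_and_normalize(matrix, config.min_abundance)
    clusters = es.cluster_expression(log2m, k=config.k_clusters)
    degs = es.screen_degs(
        filtered, control=config.control, fc_threshold=config.fc_threshold
    )
    go_table = (
        pd.read_csv(config.go, sep="\t", dtype=str)
        if config.go
        else pd.DataFrame(columns=["gene", "term_id", "term_name", "aspect"])
    )
    candidates = es.select_candidates(degs, go_table, config.salt_terms)
    clusters.labels.to_frame().assign(
        name=[name_of.get(g, "") for g in clusters.labels.index]
    ).to_csv(outdir / "clusters.tsv", sep="\t")
    with open(outdir / "degs.tsv", "w") as fh:
        treatments = [c for c in filtered.columns if c != config.control]
        fh.write("gene_id\tname\tdirection\tmax_abs_log2fc\t")
        fh.write("\t".join(f"log2fc_{t}" for t in treatments) + "\n")
        for d in sorted(degs, key=lambda d: d.gene):
            lfc = "\t".join(f"{d.log2_fold_changes[t]:.4f}" for t in treatments)
            fh.write(
                f"{d.gene}\t{name_of.get(d.gene, '')}\t{d.direction}\t"
                f"{d.max_abs_log2fc:.4f}\t{lfc}\n"
            )
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("gene_id\tname\tprovenance\n")
        for g in candidates.genes:
            fh.write(f"{g}\t{name_of.get(g, '')}\t{candidates.provenance[g]}\n")
    log2m.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", float_format="%.6f")
    manifest["clusters"] = str(outdir / "clusters.tsv")
    manifest["degs"] = str(outdir / "degs.tsv")
    manifest["candidates"] = str(outdir / "candidates.tsv")
    manifest["heatmap_matrix"] = str(outdir / "heatmap_matrix.tsv")
    summary["n_expressed"] = len(filtered)
    summary["n_clusters"] = clusters.k
    summary["n_degs"] = len(degs)
    summary["n_candidates"] = len(candidates)
    state["candidates"] = candidates


def _stage_qpcr(config, outdir, state, summary, manifest):
    _require(config, "qpcr", qpcr=config.qpcr)
    table = pd.read_csv(config.qpcr, sep="\t")
    detail, summary_table = qs.relative_expression_ddct(
        table, config.reference_gene, config.calibrator
    )
    summary_table.to_csv(
        outdir / "relexpr.tsv", sep="\t", index=False, float_format="%.6f"
    )
    rows = []
    for gene, grp in detail.groupby("gene", sort=True):
        groups = {
            t: sub["rel_expr"].tolist() for t, sub in grp.groupby("treatment")
        }
        anova = qs.anova_oneway(groups)
        means = {t: float(np.mean(v)) for t, v in groups.items()}
        n_per = {t: len(v) for t, v in groups.items()}
        letters = qs.duncan_letters(
            means, n_per, anova.ms_error, anova.df_within, config.alpha
        )
        for t in sorted(means, key=lambda t: (-means[t], t)):
            rows.append({
                "gene": gene, "treatment": t, "mean_rel_expr": round(means[t], 6),
                "letters": letters[t], "f_statistic": round(anova.f_statistic, 4)
                if np.isfinite(anova.f_statistic) else "inf",
                "p_value": round(anova.p_value, 6),
            })
    pd.DataFrame(rows).to_csv(outdir / "letters.tsv", sep="\t", index=False)
    manifest["relexpr"] = str(outdir / "relexpr.tsv")
    manifest["letters"] = str(outdir / "letters.tsv")
    summary["n_qpcr_genes"] = int(detail["gene"].nunique())


def _consistency_checks(summary: dict) -> None:
    if "binding_census" in summary and "family_size" in summary:
        total = sum(summary["binding_census"].values())
        if total != summary["family_size"]:
            raise FamscanError(
                "inconsistent report: binding census does not sum to family size"
            )
    if "n_degs" in summary and "n_candidates" in summary:
        if summary["n_candidates"] < summary["n_degs"]:
            raise FamscanError(
                "inconsistent report: fewer candidates than DEGs"
            )

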