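"""Orchestration of the three analysis stages over one input bundle.

Stage order follows the origination trilogy: emergence (alignment
quality, ORF status in outgroups, common ancestral disablers, parsimony
age), retention (GC/fragile-codon features, neutral ORF half-life and
survival probability), expression evidence, and selection (regional
diversity, πN/πS, spectra, Monte Carlo tests on the polymorphism
panels). A gene is labeled de novo only when every emergence and
expression gate passes; each excluded gene records the first rule that
fired, so the exclusion reasons partition the non-de-novo set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import expression as expr
from . import ortholog_assessment as oa
from . import popgen
from .errors import InsufficientEvidenceError
from .genome_io import (
    GeneTableRecord,
    annotation_from_bed,
    read_bed,
    read_fasta,
    read_gene_table,
    read_variants,
)
from .orf_lifespan import MutationModel, half_life, survival_probability
from .sequence_features import CodingSequence, fragile_codon_fraction, gc3, gc_content
from .synthetic_data import DEFAULT_SPECIES, DEFAULT_TREE, FixtureBundle

#: Divergence times (years) used for survival probabilities, keyed by
#: origin-clade age label.
DEFAULT_DIVERGENCE_TIMES = {
    "H": 6.0e6,
    "H-C": 8.0e6,
    "H-C-G": 14.0e6,
    "H-C-G-O": 25.0e6,
    "pre-hominoid": 25.0e6,
}


@dataclass
class PipelineConfig:
    bundle_dir: Path | str | None = None
    min_coverage: float = 0.7
    min_identity: float = 0.5
    orf_fraction: float = 0.7
    rpkm_gene: float = 0.5
    rpkm_background: float = 0.2
    lifespan_replicates: int = 20000
    mc_sims: int = 10000
    bootstrap: int = 1000
    divergence_times: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE_TIMES)
    )
    mutation_model: MutationModel = field(default_factory=MutationModel)
    run_lifespan: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("min_coverage", "min_identity", "orf_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("lifespan_replicates", "mc_sims", "bootstrap"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")


@dataclass
class PipelineResult:
    reports: pd.DataFrame
    summary: dict
    logs: list[dict]

    def write(self, out_dir: Path | str) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(out_dir / "gene_reports.tsv", sep="\t", index=False)
        with open(out_dir / "pipeline_log.jsonl", "w") as fh:
            for entry in self.logs:
                fh.write(json.dumps(entry) + "\n")
        with open(out_dir / "stage_summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)


def analyze_genes(
    human_cds: Mapping[str, CodingSequence],
    alignments: Mapping[str, Mapping[str, oa.CodonAlignment]],
    rpkms: Mapping[str, Mapping[str, float]] | None,
    config: PipelineConfig,
    tree: str = DEFAULT_TREE,
    peptide_evidence: Mapping[str, bool] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Emergence + retention + expression stages for a gene panel.

    ``rpkms`` maps gene -> tissue -> RPKM (None skips the expression
    gate); ``peptide_evidence`` is an optional per-gene boolean input
    (mass-spectrometry support is consumed as a flag, never computed).
    """
    logs: list[dict] = []
    rows = []
    rng = np.random.default_rng(config.seed)
    for gene_id in sorted(human_cds):
        cds = human_cds[gene_id]
        gene_seed = int(rng.integers(2**31))
        sense_len = len(cds.sense_codons())
        row: dict = {"gene_id": gene_id, "orf_length_codons": sense_len}
        exclusion = None

        # --- emergence -------------------------------------------------
        gene_alns = alignments.get(gene_id, {})
        passing = {
            sp: aln
            for sp, aln in gene_alns.items()
            if oa.filter_alignment_quality(
                aln, config.min_coverage, config.min_identity
            )
        }
        for sp in set(gene_alns) - set(passing):
            logs.append(
                {"stage": "emergence", "gene": gene_id, "rule": "alignment_quality",
                 "species": sp, "coverage": gene_alns[sp].coverage,
                 "identity": gene_alns[sp].identity}
            )
        row["n_outgroups_aligned"] = len(gene_alns)
        row["n_outgroups_pass"] = len(passing)
        statuses = {
            sp: oa.assess_orf(aln, sense_len, config.orf_fraction)
            for sp, aln in passing.items()
        }
        presence = {cds.species: True}
        presence.update({sp: st.present for sp, st in statuses.items()})
        row["n_outgroups_absent"] = sum(
            1 for st in statuses.values() if not st.present
        )
        if len(passing) < 2:
            exclusion = "insufficient high-quality alignments"
            row.update(age_label=None, species_label=None, common_disabler=False,
                       ambiguous=None)
        else:
            age = oa.assign_age(presence, tree, gene_id, cds.species)
            row["age_label"] = age.age_label
            row["species_label"] = age.species_label
            row["ambiguous"] = age.ambiguous
            try:
                shared, newly = oa.detect_common_disablers(
                    statuses, [sp for sp in DEFAULT_SPECIES if sp != cds.species]
                )
            except InsufficientEvidenceError:
                shared, newly = [], False
            row["common_disabler"] = newly
            row["n_shared_disablers"] = len(shared)
            if age.age_label == "pre-hominoid" or row["n_outgroups_absent"] < 2:
                exclusion = "ORF present in outgroups"
            elif not newly:
                exclusion = "no common disabler"

        # --- retention features ---------------------------------------
        row["gc"] = gc_content(cds.seq)
        row["gc3"] = gc3(cds)
        row["fragile_fraction"] = fragile_codon_fraction(cds)
        if config.run_lifespan:
            est = half_life(
                cds, config.mutation_model,
                n_replicates=config.lifespan_replicates, seed=gene_seed,
            )
            row["t_half"] = est.t_half
            row["censored_fraction"] = est.censored_fraction
            T = config.divergence_times.get(row.get("age_label") or "H", 6.0e6)
            if est.defined:
                surv = survival_probability(T, est.t_half)
                row["lambda"] = surv.lam
                row["p_survival"] = surv.p

        # --- expression ------------------------------------------------
        if rpkms is not None:
            gene_rpkms = rpkms.get(gene_id, {})
            if gene_rpkms:
                call = expr.expression_filter(gene_rpkms, config.rpkm_gene)
                row["expressed"] = call.expressed
                row["tissue_breadth"] = call.breadth
                row["top_tissue"] = call.top_tissue
            else:
                row["expressed"] = False
            if exclusion is None and not row["expressed"]:
                exclusion = "not expressed"
        if (
            exclusion is None
            and peptide_evidence is not None
            and not peptide_evidence.get(gene_id, True)
        ):
            exclusion = "no peptide evidence"

        row["de_novo"] = exclusion is None
        row["exclusion_reason"] = exclusion
        if exclusion is not None:
            logs.append(
                {"stage": "classification", "gene": gene_id, "rule": exclusion}
            )
        rows.append(row)
    return pd.DataFrame(rows), logs


def _panel_summary(vs: popgen.VariantSet, cds: CodingSequence,
                   config: PipelineConfig, seed: int) -> dict:
    vs.classify(cds)
    est = popgen.diversity_by_region(vs, classes=("CDS", "exon", "intron"))
    normalized = popgen.normalize_by_intron(est)
    pnps = popgen.pn_ps_ratio(vs, cds)
    syn = vs.subset_by_site_class("synonymous", "pseudo_synonymous")
    nonsyn = vs.subset_by_site_class("nonsynonymous", "pseudo_nonsynonymous")
    out = {
        "diversity": {
            e.region_class: {"pi": e.pi, "theta_w": e.theta_w, "S": e.S, "L": e.L}
            for e in est
        },
        "pi_normalized_by_intron": normalized,
        "pn_ps": {
            "pi_n": pnps.pi_n, "pi_s": pnps.pi_s,
            "ratio": pnps.ratio, "defined": pnps.defined,
        },
    }
    mc = popgen.exon_intron_mc_test(vs, n_sims=config.mc_sims, seed=seed)
    out["exon_intron_mc"] = {
        "p": mc.p_value, "observed_exonic": mc.observed_exonic,
        "k": mc.k_total, "p_exon": mc.p_exon,
    }
    try:
        spec_n = popgen.daf_spectrum(nonsyn, B=config.bootstrap, seed=seed)
        spec_s = popgen.daf_spectrum(
            syn, n=spec_n.n, B=config.bootstrap, seed=seed + 1
        )
        rare = popgen.excess_rare_test(spec_n, spec_s)
        out["rare_excess"] = {
            "p": rare.p_value,
            "nonsyn_singleton_prop": spec_n.singleton_proportion,
            "syn_singleton_prop": spec_s.singleton_proportion,
        }
    except popgen.UndefinedValueError as exc:
        out["rare_excess"] = {"error": str(exc)}
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages against an on-disk fixture bundle directory."""
    if config.bundle_dir is None:
        raise ValueError("config.bundle_dir is required")
    bundle_dir = Path(config.bundle_dir)
    fasta = read_fasta(bundle_dir / "human_orfs.fasta")
    tree = (bundle_dir / "tree.nwk").read_text().strip() \
        if (bundle_dir / "tree.nwk").exists() else DEFAULT_TREE
    human_cds = {
        gid: CodingSequence(gid, "human", seq, includes_terminal_stop=True)
        for gid, seq in fasta.items()
    }
    alignments: dict[str, dict[str, oa.CodonAlignment]] = {}
    for path in sorted((bundle_dir / "alignments").glob("*.tsv")):
        gid, species = path.stem.rsplit(".", 1)
        alignments.setdefault(gid, {})[species] = oa.CodonAlignment.from_tsv(path)

    rpkms: dict[str, dict[str, float]] | None = None
    expr_path = bundle_dir / "expression.tsv"
    if expr_path.exists():
        rpkms = {}
        for rec in expr.read_expression_table(expr_path):
            if not rec.region_id.startswith("human:"):
                continue
            gid = rec.region_id.split(":", 1)[1]
            rpkms.setdefault(gid, {})[rec.tissue] = rec.rpkm

    reports, logs = analyze_genes(human_cds, alignments, rpkms, config, tree)

    summary: dict = {
        "n_genes": int(len(reports)),
        "n_de_novo": int(reports["de_novo"].sum()),
        "exclusions": reports["exclusion_reason"].value_counts().to_dict(),
    }
    panel_cds_path = bundle_dir / "panel_locus.fasta"
    bed_path = bundle_dir / "panel_regions.bed"
    if panel_cds_path.exists() and bed_path.exists():
        panel_seq = read_fasta(panel_cds_path)
        panel_cds = CodingSequence(
            "panel_locus", "human", next(iter(panel_seq.values())),
            includes_terminal_stop=True,
        )
        region = annotation_from_bed("panel_locus", read_bed(bed_path))
        for i, name in enumerate(("human_like", "macaque_like")):
            vcf = bundle_dir / f"{name}.vcf"
            if not vcf.exists():
                continue
            vs = popgen.VariantSet(read_variants(vcf), region)
            summary[name] = _panel_summary(
                vs, panel_cds, config, seed=config.seed + 1000 + i
            )
    return PipelineResult(reports=reports, summary=summary, logs=logs)


def run_pipeline_in_memory(bundle: FixtureBundle,
                           config: PipelineConfig) -> PipelineResult:
    """Run the per-gene stages directly on an in-memory fixture bundle
    (no file round-trip); panel statistics are computed the same way."""
    human = bundle.expression.matrices.get("human")
    rpkms = (
        {gid: human.loc[gid].to_dict() for gid in human.index}
        if human is not None
        else None
    )
    reports, logs = analyze_genes(
        bundle.human_cds, bundle.alignments, rpkms, config
    )
    summary: dict = {
        "n_genes": int(len(reports)),
        "n_de_novo": int(reports["de_novo"].sum()),
        "exclusions": reports["exclusion_reason"].value_counts().to_dict(),
    }
    for i, (name, vs) in enumerate(bundle.panels.items()):
        summary[name] = _panel_summary(
            popgen.VariantSet(vs.variants, vs.region_annotation),
            bundle.panel_cds[name], config, seed=config.seed + 1000 + i,
        )
    return PipelineResult(reports=reports, summary=summary, logs=logs)


def summarize_age_classes(
    reports: pd.DataFrame | Sequence[GeneTableRecord] | Sequence[oa.AgeAssignment],
) -> dict[str, int]:
    """Gene counts per age label plus a ``total`` entry.

    Accepts a pipeline report table (``age_label``/``species_label``
    columns), parsed gene-table records, or age assignments."""
    labels: list[str] = []
    if isinstance(reports, pd.DataFrame):
        col = "species_label" if "species_label" in reports else "age_label"
        labels = [l for l in reports[col] if l]
    else:
        for item in reports:
            if isinstance(item, GeneTableRecord):
                labels.append(item.age_class)
            elif isinstance(item, oa.AgeAssignment):
                labels.append(item.species_label)
            else:
                raise TypeError(f"cannot summarize {type(item)!r}")
    counts: dict[str, int] = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    counts["total"] = len(labels)
    return counts


def summarize_table1(path=None) -> dict[str, int]:
    """Age-class summary of the packaged 64-gene catalog fixture."""
    records = read_gene_table() if path is None else read_gene_table(path)
    return summarize_age_classes(records)
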