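"""Synthetic fixtures for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* GC-controlled i.i.d. sequences, optionally constrained to a valid ORF;
* orthologs evolved along a dated primate phylogeny under the neutral
  mutation model, with "common ancestral disablers" injected so that all
  descendants of a chosen clade share a disruption at the same aligned
  codon — the signature of a newly originated (rather than dying) gene;
* population polymorphism whose unfolded site frequency spectrum follows
  the Wright-Fisher diffusion expectation under genic selection, with
  the neutral 1/i law as the gamma -> 0 limit;
* log-normal tissue expression matrices plus an intergenic background
  sample with a small tail above the transcription cutoff.

Query-lineage (human) branches reject nonsense substitutions, emulating
the ascertainment that an observed de novo gene is intact in human;
control genes reject them on every branch, emulating long-term coding
constraint.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import gammaln

from .genome_io import (
    GenomicInterval,
    RegionAnnotation,
    VariantRecord,
    write_fasta,
    write_variants,
)
from .orf_lifespan import MutationModel
from .ortholog_assessment import AlignmentRow, CodonAlignment
from .popgen import VariantSet
from .sequence_features import BASES, STOP_CODONS, STANDARD_TABLE, CodingSequence

#: Default species panel: dated ladder topology, branch lengths in years.
DEFAULT_TREE = (
    "(((((human:6000000,chimp:6000000):2000000,gorilla:8000000):6000000,"
    "orangutan:14000000):11000000,macaque:25000000):65000000,mouse:90000000);"
)

DEFAULT_SPECIES = ("human", "chimp", "gorilla", "orangutan", "macaque", "mouse")


# ---------------------------------------------------------------------------
# GC-controlled sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceSimConfig:
    length: int  # nucleotides; multiple of 3 when ensure_orf
    gc_target: float = 0.5
    ensure_orf: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError(f"gc_target must be in [0,1], got {self.gc_target}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.ensure_orf and self.length % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T order


_BASE_ORDER = "ACGT"


def generate_sequence(cfg: SequenceSimConfig) -> str:
    """I.i.d. bases with P(G)+P(C) = gc_target. With ``ensure_orf`` the
    sequence starts with ATG, internal stop codons are resampled, and the
    final codon is a stop drawn with composition-consistent weights."""
    rng = np.random.default_rng(cfg.seed)
    probs = _base_probs(cfg.gc_target)
    if not cfg.ensure_orf:
        idx = rng.choice(4, size=cfg.length, p=probs)
        return "".join(_BASE_ORDER[i] for i in idx)
    n_codons = cfg.length // 3
    if n_codons < 3:
        raise ValueError("an ORF needs at least start, one sense codon, stop")
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(_BASE_ORDER[i] for i in rng.choice(4, size=3, p=probs))
            if codon not in STOP_CODONS:
                codons.append(codon)
                break
    stops = sorted(STOP_CODONS)
    w = np.array(
        [np.prod([probs[_BASE_ORDER.index(b)] for b in s]) for s in stops]
    )
    codons.append(stops[rng.choice(len(stops), p=w / w.sum())])
    return "".join(codons)


def generate_coding_sequence(cfg: SequenceSimConfig, gene_id: str = "synthetic",
                             species: str = "human") -> CodingSequence:
    if not cfg.ensure_orf:
        raise ValueError("ensure_orf must be set for a CodingSequence")
    return CodingSequence(gene_id, species, generate_sequence(cfg),
                          includes_terminal_stop=True)


# ---------------------------------------------------------------------------
# Ortholog evolution along a dated tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisablerSpec:
    """A disruption injected once on an internal (or terminal) branch.

    ``clade`` names the tip species that must inherit the disabler. When
    the clade is every non-query species — the de novo scenario, where
    the disabler is ancestral and was resolved on the query lineage — it
    is applied to the root sequence and reverted on the query's terminal
    branch."""

    clade: tuple[str, ...]
    codon_position: int
    kind: str  # premature_stop | frameshift_indel

    def __post_init__(self):
        if self.kind not in ("premature_stop", "frameshift_indel"):
            raise ValueError(f"unknown disabler kind {self.kind!r}")


@dataclass
class TreeSimConfig:
    newick: str = DEFAULT_TREE
    model: MutationModel = field(default_factory=MutationModel)
    disablers: tuple[DisablerSpec, ...] = ()
    query_species: str = "human"
    reject_stops_on_query: bool = True
    reject_stops_everywhere: bool = False
    seed: int = 0


@dataclass
class OrthologSim:
    """Evolved ortholog panel with true codon alignments to the query."""

    sequences: dict[str, str]
    alignments: dict[str, CodonAlignment]  # subject species -> alignment


def _apply_disabler(cells: list[str], spec: DisablerSpec,
                    rng: np.random.Generator) -> None:
    pos = spec.codon_position
    if not 0 <= pos < len(cells) - 1:
        raise ValueError(f"disabler codon {pos} outside the ORF")
    if spec.kind == "premature_stop":
        stops = sorted(STOP_CODONS)
        cells[pos] = stops[int(rng.integers(len(stops)))]
    else:
        cell = cells[pos]
        drop = int(rng.integers(len(cell)))
        cells[pos] = cell[:drop] + cell[drop + 1 :]


def _mutate_branch(cells: list[str], years: float, model: MutationModel,
                   rng: np.random.Generator, reject_stops: bool,
                   protected: frozenset[int] = frozenset()) -> None:
    """Accrue point substitutions along one branch (Poisson in number).

    ``protected`` codon positions (injected disablers, which the study
    design ascertains as detectable) are skipped."""
    flat = [(ci, bi) for ci, cell in enumerate(cells) for bi in range(len(cell))]
    L = len(flat)
    n_subs = rng.poisson(model.point_rate * years * L)
    for _ in range(n_subs):
        ci, bi = flat[int(rng.integers(L))]
        if ci in protected:
            continue
        cell = cells[ci]
        base = cell[bi]
        choices = [b for b in BASES if b != base]
        terminal = ci == len(cells) - 1
        for _attempt in range(20):
            new = choices[int(rng.integers(3))]
            candidate = cell[:bi] + new + cell[bi + 1 :]
            if reject_stops and not terminal and candidate in STOP_CODONS:
                continue
            if (
                reject_stops
                and terminal
                and cell in STOP_CODONS
                and candidate not in STOP_CODONS
            ):
                continue  # an intact ORF keeps its terminal stop
            cells[ci] = candidate
            break


def evolve_orthologs(ancestor: str, cfg: TreeSimConfig) -> OrthologSim:
    """Evolve an ancestral ORF down the tree; emit tip sequences and true
    codon alignments of each non-query tip to the query."""
    if len(ancestor) % 3 != 0:
        raise ValueError("ancestor length must be a multiple of 3")
    tree = dendropy.Tree.get(data=cfg.newick, schema="newick")
    tree.is_rooted = True
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if cfg.query_species not in tips:
        raise ValueError(f"query species {cfg.query_species!r} not in tree")
    for spec in cfg.disablers:
        unknown = set(spec.clade) - tips
        if unknown:
            raise ValueError(f"unknown clade species {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    root_cells = [ancestor[i : i + 3] for i in range(0, len(ancestor), 3)]

    # Disablers whose clade is all non-query tips are ancestral: present at
    # the root, reverted on the query's terminal branch.
    ancestral_specs = [
        s for s in cfg.disablers if set(s.clade) == tips - {cfg.query_species}
    ]
    branch_specs: dict[int, list[DisablerSpec]] = {}
    for s in cfg.disablers:
        if s in ancestral_specs:
            continue
        mrca = (
            tree.mrca(taxon_labels=list(s.clade))
            if len(s.clade) > 1
            else next(
                l for l in tree.leaf_node_iter() if l.taxon.label == s.clade[0]
            )
        )
        clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if clade_tips != set(s.clade):
            raise ValueError(
                f"{sorted(s.clade)} is not a clade on the tree "
                f"(its MRCA spans {sorted(clade_tips)})"
            )
        branch_specs.setdefault(id(mrca), []).append(s)

    reverted = {s.codon_position: root_cells[s.codon_position]
                for s in ancestral_specs}
    protected = frozenset(s.codon_position for s in cfg.disablers)
    for s in ancestral_specs:
        _apply_disabler(root_cells, s, rng)

    sequences: dict[str, str] = {}
    cells_by_tip: dict[str, list[str]] = {}

    def descend(node, cells: list[str]):
        cells = list(cells)
        # Ancestral disablers are resolved on the query's terminal branch:
        # the query tip is ascertained to carry the intact ORF today.
        if node.is_leaf() and node.taxon.label == cfg.query_species:
            for pos, cell in reverted.items():
                cells[pos] = cell
        if node.edge.length:
            on_query_path = cfg.query_species in {
                leaf.taxon.label for leaf in node.leaf_iter()
            }
            # Rejecting nonsense substitutions along the whole query path
            # conditions on the ascertainment event (ORF intact in the
            # query); branches off that path mutate freely.
            reject = cfg.reject_stops_everywhere or (
                cfg.reject_stops_on_query and on_query_path
            )
            _mutate_branch(cells, node.edge.length, cfg.model, rng, reject,
                           protected)
        for s in branch_specs.get(id(node), []):
            _apply_disabler(cells, s, rng)
        if node.is_leaf():
            cells_by_tip[node.taxon.label] = cells
            sequences[node.taxon.label] = "".join(cells)
        else:
            for child in node.child_nodes():
                descend(child, cells)

    descend(tree.seed_node, root_cells)

    query_cells = cells_by_tip[cfg.query_species]
    alignments = {}
    for species, cells in cells_by_tip.items():
        if species == cfg.query_species:
            continue
        rows = []
        for i, (q, s) in enumerate(zip(query_cells, cells)):
            if len(s) == 3:
                event = "match" if q == s else "substitution"
                rows.append(AlignmentRow(i, q, s, event))
            else:
                rows.append(AlignmentRow(i, q, s if s else "-", "deletion"))
        alignments[species] = CodonAlignment(
            gene_id="", query_species=cfg.query_species,
            subject_species=species, rows=rows,
        )
    return OrthologSim(sequences=sequences, alignments=alignments)


# ---------------------------------------------------------------------------
# Polymorphism under the Wright-Fisher diffusion SFS
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def sfs_weights(n: int, gamma: float) -> tuple[float, ...]:
    """Expected unfolded SFS weights E[xi_i; gamma] for i = 1..n-1.

    E[xi_i] ∝ ∫0..1 C(n,i) q^i (1-q)^(n-i) f(q; gamma) dq with the genic-
    selection sojourn density f(q; gamma) = (1 - exp(-2*gamma*(1-q))) /
    ((1 - exp(-2*gamma)) * q * (1-q)); the gamma -> 0 limit is 1/i."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if abs(gamma) < 1e-9:
        return tuple(1.0 / i for i in range(1, n))
    denom = 1.0 - math.exp(-2.0 * gamma)
    out = []
    for i in range(1, n):
        logC = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)

        def integrand(q, i=i, logC=logC):
            if q <= 0.0 or q >= 1.0:
                return 0.0
            logbin = logC + i * math.log(q) + (n - i) * math.log1p(-q)
            f = (1.0 - math.exp(-2.0 * gamma * (1.0 - q))) / (
                denom * q * (1.0 - q)
            )
            return math.exp(logbin) * f

        val, _err = integrate.quad(integrand, 0.0, 1.0, limit=200)
        out.append(val)
    return tuple(out)


def selection_intensity_factor(n: int, gamma: float) -> float:
    """Total polymorphism retained under selection relative to neutrality:
    sum_i E[xi_i; gamma] / sum_i E[xi_i; 0]. Scales expected segregating-
    site counts per class."""
    return sum(sfs_weights(n, gamma)) / sum(sfs_weights(n, 0.0))


@dataclass
class SelectionConfig:
    """Polymorphism panel configuration.

    ``sites`` holds the expected number of segregating sites per class
    under neutrality; classes under selection realize a Poisson count
    scaled down by :func:`selection_intensity_factor`. ``gamma`` maps a
    class to its scaled selection coefficient (absent classes are
    neutral)."""

    n: int = 134
    sites: Mapping[str, int] = field(
        default_factory=lambda: {
            "nonsynonymous": 1200, "synonymous": 400, "intron": 2000,
        }
    )
    gamma: Mapping[str, float] = field(default_factory=dict)
    cds: CodingSequence | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n % 2 != 0:
            raise ValueError("n must be even (diploid samples)")


def _coding_choices(region: RegionAnnotation, cds: CodingSequence):
    """Per-class mutational opportunities in the CDS (terminal stop
    excluded): class -> genomic position -> [(ref, alt), ...]."""
    from .popgen import _revcomp_base

    choices: dict[str, dict[int, list[tuple[str, str]]]] = {
        "synonymous": {}, "nonsynonymous": {},
    }
    ivs = region.cds_intervals()
    strand = ivs[0].strand if ivs else "+"
    # genomic position per CDS offset, in coding order
    positions: list[tuple[str, int]] = []
    for iv in ivs:
        rng_ = (
            range(iv.end - 1, iv.start - 1, -1) if strand == "-"
            else range(iv.start, iv.end)
        )
        positions.extend((iv.contig, p) for p in rng_)
    codons = cds.codons()
    n_sense = len(codons) - (1 if cds.includes_terminal_stop else 0)
    for offset, (contig, gpos) in enumerate(positions):
        codon_idx, within = divmod(offset, 3)
        if codon_idx >= n_sense:
            continue
        codon = codons[codon_idx]
        if codon in STOP_CODONS or "N" in codon:
            continue
        for alt_coding in BASES:
            if alt_coding == codon[within]:
                continue
            mutant = codon[:within] + alt_coding + codon[within + 1 :]
            if mutant in STOP_CODONS:
                label = "nonsynonymous"  # nonsense substitutions
            elif STANDARD_TABLE.translate(mutant) == STANDARD_TABLE.translate(codon):
                label = "synonymous"
            else:
                label = "nonsynonymous"
            ref = codon[within] if strand == "+" else _revcomp_base(codon[within])
            alt = alt_coding if strand == "+" else _revcomp_base(alt_coding)
            choices[label].setdefault(gpos, []).append((ref, alt))
    return choices, (ivs[0].contig if ivs else None)


def simulate_polymorphism(region: RegionAnnotation,
                          cfg: SelectionConfig) -> VariantSet:
    """Draw a polymorphism panel for one annotated locus.

    Site positions are sampled without replacement from the mutational
    opportunities of each class; derived counts follow the SFS of the
    class's gamma; genotypes distribute the derived alleles over n/2
    diploid samples; the ancestral allele is recorded as the reference so
    spectra are unfolded."""
    rng = np.random.default_rng(cfg.seed)
    records: list[VariantRecord] = []

    coding_classes = {"synonymous", "nonsynonymous"}
    want_coding = coding_classes & set(cfg.sites)
    if want_coding:
        if cfg.cds is None:
            raise ValueError("cfg.cds required for coding site classes")
        choices, contig = _coding_choices(region, cfg.cds)

    used_positions: set[tuple[str, int]] = set()
    for cls, target in cfg.sites.items():
        gamma = float(cfg.gamma.get(cls, 0.0))
        factor = selection_intensity_factor(cfg.n, gamma)
        count = int(rng.poisson(target * factor))
        if count == 0:
            continue
        weights = np.array(sfs_weights(cfg.n, gamma))
        probs = weights / weights.sum()
        # one variant per genomic position: walk a shuffled position pool,
        # skipping positions already claimed by another class
        if cls in coding_classes:
            pool = choices[cls]
            positions = sorted(pool)
            site_contig = contig
            order = rng.permutation(len(positions))
            picked = []
            for j in order:
                if len(picked) == count:
                    break
                gpos = positions[j]
                if (site_contig, gpos) in used_positions:
                    continue
                used_positions.add((site_contig, gpos))
                opts = pool[gpos]
                ref, alt = opts[int(rng.integers(len(opts)))]
                picked.append((gpos, ref, alt))
        else:
            ivs = region.intervals.get(cls, [])
            if not ivs:
                raise ValueError(f"region has no {cls!r} intervals")
            all_pos = [
                (iv.contig, p) for iv in ivs for p in range(iv.start, iv.end)
            ]
            site_contig = all_pos[0][0]
            order = rng.permutation(len(all_pos))
            picked = []
            for j in order:
                if len(picked) == count:
                    break
                c, p = all_pos[j]
                if (c, p) in used_positions:
                    continue
                used_positions.add((c, p))
                ref = _BASE_ORDER[int(rng.integers(4))]
                alt = [b for b in BASES if b != ref][int(rng.integers(3))]
                picked.append((p, ref, alt))
        for pos, ref, alt in picked:
            i = 1 + int(rng.choice(cfg.n - 1, p=probs))
            chroms = np.zeros(cfg.n, dtype=int)
            chroms[rng.choice(cfg.n, size=i, replace=False)] = 1
            genotypes = tuple(
                (int(chroms[2 * s]), int(chroms[2 * s + 1]))
                for s in range(cfg.n // 2)
            )
            records.append(
                VariantRecord(
                    contig=site_contig, pos=pos, ref=ref, alt=alt,
                    ancestral=ref, genotypes=genotypes,
                )
            )
    records.sort(key=lambda r: (r.contig, r.pos))
    return VariantSet(records, region)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

DEFAULT_TISSUES = (
    "adipose", "adrenal", "blood", "brain", "breast", "cerebellum", "colon",
    "heart", "kidney", "liver", "lung", "lymph_node", "muscle", "ovary",
    "prostate", "testes", "thyroid",
)


@dataclass
class ExpressionSim:
    matrices: dict[str, pd.DataFrame]  # species -> genes x tissues RPKM
    background: dict[str, np.ndarray]  # tissue -> intergenic RPKM sample


def generate_expression_matrix(
    genes: Sequence[str],
    tissues: Sequence[str] = DEFAULT_TISSUES,
    species: Sequence[str] = ("human",),
    noise: float = 0.3,
    n_background: int = 10000,
    background_exceedance: float = 0.02,
    background_cutoff: float = 0.2,
    seed: int = 0,
) -> ExpressionSim:
    """Log-normal tissue profiles shared across species plus independent
    per-species noise; with ``noise=0`` cross-species profiles are
    identical (Spearman 1). The intergenic background is exponential with
    scale set so that P(RPKM > cutoff) ~= ``background_exceedance``."""
    if not genes or not tissues:
        raise ValueError("need at least one gene and one tissue")
    rng = np.random.default_rng(seed)
    # de novo genes are lowly expressed: median ~1.2 RPKM, clearly above
    # the 0.5 call cutoff in some tissue but far below abundant mRNAs
    shared = rng.normal(loc=math.log(1.2), scale=0.8,
                        size=(len(genes), len(tissues)))
    matrices = {}
    for sp in species:
        log_m = shared + noise * rng.normal(size=shared.shape)
        matrices[sp] = pd.DataFrame(
            np.exp(log_m), index=list(genes), columns=list(tissues)
        )
    scale = background_cutoff / -math.log(background_exceedance)
    background = {
        t: rng.exponential(scale, size=n_background) for t in tissues
    }
    return ExpressionSim(matrices=matrices, background=background)


# ---------------------------------------------------------------------------
# The full fixture bundle
# ---------------------------------------------------------------------------

GENE_ROLES = ("de_novo", "dying", "control")


def make_selection_panel(
    seed: int,
    gamma: float = -10.0,
    n: int = 134,
    cds_codons: int = 1600,
    intron_bp: int = 6000,
    density: float = 0.35,
    cds: CodingSequence | None = None,
) -> tuple[VariantSet, RegionAnnotation, CodingSequence]:
    """One polymorphism panel on a long synthetic locus.

    ``n=134`` chromosomes emulates 67 diploid individuals; ``gamma`` is
    applied to nonsynonymous sites only (synonymous and intronic sites
    are neutral). Neutral per-class site budgets are ``density`` times
    the NG86 site counts of the CDS (so exon and intron budgets are
    length-proportional and the neutral exon/intron split matches the
    Monte Carlo null)."""
    from .ortholog_assessment import _ng86_site_counts

    rng = np.random.default_rng(seed)
    if cds is None:
        cds = generate_coding_sequence(
            SequenceSimConfig(length=3 * cds_codons, gc_target=0.55,
                              ensure_orf=True, seed=int(rng.integers(2**31))),
            gene_id="panel_locus",
        )
    cds_len = len(cds.seq)
    region = RegionAnnotation(
        gene_id="panel_locus",
        intervals={
            "CDS": [GenomicInterval("chrSim", 1000, 1000 + cds_len)],
            "intron": [
                GenomicInterval("chrSim", 2000 + cds_len,
                                2000 + cds_len + intron_bp)
            ],
        },
        frame_anchor=1000,
    )
    s_sites = n_sites = 0.0
    for codon in cds.sense_codons():
        s, nn = _ng86_site_counts(codon, STANDARD_TABLE)
        s_sites += s
        n_sites += nn
    cfg = SelectionConfig(
        n=n,
        sites={
            "nonsynonymous": int(round(density * n_sites)),
            "synonymous": int(round(density * s_sites)),
            "intron": int(round(density * intron_bp)),
        },
        gamma={"nonsynonymous": gamma},
        cds=cds,
        seed=int(rng.integers(2**31)),
    )
    return simulate_polymorphism(region, cfg), region, cds


@dataclass
class FixtureBundle:
    out_dir: Path
    roles: dict[str, str]  # gene_id -> role
    human_cds: dict[str, CodingSequence]
    alignments: dict[str, dict[str, CodonAlignment]]  # gene -> species -> aln
    expression: ExpressionSim
    panels: dict[str, VariantSet]  # "human_like", "macaque_like"
    panel_regions: dict[str, RegionAnnotation]
    panel_cds: dict[str, CodingSequence]
    manifest: dict[str, str]  # relative path -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_bundle(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_per_role: int = 3,
    orf_codons: int = 150,
    gc_de_novo: float = 0.6,
    panel_cds_codons: int = 1600,
    panel_intron_bp: int = 6000,
    panel_density: float = 0.35,
    panel_n: int = 134,
    panel_gamma: float = -10.0,
    with_panels: bool = True,
    write: bool = True,
) -> FixtureBundle:
    """Generate the complete seeded fixture set.

    Three gene roles: de-novo-like (human-intact GC-rich ORF with a shared
    ancestral disabler in the outgroups), dying-gene decoys (independent
    disablers at different positions), and deeply conserved controls (ORF
    intact everywhere). Two polymorphism panels on a long synthetic locus:
    human-like (purifying selection, gamma on nonsynonymous sites) and
    macaque-like (fully neutral)."""
    root = np.random.default_rng(seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    tips = DEFAULT_SPECIES
    outgroups = tuple(sp for sp in tips if sp != "human")

    roles: dict[str, str] = {}
    human_cds: dict[str, CodingSequence] = {}
    alignments: dict[str, dict[str, CodonAlignment]] = {}
    lo, hi = int(orf_codons * 0.35), int(orf_codons * 0.65)

    gene_idx = 0
    for role in GENE_ROLES:
        for _ in range(n_per_role):
            gene_idx += 1
            gene_id = f"{role}_{gene_idx}"
            gene_seed = int(root.integers(2**31))
            rng = np.random.default_rng(gene_seed)
            gc = gc_de_novo if role != "control" else 0.55
            ancestor = generate_sequence(
                SequenceSimConfig(
                    length=3 * orf_codons, gc_target=gc, ensure_orf=True,
                    seed=int(rng.integers(2**31)),
                )
            )
            if role == "de_novo":
                disablers = (
                    DisablerSpec(
                        clade=outgroups,
                        codon_position=int(rng.integers(lo, hi)),
                        kind="premature_stop" if rng.random() < 0.5
                        else "frameshift_indel",
                    ),
                )
            elif role == "dying":
                positions = rng.choice(
                    np.arange(lo, hi), size=len(outgroups), replace=False
                )
                disablers = tuple(
                    DisablerSpec(clade=(sp,), codon_position=int(p),
                                 kind="premature_stop")
                    for sp, p in zip(outgroups, positions)
                )
            else:
                disablers = ()
            sim = evolve_orthologs(
                ancestor,
                TreeSimConfig(
                    disablers=disablers,
                    reject_stops_everywhere=(role == "control"),
                    seed=int(rng.integers(2**31)),
                ),
            )
            human_seq = sim.sequences["human"]
            roles[gene_id] = role
            human_cds[gene_id] = CodingSequence(
                gene_id, "human", human_seq, includes_terminal_stop=True
            )
            for aln in sim.alignments.values():
                aln.gene_id = gene_id
            alignments[gene_id] = sim.alignments

    expression = generate_expression_matrix(
        genes=list(roles), species=("human", "chimp", "macaque"),
        seed=int(root.integers(2**31)),
    )

    # Polymorphism panels on a dedicated long locus.
    panels: dict[str, VariantSet] = {}
    panel_regions: dict[str, RegionAnnotation] = {}
    panel_cds: dict[str, CodingSequence] = {}
    if with_panels:
        panel_cds_seq = generate_coding_sequence(
            SequenceSimConfig(length=3 * panel_cds_codons, gc_target=0.55,
                              ensure_orf=True, seed=int(root.integers(2**31))),
            gene_id="panel_locus",
        )
        for name, gamma in (("human_like", panel_gamma), ("macaque_like", 0.0)):
            vs, region, _ = make_selection_panel(
                seed=int(root.integers(2**31)),
                gamma=gamma,
                n=panel_n,
                intron_bp=panel_intron_bp,
                density=panel_density,
                cds=panel_cds_seq,
            )
            panels[name] = vs
            panel_regions[name] = region
            panel_cds[name] = panel_cds_seq

    bundle = FixtureBundle(
        out_dir=out_dir if out_dir is not None else Path("."),
        roles=roles,
        human_cds=human_cds,
        alignments=alignments,
        expression=expression,
        panels=panels,
        panel_regions=panel_regions,
        panel_cds=panel_cds,
        manifest={},
    )
    if write and out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: FixtureBundle, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "alignments").mkdir(parents=True, exist_ok=True)
    write_fasta(
        {gid: cds.seq for gid, cds in bundle.human_cds.items()},
        out_dir / "human_orfs.fasta",
    )
    (out_dir / "tree.nwk").write_text(DEFAULT_TREE + "\n")
    for gid, alns in bundle.alignments.items():
        for species, aln in alns.items():
            aln.to_tsv(out_dir / "alignments" / f"{gid}.{species}.tsv")
    rows = []
    library_size = 10_000_000
    region_length = 1000
    for sp, matrix in bundle.expression.matrices.items():
        for gid in matrix.index:
            for tissue in matrix.columns:
                count = int(round(
                    matrix.loc[gid, tissue] * library_size * region_length / 1e9
                ))
                rows.append((f"{sp}:{gid}", tissue, count, region_length,
                             library_size))
    pd.DataFrame(
        rows,
        columns=["region_id", "tissue", "read_count", "region_length",
                 "library_size"],
    ).to_csv(out_dir / "expression.tsv", sep="\t", index=False)
    bg_rows = [
        (tissue, f"{v:.6g}")
        for tissue, vals in bundle.expression.background.items()
        for v in vals[:2000]  # keep the on-disk sample modest
    ]
    pd.DataFrame(bg_rows, columns=["tissue", "rpkm"]).to_csv(
        out_dir / "background_rpkm.tsv", sep="\t", index=False
    )
    if bundle.panels:
        for name, vs in bundle.panels.items():
            write_variants(vs.variants, out_dir / f"{name}.vcf")
        region = next(iter(bundle.panel_regions.values()))
        with open(out_dir / "panel_regions.bed", "w") as fh:
            for cls, ivs in region.intervals.items():
                for iv in ivs:
                    fh.write(
                        f"{iv.contig}\t{iv.start}\t{iv.end}\t"
                        f"{region.gene_id}|{cls}\t0\t{iv.strand}\n"
                    )
        write_fasta(
            {"panel_locus": next(iter(bundle.panel_cds.values())).seq},
            out_dir / "panel_locus.fasta",
        )
    pd.DataFrame(
        [(gid, role) for gid, role in bundle.roles.items()],
        columns=["gene_id", "role"],
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)

    manifest = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out_dir))] = _sha256(path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle.manifest = manifest
    bundle.out_dir = out_dir
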