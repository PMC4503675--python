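"""Emergence stage: ORF presence in outgroups, shared ancestral disablers,
parsimony age assignment, and counting-based divergence dN/dS.

The decision logic follows the identification rule for hominoid-specific
de novo genes: an orthologous region in an outgroup species is scored
against the human ORF through a codon-level alignment; a premature stop
codon or a frame-disrupting indel is a *disruption*, and the ORF is
regarded as absent in that species when the longest intact stretch falls
below 70% of the human ORF length. A *common ancestral disabler* — the
same disruption at the same human-codon position in every ORF-absent
outgroup — marks the gene as newly originated (the disabler predates the
outgroup radiation and was resolved on the human lineage) rather than an
old gene dying independently in each outgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import FormatError, InsufficientEvidenceError
from .sequence_features import STANDARD_TABLE, STOP_CODONS, CodonTable

EVENTS = ("match", "substitution", "insertion", "deletion")

#: Species initials used in age-class labels.
SPECIES_INITIALS = {
    "human": "H",
    "chimp": "C",
    "gorilla": "G",
    "orangutan": "O",
}

#: Hominoid ladder, innermost first, used to name origin clades.
HOMINOID_LADDER = ("human", "chimp", "gorilla", "orangutan")


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRow:
    """One codon-level alignment event.

    ``query_index`` is the 0-based human codon index anchoring the event;
    insertion rows anchor at the codon before which the bases are
    inserted and may repeat an index. ``query_codon``/``subject`` hold the
    codon strings; for insertions ``subject`` is the inserted bases and
    ``query_codon`` is "-"; for deletions ``subject`` is the subject bases
    remaining at that codon ("-" when all three are deleted).
    """

    query_index: int
    query_codon: str
    subject: str
    event: str

    def __post_init__(self):
        if self.event not in EVENTS:
            raise ValueError(f"unknown alignment event {self.event!r}")
        if self.query_index < 0:
            raise ValueError("query_index must be non-negative")

    @property
    def indel_length(self) -> int | None:
        if self.event == "insertion":
            return len(self.subject.replace("-", ""))
        if self.event == "deletion":
            return 3 - len(self.subject.replace("-", ""))
        return None


@dataclass
class CodonAlignment:
    """Codon-level pairwise alignment of a reference CDS to an ortholog."""

    gene_id: str
    query_species: str
    subject_species: str
    rows: list[AlignmentRow]
    coverage: float | None = None
    identity: float | None = None

    def __post_init__(self):
        indices = [r.query_index for r in self.rows if r.event != "insertion"]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(
                f"{self.gene_id}: query codon indices not strictly increasing"
            )
        if self.coverage is None or self.identity is None:
            aligned = [r for r in self.rows if r.event in ("match", "substitution")]
            span = max(indices) + 1 if indices else 0
            if self.coverage is None:
                self.coverage = len(aligned) / span if span else 0.0
            if self.identity is None:
                self.identity = (
                    sum(1 for r in aligned if r.query_codon == r.subject) / len(aligned)
                    if aligned
                    else 0.0
                )

    # -- exchange format: TSV with one row per alignment event ------------
    TSV_HEADER = "query_codon_index\tquery_codon\tsubject_codon\tevent"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#gene_id={self.gene_id}\t"
                     f"query={self.query_species}\tsubject={self.subject_species}\n")
            fh.write(self.TSV_HEADER + "\n")
            for r in self.rows:
                fh.write(f"{r.query_index}\t{r.query_codon}\t{r.subject}\t{r.event}\n")

    @classmethod
    def from_tsv(cls, path) -> "CodonAlignment":
        gene_id = query = subject = None
        rows: list[AlignmentRow] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    meta = dict(
                        kv.split("=", 1) for kv in line[1:].split("\t") if "=" in kv
                    )
                    gene_id = meta.get("gene_id", gene_id)
                    query = meta.get("query", query)
                    subject = meta.get("subject", subject)
                    continue
                if line.startswith("query_codon_index"):
                    continue
                cols = line.split("\t")
                if len(cols) != 4:
                    raise FormatError(f"{path}: line {lineno}: expected 4 columns")
                try:
                    rows.append(
                        AlignmentRow(int(cols[0]), cols[1], cols[2], cols[3])
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if gene_id is None:
            raise FormatError(f"{path}: missing #gene_id metadata line")
        return cls(gene_id, query or "human", subject or "", rows)


# ---------------------------------------------------------------------------
# ORF status
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Disruption:
    kind: str  # premature_stop | frameshift_indel
    aligned_codon_position: int  # query (human) codon coordinate
    detail: str  # the stop codon, or the indel length

    def __post_init__(self):
        if self.kind not in ("premature_stop", "frameshift_indel"):
            raise ValueError(f"unknown disruption kind {self.kind!r}")


@dataclass
class OrfStatus:
    species: str
    present: bool
    disruptions: list[Disruption]
    max_intact_fraction: float


def filter_alignment_quality(
    aln: CodonAlignment, min_coverage: float = 0.7, min_identity: float = 0.5
) -> bool:
    """High-quality alignment gate: coverage and identity must *strictly*
    exceed their thresholds (boundary values fail)."""
    return aln.coverage > min_coverage and aln.identity > min_identity


def find_disruptions(aln: CodonAlignment,
                     table: CodonTable = STANDARD_TABLE) -> list[Disruption]:
    """Collect premature stops and frameshifting indels from an alignment."""
    out = []
    for row in aln.rows:
        if row.event in ("match", "substitution"):
            if row.subject in table.stops:
                out.append(
                    Disruption("premature_stop", row.query_index, row.subject)
                )
        else:
            length = row.indel_length
            if length and length % 3 != 0:
                out.append(
                    Disruption("frameshift_indel", row.query_index, str(length))
                )
    return out


def assess_orf(
    aln: CodonAlignment,
    query_len_codons: int,
    min_fraction: float = 0.7,
    table: CodonTable = STANDARD_TABLE,
) -> OrfStatus:
    """Decide whether the orthologous ORF exists in the subject species.

    The longest run of consecutive aligned query codons between
    disruptions (disrupted codons excluded), divided by the query ORF
    length, gives ``max_intact_fraction``; the ORF is present when there
    is no disruption or the fraction still reaches ``min_fraction``.
    """
    if query_len_codons <= 0:
        raise ValueError(f"query_len_codons must be positive, got {query_len_codons}")
    # Rows at or beyond the sense-codon count belong to the terminal stop
    # region and are not part of the ORF proper.
    disruptions = [
        d for d in find_disruptions(aln, table)
        if d.aligned_codon_position < query_len_codons
    ]
    broken = {d.aligned_codon_position for d in disruptions}
    aligned = sorted(
        {
            r.query_index
            for r in aln.rows
            if r.event in ("match", "substitution")
            and r.query_index < query_len_codons
        }
    )
    longest = run = 0
    prev = None
    for idx in aligned:
        if idx in broken:
            run = 0
        elif prev is not None and idx == prev + 1 and prev not in broken:
            run += 1
        else:
            run = 1
        longest = max(longest, run)
        prev = idx
    fraction = longest / query_len_codons
    present = (not disruptions) or fraction >= min_fraction
    return OrfStatus(
        species=aln.subject_species,
        present=present,
        disruptions=disruptions,
        max_intact_fraction=fraction,
    )


def detect_common_disablers(
    statuses: Mapping[str, OrfStatus], outgroups: Sequence[str]
) -> tuple[list[Disruption], bool]:
    """Shared ancestral disablers across ORF-absent outgroups.

    A disabler is *shared* when a disruption of identical kind and
    human-codon position occurs in every ORF-absent outgroup; the gene is
    flagged newly originated only when at least two outgroups are absent
    and share one (otherwise it is a candidate dying gene).
    """
    avail = [sp for sp in outgroups if sp in statuses]
    if len(avail) < 2:
        raise InsufficientEvidenceError(
            f"need >=2 outgroup ORF statuses, got {len(avail)}"
        )
    absent = [sp for sp in avail if not statuses[sp].present]
    if len(absent) < 2:
        return [], False
    keys_per_species = [
        {(d.kind, d.aligned_codon_position) for d in statuses[sp].disruptions}
        for sp in absent
    ]
    shared_keys = set.intersection(*keys_per_species)
    shared = [
        d
        for d in statuses[absent[0]].disruptions
        if (d.kind, d.aligned_codon_position) in shared_keys
    ]
    return shared, bool(shared)


# ---------------------------------------------------------------------------
# Parsimony age assignment
# ---------------------------------------------------------------------------

@dataclass
class AgeAssignment:
    gene_id: str
    origin_clade: list[str]
    age_label: str
    species_label: str
    inferred_losses: list[str]
    ambiguous: bool


def _load_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    t = dendropy.Tree.get(data=tree, schema="newick")
    t.is_rooted = True
    return t


def assign_age(
    presence: Mapping[str, bool],
    tree: str | dendropy.Tree,
    gene_id: str = "",
    query_species: str = "human",
) -> AgeAssignment:
    """Date ORF origin by Dollo parsimony (one gain, minimal losses).

    The origin clade is the most recent common ancestor of all
    ORF-present species; species inside it lacking the ORF are inferred
    losses. When an equally parsimonious multiple-independent-gain
    scenario has the same event count, the assignment is flagged
    ambiguous. Two labels are reported: the origin-clade label on the
    hominoid ladder, and the present-species list (e.g. "H-C-O" when the
    gorilla ORF is absent or unsampled).
    """
    if not presence.get(query_species, False):
        raise ValueError(f"query species {query_species!r} must be ORF-present")
    t = _load_tree(tree)
    taxa = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    unknown = set(presence) - taxa
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    present = sorted(sp for sp, p in presence.items() if p)
    mrca = t.mrca(taxon_labels=present)
    clade = sorted(leaf.taxon.label for leaf in mrca.leaf_iter())
    losses = sorted(
        sp for sp in clade if sp in presence and not presence[sp]
    )
    # Dollo cost: 1 gain + one loss per absent species in the clade. A
    # multiple-independent-gains scenario with no losses costs one event
    # per maximal fully-present clade; a tie (or cheaper) flags ambiguity.
    dollo_cost = 1 + len(losses)
    gains_cost = _min_independent_gains(t, set(present))
    ambiguous = bool(losses) and gains_cost <= dollo_cost

    age_label = _origin_clade_label(clade)
    species_label = _species_list_label(present)
    return AgeAssignment(
        gene_id=gene_id,
        origin_clade=clade,
        age_label=age_label,
        species_label=species_label,
        inferred_losses=losses,
        ambiguous=ambiguous,
    )


def _min_independent_gains(tree: dendropy.Tree, present: set[str]) -> int:
    """Number of maximal fully-present clades = minimal gains with no
    losses."""
    count = 0

    def mark(node, parent_full: bool):
        nonlocal count
        full = _is_full(node, present)
        if full and not parent_full:
            count += 1
            return
        if not node.is_leaf():
            for c in node.child_nodes():
                mark(c, full)

    mark(tree.seed_node, False)
    return count


def _is_full(node, present: set[str]) -> bool:
    return all(leaf.taxon.label in present for leaf in node.leaf_iter())


def _origin_clade_label(clade: Sequence[str]) -> str:
    ladder_species = [sp for sp in HOMINOID_LADDER if sp in clade]
    if set(clade) - set(HOMINOID_LADDER):
        return "pre-hominoid"
    return "-".join(SPECIES_INITIALS[sp] for sp in ladder_species)


def _species_list_label(present: Sequence[str]) -> str:
    if set(present) - set(HOMINOID_LADDER):
        return "pre-hominoid"
    return "-".join(
        SPECIES_INITIALS[sp] for sp in HOMINOID_LADDER if sp in present
    )


# ---------------------------------------------------------------------------
# Counting-based divergence dN/dS (NG86 with Jukes-Cantor correction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    n_sites: float
    s_sites: float
    defined: bool

    @property
    def ratio(self) -> float | None:
        return self.dn / self.ds if self.defined else None


def _ng86_site_counts(codon: str, table: CodonTable) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts of one codon.

    Changes creating a stop codon count as nonsynonymous (the convention
    of standard NG86 implementations)."""
    if codon in table.stops or "N" in codon or "-" in codon:
        return 0.0, 0.0
    aa = table.translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in table.stops and table.translate(alt) == aa:
                syn += 1.0
    syn_sites = syn / 3.0
    return syn_sites, 3.0 - syn_sites


def _ng86_diff_counts(codon1: str, codon2: str,
                      table: CodonTable) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between two
    codons (all orderings weighted equally; steps through stop codons are
    nonsynonymous)."""
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    paths = list(permutations(diff_pos))
    for path in paths:
        cur = codon1
        for pos in path:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            a1 = table.code.get(cur)
            a2 = table.code.get(nxt)
            if a1 == a2:
                syn += 1.0 / len(paths)
            else:
                nonsyn += 1.0 / len(paths)
            cur = nxt
    return syn, nonsyn


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def merged_dnds(
    alignments: Iterable[CodonAlignment], table: CodonTable = STANDARD_TABLE
) -> DnDsResult:
    """Pooled NG86 dN/dS over one or more codon alignments.

    Site and difference counts are summed across all aligned codon pairs
    of all genes, then each class is Jukes-Cantor corrected; pooling
    before correcting makes the estimate robust for short ORFs with few
    differences."""
    S_sites = N_sites = Sd = Nd = 0.0
    any_codon = False
    for aln in alignments:
        for row in aln.rows:
            if row.event not in ("match", "substitution"):
                continue
            q, s = row.query_codon, row.subject
            if len(q) != 3 or len(s) != 3 or "N" in q + s or "-" in q + s:
                continue
            if q in table.stops or s in table.stops:
                continue  # premature stops are disruptions, not divergence
            any_codon = True
            # NG86 averages site counts over the two sequences
            syn_q, nonsyn_q = _ng86_site_counts(q, table)
            syn_s, nonsyn_s = _ng86_site_counts(s, table)
            S_sites += (syn_q + syn_s) / 2.0
            N_sites += (nonsyn_q + nonsyn_s) / 2.0
            sd, nd = _ng86_diff_counts(q, s, table)
            Sd += sd
            Nd += nd
    if not any_codon:
        raise ValueError("no aligned codons in any alignment")
    ps = Sd / S_sites if S_sites else 0.0
    pn = Nd / N_sites if N_sites else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    defined = ds > 0 and math.isfinite(ds) and math.isfinite(dn)
    return DnDsResult(dn=dn, ds=ds, n_sites=N_sites, s_sites=S_sites,
                      defined=defined)
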