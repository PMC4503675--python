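"""Selection stage: diversity by region, site classification, πN/πS,
unfolded derived-allele spectra with bootstrap, and Monte Carlo regional
constraint tests.

The statistics here distinguish a constrained protein-coding locus from a
neutrally evolving non-coding ortholog: purifying selection depresses
diversity in exons relative to introns, depresses nonsynonymous relative
to synonymous diversity (πN/πS < 1), and skews the unfolded site
frequency spectrum toward rare derived alleles at nonsynonymous sites.
Sites on non-coding orthologs are classified into *pseudo*-synonymous and
*pseudo*-nonsynonymous classes by mapping them through a codon-level
alignment to the coding query, giving the neutral contrast panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedValueError
from .genome_io import RegionAnnotation, VariantRecord
from .ortholog_assessment import CodonAlignment, _ng86_site_counts
from .sequence_features import STANDARD_TABLE, CodingSequence, CodonTable

SITE_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "pseudo_synonymous",
    "pseudo_nonsynonymous",
    "noncoding",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteClassification:
    label: str
    nonsense: bool = False
    unclassifiable: bool = False

    def __post_init__(self):
        if not self.unclassifiable and self.label not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.label!r}")


def classify_site(
    variant: VariantRecord,
    region: RegionAnnotation,
    cds: CodingSequence | None,
    alignment: CodonAlignment | None = None,
    table: CodonTable = STANDARD_TABLE,
) -> SiteClassification:
    """Classify a variant as (pseudo-)synonymous/nonsynonymous/noncoding.

    With no alignment the variant lies on the coding sequence itself: the
    affected codon is located through the CDS intervals (strand-aware)
    and the alternate allele substituted. With an alignment the variant
    lies on a non-coding ortholog; its position is mapped through the
    alignment into the query reading frame and the *subject* codon is
    mutated, yielding the pseudo classes. Variants creating a stop codon
    are nonsynonymous with a nonsense sub-flag.
    """
    offset = region.cds_offset_of(variant.contig, variant.pos)
    if offset is None:
        return SiteClassification("noncoding")
    strand = region.cds_intervals()[0].strand
    ref = variant.ref if strand == "+" else _revcomp_base(variant.ref)
    alt = variant.alt if strand == "+" else _revcomp_base(variant.alt)

    if alignment is None:
        if cds is None:
            raise ValueError("cds required to classify a coding variant")
        codon_idx, within = divmod(offset, 3)
        codons = cds.codons()
        if codon_idx >= len(codons):
            return SiteClassification("noncoding", unclassifiable=True)
        codon = codons[codon_idx]
        prefix = ""
    else:
        located = _locate_in_subject(alignment, offset)
        if located is None:
            return SiteClassification("noncoding", unclassifiable=True)
        codon, within = located
        prefix = "pseudo_"

    if "N" in codon or "-" in codon or len(codon) != 3:
        return SiteClassification(prefix + "synonymous", unclassifiable=True)
    if codon[within] != ref:
        return SiteClassification(prefix + "synonymous", unclassifiable=True)
    mutant = codon[:within] + alt + codon[within + 1 :]
    if codon in table.stops:
        return SiteClassification(prefix + "synonymous", unclassifiable=True)
    if mutant in table.stops:
        return SiteClassification(prefix + "nonsynonymous", nonsense=True)
    label = "synonymous" if table.translate(codon) == table.translate(mutant) \
        else "nonsynonymous"
    return SiteClassification(prefix + label)


def _locate_in_subject(aln: CodonAlignment, offset: int) -> tuple[str, int] | None:
    """Map an offset within the subject's aligned (pseudo-CDS) sequence to
    the subject codon holding it and the within-codon position in the
    query reading frame. Bases inside insertions or partially deleted
    codons are unclassifiable (None)."""
    pos = 0
    for row in aln.rows:
        bases = row.subject.replace("-", "")
        if pos <= offset < pos + len(bases):
            if row.event in ("match", "substitution") and len(bases) == 3:
                return bases, offset - pos
            return None
        pos += len(bases)
    return None


# ---------------------------------------------------------------------------
# Variant sets
# ---------------------------------------------------------------------------

@dataclass
class VariantSet:
    """Biallelic variants plus their region/site-class annotations."""

    variants: list[VariantRecord]
    region_annotation: RegionAnnotation | None = None
    classifications: list[SiteClassification] | None = None

    def classify(
        self,
        cds: CodingSequence | None,
        alignment: CodonAlignment | None = None,
        table: CodonTable = STANDARD_TABLE,
    ) -> "VariantSet":
        if self.region_annotation is None:
            raise ValueError("region annotation required for classification")
        self.classifications = [
            classify_site(v, self.region_annotation, cds, alignment, table)
            for v in self.variants
        ]
        return self

    def region_class_of(self, variant: VariantRecord) -> str | None:
        if self.region_annotation is None:
            return None
        cls = self.region_annotation.class_of(variant.contig, variant.pos)
        return cls

    def subset_by_site_class(self, *labels: str) -> "VariantSet":
        if self.classifications is None:
            raise ValueError("classify() must run first")
        pairs = [
            (v, c)
            for v, c in zip(self.variants, self.classifications)
            if c.label in labels and not c.unclassifiable
        ]
        return VariantSet(
            variants=[v for v, _ in pairs],
            region_annotation=self.region_annotation,
            classifications=[c for _, c in pairs],
        )

    def subset_by_region_class(self, *classes: str) -> "VariantSet":
        keep = []
        for v in self.variants:
            cls = self.region_class_of(v)
            if cls in classes or (
                "exon" in classes and cls in ("CDS", "UTR")
            ):
                keep.append(v)
        return VariantSet(keep, self.region_annotation)

    def derived_counts(self) -> list[tuple[int, int]]:
        """(derived count, chromosomes) for polarizable segregating sites."""
        out = []
        for v in self.variants:
            i, n = v.derived_count, v.n_chromosomes
            if i is not None and 0 < i < n:
                out.append((i, n))
        return out

    @property
    def n_unpolarizable(self) -> int:
        return sum(1 for v in self.variants if v.derived_count is None)


# ---------------------------------------------------------------------------
# Diversity estimators
# ---------------------------------------------------------------------------

def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator."""
    return float(sum(1.0 / i for i in range(1, n)))


def site_heterozygosity(count: int, n: int) -> float:
    """Unbiased per-site heterozygosity 2p(1-p)n/(n-1)."""
    if n < 2:
        raise ValueError(f"need >=2 chromosomes, got {n}")
    p = count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def nucleotide_diversity(vs: VariantSet | Sequence[tuple[int, int]],
                         L: float) -> float:
    """Per-site nucleotide diversity π over ``L`` surveyed sites."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    if isinstance(vs, VariantSet):
        pairs = [(v.alt_count, v.n_chromosomes) for v in vs.variants]
    else:
        pairs = list(vs)
    return sum(site_heterozygosity(i, n) for i, n in pairs) / L


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's θ per site: S / (a_n · L)."""
    if n < 2:
        raise ValueError(f"need >=2 chromosomes, got {n}")
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    return S / (harmonic_number(n) * L)


@dataclass(frozen=True)
class DiversityEstimate:
    region_class: str
    pi: float
    theta_w: float
    S: int
    L: float
    n: int


def diversity_by_region(
    vs: VariantSet,
    classes: Sequence[str] = ("CDS", "UTR", "exon", "intron"),
    n: int | None = None,
) -> list[DiversityEstimate]:
    """Per-region π, θw, and segregating-site counts.

    ``n`` defaults to the maximum chromosome count observed; sites with
    missing genotypes contribute to π with their own site-specific n.
    """
    if vs.region_annotation is None:
        raise ValueError("region annotation required")
    if n is None:
        n = max((v.n_chromosomes for v in vs.variants), default=2)
    out = []
    for cls in classes:
        L = vs.region_annotation.region_length(cls)
        if L == 0:
            continue
        sub = vs.subset_by_region_class(cls)
        S = len(sub.variants)
        pi = nucleotide_diversity(sub, L) if S else 0.0
        out.append(
            DiversityEstimate(cls, pi, watterson_theta(S, n, L), S, L, n)
        )
    return out


def normalize_by_intron(estimates: Sequence[DiversityEstimate],
                        stat: str = "pi") -> dict[str, float]:
    """Divide each region's π (or θw) by the intronic value (intron -> 1)."""
    by_class = {e.region_class: getattr(e, stat) for e in estimates}
    if "intron" not in by_class:
        raise ValueError("intron estimate required for normalization")
    denom = by_class["intron"]
    if denom == 0:
        raise UndefinedValueError("intronic value is zero; normalization undefined")
    return {cls: val / denom for cls, val in by_class.items()}


# ---------------------------------------------------------------------------
# πN/πS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PnPsResult:
    pi_n: float
    pi_s: float
    n_sites: float
    s_sites: float
    defined: bool

    @property
    def ratio(self) -> float | None:
        return self.pi_n / self.pi_s if self.defined else None


def pn_ps_ratio(vs: VariantSet, cds: CodingSequence,
                table: CodonTable = STANDARD_TABLE) -> PnPsResult:
    """πN/πS with NG86 fractional site-count denominators from the CDS.

    The site-count normalization makes the neutral expectation of the
    ratio 1. Pseudo-classified variants (non-coding orthologs) use the
    same query CDS for denominators. A πS of zero flags the ratio
    undefined rather than raising."""
    if vs.classifications is None:
        raise ValueError("classify() must run before pn_ps_ratio")
    s_sites = n_sites = 0.0
    for codon in cds.sense_codons():
        s, n = _ng86_site_counts(codon, table)
        s_sites += s
        n_sites += n
    if s_sites == 0 or n_sites == 0:
        raise UndefinedValueError("CDS has no countable sites")
    syn = vs.subset_by_site_class("synonymous", "pseudo_synonymous")
    nonsyn = vs.subset_by_site_class("nonsynonymous", "pseudo_nonsynonymous")
    pi_s = nucleotide_diversity(syn, s_sites) if syn.variants else 0.0
    pi_n = nucleotide_diversity(nonsyn, n_sites) if nonsyn.variants else 0.0
    return PnPsResult(pi_n=pi_n, pi_s=pi_s, n_sites=n_sites, s_sites=s_sites,
                      defined=pi_s > 0)


# ---------------------------------------------------------------------------
# Unfolded derived-allele frequency spectra
# ---------------------------------------------------------------------------

@dataclass
class SfsSpectrum:
    """Unfolded SFS over derived counts 1..n-1 with bootstrap CIs."""

    n: int
    counts: np.ndarray  # contribution per derived count (may be fractional)
    proportions: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_sites: int
    n_unpolarizable: int = 0
    B: int = 1000

    @property
    def singleton_proportion(self) -> float:
        return float(self.proportions[0])


def _projection_vector(i: int, n_i: int, n: int) -> np.ndarray | None:
    """Expected spectrum contribution of a site with i derived of n_i
    chromosomes after hypergeometric downsampling to n chromosomes; mass
    projected to monomorphic classes (0 or n derived) is discarded."""
    if n_i == n:
        vec = np.zeros(n - 1)
        vec[i - 1] = 1.0
        return vec
    if n_i < n:
        return None  # cannot project up
    j = np.arange(1, n)
    return stats.hypergeom.pmf(j, n_i, i, n)


def daf_spectrum(
    vs: VariantSet | Sequence[tuple[int, int]],
    n: int | None = None,
    bins: int | None = None,
    B: int = 1000,
    seed: int | None = None,
) -> SfsSpectrum:
    """Unfolded derived-allele frequency spectrum, pooled over sites.

    Only polarizable segregating sites enter; unpolarizable sites are
    excluded and counted. Sites with more chromosomes than ``n`` are
    projected down hypergeometrically; sites with fewer are skipped.
    Confidence intervals come from ``B`` bootstrap resamples of sites
    (2.5/97.5 percentiles) and the per-bin standard deviation is reported.
    """
    if isinstance(vs, VariantSet):
        pairs = vs.derived_counts()
        n_unpolar = vs.n_unpolarizable
    else:
        pairs = [(i, m) for i, m in vs if 0 < i < m]
        n_unpolar = 0
    if not pairs:
        raise UndefinedValueError("no polarizable segregating sites")
    if n is None:
        n = max(m for _, m in pairs)
    vectors = []
    for i, m in pairs:
        vec = _projection_vector(i, m, n)
        if vec is not None:
            vectors.append(vec)
    if not vectors:
        raise UndefinedValueError(f"no sites projectable to n={n}")
    M = np.vstack(vectors)
    if bins is not None:
        edges = np.linspace(0.0, 1.0, bins + 1)
        freqs = np.arange(1, n) / n
        bin_idx = np.clip(np.digitize(freqs, edges) - 1, 0, bins - 1)
        Mb = np.zeros((M.shape[0], bins))
        for k in range(bins):
            Mb[:, k] = M[:, bin_idx == k].sum(axis=1)
        M = Mb
    counts = M.sum(axis=0)
    total = counts.sum()
    proportions = counts / total

    rng = np.random.default_rng(seed)
    S = M.shape[0]
    weights = rng.multinomial(S, np.full(S, 1.0 / S), size=B).astype(float)
    boot = weights @ M
    boot_tot = boot.sum(axis=1, keepdims=True)
    boot_tot[boot_tot == 0] = 1.0
    boot_prop = boot / boot_tot
    return SfsSpectrum(
        n=n,
        counts=counts,
        proportions=proportions,
        sd=boot_prop.std(axis=0),
        ci_low=np.percentile(boot_prop, 2.5, axis=0),
        ci_high=np.percentile(boot_prop, 97.5, axis=0),
        n_sites=S,
        n_unpolarizable=n_unpolar,
        B=B,
    )


def neutral_sfs_expectation(n: int) -> np.ndarray:
    """Neutral unfolded SFS proportions: P(i) ∝ 1/i for i = 1..n-1."""
    i = np.arange(1, n)
    w = 1.0 / i
    return w / w.sum()


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RareExcessResult:
    p_value: float
    rare_a: float
    total_a: float
    rare_b: float
    total_b: float


def excess_rare_test(spec_a: SfsSpectrum, spec_b: SfsSpectrum,
                     bin_index: int = 0) -> RareExcessResult:
    """One-sided two-proportion z-test for an excess of lowest-frequency
    variants in spectrum ``a`` relative to spectrum ``b``."""
    if spec_a.n != spec_b.n or len(spec_a.counts) != len(spec_b.counts):
        raise ValueError("spectra must share n and binning")
    ka, na = spec_a.counts[bin_index], spec_a.counts.sum()
    kb, nb = spec_b.counts[bin_index], spec_b.counts.sum()
    if ka == 0 and kb == 0:
        raise UndefinedValueError("lowest-frequency bin empty in both spectra")
    pa, pb = ka / na, kb / nb
    pool = (ka + kb) / (na + nb)
    se = math.sqrt(pool * (1.0 - pool) * (1.0 / na + 1.0 / nb))
    if se == 0:
        return RareExcessResult(0.5, ka, na, kb, nb)
    z = (pa - pb) / se
    return RareExcessResult(float(stats.norm.sf(z)), ka, na, kb, nb)


@dataclass(frozen=True)
class McTestResult:
    p_value: float
    observed_exonic: int
    k_total: int
    p_exon: float
    n_sims: int


def exon_intron_mc_test(
    vs: VariantSet,
    region: RegionAnnotation | None = None,
    n_sims: int = 10000,
    seed: int | None = None,
) -> McTestResult:
    """Monte Carlo test for an exonic deficit of variants.

    Null: each of the k exonic+intronic variants falls in the exon with
    probability exon_len/(exon_len+intron_len), independently. The
    one-sided p is the fraction of simulations with a simulated exonic
    count at or below the observed one, with a +1 pseudo-count so p is
    never zero."""
    region = region or vs.region_annotation
    if region is None:
        raise ValueError("region annotation required")
    exon_len = region.region_length("exon")
    intron_len = region.region_length("intron")
    if exon_len == 0 or intron_len == 0:
        raise ValueError("exon and intron lengths must both be positive")
    observed = len(vs.subset_by_region_class("exon").variants)
    k = observed + len(vs.subset_by_region_class("intron").variants)
    if k < 1:
        raise ValueError("no exonic or intronic variants")
    p_exon = exon_len / (exon_len + intron_len)
    rng = np.random.default_rng(seed)
    sims = rng.binomial(k, p_exon, size=n_sims)
    p = (int(np.sum(sims <= observed)) + 1) / (n_sims + 1)
    return McTestResult(p, observed, k, p_exon, n_sims)
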