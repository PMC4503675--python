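"""Expression evidence: RPKM, empirical intergenic backgrounds, relative
expression versus flanking regions, junction support, and cross-tissue
profile correlation.

Transcription calls are made against an empirical background: RPKM values
of 10,000 randomly selected intergenic regions define the null, and a
conservative cutoff (default 0.5 for calling a gene expressed, 0.2 for
calling an ortholog transcribed above background) separates signal from
transcriptional noise. Cutoff comparisons are strict (>): boundary ties
fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, UndefinedValueError

#: RPKM above which a human gene counts as expressed in a tissue.
GENE_RPKM_CUTOFF = 0.5
#: RPKM above which an ortholog counts as transcribed above background.
ORTHOLOG_RPKM_CUTOFF = 0.2


def rpkm(read_count: float, region_length: float, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0 or library_size <= 0:
        raise ValueError("region length and library size must be positive")
    return read_count * 1e9 / (library_size * region_length)


@dataclass(frozen=True)
class ExpressionRecord:
    region_id: str
    tissue: str
    read_count: int
    region_length: int
    library_size: int

    @property
    def rpkm(self) -> float:
        return rpkm(self.read_count, self.region_length, self.library_size)


def read_expression_table(path) -> list[ExpressionRecord]:
    """TSV columns: region_id, tissue, read_count, region_length,
    library_size."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "tissue", "read_count", "region_length", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        ExpressionRecord(
            str(r.region_id), str(r.tissue), int(r.read_count),
            int(r.region_length), int(r.library_size),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class BackgroundModel:
    """Empirical null of intergenic RPKM values for one tissue."""

    tissue: str
    intergenic_rpkms: np.ndarray

    def __post_init__(self):
        self.intergenic_rpkms = np.asarray(self.intergenic_rpkms, dtype=float)

    @property
    def sample_size(self) -> int:
        return len(self.intergenic_rpkms)


def background_p(model: BackgroundModel, value: float) -> float:
    """Empirical p of seeing an intergenic RPKM at least as large as
    ``value``, with a (k+1)/(N+1) pseudo-count so p is never zero."""
    N = model.sample_size
    if N == 0:
        raise UndefinedValueError("empty background model")
    k = int(np.sum(model.intergenic_rpkms >= value))
    return (k + 1) / (N + 1)


@dataclass(frozen=True)
class ExpressionCall:
    expressed: bool
    breadth: int
    top_tissue: str | None


def expression_filter(
    rpkms_by_tissue: Mapping[str, float], cutoff: float = GENE_RPKM_CUTOFF
) -> ExpressionCall:
    """Expressed iff the maximum RPKM strictly exceeds the cutoff; breadth
    counts tissues above it. Ortholog-transcription calls use
    ``cutoff=ORTHOLOG_RPKM_CUTOFF``."""
    if not rpkms_by_tissue:
        raise ValueError("at least one tissue required")
    top_tissue = max(rpkms_by_tissue, key=lambda t: rpkms_by_tissue[t])
    breadth = sum(1 for v in rpkms_by_tissue.values() if v > cutoff)
    return ExpressionCall(
        expressed=rpkms_by_tissue[top_tissue] > cutoff,
        breadth=breadth,
        top_tissue=top_tissue,
    )


def relative_expression(
    gene_rpkm: float, upstream_rpkm: float, downstream_rpkm: float
) -> float | None:
    """Genic RPKM normalized by genic + equal-length flanking RPKMs;
    None (undefined) when everything is zero."""
    if min(gene_rpkm, upstream_rpkm, downstream_rpkm) < 0:
        raise ValueError("RPKM values must be non-negative")
    total = gene_rpkm + upstream_rpkm + downstream_rpkm
    if total == 0:
        return None
    return gene_rpkm / total


def junction_support(read_counts: Sequence[int], min_reads: int = 1) -> float:
    """Fraction of splice junctions with at least ``min_reads`` supporting
    spliced reads."""
    if not read_counts:
        raise ValueError("at least one junction required")
    return sum(1 for c in read_counts if c >= min_reads) / len(read_counts)


def tissue_profile_correlation(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlation of tissue expression profiles.

    ``matrix`` is genes x tissues (RPKM); rows with a missing value in a
    compared pair are dropped for that pair. Constant columns yield NaN
    (undefined) for their pairs."""
    tissues = list(matrix.columns)
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(tissues) for b in tissues[i:]
        ]
    out = pd.DataFrame(np.nan, index=tissues, columns=tissues, dtype=float)
    for a, b in pairs:
        sub = matrix[[a]] if a == b else matrix[[a, b]]
        sub = sub.dropna()
        if len(sub) < min_genes:
            raise ValueError(
                f"fewer than {min_genes} genes shared between {a} and {b}"
            )
        xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
        if len(np.unique(xa)) == 1 or len(np.unique(xb)) == 1:
            rho = np.nan  # undefined for constant profiles
        elif a == b:
            rho = 1.0
        else:
            rho = stats.spearmanr(xa, xb).statistic
        out.loc[a, b] = out.loc[b, a] = rho
    return out
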