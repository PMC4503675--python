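"""Neutral-evolution simulation of ORF interruption and survival.

An ORF evolving without functional constraint is eventually destroyed by
a nonsense point mutation or a frameshifting indel. This module simulates
that process event-by-event, estimates the ORF half-life t1/2 (the time
by which half of the simulation replicates are interrupted), and converts
a half-life plus a lineage age T into the neutral survival probability

    p = lambda * exp(-lambda),   lambda = (1/2) ** (T / t1/2).

Rates default to 1.25 point substitutions and 0.1 indel events per site
per billion years. The simulation is event-driven: waiting times between
mutations are exponential with total rate L * (mu + nu), each event picks
a site uniformly, and the sequence is updated so the nonsense-mutation
hazard tracks the evolving composition. An interruption is declared when
any sense codon becomes a stop, or an indel of length not divisible by 3
lands in the ORF. Loss of the terminal stop codon does not count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequence_features import BASES, STOP_CODONS, CodingSequence

#: Censoring horizon in years; replicates with no interruption by then are
#: reported as censored (math.inf).
DEFAULT_HORIZON = 1e10

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class MutationModel:
    """Neutral mutation rates, per single site per year."""

    point_rate: float = 1.25e-9
    indel_rate: float = 0.1e-9
    transition_bias: float = 1.0
    indel_length_distribution: str = "fixed1"  # or "geometric3"

    def __post_init__(self):
        if self.point_rate < 0 or self.indel_rate < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.transition_bias < 0:
            raise ValueError("transition bias must be >= 0")
        if self.indel_length_distribution not in ("fixed1", "geometric3"):
            raise ValueError(
                f"unknown indel length distribution "
                f"{self.indel_length_distribution!r}"
            )


@dataclass
class LifespanEstimate:
    """Half-life of an ORF under neutral mutation, from replicates."""

    t_half: float | None
    n_replicates: int
    interruption_times: np.ndarray
    censored_fraction: float

    @property
    def defined(self) -> bool:
        return self.t_half is not None


@dataclass(frozen=True)
class SurvivalResult:
    """Evaluation of the neutral ORF survival formula."""

    T: float
    t_half: float
    lam: float
    p: float


def _substitute(rng: np.random.Generator, base: str, kappa: float) -> str:
    """Draw a substitute base; the transition gets weight kappa, each
    transversion weight 1."""
    others = [b for b in BASES if b != base]
    ts = _TRANSITIONS[base]
    weights = np.array([kappa if b == ts else 1.0 for b in others])
    total = weights.sum()
    if total == 0:
        raise ValueError("transition bias 0 with no transversions possible")
    return others[rng.choice(3, p=weights / total)]


def _indel_length(rng: np.random.Generator, model: MutationModel) -> int:
    if model.indel_length_distribution == "fixed1":
        return 1
    # geometric with mean 3
    return int(rng.geometric(1.0 / 3.0))


def simulate_interruption_time(
    cds: CodingSequence,
    model: MutationModel = MutationModel(),
    seed: int | np.random.Generator = 0,
    horizon: float = DEFAULT_HORIZON,
) -> float:
    """Time in years until the ORF is first interrupted; ``math.inf`` when
    censored at the horizon.

    The input must include its terminal stop codon; the whole sequence
    (terminal stop included) is an indel target, but only internal codons
    count as nonsense targets.
    """
    if not cds.includes_terminal_stop:
        raise ValueError(f"{cds.gene_id}: simulation requires the terminal stop")
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, (int, np.integer)):
        rng = np.random.default_rng(int(seed))
    else:
        raise TypeError(f"seed must be an int or Generator, got {type(seed)!r}")

    seq = list(cds.seq)
    mu, nu = model.point_rate, model.indel_rate
    if mu + nu == 0:
        return math.inf

    t = 0.0
    while True:
        L = len(seq)
        total_rate = L * (mu + nu)
        t += rng.exponential(1.0 / total_rate)
        if t > horizon:
            return math.inf
        if rng.random() < nu / (mu + nu):
            length = _indel_length(rng, model)
            if length % 3 != 0:
                return t  # frameshift
            _apply_inframe_indel(rng, seq, length)
            if _has_internal_stop(seq):
                return t
        else:
            site = int(rng.integers(L))
            seq[site] = _substitute(rng, seq[site], model.transition_bias)
            codon_idx = site // 3
            if codon_idx < len(seq) // 3 - 1:  # internal codon only
                codon = "".join(seq[codon_idx * 3 : codon_idx * 3 + 3])
                if codon in STOP_CODONS:
                    return t


def _apply_inframe_indel(rng: np.random.Generator, seq: list[str], length: int):
    """Apply an insertion or deletion whose length is a multiple of 3.

    Insertions draw bases from the current composition (the least-
    assumption choice); deletions are truncated at the sequence end.
    """
    pos = int(rng.integers(len(seq)))
    # keep frame: snap to a codon boundary
    pos -= pos % 3
    if rng.random() < 0.5:
        counts = np.array([seq.count(b) for b in BASES], dtype=float)
        probs = counts / counts.sum()
        insert = [BASES[rng.choice(4, p=probs)] for _ in range(length)]
        seq[pos:pos] = insert
    else:
        if len(seq) - length >= 6:  # keep at least start + stop codons
            del seq[pos : pos + length]


def _has_internal_stop(seq: list[str]) -> bool:
    s = "".join(seq)
    return any(
        s[i : i + 3] in STOP_CODONS for i in range(0, len(s) - 3, 3)
    )


def half_life(
    cds: CodingSequence,
    model: MutationModel = MutationModel(),
    n_replicates: int = 20000,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
) -> LifespanEstimate:
    """Estimate the ORF half-life from independent interruption replicates.

    t1/2 is the median interruption time; censored replicates count as
    later than the horizon, and when at least half are censored the
    half-life is undefined (flagged, not raised).
    """
    if n_replicates < 100:
        raise ValueError(f"n_replicates must be >= 100, got {n_replicates}")
    rng = np.random.default_rng(seed)
    times = np.array(
        [
            simulate_interruption_time(cds, model, rng, horizon)
            for _ in range(n_replicates)
        ]
    )
    censored = float(np.mean(np.isinf(times)))
    t_half = float(np.median(times)) if censored < 0.5 else None
    return LifespanEstimate(
        t_half=t_half,
        n_replicates=n_replicates,
        interruption_times=times,
        censored_fraction=censored,
    )


def survival_probability(T: float, t_half: float) -> SurvivalResult:
    """Neutral probability that an ORF of half-life ``t_half`` born at the
    lineage divergence ``T`` years ago is still intact:
    lambda = 0.5**(T/t_half), p = lambda*exp(-lambda)."""
    if t_half <= 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    if T < 0:
        raise ValueError(f"T must be non-negative, got {T}")
    lam = 0.5 ** (T / t_half)
    return SurvivalResult(T=T, t_half=t_half, lam=lam, p=lam * math.exp(-lam))


def analytic_first_event_half_life(cds: CodingSequence,
                                   model: MutationModel = MutationModel()) -> float:
    """First-event hazard approximation of the half-life: ln(2)/h with
    h = nu*L + (mu/3)*k, where k is the number of single-base changes that
    create a stop codon. Ignores sequence turnover, so it is exact only
    for the first event; used as an independent oracle on short ORFs."""
    from .sequence_features import stop_mutation_opportunities

    k = stop_mutation_opportunities(cds)
    h = model.indel_rate * len(cds.seq) + (model.point_rate / 3.0) * k
    if h == 0:
        return math.inf
    return math.log(2.0) / h
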