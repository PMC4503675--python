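"""Independent oracles used by the unit and acceptance tests.

These re-derive expected values through routes that share no code with
the implementation under test: matrix exponentials of a codon-level
continuous-time Markov chain for ORF interruption, a discrete-time
mutation simulator, and brute-force pairwise-difference counting for
diversity statistics.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

_SENSE = ["".join(c) for c in itertools.product(BASES, repeat=3)
          if "".join(c) not in STOPS]
_IDX = {c: i for i, c in enumerate(_SENSE)}


def _killed_generator(mu: float) -> np.ndarray:
    """CTMC generator over sense codons where substitution into a stop
    codon kills the chain (probability mass leaves the state space)."""
    n = len(_SENSE)
    Q = np.zeros((n, n))
    for c in _SENSE:
        i = _IDX[c]
        for pos in range(3):
            for b in BASES:
                if b == c[pos]:
                    continue
                d = c[:pos] + b + c[pos + 1 :]
                rate = mu / 3.0
                Q[i, i] -= rate
                if d not in STOPS:
                    Q[i, _IDX[d]] += rate
    return Q


def ctmc_interruption_survival(seq: str, mu: float, nu: float, t: float) -> float:
    """Exact P(no interruption by time t) for an ORF under the neutral
    model with frameshifting single-base indels.

    Internal codons evolve as independent killed CTMCs (killing =
    nonsense creation); the indel hazard nu per site is constant because
    any indel interrupts. The terminal stop codon contributes only indel
    target size."""
    assert len(seq) % 3 == 0
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    internal = codons[:-1]
    Q = _killed_generator(mu)
    P = expm(Q * t)
    surv = math.exp(-nu * len(seq) * t)
    for c in internal:
        surv *= P[_IDX[c]].sum()
    return surv


def ctmc_median_interruption_time(seq: str, mu: float, nu: float) -> float:
    """Exact median interruption time from the CTMC survival function."""
    hi = 1e12
    return brentq(
        lambda t: ctmc_interruption_survival(seq, mu, nu, t) - 0.5, 1.0, hi
    )


def discrete_time_interruption_steps(
    seq: str, mu_step: float, nu_step: float, rng: np.random.Generator,
    max_steps: int = 1_000_000,
) -> float:
    """Straightforward per-step Bernoulli re-implementation of the
    interruption process (rates per site per step, scaled up)."""
    s = list(seq)
    L = len(s)
    n_codons = L // 3
    for step in range(1, max_steps + 1):
        u = rng.random(L)
        hits = np.nonzero(u < mu_step + nu_step)[0]
        for site in hits:
            if u[site] < nu_step:
                return float(step)  # single-base indel: frameshift
            base = s[site]
            s[site] = rng.choice([b for b in BASES if b != base])
            ci = site // 3
            if ci < n_codons - 1 and "".join(s[ci * 3 : ci * 3 + 3]) in STOPS:
                return float(step)
    return math.inf


def pairwise_diversity(haplotypes: list[str]) -> float:
    """Mean per-site pairwise difference count over all haplotype pairs."""
    n = len(haplotypes)
    L = len(haplotypes[0])
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(haplotypes[i], haplotypes[j]))
            pairs += 1
    return total / pairs / L


def watterson_direct(S: int, n: int, L: float) -> float:
    return S / (sum(1.0 / i for i in range(1, n)) * L)


def spearman_rank_formula(x, y) -> float:
    """Spearman rho via mid-ranks and the Pearson formula on ranks."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
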