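"""Distance and diversity statistics on aligned mtDNA populations.

Implements the classic toolkit this pipeline hangs together: Kimura
two-parameter distances with a site-bootstrap SE, Nei's average pairwise
differences within/between populations with permutation significance,
nucleotide and haplotype diversity, Arlequin-style distance-based pairwise
Φst with permutation tests, the haploid gene-flow transform Nm, and the
shared-haplotype ratio R_shr used as an index of recent human-mediated
introduction.

All sites carrying a gap or ambiguity code in either member of a pair are
excluded from that pair's comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientSampleError,
    SaturationError,
    UndefinedStatisticError,
)
from .seqio import AlignedSeqSet, HaplotypeTable, encode


# ---------------------------------------------------------------------------
# pairwise machinery

def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(n_comparable, n_transitions, n_transversions) for one pair."""
    comp = (a < 4) & (b < 4)
    diff = (a != b) & comp
    # with A,G coded even and C,T odd, a transition preserves parity
    ts = diff & ((a & 1) == (b & 1))
    return int(comp.sum()), int(ts.sum()), int(diff.sum() - ts.sum())


def k2p_pairwise(seq_a, seq_b) -> float:
    """Kimura two-parameter distance d = −½·ln[(1−2P−Q)·√(1−2Q)].

    P and Q are the transition and transversion proportions over sites
    comparable in both sequences.  Raises :class:`SaturationError` when the
    log argument is non-positive (divergence beyond the model's reach).
    """
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    nc, nts, ntv = _pair_counts(a, b)
    if nc == 0:
        raise SaturationError("no comparable sites")
    P, Q = nts / nc, ntv / nc
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined at P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _k2p_from_counts(nts, ntv, nc):
    with np.errstate(divide="ignore", invalid="ignore"):
        P, Q = nts / nc, ntv / nc
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        bad = (w1 <= 0) | (w2 <= 0) | (nc == 0)
        d = -0.5 * np.log(np.where(bad, np.nan, w1 * np.sqrt(np.where(w2 > 0, w2, np.nan))))
    return d, bad


def k2p_population(
    seqs: AlignedSeqSet,
    pop_a: str,
    pop_b: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean between-population K2P distance and its site-bootstrap SE.

    The mean runs over every between-population sequence pair; the SE is the
    standard deviation of that mean over ``n_boot`` replicates in which
    alignment columns are resampled with replacement.
    """
    X = seqs.encoded()
    ia, ib = seqs.indices_of(pop_a), seqs.indices_of(pop_b)
    L = X.shape[1]
    A, B = X[ia][:, None, :], X[ib][None, :, :]
    comp = (A < 4) & (B < 4)
    diff = (A != B) & comp
    ts = diff & ((A & 1) == (B & 1))
    npairs = len(ia) * len(ib)
    TS = ts.reshape(npairs, L).astype(np.float64)
    TV = (diff & ~ts).reshape(npairs, L).astype(np.float64)
    CM = comp.reshape(npairs, L).astype(np.float64)

    d_obs, bad = _k2p_from_counts(TS.sum(1), TV.sum(1), CM.sum(1))
    if bad.any():
        raise SaturationError("a sequence pair is saturated under K2P")
    mean = float(d_obs.mean())
    if n_boot <= 0:
        return mean, 0.0
    rng = np.random.default_rng(seed)
    # column multiplicities per replicate; counts then come from one matmul
    M = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(np.float64)
    d_rep, _ = _k2p_from_counts(TS @ M, TV @ M, CM @ M)
    means = np.nanmean(d_rep, axis=0)
    return mean, float(np.std(means, ddof=1))


def diff_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise count of differing comparable sites for every individual pair."""
    n = X.shape[0]
    comp = X < 4
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = ((X[i] != X) & comp[i] & comp).sum(axis=1)
        D[i, i] = 0.0
    return D


def nei_within(seqs: AlignedSeqSet, pop: str) -> float:
    """Nei's average number of pairwise differences within a population (K)."""
    idx = seqs.indices_of(pop)
    if len(idx) < 2:
        raise InsufficientSampleError(f"population {pop!r} has n < 2")
    X = seqs.encoded()[idx]
    D = diff_matrix(X)
    n = len(idx)
    return float(D[np.triu_indices(n, 1)].mean())


def nei_between(
    seqs: AlignedSeqSet,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
    corrected: bool = False,
) -> tuple[float, float]:
    """Nei's average pairwise differences between two populations with a permutation p.

    ``corrected=True`` reports net divergence d_xy − (K_x + K_y)/2; the default
    is the raw between-population mean.  The p-value is the fraction of
    individual-label permutations whose statistic is >= observed, with the
    (count+1)/(reps+1) estimator.
    """
    ia, ib = seqs.indices_of(pop_a), seqs.indices_of(pop_b)
    X = seqs.encoded()[ia + ib]
    D = diff_matrix(X)
    na = len(ia)

    def stat(order: np.ndarray) -> float:
        a, b = order[:na], order[na:]
        between = D[np.ix_(a, b)].mean()
        if not corrected:
            return float(between)
        ka = D[np.ix_(a, a)][np.triu_indices(len(a), 1)].mean() if len(a) > 1 else 0.0
        kb = D[np.ix_(b, b)][np.triu_indices(len(b), 1)].mean() if len(b) > 1 else 0.0
        return float(between - (ka + kb) / 2.0)

    order = np.arange(len(X))
    obs = stat(order)
    rng = np.random.default_rng(seed)
    hits = sum(stat(rng.permutation(order)) >= obs for _ in range(n_perm))
    return obs, (hits + 1) / (n_perm + 1)


def nucleotide_diversity(seqs: AlignedSeqSet, pop: str) -> float:
    """Per-site nucleotide diversity π = K / comparable length."""
    idx = seqs.indices_of(pop)
    if len(idx) < 2:
        raise InsufficientSampleError(f"population {pop!r} has n < 2")
    X = seqs.encoded()[idx]
    comparable = int((X < 4).all(axis=0).sum())
    if comparable == 0:
        raise UndefinedStatisticError("no comparable sites in population")
    return nei_within(seqs, pop) / comparable


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased haplotype diversity D_hap = n/(n−1) · (1 − Σ p_i²)."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2")
    p = np.asarray(counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def rshr(table: HaplotypeTable, pop: str) -> float:
    """Ratio of shared haplotypes: shared / total distinct haplotypes in ``pop``."""
    haps = table.haplotypes_of(pop)
    if not haps:
        raise InsufficientSampleError(f"population {pop!r} has no haplotypes")
    return sum(table.shared_flag(h) for h in haps) / len(haps)


# ---------------------------------------------------------------------------
# Φst / gene flow

def _phi_st_from_D(D: np.ndarray, parts: list[np.ndarray]) -> float:
    """One-level AMOVA Φst from a squared-distance matrix and index partition."""
    N = sum(len(p) for p in parts)
    P = len(parts)
    allidx = np.concatenate(parts)
    ssd_t = D[np.ix_(allidx, allidx)].sum() / (2.0 * N)
    ssd_wp = sum(D[np.ix_(p, p)].sum() / (2.0 * len(p)) for p in parts)
    vc = ssd_wp / (N - P)
    msd_a = (ssd_t - ssd_wp) / (P - 1)
    n_c = (N - sum(len(p) ** 2 for p in parts) / N) / (P - 1)
    va = (msd_a - vc) / n_c
    if va + vc == 0.0:
        raise UndefinedStatisticError("zero total variance; Fst undefined")
    return float(va / (va + vc))


def _binary_matrix(X: np.ndarray) -> np.ndarray:
    D = diff_matrix(X)
    return (D > 0).astype(float)


def pairwise_fst(
    seqs: AlignedSeqSet,
    pop_a: str,
    pop_b: str,
    mode: str = "differences",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Distance-based pairwise Φst between two populations with a permutation p-value.

    ``mode='differences'`` (default) uses the number of differing sites as the
    squared inter-individual distance, Arlequin's convention for sequence data;
    ``mode='binary'`` uses haplotype identity (0/1), giving a frequency-only
    Fst.  Negative estimates are reported as computed.
    """
    ia, ib = seqs.indices_of(pop_a), seqs.indices_of(pop_b)
    if len(ia) < 2 or len(ib) < 2:
        raise InsufficientSampleError("pairwise Fst needs n >= 2 in both populations")
    X = seqs.encoded()[ia + ib]
    D = diff_matrix(X) if mode == "differences" else _binary_matrix(X)
    na = len(ia)
    parts = [np.arange(na), np.arange(na, len(X))]
    obs = _phi_st_from_D(D, parts)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(X))
        try:
            f = _phi_st_from_D(D, [perm[:na], perm[na:]])
        except UndefinedStatisticError:
            continue
        if f >= obs:
            hits += 1
    return obs, (hits + 1) / (n_perm + 1)


def gene_flow(fst: float) -> float:
    """Haploid gene-flow estimate Nm = (1−Fst)/(2·Fst); +inf when Fst <= 0."""
    if math.isnan(fst):
        raise UndefinedStatisticError("Fst is undefined")
    if fst <= 0.0:
        return math.inf
    return (1.0 - fst) / (2.0 * fst)


# ---------------------------------------------------------------------------
# aggregate result

@dataclass
class DistanceResult:
    """Population-level distance matrices and per-population diversity indices."""

    labels: list[str]
    k2p: np.ndarray
    k2p_se: np.ndarray
    nei_between: np.ndarray
    nei_p: np.ndarray
    nei_within: np.ndarray
    fst: np.ndarray
    fst_p: np.ndarray
    nm: np.ndarray
    pi: np.ndarray
    dhap: np.ndarray
    rshr: np.ndarray
    n: np.ndarray = field(default=None)

    def matrix_tsv(self, name: str) -> str:
        M = getattr(self, name)
        lines = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            row = "\t".join("inf" if math.isinf(M[i, j]) else f"{M[i, j]:.6g}"
                            for j in range(len(self.labels)))
            lines.append(f"{lab}\t{row}")
        return "\n".join(lines) + "\n"

    def indices_tsv(self) -> str:
        lines = ["population\tn\trshr\tK\tpi\tdhap"]
        for i, lab in enumerate(self.labels):
            lines.append(
                f"{lab}\t{int(self.n[i])}\t{self.rshr[i]:.4f}\t"
                f"{self.nei_within[i]:.4f}\t{self.pi[i]:.5f}\t{self.dhap[i]:.4f}"
            )
        return "\n".join(lines) + "\n"


def distance_result(
    seqs: AlignedSeqSet,
    table: HaplotypeTable | None = None,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "differences",
) -> DistanceResult:
    """Compute the full population-level distance/diversity battery."""
    from .seqio import collapse_haplotypes

    if table is None:
        table = collapse_haplotypes(seqs)
    pops = list(seqs.populations)
    P = len(pops)
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(3 * P * (P - 1) // 2 + 1))
    k2p = np.zeros((P, P)); k2p_se = np.zeros((P, P))
    neib = np.zeros((P, P)); neip = np.ones((P, P))
    fst = np.zeros((P, P)); fstp = np.ones((P, P)); nm = np.full((P, P), math.inf)
    np.fill_diagonal(nm, 0.0)
    for i, j in combinations(range(P), 2):
        a, b = pops[i], pops[j]
        d, se = k2p_population(seqs, a, b, n_boot=n_boot,
                               seed=next(child).generate_state(1)[0] % (2**31))
        k2p[i, j] = k2p[j, i] = d
        k2p_se[i, j] = k2p_se[j, i] = se
        m, p = nei_between(seqs, a, b, n_perm=n_perm,
                           seed=next(child).generate_state(1)[0] % (2**31))
        neib[i, j] = neib[j, i] = m
        neip[i, j] = neip[j, i] = p
        try:
            f, p = pairwise_fst(seqs, a, b, mode=mode, n_perm=n_perm,
                                seed=next(child).generate_state(1)[0] % (2**31))
        except UndefinedStatisticError:
            f, p = math.nan, math.nan
        fst[i, j] = fst[j, i] = f
        fstp[i, j] = fstp[j, i] = p
        g = gene_flow(f) if not math.isnan(f) else math.nan
        nm[i, j] = nm[j, i] = g
    neiw = np.array([nei_within(seqs, p) for p in pops])
    pi = np.array([nucleotide_diversity(seqs, p) for p in pops])
    dhap = np.array([
        haplotype_diversity([table.counts[(p, h)] for h in table.haplotypes_of(p)
                             if (p, h) in table.counts])
        for p in pops
    ])
    rs = np.array([rshr(table, p) for p in pops])
    n = np.array([len(seqs.indices_of(p)) for p in pops])
    return DistanceResult(pops, k2p, k2p_se, neib, neip, neiw, fst, fstp, nm,
                          pi, dhap, rs, n)
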