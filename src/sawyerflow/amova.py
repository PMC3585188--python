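"""Hierarchical (three-level) analysis of molecular variance with permutation tests.

Partitions squared inter-individual molecular distances into among-group (Va),
among-population-within-group (Vb) and within-population (Vc) components and
the Φ-statistics F_CT = Va/V, F_SC = Vb/(Vb+Vc), F_ST = (Va+Vb)/V, following
the nested expectation equations of Excoffier, Smouse & Quattro (1992).  The
number of differing sites between two sequences is used directly as the
squared distance δ², Arlequin's convention for haplotypic sequence data; a
K2P (optionally gamma-corrected) distance mode is available for rate-variable
data.

A grouping-search utility ranks candidate covariate-based partitions of the
populations by (descending F_CT, ascending P), the criterion used to pick an
optimal grouping of demes by, e.g., regional freight-turnover bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, UndefinedStatisticError
from .popgen import diff_matrix
from .seqio import AlignedSeqSet


@dataclass(frozen=True)
class Grouping:
    """Assignment of every population to a higher-level group."""

    name: str
    assignment: dict[str, str]
    criterion: str = ""

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.assignment.values()))

    def members(self, group: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == group]


@dataclass
class AmovaResult:
    grouping: str
    va: float
    vb: float
    vc: float
    df: tuple[int, int, int]
    ssd: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float = math.nan
    p_sc: float = math.nan
    p_st: float = math.nan

    @property
    def total_variance(self) -> float:
        return self.va + self.vb + self.vc

    @property
    def percentages(self) -> tuple[float, float, float]:
        v = self.total_variance
        return (100.0 * self.va / v, 100.0 * self.vb / v, 100.0 * self.vc / v)

    @property
    def df_total(self) -> int:
        return sum(self.df)

    def to_tsv(self) -> str:
        pa, pb, pc = self.percentages
        rows = [
            ("Among groups", self.df[0], self.va, pa, f"F_CT = {self.f_ct:.4f}", self.p_ct),
            ("Among populations within groups", self.df[1], self.vb, pb,
             f"F_SC = {self.f_sc:.4f}", self.p_sc),
            ("Within populations", self.df[2], self.vc, pc,
             f"F_ST = {self.f_st:.4f}", self.p_st),
        ]
        lines = ["source\td.f.\tvariance\tpct\tF\tP"]
        for src, df, v, pct, fs, p in rows:
            lines.append(f"{src}\t{df}\t{v:.5f}\t{pct:.2f}\t{fs}\t{p:.4f}")
        lines.append(f"Total\t{self.df_total}\t{self.total_variance:.5f}\t-\t-\t-")
        return "\n".join(lines) + "\n"


def _k2p_matrix(X: np.ndarray, gamma_shape: float | None) -> np.ndarray:
    """Pairwise K2P (optionally gamma-corrected, Jin & Nei 1990) distances."""
    n, L = X.shape
    comp = X < 4
    D = np.zeros((n, n))
    for i in range(n):
        both = comp[i] & comp
        diff = (X[i] != X) & both
        ts = diff & ((X[i] & 1) == (X & 1))
        nc = both.sum(1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts.sum(1) / nc
            Q = (diff.sum(1) - ts.sum(1)) / nc
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if gamma_shape is None:
                d = -0.5 * np.log(w1 * np.sqrt(w2))
            else:
                a = gamma_shape
                d = a / 2 * (w1 ** (-1 / a) + 0.5 * w2 ** (-1 / a) - 1.5)
        D[i] = np.nan_to_num(d, nan=0.0)
        D[i, i] = 0.0
    return D


def _squared_distance_matrix(seqs: AlignedSeqSet, mode: str,
                             gamma_shape: float | None) -> np.ndarray:
    X = seqs.encoded()
    if mode == "differences":
        return diff_matrix(X)
    if mode == "k2p":
        return _k2p_matrix(X, gamma_shape)
    raise ConfigError(f"unknown AMOVA distance mode {mode!r}")


def _pair_sums(D: np.ndarray, pop_idx: list[np.ndarray]) -> np.ndarray:
    """S[p, q] = sum of δ² over ordered individual pairs of populations p, q."""
    P = len(pop_idx)
    S = np.zeros((P, P))
    for p in range(P):
        for q in range(p, P):
            s = D[np.ix_(pop_idx[p], pop_idx[q])].sum()
            S[p, q] = S[q, p] = s
    return S


def _components_from_sums(S: np.ndarray, sizes: np.ndarray,
                          group_of: np.ndarray, n_groups: int):
    """Variance components from the population-pair sum matrix.

    Returns (va, vb, vc, df, ssd).  All SSD terms are block sums over ordered
    pairs divided by twice the block size.
    """
    N = sizes.sum()
    P = len(sizes)
    G = n_groups
    ssd_t = S.sum() / (2.0 * N)
    ssd_wp = sum(S[p, p] / (2.0 * sizes[p]) for p in range(P))
    Ng = np.array([sizes[group_of == g].sum() for g in range(G)], dtype=float)
    ssd_wg = 0.0
    for g in range(G):
        mem = np.where(group_of == g)[0]
        ssd_wg += S[np.ix_(mem, mem)].sum() / (2.0 * Ng[g])
    ssd_ag = ssd_t - ssd_wg
    ssd_ap = ssd_wg - ssd_wp
    df = (G - 1, P - G, int(N - P))
    vc = ssd_wp / df[2] if df[2] > 0 else 0.0
    sum_n2_over_Ng = sum(sizes[p] ** 2 / Ng[group_of[p]] for p in range(P))
    sum_n2_over_N = (sizes.astype(float) ** 2).sum() / N
    if df[1] > 0:
        n_prime = (N - sum_n2_over_Ng) / df[1]
        vb = (ssd_ap / df[1] - vc) / n_prime
    else:
        vb = 0.0
    n_dprime = (sum_n2_over_Ng - sum_n2_over_N) / (G - 1)
    n_tprime = (N - (Ng**2).sum() / N) / (G - 1)
    va = (ssd_ag / (G - 1) - vc - n_dprime * vb) / n_tprime
    return va, vb, vc, df, (ssd_ag, ssd_ap, ssd_wp)


def _phis(va, vb, vc):
    v = va + vb + vc
    if v == 0.0:
        return math.nan, math.nan, math.nan
    f_ct = va / v
    f_sc = vb / (vb + vc) if (vb + vc) != 0.0 else math.nan
    f_st = (va + vb) / v
    return f_ct, f_sc, f_st


def amova3(
    seqs: AlignedSeqSet,
    grouping: Grouping,
    mode: str = "differences",
    gamma_shape: float | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA of individuals / populations / groups.

    Permutation p-values: ``p_ct`` permutes whole populations among groups
    (statistic F_CT), ``p_sc`` permutes individuals among populations within
    their group (F_SC), ``p_st`` permutes individuals among all populations
    (F_ST); each uses the (count+1)/(reps+1) estimator.  When all individuals
    are identical the variance components are zero and the Φ-statistics are
    reported as NaN.
    """
    pops = list(seqs.populations)
    missing = [p for p in pops if p not in grouping.assignment]
    if missing:
        raise ConfigError(f"grouping {grouping.name!r} misses populations {missing}")
    groups = grouping.groups
    if len(groups) < 2:
        raise UndefinedStatisticError("F_CT needs at least 2 groups")
    D = _squared_distance_matrix(seqs, mode, gamma_shape)
    pop_idx = [np.asarray(seqs.indices_of(p)) for p in pops]
    sizes = np.array([len(ix) for ix in pop_idx])
    group_of = np.array([groups.index(grouping.assignment[p]) for p in pops])
    S = _pair_sums(D, pop_idx)
    va, vb, vc, df, ssd = _components_from_sums(S, sizes, group_of, len(groups))
    f_ct, f_sc, f_st = _phis(va, vb, vc)
    result = AmovaResult(grouping.name, va, vb, vc, df, ssd, f_ct, f_sc, f_st)
    if n_perm <= 0 or math.isnan(f_ct):
        return result

    rng = np.random.default_rng(seed)

    # p_ct: shuffle populations among groups (group sizes in populations kept)
    hits_ct = 0
    for _ in range(n_perm):
        g_perm = rng.permutation(group_of)
        a, b, c, *_ = _components_from_sums(S, sizes, g_perm, len(groups))
        f, _, _ = _phis(a, b, c)
        if not math.isnan(f) and f >= f_ct:
            hits_ct += 1
    p_ct = (hits_ct + 1) / (n_perm + 1)

    # individual-level permutations recompute S from a relabelled membership
    Z = np.zeros((D.shape[0], len(pops)))
    for p, ix in enumerate(pop_idx):
        Z[ix, p] = 1.0
    within_group_pool = [np.concatenate([pop_idx[p] for p in np.where(group_of == g)[0]])
                        for g in range(len(groups))]

    hits_sc = hits_st = 0
    order = np.arange(D.shape[0])
    for _ in range(n_perm):
        # within groups: permute individuals among populations of the same group
        perm = order.copy()
        for pool in within_group_pool:
            perm[pool] = rng.permutation(pool)
        Sp = Z[perm].T @ D @ Z[perm]
        a, b, c, *_ = _components_from_sums(Sp, sizes, group_of, len(groups))
        _, f, _ = _phis(a, b, c)
        if not math.isnan(f) and f >= f_sc:
            hits_sc += 1
        # among all: permute individuals among all populations
        perm = rng.permutation(order)
        Sp = Z[perm].T @ D @ Z[perm]
        a, b, c, *_ = _components_from_sums(Sp, sizes, group_of, len(groups))
        _, _, f = _phis(a, b, c)
        if not math.isnan(f) and f >= f_st:
            hits_st += 1
    result.p_ct = p_ct
    result.p_sc = (hits_sc + 1) / (n_perm + 1)
    result.p_st = (hits_st + 1) / (n_perm + 1)
    return result


def grouping_search(
    seqs: AlignedSeqSet,
    candidates: Sequence[Grouping],
    n_perm: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> list[tuple[Grouping, AmovaResult]]:
    """Rank candidate groupings by (descending F_CT, ascending p_ct, input order)."""
    if not candidates:
        raise ConfigError("grouping_search needs at least one candidate")
    # one seed for every candidate: common permutations keep p_ct comparable
    # and make identical candidates exact ties (broken by input order)
    scored = []
    for i, g in enumerate(candidates):
        res = amova3(seqs, g, n_perm=n_perm, seed=seed, **kwargs)
        scored.append((i, g, res))
    scored.sort(key=lambda t: (-(t[2].f_ct if not math.isnan(t[2].f_ct) else -math.inf),
                               t[2].p_ct if not math.isnan(t[2].p_ct) else math.inf,
                               t[0]))
    return [(g, r) for _, g, r in scored]


def make_covariate_grouping(
    covariates,
    variable: str,
    thresholds: Sequence[float],
    name: str | None = None,
) -> Grouping:
    """Bin populations on a covariate: bin i is (t_{i-1}, t_i], lowest includes the minimum.

    ``covariates`` is a :class:`~sawyerflow.association.CovariateTable` or a
    DataFrame indexed by population with ``variable`` as a column.
    """
    df = getattr(covariates, "df", covariates)
    if variable not in df.columns:
        raise ConfigError(f"covariate {variable!r} not in table")
    th = list(thresholds)
    if any(b <= a for a, b in zip(th, th[1:])):
        raise ConfigError("thresholds must be strictly increasing")
    labels = []
    if th:
        labels = [f"<={th[0]:g}"] + [f"({a:g},{b:g}]" for a, b in zip(th, th[1:])] + [f">{th[-1]:g}"]
    else:
        labels = ["all"]
    assignment = {}
    for pop, val in df[variable].items():
        b = int(np.searchsorted(th, val, side="left"))
        assignment[pop] = labels[b]
    crit = f"{variable} bins at {th}" if th else f"{variable}: single bin"
    return Grouping(name or f"{variable}_bins", assignment, crit)
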