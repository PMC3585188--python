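"""Independent brute-force oracles used to cross-check the variance-component code.

Everything here is written directly from the definitional sums-of-squared-
distances arithmetic with explicit Python loops, deliberately sharing no code
with the package's vectorised implementations.
"""

from __future__ import annotations


def _d2(a: str, b: str) -> int:
    """Squared molecular distance: count of differing positions."""
    return sum(x != y for x, y in zip(a, b))


def phi_st_bruteforce(pop_a: list[str], pop_b: list[str]) -> float:
    """Two-population Φst from first principles (SSD partition, one level)."""
    pops = [pop_a, pop_b]
    seqs = pop_a + pop_b
    N = len(seqs)
    P = 2
    ssd_total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            ssd_total += _d2(seqs[i], seqs[j])
    ssd_total /= N
    ssd_within = 0.0
    for grp in pops:
        s = 0.0
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                s += _d2(grp[i], grp[j])
        ssd_within += s / len(grp)
    vc = ssd_within / (N - P)
    msd_among = (ssd_total - ssd_within) / (P - 1)
    n_c = (N - sum(len(g) ** 2 for g in pops) / N) / (P - 1)
    va = (msd_among - vc) / n_c
    if va + vc == 0.0:
        raise ZeroDivisionError("degenerate: no molecular variance")
    return va / (va + vc)


def amova3_bruteforce(groups: list[list[list[str]]]):
    """Three-level variance components from first principles.

    ``groups`` is a nested list: groups -> populations -> individual sequences.
    Returns (va, vb, vc).
    """
    seqs = [s for g in groups for p in g for s in p]
    N = len(seqs)
    G = len(groups)
    P = sum(len(g) for g in groups)

    def ssd(block: list[str]) -> float:
        s = 0.0
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                s += _d2(block[i], block[j])
        return s / len(block)

    ssd_t = ssd(seqs)
    ssd_wp = sum(ssd(p) for g in groups for p in g)
    ssd_wg = sum(ssd([s for p in g for s in p]) for g in groups)
    ssd_ag = ssd_t - ssd_wg
    ssd_ap = ssd_wg - ssd_wp

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    vc = ssd_wp / df_wp

    sizes = [[len(p) for p in g] for g in groups]
    Ng = [sum(sz) for sz in sizes]
    sum_n2_over_Ng = sum(n**2 / Ng[gi] for gi, sz in enumerate(sizes) for n in sz)
    sum_n2_over_N = sum(n**2 for sz in sizes for n in sz) / N

    if df_ap > 0:
        n1 = (N - sum_n2_over_Ng) / df_ap
        vb = (ssd_ap / df_ap - vc) / n1
    else:
        vb = 0.0
    n2 = (sum_n2_over_Ng - sum_n2_over_N) / df_ag
    n3 = (N - sum(x**2 for x in Ng) / N) / df_ag
    va = (ssd_ag / df_ag - vc - n2 * vb) / n3
    return va, vb, vc
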