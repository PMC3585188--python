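"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the published survey design — 14 demes of 10 haploid
individuals, ~1,200 bp of A+T-biased mitochondrial sequence, polymorphism
dominated by C–T and A–G transitions (class weights 40:20:5 with a minor A–T
transversion class) — and couples haplotype sharing to a covariate through a
*transport knob* m: with probability m an individual's haplotype is replaced
by one copied verbatim from a donor deme drawn proportionally to the donor's
coupling covariate (freight turnover by default).  Verbatim copying models
recent human-mediated movement of infested wood, which produces identical
haplotypes shared between distant demes.

Genealogies are per-deme Kingman coalescents (simulated with msprime) hanging
off a small shared ancestral haplotype pool; there is no recombination,
selection or spatial structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .association import CovariateTable
from .errors import ConfigError
from .seqio import AlignedSeqSet, write_fasta, write_popmap

# substitution classes as unordered base-code pairs (A,C,G,T = 0..3)
_CLASS_PAIRS = {"CT": (1, 3), "AG": (0, 2), "AT": (0, 3)}


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    ``theta`` is the expected within-deme mean pairwise difference count;
    ``stem_theta`` the expected mutations private to a deme's founder lineage
    (between-deme divergence); ``pool_theta`` the divergence among the shared
    ancestral pool haplotypes.  ``transport_m`` is the per-individual
    probability of carrying an imported haplotype.
    """

    n_demes: int = 14
    n_per_deme: int = 10
    seq_length: int = 1200
    at_fraction: float = 0.732
    class_weights: tuple[float, float, float] = (40.0, 20.0, 5.0)  # CT : AG : AT
    theta: float = 3.0
    stem_theta: float = 1.0
    pool_size: int = 8
    pool_theta: float = 1.5
    transport_m: float = 0.0
    coupling: str = "rft"
    coupling_exponent: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_demes, self.n_per_deme, self.seq_length, self.pool_size) < 1:
            raise ConfigError("counts and lengths must be positive")
        if not 0.0 < self.at_fraction < 1.0:
            raise ConfigError("at_fraction must lie in (0, 1)")
        if min(self.class_weights) < 0 or sum(self.class_weights) <= 0:
            raise ConfigError("class weights must be non-negative with positive sum")
        if not 0.0 <= self.transport_m <= 1.0:
            raise ConfigError("transport_m must lie in [0, 1]")
        if self.coupling_exponent < 0:
            raise ConfigError("coupling_exponent must be non-negative")
        if min(self.theta, self.stem_theta, self.pool_theta) < 0:
            raise ConfigError("theta parameters must be non-negative")


@dataclass
class SimTruth:
    """Generating ground truth backing an emitted dataset."""

    haplotype_of: dict[str, str]
    imported: list[tuple[str, str]]  # (individual-id, donor deme)
    founder_pool: dict[str, int]  # deme -> index of ancestral pool haplotype
    config: SimConfig

    def to_json(self) -> str:
        payload = {
            "haplotype_of": self.haplotype_of,
            "imported": self.imported,
            "founder_pool": self.founder_pool,
            "config": dataclasses.asdict(self.config),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _mutate(seq: np.ndarray, k: int, rng: np.random.Generator,
            weights: np.ndarray) -> None:
    """Apply k substitutions in place, class-toggling within base pairs."""
    classes = list(_CLASS_PAIRS.values())
    for _ in range(k):
        # draw classes by weight until one has an eligible site
        remaining = list(range(3))
        while remaining:
            w = weights[remaining] / weights[remaining].sum()
            ci = remaining[rng.choice(len(remaining), p=w)]
            a, b = classes[ci]
            sites = np.flatnonzero((seq == a) | (seq == b))
            if sites.size:
                s = sites[rng.integers(sites.size)]
                seq[s] = a + b - seq[s]
                break
            remaining.remove(ci)


def _deme_tree_sequences(founder: np.ndarray, n: int, theta: float,
                         rng: np.random.Generator, weights: np.ndarray,
                         ts_seed: int) -> list[np.ndarray]:
    """Evolve n leaf sequences down a Kingman coalescent rooted at the founder."""
    if n == 1:
        return [founder.copy()]
    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                              random_seed=ts_seed)
    tree = ts.first()
    node_seq: dict[int, np.ndarray] = {}
    root = tree.root
    node_seq[root] = founder.copy()
    for u in tree.nodes(root, order="preorder"):
        if u == root:
            continue
        s = node_seq[tree.parent(u)].copy()
        bl = tree.branch_length(u)
        _mutate(s, rng.poisson(theta / 2.0 * bl), rng, weights)
        node_seq[u] = s
    return [node_seq[u] for u in ts.samples()]


def _covariates(n_demes: int, pops: list[str], rng: np.random.Generator) -> CovariateTable:
    """Plausible provincial covariates: log-normal RFT/GDP, rank-linked binaries."""
    rft = rng.lognormal(mean=np.log(180.0), sigma=0.8, size=n_demes)
    gdp = rft * rng.lognormal(mean=np.log(3.0), sigma=0.4, size=n_demes)
    rank = np.argsort(np.argsort(gdp))
    port = (rank >= n_demes / 2).astype(int)
    flip = rng.random(n_demes) < 0.2
    port[flip] = 1 - port[flip]
    rank_r = np.argsort(np.argsort(rft))
    pwn = (rank_r >= n_demes / 2).astype(int)
    flip = rng.random(n_demes) < 0.2
    pwn[flip] = 1 - pwn[flip]
    df = pd.DataFrame(
        {"port": port, "pwn": pwn, "gdp": np.round(gdp, 2), "rft": np.round(rft, 2)},
        index=pd.Index(pops, name="population"),
    )
    return CovariateTable(df)


def simulate_dataset(config: SimConfig) -> tuple[AlignedSeqSet, CovariateTable, SimTruth]:
    """Generate one dataset; byte-identical outputs for equal seeds."""
    if config.seed is None:
        raise ConfigError("simulation requires an explicit seed")
    rng = np.random.default_rng(config.seed)
    weights = np.asarray(config.class_weights, dtype=float)
    weights = weights / weights.sum()
    pops = [f"d{i + 1:02d}" for i in range(config.n_demes)]

    cov = _covariates(config.n_demes, pops, rng)
    if config.transport_m > 0 and config.coupling not in cov.df.columns:
        raise ConfigError(f"coupling covariate {config.coupling!r} absent")

    at, gc = config.at_fraction / 2.0, (1.0 - config.at_fraction) / 2.0
    root = rng.choice(4, size=config.seq_length, p=[at, gc, gc, at]).astype(np.uint8)
    pool = []
    for _ in range(config.pool_size):
        s = root.copy()
        _mutate(s, rng.poisson(config.pool_theta), rng, weights)
        pool.append(s)

    founder_pool: dict[str, int] = {}
    deme_seqs: dict[str, list[np.ndarray]] = {}
    for pop in pops:
        k = int(rng.integers(config.pool_size))
        founder_pool[pop] = k
        founder = pool[k].copy()
        _mutate(founder, rng.poisson(config.stem_theta), rng, weights)
        ts_seed = int(rng.integers(1, 2**31 - 1))
        deme_seqs[pop] = _deme_tree_sequences(
            founder, config.n_per_deme, config.theta, rng, weights, ts_seed
        )

    # Transport: both sides of the exchange are covariate-graded.  A deme at
    # covariate rank u (in [0,1]) imports each individual with probability
    # m^(1 + k(1-u)) — every deme's probability is 0 at m=0 and 1 at m=1, but
    # high-covariate demes engage first as m grows — and donors are drawn with
    # probability proportional to their covariate.  Transport randomness lives
    # on its own substream with constant per-individual consumption, so equal
    # seeds share genealogies and the imported sets are nested across m.
    snapshot = {p: [s.copy() for s in deme_seqs[p]] for p in pops}
    w = cov.df[config.coupling].to_numpy(dtype=float)
    rank = np.argsort(np.argsort(w))
    u = rank / (len(w) - 1) if len(w) > 1 else np.ones(1)
    m = config.transport_m
    p_import = m ** (1.0 + config.coupling_exponent * (1.0 - u)) if m > 0 else np.zeros(len(w))
    trng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    imported: list[tuple[str, str]] = []
    records: list[tuple[str, str, str]] = []
    for pi, pop in enumerate(pops):
        others = [q for q in range(len(pops)) if q != pi]
        pw = w[others] / w[others].sum() if others else None
        for i in range(config.n_per_deme):
            ind = f"{pop}_i{i + 1:02d}"
            seq = deme_seqs[pop][i]
            take = trng.random()
            donor = others[trng.choice(len(others), p=pw)] if others else None
            src_i = int(trng.integers(config.n_per_deme))
            if m > 0 and donor is not None and take < p_import[pi]:
                dp = pops[donor]
                seq = snapshot[dp][src_i].copy()
                imported.append((ind, dp))
            records.append((ind, pop, "".join("ACGT"[b] for b in seq)))

    seqs = AlignedSeqSet(records, populations=pops)
    hap_of: dict[str, str] = {}
    seen: dict[str, str] = {}
    for ind, _, s in records:
        if s not in seen:
            seen[s] = f"H{len(seen) + 1}"
        hap_of[ind] = seen[s]
    truth = SimTruth(hap_of, imported, founder_pool, config)
    return seqs, cov, truth


def write_dataset(seqs: AlignedSeqSet, cov: CovariateTable, truth: SimTruth,
                  outdir: str | Path) -> dict[str, str]:
    """Emit FASTA + popmap TSV + covariate TSV + truth JSON; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "alignment.fasta"),
        "popmap": str(outdir / "popmap.tsv"),
        "covariates": str(outdir / "covariates.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_fasta(seqs, paths["fasta"])
    write_popmap(seqs, paths["popmap"])
    cov.to_tsv(paths["covariates"])
    Path(paths["truth"]).write_text(truth.to_json())
    return paths
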