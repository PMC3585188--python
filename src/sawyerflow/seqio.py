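"""Aligned-sequence input, numt screening, haplotype collapsing and variability summaries.

The unit of analysis is an alignment of equal-length mitochondrial sequences
(here: concatenated cox1+cox2 fragments) with every individual assigned to a
sampled population.  Individuals with byte-identical sequences constitute one
haplotype; a haplotype observed in two or more populations is *shared*,
otherwise *private*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlignmentError, PopmapError

IUPAC_CHARS = set("ACGTURYSWKMBDHVN-")

# integer codes used throughout the numeric layer
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_LUT = np.full(256, 5, dtype=np.uint8)  # 5 = ambiguity/unknown
for _c, _v in _CODE.items():
    _LUT[ord(_c)] = _v
    _LUT[ord(_c.lower())] = _v
_LUT[ord("u")] = _LUT[ord("U")] = 3


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A,C,G,T=0..3, gap=4, other=5)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignedSeqSet:
    """An alignment: per-individual (id, population, sequence) records of equal length."""

    records: list[tuple[str, str, str]]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty alignment")
        length = len(self.records[0][2])
        for ind, pop, seq in self.records:
            if len(seq) != length:
                raise AlignmentError(
                    f"record {ind!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq.upper()) - IUPAC_CHARS
            if bad:
                raise AlignmentError(f"record {ind!r} contains non-IUPAC characters {bad}")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise AlignmentError(f"duplicate individual ids: {dup}")
        seen: list[str] = []
        for _, pop, _ in self.records:
            if pop not in seen:
                seen.append(pop)
        if not self.populations:
            self.populations = seen
        elif set(self.populations) != set(seen):
            raise PopmapError(
                "population list does not match populations present in records"
            )
        self.records = [(i, p, s.upper()) for i, p, s in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][2])

    @property
    def n(self) -> int:
        return len(self.records)

    def pop_of(self) -> list[str]:
        return [p for _, p, _ in self.records]

    def indices_of(self, pop: str) -> list[int]:
        idx = [i for i, (_, p, _) in enumerate(self.records) if p == pop]
        if not idx:
            raise PopmapError(f"unknown population {pop!r}")
        return idx

    def sequences(self, pop: str | None = None) -> list[str]:
        if pop is None:
            return [s for _, _, s in self.records]
        return [self.records[i][2] for i in self.indices_of(pop)]

    def encoded(self) -> np.ndarray:
        """(n_individuals, length) uint8 matrix of the whole alignment."""
        return np.vstack([encode(s) for _, _, s in self.records])

    def subset(self, pops: Iterable[str]) -> "AlignedSeqSet":
        pops = list(pops)
        recs = [r for r in self.records if r[1] in set(pops)]
        return AlignedSeqSet(recs, populations=[p for p in pops])


@dataclass
class HaplotypeTable:
    """Distinct haplotypes, their per-population incidence and (optionally) counts.

    ``sequences`` may be ``None`` for tables reconstructed from published
    incidence listings, where the underlying sequences were never deposited
    at the individual level.
    """

    haplotypes: list[tuple[str, str | None]]
    incidence: dict[str, set[str]]
    populations: list[str]
    counts: dict[tuple[str, str], int] | None = None

    def __post_init__(self) -> None:
        seqs = [s for _, s in self.haplotypes if s is not None]
        if len(set(seqs)) != len(seqs):
            raise AlignmentError("haplotype sequences are not pairwise distinct")
        known = {h for h, _ in self.haplotypes}
        for h, pops in self.incidence.items():
            if h not in known:
                raise PopmapError(f"incidence refers to unknown haplotype {h!r}")
            if not set(pops) <= set(self.populations):
                raise PopmapError(f"haplotype {h!r} occurs in unlisted population")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def sequence_of(self, hap: str) -> str | None:
        return dict(self.haplotypes).get(hap)

    def shared_flag(self, hap: str) -> bool:
        return len(self.incidence[hap]) >= 2

    def haplotypes_of(self, pop: str) -> list[str]:
        if pop not in self.populations:
            raise PopmapError(f"unknown population {pop!r}")
        return [h for h, _ in self.haplotypes if pop in self.incidence[h]]

    def sample_size(self, pop: str) -> int:
        if self.counts is None:
            raise PopmapError("table carries no per-population counts")
        return sum(c for (p, _), c in self.counts.items() if p == pop)

    def to_tsv(self, path: str | Path) -> None:
        """Write the per-population incidence layout (population, haplotypes, shared, private)."""
        lines = ["population\thaplotypes\tshared\tprivate"]
        for pop in self.populations:
            haps = self.haplotypes_of(pop)
            ns, npv = classify_shared_private(self, pop)
            lines.append(f"{pop}\t{','.join(haps)}\t{ns}\t{npv}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeTable":
        pops: list[str] = []
        incidence: dict[str, set[str]] = {}
        order: list[str] = []
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            pop, haps, *_ = line.split("\t")
            pops.append(pop)
            for h in haps.split(","):
                h = h.strip()
                if not h:
                    continue
                if h not in incidence:
                    incidence[h] = set()
                    order.append(h)
                incidence[h].add(pop)
        return cls([(h, None) for h in order], incidence, pops)


@dataclass
class VariabilitySummary:
    n_sites: int
    n_polymorphic: int
    n_parsimony_informative: int
    substitution_counts: dict[str, int]
    nucleotide_composition: dict[str, float]

    @property
    def pct_polymorphic(self) -> float:
        return 100.0 * self.n_polymorphic / self.n_sites


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (individual-id, population-id); order preserved."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise PopmapError(f"{path}: line {ln} is not 2-column TSV")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_alignment(fasta_path: str | Path, popmap_path: str | Path) -> AlignedSeqSet:
    """Read an aligned multi-FASTA plus popmap into an :class:`AlignedSeqSet`.

    Population order follows first appearance in the popmap file; record order
    within the alignment is preserved.
    """
    popmap = read_popmap(popmap_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in popmap:
            raise PopmapError(f"individual {rec.id!r} missing from popmap")
        records.append((rec.id, popmap[rec.id], str(rec.seq)))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    pop_order = [p for p in dict.fromkeys(popmap.values()) if p in {r[1] for r in records}]
    return AlignedSeqSet(records, populations=pop_order)


def screen_numts(seqs: AlignedSeqSet, frame: int = 0, code_table: int = 5) -> list[str]:
    """Flag individuals whose conceptual translation betrays a nuclear pseudogene.

    A mitochondrial protein-coding fragment translated in the correct frame with
    the invertebrate mitochondrial code (NCBI table 5) must contain neither an
    internal stop codon nor an alignment indel; a hit on either is the classic
    signature of a numt co-amplification.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    flagged = []
    for ind, _, seq in seqs.records:
        if "-" in seq:
            flagged.append(ind)
            continue
        coding = seq[frame:]
        coding = coding[: len(coding) - len(coding) % 3]
        protein = str(Seq(coding).translate(table=code_table))
        if "*" in protein[:-1]:
            flagged.append(ind)
    return flagged


def collapse_haplotypes(seqs: AlignedSeqSet) -> HaplotypeTable:
    """Collapse identical sequences to haplotypes H1, H2, ... in first-appearance order.

    Identity is strict string equality: an N or ambiguity code is treated as a
    distinct state, never matched against a resolved base.  Numbering walks
    populations in popmap order and individuals in record order within each.
    """
    hap_of_seq: dict[str, str] = {}
    order: list[tuple[str, str]] = []
    incidence: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    for pop in seqs.populations:
        for i in seqs.indices_of(pop):
            _, _, s = seqs.records[i]
            hap = hap_of_seq.get(s)
            if hap is None:
                hap = f"H{len(order) + 1}"
                hap_of_seq[s] = hap
                order.append((hap, s))
                incidence[hap] = set()
            incidence[hap].add(pop)
            counts[(pop, hap)] = counts.get((pop, hap), 0) + 1
    return HaplotypeTable(order, incidence, list(seqs.populations), counts)


def classify_shared_private(table: HaplotypeTable, pop: str) -> tuple[int, int]:
    """Return (n_shared, n_private) distinct haplotypes observed in ``pop``."""
    haps = table.haplotypes_of(pop)
    n_shared = sum(1 for h in haps if table.shared_flag(h))
    return n_shared, len(haps) - n_shared


def variability_summary(seqs: AlignedSeqSet) -> VariabilitySummary:
    """Site-wise polymorphism, parsimony-informative and substitution-class tallies.

    Columns containing a gap in any individual are dropped outright (the data
    this models carries no indels); ambiguity codes are dropped per site.
    Substitution classes (CT / AG transitions, transversions) are tallied for
    two-state sites only — a triallelic site has no unique class.
    """
    if seqs.n < 2:
        raise AlignmentError("variability requires at least 2 sequences")
    X = seqs.encoded()
    gap_col = (X == 4).any(axis=0)
    n_poly = n_pi = 0
    classes = {"CT": 0, "AG": 0, "TV": 0}
    for j in np.where(~gap_col)[0]:
        col = X[:, j]
        col = col[col < 4]
        vals, cnts = np.unique(col, return_counts=True)
        if len(vals) < 2:
            continue
        n_poly += 1
        if (cnts >= 2).sum() >= 2:
            n_pi += 1
        if len(vals) == 2:
            pair = set(int(v) for v in vals)
            if pair == {1, 3}:
                classes["CT"] += 1
            elif pair == {0, 2}:
                classes["AG"] += 1
            else:
                classes["TV"] += 1
    base_counts = {b: int((X == c).sum()) for b, c in (("A", 0), ("C", 1), ("G", 2), ("T", 3))}
    tot = sum(base_counts.values())
    comp = {b: (c / tot if tot else 0.0) for b, c in base_counts.items()}
    return VariabilitySummary(
        n_sites=int((~gap_col).sum()),
        n_polymorphic=n_poly,
        n_parsimony_informative=n_pi,
        substitution_counts=classes,
        nucleotide_composition=comp,
    )


def write_fasta(seqs: AlignedSeqSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, _, s in seqs.records:
            fh.write(f">{ind}\n{s}\n")


def write_popmap(seqs: AlignedSeqSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, pop, _ in seqs.records:
            fh.write(f"{ind}\t{pop}\n")
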