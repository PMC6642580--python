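"""Genomes as signed gene orders, adjacencies, and DCJ operations.

A genome is a set of linear and circular chromosomes over signed genes.
Each gene has two extremities, a tail and a head; a chromosome induces
*internal* adjacencies (unordered pairs of extremities consecutive on a
chromosome) and, for linear chromosomes, two *external* adjacencies (a
single extremity at a chromosome end).  The double cut and join (DCJ)
operation cuts one or two adjacencies and rejoins the loose ends in one
of four ways.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "Extremity",
    "Adjacency",
    "Chromosome",
    "Genome",
    "DcjOperation",
    "adjacencies_of",
    "genome_from_adjacencies",
    "apply_dcj",
    "complete_gene_content",
    "parse_grimm",
    "read_grimm",
    "format_grimm",
    "write_grimm",
]

HEAD = "h"
TAIL = "t"


@dataclass(frozen=True, order=True)
class Extremity:
    """One end of a gene: its tail (t) or head (h)."""

    gene: int
    side: str

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL):
            raise ValueError(f"extremity side must be 'h' or 't', got {self.side!r}")
        if self.gene <= 0:
            raise ValueError("gene identifiers are positive integers")

    @property
    def other(self) -> "Extremity":
        return Extremity(self.gene, HEAD if self.side == TAIL else TAIL)

    def __str__(self) -> str:
        return f"{self.gene}{self.side}"

    @classmethod
    def parse(cls, text: str) -> "Extremity":
        m = re.fullmatch(r"(\d+)([ht])", text.strip())
        if not m:
            raise ValueError(f"cannot parse extremity {text!r}")
        return cls(int(m.group(1)), m.group(2))


def head(gene: int) -> Extremity:
    return Extremity(gene, HEAD)


def tail(gene: int) -> Extremity:
    return Extremity(gene, TAIL)


@dataclass(frozen=True, order=True)
class Adjacency:
    """An internal (two extremities) or external (one extremity) adjacency.

    Stored as a sorted tuple so adjacencies compare and hash as unordered
    pairs; ``{2h, 2t}`` and ``{2t, 2h}`` are the same adjacency.
    """

    ext: tuple[Extremity, ...]

    def __post_init__(self) -> None:
        if len(self.ext) not in (1, 2):
            raise ValueError("adjacency holds one or two extremities")
        object.__setattr__(self, "ext", tuple(sorted(self.ext)))

    @classmethod
    def internal(cls, a: Extremity, b: Extremity) -> "Adjacency":
        return cls((a, b))

    @classmethod
    def external(cls, a: Extremity) -> "Adjacency":
        return cls((a,))

    @property
    def is_external(self) -> bool:
        return len(self.ext) == 1

    @property
    def is_internal(self) -> bool:
        return len(self.ext) == 2

    def __str__(self) -> str:
        return "-".join(str(e) for e in self.ext) if self.is_internal else str(self.ext[0])

    @classmethod
    def parse(cls, text: str) -> "Adjacency":
        parts = [p for p in text.strip().split("-") if p and p != "o"]
        return cls(tuple(Extremity.parse(p) for p in parts))


@dataclass(frozen=True)
class Chromosome:
    """A signed gene order; ``circular`` toggles the closing adjacency."""

    genes: tuple[int, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if any(g == 0 for g in self.genes):
            raise ValueError("0 is not a valid signed gene")

    def __len__(self) -> int:
        return len(self.genes)


def _left_ext(g: int) -> Extremity:
    """Extremity met first when reading signed gene g left to right."""
    return tail(g) if g > 0 else head(-g)


def _right_ext(g: int) -> Extremity:
    return head(g) if g > 0 else tail(-g)


def _reverse(genes: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-g for g in reversed(genes))


def _canonical_chromosome(chrom: Chromosome) -> Chromosome:
    """Deterministic orientation (and rotation, for circular chromosomes)."""
    if not chrom.genes:
        return chrom

    def key(genes: tuple[int, ...]):
        return tuple((abs(g), g < 0) for g in genes)

    if not chrom.circular:
        fwd, rev = chrom.genes, _reverse(chrom.genes)
        return Chromosome(min(fwd, rev, key=key), False)
    candidates = []
    for genes in (chrom.genes, _reverse(chrom.genes)):
        for i in range(len(genes)):
            candidates.append(genes[i:] + genes[:i])
    return Chromosome(min(candidates, key=key), True)


@dataclass(frozen=True)
class Genome:
    chromosomes: tuple[Chromosome, ...] = ()
    name: str = ""

    @classmethod
    def from_orders(
        cls,
        *orders: Iterable[int],
        circular: bool | Iterable[bool] = False,
        name: str = "",
    ) -> "Genome":
        flags = list(circular) if not isinstance(circular, bool) else [circular] * len(orders)
        chroms = tuple(Chromosome(tuple(o), f) for o, f in zip(orders, flags))
        return cls(chroms, name)

    @property
    def gene_multiset(self) -> Counter:
        c: Counter = Counter()
        for chrom in self.chromosomes:
            c.update(abs(g) for g in chrom.genes)
        return c

    @property
    def n_genes(self) -> int:
        return sum(self.gene_multiset.values())

    def canonical(self) -> "Genome":
        chroms = sorted(
            (_canonical_chromosome(c) for c in self.chromosomes),
            key=lambda c: (not c.circular, tuple((abs(g), g < 0) for g in c.genes)),
        )
        return Genome(tuple(chroms), self.name)

    def same_as(self, other: "Genome") -> bool:
        """Equality up to chromosome order and traversal direction."""
        return self.canonical().chromosomes == other.canonical().chromosomes


def adjacencies_of(genome: Genome) -> Counter:
    """Multiset of internal and external adjacencies of a genome."""
    adjs: Counter = Counter()
    for chrom in genome.chromosomes:
        genes = chrom.genes
        if not genes:
            continue
        for g, g2 in zip(genes, genes[1:]):
            adjs[Adjacency.internal(_right_ext(g), _left_ext(g2))] += 1
        if chrom.circular:
            adjs[Adjacency.internal(_right_ext(genes[-1]), _left_ext(genes[0]))] += 1
        else:
            adjs[Adjacency.external(_left_ext(genes[0]))] += 1
            adjs[Adjacency.external(_right_ext(genes[-1]))] += 1
    return adjs


def _check_extremity_usage(adjs: Counter, genes: Counter) -> None:
    usage: Counter = Counter()
    for adj, mult in adjs.items():
        for e in adj.ext:
            usage[e] += mult
    expected: Counter = Counter()
    for g, copies in genes.items():
        expected[head(g)] = copies
        expected[tail(g)] = copies
    if usage != expected:
        off = {e: (usage[e], expected[e]) for e in set(usage) | set(expected) if usage[e] != expected[e]}
        raise ValueError(f"adjacencies do not use each extremity exactly once per gene copy: {off}")


def genome_from_adjacencies(adjs: Counter | Iterable[Adjacency], genes: Mapping[int, int], name: str = "") -> Genome:
    """Reconstruct a genome from its adjacency multiset.

    Inverse of :func:`adjacencies_of` up to chromosome order and traversal
    direction.  For genomes with duplicated genes the chromosome structure
    is not always unique; a deterministic greedy traversal is used and the
    result is verified against the input (an error is raised when the
    greedy choice is inconsistent).
    """
    adjs = Counter(adjs) if not isinstance(adjs, Counter) else Counter(adjs)
    genes = Counter(dict(genes))
    _check_extremity_usage(adjs, genes)

    remaining = Counter(adjs)
    by_ext: dict[Extremity, list[Adjacency]] = {}

    def index() -> None:
        by_ext.clear()
        for adj in sorted(remaining):
            if remaining[adj] <= 0:
                continue
            for e in set(adj.ext):
                by_ext.setdefault(e, []).append(adj)

    def take(adj: Adjacency) -> None:
        remaining[adj] -= 1
        if remaining[adj] == 0:
            del remaining[adj]
        index()

    def pick(e: Extremity) -> Adjacency | None:
        for adj in by_ext.get(e, []):
            if remaining.get(adj, 0) > 0:
                return adj
        return None

    index()
    chromosomes: list[Chromosome] = []

    def walk(entry: Extremity, stop: Extremity | None) -> tuple[int, ...]:
        """Follow gene/adjacency alternation starting by entering a gene at `entry`.

        For linear chromosomes (stop is None) the walk ends at an external
        adjacency; for circular it ends when the closing extremity `stop`
        is reached with the starting adjacency already consumed.
        """
        order: list[int] = []
        while True:
            g = entry.gene
            order.append(g if entry.side == TAIL else -g)
            exit_e = entry.other
            if stop is None:
                adj = pick(exit_e)
                if adj is None:
                    raise ValueError(f"no adjacency available at extremity {exit_e}")
                take(adj)
                if adj.is_external:
                    return tuple(order)
                (nxt,) = [x for x in adj.ext if x != exit_e] or [exit_e]
                entry = nxt
            else:
                adj = pick(exit_e)
                if adj is None:
                    if exit_e != stop:
                        raise ValueError("circular walk cannot close")
                    return tuple(order)
                take(adj)
                (nxt,) = [x for x in adj.ext if x != exit_e] or [exit_e]
                entry = nxt

    # Linear chromosomes first: start from external adjacencies.
    while True:
        externals = sorted(a for a in remaining if a.is_external)
        if not externals:
            break
        start = externals[0]
        take(start)
        chromosomes.append(Chromosome(walk(start.ext[0], None), False))

    # Then circular chromosomes.
    while remaining:
        start = sorted(remaining)[0]
        take(start)
        a, b = start.ext
        chromosomes.append(Chromosome(walk(b, a), True))

    genome = Genome(tuple(chromosomes), name).canonical()
    if adjacencies_of(genome) != Counter(adjs):
        raise ValueError("could not reconstruct a genome realizing the given adjacencies")
    if genome.gene_multiset != genes:
        raise ValueError("reconstructed genome has unexpected gene content")
    return genome


@dataclass(frozen=True)
class DcjOperation:
    """One of the four rewrite forms: consumed adjacencies -> produced ones.

    {a,b},{c,d} -> {a,c},{b,d}  (two internals rewired)
    {a,b},{c}   -> {a,c},{b}    (internal + external)
    {a,b}       -> {a},{b}      (fission of an adjacency)
    {a},{b}     -> {a,b}        (fusion of two chromosome ends)
    """

    consumed: tuple[Adjacency, ...]
    produced: tuple[Adjacency, ...]

    def __post_init__(self) -> None:
        cons = Counter()
        prod = Counter()
        for adj in self.consumed:
            cons.update(adj.ext)
        for adj in self.produced:
            prod.update(adj.ext)
        if cons != prod:
            raise ValueError("produced adjacencies must reuse exactly the consumed extremities")
        shape = (sorted(len(a.ext) for a in self.consumed), sorted(len(a.ext) for a in self.produced))
        valid = {
            ((2, 2), (2, 2)),
            ((1, 2), (1, 2)),
            ((2,), (1, 1)),
            ((1, 1), (2,)),
        }
        if (tuple(shape[0]), tuple(shape[1])) not in valid:
            raise ValueError(f"not one of the four DCJ forms: {self}")

    @property
    def inverse(self) -> "DcjOperation":
        return DcjOperation(self.produced, self.consumed)

    def __str__(self) -> str:
        lhs = ",".join("{%s}" % a for a in self.consumed)
        rhs = ",".join("{%s}" % a for a in self.produced)
        return f"{lhs}->{rhs}"


def apply_dcj(genome: Genome, op: DcjOperation) -> Genome:
    """Apply a DCJ; raises if the consumed adjacencies are absent."""
    adjs = adjacencies_of(genome)
    need = Counter(op.consumed)
    for adj, mult in need.items():
        if adjs[adj] < mult:
            raise ValueError(f"adjacency {adj} not present in genome")
    adjs.subtract(need)
    adjs.update(op.produced)
    adjs = +adjs
    return genome_from_adjacencies(adjs, genome.gene_multiset, genome.name)


def complete_gene_content(a: Genome, b: Genome) -> tuple[Counter, Counter]:
    """Equalize gene content with ghost adjacencies.

    A gene occurrence present in B but missing in A contributes a ghost
    adjacency {g_t, g_h} on the A side (a black edge of the breakpoint
    graph), and symmetrically for occurrences missing in B (gray side).
    Returns the completed adjacency multisets (A side, B side).
    """
    adj_a = adjacencies_of(a)
    adj_b = adjacencies_of(b)
    genes_a = a.gene_multiset
    genes_b = b.gene_multiset
    for g in sorted(set(genes_a) | set(genes_b)):
        diff = genes_b[g] - genes_a[g]
        ghost = Adjacency.internal(tail(g), head(g))
        if diff > 0:
            adj_a[ghost] += diff
        elif diff < 0:
            adj_b[ghost] += -diff
    return adj_a, adj_b


# ---------------------------------------------------------------------------
# GRIMM-like text format: `>` name lines, one chromosome per line of signed
# integers, terminated by `$` (linear) or `@` (circular); `#` comments.
# ---------------------------------------------------------------------------

def parse_grimm(text: str) -> list[Genome]:
    genomes: list[Genome] = []
    name = ""
    chroms: list[Chromosome] = []
    started = False

    def flush() -> None:
        nonlocal chroms, name, started
        if started:
            genomes.append(Genome(tuple(chroms), name))
        chroms = []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            started = True
            continue
        started = True
        if line.endswith("$"):
            circular, body = False, line[:-1]
        elif line.endswith("@"):
            circular, body = True, line[:-1]
        else:
            raise ValueError(f"chromosome line must end with '$' or '@': {raw!r}")
        genes = tuple(int(tok) for tok in body.split())
        chroms.append(Chromosome(genes, circular))
    flush()
    return genomes


def read_grimm(path) -> list[Genome]:
    with open(path, encoding="utf-8") as fh:
        return parse_grimm(fh.read())


def format_grimm(*genomes: Genome) -> str:
    out = []
    for i, g in enumerate(genomes):
        out.append(f">{g.name or f'genome{i + 1}'}")
        for chrom in g.chromosomes:
            body = " ".join(str(x) for x in chrom.genes)
            out.append(f"{body} {'@' if chrom.circular else '$'}".strip())
    return "\n".join(out) + "\n"


def write_grimm(path, *genomes: Genome) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_grimm(*genomes))
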