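"""Conservative haplotype counting per contig from aligned reads.

When duplicated loci (homeologues) collapse into one assembled contig,
reads from all copies pile up together and the contig carries more than
the expected one or two haplotypes.  The count is estimated
conservatively: two reads are in conflict iff they overlap on at least
one variant column and disagree there; any valid coloring of the
conflict graph partitions the reads into internally consistent groups,
and the minimum number of colors is the smallest number of haplotypes
that can explain the alignment.  Color classes whose consensus sequences
agree wherever they share columns are merged, and classes supported by
fewer reads than the support threshold (default 20) are discarded.

Reads spanning more than 200 aligned bases are excluded beforehand, and
variant columns require at least two reads per allele, which absorbs
singleton sequencing errors.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

_EXACT_LIMIT = 15  # components up to this many reads are colored exactly


@dataclass(frozen=True)
class AlignedRead:
    """One read placed on a contig with base calls at variant columns."""

    read_id: str
    start: int  # 1-based inclusive
    end: int
    bases: dict[int, str] = field(default_factory=dict)  # column -> base
    true_haplotype: int | None = None  # simulation ground truth, if any

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad read span [{self.start}, {self.end}]")
        for pos in self.bases:
            if not self.start <= pos <= self.end:
                raise ValueError(f"base call at {pos} outside read span")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ContigAlignment:
    """All reads of one sample aligned to one contig."""

    contig: str
    length: int
    reads: tuple[AlignedRead, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "reads", tuple(self.reads))
        for r in self.reads:
            if r.end > self.length:
                raise ValueError(f"read {r.read_id} extends past contig end")


@dataclass(frozen=True)
class HaplotypeSummary:
    """Frequency of contigs with 1, 2 and >=3 haplotypes for one sample."""

    sample: str
    counts: dict[str, int]  # contig -> haplotype count
    freq_1: float
    freq_2: float
    freq_3plus: float


def call_variant_columns(aln: ContigAlignment, min_allele_reads: int = 2) -> list[int]:
    """Columns where at least two alleles each have enough read support."""
    by_col: dict[int, Counter] = defaultdict(Counter)
    for r in aln.reads:
        for pos, base in r.bases.items():
            by_col[pos][base] += 1
    return sorted(
        pos
        for pos, alleles in by_col.items()
        if sum(c >= min_allele_reads for c in alleles.values()) >= 2
    )


def filter_reads(aln: ContigAlignment, max_span: int = 200) -> ContigAlignment:
    """Drop reads whose aligned span exceeds ``max_span`` bases.

    A span of exactly ``max_span`` is retained ("stretching beyond"
    excludes strictly longer alignments only).
    """
    return ContigAlignment(
        contig=aln.contig,
        length=aln.length,
        reads=tuple(r for r in aln.reads if r.span <= max_span),
    )


def _conflict_graph(reads: Sequence[AlignedRead], columns: Iterable[int]) -> nx.Graph:
    cols = set(columns)
    g = nx.Graph()
    g.add_nodes_from(range(len(reads)))
    for i in range(len(reads)):
        bi = reads[i].bases
        for j in range(i + 1, len(reads)):
            bj = reads[j].bases
            if any(c in bi and c in bj and bi[c] != bj[c] for c in cols):
                g.add_edge(i, j)
    return g


def _greedy_color(g: nx.Graph, order: Sequence[int]) -> dict[int, int]:
    coloring: dict[int, int] = {}
    for node in order:
        used = {coloring[nb] for nb in g[node] if nb in coloring}
        color = 0
        while color in used:
            color += 1
        coloring[node] = color
    return coloring


def _exact_color(g: nx.Graph, order: Sequence[int]) -> dict[int, int]:
    """Branch-and-bound minimum coloring, seeded by the greedy solution."""
    nodes = [n for n in order if n in g]
    best = _greedy_color(g, nodes)
    best_k = max(best.values(), default=-1) + 1
    # search nodes in descending degree: fails fast on the dense core
    nodes = sorted(nodes, key=lambda n: (-g.degree(n), n))
    assign: dict[int, int] = {}

    def extend(idx: int, used_k: int) -> None:
        nonlocal best, best_k
        if used_k >= best_k:
            return
        if idx == len(nodes):
            best, best_k = dict(assign), used_k
            return
        node = nodes[idx]
        neighbor_colors = {assign[nb] for nb in g[node] if nb in assign}
        for color in range(min(used_k + 1, best_k)):
            if color not in neighbor_colors:
                assign[node] = color
                extend(idx + 1, max(used_k, color + 1))
                del assign[node]
                if max(used_k, color + 1) >= best_k and color == used_k:
                    break  # symmetry: first fresh color suffices

    extend(0, 0)
    return best


def _consensus(reads: Sequence[AlignedRead], members: Iterable[int], cols: Iterable[int]) -> dict[int, str]:
    votes: dict[int, Counter] = defaultdict(Counter)
    for i in members:
        for pos, base in reads[i].bases.items():
            votes[pos][base] += 1
    return {pos: c.most_common(1)[0][0] for pos, c in votes.items() if pos in set(cols)}


def count_haplotypes(
    aln: ContigAlignment,
    min_reads_per_hap: int = 20,
    min_allele_reads: int = 2,
    per_contig_support: bool = False,
) -> int:
    """Minimum number of read-supported haplotypes on one contig.

    Reads are grouped by a minimum coloring of the conflict graph (exact
    search on components of up to 15 reads, deterministic greedy in
    start-then-id order beyond that); color classes with identical
    consensus over shared variant columns are merged; classes supported
    by fewer than ``min_reads_per_hap`` reads are dropped.  A contig
    with no variant columns counts as a single haplotype provided it
    meets the read-support threshold.

    ``per_contig_support=True`` applies the read threshold to the whole
    contig instead of to each haplotype class.
    """
    reads = aln.reads
    if len(reads) == 0:
        return 0
    columns = call_variant_columns(aln, min_allele_reads=min_allele_reads)
    if not columns:
        return 1 if len(reads) >= min_reads_per_hap else 0
    if per_contig_support and len(reads) < min_reads_per_hap:
        return 0

    order = sorted(range(len(reads)), key=lambda i: (reads[i].start, reads[i].read_id))
    g = _conflict_graph(reads, columns)

    coloring: dict[int, int] = {}
    offset = 0
    for comp in nx.connected_components(g):
        comp_nodes = [n for n in order if n in comp]
        sub = g.subgraph(comp)
        local = _exact_color(sub, comp_nodes) if len(comp) <= _EXACT_LIMIT else _greedy_color(sub, comp_nodes)
        for node, color in local.items():
            coloring[node] = color + offset
        offset += max(local.values(), default=-1) + 1

    classes: dict[int, list[int]] = defaultdict(list)
    for node, color in coloring.items():
        classes[color].append(node)

    # merge classes whose consensus agrees at every shared column
    labels = sorted(classes)
    consensus = {c: _consensus(reads, classes[c], columns) for c in labels}
    merged = True
    while merged:
        merged = False
        for a in labels:
            if a not in classes:
                continue
            for b in labels:
                if b <= a or b not in classes:
                    continue
                ca, cb = consensus[a], consensus[b]
                shared = set(ca) & set(cb)
                if all(ca[p] == cb[p] for p in shared):
                    classes[a].extend(classes.pop(b))
                    consensus[a] = _consensus(reads, classes[a], columns)
                    del consensus[b]
                    merged = True
        labels = sorted(classes)

    if per_contig_support:
        return len(classes)
    return sum(1 for members in classes.values() if len(members) >= min_reads_per_hap)


def haplotype_frequency_distribution(
    counts: dict[str, int] | Sequence[int], sample: str = "sample"
) -> HaplotypeSummary:
    """Group contigs by haplotype count into frequencies over {1, 2, 3+}.

    Contigs scoring 0 (failed support filters) are excluded from the
    denominator; an input with no positive counts is an error.
    """
    if isinstance(counts, dict):
        mapping = dict(counts)
    else:
        mapping = {f"contig{i:04d}": int(c) for i, c in enumerate(counts)}
    if any(c < 0 for c in mapping.values()):
        raise ValueError("haplotype counts must be non-negative")
    positive = [c for c in mapping.values() if c >= 1]
    if not positive:
        raise ValueError("no contig retained a haplotype after filtering")
    n = len(positive)
    return HaplotypeSummary(
        sample=sample,
        counts=mapping,
        freq_1=sum(c == 1 for c in positive) / n,
        freq_2=sum(c == 2 for c in positive) / n,
        freq_3plus=sum(c >= 3 for c in positive) / n,
    )
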