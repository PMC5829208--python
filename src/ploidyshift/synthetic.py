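"""Synthetic RAD-like data with known ground truth.

Three generators, one per downstream analysis stage:

* :func:`simulate_read_ratio_dataset` — bi-allelic SNP read depths for
  replicate RAD libraries of one individual, under a known ploidy.  At a
  heterozygous site with alternate-allele dosage ``d`` in a ``p``-ploid,
  a sequenced read carries the reference allele with probability
  ``(p - d) / p``; read counts are binomial in the site depth.  Diploids
  may carry collapsed-paralog sites where two duplicated loci are stacked
  onto one position, mimicking a 0.25/0.75 signal.
* :func:`simulate_contig_alignments` — error-free reads copied from 1–4
  distinct haplotype sequences per contig, emulating homeologous loci
  collapsed into a single assembled contig.
* :func:`simulate_ou_traits` — tip traits under an Ornstein–Uhlenbeck
  process on an ultrametric tree with optimum shifts on chosen branches.

Every generator takes an explicit integer seed; no global random state is
touched, and identical configurations yield byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .snp_ratio import SnpRecord

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# SNP read-ratio simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters for the replicate SNP read-depth simulator.

    Parameters
    ----------
    ploidy
        Number of chromosome copies, one of {2, 3, 4}.
    n_snps
        Number of heterozygous sites to simulate.
    depth_mean
        Mean reads per site per replicate library.
    depth_law
        ``"fixed"`` (every site at exactly ``depth_mean`` reads) or
        ``"poisson"`` (Poisson-distributed, clipped to >= 1).
    error_rate
        Per-read probability of flipping the called allele (symmetric).
    paralog_fraction
        Probability that a diploid site is a collapsed paralog pair,
        sequenced with reference probability 0.25 or 0.75 (equal chance)
        instead of 0.5.  Ignored for ploidy > 2.
    dosage_weights
        Probability vector over alternate-allele dosages ``1..ploidy-1``.
    n_replicates
        Replicate libraries per individual (the study design uses 2).
    seed
        Integer seed for the generator.
    """

    ploidy: int
    n_snps: int
    depth_mean: float = 30.0
    depth_law: str = "fixed"
    error_rate: float = 0.0
    paralog_fraction: float = 0.0
    dosage_weights: tuple[float, ...] | None = None
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3, 4):
            raise ValueError(f"ploidy must be 2, 3 or 4, got {self.ploidy}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.depth_law not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth_law {self.depth_law!r}")
        if self.depth_mean <= 0:
            raise ValueError("mean depth must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        weights = self.dosage_weights
        if weights is None:
            # uniform over heterozygous dosages; tetraploids get the
            # (1/4, 1/2, 1/4) split that puts visible mass on all three peaks
            weights = {2: (1.0,), 3: (0.5, 0.5), 4: (0.25, 0.5, 0.25)}[self.ploidy]
            object.__setattr__(self, "dosage_weights", tuple(weights))
        else:
            weights = tuple(float(w) for w in weights)
            if len(weights) != self.ploidy - 1:
                raise ValueError(
                    f"dosage_weights must have length {self.ploidy - 1} "
                    f"(dosages 1..{self.ploidy - 1}), got {len(weights)}"
                )
            if abs(sum(weights) - 1.0) > 1e-12:
                raise ValueError("dosage_weights must sum to 1 within 1e-12")
            if any(w < 0 for w in weights):
                raise ValueError("dosage_weights must be non-negative")
            object.__setattr__(self, "dosage_weights", weights)


def simulate_read_ratio_dataset(config: SimConfig) -> list[list[SnpRecord]]:
    """Simulate per-replicate bi-allelic SNP records for one individual.

    Returns one list of :class:`~ploidyshift.snp_ratio.SnpRecord` per
    replicate library; records at the same index across replicates refer
    to the same site (same contig, position and alleles).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    p = config.ploidy

    dosages = rng.choice(np.arange(1, p), size=n, p=np.asarray(config.dosage_weights))
    p_ref = (p - dosages) / p

    if p == 2 and config.paralog_fraction > 0:
        is_paralog = rng.random(n) < config.paralog_fraction
        paralog_p = rng.choice([0.25, 0.75], size=n)
        p_ref = np.where(is_paralog, paralog_p, p_ref)

    # symmetric per-read allele flip broadens the peaks without moving 0.5
    e = config.error_rate
    p_eff = p_ref * (1 - e) + (1 - p_ref) * e

    positions = np.sort(rng.choice(np.arange(1, 10 * n + 1), size=n, replace=False))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ref_alleles = _BASES[ref_idx]
    alt_alleles = _BASES[alt_idx]

    replicates: list[list[SnpRecord]] = []
    for _ in range(config.n_replicates):
        if config.depth_law == "fixed":
            depths = np.full(n, int(round(config.depth_mean)))
        else:
            depths = np.maximum(rng.poisson(config.depth_mean, size=n), 1)
        ref_counts = rng.binomial(depths, p_eff)
        alt_counts = depths - ref_counts
        replicates.append(
            [
                SnpRecord(
                    contig="sim",
                    position=int(positions[i]),
                    ref_allele=str(ref_alleles[i]),
                    alt_allele=str(alt_alleles[i]),
                    ref_count=int(ref_counts[i]),
                    alt_count=int(alt_counts[i]),
                )
                for i in range(n)
            ]
        )
    return replicates


# ---------------------------------------------------------------------------
# Contig / haplotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeSimConfig:
    """Parameters for the collapsed-contig read simulator.

    ``true_haplotypes_per_contig`` maps haplotype counts in {1, 2, 3, 4}
    to probabilities; ``reads_per_contig`` is the total read count per
    contig, divided round-robin across haplotypes so groups are balanced.
    ``haplotype_divergence`` is the per-variant-column probability that
    the haplotypes carry mutually distinct bases there.
    """

    n_contigs: int
    true_haplotypes_per_contig: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.25, 3: 0.04, 4: 0.01}
    )
    n_variant_columns: int = 3
    reads_per_contig: int = 50
    read_span: int = 150
    haplotype_divergence: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be positive")
        if self.reads_per_contig < 1:
            raise ValueError("reads_per_contig must be >= 1")
        if self.read_span < 1:
            raise ValueError("read_span must be >= 1")
        if self.n_variant_columns < 1:
            raise ValueError("n_variant_columns must be >= 1")
        if not 0.0 <= self.haplotype_divergence <= 1.0:
            raise ValueError("haplotype_divergence must lie in [0, 1]")
        ks = set(self.true_haplotypes_per_contig)
        if not ks or not ks <= {1, 2, 3, 4}:
            raise ValueError("haplotype counts must come from {1, 2, 3, 4}")
        if abs(sum(self.true_haplotypes_per_contig.values()) - 1.0) > 1e-9:
            raise ValueError("haplotype-count probabilities must sum to 1")


def simulate_contig_alignments(config: HaplotypeSimConfig):
    """Simulate reads over contigs carrying 1–4 distinct haplotypes.

    Returns ``(alignments, truth)`` where ``alignments`` is a list of
    :class:`~ploidyshift.haplotype_contig.ContigAlignment` and ``truth``
    maps contig id to its true haplotype count.  Reads are error-free
    copies of one haplotype over a contiguous span; variant columns are
    confined to the window every read covers, so the alignment itself
    (not read placement) limits what is recoverable.
    """
    from .haplotype_contig import AlignedRead, ContigAlignment

    rng = np.random.default_rng(config.seed)
    span = config.read_span
    length = max(span + span // 2, span + 2)  # all reads overlap the centre
    lo, hi = length - span + 1, span  # window covered by every read
    if hi - lo + 1 < config.n_variant_columns:
        raise ValueError("read_span too small for n_variant_columns")

    counts = sorted(config.true_haplotypes_per_contig)
    probs = np.array([config.true_haplotypes_per_contig[k] for k in counts])
    n_haps_per_contig = rng.choice(counts, size=config.n_contigs, p=probs)

    alignments: list[ContigAlignment] = []
    truth: dict[str, int] = {}
    for c, n_hap in enumerate(n_haps_per_contig):
        contig_id = f"contig{c:04d}"
        cols = np.sort(rng.choice(np.arange(lo, hi + 1), size=config.n_variant_columns, replace=False))
        # at a divergent column every haplotype gets a distinct base
        hap_bases = np.empty((n_hap, len(cols)), dtype="<U1")
        for j in range(len(cols)):
            if n_hap > 1 and rng.random() < config.haplotype_divergence:
                hap_bases[:, j] = rng.permutation(_BASES)[:n_hap]
            else:
                hap_bases[:, j] = rng.choice(_BASES)
        reads = []
        for r in range(config.reads_per_contig):
            h = r % n_hap  # round-robin: balanced haplotype support
            start = int(rng.integers(1, length - span + 2))
            end = start + span - 1
            bases = {int(pos): str(hap_bases[h, j]) for j, pos in enumerate(cols) if start <= pos <= end}
            reads.append(AlignedRead(read_id=f"{contig_id}.r{r:03d}", start=start, end=end, bases=bases, true_haplotype=h))
        alignments.append(ContigAlignment(contig=contig_id, length=length, reads=reads))
        truth[contig_id] = int(n_hap)
    return alignments, truth


# ---------------------------------------------------------------------------
# OU trait simulation
# ---------------------------------------------------------------------------

def balanced_tree(depth: int = 5) -> dendropy.Tree:
    """Fully balanced binary tree of unit height with 2**depth tips.

    Internal splits are evenly spaced in time, so every clade size is a
    power of two and every branch has length ``1/depth``.  This is the
    canonical topology for shift-recovery power experiments: the two
    root-child branches each subtend half the tips.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counter = [0]

    def build(d: int) -> str:
        if d == 0:
            counter[0] += 1
            return f"t{counter[0]}:{1 / depth:.10f}"
        inner = f"({build(d - 1)},{build(d - 1)})"
        return inner if d == depth else f"{inner}:{1 / depth:.10f}"

    return dendropy.Tree.get(data=build(depth) + ";", schema="newick")


def simulate_coalescent_tree(n_tips: int, seed: int = 0, unit_height: bool = True) -> dendropy.Tree:
    """Random ultrametric tree from a Kingman-style coalescent.

    Lineages merge pairwise with exponential waiting times, which
    guarantees strictly positive branch lengths everywhere (no singular
    tip covariance).  With ``unit_height`` the tree is rescaled to
    height 1.  Tips are labelled ``t1..tN``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    lineages = [(f"t{i + 1}", 0.0) for i in range(n_tips)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (ni, hi), (nj, hj) = lineages[i], lineages[j]
        merged = (f"({ni}:{t - hi:.10f},{nj}:{t - hj:.10f})", t)
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)] + [merged]
    newick = lineages[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    if unit_height:
        from .ou_shift import scale_tree

        tree = scale_tree(tree)
    return tree


@dataclass(frozen=True)
class OUSimConfig:
    """Parameters for Ornstein–Uhlenbeck trait simulation on a tree.

    ``shift_edges`` holds preorder edge indices (see
    :func:`ploidyshift.ou_shift.edge_table`) where the optimum jumps by
    the matching entry of ``shift_offsets``; the shift is inherited by
    every descendant lineage.  ``alpha`` is the strength of attraction
    toward the optimum (per unit tree height), ``sigma2`` the diffusion
    variance (trait units squared per unit height).
    """

    tree: dendropy.Tree
    shift_edges: tuple[int, ...] = ()
    shift_offsets: tuple[float, ...] = ()
    theta0: float = 0.0
    alpha: float = 1.0
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if len(self.shift_edges) != len(self.shift_offsets):
            raise ValueError("shift_edges and shift_offsets must have equal length")


def simulate_ou_traits(config: OUSimConfig) -> dict[str, float]:
    """Draw tip traits from the OU model implied by ``config``.

    The tips are jointly Gaussian: the expectation of each tip is the
    root optimum plus the attenuated sum of inherited shift offsets on
    its root-to-tip path, and the covariance is the stationary OU
    covariance (Brownian in the ``alpha == 0`` limit).  Returns a dict
    mapping tip label to trait value.
    """
    from .ou_shift import check_ultrametric, edge_table, ou_design

    check_ultrametric(config.tree)
    table = edge_table(config.tree)
    n_edges = len(table.edges)
    for e in config.shift_edges:
        if not 0 <= e < n_edges:
            raise ValueError(f"shift edge index {e} outside 0..{n_edges - 1}")

    design, cov = ou_design(config.tree, config.alpha, sigma2=config.sigma2)
    mean = np.full(len(table.tip_labels), config.theta0)
    for e, beta in zip(config.shift_edges, config.shift_offsets):
        mean = mean + beta * design[:, e]

    if config.sigma2 == 0:  # zero-noise limit: expectations exactly
        return dict(zip(table.tip_labels, mean.tolist()))
    rng = np.random.default_rng(config.seed)
    # numerically safe Cholesky: cov is SPD for alpha >= 0 on a proper tree
    jitter = 1e-12 * np.trace(cov) / len(mean)
    chol = np.linalg.cholesky(cov + jitter * np.eye(len(mean)))
    traits = mean + chol @ rng.standard_normal(len(mean))
    return dict(zip(table.tip_labels, traits.tolist()))
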