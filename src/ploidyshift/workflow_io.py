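"""File formats, run configuration and the end-to-end pipeline.

Formats
-------
* SNP records: minimal VCF v4.2 (one sample column per replicate
  library, ``GT:AD`` with AD carrying ref,alt read depths) and a TSV
  dialect with columns ``contig  position  ref_allele  alt_allele
  ref_count  alt_count``.
* Contig alignments: TSV with columns ``read_id  contig  contig_length
  start  end  bases`` where ``bases`` is a comma-joined list of
  ``position:base`` pairs ('.' when the read covers no variant column).
* Trees: Newick.  Traits: two-column TSV ``tip_label  value``.

All TSVs are tab-separated, UTF-8, with a mandatory header row and '.'
for missing values; coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from . import __version__
from .haplotype_contig import (
    AlignedRead,
    ContigAlignment,
    count_haplotypes,
    filter_reads,
    haplotype_frequency_distribution,
)
from .mixture_ploidy import classify_ploidy, fit_three_component_gmm, peak_ratio
from .snp_ratio import SnpRecord, compute_ratios, filter_biallelic, intersect_replicates
from .synthetic import SimConfig, simulate_read_ratio_dataset

logger = logging.getLogger("ploidyshift")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ploidyshift {version}
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths for the ref and alt alleles">
"""


def write_vcf(replicates: list[list[SnpRecord]], path, sample_names: list[str] | None = None) -> None:
    """Write replicate SNP records as a minimal multi-sample VCF v4.2.

    Replicates must be aligned: record ``i`` of every replicate refers
    to the same variant (as produced by the simulator).
    """
    if sample_names is None:
        sample_names = [f"rep{i + 1}" for i in range(len(replicates))]
    if len(sample_names) != len(replicates):
        raise ValueError("one sample name per replicate required")
    n_sites = {len(r) for r in replicates}
    if len(n_sites) != 1:
        raise ValueError("replicates must carry the same variants")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER.format(version=__version__))
        contigs = sorted({r.contig for rep in replicates for r in rep})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names) + "\n")
        for i in range(n_sites.pop()):
            site = [rep[i] for rep in replicates]
            first = site[0]
            if any(r.key != first.key for r in site):
                raise ValueError(f"replicates disagree at row {i}")
            cells = "\t".join(f"0/1:{r.ref_count},{r.alt_count}" for r in site)
            fh.write(
                f"{first.contig}\t{first.position}\t.\t{first.ref_allele}\t"
                f"{first.alt_allele}\t.\tPASS\t.\tGT:AD\t{cells}\n"
            )


def read_vcf_subset(path, skip_multiallelic: bool = True) -> tuple[dict[str, list[SnpRecord]], int]:
    """Read per-sample SNP records from a VCF with AD depths.

    Returns ``(records_by_sample, n_multiallelic)``.  Multi-allelic rows
    are skipped (and counted) when ``skip_multiallelic`` is true,
    otherwise they raise.  A record missing its AD field is an error
    naming the site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: dict[str, list[SnpRecord]] = {s: [] for s in samples}
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"multi-allelic record at {variant.CHROM}:{variant.POS}")
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(f"missing AD field at {variant.CHROM}:{variant.POS}")
        for s_idx, sample in enumerate(samples):
            ref_c, alt_c = int(ad[s_idx, 0]), int(ad[s_idx, 1])
            if ref_c < 0 or alt_c < 0:  # cyvcf2 encodes missing as negative
                continue
            out[sample].append(
                SnpRecord(
                    contig=variant.CHROM,
                    position=variant.POS,
                    ref_allele=variant.REF,
                    alt_allele=variant.ALT[0],
                    ref_count=ref_c,
                    alt_count=alt_c,
                )
            )
    return out, n_multi


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_snp_tsv(records, path) -> None:
    pd.DataFrame(
        [
            {
                "contig": r.contig,
                "position": r.position,
                "ref_allele": r.ref_allele,
                "alt_allele": r.alt_allele,
                "ref_count": r.ref_count,
                "alt_count": r.alt_count,
            }
            for r in records
        ],
        columns=["contig", "position", "ref_allele", "alt_allele", "ref_count", "alt_count"],
    ).to_csv(path, sep="\t", index=False)


def read_snp_tsv(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref_allele": str, "alt_allele": str})
    return [
        SnpRecord(
            contig=row.contig,
            position=int(row.position),
            ref_allele=row.ref_allele,
            alt_allele=row.alt_allele,
            ref_count=int(row.ref_count),
            alt_count=int(row.alt_count),
        )
        for row in df.itertuples(index=False)
    ]


def write_alignment_tsv(alignments, path) -> None:
    rows = []
    for aln in alignments:
        for r in aln.reads:
            bases = ",".join(f"{pos}:{base}" for pos, base in sorted(r.bases.items())) or "."
            rows.append(
                {
                    "read_id": r.read_id,
                    "contig": aln.contig,
                    "contig_length": aln.length,
                    "start": r.start,
                    "end": r.end,
                    "bases": bases,
                }
            )
    pd.DataFrame(rows, columns=["read_id", "contig", "contig_length", "start", "end", "bases"]).to_csv(
        path, sep="\t", index=False
    )


def read_alignment_tsv(path) -> list[ContigAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str, "bases": str})
    out = []
    for contig, group in df.groupby("contig", sort=True):
        reads = []
        for row in group.itertuples(index=False):
            bases = {}
            if row.bases != ".":
                for pair in row.bases.split(","):
                    pos, base = pair.split(":")
                    bases[int(pos)] = base
            reads.append(AlignedRead(read_id=row.read_id, start=int(row.start), end=int(row.end), bases=bases))
        out.append(ContigAlignment(contig=contig, length=int(group["contig_length"].iloc[0]), reads=tuple(reads)))
    return out


def write_traits_tsv(traits: dict[str, float], path) -> None:
    pd.DataFrame(
        {"tip_label": list(traits), "value": list(traits.values())}
    ).to_csv(path, sep="\t", index=False)


def read_traits_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"tip_label": str})
    return dict(zip(df["tip_label"], df["value"].astype(float)))


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

KNOWN_STAGES = ("simulate", "snp_ratios", "fit_mixture", "haplotypes")
_KNOWN_TOP_KEYS = {"stages", "seed", "out_dir", "log_level", *KNOWN_STAGES}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    stages: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str = "ploidyshift_out"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    snp_ratios: dict = field(default_factory=dict)
    fit_mixture: dict = field(default_factory=dict)
    haplotypes: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: (tuple(v) if k == "stages" else v) for k, v in raw.items()})
        for stage in cfg.stages:
            if stage not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        return cfg


@dataclass
class RunManifest:
    """Record of what a pipeline run did: config echo, counts, timing."""

    config: dict
    version: str
    stage_counts: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages in order, writing TSVs and a manifest.

    Stage order is fixed: simulate -> snp_ratios (filter + replicate
    intersection + ratios) -> fit_mixture (EM fit, peak ratio,
    classification) -> haplotypes.  A rerun with the same config and
    seed is byte-identical.
    """
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    replicates: list[list[SnpRecord]] | None = None

    for stage in config.stages:
        try:
            if stage == "simulate":
                sim = SimConfig(seed=config.seed, **config.simulate)
                replicates = simulate_read_ratio_dataset(sim)
                write_vcf(replicates, out_dir / "simulated_snps.vcf")
                for i, rep in enumerate(replicates):
                    write_snp_tsv(rep, out_dir / f"simulated_rep{i + 1}.tsv")
                manifest.stage_counts[stage] = {"n_sites": sim.n_snps, "n_replicates": sim.n_replicates}
                logger.info("simulated %d sites x %d replicates", sim.n_snps, sim.n_replicates)
            elif stage == "snp_ratios":
                if replicates is None:
                    reps_by_sample, _ = read_vcf_subset(config.snp_ratios["vcf"])
                    replicates = list(reps_by_sample.values())
                params = {k: v for k, v in config.snp_ratios.items() if k != "vcf"}
                filtered = [filter_biallelic(rep, **params) for rep in replicates]
                for i, (before, after) in enumerate(zip(replicates, filtered)):
                    logger.info(
                        "replicate %d: %d of %d records pass depth filters (%d discarded)",
                        i + 1, len(after), len(before), len(before) - len(after),
                    )
                combined = filtered[0]
                for other in filtered[1:]:
                    combined = intersect_replicates(combined, other)
                ratios = compute_ratios(combined)
                write_snp_tsv(combined, out_dir / "combined_snps.tsv")
                pd.DataFrame({"ratio": ratios.ratios, "depth": ratios.depths}).to_csv(
                    out_dir / "ratios.tsv", sep="\t", index=False
                )
                manifest.stage_counts[stage] = {
                    "input": [len(r) for r in replicates],
                    "filtered": [len(r) for r in filtered],
                    "retained": len(combined),
                }
                config.fit_mixture.setdefault("_ratios", ratios)
            elif stage == "fit_mixture":
                params = dict(config.fit_mixture)
                ratios = params.pop("_ratios", None)
                if ratios is None:
                    df = pd.read_csv(params.pop("ratios"), sep="\t")
                    ratios = df["ratio"].to_numpy()
                t_low = params.pop("t_low", 0.45)
                t_high = params.pop("t_high", 0.9)
                fit = fit_three_component_gmm(ratios, **params)
                pr = peak_ratio(fit)
                category = classify_ploidy(pr, t_low=t_low, t_high=t_high)
                report = {
                    "mu": list(map(float, fit.mu)),
                    "sigma": list(map(float, fit.sigma)),
                    "lambda": list(map(float, fit.lam)),
                    "loglik": fit.loglik,
                    "peak_ratio": pr,
                    "category": category,
                }
                pd.DataFrame([report]).to_csv(out_dir / "mixture_fit.tsv", sep="\t", index=False)
                manifest.results["peak_ratio"] = pr
                manifest.results["category"] = category
                manifest.stage_counts[stage] = {"n_ratios": int(len(ratios.ratios) if hasattr(ratios, "ratios") else len(ratios))}
            elif stage == "haplotypes":
                params = dict(config.haplotypes)
                alignments = read_alignment_tsv(params.pop("alignments"))
                max_span = params.pop("max_span", 200)
                counts = {
                    aln.contig: count_haplotypes(filter_reads(aln, max_span=max_span), **params)
                    for aln in alignments
                }
                summary = haplotype_frequency_distribution(counts)
                pd.DataFrame(
                    {"contig": list(counts), "haplotypes": list(counts.values())}
                ).to_csv(out_dir / "haplotype_counts.tsv", sep="\t", index=False)
                manifest.results["haplotype_freqs"] = [summary.freq_1, summary.freq_2, summary.freq_3plus]
                manifest.stage_counts[stage] = {"n_contigs": len(alignments)}
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.wall_time_s = time.perf_counter() - t0
    manifest.write(out_dir / "manifest.json")
    return manifest
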