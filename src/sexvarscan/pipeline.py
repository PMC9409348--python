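"""End-to-end orchestration: simulate -> coverage -> variants -> clusters
-> genes -> dN/dS -> report.

Every numeric threshold is taken from :class:`~sexvarscan.config.RunConfig`
and passed to the stage functions explicitly; rerunning with an identical
config and seed reproduces byte-identical artifacts and an identical
report hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .config import FEMALE, MALE, RunConfig
from .depth import DepthMatrix, coverage_summary, parse_depth_table, sex_exclusive_positions
from .dnds import classify_selection, codon_align, ds_filter, ng86_dnds, translate
from .peaks import (
    distinct_gene_count,
    nearest_gene,
    peak_table,
    peaks_to_frame,
    read_bed,
    scan_clusters,
)
from .simulate import generate_cohort, generate_ortholog_pairs, generate_reference
from .variants import (
    filter_quality,
    interspecies_fixed_variants,
    merge_samples,
    per_segment_counts,
    read_vcf,
    sex_associated_variants,
    variant_class_proportions,
    variant_spacing_stats,
)

logger = logging.getLogger(__name__)


@dataclass
class Diagnostic:
    level: str  # "warning" | "fatal"
    message: str


def validate_inputs(
    vcf_paths: Mapping[str, str | Path],
    depth_paths: Mapping[str, str | Path],
    sex_of: Mapping[str, str],
    genes_bed: str | Path | None = None,
) -> list[Diagnostic]:
    """Pre-flight checks on a cohort bundle.

    Fatal: non-dense or unparsable depth tables, unsorted VCFs or BED,
    contigs present in a VCF but absent from the depth tables, manifests
    without exactly two sex classes or with samples missing a label.
    """
    diags: list[Diagnostic] = []
    sexes = set(sex_of.values())
    if sexes != {MALE, FEMALE}:
        diags.append(
            Diagnostic("fatal", f"manifest must have exactly male/female classes, got {sorted(sexes)}")
        )
    for s in list(vcf_paths) + list(depth_paths):
        if s not in sex_of:
            diags.append(Diagnostic("fatal", f"sample {s} missing from sex manifest"))

    depth_contigs: set[str] = set()
    for s, path in depth_paths.items():
        try:
            depth_contigs.update(parse_depth_table(path))
        except Exception as exc:
            diags.append(Diagnostic("fatal", f"depth table {path}: {exc}"))
    for s, path in vcf_paths.items():
        last = None
        contigs_here: set[str] = set()
        try:
            for rec in read_vcf(path):
                key = (rec.contig, rec.pos)
                if last is not None and key < last and key[0] == last[0]:
                    diags.append(
                        Diagnostic("fatal", f"{path}: unsorted at {rec.contig}:{rec.pos}")
                    )
                    break
                last = key
                contigs_here.add(rec.contig)
        except Exception as exc:
            diags.append(Diagnostic("fatal", f"VCF {path}: {exc}"))
            continue
        missing = contigs_here - depth_contigs
        if missing and depth_contigs:
            diags.append(
                Diagnostic(
                    "fatal",
                    f"{path}: contig(s) {sorted(missing)} absent from depth tables",
                )
            )
    if genes_bed is not None:
        try:
            genes = read_bed(genes_bed)
            by_contig: dict[str, int] = {}
            for g in genes:
                if g.contig in by_contig and g.start < by_contig[g.contig]:
                    diags.append(
                        Diagnostic(
                            "fatal",
                            f"{genes_bed}: intervals on {g.contig} not sorted; "
                            "sort by start first",
                        )
                    )
                    break
                by_contig[g.contig] = g.start
        except Exception as exc:
            diags.append(Diagnostic("fatal", f"BED {genes_bed}: {exc}"))
    return diags


@dataclass
class RunReport:
    """Machine-readable end-of-run summary; counts equal recomputation
    from the stage artifacts written next to it."""

    data: dict[str, Any]

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()

    def save(self, path: str | Path) -> None:
        payload = dict(self.data)
        payload["report_hash"] = self.hash
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _config_hash(config: RunConfig) -> str:
    # output location is not part of the scientific configuration
    d = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage on a freshly simulated cohort and write all
    intermediate artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    sim_dir = out / "sim"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    # stage 1: simulation
    reference = generate_reference(sim)
    reference.write_fasta(sim_dir / "reference.fa")
    reference.write_fai(sim_dir / "reference.fa.fai")
    reference.write_bed(sim_dir / "genes.bed")
    cohort = generate_cohort(sim, reference, sim_dir)
    orthologs = generate_ortholog_pairs(sim)
    orthologs.write_fastas(sim_dir / "cds_pairs.fna", sim_dir / "protein_pairs.faa")
    males, females = cohort.male_samples, cohort.female_samples
    samples = males + females

    # stage 2: coverage
    matrix = DepthMatrix.from_files({s: cohort.depth_paths[s] for s in samples})
    summaries = [
        coverage_summary(matrix, [s], name=s, min_depth=config.coverage_min_depth)
        for s in samples
    ]
    summaries += [
        coverage_summary(matrix, males, name="males", min_depth=config.coverage_min_depth),
        coverage_summary(matrix, females, name="females", min_depth=config.coverage_min_depth),
        coverage_summary(matrix, samples, name="all", min_depth=config.coverage_min_depth),
    ]
    from .depth import summaries_to_frame

    summaries_to_frame(summaries).to_csv(out / "coverage_summary.tsv", sep="\t", index=False)

    # stage 3: sex-exclusive coverage
    female_zero, female_zero_contigs = sex_exclusive_positions(
        matrix, females, males, zero_sex=FEMALE,
        min_depth=config.exclusive_min_depth, min_samples=config.exclusive_min_samples,
    )
    male_zero, male_zero_contigs = sex_exclusive_positions(
        matrix, males, females, zero_sex=MALE,
        min_depth=config.exclusive_min_depth, min_samples=config.exclusive_min_samples,
    )

    # stage 4: variant association
    def records(sample: str, filtered: bool):
        stream = read_vcf(cohort.vcf_paths[sample], sample=sample)
        return list(filter_quality(stream, config.min_qual)) if filtered else list(stream)

    all_filtered = merge_samples({s: records(s, True) for s in samples}, samples)
    fixed = interspecies_fixed_variants(all_filtered, n_samples=len(samples))
    male_merged = merge_samples({s: records(s, True) for s in males}, males)
    female_merged = merge_samples({s: records(s, False) for s in females}, females)
    sex_sites = sex_associated_variants(
        male_merged, female_merged, matrix, min_depth_exclusive=config.min_depth_exclusive
    )
    contig_lengths = matrix.contig_lengths
    fixed_spacing = variant_spacing_stats(fixed)
    fixed_segments = per_segment_counts(fixed, contig_lengths, window=config.window)
    sex_spacing = variant_spacing_stats(sex_sites)
    sex_segments = per_segment_counts(sex_sites, contig_lengths, window=config.window)

    # stage 5: cluster peaks and nearest genes
    hits = scan_clusters(sex_segments, threshold=config.cluster_threshold)
    peaks = peak_table(hits, sex_sites, window=config.window)
    genes = sorted(reference.genes, key=lambda g: (g.contig, g.start, g.end))
    site_assignments = nearest_gene([(s.contig, s.pos) for s in sex_sites], genes)
    n_sites_in_genes = sum(1 for a in site_assignments if a.in_gene)
    peak_assignments = nearest_gene(
        [(p.contig, p.first_variant_pos, p.last_variant_pos) for p in peaks], genes
    )
    n_distinct_genes, in_gene_flags = distinct_gene_count(peak_assignments)
    peaks_to_frame(peaks, peak_assignments).to_csv(
        out / "peak_table.tsv", sep="\t", index=False
    )

    # stage 6: dN/dS
    dnds_results = []
    for pair in orthologs.pairs:
        aln = codon_align(
            translate(pair.cds_a), translate(pair.cds_b), pair.cds_a, pair.cds_b,
            pair_id=pair.pair_id,
        )
        dnds_results.append(ng86_dnds(aln))
    kept, dropped = ds_filter(dnds_results, lo=config.ds_lo, hi=config.ds_hi)
    _write_dnds_table(dnds_results, out / "dnds.tsv")

    sex_site_keys = sorted((s.contig, s.pos) for s in sex_sites)
    _write_sites(fixed, out / "interspecies_sites.tsv")
    _write_sites(sex_sites, out / "sex_associated_sites.tsv")

    report = RunReport(
        data={
            "provenance": {
                "tool_version": __version__,
                "seed": config.seed,
                "config_hash": _config_hash(config),
            },
            "coverage": {
                s.name: {
                    "covered_fraction": s.covered_fraction,
                    "mean_depth": s.mean_depth,
                }
                for s in summaries
            },
            "sex_exclusive": {
                "female_zero_positions": len(female_zero),
                "female_zero_contigs": female_zero_contigs,
                "male_zero_positions": len(male_zero),
                "male_zero_contigs": male_zero_contigs,
            },
            "interspecies": {
                "n_sites": len(fixed),
                "class_percent": variant_class_proportions(fixed),
                "mean_distance_bp": fixed_spacing.mean_distance,
                "mean_per_segment_including_empty": fixed_segments.mean_including_empty,
                "mean_per_segment_excluding_empty": fixed_segments.mean_excluding_empty,
            },
            "sex_associated": {
                "n_sites": len(sex_sites),
                "class_percent": variant_class_proportions(sex_sites),
                "mean_distance_bp": sex_spacing.mean_distance,
                "mean_per_segment_including_empty": sex_segments.mean_including_empty,
                "mean_per_segment_excluding_empty": sex_segments.mean_excluding_empty,
                "n_nonempty_windows": sex_segments.n_nonempty_windows,
                "n_contigs_with_variants": sex_segments.n_contigs_with_variants,
                "sites": sex_site_keys,
            },
            "peaks": {
                "n_peaks": len(peaks),
                "table": [dataclasses.asdict(p) for p in peaks],
                "nearest_genes": [
                    {
                        "contig": p.contig,
                        "window_index": p.window_index,
                        "gene": a.gene.label if a.gene else None,
                        "distance": a.distance,
                        "in_gene": a.in_gene,
                    }
                    for p, a in zip(peaks, peak_assignments)
                ],
                "distinct_gene_count": n_distinct_genes,
                "in_gene_flags": in_gene_flags,
                "n_variant_sites_in_genes": n_sites_in_genes,
            },
            "dnds": {
                "n_pairs": len(dnds_results),
                "n_kept_by_ds_filter": len(kept),
                "n_dropped_by_ds_filter": len(dropped),
                "classes": {
                    cls: sum(1 for r in dnds_results if r.selection_class == cls)
                    for cls in ("purifying", "neutral", "adaptive", "undefined")
                },
            },
        }
    )
    report.save(out / "report.json")
    return report


def _write_sites(sites: Sequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def _write_dnds_table(results: Sequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tS\tN\tSd\tNd\tdN\tdS\tomega\tkept\tclass\n")
        for r in results:
            fmt = lambda v: "NA" if v is None else f"{v:.6f}"
            fh.write(
                f"{r.pair_id}\t{r.counts.S:.4f}\t{r.counts.N:.4f}\t"
                f"{r.counts.Sd:.4f}\t{r.counts.Nd:.4f}\t{fmt(r.dN)}\t{fmt(r.dS)}\t"
                f"{fmt(r.omega)}\t{r.kept_by_ds_filter}\t{classify_selection(r.omega)}\n"
            )
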