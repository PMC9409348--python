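"""Synthetic two-sex cohort generator with recorded planted truth.

Emulates the artifacts the discovery pipeline consumes - a small reference
(FASTA + gene BED), per-sample dense depth tables and per-sample
variant-only VCFs for a 5-male / 5-female diploid-coded cohort - with every
planted signal recorded in a :class:`TruthSet`:

* species-fixed sites: 1/1 in every sample, QUAL passing;
* sex-associated sites: clustered in chosen 10 kb windows, 1/1 with passing
  QUAL in all males, explicit 0/1 or no record (50/50 per female per site)
  in females;
* background heterozygous noise: 0/1 in one random sample;
* low-quality decoys: QUAL in [0, 30], including an exact-30 record to pin
  the strict QUAL > 30 rule;
* sex-exclusive coverage blocks: depth 0 in every sample of one sex,
  depth >= 10 forced in >= 3 samples of the other.

Truth categories occupy pairwise disjoint positions so recovery is exact in
the noise-free regime. Read depth is Poisson around the configured mean,
clamped >= 3 at planted variant sites so the > 2 coverage gate never erases
planted truth. All outputs are byte-identical for a fixed config and seed.

Genotypes are diploid-coded even though the study organism is octoploid,
mirroring the diploid caller model the consumed VCFs come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .config import FEMALE, MALE, WINDOW_BP, ConfigurationError, SimulationConfig
from .dnds import CODON_TO_AA, STOP_CODONS
from .peaks import GeneInterval, write_bed
from .depth import write_depth_table

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# reference


@dataclass
class Reference:
    sequences: dict[str, str]
    genes: list[GeneInterval]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, seq in self.sequences.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_fai(self, path: str | Path) -> None:
        """FAI-style contig length index (name and length columns are the
        ones the pipeline consumes)."""
        with open(path, "w") as fh:
            offset = 0
            for contig, seq in self.sequences.items():
                offset += len(contig) + 2
                fh.write(f"{contig}\t{len(seq)}\t{offset}\t70\t71\n")
                offset += len(seq) + -(-len(seq) // 70)

    def write_bed(self, path: str | Path) -> None:
        write_bed(self.genes, path)


def generate_reference(config: SimulationConfig) -> Reference:
    """Random nucleotide contigs plus non-overlapping gene intervals.

    Genes are placed one per equal-width slot at a random offset, which
    guarantees disjointness; impossible packings are rejected by the
    configuration itself. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed % (2**31), 0])
    sequences: dict[str, str] = {}
    genes: list[GeneInterval] = []
    for ci, contig in enumerate(config.contig_names):
        L = config.contig_length_bp
        sequences[contig] = "".join(_BASES[rng.integers(0, 4, size=L)])
        slot = L // config.n_genes
        if slot < config.gene_length_bp:
            raise ConfigurationError("gene packing impossible")  # pre-checked
        for k in range(config.n_genes):
            offset = int(rng.integers(0, slot - config.gene_length_bp + 1))
            start = k * slot + offset  # 0-based BED
            genes.append(
                GeneInterval(
                    contig=contig,
                    start=start,
                    end=start + config.gene_length_bp,
                    name=f"{contig}_gene_{k + 1}",
                    short_name=f"g{ci + 1}.{k + 1}",
                )
            )
    return Reference(sequences=sequences, genes=genes)


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthSet:
    """Planted coordinates of every synthetic signal category.

    Categories are pairwise disjoint in (contig, pos). ``cluster_genes``
    records, per planted window, the gene a correct nearest-gene stage
    should report for the recovered peak (computed here by independent
    all-pairs minimisation over the generated annotation).
    """

    fixed_sites: set[tuple[str, int]] = field(default_factory=set)
    sex_sites: set[tuple[str, int]] = field(default_factory=set)
    sex_windows: set[tuple[str, int]] = field(default_factory=set)
    noise_sites: set[tuple[str, int]] = field(default_factory=set)
    decoy_sites: set[tuple[str, int]] = field(default_factory=set)
    exclusive_positions: dict[str, set[tuple[str, int]]] = field(
        default_factory=lambda: {MALE: set(), FEMALE: set()}
    )
    cluster_genes: dict[tuple[str, int], str] = field(default_factory=dict)
    ortholog_truth: dict[str, tuple[int, int]] = field(default_factory=dict)

    def sex_sites_in_window(self, contig: str, window_index: int) -> set[tuple[str, int]]:
        lo = window_index * WINDOW_BP + 1
        hi = lo + WINDOW_BP - 1
        return {(c, p) for c, p in self.sex_sites if c == contig and lo <= p <= hi}

    def save(self, path: str | Path) -> None:
        """Write the truth as a sorted tabular sidecar (category, key1,
        key2, value); reloadable bit-identically via :meth:`load`."""
        rows: list[tuple[str, str, str, str]] = []
        rows += [("fixed", c, str(p), "") for c, p in self.fixed_sites]
        rows += [("sex", c, str(p), "") for c, p in self.sex_sites]
        rows += [("sex_window", c, str(w), "") for c, w in self.sex_windows]
        rows += [("noise", c, str(p), "") for c, p in self.noise_sites]
        rows += [("decoy", c, str(p), "") for c, p in self.decoy_sites]
        for sex, sites in self.exclusive_positions.items():
            rows += [("exclusive", c, str(p), sex) for c, p in sites]
        rows += [
            ("cluster_gene", c, str(w), label)
            for (c, w), label in self.cluster_genes.items()
        ]
        rows += [
            ("ortholog", pid, str(syn), str(nonsyn))
            for pid, (syn, nonsyn) in self.ortholog_truth.items()
        ]
        rows.sort()
        with open(path, "w") as fh:
            fh.write("category\tkey1\tkey2\tvalue\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthSet":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("category")
            for line in fh:
                cat, k1, k2, val = line.rstrip("\n").split("\t")
                if cat == "fixed":
                    truth.fixed_sites.add((k1, int(k2)))
                elif cat == "sex":
                    truth.sex_sites.add((k1, int(k2)))
                elif cat == "sex_window":
                    truth.sex_windows.add((k1, int(k2)))
                elif cat == "noise":
                    truth.noise_sites.add((k1, int(k2)))
                elif cat == "decoy":
                    truth.decoy_sites.add((k1, int(k2)))
                elif cat == "exclusive":
                    truth.exclusive_positions.setdefault(val, set()).add((k1, int(k2)))
                elif cat == "cluster_gene":
                    truth.cluster_genes[(k1, int(k2))] = val
                elif cat == "ortholog":
                    truth.ortholog_truth[k1] = (int(k2), int(val))
                else:
                    raise ValueError(f"unknown truth category {cat!r}")
        return truth


def _truth_nearest_gene(
    contig: str, span: tuple[int, int], genes: Iterable[GeneInterval]
) -> str:
    """All-pairs minimisation of the gap between a 1-based inclusive span
    and each gene; ties to the coordinate-first gene. Kept deliberately
    independent of the peak-calling module's search."""
    qstart, qend = span
    best_label = ""
    best = None
    for g in sorted(
        (g for g in genes if g.contig == contig), key=lambda g: (g.start, g.end)
    ):
        if g.start < qend and qstart <= g.end:
            d = 0
        elif g.end <= qstart:
            d = qstart - g.end
        else:
            d = max(1, g.start - qend)
        if best is None or d < best:
            best, best_label = d, g.label
    return best_label


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """File bundle for one simulated cohort."""

    config: SimulationConfig
    vcf_paths: dict[str, Path]
    depth_paths: dict[str, Path]
    truth: TruthSet

    @property
    def male_samples(self) -> list[str]:
        return [s for s in self.vcf_paths if self.config.sex_of[s] == MALE]

    @property
    def female_samples(self) -> list[str]:
        return [s for s in self.vcf_paths if self.config.sex_of[s] == FEMALE]


_VCF_QUAL_PASS_LO = 31.0  # pass-record QUAL drawn in [31, 100): safely > 30
_VCF_QUAL_PASS_HI = 100.0


def _write_vcf(
    path: Path,
    sample: str,
    contig_lengths: dict[str, int],
    records: list[tuple[str, int, str, str, float, str]],
) -> None:
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for contig, pos, ref, alt, qual, gt in records:
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual:.2f}\t.\t.\tGT\t{gt}\n"
            )


def generate_cohort(
    config: SimulationConfig, reference: Reference, out_dir: str | Path
) -> Cohort:
    """Emit per-sample VCFs and dense depth tables with planted truth.

    See the module docstring for the planted categories. Depth tables cover
    every reference position of every sample (``samtools depth -aa``
    semantics); VCFs are sorted, biallelic, single-sample, GT-only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed % (2**31), 1])
    samples = config.sample_names
    males = [s for s in samples if config.sex_of[s] == MALE]
    females = [s for s in samples if config.sex_of[s] == FEMALE]
    truth = TruthSet()
    # per-sample variant records: (contig, pos, ref, alt, qual, gt)
    recs: dict[str, list[tuple[str, int, str, str, float, str]]] = {
        s: [] for s in samples
    }

    def pass_qual() -> float:
        return round(float(rng.uniform(_VCF_QUAL_PASS_LO, _VCF_QUAL_PASS_HI)), 2)

    def snp_alt(contig: str, pos: int) -> tuple[str, str]:
        ref_base = reference.sequences[contig][pos - 1]
        choices = [b for b in "ACGT" if b != ref_base]
        return ref_base, choices[int(rng.integers(0, 3))]

    # -- reserved regions keep truth categories separable
    reserved: dict[str, np.ndarray] = {
        c: np.zeros(config.contig_length_bp, dtype=bool) for c in config.contig_names
    }
    for contig, start, _n in config.planted_clusters:
        reserved[contig][start - 1 : start - 1 + WINDOW_BP] = True
    for contig, start, end, _sex in config.sex_exclusive_blocks:
        reserved[contig][start - 1 : end] = True

    # -- species-fixed sites: 1/1 in every sample
    for contig in config.contig_names:
        r = rng.random(config.contig_length_bp)
        hits = np.flatnonzero((r < config.fixed_diff_rate) & ~reserved[contig]) + 1
        for pos in hits.tolist():
            if rng.random() < config.indel_fraction:
                ref_base = reference.sequences[contig][pos - 1]
                if rng.random() < 0.5 and pos < config.contig_length_bp:
                    ref, alt = reference.sequences[contig][pos - 1 : pos + 1], ref_base
                else:
                    ref, alt = ref_base, ref_base + str(_BASES[int(rng.integers(0, 4))])
            else:
                ref, alt = snp_alt(contig, pos)
            truth.fixed_sites.add((contig, pos))
            for s in samples:
                recs[s].append((contig, pos, ref, alt, pass_qual(), "1/1"))

    # -- background heterozygous noise: one random sample per site
    fixed_mask = {c: np.zeros(config.contig_length_bp, dtype=bool) for c in config.contig_names}
    for contig, pos in truth.fixed_sites:
        fixed_mask[contig][pos - 1] = True
    for contig in config.contig_names:
        r = rng.random(config.contig_length_bp)
        hits = (
            np.flatnonzero(
                (r < config.background_het_rate * len(samples))
                & ~reserved[contig]
                & ~fixed_mask[contig]
            )
            + 1
        )
        for pos in hits.tolist():
            ref, alt = snp_alt(contig, pos)
            s = samples[int(rng.integers(0, len(samples)))]
            truth.noise_sites.add((contig, pos))
            recs[s].append((contig, pos, ref, alt, pass_qual(), "0/1"))

    # -- low-QUAL decoys (QUAL in [0, 30], one exact-30 boundary record)
    pool = [
        (contig, int(pos))
        for contig in config.contig_names
        for pos in (
            np.flatnonzero(~reserved[contig] & ~fixed_mask[contig]) + 1
        ).tolist()
        if (contig, int(pos)) not in truth.noise_sites
    ]
    if config.n_lowqual_decoys > len(pool):
        raise ConfigurationError("not enough free positions for decoys")
    if config.n_lowqual_decoys:
        idx = rng.choice(len(pool), size=config.n_lowqual_decoys, replace=False)
        for k, i in enumerate(sorted(idx.tolist())):
            contig, pos = pool[i]
            ref, alt = snp_alt(contig, pos)
            qual = 30.0 if k == 0 else round(float(rng.uniform(0.0, 30.0)), 2)
            gt = "0/1" if rng.random() < 0.5 else "1/1"
            s = samples[int(rng.integers(0, len(samples)))]
            truth.decoy_sites.add((contig, pos))
            recs[s].append((contig, pos, ref, alt, qual, gt))

    # -- planted sex-associated clusters
    for contig, start, n in config.planted_clusters:
        window_index = (start - 1) // WINDOW_BP
        truth.sex_windows.add((contig, window_index))
        offsets = rng.choice(WINDOW_BP, size=n, replace=False)
        positions = sorted(start + int(o) for o in offsets)
        for pos in positions:
            ref, alt = snp_alt(contig, pos)
            truth.sex_sites.add((contig, pos))
            for s in males:
                recs[s].append((contig, pos, ref, alt, pass_qual(), "1/1"))
            for s in females:
                if rng.random() < 0.5:  # explicit 0/1 vs recordless, 50/50
                    recs[s].append((contig, pos, ref, alt, pass_qual(), "0/1"))
        span = (min(positions), max(positions))
        truth.cluster_genes[(contig, window_index)] = _truth_nearest_gene(
            contig, span, reference.genes
        )

    # -- depth tables
    clamp_mask = {
        c: fixed_mask[c].copy() for c in config.contig_names
    }  # clamp >= 3 at every planted variant site
    for contig, pos in truth.sex_sites:
        clamp_mask[contig][pos - 1] = True
    depth_paths: dict[str, Path] = {}
    forced_by_sex = {MALE: males[:3], FEMALE: females[:3]}
    for s in samples:
        sex = config.sex_of[s]
        depths: dict[str, np.ndarray] = {}
        for contig in config.contig_names:
            d = rng.poisson(config.mean_depth, size=config.contig_length_bp).astype(
                np.int64
            )
            d[clamp_mask[contig]] = np.maximum(d[clamp_mask[contig]], 3)
            depths[contig] = d
        for contig, start, end, zero_sex in config.sex_exclusive_blocks:
            sl = slice(start - 1, end)
            if sex == zero_sex:
                depths[contig][sl] = 0
            elif s in forced_by_sex[sex]:
                depths[contig][sl] = np.maximum(depths[contig][sl], 10)
        path = out_dir / f"{s}.depth.tsv"
        write_depth_table(depths, path)
        depth_paths[s] = path
    for contig, start, end, zero_sex in config.sex_exclusive_blocks:
        truth.exclusive_positions[zero_sex].update(
            (contig, p) for p in range(start, end + 1)
        )

    # -- VCFs
    vcf_paths: dict[str, Path] = {}
    for s in samples:
        path = out_dir / f"{s}.vcf"
        _write_vcf(path, s, reference.contig_lengths, recs[s])
        vcf_paths[s] = path

    truth.save(out_dir / "truth.tsv")
    return Cohort(config=config, vcf_paths=vcf_paths, depth_paths=depth_paths, truth=truth)


# ---------------------------------------------------------------------------
# ortholog pairs


_SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)


def _single_nt_neighbours(codon: str) -> list[str]:
    out = []
    for i in range(3):
        for b in "ACGT":
            if b != codon[i]:
                out.append(codon[:i] + b + codon[i + 1 :])
    return out


def _mutation_candidates(codon: str, synonymous: bool) -> list[str]:
    """Single-nucleotide, non-stop neighbours of ``codon`` in the requested
    class (synonymous keeps the amino acid, nonsynonymous changes it)."""
    aa = CODON_TO_AA[codon]
    return [
        m
        for m in _single_nt_neighbours(codon)
        if m not in STOP_CODONS and (CODON_TO_AA[m] == aa) == synonymous
    ]


@dataclass
class OrthologPair:
    pair_id: str
    cds_a: str
    cds_b: str
    planted_syn: int
    planted_nonsyn: int


@dataclass
class OrthologSet:
    pairs: list[OrthologPair]

    @property
    def truth(self) -> dict[str, tuple[int, int]]:
        return {p.pair_id: (p.planted_syn, p.planted_nonsyn) for p in self.pairs}

    def write_fastas(self, cds_path: str | Path, protein_path: str | Path) -> None:
        from .dnds import translate

        with open(cds_path, "w") as fc, open(protein_path, "w") as fp:
            for p in self.pairs:
                for suffix, cds in (("a", p.cds_a), ("b", p.cds_b)):
                    fc.write(f">{p.pair_id}_{suffix}\n{cds}\n")
                    fp.write(f">{p.pair_id}_{suffix}\n{translate(cds)}\n")


def generate_ortholog_pairs(
    config: SimulationConfig,
    n_pairs: int | None = None,
    planted: Iterable[tuple[int, int]] | None = None,
) -> OrthologSet:
    """CDS pairs with a recorded number of synonymous-only and
    nonsynonymous-only single-nucleotide codon mutations.

    Sequence A is random sense codons (stop-free); sequence B applies
    ``planted`` (syn, nonsyn) mutation counts - drawn uniformly in 0..5
    each when not given - to distinct codons, each verified against the
    standard genetic code. Codons with no available mutation of the
    requested class (e.g. ATG/TGG for synonymous) are skipped and another
    codon drawn; the rare exhaustion is logged and the pair regenerated.
    """
    if config.gene_length_bp % 3:
        raise ConfigurationError("gene_length_bp must be divisible by 3")
    rng = np.random.default_rng([config.seed % (2**31), 2])
    n_pairs = n_pairs if n_pairs is not None else config.n_ortholog_pairs
    planted_list = list(planted) if planted is not None else [
        (int(rng.integers(0, 6)), int(rng.integers(0, 6))) for _ in range(n_pairs)
    ]
    if len(planted_list) != n_pairs:
        raise ConfigurationError("planted counts must match n_pairs")
    n_codons = config.gene_length_bp // 3
    pairs: list[OrthologPair] = []
    for i, (n_syn, n_nonsyn) in enumerate(planted_list):
        if n_syn + n_nonsyn > n_codons:
            raise ConfigurationError("more planted mutations than codons")
        for attempt in range(10):
            codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
            codons_a = [_SENSE_CODONS[j] for j in codon_idx.tolist()]
            codons_b = list(codons_a)
            order = rng.permutation(n_codons).tolist()
            cursor = 0
            ok = True
            for synonymous, count in ((True, n_syn), (False, n_nonsyn)):
                placed = 0
                while placed < count:
                    if cursor >= n_codons:
                        ok = False
                        break
                    j = order[cursor]
                    cursor += 1
                    cands = _mutation_candidates(codons_a[j], synonymous)
                    if not cands:
                        continue
                    codons_b[j] = cands[int(rng.integers(0, len(cands)))]
                    placed += 1
                if not ok:
                    break
            if ok:
                pairs.append(
                    OrthologPair(
                        pair_id=f"pair_{i + 1}",
                        cds_a="".join(codons_a),
                        cds_b="".join(codons_b),
                        planted_syn=n_syn,
                        planted_nonsyn=n_nonsyn,
                    )
                )
                break
            logger.info("ortholog pair %d: mutation classes exhausted, regenerating", i)
        else:  # pragma: no cover - 10 failures at these sizes is unreachable
            raise ConfigurationError(f"could not place mutations for pair {i + 1}")
    return OrthologSet(pairs=pairs)
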