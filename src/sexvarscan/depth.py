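"""Per-position read-depth tables: parsing, coverage summaries and
sex-exclusive coverage calls.

Depth tables follow ``samtools depth -aa`` semantics: one row per reference
position per sample, tab-separated ``contig  position(1-based)  depth``,
including zero-depth positions, sorted by contig then position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DepthFormatError(ValueError):
    """Malformed depth table: gap, duplicate, unsorted or unparsable row."""


def parse_depth_table(path: str | Path) -> dict[str, np.ndarray]:
    """Parse one sample's dense depth table into per-contig depth arrays.

    Returns a mapping ``contig -> int64 array`` where index ``i`` holds the
    depth at 1-based position ``i + 1``. Positions must be dense (1..L with
    no gap or duplicate) and rows sorted by contig then position; violations
    raise :class:`DepthFormatError` naming the contig and position.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": np.int64, "depth": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DepthFormatError(f"{path}: unparsable depth table: {exc}") from exc
    if (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise DepthFormatError(f"{path}: negative depth at {bad.contig}:{bad.pos}")

    out: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    for contig, sub in df.groupby("contig", sort=False):
        if contig in seen:  # pragma: no cover - groupby(sort=False) keeps blocks
            raise DepthFormatError(f"{path}: contig {contig} split into multiple blocks")
        seen.add(contig)
        pos = sub["pos"].to_numpy()
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            i = int(np.argmax(pos != expected))
            raise DepthFormatError(
                f"{path}: contig {contig}: expected position {expected[i]} "
                f"at row {i + 1}, found {pos[i]} (gap, duplicate or unsorted input)"
            )
        out[contig] = sub["depth"].to_numpy()
    return out


def write_depth_table(depths: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-contig depth arrays as a dense samtools-depth-style TSV."""
    with open(path, "w") as fh:
        for contig in depths:
            d = depths[contig]
            block = pd.DataFrame(
                {"contig": contig, "pos": np.arange(1, len(d) + 1), "depth": d}
            )
            block.to_csv(fh, sep="\t", header=False, index=False)


@dataclass
class DepthMatrix:
    """Dense per-contig, per-position, per-sample read depths.

    ``depth[contig]`` is an ``(n_samples, contig_length)`` integer array;
    row order follows ``samples``.
    """

    samples: list[str]
    depth: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_files(cls, tables: Mapping[str, str | Path]) -> "DepthMatrix":
        """Build a matrix from ``{sample: depth_table_path}``.

        All samples must cover identical contigs at identical lengths.
        """
        samples = list(tables)
        per_sample = {s: parse_depth_table(tables[s]) for s in samples}
        first = per_sample[samples[0]]
        depth: dict[str, np.ndarray] = {}
        for contig, arr in first.items():
            rows = []
            for s in samples:
                other = per_sample[s]
                if contig not in other or len(other[contig]) != len(arr):
                    raise DepthFormatError(
                        f"sample {s}: contig {contig} missing or length mismatch"
                    )
                rows.append(other[contig])
            depth[contig] = np.vstack(rows)
        for s in samples:
            extra = set(per_sample[s]) - set(first)
            if extra:
                raise DepthFormatError(f"sample {s} has extra contigs: {sorted(extra)}")
        return cls(samples=samples, depth=depth)

    def sample_index(self, samples: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.samples.index(s) for s in samples])
        except ValueError as exc:
            raise KeyError(f"sample not present in depth matrix: {exc}") from exc

    def depth_at(self, contig: str, pos: int) -> np.ndarray:
        """Depths of all samples at 1-based ``pos``; KeyError/IndexError on miss."""
        arr = self.depth[contig]
        if not 1 <= pos <= arr.shape[1]:
            raise IndexError(f"position {contig}:{pos} outside depth matrix")
        return arr[:, pos - 1]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: a.shape[1] for c, a in self.depth.items()}


@dataclass
class CoverageSummary:
    """Coverage statistics for one sample or a pooled group of samples."""

    name: str
    total_positions: int
    covered_fraction: float
    mean_depth: float
    #: depth value -> number of positions at that depth
    depth_histogram: dict[int, int]


def coverage_summary(
    matrix: DepthMatrix,
    group: Sequence[str],
    name: str | None = None,
    min_depth: int = 1,
) -> CoverageSummary:
    """Coverage fraction, mean depth and depth histogram for a sample group.

    Group depth at a position is the arithmetic sum over member samples
    (equivalent to pooling the alignments). A position counts as covered
    when its group depth is >= ``min_depth``.
    """
    if not group:
        raise ValueError("coverage_summary: group must be non-empty")
    idx = matrix.sample_index(group)
    total = 0
    covered = 0
    depth_sum = 0
    hist: dict[int, int] = {}
    for contig, arr in matrix.depth.items():
        pooled = arr[idx].sum(axis=0)
        total += pooled.size
        covered += int((pooled >= min_depth).sum())
        depth_sum += int(pooled.sum())
        values, counts = np.unique(pooled, return_counts=True)
        for v, c in zip(values.tolist(), counts.tolist()):
            hist[v] = hist.get(v, 0) + c
    return CoverageSummary(
        name=name or "+".join(group),
        total_positions=total,
        covered_fraction=covered / total if total else 0.0,
        mean_depth=depth_sum / total if total else 0.0,
        depth_histogram=dict(sorted(hist.items())),
    )


@dataclass(frozen=True)
class SexExclusiveSite:
    """A position with zero depth in every sample of one sex and strong
    coverage in the other."""

    contig: str
    pos: int
    zero_sex: str
    supporting_samples: int


def sex_exclusive_positions(
    matrix: DepthMatrix,
    zero_samples: Sequence[str],
    covered_samples: Sequence[str],
    zero_sex: str = "female",
    min_depth: int = 10,
    min_samples: int = 3,
) -> tuple[list[SexExclusiveSite], int]:
    """Positions where all ``zero_samples`` have depth 0 and at least
    ``min_samples`` of ``covered_samples`` have depth >= ``min_depth``.

    Returns the qualifying sites and the number of distinct contigs that
    contain at least one such site.
    """
    if not zero_samples or not covered_samples:
        raise ValueError("both sample groups must be non-empty")
    if set(zero_samples) & set(covered_samples):
        raise ValueError("zero and covered sample groups must be disjoint")
    zi = matrix.sample_index(zero_samples)
    ci = matrix.sample_index(covered_samples)
    sites: list[SexExclusiveSite] = []
    contigs: set[str] = set()
    for contig in matrix.depth:
        arr = matrix.depth[contig]
        all_zero = (arr[zi] == 0).all(axis=0)
        support = (arr[ci] >= min_depth).sum(axis=0)
        hit = np.flatnonzero(all_zero & (support >= min_samples))
        if hit.size:
            contigs.add(contig)
        for i in hit.tolist():
            sites.append(
                SexExclusiveSite(
                    contig=contig,
                    pos=i + 1,
                    zero_sex=zero_sex,
                    supporting_samples=int(support[i]),
                )
            )
    return sites, len(contigs)


def summaries_to_frame(summaries: Iterable[CoverageSummary]) -> pd.DataFrame:
    rows = [
        {
            "group": s.name,
            "total_positions": s.total_positions,
            "covered_fraction": s.covered_fraction,
            "mean_depth": s.mean_depth,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
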