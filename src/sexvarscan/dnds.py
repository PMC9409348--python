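"""Pairwise dN/dS by the Nei-Gojobori (1986) counting method.

Workflow mirrors the standard protein-guided pipeline: a pairwise protein
alignment is back-translated onto the source CDS, every alignment column
containing a gap is removed (``pal2nal -nogap`` semantics), and synonymous /
nonsynonymous sites and differences are counted per codon, averaging
multi-difference codons over all minimal substitution pathways with equal
weights. Proportions are corrected for multiple hits with the Jukes-Cantor
formula d = -(3/4) ln(1 - (4/3) p).

Conventions (the counting method leaves them open; both are pinned by
tests): a single-nucleotide change that creates a stop codon counts as
nonsynonymous in the site tally, which keeps S + N = 3 x (codon count)
exact; pathway steps through stop codons likewise count as nonsynonymous
and no pathway is discarded. Ambiguity codes are rejected outright -
pathway counting is undefined for ambiguous codons.

Estimates are filtered on dS plausibility (default: keep 0.01 <= dS <= 2;
closer pairs are too similar, more distant ones too saturated, for a
reliable ratio) and classified against omega = 1: > 1 adaptive, < 1
purifying, = 1 neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"

#: codon -> amino acid, stop codons mapped to "*"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class AlignmentError(ValueError):
    pass


def translate(cds: str) -> str:
    """Translate an ungapped CDS with the standard code ('*' for stops)."""
    if len(cds) % 3:
        raise AlignmentError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon not in CODON_TO_AA:
            raise AlignmentError(f"unsupported codon {codon!r} at position {i + 1}")
        aas.append(CODON_TO_AA[codon])
    return "".join(aas)


@dataclass
class CodonAlignment:
    """Two gap-free aligned CDS of equal length divisible by 3."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentError("aligned CDS lengths differ")
        if len(self.seq_a) % 3:
            raise AlignmentError("aligned CDS length not divisible by 3")
        for name, seq in (("a", self.seq_a), ("b", self.seq_b)):
            prot = translate(seq)
            if "*" in prot[:-1]:
                raise AlignmentError(
                    f"sequence {name}: internal stop codon at residue "
                    f"{prot.index('*') + 1}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def codon_align(
    prot_a: str,
    prot_b: str,
    cds_a: str,
    cds_b: str,
    pair_id: str = "pair",
) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its CDS, dropping every
    column in which either protein has a gap.

    Each ungapped protein must equal the translation of its CDS (terminal
    stop codons are stripped from the CDS first); the first discordant
    residue is named on mismatch.
    """
    if len(prot_a) != len(prot_b):
        raise AlignmentError("aligned protein lengths differ")
    cds_a = _strip_terminal_stop(cds_a.upper())
    cds_b = _strip_terminal_stop(cds_b.upper())
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0  # codon cursors into each CDS
    for col, (ra, rb) in enumerate(zip(prot_a.upper(), prot_b.upper()), start=1):
        codon_a = codon_b = None
        if ra != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            if len(codon_a) < 3:
                raise AlignmentError(f"CDS a shorter than protein a implies")
            if CODON_TO_AA.get(codon_a) != ra:
                raise AlignmentError(
                    f"protein a residue {ia + 1} ({ra}) does not match codon "
                    f"{codon_a} ({CODON_TO_AA.get(codon_a)})"
                )
            ia += 1
        if rb != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            if len(codon_b) < 3:
                raise AlignmentError(f"CDS b shorter than protein b implies")
            if CODON_TO_AA.get(codon_b) != rb:
                raise AlignmentError(
                    f"protein b residue {ib + 1} ({rb}) does not match codon "
                    f"{codon_b} ({CODON_TO_AA.get(codon_b)})"
                )
            ib += 1
        if ra != "-" and rb != "-":
            out_a.append(codon_a)  # type: ignore[arg-type]
            out_b.append(codon_b)  # type: ignore[arg-type]
    if ia * 3 < len(cds_a) or ib * 3 < len(cds_b):
        raise AlignmentError("CDS longer than its aligned protein implies")
    return CodonAlignment(pair_id=pair_id, seq_a="".join(out_a), seq_b="".join(out_b))


def synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon: at each position, the
    fraction of the three possible single-nucleotide changes that preserve
    the amino acid (changes to stop codons count as nonsynonymous)."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over every minimal substitution pathway."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_sd = total_nd = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        for i in order:
            nxt = current[:i] + codon_b[i] + current[i + 1 :]
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        total_sd += sd
        total_nd += nd
        n_paths += 1
    return total_sd / n_paths, total_nd / n_paths


@dataclass
class NGCounts:
    """Per-pair synonymous/nonsynonymous site and difference counts."""

    S: float
    N: float
    Sd: float
    Nd: float


@dataclass
class DnDsResult:
    pair_id: str
    counts: NGCounts
    dN: float | None
    dS: float | None
    omega: float | None
    #: True when the Jukes-Cantor correction was undefined (p >= 3/4) for
    #: dN or dS; the raw proportions are retained in pN/pS
    saturated: bool
    pN: float
    pS: float
    kept_by_ds_filter: bool | None = None

    @property
    def selection_class(self) -> str:
        return classify_selection(self.omega)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(alignment: CodonAlignment) -> DnDsResult:
    """Nei-Gojobori counting estimate of dN, dS and omega for one pair.

    Sites are averaged over both sequences; differences are pathway-averaged
    per codon; pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected. omega is
    dN/dS when dS > 0 and None otherwise (including dS = 0 for identical
    synonymous content and saturated correction).
    """
    S = Sd = Nd = 0.0
    for ca, cb in alignment.codons():
        S += 0.5 * (synonymous_site_fraction(ca) + synonymous_site_fraction(cb))
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * alignment.n_codons - S
    counts = NGCounts(S=S, N=N, Sd=Sd, Nd=Nd)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    saturated = (dS is None and pS > 0) or (dN is None and pN > 0)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DnDsResult(
        pair_id=alignment.pair_id,
        counts=counts,
        dN=dN,
        dS=dS,
        omega=omega,
        saturated=saturated,
        pN=pN,
        pS=pS,
    )


def ds_filter(
    results: Iterable[DnDsResult], lo: float = 0.01, hi: float = 2.0
) -> tuple[list[DnDsResult], list[DnDsResult]]:
    """Split results into (kept, dropped) on dS plausibility.

    Keeps results with lo <= dS <= hi inclusive (the published rule drops
    dS < 0.01 or > 2, so exactly 0.01 and exactly 2 survive); results with
    undefined dS are dropped. ``kept_by_ds_filter`` is stamped on every
    result.
    """
    if lo >= hi:
        raise ValueError("ds_filter: lo must be < hi")
    kept: list[DnDsResult] = []
    dropped: list[DnDsResult] = []
    for r in results:
        ok = r.dS is not None and lo <= r.dS <= hi
        r.kept_by_ds_filter = ok
        (kept if ok else dropped).append(r)
    return kept, dropped


def classify_selection(omega: float | None) -> str:
    """'adaptive' (omega > 1), 'purifying' (< 1), 'neutral' (= 1), or
    'undefined' when omega itself is undefined (never silently purifying)."""
    if omega is None:
        return "undefined"
    if omega > 1:
        return "adaptive"
    if omega < 1:
        return "purifying"
    return "neutral"
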