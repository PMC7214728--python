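"""SpCas9 target-site (CTS) enumeration and filtering inside a CTL region.

Candidate sites are NGG PAMs with a 17-24 nt protospacer; the blunt cut is
modelled 3 bp 5' of the PAM (standard SpCas9 geometry).  A site is kept
when it is (1) at least 2 kb from any known gene, (2) unique in the genome
as an exact protospacer+PAM match on either strand, (3) flanked by unique
200-500 bp sequences (these flanks double as the HDR homology arms and the
outer PCR primer landing zones), and (4) spaced >=0.1 cM from other kept
sites so stacked insertions remain separable by crossing.  Off-target risk
is screened with the seed rule: over every other NGG locus genome-wide the
10 protospacer bases adjacent to the PAM (position 1 = PAM-proximal) must
differ at >=2 positions.

The uniqueness and seed scans have vectorised implementations
(:class:`~ctlforge._seqindex.SequenceIndex`, :class:`PamSeedScanner`); the
test suite holds them to exact agreement with brute-force scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seqindex import SequenceIndex, revcomp
from .genome_io import GeneModel, GenomeAssembly, GeneticMap, GenomicRegion

__all__ = [
    "CtsCandidate",
    "CtsFilterParams",
    "PamSeedScanner",
    "find_pam_sites",
    "distance_to_nearest_gene",
    "site_and_flank_uniqueness",
    "seed_offtarget_scan",
    "select_spaced_cts",
    "select_cts",
]


@dataclass(frozen=True)
class CtsCandidate:
    """A protospacer+PAM locus with its filter metrics.

    ``pam_start`` is the forward-strand coordinate of the PAM triplet's
    first base; ``cut_bp`` the 0-based boundary index of the blunt cut.
    ``protospacer`` and ``pam`` read 5'->3' on the protospacer strand.
    """

    chrom: str
    pam_start: int
    strand: str
    protospacer: str
    pam: str
    cut_bp: int
    cm: float | None = None
    dist_to_gene: int | None = None
    site_unique: bool | None = None
    flank_unique: bool | None = None
    min_seed_mismatches: int | None = None

    def __post_init__(self) -> None:
        if not 17 <= len(self.protospacer) <= 24:
            raise ValueError("protospacer length must be in [17, 24]")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def site_interval(self) -> tuple[int, int]:
        """Forward-strand half-open interval covered by protospacer+PAM."""
        n = len(self.protospacer) + 3
        if self.strand == "+":
            return self.pam_start - len(self.protospacer), self.pam_start + 3
        return self.pam_start, self.pam_start + n

    @property
    def site_seq_forward(self) -> str:
        """Protospacer+PAM as it reads on the forward genome strand."""
        seq = self.protospacer + self.pam
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def seed(self) -> str:
        """The 10 PAM-proximal protospacer bases, 5'->3'."""
        return self.protospacer[-10:]


@dataclass
class CtsFilterParams:
    """Filter thresholds for CTS selection (seed = 1-10 bp 5' of the PAM)."""

    spacer_len: int = 20
    min_gene_distance_bp: int = 2000
    flank_len_bp: int = 400
    seed_len: int = 10
    min_seed_mm: int = 2
    min_spacing_cm: float = 0.1
    max_spacing_cm: float = 3.0
    pam_rule: str = "NGG"  # "NGG" or "NGG+NAG" for off-target loci

    def __post_init__(self) -> None:
        if not 200 <= self.flank_len_bp <= 500:
            raise ValueError("flank_len_bp must be in [200, 500]")
        if not 17 <= self.spacer_len <= 24:
            raise ValueError("spacer_len must be in [17, 24]")
        if self.pam_rule not in {"NGG", "NGG+NAG"}:
            raise ValueError("pam_rule must be 'NGG' or 'NGG+NAG'")


def find_pam_sites(
    assembly: GenomeAssembly, region: GenomicRegion, spacer_len: int = 20
) -> list[CtsCandidate]:
    """Enumerate unfiltered NGG candidates on both strands of a region.

    A candidate needs ``spacer_len`` protospacer bases inside the region;
    candidates whose protospacer or PAM contains N are dropped.
    """
    if not 17 <= spacer_len <= 24:
        raise ValueError("spacer_len must be in [17, 24]")
    chrom_seq = assembly.sequences[region.chrom]
    if region.start_bp < 0 or region.end_bp > len(chrom_seq):
        raise ValueError("region outside chromosome")
    seq = chrom_seq[region.start_bp : region.end_bp]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out: list[CtsCandidate] = []
    G, C = ord("G"), ord("C")
    # plus strand: GG at pam_start+1, pam_start+2
    gg = np.flatnonzero((arr[1:-1] == G) & (arr[2:] == G))  # local pam_start
    for p in gg:
        p = int(p)
        if p - spacer_len < 0 or p + 3 > len(seq):
            continue
        protospacer = seq[p - spacer_len : p]
        pam = seq[p : p + 3]
        if "N" in protospacer or "N" in pam:
            continue
        gp = region.start_bp + p
        out.append(
            CtsCandidate(region.chrom, gp, "+", protospacer, pam, cut_bp=gp - 3)
        )
    # minus strand: forward CC at pam_start, pam_start+1
    cc = np.flatnonzero((arr[:-1] == C) & (arr[1:] == C))
    for p in cc:
        p = int(p)
        if p + 3 + spacer_len > len(seq):
            continue
        fwd = seq[p : p + 3 + spacer_len]
        if "N" in fwd:
            continue
        site = revcomp(fwd)
        gp = region.start_bp + p
        out.append(
            CtsCandidate(region.chrom, gp, "-", site[:spacer_len], site[spacer_len:], cut_bp=gp + 6)
        )
    out.sort(key=lambda c: (c.pam_start, c.strand))
    return out


def distance_to_nearest_gene(candidate: CtsCandidate, genes: list[GeneModel]) -> int:
    """Minimum bp gap between the cut position and any gene (0 if inside)."""
    best: int | None = None
    for g in genes:
        if g.chrom != candidate.chrom:
            continue
        c = candidate.cut_bp
        if g.start <= c < g.end:
            return 0
        d = g.start - c if c < g.start else c - g.end
        best = d if best is None else min(best, d)
    if best is None:
        # no gene on this chromosome: effectively unbounded distance
        return 10**12
    return best


def site_and_flank_uniqueness(
    assembly: GenomeAssembly,
    candidate: CtsCandidate,
    flank_len_bp: int = 400,
    index: SequenceIndex | None = None,
) -> tuple[bool, bool]:
    """Genome-wide exact-match uniqueness of the site and of both flanks.

    Both strands are counted; the candidate's own locus is the single
    allowed occurrence.  A flank running off the chromosome end makes
    ``flank_unique`` False (it could not serve as a full homology arm).
    """
    index = index or SequenceIndex(assembly)
    s, e = candidate.site_interval
    site_unique = index.count_both_strands(assembly.fetch(candidate.chrom, s, e)) == 1
    chrom_len = assembly.lengths[candidate.chrom]
    if s - flank_len_bp < 0 or e + flank_len_bp > chrom_len:
        return site_unique, False
    left = assembly.fetch(candidate.chrom, s - flank_len_bp, s)
    right = assembly.fetch(candidate.chrom, e, e + flank_len_bp)
    flank_unique = (
        index.count_both_strands(left) == 1 and index.count_both_strands(right) == 1
    )
    return site_unique, flank_unique


class PamSeedScanner:
    """All NGG (optionally NAG) loci of an assembly with their seed 10-mers.

    Seeds are stored 5'->3' on the PAM's strand, so a plain elementwise
    comparison against a candidate seed counts mismatches with position 1
    (PAM-proximal) aligned to position 1.
    """

    def __init__(self, assembly: GenomeAssembly, seed_len: int = 10, pam_rule: str = "NGG") -> None:
        self.seed_len = seed_len
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in zip(b"ACGTN", b"TGCAN"):
            comp[a] = b
        seeds, chroms, positions, strands = [], [], [], []
        second = [ord("G")] if pam_rule == "NGG" else [ord("G"), ord("A")]
        for ci, (name, seq) in enumerate(assembly.sequences.items()):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = arr.size
            if n < seed_len + 3:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, seed_len)
            G = ord("G")
            for mid in second:
                # plus strand: PAM = N, mid, G at p..p+2; seed = arr[p-10:p]
                plus = np.flatnonzero((arr[1:-1] == mid) & (arr[2:] == G))
                plus = plus[plus >= seed_len]
                if plus.size:
                    seeds.append(win[plus - seed_len])
                    chroms.append(np.full(plus.size, ci, dtype=np.int32))
                    positions.append(plus.astype(np.int64))
                    strands.append(np.zeros(plus.size, dtype=np.uint8))
                # minus strand: forward pattern comp(G), comp(mid) at p, p+1
                minus = np.flatnonzero((arr[:-1] == comp[G]) & (arr[1:] == comp[mid]))
                minus = minus[minus + 3 + seed_len <= n]
                if minus.size:
                    m = comp[win[minus + 3]][:, ::-1]  # revcomp -> 5'->3' on minus
                    seeds.append(m)
                    chroms.append(np.full(minus.size, ci, dtype=np.int32))
                    positions.append(minus.astype(np.int64))
                    strands.append(np.ones(minus.size, dtype=np.uint8))
        if seeds:
            self._seeds = np.concatenate(seeds, axis=0)
            self._chroms = np.concatenate(chroms)
            self._positions = np.concatenate(positions)
            self._strands = np.concatenate(strands)
        else:
            self._seeds = np.empty((0, seed_len), dtype=np.uint8)
            self._chroms = np.empty(0, dtype=np.int32)
            self._positions = np.empty(0, dtype=np.int64)
            self._strands = np.empty(0, dtype=np.uint8)
        self._chrom_index = {name: i for i, name in enumerate(assembly.sequences)}

    def min_mismatches(self, candidate: CtsCandidate) -> int:
        """Minimum seed Hamming distance to any other PAM-adjacent locus."""
        seed = candidate.protospacer[-self.seed_len :]
        q = np.frombuffer(seed.encode(), dtype=np.uint8)
        if self._seeds.shape[0] == 0:
            return self.seed_len
        mm = (self._seeds != q).sum(axis=1)
        own = (
            (self._chroms == self._chrom_index[candidate.chrom])
            & (self._positions == candidate.pam_start)
            & (self._strands == (0 if candidate.strand == "+" else 1))
        )
        mm = mm[~own]
        if mm.size == 0:
            return self.seed_len
        return int(mm.min())


def seed_offtarget_scan(
    assembly: GenomeAssembly,
    candidate: CtsCandidate,
    seed_len: int = 10,
    pam_rule: str = "NGG",
    scanner: PamSeedScanner | None = None,
) -> int:
    """Minimum seed mismatches versus every other PAM-adjacent genomic locus."""
    if len(candidate.protospacer) < seed_len:
        raise ValueError("protospacer shorter than the seed")
    scanner = scanner or PamSeedScanner(assembly, seed_len=seed_len, pam_rule=pam_rule)
    return scanner.min_mismatches(candidate)


def select_spaced_cts(
    candidates: list[CtsCandidate],
    min_spacing_cm: float = 0.1,
    target_count: int | None = None,
) -> list[CtsCandidate]:
    """Greedy left-to-right cM sweep keeping sites >= ``min_spacing_cm`` apart.

    Within each ``min_spacing_cm`` bin the site with the largest
    ``min_seed_mismatches`` wins, ties broken by larger gene distance, then
    leftmost bp.
    """
    pool = sorted(
        (c for c in candidates if c.cm is not None),
        key=lambda c: (c.cm, c.pam_start),
    )
    kept: list[CtsCandidate] = []
    i = 0
    while i < len(pool):
        if target_count is not None and len(kept) >= target_count:
            break
        bin_start = pool[i].cm
        j = i
        best = None
        while j < len(pool) and pool[j].cm < bin_start + min_spacing_cm:
            c = pool[j]
            key = (
                -(c.min_seed_mismatches if c.min_seed_mismatches is not None else -1),
                -(c.dist_to_gene if c.dist_to_gene is not None else -1),
                c.pam_start,
            )
            if best is None or key < best[0]:
                best = (key, c)
            j += 1
        kept.append(best[1])
        floor = best[1].cm + min_spacing_cm
        i = j
        while i < len(pool) and pool[i].cm < floor - 1e-12:
            i += 1
    return kept


def select_cts(
    assembly: GenomeAssembly,
    genes: list[GeneModel],
    gmap: GeneticMap,
    region: GenomicRegion,
    params: CtsFilterParams | None = None,
    target_count: int | None = None,
) -> list[CtsCandidate]:
    """Full CTS pipeline: enumerate, filter on all four criteria, space out.

    Filters are applied cheapest-first (gene distance, then exact
    uniqueness, then the seed off-target scan); the survivors are spaced
    by the greedy cM sweep.
    """
    params = params or CtsFilterParams()
    raw = find_pam_sites(assembly, region, spacer_len=params.spacer_len)
    near = [
        replace(c, dist_to_gene=distance_to_nearest_gene(c, genes))
        for c in raw
    ]
    near = [c for c in near if c.dist_to_gene >= params.min_gene_distance_bp]
    index = SequenceIndex(assembly)
    uniq: list[CtsCandidate] = []
    for c in near:
        su, fu = site_and_flank_uniqueness(assembly, c, params.flank_len_bp, index=index)
        if su and fu:
            uniq.append(replace(c, site_unique=su, flank_unique=fu))
    scanner = PamSeedScanner(assembly, seed_len=params.seed_len, pam_rule=params.pam_rule)
    passing: list[CtsCandidate] = []
    for c in uniq:
        mm = scanner.min_mismatches(c)
        if mm >= params.min_seed_mm:
            passing.append(
                replace(c, min_seed_mismatches=mm, cm=gmap.bp_to_cm(c.chrom, c.cut_bp).cm)
            )
    return select_spaced_cts(passing, params.min_spacing_cm, target_count=target_count)


def cts_to_frame(candidates: list[CtsCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in candidates],
            "pam_start": [c.pam_start for c in candidates],
            "strand": [c.strand for c in candidates],
            "protospacer": [c.protospacer for c in candidates],
            "pam": [c.pam for c in candidates],
            "cut_bp": [c.cut_bp for c in candidates],
            "cm": [c.cm for c in candidates],
            "dist_to_gene": [c.dist_to_gene for c in candidates],
            "min_seed_mismatches": [c.min_seed_mismatches for c in candidates],
        }
    )


def cts_to_bed(candidates: list[CtsCandidate]) -> str:
    """BED (0-based half-open) lines for the blunt cut positions."""
    lines = [
        f"{c.chrom}\t{c.cut_bp}\t{c.cut_bp + 1}\tcut_{c.pam_start}{c.strand}\t0\t{c.strand}"
        for c in candidates
    ]
    return "\n".join(lines) + ("\n" if lines else "")
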