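"""Genome assemblies, gene annotations, and genetic maps.

Coordinate conventions
----------------------
All positions are stored 0-based, half-open internally.  GFF3 input
(1-based, inclusive) is converted at the boundary.  Genetic maps are
per-chromosome anchor lists of (bp, cM) pairs with strictly increasing bp
and non-decreasing cM; conversion between physical and genetic position is
piecewise-linear between anchors.  Queries beyond the terminal anchors are
extrapolated with the terminal segment slope and flagged; cM plateaus
(zero-recombination stretches) are legal, and the inverse lookup of a
plateau cM value returns the plateau's left edge with an ambiguity flag.
Flags are part of the return value, not log noise, because downstream
spacing logic needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGTN")

__all__ = [
    "GenomeAssembly",
    "GeneModel",
    "GeneticMap",
    "GenomicRegion",
    "CmPosition",
    "BpPosition",
    "read_genome",
    "read_gff_genes",
    "read_genetic_map",
    "bp_to_cm",
    "cm_to_bp",
    "gene_density",
    "phys_gen_ratio",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of named chromosome sequences (A, C, G, T, N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-IUPAC characters: {sorted(bad)!r}"
                )

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the forward-strand sequence of [start, end) on ``chrom``."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.sequences[chrom]) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} "
                f"(length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) on a named chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


class CmPosition(NamedTuple):
    """A genetic position with its extrapolation flag."""

    cm: float
    extrapolated: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.cm


class BpPosition(NamedTuple):
    """A physical position; ``ambiguous`` marks a cM plateau hit."""

    bp: float
    extrapolated: bool
    ambiguous: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.bp


@dataclass
class GeneticMap:
    """Per-chromosome (bp, cM) anchors supporting bidirectional interpolation."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"{chrom}: a genetic map needs >=2 anchors")
            if bp.size != cm.size:
                raise ValueError(f"{chrom}: bp and cM anchor arrays differ in length")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"{chrom}: anchor bp positions must be strictly increasing")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"{chrom}: anchor cM positions must be non-decreasing")
            clean[chrom] = (bp, cm)
        self.anchors = clean

    @property
    def chrom_names(self) -> list[str]:
        return list(self.anchors)

    def _require(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        return self.anchors[chrom]

    def bp_to_cm(self, chrom: str, bp: float) -> CmPosition:
        xb, xc = self._require(chrom)
        if bp < xb[0]:
            slope = (xc[1] - xc[0]) / (xb[1] - xb[0])
            return CmPosition(float(xc[0] + slope * (bp - xb[0])), True)
        if bp > xb[-1]:
            slope = (xc[-1] - xc[-2]) / (xb[-1] - xb[-2])
            return CmPosition(float(xc[-1] + slope * (bp - xb[-1])), True)
        return CmPosition(float(np.interp(bp, xb, xc)), False)

    def cm_to_bp(self, chrom: str, cm: float) -> BpPosition:
        xb, xc = self._require(chrom)
        if cm < xc[0] or cm > xc[-1]:
            lo = cm < xc[0]
            i, j = (0, 1) if lo else (-2, -1)
            if xc[j] == xc[i]:
                raise ValueError(
                    f"{chrom}: cannot extrapolate {cm} cM across a flat terminal segment"
                )
            slope = (xb[j] - xb[i]) / (xc[j] - xc[i])
            anchor = (xb[0], xc[0]) if lo else (xb[-1], xc[-1])
            return BpPosition(float(anchor[0] + slope * (cm - anchor[1])), True, False)
        # leftmost anchor index with this cM or bracketing segment
        i = int(np.searchsorted(xc, cm, side="left"))
        if i < xc.size and xc[i] == cm:
            # exact anchor hit; a plateau extends right if the next anchor repeats cm
            ambiguous = i + 1 < xc.size and xc[i + 1] == cm
            return BpPosition(float(xb[i]), False, ambiguous)
        lo, hi = i - 1, i
        frac = (cm - xc[lo]) / (xc[hi] - xc[lo])
        return BpPosition(float(xb[lo] + frac * (xb[hi] - xb[lo])), False, False)


@dataclass(frozen=True)
class GenomicRegion:
    """An interval carrying both physical and genetic coordinates."""

    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        if not self.end_bp > self.start_bp:
            raise ValueError("region bp span must be positive")
        if self.end_cm < self.start_cm:
            raise ValueError("region cM span must be non-negative")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def span_cm(self) -> float:
        return self.end_cm - self.start_cm

    @classmethod
    def from_bp(cls, gmap: GeneticMap, chrom: str, start_bp: int, end_bp: int) -> "GenomicRegion":
        return cls(
            chrom,
            start_bp,
            end_bp,
            gmap.bp_to_cm(chrom, start_bp).cm,
            gmap.bp_to_cm(chrom, end_bp).cm,
        )

    @classmethod
    def from_cm(cls, gmap: GeneticMap, chrom: str, start_cm: float, end_cm: float) -> "GenomicRegion":
        s = gmap.cm_to_bp(chrom, start_cm)
        e = gmap.cm_to_bp(chrom, end_cm)
        return cls(chrom, int(round(s.bp)), int(round(e.bp)), start_cm, end_cm)


def read_genome(path) -> GenomeAssembly:
    """Load a FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased; duplicated record names and non-IUPAC
    characters are hard errors naming the offending record.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeAssembly(sequences)


def read_gff_genes(path, assembly: GenomeAssembly | None = None) -> list[GeneModel]:
    """Load ``gene`` features from a GFF3 file (1-based inclusive -> half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if assembly is not None and feat.seqid not in assembly.sequences:
            raise ValueError(f"gene {feat.id} on unknown chromosome {feat.seqid!r}")
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else "+",
            )
        )
    return genes


def read_genetic_map(path) -> GeneticMap:
    """Load a genetic map from a TSV with columns ``chrom``, ``bp``, ``cM``."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"genetic map must have columns {sorted(required)}")
    anchors = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("bp")
        anchors[str(chrom)] = (sub["bp"].to_numpy(float), sub["cM"].to_numpy(float))
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = [
        {"chrom": chrom, "bp": int(b), "cM": c}
        for chrom, (bp, cm) in gmap.anchors.items()
        for b, c in zip(bp, cm)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bp_to_cm(gmap: GeneticMap, chrom: str, bp: float) -> CmPosition:
    """Genetic position of ``bp`` by piecewise-linear anchor interpolation."""
    return gmap.bp_to_cm(chrom, bp)


def cm_to_bp(gmap: GeneticMap, chrom: str, cm: float) -> BpPosition:
    """Physical position of ``cm``; plateau queries return the left edge, flagged."""
    return gmap.cm_to_bp(chrom, cm)


def gene_density(genes: list[GeneModel], region: GenomicRegion) -> float:
    """Genes per cM: overlap count over the region's genetic span."""
    if region.span_cm <= 0:
        raise ValueError(
            "region has zero cM span; report a bp-based density instead"
        )
    n = sum(g.overlaps(region.chrom, region.start_bp, region.end_bp) for g in genes)
    return n / region.span_cm


def phys_gen_ratio(region: GenomicRegion) -> float:
    """Physical-to-genetic distance ratio in Mb/cM."""
    if region.span_cm <= 0:
        raise ValueError("region has zero cM span; ratio undefined")
    return (region.span_bp / 1e6) / region.span_cm
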