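"""Scan a genome for candidate complex-trait-locus (CTL) regions.

A CTL should sit in a stretch of chromosome that is (1) haplotype-conserved
within both the stiff-stalk (SS) and non-stiff-stalk (NSS) maize germplasm
pools, (2) gene-poor and outside breeding-relevant intervals, (3) highly
recombinogenic (low Mb/cM), and (4) ideally near an existing commercial
trait locus.  The scanner slides a 10-cM window along each chromosome,
enumerates 4-5 cM subregions, filters them against thresholds for criteria
1-3, marks criterion 4 as a score bonus, and returns a ranked,
overlap-merged candidate list.

"Conserved haplotype" is operationalised as identity to the pool's modal
haplotype label vector over the panel windows overlapping the region: the
simplest statistic that yields a single conservation percentage per pool,
which is how such regions are usually described.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneModel, GenomeAssembly, GeneticMap, GenomicRegion, gene_density, phys_gen_ratio

POOLS = ("SS", "NSS")

__all__ = [
    "HaplotypePanel",
    "CtlCandidate",
    "ScanParams",
    "conservation_fraction",
    "scan_ctl",
    "read_haplotype_panel",
    "read_trait_loci",
]


@dataclass
class HaplotypePanel:
    """Line x window haplotype labels for the SS and NSS germplasm pools.

    ``table`` columns: line, pool, chrom, window_start, window_end, haplotype.
    Windows must tile each chromosome without overlap and every line must
    carry a label for every window.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line", "pool", "chrom", "window_start", "window_end", "haplotype"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"haplotype panel missing columns {sorted(missing)}")
        pools = self.table.groupby("line")["pool"].nunique()
        if (pools > 1).any():
            bad = pools[pools > 1].index.tolist()
            raise ValueError(f"lines assigned to multiple pools: {bad}")
        unknown = set(self.table["pool"]) - set(POOLS)
        if unknown:
            raise ValueError(f"unknown pools {sorted(unknown)}; expected {POOLS}")
        # rectangular: every line labels every window
        counts = self.table.groupby("line").size()
        if counts.nunique() > 1:
            raise ValueError("label matrix is not rectangular across lines")
        # windows tile without overlap
        wins = self.table[["chrom", "window_start", "window_end"]].drop_duplicates()
        for chrom, sub in wins.groupby("chrom"):
            sub = sub.sort_values("window_start")
            if (sub["window_end"].to_numpy()[:-1] > sub["window_start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping panel windows on {chrom}")

    def pool_lines(self, pool: str) -> list[str]:
        return sorted(self.table.loc[self.table["pool"] == pool, "line"].unique())

    def labels_over(self, region: GenomicRegion, pool: str) -> pd.DataFrame:
        """Line x window label matrix for panel windows overlapping a region."""
        t = self.table
        sel = t[
            (t["chrom"] == region.chrom)
            & (t["window_start"] < region.end_bp)
            & (t["window_end"] > region.start_bp)
            & (t["pool"] == pool)
        ]
        if sel.empty:
            return pd.DataFrame()
        return sel.pivot(index="line", columns="window_start", values="haplotype").sort_index(
            axis=1
        )


@dataclass(frozen=True)
class CtlCandidate:
    region: GenomicRegion
    conservation_ss: float
    conservation_nss: float
    gene_density: float
    ratio_mb_per_cm: float
    known_trait_overlap: bool
    score: float


@dataclass
class ScanParams:
    """Thresholds and weights for the CTL scan.

    Defaults admit all four published CTL descriptor sets: the weakest
    reported pool conservation is 34%, the densest region 21 genes/cM, and
    the largest physical-to-genetic ratio 0.6 Mb/cM.
    """

    window_cm: float = 10.0
    region_min_cm: float = 4.0
    region_max_cm: float = 5.0
    step_cm: float = 0.5
    min_conservation: float = 0.3
    max_gene_density: float = 25.0
    max_ratio_mb_per_cm: float = 0.7
    w_conservation: float = 1.0
    w_density: float = 1.0
    w_ratio: float = 1.0
    trait_bonus: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.region_min_cm <= self.region_max_cm <= self.window_cm:
            raise ValueError("need 0 < region_min_cm <= region_max_cm <= window_cm")
        if self.step_cm <= 0:
            raise ValueError("step_cm must be positive")


def conservation_fraction(panel: HaplotypePanel, region: GenomicRegion, pool: str) -> float:
    """Fraction of pool lines matching the modal haplotype vector over a region.

    The modal vector takes the per-window modal label (ties broken toward
    the lexicographically smallest label, for determinism); a line counts
    as conserved only if it matches the modal label in every overlapping
    window.
    """
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}")
    labels = panel.labels_over(region, pool)
    if labels.empty:
        raise ValueError(f"no {pool} panel windows overlap region {region.chrom}:{region.start_bp}-{region.end_bp}")
    modal = labels.apply(lambda col: col.value_counts().sort_index().idxmax(), axis=0)
    matches = (labels == modal).all(axis=1)
    return float(matches.mean())


def _overlaps_any(region: GenomicRegion, intervals) -> bool:
    for chrom, start, end in intervals:
        if chrom == region.chrom and start < region.end_bp and region.start_bp < end:
            return True
    return False


def scan_ctl(
    assembly: GenomeAssembly,
    genes: list[GeneModel],
    gmap: GeneticMap,
    panel: HaplotypePanel,
    params: ScanParams | None = None,
    trait_loci: list[tuple[str, str, int]] | None = None,
    exclusion_intervals: list[tuple[str, int, int]] | None = None,
) -> list[CtlCandidate]:
    """Rank 4-5 cM candidate CTL regions across the assembly.

    ``trait_loci`` are (name, chrom, bp) positions of existing commercial
    trait insertions (criterion 4); ``exclusion_intervals`` are
    breeding-relevant (chrom, start, end) intervals a candidate may not
    touch — a stand-in for "not used in forward breeding", which is not
    computable from sequence alone.
    """
    params = params or ScanParams()
    trait_loci = trait_loci or []
    exclusion_intervals = exclusion_intervals or []

    candidates: list[tuple[float, int, int, CtlCandidate]] = []
    chrom_order = {c: i for i, c in enumerate(assembly.chrom_names)}
    for chrom in assembly.chrom_names:
        if chrom not in gmap.anchors:
            continue
        length = assembly.lengths[chrom]
        cm_lo = gmap.bp_to_cm(chrom, 0).cm
        cm_hi = gmap.bp_to_cm(chrom, length).cm
        if cm_hi - cm_lo < params.window_cm:
            warnings.warn(
                f"{chrom} spans {cm_hi - cm_lo:.2f} cM, shorter than the "
                f"{params.window_cm} cM scan window; skipped",
                stacklevel=2,
            )
            continue
        n_spans = int(round((params.region_max_cm - params.region_min_cm) / params.step_cm))
        spans = [params.region_min_cm + i * params.step_cm for i in range(n_spans + 1)]
        start = cm_lo
        while start + params.region_min_cm <= cm_hi + 1e-9:
            for span in spans:
                end = start + span
                if end > cm_hi + 1e-9:
                    continue
                region = GenomicRegion.from_cm(gmap, chrom, start, min(end, cm_hi))
                if region.span_cm <= 0:
                    continue
                try:
                    cons_ss = conservation_fraction(panel, region, "SS")
                    cons_nss = conservation_fraction(panel, region, "NSS")
                except ValueError:
                    continue
                if cons_ss < params.min_conservation or cons_nss < params.min_conservation:
                    continue
                density = gene_density(genes, region)
                if density > params.max_gene_density:
                    continue
                ratio = phys_gen_ratio(region)
                if ratio > params.max_ratio_mb_per_cm:
                    continue
                if _overlaps_any(region, exclusion_intervals):
                    continue
                overlap = any(
                    c == chrom and region.start_bp <= bp < region.end_bp
                    for _, c, bp in trait_loci
                )
                score = (
                    params.w_conservation * (cons_ss + cons_nss) / 2.0
                    - params.w_density * density / params.max_gene_density
                    - params.w_ratio * ratio / params.max_ratio_mb_per_cm
                    + (params.trait_bonus if overlap else 0.0)
                )
                cand = CtlCandidate(
                    region=region,
                    conservation_ss=cons_ss,
                    conservation_nss=cons_nss,
                    gene_density=density,
                    ratio_mb_per_cm=ratio,
                    known_trait_overlap=overlap,
                    score=score,
                )
                candidates.append((-score, chrom_order[chrom], region.start_bp, cand))
            start += params.step_cm

    candidates.sort(key=lambda t: t[:3])
    kept: list[CtlCandidate] = []
    for _, _, _, cand in candidates:
        clash = any(
            k.region.chrom == cand.region.chrom
            and k.region.start_bp < cand.region.end_bp
            and cand.region.start_bp < k.region.end_bp
            for k in kept
        )
        if not clash:
            kept.append(cand)
    return kept


def read_haplotype_panel(path) -> HaplotypePanel:
    """Load a haplotype panel CSV (line,pool,chrom,window_start,window_end,haplotype)."""
    return HaplotypePanel(pd.read_csv(path, dtype={"haplotype": str}))


def read_trait_loci(path) -> list[tuple[str, str, int]]:
    """Load known-trait loci from a CSV with columns name,chrom,bp."""
    df = pd.read_csv(path)
    return [(str(r["name"]), str(r["chrom"]), int(r["bp"])) for _, r in df.iterrows()]


def candidates_to_frame(candidates: list[CtlCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.region.chrom for c in candidates],
            "start_bp": [c.region.start_bp for c in candidates],
            "end_bp": [c.region.end_bp for c in candidates],
            "start_cm": [c.region.start_cm for c in candidates],
            "end_cm": [c.region.end_cm for c in candidates],
            "conservation_ss": [c.conservation_ss for c in candidates],
            "conservation_nss": [c.conservation_nss for c in candidates],
            "gene_density": [c.gene_density for c in candidates],
            "ratio_mb_per_cm": [c.ratio_mb_per_cm for c in candidates],
            "known_trait_overlap": [c.known_trait_overlap for c in candidates],
            "score": [c.score for c in candidates],
        }
    )
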