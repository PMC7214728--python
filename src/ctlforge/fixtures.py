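"""Synthetic genomes, panels, assay tables, and BC1 populations with planted truth.

Every input the toolkit consumes can be generated here deterministically
from a seed, with the planted features (a conserved, gene-poor,
high-recombination CTL region; duplicated target sites; near-seed
off-targets of chosen mismatch count; known class frequencies in
screening tables; known map distances in crosses) recorded in a truth
manifest so downstream modules can be scored without re-deriving truth.

Background sequence is i.i.d. uniform A/C/G/T and planted features are
overwritten into it post hoc, which keeps uniqueness probabilities
analyzable.  Note that a random background of a few hundred kb routinely
contains seed 10-mers within 1 mismatch of any given site by chance, so a
planted k-mismatch off-target guarantees min seed mismatches <= k, not
== k; manifests record the planted value as an upper bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeAssembly, GeneticMap, write_genetic_map
from .ctl_scanner import HaplotypePanel
from .event_screen import PlantAssayRecord, records_to_frame, HELPERS
from .stacking import Bc1Counts, CrossDesign, simulate_bc1
from ._seqindex import revcomp

__all__ = [
    "FixtureSpec",
    "GenomeBundle",
    "make_genome_bundle",
    "make_screen_table",
    "make_bc1_table",
    "random_genome",
    "plant_site_duplicate",
    "plant_seed_offtarget",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> GenomeAssembly:
    """I.i.d. uniform-nucleotide chromosomes."""
    seqs = {
        name: _BASES[rng.integers(0, 4, n)].tobytes().decode()
        for name, n in lengths.items()
    }
    return GenomeAssembly(seqs)


def _force_pam_site(seqs: dict[str, str], chrom: str, pam_start: int, spacer_len: int = 20) -> dict:
    """Ensure a plus-strand NGG at ``pam_start`` and return the site truth."""
    s = seqs[chrom]
    seqs[chrom] = s[: pam_start + 1] + "GG" + s[pam_start + 3 :]
    protospacer = seqs[chrom][pam_start - spacer_len : pam_start]
    pam = seqs[chrom][pam_start : pam_start + 3]
    return {
        "chrom": chrom,
        "pam_start": pam_start,
        "strand": "+",
        "protospacer": protospacer,
        "pam": pam,
        "cut_bp": pam_start - 3,
    }


def plant_site_duplicate(
    seqs: dict[str, str], site: dict, dest_chrom: str, dest_start: int
) -> dict:
    """Copy a site's protospacer+PAM verbatim to another locus."""
    dup = site["protospacer"] + site["pam"]
    s = seqs[dest_chrom]
    seqs[dest_chrom] = s[:dest_start] + dup + s[dest_start + len(dup) :]
    return {"chrom": dest_chrom, "start": dest_start, "sequence": dup}


def plant_seed_offtarget(
    seqs: dict[str, str],
    site: dict,
    dest_chrom: str,
    dest_start: int,
    mismatches: int,
    rng: np.random.Generator,
) -> dict:
    """Plant the site's seed (mutated at ``mismatches`` positions) next to an AGG.

    ``dest_start`` is where the 10 bp seed begins; the PAM follows it.
    """
    seed = list(site["protospacer"][-10:])
    positions = rng.choice(10, size=mismatches, replace=False)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != seed[p]]
        seed[p] = alternatives[rng.integers(0, 3)]
    insert = "".join(seed) + "AGG"
    s = seqs[dest_chrom]
    seqs[dest_chrom] = s[:dest_start] + insert + s[dest_start + len(insert) :]
    return {
        "chrom": dest_chrom,
        "seed_start": dest_start,
        "pam_start": dest_start + 10,
        "planted_mismatches": mismatches,
    }


@dataclass
class FixtureSpec:
    """Configuration for the standard genome bundle.

    The planted CTL region is conserved in both germplasm pools,
    gene-poor, and sits on a high-recombination stretch (low Mb/cM); the
    rest of the genome is gene-dense with diverse haplotypes, so the
    planted region is the unique survivor of the scan thresholds.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 200_000}
    )
    # planted region: chr1 [150 kb, 195 kb) <-> [6.0, 10.5] cM (0.01 Mb/cM)
    ctl_start_bp: int = 150_000
    ctl_end_bp: int = 195_000
    ctl_start_cm: float = 6.0
    ctl_end_cm: float = 10.5
    chr1_total_cm: float = 16.0
    chr2_total_cm: float = 8.0
    panel_window_bp: int = 15_000
    n_lines_per_pool: int = 12
    n_conserved_per_pool: int = 10
    n_background_haplotypes: int = 8
    gene_len_bp: int = 1_000
    gene_step_bp: int = 3_000
    ctl_gene_positions: tuple[int, ...] = (158_000, 185_000)
    trait_locus_bp: int = 170_000
    spacer_len: int = 20


@dataclass
class GenomeBundle:
    assembly: GenomeAssembly
    genes: list[GeneModel]
    gmap: GeneticMap
    panel: HaplotypePanel
    truth: dict


def _build_genes(spec: FixtureSpec) -> list[GeneModel]:
    genes = []
    i = 0
    for chrom, length in spec.chrom_lengths.items():
        pos = 2_000
        while pos + spec.gene_len_bp < length - 2_000:
            inside_ctl = (
                chrom == "chr1"
                and pos + spec.gene_len_bp > spec.ctl_start_bp
                and pos < spec.ctl_end_bp
            )
            if not inside_ctl:
                genes.append(GeneModel(f"gene{i:04d}", chrom, pos, pos + spec.gene_len_bp))
                i += 1
            pos += spec.gene_step_bp
    for pos in spec.ctl_gene_positions:
        genes.append(GeneModel(f"gene{i:04d}", "chr1", pos, pos + spec.gene_len_bp))
        i += 1
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _build_map(spec: FixtureSpec) -> GeneticMap:
    anchors = {
        "chr1": (
            np.array(
                [0, spec.ctl_start_bp, spec.ctl_end_bp, spec.chrom_lengths["chr1"]], float
            ),
            np.array([0.0, spec.ctl_start_cm, spec.ctl_end_cm, spec.chr1_total_cm]),
        ),
        "chr2": (
            np.array([0, spec.chrom_lengths["chr2"]], float),
            np.array([0.0, spec.chr2_total_cm]),
        ),
    }
    return GeneticMap(anchors)


def _build_panel(spec: FixtureSpec, rng: np.random.Generator) -> HaplotypePanel:
    rows = []
    lines = [("SS", f"SS{i:02d}") for i in range(spec.n_lines_per_pool)] + [
        ("NSS", f"NSS{i:02d}") for i in range(spec.n_lines_per_pool)
    ]
    for chrom, length in spec.chrom_lengths.items():
        for wstart in range(0, length, spec.panel_window_bp):
            wend = min(wstart + spec.panel_window_bp, length)
            conserved_window = (
                chrom == "chr1" and wstart < spec.ctl_end_bp and wend > spec.ctl_start_bp
            )
            for pool, line in lines:
                idx = int(line[-2:])
                if conserved_window and idx < spec.n_conserved_per_pool:
                    hap = "H0"
                else:
                    hap = f"H{rng.integers(0, spec.n_background_haplotypes)}"
                rows.append(
                    {
                        "line": line,
                        "pool": pool,
                        "chrom": chrom,
                        "window_start": wstart,
                        "window_end": wend,
                        "haplotype": hap,
                    }
                )
    return HaplotypePanel(pd.DataFrame(rows))


def make_genome_bundle(spec: FixtureSpec | None = None, out_dir=None) -> GenomeBundle:
    """Generate the standard fixture bundle; optionally write it to disk.

    Outputs (when ``out_dir`` is given): genome.fasta, genes.gff3,
    map.tsv, haplotypes.csv, truth.json.  Fully deterministic from
    ``spec.seed``.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    assembly = random_genome(rng, spec.chrom_lengths)
    seqs = dict(assembly.sequences)

    # planted target sites inside the CTL region
    dup_site = _force_pam_site(seqs, "chr1", 170_500, spec.spacer_len)
    dup = plant_site_duplicate(seqs, dup_site, "chr2", 50_000)
    ot_site = _force_pam_site(seqs, "chr1", 175_000, spec.spacer_len)
    offtarget = plant_seed_offtarget(seqs, ot_site, "chr2", 100_000, mismatches=1, rng=rng)
    assembly = GenomeAssembly(seqs)

    genes = _build_genes(spec)
    gmap = _build_map(spec)
    panel = _build_panel(spec, rng)
    truth = {
        "ctl_region": {
            "chrom": "chr1",
            "start_bp": spec.ctl_start_bp,
            "end_bp": spec.ctl_end_bp,
            "start_cm": spec.ctl_start_cm,
            "end_cm": spec.ctl_end_cm,
        },
        "conservation_per_pool": spec.n_conserved_per_pool / spec.n_lines_per_pool,
        "trait_locus": {"name": "event_dp1", "chrom": "chr1", "bp": spec.trait_locus_bp},
        "duplicated_site": {"site": dup_site, "copy": dup},
        "seed_offtarget": {"site": ot_site, "planted": offtarget},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fasta", "w") as fh:
            for name, seq in assembly.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(out / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tctlforge\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
        write_genetic_map(gmap, out / "map.tsv")
        panel.table.to_csv(out / "haplotypes.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return GenomeBundle(assembly, genes, gmap, panel, truth)


_CLASS_ASSAYS = {
    "unmodified": ("neg", "neg", 2),
    "nhej_mutant": ("neg", "neg", 1),
    "hdr1_5p": ("pos", "neg", 1),
    "hdr1_3p": ("neg", "pos", 1),
    "hdr2_monoallelic": ("pos", "pos", 1),
    "hdr2_biallelic": ("pos", "pos", 0),
    "ambiguous": ("unknown", "unknown", "unknown"),
}


def make_screen_table(
    site_id: str,
    n: int,
    class_counts: dict[str, int] | None = None,
    class_freqs: dict[str, float] | None = None,
    helper_pos_rate: float = 0.8,
    seed: int = 0,
) -> tuple[list[PlantAssayRecord], dict]:
    """Per-plant assay records realising specified event-class composition.

    Exact-counts mode (``class_counts``; remainder is unmodified) emits
    precisely those class counts, so printed-table checks are exact.
    Stochastic mode (``class_freqs``) draws each plant's class
    independently.  Helper-gene positivity is drawn per helper per plant
    at ``helper_pos_rate``.  Returns (records, truth).
    """
    if (class_counts is None) == (class_freqs is None):
        raise ValueError("specify exactly one of class_counts or class_freqs")
    rng = np.random.default_rng(seed)
    classes: list[str] = []
    if class_counts is not None:
        unknown = set(class_counts) - set(_CLASS_ASSAYS)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        total = sum(class_counts.values())
        if total > n:
            raise ValueError("class counts exceed population size")
        for cls, k in class_counts.items():
            classes += [cls] * k
        classes += ["unmodified"] * (n - total)
    else:
        names = list(class_freqs)
        p = np.array([class_freqs[c] for c in names], float)
        if p.sum() > 1 + 1e-9:
            raise ValueError("class frequencies sum to more than 1")
        names.append("unmodified")
        p = np.append(p, max(0.0, 1.0 - p.sum()))
        classes = [names[i] for i in rng.choice(len(names), size=n, p=p / p.sum())]

    records = []
    for i, cls in enumerate(classes):
        j5, j3, copies = _CLASS_ASSAYS[cls]
        helpers = {
            h: ("pos" if rng.random() < helper_pos_rate else "neg") for h in HELPERS
        }
        records.append(
            PlantAssayRecord(
                plant_id=f"{site_id}_p{i:05d}",
                site_id=site_id,
                junction5=j5,
                junction3=j3,
                wt_cts_copies=copies,
                helpers=helpers,
                long_pcr="unknown",
            )
        )
    truth = {"site_id": site_id, "n": n, "class_counts": {c: classes.count(c) for c in set(classes)}}
    return records, truth


def write_screen_table(records: list[PlantAssayRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def make_bc1_table(
    crosses: list[tuple[str, float, int]],
    seed: int = 0,
    exact_counts: dict[str, Bc1Counts] | None = None,
    map_function: str = "direct",
) -> tuple[pd.DataFrame, dict]:
    """BC1 counts for (cross_id, d_cm, n) designs, simulated or exact.

    ``exact_counts`` entries (keyed by cross id) bypass simulation so
    printed-table checks are deterministic.  Returns (counts frame, truth
    with the generating distances).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for cross_id, d_cm, n in crosses:
        if exact_counts is not None and cross_id in exact_counts:
            counts = exact_counts[cross_id]
        else:
            design = CrossDesign(0.0, d_cm, map_function=map_function)
            counts = simulate_bc1(design, n, rng)
        rows.append(
            {
                "cross_id": cross_id,
                "n_total": counts.n_total,
                "n_a_only": counts.n_a_only,
                "n_b_only": counts.n_b_only,
                "n_both": counts.n_both,
                "n_neither": counts.n_neither,
            }
        )
        truth[cross_id] = {"d_cm": d_cm, "n": n}
    return pd.DataFrame(rows), truth
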