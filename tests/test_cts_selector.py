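import numpy as np
import pytest

from ctlforge._seqindex import SequenceIndex, revcomp
from ctlforge.cts_selector import (
    CtsCandidate,
    CtsFilterParams,
    PamSeedScanner,
    distance_to_nearest_gene,
    find_pam_sites,
    seed_offtarget_scan,
    select_cts,
    select_spaced_cts,
    site_and_flank_uniqueness,
)
from ctlforge.genome_io import GeneModel, GenomeAssembly, GenomicRegion

import oracles


def bare_region(assembly, chrom):
    n = assembly.lengths[chrom]
    return GenomicRegion(chrom, 0, n, 0.0, n / 1e4)


class TestFindPamSites:
    def test_single_constructed_site(self):
        asm = GenomeAssembly({"chr1": "A" * 20 + "AGG"})
        sites = find_pam_sites(asm, bare_region(asm, "chr1"), spacer_len=20)
        assert len(sites) == 1
        (c,) = sites
        assert c.protospacer == "A" * 20
        assert c.pam == "AGG"
        assert c.strand == "+"
        assert c.pam_start == 20
        assert c.cut_bp == 17  # blunt cut 3 bp 5' of the PAM

    def test_all_c_region_counts_match_regex_oracle(self):
        asm = GenomeAssembly({"chr1": "C" * 100})
        sites = find_pam_sites(asm, bare_region(asm, "chr1"), spacer_len=20)
        assert all(c.strand == "-" for c in sites)
        assert len(sites) == oracles.pam_site_count("C" * 100, 20)

    def test_random_counts_match_regex_oracle(self, toy_assembly):
        for chrom in toy_assembly.chrom_names:
            sites = find_pam_sites(toy_assembly, bare_region(toy_assembly, chrom), 20)
            assert len(sites) == oracles.pam_site_count(toy_assembly.sequences[chrom], 20)

    def test_n_in_site_dropped(self):
        asm = GenomeAssembly({"chr1": "A" * 10 + "N" + "A" * 9 + "AGG"})
        assert find_pam_sites(asm, bare_region(asm, "chr1"), 20) == []

    def test_minus_strand_geometry(self):
        # forward CCT then 20 T's: minus-strand protospacer is 20 A's, PAM AGG
        asm = GenomeAssembly({"chr1": "CCT" + "T" * 20})
        sites = find_pam_sites(asm, bare_region(asm, "chr1"), 20)
        assert len(sites) == 1
        (c,) = sites
        assert c.strand == "-" and c.protospacer == "A" * 20 and c.pam == "AGG"
        assert c.pam_start == 0 and c.cut_bp == 6

    def test_strand_symmetry_under_reverse_complement(self, toy_assembly):
        """Reverse-complementing the genome mirrors the candidate set."""
        chrom = "chr2"
        n = toy_assembly.lengths[chrom]
        fwd = find_pam_sites(toy_assembly, bare_region(toy_assembly, chrom), 20)
        rc_asm = GenomeAssembly({chrom: revcomp(toy_assembly.sequences[chrom])})
        rev = find_pam_sites(rc_asm, bare_region(rc_asm, chrom), 20)
        assert len(fwd) == len(rev)
        assert sorted((c.protospacer, c.pam) for c in fwd) == sorted(
            (c.protospacer, c.pam) for c in rev
        )
        assert sorted(n - c.cut_bp for c in fwd) == sorted(c.cut_bp for c in rev)


class TestGeneDistance:
    genes = [GeneModel("g1", "chr1", 5_000, 6_000), GeneModel("g2", "chr1", 20_000, 21_000)]

    def _cand(self, cut):
        return CtsCandidate("chr1", cut + 3, "+", "A" * 20, "AGG", cut)

    def test_inside_gene_is_zero(self):
        assert distance_to_nearest_gene(self._cand(5_500), self.genes) == 0

    def test_boundary_inclusive(self):
        # gene g1 ends 2000 bp before the cut: passes the >=2 kb rule
        assert distance_to_nearest_gene(self._cand(8_000), self.genes) == 2_000

    def test_matches_brute_force(self, toy_assembly):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 9_000))
            genes.append(GeneModel(f"g{i}", "chr1", s, s + int(rng.integers(50, 800))))
        for cut in rng.integers(0, 10_000, 50):
            cand = self._cand(int(cut))
            assert distance_to_nearest_gene(cand, genes) == oracles.min_gene_gap(
                genes, "chr1", int(cut)
            )


class TestUniqueness:
    def test_planted_duplicate_not_unique(self, bundle):
        truth = bundle.truth["duplicated_site"]["site"]
        cand = CtsCandidate(
            truth["chrom"], truth["pam_start"], "+", truth["protospacer"], truth["pam"],
            truth["cut_bp"],
        )
        site_unique, _ = site_and_flank_uniqueness(bundle.assembly, cand)
        assert not site_unique

    def test_random_flanks_unique_and_match_oracle(self, toy_assembly):
        sites = find_pam_sites(toy_assembly, GenomicRegion("chr1", 500, 2_000, 0.05, 0.2), 20)
        index = SequenceIndex(toy_assembly)
        for cand in sites[:10]:
            su, fu = site_and_flank_uniqueness(toy_assembly, cand, 300, index=index)
            s, e = cand.site_interval
            assert su == (oracles.count_both_strands(toy_assembly, toy_assembly.fetch(cand.chrom, s, e)) == 1)
            left = toy_assembly.fetch(cand.chrom, s - 300, s)
            right = toy_assembly.fetch(cand.chrom, e, e + 300)
            expected_fu = (
                oracles.count_both_strands(toy_assembly, left) == 1
                and oracles.count_both_strands(toy_assembly, right) == 1
            )
            assert fu == expected_fu

    def test_palindromic_site_counts_once(self):
        pal = "ACGTACGTAT" + "ATACGTACGT"  # 20-mer, its own reverse complement
        assert pal == revcomp(pal)
        rng = np.random.default_rng(9)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        bg = bases[rng.integers(0, 4, 2_000)].tobytes().decode()
        seq = bg[:1_000] + pal + bg[1_000:]
        asm = GenomeAssembly({"chr1": seq})
        index = SequenceIndex(asm)
        if oracles.count_both_strands(asm, pal) == 1:  # background may collide
            assert index.count_both_strands(pal) == 1

    def test_flank_off_chromosome_end(self, toy_assembly):
        sites = find_pam_sites(toy_assembly, GenomicRegion("chr1", 0, 300, 0.0, 0.03), 20)
        near_start = [c for c in sites if c.site_interval[0] < 200]
        assert near_start, "fixture should yield a site near the chromosome start"
        _, fu = site_and_flank_uniqueness(toy_assembly, near_start[0], 400)
        assert fu is False


class TestSeedScan:
    def _cand_from_truth(self, truth):
        return CtsCandidate(
            truth["chrom"], truth["pam_start"], "+", truth["protospacer"], truth["pam"],
            truth["cut_bp"],
        )

    def test_exact_second_seed_copy_fails(self):
        rng = np.random.default_rng(2)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = {"chr1": bases[rng.integers(0, 4, 5_000)].tobytes().decode()}
        from ctlforge.fixtures import _force_pam_site, plant_seed_offtarget

        site = _force_pam_site(seqs, "chr1", 1_000)
        plant_seed_offtarget(seqs, site, "chr1", 3_000, mismatches=0, rng=rng)
        asm = GenomeAssembly(seqs)
        cand = self._cand_from_truth(site)
        assert seed_offtarget_scan(asm, cand) == 0

    def test_planted_one_mismatch_rejected(self, bundle):
        truth = bundle.truth["seed_offtarget"]["site"]
        cand = self._cand_from_truth(truth)
        mm = seed_offtarget_scan(bundle.assembly, cand)
        assert mm <= 1  # planted neighbour guarantees at most 1
        assert mm < CtsFilterParams().min_seed_mm

    def test_matches_brute_force_on_random_genome(self, toy_assembly):
        scanner = PamSeedScanner(toy_assembly)
        sites = find_pam_sites(toy_assembly, GenomicRegion("chr1", 100, 1_200, 0.01, 0.12), 20)
        for cand in sites[:8]:
            assert scanner.min_mismatches(cand) == oracles.min_seed_mismatches(
                toy_assembly, cand
            )

    def test_nag_rule_can_only_tighten(self, toy_assembly):
        sites = find_pam_sites(toy_assembly, GenomicRegion("chr1", 100, 600, 0.01, 0.06), 20)
        ngg = PamSeedScanner(toy_assembly, pam_rule="NGG")
        nag = PamSeedScanner(toy_assembly, pam_rule="NGG+NAG")
        for cand in sites[:5]:
            assert nag.min_mismatches(cand) <= ngg.min_mismatches(cand)


class TestSpacing:
    def _cand(self, cm, pam_start=0, mm=5, dist=10_000):
        return CtsCandidate(
            "chr1", pam_start, "+", "A" * 20, "AGG", pam_start - 3 if pam_start >= 3 else 0,
            cm=cm, dist_to_gene=dist, min_seed_mismatches=mm,
        )

    def test_alternating_kept_at_half_spacing(self):
        cands = [self._cand(0.05 * i, pam_start=100 * i + 10) for i in range(5)]
        kept = select_spaced_cts(cands, min_spacing_cm=0.1)
        assert [c.cm for c in kept] == [0.0, 0.1, 0.2]

    def test_already_spaced_all_kept(self):
        cands = [self._cand(0.15 * i, pam_start=100 * i + 10) for i in range(6)]
        kept = select_spaced_cts(cands, min_spacing_cm=0.1)
        assert len(kept) == 6

    def test_bin_prefers_more_seed_mismatches(self):
        a = self._cand(0.00, pam_start=10, mm=3)
        b = self._cand(0.05, pam_start=500, mm=8)
        kept = select_spaced_cts([a, b], min_spacing_cm=0.1)
        assert kept == [b]

    def test_random_positions_pairwise_gaps(self):
        rng = np.random.default_rng(17)
        cands = [
            self._cand(float(cm), pam_start=int(i * 1000 + 10), mm=int(rng.integers(0, 6)))
            for i, cm in enumerate(np.sort(rng.uniform(0, 5, 200)))
        ]
        kept = select_spaced_cts(cands, min_spacing_cm=0.1)
        cms = [c.cm for c in kept]
        gaps = np.diff(cms)
        assert (gaps >= 0.1 - 1e-9).all()

    def test_target_count_stops_sweep(self):
        cands = [self._cand(0.2 * i, pam_start=100 * i + 10) for i in range(10)]
        assert len(select_spaced_cts(cands, 0.1, target_count=4)) == 4


class TestFullPipeline:
    def test_selected_sites_satisfy_all_four_criteria(self, bundle, ctl_region):
        """Re-verify every emitted CTS independently against the criteria."""
        params = CtsFilterParams()
        sites = select_cts(bundle.assembly, bundle.genes, bundle.gmap, ctl_region, params)
        assert sites, "pipeline selected no sites on the standard fixture"
        index = SequenceIndex(bundle.assembly)
        scanner = PamSeedScanner(bundle.assembly)
        for c in sites:
            assert distance_to_nearest_gene(c, bundle.genes) >= params.min_gene_distance_bp
            su, fu = site_and_flank_uniqueness(bundle.assembly, c, params.flank_len_bp, index=index)
            assert su and fu
            assert scanner.min_mismatches(c) >= params.min_seed_mm
        cms = sorted(c.cm for c in sites)
        assert (np.diff(cms) >= params.min_spacing_cm - 1e-9).all()
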