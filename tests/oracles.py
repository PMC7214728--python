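"""Independent brute-force oracles for cross-checking the fast implementations.

Everything here is deliberately naive: stdlib substring search, regex PAM
scans, and per-position Hamming loops.  None of it shares code with the
package's indexed/vectorised paths.
"""

from __future__ import annotations

import re

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) exact-match start offsets via repeated str.find."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def count_both_strands(assembly, query: str) -> int:
    """Occurrences on either strand over all chromosomes, deduped by locus."""
    hits = set()
    for chrom, seq in assembly.sequences.items():
        for pos in find_all(seq, query):
            hits.add((chrom, pos))
        for pos in find_all(seq, rc(query)):
            hits.add((chrom, pos))
    return len(hits)


def pam_loci(assembly, pam_rule: str = "NGG", seed_len: int = 10):
    """Every PAM locus with its seed 10-mer (5'->3' on the PAM strand).

    Yields (chrom, pam_start_forward, strand, seed).
    """
    pams = ["GG"] if pam_rule == "NGG" else ["GG", "AG"]
    for chrom, seq in assembly.sequences.items():
        n = len(seq)
        for pat in pams:
            for m in re.finditer(f"(?=.{pat})", seq):
                p = m.start()
                if p >= seed_len:
                    yield chrom, p, "+", seq[p - seed_len : p]
            for m in re.finditer(f"(?={rc(pat)}.)", seq):
                p = m.start()
                if p + 3 + seed_len <= n:
                    yield chrom, p, "-", rc(seq[p + 3 : p + 3 + seed_len])


def min_seed_mismatches(assembly, candidate, pam_rule: str = "NGG", seed_len: int = 10) -> int:
    """Exhaustive Hamming scan of the candidate seed against all other PAM loci."""
    cseed = candidate.protospacer[-seed_len:]
    best = seed_len
    own = (candidate.chrom, candidate.pam_start, candidate.strand)
    for chrom, p, strand, seed in pam_loci(assembly, pam_rule, seed_len):
        if (chrom, p, strand) == own:
            continue
        mm = sum(a != b for a, b in zip(cseed, seed))
        if mm < best:
            best = mm
    return best


def pam_site_count(seq: str, spacer_len: int = 20) -> int:
    """Regex count of NGG candidates (no N in protospacer+PAM) on both strands."""
    n = 0
    for m in re.finditer("(?=.GG)", seq):
        p = m.start()
        if p >= spacer_len and "N" not in seq[p - spacer_len : p + 3]:
            n += 1
    for m in re.finditer("(?=CC.)", seq):
        p = m.start()
        if p + 3 + spacer_len <= len(seq) and "N" not in seq[p : p + 3 + spacer_len]:
            n += 1
    return n


def gene_overlap_count(genes, chrom: str, start: int, end: int) -> int:
    """Half-open interval overlap count by direct comparison."""
    return sum(g.chrom == chrom and g.start < end and start < g.end for g in genes)


def min_gene_gap(genes, chrom: str, cut: int) -> int:
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.start <= cut < g.end:
            return 0
        d = g.start - cut if cut < g.start else cut - g.end
        best = d if best is None else min(best, d)
    return best if best is not None else 10**12
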