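"""SSILP repair-template assembly and in-silico screening amplicons.

The repair template for a target site is::

    left arm (~400 bp genomic) | PSA | payload | PSB | right arm (~400 bp)

where the arms are the exact genomic sequences flanking the blunt cut, PSA
and PSB are short tags unique versus the genome that give every landing
pad the same high-throughput junction PCR assay, and the payload is the
landing-pad cassette (promoter, FRT-A, NPTII marker, terminator, FRT-B,
loxP).  HDR is modelled as a pure insertion of PSA+payload+PSB at the cut:
the arms are homology, not duplicated sequence, and because the cut falls
3 bp inside the protospacer the insertion splits the protospacer so
neither junction of the repaired allele reconstitutes an intact
protospacer+PAM.

Four diagnostic amplicons are planned on the repaired (HDR) allele:
``junction5`` (genomic HR1f -> PsaR in the PSA tag), ``junction3`` (PsbF ->
genomic HR2r), and the overlapping long products ``long5`` (HR1f -> PsbR)
and ``long3`` (PsaF -> HR2r).  Junction and long products each anchor one
primer inside the insertion, so none of them amplifies from a wild-type or
NHEJ allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._seqindex import SequenceIndex, revcomp
from .cts_selector import CtsCandidate
from .genome_io import GenomeAssembly

__all__ = [
    "PayloadElement",
    "PayloadSpec",
    "SsilpTemplate",
    "PrimerPlacements",
    "Amplicon",
    "AmpliconPlan",
    "default_payload",
    "build_repair_template",
    "simulate_allele",
    "plan_amplicons",
]

MAX_NHEJ_INDEL = 50


@dataclass(frozen=True)
class PayloadElement:
    label: str
    sequence: str


@dataclass(frozen=True)
class PayloadSpec:
    """Ordered landing-pad cassette elements plus FRT pairing metadata.

    The FRT tags are opaque labelled sequences; the 1 nt (FRT1 vs FRT87)
    and 3 nt (FRT1 vs FRT6) spacer differences that set RMCE behaviour are
    recorded in ``metadata`` only.
    """

    elements: tuple[PayloadElement, ...]
    frt_pair: str = "FRT1/87"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frt_pair not in {"FRT1/87", "FRT1/6"}:
            raise ValueError("frt_pair must be 'FRT1/87' or 'FRT1/6'")

    @property
    def sequence(self) -> str:
        return "".join(e.sequence for e in self.elements)

    def __len__(self) -> int:
        return len(self.sequence)


_DEFAULT_ELEMENT_LENGTHS = {
    "UBI_PRO": 1986,   # maize UBIQUITIN1 promoter
    "FRT_A": 48,
    "NPTII": 795,      # neomycin phosphotransferase II ORF
    "PINII_TER": 310,  # potato proteinase inhibitor II terminator
    "FRT_B": 48,
    "loxP": 34,
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def default_payload(seed: int = 2020, frt_pair: str = "FRT1/87") -> PayloadSpec:
    """A ~3.2 kb stand-in landing-pad cassette with randomised element sequences.

    Element lengths mirror the real cassette (UBI promoter, FRT-A, NPTII
    ORF, PINII terminator, FRT-B, loxP); the sequences themselves are
    synthetic placeholders generated from ``seed``.
    """
    rng = np.random.default_rng(seed)
    elements = tuple(
        PayloadElement(label, _random_seq(rng, n))
        for label, n in _DEFAULT_ELEMENT_LENGTHS.items()
    )
    meta = {"frt_spacer_note": "FRT87 differs from FRT1 by 1 nt, FRT6 by 3 nt (spacer region)"}
    return PayloadSpec(elements=elements, frt_pair=frt_pair, metadata=meta)


@dataclass(frozen=True)
class SsilpTemplate:
    """A repair template plus the genomic context needed to plan amplicons."""

    chrom: str
    cut_bp: int
    left_arm: str
    psa: str
    payload: PayloadSpec
    psb: str
    right_arm: str
    upstream_context: str = ""
    downstream_context: str = ""

    @property
    def insert_sequence(self) -> str:
        """The novel sequence added at the cut: PSA + payload + PSB."""
        return self.psa + self.payload.sequence + self.psb

    @property
    def full_sequence(self) -> str:
        return self.left_arm + self.insert_sequence + self.right_arm

    def __len__(self) -> int:
        return len(self.full_sequence)

    def to_seqrecord(self, name: str = "ssilp_template") -> SeqRecord:
        """GenBank-style annotated record of the template."""
        rec = SeqRecord(Seq(self.full_sequence), id=name[:16], name=name[:16])
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        pos = 0
        parts: list[tuple[str, int]] = [("HDR_arm_left", len(self.left_arm)), ("PSA", len(self.psa))]
        parts += [(e.label, len(e.sequence)) for e in self.payload.elements]
        parts += [("PSB", len(self.psb)), ("HDR_arm_right", len(self.right_arm))]
        for label, n in parts:
            rec.features.append(
                SeqFeature(FeatureLocation(pos, pos + n), type="misc_feature", qualifiers={"label": [label]})
            )
            pos += n
        return rec


def build_repair_template(
    assembly: GenomeAssembly,
    cts: CtsCandidate,
    payload: PayloadSpec,
    arm_len: int = 400,
    psa: str | None = None,
    psb: str | None = None,
    context_len: int = 500,
    tag_len: int = 30,
    seed: int = 7,
    index: SequenceIndex | None = None,
) -> SsilpTemplate:
    """Assemble the SSILP repair template for a selected target site.

    Arms are exact genomic substrings ending/starting at the blunt cut.
    PSA/PSB default to random ``tag_len``-mers regenerated until absent
    from the genome and until neither junction of the repaired allele
    recreates the protospacer+PAM.
    """
    chrom_len = assembly.lengths[cts.chrom]
    if cts.cut_bp - arm_len < 0 or cts.cut_bp + arm_len > chrom_len:
        feasible = min(cts.cut_bp, chrom_len - cts.cut_bp)
        raise ValueError(
            f"homology arm of {arm_len} bp runs off {cts.chrom}; "
            f"maximum feasible arm_len here is {feasible}"
        )
    index = index or SequenceIndex(assembly)
    rng = np.random.default_rng(seed)

    def _unique_tag(supplied: str | None, label: str) -> str:
        if supplied is not None:
            if index.count_both_strands(supplied) != 0:
                raise ValueError(f"{label} tag occurs in the genome; pick a unique tag")
            return supplied
        for _ in range(100):
            tag = _random_seq(rng, tag_len)
            if index.count_both_strands(tag) == 0:
                return tag
        raise RuntimeError(f"could not generate a genome-unique {label} tag")

    psa_seq = _unique_tag(psa, "PSA")
    psb_seq = _unique_tag(psb, "PSB")

    left_arm = assembly.fetch(cts.chrom, cts.cut_bp - arm_len, cts.cut_bp)
    right_arm = assembly.fetch(cts.chrom, cts.cut_bp, cts.cut_bp + arm_len)
    up = assembly.fetch(cts.chrom, max(0, cts.cut_bp - arm_len - context_len), cts.cut_bp - arm_len)
    down = assembly.fetch(
        cts.chrom, cts.cut_bp + arm_len, min(chrom_len, cts.cut_bp + arm_len + context_len)
    )
    template = SsilpTemplate(
        chrom=cts.chrom,
        cut_bp=cts.cut_bp,
        left_arm=left_arm,
        psa=psa_seq,
        payload=payload,
        psb=psb_seq,
        right_arm=right_arm,
        upstream_context=up,
        downstream_context=down,
    )
    # the insertion splits the protospacer; confirm no junction restores the site
    site = cts.site_seq_forward
    hdr_local = template.full_sequence
    if site in hdr_local or revcomp(site) in hdr_local:
        raise ValueError(
            "repaired allele would retain an intact protospacer+PAM; "
            "choose different PSA/PSB tags or payload"
        )
    return template


def simulate_allele(
    assembly: GenomeAssembly,
    cts: CtsCandidate,
    template: SsilpTemplate | None,
    outcome: str,
    indel: int = 0,
    seed: int = 0,
    max_indel: int = MAX_NHEJ_INDEL,
) -> str:
    """Return the full chromosome sequence for a repair outcome.

    ``outcome`` is ``"WT"`` (reference), ``"HDR"`` (PSA+payload+PSB inserted
    at the cut), or ``"NHEJ"`` with ``indel`` = k bases inserted (k>0,
    random, seeded) or deleted (k<0) at the cut.
    """
    chrom_seq = assembly.sequences[cts.chrom]
    cut = cts.cut_bp
    if outcome == "WT":
        return chrom_seq
    if outcome == "HDR":
        if template is None:
            raise ValueError("HDR outcome needs a template")
        if template.cut_bp != cut or template.chrom != cts.chrom:
            raise ValueError("template was built for a different target site")
        return chrom_seq[:cut] + template.insert_sequence + chrom_seq[cut:]
    if outcome == "NHEJ":
        if indel == 0:
            raise ValueError("NHEJ outcome needs a nonzero indel size")
        if abs(indel) > max_indel:
            raise ValueError(f"|indel| exceeds the configured maximum of {max_indel}")
        if indel < 0:
            return chrom_seq[:cut] + chrom_seq[cut - indel :]
        rng = np.random.default_rng(seed)
        return chrom_seq[:cut] + _random_seq(rng, indel) + chrom_seq[cut:]
    raise ValueError(f"unknown outcome {outcome!r}")


@dataclass(frozen=True)
class PrimerPlacements:
    """Default primer geometry relative to the template.

    HR1f/HR2r sit in genomic sequence outside the arms; PsaR/PsaF and
    PsbF/PsbR sit at the termini of the PSA/PSB tags.
    """

    hr1f_upstream: int = 100   # bp of genomic sequence 5' of the left arm
    hr2r_downstream: int = 100

    def __post_init__(self) -> None:
        if self.hr1f_upstream <= 0:
            raise ValueError("primer HR1f must lie upstream of the left arm")
        if self.hr2r_downstream <= 0:
            raise ValueError("primer HR2r must lie downstream of the right arm")


@dataclass(frozen=True)
class Amplicon:
    name: str
    hdr_length: int
    wt_length: int | None
    sequence: str  # product on the HDR allele


@dataclass(frozen=True)
class AmpliconPlan:
    junction5: Amplicon
    junction3: Amplicon
    long5: Amplicon
    long3: Amplicon
    overlap_len: int  # long5 ∩ long3 on the HDR allele (PsaF..PsbR)

    @property
    def amplicons(self) -> dict[str, Amplicon]:
        return {a.name: a for a in (self.junction5, self.junction3, self.long5, self.long3)}


def plan_amplicons(
    template: SsilpTemplate, primers: PrimerPlacements | None = None
) -> AmpliconPlan:
    """Compute the junction and overlapping long PCR products on the HDR allele.

    Junction products pair a genomic primer with a tag primer; long
    products run from a genomic primer across the whole insertion to the
    far tag.  None of the four amplifies from a wild-type allele because
    one primer of each pair has no binding site there (``wt_length`` is
    None).
    """
    primers = primers or PrimerPlacements()
    if primers.hr1f_upstream > len(template.upstream_context):
        raise ValueError(
            f"primer HR1f placed {primers.hr1f_upstream} bp upstream but only "
            f"{len(template.upstream_context)} bp of context is available"
        )
    if primers.hr2r_downstream > len(template.downstream_context):
        raise ValueError(
            f"primer HR2r placed {primers.hr2r_downstream} bp downstream but only "
            f"{len(template.downstream_context)} bp of context is available"
        )
    up = template.upstream_context[-primers.hr1f_upstream :] if primers.hr1f_upstream else ""
    down = template.downstream_context[: primers.hr2r_downstream]
    insert = template.insert_sequence
    payload = template.payload.sequence

    junction5 = Amplicon(
        "junction5",
        hdr_length=len(up) + len(template.left_arm) + len(template.psa),
        wt_length=None,
        sequence=up + template.left_arm + template.psa,
    )
    junction3 = Amplicon(
        "junction3",
        hdr_length=len(template.psb) + len(template.right_arm) + len(down),
        wt_length=None,
        sequence=template.psb + template.right_arm + down,
    )
    long5 = Amplicon(
        "long5",
        hdr_length=len(up) + len(template.left_arm) + len(insert),
        wt_length=None,
        sequence=up + template.left_arm + insert,
    )
    long3 = Amplicon(
        "long3",
        hdr_length=len(insert) + len(template.right_arm) + len(down),
        wt_length=None,
        sequence=insert + template.right_arm + down,
    )
    # PsaF (start of PSA) .. PsbR (end of PSB) is shared by both long products
    overlap = len(template.psa) + len(payload) + len(template.psb)
    return AmpliconPlan(junction5, junction3, long5, long3, overlap_len=overlap)
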