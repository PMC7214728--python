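"""Classify T0 screening assays into gene-targeting event classes.

Each regenerated T0 plant is assayed by 5' and 3' junction PCR (template-
genome junctions), a qPCR copy estimate of the intact wild-type target
site (2 = unmodified on both homologs, 1 = one modified, 0 = both
modified), and presence/absence PCR for the four co-delivered helper
cassettes (Cas9, gRNA, Bbm, Wus2).  Classification is rule-ordered:

1. both junctions positive and 0 wild-type copies  -> biallelic 2xHDR
2. both junctions positive                          -> monoallelic 2xHDR
3. exactly one junction positive (other negative)   -> 1xHDR (5' or 3')
4. both junctions negative, <2 wild-type copies     -> NHEJ mutant
5. both junctions negative, 2 wild-type copies      -> unmodified
6. anything blocked by an unknown field             -> ambiguous

Per-site summaries report the modification frequency as an integer
percent and the 2xHDR frequency to one decimal, both rounded half-up to
match how such screening tables are printed; ambiguous plants stay in the
denominator (plants regenerated) but never in a numerator.  Long PCR is
recorded as confirmatory follow-up and is not a classification gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._rounding import round_half_up_ratio

HELPERS = ("cas9", "grna", "bbm", "wus2")
CLASSES = (
    "unmodified",
    "nhej_mutant",
    "hdr1_5p",
    "hdr1_3p",
    "hdr2_monoallelic",
    "hdr2_biallelic",
    "ambiguous",
)
HDR2_CLASSES = ("hdr2_monoallelic", "hdr2_biallelic")

__all__ = [
    "PlantAssayRecord",
    "EventCall",
    "SiteSummary",
    "classify_event",
    "summarize_site",
    "summarize",
    "count_sites_with_2xhdr",
    "helper_free_report",
    "read_assay_table",
    "records_to_frame",
]

_CALLS = {"pos", "neg", "unknown"}


@dataclass(frozen=True)
class PlantAssayRecord:
    """One plant's screening assays at one target site."""

    plant_id: str
    site_id: str
    junction5: str
    junction3: str
    wt_cts_copies: int | str  # 0, 1, 2 or "unknown"
    helpers: dict = field(default_factory=dict)
    long_pcr: str = "unknown"

    def __post_init__(self) -> None:
        for name, val in (("junction5", self.junction5), ("junction3", self.junction3)):
            if val not in _CALLS:
                raise ValueError(f"{name} must be pos/neg/unknown, got {val!r}")
        if self.wt_cts_copies not in {0, 1, 2, "unknown"}:
            raise ValueError(f"wt_cts_copies must be 0/1/2/unknown, got {self.wt_cts_copies!r}")
        bad = {k: v for k, v in self.helpers.items() if v not in _CALLS}
        if bad:
            raise ValueError(f"helper calls must be pos/neg/unknown: {bad}")
        if self.long_pcr not in {"pass", "fail", "unknown"}:
            raise ValueError(f"long_pcr must be pass/fail/unknown, got {self.long_pcr!r}")


@dataclass(frozen=True)
class EventCall:
    event_class: str
    helper_free: bool


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    n_regenerated: int
    n_modified: int
    mod_freq_pct: int
    n_hdr1_5p: int
    n_hdr1_3p: int
    n_2xhdr: int
    hdr2_freq_pct: float


def classify_event(record: PlantAssayRecord) -> EventCall:
    """Apply the ordered junction/copy-number rules; ambiguity is the sink."""
    j5, j3, copies = record.junction5, record.junction3, record.wt_cts_copies
    helper_free = all(record.helpers.get(h) == "neg" for h in HELPERS)

    if j5 == "pos" and j3 == "pos":
        cls = "hdr2_biallelic" if copies == 0 else "hdr2_monoallelic"
    elif j5 == "pos" and j3 == "neg":
        cls = "hdr1_5p"
    elif j5 == "neg" and j3 == "pos":
        cls = "hdr1_3p"
    elif j5 == "neg" and j3 == "neg":
        if copies == "unknown":
            cls = "ambiguous"
        elif copies < 2:
            cls = "nhej_mutant"
        else:
            cls = "unmodified"
    else:
        # one junction unknown: could be 1xHDR or 2xHDR
        cls = "ambiguous"
    return EventCall(event_class=cls, helper_free=helper_free)


def summarize_site(records: list[PlantAssayRecord]) -> SiteSummary:
    """Modification and 2xHDR frequencies for one site's T0 plants."""
    if not records:
        raise ValueError("summarize_site needs at least one record")
    site_ids = {r.site_id for r in records}
    if len(site_ids) != 1:
        raise ValueError(f"records span multiple sites: {sorted(site_ids)}")
    calls = [classify_event(r).event_class for r in records]
    n = len(calls)
    n_modified = sum(c not in {"unmodified", "ambiguous"} for c in calls)
    n_2xhdr = sum(c in HDR2_CLASSES for c in calls)
    return SiteSummary(
        site_id=records[0].site_id,
        n_regenerated=n,
        n_modified=n_modified,
        mod_freq_pct=int(round_half_up_ratio(100 * n_modified, n, 0)),
        n_hdr1_5p=sum(c == "hdr1_5p" for c in calls),
        n_hdr1_3p=sum(c == "hdr1_3p" for c in calls),
        n_2xhdr=n_2xhdr,
        hdr2_freq_pct=round_half_up_ratio(100 * n_2xhdr, n, 1),
    )


def summarize(records: list[PlantAssayRecord]) -> list[SiteSummary]:
    """Per-site summaries over a mixed-site record list (stable site order)."""
    by_site: dict[str, list[PlantAssayRecord]] = {}
    for r in records:
        by_site.setdefault(r.site_id, []).append(r)
    return [summarize_site(rs) for rs in by_site.values()]


def count_sites_with_2xhdr(summaries: list[SiteSummary]) -> int:
    """Number of target sites with at least one 2xHDR event."""
    return sum(s.n_2xhdr >= 1 for s in summaries)


def helper_free_report(records: list[PlantAssayRecord]) -> pd.DataFrame:
    """Per-site counts of 2xHDR plants testing negative for all four helpers.

    A plant with any unknown helper call is conservatively excluded.
    Columns: site_id, n_2xhdr, n_2xhdr_helper_free, helper_free_available.
    """
    rows: dict[str, dict] = {}
    for r in records:
        call = classify_event(r)
        row = rows.setdefault(
            r.site_id, {"site_id": r.site_id, "n_2xhdr": 0, "n_2xhdr_helper_free": 0}
        )
        if call.event_class in HDR2_CLASSES:
            row["n_2xhdr"] += 1
            if call.helper_free:
                row["n_2xhdr_helper_free"] += 1
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        df = pd.DataFrame(columns=["site_id", "n_2xhdr", "n_2xhdr_helper_free"])
    df["helper_free_available"] = df["n_2xhdr_helper_free"] >= 1
    return df


def read_assay_table(path) -> list[PlantAssayRecord]:
    """Load per-plant assay calls from CSV.

    Expected columns: plant_id, site_id, junction5, junction3,
    wt_cts_copies, cas9, grna, bbm, wus2[, long_pcr].
    """
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    records = []
    for _, row in df.iterrows():
        copies: int | str = row["wt_cts_copies"]
        if copies != "unknown":
            copies = int(copies)
        records.append(
            PlantAssayRecord(
                plant_id=row["plant_id"],
                site_id=row["site_id"],
                junction5=row["junction5"],
                junction3=row["junction3"],
                wt_cts_copies=copies,
                helpers={h: row.get(h, "unknown") for h in HELPERS},
                long_pcr=row.get("long_pcr", "unknown"),
            )
        )
    return records


def records_to_frame(records: list[PlantAssayRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "plant_id": r.plant_id,
            "site_id": r.site_id,
            "junction5": r.junction5,
            "junction3": r.junction3,
            "wt_cts_copies": r.wt_cts_copies,
            "long_pcr": r.long_pcr,
        }
        for h in HELPERS:
            row[h] = r.helpers.get(h, "unknown")
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[SiteSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in summaries],
            "n_regenerated": [s.n_regenerated for s in summaries],
            "n_modified": [s.n_modified for s in summaries],
            "mod_freq_pct": [s.mod_freq_pct for s in summaries],
            "n_hdr1_5p": [s.n_hdr1_5p for s in summaries],
            "n_hdr1_3p": [s.n_hdr1_3p for s in summaries],
            "n_2xhdr": [s.n_2xhdr for s in summaries],
            "hdr2_freq_pct": [s.hdr2_freq_pct for s in summaries],
        }
    )
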