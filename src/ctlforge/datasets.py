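"""Bundled worked-example tables.

Two small published datasets from the maize CTL1 study in the PH184C
inbred ship with the package as plain TSV:

* ``ctl1_screen_sites`` — per-target-site T0 screening counts for the 30
  CRISPR target sites at CTL1 (plants regenerated, plants with a modified
  site, 1xHDR counts by junction, 2xHDR counts), with each site's genetic
  position.
* ``ctl1_stacking_crosses`` — the 15 BC1 stacking crosses between the PMI
  event at 51.54 cM and NPTII landing pads at CTL1 (predicted positions
  and distances, seeds assayed, recombinants recovered, and the published
  observed distance).

Both serve as inputs to worked examples and as ground truth for checking
the summarisation and distance-estimation arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .event_screen import SiteSummary
from ._rounding import round_half_up_ratio

M14_PMI_POSITION_CM = 51.54  # PMI insertion used as the stacking anchor

__all__ = [
    "ctl1_screen_sites",
    "ctl1_stacking_crosses",
    "ctl1_site_summaries",
    "M14_PMI_POSITION_CM",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("ctlforge.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def ctl1_screen_sites() -> pd.DataFrame:
    return _load("ctl1_screen_sites.tsv")


def ctl1_stacking_crosses() -> pd.DataFrame:
    return _load("ctl1_stacking_crosses.tsv")


def ctl1_site_summaries() -> list[SiteSummary]:
    """The screening counts as :class:`SiteSummary` objects.

    Frequencies are recomputed from the raw counts (they reproduce the
    published percentages), so downstream code sees exactly what
    :func:`ctlforge.event_screen.summarize_site` would emit.
    """
    out = []
    for _, r in ctl1_screen_sites().iterrows():
        n = int(r["n_regenerated"])
        out.append(
            SiteSummary(
                site_id=str(r["site_id"]),
                n_regenerated=n,
                n_modified=int(r["n_modified"]),
                mod_freq_pct=int(round_half_up_ratio(100 * int(r["n_modified"]), n, 0)),
                n_hdr1_5p=int(r["n_hdr1_5p"]),
                n_hdr1_3p=int(r["n_hdr1_3p"]),
                n_2xhdr=int(r["n_2xhdr"]),
                hdr2_freq_pct=round_half_up_ratio(100 * int(r["n_2xhdr"]), n, 1),
            )
        )
    return out
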