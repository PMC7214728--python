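"""Two-locus BC1 genetics: simulation, distance estimation, stacking plans.

Two transgenes inside a CTL (e.g. the PMI marker of an existing event and
the NPTII marker of a landing pad) are combined by crossing the two
homozygous lines and backcrossing the F1 to the recurrent parent.  In the
F1 the loci sit on opposite homologs (repulsion phase), so parental BC1
gametes carry one marker or the other; a crossover between the loci gives
a recombinant gamete carrying both markers or neither.  Genetic distance
is estimated from the recombinant fraction with the direct small-distance
rule (1% recombinants = 1 cM); the Haldane map function is available for
comparison but differs by <0.1 cM below ~3 cM.  Double crossovers within
the interval are ignored (two-point analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_half_up_ratio

__all__ = [
    "CrossDesign",
    "Bc1Counts",
    "DistanceEstimate",
    "recomb_fraction",
    "simulate_bc1",
    "estimate_distance",
    "required_population",
    "stack_plan",
    "read_counts_table",
]


@dataclass(frozen=True)
class CrossDesign:
    """Two linked marker loci and how their distance maps to recombination."""

    pos_a_cm: float
    pos_b_cm: float
    phase: str = "repulsion"
    map_function: str = "direct"

    def __post_init__(self) -> None:
        if self.phase not in {"repulsion", "coupling"}:
            raise ValueError("phase must be 'repulsion' or 'coupling'")
        if self.map_function not in {"direct", "haldane"}:
            raise ValueError("map_function must be 'direct' or 'haldane'")

    @property
    def distance_cm(self) -> float:
        return abs(self.pos_a_cm - self.pos_b_cm)


@dataclass(frozen=True)
class Bc1Counts:
    """Two-marker BC1 genotype class counts."""

    n_a_only: int
    n_b_only: int
    n_both: int
    n_neither: int

    def __post_init__(self) -> None:
        if min(self.n_a_only, self.n_b_only, self.n_both, self.n_neither) < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_both + self.n_neither

    @property
    def n_recombinant(self) -> int:
        """Recombinant classes in repulsion phase: both markers or neither."""
        return self.n_both + self.n_neither


@dataclass(frozen=True)
class DistanceEstimate:
    n_total: int
    n_recombinant: int
    cm_estimate: float
    ci_low: float
    ci_high: float


def recomb_fraction(design: CrossDesign) -> float:
    """Map distance -> recombination fraction r in [0, 0.5]."""
    d = design.distance_cm
    if design.map_function == "direct":
        return min(d / 100.0, 0.5)
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def simulate_bc1(
    design: CrossDesign, n: int, seed: int | np.random.Generator
) -> Bc1Counts:
    """Draw ``n`` independent BC1 individuals from the cross design.

    In repulsion phase each individual is A-only or B-only with
    probability (1-r)/2 each (parental) and both/neither with probability
    r/2 each (recombinant); coupling phase swaps the parental and
    recombinant classes.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = recomb_fraction(design)
    if design.phase == "repulsion":
        probs = [(1 - r) / 2, (1 - r) / 2, r / 2, r / 2]
    else:
        probs = [r / 2, r / 2, (1 - r) / 2, (1 - r) / 2]
    draws = rng.choice(4, size=n, p=probs)
    counts = np.bincount(draws, minlength=4)
    return Bc1Counts(*(int(c) for c in counts))


def estimate_distance(counts: Bc1Counts, ci_level: float = 0.95) -> DistanceEstimate:
    """Genetic distance (cM) from the recombinant fraction, with exact CI.

    cm_estimate = 100 * recombinants / total, rounded half-up to two
    decimals (the printed precision of stacking tables); the CI is
    Clopper-Pearson on the recombinant proportion, scaled to cM.
    """
    n, k = counts.n_total, counts.n_recombinant
    if n < 1:
        raise ValueError("need at least one seed")
    alpha = 1.0 - ci_level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return DistanceEstimate(
        n_total=n,
        n_recombinant=k,
        cm_estimate=round_half_up_ratio(100 * k, n, 2),
        ci_low=100 * lo,
        ci_high=100 * hi,
    )


def required_population(
    d_cm: float,
    k_recombinants: int = 1,
    confidence: float = 0.95,
    map_function: str = "direct",
) -> int:
    """Smallest BC1 size giving >= ``k`` recombinants with the stated confidence."""
    if d_cm <= 0:
        raise ValueError("recombinants are unattainable at zero distance")
    if k_recombinants < 1:
        raise ValueError("k_recombinants must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    r = recomb_fraction(CrossDesign(0.0, d_cm, map_function=map_function))

    def ok(n: int) -> bool:
        return stats.binom.sf(k_recombinants - 1, n, r) >= confidence

    lo, hi = k_recombinants, k_recombinants
    while not ok(hi):
        hi *= 2
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def stack_plan(
    site_positions: dict[str, tuple[str, float]],
    assignments: dict[str, str],
    n_seeds: int,
    confidence: float = 0.95,
    map_function: str = "direct",
) -> pd.DataFrame:
    """Pairwise stacking feasibility report for trait -> site assignments.

    ``site_positions`` maps site id -> (chrom, cM); ``assignments`` maps
    trait name -> site id.  For each trait pair on the same chromosome the
    report gives the predicted distance, expected recombinants in a BC1 of
    ``n_seeds``, and the population needed for >=1 recombinant at the
    stated confidence.  Pairs on different chromosomes are flagged
    unlinked and excluded from cM arithmetic; coincident sites are flagged
    at zero distance.
    """
    traits = sorted(assignments)
    rows = []
    for i, ta in enumerate(traits):
        for tb in traits[i + 1 :]:
            sa, sb = assignments[ta], assignments[tb]
            ca, cma = site_positions[sa]
            cb, cmb = site_positions[sb]
            row = {"trait_a": ta, "site_a": sa, "trait_b": tb, "site_b": sb}
            if ca != cb:
                row.update(
                    {"linked": False, "flag": "unlinked", "d_cm": np.nan,
                     "expected_recombinants": np.nan, "n_for_one_recombinant": np.nan}
                )
            else:
                d = abs(cma - cmb)
                design = CrossDesign(cma, cmb, map_function=map_function)
                r = recomb_fraction(design)
                row.update(
                    {
                        "linked": True,
                        "flag": "zero_distance" if d == 0 else "",
                        "d_cm": d,
                        "expected_recombinants": n_seeds * r,
                        "n_for_one_recombinant": (
                            required_population(d, 1, confidence, map_function)
                            if d > 0
                            else np.nan
                        ),
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def read_counts_table(path) -> pd.DataFrame:
    """Load a BC1 counts CSV (cross_id,n_total,n_a_only,n_b_only,n_both,n_neither)."""
    df = pd.read_csv(path)
    required = {"cross_id", "n_a_only", "n_b_only", "n_both", "n_neither"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    return df


def estimate_table(df: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Distance estimates for every cross in a counts table."""
    rows = []
    for _, row in df.iterrows():
        counts = Bc1Counts(
            int(row["n_a_only"]), int(row["n_b_only"]), int(row["n_both"]), int(row["n_neither"])
        )
        est = estimate_distance(counts, ci_level)
        rows.append(
            {
                "cross_id": row["cross_id"],
                "n_total": est.n_total,
                "n_recombinant": est.n_recombinant,
                "cm_estimate": est.cm_estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)
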