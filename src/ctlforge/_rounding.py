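"""Exact half-up rounding of count ratios.

Printed screening and stacking tables round half-up (93% from 198/214,
2.88 cM from 55/1913).  Doing the arithmetic on integers avoids both
binary-float ties and banker's rounding.
"""

from __future__ import annotations


def round_half_up_ratio(numerator: int, denominator: int, decimals: int) -> float:
    """Round ``numerator/denominator`` to ``decimals`` places, ties away up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    scale = 10**decimals
    q, r = divmod(numerator * scale, denominator)
    if 2 * r >= denominator:
        q += 1
    return q / scale if decimals else float(q)
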