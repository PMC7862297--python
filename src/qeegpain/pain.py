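"""Pain quartiles and the NRS -> quartile mapping.

The numerical rating scale (NRS) is an 11-point integer scale, 0 (no
pain) to 10 (worst pain). The analysis discretizes it into four ordered
levels: none (0), mild (1-3), moderate (4-6), severe (7-10). The four
ranges partition 0-10 with no overlap, so the mapping is total on valid
input and invertible up to the range.
"""

from __future__ import annotations

from enum import IntEnum

from .errors import SessionError

__all__ = ["PainQuartile", "CLASS_ORDER", "NRS_RANGES", "nrs_to_quartile", "quartile_nrs_range"]


class PainQuartile(IntEnum):
    """Ordered pain level; integer value encodes severity rank."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "PainQuartile":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise SessionError(f"unknown pain quartile: {label!r}") from None


#: Fixed class order used for every confusion matrix, report and CSV.
CLASS_ORDER: list[str] = [q.label for q in PainQuartile]

#: Inclusive NRS range per quartile.
NRS_RANGES: dict[PainQuartile, tuple[int, int]] = {
    PainQuartile.NONE: (0, 0),
    PainQuartile.MILD: (1, 3),
    PainQuartile.MODERATE: (4, 6),
    PainQuartile.SEVERE: (7, 10),
}


def nrs_to_quartile(nrs: int) -> PainQuartile:
    """Map an NRS score to its pain quartile.

    0 -> none, 1-3 -> mild, 4-6 -> moderate, 7-10 -> severe.

    Raises
    ------
    SessionError
        If ``nrs`` is not an integer in [0, 10].
    """
    if not float(nrs).is_integer() or not 0 <= int(nrs) <= 10:
        raise SessionError(f"NRS must be an integer in [0, 10], got {nrs!r}")
    nrs = int(nrs)
    for quartile, (lo, hi) in NRS_RANGES.items():
        if lo <= nrs <= hi:
            return quartile
    raise SessionError(f"NRS {nrs} not covered by any quartile")  # pragma: no cover


def quartile_nrs_range(quartile: PainQuartile | str) -> tuple[int, int]:
    """Inclusive (low, high) NRS range of a quartile."""
    if isinstance(quartile, str):
        quartile = PainQuartile.from_label(quartile)
    return NRS_RANGES[quartile]
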