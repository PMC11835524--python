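"""Age-band encoding and arithmetic.

Bands are encoded as strings: closed bands ``"lo-hi"`` (inclusive), the open
band ``"85+"``, and single ages ``"7"`` (used for child strata 0-17).
Adult mortality uses 5-year bands 15-19 through 80-84 plus 85+; natality uses
mother bands 15-19..45-49 and father bands 15-19..50-54 plus 55-77.
"""

from __future__ import annotations

import re

from .errors import SchemaError

# 5-year adult bands used for mortality and population tables.
ADULT_BANDS: list[str] = [f"{lo}-{lo + 4}" for lo in range(15, 85, 5)] + ["85+"]

MOTHER_BANDS: list[str] = [f"{lo}-{lo + 4}" for lo in range(15, 50, 5)]
FATHER_BANDS: list[str] = [f"{lo}-{lo + 4}" for lo in range(15, 55, 5)] + ["55-77"]

CHILD_AGES: list[int] = list(range(18))

SEXES = ("female", "male")

# Maximum parental ages at the birth of a child and at death.
MOTHER_MAX_AGE_AT_BIRTH = 49
FATHER_MAX_AGE_AT_BIRTH = 77
MOTHER_MAX_AGE_AT_DEATH = 66  # 49 + 17
FATHER_MAX_AGE_AT_DEATH = 94  # 77 + 17
MIN_PARENT_AGE = 15

_BAND_RE = re.compile(r"^(\d+)-(\d+)$")
_OPEN_RE = re.compile(r"^(\d+)\+$")
_SINGLE_RE = re.compile(r"^(\d+)$")


def parse_band(band: str) -> tuple[int, int | None]:
    """Parse a band label into (lo, hi); hi is None for an open band."""
    band = str(band).strip()
    if m := _BAND_RE.match(band):
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise SchemaError(f"age band {band!r} has hi < lo")
        return lo, hi
    if m := _OPEN_RE.match(band):
        return int(m.group(1)), None
    if m := _SINGLE_RE.match(band):
        a = int(m.group(1))
        return a, a
    raise SchemaError(f"unparseable age band {band!r}")


def band_width(band: str) -> int:
    """Width in years; open bands are treated as 5-year for hazard purposes."""
    lo, hi = parse_band(band)
    if hi is None:
        return 5
    return hi - lo + 1


def band_midpoint(band: str) -> float:
    """Midpoint x = (lo + hi + 1) / 2 for closed bands; 87.5 for 85+."""
    lo, hi = parse_band(band)
    if hi is None:
        return 87.5
    return (lo + hi + 1) / 2


def band_for_age(age: int, bands: list[str] | None = None) -> str | None:
    """The band in ``bands`` (default adult bands) containing ``age``."""
    if bands is None:
        bands = ADULT_BANDS
    for band in bands:
        lo, hi = parse_band(band)
        if hi is None:
            if age >= lo:
                return band
        elif lo <= age <= hi:
            return band
    return None


def is_child_band(band: str) -> bool:
    """True for single-age child strata 0-17."""
    lo, hi = parse_band(band)
    return hi is not None and hi == lo and lo <= 17


def band_single_ages(band: str) -> list[int]:
    """Single ages used when averaging over a band.

    Closed bands enumerate lo..hi; the open 85+ band uses ages 85-89 when a
    5-age average is needed (expected-children band means instead enumerate
    to the sex-specific maximum parental age; see orphanhood module).
    """
    lo, hi = parse_band(band)
    if hi is None:
        return list(range(lo, lo + 5))
    return list(range(lo, hi + 1))


def check_non_overlapping(bands: list[str]) -> None:
    """Raise SchemaError if any two bands overlap."""
    parsed = sorted(parse_band(b) for b in set(bands))
    for (lo1, hi1), (lo2, _hi2) in zip(parsed, parsed[1:]):
        if hi1 is None or lo2 <= hi1:
            raise SchemaError(f"age bands overlap near {lo1}-{hi1}/{lo2}")
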