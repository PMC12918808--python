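"""Sample-naming scheme shared by all count tables.

Screen and fractionation samples are identified by underscore-joined fields:
``<background>_<tempC>_<minutes>_<fraction>_rep<k>`` for replicate-level
columns (e.g. ``WT_42_30_pellet_rep2``) and
``<background>_<tempC>_<minutes>_<fraction>`` for replicate-pooled columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

FRACTIONS = ("total", "pellet", "ribosome")

_REP_RE = re.compile(r"^rep(\d+)$")


@dataclass(frozen=True)
class SampleName:
    background: str
    temperature_c: int
    minutes: int
    fraction: str
    replicate: int | None = None  # None for replicate-pooled columns

    def __str__(self) -> str:
        base = f"{self.background}_{self.temperature_c}_{self.minutes}_{self.fraction}"
        if self.replicate is None:
            return base
        return f"{base}_rep{self.replicate}"


def sample_name(
    background: str,
    temperature_c: int,
    minutes: int,
    fraction: str,
    replicate: int | None = None,
) -> str:
    if "_" in background:
        raise ValueError(f"background {background!r} must not contain underscores")
    if fraction not in FRACTIONS:
        raise ValueError(f"fraction {fraction!r} not one of {FRACTIONS}")
    return str(SampleName(background, temperature_c, minutes, fraction, replicate))


def parse_sample_name(name: str) -> SampleName:
    """Parse a sample column name; accepts replicate-level and pooled forms."""
    parts = name.split("_")
    if len(parts) == 5:
        m = _REP_RE.match(parts[4])
        if m is None:
            raise ValueError(
                f"sample name {name!r}: fifth field must look like 'rep<k>'"
            )
        replicate: int | None = int(m.group(1))
    elif len(parts) == 4:
        replicate = None
    else:
        raise ValueError(
            f"sample name {name!r} does not match "
            "'<background>_<tempC>_<minutes>_<fraction>[_rep<k>]'"
        )
    background, temp_s, minutes_s, fraction = parts[:4]
    if fraction not in FRACTIONS:
        raise ValueError(f"sample name {name!r}: unknown fraction {fraction!r}")
    try:
        temperature_c = int(temp_s)
        minutes = int(minutes_s)
    except ValueError as exc:
        raise ValueError(f"sample name {name!r}: {exc}") from None
    return SampleName(background, temperature_c, minutes, fraction, replicate)
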