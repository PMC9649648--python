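"""Kleiner/Brunt threshold rules mapping measured quantities to scores.

Interval boundaries follow the printed score definitions; where printed
intervals share an endpoint (steatosis 33% and 66%), the boundary resolves
to the lower score (closed-below / open-above convention).
"""

from __future__ import annotations


def kleiner_steatosis_score(area_pct: float) -> int:
    """Steatosis score from macrovesicular area coverage in percent.

    0 (< 5%), 1 (5-33%), 2 (> 33-66%), 3 (> 66%).
    """
    if not 0.0 <= area_pct <= 100.0:
        raise ValueError(f"steatosis area percent out of [0, 100]: {area_pct}")
    if area_pct < 5.0:
        return 0
    if area_pct <= 33.0:
        return 1
    if area_pct <= 66.0:
        return 2
    return 3


def kleiner_inflammation_score(foci_per_field: float) -> int:
    """Lobular inflammation score from inflammatory foci per 200x field.

    0 (no foci), 1 (< 2 foci), 2 (2-4 foci), 3 (> 4 foci per field).
    """
    if foci_per_field < 0:
        raise ValueError(f"negative foci count: {foci_per_field}")
    if foci_per_field == 0:
        return 0
    if foci_per_field < 2:
        return 1
    if foci_per_field <= 4:
        return 2
    return 3


def kleiner_ballooning_score(burden: str) -> int:
    """Ballooning score from a qualitative burden: none / few / many -> 0 / 1 / 2."""
    mapping = {"none": 0, "few": 1, "many": 2}
    if burden not in mapping:
        raise ValueError(f"ballooning burden must be one of {sorted(mapping)}: {burden!r}")
    return mapping[burden]
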