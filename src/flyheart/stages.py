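"""Controlled vocabulary for Drosophila post-embryonic developmental stages.

Stages follow the longitudinal imaging design: second and third larval
instars (L2, L3), pupa days 1-5 sampled every 8 hours after puparium
formation (APF), and adult day 1 (AD1).
"""

from __future__ import annotations

# Ordered stage labels; pupal labels carry hours APF.
STAGE_ORDER: tuple[str, ...] = (
    "L2",
    "L3",
    "PD1 16h",
    "PD1 24h",
    "PD2 32h",
    "PD2 40h",
    "PD2 48h",
    "PD3 56h",
    "PD3 64h",
    "PD3 72h",
    "PD4 80h",
    "PD4 88h",
    "PD4 96h",
    "PD5 104h",
    "PD5 112h",
    "PD5 120h",
    "AD1",
)

STAGE_VOCABULARY: frozenset[str] = frozenset(STAGE_ORDER) | {"unknown"}

#: Default 8-hour pupal sampling interval.
SAMPLING_INTERVAL_H: float = 8.0


def is_pupal(stage_label: str) -> bool:
    """True for pupa-day stages (the span over which diastasis is scored)."""
    return stage_label.startswith("PD")


def hours_apf(stage_label: str) -> float | None:
    """Hours after puparium formation encoded in a pupal stage label.

    Returns None for non-pupal stages (L2, L3, AD1, unknown).
    """
    if not is_pupal(stage_label):
        return None
    return float(stage_label.split()[1].rstrip("h"))


def stage_sort_key(stage_label: str) -> int:
    """Position of a stage in developmental order."""
    return STAGE_ORDER.index(stage_label)


def validate_stage(stage_label: str) -> str:
    from .errors import VocabularyError

    if stage_label not in STAGE_VOCABULARY:
        raise VocabularyError(
            f"unknown stage label {stage_label!r}; expected one of "
            f"{sorted(STAGE_VOCABULARY)}"
        )
    return stage_label
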