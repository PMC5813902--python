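"""Sample identity for the six-gland worker honeybee study design.

The study design crosses three exocrine glands — postcerebral (PcG),
thoracic (TG), and mandibular (MG) — with two worker labors, nurse bees
(``n``) and foragers (``f``), giving six atomic samples: nPcG, fPcG, nTG,
fTG, nMG, fMG.  A third, derived labor level ``merged`` denotes the
nurse+forager pooled column ``(n+f)X``; merged columns are always computed
from the atomic ones, never read from input files.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass


class Gland(str, enum.Enum):
    """Worker exocrine gland."""

    PcG = "PcG"  # postcerebral gland (head salivary gland)
    TG = "TG"    # thoracic gland (thoracic salivary gland)
    MG = "MG"    # mandibular gland


class Labor(str, enum.Enum):
    """Division-of-labor state of the sampled workers."""

    NURSE = "n"
    FORAGER = "f"
    MERGED = "(n+f)"  # derived: nurse + forager pooled


@dataclass(frozen=True, order=True)
class SampleKey:
    """One sample column: a (gland, labor) pair such as nPcG or (n+f)MG."""

    gland: Gland
    labor: Labor

    @property
    def name(self) -> str:
        return f"{self.labor.value}{self.gland.value}"

    @property
    def is_merged(self) -> bool:
        return self.labor is Labor.MERGED

    @classmethod
    def from_name(cls, name: str) -> "SampleKey":
        m = re.fullmatch(r"(n|f|\(n\+f\))(PcG|TG|MG)", name)
        if m is None:
            raise ValueError(f"not a recognized sample name: {name!r}")
        return cls(Gland(m.group(2)), Labor(m.group(1)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


#: The six atomic samples, in the study's canonical order.
ATOMIC_SAMPLES: tuple[SampleKey, ...] = tuple(
    SampleKey(g, l)
    for g in (Gland.PcG, Gland.TG, Gland.MG)
    for l in (Labor.NURSE, Labor.FORAGER)
)

ATOMIC_SAMPLE_NAMES: tuple[str, ...] = tuple(k.name for k in ATOMIC_SAMPLES)


def merged_name(gland: Gland | str) -> str:
    """Column name of the pooled nurse+forager sample for *gland*."""
    return SampleKey(Gland(gland), Labor.MERGED).name


def atomic_names(gland: Gland | str) -> tuple[str, str]:
    """(nurse, forager) column names for *gland*."""
    g = Gland(gland)
    return (SampleKey(g, Labor.NURSE).name, SampleKey(g, Labor.FORAGER).name)
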