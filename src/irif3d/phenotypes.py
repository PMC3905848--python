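"""Knockdown-condition → IRIF-phenotype lookup.

During the G2-phase switch from non-homologous end-joining to homologous
recombination, ionizing-radiation-induced foci (IRIF) reorganize: 53BP1 and
conjugated-ubiquitin (FK2) signal enlarges roughly two-fold in volume and
vacates a central core where RPA foci form, with BRCA1 sitting between the
53BP1 rim and the RPA core.  Which parts of that reorganization occur
depends on the cell-cycle phase, the time after irradiation, and which
repair factors have been depleted by siRNA.

This module encodes the characterized condition → phenotype mapping as an
explicit, exhaustive table.  Each supported
(depleted-gene-set, phase, time) combination resolves to a
:class:`PhenotypeSpec` describing focus enlargement, whether a
53BP1/ubiquitin-devoid core forms, RPA/RAD51 levels, and per-channel focus
geometry templates used by :mod:`irif3d.simulate`.  Anything outside the
table raises :class:`UnsupportedConditionError` — no phenotype is ever
invented for an uncharacterized combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .grids import ROLE_53BP1, ROLE_BRCA1, ROLE_FK2, ROLE_GH2AX, ROLE_RPA

#: Controlled vocabulary of depletable factors.
GENES = frozenset(
    {
        "BRCA1",
        "BRCA2",
        "CtIP",
        "POH1",
        "RAP80",
        "BRCC36",
        "ABRAXAS",
        "53BP1",
        "KAP1",
        "Artemis",
        "BACH1",
    }
)

#: Devoid-core radius as a fraction of the focus outer radius.
CORE_RADIUS_FRACTION = 0.4

#: Per-focus probability that an RPA spot is present, by level.  The source
#: bar charts are not numerically recoverable; "reduced" is encoded as 50%
#: of the control probability and "none (in the majority of cells)" as 20%.
RPA_SPOT_PROBABILITY = {"none": 0.18, "reduced": 0.45, "normal": 0.90}

#: Radius scale for the "RPA foci formed ... although smaller" conditions.
SMALL_RPA_SCALE = 0.75

#: Default per-role fluorescence amplitudes (arbitrary units).  They differ
#: per role on purpose so that per-channel normalization is exercised.
CHANNEL_AMPLITUDES = {
    ROLE_53BP1: 220.0,
    ROLE_FK2: 180.0,
    ROLE_RPA: 160.0,
    ROLE_GH2AX: 200.0,
    ROLE_BRCA1: 140.0,
}


class UnsupportedConditionError(ValueError):
    """Condition not characterized in the source study."""


@dataclass(frozen=True)
class KnockdownCondition:
    """One experimental condition: siRNA set, cell-cycle phase, time post-IR."""

    depleted: frozenset = frozenset()
    phase: str = "G2"
    time_h: float = 8.0
    dose_Gy: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "depleted", frozenset(self.depleted))
        unknown = self.depleted - GENES
        if unknown:
            raise ValueError(f"unknown gene name(s): {sorted(unknown)}")
        if self.phase not in ("G1", "G2"):
            raise ValueError(f"phase must be 'G1' or 'G2', got {self.phase!r}")
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")

    @property
    def label(self) -> str:
        return condition_label(self)


@dataclass(frozen=True)
class ChannelTemplate:
    """Per-channel focus geometry template, sized relative to the focus
    reference radius (the enlarged 53BP1-equivalent outer radius).

    ``outer_rel`` scales the outer radius; ``inner_frac`` is the inner
    radius as a fraction of this channel's own outer radius (shells and
    central dips); ``prob`` is the per-focus probability that the channel
    shows the structure at all (used for stochastic RPA spots).
    """

    kind: str  # solid_sphere | hollow_shell | core_spot | broad_solid_with_dip
    outer_rel: float
    inner_frac: float = 0.0
    amplitude: float = 1.0
    prob: float = 1.0


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative phenotype for one condition.

    ``enlargement`` is the fold-change of measured 53BP1/FK2 focus volume
    relative to the 0.5 h reference (>= 1); since segmentation fills hollow
    foci, the focus reference radius scales as ``enlargement ** (1/3)``.
    ``core_devoid`` states whether the 53BP1/ubiquitin channels vacate the
    focus core (bipolar line profile); it always matches the FK2 geometry,
    and the 53BP1 geometry too whenever 53BP1 is not itself depleted.
    """

    enlargement: float
    core_devoid: bool
    rpa_level: str
    rad51_level: str
    core_radius_fraction: float = CORE_RADIUS_FRACTION
    channel_geometries: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.enlargement < 1.0:
            raise ValueError("enlargement must be >= 1")
        if self.core_devoid and not self.core_radius_fraction > 0:
            raise ValueError("core_devoid requires core_radius_fraction > 0")
        for level_name, level in (("rpa", self.rpa_level), ("rad51", self.rad51_level)):
            if level not in ("none", "reduced", "normal"):
                raise ValueError(f"bad {level_name} level {level!r}")


def _channels(
    depleted: frozenset,
    core_devoid: bool,
    rpa_level: str,
    small_rpa: bool = False,
) -> dict:
    """Build the per-role geometry templates implied by the phenotype flags."""
    cf = CORE_RADIUS_FRACTION
    amp = CHANNEL_AMPLITUDES
    geoms: dict[str, Optional[ChannelTemplate]] = {}

    # 53BP1 and ubiquitin chains share geometry: a hollow shell around the
    # devoid core when repositioning occurred, otherwise a solid focus.
    if core_devoid:
        body = dict(kind="hollow_shell", outer_rel=1.0, inner_frac=cf)
    else:
        body = dict(kind="solid_sphere", outer_rel=1.0)
    geoms[ROLE_53BP1] = (
        None if "53BP1" in depleted else ChannelTemplate(amplitude=amp[ROLE_53BP1], **body)
    )
    geoms[ROLE_FK2] = ChannelTemplate(amplitude=amp[ROLE_FK2], **body)

    # RPA: a small core spot, present per-focus with level-dependent
    # probability.  Spot radius is tied to the devoid-core radius scale.
    rpa_rel = 0.7 * cf * (SMALL_RPA_SCALE if small_rpa else 1.0)
    geoms[ROLE_RPA] = ChannelTemplate(
        kind="core_spot",
        outer_rel=rpa_rel,
        amplitude=amp[ROLE_RPA],
        prob=RPA_SPOT_PROBABILITY[rpa_level],
    )

    # γH2AX does not reposition with 53BP1: it stays a broad solid, sitting
    # slightly internally to 53BP1 by 8 h, with a shallower, smaller central
    # dip when a devoid core has formed.
    if core_devoid:
        geoms[ROLE_GH2AX] = ChannelTemplate(
            kind="broad_solid_with_dip",
            outer_rel=0.95,
            inner_frac=0.2,
            amplitude=amp[ROLE_GH2AX],
        )
    else:
        geoms[ROLE_GH2AX] = ChannelTemplate(
            kind="solid_sphere", outer_rel=1.05, amplitude=amp[ROLE_GH2AX]
        )

    # BRCA1 sits between the 53BP1 rim and the RPA core once the devoid core
    # exists; before that it is a compact internal focus.
    if "BRCA1" in depleted:
        geoms[ROLE_BRCA1] = None
    elif core_devoid:
        geoms[ROLE_BRCA1] = ChannelTemplate(
            kind="hollow_shell", outer_rel=cf, inner_frac=0.6, amplitude=amp[ROLE_BRCA1]
        )
    else:
        geoms[ROLE_BRCA1] = ChannelTemplate(
            kind="solid_sphere", outer_rel=0.5, amplitude=amp[ROLE_BRCA1]
        )
    return geoms


def _spec(
    depleted: frozenset,
    enlargement: float,
    core_devoid: bool,
    rpa: str,
    rad51: str,
    small_rpa: bool = False,
) -> PhenotypeSpec:
    return PhenotypeSpec(
        enlargement=enlargement,
        core_devoid=core_devoid,
        rpa_level=rpa,
        rad51_level=rad51,
        channel_geometries=_channels(depleted, core_devoid, rpa, small_rpa),
    )


def _row(genes, phase, time_h, *args, **kwargs):
    key = (frozenset(genes), phase, float(time_h))
    return key, _spec(frozenset(genes), *args, **kwargs)


# The characterized condition table.  G2 / 8 h / 3 Gy unless stated; the
# 0.5 h rows are the pre-reorganization reference states.
_TABLE: dict = dict(
    [
        # untreated controls
        _row((), "G2", 0.5, 1.0, False, "none", "none"),
        _row((), "G2", 8.0, 2.0, True, "normal", "normal"),
        _row((), "G1", 0.5, 1.0, False, "none", "none"),
        _row((), "G1", 8.0, 1.0, False, "none", "none"),
        # single depletions
        _row(("BRCA1",), "G2", 0.5, 1.0, False, "none", "none"),
        _row(("BRCA1",), "G2", 8.0, 1.0, False, "reduced", "reduced"),
        _row(("POH1",), "G2", 0.5, 1.0, False, "none", "none"),
        _row(("POH1",), "G2", 8.0, 2.0, False, "none", "none"),
        _row(("Artemis",), "G2", 8.0, 2.0, True, "reduced", "reduced"),
        _row(("RAP80",), "G2", 8.0, 2.0, True, "normal", "normal"),
        _row(("BRCC36",), "G2", 8.0, 2.0, True, "normal", "normal"),
        _row(("BACH1",), "G2", 8.0, 2.0, True, "normal", "normal"),
        _row(("CtIP",), "G2", 8.0, 1.0, False, "none", "none"),
        # POH1 rescue by removing the RAP80 complex
        _row(("POH1", "RAP80"), "G2", 8.0, 2.0, True, "normal", "none", small_rpa=True),
        _row(("POH1", "BRCC36"), "G2", 8.0, 2.0, True, "normal", "none", small_rpa=True),
        _row(("POH1", "ABRAXAS"), "G2", 8.0, 2.0, True, "normal", "none", small_rpa=True),
        # combined-barrier dissections (KAP1 co-depletion relieves the
        # heterochromatin role of 53BP1)
        _row(("KAP1", "53BP1", "BRCA1"), "G2", 8.0, 2.0, True, "reduced", "reduced"),
        _row(("KAP1", "53BP1", "POH1"), "G2", 8.0, 2.0, False, "none", "none"),
        _row(("KAP1", "53BP1", "BRCA1", "POH1"), "G2", 8.0, 1.5, False, "none", "none"),
        _row(("KAP1", "53BP1", "RAP80"), "G2", 8.0, 2.0, True, "normal", "normal"),
        _row(("BRCA1", "RAP80"), "G2", 8.0, 1.0, False, "reduced", "reduced"),
        _row(("BRCA1", "RAP80", "POH1"), "G2", 8.0, 1.5, False, "none", "none"),
    ]
)


def resolve_phenotype(condition: KnockdownCondition) -> PhenotypeSpec:
    """Look up the phenotype for a condition.

    Matching is exact on the depleted-gene set, phase and time: partial or
    fuzzy matches are rejected so no phenotype is extrapolated to an
    untested combination.
    """
    key = (condition.depleted, condition.phase, float(condition.time_h))
    try:
        return _TABLE[key]
    except KeyError:
        raise UnsupportedConditionError(
            f"condition {condition_label(condition)} not characterized in source study"
        ) from None


def list_supported_conditions() -> list[KnockdownCondition]:
    """Enumerate exactly the encoded condition table."""
    conds = [
        KnockdownCondition(depleted=genes, phase=phase, time_h=t)
        for (genes, phase, t) in _TABLE
    ]
    conds.sort(key=lambda c: (len(c.depleted), sorted(c.depleted), c.phase, c.time_h))
    return conds


# -- labels ----------------------------------------------------------------

def _fmt_time(t: float) -> str:
    return f"{t:g}h"


def condition_label(condition: KnockdownCondition) -> str:
    """Canonical string form, e.g. ``control_G2_8h`` or ``siBRCA1+RAP80_G2_8h``."""
    if condition.depleted:
        genes = "si" + "+".join(sorted(condition.depleted))
    else:
        genes = "control"
    return f"{genes}_{condition.phase}_{_fmt_time(condition.time_h)}"


def parse_condition_label(label: str) -> KnockdownCondition:
    """Inverse of :func:`condition_label`."""
    parts = label.rsplit("_", 2)
    if len(parts) != 3 or not parts[2].endswith("h"):
        raise ValueError(f"cannot parse condition label {label!r}")
    genes_part, phase, time_part = parts
    if genes_part == "control":
        genes: frozenset = frozenset()
    elif genes_part.startswith("si"):
        genes = frozenset(genes_part[2:].split("+"))
    else:
        raise ValueError(f"cannot parse condition label {label!r}")
    return KnockdownCondition(depleted=genes, phase=phase, time_h=float(time_part[:-1]))


def phenotype_table() -> pd.DataFrame:
    """The encoded table as a human-readable DataFrame (one row per condition)."""
    rows = []
    for (genes, phase, t), spec in _TABLE.items():
        rows.append(
            {
                "condition": condition_label(
                    KnockdownCondition(depleted=genes, phase=phase, time_h=t)
                ),
                "depleted": "+".join(sorted(genes)) if genes else "",
                "phase": phase,
                "time_h": t,
                "enlargement": spec.enlargement,
                "core_devoid": spec.core_devoid,
                "rpa_level": spec.rpa_level,
                "rad51_level": spec.rad51_level,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["phase", "time_h", "depleted"]).reset_index(drop=True)
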