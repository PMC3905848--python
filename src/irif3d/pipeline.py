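"""End-to-end condition analysis: simulate → segment → measure.

Ties the generator, segmentation, profile and statistics modules together
for in-memory workflows (the CLI provides the file-based equivalent).
Stacks are processed one nucleus at a time so large conditions stay within
a modest memory footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grids import ROLE_53BP1, ROLE_FK2, ROLE_RPA, VoxelGrid
from .phenotypes import KnockdownCondition, condition_label
from .profiles import (
    IntensityProfile,
    ProfileBorderError,
    ProfileMetrics,
    ProfileParams,
    average_profiles,
    classify_polarity,
    extract_profile,
)
from .quantify import (
    DetectionParams,
    VolumeSummary,
    classify_phase,
    detect_foci,
    segment_nuclei,
    volume_summary,
)
from .simulate import SimulationConfig, iter_condition_nuclei, with_seed
from .stats import ZeroVarianceError, pearson_coloc


@dataclass
class ConditionMeasurements:
    """Everything the pipeline measures for one condition."""

    label: str
    quant_role: str
    n_nuclei: int
    volumes: np.ndarray
    volume_summary: VolumeSummary
    rpa_counts: list  # detected RPA spots per nucleus
    phases: list  # phase call per nucleus
    mean_profile: Optional[IntensityProfile]
    metrics: dict  # role -> ProfileMetrics (from the averaged profile)
    pearson_rs: list  # per-focus 53BP1-vs-FK2 Pearson r
    rpa_reported: bool  # False when < 50% of foci contain an RPA spot
    n_profiles: int = 0


def quantification_role(condition: KnockdownCondition) -> str:
    """Channel used for focus volume/profile quantification: 53BP1, or the
    ubiquitin-chain (FK2) channel when 53BP1 itself is depleted."""
    return ROLE_FK2 if "53BP1" in condition.depleted else ROLE_53BP1


def analyze_stack(
    stack: VoxelGrid,
    quant_role: str,
    detection: DetectionParams,
    profile_params: ProfileParams,
    collect_profiles: bool = True,
    coloc_roles: Optional[tuple[str, str]] = None,
) -> dict:
    """Run segmentation and measurement on one stack.

    Returns a dict with nuclei, foci, per-focus profiles, RPA counts and
    per-focus Pearson r values. Foci whose profile line would leave the
    stack are skipped for profiling only.
    """
    nuclei = segment_nuclei(stack, detection)
    out = {
        "nuclei": nuclei,
        "foci": [],
        "profiles": [],
        "rpa_counts": [],
        "phases": [],
        "pearson_rs": [],
        "rpa_spot_foci": 0,
    }
    for nucleus in nuclei:
        out["phases"].append(classify_phase(nucleus, stack, params=detection))
        foci = detect_foci(stack, nucleus, quant_role, detection)
        out["foci"].extend(foci)
        rpa_spots = detect_foci(stack, nucleus, ROLE_RPA, detection)
        out["rpa_counts"].append(len(rpa_spots))
        if collect_profiles:
            for focus in foci:
                try:
                    out["profiles"].append(
                        extract_profile(
                            stack,
                            focus,
                            length_um=profile_params.length_um,
                            n_orientations=profile_params.n_orientations,
                        )
                    )
                except ProfileBorderError:
                    continue
        if coloc_roles is not None:
            for focus in foci:
                try:
                    res = pearson_coloc(
                        stack, focus.mask(stack.shape), *coloc_roles, scope="per-focus"
                    )
                    out["pearson_rs"].append(res.r)
                except (ZeroVarianceError, ValueError):
                    continue
        # fraction of quantified foci containing an RPA spot (for the
        # <50% reporting rule): an RPA spot belongs to the focus whose
        # centroid it is nearest
        for spot in rpa_spots:
            d = [
                np.linalg.norm(np.asarray(spot.centroid) - np.asarray(f.centroid))
                for f in foci
            ]
            if d and min(d) < 1.0:
                out["rpa_spot_foci"] += 1
    return out


def measure_condition(
    condition: KnockdownCondition,
    sim_config: SimulationConfig,
    detection: Optional[DetectionParams] = None,
    profile_params: Optional[ProfileParams] = None,
    n_nuclei: Optional[int] = None,
    seed: Optional[int] = None,
) -> ConditionMeasurements:
    """Simulate one condition and run the full quantification on it."""
    detection = detection or DetectionParams()
    profile_params = profile_params or ProfileParams()
    cfg = with_seed(sim_config, seed if seed is not None else sim_config.seed, n_nuclei)

    quant_role = quantification_role(condition)
    coloc = (
        (ROLE_53BP1, ROLE_FK2) if "53BP1" not in condition.depleted else None
    )

    all_volumes: list[float] = []
    all_profiles: list[IntensityProfile] = []
    rpa_counts: list[int] = []
    phases: list[str] = []
    pearson_rs: list[float] = []
    n_foci = 0
    n_rpa_foci = 0
    for stack, _truth in iter_condition_nuclei(condition, cfg):
        res = analyze_stack(
            stack, quant_role, detection, profile_params, coloc_roles=coloc
        )
        all_volumes.extend(f.volume for f in res["foci"])
        all_profiles.extend(res["profiles"])
        rpa_counts.extend(res["rpa_counts"])
        phases.extend(res["phases"])
        pearson_rs.extend(res["pearson_rs"])
        n_foci += len(res["foci"])
        n_rpa_foci += res["rpa_spot_foci"]

    mean_profile = average_profiles(all_profiles) if all_profiles else None
    metrics: dict[str, ProfileMetrics] = {}
    if mean_profile is not None:
        for role in mean_profile.channel_roles:
            metrics[role] = classify_polarity(mean_profile, role, profile_params)

    return ConditionMeasurements(
        label=condition_label(condition),
        quant_role=quant_role,
        n_nuclei=cfg.n_nuclei,
        volumes=np.asarray(all_volumes),
        volume_summary=volume_summary(all_volumes) if all_volumes else None,
        rpa_counts=rpa_counts,
        phases=phases,
        mean_profile=mean_profile,
        metrics=metrics,
        pearson_rs=pearson_rs,
        rpa_reported=(n_foci > 0 and n_rpa_foci / n_foci >= 0.5),
        n_profiles=len(all_profiles),
    )
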