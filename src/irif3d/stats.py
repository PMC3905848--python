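"""Co-localization and nonparametric statistics.

Pearson's correlation coefficient between two channels over a voxel mask
quantifies co-localization (full co-localization is 1.0).  Condition
comparisons of focus volumes use the Mann–Whitney rank-sum test: exact
two-sided p by full enumeration for small tie-free samples, otherwise the
normal approximation with midranks, tie correction and continuity
correction.  No multiple-testing adjustment is applied; raw p-values are
reported with a 0.05 significance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .phenotypes import PhenotypeSpec
from .grids import VoxelGrid

#: Largest pooled sample size for which the exact null distribution of U
#: is enumerated (C(12, 6) = 924 assignments at worst).
EXACT_MAX_N = 12

SIGNIFICANCE_LEVEL = 0.05


class ZeroVarianceError(ValueError):
    """Pearson correlation undefined: a channel is constant over the mask."""


@dataclass
class ColocResult:
    r: float
    n_voxels: int
    scope: str = "per-nucleus"


@dataclass
class RankSumResult:
    U: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "approximate"


def pearson_coloc(
    stack: VoxelGrid,
    mask: np.ndarray,
    role_a: str,
    role_b: str,
    scope: str = "per-nucleus",
) -> ColocResult:
    """Pearson correlation of two channels over the voxels in ``mask``."""
    x = np.asarray(stack.channel(role_a)[mask], dtype=float)
    y = np.asarray(stack.channel(role_b)[mask], dtype=float)
    if x.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if x.std() == 0 or y.std() == 0:
        raise ZeroVarianceError(
            f"constant intensity in {role_a!r} or {role_b!r}: correlation undefined"
        )
    if np.array_equal(x, y):
        r = 1.0  # identical signals co-localize fully, by definition
    else:
        r = float(np.clip(pearsonr(x, y).statistic, -1.0, 1.0))
    return ColocResult(r=r, n_voxels=int(x.size), scope=scope)


def _exact_two_sided_p(n1: int, n2: int, u_obs: float) -> float:
    """P(U <= min(U1, U2)) doubled, by enumerating all rank assignments."""
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2
    count = 0
    total = 0
    u_min = min(u_obs, n1 * n2 - u_obs)
    for ranks in combinations(range(1, n + 1), n1):
        u = sum(ranks) - offset
        total += 1
        if u <= u_min + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / total)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Mann–Whitney rank-sum test, two-sided.

    ``U`` is the statistic of the first sample computed from midranks.
    For pooled n <= 12 with no ties the p-value is exact (twice the
    one-tail probability from full enumeration, capped at 1); otherwise a
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(n1, n2, u1)
        return RankSumResult(U=u1, p_two_sided=p, n1=n1, n2=n2, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(U=u1, p_two_sided=1.0, n1=n1, n2=n2, method="approximate")
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + math.erf(abs(z) / math.sqrt(2.0)))))
    return RankSumResult(U=u1, p_two_sided=p, n1=n1, n2=n2, method="approximate")


# -- condition report ------------------------------------------------------

ENLARGEMENT_TOLERANCE = 0.20  # relative


def condition_report(
    measurements: dict,
    expected: dict,
    control_key: Optional[str] = None,
    baseline_key: Optional[str] = None,
) -> pd.DataFrame:
    """Tabulate measurements per condition against expected phenotypes.

    Parameters
    ----------
    measurements
        Mapping condition label -> :class:`irif3d.pipeline.ConditionMeasurements`.
    expected
        Mapping condition label -> :class:`PhenotypeSpec`.
    control_key
        Label of the late control condition used for rank-sum p-values
        (required if more than one condition is present).
    baseline_key
        Label of the early (0.5 h) reference used to convert median volume
        into a measured enlargement fold; enlargement checks are skipped
        when absent.

    The pass flags are: polarity matches ``core_devoid`` (bipolar iff a
    devoid core is expected), measured enlargement within ±20% of the
    expected fold, and RPA spot counts ordered none < reduced < normal
    across conditions (a dataset-level check repeated on each row's level).
    """
    if control_key is None and len(measurements) > 1:
        raise ValueError("control_key required to compute p-values vs control")
    control = measurements.get(control_key) if control_key else None
    if control_key is not None and control is None:
        raise ValueError(f"control condition {control_key!r} missing from measurements")
    baseline = measurements.get(baseline_key) if baseline_key else None

    # dataset-level RPA ordering: mean counts grouped by expected level
    level_counts: dict[str, list[float]] = {"none": [], "reduced": [], "normal": []}
    for key, m in measurements.items():
        spec = expected[key]
        level_counts[spec.rpa_level].append(float(np.mean(m.rpa_counts)))
    group_means = {
        lvl: (float(np.mean(v)) if v else None) for lvl, v in level_counts.items()
    }
    present = [group_means[l] for l in ("none", "reduced", "normal") if group_means[l] is not None]
    rpa_ordering_ok = all(x < y for x, y in zip(present, present[1:]))

    rows = []
    for key, m in measurements.items():
        spec = expected[key]
        vs = m.volume_summary
        fk2 = m.metrics.get("FK2")
        polarity = fk2.polarity if fk2 is not None else "undetected"
        polarity_ok = (polarity == "bipolar") == spec.core_devoid

        enlargement_measured = None
        enlargement_ok = None
        if baseline is not None and baseline.volume_summary.median > 0:
            enlargement_measured = vs.median / baseline.volume_summary.median
            enlargement_ok = (
                abs(enlargement_measured - spec.enlargement)
                <= ENLARGEMENT_TOLERANCE * spec.enlargement
            )

        p_vs_control = None
        if control is not None and key != control_key:
            p_vs_control = mann_whitney(vs.volumes, control.volume_summary.volumes).p_two_sided

        rows.append(
            {
                "condition": key,
                "n_nuclei": m.n_nuclei,
                "n_foci": int(vs.volumes.size),
                "median_volume_um3": vs.median,
                "min_volume_um3": vs.minimum,
                "max_valid_volume_um3": vs.max_valid,
                "n_excluded": vs.n_excluded,
                "polarity_fk2": polarity,
                "clearance_um": fk2.clearance if fk2 else None,
                "outer_width_um": fk2.outer_width if fk2 else None,
                "trough_ratio": fk2.trough_ratio if fk2 else None,
                "rpa_count_mean": float(np.mean(m.rpa_counts)) if m.rpa_counts else 0.0,
                "pearson_53bp1_fk2": (
                    float(np.mean(m.pearson_rs)) if m.pearson_rs else None
                ),
                "p_vs_control": p_vs_control,
                "significant": (
                    bool(p_vs_control < SIGNIFICANCE_LEVEL)
                    if p_vs_control is not None
                    else None
                ),
                "expected_core_devoid": spec.core_devoid,
                "expected_enlargement": spec.enlargement,
                "expected_rpa_level": spec.rpa_level,
                "enlargement_measured": enlargement_measured,
                "polarity_ok": polarity_ok,
                "enlargement_ok": enlargement_ok,
                "rpa_ordering_ok": rpa_ordering_ok,
            }
        )
    return pd.DataFrame(rows)


def report_passes(report: pd.DataFrame) -> bool:
    """True iff every phenotype check in the report passed (None = skipped)."""
    checks = report[["polarity_ok", "enlargement_ok", "rpa_ordering_ok"]]
    return bool(checks.fillna(True).all().all())
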