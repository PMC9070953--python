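"""Per-bin group comparison: Welch's t-test with Holm-Sidak correction.

The replicate unit is the plate/experiment: each condition contributes one
profile value per bin per replicate.  One profile comparison forms one
multiplicity family; bins with fewer than two finite replicate values in
either condition are flagged untested and excluded from the family size m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridError, InsufficientDataError, ValidationError
from .spatial_metrics import ResidenceProfile, VelocityProfile

DEFAULT_ALPHA = 0.05


def welch_t(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Unequal-variance two-sample t-test.

    Returns (t statistic, Welch-Satterthwaite degrees of freedom, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("welch_t needs >= 2 values per sample")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InsufficientDataError("welch_t requires finite values")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        # two constant samples
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math_inf_sign(diff), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(p)


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Sidak-adjusted p-values, returned in input order.

    Sorted ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1), with a
    running maximum enforcing monotonicity, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValidationError("holm_sidak needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class BinComparison:
    bin_left: float
    bin_right: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    tested: bool
    t_stat: float | None = None
    dof: float | None = None
    p_raw: float | None = None
    p_adj: float | None = None
    significant: bool = False


def _profile_values(profile) -> np.ndarray:
    if isinstance(profile, ResidenceProfile):
        return np.asarray(profile.probabilities, dtype=float)
    if isinstance(profile, VelocityProfile):
        return np.asarray(profile.mean_velocity, dtype=float)
    raise ValidationError(f"unsupported profile type {type(profile).__name__}")


def compare_profiles(
    profiles_a: Sequence,
    profiles_b: Sequence,
    alpha: float = DEFAULT_ALPHA,
) -> list[BinComparison]:
    """Per-bin Welch tests between two groups of replicate profiles.

    All profiles must share one bin grid.  Holm-Sidak correction is applied
    across the tested bins of this single comparison.
    """
    if not profiles_a or not profiles_b:
        raise InsufficientDataError("each group needs at least one profile")
    edges = np.asarray(profiles_a[0].bin_edges, dtype=float)
    for p in list(profiles_a) + list(profiles_b):
        if not np.array_equal(np.asarray(p.bin_edges, dtype=float), edges):
            raise GridError("profiles do not share a common bin grid")
    A = np.vstack([_profile_values(p) for p in profiles_a])
    B = np.vstack([_profile_values(p) for p in profiles_b])
    nb = edges.size - 1
    results: list[dict] = []
    raw_ps: list[float] = []
    for j in range(nb):
        a = A[:, j][np.isfinite(A[:, j])]
        b = B[:, j][np.isfinite(B[:, j])]
        row = {
            "bin_left": float(edges[j]),
            "bin_right": float(edges[j + 1]),
            "n_a": int(a.size),
            "n_b": int(b.size),
            "mean_a": float(a.mean()) if a.size else float("nan"),
            "mean_b": float(b.mean()) if b.size else float("nan"),
        }
        if a.size >= 2 and b.size >= 2:
            t, dof, p = welch_t(a, b)
            p = max(p, float(np.nextafter(0.0, 1.0)))  # keep p in (0, 1]
            row.update(tested=True, t_stat=t, dof=dof, p_raw=min(p, 1.0))
            raw_ps.append(row["p_raw"])
        else:
            row.update(tested=False)
        results.append(row)
    if raw_ps:
        adj = holm_sidak(raw_ps)
        it = iter(adj)
        for row in results:
            if row["tested"]:
                row["p_adj"] = float(next(it))
                row["significant"] = row["p_adj"] < alpha
    return [BinComparison(**row) for row in results]


def comparisons_to_frame(comparisons: Sequence[BinComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin_left_mm": c.bin_left,
                "bin_right_mm": c.bin_right,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "tested": c.tested,
                "t_stat": c.t_stat,
                "dof": c.dof,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )


def write_comparisons_csv(
    comparisons: Sequence[BinComparison], path: str | Path
) -> None:
    comparisons_to_frame(comparisons).to_csv(path, index=False, lineterminator="\n")
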