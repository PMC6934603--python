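"""ROC/AUC comparison of ordinal rating samples with DeLong intervals.

Listeners rate each stimulus on a 4-point scale (1 = "not at all" to
4 = "very much").  Two conditions of a piece are compared with the
Mann-Whitney AUC

    AUC = P(rating_manipulated > rating_original)
          + 1/2 P(rating_manipulated = rating_original),

so AUC > 0.5 means the manipulated version tends to receive higher
ratings and AUC < 0.5 a preference for the original.  The variance is
estimated with DeLong's structural components, using the tie-adjusted
1/2 kernel throughout — essential on a 4-point scale, where ties
dominate.  The ROC curve itself is the polygon of cumulative rating
proportions taken from category 4 down to 1; its trapezoidal area equals
the Mann-Whitney AUC exactly.

The design is between-subjects (each participant hears only one version
of a piece), so the unpaired DeLong variance applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingSample",
    "RocResult",
    "roc_auc",
    "rating_distribution",
    "export_long_table",
    "read_long_table",
    "CATEGORIES",
]

CATEGORIES = (1, 2, 3, 4)
CONDITIONS = ("original", "quantized", "exaggerated", "inverted")


@dataclass(frozen=True)
class RatingSample:
    """Ordinal ratings for one condition of one piece."""

    piece: str
    condition: str
    ratings: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.ratings:
            raise ValueError("rating sample must be nonempty")
        if any(r not in CATEGORIES for r in self.ratings):
            raise ValueError(f"ratings must be in {CATEGORIES}")

    def __len__(self) -> int:
        return len(self.ratings)


@dataclass(frozen=True)
class RocResult:
    """AUC with a 95% DeLong interval and the cumulative-proportion curve."""

    auc: float
    ci_low: float
    ci_high: float
    se: float
    curve: Tuple[Tuple[float, float], ...]  # (x=original, y=manipulated), (0,0)..(1,1)
    n_x: int
    n_y: int

    @property
    def significant(self) -> bool:
        """True when the interval excludes 0.5 (conditions distinguishable)."""
        return not (self.ci_low <= 0.5 <= self.ci_high)


def _mw_kernel_means(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Structural components: V10[i] = mean_j psi(x_i, y_j) and V01 likewise."""
    greater = x[:, None] > y[None, :]
    equal = x[:, None] == y[None, :]
    psi = greater + 0.5 * equal
    return psi.mean(axis=1), psi.mean(axis=0)


def roc_auc(
    manipulated: "RatingSample | Sequence[int]",
    original: "RatingSample | Sequence[int]",
    alpha: float = 0.05,
    orientation: str = "manipulated_high",
) -> RocResult:
    """Mann-Whitney AUC of manipulated vs original ratings with DeLong CI.

    ``orientation='manipulated_high'`` (default) scores the probability
    that the manipulated version out-rates the original; ``'original_high'``
    flips the roles.  With zero variance in both samples the AUC is still
    defined (0.5 when the constants coincide) but the interval collapses
    and a degenerate SE of 0 is reported.
    """
    x = np.asarray(
        manipulated.ratings if isinstance(manipulated, RatingSample) else manipulated,
        dtype=float,
    )
    y = np.asarray(
        original.ratings if isinstance(original, RatingSample) else original,
        dtype=float,
    )
    if x.size == 0 or y.size == 0:
        raise ValueError("both rating samples must be nonempty")
    if (
        isinstance(manipulated, RatingSample)
        and isinstance(original, RatingSample)
        and manipulated.piece != original.piece
    ):
        raise ValueError(
            f"samples compare different pieces: "
            f"{manipulated.piece!r} vs {original.piece!r}"
        )
    if orientation == "original_high":
        x, y = y, x
    elif orientation != "manipulated_high":
        raise ValueError(f"unknown orientation {orientation!r}")

    v10, v01 = _mw_kernel_means(x, y)
    auc = float(v10.mean())
    if x.size > 1 and y.size > 1:
        var = v10.var(ddof=1) / x.size + v01.var(ddof=1) / y.size
    else:
        var = np.nan
    se = float(np.sqrt(var)) if np.isfinite(var) else float("nan")
    z = stats.norm.ppf(1 - alpha / 2)
    if np.isfinite(se) and se > 0:
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    else:
        lo = hi = auc  # degenerate: no variability in either sample

    curve = _cumulative_curve(x, y)
    return RocResult(
        auc=auc, ci_low=lo, ci_high=hi, se=se, curve=curve, n_x=int(x.size), n_y=int(y.size)
    )


def _cumulative_curve(x: np.ndarray, y: np.ndarray) -> Tuple[Tuple[float, float], ...]:
    """ROC polygon from cumulative proportions, category 4 down to 1.

    Point k is (P(original >= c_k), P(manipulated >= c_k)) for thresholds
    c = 4, 3, 2, 1; prepending (0, 0) closes the polygon at the origin and
    the last point is always (1, 1).
    """
    points = [(0.0, 0.0)]
    for c in sorted(CATEGORIES, reverse=True):
        points.append((float(np.mean(y >= c)), float(np.mean(x >= c))))
    return tuple(points)


def rating_distribution(sample: "RatingSample | Sequence[int]") -> Dict[int, float]:
    """Proportion of answers per category 1-4 (sums to 1)."""
    ratings = np.asarray(
        sample.ratings if isinstance(sample, RatingSample) else sample, dtype=int
    )
    if ratings.size == 0:
        raise ValueError("empty rating sample")
    return {c: float(np.mean(ratings == c)) for c in CATEGORIES}


def export_long_table(
    samples: Sequence[RatingSample],
    participants: Sequence[Sequence[str]],
    musician_category: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Long-format survey table, one row per rating.

    ``participants[k][i]`` is the id of the listener who gave
    ``samples[k].ratings[i]``.  Columns: participant, piece, condition,
    musician_category, rating — the layout ordinal mixed-model software
    consumes.  Because each participant may hear only one version of a
    piece, a participant appearing under two conditions of the same piece
    is an error.
    """
    if len(participants) != len(samples):
        raise ValueError("need one participant list per sample")
    rows = []
    for sample, pids in zip(samples, participants):
        if len(pids) != len(sample.ratings):
            raise ValueError(
                f"sample {sample.piece}/{sample.condition}: "
                f"{len(pids)} participants for {len(sample.ratings)} ratings"
            )
        for pid, rating in zip(pids, sample.ratings):
            rows.append(
                {
                    "participant": pid,
                    "piece": sample.piece,
                    "condition": sample.condition,
                    "musician_category": (musician_category or {}).get(pid, ""),
                    "rating": rating,
                }
            )
    frame = pd.DataFrame(rows)
    dup = frame.duplicated(subset=["participant", "piece"], keep=False)
    if dup.any():
        offenders = frame.loc[dup, ["participant", "piece", "condition"]]
        if offenders.groupby(["participant", "piece"])["condition"].nunique().gt(1).any():
            raise ValueError(
                "between-subjects design violated: a participant rated two "
                "conditions of the same piece:\n" + offenders.to_string(index=False)
            )
        raise ValueError("duplicate participant x piece rows in export")
    return frame


def read_long_table(path) -> List[RatingSample]:
    """Read a long-format ratings CSV back into RatingSamples."""
    frame = pd.read_csv(path)
    samples = []
    for (piece, condition), group in frame.groupby(["piece", "condition"], sort=True):
        samples.append(
            RatingSample(
                piece=str(piece),
                condition=str(condition),
                ratings=tuple(int(r) for r in group["rating"]),
            )
        )
    return samples
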