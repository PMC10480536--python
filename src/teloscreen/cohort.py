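"""Cohort-level aggregation, ranking, and outlier calling.

Collapses per-sample repeat-read ratios to one score per protein target,
summarizes the score distribution the way a box plot does (quartiles and
Tukey fences), ranks targets by score, and flags candidates whose score
exceeds the upper fence — the screen's candidate-nomination step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .screen import SampleScreenResult

AGGREGATES = {"mean": np.mean, "median": np.median, "max": np.max}


@dataclass
class TargetScore:
    target: str
    n_samples: int
    ratios: list[float] = field(default_factory=list)
    score: float = float("nan")
    rank: int | None = None
    is_outlier: bool = False
    target_class: str = "protein"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary plus Tukey fences (quartiles by linear
    interpolation between order statistics; fences at q1/q3 -/+ 1.5 IQR)."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    lower_fence: float
    upper_fence: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iqr"] = self.iqr
        return d


class EmptyCohortError(ValueError):
    """No usable samples in the cohort."""


def aggregate_targets(
    results: Sequence[SampleScreenResult],
    manifest: pd.DataFrame,
    aggregate: str = "mean",
) -> list[TargetScore]:
    """Collapse per-sample ratios to one score per target.

    Only samples with status "ok" and a passing QC verdict contribute;
    targets left with no passing replicate are dropped with a warning.
    The manifest's optional ``class`` column (e.g. "protein" vs "histone")
    is carried through for downstream ranking policy.
    """
    if aggregate not in AGGREGATES:
        raise ValueError(f"aggregate must be one of {sorted(AGGREGATES)}")
    agg = AGGREGATES[aggregate]
    meta = manifest.set_index("sample_id")
    classes = (
        meta["class"] if "class" in meta.columns else pd.Series(dtype=str)
    )

    by_target: dict[str, list[float]] = {}
    target_class: dict[str, str] = {}
    order: list[str] = []
    for sid in meta.index:
        t = str(meta.loc[sid, "target"])
        if t not in by_target:
            by_target[t] = []
            order.append(t)
            target_class[t] = str(classes.get(sid, "protein"))
    for r in results:
        if r.status != "ok" or not r.qc_pass or r.ratio is None:
            continue
        if r.sample_id not in meta.index:
            raise ValueError(f"screen result {r.sample_id!r} not in manifest")
        by_target[str(meta.loc[r.sample_id, "target"])].append(r.ratio)

    scores = []
    for t in order:
        ratios = by_target[t]
        if not ratios:
            warnings.warn(f"target {t!r} has no QC-passing samples; excluded")
            continue
        scores.append(
            TargetScore(
                target=t,
                n_samples=len(ratios),
                ratios=ratios,
                score=float(agg(ratios)),
                target_class=target_class[t],
            )
        )
    if not scores:
        raise EmptyCohortError("no target has any QC-passing sample")
    return scores


def summarize_distribution(scores: Sequence[float]) -> DistributionSummary:
    """Box-plot style summary of a score distribution."""
    if len(scores) == 0:
        raise ValueError("cannot summarize an empty distribution")
    arr = np.asarray(scores, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    return DistributionSummary(
        n=len(arr),
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(arr.max()),
        lower_fence=float(q1 - 1.5 * iqr),
        upper_fence=float(q3 + 1.5 * iqr),
    )


def rank_and_call(
    scores: Sequence[TargetScore],
    outlier: str = "tukey",
    z_cutoff: float = 3.0,
    rank_classes: tuple[str, ...] = ("protein",),
) -> list[TargetScore]:
    """Rank targets by descending score and flag outlier candidates.

    Ties break lexicographically by target name. Targets whose class is
    outside ``rank_classes`` (histone markers, by convention) contribute
    to the fence distribution but are not ranked or flagged. The outlier
    rule is the Tukey upper fence (default) or a z-score cut
    (score > mean + z_cutoff * sd).
    """
    ranked = [s for s in scores if s.target_class in rank_classes]
    if len(ranked) < 2:
        raise ValueError("ranking needs at least 2 targets")
    all_scores = [s.score for s in scores]
    if outlier == "tukey":
        cut = summarize_distribution(all_scores).upper_fence
    elif outlier == "zscore":
        cut = float(np.mean(all_scores) + z_cutoff * np.std(all_scores, ddof=1))
    else:
        raise ValueError(f"unknown outlier rule {outlier!r}")

    ranked.sort(key=lambda s: (-s.score, s.target))
    for i, s in enumerate(ranked, start=1):
        s.rank = i
        s.is_outlier = s.score > cut
    return ranked


def ranking_frame(ranked: Sequence[TargetScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": s.target,
                "n_samples": s.n_samples,
                "score": s.score,
                "rank": s.rank,
                "is_outlier": s.is_outlier,
            }
            for s in ranked
        ]
    )
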