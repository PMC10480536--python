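"""Cross-channel focus colocalization from coordinate tables.

Quantifies what a microscopist counts by eye: how many foci in one
fluorescence channel sit on top of foci in another. Two channels are
matched by one-to-one mutual nearest neighbors within a distance
threshold; a third channel extends a matched pair to a triple when a
focus lies within the threshold of the pair midpoint. From the matches
come the per-nucleus cofocus counts and histograms, the TIF ratio
(damage-marker foci colocalized with telomeres, per telomere), and the
APB ratio (PML bodies colocalized with telomeric DNA, per telomere),
with chi-squared and t-test group comparisons.

Coordinates are 2D, in whatever common unit the table uses; the matching
threshold is expressed in that same unit and must be supplied by the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .qpcr import anova, compare_means

DEFAULT_BINS: tuple[tuple[str, int, int | None], ...] = (
    ("0", 0, 0),
    ("1-4", 1, 4),
    ("5-8", 5, 8),
    ("9-10", 9, 10),
    (">10", 11, None),
)


@dataclass
class ColocResult:
    nucleus_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_coloc: int = 0
    ratio: float | None = None
    reference: str = ""
    threshold: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _sorted_points(points: np.ndarray) -> np.ndarray:
    """Stable sort by (x, y) so nearest-neighbor ties resolve to the
    lowest index deterministically, independent of input row order."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def _mutual_nn_pairs(a: np.ndarray, b: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    d = cdist(a, b)
    nn_b = d.argmin(axis=1)  # argmin takes the first (lowest index) on ties
    nn_a = d.argmin(axis=0)
    pairs = []
    for i in range(len(a)):
        j = nn_b[i]
        if nn_a[j] == i and d[i, j] <= threshold:
            pairs.append((i, int(j)))
    return pairs


def match_foci(
    foci: Mapping[str, np.ndarray],
    threshold: float,
    channels: Sequence[str] | None = None,
    reference: str | None = None,
    nucleus_id: str = "",
) -> ColocResult:
    """Match foci across 2 or 3 channels within one nucleus.

    ``foci`` maps channel name to an (n, 2) coordinate array. Pairwise:
    a focus pair is matched iff each is the other's nearest cross-channel
    focus and their distance is <= threshold (mutual nearest neighbors,
    hence one-to-one). With a third channel, a matched pair becomes a
    triple iff an unclaimed third-channel focus lies within threshold of
    the pair midpoint; each focus is used at most once.

    ``ratio`` divides the match count by the reference channel's focus
    count (default: the last queried channel, conventionally the telomere
    channel); it is None, flagged rather than zero, when that count is 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    chans = list(channels) if channels is not None else list(foci)
    if not 2 <= len(chans) <= 3:
        raise ValueError("matching needs 2 or 3 channels")
    for ch in chans:
        if ch not in foci:
            raise ValueError(f"unknown channel {ch!r}")
    ref = reference if reference is not None else chans[-1]
    if ref not in chans:
        raise ValueError(f"reference channel {ref!r} not among {chans}")

    pts = {ch: _sorted_points(foci[ch]) for ch in chans}
    counts = {ch: len(pts[ch]) for ch in chans}
    a, b = pts[chans[0]], pts[chans[1]]
    if len(a) == 0 or len(b) == 0:
        pairs: list[tuple[int, int]] = []
    else:
        pairs = _mutual_nn_pairs(a, b, threshold)

    if len(chans) == 2:
        n_coloc = len(pairs)
    else:
        c = pts[chans[2]]
        claimed = np.zeros(len(c), dtype=bool)
        n_coloc = 0
        for i, j in pairs:
            if len(c) == 0:
                break
            mid = (a[i] + b[j]) / 2.0
            dist = np.linalg.norm(c - mid, axis=1)
            dist[claimed] = np.inf
            k = int(dist.argmin())
            if dist[k] <= threshold:
                claimed[k] = True
                n_coloc += 1

    ratio = n_coloc / counts[ref] if counts[ref] > 0 else None
    return ColocResult(
        nucleus_id=nucleus_id,
        counts=counts,
        n_coloc=n_coloc,
        ratio=ratio,
        reference=ref,
        threshold=threshold,
    )


def match_foci_table(
    table: pd.DataFrame,
    channels: Sequence[str],
    threshold: float,
    reference: str | None = None,
) -> list[ColocResult]:
    """Per-nucleus matching over a foci table (nucleus_id, channel, x, y).

    Nuclei appear in first-occurrence order; a nucleus missing a queried
    channel contributes zero foci for it.
    """
    known = set(table["channel"].unique())
    for ch in channels:
        if ch not in known:
            raise ValueError(f"channel {ch!r} not present in table")
    results = []
    for nucleus_id, sub in table.groupby("nucleus_id", sort=False):
        foci = {
            ch: sub.loc[sub["channel"] == ch, ["x", "y"]].to_numpy(dtype=float)
            for ch in channels
        }
        results.append(
            match_foci(foci, threshold, channels, reference, nucleus_id=str(nucleus_id))
        )
    return results


def cofoci_histogram(
    results: Sequence[ColocResult] | Sequence[int],
    bins: Sequence[tuple[str, int, int | None]] = DEFAULT_BINS,
) -> dict[str, float]:
    """Fraction of nuclei per cofocus-count bin.

    Bins are (label, low, high) with inclusive bounds; high=None means
    unbounded. The defaults mirror the conventional reporting bins
    {0, 1-4, 5-8, 9-10, >10}. Fractions sum to 1 over all nuclei.
    """
    counts = [r.n_coloc if isinstance(r, ColocResult) else int(r) for r in results]
    if not counts:
        raise ValueError("need at least one nucleus")
    edges = sorted((lo, np.inf if hi is None else hi) for _, lo, hi in bins)
    for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
        if lo2 <= hi1:
            raise ValueError("bins overlap")
    hist = {label: 0 for label, _, _ in bins}
    for c in counts:
        for label, lo, hi in bins:
            if lo <= c <= (np.inf if hi is None else hi):
                hist[label] += 1
                break
        else:
            raise ValueError(f"cofocus count {c} falls in no bin")
    n = len(counts)
    return {label: hist[label] / n for label in hist}


def positive_fraction_test(
    n_positive_a: int, n_a: int, n_positive_b: int, n_b: int, yates: bool = False
) -> dict:
    """2x2 chi-squared test comparing two positive-nucleus fractions.

    No continuity correction by default (Yates available via ``yates``).
    Used, e.g., to compare the fraction of nuclei showing colocalization
    between two cell lines.
    """
    if min(n_positive_a, n_positive_b) < 0 or n_positive_a > n_a or n_positive_b > n_b:
        raise ValueError("need 0 <= n_positive <= n for both groups")
    table = np.array(
        [[n_positive_a, n_a - n_positive_a], [n_positive_b, n_b - n_positive_b]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a margin of the 2x2 table is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return {"chi2": float(chi2), "p_value": float(p)}


def group_ratio_summary(
    ratios_by_group: Mapping[str, Sequence[ColocResult] | Sequence[float]],
) -> dict:
    """Per-group mean colocalization ratio plus a mean comparison.

    Each group's per-nucleus ratios (nuclei with an undefined ratio are
    dropped) are averaged; two groups are compared with Welch's t test,
    three or more with one-way ANOVA.
    """
    if len(ratios_by_group) < 2:
        raise ValueError("need at least 2 groups")
    pooled: dict[str, list[float]] = {}
    for group, items in ratios_by_group.items():
        vals = [
            (r.ratio if isinstance(r, ColocResult) else float(r))
            for r in items
            if not (isinstance(r, ColocResult) and r.ratio is None)
        ]
        if len(vals) < 2:
            raise ValueError(f"group {group!r} needs at least 2 nuclei")
        pooled[group] = vals
    means = {g: float(np.mean(v)) for g, v in pooled.items()}
    groups = list(pooled)
    if len(groups) == 2:
        comparison = compare_means(pooled[groups[0]], pooled[groups[1]])
    else:
        comparison = anova([pooled[g] for g in groups])
    return {"group_means": means, "comparison": comparison}


def coloc_results_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"nucleus_id": r.nucleus_id}
        row.update({f"n_{ch}": c for ch, c in r.counts.items()})
        row.update(
            {
                "n_coloc": r.n_coloc,
                "ratio": r.ratio,
                "reference": r.reference,
                "threshold": r.threshold,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
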