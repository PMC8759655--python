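"""Single-cell division statistics from a lineage tree.

Doubling times (birth to own abscission), a Gaussian fit of their
distribution, and the division asynchrony of sibling pairs. Founders (whose
birth was not observed) and cells still alive at the end of observation are
excluded, i.e. right-censoring by exclusion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cell_sim import LineageTree

__all__ = [
    "DoublingRecord",
    "SiblingPair",
    "extract_doubling_times",
    "fit_gaussian",
    "sibling_differences",
]


@dataclass(frozen=True)
class DoublingRecord:
    track_id: int
    doubling_time_h: float  # birth to own abscission


@dataclass(frozen=True)
class SiblingPair:
    pair_id: int  # the parent's track id
    division_times_h: tuple[float, float]  # each sibling's doubling time
    difference_h: float  # |t1 - t2|


def extract_doubling_times(lineage: LineageTree) -> list[DoublingRecord]:
    """One record per cell with both birth and abscission observed."""
    records = []
    for node in lineage.nodes.values():
        if node.parent_id is None:  # founder: birth unobserved
            continue
        if not node.divided:  # alive at the end: censored
            continue
        dt_h = (node.abscission_s - node.birth_s) / 3600.0
        if dt_h <= 0:
            raise ValueError(f"track {node.track_id}: non-positive doubling time")
        records.append(DoublingRecord(node.track_id, dt_h))
    return sorted(records, key=lambda r: r.track_id)


def fit_gaussian(times_h, bin_width: float = 1.0):
    """Maximum-likelihood Normal fit of doubling times, plus a histogram.

    The estimate is computed on the raw values (mean = sample mean, sd =
    ML sample SD); the histogram at ``bin_width`` (hours) is returned only
    for plotting and does not influence the fit.

    Returns ``(mean, sd, (counts, bin_edges))``.
    """
    times = np.asarray(list(times_h), dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 doubling times to fit")
    mean = float(np.mean(times))
    sd = float(np.std(times))  # ddof=0: maximum-likelihood estimate
    lo = math.floor(times.min() / bin_width) * bin_width
    hi = math.ceil(times.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(times, bins=edges)
    return mean, sd, (counts, edges)


def sibling_differences(lineage: LineageTree):
    """Division asynchrony of sibling pairs.

    For every division whose two children both divided within the
    observation, pairs the children's own doubling times (birth to
    abscission, i.e. full cell-cycle asynchrony) and takes the absolute
    difference.

    Returns ``(pairs, summary)`` where summary has keys ``mean_diff_h``,
    ``sd_diff_h``, ``max_diff_h`` and ``n_pairs``.
    """
    pairs: list[SiblingPair] = []
    for node in lineage.nodes.values():
        if not node.divided:
            continue
        kids = [lineage.nodes[c] for c in node.child_ids]
        if len(kids) != 2 or not all(k.divided for k in kids):
            continue
        t1, t2 = ((k.abscission_s - k.birth_s) / 3600.0 for k in kids)
        pairs.append(SiblingPair(node.track_id, (t1, t2), abs(t1 - t2)))
    pairs.sort(key=lambda p: p.pair_id)
    if not pairs:
        warnings.warn("no complete sibling pairs in lineage", stacklevel=2)
        summary = {"mean_diff_h": math.nan, "sd_diff_h": math.nan,
                   "max_diff_h": math.nan, "n_pairs": 0}
        return pairs, summary
    diffs = np.array([p.difference_h for p in pairs])
    summary = {
        "mean_diff_h": float(diffs.mean()),
        "sd_diff_h": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        "max_diff_h": float(diffs.max()),
        "n_pairs": len(pairs),
    }
    return pairs, summary
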