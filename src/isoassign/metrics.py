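"""Pairwise comparison of assignment models: accuracy, precision, similarity.

Three individual-level metrics compare two probability-of-origin
surfaces for the same sample:

* **accuracy difference** — change in rescaled probability at the known
  origin cell (A − B): positive means model A places more relative
  probability on the truth.
* **precision area** — total area of cells whose rescaled probability
  is at least that of the true-origin cell (ties included, so the
  metric is well defined on flat surfaces); smaller is more precise.
  Differences are conventionally reported in 10³ km².
* **similarity index** — for each threshold q in {0, step, …, 1}, the
  Jaccard overlap |maskA ∩ maskB| / |maskA ∪ maskB| of the two
  rescaled-probability masks at ≥ q, integrated over q by the
  trapezoidal rule; 1 for identical surfaces, ≈ 0 for disjoint ones.
  (The intersection-over-*all-valid-cells* denominator is available
  behind ``denominator="all"`` but does not reach 1 for identical
  non-full surfaces.)

Summaries use two-sided paired t-tests on the per-sample differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import PosteriorSurface
from .exceptions import ConfigError, PairingError
from .grids import Site, cell_area_km2, require_coregistered


@dataclass
class ComparisonRecord:
    sample_id: str
    accuracy_diff: float           # rescaled probability at truth, A − B
    precision_diff_km2: float      # precision area A − B, km²
    similarity: float

    @property
    def precision_diff_thousand_km2(self) -> float:
        return self.precision_diff_km2 / 1e3


@dataclass
class ComparisonSummary:
    n: int
    df: int
    mean_accuracy_diff: float
    mean_precision_diff_km2: float
    mean_similarity: float | None
    t_accuracy: float
    p_accuracy: float
    t_precision: float
    p_precision: float
    degenerate_accuracy: bool = False
    degenerate_precision: bool = False

    @property
    def mean_precision_diff_thousand_km2(self) -> float:
        return self.mean_precision_diff_km2 / 1e3


def accuracy_difference(
    postA: PosteriorSurface, postB: PosteriorSurface, true_site: Site
) -> float:
    """rescaledA − rescaledB at the cell containing the true origin."""
    require_coregistered(postA.rescaled, postB.rescaled)
    return postA.rescaled_at(true_site) - postB.rescaled_at(true_site)


def precision_area(post: PosteriorSurface, true_site: Site) -> float:
    """Area (km²) of valid cells with rescaled probability ≥ the value
    at the true-origin cell."""
    resc = post.rescaled
    p0 = resc.value_at(true_site.lon, true_site.lat)
    mask = np.zeros(resc.shape, dtype=bool)
    mask[resc.valid] = resc.values[resc.valid] >= p0
    areas = cell_area_km2(resc).values
    return float(areas[mask].sum())


def similarity_index(
    postA: PosteriorSurface,
    postB: PosteriorSurface,
    threshold_step: float = 0.01,
    denominator: str = "union",
) -> float:
    """Threshold-integrated overlap of two rescaled surfaces in [0, 1]."""
    require_coregistered(postA.rescaled, postB.rescaled)
    if not 0 < threshold_step <= 1:
        raise ConfigError(f"threshold_step must be in (0, 1], got {threshold_step}")
    valid = postA.rescaled.valid & postB.rescaled.valid
    a = postA.rescaled.values[valid]
    b = postB.rescaled.values[valid]
    qs = np.arange(0.0, 1.0 + threshold_step / 2, threshold_step)
    s = np.empty(len(qs))
    n_valid = a.size
    for i, q in enumerate(qs):
        ma = a >= q
        mb = b >= q
        inter = np.count_nonzero(ma & mb)
        if denominator == "union":
            union = np.count_nonzero(ma | mb)
            s[i] = inter / union if union > 0 else 1.0
        elif denominator == "all":
            s[i] = inter / n_valid if n_valid > 0 else 1.0
        else:
            raise ConfigError(f"unknown denominator {denominator!r}")
    return float(np.trapezoid(s, qs))


def paired_t(differences: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test of mean difference = 0.

    All-identical differences of 0 make the statistic 0/0; that case is
    returned as (0, 1, degenerate=True).
    """
    d = np.asarray(differences, dtype=float)
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0, True
        return np.inf * np.sign(d.mean()), 0.0, True
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p), False


def summarize_paired_differences(
    accuracy_diffs: Sequence[float],
    precision_diffs_km2: Sequence[float],
    similarities: Sequence[float] | None = None,
) -> ComparisonSummary:
    """Means and two-sided paired t-tests for per-sample differences."""
    acc = np.asarray(accuracy_diffs, dtype=float)
    prec = np.asarray(precision_diffs_km2, dtype=float)
    if len(acc) != len(prec) or len(acc) == 0:
        raise PairingError("accuracy and precision difference vectors must align")
    t_a, p_a, deg_a = paired_t(acc)
    t_p, p_p, deg_p = paired_t(prec)
    return ComparisonSummary(
        n=len(acc),
        df=len(acc) - 1,
        mean_accuracy_diff=float(acc.mean()),
        mean_precision_diff_km2=float(prec.mean()),
        mean_similarity=(
            float(np.mean(similarities)) if similarities is not None else None
        ),
        t_accuracy=t_a,
        p_accuracy=p_a,
        t_precision=t_p,
        p_precision=p_p,
        degenerate_accuracy=deg_a,
        degenerate_precision=deg_p,
    )


def compare_models(
    surfacesA: Sequence[PosteriorSurface],
    surfacesB: Sequence[PosteriorSurface],
    true_sites: Sequence[Site],
    threshold_step: float = 0.01,
    denominator: str = "union",
) -> tuple[list[ComparisonRecord], ComparisonSummary]:
    """Per-sample accuracy/precision/similarity records and their summary.

    The two surface lists must cover the same samples in the same order
    on co-registered grids.
    """
    if not (len(surfacesA) == len(surfacesB) == len(true_sites)):
        raise PairingError(
            f"mismatched collections: {len(surfacesA)} vs {len(surfacesB)} surfaces, "
            f"{len(true_sites)} true sites"
        )
    for a, b in zip(surfacesA, surfacesB):
        if a.sample_id != b.sample_id:
            raise PairingError(f"sample order mismatch: {a.sample_id} vs {b.sample_id}")
    records = []
    for a, b, site in zip(surfacesA, surfacesB, true_sites):
        records.append(
            ComparisonRecord(
                sample_id=a.sample_id,
                accuracy_diff=accuracy_difference(a, b, site),
                precision_diff_km2=precision_area(a, site) - precision_area(b, site),
                similarity=similarity_index(a, b, threshold_step, denominator),
            )
        )
    summary = summarize_paired_differences(
        [r.accuracy_diff for r in records],
        [r.precision_diff_km2 for r in records],
        [r.similarity for r in records],
    )
    return records, summary


def comparison_table(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Per-sample comparison records as a DataFrame (precision in 10³ km²)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "accuracy_diff": [r.accuracy_diff for r in records],
            "precision_diff_thousand_km2": [r.precision_diff_thousand_km2 for r in records],
            "similarity": [r.similarity for r in records],
        }
    )
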