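"""Replicate merging, correlation/distribution summaries, the intensity-
binned robust outlier statistic ("significance B") and FDR adjustment.

The outlier statistic follows the Perseus-style construction: records are
sorted by summed MS intensity and split into equal-occupancy bins; within
each bin the ratio distribution is centred at its median and scaled
separately on each side by the distance from the median to the 15.87th /
84.13th percentile (the one-sigma quantiles of a normal), giving a robust
z from which a two-sided normal p-value is derived.  Benjamini-Hochberg
adjustment is then applied across all records and proteins flagged at
q < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MergedRatio",
    "SignificanceResult",
    "merge_replicates",
    "squared_spearman",
    "distribution_summary",
    "significance_b",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class MergedRatio:
    id: str
    log2_hl_merged: float
    n_replicates: int


@dataclass(frozen=True)
class SignificanceResult:
    id: str
    z: float
    p: float
    q: float
    significant: bool


def merge_replicates(records, method: str = "mean"):
    """Combine per-replicate log2 ratios into one value per record.

    ``records`` is an iterable with ``log2_hl`` dicts (SiteRecord /
    ProteinRecord) keyed by an ``site_id``/``protein_id`` attribute.
    Records with no replicate values are excluded.  Returns a list of
    :class:`MergedRatio`.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown merge method: {method}")
    combine = np.mean if method == "mean" else np.median
    merged = []
    for rec in records:
        values = [v for v in rec.log2_hl.values() if math.isfinite(v)]
        if not values:
            continue
        rid = getattr(rec, "site_id", None) or getattr(rec, "protein_id")
        merged.append(MergedRatio(id=rid, log2_hl_merged=float(combine(values)),
                                  n_replicates=len(values)))
    return merged


def squared_spearman(x, y) -> float:
    """Square of the Spearman rank correlation over complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, have {int(ok.sum())}")
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho ** 2)


def distribution_summary(values, bin_width: float = 0.1):
    """Sample mean, sd (n-1 denominator) and a fixed-width histogram."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need >= 2 finite values")
    lo = bin_width * math.floor(values.min() / bin_width)
    hi = bin_width * math.ceil(values.max() / bin_width)
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return float(values.mean()), float(values.std(ddof=1)), (counts, edges)


def _robust_z(ratios: np.ndarray) -> np.ndarray:
    center = np.median(ratios)
    left = center - np.percentile(ratios, 15.87)
    right = np.percentile(ratios, 84.13) - center
    dev = ratios - center
    z = np.zeros_like(dev)
    neg, pos = dev < 0, dev > 0
    z[neg] = dev[neg] / left if left > 0 else np.inf * np.sign(dev[neg])
    z[pos] = dev[pos] / right if right > 0 else np.inf * np.sign(dev[pos])
    return z


def default_n_bins(n_records: int, min_per_bin: int = 300) -> int:
    """As many intensity bins as leave >= min_per_bin records each."""
    return max(1, n_records // min_per_bin)


def significance_b(merged, intensities, n_bins: int | None = None,
                   alpha: float = 0.05):
    """Intensity-binned robust outlier p-values with BH adjustment.

    ``merged`` is a list of :class:`MergedRatio`; ``intensities`` maps
    record id -> summed MS intensity.  Records are split into ``n_bins``
    equal-occupancy intensity bins (default sized so each holds >= 300
    records); within each bin the side-specific robust z is computed and
    p = erfc(|z| / sqrt(2)) taken two-sided.  Flags significance at
    q < alpha after BH across all records.
    """
    ids = [m.id for m in merged]
    ratios = np.array([m.log2_hl_merged for m in merged], dtype=float)
    try:
        inten = np.array([float(intensities[i]) for i in ids])
    except KeyError as e:
        raise ValueError(f"no intensity for record {e.args[0]!r}") from e
    n = len(merged)
    if n == 0:
        raise ValueError("no records")
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n // n_bins < 10:
        raise ValueError(
            f"{n_bins} bins leave bins of <10 records; use fewer bins")

    order = np.argsort(inten, kind="stable")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    z = np.empty(n)
    for b in range(n_bins):
        idx = order[edges[b]:edges[b + 1]]
        z[idx] = _robust_z(ratios[idx])
    p = special.erfc(np.abs(z) / math.sqrt(2.0))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = benjamini_hochberg(p)
    return [SignificanceResult(id=i, z=float(zz), p=float(pp), q=float(qq),
                               significant=bool(qq < alpha))
            for i, zz, pp, qq in zip(ids, z, p, q)]


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up adjusted values, capped at 1 and monotone in p-rank."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) <= 0 or np.max(p) > 1 or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
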