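"""Core inference: site-to-protein ratio normalization and target calling.

A ubiquitination site's H/L ratio confounds ubiquitination change with
abundance change of its parent protein.  Normalizing by the cognate
protein's pre-enrichment ratio,

    delta = log2(H/L)_site - log2(H/L)_protein,

isolates the ubiquitination component.  Sites are called *reduced* when
delta <= -log2(threshold_fold) and *increased* when
delta >= +log2(threshold_fold) (inclusive at the boundary; default
threshold 3-fold); sites whose protein lacks pre-enrichment
quantification are *unmatched*, never silently dropped.  The module also
cross-tabulates affected proteins against abundance-change calls and
quantifies polyubiquitin chain usage from GG sites on ubiquitin's own
seven lysines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .quant_stats import MergedRatio, merge_replicates
from .synthetic_data import UBIQUITIN_LYSINES

__all__ = [
    "TargetCall",
    "CrossTab",
    "LinkageEntry",
    "LinkageProfile",
    "classify_site",
    "call_targets",
    "crosstab_vs_abundance",
    "linkage_profile",
]

UBIQUITIN_LENGTH = 76

REDUCED, INCREASED, UNCHANGED, UNMATCHED = (
    "reduced", "increased", "unchanged", "unmatched")


@dataclass(frozen=True)
class TargetCall:
    site_id: str
    protein_id: str
    delta: float | None       # None iff unmatched
    fold: float | None        # 2**delta on the linear scale
    label: str


@dataclass(frozen=True)
class CrossTab:
    """Counts over (site class, protein abundance class)."""

    counts: dict  # (site_class, abundance_class) -> count

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class LinkageEntry:
    lysine: int
    mean_log2_hl: float | None
    sem: float | None
    values: tuple  # per-experiment log2 ratios


@dataclass(frozen=True)
class LinkageProfile:
    entries: dict  # lysine -> LinkageEntry, exactly the 7 canonical slots
    total_ubiquitin_log2_hl: float | None


def classify_site(site_log2: float, protein_log2: float | None,
                  threshold_fold: float = 3.0, site_id: str = "",
                  protein_id: str = "") -> TargetCall:
    """Classify one site's relative ratio against the fold threshold."""
    if threshold_fold <= 1:
        raise ValueError(f"threshold_fold must be > 1, got {threshold_fold}")
    if site_log2 is None or not math.isfinite(site_log2):
        raise ValueError("site ratio absent; filter/merge upstream")
    if protein_log2 is None or not math.isfinite(protein_log2):
        return TargetCall(site_id, protein_id, None, None, UNMATCHED)
    delta = site_log2 - protein_log2
    cut = math.log2(threshold_fold)
    if delta <= -cut:
        label = REDUCED
    elif delta >= cut:
        label = INCREASED
    else:
        label = UNCHANGED
    return TargetCall(site_id, protein_id, delta, 2.0 ** delta, label)


def call_targets(sites, proteins, threshold_fold: float = 3.0,
                 merge_method: str = "mean"):
    """Classify every quantified site against its cognate protein.

    ``sites`` / ``proteins`` are filtered SiteRecord / ProteinRecord
    lists; replicates are merged (arithmetic mean of available log2
    ratios by default) before the comparison.  Returns ``(calls,
    summary)`` where summary counts reduced/increased sites, the unique
    proteins contributing them, and matched/unmatched totals.
    """
    if not sites:
        raise ValueError("empty site table")
    site_merged = merge_replicates(sites, method=merge_method)
    prot_merged = {m.id: m.log2_hl_merged
                   for m in merge_replicates(proteins, method=merge_method)}
    site_protein = {s.site_id: s.protein_id for s in sites}
    calls = []
    for m in site_merged:
        pid = site_protein[m.id]
        calls.append(classify_site(m.log2_hl_merged, prot_merged.get(pid),
                                   threshold_fold, site_id=m.id, protein_id=pid))
    summary = summarize_calls(calls)
    return calls, summary


def summarize_calls(calls) -> dict:
    labels = [c.label for c in calls]
    summary = {
        "n_total": len(calls),
        "n_reduced_sites": labels.count(REDUCED),
        "n_increased_sites": labels.count(INCREASED),
        "n_unchanged_sites": labels.count(UNCHANGED),
        "n_unmatched": labels.count(UNMATCHED),
        "n_reduced_proteins": len({c.protein_id for c in calls
                                   if c.label == REDUCED}),
        "n_increased_proteins": len({c.protein_id for c in calls
                                     if c.label == INCREASED}),
    }
    summary["n_matched"] = summary["n_total"] - summary["n_unmatched"]
    return summary


def crosstab_vs_abundance(calls, sig) -> CrossTab:
    """Affected proteins broken down by protein-abundance change.

    ``sig`` is a list of SignificanceResult (z, q, significant) on the
    merged protein ratios.  A protein is "up"/"down" when significant at
    the FDR with positive/negative z, else "no-change".  Each affected
    protein is counted once per site class it contributes to.
    """
    abundance = {}
    for s in sig:
        if s.significant:
            abundance[s.id] = "up" if s.z > 0 else "down"
        else:
            abundance[s.id] = "no-change"
    counts = {(sc, ac): 0 for sc in (REDUCED, INCREASED)
              for ac in ("up", "down", "no-change")}
    for site_class in (REDUCED, INCREASED):
        proteins = {c.protein_id for c in calls if c.label == site_class}
        for pid in proteins:
            counts[(site_class, abundance.get(pid, "no-change"))] += 1
    return CrossTab(counts=counts)


def map_to_monomer(position: int) -> int:
    """Map a position on a polyubiquitin precursor onto the 76-aa monomer."""
    if position < 1:
        raise ValueError("position must be >= 1")
    return ((position - 1) % UBIQUITIN_LENGTH) + 1


def linkage_profile(sites, ubiquitin_ids, proteins=None) -> LinkageProfile:
    """Per-lysine chain-linkage quantification from ubiquitin's GG sites.

    GG sites on any accession in ``ubiquitin_ids`` are remapped onto the
    monomer and pooled into the seven canonical lysine slots; each slot
    reports the mean log2(H/L) +/- SEM over the available experiment
    values.  Positions that do not map to a canonical lysine are excluded
    with a warning.  ``proteins`` (ProteinRecord list) supplies the
    total-ubiquitin ratio, reported alongside.
    """
    ubiquitin_ids = set(ubiquitin_ids)
    per_lysine = {k: [] for k in UBIQUITIN_LYSINES}
    for s in sites:
        if s.protein_id not in ubiquitin_ids:
            continue
        pos = map_to_monomer(s.position)
        if pos not in per_lysine:
            warnings.warn(
                f"site {s.site_id}: position {s.position} does not map to a "
                f"canonical ubiquitin lysine; excluded")
            continue
        per_lysine[pos].extend(
            v for v in s.log2_hl.values() if math.isfinite(v))
    entries = {}
    for k in UBIQUITIN_LYSINES:
        vals = per_lysine[k]
        if vals:
            mean = float(np.mean(vals))
            sem = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                   if len(vals) > 1 else None)
        else:
            mean = sem = None
        entries[k] = LinkageEntry(lysine=k, mean_log2_hl=mean, sem=sem,
                                  values=tuple(vals))
    total = None
    if proteins is not None:
        ub_merged = [m for m in merge_replicates(
            [p for p in proteins if p.protein_id in ubiquitin_ids])]
        if ub_merged:
            total = float(np.mean([m.log2_hl_merged for m in ub_merged]))
    return LinkageProfile(entries=entries, total_ubiquitin_log2_hl=total)
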