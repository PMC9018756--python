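"""Evidence integration around the target list.

Combines the called targets with orthogonal evidence: SILAC IP
co-precipitation (bait vs IgG channel enrichment), known-interactor
lists, WW-domain recognition motifs (L/PPXY and the PY-like S/VPXF), a
generic Fisher's-exact over-representation test against user-supplied
annotation sets (GMT), and a proteome-transcriptome comparison.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quant_stats import benjamini_hochberg, squared_spearman
from .target_calling import INCREASED, REDUCED

__all__ = [
    "InteractorRecord",
    "MotifHit",
    "EnrichmentRow",
    "PY_PATTERN",
    "PY_LIKE_PATTERN",
    "read_ip_table",
    "affected_proteins",
    "interactor_overlap",
    "known_interactor_overlap",
    "scan_py_motifs",
    "read_gmt",
    "fisher_enrichment",
    "proteome_transcriptome_compare",
]

# WW-domain recognition motifs: canonical L/PPXY and the "PY-like" S/VPXF.
PY_PATTERN = r"[LP]P.Y"
PY_LIKE_PATTERN = r"[SV]P.F"
VALID_AA = set("ACDEFGHIKLMNPQRSTVWYUBXZJO*")


@dataclass(frozen=True)
class InteractorRecord:
    protein_id: str
    ip_enrichment: float  # linear fold, bait IP over IgG control

    def __post_init__(self):
        if self.ip_enrichment <= 0:
            raise ValueError("ip_enrichment must be > 0")

    def is_interactor(self, threshold: float = 1.5) -> bool:
        return self.ip_enrichment >= threshold


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_class: str  # "PY" or "PY-like"
    start: int        # 1-based
    matched_text: str


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int   # foreground hits
    K: int   # foreground size
    n: int   # background hits
    N: int   # background size
    fold_enrichment: float
    p: float
    p_bonferroni: float
    p_benjamini: float
    fdr: float


def read_ip_table(path, protein_col: str = "Protein",
                  enrichment_col: str = "IP enrichment",
                  invert: bool = False):
    """Tab-delimited IP table -> InteractorRecord list.

    ``invert`` flips the channel orientation (control/bait instead of
    bait/control) for experiments with swapped SILAC labels.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (protein_col, enrichment_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in IP table")
    records = []
    for _, row in df.iterrows():
        enr = float(row[enrichment_col])
        if invert:
            enr = 1.0 / enr
        records.append(InteractorRecord(str(row[protein_col]), enr))
    return records


def affected_proteins(calls) -> set:
    """Unique proteins with at least one reduced or increased site."""
    return {c.protein_id for c in calls if c.label in (REDUCED, INCREASED)}


def interactor_overlap(calls, ip, threshold: float = 1.5) -> dict:
    """Affected proteins that also co-precipitate with the bait."""
    affected = affected_proteins(calls)
    interactors = {r.protein_id for r in ip if r.is_interactor(threshold)}
    overlap = affected & interactors
    return {
        "n_affected": len(affected),
        "n_interactors": len(interactors),
        "n_overlap": len(overlap),
        "fraction_of_affected": len(overlap) / len(affected) if affected else 0.0,
        "overlap": sorted(overlap),
    }


def known_interactor_overlap(calls, known_set) -> dict:
    """Affected proteins previously reported as interactors."""
    affected = affected_proteins(calls)
    overlap = affected & set(known_set)
    return {
        "n_affected": len(affected),
        "n_known": len(set(known_set)),
        "n_overlap": len(overlap),
        "fraction_of_affected": len(overlap) / len(affected) if affected else 0.0,
        "overlap": sorted(overlap),
    }


def scan_py_motifs(sequences) -> list:
    """Scan {accession: sequence} for PY and PY-like motifs.

    All match *starts* are reported (overlapping matches included),
    1-based.  Non-amino-acid characters trigger a warning and are never
    part of a reported hit.
    """
    hits = []
    patterns = (("PY", re.compile(f"(?=({PY_PATTERN}))")),
                ("PY-like", re.compile(f"(?=({PY_LIKE_PATTERN}))")))
    for acc, seq in sequences.items():
        seq = seq.upper()
        bad = {c for c in seq} - VALID_AA
        if bad:
            warnings.warn(
                f"{acc}: non-amino-acid character(s) {sorted(bad)}; skipped")
        for name, pat in patterns:
            for m in pat.finditer(seq):
                hits.append(MotifHit(protein_id=acc, motif_class=name,
                                     start=m.start() + 1,
                                     matched_text=m.group(1)))
    return hits


def read_gmt(path) -> dict:
    """GMT annotation file -> {term: protein set} (description dropped)."""
    annotation = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            annotation[parts[0]] = set(p for p in parts[2:] if p)
    return annotation


def fisher_enrichment(foreground, background, annotation) -> list:
    """One-sided over-representation per annotation term.

    p is the hypergeometric upper tail P(X >= k) of drawing k annotated
    proteins in a foreground of size K from a background of size N
    containing n annotated; fold enrichment is (k/K)/(n/N).  Adjustments:
    Bonferroni (min(1, m*p)) and BH (reported as both the "Benjamini"
    column and the FDR).  Rows sorted by p.
    """
    foreground, background = set(foreground), set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    K, N = len(foreground), len(background)
    terms, raw = [], []
    for term, members in annotation.items():
        members = set(members) & background
        n = len(members)
        k = len(foreground & members)
        p = float(stats.hypergeom.sf(k - 1, N, n, K)) if n else 1.0
        fold = (k / K) / (n / N) if (K and n) else 0.0
        terms.append((term, k, K, n, N, fold))
        raw.append(min(max(p, np.finfo(float).tiny), 1.0))
    if not terms:
        return []
    raw = np.asarray(raw)
    m = len(raw)
    bonf = np.minimum(1.0, m * raw)
    bh = benjamini_hochberg(raw)
    rows = [EnrichmentRow(term=t, k=k, K=K_, n=n, N=N_, fold_enrichment=f,
                          p=float(p), p_bonferroni=float(b),
                          p_benjamini=float(q), fdr=float(q))
            for (t, k, K_, n, N_, f), p, b, q in zip(terms, raw, bonf, bh)]
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def proteome_transcriptome_compare(protein_merged, expression,
                                   gene_col: str = "Gene",
                                   fc_col: str = "log2 fc",
                                   p_col: str = "step-up p",
                                   id_map=None, alpha: float = 0.05):
    """Join merged protein ratios with a gene-expression table.

    ``protein_merged`` is a list of MergedRatio; ``id_map`` maps protein
    accession -> gene identifier (identity when omitted).  Returns the
    squared Spearman correlation over joined pairs and the joined table
    with per-gene up/down/no-change flags at the supplied step-up p.
    """
    for col in (gene_col, fc_col, p_col):
        if col not in expression.columns:
            raise ValueError(f"missing column {col!r} in expression table")
    expr = expression.set_index(gene_col)
    rows = []
    for m in protein_merged:
        gene = id_map.get(m.id) if id_map is not None else m.id
        if gene is None or gene not in expr.index:
            continue
        fc = float(expr.at[gene, fc_col])
        p = float(expr.at[gene, p_col])
        flag = ("up" if fc > 0 else "down") if p < alpha else "no-change"
        rows.append({"protein": m.id, "gene": gene,
                     "protein_log2_hl": m.log2_hl_merged,
                     "expression_log2_fc": fc, "step_up_p": p,
                     "expression_change": flag})
    if not rows:
        raise ValueError("no joinable protein/gene identifiers")
    joined = pd.DataFrame(rows)
    r2 = squared_spearman(joined["protein_log2_hl"], joined["expression_log2_fc"])
    return r2, joined
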