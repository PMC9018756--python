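"""Synthetic SILAC ubiquitinome bundles with planted ground truth.

The generator emulates the data model of a two-channel SILAC knockdown
experiment quantified by a MaxQuant-style search: a pre-enrichment protein
table and a diGly-site table, each with per-replicate normalized H/L
ratios, plus an IP-enrichment table, a gene-expression table, and protein
sequences.  The statistical skeleton:

* each protein carries a latent log2(H/L) drawn from
  Normal(protein_mu, protein_sigma); the two replicates observe it with
  independent noise sized so that the inter-replicate correlation equals
  ``replicate_corr`` and the per-replicate marginal keeps the configured
  mean and sd,
* each diGly site inherits its cognate protein's latent ratio plus a
  site-to-protein offset drawn from a two-component Gaussian mixture
  whose component means are placed so the *marginal* site ratios peak at
  ``mix_means`` (the observed bimodal site distribution),
* planted target sites instead draw their offset strictly below
  -log2(3): offset = -log2(3) - Exponential(target_excess_scale), so the
  true relative shift of every planted site is at least 3-fold down,
* ubiquitin itself appears with GG sites on its seven lysines, carrying
  the planted linkage shifts on top of the total-ubiquitin ratio.

Because the protein latent enters site and protein rows identically, it
cancels exactly in the site-minus-protein statistic the target caller
uses; closed-form tail masses for that statistic are exposed via
:func:`analytic_reduced_rate` and :func:`analytic_sensitivity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy import integrate, stats

from .tables_io import (ProteinRecord, SiteRecord, write_fasta,
                        write_protein_table, write_site_table)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimBundle",
    "ConfigurationError",
    "UBIQUITIN_SEQUENCE",
    "UBIQUITIN_LYSINES",
    "UBIQUITIN_ACCESSION",
    "simulate_dataset",
    "simulate_cell_image",
    "make_disk_mask",
    "make_ellipse_mask",
    "implied_site_marginal",
    "implied_delta_mixture",
    "analytic_reduced_rate",
    "analytic_increased_rate",
    "analytic_sensitivity",
]

# Canonical 76-residue ubiquitin monomer; lysines at 6, 11, 27, 29, 33, 48, 63.
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYN"
    "IQKESTLHLVLRLRGG"
)
UBIQUITIN_LYSINES = (6, 11, 27, 29, 33, 48, 63)
UBIQUITIN_ACCESSION = "UBIQ"

AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    """An invalid SimConfig field; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study conditions emulated.

    Log2-ratio parameters are in log2(H/L) units.  ``protein_mu`` and
    ``protein_sigma`` reproduce the observed pre-enrichment distribution
    (mean -0.07, sd 0.596); ``mix_means`` the observed site-ratio peaks
    (-1.15 and -0.35).  Weights, component sds, replicate correlation and
    missingness are free parameters of the emulation (see docs/methods.md).
    """

    n_proteins: int = 2000
    sites_per_protein_mean: float = 2.0
    frac_target_sites: float = 0.10
    protein_mu: float = -0.07
    protein_sigma: float = 0.596
    mix_means: tuple = (-1.15, -0.35)
    mix_weights: tuple = (0.4, 0.6)
    mix_sigmas: tuple = (0.18, 0.18)
    replicate_corr: float = 0.9
    missing_rate: float = 0.15
    contam_frac: float = 0.02
    reverse_frac: float = 0.01
    cterm_gg_frac: float = 0.02
    locprob_alpha_beta: tuple = (8.0, 2.0)
    target_excess_scale: float = 0.5
    ubiquitin_log2_hl: float = 0.068
    linkage_shifts: tuple = ((48, -1.0), (63, -1.0))
    interactor_frac_of_targets: float = 0.3
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        def bad(name, why):
            raise ConfigurationError(f"invalid {name}: {why}")

        if self.n_proteins < 1:
            bad("n_proteins", "must be >= 1")
        if self.sites_per_protein_mean <= 0:
            bad("sites_per_protein_mean", "must be > 0")
        for name in ("frac_target_sites", "replicate_corr", "missing_rate",
                     "contam_frac", "reverse_frac", "cterm_gg_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad(name, f"must lie in [0, 1], got {v}")
        if self.protein_sigma <= 0:
            bad("protein_sigma", "must be > 0")
        if len(self.mix_weights) != 2 or abs(sum(self.mix_weights) - 1) > 1e-9 \
                or min(self.mix_weights) < 0:
            bad("mix_weights", "must be a pair on the simplex")
        if len(self.mix_sigmas) != 2 or min(self.mix_sigmas) <= 0:
            bad("mix_sigmas", "must be a positive pair")
        if len(self.mix_means) != 2:
            bad("mix_means", "must be a pair")
        if len(self.locprob_alpha_beta) != 2 or min(self.locprob_alpha_beta) <= 0:
            bad("locprob_alpha_beta", "must be positive Beta parameters")
        if self.target_excess_scale <= 0:
            bad("target_excess_scale", "must be > 0")
        if self.n_replicates < 1:
            bad("n_replicates", "must be >= 1")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    target_site_ids: set = field(default_factory=set)
    target_protein_ids: set = field(default_factory=set)
    planted_linkage_shifts: dict = field(default_factory=dict)
    planted_interactors: set = field(default_factory=set)
    true_site_offsets: dict = field(default_factory=dict)  # site_id -> true shift


@dataclass
class SimBundle:
    """All tables of one simulated experiment."""

    proteins: list
    sites: list
    ip: "object"          # pandas DataFrame: Protein, IP enrichment
    expression: "object"  # pandas DataFrame: Gene, log2 fc, step-up p
    sequences: dict
    replicates: tuple

    def write(self, outdir) -> dict:
        """Serialize to the tab-delimited dialect the io module reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteinGroups.txt",
            "sites": outdir / "GlyGly_sites.txt",
            "ip": outdir / "ip_enrichment.txt",
            "expression": outdir / "expression.txt",
            "fasta": outdir / "proteome.fasta",
        }
        write_protein_table(self.proteins, paths["proteins"], replicates=self.replicates)
        write_site_table(self.sites, paths["sites"], replicates=self.replicates)
        self.ip.to_csv(paths["ip"], sep="\t", index=False)
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        write_fasta(self.sequences, paths["fasta"])
        return paths


# ---------------------------------------------------------------------------
# variance bookkeeping shared by the generator and the analytic formulas

def _variance_split(config: SimConfig):
    rho = config.replicate_corr
    sd_theta = config.protein_sigma * math.sqrt(rho)        # shared protein latent
    sd_eps_p = config.protein_sigma * math.sqrt(1.0 - rho)  # per-rep protein noise
    sigmas = np.asarray(config.mix_sigmas, dtype=float)
    weights = np.asarray(config.mix_weights, dtype=float)
    sd_shared = sigmas * math.sqrt(rho)                      # shared site offset sd
    sigma_bar = math.sqrt(float(weights @ sigmas ** 2))
    sd_eps_s = sigma_bar * math.sqrt(1.0 - rho)              # per-rep site noise
    return sd_theta, sd_eps_p, sd_shared, sd_eps_s


def implied_site_marginal(config: SimConfig):
    """Per-replicate marginal distribution of non-target site log2 ratios.

    Returns (weights, means, sds): a two-component normal mixture.  The
    component means equal ``mix_means``; the sds are the configured
    component sds convolved with the shared protein latent and the
    per-replicate site noise.
    """
    sd_theta, _, sd_shared, sd_eps_s = _variance_split(config)
    weights = np.asarray(config.mix_weights, dtype=float)
    means = np.asarray(config.mix_means, dtype=float)
    sds = np.sqrt(sd_theta ** 2 + sd_shared ** 2 + sd_eps_s ** 2)
    return weights, means, sds


def marginal_site_cdf(config: SimConfig, x):
    """Exact CDF of the implied per-replicate site marginal (for KS tests)."""
    weights, means, sds = implied_site_marginal(config)
    x = np.asarray(x, dtype=float)[..., None]
    return np.sum(weights * stats.norm.cdf(x, loc=means, scale=sds), axis=-1)


def _replicate_count_probs(config: SimConfig):
    """P(n observed replicates | >=1 observed) under MCAR missingness."""
    q, R = config.missing_rate, config.n_replicates
    ns = np.arange(1, R + 1)
    probs = np.array([math.comb(R, int(n)) * (1 - q) ** n * q ** (R - n)
                      for n in ns])
    return ns, probs / probs.sum()


def _delta_noise_sds(config: SimConfig):
    """sd of the merged-replicate noise in delta = site - protein, by
    (n_site, n_protein) observed-replicate combination, with weights."""
    _, sd_eps_p, _, sd_eps_s = _variance_split(config)
    ns, pn = _replicate_count_probs(config)
    combos = []
    for n_s, p_s in zip(ns, pn):
        for n_p, p_p in zip(ns, pn):
            sd = math.sqrt(sd_eps_s ** 2 / n_s + sd_eps_p ** 2 / n_p)
            combos.append((float(p_s * p_p), sd))
    return combos


def implied_delta_mixture(config: SimConfig):
    """Distribution of merged delta = site - protein for non-target sites.

    Returns a list of (weight, mean, sd) normal components: the offset
    mixture convolved with merged replicate noise, averaged over
    observed-replicate-count combinations.
    """
    sd_theta, _, sd_shared, _ = _variance_split(config)
    offset_means = np.asarray(config.mix_means) - config.protein_mu
    weights = np.asarray(config.mix_weights, dtype=float)
    comps = []
    for p_combo, sd_noise in _delta_noise_sds(config):
        for w, m, s in zip(weights, offset_means, sd_shared):
            comps.append((float(p_combo * w), float(m),
                          math.sqrt(s ** 2 + sd_noise ** 2)))
    return comps


def analytic_reduced_rate(config: SimConfig, threshold_fold: float = 3.0) -> float:
    """Exact P(delta <= -log2(threshold)) for a matched non-target site."""
    t = -math.log2(threshold_fold)
    return float(sum(w * stats.norm.cdf(t, loc=m, scale=s)
                     for w, m, s in implied_delta_mixture(config)))


def analytic_increased_rate(config: SimConfig, threshold_fold: float = 3.0) -> float:
    """Exact P(delta >= +log2(threshold)) for a matched non-target site."""
    t = math.log2(threshold_fold)
    return float(sum(w * stats.norm.sf(t, loc=m, scale=s)
                     for w, m, s in implied_delta_mixture(config)))


def analytic_sensitivity(config: SimConfig, threshold_fold: float = 3.0) -> float:
    """P(planted target called reduced): the planted offset sits below the
    threshold by an Exponential excess; the call survives iff the merged
    replicate noise does not push delta back above the threshold."""
    scale = config.target_excess_scale
    total = 0.0
    for p_combo, sd_noise in _delta_noise_sds(config):
        val, _ = integrate.quad(
            lambda x: math.exp(-x / scale) / scale
            * stats.norm.cdf(x / sd_noise), 0, np.inf)
        total += p_combo * val
    return float(total)


# ---------------------------------------------------------------------------
# dataset generation

def _random_sequence(rng, length: int, lysine_positions) -> str:
    seq = rng.choice(list(AA), size=length)
    for pos in lysine_positions:
        seq[pos - 1] = "K"
    return "".join(seq)


def _observed(rng, values, missing_rate, replicates):
    """Apply MCAR missingness; returns replicate -> log2 ratio dict."""
    out = {}
    keep = rng.random(len(replicates)) >= missing_rate
    for rep, v, k in zip(replicates, values, keep):
        if k:
            out[rep] = float(v)
    return out


def simulate_dataset(config: SimConfig):
    """Generate one full synthetic bundle.

    Returns ``(SimBundle, GroundTruth)``.  Identical config (including
    seed) yields identical output, row for row.
    """
    rng = np.random.default_rng(config.seed)
    replicates = tuple(str(i + 1) for i in range(config.n_replicates))
    sd_theta, sd_eps_p, sd_shared, sd_eps_s = _variance_split(config)
    offset_means = np.asarray(config.mix_means) - config.protein_mu
    weights = np.asarray(config.mix_weights, dtype=float)
    thr = math.log2(3.0)

    truth = GroundTruth(planted_linkage_shifts=dict(config.linkage_shifts))
    proteins, sites, sequences = [], [], {}

    prot_ids = [f"SYNP{i:05d}" for i in range(1, config.n_proteins + 1)]
    thetas = config.protein_mu + sd_theta * rng.standard_normal(config.n_proteins)
    n_sites = rng.poisson(config.sites_per_protein_mean, size=config.n_proteins)

    for pid, theta, k in zip(prot_ids, thetas, n_sites):
        prot_values = theta + sd_eps_p * rng.standard_normal(config.n_replicates)
        proteins.append(ProteinRecord(
            protein_id=pid,
            log2_hl=_observed(rng, prot_values, config.missing_rate, replicates),
            intensity=float(10 ** rng.normal(7.0, 0.7)),
        ))
        length = 120 + int(rng.integers(0, 400))
        positions = sorted(rng.choice(np.arange(2, length), size=min(int(k), length - 2),
                                      replace=False).tolist()) if k > 0 else []
        sequences[pid] = _random_sequence(rng, length, positions)
        for pos in positions:
            site_id = f"{pid}_K{pos}"
            is_target = rng.random() < config.frac_target_sites
            if is_target:
                offset = -thr - rng.exponential(config.target_excess_scale)
                truth.target_site_ids.add(site_id)
                truth.target_protein_ids.add(pid)
            else:
                comp = int(rng.random() >= weights[0])
                offset = rng.normal(offset_means[comp], sd_shared[comp])
            truth.true_site_offsets[site_id] = float(offset)
            site_values = (theta + offset
                           + sd_eps_s * rng.standard_normal(config.n_replicates))
            is_cterm = rng.random() < config.cterm_gg_frac
            sites.append(SiteRecord(
                site_id=site_id, protein_id=pid, position=int(pos), residue="K",
                log2_hl=_observed(rng, site_values, config.missing_rate, replicates),
                localization_prob=float(rng.beta(*config.locprob_alpha_beta)),
                is_cterm_gg=is_cterm,
            ))

    # ubiquitin: total-abundance protein group + GG sites at its 7 lysines
    sequences[UBIQUITIN_ACCESSION] = UBIQUITIN_SEQUENCE
    ub_values = (config.ubiquitin_log2_hl
                 + 0.05 * rng.standard_normal(config.n_replicates))
    proteins.append(ProteinRecord(
        protein_id=UBIQUITIN_ACCESSION,
        log2_hl={r: float(v) for r, v in zip(replicates, ub_values)},
        intensity=float(10 ** rng.normal(9.0, 0.3)),
    ))
    for lys in UBIQUITIN_LYSINES:
        shift = truth.planted_linkage_shifts.get(lys, 0.0)
        vals = (config.ubiquitin_log2_hl + shift
                + 0.05 * rng.standard_normal(config.n_replicates))
        sites.append(SiteRecord(
            site_id=f"{UBIQUITIN_ACCESSION}_K{lys}",
            protein_id=UBIQUITIN_ACCESSION, position=lys, residue="K",
            log2_hl={r: float(v) for r, v in zip(replicates, vals)},
            localization_prob=float(rng.beta(*config.locprob_alpha_beta)),
        ))

    # contaminant / reverse decoy rows carrying the MaxQuant "+" dialect
    n_con = int(round(config.contam_frac * config.n_proteins))
    n_rev = int(round(config.reverse_frac * config.n_proteins))
    for i in range(n_con):
        v = rng.normal(0.0, 1.0, size=config.n_replicates)
        proteins.append(ProteinRecord(
            protein_id=f"CON__{i:04d}",
            log2_hl={r: float(x) for r, x in zip(replicates, v)},
            intensity=float(10 ** rng.normal(8.0, 0.7)), contaminant=True))
        sites.append(SiteRecord(
            site_id=f"CON__{i:04d}_K10", protein_id=f"CON__{i:04d}", position=10,
            residue="K", log2_hl={replicates[0]: float(rng.normal())},
            localization_prob=float(rng.beta(*config.locprob_alpha_beta)),
            contaminant=True))
    for i in range(n_rev):
        v = rng.normal(0.0, 1.0, size=config.n_replicates)
        proteins.append(ProteinRecord(
            protein_id=f"REV__{i:04d}",
            log2_hl={r: float(x) for r, x in zip(replicates, v)},
            intensity=float(10 ** rng.normal(6.0, 0.7)), reverse=True))
        sites.append(SiteRecord(
            site_id=f"REV__{i:04d}_K5", protein_id=f"REV__{i:04d}", position=5,
            residue="K", log2_hl={replicates[0]: float(rng.normal())},
            localization_prob=float(rng.beta(*config.locprob_alpha_beta)),
            reverse=True))

    # SILAC IP enrichment: a subset of target proteins interact with the bait
    import pandas as pd
    target_list = sorted(truth.target_protein_ids)
    n_int = int(round(config.interactor_frac_of_targets * len(target_list)))
    planted = set(rng.choice(target_list, size=n_int, replace=False).tolist()) \
        if n_int else set()
    extra = [p for p in prot_ids if p not in truth.target_protein_ids]
    n_extra = int(round(0.05 * len(extra)))
    if n_extra:
        planted |= set(rng.choice(extra, size=n_extra, replace=False).tolist())
    truth.planted_interactors = planted
    ip_rows = []
    for pid in prot_ids:
        if pid in planted:
            enr = float(1.5 * 2 ** rng.uniform(0.05, 2.5))
        else:
            enr = float(2 ** rng.normal(0.0, 0.25))
        ip_rows.append({"Protein": pid, "IP enrichment": enr})
    ip = pd.DataFrame(ip_rows)

    # expression table weakly correlated with the protein latent
    z = (thetas - config.protein_mu) / max(sd_theta, 1e-12)
    rho_e = 0.46
    e = rho_e * z + math.sqrt(1 - rho_e ** 2) * rng.standard_normal(len(z))
    p_raw = 2 * stats.norm.sf(np.abs(e))
    from statsmodels.stats.multitest import multipletests
    p_step = multipletests(p_raw, method="fdr_bh")[1]
    expression = pd.DataFrame({
        "Gene": prot_ids,
        "log2 fc": e,
        "step-up p": p_step,
    })

    bundle = SimBundle(proteins=proteins, sites=sites, ip=ip,
                       expression=expression, sequences=sequences,
                       replicates=replicates)
    return bundle, truth


# ---------------------------------------------------------------------------
# synthetic cell images (fixtures for the radial-intensity statistic)

def make_disk_mask(size: int, radius: float, center=None) -> np.ndarray:
    center = (size / 2 - 0.5, size / 2 - 0.5) if center is None else center
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius ** 2


def make_ellipse_mask(size: int, a: float, b: float, center=None) -> np.ndarray:
    center = (size / 2 - 0.5, size / 2 - 0.5) if center is None else center
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - center[0]) / b) ** 2 + ((xx - center[1]) / a) ** 2 <= 1.0


def simulate_cell_image(mask: np.ndarray, intensity_field, noise_sd: float = 0.0,
                        seed: int = 0):
    """Paint ``intensity_field(r)`` over a cell mask, r being the same
    shape-normalized centroid-to-edge radius the profiler uses; add
    Gaussian noise inside the mask; zero outside.

    Returns ``(image, mask)`` as float64 / bool arrays.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    from .imaging import normalized_radius
    r = normalized_radius(mask)
    rng = np.random.default_rng(seed)
    image = np.zeros(mask.shape, dtype=float)
    image[mask] = intensity_field(r[mask])
    if noise_sd > 0:
        image[mask] += noise_sd * rng.standard_normal(int(mask.sum()))
    return image, mask
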