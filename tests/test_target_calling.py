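"""Site classification, planted-truth recovery, crosstab, linkage profile."""

import math

import numpy as np
import pytest

from diglyquant.quant_stats import SignificanceResult
from diglyquant.synthetic_data import (SimConfig, UBIQUITIN_ACCESSION,
                                       UBIQUITIN_LYSINES, simulate_dataset)
from diglyquant.tables_io import ProteinRecord, SiteRecord, filter_rows
from diglyquant.target_calling import (call_targets, classify_site,
                                       crosstab_vs_abundance, linkage_profile,
                                       map_to_monomer, summarize_calls)


def _site(sid, pid, pos, **ratios):
    return SiteRecord(site_id=sid, protein_id=pid, position=pos, residue="K",
                      log2_hl=dict(ratios), localization_prob=0.95)


def _prot(pid, **ratios):
    return ProteinRecord(protein_id=pid, log2_hl=dict(ratios))


class TestClassifySite:
    def test_profilin_worked_example(self):
        """Of the three PFN1 site fold-changes relative to the protein
        (-2.68, -2.89 and -3.46-fold for K54, K70, K128), exactly the
        -3.46-fold site crosses the 3-fold threshold."""
        folds = {"K54": 2.68, "K70": 2.89, "K128": 3.46}
        calls = {name: classify_site(-math.log2(f), 0.0, threshold_fold=3.0,
                                     site_id=name, protein_id="PFN1")
                 for name, f in folds.items()}
        assert calls["K128"].label == "reduced"
        assert calls["K54"].label == "unchanged"
        assert calls["K70"].label == "unchanged"

    def test_zero_delta_unchanged(self):
        assert classify_site(0.5, 0.5).label == "unchanged"

    def test_direct_arithmetic(self):
        call = classify_site(-2.0, 0.2, threshold_fold=3.0)
        assert call.delta == pytest.approx(-2.2)
        assert call.fold == pytest.approx(2.0 ** -2.2)
        assert call.fold == pytest.approx(0.2176, abs=5e-4)
        assert call.label == "reduced"

    def test_boundary_exactly_threefold_is_affected(self):
        cut = math.log2(3.0)
        assert classify_site(-cut, 0.0).label == "reduced"
        assert classify_site(cut, 0.0).label == "increased"

    def test_absent_protein_ratio_is_unmatched(self):
        call = classify_site(-2.0, None)
        assert call.label == "unmatched"
        assert call.delta is None and call.fold is None

    def test_absent_site_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_site(float("nan"), 0.0)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_site(0.0, 0.0, threshold_fold=1.0)

    def test_monotone_in_site_ratio(self):
        labels = [classify_site(s, 0.0).label
                  for s in np.linspace(-4, 4, 200)]
        order = {"reduced": 0, "unchanged": 1, "increased": 2}
        ranks = [order[l] for l in labels]
        assert ranks == sorted(ranks)


class TestCallTargets:
    def test_zero_noise_recovers_exactly_the_planted_sites(self):
        cfg = SimConfig(n_proteins=500, frac_target_sites=0.05,
                        mix_sigmas=(1e-3, 1e-3), replicate_corr=1.0,
                        missing_rate=0.0, seed=13)
        bundle, truth = simulate_dataset(cfg)
        sites = filter_rows(bundle.sites)
        prots = filter_rows(bundle.proteins)
        calls, _ = call_targets(sites, prots, threshold_fold=3.0)
        called = {c.site_id for c in calls if c.label == "reduced"}
        retained_targets = truth.target_site_ids & {s.site_id for s in sites}
        assert called == retained_targets

    def test_recovery_floors_on_default_bundle(self, filtered_bundle):
        sites, prots, truth = filtered_bundle
        calls, _ = call_targets(sites, prots)
        matched = {c.site_id for c in calls if c.label != "unmatched"}
        called = {c.site_id for c in calls if c.label == "reduced"}
        targets = truth.target_site_ids & matched
        non_targets = matched - truth.target_site_ids
        sensitivity = len(called & targets) / len(targets)
        specificity = 1 - len(called & non_targets) / len(non_targets)
        assert sensitivity >= 0.8
        assert specificity >= 0.99

    def test_labels_invariant_to_global_ratio_shift(self):
        rng = np.random.default_rng(2)
        sites, prots, shifted_s, shifted_p = [], [], [], []
        c = 0.83
        for i in range(200):
            pv = float(rng.normal())
            sv = pv + float(rng.normal(scale=1.5))
            prots.append(_prot(f"P{i}", **{"1": pv}))
            shifted_p.append(_prot(f"P{i}", **{"1": pv + c}))
            sites.append(_site(f"P{i}_K5", f"P{i}", 5, **{"1": sv}))
            shifted_s.append(_site(f"P{i}_K5", f"P{i}", 5, **{"1": sv + c}))
        calls_a, _ = call_targets(sites, prots)
        calls_b, _ = call_targets(shifted_s, shifted_p)
        assert [x.label for x in calls_a] == [x.label for x in calls_b]

    def test_summary_counts_conserve_totals(self, filtered_bundle):
        sites, prots, _ = filtered_bundle
        calls, summary = call_targets(sites, prots)
        assert summary["n_total"] == len(calls)
        assert (summary["n_reduced_sites"] + summary["n_increased_sites"]
                + summary["n_unchanged_sites"] + summary["n_unmatched"]
                ) == summary["n_total"]
        assert summary["n_matched"] + summary["n_unmatched"] == summary["n_total"]
        assert summary == summarize_calls(calls)

    def test_sites_without_protein_quantification_kept_as_unmatched(self):
        sites = [_site("A_K1", "A", 1, **{"1": -2.0}),
                 _site("B_K1", "B", 1, **{"1": -2.0})]
        prots = [_prot("A", **{"1": 0.0})]
        calls, summary = call_targets(sites, prots)
        assert summary["n_unmatched"] == 1
        assert {c.label for c in calls} == {"reduced", "unmatched"}

    def test_empty_site_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_targets([], [])


class TestCrossTab:
    def _sig(self, pid, z, significant):
        return SignificanceResult(id=pid, z=z, p=0.5, q=0.5,
                                  significant=significant)

    def test_nothing_significant_means_all_no_change(self):
        calls, _ = call_targets(
            [_site("A_K1", "A", 1, **{"1": -3.0})], [_prot("A", **{"1": 0.0})])
        ct = crosstab_vs_abundance(calls, [self._sig("A", 1.0, False)])
        assert ct.counts[("reduced", "no-change")] == 1
        assert ct.total() == 1

    def test_counts_sum_to_affected_proteins(self, filtered_bundle):
        sites, prots, _ = filtered_bundle
        calls, summary = call_targets(sites, prots)
        rng = np.random.default_rng(4)
        sig = [self._sig(p.protein_id, float(rng.normal()),
                         bool(rng.random() < 0.05)) for p in prots]
        ct = crosstab_vs_abundance(calls, sig)
        assert ct.total() == (summary["n_reduced_proteins"]
                              + summary["n_increased_proteins"])

    def test_planted_targets_have_unchanged_abundance(self, filtered_bundle):
        """The generator does not couple the planted ubiquitination shift
        to abundance, so nearly all affected proteins sit in no-change."""
        from diglyquant.quant_stats import merge_replicates, significance_b
        sites, prots, _ = filtered_bundle
        calls, _ = call_targets(sites, prots)
        merged = merge_replicates(prots)
        inten = {p.protein_id: p.intensity for p in prots}
        sig = significance_b(merged, inten)
        ct = crosstab_vs_abundance(calls, sig)
        no_change = ct.counts[("reduced", "no-change")]
        reduced_total = sum(v for (sc, _), v in ct.counts.items()
                            if sc == "reduced")
        assert no_change / reduced_total > 0.9


class TestLinkageProfile:
    def test_position_48_lands_in_k48_slot(self):
        sites = [_site("U_K48", "U", 48, **{"1": -1.2})]
        prof = linkage_profile(sites, {"U"})
        assert prof.entries[48].mean_log2_hl == pytest.approx(-1.2)
        assert all(prof.entries[k].mean_log2_hl is None
                   for k in UBIQUITIN_LYSINES if k != 48)

    def test_polyubiquitin_precursor_positions_remap_modulo_monomer(self):
        assert map_to_monomer(76 + 48) == 48
        assert map_to_monomer(3 * 76 + 63) == 63
        assert map_to_monomer(76) == 76
        sites = [_site("U_K124", "U", 124, **{"1": -0.5})]
        prof = linkage_profile(sites, {"U"})
        assert prof.entries[48].mean_log2_hl == pytest.approx(-0.5)

    def test_exactly_seven_slots(self, filtered_bundle):
        sites, prots, _ = filtered_bundle
        prof = linkage_profile(sites, {UBIQUITIN_ACCESSION}, proteins=prots)
        assert tuple(sorted(prof.entries)) == UBIQUITIN_LYSINES

    def test_planted_k48_k63_depression_recovered(self, filtered_bundle):
        sites, prots, truth = filtered_bundle
        prof = linkage_profile(sites, {UBIQUITIN_ACCESSION}, proteins=prots)
        depressed = {k for k, v in truth.planted_linkage_shifts.items()
                     if v != 0.0}
        assert depressed == {48, 63}
        others = [prof.entries[k].mean_log2_hl for k in UBIQUITIN_LYSINES
                  if k not in depressed]
        for k in depressed:
            assert all(prof.entries[k].mean_log2_hl <= o - 0.5 for o in others)
        assert prof.total_ubiquitin_log2_hl == pytest.approx(0.068, abs=0.15)

    def test_unmappable_position_warns_and_excludes(self):
        sites = [_site("U_K10", "U", 10, **{"1": 0.0})]
        with pytest.warns(UserWarning, match="canonical"):
            prof = linkage_profile(sites, {"U"})
        assert all(e.mean_log2_hl is None for e in prof.entries.values())

    def test_no_ubiquitin_sites_degenerates_gracefully(self):
        prof = linkage_profile([_site("A_K1", "A", 1, **{"1": 0.0})], {"U"})
        assert all(e.mean_log2_hl is None for e in prof.entries.values())

    def test_invariant_to_row_order(self, filtered_bundle):
        sites, _, _ = filtered_bundle
        prof_fwd = linkage_profile(sites, {UBIQUITIN_ACCESSION})
        prof_rev = linkage_profile(list(reversed(sites)), {UBIQUITIN_ACCESSION})
        for k in UBIQUITIN_LYSINES:
            assert prof_fwd.entries[k].mean_log2_hl == \
                pytest.approx(prof_rev.entries[k].mean_log2_hl)
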