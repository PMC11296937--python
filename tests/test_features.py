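"""Disorder fractions, KS tests, binding classes, motifs, PTM intersection."""
import numpy as np
import pytest
from scipy import special, stats

from spliceform.alignment import align_isoform_pair
from spliceform.errors import ContractError, ValidationError
from spliceform.features import (classify_idr_function, disorder_fraction,
                                 intersect_ptm_sites, kolmogorov_sf,
                                 ks_two_sample, scan_nglyco_motifs,
                                 summarize_enrichment,
                                 variant_invariant_fractions)
from spliceform.models import GAP, PtmAnnotation, ResidueTrack
from spliceform.simulate import (SimulationConfig, simulate_isoform_pairs,
                                 simulate_tracks_and_ptms)

from .oracles import oracle_ks_exact_p, oracle_motif_regex


def _track(pid, scores, name="disorder_meta"):
    return ResidueTrack(pid, name, list(scores))


class TestDisorderFraction:
    def test_all_high_scores(self):
        assert disorder_fraction(_track("p", [0.9] * 10), (1, 10)) == 1.0

    def test_all_low_scores(self):
        assert disorder_fraction(_track("p", [0.1] * 10), (1, 10)) == 0.0

    def test_threshold_is_strict(self):
        track = _track("p", [0.6, 0.5, 0.4, 0.7])
        assert disorder_fraction(track, (1, 4)) == 0.5

    def test_empty_or_out_of_bounds_region_rejected(self):
        track = _track("p", [0.5] * 5)
        with pytest.raises(ContractError):
            disorder_fraction(track, (3, 2))
        with pytest.raises(ContractError):
            disorder_fraction(track, (1, 6))


class TestVariantInvariantFractions:
    CAN = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
           "AVQVKVKALPDAQFEVVHSLAKWKR")

    def test_no_variant_regions_gives_undefined_variant_fraction(self):
        pair = align_isoform_pair(self.CAN, self.CAN)
        tracks = {"canonical": {"disorder_meta": _track("canonical", [0.9] * len(self.CAN))},
                  "alternative": {"disorder_meta": _track("alternative", [0.9] * len(self.CAN))}}
        vf, inv = variant_invariant_fractions(pair, tracks)
        assert vf is None and inv == 1.0

    def test_disordered_insertion_ordered_backbone(self):
        ins = "EEDEGKVVVRLSE"
        alt = self.CAN[:40] + ins + self.CAN[40:]
        pair = align_isoform_pair(self.CAN, alt)
        can_scores = [0.1] * len(self.CAN)
        alt_scores = [0.1] * 40 + [0.95] * 13 + [0.1] * (len(self.CAN) - 40)
        tracks = {"canonical": {"disorder_meta": _track("canonical", can_scores)},
                  "alternative": {"disorder_meta": _track("alternative", alt_scores)}}
        vf, inv = variant_invariant_fractions(pair, tracks)
        assert vf == 1.0 and inv == 0.0

    def test_matches_per_residue_pooling_oracle(self, rng):
        cfg = SimulationConfig(seed=21, protein_len=(80, 140), indel_len=(5, 25))
        pairs, truth = simulate_isoform_pairs(cfg, rng=rng, n_pairs=10)
        tracks, _, _ = simulate_tracks_and_ptms(pairs, truth, cfg,
                                                rng=np.random.default_rng(5))
        for cid, can, aid, alt in pairs:
            pair = align_isoform_pair(can, alt, cid, aid)
            vf, inv = variant_invariant_fractions(pair, tracks)
            info = truth.pairs[aid]
            can_scores = tracks[cid]["disorder_meta"].scores
            alt_scores = tracks[aid]["disorder_meta"].scores
            if info["kind"] == "deletion":
                s, e = info["canonical_interval"]
                var_pool = can_scores[s - 1:e]
                inv_pool = can_scores[: s - 1] + can_scores[e:]
            else:
                s, e = info["alternative_interval"]
                var_pool = alt_scores[s - 1:e]
                inv_pool = can_scores
            assert vf == pytest.approx(np.mean([v > 0.5 for v in var_pool]))
            assert inv == pytest.approx(np.mean([v > 0.5 for v in inv_pool]))

    def test_track_length_mismatch_is_fatal(self):
        pair = align_isoform_pair(self.CAN, self.CAN)
        tracks = {"canonical": {"disorder_meta": _track("canonical", [0.5] * 3)},
                  "alternative": {"disorder_meta": _track("alternative", [0.5] * 3)}}
        with pytest.raises(ValidationError, match="canonical"):
            variant_invariant_fractions(pair, tracks)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples(self):
        d, _ = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    def test_exact_p_matches_full_enumeration(self):
        a, b = [0.1, 0.4], [0.2, 0.8]
        d, p = ks_two_sample(a, b)
        assert p == pytest.approx(oracle_ks_exact_p(a, b), abs=1e-12)

    def test_exact_matches_scipy_over_random_cases(self, rng):
        for _ in range(100):
            m, n = rng.integers(3, 25, 2)
            a = rng.normal(0, 1, m)
            b = rng.normal(rng.uniform(-1, 1), 1, n)
            d, p = ks_two_sample(a, b)
            ref = stats.ks_2samp(a, b, method="exact")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_asymptotic_matches_kolmogorov_distribution(self, rng):
        for _ in range(50):
            m, n = rng.integers(120, 300, 2)
            a = rng.normal(0, 1, m)
            b = rng.normal(0.1, 1, n)
            d, p = ks_two_sample(a, b)
            en = np.sqrt(m * n / (m + n))
            assert p == pytest.approx(float(special.kolmogorov(en * d)), abs=1e-10)

    def test_own_kolmogorov_series_matches_scipy_special(self):
        for x in np.linspace(0.01, 3.0, 50):
            assert kolmogorov_sf(x) == pytest.approx(float(special.kolmogorov(x)), abs=1e-12)

    def test_empty_sample_is_contract_error(self):
        with pytest.raises(ContractError):
            ks_two_sample([], [1.0])


class TestClassifyIdrFunction:
    def _setup(self, prot_high, rna_high):
        can = "A" * 60
        alt = can[:30] + "W" * 15 + can[30:]
        pair = align_isoform_pair(can, alt)
        n = len(alt)
        base = [0.05] * n
        prot = list(base)
        rna = list(base)
        if prot_high:
            prot[30:45] = [0.9] * 15
        if rna_high:
            rna[30:45] = [0.9] * 15
        disorder = [0.9] * n
        tracks = {
            "canonical": {
                "protein_binding": _track("canonical", [0.05] * 60, "protein_binding"),
                "rna_binding": _track("canonical", [0.05] * 60, "rna_binding"),
                "disorder_fldpnn": _track("canonical", [0.9] * 60, "disorder_fldpnn"),
            },
            "alternative": {
                "protein_binding": _track("alternative", prot, "protein_binding"),
                "rna_binding": _track("alternative", rna, "rna_binding"),
                "disorder_fldpnn": _track("alternative", disorder, "disorder_fldpnn"),
            },
        }
        return pair, tracks

    def test_protein_binding_only(self):
        pair, tracks = self._setup(True, False)
        assert classify_idr_function(pair, tracks) == "protein_binding"

    def test_both_tracks_above_threshold(self):
        pair, tracks = self._setup(True, True)
        assert classify_idr_function(pair, tracks) == "both"

    def test_flat_tracks_give_none(self):
        pair, tracks = self._setup(False, False)
        assert classify_idr_function(pair, tracks) == "none"

    def test_min_run_requirement_suppresses_isolated_spikes(self):
        pair, tracks = self._setup(True, False)
        # thin the bump to single-residue spikes
        scores = tracks["alternative"]["protein_binding"].scores
        for i in range(30, 45):
            if i % 2:
                scores[i] = 0.05
        assert classify_idr_function(pair, tracks, min_run=3) == "none"
        assert classify_idr_function(pair, tracks, min_run=1) == "protein_binding"


class TestScanNglycoMotifs:
    def test_simple_hit(self):
        assert scan_nglyco_motifs("NAS") == [1]

    def test_proline_rule_difference(self):
        assert scan_nglyco_motifs("NPT", rule="NXS_T_literal") == [1]
        assert scan_nglyco_motifs("NPT", rule="sequon_no_proline") == []

    def test_overlapping_hits_all_reported(self):
        assert scan_nglyco_motifs("NNSS") == [1, 2]

    def test_motif_must_start_inside_region_but_may_extend_past(self):
        seq = "AAANQSAA"
        assert scan_nglyco_motifs(seq, region=(1, 4)) == [4]
        assert scan_nglyco_motifs(seq, region=(5, 8)) == []

    @pytest.mark.parametrize("rule", ["NXS_T_literal", "sequon_no_proline"])
    def test_matches_regex_oracle_on_random_sequences(self, rng, rule):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(30):
            seq = "".join(rng.choice(aas, size=80))
            assert scan_nglyco_motifs(seq, rule=rule) == oracle_motif_regex(seq, rule)


class TestIntersectPtmSites:
    CAN = ("MKTAYSAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
           "AVQVKVKALPDAQFEVVHSLAKWKR")

    def test_site_in_deleted_block_is_lost(self):
        alt = self.CAN[:40] + self.CAN[60:]
        pair = align_isoform_pair(self.CAN, alt)
        (out,) = intersect_ptm_sites([PtmAnnotation("c", 45, ptm_type="other")], pair)
        assert out[1] == "lost_by_deletion" and out[2] == GAP

    def test_site_downstream_of_insertion_shifts(self):
        alt = self.CAN[:40] + "EEDEGKVVVRLSE" + self.CAN[40:]
        pair = align_isoform_pair(self.CAN, alt)
        (out,) = intersect_ptm_sites([PtmAnnotation("c", 50, ptm_type="other")], pair)
        assert out[1] == "mapped_to_alternative" and out[2] == 63

    def test_no_variant_regions_all_mapped(self):
        pair = align_isoform_pair(self.CAN, self.CAN)
        sites = [PtmAnnotation("c", 6), PtmAnnotation("c", 17)]
        results = intersect_ptm_sites(sites, pair)
        assert all(cat == "mapped_to_alternative" for _, cat, _ in results)

    def test_site_beyond_length_is_row_error(self):
        pair = align_isoform_pair(self.CAN, self.CAN)
        with pytest.raises(ValidationError, match="beyond"):
            intersect_ptm_sites([PtmAnnotation("c", 999)], pair)

    def test_non_sty_phosphosite_warns(self):
        pair = align_isoform_pair(self.CAN, self.CAN)
        with pytest.warns(UserWarning, match="expected S/T/Y"):
            intersect_ptm_sites([PtmAnnotation("c", 2)], pair)  # K residue

    def test_classification_exhaustive_and_exclusive(self, rng):
        cfg = SimulationConfig(seed=22, protein_len=(80, 140), indel_len=(5, 25))
        pairs, truth = simulate_isoform_pairs(cfg, rng=rng, n_pairs=10)
        for cid, can, aid, alt in pairs:
            pair = align_isoform_pair(can, alt, cid, aid)
            sites = [PtmAnnotation(cid, s) for s in range(1, len(can) + 1)
                     if can[s - 1] in "STY"]
            results = intersect_ptm_sites(sites, pair)
            assert len(results) == len(sites)
            for _, cat, mapped in results:
                assert cat in ("lost_by_deletion", "in_variant_region",
                               "mapped_to_alternative")
                assert (cat == "lost_by_deletion") == (mapped == GAP)


class TestSummarizeEnrichment:
    def _pairs_with_tracks(self, cfg, n_pairs, rng_seed=3):
        pairs, truth = simulate_isoform_pairs(cfg, n_pairs=n_pairs)
        tracks, annotations, truth = simulate_tracks_and_ptms(
            pairs, truth, cfg, rng=np.random.default_rng(rng_seed))
        aligned = [align_isoform_pair(can, alt, cid, aid)
                   for cid, can, aid, alt in pairs]
        return aligned, tracks, annotations

    def test_planted_enrichment_detected(self):
        cfg = SimulationConfig(seed=23, protein_len=(120, 200), indel_len=(10, 40))
        aligned, tracks, annotations = self._pairs_with_tracks(cfg, 40)
        report = summarize_enrichment(aligned, tracks, annotations)
        assert report.ks_disorder[1] < 1e-6
        assert report.n_variant_frac_ge_half >= (2 * report.n_pairs) // 3
        assert sum(report.function_classes.values()) == report.n_pairs

    def test_null_tracks_give_unremarkable_ks(self):
        cfg = SimulationConfig(seed=24, beta_var=(2.0, 8.0), beta_inv=(2.0, 8.0),
                               protein_len=(120, 200), indel_len=(10, 40))
        aligned, tracks, annotations = self._pairs_with_tracks(cfg, 40)
        report = summarize_enrichment(aligned, tracks, annotations)
        assert report.ks_disorder[1] > 1e-4

    def test_single_pair_marked_underpowered_without_crash(self):
        cfg = SimulationConfig(seed=25, protein_len=(120, 200), indel_len=(10, 40))
        aligned, tracks, annotations = self._pairs_with_tracks(cfg, 1)
        report = summarize_enrichment(aligned, tracks, annotations)
        assert report.underpowered
        assert np.isnan(report.ks_disorder[1])
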