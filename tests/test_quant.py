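"""Digestion, uniqueness/razor, normalization, differential model, z-score."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceform.alignment import align_isoform_pair
from spliceform.errors import ContractError, UndefinedStatistic, ValidationError
from spliceform.models import PeptideRecord, SampleDesign
from spliceform.quant import (adjust_bh, assign_razor, classify_uniqueness,
                              digest, fit_differential_model,
                              flag_junction_spanning, normalize_intensities,
                              peptide_ratio_zscore, rollup_protein_intensity,
                              va_log_ratios)
from spliceform.simulate import (SimulationConfig, make_design,
                                 simulate_protein_matrix)

from .oracles import oracle_parent_scan

PDLIM_PEPTIDE = "GLIPSSPQNEPTASVPPESDVYR"


class TestDigest:
    def test_known_unique_peptide_released_at_zero_missed_cleavages(self):
        parent = "MAAAK" + PDLIM_PEPTIDE + "KAAAAAAR"
        assert PDLIM_PEPTIDE in digest(parent, missed_cleavages=0)

    def test_no_cleavage_before_proline(self):
        peps = digest("MKRPAAAAAAK", missed_cleavages=0, min_len=7)
        assert "RPAAAAAAK" in peps
        assert "PAAAAAAK" not in peps

    def test_cleavage_free_sequence_returns_whole_protein(self):
        seq = "MAAAAAQQQWWW"
        assert digest(seq, missed_cleavages=0) == [seq, seq[1:]]

    def test_nterminal_met_cleaved_variant_of_first_peptide(self):
        peps = digest("MAAAAAAKGGGGGGGR", missed_cleavages=0)
        assert "MAAAAAAK" in peps and "AAAAAAK" in peps

    def test_missed_cleavage_budget_and_length_filter(self):
        seq = "AAAAAAKCCCCCCRDDDDDDK"
        zero = digest(seq, missed_cleavages=0)
        one = digest(seq, missed_cleavages=1)
        assert "AAAAAAKCCCCCCR" in one and "AAAAAAKCCCCCCR" not in zero
        assert all(7 <= len(p) <= 50 for p in one)


class TestUniqueness:
    def test_single_parent_is_unique(self):
        recs = classify_uniqueness(["PEPTIDEK"], {"A": "MMPEPTIDEKWW", "B": "MMMM"})
        assert recs[0].uniqueness == "unique" and recs[0].parent_ids == {"A"}

    def test_peptide_in_canonical_and_isoform_is_shared(self):
        db = {"G1": "MMPEPTIDEKWW", "G1-J1": "MMPEPTIDEKYY"}
        recs = classify_uniqueness(["PEPTIDEK"], db)
        assert recs[0].uniqueness == "shared" and len(recs[0].parent_ids) == 2

    def test_il_equate_flag_folds_isoleucine(self):
        db = {"A": "MMPEPTLDEKWW"}
        assert classify_uniqueness(["PEPTIDEK"], db)[0].parent_ids == frozenset()
        assert classify_uniqueness(["PEPTIDEK"], db, equate_il=True)[0].parent_ids == {"A"}

    def test_matches_regex_oracle_on_random_database(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        db = {f"P{i}": "".join(rng.choice(aas, size=120)) for i in range(60)}
        peptides = [seq[j:j + 9] for seq in list(db.values())[:20] for j in (0, 40, 80)]
        for rec in classify_uniqueness(peptides, db):
            assert rec.parent_ids == oracle_parent_scan(rec.sequence, db)


class TestAssignRazor:
    def _records(self, shared_parents, unique_map):
        recs = [PeptideRecord(f"UNIQ{i}PEPT{j}K", frozenset({pid}), "unique")
                for i, (pid, n) in enumerate(unique_map.items()) for j in range(n)]
        recs.append(PeptideRecord("SHAREDPEPK", frozenset(shared_parents)))
        return recs

    def test_razor_goes_to_parent_with_most_unique_peptides(self):
        recs = self._records({"G1", "G1-J1"}, {"G1": 3, "G1-J1": 1})
        shared = [r for r in assign_razor(recs) if r.sequence == "SHAREDPEPK"][0]
        assert shared.uniqueness == "razor" and shared.razor_parent == "G1"

    def test_zero_unique_tie_prefers_canonical(self):
        recs = [PeptideRecord("SHAREDPEPK", frozenset({"G1", "G1-J1"}))]
        shared = assign_razor(recs)[0]
        assert shared.razor_parent == "G1"

    def test_unique_peptides_left_untouched(self):
        recs = self._records({"G1", "G1-J1"}, {"G1": 1})
        out = assign_razor(recs)
        assert all(r.razor_parent is None for r in out if r.uniqueness == "unique")

    def test_lexicographic_tie_break_among_isoforms(self):
        recs = [PeptideRecord("SHAREDPEPK", frozenset({"G1-J2", "G1-J1"}))]
        assert assign_razor(recs)[0].razor_parent == "G1-J1"


class TestFlagJunctionSpanning:
    CAN = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
           "AVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLS")

    def _insertion_pair(self):
        alt = self.CAN[:60] + "EEDEGKVVVRLSE" + self.CAN[60:]
        return align_isoform_pair(self.CAN, alt), alt

    def test_peptide_crossing_into_insertion_is_flagged(self):
        pair, alt = self._insertion_pair()
        peptide = alt[54:68]  # 6 canonical + 8 inserted residues
        assert flag_junction_spanning(peptide, pair) is True

    def test_peptide_inside_invariant_sequence_not_flagged(self):
        pair, alt = self._insertion_pair()
        assert flag_junction_spanning(alt[5:20], pair) is False

    def test_peptide_abutting_region_not_flagged(self):
        pair, alt = self._insertion_pair()
        assert flag_junction_spanning(alt[50:60], pair) is False   # ends at region - 1
        assert flag_junction_spanning(alt[73:85], pair) is False   # starts just after

    def test_peptide_spanning_deletion_junction_is_flagged(self):
        alt = self.CAN[:40] + self.CAN[60:]
        pair = align_isoform_pair(self.CAN, alt)
        assert flag_junction_spanning(alt[35:45], pair) is True
        assert flag_junction_spanning(alt[41:55], pair) is False

    def test_absent_peptide_is_contract_error(self):
        pair, _ = self._insertion_pair()
        with pytest.raises(ContractError):
            flag_junction_spanning("WWWWWWWWW", pair)


class TestNormalizeIntensities:
    def test_single_sample_median_centering(self):
        mat = pd.DataFrame({"s1": [2.0, 8.0]}, index=["p1", "p2"])
        norm, meta = normalize_intensities(mat)
        assert list(norm["s1"]) == [-1.0, 1.0]
        assert meta["sample_medians"]["s1"] == 2.0

    def test_constant_matrix_becomes_zero(self):
        mat = pd.DataFrame({"s1": [8.0, 8.0], "s2": [8.0, 8.0]})
        norm, _ = normalize_intensities(mat)
        assert (norm.to_numpy() == 0).all()

    def test_missing_values_propagate(self):
        mat = pd.DataFrame({"s1": [2.0, np.nan, 8.0], "s2": [1.0, 4.0, 16.0]})
        norm, _ = normalize_intensities(mat)
        assert np.isnan(norm.iloc[1, 0]) and np.isfinite(norm.iloc[1, 1])

    def test_all_missing_sample_is_error_naming_it(self):
        mat = pd.DataFrame({"good": [2.0, 4.0], "empty": [np.nan, np.nan]})
        with pytest.raises(ValidationError, match="empty"):
            normalize_intensities(mat)


class TestRollup:
    def _recs(self):
        return [
            PeptideRecord("AAAAAAK", frozenset({"G1"}), "unique",
                          intensities={"s1": 3e8, "s2": 1e8}),
            PeptideRecord("CCCCCCK", frozenset({"G1"}), "unique",
                          intensities={"s1": 1e8}),
            PeptideRecord("DDDDDDK", frozenset({"G1", "G2"}), "razor",
                          razor_parent="G2", intensities={"s1": 5e8, "s2": 5e8}),
        ]

    def test_unique_mode_sums_unique_only(self):
        mat, n_pep, dropped = rollup_protein_intensity(self._recs(), "unique",
                                                       sample_ids=["s1", "s2"])
        assert mat.loc["G1", "s1"] == 4e8
        assert mat.loc["G1", "s2"] == 1e8
        assert "G2" in dropped

    def test_mode_switch_changes_only_razor_owners(self):
        uniq, _, _ = rollup_protein_intensity(self._recs(), "unique", ["s1", "s2"])
        both, _, _ = rollup_protein_intensity(self._recs(), "unique_razor", ["s1", "s2"])
        assert both.loc["G2", "s1"] == 5e8
        assert (both.loc["G1"] == uniq.loc["G1"]).all()


class TestDifferentialModel:
    def test_noiseless_planted_contrast_recovered_exactly(self):
        cfg = SimulationConfig(seed=13, residual_sd=0.0, donor_sd=0.0,
                               missing_rate=0.0, frac_biased=0.5)
        mat, design, truth = simulate_protein_matrix(cfg, 40)
        for r in fit_differential_model(mat, design):
            assert r.log2fc == pytest.approx(truth[r.feature_id], abs=1e-9)

    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(seed=14, frac_biased=0.0)
        mat, design, _ = simulate_protein_matrix(cfg, 600)
        res = fit_differential_model(mat, design)
        p = np.array([r.p_value for r in res])
        p = p[np.isfinite(p)]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_sample_shift_invariance_after_normalization(self):
        cfg = SimulationConfig(seed=15, missing_rate=0.0)
        mat, design, _ = simulate_protein_matrix(cfg, 50)
        raw = (2.0 ** mat)
        shifted = raw.copy()
        shifted.iloc[:, 3] *= 8.0   # +3 on log2 scale for one sample
        fc_a = [r.log2fc for r in fit_differential_model(normalize_intensities(raw)[0], design)]
        fc_b = [r.log2fc for r in fit_differential_model(normalize_intensities(shifted)[0], design)]
        assert np.allclose(fc_a, fc_b, atol=1e-9)

    def test_protein_short_of_two_samples_per_chamber_is_skipped(self):
        design = make_design(SimulationConfig(n_donors=3))
        cols = [d.sample_id for d in design]
        row = [1.0] * len(cols)
        mat = pd.DataFrame([row, row], index=["ok", "sparse"], columns=cols, dtype=float)
        vent = [i for i, d in enumerate(design) if d.chamber == "ventricle"]
        mat.iloc[1, vent[:-1]] = np.nan   # leave a single ventricle observation
        res = {r.feature_id: r for r in fit_differential_model(mat, design)}
        assert np.isnan(res["sparse"].p_value)
        assert np.isfinite(res["ok"].log2fc)

    def test_ols_flag_matches_statsmodels(self):
        import statsmodels.api as sm

        cfg = SimulationConfig(seed=16, missing_rate=0.0)
        mat, design, _ = simulate_protein_matrix(cfg, 5)
        res = fit_differential_model(mat, design, moderate=False)
        chambers = pd.get_dummies([d.chamber for d in design], dtype=float)
        donors = pd.get_dummies([d.donor for d in design], drop_first=True, dtype=float)
        X = pd.concat([chambers, donors], axis=1).to_numpy()
        for i, r in enumerate(res):
            fit = sm.OLS(mat.iloc[i].to_numpy(), X).fit()
            contrast = np.zeros(X.shape[1])
            contrast[0], contrast[1] = -1.0, 1.0
            tt = fit.t_test(contrast)
            assert r.log2fc == pytest.approx(np.ravel(tt.effect)[0], abs=1e-9)
            assert r.t_stat == pytest.approx(np.ravel(tt.tvalue)[0], abs=1e-8)
            assert r.p_value == pytest.approx(np.ravel(tt.pvalue)[0], abs=1e-10)


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == 0.2

    def test_elementwise_bounds_and_reference_agreement(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 400)))
            adj = adjust_bh(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
            assert np.max(np.abs(adj - multipletests(p, method="fdr_bh")[1])) < 1e-12

    def test_out_of_range_is_contract_error(self):
        with pytest.raises(ContractError):
            adjust_bh([0.1, 1.5])


class TestPeptideRatioZscore:
    def test_constructed_tensin_like_deviation(self):
        shared = [-1.0, 0.0, 1.0]   # mean 0, sample SD 1
        assert peptide_ratio_zscore(2.95, shared) == pytest.approx(2.95)

    def test_target_at_shared_mean_is_zero(self):
        assert peptide_ratio_zscore(0.5, [0.0, 0.5, 1.0]) == pytest.approx(0.0)

    def test_hand_computed_sample_sd(self):
        z = peptide_ratio_zscore(1.0, [-1.0, 1.0, 0.0])
        assert z == pytest.approx(1.0 / np.std([-1, 1, 0], ddof=1))

    def test_shift_invariance(self, rng):
        shared = list(rng.normal(0, 1, 10))
        z0 = peptide_ratio_zscore(0.7, shared)
        z1 = peptide_ratio_zscore(0.7 + 5, [s + 5 for s in shared])
        assert z0 == pytest.approx(z1, abs=1e-12)

    def test_too_few_or_degenerate_shared_signals_undefined(self):
        with pytest.raises(UndefinedStatistic):
            peptide_ratio_zscore(1.0, [0.1, 0.2])
        with pytest.raises(UndefinedStatistic):
            peptide_ratio_zscore(1.0, [0.3, 0.3, 0.3])

    def test_intensity_floor_drops_low_abundance_peptides(self):
        design = make_design(SimulationConfig(n_donors=2))
        cols = [d.sample_id for d in design]
        mat = pd.DataFrame(
            {c: [2e8, 5e7] for c in cols}, index=["bright", "dim"], dtype=float
        )
        ratios = va_log_ratios(mat, design, min_intensity=1e8)
        assert "bright" in ratios.index and "dim" not in ratios.index
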