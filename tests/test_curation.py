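"""Curation workflow: standardization, filters, duplicate merging, audit trail."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cdscreen as cs
from cdscreen.curation import (
    CurationConfig,
    RawRecord,
    Rejection,
    StabilityRecord,
    filter_conditions,
    filter_molecular_weight,
    filter_outliers,
    merge_duplicates,
    run_curation,
    standardize_record,
    strip_counter_ions,
)


def make_record(ln_ks=5.0, guest="c1ccccc1O", cd="betaCD", t=25.0, ph=7.0, source="s"):
    res = standardize_record(RawRecord(guest, cd, ln_ks, "ln", t, ph, source))
    assert isinstance(res, StabilityRecord)
    return res


class TestStandardize:
    def test_missing_conditions_imputed_to_normal(self):
        rec = standardize_record(RawRecord("CCO", "betaCD", 5.0, "ln", None, None))
        assert rec.temperature == 25.0 and rec.ph == 7.0
        assert rec.imputed_temperature and rec.imputed_ph

    def test_missing_structure_rejected(self):
        res = standardize_record(RawRecord(None, "betaCD", 5.0))
        assert isinstance(res, Rejection) and res.reason == "missing_structure"

    def test_identity_passthrough(self):
        rec = make_record(ln_ks=5.0, t=25.0, ph=7.0)
        assert (rec.ln_ks, rec.temperature, rec.ph) == (5.0, 25.0, 7.0)
        assert not rec.imputed_temperature

    def test_linear_ks_converted_to_ln(self):
        rec = standardize_record(RawRecord("CCO", "betaCD", 100.0, "linear"))
        assert rec.ln_ks == pytest.approx(np.log(100.0))

    def test_malformed_value_rejected_not_raised(self):
        res = standardize_record(RawRecord("CCO", "betaCD", float("nan")))
        assert isinstance(res, Rejection)

    def test_stereochemistry_preserved_in_key(self):
        r = standardize_record(RawRecord("C[C@H](N)C(=O)O", "betaCD", 5.0))
        s = standardize_record(RawRecord("C[C@@H](N)C(=O)O", "betaCD", 5.0))
        assert r.guest_key != s.guest_key


class TestCounterIons:
    @pytest.mark.parametrize(
        "inp,expected",
        [("CC(=O)O.[Na+]", "CC(=O)O"), ("c1ccccc1", "c1ccccc1"), ("CC(=O)[O-].[Na+]", "CC(=O)[O-]")],
    )
    def test_single_atom_components_removed(self, inp, expected):
        from rdkit import Chem
        assert strip_counter_ions(inp) == Chem.CanonSmiles(expected)

    def test_all_ion_input_rejected(self):
        with pytest.raises(cs.curation.chem.StructureError, match="no_multi_atom"):
            strip_counter_ions("[Na+].[Cl-]")


class TestFilters:
    def test_mw_strict_boundaries(self):
        # glucose (MW 180.16) passes; methanol and a C40 alkane do not
        kept, removed = filter_molecular_weight(
            [make_record(guest="OCC1OC(O)C(O)C(O)C1O"), make_record(guest="CO"),
             make_record(guest="C" * 40)]
        )
        assert len(kept) == 1 and len(removed) == 2

    @pytest.mark.parametrize("t,ph,keep", [(25, 7, True), (37, 7, False), (20, 5, True), (30, 8, True), (25, 4.9, False)])
    def test_condition_window_inclusive(self, t, ph, keep):
        kept, _ = filter_conditions([make_record(t=t, ph=ph)])
        assert bool(kept) is keep

    @pytest.mark.parametrize("v,keep", [(5.37, True), (11.2, False), (1.1, False), (2.0, True), (10.0, True)])
    def test_lnks_outlier_bounds_inclusive(self, v, keep):
        kept, _ = filter_outliers([make_record(ln_ks=v)])
        assert bool(kept) is keep


class TestMergeDuplicates:
    def _group(self, values, spread_anchor=(2.0, 10.0)):
        """Records forming one duplicate group plus two far-apart singletons
        that pin the global ln(Ks) range to spread_anchor."""
        recs = [make_record(ln_ks=v, guest="CCO") for v in values]
        recs.append(make_record(ln_ks=spread_anchor[0], guest="CCN"))
        recs.append(make_record(ln_ks=spread_anchor[1], guest="CCS"))
        return recs

    def test_small_spread_merges_to_mean(self):
        out, merged, rej = merge_duplicates(self._group([5.0, 5.5]))
        assert merged == 1 and not rej
        merged_rec = next(r for r in out if r.merged_from == 2)
        assert merged_rec.ln_ks == pytest.approx(5.25)

    def test_large_spread_drops_group(self):
        out, merged, rej = merge_duplicates(self._group([3.0, 6.0]))
        assert merged == 0 and len(rej) == 2
        assert all(r.merged_from == 1 for r in out)

    def test_singleton_untouched(self):
        out, merged, rej = merge_duplicates(self._group([4.2]))
        assert merged == 0 and not rej and len(out) == 3

    def test_merge_idempotent(self):
        out1, _, _ = merge_duplicates(self._group([5.0, 5.2, 5.1]))
        out2, merged2, rej2 = merge_duplicates(out1)
        assert merged2 == 0 and not rej2
        assert [(r.guest_key, r.ln_ks) for r in out2] == [(r.guest_key, r.ln_ks) for r in out1]

    @given(st.lists(st.floats(min_value=2.1, max_value=9.9), min_size=1, max_size=6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_merged_value_within_group_bounds(self, values):
        out, _, _ = merge_duplicates(self._group(values))
        grp = [r for r in out if r.guest_key == make_record(guest="CCO").guest_key]
        if grp and grp[0].merged_from > 1:
            assert min(values) - 1e-9 <= grp[0].ln_ks <= max(values) + 1e-9


class TestFullPipeline:
    def test_planted_counts_match_report_exactly(self, planted_world, curated_world):
        _, _, truth = planted_world
        _, df, report, _ = curated_world
        assert report.step_named("structure_filter").records_removed == truth.n_structureless
        assert report.step_named("duplicate_merge").records_merged == truth.expected_merged_away
        assert report.step_named("duplicate_merge").records_removed == truth.expected_discordant_removed
        assert report.step_named("molecular_weight_filter").records_removed == truth.n_mw_outliers
        assert report.step_named("condition_filter").records_removed == truth.n_condition_outliers
        assert report.step_named("outlier_filter").records_removed == truth.n_lnks_outliers
        assert len(df) == truth.expected_final

    def test_report_conservation(self, curated_world):
        _, _, report, _ = curated_world
        for step in report.steps:
            assert step.records_in - step.records_removed - step.records_merged == step.records_out
        for a, b in zip(report.steps[1:], report.steps[2:]):
            assert a.records_out == b.records_in

    def test_deterministic_and_permutation_invariant(self, planted_world):
        _, raws, _ = planted_world
        rec1, rep1 = run_curation(raws)
        shuffled = [raws[i] for i in np.random.default_rng(5).permutation(len(raws))]
        rec2, rep2 = run_curation(shuffled)
        key = lambda r: (r.guest_key, r.cd_key, r.temperature, r.ph, round(r.ln_ks, 9))
        assert sorted(map(key, rec1)) == sorted(map(key, rec2))
        assert [s.records_out for s in rep1.steps] == [s.records_out for s in rep2.steps]

    def test_empty_output_raises_with_advice(self):
        raws = [RawRecord("CCO", "betaCD", 50.0, "ln", 25, 7)]  # outlier only
        with pytest.raises(cs.curation.EmptyDatasetError, match="report"):
            run_curation(raws)
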