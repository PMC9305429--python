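"""Peak matching, the seven criteria and chemical cluster assignment."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lavauth import (
    PANEL,
    CriteriaProfile,
    PeakTable,
    assign_cluster,
    evaluate_criteria,
    make_peak_table,
    match_peaks,
    select_marker_compounds,
    zero_noise_config,
)


def _table(rows, sample_id="s"):
    return PeakTable(sample_id=sample_id, peaks=pd.DataFrame(rows, columns=["rt", "area"]))


class TestMatchPeaks:
    def test_peak_within_tolerance_matches(self, library):
        matched = match_peaks(_table([(3.24, 100.0)]), library, rt_tolerance=0.05)
        assert matched[8] == 100.0

    def test_peak_outside_tolerance_does_not_match(self, library):
        matched = match_peaks(_table([(3.40, 100.0)]), library, rt_tolerance=0.05)
        assert matched[8] == 0.0

    def test_largest_area_wins_within_tolerance(self, library):
        matched = match_peaks(_table([(3.21, 50.0), (3.25, 80.0)]), library)
        assert matched[8] == 80.0

    def test_one_peak_serves_colliding_reference_rts(self, library):
        matched = match_peaks(_table([(12.85, 42.0)]), library)
        assert matched[94] == 42.0 and matched[95] == 42.0

    def test_empty_library_rejected(self, library):
        from lavauth.chemo import CompoundLibrary

        with pytest.raises(ValueError):
            match_peaks(_table([(3.23, 1.0)]), CompoundLibrary(entries=[]))


class TestEvaluateCriteria:
    def _profile_for(self, taxon_id, library, key):
        config = zero_noise_config(seed=0)
        taxon = next(t for t in PANEL if t.taxon_id == taxon_id)
        matched = match_peaks(make_peak_table(taxon, library, config, key=key), library)
        return evaluate_criteria(matched, library)

    def test_dentata_meets_criteria_1_2_3(self, library, key):
        profile = self._profile_for("dentata", library, key)
        assert (profile.c1, profile.c2, profile.c3) == (True, True, True)
        assert not profile.c4

    def test_perovskia_meets_criteria_2_4_5_7(self, library, key):
        profile = self._profile_for("perovskia", library, key)
        assert profile.as_tuple() == (False, True, False, True, True, False, True)

    def test_all_zero_matches_give_only_c4(self, library):
        matched = {c.compound_id: 0.0 for c in library.entries}
        profile = evaluate_criteria(matched, library)
        assert profile.as_tuple() == (False, False, False, True, False, False, False)

    def test_zero_noise_panel_reproduces_key_matrix(self, library, key):
        """Every taxon's evaluated criteria equal its key row, cell for cell."""
        config = zero_noise_config(seed=11)
        for taxon in PANEL:
            matched = match_peaks(make_peak_table(taxon, library, config, key=key), library)
            profile = evaluate_criteria(matched, library)
            assert profile == key.by_taxon[taxon.taxon_id].profile, taxon.taxon_id

    def test_c3_and_c4_never_both_hold(self, library):
        with pytest.raises(ValueError):
            CriteriaProfile(False, False, True, True, False, False, False)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a15=st.floats(min_value=0, max_value=100, allow_nan=False),
        a16=st.floats(min_value=0, max_value=100, allow_nan=False),
        a53=st.floats(min_value=0, max_value=100, allow_nan=False),
    )
    def test_c3_c4_mutual_exclusion_property(self, library, a15, a16, a53):
        matched = {c.compound_id: 0.0 for c in library.entries}
        matched[15], matched[16], matched[53] = a15, a16, a53
        profile = evaluate_criteria(matched, library)
        assert not (profile.c3 and profile.c4)


class TestAssignCluster:
    def test_exact_key_rows_assign_printed_clusters(self, key):
        for row in key.rows:
            assignment = assign_cluster(row.profile, key, sample_id=row.taxon)
            assert assignment.cluster == row.cluster
            assert assignment.hamming_distance == 0

    def test_distant_profile_left_unassigned(self, key):
        profile = CriteriaProfile(False, False, False, False, False, False, False)
        worst = min(profile.hamming(r.profile) for r in key.rows)
        assignment = assign_cluster(profile, key, max_hamming=worst - 1)
        assert assignment.cluster is None
        assert assignment.hamming_distance == worst

    def test_tie_broken_by_lowest_cluster(self, key):
        # White and Abrial share a profile; the tie must resolve stably.
        white = key.by_taxon["ang_white"]
        assignment = assign_cluster(white.profile, key)
        assert assignment.matched_profile_taxon == "ang_white"

    def test_zero_noise_panel_covers_six_clusters(self, library, key):
        config = zero_noise_config(seed=13)
        clusters = set()
        for taxon in PANEL:
            matched = match_peaks(make_peak_table(taxon, library, config, key=key), library)
            profile = evaluate_criteria(matched, library)
            clusters.add(assign_cluster(profile, key, sample_id=taxon.taxon_id).cluster)
        assert clusters == {1, 2, 3, 4, 5, 6}

    def test_empty_key_rejected(self):
        from lavauth.chemo import ChemotaxonomicKey

        with pytest.raises(ValueError):
            ChemotaxonomicKey(rows=[])


class TestSelectMarkerCompounds:
    def test_zero_noise_panel_flags_the_seven_discriminants(self, library, key):
        config = zero_noise_config(seed=17)
        tables = [make_peak_table(t, library, config, key=key) for t in PANEL]
        selected = select_marker_compounds(tables, library)
        assert sorted(selected) == [8, 14, 15, 16, 21, 37, 53]

    def test_threshold_zero_returns_every_matched_compound(self, library, key):
        config = zero_noise_config(seed=17)
        tables = [make_peak_table(t, library, config, key=key) for t in PANEL]
        selected = select_marker_compounds(tables, library, presence_threshold=0.0)
        matched_any = set()
        for table in tables:
            matched = match_peaks(table, library)
            matched_any |= {cid for cid, area in matched.items() if area > 0}
        assert set(selected) == matched_any

    def test_single_empty_table_gives_empty_list(self, library):
        assert select_marker_compounds([_table([])], library) == []

    def test_noise_peaks_never_change_assignments(self, library, key):
        quiet = zero_noise_config(seed=19)
        noisy = zero_noise_config(seed=19, n_noise_peaks=15)
        for taxon in PANEL:
            quiet_profile = evaluate_criteria(
                match_peaks(make_peak_table(taxon, library, quiet, key=key), library), library
            )
            noisy_profile = evaluate_criteria(
                match_peaks(make_peak_table(taxon, library, noisy, key=key), library), library
            )
            assert quiet_profile == noisy_profile
            assert (
                assign_cluster(quiet_profile, key).cluster
                == assign_cluster(noisy_profile, key).cluster
            )
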