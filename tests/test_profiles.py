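"""B-factor conversion, terminal truncation, normalization, replicate
averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexbench.exceptions import (
    AlignmentError,
    MissingDataError,
    NormalizationError,
    TruncationDegenerateError,
)
from flexbench.metrics import ProfilePair, pearson, spearman
from flexbench.profiles import (
    FluctProfile,
    apply_truncation,
    average_replicates,
    bfactor_to_rmsf,
    normalize_profile,
    rmsf_to_bfactor,
    truncate_termini,
    xray_profile,
)
from conftest import structure_from, random_coords

B_UNIT = 8 * np.pi**2 / 3  # B-factor equal to RMSF of exactly 1 Å


def profile_from(values, source="predicted"):
    values = np.asarray(values, dtype=float)
    return FluctProfile(
        protein_id="p",
        residue_numbers=np.arange(1, len(values) + 1),
        values=values,
        source=source,
    )


class TestDebyeWaller:
    def test_zero_maps_to_zero(self):
        assert bfactor_to_rmsf(0.0) == 0.0

    def test_unit_point(self):
        assert bfactor_to_rmsf(B_UNIT) == pytest.approx(1.0, abs=1e-15)

    def test_closed_form_value(self):
        assert bfactor_to_rmsf(78.96) == pytest.approx(1.7321, abs=1e-4)

    def test_round_trip(self, rng):
        b = rng.uniform(0, 1000, size=200)
        back = rmsf_to_bfactor(bfactor_to_rmsf(b))
        np.testing.assert_allclose(back, b, rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bfactor_to_rmsf(-1.0)
        with pytest.raises(ValueError):
            rmsf_to_bfactor(-0.5)


class TestXrayProfile:
    def test_flat_bfactors_give_flat_profile(self, rng):
        s = structure_from(random_coords(5, rng), bfactors=np.full(5, 30.0))
        prof = xray_profile(s)
        assert prof.source == "xray"
        assert np.ptp(prof.values) == 0.0

    def test_forced_values(self, rng):
        s = structure_from(random_coords(3, rng), bfactors=[B_UNIT, 0.0, B_UNIT])
        np.testing.assert_allclose(xray_profile(s).values, [1, 0, 1], atol=1e-12)

    def test_elementwise_oracle(self, rng):
        b = rng.uniform(0, 80, size=12)
        s = structure_from(random_coords(12, rng), bfactors=b)
        np.testing.assert_allclose(
            xray_profile(s).values, np.sqrt(3 * b / (8 * np.pi**2)), rtol=1e-12
        )

    def test_missing_bfactors(self, rng):
        with pytest.raises(MissingDataError):
            xray_profile(structure_from(random_coords(4, rng)))


class TestTruncation:
    def test_flat_profile_untouched(self):
        rng_ = truncate_termini(profile_from([2.0] * 8))
        assert (rng_.lnt, rng_.lct) == (0, 0)

    def test_worked_example_removes_one_per_end(self):
        # mean 3.25, sample SD 4.166, threshold 7.416: only the 10s fall
        prof = profile_from([10, 1, 1, 1, 1, 1, 1, 10])
        rng_ = truncate_termini(prof)
        assert (rng_.lnt, rng_.lct) == (1, 1)
        assert (rng_.first_kept, rng_.last_kept) == (2, 7)

    def test_interior_spike_never_removed(self):
        rng_ = truncate_termini(profile_from([1, 1, 9, 1, 1]))
        assert (rng_.lnt, rng_.lct) == (0, 0)

    def test_invariant_under_positive_rescaling(self, rng):
        vals = rng.uniform(0.5, 2.0, size=20)
        vals[:2] *= 8
        vals[-3:] *= 6
        p = profile_from(vals)
        r1 = truncate_termini(p, iterate=True)
        r2 = truncate_termini(profile_from(37.5 * vals), iterate=True)
        assert r1 == r2

    def test_iterated_truncation_reaches_fixed_point(self, rng):
        vals = np.concatenate(
            [[40, 20, 10], rng.uniform(0.9, 1.1, size=24), [12, 30]]
        )
        p = profile_from(vals)
        r1 = truncate_termini(p, iterate=True)
        kept = apply_truncation(p, r1)
        r2 = truncate_termini(kept, iterate=True)
        assert (r2.lnt, r2.lct) == (0, 0)

    def test_everything_removed_raises(self):
        """With the default strict > mean + 1*SD rule at least the minimum
        always survives a pass, so total removal needs a pathological
        threshold; the guard must still refuse to return an empty range."""
        with pytest.raises(TruncationDegenerateError):
            truncate_termini(profile_from([3.0, 1.0, 2.0]), threshold_sd=-10.0)

    def test_iterated_truncation_stops_at_three_residues(self):
        # ever-increasing tail: each pass trims the current maximum, but the
        # iteration must bottom out instead of eating the whole chain
        rng_ = truncate_termini(profile_from(np.exp(np.arange(12.0))), iterate=True)
        assert rng_.last_kept - rng_.first_kept + 1 >= 3

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=100.0), min_size=4, max_size=30
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_truncation_range_scale_free(self, values, scale):
        p = profile_from(values)
        q = profile_from(scale * np.asarray(values))
        assert truncate_termini(p, iterate=True) == truncate_termini(q, iterate=True)

    def test_single_pass_vs_iterated(self):
        # second pass only fires in the iterated (NMR) convention
        vals = [50.0, 9.0] + [1.0] * 10
        single = truncate_termini(profile_from(vals), iterate=False)
        iterated = truncate_termini(profile_from(vals), iterate=True)
        assert single.lnt == 1
        assert iterated.lnt == 2


class TestNormalization:
    def test_max_division(self):
        np.testing.assert_allclose(
            normalize_profile(profile_from([2, 4, 8])).values, [0.25, 0.5, 1.0]
        )

    def test_idempotent(self, rng):
        p = normalize_profile(profile_from(rng.uniform(0.1, 3, size=9)))
        np.testing.assert_allclose(normalize_profile(p).values, p.values)

    def test_all_zero_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_profile(profile_from([0.0, 0.0, 0.0]))

    def test_correlations_invariant_under_normalization(self, rng):
        a = profile_from(rng.uniform(0.1, 2, size=15))
        b = profile_from(rng.uniform(0.1, 2, size=15))
        raw = ProfilePair(predicted=a, experimental=b)
        norm = ProfilePair(
            predicted=normalize_profile(a), experimental=normalize_profile(b)
        )
        assert pearson(raw) == pytest.approx(pearson(norm), abs=1e-12)
        assert spearman(raw) == pytest.approx(spearman(norm), abs=1e-12)


class TestReplicateAveraging:
    def test_identical_profiles_unchanged(self):
        p = profile_from([1, 2, 4])
        out = average_replicates([p, p, p])
        np.testing.assert_allclose(out.values, [0.25, 0.5, 1.0])  # normalized

    def test_symmetric_pair(self):
        out = average_replicates([profile_from([1, 0]), profile_from([0, 1])])
        np.testing.assert_allclose(out.values, [1.0, 1.0])

    def test_normalize_mean_renormalize_chain(self, rng):
        profs = [profile_from(rng.uniform(0.2, 3, size=7)) for _ in range(3)]
        out = average_replicates(profs)
        stack = np.stack([p.values / p.values.max() for p in profs])
        expected = stack.mean(axis=0)
        expected /= expected.max()
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_residue_mismatch_rejected(self):
        a = profile_from([1, 2, 3])
        b = FluctProfile(
            protein_id="p",
            residue_numbers=[2, 3, 4],
            values=[1, 2, 3],
            source="predicted",
        )
        with pytest.raises(AlignmentError):
            average_replicates([a, b])
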