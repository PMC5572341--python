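"""V_st statistic, run scanning, CNV mapping and the sex-artifact filter."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from conftest import make_probes, make_signal
from cnvherd.calls import CnvCall
from cnvherd.regions import build_cnvrs
from cnvherd.signal import SampleMeta
from cnvherd.vst import (
    VstTrack,
    map_runs_to_cnvs,
    per_probe_vst,
    scan_differentiated_runs,
    sex_artifact_filter,
    vst_from_arrays,
)


class TestVstFromArrays:
    def test_identical_groups_give_zero(self):
        vst = vst_from_arrays(np.array([[0.0, 1.0]]), np.array([[0.0, 1.0]]))
        assert vst[0] == pytest.approx(0.0, abs=1e-10)

    def test_no_within_group_variance_gives_one(self):
        vst = vst_from_arrays(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))
        assert vst[0] == pytest.approx(1.0, abs=1e-10)

    def test_worked_two_plus_two_example(self):
        # A = {0, 0.2}, B = {0.8, 1.2}: V_T = 0.2275, V_S = 0.025
        vst = vst_from_arrays(np.array([[0.0, 0.2]]), np.array([[0.8, 1.2]]))
        assert vst[0] == pytest.approx((0.2275 - 0.025) / 0.2275, abs=1e-10)

    def test_zero_total_variance_defined_as_zero(self):
        vst = vst_from_arrays(np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]))
        assert vst[0] == 0.0

    def test_group_with_one_sample_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            vst_from_arrays(np.array([[0.0]]), np.array([[1.0, 2.0]]))

    def test_weighted_variant_bounded_below_by_zero(self, rng):
        # size-weighted V_S with denominator-n variances: law of total
        # variance guarantees V_T >= V_S, so V_st stays in [0, 1]
        for _ in range(200):
            a = rng.normal(0, 1, (1, int(rng.integers(2, 6))))
            b = rng.normal(0, 1, (1, int(rng.integers(2, 6))))
            assert 0.0 <= vst_from_arrays(a, b)[0] <= 1.0

    def test_unweighted_variant_can_go_negative_unclamped(self):
        # variable group A in a small group, quiet large group B
        a = np.array([[-1.0, 1.0]])
        b = np.array([[0.0, 0.0, 0.0, 0.0]])
        assert vst_from_arrays(a, b, weighted=False)[0] < 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-5, 5, allow_nan=False),
        scale=st.floats(0.1, 10.0),
        data=st.lists(
            st.floats(-2, 2, allow_nan=False, allow_infinity=False),
            min_size=6, max_size=6,
        ),
    )
    def test_invariant_to_affine_lrr_transform(self, shift, scale, data):
        assume(np.ptp(data) > 1e-3)  # avoid catastrophic cancellation regime
        a = np.array([data[:3]])
        b = np.array([data[3:]])
        base = vst_from_arrays(a, b)
        moved = vst_from_arrays(a * scale + shift, b * scale + shift)
        np.testing.assert_allclose(moved, base, atol=1e-8)


class TestScanRuns:
    def _track(self, values):
        return VstTrack(("A", "B"), np.asarray(values, dtype=float))

    def test_three_consecutive_probes_form_a_run(self):
        probes = make_probes(3)
        runs = scan_differentiated_runs(self._track([0.4, 0.4, 0.4]), probes)
        assert len(runs) == 1 and runs[0].n_probes == 3

    def test_interruption_splits_runs(self):
        probes = make_probes(5)
        runs = scan_differentiated_runs(
            self._track([0.4, 0.2, 0.4, 0.4, 0.4]), probes
        )
        (run,) = runs
        assert (run.first_probe, run.last_probe) == (2, 4)

    def test_two_probes_never_form_a_run(self):
        probes = make_probes(2)
        assert scan_differentiated_runs(self._track([0.9, 0.9]), probes) == []

    def test_threshold_is_strict(self):
        probes = make_probes(3)
        assert scan_differentiated_runs(self._track([0.35, 0.35, 0.35]), probes) == []

    def test_runs_do_not_cross_chromosomes(self):
        probes = make_probes(6, chrom=[1, 1, 1, 2, 2, 2])
        runs = scan_differentiated_runs(self._track([0.4] * 6), probes)
        assert [r.chrom for r in runs] == [1, 2]
        assert all(r.n_probes == 3 for r in runs)

    def test_raising_threshold_shrinks_runs(self, rng):
        probes = make_probes(200)
        track = self._track(rng.uniform(0, 1, 200))
        low = scan_differentiated_runs(track, probes, threshold=0.3)
        high = scan_differentiated_runs(track, probes, threshold=0.6)
        low_probes = {
            i for r in low for i in range(r.first_probe, r.last_probe + 1)
        }
        high_probes = {
            i for r in high for i in range(r.first_probe, r.last_probe + 1)
        }
        assert high_probes <= low_probes
        assert len(high) <= len(low) or sum(r.n_probes for r in high) <= sum(
            r.n_probes for r in low
        )


class TestMapRuns:
    def _runs(self, start_bp, end_bp, chrom=1):
        probes = make_probes(60, chrom=chrom, spacing=5_000)
        vst = np.zeros(60)
        i0 = start_bp // 5_000 - 1
        i1 = end_bp // 5_000 - 1
        vst[i0 : i1 + 1] = 0.5
        return scan_differentiated_runs(VstTrack(("A", "B"), vst), probes)

    def test_containing_cnvr_is_flagged(self):
        runs = self._runs(150_000, 170_000)
        cnvrs, _ = build_cnvrs(
            [CnvCall("A", 1, 100_000, 200_000, 1, 5),
             CnvCall("B", 1, 100_000, 200_000, 1, 5)], 2
        )
        (run,) = map_runs_to_cnvs(runs, cnvrs)
        assert run.mapped_ids == (cnvrs[0].cnvr_id,)

    def test_partially_covering_cnvr_is_not_flagged(self):
        runs = self._runs(150_000, 170_000)
        cnvrs, _ = build_cnvrs(
            [CnvCall("A", 1, 100_000, 160_000, 1, 5),
             CnvCall("B", 1, 100_000, 160_000, 1, 5)], 2
        )
        (run,) = map_runs_to_cnvs(runs, cnvrs)
        assert run.mapped_ids == ()

    def test_run_without_cnv_reported_unmapped(self):
        (run,) = map_runs_to_cnvs(self._runs(150_000, 170_000), [])
        assert run.mapped_ids == ()


class TestSexArtifactFilter:
    def _setup(self, male_offset, n=10, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        probes = make_probes(10)
        lrr = rng.normal(0, noise, (10, 2 * n))
        lrr[:, :n] += male_offset
        sig = make_signal(lrr, probes=probes)
        meta = [
            SampleMeta(s, "X", "BAI", "male" if j < n else "female")
            for j, s in enumerate(sig.samples)
        ]
        runs = scan_differentiated_runs(
            VstTrack(("A", "B"), np.full(10, 0.5)), probes
        )
        return runs, sig, meta

    def test_male_offset_is_flagged(self):
        runs, sig, meta = self._setup(0.3)
        (run,) = sex_artifact_filter(runs, sig, meta)
        assert run.sex_artifact is True

    def test_single_sex_cohort_is_untestable(self):
        runs, sig, meta = self._setup(0.3)
        meta = [SampleMeta(m.sample_id, m.breed, m.group, "male") for m in meta]
        (run,) = sex_artifact_filter(runs, sig, meta)
        assert run.sex_artifact is None

    def test_null_flag_rate_within_nominal_alpha(self):
        n_reps, alpha = 1000, 0.05
        flagged = 0
        for rep in range(n_reps):
            runs, sig, meta = self._setup(0.0, seed=12_345 + rep)
            (run,) = sex_artifact_filter(runs, sig, meta)
            flagged += run.sex_artifact is True
        # empirical rate must be consistent with size <= alpha; allow 3 SE of
        # binomial Monte-Carlo error so a correctly calibrated test is stable
        margin = 3 * np.sqrt(n_reps * alpha * (1 - alpha))
        assert flagged <= alpha * n_reps + margin


class TestRecoveryOnSyntheticCohort:
    def test_group_specific_deletion_detected_and_null_clean(self):
        # frequency 0.9 vs 0.0 for a 10-probe deletion: a >= 3-probe run
        # overlapping the truth span should appear in nearly every replicate;
        # with equal frequencies the scan should stay quiet
        from helpers_vst import recovery_replicates

        hits, false_alarms = recovery_replicates(n_reps=25, seed0=777)
        assert hits >= 24
        assert false_alarms <= 1
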