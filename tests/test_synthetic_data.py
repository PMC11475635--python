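"""Latent-mixing cohort generator: coupling, demographics, determinism."""

import numpy as np
import pytest

from phieeg.eeg_io import ElectrodePair
from phieeg.phi_core import DEFAULT_PAIRS, discretize, mutual_information
from phieeg.synthetic_data import (
    CohortSpec,
    CouplingProfile,
    default_cohort_spec,
    gaussian_mi_bits,
    generate_cohort,
    generate_pair_signals,
    write_cohort,
)


class TestGeneratePairSignals:
    def test_zero_coupling_gives_near_zero_correlation(self):
        n = 10000
        x, y = generate_pair_signals(0.0, n, seed=1)
        assert abs(np.corrcoef(x, y)[0, 1]) < 4 / np.sqrt(n)

    def test_sample_correlation_tracks_rho(self):
        x, y = generate_pair_signals(0.6, 30000, seed=2)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.6, abs=0.02)

    def test_high_coupling_mi_matches_gaussian_closed_form(self):
        """At rho = 0.99 / scale 50 µV the 10-µV bins are coarse relative to
        the conditional spread (~7 µV), so the plug-in estimate sits a little
        below the closed form; tolerance frozen from the pilot oracle run."""
        x, y = generate_pair_signals(0.99, 30000, amplitude_scale=50.0, seed=3)
        mi = mutual_information(discretize(x), discretize(y))
        assert mi == pytest.approx(gaussian_mi_bits(0.99), abs=0.25)

    def test_deterministic_given_seed(self):
        a = generate_pair_signals(0.5, 100, seed=9)
        b = generate_pair_signals(0.5, 100, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            generate_pair_signals(1.0, 100)
        with pytest.raises(ValueError):
            generate_pair_signals(-0.1, 100)
        with pytest.raises(ValueError):
            generate_pair_signals(0.5, 1)


class TestCohort:
    @pytest.fixture(scope="class")
    def tiny_spec(self):
        spec = default_cohort_spec(seed=5, n_per_group={"AD": 3, "FTD": 3, "HC": 3})
        spec.duration = 2.0  # keep the fixture fast; full epochs are exercised elsewhere
        return spec

    def test_bookkeeping(self, tiny_spec):
        recs = generate_cohort(tiny_spec)
        assert len(recs) == 9
        groups = [r.group for r in recs]
        assert groups.count("AD") == groups.count("FTD") == groups.count("HC") == 3

    def test_sample_count_and_montage(self, tiny_spec):
        rec = generate_cohort(tiny_spec)[0]
        assert rec.n_samples == 1000
        assert len(rec.channels) == 19

    def test_determinism_and_seed_splitting(self, tiny_spec):
        a = generate_cohort(tiny_spec)
        b = generate_cohort(tiny_spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)
            assert (ra.age, ra.sex, ra.group) == (rb.age, rb.sex, rb.group)
        # extending the cohort must not reshuffle existing subjects
        bigger = default_cohort_spec(seed=5, n_per_group={"AD": 4, "FTD": 3, "HC": 3})
        bigger.duration = 2.0
        c = generate_cohort(bigger)
        np.testing.assert_array_equal(a[0].data, c[0].data)

    def test_ages_within_truncation_window(self, tiny_spec):
        for rec in generate_cohort(tiny_spec):
            assert 40.0 <= rec.age <= 95.0
            assert rec.sex in ("male", "female")

    def test_default_spec_mirrors_target_cohort(self):
        spec = default_cohort_spec()
        assert spec.n_per_group == {"AD": 36, "FTD": 23, "HC": 29}
        assert spec.sampling_rate == 500.0 and spec.duration == 60.0

    def test_channel_overload_rejected(self):
        profile = CouplingProfile(
            group_label="HC",
            pair_coupling={ElectrodePair("Fp1", "Fp2"): 0.6, ElectrodePair("Fp2", "F4"): 0.5},
        )
        with pytest.raises(ValueError, match="below 1"):
            profile.validate(["Fp1", "Fp2", "F4"])

    def test_pair_outside_montage_rejected(self):
        profile = CouplingProfile(
            group_label="HC", pair_coupling={ElectrodePair("Fp1", "O9"): 0.3}
        )
        with pytest.raises(ValueError, match="montage"):
            profile.validate(["Fp1", "Fp2"])

    def test_write_cohort_roundtrip(self, tiny_spec, tmp_path):
        from phieeg.eeg_io import load_demographics
        from phieeg.pipeline import load_cohort

        recs = generate_cohort(tiny_spec)
        demo_path = write_cohort(recs, tmp_path)
        demo = load_demographics(demo_path)
        assert len(demo) == 9
        back = load_cohort(tmp_path)
        assert len(back) == 9
        np.testing.assert_allclose(back[0].data, recs[0].data, atol=5e-7)


class TestPlantedCoupling:
    def test_mean_phi_monotone_in_rho(self):
        """Group-mean binned MI is non-decreasing in the planted coupling."""
        means = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            vals = [
                mutual_information(
                    *(discretize(s) for s in generate_pair_signals(rho, 10000, seed=100 * k + int(10 * rho)))
                )
                for k in range(20)
            ]
            means.append(np.mean(vals))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_coupled_pair_recoverable_across_groups(self):
        """HC cohort with rho(Fp1-Fp2)=0.8 shows higher mean PHI on that pair
        than an AD cohort with rho=0.2."""
        from phieeg.phi_core import phi_matrix

        pair = ElectrodePair("Fp1", "Fp2")
        spec = CohortSpec(
            n_per_group={"AD": 20, "HC": 20},
            profiles={
                "AD": CouplingProfile("AD", {pair: 0.2}),
                "HC": CouplingProfile("HC", {pair: 0.8}),
            },
            montage=["Fp1", "Fp2"],
            duration=10.0,
            seed=17,
        )
        by_group = {"AD": [], "HC": []}
        for rec in generate_cohort(spec):
            by_group[rec.group].append(phi_matrix(rec, [pair])[0].phi)
        assert np.mean(by_group["HC"]) > np.mean(by_group["AD"])
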