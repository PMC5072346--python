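"""Filter cascade, beta computation and the logit2 transform pair."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdxmeth import manifest_io as mio
from pdxmeth.preprocess import (
    FilterReport,
    beta_to_m,
    compute_beta,
    detection_filter,
    exclude_probes,
    m_to_beta,
    mouse_mask,
)
from pdxmeth.synthetic import SimulationDesign, simulate_dataset


def _intensity_data(detp: pd.DataFrame) -> mio.IntensityData:
    ones = pd.DataFrame(1.0, index=detp.index, columns=detp.columns)
    return mio.IntensityData(ones, ones, detp)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected", [(0, 0, 0.0), (100, 0, 0.5), (300, 100, 0.6)]
    )
    def test_point_values(self, m, u, expected):
        assert compute_beta(m, u) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_formula_on_grid(self, rng):
        m = rng.uniform(0, 10_000, size=(40, 25))
        u = rng.uniform(0, 10_000, size=(40, 25))
        got = compute_beta(m, u, offset=100)
        expected = np.array(
            [[m[i, j] / (m[i, j] + u[i, j] + 100) for j in range(25)] for i in range(40)]
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_beta(-1.0, 5.0)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(1.0, 1.0, offset=-1)


class TestLogitPair:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_points(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)
        assert m_to_beta(m) == pytest.approx(beta, abs=1e-12)

    @given(st.floats(min_value=0.001, max_value=0.999))
    def test_round_trip_identity(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-9)

    def test_clamp_keeps_logit_finite(self):
        assert np.isfinite(beta_to_m(0.0))
        assert np.isfinite(beta_to_m(1.0))


class TestDetectionFilter:
    def test_one_failing_probe_removed(self):
        detp = pd.DataFrame(
            0.001, index=[f"cg{i}" for i in range(5)], columns=["s1", "s2"]
        )
        detp.loc["cg2", "s2"] = 0.5
        out, report = detection_filter(_intensity_data(detp))
        assert len(out.probe_ids) == 4
        assert "cg2" not in out.probe_ids
        assert report.stages == [("detection", 1)]

    def test_all_passing_is_identity(self):
        detp = pd.DataFrame(0.001, index=["a", "b"], columns=["s1"])
        out, report = detection_filter(_intensity_data(detp))
        assert len(out.probe_ids) == 2 and report.total_removed == 0

    def test_all_samples_scope_requires_universal_failure(self):
        detp = pd.DataFrame(
            [[0.5, 0.001], [0.5, 0.5]], index=["a", "b"], columns=["s1", "s2"]
        )
        out, _ = detection_filter(_intensity_data(detp), scope="all_samples")
        assert list(out.probe_ids) == ["a"]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_threshold_bounds(self, bad):
        detp = pd.DataFrame(0.001, index=["a"], columns=["s1"])
        with pytest.raises(ValueError):
            detection_filter(_intensity_data(detp), threshold=bad)

    def test_planted_noise_retention_binomial(self):
        # 12 human samples, per-entry failure rate 0.02 -> retain ~0.98^12
        design = SimulationDesign(
            n_probes=10_000,
            models=("A",),
            generations=("F0",),
            replicates=3,
            detection_noise=0.02,
            include_invitro=False,
            seed=21,
        )
        sim = simulate_dataset(design)
        n_human = len(sim.samples.human_samples)
        assert n_human == 12
        _, report = detection_filter(sim.intensities, sim.samples)
        p_keep = 0.98**n_human
        sd = np.sqrt(10_000 * p_keep * (1 - p_keep))
        assert abs(report.retained - 10_000 * p_keep) <= 3 * sd


class TestExcludeProbes:
    def test_sex_chromosome_removal(self, rng):
        n = 10
        df = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "chromosome": ["X", "Y"] + ["1"] * 8,
                "position": range(1, n + 1),
                "design_type": ["II"] * n,
                "compartment": ["Body"] * n,
                "cgi_relation": ["OpenSea"] * n,
                "hil_class": ["LC"] * n,
                "genes": [""] * n,
                "snp_flag": [False] * n,
                "crosshyb_flag": [False] * n,
            }
        )
        manifest = mio.ProbeManifest(df)
        detp = pd.DataFrame(0.001, index=manifest.probe_ids, columns=["s1"])
        out, report = exclude_probes(_intensity_data(detp), manifest)
        assert report.stages[0] == ("sex_chromosomes", 2)
        assert len(out.probe_ids) == 8

    def test_double_flagged_probe_counted_once_at_snp_stage(self, tiny_manifest_df):
        df = tiny_manifest_df.copy()
        df["chromosome"] = "1"  # keep the sex stage out of the way
        df.loc[1, "crosshyb_flag"] = True  # cg02 now SNP- and crosshyb-flagged
        manifest = mio.ProbeManifest(df)
        detp = pd.DataFrame(0.001, index=manifest.probe_ids, columns=["s1"])
        _, report = exclude_probes(_intensity_data(detp), manifest)
        assert ("snp", 1) in report.stages
        assert ("crosshyb", 1) in report.stages  # cg03 only

    def test_no_flags_is_identity(self, tiny_manifest_df):
        df = tiny_manifest_df.copy()
        df["chromosome"] = "1"
        df["snp_flag"] = False
        df["crosshyb_flag"] = False
        manifest = mio.ProbeManifest(df)
        detp = pd.DataFrame(0.001, index=manifest.probe_ids, columns=["s1"])
        out, report = exclude_probes(_intensity_data(detp), manifest)
        assert len(out.probe_ids) == 3 and report.total_removed == 0


class TestMouseMask:
    def _sheet(self):
        return mio.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["h1", "mt"],
                    "model": ["PDX36", "mouse"],
                    "generation": ["F0", "NA"],
                    "treatment": ["none", "none"],
                    "batch": ["B1", "B1"],
                    "species": ["human", "mouse"],
                }
            )
        )

    def test_detectable_in_mouse_removed_and_mouse_dropped(self):
        detp = pd.DataFrame(
            {"h1": [0.001] * 3, "mt": [0.001, 0.9, 0.9]}, index=["a", "b", "c"]
        )
        out, report = mouse_mask(_intensity_data(detp), self._sheet())
        assert list(out.probe_ids) == ["b", "c"]
        assert "mt" not in out.sample_ids
        assert report.stages == [("mouse_detected", 1)]

    def test_undetectable_mouse_is_identity_mask(self):
        detp = pd.DataFrame({"h1": [0.001] * 3, "mt": [0.9] * 3}, index=["a", "b", "c"])
        out, report = mouse_mask(_intensity_data(detp), self._sheet())
        assert report.total_removed == 0 and len(out.probe_ids) == 3

    def test_missing_mouse_sample_rejected(self):
        detp = pd.DataFrame({"h1": [0.001]}, index=["a"])
        with pytest.raises(ValueError, match="mouse"):
            mouse_mask(_intensity_data(detp), self._sheet())

    def test_masked_fraction_matches_planted(self, small_sim):
        _, report = mouse_mask(small_sim.intensities, small_sim.samples)
        frac = report.stages[0][1] / small_sim.design.n_probes
        p = small_sim.design.mouse_crossreactive_fraction
        sd = np.sqrt(p * (1 - p) / small_sim.design.n_probes)
        assert abs(frac - p) <= 3 * sd


class TestFilterReport:
    def test_conservation_enforced(self):
        report = FilterReport(10, [("x", 3)], retained=6)
        with pytest.raises(AssertionError, match="accounting"):
            report.validate()

    def test_merge_chains_and_conserves(self, small_sim):
        data, r1 = detection_filter(small_sim.intensities, small_sim.samples)
        data, r2 = mouse_mask(data, small_sim.samples)
        data, r3 = exclude_probes(data, small_sim.manifest)
        merged = r1.merge(r2).merge(r3)
        assert merged.input_probes == small_sim.design.n_probes
        assert merged.retained == len(data.probe_ids)
        merged.validate()

    def test_cascade_replay_reproduces_retained_set(self, small_sim):
        def run():
            d, _ = detection_filter(small_sim.intensities, small_sim.samples)
            d, _ = mouse_mask(d, small_sim.samples)
            d, _ = exclude_probes(d, small_sim.manifest)
            return d.probe_ids

        assert run().equals(run())
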