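"""Spike-in calibration, normalization formula, and global normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shrnakit import ncounter, synthetic
from shrnakit.errors import DegenerateFitError, ParseError, ShrnakitError

CONCS = (32.0, 8.0, 2.0, 0.5)


def ols_oracle(x, y):
    """Independent least-squares via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = (x**2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - ss_res / ss_tot


class TestFitSpikeinResponse:
    def test_exact_line(self):
        counts = [10 * c + 5 for c in CONCS]
        fit = ncounter.fit_spikein_response(counts, CONCS, "s1")
        assert fit.slope == pytest.approx(10.0, abs=1e-12)
        assert fit.B == pytest.approx(5.0, abs=1e-12)
        # fitted linear response signal at the POS_B concentration
        assert fit.pos_b_signal == pytest.approx(325.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_counts_degenerate(self):
        with pytest.raises(DegenerateFitError):
            ncounter.fit_spikein_response([50, 50, 50, 50], CONCS)

    def test_too_few_points_degenerate(self):
        with pytest.raises(DegenerateFitError):
            ncounter.fit_spikein_response([10, 5], (2.0, 1.0))

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            counts = 20 + 200 * np.asarray(CONCS) * rng.lognormal(0, 0.1, 4)
            fit = ncounter.fit_spikein_response(counts, CONCS)
            slope, intercept, r2 = ols_oracle(CONCS, counts)
            assert fit.slope == pytest.approx(slope, abs=1e-10 * abs(slope))
            assert fit.pos_b_signal == pytest.approx(
                intercept + slope * CONCS[0], rel=1e-10
            )
            assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_log_space_variant(self):
        # power-law counts: exact fit in log-log space
        counts = [4.0 * c for c in CONCS]
        fit = ncounter.fit_spikein_response(counts, CONCS, log_space=True)
        assert fit.log_space
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.B == pytest.approx(np.log2(4 * 32), abs=1e-12)


def _matrix(values, meta=None):
    df = pd.DataFrame(values)
    if meta is None:
        meta = pd.DataFrame(
            {
                "sample_id": df.columns,
                "condition": "c",
                "timepoint": [f"t{i}" for i in range(len(df.columns))],
                "pair_id": [f"t{i}" for i in range(len(df.columns))],
            }
        ).set_index("sample_id")
    return ncounter.CountMatrix(counts=df, meta=meta)


class TestNormalizeSpikein:
    @pytest.fixture
    def small(self):
        counts = {
            "s1": [325, 85, 25, 10, 5, 15, 105],
            "s2": [645, 165, 45, 15, 5, 25, 205],
        }
        idx = ["POS_B", "POS_C", "POS_D", "POS_E", "m1", "m2", "m3"]
        df = pd.DataFrame(counts, index=idx)
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "condition": ["a", "b"],
             "timepoint": ["t1", "t1"], "pair_id": ["t1", "t1"]}
        ).set_index("sample_id")
        return ncounter.CountMatrix(counts=df, meta=meta)

    def test_formula_substitutions(self, small):
        # s1 lies on counts = 5 + 10*conc, s2 on counts = 5 + 20*conc
        fits = ncounter.fit_all_samples(small, CONCS)
        nm = ncounter.normalize_spikein(small, fits)
        # R = B -> E = 0
        assert nm.values.loc["m1", "s1"] == pytest.approx(0.0, abs=1e-12)
        # R = B + slope -> E = 1
        assert nm.values.loc["m2", "s1"] == pytest.approx(1.0, abs=1e-12)
        assert nm.values.loc["m3", "s1"] == pytest.approx(10.0, abs=1e-12)
        assert nm.values.loc["m3", "s2"] == pytest.approx(10.0, abs=1e-12)
        # spike-in rows dropped
        assert nm.feature_ids == ["m1", "m2", "m3"]
        # log2 with pseudocount 1
        assert nm.log2_values.loc["m2", "s1"] == pytest.approx(1.0, abs=1e-12)

    def test_negative_values_clipped(self, small):
        fits = ncounter.fit_all_samples(small, CONCS)
        m2 = small.counts.copy()
        m2.loc["m1", "s1"] = 0  # below background
        mat = ncounter.CountMatrix(counts=m2, meta=small.meta)
        nm = ncounter.normalize_spikein(mat, fits)
        assert nm.values.loc["m1", "s1"] == 0.0

    def test_missing_fit_errors(self, small):
        fits = ncounter.fit_all_samples(small, CONCS)
        del fits["s2"]
        with pytest.raises(ShrnakitError, match="s2"):
            ncounter.normalize_spikein(small, fits)

    def test_zero_noise_recovers_planted_abundances(self, zero_noise_run):
        cfg, m = zero_noise_run
        fits = ncounter.fit_all_samples(m, cfg.spike_concs)
        nm = ncounter.normalize_spikein(m, fits)
        np.testing.assert_allclose(
            nm.values.to_numpy(), m.true_abundance.to_numpy(), atol=1e-9
        )

    def test_affine_map_preserves_rank_order(self, noisy_run):
        cfg, m = noisy_run
        fits = ncounter.fit_all_samples(m, cfg.spike_concs)
        nm = ncounter.normalize_spikein(m, fits)
        raw = m.counts.loc[m.mirna_ids]
        for s in m.sample_ids:
            clipped = nm.values[s] > 0
            r1 = raw.loc[clipped, s].rank(method="average")
            r2 = nm.values.loc[clipped, s].rank(method="average")
            assert (r1 == r2).all()

    def test_clipping_monotonicity(self, small):
        # increasing a raw count never decreases its normalized value
        fits = ncounter.fit_all_samples(small, CONCS)
        base = ncounter.normalize_spikein(small, fits).values.loc["m1", "s1"]
        bumped = small.counts.copy()
        bumped.loc["m1", "s1"] += 7
        nm2 = ncounter.normalize_spikein(
            ncounter.CountMatrix(counts=bumped, meta=small.meta), fits
        )
        assert nm2.values.loc["m1", "s1"] >= base


class TestGlobalNormalize:
    def test_hand_computed_scale_factors(self):
        nm = ncounter.NormalizedMatrix(
            values=pd.DataFrame({"s1": [5.0, 15.0], "s2": [10.0, 30.0]}, index=["a", "b"])
        )
        out = ncounter.global_normalize(nm)
        # sample means 10 and 20 -> grand mean 15 -> factors 1.5 and 0.75
        pd.testing.assert_frame_equal(
            out.values,
            pd.DataFrame({"s1": [7.5, 22.5], "s2": [7.5, 22.5]}, index=["a", "b"]),
        )

    def test_defining_property_and_idempotence(self, normalized):
        out = ncounter.global_normalize(normalized)
        grand = normalized.values.to_numpy().mean()
        np.testing.assert_allclose(out.values.mean(axis=0), grand, atol=1e-12 * grand)
        again = ncounter.global_normalize(out)
        pd.testing.assert_frame_equal(again.values, out.values)

    def test_preserves_within_sample_ratios(self, normalized):
        out = ncounter.global_normalize(normalized)
        v0, v1 = normalized.values, out.values
        for s in v0.columns:
            nz = v0[s] > 0
            np.testing.assert_allclose(
                (v1[s][nz] / v0[s][nz]).to_numpy(),
                (v1[s][nz] / v0[s][nz]).iloc[0],
            )

    def test_all_zero_sample_rejected(self):
        nm = ncounter.NormalizedMatrix(
            values=pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 2.0]})
        )
        with pytest.raises(ShrnakitError, match="s1"):
            ncounter.global_normalize(nm)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pipeline_closure_up_to_global_scalar(self, seed):
        # zero-noise run with integer abundances: fit -> normalize ->
        # global normalize equals the planted abundances times one scalar
        rng = np.random.default_rng(seed)
        abundances = tuple(float(a) for a in rng.integers(1, 300, size=12))
        cfg = synthetic.SimConfig(
            n_mirnas=12, noise_cv=0.0, abundances=abundances, seed=1
        )
        m = synthetic.simulate_ncounter(cfg)
        nm = ncounter.global_normalize(
            ncounter.normalize_spikein(
                m, ncounter.fit_all_samples(m, cfg.spike_concs)
            )
        )
        est = nm.values.to_numpy()
        truth = m.true_abundance.to_numpy()
        scalar = est.sum() / truth.sum()
        np.testing.assert_allclose(est, truth * scalar, rtol=1e-9)


class TestIO:
    def test_csv_round_trip(self, tmp_path, noisy_run):
        _, m = noisy_run
        ncounter.write_counts(m, tmp_path / "c.csv", tmp_path / "m.csv")
        back = ncounter.read_counts(tmp_path / "c.csv", tmp_path / "m.csv")
        pd.testing.assert_frame_equal(back.counts, m.counts, check_names=False)
        pd.testing.assert_frame_equal(back.meta, m.meta, check_names=False)

    def test_rcc_round_trip(self, tmp_path, noisy_run):
        _, m = noisy_run
        ncounter.write_rcc(m, tmp_path / "rcc")
        m.meta.to_csv(tmp_path / "meta.csv", index_label="sample_id")
        back = ncounter.read_counts(tmp_path / "rcc", tmp_path / "meta.csv", fmt="rcc")
        pd.testing.assert_frame_equal(
            back.counts.sort_index(axis=1), m.counts.sort_index(axis=1)
        )

    def test_negative_count_names_cell(self):
        df = pd.DataFrame({"s1": [1, -2]}, index=["a", "b"])
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "condition": ["c"], "timepoint": ["t"]}
        ).set_index("sample_id")
        with pytest.raises(ParseError, match="'b'.*'s1'"):
            ncounter.CountMatrix(counts=df, meta=meta)

    def test_duplicate_feature_ids_rejected(self):
        df = pd.DataFrame({"s1": [1, 2]}, index=["a", "a"])
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "condition": ["c"], "timepoint": ["t"]}
        ).set_index("sample_id")
        with pytest.raises(ParseError, match="duplicate"):
            ncounter.CountMatrix(counts=df, meta=meta)

    def test_missing_metadata_rejected(self, noisy_run):
        _, m = noisy_run
        with pytest.raises(ParseError, match="missing"):
            ncounter.CountMatrix(counts=m.counts, meta=m.meta.iloc[:3])

    def test_well_formed_csv(self, tmp_path):
        lines = ["feature_id,s1,s2"] + [f"f{i},{i},{i * 2}" for i in range(10)]
        (tmp_path / "c.csv").write_text("\n".join(lines))
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "condition": ["a", "b"],
             "timepoint": ["t", "t"], "pair_id": ["t", "t"]}
        )
        meta.to_csv(tmp_path / "m.csv", index=False)
        m = ncounter.read_counts(tmp_path / "c.csv", tmp_path / "m.csv")
        assert len(m.feature_ids) == 10
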