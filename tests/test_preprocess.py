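"""Layout/spot-file IO, net intensity, replicate aggregation, normalization."""
import numpy as np
import pandas as pd
import pytest

from seromic import (
    EffectSpec,
    aggregate_replicates,
    make_panel,
    net_intensity,
    normalize,
    read_gal,
    read_spot_tables,
    simulate_spot_table,
    write_gal,
    write_gpr_set,
)
from seromic.gpr_io import FormatError, ReconciliationError
from seromic.preprocess import RFUMatrix

from conftest import spot_rows


class TestGalIO:
    def test_round_trip_identity(self, small_panel, tmp_path):
        write_gal(small_panel, tmp_path / "x.gal")
        assert read_gal(tmp_path / "x.gal") == small_panel

    def test_replicate_count_inferred(self, tmp_path):
        panel = make_panel(1, 0, 3, seed=0)
        write_gal(panel, tmp_path / "one.gal")
        back = read_gal(tmp_path / "one.gal")
        assert back.n_replicates == 3 and back.n_antigens == 1

    def test_clashing_coordinates_rejected(self, tmp_path):
        lines = ["ATF\t1.0", "1\t5", '"Type=ArrayList V1.0"',
                 "Block\tRow\tColumn\tID\tName",
                 "1\t1\t1\tCT001\tCT", "1\t1\t1\tCT002\tCT"]
        p = tmp_path / "bad.gal"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="clashing"):
            read_gal(p)


class TestReadSpotTables:
    def test_gpr_set_round_trip(self, small_panel, small_cohort, small_spots, tmp_path):
        paths = write_gpr_set(small_spots, tmp_path)
        back = read_spot_tables(paths, small_panel, small_cohort)
        assert len(back) == len(small_spots)
        merged = back.sort_values(["sample_id", "channel", "antigen_id",
                                   "replicate_index"]).reset_index(drop=True)
        orig = small_spots.sort_values(["sample_id", "channel", "antigen_id",
                                        "replicate_index"]).reset_index(drop=True)
        np.testing.assert_allclose(merged["foreground_median"],
                                   orig["foreground_median"], rtol=1e-5)

    def test_unknown_sample_named_in_error(self, small_panel, small_cohort,
                                           small_spots, tmp_path):
        rogue = small_spots.copy()
        rogue.loc[rogue.index[:3], "sample_id"] = "GHOST_01"
        rogue.to_csv(tmp_path / "rogue.csv", index=False)
        with pytest.raises(ReconciliationError, match="GHOST_01"):
            read_spot_tables(tmp_path / "rogue.csv", small_panel, small_cohort)

    def test_unknown_antigen_rejected(self, small_panel, small_cohort,
                                      small_spots, tmp_path):
        rogue = small_spots.copy()
        rogue.loc[rogue.index[:1], "antigen_id"] = "ZZ999"
        rogue.to_csv(tmp_path / "rogue.csv", index=False)
        with pytest.raises(ReconciliationError, match="ZZ999"):
            read_spot_tables(tmp_path / "rogue.csv", small_panel, small_cohort)

    def test_missing_replicates_flagged_in_qc(self, small_panel, small_cohort,
                                              small_spots, tmp_path):
        drop = small_spots.index[
            (small_spots["sample_id"] == "PDAC_001")
            & (small_spots["channel"] == "IgG")
            & (small_spots["antigen_id"] == "CT003")
            & (small_spots["replicate_index"] == 0)
        ]
        trimmed = small_spots.drop(index=drop)
        trimmed.to_csv(tmp_path / "trim.csv", index=False)
        back = read_spot_tables(tmp_path / "trim.csv", small_panel, small_cohort)
        _, qc = aggregate_replicates(back, small_panel)
        flags = qc.replicate_flags
        hit = flags[(flags["reason"] == "missing_replicates")]
        assert len(hit) == 1
        assert hit.iloc[0]["antigen_id"] == "CT003"


class TestNetIntensity:
    @pytest.mark.parametrize("fg,bg,expected", [(1000, 200, 800), (150, 150, 0),
                                                (100, 250, -150)])
    def test_arithmetic(self, fg, bg, expected):
        assert net_intensity(fg, bg) == expected

    def test_negative_net_recorded_not_clipped(self, small_panel):
        spots = spot_rows([-150, -150, -150], antigen="CT001")
        spots = spots.assign(foreground_median=100.0, local_background=250.0)
        matrices, qc = aggregate_replicates(spots, make_panel(1, 0, 3, seed=0))
        assert (qc.spot_flags["reason"] == "negative_net").sum() == 3
        assert matrices["IgG"].values.iloc[0, 0] == pytest.approx(-150.0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            net_intensity(np.nan, 1.0)
        with pytest.raises(ValueError):
            net_intensity(1.0, np.inf)


class TestAggregateReplicates:
    def test_mean_and_cv(self):
        panel = make_panel(1, 0, 3, seed=0)
        matrices, _ = aggregate_replicates(spot_rows([800, 820, 780]), panel)
        m = matrices["IgG"]
        assert m.values.iloc[0, 0] == pytest.approx(800.0)
        assert m.cv.iloc[0, 0] == pytest.approx(np.std([800, 820, 780], ddof=1) / 800.0)

    def test_identical_replicates_zero_cv(self):
        panel = make_panel(1, 0, 3, seed=0)
        matrices, _ = aggregate_replicates(spot_rows([500, 500, 500]), panel)
        assert matrices["IgG"].cv.iloc[0, 0] == 0.0

    def test_nonpositive_mean_cv_undefined(self):
        panel = make_panel(1, 0, 3, seed=0)
        matrices, _ = aggregate_replicates(spot_rows([-10, -10, -10]), panel)
        m = matrices["IgG"]
        assert m.values.iloc[0, 0] == pytest.approx(-10.0)
        assert np.isnan(m.cv.iloc[0, 0])

    def test_replicate_order_invariance(self):
        panel = make_panel(1, 0, 3, seed=0)
        a, _ = aggregate_replicates(spot_rows([700, 810, 920]), panel)
        shuffled = spot_rows([920, 700, 810])
        b, _ = aggregate_replicates(shuffled, panel)
        assert a["IgG"].values.iloc[0, 0] == pytest.approx(b["IgG"].values.iloc[0, 0])
        assert a["IgG"].cv.iloc[0, 0] == pytest.approx(b["IgG"].cv.iloc[0, 0])

    def test_saturated_spots_excluded(self):
        panel = make_panel(1, 0, 3, seed=0)
        spots = spot_rows([500, 510, 100000])
        matrices, qc = aggregate_replicates(spots, panel)
        assert matrices["IgG"].values.iloc[0, 0] == pytest.approx(505.0)
        assert (qc.spot_flags["reason"] == "saturated").sum() == 1

    def test_simulated_round_trip_recovers_expected_means(self):
        """simulate -> aggregate reproduces the generator's expected
        per-antigen level within replicate-noise tolerance."""
        from seromic import CohortDesign, make_cohort

        panel = make_panel(10, 0, 3, seed=1)
        design = CohortDesign(groups=[("A", 40, "serum")], channels=["IgA"], seed=1)
        cohort = make_cohort(design)
        eff = EffectSpec(antigen_log_sd=0.0)
        spots = simulate_spot_table(panel, cohort, eff, seed=1)
        matrices, _ = aggregate_replicates(spots, panel)
        expected = np.exp(eff.baseline_log_mean
                          + (eff.baseline_log_sd**2 + eff.replicate_log_sd**2) / 2)
        observed = matrices["IgA"].values.to_numpy().mean()
        assert observed == pytest.approx(expected, rel=0.02)


class TestNormalize:
    def _matrix(self, values):
        v = pd.DataFrame(values, index=[f"S{i}" for i in range(len(values))],
                         columns=[f"A{j}" for j in range(len(values[0]))], dtype=float)
        return RFUMatrix(values=v, cv=v * 0.0, channel="IgG")

    def test_identical_samples_are_fixed_point(self):
        m = self._matrix([[10, 20, 30]] * 4)
        for method in ("median_scale", "quantile", "none"):
            out = normalize(m, method)
            np.testing.assert_allclose(out.values, m.values)

    def test_median_scale_restores_scaled_sample(self):
        base = [10.0, 20.0, 30.0, 40.0, 50.0]
        m = self._matrix([base, base, [2 * x for x in base]])
        out = normalize(m, "median_scale")
        medians = out.values.median(axis=1)
        assert medians.nunique() == 1

    def test_none_is_passthrough(self, small_rfu):
        m = small_rfu["IgG"]
        out = normalize(m, "none")
        assert out.values.equals(m.values)

    def test_median_scale_preserves_within_sample_ranks(self, small_rfu):
        m = small_rfu["IgG"]
        out = normalize(m, "median_scale")
        for s in m.values.index[:5]:
            a = m.values.loc[s].rank()
            b = out.values.loc[s].rank()
            assert (a == b).all()

    def test_quantile_equalizes_sample_distributions(self):
        rng = np.random.default_rng(0)
        m = self._matrix(rng.lognormal(6, 1, size=(5, 50)).tolist())
        out = normalize(m, "quantile")
        sorted_rows = np.sort(out.values.to_numpy(), axis=1)
        np.testing.assert_allclose(sorted_rows, np.tile(sorted_rows[0], (len(sorted_rows), 1)))

    def test_unknown_method_rejected(self, small_rfu):
        with pytest.raises(ValueError):
            normalize(small_rfu["IgG"], "loess")
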