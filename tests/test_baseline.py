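"""Direct rejection-sampling baseline and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest

import smorepars as sp
from smorepars.baseline import abm_rss_table, direct_calibrate, rss_split, zscores
from smorepars.data import Arm, TimeSeriesDataset


@pytest.fixture(scope="module")
def toy_world():
    """Five ABM vectors simulated against one small synthetic data arm."""
    times = [0.0, 10.0, 24.0]
    outputs = {}
    for i, ka in enumerate((200, 400, 900, 1600, 2500)):
        control = sp.ABMControlParams(K_A=ka, s=0.5)
        outputs[f"v{i}"] = [sp.simulate(control, t_grid=times, n_reps=3, rng_seed=i)]
    ref = outputs["v2"][0]
    mean = ref.total.mean(axis=0)[1:]
    data = TimeSeriesDataset(
        arms=(
            Arm(dose=0.0, observable="total_count", times=times[1:], mean=mean,
                sd=0.1 * mean, n_replicates=3),
        ),
        provenance="synthetic",
    )
    return outputs, data


class TestDirect:
    def test_rss_table_and_exact_topk(self, toy_world):
        outputs, data = toy_world
        tab = abm_rss_table(outputs, data)
        assert len(tab) == 5
        # hand-rank: lowest RSS vectors are the exact accepted set for k=2
        expected_top2 = set(tab.sort_values(["rss", "vector_id"])["vector_id"].head(2))
        res = direct_calibrate(tab, k=2)
        assert res.accepted_ids == expected_top2
        assert res.table["accepted"].sum() == 2

    def test_k_edge_cases(self, toy_world):
        outputs, data = toy_world
        tab = abm_rss_table(outputs, data)
        assert direct_calibrate(tab, k=0).accepted_ids == set()
        assert direct_calibrate(tab, k=5).accepted_ids == set(tab["vector_id"])
        with pytest.raises(ValueError):
            direct_calibrate(tab, k=-1)
        with pytest.raises(ValueError):
            direct_calibrate(tab, k=6)

    def test_tie_break_by_vector_id(self):
        tab = pd.DataFrame({"vector_id": ["b", "a", "c"], "rss": [1.0, 1.0, 2.0]})
        res = direct_calibrate(tab, k=1)
        assert res.accepted_ids == {"a"}
        assert res.had_ties

    def test_per_arm_sums_equal_total(self, toy_world):
        outputs, data = toy_world
        tab = abm_rss_table(outputs, data)
        arm_cols = [c for c in tab.columns if c.startswith("rss|")]
        assert np.allclose(tab[arm_cols].sum(axis=1), tab["rss"])


class TestZScores:
    def test_arithmetic(self, toy_world):
        outputs, data = toy_world
        arm = data.arms[0]
        df = zscores({"v2": outputs["v2"]}, data)
        mean_rows = df[df["replicate"] == "mean"].set_index("time_h")
        # recompute directly from the output
        sim_mean = outputs["v2"][0].total.mean(axis=0)[1:]
        for t, sm_val, dm, sd in zip(arm.times, sim_mean, arm.mean, arm.sd):
            assert mean_rows.loc[t, "z"] == pytest.approx((sm_val - dm) / sd)

    def test_sim_equal_mean_gives_zero_and_offsets_scale(self):
        times = [10.0]
        out = sp.simulate(sp.ABMControlParams(K_A=100), t_grid=times, n_reps=2, rng_seed=0)
        mean_val = out.total.mean(axis=0)
        data = TimeSeriesDataset(
            arms=(Arm(dose=0.0, observable="total_count", times=times,
                      mean=mean_val, sd=np.array([10.0])),),
        provenance="synthetic")
        df = zscores({"v": [out]}, data)
        assert df.loc[df["replicate"] == "mean", "z"].iloc[0] == pytest.approx(0.0)

    def test_rescaling_invariance(self, toy_world):
        """z-scores do not change when counts, means and SDs share a scale."""
        outputs, data = toy_world
        df1 = zscores({"v2": outputs["v2"]}, data)
        scaled_arm = data.arms[0]
        factor = 4  # integral so scaled counts stay exact integers
        out = outputs["v2"][0]
        scaled_out = sp.abm.ABMOutput(
            times=out.times, counts=out.counts * factor,
            dose=out.dose, n0=out.n0, seed=out.seed,
        )
        scaled_data = TimeSeriesDataset(
            arms=(Arm(dose=0.0, observable="total_count", times=scaled_arm.times,
                      mean=scaled_arm.mean * factor, sd=scaled_arm.sd * factor,
                      n_replicates=3),),
            provenance="synthetic",
        )
        df2 = zscores({"v2": [scaled_out]}, scaled_data)
        assert np.allclose(df1["z"].to_numpy(), df2["z"].to_numpy())

    def test_zero_sd_scored_missing(self, toy_world):
        outputs, _ = toy_world
        times = [10.0]
        data = TimeSeriesDataset(
            arms=(Arm(dose=0.0, observable="total_count", times=times,
                      mean=np.array([100.0]), sd=np.array([0.0])),),
            provenance="synthetic")
        df = zscores({"v0": [outputs["v0"][0]]}, data)
        assert df["missing_sd"].all()
        assert df["z"].isna().all()


class TestRSSSplit:
    def test_identical_vectors_identical_distributions(self):
        tab = pd.DataFrame({
            "vector_id": ["a", "b", "c", "d"],
            "rss": [2.0, 2.0, 2.0, 2.0],
            "rss|0|total_count": [2.0, 2.0, 2.0, 2.0],
        })
        df = rss_split(tab, accepted={"a", "b"})
        med = df[df["component"] == "rss"].set_index("group")["median"]
        assert med["accepted"] == med["rejected"] == 2.0

    def test_summary_groups_and_quantiles(self, toy_world):
        outputs, data = toy_world
        tab = abm_rss_table(outputs, data)
        df = rss_split(tab, accepted={"v2", "v3"})
        groups = set(df["group"])
        assert groups == {"accepted", "rejected"}
        acc = df[(df["group"] == "accepted") & (df["component"] == "rss")].iloc[0]
        assert acc["q25"] <= acc["median"] <= acc["q75"] <= acc["p95"]
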