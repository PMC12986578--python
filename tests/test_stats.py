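"""Statistics battery: identities, Holm properties, MANOVA gates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from emgtf import stats as estats
from emgtf.pipeline import RunConfig, trajectory_features
from emgtf.preprocess import bandpass_notch, detect_bursts
from emgtf.synth import SessionSpec, default_profiles, generate_session, profile_phase_centroid


def _table(groups, values, metric="f_median", source="stft80", phase="sustained"):
    rows = []
    for g, vals in zip(groups, values):
        for i, v in enumerate(vals):
            rows.append({"subject": f"{g}_s0", "group": g, "burst_id": i,
                         "phase": phase, "source": source, "metric": metric,
                         "value": v})
    return pd.DataFrame(rows)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1, 25)
    table = _table(["g1", "g2"], [a, b])
    res = estats.anova_tukey(table, "f_median", "stft80", "sustained")
    t_stat, t_p = sstats.ttest_ind(a, b)
    assert res.statistic == pytest.approx(t_stat**2, abs=1e-9)
    assert res.p_value == pytest.approx(t_p, abs=1e-12)


def test_tukey_kramer_equal_n_matches_statsmodels():
    rng = np.random.default_rng(1)
    vals = [rng.normal(m, 1, 20) for m in (0.0, 0.5, 1.0)]
    table = _table(["a", "b", "c"], vals)
    res = estats.anova_tukey(table, "f_median", "stft80", "sustained")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sm = pairwise_tukeyhsd(np.concatenate(vals), np.repeat(["a", "b", "c"], 20))
    np.testing.assert_allclose(res.pairwise["p"].to_numpy(),
                               sm.pvalues, atol=1e-6)


def test_holm_spec_examples():
    assert estats.holm_adjust([0.04]) == pytest.approx([0.04])
    np.testing.assert_allclose(estats.holm_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.04, 0.04])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_holm_dominance_and_range(pvals):
    p = np.asarray(pvals)
    adj = estats.holm_adjust(p)
    bon = estats.bonferroni_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= bon + 1e-15)
    assert np.all((adj >= 0) & (adj <= 1))


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=10),
       st.randoms(use_true_random=False))
def test_holm_permutation_equivariance(pvals, rnd):
    p = np.asarray(pvals)
    perm = np.arange(p.size)
    rnd.shuffle(perm)
    adj = estats.holm_adjust(p)
    adj_perm = estats.holm_adjust(p[perm])
    np.testing.assert_allclose(adj_perm, adj[perm])


def test_adjust_rejects_invalid_pvalues():
    for bad in ([1.5], [-0.1], [np.nan]):
        with pytest.raises(ValueError):
            estats.holm_adjust(bad)
        with pytest.raises(ValueError):
            estats.bonferroni_adjust(bad)


def _imf_table(rng, shift=0.0, n=30):
    rows = []
    for g, mu in (("control", 0.0), ("week6", shift)):
        for i in range(n):
            for metric, base in (("inst_freq_mean", 100.0), ("inst_energy_mean", 1.0)):
                rows.append({"subject": f"{g}_s0", "group": g, "burst_id": i,
                             "phase": "sustained", "source": "imf2",
                             "metric": metric,
                             "value": base + mu + rng.normal(0, 1)})
    return pd.DataFrame(rows)


def test_manova_null_and_alternative():
    rng = np.random.default_rng(2)
    null = estats.manova_pairs(_imf_table(rng, shift=0.0), "imf2", "sustained")
    alt = estats.manova_pairs(_imf_table(rng, shift=2.0), "imf2", "sustained")
    assert alt.p_value < 1e-4
    assert null.p_value > 0.01
    # Pillai option agrees on the verdicts
    alt_p = estats.manova_pairs(_imf_table(rng, shift=2.0), "imf2", "sustained",
                                statistic="pillai")
    assert alt_p.p_value < 1e-4
    assert "pillai_trace" in alt_p.extras
    with pytest.raises(ValueError):
        estats.manova_pairs(_imf_table(rng), "imf2", "sustained", statistic="roy")


def test_manova_identical_groups_p_one():
    rng = np.random.default_rng(3)
    t = _imf_table(rng, shift=0.0, n=15)
    # make week6 an exact copy of control
    ctrl = t[t.group == "control"].copy()
    copy = ctrl.copy()
    copy["group"] = "week6"
    copy["subject"] = "week6_s0"
    res = estats.manova_pairs(pd.concat([ctrl, copy], ignore_index=True),
                              "imf2", "sustained")
    assert res.p_value == 1.0


def test_manova_singular_covariance_names_metric():
    rng = np.random.default_rng(4)
    t = _imf_table(rng)
    t.loc[t.metric == "inst_energy_mean", "value"] = 5.0  # zero variance
    with pytest.raises(ValueError, match="inst_energy_mean"):
        estats.manova_pairs(t, "imf2", "sustained")


def test_battery_structure_and_gating():
    rng = np.random.default_rng(5)
    vals = [rng.normal(m, 1, 25) for m in (300.0, 280.0, 260.0, 250.0, 200.0)]
    groups = ["control", "week3", "week4", "week5", "week6"]
    traj = pd.concat(
        [_table(groups, vals, metric=m, source="stft80", phase=p)
         for m in ("f_mean", "f_median") for p in ("recruitment", "sustained")],
        ignore_index=True,
    )
    # null IMF source: gate should mostly fail and emit no post hoc rows
    imf = pd.concat([_imf_table(rng, shift=0.0)], ignore_index=True)
    summary, pairwise = estats.run_stat_battery(pd.concat([traj, imf], ignore_index=True))
    stft = summary[(summary.source == "stft80") & (summary.test == "anova")]
    assert len(stft) == 4  # 2 metrics x 2 phases present
    # 5 groups -> 10 pairwise contrasts per significant (source, metric, phase)
    for (_, m, p), sub in pairwise[pairwise.source == "stft80"].groupby(
        ["source", "metric", "phase"]
    ):
        assert len(sub) == 10
    gates = summary[(summary.source == "imf2") & (summary.test == "manova")]
    for r in gates.itertuples():
        if not r.gate:
            posthoc = pairwise[(pairwise.source == "imf2") & (pairwise.phase == r.phase)]
            assert posthoc.empty
    # adjusted p never below raw within the Holm family
    fam = summary[(summary.source == "imf2") & (summary.test == "anova")]
    assert np.all(fam.p_adj.to_numpy() >= fam.p_raw.to_numpy() - 1e-15)


def test_battery_missing_source_skipped_and_unit_subject():
    rng = np.random.default_rng(6)
    vals = [rng.normal(m, 1, 20) for m in (300.0, 200.0)]
    traj = pd.concat(
        [_table(["control", "week6"], vals, metric=m)
         for m in ("f_mean", "f_median")],
        ignore_index=True,
    )
    summary, _ = estats.run_stat_battery(traj, sources=["stft80", "imf9"])
    assert set(summary.source) == {"stft80"}
    with pytest.raises(ValueError):
        estats.run_stat_battery(traj, correction="fdr")
    # subject-level aggregation needs >= 2 subjects per group
    traj2 = traj.copy()
    traj2.loc[traj2.burst_id >= 10, "subject"] = traj2.loc[
        traj2.burst_id >= 10, "group"
    ] + "_s1"
    summary_s, _ = estats.run_stat_battery(traj2, unit="subject")
    assert (summary_s.test == "anova").all()


def test_no_sign_flipped_discoveries_across_seeds():
    """Every significant F_median pairwise difference matches the generator's
    centroid ordering, across 10 seeds (small sessions)."""
    target = {
        p.name: profile_phase_centroid(p, 250.0, 0.0, 250.0) for p in default_profiles()
    }
    for seed in range(10):
        spec = SessionSpec(subjects_per_group=1, bursts_per_subject=8,
                           session_length_s=8.0, seed=1000 + seed)
        recordings, _ = generate_session(spec)
        segments = []
        for rec in recordings:
            segments.extend(detect_bursts(bandpass_notch(rec)))
        table, _ = trajectory_features(segments, RunConfig(stft_configs=(
            {"name": "stft80", "window_ms": 80.0, "overlap_ms": 75.0, "nfft": 160},
        )))
        table = table[table.source == "stft80"]
        summary, pairwise = estats.run_stat_battery(table, sources=["stft80"])
        sel = pairwise[pairwise.metric == "f_median"]
        for r in sel.itertuples():
            if r.p < 0.05:
                expected = np.sign(target[r.group1] - target[r.group2])
                assert np.sign(r.mean_diff) == expected, (
                    f"seed {seed}: {r.group1} vs {r.group2} flipped"
                )
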