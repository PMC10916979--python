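"""Mixed ANCOVA, Tukey post-hocs, and effect sizes.

The reference values in ``test_matches_mixed_model_reference`` were computed
with an independent linear-mixed-model implementation (random subject
intercept, Type III tests, sum-to-zero contrasts, grand-mean-centered
continuous covariates) on the same deterministic fixture; they are frozen
here and the implementation must reproduce them to 1e-6.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluprop.group_stats import (
    cohen_d,
    mixed_ancova,
    partial_eta_squared,
    tukey_posthoc,
)


def ancova_fixture(seed=12345, n=24):
    """Deterministic 2x2 mixed-design fixture with covariates."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["AD", "HC"], n // 2)
    sex = rng.choice(["F", "M"], n)
    age = rng.normal(70, 6, n).round(1)
    edu = rng.normal(12, 4, n).clip(2).round(1)
    sev = (groups == "AD") * 1.0
    y_ph = 10 - 2 * sev + 0.05 * (age - 70) + rng.normal(0, 2, n)
    y_se = 12 - 3 * sev + 0.05 * (age - 70) + rng.normal(0, 2, n)
    rows = []
    for i in range(n):
        for task, y in (("phonemic", y_ph[i]), ("semantic", y_se[i])):
            rows.append(
                dict(
                    participant_id=f"P{i:02d}",
                    group=groups[i],
                    sex=sex[i],
                    age=age[i],
                    education=edu[i],
                    task=task,
                    value=round(y, 6),
                )
            )
    return pd.DataFrame(rows)


def simulated_long(rng, n_per_group=30, shift=0.0):
    """Two groups, two tasks, independent subjects; optional group shift."""
    n = 2 * n_per_group
    groups = np.repeat(["A", "B"], n_per_group)
    subj = rng.normal(0, 1, n)  # between-subject variation
    rows = []
    for i in range(n):
        base = subj[i] + (shift if groups[i] == "A" else 0.0)
        for task in ("phonemic", "semantic"):
            rows.append(
                dict(
                    participant_id=f"S{i}",
                    group=groups[i],
                    sex="F" if rng.random() < 0.5 else "M",
                    age=rng.normal(70, 5),
                    education=rng.normal(12, 3),
                    task=task,
                    value=base + rng.normal(0, 1),
                )
            )
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_matches_mixed_model_reference(self):
        res = {r.term: r for r in mixed_ancova(ancova_fixture())}
        assert res["group"].F == pytest.approx(16.402509, abs=1e-6)
        assert res["group"].p == pytest.approx(0.0006835, abs=1e-6)
        assert res["group"].df == (1, 19)
        assert res["task"].F == pytest.approx(19.849261, abs=1e-6)
        assert res["task"].p == pytest.approx(0.0001984, abs=1e-6)
        assert res["group:task"].F == pytest.approx(1.292423, abs=1e-6)
        assert res["group:task"].p == pytest.approx(0.2678337, abs=1e-6)
        assert res["group:task"].df == (1, 22)
        # within-stratum error mean square equals the mixed model's
        # residual variance
        assert res["group:task"].mse == pytest.approx(2.573196, abs=1e-5)

    def test_between_term_matches_ancova_oracle(self):
        """Group F must equal a one-way ANCOVA on subject task-means."""
        pingouin = pytest.importorskip("pingouin")
        df = ancova_fixture()
        wide = df.pivot_table(index="participant_id", columns="task", values="value")
        subj = df.drop_duplicates("participant_id").set_index("participant_id")
        subj["m"] = wide.mean(axis=1)
        subj["sex_num"] = np.where(subj["sex"] == "F", 1.0, -1.0)
        aov = pingouin.ancova(
            data=subj, dv="m", between="group", covar=["sex_num", "age", "education"]
        )
        f_oracle = float(aov.loc[aov["Source"] == "group", "F"].iloc[0])
        res = {r.term: r for r in mixed_ancova(df)}
        assert res["group"].F == pytest.approx(f_oracle, rel=1e-6)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        reps = 800
        rej = 0
        for _ in range(reps):
            df = simulated_long(rng, n_per_group=15)
            res = {r.term: r for r in mixed_ancova(df)}
            rej += res["group"].p < 0.05
        rate = rej / reps
        assert 0.027 <= rate <= 0.073  # 0.05 +- 3 binomial SE

    def test_power_for_large_planted_shift(self):
        rng = np.random.default_rng(7)
        reps = 150
        rej = 0
        for _ in range(reps):
            # 1.5 x pooled between-subject SD shift, n=30/group
            df = simulated_long(rng, n_per_group=30, shift=1.5 * np.sqrt(1.5))
            res = {r.term: r for r in mixed_ancova(df)}
            rej += res["group"].p < 0.05
        assert rej / reps > 0.9

    def test_label_permutation_destroys_planted_effect(self):
        rng = np.random.default_rng(99)
        df = simulated_long(rng, n_per_group=25, shift=2.0)
        f_obs = {r.term: r for r in mixed_ancova(df)}["group"].F
        perms = []
        subj = df.drop_duplicates("participant_id")
        for _ in range(60):
            relabel = dict(
                zip(subj["participant_id"], rng.permutation(subj["group"].to_numpy()))
            )
            d2 = df.assign(group=df["participant_id"].map(relabel))
            perms.append({r.term: r for r in mixed_ancova(d2)}["group"].F)
        # permuted F behaves like a null F (mean ~ df2/(df2-2) ~ 1.04)
        assert np.mean(perms) < 2.0
        assert f_obs > np.percentile(perms, 95)

    def test_eta_invariant_under_affine_rescaling(self):
        df = ancova_fixture()
        base = {r.term: r.eta_p_sq for r in mixed_ancova(df)}
        df2 = df.assign(value=5.0 * df["value"] - 11.0)
        scaled = {r.term: r.eta_p_sq for r in mixed_ancova(df2)}
        for term in base:
            assert scaled[term] == pytest.approx(base[term], abs=1e-10)

    def test_listwise_deletion_of_incomplete_subjects(self):
        df = ancova_fixture()
        # drop one subject's semantic observation and blank another's age
        df = df[~((df.participant_id == "P00") & (df.task == "semantic"))]
        df.loc[df.participant_id == "P01", "age"] = np.nan
        res = mixed_ancova(df)
        assert res[0].df[1] == 24 - 2 - 5  # two subjects removed listwise

    def test_errors_on_degenerate_input(self):
        df = ancova_fixture()
        with pytest.raises(ValueError, match="fewer than 3"):
            mixed_ancova(df[df.participant_id.isin(["P00", "P01", "P12", "P13"])])
        with pytest.raises(ValueError, match="constant"):
            mixed_ancova(df.assign(value=1.0))
        with pytest.raises(ValueError, match="two groups"):
            mixed_ancova(df.assign(group="AD"))


class TestEffectSizes:
    def test_eta_symmetry_point(self):
        assert partial_eta_squared(3.3, 3.3) == 0.5

    def test_eta_rejects_zero_error(self):
        with pytest.raises(ValueError):
            partial_eta_squared(1.0, 0.0)

    def test_cohen_d_zero_for_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        assert cohen_d(x, x) == 0.0

    def test_cohen_d_matches_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 40), rng.normal(1, 2, 30)
        pooled = np.sqrt((39 * a.var(ddof=1) + 29 * b.var(ddof=1)) / 68)
        assert cohen_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-12)


class TestTukeyPosthoc:
    def test_identical_cells_null(self):
        cell = list(np.random.default_rng(0).normal(0, 1, 20))
        rows = [
            dict(participant_id=f"{g}{t}{i}", group=g, task=t, value=v)
            for g in ("A", "B")
            for t in ("phonemic", "semantic")
            for i, v in enumerate(cell)
        ]
        res = tukey_posthoc(pd.DataFrame(rows))
        assert all(r.p > 0.999 for r in res)
        assert all(abs(r.cohen_d) < 1e-12 for r in res)

    def test_two_pooled_sd_separation_gives_d_of_two(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 4000)
        b = rng.normal(2, 1, 4000)
        rows = [
            dict(participant_id=f"a{i}", group="A", task="phonemic", value=v)
            for i, v in enumerate(a)
        ] + [
            dict(participant_id=f"b{i}", group="B", task="phonemic", value=v)
            for i, v in enumerate(b)
        ]
        res = tukey_posthoc(pd.DataFrame(rows))
        assert len(res) == 1
        assert res[0].cohen_d == pytest.approx(-2.0, abs=0.1)

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(8)
        cells = {("A", "phonemic"): 0.0, ("A", "semantic"): 0.6, ("B", "phonemic"): 0.2, ("B", "semantic"): 1.0}
        samples = {k: rng.normal(mu, 1, 15) for k, mu in cells.items()}
        rows = [
            dict(participant_id=f"{g}{t}{i}", group=g, task=t, value=v)
            for (g, t), vals in samples.items()
            for i, v in enumerate(vals)
        ]
        res = tukey_posthoc(pd.DataFrame(rows))
        oracle = stats.tukey_hsd(*samples.values())
        keys = list(samples)
        got = {r.contrast: r.p for r in res}
        for i in range(4):
            for j in range(i + 1, 4):
                ka, kb = keys[i], keys[j]
                label = f"{ka[0]}:{ka[1]} - {kb[0]}:{kb[1]}"
                assert got[label] == pytest.approx(oracle.pvalue[i, j], abs=1e-9), label

    def test_degenerate_cells_rejected(self):
        rows = [dict(participant_id="a", group="A", task="phonemic", value=1.0)]
        with pytest.raises(ValueError):
            tukey_posthoc(pd.DataFrame(rows))
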