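"""Statistics layer checked against brute-force sums-of-squares oracles."""

import numpy as np
import pandas as pd
import pytest

from decicomp.analysis import (
    arcsine_transform,
    paired_test,
    pairwise_bonferroni,
    rm_anova,
)


def _toy_table(seed=3, n_subj=5):
    """Fixed 3 x 2 within-subject table with real effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        subj_shift = rng.normal(0, 0.5)
        for i, t in enumerate(["x", "y", "z"]):
            for j, c in enumerate(["p", "q"]):
                rows.append(
                    dict(
                        participant=s,
                        type=t,
                        relation=c,
                        dv=10 + 0.6 * i - 0.4 * j + 0.2 * i * j + subj_shift + rng.normal(0, 0.3),
                    )
                )
    return pd.DataFrame(rows)


def _brute_force_two_way_rm(df):
    """Textbook SS decomposition of a two-way fully-within design."""
    a_lv = sorted(df.type.unique())
    b_lv = sorted(df.relation.unique())
    s_lv = sorted(df.participant.unique())
    na, nb, ns = len(a_lv), len(b_lv), len(s_lv)
    y = df.set_index(["participant", "type", "relation"]).dv
    G = y.mean()
    A = y.groupby("type").mean()
    B = y.groupby("relation").mean()
    S = y.groupby("participant").mean()
    AB = y.groupby(["type", "relation"]).mean()
    AS = y.groupby(["type", "participant"]).mean()
    BS = y.groupby(["relation", "participant"]).mean()

    ss_a = ns * nb * sum((A[a] - G) ** 2 for a in a_lv)
    ss_b = ns * na * sum((B[b] - G) ** 2 for b in b_lv)
    ss_ab = ns * sum((AB[a, b] - A[a] - B[b] + G) ** 2 for a in a_lv for b in b_lv)
    ss_as = nb * sum((AS[a, s] - A[a] - S[s] + G) ** 2 for a in a_lv for s in s_lv)
    ss_bs = na * sum((BS[b, s] - B[b] - S[s] + G) ** 2 for b in b_lv for s in s_lv)
    ss_abs = sum(
        (
            y[s, a, b] - AB[a, b] - AS[a, s] - BS[b, s] + A[a] + B[b] + S[s] - G
        ) ** 2
        for a in a_lv
        for b in b_lv
        for s in s_lv
    )
    f_a = (ss_a / (na - 1)) / (ss_as / ((na - 1) * (ns - 1)))
    f_b = (ss_b / (nb - 1)) / (ss_bs / ((nb - 1) * (ns - 1)))
    f_ab = (ss_ab / ((na - 1) * (nb - 1))) / (ss_abs / ((na - 1) * (nb - 1) * (ns - 1)))
    eta_a = ss_a / (ss_a + ss_as)
    return dict(F_a=f_a, F_b=f_b, F_ab=f_ab, eta_a=eta_a)


class TestArcsine:
    @pytest.mark.parametrize(
        "p, expected", [(0.0, 0.0), (1.0, np.pi / 2), (0.25, np.pi / 6)]
    )
    def test_reference_values(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_strictly_monotone_on_unit_interval(self):
        grid = np.linspace(0, 1, 101)
        out = arcsine_transform(grid)
        assert np.all(np.diff(out) > 0)

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_rejects_values_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            arcsine_transform(bad)


class TestRmAnova:
    def test_matches_brute_force_decomposition(self):
        df = _toy_table()
        oracle = _brute_force_two_way_rm(df)
        effects = {e.effect: e for e in rm_anova(df, dv="dv", within=["type", "relation"])}
        assert effects["type"].F == pytest.approx(oracle["F_a"], abs=1e-6)
        assert effects["relation"].F == pytest.approx(oracle["F_b"], abs=1e-6)
        assert effects["type * relation"].F == pytest.approx(oracle["F_ab"], abs=1e-6)
        assert effects["type"].eta_p_sq == pytest.approx(oracle["eta_a"], abs=1e-6)

    def test_constant_cells_give_zero_f(self):
        df = _toy_table()
        df["dv"] = df.participant * 1.0  # varies only between subjects
        effects = rm_anova(df, dv="dv", within=["type", "relation"])
        for e in effects:
            assert e.F == pytest.approx(0.0, abs=1e-9)

    def test_two_level_factor_f_equals_squared_paired_t(self):
        df = _toy_table()
        sub = df.groupby(["participant", "relation"], as_index=False).dv.mean()
        eff = rm_anova(sub, dv="dv", within="relation")[0]
        piv = sub.pivot(index="participant", columns="relation", values="dv")
        t_res = paired_test(piv["p"].to_numpy(), piv["q"].to_numpy())
        assert eff.F == pytest.approx(t_res.F, rel=1e-9)
        assert eff.p == pytest.approx(t_res.p, rel=1e-9)

    def test_gg_epsilon_in_unit_interval(self):
        df = _toy_table()
        for e in rm_anova(df, dv="dv", within=["type", "relation"]):
            assert 0 < e.gg_epsilon <= 1

    def test_unbalanced_design_rejected(self):
        df = _toy_table().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, dv="dv", within=["type", "relation"])


class TestPairedTest:
    def test_matches_closed_form(self):
        x = np.array([10.2, 9.8, 11.0, 10.5, 9.9])
        y = np.array([9.1, 9.9, 10.1, 10.0, 9.0])
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = paired_test(x, y)
        assert res.F == pytest.approx(t**2, rel=1e-12)
        assert res.df1 == 1 and res.df2 == 4
        assert res.eta_p_sq == pytest.approx(t**2 / (t**2 + 4), rel=1e-12)

    def test_identical_samples_are_null(self):
        x = np.arange(5.0)
        res = paired_test(x, x)
        assert res.F == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_flagged_degenerate(self):
        x = np.arange(5.0) + 1.0
        res = paired_test(x, np.arange(5.0))
        assert res.p == 0.0
        assert "degenerate" in res.note

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            paired_test(np.zeros(3), np.zeros(4))


def test_bonferroni_dominates_uncorrected():
    df = _toy_table().groupby(["participant", "type"], as_index=False).dv.mean()
    table = pairwise_bonferroni(df, dv="dv", within="type")
    assert len(table) == 3
    assert (table.p_bonf >= table.p_unc - 1e-15).all()
    assert (table.p_bonf <= 1.0).all()


def test_summarize_rejects_empty_cells():
    from decicomp.analysis import summarize_run
    from decicomp.experiment import SimulationRun

    rows = []
    for s in range(3):
        for t in ["a.0c", "a.b0", "a.bc"]:
            for rel in ["compatible", "incompatible"]:
                if s == 0 and t == "a.0c" and rel == "compatible":
                    continue  # missing cell
                rows.append(
                    dict(participant=s, trial=0, item_id=0, type=t, relation=rel,
                         steps=10, response="a", correct=True, conflict=0.0)
                )
    run = SimulationRun(trials=pd.DataFrame(rows), n_participants=3, master_seed=0)
    with pytest.raises(ValueError, match="a.0c"):
        summarize_run(run)
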