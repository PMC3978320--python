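"""Repeated-measures statistics mirroring the simulated-experiment analyses.

The simulated data are summarised exactly the way the behavioural
literature analyses such designs: one mean per participant and
condition cell, a 3 x 2 repeated-measures ANOVA (decimal type x
tenth-hundredth compatibility) on RT and on arcsine-transformed error
rates, Bonferroni-corrected pairwise comparisons for significant main
effects, and paired t tests for the two-level string-length congruity
contrast (reported as F = t^2 with df (1, n-1)).  Sphericity is checked
with Mauchly's test; when it is violated the Greenhouse-Geisser
correction adjusts the degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .experiment import SimulationRun, exclude_errors

__all__ = [
    "EffectSummary",
    "RunSummary",
    "arcsine_transform",
    "rm_anova",
    "paired_test",
    "pairwise_bonferroni",
    "summarize_run",
]

THREE_DIGIT_TYPES = ("a.0c", "a.b0", "a.bc")


@dataclass
class EffectSummary:
    """One effect: F, (possibly GG-adjusted) dfs, p, partial eta squared."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta_p_sq: float
    gg_epsilon: float = 1.0
    gg_applied: bool = False
    means: dict = field(default_factory=dict)
    note: str = ""

    def __str__(self) -> str:
        df1, df2 = self.df1, self.df2
        gg = f", GG eps = {self.gg_epsilon:.3f}" if self.gg_applied else ""
        return (
            f"{self.effect}: F({df1:g}, {df2:g}) = {self.F:.2f}, "
            f"p = {self.p:.4g}, eta_p^2 = {self.eta_p_sq:.3f}{gg}"
        )


def arcsine_transform(p):
    """Variance-stabilising arcsine-square-root transform of a proportion."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def _check_balanced(data: pd.DataFrame, subject: str, within: list[str]) -> None:
    counts = data.groupby([subject] + within, observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced within-participant design: each participant "
                         "needs exactly one value per condition cell")
    full = data.groupby(subject, observed=True).size()
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    if (full != n_cells).any():
        raise ValueError("unbalanced within-participant design: missing condition "
                         "cells for some participants")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str = "participant",
    alpha: float = 0.05,
) -> list[EffectSummary]:
    """Repeated-measures ANOVA with sphericity-gated GG correction.

    ``data`` holds one row per participant x condition cell.  Effects
    with more than one numerator df are tested for sphericity
    (Mauchly); when the test rejects at ``alpha``, the Greenhouse-
    Geisser corrected p value is reported together with the epsilon.
    Partial eta squared is SS_effect / (SS_effect + SS_error).
    """
    within = [within] if isinstance(within, str) else list(within)
    _check_balanced(data, subject, within)
    table = pg.rm_anova(
        data=data, dv=dv, within=within, subject=subject,
        detailed=True, effsize="np2", correction=True,
    )
    if "ddof1" not in table.columns:
        # one-way layout: effect row(s) plus an Error row carrying df2
        err_df = float(table.loc[table["Source"] == "Error", "DF"].iloc[0])
        table = table.rename(columns={"DF": "ddof1"})
        table["ddof2"] = err_df
    out = []
    for _, row in table.iterrows():
        if row["Source"] == "Error":
            continue
        eps = float(row.get("eps", 1.0)) if not pd.isna(row.get("eps", np.nan)) else 1.0
        needs_gg = row["ddof1"] > 1 and _mauchly_rejects(data, dv, within, subject, row["Source"], alpha)
        use_gg = bool(needs_gg and not pd.isna(row.get("p_GG_corr", np.nan)))
        F = float(row["F"])
        p = float(row["p_GG_corr"] if use_gg else row["p_unc"])
        eta = float(row["np2"])
        note = ""
        if not np.isfinite(F):
            # zero error variance and zero effect variance (e.g. an error-free
            # run analysed on error rates): report a null effect, flagged
            F, p, eta, note = 0.0, 1.0, 0.0, "degenerate: no variance in any cell"
        out.append(
            EffectSummary(
                effect=str(row["Source"]),
                F=F,
                df1=float(row["ddof1"]),
                df2=float(row["ddof2"]),
                p=p,
                eta_p_sq=eta,
                gg_epsilon=eps if use_gg else 1.0,
                gg_applied=use_gg,
                note=note,
            )
        )
    return out


def _mauchly_rejects(data, dv, within, subject, source, alpha) -> bool:
    """Mauchly sphericity test for one ANOVA effect (collapsing other factors)."""
    factors = [f for f in within if f in source.split(" * ")]
    if not factors:
        return False
    collapsed = data.groupby([subject] + factors, observed=True)[dv].mean().reset_index()
    if len(factors) > 1:
        # interaction: test sphericity on the cell combinations
        collapsed["_cell"] = collapsed[factors].astype(str).agg(":".join, axis=1)
        factors = ["_cell"]
    if collapsed[factors[0]].nunique() <= 2:
        return False
    try:
        spher = pg.sphericity(collapsed, dv=dv, within=factors[0], subject=subject)
        return bool(spher.pval < alpha)
    except Exception:
        return False


def paired_test(x, y, effect: str = "paired contrast") -> EffectSummary:
    """Paired t test reported as F(1, n-1) = t^2 with partial eta squared.

    Degenerate inputs (zero variance of the differences) are flagged in
    the summary's note instead of producing spurious p values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.shape} vs {y.shape}")
    n = len(x)
    d = x - y
    sd = d.std(ddof=1)
    note = ""
    if sd == 0:
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(d.mean()), 0.0
            note = "degenerate: constant nonzero difference (zero variance)"
    else:
        t, p = stats.ttest_rel(x, y)
    F = float(t) ** 2 if np.isfinite(t) else float("inf")
    eta = F / (F + (n - 1)) if np.isfinite(F) else 1.0
    return EffectSummary(
        effect=effect, F=F, df1=1, df2=n - 1, p=float(p), eta_p_sq=float(eta),
        means={"x": float(x.mean()), "y": float(y.mean())}, note=note,
    )


def pairwise_bonferroni(
    data: pd.DataFrame, dv: str, within: str, subject: str = "participant"
) -> pd.DataFrame:
    """All pairwise paired t tests on one factor, Bonferroni-corrected."""
    levels = sorted(data[within].unique())
    cells = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    rows = []
    m = len(levels) * (len(levels) - 1) // 2
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            res = paired_test(cells[a].to_numpy(), cells[b].to_numpy(), f"{a} vs {b}")
            rows.append(
                {
                    "A": a, "B": b,
                    "mean_A": res.means["x"], "mean_B": res.means["y"],
                    "F": res.F, "p_unc": res.p,
                    "p_bonf": min(1.0, res.p * m),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run-level summaries


def participant_cell_means(
    trials: pd.DataFrame, types, value: str = "steps", correct_only: bool = True
) -> pd.DataFrame:
    """One RT mean (correct trials) per participant x type x relation cell."""
    sub = trials[trials["type"].isin(types)]
    if correct_only:
        sub = sub[sub["correct"]]
    cells = (
        sub.groupby(["participant", "type", "relation"], observed=True)[value]
        .mean()
        .reset_index()
    )
    return cells


def participant_error_rates(trials: pd.DataFrame, types) -> pd.DataFrame:
    """Per participant x cell error fraction (wrong or capped responses)."""
    sub = trials[trials["type"].isin(types)].copy()
    sub["error"] = ~sub["correct"]
    cells = (
        sub.groupby(["participant", "type", "relation"], observed=True)["error"]
        .mean()
        .reset_index()
    )
    return cells


@dataclass
class RunSummary:
    """Machine-readable twin of the simulated-results figures.

    Holds the 3 x 2 type-by-compatibility RT and ER tables with their
    ANOVAs, the string-length congruity contrasts, and the overall
    error loss of the run.
    """

    rt_cells: pd.DataFrame
    er_cells: pd.DataFrame
    rt_anova: list[EffectSummary]
    er_anova: list[EffectSummary]
    rt_type_means: pd.Series
    rt_pairwise: pd.DataFrame
    congruity_rt: EffectSummary
    congruity_er: EffectSummary
    congruity_rt_means: dict
    congruity_er_means: dict
    loss_fraction: float

    def report(self) -> str:
        lines = [
            "Simulated decimal-fraction comparison — results summary",
            "=======================================================",
            f"error loss: {100 * self.loss_fraction:.2f}% of trials excluded",
            "",
            "Mean simulated RT (steps) by decimal type:",
        ]
        for t, v in self.rt_type_means.items():
            lines.append(f"  {t}: {v:.2f}")
        lines.append("")
        lines.append("3 x 2 ANOVA on RT (decimal type x compatibility):")
        lines += [f"  {e}" for e in self.rt_anova]
        lines.append("Pairwise type comparisons (Bonferroni):")
        for _, r in self.rt_pairwise.iterrows():
            lines.append(
                f"  {r.A} ({r.mean_A:.2f}) vs {r.B} ({r.mean_B:.2f}): p_bonf = {r.p_bonf:.4g}"
            )
        lines.append("3 x 2 ANOVA on arcsine-transformed ER:")
        lines += [f"  {e}" for e in self.er_anova]
        lines.append("")
        lines.append("String-length congruity (a.b pairs):")
        m = self.congruity_rt_means
        lines.append(f"  RT: congruent {m['congruent']:.2f} vs incongruent {m['incongruent']:.2f} steps")
        lines.append(f"    {self.congruity_rt}")
        m = self.congruity_er_means
        lines.append(f"  ER: congruent {m['congruent']:.2f}% vs incongruent {m['incongruent']:.2f}%")
        lines.append(f"    {self.congruity_er}")
        return "\n".join(lines)


def _require_complete_cells(cells: pd.DataFrame, label: str) -> None:
    counts = cells.groupby(["type", "relation"], observed=True).size()
    if counts.empty:
        raise ValueError(f"{label}: no data cells at all")
    n = cells["participant"].nunique()
    short = counts[counts < n]
    if not short.empty:
        missing = ", ".join(f"{t}/{r}" for t, r in short.index)
        raise ValueError(f"{label}: empty cells for some participants ({missing})")


def summarize_run(run: SimulationRun) -> RunSummary:
    """Full statistical summary of one simulated experiment."""
    trials = run.trials
    _correct, loss = exclude_errors(run)

    # --- 3 x 2 type x compatibility, RT and ER
    rt_cells = participant_cell_means(trials, THREE_DIGIT_TYPES)
    _require_complete_cells(rt_cells, "RT analysis")
    rt_anova = rm_anova(rt_cells, dv="steps", within=["type", "relation"])
    rt_type_means = rt_cells.groupby("type", observed=True)["steps"].mean()
    rt_pairwise = pairwise_bonferroni(
        rt_cells.groupby(["participant", "type"], observed=True)["steps"].mean().reset_index(),
        dv="steps", within="type",
    )

    er_cells = participant_error_rates(trials, THREE_DIGIT_TYPES)
    er_cells["arcsine"] = arcsine_transform(er_cells["error"].to_numpy())
    er_anova = rm_anova(er_cells, dv="arcsine", within=["type", "relation"])

    # --- string-length congruity (a.b pairs): paired t tests
    ab_rt = participant_cell_means(trials, ["a.b"])
    piv_rt = ab_rt.pivot_table(index="participant", columns="relation", values="steps", observed=True)
    if piv_rt.isna().any().any() or piv_rt.shape[1] < 2:
        raise ValueError("congruity RT analysis: empty congruent or incongruent cell")
    congruity_rt = paired_test(
        piv_rt["congruent"].to_numpy(), piv_rt["incongruent"].to_numpy(),
        "string-length congruity (RT)",
    )

    ab_er = participant_error_rates(trials, ["a.b"])
    piv_er = ab_er.pivot_table(index="participant", columns="relation", values="error", observed=True)
    congruity_er = paired_test(
        arcsine_transform(piv_er["congruent"].to_numpy()),
        arcsine_transform(piv_er["incongruent"].to_numpy()),
        "string-length congruity (arcsine ER)",
    )

    return RunSummary(
        rt_cells=rt_cells,
        er_cells=er_cells,
        rt_anova=rt_anova,
        er_anova=er_anova,
        rt_type_means=rt_type_means,
        rt_pairwise=rt_pairwise,
        congruity_rt=congruity_rt,
        congruity_er=congruity_er,
        congruity_rt_means={
            "congruent": float(piv_rt["congruent"].mean()),
            "incongruent": float(piv_rt["incongruent"].mean()),
        },
        congruity_er_means={
            "congruent": 100 * float(piv_er["congruent"].mean()),
            "incongruent": 100 * float(piv_er["incongruent"].mean()),
        },
        loss_fraction=loss,
    )
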