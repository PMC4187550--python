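"""Inferential pipeline for within-subject training studies.

Implements the study's decision cascade on balanced, complete designs:

* a mixed repeated-measures ANOVA (training within × training mode
  between) for whole-fibre metrics;
* a two-within-factor repeated-measures ANOVA (training × layer) for
  layered metrics, each within effect tested against its own
  subject-interaction error stratum;
* Bonferroni-adjusted pairwise comparisons on significant main effects;
* paired t-tests within layers, run only when the training×layer
  interaction is significant.

No sphericity correction is applied by default; a Greenhouse–Geisser
correction of the within-factor p-values is available behind a flag.
Sums of squares use the closed-form balanced decomposition, so component
SS add exactly to the total SS (a tested invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import IncompleteDesignError, UndefinedStatisticError


@dataclass
class AnovaTable:
    """Effect rows (name, SS, df, MS, F, p) plus the design descriptor."""

    rows: pd.DataFrame
    design: dict

    def effect(self, name: str) -> pd.Series:
        match = self.rows[self.rows.effect == name]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name).p)

    @property
    def ss_total(self) -> float:
        return float(self.rows.ss.sum())


def paired_t(pre, post):
    """Two-sided paired t-test: t = mean(d)/(sd(d)/√n), df = n−1.

    ``d = post − pre`` so a positive t means an increase after training.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise UndefinedStatisticError("paired vectors must share one length")
    n = pre.size
    if n < 2:
        raise UndefinedStatisticError("paired t needs n >= 2")
    d = post - pre
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, n - 1, 1.0   # identical vectors: no change, no evidence
        return np.inf * np.sign(d.mean()), n - 1, 0.0
    res = sps.ttest_rel(post, pre)
    return float(res.statistic), n - 1, float(res.pvalue)


def bonferroni(pvals, m: int | None = None):
    """Bonferroni adjustment: adjusted = min(1, m·p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise UndefinedStatisticError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size or p.size < 1:
        raise UndefinedStatisticError("need m >= len(pvals) >= 1")
    return np.minimum(1.0, m * p)


def _f_p(ss_eff, df_eff, ss_err, df_err):
    if df_eff <= 0 or df_err <= 0 or ss_err <= 0:
        return np.nan, np.nan
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0:
        return np.nan, np.nan
    F = ms_eff / ms_err
    return F, float(sps.f.sf(F, df_eff, df_err))


def _pivot_complete(df, index, columns, values):
    try:
        wide = df.pivot_table(index=index, columns=columns, values=values,
                              aggfunc="mean")
    except Exception as exc:  # noqa: BLE001
        raise IncompleteDesignError(f"cannot pivot design table: {exc}") from exc
    na = wide.isna()
    if na.to_numpy().any():
        bad = [(i, c) for i, row in na.iterrows()
               for c, v in row.items() if v][:6]
        raise IncompleteDesignError(
            f"missing design cells (no imputation): {bad}")
    return wide


def mixed_anova_from_array(y: np.ndarray) -> AnovaTable:
    """Mixed RM-ANOVA on a balanced array ``y[group, subject, within]``.

    Decomposition: between stratum = group effect against
    subjects-within-groups; within stratum = within effect and
    within×group interaction against within×subjects-within-groups.
    """
    y = np.asarray(y, dtype=float)
    g, n, w = y.shape
    if g < 1 or n < 2 or w < 2:
        raise IncompleteDesignError(
            f"mixed ANOVA needs >= 2 subjects/group and >= 2 within levels, "
            f"got groups={g}, subjects={n}, within={w}")
    grand = y.mean()
    m_subj = y.mean(axis=2)                       # (g, n)
    m_grp = y.mean(axis=(1, 2))                   # (g,)
    m_win = y.mean(axis=(0, 1))                   # (w,)
    m_cell = y.mean(axis=1)                       # (g, w)

    ss_between_subj = w * ((m_subj - grand) ** 2).sum()
    ss_group = n * w * ((m_grp - grand) ** 2).sum()
    ss_subj_within_grp = ss_between_subj - ss_group
    ss_within_total = ((y - m_subj[:, :, None]) ** 2).sum()
    ss_win = g * n * ((m_win - grand) ** 2).sum()
    ss_cells = n * ((m_cell - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_win
    ss_err = ss_within_total - ss_win - ss_inter

    df_group, df_subj = g - 1, g * (n - 1)
    df_win = w - 1
    df_inter = (g - 1) * (w - 1)
    df_err = (w - 1) * g * (n - 1)

    rows = []
    for name, ss, df, err_ss, err_df in [
        ("between", ss_group, df_group, ss_subj_within_grp, df_subj),
        ("subjects_within_groups", ss_subj_within_grp, df_subj, None, None),
        ("within", ss_win, df_win, ss_err, df_err),
        ("within_x_between", ss_inter, df_inter, ss_err, df_err),
        ("within_x_subjects", ss_err, df_err, None, None),
    ]:
        ms = ss / df if df > 0 else np.nan
        if err_ss is None:
            F = p = np.nan
        else:
            F, p = _f_p(ss, df, err_ss, err_df)
        rows.append({"effect": name, "ss": max(ss, 0.0), "df": df,
                     "ms": ms, "F": F, "p": p})
    table = pd.DataFrame(rows)
    return AnovaTable(rows=table, design={
        "between_levels": g, "subjects_per_group": n, "within_levels": w,
        "n_subjects": g * n})


def mixed_anova(df: pd.DataFrame, dv: str, subject: str, within: str,
                between: str) -> AnovaTable:
    """Mixed RM-ANOVA from a tidy table (one value per subject × within level).

    Requires a complete, balanced design: every subject observed at every
    within level, equal subject counts per between group.
    """
    counts = df.groupby(between)[subject].nunique()
    if counts.nunique() != 1:
        raise IncompleteDesignError(
            f"unbalanced groups (subjects per group): {counts.to_dict()}")
    wide = _pivot_complete(df, [between, subject], within, dv)
    groups = wide.index.get_level_values(0).unique()
    y = np.stack([wide.loc[grp].to_numpy() for grp in groups])
    table = mixed_anova_from_array(y)
    win_levels = list(wide.columns)
    table.design.update({"within_factor": within, "between_factor": between,
                         "within_level_names": win_levels,
                         "between_level_names": list(groups)})
    rename = {"between": between, "within": within,
              "within_x_between": f"{within}*{between}",
              "within_x_subjects": f"{within}*subjects"}
    table.rows["effect"] = table.rows.effect.replace(rename)
    return table


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser ε from a within-factor covariance matrix."""
    k = cov.shape[0]
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    dbar = np.diag(cov).mean()
    num = (k * (dbar - mean_all)) ** 2
    den = (k - 1) * ((cov ** 2).sum() - 2 * k * (row_means ** 2).sum()
                     + k ** 2 * mean_all ** 2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_two_within_from_array(y: np.ndarray,
                                   gg_correction: bool = False) -> AnovaTable:
    """Two-within-factor RM-ANOVA on ``y[subject, a, b]`` (complete, balanced).

    Each within effect is tested against its own subject-interaction error
    term (A vs A×S, B vs B×S, A×B vs A×B×S).
    """
    y = np.asarray(y, dtype=float)
    s, a, b = y.shape
    if s < 2 or a < 2 or b < 2:
        raise IncompleteDesignError(
            f"two-within RM-ANOVA needs >= 2 levels everywhere, got "
            f"subjects={s}, a={a}, b={b}")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_s = a * b * ((m_s - grand) ** 2).sum()
    ss_a = s * b * ((m_a - grand) ** 2).sum()
    ss_b = s * a * ((m_b - grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_ab = s * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_abs = ss_total - ss_s - ss_a - ss_b - ss_as - ss_bs - ss_ab

    rows = []
    specs = [
        ("subjects", ss_s, s - 1, None, None, None),
        ("A", ss_a, a - 1, ss_as, (a - 1) * (s - 1), "A"),
        ("A*subjects", ss_as, (a - 1) * (s - 1), None, None, None),
        ("B", ss_b, b - 1, ss_bs, (b - 1) * (s - 1), "B"),
        ("B*subjects", ss_bs, (b - 1) * (s - 1), None, None, None),
        ("A*B", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (s - 1), "AB"),
        ("A*B*subjects", ss_abs, (a - 1) * (b - 1) * (s - 1), None, None, None),
    ]
    eps = {}
    if gg_correction:
        flat_a = y.mean(axis=2)
        flat_b = y.mean(axis=1)
        eps["A"] = _gg_epsilon(np.cov(flat_a, rowvar=False))
        eps["B"] = _gg_epsilon(np.cov(flat_b, rowvar=False))
        eps["AB"] = min(eps["A"], eps["B"])  # conservative for the interaction
    for name, ss, df, err_ss, err_df, key in specs:
        ms = ss / df if df > 0 else np.nan
        if err_ss is None:
            F = p = np.nan
        else:
            F, p = _f_p(ss, df, err_ss, err_df)
            if gg_correction and np.isfinite(F):
                e = eps[key]
                p = float(sps.f.sf(F, df * e, err_df * e))
        rows.append({"effect": name, "ss": max(ss, 0.0), "df": df,
                     "ms": ms, "F": F, "p": p})
    return AnovaTable(rows=pd.DataFrame(rows), design={
        "n_subjects": s, "a_levels": a, "b_levels": b,
        "gg_correction": gg_correction})


def rm_anova_two_within(df: pd.DataFrame, dv: str, subject: str,
                        within_a: str, within_b: str,
                        gg_correction: bool = False) -> AnovaTable:
    """Two-within-factor RM-ANOVA from a tidy table."""
    wide = _pivot_complete(df, subject, [within_a, within_b], dv)
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    y = wide.to_numpy().reshape(len(wide), len(a_levels), len(b_levels))
    table = rm_anova_two_within_from_array(y, gg_correction=gg_correction)
    table.design.update({"a_factor": within_a, "b_factor": within_b,
                         "a_level_names": list(a_levels),
                         "b_level_names": list(b_levels),
                         "subject_ids": list(wide.index)})
    rename = {"A": within_a, "B": within_b, "A*B": f"{within_a}*{within_b}",
              "A*subjects": f"{within_a}*subjects",
              "B*subjects": f"{within_b}*subjects",
              "A*B*subjects": f"{within_a}*{within_b}*subjects"}
    table.rows["effect"] = table.rows.effect.replace(rename)
    return table


# ---------------------------------------------------------------------------
# study-level decision cascade

WHOLE_FIBRE_METRICS = ("mean_intensity", "large_density_per_um2",
                       "mean_large_size_um2", "small_density_per_um2",
                       "mean_small_size_um2")
LAYER_METRICS = ("mean_intensity", "large_count_per_um2")


@dataclass
class StudyReport:
    alpha: float
    whole_fibre: dict = field(default_factory=dict)
    layers: dict = field(default_factory=dict)
    tests_run: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "whole_fibre": self.whole_fibre,
                "layers": self.layers, "tests_run": self.tests_run}


def _table_dict(t: AnovaTable) -> dict:
    return {"design": {k: v for k, v in t.design.items()
                       if k != "subject_ids"},
            "effects": t.rows.replace({np.nan: None}).to_dict("records")}


def aggregate_whole_fibre(fibre_metrics: pd.DataFrame) -> pd.DataFrame:
    """Fibre → subject × timepoint means (fibre types and replicates pooled)."""
    keys = ["subject_id", "mode", "timepoint"]
    return (fibre_metrics.groupby(keys)[list(WHOLE_FIBRE_METRICS)]
            .mean().reset_index())


def aggregate_layers(layer_metrics: pd.DataFrame) -> pd.DataFrame:
    """Fibre → subject × timepoint × layer means (fibre types pooled,
    mirroring the layered analysis where type I and II are not separated)."""
    keys = ["subject_id", "mode", "timepoint", "layer_index"]
    return (layer_metrics.groupby(keys)[list(LAYER_METRICS)]
            .mean().reset_index())


def analyze_study(fibre_metrics: pd.DataFrame, layer_metrics: pd.DataFrame,
                  alpha: float = 0.05, gg_correction: bool = False,
                  adjust_within_layer: bool = False,
                  max_layer: int | None = None) -> StudyReport:
    """Run the full decision cascade and return a structured report.

    Whole-fibre metrics: mixed ANOVA (training within × mode between) on
    subject means; Bonferroni pairwise comparisons on significant main
    effects.  Layered metrics, per mode: training × layer RM-ANOVA;
    Bonferroni layer pairwise on a significant layer main effect; paired
    t-tests within layers only when the training×layer interaction is
    significant (unadjusted by default, matching a cascade in which
    Bonferroni guards only the main-effect comparisons).
    """
    report = StudyReport(alpha=alpha)

    subj = aggregate_whole_fibre(fibre_metrics)
    for metric in WHOLE_FIBRE_METRICS:
        if metric not in fibre_metrics:
            continue
        entry = {}
        table = mixed_anova(subj, dv=metric, subject="subject_id",
                            within="timepoint", between="mode")
        entry["anova"] = _table_dict(table)
        report.tests_run.append(f"mixed_anova:{metric}")
        posthoc = []
        if table.p("timepoint") < alpha:
            wide = subj.pivot_table(index=["mode", "subject_id"],
                                    columns="timepoint", values=metric)
            t, dfree, p = paired_t(wide["pre"], wide["post"])
            posthoc.append({"comparison": "post vs pre", "t": t, "df": dfree,
                            "p": p, "p_adjusted": float(bonferroni([p])[0]),
                            "method": "Bonferroni"})
            report.tests_run.append(f"posthoc:{metric}:post vs pre")
        entry["posthoc"] = posthoc
        report.whole_fibre[metric] = entry

    agg = aggregate_layers(layer_metrics)
    if max_layer is not None:
        agg = agg[agg.layer_index <= max_layer]
    for mode in sorted(agg["mode"].unique()):
        sub = agg[agg["mode"] == mode]
        report.layers[mode] = {}
        for metric in LAYER_METRICS:
            if metric not in sub:
                continue
            entry = {}
            table = rm_anova_two_within(sub, dv=metric, subject="subject_id",
                                        within_a="timepoint",
                                        within_b="layer_index",
                                        gg_correction=gg_correction)
            entry["anova"] = _table_dict(table)
            report.tests_run.append(f"rm_anova:{mode}:{metric}")
            if table.p("layer_index") < alpha:
                entry["layer_pairwise"] = _layer_pairwise(sub, metric)
                report.tests_run.append(f"layer_pairwise:{mode}:{metric}")
            interaction_p = table.p("timepoint*layer_index")
            if interaction_p < alpha:
                entry["within_layer"] = _within_layer_t(
                    sub, metric, alpha, adjust_within_layer)
                report.tests_run.append(f"within_layer_t:{mode}:{metric}")
            report.layers[mode][metric] = entry
    return report


def _layer_pairwise(sub: pd.DataFrame, metric: str) -> list:
    """Bonferroni-adjusted paired comparisons between layers (timepoints
    pooled per subject)."""
    means = (sub.groupby(["subject_id", "layer_index"])[metric]
             .mean().unstack("layer_index"))
    layers = list(means.columns)
    pairs = list(combinations(layers, 2))
    out = []
    raw = []
    for i, j in pairs:
        try:
            t, dfree, p = paired_t(means[j], means[i])
        except UndefinedStatisticError:
            t, dfree, p = np.nan, len(means) - 1, np.nan
        raw.append(p)
        out.append({"comparison": f"layer {i} vs layer {j}", "t": t,
                    "df": dfree, "p": p, "method": "Bonferroni"})
    valid = np.array([p if np.isfinite(p) else 1.0 for p in raw])
    adj = bonferroni(valid, m=len(pairs))
    for rec, a in zip(out, adj):
        rec["p_adjusted"] = float(a)
    return out


def _within_layer_t(sub: pd.DataFrame, metric: str, alpha: float,
                    adjust: bool) -> dict:
    """Paired pre-vs-post t-test per layer (after a significant interaction)."""
    wide = sub.pivot_table(index=["subject_id"], columns=["timepoint",
                                                          "layer_index"],
                           values=metric)
    layers = sorted({c[1] for c in wide.columns})
    results = {}
    raw = []
    for layer in layers:
        t, dfree, p = paired_t(wide[("pre", layer)], wide[("post", layer)])
        raw.append(p)
        results[int(layer)] = {"t": t, "df": dfree, "p": p}
    if adjust:
        adj = bonferroni(raw, m=len(layers))
        for layer, a in zip(layers, adj):
            results[int(layer)]["p_adjusted"] = float(a)
    for layer in layers:
        p_use = results[int(layer)].get("p_adjusted", results[int(layer)]["p"])
        results[int(layer)]["significant"] = bool(p_use < alpha)
    return results
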