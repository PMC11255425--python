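"""Group statistics over fiber-level ES DA and τ tables.

The analysis unit is the individual fiber.  The layer provides:

* one-way ANOVA across groups with Tukey HSD pairwise comparisons;
* two-way factorial ANOVA (between-subjects via OLS, or fully
  repeated-measures with Greenhouse–Geisser sphericity correction) with
  Bonferroni/Šídák post-hoc families;
* a repeated-measures "mixed model" for chronic week × stimulation-parameter
  designs that tolerates missing cells (fibers below threshold on some days):
  on complete data it is the classical two-way within-subject ANOVA computed
  from expected mean squares; with missingness it falls back to a REML
  linear mixed model with a random fiber intercept;
* per-animal coefficient-of-variation tables (mean ± SEM over animals);
* null-calibration utilities (empirical type-I error of the week effect
  under cohort simulations).

Significance threshold is α = 0.05 throughout unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "anova_oneway",
    "anova_twoway",
    "mixed_model_weeks",
    "rm_anova_two_way",
    "pairwise_posthoc",
    "cv_table",
    "simulate_null_rejection_rate",
]


# ---------------------------------------------------------------------------
# One-way
# ---------------------------------------------------------------------------

def anova_oneway(df: pd.DataFrame, dv: str, group: str) -> dict:
    """One-way ANOVA across groups plus a Tukey HSD pairwise table.

    Returns ``{"F", "df", "p", "posthoc"}`` with ``df = (df_between,
    df_within)``.
    """
    groups = [g[dv].dropna().to_numpy() for _, g in df.groupby(group, observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    f, p = sps.f_oneway(*groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    clean = df.dropna(subset=[dv, group])
    tk = pairwise_tukeyhsd(clean[dv], clean[group])
    posthoc = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return {"F": float(f), "df": (df_b, df_w), "p": float(p), "posthoc": posthoc}


# ---------------------------------------------------------------------------
# Two-way (between or fully repeated)
# ---------------------------------------------------------------------------

def anova_twoway(
    df: pd.DataFrame,
    dv: str,
    factors: "tuple[str, str]",
    repeated: bool = False,
    subject: "str | None" = None,
    gg_correction: bool = True,
    posthoc: "str | None" = None,
) -> dict:
    """Two-way factorial ANOVA.

    Between-subjects designs use an OLS fit with type-II sums of squares.
    With ``repeated=True`` (both factors within-subject, ``subject``
    required) a classical repeated-measures ANOVA is run with
    Greenhouse–Geisser-corrected p-values when ``gg_correction`` is on.
    ``posthoc`` ("bonferroni" or "sidak") adds pairwise comparisons of the
    cell means.
    """
    a, b = factors
    if repeated:
        if subject is None:
            raise ValueError("repeated design requires a subject column")
        import pingouin as pg

        aov = pg.rm_anova(
            data=df, dv=dv, within=[a, b], subject=subject,
            correction=gg_correction, detailed=True,
        )
        effects = aov.rename(columns={
            "p-unc": "p_unc", "p-GG-corr": "p_gg", "p_GG_corr": "p_gg",
        })
    else:
        cells = df.groupby([a, b], observed=True)[dv].count()
        if (cells < 1).any() or cells.size < len(df[a].unique()) * len(df[b].unique()):
            raise ValueError("empty cell in a non-repeated two-way design")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        data = df.rename(columns={dv: "_y", a: "_a", b: "_b"})
        model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
        tab = anova_lm(model, typ=2)
        tab.index = [a, b, f"{a} * {b}", "Residual"]
        effects = tab.rename(columns={"PR(>F)": "p_unc"})

    out = {"effects": effects}
    if posthoc:
        cell = df[a].astype(str) + ":" + df[b].astype(str)
        tmp = df.assign(_cell=cell)
        out["posthoc"] = pairwise_posthoc(
            tmp, dv, "_cell", subject=subject if repeated else None, method=posthoc
        )
    return out


# ---------------------------------------------------------------------------
# Manual two-way within-subject ANOVA (complete data)
# ---------------------------------------------------------------------------

def _gg_epsilon(cells: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon for one effect.

    ``cells`` is (n_subjects, m) per-subject responses; ``contrast`` is a
    (q, m) orthonormal contrast matrix spanning the effect.  ε =
    tr(CVC')² / (q · tr((CVC')²)), clipped to [1/q, 1].
    """
    v = np.cov(cells, rowvar=False, ddof=1)
    w = contrast @ v @ contrast.T
    q = contrast.shape[0]
    tr = np.trace(w)
    tr2 = np.trace(w @ w)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (q * tr2), 1.0 / q, 1.0))


def rm_anova_two_way(
    wide: np.ndarray,
    a_levels: int,
    b_levels: int,
    gg_correction: bool = True,
) -> pd.DataFrame:
    """Classical two-way fully-within-subject ANOVA from expected mean squares.

    ``wide`` is (n_subjects, a_levels · b_levels) with cell order
    (a0b0, a0b1, ..., a1b0, ...), one observation per subject × cell.  Each
    effect is tested against its own subject-interaction error stratum
    (A against A×S, B against B×S, A×B against A×B×S), with per-effect
    Greenhouse–Geisser ε correcting the degrees of freedom.
    """
    y = np.asarray(wide, dtype=float)
    n = y.shape[0]
    a, b = a_levels, b_levels
    if y.shape[1] != a * b:
        raise ValueError("wide matrix does not match a_levels*b_levels")
    if not np.isfinite(y).all():
        raise ValueError("complete (non-missing) data required")
    cube = y.reshape(n, a, b)

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_tot = np.sum((cube - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    rows = []
    ca = helmert(a)
    cb = helmert(b)
    ones_a = np.full((1, a), 1.0 / a)
    ones_b = np.full((1, b), 1.0 / b)
    specs = [
        ("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1), np.kron(ca, ones_b)),
        ("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1), np.kron(ones_a, cb)),
        ("A * B", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (n - 1), np.kron(ca, cb)),
    ]
    for name, ss_eff, df_eff, ss_err, df_err, contrast in specs:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else np.nan
        p_unc = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else np.nan
        if gg_correction and df_eff > 1:
            # normalize contrast rows (kron with the averaging row is not
            # unit-norm); epsilon is invariant to row scaling only when
            # uniform, which holds here
            cmat = contrast / np.linalg.norm(contrast, axis=1, keepdims=True)
            eps = _gg_epsilon(y, cmat)
        else:
            eps = 1.0
        p_gg = float(sps.f.sf(f, df_eff * eps, df_err * eps)) if np.isfinite(f) else np.nan
        rows.append({
            "Source": name, "SS": ss_eff, "df1": df_eff, "df2": df_err,
            "MS": ms_eff, "F": f, "eps": eps, "p_unc": p_unc, "p_gg": p_gg,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed model across weeks
# ---------------------------------------------------------------------------

def mixed_model_weeks(
    df: pd.DataFrame,
    dv: str = "es_da_nM",
    subject: str = "fiber",
    within: "tuple[str, str]" = ("week", "param"),
    gg_correction: bool = True,
    posthoc: "str | None" = None,
    posthoc_factor: "str | None" = None,
) -> dict:
    """Week × parameter effect tests tolerant of missing fiber-days.

    Complete data take the exact repeated-measures route
    (:func:`rm_anova_two_way`); incomplete data are fit by REML with a
    random intercept per fiber and Wald tests per term (the
    Greenhouse–Geisser correction applies only on the complete route).
    Weeks with zero observations are dropped with a warning.  ``posthoc``
    ("tukey" or "sidak") adds pairwise marginal-mean comparisons over
    ``posthoc_factor`` (default: the first within factor).
    """
    a_col, b_col = within
    data = df.dropna(subset=[dv]).copy()

    # drop empty within-levels
    for col in within:
        counts = data.groupby(col, observed=True)[dv].count()
        empty = [lv for lv in df[col].unique() if counts.get(lv, 0) == 0]
        if empty:
            warnings.warn(f"{col} level(s) {empty} have no observations; dropped",
                          stacklevel=2)

    wide = data.pivot_table(index=subject, columns=[a_col, b_col], values=dv)
    complete = not wide.isna().any().any()

    if complete:
        a_levels = wide.columns.get_level_values(0).nunique()
        b_levels = wide.columns.get_level_values(1).nunique()
        wide = wide.sort_index(axis=1)
        effects = rm_anova_two_way(
            wide.to_numpy(), a_levels, b_levels, gg_correction=gg_correction
        )
        effects["Source"] = [a_col, b_col, f"{a_col} * {b_col}"]
        method = "rm_anova"
    else:
        import statsmodels.formula.api as smf

        tmp = data.rename(columns={dv: "_y", a_col: "_a", b_col: "_b"})
        tmp["_a"] = tmp["_a"].astype(str)
        tmp["_b"] = tmp["_b"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("_y ~ C(_a) * C(_b)", tmp, groups=tmp[subject])
            res = md.fit(reml=True)
        rows = []
        for name, pattern in (
            (a_col, "C(_a)["), (b_col, "C(_b)["), (f"{a_col} * {b_col}", ":"),
        ):
            if name == f"{a_col} * {b_col}":
                idx = [i for i, nm in enumerate(res.model.exog_names) if ":" in nm]
            else:
                idx = [i for i, nm in enumerate(res.model.exog_names)
                       if nm.startswith(pattern) and ":" not in nm]
            contrast = np.zeros((len(idx), len(res.params)))
            for r, i in enumerate(idx):
                contrast[r, i] = 1.0
            wt = res.wald_test(contrast, scalar=False)
            chi2 = float(np.squeeze(wt.statistic))
            dfn = len(idx)
            dfd = max(int(data[subject].nunique()) - dfn, 1)
            f = chi2 / dfn
            rows.append({
                "Source": name, "df1": dfn, "df2": dfd, "F": f, "eps": np.nan,
                "p_unc": float(sps.f.sf(f, dfn, dfd)),
                "p_gg": float(sps.f.sf(f, dfn, dfd)),
            })
        effects = pd.DataFrame(rows)
        method = "mixedlm"

    out = {"effects": effects, "method": method}
    if posthoc:
        factor = posthoc_factor or a_col
        out["posthoc"] = pairwise_posthoc(
            data, dv, factor, subject=subject, method=posthoc
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise comparisons
# ---------------------------------------------------------------------------

def pairwise_posthoc(
    df: pd.DataFrame,
    dv: str,
    factor: str,
    subject: "str | None" = None,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise comparisons of factor levels with a multiplicity correction.

    With ``subject`` given, comparisons are paired on the subjects present at
    both levels.  ``method`` is "bonferroni", "sidak" or "tukey" (studentized
    range on the per-pair t statistics).
    """
    from itertools import combinations

    levels = sorted(df[factor].dropna().unique(), key=str)
    k = len(levels)
    rows = []
    for la, lb in combinations(levels, 2):
        if subject is not None:
            # marginal mean per subject within each level (averages over any
            # other within factors before pairing)
            wa = df[df[factor] == la].groupby(subject)[dv].mean()
            wb = df[df[factor] == lb].groupby(subject)[dv].mean()
            common = wa.index.intersection(wb.index)
            x, y = wa.loc[common].to_numpy(), wb.loc[common].to_numpy()
            if len(common) < 2:
                continue
            t, p = sps.ttest_rel(x, y)
            dof = len(common) - 1
        else:
            x = df[df[factor] == la][dv].dropna().to_numpy()
            y = df[df[factor] == lb][dv].dropna().to_numpy()
            t, p = sps.ttest_ind(x, y)
            dof = len(x) + len(y) - 2
        rows.append({
            "A": la, "B": lb, "mean_diff": float(np.mean(x) - np.mean(y)),
            "t": float(t), "df": dof, "p_unc": float(p),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table

    if method == "tukey":
        q = np.abs(table["t"]) * np.sqrt(2.0)
        table["p_adj"] = [
            float(sps.studentized_range.sf(qi, k, dfi))
            for qi, dfi in zip(q, table["df"])
        ]
    else:
        from statsmodels.stats.multitest import multipletests

        alias = {"bonferroni": "bonferroni", "sidak": "sidak"}
        if method not in alias:
            raise ValueError(f"unknown posthoc method: {method}")
        table["p_adj"] = multipletests(table["p_unc"], method=alias[method])[1]
    table["significant"] = table["p_adj"] < 0.05
    return table


# ---------------------------------------------------------------------------
# Variability and calibration-under-null
# ---------------------------------------------------------------------------

def cv_table(
    df: pd.DataFrame,
    dv: str = "es_da_nM",
    animal: str = "animal",
    cells: "tuple[str, ...]" = ("group", "week", "param"),
) -> pd.DataFrame:
    """Coefficient-of-variation table: per-animal CV over fibers, then
    mean ± SEM over animals per design cell.

    Animals contributing fewer than 2 fibers to a cell are excluded from
    that cell.
    """
    def _cv(x: pd.Series) -> float:
        x = x.dropna()
        return float(x.std(ddof=1) / x.mean()) if len(x) >= 2 else np.nan

    per_animal = (
        df.groupby([*cells, animal], observed=True)[dv].apply(_cv).dropna()
    )
    grouped = per_animal.groupby(level=list(range(len(cells))), observed=True)
    out = grouped.agg(
        cv_mean="mean",
        cv_sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n_animals="count",
    )
    return out.reset_index()


def simulate_null_rejection_rate(
    design=None,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    effect: str = "week",
    group: "str | None" = None,
    gg_correction: bool = True,
) -> float:
    """Empirical type-I error of a within-subject effect under the null.

    Cohorts are simulated with no week effect and identical groups; each
    replicate runs the complete-data repeated-measures route on one group's
    fiber table and the rejection frequency of ``effect`` at ``alpha`` is
    returned.
    """
    from .synthetic import default_cohort_design, generate_cohort

    if design is None:
        design = default_cohort_design(sensitization_slope=0.0)
    rejections = 0
    for rep in range(n_reps):
        table, _ = generate_cohort(design, seed=seed + rep)
        sub = table if group is None else table[table["group"] == group]
        gname = sub["group"].iloc[0]
        sub = sub[sub["group"] == gname]
        wide = sub.pivot_table(index="fiber", columns=["week", "param"],
                               values="es_da_nM").sort_index(axis=1)
        a = wide.columns.get_level_values(0).nunique()
        b = wide.columns.get_level_values(1).nunique()
        eff = rm_anova_two_way(wide.to_numpy(), a, b, gg_correction=gg_correction)
        source = {"week": "A", "param": "B"}.get(effect, "A * B")
        p = float(eff.loc[eff["Source"] == source, "p_gg"].iloc[0])
        if p < alpha:
            rejections += 1
    return rejections / n_reps
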