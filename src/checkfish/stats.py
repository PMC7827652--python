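"""Group-level statistics: split-plot ANOVA and similarity comparisons.

The IEG design is a 2 (treatment: QNP vs control) x 2 (environment:
arena-exploring A1A2 vs home-cage HC) between-subjects layout with
repeated measures on the exploration session (epoch E1/A1 vs E2/A2), each
brain region analysed separately.  ``run_mixed_anova`` implements the
classical split-plot decomposition:

* between-subjects stratum -- treatment, environment and their
  interaction tested on per-subject means against the subjects-within-
  groups mean square;
* within-subjects stratum -- session and its interactions with the
  between factors tested against the session x subject residual.

Similarity scores have one value per animal, so ``compare_similarity``
is a plain two-way between-subjects ANOVA per region, excluding (and
counting) animals whose score is undefined.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["run_mixed_anova", "compare_similarity", "simple_effects"]


def _check_cells(data: pd.DataFrame, factors: Sequence[str], min_n: int) -> None:
    sizes = data.groupby(list(factors), observed=True).size()
    small = sizes[sizes < min_n]
    if len(small):
        warnings.warn(f"cells with fewer than {min_n} observations: {small.to_dict()}")


def _f_test(ss: float, df1: float, err_ss: float, err_df: float, scale: float):
    """F and p with a relative-tolerance guard for zero error variance.

    With distinct cell means and no within-cell variance the F statistic
    diverges (reported as inf with p = 0 and a warning); a term whose own
    SS is also numerically zero is undetermined (NaN)."""
    from scipy import stats as sps

    tol = 1e-9 * max(scale, 1e-300)
    ss = max(ss, 0.0)
    if err_df <= 0 or err_ss <= tol:
        warnings.warn("zero within-cell error variance; F is infinite")
        return (np.nan, np.nan) if ss <= tol else (np.inf, 0.0)
    F = (ss / df1) / (err_ss / err_df)
    return float(F), float(sps.f.sf(F, df1, err_df))


def run_mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "animal_id",
    between: Sequence[str] = ("treatment", "environment"),
    within: str = "session",
) -> pd.DataFrame:
    """Split-plot (mixed-design) ANOVA effect table.

    Parameters
    ----------
    data : long-format DataFrame
        One row per subject x within-level; between-factor labels are
        constant within subject.
    dv : str
        Dependent-variable column (a proportion or score).

    Returns
    -------
    DataFrame with columns ``source, stratum, ss, df1, df2, F, p``:
    between-factor main effects and interaction, the within main effect
    and all within x between interactions.  With zero error variance the
    F statistic is infinite and the p-value 0 (degenerate data; a warning
    is emitted).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    between = list(between)
    work = data[[subject, dv, within] + between].dropna(subset=[dv]).copy()
    work = work.rename(columns={dv: "_dv", subject: "_subj", within: "_w"})
    _check_cells(work, between + ["_w"], 2)

    # --- between stratum: subject means ---
    subj_means = (
        work.groupby(["_subj"] + between, observed=True)["_dv"].mean().reset_index()
    )
    bterms = " * ".join(f"C({b})" for b in between)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on perfect fits
        m_between = ols(f"_dv ~ {bterms}", data=subj_means).fit()
        tab_b = sm.stats.anova_lm(m_between, typ=2)

    rows = []
    err_b = tab_b.loc["Residual"]
    scale_b = float(subj_means["_dv"].var(ddof=0) * len(subj_means)) or 1.0
    for name, row in tab_b.iterrows():
        if name == "Residual":
            continue
        F, p = _f_test(
            float(row["sum_sq"]), float(row["df"]),
            float(err_b["sum_sq"]), float(err_b["df"]), scale_b,
        )
        rows.append(
            {
                "source": name.replace("C(", "").replace(")", ""),
                "stratum": "between",
                "ss": float(row["sum_sq"]),
                "df1": float(row["df"]),
                "df2": float(err_b["df"]),
                "F": F,
                "p": p,
            }
        )

    # --- within stratum: subject factor absorbs all between variation ---
    # Sequential (type-I) sums of squares from nested OLS fits; SS and df
    # come from residual differences, which handles the collinearity of
    # within x between interactions with the subject factor correctly.
    from scipy import stats as sps

    terms = ["C(_subj)", "C(_w)"] + [f"C(_w):C({b})" for b in between]
    if len(between) > 1:
        terms.append("C(_w):" + ":".join(f"C({b})" for b in between))
    names = [None, within] + [f"{within}:{b}" for b in between]
    if len(between) > 1:
        names.append(f"{within}:" + ":".join(between))

    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, len(terms) + 1):
            fits.append(ols("_dv ~ " + " + ".join(terms[:k]), data=work).fit())
    full = fits[-1]
    err_ss, err_df = float(full.ssr), float(full.df_resid)
    scale_w = float(work["_dv"].var(ddof=0) * len(work)) or 1.0
    for k in range(1, len(fits)):
        ss = float(fits[k - 1].ssr - fits[k].ssr)
        df1 = float(fits[k - 1].df_resid - fits[k].df_resid)
        if df1 <= 0:
            warnings.warn(f"term {names[k]} dropped (no degrees of freedom)")
            continue
        F, p = _f_test(ss, df1, err_ss, err_df, scale_w)
        rows.append(
            {
                "source": names[k],
                "stratum": "within",
                "ss": ss,
                "df1": df1,
                "df2": err_df,
                "F": F,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def compare_similarity(
    scores: pd.DataFrame,
    dv: str = "score",
    between: Sequence[str] = ("treatment", "environment"),
    region_col: Optional[str] = "region",
) -> Dict[str, pd.DataFrame]:
    """Two-way between-subjects ANOVA on similarity scores, per region.

    Undefined (NaN) scores are excluded listwise; the number excluded is
    reported in each table's ``n_excluded`` attribute column.  Regions in
    which every score is undefined are skipped with a warning.
    """
    import pingouin as pg

    between = list(between)
    out: Dict[str, pd.DataFrame] = {}
    groups = scores.groupby(region_col) if region_col else [("all", scores)]
    for region, g in groups:
        valid = g.dropna(subset=[dv])
        n_excl = len(g) - len(valid)
        if valid.empty:
            warnings.warn(f"region {region}: all scores undefined, skipped")
            continue
        if valid[dv].nunique() <= 1:
            # constant scores: no variance to partition, no effects
            warnings.warn(f"region {region}: scores are constant; effects undetermined")
            tab = pd.DataFrame(
                {
                    "source": between + [" * ".join(between)],
                    "F": np.nan,
                    "p": np.nan,
                    "n_excluded": n_excl,
                }
            )
            out[str(region)] = tab
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = pg.anova(data=valid, dv=dv, between=between, detailed=True)
        tab = tab.rename(columns={"Source": "source", "p-unc": "p", "p_unc": "p"})
        tab["n_excluded"] = n_excl
        out[str(region)] = tab
    return out


def simple_effects(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    by: str,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Two-level simple-effects follow-up: Welch t-tests of ``factor``
    within each level of ``by``, Bonferroni-corrected across levels."""
    from scipy import stats as sps

    rows = []
    levels = sorted(data[by].dropna().unique())
    for lev in levels:
        sub = data[data[by] == lev]
        fl = sorted(sub[factor].dropna().unique())
        if len(fl) != 2:
            warnings.warn(f"{by}={lev}: need exactly 2 levels of {factor}, got {fl}")
            continue
        a = sub.loc[sub[factor] == fl[0], dv].dropna()
        b = sub.loc[sub[factor] == fl[1], dv].dropna()
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({by: lev, "contrast": f"{fl[0]} vs {fl[1]}", "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if bonferroni and len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
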