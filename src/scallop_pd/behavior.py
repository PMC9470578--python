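"""Behavioral event-rate analysis from video annotation tables.

Annotation tables (BORIS-style exports) carry one behavioral event per row.
This module filters fish-related partial closures, converts events to
per-individual rates (events per minute), quantifies strike-response
synchronization, and compares treatments with a linear mixed model followed
by Tukey-adjusted pairwise contrasts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist

__all__ = [
    "BEHAVIORS",
    "STAGES",
    "SITES",
    "TREATMENTS",
    "validate_annotations",
    "filter_annotations",
    "compute_rates",
    "rate_summary",
    "response_fraction",
    "compare_treatments",
    "ComparisonResult",
]

BEHAVIORS = ("coughing", "partial_closure", "total_closure", "swimming")
STAGES = ("juvenile", "subadult", "adult")
SITES = ("near", "far")
TREATMENTS = ("preexposure", "IH1", "VH1", "IH2", "VH2")

_REQUIRED = ("time_s", "subject", "stage", "site", "treatment", "behavior",
             "fish_nearby")


def validate_annotations(table: pd.DataFrame) -> None:
    """Check required columns and categorical vocabularies."""
    missing = set(_REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    for col, vocab in (("behavior", BEHAVIORS), ("stage", STAGES),
                       ("site", SITES), ("treatment", TREATMENTS)):
        bad = set(table[col].unique()) - set(vocab)
        if bad:
            raise ValueError(
                f"unknown {col} value(s) {sorted(bad)}; allowed: {list(vocab)}")


def filter_annotations(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop partial closures attributable to fish near the cage.

    Only rows with ``behavior == partial_closure`` and a truthy
    ``fish_nearby`` flag are removed; returns the retained table and the
    number of rows removed.
    """
    if len(table) == 0:
        return table.copy(), 0
    validate_annotations(table)
    drop = (table["behavior"] == "partial_closure") & table["fish_nearby"].astype(bool)
    return table.loc[~drop].reset_index(drop=True), int(drop.sum())


def compute_rates(
    table: pd.DataFrame,
    windows: float | dict = 15.0,
    subjects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Events per minute per individual x treatment x behavior.

    ``windows`` is the observation window in minutes, a scalar or a
    per-treatment dict.  ``subjects`` optionally supplies the full roster
    (columns subject, stage, site) so individuals with zero events still
    appear; by default the roster is inferred from the table.
    """
    if len(table):
        validate_annotations(table)
    if subjects is None:
        if len(table) == 0:
            return pd.DataFrame(columns=["subject", "stage", "site", "treatment",
                                         "window_min",
                                         *(f"{b}_per_min" for b in BEHAVIORS)])
        subjects = (table[["subject", "stage", "site"]]
                    .drop_duplicates().reset_index(drop=True))

    def _window(tr: str) -> float:
        w = windows.get(tr) if isinstance(windows, dict) else windows
        if w is None or not w > 0:
            raise ValueError(f"no positive observation window for treatment {tr!r}")
        return float(w)

    treatments = (sorted(table["treatment"].unique(), key=TREATMENTS.index)
                  if len(table) else list(TREATMENTS))
    counts = (table.groupby(["subject", "treatment", "behavior"]).size()
              if len(table) else pd.Series(dtype=int))
    rows = []
    for _, subj in subjects.iterrows():
        for tr in treatments:
            w = _window(tr)
            row = {"subject": subj["subject"], "stage": subj["stage"],
                   "site": subj["site"], "treatment": tr, "window_min": w}
            for b in BEHAVIORS:
                c = counts.get((subj["subject"], tr, b), 0) if len(table) else 0
                row[f"{b}_per_min"] = c / w
            rows.append(row)
    return pd.DataFrame(rows)


def rate_summary(rates: pd.DataFrame,
                 by: tuple[str, ...] = ("site", "stage", "treatment")) -> pd.DataFrame:
    """Group mean, SD, and SEM of each behavior rate across individuals."""
    cols = [f"{b}_per_min" for b in BEHAVIORS]
    g = rates.groupby(list(by))[cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std(ddof=1).add_suffix("_sd")
    sem = g.sem(ddof=1).add_suffix("_sem")
    return pd.concat([mean, sd, sem], axis=1).reset_index()


def response_fraction(closure_times, strike_times, sync_window_s: float = 2.0) -> float:
    """Fraction of strikes answered by at least one closure within the sync
    window; each closure is credited to its nearest preceding strike only."""
    strikes = np.sort(np.asarray(strike_times, dtype=float))
    if len(strikes) == 0:
        raise ValueError("strike list is empty")
    closures = np.asarray(closure_times, dtype=float)
    answered: set[int] = set()
    for c in closures:
        k = int(np.searchsorted(strikes, c, side="right")) - 1
        if k >= 0 and c - strikes[k] <= sync_window_s:
            answered.add(k)
    return len(answered) / len(strikes)


@dataclass
class ComparisonResult:
    """Mixed-model treatment comparison: per-factor Wald F tests and
    Tukey-adjusted pairwise treatment contrasts."""

    factor_tests: pd.DataFrame
    tukey: pd.DataFrame
    model_params: pd.Series
    df_resid: float


def compare_treatments(
    rates: pd.DataFrame,
    response: str = "partial_closure_per_min",
    fixed: tuple[str, ...] = ("site", "stage", "treatment"),
    contrast_factor: str = "treatment",
) -> ComparisonResult:
    """Fit ``response ~ fixed effects`` with a random intercept per
    individual and compare all pairs of ``contrast_factor`` levels.

    F statistics are Wald chi-square tests divided by their numerator df;
    the denominator df reported is the residual df (observations minus
    fixed-effect parameters).  Pairwise contrasts are Tukey-adjusted via the
    studentized-range distribution, emmeans-style.
    """
    import statsmodels.formula.api as smf

    fixed = [f for f in fixed if f in rates.columns]
    for f in fixed:
        if rates[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    if contrast_factor not in fixed:
        raise ValueError(f"contrast factor {contrast_factor!r} not among fixed effects")
    if response not in rates.columns:
        raise ValueError(f"response column {response!r} not found")

    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in fixed)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, rates, groups=rates["subject"])
        for method in ("lbfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(cand.llf):
                res = cand
                break
    if res is None:
        raise RuntimeError("mixed model failed to fit (possibly a "
                           "rank-deficient design)")

    fe_names = list(res.fe_params.index)
    k_fe = len(fe_names)
    n = len(rates)
    df_resid = float(n - k_fe)
    cov = res.cov_params().iloc[:k_fe, :k_fe]

    # per-factor Wald F: chi2 = b' Cov_bb^{-1} b on the factor's coefficients
    from scipy.stats import f as f_dist
    frows = []
    for f in fixed:
        idx = [i for i, nm in enumerate(fe_names) if nm.startswith(f"C({f})")]
        if not idx:
            continue
        b = res.fe_params.to_numpy()[idx]
        V = cov.to_numpy()[np.ix_(idx, idx)]
        chi2_stat = float(b @ np.linalg.solve(V, b))
        df_num = len(idx)
        F = chi2_stat / df_num
        frows.append({"factor": f, "F": F, "df_num": df_num,
                      "df_den": df_resid,
                      "p_value": float(f_dist.sf(F, df_num, df_resid))})
    factor_tests = pd.DataFrame(frows)

    # Tukey pairwise contrasts on the contrast factor (additive model:
    # level effects are the dummy coefficients, baseline = 0)
    levels = sorted(rates[contrast_factor].unique())
    coef = {levels[0]: 0.0}
    pos = {levels[0]: None}
    for lv in levels[1:]:
        nm = f"C({contrast_factor})[T.{lv}]"
        if nm not in fe_names:
            raise ValueError(f"rank-deficient design: missing coefficient {nm}")
        coef[lv] = float(res.fe_params[nm])
        pos[lv] = fe_names.index(nm)
    k = len(levels)
    trows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            est = coef[a] - coef[b]
            var = 0.0
            if pos[a] is not None:
                var += cov.iloc[pos[a], pos[a]]
            if pos[b] is not None:
                var += cov.iloc[pos[b], pos[b]]
            if pos[a] is not None and pos[b] is not None:
                var -= 2.0 * cov.iloc[pos[a], pos[b]]
            se = float(np.sqrt(var))
            tval = abs(est) / se if se > 0 else np.inf
            p_raw = float(2.0 * t_dist.sf(tval, df_resid))
            p_tukey = float(studentized_range.sf(np.sqrt(2.0) * tval, k, df_resid))
            trows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                          "t": tval, "p_raw": p_raw,
                          "p_tukey": min(1.0, p_tukey)})
    return ComparisonResult(factor_tests=factor_tests, tukey=pd.DataFrame(trows),
                            model_params=res.fe_params, df_resid=df_resid)
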