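"""Group-statistics layer: gated t-tests, ANOVA + Tukey HSD, GLM lsmeans.

Three entry points used across the pipeline:

* :func:`t_test_gated` — the fractional-area comparison: Shapiro–Wilk
  normality and Levene equal-variance gates recorded, then a pooled-variance
  one-sided two-sample t-test.
* :func:`anova_tukey` — the respirometry comparison: one-way ANOVA with
  Tukey HSD post-hoc pairwise p-values (studentized-range distribution).
* :func:`fit_group_model` — the morphometry comparison: fixed-effects GLM
  (Poisson/Gamma/Gaussian, log or identity link) over group × cell-type
  cells, fitted on section-level aggregates, producing least-squares means
  on the link scale, all pairwise contrasts with Tukey-style adjustment,
  and back-transformed response-scale means. Nesting of sections within
  animals is honored by aggregating to sections and bootstrapping animal
  clusters for contrast uncertainty, rather than by an explicit
  random-effects fit; lsmean point estimates agree in balanced designs.

Counts are modeled as Poisson with a log(cell-area) offset, so their
lsmeans are log-densities; sizes as Gamma with log link, so their lsmeans
back-transform by exponentiation to mean sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GatedTTestResult",
    "AnovaTukeyResult",
    "GroupComparison",
    "t_test_gated",
    "anova_tukey",
    "fit_group_model",
    "backtransform_lsmean",
]


# --------------------------------------------------------------------------
# gated two-sample t-test

@dataclass
class GatedTTestResult:
    statistic: float
    pvalue: float
    side: str
    shapiro_p: tuple[float, float]
    levene_p: float
    normality_ok: bool
    equal_variance_ok: bool
    significant: bool
    note: str | None = None


def t_test_gated(
    a: np.ndarray,
    b: np.ndarray,
    side: str,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
) -> GatedTTestResult:
    """One-sided pooled-variance two-sample t-test with distributional gates.

    ``side="greater"`` tests mean(a) > mean(b); ``"less"`` the reverse.
    Shapiro–Wilk is run on each sample and Levene across both; the gate
    outcomes are recorded (a gate failure flags, it does not abort — the
    caller decides whether a non-parametric fallback is warranted).
    Two zero-variance samples with equal means yield p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")

    note = None
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        sh = (np.nan, np.nan)
        lev = np.nan
        if a[0] == b[0]:
            t_stat, p = 0.0, 1.0
            note = "both samples constant and equal; p = 1 by convention"
        else:
            t_stat = np.inf if (a[0] > b[0]) == (side == "greater") else -np.inf
            p = 0.0 if t_stat > 0 else 1.0
            note = "both samples constant; degenerate t"
    else:
        sh = (
            float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else np.nan,
            float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else np.nan,
        )
        lev = float(sps.levene(a, b).pvalue)
        res = sps.ttest_ind(a, b, equal_var=True, alternative=side)
        t_stat, p = float(res.statistic), float(res.pvalue)

    normality_ok = bool(np.all(np.nan_to_num(np.array(sh), nan=1.0) >= gate_alpha))
    equal_var_ok = bool(np.nan_to_num(lev, nan=1.0) >= gate_alpha)
    return GatedTTestResult(
        statistic=t_stat,
        pvalue=p,
        side=side,
        shapiro_p=sh,
        levene_p=lev,
        normality_ok=normality_ok,
        equal_variance_ok=equal_var_ok,
        significant=p < alpha,
        note=note,
    )


# --------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD

@dataclass
class AnovaTukeyResult:
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group1, group2, diff, p_adj
    degenerate: bool = False
    note: str | None = None


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA across named groups with Tukey HSD pairwise p-values."""
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 observations per group")

    pooled_var = np.concatenate([s - s.mean() for s in samples]).var()
    pairs = list(itertools.combinations(range(len(names)), 2))
    if pooled_var == 0:
        means = [s.mean() for s in samples]
        all_equal = np.ptp(means) == 0
        pairwise = pd.DataFrame(
            [
                {
                    "group1": names[i],
                    "group2": names[j],
                    "diff": means[i] - means[j],
                    "p_adj": 1.0 if means[i] == means[j] else 0.0,
                }
                for i, j in pairs
            ]
        )
        return AnovaTukeyResult(
            statistic=0.0 if all_equal else np.inf,
            pvalue=1.0 if all_equal else 0.0,
            pairwise=pairwise,
            degenerate=True,
            note="zero within-group variance",
        )

    f_res = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    pairwise = pd.DataFrame(
        [
            {
                "group1": names[i],
                "group2": names[j],
                "diff": samples[i].mean() - samples[j].mean(),
                "p_adj": float(hsd.pvalue[i, j]),
            }
            for i, j in pairs
        ]
    )
    return AnovaTukeyResult(
        statistic=float(f_res.statistic),
        pvalue=float(f_res.pvalue),
        pairwise=pairwise,
    )


# --------------------------------------------------------------------------
# GLM group-mean model with lsmeans and contrasts

_FAMILIES = {
    "poisson_log": lambda: sm.families.Poisson(sm.families.links.Log()),
    "gamma_log": lambda: sm.families.Gamma(sm.families.links.Log()),
    "gaussian": lambda: sm.families.Gaussian(sm.families.links.Identity()),
}


@dataclass
class GroupComparison:
    """lsmeans (link scale), their SEs, pairwise contrasts, back-transforms."""

    lsmeans: pd.Series
    lsmean_se: pd.Series
    contrasts: pd.DataFrame  # columns: contrast, estimate, se, z, p_adj
    back_transformed: pd.Series
    family: str
    link: str
    n_boot: int = 0
    missing_cells: list[str] = field(default_factory=list)


def _aggregate_sections(
    data: pd.DataFrame, value: str, offset_area: str | None, family: str
) -> pd.DataFrame:
    """Collapse images to section-level rows (counts summed, sizes averaged)."""
    keys = [k for k in ("group", "cell_type", "animal_id", "section_id") if k in data]
    if "group" not in keys or "cell_type" not in keys:
        raise ValueError("data must have 'group' and 'cell_type' columns")
    if "section_id" not in keys:  # already aggregated or unstructured input
        return data.copy()
    agg = {value: "sum" if family == "poisson_log" else "mean"}
    if offset_area:
        agg[offset_area] = "sum"
    return data.groupby(keys, as_index=False).agg(agg)


def _fit_cells(
    df: pd.DataFrame, value: str, offset_area: str | None, family: str
) -> tuple[pd.Series, pd.Series]:
    """Fit a no-intercept cell-means GLM; return lsmeans and their SEs."""
    cells = df["group"].astype(str) + ":" + df["cell_type"].astype(str)
    X = pd.get_dummies(cells, dtype=float)
    offset = np.log(df[offset_area].to_numpy(dtype=float)) if offset_area else None
    model = sm.GLM(
        df[value].to_numpy(dtype=float),
        X.to_numpy(),
        family=_FAMILIES[family](),
        offset=offset,
    )
    fit = model.fit()
    return (
        pd.Series(fit.params, index=X.columns),
        pd.Series(fit.bse, index=X.columns),
    )


def fit_group_model(
    data: pd.DataFrame,
    family: str = "poisson_log",
    value: str = "value",
    offset_area: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Fit the fixed-effects group × cell-type model and derive lsmeans/contrasts.

    ``data`` is tidy with columns ``value``, ``group``, ``cell_type`` and
    optionally ``animal_id``, ``section_id`` (nesting) and an area column
    for the Poisson offset (then lsmeans are log-densities per area unit).
    Images are aggregated to sections before fitting; when ``n_boot > 0``
    and an ``animal_id`` column is present, contrast standard errors come
    from an animal-level cluster bootstrap (resampling animals with
    replacement within each group), otherwise from the GLM covariance.
    Pairwise contrast p-values use a Tukey-style studentized-range
    adjustment over all cells (asymptotic df).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {sorted(_FAMILIES)}")
    if family == "poisson_log":
        vals = data[value].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("poisson_log expects integer counts")

    df = _aggregate_sections(data, value, offset_area, family)
    lsmeans, lsmean_se = _fit_cells(df, value, offset_area, family)
    cell_names = list(lsmeans.index)
    k = len(cell_names)
    if k < 2:
        raise ValueError("need >= 2 design cells")

    expected = {
        f"{g}:{c}"
        for g in data["group"].astype(str).unique()
        for c in data["cell_type"].astype(str).unique()
    }
    missing = sorted(expected - set(cell_names))

    pairs = list(itertools.combinations(cell_names, 2))

    boot_se: dict[tuple[str, str], float] = {}
    if n_boot > 0 and "animal_id" in df:
        rng = np.random.default_rng(seed)
        animals_by_group = {
            g: sub["animal_id"].unique() for g, sub in df.groupby("group")
        }
        reps: list[pd.Series] = []
        for _ in range(n_boot):
            parts = []
            for g, animals in animals_by_group.items():
                chosen = rng.choice(animals, size=len(animals), replace=True)
                for rep_id, a in enumerate(chosen):
                    part = df[(df["group"] == g) & (df["animal_id"] == a)].copy()
                    part["animal_id"] = f"{a}#rep{rep_id}"
                    parts.append(part)
            bdf = pd.concat(parts, ignore_index=True)
            try:
                b_ls, _ = _fit_cells(bdf, value, offset_area, family)
            except Exception:
                continue
            reps.append(b_ls)
        if reps:
            boot = pd.DataFrame(reps)
            for c1, c2 in pairs:
                if c1 in boot and c2 in boot:
                    diffs = (boot[c1] - boot[c2]).dropna()
                    if len(diffs) >= 10:
                        boot_se[(c1, c2)] = float(diffs.std(ddof=1))

    rows = []
    for c1, c2 in pairs:
        est = float(lsmeans[c1] - lsmeans[c2])
        se = boot_se.get(
            (c1, c2), float(np.hypot(lsmean_se[c1], lsmean_se[c2]))
        )
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        p = float(sps.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
        rows.append(
            {"contrast": f"{c1} - {c2}", "estimate": est, "se": se, "z": z, "p_adj": p}
        )

    link = "identity" if family == "gaussian" else "log"
    return GroupComparison(
        lsmeans=lsmeans,
        lsmean_se=lsmean_se,
        contrasts=pd.DataFrame(rows),
        back_transformed=lsmeans.map(lambda v: backtransform_lsmean(v, link)),
        family=family,
        link=link,
        n_boot=n_boot,
        missing_cells=missing,
    )


def backtransform_lsmean(lsmean: float, link: str = "log") -> float:
    """Map a link-scale least-squares mean back to the response scale."""
    if link == "log":
        return float(np.exp(lsmean))
    if link == "identity":
        return float(lsmean)
    raise ValueError("link must be 'log' or 'identity'")
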