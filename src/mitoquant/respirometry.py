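"""SUIT high-resolution respirometry: per-state O2 flows and efficiency metrics.

A SUIT (substrate–uncoupler–inhibitor titration) run on permeabilized
cells steps through defined respiratory states by sequential injection:

====================  =====================================================
state                 condition
====================  =====================================================
Ce                    intact basal cellular respiration (pre-digitonin)
CI_L                  complex I leak (pyruvate + malate, no ADP)
CI_P                  complex I OXPHOS (+ADP)
CIcytc                CI_P after exogenous cytochrome c (membrane QC)
CIplusCII_P           combined CI+CII OXPHOS (+succinate)
CII_P                 complex II OXPHOS (+rotenone, CI inhibited)
CII_E                 CII uncoupled / electron-transfer capacity (+FCCP)
====================  =====================================================

Flows are O2 consumption per cell, positive, in pmol·s⁻¹·(10⁶ cells)⁻¹,
obtained as minus the least-squares slope of the O2 concentration over the
trailing part of each inter-injection segment, scaled to the chamber cell
content. A sample whose respiration rises by more than 10% after the
cytochrome-c injection has a damaged outer membrane and is excluded.

Derived efficiency metrics (dimensionless unless noted):

* relative CI contribution  = CI_P / CI+CII_P
* relative CII contribution = CII_P / CI+CII_P
* CI coupling efficiency    = 1 − CI_L / CI_P
* % flow change on ADP      = (CI_P − Ce)·100 / Ce
* % flow change on succinate = (CI+CII_P − CI_P)·100 / CI_P

The measured combined state is used as the denominator of the relative
contributions: CI and CII capacities are not additive, so CI_P + CII_P
typically exceeds the measured CI+CII_P and the two relative contributions
may jointly exceed 1. A ``literal_sum`` flag computes the arithmetic-sum
variant for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "SUIT_EVENT_ORDER",
    "SUITExperiment",
    "SUITFlows",
    "RespMetrics",
    "extract_flows",
    "cytc_quality_check",
    "derived_metrics",
    "group_compare",
]

#: canonical injection order of the protocol
SUIT_EVENT_ORDER = (
    "digitonin",
    "pyruvate",
    "malate",
    "ADP",
    "cytc",
    "succinate",
    "rotenone",
    "FCCP",
)

#: respiratory state measured in the segment that *ends* at the named injection
#: (i.e. the steady state reached after the previous injections); FCCP segments
#: run to the end of the trace.
_STATE_SEGMENTS = {
    "Ce": (None, "digitonin"),
    "CI_L": ("malate", "ADP"),
    "CI_P": ("ADP", "cytc"),
    "CIcytc": ("cytc", "succinate"),
    "CIplusCII_P": ("succinate", "rotenone"),
    "CII_P": ("rotenone", "FCCP"),
    "CII_E": ("FCCP", None),
}


@dataclass
class SUITExperiment:
    """One chamber run: O2 trace, injection events, and normalization info.

    ``trace`` has columns ``time_s`` (strictly increasing) and ``o2_conc``
    (nmol/mL). ``events`` has ``time_s`` and ``label`` drawn from
    :data:`SUIT_EVENT_ORDER`; each label at most once except FCCP, which may
    repeat (titration steps). ``cell_count`` is the chamber cell density in
    10⁶ cells/mL; ``chamber_volume`` in mL.
    """

    trace: pd.DataFrame
    events: pd.DataFrame
    cell_count: float
    chamber_volume: float = 2.1
    cell_type: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.trace["time_s"], dtype=float)
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("trace time must be strictly increasing")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be > 0")
        labels = list(self.events["label"])
        unknown = set(labels) - set(SUIT_EVENT_ORDER)
        if unknown:
            raise ValueError(f"unknown event labels: {sorted(unknown)}")
        non_fccp = [l for l in labels if l != "FCCP"]
        if len(set(non_fccp)) != len(non_fccp):
            raise ValueError("every protocol label except FCCP may appear at most once")

    def event_time(self, label: str) -> float | None:
        hit = self.events.loc[self.events["label"] == label, "time_s"]
        return float(hit.iloc[0]) if len(hit) else None


@dataclass
class SUITFlows:
    """Per-state O2 flows (pmol·s⁻¹·10⁻⁶ cells, consumption positive)."""

    Ce: float | None = None
    CI_L: float | None = None
    CI_P: float | None = None
    CIcytc: float | None = None
    CIplusCII_P: float | None = None
    CII_P: float | None = None
    CII_E: float | None = None
    qc_pass: bool | None = None
    qc_reason: str | None = None
    cell_type: str | None = None
    sample_id: str | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {s: getattr(self, s) for s in _STATE_SEGMENTS}


@dataclass
class RespMetrics:
    """Derived relative-efficiency metrics; missing entries carry a reason."""

    rel_CI: float | None = None
    rel_CII: float | None = None
    coupling_CI: float | None = None
    pct_change_ADP: float | None = None
    pct_change_succinate: float | None = None
    missing: dict[str, str] = field(default_factory=dict)
    cell_type: str | None = None
    sample_id: str | None = None


def _segment_slope(
    t: np.ndarray, y: np.ndarray, lo: float, hi: float, fraction: float
) -> float | None:
    """Least-squares slope over the trailing ``fraction`` of [lo, hi)."""
    window_lo = hi - fraction * (hi - lo)
    sel = (t >= window_lo) & (t < hi)
    if sel.sum() < 5:
        return None
    coeffs = np.polynomial.polynomial.polyfit(t[sel], y[sel], 1)
    return float(coeffs[1])


def extract_flows(
    exp: SUITExperiment, fraction: float = 0.5
) -> SUITFlows:
    """Extract per-state O2 flows from an experiment.

    For each state the O2 slope is fitted over the trailing ``fraction``
    of the corresponding inter-injection segment (steady-state window; the
    first part of a segment is contaminated by mixing after the injection).
    Flow per 10⁶ cells is −slope × 1000 / cell_count, equivalently
    −slope × 1000 × chamber_volume / (cell_count × chamber_volume): the
    chamber volume cancels because both the O2 amount and the cell content
    scale with it. Missing injections leave the corresponding flows None.
    With repeated FCCP titration steps, CII_E is the maximum flow over the
    FCCP segments.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    t = np.asarray(exp.trace["time_s"], dtype=float)
    y = np.asarray(exp.trace["o2_conc"], dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    t_start, t_end = float(t[0]), float(t[-1]) + 1e-9

    def to_flow(slope: float | None) -> float | None:
        if slope is None:
            return None
        return -slope * 1000.0 / exp.cell_count

    event_times = sorted(exp.events["time_s"].astype(float))

    def next_event_after(lo: float) -> float:
        later = [et for et in event_times if et > lo]
        return later[0] if later else t_end

    flows = SUITFlows(cell_type=exp.cell_type, sample_id=exp.sample_id)
    for state, (after, _before) in _STATE_SEGMENTS.items():
        if state == "CII_E":
            continue
        lo = t_start if after is None else exp.event_time(after)
        if lo is None:
            continue  # defining injection absent: state not reached
        hi = next_event_after(lo)  # state persists until the next injection
        if hi <= lo:
            continue
        setattr(flows, state, to_flow(_segment_slope(t, y, lo, hi, fraction)))

    fccp_times = sorted(exp.events.loc[exp.events["label"] == "FCCP", "time_s"].astype(float))
    if fccp_times:
        bounds = fccp_times + [t_end]
        step_flows = [
            f
            for lo, hi in zip(bounds, bounds[1:])
            if (f := to_flow(_segment_slope(t, y, lo, hi, fraction))) is not None
        ]
        if step_flows:
            flows.CII_E = max(step_flows)

    if flows.CI_P is not None and flows.CIcytc is not None:
        cytc_quality_check(flows)
    return flows


def cytc_quality_check(flows: SUITFlows, max_increase: float = 0.10) -> bool:
    """Outer-membrane integrity check after the cytochrome-c injection.

    A relative flow increase strictly greater than ``max_increase``
    (default 10%) means cytochrome c leaked into a damaged mitochondrial
    preparation; the sample fails QC and is excluded downstream. Exactly
    +10% passes. Sets ``qc_pass``/``qc_reason`` on ``flows`` and returns
    the verdict.
    """
    if flows.CI_P is None or flows.CIcytc is None:
        raise ValueError("cytc_quality_check requires both CI_P and CIcytc flows")
    if flows.CI_P == 0:
        flows.qc_pass = False
        flows.qc_reason = "CI_P is zero; relative cytochrome-c increase undefined"
        return False
    increase = (flows.CIcytc - flows.CI_P) / flows.CI_P
    flows.qc_pass = increase <= max_increase
    if not flows.qc_pass:
        flows.qc_reason = (
            f"respiration rose {increase:.1%} after cytochrome c (> {max_increase:.0%})"
        )
    return flows.qc_pass


def derived_metrics(flows: SUITFlows, literal_sum: bool = False) -> RespMetrics:
    """Compute the relative-efficiency metrics from per-state flows.

    Requires QC pass (if a cytochrome-c check was recorded). By default the
    relative CI/CII contributions are taken against the measured combined
    CI+CII OXPHOS state; ``literal_sum=True`` divides by the arithmetic sum
    CI_P + CII_P instead. Metrics whose inputs are missing or whose
    denominator is zero are left None with a reason in ``missing``.
    """
    if flows.qc_pass is False:
        raise ValueError(f"sample failed cytochrome-c QC: {flows.qc_reason}")
    m = RespMetrics(cell_type=flows.cell_type, sample_id=flows.sample_id)

    denom = None
    if literal_sum:
        if flows.CI_P is not None and flows.CII_P is not None:
            denom = flows.CI_P + flows.CII_P
    else:
        denom = flows.CIplusCII_P

    def ratio(num: float | None, den: float | None, what: str) -> float | None:
        if num is None or den is None:
            m.missing[what] = "required flow missing"
            return None
        if den == 0:
            m.missing[what] = "zero denominator"
            return None
        return num / den

    m.rel_CI = ratio(flows.CI_P, denom, "rel_CI")
    m.rel_CII = ratio(flows.CII_P, denom, "rel_CII")
    leak_ratio = ratio(flows.CI_L, flows.CI_P, "coupling_CI")
    m.coupling_CI = None if leak_ratio is None else 1.0 - leak_ratio
    adp = ratio(
        None if flows.CI_P is None or flows.Ce is None else flows.CI_P - flows.Ce,
        flows.Ce,
        "pct_change_ADP",
    )
    m.pct_change_ADP = None if adp is None else adp * 100.0
    suc = ratio(
        None
        if flows.CIplusCII_P is None or flows.CI_P is None
        else flows.CIplusCII_P - flows.CI_P,
        flows.CI_P,
        "pct_change_succinate",
    )
    m.pct_change_succinate = None if suc is None else suc * 100.0
    return m


def group_compare(
    metrics: dict[str, list[float]] | pd.DataFrame,
    metric: str | None = None,
) -> "_stats.AnovaTukeyResult":
    """One-way ANOVA with Tukey HSD post-hoc comparison across cell types.

    ``metrics`` is either a mapping group name → list of metric values, or
    a tidy DataFrame with columns ``cell_type`` and the metric named by
    ``metric``. Delegates to :func:`mitoquant.stats.anova_tukey`.
    """
    if isinstance(metrics, pd.DataFrame):
        if metric is None:
            raise ValueError("metric column name required with a DataFrame input")
        groups = {
            str(g): sub[metric].dropna().to_numpy()
            for g, sub in metrics.groupby("cell_type")
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in metrics.items()}
    return _stats.anova_tukey(groups)
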