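"""Phase-resolved group statistics on the tidy feature table.

Spectral-trajectory metrics (F_mean/F_median from STFT or CWT) are compared
with one-way ANOVA followed, when significant, by Tukey-Kramer pairwise
comparisons (studentized range, valid for unequal group sizes).  IMF-derived
metric pairs (mean instantaneous frequency, mean instantaneous energy) are
gated by a one-way MANOVA (Wilks' lambda with Rao's F approximation); the
follow-up per-variable ANOVAs are corrected over the whole battery family
with the step-down Holm-Bonferroni procedure (plain Bonferroni available),
and post hoc comparisons run only where the adjusted ANOVA survives.

The observation unit is the individual contraction by default (large-n,
pseudo-replication accepted); ``unit="subject"`` aggregates to per-subject
means for a conservative analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "StatResult",
    "anova_tukey",
    "manova_pairs",
    "holm_adjust",
    "bonferroni_adjust",
    "run_stat_battery",
]

ALPHA_DEFAULT = 0.05


@dataclass
class StatResult:
    """Outcome of one test: statistic, dof, p-values and pairwise contrasts."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    significant: bool
    pairwise: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _select(
    table: pd.DataFrame, metric: str, source: str, phase: str, unit: str
) -> pd.DataFrame:
    sel = table[
        (table["metric"] == metric)
        & (table["source"] == source)
        & (table["phase"] == phase)
    ].dropna(subset=["value"])
    if unit == "subject":
        sel = (
            sel.groupby(["group", "subject"], as_index=False)["value"].mean()
        )
    elif unit != "burst":
        raise ValueError(f"unknown observation unit: {unit!r}")
    return sel


def _grouped_values(sel: pd.DataFrame) -> tuple[list[str], list[np.ndarray]]:
    names, arrays = [], []
    for g, sub in sel.groupby("group", sort=True):
        v = sub["value"].to_numpy(dtype=float)
        if v.size < 2:
            warnings.warn(f"group {g!r} has < 2 observations; dropped", stacklevel=3)
            continue
        names.append(str(g))
        arrays.append(v)
    return names, arrays


def anova_tukey(
    table: pd.DataFrame,
    metric: str,
    source: str,
    phase: str,
    alpha: float = ALPHA_DEFAULT,
    unit: str = "burst",
) -> StatResult:
    """One-way fixed-effects ANOVA with Tukey-Kramer post hoc contrasts.

    The full pairwise table is returned either way; ``significant`` flags
    whether the omnibus ANOVA gated the post hoc test at ``alpha``.
    """
    sel = _select(table, metric, source, phase, unit)
    names, arrays = _grouped_values(sel)
    if len(names) < 2:
        raise ValueError(
            f"need >= 2 groups with >= 2 observations for {source}/{metric}/{phase}"
        )
    f_stat, p = sstats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    hsd = sstats.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p": float(hsd.pvalue[i, j]),
                }
            )
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p"])
    return StatResult(
        test="anova",
        statistic=float(f_stat),
        df=(float(k - 1), float(n - k)),
        p_value=float(p),
        significant=bool(p < alpha),
        pairwise=pairwise,
    )


def manova_pairs(
    table: pd.DataFrame,
    source: str,
    phase: str,
    metrics: tuple[str, str] = ("inst_freq_mean", "inst_energy_mean"),
    alpha: float = ALPHA_DEFAULT,
    unit: str = "burst",
    statistic: str = "wilks",
) -> StatResult:
    """One-way MANOVA on a bivariate metric response.

    Both metrics must be present for the same (subject, burst) keys.
    ``statistic`` selects Wilks' lambda (Rao's F approximation, exact for two
    response variables; default) or Pillai's trace.
    """
    frames = []
    for m in metrics:
        sel = _select(table, m, source, phase, unit)
        key = ["group", "subject"] if unit == "subject" else ["group", "subject", "burst_id"]
        frames.append(sel.set_index(key)["value"].rename(m))
    wide = pd.concat(frames, axis=1).dropna()
    if wide.empty:
        raise ValueError(f"no paired observations for {source}/{phase}")
    y = wide.to_numpy(dtype=float)
    groups = wide.index.get_level_values("group").to_numpy()
    if statistic == "wilks":
        return _wilks_manova(y, groups, alpha, metrics)
    if statistic == "pillai":
        return _pillai_manova(y, groups, alpha, metrics)
    raise ValueError("statistic must be 'wilks' or 'pillai'")


def _scatter_matrices(
    y: np.ndarray, groups: np.ndarray, metric_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, int, int, int]:
    """Between-group (H) and within-group (E) scatter matrices."""
    names = np.unique(groups)
    k, n, p = names.size, y.shape[0], y.shape[1]
    if k < 2:
        raise ValueError("MANOVA needs >= 2 groups")
    grand = y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in names:
        sub = y[groups == g]
        d = sub.mean(axis=0) - grand
        H += sub.shape[0] * np.outer(d, d)
        r = sub - sub.mean(axis=0)
        E += r.T @ r
    diag = np.diag(E)
    if np.any(diag <= 0):
        bad = metric_names[int(np.argmin(diag))]
        raise ValueError(f"singular within-group covariance: metric {bad!r} has no variance")
    if np.linalg.matrix_rank(E) < p:
        raise ValueError("singular within-group covariance matrix")
    return H, E, k, n, p


def _pillai_manova(
    y: np.ndarray, groups: np.ndarray, alpha: float, metric_names: tuple[str, ...]
) -> StatResult:
    """One-way MANOVA via Pillai's trace V = tr(H (H + E)^-1)."""
    H, E, k, n, p = _scatter_matrices(y, groups, metric_names)
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p, k - 1)
    m = (abs(p - k + 1) - 1) / 2.0
    n2 = (n - k - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n2 + s + 1)
    V = min(V, s * (1.0 - 1e-12))
    f_stat = (df2 / df1) * V / (s - V)
    p_val = float(sstats.f.sf(f_stat, df1, df2))
    if V <= 1e-12:
        p_val = 1.0
    return StatResult(
        test="manova",
        statistic=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=p_val,
        significant=bool(p_val < alpha),
        extras={"pillai_trace": V},
    )


def _wilks_manova(
    y: np.ndarray, groups: np.ndarray, alpha: float, metric_names: tuple[str, ...]
) -> StatResult:
    H, E, k, n, p = _scatter_matrices(y, groups, metric_names)
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    nu_h, nu_e = k - 1, n - k
    denom = p**2 + nu_h**2 - 5
    t = np.sqrt((p**2 * nu_h**2 - 4) / denom) if denom > 0 else 1.0
    w = nu_e + nu_h - (p + nu_h + 1) / 2.0
    df1 = p * nu_h
    df2 = w * t - (p * nu_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1 - lam_t) / lam_t * (df2 / df1) if lam_t > 0 else np.inf
    p_val = float(sstats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    # label-permuted identical groups give lambda == 1 -> p == 1
    if lam >= 1.0 - 1e-12:
        p_val = 1.0
    return StatResult(
        test="manova",
        statistic=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=p_val,
        significant=bool(p_val < alpha),
        extras={"wilks_lambda": lam},
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, order-equivariant.

    Sort ascending, multiply p_(i) by (m - i), enforce monotone non-decrease
    with a running maximum, cap at 1, restore original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bonferroni_adjust(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p.size * p, 1.0)


TRAJECTORY_METRICS = ("f_mean", "f_median")
IMF_METRICS = ("inst_freq_mean", "inst_energy_mean")


def run_stat_battery(
    table: pd.DataFrame,
    sources: list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    correction: str = "holm",
    unit: str = "burst",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full comparison battery over a feature table.

    Trajectory sources (anything not named ``imf<k>``): ANOVA + Tukey per
    metric and phase, no multiplicity correction across phases.  IMF sources:
    a MANOVA gate per (imf, phase), then one family of per-variable ANOVAs
    across all imf x phase x metric cells corrected by Holm (or Bonferroni),
    with post hoc Tukey contrasts only where the gate passed and the adjusted
    ANOVA p < alpha.

    Returns (summary, pairwise) tidy frames.
    """
    if correction not in ("holm", "bonferroni"):
        raise ValueError("correction must be 'holm' or 'bonferroni'")
    adjust = holm_adjust if correction == "holm" else bonferroni_adjust
    if sources is None:
        sources = sorted(table["source"].unique())
    phases = [p for p in ("recruitment", "sustained", "derecruitment")
              if p in set(table["phase"])]

    summary_rows: list[dict] = []
    pairwise_rows: list[dict] = []

    def _emit_pairwise(res: StatResult, source: str, metric: str, phase: str) -> None:
        for r in res.pairwise.itertuples():
            pairwise_rows.append(
                {
                    "source": source,
                    "metric": metric,
                    "phase": phase,
                    "group1": r.group1,
                    "group2": r.group2,
                    "mean_diff": r.mean_diff,
                    "p": r.p,
                }
            )

    traj_sources = [s for s in sources if not s.startswith("imf")]
    imf_sources = [s for s in sources if s.startswith("imf")]

    for source in traj_sources:
        if source not in set(table["source"]):
            continue  # missing source: skipped
        for metric in TRAJECTORY_METRICS:
            for phase in phases:
                cell = _select(table, metric, source, phase, unit)
                if cell.empty:
                    warnings.warn(
                        f"no observations for {source}/{metric}/{phase}; skipped",
                        stacklevel=2,
                    )
                    continue
                res = anova_tukey(table, metric, source, phase, alpha, unit)
                summary_rows.append(
                    {
                        "source": source,
                        "metric": metric,
                        "phase": phase,
                        "test": "anova",
                        "statistic": res.statistic,
                        "p_raw": res.p_value,
                        "p_adj": res.p_value,
                        "gate": res.significant,
                    }
                )
                if res.significant:
                    _emit_pairwise(res, source, metric, phase)

    # IMF battery: MANOVA gates, then one Holm family of univariate ANOVAs
    gates: dict[tuple[str, str], bool] = {}
    anova_cells: list[tuple[str, str, str, StatResult]] = []
    for source in imf_sources:
        if source not in set(table["source"]):
            continue
        for phase in phases:
            cell = table[(table["source"] == source) & (table["phase"] == phase)]
            if cell["value"].dropna().empty:
                warnings.warn(f"no observations for {source}/{phase}; skipped",
                              stacklevel=2)
                continue
            gate = manova_pairs(table, source, phase, IMF_METRICS, alpha, unit)
            gates[(source, phase)] = gate.significant
            summary_rows.append(
                {
                    "source": source,
                    "metric": "+".join(IMF_METRICS),
                    "phase": phase,
                    "test": "manova",
                    "statistic": gate.statistic,
                    "p_raw": gate.p_value,
                    "p_adj": gate.p_value,
                    "gate": gate.significant,
                }
            )
            for metric in IMF_METRICS:
                res = anova_tukey(table, metric, source, phase, alpha, unit)
                anova_cells.append((source, phase, metric, res))

    if anova_cells:
        adj = adjust([c[3].p_value for c in anova_cells])
        for (source, phase, metric, res), p_adj in zip(anova_cells, adj):
            passed = gates[(source, phase)] and p_adj < alpha
            summary_rows.append(
                {
                    "source": source,
                    "metric": metric,
                    "phase": phase,
                    "test": "anova",
                    "statistic": res.statistic,
                    "p_raw": res.p_value,
                    "p_adj": float(p_adj),
                    "gate": passed,
                }
            )
            if passed:
                _emit_pairwise(res, source, metric, phase)

    summary = pd.DataFrame(
        summary_rows,
        columns=["source", "metric", "phase", "test", "statistic", "p_raw", "p_adj", "gate"],
    )
    pairwise = pd.DataFrame(
        pairwise_rows,
        columns=["source", "metric", "phase", "group1", "group2", "mean_diff", "p"],
    )
    return summary, pairwise
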