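"""In vivo PK/PD statistics for GalNAc-siRNA time courses.

Covers the analysis battery applied to liver-directed siRNA studies:

* pre-dose normalization of per-animal series;
* semilog EC fits — knockdown (%) against log10 Ago2-loaded antisense
  strand (ng/g liver), with EC50/EC80 by inversion of the fitted line;
* extra-sum-of-squares F-test asking whether per-group semilog lines beat a
  single pooled line;
* baseline-100 AUC of % -of-control time courses with the 10% peak-ignore
  rule and |area| counting of below-baseline excursions;
* recovery-phase slope comparison (per-group linear regressions, equality
  tested via the interaction term of the pooled two-line model);
* two-way ANOVA (time x design) with Dunnett or Sidak post-tests, Dunnett
  critical values by seeded Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .positional import ALPHA, fit_ols

__all__ = [
    "ECFit",
    "StatTestResult",
    "ECUndefinedError",
    "normalize_to_predose",
    "SemilogECModel",
    "fit_semilog_ec",
    "ess_f_test",
    "auc_vs_baseline",
    "recovery_slope_compare",
    "anova2_posttests",
    "sidak_adjust",
]

#: default recovery-regression window (days post-dose), endpoints inclusive
RECOVERY_WINDOW = (29.0, 71.0)


class ECUndefinedError(ValueError):
    """Fitted slope is (numerically) zero; EC values are undefined."""


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    df_num: float
    df_den: float
    p: float
    significant: bool

    @classmethod
    def from_fp(cls, stat, df_num, df_den, p, alpha=ALPHA):
        return cls(float(stat), float(df_num), float(df_den), float(p),
                   bool(p < alpha))


@dataclass(frozen=True)
class ECFit:
    """Semilog line knockdown% = a + b*log10(loading) and derived ECs."""

    a: float  # % knockdown at 1 ng/g
    b: float  # % knockdown per log10(ng/g)
    residual_ss: float
    df: int
    ec50: float
    ec80: float
    ec50_extrapolated: bool
    ec80_extrapolated: bool

    def ec(self, pct: float) -> float:
        """Loading (ng/g) at which the fitted line reaches ``pct`` % knockdown."""
        return 10.0 ** ((pct - self.a) / self.b)

    def predict(self, loading) -> np.ndarray:
        return self.a + self.b * np.log10(np.asarray(loading, dtype=float))


def normalize_to_predose(
    series: pd.DataFrame,
    predose_day: float = 0.0,
    value_col: str = "value",
) -> pd.DataFrame:
    """Express each animal's series as % of its own pre-dose value.

    ``series`` needs columns ``group, animal, day`` and ``value_col``.  Each
    animal must have exactly one measurement at ``predose_day``, and it must
    be positive; the pre-dose row itself maps to exactly 100.
    """
    required = {"group", "animal", "day", value_col}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series is missing columns {sorted(missing)}")
    out = series.copy()
    norm = np.empty(len(out))
    for animal, sub in out.groupby("animal"):
        pre = sub.loc[np.isclose(sub["day"].astype(float), predose_day), value_col]
        if len(pre) != 1:
            raise ValueError(
                f"animal {animal!r}: expected exactly one pre-dose (day "
                f"{predose_day}) measurement, found {len(pre)}"
            )
        pv = float(pre.iloc[0])
        if not np.isfinite(pv) or pv <= 0:
            raise ValueError(f"animal {animal!r}: pre-dose value {pv} is not positive")
        norm[out.index.get_indexer(sub.index)] = sub[value_col].astype(float) / pv
    out[value_col] = 100.0 * norm
    return out


class SemilogECModel(BaseEstimator):
    """Least-squares semilog line of knockdown vs log10(Ago2 loading).

    Attributes after ``fit(loading, knockdown_pct)``: ``intercept_`` (a),
    ``slope_`` (b), ``ec50_``, ``ec80_``, ``residual_ss_``, ``df_``,
    ``extrapolated_`` (dict flagging EC values outside the observed loading
    range).
    """

    def __init__(self, slope_tol: float = 1e-12):
        self.slope_tol = slope_tol

    def fit(self, loading, knockdown_pct) -> "SemilogECModel":
        x = np.asarray(loading, dtype=float).ravel()
        y = np.asarray(knockdown_pct, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("loading and knockdown vectors differ in length")
        if len(x) < 3:
            raise ValueError("need at least 3 points for a semilog EC fit")
        if np.any(x <= 0):
            raise ValueError("all loadings must be strictly positive for log10")
        lx = np.log10(x)
        if np.ptp(lx) == 0:
            raise ValueError("need at least 2 distinct loading values")
        X = np.column_stack([np.ones_like(lx), lx])
        fr = fit_ols(X, y, column_names=["a", "b"])
        a, b = float(fr.params["a"]), float(fr.params["b"])
        scale = max(1.0, abs(y).max() / max(np.ptp(lx), 1.0))
        if abs(b) <= self.slope_tol * scale:
            raise ECUndefinedError("fitted slope is zero; EC values undefined")
        self.intercept_, self.slope_ = a, b
        self.residual_ss_ = fr.residual_ss
        self.df_ = fr.df_residual
        self.ec50_ = 10.0 ** ((50.0 - a) / b)
        self.ec80_ = 10.0 ** ((80.0 - a) / b)
        lo, hi = float(x.min()), float(x.max())
        self.extrapolated_ = {
            "ec50": not lo <= self.ec50_ <= hi,
            "ec80": not lo <= self.ec80_ <= hi,
        }
        if any(self.extrapolated_.values()):
            flagged = [k for k, v in self.extrapolated_.items() if v]
            warnings.warn(
                f"{', '.join(flagged)} outside the observed loading range "
                f"[{lo:.3g}, {hi:.3g}] ng/g (extrapolated)",
                stacklevel=2,
            )
        return self

    def to_ecfit(self) -> ECFit:
        return ECFit(
            a=self.intercept_,
            b=self.slope_,
            residual_ss=self.residual_ss_,
            df=self.df_,
            ec50=self.ec50_,
            ec80=self.ec80_,
            ec50_extrapolated=self.extrapolated_["ec50"],
            ec80_extrapolated=self.extrapolated_["ec80"],
        )


def fit_semilog_ec(loading, knockdown_pct) -> ECFit:
    """Fit the semilog EC line and return an :class:`ECFit`."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SemilogECModel().fit(loading, knockdown_pct)
    return model.to_ecfit()


def _semilog_rss(x: np.ndarray, y: np.ndarray) -> Tuple[float, int]:
    lx = np.log10(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(lx), lx])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), len(y) - 2


def ess_f_test(groups: Sequence[Tuple], alpha: float = ALPHA) -> StatTestResult:
    """Extra-sum-of-squares F-test: one pooled semilog line vs per-group lines.

    ``groups`` is a sequence of ``(loading, knockdown_pct)`` pairs.  The null
    model fits a single line to the pooled data; the alternative fits one
    line per group.  F = [(SSp - SSs)/(dfp - dfs)] / (SSs/dfs) on
    (dfp - dfs, dfs) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ss_sep = 0.0
    df_sep = 0
    xs, ys = [], []
    for x, y in groups:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3 or np.any(x <= 0):
            raise ValueError("each group needs >=3 points with positive loadings")
        rss, df = _semilog_rss(x, y)
        ss_sep += rss
        df_sep += df
        xs.append(x)
        ys.append(y)
    if df_sep <= 0:
        raise ValueError("no residual degrees of freedom in the separate fits")
    ss_pool, df_pool = _semilog_rss(np.concatenate(xs), np.concatenate(ys))
    df_num = df_pool - df_sep
    diff = max(ss_pool - ss_sep, 0.0)
    if ss_sep == 0.0:
        f = 0.0 if diff == 0.0 else np.inf
    else:
        f = (diff / df_num) / (ss_sep / df_sep)
    p = float(stats.f.sf(f, df_num, df_sep)) if np.isfinite(f) else 0.0
    return StatTestResult.from_fp(f, df_num, df_sep, p, alpha)


def auc_vs_baseline(
    days,
    values,
    baseline: float = 100.0,
    peak_ignore_frac: float = 0.10,
) -> float:
    """Trapezoidal area between a % time course and a baseline of 100.

    The series is split into "peaks": maximal runs between baseline
    crossings, with crossing points located by linear interpolation.  A peak
    whose maximal deviation from baseline is smaller than
    ``peak_ignore_frac`` times the overall Y range (max - min of the series)
    is ignored.  Below-baseline peaks contribute their absolute area, so
    silencing (values < 100) accrues positive area.  Units: % x day.
    """
    t = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("days and values differ in length")
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")

    d = v - baseline
    # refine with exact crossing points
    rt = [t[0]]
    rd = [d[0]]
    for i in range(1, len(t)):
        if d[i - 1] * d[i] < 0:
            tc = t[i - 1] + (t[i] - t[i - 1]) * d[i - 1] / (d[i - 1] - d[i])
            rt.append(tc)
            rd.append(0.0)
        rt.append(t[i])
        rd.append(d[i])
    rt = np.asarray(rt)
    rd = np.asarray(rd)

    threshold = peak_ignore_frac * float(v.max() - v.min())
    total = 0.0
    # walk maximal constant-sign runs delimited by zeros
    start = 0
    for i in range(1, len(rt) + 1):
        at_end = i == len(rt)
        boundary = at_end or rd[i] == 0.0
        if not boundary:
            continue
        seg = slice(start, i + (0 if at_end else 1))
        segd = rd[seg]
        if np.any(segd != 0.0):
            peak_height = float(np.max(np.abs(segd)))
            if peak_height >= threshold:
                total += float(np.trapezoid(np.abs(segd), rt[seg]))
        if not at_end and rd[i] == 0.0:
            start = i
    return total


def recovery_slope_compare(
    records: pd.DataFrame,
    day_window: Tuple[float, float] = RECOVERY_WINDOW,
    value_col: str = "value",
    group_col: str = "group",
    alpha: float = ALPHA,
) -> dict:
    """Per-group recovery slopes over a day window and a slope-equality test.

    Fits one OLS line per group on the records whose ``day`` lies inside the
    window (endpoints inclusive), then tests slope equality through the
    day x group interaction term of the pooled two-line model.  Exactly two
    groups are required.  Slopes are in % of control per day.
    """
    lo, hi = float(day_window[0]), float(day_window[1])
    sub = records[(records["day"].astype(float) >= lo) & (records["day"].astype(float) <= hi)]
    labels = sorted(sub[group_col].astype(str).unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups in the window, found {labels}")
    slopes = {}
    for g in labels:
        gsub = sub[sub[group_col].astype(str) == g]
        if len(gsub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points in the window")
        tt = gsub["day"].astype(float).to_numpy()
        yy = gsub[value_col].astype(float).to_numpy()
        X = np.column_stack([np.ones_like(tt), tt])
        fr = fit_ols(X, yy, column_names=["intercept", "day"])
        slopes[g] = float(fr.params["day"])

    tt = sub["day"].astype(float).to_numpy()
    yy = sub[value_col].astype(float).to_numpy()
    ind = (sub[group_col].astype(str) == labels[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(tt), tt, ind, tt * ind])
    fr = fit_ols(X, yy, column_names=["intercept", "day", "group", "day:group"])
    t_stat = fr.params["day:group"] / fr.bse["day:group"]
    p = 2.0 * float(stats.t.sf(abs(t_stat), fr.df_residual))
    return {
        "slopes": slopes,
        "slope_difference": float(fr.params["day:group"]),
        "test": StatTestResult.from_fp(t_stat, 1, fr.df_residual, p, alpha),
        "window": (lo, hi),
    }


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity correction: 1 - (1-p)^m."""
    return float(1.0 - (1.0 - p) ** m)


def _dunnett_null_maxabs(ns: np.ndarray, control_idx: int, df: int,
                         n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo draws of max_i |T_i| for Dunnett-type contrasts.

    Group means under the null are N(0, 1/n_i); the pooled SD estimate is
    sqrt(chi2_df/df).  Returns the sorted max|T| sample.
    """
    z = rng.standard_normal((n_draws, len(ns))) / np.sqrt(ns)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    others = [i for i in range(len(ns)) if i != control_idx]
    tmat = np.empty((n_draws, len(others)))
    for j, i in enumerate(others):
        denom = s * np.sqrt(1.0 / ns[i] + 1.0 / ns[control_idx])
        tmat[:, j] = (z[:, i] - z[:, control_idx]) / denom
    return np.sort(np.max(np.abs(tmat), axis=1))


def anova2_posttests(
    records: pd.DataFrame,
    control: str,
    post: str = "dunnett",
    seed: int = 0,
    n_mc: int = 100_000,
    value_col: str = "value",
    design_col: str = "group",
    time_col: str = "day",
    alpha: float = ALPHA,
) -> dict:
    """Two-way ANOVA (time x design) with Dunnett or Sidak post-tests.

    With balanced cells the classical factorial decomposition is used (main
    effects of design and time, their interaction, residual).  Unbalanced
    tables fall back to a regression-based type-II decomposition via
    statsmodels, with a warning.

    Post-tests compare every non-control design to ``control`` at each time
    point using the pooled residual mean square.  ``post="dunnett"`` adjusts
    within each time point by seeded Monte Carlo from the joint null
    (``n_mc`` draws, at least 100,000 recommended; adjusted p is never below
    the unadjusted p).  ``post="sidak"`` applies 1-(1-p)^m over all
    comparisons.

    Returns ``{"anova": table, "comparisons": table, "residual_df": int,
    "residual_ms": float}``.
    """
    for col in (value_col, design_col, time_col):
        if col not in records.columns:
            raise ValueError(f"records are missing column {col!r}")
    designs = sorted(records[design_col].astype(str).unique())
    times = sorted(records[time_col].astype(float).unique())
    if control not in designs:
        raise ValueError(f"control label {control!r} absent from {design_col}")
    if len(designs) < 2 or len(times) < 2:
        raise ValueError("need at least 2 levels of design and of time")
    if post not in ("dunnett", "sidak"):
        raise ValueError("post must be 'dunnett' or 'sidak'")

    df = records.assign(
        _d=records[design_col].astype(str), _t=records[time_col].astype(float)
    )
    cell_counts = df.groupby(["_d", "_t"])[value_col].count()
    full_grid = len(cell_counts) == len(designs) * len(times)
    if not full_grid or cell_counts.min() == 0:
        raise ValueError("every design x time cell must be non-empty")
    balanced = cell_counts.nunique() == 1

    y = df[value_col].astype(float).to_numpy()
    n_total = len(y)
    grand = y.mean()

    if balanced:
        n_cell = int(cell_counts.iloc[0])
        a, b = len(designs), len(times)
        mean_d = df.groupby("_d")[value_col].mean()
        mean_t = df.groupby("_t")[value_col].mean()
        mean_dt = df.groupby(["_d", "_t"])[value_col].mean()
        ss_design = n_cell * b * float(((mean_d - grand) ** 2).sum())
        ss_time = n_cell * a * float(((mean_t - grand) ** 2).sum())
        ss_cells = n_cell * float(((mean_dt - grand) ** 2).sum())
        ss_inter = ss_cells - ss_design - ss_time
        ss_total = float(((y - grand) ** 2).sum())
        ss_resid = ss_total - ss_cells
        df_design, df_time = a - 1, b - 1
        df_inter = df_design * df_time
        df_resid = n_total - a * b
        rows = []
        for name, ss, dff in (
            ("design", ss_design, df_design),
            ("time", ss_time, df_time),
            ("design:time", ss_inter, df_inter),
        ):
            ms = ss / dff
            mse = ss_resid / df_resid
            f = ms / mse
            rows.append(
                {"effect": name, "sum_sq": ss, "df": dff, "F": f,
                 "p": float(stats.f.sf(f, dff, df_resid))}
            )
        rows.append(
            {"effect": "residual", "sum_sq": ss_resid, "df": df_resid,
             "F": np.nan, "p": np.nan}
        )
        anova_table = pd.DataFrame(rows)
        residual_ms = ss_resid / df_resid
        residual_df = df_resid
    else:
        warnings.warn(
            "unbalanced cells: using regression-based (type II) decomposition",
            stacklevel=2,
        )
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        model = smf.ols(
            "value ~ C(design) * C(time)",
            data=df.rename(columns={value_col: "value", "_d": "design", "_t": "time"}),
        ).fit()
        tbl = anova_lm(model, typ=2)
        anova_table = (
            tbl.rename(
                index={
                    "C(design)": "design",
                    "C(time)": "time",
                    "C(design):C(time)": "design:time",
                    "Residual": "residual",
                },
                columns={"PR(>F)": "p"},
            )
            .reset_index()
            .rename(columns={"index": "effect"})
        )
        residual_df = int(model.df_resid)
        residual_ms = float(model.ssr / model.df_resid)

    # per-time-point comparisons vs control on the pooled residual MS
    rng = np.random.default_rng(seed)
    others = [d for d in designs if d != control]
    comparisons = []
    mc_cache = {}
    for tpt in times:
        cell = df[df["_t"] == tpt]
        ns = np.array(
            [int((cell["_d"] == d).sum()) for d in designs], dtype=float
        )
        ctrl_idx = designs.index(control)
        key = (tuple(ns), ctrl_idx)
        if post == "dunnett" and key not in mc_cache:
            mc_cache[key] = _dunnett_null_maxabs(ns, ctrl_idx, residual_df, n_mc, rng)
        ctrl_mean = cell.loc[cell["_d"] == control, value_col].mean()
        for d in others:
            m = cell.loc[cell["_d"] == d, value_col].mean()
            se = np.sqrt(
                residual_ms * (1.0 / ns[designs.index(d)] + 1.0 / ns[ctrl_idx])
            )
            tval = (m - ctrl_mean) / se
            p_un = 2.0 * float(stats.t.sf(abs(tval), residual_df))
            comparisons.append(
                {
                    "time": tpt,
                    "design": d,
                    "mean_diff": float(m - ctrl_mean),
                    "t": float(tval),
                    "p_unadjusted": p_un,
                    "_key": key,
                }
            )
    comp = pd.DataFrame(comparisons)
    if post == "dunnett":
        adj = []
        for _, row in comp.iterrows():
            sample = mc_cache[row["_key"]]
            # P(max |T| >= |t_obs|) with the MC sample; never below unadjusted
            exceed = 1.0 - np.searchsorted(sample, abs(row["t"]), side="left") / len(sample)
            adj.append(max(float(exceed), row["p_unadjusted"]))
        comp["p_adjusted"] = adj
    else:
        m = len(comp)
        comp["p_adjusted"] = [sidak_adjust(p, m) for p in comp["p_unadjusted"]]
    comp["significant"] = comp["p_adjusted"] < alpha
    comp = comp.drop(columns=["_key"])
    return {
        "anova": anova_table,
        "comparisons": comp,
        "residual_df": residual_df,
        "residual_ms": residual_ms,
    }
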