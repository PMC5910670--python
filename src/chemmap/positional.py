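"""Positional 2'-F vs 2'-OMe activity model.

Fits a multiple linear regression of ln(fraction of target mRNA remaining)
on one 2'-F indicator per strand position (2'-OMe is the reference
chemistry), with target-site and cell-line-species fixed effects.  Each
fitted chemistry coefficient is the model-adjusted mean ln-difference of
2'-F from 2'-OMe at that position: negative values mean 2'-F improves
silencing there.  Analyses are agnostic to PS backbone content, which never
enters the design matrix.

Site identifiers are unique across targets (nested), so site fixed effects
absorb the target effect; species is a per-site attribute and is likewise
absorbed when collinear.  The column map records what was absorbed or
dropped — nothing is ever silently aliased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .strands import ANTISENSE_LENGTH, SENSE_LENGTH

__all__ = [
    "FitResult",
    "PositionalCoefficient",
    "filter_sites",
    "build_design_matrix",
    "fit_ols",
    "extract_positional_map",
    "PositionalActivityModel",
    "fit_positional_model",
    "chem_column_names",
]

#: relative tolerance for declaring a column linearly dependent
RANK_TOL = 1e-10

ALPHA = 0.05


class EmptyResultError(ValueError):
    """All records were filtered out."""


def chem_column_names() -> list:
    """Design-matrix column names for the 21+23 per-position 2'-F indicators."""
    return [f"S{p}_F" for p in range(1, SENSE_LENGTH + 1)] + [
        f"AS{p}_F" for p in range(1, ANTISENSE_LENGTH + 1)
    ]


def filter_sites(records: pd.DataFrame, min_designs: int = 10):
    """Restrict a screen to target sites with enough distinct designs.

    A "design" is a distinct ``duplex_id``; replicate rows of the same duplex
    count once.  Returns ``(filtered, report)`` where ``report`` is a
    per-site DataFrame of design counts and whether the site was kept.
    Raises :class:`EmptyResultError` (carrying the report) when no site
    survives.
    """
    if records.empty:
        raise ValueError("records table is empty")
    counts = records.groupby("site_id")["duplex_id"].nunique()
    report = pd.DataFrame(
        {"n_designs": counts, "kept": counts >= min_designs}
    ).reset_index()
    kept_sites = set(report.loc[report["kept"], "site_id"])
    if not kept_sites:
        err = EmptyResultError(
            f"no site has >= {min_designs} designs "
            f"(max observed {int(counts.max())})"
        )
        err.report = report
        raise err
    filtered = records[records["site_id"].isin(kept_sites)].reset_index(drop=True)
    return filtered, report


def _chem_indicator_matrix(records: pd.DataFrame) -> np.ndarray:
    """Rows x 44 matrix of 2'-F indicators from the compact pattern strings."""
    sense = np.frombuffer(
        "".join(records["sense_pattern"]).encode(), dtype="S1"
    ).reshape(len(records), SENSE_LENGTH)
    anti = np.frombuffer(
        "".join(records["antisense_pattern"]).encode(), dtype="S1"
    ).reshape(len(records), ANTISENSE_LENGTH)
    return np.hstack([(sense == b"F"), (anti == b"F")]).astype(float)


def build_design_matrix(records: pd.DataFrame):
    """Encode screen records into the positional regression design.

    Columns: intercept; one 0/1 indicator per strand position, 1 iff the
    chemistry there is 2'-F (2'-OMe is the reference and maps to 0); site
    fixed effects (first site in sorted order is the reference level);
    species indicators (first species is the reference).  PS content
    contributes no column.  The response ``y`` is the natural log of
    ``fraction_remaining``.

    Chemistry indicators constant across all records are dropped up front
    and listed in ``column_info["inestimable"]``.

    Returns ``(X, y, column_info)`` with ``X`` a DataFrame and
    ``column_info`` a dict describing the encoding (chemistry columns,
    reference levels, absorbed/inestimable columns).
    """
    if records.empty:
        raise ValueError("records table is empty")
    frac = records["fraction_remaining"].to_numpy(dtype=float)
    if np.any(~np.isfinite(frac)) or np.any(frac <= 0):
        raise ValueError("fraction_remaining must be finite and strictly positive")
    y = pd.Series(np.log(frac), name="ln_fraction_remaining", index=records.index)

    chem = _chem_indicator_matrix(records)
    chem_cols = chem_column_names()
    keep = []
    inestimable = []
    for j, name in enumerate(chem_cols):
        col = chem[:, j]
        if col.min() == col.max():
            inestimable.append(name)
        else:
            keep.append(j)
    X = pd.DataFrame(
        chem[:, keep], columns=[chem_cols[j] for j in keep], index=records.index
    )
    X.insert(0, "Intercept", 1.0)

    site_levels = sorted(records["site_id"].astype(str).unique())
    for lvl in site_levels[1:]:
        X[f"site[{lvl}]"] = (records["site_id"].astype(str) == lvl).astype(float)
    species_levels = []
    if "species" in records.columns:
        species_levels = sorted(records["species"].astype(str).unique())
        for lvl in species_levels[1:]:
            X[f"species[{lvl}]"] = (records["species"].astype(str) == lvl).astype(float)

    column_info = {
        "chem_columns": [chem_cols[j] for j in keep],
        "inestimable": inestimable,
        "site_reference": site_levels[0] if site_levels else None,
        "species_reference": species_levels[0] if species_levels else None,
        "absorbed": ["target"],  # sites are nested within targets
    }
    return X, y, column_info


@dataclass
class FitResult:
    """An OLS fit: coefficients, covariance and summary statistics."""

    params: pd.Series
    cov_params: Optional[pd.DataFrame]
    bse: pd.Series
    pvalues: pd.Series
    residual_ss: float
    df_residual: int
    r2: float
    adjusted_r2: float
    overall_f: float
    overall_p: float
    nobs: int
    rank: int
    dropped: list = field(default_factory=list)

    def conf_int(self, alpha: float = ALPHA) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_residual)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )


def _select_independent_columns(A: np.ndarray, tol: float = RANK_TOL):
    """Greedy left-to-right choice of a linearly independent column subset.

    Modified Gram-Schmidt with re-orthogonalization; a column is rejected
    when its residual norm after projection falls below ``tol`` times its
    original norm (columns of zero norm are rejected outright).  Earlier
    columns win ties, so orderings like [intercept, chemistry, site, species]
    keep the scientifically primary columns.
    """
    n, p = A.shape
    Q = np.empty((n, min(n, p)))
    kept = []
    r = 0
    for j in range(p):
        v = A[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        if norm0 == 0.0:
            continue
        for _ in range(2):  # re-orthogonalize for stability
            if r:
                v -= Q[:, :r] @ (Q[:, :r].T @ v)
        norm = np.linalg.norm(v)
        if norm > tol * norm0 and r < n:
            Q[:, r] = v / norm
            kept.append(j)
            r += 1
    return kept


def fit_ols(X, y, column_names: Optional[list] = None) -> FitResult:
    """Ordinary least squares with explicit rank handling and inference.

    Rank-deficient columns are dropped (recorded in ``dropped``), never
    silently aliased.  Standard errors come from sigma2*(X'X)^-1 on the
    retained columns; two-sided p-values from the t distribution with the
    residual degrees of freedom.  With zero residual df the coefficients are
    still returned but SE/p are NaN and a warning is emitted.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        names = list(column_names) if column_names is not None else [
            f"x{j}" for j in range(A.shape[1])
        ]
    yv = np.asarray(y, dtype=float).ravel()
    if A.shape[0] != yv.shape[0]:
        raise ValueError("X and y have different numbers of rows")

    kept_idx = _select_independent_columns(A)
    dropped = [names[j] for j in range(A.shape[1]) if j not in set(kept_idx)]
    if dropped:
        warnings.warn(
            f"rank-deficient design: dropped columns {dropped}", stacklevel=2
        )
    Ak = A[:, kept_idx]
    kept_names = [names[j] for j in kept_idx]
    n, rank = Ak.shape

    Qf, Rf = np.linalg.qr(Ak)
    beta = np.linalg.solve(Rf, Qf.T @ yv)
    resid = yv - Ak @ beta
    rss = float(resid @ resid)
    df_resid = n - rank

    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = (
        1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
    )

    has_intercept = any(
        np.allclose(Ak[:, j], Ak[0, j]) and Ak[0, j] != 0 for j in range(rank)
    )
    df_model = rank - 1 if has_intercept else rank

    if df_resid > 0:
        sigma2 = rss / df_resid
        Rinv = np.linalg.inv(Rf)
        cov = sigma2 * (Rinv @ Rinv.T)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        if df_model > 0 and rss > 0:
            f_stat = ((tss - rss) / df_model) / sigma2 if has_intercept else np.nan
            f_p = float(stats.f.sf(f_stat, df_model, df_resid)) if has_intercept else np.nan
        elif rss == 0:
            f_stat, f_p = np.inf, 0.0
        else:
            f_stat, f_p = np.nan, np.nan
        cov_df = pd.DataFrame(cov, index=kept_names, columns=kept_names)
    else:
        warnings.warn(
            "zero residual degrees of freedom: coefficients returned, "
            "inference unavailable",
            stacklevel=2,
        )
        se = np.full(rank, np.nan)
        pvals = np.full(rank, np.nan)
        f_stat, f_p = np.nan, np.nan
        cov_df = None

    return FitResult(
        params=pd.Series(beta, index=kept_names),
        cov_params=cov_df,
        bse=pd.Series(se, index=kept_names),
        pvalues=pd.Series(pvals, index=kept_names),
        residual_ss=rss,
        df_residual=df_resid,
        r2=r2,
        adjusted_r2=adj_r2,
        overall_f=float(f_stat),
        overall_p=float(f_p) if np.isfinite(f_stat) or f_stat == np.inf else np.nan,
        nobs=n,
        rank=rank,
        dropped=dropped,
    )


@dataclass(frozen=True)
class PositionalCoefficient:
    """Model-adjusted ln-difference of 2'-F vs 2'-OMe at one position."""

    strand: str  # "sense" or "antisense"
    position: int  # 1-based from the 5' end
    delta_ln: float
    se: float
    p: float
    significant: bool
    estimable: bool = True


def extract_positional_map(fit: FitResult, column_info: dict, alpha: float = ALPHA) -> pd.DataFrame:
    """Tabulate the per-position 2'-F effects from a fitted model.

    Returns one row per strand position (21 sense + 23 antisense) with
    columns ``strand, position, delta_ln, se, p, significant, estimable``.
    Negative ``delta_ln`` means 2'-F improves silencing (lower fraction
    remaining) at that position.  Positions whose indicator was constant in
    the data, or dropped for collinearity, are flagged inestimable and carry
    no numbers.
    """
    known = set(column_info["chem_columns"]) | set(column_info["inestimable"])
    rows = []
    for name in chem_column_names():
        if name not in known:
            raise ValueError(f"column map does not describe chemistry column {name}")
        strand = "antisense" if name.startswith("AS") else "sense"
        position = int(name[:-2].lstrip("AS"))
        estimable = name in column_info["chem_columns"] and name in fit.params.index
        if estimable:
            p = float(fit.pvalues[name])
            rows.append(
                {
                    "strand": strand,
                    "position": position,
                    "delta_ln": float(fit.params[name]),
                    "se": float(fit.bse[name]),
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "estimable": True,
                }
            )
        else:
            rows.append(
                {
                    "strand": strand,
                    "position": position,
                    "delta_ln": np.nan,
                    "se": np.nan,
                    "p": np.nan,
                    "significant": False,
                    "estimable": False,
                }
            )
    return pd.DataFrame(rows)


class PositionalActivityModel(BaseEstimator):
    """Per-position 2'-F/2'-OMe activity regression over a screen.

    Parameters
    ----------
    min_designs : int
        Minimum distinct duplexes per target site; sites below the threshold
        are excluded before fitting (default 10).
    dose_nM : float or None
        Transfection dose whose records enter the model (default 0.1 nM, the
        low-dose arm where positional effects are most visible).  ``None``
        uses every dose.
    aggregate : {"duplex_mean", "replicate"}
        "duplex_mean" (default) averages ln(fraction) over replicate wells of
        each duplex before fitting; "replicate" fits per-well rows.
    alpha : float
        Two-sided significance level for flagging positions (default 0.05).

    Attributes
    ----------
    positional_map_ : DataFrame
        One row per strand position: delta_ln, se, p, significant, estimable.
    fit_result_ : FitResult
    adjusted_r2_ : float
    site_report_ : DataFrame
        Per-site design counts and filter outcome.
    column_info_ : dict
    n_obs_ : int
    """

    def __init__(self, min_designs: int = 10, dose_nM: Optional[float] = 0.1,
                 aggregate: str = "duplex_mean", alpha: float = ALPHA):
        self.min_designs = min_designs
        self.dose_nM = dose_nM
        self.aggregate = aggregate
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None) -> "PositionalActivityModel":
        """Fit on a screen table (columns as produced by ``gen_screen``)."""
        if self.aggregate not in ("duplex_mean", "replicate"):
            raise ValueError("aggregate must be 'duplex_mean' or 'replicate'")
        records = X
        if self.dose_nM is not None and "dose_nM" in records.columns:
            records = records[records["dose_nM"].astype(float) == float(self.dose_nM)]
            if records.empty:
                raise ValueError(f"no records at dose {self.dose_nM} nM")
        records, self.site_report_ = filter_sites(records, self.min_designs)
        if self.aggregate == "duplex_mean":
            records = _aggregate_duplex_mean(records)
        Xd, yv, self.column_info_ = build_design_matrix(records)
        self.fit_result_ = fit_ols(Xd, yv)
        self.positional_map_ = extract_positional_map(
            self.fit_result_, self.column_info_, self.alpha
        )
        self.adjusted_r2_ = self.fit_result_.adjusted_r2
        self.n_obs_ = self.fit_result_.nobs
        return self

    def get_map(self) -> pd.DataFrame:
        return self.positional_map_


def _aggregate_duplex_mean(records: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean fraction remaining per duplex (mean on the ln scale)."""
    keys = ["duplex_id", "target", "site_id", "sense_pattern", "antisense_pattern"]
    if "species" in records.columns:
        keys.insert(3, "species")
    g = records.assign(_lnf=np.log(records["fraction_remaining"]))
    agg = g.groupby(keys, as_index=False)["_lnf"].mean()
    agg["fraction_remaining"] = np.exp(agg.pop("_lnf"))
    return agg


def fit_positional_model(records: pd.DataFrame, **kwargs) -> PositionalActivityModel:
    """Convenience wrapper: fit a :class:`PositionalActivityModel`."""
    return PositionalActivityModel(**kwargs).fit(records)
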