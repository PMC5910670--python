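"""Design-variant comparison: ddCt processing and covariate-adjusted effects.

A directed SAR panel measures a handful of design variants (DVs) against a
reference design (usually the parent) across several target sites, two
transfection doses and replicate batches.  The comparison is an OLS fit of
ln(fraction remaining) on DV indicators (reference dropped) plus categorical
covariates for dose, site and replicate; each DV coefficient is its
model-adjusted mean ln-difference from the reference across sequences.

Raw qPCR plates are reduced to fraction-remaining by the ddCt method,
normalizing each well's target Ct to the housekeeping gene and treated
groups to the non-targeting control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .positional import ALPHA, fit_ols

__all__ = [
    "ddct_relative_expression",
    "DesignVariantModel",
    "fit_dv_comparison",
]


def ddct_relative_expression(plate: pd.DataFrame, control: str = "control") -> pd.Series:
    """ddCt relative expression per treated sample group.

    Expects columns ``sample``, ``ct_target``, ``ct_housekeeping``; the rows
    with ``sample == control`` are the non-targeting control wells.  Per
    well, dCt = Ct_target - Ct_housekeeping; per group, ddCt = mean
    dCt(treated) - mean dCt(control); relative expression is 2**(-ddCt).
    Adding any constant to every Ct on the plate leaves the result
    unchanged.

    Returns a Series of fraction-remaining indexed by treated sample label.
    Wells with non-finite Ct are excluded with a warning.
    """
    required = {"sample", "ct_target", "ct_housekeeping"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate is missing columns {sorted(missing)}")
    finite = np.isfinite(plate["ct_target"]) & np.isfinite(plate["ct_housekeeping"])
    if not finite.all():
        warnings.warn(
            f"excluding {int((~finite).sum())} wells with non-finite Ct", stacklevel=2
        )
        plate = plate[finite]
    dct = plate["ct_target"] - plate["ct_housekeeping"]
    groups = plate["sample"].astype(str)
    if control not in set(groups):
        raise ValueError(f"no control wells (sample == {control!r}) on the plate")
    mean_dct = dct.groupby(groups).mean()
    ddct = mean_dct.drop(control) - mean_dct[control]
    out = 2.0 ** (-ddct)
    out.name = "fraction_remaining"
    return out


class DesignVariantModel(BaseEstimator):
    """Covariate-adjusted DV-vs-reference comparison across sequences.

    Parameters
    ----------
    reference : str
        DV label used as the regression reference (its own effect is 0).
    alpha : float
        Significance level for flagging effects (default 0.05).

    Attributes
    ----------
    effects_ : DataFrame
        One row per DV: ``dv_id, delta_ln, se, p, significant, n_obs,
        n_sites, low_support`` (reference row included with delta_ln 0).
    fit_result_ : FitResult
    """

    def __init__(self, reference: str = "parent", alpha: float = ALPHA):
        self.reference = reference
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None) -> "DesignVariantModel":
        records = X
        required = {"dv_id", "site_id", "dose_nM", "replicate", "fraction_remaining"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records are missing columns {sorted(missing)}")
        dvs = sorted(records["dv_id"].astype(str).unique())
        if self.reference not in dvs:
            raise ValueError(
                f"reference design {self.reference!r} absent from records"
            )
        if len(dvs) < 2:
            raise ValueError("need at least two distinct dv_ids including the reference")
        frac = records["fraction_remaining"].to_numpy(dtype=float)
        if np.any(~np.isfinite(frac)) or np.any(frac <= 0):
            raise ValueError("fraction_remaining must be finite and strictly positive")

        yv = np.log(frac)
        Xd = pd.DataFrame(index=records.index)
        Xd["Intercept"] = 1.0
        non_ref = [d for d in dvs if d != self.reference]
        for d in non_ref:
            Xd[f"dv[{d}]"] = (records["dv_id"].astype(str) == d).astype(float)
        for col, prefix in (("dose_nM", "dose"), ("site_id", "site"), ("replicate", "rep")):
            levels = sorted(records[col].astype(str).unique())
            for lvl in levels[1:]:
                Xd[f"{prefix}[{lvl}]"] = (records[col].astype(str) == lvl).astype(float)

        self.fit_result_ = fit_ols(Xd, yv)
        fr = self.fit_result_

        rows = [
            {
                "dv_id": self.reference,
                "delta_ln": 0.0,
                "se": np.nan,
                "p": np.nan,
                "significant": False,
                "n_obs": int((records["dv_id"].astype(str) == self.reference).sum()),
                "n_sites": int(
                    records.loc[
                        records["dv_id"].astype(str) == self.reference, "site_id"
                    ].nunique()
                ),
                "low_support": False,
                "reference": True,
            }
        ]
        for d in non_ref:
            name = f"dv[{d}]"
            mask = records["dv_id"].astype(str) == d
            n_sites = int(records.loc[mask, "site_id"].nunique())
            if name in fr.params.index:
                p = float(fr.pvalues[name])
                rows.append(
                    {
                        "dv_id": d,
                        "delta_ln": float(fr.params[name]),
                        "se": float(fr.bse[name]),
                        "p": p,
                        "significant": bool(p < self.alpha) if np.isfinite(p) else False,
                        "n_obs": int(mask.sum()),
                        "n_sites": n_sites,
                        "low_support": n_sites < 2,
                        "reference": False,
                    }
                )
            else:  # dropped for collinearity
                rows.append(
                    {
                        "dv_id": d,
                        "delta_ln": np.nan,
                        "se": np.nan,
                        "p": np.nan,
                        "significant": False,
                        "n_obs": int(mask.sum()),
                        "n_sites": n_sites,
                        "low_support": True,
                        "reference": False,
                    }
                )
        self.effects_ = pd.DataFrame(rows)
        return self


def fit_dv_comparison(records: pd.DataFrame, reference: str = "parent",
                      alpha: float = ALPHA) -> pd.DataFrame:
    """Fit the DV comparison and return the effects table."""
    return DesignVariantModel(reference=reference, alpha=alpha).fit(records).effects_
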