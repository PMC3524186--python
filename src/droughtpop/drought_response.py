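"""Growth-rate-versus-drought regressions.

The link between annual drought intensity and population growth is a single
predictor linear mixed model

    r_t = intercept + b * D + u_location + v_species + e,

with crossed random intercepts for population location and species, fitted by
maximum likelihood. ``D`` is one of the four annual drought indices (C, T,
C_t2, T_t2); the slope ``b`` (change in log growth rate per drought month) is
the quantity carried forward into the stochastic projection model. Fits are
run pooled across all observations and separately per life-history group.
A Wald z test on the slope provides the p-value. Groups containing a single
species drop the species random term (its variance is unidentifiable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PREDICTORS",
    "DroughtResponseFit",
    "fit_drought_response",
    "compare_indices",
    "spearman_index_vs_pdsi",
]

PREDICTORS = ("C", "T", "C_t2", "T_t2")


@dataclass(frozen=True)
class DroughtResponseFit:
    """A fitted growth-rate-versus-drought regression."""

    group: str
    predictor: str
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n_obs: int
    var_location: float
    var_species: float
    var_residual: float

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for the slope."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.slope - z * self.slope_se, self.slope + z * self.slope_se


def _clean(observations: pd.DataFrame, predictor: str) -> pd.DataFrame:
    df = observations.dropna(subset=["r", predictor]).copy()
    df[predictor] = df[predictor].astype(float)
    df["r"] = df["r"].astype(float)
    return df


def fit_drought_response(
    observations: pd.DataFrame,
    predictor: str = "C",
    group: str = "all",
    random_effects: bool = True,
) -> DroughtResponseFit:
    """Fit r ~ predictor with crossed random intercepts (location, species).

    Maximum likelihood (not REML) so single-predictor fits are comparable
    across predictors. ``random_effects=False`` reduces the model to
    ordinary least squares on the same data. The species random term is
    dropped automatically when only one species is present.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    df = _clean(observations, predictor)
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    x = df[predictor].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor} is constant in these data")

    if not random_effects:
        X = sm.add_constant(x)
        res = sm.OLS(df["r"].to_numpy(), X).fit()
        return DroughtResponseFit(
            group=group,
            predictor=predictor,
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            p_value=float(2 * stats.norm.sf(abs(res.params[1] / res.bse[1]))),
            n_obs=n,
            var_location=0.0,
            var_species=0.0,
            var_residual=float(res.scale),
        )

    if df["location_id"].nunique() < 2:
        raise ValueError("need at least 2 locations for a location random effect")
    one_species = df["species"].nunique() < 2
    if one_species:
        logger.info("group %s: single species, species random term dropped", group)

    # keep only model columns: a predictor column named "C" would otherwise
    # shadow patsy's categorical-coding function in the vc formulas
    df = pd.DataFrame(
        {
            "r": df["r"].to_numpy(),
            "_D": df[predictor].to_numpy(),
            "location_id": df["location_id"].to_numpy(),
            "species": df["species"].to_numpy(),
            "_one": 1,
        }
    )
    vc = {"location": "0 + C(location_id)"}
    if not one_species:
        vc["species"] = "0 + C(species)"
    model = sm.MixedLM.from_formula(
        "r ~ _D", groups="_one", vc_formula=vc, re_formula="0", data=df
    )
    res = None
    errors: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # variance components at the zero boundary can stall the gradient
        # optimizers; nelder-mead is the robust last resort
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                candidate = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
                continue
            if candidate.converged:
                res = candidate
                break
            errors.append(f"{method}: not converged")
    if res is None:
        raise RuntimeError(
            f"mixed model did not converge (group={group}, predictor={predictor}); "
            f"optimizer attempts: {errors}"
        )
    slope = float(res.params["_D"])
    se = float(res.bse["_D"])
    vcomp = dict(zip(model.exog_vc.names, res.vcomp))
    return DroughtResponseFit(
        group=group,
        predictor=predictor,
        slope=slope,
        intercept=float(res.params["Intercept"]),
        slope_se=se,
        p_value=float(2 * stats.norm.sf(abs(slope / se))),
        n_obs=n,
        var_location=float(vcomp.get("location", 0.0)),
        var_species=float(vcomp.get("species", 0.0)),
        var_residual=float(res.scale),
    )


def fit_by_group(
    observations: pd.DataFrame, predictor: str = "C"
) -> dict[str, DroughtResponseFit]:
    """One fit per life-history group present in `observations['group']`."""
    out = {}
    for g, sub in observations.groupby("group"):
        try:
            out[str(g)] = fit_drought_response(sub, predictor, group=str(g))
        except (ValueError, RuntimeError) as exc:
            logger.warning("group %s not fitted: %s", g, exc)
    return out


def compare_indices(
    observations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One pooled fit per drought index, plus their rank correlations.

    Returns (fits, rho): `fits` has one row per predictor with slope, SE,
    Wald p and variance components; `rho` is the 4x4 Spearman correlation
    matrix between the predictors (pairwise complete observations).
    """
    rows = []
    for pred in PREDICTORS:
        f = fit_drought_response(observations, pred)
        rows.append(
            {
                "predictor": pred,
                "slope": f.slope,
                "se": f.slope_se,
                "p": f.p_value,
                "n": f.n_obs,
                "var_location": f.var_location,
                "var_species": f.var_species,
                "var_resid": f.var_residual,
            }
        )
    fits = pd.DataFrame(rows).set_index("predictor")

    rho = pd.DataFrame(
        np.eye(len(PREDICTORS)), index=PREDICTORS, columns=PREDICTORS
    )
    for i, a in enumerate(PREDICTORS):
        for b in PREDICTORS[i + 1:]:
            sub = observations.dropna(subset=[a, b])
            r, _ = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = r
    return fits, rho


def spearman_index_vs_pdsi(
    c_values, annual_mean_q, annual_modal_q
) -> dict[str, tuple[float, float]]:
    """Spearman rho of the drought index C against annual mean and modal q.

    Mid-ranks for ties; two-sided p. Raises on zero-variance input.
    """
    c = np.asarray(c_values, dtype=float)
    if len(c) < 5:
        raise ValueError("need at least 5 paired values")
    out = {}
    for name, other in (("mean", annual_mean_q), ("mode", annual_modal_q)):
        y = np.asarray(other, dtype=float)
        if len(y) != len(c):
            raise ValueError("unequal lengths")
        if np.ptp(c) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in C or annual {name} q")
        rho, p = stats.spearmanr(c, y)
        out[name] = (float(rho), float(p))
    return out
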