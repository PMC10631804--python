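"""Donor-effect inference on secreted-protein abundance.

Per-protein generalized linear models with a Gamma response and log link
relate LFQ abundance to donor age (years, continuous), sex (M vs F) and
tissue source (BMSC vs ASC).  Abundances are strictly positive and
right-skewed, which the Gamma family reflects; the log link makes
coefficients scale-free and directly interpretable as log fold changes.
Samples missing a protein's value are dropped for that protein only
(complete-case per protein) and the n actually used is reported.  Wald
inference uses the t reference with n - p degrees of freedom and the
Pearson-estimated dispersion.  Benjamini-Hochberg adjustment is applied per
predictor across proteins.

The same machinery covers the enzymatic-activity assay (Gaussian
random-intercept mixed model with time, age and time x age fixed effects)
and the immunoassay concentration (Gamma GLM on age, sex, tissue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ora import bh_adjust

__all__ = [
    "PREDICTORS",
    "AssociationResult",
    "build_design",
    "fit_gamma_glm",
    "associate",
    "protein_family_adjust",
    "compute_log2fc",
    "fit_lmm_activity",
    "delta_response",
    "fit_concentration_glm",
]

#: Reported predictor names mapped from design-matrix columns.  Reference
#: levels: sex F, tissue ASC; age in years, uncentered.
PREDICTORS = ("age", "sex_M", "tissue_BMSC")


@dataclass
class AssociationResult:
    """Per-protein GLM summary on the link (log) scale."""

    protein_id: str
    n_used: int
    coefficients: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    q_values: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""


def build_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Design matrix with intercept, age (years), sex_M, tissue_BMSC dummies."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": meta["age_years"].astype(float),
            "sex_M": (meta["sex"] == "M").astype(float),
            "tissue_BMSC": (meta["tissue"] == "BMSC").astype(float),
        },
        index=meta.index,
    )
    return design


def _wald_t(params, bse, df_resid) -> np.ndarray:
    tvals = params / bse
    return 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)


def fit_gamma_glm(
    abundance: pd.Series,
    metadata: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    protein_id: str = "",
    link: str = "log",
) -> AssociationResult:
    """Fit one protein's Gamma GLM on complete cases.

    ``abundance`` is indexed by sample id; missing values define the
    per-protein exclusions.  Either ``metadata`` or a prebuilt ``design``
    (from :func:`build_design`) must be supplied; reuse of one design across
    proteins avoids rebuilding it per fit.
    """
    if design is None:
        if metadata is None:
            raise ValueError("provide metadata or a prebuilt design")
        design = build_design(metadata)
    y = abundance.dropna()
    if (y <= 0).any():
        raise ValueError("Gamma GLM requires strictly positive abundances")
    x = design.loc[y.index]
    n, p = x.shape
    if n < p + 2:
        return AssociationResult(
            protein_id, n_used=n, converged=False, message="too few complete cases"
        )
    names = list(x.columns)
    if float(np.ptp(y.to_numpy())) == 0.0:
        # constant response: the MLE limit is an exact intercept-only fit
        coefs = {name: 0.0 for name in names}
        if "intercept" in coefs:
            coefs["intercept"] = float(np.log(y.iloc[0]))
        return AssociationResult(
            protein_id=protein_id,
            n_used=n,
            coefficients=coefs,
            std_errors={name: 0.0 for name in names},
            p_values={name: float("nan") for name in names},
            message="constant response",
        )
    link_fn = sm.families.links.Log() if link == "log" else sm.families.links.InversePower()
    model = sm.GLM(y.to_numpy(dtype=float), x.to_numpy(), family=sm.families.Gamma(link=link_fn))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit()
    except Exception as exc:  # IRLS breakdown on degenerate inputs
        return AssociationResult(
            protein_id, n_used=n, converged=False, message=f"fit failed: {exc}"
        )
    pvals = _wald_t(fit.params, fit.bse, n - p)
    return AssociationResult(
        protein_id=protein_id,
        n_used=n,
        coefficients=dict(zip(names, map(float, fit.params))),
        std_errors=dict(zip(names, map(float, fit.bse))),
        p_values=dict(zip(names, map(float, pvals))),
    )


def compute_log2fc(
    abundance: pd.Series, metadata: pd.DataFrame, predictor: str
) -> float:
    """log2 ratio of mean abundance between levels of a categorical predictor.

    Orientation: BMSC relative to ASC for tissue, M relative to F for sex.
    Computed on the protein's complete cases only.
    """
    groups = {"tissue": ("BMSC", "ASC"), "sex": ("M", "F")}
    if predictor not in groups:
        raise ValueError(f"predictor must be one of {sorted(groups)}")
    num_level, den_level = groups[predictor]
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    y = abundance.dropna()
    levels = meta.loc[y.index, predictor]
    num = y[levels == num_level].mean()
    den = y[levels == den_level].mean()
    return float(np.log2(num / den))


def associate(
    lfq: pd.DataFrame,
    metadata: pd.DataFrame,
    proteins=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-protein donor-effect GLMs over an LFQ matrix.

    ``proteins`` restricts the analysis (e.g. to the kinetically secreted
    list intersected with the label-free identifications).  Returns one row
    per protein: ``n_used``, per-predictor coefficient/p/q columns, log2
    fold changes for the categorical predictors, and a ``converged`` flag.
    """
    if proteins is not None:
        proteins = [p for p in proteins if p in lfq.index]
        lfq = lfq.loc[proteins]
    design = build_design(metadata)
    missing = [s for s in lfq.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")

    rows = []
    for protein_id, values in lfq.iterrows():
        res = fit_gamma_glm(values, design=design, protein_id=protein_id)
        row = {"protein_id": protein_id, "n_used": res.n_used, "converged": res.converged}
        for pred in PREDICTORS:
            row[f"b_{pred}"] = res.coefficients.get(pred, np.nan)
            row[f"p_{pred}"] = res.p_values.get(pred, np.nan)
        if res.converged:
            row["log2fc_tissue"] = compute_log2fc(values, metadata, "tissue")
            row["log2fc_sex"] = compute_log2fc(values, metadata, "sex")
        else:
            row["log2fc_tissue"] = np.nan
            row["log2fc_sex"] = np.nan
        rows.append(row)
    results = pd.DataFrame(rows).set_index("protein_id")
    if adjust:
        results = protein_family_adjust(results)
    return results


def protein_family_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment per predictor family (one predictor across all proteins)."""
    out = results.copy()
    for pred in PREDICTORS:
        pcol = f"p_{pred}"
        if pcol not in out.columns:
            continue
        qcol = f"q_{pred}"
        out[qcol] = np.nan
        tested = out[pcol].notna()
        if tested.any():
            out.loc[tested, qcol] = bh_adjust(out.loc[tested, pcol].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Orthogonal assays
# ---------------------------------------------------------------------------

def fit_lmm_activity(measurements: pd.DataFrame) -> dict:
    """Random-intercept model for the enzymatic-activity time course.

    Fits ``response ~ time_min + age_years + time_min:age_years`` with a
    per-donor random intercept by maximum likelihood.  When the estimated
    random-intercept variance is effectively zero (singular fit) the model
    degenerates to ordinary least squares, which is then reported with a
    warning.

    Returns a dict with ``coefficients``, ``std_errors``, ``p_values``
    (keys: intercept, time, age, time_age), ``random_intercept_var``,
    ``method`` ('mixed' or 'ols').
    """
    df = measurements.copy()
    for col in ("donor_id", "time_min", "age_years", "response"):
        if col not in df.columns:
            raise ValueError(f"measurements missing column {col!r}")
    if df.groupby("donor_id")["time_min"].nunique().min() < 2:
        raise ValueError("each donor needs at least 2 time points")
    if df["donor_id"].nunique() < 5:
        raise ValueError("need at least 5 donors")
    df["time_age"] = df["time_min"] * df["age_years"]
    exog = sm.add_constant(df[["time_min", "age_years", "time_age"]])
    names = ("intercept", "time", "age", "time_age")

    method = "mixed"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["response"], exog, groups=df["donor_id"])
        try:
            fit = model.fit(reml=False)
            re_var = float(np.asarray(fit.cov_re).squeeze())
        except Exception:
            fit, re_var = None, 0.0
    resid_var = float(fit.scale) if fit is not None else float("nan")
    if fit is None or not np.isfinite(re_var) or re_var <= 1e-8 * max(resid_var, 1e-12):
        warnings.warn("singular random-intercept variance; reporting OLS fixed effects")
        ols = sm.OLS(df["response"], exog).fit()
        params, bse, pvals = ols.params, ols.bse, ols.pvalues
        method, re_var = "ols", 0.0
    else:
        params = fit.params[: len(names)]
        bse = fit.bse[: len(names)]
        pvals = fit.pvalues[: len(names)]
    return {
        "coefficients": dict(zip(names, map(float, params))),
        "std_errors": dict(zip(names, map(float, bse))),
        "p_values": dict(zip(names, map(float, pvals))),
        "random_intercept_var": re_var,
        "method": method,
        "n_donors": int(df["donor_id"].nunique()),
        "n_obs": int(len(df)),
    }


def delta_response(
    measurements: pd.DataFrame, t_late: float = 30.0, t_early: float = 10.0
) -> pd.DataFrame:
    """Per-donor late-minus-early response difference (the delta-RFU summary)."""
    df = measurements.set_index(["donor_id", "time_min"])["response"].unstack()
    delta = (df[t_late] - df[t_early]).rename("delta_response").reset_index()
    covars = measurements.drop_duplicates("donor_id")[
        [c for c in ("donor_id", "age_years", "sex", "tissue") if c in measurements.columns]
    ]
    return delta.merge(covars, on="donor_id")


def fit_concentration_glm(measurements: pd.DataFrame) -> AssociationResult:
    """Gamma GLM of an assayed concentration on donor age, sex and tissue.

    Uses the identical machinery as the per-protein abundance models; the
    response column is ``response`` (e.g. pg/mL), one row per donor.
    """
    meta = measurements.rename(columns={"donor_id": "sample_id"})
    y = pd.Series(
        measurements["response"].to_numpy(dtype=float),
        index=meta["sample_id"].to_numpy(),
    )
    return fit_gamma_glm(y, metadata=meta, protein_id="concentration")
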