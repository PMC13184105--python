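"""Band-power extraction, mixed-effects models, and clinical associations.

Band power is the mean dB value over a band's frequencies, time window, and
electrode set, one scalar per subject x site.  The group x site linear mixed
model (random subject intercept, age and antipsychotic covariates) tests
whether the regional differentiation of the TMS response differs between
groups; Spearman rank correlations with Benjamini-Hochberg correction probe
symptom associations within the clinical group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bands import BandWindow, band_mean, roi_average

__all__ = [
    "extract_band_power",
    "LmmSummary",
    "fit_group_site_lmm",
    "fit_comorbidity_lmm",
    "spearman_fdr",
]

CLINICAL_COLS = (
    "age", "antipsychotic", "mood_comorbidity",
    "P1", "P2", "P3", "P4", "P5", "N1", "N2", "N3", "N4", "N5", "N6",
    "COPER", "COGDIS", "SOFAS", "AVLT_first", "AVLT_total", "AVLT_delay", "DSST",
)


# ---------------------------------------------------------------------------
# band power extraction
# ---------------------------------------------------------------------------

def extract_band_power(
    tf_maps: dict,
    band: BandWindow,
    electrodes,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean band power per subject x site, in long format.

    Parameters
    ----------
    tf_maps : mapping ``subject -> {site -> TFMap}``
        dB-scaled, time-binned, channel-resolved maps on a common grid.
    band : BandWindow
        Frequency range and time window to average over.
    electrodes : sequence of str, or mapping ``site -> str``
        Fixed electrode set (theta) or one selected electrode per site
        (gamma).
    clinical : DataFrame, optional
        Per-subject covariates/items merged on ``subject``.
    """
    rows = []
    for subject, by_site in tf_maps.items():
        for site, tf in by_site.items():
            if isinstance(electrodes, dict):
                elec = [electrodes[site]]
            else:
                elec = list(electrodes)
            roi = roi_average(tf, elec) if tf.channels is not None else tf
            rows.append(
                {
                    "subject": subject,
                    "group": tf.group,
                    "site": site,
                    "band": band.name,
                    "mean_power": float(band_mean(roi, band)),
                }
            )
    if not rows:
        raise ValueError("no maps supplied")
    table = pd.DataFrame(rows)
    if not np.isfinite(table["mean_power"]).all():
        raise ValueError("non-finite band power encountered")
    if clinical is not None:
        cols = ["subject"] + [c for c in CLINICAL_COLS if c in clinical.columns]
        table = table.merge(clinical[cols], on="subject", how="left")
    return table


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LmmSummary:
    """Fixed-effect table plus variance components of one mixed-model fit."""

    coefficients: pd.DataFrame   # index: term; columns: estimate, se, t, df, p
    subject_var: float
    resid_var: float
    conditional_r2: float        # NaN when undefined
    converged: bool
    singular: bool
    df_method: str
    formula: str
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def find_term(self, *substrings: str) -> str:
        """The unique coefficient term containing all given substrings."""
        hits = [
            t for t in self.coefficients.index
            if all(s in t for s in substrings)
        ]
        if len(hits) != 1:
            raise KeyError(f"{substrings} matched {len(hits)} terms: {hits}")
        return hits[0]


def _fit_lmm(table: pd.DataFrame, factor: str, reference: str,
             site_reference: str) -> LmmSummary:
    req = ["mean_power", factor, "site", "age", "antipsychotic", "subject"]
    missing = [c for c in req if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing covariate column(s): {', '.join(missing)}")
    data = table.dropna(subset=req).copy()
    if data[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    for g in data[factor].unique():
        if data.loc[data[factor] == g, "subject"].nunique() < 2:
            raise ValueError(f"level {g!r} of {factor!r} has fewer than 2 subjects")
    if set(data["site"].unique()) != set(table["site"].unique()):
        raise ValueError("all sites must be present after dropping missing rows")
    data["antipsychotic"] = data["antipsychotic"].astype(int)
    if data[factor].dtype == bool:
        data[factor] = data[factor].astype(int)
        fac_term = factor
    else:
        fac_term = f"C({factor}, Treatment('{reference}'))"
    # constant covariates (e.g. no medicated subject in the subset) would
    # make the design singular; drop them rather than fail
    covariates = [c for c in ("age", "antipsychotic") if data[c].nunique() > 1]
    formula = f"mean_power ~ {fac_term} * C(site, Treatment('{site_reference}'))"
    if covariates:
        formula += " + " + " + ".join(covariates)

    singular = False
    response_degenerate = np.allclose(data["mean_power"].var(ddof=0), 0.0)
    if response_degenerate:
        # a constant response carries no information: report zero effects,
        # flag the fit, leave R^2 undefined
        model = smf.mixedlm(formula, data=data, groups=data["subject"])
        names = model.exog_names
        coefs = pd.DataFrame(
            {"estimate": 0.0, "se": np.nan, "t": np.nan,
             "df": float(max(len(data) - len(names), 1)), "p": np.nan},
            index=pd.Index(names, name="term"),
        )
        return LmmSummary(
            coefficients=coefs, subject_var=0.0, resid_var=0.0,
            conditional_r2=float("nan"), converged=False, singular=True,
            df_method="residual", formula=formula, n_obs=len(data),
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=data, groups=data["subject"])
        try:
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        except Exception:
            fit = model.fit(reml=True, method="powell")
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
                singular = True

    fe = fit.fe_params
    bse = fit.bse_fe
    n_obs = len(data)
    df_resid = max(n_obs - len(fe), 1)
    tvals = fe / bse.replace(0.0, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    coefs = pd.DataFrame(
        {
            "estimate": fe,
            "se": bse,
            "t": tvals,
            "df": float(df_resid),
            "p": pvals,
        }
    )
    coefs.index.name = "term"

    subject_var = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    resid_var = float(fit.scale)
    var_fixed = float(np.var(model.exog @ fe.values))
    denom = var_fixed + subject_var + resid_var
    cond_r2 = (var_fixed + subject_var) / denom if denom > 0 else float("nan")

    return LmmSummary(
        coefficients=coefs,
        subject_var=subject_var,
        resid_var=resid_var,
        conditional_r2=cond_r2,
        converged=bool(fit.converged),
        singular=singular,
        df_method="residual",
        formula=formula,
        n_obs=n_obs,
    )


def fit_group_site_lmm(
    table: pd.DataFrame,
    band: str | None = None,
    site_reference: str = "lDLPFC",
) -> LmmSummary:
    """Group x site mixed model on mean band power.

    ``mean_power ~ group * site + age + antipsychotic`` with a random
    intercept per subject; reference levels HC and lDLPFC.  Reports
    estimates, standard errors, t statistics on residual degrees of freedom
    (method recorded in the summary), p-values, variance components, and
    the conditional R^2 (fixed + random variance over total).
    """
    if band is not None:
        table = table[table["band"] == band]
        if table.empty:
            raise ValueError(f"no rows for band {band!r}")
    return _fit_lmm(table, factor="group", reference="HC",
                    site_reference=site_reference)


def fit_comorbidity_lmm(
    table: pd.DataFrame,
    band: str | None = None,
    site_reference: str = "lDLPFC",
) -> LmmSummary:
    """Mood-comorbidity x site mixed model within the CHR-P group."""
    data = table[table["group"] == "CHR"]
    if band is not None:
        data = data[data["band"] == band]
    if data.empty:
        raise ValueError("no CHR rows to fit")
    if data["mood_comorbidity"].nunique() < 2:
        raise ValueError("mood_comorbidity has a single level in the CHR group")
    return _fit_lmm(data, factor="mood_comorbidity", reference="False",
                    site_reference=site_reference)


# ---------------------------------------------------------------------------
# Spearman correlations with FDR correction
# ---------------------------------------------------------------------------

def spearman_fdr(
    table: pd.DataFrame,
    items,
    alpha: float = 0.05,
    family: str = "band",
) -> pd.DataFrame:
    """Spearman rank correlations of band power with clinical items (CHR only).

    One test per (band, site, item) with pairwise deletion of missing
    values and average ranks for ties.  Benjamini-Hochberg correction is
    applied within the chosen ``family``: ``"band"`` (all site x item tests
    of one band, the default), ``"band_site"``, or ``"global"``.

    Returns a long table with rho, n, raw p, BH-adjusted p, and
    significance flags; pairs with fewer than 3 complete observations get
    ``rho = NaN`` and are excluded from the correction family.
    """
    if family not in ("band", "band_site", "global"):
        raise ValueError("family must be 'band', 'band_site' or 'global'")
    data = table[table["group"] == "CHR"]
    if data.empty:
        raise ValueError("no CHR rows")
    rows = []
    for band in sorted(data["band"].unique()):
        for site in data["site"].unique():
            sub = data[(data["band"] == band) & (data["site"] == site)]
            for item in items:
                if item not in sub.columns:
                    raise ValueError(f"item {item!r} not in table")
                pair = sub[["mean_power", item]].dropna()
                if len(pair) < 3 or pair[item].nunique() < 2:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = stats.spearmanr(pair["mean_power"], pair[item])
                rows.append(
                    {"band": band, "site": site, "item": item,
                     "rho": rho, "n": len(pair), "p": p}
                )
    out = pd.DataFrame(rows)

    out["p_fdr"] = np.nan
    if family == "global":
        groups = [np.ones(len(out), dtype=bool)]
    elif family == "band":
        groups = [(out["band"] == b).to_numpy() for b in out["band"].unique()]
    else:
        groups = [
            ((out["band"] == b) & (out["site"] == s)).to_numpy()
            for b in out["band"].unique()
            for s in out["site"].unique()
        ]
    for g in groups:
        valid = g & out["p"].notna().to_numpy()
        if valid.any():
            _, p_adj, _, _ = multipletests(out.loc[valid, "p"], alpha=alpha,
                                           method="fdr_bh")
            out.loc[valid, "p_fdr"] = p_adj
    out["sig_raw"] = out["p"] <= alpha
    out["sig_fdr"] = out["p_fdr"] < alpha
    return out
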