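"""Effect-modification models: HLA-allele x genus and antibody-titer x disease.

The question is whether a taxon's association with clinical severity is
modified by host genotype (four SLE-risk HLA class II alleles, dominant
carrier coding) or reflected in anti-Ro autoantibody titers differently in
the two disease groups.  Abundance enters as the clr value so effect sizes
are "per clr unit" and interpretable on the log-ratio scale.

* HLA x genus: logistic regression of SS/SLE-vs-Asym/UAS (anti-Ro mothers
  only; default) or a proportional-odds model over all three groups, with
  clr, carrier, and their product; the interaction odds ratio is
  exp(product-term coefficient) with a Wald 95% CI.
* titer x disease: linear model of titer on clr, disease group, and their
  product among anti-Ro mothers; per-group fitted lines are returned for
  interaction plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import (
    HLA_COLUMNS,
    TITER_COLUMNS,
    CountTable,
    SampleMetadata,
    ValidationError,
)
from .transforms import DEFAULT_PSEUDOCOUNT, clr

_Z95 = stats.norm.ppf(0.975)


@dataclass
class HlaInteraction:
    allele: str
    taxon_id: str
    interaction_p: float
    log_or: float
    odds_ratio: float
    ci95: tuple[float, float]
    overall_mean_abundance: float
    estimable: bool = True
    note: str = ""


@dataclass
class TiterInteraction:
    titer_name: str
    taxon_id: str
    interaction_p: float
    slope_asym_uas: float
    slope_ss_sle: float
    predicted_lines: dict  # group -> (intercept, slope) in clr space
    n_used: int = 0


def _clr_column(ct: CountTable, taxon_id: str, pseudocount: float) -> pd.Series:
    if taxon_id not in ct.data.columns:
        raise ValidationError(f"taxon {taxon_id!r} not in count table")
    return clr(ct, pseudocount)[taxon_id]


def hla_by_genus(
    ct: CountTable,
    md: SampleMetadata,
    allele: str,
    taxon_id: str,
    outcome_coding: str = "binary_ssle_vs_asym",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> HlaInteraction:
    """Test whether carrying an HLA risk allele modifies a taxon's effect.

    Complete separation or a singular fit is reported as non-estimable
    (``estimable=False`` with NaN statistics), never raised.
    """
    if allele not in HLA_COLUMNS:
        raise ValueError(f"allele must be one of {HLA_COLUMNS}, got {allele!r}")
    x = _clr_column(ct, taxon_id, pseudocount)
    mean_ab = float(
        (ct.data[taxon_id] / ct.data.sum(axis=1)).mean()
    )
    dat = md.data.reindex(x.index).copy()
    dat["clr"] = x
    if outcome_coding == "binary_ssle_vs_asym":
        dat = dat[dat["group"].isin(["ASYM_UAS", "SS_SLE"])]
    elif outcome_coding != "ordinal3":
        raise ValueError(f"unknown outcome_coding {outcome_coding!r}")
    carrier = dat[allele]
    n_nonmissing = carrier.notna().sum()
    if len(dat) == 0 or n_nonmissing / len(dat) < 0.8:
        raise ValidationError(
            f"allele {allele}: carrier status missing for more than 20% of samples"
        )
    keep = carrier.notna()
    dat = dat[keep]
    carrier = carrier[keep].astype(float)
    if carrier.nunique() < 2:
        raise ValidationError(f"allele {allele}: a carrier stratum is empty")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "clr": dat["clr"],
            "carrier": carrier,
            "clr_x_carrier": dat["clr"] * carrier,
        }
    )
    try:
        if outcome_coding == "binary_ssle_vs_asym":
            yv = (dat["group"] == "SS_SLE").astype(float)
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
            est = fit.params["clr_x_carrier"]
            se = fit.bse["clr_x_carrier"]
            p = fit.pvalues["clr_x_carrier"]
        else:
            from statsmodels.miscmodels.ordinal_model import OrderedModel

            yv = pd.Categorical(
                dat["group"], categories=["HC", "ASYM_UAS", "SS_SLE"], ordered=True
            )
            fit = OrderedModel(
                yv, X.drop(columns="const"), distr="logit"
            ).fit(method="bfgs", disp=0, maxiter=500)
            est = fit.params["clr_x_carrier"]
            se = fit.bse["clr_x_carrier"]
            p = fit.pvalues["clr_x_carrier"]
        if not (np.isfinite(est) and np.isfinite(se) and se > 0 and se < 1e3):
            raise np.linalg.LinAlgError("degenerate fit")
    except Exception as exc:  # separation / singular design
        return HlaInteraction(
            allele, taxon_id, np.nan, np.nan, np.nan, (np.nan, np.nan),
            mean_ab, estimable=False, note=f"non-estimable: {exc}",
        )
    lo, hi = est - _Z95 * se, est + _Z95 * se
    return HlaInteraction(
        allele, taxon_id, float(p), float(est), float(np.exp(est)),
        (float(np.exp(lo)), float(np.exp(hi))), mean_ab,
    )


def titer_by_disease(
    ct: CountTable,
    md: SampleMetadata,
    titer_name: str,
    taxon_id: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_titer: bool = False,
) -> TiterInteraction:
    """Linear titer ~ clr * disease-group interaction among anti-Ro mothers."""
    if titer_name not in TITER_COLUMNS:
        raise ValueError(f"titer must be one of {TITER_COLUMNS}, got {titer_name!r}")
    x = _clr_column(ct, taxon_id, pseudocount)
    dat = md.data.reindex(x.index).copy()
    dat["clr"] = x
    dat = dat[dat["group"].isin(["ASYM_UAS", "SS_SLE"])]
    dat = dat[dat[titer_name].notna()]
    for g in ("ASYM_UAS", "SS_SLE"):
        if (dat["group"] == g).sum() < 3:
            raise ValidationError(f"group {g} has < 3 samples with {titer_name}")
    y = dat[titer_name].astype(float)
    if log_titer:
        y = np.log1p(y)
    ss = (dat["group"] == "SS_SLE").astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "clr": dat["clr"],
            "ss_sle": ss,
            "clr_x_ss_sle": dat["clr"] * ss,
        }
    )
    fit = sm.OLS(y, X).fit()
    b = fit.params
    slope_asym = float(b["clr"])
    slope_ss = float(b["clr"] + b["clr_x_ss_sle"])
    lines = {
        "ASYM_UAS": (float(b["const"]), slope_asym),
        "SS_SLE": (float(b["const"] + b["ss_sle"]), slope_ss),
    }
    return TiterInteraction(
        titer_name, taxon_id, float(fit.pvalues["clr_x_ss_sle"]),
        slope_asym, slope_ss, lines, n_used=len(dat),
    )


def screen_interactions(
    ct: CountTable,
    md: SampleMetadata,
    candidate_taxa,
    alleles=HLA_COLUMNS,
    titers=TITER_COLUMNS,
    alpha_report: float = 0.05,
    outcome_coding: str = "binary_ssle_vs_asym",
    adjust_fdr: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All allele x taxon and titer x taxon models over a candidate set.

    Candidates are meant to be the FDR-significant taxa from the
    differential module.  No multiplicity adjustment by default (the
    reporting threshold is descriptive); ``adjust_fdr=True`` adds a BH
    column per screen.  Returns (hla_table, titer_table) sorted by p.
    """
    candidate_taxa = list(candidate_taxa)
    if not candidate_taxa:
        raise ValidationError("candidate taxon set is empty")
    hla_rows, titer_rows = [], []
    for taxon in candidate_taxa:
        for allele in alleles:
            r = hla_by_genus(ct, md, allele, taxon,
                             outcome_coding=outcome_coding,
                             pseudocount=pseudocount)
            hla_rows.append(
                {
                    "allele": r.allele, "taxon_id": r.taxon_id,
                    "interaction_p": r.interaction_p,
                    "odds_ratio": r.odds_ratio,
                    "ci95_low": r.ci95[0], "ci95_high": r.ci95[1],
                    "overall_mean_abundance": r.overall_mean_abundance,
                    "estimable": r.estimable,
                }
            )
        for titer in titers:
            r = titer_by_disease(ct, md, titer, taxon, pseudocount=pseudocount)
            titer_rows.append(
                {
                    "titer": r.titer_name, "taxon_id": r.taxon_id,
                    "interaction_p": r.interaction_p,
                    "slope_asym_uas": r.slope_asym_uas,
                    "slope_ss_sle": r.slope_ss_sle,
                    "n_used": r.n_used,
                }
            )
    hla_cols = ["allele", "taxon_id", "interaction_p", "odds_ratio",
                "ci95_low", "ci95_high", "overall_mean_abundance", "estimable"]
    titer_cols = ["titer", "taxon_id", "interaction_p", "slope_asym_uas",
                  "slope_ss_sle", "n_used"]
    hla_tab = pd.DataFrame(hla_rows, columns=hla_cols)
    titer_tab = pd.DataFrame(titer_rows, columns=titer_cols)
    for tab in (hla_tab, titer_tab):
        if adjust_fdr and len(tab):
            ok = tab["interaction_p"].notna()
            tab["p_fdr"] = np.nan
            tab.loc[ok, "p_fdr"] = bh_like(tab.loc[ok, "interaction_p"])
        tab["flagged"] = tab["interaction_p"] < alpha_report
        tab.sort_values("interaction_p", inplace=True)
    return hla_tab, titer_tab


def bh_like(p: pd.Series) -> np.ndarray:
    from .differential import bh_fdr

    return bh_fdr(p.to_numpy())
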