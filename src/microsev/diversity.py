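"""Alpha diversity (Shannon H in nats, effective number e^H) and group tests.

H is computed on closed proportions without pseudocount: zero-abundance taxa
contribute nothing, and e^H is the "effective number" of equally abundant
taxa, bounded by the observed richness of the sample.  Group comparisons are
a two-group Welch t-test (optionally batch-adjusted through a linear model)
and an ordinal three-group trend test with severity scores HC=-1,
Asym/UAS=0, SS/SLE=+1 plus a sequencing-batch covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS, CountTable, SampleMetadata, TaxonomyTable, ValidationError  # noqa: F401
from .transforms import aggregate_to_level, relative_abundance


@dataclass
class DiversityTest:
    level: str
    contrast: str  # "two_group" | "three_group_ordinal"
    estimate: float
    p_value: float


def shannon(
    ct: CountTable,
    tax: TaxonomyTable | None = None,
    level: str | None = None,
) -> pd.DataFrame:
    """Per-sample Shannon entropy H = -sum p ln p and e^H.

    If ``level`` is given the table is first aggregated there (requires a
    taxonomy).  Returns a DataFrame indexed by sample id with columns
    ``level``, ``H``, ``eH``.
    """
    if level is not None:
        if tax is None:
            raise ValueError("aggregating to a level requires a taxonomy")
        ct = aggregate_to_level(ct, tax, level)
    p = relative_abundance(ct).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    h = np.maximum(h, 0.0)  # clip -0.0 / roundoff
    return pd.DataFrame(
        {"level": level or "", "H": h, "eH": np.exp(h)}, index=ct.data.index
    )


def _batch_design(batch: pd.Series) -> np.ndarray:
    d = pd.get_dummies(batch.astype(str), drop_first=True, dtype=float)
    return d.to_numpy()


def _lm_t_p(y: np.ndarray, X: np.ndarray, coef_idx: int) -> tuple[float, float]:
    """OLS of y on X; (coefficient, two-sided t p-value) for one column."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - rank
    if dof <= 0:
        raise ValidationError("not enough samples for the linear model")
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[coef_idx, coef_idx])
    if se == 0:
        return float(beta[coef_idx]), 1.0
    t = beta[coef_idx] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[coef_idx]), float(p)


def diversity_two_group_test(
    dr: pd.DataFrame,
    md: SampleMetadata,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    batch_adjust: bool = False,
    equal_var: bool = False,
) -> DiversityTest:
    """Compare mean H between two (possibly pooled) groups.

    Default is a Welch t-test; ``batch_adjust`` switches to a linear model
    of H on the group indicator plus sequencing-batch dummies.
    """
    ga = (group_a,) if isinstance(group_a, str) else tuple(group_a)
    gb = (group_b,) if isinstance(group_b, str) else tuple(group_b)
    grp = md.group.reindex(dr.index)
    in_a = grp.isin(ga).to_numpy()
    in_b = grp.isin(gb).to_numpy()
    ha, hb = dr["H"].to_numpy()[in_a], dr["H"].to_numpy()[in_b]
    if len(ha) < 2 or len(hb) < 2:
        raise ValidationError("each group needs >= 2 samples")
    level = str(dr["level"].iloc[0])
    if batch_adjust:
        sel = in_a | in_b
        y = dr["H"].to_numpy()[sel]
        ind = in_b[sel].astype(float)
        B = _batch_design(md.batch.reindex(dr.index)[sel])
        X = np.column_stack([np.ones(len(y)), ind, B])
        est, p = _lm_t_p(y, X, 1)
        return DiversityTest(level, "two_group", est, p)
    t, p = stats.ttest_ind(hb, ha, equal_var=equal_var)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0
    return DiversityTest(level, "two_group", float(np.mean(hb) - np.mean(ha)), float(p))


def diversity_ordinal_test(
    dr: pd.DataFrame, md: SampleMetadata, batch_adjust: bool = True
) -> DiversityTest:
    """Trend of H across HC < Asym/UAS < SS/SLE via the (-1, 0, 1) contrast."""
    grp = md.group.reindex(dr.index)
    missing = [g for g in GROUPS if g not in set(grp)]
    if missing:
        raise ValidationError(f"ordinal test needs all three groups; missing {missing}")
    y = dr["H"].to_numpy(dtype=float)
    score = md.severity_score().reindex(dr.index).to_numpy(dtype=float)
    cols = [np.ones(len(y)), score]
    if batch_adjust:
        B = _batch_design(md.batch.reindex(dr.index))
        if B.shape[1]:
            cols.append(B)
    X = np.column_stack(cols)
    est, p = _lm_t_p(y, X, 1)
    return DiversityTest(str(dr["level"].iloc[0]), "three_group_ordinal", est, p)


def diversity_table(
    ct: CountTable, tax: TaxonomyTable, md: SampleMetadata,
    levels: Sequence[str] = ("phylum", "class", "order", "family", "genus", "species"),
) -> pd.DataFrame:
    """Per-level summary: group mean +/- SD of H (e^H) and the three tests."""
    rows = []
    for level in levels:
        dr = shannon(ct, tax, level)
        row: dict[str, object] = {"level": level}
        for g in GROUPS:
            h = dr["H"][md.group.reindex(dr.index) == g]
            row[f"{g}_H_mean"] = h.mean()
            row[f"{g}_H_sd"] = h.std(ddof=1)
            row[f"{g}_eH"] = float(np.exp(h.mean()))
        row["p_hc_vs_antiro"] = diversity_two_group_test(
            dr, md, "HC", ("ASYM_UAS", "SS_SLE")
        ).p_value
        row["p_ordinal3"] = diversity_ordinal_test(dr, md).p_value
        row["p_asym_vs_ssle"] = diversity_two_group_test(
            dr, md, "ASYM_UAS", "SS_SLE"
        ).p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")
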