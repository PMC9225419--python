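"""Per-taxon rank-based GLM tests and the taxonomic stepdown (TSD) procedure.

Each taxon's clr-transformed abundance is rank-transformed within taxon
(the clr values are not reliably conditionally normal), then regressed on a
severity contrast plus sequencing-batch dummies:

* ``ordinal3`` — single-df trend on the severity score (HC=-1, Asym/UAS=0,
  SS/SLE=+1); p from the score coefficient's t-test.
* ``discrete3`` — two group indicators; p from the 2-df F-test, agnostic to
  ordering.
* ``two_group`` — one indicator for an arbitrary (possibly pooled) split,
  e.g. HC vs all anti-Ro positive mothers.

Within a comparison family, p-values are Benjamini-Hochberg adjusted.  The
TSD exploits the taxonomic hierarchy: all phyla are tested with BH across
phyla; the classes *within* each FDR-significant phylum are then tested with
BH within that sibling set only, and so on down to species.  Gating narrows
the hypothesis space, never widening it relative to flat testing.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GROUPS, RANKS, CountTable, SampleMetadata, TaxonomyTable, ValidationError
from .transforms import (
    DEFAULT_PSEUDOCOUNT,
    aggregate_by_path,
    aggregate_to_level,
    clr,
    rank_columns,
    relative_abundance,
)

logger = logging.getLogger("microsev")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _design(
    md: SampleMetadata,
    samples: pd.Index,
    contrast: str,
    batch: bool,
    two_group: tuple | None,
) -> tuple[np.ndarray, np.ndarray | None, int, int]:
    """(full design, reduced design for F-test, coef index, n df tested)."""
    grp = md.group.reindex(samples)
    n = len(samples)
    cols = [np.ones(n)]
    if contrast == "ordinal3":
        missing = [g for g in GROUPS if g not in set(grp)]
        if missing:
            raise ValidationError(f"ordinal3 requires all groups; missing {missing}")
        cols.append(md.severity_score().reindex(samples).to_numpy(float))
        test_cols, q = [1], 1
    elif contrast == "discrete3":
        missing = [g for g in GROUPS if g not in set(grp)]
        if missing:
            raise ValidationError(f"discrete3 requires all groups; missing {missing}")
        cols.append((grp == "ASYM_UAS").to_numpy(float))
        cols.append((grp == "SS_SLE").to_numpy(float))
        test_cols, q = [1, 2], 2
    elif contrast == "two_group":
        if two_group is None:
            raise ValueError("two_group contrast needs the (group_a, group_b) pair")
        ga, gb = two_group
        ga = (ga,) if isinstance(ga, str) else tuple(ga)
        gb = (gb,) if isinstance(gb, str) else tuple(gb)
        if not grp.isin(ga).any() or not grp.isin(gb).any():
            raise ValidationError("both groups of the two_group contrast must be present")
        cols.append(grp.isin(gb).to_numpy(float))
        test_cols, q = [1], 1
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if batch:
        b = pd.get_dummies(md.batch.reindex(samples).astype(str),
                           drop_first=True, dtype=float)
        for j in range(b.shape[1]):
            cols.append(b.iloc[:, j].to_numpy())
    X = np.column_stack(cols)
    Xr = np.delete(X, test_cols, axis=1) if q > 1 else None
    return X, Xr, test_cols[0], q


def _ols_many(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of every column of Y on shared X: (betas k x m, rss m, rank)."""
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    return B, rss, int(np.linalg.matrix_rank(X))


def taxon_test(
    clr_ranks: pd.DataFrame,
    md: SampleMetadata,
    contrast: str = "ordinal3",
    batch: bool = True,
    two_group: tuple | None = None,
    level: str = "",
) -> pd.DataFrame:
    """Rank-GLM test for every taxon column; BH-adjusted within the call.

    Returns a DataFrame indexed by taxon id with ``estimate``, ``p_value``,
    ``p_fdr``, ``direction`` (sign of the estimate), ``contrast``, ``level``.
    Taxa with all-tied ranks get p = 1 (family size stays fixed).
    """
    if contrast == "two_group" and two_group is not None:
        ga, gb = two_group
        ga = (ga,) if isinstance(ga, str) else tuple(ga)
        gb = (gb,) if isinstance(gb, str) else tuple(gb)
        keep = md.group.reindex(clr_ranks.index).isin(ga + gb)
        clr_ranks = clr_ranks.loc[keep.to_numpy()]
    X, Xr, ci, q = _design(md, clr_ranks.index, contrast, batch, two_group)
    Y = clr_ranks.to_numpy(dtype=float)
    n, m = Y.shape
    B, rss, rank = _ols_many(Y, X)
    dof = n - rank
    if dof <= 0:
        raise ValidationError("not enough samples for the rank GLM")
    const = np.ptp(Y, axis=0) == 0
    s2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    est = B[ci]
    if q == 1:
        se = np.sqrt(np.maximum(s2 * xtx_inv[ci, ci], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2 * stats.t.sf(np.abs(t), dof)
    else:
        _, rss_r, _ = _ols_many(Y, Xr)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_r - rss) / q) / np.where(s2 > 0, s2, np.inf)
        f = np.maximum(f, 0.0)
        p = stats.f.sf(f, q, dof)
    p = np.where(const, 1.0, p)
    est = np.where(const, 0.0, est)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} taxa with constant ranks set to p = 1",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "estimate": est,
            "p_value": np.clip(p, 0.0, 1.0),
            "direction": np.sign(est),
            "contrast": contrast,
            "level": level,
        },
        index=clr_ranks.columns,
    )
    out["p_fdr"] = bh_fdr(out["p_value"].to_numpy())
    out.index.name = "taxon_id"
    return out


def _level_pvalues(
    ct: CountTable,
    tax: TaxonomyTable,
    md: SampleMetadata,
    level: str,
    contrast: str,
    batch: bool,
    pseudocount: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Path-keyed per-node unadjusted p-values at one level, plus node table."""
    agg, nodes = aggregate_by_path(ct, tax, level)
    ranks = rank_columns(clr(agg, pseudocount))
    res = taxon_test(ranks, md, contrast=contrast, batch=batch, level=level)
    return res, nodes


def tsd(
    ct: CountTable,
    tax: TaxonomyTable,
    md: SampleMetadata,
    contrast: str = "ordinal3",
    alpha: float = 0.05,
    start_level: str = "phylum",
    batch: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Taxonomic stepdown: gated hierarchical testing from ``start_level``.

    All nodes at the start level form one BH family; a node whose adjusted
    p < alpha opens its gate, and only its children are tested at the next
    level, BH-adjusted within that sibling set.  Returns every *tested* node
    (path-keyed) with ``p_value``, ``p_fdr_within_gate``, ``gate_open``,
    ``parent_id``, ``name``, ``level``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if start_level not in RANKS:
        raise ValueError(f"start_level must be one of {RANKS}")
    levels = RANKS[RANKS.index(start_level):]
    rows: list[pd.DataFrame] = []
    open_parents: set[str] | None = None  # None = root gate (test everything)
    for level in levels:
        res, nodes = _level_pvalues(ct, tax, md, level, contrast, batch, pseudocount)
        if open_parents is None:
            families = {"": list(res.index)}
        else:
            tested = nodes.index[nodes["parent"].isin(open_parents)]
            if len(tested) == 0:
                break
            families = {
                parent: list(grp.index)
                for parent, grp in nodes.loc[tested].groupby("parent")
            }
        level_rows = []
        for parent, members in families.items():
            fam = res.loc[members, ["p_value"]].copy()
            fam["p_fdr_within_gate"] = bh_fdr(fam["p_value"].to_numpy())
            fam["gate_open"] = fam["p_fdr_within_gate"] < alpha
            fam["parent_id"] = parent
            level_rows.append(fam)
        lv = pd.concat(level_rows)
        lv["name"] = nodes.loc[lv.index, "name"]
        lv["level"] = level
        rows.append(lv)
        open_parents = set(lv.index[lv["gate_open"]])
        if not open_parents:
            break
    out = pd.concat(rows) if rows else pd.DataFrame(
        columns=["p_value", "p_fdr_within_gate", "gate_open", "parent_id",
                 "name", "level"]
    )
    out.index.name = "taxon_id"
    _check_gate_consistency(out, start_level)
    return out


def _check_gate_consistency(result: pd.DataFrame, start_level: str) -> None:
    """Structural invariant: every emitted node's ancestor gates are open."""
    open_ids = set(result.index[result["gate_open"]]) if len(result) else set()
    for tid, row in result.iterrows():
        if row["level"] == start_level:
            continue
        if row["parent_id"] not in open_ids:
            raise AssertionError(
                f"TSD invariant violated: {tid} tested under closed gate "
                f"{row['parent_id']}"
            )


def summarize_level(
    ct: CountTable,
    tax: TaxonomyTable,
    md: SampleMetadata,
    level: str = "genus",
    alpha: float = 0.05,
    batch: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-taxon summary at one level, filtered to ordinal FDR < alpha.

    Columns: parent rank name, per-group mean +/- SD relative abundance,
    ordinal p and FDR p, pooled HC-vs-anti-Ro p, discrete 3-group p and FDR
    p, direction.  ``alpha >= 1`` keeps every taxon.
    """
    agg = aggregate_to_level(ct, tax, level)
    rel = relative_abundance(agg)
    ranks = rank_columns(clr(agg, pseudocount))
    ordinal = taxon_test(ranks, md, "ordinal3", batch=batch, level=level)
    discrete = taxon_test(ranks, md, "discrete3", batch=batch, level=level)
    pooled = taxon_test(
        ranks, md, "two_group", batch=batch,
        two_group=("HC", ("ASYM_UAS", "SS_SLE")), level=level,
    )
    li = RANKS.index(level)
    parent_rank = RANKS[li - 1] if li > 0 else None
    parent_map = {}
    if parent_rank:
        sub = tax.data[tax.data[level] != ""]
        parent_map = sub.set_index(level)[parent_rank].to_dict()
    out = pd.DataFrame(index=agg.data.columns)
    out.index.name = level
    if parent_rank:
        out[parent_rank] = [parent_map.get(t, "") for t in out.index]
    grp = md.group.reindex(agg.data.index)
    for g in GROUPS:
        sub = rel[(grp == g).to_numpy()]
        out[f"{g}_mean"] = sub.mean(axis=0)
        out[f"{g}_sd"] = sub.std(axis=0, ddof=1)
    out["p_ordinal3"] = ordinal["p_value"]
    out["p_fdr_ordinal3"] = ordinal["p_fdr"]
    out["direction"] = ordinal["direction"]
    out["p_hc_vs_antiro"] = pooled["p_value"]
    out["p_discrete3"] = discrete["p_value"]
    out["p_fdr_discrete3"] = discrete["p_fdr"]
    if alpha < 1:
        out = out[out["p_fdr_ordinal3"] < alpha]
    return out.sort_values("p_ordinal3")
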