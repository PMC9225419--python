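"""Taxonomic aggregation, abundance filtering and compositional transforms.

Count data live on the simplex, so Euclidean statistics on raw proportions
are biased; every test downstream works on a log-ratio representation.
Univariate tests use the centered log-ratio (clr), multivariate ones a
tree-structured isometric log-ratio (ilr, one balance per internal node of a
bifurcating tree over the taxa).  With uniform node weights the ilr basis is
orthonormal, so Euclidean distance between balance rows equals the Aitchison
distance between the source compositions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import RANKS, CountTable, TaxonomyTable, ValidationError

logger = logging.getLogger("microsev")

#: Half-count pseudocount added before closure when zeros are present.
DEFAULT_PSEUDOCOUNT = 0.5


def aggregate_to_level(
    ct: CountTable, tax: TaxonomyTable, level: str
) -> CountTable:
    """Sum counts of taxa sharing the same lineage value at ``level``.

    Taxa without an assignment at that level are dropped (and logged);
    output columns are the distinct lineage values at the level.
    """
    if level not in RANKS:
        raise ValueError(f"level must be one of {RANKS}, got {level!r}")
    assignable = [t for t in ct.taxon_ids if t in set(tax.assignable_at(level))]
    dropped = [t for t in ct.taxon_ids if t not in set(assignable)]
    if not assignable:
        raise ValidationError(f"no taxon assignable at level {level!r}")
    if dropped:
        logger.info(
            "aggregate_to_level(%s): dropped %d unassigned taxa", level, len(dropped)
        )
    labels = tax.data.loc[assignable, level]
    agg = ct.data[assignable].T.groupby(labels.values, sort=False).sum().T
    agg.columns = agg.columns.astype(str)
    return CountTable(agg)


def aggregate_by_path(
    ct: CountTable, tax: TaxonomyTable, level: str
) -> tuple[CountTable, pd.DataFrame]:
    """Aggregate by the full lineage *path* down to ``level``.

    Like :func:`aggregate_to_level` but columns are keyed by the joined
    ``kingdom;...;level`` path, so identical rank names under different
    parents stay distinct.  Returns the aggregated table and a node table
    (index = path) with columns ``name`` and ``parent`` (path at the rank
    above, '' for the top rank).  Used by the taxonomic stepdown.
    """
    j = RANKS.index(level)
    assignable = [t for t in ct.taxon_ids if t in set(tax.assignable_at(level))]
    if not assignable:
        raise ValidationError(f"no taxon assignable at level {level!r}")
    lin = tax.data.loc[assignable, list(RANKS[: j + 1])]
    paths = lin.apply(lambda r: ";".join(r), axis=1)
    agg = ct.data[assignable].T.groupby(paths.values, sort=False).sum().T
    nodes = pd.DataFrame(index=agg.columns.astype(str))
    nodes["name"] = [p.rsplit(";", 1)[-1] for p in nodes.index]
    nodes["parent"] = [
        p.rsplit(";", 1)[0] if ";" in p else "" for p in nodes.index
    ]
    return CountTable(agg), nodes


def drop_zero_taxa(ct: CountTable) -> CountTable:
    """Remove taxa whose total count across all samples is zero."""
    totals = ct.data.sum(axis=0)
    keep = totals[totals > 0].index
    if len(keep) == 0:
        raise ValidationError("all taxa have zero total count")
    if len(keep) == len(ct.taxon_ids):
        return ct
    logger.info("drop_zero_taxa: removed %d taxa", len(ct.taxon_ids) - len(keep))
    return CountTable(ct.data[keep])


def relative_abundance(ct: CountTable) -> pd.DataFrame:
    """Close each sample's counts to proportions."""
    m = ct.data.to_numpy(dtype=float)
    totals = m.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        i = int(np.argwhere(totals[:, 0] == 0)[0][0])
        raise ValidationError(f"sample {ct.sample_ids[i]!r} has zero total count")
    return pd.DataFrame(m / totals, index=ct.data.index, columns=ct.data.columns)


def filter_mean_relabund(ct: CountTable, threshold: float = 1e-4) -> CountTable:
    """Drop taxa whose mean relative abundance across samples is < threshold."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    means = relative_abundance(ct).mean(axis=0)
    keep = means.index[means.to_numpy() >= threshold]
    if len(keep) == 0:
        raise ValidationError("no taxa survive the mean-abundance filter")
    if len(keep) < len(ct.taxon_ids):
        logger.info(
            "filter_mean_relabund(%.2g): removed %d taxa",
            threshold, len(ct.taxon_ids) - len(keep),
        )
    return CountTable(ct.data[keep]) if len(keep) < len(ct.taxon_ids) else ct


def clr(ct: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Centered log-ratio transform: ln(x_i / g(x)) per sample.

    ``pseudocount`` is added to every count before closure; it must be
    positive if any zeros are present.  Rows of the result sum to zero.
    """
    m = ct.data.to_numpy(dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(m == 0):
        i, j = np.argwhere(m == 0)[0]
        raise ValidationError(
            f"zero count at sample {ct.sample_ids[i]!r}, taxon "
            f"{ct.taxon_ids[j]!r} requires a positive pseudocount"
        )
    m = m + pseudocount
    logm = np.log(m / m.sum(axis=1, keepdims=True))
    out = logm - logm.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=ct.data.index, columns=ct.data.columns)


def rank_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Rank samples 1..n within each column, ties getting midranks."""
    if m.shape[0] < 2:
        raise ValidationError("ranking needs >= 2 samples")
    return m.rank(axis=0, method="average")


def build_tree_from_taxonomy(
    tax: TaxonomyTable, seed: int = 0, taxa: list[str] | None = None
) -> TreeNode:
    """Bifurcating tree over taxon ids following the lineage nesting.

    Multifurcations (including same-lineage sibling taxa) are resolved into
    random cherries with a seeded RNG; branch lengths are 1.  Stands in for a
    sequence-based phylogeny when only the taxonomy is available.
    """
    rng = np.random.default_rng(seed)
    ids = list(taxa) if taxa is not None else list(tax.data.index)
    if len(ids) < 2:
        raise ValidationError("tree needs >= 2 taxa")

    def subtree(members: list[str], depth: int) -> TreeNode:
        if len(members) == 1:
            return TreeNode(name=members[0], length=1.0)
        if depth < len(RANKS):
            vals = tax.data.loc[members, RANKS[depth]]
            groups = [list(g.index) for _, g in vals.groupby(vals, sort=True)]
        else:
            groups = [[m] for m in members]
        if len(groups) == 1:
            children = (
                [subtree(groups[0], depth + 1)]
                if depth < len(RANKS)
                else [TreeNode(name=m, length=1.0) for m in groups[0]]
            )
        else:
            children = [subtree(g, depth + 1) for g in groups]
        # resolve multifurcation into a seeded random bifurcating caterpillar
        while len(children) > 2:
            i, k = sorted(rng.choice(len(children), size=2, replace=False))
            merged = TreeNode(length=1.0, children=[children[i], children[k]])
            children = [c for idx, c in enumerate(children) if idx not in (i, k)]
            children.append(merged)
        if len(children) == 1:
            return children[0]
        return TreeNode(length=1.0, children=children)

    root = subtree(ids, 0)
    root.length = None
    return root


def _node_partitions(tree: TreeNode, taxon_ids: list[str]):
    """(node name, left-leaf indices, right-leaf indices) per internal node."""
    idx = {t: i for i, t in enumerate(taxon_ids)}
    tips = {t.name for t in tree.tips()}
    if tips != set(taxon_ids):
        raise ValidationError(
            "tree leaf set does not match the table's taxa: "
            f"missing {sorted(set(taxon_ids) - tips)[:5]}, "
            f"extra {sorted(tips - set(taxon_ids))[:5]}"
        )
    parts = []
    for k, node in enumerate(tree.non_tips(include_self=True)):
        if len(node.children) != 2:
            raise ValidationError(
                "tree is not bifurcating; resolve it with build_tree_from_taxonomy"
            )
        left = [idx[t.name] for t in node.children[0].tips(include_self=True)]
        right = [idx[t.name] for t in node.children[1].tips(include_self=True)]
        name = node.name if node.name else f"n{k}"
        parts.append((name, np.array(left), np.array(right)))
    return parts


def ilr_balances(
    ct: CountTable,
    tree: TreeNode,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weighting: str = "uniform",
) -> pd.DataFrame:
    """One ilr balance per internal tree node (samples x (n_taxa - 1)).

    ``uniform``: balance = sqrt(|L||R|/(|L|+|R|)) * ln(g(x_L)/g(x_R)) with g
    the geometric mean of the closed proportions — an exact isometry of the
    Aitchison geometry.  ``mean_descendants``: each taxon weighted by its
    mean relative abundance across samples; weighted geometric means and
    weighted normalizers (down-weights rare taxa, no longer an isometry).
    """
    if weighting not in ("uniform", "mean_descendants"):
        raise ValueError(f"unknown weighting {weighting!r}")
    m = ct.data.to_numpy(dtype=float) + pseudocount
    if np.any(m <= 0):
        raise ValidationError("zero counts require a positive pseudocount")
    props = m / m.sum(axis=1, keepdims=True)
    logp = np.log(props)
    if weighting == "uniform":
        w = np.ones(m.shape[1])
    else:
        w = props.mean(axis=0)
    parts = _node_partitions(tree, ct.taxon_ids)
    cols, names = [], []
    for name, left, right in parts:
        wl, wr = w[left].sum(), w[right].sum()
        gl = logp[:, left] @ w[left] / wl
        gr = logp[:, right] @ w[right] / wr
        scale = np.sqrt(wl * wr / (wl + wr))
        cols.append(scale * (gl - gr))
        names.append(name)
    out = pd.DataFrame(np.column_stack(cols), index=ct.data.index, columns=names)
    return out


def aitchison_distance(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between clr rows (the Aitchison metric)."""
    x = clr_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("distance needs >= 2 samples")
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    d = (d + d.T) / 2
    return pd.DataFrame(d, index=clr_matrix.index, columns=clr_matrix.index)
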