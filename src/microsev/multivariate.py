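"""PCA on ilr balances and PERMANOVA on a distance matrix.

PERMANOVA follows the one-way sums-of-squares decomposition of squared
distances (Anderson's pseudo-F); the p-value uses label permutations with
the add-one rule p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), or exhaustive
enumeration over all label orderings when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    method: str = "permutation"  # or "exhaustive"
    permuted_F: np.ndarray | None = field(default=None, repr=False)


@dataclass
class PcaResult:
    scores: pd.DataFrame
    explained_fraction: np.ndarray


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    sst = d2.sum() / (2 * n)
    ssw = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        ssw += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ssa = sst - ssw
    return (ssa / (n_groups - 1)) / (ssw / (n - n_groups))


def permanova(
    d: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 19999,
    seed: int = 0,
    exhaustive: bool = False,
    keep_permuted: bool = False,
    strata=None,
) -> PermanovaResult:
    """Permutation multivariate ANOVA of group location on a distance matrix.

    ``exhaustive=True`` enumerates all n! label orderings (small n only) and
    reports the exact permutation p; otherwise ``n_perm`` seeded random
    permutations with the add-one rule.  ``strata`` (e.g. sequencing batch)
    restricts permutations to within-stratum shuffles.
    """
    dm = np.asarray(d, dtype=float) if not isinstance(d, pd.DataFrame) else d.to_numpy()
    if dm.shape[0] != dm.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10) or np.any(np.abs(np.diag(dm)) > 1e-10):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(pd.Categorical(np.asarray(labels)).codes)
    n = dm.shape[0]
    if len(labels) != n:
        raise ValidationError("labels length must match distance matrix")
    n_groups = len(np.unique(labels))
    counts = np.bincount(labels)
    if n_groups < 2 or counts.min() < 2:
        raise ValidationError(">= 2 groups with >= 2 samples each required")
    d2 = dm**2
    f_obs = _pseudo_f(d2, labels, n_groups)

    if exhaustive:
        if strata is not None:
            raise ValidationError("exhaustive enumeration does not support strata")
        fs = np.array(
            [_pseudo_f(d2, np.asarray(perm), n_groups)
             for perm in permutations(labels)]
        )
        p = float(np.mean(fs >= f_obs - 1e-12))
        return PermanovaResult(
            float(f_obs), p, factorial(n), "exhaustive",
            fs if keep_permuted else None,
        )

    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    fs = np.empty(n_perm)
    lab = labels.copy()
    if strata is not None:
        strata = np.asarray(pd.Categorical(np.asarray(strata)).codes)
        if len(strata) != n:
            raise ValidationError("strata length must match distance matrix")
        groups_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for i in range(n_perm):
        if strata is None:
            rng.shuffle(lab)
        else:
            for idx in groups_idx:
                lab[idx] = lab[idx[rng.permutation(len(idx))]]
        fs[i] = _pseudo_f(d2, lab, n_groups)
    p = (1 + int(np.sum(fs >= f_obs - 1e-12))) / (1 + n_perm)
    return PermanovaResult(
        float(f_obs), float(p), n_perm, "permutation",
        fs if keep_permuted else None,
    )


def pca(b: pd.DataFrame) -> PcaResult:
    """Column-centered SVD of a balance (or any feature) matrix."""
    x = b.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValidationError("matrix is constant; PCA undefined")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    frac = s**2 / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(pd.DataFrame(scores, index=b.index, columns=cols), frac)


def pc_association(
    pc_scores: pd.Series, covariate: pd.Series, n_pcs_tested: int = 1
) -> tuple[float, float]:
    """Association of one PC with a covariate.

    Numeric covariates: t-test of the OLS slope; binary categoricals: Welch
    t-test.  Returns (p, Bonferroni-adjusted p for ``n_pcs_tested`` PCs).
    """
    cov = covariate.reindex(pc_scores.index)
    keep = cov.notna().to_numpy()
    if not keep.any():
        raise ValidationError("covariate is entirely missing")
    y = pc_scores.to_numpy(dtype=float)[keep]
    c = cov[keep]
    if pd.api.types.is_numeric_dtype(c):
        x = c.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValidationError("covariate is constant")
        res = stats.linregress(x, y)
        p = float(res.pvalue)
    else:
        levels = pd.unique(c)
        if len(levels) != 2:
            raise ValidationError(
                f"categorical covariate must have 2 levels, got {len(levels)}"
            )
        a = y[(c == levels[0]).to_numpy()]
        bvals = y[(c == levels[1]).to_numpy()]
        p = float(stats.ttest_ind(a, bvals, equal_var=False).pvalue)
    return p, float(min(1.0, p * n_pcs_tested))
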