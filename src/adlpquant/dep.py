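"""Differential-expression calling, profile clustering, exclusive-DEP selection.

Two significance rules are used in the study design and reproduced here:

* per-contrast Student's t-test (transgenic vs age-matched wild type) with a
  dual threshold: p < 0.05 AND fold change > 1.25 in either direction;
* omnibus one-way ANOVA across user-specified (genotype, age) groups with
  Benjamini-Hochberg FDR control at 0.05.

Profiles of significant proteins are z-normalized per protein and clustered
by average-linkage hierarchical clustering on Euclidean distance.  The
"exclusive" selection keeps proteins significant in the double-pathology
(APT) model whose fold change stays below the cut-off in every
single-pathology model at the same age.

Result containers are plain DataFrames indexed by accession (one row per
protein, one frame per contrast), which keeps them directly writable as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import cluster as scipy_cluster
from scipy import stats

from ._errors import ValidationError
from .normalize import group_block

logger = logging.getLogger(__name__)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} (p_(j) * m / j)`` over the ascending order
    statistics, clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("bh_adjust requires a non-empty p-value list")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _ratio_fc(fc: np.ndarray) -> np.ndarray:
    """Symmetric fold change max(FC, 1/FC)."""
    return np.maximum(fc, 1.0 / fc)


def ttest_dep(
    matrix: pd.DataFrame,
    genotype: str,
    age_months: int,
    alpha: float = 0.05,
    fc_cut: float = 1.25,
    log2_transform: bool = False,
    equal_var: bool = True,
    two_sided_fc: bool = True,
) -> pd.DataFrame:
    """Two-sample Student's t-test of a transgenic group vs age-matched WT.

    Tests run on the normalized abundances (optionally log2-transformed);
    the fold change is always the ratio of group means on the abundance
    scale.  ``significant`` requires ``p < alpha`` and fold change beyond
    ``fc_cut`` (symmetrically, unless ``two_sided_fc`` is False, in which
    case only up-regulation counts).

    Returns a frame with columns ``contrast``, ``fold_change``, ``p_value``,
    ``significant``.
    """
    tg = group_block(matrix, genotype, age_months)
    wt = group_block(matrix, "WT", age_months)
    if tg.shape[1] < 2 or wt.shape[1] < 2:
        raise ValidationError(
            f"t-test for ({genotype}, {age_months}) needs >= 2 replicates per group"
        )
    x = tg.to_numpy(dtype=float)
    y = wt.to_numpy(dtype=float)
    fc = x.mean(axis=1) / y.mean(axis=1)
    if log2_transform:
        x, y = np.log2(x), np.log2(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    p = np.asarray(result.pvalue, dtype=float)
    degenerate = np.isnan(p)  # zero variance in both groups
    if degenerate.any():
        same = np.isclose(x.mean(axis=1), y.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    effect = _ratio_fc(fc) if two_sided_fc else fc
    significant = (p < alpha) & (effect > fc_cut)
    return pd.DataFrame(
        {
            "contrast": f"{genotype}.{age_months}_vs_WT.{age_months}",
            "fold_change": fc,
            "p_value": p,
            "significant": significant,
        },
        index=matrix.index,
    )


def anova_dep(
    matrix: pd.DataFrame,
    groups: Sequence[tuple[str, int]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per protein across (genotype, age) groups, BH-adjusted.

    The grouping is explicit (e.g. all 12 genotype x age cells, or the six
    APT/WT x age cells), mirroring how the omnibus DEP sets of the study are
    defined.  BH adjustment spans all proteins of this one call;
    ``significant`` means adjusted p < ``fdr``.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    arrays = []
    for genotype, age in groups:
        block = group_block(matrix, genotype, age)
        if block.shape[1] < 2:
            raise ValidationError(f"group ({genotype}, {age}) has < 2 replicates")
        arrays.append(block.to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows handled below
            result = stats.f_oneway(*arrays, axis=1)
    f = np.asarray(result.statistic, dtype=float)
    p = np.asarray(result.pvalue, dtype=float)
    # all observations identical in a row -> 0/0; the contract is F=0, p=1
    stacked = np.concatenate(arrays, axis=1)
    constant = np.ptp(stacked, axis=1) == 0
    f[constant] = 0.0
    p[constant] = 1.0
    adjusted = bh_adjust(p)
    return pd.DataFrame(
        {
            "f_statistic": f,
            "p_value": p,
            "adjusted_p": adjusted,
            "significant": adjusted < fdr,
        },
        index=matrix.index,
    )


def znormalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-scores across samples ((x - mean) / sample sd).

    Zero-variance rows map to all-zeros with a logged notice (they carry no
    profile shape to cluster).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("z-normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    # exact-range test: the sample sd of a constant row can round to ~1e-16
    flat = (np.ptp(values, axis=1) == 0) | (sd == 0).ravel()
    sd[flat, :] = 1.0  # placeholder; flat rows are zeroed below
    if flat.any():
        logger.info("%d zero-variance rows z-normalized to all-zeros", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k, numbered by descending size) and mean z-profiles."""

    labels: pd.Series  # accession -> cluster index
    profiles: pd.DataFrame  # cluster index x ordered samples

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def hierarchical_cluster(zmatrix: pd.DataFrame, k: int) -> ClusterAssignment:
    """Average-linkage agglomerative clustering on Euclidean distance, cut at k.

    Deterministic for a given row order (scipy's linkage breaks distance
    ties by merging the lower-index pair first).  Clusters are renumbered by
    descending size, ties by first occurrence.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(zmatrix):
        raise ValidationError(f"k={k} exceeds the {len(zmatrix)} proteins available")
    if len(zmatrix) == 1:
        raw = np.array([1])
    else:
        linkage = scipy_cluster.hierarchy.linkage(
            zmatrix.to_numpy(dtype=float), method="average", metric="euclidean"
        )
        raw = scipy_cluster.hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    counts = pd.Series(raw).value_counts()
    first_seen = {c: int(np.argmax(raw == c)) for c in counts.index}
    ordered = sorted(counts.index, key=lambda c: (-counts[c], first_seen[c]))
    remap = {old: new for new, old in enumerate(ordered, start=1)}
    labels = pd.Series([remap[c] for c in raw], index=zmatrix.index, name="cluster")
    profiles = pd.DataFrame(
        {c: zmatrix.loc[labels == c].mean(axis=0) for c in sorted(remap.values())}
    ).T
    profiles.index.name = "cluster"
    return ClusterAssignment(labels=labels, profiles=profiles)


def exclusive_deps(
    results_by_model: Mapping[str, Mapping[int, pd.DataFrame]],
    fold_changes: pd.DataFrame,
    target: str = "APT",
    ages: Sequence[int] = (4, 10),
    fc_cut: float = 1.25,
) -> set[str]:
    """Proteins significantly altered only in the target (double-pathology) model.

    A protein qualifies if, at the early or the late age, it is significant
    in the target model's t-test AND its symmetric fold change stays below
    ``fc_cut`` in every other transgenic model at that same age.
    """
    if target not in results_by_model:
        raise ValidationError(f"missing t-test results for model {target!r}")
    others = [m for m in results_by_model if m != target]
    if not others:
        raise ValidationError("exclusive selection needs at least one other model")
    for model in others:
        for age in ages:
            if (model, age) not in fold_changes.columns:
                raise ValidationError(
                    f"missing fold changes for model {model!r} at {age} months"
                )
    selected: set[str] = set()
    for age in ages:
        if age not in results_by_model[target]:
            raise ValidationError(f"missing {target} t-test results at {age} months")
        result = results_by_model[target][age]
        hits = result.index[result["significant"]]
        quiet = np.ones(len(hits), dtype=bool)
        for model in others:
            fc = fold_changes.loc[hits, (model, age)].to_numpy(dtype=float)
            quiet &= _ratio_fc(fc) < fc_cut
        selected |= set(hits[quiet])
    return selected


@dataclass(frozen=True)
class OverlapSummary:
    """Cross-study list comparison: coverage plus directional concordance."""

    n_a: int
    n_b: int
    n_shared: int
    overlap_percent: float  # % of list_b identifiers present in list_a
    concordance_percent: dict[str, float]  # per direction of list_a


def overlap_comparison(
    list_a: Mapping[str, str] | Iterable[str],
    list_b: Mapping[str, str] | Iterable[str],
) -> OverlapSummary:
    """Compare two identifier lists with optional up/down direction labels.

    ``overlap_percent`` is the share of ``list_b`` identifiers found in
    ``list_a``.  Where both lists carry directions, concordance is reported
    per direction of ``list_a`` among the shared identifiers.
    """
    a_dir = dict(list_a) if isinstance(list_a, Mapping) else {x: None for x in list_a}
    b_dir = dict(list_b) if isinstance(list_b, Mapping) else {x: None for x in list_b}
    shared = set(a_dir) & set(b_dir)
    overlap = 100.0 * len(shared) / len(b_dir) if b_dir else 0.0
    concordance: dict[str, float] = {}
    directions = {d for x, d in a_dir.items() if x in shared and d is not None}
    for direction in sorted(directions):
        in_dir = [x for x in shared if a_dir[x] == direction]
        if in_dir:
            agree = sum(1 for x in in_dir if b_dir[x] == direction)
            concordance[direction] = 100.0 * agree / len(in_dir)
    return OverlapSummary(
        n_a=len(a_dir),
        n_b=len(b_dir),
        n_shared=len(shared),
        overlap_percent=overlap,
        concordance_percent=concordance,
    )
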