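"""Abundance normalization and community ecology for vOTU / MAG tables.

Coverage depths are normalized by library size to "coverage per gigabase"
(mean depth x 1e9 / sequenced bases), occupancy is partitioned across
sample groupings (site, depth, metagenome type), and community differences
are tested with Bray-Curtis dissimilarities, classical PCoA, and a
distance-based PERMANOVA with seeded label permutations.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, the convention used for reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_coverage(
    depth: pd.DataFrame, library_bases: pd.Series | dict
) -> pd.DataFrame:
    """Normalize a feature x sample mean-depth table to coverage per gigabase.

    value = raw mean depth * 1e9 / library_bases[sample]. Features absent from
    a sample stay 0. Every depth column must have a known library size.
    """
    lib = pd.Series(library_bases, dtype=float)
    unknown = [s for s in depth.columns if s not in lib.index]
    if unknown:
        raise KeyError(f"samples with no library size: {unknown}")
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"non-positive library sizes for samples: {bad}")
    if (depth.to_numpy() < 0).any():
        raise ValueError("negative depth values")
    return depth * 1e9 / lib[depth.columns]


@dataclass(frozen=True)
class PresencePartition:
    """Occupancy of features across the groups of one sample grouping."""

    grouping: str
    n_features: int           # features present in at least one group
    n_groups: int
    in_all_groups: int
    in_one_group: int
    pct_in_all: float         # one-decimal, half-up
    pct_in_one: float
    pattern: pd.DataFrame     # feature x group boolean occupancy


def partition_presence(
    matrix: pd.DataFrame, sample_groups: pd.Series | dict, grouping: str = "group"
) -> PresencePartition:
    """Partition feature occurrence by a sample grouping (site/depth/type).

    `matrix` is feature x sample; presence means value > 0. Percentages are
    over features present in at least one group, rounded half-up to one
    decimal (the convention of reported community-overlap figures).
    """
    groups = pd.Series(sample_groups)
    missing = [s for s in matrix.columns if s not in groups.index]
    if missing:
        raise KeyError(f"samples with no group label: {missing}")
    labels = sorted(set(groups[matrix.columns]))
    if len(labels) < 2:
        raise ValueError(f"grouping '{grouping}' has a single group; nothing to partition")

    pattern = pd.DataFrame(index=matrix.index, columns=labels, dtype=bool)
    for g in labels:
        cols = [s for s in matrix.columns if groups[s] == g]
        pattern[g] = (matrix[cols] > 0).any(axis=1)

    occ = pattern.sum(axis=1)
    present = occ > 0
    n_feat = int(present.sum())
    in_all = int((occ == len(labels)).sum())
    in_one = int((occ == 1).sum())
    pct = lambda k: round_half_up(100.0 * k / n_feat) if n_feat else 0.0
    return PresencePartition(
        grouping=grouping,
        n_features=n_feat,
        n_groups=len(labels),
        in_all_groups=in_all,
        in_one_group=in_one,
        pct_in_all=pct(in_all),
        pct_in_one=pct(in_one),
        pattern=pattern.loc[present],
    )


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns) of an abundance table.

    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j). A pair of all-zero samples has
    an undefined dissimilarity; it is reported as 0 with a warning so that
    degenerate fixtures do not poison the whole matrix.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if (x < 0).any():
        raise ValueError("abundance values must be non-negative")
    n = x.shape[0]
    d = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                if not warned:
                    warnings.warn("all-zero sample pair; Bray-Curtis defined as 0", stacklevel=2)
                    warned = True
                val = 0.0
            else:
                val = float(np.abs(x[i] - x[j]).sum() / denom)
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame     # samples x retained axes
    eigenvalues: np.ndarray       # retained (non-negative) eigenvalues, descending
    n_negative: int               # axes dropped for negative eigenvalues
    proportion_explained: np.ndarray


def pcoa(distance: pd.DataFrame, k: int | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    The squared distance matrix is double-centered (Gower) and
    eigendecomposed; axes are ordered by descending eigenvalue and
    negative-eigenvalue axes are dropped and counted.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-10 * max(1.0, abs(eigval[0])) if n else 0.0
    pos = eigval > tol
    n_negative = int((eigval < -tol).sum())
    vals = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(vals)
    if k is not None:
        vals = vals[:k]
        coords = coords[:, :k]
    total = eigval[eigval > tol].sum()
    prop = vals / total if total > 0 else np.zeros_like(vals)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=distance.index, columns=cols),
        eigenvalues=vals,
        n_negative=n_negative,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's distance-based pseudo-F computed directly from squared distances."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = groups.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    if n - a == 0 or ss_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    distance: pd.DataFrame,
    labels,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), the unbiased
    permutation estimate that includes the observed statistic on both sides.
    With n_permutations="exhaustive", all distinct label orderings are
    enumerated and p = #{F >= observed} / total (the identity ordering counts
    in both numerator and denominator).
    """
    lab = pd.Series(labels)
    lab = lab[distance.index] if set(distance.index) <= set(lab.index) else lab
    y = np.asarray(lab)
    if np.unique(y).size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d = distance.to_numpy(dtype=float)
    d2 = d**2
    f_obs = _pseudo_f(d2, y)

    if n_permutations == "exhaustive":
        count = total = 0
        for perm in set(itertools.permutations(y)):
            total += 1
            if _pseudo_f(d2, np.asarray(perm)) >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(float(f_obs), count / total, total, seed)

    rng = np.random.default_rng(seed)
    n_perm = int(n_permutations)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(y)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), p, n_perm, seed)


def read_abundance_table(path) -> pd.DataFrame:
    """Abundance TSV: feature_id column then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("feature_id")


def read_metadata_table(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, site, depth_cm, type, library_bases."""
    return pd.read_csv(path, sep="\t").set_index("sample_id")
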