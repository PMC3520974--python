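"""Clustering of residues by CCSP profile similarity and group statistics.

Residues whose engaged-conformer populations move together across complexes
are coupled: their CCSP rows are similar up to noise.  Similarity is the
uncentered correlation (cosine similarity without mean-centering, the
convention of Cluster 3.0); rows are agglomerated by average linkage on the
distance 1 - similarity.  Group averages carry Student-t 95% confidence
intervals over the member residues.

The default groups are the canonical PxxP surface (SI: residues 9, 11, 25),
the specificity surface (SII: 30-32, 34, 37-39, 49, 57 plus the side-chain
NH of 36 — the backbone amide of 36 is NOT a member), and the RT-loop tip
associated with SII (SII_RT: 13, 15, 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

SeriesKey = Tuple[int, str]


@dataclass
class GroupSpec:
    """A named residue group; members are (residue_id, atom_tag) keys."""

    name: str
    members: List[SeriesKey]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")

    def member_labels(self) -> List[str]:
        return [
            f"{r}{'s' if t == 's' else ''}" for r, t in self.members
        ]


def default_groups() -> List[GroupSpec]:
    """SI / SII / SII_RT memberships for the 59-residue SH3 construct."""
    return [
        GroupSpec("SI", [(9, "bb"), (11, "bb"), (25, "bb")]),
        GroupSpec(
            "SII",
            [(30, "bb"), (31, "bb"), (32, "bb"), (34, "bb"), (36, "s"),
             (37, "bb"), (38, "bb"), (39, "bb"), (49, "bb"), (57, "bb")],
        ),
        GroupSpec("SII_RT", [(13, "bb"), (15, "bb"), (16, "bb")]),
    ]


@dataclass
class GroupAverage:
    """Mean CCSP over a residue group in one complex, with a 95% CI."""

    complex_id: str
    group: str
    mean_ccsp: float
    ci95_halfwidth: float  # NaN when undefined (single member)
    n_members_used: int


class InsufficientOverlapError(ValueError):
    """Fewer than two shared complexes after pairwise deletion."""


def uncentered_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity without mean-centering, in [-1, 1].

    Missing cells (NaN) are removed pairwise; fewer than two shared finite
    entries, or an all-zero vector, is an error.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(u) & np.isfinite(v)
    if mask.sum() < 2:
        raise InsufficientOverlapError(
            f"only {int(mask.sum())} shared finite entries"
        )
    uu = float(np.dot(u[mask], u[mask]))
    vv = float(np.dot(v[mask], v[mask]))
    if uu == 0.0 or vv == 0.0:
        raise ValueError("uncentered correlation undefined for an all-zero vector")
    return float(np.dot(u[mask], v[mask]) / np.sqrt(uu * vv))


@dataclass
class Dendrogram:
    """Average-linkage tree over CCSP rows.

    ``linkage`` is a scipy linkage matrix over ``labels``; ``excluded`` lists
    rows dropped for insufficient pairwise overlap.
    """

    labels: List[str]
    linkage: np.ndarray
    excluded: List[str] = field(default_factory=list)

    def cut(self, n_clusters: int) -> Dict[str, int]:
        """Label -> cluster id (1-based) after cutting into n_clusters."""
        assignment = hierarchy.fcluster(
            self.linkage, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        """Newick export with merge heights converted to branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(_fmt(c, node.dist) for c in
                                (node.get_left(), node.get_right()))
            return f"({children}):{length:.6g}"

        return _fmt(tree, tree.dist) + ";"


def cluster_residues(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering of CCSP rows.

    Distance between rows is 1 - uncentered correlation with pairwise
    deletion of missing cells.  Rows that share fewer than two complexes
    with every other row are excluded with a warning.
    """
    import warnings

    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    labels = list(matrix.index)
    values = matrix.to_numpy(dtype=float)

    n = len(labels)
    dist = np.zeros((n, n))
    reachable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                sim = uncentered_correlation(values[i], values[j])
            except InsufficientOverlapError:
                continue
            dist[i, j] = dist[j, i] = 1.0 - sim
            reachable[i, j] = reachable[j, i] = True

    keep = [i for i in range(n) if reachable[i].any()]
    excluded = [labels[i] for i in range(n) if i not in keep]
    if excluded:
        warnings.warn(
            f"rows excluded for insufficient overlap: {excluded}", stacklevel=2
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 clusterable rows after overlap filtering")
    sub = dist[np.ix_(keep, keep)]
    condensed = sub[np.triu_indices(len(keep), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram([labels[i] for i in keep], linkage, excluded)


def group_average(
    matrix: pd.DataFrame, spec: GroupSpec, complex_id: str
) -> Optional[GroupAverage]:
    """Mean CCSP +/- t-based 95% CI for one group in one complex.

    Returns None when no member has a value (a missing average); with a
    single member the mean is returned and the CI is NaN (undefined).
    """
    if complex_id not in matrix.columns:
        raise KeyError(f"unknown complex {complex_id!r}")
    wanted = [lab for lab in spec.member_labels() if lab in matrix.index]
    vals = matrix.loc[wanted, complex_id].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if n == 0:
        return None
    mean = float(vals.mean())
    if n == 1:
        return GroupAverage(complex_id, spec.name, mean, float("nan"), 1)
    half = float(
        stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
    )
    return GroupAverage(complex_id, spec.name, mean, half, n)


def group_average_table(
    matrix: pd.DataFrame, groups: Sequence[GroupSpec]
) -> pd.DataFrame:
    """Complex x group table of means with a parallel ci95/n in columns.

    Columns are a MultiIndex (group, field) with fields mean / ci95 / n.
    """
    records = {}
    for spec in groups:
        for cid in matrix.columns:
            ga = group_average(matrix, spec, cid)
            if ga is None:
                records[(spec.name, "mean"), cid] = np.nan
                records[(spec.name, "ci95"), cid] = np.nan
                records[(spec.name, "n"), cid] = 0
            else:
                records[(spec.name, "mean"), cid] = ga.mean_ccsp
                records[(spec.name, "ci95"), cid] = ga.ci95_halfwidth
                records[(spec.name, "n"), cid] = ga.n_members_used
    frame = pd.Series(records).unstack(level=0)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame.loc[list(matrix.columns)]


def pairwise_group_r2(
    x: Dict[str, float], y: Dict[str, float]
) -> Tuple[float, float, float]:
    """OLS fit of group-average y on x over shared complexes: (slope, intercept, R^2)."""
    shared = sorted(
        k for k in set(x) & set(y)
        if np.isfinite(x[k]) and np.isfinite(y[k])
    )
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared complexes, got {len(shared)}")
    xv = np.array([x[k] for k in shared])
    yv = np.array([y[k] for k in shared])
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ValueError("zero variance: R^2 undefined")
    fit = stats.linregress(xv, yv)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)
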