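"""Cluster-based permutation tests over channel x time(-frequency) arrays.

Paired two-condition designs: a pointwise paired t statistic is
thresholded at a two-sided cluster-forming alpha (default 0.01);
suprathreshold samples are clustered by flood-fill over temporal,
spectral and spatial (montage neighborhood) adjacency, positive and
negative clusters separately; each observed cluster mass (sum of
t-values) is compared against the permutation distribution of the
maximum cluster mass obtained by randomly sign-flipping each subject's
condition difference (the within-subject relabelling null). Monte-Carlo
p = (r + 1) / (n_permutations + 1). Cohen's d for a cluster is computed
on the subject-level means of the difference within the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

#: default montage neighborhood
DEFAULT_EDGES = (
    ("Fz", "Cz"), ("Cz", "Pz"), ("Pz", "Oz"), ("C3", "Cz"), ("Cz", "C4"),
    ("Fz", "C3"), ("Fz", "C4"), ("C3", "Pz"), ("C4", "Pz"),
)

#: Bonferroni-corrected cluster significance level for the three
#: condition contrasts (up-down, up-not, down-not)
BONFERRONI_ALPHA_3 = 0.05 / 3.0


@dataclass
class Cluster:
    sign: int                   # +1 / -1
    mass: float                 # sum of t values
    p: float
    members: np.ndarray         # indices into the flattened stat map
    cohens_d: float = np.nan


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    threshold: float
    n_permutations: int
    shape: tuple

    def significant(self, alpha=0.05):
        return [c for c in self.clusters if c.p < alpha]

    def mask(self, alpha=0.05):
        m = np.zeros(int(np.prod(self.shape)), dtype=bool)
        for c in self.significant(alpha):
            m[c.members] = True
        return m.reshape(self.shape)


def build_adjacency(channels, edges=None):
    """Symmetric channel adjacency matrix for a montage.

    ``edges`` defaults to the fronto-centro-parietal neighborhood of the
    {Fz, Cz, Pz, Oz, C3, C4} montage; unknown labels raise. A single
    channel yields the empty graph (clustering is then purely
    time/frequency adjacency).
    """
    channels = list(channels)
    if edges is None:
        edges = [e for e in DEFAULT_EDGES
                 if e[0] in channels and e[1] in channels]
    else:
        for a, b in edges:
            if a not in channels or b not in channels:
                raise ValueError(f"unknown channel in edge ({a}, {b})")
    nch = len(channels)
    adj = np.zeros((nch, nch), dtype=bool)
    for a, b in edges:
        i, j = channels.index(a), channels.index(b)
        if i == j:
            continue
        adj[i, j] = adj[j, i] = True
    return adj


def _structure_edges(shape, adjacency):
    """Sparse sample-adjacency graph for a (ch[, f], t) stat map."""
    nch = shape[0]
    grid = np.prod(shape[1:], dtype=int)
    idx = np.arange(nch * grid).reshape(shape)
    rows, cols = [], []

    def link(a, b):
        rows.append(a.ravel())
        cols.append(b.ravel())

    # temporal adjacency (last axis)
    link(idx[..., :-1], idx[..., 1:])
    # frequency adjacency (middle axis, if present)
    if len(shape) == 3:
        link(idx[:, :-1, :], idx[:, 1:, :])
    # channel adjacency
    if adjacency is not None:
        for i in range(nch):
            for j in range(i + 1, nch):
                if adjacency[i, j]:
                    link(idx[i], idx[j])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = nch * grid
    g = sparse.coo_matrix((np.ones(r.size, bool), (r, c)), shape=(n, n))
    return (g + g.T).tocsr()


def _cluster_masses(t_flat, above, graph):
    """Cluster labels and masses of the suprathreshold samples."""
    if not above.any():
        return [], []
    sub = graph[above][:, above]
    n_comp, labels = connected_components(sub, directed=False)
    members_idx = np.flatnonzero(above)
    masses = np.zeros(n_comp)
    np.add.at(masses, labels, t_flat[above])
    members = [members_idx[labels == k] for k in range(n_comp)]
    return members, masses


def _paired_t(diff_flat):
    n = diff_flat.shape[0]
    mean = diff_flat.mean(axis=0)
    sd = diff_flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _max_mass(t_flat, thr, graph):
    out = 0.0
    for sign in (1, -1):
        _, masses = _cluster_masses(sign * t_flat, sign * t_flat > thr, graph)
        if len(masses):
            out = max(out, float(np.max(masses)))
    return out


def cohens_d_paired(cond_a, cond_b, members, shape):
    """Paired Cohen's d over subject-level means within a cluster."""
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty cluster")
    diff = (np.asarray(cond_a) - np.asarray(cond_b)).reshape(
        cond_a.shape[0], -1)[:, members].mean(axis=1)
    sd = diff.std(ddof=1)
    if sd == 0:
        return np.nan
    return float(diff.mean() / sd)


def paired_cluster_test(cond_a, cond_b, adjacency=None, alpha_cluster=0.01,
                        n_permutations=500, seed=0):
    """Cluster-based permutation test of two paired conditions.

    ``cond_a``/``cond_b`` are subject x channel x [frequency x] time
    arrays with matched subjects. Returns a :class:`ClusterResult`
    whose clusters carry the Monte-Carlo p-value and paired Cohen's d.
    Cluster significance is conventionally assessed at 0.05, or at
    :data:`BONFERRONI_ALPHA_3` when the three condition contrasts form
    one family.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching shapes")
    if a.ndim not in (3, 4):
        raise ValueError("expected subject x channel x [freq x] time arrays")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n_sub = a.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    shape = a.shape[1:]
    diff = (a - b).reshape(n_sub, -1)
    thr = float(t_dist.ppf(1.0 - alpha_cluster / 2.0, n_sub - 1))
    graph = _structure_edges(shape, adjacency)

    t_obs = _paired_t(diff)
    clusters = []
    for sign in (1, -1):
        members, masses = _cluster_masses(
            sign * t_obs, sign * t_obs > thr, graph)
        for mem, mass in zip(members, masses):
            clusters.append(Cluster(sign=sign, mass=float(sign * mass),
                                    p=np.nan, members=mem))

    if clusters:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n_sub)
            t_perm = _paired_t(diff * signs[:, None])
            null[k] = _max_mass(t_perm, thr, graph)
        for c in clusters:
            r = int(np.sum(null >= abs(c.mass)))
            c.p = (r + 1.0) / (n_permutations + 1.0)
            c.cohens_d = cohens_d_paired(a, b, c.members, shape)
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(clusters, t_obs.reshape(shape), thr,
                         n_permutations, shape)
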