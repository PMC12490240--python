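"""Clonal evolution from cancer cell fractions.

CCF of a mutation: ``ccf = vaf * (purity*CN + (1-purity)*2) / (purity *
multiplicity)``, clipped to [0, 1] — the standard purity/local-copy-number
correction with known multiplicity. Variants are grouped into clones by a
binomial-mixture EM over alt/total read counts with cluster-specific
per-sample CCFs (K by BIC), and clone trees are enumerated exhaustively
under the sum rule: in every sample a parent's CCF (+ epsilon) must cover
the sum of its children's CCFs, and a child never exceeds its parent by
more than epsilon. Surviving trees are ranked by total residual slack
(ascending: the tightest explanation first).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_EPSILON = 0.05


def compute_ccf(vaf, purity, copy_number=2.0, multiplicity=1.0):
    """Cancer cell fraction from VAF, purity, local CN and multiplicity.

    Vectorized over ``vaf``; monotone increasing in vaf and decreasing in
    purity. Result clipped to [0, 1].
    """
    vaf = np.asarray(vaf, dtype=float)
    if np.any(purity <= 0) or np.any(np.asarray(purity) > 1):
        raise ValueError("purity must lie in (0, 1]")
    if np.any(vaf > 1) or np.any(vaf < 0):
        raise ValueError("vaf must lie in [0, 1]")
    if np.any(np.asarray(copy_number) < 1) or np.any(np.asarray(multiplicity) < 1):
        raise ValueError("copy_number and multiplicity must be >= 1")
    ccf = vaf * (purity * copy_number + (1.0 - purity) * 2.0) / (purity * multiplicity)
    out = np.clip(ccf, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def estimate_multiplicity(vaf, purity, copy_number):
    """round(vaf * CN / purity) clipped to [1, CN] — the usual point estimate."""
    m = np.rint(np.asarray(vaf) * np.asarray(copy_number) / purity)
    return np.clip(m, 1, np.asarray(copy_number))


@dataclass
class CloneCluster:
    cluster_id: int
    members: list  # variant identifiers
    ccf: pd.Series  # per-sample mean CCF
    size: int


@dataclass
class CcfClusterResult:
    clusters: list[CloneCluster]
    assignments: pd.Series  # variant -> cluster_id
    k: int
    bic: dict[int, float]
    log_likelihood: float
    ll_path: list[float] = field(default_factory=list)  # winning run's EM path

    @property
    def ccf_matrix(self) -> pd.DataFrame:
        return pd.DataFrame({c.cluster_id: c.ccf for c in self.clusters}).T


def _em_binomial(alt, depth, f, k, rng, max_iter=300, tol=1e-8):
    """One EM run; returns (loglik, phi, pi, resp, ll_path)."""
    n, s = alt.shape
    # init: cluster CCFs from randomly chosen variants' naive estimates
    with np.errstate(invalid="ignore", divide="ignore"):
        naive = np.where(depth * f > 0, alt / np.maximum(depth * f, 1e-12), 0.0)
    naive = np.clip(naive, 0.0, 1.0)
    phi = naive[rng.choice(n, size=k, replace=n < k)]
    phi = np.clip(phi + rng.normal(0, 0.01, phi.shape), 0.0, 1.0)
    pi = np.full(k, 1.0 / k)
    ll_prev, path = -np.inf, []
    resp = None
    for _ in range(max_iter):
        p = np.clip(f[None, :, :] * phi[:, None, :], 1e-9, 1 - 1e-9)  # k x n x s
        loglik_ks = (
            alt[None] * np.log(p) + (depth - alt)[None] * np.log1p(-p)
        ).sum(axis=2)  # k x n
        weighted = loglik_ks + np.log(pi)[:, None]
        norm = logsumexp(weighted, axis=0)
        ll = float(norm.sum())
        path.append(ll)
        resp = np.exp(weighted - norm)  # k x n
        pi = np.clip(resp.mean(axis=1), 1e-12, None)
        pi /= pi.sum()
        num = resp @ alt  # k x s
        den = resp @ (depth * f)
        phi = np.clip(np.where(den > 0, num / np.maximum(den, 1e-12), 0.0), 0.0, 1.0)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return ll, phi, pi, resp, path


def cluster_ccf(
    alt: pd.DataFrame,
    depth: pd.DataFrame,
    purity: dict[str, float],
    copy_number=2.0,
    multiplicity=1.0,
    k_max: int = 8,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 300,
) -> CcfClusterResult:
    """Binomial-mixture clustering of variants into clones across samples.

    ``alt``/``depth`` are variants x samples read-count tables; the
    per-variant expected VAF at CCF 1 is ``purity*mult / (purity*CN +
    (1-purity)*2)``. K is chosen by BIC over 1..k_max; each K uses a fixed
    best-of-restarts schedule, so results are deterministic given the seed.
    The EM log-likelihood is non-decreasing (exposed as ``ll_path``).
    """
    if len(alt) < 2:
        raise ValueError("need at least 2 variants")
    samples = list(alt.columns)
    A = alt.to_numpy(dtype=float)
    D = depth.to_numpy(dtype=float)
    pur = np.array([purity[s] for s in samples])
    cn = np.broadcast_to(np.asarray(copy_number, dtype=float), A.shape)
    mult = np.broadcast_to(np.asarray(multiplicity, dtype=float), A.shape)
    f = pur[None, :] * mult / (pur[None, :] * cn + (1 - pur[None, :]) * 2.0)

    n = len(alt)
    best_by_k = {}
    bic = {}
    for k in range(1, k_max + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        best = None
        for _ in range(n_restarts):
            ll, phi, pi, resp, path = _em_binomial(A, D, f, k, rng, max_iter)
            if best is None or ll > best[0]:
                best = (ll, phi, pi, resp, path)
        ll = best[0]
        n_params = k * len(samples) + (k - 1)
        bic[k] = -2.0 * ll + n_params * np.log(n)
        best_by_k[k] = best
    k_star = min(bic, key=lambda k: (bic[k], k))
    ll, phi, pi, resp, path = best_by_k[k_star]
    assign = resp.argmax(axis=0)
    # drop empty clusters and relabel densely by descending mean CCF
    used = sorted(set(assign), key=lambda c: -phi[c].mean())
    clusters = []
    relabel = {}
    assignments = pd.Series(index=alt.index, dtype=int)
    for new_id, c in enumerate(used):
        members = list(alt.index[assign == c])
        relabel[c] = new_id
        clusters.append(
            CloneCluster(
                cluster_id=new_id,
                members=members,
                ccf=pd.Series(phi[c], index=samples),
                size=len(members),
            )
        )
    for i, c in enumerate(assign):
        assignments.iloc[i] = relabel[c]
    return CcfClusterResult(
        clusters=clusters, assignments=assignments, k=len(used), bic=bic,
        log_likelihood=ll, ll_path=path,
    )


@dataclass
class CloneTree:
    parents: dict  # cluster -> parent (root -> None)
    ccf: pd.DataFrame  # clusters x samples
    residual: float  # total sum-rule slack over samples and nodes

    def children(self) -> dict:
        kids: dict = {c: [] for c in self.parents}
        for c, p in self.parents.items():
            if p is not None:
                kids[p].append(c)
        return kids

    def newick(self) -> str:
        kids = self.children()
        root = [c for c, p in self.parents.items() if p is None][0]

        def rec(node):
            if not kids[node]:
                return str(node)
            return "(" + ",".join(rec(c) for c in sorted(kids[node], key=str)) + ")" + str(node)

        return rec(root) + ";"


@dataclass
class TreeEnumeration:
    trees: list[CloneTree]
    n_examined: int
    violations: list[tuple[dict, str]]


def _tree_residual(parents: dict, ccf: pd.DataFrame) -> float:
    kids: dict = {c: [] for c in parents}
    for c, p in parents.items():
        if p is not None:
            kids[p].append(c)
    res = 0.0
    for node, ks in kids.items():
        res += float((ccf.loc[node] - sum(ccf.loc[k] for k in ks)).sum()) if ks else float(
            ccf.loc[node].sum()
        )
    return res


def check_sum_rule(parents: dict, ccf: pd.DataFrame, epsilon: float) -> str | None:
    """None when the tree is valid, else a human-readable violation."""
    kids: dict = {c: [] for c in parents}
    for c, p in parents.items():
        if p is not None:
            if ccf.loc[c].gt(ccf.loc[p] + epsilon).any():
                return f"clone {c} exceeds parent {p}"
            kids[p].append(c)
    for node, ks in kids.items():
        if not ks:
            continue
        total = sum(ccf.loc[k] for k in ks)
        if total.gt(ccf.loc[node] + epsilon).any():
            return f"children of {node} exceed its CCF"
    return None


def enumerate_trees(
    ccf: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    sizes: pd.Series | None = None,
    founder=None,
    max_clusters: int = 10,
) -> TreeEnumeration:
    """All rooted clone trees over the clusters satisfying the sum rule.

    ``ccf`` is a clusters x samples table. The root (founder) is the cluster
    with maximal CCF in the earliest (first) sample, ties broken by cluster
    size; candidate parents for each node are pruned by the crossing rule
    before the exhaustive recursion, which keeps up to 10 clusters
    practical. Survivors are ranked by total residual slack, ascending.
    """
    clusters = list(ccf.index)
    if len(clusters) > max_clusters:
        raise ValueError(f"exhaustive enumeration limited to {max_clusters} clusters")
    if founder is None:
        first = ccf.columns[0]
        top = ccf[first].max()
        cands = [c for c in clusters if ccf.loc[c, first] == top]
        if len(cands) > 1 and sizes is not None:
            cands = sorted(cands, key=lambda c: -sizes.get(c, 0))
        founder = cands[0]
    others = [c for c in clusters if c != founder]
    if not others:
        tree = CloneTree({founder: None}, ccf, _tree_residual({founder: None}, ccf))
        return TreeEnumeration([tree], 1, [])

    candidates = {}
    for c in others:
        ok = [
            p
            for p in clusters
            if p != c and not ccf.loc[c].gt(ccf.loc[p] + epsilon).any()
        ]
        candidates[c] = ok

    trees, violations = [], []
    n_examined = 0
    for combo in itertools.product(*(candidates[c] for c in others)):
        parents = {founder: None}
        parents.update(dict(zip(others, combo)))
        # reject cycles (root-unreachable components)
        ok = True
        for c in others:
            seen = set()
            node = c
            while node is not None:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parents[node]
            if not ok:
                break
        if not ok:
            continue
        n_examined += 1
        reason = check_sum_rule(parents, ccf, epsilon)
        if reason is None:
            trees.append(CloneTree(parents, ccf, _tree_residual(parents, ccf)))
        elif len(violations) < 100:
            violations.append((dict(parents), reason))
    trees.sort(key=lambda t: (t.residual, sorted(map(str, t.parents.items()))))
    return TreeEnumeration(trees, n_examined, violations)


def export_fishplot(
    tree: CloneTree,
    timepoints: list | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Nested clone-fraction table ready for fishplot-style drawing.

    Each clone's printed fraction is its CCF, which by the sum rule already
    includes its descendants; rows carry the parent so nesting can be drawn
    directly. Raises when the tree violates the sum rule beyond epsilon.
    """
    reason = check_sum_rule(tree.parents, tree.ccf, epsilon)
    if reason is not None:
        raise ValueError(f"inconsistent clone fractions: {reason}")
    cols = timepoints if timepoints is not None else list(tree.ccf.columns)
    rows = []
    for clone in tree.ccf.index:
        row = {"clone": clone, "parent": tree.parents.get(clone)}
        for t in cols:
            row[t] = float(tree.ccf.loc[clone, t])
        rows.append(row)
    return pd.DataFrame(rows)
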