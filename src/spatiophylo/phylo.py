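"""Phylogenies, Brownian-motion covariance, and Pagel's lambda.

Under Brownian trait evolution the covariance between two tips equals
the branch length shared on their root-to-tip paths, i.e. the depth of
their most recent common ancestor.  :func:`brownian_vcv` builds that
matrix; :func:`estimate_lambda` rescales its off-diagonal by a factor
``lambda`` and profiles the factor's maximum likelihood under a GLS
model with an intercept-only mean, giving the standard measure of
phylogenetic signal (0 = no signal, 1 = pure Brownian motion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

from .covariance import CovarianceStructure
from .errors import IntegrityError, NumericalError

log = logging.getLogger(__name__)

LAMBDA_MAX_CAP = 1.2


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy tree.

    Invariants checked on construction: at least two tips, unique tip
    labels, every non-root edge carries a nonnegative length.
    Polytomies and zero-length branches are accepted (global language
    supertrees contain both).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise IntegrityError("phylogeny must have at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise IntegrityError(f"duplicate tip labels: {dupes}")
        bad = []
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                head = edge.head_node.taxon
                bad.append(head.label if head else "<internal>")
            elif edge.length < 0:
                raise IntegrityError("negative branch length")
        if bad:
            raise IntegrityError(f"edges without branch lengths above: {bad}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise IntegrityError(f"duplicate tip labels: {exc}") from exc
    return Phylogeny(tree)


def from_newick_string(s: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise IntegrityError(f"duplicate tip labels: {exc}") from exc
    return Phylogeny(tree)


def prune_to(t: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on ``keep``; patristic distances are preserved."""
    keep = list(keep)
    tips = set(t.tip_labels)
    unknown = [k for k in keep if k not in tips]
    if unknown:
        raise IntegrityError(f"taxa not in tree: {unknown[:5]}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    sub = t.tree.extract_tree_with_taxa_labels(labels=keep)
    return Phylogeny(sub)


def brownian_vcv(t: Phylogeny) -> CovarianceStructure:
    """Brownian-motion tip covariance: C[i, j] = depth of MRCA(i, j).

    Computed by a single postorder sweep: when an internal node at root
    distance ``d`` joins child subtrees, every cross-subtree tip pair
    receives covariance ``d``.  Diagonal entries are root-to-tip
    distances.
    """
    tree = t.tree
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels: list[str] = []
    leaf_index: dict[int, int] = {}
    for leaf in tree.leaf_node_iter():
        leaf_index[id(leaf)] = len(labels)
        labels.append(leaf.taxon.label)
    n = len(labels)
    C = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = leaf_index[id(node)]
            C[i, i] = node.root_distance
            below[id(node)] = np.array([i])
            continue
        child_sets = [below.pop(id(ch)) for ch in node.child_nodes()]
        depth = node.root_distance
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia, ib = child_sets[a], child_sets[b]
                C[np.ix_(ia, ib)] = depth
                C[np.ix_(ib, ia)] = depth
        below[id(node)] = np.concatenate(child_sets)
    return CovarianceStructure(name="phylo", kind="phylogenetic", taxa=labels, matrix=C)


def lambda_transform(c: CovarianceStructure, lam: float) -> CovarianceStructure:
    """Multiply off-diagonal covariance by ``lam``, keeping the diagonal."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if c.kind != "phylogenetic":
        raise ValueError("lambda transform applies to phylogenetic covariance")
    if c.standardized:
        raise ValueError("lambda transform expects the unstandardized covariance")
    C = c.matrix.copy()
    d = C.diagonal().copy()
    C *= lam
    np.fill_diagonal(C, d)
    return CovarianceStructure(name=c.name, kind=c.kind, taxa=list(c.taxa), matrix=C)


def gls_loglik(y, X, C, beta, sigma2: float) -> float:
    """Log density of ``y`` under Normal(X beta, sigma2 * C)."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    Cm = C.matrix if isinstance(C, CovarianceStructure) else np.asarray(C, float)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    n = y.shape[0]
    r = y - X @ np.atleast_1d(np.asarray(beta, float))
    try:
        L = np.linalg.cholesky(sigma2 * Cm)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance not positive definite") from exc
    z = np.linalg.solve(L, r)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + z @ z))


@dataclass
class LambdaEstimate:
    """Profile-ML estimate of Pagel's lambda with a likelihood-ratio test."""

    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    lrt_stat: float
    lrt_p: float
    lambda_max: float
    flagged: bool = False
    note: str = ""

    def summary(self) -> str:
        return (
            f"Pagel's lambda = {self.lambda_hat:.4f} "
            f"(search bound {self.lambda_max:.2f})\n"
            f"logL(lambda_hat) = {self.loglik_at_hat:.4f}, "
            f"logL(0) = {self.loglik_at_zero:.4f}\n"
            f"LRT chi2(1) = {self.lrt_stat:.4f}, p = {self.lrt_p:.3g}"
            + (f"\nnote: {self.note}" if self.note else "")
        )


class _ProfileLikelihood:
    """Intercept-only GLS profile log-likelihood over lambda.

    beta and sigma^2 are profiled out in closed form.  For (near-)
    ultrametric trees the transformed covariance shares eigenvectors
    with the original, so each evaluation is O(n); otherwise a Cholesky
    per evaluation is used.
    """

    def __init__(self, y: np.ndarray, C: np.ndarray):
        self.y = np.asarray(y, float)
        self.C = C
        self.n = len(self.y)
        d = C.diagonal()
        self.ultrametric = np.allclose(d, d[0], rtol=1e-8, atol=1e-10)
        if self.ultrametric:
            self.depth = float(d[0])
            w, U = np.linalg.eigh(C)
            self.w = w
            self.yt = U.T @ self.y
            self.ot = U.T @ np.ones(self.n)

    def transformed(self, lam: float) -> np.ndarray:
        C = self.C * lam
        np.fill_diagonal(C, self.C.diagonal())
        return C

    def __call__(self, lam: float) -> float:
        n = self.n
        if self.ultrametric:
            dvec = lam * self.w + (1 - lam) * self.depth
            if dvec.min() <= 0:
                return -np.inf
            bhat = (self.ot * self.yt / dvec).sum() / (self.ot**2 / dvec).sum()
            rt = self.yt - bhat * self.ot
            rss = (rt**2 / dvec).sum()
            logdet = np.log(dvec).sum()
        else:
            C = self.transformed(lam)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return -np.inf
            one = np.ones(n)
            a = np.linalg.solve(L, one)
            b = np.linalg.solve(L, self.y)
            bhat = (a @ b) / (a @ a)
            z = b - bhat * a
            rss = z @ z
            logdet = 2.0 * np.log(np.diag(L)).sum()
        sigma2 = rss / n
        if sigma2 <= 0:
            return -np.inf
        return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))

    def lambda_max(self, cap: float = LAMBDA_MAX_CAP) -> float:
        if self.ultrametric:
            wmin = self.w.min()
            if wmin >= self.depth:  # cannot lose positivity below the cap
                return cap
            bound = self.depth / (self.depth - wmin)
            return float(min(cap, max(1.0, bound * (1 - 1e-9))))
        lam = cap
        while lam > 1.0 and not np.isfinite(self(lam)):
            lam -= 0.05
        return float(max(lam, 1.0))


def estimate_lambda(
    y,
    t: Phylogeny | CovarianceStructure,
    boundary_mixture: bool = False,
) -> LambdaEstimate:
    """Estimate Pagel's lambda for trait ``y`` on tree ``t`` by profile ML.

    ``y`` may be a mapping/Series indexed by taxon or a vector already in
    tip order.  The LRT p-value compares lambda_hat against lambda = 0
    using a chi-square with 1 df (optionally the 50:50 boundary mixture).
    """
    cov = t if isinstance(t, CovarianceStructure) else brownian_vcv(t)
    taxa = cov.taxa
    if hasattr(y, "reindex"):
        yv = np.asarray(y.reindex(taxa), float)
        if np.isnan(yv).any():
            raise ValueError("trait values missing for some tips")
    elif isinstance(y, dict):
        yv = np.array([y[t_] for t_ in taxa], float)
    else:
        yv = np.asarray(y, float)
        if len(yv) != len(taxa):
            raise ValueError("trait vector length does not match tip count")

    off = cov.matrix - np.diag(cov.matrix.diagonal())
    if np.abs(off).max() <= 1e-12 * max(cov.matrix.diagonal().max(), 1.0):
        log.warning("star tree: lambda unidentifiable, returning 0")
        ll = _ProfileLikelihood(yv, cov.matrix)(0.0)
        return LambdaEstimate(0.0, ll, ll, 0.0, 1.0, 0.0, flagged=True,
                              note="star tree: lambda unidentifiable")

    prof = _ProfileLikelihood(yv, cov.matrix)
    lam_max = prof.lambda_max()
    res = optimize.minimize_scalar(
        lambda lam: -prof(lam), bounds=(0.0, lam_max), method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(float(res.x), prof(float(res.x))), (0.0, prof(0.0)),
                  (lam_max, prof(lam_max))]
    lam_hat, ll_hat = max(candidates, key=lambda p: p[1])
    ll0 = prof(0.0)
    stat = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(stat, df=1))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return LambdaEstimate(lam_hat, ll_hat, ll0, stat, p, lam_max)
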