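"""Phylogenetic Ornstein-Uhlenbeck shift detection with LASSO and BIC.

Trait values on the tips of an ultrametric phylogeny are modelled as a
stationary OU process with selection strength ``alpha``, diffusion
variance ``sigma2`` and a piecewise-constant optimum: the optimum starts
at ``theta0`` at the root and may jump on any branch, the jump being
inherited by every descendant lineage.  On an ultrametric tree of
height ``T`` the tip expectations are linear in the shift offsets,

    E[y_i] = theta0 + sum_b  beta_b * (1 - exp(-alpha (T - t_b))),

where the sum runs over shifted branches ``b`` on the root-to-tip path
of tip ``i`` and ``t_b`` is the depth at which branch ``b`` begins; the
tip covariance is

    V_ij = sigma2 / (2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))

with ``t_ij`` the shared path length from the root and ``d_ij`` the
patristic distance (Brownian ``sigma2 * t_ij`` in the ``alpha -> 0``
limit).  Shift placement is selected by an L1-penalized regression of
the whitened traits on the whitened per-branch design, with every
support set along the LASSO path refit by generalized least squares and
scored by BIC (free parameters: the shifts, theta0, alpha and sigma2);
``alpha`` is profiled over a log-spaced grid.  Per-shift confidence
comes from a residual bootstrap: whitened (hence uncorrelated,
standardized) residuals are resampled with replacement, colored back
through the fitted covariance, and the whole selection is rerun.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

DEFAULT_ALPHA_GRID = tuple(np.logspace(-2, 2, 20))
LASSO_TOL = 1e-8


@dataclass(frozen=True)
class EdgeTable:
    """Preorder-indexed edges of a rooted tree with tip incidence."""

    tip_labels: tuple[str, ...]
    edges: tuple  # dendropy Edge objects, preorder, root edge excluded
    t_start: np.ndarray  # depth of each edge's parent node
    t_end: np.ndarray  # depth of each edge's child node
    tip_indicator: np.ndarray  # (n_tips, n_edges) 0/1 membership
    height: float


@dataclass(frozen=True)
class ShiftModel:
    """A fitted OU shift configuration on a (unit-height) tree."""

    tree: dendropy.Tree = field(repr=False)
    shift_edges: tuple[int, ...]
    beta: tuple[float, ...]
    theta0: float
    alpha: float
    sigma2: float
    bic: float
    loglik: float
    support: dict[int, float] | None = None
    equivalent_edges: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.support is not None and any(not 0 <= s <= 1 for s in self.support.values()):
            raise ValueError("bootstrap support must lie in [0, 1]")
        if len(self.beta) != len(self.shift_edges):
            raise ValueError("one offset per shift edge required")


# ---------------------------------------------------------------------------
# tree preparation
# ---------------------------------------------------------------------------

def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        length = node.edge.length or 0.0
        depths[node] = (depths[parent] if parent is not None else 0.0) + (length if parent is not None else 0.0)
    return depths


def check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> float:
    """Verify all tips are equidistant from the root; return the height.

    Raises ``ValueError`` naming the most discrepant tip if the spread
    of root-to-tip distances exceeds ``rel_tol`` times the height.
    """
    depths = _node_depths(tree)
    tip_depths = {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}
    if not tip_depths:
        raise ValueError("tree has no labelled tips")
    height = max(tip_depths.values())
    if height <= 0:
        raise ValueError("tree has zero height")
    worst = max(tip_depths, key=lambda t: abs(tip_depths[t] - height))
    spread = height - min(tip_depths.values())
    if spread > rel_tol * height:
        raise ValueError(
            f"tree is not ultrametric: tip {worst!r} deviates by {spread:.6g} "
            f"from height {height:.6g}"
        )
    return height


def scale_tree(tree: dendropy.Tree, rel_tol: float = 1e-6) -> dendropy.Tree:
    """Return a copy with all branch lengths divided by the tree height."""
    height = check_ultrametric(tree, rel_tol=rel_tol)
    scaled = tree.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    return scaled


def edge_table(tree: dendropy.Tree) -> EdgeTable:
    """Index edges in preorder with start/end depths and tip membership."""
    depths = _node_depths(tree)
    tips = [leaf for leaf in tree.leaf_node_iter()]
    tip_index = {id(leaf): i for i, leaf in enumerate(tips)}
    edges, t_start, t_end, cols = [], [], [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        edges.append(node.edge)
        t_start.append(depths[node.parent_node])
        t_end.append(depths[node])
        ind = np.zeros(len(tips))
        for leaf in node.leaf_iter():
            ind[tip_index[id(leaf)]] = 1.0
        cols.append(ind)
    return EdgeTable(
        tip_labels=tuple(leaf.taxon.label for leaf in tips),
        edges=tuple(edges),
        t_start=np.array(t_start),
        t_end=np.array(t_end),
        tip_indicator=np.column_stack(cols) if cols else np.zeros((len(tips), 0)),
        height=max(depths[leaf] for leaf in tips),
    )


def _shared_time_matrix(tree: dendropy.Tree, table: EdgeTable) -> np.ndarray:
    """Depth of the MRCA for every tip pair (diagonal = tree height)."""
    depths = _node_depths(tree)
    n = len(table.tip_labels)
    tip_pos = {label: i for i, label in enumerate(table.tip_labels)}
    t = np.zeros((n, n))
    for leaf in tree.leaf_node_iter():
        i = tip_pos[leaf.taxon.label]
        t[i, i] = depths[leaf]
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        groups = [[tip_pos[l.taxon.label] for l in child.leaf_iter()] for child in kids]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        t[i, j] = t[j, i] = depths[node]
    return t


def ou_design(tree: dendropy.Tree, alpha: float, sigma2: float = 1.0):
    """Shift design matrix and OU tip covariance for a given ``alpha``.

    Design entry (i, b) is ``1 - exp(-alpha (T - t_start(b)))`` for tips
    ``i`` descending from branch ``b`` (0 otherwise): the attenuated
    effect of an inherited optimum shift, approaching the full offset as
    ``alpha`` grows and vanishing in the Brownian limit.  Returns
    ``(design, covariance)``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    table = edge_table(tree)
    T = table.height
    if alpha == 0:
        atten = np.zeros(len(table.edges))
    else:
        atten = 1.0 - np.exp(-alpha * (T - table.t_start))
    design = table.tip_indicator * atten[None, :]

    t_shared = _shared_time_matrix(tree, table)
    d_patristic = 2.0 * T - 2.0 * t_shared
    np.fill_diagonal(d_patristic, 0.0)
    if alpha == 0:
        cov = sigma2 * t_shared
    else:
        cov = sigma2 / (2 * alpha) * np.exp(-alpha * d_patristic) * (1 - np.exp(-2 * alpha * t_shared))
    return design, cov


# ---------------------------------------------------------------------------
# shift detection
# ---------------------------------------------------------------------------

def _trait_vector(table: EdgeTable, traits) -> np.ndarray:
    if isinstance(traits, dict):
        missing = [t for t in table.tip_labels if t not in traits]
        if missing:
            raise ValueError(f"traits missing for tips: {missing}")
        return np.array([float(traits[t]) for t in table.tip_labels])
    y = np.asarray(traits, dtype=float)
    if y.shape != (len(table.tip_labels),):
        raise ValueError("trait vector length must match the number of tips")
    return y


def _gls_score(
    yw: np.ndarray,
    Xw: np.ndarray,
    logdet_R: float,
    n_shifts: int,
    n_edges: int,
    criterion: str,
):
    """GLS refit of [theta0 | shifts] on whitened data, with an IC score.

    ``criterion="pbic"`` (default) scores plain BIC plus an extended-BIC
    placement term ``2 ln C(n_edges, K)`` — a uniform model-space prior
    over the K-shift configurations — which controls the selection bias
    of scanning every branch of the tree; ``criterion="bic"`` is the
    plain BIC with parameters counted as shifts + theta0 + alpha +
    sigma2.
    """
    n = len(yw)
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ coef) ** 2))
    sigma2 = rss / n
    if sigma2 < 1e-300:
        return coef, 0.0, np.inf, -np.inf
    loglik = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * logdet_R - 0.5 * n
    k = n_shifts + 3  # shifts + theta0 + alpha + sigma2
    score = -2.0 * loglik + k * np.log(n)
    if criterion == "pbic":
        score += 2.0 * (gammaln(n_edges + 1) - gammaln(n_shifts + 1) - gammaln(n_edges - n_shifts + 1))
    return coef, sigma2, loglik, score


def detect_shifts(
    tree: dendropy.Tree,
    traits,
    criterion: str = "pbic",
    alpha_grid=DEFAULT_ALPHA_GRID,
    max_shifts: int | None = None,
    lasso_path_length: int = 100,
) -> ShiftModel:
    """BIC-selected LASSO placement of OU optimum shifts.

    For each ``alpha`` on the grid the traits and the per-branch shift
    design are whitened by the Cholesky factor of the OU covariance, an
    L1 path over shift coefficients proposes nested support sets, and
    each support (plus the empty set) is refit by generalized least
    squares and scored by BIC.  The minimum-BIC model over the whole
    grid and path wins; BIC ties break toward fewer shifts, then toward
    the smaller preorder edge index.  Deterministic given its inputs.
    """
    scaled = scale_tree(tree)
    table = edge_table(scaled)
    n = len(table.tip_labels)
    if n < 4:
        raise ValueError(f"need at least 4 tips, got {n}")
    y = _trait_vector(table, traits)
    if max_shifts is None:
        max_shifts = max(1, n // 4)

    best = None  # (bic, n_shifts, alpha, support, coef, sigma2, loglik)
    for alpha in alpha_grid:
        design, cov = ou_design(scaled, float(alpha), sigma2=1.0)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular OU covariance at alpha={alpha}") from exc
        logdet_R = 2.0 * float(np.sum(np.log(np.diag(chol))))
        yw = solve_triangular(chol, y, lower=True)
        ones_w = solve_triangular(chol, np.ones(n), lower=True)
        Xw = solve_triangular(chol, design, lower=True)

        # residualize the (unpenalized) intercept out of the L1 problem
        proj = np.outer(ones_w, ones_w) / float(ones_w @ ones_w)
        y_r = yw - proj @ yw
        X_r = Xw - proj @ Xw
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # the path only proposes candidate supports; refits are exact GLS
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(
                X_r, y_r, alphas=lasso_path_length, eps=1e-4, tol=LASSO_TOL, max_iter=5000
            )
        supports: list[tuple[int, ...]] = [()]
        seen = {()}
        for col in range(coefs.shape[1]):
            s = tuple(np.nonzero(np.abs(coefs[:, col]) > 1e-12)[0])
            if s not in seen and len(s) <= max_shifts:
                seen.add(s)
                supports.append(s)

        for s in supports:
            Xs = np.column_stack([ones_w] + [Xw[:, e] for e in s])
            coef, sigma2, loglik, bic = _gls_score(
                yw, Xs, logdet_R, len(s), design.shape[1], criterion
            )
            key = (bic, len(s), s)
            if best is None or key < (best[0], len(best[3]), best[3]):
                best = (bic, float(alpha), coef, s, sigma2, loglik)

    bic, alpha_hat, coef, support_set, sigma2_hat, loglik = best
    beta = tuple(float(b) for b in coef[1:])
    # flag likelihood-equivalent placements: an identical design column, or
    # a complementary one (root-child sisters: col_e + col_o is constant, so
    # the intercept absorbs the difference and only the sign of beta flips)
    design, _ = ou_design(scaled, alpha_hat if alpha_hat > 0 else 1.0, sigma2=1.0)
    equivalent: dict[int, tuple[int, ...]] = {}
    for e in support_set:
        col_e = design[:, e]
        same = []
        for other in range(design.shape[1]):
            if other == e:
                continue
            col_o = design[:, other]
            if np.allclose(col_o, col_e, atol=1e-9):
                same.append(other)
            else:
                s = col_e + col_o
                if np.allclose(s, s.mean(), atol=1e-9):
                    same.append(other)
        if same:
            equivalent[e] = tuple(same)
    return ShiftModel(
        tree=scaled,
        shift_edges=tuple(int(e) for e in support_set),
        beta=beta,
        theta0=float(coef[0]),
        alpha=alpha_hat,
        sigma2=float(sigma2_hat),
        bic=float(bic),
        loglik=float(loglik),
        equivalent_edges=equivalent,
    )


def bootstrap_support(
    model: ShiftModel,
    traits,
    n_boot: int = 100,
    seed: int = 0,
    criterion: str = "pbic",
    alpha_grid=DEFAULT_ALPHA_GRID,
    max_shifts: int | None = None,
) -> ShiftModel:
    """Residual-bootstrap support for each fitted shift.

    Residuals are whitened through the fitted OU covariance (making them
    uncorrelated and standardized), resampled with replacement, colored
    back through the covariance and added to the fitted tip
    expectations; shift detection is rerun on each replicate and the
    support of a shift is the fraction of replicates selecting its edge.
    Returns a copy of ``model`` with ``support`` filled in.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    table = edge_table(model.tree)
    y = _trait_vector(table, traits)
    alpha = model.alpha if model.alpha > 0 else 1e-8
    design, cov = ou_design(model.tree, alpha, sigma2=1.0)
    chol = np.linalg.cholesky(cov)
    mean = np.full(len(y), model.theta0)
    for e, b in zip(model.shift_edges, model.beta):
        mean = mean + b * design[:, e]
    z = solve_triangular(chol, y - mean, lower=True)  # iid N(0, sigma2) under the fit

    rng = np.random.default_rng(seed)
    hits = {e: 0 for e in model.shift_edges}
    n = len(y)
    for _ in range(n_boot):
        z_star = z[rng.integers(0, n, size=n)]
        y_star = mean + chol @ z_star
        refit = detect_shifts(
            model.tree, y_star, criterion=criterion, alpha_grid=alpha_grid, max_shifts=max_shifts
        )
        for e in model.shift_edges:
            if e in refit.shift_edges or any(
                e in refit.equivalent_edges.get(x, ()) for x in refit.shift_edges
            ):
                hits[e] += 1
    support = {e: hits[e] / n_boot for e in model.shift_edges}
    return replace(model, support=support)
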