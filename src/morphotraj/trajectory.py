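"""Trajectory inference on the 2-D atlas embedding.

The differentiation atlas is modelled as a branched trajectory built in
four stages, following the slingshot family of methods:

1. cells are clustered in the embedding with a full-covariance Gaussian
   mixture, the number of components chosen by BIC;
2. a minimum spanning tree over cluster centroids defines the backbone;
   the progenitor start cluster and the terminal fate clusters are picked
   (or supplied), and each start-to-end tree path is a *lineage*;
3. one principal curve per lineage is fitted by alternating orthogonal
   projection, pseudotime-local smoothing and arc-length reparameterization,
   after which the shared pre-branch segment is refitted on the union of
   pre-branch cells and spliced onto both lineages — so the curves are
   identical up to the branch pseudotime ``t_b`` (the spliced arc length);
4. every cell gets a per-lineage pseudotime (arc length of its orthogonal
   projection), a per-lineage weight w_l = min(1, d_min^2 / d_l^2) (1 on
   its nearest lineage, shared before the branch, 0/0 := 1), and a label:
   Progenitor when pseudotime <= t_b, otherwise the lineage holding weight
   1 while the other is below 1.

New (perturbed) cells transformed into the frozen embedding are projected
onto the stored curves without any refitting, exactly as the atlas cells
were — this is what lets a drug screen be quantified against an untreated
reference atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterModel",
    "LineageTree",
    "cluster_cells",
    "infer_lineages",
    "select_backbone",
    "PrincipalTrajectory",
    "TrajectoryResults",
    "project_to_polyline",
    "resample_polyline",
    "lineage_weights",
    "assign_lineage",
]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Gaussian-mixture clustering of embedding coordinates with BIC selection."""

    gmm: GaussianMixture
    labels: np.ndarray
    responsibilities: np.ndarray
    means: np.ndarray
    k: int
    bic_table: pd.DataFrame
    seed: int

    def relabel(self, perm: np.ndarray) -> "ClusterModel":
        """Return a copy with cluster ids permuted (cluster i -> perm[i])."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return ClusterModel(
            gmm=self.gmm,
            labels=perm[self.labels],
            responsibilities=self.responsibilities[:, inv],
            means=self.means[inv],
            k=self.k,
            bic_table=self.bic_table,
            seed=self.seed,
        )


def cluster_cells(
    coords: np.ndarray,
    k_range=range(2, 11),
    seed: int = 0,
    n_init: int = 5,
) -> ClusterModel:
    """Cluster 2-D coordinates with full-covariance GMMs, choosing K by BIC.

    Each candidate K gets ``n_init`` seeded EM restarts; the selection table
    is retained on the model.  Requires at least 10 x max(K) cells.
    """
    coords = np.asarray(coords, dtype=float)
    ks = list(k_range)
    if len(coords) < 10 * max(ks):
        raise ValueError(f"need >= {10 * max(ks)} cells for K up to {max(ks)}")
    rows, fits = [], {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init, random_state=seed
        ).fit(coords)
        bic = float(gm.bic(coords))
        rows.append({"k": k, "bic": bic, "converged": bool(gm.converged_)})
        fits[k] = gm
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    gm = fits[best_k]
    return ClusterModel(
        gmm=gm,
        labels=gm.predict(coords),
        responsibilities=gm.predict_proba(coords),
        means=np.asarray(gm.means_, dtype=float),
        k=best_k,
        bic_table=table,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Backbone / lineages
# ---------------------------------------------------------------------------


@dataclass
class LineageTree:
    """MST backbone over cluster centroids with one path per lineage."""

    edges: list[tuple[int, int]]
    start: int
    ends: list[int]
    paths: list[list[int]]
    shared_prefix: list[int]


def _mst_edges(means: np.ndarray) -> list[tuple[int, int]]:
    d = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=-1)
    mst = minimum_spanning_tree(d).tocoo()
    return [(int(i), int(j)) for i, j in zip(mst.row, mst.col)]


def _tree_paths(edges, start, n_nodes):
    adj = {i: [] for i in range(n_nodes)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = {start: None}
    queue = [start]
    while queue:
        node = queue.pop(0)
        for nb in adj[node]:
            if nb not in parent:
                parent[nb] = node
                queue.append(nb)
    return parent, adj


def infer_lineages(cluster_model: ClusterModel, start: int, ends: list[int]) -> LineageTree:
    """Build the MST over centroids and extract start-to-end lineage paths.

    Each lineage is the unique tree path from the start cluster to one end
    cluster; the shared prefix of all paths is the pre-branch backbone.
    """
    means = cluster_model.means
    n = len(means)
    ends = list(ends)
    for e in [start, *ends]:
        if not 0 <= e < n:
            raise ValueError(f"cluster {e} does not exist (K = {n})")
    if any(e == start for e in ends):
        raise ValueError("an end cluster equals the start cluster")
    if len(set(ends)) != len(ends):
        raise ValueError("duplicate end clusters")
    edges = _mst_edges(means)
    parent, _ = _tree_paths(edges, start, n)
    paths = []
    for e in ends:
        if e not in parent:
            raise ValueError(f"end cluster {e} unreachable from start {start}")
        path = [e]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        paths.append(path[::-1])
    shared = []
    for nodes in zip(*paths):
        if len(set(nodes)) == 1:
            shared.append(nodes[0])
        else:
            break
    if len(paths) > 1 and not shared:
        shared = [start]
    return LineageTree(edges=edges, start=start, ends=ends, paths=paths, shared_prefix=shared)


def select_backbone(
    cluster_model: ClusterModel,
    covariate: np.ndarray,
    n_ends: int = 2,
    n_candidates: int = 4,
) -> tuple[int, list[int]]:
    """Pick start and end clusters from a progression covariate.

    The start is the cluster with the lowest median covariate (e.g. imaging
    timepoint).  End candidates are MST leaf clusters ranked by median
    covariate; among the top ``n_candidates`` the pair (or n-tuple) with the
    largest mutual centroid distance is chosen, one terminal fate per arm.
    """
    covariate = np.asarray(covariate, dtype=float)
    labels = cluster_model.labels
    med = np.array([np.median(covariate[labels == c]) for c in range(cluster_model.k)])
    start = int(np.argmin(med))
    edges = _mst_edges(cluster_model.means)
    deg = np.zeros(cluster_model.k, dtype=int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    leaves = [c for c in range(cluster_model.k) if deg[c] == 1 and c != start]
    if len(leaves) < n_ends:
        leaves = [c for c in range(cluster_model.k) if c != start]
    cand = sorted(leaves, key=lambda c: -med[c])[:max(n_candidates, n_ends)]
    if n_ends == 1:
        return start, [cand[0]]
    from itertools import combinations

    best, best_d = None, -np.inf
    for combo in combinations(cand, n_ends):
        pts = cluster_model.means[list(combo)]
        d = np.min(
            [np.linalg.norm(pts[a] - pts[b]) for a in range(n_ends) for b in range(a + 1, n_ends)]
        )
        if d > best_d:
            best, best_d = combo, d
    return start, sorted(best, key=cand.index)


# ---------------------------------------------------------------------------
# Polyline geometry
# ---------------------------------------------------------------------------


def resample_polyline(curve: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` arc-length-uniform points."""
    curve = np.asarray(curve, dtype=float)
    keep = np.ones(len(curve), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(curve, axis=0), axis=1) > 0
    curve = curve[keep]
    if len(curve) == 1:
        return np.repeat(curve, n, axis=0)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, cum[-1], n)
    out = np.column_stack([np.interp(s, cum, curve[:, d]) for d in range(curve.shape[1])])
    return out


def polyline_length(curve: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(curve, float), axis=0), axis=1).sum())


def project_to_polyline(
    points: np.ndarray, curve: np.ndarray, chunk: int = 4000
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonally project points onto a polyline, exactly, segment-wise.

    Returns (arc length at the nearest point, distance to it).  Projection
    beyond either terminus clamps to the endpoint, so arc is in
    [0, curve length].
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    curve = np.asarray(curve, dtype=float)
    a = curve[:-1]
    v = np.diff(curve, axis=0)
    seg_len2 = (v**2).sum(axis=1)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    safe = np.where(seg_len2 > 0, seg_len2, 1.0)
    arcs = np.empty(len(points))
    dists = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        diff = p[:, None, :] - a[None, :, :]
        tt = np.clip(np.einsum("nsd,sd->ns", diff, v) / safe, 0.0, 1.0)
        tt[:, seg_len2 == 0] = 0.0
        proj = a[None, :, :] + tt[:, :, None] * v[None, :, :]
        d2 = ((p[:, None, :] - proj) ** 2).sum(axis=2)
        j = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        arcs[lo : lo + chunk] = cum[j] + tt[rows, j] * seg_len[j]
        dists[lo : lo + chunk] = np.sqrt(d2[rows, j])
    return arcs, dists


# ---------------------------------------------------------------------------
# Principal curves
# ---------------------------------------------------------------------------


def _smooth_against_arc(
    points: np.ndarray, arc: np.ndarray, n_points: int, span: float, df: float = 5.0
) -> np.ndarray:
    """Coordinate-wise penalized-spline smoother against pseudotime.

    Each coordinate is regressed on arc length with a cubic B-spline basis
    (interior knots at arc quantiles spaced ``span`` of the data apart) and
    a second-difference coefficient penalty whose strength is chosen so the
    smoother's effective degrees of freedom equal ``df``.  A fixed, small
    df is essential: the projection step correlates residuals with arc, so
    data-driven penalty selection (GCV-style) systematically under-smooths
    and lets the curve chase cell-level noise laterally.  Returns the
    smoothed curve on a uniform arc grid.
    """
    from scipy.interpolate import BSpline

    lo, hi = float(arc.min()), float(arc.max())
    if hi <= lo:
        return np.repeat(points.mean(axis=0, keepdims=True), n_points, axis=0)
    degree = 3
    n_interior = max(1, int(round(1.0 / span)) - 1)
    qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(arc, qs))
    interior = interior[(interior > lo) & (interior < hi)]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    b = BSpline.design_matrix(np.clip(arc, lo, hi), knots, degree).toarray()
    m = b.shape[1]
    d2 = np.diff(np.eye(m), n=2, axis=0)
    btb = b.T @ b
    bty = b.T @ points
    dtd = d2.T @ d2
    target = min(df, m - 0.5)
    lam_lo, lam_hi = 1e-8, 1e12
    lam = 1.0
    for _ in range(60):  # bisect lambda to hit the target effective df
        lam = np.sqrt(lam_lo * lam_hi)
        eff = float(np.trace(np.linalg.solve(btb + lam * dtd, btb)))
        if eff > target:
            lam_lo = lam
        else:
            lam_hi = lam
    coef = np.linalg.solve(btb + lam * dtd, bty)
    grid = np.linspace(lo, hi, n_points)
    return BSpline.design_matrix(grid, knots, degree).toarray() @ coef


def _fit_single_curve(
    points: np.ndarray,
    init_curve: np.ndarray,
    n_points: int,
    span: float,
    max_iter: int,
    tol: float,
    df: float = 5.0,
) -> tuple[np.ndarray, bool, int]:
    """Alternating projection / smoothing / reparameterization for one curve."""
    curve = resample_polyline(init_curve, n_points)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        arc, _ = project_to_polyline(points, curve)
        new = _smooth_against_arc(points, arc, n_points, span, df)
        new = resample_polyline(new, n_points)
        disp = float(np.linalg.norm(new - curve, axis=1).mean())
        curve = new
        if disp < tol:
            converged = True
            break
    return curve, converged, it


def _point_at_arc(curve: np.ndarray, s0: float) -> np.ndarray:
    """Point on a polyline at arc length s0 (clamped to the curve)."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = min(max(s0, 0.0), cum[-1])
    return np.array([np.interp(s0, cum, curve[:, d]) for d in range(curve.shape[1])])


def _sub_polyline_to(curve: np.ndarray, s0: float) -> np.ndarray:
    """Portion of a polyline from its start to arc length s0."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = min(max(s0, 0.0), cum[-1])
    before = curve[cum < s0]
    if len(before) == 0:
        before = curve[:1]
    return np.vstack([before, _point_at_arc(curve, s0)])


def _sub_polyline_from(curve: np.ndarray, s0: float) -> np.ndarray:
    """Portion of a polyline from arc length s0 to its end."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = min(max(s0, 0.0), cum[-1])
    start_pt = np.array([np.interp(s0, cum, curve[:, d]) for d in range(curve.shape[1])])
    after = curve[cum > s0]
    if len(after) == 0:
        after = curve[-1:][:]
    return np.vstack([start_pt, after])


class PrincipalTrajectory:
    """Branched principal-curve trajectory model.

    Parameters
    ----------
    coords
        2-D embedding coordinates of the atlas cells.
    cluster_model
        :class:`ClusterModel` for the same cells.
    tree
        :class:`LineageTree` naming the start, ends and lineage paths.
    lineage_names
        Labels for the terminal fates, in the order of ``tree.ends``
        (default ``("Hepatocyte", "Biliary")`` for a two-lineage model).
    span, df, n_points, max_iter, tol
        Smoother knot spacing (fraction of the pseudotime range), effective
        degrees of freedom of the penalized smoother, curve discretization,
        and convergence controls.
    min_lineage_cells
        A lineage whose member clusters hold fewer cells than this is an
        error — too few cells to support a curve.
    """

    def __init__(
        self,
        coords: np.ndarray,
        cluster_model: ClusterModel,
        tree: LineageTree,
        lineage_names: tuple[str, ...] = ("Hepatocyte", "Biliary"),
        span: float = 0.1,
        df: float = 5.0,
        n_points: int = 200,
        max_iter: int = 50,
        tol: float = 1e-3,
        min_lineage_cells: int = 50,
    ):
        self.coords = np.asarray(coords, dtype=float)
        self.cluster_model = cluster_model
        self.tree = tree
        if len(lineage_names) < len(tree.paths):
            lineage_names = tuple(f"Lineage{i+1}" for i in range(len(tree.paths)))
        self.lineage_names = tuple(lineage_names[: len(tree.paths)])
        self.span = span
        self.df = df
        self.n_points = n_points
        self.max_iter = max_iter
        self.tol = tol
        self.min_lineage_cells = min_lineage_cells

    def fit(self) -> "TrajectoryResults":
        labels = self.cluster_model.labels
        curves, convs, iters = [], [], []
        for path in self.tree.paths:
            members = np.isin(labels, path)
            if members.sum() < self.min_lineage_cells:
                raise ValueError(
                    f"lineage through clusters {path} has {int(members.sum())} cells "
                    f"(need >= {self.min_lineage_cells})"
                )
            init = self.cluster_model.means[path]
            curve, conv, it = _fit_single_curve(
                self.coords[members], init, self.n_points, self.span, self.max_iter, self.tol,
                self.df,
            )
            curves.append(curve)
            convs.append(conv)
            iters.append(it)

        if len(curves) > 1:
            curves, t_b, shared_arc = self._splice_shared(curves)
        else:
            t_b, shared_arc = 0.0, 0.0
        results = TrajectoryResults(
            model=self,
            curves=curves,
            t_b=float(t_b),
            lineage_names=self.lineage_names,
            converged=convs,
            n_iter=iters,
            shared_arc=float(shared_arc),
        )
        results.states = results.project(self.coords)
        return results

    def _branch_arc(self, curves: list[np.ndarray]) -> tuple[float, float, np.ndarray]:
        """Locate the branch point from the cells, not the curves.

        Along the trajectory, the distance D(s) between the mean positions
        of the cells nearer curve 1 and the cells nearer curve 2 has two
        regimes: before the branch the split is pure selection noise, so
        D sits at a small constant floor; after it, the true fate
        divergence (linear in latent time by assumption, hence locally
        linear in arc) takes over.  A hinge fit D(s) = a + b (s - s0)+
        over a changepoint grid places s0 at the kink, an estimate biased
        neither by the curves' pre-branch lean (which plagues
        curve-to-curve divergence) nor by the detection lag of threshold
        rules.  Falls back to the extent of the shared-prefix clusters'
        cells when the profile carries no usable growth.

        Returns (branch arc, bin half-width, per-cell nearest-curve arc).
        """
        ref = curves[0]
        arcs, dists = [], []
        for curve in curves:
            a, di = project_to_polyline(self.coords, curve)
            arcs.append(a)
            dists.append(di)
        side = np.argmin(np.column_stack(dists), axis=1)
        nearest_arc = np.column_stack(arcs)[np.arange(len(side)), side]

        n_bins = int(np.clip(len(self.coords) / 250, 20, 60))
        hi = float(np.quantile(nearest_arc, 0.99))
        edges = np.linspace(0.0, hi, n_bins + 1)
        min_cells = max(20, len(self.coords) // (4 * n_bins))
        centers, sep = [], []
        for lo_e, hi_e in zip(edges[:-1], edges[1:]):
            m = (nearest_arc >= lo_e) & (nearest_arc < hi_e)
            if m.sum() < min_cells:
                continue
            m1, m2 = m & (side == 0), m & (side != 0)
            if m1.sum() < 5 or m2.sum() < 5:
                continue
            d = np.linalg.norm(self.coords[m1].mean(axis=0) - self.coords[m2].mean(axis=0))
            centers.append(0.5 * (lo_e + hi_e))
            sep.append(d)
        centers = np.asarray(centers)
        sep = np.asarray(sep)
        def hinge_fit(ss, dd):
            best = (np.inf, None)
            for cand in ss[1:-1]:
                u = np.maximum(0.0, ss - cand)
                x = np.column_stack([np.ones_like(u), u])
                coef, *_ = np.linalg.lstsq(x, dd, rcond=None)
                if coef[1] <= 0:
                    continue
                sse = float(((dd - x @ coef) ** 2).sum())
                if sse < best[0]:
                    best = (sse, cand)
            return best[1]

        s0 = None
        if len(sep) >= 6 and sep.max() > 0:
            # fit the floor and the early rise only: far from the branch the
            # profile saturates (and in curved embeddings can plateau and
            # rise again), which would tilt the hinge.  The exact saturation
            # cut is arbitrary, so the estimate is the median over a range
            # of cuts.
            estimates = []
            for frac in (0.4, 0.5, 0.6, 0.7, 0.8):
                keep = np.ones(len(sep), dtype=bool)
                sat = np.flatnonzero(sep > frac * sep.max())
                if sat.size and sat[0] + 1 >= 8:
                    keep[sat[0] + 1 :] = False
                ss, dd = centers[keep], sep[keep]
                if len(ss) >= 6:
                    est = hinge_fit(ss, dd)
                    if est is not None:
                        estimates.append(est)
            if estimates:
                s0 = float(np.median(estimates))
        half_width = (edges[1] - edges[0]) if len(edges) > 1 else 1.0
        if s0 is not None:
            return float(s0), float(half_width), nearest_arc
        pre = np.isin(self.cluster_model.labels, self.tree.shared_prefix)
        if pre.any():
            arc, _ = project_to_polyline(self.coords[pre], ref)
            return float(np.quantile(arc, 0.95)), float(half_width), nearest_arc
        return float(0.25 * polyline_length(ref)), float(half_width), nearest_arc

    def _splice_shared(self, curves: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
        """Refit the shared pre-branch segment and splice it onto every lineage.

        Each lineage curve is cut at the branch arc located by
        :meth:`_branch_arc`; the shared segment is the pointwise average of
        the (near-coincident) pre-branch portions and each lineage keeps its
        post-branch remainder bridged to the shared endpoint.  Both final
        curves carry the identical shared point sequence.  The branch
        pseudotime t_b is then calibrated on the final geometry as the
        median final pseudotime of the cells the estimator localized at the
        branch, so t_b is directly comparable to cell pseudotimes (the
        splice slightly rescales arcs, which a raw splice length would
        ignore).
        """
        s_star, half_width, nearest_raw = self._branch_arc(curves)
        # translate the branch arc from the reference curve to each lineage
        cut_pt = _point_at_arc(curves[0], s_star)
        cuts = [s_star]
        for curve in curves[1:]:
            a0, _ = project_to_polyline(cut_pt[None, :], curve)
            cuts.append(float(a0[0]))
        # shared segment = pointwise average of the (near-coincident)
        # pre-branch portions, the discrete analogue of slingshot's
        # root-side shrinkage; its length stays close to both lineages'
        # own pre-branch arc scales
        l_posts = [polyline_length(c) - cut for c, cut in zip(curves, cuts)]
        l_sh = float(np.mean(cuts))
        l_post = max(max(l_posts), 1e-9)
        n_shared = int(round(self.n_points * l_sh / (l_sh + l_post)))
        n_shared = min(max(n_shared, 2), self.n_points - 2)
        pre_parts = [
            resample_polyline(_sub_polyline_to(c, cut), n_shared) for c, cut in zip(curves, cuts)
        ]
        shared_pts = np.mean(pre_parts, axis=0)
        end_pt = shared_pts[-1]
        out = []
        for curve, cut in zip(curves, cuts):
            post = _sub_polyline_from(curve, cut)
            post_pts = resample_polyline(np.vstack([end_pt, post]), self.n_points - n_shared + 1)
            out.append(np.vstack([shared_pts, post_pts[1:]]))
        shared_arc = polyline_length(shared_pts)
        # calibrate t_b against the branch-region cells on the final curves
        near = np.abs(nearest_raw - s_star) <= half_width
        if near.sum() < 50:
            near = np.argsort(np.abs(nearest_raw - s_star))[:200]
        arcs, dists = [], []
        for curve in out:
            a, di = project_to_polyline(self.coords[near], curve)
            arcs.append(a)
            dists.append(di)
        side = np.argmin(np.column_stack(dists), axis=1)
        final_pt = np.column_stack(arcs)[np.arange(len(side)), side]
        t_b = max(float(np.median(final_pt)), shared_arc)
        return out, t_b, shared_arc


def lineage_weights(dists: np.ndarray) -> np.ndarray:
    """Per-lineage weights w_l = min(1, d_min^2 / d_l^2), 0/0 := 1.

    The nearest lineage gets exactly 1; a cell equidistant from all curves
    (e.g. on the shared pre-branch segment) gets all-1 weights.
    """
    dists = np.atleast_2d(np.asarray(dists, dtype=float))
    d_min = dists.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d_min**2 / dists**2
    w[np.isnan(w)] = 1.0  # 0/0: cell sits on every curve
    w[np.isinf(w)] = 1.0
    return np.minimum(w, 1.0)


def assign_lineage(
    weights: np.ndarray, pseudotime: np.ndarray, t_b: float, lineage_names=("Hepatocyte", "Biliary")
) -> tuple[np.ndarray, int]:
    """Apply the lineage-assignment rule for a two-lineage model.

    Progenitor: pseudotime <= t_b.  Hepatocyte: lineage-1 weight exactly 1,
    lineage-2 weight < 1 and pseudotime > t_b; Biliary: the opposite
    weighting.  Post-branch all-1 ties are labelled Progenitor and counted
    (second return value).
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[1] != 2:
        raise ValueError("assignment rule is defined for exactly two lineages")
    if np.any((weights < 0) | (weights > 1)):
        raise ValueError("lineage weights must lie in [0, 1]")
    pseudotime = np.asarray(pseudotime, dtype=float)
    labels = np.full(len(weights), "Progenitor", dtype=object)
    post = pseudotime > t_b
    w1, w2 = weights[:, 0], weights[:, 1]
    labels[post & (w1 == 1.0) & (w2 < 1.0)] = lineage_names[0]
    labels[post & (w2 == 1.0) & (w1 < 1.0)] = lineage_names[1]
    ties = int((post & (w1 == 1.0) & (w2 == 1.0)).sum())
    return labels, ties


@dataclass
class TrajectoryResults:
    """Fitted branched trajectory: frozen curves, branch time and cell states."""

    model: PrincipalTrajectory
    curves: list[np.ndarray]
    t_b: float
    lineage_names: tuple[str, ...]
    converged: list[bool]
    n_iter: list[int]
    states: pd.DataFrame | None = None
    tie_count: int = 0
    #: arc length of the segment both curves share verbatim (<= t_b; the
    #: short stretch between them is the bridge at the branch region)
    shared_arc: float = 0.0

    @property
    def n_lineages(self) -> int:
        return len(self.curves)

    @property
    def curve_lengths(self) -> list[float]:
        return [polyline_length(c) for c in self.curves]

    def project(self, coords: np.ndarray) -> pd.DataFrame:
        """Project cells onto the frozen curves; no refitting occurs.

        Pseudotime per lineage is the arc length of the exact nearest point
        (clamped to [0, length]; cells beyond a terminus are flagged
        ``terminal``).  Weights follow :func:`lineage_weights`; the cell's
        headline ``pseudotime`` is taken along its weight-1 lineage.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        arcs, dists = [], []
        for curve in self.curves:
            a, d = project_to_polyline(coords, curve)
            arcs.append(a)
            dists.append(d)
        arcs = np.column_stack(arcs)
        dists = np.column_stack(dists)
        w = lineage_weights(dists)
        nearest = np.argmin(dists, axis=1)
        pseudotime = arcs[np.arange(len(coords)), nearest]
        lengths = self.curve_lengths
        terminal = np.any(
            np.column_stack([arcs[:, l] >= lengths[l] for l in range(self.n_lineages)])
            & (w == 1.0),
            axis=1,
        )
        out = pd.DataFrame(
            {
                **{f"t_{l+1}": arcs[:, l] for l in range(self.n_lineages)},
                **{f"w_{l+1}": w[:, l] for l in range(self.n_lineages)},
                **{f"d_{l+1}": dists[:, l] for l in range(self.n_lineages)},
                "pseudotime": pseudotime,
                "terminal": terminal,
            }
        )
        if self.n_lineages == 2:
            labels, ties = assign_lineage(w, pseudotime, self.t_b, self.lineage_names)
            out["label"] = labels
            self.tie_count = ties
        return out

    def summary(self) -> str:
        lines = [
            "Branched principal-curve trajectory",
            "=" * 42,
            f"lineages:        {self.n_lineages} ({', '.join(self.lineage_names)})",
            f"branch time t_b: {self.t_b:.4f} (arc-length units)",
        ]
        for i, (L, conv, it) in enumerate(zip(self.curve_lengths, self.converged, self.n_iter)):
            lines.append(
                f"  lineage {i+1}: length {L:.4f}, "
                f"{'converged' if conv else 'max_iter reached'} in {it} iterations"
            )
        if self.states is not None and "label" in self.states:
            frac = self.states["label"].value_counts(normalize=True)
            lines.append("atlas composition: " + ", ".join(f"{k} {v:.1%}" for k, v in frac.items()))
            lines.append(f"post-branch all-1 ties labelled Progenitor: {self.tie_count}")
        return "\n".join(lines)
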