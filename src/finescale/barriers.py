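"""Anisotropy and genetic-barrier model of a coancestry matrix.

Normalized pairwise coancestry is modelled as an exponential decay in an
effective distance: within a group of regions the distance is a Mahalanobis
form with a per-group anisotropic metric (angle, axis ratio, scale); across
groups the two metrics are averaged and a nonnegative barrier term is added:

    c_ij ~ beta0 + beta1 * exp(-lambda * d_ij)
    d_ij = sqrt(dx' M dx) + b_gh   (b_gh = 0 within a group)
    M_g  = s_g * R(theta_g)' diag(1, rho_g^2) R(theta_g)

The decay rate lambda is held fixed (default 1, distances absorb the decay
length through the per-group scales s_g) because the model is otherwise
invariant under a joint rescaling of (s_g, b_gh, lambda). Partition search
enumerates all set partitions of the regions into k groups and keeps the
best-fitting one; significance of the barrier comes from a permutation test
that shuffles the individuals' region assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .coancestry import CoancestryMatrix
from .exceptions import ValidationError


@dataclass
class SpatialGroup:
    """One group of regions with an anisotropic distance metric."""

    regions: set
    theta: float  # anisotropy angle, radians in [0, pi)
    rho: float  # anisotropy ratio >= 1
    scale: float  # metric scale > 0

    def __post_init__(self) -> None:
        if self.rho < 1:
            raise ValidationError("anisotropy ratio must be >= 1")
        if self.scale <= 0:
            raise ValidationError("metric scale must be > 0")
        self.theta = float(self.theta) % np.pi

    def metric(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        r = np.array([[c, s], [-s, c]])
        return self.scale * (r.T @ np.diag([1.0, self.rho**2]) @ r)


@dataclass
class BarrierModelFit:
    """Fitted barrier model: partition, group metrics, barriers, decay."""

    partition: dict  # region -> group index
    groups: list  # list[SpatialGroup], indexed by group
    barrier: dict  # (g, h) with g < h -> b_gh >= 0
    beta0: float
    beta1: float
    lam: float
    fit_score: float  # residual sum of squares
    p_value: float | None = None

    def barrier_between(self, g: int, h: int) -> float:
        if g == h:
            return 0.0
        return self.barrier[(min(g, h), max(g, h))]


def effective_distance(
    coord_i: np.ndarray,
    coord_j: np.ndarray,
    group_i: int,
    group_j: int,
    fit: BarrierModelFit,
) -> float:
    """Model distance between two individuals under a fitted model."""
    dx = np.asarray(coord_j, dtype=float) - np.asarray(coord_i, dtype=float)
    if group_i == group_j:
        m = fit.groups[group_i].metric()
        b = 0.0
    else:
        m = (fit.groups[group_i].metric() + fit.groups[group_j].metric()) / 2.0
        b = fit.barrier_between(group_i, group_j)
    return float(np.sqrt(dx @ m @ dx) + b)


def predict_coancestry(
    fit: BarrierModelFit, coords: np.ndarray, region_labels: np.ndarray
) -> np.ndarray:
    """Forward model: expected normalized coancestry for all pairs."""
    coords = np.asarray(coords, dtype=float)
    groups = np.array([fit.partition[r] for r in region_labels])
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = effective_distance(
                coords[i], coords[j], groups[i], groups[j], fit
            )
            out[i, j] = out[j, i] = fit.beta0 + fit.beta1 * np.exp(-fit.lam * d)
    return out


# ---------------------------------------------------------------------------
# Fitting


def _metric_from(theta: float, rho: float, scale: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    r = np.array([[c, s], [-s, c]])
    return scale * (r.T @ np.diag([1.0, rho**2]) @ r)


class _Problem:
    """Precomputed pair structure for the least-squares objective.

    The decay curve's linear coefficients (beta0, beta1 >= 0) are profiled
    out analytically for every candidate set of nonlinear parameters, so
    the optimizer only searches over the per-group metrics and barriers:
    layout (theta_g, rho_g, log s_g) per group, then log(b_gh + eps) per
    group pair when barriers are fitted.
    """

    def __init__(
        self,
        cmat: np.ndarray,
        coords: np.ndarray,
        group_ids: np.ndarray,
        n_groups: int,
        lam: float,
        with_barrier: bool,
    ) -> None:
        n = len(coords)
        iu, ju = np.triu_indices(n, k=1)
        self.c_obs = cmat[iu, ju]
        self.dx = coords[ju] - coords[iu]
        gi = np.minimum(group_ids[iu], group_ids[ju])
        gj = np.maximum(group_ids[iu], group_ids[ju])
        self.n_groups = n_groups
        self.lam = lam
        self.with_barrier = with_barrier
        self.pairs = list(itertools.combinations(range(n_groups), 2))
        self.pair_index = {p: k for k, p in enumerate(self.pairs)}
        self.cat_masks: dict[tuple[int, int], np.ndarray] = {}
        for g in range(n_groups):
            for h in range(g, n_groups):
                mask = (gi == g) & (gj == h)
                if mask.any():
                    self.cat_masks[(g, h)] = mask
        self.n_params = 3 * n_groups + (len(self.pairs) if with_barrier else 0)

    def unpack(self, x: np.ndarray):
        thetas = x[0 : 3 * self.n_groups : 3]
        rhos = x[1 : 3 * self.n_groups : 3]
        scales = np.exp(x[2 : 3 * self.n_groups : 3])
        if self.with_barrier:
            bs = np.maximum(np.exp(x[3 * self.n_groups :]) - _B_EPS, 0.0)
        else:
            bs = np.zeros(len(self.pairs))
        return thetas, rhos, scales, bs

    def distances(self, thetas, rhos, scales, bs) -> np.ndarray:
        d = np.empty_like(self.c_obs)
        metrics = [
            _metric_from(thetas[g], rhos[g], scales[g])
            for g in range(self.n_groups)
        ]
        for (g, h), mask in self.cat_masks.items():
            m = metrics[g] if g == h else (metrics[g] + metrics[h]) / 2.0
            dx = self.dx[mask]
            q = np.einsum("ij,jk,ik->i", dx, m, dx)
            dd = np.sqrt(np.maximum(q, 0.0))
            if g != h:
                dd = dd + bs[self.pair_index[(g, h)]]
            d[mask] = dd
        return d

    def _linear_fit(self, u: np.ndarray) -> tuple[float, float]:
        """Optimal (beta0, beta1 >= 0) for predictors c ~ beta0 + beta1*u."""
        um = u.mean()
        cm = self.c_obs.mean()
        su = ((u - um) ** 2).sum()
        if su <= 1e-300:
            return float(cm), 0.0
        b1 = float(((u - um) * (self.c_obs - cm)).sum() / su)
        if b1 < 0:
            return float(cm), 0.0
        return float(cm - b1 * um), b1

    def residuals(self, x: np.ndarray) -> np.ndarray:
        thetas, rhos, scales, bs = self.unpack(x)
        d = self.distances(thetas, rhos, scales, bs)
        u = np.exp(-self.lam * d)
        beta0, beta1 = self._linear_fit(u)
        return self.c_obs - (beta0 + beta1 * u)

    def rss(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)

    def linear_coefficients(self, x: np.ndarray) -> tuple[float, float]:
        thetas, rhos, scales, bs = self.unpack(x)
        u = np.exp(-self.lam * self.distances(thetas, rhos, scales, bs))
        return self._linear_fit(u)


_B_EPS = 1e-6


def _bounds(problem: _Problem, d_scale: float):
    lo: list[float] = []
    hi: list[float] = []
    lo_s = np.log(1e-6 / max(d_scale, 1e-9) ** 2)
    hi_s = np.log(1e4 / max(d_scale, 1e-9) ** 2)
    for _ in range(problem.n_groups):
        lo.extend([0.0, 1.0, lo_s])
        hi.extend([np.pi, 20.0, hi_s])
    if problem.with_barrier:
        for _ in problem.pairs:
            lo.append(np.log(_B_EPS))
            hi.append(np.log(50.0))
    return np.array(lo), np.array(hi)


def _initial_points(problem, lo, hi, rng, n_starts, d_scale):
    """One data-scaled isotropic start plus seeded random interior points."""
    pts = []
    x0 = np.zeros(problem.n_params)
    for g in range(problem.n_groups):
        x0[3 * g] = np.pi / 4
        x0[3 * g + 1] = 1.0
        x0[3 * g + 2] = np.log(1.0 / max(d_scale, 1e-9) ** 2)
    if problem.with_barrier:
        x0[3 * problem.n_groups :] = np.log(1.0)
    pts.append(x0)
    for _ in range(n_starts - 1):
        pts.append(lo + rng.random(problem.n_params) * (hi - lo))
    return pts


def _fit_problem(
    problem: _Problem,
    seed: int,
    n_starts: int,
    maxiter: int,
    extra_starts: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    d_scale = float(np.median(np.linalg.norm(problem.dx, axis=1)))
    if d_scale == 0:
        d_scale = 1.0
    lo, hi = _bounds(problem, d_scale)
    starts = _initial_points(problem, lo, hi, rng, n_starts, d_scale)
    if extra_starts:
        starts = list(extra_starts) + starts
    best_x, best_f = None, np.inf
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                problem.residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                max_nfev=maxiter,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        f = float(res.fun @ res.fun)
        if f < best_f:
            best_f, best_x = f, res.x
    if best_x is None:
        raise ValidationError(
            "barrier-model optimizer failed to converge on every start"
        )
    return best_x, best_f


def _group_ids(region_labels: np.ndarray, partition: dict) -> np.ndarray:
    return np.array([partition[r] for r in region_labels])


def fit_barrier_model(
    coancestry: CoancestryMatrix,
    coords: np.ndarray,
    partition: dict,
    n_starts: int = 20,
    seed: int = 0,
    lam: float = 1.0,
    maxiter: int = 500,
    with_barrier: bool = True,
) -> BarrierModelFit:
    """Least-squares fit of the anisotropy/barrier model for one partition.

    The coancestry matrix is symmetrized and divided by its grand mean
    before fitting. Multi-start bounded local optimization; the first start
    is the fitted no-barrier shared-metric model, so the barrier model's
    score never exceeds the nested model's.
    """
    if coancestry.region_labels is None:
        raise ValidationError("coancestry matrix carries no region labels")
    cmat = coancestry.normalized()
    if not np.all(np.isfinite(cmat)):
        raise ValidationError("coancestry matrix has non-finite entries")
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(coancestry.region_labels)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValidationError("every region needs at least 2 individuals")
    group_ids = _group_ids(labels, partition)
    n_groups = int(group_ids.max()) + 1

    # Nested no-barrier, shared-metric fit used both as a reference and as
    # the first start of the full model.
    null_problem = _Problem(
        cmat, coords, np.zeros_like(group_ids), 1, lam, with_barrier=False
    )
    null_x, null_f = _fit_problem(
        null_problem, seed, max(4, n_starts // 2), maxiter
    )
    if not with_barrier and n_groups == 1:
        beta0, beta1 = null_problem.linear_coefficients(null_x)
        thetas, rhos, scales, _ = null_problem.unpack(null_x)
        groups = [
            SpatialGroup(set(partition), float(thetas[0]), float(rhos[0]), float(scales[0]))
        ]
        return BarrierModelFit(
            partition=dict(partition), groups=groups, barrier={},
            beta0=float(beta0), beta1=float(beta1), lam=lam,
            fit_score=null_f, p_value=None,
        )

    problem = _Problem(cmat, coords, group_ids, n_groups, lam, with_barrier)
    # Embed the null solution in the full parameter space so the barrier
    # model's score never exceeds the nested model's.
    x_null = np.zeros(problem.n_params)
    for g in range(n_groups):
        x_null[3 * g : 3 * g + 3] = null_x[:3]
    if with_barrier:
        x_null[3 * n_groups :] = np.log(_B_EPS)
    best_x, best_f = _fit_problem(
        problem, seed + 1, n_starts, maxiter, extra_starts=[x_null]
    )
    if null_f < best_f:
        best_x, best_f = x_null, null_f
    beta0, beta1 = problem.linear_coefficients(best_x)
    thetas, rhos, scales, bs = problem.unpack(best_x)
    groups = []
    for g in range(n_groups):
        regions = {r for r, gg in partition.items() if gg == g}
        groups.append(
            SpatialGroup(regions, float(thetas[g]), float(rhos[g]), float(scales[g]))
        )
    barrier = {
        p: float(bs[k]) for k, p in enumerate(problem.pairs)
    } if with_barrier else {p: 0.0 for p in problem.pairs}
    return BarrierModelFit(
        partition=dict(partition),
        groups=groups,
        barrier=barrier,
        beta0=float(beta0),
        beta1=float(beta1),
        lam=lam,
        fit_score=float(best_f),
        p_value=None,
    )


def fit_null_model(
    coancestry: CoancestryMatrix,
    coords: np.ndarray,
    n_starts: int = 10,
    seed: int = 0,
    lam: float = 1.0,
    maxiter: int = 500,
) -> BarrierModelFit:
    """No-barrier nested model: one shared metric, b identically 0."""
    labels = np.asarray(coancestry.region_labels)
    partition = {r: 0 for r in np.unique(labels)}
    return fit_barrier_model(
        coancestry, coords, partition, n_starts=n_starts, seed=seed,
        lam=lam, maxiter=maxiter, with_barrier=False,
    )


def set_partitions(items: list, k: int):
    """All set partitions of ``items`` into exactly k nonempty blocks."""
    items = list(items)
    if k > len(items):
        raise ValidationError("k exceeds the number of regions")

    def helper(seq, k):
        if len(seq) == k:
            yield [[x] for x in seq]
            return
        if k == 1:
            yield [list(seq)]
            return
        first, rest = seq[0], seq[1:]
        for part in helper(rest, k - 1):
            yield [[first]] + part
        for part in helper(rest, k):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]

    yield from helper(items, k)


def search_partitions(
    coancestry: CoancestryMatrix,
    coords: np.ndarray,
    k: int = 2,
    n_starts: int = 8,
    seed: int = 0,
    lam: float = 1.0,
    maxiter: int = 400,
) -> tuple[BarrierModelFit, pd.DataFrame]:
    """Fit every k-group partition of the regions; return the best fit and
    a ranked table of all candidate partitions."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    labels = np.asarray(coancestry.region_labels)
    regions = sorted(set(labels))
    best_fit = None
    rows = []
    for blocks in set_partitions(regions, k):
        partition = {r: g for g, block in enumerate(blocks) for r in block}
        fit = fit_barrier_model(
            coancestry, coords, partition, n_starts=n_starts,
            seed=seed, lam=lam, maxiter=maxiter,
        )
        rows.append(
            {
                "partition": " | ".join(
                    ",".join(sorted(b)) for b in sorted(blocks, key=min)
                ),
                "fit_score": fit.fit_score,
                "max_barrier": max(fit.barrier.values()) if fit.barrier else 0.0,
            }
        )
        if best_fit is None or fit.fit_score < best_fit.fit_score:
            best_fit = fit
    table = pd.DataFrame(rows).sort_values("fit_score").reset_index(drop=True)
    return best_fit, table


def _improvement_statistic(
    cmat: np.ndarray,
    coords: np.ndarray,
    labels: np.ndarray,
    partitions: list[dict],
    lam: float,
    seed: int,
    n_starts: int,
    maxiter: int,
) -> float:
    """Fit-score improvement of the best barrier partition over the
    no-barrier shared-metric model (one null fit, reused as a start)."""
    null_problem = _Problem(
        cmat, coords, np.zeros(len(labels), dtype=int), 1, lam, False
    )
    null_x, null_f = _fit_problem(null_problem, seed, max(2, n_starts), maxiter)
    best_alt = np.inf
    for k, partition in enumerate(partitions):
        group_ids = _group_ids(labels, partition)
        n_groups = int(group_ids.max()) + 1
        problem = _Problem(cmat, coords, group_ids, n_groups, lam, True)
        x0 = np.zeros(problem.n_params)
        for g in range(n_groups):
            x0[3 * g : 3 * g + 3] = null_x[:3]
        x0[3 * n_groups :] = np.log(_B_EPS)
        _, f = _fit_problem(
            problem, seed + 7 * k, n_starts, maxiter, extra_starts=[x0]
        )
        best_alt = min(best_alt, f)
    return max(0.0, null_f - best_alt)


def barrier_permutation_test(
    coancestry: CoancestryMatrix,
    coords: np.ndarray,
    best_fit: BarrierModelFit,
    n_perm: int = 199,
    seed: int = 0,
    n_starts: int = 4,
    maxiter: int = 250,
    early_stop_h: int | None = 10,
    search_k: int | None = None,
) -> float:
    """Permutation significance of the barrier-model improvement.

    The statistic is the fit-score improvement of the barrier model over
    the nested no-barrier model; the null shuffles which individual
    carries which (region, coordinate) assignment. When ``best_fit`` came
    out of a partition search, pass ``search_k`` so that every permutation
    (and the observed statistic) replays the search over all k-group
    partitions — refitting only the selected partition would ignore the
    selection step and make the test anti-conservative.

    Uses the sequential Monte Carlo rule of Besag & Clifford: if
    ``early_stop_h`` null statistics at least as large as the observed one
    are seen after i permutations, stop and report p = h / i; otherwise
    p = (1 + count) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    labels = np.asarray(coancestry.region_labels)
    coords = np.asarray(coords, dtype=float)
    cmat = coancestry.normalized()
    if search_k is not None:
        regions = sorted(set(labels))
        partitions = [
            {r: g for g, block in enumerate(blocks) for r in block}
            for blocks in set_partitions(regions, search_k)
        ]
    else:
        partitions = [best_fit.partition]

    def improvement(lab: np.ndarray, crd: np.ndarray, s: int) -> float:
        return _improvement_statistic(
            cmat, crd, lab, partitions, best_fit.lam, s, n_starts, maxiter
        )

    obs = improvement(labels, coords, seed)
    rng = np.random.default_rng(seed)
    count = 0
    for i in range(n_perm):
        perm = rng.permutation(len(labels))
        stat = improvement(labels[perm], coords[perm], seed + 1000 + i)
        if stat >= obs - 1e-12:
            count += 1
            if early_stop_h is not None and count >= early_stop_h:
                return count / (i + 1)
    return (1 + count) / (n_perm + 1)
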