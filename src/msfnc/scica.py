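"""Subject-level spatially constrained ICA (ICA-with-reference).

For each reference spatial map, a single component is estimated from the
subject's whitened data by maximizing a convex blend of two objectives:

    F(w) = (1 - lambda) * Jhat(w'Z) + lambda * |rho(w'Z, r)|

where ``Jhat(y) = (E[G(y)] - E[G(nu)])^2`` is the log-cosh negentropy
approximation (``nu`` standard normal), ``Z`` is the spatially whitened data
(components x voxels) and ``r`` the z-scored reference map.  ``lambda = 0``
is plain one-unit FastICA; ``lambda = 1`` returns the projection of the
reference onto the whitened subspace.  Optimization alternates a one-unit
negentropy fixed-point step with a blend toward the reference direction; a
step-halving safeguard keeps the objective trace non-decreasing, which also
serves as the convergence certificate in degenerate cases.

Each reference is estimated independently (one-unit extraction, no joint
decorrelation): components from different references — in particular from
different model orders — may legitimately correlate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import BoldScan, TemplateSet
from .preprocess import TimeCourseSet

# E[log cosh nu] for nu ~ N(0,1), via 64-point Gauss-Hermite quadrature
_nodes, _weights = np.polynomial.hermite_e.hermegauss(64)
_EG_GAUSS = float((_weights * np.log(np.cosh(_nodes))).sum() / _weights.sum())


class RankDeficiencyError(ValueError):
    pass


def whiten_spatial(scan: BoldScan, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Spatial whitening: data -> K uncorrelated, unit-variance voxel maps.

    Returns ``(Z, D)`` with ``Z`` (K x voxels; rows zero-mean, unit variance,
    Gram = identity) and the dewhitening matrix ``D`` (time x K) such that
    ``D @ Z`` reconstructs the rank-K part of the (spatially demeaned) data.
    """
    if K < 1 or K > min(scan.n_volumes, scan.n_voxels):
        raise ValueError(f"K={K} outside [1, min(time, voxels)]")
    y = scan.data.T.astype(float)                       # time x voxels
    y = y - y.mean(axis=1, keepdims=True)               # demean each map
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < K:
        raise RankDeficiencyError(
            f"data rank {rank} below requested K={K}"
        )
    v = scan.n_voxels
    z = np.sqrt(v) * vt[:K]
    d = u[:, :K] * (s[:K] / np.sqrt(v))
    return z, d


@dataclass
class ComponentDiagnostics:
    reference_similarity: float
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def _objective(z: np.ndarray, w: np.ndarray, ref: np.ndarray, lam: float) -> float:
    y = w @ z
    neg = (np.mean(np.log(np.cosh(y))) - _EG_GAUSS) ** 2
    rho = float(y @ ref) / (len(ref) * y.std() * ref.std())
    return (1.0 - lam) * neg + lam * abs(rho)


def _normalize(w: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(w)
    if n == 0:
        raise ZeroDivisionError("zero-norm weight vector")
    return w / n


def extract_component(
    whitened: np.ndarray,
    reference: np.ndarray,
    lam: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, ComponentDiagnostics]:
    """Estimate one component constrained toward ``reference``.

    Returns ``(w, component_map, diagnostics)``; the map is z-scored over
    voxels and sign-flipped so its correlation with the reference is
    non-negative.  Initialization is the (deterministic) projection of the
    reference onto the whitened space.
    """
    z = np.asarray(whitened, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ref = (ref - ref.mean()) / (ref.std() if ref.std() else 1.0)
    v = z.shape[1]

    proj = z @ ref
    norm = np.linalg.norm(proj)
    if norm < 1e-10 * np.sqrt(v):
        warnings.warn(
            "reference is (near-)orthogonal to the data span; the constraint "
            "cannot guide extraction",
            stacklevel=2,
        )
        c = np.zeros(z.shape[0])
        c[0] = 1.0
    else:
        c = proj / norm
    w = c.copy()

    trace = [_objective(z, w, ref, lam)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        y = w @ z
        gy = np.tanh(y)
        w_plus = (z @ gy) / v - np.mean(1.0 - gy**2) * w
        if np.linalg.norm(w_plus) < 1e-12:
            w_plus = w.copy()
        w_plus = _normalize(w_plus)
        if w_plus @ w < 0:                      # fixed point is sign-blind
            w_plus = -w_plus
        c_eff = c if (w @ c) >= 0 else -c       # blend toward |rho| increase
        cand = _normalize((1.0 - lam) * w_plus + lam * c_eff)

        # step-halving safeguard: keep the objective trace non-decreasing
        t, f_prev = 1.0, trace[-1]
        w_new, f_new = cand, _objective(z, cand, ref, lam)
        while f_new < f_prev - 1e-12 and t > 1.0 / 64:
            t *= 0.5
            w_new = _normalize(w + t * (cand - w))
            f_new = _objective(z, w_new, ref, lam)
        if f_new < f_prev - 1e-12:              # no uphill step exists
            converged = True
            break
        delta = 1.0 - abs(float(w_new @ w))
        w = w_new
        trace.append(max(f_new, f_prev))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"constrained extraction did not converge in {max_iter} iterations",
            stacklevel=2,
        )

    comp = w @ z
    sim = float(np.corrcoef(comp, ref)[0, 1]) if comp.std() > 0 else 0.0
    if sim < 0:
        w, comp, sim = -w, -comp, -sim
    comp = (comp - comp.mean()) / (comp.std() if comp.std() else 1.0)
    diag = ComponentDiagnostics(
        reference_similarity=sim,
        iterations=it,
        converged=converged,
        objective_trace=trace,
    )
    return w, comp, diag


def backproject_timecourse(scan: BoldScan, comp_map: np.ndarray) -> np.ndarray:
    """Least-squares time course of a spatial map: a(t) = X[:,t].s / s.s.

    The output is variance-normalized (zero mean, unit sd); a map orthogonal
    to every volume yields the zero series.
    """
    s = np.asarray(comp_map, dtype=float)
    ss = float(s @ s)
    if ss == 0:
        raise ValueError("zero-norm component map")
    a = (scan.data.T @ s) / ss
    sd = a.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def joint_timecourses(scan: BoldScan, maps: np.ndarray) -> np.ndarray:
    """Joint least-squares time courses for a stack of spatial maps.

    Solves ``X ~ maps' A`` for all maps of one model order at once, so
    shared background between maps does not leak between their courses
    (single-map projection suffers that cross-talk).  Returns time x n_maps,
    each course variance-normalized; an all-zero course stays zero.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if not maps.any(axis=1).all():
        raise ValueError("zero-norm component map")
    a, *_ = np.linalg.lstsq(maps.T, scan.data, rcond=None)
    a = a.T                                        # time x n_maps
    sd = a.std(axis=0, keepdims=True)
    return np.where(sd == 0, 0.0, (a - a.mean(axis=0, keepdims=True)) / np.where(sd == 0, 1.0, sd))


@dataclass
class SubjectICAResult:
    """Per-subject constrained-ICA output across all model orders."""

    subject_id: str
    icn_ids: list[str]
    orders: list[int | str]
    domains: list[str]
    maps: np.ndarray          # n_icns x voxels, z-scored
    timecourses: np.ndarray   # time x n_icns, variance-normalized
    diagnostics: list[ComponentDiagnostics]
    tr: float

    def __post_init__(self) -> None:
        assert self.maps.shape[0] == len(self.icn_ids) == self.timecourses.shape[1]
        for d, icn in zip(self.diagnostics, self.icn_ids):
            if d.reference_similarity < 0:
                raise ValueError(f"{icn}: negative reference similarity")

    def timecourse_set(self) -> TimeCourseSet:
        return TimeCourseSet(
            data=self.timecourses,
            tr=self.tr,
            icn_ids=list(self.icn_ids),
            orders=list(self.orders),
            domains=list(self.domains),
            subject_id=self.subject_id,
        )

    def mean_similarity(self) -> float:
        return float(np.mean([d.reference_similarity for d in self.diagnostics]))


def extract_subject(
    scan: BoldScan,
    template: TemplateSet,
    lam: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SubjectICAResult:
    """Constrained extraction of every template ICN from one subject's scan.

    Each model order is processed independently: the data are whitened to
    K = (number of references in that order) dimensions, and one constrained
    component is estimated per reference.  Results from all orders are
    concatenated in template entry order.
    """
    if scan.n_voxels != template.maps.shape[1]:
        raise ValueError(
            f"scan has {scan.n_voxels} voxels but template maps have "
            f"{template.maps.shape[1]}"
        )
    n = len(template)
    maps = np.empty((n, scan.n_voxels))
    tcs = np.empty((scan.n_volumes, n))
    diags: list[ComponentDiagnostics | None] = [None] * n
    for order in template.orders:
        idx = template.order_indices(order)
        z, _ = whiten_spatial(scan, K=len(idx))
        for i in idx:
            _, comp, diag = extract_component(
                z, template.maps[i], lam=lam, tol=tol, max_iter=max_iter
            )
            maps[i] = comp
            diags[i] = diag
        tcs[:, idx] = joint_timecourses(scan, maps[idx])
    return SubjectICAResult(
        subject_id=scan.subject_id,
        icn_ids=template.icn_ids,
        orders=[e.model_order for e in template.entries],
        domains=[e.domain for e in template.entries],
        maps=maps,
        timecourses=tcs,
        diagnostics=diags,  # type: ignore[arg-type]
        tr=scan.tr,
    )
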