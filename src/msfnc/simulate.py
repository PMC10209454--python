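"""Synthetic resting-state cohorts with planted multiscale network structure.

The generator emulates the statistical skeleton of a two-cohort rsfMRI case/
control study: Gaussian-blob spatial networks at a fine and a coarse spatial
scale, subject time courses drawn from group-specific correlation structure,
volumes mixed as maps x time courses plus white noise, and PANSS-like symptom
scores linearly coupled to chosen connectivity pairs.  Everything planted is
recorded in a :class:`GroundTruth` bundle so each downstream stage can be
tested against known truth.

Defaults describe a desk-scale study: a 20x20x10 grid, 10 fine + 5 coarse
networks, 135 volumes at TR = 2 s, group differences of 0.6 on the Fisher-z
scale on five fine-network pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import DOMAIN_ORDER, BoldScan, CohortManifest, TemplateEntry, TemplateSet
from .preprocess import TimeCourseSet

FINE_TAG = "fine"
COARSE_TAG = "coarse"

#: blob support threshold: voxels within ~3 sigma of any blob center
_SUPPORT = np.exp(-4.5)


class NotPositiveDefiniteError(ValueError):
    pass


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests.

    ``diff_pairs`` lists fine-network index pairs (i < j) whose time-course
    correlation differs between groups by ``delta_z`` on the Fisher-z scale
    (positive = increased in SZ).  ``score_pairs_pos``/``_neg`` are disjoint
    pair subsets that linearly drive the positive/negative symptom scores.
    """

    grid: tuple[int, int, int]
    fine_maps: np.ndarray                  # F x V (z-scored, mask voxels)
    coarse_maps: np.ndarray                # C x V
    mask: np.ndarray                       # 3-D bool
    fine_centers: np.ndarray               # F x 3
    coarse_membership: dict[int, list[int]]
    blob_sd: float
    sigma_tc: np.ndarray = field(default=None)   # F x F correlation
    sigma_sz: np.ndarray = field(default=None)
    diff_pairs: list[tuple[int, int]] = field(default_factory=list)
    delta_z: np.ndarray = field(default=None)    # per diff pair
    score_pairs_pos: list[tuple[int, int]] = field(default_factory=list)
    score_pairs_neg: list[tuple[int, int]] = field(default_factory=list)
    beta_pos: float = 6.0
    beta_neg: float = 5.0
    score_noise_sd: float = 1.0
    coarse_alpha: float = 0.3
    seed: int = 0

    @property
    def n_fine(self) -> int:
        return self.fine_maps.shape[0]

    @property
    def n_coarse(self) -> int:
        return self.coarse_maps.shape[0]

    def fine_ids(self) -> list[str]:
        return [f"fine{i:02d}" for i in range(self.n_fine)]

    def coarse_ids(self) -> list[str]:
        return [f"coarse{i:02d}" for i in range(self.n_coarse)]

    def pair_label(self, pair: tuple[int, int]) -> str:
        ids = self.fine_ids()
        i, j = pair
        return f"{ids[i]}|{ids[j]}"

    def validate(self) -> None:
        for name, sig in (("sigma_tc", self.sigma_tc), ("sigma_sz", self.sigma_sz)):
            if sig is None:
                continue
            if not np.allclose(sig, sig.T):
                raise NotPositiveDefiniteError(f"{name} not symmetric")
            if not np.allclose(np.diag(sig), 1.0):
                raise NotPositiveDefiniteError(f"{name} diagonal != 1")
            if np.linalg.eigvalsh(sig).min() <= 0:
                raise NotPositiveDefiniteError(f"{name} not positive definite")
        members = [m for ms in self.coarse_membership.values() for m in ms]
        if len(members) != len(set(members)):
            raise ValueError("coarse groups must be disjoint")
        for i, j in self.diff_pairs:
            if not (0 <= i < j < self.n_fine):
                raise ValueError(f"diff pair {(i, j)} outside fine networks")

    def save(self, path: str | Path) -> Path:
        payload = {
            "grid": list(self.grid),
            "coarse_membership": {str(k): v for k, v in self.coarse_membership.items()},
            "sigma_tc": self.sigma_tc.tolist(),
            "sigma_sz": self.sigma_sz.tolist(),
            "diff_pairs": [list(p) for p in self.diff_pairs],
            "delta_z": np.asarray(self.delta_z).tolist(),
            "score_pairs_pos": [list(p) for p in self.score_pairs_pos],
            "score_pairs_neg": [list(p) for p in self.score_pairs_neg],
            "beta_pos": self.beta_pos,
            "beta_neg": self.beta_neg,
            "score_noise_sd": self.score_noise_sd,
            "coarse_alpha": self.coarse_alpha,
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# spatial template


def _render_blobs(
    centers: np.ndarray, grid: tuple[int, int, int], blob_sd: float
) -> np.ndarray:
    """Gaussian blobs on the full grid, one row per center (F x prod(grid))."""
    axes = np.indices(grid).reshape(3, -1).T  # V x 3
    d2 = ((axes[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * blob_sd**2))


def _zscore_rows(maps: np.ndarray) -> np.ndarray:
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    return (maps - mu) / np.where(sd == 0, 1.0, sd)


def make_blob_template(
    grid: tuple[int, int, int] = (20, 20, 10),
    n_fine: int = 10,
    n_coarse: int = 5,
    blob_sd: float = 1.8,
    jitter_sd: float = 0.5,
    seed: int = 0,
) -> tuple[TemplateSet, GroundTruth]:
    """Build a two-order blob template and the matching partial ground truth.

    Fine networks are Gaussian blobs at distinct centers; each coarse network
    is the voxelwise max over >= 2 member fine networks, giving the template a
    coarse order of ``n_coarse`` entries and a fine order of ``n_fine``.
    Coarse groups carry a functional-domain label which their members inherit.
    With ``n_coarse = 0`` a single-order (fine only) template is returned.
    """
    if n_fine < 1 or n_coarse < 0 or (n_coarse and n_fine < 2 * n_coarse):
        raise ValueError("need n_fine >= 2*n_coarse >= 0 and n_fine >= 1")
    rng = np.random.default_rng(seed)
    centers = _place_centers(grid, n_fine, blob_sd, rng)

    fine_full = _render_blobs(centers, grid, blob_sd)
    membership: dict[int, list[int]] = {}
    if n_coarse:
        # contiguous partition: every fine network belongs to one coarse group
        bounds = np.linspace(0, n_fine, n_coarse + 1).astype(int)
        membership = {
            c: list(range(bounds[c], bounds[c + 1])) for c in range(n_coarse)
        }
        coarse_full = np.stack(
            [fine_full[m].max(axis=0) for m in membership.values()]
        )
    else:
        coarse_full = np.empty((0, fine_full.shape[1]))

    support = np.concatenate([fine_full, coarse_full]).max(axis=0) > _SUPPORT
    mask = support.reshape(grid)

    fine_maps = _zscore_rows(fine_full[:, support])
    coarse_maps = _zscore_rows(coarse_full[:, support]) if n_coarse else coarse_full[:, support]

    domains = list(DOMAIN_ORDER[:7])
    entries: list[TemplateEntry] = []
    fine_domain = {}
    if n_coarse:
        for c, members in membership.items():
            dom = domains[c % len(domains)]
            for m in members:
                fine_domain[m] = dom
        for c in range(n_coarse):
            entries.append(
                TemplateEntry(f"coarse{c:02d}", COARSE_TAG, domains[c % len(domains)])
            )
    else:
        fine_domain = {i: domains[i % len(domains)] for i in range(n_fine)}
    for i in range(n_fine):
        entries.append(TemplateEntry(f"fine{i:02d}", FINE_TAG, fine_domain[i]))

    maps = np.vstack([coarse_maps, fine_maps]) if n_coarse else fine_maps
    template = TemplateSet(entries=entries, maps=maps, mask=mask)
    fine_domains = [fine_domain[i] for i in range(n_fine)]
    coarse_domains = [domains[c % len(domains)] for c in range(n_coarse)]
    gt = GroundTruth(
        grid=grid,
        fine_maps=fine_maps,
        coarse_maps=coarse_maps,
        mask=mask,
        fine_centers=centers,
        coarse_membership=membership,
        blob_sd=blob_sd,
        seed=seed,
    )
    gt.jitter_sd = jitter_sd
    gt.fine_domains = fine_domains
    gt.coarse_domains = coarse_domains
    return template, gt


def _place_centers(
    grid: tuple[int, int, int], n: int, blob_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Distinct blob centers with margins; fatal if the grid cannot hold them."""
    margin = max(2.0, 1.5 * blob_sd)
    lo = np.full(3, margin)
    hi = np.array(grid) - 1 - margin
    if np.any(hi <= lo):
        raise ValueError(f"grid {grid} too small for blobs of sd {blob_sd}")
    min_sep = 2.0 * blob_sd
    # greedy dart-throwing can dead-end; restart from scratch when stuck
    best = 0
    for _ in range(100):
        centers: list[np.ndarray] = []
        for _ in range(2000):
            cand = lo + rng.random(3) * (hi - lo)
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
                if len(centers) == n:
                    return np.array(centers)
        best = max(best, len(centers))
    raise ValueError(
        f"grid {grid} too small to place {n} separated blobs (placed {best})"
    )


# ---------------------------------------------------------------------------
# covariance structure


def nearest_correlation(
    mat: np.ndarray,
    fixed: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    floor: float = 1e-3,
) -> np.ndarray:
    """Nearest correlation matrix by Higham-style alternating projections.

    Entries flagged in ``fixed`` (boolean, symmetric) are re-imposed after
    each eigenvalue projection so planted values survive the repair exactly.
    Eigenvalues are floored at ``floor`` (not zero) so the iteration targets
    a strictly positive-definite matrix rather than the PSD boundary.
    """
    target = np.asarray(mat, dtype=float)
    y = target.copy()
    ds = np.zeros_like(y)
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh(r)
        x = (vecs * np.clip(vals, floor, None)) @ vecs.T
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if fixed is not None:
            y[fixed] = target[fixed]
        if np.linalg.eigvalsh(y).min() > tol:
            return y
    raise NotPositiveDefiniteError(
        "could not repair matrix to positive definite; reduce the planted "
        "effect sizes or base correlations (nearest-PD projection failed)"
    )


def plant_group_difference(
    gt: GroundTruth,
    n_diff_pairs: int = 5,
    delta_z: float | np.ndarray = 0.6,
    base_within: float = 0.35,
    base_between: float = 0.05,
    n_score_pairs: int = 1,
    beta_pos: float = 6.0,
    beta_neg: float = 5.0,
    score_noise_sd: float = 1.0,
    seed: int | None = None,
) -> GroundTruth:
    """Fill in group covariances, discriminative pairs and score couplings.

    The control correlation matrix has ``base_within`` within coarse groups
    and ``base_between`` elsewhere; the SZ matrix shifts ``n_diff_pairs``
    between-group pairs by ``delta_z`` on the Fisher-z scale.  If the shift
    breaks positive definiteness the matrix is repaired with the planted
    entries held fixed.
    """
    rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)
    f = gt.n_fine
    sigma = np.full((f, f), base_between)
    for members in gt.coarse_membership.values():
        for a in members:
            for b in members:
                sigma[a, b] = base_within
    np.fill_diagonal(sigma, 1.0)

    # candidate pairs: between coarse groups, so planted effects are
    # cross-network couplings rather than within-blob redundancy
    group_of = {m: c for c, ms in gt.coarse_membership.items() for m in ms}
    candidates = [
        (i, j)
        for i in range(f)
        for j in range(i + 1, f)
        if group_of.get(i, i) != group_of.get(j, j)
    ]
    if n_diff_pairs > len(candidates):
        raise ValueError("not enough between-group pairs to plant differences")
    # prefer node-disjoint pairs: planted effects then perturb independent
    # 2x2 blocks of the correlation matrix, which keeps it comfortably PD
    perm = rng.permutation(len(candidates))
    diff_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for c in perm:
        i, j = candidates[c]
        if i not in used and j not in used:
            diff_pairs.append((i, j))
            used.update((i, j))
        if len(diff_pairs) == n_diff_pairs:
            break
    for c in perm:                          # top up with overlapping pairs
        if len(diff_pairs) == n_diff_pairs:
            break
        if candidates[c] not in diff_pairs:
            diff_pairs.append(candidates[c])
    diff_pairs = sorted(diff_pairs)
    dz = np.broadcast_to(np.asarray(delta_z, dtype=float), (n_diff_pairs,)).copy()

    sigma_sz = sigma.copy()
    for (i, j), d in zip(diff_pairs, dz):
        r_new = np.tanh(np.arctanh(sigma[i, j]) + d)
        sigma_sz[i, j] = sigma_sz[j, i] = r_new

    fixed = np.zeros_like(sigma_sz, dtype=bool)
    for i, j in diff_pairs:
        fixed[i, j] = fixed[j, i] = True
    if np.linalg.eigvalsh(sigma_sz).min() <= 0:
        sigma_sz = nearest_correlation(sigma_sz, fixed=fixed)
    if np.linalg.eigvalsh(sigma).min() <= 0:
        sigma = nearest_correlation(sigma)

    gt.sigma_tc = sigma
    gt.sigma_sz = sigma_sz
    gt.diff_pairs = diff_pairs
    gt.delta_z = dz
    gt.score_pairs_pos = diff_pairs[:n_score_pairs]
    gt.score_pairs_neg = diff_pairs[n_score_pairs : 2 * n_score_pairs]
    gt.beta_pos = beta_pos
    gt.beta_neg = beta_neg
    gt.score_noise_sd = score_noise_sd
    gt.validate()
    return gt


def population_template(template: TemplateSet, gt: GroundTruth) -> TemplateSet:
    """Re-express template maps in the preprocessed-data convention.

    Real templates are estimated from voxel-variance-normalized data, where a
    network's apparent map is its mixing map divided by each voxel's signal
    std.  Flattening the raw blob maps by the analytic population (control)
    voxel std puts the references in the convention of the volumes the
    pipeline will see, which is what makes them good references.
    """
    var_v = np.einsum("fv,fg,gv->v", gt.fine_maps, gt.sigma_tc, gt.fine_maps)
    if gt.n_coarse:
        var_v = var_v + gt.coarse_alpha**2 * (gt.coarse_maps**2).sum(axis=0)
    n0 = np.sqrt(var_v)
    n0[n0 == 0] = 1.0
    fine = _zscore_rows(gt.fine_maps / n0)
    if gt.n_coarse:
        coarse = _zscore_rows(gt.coarse_maps / n0)
        maps = np.vstack([coarse, fine])
    else:
        maps = fine
    return TemplateSet(
        entries=template.entries, maps=maps, mask=template.mask,
        affine=template.affine,
    )


def make_ground_truth(
    grid: tuple[int, int, int] = (20, 20, 10),
    n_fine: int = 10,
    n_coarse: int = 5,
    n_diff_pairs: int = 5,
    delta_z: float = 0.6,
    seed: int = 0,
    **kwargs,
) -> tuple[TemplateSet, GroundTruth]:
    """Convenience: blob template + planted covariance/score structure.

    The returned template is in the preprocessed-data (variance-normalized)
    convention — see :func:`population_template`.
    """
    template, gt = make_blob_template(
        grid=grid, n_fine=n_fine, n_coarse=n_coarse, seed=seed
    )
    plant_group_difference(
        gt, n_diff_pairs=n_diff_pairs, delta_z=delta_z, **kwargs
    )
    return population_template(template, gt), gt


# ---------------------------------------------------------------------------
# cohort sampling


def _bandlimit(x: np.ndarray, tr: float, band=(0.01, 0.15)) -> np.ndarray:
    """Shape white columns to a 0.01-0.15 Hz dominant spectrum (zero-phase).

    The same linear filter on every channel preserves the zero-lag cross-
    correlation structure in expectation, so planted covariances survive.
    """
    nyq = 0.5 / tr
    sos = signal.butter(5, [band[0] / nyq, min(band[1] / nyq, 0.99)], "bandpass", output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


@dataclass
class Cohort:
    """A sampled cohort plus its planted per-subject truth."""

    scans: list[BoldScan]
    manifest: CohortManifest
    fine_tcs: dict[str, np.ndarray]        # subject -> T x F
    coarse_tcs: dict[str, np.ndarray]      # subject -> T x C
    subject_fine_maps: dict[str, np.ndarray]   # subject -> F x V
    subject_voxel_sd: dict[str, np.ndarray]    # subject -> V (volume normalizer)
    true_fnc: pd.DataFrame                 # subjects x fine-pair Fisher-z
    ground_truth: GroundTruth

    def __len__(self) -> int:
        return len(self.scans)

    def timecourse_features(self, include_coarse: bool = True) -> pd.DataFrame:
        """Subjects x msFNC features computed from the planted time courses.

        Bypasses volume rendering and network extraction: the planted fine
        (and optionally coarse) courses go straight into the connectivity
        stage.  This is the fast path for protocol-level studies where
        spatial estimation is not under test.
        """
        from . import connectivity  # local import: keep module deps one-way

        gt = self.ground_truth
        fine_dom = getattr(gt, "fine_domains", ["cerebellum"] * gt.n_fine)
        coarse_dom = getattr(gt, "coarse_domains", ["cerebellum"] * gt.n_coarse)
        vectors = []
        for sid in self.manifest.subject_ids:
            data = self.fine_tcs[sid]
            ids = gt.fine_ids()
            orders: list[int | str] = [FINE_TAG] * gt.n_fine
            doms = list(fine_dom)
            if include_coarse and gt.n_coarse:
                data = np.concatenate([data, self.coarse_tcs[sid]], axis=1)
                ids = ids + gt.coarse_ids()
                orders = orders + [COARSE_TAG] * gt.n_coarse
                doms = doms + list(coarse_dom)
            tcs = TimeCourseSet(
                data=data,
                tr=float(self.manifest.table["tr"].iloc[0]),
                icn_ids=ids,
                orders=orders,
                domains=doms,
                subject_id=sid,
            )
            vectors.append(connectivity.vectorize(connectivity.compute_fnc(tcs)))
        return connectivity.feature_table(vectors)


def _fine_pair_labels(gt: GroundTruth) -> list[str]:
    ids = gt.fine_ids()
    return [
        f"{ids[i]}|{ids[j]}"
        for i in range(gt.n_fine)
        for j in range(i + 1, gt.n_fine)
    ]


def sample_cohort(
    gt: GroundTruth,
    n_tc: int = 30,
    n_sz: int = 30,
    T: int = 135,
    tr: float = 2.0,
    snr: float = 10.0,
    site: str = "sim",
    subject_prefix: str = "",
    render_volumes: bool = True,
    seed: int = 0,
) -> Cohort:
    """Draw a cohort of subjects from the planted generative model.

    Per subject: fine time courses ~ multivariate normal with the group's
    correlation matrix, band-limited and standardized; coarse truth courses =
    standardized mean of member fine courses plus a small (alpha-weighted)
    unique component; volumes = subject-jittered fine maps x fine courses +
    alpha x coarse maps x unique coarse components + white noise at the
    requested amplitude SNR.  ``render_volumes=False`` skips volume rendering
    for time-course-level studies (the truth tables are still produced).
    """
    if T < 20:
        raise ValueError("T must be >= 20")
    if snr <= 0:
        raise ValueError("snr must be positive")
    gt.validate()
    rng = np.random.default_rng(seed)
    jitter_sd = getattr(gt, "jitter_sd", 0.5)
    support = gt.mask.reshape(-1)

    chol = {
        "TC": np.linalg.cholesky(gt.sigma_tc),
        "SZ": np.linalg.cholesky(gt.sigma_sz),
    }
    rows = []
    scans: list[BoldScan] = []
    fine_tcs: dict[str, np.ndarray] = {}
    coarse_tcs: dict[str, np.ndarray] = {}
    subj_maps: dict[str, np.ndarray] = {}
    subj_norm: dict[str, np.ndarray] = {}
    true_rows = []
    subjects = [("TC", i) for i in range(n_tc)] + [("SZ", i) for i in range(n_sz)]
    iu = np.triu_indices(gt.n_fine, k=1)
    for group, i in subjects:
        sid = f"{subject_prefix}{group.lower()}{i + 1:03d}"
        white = rng.standard_normal((T, gt.n_fine))
        a_fine = _standardize(_bandlimit(white @ chol[group].T, tr))
        fine_tcs[sid] = a_fine
        if gt.n_coarse:
            uniq = _standardize(_bandlimit(rng.standard_normal((T, gt.n_coarse)), tr))
            a_coarse = np.stack(
                [
                    a_fine[:, m].mean(axis=1) + gt.coarse_alpha * uniq[:, c]
                    for c, m in gt.coarse_membership.items()
                ],
                axis=1,
            )
            coarse_tcs[sid] = _standardize(a_coarse)
        else:
            uniq = np.empty((T, 0))
            coarse_tcs[sid] = np.empty((T, 0))

        r = np.corrcoef(a_fine, rowvar=False)[iu]
        true_rows.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))

        if render_volumes:
            centers = gt.fine_centers + rng.normal(0, jitter_sd, gt.fine_centers.shape)
            s_fine = _zscore_rows(
                _render_blobs(centers, gt.grid, gt.blob_sd)[:, support]
            )
            x = s_fine.T @ a_fine.T
            if gt.n_coarse:
                x = x + gt.coarse_alpha * (gt.coarse_maps.T @ uniq.T)
            noise_sd = x.std() / snr if np.isfinite(snr) else 0.0
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, x.shape)
            # emit variance-normalized volumes (each voxel unit variance in
            # expectation), the convention of preprocessed rsfMRI; the planted
            # subject maps are reported in the same convention so recovery is
            # measured against what the data actually contain
            sigma = chol[group] @ chol[group].T
            var_v = np.einsum("fv,fg,gv->v", s_fine, sigma, s_fine)
            if gt.n_coarse:
                var_v = var_v + gt.coarse_alpha**2 * (gt.coarse_maps**2).sum(axis=0)
            n_v = np.sqrt(var_v + noise_sd**2)
            n_v = np.where(n_v == 0, 1.0, n_v)
            subj_maps[sid] = _zscore_rows(s_fine / n_v)
            subj_norm[sid] = n_v
            scans.append(
                BoldScan(subject_id=sid, data=x / n_v[:, None], tr=tr, mask=gt.mask)
            )
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "site": site,
                "tr": tr,
                "n_volumes": T,
            }
        )

    manifest = CohortManifest(pd.DataFrame(rows))
    true_fnc = pd.DataFrame(
        np.array(true_rows),
        index=[r["subject_id"] for r in rows],
        columns=_fine_pair_labels(gt),
    )
    return Cohort(
        scans=scans,
        manifest=manifest,
        fine_tcs=fine_tcs,
        coarse_tcs=coarse_tcs,
        subject_fine_maps=subj_maps,
        subject_voxel_sd=subj_norm,
        true_fnc=true_fnc,
        ground_truth=gt,
    )


def attach_scores(
    gt: GroundTruth,
    fnc_truth: pd.DataFrame,
    manifest: CohortManifest,
    seed: int = 0,
) -> CohortManifest:
    """Attach PANSS-like scores to SZ rows, linearly driven by chosen pairs.

    positive = 15 + beta_pos * mean(driving pairs) + noise;
    negative = 14 + beta_neg * mean(disjoint driving pairs) + noise;
    total = positive + negative exactly.  TC rows stay scoreless.
    """
    table = manifest.table.copy()
    sz = table["group"] == "SZ"
    if not sz.any():
        raise ValueError("no SZ subjects to score")
    for pair in gt.score_pairs_pos + gt.score_pairs_neg:
        label = gt.pair_label(pair)
        if label not in fnc_truth.columns:
            raise ValueError(
                f"score pair {label} missing from fnc_truth columns"
            )
    rng = np.random.default_rng(seed)
    sz_ids = table.loc[sz, "subject_id"].tolist()
    vals = fnc_truth.loc[sz_ids]

    def _drive(pairs, beta, base):
        x = vals[[gt.pair_label(p) for p in pairs]].to_numpy().mean(axis=1)
        return base + beta * x + rng.normal(0.0, gt.score_noise_sd, len(x))

    pos = _drive(gt.score_pairs_pos, gt.beta_pos, 15.0)
    neg = _drive(gt.score_pairs_neg, gt.beta_neg, 14.0)
    table.loc[sz, "panss_positive"] = pos
    table.loc[sz, "panss_negative"] = neg
    table.loc[sz, "panss_total"] = pos + neg
    return CohortManifest(table)
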