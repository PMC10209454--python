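"""End-to-end orchestration: simulate -> extract -> FNC -> stats -> select
-> classify -> correlate, with every artifact written as CSV/JSON and the
configuration snapshot recorded next to the outputs.

All randomness flows from one master seed; each stage and cohort derives its
own child seed from it, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, preprocess, scica, selection, simulate, stats
from .classify import cross_dataset_evaluate
from .selection import multiround_select

logger = logging.getLogger(__name__)


def derive_seed(master: int, *tokens) -> int:
    """Stable child seed from a master seed and context tokens (< 2**31).

    Tokens are digested with zlib.crc32 (not Python's ``hash``, which is
    salted per process) so the derivation is reproducible across runs.
    """
    h = [int(master)] + [zlib.crc32(str(t).encode()) for t in tokens]
    return int(np.random.SeedSequence(h).generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """All tunable parameters of the synthetic end-to-end run."""

    out_dir: str = "msfnc_run"
    seed: int = 0
    # synthetic cohort
    grid: tuple[int, int, int] = (20, 20, 10)
    n_fine: int = 10
    n_coarse: int = 5
    n_diff_pairs: int = 5
    delta_z: float = 0.6
    n_tc: int = 30
    n_sz: int = 30
    n_volumes: int = 140
    tr: float = 2.0
    snr: float = 10.0
    # preprocessing
    n_discard: int = 5
    target_len: int = 135
    target_tr: float = 2.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.15
    filter_order: int = 5
    # constrained ICA
    lam: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    # selection
    relieff_k: int = 10
    rounds: int = 10
    subsample_frac: float = 0.5
    retain: float = 0.70
    top_j: int = 10
    # classification
    n_iter: int = 100
    test_frac: float = 0.2
    folds: int = 10
    # toggles
    welch: bool = False

    def validate(self) -> None:
        checks = [
            (self.n_fine >= 1, "n_fine >= 1"),
            (self.n_coarse >= 0, "n_coarse >= 0"),
            (self.n_tc >= 2 and self.n_sz >= 2, "need >= 2 subjects per group"),
            (self.n_volumes > self.n_discard + 1, "n_volumes vs n_discard"),
            (self.target_len <= self.n_volumes - self.n_discard, "target_len fits"),
            (0 < self.band_low_hz < self.band_high_hz, "band ordering"),
            (self.band_high_hz < 0.5 / self.target_tr, "band below Nyquist"),
            (0 < self.lam < 1 or self.lam in (0.0, 1.0), "lambda in [0, 1]"),
            (0 < self.subsample_frac <= 1, "subsample_frac in (0, 1]"),
            (0 < self.retain <= 1, "retain in (0, 1]"),
            (0 < self.test_frac < 1, "test_frac in (0, 1)"),
            (self.snr > 0, "snr > 0"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError(f"invalid configuration: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["grid"] = list(d["grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)


def cohort_features(
    cohort: simulate.Cohort,
    template,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, list[connectivity.FNCMatrix], connectivity.FNCVector]:
    """Extract networks and build the subjects x features msFNC table."""
    vectors, matrices = [], []
    for scan in cohort.scans:
        conditioned = preprocess.zscore_voxels(
            preprocess.discard_and_truncate(
                scan, n_discard=config.n_discard, target_len=config.target_len
            )
        )
        result = scica.extract_subject(
            conditioned, template, lam=config.lam, tol=config.tol,
            max_iter=config.max_iter,
        )
        tcs = preprocess.condition_timecourses(
            result.timecourse_set(),
            target_tr=config.target_tr,
            band=(config.band_low_hz, config.band_high_hz),
            filter_order=config.filter_order,
        )
        fnc = connectivity.compute_fnc(tcs)
        matrices.append(fnc)
        vectors.append(connectivity.vectorize(fnc))
    table = connectivity.feature_table(vectors)
    return table, matrices, vectors[0]


def export_edgelist(
    values: pd.Series, metadata: pd.DataFrame, path: str | Path | None = None
) -> pd.DataFrame:
    """Edge-list export for connectogram renderers.

    ``values`` is indexed by feature label ("icnA|icnB"); ``metadata`` is the
    per-feature table from :func:`connectivity.pair_metadata`.  Each pair
    appears once (upper triangle).
    """
    meta = metadata.set_index("feature")
    rows = meta.loc[values.index, ["icn_a", "icn_b", "domain_a", "domain_b",
                                   "order_a", "order_b", "cross_order"]].copy()
    rows["value"] = values.to_numpy()
    rows = rows.reset_index()
    if path is not None:
        rows.to_csv(path, index=False)
    return rows


def run_all(config: PipelineConfig) -> Path:
    """Execute the full synthetic two-cohort study; returns the output dir.

    Stages: simulate two independent cohorts sharing planted effects ->
    constrained ICA per subject -> msFNC tables -> group statistics per
    cohort -> multi-round selection per cohort + common features ->
    cross-dataset classification (select on A, evaluate on B) -> symptom
    correlation on scored patients.  Every stage writes its artifacts under
    its own subdirectory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    master = config.seed

    # -- simulate ---------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    template, gt = simulate.make_ground_truth(
        grid=config.grid,
        n_fine=config.n_fine,
        n_coarse=config.n_coarse,
        n_diff_pairs=config.n_diff_pairs,
        delta_z=config.delta_z,
        seed=derive_seed(master, "template"),
    )
    template.save(sim_dir / "template")
    gt.save(sim_dir / "ground_truth.json")
    cohorts: dict[str, simulate.Cohort] = {}
    for name in ("a", "b"):
        cohort = simulate.sample_cohort(
            gt,
            n_tc=config.n_tc,
            n_sz=config.n_sz,
            T=config.n_volumes,
            tr=config.tr,
            snr=config.snr,
            site=f"site_{name}",
            subject_prefix=f"{name}_",
            seed=derive_seed(master, "cohort", name),
        )
        manifest = simulate.attach_scores(
            gt, cohort.true_fnc, cohort.manifest,
            seed=derive_seed(master, "scores", name),
        )
        cohort.manifest = manifest
        manifest.save(sim_dir / f"manifest_{name}.csv")
        cohorts[name] = cohort
    logger.info("simulated cohorts: %d + %d subjects", *(len(c) for c in cohorts.values()))

    # -- extract + msFNC --------------------------------------------------
    fnc_dir = out / "fnc"
    fnc_dir.mkdir(exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    meta = None
    for name, cohort in cohorts.items():
        table, matrices, vec0 = cohort_features(cohort, template, config)
        tables[name] = table
        table.to_csv(fnc_dir / f"features_{name}.csv")
        mean_fnc = connectivity.aggregate_mean(matrices)
        mean_fnc.to_frame().to_csv(fnc_dir / f"mean_fnc_{name}.csv")
        if meta is None:
            meta = connectivity.pair_metadata(vec0)
            meta.to_csv(fnc_dir / "pair_metadata.csv", index=False)

    # -- group statistics -------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for name, cohort in cohorts.items():
        res = stats.group_diff(
            tables[name], cohort.manifest.groups, welch=config.welch
        )
        res.to_csv(stats_dir / f"group_diff_{name}.csv")
        export_edgelist(
            res["intensity"], meta, stats_dir / f"intensity_edges_{name}.csv"
        )

    # -- feature selection + replication ----------------------------------
    sel_dir = out / "select"
    sel_dir.mkdir(exist_ok=True)
    weight_tables: dict[str, selection.WeightTable] = {}
    for name, cohort in cohorts.items():
        wt = multiround_select(
            tables[name],
            cohort.manifest.groups,
            rounds=config.rounds,
            frac=config.subsample_frac,
            k=config.relieff_k,
            retain=config.retain,
            seed=derive_seed(master, "select", name),
        )
        weight_tables[name] = wt
        wt.save(sel_dir / f"weights_{name}.csv")
    common = selection.common_features(
        weight_tables["a"], weight_tables["b"], j=config.top_j
    )
    common.to_csv(sel_dir / "common_features.csv", index=False)
    if len(common):
        export_edgelist(
            common.set_index("feature")["weight_a"], meta,
            sel_dir / "common_edges.csv",
        )

    # -- cross-dataset classification -------------------------------------
    clf_dir = out / "classify"
    clf_dir.mkdir(exist_ok=True)
    report, chosen = cross_dataset_evaluate(
        tables["a"], cohorts["a"].manifest.groups,
        tables["b"], cohorts["b"].manifest.groups,
        selection=weight_tables["a"],
        n_iter=config.n_iter,
        test_frac=config.test_frac,
        folds=config.folds,
        seed=derive_seed(master, "classify"),
    )
    report.iterations.to_csv(clf_dir / "iterations.csv", index=False)
    summary = report.summary()
    summary.to_csv(clf_dir / "summary.csv")
    (clf_dir / "report.json").write_text(
        json.dumps(
            {
                "n_features": report.n_features,
                "n_iter": report.n_iter,
                "mean": summary["mean"].to_dict(),
                "sd": summary["sd"].round(6).to_dict(),
            },
            indent=2,
        )
    )

    # -- symptom correlation ----------------------------------------------
    corr_dir = out / "correlate"
    corr_dir.mkdir(exist_ok=True)
    for name, cohort in cohorts.items():
        table = tables[name]
        mtab = cohort.manifest.table.set_index("subject_id")
        sz_ids = mtab.index[mtab["group"] == "SZ"]
        scales = ["panss_total", "panss_positive", "panss_negative"]
        res = stats.symptom_correlation(table.loc[sz_ids], mtab.loc[sz_ids, scales])
        res.to_csv(corr_dir / f"symptom_corr_{name}.csv", index=False)

    (out / "MANIFEST.json").write_text(
        json.dumps(
            {
                "seed": master,
                "stages": ["simulate", "fnc", "stats", "select", "classify", "correlate"],
                "n_features": int(tables["a"].shape[1]),
                "transferred_features": chosen,
            },
            indent=2,
        )
    )
    return out
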