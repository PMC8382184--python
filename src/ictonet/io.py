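"""Plain-text file formats, run configuration, and pipeline orchestration.

All artifacts are CSV + JSON so results stay language-neutral and diffable.
Conventions: angles in radians; simulation time in model units (steps x dt);
signal time in seconds. Every output directory receives a ``provenance.json``
recording the full resolved configuration, per-stage seeds, and the package
version — enough to regenerate every file exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .ictogenicity import BNIGrid, NIProfile, bni, node_ictogenicity
from .model import ModelParams, WeightedNetwork
from .networks import NetworkConfig, ROITimeSeriesSet, build_network
from .stats import friedman, mann_whitney, mvpa_auc, mvpa_permutation, nni_bootstrap
from .synth import CohortSpec, GroupDataset, make_group_dataset, simulate_roi_signals

__all__ = [
    "load_network",
    "save_network",
    "load_timeseries",
    "save_timeseries",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("ictonet")

_STAGES = ("synth", "build_network", "bni", "ni", "group_stats")


def load_network(path) -> WeightedNetwork:
    """Read an adjacency CSV (header row = ROI labels, N numeric rows).

    Symmetry is enforced to 1e-12 (the offending entry is named otherwise),
    the diagonal is zeroed, and negative weights are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: adjacency must be square, got {w.shape}")
    return WeightedNetwork(w, tuple(str(c) for c in df.columns))


def save_network(net: WeightedNetwork, path) -> None:
    pd.DataFrame(net.weights, columns=list(net.labels)).to_csv(path, index=False)


def load_timeseries(path, sidecar=None) -> ROITimeSeriesSet:
    """Read a samples x channels CSV plus a JSON sidecar holding ``fs``."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    return ROITimeSeriesSet(
        df.to_numpy(dtype=float).T, float(meta["fs"]), tuple(str(c) for c in df.columns)
    )


def save_timeseries(ts: ROITimeSeriesSet, path, sidecar=None) -> None:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    pd.DataFrame(ts.data.T, columns=list(ts.labels)).to_csv(path, index=False)
    sidecar.write_text(json.dumps({"fs": ts.fs, "units": "arbitrary"}, indent=2))


@dataclass(frozen=True)
class RunConfig:
    """Configuration for an end-to-end run.

    ``stages`` selects which steps execute; every stochastic stage derives
    its seed deterministically from ``seed``. Scaled-down simulation sizes
    are the default here; pass n_steps=4_000_000, n_rois=40 etc. for
    full-size runs.
    """

    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    out_dir: str = "ictonet-out"
    # model block
    k: float = 10.0
    sigma: float = 6.0
    dt: float = 1e-2
    n_steps: int = 100_000
    noise_scaling: str = "sqrt_dt"
    # BNI grid block
    lambda1: float = -1.7
    lambda2: float = -0.5
    grid_points: int = 13
    # cohort block
    n_group_a: int = 10
    n_group_b: int = 10
    n_rois: int = 12
    effect: float = 1.3
    topology: str = "uniform-random"
    base_weight: float = 0.5
    density: float = 0.3
    # signal/network-construction block (only used when build_network runs)
    fs: float = 250.0
    duration: float = 20.0
    n_surrogates: int = 19
    alpha: float = 0.05
    # statistics block
    n_boot: int = 2000
    mvpa_reps: int = 5
    mvpa_perms: int = 200
    # inputs when synth is disabled
    network_paths: tuple[str, ...] = ()
    group_labels: tuple[str, ...] = ()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "network_paths", "group_labels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def model_params(self, i0: float = -1.0) -> ModelParams:
        return ModelParams(
            i0=i0, k=self.k, sigma=self.sigma, dt=self.dt,
            n_steps=self.n_steps, noise_scaling=self.noise_scaling,
        )

    def grid(self) -> BNIGrid:
        return BNIGrid(self.lambda1, self.lambda2, self.grid_points)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_group_a=self.n_group_a, n_group_b=self.n_group_b,
            n_rois=self.n_rois, effect=self.effect, topology=self.topology,
            base_weight=self.base_weight, density=self.density,
            seed=derive_seed(self.seed, "synth"),
        )


def _preflight(config: RunConfig) -> None:
    if "synth" not in config.stages:
        if not config.network_paths:
            raise FileNotFoundError("no synth stage and no network_paths given")
        for p in config.network_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input network not found: {p}")
        if len(config.group_labels) != len(config.network_paths):
            raise ValueError("group_labels must match network_paths")


def _load_inputs(config: RunConfig) -> GroupDataset:
    networks = tuple(load_network(p) for p in config.network_paths)
    return GroupDataset(
        networks, tuple(config.group_labels),
        CohortSpec(n_group_a=1, n_group_b=1, n_rois=networks[0].n, seed=config.seed),
        tuple(-1 for _ in networks),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write all result files.

    Flow: synth (planted cohort) -> build_network (per-subject signals +
    PLV pipeline; optional) -> bni -> ni -> group_stats. Returns a result
    bundle dict; identical configs give byte-identical output CSVs.
    """
    _preflight(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.to_dict()}
    log_lines = [f"stages: {','.join(config.stages)}; master seed {config.seed}"]

    if "synth" in config.stages:
        dataset = make_group_dataset(config.cohort_spec())
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for i, net in enumerate(dataset.networks):
            save_network(net, net_dir / f"subject{i:03d}.csv")
        log_lines.append(f"synth: {len(dataset.networks)} planted networks")
    else:
        dataset = _load_inputs(config)
        log_lines.append(f"loaded {len(dataset.networks)} networks")
    bundle["labels"] = dataset.labels

    if "build_network" in config.stages:
        rebuilt = []
        for i, net in enumerate(dataset.networks):
            ts = simulate_roi_signals(
                net, fs=config.fs, duration=config.duration,
                seed=derive_seed(config.seed, "signals", i),
            )
            fnet = build_network(ts, NetworkConfig(
                n_surrogates=config.n_surrogates, alpha=config.alpha,
                seed=derive_seed(config.seed, "surrogates", i),
            ))
            rebuilt.append(fnet.final)
            save_network(fnet.final, out / "networks" / f"subject{i:03d}_plv.csv")
        dataset = GroupDataset(tuple(rebuilt), dataset.labels, dataset.spec, dataset.subject_seeds)
        log_lines.append("build_network: PLV networks reconstructed from signals")

    bni_values = None
    if "bni" in config.stages or "group_stats" in config.stages:
        grid = config.grid()
        params = config.model_params()
        rows = []
        for i, net in enumerate(dataset.networks):
            res = bni(net, grid, params, derive_seed(config.seed, "bni", i))
            rows.append((f"subject{i:03d}", dataset.labels[i], res.bni, res.normalized))
        bni_df = pd.DataFrame(rows, columns=["subject", "group", "bni", "bni_normalized"])
        bni_df.to_csv(out / "bni.csv", index=False)
        bni_values = bni_df
        bundle["bni"] = bni_df
        log_lines.append(f"bni: {len(rows)} subjects on {grid.n_points}-point grid")

    ni_profiles: list[NIProfile | None] = []
    if "ni" in config.stages or "group_stats" in config.stages:
        grid = config.grid()
        params = config.model_params()
        rows = []
        for i, net in enumerate(dataset.networks):
            try:
                prof = node_ictogenicity(net, grid, params, derive_seed(config.seed, "bni", i))
            except ValueError as exc:
                log.warning("subject %d excluded from NI: %s", i, exc)
                log_lines.append(f"ni: subject {i} excluded ({exc})")
                ni_profiles.append(None)
                continue
            ni_profiles.append(prof)
            for roi, label in enumerate(net.labels):
                rows.append((
                    f"subject{i:03d}", dataset.labels[i], label,
                    prof.ni[roi],
                    prof.nni[roi] if prof.nni is not None else np.nan,
                ))
        ni_df = pd.DataFrame(rows, columns=["subject", "group", "roi", "ni", "nni"])
        ni_df.to_csv(out / "ni.csv", index=False)
        bundle["ni"] = ni_df
        log_lines.append(f"ni: {sum(p is not None for p in ni_profiles)} subjects profiled")

    if "group_stats" in config.stages:
        stats_out = _group_stats(config, dataset, bni_values, ni_profiles)
        (out / "group_stats.json").write_text(json.dumps(stats_out, indent=2))
        pd.DataFrame(stats_out["per_roi"]).to_csv(out / "group_stats_per_roi.csv", index=False)
        bundle["group_stats"] = stats_out
        log_lines.append("group_stats written")

    provenance = {
        "config": config.to_dict(),
        "software": "ictonet 0.1.0",
        "stage_seeds": {
            "synth": derive_seed(config.seed, "synth"),
            "bni_per_subject": [
                derive_seed(config.seed, "bni", i) for i in range(len(dataset.networks))
            ],
            "stats": derive_seed(config.seed, "stats"),
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    bundle["provenance"] = provenance
    return bundle


def _group_stats(config, dataset, bni_df, ni_profiles) -> dict:
    """Group comparisons: BNI MWU, NI mean/SD MWU, Friedman + bootstrap on
    group-b nNI, and MVPA on NI and nNI spatial profiles."""
    labels = np.asarray(dataset.labels)
    groups = np.unique(labels)
    res: dict = {"groups": groups.tolist(), "per_roi": {}}
    seed = derive_seed(config.seed, "stats")

    if bni_df is not None and groups.size == 2:
        a = bni_df.loc[bni_df.group == groups[0], "bni"].to_numpy()
        b = bni_df.loc[bni_df.group == groups[1], "bni"].to_numpy()
        r = mann_whitney(a, b)
        res["bni_mwu"] = {"U": r.u, "z": r.z, "p": r.p}

    kept = [(i, p) for i, p in enumerate(ni_profiles) if p is not None and p.nni is not None]
    if kept:
        idx = [i for i, _ in kept]
        ni_mat = np.vstack([p.ni for _, p in kept])
        nni_mat = np.vstack([p.nni for _, p in kept])
        klabels = labels[idx]
        roi_names = list(kept[0][1].labels)

        if groups.size == 2:
            for name, mat in (("ni_mean", ni_mat.mean(axis=1)), ("ni_sd", ni_mat.std(axis=1))):
                r = mann_whitney(mat[klabels == groups[0]], mat[klabels == groups[1]])
                res[f"{name}_mwu"] = {"U": r.u, "z": r.z, "p": r.p}

        b_mask = klabels == groups[-1]
        if b_mask.sum() >= 2:
            chi2, p = friedman(nni_mat[b_mask])
            res["nni_friedman"] = {"chi2": chi2, "p": p}
            boot = nni_bootstrap(nni_mat[b_mask], n_boot=config.n_boot, seed=seed)
            res["per_roi"] = {
                "roi": roi_names,
                "nni_median": boot.observed_medians.tolist(),
                "z": boot.z_per_roi.tolist(),
                "p": boot.p_per_roi.tolist(),
                "q": boot.q_per_roi.tolist(),
                "significant": boot.significant.tolist(),
            }

        # stratified 5-fold CV needs at least 5 subjects per class
        if groups.size == 2 and min((klabels == g).sum() for g in groups) >= 5:
            for name, mat in (("ni", ni_mat), ("nni", nni_mat)):
                try:
                    mv = mvpa_auc(mat, klabels, n_reps=config.mvpa_reps, seed=seed)
                    p_perm, _ = mvpa_permutation(
                        mat, klabels, n_perm=config.mvpa_perms, seed=seed,
                        n_reps=config.mvpa_reps, result=mv,
                    )
                    res[f"mvpa_{name}"] = {
                        "auc_mean": mv.auc_mean, "auc_sd": mv.auc_sd, "p_perm": p_perm,
                    }
                except ValueError as exc:
                    res[f"mvpa_{name}"] = {"error": str(exc)}
    return res
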