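"""End-to-end orchestration: simulate -> unmix -> quantify -> map -> profile
-> classify, with a JSON manifest tying configuration, seed and outputs
together so a run can be reproduced exactly.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DomainError
from .io import write_hypermap, write_reference
from .maps import classify_similarity, mixed_overlap_map, similarity_map
from .mcr import run_mcr_als
from .preprocess import baseline_correct_matrix
from .profiles import depth_profile, total_content_curve
from .sml import curate_training_set, evaluate, split_dataset, train_classifier
from .synthetic import (
    SceneConfig,
    assemble_hypermap,
    default_scene,
    make_labeled_spectra,
    make_reference_spectrum,
    simulate_penetration_field,
)
from .types import PipelineConfig
from .unmix import match_endmembers, run_vca

__all__ = ["RunManifest", "run_pipeline", "export_figures", "DEMO_CONFIG"]

log = logging.getLogger("serspen")

#: demo configuration: a small two-pesticide apple scene over the full
#: 2-96 h schedule, sized to run end-to-end in a couple of minutes
DEMO_CONFIG: dict = {
    "seed": 0,
    "scene": {"n_depth": 30, "n_lateral": 12},
    "pipeline": {},
    "mcr": {"tol": 1e-6, "max_iter": 50},
    "map_time_h": 24.0,
    "classify": {"n_per_class": 300, "families": ["logistic"], "k": None},
}

_TOP_KEYS = set(DEMO_CONFIG)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    out_dir: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[str], elapsed_s: float, **scalars) -> None:
        self.stages[stage] = {
            "outputs": outputs,
            "elapsed_s": round(elapsed_s, 3),
            "scalars": scalars,
        }
        log.info("stage=%s elapsed=%.2fs %s", stage, elapsed_s,
                 " ".join(f"{k}={v}" for k, v in scalars.items()))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=_jsonable))
        return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(source: str | Path | dict | None) -> dict:
    """Merge a JSON/YAML config file (or dict) over the demo defaults."""
    merged = json.loads(json.dumps(DEMO_CONFIG))
    if source is None:
        return merged
    if isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            import yaml

            user = yaml.safe_load(text)
        else:
            user = json.loads(text)
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    for key, value in user.items():
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown config field: {key}")
        if isinstance(merged.get(key), dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config field {key} must be a mapping")
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _save_table(arr: np.ndarray, path: Path, header: str = "") -> Path:
    np.savetxt(path, np.atleast_2d(arr), delimiter="\t", fmt="%.12g",
               header=header, comments="# ")
    return path


def run_pipeline(
    config: str | Path | dict | None = None,
    out_dir: str | Path = "serspen_run",
    seed: int | None = None,
) -> RunManifest:
    """Execute every stage on a synthetic scene; returns the run manifest.

    All randomness flows from the single top-level seed.  Stage outputs are
    delimited tables (plus cubes and reference spectra); figures are
    rendered separately by :func:`export_figures`.
    """
    from . import __version__

    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        scene: SceneConfig = default_scene(seed=int(cfg["seed"]), **cfg["scene"])
        pipe = PipelineConfig(seed=int(cfg["seed"]), **cfg["pipeline"])
    except (TypeError, DomainError) as exc:
        raise ConfigError(f"invalid scene/pipeline configuration: {exc}") from exc
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]), version=__version__,
                           out_dir=str(out))

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    cube_paths, cubes = [], {}
    for t_h in scene.times_h:
        cube, _ = assemble_hypermap(scene, t_h)
        cubes[t_h] = cube
        cube_paths.append(str(write_hypermap(cube, out / f"cube_t{t_h:g}h.h5")))
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for k, comp in enumerate(scene.components):
        fld = simulate_penetration_field(scene, k)
        _save_table(fld.values, truth_dir / f"conc_{comp.name}.tsv",
                    header=f"rows=times_h {list(scene.times_h)}; cols=depth_um")
    refs = [
        make_reference_spectrum(c.peaks, scene.axis, scene.band_shape, c.name)
        for c in scene.components
    ]
    ref_paths = [str(write_reference(r, out / f"ref_{r.name}.tsv")) for r in refs]
    manifest.record("simulate", cube_paths + ref_paths, time.perf_counter() - t0,
                    n_cubes=len(cube_paths))

    # --- unmix + quantify (per cube) ---------------------------------
    t0 = time.perf_counter()
    p = pipe.n_endmembers if pipe.n_endmembers else len(refs) + 1
    mcr_cfg = cfg["mcr"]
    abundances, lofs = {}, {}
    for t_h, cube in cubes.items():
        Xc = baseline_correct_matrix(cube.spectra, pipe.baseline_smoothness,
                                     pipe.baseline_asymmetry, pipe.baseline_n_iter)
        E = run_vca(Xc, p, seed=pipe.seed)
        E = match_endmembers(E, refs)
        res = run_mcr_als(Xc, E, tol=float(mcr_cfg["tol"]), max_iter=int(mcr_cfg["max_iter"]))
        abundances[t_h] = (res, E.names)
        lofs[t_h] = float(res.lof_trace[-1])
        _save_table(res.C.C, out / f"abundance_t{t_h:g}h.tsv",
                    header="columns=" + ",".join(res.S.names))
    unmix_outputs = [str(out / f"abundance_t{t_h:g}h.tsv") for t_h in cubes]
    manifest.record("quantify", unmix_outputs, time.perf_counter() - t0,
                    mean_final_lof=float(np.mean(list(lofs.values()))))

    # --- maps at the configured inspection time -----------------------
    t0 = time.perf_counter()
    map_time = float(cfg["map_time_h"])
    if map_time not in cubes:
        raise ConfigError(f"map_time_h={map_time} is not an acquisition time")
    cube = cubes[map_time]
    map_outputs = []
    for ref in refs:
        sim = similarity_map(cube, ref, "pearson", pipe)
        lab = classify_similarity(sim, pipe)
        map_outputs.append(str(_save_table(sim.values, out / f"similarity_{ref.name}.tsv")))
        map_outputs.append(str(_save_table(lab.color_values, out / f"labels_{ref.name}.tsv")))
    overlap = mixed_overlap_map(cube, refs[0], refs[1], pipe)
    map_outputs.append(str(_save_table(overlap.color_values, out / "overlap_codes.tsv")))
    manifest.record("map", map_outputs, time.perf_counter() - t0, time_h=map_time)

    # --- profiles ------------------------------------------------------
    t0 = time.perf_counter()
    profile_outputs = []
    for name in [c.name for c in scene.components]:
        profs = []
        for t_h, cube_t in cubes.items():
            res, names = abundances[t_h]
            if name in names:
                col = names.index(name)
                content = res.C.C[:, col]
            else:  # unmatched at this time point: no attributable content
                content = np.zeros(cube_t.n_pixels)
            profs.append(depth_profile(content, cube_t))
        curve = total_content_curve(profs, spline_df=min(6, len(profs)))
        prof_mat = np.vstack([pr.mean_content for pr in profs])
        profile_outputs.append(str(_save_table(prof_mat, out / f"depth_profiles_{name}.tsv",
                                               header="rows=times_h; cols=depth bins")))
        curve_tab = np.column_stack([curve.times_h, curve.total_content])
        profile_outputs.append(str(_save_table(curve_tab, out / f"content_curve_{name}.tsv",
                                               header="time_h\ttotal_content")))
        trend_tab = np.column_stack([curve.trend_times_h, curve.trend])
        profile_outputs.append(str(_save_table(trend_tab, out / f"content_trend_{name}.tsv",
                                               header="time_h\ttrend")))
    manifest.record("profile", profile_outputs, time.perf_counter() - t0)

    # --- classify ------------------------------------------------------
    t0 = time.perf_counter()
    cls_cfg = cfg["classify"]
    ds = make_labeled_spectra(scene, int(cls_cfg["n_per_class"]))
    Xc = baseline_correct_matrix(ds.X, pipe.baseline_smoothness,
                                 pipe.baseline_asymmetry, pipe.baseline_n_iter)
    E = match_endmembers(run_vca(Xc, len(refs) + 1, seed=pipe.seed), refs)
    curated = curate_training_set(Xc, E, pipe, k=cls_cfg.get("k"), seed=pipe.seed)
    train, test = split_dataset(curated, pipe.train_fraction, seed=pipe.seed)
    classify_outputs = []
    auc_rows = []
    for family in cls_cfg["families"]:
        model = train_classifier(train, family, seed=pipe.seed)
        report = evaluate(model, test)
        for cls_name, a in sorted(report.auc.items()):
            auc_rows.append((family, cls_name, a))
        conf_path = out / f"confusion_{family}.tsv"
        report.confusion.to_csv(conf_path, sep="\t")
        classify_outputs.append(str(conf_path))
        prop_path = out / f"proportional_{family}.tsv"
        report.proportional_scores.to_csv(prop_path, sep="\t")
        classify_outputs.append(str(prop_path))
    auc_path = out / "auc_summary.tsv"
    with auc_path.open("w") as fh:
        fh.write("family\tclass\tauc\n")
        for family, cls_name, a in auc_rows:
            fh.write(f"{family}\t{cls_name}\t{a:.12g}\n")
    classify_outputs.append(str(auc_path))
    min_auc = min((a for _, _, a in auc_rows), default=float("nan"))
    manifest.record("classify", classify_outputs, time.perf_counter() - t0,
                    n_curated=len(curated), min_auc=round(min_auc, 6))

    manifest_path = manifest.save(out / "manifest.json")
    manifest.record("manifest", [str(manifest_path)], 0.0)
    manifest.save(manifest_path)
    return manifest


def export_figures(manifest: RunManifest | str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Render the standard figure panels from a completed run's tables.

    Similarity maps are drawn red-high, depth-content maps blue-high, the
    overlap map with a fixed 4-color categorical palette, plus the content
    curve with its spline trend and the per-family AUC bar chart.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if not isinstance(manifest, RunManifest):
        data = json.loads(Path(manifest).read_text())
        manifest = RunManifest(**data)
    run_dir = Path(manifest.out_dir)
    fig_dir = Path(out_dir) if out_dir is not None else run_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _finish(fig, name: str):
        path = fig_dir / name
        fig.savefig(path, dpi=100, metadata={"Software": "serspen"})
        plt.close(fig)
        written.append(path)

    for tsv in sorted(run_dir.glob("similarity_*.tsv")):
        vals = np.loadtxt(tsv, delimiter="\t", ndmin=2)
        fig, ax = plt.subplots(figsize=(4, 5))
        im = ax.imshow(vals, cmap="RdYlBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xlabel("lateral pixel")
        ax.set_ylabel("depth pixel (surface at top)")
        ax.set_title(tsv.stem.replace("similarity_", "similarity: "))
        fig.colorbar(im, ax=ax, label="similarity")
        _finish(fig, tsv.stem + ".png")

    for tsv in sorted(run_dir.glob("depth_profiles_*.tsv")):
        vals = np.loadtxt(tsv, delimiter="\t", ndmin=2)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(vals.T, cmap="Blues", aspect="auto")
        ax.set_xlabel("time point index")
        ax.set_ylabel("depth bin (surface at top)")
        ax.set_title(tsv.stem.replace("depth_profiles_", "content vs depth: "))
        fig.colorbar(im, ax=ax, label="content (a.u.)")
        _finish(fig, tsv.stem + ".png")

    overlap_tsv = run_dir / "overlap_codes.tsv"
    if overlap_tsv.exists():
        codes = np.loadtxt(overlap_tsv, delimiter="\t", ndmin=2)
        palette = ListedColormap(["#f0f0f0", "#d62728", "#ffdf00", "#7f2ca7"])
        norm = BoundaryNorm([-0.5, 5, 15, 25, 35], palette.N)
        fig, ax = plt.subplots(figsize=(4, 5))
        ax.imshow(codes, cmap=palette, norm=norm, aspect="auto")
        ax.set_title("mixture overlap (0/10/20/30)")
        ax.set_xlabel("lateral pixel")
        ax.set_ylabel("depth pixel")
        _finish(fig, "overlap_map.png")

    for tsv in sorted(run_dir.glob("content_curve_*.tsv")):
        name = tsv.stem.replace("content_curve_", "")
        curve = np.loadtxt(tsv, delimiter="\t", ndmin=2)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(curve[:, 0], curve[:, 1], "o", label="measured")
        trend_tsv = run_dir / f"content_trend_{name}.tsv"
        if trend_tsv.exists():
            trend = np.loadtxt(trend_tsv, delimiter="\t", ndmin=2)
            ax.plot(trend[:, 0], trend[:, 1], "-", label="B-spline trend")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("total content (a.u.)")
        ax.set_title(f"penetration content: {name}")
        ax.legend()
        _finish(fig, f"content_curve_{name}.png")

    auc_tsv = run_dir / "auc_summary.tsv"
    if auc_tsv.exists():
        import pandas as pd

        auc = pd.read_csv(auc_tsv, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        labels = auc["family"] + ":" + auc["class"]
        ax.bar(labels, auc["auc"])
        ax.set_ylim(0, 1.05)
        ax.axhline(0.92, color="k", ls="--", lw=0.8)
        ax.set_ylabel("held-out AUC")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        _finish(fig, "auc_summary.png")

    return written
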