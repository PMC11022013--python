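"""End-to-end pipeline orchestration.

Runs: (optional) simulation -> missing-landmark estimation -> semilandmark
sliding -> generalized Procrustes analysis -> PCAs (shape, form, BM) ->
shape-change heatmaps -> map standardization and mean maps -> total-%BR
trajectories -> per-square profiles -> permutation tests, PERMANOVA and the
size regression. All outputs are plain text/CSV/PLY/PNG in a run directory,
listed with content hashes in a machine-readable manifest; all randomness
derives from one configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bm import (bm_matrix, mean_bm_map, per_square_profile,
                 standardize_bm_grid, total_percent_resorption)
from .io import (read_bm_grids, read_landmark_table, write_bm_grid,
                 write_landmark_table, write_mesh_ply)
from .pca import pca
from .procrustes import gpa_align
from .shape_change import (group_mean_shape, heatmap_pairs,
                           signed_distance_heatmap, warp_mesh_to_shape)
from .sliding import slide_semilandmarks
from .stats import permanova, permutation_test_pc_scores, regress_bm_on_size
from .synthetic import SimulationConfig, simulate_dataset
from .template import Template, make_template
from .tps import estimate_missing_landmarks


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    output_dir: str | Path = "osteomap_run"
    seed: int = 0
    simulation: SimulationConfig | None = None   # synthetic mode when set
    landmark_table: str | None = None            # non-synthetic inputs
    grid_paths: tuple = ()
    n_perm: int = 1000
    pc_components: int = 3                       # PCs for shape-score tests
    grid_target: tuple[int, int] = (8, 8)
    coverage_threshold: float = 0.5
    sliding_iterations: int = 3
    mesh_resolution: int = 24
    heatmaps: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold < 1:
            raise ConfigError("coverage_threshold must be in (0, 1)")
        if self.simulation is None:
            if self.landmark_table is None and not self.grid_paths:
                raise ConfigError(
                    "need a simulation block or input data paths")
            if (self.landmark_table is not None
                    and not Path(self.landmark_table).exists()):
                raise ConfigError(f"missing file: {self.landmark_table}")
            for p in self.grid_paths:
                if not Path(p).exists():
                    raise ConfigError(f"missing file: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("species", "absent_cells"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(tuple(x) if isinstance(x, list) else x
                                     for x in sim[key])
            for key in ("grid_rows_range", "grid_cols_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            try:
                sim = SimulationConfig(**sim)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad simulation block: {exc}") from exc
        for key in ("grid_target",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "grid_paths" in raw:
            raw["grid_paths"] = tuple(raw["grid_paths"])
        try:
            return cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _stage_seed(seed: int, counter: int) -> int:
    ss = np.random.SeedSequence([seed, counter])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_stats_csv(df: pd.DataFrame, path: Path, seed: int,
                     n_perm: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {seed}\n# n_perm: {n_perm}\n")
        df.to_csv(fh, index=False)


def _pairwise_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "group_a": r.pair[0], "group_b": r.pair[1],
        "statistic": r.statistic, "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted} for r in results])


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure raises PipelineError naming the stage; partial
    outputs written so far are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("osteomap.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("osteomap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    log.info("osteomap %s, seed %d", __version__, config.seed)

    stages_done: list[str] = []
    outputs: list[Path] = []
    plots = config.make_plots
    if plots:
        from . import plotting

    def record(path: Path) -> None:
        outputs.append(path)

    stage = "configure"
    try:
        # ------------------------------------------------ inputs
        stage = "simulate" if config.simulation is not None else "load"
        template: Template | None = None
        if config.simulation is not None:
            dataset = simulate_dataset(config.simulation)
            template = dataset.truth.template
            configs = dataset.landmark_configs
            grids = dataset.grids
            inputs = out / "inputs"
            (inputs / "grids").mkdir(parents=True, exist_ok=True)
            write_landmark_table(configs, inputs / "landmarks.csv", template)
            record(inputs / "landmarks.csv")
            for g in grids:
                p = inputs / "grids" / f"{g.specimen_id}.csv"
                write_bm_grid(g, p)
                record(p)
        else:
            template = make_template()
            configs = (read_landmark_table(config.landmark_table,
                                           template.n_landmarks)
                       if config.landmark_table else [])
            grids = read_bm_grids(config.grid_paths)
        stages_done.append(stage)
        log.info("%s: %d landmark configs, %d grids", stage,
                 len(configs), len(grids))

        gm_ok = len(configs) >= 2
        bm_ok = len(grids) >= 1
        aligned = None

        # ------------------------------------------------ GM track
        if gm_ok:
            stage = "estimate_missing"
            # reference = per-landmark mean over the specimens measured there
            stack = np.stack([c.coords for c in configs])
            with np.errstate(invalid="ignore"):
                reference = np.nanmean(stack, axis=0)
            if np.any(np.isnan(reference)):
                raise ValueError(
                    "some landmarks are missing in every specimen; "
                    "no reference can be formed")
            configs = [estimate_missing_landmarks(c, reference)
                       if not c.is_complete else c for c in configs]
            stages_done.append(stage)

            stage = "slide"
            slid = slide_semilandmarks(configs, template,
                                       iterations=config.sliding_iterations)
            configs = slid.dataset
            stages_done.append(stage)

            stage = "gpa"
            aligned = gpa_align(configs)
            gm_dir = out / "gm"
            gm_dir.mkdir(exist_ok=True)
            pd.DataFrame({"specimen_id": aligned.specimen_ids,
                          "species": aligned.species,
                          "age_group": aligned.age_groups,
                          "centroid_size": aligned.centroid_sizes}).to_csv(
                gm_dir / "centroid_sizes.csv", index=False)
            record(gm_dir / "centroid_sizes.csv")
            stages_done.append(stage)

            stage = "pca_shape_form"
            flat = aligned.aligned.reshape(len(configs), -1)
            shape_pca = pca(flat, space="shape")
            form_pca = pca(flat, space="form",
                           centroid_sizes=aligned.centroid_sizes)
            for name, res in (("shape", shape_pca), ("form", form_pca)):
                sc = pd.DataFrame(res.scores[:, :10],
                                  columns=[f"PC{i+1}" for i in
                                           range(min(10, res.scores.shape[1]))])
                sc.insert(0, "specimen_id", aligned.specimen_ids)
                sc.insert(1, "species", aligned.species)
                sc.insert(2, "age_group", aligned.age_groups)
                sc.to_csv(gm_dir / f"pca_{name}_scores.csv", index=False)
                record(gm_dir / f"pca_{name}_scores.csv")
                pd.DataFrame({
                    "component": np.arange(1, len(res.eigenvalues) + 1),
                    "eigenvalue": res.eigenvalues,
                    "variance_fraction": res.variance_fractions}).to_csv(
                    gm_dir / f"pca_{name}_variance.csv", index=False)
                record(gm_dir / f"pca_{name}_variance.csv")
                if plots:
                    p = gm_dir / f"pca_{name}.png"
                    plotting.render_pca(res.scores, res.variance_fractions,
                                        aligned.species, p,
                                        title=f"{name} space")
                    record(p)
            stages_done.append(stage)

            if config.heatmaps:
                stage = "heatmaps"
                hm_dir = out / "heatmaps"
                hm_dir.mkdir(exist_ok=True)
                base_mesh = template.build_mesh(config.mesh_resolution)
                for sp in sorted({s for s in aligned.species if s}):
                    ags = [a for s, a in zip(aligned.species,
                                             aligned.age_groups) if s == sp]
                    for a, b in heatmap_pairs(ags):
                        young = group_mean_shape(aligned, sp, a)
                        old = group_mean_shape(aligned, sp, b)
                        m_young = warp_mesh_to_shape(base_mesh,
                                                     template.coords, young)
                        m_old = warp_mesh_to_shape(base_mesh,
                                                   template.coords, old)
                        hm = signed_distance_heatmap(m_young, m_old, (a, b),
                                                     species=sp)
                        ply = hm_dir / f"{sp}_ag{a}to{b}.ply"
                        write_mesh_ply(hm.base_mesh, ply)
                        record(ply)
                        if plots:
                            png = hm_dir / f"{sp}_ag{a}to{b}.png"
                            plotting.render_heatmap(hm, png,
                                                    title=f"{sp} AG{a}->AG{b}")
                            record(png)
                stages_done.append(stage)
        else:
            log.info("GM track skipped: fewer than 2 landmark configurations")

        # ------------------------------------------------ BM track
        maps = []
        profile = None
        bm_meta = None
        X = None
        if bm_ok:
            stage = "standardize_maps"
            bm_dir = out / "bm"
            bm_dir.mkdir(exist_ok=True)
            maps = [standardize_bm_grid(g, config.grid_target,
                                        config.coverage_threshold)
                    for g in grids]
            stages_done.append(stage)

            stage = "mean_maps"
            cells = sorted({(m.species, m.age_group) for m in maps
                            if m.species is not None})
            for sp, ag in cells:
                mm = mean_bm_map(maps, sp, ag, config.coverage_threshold)
                dfm = pd.DataFrame(np.where(mm.valid, mm.values, np.nan))
                dfm.to_csv(bm_dir / f"mean_map_{sp}_ag{ag}.csv", index=False)
                record(bm_dir / f"mean_map_{sp}_ag{ag}.csv")
                if plots:
                    png = bm_dir / f"mean_map_{sp}_ag{ag}.png"
                    plotting.render_bm_map(mm.values, mm.valid, png,
                                           title=f"{sp} AG {ag}")
                    record(png)
            stages_done.append(stage)

            stage = "total_br"
            br = pd.DataFrame([{
                "specimen_id": g.specimen_id, "species": g.species,
                "age_group": g.age_group,
                "total_pct_br": total_percent_resorption(g)} for g in grids])
            br.to_csv(bm_dir / "total_br.csv", index=False)
            record(bm_dir / "total_br.csv")
            if plots and br["species"].notna().any():
                png = bm_dir / "total_br_trajectories.png"
                plotting.render_br_trajectories(br, png)
                record(png)
            stages_done.append(stage)

            stage = "per_square_profile"
            profile = per_square_profile(maps, config.coverage_threshold)
            profile.to_csv(bm_dir / "per_square_profile.csv", index=False)
            record(bm_dir / "per_square_profile.csv")
            stages_done.append(stage)

            stage = "pca_bm"
            X, bm_meta, imputed = bm_matrix(maps, config.coverage_threshold)
            if imputed:
                log.info("imputed missing squares in %d specimens: %s",
                         len(imputed), imputed[:20])
            if len(X) >= 3:
                bm_pca = pca(X, space="bm")
                sc = pd.DataFrame(bm_pca.scores[:, :10],
                                  columns=[f"PC{i+1}" for i in
                                           range(min(10,
                                                     bm_pca.scores.shape[1]))])
                sc = pd.concat([bm_meta.reset_index(drop=True), sc], axis=1)
                sc.to_csv(bm_dir / "pca_bm_scores.csv", index=False)
                record(bm_dir / "pca_bm_scores.csv")
                pd.DataFrame({
                    "component": np.arange(1, len(bm_pca.eigenvalues) + 1),
                    "eigenvalue": bm_pca.eigenvalues,
                    "variance_fraction": bm_pca.variance_fractions}).to_csv(
                    bm_dir / "pca_bm_variance.csv", index=False)
                record(bm_dir / "pca_bm_variance.csv")
            else:
                bm_pca = None
            stages_done.append(stage)
        else:
            bm_pca = None
            log.info("BM track skipped: no grids provided")

        # ------------------------------------------------ statistics
        stage = "stats"
        st_dir = out / "stats"
        st_dir.mkdir(exist_ok=True)
        if gm_ok and len(set(aligned.species) - {None}) >= 2:
            res = permutation_test_pc_scores(
                shape_pca.scores, aligned.species,
                k_components=min(config.pc_components,
                                 shape_pca.scores.shape[1]),
                n_perm=config.n_perm, seed=_stage_seed(config.seed, 11))
            _write_stats_csv(_pairwise_frame(res),
                             st_dir / "shape_pc_permutation.csv",
                             _stage_seed(config.seed, 11), config.n_perm)
            record(st_dir / "shape_pc_permutation.csv")
        if bm_pca is not None and bm_meta["species"].nunique() >= 2:
            labels = bm_meta["species"].to_numpy()
            for pc in range(min(3, bm_pca.scores.shape[1])):
                res = permutation_test_pc_scores(
                    bm_pca.scores[:, [pc]], labels, k_components=1,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, 20 + pc))
                _write_stats_csv(_pairwise_frame(res),
                                 st_dir / f"bm_pc{pc+1}_permutation.csv",
                                 _stage_seed(config.seed, 20 + pc),
                                 config.n_perm)
                record(st_dir / f"bm_pc{pc+1}_permutation.csv")
            perma = permanova(X, labels, n_perm=config.n_perm,
                              seed=_stage_seed(config.seed, 30),
                              pairwise=True)
            head = pd.DataFrame([{
                "pseudo_F": perma.pseudo_F, "R2": perma.R2, "p": perma.p,
                "df_between": perma.df_between,
                "df_within": perma.df_within}])
            _write_stats_csv(head, st_dir / "permanova.csv",
                             _stage_seed(config.seed, 30), config.n_perm)
            record(st_dir / "permanova.csv")
            _write_stats_csv(_pairwise_frame(perma.pairwise),
                             st_dir / "permanova_pairwise.csv",
                             _stage_seed(config.seed, 30), config.n_perm)
            record(st_dir / "permanova_pairwise.csv")
        if bm_pca is not None and gm_ok:
            cs_by_id = dict(zip(aligned.specimen_ids,
                                aligned.centroid_sizes))
            sel = [i for i, sid in enumerate(bm_meta["specimen_id"])
                   if sid in cs_by_id]
            if len(sel) > 3:
                cs = np.array([cs_by_id[bm_meta["specimen_id"][i]]
                               for i in sel])
                reg = regress_bm_on_size(X[sel], cs, n_perm=config.n_perm,
                                         seed=_stage_seed(config.seed, 40))
                _write_stats_csv(pd.DataFrame([{
                    "R2_multivariate": reg.R2_multivariate,
                    "p_perm": reg.p_perm, "n": len(sel)}]),
                    st_dir / "bm_size_regression.csv",
                    _stage_seed(config.seed, 40), config.n_perm)
                record(st_dir / "bm_size_regression.csv")
        stages_done.append(stage)

    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        log.error("stage %r failed: %s", stage, exc)
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, exc) from exc

    # ---------------------------------------------------- manifest
    manifest = {
        "package": "osteomap",
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "stages": stages_done,
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote manifest with %d outputs", len(outputs))
    root.removeHandler(handler)
    handler.close()
    return out
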