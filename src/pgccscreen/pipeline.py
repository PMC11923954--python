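"""Stage orchestration: wire the stages into reproducible, audited runs.

A run is driven by a :class:`RunConfig` (typically loaded from a YAML file;
CLI flags override fields).  Stages execute in dependency order

    simulate -> quantify -> screen-summary -> features -> benchmark
             -> ensemble -> vscreen

and every stage records its outputs in a JSON manifest together with the
config hash and the seeds in play, so each artifact file is traceable.  A
stage failure halts downstream stages; the partial manifest is still
written.

On synthetic runs the planted structure-activity relationship drives both
the image phenotype (per-well PGCC counts scale with the planted response)
and the modelling target, so the full chain is exercisable without any
external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import ensemble as ens
from . import features as feat
from . import fixtures as fx
from . import imaging, models, screening, vscreen

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = (
    "simulate",
    "quantify",
    "screen-summary",
    "features",
    "benchmark",
    "ensemble",
    "vscreen",
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run.  Paths are relative to ``output_dir``."""

    output_dir: str = "pgccscreen-run"
    seed: int = 0
    # --- simulate ---
    n_plate_compounds: int = 6  # compound wells imaged per plate
    n_control_wells: int = 2
    base_nonpgcc: int = 24
    base_pgcc: int = 6
    base_dead: int = 3
    image_shape: tuple[int, int] = (384, 384)
    n_compounds: int = 60  # synthetic library size for modelling
    sar_n_nonzero: int = 12
    sar_noise_sd: float = 0.25
    # --- modelling ---
    cv_rounds: int = 10
    cv_folds: int = 10
    families: tuple[str, ...] = models.MODEL_FAMILIES
    feature_set_ids: tuple[str, ...] | None = None  # None = all nine
    embedding_provider: str = "mock"
    embedding_signal_strength: float = 4.0
    # --- vscreen ---
    vscreen_n_compounds: int = 40
    top_k: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("image_shape", "families", "feature_set_ids"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sar(config: RunConfig) -> fx.PlantedSAR:
    return fx.PlantedSAR.random(
        system="MACCS",
        n_nonzero=config.sar_n_nonzero,
        noise_sd=config.sar_noise_sd,
        seed=config.seed,
    )


def _provider(config: RunConfig, library: pd.DataFrame) -> fx.MockEmbeddingProvider:
    if config.embedding_provider != "mock":
        raise ValueError(
            f"unknown embedding provider {config.embedding_provider!r}; "
            "only the deterministic 'mock' provider ships with the package"
        )
    signal_map = dict(zip(library["description"], library["y_true"].astype(float)))
    return fx.MockEmbeddingProvider(
        seed=config.seed,
        signal_map=signal_map,
        signal_strength=config.embedding_signal_strength,
    )


class PipelineRun:
    """Executes stages against one output directory, collecting a manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.root = Path(config.output_dir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "stages": {},
        }
        self._cache: dict = {}

    # ---------------- helpers ----------------
    def _record(self, stage: str, outputs: dict[str, str], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": outputs,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s finished in %.1fs", stage, time.time() - t0)

    def _write_manifest(self) -> Path:
        path = self.root / "run_manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path

    def _library(self) -> pd.DataFrame:
        if "library" not in self._cache:
            path = self.root / "compound_library.csv"
            if not path.exists():
                raise FileNotFoundError("compound library missing; run 'simulate' first")
            self._cache["library"] = pd.read_csv(path)
        return self._cache["library"]

    # ---------------- stages ----------------
    def stage_simulate(self) -> dict[str, str]:
        cfg = self.config
        geom = fx.PlateGeometry(shape=cfg.image_shape)
        img_dir = self.root / "images"
        img_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(cfg.seed)
        sar = _sar(cfg)
        library = fx.generate_compound_library(cfg.n_compounds, sar, seed=cfg.seed)
        library.to_csv(self.root / "compound_library.csv", index=False)
        self._cache["library"] = library

        platemap_rows, truth_frames = [], []
        plate_id = "P1"
        wells = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
        roles = [("control", None)] * cfg.n_control_wells + [
            ("compound", library.iloc[i]["compound_id"])
            for i in range(min(cfg.n_plate_compounds, len(library)))
        ]
        for (role, compound), well in zip(roles, wells):
            if role == "control":
                counts = (cfg.base_nonpgcc, cfg.base_pgcc, cfg.base_dead)
            else:
                # planted response scales the surviving-cell phenotype
                y = float(library.set_index("compound_id").loc[compound, "y_true"])
                norm = float(np.clip(np.exp2(y), 0.0, 3.0))
                counts = (
                    int(round(cfg.base_nonpgcc * norm)),
                    int(round(cfg.base_pgcc * norm)),
                    cfg.base_dead,
                )
            img, truth = fx.generate_plate_image(
                counts[0],
                counts[1],
                counts[2],
                seed=int(rng.integers(2**31)),
                geom=geom,
                well_id=well,
            )
            tifffile.imwrite(
                img_dir / f"{plate_id}_{well}.tif",
                img.astype(np.uint16),
                photometric="minisblack",
                planarconfig="separate",
            )
            truth_frames.append(truth.to_frame())
            platemap_rows.append(
                {
                    "well_id": well,
                    "plate_id": plate_id,
                    "role": role,
                    "compound_id": compound or "",
                }
            )
        pd.concat(truth_frames, ignore_index=True).to_csv(
            self.root / "ground_truth.csv", index=False
        )
        pd.DataFrame(platemap_rows).to_csv(self.root / "platemap.csv", index=False)
        return {
            "images": str(img_dir),
            "platemap": str(self.root / "platemap.csv"),
            "ground_truth": str(self.root / "ground_truth.csv"),
            "compound_library": str(self.root / "compound_library.csv"),
        }

    def stage_quantify(self) -> dict[str, str]:
        cfg = self.config
        params = fx.default_segmentation_params(fx.PlateGeometry(shape=cfg.image_shape))
        platemap = pd.read_csv(self.root / "platemap.csv")
        records_rows, counts_rows = [], []
        well_counts: list[imaging.WellCounts] = []
        for row in platemap.itertuples():
            img = tifffile.imread(self.root / "images" / f"{row.plate_id}_{row.well_id}.tif")
            counts, records = imaging.quantify_well(
                np.asarray(img, dtype=float),
                params,
                well_id=str(row.well_id),
                return_records=True,
            )
            well_counts.append(counts)
            counts_rows.append(dataclasses.asdict(counts) | {"plate_id": row.plate_id})
            for rec in records:
                records_rows.append(
                    {
                        "well": row.well_id,
                        "label": rec.label,
                        "x": rec.centroid[1],
                        "y": rec.centroid[0],
                        "area_px": rec.area,
                        "viability": rec.viability,
                        "is_pgcc": rec.is_pgcc,
                    }
                )
        pd.DataFrame(records_rows).to_csv(self.root / "nuclei.csv", index=False)
        pd.DataFrame(counts_rows).to_csv(self.root / "well_counts.csv", index=False)
        self._cache["well_counts"] = well_counts
        return {
            "nuclei": str(self.root / "nuclei.csv"),
            "well_counts": str(self.root / "well_counts.csv"),
        }

    def stage_screen_summary(self) -> dict[str, str]:
        platemap = pd.read_csv(self.root / "platemap.csv")
        counts_df = pd.read_csv(self.root / "well_counts.csv")
        counts = [
            imaging.WellCounts(
                well_id=str(r.well_id),
                n_live=int(r.n_live),
                n_dead=int(r.n_dead),
                n_pgcc=int(r.n_pgcc),
                n_nonpgcc=int(r.n_nonpgcc),
            )
            for r in counts_df.itertuples()
        ]
        layout = screening.PlateLayout.from_frame(platemap, plate_id="P1")
        table = screening.normalize_plate(counts, layout)
        table.to_csv(self.root / "response_table.csv", index=False)
        summary = screening.summarize_screen(table)
        (self.root / "screen_summary.json").write_text(json.dumps(summary, indent=2))
        return {
            "response_table": str(self.root / "response_table.csv"),
            "screen_summary": str(self.root / "screen_summary.json"),
        }

    def _feature_sets(self) -> list[feat.FeatureSet]:
        sets = feat.enumerate_feature_sets()
        if self.config.feature_set_ids is not None:
            wanted = set(self.config.feature_set_ids)
            sets = [s for s in sets if s.id in wanted]
            if len(sets) != len(wanted):
                raise ValueError("unknown feature set id(s) requested")
        return sets

    def stage_features(self) -> dict[str, str]:
        library = self._library()
        provider = _provider(self.config, library)
        fdir = self.root / "features"
        fdir.mkdir(exist_ok=True)
        manifest = {}
        for fs in self._feature_sets():
            X, retained = feat.assemble_feature_matrix(library, fs, provider=provider)
            path = fdir / f"{fs.id}.npz"
            np.savez_compressed(path, X=X, compound_id=np.array(retained))
            manifest[fs.id] = {
                "path": str(path),
                "n_features": fs.n_features,
                "n_retained": len(retained),
                "kind": fs.kind,
            }
        (fdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"features_dir": str(fdir), "manifest": str(fdir / "manifest.json")}

    def _load_features(self) -> tuple[dict[str, np.ndarray], list[feat.FeatureSet], np.ndarray]:
        library = self._library()
        y = library.set_index("compound_id")["y_true"]
        sets = self._feature_sets()
        matrices = {}
        ids_ref: list[str] | None = None
        for fs in sets:
            data = np.load(self.root / "features" / f"{fs.id}.npz", allow_pickle=False)
            matrices[fs.id] = data["X"]
            ids = [str(c) for c in data["compound_id"]]
            if ids_ref is None:
                ids_ref = ids
            elif ids != ids_ref:
                raise ValueError("feature sets retain different compounds; re-run features")
        assert ids_ref is not None
        return matrices, sets, y.loc[ids_ref].to_numpy(dtype=float)

    def stage_benchmark(self) -> dict[str, str]:
        cfg = self.config
        matrices, sets, y = self._load_features()
        n = len(y)
        plan = models.build_cv_plan(n, rounds=cfg.cv_rounds, folds=cfg.cv_folds, seed=cfg.seed)
        results = models.benchmark_grid(
            matrices, sets, y, plan, families=tuple(cfg.families), seed=cfg.seed
        )
        models.results_frame(results).to_csv(self.root / "benchmark_results.csv", index=False)
        (self.root / "benchmark_manifest.json").write_text(
            json.dumps(
                {
                    "plan_hash": plan.plan_hash,
                    "seed": cfg.seed,
                    "rounds": cfg.cv_rounds,
                    "folds": cfg.cv_folds,
                    "n_items": n,
                    "n_configs": len(results),
                },
                indent=2,
            )
        )
        self._cache["benchmark"] = (results, plan, y, matrices)
        return {
            "results": str(self.root / "benchmark_results.csv"),
            "manifest": str(self.root / "benchmark_manifest.json"),
        }

    def stage_ensemble(self) -> dict[str, str]:
        if "benchmark" not in self._cache:
            raise RuntimeError("ensemble stage requires the benchmark stage in-run")
        results, plan, y, matrices = self._cache["benchmark"]
        best_s = models.select_best(results, "structure")
        best_d = models.select_best(results, "description")
        stack_result, meta = ens.run_stacked_cv(best_s, best_d, y, plan)
        t_stat_s, p_s = ens.compare_paired(stack_result.round_scores, best_s.round_scores)
        t_stat_d, p_d = ens.compare_paired(stack_result.round_scores, best_d.round_scores)
        deployed = ens.fit_deployment_stack(
            best_s,
            best_d,
            matrices[best_s.config.feature_set.id],
            matrices[best_d.config.feature_set.id],
            y,
            plan,
            seed=self.config.seed,
        )
        manifest = {
            "base_structure": best_s.config.config_id,
            "base_description": best_d.config.config_id,
            "median_rho": {
                "structure": best_s.median_score,
                "description": best_d.median_score,
                "ensemble": stack_result.median_score,
            },
            "paired_t_vs_structure": {"t": t_stat_s, "p": p_s},
            "paired_t_vs_description": {"t": t_stat_d, "p": p_d},
            "meta_coefficients": {
                "intercept": meta.intercept,
                "beta_structure": meta.beta_structure,
                "beta_description": meta.beta_description,
                "p_values": list(meta.p_values),
            },
            "plan_hash": plan.plan_hash,
        }
        (self.root / "ensemble_manifest.json").write_text(json.dumps(manifest, indent=2))
        self._cache["deployed"] = (deployed, best_s, best_d)
        return {"manifest": str(self.root / "ensemble_manifest.json")}

    def stage_vscreen(self) -> dict[str, str]:
        cfg = self.config
        if "deployed" not in self._cache:
            raise RuntimeError("vscreen stage requires the ensemble stage in-run")
        deployed, best_s, best_d = self._cache["deployed"]
        library = self._library()
        sar = _sar(cfg)
        external = fx.generate_compound_library(
            cfg.vscreen_n_compounds, sar, seed=cfg.seed + 10_001
        )
        external["compound_id"] = "EXT" + external["compound_id"].str.removeprefix("CPD")
        provider = _provider(cfg, pd.concat([library, external], ignore_index=True))
        ranked, audit = vscreen.score_library(
            deployed,
            external,
            best_s.config.feature_set,
            best_d.config.feature_set,
            provider,
            training_library=library,
        )
        ranked.to_csv(self.root / "vscreen_ranked.csv", index=False)
        audit.to_frame().to_csv(self.root / "vscreen_audit.csv", index=False)
        top = vscreen.select_top(ranked, min(cfg.top_k, len(ranked)))
        top.to_csv(self.root / "vscreen_top.csv", index=False)
        return {
            "ranked": str(self.root / "vscreen_ranked.csv"),
            "audit": str(self.root / "vscreen_audit.csv"),
            "top": str(self.root / "vscreen_top.csv"),
        }


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Unknown stage names raise before any work.  A stage failure stops the
    run; the partial manifest (with the failure recorded) is still written.
    """
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    run = PipelineRun(config)
    dispatch = {
        "simulate": run.stage_simulate,
        "quantify": run.stage_quantify,
        "screen-summary": run.stage_screen_summary,
        "features": run.stage_features,
        "benchmark": run.stage_benchmark,
        "ensemble": run.stage_ensemble,
        "vscreen": run.stage_vscreen,
    }
    try:
        for stage in ordered:
            t0 = time.time()
            outputs = dispatch[stage]()
            run._record(stage, outputs, t0)
    except Exception as err:
        run.manifest["failed_stage"] = stage
        run.manifest["error"] = str(err)
        run._write_manifest()
        raise
    run.manifest["manifest_path"] = str(run._write_manifest())
    return run.manifest
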