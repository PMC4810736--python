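"""Config-driven orchestration of the full analysis.

A run takes either a directory of multi-channel TIFFs or a synthetic
preset, and executes the sequence: segmentation -> morphometry -> pairwise
Welch/Holm tests -> PCA -> NMDS + PERMANOVA -> MLP classification, writing
every artifact (features.csv, tests.json, pca.csv, nmds.csv, permanova.csv,
classifier_report.json, manifest.json, run.log) into one run directory.

A single global seed fans out to per-stage child seeds through a
SeedSequence, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify as clf
from . import imgproc, morphometry, stats, synthetic

logger = logging.getLogger(__name__)

STAGE_NAMES = ("generate", "segment", "measure", "compare", "pca", "nmds",
               "classify")


@dataclass
class RunConfig:
    input_mode: str = "synthetic"          # "synthetic" | "tiff_dir"
    preset: str = "type1"
    n_per_line: int = 100
    tiff_dir: str | None = None
    channel_order: tuple[str, str, str] = ("nucleus", "actin", "membrane")
    surface: str = "synthetic"
    # imgproc
    low_pct: float = 1.0
    high_pct: float = 99.9
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area: int = 200
    border_margin: int = 4
    # stats
    alpha: float = 0.05
    n_permutations: int = 999
    nmds_k: int = 3
    nmds_starts: int = 8
    # classifier
    hidden_units: tuple[int, ...] = (2, 5, 10)
    n_repartitions: int = 3
    n_sample_pairs: int = 100
    sample_size: int = 10
    decision_threshold: float = 0.6
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs/run"
    fast_synthetic: bool = False           # skip image formation, measure masks

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channel_order", "hidden_units"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.input_mode not in ("synthetic", "tiff_dir"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "synthetic" and self.preset not in synthetic.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.input_mode == "tiff_dir":
            if not self.tiff_dir or not Path(self.tiff_dir).is_dir():
                raise ValueError(f"tiff_dir {self.tiff_dir!r} does not exist")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _features_synthetic(config: RunConfig, seed: int) -> pd.DataFrame:
    if config.fast_synthetic:
        low_p, high_p = synthetic.preset_populations(config.preset)
        s_low, s_high = _child_seeds(seed, 2)
        inst_low, _ = synthetic.single_cell_instances(
            low_p, config.n_per_line, seed=s_low, surface=config.surface)
        inst_high, _ = synthetic.single_cell_instances(
            high_p, config.n_per_line, seed=s_high, surface=config.surface)
        return morphometry.feature_table(inst_low + inst_high)
    exp = synthetic.generate_paired_experiment(
        config.preset, config.n_per_line, seed=seed)
    instances = []
    for ds, label in ((exp.low, "low"), (exp.high, "high")):
        for i, planes in enumerate(ds.images):
            stack = imgproc.ChannelStack(
                nucleus_plane=planes["nucleus"].astype(float),
                actin_plane=planes["actin"].astype(float),
                membrane_plane=planes["membrane"].astype(float),
                line=label, surface=config.surface,
                image_id=f"{label}_img{i:03d}",
            )
            found = imgproc.segment_stack(
                stack, low_pct=config.low_pct, high_pct=config.high_pct,
                method=config.threshold_method,
                fixed_value=config.fixed_threshold,
                min_area=config.min_area,
                border_margin=config.border_margin,
            )
            for inst in found:
                inst.metastatic_class = label
            instances.extend(found)
    return morphometry.feature_table(instances)


def _features_tiff(config: RunConfig) -> pd.DataFrame:
    instances = []
    for path in sorted(Path(config.tiff_dir).glob("*.tif*")):
        # file naming convention: <line>_<anything>.tif; "high"/"low" in the
        # line token sets the metastatic class
        line = path.stem.split("_")[0]
        stack = imgproc.read_channel_stack(
            path, channel_order=config.channel_order,
            line=line, surface=config.surface, image_id=path.stem,
        )
        found = imgproc.segment_stack(
            stack, low_pct=config.low_pct, high_pct=config.high_pct,
            method=config.threshold_method, fixed_value=config.fixed_threshold,
            min_area=config.min_area, border_margin=config.border_margin,
        )
        for inst in found:
            inst.metastatic_class = "high" if "high" in line else "low"
        instances.extend(found)
    return morphometry.feature_table(instances)


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    A stage failure preserves all artifacts written so far and is recorded
    in the manifest with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("cytoshape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seeds = dict(zip(STAGE_NAMES, _child_seeds(config.seed, len(STAGE_NAMES))))
    manifest = {
        "config": _jsonable(asdict(config)),
        "stage_seeds": seeds,
        "version": __version__,
        "completed_stages": [],
        "failed_stage": None,
    }
    descriptors = list(morphometry.ALL_DESCRIPTORS)
    try:
        # --- features -----------------------------------------------------
        logger.info("stage: generate/segment/measure")
        if config.input_mode == "synthetic":
            table = _features_synthetic(config, seeds["generate"])
        else:
            table = _features_tiff(config)
        if table.empty:
            raise RuntimeError("no cells survived segmentation")
        morphometry.write_feature_table(
            table, out / "features.csv", out / "feature_schema.json")
        manifest["completed_stages"] += ["generate", "segment", "measure"]

        # --- pairwise tests -----------------------------------------------
        logger.info("stage: compare")
        tests = stats.compare_groups(
            table, descriptors, "metastatic_class", "high", "low",
            alpha=config.alpha)
        tests.to_json(out / "tests.json", orient="records", indent=2)
        manifest["completed_stages"].append("compare")

        # --- PCA ----------------------------------------------------------
        logger.info("stage: pca")
        pca = stats.pca_svd(table, columns=descriptors)
        pca_df = pd.DataFrame(
            pca.coordinates[:, :3], columns=["PC1", "PC2", "PC3"])
        pca_df["metastatic_class"] = table["metastatic_class"].to_numpy()
        pca_df.to_csv(out / "pca.csv", index=False)
        with open(out / "pca_variance.json", "w") as fh:
            json.dump({"variance_fraction":
                       pca.variance_fraction[:10].tolist()}, fh, indent=2)
        manifest["completed_stages"].append("pca")

        # --- NMDS + PERMANOVA ----------------------------------------------
        logger.info("stage: nmds")
        rel = stats.relativize_by_max(table, columns=descriptors)
        D = stats.bray_curtis(rel[descriptors])
        nm = stats.nmds(D, k=config.nmds_k, n_starts=config.nmds_starts,
                        seed=seeds["nmds"])
        coords = stats.rotate_and_center(nm.coordinates)
        nmds_df = pd.DataFrame(
            coords, columns=[f"NMDS{i + 1}" for i in range(config.nmds_k)])
        nmds_df["metastatic_class"] = table["metastatic_class"].to_numpy()
        nmds_df.to_csv(out / "nmds.csv", index=False)
        perma = stats.permanova(D, table["metastatic_class"].to_numpy(),
                                n_permutations=config.n_permutations,
                                seed=seeds["nmds"])
        pd.DataFrame([{
            "comparison": "high_vs_low", "surface": config.surface,
            "stress": nm.stress, "R2": perma.r_squared,
            "pseudo_F": perma.pseudo_f, "p": perma.p_value,
            "n_permutations": config.n_permutations,
        }]).to_csv(out / "permanova.csv", index=False)
        manifest["completed_stages"].append("nmds")

        # --- classification -------------------------------------------------
        logger.info("stage: classify")
        part = clf.partition_data(table, "metastatic_class",
                                  seed=seeds["classify"])
        cands = clf.candidate_specs(descriptors,
                                    hidden_units=config.hidden_units,
                                    seed=seeds["classify"])
        spec, scores = clf.select_model(
            cands, table, "metastatic_class", "high", part,
            n_repartitions=config.n_repartitions, seed=seeds["classify"])
        model, cell_acc = clf.final_fit_and_validate(
            spec, table, "metastatic_class", "high", part)
        report = clf.classify_samples(
            model, table.loc[part.validation], "metastatic_class", "high",
            n_pairs=config.n_sample_pairs, sample_size=config.sample_size,
            threshold=config.decision_threshold, seed=seeds["classify"])
        model.save(out / "model.json")
        with open(out / "classifier_report.json", "w") as fh:
            json.dump({
                "single_cell_validation_accuracy": cell_acc,
                "selected_hidden_units": spec.hidden_units,
                "selected_n_features": len(spec.features),
                "selection_scores": scores.to_dict(orient="records"),
                "sample_report": report.as_dict(),
            }, fh, indent=2)
        manifest["completed_stages"].append("classify")
    except Exception as exc:  # preserve partial outputs, record the stage
        done = set(manifest["completed_stages"])
        manifest["failed_stage"] = next(
            (s for s in STAGE_NAMES if s not in done), "unknown")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("stage %s failed:\n%s", manifest["failed_stage"],
                     traceback.format_exc())
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        root.removeHandler(handler)
        handler.close()
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(run_dir) -> str:
    """Human-readable markdown summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = [f"# cytoshape run report: {run_dir.name}", ""]
    absent = []

    tests_path = run_dir / "tests.json"
    if tests_path.exists():
        tests = pd.read_json(tests_path)
        sig = tests.loc[tests["significant_holm"]]
        lines += ["## Pairwise comparisons (Welch + Holm)",
                  f"{len(sig)}/{len(tests)} descriptors significant "
                  "after Holm correction:", ""]
        for _, row in sig.iterrows():
            lines.append(
                f"- {row['descriptor']}: {row['percent_difference']:+.1f}% "
                f"(high vs low), p = {row['p']:.2e}")
        lines.append("")
    else:
        absent.append("tests.json")

    perma_path = run_dir / "permanova.csv"
    if perma_path.exists():
        pm = pd.read_csv(perma_path).iloc[0]
        lines += ["## Ordination",
                  f"- NMDS stress (k=3): {pm['stress']:.4f}",
                  f"- PERMANOVA R^2 = {pm['R2']:.3f}, p = {pm['p']:.4f} "
                  f"({int(pm['n_permutations'])} permutations)", ""]
    else:
        absent.append("permanova.csv")

    clf_path = run_dir / "classifier_report.json"
    if clf_path.exists():
        with open(clf_path) as fh:
            rep = json.load(fh)
        s = rep["sample_report"]
        lines += ["## Classification",
                  "- single-cell validation accuracy: "
                  f"{rep['single_cell_validation_accuracy']:.3f}",
                  f"- sample-level accuracy ({s['sample_size']}-cell samples, "
                  f"threshold {s['threshold']}): {s['accuracy']:.3f} "
                  f"(TP={s['tp']}, TN={s['tn']}, FP={s['fp']}, FN={s['fn']}; "
                  f"FNR={s['fnr']:.3f}, TPR={s['tpr']:.3f})", ""]
    else:
        absent.append("classifier_report.json")

    if absent:
        lines += ["## Missing artifacts"] + [f"- {a}" for a in absent]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
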