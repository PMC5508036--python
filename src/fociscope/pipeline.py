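"""End-to-end workflow: simulate -> segment -> detect -> measure -> associate.

This module wires the stage functions together around a single YAML run
configuration and a single seed, producing CSV outputs plus a JSON run
manifest.  It also hosts the field-level analysis helper and the
synthetic-training utilities shared by the CLI, the test suite and the
acceptance script.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import detection, metrics, segmentation, stacks, stats, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "region_segmentation_params",
    "analyze_field",
    "match_to_planted",
    "train_classifier_from_synthetic",
    "run_pipeline",
    "validate_run",
]

CLASS_NAME_MAP = {
    "cortical_neuron": "neuron",
    "cortical_glia": "glia",
    "granule": "granule",
    "purkinje": "purkinje",
}

STAGES = ("simulate", "segment", "detect", "measure", "associate", "validate")


@dataclasses.dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "runs/demo"
    region: str = "frontal_cortex"
    probe: str = "sense"
    mode: str = "all_cells"  # all_cells | neurons
    n_subjects: int = 2
    fields_per_subject: int = 3
    n_validation_fields: int = 20
    background_percentile: float = 5.0
    speckle_k: float = 5.0
    classifier_path: str | None = None
    image_shape: tuple = (256, 256)
    n_planes: int = 8
    association_enabled: bool = True
    validation_floors: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"concordance_r": 0.0, "nucleus_count_error": 1.0}
    )

    def validate(self) -> None:
        if self.mode not in ("all_cells", "neurons"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.region not in detection.GATE_BY_REGION:
            raise ValueError(f"unknown region {self.region!r}")
        if self.mode == "neurons":
            if not self.classifier_path:
                raise ValueError("neurons mode requires classifier_path")
            if not os.path.exists(self.classifier_path):
                raise ValueError(
                    f"classifier_path {self.classifier_path!r} does not exist"
                )
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "image_shape" in raw:
        raw["image_shape"] = tuple(raw["image_shape"])
    return RunConfig(**raw)


def region_segmentation_params(region: str) -> segmentation.SegmentationParams:
    """Nucleus gates per region; faint large cerebellar objects excluded."""
    if region == "frontal_cortex":
        return segmentation.SegmentationParams(min_diameter_px=7.0, max_diameter_px=30.0)
    # granule-sized gate: Purkinje nuclei (large, faint) never auto-counted
    return segmentation.SegmentationParams(
        min_diameter_px=6.0,
        max_diameter_px=16.0,
        min_mean_intensity=0.30,
        declump_min_distance_px=3,
    )


def analyze_field(
    stack: stacks.ZStack,
    region: str,
    probe: str = "sense",
    mode: str = "all_cells",
    classifier: segmentation.NucleusClassifier | None = None,
    background_percentile: float = 5.0,
    speckle_k: float = 5.0,
) -> dict:
    """Run projection, segmentation, detection and counting on one stack.

    Returns a dict with ``label_map``, ``nuclei`` (records after any
    class filtering), ``foci``, ``masked_object_count`` and ``counts``
    (per-nucleus table over the retained nuclei).
    """
    field = stacks.suppress_background(stacks.max_project(stack), background_percentile)
    seg_params = region_segmentation_params(region)
    label_map, records = segmentation.segment_nuclei(field.nuclear, seg_params)

    det_params = detection.DetectionParams(region=region, speckle_k=speckle_k)
    response = detection.enhance_speckles(field.probe, det_params.gate[1])
    foci, masked = detection.detect_foci(
        response, label_map, det_params, probe=probe, raw_image=field.probe
    )

    kept = segmentation.classify_nuclei(records, classifier, mode=mode)
    kept_ids = {rec.nucleus_id for rec in kept}
    kept_foci = [f for f in foci if f.nucleus_id in kept_ids]
    counts = detection.count_per_nucleus(kept_foci, kept)
    return dict(
        label_map=label_map,
        nuclei=kept,
        all_nuclei=records,
        foci=kept_foci,
        masked_object_count=masked,
        counts=counts,
    )


def match_to_planted(
    records: Sequence[segmentation.NucleusRecord],
    truth_nuclei: pd.DataFrame,
    max_distance_px: float = 5.0,
) -> pd.DataFrame:
    """Hungarian-match segmented nuclei to planted nuclei by centroid.

    Returns rows ``nucleus_id, planted_id, planted_class, distance_px``
    for matches within ``max_distance_px``.
    """
    if not records or truth_nuclei.empty:
        return pd.DataFrame(
            columns=["nucleus_id", "planted_id", "planted_class", "distance_px"]
        )
    seg_xy = np.array([rec.centroid for rec in records])
    tru_xy = truth_nuclei[["centroid_row", "centroid_col"]].to_numpy()
    dist = cdist(seg_xy, tru_xy)
    rows_idx, cols_idx = linear_sum_assignment(dist)
    out = []
    for i, j in zip(rows_idx, cols_idx):
        if dist[i, j] > max_distance_px:
            continue
        out.append(
            dict(
                nucleus_id=records[i].nucleus_id,
                planted_id=int(truth_nuclei.iloc[j]["nucleus_id"]),
                planted_class=truth_nuclei.iloc[j]["cell_class"],
                distance_px=float(dist[i, j]),
            )
        )
    return pd.DataFrame(out, columns=["nucleus_id", "planted_id", "planted_class", "distance_px"])


def train_classifier_from_synthetic(
    region: str = "frontal_cortex",
    n_fields: int = 10,
    seed: int = 123,
    field_spec: synthetic.FieldSpec | None = None,
) -> segmentation.NucleusClassifier:
    """Train the nucleus class forest on labeled synthetic fields.

    Fields are generated, segmented, and the segmented nuclei labeled by
    Hungarian matching against the planted classes; unmatched nuclei are
    dropped from training.
    """
    spec = field_spec or synthetic.default_field_spec(region)
    frames = []
    labels: list[str] = []
    for i in range(n_fields):
        stack, truth = synthetic.generate_field(spec, "sense", seed=seed + 1000 + i)
        result = analyze_field(stack, region)
        matched = match_to_planted(result["all_nuclei"], truth.nuclei)
        by_id = dict(zip(matched["nucleus_id"], matched["planted_class"]))
        for rec in result["all_nuclei"]:
            planted = by_id.get(rec.nucleus_id)
            if planted is None:
                continue
            frames.append(rec.features)
            labels.append(CLASS_NAME_MAP[planted])
    features = pd.DataFrame(frames)
    return segmentation.train_classifier(features, labels, seed=seed)


# ---------------------------------------------------------------------------
# staged pipeline
# ---------------------------------------------------------------------------

def _stage_paths(out_dir: str) -> dict:
    return {
        "fixture": os.path.join(out_dir, "fixture"),
        "nuclei": os.path.join(out_dir, "nuclei.csv"),
        "foci": os.path.join(out_dir, "foci.csv"),
        "counts": os.path.join(out_dir, "counts.csv"),
        "summaries": os.path.join(out_dir, "per_subject_summaries.csv"),
        "table2": os.path.join(out_dir, "table2.csv"),
        "table3": os.path.join(out_dir, "table3.csv"),
        "validation": os.path.join(out_dir, "validation.json"),
        "manifest": os.path.join(out_dir, "run_manifest.json"),
        "log": os.path.join(out_dir, "run.log"),
    }


def _field_stems(fixture_dir: str, probe: str) -> list:
    stems = sorted(
        os.path.basename(p)[: -len(".tif")]
        for p in glob.glob(os.path.join(fixture_dir, f"*_{probe}.tif"))
    )
    return stems


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = STAGES,
    resume: bool = False,
) -> dict:
    """Run the requested stages; returns the run manifest dict.

    Outputs are deterministic given the configured seed.  A stage failure
    propagates after logging which stage failed; downstream outputs are
    not written.  With ``resume=True`` a stage whose primary output file
    already exists is skipped.
    """
    config.validate()
    paths = _stage_paths(config.out_dir)
    os.makedirs(config.out_dir, exist_ok=True)
    handler = logging.FileHandler(paths["log"])
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("fociscope")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    classifier = (
        segmentation.NucleusClassifier.load(config.classifier_path)
        if config.mode == "neurons"
        else None
    )
    try:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            try:
                rows = _run_stage(stage, config, paths, classifier, resume)
            except Exception:
                root.error("stage %s failed", stage)
                raise RuntimeError(f"pipeline stage {stage!r} failed") from None
            manifest["stages"][stage] = rows
            root.info("stage %s done: %s", stage, rows)
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2)
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest


def _run_stage(stage, config, paths, classifier, resume):  # noqa: C901
    probe = config.probe

    if stage == "simulate":
        manifest_path = os.path.join(paths["fixture"], "manifest.txt")
        if resume and os.path.exists(manifest_path):
            return {"skipped": True}
        spec = synthetic.default_field_spec(
            config.region,
            image_shape_px=tuple(config.image_shape),
            n_planes=config.n_planes,
        )
        bundle = synthetic.generate_cohort(
            config.n_subjects,
            spec,
            config.fields_per_subject,
            seed=config.seed,
            probe=probe,
        )
        synthetic.write_fixture(bundle, paths["fixture"])
        return {"fields": len(bundle.fields), "subjects": config.n_subjects}

    if stage == "segment":
        if resume and os.path.exists(paths["nuclei"]):
            return {"skipped": True}
        rows = []
        for stem in _field_stems(paths["fixture"], probe):
            subject_id, field_id, _ = stem.split("_")
            stack = stacks.read_stack(os.path.join(paths["fixture"], f"{stem}.tif"))
            result = analyze_field(
                stack,
                config.region,
                probe=probe,
                mode="all_cells",
                background_percentile=config.background_percentile,
                speckle_k=config.speckle_k,
            )
            for rec in result["all_nuclei"]:
                row = dict(
                    subject_id=subject_id,
                    field_id=field_id,
                    nucleus_id=rec.nucleus_id,
                    centroid_row=rec.centroid[0],
                    centroid_col=rec.centroid[1],
                )
                row.update(rec.features)
                rows.append(row)
        pd.DataFrame(rows).to_csv(paths["nuclei"], index=False)
        return {"nuclei": len(rows)}

    if stage == "detect":
        if resume and os.path.exists(paths["foci"]):
            return {"skipped": True}
        foci_rows = []
        count_rows = []
        masked_total = 0
        for stem in _field_stems(paths["fixture"], probe):
            subject_id, field_id, _ = stem.split("_")
            stack = stacks.read_stack(os.path.join(paths["fixture"], f"{stem}.tif"))
            result = analyze_field(
                stack,
                config.region,
                probe=probe,
                mode=config.mode,
                classifier=classifier,
                background_percentile=config.background_percentile,
                speckle_k=config.speckle_k,
            )
            masked_total += result["masked_object_count"]
            for focus in result["foci"]:
                foci_rows.append(
                    dict(
                        subject_id=subject_id,
                        field_id=field_id,
                        probe=probe,
                        nucleus_id=focus.nucleus_id,
                        focus_id=focus.focus_id,
                        centroid_row=focus.centroid[0],
                        centroid_col=focus.centroid[1],
                        diameter_px=focus.equivalent_diameter_px,
                        peak_intensity=focus.peak_intensity,
                    )
                )
            counts = result["counts"].copy()
            counts.insert(0, "field_id", field_id)
            counts.insert(0, "subject_id", subject_id)
            count_rows.append(counts)
        foci_cols = [
            "subject_id",
            "field_id",
            "probe",
            "nucleus_id",
            "focus_id",
            "centroid_row",
            "centroid_col",
            "diameter_px",
            "peak_intensity",
        ]
        pd.DataFrame(foci_rows, columns=foci_cols).to_csv(paths["foci"], index=False)
        counts = (
            pd.concat(count_rows, ignore_index=True)
            if count_rows
            else pd.DataFrame(columns=["subject_id", "field_id", "nucleus_id", "foci_count"])
        )
        counts.to_csv(paths["counts"], index=False)
        return {"foci": len(foci_rows), "masked_objects": masked_total}

    if stage == "measure":
        if resume and os.path.exists(paths["summaries"]):
            return {"skipped": True}
        counts = pd.read_csv(paths["counts"])
        population = "neurons" if config.mode == "neurons" else (
            "granule" if config.region == "cerebellum" else "all_cells"
        )
        summaries = []
        for subject_id, grp in counts.groupby("subject_id", sort=True):
            summaries.append(
                metrics.aggregate_subject(
                    grp[["field_id", "nucleus_id", "foci_count"]],
                    subject_id=str(subject_id),
                    region=config.region,
                    population=population,
                    probe=probe,
                )
            )
        frame = pd.DataFrame([s.as_dict() for s in summaries])
        frame.to_csv(paths["summaries"], index=False)
        if len(summaries) >= 3:
            metrics.build_table2(summaries).to_csv(paths["table2"], index=False)
        else:
            logger.warning("fewer than 3 subjects; table2 skipped")
            pd.DataFrame().to_csv(paths["table2"], index=False)
        return {"subjects": len(summaries)}

    if stage == "associate":
        if resume and os.path.exists(paths["table3"]):
            return {"skipped": True}
        if not config.association_enabled:
            return {"skipped": True}
        summaries = pd.read_csv(paths["summaries"])
        clinical = pd.read_csv(os.path.join(paths["fixture"], "clinical.csv"))
        results = stats.run_association_suite(summaries, clinical)
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            paths["table3"], index=False
        )
        return {"associations": len(results)}

    if stage == "validate":
        report = validate_run(config)
        with open(paths["validation"], "w") as fh:
            json.dump(report, fh, indent=2)
        if not report["passed"]:
            raise RuntimeError("validation floors not met")
        return {"validation_fields": report["n_fields"], "passed": report["passed"]}

    raise ValueError(f"unknown stage {stage!r}")


def validate_run(config: RunConfig) -> dict:
    """Compare automated per-field results with planted ground truth.

    Uses up to ``n_validation_fields`` fields of the run's fixture and
    reports the concordance Spearman r on per-field foci totals, the mean
    relative nucleus-count error, and pass/fail against the configured
    floors.
    """
    paths = _stage_paths(config.out_dir)
    probe = config.probe
    stems = _field_stems(paths["fixture"], probe)[: config.n_validation_fields]
    if not stems:
        raise FileNotFoundError("no reference fixture fields available for validation")
    counts = pd.read_csv(paths["counts"])

    auto_totals = []
    truth_totals = []
    nucleus_errors = []
    for stem in stems:
        subject_id, field_id, _ = stem.split("_")
        truth_foci = pd.read_csv(
            os.path.join(paths["fixture"], f"{stem}_truth_foci.csv")
        )
        truth_nuclei = pd.read_csv(
            os.path.join(paths["fixture"], f"{stem}_truth_nuclei.csv")
        )
        truth_classes = None
        if config.mode == "neurons":
            truth_classes = {"cortical_neuron"}
        elif config.region == "cerebellum":
            truth_classes = {"granule"}
        if truth_classes is not None:
            owners = truth_nuclei[truth_nuclei["cell_class"].isin(truth_classes)]
            truth_foci = truth_foci[truth_foci["nucleus_id"].isin(owners["nucleus_id"])]
        sel = counts[(counts.subject_id == subject_id) & (counts.field_id == field_id)]
        auto_totals.append(int(sel["foci_count"].sum()))
        truth_totals.append(len(truth_foci))
        n_auto = sel["nucleus_id"].nunique()
        n_true = len(truth_nuclei)
        if config.region == "cerebellum":
            n_true = int((truth_nuclei["cell_class"] == "granule").sum())
        nucleus_errors.append(abs(n_auto - n_true) / max(n_true, 1))

    if len(stems) >= 5:
        r, p = metrics.concordance(auto_totals, truth_totals)
    else:
        r, p = float("nan"), float("nan")
    nucleus_error = float(np.mean(nucleus_errors))
    floors = config.validation_floors
    passed = bool(
        (np.isnan(r) or r >= floors.get("concordance_r", 0.0))
        and nucleus_error <= floors.get("nucleus_count_error", 1.0)
    )
    return {
        "n_fields": len(stems),
        "concordance_r": None if np.isnan(r) else float(r),
        "concordance_p": None if np.isnan(p) else float(p),
        "nucleus_count_error": nucleus_error,
        "auto_totals": auto_totals,
        "truth_totals": truth_totals,
        "passed": passed,
    }
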