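"""End-to-end orchestration: keyframes -> [external SfM] -> filter ->
downsample -> segment -> map -> count -> report.

Each enabled stage reads the previous stage's persisted artifact and
writes its own into the run directory, so a run can resume from any
stage. Reconstruction itself (SfM) is delegated to an external tool
behind a small subprocess adapter; when no backend is configured the
pipeline starts from a provided point cloud.
"""

from __future__ import annotations

import json
import os
import subprocess
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import cloudio, counting, dgcnn, keyframes, mapping
from .cloudio import PointCloud, PassthroughRange

__all__ = ["PipelineConfig", "SfmAdapter", "run_pipeline",
           "segmentation_metrics"]


@dataclass
class SfmAdapter:
    """Subprocess interface to an external structure-from-motion tool.

    ``command`` is a format string receiving ``{frames}`` (directory of
    keyframe PNGs) and ``{output}`` (path of the dense PLY the tool must
    write). No reconstruction math lives in this package.
    """

    command: str

    def reconstruct(self, frames_dir: str, output_ply: str) -> PointCloud:
        cmd = self.command.format(frames=frames_dir, output=output_ply)
        subprocess.run(cmd, shell=True, check=True)
        return cloudio.read_cloud(output_ply, format="ply")


@dataclass
class PipelineConfig:
    """One record driving a full run; every stage can be toggled."""

    run_dir: str = "siliqueseg_run"
    seed: int = 0

    # stage toggles
    do_keyframes: bool = False
    do_sfm: bool = False
    do_passthrough: bool = False
    do_downsample: bool = True
    do_segment: bool = True
    do_map: bool = True
    do_count: bool = True

    # inputs
    frames_dir: str | None = None
    input_cloud: str | None = None
    true_count: int | None = None

    # per-stage parameter blocks
    keyframe_params: keyframes.KeyframeParams | None = None
    sfm_command: str | None = None
    passthrough_axis: str = "z"
    passthrough_lo: float = 0.0
    passthrough_hi: float = 1.0
    downsample_n: int = 8192
    downsample_method: str = "fps"
    segmenter: str = "baseline"          # "baseline" or "dgcnn"
    model_path: str | None = None
    baseline_height_quantile: float = 0.4
    mapping_params: mapping.MappingParams = field(
        default_factory=mapping.MappingParams)
    counting_params: counting.CountingParams = field(
        default_factory=counting.CountingParams)

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw = dict(raw)
        if "keyframe_params" in kw:
            kw["keyframe_params"] = keyframes.KeyframeParams(
                **kw["keyframe_params"])
        if "mapping_params" in kw:
            kw["mapping_params"] = mapping.MappingParams(**kw["mapping_params"])
        if "counting_params" in kw:
            kw["counting_params"] = counting.CountingParams(
                **kw["counting_params"])
        return cls(**kw)


def _persist_cloud(cloud: PointCloud, path: str) -> None:
    cloudio.write_cloud(path, cloud)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    The manifest maps stage names to their artifact paths plus the final
    counting report (when the count stage runs). Stage outputs are pure
    functions of (inputs, config, seed): re-running with the same config
    reproduces every artifact byte-for-byte.
    """
    stages = [config.do_keyframes, config.do_sfm, config.do_passthrough,
              config.do_downsample, config.do_segment, config.do_map,
              config.do_count]
    if not any(stages):
        raise ValueError("no stage enabled")
    os.makedirs(config.run_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, path: str | None, **extra) -> None:
        manifest["stages"][stage] = {"artifact": path, **extra}

    frames_dir = config.frames_dir
    if config.do_keyframes:
        if frames_dir is None:
            raise RuntimeError("keyframes stage: frames_dir not set")
        frames = keyframes.load_frames(frames_dir)
        params = config.keyframe_params or keyframes.KeyframeParams.for_sequence(
            len(frames))
        chosen = keyframes.select_keyframes(frames, params)
        out_dir = os.path.join(config.run_dir, "keyframes")
        keyframes.save_keyframes(frames, chosen, out_dir)
        record("keyframes", out_dir, n_selected=len(chosen))
        frames_dir = out_dir

    cloud: PointCloud | None = None
    if config.do_sfm:
        if config.sfm_command is None:
            if config.input_cloud is None:
                raise RuntimeError(
                    "sfm stage: no backend configured and no input cloud")
            warnings.warn("sfm stage skipped: no backend configured; "
                          "using the supplied cloud", stacklevel=2)
            record("sfm", None, skipped=True)
        else:
            ply = os.path.join(config.run_dir, "dense.ply")
            cloud = SfmAdapter(config.sfm_command).reconstruct(frames_dir, ply)
            record("sfm", ply)
    if cloud is None:
        if config.input_cloud is None:
            raise RuntimeError("no point cloud available: provide "
                               "input_cloud or enable a working sfm stage")
        cloud = cloudio.read_cloud(config.input_cloud)

    if config.do_passthrough:
        cloud = cloudio.passthrough(cloud, PassthroughRange(
            config.passthrough_axis, config.passthrough_lo,
            config.passthrough_hi))
        path = os.path.join(config.run_dir, "filtered.txt")
        _persist_cloud(cloud, path)
        record("passthrough", path, n_points=len(cloud))

    dense = cloud
    sparse = cloud
    if config.do_downsample:
        n = min(config.downsample_n, len(cloud))
        sparse = cloudio.downsample(cloud, n, config.downsample_method,
                                    seed=config.seed)
        path = os.path.join(config.run_dir, "sparse.txt")
        _persist_cloud(sparse, path)
        record("downsample", path, n_points=n)

    if config.do_segment:
        if config.segmenter == "dgcnn":
            if config.model_path is None:
                raise RuntimeError("segment stage: model_path not set")
            model = dgcnn.load_model(config.model_path)
            result = dgcnn.segment(sparse, model, seed=config.seed)
        elif config.segmenter == "baseline":
            result = dgcnn.baseline_segment(
                sparse, height_quantile=config.baseline_height_quantile)
        else:
            raise ValueError(f"unknown segmenter {config.segmenter!r}")
        sparse = PointCloud(sparse.coords, result.labels, sparse.colors)
        path = os.path.join(config.run_dir, "sparse_labeled.txt")
        _persist_cloud(sparse, path)
        record("segment", path,
               n_silique=int((result.labels == 1).sum()))

    canopy = sparse
    if config.do_map:
        if not sparse.is_labeled:
            raise RuntimeError("map stage needs a labeled sparse cloud")
        canopy = mapping.map_sparse_to_dense(sparse, dense,
                                             config.mapping_params)
        path = os.path.join(config.run_dir, "canopy.txt")
        if len(canopy):
            _persist_cloud(canopy, path)
        record("map", path, n_points=len(canopy))
    elif canopy.is_labeled:
        canopy = canopy.select(canopy.labels == 1)

    if config.do_count:
        lines = counting.count_siliques(canopy, config.counting_params)
        labels = np.zeros(len(canopy), dtype=int)
        for li, line in enumerate(lines, start=1):
            labels[line.inlier_indices] = li
        seg_path = os.path.join(config.run_dir, "siliques.ply")
        if len(canopy):
            cloudio.write_cloud(
                seg_path, PointCloud(canopy.coords, labels))
        count = len(lines)
        report = {"count": count}
        if config.true_count is not None:
            correct = min(count, config.true_count)
            rep = counting.counting_metrics([config.true_count], [correct])
            report = rep.to_dict()
            report["count"] = count
        report_path = os.path.join(config.run_dir, "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        record("count", report_path, count=count)
        manifest["report"] = report

    manifest_path = os.path.join(config.run_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def segmentation_metrics(predicted: np.ndarray, true: np.ndarray,
                         positive_label: int = 1) -> dict:
    """Precision/recall/F1/IoU (percent) for the silique class.

    Standard confusion-matrix metrics of the positive (silique) class;
    IoU is intersection-over-union of the predicted and true positive
    sets (tp / (tp + fp + fn)).
    """
    from sklearn.metrics import jaccard_score, precision_recall_fscore_support

    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    prec, rec, f1, _ = precision_recall_fscore_support(
        true, predicted, labels=[positive_label], average=None,
        zero_division=0.0)
    iou = jaccard_score(true, predicted, labels=[positive_label],
                        average=None, zero_division=0.0)
    return {"precision_percent": 100.0 * float(prec[0]),
            "recall_percent": 100.0 * float(rec[0]),
            "f1_percent": 100.0 * float(f1[0]),
            "iou_percent": 100.0 * float(iou[0])}
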