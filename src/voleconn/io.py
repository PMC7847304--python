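"""File formats, manifests and the pipeline driver.

Conventions: time series and matrices are TSV (ROI-label headers),
behavior and design tables are CSV, configurations/manifests/results are
JSON, volumes and masks are NIfTI (optional, via nibabel).  A connectome
stack is a directory of per-(subject, session) TSVs plus a JSON manifest
that records the ROI list and the canonical edge ordering (upper triangle
in ROI-list order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .connectome import (ROI_16, ConnectomeStack, build_connectome_stack,
                         edge_index_map, n_edges)
from .lmm import NBSLMM
from .nbs_glm import NBSGLM, NbsResult, NetworkComponent
from .preprocess import bandpass
from .synthetic import RoiTimeSeriesPanel, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


def _key_name(subject: int, session: int) -> str:
    return f"sub-{subject:02d}_ses-{session}"


def write_timeseries_tsv(path, series: np.ndarray, roi_names) -> None:
    pd.DataFrame(np.asarray(series), columns=list(roi_names)).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_timeseries_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_panel(panel: RoiTimeSeriesPanel, out_dir) -> Path:
    """One TSV per (subject, session) plus a JSON cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (subj, sess), series in panel.data.items():
        write_timeseries_tsv(out / f"{_key_name(subj, sess)}_timeseries.tsv",
                             series, panel.roi_names)
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": "timeseries_panel",
        "roi_names": list(panel.roi_names),
        "tr": panel.tr,
        "cells": [list(k) for k in panel.keys()],
        "subjects": panel.meta.to_dict(orient="list"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def read_panel(in_dir) -> RoiTimeSeriesPanel:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    data = {}
    for subj, sess in manifest["cells"]:
        series, cols = read_timeseries_tsv(
            src / f"{_key_name(subj, sess)}_timeseries.tsv")
        if cols != manifest["roi_names"]:
            raise ValueError(f"ROI header mismatch in cell ({subj}, {sess})")
        data[(subj, sess)] = series
    return RoiTimeSeriesPanel(data=data, roi_names=manifest["roi_names"],
                              tr=manifest["tr"],
                              meta=pd.DataFrame(manifest["subjects"]))


def write_stack(stack: ConnectomeStack, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (subj, sess), mat in stack.matrices.items():
        pd.DataFrame(mat, index=stack.roi_names, columns=stack.roi_names).to_csv(
            out / f"{_key_name(subj, sess)}_zmatrix.tsv", sep="\t",
            float_format="%.17g")
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": "connectome_stack",
        "roi_names": list(stack.roi_names),
        "edge_order": [list(e) for e in stack.edge_names],
        "cells": [list(k) for k in stack.keys()],
        "subjects": stack.meta.to_dict(orient="list"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def read_stack(in_dir) -> ConnectomeStack:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    roi = manifest["roi_names"]
    matrices = {}
    for subj, sess in manifest["cells"]:
        df = pd.read_csv(src / f"{_key_name(subj, sess)}_zmatrix.tsv",
                         sep="\t", index_col=0, float_precision="round_trip")
        if list(df.columns) != roi:
            raise ValueError(f"ROI header mismatch in cell ({subj}, {sess})")
        matrices[(subj, sess)] = df.to_numpy(dtype=float)
    return ConnectomeStack(matrices=matrices, roi_names=roi,
                           meta=pd.DataFrame(manifest["subjects"]))


def write_behavior(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g", na_rep="NA")


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


def nbs_result_to_dict(result: NbsResult, roi_names) -> dict:
    edges = edge_index_map(roi_names)
    return {
        "direction": result.direction,
        "t_thresh": result.t_thresh,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "components": [c.named(roi_names, edges) for c in result.components],
        "edge_stats": [round(float(v), 12) for v in result.edge_stats],
        "null_summary": {
            "max": float(np.max(result.null_max_strength)),
            "mean": float(np.mean(result.null_max_strength)),
            "q95": float(np.quantile(result.null_max_strength, 0.95)),
        },
    }


def nbs_result_from_dict(d: dict, roi_names) -> NbsResult:
    comps = [NetworkComponent(
        nodes=tuple(roi_names.index(nm) for nm in c["nodes"]),
        edges=tuple(c["edge_ids"]), strength=c["strength"], p_fwe=c["p_fwe"])
        for c in d["components"]]
    return NbsResult(components=comps,
                     edge_stats=np.asarray(d["edge_stats"], dtype=float),
                     null_max_strength=np.empty(0), t_thresh=d["t_thresh"],
                     direction=d["direction"], n_perm=d["n_perm"],
                     seed=d["seed"])


# ---------------------------------------------------------------------------
# optional NIfTI support

def write_nifti(path, array: np.ndarray, affine: np.ndarray | None = None) -> None:
    import nibabel as nib
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def read_nifti(path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).get_fdata())


# ---------------------------------------------------------------------------
# pipeline driver

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end configuration mirroring the study's analysis choices."""

    roi_names: list[str] = dataclasses.field(default_factory=lambda: list(ROI_16))
    t_thresh: float = 1.7
    alpha_edge: float = 0.05
    fdr_q: float = 0.05
    n_perm: int = 5000
    seed: int = 0
    band: tuple[float, float] = (0.01, 0.1)
    tr: float = 2.0
    behavior_covariate: str = "huddling_latency"
    stack_dir: str | None = None
    behavior_path: str | None = None

    def __post_init__(self):
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI names must be unique")
        if min(self.t_thresh, self.alpha_edge, self.fdr_q) <= 0:
            raise ValueError("thresholds must be positive")
        low, high = self.band
        if not (0 <= low < high < 1.0 / (2.0 * self.tr)):
            raise ValueError("band must lie inside (0, Nyquist)")


def _hash_config(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, mode: str = "simulate",
                 out_dir=None) -> dict:
    """Run simulate -> preprocess -> connectome -> NBS-GLM -> NBS-LMM ->
    behavior and return (and optionally write) a machine-readable summary.

    ``mode="simulate"`` generates a synthetic cohort under the configured
    ROI set; ``mode="analyze"`` reads a connectome stack and behavior table
    from ``config.stack_dir`` / ``config.behavior_path``.
    """
    stage = "setup"
    summary = {
        "config": dataclasses.asdict(config),
        "input_hash": _hash_config(config),
        "seed": config.seed,
        "n_edges": n_edges(len(config.roi_names)),
        "edge_ids": list(range(n_edges(len(config.roi_names)))),
    }
    try:
        if mode == "simulate":
            stage = "simulate"
            syn = SyntheticConfig(n_rois=len(config.roi_names),
                                  roi_names=list(config.roi_names),
                                  tr=config.tr, seed=config.seed)
            panel, behavior, _ = generate_cohort(syn)
            stage = "preprocess"
            for key in list(panel.data):
                panel.data[key] = bandpass(panel.data[key], tr=config.tr,
                                           low=config.band[0], high=config.band[1])
            stage = "connectome"
            stack = build_connectome_stack(panel)
        elif mode == "analyze":
            stage = "load"
            if config.stack_dir is None or config.behavior_path is None:
                raise ValueError("analyze mode needs stack_dir and behavior_path")
            stack = read_stack(config.stack_dir)
            behavior = read_behavior(config.behavior_path)
        else:
            raise ValueError(f"unknown mode {mode!r}")

        stage = "nbs-glm"
        baseline, subjects = stack.session_edge_matrix(1)
        bsel = behavior.set_index("subject").loc[subjects]
        covariate = bsel[config.behavior_covariate].to_numpy(dtype=float)
        glm = NBSGLM(t_thresh=config.t_thresh, n_perm=config.n_perm,
                     seed=config.seed).fit(baseline, covariate)
        summary["nbs_glm"] = {
            d: nbs_result_to_dict(res, stack.roi_names)
            for d, res in glm.results_.items()}

        stage = "nbs-lmm"
        lmm = NBSLMM(alpha_edge=config.alpha_edge, n_perm=config.n_perm,
                     terms=("sex", "session"), seed=config.seed,
                     fdr_q=config.fdr_q).fit(stack.edge_long_table())
        summary["nbr_lmm"] = {
            term: nbs_result_to_dict(res, stack.roi_names)
            for term, res in lmm.results_.items()}
        posthoc = lmm.posthoc("session")
        summary["posthoc_rows"] = (posthoc.drop(columns=["component_nodes"])
                                   .to_dict(orient="records")
                                   if len(posthoc) else [])

        stage = "behavior"
        summary["behavior"] = beh.behavior_summary(behavior)
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        if out_dir is not None:
            _write_summary(summary, out_dir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        _write_summary(summary, out_dir)
    return summary


def _write_summary(summary: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    return path
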