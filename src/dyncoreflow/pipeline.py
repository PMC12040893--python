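"""End-to-end orchestration: simulate -> graphs -> kcore -> flow -> report.

One serialisable RunConfig drives all stages; every stage writes plain-text
tables into the output directory and the run manifest records the config,
input checksums, package versions, and per-stage status, so a run can be
reproduced bit-identically (flow values to the solver tolerance) from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flow import flow_timecourse
from .kcore import (composition_table, compute_coreness_timecourse,
                    detect_state_transitions)
from .reporting import (DisplayNormalization, figure_to_array, glass_brain,
                        render_animation, stacked_histogram, timepoint_plot)
from .synthetic import (SyntheticConfig, VoxelTimeSeries,
                        generate_voxel_timeseries, lattice_coords)
from .windows import WindowSpec, build_windowed_graphs, diagnostics_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "ConfigError"]

STAGES = ("simulate", "build-graphs", "kcore", "flow", "report")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    # input: either a synthetic config or paths to a series + labels
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    timeseries_path: str | None = None
    labels_path: str | None = None
    tr_seconds: float = 0.72

    window: WindowSpec = field(default_factory=WindowSpec)
    theta_pos: float = 0.65
    theta_neg: float = 0.50

    tau: float = 0.2
    min_run: int = 5

    length_transform: str = "one-minus-r"
    length_eps: float = 0.05
    flow_tol: float = 1e-8
    flow_stride: int = 1        # solve flow every k-th window
    channels: tuple[str, ...] = ("positive", "negative")

    animate: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.timeseries_path:
                raise ConfigError("either a synthetic config or timeseries_path is required")
            if not Path(self.timeseries_path).exists():
                raise ConfigError(f"timeseries_path {self.timeseries_path!r} does not exist")
            if self.labels_path and not Path(self.labels_path).exists():
                raise ConfigError(f"labels_path {self.labels_path!r} does not exist")
        if self.flow_stride < 1:
            raise ConfigError("flow_stride must be >= 1")
        for ch in self.channels:
            if ch not in ("positive", "negative"):
                raise ConfigError(f"unknown channel {ch!r}")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["ic_spec"] = [list(x) for x in self.synthetic.ic_spec]
            d["synthetic"]["state_boundaries"] = list(self.synthetic.state_boundaries)
            d["synthetic"]["state_coupling"] = [dict(m) for m in self.synthetic.state_coupling]
        d["window"] = dataclasses.asdict(self.window)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            syn["ic_spec"] = tuple((str(n), int(c)) for n, c in syn.get("ic_spec", []))
            syn["state_boundaries"] = tuple(int(b) for b in syn.get("state_boundaries", ()))
            syn["state_coupling"] = tuple(dict(m) for m in syn.get("state_coupling", ()))
            d["synthetic"] = SyntheticConfig(**syn)
        if "window" in d and d["window"] is not None:
            d["window"] = WindowSpec(**d["window"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError as exc:
            raise ConfigError(str(exc)) from exc
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input(cfg: RunConfig) -> tuple[VoxelTimeSeries, np.ndarray]:
    if cfg.synthetic is not None:
        ts, truth = generate_voxel_timeseries(cfg.synthetic)
        return ts, truth.ic_labels
    path = Path(cfg.timeseries_path)
    if path.suffix in (".nii", ".gz"):
        ts = VoxelTimeSeries.from_nifti(path, tr_seconds=cfg.tr_seconds)
    else:
        ts = VoxelTimeSeries.from_tsv(path, tr_seconds=cfg.tr_seconds)
    if cfg.labels_path:
        labels = pd.read_csv(cfg.labels_path, sep="\t")["ic_name"].to_numpy(dtype=object)
    else:
        labels = np.full(ts.n_voxels, "unclassified", dtype=object)
    return ts, labels


def run_all(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages, write tables/figures, and return the manifest.

    Per-window computations are independent (results do not depend on
    evaluation order); stage failures are recorded in the manifest and
    re-raised by the CLI as a partial-completion exit.
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": cfg.to_dict(),
        "versions": {"dyncoreflow": __version__, "numpy": np.__version__},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str, **extra: Any) -> None:
        manifest["stages"][stage] = {"status": status, **extra}

    # -- simulate / load ----------------------------------------------------
    ts, labels = _load_input(cfg)
    ts.to_tsv(out / "timeseries.tsv")
    pd.DataFrame({
        "voxel_id": np.arange(ts.n_voxels),
        "x": ts.coords[:, 0], "y": ts.coords[:, 1], "z": ts.coords[:, 2],
        "ic_name": labels,
    }).to_csv(out / "ic_labels.tsv", sep="\t", index=False)
    record("simulate", "completed", n_voxels=ts.n_voxels, n_frames=ts.n_frames)

    # -- graphs -------------------------------------------------------------
    graphset = build_windowed_graphs(ts, cfg.window, cfg.theta_pos, cfg.theta_neg)
    for ch in cfg.channels:
        graphset.edge_table(ch).to_csv(out / f"edges_{ch}.tsv", sep="\t", index=False)
        diagnostics_table(graphset, ch).to_csv(out / f"diagnostics_{ch}.csv", index=False)
    record("build-graphs", "completed", n_windows=graphset.n_windows)

    # -- kcore --------------------------------------------------------------
    segmentations = {}
    timecourses = {}
    for ch in cfg.channels:
        tc = compute_coreness_timecourse(graphset, ch)
        timecourses[ch] = tc
        tc.to_frame().to_csv(out / f"coreness_{ch}.tsv", sep="\t", index=False)
        seg = detect_state_transitions(tc.kmax_sets, cfg.tau, cfg.min_run)
        segmentations[ch] = seg
        comp = composition_table(tc.kmax_sets, labels)
        comp.to_csv(out / f"kmaxcore_composition_{ch}.csv")
        ratio = tc.coreness_edge_ratio()
        (out / f"segmentation_{ch}.json").write_text(json.dumps({
            "transitions": [int(t) for t in seg.transitions],
            "segments": [[int(a), int(b)] for a, b in seg.segments],
            "n_empty_windows": int(seg.empty_windows.sum()),
            "tau": seg.tau, "min_run": seg.min_run,
            # report-only analogues of full-scale observations
            "coreness_edge_ratio_mean": None if np.isnan(ratio).all()
            else float(np.nanmean(ratio)),
            "coreness_edge_ratio_sd": None if np.isnan(ratio).all()
            else float(np.nanstd(ratio)),
        }, indent=1))
    record("kcore", "completed",
           transitions={ch: len(s.transitions) for ch, s in segmentations.items()})

    # -- flow ---------------------------------------------------------------
    flow_results = {}
    for ch in cfg.channels:
        idx = list(range(0, graphset.n_windows, cfg.flow_stride))
        res = flow_timecourse(graphset, ch, eps=cfg.length_eps, tol=cfg.flow_tol,
                              length_transform=cfg.length_transform,
                              window_indices=idx)
        flow_results[ch] = res
        rows = []
        caps = []
        for w, fr in res.items():
            rows.append({"window_id": w,
                         "volume_entropy": np.nan if fr is None else fr.h,
                         "solved": fr is not None})
            if fr is not None:
                a = fr.node_capacity(ts.n_voxels, "afferent")
                f = fr.node_capacity(ts.n_voxels, "efferent")
                caps.append(pd.DataFrame({
                    "window_id": w, "voxel_id": np.arange(ts.n_voxels),
                    "afferent": a, "efferent": f,
                }))
        pd.DataFrame(rows).to_csv(out / f"volume_entropy_{ch}.csv", index=False)
        cap_df = (pd.concat(caps, ignore_index=True) if caps else
                  pd.DataFrame(columns=["window_id", "voxel_id", "afferent", "efferent"]))
        cap_df.to_csv(out / f"capacities_{ch}.tsv", sep="\t", index=False)
    record("flow", "completed",
           solved={ch: sum(v is not None for v in r.values())
                   for ch, r in flow_results.items()})

    # -- report -------------------------------------------------------------
    import matplotlib.pyplot as plt

    for ch in cfg.channels:
        tc = timecourses[ch]
        comp = composition_table(tc.kmax_sets, labels)
        _, fig = stacked_histogram(comp)
        fig.savefig(out / f"stacked_histogram_{ch}.png", dpi=100)
        plt.close(fig)
        tidy, fig = timepoint_plot(tc.edge_scaled, labels, mode="kcore_edge_scaled")
        tidy.to_csv(out / f"timepoints_kcore_{ch}.tsv", sep="\t", index=False)
        fig.savefig(out / f"timepoints_kcore_{ch}.png", dpi=100)
        plt.close(fig)

        solved = [w for w, fr in flow_results[ch].items() if fr is not None]
        if solved:
            aff = np.full((len(solved), ts.n_voxels), np.nan)
            eff = np.full((len(solved), ts.n_voxels), np.nan)
            for i, w in enumerate(solved):
                fr = flow_results[ch][w]
                aff[i] = fr.node_capacity(ts.n_voxels, "afferent")
                eff[i] = fr.node_capacity(ts.n_voxels, "efferent")
            norm = DisplayNormalization.fit(aff, eff)
            tidy, fig = timepoint_plot(norm.scale(aff), labels, mode="afferent")
            tidy.to_csv(out / f"timepoints_afferent_{ch}.tsv", sep="\t", index=False)
            fig.savefig(out / f"timepoints_afferent_{ch}.png", dpi=100)
            plt.close(fig)
            # report-only analogue of the full-scale module-height contrast
            (out / f"capacity_summary_{ch}.json").write_text(json.dumps({
                "max_afferent": float(np.nanmax(aff)),
                "max_efferent": float(np.nanmax(eff)),
                "display_max": norm.max_value,
            }, indent=1))

        if cfg.animate:
            frames = []
            for s in tc.kmax_sets[: min(40, len(tc.kmax_sets))]:
                vals = np.zeros(ts.n_voxels)
                if len(s):
                    vals[s] = 1.0
                _, fig = glass_brain(vals, ts.coords)
                frames.append(figure_to_array(fig))
                plt.close(fig)
            render_animation(frames, out / f"kmaxcore_{ch}.gif")
    record("report", "completed")

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
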