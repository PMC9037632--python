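"""End-to-end ensemble analysis: pairing -> frames -> steps -> grooves ->
bending/kink/theta -> loop states -> clustering -> tables/histograms.

The per-model bending series in the report is the analogue of following
the bending angle along a trajectory; all randomness (k-means) flows from
the single seed in :class:`AnalysisConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from . import bending as bd
from . import grooves as gr
from . import hbonds as hb
from . import stats as st
from .frames import duplex_pair_frames, infer_pairing, step_parameters
from .io import Conformation, Ensemble, read_pdb

__all__ = ["AnalysisConfig", "Report", "analyze_ensemble", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants; defaults follow the printed conventions
    (five terminal pairs excluded, 12 A collapse threshold, k in 8..20)."""

    exclude_terminal: int = 5
    collapse_threshold: float = 12.0
    k: int | None = None
    k_range: tuple[int, int] = (8, 20)
    seed: int = 0
    smoothing_window: int = 5
    hbond: hb.HBondCriteria = field(default_factory=hb.HBondCriteria)
    hist_bins: int = 24

    def as_dict(self) -> dict:
        return {
            "exclude_terminal": self.exclude_terminal,
            "collapse_threshold": self.collapse_threshold,
            "k": self.k,
            "k_range": list(self.k_range),
            "seed": self.seed,
            "smoothing_window": self.smoothing_window,
            "hbond_max_distance": self.hbond.max_distance,
            "hbond_min_donor_angle": self.hbond.min_donor_angle,
            "hist_bins": self.hist_bins,
        }


@dataclass
class Report:
    config: dict
    n_models: int
    n_pairs: int
    bending: pd.DataFrame
    steps: pd.DataFrame
    grooves: pd.DataFrame
    theta: pd.DataFrame
    loops: pd.DataFrame | None
    loop_state_populations: dict[str, float]
    cluster: st.ClusterResult
    bending_table: st.BendingTable
    histograms: dict[str, st.Histogram2D]

    # -- serialization -----------------------------------------------------
    def summary(self) -> dict:
        return {
            "config": self.config,
            "n_models": self.n_models,
            "n_pairs": self.n_pairs,
            "bending_series": [round(v, 6) for v in self.bending["bending_angle"]],
            "bending_categories": list(self.bending["category"]),
            "collapse_counts": [int(v) for v in self.bending["collapse_count"]],
            "kink_detected": [bool(v) for v in self.bending["kink_detected"]],
            "cluster_k": int(self.cluster.k),
            "cluster_populations": [round(float(p), 6) for p in self.cluster.populations],
            "bending_table": {
                "bins": list(self.bending_table.bins),
                "percent": [round(float(p), 6) for p in self.bending_table.percent],
                "average_angle": round(float(self.bending_table.average_angle), 6),
            },
            "loop_state_populations": {
                k: round(v, 6) for k, v in sorted(self.loop_state_populations.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=1, sort_keys=True)

    def write(self, outdir: str | PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.bending.to_csv(out / "bending.csv", index=False, float_format="%.6f")
        self.steps.to_csv(out / "steps.csv", index=False, float_format="%.6f")
        self.grooves.to_csv(out / "grooves.csv", index=False, float_format="%.6f")
        self.theta.to_csv(out / "theta.csv", index=False, float_format="%.6f")
        if self.loops is not None:
            self.loops.to_csv(out / "loops.csv", index=False)
        pd.DataFrame(
            {"model": np.arange(1, self.n_models + 1), "label": self.cluster.labels}
        ).to_csv(out / "clusters.csv", index=False)
        pd.DataFrame(
            {"bin": self.bending_table.bins, "percent": self.bending_table.percent}
        ).to_csv(out / "bending_table.csv", index=False, float_format="%.6f")
        for name, h in self.histograms.items():
            np.savetxt(out / f"hist_{name}.csv", h.density, delimiter=",", fmt="%.8g")
            meta = {
                "x_label": h.x_label,
                "y_label": h.y_label,
                "x_edges": [round(float(v), 6) for v in h.x_edges],
                "y_edges": [round(float(v), 6) for v in h.y_edges],
            }
            (out / f"hist_{name}.json").write_text(json.dumps(meta, sort_keys=True))
        (out / "report.json").write_text(self.to_json())


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _loop_signature(state: hb.LoopState) -> str:
    counts = "/".join(str(s.count) for s in state.pair_states)
    closing = "".join("D" if c.distorted else "-" for c in state.closing)
    return f"{counts}|{closing}"


def analyze_ensemble(
    source: Ensemble | Conformation | str | PathLike,
    cfg: AnalysisConfig | None = None,
) -> Report:
    """Run the full geometric analysis of a duplex ensemble."""
    cfg = cfg or AnalysisConfig()
    if isinstance(source, (str, PathLike)):
        ensemble = read_pdb(source)
    elif isinstance(source, Conformation):
        ensemble = Ensemble([source])
    else:
        ensemble = source
    pm = infer_pairing(ensemble[0])
    n = pm.n_pairs

    bending_rows, step_rows, groove_rows, theta_rows, loop_rows = [], [], [], [], []
    per_model_profiles: list[gr.GrooveProfile] = []
    per_model_theta: list[np.ndarray] = []
    per_model_steps: list[np.ndarray] = []
    has_loops = bool(pm.internal_loops())

    for im, model in enumerate(ensemble, start=1):
        frames, flipped = _stage("frames")(duplex_pair_frames)(model, pm)
        params = np.full((n - 1, 6), np.nan)
        for s in range(n - 1):
            if flipped[s] or flipped[s + 1]:
                continue
            p = _stage("steps")(step_parameters)(frames[s], frames[s + 1])
            params[s] = p.as_tuple()
            step_rows.append(
                {"model": im, "step_index": s + 1, "tilt": p.tilt, "roll": p.roll,
                 "twist": p.twist, "shift": p.shift, "slide": p.slide, "rise": p.rise}
            )
        per_model_steps.append(params)

        profile = _stage("grooves")(gr.groove_widths)(model, pm)
        per_model_profiles.append(profile)
        collapse = gr.count_collapsed(profile, cfg.collapse_threshold)
        for s in range(profile.step_count):
            groove_rows.append(
                {"model": im, "step_index": s + 1, "Mgw": profile.Mgw[s],
                 "mgw": profile.mgw[s], "collapsed": bool(s + 1 in collapse.collapsed_indices)}
            )

        axis = _stage("axis")(bd.helical_axis)(frames, cfg.smoothing_window)
        bres = _stage("bending")(bd.bending_angle)(axis, cfg.exclude_terminal)
        restricted = axis.restrict(cfg.exclude_terminal)
        if len(restricted) >= 10:
            kres = _stage("kink")(bd.kink_angle)(restricted)
            kink_detected, kink_step, kink_ang = (
                kres.kink_detected,
                kres.kink_step + cfg.exclude_terminal,
                kres.kink_angle,
            )
        else:
            kink_detected, kink_step, kink_ang = False, -1, float("nan")
        tp = _stage("theta")(bd.theta_profile)(model, pm)
        per_model_theta.append(tp.theta)
        for s, th in enumerate(tp.theta, start=1):
            theta_rows.append({"model": im, "inner_step": s, "theta": th})
        bending_rows.append(
            {"model": im, "bending_angle": bres.bending_angle,
             "category": bres.category, "collapse_count": collapse.count,
             "kink_detected": kink_detected, "kink_step": kink_step,
             "kink_angle": kink_ang}
        )

        if has_loops:
            for state in _stage("loops")(hb.loop_states)(model, pm, cfg.hbond):
                loop_rows.append(
                    {"model": im, "loop_id": state.loop_id,
                     "signature": _loop_signature(state),
                     "pair_counts": "/".join(str(s.count) for s in state.pair_states),
                     "closing_distorted": sum(c.distorted for c in state.closing)}
                )

    loops_df = pd.DataFrame(loop_rows) if loop_rows else None
    loop_pops: dict[str, float] = {}
    if loops_df is not None and len(loops_df):
        counts = loops_df["signature"].value_counts()
        loop_pops = {k: 100.0 * v / len(loops_df) for k, v in counts.items()}

    # clustering and the bending table over cluster average structures
    n_models = len(ensemble)
    if cfg.k is not None:
        k = min(cfg.k, n_models)
    elif n_models < 3:
        k = 1
    else:
        k = _stage("cluster")(st.select_k)(ensemble, cfg.k_range, cfg.seed)
    cluster = _stage("cluster")(st.kmeans_cluster)(ensemble, k, cfg.seed)
    cluster_angles = []
    for cid in range(cluster.k):
        avg = _stage("average")(st.average_structure)(ensemble, cluster.labels, cid)
        frames, _ = duplex_pair_frames(avg, pm)
        axis = bd.helical_axis(frames, cfg.smoothing_window)
        cluster_angles.append(bd.bending_angle(axis, cfg.exclude_terminal).bending_angle)
    table = _stage("table")(st.bending_table)(cluster_angles, cluster.populations)

    # pooled 2D population distributions, paired per (model, step)
    mgw_steps, mgw_vals = [], []
    histograms: dict[str, st.Histogram2D] = {}
    Mgw_all = np.array([p.Mgw for p in per_model_profiles])  # (models, n-1)
    mgw_all = np.array([p.mgw for p in per_model_profiles])
    theta_all = np.array(per_model_theta)  # (models, n-2)
    steps_all = np.array(per_model_steps)  # (models, n-1, 6)
    pairs = {
        "Mgw_theta": (Mgw_all[:, : n - 2], theta_all, "Mgw", "theta"),
        "Mgw_mgw": (Mgw_all, mgw_all, "Mgw", "mgw"),
        "Mgw_twist": (Mgw_all, steps_all[:, :, 2], "Mgw", "twist"),
        "Mgw_slide": (Mgw_all, steps_all[:, :, 4], "Mgw", "slide"),
        "Mgw_shift": (Mgw_all, steps_all[:, :, 3], "Mgw", "shift"),
    }
    for name, (x, y, xl, yl) in pairs.items():
        try:
            histograms[name] = st.hist2d(
                x.ravel(), y.ravel(), bins=cfg.hist_bins, x_label=xl, y_label=yl
            )
        except ValueError:
            continue  # no overlapping defined values

    return Report(
        config=cfg.as_dict(),
        n_models=n_models,
        n_pairs=n,
        bending=pd.DataFrame(bending_rows),
        steps=pd.DataFrame(step_rows),
        grooves=pd.DataFrame(groove_rows),
        theta=pd.DataFrame(theta_rows),
        loops=loops_df,
        loop_state_populations=loop_pops,
        cluster=cluster,
        bending_table=table,
        histograms=histograms,
    )
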