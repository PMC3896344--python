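"""End-to-end orchestration: subsets, windows, comparisons, outputs.

``run_pipeline`` chains the full analysis for a set of spike trains: the
trains are partitioned into subsets by metadata (response type and
morphological type by default; comparisons are performed only within these
subsets), each trial is smoothed and decomposed over its stimulus-aligned
response window and the immediately preceding control window, corresponding
coefficients are compared between the requested condition pairs with the
two-tier FDR procedure, the PSTH baseline is run on the same trials, and
optionally the label-shuffle control.  All result tables are delimited
text; a JSON summary collects merged intervals and diagnostics.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .core import AnalysisWindow, SpikeTrain
from .io import write_comparison_table
from .psth import compare_psth, psth_marginal_tier
from .rates import rate_function
from .stats import (ComparisonResult, SignificanceConfig,
                    compare_coefficients, marginal_tier, shuffle_control,
                    significant_duration)
from .wavelet import DWTConfig, dwt_decompose


@dataclass(frozen=True)
class RunConfig:
    """All analysis constants of one run.

    The control window immediately precedes the response window and has
    the same duration.  ``comparisons`` lists (condition A, condition B)
    pairs; ``subset_keys`` names the metadata fields that partition the
    data into independently analyzed subsets.
    """

    duration_s: float = 1.4
    n_bins: int = 128
    levels: int = 4
    kernel: str = "db1"
    halfwidth_ms: float = 50.0
    grid_step_ms: float = 1.0
    psth_bin_ms: float = 50.0
    q_primary: float = 0.10
    q_marginal_max: float = 0.25
    q_grid_step: float = 0.01
    n_shuffles: int = 0
    seed: int = 0
    subset_keys: tuple[str, ...] = ("response_type", "morph_type")
    comparisons: tuple[tuple[str, str], ...] = ()

    def significance(self) -> SignificanceConfig:
        return SignificanceConfig(
            q_primary=self.q_primary, q_marginal_max=self.q_marginal_max,
            q_grid_step=self.q_grid_step,
            n_shuffles=max(self.n_shuffles, 1), seed=self.seed)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "subset_keys" in raw:
            raw["subset_keys"] = tuple(raw["subset_keys"])
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        return cls(**raw)


def trial_power_maps(trains: Sequence[SpikeTrain], cfg: RunConfig,
                     period: str = "response"):
    """Rate-smooth and DWT-decompose each trial over its stimulus-aligned
    window (``response`` or pre-stimulus ``control``)."""
    maps = []
    for tr in trains:
        if period == "response":
            win = AnalysisWindow.response(tr.stimulus_onset, cfg.duration_s, cfg.n_bins)
        elif period == "control":
            win = AnalysisWindow.control(tr.stimulus_onset, cfg.duration_s, cfg.n_bins)
        else:
            raise ValueError("period must be 'response' or 'control'")
        rf = rate_function(tr, win, cfg.halfwidth_ms, cfg.grid_step_ms)
        maps.append(dwt_decompose(rf.binned, DWTConfig(window=win, levels=cfg.levels,
                                                       kernel=cfg.kernel)))
    return maps


def compare_conditions(trains_a: Sequence[SpikeTrain],
                       trains_b: Sequence[SpikeTrain],
                       cfg: RunConfig,
                       label_a: str = "A", label_b: str = "B",
                       run_shuffles: bool = False) -> dict:
    """Response + control DWT comparison with marginal tiering, the PSTH
    baseline, and (optionally) the shuffle control, for one condition pair."""
    sig = cfg.significance()
    maps_a = trial_power_maps(trains_a, cfg, "response")
    maps_b = trial_power_maps(trains_b, cfg, "response")
    ctrl_a = trial_power_maps(trains_a, cfg, "control")
    ctrl_b = trial_power_maps(trains_b, cfg, "control")

    response = compare_coefficients(maps_a, maps_b, sig, label_a, label_b)
    control = compare_coefficients(ctrl_a, ctrl_b, sig, label_a, label_b)
    response = marginal_tier(response, control, sig)

    wins_a = [AnalysisWindow.response(t.stimulus_onset, cfg.duration_s, cfg.n_bins)
              for t in trains_a]
    wins_b = [AnalysisWindow.response(t.stimulus_onset, cfg.duration_s, cfg.n_bins)
              for t in trains_b]
    cwins_a = [AnalysisWindow.control(t.stimulus_onset, cfg.duration_s, cfg.n_bins)
               for t in trains_a]
    cwins_b = [AnalysisWindow.control(t.stimulus_onset, cfg.duration_s, cfg.n_bins)
               for t in trains_b]
    psth = compare_psth(trains_a, trains_b, wins_a, wins_b, sig,
                        cfg.psth_bin_ms, label_a, label_b)
    psth_ctrl = compare_psth(trains_a, trains_b, cwins_a, cwins_b, sig,
                             cfg.psth_bin_ms, label_a, label_b)
    psth = psth_marginal_tier(psth, psth_ctrl, sig)

    out = {
        "dwt": response, "dwt_control": control,
        "psth": psth, "psth_control": psth_ctrl,
        "shuffle_rejections": None,
    }
    if run_shuffles and cfg.n_shuffles > 0:
        out["shuffle_rejections"] = shuffle_control(maps_a, maps_b, sig)
    return out


def _subset_key(train: SpikeTrain, keys: Sequence[str]) -> tuple:
    return tuple(getattr(train, k) for k in keys)


def run_pipeline(trains: Sequence[SpikeTrain], cfg: RunConfig,
                 outdir=None, log=print) -> dict:
    """Run every configured comparison within every metadata subset.

    Subsets with fewer than 2 trials in either condition are skipped with a
    warning.  If ``outdir`` is given, per-comparison tables (wavelet and
    PSTH, response and control) and a JSON run summary are written there;
    the summary records config, seed and versions so control/shuffle
    diagnostics are auditable.  Returns {(subset, (A, B)): results}.
    """
    subsets: dict[tuple, list[SpikeTrain]] = {}
    for tr in trains:
        subsets.setdefault(_subset_key(tr, cfg.subset_keys), []).append(tr)

    comparisons = cfg.comparisons
    if not comparisons:
        conds = sorted({t.condition for t in trains})
        comparisons = tuple((a, b) for i, a in enumerate(conds)
                            for b in conds[i + 1:])

    results: dict = {}
    summary: dict = {"config": asdict(cfg), "package_version": __version__,
                     "python": platform.python_version(), "comparisons": []}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for key in sorted(subsets):
        by_cond: dict[str, list[SpikeTrain]] = {}
        for tr in subsets[key]:
            by_cond.setdefault(tr.condition, []).append(tr)
        for (cond_a, cond_b) in comparisons:
            ta, tb = by_cond.get(cond_a, []), by_cond.get(cond_b, [])
            name = "_".join(filter(None, ["-".join(map(str, key)).strip("-"),
                                          f"{cond_a}-vs-{cond_b}"]))
            if len(ta) < 2 or len(tb) < 2:
                log(f"skipping {name}: fewer than 2 trials per condition")
                continue
            res = compare_conditions(ta, tb, cfg, cond_a, cond_b,
                                     run_shuffles=cfg.n_shuffles > 0)
            results[(key, (cond_a, cond_b))] = res
            entry = {
                "subset": dict(zip(cfg.subset_keys, key)),
                "comparison": [cond_a, cond_b],
                "n_trials": [len(ta), len(tb)],
                "dwt_primary_intervals_ms": res["dwt"].intervals("significant"),
                "dwt_marginal_intervals_ms": res["dwt"].intervals("marginal"),
                "dwt_significant_duration_ms": significant_duration(res["dwt"]),
                "psth_primary_intervals_ms": res["psth"].intervals("significant"),
                "psth_significant_duration_ms": significant_duration(res["psth"].comparison),
                "control_clean": res["dwt"].control_clean,
                "control_primary_rejections": res["dwt_control"].n_primary,
                "shuffle_rejections": (None if res["shuffle_rejections"] is None
                                       else [int(c) for c in res["shuffle_rejections"]]),
            }
            summary["comparisons"].append(entry)
            if outdir is not None:
                write_comparison_table(res["dwt"], outdir / f"{name}_dwt.tsv", name)
                write_comparison_table(res["dwt_control"],
                                       outdir / f"{name}_dwt_control.tsv", name)
                write_comparison_table(res["psth"].comparison,
                                       outdir / f"{name}_psth.tsv", name)
                write_comparison_table(res["psth_control"].comparison,
                                       outdir / f"{name}_psth_control.tsv", name)
            log(f"{name}: DWT primary intervals {entry['dwt_primary_intervals_ms']}, "
                f"control clean: {entry['control_clean']}")

    if outdir is not None:
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    results["summary"] = summary
    return results
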