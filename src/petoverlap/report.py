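"""Wide-format report of the simulated example (one row per configuration and
metric, one column per segmentation combination, percent deviation from ground
truth in parentheses)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import run_case
from .metrics import OverlapReport, overlap_metrics
from .phantom import PhantomConfig, canonical_phantom, render
from .published import COLUMNS, CONFIGURATIONS
from .segment import roi_from_mask

__all__ = ["make_table1_report", "simulated_example_results"]

_METRICS = ("dice", "of", "x", "y")


def simulated_example_results(config: PhantomConfig | None = None,
                              noise_seed: int | None = None,
                              ) -> dict[str, dict[str, OverlapReport]]:
    """Run the full simulated example: three overlap configurations, all
    segmentation combinations, plus the ground-truth reference column."""
    results: dict[str, dict[str, OverlapReport]] = {}
    for cfg_name in CONFIGURATIONS:
        gt, cfg = canonical_phantom(cfg_name, config)
        pet1 = render(gt, cfg, "PET1", noise_seed=noise_seed)
        pet2 = render(gt, cfg, "PET2", noise_seed=noise_seed)
        rec = run_case(pet1, pet2,
                       roi_from_mask(gt.tumour_mask, 3), roi_from_mask(gt.v2_mask, 3),
                       gt=gt, case_id=cfg_name)
        column_reports = dict(rec.metric_grid)
        column_reports["GT"] = overlap_metrics(gt.v1_mask, gt.v2_mask,
                                               gt.grid.spacing, accuracy=None)
        results[cfg_name] = column_reports
    return results


def _cell(value: float, gt_value: float) -> str:
    if gt_value > 0:
        dev = int(round(100.0 * (value - gt_value) / gt_value))
        return f"{value:.3f} ({dev:+d}%)"
    return f"{value:.3f}"


def make_table1_report(results: dict[str, dict[str, OverlapReport]]) -> pd.DataFrame:
    """Format per-configuration overlap reports as the wide simulation table.

    ``results`` maps configuration name -> column code -> OverlapReport and
    must contain a "GT" column plus every threshold combination and "FLAB".
    The accuracy row shows "N/A" for the ground-truth column and is blank where
    the ground-truth overlap is empty.
    """
    rows = {}
    for cfg_name, cols in results.items():
        missing = [c for c in COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"configuration {cfg_name!r} lacks columns {missing}")
        gt_rep = cols["GT"]
        for metric in _METRICS:
            gt_val = getattr(gt_rep, metric)
            rows[(cfg_name, metric.upper() if metric != "dice" else "Dice")] = {
                col: (f"{gt_val:.3f}" if col == "GT"
                      else _cell(getattr(cols[col], metric), gt_val))
                for col in COLUMNS
            }
        acc_row = {}
        for col in COLUMNS:
            if col == "GT":
                acc_row[col] = "N/A"
            else:
                acc = cols[col].accuracy
                acc_row[col] = "" if acc is None or np.isnan(acc) else f"{acc:.3f}"
        rows[(cfg_name, "Acc")] = acc_row
    frame = pd.DataFrame.from_dict(rows, orient="index")[COLUMNS]
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["configuration", "metric"])
    return frame
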