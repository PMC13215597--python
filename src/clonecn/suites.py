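"""Standard simulation benchmark suites.

Two reduced sweeps cover the headline performance checks: integer-CN error /
clone recovery on mid-sized cohorts, and broad-event sensitivity / breakpoint
localization on a small condition grid.  Problem sizes are chosen so each
suite completes in minutes on one CPU; the simulated genome spans 6 autosomes
(~818 Mb) at realistic peak density (~10 peaks/Mb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clonecn.pipeline import RunConfig, _combine, evaluate_run, run
from clonecn.simulate import SimConfig, simulate_dataset

#: min_peaks scaled pro rata to the 6-of-22-autosome simulated genome
MIN_PEAKS_SCALED = 2700

_PREVALENCES = {
    1: (1.0,),
    2: (0.7, 0.3),
    3: (0.5, 0.3, 0.2),
}
_PREVALENCES_RARE = {
    1: (1.0,),
    2: (0.9, 0.1),
    3: (0.45, 0.45, 0.1),
}


def _child_seed(base: int, i: int) -> int:
    return int((base + 104_729 * (i + 1)) % (2**31 - 1))


def cn_error_suite(seed: int = 0, n_datasets: int = 10) -> list[SimConfig]:
    """Mid-sized cohorts for integer-CN error and clone recovery:
    500-1000 cells, 1-3 clones, CNV genome fraction 20-40%, events >= 10 Mb."""
    configs = []
    for i in range(n_datasets):
        configs.append(
            SimConfig(
                n_cells=(500, 1000)[i % 2],
                n_ref_cells=200,
                clone_prevalences=_PREVALENCES[1 + i % 3],
                cnv_genome_frac=(0.2, 0.3, 0.4)[(i // 2) % 3],
                min_event_mb=10.0,
                seed=_child_seed(seed, i),
            )
        )
    return configs


def broad_event_suite(seed: int = 0) -> list[SimConfig]:
    """Condition grid for broad-event sensitivity and breakpoint accuracy:
    cells {200, 1000} x 1-3 clones (10% rare clone) x CNV fractions
    {0.1, 0.3, 0.6}, planted events >= 20 Mb."""
    configs = []
    i = 1000
    for n_cells in (200, 1000):
        for k in (1, 2, 3):
            for frac in (0.1, 0.3, 0.6):
                configs.append(
                    SimConfig(
                        n_cells=n_cells,
                        n_ref_cells=150,
                        clone_prevalences=_PREVALENCES_RARE[k],
                        cnv_genome_frac=frac,
                        min_event_mb=20.0,
                        seed=_child_seed(seed, i),
                    )
                )
                i += 1
    return configs


def run_suite(configs: list[SimConfig], seed: int = 0) -> pd.DataFrame:
    """Simulate, infer and score every config; one row per dataset."""
    rows = []
    for i, cfg in enumerate(configs):
        ref, inf, truth = simulate_dataset(cfg)
        counts, ann = _combine(ref, inf)
        rc = RunConfig(seed=_child_seed(seed, 5000 + i), min_peaks=MIN_PEAKS_SCALED)
        result = run(counts, ann, rc)
        rep = evaluate_run(truth, result)
        row = rep.to_dict()
        row.update(
            n_cells=cfg.n_cells,
            n_clones_planted=len(cfg.clone_prevalences),
            cnv_frac=cfg.cnv_genome_frac,
            n_breakpoints=len(rep.breakpoint_deviations),
            sim_seed=cfg.seed,
        )
        row["_deviations"] = rep.breakpoint_deviations
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(cn_table: pd.DataFrame, broad_table: pd.DataFrame) -> dict:
    """Headline numbers from the two suites."""
    multi = cn_table[cn_table["n_clones_planted"] >= 2]
    all_devs = [d for devs in broad_table["_deviations"] for d in devs]
    return {
        "max_cn_rmse": float(cn_table["rmse"].max()),
        "mean_bacc": float(multi["bacc_weighted"].mean()),
        "mean_broad_sensitivity": float(broad_table["broad_sensitivity"].mean()),
        "mean_breakpoint_deviation_mb": float(np.mean(all_devs)),
        "n_cn_datasets": int(len(cn_table)),
        "n_bacc_datasets": int(len(multi)),
        "n_broad_events": int(broad_table["n_broad_events"].sum()),
        "n_breakpoints": int(len(all_devs)),
    }
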