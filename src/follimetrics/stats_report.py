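"""Statistical comparisons and the end-to-end pipeline driver.

Group comparisons mirror the measurements' reporting conventions: two-sided
Welch's unequal-variances t-test for scalar quantities, the two-sample
Kolmogorov–Smirnov test for orientation distributions, and two-sided paired
t-tests for within-organ regional contrasts.  No multiple-testing
correction is applied; p-values are reported raw with group sizes, and
dispersion in reports is s.e.m.

``run_pipeline`` executes the synthesis → surface → segmentation →
measurement chain from a config mapping and writes per-cell CSV,
per-follicle JSON, comparison tables, and a reproducibility log (package
version, seeds, config hash).  Identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cellmetrics import measure_cells, orientation_distribution
from .lattice import build_lattice, neighbor_stats, segment_cells
from .organmetrics import DEFAULT_STAGES, organ_metrics
from .synthgen import SynthParams, make_epithelium

__all__ = [
    "ComparisonResult",
    "welch_t",
    "ks_2sample",
    "paired_t",
    "run_pipeline",
    "demo_config",
]


@dataclass
class ComparisonResult:
    test: str            # welch_t | ks_2sample | paired_t
    statistic: float
    pvalue: float        # two-sided
    n_a: int
    n_b: int
    effect: float        # mean difference (t-tests) or KS D

    def __post_init__(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _clean(x, name, n_min):
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < n_min:
        raise ValueError(f"{name} needs >= {n_min} finite values (got {len(x)})")
    return x


def welch_t(sample_a, sample_b) -> ComparisonResult:
    """Two-sided Welch's unequal-variances t-test (Satterthwaite dof)."""
    a = _clean(sample_a, "sample_a", 2)
    b = _clean(sample_b, "sample_b", 2)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return ComparisonResult("welch_t", 0.0, 1.0, len(a), len(b),
                                    float(a.mean() - b.mean()))
        raise ValueError("degenerate variance: both samples are constant")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        test="welch_t",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        effect=float(a.mean() - b.mean()),
    )


def ks_2sample(sample_a, sample_b) -> ComparisonResult:
    """Two-sample Kolmogorov–Smirnov test, asymptotic two-sided p."""
    a = _clean(sample_a, "sample_a", 5)
    b = _clean(sample_b, "sample_b", 5)
    res = stats.ks_2samp(a, b, method="asymp")
    return ComparisonResult(
        test="ks_2sample",
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n_a=len(a),
        n_b=len(b),
        effect=float(res.statistic),
    )


def paired_t(sample_a, sample_b) -> ComparisonResult:
    """Two-sided paired-sample t-test (one-sample t on differences)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return ComparisonResult("paired_t", 0.0, 1.0, len(a), len(b), 0.0)
        raise ValueError("degenerate: differences have zero variance")
    res = stats.ttest_rel(a, b)
    return ComparisonResult(
        test="paired_t",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        effect=float(d.mean()),
    )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def demo_config(seed: int = 0, n_cells: int = 150) -> dict:
    """Built-in two-cohort demo: isotropic vs meridionally biased cells."""
    return {
        "seed": seed,
        "synthesis": {
            "cohorts": [
                {
                    "name": "isotropic",
                    "n_follicles": 1,
                    "params": {
                        "semi_axis_ap": 10.0, "semi_axis_eq": 10.0,
                        "n_cells": n_cells, "target_eccentricity": 0.55,
                        "orientation_bias": "uniform", "concentration": 0.0,
                    },
                },
                {
                    "name": "meridional",
                    "n_follicles": 1,
                    "params": {
                        "semi_axis_ap": 10.0, "semi_axis_eq": 10.0,
                        "n_cells": n_cells, "target_eccentricity": 0.55,
                        "orientation_bias": "meridional", "concentration": 8.0,
                    },
                },
            ]
        },
        "lattice": {"min_cell_area": 3.0},
        "pixel_size": 0.25,
    }


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Execute the synthesis + measurement pipeline described by ``config``.

    Writes, under ``out_dir``: ``cells.csv`` (one row per cell across all
    follicles), ``follicles.json`` (per-follicle organ metrics),
    ``comparisons.csv`` (pairwise cohort tests), and ``run_log.json``.
    Returns the report bundle as a dict.  Any stage failure raises with the
    cohort/follicle identity attached.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    pixel_size = float(config.get("pixel_size", 0.2))
    min_area = float(config.get("lattice", {}).get("min_cell_area", 3.0))
    cohorts = config.get("synthesis", {}).get("cohorts", [])
    if not cohorts:
        raise ValueError("config.synthesis.cohorts is empty")

    cell_tables = []
    follicle_rows = []
    orientations = {}
    for ci, cohort in enumerate(cohorts):
        name = cohort.get("name", f"cohort{ci}")
        for fi in range(int(cohort.get("n_follicles", 1))):
            try:
                params = SynthParams(seed=seed + 1000 * ci + fi,
                                     **cohort.get("params", {}))
                epi = make_epithelium(params, pixel_size=pixel_size)
                seg = segment_cells(epi.pullback, min_cell_area=min_area,
                                    expected_cells=params.n_cells)
                lat = build_lattice(seg)
                _, topo = neighbor_stats(lat)
                cells = measure_cells(seg, epi.pullback, epi.param, lattice=lat)
                om = organ_metrics(epi.param, cells,
                                   hexagon_fraction=topo["hexagon_fraction"])
            except Exception as err:
                raise RuntimeError(
                    f"pipeline stage failed for cohort {name!r} follicle {fi}: {err}"
                ) from err
            cells.insert(0, "follicle", fi)
            cells.insert(0, "cohort", name)
            cell_tables.append(cells)
            row = om.as_dict()
            row.update({"cohort": name, "follicle": fi})
            follicle_rows.append(row)
            ori = cells["orientation_deg"].to_numpy()
            orientations.setdefault(name, []).append(ori[np.isfinite(ori)])

    all_cells = pd.concat(cell_tables, ignore_index=True)
    comparisons = []
    names = list(orientations)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.concatenate(orientations[names[i]])
            b = np.concatenate(orientations[names[j]])
            r = ks_2sample(a, b)
            comparisons.append({
                "quantity": "orientation_deg", "cohort_a": names[i],
                "cohort_b": names[j], **r.as_dict(),
            })
            ea = all_cells.loc[all_cells.cohort == names[i], "eccentricity"].dropna()
            eb = all_cells.loc[all_cells.cohort == names[j], "eccentricity"].dropna()
            w = welch_t(ea, eb)
            comparisons.append({
                "quantity": "eccentricity", "cohort_a": names[i],
                "cohort_b": names[j], **w.as_dict(),
            })
    comp_df = pd.DataFrame(comparisons)

    all_cells.to_csv(out / "cells.csv", index=False, float_format="%.6g")
    comp_df.to_csv(out / "comparisons.csv", index=False, float_format="%.6g")
    with open(out / "follicles.json", "w") as fh:
        json.dump(follicle_rows, fh, indent=2, sort_keys=True, default=float)
    log = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_follicles": len(follicle_rows),
        "n_cells_total": int(len(all_cells)),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {
        "cells": all_cells,
        "follicles": follicle_rows,
        "comparisons": comp_df,
        "log": log,
    }
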