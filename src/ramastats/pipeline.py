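"""End-to-end orchestration: simulate -> bins -> densities -> topology -> inertia.

Two entry modes:

* **data mode** — dihedral observations (a TSV or the synthetic generator)
  are carried through bin-width optimisation, density estimation, the
  distance topology and the inertia/correlation analyses;
* **table-only mode** — no dihedral data at all: the built-in published
  per-residue statistics feed the common-grid rule, the inertia table and
  every correlation, bit-stably and with no random number generation.

``run_pipeline`` writes each stage's interface files under the output
directory and returns the machine-readable report as a dict.
"""

from __future__ import annotations

import json
import logging
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import reference
from .binning import common_grid, sweep_table
from .distance import pair_match_probability
from .inertia import (
    build_table,
    helix_former_partition,
    pearson,
    read_substitution_matrix,
)
from .model import RamachandranModel
from .synthetic import default_profiles, generate_dataset, profiles_from_config

logger = logging.getLogger("ramastats.pipeline")

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",         # synthetic | tsv | table-only
    "scale": 1000,               # samples per residue (synthetic mode)
    "seed": 0,
    "input": None,               # dihedral TSV (tsv mode) or profile config
    "k_min": 10,
    "k_max": 200,
    "helix_threshold": 0.200,
    "matrices": [],              # substitution-matrix files for the survey
    "matrix_format": "ncbi",
    "reference_pairs": sorted(sorted(p) for p in reference.BLOSUM_PAIRS),
}


def compare_pairs(
    found: Iterable[frozenset[str]],
    reference_pairs: Iterable[frozenset[str]],
    universe_size: int = 20,
) -> dict:
    """Overlap between found and reference replacement pairs.

    Returns the overlap count and the sequential pair-match probability for
    (|reference|, overlap). A zero overlap has no probability term (the
    product is empty); it is reported as 1 by convention.
    """
    found = {frozenset(p) for p in found}
    ref = {frozenset(p) for p in reference_pairs}
    universe = {r for p in found | ref for r in p}
    if len(universe) > universe_size:
        raise ValueError(
            f"pair labels span {len(universe)} elements > universe {universe_size}"
        )
    overlap = sorted(sorted(p) for p in (found & ref))
    m = len(overlap)
    prob = pair_match_probability(len(ref), m) if m > 0 else Fraction(1)
    return {
        "n_reference": len(ref),
        "n_found": len(found),
        "overlap": m,
        "overlap_pairs": overlap,
        "probability": float(prob),
        "probability_exact": f"{prob.numerator}/{prob.denominator}",
    }


def run_pipeline(config: Mapping | None = None, out_dir: str | Path = "out") -> dict:
    """Execute the configured stages and write artifacts under ``out_dir``."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            if not isinstance(v, (list, tuple))
            else [str(x) if isinstance(x, Path) else x for x in v]
            for k, v in cfg.items()
        },
        "mode": cfg["mode"],
    }

    if cfg["mode"] == "table-only":
        report.update(_table_only_report(cfg))
    else:
        report.update(_data_mode_report(cfg, out))

    # correlation survey over any supplied substitution matrices
    if cfg["matrices"]:
        from .inertia import correlation_survey

        matrices = [
            read_substitution_matrix(p, cfg["matrix_format"]) for p in cfg["matrices"]
        ]
        inertia = pd.Series({r: v["inertia"] for r, v in report["table"].items()})
        survey = correlation_survey(inertia, matrices)
        survey.per_matrix.to_csv(out / "survey.tsv", sep="\t")
        survey.cross_correlation.to_csv(out / "cross_correlation.tsv", sep="\t")
        report["survey"] = {
            "per_matrix_r": survey.per_matrix["r"].to_dict(),
            "mean_r": survey.mean_r,
            "mean_pairwise_r": survey.mean_pairwise_r,
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report


def _correlations(table: pd.DataFrame, threshold: float) -> dict:
    part = helix_former_partition(table, threshold)
    return {
        "mass_vs_bsteps": pearson(table["mass"], table["b_steps"]),
        "mass_vs_bsteps_excl_amide_acid": pearson(
            table["mass"], table["b_steps"], exclude=["Asn", "Asp", "Gln", "Glu"]
        ),
        "mass_vs_pmax_overall": part.r_overall,
        "mass_vs_pmax_strong": part.r_strong,
        "mass_vs_pmax_weak": part.r_weak,
        "mass_vs_pmax_cbeta_pro": part.r_cbeta_pro,
        "mass_vs_pmax_strong_excl": part.r_strong_excl,
        "mass_vs_pmax_weak_excl": part.r_weak_excl,
        "strong_set": list(part.strong),
        "weak_set": list(part.weak),
    }


def _table_only_report(cfg: Mapping) -> dict:
    table = reference.reference_table()
    grid = common_grid(zip(table["delta_min"], table["n_obs"]))
    # recompute W and I from the printed columns for the report
    derived = table.copy()
    derived["w_recomputed"] = derived["p_max_percent"] / 100.0 * derived["n_obs"]
    derived["inertia_recomputed"] = derived["mass"] / derived["w"]
    return {
        "grid": {
            "delta_bar": grid.delta_bar,
            "n_bins_per_axis": grid.n_bins_per_axis,
            "bin_width": grid.bin_width,
            "total_bins": grid.total_bins,
        },
        "table": derived.to_dict(orient="index"),
        "correlations": _correlations(table, cfg["helix_threshold"]),
        "pair_match": {
            "6_of_7": {
                "probability": float(pair_match_probability(7, 6)),
                "exact": str(pair_match_probability(7, 6)),
            }
        },
    }


def _data_mode_report(cfg: Mapping, out: Path) -> dict:
    if cfg["mode"] == "synthetic":
        if cfg.get("input"):
            profiles = profiles_from_config(cfg["input"])
        else:
            profiles = default_profiles(cfg["scale"], master_seed=cfg["seed"])
        records, truth = generate_dataset(
            profiles, master_seed=cfg["seed"], compute_modal_mass=False
        )
        truth.to_json(out / "ground_truth.json")
        from .dihedral_io import write_dihedral_table

        write_dihedral_table(records, out / "dihedrals.tsv")
        model = RamachandranModel(records)
    elif cfg["mode"] == "tsv":
        model = RamachandranModel.from_tsv(cfg["input"])
    else:
        raise ValueError(f"unknown mode {cfg['mode']!r}")

    results = model.fit(k_range=range(cfg["k_min"], cfg["k_max"] + 1))
    if results.sweeps:
        sweep_table(results.sweeps.values()).to_csv(
            out / "sweeps.tsv", sep="\t", index=False
        )
    results.table.to_csv(out / "table.tsv", sep="\t")
    results.matrix.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
    results.topology.neighbors_frame().to_csv(out / "neighbors.tsv", sep="\t")
    topo = results.topology
    topo_json = {
        "open_sets": [sorted(s) for s in topo.open_sets],
        "boundary_elements": {
            "+".join(sorted(k)): v for k, v in topo.boundary_elements.items()
        },
        "replacements": topo.replacements,
        "reciprocal_pairs": sorted(sorted(p) for p in topo.reciprocal),
    }
    (out / "topology.json").write_text(json.dumps(topo_json, indent=1, sort_keys=True))
    ref_pairs = [frozenset(p) for p in cfg["reference_pairs"]]
    pair_report = compare_pairs(topo.reciprocal, ref_pairs)
    return {
        "grid": {
            "delta_bar": results.grid.delta_bar,
            "n_bins_per_axis": results.grid.n_bins_per_axis,
            "bin_width": results.grid.bin_width,
            "total_bins": results.grid.total_bins,
        },
        "table": results.table.to_dict(orient="index"),
        "topology": topo_json,
        "pair_comparison": pair_report,
        "correlations": _correlations(results.table, cfg["helix_threshold"]),
        "seed": cfg["seed"],
    }
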