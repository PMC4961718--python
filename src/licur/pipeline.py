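"""End-to-end orchestration: (simulate | ingest) -> preprocess -> residue
screening -> per-timepoint clustering -> structural-stability linking ->
type/antitype transition tests -> combined report.

A single JSON config governs every stage; the same config and seed produce a
byte-identical JSON report.  The report's centroid table (cluster x factor
z-scores with names) is the tabular analog of the usual profile figure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import relocate, select_solution, ward_tree
from .core_data import (
    FACTOR_NAMES,
    TIME_COL,
    FactorPanel,
    RawPanel,
    read_factor_panel,
    read_panel,
    PanelSchema,
)
from .preprocess import EMConfig, FactorRecipe, build_factor_panel, zscore_column
from .residues import ResidueConfig, find_residues_panel, remove_residues
from .stability import centroid_distances, name_cluster, pair_by_distance
from .synthetic import GeneratorConfig, adjusted_rand_index, generate
from .transitions import scan_types

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_report"]

log = logging.getLogger("licur")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to one JSON file.

    With simulate=True the generator provides the input panel (its seed is
    taken from the pipeline seed); otherwise input_path/schema_path name a
    raw CSV panel, or factor_input_path a precomputed factor panel.
    """

    seed: int = 1
    simulate: bool = True
    input_path: str | None = None
    schema_path: str | None = None
    factor_input_path: str | None = None
    k_min: int = 2
    k_max: int = 6
    mojena_c: float = 2.75
    use_increments: bool = False
    alpha: float = 0.05
    correction: str = "none"
    name_threshold: float = 0.5
    residue: ResidueConfig = field(default_factory=ResidueConfig)
    em: EMConfig = field(default_factory=EMConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("none", "holm", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return json.dumps(enc(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        def build(dc_cls, data: dict):
            names = {f.name for f in dataclasses.fields(dc_cls)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown {dc_cls.__name__} keys: {sorted(unknown)}")
            return dc_cls(**data)

        payload = dict(payload)
        sub = {}
        for key, dc_cls in (("residue", ResidueConfig), ("em", EMConfig),
                            ("generator", GeneratorConfig)):
            if key in payload:
                entry = dict(payload.pop(key))
                if dc_cls is GeneratorConfig:
                    for arr in ("centroids", "transition_matrix", "outcome_probs"):
                        if entry.get(arr) is not None:
                            entry[arr] = np.asarray(entry[arr], dtype=float)
                sub[key] = build(dc_cls, entry)
        cfg = build(cls, payload)
        for key, value in sub.items():
            setattr(cfg, key, value)
        return cfg


@dataclass
class PipelineResult:
    bundle: dict                      # plain-JSON report
    factor_panel: FactorPanel         # post-preprocessing, pre-residue
    kept_panel: FactorPanel           # after residue removal
    solutions: dict[int, object]
    truth: object | None = None


def _standardize_factor_panel(panel: FactorPanel) -> FactorPanel:
    """Within-timepoint z-scores on an ingested factor panel (no-op up to
    tolerance when it is already standardized)."""
    data = panel.data.copy()
    for t in panel.timepoints:
        rows = data[TIME_COL] == t
        for f in FACTOR_NAMES:
            data.loc[rows, f] = zscore_column(data.loc[rows, f].to_numpy(), "higher")
    return FactorPanel(data=data, outcome=panel.outcome)


def run_pipeline(cfg: PipelineConfig, panel: RawPanel | FactorPanel | None = None) -> PipelineResult:
    """Run every stage and assemble the report bundle.

    Any stage failure raises PipelineError tagged with the stage name.
    """
    bundle: dict = {"config_seed": cfg.seed, "stages": {}}
    truth = None

    # -- input ---------------------------------------------------------------
    try:
        if panel is None:
            if cfg.simulate:
                gen_cfg = dataclasses.replace(cfg.generator, seed=cfg.seed)
                panel, truth = generate(gen_cfg)
                log.info("simulated panel: %d persons", len(panel.persons))
            elif cfg.factor_input_path:
                panel = read_factor_panel(cfg.factor_input_path)
            elif cfg.input_path and cfg.schema_path:
                schema = PanelSchema.from_json(Path(cfg.schema_path).read_text())
                panel = read_panel(cfg.input_path, schema)
            else:
                raise ValueError("no input: set simulate or provide paths")
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # -- preprocess ----------------------------------------------------------
    try:
        if isinstance(panel, RawPanel):
            factor_panel, prep = build_factor_panel(panel, FactorRecipe(), cfg.em)
            bundle["stages"]["preprocess"] = prep.to_dict()
        else:
            factor_panel = _standardize_factor_panel(panel)
            bundle["stages"]["preprocess"] = {
                "n_persons": len(factor_panel.persons),
                "n_timepoints": len(factor_panel.timepoints),
                "imputed_fraction_pct": 0.0,
                "mcar": None,
                "analysis_variables": list(FACTOR_NAMES),
            }
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    # -- residues ------------------------------------------------------------
    try:
        reports = find_residues_panel(factor_panel, cfg.residue)
        kept, removed = remove_residues(factor_panel, reports)
        bundle["stages"]["residues"] = {
            "per_timepoint": [
                {
                    "timepoint": r.timepoint,
                    "residue_ids": sorted(str(p) for p in r.residue_ids),
                    "fraction": round(r.fraction, 4),
                    "exceeded_guideline": r.exceeded_guideline,
                }
                for r in reports
            ],
            "removed_ids": sorted(str(p) for p in removed),
            "n_in": len(factor_panel.persons),
            "n_kept": len(kept.persons),
        }
        log.info("residues removed: %d of %d persons", len(removed), len(factor_panel.persons))
    except Exception as exc:
        raise PipelineError("residues", str(exc)) from exc

    # -- clustering per timepoint ---------------------------------------------
    solutions = {}
    try:
        ks = range(cfg.k_min, cfg.k_max + 1)
        cluster_stage = []
        for t in kept.timepoints:
            ids, X = kept.matrix(t)
            diag = select_solution(X, ks, cfg.mojena_c, cfg.use_increments)
            tree = ward_tree(X)
            sol = relocate(X, tree.cut(diag.picked_k), timepoint=t)
            sol.person_ids = ids
            sol.names = {
                c: name_cluster(sol.centroids[c - 1], cfg.name_threshold)
                for c in range(1, sol.k + 1)
            }
            solutions[t] = sol
            cluster_stage.append(
                {
                    "timepoint": t,
                    "k": sol.k,
                    "low_confidence": diag.low_confidence,
                    "mojena_suggested_k": diag.mojena.suggested_k,
                    "eess_percent": round(sol.eess_percent, 2),
                    "f_count": sol.f_count,
                    "sizes": {str(c): v for c, v in sol.sizes().items()},
                    "diagnostics": [
                        {k2: (round(v, 4) if isinstance(v, float) else v)
                         for k2, v in row.items()}
                        for row in diag.table
                    ],
                    "centroids": {
                        str(c): {
                            f: round(float(sol.centroids[c - 1][fi]), 3)
                            for fi, f in enumerate(FACTOR_NAMES)
                        }
                        for c in range(1, sol.k + 1)
                    },
                    "names": {
                        str(c): [f"{f}:{d}" for f, d in sol.names[c]]
                        for c in range(1, sol.k + 1)
                    },
                }
            )
        bundle["stages"]["clustering"] = cluster_stage
    except Exception as exc:
        raise PipelineError("clustering", str(exc)) from exc

    # -- structural stability --------------------------------------------------
    try:
        stability_stage = []
        tps = kept.timepoints
        for ta, tb in zip(tps[:-1], tps[1:]):
            d = centroid_distances(solutions[ta], solutions[tb])
            match = pair_by_distance(d)
            stability_stage.append(
                {
                    "pair": [ta, tb],
                    "pairs": [[a, b, round(dist, 4)] for a, b, dist in match.pairs],
                    "unmatched_a": list(match.unmatched_a),
                    "unmatched_b": list(match.unmatched_b),
                    "greedy_is_optimal": match.greedy_is_optimal,
                }
            )
        bundle["stages"]["stability"] = stability_stage
    except Exception as exc:
        raise PipelineError("stability", str(exc)) from exc

    # -- individual stability / outcome ---------------------------------------
    try:
        transition_stage = []
        for ta, tb in zip(tps[:-1], tps[1:]):
            sa, sb = solutions[ta], solutions[tb]
            rep = scan_types(
                pd.Series(sa.assignments, index=sa.person_ids),
                pd.Series(sb.assignments, index=sb.person_ids),
                alpha=cfg.alpha, correction=cfg.correction,
                categories_from=range(1, sa.k + 1), categories_to=range(1, sb.k + 1),
            )
            transition_stage.append(
                {
                    "pair": [ta, tb],
                    "kind": "cluster->cluster",
                    "n": rep.n,
                    "table": rep.table.to_numpy().tolist(),
                    "cells": rep.to_records(),
                    "zero_paths": [[str(i), str(j)] for i, j in rep.zero_cells()],
                }
            )
        if kept.outcome is not None:
            t_last = tps[-1]
            s_last = solutions[t_last]
            levels = sorted(kept.outcome.unique().tolist())
            rep = scan_types(
                pd.Series(s_last.assignments, index=s_last.person_ids),
                kept.outcome,
                alpha=cfg.alpha, correction=cfg.correction,
                categories_from=range(1, s_last.k + 1), categories_to=levels,
            )
            transition_stage.append(
                {
                    "pair": [t_last, "outcome"],
                    "kind": "cluster->outcome",
                    "n": rep.n,
                    "table": rep.table.to_numpy().tolist(),
                    "cells": rep.to_records(),
                    "zero_paths": [[str(i), str(j)] for i, j in rep.zero_cells()],
                }
            )
        bundle["stages"]["transitions"] = transition_stage
    except Exception as exc:
        raise PipelineError("transitions", str(exc)) from exc

    n_types = sum(1 for block in transition_stage for c in block["cells"]
                  if c["classification"] == "type")
    n_antitypes = sum(1 for block in transition_stage for c in block["cells"]
                      if c["classification"] == "antitype")
    bundle["summary"] = {
        "n_persons_final": len(kept.persons),
        "n_residues_removed": len(removed),
        "k_per_timepoint": {str(t): solutions[t].k for t in tps},
        "eess_per_timepoint": {str(t): round(solutions[t].eess_percent, 2) for t in tps},
        "n_types": n_types,
        "n_antitypes": n_antitypes,
    }

    # -- recovery metrics when the truth is known ------------------------------
    if truth is not None:
        recovery = {}
        for t in tps:
            sol = solutions[t]
            recovery[str(t)] = round(
                adjusted_rand_index(truth.labels(t, sol.person_ids), sol.assignments), 4
            )
        found = frozenset(bundle["stages"]["residues"]["removed_ids"])
        true_out = frozenset(str(p) for p in truth.outlier_ids)
        bundle["recovery"] = {
            "ari_per_timepoint": recovery,
            "outliers_flagged": len(found & true_out),
            "outliers_planted": len(true_out),
        }

    return PipelineResult(bundle=bundle, factor_panel=factor_panel, kept_panel=kept,
                          solutions=solutions, truth=truth)


def render_report(result: PipelineResult | dict) -> tuple[str, str]:
    """Human-readable text plus canonical JSON (stable key order) for a
    pipeline bundle."""
    bundle = result.bundle if isinstance(result, PipelineResult) else result
    js = json.dumps(bundle, indent=2, sort_keys=True)

    lines = []
    summary = bundle.get("summary", {})
    lines.append("person-oriented pattern analysis report")
    lines.append("=" * 40)
    lines.append(f"final sample: {summary.get('n_persons_final')} persons "
                 f"({summary.get('n_residues_removed')} residues removed)")
    prep = bundle["stages"].get("preprocess", {})
    lines.append(f"imputed cells: {prep.get('imputed_fraction_pct')}%")
    if prep.get("mcar"):
        m = prep["mcar"]
        lines.append(f"MCAR test: chi2={m['chi2']}, df={m['df']}, p={m['p_value']}")
    for block in bundle["stages"].get("clustering", []):
        lines.append(f"-- timepoint {block['timepoint']}: k={block['k']}, "
                     f"EESS={block['eess_percent']}%")
        for c, names in sorted(block["names"].items()):
            label = ", ".join(names) if names else "(average profile)"
            lines.append(f"   cluster {c} (n={block['sizes'][c]}): {label}")
    for block in bundle["stages"].get("transitions", []):
        lines.append(f"-- transitions {block['pair'][0]} -> {block['pair'][1]}:")
        hits = [c for c in block["cells"] if c["classification"] != "none"]
        if not hits:
            lines.append("   no types/antitypes")
        for c in hits:
            lines.append(
                f"   {c['classification']}: {c['from']} -> {c['to']} "
                f"(observed {c['observed']}, expected {c['expected']}, "
                f"OR {c['odds_ratio']})"
            )
        if block["zero_paths"]:
            for i, j in block["zero_paths"]:
                lines.append(f"   zero-transition path: {i} -> {j}")
    if "recovery" in bundle:
        lines.append(f"recovery (simulation truth known): "
                     f"ARI per timepoint {bundle['recovery']['ari_per_timepoint']}, "
                     f"outliers flagged {bundle['recovery']['outliers_flagged']}"
                     f"/{bundle['recovery']['outliers_planted']}")
    return "\n".join(lines) + "\n", js
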