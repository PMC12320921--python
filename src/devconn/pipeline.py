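"""Config-driven end-to-end runs: simulate/load -> metrics -> PLS -> QC.

A :class:`RunConfig` (built directly or from YAML) names the inputs, the
regional metrics to compute, the PLS analyses to run and the resampling
depths.  :func:`run_pipeline` executes the stages, writes CSV outputs plus a
JSON run manifest recording the package version, a config hash and every
seed, and returns the in-memory results; identical config and inputs give
identical outputs.  :func:`write_report` renders a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CohortPanel, read_cohort_panel, write_cohort_panel
from .metrics import modularity_signed
from .nulls import generate_signed_null, null_ensemble_pvalue
from .pls import (
    BSR_THRESHOLD,
    PLSResult,
    ReproducibilityReport,
    behavioral_pls,
    bootstrap_saliences,
    mean_centered_pls,
    permutation_pvalues,
    split_half_vector_reproducibility,
    test_train_reproducibility,
)
from .qc import exclusion_ledger, fingerprint_match_rate
from .synth import SyntheticCohortSpec, cohort_metric_panel, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PLSAnalysisConfig", "run_pipeline", "write_report"]


@dataclass
class PLSAnalysisConfig:
    """One requested PLS analysis."""

    mode: str  # "mean_centered" or "behavioral"
    metric: str = "fc_degree"
    behavior_columns: list[str] = field(default_factory=list)

    def validate(self, have_behavior: bool) -> None:
        if self.mode not in ("mean_centered", "behavioral"):
            raise ValueError(f"unknown PLS mode {self.mode!r}")
        if self.mode == "behavioral":
            if not have_behavior:
                raise ValueError(
                    "behavioral PLS requested but no behavior table is available"
                )
            if not self.behavior_columns:
                raise ValueError("behavioral PLS requires behavior_columns")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str = "devconn_run"
    # inputs: either a synthetic cohort spec, or panel/behavior CSV paths
    simulate: dict | None = None
    panel_csv: str | None = None
    behavior_csv: str | None = None
    metrics: list[str] = field(default_factory=lambda: ["fc_degree"])
    pls: list[PLSAnalysisConfig] = field(default_factory=list)
    n_perm: int = 1000
    n_boot: int = 500
    n_splits: int = 500
    n_perm_reproducibility: int = 50
    n_nulls: int = 0  # modularity null-model comparison, 0 disables
    consensus_fraction: float = 0.75
    run_reproducibility: bool = False
    fingerprint: bool = False
    exclusion_stages: list[tuple[str, int]] = field(default_factory=list)
    exclusion_initial: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pls = [PLSAnalysisConfig(**p) for p in raw.pop("pls", [])]
        stages = [tuple(s) for s in raw.pop("exclusion_stages", [])]
        return cls(pls=pls, exclusion_stages=stages, **raw)

    def validate(self) -> None:
        if self.simulate is None and self.panel_csv is None:
            raise ValueError("config must name either simulate parameters or panel_csv")
        have_behavior = self.simulate is not None or self.behavior_csv is not None
        for p in self.pls:
            p.validate(have_behavior)
        for depth, name in [
            (self.n_perm, "n_perm"),
            (self.n_boot, "n_boot"),
            (self.n_splits, "n_splits"),
        ]:
            if depth < 2:
                raise ValueError(f"{name} must be >= 2")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _lv_summary(
    res: PLSResult, rep: ReproducibilityReport | None
) -> pd.DataFrame:
    rows = []
    for l in range(res.n_lv):
        row = {
            "lv": l + 1,
            "singular_value": res.s[l],
            "covariance_explained": res.covariance_explained()[l],
            "perm_p": res.perm_p[l] if res.perm_p is not None else np.nan,
        }
        if rep is not None:
            row.update(
                z_test_train=rep.z_test_train[l],
                z_null_test_train=rep.z_null_test_train[l],
                z_split_half=rep.z_split_half[l],
                z_null_split_half=rep.z_null_split_half[l],
                reproducible_test_train=bool(rep.reproducible("test_train")[l]),
                reproducible_split_half=bool(rep.reproducible("split_half")[l]),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _run_one_pls(
    cfg: RunConfig,
    analysis: PLSAnalysisConfig,
    panel: CohortPanel,
    behavior: pd.DataFrame | None,
    out: Path,
    seeds: dict,
) -> dict:
    tag = f"{analysis.mode}_{analysis.metric}"
    if analysis.mode == "mean_centered":
        res = mean_centered_pls(panel)
        behav_args = (None, None)
    else:
        res = behavioral_pls(panel, behavior, analysis.behavior_columns)
        behav_args = (behavior, analysis.behavior_columns)
    seeds[f"{tag}:permutation"] = cfg.seed + 1
    permutation_pvalues(
        res, panel, *behav_args, n_perm=cfg.n_perm, seed=cfg.seed + 1
    )
    seeds[f"{tag}:bootstrap"] = cfg.seed + 2
    boot = bootstrap_saliences(
        res, panel, *behav_args, n_boot=cfg.n_boot, seed=cfg.seed + 2
    )
    rep = None
    if cfg.run_reproducibility:
        seeds[f"{tag}:reproducibility"] = cfg.seed + 3
        rep = test_train_reproducibility(
            panel,
            *behav_args,
            n_splits=cfg.n_splits,
            n_perm=cfg.n_perm_reproducibility,
            seed=cfg.seed + 3,
        )
        rep = split_half_vector_reproducibility(
            panel,
            *behav_args,
            n_splits=cfg.n_splits,
            n_perm=cfg.n_perm_reproducibility,
            seed=cfg.seed + 3,
            report=rep,
        )
    summary = _lv_summary(res, rep)
    summary.to_csv(out / f"{tag}_lv_summary.csv", index=False)
    pd.DataFrame(
        res.U, index=panel.region_labels, columns=[f"LV{l+1}" for l in range(res.n_lv)]
    ).to_csv(out / f"{tag}_saliences.csv")
    pd.DataFrame(
        boot.bsr,
        index=panel.region_labels,
        columns=[f"LV{l+1}" for l in range(res.n_lv)],
    ).to_csv(out / f"{tag}_bsr.csv")
    scores = pd.DataFrame(
        res.brain_scores, columns=[f"LV{l+1}" for l in range(res.n_lv)]
    )
    scores.insert(0, "timepoint", panel.condition)
    scores.insert(0, "subject_id", panel.subject_ids)
    scores.to_csv(out / f"{tag}_brain_scores.csv", index=False)
    return {"tag": tag, "metric": analysis.metric, "result": res, "bootstrap": boot,
            "reproducibility": rep, "lv_summary": summary}


def run_pipeline(config: RunConfig) -> dict:
    """Execute a configured run and return {manifest, panels, pls, qc}."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds: dict[str, int] = {}
    cohort = None
    behavior = None
    panels: dict[str, CohortPanel] = {}
    if config.simulate is not None:
        spec = SyntheticCohortSpec(**{**config.simulate, "seed": config.seed})
        seeds["simulate"] = config.seed
        cohort = generate_cohort(spec)
        behavior = cohort.behavior
        behavior.to_csv(out / "behavior.csv", index=False)
        for metric in config.metrics:
            panels[metric] = cohort_metric_panel(cohort, metric)
    else:
        panel = read_cohort_panel(config.panel_csv)
        panels[panel.metric_name] = panel
        if config.behavior_csv:
            behavior = pd.read_csv(config.behavior_csv)
    for metric, panel in panels.items():
        write_cohort_panel(panel, out / f"panel_{metric}.csv")
    results: dict = {"panels": panels, "pls": [], "qc": {}}

    if config.n_nulls > 0 and cohort is not None:
        key = (cohort.subject_ids[0], 1)
        seeds["nulls"] = config.seed + 10
        obs = modularity_signed(cohort.fc[key], n_restarts=20, seed=config.seed + 10)
        ens = generate_signed_null(cohort.fc[key], config.n_nulls, seed=config.seed + 10)
        null_q = [
            modularity_signed(m, n_restarts=5, seed=config.seed + 10).Q
            for m in ens.matrices
        ]
        p = null_ensemble_pvalue(obs.Q, null_q, "greater")
        results["qc"]["modularity_null"] = {"observed_q": obs.Q, "null_p": p}
        pd.DataFrame({"null_q": null_q}).to_csv(out / "null_modularity.csv", index=False)

    for analysis in config.pls:
        if analysis.metric not in panels:
            raise ValueError(
                f"PLS stage requests metric {analysis.metric!r} but only "
                f"{sorted(panels)} were computed"
            )
        results["pls"].append(
            _run_one_pls(config, analysis, panels[analysis.metric], behavior, out, seeds)
        )

    if config.fingerprint and cohort is not None:
        results["qc"]["fingerprint_match_rate"] = fingerprint_match_rate(
            list(cohort.fc.values())
        )
    if config.exclusion_stages:
        initial = config.exclusion_initial
        if initial is None:
            raise ValueError("exclusion_stages given without exclusion_initial")
        ledger = exclusion_ledger(initial, config.exclusion_stages)
        results["qc"]["exclusion_ledger"] = ledger
        (out / "exclusion_ledger.txt").write_text(ledger.report() + "\n")

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def write_report(results: dict, top_n: int = 10) -> str:
    """Human-readable per-LV summary of a completed run."""
    lines: list[str] = []
    for entry in results.get("pls", []):
        res: PLSResult = entry["result"]
        lines.append(f"== {entry['tag']} ==")
        summary: pd.DataFrame = entry["lv_summary"]
        lines.append(summary.round(4).to_string(index=False))
        bsr = entry["bootstrap"].bsr
        labels = np.asarray(results["panels"][entry["metric"]].region_labels)
        for l in range(min(res.n_lv, 2)):
            strong = np.abs(bsr[:, l]) > BSR_THRESHOLD
            order = np.argsort(-np.abs(bsr[:, l]))
            top = [o for o in order if strong[o]][:top_n]
            if top:
                picks = ", ".join(f"{labels[i]} ({bsr[i, l]:+.1f})" for i in top)
                lines.append(f"LV{l+1} reliable regions (|BSR| > {BSR_THRESHOLD}): {picks}")
        lines.append("")
    qc = results.get("qc", {})
    if "fingerprint_match_rate" in qc:
        lines.append(
            f"Fingerprint match rate: {100 * qc['fingerprint_match_rate']:.1f}%"
        )
    if "modularity_null" in qc:
        mn = qc["modularity_null"]
        lines.append(
            f"Observed FC modularity Q = {mn['observed_q']:.3f} "
            f"(null-model p = {mn['null_p']:.3g})"
        )
    if "exclusion_ledger" in qc:
        lines.append(qc["exclusion_ledger"].report())
    return "\n".join(lines) + ("\n" if lines else "")
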