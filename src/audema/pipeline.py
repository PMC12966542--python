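"""End-to-end orchestration: simulate -> score -> decompose -> correlate
-> model -> mediate, with a machine-readable run manifest.

Each stage writes RFC-4180 CSV tables into the output directory; the
manifest records the config hash, seed, per-stage row counts, warnings
and a SHA-256 checksum for every artifact, so reruns with an identical
config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import TruthConfig
from .correlation import (DEFAULT_MEASURES, between_subject_matrix,
                          contrast_table, within_subject_matrices)
from .decompose import add_decomposition
from .mediation import MediationConfig, run_mediation
from .models import ModelSpec, fit_between_regression, fit_moderation_model
from .scoring import LABEL_MAP_VERSION, score_table
from .simulate import simulate_study

logger = logging.getLogger(__name__)

PARTICIPANT_COLUMNS = ["participant_id", "pta", "age", "sex",
                       "sleep_quality", "sleep_hours", "hearing_aid"]

EMA_COLUMNS = ["participant_id", "day", "prompt", "timestamp_hours",
               "answered", "difficulty", "importance", "who_with",
               "situation", "pos1", "pos2", "pos3", "pos4",
               "neg1", "neg2", "neg3", "neg4", "neg5",
               "feeling_now", "effort", "fatigue"]

OUTCOMES = ("effort", "affect", "fatigue")
DEMANDS = ("environmental", "social", "subjective")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    label_map_version: str
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    metadata: dict = field(default_factory=dict)

    def register(self, path: Path) -> None:
        self.artifacts[path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest,
               index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\r\n")
    manifest.register(path)


def run_all(config: TruthConfig, out_dir: str | Path,
            mediation_draws: int = 4000) -> RunManifest:
    """Run every stage on a simulated study and write all artifacts.

    Fails fast with a clear error when a stage has no analyzable data
    (e.g. compliance set to zero).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=config.seed,
                           version=__version__,
                           label_map_version=LABEL_MAP_VERSION)

    # 1. simulate
    study = simulate_study(config)
    manifest.row_counts["participants"] = len(study.participants)
    manifest.row_counts["ema_prompts"] = len(study.ema)
    manifest.row_counts["ema_answered"] = int(study.ema["answered"].sum())
    manifest.metadata["clip_rates"] = study.clip_rates
    for name, rate in study.clip_rates.items():
        if rate > 0.05:
            manifest.warnings.append(
                f"{name}: {100 * rate:.1f}% of generated values clipped")
    _write_csv(study.participants[PARTICIPANT_COLUMNS],
               out / "participants.csv", manifest)
    _write_csv(study.ema[EMA_COLUMNS], out / "ema_long.csv", manifest)

    # 2. score
    scored, cuts = score_table(study.ema)
    manifest.metadata["tertile_cutpoints"] = {
        "lower": cuts.lower, "upper": cuts.upper, "source_n": cuts.source_n}
    (out / "tertile_cutpoints.json").write_text(json.dumps(
        manifest.metadata["tertile_cutpoints"]
        | {"label_map_version": LABEL_MAP_VERSION}, indent=2))
    manifest.register(out / "tertile_cutpoints.json")

    # 3. decompose
    scored = scored.merge(study.participants[PARTICIPANT_COLUMNS],
                          on="participant_id", how="left")
    scored = add_decomposition(scored)
    manifest.row_counts["scored"] = int(scored["answered"].sum())
    _write_csv(scored, out / "ema_scored.csv", manifest)

    # 4. correlation structure
    between = between_subject_matrix(scored)
    within = within_subject_matrices(scored)
    contrasts = contrast_table(scored)
    _write_csv(between, out / "correlations_between.csv", manifest, index=True)
    _write_csv(within.median, out / "correlations_within_median.csv",
               manifest, index=True)
    _write_csv(within.pooled, out / "correlations_within_pooled.csv",
               manifest, index=True)
    _write_csv(contrasts, out / "correlation_contrasts.csv", manifest)
    manifest.row_counts["correlation_contrasts"] = len(contrasts)

    # 5. person-level PTA -> mean demand regressions
    rows = []
    for demand in DEMANDS:
        reg = fit_between_regression(study.participants, scored, demand)
        rows.append({"demand": demand, "slope_per_db": reg.slope,
                     "se": reg.se, "t": reg.t, "p": reg.p,
                     "r_squared": reg.r_squared, "n": reg.n})
    _write_csv(pd.DataFrame(rows), out / "pta_demand_regressions.csv",
               manifest)

    # 6. moderation models (the full outcome x demand family)
    tables = []
    for outcome in OUTCOMES:
        for demand in DEMANDS:
            res = fit_moderation_model(scored, ModelSpec(outcome, demand))
            tab = res.coefficients.reset_index(names="term")
            tab.insert(0, "outcome", outcome)
            tab.insert(1, "demand", demand)
            tab["group_var"] = res.group_var
            tab["residual_var"] = res.residual_var
            tab["n_obs"] = res.n_obs
            tables.append(tab)
    _write_csv(pd.concat(tables, ignore_index=True),
               out / "moderation_models.csv", manifest)

    # 7. mediation (both mediators, all demand definitions)
    med_rows = []
    med_cfg = MediationConfig(draws=mediation_draws, seed=config.seed)
    for demand in DEMANDS:
        for mediator in ("effort", "affect"):
            res = run_mediation(scored, demand, mediator, med_cfg)
            med_rows.append({
                "demand": demand, "mediator": mediator,
                "a": res.a, "se_a": res.se_a, "b": res.b, "se_b": res.se_b,
                "indirect": res.indirect,
                "indirect_ci_lower": res.indirect_ci[0],
                "indirect_ci_upper": res.indirect_ci[1],
                "c_prime": res.c_prime, "c": res.c,
                "a_moderation": res.a_moderation,
                "pattern": res.pattern, "n_obs": res.n_obs,
            })
    _write_csv(pd.DataFrame(med_rows), out / "mediation_results.csv",
               manifest)
    manifest.row_counts["mediation_models"] = len(med_rows)

    manifest.write(out / "manifest.json")
    return manifest
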