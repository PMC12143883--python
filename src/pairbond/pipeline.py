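"""End-to-end orchestration: generate (or load) → analyze → stats → report.

A run is described by a :class:`RunConfig`. In ``synthetic`` mode the
pipeline generates a full experiment (per-animal photometry sessions for
each stimulus, preference trials per arm), pushes the sessions through
the ΔF/F chain, and applies the per-figure statistical recipes. In
``source_data`` mode it loads long-format tables and applies the recipes
directly, touching no random stream.

Recipes (which table, which test, which factors) are data, not code:
see ``recipes/default.yaml``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from pairbond import behavior, photometry, stats
from pairbond.photometry import BoutResponse
from pairbond.synthetic import (
    GroundTruth,
    PhotometrySession,
    SimConfig,
    generate_photometry_session,
    generate_preference_trial,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "session_bout_responses",
    "run_photometry_experiment",
    "run_preference_experiment",
    "run_recipes",
    "run_experiment",
    "stat_result_rows",
]

STIMULI = ("partner", "stranger", "object")


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "source_data"
    seed: int = 0
    out_dir: str | Path = "results"
    n_animals: int = 7
    day: str = "day7"
    preference_arms: tuple[str, ...] = ()
    n_per_arm: int = 8
    sim: SimConfig | None = None
    table_paths: dict[str, str] = field(default_factory=dict)
    recipe_path: str | Path | None = None
    refractory_reference: str = "offset"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "source_data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "source_data" and not self.table_paths:
            raise ValueError("source_data mode requires table paths")
        if self.mode == "synthetic" and self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "n_animals": self.n_animals,
                "day": self.day,
                "arms": list(self.preference_arms),
                "n_per_arm": self.n_per_arm,
                "tables": sorted(self.table_paths),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def session_bout_responses(
    session: PhotometrySession,
    refractory_reference: str = "offset",
    pre_s: float = 10.0,
    post_s: float = 10.0,
) -> list[BoutResponse]:
    """Full ΔF/F chain for one session: F0 → ΔF/F → exclusion → responses.

    Excluded bouts are carried through with ``included=False`` and a
    reason, so the filtering stays auditable downstream.
    """
    dff = photometry.compute_dff(session.trace, session.epoch)
    flags = photometry.apply_refractory_exclusion(
        session.bouts, reference=refractory_reference
    )
    included = [b for b, keep in flags if keep]
    peri = photometry.extract_peri_event(dff, included, pre_s=pre_s, post_s=post_s)
    responses = photometry.bout_response(peri)
    kept_starts = {b.start_s for b in peri.bouts}
    out: list[BoutResponse] = list(responses)
    for i, (b, keep) in enumerate(flags):
        if not keep:
            out.append(
                BoutResponse(
                    bout_index=-1,
                    bout=b,
                    mean_dff=float("nan"),
                    included=False,
                    exclusion_reason="within 4 s of prior included bout",
                )
            )
        elif b.start_s not in kept_starts:
            out.append(
                BoutResponse(
                    bout_index=-1,
                    bout=b,
                    mean_dff=float("nan"),
                    included=False,
                    exclusion_reason="peri-event window outside trace",
                )
            )
    n_excluded = sum(1 for r in out if not r.included)
    logger.info(
        "session %s/%s: %d bouts, %d excluded",
        session.animal_id,
        session.condition,
        len(out),
        n_excluded,
    )
    return out


def run_photometry_experiment(
    sim: SimConfig,
    day: str = "day7",
    n_animals: int = 7,
    refractory_reference: str = "offset",
) -> tuple[pd.DataFrame, stats.StatResult, list[GroundTruth]]:
    """Simulate and quantify one photometry cohort.

    Each animal contributes one exposure session per stimulus
    (partner / stranger / object). Per-animal per-stimulus means feed a
    one-way repeated-measures ANOVA with GG correction and Sidak
    post-hocs, mirroring the study's quantification of bout responses.
    """
    rows = []
    truths: list[GroundTruth] = []
    for a in range(n_animals):
        animal = f"A{a:02d}"
        per_stim: dict[str, list[BoutResponse]] = {}
        for stim in STIMULI:
            session, truth = generate_photometry_session(sim, f"{day}:{stim}", animal)
            truths.append(truth)
            per_stim[stim] = session_bout_responses(
                session, refractory_reference=refractory_reference
            )
        summary = photometry.summarize_session(
            per_stim, animal_id=animal, condition=day, expected_stimuli=STIMULI
        )
        for stim in STIMULI:
            if stim in summary.stimulus_means:
                rows.append(
                    {
                        "animal": animal,
                        "condition": day,
                        "stimulus": stim,
                        "mean_dff_pct": 100.0 * summary.stimulus_means[stim],
                        "n_bouts": summary.n_bouts_included[stim],
                    }
                )
    table = pd.DataFrame(rows)
    design = table.rename(columns={"animal": "subject", "stimulus": "level", "mean_dff_pct": "value"})
    anova = stats.rm_anova_gg(design[["subject", "level", "value"]])
    return table, anova, truths


def run_preference_experiment(
    sim: SimConfig,
    arms: Sequence[str],
    n_per_arm: int = 8,
) -> tuple[pd.DataFrame, dict[str, stats.StatResult]]:
    """Simulate preference trials and apply the behavioral statistics.

    Emits the two-way (virus group × drug) ANOVA on the preference
    ratio and a Kruskal–Wallis over the per-arm side-by-side partner
    times, the two analyses the chemogenetic panels report.
    """
    trials = []
    for arm in arms:
        for i in range(n_per_arm):
            trials.append(
                generate_preference_trial(sim, arm, subject_id=f"{arm}-S{i:02d}")
            )
    frame = behavior.trials_to_frame(trials)
    frame[["virus", "drug"]] = frame["arm"].str.split(":", expand=True)
    results: dict[str, stats.StatResult] = {}
    if frame["virus"].nunique() >= 2 and frame["drug"].nunique() >= 2:
        aov = stats.two_way_anova(frame, "virus", "drug", dv="preference_ratio")
        results.update({f"two_way_{k}": v for k, v in aov.items()})
    groups = [g["sbs_partner_s"].to_numpy() for _, g in frame.groupby("arm")]
    labels = [str(a) for a, _ in frame.groupby("arm")]
    if len(groups) >= 2:
        results["kruskal_sbs_partner"] = stats.kruskal_wallis(groups, labels)
    return frame, results


def stat_result_rows(named: dict[str, stats.StatResult]) -> pd.DataFrame:
    """Flatten StatResults (and their post-hocs) into a report table."""
    rows = []
    for name, res in named.items():
        items = [(name, res)]
        for extra_name, extra in getattr(res, "extras", {}).items():
            items.append((f"{name}.{extra_name}", extra))
        for label, r in items:
            rows.append(
                {
                    "analysis": label,
                    "test": r.test,
                    "term": r.term,
                    "statistic": r.statistic,
                    "df1": r.df1,
                    "df2": r.df2 if r.df2 is not None else "",
                    "epsilon": r.epsilon,
                    "p": r.p,
                    "contrast": "",
                    "p_adj": "",
                }
            )
            for ph in r.posthoc:
                rows.append(
                    {
                        "analysis": label,
                        "test": ph.method,
                        "term": "posthoc",
                        "statistic": "",
                        "df1": "",
                        "df2": "",
                        "epsilon": "",
                        "p": ph.p_raw,
                        "contrast": ph.contrast,
                        "p_adj": ph.p_adj,
                    }
                )
    return pd.DataFrame(rows)


def _load_recipes(path: str | Path | None) -> list[dict]:
    if path is None:
        ref = resources.files("pairbond") / "recipes" / "default.yaml"
        raw = ref.read_text()
    else:
        raw = Path(path).read_text()
    return yaml.safe_load(raw) or []


def run_recipes(
    tables: dict[str, pd.DataFrame], recipes: list[dict]
) -> dict[str, stats.StatResult]:
    """Apply data-driven statistical recipes to named long-format tables."""
    out: dict[str, stats.StatResult] = {}
    for rec in recipes:
        name = rec["name"]
        table = tables.get(rec["table"])
        if table is None:
            logger.warning("recipe %s skipped: table %r not provided", name, rec["table"])
            continue
        test = rec["test"]
        if test == "rm_anova":
            out[name] = stats.rm_anova_gg(
                table,
                within=rec.get("within", "level"),
                subject=rec.get("subject", "subject"),
                dv=rec.get("dv", "value"),
            )
        elif test == "mixed_anova":
            out[name] = stats.mixed_anova(
                table,
                between=rec.get("between", "group"),
                within=rec.get("within", "treatment"),
                subject=rec.get("subject", "subject"),
                dv=rec.get("dv", "value"),
            )
        elif test == "two_way_anova":
            res = stats.two_way_anova(table, rec["f1"], rec["f2"], dv=rec.get("dv", "value"))
            for k, v in res.items():
                out[f"{name}.{k}"] = v
        elif test == "kruskal":
            by = rec.get("by", "group")
            dv = rec.get("dv", "value")
            groups = [g[dv].to_numpy() for _, g in table.groupby(by)]
            labels = [str(k) for k, _ in table.groupby(by)]
            out[name] = stats.kruskal_wallis(groups, labels)
        elif test in ("paired_t", "unpaired_t"):
            by = rec.get("by", "group")
            dv = rec.get("dv", "value")
            levels = rec.get("levels") or sorted(table[by].unique())
            x = table.loc[table[by] == levels[0], dv].to_numpy()
            y = table.loc[table[by] == levels[1], dv].to_numpy()
            out[name] = stats.paired_t(x, y) if test == "paired_t" else stats.unpaired_t(x, y)
        else:
            raise ValueError(f"recipe {name}: unknown test {test!r}")
    return out


def run_experiment(config: RunConfig) -> dict[str, Path]:
    """Execute a full run and write its report bundle.

    Writes per-animal summary CSVs, a stats CSV in the study's reporting
    style, and a small JSON log; every output carries the config hash.
    Deterministic: the same config and seed yield byte-identical CSVs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    written: dict[str, Path] = {}
    results: dict[str, stats.StatResult] = {}

    if config.mode == "synthetic":
        sim = config.sim if config.sim is not None else SimConfig(seed=config.seed)
        sim = sim.with_(seed=config.seed)
        table, anova, _ = run_photometry_experiment(
            sim,
            day=config.day,
            n_animals=config.n_animals,
            refractory_reference=config.refractory_reference,
        )
        table.insert(0, "config_hash", tag)
        p = out_dir / "photometry_summary.csv"
        table.to_csv(p, index=False, float_format="%.6f")
        written["photometry_summary"] = p
        results[f"photometry_{config.day}_rm_anova"] = anova

        if config.preference_arms:
            frame, pref_stats = run_preference_experiment(
                sim, config.preference_arms, config.n_per_arm
            )
            frame.insert(0, "config_hash", tag)
            p = out_dir / "preference_summary.csv"
            frame.to_csv(p, index=False, float_format="%.6f")
            written["preference_summary"] = p
            results.update(pref_stats)
    else:
        tables = {name: pd.read_csv(path) for name, path in config.table_paths.items()}
        for name, tab in tables.items():
            missing = {"value"} - set(tab.columns)
            if missing:
                raise ValueError(f"table {name!r} lacks columns: {sorted(missing)}")
        results.update(run_recipes(tables, _load_recipes(config.recipe_path)))

    report = stat_result_rows(results)
    report.insert(0, "config_hash", tag)
    p = out_dir / "stats_report.csv"
    report.to_csv(p, index=False, float_format="%.6g")
    written["stats_report"] = p
    (out_dir / "run_log.json").write_text(
        json.dumps({"config_hash": tag, "mode": config.mode, "seed": config.seed}, indent=2)
    )
    written["run_log"] = out_dir / "run_log.json"
    return written
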