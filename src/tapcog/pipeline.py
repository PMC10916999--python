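"""End-to-end study orchestration: simulate/load -> validate -> extract -> filter -> analyze.

The full study asks nine questions: for each of three cognitive outcomes
(paltea6, swmbe6, swms) and each of three candidate motor-feature sets
(single-key, alternate-key, combined), does any motor feature enter the
AICc-equivalence set ahead of the covariates-only null model?  The result is
a 3x3 hypothesis matrix of improvement decisions plus the full ranked model
table behind every cell.

Feature-set presets
-------------------
``single_full`` (16 features, 2^16 models), ``alternate`` (8), and
``combined_full`` (24, gated behind ``allow_full_enumeration`` because 2^24
fits is a cluster-scale job) enumerate the complete sets.  The default study
uses scaled-down sets that keep a full 9-cell run at desk scale while
preserving each set's character: ``single_reduced`` (blocks 1 and 4, 8
features), ``alternate`` (all 8), ``combined_reduced`` (block 1 + all
alternate, 12 features).

Reports are byte-deterministic under a fixed seed: timings go to the logger,
never into report files, and the configuration hash is embedded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tapcog.cohort_filter import ExclusionLedger, apply_exclusions
from tapcog.keystroke_io import (
    Cohort,
    attach_blocks,
    read_events,
    read_participants,
    segment_protocol,
)
from tapcog.model_selection import (
    FamilyChoice,
    HypothesisDecision,
    ModelTable,
    dredge_subsets,
    evaluate_hypothesis,
    select_family,
)
from tapcog.motor_features import (
    ALTERNATE_KEY_FEATURES,
    FEATURE_COLUMNS,
    SINGLE_KEY_FEATURES,
    build_feature_table,
)
from tapcog.synthetic_cohort import SimConfig, simulate_cohort

__all__ = [
    "FEATURE_SET_PRESETS",
    "StudyConfig",
    "StudyReport",
    "build_analysis_frame",
    "run_study",
    "write_report",
]

log = logging.getLogger("tapcog")

OUTCOMES = ("paltea6", "swmbe6", "swms")

_SINGLE_REDUCED = [c for c in SINGLE_KEY_FEATURES if c.endswith(("b1", "b4"))]
_COMBINED_REDUCED = [c for c in SINGLE_KEY_FEATURES if c.endswith("b1")] + list(
    ALTERNATE_KEY_FEATURES
)

FEATURE_SET_PRESETS: dict[str, list[str]] = {
    "single_full": list(SINGLE_KEY_FEATURES),
    "alternate": list(ALTERNATE_KEY_FEATURES),
    "combined_full": list(FEATURE_COLUMNS),
    "single_reduced": _SINGLE_REDUCED,
    "combined_reduced": _COMBINED_REDUCED,
}

_DEFAULT_SETS = {
    "single": "single_reduced",
    "alternate": "alternate",
    "combined": "combined_reduced",
}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Everything needed to reproduce one full study run."""

    sim: SimConfig | None = None
    events_path: str | None = None
    participants_path: str | None = None
    outcomes: tuple[str, ...] = OUTCOMES
    feature_sets: dict[str, list[str]] = field(
        default_factory=lambda: {
            name: list(FEATURE_SET_PRESETS[preset])
            for name, preset in _DEFAULT_SETS.items()
        }
    )
    family_policy: str = "auto"  # "auto" | explicit family name
    seed: int = 0
    allow_full_enumeration: bool = False
    max_set_size: int = 16

    def __post_init__(self):
        if self.sim is None and not (self.events_path and self.participants_path):
            self.sim = SimConfig(seed=self.seed)
        elif self.sim is not None:
            self.sim = self.sim.with_updates(seed=self.seed)
        for name, feats in self.feature_sets.items():
            unknown = set(feats) - set(FEATURE_COLUMNS)
            if unknown:
                raise ValueError(f"feature set {name!r} has unknown features {sorted(unknown)}")
            if len(feats) > self.max_set_size and not self.allow_full_enumeration:
                raise ValueError(
                    f"feature set {name!r} has {len(feats)} features (2^{len(feats)} "
                    f"models); exceeds max_set_size={self.max_set_size}. Pass "
                    "allow_full_enumeration=True to run it anyway."
                )
        for oc in self.outcomes:
            if oc not in OUTCOMES:
                raise ValueError(f"unknown outcome {oc!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "outcomes" in d:
            d["outcomes"] = tuple(d["outcomes"])
        if "feature_sets" in d:
            resolved = {}
            for name, val in d["feature_sets"].items():
                if isinstance(val, str):
                    resolved[name] = list(FEATURE_SET_PRESETS[val])
                else:
                    resolved[name] = list(val)
            d["feature_sets"] = resolved
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "sim": None if self.sim is None else self.sim.to_dict(),
            "events_path": self.events_path,
            "participants_path": self.participants_path,
            "outcomes": list(self.outcomes),
            "feature_sets": {k: list(v) for k, v in self.feature_sets.items()},
            "family_policy": self.family_policy,
            "seed": self.seed,
            "allow_full_enumeration": self.allow_full_enumeration,
            "max_set_size": self.max_set_size,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    """Outputs of one study run: the hypothesis matrix and everything behind it."""

    config: StudyConfig
    cohort_provenance: dict
    ledger: ExclusionLedger
    family_choices: dict[str, FamilyChoice]
    decisions: dict[tuple[str, str], HypothesisDecision]
    model_tables: dict[tuple[str, str], ModelTable]
    n_analyzed: int

    def hypothesis_matrix(self) -> pd.DataFrame:
        """Improvement decision per (outcome, feature set)."""
        sets = list(self.config.feature_sets)
        data = {
            s: [self.decisions[(oc, s)].improvement for oc in self.config.outcomes]
            for s in sets
        }
        return pd.DataFrame(data, index=list(self.config.outcomes))

    def null_delta_matrix(self) -> pd.DataFrame:
        sets = list(self.config.feature_sets)
        data = {
            s: [self.decisions[(oc, s)].null_delta_aicc for oc in self.config.outcomes]
            for s in sets
        }
        return pd.DataFrame(data, index=list(self.config.outcomes))


def build_analysis_frame(cohort: Cohort, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Merge participant scalars with motor features into the modelling table."""
    rows = []
    for p in cohort.participants:
        rows.append(
            {
                "participant_id": p.participant_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "education_level": p.education_level,
                "hads_anxiety": p.hads_anxiety,
                "hads_depression": p.hads_depression,
                "paltea6": p.paltea6,
                "swmbe6": p.swmbe6,
                "swms": p.swms,
            }
        )
    df = pd.DataFrame(rows).set_index("participant_id")
    return df.join(feature_table, how="left")


def _load_or_simulate(config: StudyConfig) -> Cohort:
    if config.events_path and config.participants_path:
        cohort = read_participants(config.participants_path)
        blocks = read_events(config.events_path)
        return attach_blocks(cohort, blocks)
    return simulate_cohort(config.sim)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline and return the study report.

    Stages: acquire cohort -> protocol validation -> feature extraction ->
    exclusions -> per-outcome family selection -> per (outcome, feature set)
    all-subsets AICc comparison.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    t0 = time.perf_counter()
    import numpy
    import pandas

    import tapcog

    log.info(
        "tapcog %s (numpy %s, pandas %s), seed %d, config %s",
        tapcog.__version__,
        numpy.__version__,
        pandas.__version__,
        config.seed,
        config.config_hash(),
    )
    try:
        cohort = _load_or_simulate(config)
    except Exception as exc:
        raise StageError("acquire", str(exc)) from exc
    log.info("cohort of %d participants (%.1fs)", len(cohort), time.perf_counter() - t0)

    n_incomplete = sum(
        not segment_protocol(p.blocks, p.participant_id).complete
        for p in cohort.participants
    )
    log.info("validate: %d participants with incomplete protocols", n_incomplete)

    try:
        filtered, ledger = apply_exclusions(cohort)
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc
    log.info(
        "filter: %d included, %d excluded %s",
        ledger.n_included,
        ledger.n_excluded,
        ledger.counts,
    )

    try:
        features = build_feature_table(filtered)
        data = build_analysis_frame(filtered, features)
    except Exception as exc:
        raise StageError("extract", str(exc)) from exc

    family_choices: dict[str, FamilyChoice] = {}
    decisions: dict[tuple[str, str], HypothesisDecision] = {}
    tables: dict[tuple[str, str], ModelTable] = {}
    for outcome in config.outcomes:
        try:
            if config.family_policy == "auto":
                choice = select_family(outcome, data)
            else:
                choice = FamilyChoice(
                    outcome=outcome,
                    family=config.family_policy,
                    aicc_poisson=None,
                    aicc_negbin=None,
                    fallback_reason="fixed by config",
                )
            family_choices[outcome] = choice
            if choice.fallback_reason:
                log.info("family for %s: %s (%s)", outcome, choice.family, choice.fallback_reason)
            else:
                log.info("family for %s: %s", outcome, choice.family)
        except Exception as exc:
            raise StageError("family_selection", f"{outcome}: {exc}") from exc

        for set_name, feats in config.feature_sets.items():
            t1 = time.perf_counter()
            try:
                table = dredge_subsets(
                    outcome,
                    feats,
                    data,
                    family=family_choices[outcome].family,
                    max_features=24 if config.allow_full_enumeration else config.max_set_size,
                )
            except Exception as exc:
                raise StageError("analyze", f"{outcome}/{set_name}: {exc}") from exc
            decision = evaluate_hypothesis(table)
            decisions[(outcome, set_name)] = decision
            tables[(outcome, set_name)] = table
            n_bad = int((~table.table["converged"]).sum())
            if n_bad:
                log.warning("%s/%s: %d non-converged fits", outcome, set_name, n_bad)
            log.info(
                "%s/%s: 2^%d models, null dAICc=%.2f, improvement=%s (%.1fs)",
                outcome,
                set_name,
                len(feats),
                decision.null_delta_aicc,
                decision.improvement,
                time.perf_counter() - t1,
            )

    return StudyReport(
        config=config,
        cohort_provenance=dict(cohort.provenance),
        ledger=ledger,
        family_choices=family_choices,
        decisions=decisions,
        model_tables=tables,
        n_analyzed=len(data),
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def _markdown_matrix(report: StudyReport) -> str:
    imp = report.hypothesis_matrix()
    delta = report.null_delta_matrix()
    sets = list(imp.columns)
    lines = ["| outcome | " + " | ".join(sets) + " |"]
    lines.append("|" + "---|" * (len(sets) + 1))
    for oc in imp.index:
        cells = [
            f"{'improved' if imp.loc[oc, s] else 'null retained'} (dAICc {delta.loc[oc, s]:.2f})"
            for s in sets
        ]
        lines.append(f"| {oc} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def write_report(report: StudyReport, out_dir) -> None:
    """Write report.md, tables/*.csv, decisions.json, and ledger.csv (deterministic bytes)."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)

    report.ledger.to_frame().to_csv(out / "ledger.csv", index=False)

    for (outcome, set_name), table in report.model_tables.items():
        df = table.table.copy()
        df["features"] = df["features"].map(lambda f: "+".join(f))
        df.to_csv(out / "tables" / f"{outcome}_{set_name}.csv", index=False, float_format="%.6f")

    decisions = {
        f"{oc}/{s}": d.to_dict() for (oc, s), d in sorted(report.decisions.items())
    }
    payload = {
        "config_hash": report.config.config_hash(),
        "seed": report.config.seed,
        "n_analyzed": report.n_analyzed,
        "exclusions": report.ledger.counts,
        "families": {oc: fc.to_dict() for oc, fc in report.family_choices.items()},
        "decisions": decisions,
    }
    with open(out / "decisions.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    md = [
        "# Tapping-cognition study report",
        "",
        f"- config hash: `{report.config.config_hash()}`",
        f"- seed: {report.config.seed}",
        f"- cohort: {report.cohort_provenance.get('source', 'files')}, "
        f"{report.ledger.n_total} participants, {report.n_analyzed} analyzed",
        f"- exclusions: {json.dumps(report.ledger.counts, sort_keys=True)}",
        "",
        "## Residual families",
        "",
    ]
    for oc, fc in report.family_choices.items():
        note = f" ({fc.fallback_reason})" if fc.fallback_reason else ""
        md.append(f"- {oc}: {fc.family}{note}")
    md += ["", "## Hypothesis matrix", "", _markdown_matrix(report), ""]
    md.append(
        "Adjusted pseudo-R2 in the model tables is the deviance-based convention "
        "1 - (D_model/D_intercept_only) x (n-1)/(n-k); equivalence is dAICc < 2."
    )
    with open(out / "report.md", "w") as fh:
        fh.write("\n".join(md) + "\n")
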