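"""End-to-end orchestration: generate -> impute -> score -> classify ->
multistate fits -> standardization -> reports.

Every stage writes its artifact plus a manifest (input hashes, seed,
config snapshot) into the output directory, so a run is reproducible from
its manifests alone and stages communicate only through on-disk files.
With multiple imputations the full analysis runs once per completed
dataset and posterior draws are pooled by simple mixing before effect
summaries are computed.
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

from . import __version__
from .cohort import (
    GeneratorConfig,
    apply_missingness,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .emdecline import DeclineConfig, decline_cohort, decline_events
from .impute import BartImputer
from .multistate import (
    AD_VAD_SPLIT,
    GROUP_CODES,
    ILLNESS_DEATH,
    SINGLE_EVENT,
    baseline_table,
    expand_person_period,
    fit_transitions,
)
from .standardize import (
    StandardizedCurve,
    arr_nnt,
    risk_ratio,
    sample_pseudodata,
    standardized_curves,
    write_rr_table,
)
from .trajectory import TrajectoryConfig, label_cohort

__all__ = ["RunConfig", "run"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "cvdtraj_run"
    cohort_csv: str | None = None  # analyze an existing cohort instead
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    apply_dropout: bool = True
    n_imputations: int = 2
    imputation_cycles: int = 3
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    decline: DeclineConfig = field(default_factory=DeclineConfig)
    dementia_age_floor: float = 70.0
    em_age_ceiling: float = 65.0
    split_ad_vad: bool = False
    bart_trees: int = 20
    bart_burn: int = 250
    bart_draws: int = 1000
    pseudodata_size: int = 10_000
    n_curve_draws: int = 1000
    seed: int = 0
    stages: tuple[str, ...] = (
        "generate", "impute", "classify", "fit", "standardize", "report"
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _manifest(outdir: Path, stage: str, seed: int, config: RunConfig, files: list[Path]):
    payload = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {f.name: _hash_file(f) for f in files if f.exists()},
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2))


def _pool_curves(chunks: list[StandardizedCurve]) -> StandardizedCurve:
    """Mix posterior draws across imputations (paired within each chunk)."""
    return StandardizedCurve(
        group=chunks[0].group,
        waves=chunks[0].waves,
        incidence=np.concatenate([c.incidence for c in chunks], axis=0),
    )


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns artifact paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {"output_dir": str(outdir)}
    stages = config.stages
    gen = config.generator

    # ---- generate ------------------------------------------------------
    cohort_path = outdir / "cohort.csv"
    truth_path = outdir / "truth.csv"
    if "generate" in stages and config.cohort_csv is None:
        gen = dataclasses.replace(gen, seed=gen.seed + config.seed)
        latent, truth = generate_cohort(gen)
        if config.apply_dropout:
            observed, truth = apply_missingness(latent, gen, truth)
        else:
            observed = latent
        write_cohort(observed, cohort_path)
        truth.to_csv(truth_path, index=False)
        log.info("generate: %d subjects, %d rows", gen.n_subjects, len(observed))
        _manifest(outdir, "generate", gen.seed, config, [])
        artifacts["cohort"] = str(cohort_path)
        artifacts["truth"] = str(truth_path)
        cohort = observed
    elif config.cohort_csv is not None:
        cohort = read_cohort(config.cohort_csv)
        artifacts["cohort"] = config.cohort_csv
    else:
        cohort = read_cohort(cohort_path)
    if stages == ("generate",) or set(stages) == {"generate"}:
        return artifacts

    # ---- impute --------------------------------------------------------
    completed = [cohort]
    if "impute" in stages:
        any_missing = (
            cohort.loc[cohort["state"].isin(["healthy", "AD", "VaD"]),
                       ["sbp_mmHg", "bmi_kg_m2", "smoker", "diabetes",
                        "bp_medication"]]
            .isna().any().any()
        )
        if any_missing:
            imputer = BartImputer(
                m=config.n_imputations,
                n_cycles=config.imputation_cycles,
                random_state=config.seed + 11,
            )
            completed = imputer.fit_transform(cohort)
            for i, df in enumerate(completed):
                p = outdir / f"cohort_imputed_{i + 1}.csv"
                write_cohort(df, p)
            log.info("impute: %d completed datasets", len(completed))
            _manifest(outdir, "impute", config.seed, config, [cohort_path])
        else:
            log.info("impute: no missing risk-factor cells; skipped")

    # ---- classify (per completed dataset) ------------------------------
    labels_list = []
    if "classify" in stages:
        for i, df in enumerate(completed):
            labels = label_cohort(df, config.trajectory,
                                  wave_spacing_years=gen.wave_spacing_years)
            labels_list.append(labels)
            labels.to_csv(outdir / f"trajectory_labels_{i + 1}.csv", index=False)
        counts = labels_list[0]["class"].value_counts()
        log.info("classify: %s", counts.to_dict())
        _manifest(outdir, "classify", config.seed, config, [cohort_path])
        artifacts["labels"] = str(outdir / "trajectory_labels_1.csv")
    else:
        return artifacts

    # ---- fit + standardize per imputation ------------------------------
    specs = AD_VAD_SPLIT if config.split_ad_vad else ILLNESS_DEATH
    model = "ad-vad" if config.split_ad_vad else "illness-death"
    targets = ["AD", "VaD"] if config.split_ad_vad else ["dementia"]
    group_levels = ("accelerated", "average", "stable")
    n_waves = gen.n_waves

    dem_curves: dict[str, dict[str, list]] = {t: {g: [] for g in group_levels} for t in targets}
    apoe_curves: dict[str, dict[tuple, list]] = {t: {} for t in targets}
    em_curves: dict[str, list] = {g: [] for g in group_levels}

    for i, df in enumerate(completed):
        labels = labels_list[i]
        groups = labels.set_index("subject_id")["class"]
        groups = groups[groups != "unclassified"]

        tables = expand_person_period(
            df, specs, groups=groups, min_entry_age=config.dementia_age_floor
        )
        posteriors = fit_transitions(
            tables,
            n_trees=config.bart_trees,
            n_burn=config.bart_burn,
            n_draws=config.bart_draws,
            random_state=config.seed + 101 * (i + 1),
        )
        if "fit" in stages and i == 0:
            for name, post in posteriors.items():
                (outdir / f"posterior_{name.replace('->', '_')}.json").write_text(
                    post.to_json()
                )
            _manifest(outdir, "fit", config.seed, config, [cohort_path])
        if "standardize" not in stages:
            continue

        base = baseline_table(
            df[df["subject_id"].isin(groups.index)]
        )
        base = base[base["baseline_age"] >= config.dementia_age_floor]
        bl = base.drop(columns="subject_id")
        pseudo = sample_pseudodata(bl, config.pseudodata_size,
                                   seed=config.seed + 13 * (i + 1))
        for t in targets:
            for g in group_levels:
                dem_curves[t][g].append(
                    standardized_curves(
                        posteriors, pseudo, g, GROUP_CODES, target_state=t,
                        n_waves=n_waves, model=model,
                        n_curve_draws=config.n_curve_draws,
                    )
                )
            for carrier in (0.0, 1.0):
                pseudo_c = sample_pseudodata(
                    bl, config.pseudodata_size,
                    seed=config.seed + 17 * (i + 1) + int(carrier),
                    condition={"apoe4_code": carrier},
                )
                for g in ("accelerated", "stable"):
                    apoe_curves[t].setdefault((carrier, g), []).append(
                        standardized_curves(
                            posteriors, pseudo_c, g, GROUP_CODES,
                            target_state=t, n_waves=n_waves, model=model,
                            n_curve_draws=config.n_curve_draws,
                        )
                    )

        # EM decline, younger stratum
        events = decline_events(df, config.decline)
        em_tab_cohort = decline_cohort(df, events)
        em_tables = expand_person_period(
            em_tab_cohort, SINGLE_EVENT, groups=groups,
            max_entry_age=config.em_age_ceiling,
        )
        if em_tables["nodecline->decline"].n_events > 0:
            em_post = fit_transitions(
                em_tables,
                n_trees=config.bart_trees,
                n_burn=config.bart_burn,
                n_draws=config.bart_draws,
                random_state=config.seed + 211 * (i + 1),
            )
            em_base = baseline_table(
                df[df["subject_id"].isin(groups.index)]
            )
            em_base = em_base[em_base["baseline_age"] <= config.em_age_ceiling]
            em_pseudo = sample_pseudodata(
                em_base.drop(columns="subject_id"), config.pseudodata_size,
                seed=config.seed + 19 * (i + 1),
            )
            for g in group_levels:
                em_curves[g].append(
                    standardized_curves(
                        em_post, em_pseudo, g, GROUP_CODES,
                        target_state="event", n_waves=n_waves, model="single",
                        n_curve_draws=config.n_curve_draws,
                    )
                )

    if "standardize" not in stages or "report" not in stages:
        return artifacts

    # ---- report --------------------------------------------------------
    summaries, effects = [], {}
    for t in targets:
        pooled = {g: _pool_curves(dem_curves[t][g]) for g in group_levels}
        for num, den in (("accelerated", "stable"), ("average", "stable")):
            s = risk_ratio(pooled[num], pooled[den])
            s.contrast = f"{t}: {num} vs stable"
            summaries.append(s)
        for g in ("average", "stable"):
            arr, nnt = arr_nnt(pooled[g], pooled["accelerated"])
            effects[f"{t}: ARR {g} vs accelerated"] = {
                "ARR": arr, "NNT": nnt, "reference_wave": int(pooled[g].waves[-1]),
            }
        for carrier, tag in ((1.0, "APOE4+"), (0.0, "APOE4-")):
            key_a = (carrier, "accelerated")
            if key_a in apoe_curves[t]:
                s = risk_ratio(
                    _pool_curves(apoe_curves[t][(carrier, "accelerated")]),
                    _pool_curves(apoe_curves[t][(carrier, "stable")]),
                )
                s.contrast = f"{t} [{tag}]: accelerated vs stable"
                summaries.append(s)
    if em_curves["accelerated"]:
        pooled_em = {g: _pool_curves(em_curves[g]) for g in group_levels}
        for num in ("accelerated", "average"):
            s = risk_ratio(pooled_em[num], pooled_em["stable"])
            s.contrast = f"EM decline: {num} vs stable"
            summaries.append(s)

    rr_path = outdir / "rr_table.csv"
    write_rr_table(summaries, rr_path)
    (outdir / "effects.json").write_text(json.dumps(effects, indent=2))
    table1 = _table1(cohort, labels_list[0])
    table1.to_csv(outdir / "trajectory_groups.csv", index=False)
    _manifest(outdir, "report", config.seed, config, [cohort_path, rr_path])
    artifacts.update(
        rr_table=str(rr_path),
        effects=str(outdir / "effects.json"),
        trajectory_groups=str(outdir / "trajectory_groups.csv"),
    )
    log.info("report: %d contrasts written", len(summaries))
    return artifacts


def _table1(cohort: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-trajectory-group characteristics at baseline."""
    base = (
        cohort.sort_values(["subject_id", "wave_index"])
        .groupby("subject_id").first().reset_index()
    )
    merged = base.merge(labels[["subject_id", "class"]], on="subject_id")
    rows = []
    for cls, sub in merged.groupby("class"):
        rows.append(
            {
                "class": cls,
                "n": len(sub),
                "baseline_age_mean": sub["age"].mean(),
                "female_pct": 100.0 * (sub["sex"] == "female").mean(),
                "apoe4_pct": 100.0 * (sub["apoe4"] == "carrier").mean(),
                "sbp_mean": sub["sbp_mmHg"].mean(),
                "bmi_mean": sub["bmi_kg_m2"].mean(),
                "em_mean": sub["em_composite"].mean(),
            }
        )
    return pd.DataFrame(rows)
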