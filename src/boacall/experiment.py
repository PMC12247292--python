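"""End-to-end experiment runner: simulate, assign, merge, score.

One replicate = founder simulation -> breeding program -> core-based
assignment of every crossbred cohort against its contemporaneous purebred
panels -> consensus across scenarios -> scoring against the tracked true
origins.  Replicates use independent random streams keyed by (stage,
replicate), so results are reproducible from the master seed and
invariant to replicate execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assign import assign_all
from .breeding import ProgramConfig, run_program, true_exotic_dosage
from .consensus import ThresholdGrid, consensus_matrix
from .founders import FounderConfig, simulate_founders
from .metrics import fst, score
from .windows import PhasingScheme, inject_switch_errors

_STAGES = {"founders": 1, "breeding": 2, "phasing": 3, "assignment": 4}


def stream(master_seed: int, replicate: int, stage: str) -> np.random.Generator:
    """Independent random stream for one (stage, replicate) pair."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(master_seed, replicate, _STAGES[stage]))
    )


@dataclass
class ExperimentConfig:
    """Settings of one full evaluation experiment."""

    founder: FounderConfig = field(default_factory=FounderConfig)
    program: ProgramConfig = field(default_factory=ProgramConfig)
    scheme: PhasingScheme = field(default_factory=PhasingScheme)
    thresholds: ThresholdGrid = field(default_factory=ThresholdGrid)
    n_replicates: int = 10
    master_seed: int = 1
    min_match_fraction: float | None = None
    all_votes_denominator: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "founder" in data:
            data["founder"] = FounderConfig(**data["founder"])
        if "program" in data:
            data["program"] = ProgramConfig(**data["program"])
        if "scheme" in data:
            sc = dict(data["scheme"])
            for key in ("core_lengths", "offset_modes"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            data["scheme"] = PhasingScheme(**sc)
        if "thresholds" in data:
            th = data["thresholds"]
            if isinstance(th, dict):
                th = th["thresholds"]
            data["thresholds"] = ThresholdGrid(tuple(th))
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))


@dataclass
class ReplicateResult:
    replicate: int
    founder_fst: float
    core_scores: pd.DataFrame  # one row per (generation, core_length, mode)
    consensus_scores: pd.DataFrame  # one row per (generation, threshold)
    exotic_dosage: pd.DataFrame  # mean true exotic fraction per generation


@dataclass
class ExperimentResult:
    """Aggregated result bundle over all replicates."""

    config: ExperimentConfig
    core_long: pd.DataFrame
    consensus_long: pd.DataFrame
    founder_fst: pd.DataFrame
    exotic_dosage: pd.DataFrame

    def table_yield_by_generation(self) -> pd.DataFrame:
        """Core-based mean calls per 1000 SNPs and yield per generation."""
        frame = self.core_long.copy()
        frame["local_per_1000"] = 1000 * frame["n_local_calls"] / frame["n_cells"]
        frame["exotic_per_1000"] = 1000 * frame["n_exotic_calls"] / frame["n_cells"]
        frame["unassigned_per_1000"] = 1000 * frame["n_unassigned"] / frame["n_cells"]
        g = frame.groupby("generation", sort=True)
        table = g[["local_per_1000", "exotic_per_1000", "unassigned_per_1000", "yield"]].mean()
        return table.reset_index()

    def table_by_core_length(self) -> pd.DataFrame:
        """Mean %correct / %incorrect / %unassigned / accuracy per core length."""
        g = self.core_long.groupby("core_length", sort=True)
        table = g[["pct_correct", "pct_incorrect", "pct_unassigned"]].mean()
        table["accuracy"] = table["pct_correct"] / (
            table["pct_correct"] + table["pct_incorrect"]
        )
        return table.reset_index()

    def table_by_threshold(self) -> pd.DataFrame:
        """Consensus mean percentages and accuracy per agreement threshold."""
        g = self.consensus_long.groupby("threshold", sort=True)
        table = g[["pct_correct", "pct_incorrect", "pct_unassigned"]].mean()
        table["accuracy"] = table["pct_correct"] / (
            table["pct_correct"] + table["pct_incorrect"]
        )
        return table.reset_index()

    def summary(self) -> dict:
        """Headline means over all strata (equal weight per stratum row)."""
        core = self.core_long
        cons = self.table_by_threshold()
        yield_by_gen = (
            core.groupby("generation", sort=True)["yield"].mean().to_numpy()
        )
        return {
            "core_pct_correct": float(core["pct_correct"].mean()),
            "core_pct_incorrect": float(core["pct_incorrect"].mean()),
            "core_pct_unassigned": float(core["pct_unassigned"].mean()),
            "core_accuracy": float(self.table_by_core_length()["accuracy"].mean()),
            "consensus_pct_correct": float(cons["pct_correct"].mean()),
            "consensus_pct_incorrect": float(cons["pct_incorrect"].mean()),
            "consensus_accuracy": float(cons["accuracy"].mean()),
            "founder_fst_mean": float(self.founder_fst["fst"].mean()),
            "yield_by_generation": yield_by_gen.tolist(),
        }


def run_replicate(cfg: ExperimentConfig, rep: int) -> ReplicateResult:
    """Run one replicate of the full pipeline."""
    rng_f = stream(cfg.master_seed, rep, "founders")
    founder_cfg = replace(cfg.founder, seed=int(rng_f.integers(1, 2**31 - 1)))
    founders = simulate_founders(founder_cfg)
    founder_fst = fst(
        founders.exotic().haplotypes, founders.local_pooled().haplotypes
    )

    program = run_program(founders, cfg.program, stream(cfg.master_seed, rep, "breeding"))

    rng_p = stream(cfg.master_seed, rep, "phasing")
    rate = cfg.scheme.switch_error_rate

    core_rows, cons_rows, dosage_rows = [], [], []
    n_premix = cfg.program.n_premix_generations
    for r in range(1, cfg.program.n_cross_rounds + 1):
        cohort = program.crossbred[r - 1]
        exotic_panel = program.exotic_purebred[n_premix + r - 1].haplo
        local_panel = program.local_purebred[n_premix + r - 1].haplo
        cross_hap = cohort.haplo
        if rate > 0:
            cross_hap = inject_switch_errors(cross_hap, rate, rng_p)
            exotic_panel = inject_switch_errors(exotic_panel, rate, rng_p)
            local_panel = inject_switch_errors(local_panel, rate, rng_p)

        tensor = assign_all(
            cross_hap,
            exotic_panel,
            local_panel,
            cfg.scheme,
            min_match_fraction=cfg.min_match_fraction,
        )
        truth = cohort.origin
        for (length, off), _ in tensor.scenarios.items():
            row = score(tensor.expand(length, off), truth).iloc[0].to_dict()
            row.update(
                replicate=rep,
                generation=r,
                core_length=length,
                mode="offset" if off else "no_offset",
            )
            core_rows.append(row)

        cons = consensus_matrix(
            tensor, cfg.thresholds, all_votes_denominator=cfg.all_votes_denominator
        )
        for tau in cons.thresholds:
            row = score(cons.at(tau), truth).iloc[0].to_dict()
            row.update(replicate=rep, generation=r, threshold=tau)
            cons_rows.append(row)

        dosage_rows.append(
            {
                "replicate": rep,
                "generation": r,
                "mean_exotic_fraction": float(true_exotic_dosage(truth).mean()),
            }
        )

    return ReplicateResult(
        replicate=rep,
        founder_fst=founder_fst,
        core_scores=pd.DataFrame(core_rows),
        consensus_scores=pd.DataFrame(cons_rows),
        exotic_dosage=pd.DataFrame(dosage_rows),
    )


def run_experiment(cfg: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run all replicates and assemble the aggregated bundle."""
    reps = []
    for rep in range(cfg.n_replicates):
        if progress:
            print(f"[boacall] replicate {rep + 1}/{cfg.n_replicates}", flush=True)
        reps.append(run_replicate(cfg, rep))
    return ExperimentResult(
        config=cfg,
        core_long=pd.concat([r.core_scores for r in reps], ignore_index=True),
        consensus_long=pd.concat([r.consensus_scores for r in reps], ignore_index=True),
        founder_fst=pd.DataFrame(
            {"replicate": [r.replicate for r in reps], "fst": [r.founder_fst for r in reps]}
        ),
        exotic_dosage=pd.concat([r.exotic_dosage for r in reps], ignore_index=True),
    )


def write_outputs(result: ExperimentResult, outdir: str | Path) -> list[Path]:
    """Write the result bundle's CSV mirrors and provenance records."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    emit(result.core_long, "core_scores_long.csv")
    emit(result.consensus_long, "consensus_scores_long.csv")
    emit(result.founder_fst, "founder_fst.csv")
    emit(result.exotic_dosage, "exotic_dosage.csv")
    emit(result.table_yield_by_generation(), "yield_by_generation.csv")
    emit(result.table_by_core_length(), "scores_by_core_length.csv")
    emit(result.table_by_threshold(), "consensus_by_threshold.csv")
    save_config(result.config, outdir / "config.yaml")
    written.append(outdir / "config.yaml")
    provenance = {
        "master_seed": result.config.master_seed,
        "config_hash": result.config.config_hash(),
        "summary": result.summary(),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    written.append(outdir / "provenance.json")
    return written
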