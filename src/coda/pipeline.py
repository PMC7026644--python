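"""End-to-end orchestration: simulate -> preprocess -> score -> fold -> eval.

A run is driven by a :class:`RunConfig` (YAML round-trippable), writes every
intermediate table into an append-only run directory, and is byte-for-byte
reproducible from the master seed, from which per-stage seeds are derived
deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluate, fold, scoring, simulate, structures
from .energy import EnergyModel
from .fold import AnnealSchedule
from .library import ActivityTable, WildType

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the individual modules."""

    out_dir: str = "coda_run"
    seed: int = 0
    # inputs; when absent, the synthetic benchmark is generated
    wt_fasta: str | None = None
    activity_tsv: str | None = None
    reference: str | None = None
    # synthetic library
    n_variants: int = 30_000
    depth: int = 50
    mutation_rate: float = 0.008
    n_rounds: int = 3
    at_bias: float = 2.5
    # preprocessing
    min_reads: int = 5
    use_triples: bool = True
    # CODA
    C: float = 2000.0
    gamma: float = 2.0
    shift: float = 0.2
    k_sd: float = 3.0
    max_train: int | None = 2000
    # folding
    weight: float = 2.0
    penalty: float = 3.0
    n_runs: int = 100
    t_initial: float = 10.0
    cooling_factor: float = 0.95
    t_final: float = 0.1
    steps_per_temperature: int = 500_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        return int(
            np.random.SeedSequence([self.seed, tag]).generate_state(1)[0] % (2**31)
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, persisting artifacts under ``config.out_dir``.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}

    # --- stage 1: inputs ---------------------------------------------------
    try:
        reference = None
        if config.activity_tsv is not None:
            if config.wt_fasta is None:
                raise ValueError("config field 'wt_fasta' is required with activity_tsv")
            wt = WildType.from_fasta(config.wt_fasta)
            table = ActivityTable.from_tsv(config.activity_tsv, wt)
            if config.reference:
                reference = structures.read_reference(config.reference)
        else:
            ribozyme = simulate.make_default_benchmark(seed=config.seed)
            wt = ribozyme.wild_type
            reference = ribozyme.structure
            lib = simulate.LibraryParams(
                n_variants=config.n_variants,
                depth=config.depth,
                mutation_rate=config.mutation_rate,
                n_rounds=config.n_rounds,
                at_bias=config.at_bias,
            )
            variants, truth = simulate.simulate_library(
                ribozyme, lib, rng=config.stage_seed("simulate")
            )
            truth.to_csv(out / "truth_ra.tsv", sep="\t", index=False)
            structures.write_ct(
                out / "truth_structure.ct", reference.to_structure(), wt.sequence
            )
            table = simulate.library_to_activity_table(
                ribozyme, variants, min_reads=config.min_reads, use_triples=config.use_triples
            )
        (out / "wt.fa").write_text(f">{wt.id}\n{wt.sequence}\n")
        table.to_tsv(out / "activity.tsv")
        summary["n_singles"] = len(table.singles)
        summary["n_doubles"] = len(table.doubles)
        summary["single_coverage"] = table.single_coverage
        summary["double_coverage"] = table.double_coverage
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {e}") from e

    # --- stage 2: CODA scoring ---------------------------------------------
    try:
        model, mixture, score_map = scoring.run_coda(
            table,
            C=config.C,
            gamma=config.gamma,
            shift=config.shift,
            k_sd=config.k_sd,
            max_train=config.max_train,
            seed=config.stage_seed("svr"),
        )
        score_map.to_tsv(out / "scores.tsv", out / "scores_by_position.tsv")
        summary["mixture"] = {
            "a1": mixture.a1, "sd1": mixture.sd1,
            "a2": mixture.a2, "sd2": mixture.sd2,
            "p_paired": mixture.p_paired,
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'coda' failed: {e}") from e

    # --- stage 3: folding ---------------------------------------------------
    try:
        energy_model = EnergyModel(
            lone_penalty=config.penalty, noncanonical_penalty=config.penalty
        )
        schedule = AnnealSchedule(
            t_initial=config.t_initial,
            cooling_factor=config.cooling_factor,
            t_final=config.t_final,
            steps_per_temperature=config.steps_per_temperature,
            seed=config.stage_seed("fold"),
        )
        ensemble = fold.fold_ensemble(
            wt.sequence,
            model=energy_model,
            ps_map=score_map.per_position,
            weight=config.weight,
            schedule=schedule,
            n_runs=config.n_runs,
        )
        ensemble.to_tsv(out / "pair_frequency.tsv")
        structures.write_dotbracket(
            out / "consensus.db", ensemble.consensus, wt.sequence, name="consensus"
        )
        structures.write_ct(out / "consensus.ct", ensemble.consensus, wt.sequence)
        summary["n_consensus_pairs"] = len(ensemble.consensus.pairs())
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fold' failed: {e}") from e

    # --- stage 4: evaluation -------------------------------------------------
    if reference is not None:
        try:
            counts = evaluate.confusion(ensemble.consensus.pairs(), reference)
            summary["consensus"] = {
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "mcc": evaluate.mcc(counts),
                "sensitivity": evaluate.sensitivity(counts),
                "precision": evaluate.precision(counts),
            }
            threshold, mcounts = evaluate.max_mcc_threshold(
                score_map.per_position, reference
            )
            _, auc = evaluate.pr_curve(score_map.per_position, reference)
            summary["coda_scores"] = {
                "max_mcc": evaluate.mcc(mcounts),
                "threshold": threshold,
                "auc_pr": auc,
            }
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'eval' failed: {e}") from e

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
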