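"""End-to-end orchestration: simulate (or load) -> per-fraction contrasts ->
state classification -> summary -> optional set enrichment, with a JSON
manifest recording config, seed, version and per-stage row counts.

A single master seed drives everything; stage and pair sub-seeds are
derived deterministically so adding stages never perturbs earlier stages'
random streams, and re-running an identical config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .diffexpr import contrast_to_frame, global_correction, test_contrast
from .enrichment import enrichment_grid, grid_to_frame
from .errors import ValidationError
from .io import (FRACTIONS, read_abundance, read_gmt, read_universe,
                 write_abundance, write_table)
from .simulate import SimulationConfig, simulate_polysome_experiment
from .states import classify_states, summarize_states

logger = logging.getLogger("polystate")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int | None = None
    alpha: float = 0.05
    detection_threshold: float = 1.0
    pseudocount: float = 1.0
    n_permutations: int = 10_000
    # either simulate (dict of SimulationConfig overrides) or matrix+samples
    simulate: dict | None = None
    matrix: str | None = None
    samples: str | None = None
    # optional enrichment stage
    input_gmt: str | None = None
    target_gmt: str | None = None
    universe: str | None = None
    clip_to_universe: bool = False
    global_correction: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.detection_threshold < 0:
            raise ValidationError("detection_threshold must be >= 0")
        if self.simulate is None and (self.matrix is None or self.samples is None):
            raise ValidationError(
                "provide either a 'simulate' block or matrix + samples paths")
        if self.simulate is not None and self.seed is None:
            raise ValidationError("a seed is required when simulating")
        enrich_given = [self.input_gmt, self.target_gmt, self.universe]
        if any(p is not None for p in enrich_given) and not all(
                p is not None for p in enrich_given):
            raise ValidationError(
                "enrichment needs input_gmt, target_gmt and universe together")
        if any(p is not None for p in enrich_given) and self.seed is None:
            raise ValidationError("a seed is required for permutation enrichment")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def demo_config(out_dir: str | Path, seed: int = 7) -> RunConfig:
    """Bundled demonstration: simulate 2,000 isoforms with planted states
    and classify them."""
    return RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        simulate={
            "n_isoforms": 2000,
            "state_proportions": {
                "steady": 0.7, "transcription_up": 0.05, "transcription_down": 0.05,
                "repressed": 0.1, "derepressed": 0.1,
            },
            "detection_fraction": 0.1,
        },
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline stages in order and write results + manifest.

    Returns the manifest dict. Any stage error aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "polystate",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "outputs": {},
    }

    written: list[Path] = []

    def record(stage: str, path: Path, n_rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[path.name] = n_rows
        manifest["outputs"][path.name] = str(path)
        written.append(path)

    try:
        _run_stages(config, out, manifest, record)
    except Exception as exc:
        # a stage failure must not leave partial outputs behind
        for path in written:
            path.unlink(missing_ok=True)
        exc.add_note(f"pipeline aborted; partial outputs removed from {out}")
        raise

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _run_stages(config: RunConfig, out: Path, manifest: dict, record) -> None:
    # -- stage 1: obtain the abundance matrix --------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(seed=config.seed,
                                   detection_threshold=config.detection_threshold,
                                   **config.simulate)
        logger.info("simulate: %d isoforms, %d replicates",
                    sim_cfg.n_isoforms, sim_cfg.n_replicates)
        matrix, truth = simulate_polysome_experiment(sim_cfg)
        write_abundance(matrix, out / "abundance.tsv", out / "samples.tsv")
        record("simulate", out / "abundance.tsv", len(matrix.isoform_ids))
        record("simulate", out / "samples.tsv", len(matrix.sample_ids))
        p = write_table(truth, out / "truth.tsv")
        record("simulate", p, len(truth))
    else:
        logger.info("load: %s", config.matrix)
        matrix = read_abundance(config.matrix, config.samples)

    # -- stage 2: per-fraction contrasts --------------------------------
    contrasts = {}
    for fraction in FRACTIONS:
        res = test_contrast(matrix, fraction, alpha=config.alpha,
                            pseudocount=config.pseudocount,
                            detection_threshold=config.detection_threshold)
        contrasts[fraction] = res
    if config.global_correction:
        corrected = global_correction([contrasts[f] for f in FRACTIONS])
        contrasts = dict(zip(FRACTIONS, corrected))
    for fraction, res in contrasts.items():
        p = write_table(contrast_to_frame(res), out / f"contrast_{fraction}.tsv")
        record("contrast", p, len(res.table))
        logger.info("contrast %s: %d isoforms, %d significant at q<=%g",
                    fraction, len(res.table),
                    int((res.table["q_value"] <= config.alpha).sum()), config.alpha)

    # -- stage 3: classification ----------------------------------------
    table = classify_states(contrasts["input"], contrasts["monosome"],
                            contrasts["polysome"], alpha=config.alpha)
    p = write_table(table.reset_index(names="isoform_id"), out / "state_table.tsv")
    record("classify", p, len(table))
    summary = summarize_states(table)
    p = write_table(summary.to_frame(), out / "state_summary.tsv")
    record("summarize", p, 1)
    logger.info("classified %d isoforms; translationally altered: %d",
                summary.n_total, summary.translationally_altered)

    # -- stage 4: optional enrichment ------------------------------------
    if config.input_gmt is not None:
        inputs = read_gmt(config.input_gmt)
        targets = read_gmt(config.target_gmt)
        universe = read_universe(config.universe)
        results = enrichment_grid(inputs, targets, universe,
                                  n_permutations=config.n_permutations,
                                  seed=config.seed,
                                  clip_to_universe=config.clip_to_universe)
        p = write_table(grid_to_frame(results), out / "enrichment.tsv")
        record("enrich", p, len(results))
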