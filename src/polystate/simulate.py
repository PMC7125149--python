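"""Synthetic polysome-profiling data with planted ground truth.

The generator emulates a two-stage, three-fraction profiling design —
input (total RNA), monosome (40S-60S-80S) and polysome pools, each with a
fixed number of biological replicates per stage (default 3, 18 samples in
all) — and plants translational-regulation states whose identities are
returned as a truth table, so every downstream stage of the pipeline can be
scored against a known answer.

Abundances are drawn from a negative binomial around per-(isoform, sample)
means (variance = mu + dispersion * mu^2), the standard overdispersed
stand-in for RNA-seq-derived abundance noise; a Gaussian-on-log alternative
is available via ``noise_model="lognormal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexpr import DEFAULT_DETECTION_THRESHOLD
from .errors import ConfigurationError, ValidationError
from .fractions import PROFILE_FRACTIONS
from .io import FRACTIONS, AbundanceMatrix
from .states import STATES


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated profiling experiment.

    Parameters
    ----------
    n_isoforms
        Number of simulated isoforms.
    n_replicates
        Biological replicates per (stage, fraction) cell; the emulated
        design uses 3.
    baseline_mean
        Mean abundance (FPKM-like units) of an unregulated isoform in
        every cell.
    dispersion
        Negative-binomial dispersion phi; variance = mu + phi * mu^2.
        phi = 0 degenerates to Poisson noise.
    state_proportions
        Mapping state -> fraction of isoforms planted in that state;
        must sum to 1. Missing states get proportion 0.
    effect_fold
        Multiplicative fold (> 1) applied to the affected cell(s) of a
        planted state.
    detection_fraction
        Fraction of the derepressed isoforms whose input abundance is
        planted below the detection threshold at both stages.
    seed
        RNG seed; identical configs and seeds give bit-identical output.
    noise_model
        "nb" (negative binomial) or "lognormal" (Gaussian on log scale
        with matched mean and CV).
    mass_conserving
        If True, polysome mass gained/lost by repression or derepression
        is taken from / returned to the monosome pool (clamped at zero).
    detection_threshold, below_detection_scale
        Below-detection isoforms get input mean
        ``below_detection_scale * detection_threshold``.
    stage_labels
        The two stage names, earlier first.
    """

    n_isoforms: int
    n_replicates: int = 3
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    state_proportions: dict[str, float] = field(
        default_factory=lambda: {"steady": 1.0})
    effect_fold: float = 4.0
    detection_fraction: float = 0.0
    seed: int | None = None
    noise_model: str = "nb"
    mass_conserving: bool = False
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD
    below_detection_scale: float = 0.1
    stage_labels: tuple[str, str] = ("E13", "E16")

    def __post_init__(self) -> None:
        if self.n_isoforms < 1:
            raise ConfigurationError("n_isoforms must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.baseline_mean <= 0 or self.effect_fold <= 0:
            raise ConfigurationError("baseline_mean and effect_fold must be > 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        unknown = set(self.state_proportions) - set(STATES)
        if unknown:
            raise ConfigurationError(f"unknown states: {sorted(unknown)}")
        if any(v < 0 for v in self.state_proportions.values()):
            raise ConfigurationError("state proportions must be non-negative")
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"state_proportions must sum to 1 (got {total!r})")
        if not 0 <= self.detection_fraction <= 1:
            raise ConfigurationError("detection_fraction must be in [0, 1]")
        if self.noise_model not in ("nb", "lognormal"):
            raise ConfigurationError("noise_model must be 'nb' or 'lognormal'")
        if len(self.stage_labels) != 2 or self.stage_labels[0] == self.stage_labels[1]:
            raise ConfigurationError("stage_labels must be two distinct names")


def _state_counts(config: SimulationConfig) -> dict[str, int]:
    """Integer state counts by largest-remainder apportionment."""
    n = config.n_isoforms
    props = {s: config.state_proportions.get(s, 0.0) for s in STATES}
    raw = {s: p * n for s, p in props.items()}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda s: (raw[s] - counts[s]), reverse=True)
    for s in remainders[:short]:
        counts[s] += 1
    return counts


def planted_means(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected abundance per (isoform, stage, fraction) plus the truth table.

    Effects by state (fold f = ``effect_fold``, baseline b, stage B = later):

    * transcription_up / _down — all fractions at stage B scaled by f / 1/f.
    * repressed — polysome at stage B scaled by 1/f; input unchanged.
    * derepressed — polysome at stage B scaled by f; input unchanged.
    * monosome_shift — monosome at stage B scaled by f.
    * steady — no change.

    In mass-conserving mode the polysome mass change is balanced by the
    monosome pool: repression adds b(1 − 1/f) to the stage-B monosome mean,
    derepression removes min(b, b(f − 1)) from it (a pool cannot donate
    more mass than it holds).
    """
    counts = _state_counts(config)
    states: list[str] = []
    for s in STATES:
        states.extend([s] * counts[s])
    ids = [f"iso{i:06d}" for i in range(config.n_isoforms)]
    truth = pd.DataFrame({"isoform_id": ids, "state": states})
    truth["fold"] = np.where(truth["state"] == "steady", 1.0, config.effect_fold)
    n_dere = counts["derepressed"]
    n_below = int(np.floor(config.detection_fraction * n_dere))
    below = np.zeros(config.n_isoforms, dtype=bool)
    dere_idx = np.flatnonzero((truth["state"] == "derepressed").to_numpy())
    below[dere_idx[:n_below]] = True
    truth["below_detection"] = below

    b, f = config.baseline_mean, config.effect_fold
    stage_a, stage_b = config.stage_labels
    cols = pd.MultiIndex.from_product(
        [config.stage_labels, FRACTIONS], names=["stage", "fraction"])
    means = pd.DataFrame(b, index=pd.Index(ids, name="isoform_id"), columns=cols)
    state_arr = truth["state"].to_numpy()

    def cell(stage, fraction):
        return (stage, fraction)

    m = means.to_numpy()
    col_pos = {c: i for i, c in enumerate(means.columns)}
    for st, effect in (("transcription_up", f), ("transcription_down", 1 / f)):
        rows = state_arr == st
        for fr in FRACTIONS:
            m[rows, col_pos[cell(stage_b, fr)]] = b * effect
    rows = state_arr == "repressed"
    m[rows, col_pos[cell(stage_b, "polysome")]] = b / f
    if config.mass_conserving:
        m[rows, col_pos[cell(stage_b, "monosome")]] = b + b * (1 - 1 / f)
    rows = state_arr == "derepressed"
    m[rows, col_pos[cell(stage_b, "polysome")]] = b * f
    if config.mass_conserving:
        m[rows, col_pos[cell(stage_b, "monosome")]] = max(0.0, b - b * (f - 1))
    rows = state_arr == "monosome_shift"
    m[rows, col_pos[cell(stage_b, "monosome")]] = b * f
    # below-detection derepressed: input mean under the threshold at both stages
    low = config.below_detection_scale * config.detection_threshold
    for stg in (stage_a, stage_b):
        m[below, col_pos[cell(stg, "input")]] = low
    means = pd.DataFrame(m, index=means.index, columns=means.columns)
    return means, truth


def _sample_noise(rng: np.random.Generator, mu: np.ndarray,
                  dispersion: float, noise_model: str) -> np.ndarray:
    if noise_model == "lognormal":
        sigma2 = np.log1p(dispersion)  # matches the NB CV^2 (mu >> 1 regime)
        return mu * np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=mu.shape))
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def simulate_polysome_experiment(config: SimulationConfig) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Simulate one two-stage, three-fraction profiling experiment.

    Returns the abundance matrix (2 stages x 3 fractions x n_replicates
    samples) and the truth table (isoform_id, state, fold, below_detection),
    which covers every simulated isoform exactly once.
    """
    means, truth = planted_means(config)
    rng = np.random.default_rng(config.seed)
    sample_ids, meta_rows, blocks = [], [], []
    for stage in config.stage_labels:
        for fraction in FRACTIONS:
            mu = means[(stage, fraction)].to_numpy()[:, None]
            mu_rep = np.broadcast_to(mu, (config.n_isoforms, config.n_replicates))
            blocks.append(_sample_noise(rng, mu_rep, config.dispersion,
                                        config.noise_model))
            for rep in range(1, config.n_replicates + 1):
                sample_ids.append(f"{stage}_{fraction}_r{rep}")
                meta_rows.append({"stage": stage, "fraction": fraction,
                                  "replicate": rep})
    values = pd.DataFrame(np.hstack(blocks), index=means.index, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return AbundanceMatrix(values=values, sample_meta=meta), truth


def simulate_fraction_profiles(n_replicates: int = 3,
                               baseline_composition=(0.4, 0.3, 0.2, 0.1),
                               shift_delta: float = 0.2,
                               noise_sd: float = 0.05,
                               seed: int | None = None,
                               condition_labels: tuple[str, str] = ("baseline", "shifted"),
                               ) -> pd.DataFrame:
    """Simulate raw F/M/LP/HP profiles for two conditions.

    Condition 2 moves ``shift_delta`` of compositional mass from the free
    (F) pool to the heavy-polysome (HP) pool before multiplicative
    log-normal noise of scale ``noise_sd`` is applied per component.
    Returns a table with columns condition, replicate, F, M, LP, HP.
    """
    base = np.asarray(baseline_composition, dtype=float)
    if base.shape != (4,):
        raise ValidationError("baseline_composition needs exactly 4 components")
    if (base < 0).any():
        raise ValidationError("baseline_composition components must be non-negative")
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    shifted = base.copy()
    shifted[0] -= shift_delta
    shifted[3] += shift_delta
    if shifted[0] < 0:
        raise ValidationError(
            f"shift_delta={shift_delta} exceeds the free-pool mass {base[0]}")
    rng = np.random.default_rng(seed)
    rows = []
    for label, comp in zip(condition_labels, (base, shifted)):
        noise = np.exp(rng.normal(0.0, noise_sd, size=(n_replicates, 4)))
        raw = comp[None, :] * noise
        for rep in range(1, n_replicates + 1):
            rows.append({"condition": label, "replicate": rep,
                         **dict(zip(PROFILE_FRACTIONS, raw[rep - 1]))})
    return pd.DataFrame(rows)


def simulate_gene_sets(n_universe: int, n_input: int, n_target: int,
                       planted_overlap: int, seed: int | None = None,
                       ) -> tuple[list[str], frozenset[str], frozenset[str]]:
    """Construct a universe plus input/target sets with an exact overlap.

    |input ∩ target| equals ``planted_overlap`` exactly; all members are
    drawn from the universe without replacement.
    """
    if n_input > n_universe or n_target > n_universe:
        raise ConfigurationError("set sizes cannot exceed the universe")
    if planted_overlap > min(n_input, n_target):
        raise ConfigurationError(
            f"planted_overlap={planted_overlap} exceeds min(n_input, n_target)")
    if planted_overlap < 0:
        raise ConfigurationError("planted_overlap must be >= 0")
    if n_input + n_target - planted_overlap > n_universe:
        raise ConfigurationError("universe too small for the requested sets")
    universe = [f"g{i:06d}" for i in range(n_universe)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_universe)
    shared = perm[:planted_overlap]
    input_only = perm[planted_overlap:n_input]
    target_only = perm[n_input:n_input + (n_target - planted_overlap)]
    input_set = frozenset(universe[i] for i in np.concatenate([shared, input_only]))
    target_set = frozenset(universe[i] for i in np.concatenate([shared, target_only]))
    return universe, input_set, target_set


def steady_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every isoform steady (global-null simulation)."""
    return replace(config, state_proportions={"steady": 1.0}, detection_fraction=0.0)
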