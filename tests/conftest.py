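import numpy as np
import pandas as pd
import pytest

from polystate.diffexpr import ContrastResult
from polystate.io import FRACTIONS, AbundanceMatrix


def build_matrix(values_by_cell: dict, stages=("E13", "E16"), n_replicates=3,
                 isoform_ids=None) -> AbundanceMatrix:
    """Assemble an AbundanceMatrix from {(stage, fraction): (n_iso, n_rep) array}.

    Missing cells default to a constant 8.0.
    """
    some = next(iter(values_by_cell.values()))
    n_iso = np.asarray(some).shape[0]
    if isoform_ids is None:
        isoform_ids = [f"iso{i}" for i in range(n_iso)]
    cols, meta_rows, blocks = [], [], []
    for stage in stages:
        for fraction in FRACTIONS:
            block = values_by_cell.get(
                (stage, fraction), np.full((n_iso, n_replicates), 8.0))
            blocks.append(np.asarray(block, dtype=float))
            for rep in range(1, n_replicates + 1):
                cols.append(f"{stage}_{fraction}_r{rep}")
                meta_rows.append({"stage": stage, "fraction": fraction,
                                  "replicate": rep})
    values = pd.DataFrame(np.hstack(blocks), index=isoform_ids, columns=cols)
    meta = pd.DataFrame(meta_rows, index=pd.Index(cols, name="sample_id"))
    return AbundanceMatrix(values=values, sample_meta=meta)


def make_contrast(directions, fraction="polysome", alpha=0.05,
                  detected_a=None, detected_b=None,
                  stage_a="E13", stage_b="E16") -> ContrastResult:
    """Construct a ContrastResult directly from desired direction calls.

    "up"/"down" get q = alpha/5 with a matching-sign log2FC; "none" gets
    q = 0.5.
    """
    directions = list(directions)
    n = len(directions)
    idx = pd.Index([f"iso{i}" for i in range(n)])
    sig = np.array([d != "none" for d in directions])
    lfc = np.array([{"up": 2.0, "down": -2.0, "none": 0.0}[d] for d in directions])
    q = np.where(sig, alpha / 5, 0.5)
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "statistic": lfc * 3,
            "p_value": q / 2,
            "q_value": q,
            "detected_A": np.ones(n, bool) if detected_a is None else np.asarray(detected_a),
            "detected_B": np.ones(n, bool) if detected_b is None else np.asarray(detected_b),
            "degenerate": np.zeros(n, bool),
        },
        index=idx,
    )
    res = ContrastResult(fraction=fraction, stage_a=stage_a, stage_b=stage_b,
                         alpha=alpha, table=table)
    table["direction"] = res.directions(alpha)
    return res


def bh_step_up_bruteforce(p):
    """Independent Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@pytest.fixture
def small_matrix():
    """2 isoforms x 18 samples, constant abundance 8 everywhere."""
    return build_matrix({("E13", "input"): np.full((2, 3), 8.0)})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
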