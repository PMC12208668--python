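"""Monte-Carlo calibration studies for the pipeline's statistics.

These routines measure, by simulation against the generator's ground
truth, the operating characteristics the pipeline claims: CI coverage of
the ribbon, type-I error of the two-group comparison, family-wise error
of the Dunnett adjustment, label recovery of the shape classifier, the
chemotaxis-index estimator's consistency, and the image round trip.
All are seeded and deterministic.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .chemo import dunnett_critical_value
from .group_stats import compare_groups, pointwise_mean_ci
from .responses import ClassifierThresholds, classify_trace
from .stacks import extract_traces
from .synthetic import (
    CLASS_LABELS,
    NoiseModel,
    RoiSpec,
    simulate_chemotaxis_plate,
    simulate_cohort,
    simulate_stack,
    simulate_trace,
)
from .traces import StimulusProtocol, normalize_trace

__all__ = [
    "ci_coverage",
    "type1_error_rate",
    "dunnett_fwer",
    "dunnett_power",
    "classifier_recovery",
    "chemotaxis_estimator",
    "stack_roundtrip_rms",
]


def ci_coverage(
    n_reps: int = 10_000,
    n_traces: int = 12,
    n_frames: int = 120,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of pointwise t-intervals covering the true mean (0) over
    ``n_reps`` simulated groups of Gaussian traces."""
    rng = np.random.default_rng(seed)
    covered = 0
    total = 0
    for _ in range(n_reps):
        arr = rng.normal(0.0, 1.0, size=(n_traces, n_frames))
        _, lo, hi = pointwise_mean_ci(arr, alpha=alpha)
        covered += int(((lo <= 0.0) & (0.0 <= hi)).sum())
        total += n_frames
    return covered / total


def type1_error_rate(
    n_reps: int = 10_000, n_per_group: int = 20, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of compare_groups under the null (both N(0,1))."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        res = compare_groups(
            rng.normal(size=n_per_group), rng.normal(size=n_per_group)
        )
        rejections += res.p_value < alpha
    return rejections / n_reps


def _dunnett_t_stats(
    cells: np.ndarray, control_idx: int = 0
) -> Tuple[np.ndarray, float, int]:
    """Many-to-one t statistics for one (n_genotypes, n_salts, n) design.

    Pools the residual variance over all cells (the full cell-means
    model, as the two-way ANOVA with interaction does) and compares each
    non-control genotype with the control within every salt.
    """
    g, s, n = cells.shape
    cell_means = cells.mean(axis=2)
    ss_resid = ((cells - cell_means[:, :, None]) ** 2).sum()
    df_resid = g * s * (n - 1)
    mse = ss_resid / df_resid
    se = np.sqrt(mse * (2.0 / n))
    others = [i for i in range(g) if i != control_idx]
    t = (cell_means[others, :] - cell_means[control_idx, :]) / se
    return t, mse, df_resid


def dunnett_fwer(
    n_reps: int = 5_000,
    n_genotypes: int = 3,
    n_salts: int = 2,
    n_per_cell: int = 12,
    mu: float = 0.3,
    sd: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error of the Dunnett comparisons under a global null.

    Every cell is N(mu, sd^2); a family is the set of genotype-vs-control
    comparisons within one salt; returns the fraction of (replicate,
    family) pairs with at least one rejection at the Monte-Carlo Dunnett
    critical value.
    """
    rng = np.random.default_rng(seed)
    k = n_genotypes - 1
    df_resid = n_genotypes * n_salts * (n_per_cell - 1)
    crit = dunnett_critical_value(
        [n_per_cell] * k, n_per_cell, df_resid, alpha=alpha, seed=seed + 1
    )
    hits = 0
    for _ in range(n_reps):
        cells = rng.normal(mu, sd, size=(n_genotypes, n_salts, n_per_cell))
        t, _, _ = _dunnett_t_stats(cells)
        hits += int((np.abs(t).max(axis=0) > crit).sum())  # per-salt families
    return hits / (n_reps * n_salts)


def dunnett_power(
    n_reps: int = 1_000,
    n_genotypes: int = 3,
    n_salts: int = 2,
    n_per_cell: int = 12,
    mu: float = 0.3,
    sd: float = 0.1,
    shift_sds: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, float]:
    """Detection rate for one shifted cell (genotype 1, salt 0) and the
    false-rejection rate of the remaining comparisons."""
    rng = np.random.default_rng(seed)
    k = n_genotypes - 1
    df_resid = n_genotypes * n_salts * (n_per_cell - 1)
    crit = dunnett_critical_value(
        [n_per_cell] * k, n_per_cell, df_resid, alpha=alpha, seed=seed + 1
    )
    hit_shifted = 0
    others_rejected = 0
    n_other_families = 0
    for _ in range(n_reps):
        cells = rng.normal(mu, sd, size=(n_genotypes, n_salts, n_per_cell))
        cells[1, 0] += shift_sds * sd
        t, _, _ = _dunnett_t_stats(cells)
        hit_shifted += abs(t[0, 0]) > crit
        # families untouched by the shift: the other salts
        others_rejected += int((np.abs(t[:, 1:]).max(axis=0) > crit).sum())
        n_other_families += n_salts - 1
    return {
        "power_shifted": hit_shifted / n_reps,
        "fwer_null_families": others_rejected / n_other_families,
    }


def classifier_recovery(
    n_per_class: int = 40,
    sigma_shot: float = 8.0,
    amplitude_range: Tuple[float, float] = (40.0, 80.0),
    protocol: StimulusProtocol = StimulusProtocol(),
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    seed: int = 0,
) -> float:
    """Fraction of cohort traces whose assigned label matches the
    generator's ground truth."""
    mix = {label: n_per_class for label in CLASS_LABELS}
    traces, truths = simulate_cohort(
        protocol,
        mix,
        amplitude_range=amplitude_range,
        noise=NoiseModel(sigma_shot=sigma_shot),
        seed=seed,
    )
    correct = sum(
        classify_trace(normalize_trace(tr, protocol), protocol, thresholds).label
        == gt.class_label
        for tr, gt in zip(traces, truths)
    )
    return correct / len(traces)


def chemotaxis_estimator(
    p_attract: float,
    n_plates: int = 10_000,
    n_loaded: int = 200,
    participation: float = 0.4,
    seed: int = 0,
) -> Dict[str, float]:
    """Mean simulated plate index, its Monte-Carlo standard error, and
    the analytic expectation 2p - 1."""
    indices = np.empty(n_plates)
    for i in range(n_plates):
        plate = simulate_chemotaxis_plate(
            n_loaded, participation, p_attract, seed=seed + i, plate_id=f"p{i}"
        )
        indices[i] = plate.index
    return {
        "mean_index": float(indices.mean()),
        "mc_se": float(indices.std(ddof=1) / np.sqrt(n_plates)),
        "expected": 2.0 * p_attract - 1.0,
    }


def stack_roundtrip_rms(
    protocol: StimulusProtocol = StimulusProtocol(),
    gain: float = 50.0,
    seed: int = 0,
) -> float:
    """RMS %dF/F error of simulate_stack -> extract_traces -> normalize
    against the generator's noiseless ground truth (two drifting ROIs)."""
    from .synthetic import ResponseTemplate

    specs = []
    truths = []
    for template, start, drift in (
        (ResponseTemplate("ON", a_on=50.0), (16.0, 16.0), (0.05, 0.02)),
        (ResponseTemplate("OFF", a_off_dip=-30.0), (45.0, 45.0), (-0.04, 0.03)),
    ):
        raw, gt = simulate_trace(protocol, template, NoiseModel(seed=seed))
        fluor = (raw.f_raw - raw.f_background) * gain
        specs.append(RoiSpec(start_xy=start, drift_xy=drift, trace=fluor))
        truths.append(gt)
    stack, _ = simulate_stack(protocol, specs, frame_size=(64, 64), seed=seed)
    extracted = extract_traces(stack, [s.start_xy for s in specs])
    errs = []
    for tr, gt in zip(extracted, truths):
        norm = normalize_trace(tr, protocol)
        errs.append(np.mean((norm.dff_pct - gt.dff_noiseless) ** 2))
    return float(np.sqrt(np.mean(errs)))
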