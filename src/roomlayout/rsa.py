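"""Representational similarity analysis: full and partial Spearman, group stats.

The core kernel compares a neural RDM with a target model RDM while
partialling out control model RDMs: all off-diagonal vectors are rank
transformed (average ranks for ties), the neural and target rank vectors
are each regressed on the control ranks plus an intercept by least
squares, and the coefficient is the Pearson correlation of the two
residual vectors.  With no controls this reduces exactly to the Spearman
rank correlation.  Group inference is a one-sample t-test of the
per-subject coefficients against zero (upper-tailed by default — the
hypothesis is positive representational alignment), with
Benjamini-Hochberg FDR across the family of (model x region/timepoint)
cells; paired task contrasts use a two-tailed paired t-test on the
coefficient differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import RDM

__all__ = [
    "RsaResult",
    "GroupStat",
    "spearman_rdm_corr",
    "partial_spearman",
    "group_ttest_fdr",
    "paired_contrast",
    "paired_contrasts",
    "planted_dissociation_experiment",
]


@dataclass(frozen=True)
class RsaResult:
    coefficient: float
    kind: str  # "full_spearman" | "partial_spearman"
    target_id: str = ""
    control_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.coefficient):
            raise ValueError("RSA coefficient must be finite")


@dataclass(frozen=True)
class GroupStat:
    family_id: str
    coefficient_mean: float
    t_value: float
    dof: int
    p_value: float
    q_value: float
    tail: str  # "one" | "two"


def _check_aligned(*rdms: RDM) -> None:
    ids = rdms[0].condition_ids
    for r in rdms[1:]:
        if r.condition_ids != ids:
            raise ValueError("RDMs must share the same condition set and ordering")


def _vector(rdm: RDM, min_conditions: int = 4) -> np.ndarray:
    if rdm.n_conditions < min_conditions:
        raise ValueError(f"need at least {min_conditions} conditions")
    v = rdm.vector()
    if np.ptp(v) == 0:
        raise ValueError("RDM vector has zero variance")
    return v


def spearman_rdm_corr(a: RDM, b: RDM) -> float:
    """Spearman rank correlation between the off-diagonal vectors of two RDMs."""
    _check_aligned(a, b)
    rho, _ = stats.spearmanr(_vector(a), _vector(b))
    return float(rho)


def partial_spearman(
    neural: RDM, target: RDM, controls: Sequence[RDM] = (),
    target_id: str = "target",
) -> RsaResult:
    """Partial Spearman correlation of neural and target RDMs given controls."""
    _check_aligned(neural, target, *controls)
    vec_n = stats.rankdata(_vector(neural))
    vec_t = stats.rankdata(_vector(target))
    m = vec_n.size
    if len(controls) >= m - 2:
        raise ValueError("too many control RDMs for the number of condition pairs")
    names = ("neural", "target") + tuple(f"control {i}" for i in range(len(controls)))
    design = np.column_stack(
        [np.ones(m)] + [stats.rankdata(_vector(c)) for c in controls]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear control RDMs")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([vec_n, vec_t]), rcond=None)
    resid = np.column_stack([vec_n, vec_t]) - design @ coef
    for label, r in zip(names[:2], resid.T):
        if np.std(r) < 1e-12 * max(1.0, np.std(vec_n)):
            raise ValueError(f"{label} RDM has no variance left after removing controls")
    rho = float(stats.pearsonr(resid[:, 0], resid[:, 1])[0])
    kind = "partial_spearman" if controls else "full_spearman"
    control_ids = tuple(f"control_{i}" for i in range(len(controls)))
    return RsaResult(rho, kind, target_id, control_ids)


def _one_sample(values: np.ndarray, tail: str) -> tuple[float, float, int, float]:
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(values, ddof=1) <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise ValueError("zero variance across subjects")
    alternative = {"one": "greater", "two": "two-sided"}[tail]
    res = stats.ttest_1samp(values, 0.0, alternative=alternative)
    return float(values.mean()), float(res.statistic), values.size - 1, float(res.pvalue)


def group_ttest_fdr(
    values_by_family: Mapping[str, Sequence[float]], tail: str = "one"
) -> list[GroupStat]:
    """Per-family one-sample t-tests against 0 with BH-FDR across the family set."""
    if not values_by_family:
        raise ValueError("empty test family")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    families = list(values_by_family)
    stats_raw = [_one_sample(np.asarray(values_by_family[f]), tail) for f in families]
    pvals = [s[3] for s in stats_raw]
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    return [
        GroupStat(fid, mean, t, dof, p, float(q), tail)
        for fid, (mean, t, dof, p), q in zip(families, stats_raw, qvals)
    ]


def paired_contrast(
    values_task_a: Sequence[float], values_task_b: Sequence[float], family_id: str = "contrast"
) -> GroupStat:
    """Two-tailed paired t-test on per-subject coefficient differences (a - b)."""
    a = np.asarray(values_task_a, dtype=float)
    b = np.asarray(values_task_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("task coefficient lists must pair by subject")
    diffs = a - b
    if diffs.size >= 3 and np.all(diffs == 0.0):
        # identical tasks: no effect, not a degenerate test
        return GroupStat(family_id, 0.0, 0.0, diffs.size - 1, 1.0, 1.0, "two")
    mean, t, dof, p = _one_sample(diffs, "two")
    return GroupStat(family_id, mean, t, dof, p, p, "two")


def paired_contrasts(
    pairs_by_family: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> list[GroupStat]:
    """Family of paired contrasts with BH-FDR across the family."""
    raw = [paired_contrast(a, b, fid) for fid, (a, b) in pairs_by_family.items()]
    _, qvals, *_ = multipletests([g.p_value for g in raw], method="fdr_bh")
    return [
        GroupStat(g.family_id, g.coefficient_mean, g.t_value, g.dof, g.p_value, float(q), g.tail)
        for g, q in zip(raw, qvals)
    ]


def planted_dissociation_experiment(
    n_subjects: int = 8,
    n_conditions: int = 60,
    target_spearman: float = 0.3,
    seed: int = 0,
    n_nuisance: int = 3,
):
    """Recover a planted regional dissociation between the two layout models.

    Synthetic rooms supply the layout orientation and relative-distance
    model RDMs for ``n_conditions`` conditions.  Two simulated regions get
    per-subject neural RDMs built as a monotone (rank) transform of one
    planted model RDM plus Gaussian noise — the distance model in region
    "dist_region", the orientation model in "ori_region".  The noise SD is
    set analytically so the expected full Spearman with the planted model
    is ``target_spearman``.  Each model's partial correlation controls for
    the nuisance RDMs *and* the other layout model (its unique
    contribution), and the group pipeline returns one-tailed BH-FDR
    q-values for every (region x model) cell.

    Returns a dict with the model RDMs, the per-cell coefficients, the
    group statistics, and the mean planted full-Spearman per region.
    """
    from .features import model_rdm, orientation_feature, reldist_feature
    from .synthetic import make_scene, run_pipeline

    if not 0 < target_spearman < 1:
        raise ValueError("target_spearman must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))

    ori_rows, dist_rows = [], []
    for c in range(n_conditions):
        scene = make_scene([seed, 2**21 + c], jitter_px=0.0)
        result = run_pipeline(scene)
        fov = result["camera"].fov_h_deg
        ori_rows.append(orientation_feature(result["aerial"], fov).values)
        dist_rows.append(reldist_feature(result["segmentation"]).values)
    ids = tuple(f"scene_{c}" for c in range(n_conditions))
    models = {
        "orientation": model_rdm(np.array(ori_rows), "cityblock", ids),
        "reldist": model_rdm(np.array(dist_rows), "cityblock", ids),
    }
    nuisance = []
    for j in range(n_nuisance):
        feats = rng.standard_normal((n_conditions, 20))
        nuisance.append(model_rdm(feats, "cosine" if j == 2 else "euclidean", ids))

    planted = {"dist_region": "reldist", "ori_region": "orientation"}
    sibling = {"orientation": "reldist", "reldist": "orientation"}
    m = n_conditions * (n_conditions - 1) // 2
    coefficients: dict[str, list[float]] = {
        f"{region}/{model}": [] for region in planted for model in models
    }
    full_spearman = {region: [] for region in planted}
    for _ in range(n_subjects):
        for region, planted_model in planted.items():
            ranks = stats.rankdata(models[planted_model].vector())
            noise_sd = np.std(ranks) * math.sqrt(1.0 / target_spearman**2 - 1.0)
            neural = RDM.from_vector(ranks + noise_sd * rng.standard_normal(m), ids)
            full_spearman[region].append(spearman_rdm_corr(neural, models[planted_model]))
            for model_name, model in models.items():
                controls = nuisance + [models[sibling[model_name]]]
                res = partial_spearman(neural, model, controls, target_id=model_name)
                coefficients[f"{region}/{model_name}"].append(res.coefficient)

    group = group_ttest_fdr(coefficients, tail="one")
    return {
        "models": models,
        "coefficients": coefficients,
        "group_stats": group,
        "planted": planted,
        "mean_planted_full_spearman": {
            region: float(np.mean(v)) for region, v in full_spearman.items()
        },
    }
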