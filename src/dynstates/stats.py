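"""Two-group permutation inference, FDR control and clinical correlations.

The group test is the standard exchangeability construction: the statistic
is the difference of group means (patients minus controls), group labels are
shuffled ``n_perm`` times (default 5,000), and the two-sided p-value uses
the add-one correction ``p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)`` so it
can never be zero.  False-discovery control is Benjamini-Hochberg, applied
within each metric family (FO across states; LT across states; transition
entries; correlations within each clinical variable).  Correlations are
Spearman rank correlations over patients only, reported with rho, rho^2 and
the large-sample p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .metrics import TemporalMetrics

logger = logging.getLogger(__name__)

CLINICAL_VARIABLES = ("ibs_sss", "phq9", "pass")


@dataclass
class GroupStatsResult:
    family: str                    # "fo" | "lt" | "sr" | "transition"
    state: int | None              # 1-based, None for sr
    from_state: int | None         # 1-based, transitions only
    to_state: int | None
    observed: float                # patients minus controls
    p_perm: float
    p_fdr: float
    n_patients: int
    n_controls: int


@dataclass
class CorrelationResult:
    family: str                    # "fo" | "lt"
    state: int                     # 1-based
    clinical_variable: str
    rho: float
    r_squared: float
    p: float
    p_fdr: float
    n: int


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of means (a minus b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty after missing-value removal")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(a.mean() - b.mean())
    # draw permuted subsets from the *sorted* pool, always of the smaller
    # group's size: |perm stat| is then invariant to within-group order and
    # to which sample is called "a" (label swap), as exchangeability demands
    pooled = np.sort(np.concatenate([a, b]))
    n, m = pooled.size, min(a.size, b.size)
    rng = np.random.default_rng(seed)
    total = pooled.sum()
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    perm_sums = pooled[idx].sum(axis=1)
    perm_stats = perm_sums / m - (total - perm_sums) / (n - m)
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    return observed, float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation with pairwise missing removal.

    Returns ``(rho, rho^2, p)``; requires at least three complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three complete pairs")
    rho, p = spearmanr(x, y)
    rho = float(rho)
    return rho, rho * rho, float(p)


def classify_ibs_sss(score: float) -> str:
    """Severity band of an IBS-SSS total score (0-500)."""
    if not 0 <= score <= 500 or not math.isfinite(score):
        raise ValueError(f"IBS-SSS score {score} outside [0, 500]")
    if score < 75:
        return "none"
    if score <= 175:
        return "mild"
    if score <= 300:
        return "moderate"
    return "severe"


def classify_phq9(score: float) -> str:
    """Depression band of a PHQ-9 total score (0-27); band floors 5/10/15/20."""
    if not 0 <= score <= 27 or not math.isfinite(score):
        raise ValueError(f"PHQ-9 score {score} outside [0, 27]")
    if score < 5:
        return "none"
    if score < 10:
        return "mild"
    if score < 15:
        return "moderate"
    if score < 20:
        return "moderately severe"
    return "severe"


def _metric_arrays(metrics: list[TemporalMetrics], groups: dict[str, str]):
    """Split each metric into patient/control arrays keyed by family."""
    pat = [m for m in metrics if groups[m.subject_id] == "patient"]
    con = [m for m in metrics if groups[m.subject_id] == "control"]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("each group needs at least two subjects")
    return pat, con


def run_group_analysis(
    metrics: list[TemporalMetrics],
    groups: dict[str, str],
    clinical: pd.DataFrame | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[list[GroupStatsResult], list[CorrelationResult]]:
    """Full two-group inference over temporal metrics plus clinical correlations.

    Permutation tests are run for each state's FO and LT, the switching rate,
    and every off-diagonal empirical-transition entry; BH-FDR is applied
    within each family.  If a clinical table is given, each state's FO and LT
    are Spearman-correlated with IBS-SSS, PHQ-9 and PASS over patients, with
    FDR within each clinical variable.  Fully deterministic given ``seed``.

    Subjects missing a state (NaN LT or transition row) are dropped from that
    particular comparison, with a logged count.
    """
    pat, con = _metric_arrays(metrics, groups)
    k = metrics[0].fo.size
    ss = np.random.SeedSequence(seed)

    def _run_family(family, pairs):
        # pairs: list of (label_tuple, patient_values, control_values)
        results = []
        seeds = ss.spawn(len(pairs))
        for (labels, a, b), child in zip(pairs, seeds):
            n_a, n_b = np.isfinite(a).sum(), np.isfinite(b).sum()
            dropped = (a.size - n_a) + (b.size - n_b)
            if dropped:
                logger.info(
                    "%s %s: dropped %d subject(s) with missing values",
                    family, labels, dropped,
                )
            obs, p = permutation_test(a, b, n_perm=n_perm, seed=child)
            results.append(
                GroupStatsResult(
                    family=family, state=labels[0], from_state=labels[1],
                    to_state=labels[2], observed=obs, p_perm=p, p_fdr=np.nan,
                    n_patients=int(n_a), n_controls=int(n_b),
                )
            )
        adj = bh_fdr([r.p_perm for r in results])
        for r, q in zip(results, adj):
            r.p_fdr = float(q)
        return results

    fo_pairs = [
        ((s + 1, None, None),
         np.array([m.fo[s] for m in pat]), np.array([m.fo[s] for m in con]))
        for s in range(k)
    ]
    lt_pairs = [
        ((s + 1, None, None),
         np.array([m.lt_tr[s] for m in pat]), np.array([m.lt_tr[s] for m in con]))
        for s in range(k)
    ]
    sr_pairs = [
        ((None, None, None),
         np.array([m.sr for m in pat]), np.array([m.sr for m in con]))
    ]
    trans_pairs = [
        ((None, i + 1, j + 1),
         np.array([m.empirical_transitions[i, j] for m in pat]),
         np.array([m.empirical_transitions[i, j] for m in con]))
        for i in range(k) for j in range(k) if i != j
    ]
    results = (
        _run_family("fo", fo_pairs)
        + _run_family("lt", lt_pairs)
        + _run_family("sr", sr_pairs)
        + _run_family("transition", trans_pairs)
    )

    correlations: list[CorrelationResult] = []
    if clinical is not None:
        clin = clinical.set_index("subject_id")
        pat_ids = [m.subject_id for m in pat]
        for var in CLINICAL_VARIABLES:
            scores = np.array([clin.loc[sid, var] for sid in pat_ids], dtype=float)
            fam_results = []
            for family, getter in (("fo", lambda m, s: m.fo[s]),
                                   ("lt", lambda m, s: m.lt_tr[s])):
                for s in range(k):
                    vals = np.array([getter(m, s) for m in pat])
                    rho, r2, p = spearman(vals, scores)
                    fam_results.append(
                        CorrelationResult(
                            family=family, state=s + 1, clinical_variable=var,
                            rho=rho, r_squared=r2, p=p, p_fdr=np.nan,
                            n=int(np.sum(np.isfinite(vals) & np.isfinite(scores))),
                        )
                    )
            adj = bh_fdr([r.p for r in fam_results])
            for r, q in zip(fam_results, adj):
                r.p_fdr = float(q)
            correlations.extend(fam_results)
    return results, correlations


def group_results_to_frame(results: list[GroupStatsResult], alpha: float = 0.05) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    df["significant"] = df["p_fdr"] < alpha
    return df


def correlations_to_frame(results: list[CorrelationResult], alpha: float = 0.05) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["significant"] = df["p_fdr"] < alpha
    return df
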