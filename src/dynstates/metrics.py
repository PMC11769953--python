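"""Per-subject temporal properties and per-state spatial summaries.

Temporal metrics follow the usual dynamic-brain-state definitions:

* fractional occupancy (FO) - the fraction of total time a state accounts
  for; computed from the soft responsibilities (column means of gamma), the
  posterior-mean analogue of time-point counting;
* lifetime (LT) - the mean length of a state's maximal constant runs before
  a switch, in TRs and seconds; computed from the hard Viterbi path, since
  "runs" presuppose discrete assignments;
* switching rate (SR) - state changes per transition opportunity,
  ``#{t : path[t] != path[t-1]} / (T - 1)``;
* empirical transition matrix - row-normalised successor counts of the hard
  path; rows of states never visited as a source are left missing.

Spatial summaries are the fitted model's state means ("activation maps", in
z-units of the standardized data) and the state covariances converted to
correlation ("state functional connectivity"), optionally averaged within
and between resting-state network blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.moment_helpers import cov2corr

from .hmm import HMMModel, StatePosterior
from .parcellation import NetworkTable

#: Canonical display order of network blocks.
NETWORK_ORDER = ("SMN", "VIS", "AUD", "DMN", "FPN", "CON", "CN", "SUB", "ATT", "ND")


@dataclass
class TemporalMetrics:
    """One subject's temporal-state summary."""

    subject_id: str
    fo: np.ndarray                     # (K,)
    lt_tr: np.ndarray                  # (K,) NaN where a state never occurs
    lt_seconds: np.ndarray             # (K,)
    sr: float
    empirical_transitions: np.ndarray  # (K, K) NaN rows for unvisited sources


def fractional_occupancy(gamma: np.ndarray) -> np.ndarray:
    """Column means of the T x K responsibility matrix."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2:
        raise ValueError("gamma must be T x K")
    if not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("gamma rows must sum to 1")
    return gamma.mean(axis=0)


def _runs(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of each maximal constant run, in order."""
    path = np.asarray(path, dtype=int)
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [path.size]])
    return path[starts], ends - starts


def mean_lifetime(
    path: np.ndarray, n_states: int, tr_seconds: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean maximal-run length per state, in TRs and in seconds (NaN if unvisited)."""
    states, lengths = _runs(np.asarray(path, dtype=int))
    lt_tr = np.full(n_states, np.nan)
    for k in range(n_states):
        mask = states == k
        if mask.any():
            lt_tr[k] = lengths[mask].mean()
    return lt_tr, lt_tr * tr_seconds


def switching_rate(path: np.ndarray) -> float:
    """Fraction of steps at which the state changes."""
    path = np.asarray(path, dtype=int)
    if path.size < 2:
        raise ValueError("switching rate needs at least two timepoints")
    return float(np.mean(path[1:] != path[:-1]))


def empirical_transition_matrix(path: np.ndarray, n_states: int) -> np.ndarray:
    """Row-normalised successor counts; unvisited source states give NaN rows."""
    path = np.asarray(path, dtype=int)
    if path.size < 2:
        raise ValueError("need at least two timepoints")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (path[:-1], path[1:]), 1.0)
    rowsum = counts.sum(axis=1)
    out = np.full((n_states, n_states), np.nan)
    visited = rowsum > 0
    out[visited] = counts[visited] / rowsum[visited, None]
    return out


def compute_subject_metrics(
    subject_id: str,
    gamma: np.ndarray,
    viterbi_path: np.ndarray,
    tr_seconds: float,
) -> TemporalMetrics:
    """Bundle all temporal metrics for one subject (FO soft, LT/SR/A hard)."""
    k = gamma.shape[1]
    lt_tr, lt_s = mean_lifetime(viterbi_path, k, tr_seconds)
    return TemporalMetrics(
        subject_id=subject_id,
        fo=fractional_occupancy(gamma),
        lt_tr=lt_tr,
        lt_seconds=lt_s,
        sr=switching_rate(viterbi_path),
        empirical_transitions=empirical_transition_matrix(viterbi_path, k),
    )


def cohort_metrics(
    posterior: StatePosterior, subject_ids: list[str], tr_seconds: float
) -> list[TemporalMetrics]:
    return [
        compute_subject_metrics(sid, g, p, tr_seconds)
        for sid, g, p in zip(subject_ids, posterior.gamma, posterior.viterbi_path)
    ]


def metrics_to_tidy(
    metrics: list[TemporalMetrics], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Long-format table: subject_id, group, metric, state(s), value.

    State indices are reported 1-based.
    """
    rows = []
    for m in metrics:
        group = groups.get(m.subject_id, "") if groups else ""
        k = m.fo.size
        for s in range(k):
            rows.append((m.subject_id, group, "fo", s + 1, None, None, m.fo[s]))
            rows.append((m.subject_id, group, "lt_tr", s + 1, None, None, m.lt_tr[s]))
            rows.append(
                (m.subject_id, group, "lt_seconds", s + 1, None, None, m.lt_seconds[s])
            )
        rows.append((m.subject_id, group, "sr", None, None, None, m.sr))
        for i in range(k):
            for j in range(k):
                rows.append(
                    (m.subject_id, group, "transition", None, i + 1, j + 1,
                     m.empirical_transitions[i, j])
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "metric", "state", "from_state", "to_state", "value"],
    )


# --------------------------------------------------------------------------
# spatial summaries
# --------------------------------------------------------------------------

@dataclass
class StateSpatialSummary:
    state: int                                  # 0-based
    activation_map: np.ndarray                  # (N,)
    fc_matrix: np.ndarray                       # (N, N)
    network_block_means: pd.DataFrame | None = field(default=None)


def state_activation_map(model: HMMModel, state: int) -> np.ndarray:
    """The state's posterior mean vector on the standardized (z) scale.

    Positive entries mean activity above the region's subject-wise temporal
    mean while the state is active; negative entries, below it.
    """
    if not 0 <= state < model.n_states:
        raise IndexError(f"state {state} out of range 0..{model.n_states - 1}")
    return model.state_means[state].copy()


def state_fc_matrix(model: HMMModel, state: int) -> np.ndarray:
    """State covariance converted to a correlation matrix D^{-1/2} S D^{-1/2}."""
    if not 0 <= state < model.n_states:
        raise IndexError(f"state {state} out of range 0..{model.n_states - 1}")
    cov = model.state_covariances[state]
    if np.any(np.diag(cov) <= 0):
        raise np.linalg.LinAlgError("state covariance has non-positive diagonal")
    corr = cov2corr(cov)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def network_block_summary(
    fc: np.ndarray, networks: NetworkTable, region_labels: list[str]
) -> pd.DataFrame:
    """Mean connectivity within/between network blocks (10 x 10).

    Entry (a, b) averages ``fc[i, j]`` over region pairs with i in network a,
    j in network b and i != j; diagonal blocks therefore use off-diagonal
    pairs only, and networks with fewer than two regions get a missing
    within-network value.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != fc.shape[1] or not np.allclose(fc, fc.T, atol=1e-8):
        raise ValueError("fc must be a symmetric square matrix")
    tags = networks.networks_for(region_labels)
    out = np.full((len(NETWORK_ORDER), len(NETWORK_ORDER)), np.nan)
    idx = {net: np.flatnonzero(tags == net) for net in NETWORK_ORDER}
    for a, net_a in enumerate(NETWORK_ORDER):
        for b, net_b in enumerate(NETWORK_ORDER):
            ia, ib = idx[net_a], idx[net_b]
            if ia.size == 0 or ib.size == 0:
                continue
            block = fc[np.ix_(ia, ib)]
            if net_a == net_b:
                if ia.size < 2:
                    continue
                mask = ~np.eye(ia.size, dtype=bool)
                out[a, b] = block[mask].mean()
            else:
                out[a, b] = block.mean()
    return pd.DataFrame(out, index=list(NETWORK_ORDER), columns=list(NETWORK_ORDER))


def state_spatial_summaries(
    model: HMMModel,
    networks: NetworkTable | None = None,
    region_labels: list[str] | None = None,
) -> list[StateSpatialSummary]:
    out = []
    for k in range(model.n_states):
        fc = state_fc_matrix(model, k)
        blocks = None
        if networks is not None and region_labels is not None:
            blocks = network_block_summary(fc, networks, region_labels)
        out.append(
            StateSpatialSummary(
                state=k,
                activation_map=state_activation_map(model, k),
                fc_matrix=fc,
                network_block_means=blocks,
            )
        )
    return out
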