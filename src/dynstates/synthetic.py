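"""Synthetic multi-subject cohorts drawn from a known Gaussian HMM.

The generator emulates the study conditions the pipeline is built for: two
groups (35 patients, 31 controls) of parcellated resting-state series, 190
timepoints at TR = 2 s, a 6-state sticky Gaussian HMM, group-differential
temporal structure confined to two designated states plus one elevated
transition probability, and patient symptom scores monotonically linked to
the designated state's occupancy.  Because every subject is sampled from an
explicit ground-truth model, every downstream stage (fitting, metrics,
statistics) can be checked against known answers.

Construction rules
------------------
* The control transition matrix is "sticky uniform": diagonal ``s``,
  off-diagonals ``(1 - s) / (K - 1)``.  Its stationary distribution weights
  state ``i`` proportionally to the mean dwell mass ``1 / (1 - s_i)``, so
  occupancy effects can be dialled in per state with almost no spillover.
* The patient group differs only through :class:`GroupEffect`: the
  designated "up" ("down") state's mean lifetime is raised (lowered) by a
  fixed number of TRs, and one off-diagonal transition entry is raised at
  the expense of the *other* off-diagonal entries of its row, which leaves
  the source state's leave-rate (hence its lifetime) untouched.
* State means sit on random orthogonal directions scaled by
  ``mean_separation``; state covariances are unit-variance-scale matrices
  with one state-specific rank-one bump, so states differ in connectivity as
  well as activation.
* Patient IBS-SSS scores are a linear map on the ranks of the designated
  state's true fractional occupancy plus Gaussian noise, rescaled to the
  scale's observed mean/SD and clipped to its range; PHQ-9 and PASS share a
  separate latent distress factor (mutually correlated, unlinked to state
  occupancy); IBS-QOL declines with the same severity latent.  Controls
  carry missing scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.stats import ortho_group, rankdata

from .parcellation import SubjectTimeSeries, aal116_region_labels

#: (mean, sd, lower, upper) used to place synthetic scores on each scale.
SCALE_CALIBRATION = {
    "ibs_sss": (223.71, 50.11, 0.0, 500.0),
    "phq9": (5.17, 3.97, 0.0, 27.0),
    "pass": (29.42, 16.22, 0.0, 100.0),
    "ibs_qol": (50.94, 11.44, 0.0, 100.0),
}


@dataclass(frozen=True)
class GroupEffect:
    """Where the patient group's dynamics differ from the control group's.

    State indices are 0-based: the defaults place the occupancy decrease in
    state index 4, the increase in state index 5, and the elevated transition
    from state index 1 to state index 5 (states 5, 6 and the 2 -> 6
    transition in 1-based reporting).

    When ``transition_boost > 0`` the up state's dwell time is re-derived by
    an occupancy-balancing step (see ``_balance_null_occupancy``) so that the
    extra boost inflow does not drain occupancy from non-designated states;
    ``lifetime_up_shift_tr`` then only sets the pre-balance starting point.
    """

    fo_down_state: int = 4
    fo_up_state: int = 5
    lifetime_up_shift_tr: float = 2.0
    lifetime_down_shift_tr: float = 2.0
    transition_from: int = 1
    transition_to: int = 5
    transition_boost: float = 0.055

    def validate(self, n_states: int) -> None:
        for name in ("fo_down_state", "fo_up_state", "transition_from", "transition_to"):
            idx = getattr(self, name)
            if not 0 <= idx < n_states:
                raise ValueError(f"group_effect.{name} = {idx} is not a valid state index")
        if self.transition_from == self.transition_to:
            raise ValueError("transition boost must target an off-diagonal entry")
        if self.lifetime_down_shift_tr < 0 or self.lifetime_up_shift_tr < 0:
            raise ValueError("lifetime shifts are magnitudes; must be non-negative")
        if not 0 <= self.transition_boost < 1:
            raise ValueError("transition_boost must lie in [0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings; the defaults emulate the study conditions.

    ``n_regions`` defaults to a reduced 20 (the HMM mathematics is
    dimension-agnostic); set 116 for full-atlas-sized cohorts.
    """

    n_states: int = 6
    n_regions: int = 20
    n_timepoints: int = 190
    tr_seconds: float = 2.0
    n_subjects_per_group: tuple[int, int] = (35, 31)  # (patients, controls)
    mean_separation: float = 3.0
    transition_stickiness: float = 0.7
    group_effect: GroupEffect | None = field(default_factory=GroupEffect)
    clinical_effect: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not 0 < self.transition_stickiness < 1:
            raise ValueError("transition_stickiness must lie in (0, 1)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if min(self.n_subjects_per_group) < 0 or max(self.n_subjects_per_group) < 1:
            raise ValueError("need at least one subject")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.group_effect is not None:
            self.group_effect.validate(self.n_states)


@dataclass
class GroundTruth:
    """The generating model: the ground-truth counterpart of a fitted HMM."""

    config: GeneratorConfig
    true_transition_matrices: dict[str, np.ndarray]   # group -> (K, K)
    true_initial_distribution: np.ndarray             # (K,)
    true_state_means: np.ndarray                      # (K, N)
    true_state_covariances: np.ndarray                # (K, N, N)
    true_state_paths: dict[str, np.ndarray] | None = None  # subject_id -> (T,)
    region_labels: list[str] = field(default_factory=list)

    def stationary_distribution(self, group: str) -> np.ndarray:
        """Stationary distribution of the group's transition matrix."""
        return _stationary(self.true_transition_matrices[group])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": _config_to_jsonable(self.config),
            "true_transition_matrices": {
                g: m.tolist() for g, m in self.true_transition_matrices.items()
            },
            "true_initial_distribution": self.true_initial_distribution.tolist(),
            "true_state_means": self.true_state_means.tolist(),
            "true_state_covariances": self.true_state_covariances.tolist(),
            "true_state_paths": (
                {sid: p.tolist() for sid, p in self.true_state_paths.items()}
                if self.true_state_paths is not None else None
            ),
            "region_labels": self.region_labels,
        }
        Path(path).write_text(json.dumps(payload))


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["n_subjects_per_group"] = list(config.n_subjects_per_group)
    return d


def _stationary(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(a.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, idx]))
    return pi / pi.sum()


def _set_row_dwell(a: np.ndarray, i: int, stickiness: float) -> None:
    """Set row i's diagonal, rescaling its off-diagonal profile in place."""
    off = a[i].copy()
    off[i] = 0.0
    off *= (1.0 - stickiness) / off.sum()
    a[i] = off
    a[i, i] = stickiness


def _balance_null_occupancy(patient: np.ndarray, eff: "GroupEffect") -> None:
    """Tune two dwell knobs so non-designated states keep occupancy 1/K.

    The transition boost feeds extra visits into the (sticky) target state,
    which would otherwise drain occupancy from every other state and smear
    the group effect across the whole occupancy profile.  Solving for the
    boost-source and up-state diagonals restores all non-designated states
    to exactly the control occupancy (they are exchangeable by symmetry, so
    two conditions suffice).  Purely a construction step: deterministic,
    data-independent.
    """
    k = patient.shape[0]
    designated = {eff.fo_up_state, eff.fo_down_state}
    nulls = [s for s in range(k) if s not in designated]
    others = [s for s in nulls if s != eff.transition_from]
    if eff.transition_boost <= 0 or eff.transition_from in designated or not others:
        return
    target = 1.0 / k
    src, up = eff.transition_from, eff.fo_up_state

    def residual(params):
        s_src, s_up = params
        if not (0 < s_src < 1 and 0 < s_up < 1):
            return [1.0, 1.0]
        b = patient.copy()
        _set_row_dwell(b, src, s_src)
        _set_row_dwell(b, up, s_up)
        pi = _stationary(b)
        return [pi[src] - target, pi[others[0]] - target]

    sol = root(residual, [patient[src, src], patient[up, up]], tol=1e-13)
    s_src, s_up = sol.x
    if sol.success and 0 < s_src < 1 and 0 < s_up < 1:
        _set_row_dwell(patient, src, float(s_src))
        _set_row_dwell(patient, up, float(s_up))


def _sticky_uniform(n_states: int, stickiness: float) -> np.ndarray:
    a = np.full((n_states, n_states), (1.0 - stickiness) / (n_states - 1))
    np.fill_diagonal(a, stickiness)
    return a


def _row_with_lifetime(n_states: int, mean_lifetime: float) -> np.ndarray:
    """Sticky-uniform row whose diagonal gives the requested mean dwell (TRs)."""
    mean_lifetime = max(mean_lifetime, 1.05)  # dwell mass cannot drop below one TR
    s = 1.0 - 1.0 / mean_lifetime
    row = np.full(n_states, (1.0 - s) / (n_states - 1))
    return row, s


def make_generating_model(config: GeneratorConfig) -> GroundTruth:
    """Build the ground-truth HMM (means, covariances, per-group dynamics)."""
    config.validate()
    k, n = config.n_states, config.n_regions
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    if n >= k:
        q = ortho_group.rvs(dim=n, random_state=rng)[:k]
    else:  # fewer regions than states: fall back to random unit directions
        q = rng.standard_normal((k, n))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
    means = config.mean_separation * q

    covs = np.empty((k, n, n))
    eye = np.eye(n)
    for s in range(k):
        u = rng.standard_normal(n)
        u /= np.linalg.norm(u)
        covs[s] = config.noise_scale**2 * (eye + np.outer(u, u))

    control = _sticky_uniform(k, config.transition_stickiness)
    patient = control.copy()
    eff = config.group_effect
    if eff is not None:
        base_lt = 1.0 / (1.0 - config.transition_stickiness)
        for state, lt in (
            (eff.fo_up_state, base_lt + eff.lifetime_up_shift_tr),
            (eff.fo_down_state, base_lt - eff.lifetime_down_shift_tr),
        ):
            row, s = _row_with_lifetime(k, lt)
            patient[state] = row
            patient[state, state] = s
        # shift transition mass toward the designated entry, taken evenly
        # from the other off-diagonal entries (leave-rate preserved)
        i, j = eff.transition_from, eff.transition_to
        others = [c for c in range(k) if c not in (i, j)]
        take = eff.transition_boost / len(others)
        if np.any(patient[i, others] - take < 0):
            raise ValueError("transition_boost too large for the source row")
        patient[i, j] += eff.transition_boost
        patient[i, others] -= take
        _balance_null_occupancy(patient, eff)
    for a in (control, patient):
        a /= a.sum(axis=1, keepdims=True)

    labels = (
        aal116_region_labels() if n == 116 else [f"roi_{i + 1:03d}" for i in range(n)]
    )
    return GroundTruth(
        config=config,
        true_transition_matrices={"control": control, "patient": patient},
        true_initial_distribution=np.full(k, 1.0 / k),
        true_state_means=means,
        true_state_covariances=covs,
        region_labels=labels,
    )


def sample_state_path(
    truth: GroundTruth, group: str, length: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Sample one hidden state sequence from the group's Markov chain."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if group not in truth.true_transition_matrices:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    a = truth.true_transition_matrices[group]
    k = a.shape[0]
    path = np.empty(length, dtype=int)
    path[0] = rng.choice(k, p=truth.true_initial_distribution)
    cum = np.cumsum(a, axis=1)
    u = rng.random(length)
    for t in range(1, length):
        path[t] = int(np.searchsorted(cum[path[t - 1]], u[t]))
    return path


def sample_observations(
    truth: GroundTruth,
    path: np.ndarray,
    seed: int | np.random.SeedSequence,
    subject_id: str = "subject",
) -> SubjectTimeSeries:
    """Draw row ``t`` from the multivariate normal of state ``path[t]``."""
    path = np.asarray(path, dtype=int)
    k, n = truth.true_state_means.shape
    if path.min() < 0 or path.max() >= k:
        raise ValueError("path contains invalid state indices")
    rng = np.random.default_rng(seed)
    chols = np.linalg.cholesky(truth.true_state_covariances)
    z = rng.standard_normal((path.size, n))
    data = truth.true_state_means[path] + np.einsum("tij,tj->ti", chols[path], z)
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=data,
        tr_seconds=truth.config.tr_seconds,
        region_labels=list(truth.region_labels),
    )


def _rank_z(values: np.ndarray) -> np.ndarray:
    """Ranks mapped to an equally spaced standard-normal-like score."""
    r = rankdata(values, method="average")
    u = (r - 0.5) / values.size
    return (u - u.mean()) / max(u.std(), 1e-12)


def _to_scale(latent: np.ndarray, scale: str, rng: np.random.Generator) -> np.ndarray:
    mean, sd, lo, hi = SCALE_CALIBRATION[scale]
    z = (latent - latent.mean()) / max(latent.std(), 1e-12)
    return np.clip(np.round(mean + sd * z), lo, hi)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SubjectTimeSeries], pd.DataFrame, GroundTruth]:
    """Generate the full two-group cohort with clinical scores and ground truth.

    Returns ``(subjects, clinical_table, truth)``; the clinical table has one
    row per subject with columns ``subject_id, group, ibs_sss, phq9, pass,
    ibs_qol`` (scores missing for controls), and ``truth.true_state_paths``
    records every subject's generating state sequence.
    """
    config.validate()
    truth = make_generating_model(config)
    n_pat, n_con = config.n_subjects_per_group
    ss = np.random.SeedSequence(config.seed)
    path_seeds = ss.spawn(n_pat + n_con)
    obs_seeds = ss.spawn(n_pat + n_con + 1)[1:]  # distinct stream from paths
    clin_seed = np.random.default_rng(ss.spawn(1)[0].generate_state(2))

    subjects: list[SubjectTimeSeries] = []
    paths: dict[str, np.ndarray] = {}
    groups = ["patient"] * n_pat + ["control"] * n_con
    ids = [f"IBS{i + 1:03d}" for i in range(n_pat)] + [
        f"HC{i + 1:03d}" for i in range(n_con)
    ]
    for idx, (sid, group) in enumerate(zip(ids, groups)):
        path = sample_state_path(truth, group, config.n_timepoints, path_seeds[idx])
        series = sample_observations(truth, path, obs_seeds[idx], subject_id=sid)
        subjects.append(series)
        paths[sid] = path
    truth.true_state_paths = paths

    # patient clinical scores: severity driven by the designated state's true FO
    eff = config.group_effect or GroupEffect()
    fo_up = np.array(
        [np.mean(paths[sid] == eff.fo_up_state) for sid in ids[:n_pat]]
    )
    sev = config.clinical_effect * _rank_z(fo_up) + clin_seed.standard_normal(n_pat)
    distress = clin_seed.standard_normal(n_pat)
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "ibs_sss": np.nan,
            "phq9": np.nan,
            "pass": np.nan,
            "ibs_qol": np.nan,
        }
    )
    table.loc[: n_pat - 1, "ibs_sss"] = _to_scale(sev, "ibs_sss", clin_seed)
    table.loc[: n_pat - 1, "phq9"] = _to_scale(
        distress + 0.8 * clin_seed.standard_normal(n_pat), "phq9", clin_seed
    )
    table.loc[: n_pat - 1, "pass"] = _to_scale(
        distress + 0.8 * clin_seed.standard_normal(n_pat), "pass", clin_seed
    )
    table.loc[: n_pat - 1, "ibs_qol"] = _to_scale(
        -0.8 * sev + 0.8 * clin_seed.standard_normal(n_pat), "ibs_qol", clin_seed
    )
    return subjects, table, truth


def validate_clinical_table(table: pd.DataFrame) -> None:
    """Check the subject-table contract (score ranges, patient-only scores)."""
    required = {"subject_id", "group", "ibs_sss", "phq9", "pass", "ibs_qol"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    if not set(table["group"]).issubset({"patient", "control"}):
        raise ValueError("group labels must be 'patient' or 'control'")
    patients = table["group"] == "patient"
    for col in ("ibs_sss", "phq9", "pass", "ibs_qol"):
        _, _, lo, hi = SCALE_CALIBRATION[col]
        vals = table.loc[patients, col]
        if vals.isna().any():
            raise ValueError(f"patients must carry {col} scores")
        if ((vals < lo) | (vals > hi)).any():
            raise ValueError(f"{col} outside [{lo}, {hi}]")
        if table.loc[~patients, col].notna().any():
            raise ValueError(f"controls must not carry {col} scores")


def write_fixture(
    outdir: str | Path,
    subjects: list[SubjectTimeSeries],
    clinical: pd.DataFrame,
    truth: GroundTruth,
) -> Path:
    """Materialise a complete fixture directory (per-subject TSVs + metadata)."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        s.to_tsv(ts_dir / f"{s.subject_id}.tsv")
    clinical.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return outdir
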