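"""Config-driven orchestration of the full brain-state analysis.

A :class:`PipelineConfig` names exactly one input mode:

``synthetic``
    Generate a seeded cohort from :class:`~dynstates.synthetic.GeneratorConfig`.
``timeseries_dir``
    Load per-subject TSV matrices (``timeseries/*.tsv``) plus a
    ``subjects.tsv`` table with group labels and clinical scores.
``nifti_dir``
    Load 4D functional NIfTI images plus an integer-labelled atlas and
    extract ROI series.

The pipeline then applies the in-scope preprocessing (discard initial
volumes, band-pass, standardize), selects the number of states by minimum
free energy over ``k_range``, fits the final model, decodes per-subject
state time courses, computes temporal metrics and state spatial summaries,
runs the permutation/FDR group statistics and clinical correlations, and
writes every result (plus a manifest sufficient to reproduce the run) to
the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hmm import HMMPrior, select_model_order, vb_fit
from .metrics import cohort_metrics, metrics_to_tidy, state_spatial_summaries
from .parcellation import (
    NetworkTable,
    SubjectTimeSeries,
    extract_roi_timeseries,
    load_network_table,
    preprocess,
)
from .stats import correlations_to_frame, group_results_to_frame, run_group_analysis
from .synthetic import GeneratorConfig, GroupEffect, generate_cohort

logger = logging.getLogger(__name__)

INPUT_MODES = ("synthetic", "timeseries_dir", "nifti_dir")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_mode: str = "synthetic"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_dir: str | None = None
    tr_seconds: float = 2.0
    # preprocessing (synthetic series are generated post-preprocessing, so
    # discard/band-pass default off in synthetic mode; see run_pipeline)
    discard_n: int = 10
    bandpass: tuple[float, float] | None = (0.01, 0.08)
    standardize: bool = True
    # HMM settings
    k_range: tuple[int, int] = (2, 15)
    n_init: int = 5
    tol: float = 1e-5
    max_iter: int = 500
    prior: HMMPrior = field(default_factory=HMMPrior)
    # statistics
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "dynstates_results"

    def validate(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.input_mode != "synthetic" and not self.input_dir:
            raise ValueError(f"input_mode {self.input_mode!r} requires input_dir")
        lo, hi = self.k_range
        if not (1 <= lo <= hi):
            raise ValueError("k_range must satisfy 1 <= low <= high")
        if self.n_perm < 1 or not 0 < self.alpha < 1:
            raise ValueError("invalid statistics settings")
        if self.discard_n < 0:
            raise ValueError("discard_n must be non-negative")
        if self.input_mode == "synthetic":
            self.generator.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        gen = raw.pop("generator", {})
        if isinstance(gen, dict):
            eff = gen.pop("group_effect", "default")
            if eff is None:
                gen["group_effect"] = None
            elif isinstance(eff, dict):
                gen["group_effect"] = GroupEffect(**eff)
            gen.setdefault("seed", raw.get("seed", 0))
            if "n_subjects_per_group" in gen:
                gen["n_subjects_per_group"] = tuple(gen["n_subjects_per_group"])
            raw["generator"] = GeneratorConfig(**gen)
        prior = raw.pop("prior", {})
        if isinstance(prior, dict):
            raw["prior"] = HMMPrior(**prior)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if raw.get("bandpass") is not None and "bandpass" in raw:
            raw["bandpass"] = tuple(raw["bandpass"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            return obj
        return convert(self)


def _load_timeseries_dir(input_dir: Path, tr_seconds: float):
    ts_dir = input_dir / "timeseries" if (input_dir / "timeseries").is_dir() else input_dir
    files = sorted(ts_dir.glob("*.tsv"))
    files = [f for f in files if f.name != "subjects.tsv"]
    if not files:
        raise ValueError(f"no time-series TSV files under {ts_dir}")
    subjects = [SubjectTimeSeries.from_tsv(f, tr_seconds=tr_seconds) for f in files]
    clin_path = input_dir / "subjects.tsv"
    clinical = pd.read_csv(clin_path, sep="\t") if clin_path.exists() else None
    return subjects, clinical


def _load_nifti_dir(input_dir: Path, tr_seconds: float):
    import nibabel as nib

    atlas_files = sorted(input_dir.glob("atlas*.nii*"))
    if not atlas_files:
        raise ValueError(f"no atlas*.nii[.gz] under {input_dir}")
    atlas = nib.load(atlas_files[0])
    func_files = [
        f for f in sorted(input_dir.glob("*.nii*")) if not f.name.startswith("atlas")
    ]
    if not func_files:
        raise ValueError(f"no functional NIfTI files under {input_dir}")
    subjects = []
    for f in func_files:
        img = nib.load(f)
        sid = f.name.split(".nii")[0]
        subjects.append(
            extract_roi_timeseries(img, atlas, tr_seconds=tr_seconds, subject_id=sid)
        )
    clin_path = input_dir / "subjects.tsv"
    clinical = pd.read_csv(clin_path, sep="\t") if clin_path.exists() else None
    return subjects, clinical


def _write_tsv_matrix(path: Path, matrix: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(matrix, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the result directory.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    fit_seed, stats_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)
    )

    # ---- load / generate -------------------------------------------------
    stage = "load"
    truth = None
    try:
        if config.input_mode == "synthetic":
            subjects, clinical, truth = generate_cohort(config.generator)
            discard_n, bandpass = 0, None  # generator emulates preprocessed data
        elif config.input_mode == "timeseries_dir":
            subjects, clinical = _load_timeseries_dir(
                Path(config.input_dir), config.tr_seconds
            )
            discard_n, bandpass = config.discard_n, config.bandpass
        else:
            subjects, clinical = _load_nifti_dir(Path(config.input_dir), config.tr_seconds)
            discard_n, bandpass = config.discard_n, config.bandpass
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    logger.info("loaded %d subjects (%s mode)", len(subjects), config.input_mode)

    # ---- preprocess ------------------------------------------------------
    stage = "preprocess"
    try:
        subjects = [
            preprocess(s, n_discard=discard_n, bandpass=bandpass,
                       do_standardize=config.standardize)
            for s in subjects
        ]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- model-order selection ------------------------------------------
    stage = "select_model_order"
    lo, hi = config.k_range
    try:
        if lo == hi:
            selected_k = lo
            fe_table = None
        else:
            selected_k, fe_table = select_model_order(
                subjects, prior=config.prior, k_range=range(lo, hi + 1),
                n_init=config.n_init, seed=fit_seed, max_iter=config.max_iter,
                tol=config.tol,
            )
            fe_table.to_csv(out / "free_energy_by_k.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    logger.info("selected K = %d", selected_k)

    # ---- final fit + decode ---------------------------------------------
    stage = "fit"
    try:
        model, posterior = vb_fit(
            subjects, selected_k, prior=config.prior, n_init=config.n_init,
            seed=fit_seed, max_iter=config.max_iter, tol=config.tol,
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    (out / "model.json").write_text(json.dumps(model.to_dict()))
    post_dir = out / "posteriors"
    post_dir.mkdir(exist_ok=True)
    for s, gamma, path in zip(subjects, posterior.gamma, posterior.viterbi_path):
        df = pd.DataFrame(gamma, columns=[f"state_{k + 1}" for k in range(selected_k)])
        df["viterbi_state"] = path + 1
        df.to_csv(post_dir / f"{s.subject_id}.tsv", sep="\t", index=False,
                  float_format="%.10g")

    # ---- metrics ---------------------------------------------------------
    stage = "metrics"
    try:
        mets = cohort_metrics(
            posterior, [s.subject_id for s in subjects], subjects[0].tr_seconds
        )
        groups = None
        if clinical is not None:
            groups = dict(zip(clinical["subject_id"], clinical["group"]))
        tidy = metrics_to_tidy(mets, groups)
        tidy.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
        networks = None
        try:
            networks = load_network_table()
            if set(subjects[0].region_labels) - set(networks.mapping):
                networks = None  # non-atlas regions: skip network blocks
        except Exception:
            networks = None
        summaries = state_spatial_summaries(
            model, networks, subjects[0].region_labels if networks else None
        )
        spatial = {
            f"state_{s.state + 1}": {
                "activation_map": s.activation_map.tolist(),
                "fc_matrix": s.fc_matrix.tolist(),
                "network_block_means": (
                    s.network_block_means.to_dict() if s.network_block_means is not None
                    else None
                ),
            }
            for s in summaries
        }
        (out / "state_spatial.json").write_text(json.dumps(spatial))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- group statistics ------------------------------------------------
    stage = "group_stats"
    results_frame = corr_frame = None
    try:
        if groups is not None and len(set(groups.values())) == 2:
            res, corr = run_group_analysis(
                mets, groups, clinical=clinical, n_perm=config.n_perm,
                seed=stats_seed,
            )
            results_frame = group_results_to_frame(res, config.alpha)
            results_frame.to_csv(out / "group_stats.tsv", sep="\t", index=False,
                                 float_format="%.10g")
            corr_frame = correlations_to_frame(corr, config.alpha)
            corr_frame.to_csv(out / "correlations.tsv", sep="\t", index=False,
                              float_format="%.10g")
        else:
            logger.info("no two-group labels available; skipping group statistics")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- manifest --------------------------------------------------------
    manifest = {
        "dynstates_version": __version__,
        "config": config.to_jsonable(),
        "seeds": {"master": config.seed, "fit": fit_seed, "stats": stats_seed},
        "n_subjects": len(subjects),
        "n_regions": subjects[0].n_regions,
        "n_timepoints": [s.n_timepoints for s in subjects],
        "selected_n_states": selected_k,
        "free_energy": model.free_energy,
        "converged": model.converged,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
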