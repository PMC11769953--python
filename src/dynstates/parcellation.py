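"""Parcellated time-series I/O and in-scope temporal preprocessing.

This module owns the per-subject data container (:class:`SubjectTimeSeries`),
ROI extraction from a 4D functional image + integer-labelled atlas, the three
temporal preprocessing steps applied before HMM fitting (discard initial
volumes, zero-phase band-pass, per-column standardization), and the
region -> resting-state-network lookup used to summarise state connectivity.

The intended preprocessing order is fixed:

    extract -> discard_initial_volumes -> bandpass_filter -> standardize

Each step preserves the number of regions and their labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: The closed vocabulary of network tags (ND = not defined).
NETWORK_TAGS = ("SMN", "VIS", "AUD", "DMN", "FPN", "CON", "CN", "SUB", "ATT", "ND")


@dataclass
class SubjectTimeSeries:
    """One subject's T x N region-by-time matrix (rows = time, columns = regions)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x regions) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")
        if self.n_timepoints < 2:
            raise ValueError("need at least two timepoints")
        if not self.region_labels:
            self.region_labels = [f"roi_{i + 1:03d}" for i in range(self.n_regions)]
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length does not match the number of columns")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data, columns=self.region_labels)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, subject_id: str | None = None, tr_seconds: float = 2.0
    ) -> "SubjectTimeSeries":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t")
            data = df.to_numpy(dtype=float)
        except Exception as exc:  # surface the offending file in pipeline aborts
            raise ValueError(f"malformed time-series TSV {path}: {exc}") from exc
        return cls(
            subject_id=subject_id or path.stem,
            data=data,
            tr_seconds=tr_seconds,
            region_labels=list(df.columns),
        )


def extract_roi_timeseries(
    functional_image,
    atlas,
    tr_seconds: float | None = None,
    region_labels: Sequence[str] | None = None,
    subject_id: str = "subject",
) -> SubjectTimeSeries:
    """Average a 4D functional image within each integer atlas label.

    Column ``r`` at time ``t`` is the mean of the functional volume at time
    ``t`` over all voxels carrying atlas label ``r``; columns are ordered by
    ascending label.  No resampling is performed: the functional and atlas
    grids must already coincide.

    Parameters
    ----------
    functional_image
        4D array or nibabel image (x, y, z, t).
    atlas
        3D integer-labelled array or nibabel image on the same grid; label 0
        is background.
    """
    func_img = None
    if hasattr(functional_image, "get_fdata"):
        func_img = functional_image
        functional = np.asarray(functional_image.get_fdata())
    else:
        functional = np.asarray(functional_image, dtype=float)
    if hasattr(atlas, "get_fdata"):
        atlas = np.asarray(atlas.get_fdata())
    atlas = np.asarray(np.rint(atlas), dtype=int)

    if functional.ndim != 4:
        raise ValueError("functional image must be 4-D (x, y, z, t)")
    if atlas.ndim != 3:
        raise ValueError("atlas must be 3-D")
    if functional.shape[:3] != atlas.shape:
        raise ValueError(
            f"spatial grid mismatch: functional {functional.shape[:3]} vs atlas {atlas.shape}"
        )
    if atlas.min() < 0:
        raise ValueError("atlas labels must be non-negative integers")

    n_labels = int(atlas.max())
    if n_labels < 1:
        raise ValueError("atlas contains no positive labels")

    T = functional.shape[3]
    flat_func = functional.reshape(-1, T)
    flat_atlas = atlas.reshape(-1)
    data = np.empty((T, n_labels))
    for lab in range(1, n_labels + 1):
        mask = flat_atlas == lab
        if not mask.any():
            raise ValueError(f"atlas label {lab} has zero voxels")
        data[:, lab - 1] = flat_func[mask].mean(axis=0)

    if tr_seconds is None:
        tr_seconds = 2.0
        if func_img is not None:
            zooms = func_img.header.get_zooms()
            if len(zooms) >= 4 and zooms[3] > 0:
                tr_seconds = float(zooms[3])
    labels = list(region_labels) if region_labels else [f"label_{i}" for i in range(1, n_labels + 1)]
    return SubjectTimeSeries(
        subject_id=subject_id, data=data, tr_seconds=float(tr_seconds), region_labels=labels
    )


def discard_initial_volumes(series: SubjectTimeSeries, n_discard: int) -> SubjectTimeSeries:
    """Drop the first ``n_discard`` rows (signal-equilibration volumes)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_timepoints} volumes"
        )
    if n_discard == 0:
        return replace(series, data=series.data.copy())
    return replace(series, data=series.data[n_discard:].copy())


def bandpass_filter(
    series: SubjectTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08, order: int = 4
) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass applied independently per region.

    A 4th-order Butterworth design applied forward and backward
    (:func:`scipy.signal.filtfilt`) so that no phase shift distorts state
    timing.  ``low_hz = 0`` degenerates to a low-pass.
    """
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyquist:.4g} Hz"
        )
    if low_hz == 0:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=1.0 / series.tr_seconds, output="sos")
    else:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="bandpass", fs=1.0 / series.tr_seconds, output="sos"
        )
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return replace(series, data=np.ascontiguousarray(filtered), standardized=False)


def standardize(series: SubjectTimeSeries) -> SubjectTimeSeries:
    """Centre each region to mean 0 and scale to unit sample (n-1) SD.

    Constant columns are centred and left at zero (with a logged warning)
    rather than producing NaNs.
    """
    data = series.data - series.data.mean(axis=0, keepdims=True)
    sd = data.std(axis=0, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        bad = [series.region_labels[i] for i in np.flatnonzero(constant)]
        logger.warning(
            "subject %s: %d constant region(s) left at zero after centring: %s",
            series.subject_id, len(bad), ", ".join(bad[:5]),
        )
    scale = np.where(constant, 1.0, sd)
    return replace(series, data=data / scale, standardized=True)


def preprocess(
    series: SubjectTimeSeries,
    n_discard: int = 0,
    bandpass: tuple[float, float] | None = None,
    do_standardize: bool = True,
) -> SubjectTimeSeries:
    """Apply the canonical preprocessing order: discard -> band-pass -> standardize."""
    out = discard_initial_volumes(series, n_discard)
    if bandpass is not None:
        out = bandpass_filter(out, *bandpass)
    if do_standardize:
        out = standardize(out)
    return out


@dataclass
class NetworkTable:
    """Mapping of region label -> resting-state network tag (closed vocabulary)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad_tags = sorted({t for t in self.mapping.values() if t not in NETWORK_TAGS})
        if bad_tags:
            raise ValueError(
                f"unknown network tag(s) {bad_tags}; allowed: {sorted(NETWORK_TAGS)}"
            )

    def __len__(self) -> int:
        return len(self.mapping)

    def networks_for(self, region_labels: Sequence[str]) -> np.ndarray:
        missing = [r for r in region_labels if r not in self.mapping]
        if missing:
            raise ValueError(f"unlabelled region(s): {missing[:5]}")
        return np.array([self.mapping[r] for r in region_labels])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"region_label": list(self.mapping), "network": list(self.mapping.values())}
        )
        df.to_csv(path, sep="\t", index=False)


def load_network_table(path: str | Path | None = None) -> NetworkTable:
    """Load a region->network table; the packaged default covers all 116 AAL regions."""
    if path is None:
        ref = resources.files("dynstates.data") / "aal116_networks.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"region_label", "network"}.issubset(df.columns):
        raise ValueError("network table needs columns: region_label, network")
    if df["region_label"].duplicated().any():
        dupes = df.loc[df["region_label"].duplicated(), "region_label"].tolist()
        raise ValueError(f"duplicate region labels in network table: {dupes[:5]}")
    return NetworkTable(dict(zip(df["region_label"], df["network"])))


def aal116_region_labels() -> list[str]:
    """The 116 AAL region names in ascending atlas-label order."""
    ref = resources.files("dynstates.data") / "aal116_networks.tsv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return df["region_label"].tolist()
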