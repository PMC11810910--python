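"""Choice datasets, selected/unselected averages, and enhanced difference images.

For every non-correction test trial the luminance plane of the chosen noise
pattern is recorded together with the pixelwise mean of the two patterns
that were not chosen.  Averaging these planes over trials and subtracting
gives the raw difference image — the reverse-correlation estimate of what
the observer was looking for.  For display, low-contrast planes are
stretched with the linear enhancement

    E(i, j) = (L(i, j) - M) * 20 + 128,

where M is the mean luminance of the entire plane; statistics always use
the raw (unrounded) planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AOISpec
from .simulate import StimulusStore
from .stimuli import _to_uint8


@dataclass
class ChoiceDataset:
    """Per-test-trial stimulus planes and choices, in long format.

    stimuli    : uint8 array (n_trials, 3, H, W) — all three presented planes
    chosen_idx : int array (n_trials,) — index (0-2) of the chosen plane
    participant, trial, rt_ms, category : per-trial metadata
    """

    stimuli: np.ndarray
    chosen_idx: np.ndarray
    participant: np.ndarray
    trial: np.ndarray
    rt_ms: np.ndarray
    category: str

    def __post_init__(self) -> None:
        if self.stimuli.ndim != 4 or self.stimuli.shape[1] != 3:
            raise ValueError("stimuli must have shape (n, 3, H, W)")
        n = len(self.stimuli)
        for name in ("chosen_idx", "participant", "trial", "rt_ms"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match trial count")

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.stimuli.shape[2:]

    @property
    def selected(self) -> np.ndarray:
        """(n, H, W) float64 — the chosen plane per trial."""
        idx = np.arange(len(self))
        return self.stimuli[idx, self.chosen_idx].astype(np.float64)

    @property
    def unselected_mean(self) -> np.ndarray:
        """(n, H, W) float64 — mean of the two non-chosen planes per trial."""
        total = self.stimuli.sum(axis=1, dtype=np.float64)
        return (total - self.selected) / 2.0

    @property
    def participants(self) -> list[str]:
        return sorted(set(self.participant.tolist()))

    def subset(self, mask: np.ndarray) -> "ChoiceDataset":
        mask = np.asarray(mask)
        return ChoiceDataset(
            stimuli=self.stimuli[mask], chosen_idx=self.chosen_idx[mask],
            participant=self.participant[mask], trial=self.trial[mask],
            rt_ms=self.rt_ms[mask], category=self.category,
        )

    def restrict(self, participant: str) -> "ChoiceDataset":
        return self.subset(self.participant == participant)


@dataclass
class ClassificationImage:
    """Averaged planes and their difference, raw and display-enhanced."""

    selected_mean: np.ndarray
    unselected_mean: np.ndarray
    difference: np.ndarray
    enhanced_selected: np.ndarray
    enhanced_unselected: np.ndarray
    enhanced_difference: np.ndarray
    n_trials: int
    aoi: AOISpec
    M_selected: float
    M_unselected: float
    M_difference: float


def build_choice_dataset(log: pd.DataFrame, store: StimulusStore) -> ChoiceDataset:
    """Assemble the choice dataset from a trial log and its stimulus store.

    Uses the non-correction test trials only; raises on unresolvable ids.
    """
    test = log[(log["trial_type"] == "test") & (~log["is_correction"].astype(bool))]
    if test.empty:
        raise ValueError("log contains no test trials")
    n = len(test)
    h, w = store.geometry.canvas_shape
    stimuli = np.empty((n, 3, h, w), dtype=np.uint8)
    chosen = np.empty(n, dtype=np.int64)
    for i, (_, row) in enumerate(test.iterrows()):
        ids = [row["stim_id_1"], row["stim_id_2"], row["stim_id_3"]]
        try:
            for j, sid in enumerate(ids):
                stimuli[i, j] = store.resolve(sid)
        except KeyError as exc:
            raise ValueError(f"missing stimulus image for trial {row['trial']}") from exc
        chosen[i] = ids.index(row["chosen_stim"])
    categories = test["category"].unique()
    return ChoiceDataset(
        stimuli=stimuli,
        chosen_idx=chosen,
        participant=test["participant"].to_numpy(dtype=object),
        trial=np.arange(n),
        rt_ms=test["rt_ms"].to_numpy(dtype=np.float64),
        category=categories[0] if len(categories) == 1 else "mixed",
    )


def concat_datasets(datasets: list[ChoiceDataset]) -> ChoiceDataset:
    """Stack several choice datasets (e.g. one per participant) into one.

    Trial ids are renumbered to stay unique across the combined dataset.
    """
    if not datasets:
        raise ValueError("nothing to concatenate")
    shapes = {ds.plane_shape for ds in datasets}
    if len(shapes) != 1:
        raise ValueError("datasets have mismatched plane shapes")
    cats = {ds.category for ds in datasets}
    n_total = sum(len(ds) for ds in datasets)
    return ChoiceDataset(
        stimuli=np.concatenate([ds.stimuli for ds in datasets]),
        chosen_idx=np.concatenate([ds.chosen_idx for ds in datasets]),
        participant=np.concatenate([ds.participant for ds in datasets]),
        trial=np.arange(n_total),
        rt_ms=np.concatenate([ds.rt_ms for ds in datasets]),
        category=cats.pop() if len(cats) == 1 else "mixed",
    )


def average_planes(ds: ChoiceDataset, which: str) -> np.ndarray:
    """Elementwise mean over trials of the selected or unselected-mean planes."""
    if len(ds) == 0:
        raise ValueError("cannot average an empty dataset")
    if which == "selected":
        return ds.selected.mean(axis=0)
    if which == "unselected":
        return ds.unselected_mean.mean(axis=0)
    raise ValueError("which must be 'selected' or 'unselected'")


def enhance(
    plane: np.ndarray,
    M: float | None = None,
    gain: float = 20.0,
    offset: float = 128.0,
) -> np.ndarray:
    """Contrast-stretch a plane: ``E = clip(round((L - M) * gain + offset))``.

    ``M`` defaults to the mean luminance of the entire plane, making the
    plane's mean the fixed point (mapped to ``offset``).  Rounding is
    half-up; output is uint8.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if M is None:
        M = float(plane.mean())
    return _to_uint8((plane - M) * gain + offset)


def crop_aoi(plane: np.ndarray, aoi: AOISpec) -> np.ndarray:
    """Copy of the AOI sub-grid of a plane."""
    plane = np.asarray(plane)
    if not aoi.fits_inside(plane.shape[:2]):
        raise ValueError(f"AOI {aoi} exceeds plane shape {plane.shape}")
    return plane[aoi.row_slice, aoi.col_slice].copy()


def classification_image(ds: ChoiceDataset, aoi: AOISpec,
                         gain: float = 20.0, offset: float = 128.0) -> ClassificationImage:
    """Full classification-image bundle for one dataset."""
    sel = average_planes(ds, "selected")
    uns = average_planes(ds, "unselected")
    diff = sel - uns
    m_sel, m_uns, m_diff = float(sel.mean()), float(uns.mean()), float(diff.mean())
    return ClassificationImage(
        selected_mean=sel, unselected_mean=uns, difference=diff,
        enhanced_selected=enhance(sel, m_sel, gain, offset),
        enhanced_unselected=enhance(uns, m_uns, gain, offset),
        enhanced_difference=enhance(diff, m_diff, gain, offset),
        n_trials=len(ds), aoi=aoi,
        M_selected=m_sel, M_unselected=m_uns, M_difference=m_diff,
    )
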