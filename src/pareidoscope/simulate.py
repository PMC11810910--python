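"""Oddity-task session plans and synthetic template-matching observers.

A test session holds 48 trials — 24 difficult baseline, 12 easy baseline and
12 target-absent test trials — in random order.  On each trial three stimuli
occupy three of six cells of a 3 x 2 grid.  Baseline trials embed one target
(at the easy or difficult opacity) among two noise distractors and reward
correct choices; test trials present three unique noise patterns and reward
any choice with probability 0.5, which decouples reward from choice and
discourages position habits.  After an incorrect baseline trial a single
correction trial re-presents the previous target; correction trials are
flagged and excluded from analysis.

The synthetic observer operationalises a "search image": it correlates an
internal template with the central region of each stimulus and chooses via a
softmax over ``beta * similarity + position_bias``, with a lapse rate of
fully random choices and a response time that decreases with the strongest
evidence on the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, StimulusGeometry
from .stimuli import (
    CATEGORIES,
    CompositeStimulus,
    TargetImage,
    composite_target,
    generate_noise,
    make_target_bank,
)

#: per-session trial composition (counts by trial type)
DEFAULT_COMPOSITION = {"baseline_easy": 12, "baseline_difficult": 24, "test": 12}
N_GRID_CELLS = 6  # 3 columns x 2 rows, indexed 0-5 row-major

DEFAULT_OPACITY = {"easy": 0.50, "difficult": 0.20}

LOG_COLUMNS = [
    "participant", "session", "trial", "trial_type", "category",
    "stim_id_1", "stim_id_2", "stim_id_3", "cell_1", "cell_2", "cell_3",
    "chosen_cell", "chosen_stim", "rt_ms", "rewarded", "correct", "is_correction",
]


@dataclass(frozen=True)
class TrialPlan:
    session_index: int
    trial_index: int
    trial_type: str  # baseline_easy | baseline_difficult | test
    category: str
    stimulus_ids: tuple[str, ...]  # 3 ids, target first for baseline trials
    grid_cells: tuple[int, ...]  # cells occupied by the stimuli, aligned with ids
    correct_cell: int | None  # None on test trials
    target_index: int | None = None
    opacity: float = 0.0


@dataclass(frozen=True)
class TrialRecord:
    plan: TrialPlan
    chosen_cell: int
    chosen_stimulus_id: str
    rt_ms: float
    rewarded: bool
    correct: bool | None
    is_correction: bool = False


@dataclass
class ObserverParams:
    """Template-similarity observer with softmax choice and noisy RTs.

    template      : luminance grid, sized to the geometry's AOI
    beta          : softmax inverse temperature (>= 0)
    position_bias : 6 additive cell utilities
    lapse         : probability of a fully random choice
    rt_base/rt_slope/rt_sd : linear evidence-dependent RT model (ms);
        rt = rt_base - rt_slope * max(similarity) + N(0, rt_sd), floored at 1
    """

    template: np.ndarray
    beta: float = 15.0
    position_bias: np.ndarray = field(default_factory=lambda: np.zeros(N_GRID_CELLS))
    lapse: float = 0.02
    rt_base: float = 1400.0
    rt_slope: float = 1500.0
    rt_sd: float = 150.0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=np.float64)
        self.position_bias = np.asarray(self.position_bias, dtype=np.float64)
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if self.position_bias.shape != (N_GRID_CELLS,):
            raise ValueError(f"position_bias must have {N_GRID_CELLS} entries")
        if self.template.std() == 0:
            raise ValueError("degenerate template: zero variance")


def template_from_bank(bank: Sequence[TargetImage]) -> np.ndarray:
    """Category prototype: the pixelwise mean of a target bank."""
    return np.mean([t.pixels.astype(np.float64) for t in bank], axis=0)


class StimulusStore:
    """Deterministic id -> pixel-plane resolver.

    Stimulus ids are self-describing: ``n<k>`` is the k-th unique noise
    canvas of the experiment (seeded by ``(master_seed, k)``) and
    ``c<k>:<category>:<target_index>:<opacity>`` composites target
    ``target_index`` of the category bank onto noise ``k``.  Resolution is
    pure, so stores never need to persist pixel data.
    """

    def __init__(
        self,
        master_seed: int,
        geometry: StimulusGeometry = DEFAULT_GEOMETRY,
        noise_mean: float = 128.0,
        noise_sd: float = 30.0,
        bank_size: int = 20,
        bank_seed: int | None = None,
    ) -> None:
        self.master_seed = int(master_seed)
        self.geometry = geometry
        self.noise_mean = noise_mean
        self.noise_sd = noise_sd
        self.bank_size = bank_size
        self.bank_seed = self.master_seed if bank_seed is None else int(bank_seed)
        self._banks: dict[str, list[TargetImage]] = {}
        self._counter = 0
        # caching pays off only for small canvases (fixture scales)
        self._cache: dict[str, np.ndarray] | None = (
            {} if geometry.canvas_height * geometry.canvas_width <= 20_000 else None
        )

    # -- id allocation -----------------------------------------------------
    def new_noise_id(self) -> str:
        nid = f"n{self._counter}"
        self._counter += 1
        return nid

    def new_composite_id(self, category: str, target_index: int, opacity: float) -> str:
        cid = f"c{self._counter}:{category}:{target_index}:{opacity:g}"
        self._counter += 1
        return cid

    # -- banks -------------------------------------------------------------
    def bank(self, category: str) -> list[TargetImage]:
        if category not in self._banks:
            self._banks[category] = make_target_bank(
                category, self.bank_size, seed=self.bank_seed, geometry=self.geometry
            )
        return self._banks[category]

    # -- resolution --------------------------------------------------------
    def _noise_from_counter(self, k: int, canvas_id: str):
        seed_pair = np.random.default_rng([self.master_seed, k]).integers(0, 2**31)
        return generate_noise(
            self.geometry.canvas_width,
            self.geometry.canvas_height,
            mean=self.noise_mean,
            sd=self.noise_sd,
            seed=int(seed_pair),
            canvas_id=canvas_id,
        )

    def resolve(self, stimulus_id: str) -> np.ndarray:
        """Return the unframed uint8 pixel plane for a stimulus id."""
        if self._cache is not None and stimulus_id in self._cache:
            return self._cache[stimulus_id]
        if stimulus_id.startswith("n"):
            pixels = self._noise_from_counter(int(stimulus_id[1:]), stimulus_id).pixels
        elif stimulus_id.startswith("c"):
            head, category, tindex, opacity = stimulus_id.split(":")
            noise = self._noise_from_counter(int(head[1:]), stimulus_id)
            target = self.bank(category)[int(tindex) - 1]
            pixels = composite_target(noise, target, float(opacity), self.geometry).pixels
        else:
            raise KeyError(f"unresolvable stimulus id {stimulus_id!r}")
        if self._cache is not None:
            self._cache[stimulus_id] = pixels
        return pixels

    def resolve_composite(self, stimulus_id: str) -> CompositeStimulus:
        pixels = self.resolve(stimulus_id)
        if stimulus_id.startswith("c"):
            _, category, tindex, opacity = stimulus_id.split(":")
            return CompositeStimulus(pixels, stimulus_id, (category, int(tindex)), float(opacity))
        return CompositeStimulus(pixels, stimulus_id, None, 0.0)


def build_experiment(
    category: str,
    n_sessions: int,
    seed: int,
    geometry: StimulusGeometry = DEFAULT_GEOMETRY,
    composition: dict[str, int] | None = None,
    opacity: dict[str, float] | None = None,
    noise_mean: float = 128.0,
    noise_sd: float = 30.0,
    bank_size: int = 20,
    store: StimulusStore | None = None,
) -> tuple[list[TrialPlan], StimulusStore]:
    """Plan ``n_sessions`` independently shuffled sessions for one category.

    Every noise canvas id is unique across the whole experiment.  Returns
    the trial plans together with the store that resolves their stimuli.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if n_sessions < 1:
        raise ValueError("need at least one session")
    composition = dict(DEFAULT_COMPOSITION if composition is None else composition)
    opacity = dict(DEFAULT_OPACITY if opacity is None else opacity)
    if store is None:
        store = StimulusStore(
            master_seed=seed, geometry=geometry, noise_mean=noise_mean,
            noise_sd=noise_sd, bank_size=bank_size,
        )
    rng = np.random.default_rng([int(seed), 9173])
    plans: list[TrialPlan] = []
    for s in range(n_sessions):
        types = [t for t, k in composition.items() for _ in range(k)]
        rng.shuffle(types)
        for t_idx, trial_type in enumerate(types):
            cells = tuple(int(c) for c in rng.choice(N_GRID_CELLS, size=3, replace=False))
            if trial_type == "test":
                ids = tuple(store.new_noise_id() for _ in range(3))
                plans.append(TrialPlan(s, t_idx, trial_type, category, ids, cells, None))
            else:
                level = "easy" if trial_type == "baseline_easy" else "difficult"
                target_index = int(rng.integers(1, store.bank_size + 1))
                tid = store.new_composite_id(category, target_index, opacity[level])
                ids = (tid, store.new_noise_id(), store.new_noise_id())
                plans.append(
                    TrialPlan(
                        s, t_idx, trial_type, category, ids, cells,
                        correct_cell=cells[0], target_index=target_index,
                        opacity=opacity[level],
                    )
                )
    return plans, store


# ---------------------------------------------------------------------------
# observer simulation
# ---------------------------------------------------------------------------


def _similarity(template: np.ndarray, plane: np.ndarray, geometry: StimulusGeometry) -> float:
    """Pearson correlation between the template and a stimulus AOI."""
    aoi = geometry.aoi
    patch = plane[aoi.row_slice, aoi.col_slice].astype(np.float64)
    t = template - template.mean()
    p = patch - patch.mean()
    denom = np.sqrt((t * t).sum() * (p * p).sum())
    if denom == 0:
        return 0.0
    return float((t * p).sum() / denom)


def simulate_choice(
    stimuli: Sequence[np.ndarray | CompositeStimulus],
    plan: TrialPlan,
    obs: ObserverParams,
    rng: np.random.Generator,
    geometry: StimulusGeometry = DEFAULT_GEOMETRY,
) -> TrialRecord:
    """Simulate one trial: softmax choice over template similarity, RT, reward."""
    if len(stimuli) != len(plan.stimulus_ids):
        raise ValueError("stimuli must align with the trial plan")
    planes = [s.pixels if isinstance(s, CompositeStimulus) else np.asarray(s) for s in stimuli]
    if obs.template.std() == 0:
        raise ValueError("degenerate template: zero variance")
    sims = np.array([_similarity(obs.template, p, geometry) for p in planes])
    utilities = obs.beta * sims + obs.position_bias[list(plan.grid_cells)]
    u = utilities - utilities.max()
    probs = np.exp(u) / np.exp(u).sum()
    if obs.lapse > 0 and rng.random() < obs.lapse:
        k = int(rng.integers(len(planes)))
    else:
        k = int(rng.choice(len(planes), p=probs))
    rt = obs.rt_base - obs.rt_slope * float(sims.max()) + rng.normal(0.0, obs.rt_sd)
    rt = max(rt, 1.0)
    chosen_cell = plan.grid_cells[k]
    if plan.trial_type == "test":
        rewarded = bool(rng.random() < 0.5)  # non-contingent 50% reward
        correct: bool | None = None
    else:
        correct = chosen_cell == plan.correct_cell
        rewarded = bool(correct)
    return TrialRecord(
        plan=plan, chosen_cell=chosen_cell, chosen_stimulus_id=plan.stimulus_ids[k],
        rt_ms=float(rt), rewarded=rewarded, correct=correct,
    )


def _record_to_row(rec: TrialRecord, participant: str) -> dict:
    p = rec.plan
    ids = list(p.stimulus_ids) + [""] * (3 - len(p.stimulus_ids))
    cells = list(p.grid_cells) + [-1] * (3 - len(p.grid_cells))
    return {
        "participant": participant, "session": p.session_index, "trial": p.trial_index,
        "trial_type": p.trial_type, "category": p.category,
        "stim_id_1": ids[0], "stim_id_2": ids[1], "stim_id_3": ids[2],
        "cell_1": cells[0], "cell_2": cells[1], "cell_3": cells[2],
        "chosen_cell": rec.chosen_cell, "chosen_stim": rec.chosen_stimulus_id,
        "rt_ms": rec.rt_ms, "rewarded": rec.rewarded,
        "correct": rec.correct, "is_correction": rec.is_correction,
    }


def run_experiment(
    plans: Sequence[TrialPlan],
    obs: ObserverParams,
    store: StimulusStore,
    seed: int,
    participant: str = "S01",
) -> pd.DataFrame:
    """Run an observer through a planned experiment, returning the trial log.

    After each incorrect baseline trial one correction trial (the previous
    target alone, always resolved) is appended and flagged.
    """
    rng = np.random.default_rng([int(seed), 551])
    geometry = store.geometry
    rows: list[dict] = []
    for plan in plans:
        planes = [store.resolve(sid) for sid in plan.stimulus_ids]
        rec = simulate_choice(planes, plan, obs, rng, geometry)
        rows.append(_record_to_row(rec, participant))
        if rec.correct is False:
            # correction: only the previous target, always "chosen" and rewarded
            cplan = TrialPlan(
                plan.session_index, plan.trial_index, "correction", plan.category,
                (plan.stimulus_ids[0],), (plan.correct_cell,), plan.correct_cell,
                plan.target_index, plan.opacity,
            )
            sim = _similarity(obs.template, planes[0], geometry)
            crt = max(obs.rt_base - obs.rt_slope * sim + rng.normal(0.0, obs.rt_sd), 1.0)
            rows.append(
                _record_to_row(
                    TrialRecord(cplan, plan.correct_cell, plan.stimulus_ids[0],
                                float(crt), True, True, is_correction=True),
                    participant,
                )
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def stimulus_manifest(plans: Sequence[TrialPlan], master_seed: int) -> pd.DataFrame:
    """Tabulate every planned stimulus: id, category, target index, opacity.

    Target-absent noise rows have a missing target index and opacity 0.
    """
    rows = []
    for plan in plans:
        for sid in plan.stimulus_ids:
            is_target = sid.startswith("c")
            rows.append(
                {
                    "id": sid,
                    "category": plan.category if is_target else "",
                    "target_index": plan.target_index if is_target else pd.NA,
                    "opacity": plan.opacity if is_target else 0.0,
                    "seed": master_seed,
                }
            )
    return pd.DataFrame(rows)


def simulate_test_trials(
    n_trials: int,
    obs: ObserverParams,
    seed: int,
    geometry: StimulusGeometry = DEFAULT_GEOMETRY,
    noise_mean: float = 128.0,
    noise_sd: float = 30.0,
    category: str = "human_face",
) -> pd.DataFrame:
    """Simulate ``n_trials`` stand-alone test trials (all-noise, 50% reward).

    Convenience path for calibration checks of the reward rule at large n
    without planning full sessions.
    """
    store = StimulusStore(master_seed=seed, geometry=geometry,
                          noise_mean=noise_mean, noise_sd=noise_sd)
    rng = np.random.default_rng([int(seed), 552])
    plan_rng = np.random.default_rng([int(seed), 553])
    rows = []
    for i in range(n_trials):
        cells = tuple(int(c) for c in plan_rng.choice(N_GRID_CELLS, size=3, replace=False))
        ids = tuple(store.new_noise_id() for _ in range(3))
        plan = TrialPlan(0, i, "test", category, ids, cells, None)
        planes = [store.resolve(sid) for sid in ids]
        rec = simulate_choice(planes, plan, obs, rng, geometry)
        rows.append(_record_to_row(rec, "S01"))
    return pd.DataFrame(rows, columns=LOG_COLUMNS)
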