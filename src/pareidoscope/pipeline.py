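"""End-to-end experiment orchestration: simulate -> analyze -> null -> report.

``ExperimentConfig`` carries the full study design (session composition,
noise and opacity parameters, observer settings, AOI and FDR level) with
defaults matching the reference design: 48-trial sessions (24 difficult +
12 easy baseline, 12 test), 25 sessions per category, 5 participants, a
200 x 220 centred AOI and q = 0.05.  ``run_pipeline`` materialises every
stage into an output directory deterministically under the config seed;
``make_fixtures`` produces proportionally scaled-down experiments (tiny /
small) used throughout the test suite and documentation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification as ci
from . import pixelstats as px
from . import secondary as sec
from .geometry import StimulusGeometry
from .simulate import (
    DEFAULT_COMPOSITION,
    DEFAULT_OPACITY,
    ObserverParams,
    StimulusStore,
    build_experiment,
    run_experiment,
    stimulus_manifest,
    template_from_bank,
)
from .stimuli import CATEGORIES, save_png


@dataclass
class ObserverConfig:
    """Observer population settings (template comes from the category bank)."""

    beta: float = 15.0
    lapse: float = 0.02
    rt_base: float = 1400.0
    rt_slope: float = 1500.0
    rt_sd: float = 150.0
    position_bias_sd: float = 0.3  # per-participant bias jitter (utility units)


@dataclass
class ExperimentConfig:
    categories: tuple[str, ...] = CATEGORIES
    n_sessions: int = 25
    participants: tuple[str, ...] = ("S01", "S02", "S03", "S04", "S05")
    composition: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    noise_mean: float = 128.0
    noise_sd: float = 30.0
    opacity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OPACITY))
    bank_size: int = 20
    geometry_scale: float = 1.0
    q: float = 0.05
    seed: int = 0
    observer: ObserverConfig = field(default_factory=ObserverConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if self.n_sessions < 1:
            raise ValueError("need at least one session")
        if not self.participants:
            raise ValueError("need at least one participant")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        for key in ("baseline_easy", "baseline_difficult", "test"):
            if self.composition.get(key, 0) < 1:
                raise ValueError(f"composition must include {key} trials")
        for level in ("easy", "difficult"):
            if not 0.0 <= self.opacity.get(level, -1) <= 1.0:
                raise ValueError(f"opacity.{level} must lie in [0, 1]")

    @property
    def geometry(self) -> StimulusGeometry:
        return (
            StimulusGeometry()
            if self.geometry_scale == 1.0
            else StimulusGeometry.scaled(self.geometry_scale)
        )

    @property
    def session_length(self) -> int:
        return sum(self.composition.values())

    # -- (de)serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["categories"] = list(self.categories)
        payload["participants"] = list(self.participants)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["observer"] = ObserverConfig(**payload.get("observer", {}))
        payload["categories"] = tuple(payload.get("categories", CATEGORIES))
        payload["participants"] = tuple(payload["participants"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# deterministic sub-seeding and observer construction
# ---------------------------------------------------------------------------


def _sub_seed(config: ExperimentConfig, category: str, participant: str) -> int:
    ci_ = list(config.categories).index(category)
    pi = list(config.participants).index(participant)
    return int(config.seed) * 7919 + ci_ * 101 + pi + 1


def make_observer(
    config: ExperimentConfig, category: str, participant: str, store: StimulusStore
) -> ObserverParams:
    """Participant-specific observer: category-prototype template plus
    jittered position bias and RT baseline."""
    oc = config.observer
    rng = np.random.default_rng([int(config.seed), 77, _sub_seed(config, category, participant)])
    return ObserverParams(
        template=template_from_bank(store.bank(category)),
        beta=oc.beta,
        position_bias=rng.normal(0.0, oc.position_bias_sd, 6),
        lapse=oc.lapse,
        rt_base=oc.rt_base + rng.normal(0.0, 50.0),
        rt_slope=oc.rt_slope,
        rt_sd=oc.rt_sd,
    )


def simulate_participant(
    config: ExperimentConfig, category: str, participant: str
) -> tuple[pd.DataFrame, StimulusStore]:
    """Plan and run one participant's sessions for one category."""
    seed = _sub_seed(config, category, participant)
    plans, store = build_experiment(
        category, config.n_sessions, seed=seed, geometry=config.geometry,
        composition=config.composition, opacity=config.opacity,
        noise_mean=config.noise_mean, noise_sd=config.noise_sd,
        bank_size=config.bank_size,
    )
    obs = make_observer(config, category, participant, store)
    log = run_experiment(plans, obs, store, seed=seed, participant=participant)
    return log, store


def build_category_dataset(
    config: ExperimentConfig, category: str,
    logs: dict[str, pd.DataFrame] | None = None,
) -> tuple[ci.ChoiceDataset, pd.DataFrame]:
    """Simulate (or reuse) all participants for a category; return the
    combined choice dataset and log."""
    datasets, frames = [], []
    for participant in config.participants:
        if logs is not None and participant in logs:
            log = logs[participant]
            # store is reconstructable because simulation is deterministic
            _, store = build_experiment(
                category, config.n_sessions, seed=_sub_seed(config, category, participant),
                geometry=config.geometry, composition=config.composition,
                opacity=config.opacity, noise_mean=config.noise_mean,
                noise_sd=config.noise_sd, bank_size=config.bank_size,
            )
        else:
            log, store = simulate_participant(config, category, participant)
        frames.append(log)
        datasets.append(ci.build_choice_dataset(log, store))
    return ci.concat_datasets(datasets), pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def run_pipeline(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write artifacts under ``out_dir``.

    Layout: ``config.yaml``, ``logs/``, ``classification/`` (enhanced PNGs +
    raw AOI difference CSVs), ``stats/`` (per-pixel CSVs + heatmap PNGs,
    including a random-selection null per category), ``report.json``.
    Outputs are deterministic under the config seed.
    """
    out = Path(out_dir)
    for sub in ("logs", "classification", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    aoi = config.geometry.aoi

    report: dict = {"seed": config.seed, "categories": {}}
    all_logs: list[pd.DataFrame] = []
    diff_planes: dict[str, np.ndarray] = {}
    for category in config.categories:
        ds, log = build_category_dataset(config, category)
        log.to_csv(out / "logs" / f"{category}.csv", index=False)
        all_logs.append(log)

        manifests = []
        for participant in config.participants:
            seed = _sub_seed(config, category, participant)
            plans, _ = build_experiment(
                category, config.n_sessions, seed=seed, geometry=config.geometry,
                composition=config.composition, opacity=config.opacity,
                noise_mean=config.noise_mean, noise_sd=config.noise_sd,
                bank_size=config.bank_size,
            )
            manifests.append(stimulus_manifest(plans, seed).assign(participant=participant))
        pd.concat(manifests, ignore_index=True).to_csv(
            out / "logs" / f"{category}_stimuli.csv", index=False
        )

        image = ci.classification_image(ds, aoi)
        for name in ("enhanced_selected", "enhanced_unselected", "enhanced_difference"):
            save_png(getattr(image, name), out / "classification" / f"{category}_{name}.png")
        diff_aoi = ci.crop_aoi(image.difference, aoi)
        pd.DataFrame(diff_aoi).to_csv(
            out / "classification" / f"{category}_difference_aoi.csv",
            index=False, header=False,
        )
        diff_planes[category] = image.difference

        smap = px.pixelwise_mixed_model(ds, aoi, variant="group", q=config.q)
        px.render_heatmap(
            smap, out / "stats" / f"{category}_heatmap.png",
            out / "stats" / f"{category}_pixels.csv",
        )
        null_ds = px.random_selection_null(ds, seed=config.seed)
        null_map = px.pixelwise_mixed_model(null_ds, aoi, variant="group", q=config.q)
        px.render_heatmap(
            null_map, out / "stats" / f"{category}_null_heatmap.png",
            out / "stats" / f"{category}_null_pixels.csv",
        )

        test_log = log[(log["trial_type"] == "test") & (~log["is_correction"].astype(bool))]
        base_log = log[log["trial_type"].str.startswith("baseline")]
        report["categories"][category] = {
            "n_test_trials": int(len(test_log)),
            "test_reward_rate": float(test_log["rewarded"].mean()),
            "baseline_error_rate": float(1.0 - base_log["correct"].astype(float).mean()),
            "n_sig_pixels": int(smap.sig_mask.sum()),
            "n_sig_pixels_null": int(null_map.sig_mask.sum()),
            "aoi_mean_difference": float(diff_aoi.mean()),
        }

    combined_log = pd.concat(all_logs, ignore_index=True)
    rt_result = sec.log_rt_mixed_model(combined_log)
    rt_result.contrasts.to_csv(out / "rt_contrasts.csv", index=False)
    report["rt_contrasts"] = rt_result.contrasts.to_dict(orient="records")

    bias = sec.position_bias_chisq(combined_log)
    bias.to_csv(out / "position_bias.csv", index=False)

    if len(diff_planes) >= 2:
        brightness = sec.brightness_difference_model(diff_planes, aoi)
        brightness.category_stats.to_csv(out / "brightness_categories.csv", index=False)
        brightness.contrasts.to_csv(out / "brightness_contrasts.csv", index=False)
        report["brightness"] = {
            "category_means": brightness.category_stats.to_dict(orient="records"),
            "contrasts": brightness.contrasts.to_dict(orient="records"),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return out


def null_calibration(
    ds: ci.ChoiceDataset,
    aoi,
    n_replicates: int,
    seed: int,
    q: float = 0.05,
) -> pd.DataFrame:
    """Repeat the random-selection analysis; report discoveries per replicate.

    Each replicate redraws the "selected" stimulus uniformly and re-runs the
    per-pixel map + BH adjustment.  Under this computer-random selection the
    family of FDR-significant pixels should be empty in ~95% of replicates.
    """
    rows = []
    for r in range(n_replicates):
        null_ds = px.random_selection_null(ds, seed=seed * 100_003 + r)
        smap = px.pixelwise_mixed_model(null_ds, aoi, variant="fast_paired", q=q)
        rows.append(
            {"replicate": r, "n_sig_pixels": int(smap.sig_mask.sum()),
             "min_p_fdr": float(np.nanmin(smap.p_fdr)),
             "n_singular": smap.n_singular}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_SCALES = {
    # geometry scale, participants, sessions per category
    "tiny": (0.1, 3, 3),
    "small": (0.25, 3, 9),
}


@dataclass
class Fixture:
    """A miniature, fully simulated experiment for tests and examples."""

    config: ExperimentConfig
    category: str
    ds: ci.ChoiceDataset
    log: pd.DataFrame
    stores: dict[str, StimulusStore]
    observers: dict[str, ObserverParams]

    @property
    def geometry(self) -> StimulusGeometry:
        return self.config.geometry

    @property
    def aoi(self):
        return self.config.geometry.aoi


def make_fixtures(
    scale: str = "tiny",
    seed: int = 0,
    category: str = "human_face",
    observer_overrides: dict | None = None,
) -> Fixture:
    """Build a miniature single-category experiment.

    ``tiny`` uses a 1/10-scale geometry (30 x 35 canvas, 20 x 22 AOI) with
    3 participants x 3 sessions; ``small`` is 1/4 scale with 9 sessions.
    ``observer_overrides`` patches ObserverConfig fields (e.g. beta=0 for a
    random observer).
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    factor, n_participants, n_sessions = FIXTURE_SCALES[scale]
    config = ExperimentConfig(
        categories=(category,),
        n_sessions=n_sessions,
        participants=tuple(f"S{i + 1:02d}" for i in range(n_participants)),
        geometry_scale=factor,
        seed=seed,
        observer=ObserverConfig(**(observer_overrides or {})),
    )
    datasets, frames, stores, observers = [], [], {}, {}
    for participant in config.participants:
        log, store = simulate_participant(config, category, participant)
        frames.append(log)
        datasets.append(ci.build_choice_dataset(log, store))
        stores[participant] = store
        observers[participant] = make_observer(config, category, participant, store)
    return Fixture(
        config=config, category=category,
        ds=ci.concat_datasets(datasets), log=pd.concat(frames, ignore_index=True),
        stores=stores, observers=observers,
    )
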