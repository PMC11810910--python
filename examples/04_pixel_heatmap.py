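"""Per-pixel mixed-model heatmaps with FDR control, and the random null.

Fits the selected-vs-unselected condition model at every AOI pixel for a
template observer's 300 test trials, adjusts p-values by
Benjamini-Hochberg at q = 0.05, and contrasts the observer's map with a
computer-random selection of the same stimuli — the latter should show
(almost) nothing.
"""

from pathlib import Path

import pareidoscope as ps
from pareidoscope.pipeline import ExperimentConfig, ObserverConfig, simulate_participant

out = Path("example_output/heatmaps")
out.mkdir(parents=True, exist_ok=True)

cfg = ExperimentConfig(
    categories=("human_face",), n_sessions=25, participants=("S01",),
    geometry_scale=0.1, seed=1, observer=ObserverConfig(beta=50.0, lapse=0.0),
)
log, store = simulate_participant(cfg, "human_face", "S01")
ds = ps.build_choice_dataset(log, store)
aoi = cfg.geometry.aoi

smap = ps.pixelwise_mixed_model(ds, aoi, variant="individual", q=0.05)
print(f"observer map:  {int(smap.sig_mask.sum()):4d} / {aoi.n_pixels} "
      f"FDR-significant pixels (q={smap.q})")

null_ds = ps.random_selection_null(ds, seed=0)
null_map = ps.pixelwise_mixed_model(null_ds, aoi, variant="individual", q=0.05)
print(f"random null:   {int(null_map.sig_mask.sum()):4d} / {aoi.n_pixels} "
      "FDR-significant pixels")

ps.render_heatmap(smap, out / "observer_heatmap.png", out / "observer_pixels.csv")
ps.render_heatmap(null_map, out / "null_heatmap.png", out / "null_pixels.csv")
print(f"heatmaps + per-pixel tables written to {out}/")
print("\nsignificant structure appears only when choices carry pixel "
      "information, mirroring the observer-vs-random contrast.")
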