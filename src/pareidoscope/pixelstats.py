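"""Per-pixel mixed-model maps of selected vs unselected luminance, with FDR.

At every AOI coordinate the condition effect (selected minus unselected) is
tested with a linear mixed model whose random intercepts are participants
and trials nested within participants.  Because each trial contributes
exactly one selected and one unselected observation per pixel, both random
intercepts cancel in the within-trial difference, so the model reduces
*exactly* to a one-sample problem on per-trial differences: the REML
fixed-effect estimate is the mean difference, its variance is estimated
from the difference variance alone, and the Satterthwaite denominator
degrees of freedom equal ``n_trials - 1`` whenever the variance components
are interior.  The vectorised paired reduction is therefore the default
full-AOI path (``fast_paired``); :func:`mixedlm_single_pixel` fits the
generic model numerically with statsmodels for spot verification.

Raw p-values are corrected over all non-degenerate AOI pixels jointly by
the Benjamini–Hochberg step-up at ``q`` (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classification import ChoiceDataset, crop_aoi
from .geometry import AOISpec

VARIANTS = ("group", "individual", "fast_paired")


@dataclass
class PixelStatMap:
    """Per-pixel condition-effect estimates with raw and FDR-adjusted p."""

    estimate: np.ndarray  # luminance units, AOI-shaped
    p_raw: np.ndarray  # NaN where the pixel was degenerate
    p_fdr: np.ndarray
    sig_mask: np.ndarray
    q: float
    model_variant: str
    aoi: AOISpec
    n_trials: int
    df: float
    n_singular: int = 0

    def __post_init__(self) -> None:
        shapes = {self.estimate.shape, self.p_raw.shape, self.p_fdr.shape, self.sig_mask.shape}
        if len(shapes) != 1:
            raise ValueError("all planes must share the AOI shape")


def _paired_stats(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Vectorised paired t over axis 0: estimate, two-sided p, n_singular, df."""
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials for per-pixel inference")
    est = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    singular = sd == 0
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(tval), df)
    p[singular] = np.nan
    return est, p, int(singular.sum()), float(df)


def pixelwise_mixed_model(
    ds: ChoiceDataset,
    aoi: AOISpec,
    variant: str = "fast_paired",
    q: float = 0.05,
) -> PixelStatMap:
    """Fit the per-pixel condition model over the AOI and BH-adjust p-values.

    variant:
      - ``group``: participant + trial-nested random intercepts; requires
        at least 2 participants.  Fitted by the exact paired reduction.
      - ``individual``: trial-only random intercept, for one participant's
        data.
      - ``fast_paired``: the paired reduction with no participant-count
        validation (identical arithmetic; the full-AOI fast path).

    Degenerate (zero-variance) pixels are flagged, their p set missing and
    excluded from the FDR family; ``n_singular`` reports the count.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    n_participants = len(ds.participants)
    if variant == "group" and n_participants < 2:
        raise ValueError("group variant requires at least 2 participants")
    if variant == "individual" and n_participants != 1:
        raise ValueError("individual variant expects a single participant's dataset")
    diffs = (ds.selected - ds.unselected_mean)[:, aoi.row_slice, aoi.col_slice]
    est, p_raw, n_singular, df = _paired_stats(diffs)
    p_fdr, sig = fdr_adjust(p_raw, q)
    return PixelStatMap(
        estimate=est, p_raw=p_raw, p_fdr=p_fdr, sig_mask=sig, q=q,
        model_variant=variant, aoi=aoi, n_trials=len(ds), df=df,
        n_singular=n_singular,
    )


def fdr_adjust(p_raw: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up over all non-missing entries jointly.

    Returns the adjusted-p plane (NaN preserved) and the significance mask
    ``p_fdr <= q``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p_raw = np.asarray(p_raw, dtype=np.float64)
    valid = ~np.isnan(p_raw)
    if not valid.any():
        raise ValueError("no valid p-values to adjust")
    p_fdr = np.full_like(p_raw, np.nan)
    rejected, adjusted, _, _ = multipletests(p_raw[valid], alpha=q, method="fdr_bh")
    p_fdr[valid] = adjusted
    sig = np.zeros_like(valid)
    sig[valid] = rejected
    return p_fdr, sig


def random_selection_null(ds: ChoiceDataset, seed: int) -> ChoiceDataset:
    """Re-draw each trial's "selected" stimulus uniformly at random.

    Emulates computer-random selection: same trials and stimuli, choice
    replaced by a uniform draw over the three presented patterns, with the
    unselected mean recomputed implicitly.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng([int(seed), 7919])
    new_idx = rng.integers(0, 3, size=len(ds))
    return ChoiceDataset(
        stimuli=ds.stimuli, chosen_idx=new_idx, participant=ds.participant,
        trial=ds.trial, rt_ms=ds.rt_ms, category=ds.category,
    )


# ---------------------------------------------------------------------------
# generic (numerical) mixed-model route for spot verification
# ---------------------------------------------------------------------------


def mixedlm_single_pixel(ds: ChoiceDataset, row: int, col: int) -> dict[str, float]:
    """Fit the full two-condition mixed model at one canvas pixel.

    Long format: two observations per trial (selected, unselected mean),
    participant random intercept plus trial variance component, fitted by
    REML with statsmodels.  The p-value uses a t reference with the paired
    Satterthwaite df (``n_trials - 1``).  Coordinates are canvas-absolute.
    """
    import statsmodels.formula.api as smf

    n = len(ds)
    sel = ds.selected[:, row, col]
    uns = ds.unselected_mean[:, row, col]
    frame = pd.DataFrame(
        {
            "luminance": np.concatenate([sel, uns]),
            "condition": np.repeat([1.0, 0.0], n),  # 1 = selected
            "participant": np.tile(ds.participant, 2),
            "trial": np.tile(ds.trial, 2).astype(str),
        }
    )
    model = smf.mixedlm(
        "luminance ~ condition", frame, groups="participant",
        re_formula="1", vc_formula={"trial": "0 + C(trial)"},
    )
    fit = model.fit(reml=True, method="powell", maxiter=2000)
    est = float(fit.params["condition"])
    se = float(fit.bse["condition"])
    df = n - 1
    tval = est / se
    return {
        "estimate": est, "se": se, "df": float(df),
        "p": float(2.0 * sps.t.sf(abs(tval), df)),
    }


# ---------------------------------------------------------------------------
# serialization / rendering
# ---------------------------------------------------------------------------


def stat_map_to_frame(smap: PixelStatMap) -> pd.DataFrame:
    rows, cols = np.indices(smap.estimate.shape)
    return pd.DataFrame(
        {
            "row": rows.ravel(), "col": cols.ravel(),
            "estimate": smap.estimate.ravel(),
            "p_raw": smap.p_raw.ravel(), "p_fdr": smap.p_fdr.ravel(),
            "sig": smap.sig_mask.ravel(),
        }
    )


def stat_map_from_frame(frame: pd.DataFrame, q: float, variant: str, aoi: AOISpec,
                        n_trials: int = 0, df: float = 0.0) -> PixelStatMap:
    shape = (int(frame["row"].max()) + 1, int(frame["col"].max()) + 1)
    planes = {}
    for key in ("estimate", "p_raw", "p_fdr"):
        plane = np.full(shape, np.nan)
        plane[frame["row"], frame["col"]] = frame[key]
        planes[key] = plane
    sig = np.zeros(shape, dtype=bool)
    sig[frame["row"], frame["col"]] = frame["sig"].astype(bool)
    return PixelStatMap(
        estimate=planes["estimate"], p_raw=planes["p_raw"], p_fdr=planes["p_fdr"],
        sig_mask=sig, q=q, model_variant=variant, aoi=aoi,
        n_trials=n_trials, df=df,
        n_singular=int(np.isnan(planes["p_raw"]).sum()),
    )


def render_heatmap(smap: PixelStatMap, out_png: str | Path, out_csv: str | Path,
                   cmap: str = "hot_r") -> pd.DataFrame:
    """Write the FDR-p heatmap (PNG) and the per-pixel table (CSV)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = stat_map_to_frame(smap)
    frame.to_csv(out_csv, index=False)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5))
    im0 = axes[0].imshow(smap.estimate, cmap="coolwarm")
    axes[0].set_title("condition effect (luminance)")
    fig.colorbar(im0, ax=axes[0], shrink=0.8)
    shown = np.where(np.isnan(smap.p_fdr), 1.0, smap.p_fdr)
    im1 = axes[1].imshow(shown, cmap=cmap, vmin=0.0, vmax=1.0)
    axes[1].set_title(f"FDR-adjusted p (q={smap.q:g})")
    fig.colorbar(im1, ax=axes[1], shrink=0.8)
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
    return frame
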