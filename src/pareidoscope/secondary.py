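"""Supporting analyses: log-RT mixed model, position bias, RT median split,
category brightness contrasts, and image-similarity metrics.

Contrast direction convention: a contrast labelled ``"A_vs_B"`` estimates
``mean(B) - mean(A)`` (second level minus first), on the natural-log scale
for response times and in luminance units for brightness differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classification import ChoiceDataset, crop_aoi
from .geometry import AOISpec
from .pixelstats import PixelStatMap

TRIAL_TYPE_ORDER = ("baseline_easy", "baseline_difficult", "test")
_TYPE_LABEL = {"baseline_easy": "easy", "baseline_difficult": "difficult", "test": "test"}


# ---------------------------------------------------------------------------
# response-time mixed model
# ---------------------------------------------------------------------------


@dataclass
class RTModelResult:
    """Pairwise trial-type contrasts on log RT, per stimulus category."""

    contrasts: pd.DataFrame  # category, contrast, estimate, se, ci_low, ci_high, p
    n_used: int
    n_corrections_excluded: int
    n_missing_dropped: int


def log_rt_mixed_model(log: pd.DataFrame) -> RTModelResult:
    """Mixed model of natural-log RT in test sessions.

    Fixed effects: stimulus category, trial type (easy/difficult/test) and
    their interaction; random intercept per participant.  Correction trials
    are excluded; correct and incorrect trials are both included.  Pairwise
    trial-type contrasts are reported per category with Wald 95% CIs.
    """
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    corrections = log["is_correction"].astype(bool)
    data = log[~corrections].copy()
    n_corr = int(corrections.sum())
    missing = data["rt_ms"].isna() | (data["rt_ms"] <= 0)
    n_missing = int(missing.sum())
    data = data[~missing]
    data["log_rt"] = np.log(data["rt_ms"].astype(float))
    present_types = [t for t in TRIAL_TYPE_ORDER if t in set(data["trial_type"])]
    data["trial_type"] = pd.Categorical(data["trial_type"], categories=present_types)
    categories = sorted(data["category"].unique())
    multi_cat = len(categories) > 1
    formula = (
        "log_rt ~ C(category) * C(trial_type)" if multi_cat else "log_rt ~ C(trial_type)"
    )
    model = smf.mixedlm(formula, data, groups="participant")
    fit = model.fit(reml=True, method="lbfgs")
    design_info = model.data.design_info

    def cell_row(category: str, trial_type: str) -> np.ndarray:
        new = pd.DataFrame({"category": [category], "trial_type": [trial_type]})
        return np.asarray(build_design_matrices([design_info], new)[0])[0]

    rows = []
    pairs = [(a, b) for a, b in
             [("baseline_easy", "baseline_difficult"), ("baseline_easy", "test"),
              ("baseline_difficult", "test")]
             if a in present_types and b in present_types]
    k = len(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k, :k]
    for cat in categories:
        for a, b in pairs:
            L = cell_row(cat, b) - cell_row(cat, a)
            est = float(L @ fit.fe_params)
            se = float(np.sqrt(L @ cov @ L))
            z = est / se if se > 0 else 0.0
            rows.append(
                {
                    "category": cat,
                    "contrast": f"{_TYPE_LABEL[a]}_vs_{_TYPE_LABEL[b]}",
                    "estimate": est, "se": se,
                    "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
                    "p": float(2 * sps.norm.sf(abs(z))),
                }
            )
    return RTModelResult(
        contrasts=pd.DataFrame(rows), n_used=len(data),
        n_corrections_excluded=n_corr, n_missing_dropped=n_missing,
    )


# ---------------------------------------------------------------------------
# position bias and bias-vs-clarity correlation
# ---------------------------------------------------------------------------


def position_bias_chisq(log: pd.DataFrame, n_cells: int = 6) -> pd.DataFrame:
    """Chi-square goodness of fit of chosen grid cells against uniformity.

    Computed over test-trial choices, per (participant, category).
    """
    test = log[(log["trial_type"] == "test") & (~log["is_correction"].astype(bool))]
    if test.empty:
        raise ValueError("log contains no test trials")
    rows = []
    for (participant, category), grp in test.groupby(["participant", "category"]):
        observed = np.bincount(grp["chosen_cell"].astype(int), minlength=n_cells)
        expected = np.full(n_cells, len(grp) / n_cells)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        rows.append(
            {"participant": participant, "category": category,
             "n_trials": len(grp), "chi_square": chi2}
        )
    return pd.DataFrame(rows)


def spearman_corr(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    ``alternative`` may be ``"two-sided"``, ``"less"`` or ``"greater"``
    (one-tailed tests of negative/positive association).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    res = sps.spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def mean_raw_p(smap: PixelStatMap) -> float:
    """Mean uncorrected p-value over all non-degenerate AOI pixels."""
    return float(np.nanmean(smap.p_raw))


def bias_clarity_correlation(summary: pd.DataFrame,
                             alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman correlation between per-condition position bias and map clarity.

    ``summary`` needs columns ``chi_square`` (position bias) and ``mean_p``
    (mean uncorrected AOI p-value), one row per (participant, category).
    """
    return spearman_corr(summary["chi_square"], summary["mean_p"], alternative)


# ---------------------------------------------------------------------------
# response-time median split
# ---------------------------------------------------------------------------


@dataclass
class MedianSplit:
    faster: ChoiceDataset
    slower: ChoiceDataset
    empty_groups: list[str] = field(default_factory=list)


def rt_median_split(ds: ChoiceDataset) -> MedianSplit:
    """Partition a dataset at each participant's median test-trial RT.

    Trials with RT less than or equal to the participant's median go to the
    faster half, the rest to the slower half.  Participants whose slower
    half is empty (e.g. constant RTs) are flagged.
    """
    faster_mask = np.zeros(len(ds), dtype=bool)
    empty: list[str] = []
    for participant in ds.participants:
        pmask = ds.participant == participant
        median = float(np.median(ds.rt_ms[pmask]))
        fast = pmask & (ds.rt_ms <= median)
        faster_mask |= fast
        if fast.sum() == pmask.sum():
            empty.append(participant)
    return MedianSplit(
        faster=ds.subset(faster_mask), slower=ds.subset(~faster_mask),
        empty_groups=empty,
    )


# ---------------------------------------------------------------------------
# category brightness contrasts
# ---------------------------------------------------------------------------


@dataclass
class BrightnessResult:
    category_stats: pd.DataFrame  # category, mean, se, n_coords
    contrasts: pd.DataFrame  # contrast, estimate, se, ci_low, ci_high


def brightness_difference_model(
    diff_planes: dict[str, np.ndarray],
    aoi: AOISpec,
) -> BrightnessResult:
    """Category means/SEs of AOI brightness differences and pairwise contrasts.

    AOI coordinates are the observational units.  Because every category
    map is defined on the same coordinates, pairwise contrasts are paired
    by coordinate: the contrast ``A_vs_B`` is the mean over coordinates of
    ``B - A`` with its paired standard error and Wald 95% CI.
    """
    if len(diff_planes) < 2:
        raise ValueError("need at least two categories")
    values: dict[str, np.ndarray] = {}
    shape = None
    for cat, plane in diff_planes.items():
        v = crop_aoi(np.asarray(plane, dtype=np.float64), aoi).ravel()
        if shape is None:
            shape = v.shape
        elif v.shape != shape:
            raise ValueError("all difference planes must share the AOI shape")
        values[cat] = v
    stats_rows = [
        {"category": cat, "mean": float(v.mean()),
         "se": float(v.std(ddof=1) / np.sqrt(v.size)), "n_coords": int(v.size)}
        for cat, v in values.items()
    ]
    contrast_rows = []
    cats = list(values)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            d = values[b] - values[a]
            est = float(d.mean())
            se = float(d.std(ddof=1) / np.sqrt(d.size))
            contrast_rows.append(
                {"contrast": f"{a}_vs_{b}", "estimate": est, "se": se,
                 "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se}
            )
    return BrightnessResult(
        category_stats=pd.DataFrame(stats_rows),
        contrasts=pd.DataFrame(contrast_rows),
    )


# ---------------------------------------------------------------------------
# image-similarity metrics
# ---------------------------------------------------------------------------


def radial_amplitude_spectrum(plane: np.ndarray) -> np.ndarray:
    """Radially averaged 2-D Fourier amplitude spectrum.

    The plane is mean-removed, transformed, and the amplitude is averaged
    over integer-radius annuli around the spectrum centre; the profile has
    ``floor(min(h, w) / 2)`` bins (radius 0 = DC, which is ~0 after mean
    removal).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("expected a 2-D luminance plane")
    h, w = plane.shape
    amp = np.abs(np.fft.fftshift(np.fft.fft2(plane - plane.mean())))
    cy, cx = h // 2, w // 2
    rows, cols = np.indices((h, w))
    radius = np.rint(np.hypot(rows - cy, cols - cx)).astype(int)
    n_bins = min(h, w) // 2
    profile = np.array([amp[radius == r].mean() for r in range(n_bins)])
    return profile


def spectrum_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between the log radial amplitude profiles of two images.

    Accepts either 2-D planes (profiles are computed) or precomputed 1-D
    profiles.  The DC bin is excluded before taking logs.
    """
    pa = radial_amplitude_spectrum(a) if np.ndim(a) == 2 else np.asarray(a, dtype=np.float64)
    pb = radial_amplitude_spectrum(b) if np.ndim(b) == 2 else np.asarray(b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise ValueError("profiles must have equal length")
    pa, pb = pa[1:], pb[1:]
    if np.any(pa <= 0) or np.any(pb <= 0):
        raise ValueError("amplitude profile has non-positive bins; cannot take logs")
    la, lb = np.log(pa), np.log(pb)
    return float(np.corrcoef(la, lb)[0, 1])


def euclidean_image_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-shaped luminance planes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))
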