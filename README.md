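# pareidoscope

A reverse-correlation ("classification image") toolkit for **noise-pattern
oddity tasks**: simulate forced-choice experiments in which an observer
picks one of three Gaussian-noise stimuli, then recover *what the observer
was looking for* from the choices alone.

The package targets the study design used in comparative work on **face and
letter pareidolia**: observers are first trained to find a target (a face
or a letter-like glyph) superimposed on noise at an easy or difficult
opacity, and are then probed with *test trials* in which all three stimuli
are pure noise. If the observer has formed a search image for the trained
category, the noise patterns it selects should — on average — look more
like that category than the ones it rejects.

## What it computes

For each test trial the luminance plane of the chosen pattern and the
pixelwise mean of the two non-chosen patterns are recorded. Averaging over
trials gives the selected mean `S(i,j)` and the unselected mean `U(i,j)`;
the **difference image** `D = S − U` is the reverse-correlation estimate of
the observer's internal template. For display, low-contrast planes are
stretched with

```
E(i,j) = (L(i,j) − M) · 20 + 128
```

where `M` is the mean luminance of the entire plane.

Inference is pixel-wise over a 200 × 220 centred area of interest (AOI): at
each coordinate a linear mixed model tests the selected-vs-unselected
condition effect with random intercepts for participants and trials nested
within participants. Because every trial contributes exactly one selected
and one unselected observation per pixel, both random intercepts cancel in
the within-trial difference and the model reduces *exactly* to a paired
one-sample problem — estimate `mean(d)`, standard error `sd(d)/√n`,
Satterthwaite df `n − 1` — which makes the 44,000-pixel map a single
vectorised computation (verified against statsmodels `MixedLM` and R's
`lmerTest` in the test suite). Raw p-values are corrected by the
Benjamini–Hochberg step-up at `q = 0.05`, and the whole analysis can be
re-run with computer-random selections as a null calibration.

Also included: the simulated 3 × 2-grid oddity task (48-trial sessions:
24 difficult + 12 easy baseline, 12 test; correction trials after baseline
errors; non-contingent 50 % reward on test trials), a template-matching
observer model (softmax over template correlation, position bias, lapses,
evidence-dependent response times), log-RT mixed models with trial-type
contrasts, position-bias chi-square statistics, RT median splits, category
brightness contrasts, radially averaged Fourier-spectrum correlation, and
Euclidean image distances.

## Worked example

A strong template observer (softmax inverse temperature β = 50, no lapses)
runs 25 test sessions at 1/10 scale — 300 test trials, the reference
per-category count (`examples/04_pixel_heatmap.py`):

```
observer map:     3 / 440 FDR-significant pixels (q=0.05)
random null:      0 / 440 FDR-significant pixels
```

The observer's choices produce FDR-significant structure; re-running the
identical analysis with computer-random selections of the same stimuli
yields none. The raw difference image from the same run correlates with
the observer's actual internal template at r = 0.63
(`examples/03_classification_images.py`), and a response-time median split
shows the faster half of trials carries the clearer search image
(`examples/05_secondary_analyses.py`):

```
template recovery r: faster-RT half 0.72, slower-RT half 0.66
```

Each script in `examples/` builds a small input, runs one capability and
prints what the numbers mean. A thin CLI wraps the same pipeline
(`pareidoscope simulate / analyze / null / report / fixtures / run`); the
library API is the primary interface.

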