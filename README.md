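# wormscan

High-throughput phenotyping of *Caenorhabditis elegans* from flatbed-scanner
images.

A consumer flatbed scanner imaging standard NGM plates at 2400 dpi resolves
every worm above ~0.5 mm. The scanner's own light is an aversive stimulus:
a live worm crawls between two sequential scans taken 90 s apart, a dead one
does not. From one scan pair this package quantifies the four workhorse
phenotypes of whole-organism *C. elegans* studies — mortality, movement,
size and (via repeated counting) fecundity and lifespan — without any
per-worm manual scoring.

## Method

For a scan pair (I₁, I₂) of the same plate:

1. **Segmentation** — a random-forest pixel classifier over a multi-scale
   filter bank (Gaussian blur, mean, Lipschitz bottom-hat, difference of
   Gaussians, variance, structure-tensor eigenvalue; σ = 2…16 px) labels
   worm pixels; 8-connected *particle analysis* keeps components with a
   plausible single-worm area, giving regions W₁…Wₙ.
2. **Registration** — the inter-scan plate shift is estimated by phase
   cross-correlation (translation-only, subpixel) and I₂ is resampled onto
   I₁'s frame.
3. **Movement** — the absolute difference |I₁ − I₂| is binarized by
   hysteresis (keep pixels ≥ high plus ≥ low pixels 8-connected to them).
   Each worm's movement fraction is

   mᵢ = |{p ∈ Wᵢ : binary(p)}| / |Wᵢ| ∈ [0, 1],

   the share of its original footprint that changed. A worm is scored
   **dead iff mᵢ < 0.10**; the 10 % floor absorbs image noise.
4. **Morphometry** — each worm's length is the geodesic length of its
   morphological skeleton (bias-corrected; px → mm via 25.4/dpi).
5. **Counting** — the abbreviated algorithm counts live worms directly from
   the binarized difference image (no per-worm segmentation), for daily
   lifespan and fecundity scans.
6. **Endpoints** — mortality tables feed a binomial probit regression
   Φ⁻¹(P(dead)) = β₀ + β₁·dose with LC50 = −β₀/β₁; counting feeds fecundity
   curves and mean-lifespan summaries; repeated scans feed habituation
   series (responding fraction per 90 s interval).

A synthetic-plate generator renders worm-like ribbons with controlled
per-worm displacement and exact ground truth (masks, centerline lengths,
alive flags), so the whole pipeline is testable without a scanner.

## Worked example

Render a synthetic plate pair and score mortality:

```sh
wormscan simulate --n-worms 8 --width-px 500 --height-px 500 \
    --displacement 0.5 --seed 5 --out-dir demo
wormscan score --first demo/scan_000.tif --second demo/scan_001.tif --out-dir demo
```

This produces `demo/movement.csv`:

```
# wormscan 0.1.0 config_sha256=89665e1f28dfda6d
worm_id,area_px,movement_fraction,alive
0,718,0.495822,True
1,614,0.509772,True
...
```

and `demo/plate_summary.json` with the plate-level counts
(`"n_alive": 8, "n_dead": 0, "mortality": 0.0` for this all-moving plate).
`movement_fraction` is the share of each worm's first-scan pixels inside
the binarized difference image — 0.5 means half its body area moved out of
place between scans — and `alive` applies the strict `< 0.10 → dead` rule.

Fit an LC50 from a dose–mortality table:

```sh
wormscan lc50 --table doses.csv     # concentration,n_total,n_dead[,replicate]
```

which prints the probit fit report (intercept, slope, standard errors,
log-likelihood, `lc50`).

The same workflows are available in Python (`wormscan.render_scan_pair`,
`wormscan.score_pair`, `wormscan.fit_probit`, …) and via the other
subcommands: `train`, `segment`, `align`, `measure`, `count`, `fecundity`,
`lifespan`, `habituation`.

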