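# synmorph

Quantitative electron-microscopy morphometry of presynaptic terminals and
their glial envelopes.

At cerebellar parallel-fibre synapses, glutamate can be released not only at
the active zone (AZ, the membrane apposed to the postsynaptic density) but
also "ectopically" onto the processes of Bergmann glia that ensheathe the
terminal. Testing anatomical predictions about these release sites requires
measuring, from traced EM micrographs, where synaptic vesicles sit relative
to each membrane compartment and how closely glia appose the terminal.
`synmorph` implements that measurement pipeline for coordinate exports of
manual traces (terminal perimeter, postsynaptic density, glial membranes,
vesicle centre points):

- **Membrane classification** — the perimeter is resampled at a fixed
  arc-length step and each sample is labelled *active_zone* / *glial_facing*
  / *other* by its distance to the PSD and glial traces (thresholds
  τ_AZ = τ_glial = 30 nm by default), reproducing the manual demarcation of
  apposed membrane. Explicit per-terminal compartment extents, when present
  in the input, bypass the classifier.
- **Vesicle distances** — for every vesicle centre *v*, the shortest
  Euclidean distance d(v, C) = min_{x∈C} ‖v − x‖ to the whole membrane and
  to each compartment C.
- **Pool identification** — pooled distances per condition are summarised by
  a percentage histogram and a Gaussian KDE with Silverman's bandwidth
  h = 0.9·min(s, IQR/1.34)·n^(−1/5); vesicle pools are the local density
  maxima, each assigned the probability mass ∫ f̂(x)dx over one histogram
  bin width centred on the peak (trapezoidal rule).
- **Near-membrane contingency analysis** — the fraction of vesicles with
  centres strictly within 50 nm (one vesicle diameter) of each compartment,
  compared between stimulation conditions by two-sided Fisher's exact tests
  (log-factorial hypergeometric, small-p convention).
- **Glial morphometry** — fractional coverage (glial-facing length /
  perimeter length) and the terminal-to-glia gap at the arc-length midpoint
  of each apposition; groups compared by tie-corrected Kruskal–Wallis with
  Dunn's Bonferroni-adjusted post hoc z tests.
- **Synthetic terminals** — a generator emitting annotation bundles with
  known ground truth (Fourier-perturbed perimeters, parallel PSD/glial
  traces, vesicles placed by a Gaussian-mixture distance model), so every
  stage is testable without raw micrographs.

## Worked example

```python
import synmorph as sm

cfg = sm.SyntheticConfig(n_terminals=20, seed=42, vesicle_count_mean=300)
annotations, _ = sm.generate_condition(cfg)
report = sm.analyze_condition(annotations)

dist = report.distributions["active_zone"]
for pk in dist.peaks:
    print(f"{pk.location:6.1f} nm   {pk.density:.5f} /nm   {pk.probability:5.2f} %")
near = report.near_counts["active_zone"]
print(f"vesicles < 50 nm of AZ: {near.n_within}/{near.n_total} = {near.fraction:.3f}")
```

prints

```
  34.0 nm   0.00910 /nm    8.97 %
  97.5 nm   0.00777 /nm    7.73 %
vesicles < 50 nm of AZ: 1955/6020 = 0.325
```

The two peaks recover the generator's configured vesicle pools at 32 nm
(readily-releasable, narrow) and 97 nm (reserve, broad): pooled over 6020
vesicles, the KDE modes land within ~2 nm and ~1 nm of the configured
means. The `%` column is the probability mass under the fitted density
across one 10 nm bin centred on each peak; the final line is the
near-membrane fraction that feeds the contingency analysis.

The `examples/` directory holds one short script per capability
(classification, pools, contingency tests, cross-condition comparison);
each prints the numbers it computes and what they mean.

## Reading real annotations

`read_annotation_bundle` accepts either a JSON bundle (a list of terminals
with `perimeter`, `psd`, `glial`, `vesicles` in pixel coordinates and a
`scale_nm_per_px` calibration) or a directory of ImageJ "Save XY
Coordinates" text files named `<terminal_id>__<role>[_<i>].txt`; the
nm-per-pixel scale must be supplied for the latter, since tracing exports
do not embed it. All coordinates are converted to nm once at load.

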