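# podoquant

Quantitative image analysis of podocyte protein localization, for
renal-biology groups measuring where actin-associated proteins sit within
the glomerular capillary wall and how foot-process architecture changes
after injury. The package implements three measurements that are usually
done by hand in ImageJ/NIS-Elements, together with a ground-truthed
synthetic scene simulator so the whole pipeline is testable without a single
real micrograph:

1. **Apicobasal positional ratio.** On super-resolution images of capillary
   loops, three markers form roughly parallel bands: nidogen at the
   glomerular basement membrane (basal), podocalyxin at the urinary-space
   surface (apical), and the target protein somewhere in between. Along a
   line drawn perpendicular to the wall, with intensity peaks at positions
   `p_basal`, `p_target`, `p_apical`, the statistic is

       ratio = b / a,   b = |p_target − p_basal|,   a = |p_apical − p_basal|

   so 0 means "on the basement membrane" and 1 "at the apical surface".
   Peaks are global profile maxima with three-point parabolic sub-sample
   refinement; QC rejects misaligned windows, degenerate lines and
   misordered peaks. Groups are compared with a Mann–Whitney U test (exact
   by enumeration for small samples).

2. **Membrane colocalization.** Pearson correlation R of two channels'
   luminances over matched sample points — along a plotted line or over a
   boundary-band region — with a two-sided t test between groups of R values.

3. **Foot-process morphometry.** Widths as arc distances between successive
   slit-diaphragm/junction positions along the membrane, seeded random site
   sampling, and two-group comparison with mean ± SEM summaries.

The simulator renders capillary-loop scenes (Gaussian-profile bands at
offsets 0, f·a and a from the basal band, f and a known exactly) and
cultured-cell scenes (a known fraction q of target signal on cell–cell
junctions, the rest on interior stress fibers), with optional Gaussian or
Poisson-Gaussian noise and bit-identical output under a fixed seed.

## Worked example

```bash
podoquant experiment --out results/demo --seed 11
```

simulates one control scene (true f = 0.55) and one knockout-like scene
(true f = 0.35) at SNR 10, measures 30 perpendicular lines per scene, and
prints:

```
  group  n_accepted  mean_ratio  sem_ratio
control          27    0.551788   0.003223
     ko          29    0.352620   0.002770
U test (normal_approx): control (n=27) mean±SEM = 0.5518±0.0032; ko (n=29)
mean±SEM = 0.3526±0.0028; U = 783, P = 1.442e-10 (significant, α=0.05)
```

The group means recover the simulated depth fractions to ~0.003 (a few QC
rejections at this noise level are expected and logged in `per_line.csv`),
and the U test separates the groups decisively. `results/demo/` holds the
per-line table, group summary, test report and a manifest with the config,
seed and software version; rerunning with the same seed reproduces every
CSV byte for byte.

The same stages are available as a library (see `podoquant.scenes`,
`podoquant.profiles`, `podoquant.ratio`, `podoquant.coloc`,
`podoquant.morphometry`, `podoquant.stats`, `podoquant.pipeline`) and as
narrative drivers under `analysis/` (01 simulate … 05 morphometry), which
write their tables under `results/`.

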