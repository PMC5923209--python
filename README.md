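# cardiohelix

Dual-modality mapping of cardiomyocyte orientation in the left ventricle:
diffusion-tensor MRI (DTI) and structure-tensor analysis of tissue-cleared
light-sheet volumes, with helix-angle transmurality quantification,
regional/infarct analysis, FACT tractography, cross-modality agreement
statistics, and ground-truthed synthetic LV phantoms for end-to-end
validation.

## The problem

The ventricular wall is built from helically wound myocyte layers: the
helix angle (HA) — the angle between a fiber's projection onto the local
circumferential–longitudinal plane and the circumferential direction —
runs from right-handed (+HA) at the endocardium to left-handed (−HA) at
the epicardium. DTI measures this architecture non-invasively through the
primary eigenvector e1 of the per-voxel self-diffusion tensor D, fitted
from `S(b,g) = S0 · exp(−b gᵀDg)` by log-linear least squares; optical
imaging of cleared hearts measures the same vector from image texture, as
the eigenvector of the smallest eigenvalue of the windowed structure
tensor `⟨∇I ∇Iᵀ⟩`. The summary statistic is the **helix-angle
transmurality** (HAT): the mean fitted slope of HA against transmural
depth (TD, 0 % endo → 100 % epi) over 20 equidistant radial projections
per short-axis slice, in °/%TD. Lower |HAT| means less helical winding —
the signature of ischemic remodeling. Mean diffusivity (trace(D)/3) zones
the myocardium into infarct (> 1.12 µm²/ms, excluded from HAT), peri-
infarct (0.9–1.12) and remote (≤ 0.9) tissue.

The package is aimed at researchers validating cardiac fiber-mapping
pipelines: since raw ex vivo datasets of this kind are rarely shared, it
generates annular LV phantoms with a known linear HA ramp (true HAT =
(HA_epi − HA_endo)/100 exactly), synthesizes both the DWI stack (Rician
noise) and the striped optical volume from the same fiber field, and
checks that each analysis path recovers the truth.

## Worked example

```python
from cardiohelix.io_cli import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo", seed=7,
    phantom={"shape": [48, 48, 16], "spacing": [125.0, 125.0, 125.0],
             "endo_radius_um": 750.0, "epi_radius_um": 2250.0,
             "noise": "rician", "sigma": 20.0},   # sigma/S0 = 2 %
    optical_refine=(4, 4, 4))                     # optical grid at 31.25 um
r = run_pipeline(cfg)
print(r["true_global_hat"], r["dti_global_hat"], r["optical_global_hat"])
```

prints

```
true_global_hat    -1.2
dti_global_hat     -1.214
optical_global_hat -1.245
```

the prescribed +60°→−60° ramp has a true global HAT of −1.2 °/%TD; the
DTI path recovers −1.214 and the optical (structure-tensor) path −1.245
under 2 % Rician noise. The output directory contains the DWI stack
(NIfTI + FSL `bval`/`bvec`), the optical TIFF, HA/TD/MD maps, per-profile
and per-segment HAT tables (TSV), the agreement report, and a manifest
with checksums — reruns with the same config and seed are bit-identical.
Segment-level agreement statistics are only informative when there is real
regional variance (e.g. lesioned phantoms); on a homogeneous phantom they
correlate noise with noise.

A cohort-level study (7 control-like vs 8 ischemic-like phantoms, group
|HAT| drawn at 1.31 ± 0.20 and 0.79 ± 0.13 °/%TD) is available through
`cardiohelix.io_cli.phantom_study`.

There is also a CLI: `cardiohelix phantom|dti|optical|run|track`
(see `cardiohelix --help`).

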