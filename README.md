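# condensekit

Quantitative image analysis for biomolecular condensates and nucleoprotein
filaments. The package is aimed at researchers who image liquid–liquid
phase separation and DNA-repair filament assemblies and need the standard
measurements of that field as tested, scriptable building blocks rather
than one-off analysis scripts:

- **Brightfield phase-separation scoring** — the droplet-edge fractional
  area: Farid–Simoncelli 5-tap derivative filtering, selection of pixels
  with gradient magnitude > k·σ (k = 10), edge-pixel count divided by field
  area, averaged over fields and normalized by a non-phase-separating
  reference to cancel fixed optical speckle. Supports assembling full state
  diagrams over condition grids (crowder %, protein, salt, mixing ratio).
- **Partition coefficients** — condensate segmentation (automatic
  threshold, or a trained pixel classifier on intensity / gradient / LoG
  features) and per-condensate PC = ⟨I⟩_condensate / ⟨I⟩_dilute-phase, plus
  multi-channel line profiles.
- **Single-molecule localization** (desk scale) — blink detection,
  pixel-integrated Gaussian PSF fitting with shot-noise weights,
  σ/√N precision estimates, and mass-preserving super-resolution rendering.
- **Filament analysis** — density-mask tracing of filaments from
  localization tables: contour lengths, open/closed classification,
  cluster/bundle detection, inter-puncta spacing along a filament (the
  objective version of counting pixels between consecutive bright spots),
  and two-channel colocalization fractions.
- **AFM stack processing** — least-squares plane leveling and per-pixel
  median projection.
- **Synthetic scenes** — generators for all of the above with exact,
  serializable ground truth, used by the test suite and usable for
  benchmarking.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from condensekit import synthetic as syn, brightfield as bf, partition as pt, filaments as fil

# --- phase separation from brightfield fields ---------------------------
ref_spec = syn.BrightfieldSceneSpec(n_fields=5, n_droplets_in_focus=0, seed=0)
reference, _ = syn.make_brightfield_set(ref_spec)
sample_spec = syn.BrightfieldSceneSpec(n_fields=5, n_droplets_in_focus=30, seed=1)
sample, _ = syn.make_brightfield_set(sample_spec)
norm = bf.normalize_to_reference(bf.summarize_sample(sample),
                                 bf.summarize_sample(reference))
print(f"normalized phase separation: {norm.value:.2f} +/- {norm.error:.2f}")

# --- partition coefficient of a fluorescent client ----------------------
spec = syn.CondensateSceneSpec(enrichment=3.0, noise_model="poisson", seed=2)
image, truth = syn.make_condensate_image(spec)
mask = pt.segment_condensates(image, mode="threshold")
summary = pt.partition_coefficients(image, mask)
print(f"mean PC = {summary.mean:.2f} +/- {summary.sd:.2f} "
      f"over {summary.n_condensates} condensates")

# --- end-to-end tethered filament with junction puncta ------------------
tether = syn.FilamentSceneSpec(geometry="line", n_units_tethered=4,
                               puncta_at_junctions=True,
                               field_extent_nm=30_000, seed=13)
table, puncta, _ = syn.make_filament_localizations(tether)
(trace,) = fil.trace_filaments(fil.density_mask(table))
report = fil.inter_puncta_spacing(trace, puncta)
print(f"tether length = {trace.contour_length_um:.2f} um (true 8.40 um)")
print("inter-puncta spacings (nm):", [round(s) for s in report.spacings_nm])
```

prints

```
normalized phase separation: 4.09 +/- 0.08
mean PC = 2.92 +/- 0.02 over 10 condensates
tether length = 8.49 um (true 8.40 um)
inter-puncta spacings (nm): [2117, 2097]
```

The droplet sample scores ~4× its droplet-free reference (1.0 would mean
no phase separation); the client is ~3-fold enriched in condensates, as
generated; and the four tethered 2.1 µm filament units are traced as one
8.4 µm structure whose junction puncta sit one unit length apart.

A command-line interface mirrors the library (`condensekit --help`):
`simulate`, `quantify-brightfield`, `partition`, `profile`, `localize`,
`render`, `trace`, `spacing`, `afm`.

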