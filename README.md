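# ecgforge

Mechanistic simulation and synthesis of labeled 12-lead ECG records.

`ecgforge` generates synthetic electrocardiograms the way a cardiac
electrophysiology lab would at desk scale: the electrical activation of
parametric idealized heart geometries is computed mechanistically, the
body-surface potentials follow from a biophysical forward model, and
complete 10 s, 500 Hz records are assembled with physiological beat-to-beat
variability, realistic noise and exact ground-truth labels.  It is intended
for researchers who need labeled ECG cohorts — for developing or
stress-testing machine-learning ECG classifiers and delineation algorithms —
where every waveform carries a known pathology and exact fiducials, something
clinical databases cannot offer.

## The model

**Activation.** Ventricular excitation starts at five fascicular
breakthrough sites (a His–Purkinje surrogate) placed in universal
ventricular coordinates (transmural ρ, rotational φ, apico-basal z) on a
fast-conducting endocardial layer (2.0 m/s).  Local activation times solve
the anisotropic Eikonal equation with conduction velocity 0.6 m/s along the
fiber direction and a 4:2:1 off-axis ratio; fibers rotate linearly from
+60° (endo) to −60° (epi).  Atrial excitation starts at the sinoatrial node
and propagates through regionally heterogeneous tissue (bulk, crista
terminalis, pectinate muscles, inferior isthmus, interatrial connections),
each with its own conduction velocity range and fixed anisotropy ratio.

**Voltages and ECG.** Transmembrane voltage is built reaction-Eikonal
style, V_m(x,t) = AP(t − LAT(x); APD(x)), from Mitchell–Schaeffer action
potential templates (resting −86.2 mV, peak +40 mV; APD calibrated through
τ_close).  A weighted combination of the universal coordinates, mapped onto
[APD_min, APD_max], creates the repolarization gradients that shape the
T wave.  Electrode potentials are the infinite-volume-conductor dipole sum
φ(y,t) = (4πσ_m)⁻¹ Σ_e σ_i ∇V_m·(y−x_e)/|y−x_e|³ Vol_e, combined into the
12 standard leads (I, II, III, aVR, aVL, aVF, V1–V6).

**Pathologies.** Seven disease classes are mechanistic transformations of
the healthy configuration: left/right bundle branch block (fascicular sites
of one ventricle removed), myocardial infarction in six sub-classes (LAD /
RCA / LCX territories × 30%-subendocardial / transmural, with an inert core
and a slow border zone carrying its own cell parameterization), fibrotic
atrial cardiomyopathy (patches with 50% element removal and 2.5× anisotropy),
interatrial conduction block (Bachmann's bundle inert), left atrial
enlargement (LA volume scaling) and 1st-degree AV block (PQ > 200 ms at the
synthesis stage).

**Record synthesis.** Single-beat P waves and QRST complexes are coupled
through conditional Gaussian draws on clinical lead-II statistics
(R amplitude | P amplitude; PQ | P duration; QT | QRS, RR), joined with
endpoint-exact sigmoid connectors, repeated over a 1/f-correlated RR series,
per-beat QT-warped, overlaid with composite noise (baseline wander,
electrode transients, motion artifact) at 15–20 dB SNR, and band-passed
with a zero-phase 3rd-order 0.5–150 Hz Butterworth filter.  Each run yields
`*_raw.csv`, `*_noise.csv` and `*_filtered.csv` (12 rows × 5000 samples,
mV) plus two key=value parameter files, organized into anatomy-disjoint
training / validation / test splits.

## Worked example

```python
import numpy as np
from ecgforge import PathologyLabel, generate_records, write_record

for i, (sample, anatomy_id, rec) in enumerate(
        generate_records(PathologyLabel("sinus"), n=3, seed=11)):
    noise = rec.noisy - rec.raw
    snr = 10 * np.log10(np.mean(rec.raw**2) / np.mean(noise**2))
    rr = np.diff([f["QRS_on"] for f in rec.fiducials]).mean()
    print(f"record {i}: anatomy {anatomy_id}, {len(rec.fiducials)} beats, "
          f"mean RR {rr:.0f} ms, SNR {snr:.2f} dB")
    write_record(rec, "example_dataset", f"run_S{i}")
```

prints

```
record 0: anatomy a0, 16 beats, mean RR 650 ms, SNR 17.48 dB
record 1: anatomy a1, 16 beats, mean RR 666 ms, SNR 15.02 dB
record 2: anatomy a2, 15 beats, mean RR 711 ms, SNR 19.41 dB
```

— three healthy 10 s records on three different anatomies, each with its
per-beat ground-truth fiducials (`rec.fiducials`), the drawn
signal-to-noise ratio realized exactly in the noisy variant, and the
record triple written in the dataset layout.  The `examples/` directory
holds one narrative script per capability (anatomy construction, beat
simulation, record generation, pathology effects, delineation and
feature summaries), and the `ecgforge` command-line tool wraps generation
(`generate`, `manifest`, `features`, `validate`, `demo`).

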