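# voxdcs

Voxel volume-conductor dosimetry for cerebellar and transcutaneous spinal
direct-current stimulation (ctDCS / tsDCS), aimed at researchers who model
how weak DC currents distribute through child-scale anatomies before
planning stimulation protocols.

Weak DC stimulation is quasi-static: tissue is a passive resistive medium,
the potential obeys the current-conservation (Laplace) equation

    ∇·(σ ∇φ) = 0,     E = −∇φ,     J = σ E,

with per-tissue DC conductivities σ (CSF 2 S/m, skin 0.1, muscle 0.202,
bone 0.020, cerebellum 0.0475, cord/nerve 0.0171 S/m, ...).  `voxdcs`
discretises this on labeled voxel grids with a cell-centred finite-volume
scheme (harmonic-mean face conductances, insulated air boundaries), places
pad+sponge electrode montages on the body surface, solves with
conjugate gradients, rescales to the target current (2 mA cerebellar,
3 mA spinal), and computes the standard exposure metrics:

* per-tissue |E| statistics (min, quartiles, 99th-percentile "peak"),
  after the regulatory 2 mm same-tissue vector averaging;
* V50 / V70 focality (% of the target tissue at ≥ 50% / 70% of its peak)
  and spread into neighbouring structures;
* slice-wise coefficient of variation and longitudinal/transverse ratio
  R = |E_z| / √(E_x²+E_y²) along the spinal cord, per segment;
* heart exposure and the safety margin against the 5 A/m² cardiac
  fibrillation threshold;
* linearity-based dose-equivalence (current matching a reference peak).

Because the anatomies such studies use are commercially licensed, the
package ships parametric **synthetic phantoms** whose control parameters
are published child anthropometrics: a layered head (scalp/skull/CSF/brain)
with cerebellum, brainstem, occipital cortex, deep nuclei and a tunable
cerebellar CSF volume and occipital skull thickness; and a trunk with
vertebral column, CSF sheath, segmented spinal cord, nerve roots, cauda
equina and heart.  Presets `roberta`, `thelonious`, `eartha`, `dizzy`
carry the published per-model parameters.  See `docs/methods.md` for the
model, the metric definitions and what phantom results do and do not show.

## Worked example

A 3 mA spinal run on the 6-year-old trunk preset at 2 mm:

```python
from voxdcs.pipeline import RunConfig, execute

cfg = RunConfig(mode="tsdcs", preset="thelonious", spacing=2.0, seed=1)
rep = execute(cfg).report

for seg in ("cervical", "thoracic", "lumbar", "sacral"):
    s = rep.cord_segments_E[seg]
    print(f"{seg:9s} cord |E| median {s.median:5.2f} V/m   peak {s.p99:5.2f} V/m")
print(f"thoracic mean R     : {rep.r_profile.segment_means['thoracic']:.2f}")
print(f"heart |J| peak      : {rep.heart_J.p99:.3f} A/m^2")
print(f"fibrillation margin : {rep.safety_margin:.0f}x")
```

prints

```
cervical  cord |E| median  0.06 V/m   peak  0.49 V/m
thoracic  cord |E| median  1.86 V/m   peak  3.86 V/m
lumbar    cord |E| median  0.24 V/m   peak  1.78 V/m
sacral    cord |E| median  0.01 V/m   peak  0.05 V/m
thoracic mean R     : 1.17
heart |J| peak      : 0.103 A/m^2
fibrillation margin : 49x
```

The field concentrates under the T10 electrode: the cervical and sacral
cord medians are a few percent of the thoracic median, the thoracic field
is predominantly longitudinal (R > 1, the component neurons respond to
most readily along the cord axis), and the current reaching the heart is
~50× below the average fibrillation threshold.

The same pipeline is available from the shell:

```sh
voxdcs run --mode tsdcs --preset thelonious --spacing 2.0 --seed 1 --out out/
voxdcs sweep --mode ctdcs --preset roberta --spacing 2.0 \
    --parameter phantom.cerebellar_csf_volume --values 30.7,48.6,88.6 \
    --metrics tissues_E.Cerebellum.median --out sweep.csv
```

`run` writes the label, conductivity, potential and |E| volumes as NIfTI
plus the exposure report as JSON/CSV; `phantom`, `solve`, `analyze`,
`validate` and `presets` expose the individual stages.

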