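# qmrikit

Quantitative-MRI relaxometry validation toolkit: forward signal models and
per-voxel T1/T2/PD map fitting for variable-flip-angle (VFA/DESPOT1),
multi-echo spin-echo (ME-SE) and multispectral saturation-recovery
(QRAPMASTER/MAGiC-style) acquisitions, plus synthetic weighted-image
generation, QA-phantom metrology and the agreement/repeatability statistics
used to qualify such maps — e.g. for radiotherapy planning, where contouring
on synthetic contrasts demands verified geometric and quantitative accuracy.

Everything runs end to end on digital phantoms with known ground truth: an
eight-insert relaxometry phantom spanning T1 29–2386 ms / T2 25–1311 ms, and
a 190 mm QA disk phantom with landmark grid, 45° ramp, diagonal rod,
line-pair groups and uniform regions.

## The models

With K a global intensity scale, ρ proton density, B1 the transmit-field
scale and E1 = e^(−TR/T1):

* Spoiled GRE (VFA T1 mapping):
  S = K·ρ·sin(B1θ)·(1−E1) / (1 − cos(B1θ)·E1)
* Spin echo (ME-SE T2 mapping):
  S = K·ρ·(1 − e^(−TR/T1))·e^(−TE/T2)
* Saturation recovery (multispectral T1/T2/PD mapping):
  S = K·ρ·e^(−TE/T2)·[1 − (1−cos B1θ)e^(−TI/T1) − cos B1θ·e^(−TR/T1)] /
  [1 − cos B1α − cos B1θ·e^(−TR/T1)]

T1 is fitted by linearized DESPOT1 regression, T2 by weighted log-linear
regression, and the multispectral model by a staged solve (echo-decay T2,
then variable-projection T1, then PD), each with optional nonlinear
least-squares refinement. See `docs/methods.md` for the details and the
numerical choices.

## Worked example

```python
import qmrikit as qk

# Ground-truth maps of the eight-insert phantom, then a simulated
# multi-echo spin-echo acquisition and its T2 map.
t1, t2, pd, labels = qk.make_insert_phantom()
stack = qk.simulate_acquisition(t1, t2, pd, qk.MeseProtocol())
t2_map, amp_map = qk.fit_mese_t2(stack, qk.MeseProtocol())

for k in (1, 4, 8):
    s = qk.voi_stats(t2_map, labels == k)
    print(f"insert {k}: T2 = {s.mean:.1f} ms  (CV {s.cv_percent:.2f}%, n={s.n_voxels})")
```

prints

```
insert 1: T2 = 24.7 ms  (CV 0.00%, n=490)
insert 4: T2 = 181.7 ms  (CV 0.00%, n=490)
insert 8: T2 = 1311.3 ms  (CV 0.00%, n=490)
```

i.e. on noiseless data the fitted VOI means reproduce the insert reference
values exactly. Adding Rician noise (`qk.NoiseModel(kind="rician",
target_snr=50, seed=0)`) shows the realistic behaviour: short and
intermediate T2 stay accurate while the 1311 ms insert — sampled only out to
TE = 64.5 ms — develops a negative median bias.

The same pipeline is available from the shell:

```
qmrikit simulate-acq --protocol mese --out acq/
qmrikit fit-mese --stack acq/mese_stack.manifest.json --out maps/
qmrikit synth --maps maps/ --preset t2w --out t2w.nii.gz
qmrikit simulate-phantom --kind qa --out qa/
qmrikit qa --stack qa/qa_phantom.manifest.json --out qa_report.json
```

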