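# utebone

Cluster-based bone segmentation of dual-echo ultra-short echo time (UTE)
MR volumes, for MR-based PET attenuation correction.

## The problem

PET/MR scanners must correct for photon attenuation without a CT scan,
which means segmenting MR images into tissue classes (air, soft tissue,
bone) of known attenuation. Bone is the hard part: its water pool decays
in well under a millisecond, so it is invisible at conventional echo
times. Dual-echo UTE acquisitions (first echo ~30 μs, second ~1.7 ms)
capture bone in the first echo and watch it vanish by the second, so
each voxel yields a point (I_TE1, I_TE2) in dual-echo space where the
tissue classes form (overlapping) clusters.

Two classical classifiers cut this space with fixed curves:

* **R₂ map** — R₂ = ln(I_TE1 / I_TE2) / (TE2 − TE1), thresholded; a
  straight cut e₂ = e₁·exp(−t·ΔTE) through the origin.
* **Normalized difference** — N = (I_TE1 − I_TE2) / I_TE2², thresholded;
  a slightly curved cut, also through the origin.

This package implements a data-driven alternative: with co-registered
CT available for training, every (echo1, echo2) pair is a key into a
lookup table of **posterior tissue probabilities** P(class | echo pair),
estimated by counting, for each echo-pair bin, how often it came from
air / soft tissue / bone according to HU-thresholded CT labels. Each
patient's echoes are first prescaled so the soft-tissue histogram peak
sits on the canonical point (4,000, 4,000); per-patient maps are
averaged over the cohort; and a priori rules are imposed (voxels with
echo1 + echo2 > 4,000 are never air; voxels with echo2 > echo1,
echo1 > 8,000, echo2 > 5,000 or echo1 − echo2 > 4,000 are never bone).
Voxels are then classified by maximum posterior, with the bone mask
taken at P(bone) > 0.5, and scored against CT bone masks by the Jaccard
distance 100·(1 − |A∩B|/|A∪B|).

Since clinical tri-modality data cannot ship with a package, a phantom
module generates co-registered synthetic CT + dual-echo UTE "head"
volumes (nested-ellipsoid geometry, known ground truth, controllable
cluster overlap, per-case intensity jitter) on which the whole pipeline
runs end to end.

## Worked example

```python
from utebone import PhantomSpec, generate_cohort
from utebone.cli import train_from_cases, evaluate_cohort

cohort = generate_cohort(10, PhantomSpec(), jitter_sd=0.1, seed=1)
pmap, _ = train_from_cases([(case.ute, case.ct) for case in cohort])
report = evaluate_cohort(cohort, pmap)
for method in ("posterior", "ndiff", "r2"):
    s = report.methods[method]
    print(f"{method:9s} mean {s['mean']:5.1f}%  median {s['median']:5.1f}%  "
          f"sd {s['sd']:4.1f}%  range {s['min']:.1f}-{s['max']:.1f}%")
print("Welch p (posterior vs r2):   ", f"{report.tests['posterior_vs_r2']['p']:.4f}")
print("Welch p (posterior vs ndiff):", f"{report.tests['posterior_vs_ndiff']['p']:.4f}")
```

prints

```
posterior mean  13.8%  median  13.8%  sd  0.4%  range 12.9-14.4%
ndiff     mean  16.5%  median  14.3%  sd  5.9%  range 10.2-27.2%
r2        mean  23.5%  median  21.4%  sd  7.9%  range 14.3-39.0%
Welch p (posterior vs r2):    0.0038
Welch p (posterior vs ndiff): 0.1822
```

Lower Jaccard distance is better (0% = identical bone masks). The
trained posterior classifier beats both fixed-threshold baselines at
their published operating points (R₂ > 0.35 ms⁻¹, N > 5×10⁻⁴,
P(bone) > 0.5), and — because it prescales each case before the lookup —
it is far less sensitive to inter-case intensity scaling than either
baseline (sd 0.4% vs 5.9% / 7.9%). On clinical cohorts the absolute
distances are much larger (overlap from partial volume, motion and
misregistration); the phantoms reproduce the ranking, not the clinical
magnitudes.

The same pipeline is available from the shell:

```bash
utebone demo --out runs/demo --n 10 --seed 1        # simulate→train→classify→evaluate
utebone simulate --out runs/sim --n 3 --seed 0      # NIfTI phantom triplets
utebone train --manifest cases.yaml --out map.npz   # cohort posterior map
utebone classify --method posterior --map map.npz --in runs/sim/case00 --out runs/seg
utebone evaluate --pred runs/seg/bone_mask.nii.gz \
                 --ref runs/sim/case00/labels.nii.gz --out eval.json
```

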