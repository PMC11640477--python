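# ce4dct

Analysis tools for synchronized contrast-enhanced 4DCT (ce4DCT) simulation in
abdominal SBRT planning:

- **timing** — personalized injection-delay computation from 4DCT slice
  timing (`t_scan = (t1 + t2)/2 − t0`, `t_delay = t_phase − t_scan`,
  automated vs. manual synchronization by the sign of the delay) and
  weight-based contrast-protocol arithmetic (1.8–2.0 mL/kg, 140 mL cap,
  2.5 mL/s).
- **kinetics** — aortic ROI construction (≥5 mm diameter, ≥2 mm inside the
  vessel edge), time–density-curve extraction on the post-injection
  timeline, contrast-peak and washout-plateau detection, and population
  refinement of the target contrast-phase time.
- **structures** — binary masks on physical voxel grids with patient-axis
  (R/L, A/P, S/I) semantics, NIfTI/NRRD I/O, ITV construction as the union
  of respiratory phases, and exact-mm isotropic (distance-transform) and
  direction-dependent anisotropic expansions.
- **compare** — ITV-vs-ITV comparison (volume, centroid shift, Dice,
  Jaccard, mean distance agreement) and the six-direction margin derivation
  with post-margin re-evaluation.
- **report** — cohort margin-table summaries (mean ± sample SD per
  direction, overall or by tumor group), paired t-test, structured run
  reports. A twelve-patient reference margin table ships with the package.
- **phantom** — a digital 4DCT phantom (moving ellipsoidal lesion split
  into phases, enhancing aorta with gamma-variate-plus-plateau kinetics,
  helical slice timestamps, ground-truth ITV pairs) so the whole chain is
  testable without clinical data.

## Test

```sh
python -m pytest tests/
```

The suite includes brute-force oracle checks for every geometry operation
and an acceptance suite (`tests/test_acceptance.py`) exercising the package
end to end on seeded phantoms.

## CLI

```sh
ce4dct phantom --out phantom/                      # generate synthetic data
ce4dct timing --t0 0 --t1 30 --t2 50 --weight 70   # delay + contrast protocol
ce4dct kinetics --tdc curve.csv                    # peak/plateau of one curve
ce4dct kinetics-pop --dir curves/                  # population kinetics report
ce4dct itv --phases p0.nii.gz --phases p1.nii.gz --out itv.nii.gz
ce4dct ptv --itv itv.nii.gz --margin 5 --out ptv.nii.gz
ce4dct compare --itv1 a.nii.gz --itv2 b.nii.gz --derive-margins --apply-margins
ce4dct report --group liver                        # cohort margin summary
```

All commands print JSON (or CSV for batch modes).

## Conventions

- Canonical patient frame: grid axes ordered so increasing index runs
  R→L, A→P, I→S; voxel coordinates are voxel centers; masks read from
  differently-oriented axis-aligned NIfTI/NRRD files are canonicalized on
  load. Oblique affines are rejected.
- Margins are reported in the order R, L, A, P, S, I; each is the clipped
  per-direction difference of outermost occupied-voxel face coordinates.
- MDA is the symmetric mean surface distance over face-connectivity
  boundary voxels, both directions pooled.
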