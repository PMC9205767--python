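# lesionnet

Lesion network mapping for outcome-linked brain circuits: from binary
lesion masks and a multi-subject resting-state connectome to a group
"remission network" map, with permutation inference, reproducibility and
specificity tests, structural disconnection scores, and a voxel-wise
therapeutic-target (hub) map.

## Who this is for

Researchers analyzing cohorts of patients with focal brain lesions and a
behavioral outcome (the motivating case: smokers whose addiction remitted
after a stroke or other focal damage). Individual lesion locations are
heterogeneous, so voxel-lesion-symptom mapping (VLSM) often finds nothing;
lesion network mapping (LNM) instead asks whether the lesions share a
profile of functional connectivity.

## The method

For each lesion mask, the mean time series over lesion voxels is extracted
from every connectome subject and correlated with all brain voxels; the
Fisher-transformed maps `z = atanh(r)` are averaged across subjects into
one *lesion network map* per patient. At each voxel an OLS GLM relates z to
outcome (remission = 1, quit-without-remission = 0.5, non-quitter = 0; site
and optional covariates adjusted):

* the contrast effect map `c'β̂` estimates the network's amplitude;
* the t map, enhanced by threshold-free cluster enhancement
  (TFCE: `Σ_h e(h)^0.5 · h^2 · dh`) and thresholded by the permutation
  distribution of the maximum TFCE statistic (Freedman–Lane), gives
  family-wise-error-corrected significance.

Downstream: spatial-correlation tests with label-permutation nulls
(cross-cohort reproducibility, behavioral specificity), tract-damage and
disconnectome-score tests (one-tailed permutation GLMs), and a hub map that
correlates every voxel's own connectivity profile with the network to
nominate stimulation/lesion targets (thresholded at |r| > 0.75).

A first-class synthetic-data module generates connectomes with planted
spatial networks, lesion cohorts whose remission probability is logistic in
the similarity to a planted map, tract atlases, and behavioral scores — so
the whole pipeline is validated against known ground truth. See
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Run the full synthetic pipeline (24³ grid, 20-subject connectome,
120-lesion cohort, β = 2, 200 permutations):

```bash
lesionnet run --out demo-out
```

which finishes in a couple of minutes and prints the manifest statistics:

```
{
  "contrast_max_abs_t": 5.277844468226858,
  "cross_site_p_perm": 0.004975124378109453,
  "cross_site_r": 0.8029560747152155,
  "disconnectome_p": 0.07960199004975124,
  "disconnectome_t": 1.4563767383919537,
  "hub_peak_r": 0.7690026359251684,
  "n_hub_peaks": 1,
  "n_significant_voxels": 1223,
  "planted_recovery_r": 0.8628369269591103,
  "score_separation_U": 1522.0,
  "score_separation_p": 2.819231289428002e-05,
  "specificity_target_rank": 1,
  "vlsm_min_p_fwe": 0.05472636815920398
}
```

Reading the numbers: the recovered contrast effect map correlates with the
planted network at r = 0.86 and 1,223 voxels survive P_FWE < 0.05
(`contrast_*`); the two synthetic "sites" reproduce each other's map
(r = 0.80, permutation P = 0.005); the linked behavioral variable ranks
1st of 38 against the network (`specificity_target_rank`); remitters'
lesion maps score higher against the network than non-quitters'
(Mann–Whitney U = 1522, one-sided P ≈ 3e-5); the hub map finds one voxel
whose profile matches the network above |r| > 0.75. VLSM, the
location-only negative control, finds nothing (min P_FWE = 0.055) —
lesion *location* does not carry the signal, lesion *connectivity* does.
The disconnectome test is directionally positive but not significant here
(t = 1.46, one-tailed P = 0.08): this demo draws tracts independently of
the planted network, so the coupling is weak by construction; the
dedicated coupled-tract study in the test suite shows the planted
directional effect (see `docs/methods.md`).

Every stage is also available separately (`lesionnet simulate / lnm /
contrast / vlsm / similarity / structural / targets`), reading and writing
NIfTI volumes and TSV tables, or as library calls
(`lesionnet.lesion_network_map`, `lesionnet.permutation_fwe`, ...).

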