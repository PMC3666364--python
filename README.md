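# somseg

Unsupervised 3D brain-MRI tissue segmentation from volumetric statistical
descriptors.  Every brain voxel of a skull-stripped T1-weighted volume is
described by a 23-dimensional feature vector — 12 Haralick texture
statistics averaged over the 13 independent 3D co-occurrence directions,
3 first-order window features, 7 local-histogram features, and 1 global
intensity-frequency feature — computed from overlapping 3×3×3 cubes.  A
self-organizing map (SOM) quantizes the feature space into prototype
vectors, fuzzy c-means (FCM) clusters the prototypes into CSF/GM/WM, each
voxel inherits the fuzzy memberships of its best-matching unit, and a
membership-difference threshold τ optionally assigns partial-volume voxels
to multiple tissues at once.  A genetic algorithm selects discriminative
feature subsets by maximizing the mean Jaccard overlap against reference
segmentations.

## Layout

| module | contents |
|---|---|
| `somseg.io_volume` | NIfTI volume/label-map I/O, brain mask handling, linear-index mapping |
| `somseg.features` | quantization, 13-direction 3D GLCMs, Haralick statistics, window and histogram features |
| `somseg.som` | SOM training (batch/online), BMU lookup, quantization error |
| `somseg.fcm` | fuzzy c-means on prototypes, voxel assignment, PVE multi-labeling, tissue identification |
| `somseg.selection` | elitist GA over feature bit-masks, pipeline-based fitness |
| `somseg.evaluation` | per-tissue Jaccard scoring (crisp and PVE) |
| `somseg.synthetic` | three-tissue phantom generator and feature-space toys with ground truth |
| `somseg.pipeline` | end-to-end `segment()` with config, metadata, and feature caching |
| `somseg.cli` | `somseg` command-line interface |

## CLI

```bash
# generate a phantom with ground truth
somseg make-phantom --shape 64,64,64 --means 30,100,180 --noise 10 \
    --seed 0 --out vol.nii.gz --truth truth.nii.gz

# segment (CSF=1, GM=2, WM=3 in the output label map)
somseg segment vol.nii.gz --out seg.nii.gz --tau 0.02 --seed 0 \
    --metadata-out run.json

# score against a reference
somseg evaluate --pred seg.nii.gz --ref truth.nii.gz

# GA feature selection on training volumes with references
somseg select-features --train-volumes vol.nii.gz --refs truth.nii.gz \
    --pop 20 --gens 15 --seed 0 --mask-out selected.txt
```

`somseg segment` accepts `--mask` for an explicit brain mask (default:
voxels with positive intensity), `--som-shape ROWSxCOLS`, `--features`
(comma-separated subset of the 23 canonical names), and
`--memberships-prefix` to write per-tissue probability volumes.

## Notes

- Feature columns are min-max scaled to [0, 1] by default
  (`extract_features(..., scale=...)` also offers `"zscore"` and
  `"none"`); range scaling keeps strongly discriminative columns dominant
  in the Euclidean metric that the SOM and FCM share.
- All randomness (phantom noise, SOM init/subsampling, FCM init, GA) is
  driven by explicit seeds; fixed seeds give bit-identical results.
- The affine of the input volume is carried to all outputs but never used
  in computation.
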