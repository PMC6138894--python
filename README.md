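# cinefcn

Automated analysis of cine cardiac MR: a multi-scale fully convolutional
network (FCN) for short-axis and long-axis segmentation, the metrics used to
judge it (Dice, mean contour distance, Hausdorff distance), derivation of
clinical measures (chamber volumes, LV mass, stroke volume, ejection
fraction, cardiac output), and inter-observer agreement statistics
(absolute/relative differences, Bland-Altman).  A synthetic cine phantom
with exact ground truth and analytic volumes makes the whole pipeline
testable without any restricted imaging data.

The network is implemented in pure NumPy (convolutions, batch
normalisation, max pooling, transposed-convolution upsampling, softmax,
with manual backpropagation and an Adam optimiser), so the package has no
deep-learning framework dependency.

## Layout

| module | purpose |
| --- | --- |
| `cinefcn.image_io` | NIfTI cine/label I/O, 192x192 crop/pad + [0,1] normalisation, invertible geometry |
| `cinefcn.phantom` | synthetic cine phantom, analytic volumes, simulated observers |
| `cinefcn.nn` | NumPy layer framework (conv, BN, ReLU, pool, transposed conv, Adam) |
| `cinefcn.network` | the 16-conv-layer FCN and its 33-layer residual variant |
| `cinefcn.training` | cross-entropy loss, on-the-fly augmentation, Adam schedule, fine-tuning |
| `cinefcn.inference` | per-slice forward pass, argmax, geometry restoration |
| `cinefcn.seg_metrics` | Dice / mean contour distance / Hausdorff distance in mm |
| `cinefcn.clinical` | volumes, LV mass, ED/ES detection, SV / EF / CO |
| `cinefcn.agreement` | paired differences, Bland-Altman, observer-study tables |
| `cinefcn.cli` | `cinefcn` command-line entry point |

## CLI

```bash
# generate 4 phantom cases with exact ground truth
cinefcn phantom --out data --n 4 --seed 1

# train a network (use --reduced for a desk-scale architecture)
cinefcn train --data data --out model.npz --iterations 500 --reduced --size 64

# segment a cine stack, evaluate against truth, derive clinical measures
cinefcn segment --model model.npz --image data/case000_image.nii.gz --out seg.nii.gz
cinefcn evaluate --auto seg.nii.gz --manual data/case000_label.nii.gz --out metrics.csv
cinefcn measure --seg seg.nii.gz --out measures.csv

# fine-tune to a reduced (LV-only) label scheme
cinefcn finetune --model model.npz --data data --out tuned.npz --scheme lv_only

# observer agreement study on simulated raters
cinefcn agreement --n 10 --jitter 1.8 --seed 2 --out agree/
```

Defaults follow the reference protocol: 192x192 input crop, mini-batches
of 20 slices, Adam at learning rate 0.001 for 50,000 iterations (10,000
for fine-tuning), 50 frames per cardiac cycle at 1.8x1.8 mm in-plane /
10 mm slice separation, myocardial density 1.05 g/mL.

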