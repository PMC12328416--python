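# sonoseg

Pure-transformer segmentation of thyroid nodules in B-mode ultrasound,
with masked-autoencoder (MAE) self-supervised pre-training — implemented
from the ground up in NumPy (including a small reverse-mode autodiff
engine) and exercised end to end on synthetic speckle phantoms, so the
whole pipeline runs and is testable on a laptop CPU without any external
dataset.

## Who this is for

Researchers and students who want a transparent, dependency-light
reference implementation of the MAE → ViT-segmentation recipe for medical
ultrasound: every stage (patch tokenisation, masking, attention, loss,
weight transfer, Dice training) is plain code with tests, rather than a
stack of framework callbacks.

## The method

**Model.** An image is resized to 224×224 and cut into 14×14 patches
(L = 256 tokens), linearly embedded into D = 192 dimensions with a learned
positional table, and passed through a 12-layer pre-norm ViT encoder and a
3-layer decoder (3 heads, feed-forward hidden width 384).  A per-token
linear head emits p² = 196 sigmoid probabilities — one per patch pixel —
which reassemble into the full-resolution soft mask.  The baseline model
has 4.66M trainable parameters.  An optional cross-attention variant adds
two pre-norm cross-attention sublayers per decoder layer
(`Attention(Q,K,V) = softmax(QKᵀ/√d_k)V` with Q from the decoder stream,
K/V from stored encoder layer outputs — U-Net-like skips), bringing the
count to 5.54M (+18.88%).

**Pre-training.** 75% of tokens are masked; the encoder sees only the
visible 25%; the decoder inpaints from a shared learned mask token and
reconstructs raw pixel patches under

    loss = MSE(masked) + α · MSE(unmasked),   α = 0.1.

**Fine-tuning.** Encoder + first three decoder layers transfer verbatim
(the fourth pre-trained decoder layer is dropped); training minimises soft
Dice loss `1 − (2Σpg + ε)/(Σp + Σg + ε)`; evaluation reports per-image
hard Dice at threshold 0.5.

Design rationale, calibration of unstated hyperparameters, and the limits
of the synthetic phantoms are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Desk-scale end-to-end run (56×56 phantoms, 7×7 patches, width-64 model;
≈1 minute on one CPU core):

```bash
sonoseg synth --n 16 --size 56 --seed 0 --out data
sonoseg pretrain --data data --patch-size 7 --image-size 56 --embed-dim 64 \
    --heads 4 --enc-layers 2 --mae-dec-layers 2 \
    --epochs 40 --batch 8 --lr 1e-3 --seed 0 --out runs/mae.ckpt
sonoseg finetune --data data --init runs/mae.ckpt --patch-size 7 \
    --image-size 56 --embed-dim 64 --heads 4 --enc-layers 2 \
    --seg-dec-layers 1 --epochs 150 --batch 8 --lr 2e-3 --no-augment \
    --seed 0 --out runs/seg.ckpt
sonoseg evaluate --ckpt runs/seg.ckpt --data data --out-csv runs/dice.csv
```

(augmentation is switched off because this small demo deliberately fits
its own 16-image corpus) which prints, from this exact command sequence:

```
wrote 16 image/mask pairs to data
pre-training loss 0.29694 -> 0.01318 (40 epochs); checkpoint at runs/mae.ckpt
transferred 43 entries, dropped 15, fresh 2
fine-tuning loss 0.86255 -> 0.22462 (150 epochs); checkpoint at runs/seg.ckpt
mean Dice 0.7757 over 16 images; table at runs/dice.csv
```

Reading the output: pre-training drives the α-weighted reconstruction
error down ~23×; the transfer copies 43 arrays (patch embedding,
positional table, encoder, first decoder layer) and discards 15 MAE-only
entries (deepest decoder layer, mask token, reconstruction head) while
the segmentation head's two arrays start fresh; Dice loss falls from 0.86
(near-chance) to 0.22, i.e. the model segments its training phantoms with
mean overlap Dice ≈ 0.78.  `runs/*.config.yaml` snapshots make every
artifact reproducible from its seed.

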