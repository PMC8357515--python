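# periseg

Synthetic perianal CT phantoms, region-of-interest extraction, a small
fully convolutional segmentation network with a patch-classifier baseline,
segmentation metrics, and clinical morphometry (skin-band thickness,
subcutaneous-fascia HU statistics) — all in pure scientific Python.

Since no real CT data exists for this problem, every component is
exercised on seeded synthetic phantoms with known ground truth:
a circular body cross-section with a skin band, a subcutaneous-fascia
layer, an anal canal, and (in the lesion group) a U-shaped
high-attenuation abscess wall around a low-attenuation core, rendered in
Hounsfield units with per-tissue noise and Gaussian edge blur.

## Package layout

| module               | contents |
|----------------------|----------|
| `periseg.phantom`    | seeded phantom/cohort generator with full ground truth |
| `periseg.roi`        | iterative (two-class-mean) threshold, morphology chain, ROI extraction |
| `periseg.network`    | conv/pool/upsample layers with hand-written backprop, dilation-gap analysis, the segmentation FCN and the sliding-window patch CNN, SGD training |
| `periseg.metrics`    | Jaccard, Dice, precision, recall, confusion counts |
| `periseg.morphometry`| ray-cast skin thickness, region HU statistics, Welch group comparison |
| `periseg.io` / `periseg.cli` / `periseg.pipeline` | slice/mask readers and writers (16-bit PNG/TIFF + spacing sidecar, NIfTI), the `periseg` CLI, the end-to-end experiment |

## Command line

```bash
periseg simulate --n-lesion 60 --n-control 60 --seed 1 --out data/ --size 128 --spacing 0.5
periseg extract-roi --in data/sample_000_lesion.tif --out-mask roi.png
periseg train --data data/ --out weights.npz --model dlfcnn --seed 1
periseg segment --weights weights.npz --in data/sample_000_lesion.tif --out pred.png
periseg evaluate --gold gold/ --pred pred/ --out metrics.csv
periseg morphometry --in data/ --out morpho.csv
periseg compare --data data/ --models dlfcnn,cnn --out compare.json
periseg run --out run/ --seed 1        # full simulate/train/evaluate/morphometry pipeline
```

Slices travel as 16-bit unsigned PNG/TIFF with HU offset by +1024 and a
JSON spacing sidecar, or as NIfTI with spacing in the header. Masks are
8-bit {0, 255} images. Model weights are NumPy archives with a JSON layer
manifest.

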