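# fbastack

Merge an ordered focal stack (one image per focal plane) into a single
deep-focus image by running **Fourier Burst Accumulation (FBA)** on
overlapping local regions and blending the regions back together.  The
package also ships the supporting machinery needed to validate such a merge
end to end:

- `fbastack.image_io` — PNG/TIFF/JPEG images and directory-of-frames focal
  stacks on a 0–255 intensity scale; Rec. 601 grayscale conversion.
- `fbastack.fba_core` — FBA proper: per-frequency weighted averaging of the
  frames' 2-D spectra, weights ∝ (smoothed magnitude)^p.
- `fbastack.tiled_merge` — the merging pipeline: 256×256 tiles shifted by
  128 px, a 7-frame window around the best-focused frame, per-tile FBA, and
  Hann-weighted overlap-add synthesis with partition-of-unity normalization.
- `fbastack.focus_measures` — Laplacian energy (mean |ΔI| of the grayscale
  image), best-frame selection, and forced-choice pair comparison.
- `fbastack.synthetic` — seeded synthetic focal stacks with an all-in-focus
  ground truth and a depth-dependent defocus model, for testing without any
  external data.
- `fbastack.evaluation` — paired-comparison counts, exact two-sided sign
  test, win percentages, and an objective summary table.

## CLI

```sh
# render a seeded 15-plane synthetic stack (+ truth.png / depth.tiff)
fbastack simulate out/stack --height 320 --width 256 --seed 1

# merge it into one deep-focus image (writes merged.png + merged.png.json)
fbastack merge out/stack --out out/merged.png

# sharpness of individual images (mean |ΔI|)
fbastack measure out/merged.png out/stack/plane_07.png

# objective paired comparison of two directories of matched filenames
fbastack evaluate out/merged_dir out/baseline_dir --out-csv summary.csv
```

Key `merge` options: `--tile-size` (256), `--stride` (128), `--frames` (7),
`--p` (11), `--mag-sigma` (2), `--best` (index or `auto`), `--sharpen`,
`--foreground-bias`.  Every command takes `--log-level`; logs go to stderr,
results to stdout or files.

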