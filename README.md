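# blockpet

PET image reconstruction for scanners whose detectors are rectangular crystal
blocks laid flat on the faces of a regular polygonal prism
("blocks-on-cylindrical" geometry), alongside the conventional idealization
that places the same detectors on a cylinder. The package implements the full
chain needed to quantify what the idealization costs:

- **geometry** — exact Cartesian detector-position maps for both models,
  including crystal/block gaps and average depth of interaction;
- **projection_data** — sinogram binning (segment, axial position, view,
  tangential position) computed directly from detector indices, its exact
  inverse, LOR lookup, and list-mode histogramming (span 1, no arc
  correction);
- **projectors** — Siddon raytracing with multi-ray tangential sampling and a
  matched (exactly adjoint) forward/back projector pair, numba-accelerated;
- **osem_recon** — fully-3D OSEM over interleaved view subsets with a
  factorized normalization x attenuation x geometry forward model;
- **corrections** — normalization factors from rotating-plane-source scans
  (orthogonal-view extraction, symmetric folding, inversion, capping) and
  attenuation sinograms from mu-maps;
- **phantom_sim** — analytic synthetic acquisitions (resolution phantom,
  uniform cylinder, point source, image-quality phantom, rotating plane) with
  Poisson noise, plus the remapping of block-truth data onto the virtual
  cylindrical scanner;
- **metrics** — COV, FWHM, spill-over ratio, peak-to-valley, and NU-4-style
  recovery coefficients;
- **io_cli** — interfile-style header + raw binary I/O with a run-time
  `geometry := cylindrical | blocks-on-cylindrical` keyword, and a CLI.

## CLI

```sh
blockpet info data.hs
blockpet simulate experiment.yaml -o acq.hs --seed 1 --remap-to acq_cyl.hs
blockpet normalize experiment.yaml -o norm.hs --geometry blocks-on-cylindrical
blockpet reconstruct acq.hs -o recon.hv --geometry blocks-on-cylindrical \
    --subsets 6 --subiterations 24 --rays 10 --norm norm.hs
blockpet evaluate recon.hv --metric cov --roi cylinder,0,0,0,54,10
```

An experiment config is a small YAML document:

```yaml
scanner: dodecagon-8x8      # preset, or an inline ScannerSpec mapping
axial_blocks: 1             # optional axial reduction for desk-scale runs
num_tangential: 100
grid: {n_xyz: [63, 63, 15], voxel_size: [1.1, 1.1, 1.1]}
phantom:
  kind: uniform_cylinder
  params: {diameter: 60.0, length: 25.0}
  total_counts: 1.0e6
seed: 11
rays: 10
```

## File formats

Projection data: `name.hs` text header plus `name.s` raw little-endian
float32 in [sinogram, view, tangential] order. Images: `name.hv` plus
`name.v` in [z, y, x] order. Headers are plain `key := value` lines; see
`blockpet.io_cli` for the key set.
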