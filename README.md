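# veneerfit

Digital design and fit validation of temporary dental veneers for
autotransplanted premolars, exercised end to end on synthetic tooth
phantoms.

The toolkit covers the full chain:

1. **Imaging I/O & preprocessing** (`veneerfit.imaging`) — volumes with a
   physical world frame (MetaImage `.mhd`/`.raw`, uncompressed DICOM
   series), intensity windowing, cubic median filtering, ROI cropping.
2. **Livewire segmentation** (`veneerfit.segmentation`) — inverted
   gradient-magnitude cost fields, globally minimal-cost anchor-to-anchor
   paths via an iterative raster-scan dynamic program (Dijkstra-
   equivalent, enforced by test oracle), orthogonal contour stacks,
   energy-minimizing radial-basis implicit surfaces (triharmonic kernel
   plus linear trend), sign rasterization, and marching-cubes mesh
   extraction to print-ready STL.
3. **Veneer CAD** (`veneerfit.design`) — crown isolation at a cervical
   plane, mirroring of the contralateral incisor, centroid/principal-axes
   placement with explicit override, Boolean subtraction with a cement
   spacer, undercut blockout along an insertion axis verified by a
   20-station seating sweep, 45° margin chamfer, and ray-cast wall
   thickness inspection. Solid operations run on a voxel-remesh kernel
   (default pitch 50 µm); the pipeline is deterministic, so identical
   inputs give byte-identical STL.
4. **Fit assessment** (`veneerfit.assessment`) — marginal gaps measured
   on calibrated margin images at six evenly spaced stations per image
   (three sides, 18 readings per veneer); internal adaptation from
   µCT-like volumes by indirect gap segmentation (threshold + Euclidean
   ball closing, `gap = combined AND NOT enamel`), mesh reconstruction,
   inscribed-sphere 3D thickness mapping, summary statistics against the
   200 µm clinical cutoff, and one-way ANOVA.
5. **Phantoms** (`veneerfit.phantoms`) — parametric superellipsoid teeth,
   seated veneers with prescribed uniform / truncated-normal / sinusoidal
   gap fields (gap truth exact at every intaglio vertex), noisy
   CBCT-like (200 µm) and µCT-like (12.8 µm) voxelizations with ground
   truth labels, and margin-image rendering.
6. **Workflow & CLI** (`veneerfit.workflow`, `veneerfit.cli`) — YAML
   config driving segment → design → assess with a hashed run manifest.

## CLI

```sh
veneerfit phantom --n 15 --gap-mean 100 --gap-sd 50 --seed 7 --out batch/
veneerfit segment --volume scan.mhd --anchors anchors.jsonl --out tooth.stl \
    --window 100 800
veneerfit design --incisor incisor.stl --tooth tooth.stl --out veneer.stl
veneerfit assess-margin --image cervical=img.npy --pixel-size 4 --out stats.json
veneerfit assess-internal --volume uct.mhd --out internal.json --csv thickness.csv
veneerfit run pipeline.yml --manifest manifest.json
```

Anchor files are JSON lines: `{"axis": 2, "slice": 30, "points": [[r, c], ...]}`.
The `run` verb takes a YAML config with per-stage sections (`phantom`,
`segment`, `design`, `assess_margin`, `assess_internal`); stages without
a section are skipped, and every output file is recorded with a content
hash in the manifest.

## Conventions

Right-handed world frame in mm, voxel centers at `origin + index * spacing`;
gap fields and thickness maps in µm. Implicit surfaces are negative
inside. Mesh Booleans, plane cuts, and blockout all go through the voxel
parity kernel: results are watertight by construction and their accuracy
is set by the stated pitch (see the tolerance notes in each docstring).
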