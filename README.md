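# aztomo

Quantitative cryo-electron tomography morphometrics of presynaptic active
zones.

Before fusing, synaptic vesicles (SVs) are held near the active-zone (AZ)
membrane by short pleomorphic protein bridges: *tethers* (SV to plasma
membrane) and *connectors* (SV to SV). Their lengths and the SV-to-membrane
distances encode functional states — SVs closer than 5 nm with short
tethers correspond to a molecularly primed, SNAP25-dependent state, SVs at
5-10 nm to an intermediate state, and SVs beyond 10 nm to a
Munc13-independent state. `aztomo` turns reconstructed tomograms (MRC
density plus integer label volumes for membranes and vesicles) into these
quantities, for structural neurobiologists analyzing synaptic tomograms and
for anyone who needs a tested, ground-truthed implementation of
hierarchical connectivity segmentation and voxel-geodesic morphometry.

## The method

**Detection.** Bridges are found as 26-connected clusters of dark voxels
(cryo-ET density is structure-low) linking two boundaries, over an
increasing threshold ladder t1 < ... < tK. Each bridge is reported at the
*lowest* threshold at which it links its boundaries — its "core":

- contacts {one SV, AZ membrane} → tether
- contacts {two SVs, no membrane} → connector
- anything else → rejected

**Measurement.** The SV distance *d* is the shortest edge-to-edge distance
between vesicle and AZ voxels. The bridge length *L* is the minimal
geodesic through the segment's voxels between its two contact sets
(26-neighbor steps weighted 1, √2, √3 voxels), so curvature contributes to
*L*. Vesicles are classified by *d* into states (bounds 5/10 nm), tethers
by *L* into short/intermediate/long (bounds 6/12/24 nm), and the cytoplasm
into proximal/intermediate/distal zones (bounds 45/75/250 nm). Per-vesicle
tether/connector counts, 1-voxel layer occupancy profiles, AZ surface area,
and surface concentrations complete the per-synapse tables.

**Statistics.** Conditions are compared only along planned, orthogonal
pairs: Student's t for continuous values, Kruskal-Wallis for per-vesicle
counts, Pearson's chi-squared (no continuity correction) for frequencies,
Pearson r for associations; all two-tailed, with SEM between synapse means
for fractions, CDF inflection points, and missing-wedge orientation
equalization before tether/connector comparisons.

Everything is exercisable without data downloads through a seeded phantom
generator that plants membranes, vesicles, and curved tube bridges with
exactly known geometry. See `docs/methods.md` for conventions, defaults,
and limitations.

## Worked example

```python
from aztomo import phantom, pipeline

spec = phantom.validation_phantom()          # 128^3 voxels at 1.4 nm
density, labels, truth = phantom.generate_phantom(spec)
record = pipeline.run_synapse(density, labels, pipeline.RunConfig(),
                              synapse_id="demo", condition="wt")
print(record.vesicles[["vesicle_id", "distance_to_az_nm", "n_tethers",
                       "n_connectors", "state"]].to_string(index=False))
print(f"AZ area: {record.az_area_nm2:.0f} nm^2")
```

prints

```
 vesicle_id  distance_to_az_nm  n_tethers  n_connectors              state
         10                4.2          1             1   SNAP25-dependent
         11                5.6          1             2       intermediate
         12                8.4          1             1       intermediate
         13                9.8          2             1       intermediate
         14               14.0          2             2 Munc13-independent
         15               16.8          1             1 Munc13-independent
AZ area: 19598 nm^2
```

All 8 planted tethers and 4 connectors are recovered (the vesicle at 9.8 nm
carries the bent tether whose geodesic exceeds its chord), every measured
distance is within one voxel diagonal (2.4 nm) of the planted value, and
the AZ patch area matches its 140 x 140 nm construction. The same run on
your own data starts from `tomio.read_mrc` / `tomio.read_labels`, or from
the CLI:

```bash
aztomo phantom --config phantom.yaml --out phantom_out/
aztomo measure --density phantom_out/density.mrc \
               --labels phantom_out/labels.mrc --out results/
aztomo compare --config study.yaml --out results/
```

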