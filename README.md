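# synaptomap

Single-synapse phenotyping from multiplexed immunofluorescence images of
cultured neurons.

Multiplexed imaging (e.g. sequential-probe methods such as PRISM) stains the
same field of neurons for a dozen synaptic proteins over many imaging
rounds — vesicle markers (synapsin1, vGlut1, vGAT, bassoon), postsynaptic
scaffolds (PSD-95, SHANK3, homer-1b/c, NR2B, gephyrin), cytoskeleton (actin,
cortactin), plus MAP2 (dendrites) and DAPI (nuclei).  `synaptomap` turns
those image stacks into a per-synapse molecular profile table and the
statistics built on it, for neurobiologists studying synapse diversity and
homeostatic plasticity:

1. **Image processing** — per-round registration on the repeated MAP2
   channel (integer translation by cross-correlation), illumination
   correction by large-kernel morphological opening, white top-hat spot
   enhancement, and robust-background thresholding computed on untreated
   wells only and reused everywhere.
2. **Synapse assembly** — puncta are declumped by intensity peaks
   (seeded watershed), filtered to equivalent diameters
   `d = 2·sqrt(A/π) ∈ [3, 15]` px, excluded over nuclei or farther than
   8 px from the dendrite mask, and grouped onto synapsin1 anchors:
   presynaptic puncta join with ≥ 50 % child-area overlap, postsynaptic
   with ≥ 6.25 % (= 1 px of a 16-px punctum).  Each synapse is classified
   excitatory / inhibitory / dual / unknown from its vGlut1 and vGAT
   children.
3. **Features** — a CellProfiler-style battery (shape moments, Crofton
   perimeter, intensity statistics, mass displacement, child-to-anchor
   distances, per-target punctum counts), reduced to the published
   clustering-input column set and normalized to untreated-group means.
4. **Subtype discovery** — 2 000 synapses per replicate, correlation-based
   feature pruning, centring/scaling, 2D UMAP, HDBSCAN with
   `min_cluster_size = 100` (noise removed), per-cluster intensity
   profiles and masked correlation heatmap inputs.
5. **Statistics** — replicate-level two-tailed permutation t tests
   (5 000 reshuffles, exact enumeration when feasible), Cohen's *d* with
   BCa bootstrap intervals (5 000 resamples), noncentral-*t* power, and
   synapse densities per 100 µm of skeletonized dendrite at 187 nm/px.

Because raw multiplexed image sets of this kind are rarely deposited, the
package ships a first-class **synthetic cohort generator**
(`synaptomap.synthetic_data`): dendrite arbors, nuclei, and per-target
puncta drawn from six configurable subtype profiles, with round-to-round
misalignment, illumination gradients, Poisson + Gaussian noise,
untreated/treated replicate structure, and injected per-target treatment
effects — all recorded in a ground-truth table, so every pipeline stage is
testable against known truth.

## Worked example

```python
from collections import Counter
from synaptomap import SynthConfig, generate_field
from synaptomap.pipeline import (
    RunConfig, process_field, compute_thresholds, assemble_field,
)
from synaptomap.statistics import synapse_density

config = SynthConfig(image_shape=(256, 256), seed=42)
field, truth = generate_field(config, replicate_id=0, field_id=0)

run_config = RunConfig()
proc = process_field(field, run_config)
thresholds = compute_thresholds([proc], run_config)
synapses, counts = assemble_field(proc, thresholds, run_config)

print("rendered :", len(truth.synapses), "true synapses")
print("detected :", Counter(s.class_label for s in synapses))
dens = synapse_density(
    {"excitatory": sum(s.class_label == "excitatory" for s in synapses),
     "inhibitory": sum(s.class_label == "inhibitory" for s in synapses)},
    proc.dendrite_mask, config.pixel_size_um)
print("dendrite :", round(dens["length_um"], 1), "um")
print("density  :", round(dens["density_excitatory"], 1), "excitatory and",
      round(dens["density_inhibitory"], 1), "inhibitory per 100 um")
```

prints

```
rendered : 70 true synapses
detected : Counter({'excitatory': 38, 'dual': 13, 'unknown': 12, 'inhibitory': 6})
dendrite : 104.5 um
density  : 36.3 excitatory and 5.7 inhibitory per 100 um
```

i.e. on this noisy 256×256 field (48 × 48 µm) the pipeline assembles 69
synapses from the 70 rendered, classifies most as excitatory (the generator's
default composition is 5:1 excitatory:inhibitory among classified
synapses, with ~22 % synapsin1-only "unknown" and ~12 % dual), and
reports dendritic densities for the classified population.

An end-to-end run over a whole simulated cohort (through UMAP/HDBSCAN and
the permutation-test battery) is one command:

```sh
synaptomap run --simulate --seed 7 --out my_run
```

which writes `synapses.csv`, `features.csv`, `embedding.csv`,
`cluster_profiles.csv`, `comparisons.csv`, per-cluster correlation
matrices, and a provenance `run_config.yaml`.  Re-running with the same
seed reproduces every CSV byte-identically.

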