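# vegsynth

Sample-based synthesis of vegetation distribution patterns.

Building a virtual forest scene needs the position and species of every
plant over a large area, but forest inventories only cover small plots.
Plant communities are also far from random — tall arbors keep their
distance, shrubs clump — so purely random placement (Poisson disk and
friends) misses the biology. `vegsynth` takes a small measured or designed
plot (a *sample pattern*: points with species ids and optional DBH / height
/ crown-width attributes) and grows an arbitrarily large pattern with the
same local arrangement statistics, by texture-synthesis-style neighborhood
matching on vector elements. It is aimed at forest-scene construction,
stand-structure simulation, and anyone who needs realistic large point
patterns conditioned on a small exemplar.

## Method in brief

Each element's local context is summarised by **neighborhood histograms**:
the disc of radius `R` around it is cut by 3 concentric circles and 8 radial
lines into 24 grids (`bin = shell·8 + sector`), and the neighbors of each
species are counted per grid. Synthesis grows outward from a seed element:
the unextended element nearest the centre is *extended* by finding the
sample element whose histograms best match on the already-determined grids,

    d_A²(p, q) = (p − q) A (p − q)ᵀ,   a_ij = e^(−σ·d(i,j)),
    d(i, j) = |shell_i − shell_j| + |sector_i − sector_j|,

(multi-species: `d_z = Σ_t w_t d_t`) and copying that element's neighbors —
with species and tree attributes — into the not-yet-covered part of its
disc. The result is evaluated by how well it preserves the sample's
**density** and **aggregation index** (centred Ripley statistic
`L(d) − d`; negative = regular, ≈0 = random, positive = clustered), scored
as `PCT.DEV = |mean(I₁,I₂,I₃) − I_s| / |I_s| × 100` over random evaluation
patches of increasing size. See `docs/methods.md` for the full model,
parameter meanings and design choices.

## Worked example

```python
from vegsynth import (SynthesisParams, density, evaluate_synthesis,
                      gen_regular, synthesize)

sample = gen_regular(64)                 # 8x8 lattice, unit plot, 64 trees
master = synthesize(sample, (0, 0, 10.5, 10.5), SynthesisParams(seed=1))
print(master.n)
report = evaluate_synthesis(sample, master, density, seed=0,
                            index_name="density")
print(report.to_text())
```

prints

```
7225
Sample(1x1)  Synthesis(3x3)  Synthesis(6x6)  Synthesis(10x10)  PCT. DEV.
         64              64              64                64         0%
```

7225 = 85² trees: the 10.5×10.5 master is the sample lattice continued at
spacing 0.125. The evaluation draws 10 random 3×3, 6×6 and 10×10 windows
from the master; every window holds exactly 64 trees per unit area, so the
deviation from the sample's density is 0% — the synthesis preserved the
stand's density at every scale. The same pipeline runs from the shell:

```sh
vegsynth generate --kind regular --density 64 --out sample.csv
vegsynth synthesize --sample sample.csv --region 10.5 10.5 --seed 1 --out big.csv
vegsynth evaluate --sample sample.csv --synth big.csv --index density --out report.json
vegsynth export-scene --in big.csv --out scene.csv   # placement table for 3-D builders
```

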