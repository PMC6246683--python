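# estuarynet

Statistical pipeline for sediment microbiome transects in polluted coastal
estuaries: community dissimilarity and its permutation tests,
environment–taxon association screens, functional-category comparisons, and
co-occurrence networks whose correlation threshold is selected by random
matrix theory (RMT), with module eigengenes, Zi/Pi node roles and keystone
taxa. A ground-truthed synthetic transect generator makes every stage
testable without any external sequence data.

## Who it is for

Microbial ecologists asking, for a small set of samples along an
environmental gradient (the motivating design is 6 sites × 2 years in an
urbanized bay): does the community differ between zones (MRPP / ANOSIM /
PERMANOVA on Bray-Curtis, Sørensen, UniFrac, Euclidean distances)? Which
factors track beta-diversity once geographic distance is controlled
(Mantel / partial Mantel)? Which taxa and gene categories respond to which
factors (Pearson screens with BH-FDR, Welch tests on category shares)? And
how is the community wired (RMT-thresholded correlation network, fast-greedy
modules, SVD eigengenes, keystones)?

## The core method

Given pairwise |Pearson r| between OTU profiles, the RMT scan zeroes entries
below a candidate threshold t and examines the nearest-neighbour spacing
distribution (NNSD) of the unfolded eigenvalue spectrum. Noise-dominated
matrices follow the Gaussian orthogonal ensemble law (Wigner surmise,
p(s) = (πs/2)·e^(−πs²/4), level repulsion); modular, system-specific
structure follows the Poisson law p(s) = e^(−s). The chosen cutoff is the
smallest t whose NNSD is Poisson-consistent (χ² p > 0.05) at two consecutive
grid points. The network at that cutoff is decomposed into fast-greedy
modules; each module is summarized by its eigengene (first sample-side
singular vector of the standardized member submatrix) and correlated with
the environment; nodes are classified in the Zi/Pi plane (within-module
degree z-score vs participation coefficient, hubs at Zi > 2.5, connectors at
Pi > 0.62); keystones are hubs, connectors and top-degree nodes.

## Worked example

```sh
python analysis/01_simulate.py --seed 1      # synthetic 12-sample transect
python analysis/05_network.py  --seed 1      # RMT network on it
```

The simulated transect spans salinity 2.5–22.5 ‰ with seawater DIN falling
from 3.5 to 0.4 mg/L, 300 OTUs in four planted guilds (one driven by DIN),
and prints, for the network stage:

```
prevalence filter: 300/300 OTUs present in >= 8/12 samples
RMT threshold: 0.82 (Poisson-consistent at two consecutive grid points)
network: 201 nodes, 2618 edges, 13 modules, Q = 0.667
observed vs degree-preserving null:
                 observed  null_mean  null_sd        z
avg_clustering      0.674      0.203    0.008   57.827
avg_path_length     3.550      2.155    0.007  205.124
modularity_q        0.667      0.128    0.004  149.949

keystones (12): module hubs/connectors = {}, rest by top degree
module most correlated with seawater DIN: module 4, r = 0.92
module recovery vs planted guilds: ARI = 1.000
```

Read: the scan picked 0.82 as the point where the spectrum turns modular;
the network is far more clustered and modular than degree-matched random
graphs (z ≫ 2); the four planted guilds are recovered exactly (ARI 1.0); and
the pollutant guild's eigengene tracks the DIN gradient at r = 0.92 — the
module-level signature of pollutant-selected taxa. The other drivers
(`02`–`04`, `06`) produce the group-test table, the Mantel grids, the
OTU–factor screen and the functional-category comparison; `07` runs the
calibration benchmarks.

The same stages run on real data from TSV tables (`estuarynet run
--config run.yaml`, or the `dist` / `grouptest` / `mantel` / `screen` /
`net` / `func` subcommands).

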