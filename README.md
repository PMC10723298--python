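# phenofluct

Clonal fluctuation analysis of reversible phenotype switching, built for
the question of whether acquired **anoikis resistance** — the ability of
ovarian cancer cells to survive detachment from the extracellular matrix
in suspension — is genetic, stably heritable, or a transient non-genetic
state.

The approach is a Luria–Delbrück-style fluctuation test read in reverse:
instead of counting rare resistant mutants, one expands single-cell
clones for ~20 generations, plates each clone into low-attachment
suspension for 24 h, and asks whether the **clone-to-clone variability**
in the surviving fraction is compatible with a given model of how the
resistant state is inherited.

## The model

Cells switch reversibly between an anoikis-**sensitive** (S) and an
anoikis-**resistant** (R) state. Switching is fitness-neutral in attached
growth and happens at division: each daughter switches S→R with
probability $p_{sr}$ and R→S with probability $p_{rs}$, so the resistant
state persists for a geometric number of divisions with mean
$1/p_{rs}$ (its *memory*), and the steady-state resistant fraction is

$$f = \frac{p_{sr}}{p_{sr} + p_{rs}}.$$

In a suspension assay of duration $T$, resistant cells grow at rate
$\gamma = \ln 2 / T_d$ ($T_d$ = suspension doubling time) while sensitive
cells die, so the expected surviving fraction (which may exceed 1) is

$$\bar S = f\,e^{\gamma T}.$$

With $\bar S \approx 0.9$, $T = 24$ h and $T_d = 100$ h this inverts to
$f \approx 0.76$. Simulating the full branching process (20 generations
of expansion, memory ≈ 10.5 generations) shows the two-state model
predicts an interclonal CV of survival **below 0.01** — per-division
switching decorrelates clones from their founders and averaging over
$2^{20}$ cells crushes demographic noise. Observed fluctuations of
0.25–0.3 are therefore orders of magnitude too large for this model.

The alternative considered is heritable **growth-rate heterogeneity**:
each clone carries its own effective rate $\gamma_c \sim \mathcal N(\bar\gamma,
\sigma^2)$, giving survival CV $\sqrt{e^{(T\sigma)^2} - 1}$. Inverting at
an observed CV of 0.25 requires a growth-rate CV of
$\sqrt{\ln(1+0.25^2)}/(T\bar\gamma) \approx 1.48$ — i.e. massive
cell-to-cell variation in the effective suspension growth rate, including
net-death rates.

## Worked example

```python
import phenofluct as pf
from phenofluct.switching_model import AssayParams, rates_from_fraction_and_memory
from phenofluct.synthetic_data import ExperimentDesign, generate_clone_experiment

# invert the survival relation
f = pf.resistant_fraction_from_survival(0.9, T=24, T_d=100)

# two-state model with memory 10.5 generations, pinned at f = 0.76
params = rates_from_fraction_and_memory(0.76, 10.5)
pred = pf.predicted_cv_two_state(params, 20, AssayParams(count_depth=None),
                                 n_clones=10_000, seed=0)

# synthetic 60-clone experiment (combined model) and its fluctuation summary
table = generate_clone_experiment(ExperimentDesign(seed=0))
summary = pf.interclonal_summary(table, passage=1, seed=0)
res = pf.infer_growth_rate_cv(summary.cv)
```

prints (via the obvious format strings):

```
resistant fraction f = 0.7621
switching rates: p_sr = 0.3016, p_rs = 0.0952
two-state predicted CV = 0.00085 (MC SE 6.0e-06)
synthetic experiment: mean survival = 0.911, CV = 0.269, 95% CI [0.229, 0.303]
fold difference = 317
required growth-rate CV = 1.590
```

Reading: the survival relation implies ~76% of cells sit in the resistant
state; the two-state switching model predicts essentially no interclonal
fluctuation (CV ≈ 0.001), while the synthetic experiment — generated
with clone-level growth-rate heterogeneity at CV(γ) = 1.45 — shows the
observed-scale CV ≈ 0.27, hundreds of times larger than the two-state
prediction. Inverting that particular realisation's CV returns a
growth-rate CV of ≈ 1.59 (the closed form at the band edge 0.25 gives
1.48).

## Command line

A thin CLI wraps the same functions:

```bash
phenofluct simulate --seed 7 --out runs/sim
phenofluct analyze --input runs/sim/clones.csv --seed 1 --out runs/analysis
phenofluct predict-two-state --seed 3 --out runs/pred
phenofluct infer-gamma-cv --target-cv 0.25 --out runs/infer
phenofluct growth --input growth.csv --out runs/growth
phenofluct revert --passages 30 --gens-per-passage 1 --out runs/revert
```

Every run writes a `manifest.json` (parameters, seeds, version, headline
metrics) from which it can be reproduced. Exit codes: 0 success, 2
validation error, 3 numerical failure.

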