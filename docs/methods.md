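# Methods

`kinasecv` analyses the conformational ensemble of a protein kinase domain
through low-dimensional collective variables (CVs) and triages candidate
allosteric modulators from score and energy tables. This note records the
models, the defaults and why, and what the synthetic data does and does not
establish.

## Collective variables and state model

The two CVs are inter-residue distances in angstrom: the K745(NZ)–E762(CD)
salt-bridge distance `d1`, whose formation (~3–4 Å) marks the active EGFR
kinase conformation and whose rupture (~14.4 Å) the inactive one, and an
E762–D855 distance `d2` reporting on αC-helix position (inward ~7–10 Å,
outward >12 Å). Frames are classified by joint strict thresholds:
inactive-like (`d1 > 13` and `d2 > 12`), active-like (`d1 < 7` and
`d2 < 7`), intermediate-like otherwise. Boundary frames are
intermediate-like because the inequalities are strict. 1D band populations
use half-open bands `(-inf, 7), [7, 13), [13, inf)` by default, and all
time windows are half-open `[start, end)` ns so consecutive windows
partition a trajectory exactly.

The atom pair defining `d2` is not uniquely standardized; the default is
the side-chain carboxylate carbon of each residue (CD for Glu, CG for Asp),
overridable through the selection strings, and echoed in output metadata.

## Population statistics

State fractions carry normal-approximation binomial intervals,
`p ± z sqrt(p(1-p)/n)`, default 95% (z = 1.96). By default `n` is the raw
frame count, which matches how occupancies of long production runs are
conventionally quoted. MD frames are autocorrelated, so an optional
correction replaces `n` with the effective sample size `n/τ`, where τ is
the integrated autocorrelation time of the state-indicator series
estimated with Geyer's initial-positive-sequence truncation. The
correction is off by default and should be switched on whenever the
interval is used as an actual coverage statement about a correlated
series; the parameter-recovery tests do exactly that.

## Free-energy surfaces and densities

The 2D surface is the Boltzmann inversion of the binned CV histogram,
`G = -kB T ln P`, with `kB = 0.0019872041 kcal mol⁻¹ K⁻¹` and default
`T = 300 K` (the production-ensemble temperature the analysis assumes).
The grid defaults to 100×100 bins spanning the data range padded by 0.5 Å;
binning is an analysis choice, so it is recorded in the surface metadata.
G is shifted so the occupied minimum is 0 and empty bins are masked, never
imputed. Inverting the shifted surface recovers the empirical bin
probabilities exactly (a tested 1e-10 round trip). Frames are unweighted:
the inputs are plain unbiased trajectories, and no enhanced-sampling
reweighting is attempted.

1D distributions are Gaussian KDEs with Silverman's rule bandwidth
`h = 0.9 min(σ, IQR/1.34) n^{-1/5}` by default, echoed in the output. The
rule errors on a zero-variance sample; passing an explicit bandwidth
handles that degenerate case (a single Gaussian at the common value). Note
that a fixed global bandwidth can merge modes separated by less than ~3
bandwidths; resolving close basin modes may need an explicit smaller `h`.

## Block averaging

A windowed channel is split into `n_blocks` contiguous equal-count blocks
(remainder frames join the last block; with uneven blocks the reported
mean is the plain mean over the window). The uncertainty is the **sample
standard deviation of the block means** — deliberately not the standard
error, as the conservative convention when the block count is small and
unstated in comparable reports; divide by `sqrt(n_blocks)` for an SEM-like
quantity. Default `n_blocks = 5`, configurable and echoed in every output.
With one block the uncertainty is undefined and reported as NaN.

## PCA and representative frames

PCA is an eigendecomposition of the covariance (not correlation) of a
caller-supplied frames × features matrix; the feature definition (CV
channels, or externally superposed coordinates) is the caller's and is
recorded in metadata. Components use a deterministic sign convention
(largest-magnitude loading positive). The representative frame of an
ensemble is found by binning the PC1/PC2 projections (default 50×50),
taking the highest-count bin (ties: smallest row-major index) and
returning the frame nearest that bin's center (ties: earliest frame).

## Synthetic trajectory generator

Raw trajectories are typically not redistributable, so the generator
produces CV series with the statistical structure the analyses assume: a
discrete-time hidden Markov chain with per-state 2D Gaussian emissions.
This endows the series with metastability, exchange-rate-controlled
autocorrelation and multimodal densities — sufficient for every statistic
in this package, which depends on the CV distribution and its mixing, not
on Cartesian physics. It does **not** emulate force-field energetics,
within-basin anharmonicity, or slow drift between more than the configured
basins; passing tests therefore demonstrate statistical correctness of the
estimators, not fidelity of any particular MD ensemble. An optional
Ornstein–Uhlenbeck smoothing (relaxation time in ns) adds within-basin
autocorrelation; it is off by default. All draws flow from one integer
seed and identical (model, n_frames, seed) triples are bit-identical.
Default `frame_interval = 0.01 ns` (10 ps), the common save stride of
short production runs; it is a free parameter.

Three presets emulate the qualitative study systems: a wild-type-like
ensemble dominated by the inactive basin (~80% inactive-like, `d1` near
14.5 Å), a mutant-like ensemble collapsed to an intermediate basin
(mean `d1` 12.08 Å, ~0.1% inactive-like), and an inhibitor-bound-like
trimodal ensemble (`d1` modes near 9.5/12/14 Å, ~15% inactive-like).
Transition matrices use `T = (1-ε)I + ε 1πᵀ` with ε = 0.005, giving the
exact stationary vector π and ~2 ns basin lifetimes at the default frame
interval — metastable yet well sampled at 10⁵–10⁶ frames. These presets
define fixed study conditions for the ordering tests; only the ordering of
inactive-like fractions (wild > inhibitor-bound > mutant) is asserted, not
the exact percentages. A separate two-state benchmark model (stationary
0.8/0.2, mixing eigenvalue 0.95, well-separated emissions) underlies the
occupancy-recovery checks, where classification error is negligible
(<2×10⁻⁴) against a sampling SE of ~6×10⁻³.

## Screening triage

MM/GBSA components are consumed as tables (per-compound means or per-frame
rows); the module computes `dG_gas = VDW + EEL`, `dG_solv = EGB + ESURF`,
`dG_total = dG_gas + dG_solv` exactly, with the sample SD of per-frame
totals when frames are given. Entropy terms are intentionally absent from
the schema. A validation mode recomputes printed aggregate columns from
their own components at a ±0.02 kcal/mol tolerance (the slack that
2-decimal component rounding can introduce) and reports any row exceeding
it rather than silently accepting the table — the packaged reference table
contains two such rows, which the tests pin down.

Ranking: rank 1 is best under a per-criterion direction (ML affinity
descending, docking score and binding energy ascending). Ties default to
stable input-order resolution, producing distinct consecutive ranks — the
convention evidenced by the packaged tables, where four compounds share an
ML score yet hold distinct ranks in listing order — with min-rank
("competition") style available. Lead selection takes compounds ranking
≤ top_k in ≥ min_criteria criteria (defaults 5 and 3 of 5); structural
criteria that cannot be recomputed from score tables (αC-helix
displacement, salt-bridge shift) enter as externally supplied rank
columns.

## Numerical and degenerate-input choices

* Transition-matrix rows must sum to 1 within 1e-12; covariances must be
  PSD within -1e-10 on the smallest eigenvalue.
* The stationary distribution requires a unique unit eigenvalue; reducible
  chains (e.g. the identity) are rejected.
* Distances are clipped at 0 on emission (never engaged at realistic
  configurations) and validated non-negative on ingestion.
* CV tables reject non-numeric or blank cells with 1-based line numbers
  and non-monotonic times; exports keep full float precision so read/write
  round-trips to ≥6 significant digits.
* PDB reading takes the first model with first-altloc filtering; a
  selection resolving to ≠1 atoms is an error naming the selection and
  count.

## Problem sizes

The test suite simulates 2×10⁴–2×10⁵ frames per trajectory and 20 seeds
for the coverage check (~30 s total); the acceptance script regenerates
4×10⁶ benchmark frames plus three 10⁵-frame ensembles (~10 s). These sizes
put sampling error well below every asserted tolerance while keeping runs
reproducible on a single CPU.

## Known limitations

* The generator's basins are Gaussian and exchange is memoryless; real
  kinase ensembles show anharmonic basins and broad waiting-time spectra.
* KDE peak detection depends on bandwidth; close modes can merge under the
  default rule.
* The binomial interval (even ESS-corrected) assumes a stationary series;
  strongly drifting trajectories need windowed analysis instead.
* No kinetic modeling: occupancies only, no rates or transition-path
  statistics.
* MM/GBSA values are consumed, not computed; absolute binding affinities
  are out of scope and all energy comparisons are relative rankings.
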