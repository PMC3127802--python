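# Methods

## Model overview

`spinerd` simulates the biochemical network that couples synaptic calcium
and dopamine input to protein kinase A (PKA) activity in a CA1 pyramidal
neuron dendrite bearing one or more spines.  The question the simulations
address is spatial: PKA is tethered by A-kinase anchoring proteins (AKAPs),
and anchoring may serve to place PKA near its activator (adenylyl cyclase,
the source of cAMP) or near its targets (AMPA-receptor GluR1 in the
post-synaptic density).  Because the spine head holds only tens to hundreds
of molecules of most species, concentrations are not well defined and the
dynamics are simulated stochastically, at mesoscopic resolution: space is
divided into well-stirred subvolumes (voxels), reactions fire within
voxels, and molecules hop between adjacent voxels.

The reaction network comprises ~100 species and 81 reaction rows
(expanding to 182 elementary mass-action steps): dopamine D1 receptor /
G-protein activation of adenylyl cyclase types 1 and 8; calcium binding to
calmodulin and activation of AC1/AC8, PDE1, calcineurin (PP2B) and CaMKII;
cAMP production and degradation (PDE1, PDE4B, PDE4D, with PKA
phosphorylation of PDE4s as negative feedback); PKA holoenzyme activation
by four cAMP molecules; phosphorylation of inhibitor-1 (which inhibits
PP1), of PDE4B/D, and of GluR1 on S845 (PKA) and S831 (CaMKII); calcium
buffering (calbindin, an irreversible clean-up buffer CaB) and extrusion
(PMCA- and NCX-like pumps).  All rate constants, basal concentrations and
diffusion constants are in the declarative files under
`src/spinerd/data/`.

## Geometry

The dendrite is a rectangular cuboid standing in for a 0.6 um cylinder
(correct surface-to-volume ratio), discretized into a 2-D grid of
single-depth cuboids; the two outermost width columns form the submembrane
region, whose volume fraction matches a 0.07-um shell on the equivalent
cylinder.  The default single-spine mesh is 5 x 40 voxels of
0.12 x 0.125 x 0.4 um^3 (200 subvolumes) plus a spine of 0.1-um slices:
three 0.2-um-diameter neck cylinders, two 0.6-um head cylinders and one
PSD slice (206 voxels total).  Spine-neck variants of 0 and 1.0 um replace
the three neck slices with zero or ten.  The multi-spine mesh is a 20-um
dendrite of 3 x 100 voxels (0.2 x 0.2 x 0.4 um^3) with 11 evenly spaced
spines, the two nearest one end being the stimulated ones.  Diffusion is
2-D in the dendrite and 1-D along the spine chain, with reflective outer
boundaries.  The spine head compartment (two head slices + PSD,
3*pi*0.3^2*0.1 ~ 0.085 um^3) defines the "spine" anchor zone; the focal
dendritic anchor zone is a contiguous run of submembrane voxels beneath
the spine whose volume best matches the head compartment, so anchored
species have equal local concentration in either placement.

## Stochastic engine

Reactions advance by fixed-step tau-leaping: each voxel/channel draws a
Poisson event count with mean a*dt, where the mass-action propensity uses
k*n for unimolecular steps and k*n_A*n_B/(N_A*V) for bimolecular steps (V
the voxel volume; "A+2B" rows are second order overall, consuming two B
per event; homodimerizations use n(n-1)).  Draws are capped at the
available molecules, so counts never go negative; with the default steps
the cap engages only during the sub-millisecond calcium-injection spikes.
Diffusion uses the same leaping idea: for each directed coupling the
number of jumping molecules is binomial with per-molecule probability
D*A/(V*d)*dt; any (species, edge) pair whose probability would exceed 0.1
(in practice only the fast diffusers on the thin spine couplings) is
substepped.  Injections add floor(rate*dt) molecules plus a Bernoulli
remainder.  Initial concentrations are converted to per-voxel expectations
and rounded stochastically, so dilute species occupy some voxels and not
others.  All randomness derives from the single run seed; trajectories are
bit-reproducible.

Two reference modes validate the engine: an exact Gillespie direct-method
SSA including diffusion channels (for small systems), and a deterministic
well-mixed mass-action ODE (scipy LSODA).  The tests compare tau-leap
means and variances against the SSA on toy systems, check every printed
reversible pair against kb/kf, and recover Michaelis-Menten initial rates
(e.g. Km = 5000 nM for the inhibitor-1/PKAc triple).

Default time step: 5 us at full scale (following the source protocol);
40 us for desk-scale runs, chosen so that every first-order channel has
lambda*dt <= ~0.11 and diffusion jump probabilities stay below 0.1 after
substepping.  Desk-scale runs also coarsen the dendrite grid (3 x 20
voxels of 0.2 x 0.25 x 0.4 um^3 for the single-spine mesh; 3 x 50 for the
multi-spine mesh); the spine discretization, where the microdomains live,
is never coarsened.

## Stimulation

Long-lasting LTP induction: four 1-s trains of 100 Hz stimulation.  Each
pulse injects calcium for 0.7 ms at 62.5 molecules/ms, independently at
the PSD (NMDA-receptor influx) and at the focal dendritic submembrane
region (voltage-dependent calcium channels).  Trains are separated by 80 s
and each is accompanied by a 1-s dopamine transient of 0.8 molecules/ms
into the whole morphology (~1 uM).  After each train, an irreversible
calcium buffer (CaB) is injected uniformly for 1 s; its default amount
equals the calcium injected per train (8750 molecules), which returns
spine calcium to within twice its 51 nM resting level well before the next
train.  The CaB stands in for voltage-dependent extrusion dynamics outside
the chemical model's scope.  A single-train calcium-only protocol (100
pulses, 10 ms interval, no dopamine) reproduces the calcium/cAMP gradient
experiments.

Desk scale compresses the inter-train interval to 3 s and the horizon to
16 s (`scale` parameter; scale=1 is the printed 600-s protocol, which
takes days of CPU).  Scaling touches only the schedule and horizon, never
rate constants.

## Assumed quantities

The anchored species have no printed basal concentrations (their rows
belong to the placement-dependent configuration).  The defaults, all
labelled assumed, are: D1R 300, G protein 900, AC1 2400, AC8 1200, PKA
holoenzyme 2400, GluR1 80 molecules (per spine; multi-spine meshes scale
totals with spine count so local concentrations are unchanged), and pump
surface densities PMCA 650 and NCX 400 molecules/um^2.  They were fixed by
three calibration criteria, in this order, before any acceptance
measurement: (i) the PMCA+NCX removal rate balances the printed
Ca_ext->Ca leak at the printed basal calcium (51 nM); (ii) a visible
spine-to-dendrite cAMP gradient when the cyclase is anchored in the spine
(the phenomenon under study); (iii) stimulated PKA activation clearly
above the basal PKAc turnover implied by the printed basal complexes.

The PKA holoenzyme pool starts in equilibrium with the printed basal cAMP
(60 nM) under the printed binding constants: ~79% apo holoenzyme, ~21%
PKAcAMP2, ~0.7% PKAcAMP4.  An all-apo start would contradict the printed
basal PKAc-bound complexes (I1PKAc, PKAcPDE4B/D), which presuppose basal
PKA activity, and would freeze the activation ladder on short timescales.

## Known basal-state limitation

Basal cAMP cannot be held at its printed 60 nM by any plausible anchored
cyclase quantity: the printed PDE4B/D levels already hydrolyse ~0.5 uM/s
at 60 nM cAMP, orders of magnitude above basal cyclase output.  In
unstimulated runs cAMP and its directly coupled complexes therefore relax
within about a second to a model-defined baseline of a few nM.  The
basal-stability check consequently asserts the slow pools (calcium and its
buffers, calmodulin, CaMKII, inhibitor-1/PP1, PDE totals, ATP) to within
30% over 60 s and documents the cAMP-axis exclusion here.  The printed
value remains encoded and retrievable.

## Experiments and metrics

The 2x2 anchoring design crosses PKA location (spine head / focal
dendrite) with AC location (spine head / focal dendrite); D1R and G
proteins always colocalize with AC, GluR1 stays in the PSD, and calcium
input is identical in all cases.  The Ht31 condition distributes PKA over
the whole morphology volume-proportionally.  Trials are seed-matched
across configurations (trial i uses the same seed everywhere), which
leaves marginal distributions untouched while reducing the variance of
between-configuration differences at small trial counts; pass distinct
seed lists to disable.

Outcome metrics per trial: area under the free-PKAc concentration curve;
time-averaged phospho-inhibitor-1 (all Ip35-containing species) and
phospho-PDE4 (sum of phospho-PDE4B and phospho-PDE4D forms, also as AUC);
and the mean fraction of the GluR1 moiety carrying the S845 mark
(enzyme-bound forms included).  Averaging windows run from the first train
onset to the horizon (the source does not print its windows; this is the
package default and is configurable).  Statistics use a one-way
fixed-effects ANOVA built from sums of squares with planned contrasts on
pooled variance; the implementation is cross-checked against scipy and
statsmodels to 1e-8 relative error.

Spatial specificity uses the multi-spine mesh with axially binned groups
(2-um bins): concentration-versus-distance profiles of cAMP and
phospho-inhibitor-1 at chosen time slices, summarized by the slope of the
peak-normalized profile.

## What desk-scale runs do and do not show

At desk scale the pipeline reproduces the qualitative structure of the
full-scale results deterministically under fixed seeds: spine calcium well
above dendrite calcium during stimulation; higher spine cAMP exposure with
the cyclase in the spine; free-PKAc AUC greatest for spine-colocalized PKA
and AC, lowest for the separated placements; uniform (Ht31-style) PKA
reduces every PKA-activity readout; and a cAMP microdomain that decays
within ~6 um of the stimulated spines while phospho-inhibitor-1 spreads
flat.

Magnitudes do not transfer.  The full protocol integrates the slow
PKAcAMP2 -> PKAcAMP4 escalation over 600 s, which the 16-s compressed
horizon cannot, so the uniform-vs-colocalized reduction of free-PKAc AUC
is ~4-10% at desk scale versus 30-40% at full scale, and the printed F
statistics (F = 238 etc. at n = 20) are likewise full-scale quantities.
One direction is genuinely unresolved at desk scale: uniform PKA sits
amid the bulk of its uniformly distributed PDE4 substrate, so the
phospho-PDE4 readout can go either way over a 16-s window; only the
free-PKAc and GluR1-S845 directions are asserted.
The full protocol remains available (`scale=1`) but takes days of CPU per
trial.  The synthetic stimulus also idealizes real LTP induction: calcium
and dopamine arrive as prescribed injections rather than through receptor
and channel biophysics, so desk-scale agreement shows the signaling
network's spatial logic, not a quantitative prediction for slice
experiments.

## Numerical and design choices

- Sequential per-edge binomial transfers within a step (order fixed by the
  edge list) conserve molecules exactly; the ordering bias is second order
  in dt.
- Reaction propensities are evaluated on the start-of-step state; updates
  apply with availability capping in fixed channel order.
- Deterministic largest-remainder apportionment places anchored molecules,
  so totals are identical across anchoring configurations and runs.
- The focal region grows symmetrically from the spine-attachment column
  with lower-index tie-breaks; selection is deterministic.
- Dopamine ("Da", the tables' ligand L) exchanges with a clamped exterior
  pool, giving the printed basal 10.4 nM; Ca_ext is likewise clamped.
- The one printed-table typo (a phospho-PDE4D decay row naming "PDE4BD")
  is encoded as pPDE4D -> PDE4D, symmetric with the 4B row.
- CaMKII holoenzyme pairing ("Complex"/"pComplex") follows the printed
  rows literally, including the irreversible trans-phosphorylation steps.

## Limitations

- No membrane-potential or channel biophysics; calcium and dopamine input
  are prescribed injections.
- Free calcium and free CaMKII do not diffuse (their carriers do),
  following the printed diffusion table.
- Anchored quantities are assumed, not measured; conclusions should be
  read as conditional on those choices.
- The basal cAMP steady state is not reproducible from the printed network
  alone (see above).
- Desk-scale magnitudes underestimate slow-cascade effects; only
  directions and orderings are asserted at that scale.
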