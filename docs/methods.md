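# Methods

This note records the models, conventions, parameter choices and known
limitations behind `memlip`, at the level of detail a user needs to judge
what a passing test does and does not demonstrate.

## Units and conventions

Lengths are nm and times ns everywhere inside the package; van der Waals
and pore radii are Angstrom, because that is the scale at which they are
consumed and reported.  Residue numbering is 1-based and taken verbatim
from the input structure, so crystal-structure residue labels map
directly.  Coordinates are stored wrapped in the periodic cell; analyses
use minimum-image distances, and the MSD unwraps displacements between
consecutive frames before accumulating them.

Headgroup definitions are per species: the phosphate bead for
POPE/POPG/POPC, and both phosphate beads plus the central glycerol bead
for cardiolipin (CL), which has a two-phosphate architecture.  This is a
documented package choice — contact analyses depend only on which beads
the annotation table marks `HEADGROUP`.

## Contact occupancy and residence

The occupancy indicator of site *i* for species *j* is ζ(t) = 1 iff the
minimum over all beads of the site's two anchor residues × all headgroup
beads of the species is ≤ δ (the boundary itself counts as contact).
Cutoff defaults: 0.7 nm for POPE/POPG; CL uses 0.8 nm for residue-level
contacts and 1.1 nm for site-level occupancy, reflecting its larger
headgroup and caged bound motion, with a standard sensitivity scan over
0.8–1.6 nm.  Series are taken at a fixed 0.3 ns interval by nearest-frame
selection (never interpolation) and never smoothed: smoothing would
suppress exactly the fast rebinding events that distinguish the weakly
bound species.

Binding events are maximal runs of ζ = 1 at species level, so the
occupant identity may change within one event; duration is
n_samples × interval (an isolated occupied sample lasts one interval).
Events truncated by the trajectory boundaries are flagged censored and
excluded from mean-residence estimates, avoiding the length bias of
incomplete dwells.  Exchange counting uses the restrictive single-lipid
rule: only samples where the site holds exactly one occupant enter, and an
exchange is an identity change between consecutive samples of that
restricted subsequence.

Residue-level contact profiles offer the two normalizations in use for
such data: counts divided by lipids × frames × the cutoff-volume ratio
(δ_species/δ_ref)³ with δ_ref = 0.7 nm (so the POPE/POPG divisor is 1 —
the reference is a package choice, recorded here because the convention
varies), and counts divided by the per-species maximum over residues (top
residue ≡ 1).

## Enrichment ratio S

S divides the mean per-leaflet headgroup density in the annulus 0–3 nm
from the protein centre of mass by the mean density at 3.5–6 nm.  The
protein COM is computed from backbone-CA beads globally (not per leaflet).
Footprint masking is ON by default: positions and area inside the lateral
protein footprint (convex hull of protein beads, dilated by the largest
bead radius) are excluded from both annuli, so S compares densities over
lipid-accessible area.  With masking off, uniform lipids give S < 1
because the footprint dilutes the near annulus — both behaviours are
asserted in the tests precisely because the choice changes S.  The
site-local variant (numerator = density inside the binding-site discs)
does **not** mask its own discs: bound lipids sit at the protein surface
and masking would remove the very density being measured.

Two computational routes exist: a gridded density map (0.2 nm cells by
default, fine enough to resolve the ~0.5 nm packing rings of annular
lipids; frames merged after a per-frame rigid superposition of the protein
onto the first frame) and a grid-free radial count with numerically
integrated accessible areas, which is what the recovery tests use since it
has no discretization bias.  Standard errors come from 10 contiguous
frame blocks.

## Lateral diffusion

MSD is computed over xy only, FFT-accelerated over all time origins and
averaged over lipids (one headgroup-centroid track per molecule); D is the
fitted slope/4 over a lag window of 10–50% of the maximum lag, skipping
the discrete-step microdynamics at short lags and the poorly averaged
tail.  A quadratic-term diagnostic flags fits where the MSD is visibly
non-linear (e.g. drift).  The quoted error is the fit standard error of
the slope and is labelled as such; block-averaged errors would be larger.

## Superposition metrics

Rigid-body fits are proper-rotation least squares (no reflection),
requiring ≥ 3 non-collinear points.  RMSF superposes each frame onto the
trajectory-mean structure (two fixed-point iterations).  Gate motion is
probed by the distance of a probe Cα (residue 350 by default) from its
reference position after fitting only the core-domain Cα set; core/gate
residue sets are user configuration, since they derive from the particular
crystal structure being analysed.

## Pore profile

At each plane z along the transport axis the profiler maximizes
f(x, y) = min over beads (|centre − bead| − bead radius), i.e. the radius
of the largest sphere centred in that plane that avoids all protein beads,
using full 3D distances with beads within ±10 Å of the plane.  The search
is a coarse 0.5 Å grid within 5 Å of the previous plane's optimum
(channel continuity) refined by Nelder–Mead; the refined value never falls
below the coarse optimum, and the result is always ≥ the on-axis value.
Radii are banded RED < 1.15 Å ≤ GREEN ≤ 2.3 Å < BLUE, with strict
inequality on the RED side ("lower than"), so a plane at exactly 1.15 Å
is not closed; negative radii (fully occluded planes) clamp to 0 for
banding.  Planes with no bead in the slab report the search cap and are
flagged.  For very small test fixtures the continuity region must be kept
inside the cavity (the open exterior is otherwise a larger "pore"); real
proteins provide the enclosure naturally.

## Synthetic generator

Each lipid is a single headgroup bead confined to its leaflet plane
(z = ±leaflet_z), diffusing by Metropolis-adjusted Brownian steps:
Gaussian proposals with per-axis variance 2·D·dt, rejected inside the
static protein disc, and accepted against the annular well energy
(u = −ε between the well radii, 0 outside) with probability
min(1, e^(−Δu)).  Metropolis rather than Langevin dynamics is a deliberate
choice: detailed balance gives the exact equilibrium density ∝ e^(−u) on
the accessible area, so the expected enrichment ratio is e^ε in closed
form, and for small dt the free diffusion constant is still D.  Initial
placement samples that equilibrium directly (dart throwing with a minimum
spacing; an impossible request errors out).

Sticky sites hold one occupant.  An unbound lipid within the capture
radius of a free site's anchor binds with probability p_on per step;
while bound it is resampled uniformly in the accessible part of the
capture disc (the cage) and escapes with probability 1 − e^(−dt/τ) per
step — exponential residence with mean τ, independent per species.
Capture requires both proximity and the p_on coin so the on-rate is
decoupled from the off-rate.  The anchor pair of each site is rendered as
two designated protein residues; a site may carry a radial offset placing
its pocket centre beyond the rim ring, reflecting that headgroups bind at
contact distance from the anchor residues rather than on top of the
backbone bead.  Everything is deterministic given the seed.

Default parameters emulate the study conditions at native scale: a
14 × 14 nm patch, protein radius 2 nm, 400 lipids at 75/20/5
POPE/POPG/CL, dt = 0.3 ns (the analysis sampling interval), protein-free
diffusion constants 6.2/5.9/4.5 ×10⁻⁷ cm²/s, a 0.25 kT annular well
(S ≈ 1.3, the scale observed for the anionic species), and three
CL-favouring sites — two cytosolic, one periplasmic — with residence
ranking site 1 > site 2 > site 3.  Site residences default to 30/20/12 ns
for CL: deliberately scaled down from the hundreds-of-ns scale of
multi-microsecond production simulations so that hundreds of completed
events fit in a desk-scale run; the estimators are scale-free.

What the generator does **not** emulate: lipid shape and tails, protein
flexibility, inter-lipid interactions (ideal-gas in-plane statistics),
solvent, and electrostatics.  Passing recovery tests therefore
demonstrates estimator correctness on data satisfying the analyses'
statistical assumptions — not force-field realism.

## Recovery study conditions

Chosen from first-principles bias analyses, then frozen:

- **Enrichment recovery**: ε = ln 2 well spanning the near annulus,
  1000 lipids (75/20/5 mixture) in an 18 × 18 nm box, 50 000 steps
  recorded every 10.  The grid-free S estimator is exact in expectation
  here (Boltzmann equilibrium + consistent area integration); measured on
  the 750-lipid majority species, sampling noise is ~1–2%.
- **Residence recovery** (τ = 30 ns, dt = 0.3 ns): occupancy events only
  coincide with single bound dwells in a dilute, sharp-capture regime.
  Ambient passers-by are eliminated by making capture certain on zone
  entry (p_on = 1) with the measurement cutoff equal to the capture
  radius (0.1 nm, co-located anchors), and rebinding-merges are suppressed
  by placing the pocket centre 1.3 nm off the rim (so wall-rejected moves
  cannot trap a released lipid in the zone) and using a fast-diffusing
  species (4.2 ×10⁻⁶ cm²/s, the coarse-grained effective scale), which
  leaves the zone in about one step.  Predicted residual bias ≈ +2–3%
  (entry-frame offset, corrected by subtracting one sampling interval per
  the geometric law E[duration − dt] = dt/(1 − e^(−dt/τ)), plus ~2%
  re-capture merges); 6 sites × 100 000 steps yield ~1800 completed
  events (sampling error ~2.3%).
- **Diffusion recovery**: ε = 0, no sites, 512 lipids × 8000 steps in a
  30 nm box (protein area fraction < 1%, so obstruction is negligible);
  the slope-fit noise over the default window is then ~2%.
- **Knockout (mutant mimic)**: two sites on opposite leaflets, 150 000
  steps; the knocked-out site's occupancy is compared against a run with
  all sites disabled (ambient passage), and the untouched site's mean
  residence across runs differs only by sampling error (~6% at ~450
  events per run).

## Numerical choices and degenerate inputs

Distance-at-cutoff counts as contact (≤, per the indicator's definition).
Leaflet assignment: midplane = mean z of all lipid headgroup beads; an
exact tie falls back to the molecule-mean z, then to INNER.  Nearest-frame
resampling is the identity when the trajectory interval already matches.
Single-frame trajectories load with a warning (interval undefined).
Zero bulk density makes S undefined (NaN with a warning); an empty bulk
annulus is an error.  The longest-events tie-break is earlier start time.
Ion balancing is exact integer arithmetic and errors rather than returning
a negative count; the salt path uses round(molarity × waters / 55.5) for
Cl⁻.  The text trajectory format writes 6 decimals (nm), so round trips
preserve coordinates to that precision.

## Known limitations

Occupancy-based mean residence is only an unbiased estimate of the
single-lipid dwell time in the dilute regime described above; at realistic
densities species-level events merge across exchanges (by design — that is
what the exchange counter quantifies) and their durations exceed
single-lipid dwells.  The density-map route to S carries a small
discretization bias at annulus boundaries (use the grid-free route for
quantitative work).  The pore profiler assumes a single connected channel
near the seeded axis; it does not detect branched or strongly tilted
paths.  Trajectory readers trust the file's time stamps; files without
time information get frame indices scaled by the declared interval only in
the text format.
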