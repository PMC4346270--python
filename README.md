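# memlip

Trajectory analysis of lipid–protein interactions for membrane
transporters: binding-site occupancy and residence times, annular lipid
enrichment, lateral diffusion, superposition metrics, and pore-radius
profiling — together with a synthetic membrane-trajectory generator that
provides exact ground truth for every estimator.

## Who this is for

Simulators studying how specific lipids (cardiolipin in particular)
organize around membrane proteins in mixed bilayers, e.g. a bacterial
inner-membrane transporter in POPE/POPG/CL.  The package takes a structure
(GRO/PDB) plus a species/role annotation table and a trajectory
(XTC/TRR/DCD or a plain-text fallback), and quantifies:

- **Contact occupancy** ζᵢⱼ(t): 1 when the minimum distance between a
  binding site *i* (represented by its two anchor residues) and the
  nearest headgroup of lipid type *j* is ≤ δ, else 0.  Default cutoffs:
  δ = 0.7 nm for POPE/POPG; for the bulky CL headgroup 0.8 nm at residue
  level and 1.1 nm for site occupancy, with a sensitivity scan over
  δ = 0.8–1.6 nm.  Series are sampled every 0.3 ns and never smoothed.
- **Binding events**: maximal runs of ζ = 1, their durations, the top-k
  longest stretches, and single-lipid exchanges (identity changes of a
  sole occupant between single-occupant samples).
- **Enrichment ratio** S = ⟨ρ⟩(0–3 nm) / ⟨ρ⟩(3.5–6 nm): mean per-leaflet
  headgroup density in the annulus adjacent to the protein over the bulk
  annulus; S > 1 means enrichment.  A site-local variant restricts the
  numerator to the binding-site discs.
- **Lateral diffusion**: D = slope/4 of the time-origin-averaged lateral
  MSD, in cm²/s.
- **Superposition metrics**: Kabsch RMSD/RMSF and a gate-motion probe
  (distance of a probe Cα — residue 350 by default — after a core-domain
  fit).
- **Pore profile**: largest-sphere radius along the transport axis,
  colour-banded RED < 1.15 Å ≤ GREEN ≤ 2.3 Å < BLUE; a window is *closed*
  when its minimum radius is below 1.15 Å.
- **System composition accounting**: the random POPC→POPE/POPG/CL
  exchange plan (two POPC per CL) and exact neutralizing-ion arithmetic.

The synthetic generator (`memlip.synth`) emulates the statistical
structure these analyses assume — Brownian lateral diffusion, a Boltzmann
annular well (equilibrium density ∝ e^ε, so S → e^ε), discrete sticky
sites with exponential escape and "rattling-in-a-cage" bound motion — with
every true parameter recorded in a `GroundTruth` object.

## Worked example

Generate a bilayer patch around a protein disc with an annular well and
three CL-favouring sites, then analyse it:

```
$ memlip synth --config synth.yaml --seed 11 --out demo_out
wrote synthetic system (3001 frames, 470 beads) to demo_out

$ memlip enrich --structure demo_out/system.gro \
    --annotation demo_out/annotation.csv \
    --trajectory demo_out/trajectory.txt \
    --species POPG --leaflet INNER --out demo_out
S(POPG, INNER) = 1.811 +/- 0.184

$ memlip residence --structure demo_out/system.gro \
    --annotation demo_out/annotation.csv \
    --trajectory demo_out/trajectory.txt \
    --site site1:INNER:65,66 --species CL --out demo_out
15 events; occupancy fraction 0.880; mean residence 50.14 ns

$ memlip neutralize --charges "-84,-42,6" --n-cl 176
296 Na+ and 176 Cl- (residual charge 0 e)
```

with `synth.yaml`:

```yaml
n_steps: 3000
box: [14.0, 14.0]
protein_radius: 2.0
well: [2.0, 3.0, 0.35]
```

Reading the numbers: the well depth 0.35 kT predicts an equilibrium
enrichment of e^0.35 ≈ 1.42 for every species; the measured POPG
S = 1.81 ± 0.18 over only 900 ns of a 14 nm patch is consistent at ~2
standard errors.  Site 1 is continuously occupied by some CL 88% of the
time and its mean continuous-occupancy stretch (50 ns) exceeds the
single-lipid mean residence (30 ns) because occupants can exchange without
the site ever falling vacant.  The ion arithmetic reproduces the exact
neutralization balance: Na⁺ − Cl⁻ = −(−84 − 42 + 6).

The same stages run as one pipeline from a YAML config
(`memlip run --config run.yaml`), writing per-stage CSV/OpenDX outputs and
a machine-readable `summary.json`; unknown config keys are rejected before
any computation and two runs with the same config and seed produce
byte-identical summaries.

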