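# Methods

## Scope and model

`cphprep` prepares inputs for constant-pH MD in the λ-dynamics
formulation: each titratable site carries a continuous protonation
coordinate λ ∈ [0, 1] whose end states are the physical protonation
states. The package performs no dynamics itself. Everything it writes —
thermostat and barostat settings, PME and van-der-Waals cutoffs, the
λ-particle mass (5 amu) and λ-thermostat time constant (2.0 ps), the
biasing-barrier height (default 7.5 kJ/mol) — is emitted as literal
run-parameter text for an external engine, never simulated. The one piece
of numerical science the package owns is the two-step parametrization of
the correction potential *V*ᴹᴹ, described below, which is exercised
end-to-end against a built-in exact sampler.

## Structures and units

Coordinates are stored in nm (the GRO convention); PDB I/O converts from
Å. All distance cutoffs are quoted in nm: candidate-water cutoff R_c =
0.5, density-count radius R = 1.0, ion/buffer minimum placement distance
0.6. Distance comparisons use ≤ (a point exactly at the cutoff is inside).
Periodic distances use the minimum-image convention and are only supported
for rectangular boxes; triclinic boxes are rejected with an error rather
than silently mishandled, since every distance in the pipeline would
otherwise be wrong. Neighbour queries run through a k-d tree with an exact
distance confirmation pass, and tests assert equality with an all-pairs
scan. Whether published cavity-water criteria intend periodic images is
not specified; the package exposes `pbc` as a flag on neighbour counting
and uses non-periodic distances in the cleanup algorithms, where solutes
sit in the box interior.

## Group types and charges

A group-type definition carries alias residue names, the titratable atom
list, common-state charges `qqA`, and per-physical-state reference pKₐ,
charges `qqB_i`, and dV/dλ polynomial coefficients `dvdl_i`. Charges
interpolate linearly: q_i(λ) = (1−λ)·qqA_i + λ·qqB_i, with extrapolation
allowed outside [0, 1] for the ends of the TI grid. **Coefficient order
convention:** `dvdl` lines store highest power first (six numbers = a
degree-5 polynomial). The file dialect does not state an order, so this
package fixes one and uses it consistently in parsing, writing, fitting,
and the emitted run parameters; anyone importing coefficient lines
produced by other tools should verify the order matches.

The shipped default file contains an aspartate (ASPT, pKₐ 3.65) and a
three-state histidine (HSPT, pKₐ 0.0/6.53/6.92) with published reference
values, a glutamate entry (GLUT, pKₐ 4.25) whose charges are synthetic
placeholders mirroring the aspartate carboxyl (charge validation against a
force field is out of scope — charges are read, never derived), and the
±0.5 buffer particle. Single-site sanity: |Σ qqB − Σ qqA| must be an
integer within 0.02 e.

## Initial λ assignment

The deprotonated fraction at equilibrium is f = 1/(1 + 10^(pKₐ−pH)).
Initial λ snaps to the nearer end state (f ≥ 0.5 → λ = 1) rather than
starting at the fractional value: the λ-potential wells sit at the end
states, and a fractional start would place the coordinate on the barrier.
The tie at f = 0.5 goes to the deprotonated state, a documented arbitrary
choice.

For multisite groups the file convention lists one artificial common state
(`qqA`, usually all zeros) plus N physical states. How to weight the
physical states at a given pH is genuinely open; this package treats the
first listed physical state as the protonated parent (its pKₐ entry is a
dummy) and each later state i as a single deprotonation with microscopic
pKₐ_i, giving relative weight 10^(pH − pKₐ_i). The dominant state starts
at λ = 1, all others at 0, so the initial λ-vector always sums to 1. For
the shipped histidine this puts the doubly protonated form first below
pH ≈ 6.5 and a neutral tautomer above, which is chemically sensible. Ties
go to the earlier state in file order.

Missing titratable hydrogens are added 0.10 nm from their bonded heavy
atom (identified by name suffix, e.g. HD2 → OD2), pointing away from the
residue centroid. Any placement error is relaxed by the mandatory energy
minimization; the package deliberately does not attempt real hydrogen
geometry, which belongs to the topology builder. Residues missing heavy
atoms are skipped with a warning rather than aborting the run.

## Water cleanup

Both published criteria operate on candidate waters (oxygen within R_c of
any non-solvent atom) and score each candidate on the *original*
structure; removals are then applied at once. Single-pass scoring is a
deliberate choice: it is deterministic and order-independent, and the
published description mentions no iteration. The water reference point is
the oxygen; residue–residue distance is the minimum over the candidate
oxygen to all atoms of the other residue; the candidate's own atoms are
excluded from its counts (otherwise every density count would be inflated
by 3 and the ~400 bulk vs 120 cutoff calibration would shift). Ions count
as non-solvent for the candidate cutoff but never as waters. The
neighbour criterion breaks distance ties at the 20th-neighbour rank toward
the lower residue index (stable sort).

## Neutralization

Ion pairs from a salt concentration c are round(c · N_waters / 55.345),
using the molarity of pure water to convert concentration into a
per-water pair count; the species opposing the rounded net charge is then
topped up to make the total exactly zero. A net charge farther than
0.05 e from an integer is treated as a setup bug and is an error. The
default buffer count is one per titratable site; a user override above
twice the site count logs a warning. The advisory lower bound
√N_sites / 0.5 (treating per-site charge fluctuations as independent, with
maximal buffer charge 0.5) is this package's own estimate, exposed only
through `recommended_buffer_range` and never used as a default.

Placement replaces uniformly chosen eligible waters (oxygen ≥ 0.6 nm from
every non-solvent atom) one at a time with a seeded RNG (default seed 1,
explicit in `NeutralizePlan`, so system preparation is reproducible); each
placed particle immediately counts as non-solvent, so later picks keep the
minimum distance from it too.

## Two-step correction-potential parametrization

The mean force along λ, ⟨∂V/∂λ⟩, is fitted on the fixed-λ grid −0.1 …
1.1 (step 0.1, 13 points) by a degree-5 least-squares polynomial — step
one, fast but noisy. Step two inverts the sampled λ-histogram from a run
at pH = pKₐ with zero barrier: with residual free energy R(λ) the sampler
sees p(λ) ∝ exp(−R/k_BT), so R = −k_BT ln p up to an additive constant.
R is fitted with a degree-6 polynomial over the non-empty histogram bins,
differentiated analytically, and the resulting degree-5 dV/dλ update is
added coefficient-wise to the stored fit. Two numerical choices matter
here:

* the fit is done in energy space and then differentiated, never by
  numerically differentiating the histogram, which amplifies bin noise;
* empty bins are excluded rather than regularized with pseudo-counts,
  which would bias ln p; more than 50% empty bins aborts with an error.

The sign convention follows from the flattening requirement. The stored
`dvdl` line is a fit *of* the measured mean force, and the engine applies
it subtractively, so the sampled residual is R = F − V_old and the update
that flattens is ΔV = −k_BT ln p (equivalently: the *applied* correction
−V is raised wherever λ is over-visited). The closed-loop test pins this
down: sampling a deliberately mis-fit potential, reweighting once, and
resampling must reduce the flatness statistic below 0.05 — with the
opposite sign the mis-fit would double instead.

The histogram covers the sampled λ-range only; the polynomial update
nevertheless acts globally, a documented caveat for potentials whose
mis-fit confines sampling to a sub-interval. Defaults: 100 bins for the
correction, 50 for the flatness diagnostic. The flatness statistic is the
maximum absolute deviation of the sampled density from the uniform density
over the sampled range (0 = perfectly flat).

Whether a reweighting refits from scratch or adds corrections
coefficient-wise is an open design point; coefficient-wise addition was
chosen because it makes successive corrections estimated from the same
histogram commute.

## Synthetic fixtures: what they do and do not show

The fixture module replaces the MD engine for testing purposes:

* **Water boxes** are jittered cubic lattices at 1/0.31³ ≈ 33.6 waters/nm³,
  chosen to reproduce liquid-water density and hence the bulk regime of
  roughly 400 water atoms inside a 1 nm probe sphere that the density
  cleanup criterion calibrates against (its cutoff is 120).
* **Cavity systems** trap a known set of waters 0.30–0.45 nm inside a
  spherical shell of dummy atoms spaced ~0.2 nm apart, giving an exact
  ground-truth removal set; construction verifies isolation by brute
  force. The shell spacing balances two needs: trapped waters must see
  mostly shell residues among their nearest neighbours, while bulk waters
  just outside must still see ≥ 3 waters among theirs.
* **Toy proteins** provide residue- and atom-level realism (names,
  grouping, the heavy atoms each group type requires) with synthetic
  coordinates. The cardiotoxin and barnase–barstar stand-ins reproduce the
  documented titratable-residue content of the real structures (4 and 30
  sites); they are labelled synthetic and exist because the tests run
  without network access to structure databases.
* **λ-samples** are exact i.i.d. draws by inverse CDF on a 10⁴-point
  quadrature grid over [−0.1, 1.1]; **TI samples** are Gaussian draws
  around the analytic derivative. Exact sampling removes autocorrelation
  as a confounder, so the tests validate the *distributional* claims
  (Boltzmann inversion, flatness, Henderson–Hasselbalch occupancies) —
  they say nothing about kinetics, sampling efficiency, conformational
  coupling, or force-field accuracy in real systems, and the λ-particle
  mass/thermostat parameters are written to the run files but never
  exercised.

Problem sizes used by the test suite and the acceptance script — 5³–15³
water boxes, 50 random cleanup fixtures, 100 random neutralization
fixtures, 100 TI repetitions, 10⁶-sample closed loops — were chosen so the
statistical assertions have comfortable margins while the whole suite runs
in seconds on one CPU.

## Known limitations

* Parametrization supports single-site group types only; multisite
  reweighting is not implemented.
* No bonded-topology generation: the package writes a per-site end-state
  charge table (itp fragment) and delegates full topology building to an
  external tool.
* PDB output is limited to 3-character residue names (the strict column
  convention of the I/O backend); titratable forms with 4-character names
  round-trip through GRO.
* The mdp key spellings of the constant-pH engine vary between beta
  versions; the shipped logical-name → key template can be overridden per
  engine version, and no key validation against a live engine is
  attempted.
* Triclinic boxes, mmCIF, trajectory formats, altLoc handling beyond
  first-variant selection, termini chemistry, and multivalent ions are out
  of scope.
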