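# Methods

## Model overview

`dnarom` treats an electrically readable DNA memory in two coupled stages.

**Stage 1 — decoherent molecular transport.**  A double-stranded DNA
junction is described by an orthogonal Hamiltonian with one block per
nucleotide; the diagonal of each block holds that nucleotide's
molecular-orbital energies and the off-diagonal blocks the inter-nucleotide
electronic couplings.  For user-supplied electronic-structure input the
blocks are produced from Fock/overlap matrices by Löwdin symmetric
orthogonalization, `H_a = S^(-1/2) F S^(-1/2)` (computed through the
eigendecomposition of `S`; the smallest overlap eigenvalue must be
positive), followed by an orthogonal rotation assembled from the
eigenvectors of each nucleotide's diagonal sub-block.  Both steps are exact
similarity transforms: the spectrum and trace of the generalized problem
`(F, S)` are preserved, which the test suite checks to 1e-9 relative.

The junction is opened with wide-band self-energies `-i Γ/2`: contacts of
strength `Γ_L = Γ_R = 1 eV` on the 3' and 5' terminal nucleotide blocks,
and a Büttiker dephasing probe of strength `Γ_k = 10 meV` on every other
nucleotide block (`N_b = N_nuc - 2` probes).  The probes model phase
breaking: each is a fictitious terminal whose occupation floats so that its
net energy-resolved current vanishes.  Writing
`T_kl(E) = Tr_blocks(Γ_k G^r Γ_l G^a)` for all terminal pairs (the trace
over block subspaces is the multi-orbital generalization of the scalar
single-site form), the probe conditions eliminate to

    T_eff = T_LR + Σ_kl T_Lk [W^-1]_kl T_lR,
    W_kl  = (1 - R_kk) δ_kl - T_kl (1 - δ_kl),
    R_kk  = 1 - Σ_{l≠k} T_kl,

solved as a linear system (never an explicit inverse).  The terminal
current is `I = (2e²/h) ∫ T_eff(E) [f_R - f_L] dE` with
`E_fR = E_fL + qV`; the sign convention is positive current left→right for
positive bias (the electron-charge sign is absorbed into the convention, so
the reported I-V curves are positive in the read quadrant).  Probe balance
(zero reconstructed probe current at every energy) and contact-current
conservation `I_L + I_R = 0` are verified to 1e-9 relative.

Bias enters through a fixed, non-self-consistent potential ramp: base pair
`n` of `N` is shifted by `qV_n` with `V_1 = 0`, `V_N = V_bias` and
`V_n = V_bias (0.4 + 0.2 (n-2)/(N-3))` in between — 40% of the drop at each
contact, 20% linear along the strand.  Both nucleotides of a pair shift
together.  `N = 3` makes the interior expression ill-defined and is
rejected.  Self-consistent electrostatics, polaronic/inelastic effects and
time-dependent transport are out of scope.

**Stage 2 — crossbar read-out.**  Cells are nonlinear resistors described
by I-V lookup surfaces `I(V, δ)` (bilinear interpolation; `δ` is the Fermi
offset above the HOMO anchor).  Word- and bitlines are chains of
interconnect segments of resistance `R_int` (one shared parameter).  A read
applies `V_in = 1 V` to one wordline through a lead segment, leaves the
other wordlines floating (exactly disconnected), grounds every bitline at
the bottom of its column, and measures the grounding-segment currents.
Cells on floating rows can be back-fed by sneak paths, so the I-V is
extended oddly, `I(-V) = -I(V)`.  Power is the sum of `V·I` over cells and
`I²R_int` over every segment, and equals the source power to 1e-9 relative
on every converged solve.

## Numerical schemes

*Transport.*  Green's functions are dense batched inversions over the
energy grid (blocks are tens of orbitals).  Integration is trapezoidal on a
uniform grid, default step 1 meV — fine enough to resolve the 10 meV probe
broadening — over the Fermi window plus a 10 kT guard band;
`kT = 0.0259 eV` (300 K) by default since the operating temperature is a
free parameter.  Doubling the grid density changes the fixture current at
1 V by < 0.01%.  Transmission peaks are located with a relative-prominence
peak finder (the HOMO resonance and its bias-induced shift).

*Crossbar (exact).*  The ladder network is solved by a structured direct
method: bitline chains are eliminated per column (tridiagonal solves),
leaving a block-tridiagonal system over wordline nodes whose block-Thomas
inverses are stored, so any new right-hand side re-solves in O(n·m²).  The
driven-row lead is a rank-one (Sherman-Morrison) update, so one
factorization serves every row of a full read-out.  The nonlinear cells are
handled by a preconditioned residual iteration: the KCL residual is
evaluated with the true table currents and corrected through the factored
network, whose cells hold secant conductances `I(V)/V` seeded at 0.05 V
(voltages below 1 µV fall back to the 0.05 V secant to avoid 0/0).
Anderson mixing (depth 3) removes the slowly contracting collective error
modes; if contraction still stalls the factorization is rebuilt at the
current tangent slopes — the exact per-cell Jacobian for piecewise-linear
tables.  The factorization is only a preconditioner, so it is built in
single precision when the cell/interconnect conductance ratio allows
(falling back to double precision when weak cells leave the wordline chains
nearly floating); the converged solution is fixed by the double-precision
residuals, with tolerance 1e-10 relative to the source current
(`V_in/R_int`), comfortably inside the 1e-9 KCL bound asserted in tests.
The solver is validated against an independent scipy sparse netlist solve
to 1e-10 on linear arrays, and — for nonlinear cells — by re-solving the
netlist at the converged secants.

*Crossbar (parametric).*  The closed-form wordline voltage distribution

    V_ij = [1 + Σ_{k>j} G_ik Σ_{w=j+1..k} 1/g] /
           [1 + Σ_k   G_ik Σ_{w=1..k}   1/g] · V_in α_i

is iterated against the conductance update `G_ij = I(V_ij)/V_ij` from a
0.05 V seed (damped 0.5 on oscillation), then `I_ij = β_j I(V_ij)`.  Two
denominator conventions are implemented: the *literal* form, whose inner
sums are empty for `k ≤ j` so the fraction collapses to `V_in α_i`, and the
*full* form starting the denominator sum at `w = 1`, which accumulates the
wordline voltage divider.  Calibrated against the exact solver on the
homogeneous 64×64 array at 10 kΩ, the full form agrees to 1.4% RMS in the
read-out map while the literal form misses by 16%; the full form is
therefore the shipped default, with the literal form kept selectable.

The sneak factors have no closed form here; they are defined operationally:
the homogeneous linear array at the mean cell conductance is solved exactly
for every driven row, `α_i` is the mean over columns of the ratio between
the solved driven-row voltage and the closed-form fraction, and `β_j` the
mean over rows of measured bitline current over the driven cell's own
current.  Both are bias-independent (verified at two read biases to 1e-9).
`α_i` lies in (0, 1] and grows toward the grounded edge.  `β_j` is positive
but *exceeds 1* in far columns: floating rows feed net sneak current into
those bitlines, so the measured current tops the driven cell's own.  A
consequence worth noting: the parametric map places the weakest read at the
far corner of the *first* row (smallest `α`), whereas the exact solution
places it at the far corner of the row nearest the ground, which lacks the
sneak boost; the two maps still agree to a few percent RMS in the
moderate-interconnect regime where the parametric model is meant to be
used.

*Thresholding.*  The read threshold minimizes misclassifications over all
midpoints of the pooled sorted currents (ties to the lower threshold); a
cell reads logic 1 above threshold.  BER is reported in percent.

*Reproducibility.*  One master seed spawns an independent substream per
Monte Carlo simulation (`numpy` SeedSequence), so runs are bit-identical
for identical configurations regardless of interruption or ordering.

## Synthetic surrogates

The electronic-structure matrices of the two studied heptamers
(3'-CCCTCCC-5' "CT1C" and 3'-TTTCTTT-5' "TC1T") are not distributed, so the
fixture generator builds tight-binding stand-ins: a two-leg ladder with
seven HOMO-manifold orbitals per contacted-strand nucleotide (graded
energies and hoppings), one off-resonant orbital per complementary
nucleotide, weak injection junctions next to the contacted terminal
nucleotides, and a rigid shift placing the HOMO exactly at -5.2 eV.  The
multi-orbital ladder is essential, not decorative: under the 40/20/40 ramp
the contact junctions detune by up to 0.4 eV at 1 V, and a single-orbital
chain then shows strong negative differential resistance; a ladder of
orbitals keeps states flowing into the bias window at every bias, which is
what makes the surrogate I-V monotone (as the real multi-orbital duplexes
are).  It also exercises the engine's block-trace transmission path.

The surrogate defaults are a calibration, not a physical claim.  They were
chosen once so that the fixtures sit in the regime the array studies
require — low-bias resistance in the MΩ-GΩ band, read currents of a few to
a few tens of nA (cells of tens of MΩ at 1 V; substantially more conductive
cells let wordline droop destroy even the 10 kΩ read-out at 128×128),
logic-1/logic-0 current contrast of 7 at 1 V with contrast 2.5 remaining
between a logic-1 cell at δ = 0.2 eV and a logic-0 cell at δ = 0, and
current strictly decreasing in δ — and then frozen: CT1C-like spacing
0.11 eV with full deep hoppings, TC1T-like spacing 0.14 eV with deep
hoppings scaled 0.6 and the weakly coupled band top scaled 1.2, contact
junction scale 0.045.  Every generated table is checked against this
contract at generation time.  With these fixtures the arrays reproduce the
qualitative regime map: error-free read-out at 10 kΩ for 64×64 and 128×128
(with and without Fermi variability up to 0.2 eV), a small error rate at
100 kΩ, and sneak-dominated error rates of tens of percent at 1 MΩ, with
read power decreasing as `R_int` grows.

What the surrogates do **not** capture: the quantitative I-V curves, HOMO
peak shifts (10.4%/8.5% for the real CT1C) or absolute BER/power figures of
the DFT-derived duplexes; backbone/counterion electronic structure;
conformational fluctuations (a static structure and a single seeded on-site
disorder realization stand in for them); and any write process (the device
is a ROM).  Passing tests therefore demonstrate the correctness and the
qualitative regime structure of the simulation machinery, not quantitative
predictions for real sequences.

Benchmark images are Gaussian-smoothed random fields, rank-normalized and
grey-warped so that mid-grey thresholding yields an exact target bit load;
targets are drawn normal(60%, 8%) clipped to [40, 80]%, concentrating the
benchmark in the critical 50-70% band.  User image folders are binarized at
the whole-image median instead (mid-grey is meaningless for arbitrary
exposure); a median rule is deliberately *not* used for the synthetic set,
since on same-size images it would pin every bit load at 50% and defeat the
bit-load sweep.  Images larger than the array are center-cropped.

## Problem sizes

Default study sizes keep every stage at desk scale: the bundled regime-map
test runs 100 Monte Carlo simulations per interconnect value on 32×32
arrays; the acceptance script runs the spec's full conditions — 50 images
on 64×64 and 128×128 arrays and 2×100 Monte Carlo simulations on 64×64 —
in a few minutes of one CPU.  The solver's per-read cost is O(n·m²) after
one O(n·m³) factorization per array, so 10³×10³ arrays remain tractable.

## Known limitations

* The probe-elimination matrix `W` is ill-conditioned where all
  transmissions vanish (deep in the gap); the elimination is solved
  per-energy and raises a dedicated error with the condition estimate if it
  is singular, but values of `T_eff` far below ~1e-14 are at the numerical
  floor.
* The coherent limit `Γ_k → 0` converges linearly in `Γ_k`; at
  `Γ_k = 1e-9 eV` the surrogate's narrow band-top resonance still deviates
  by ~2% relative, reaching the sub-0.1% regime around `1e-11 eV`.
* Interconnects are purely resistive: capacitance, transients and read
  latency are out of scope, as are selector devices and WRITE operations.
* The parametric α/β model degrades when `R_int` is within an order of
  magnitude of the cell resistance (132% RMS at 1 MΩ on 64×64); it is an
  approximation for the moderate-interconnect regime only.
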