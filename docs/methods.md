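# Methods

## Model and scope

`aotrunc` implements restricted closed-shell RT-TDHF for fixed nuclei in a
Gaussian AO basis, and on top of it a basis-truncation scheme and a
complete-basis-set (CBS) growth loop for absorption spectra. Everything is
in Hartree atomic units internally (lengths in Bohr); XYZ files are read
and written in Ångström. Only neutral/even-electron, spin-restricted
systems are supported — the indicator analysis rests on a closed-shell SCF
reference.

The electronic-structure layer is deliberately self-contained:
McMurchie–Davidson integrals (overlap, kinetic, nuclear attraction,
origin-referenced dipole, dense two-electron integrals with Boys-function
recursions via `scipy.special.hyp1f1`), real-solid-harmonic (5d/7f)
contraction for **all** basis families including Pople sets, RHF with DIIS
(density convergence 1e-10), and the ETRS propagator. Dense ERIs limit
practical system sizes to a few dozen AO functions, which covers the
desk-scale fixtures the package ships; the `IntegralSet`/Fock-builder
contract is the seam where a larger backend could be plugged in.

## Propagation

The δ-pulse exp(−iκ·r) is applied to the converged occupied orbitals in
the S-metric, C(0⁺) = S^(−1/2) exp(−i S^(−1/2)(κ·D)S^(−1/2)) S^(1/2) C₀,
so S-orthonormality holds to machine precision. Each ETRS step evaluates
U = exp[−(i/2)S⁻¹(F(t)+F(t+Δt))Δt] exactly by eigendecomposition in the
Löwdin-orthogonalized basis; F(t+Δt) is iterated to self-consistency
(fixed point on ‖ΔP‖_F < 1e-8, predictor F(t), at most 20 iterations —
the literature specifies only "self-consistently", these tolerances are
package choices). Consequences verified by the test suite: S-unitarity
and Tr(PS) electron-count conservation at every step, local error O(Δt³),
exact time reversal, and energy drift ~1e-12 Hartree over 10,000 steps.

Only the occupied MOs are propagated and recorded. Virtual columns never
enter the density P = C f C†, and if they were carried along they would
evolve by bare e^(−iεt) phases whose standard deviation is O(1) — which
would bury the propagation-stability indicator (every function would look
"important" through its virtual-MO amplitudes, and nothing would ever be
deletable). The per-MO sum in x^IP therefore runs over the propagated
(occupied) orbitals. This is also what makes the H2-dimer benchmark
behave: the p_x/p_y polarization functions score ~1e-3 on x^IP instead of
~0.5.

The dipole signal includes the (constant) nuclear term; it is removed by
the baseline subtraction before Fourier transform, so spectra are
unaffected.

## Indicators and truncation

O_μ(t) = (P(t)S)_μμ is the Mulliken electron count associated with χ_μ;
its time variation is translation invariant (verified to <1e-6 under a
10-Bohr rigid shift), which is the reason this form is used rather than
any dipole-matrix-based decomposition. The standard deviation of a
complex series is the population form sqrt(mean|z − z̄|²) — the
single documented convention, isolated in `complex_std`. The t = 0⁻
(pre-pulse) frame is excluded; the series starts at the kicked state 0⁺.
A series whose variance sits at the numerical noise floor (mean numerator
below 1e-9, e.g. an unpulsed run) raises a degenerate-trace error rather
than returning noise-normalized indicators.

Deletion is the joint criterion: χ_μ is kept iff x_μ^DC > x^thr or
x_μ^IP > x^thr, so exact ties at the threshold are deleted. At shell
level a shell survives iff strictly more than half of its members
survive; before a shell is discarded, any member with
x^DC ≥ 2·x^thr triggers a warning (a strong dipole contributor would be
lost). The Jaccard index uses strict `<` sets and defines 0/0 := 0, so
bases with no deletable functions read J = 0. Function-level truncation
produces partial shells that cannot be expressed in a standard basis-set
file; they are carried in memory (`m_indices` masks) and the file writer
refuses them, while shell-level truncations are written as plain files,
with per-atom element classes (`H.1`, `H.2`, …) when symmetry-inequivalent
atoms truncate differently.

## Synthetic fixtures and what the tests show

The H2-dimer generator (r_HH = 1.4 Bohr, 6 Bohr separation, bonds along
z, atoms in the xz plane) realizes the symmetry argument that makes the
benchmark interpretable: a z pulse cannot drive π-type transitions, so
p_x/p_y must come out deletable. The water-dimer generator builds a
standard hydrogen-bonded arrangement (r_OH = 0.9572 Å, ∠HOH = 104.52°,
donor O–H on the O–O axis). Both are deterministic. The bundled 6-31G
family files carry the standard published exponents; the shipped
`tz-synthetic` basis reproduces only the *shell structure* of an augmented
triple-zeta set (H 3s3p1d / O 6s4p3d1f) with synthetic exponents and is
used for structural and counting tests, not for quantitative energies.
Passing tests on these fixtures demonstrate the scheme's selection logic,
conservation laws and spectral stability on small high-symmetry systems;
they do not probe large low-symmetry molecules, effective-core
potentials, or DFT exchange-correlation, all outside scope.

A note on the Jaccard diagnostic: with these fixtures the two criteria
agree exactly (J = 1) at small thresholds and at the operative deletion
thresholds, but J dips to 0.5–0.75 in threshold bands where single
functions (p_z, the diffuse 3s) lie below one indicator and above the
other. The dip is robust to the dimer separation (3–10 Bohr), the pulse
strength (1e-3–0.2 a.u.) and the complex-std convention; the deleted sets
themselves are unaffected.

## Spectra

The induced dipole along the pulse axis is baseline-subtracted, damped by
exp(−γt) (default γ = 0.004 a.u.⁻¹ of time ≈ 0.1–0.2 eV width, chosen for
10,000-step runs at Δt = 0.2; always identical across compared spectra),
zero-padded 4× and Fourier transformed; intensity is ω·Im d̃(ω)/|κ|.
Basis-truncation accuracy is quantified by greedy nearest-neighbor
matching of peak positions within 1 eV — a relative metric insensitive to
the common damping/grid choices. Isotropic spectra average three
Cartesian pulse runs.

## Add-While-Truncate

Each cycle: short RT run → shell-level truncation → one even-tempered
diffuse candidate per surviving l-channel (from the two smallest distinct
exponents of the channel; channels with fewer cannot be extrapolated and
are skipped) → candidates that match any previously deleted shell
(keyed by atom, l, exponents rounded to 10 digits) are discarded → union
→ smallest |overlap eigenvalue| check. On overcompleteness
(|λ|_min < ϵ, default ϵ = 1e-6) the *current cycle's* candidates are
removed in order of decreasing angular momentum (ties: most diffuse
first) until the bound clears, then one confirming cycle runs and its
truncated set is the CBS; earlier cycles' shells are never removed by
this rule. If even the bare truncated set violates ϵ (e.g. ϵ = ∞), the
loop stops after the first cycle with that truncated set. A basis that
neither deletes nor adds terminates as a fixed point. The loop is capped
at 10 cycles and raises with its log if it oscillates. Polarization
functions are only ever removed, never added.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| κ | 1e-3 a.u. | δ-pulse impulse; linear-response regime (doubling test in suite) |
| Δt | 0.2 a.u. | ETRS timestep |
| indicator run | 100 steps | ≈1% of a 10,000-step production run |
| x^thr | 0.1 | joint deletion threshold (empirical; 0.2 = more aggressive) |
| ϵ | 1e-6 | overlap-eigenvalue overcompleteness bound for CBS |
| γ | 0.004 a.u.⁻¹ | spectral damping |
| SCF / ETRS tolerances | 1e-10 / 1e-8 | density convergence norms |

## Known limitations

Dense O(N⁴) ERIs in memory (no Schwarz screening by default, matching the
small-fixture setting; a screening hook is not implemented), HF only
(the Fock-builder hook admits other mean fields but none ship), no ECD/
rotatory strengths, no pseudopotentials or general contraction, and the
x^IP indicator is gauge-dependent through the propagated orbitals — it is
meaningful for the ETRS propagation scheme used here.
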